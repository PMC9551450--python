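import numpy as np
import pandas as pd
import pytest

from ecoassembly.data_model import (
    DistanceMatrix,
    OtuTable,
    SampleMetadata,
    ValidationError,
    collinearity_screen,
    derive_aridity_index,
    filter_low_count_otus,
    rarefy,
    read_metadata,
    read_otu_table,
    write_metadata,
    write_otu_table,
)


class TestOtuTable:
    def test_shape_and_labels(self, small_table):
        assert small_table.n_samples == 3
        assert small_table.n_otus == 4
        assert small_table.sample_totals().tolist() == [10, 12, 9]

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            OtuTable(np.array([[1, -2]]), ["S1"], ["O1", "O2"])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            OtuTable(np.ones((2, 2), dtype=int), ["S1", "S1"], ["O1", "O2"])
        with pytest.raises(ValidationError, match="duplicate"):
            OtuTable(np.ones((2, 2), dtype=int), ["S1", "S2"], ["O1", "O1"])

    def test_label_shape_mismatch(self):
        with pytest.raises(ValidationError):
            OtuTable(np.ones((2, 2), dtype=int), ["S1"], ["O1", "O2"])

    def test_non_integer_rejected(self):
        with pytest.raises(ValidationError, match="non-integer"):
            OtuTable(np.array([[1.5, 2.0]]), ["S1"], ["O1", "O2"])


class TestIo:
    def test_3x4_roundtrip_shape(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "#OTU ID\tS1\tS2\tS3\n"
            "O1\t1\t2\t3\n"
            "O2\t0\t0\t1\n"
            "O3\t5\t4\t2\n"
            "O4\t1\t1\t1\n"
        )
        t = read_otu_table(p)
        assert (t.n_samples, t.n_otus) == (3, 4)
        assert t.counts[0].tolist() == [1, 0, 5, 1]

    def test_negative_value_errors(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("#OTU ID\tS1\nO1\t-3\n")
        with pytest.raises(ValidationError):
            read_otu_table(p)

    def test_non_integer_cell_named(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("#OTU ID\tS1\tS2\nO1\t1\t2.5\n")
        with pytest.raises(ValidationError, match="O1"):
            read_otu_table(p)

    def test_roundtrip_random_table(self, tmp_path):
        # [DERIVED] round-trip oracle on random 10x20 table, seed 1
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 100, size=(10, 20))
        tax = {f"O{j}": f"k__Fungi;g__G{j}" for j in range(20)}
        t = OtuTable(counts, [f"S{i}" for i in range(10)],
                     [f"O{j}" for j in range(20)], tax)
        p = tmp_path / "rt.tsv"
        write_otu_table(t, p)
        t2 = read_otu_table(p)
        assert np.array_equal(t.counts, t2.counts)
        assert t.sample_ids == t2.sample_ids
        assert t.otu_ids == t2.otu_ids
        assert t.taxonomy == t2.taxonomy

    def test_comment_lines_ignored(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "# Constructed from biom file\n#OTU ID\tS1\tS2\nO1\t1\t2\n"
        )
        t = read_otu_table(p, format="biom_tsv")
        assert t.counts.tolist() == [[1], [2]]

    def test_metadata_roundtrip(self, tmp_path, small_metadata):
        p = tmp_path / "meta.tsv"
        write_metadata(small_metadata, p)
        m2 = read_metadata(p)
        pd.testing.assert_frame_equal(small_metadata.data, m2.data)


class TestFilterLowCount:
    def test_threshold_boundary(self):
        # totals 19, 20, 21 -> keep 20 and 21 ('less than 20' is strict)
        counts = np.array([[10, 10, 10], [9, 10, 11]])
        t = OtuTable(counts, ["S1", "S2"], ["O19", "O20", "O21"])
        out = filter_low_count_otus(t, min_reads=20)
        assert out.otu_ids == ["O20", "O21"]

    def test_min_reads_zero_identity(self, random_table):
        out = filter_low_count_otus(random_table, min_reads=0)
        assert np.array_equal(out.counts, random_table.counts)

    def test_against_brute_force(self, random_table):
        # [DERIVED] brute-force column-sum filter
        out = filter_low_count_otus(random_table, min_reads=200)
        expected_cols = [
            j for j in range(random_table.n_otus)
            if sum(random_table.counts[i, j] for i in range(random_table.n_samples)) >= 200
        ]
        expected_ids = [random_table.otu_ids[j] for j in expected_cols]
        assert out.otu_ids == expected_ids
        assert np.array_equal(out.counts, random_table.counts[:, expected_cols])

    def test_idempotent(self, random_table):
        once = filter_low_count_otus(random_table, min_reads=150)
        twice = filter_low_count_otus(once, min_reads=150)
        assert np.array_equal(once.counts, twice.counts)

    def test_all_removed_errors(self, small_table):
        with pytest.raises(ValidationError):
            filter_low_count_otus(small_table, min_reads=10**6)

    def test_sample_order_preserved(self, random_table):
        out = filter_low_count_otus(random_table, min_reads=100)
        assert out.sample_ids == random_table.sample_ids


class TestRarefy:
    def test_depth_equals_totals_unchanged(self, small_table):
        # all samples at their own depth: impossible (depths differ) -> use equal table
        counts = np.array([[3, 4, 3], [5, 2, 3]])
        t = OtuTable(counts, ["S1", "S2"], ["O1", "O2", "O3"])
        out = rarefy(t, 10, seed=0)
        assert np.array_equal(out.counts, counts)

    def test_row_totals_exact_and_columns_never_increase(self, random_table):
        depth = int(random_table.sample_totals().min())
        out = rarefy(random_table, depth, seed=3)
        assert (out.sample_totals() == depth).all()
        assert (out.counts <= random_table.counts).all()

    def test_deterministic(self, random_table):
        depth = int(random_table.sample_totals().min()) - 5
        a = rarefy(random_table, depth, seed=11)
        b = rarefy(random_table, depth, seed=11)
        assert np.array_equal(a.counts, b.counts)

    def test_deficient_samples_listed(self, small_table):
        with pytest.raises(ValidationError, match="S3"):
            rarefy(small_table, 10, seed=0)

    def test_grand_total_bookkeeping(self, rng):
        # 24 samples rarefied at a common depth -> grand total 24 * depth
        counts = rng.integers(5, 40, size=(24, 30))
        t = OtuTable(counts, [f"S{i}" for i in range(24)], [f"O{j}" for j in range(30)])
        depth = int(t.sample_totals().min())
        out = rarefy(t, depth, seed=1)
        assert out.total_reads() == 24 * depth

    def test_hypergeometric_mean(self):
        # [DERIVED] expected post-rarefaction count equals depth * count/N_k,
        # in the mean over 1,000 seeds, within 3 standard errors
        counts = np.array([[40, 25, 10, 5]])
        t = OtuTable(counts, ["S1"], ["O1", "O2", "O3", "O4"])
        depth, n_rep = 30, 1000
        draws = np.array([rarefy(t, depth, seed=s).counts[0] for s in range(n_rep)])
        expected = depth * counts[0] / counts[0].sum()
        mean = draws.mean(axis=0)
        se = draws.std(axis=0, ddof=1) / np.sqrt(n_rep)
        assert np.all(np.abs(mean - expected) <= 3 * np.maximum(se, 1e-9))


class TestAridityIndex:
    def test_simple_values(self, small_metadata):
        df = small_metadata.data.drop(columns=["AI"]).copy()
        df.loc[:, "MAP"] = [200.0, 1000.0, 500.0, 250.0]
        df.loc[:, "PET"] = [1000.0, 1000.0, 1000.0, 1000.0]
        out = derive_aridity_index(SampleMetadata(df))
        assert out.data["AI"].tolist() == [0.2, 1.0, 0.5, 0.25]

    def test_map_equals_pet(self):
        df = pd.DataFrame({"MAP": [500.0], "PET": [500.0]}, index=["S1"])
        out = derive_aridity_index(SampleMetadata(df))
        assert out.data["AI"].iloc[0] == 1.0

    def test_random_pairs_oracle(self, rng):
        maps = rng.uniform(50, 800, size=20)
        pets = rng.uniform(500, 2000, size=20)
        df = pd.DataFrame({"MAP": maps, "PET": pets},
                          index=[f"S{i}" for i in range(20)])
        out = derive_aridity_index(SampleMetadata(df))
        assert np.allclose(out.data["AI"], maps / pets)

    def test_zero_pet_errors(self):
        df = pd.DataFrame({"MAP": [100.0], "PET": [0.0]}, index=["S1"])
        with pytest.raises(ValidationError):
            derive_aridity_index(SampleMetadata(df))

    def test_inconsistent_ai_rejected(self):
        df = pd.DataFrame(
            {"MAP": [100.0], "PET": [1000.0], "AI": [0.5]}, index=["S1"]
        )
        with pytest.raises(ValidationError, match="AI"):
            SampleMetadata(df)


def _greedy_screen_oracle(df, variables, threshold):
    """Independent greedy re-implementation: recompute correlations each
    round, drop the violating variable with the highest mean |r|."""
    kept = list(variables)
    while True:
        c = df[kept].corr().abs()
        violating = [
            v for v in kept
            if any(c.loc[v, u] > threshold for u in kept if u != v)
        ]
        if not violating:
            return kept
        # highest mean |r| (self-correlation excluded); ties -> later position
        worst = max(violating, key=lambda v: (c.loc[v, kept].sum() - 1.0, kept.index(v)))
        kept.remove(worst)


class TestCollinearityScreen:
    def test_perfectly_correlated_pair(self, rng):
        x = rng.normal(size=10)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1, "c": rng.normal(size=10)},
                          index=[f"S{i}" for i in range(10)])
        kept = collinearity_screen(SampleMetadata(df), ["a", "b", "c"])
        assert len([v for v in kept if v in ("a", "b")]) == 1
        assert "c" in kept

    def test_no_violation_identity(self, rng):
        df = pd.DataFrame(
            rng.normal(size=(50, 4)), columns=list("abcd"),
            index=[f"S{i}" for i in range(50)],
        )
        kept = collinearity_screen(SampleMetadata(df), list("abcd"))
        assert kept == list("abcd")

    def test_post_condition_no_violating_pair(self, rng):
        base = rng.normal(size=(30, 2))
        df = pd.DataFrame({
            "v1": base[:, 0],
            "v2": base[:, 0] + rng.normal(scale=0.2, size=30),
            "v3": base[:, 1],
            "v4": base[:, 1] - rng.normal(scale=0.3, size=30),
            "v5": rng.normal(size=30),
        }, index=[f"S{i}" for i in range(30)])
        kept = collinearity_screen(SampleMetadata(df), list(df.columns))
        c = df[kept].corr().abs().to_numpy()
        np.fill_diagonal(c, 0.0)
        assert (c <= 0.7).all()

    def test_against_greedy_oracle(self):
        # [DERIVED] random 5-variable set vs brute-force greedy oracle
        rng = np.random.default_rng(42)
        base = rng.normal(size=(25, 2))
        df = pd.DataFrame({
            "v1": base[:, 0],
            "v2": 0.9 * base[:, 0] + 0.1 * rng.normal(size=25),
            "v3": base[:, 1],
            "v4": 0.8 * base[:, 1] + 0.2 * rng.normal(size=25),
            "v5": rng.normal(size=25),
        }, index=[f"S{i}" for i in range(25)])
        variables = list(df.columns)
        kept = collinearity_screen(SampleMetadata(df), variables)
        assert kept == _greedy_screen_oracle(df, variables, 0.7)

    def test_drop_override(self, small_metadata, caplog):
        kept = collinearity_screen(
            small_metadata,
            ["MAT", "TSN", "TOC", "NP", "pH"],
            drop_override=["TOC", "NP"],
        )
        assert kept == ["MAT", "TSN", "pH"]

    def test_override_without_violation_warns(self, rng, caplog):
        df = pd.DataFrame(
            rng.normal(size=(40, 3)), columns=list("abc"),
            index=[f"S{i}" for i in range(40)],
        )
        with caplog.at_level("WARNING"):
            kept = collinearity_screen(
                SampleMetadata(df), list("abc"), drop_override=["c"]
            )
        assert kept == ["a", "b"]
        assert any("no |r|" in r.message for r in caplog.records)


class TestDistanceMatrix:
    def test_invariants_enforced(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]), ["a", "b"])
        with pytest.raises(ValidationError):
            DistanceMatrix(np.array([[1.0, 0.0], [0.0, 0.0]]), ["a", "b"])

    def test_condensed_order(self):
        v = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        dm = DistanceMatrix(v, ["a", "b", "c"])
        assert dm.condensed().tolist() == [1.0, 2.0, 3.0]

    def test_tsv_roundtrip(self, tmp_path):
        v = np.array([[0, 1.5], [1.5, 0]])
        dm = DistanceMatrix(v, ["a", "b"], "test")
        p = tmp_path / "dm.tsv"
        dm.to_tsv(p)
        dm2 = DistanceMatrix.from_tsv(p, "test")
        assert np.allclose(dm.values, dm2.values)
        assert dm.labels == dm2.labels
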