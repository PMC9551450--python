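"""Core domain types and I/O.

Defines the three labelled containers the rest of the package operates on
(:class:`OtuTable`, :class:`SampleMetadata`, :class:`DistanceMatrix`),
readers/writers for the classic tab-separated OTU-table dialect, rarefaction,
low-count filtering, the derived aridity index, and a pairwise-correlation
collinearity screen for environmental variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Environmental / climatic columns recognised in metadata files.
METADATA_VARIABLES = (
    "latitude", "longitude", "altitude",
    "MAT", "MAP", "PET", "AI",
    "SM", "pH", "TSN", "TSP", "TOC", "AN", "CN", "NP",
)


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


# ---------------------------------------------------------------------------
# OtuTable
# ---------------------------------------------------------------------------

@dataclass
class OtuTable:
    """Integer count matrix of shape (n_samples, n_otus) with labels.

    Parameters
    ----------
    counts
        Non-negative integer matrix, rows are samples, columns are OTUs.
    sample_ids, otu_ids
        Ordered, unique label lists matching the matrix shape.
    taxonomy
        Optional map of ``otu_id -> lineage string``.
    """

    counts: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                bad = np.argwhere(np.mod(self.counts, 1) != 0)[0]
                raise ValidationError(
                    f"non-integer count at sample {self.sample_ids[bad[0]]!r}, "
                    f"OTU {self.otu_ids[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"OTU {self.otu_ids[j]!r}"
            )
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        if len(self.sample_ids) != self.counts.shape[0]:
            raise ValidationError("sample_ids length does not match matrix rows")
        if len(self.otu_ids) != self.counts.shape[1]:
            raise ValidationError("otu_ids length does not match matrix columns")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValidationError("duplicate OTU ids")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> np.ndarray:
        """Per-sample read depth N_k."""
        return self.counts.sum(axis=1)

    def otu_totals(self) -> np.ndarray:
        """Per-OTU total reads across samples."""
        return self.counts.sum(axis=0)

    def total_reads(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def select_otus(self, otu_ids: list[str]) -> "OtuTable":
        """Return a copy restricted to ``otu_ids`` (order preserved as given)."""
        index = {o: j for j, o in enumerate(self.otu_ids)}
        cols = [index[o] for o in otu_ids]
        tax = None
        if self.taxonomy is not None:
            tax = {o: self.taxonomy[o] for o in otu_ids if o in self.taxonomy}
        return OtuTable(self.counts[:, cols], list(self.sample_ids), list(otu_ids), tax)


# ---------------------------------------------------------------------------
# SampleMetadata
# ---------------------------------------------------------------------------

@dataclass
class SampleMetadata:
    """Per-sample coordinates, climate, and soil chemistry.

    Wraps a DataFrame indexed by sample id; columns follow
    :data:`METADATA_VARIABLES` where present.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        self.data.index = self.data.index.astype(str)
        if "pH" in self.data.columns:
            ph = self.data["pH"].dropna()
            if ((ph <= 0) | (ph >= 14)).any():
                raise ValidationError("pH outside (0, 14)")
        if {"MAP", "PET", "AI"} <= set(self.data.columns):
            ok = np.isclose(
                self.data["AI"], self.data["MAP"] / self.data["PET"], atol=1e-9
            )
            if not np.all(ok | self.data["AI"].isna()):
                raise ValidationError("AI column inconsistent with MAP/PET")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def aligned_to(self, sample_ids: list[str]) -> "SampleMetadata":
        missing = set(sample_ids) - set(self.data.index)
        if missing:
            raise ValidationError(f"metadata missing samples: {sorted(missing)}")
        return SampleMetadata(self.data.loc[sample_ids].copy())


# ---------------------------------------------------------------------------
# DistanceMatrix
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Labelled symmetric pairwise matrix with zero diagonal."""

    values: np.ndarray
    labels: list[str]
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = [str(x) for x in self.labels]
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("labels do not match matrix shape")
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("diagonal not zero")
        if np.any(self.values < -1e-12):
            raise ValidationError("negative distances")
        # enforce exact symmetry / zero diagonal after tolerance check
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i < j) vector in row-major pair order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reordered(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return type(self)(
            self.values[np.ix_(idx, idx)], list(labels), self.metric_name
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path, metric_name: str = "") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), [str(x) for x in df.index], metric_name)


def pair_labels(labels: list[str]) -> list[tuple[str, str]]:
    """Unordered sample pairs in the order :meth:`DistanceMatrix.condensed` uses."""
    n = len(labels)
    return [(labels[i], labels[j]) for i in range(n) for j in range(i + 1, n)]


# ---------------------------------------------------------------------------
# OTU table I/O — QIIME-classic TSV dialect
# ---------------------------------------------------------------------------

def read_otu_table(path, format: str = "tsv") -> OtuTable:
    """Read an OTU table from a classic tab-separated file.

    On disk OTUs are rows and samples are columns ('#OTU ID' header, '#'
    comment lines ignored, optional trailing 'taxonomy' column); in memory
    the table is samples x OTUs.

    Parameters
    ----------
    path
        File to read.
    format
        ``"tsv"`` or ``"biom_tsv"`` (the biom-style TSV export differs only
        in its leading '# Constructed from biom file' comment, which the
        comment rule already skips).
    """
    if format not in ("tsv", "biom_tsv"):
        raise ValueError(f"unknown format {format!r}")
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.lower().startswith("#otu id"):
                    header = line.split("\t")
                continue
            rows.append(line.split("\t"))
    if header is None:
        raise ValidationError(f"{path}: no '#OTU ID' header line found")
    if not rows:
        raise ValidationError(f"{path}: no data rows")

    has_taxonomy = header[-1].strip().lower() == "taxonomy"
    sample_ids = header[1 : len(header) - 1 if has_taxonomy else len(header)]
    otu_ids: list[str] = []
    taxonomy: dict[str, str] = {}
    counts = np.empty((len(rows), len(sample_ids)), dtype=np.int64)
    for i, row in enumerate(rows):
        expected = 1 + len(sample_ids) + (1 if has_taxonomy else 0)
        if len(row) != expected:
            raise ValidationError(
                f"{path}: row {row[0]!r} has {len(row)} fields, expected {expected}"
            )
        otu_ids.append(row[0])
        if has_taxonomy:
            taxonomy[row[0]] = row[-1]
            values = row[1:-1]
        else:
            values = row[1:]
        for j, v in enumerate(values):
            x = float(v)
            if x != int(x):
                raise ValidationError(
                    f"{path}: non-integer count {v!r} for OTU {row[0]!r}, "
                    f"sample {sample_ids[j]!r}"
                )
            counts[i, j] = int(x)
    return OtuTable(
        counts.T, sample_ids, otu_ids, taxonomy if has_taxonomy else None
    )


def write_otu_table(table: OtuTable, path) -> None:
    """Write in the same dialect :func:`read_otu_table` reads (OTUs as rows)."""
    with open(path, "w") as fh:
        cols = list(table.sample_ids)
        has_tax = table.taxonomy is not None
        fh.write("#OTU ID\t" + "\t".join(cols) + ("\ttaxonomy" if has_tax else "") + "\n")
        for j, otu in enumerate(table.otu_ids):
            vals = "\t".join(str(int(x)) for x in table.counts[:, j])
            tax = "\t" + table.taxonomy.get(otu, "") if has_tax else ""
            fh.write(f"{otu}\t{vals}{tax}\n")


def read_metadata(path) -> SampleMetadata:
    """Read a tab-separated metadata file; first column is the sample id."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    df.index.name = "sample_id"
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.data.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Filtering and rarefaction
# ---------------------------------------------------------------------------

def filter_low_count_otus(table: OtuTable, min_reads: int = 20) -> OtuTable:
    """Drop OTUs whose total reads across samples fall below ``min_reads``.

    'Below' is strict: an OTU with exactly ``min_reads`` reads is retained.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    keep = table.otu_totals() >= min_reads
    if not keep.any():
        raise ValidationError("filter removed every OTU")
    kept_ids = [o for o, k in zip(table.otu_ids, keep) if k]
    return table.select_otus(kept_ids)


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample without replacement to a common ``depth``.

    Uses a per-sample multivariate hypergeometric draw, so the expected
    post-rarefaction count of OTU j in sample k is ``depth * count_jk / N_k``.
    Deterministic given ``seed``.
    """
    totals = table.sample_totals()
    deficient = [s for s, t in zip(table.sample_ids, totals) if t < depth]
    if deficient:
        raise ValidationError(
            f"samples with fewer than {depth} reads: {deficient}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for k in range(table.n_samples):
        if totals[k] == depth:
            out[k] = table.counts[k]
        else:
            out[k] = rng.multivariate_hypergeometric(table.counts[k], depth)
    return OtuTable(out, list(table.sample_ids), list(table.otu_ids),
                    dict(table.taxonomy) if table.taxonomy else None)


# ---------------------------------------------------------------------------
# Derived variables and the collinearity screen
# ---------------------------------------------------------------------------

def derive_aridity_index(meta: SampleMetadata) -> SampleMetadata:
    """Populate AI = MAP / PET."""
    df = meta.data.copy()
    if "MAP" not in df.columns or "PET" not in df.columns:
        raise ValidationError("MAP and PET required to derive AI")
    if (df["PET"] == 0).any():
        raise ValidationError("PET == 0 for some samples; AI undefined")
    df["AI"] = df["MAP"] / df["PET"]
    return SampleMetadata(df)


def collinearity_screen(
    meta: SampleMetadata,
    variables: list[str],
    threshold: float = 0.7,
    drop_override: list[str] | None = None,
) -> list[str]:
    """Reduce a variable set until no pair has |Pearson r| > ``threshold``.

    Without an override, repeatedly drops the member of some violating pair
    with the highest mean absolute correlation against all other retained
    variables (ties broken by later column order). With ``drop_override``,
    exactly those variables are dropped; each is checked for membership in at
    least one violating pair and a warning is logged otherwise.
    """
    if len(variables) < 2:
        raise ValueError("need at least two variables")
    if len(meta) < 3:
        raise ValueError("need at least three samples")
    df = meta.data[list(variables)].astype(float)
    corr = df.corr().to_numpy()

    if drop_override is not None:
        absr = np.abs(corr)
        np.fill_diagonal(absr, 0.0)
        for var in drop_override:
            if var not in variables:
                raise ValueError(f"override variable {var!r} not among candidates")
            i = variables.index(var)
            if not (absr[i] > threshold).any():
                logger.warning(
                    "collinearity override drops %r which has no |r| > %.2f pair",
                    var, threshold,
                )
        return [v for v in variables if v not in set(drop_override)]

    retained = list(variables)
    while True:
        sub = df[retained]
        absr = sub.corr().abs().to_numpy()
        np.fill_diagonal(absr, 0.0)
        if not (absr > threshold).any():
            return retained
        violating = np.where((absr > threshold).any(axis=0))[0]
        mean_abs = absr.mean(axis=0)
        # highest mean |r| among violating variables; ties -> later position
        order = sorted(violating, key=lambda i: (mean_abs[i], i))
        retained.pop(order[-1])
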