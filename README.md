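# ecoassembly

Community-assembly inference for abundant and rare soil taxa. The package
takes an OTU count table plus per-sample environmental metadata and runs the
full comparative-biogeography workflow:

- **Partitioning** — classify OTUs as abundant (> 0.1% of total reads), rare
  (< 0.01%), or intermediate; occupancy profiles and abundance–occupancy
  regressions.
- **Biogeographic pattern** — Bray–Curtis β-diversity, haversine geographic
  distances, standardized environmental distances, distance-decay regression
  with permutation inference, Levins niche breadth (B) and abundance-weighted
  community breadth (Bcom).
- **Assembly inference** — abundance-based null communities preserving each
  sample's richness and depth, the β-deviation standardized effect size with
  interpretation rules, and Sloan's neutral community model (migration rate m,
  R², bootstrap CI).
- **Distance-matrix statistics** — Mantel tests, multiple regression on
  distance matrices (MRM) with forward selection, variation partitioning of
  β-deviations into pure-environment / pure-space / shared / residual
  fractions, the environment-to-space effect ratio (ESDR), and median-split
  gradient comparisons of β-deviation distributions.
- **Synthetic scenarios** — generators for neutral, dispersal-limited,
  environment-filtered, and mixed assembly regimes with exported latent truth,
  so every stage can be validated against known processes.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance suite: definitional
arithmetic checks plus statistical calibration/recovery/identifiability
properties. One criterion (neutral-model parameter recovery at ±20%/10%
tolerance) fails by design of the standard estimator: the continuous
detection-limit fit carries a structural positive bias against
count-sampled data (see the test docstring).

## CLI

```sh
ecoassembly simulate --regime dispersal_limited --seed 7 --out-dir scenario/
ecoassembly partition scenario/otu_table.tsv --out-dir partition/
ecoassembly assembly scenario/otu_table.tsv --n-null 999 --seed 1
ecoassembly stats scenario/otu_table.tsv scenario/metadata.tsv --seed 1
ecoassembly all scenario/otu_table.tsv scenario/metadata.tsv --seed 1 --out-dir analysis/
```

`all` runs filter → rarefy → partition → per-sub-community (whole / abundant
/ rare) distance decay, niche breadth, β-deviation, neutral-model fit, then
Mantel / MRM / VPA / ESDR and gradient splits, and writes TSV/JSON artifacts
plus `report.md`. Analysis options (thresholds, replicate counts, variable
lists) can be given as a YAML config via `--config`.

OTU tables use the classic tab-separated dialect: `#OTU ID` header, OTUs as
rows, samples as columns, optional trailing `taxonomy` column, `#` comments
ignored. Metadata is a TSV with `sample_id` in the first column.

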