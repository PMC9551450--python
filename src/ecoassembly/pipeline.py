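"""End-to-end orchestration: filter -> rarefy -> partition -> per-sub-community
biogeography and assembly inference -> distance-matrix statistics -> report.

All randomness descends from one master seed; each stage draws its own
sub-seed so changing, say, the null-model replicate count does not perturb
the neutral-model bootstrap.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community_metrics as cm
from . import matrix_stats as ms
from . import neutral_model as nm
from . import null_model as nulls
from . import partition as pt
from .data_model import (
    OtuTable,
    SampleMetadata,
    ValidationError,
    collinearity_screen,
    filter_low_count_otus,
    rarefy,
    read_metadata,
    read_otu_table,
)

logger = logging.getLogger(__name__)

SUBCOMMUNITIES = ("whole", "abundant", "rare")

DEFAULT_ENV_VARIABLES = [
    "MAT", "AI", "SM", "TSN", "TOC", "AN", "TSP", "CN", "NP", "pH", "altitude",
]


@dataclass
class AnalysisConfig:
    """Thresholds and replicate counts for one pipeline run."""

    seed: int = 0
    min_reads: int = 20
    rarefaction_depth: int | None = None  # None -> minimum sample total
    filter_before_rarefaction: bool = True
    abundant_min_frac: float = 0.001
    rare_max_frac: float = 0.0001
    n_null: int = 999
    n_perm: int = 999
    n_boot: int = 200
    alpha: float = 0.05
    env_variables: list[str] = field(default_factory=lambda: list(DEFAULT_ENV_VARIABLES))
    collinearity_threshold: float = 0.7
    collinearity_drop: list[str] | None = None
    gradient_vars: list[str] = field(default_factory=lambda: ["pH", "TSP"])

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in raw.items() if k in known})


def _stage_seed(master: int, stage: str) -> int:
    """Stable per-stage sub-seed derived from the master seed."""
    # str hash() is salted per process; use a deterministic digest
    digest = sum(ord(c) * 31**i for i, c in enumerate(stage)) % (2**31)
    return int(np.random.SeedSequence([master, digest]).generate_state(1)[0])


@dataclass
class SubcommunityReport:
    name: str
    n_otus: int
    total_reads: int
    ddr: cm.DdrFit
    bcom: dict[str, float]
    beta_deviation_mean: float
    deviation_test: nulls.DeviationSignTest
    interpretation: str
    ncm: nm.NcmFit
    mantel_table: pd.DataFrame
    mrm: ms.MrmResult
    vpa: ms.VpaResult | None
    gradient_splits: dict[str, ms.GradientSplit]


@dataclass
class AnalysisReport:
    partition_summary: pd.DataFrame
    retained_env_variables: list[str]
    subcommunities: dict[str, SubcommunityReport]
    bcom_comparison: cm.GroupComparison | None
    provenance: dict


def _analyze_subcommunity(
    name: str,
    table: OtuTable,
    meta: SampleMetadata,
    geo: "ms.DistanceMatrix",
    env_matrices: dict[str, "ms.DistanceMatrix"],
    config: AnalysisConfig,
) -> SubcommunityReport:
    seed = _stage_seed(config.seed, f"sub:{name}")
    bc = cm.bray_curtis(table)
    ddr = cm.distance_decay(bc, geo, n_perm=config.n_perm, seed=_stage_seed(seed, "ddr"))
    breadth = cm.levins_breadth(table)

    dev = nulls.beta_deviation(table, n_null=config.n_null, seed=_stage_seed(seed, "null"))
    dev_test = nulls.test_deviation_sign(dev)
    label = nulls.interpret_deviation(dev, dev_test, alpha=config.alpha)

    ncm = nm.fit_ncm(table, n_boot=config.n_boot, seed=_stage_seed(seed, "ncm"))

    candidates = dict(env_matrices)
    candidates["Space"] = geo
    rows = []
    for var, mat in candidates.items():
        res = ms.mantel(
            dev.beta_dev, mat, n_perm=config.n_perm,
            seed=_stage_seed(seed, f"mantel:{var}"),
        )
        rows.append({"variable": var, "mantel_r": res.r, "p": res.p})
    mantel_table = pd.DataFrame(rows).set_index("variable")

    mrm = ms.mrm_forward_select(
        dev.beta_dev, candidates, alpha=config.alpha,
        n_perm=config.n_perm, seed=_stage_seed(seed, "mrm"),
    )
    selected_env = {k: env_matrices[k] for k in mrm.selected if k in env_matrices}
    if not selected_env:  # fall back to all candidates so VPA is always reported
        selected_env = env_matrices
    vpa = None
    try:
        vpa = ms.variation_partition(dev.beta_dev, selected_env, {"Space": geo})
    except (ValidationError, ValueError) as exc:
        logger.warning("VPA failed for %s: %s", name, exc)

    splits = {}
    for var in config.gradient_vars:
        try:
            splits[var] = ms.gradient_split_deviation(dev, meta, var)
        except ValidationError as exc:
            logger.warning("gradient split on %r failed for %s: %s", var, name, exc)

    return SubcommunityReport(
        name=name,
        n_otus=table.n_otus,
        total_reads=table.total_reads(),
        ddr=ddr,
        bcom=breadth.Bcom,
        beta_deviation_mean=float(dev.condensed().mean()),
        deviation_test=dev_test,
        interpretation=label,
        ncm=ncm,
        mantel_table=mantel_table,
        mrm=mrm,
        vpa=vpa,
        gradient_splits=splits,
    )


def run_pipeline(
    otu_path, meta_path, config: AnalysisConfig, out_dir=None
) -> AnalysisReport:
    """Run the full analysis on an OTU table + metadata pair.

    When ``out_dir`` is given, TSV/JSON artifacts and a Markdown report are
    written there.
    """
    table = read_otu_table(otu_path) if not isinstance(otu_path, OtuTable) else otu_path
    meta = read_metadata(meta_path) if not isinstance(meta_path, SampleMetadata) else meta_path

    missing = set(table.sample_ids) - set(meta.sample_ids)
    if missing:
        raise ValidationError(f"metadata missing samples: {sorted(missing)}")
    meta = meta.aligned_to(table.sample_ids)

    if config.filter_before_rarefaction:
        table = filter_low_count_otus(table, config.min_reads)
    depth = config.rarefaction_depth or int(table.sample_totals().min())
    table = rarefy(table, depth, seed=_stage_seed(config.seed, "rarefy"))
    if not config.filter_before_rarefaction:
        table = filter_low_count_otus(table, config.min_reads)

    part = pt.classify_otus(
        table, config.abundant_min_frac, config.rare_max_frac
    )

    env_vars = [v for v in config.env_variables if v in meta.data.columns]
    retained = collinearity_screen(
        meta, env_vars, threshold=config.collinearity_threshold,
        drop_override=config.collinearity_drop,
    )
    geo = cm.geographic_distance(meta)
    env_matrices = {v: cm.variable_difference_distance(meta, v) for v in retained}

    subreports: dict[str, SubcommunityReport] = {}
    for name in SUBCOMMUNITIES:
        if name == "whole":
            sub = table
        else:
            try:
                sub = pt.subset_by_class(table, part, name)
            except ValidationError:
                logger.warning("no OTUs in class %r; skipping", name)
                continue
        if sub.n_otus < 10:
            logger.warning("class %r has < 10 OTUs; skipping", name)
            continue
        try:
            subreports[name] = _analyze_subcommunity(
                name, sub, meta, geo, env_matrices, config
            )
        except ValidationError as exc:
            logger.warning("sub-community %r not analyzable: %s", name, exc)

    bcom_cmp = None
    if "abundant" in subreports and "rare" in subreports:
        bcom_cmp = cm.compare_groups(
            list(subreports["abundant"].bcom.values()),
            list(subreports["rare"].bcom.values()),
        )

    report = AnalysisReport(
        partition_summary=part.summary,
        retained_env_variables=retained,
        subcommunities=subreports,
        bcom_comparison=bcom_cmp,
        provenance={
            "seed": config.seed,
            "rarefaction_depth": depth,
            "min_reads": config.min_reads,
            "abundant_min_frac": config.abundant_min_frac,
            "rare_max_frac": config.rare_max_frac,
            "n_null": config.n_null,
            "n_perm": config.n_perm,
            "alpha": config.alpha,
        },
    )
    if out_dir is not None:
        write_report(report, table, part, Path(out_dir))
    return report


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def report_to_dict(report: AnalysisReport) -> dict:
    subs = {}
    for name, sr in report.subcommunities.items():
        subs[name] = {
            "n_otus": sr.n_otus,
            "total_reads": sr.total_reads,
            "ddr": {
                "slope_per_km": sr.ddr.slope,
                "slope_per_100km": sr.ddr.slope * 100,
                "intercept": sr.ddr.intercept,
                "r_squared": sr.ddr.r_squared,
                "p_value": sr.ddr.p_value,
                "n_pairs": sr.ddr.n_pairs,
            },
            "bcom_mean": float(np.mean(list(sr.bcom.values()))),
            "beta_deviation_mean": sr.beta_deviation_mean,
            "deviation_p": sr.deviation_test.p_value,
            "interpretation": sr.interpretation,
            "ncm": {
                "m": sr.ncm.m,
                "r_squared": sr.ncm.r_squared,
                "NT": sr.ncm.NT,
                "ci_m": list(sr.ncm.ci_m),
                "n_otus_fit": sr.ncm.n_otus_fit,
            },
            "mantel": sr.mantel_table.reset_index().to_dict(orient="records"),
            "mrm": {
                "selected": sr.mrm.selected,
                "coefficients": sr.mrm.coefficients,
                "r_squared": sr.mrm.r_squared,
                "p_values": sr.mrm.p_values,
            },
            "vpa": None
            if sr.vpa is None
            else {
                "env_individual": sr.vpa.env_individual,
                "space_individual": sr.vpa.space_individual,
                "shared": sr.vpa.shared,
                "residual": sr.vpa.residual,
                "esdr": sr.vpa.esdr,
            },
            "gradient_splits": {
                var: {
                    "low_median": float(np.median(gs.low_values)) if len(gs.low_values) else None,
                    "high_median": float(np.median(gs.high_values)) if len(gs.high_values) else None,
                    "p": gs.comparison.p_value if gs.comparison else None,
                }
                for var, gs in sr.gradient_splits.items()
            },
        }
    return {
        "partition_summary": report.partition_summary.to_dict(orient="index"),
        "retained_env_variables": report.retained_env_variables,
        "subcommunities": subs,
        "bcom_comparison": None
        if report.bcom_comparison is None
        else {
            "statistic": report.bcom_comparison.statistic,
            "p_value": report.bcom_comparison.p_value,
        },
        "provenance": report.provenance,
    }


def write_report(
    report: AnalysisReport, table: OtuTable, part: pt.PartitionResult, out_dir: Path
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.partition_summary.to_csv(out_dir / "partition_summary.tsv", sep="\t")
    pt.partition_table(table, part).to_csv(out_dir / "partition_otus.tsv", sep="\t")
    payload = report_to_dict(report)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    for name, sr in report.subcommunities.items():
        sr.mantel_table.to_csv(out_dir / f"mantel_{name}.tsv", sep="\t")
    with open(out_dir / "report.md", "w") as fh:
        fh.write(_markdown_report(payload))


def _markdown_report(payload: dict) -> str:
    lines = ["# Community assembly analysis report", ""]
    lines.append("## Partition summary")
    for cls, row in payload["partition_summary"].items():
        lines.append(
            f"- {cls}: {row['n_otus']} OTUs ({row['otu_pct']:.2f}%), "
            f"{row['reads']} reads ({row['read_pct']:.2f}%)"
        )
    lines.append("")
    lines.append(
        "Retained environmental variables: "
        + ", ".join(payload["retained_env_variables"])
    )
    for name, sub in payload["subcommunities"].items():
        lines += ["", f"## Sub-community: {name}"]
        ddr = sub["ddr"]
        lines.append(
            f"- DDR slope {ddr['slope_per_100km']:.4g} per 100 km "
            f"(r^2 = {ddr['r_squared']:.3f}, p = {ddr['p_value']:.4g})"
        )
        lines.append(f"- mean Bcom {sub['bcom_mean']:.3f}")
        lines.append(
            f"- mean beta-deviation {sub['beta_deviation_mean']:.3f} "
            f"(p = {sub['deviation_p']:.4g}) -> {sub['interpretation']}"
        )
        ncm = sub["ncm"]
        lines.append(
            f"- NCM m = {ncm['m']:.4g} (95% CI {ncm['ci_m'][0]:.4g}-{ncm['ci_m'][1]:.4g}), "
            f"R^2 = {ncm['r_squared']:.3f}, NT = {ncm['NT']}"
        )
        if sub["vpa"]:
            v = sub["vpa"]
            esdr_txt = "undefined" if v["esdr"] is None else f"{v['esdr']:.3f}"
            lines.append(
                f"- VPA: env {100 * v['env_individual']:.2f}%, "
                f"space {100 * v['space_individual']:.2f}%, "
                f"shared {100 * v['shared']:.2f}%, "
                f"residual {100 * v['residual']:.2f}%; ESDR {esdr_txt}"
            )
    lines.append("")
    prov = payload["provenance"]
    lines.append(
        f"_seed {prov['seed']}, n_null {prov['n_null']}, n_perm {prov['n_perm']}, "
        f"depth {prov['rarefaction_depth']}_"
    )
    return "\n".join(lines) + "\n"
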