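"""Partition OTUs into abundant / intermediate / rare sub-communities.

Classification is by each OTU's share of the dataset's total reads:
strictly above ``abundant_min_frac`` is abundant, strictly below
``rare_max_frac`` is rare, everything else (including values exactly at a
threshold) is intermediate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import OtuTable, ValidationError

logger = logging.getLogger(__name__)

CLASSES = ("abundant", "intermediate", "rare")


@dataclass
class PartitionResult:
    """Class membership plus per-class OTU and read bookkeeping."""

    class_of: dict[str, str]
    thresholds: tuple[float, float]  # (abundant_min_frac, rare_max_frac)
    summary: pd.DataFrame  # index = class, columns: n_otus, reads, otu_pct, read_pct

    def otus_in(self, cls: str) -> list[str]:
        return [o for o, c in self.class_of.items() if c == cls]


def summarize_partition(
    n_otus_per_class: dict[str, int], reads_per_class: dict[str, int]
) -> pd.DataFrame:
    """Build the per-class summary from raw class counts and read totals.

    Percentages are of the whole dataset (all classes combined), reported on
    a 0–100 scale.
    """
    total_otus = sum(n_otus_per_class.values())
    total_reads = sum(reads_per_class.values())
    rows = {}
    for cls in CLASSES:
        n = n_otus_per_class.get(cls, 0)
        r = reads_per_class.get(cls, 0)
        rows[cls] = {
            "n_otus": n,
            "reads": r,
            "otu_pct": 100.0 * n / total_otus if total_otus else 0.0,
            "read_pct": 100.0 * r / total_reads if total_reads else 0.0,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def classify_otus(
    table: OtuTable,
    abundant_min_frac: float = 0.001,
    rare_max_frac: float = 0.0001,
    basis: str = "dataset_total",
) -> PartitionResult:
    """Classify every OTU by relative abundance.

    Parameters
    ----------
    table
        Count table (typically filtered and rarefied).
    abundant_min_frac, rare_max_frac
        Strict thresholds on the relative-abundance basis; defaults are the
        conventional 0.1% / 0.01% cutoffs.
    basis
        ``"dataset_total"`` (default): OTU total reads over the grand total.
        ``"per_sample_mean"``: mean of per-sample relative abundances —
        provided because part of the literature classifies on that basis.
    """
    if table.n_otus == 0:
        raise ValidationError("empty table")
    if not (0 < rare_max_frac < abundant_min_frac < 1):
        raise ValueError("need 0 < rare_max_frac < abundant_min_frac < 1")
    totals = table.otu_totals()
    if basis == "dataset_total":
        rel = totals / table.total_reads()
    elif basis == "per_sample_mean":
        props = table.counts / table.sample_totals()[:, None]
        rel = props.mean(axis=0)
    else:
        raise ValueError(f"unknown basis {basis!r}")

    class_of: dict[str, str] = {}
    n_per = {c: 0 for c in CLASSES}
    reads_per = {c: 0 for c in CLASSES}
    for j, otu in enumerate(table.otu_ids):
        if rel[j] > abundant_min_frac:
            cls = "abundant"
        elif rel[j] < rare_max_frac:
            cls = "rare"
        else:
            cls = "intermediate"
        class_of[otu] = cls
        n_per[cls] += 1
        reads_per[cls] += int(totals[j])
    return PartitionResult(
        class_of=class_of,
        thresholds=(abundant_min_frac, rare_max_frac),
        summary=summarize_partition(n_per, reads_per),
    )


def subset_by_class(table: OtuTable, part: PartitionResult, cls: str) -> OtuTable:
    """Restrict the table's columns to OTUs of one class."""
    if cls not in CLASSES:
        raise ValueError(f"unknown class {cls!r}")
    otus = [o for o in table.otu_ids if part.class_of.get(o) == cls]
    if not otus:
        raise ValidationError(f"no OTUs in class {cls!r}")
    sub = table.select_otus(otus)
    empty = [s for s, t in zip(sub.sample_ids, sub.sample_totals()) if t == 0]
    if empty:
        logger.info("subset %r leaves zero-total samples (retained): %s", cls, empty)
    return sub


@dataclass
class OccupancyProfile:
    """Per-OTU occupancy and mean relative abundance."""

    occupancy: dict[str, float]
    mean_relative_abundance: dict[str, float]

    def fraction_above(self, min_occupancy: float = 0.5) -> float:
        """Fraction of OTUs with occupancy strictly above ``min_occupancy``."""
        vals = np.array(list(self.occupancy.values()))
        return float((vals > min_occupancy).mean())


def occupancy_profile(table: OtuTable) -> OccupancyProfile:
    """Occupancy = fraction of samples where the OTU has a positive count."""
    occ = (table.counts > 0).mean(axis=0)
    props = table.counts / table.sample_totals()[:, None]
    mra = props.mean(axis=0)
    return OccupancyProfile(
        occupancy=dict(zip(table.otu_ids, occ.astype(float))),
        mean_relative_abundance=dict(zip(table.otu_ids, mra.astype(float))),
    )


@dataclass
class AbundanceOccupancyFit:
    slope: float
    intercept: float
    r: float
    p_value: float
    n_otus: int


def abundance_occupancy_fit(
    profile: OccupancyProfile, otus: list[str] | None = None
) -> AbundanceOccupancyFit:
    """OLS of occupancy on log10(mean relative abundance) over an OTU subset."""
    if otus is None:
        otus = list(profile.occupancy)
    otus = [o for o in otus if profile.mean_relative_abundance[o] > 0]
    if len(otus) < 3:
        raise ValueError("need >= 3 OTUs with positive mean abundance")
    x = np.log10([profile.mean_relative_abundance[o] for o in otus])
    y = np.array([profile.occupancy[o] for o in otus])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log-abundance predictor")
    res = stats.linregress(x, y)
    return AbundanceOccupancyFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        n_otus=len(otus),
    )


def partition_table(table: OtuTable, part: PartitionResult) -> pd.DataFrame:
    """Per-OTU export: class, totals, relative abundance, occupancy."""
    totals = table.otu_totals()
    grand = table.total_reads()
    prof = occupancy_profile(table)
    return pd.DataFrame(
        {
            "class": [part.class_of[o] for o in table.otu_ids],
            "total_reads": totals,
            "rel_abund": totals / grand,
            "occupancy": [prof.occupancy[o] for o in table.otu_ids],
        },
        index=pd.Index(table.otu_ids, name="otu_id"),
    )
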