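"""Abundance-based null communities and the beta-deviation statistic.

Each null realization preserves every sample's observed richness S_k and
depth N_k while drawing OTU identities from the regional pool in proportion
to regional relative abundance.  The beta-deviation of a sample pair is the
standardized effect size of its observed Bray-Curtis dissimilarity against
the null distribution:

    beta_dev = (obs - mean(null)) / sd(null)

A significantly positive beta-deviation indicates dispersal limitation or
heterogeneous selection; significantly negative indicates homogenizing
dispersal or homogeneous selection; indistinguishable from zero indicates
stochastic dominance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .community_metrics import bray_curtis
from .data_model import DistanceMatrix, OtuTable, ValidationError

logger = logging.getLogger(__name__)

LABEL_POSITIVE = "dispersal-limitation-or-heterogeneous-selection"
LABEL_NEGATIVE = "homogenizing-dispersal-or-homogeneous-selection"
LABEL_STOCHASTIC = "stochastic-dominated"


def _null_counts(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One null realization of a (samples x OTUs) count matrix."""
    regional = counts.sum(axis=0).astype(float)
    weights = regional / regional.sum()
    n_pool = int((regional > 0).sum())
    out = np.zeros_like(counts)
    for k in range(counts.shape[0]):
        n_k = int(counts[k].sum())
        s_k = int((counts[k] > 0).sum())
        if s_k > n_pool:
            raise ValidationError(
                f"sample richness {s_k} exceeds pool size {n_pool}"
            )
        if s_k == 0:
            raise ValidationError("all-zero sample")
        chosen = rng.choice(len(weights), size=s_k, replace=False, p=weights)
        out[k, chosen] = 1
        remaining = n_k - s_k
        if remaining > 0:
            w = weights[chosen]
            out[k, chosen] += rng.multinomial(remaining, w / w.sum())
    return out


def generate_null_community(table: OtuTable, seed: int) -> OtuTable:
    """Draw one null community table under the abundance-based null model.

    For each sample: choose S_k distinct OTUs without replacement with
    probabilities proportional to regional relative abundance, seed each with
    one individual, then distribute the remaining N_k - S_k individuals
    multinomially over the chosen OTUs with renormalized regional weights.
    """
    rng = np.random.default_rng(seed)
    out = _null_counts(table.counts, rng)
    return OtuTable(out, list(table.sample_ids), list(table.otu_ids))


@dataclass
class BetaDeviationResult:
    """Standardized effect sizes of observed beta-diversity vs the null."""

    beta_dev: DistanceMatrix
    null_mean: DistanceMatrix
    null_sd: DistanceMatrix
    observed: DistanceMatrix
    n_null: int
    seed: int

    def condensed(self) -> np.ndarray:
        return self.beta_dev.condensed()


def beta_deviation(table: OtuTable, n_null: int = 999, seed: int = 0) -> BetaDeviationResult:
    """Compute per-pair beta-deviations from ``n_null`` null realizations.

    Null mean and sd (denominator n-1) are per sample pair; pairs whose null
    sd is zero get a beta-deviation of 0 with a logged warning.
    """
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    obs = bray_curtis(table)
    rng = np.random.default_rng(seed)
    n = table.n_samples
    acc = np.zeros((n, n))
    acc_sq = np.zeros((n, n))
    for _ in range(n_null):
        null_counts = _null_counts(table.counts, rng)
        d = bray_curtis(
            OtuTable(null_counts, list(table.sample_ids), list(table.otu_ids))
        ).values
        acc += d
        acc_sq += d * d
    mean = acc / n_null
    var = (acc_sq - n_null * mean**2) / (n_null - 1)
    sd = np.sqrt(np.clip(var, 0.0, None))

    dev = np.zeros((n, n))
    nonzero = sd > 0
    dev[nonzero] = (obs.values[nonzero] - mean[nonzero]) / sd[nonzero]
    degenerate = (~nonzero) & ~np.eye(n, dtype=bool)
    if degenerate.any():
        logger.warning(
            "%d sample pairs have zero null sd; beta-deviation set to 0",
            int(degenerate.sum()) // 2,
        )
    np.fill_diagonal(dev, 0.0)
    np.fill_diagonal(sd, 0.0)
    np.fill_diagonal(mean, 0.0)
    labels = list(table.sample_ids)
    return BetaDeviationResult(
        beta_dev=SignedDistanceMatrix(dev, labels, "beta_deviation"),
        null_mean=DistanceMatrix(mean, labels, "null_mean_bray_curtis"),
        null_sd=DistanceMatrix(sd, labels, "null_sd_bray_curtis"),
        observed=obs,
        n_null=n_null,
        seed=seed,
    )


class SignedDistanceMatrix(DistanceMatrix):
    """Symmetric labelled matrix allowed to hold negative values
    (beta-deviations are standardized effect sizes, not distances)."""

    def __post_init__(self) -> None:  # relax the non-negativity invariant
        self.values = np.asarray(self.values, dtype=float)
        self.labels = [str(x) for x in self.labels]
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("labels do not match matrix shape")
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("matrix not symmetric")
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)


@dataclass
class DeviationSignTest:
    statistic: float
    p_value: float
    direction: str  # "positive" | "negative" | "none"


def test_deviation_sign(result: BetaDeviationResult) -> DeviationSignTest:
    """One-sample two-sided Wilcoxon signed-rank of pairwise beta-deviations
    against zero; direction is the sign of the median."""
    vals = result.condensed()
    if len(vals) < 2:
        raise ValueError("need at least two sample pairs")
    if np.all(vals == 0):
        return DeviationSignTest(statistic=0.0, p_value=1.0, direction="none")
    med = float(np.median(vals))
    nz = vals[vals != 0]
    res = stats.wilcoxon(nz, alternative="two-sided")
    direction = "positive" if med > 0 else ("negative" if med < 0 else "none")
    return DeviationSignTest(
        statistic=float(res.statistic), p_value=float(res.pvalue), direction=direction
    )


def interpret_deviation(
    result: BetaDeviationResult, test: DeviationSignTest, alpha: float = 0.05
) -> str:
    """Map the sign test onto the assembly-process interpretation labels."""
    if test.p_value >= alpha or test.direction == "none":
        return LABEL_STOCHASTIC
    return LABEL_POSITIVE if test.direction == "positive" else LABEL_NEGATIVE
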