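"""Sloan's neutral community model: forward simulation and fitting.

The model predicts an OTU's occurrence frequency across samples from its
mean relative abundance p via a beta distribution governed by the product of
the sampling depth NT and migration rate m:

    F(p) = 1 - BetaCDF(d; NT*m*p, NT*m*(1 - p)),   d = 1/NT

m is estimated by least squares on (p_j, f_j) pairs; R^2 = 1 - SSE/SST and
may be negative for poor fits.  The forward simulator draws each sample from
a Dirichlet-multinomial with concentration NT*m*p, whose per-OTU marginals
are the beta-binomials the fit assumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .data_model import OtuTable

logger = logging.getLogger(__name__)

_M_LOWER = 1e-6
_M_UPPER = 1.0


def predicted_frequency(p: np.ndarray, m: float, nt: int) -> np.ndarray:
    """Expected occurrence frequency for mean relative abundance ``p``."""
    p = np.asarray(p, dtype=float)
    d = 1.0 / nt
    a = nt * m * p
    b = nt * m * (1.0 - p)
    return 1.0 - stats.beta.cdf(d, a, b)


@dataclass
class NcmFit:
    """Fitted migration rate and goodness of fit."""

    m: float
    r_squared: float
    NT: int
    ci_m: tuple[float, float]
    n_otus_fit: int
    p: np.ndarray  # mean relative abundances
    f_obs: np.ndarray  # observed occurrence frequencies
    f_pred: np.ndarray  # model frequencies at the fitted m


def _fit_m(p: np.ndarray, f: np.ndarray, nt: int) -> float:
    def sse(m: float) -> float:
        resid = f - predicted_frequency(p, m, nt)
        return float(resid @ resid)

    res = optimize.minimize_scalar(
        sse, bounds=(_M_LOWER, _M_UPPER), method="bounded",
        options={"xatol": 1e-6},
    )
    if not res.success:
        raise RuntimeError(f"m optimization failed: {res.message}")
    return float(res.x)


def fit_ncm(
    table: OtuTable,
    n_boot: int = 1000,
    seed: int = 0,
    nt: int | None = None,
) -> NcmFit:
    """Fit the neutral model to occurrence frequency vs mean abundance.

    Parameters
    ----------
    table
        Count table, ideally rarefied to equal depth.  If depths are unequal
        (e.g. a sub-community slice of a rarefied table), NT defaults to the
        rounded mean depth.
    n_boot
        Bootstrap resamples (over OTUs) for the 95% CI on m; 0 disables.
    nt
        Override the sampling depth NT.
    """
    if table.n_otus < 10:
        raise ValueError("need at least 10 OTUs to fit")
    totals = table.sample_totals().astype(float)
    if nt is None:
        if np.ptp(totals) > 0:
            logger.info("unequal sample depths; using rounded mean as NT")
        nt = int(round(totals.mean()))
    props = table.counts / totals[:, None]
    p = props.mean(axis=0)
    f = (table.counts > 0).mean(axis=0)
    keep = p > 0
    p, f = p[keep], f[keep]

    m_hat = _fit_m(p, f, nt)
    f_pred = predicted_frequency(p, m_hat, nt)
    sse = float(np.sum((f - f_pred) ** 2))
    sst = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        n = len(p)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            boots[b] = _fit_m(p[idx], f[idx], nt)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        ci = (min(float(lo), m_hat), max(float(hi), m_hat))
    else:
        ci = (m_hat, m_hat)
    return NcmFit(
        m=m_hat, r_squared=r2, NT=nt, ci_m=ci,
        n_otus_fit=len(p), p=p, f_obs=f, f_pred=f_pred,
    )


def simulate_ncm(
    n_samples: int,
    nt: int,
    m: float,
    metacommunity: np.ndarray,
    seed: int,
    sample_ids: list[str] | None = None,
    otu_ids: list[str] | None = None,
) -> OtuTable:
    """Simulate local communities under the neutral model.

    Each sample's composition is a Dirichlet-multinomial draw of depth ``nt``
    with concentration ``nt * m * metacommunity``.
    """
    if not (0 < m <= 1):
        raise ValueError("m must be in (0, 1]")
    meta = np.asarray(metacommunity, dtype=float)
    if abs(meta.sum() - 1.0) > 1e-8:
        raise ValueError("metacommunity abundances must sum to 1")
    rng = np.random.default_rng(seed)
    alpha = nt * m * meta
    n_otus = len(meta)
    counts = np.zeros((n_samples, n_otus), dtype=np.int64)
    for k in range(n_samples):
        # gamma draws give the Dirichlet; alphas may be tiny, zeros are fine
        g = rng.gamma(np.clip(alpha, 1e-300, None))
        total = g.sum()
        if total == 0:
            g[rng.integers(n_otus)] = 1.0
            total = 1.0
        counts[k] = rng.multinomial(nt, g / total)
    if sample_ids is None:
        sample_ids = [f"S{k + 1}" for k in range(n_samples)]
    if otu_ids is None:
        otu_ids = [f"OTU{j + 1}" for j in range(n_otus)]
    return OtuTable(counts, sample_ids, otu_ids)


def lognormal_metacommunity(n_otus: int, sigma: float = 2.0, seed: int = 0) -> np.ndarray:
    """Normalized lognormal(0, sigma) regional abundance vector."""
    rng = np.random.default_rng(seed)
    x = rng.lognormal(mean=0.0, sigma=sigma, size=n_otus)
    return x / x.sum()
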