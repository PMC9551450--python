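"""Distance-matrix statistics: Mantel tests, multiple regression on distance
matrices (MRM) with forward selection, variation partitioning, the
environment-to-space effect ratio (ESDR), and gradient splits of
beta-deviation distributions.

All tests permute rows and columns of one matrix jointly, preserving the
pair structure; p-values use the add-one convention
p = (1 + #{permuted >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .community_metrics import GroupComparison, compare_groups
from .data_model import DistanceMatrix, SampleMetadata, ValidationError
from .null_model import BetaDeviationResult

logger = logging.getLogger(__name__)


def _aligned_condensed(
    matrices: list[DistanceMatrix], labels: list[str]
) -> list[np.ndarray]:
    out = []
    for m in matrices:
        if set(m.labels) != set(labels):
            raise ValidationError("distance matrices have mismatched labels")
        if m.labels != labels:
            m = m.reordered(labels)
        out.append(m.condensed())
    return out


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    uc = u - u.mean()
    vc = v - v.mean()
    return float(uc @ vc / np.sqrt((uc @ uc) * (vc @ vc)))


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int


def mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test between two labelled distance matrices.

    Pearson correlation of the upper-triangle vectors; significance by
    jointly permuting rows/columns of ``a``.  ``alternative`` is "greater"
    (ecological default) or "two-sided".
    """
    labels = list(a.labels)
    n = len(labels)
    if n < 4:
        raise ValidationError("need at least four samples")
    va, vb = _aligned_condensed([a, b], labels)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValidationError("constant distance matrix")

    r_obs = _pearson(va, vb)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    avals = a.values
    vb_c = vb - vb.mean()
    vb_norm = float(np.sqrt(vb_c @ vb_c))
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = avals[np.ix_(perm, perm)][iu]
        vp_c = vp - vp.mean()
        r_p = float(vp_c @ vb_c) / (np.sqrt(vp_c @ vp_c) * vb_norm)
        if alternative == "greater":
            hits += r_p >= r_obs
        elif alternative == "two-sided":
            hits += abs(r_p) >= abs(r_obs)
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    return MantelResult(r=r_obs, p=(1 + hits) / (1 + n_perm), n_perm=n_perm)


def _ols_r2(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares fit with intercept; returns (coefficients, R^2).

    Coefficient order: [intercept, predictors...].
    """
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 0.0
    return coef, r2


@dataclass
class MrmResult:
    selected: list[str]
    coefficients: dict[str, float]
    r_squared: float
    p_values: dict[str, float]
    n_perm: int
    entry_p: dict[str, float] = field(default_factory=dict)


def _mrm_perm_pvalues(
    response: DistanceMatrix,
    predictor_vectors: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Permutation p-values for each coefficient of the full model.

    The response matrix's rows/columns are permuted jointly; two-sided on
    |coefficient|.  Returns (coefs without intercept, R^2, p-values).
    """
    n = response.n
    iu = np.triu_indices(n, k=1)
    y = response.values[iu]
    coef, r2 = _ols_r2(y, predictor_vectors)
    betas = coef[1:]
    hits = np.zeros(len(betas))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = response.values[np.ix_(perm, perm)][iu]
        cp, _ = _ols_r2(yp, predictor_vectors)
        hits += np.abs(cp[1:]) >= np.abs(betas)
    pvals = (1 + hits) / (1 + n_perm)
    return betas, r2, pvals


def mrm_forward_select(
    response: DistanceMatrix,
    candidates: dict[str, DistanceMatrix],
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> MrmResult:
    """Greedy forward selection of distance-matrix predictors.

    At each step the candidate giving the largest R^2 increase is considered;
    it enters only if its coefficient's permutation p-value in the augmented
    model is below ``alpha``.  Selection stops when no candidate qualifies.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    labels = list(response.labels)
    names = list(candidates)
    vectors = dict(zip(names, _aligned_condensed([candidates[k] for k in names], labels)))
    rng = np.random.default_rng(seed)

    selected: list[str] = []
    entry_p: dict[str, float] = {}
    current_r2 = 0.0
    remaining = list(names)
    iu_y = response.condensed()
    while remaining:
        best_name, best_r2 = None, current_r2
        for name in remaining:
            X = np.column_stack([vectors[v] for v in selected + [name]])
            _, r2 = _ols_r2(iu_y, X)
            if r2 > best_r2 + 1e-12:
                best_name, best_r2 = name, r2
        if best_name is None:
            break
        X = np.column_stack([vectors[v] for v in selected + [best_name]])
        _, _, pvals = _mrm_perm_pvalues(response, X, n_perm, rng)
        p_new = float(pvals[-1])
        if p_new < alpha:
            selected.append(best_name)
            entry_p[best_name] = p_new
            remaining.remove(best_name)
            current_r2 = best_r2
        else:
            break

    if not selected:
        return MrmResult([], {}, 0.0, {}, n_perm, {})
    X = np.column_stack([vectors[v] for v in selected])
    betas, r2, pvals = _mrm_perm_pvalues(response, X, n_perm, rng)
    return MrmResult(
        selected=selected,
        coefficients=dict(zip(selected, map(float, betas))),
        r_squared=r2,
        p_values=dict(zip(selected, map(float, pvals))),
        n_perm=n_perm,
        entry_p=entry_p,
    )


@dataclass
class VpaResult:
    """Variation-partitioning fractions on the 0-1 scale plus ESDR."""

    env_individual: float
    space_individual: float
    shared: float
    residual: float
    esdr: float | None

    def fractions(self) -> tuple[float, float, float, float]:
        return (self.env_individual, self.space_individual, self.shared, self.residual)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    A = np.column_stack([np.ones(X.shape[0]), X])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValidationError(f"collinear predictor vectors among: {names}")


def variation_partition(
    response: DistanceMatrix,
    env: dict[str, DistanceMatrix],
    space: dict[str, DistanceMatrix],
) -> VpaResult:
    """Partition response-distance variance into pure-environment,
    pure-space, shared, and residual fractions.

    Fractions come from three plain OLS R^2 values on the pair vectors:
    env_individual = R2(env+space) - R2(space), space_individual =
    R2(env+space) - R2(env), shared = R2(env) + R2(space) - R2(env+space).
    """
    if not env or not space:
        raise ValueError("env and space predictor sets must be non-empty")
    labels = list(response.labels)
    y = response.condensed()
    env_names, space_names = list(env), list(space)
    env_vecs = _aligned_condensed([env[k] for k in env_names], labels)
    space_vecs = _aligned_condensed([space[k] for k in space_names], labels)

    X_e = np.column_stack(env_vecs)
    X_s = np.column_stack(space_vecs)
    X_es = np.column_stack(env_vecs + space_vecs)
    _check_rank(X_es, env_names + space_names)
    _, r2_e = _ols_r2(y, X_e)
    _, r2_s = _ols_r2(y, X_s)
    _, r2_es = _ols_r2(y, X_es)

    env_ind = r2_es - r2_s
    space_ind = r2_es - r2_e
    shared = r2_e + r2_s - r2_es
    residual = 1.0 - r2_es
    return VpaResult(
        env_individual=env_ind,
        space_individual=space_ind,
        shared=shared,
        residual=residual,
        esdr=esdr_from_fractions(env_ind, space_ind),
    )


def esdr_from_fractions(env_individual: float, space_individual: float) -> float | None:
    if space_individual <= 0:
        logger.warning("space_individual <= 0; ESDR undefined")
        return None
    return env_individual / space_individual


def esdr(v: VpaResult) -> float | None:
    """Effect ratio of environmental selection to dispersal limitation:
    the pure environmental fraction over the pure spatial fraction."""
    return esdr_from_fractions(v.env_individual, v.space_individual)


@dataclass
class GradientSplit:
    variable: str
    low_samples: list[str]
    high_samples: list[str]
    low_values: np.ndarray  # within-group beta-deviations
    high_values: np.ndarray
    comparison: GroupComparison | None


def gradient_split_deviation(
    result: BetaDeviationResult, meta: SampleMetadata, variable: str
) -> GradientSplit:
    """Split samples at the variable's median into equal-size low/high groups
    and collect within-group beta-deviation pairs.

    With an odd sample count the extra sample goes to the low group.  A pair
    contributes to a group only when both members belong to it.
    """
    if variable not in meta.data.columns:
        raise ValidationError(f"metadata missing variable {variable!r}")
    labels = result.beta_dev.labels
    x = meta.aligned_to(labels).data[variable].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValidationError(f"variable {variable!r} is constant; no split possible")
    order = np.argsort(x, kind="stable")
    n = len(labels)
    n_low = (n + 1) // 2
    low_idx = set(order[:n_low].tolist())
    high_idx = set(order[n_low:].tolist())
    if len(low_idx) < 2 or len(high_idx) < 2:
        raise ValidationError("need at least two samples per group")

    vals = result.beta_dev.values
    low, high = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if i in low_idx and j in low_idx:
                low.append(vals[i, j])
            elif i in high_idx and j in high_idx:
                high.append(vals[i, j])
    low_a, high_a = np.array(low), np.array(high)
    comparison = (
        compare_groups(low_a, high_a) if len(low_a) >= 2 and len(high_a) >= 2 else None
    )
    return GradientSplit(
        variable=variable,
        low_samples=[labels[i] for i in sorted(low_idx)],
        high_samples=[labels[i] for i in sorted(high_idx)],
        low_values=low_a,
        high_values=high_a,
        comparison=comparison,
    )
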