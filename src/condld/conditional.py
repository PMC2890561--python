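"""Conditional-likelihood estimation of D (Method L).

The model conditions on the marker genotype: with ``Q = P(A | M gamete) =
(p*q + D)/p`` and ``R = P(A | m gamete) = ((1-p)*q - D)/(1-p)``, the disease
genotype of an individual with marker genotype MM, Mm or mm follows a
row-specific trinomial whose probabilities are quadratic in Q and R.  Because
the likelihood conditions on the marker classes actually sampled, the
resulting estimator of D is insensitive to how many individuals of each
marker (or disease, by symmetry of the argument) class entered the sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .core import (
    EstimationResult,
    GenotypeCountTable,
    PopulationParams,
    d_bounds,
)

__all__ = [
    "ConditionalProbTable",
    "conditional_probs",
    "loglik_conditional",
    "score_conditional",
    "mle_D_conditional",
    "lrt_lod",
    "estimate_conditional",
    "q_profile",
]

#: inset from the theoretical bounds used by the optimiser
_EPS = 1e-9
#: default number of grid points in the coarse scan
_GRID_POINTS = 2001
#: likelihood ties closer than this prefer the smaller |D|
_TIE_TOL = 1e-10


@dataclass(frozen=True)
class ConditionalProbTable:
    """Disease-genotype probabilities by marker genotype (rows sum to 1)."""

    f: np.ndarray  # (3, 3) rows MM, Mm, mm; columns AA, Aa, aa
    Q: float
    R: float


def _qr(p: float, q: float, D) -> tuple[np.ndarray, np.ndarray]:
    Q = (p * q + np.asarray(D, dtype=float)) / p
    R = ((1.0 - p) * q - np.asarray(D, dtype=float)) / (1.0 - p)
    return Q, R


def _f_table(Q, R) -> np.ndarray:
    """Conditional probability table(s); trailing shape (3, 3)."""
    Q = np.asarray(Q, dtype=float)
    f = np.empty(Q.shape + (3, 3))
    f[..., 0, 0] = Q * Q
    f[..., 0, 1] = 2.0 * Q * (1.0 - Q)
    f[..., 0, 2] = (1.0 - Q) ** 2
    f[..., 1, 0] = Q * R
    f[..., 1, 1] = Q + R - 2.0 * Q * R
    f[..., 1, 2] = (1.0 - Q) * (1.0 - R)
    f[..., 2, 0] = R * R
    f[..., 2, 1] = 2.0 * R * (1.0 - R)
    f[..., 2, 2] = (1.0 - R) ** 2
    return np.clip(f, 0.0, 1.0)


def conditional_probs(params: PopulationParams) -> ConditionalProbTable:
    """Conditional distribution of disease genotype given marker genotype."""
    if not 0.0 < params.p < 1.0:
        raise ValueError("conditional model requires 0 < p < 1")
    Q, R = _qr(params.p, params.q, params.D)
    return ConditionalProbTable(f=_f_table(Q, R), Q=float(Q), R=float(R))


def _loglik_arr(counts: np.ndarray, p: float, q: float, D) -> np.ndarray:
    """Vectorised conditional log-likelihood over an array of D values.

    Cells with ``f_ij == 0`` but ``n_ij > 0`` make the value ``-inf`` (that D
    is infeasible for the data); zero-count cells contribute nothing.
    """
    Q, R = _qr(p, q, D)
    f = _f_table(Q, R)
    mask = counts > 0
    with np.errstate(divide="ignore"):
        lf = np.where(f > 0, np.log(np.where(f > 0, f, 1.0)), -np.inf)
    lf = np.where(mask, lf, 0.0)
    return np.einsum("...ij,ij->...", lf, counts)


def loglik_conditional(
    counts: GenotypeCountTable, p: float, q: float, D: float
) -> float:
    """Conditional log-likelihood ``sum_ij n_ij * ln f_ij(p, q, D)``.

    Combinatorial constants that do not depend on (p, q, D) are dropped; they
    cancel in likelihood ratios and in the score.
    """
    d_min, d_max = d_bounds(p, q)
    if D < d_min - 1e-12 or D > d_max + 1e-12:
        raise ValueError(f"D={D} outside theoretical bounds [{d_min}, {d_max}]")
    return float(_loglik_arr(counts.counts, p, q, float(D)))


def score_conditional(counts: GenotypeCountTable | np.ndarray, p: float, q: float, D: float) -> float:
    """Derivative of the conditional log-likelihood with respect to D.

    Uses dQ/dD = 1/p and dR/dD = -1/(1-p); valid strictly inside the bounds
    where all table entries are positive.
    """
    n = counts.counts if isinstance(counts, GenotypeCountTable) else np.asarray(counts)
    Q, R = _qr(p, q, D)
    f = _f_table(Q, R)
    a = 1.0 / p
    b = 1.0 / (1.0 - p)
    df = np.array(
        [
            [2 * Q * a, 2 * (1 - 2 * Q) * a, -2 * (1 - Q) * a],
            [
                R * a - Q * b,
                (1 - 2 * R) * a - (1 - 2 * Q) * b,
                -(1 - R) * a + (1 - Q) * b,
            ],
            [-2 * R * b, -2 * (1 - 2 * R) * b, 2 * (1 - R) * b],
        ]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > 0, n * df / f, 0.0)
    return float(terms.sum())


def _degenerate_result(method: str, p: float, q: float, bounds) -> EstimationResult:
    return EstimationResult(
        method=method,
        D_hat=0.0,
        p_used=p,
        q_used=q,
        loglik_at_Dhat=0.0,
        loglik_at_0=0.0,
        degenerate=True,
        bounds=bounds,
    )


def mle_D_conditional(
    counts: GenotypeCountTable,
    p: float,
    q: float,
    *,
    grid_points: int = _GRID_POINTS,
) -> EstimationResult:
    """Maximum-conditional-likelihood estimate of D with (p, q) supplied.

    A ``grid_points``-point scan over ``[D_min + eps, D_max - eps]`` locates
    every local maximum; each is polished by Brent root-finding on the
    analytic score bracketed by its neighbouring grid points.  Among
    candidates whose log-likelihoods tie within 1e-10 the smallest ``|D|``
    wins (conservative toward the null).
    """
    if counts.n <= 0:
        raise ValueError("empty count table")
    d_min, d_max = d_bounds(p, q)
    if d_max - d_min <= 2 * _EPS or p in (0.0, 1.0) or q in (0.0, 1.0):
        return _degenerate_result("conditional", p, q, (d_min, d_max))

    lo, hi = d_min + _EPS, d_max - _EPS
    grid = np.linspace(lo, hi, grid_points)
    arr = counts.counts
    ll = _loglik_arr(arr, p, q, grid)

    candidates: list[float] = [lo, hi]
    if lo < 0.0 < hi:
        candidates.append(0.0)
    # each interior local grid maximum contributes its polished score root (or
    # the raw grid point when no score sign change brackets it)
    for i in range(grid_points):
        left = ll[i - 1] if i > 0 else -np.inf
        right = ll[i + 1] if i < grid_points - 1 else -np.inf
        if np.isfinite(ll[i]) and ll[i] >= left and ll[i] >= right:
            polished = None
            if 0 < i < grid_points - 1:
                a, b = float(grid[i - 1]), float(grid[i + 1])
                sa = score_conditional(arr, p, q, a)
                sb = score_conditional(arr, p, q, b)
                if np.isfinite(sa) and np.isfinite(sb) and sa * sb < 0:
                    polished = float(
                        optimize.brentq(
                            lambda d: score_conditional(arr, p, q, d),
                            a,
                            b,
                            xtol=1e-15,
                        )
                    )
            candidates.append(polished if polished is not None else float(grid[i]))

    cand = np.array(sorted(set(candidates)))
    cand_ll = _loglik_arr(arr, p, q, cand)
    best_ll = cand_ll.max()
    if not np.isfinite(best_ll):
        # no feasible D explains the data (cannot occur for consistent input)
        res = _degenerate_result("conditional", p, q, (d_min, d_max))
        res.converged = False
        return res
    tied = cand[cand_ll >= best_ll - _TIE_TOL]
    D_hat = float(tied[np.argmin(np.abs(tied))])
    ll_hat = float(_loglik_arr(arr, p, q, np.array(D_hat)))

    at_boundary = min(D_hat - d_min, d_max - D_hat) <= _EPS + 1e-9
    return EstimationResult(
        method="conditional",
        D_hat=D_hat,
        p_used=float(p),
        q_used=float(q),
        loglik_at_Dhat=ll_hat,
        loglik_at_0=float(_loglik_arr(arr, p, q, np.array(0.0))),
        at_boundary=bool(at_boundary),
        bounds=(d_min, d_max),
    )


def lrt_lod(
    counts: GenotypeCountTable, p: float, q: float, result: EstimationResult
) -> EstimationResult:
    """Fill the likelihood-ratio statistic, LOD score and p-value in place.

    ``lambda = 2*(loglik(D_hat) - loglik(0))`` is referred to a chi-square
    distribution with 1 df; ``lod = lambda / (2 ln 10)``.
    """
    ll_hat = result.loglik_at_Dhat
    ll_0 = result.loglik_at_0
    if math.isnan(ll_0):
        ll_0 = loglik_conditional(counts, p, q, 0.0)
        result.loglik_at_0 = ll_0
    lam = 2.0 * (ll_hat - ll_0)
    if math.isfinite(lam):
        lam = max(lam, 0.0)  # clamp score-zero roundoff
    result.lambda_ = lam
    result.lod = lam / (2.0 * math.log(10.0))
    result.p_value = float(stats.chi2.sf(lam, df=1)) if math.isfinite(lam) else math.nan
    return result


def estimate_conditional(
    counts: GenotypeCountTable, p: float, q: float, **kwargs
) -> EstimationResult:
    """MLE of D plus its significance test in one call."""
    result = mle_D_conditional(counts, p, q, **kwargs)
    return lrt_lod(counts, p, q, result)


def q_profile(
    counts: GenotypeCountTable, p: float, q_grid
) -> list[tuple[float, float, float]]:
    """Profile of (q, D_hat, LOD) over a grid of disease allele frequencies.

    The recommended ``q`` is the grid argmax of the LOD column; useful when no
    external survey estimate of the disease allele frequency exists.
    """
    q_grid = list(q_grid)
    if not q_grid:
        raise ValueError("q_grid must be non-empty")
    out = []
    for q in q_grid:
        if not 0.0 < q < 1.0:
            raise ValueError(f"q grid values must lie in (0, 1), got {q}")
        res = estimate_conditional(counts, p, q)
        out.append((float(q), res.D_hat, res.lod))
    return out
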