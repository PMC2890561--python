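"""Joint-likelihood estimation of D (Method H).

Hill's joint two-locus genotype distribution under random union of gametes,
the "chromosome counting" EM for the M-A gamete frequency g11, the cubic
stationarity equation of Weir and Cockerham, and the resulting estimator
``D_hat = g11_hat - p*q`` with its likelihood-ratio test.  This estimator
assumes individuals were sampled at random; the package keeps it primarily as
a comparison baseline for the conditional method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .core import (
    EstimationResult,
    GenotypeCountTable,
    PopulationParams,
    d_bounds,
    g11_bounds,
)

__all__ = [
    "JointProbTable",
    "joint_probs",
    "loglik_joint",
    "em_g11",
    "EmResult",
    "cubic_coeffs",
    "cubic_g11",
    "CubicRoot",
    "mle_D_joint",
]

_EPS = 1e-9
_IN_BOUNDS_TOL = 1e-9


@dataclass(frozen=True)
class JointProbTable:
    """Joint genotype probabilities and the generating gamete frequencies."""

    P: np.ndarray  # (3, 3) rows MM, Mm, mm; columns AA, Aa, aa
    g: np.ndarray  # (4,) gamete frequencies (MA, Ma, mA, ma)


def _joint_from_g(g11: float, p: float, q: float) -> np.ndarray:
    """Joint genotype probabilities from g11 with allele frequencies fixed.

    Entries are products of gamete pairs; the double heterozygote pools the
    cis and trans phases: ``P(MmAa) = 2*(g11*g22 + g12*g21)``.  May contain
    negative entries when g11 lies outside its theoretical bounds.
    """
    g12 = p - g11
    g21 = q - g11
    g22 = 1.0 - p - q + g11
    return np.array(
        [
            [g11 * g11, 2 * g11 * g12, g12 * g12],
            [2 * g11 * g21, 2 * (g11 * g22 + g12 * g21), 2 * g12 * g22],
            [g21 * g21, 2 * g21 * g22, g22 * g22],
        ]
    )


def joint_probs(params: PopulationParams) -> JointProbTable:
    """Hill's joint genotype distribution for the given ``(p, q, D)``."""
    g = params.haplotype_freqs
    P = _joint_from_g(float(g[0]), params.p, params.q)
    return JointProbTable(P=np.clip(P, 0.0, 1.0), g=g)


def loglik_joint(
    counts: GenotypeCountTable | np.ndarray, p: float, q: float, g11: float
) -> float:
    """Joint log-likelihood ``sum_ij n_ij * ln P_ij`` at fixed (p, q, g11).

    Returns ``-inf`` when a zero-probability cell carries observations, and
    ``nan`` when g11 implies a negative gamete frequency (infeasible model).
    """
    n = counts.counts if isinstance(counts, GenotypeCountTable) else np.asarray(counts)
    if min(g11, p - g11, q - g11, 1.0 - p - q + g11) < -1e-12:
        return math.nan
    P = _joint_from_g(g11, p, q)
    P = np.clip(P, 0.0, None)
    mask = n > 0
    with np.errstate(divide="ignore"):
        lP = np.where(P > 0, np.log(np.where(P > 0, P, 1.0)), -np.inf)
    return float((n * np.where(mask, lP, 0.0)).sum())


class EmResult(NamedTuple):
    g11: float
    converged: bool
    n_iter: int


def em_g11(
    counts: GenotypeCountTable,
    p: float,
    q: float,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> EmResult:
    """Chromosome-counting iteration for g11 with (p, q) supplied.

    Haplotypes other than the double heterozygote's are read directly from the
    genotypes; each double heterozygote contributes its expected cis fraction
    ``w = g11*g22 / (g11*g22 + g12*g21)`` with ``g12 = p - g11`` etc.  Starts
    from linkage equilibrium ``g11 = p*q``.  When (p, q) are the sample allele
    frequencies this is Hill's EM and its fixed point is a stationary point of
    the joint likelihood; with external (p, q) it is the literal counting
    recipe, whose fixed point may leave the theoretical g11 interval.
    """
    n = counts.counts
    two_n = 2.0 * counts.n
    if two_n <= 0:
        raise ValueError("empty count table")
    a = 2.0 * n[0, 0] + n[0, 1] + n[1, 0]  # unambiguous MA haplotypes
    n22 = n[1, 1]
    g11 = p * q
    if n22 == 0:
        # no phase ambiguity: closed form in one step
        return EmResult(float(a / two_n), True, 1)
    for it in range(1, max_iter + 1):
        g12 = p - g11
        g21 = q - g11
        g22 = 1.0 - p - q + g11
        denom = g11 * g22 + g12 * g21
        if denom == 0.0 or not math.isfinite(denom):
            return EmResult(float(g11), False, it)
        w = g11 * g22 / denom
        new = (a + n22 * w) / two_n
        if not math.isfinite(new):
            return EmResult(float(g11), False, it)
        done = abs(new - g11) < tol
        g11 = new
        if done:
            return EmResult(float(g11), True, it)
    return EmResult(float(g11), False, max_iter)


def cubic_coeffs(counts: GenotypeCountTable, p: float, q: float) -> np.ndarray:
    """Coefficients (descending powers) of the cubic fixed-point equation.

    Clearing denominators from the counting iteration's fixed-point condition
    ``2n*g11*h = A*h + n22*g11*g22`` with ``h = g11*g22 + g12*g21`` and
    ``A = 2n11 + n12 + n21`` gives

        4n*g^3 + (2n*s - 2A - n22)*g^2
               + (2n*p*q - A*s - n22*(1-p-q))*g - A*p*q = 0,

    where ``s = 1 - 2p - 2q``.  When (p, q) are the sample allele frequencies
    this is also the score equation of the joint log-likelihood in g11.
    """
    n = counts.counts
    N = counts.n
    a = 2.0 * n[0, 0] + n[0, 1] + n[1, 0]
    n22 = n[1, 1]
    s = 1.0 - 2.0 * p - 2.0 * q
    return np.array(
        [
            4.0 * N,
            2.0 * N * s - 2.0 * a - n22,
            2.0 * N * p * q - a * s - n22 * (1.0 - p - q),
            -a * p * q,
        ]
    )


class CubicRoot(NamedTuple):
    g11: float
    loglik: float
    in_bounds: bool


def cubic_g11(counts: GenotypeCountTable, p: float, q: float) -> list[CubicRoot]:
    """All real roots of the cubic, each annotated with its joint log-likelihood.

    A cubic with positive leading coefficient always has at least one real
    root.  ``in_bounds`` compares against :func:`~condld.core.g11_bounds`.
    """
    coeffs = cubic_coeffs(counts, p, q)
    roots = np.roots(coeffs)
    real = roots[np.abs(roots.imag) < 1e-9].real
    # polish with a couple of Newton steps on the polynomial itself
    deriv = np.polyder(coeffs)
    for _ in range(3):
        val = np.polyval(coeffs, real)
        dval = np.polyval(deriv, real)
        step = np.where(dval != 0, val / np.where(dval != 0, dval, 1.0), 0.0)
        real = real - step
    lo, hi = g11_bounds(p, q)
    out = []
    for r in sorted(set(np.round(real, 15))):
        in_b = lo - _IN_BOUNDS_TOL <= r <= hi + _IN_BOUNDS_TOL
        out.append(CubicRoot(float(r), loglik_joint(counts, p, q, float(r)), in_b))
    return out


def mle_D_joint(
    counts: GenotypeCountTable,
    p: float,
    q: float,
    mode: str = "strict",
) -> EstimationResult:
    """Joint-likelihood estimate ``D_hat = g11_hat - p*q`` (Method H).

    ``strict`` maximises the joint likelihood over the theoretical g11
    interval (cubic roots plus the interval endpoints).  ``replication`` runs
    the literal chromosome-counting iteration with the supplied (p, q) and
    reports its fixed point even outside the interval, setting
    ``out_of_bounds`` — the behaviour needed to reproduce the classical
    estimator's failure on ascertained samples.
    """
    if mode not in ("strict", "replication"):
        raise ValueError(f"unknown mode {mode!r}")
    if counts.n <= 0:
        raise ValueError("empty count table")
    d_b = d_bounds(p, q)
    if p in (0.0, 1.0) or q in (0.0, 1.0):
        return EstimationResult(
            method=f"joint-{mode}",
            D_hat=0.0,
            p_used=p,
            q_used=q,
            loglik_at_Dhat=0.0,
            loglik_at_0=0.0,
            degenerate=True,
            g11_hat=p * q,
            bounds=d_b,
        )
    lo, hi = g11_bounds(p, q)
    null_g = min(max(p * q, lo), hi)
    ll_0 = loglik_joint(counts, p, q, null_g)
    converged = True

    if mode == "replication":
        em = em_g11(counts, p, q)
        g11_hat = em.g11
        converged = em.converged
        out_of_bounds = not (lo - _IN_BOUNDS_TOL <= g11_hat <= hi + _IN_BOUNDS_TOL)
        ll_hat = loglik_joint(counts, p, q, g11_hat)
    else:
        cands = [lo + _EPS * (hi - lo), hi - _EPS * (hi - lo), null_g]
        cands += [r.g11 for r in cubic_g11(counts, p, q) if r.in_bounds]
        cands = [min(max(c, lo), hi) for c in cands]
        lls = np.array([loglik_joint(counts, p, q, c) for c in cands])
        lls = np.where(np.isnan(lls), -np.inf, lls)
        best = lls.max()
        tied = [c for c, l in zip(cands, lls) if l >= best - 1e-10]
        g11_hat = min(tied, key=lambda c: abs(c - p * q))
        ll_hat = loglik_joint(counts, p, q, g11_hat)
        out_of_bounds = False

    D_hat = g11_hat - p * q
    lam = math.nan
    if math.isfinite(ll_hat) and math.isfinite(ll_0):
        lam = max(2.0 * (ll_hat - ll_0), 0.0) if ll_hat >= ll_0 - 1e-9 else 2.0 * (ll_hat - ll_0)
    result = EstimationResult(
        method=f"joint-{mode}",
        D_hat=float(D_hat),
        p_used=float(p),
        q_used=float(q),
        loglik_at_Dhat=ll_hat,
        loglik_at_0=ll_0,
        lambda_=lam,
        lod=lam / (2.0 * math.log(10.0)) if math.isfinite(lam) else math.nan,
        p_value=float(stats.chi2.sf(max(lam, 0.0), df=1)) if math.isfinite(lam) else math.nan,
        at_boundary=bool(min(g11_hat - lo, hi - g11_hat) <= 1e-8),
        out_of_bounds=bool(out_of_bounds),
        converged=converged,
        g11_hat=float(g11_hat),
        bounds=d_b,
    )
    return result
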