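"""Shared types and statistics for two-locus linkage-disequilibrium analysis.

The basic parameterisation is the triple ``(p, q, D)``: the frequency ``p`` of
the designated marker allele M, the frequency ``q`` of the designated disease
allele A, and the gamete-scale disequilibrium coefficient ``D`` defined as the
frequency of the M-A gamete minus ``p*q``.  Genotype data enter as 3x3 count
tables with marker genotypes (MM, Mm, mm) on rows and disease genotypes
(AA, Aa, aa) on columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats

__all__ = [
    "MARKER_GENOTYPES",
    "DISEASE_GENOTYPES",
    "PopulationParams",
    "GenotypeCountTable",
    "EstimationResult",
    "d_bounds",
    "g11_bounds",
    "allele_freqs",
    "r_squared",
    "hwe_chisq",
    "allelic_chisq",
    "HweTest",
    "AllelicTest",
]

MARKER_GENOTYPES = ("MM", "Mm", "mm")
DISEASE_GENOTYPES = ("AA", "Aa", "aa")

#: tolerance used when checking that D lies within its theoretical bounds
_BOUND_TOL = 1e-12


def _validate_freq(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value < 0.0 or value > 1.0:
        raise ValueError(f"{name} must be a finite frequency in [0, 1], got {value!r}")
    return value


def d_bounds(p: float, q: float) -> tuple[float, float]:
    """Theoretical bounds for the disequilibrium coefficient D.

    ``D_min = max(-p*q, -(1-p)*(1-q))`` and ``D_max = min(p*(1-q), (1-p)*q)``,
    the interval on which all four implied gamete frequencies are
    non-negative.  Degenerate ``p`` or ``q`` in {0, 1} yields the zero-width
    interval (0, 0).
    """
    p = _validate_freq("p", p)
    q = _validate_freq("q", q)
    d_min = max(-p * q, -(1.0 - p) * (1.0 - q))
    d_max = min(p * (1.0 - q), (1.0 - p) * q)
    return d_min, d_max


def g11_bounds(p: float, q: float) -> tuple[float, float]:
    """Theoretical bounds for the M-A gamete frequency g11 = p*q + D.

    Equals :func:`d_bounds` shifted by ``+p*q``:
    ``{max(0, p+q-1), min(p, q)}``.
    """
    p = _validate_freq("p", p)
    q = _validate_freq("q", q)
    return max(0.0, p + q - 1.0), min(p, q)


@dataclass(frozen=True)
class PopulationParams:
    """Generative population parameters ``(p, q, D)``.

    Validates that ``D`` lies within :func:`d_bounds` so the four implied
    gamete frequencies are a valid probability vector.
    """

    p: float
    q: float
    D: float

    def __post_init__(self) -> None:
        _validate_freq("p", self.p)
        _validate_freq("q", self.q)
        if not math.isfinite(self.D):
            raise ValueError(f"D must be finite, got {self.D!r}")
        d_min, d_max = d_bounds(self.p, self.q)
        if self.D < d_min - _BOUND_TOL or self.D > d_max + _BOUND_TOL:
            raise ValueError(
                f"D={self.D} outside theoretical bounds [{d_min}, {d_max}] "
                f"for p={self.p}, q={self.q}"
            )

    @property
    def haplotype_freqs(self) -> np.ndarray:
        """Gamete frequencies ``[g11, g12, g21, g22]`` for (MA, Ma, mA, ma)."""
        p, q, D = self.p, self.q, self.D
        g = np.array(
            [
                p * q + D,
                p * (1.0 - q) - D,
                (1.0 - p) * q - D,
                (1.0 - p) * (1.0 - q) + D,
            ]
        )
        # clip roundoff at the feasibility boundary
        return np.clip(g, 0.0, 1.0)

    @property
    def bounds(self) -> tuple[float, float]:
        return d_bounds(self.p, self.q)


class GenotypeCountTable:
    """A 3x3 table of two-locus genotype counts.

    Rows index the marker genotype (MM, Mm, mm), columns the disease genotype
    (AA, Aa, aa).  Cells are non-negative; fractional cells are permitted so
    that expectation tables (``n * joint probabilities``) can be analysed.
    """

    __slots__ = ("counts",)

    def __init__(self, counts) -> None:
        arr = np.array(counts, dtype=float)
        if arr.shape != (3, 3):
            raise ValueError(f"count table must be 3x3, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("count table contains non-finite cells")
        if np.any(arr < 0):
            raise ValueError("count table contains negative cells")
        self.counts = arr

    @classmethod
    def zeros(cls) -> "GenotypeCountTable":
        return cls(np.zeros((3, 3)))

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @property
    def marker_margins(self) -> np.ndarray:
        """Row totals ``n_i.`` for (MM, Mm, mm)."""
        return self.counts.sum(axis=1)

    @property
    def disease_margins(self) -> np.ndarray:
        """Column totals ``n_.j`` for (AA, Aa, aa)."""
        return self.counts.sum(axis=0)

    def swapped_marker(self) -> "GenotypeCountTable":
        """Table after relabelling the marker allele (rows MM and mm swap)."""
        return GenotypeCountTable(self.counts[::-1].copy())

    def swapped_disease(self) -> "GenotypeCountTable":
        """Table after relabelling the disease allele (columns AA and aa swap)."""
        return GenotypeCountTable(self.counts[:, ::-1].copy())

    def __add__(self, other: "GenotypeCountTable") -> "GenotypeCountTable":
        return GenotypeCountTable(self.counts + other.counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeCountTable):
            return NotImplemented
        return bool(np.array_equal(self.counts, other.counts))

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypeCountTable(n={self.n:g})"


@dataclass
class EstimationResult:
    """Outcome of a single disequilibrium estimation plus its significance test.

    ``lambda_`` is the 1-df likelihood-ratio statistic
    ``2*(loglik_at_Dhat - loglik_at_0)`` and ``lod = lambda_ / (2 ln 10)``.
    ``out_of_bounds`` can only be set by the joint method in replication mode,
    where the unconstrained gamete-frequency estimate may leave its
    theoretical interval.
    """

    method: str
    D_hat: float
    p_used: float
    q_used: float
    p_source: str = "sample"
    q_source: str = "sample"
    loglik_at_Dhat: float = math.nan
    loglik_at_0: float = math.nan
    lambda_: float = math.nan
    lod: float = math.nan
    p_value: float = math.nan
    at_boundary: bool = False
    out_of_bounds: bool = False
    degenerate: bool = False
    converged: bool = True
    g11_hat: float | None = None
    bounds: tuple[float, float] = field(default=(math.nan, math.nan))

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "D_hat": self.D_hat,
            "p_used": self.p_used,
            "q_used": self.q_used,
            "p_source": self.p_source,
            "q_source": self.q_source,
            "loglik_at_Dhat": self.loglik_at_Dhat,
            "loglik_at_0": self.loglik_at_0,
            "lambda": self.lambda_,
            "lod": self.lod,
            "p_value": self.p_value,
            "D_min": self.bounds[0],
            "D_max": self.bounds[1],
            "at_boundary": self.at_boundary,
            "out_of_bounds": self.out_of_bounds,
            "degenerate": self.degenerate,
            "converged": self.converged,
        }
        if self.g11_hat is not None:
            d["g11_hat"] = self.g11_hat
        return d


def allele_freqs(table: GenotypeCountTable) -> tuple[float, float]:
    """Allele-counting estimates ``(p_hat, q_hat)`` from a count table."""
    n = table.n
    if n <= 0:
        raise ValueError("cannot estimate allele frequencies from an empty table")
    m = table.marker_margins
    d = table.disease_margins
    p_hat = (2.0 * m[0] + m[1]) / (2.0 * n)
    q_hat = (2.0 * d[0] + d[1]) / (2.0 * n)
    return float(p_hat), float(q_hat)


def r_squared(D: float, p: float, q: float) -> float:
    """Squared correlation ``D**2 / (p(1-p)q(1-q))`` between the two loci."""
    p = _validate_freq("p", p)
    q = _validate_freq("q", q)
    denom = p * (1.0 - p) * q * (1.0 - q)
    if denom == 0.0:
        raise ValueError("r_squared undefined for p or q in {0, 1}")
    return float(D * D / denom)


class HweTest(NamedTuple):
    chi2: float
    p_value: float
    degenerate: bool = False


def hwe_chisq(g0: float, g1: float, g2: float) -> HweTest:
    """Pearson chi-square test of Hardy-Weinberg proportions at one locus.

    ``(g0, g1, g2)`` are counts of the three genotype classes ordered by
    copies of the designated allele (2, 1, 0).  Expected counts come from the
    sample allele frequency; 1 degree of freedom, no continuity correction.
    A monomorphic sample returns ``chi2 = 0`` with ``degenerate=True``.
    """
    obs = np.array([g0, g1, g2], dtype=float)
    if np.any(obs < 0) or not np.all(np.isfinite(obs)):
        raise ValueError("genotype counts must be non-negative and finite")
    n = obs.sum()
    if n <= 0:
        raise ValueError("empty genotype sample")
    p_hat = (2.0 * obs[0] + obs[1]) / (2.0 * n)
    if p_hat == 0.0 or p_hat == 1.0:
        return HweTest(0.0, 1.0, True)
    expected = n * np.array([p_hat**2, 2 * p_hat * (1 - p_hat), (1 - p_hat) ** 2])
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return HweTest(chi2, float(stats.chi2.sf(chi2, df=1)), False)


class AllelicTest(NamedTuple):
    chi2: float
    p_value: float


def allelic_chisq(
    case_counts: tuple[float, float, float],
    control_counts: tuple[float, float, float],
) -> AllelicTest:
    """2x2 allele-count chi-square for a marker-frequency difference.

    Each argument is a genotype-count triple ordered by copies of the
    designated allele (2, 1, 0).  Pearson statistic on the alleles-by-group
    table, 1 df, no continuity correction.
    """
    rows = []
    for name, counts in (("case", case_counts), ("control", control_counts)):
        c = np.array(counts, dtype=float)
        if np.any(c < 0) or not np.all(np.isfinite(c)):
            raise ValueError(f"{name} counts must be non-negative and finite")
        total = 2.0 * c.sum()
        if total <= 0:
            raise ValueError(f"{name} group has zero alleles")
        rows.append([2.0 * c[0] + c[1], 2.0 * c[2] + c[1]])
    table = np.array(rows)
    col = table.sum(axis=0)
    if col[0] == 0.0 or col[1] == 0.0:
        # marker monomorphic across both groups: no difference testable
        return AllelicTest(0.0, 1.0)
    n = table.sum()
    a, b = table[0]
    c, d = table[1]
    chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * col[0] * col[1])
    return AllelicTest(float(chi2), float(stats.chi2.sf(chi2, df=1)))
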