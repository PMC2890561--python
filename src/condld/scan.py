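"""Pairwise LD scan of a genotype matrix against a focal (disease) locus."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .conditional import estimate_conditional
from .core import EstimationResult, GenotypeCountTable, allele_freqs
from .io import GenotypeMatrix
from .joint import mle_D_joint

__all__ = ["ScanRecord", "ld_scan"]


@dataclass
class ScanRecord:
    """One scanned locus: estimation outcome or a skip flag."""

    locus: str
    n_complete: int
    status: str  # "ok", "monomorphic", "no_data"
    result: EstimationResult | None = None


def _pair_table(marker: np.ndarray, disease: np.ndarray) -> tuple[GenotypeCountTable, int]:
    """3x3 table over pairwise-complete individuals.

    Codes count copies of the designated allele, so code 2 maps to row/column
    0 (MM / AA) and code 0 to row/column 2.
    """
    complete = (marker >= 0) & (disease >= 0)
    m = marker[complete]
    d = disease[complete]
    table = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            table[i, j] = np.sum((m == 2 - i) & (d == 2 - j))
    return GenotypeCountTable(table), int(complete.sum())


def ld_scan(
    matrix: GenotypeMatrix,
    focal: str,
    method: str = "L",
    p_source: str = "sample",
    q_value: float | None = None,
    h_mode: str = "replication",
) -> list[ScanRecord]:
    """Estimate D between the focal locus and every other locus.

    Per pair, a 3x3 table is built from pairwise-complete individuals, the
    marker allele frequency comes from the full pair sample or from control
    individuals only (``p_source``), and the disease allele frequency is
    ``q_value`` (survey) or counted from the pair sample.  Monomorphic or
    empty pairs are flagged and carry no estimate.
    """
    if focal not in matrix.loci:
        raise ValueError(f"focal locus {focal!r} not present in matrix")
    if method not in ("L", "H"):
        raise ValueError("method must be 'L' or 'H'")
    if p_source not in ("sample", "controls"):
        raise ValueError("p_source must be 'sample' or 'controls'")
    if p_source == "controls" and matrix.labels is None:
        raise ValueError("p_source='controls' requires a status column")

    fi = matrix.loci.index(focal)
    disease = matrix.codes[:, fi]
    is_control = (
        np.array([lab == "control" for lab in matrix.labels])
        if matrix.labels is not None
        else None
    )

    records: list[ScanRecord] = []
    for j, locus in enumerate(matrix.loci):
        if j == fi:
            continue
        marker = matrix.codes[:, j]
        table, n_complete = _pair_table(marker, disease)
        if n_complete == 0:
            records.append(ScanRecord(locus, 0, "no_data"))
            continue
        if p_source == "controls":
            keep = is_control & (marker >= 0) & (disease >= 0)
            m_ctl = marker[keep]
            if m_ctl.size == 0:
                records.append(ScanRecord(locus, n_complete, "no_data"))
                continue
            p_hat = float(m_ctl.mean() / 2.0)
        else:
            p_hat, _ = allele_freqs(table)
        if q_value is not None:
            q_hat = float(q_value)
            q_source = "survey"
        else:
            _, q_hat = allele_freqs(table)
            q_source = "sample"
        if p_hat in (0.0, 1.0) or q_hat in (0.0, 1.0):
            records.append(ScanRecord(locus, n_complete, "monomorphic"))
            continue
        if method == "L":
            res = estimate_conditional(table, p_hat, q_hat)
        else:
            res = mle_D_joint(table, p_hat, q_hat, mode=h_mode)
        res.p_source = p_source
        res.q_source = q_source
        records.append(ScanRecord(locus, n_complete, "ok", res))
    return records
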