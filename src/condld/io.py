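"""Readers and writers for the package's plain-text formats.

Count tables are 3x3 TSV files with a metadata header line recording allele
orientation; genotype matrices are individuals-by-loci TSV files whose cells
count copies of the designated allele (0/1/2, '.' for missing) with an
optional case/control ``status`` column; simulation configs are flat
``key = value`` files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DISEASE_GENOTYPES, MARKER_GENOTYPES, GenotypeCountTable
from .sampler import SchemeSpec
from .core import PopulationParams

__all__ = [
    "ParseError",
    "GenotypeMatrix",
    "read_count_table",
    "write_count_table",
    "read_genotype_matrix",
    "read_sim_config",
    "result_to_tsv_row",
    "RESULT_COLUMNS",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending line/column."""


_HEADER = "#marker_allele={m} #disease_allele={d}"


def write_count_table(
    table: GenotypeCountTable,
    path,
    marker_allele: str = "M",
    disease_allele: str = "A",
) -> None:
    """Write a count table in the canonical TSV dialect."""
    lines = [_HEADER.format(m=marker_allele, d=disease_allele)]
    lines.append("\t".join(["genotype", *DISEASE_GENOTYPES]))
    for i, row_label in enumerate(MARKER_GENOTYPES):
        cells = [f"{table.counts[i, j]:g}" for j in range(3)]
        lines.append("\t".join([row_label, *cells]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_count_table(path) -> tuple[GenotypeCountTable, dict]:
    """Read a count-table TSV; returns the table and its orientation metadata."""
    text = Path(path).read_text().splitlines()
    meta = {"marker_allele": "M", "disease_allele": "A"}
    rows: dict[str, list[float]] = {}
    saw_header = False
    for lineno, raw in enumerate(text, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            for token in line.lstrip("#").replace("#", " ").split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k.strip()] = v.strip()
            continue
        parts = line.split("\t")
        if parts[0] == "genotype":
            if [p.strip() for p in parts[1:]] != list(DISEASE_GENOTYPES):
                raise ParseError(
                    f"line {lineno}: column labels must be {DISEASE_GENOTYPES}"
                )
            saw_header = True
            continue
        label = parts[0].strip()
        if label not in MARKER_GENOTYPES:
            raise ParseError(f"line {lineno}: unknown row label {label!r}")
        if label in rows:
            raise ParseError(f"line {lineno}: duplicate row {label!r}")
        if len(parts) != 4:
            raise ParseError(f"line {lineno}: expected 3 cells, got {len(parts) - 1}")
        vals = []
        for col, cell in enumerate(parts[1:], start=1):
            try:
                v = float(cell)
            except ValueError:
                raise ParseError(f"line {lineno}, column {col}: non-numeric cell {cell!r}") from None
            if not math.isfinite(v) or v < 0:
                raise ParseError(f"line {lineno}, column {col}: negative or non-finite cell {cell!r}")
            if v != int(v):
                raise ParseError(f"line {lineno}, column {col}: non-integer cell {cell!r}")
            vals.append(v)
        rows[label] = vals
    if not saw_header:
        raise ParseError("missing 'genotype' column-header line")
    missing = [g for g in MARKER_GENOTYPES if g not in rows]
    if missing:
        raise ParseError(f"missing rows: {missing}")
    arr = np.array([rows[g] for g in MARKER_GENOTYPES])
    return GenotypeCountTable(arr), meta


@dataclass
class GenotypeMatrix:
    """Individuals-by-loci genotype codes with optional case/control labels.

    ``codes`` holds copies of the designated allele per locus (0/1/2) with
    ``-1`` for missing.  ``labels`` maps to "case"/"control" when a status
    column was present.
    """

    individuals: list[str]
    loci: list[str]
    codes: np.ndarray  # (n_individuals, n_loci) int8, -1 = missing
    labels: list[str] | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def missingness(self) -> np.ndarray:
        """Per-locus fraction of missing codes."""
        return (self.codes < 0).mean(axis=0)


def read_genotype_matrix(path) -> GenotypeMatrix:
    """Read a genotype matrix TSV (first column: individual id).

    Header gives locus names; an optional trailing ``status`` column carries
    case/control labels.  Cells must be 0, 1, 2 or '.'.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise ParseError("genotype matrix needs an id column and at least one locus")
    seen: set[str] = set()
    dupes = sorted({c for c in header if c in seen or seen.add(c)})
    if dupes:
        raise ParseError(f"duplicated locus names: {dupes}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    id_col = cols[0]
    labels = None
    if cols[-1].lower() == "status":
        status = df[cols[-1]].str.strip().str.lower()
        bad = sorted(set(status) - {"case", "control"})
        if bad:
            raise ParseError(f"status column contains invalid labels: {bad}")
        labels = status.tolist()
        cols = cols[:-1]
    loci = cols[1:]
    individuals = df[id_col].tolist()
    codes = np.empty((len(individuals), len(loci)), dtype=np.int8)
    for j, locus in enumerate(loci):
        col = df[locus].str.strip()
        for i, cell in enumerate(col):
            if cell == ".":
                codes[i, j] = -1
            elif cell in ("0", "1", "2"):
                codes[i, j] = int(cell)
            else:
                raise ParseError(
                    f"locus {locus!r}, individual {individuals[i]!r}: "
                    f"invalid code {cell!r} (allowed: 0, 1, 2, '.')"
                )
    matrix = GenotypeMatrix(individuals, loci, codes, labels)
    for locus, miss in zip(loci, matrix.missingness):
        if miss == 1.0:
            matrix.warnings.append(f"locus {locus!r} is entirely missing")
    return matrix


_CONFIG_KEYS = {
    "scheme", "p", "q", "D", "n", "n_case", "n_control",
    "excluded", "q_mode", "reps", "seed", "methods", "h_mode",
}


def read_sim_config(path) -> dict:
    """Read a flat ``key = value`` simulation config into a typed dict."""
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in _CONFIG_KEYS:
            raise ParseError(f"line {lineno}: unknown key {key!r}")
        out[key] = value
    for key in ("p", "q", "D"):
        if key in out:
            out[key] = float(out[key])
    for key in ("n", "n_case", "n_control", "reps", "seed"):
        if key in out:
            out[key] = int(out[key])
    if "methods" in out:
        out["methods"] = tuple(m.strip() for m in out["methods"].split(",") if m.strip())
    return out


def spec_from_config(cfg: dict) -> tuple[SchemeSpec, dict]:
    """Build a SchemeSpec from a parsed config; returns leftover run options."""
    params = PopulationParams(cfg["p"], cfg["q"], cfg["D"])
    spec = SchemeSpec(
        scheme=cfg["scheme"],
        params=params,
        n=cfg["n"],
        excluded=cfg.get("excluded"),
        n_case=cfg.get("n_case"),
        n_control=cfg.get("n_control"),
        q_mode=cfg.get("q_mode", "sample"),
    )
    run = {
        "reps": cfg.get("reps", 1000),
        "base_seed": cfg.get("seed", 0),
        "methods": cfg.get("methods", ("L", "H")),
        "h_mode": cfg.get("h_mode", "replication"),
    }
    return spec, run


RESULT_COLUMNS = [
    "method", "D_hat", "p_used", "q_used", "p_source", "q_source",
    "loglik_at_Dhat", "loglik_at_0", "lambda", "lod", "p_value",
    "D_min", "D_max", "at_boundary", "out_of_bounds", "degenerate", "converged",
]


def result_to_tsv_row(result) -> str:
    d = result.to_dict()
    cells = []
    for col in RESULT_COLUMNS:
        v = d.get(col)
        if isinstance(v, bool):
            cells.append(str(int(v)))
        elif isinstance(v, float):
            cells.append(f"{v:.10g}")
        else:
            cells.append(str(v))
    return "\t".join(cells)


def result_to_json(result) -> str:
    return json.dumps(result.to_dict(), default=float)
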