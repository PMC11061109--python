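"""TPM normalization and differential-expression status classification.

The differential-expression model fit itself (size factors, dispersion, Wald
tests) is upstream of this module: it consumes a results table of (gene,
log2 fold change, adjusted p) and classifies each gene as up, down,
not_significant or not_detected, then arranges the calls into a component x
condition profile matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .homolog_profile import Registry

__all__ = [
    "STATUS_UP",
    "STATUS_DOWN",
    "STATUS_NS",
    "STATUS_ND",
    "STATUS_CODES",
    "ExpressionRecord",
    "compute_tpm",
    "classify_de",
    "profile_matrix",
    "read_de_table",
    "write_profile_tsv",
]

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_NS = "not_significant"
STATUS_ND = "not_detected"

#: short codes used in the exported profile matrix
STATUS_CODES = {STATUS_UP: "up", STATUS_DOWN: "down", STATUS_NS: "ns", STATUS_ND: "nd"}

_PRECEDENCE = {STATUS_UP: 0, STATUS_DOWN: 1, STATUS_NS: 2, STATUS_ND: 3}

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class ExpressionRecord:
    """Differential-expression call for one gene copy in one condition."""

    taxon_id: str
    gene_id: str
    component: str
    condition_id: str
    log2fc: float
    padj: float | None
    status: str

    def __post_init__(self) -> None:
        if self.status not in _PRECEDENCE:
            raise ValueError(f"bad status {self.status!r}")


def compute_tpm(counts: Sequence[float], lengths: Sequence[float]) -> np.ndarray:
    """Transcripts per million: length-normalize counts, scale to sum 1e6.

    rate_i = counts_i / lengths_i; TPM_i = rate_i / sum_j rate_j * 1e6.
    """
    c = np.asarray(counts, dtype=float)
    ln = np.asarray(lengths, dtype=float)
    if c.shape != ln.shape:
        raise ValueError("counts and lengths must have equal shapes")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    if np.any(ln <= 0):
        raise ValueError("gene lengths must be positive")
    rate = c / ln
    total = rate.sum()
    if total == 0:
        raise ValueError("no expressed genes")
    return rate / total * 1e6


def classify_de(log2fc: float, padj: float | None, alpha: float = DEFAULT_ALPHA) -> str:
    """Classify one differential-expression result.

    Missing padj (gene absent from the analysis) -> not_detected;
    padj > alpha -> not_significant; otherwise the sign of the fold change
    decides: positive -> up, negative -> down.  A fold change of exactly 0 is
    neither up- nor downregulation and classifies as not_significant.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if padj is None or (isinstance(padj, float) and math.isnan(padj)):
        return STATUS_ND
    if not (0 <= padj <= 1):
        raise ValueError(f"padj outside [0, 1]: {padj}")
    if padj > alpha:
        return STATUS_NS
    if log2fc > 0:
        return STATUS_UP
    if log2fc < 0:
        return STATUS_DOWN
    return STATUS_NS


def profile_matrix(
    records: Sequence[ExpressionRecord],
    registry: Registry,
    conditions: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Arrange per-copy calls into a component x condition status grid.

    Components with no record in a condition show ``not_detected`` (the empty
    cell).  When several copies of one component fall in one condition, the
    cell takes the highest-precedence status (up > down > not_significant >
    not_detected) and the copy count is retained in a parallel multiplicity
    grid, so multi-copy evidence is not silently lost.
    """
    if conditions is None:
        conditions = sorted({r.condition_id for r in records})
    comps = registry.symbols
    status = pd.DataFrame(STATUS_ND, index=pd.Index(comps, name="component"),
                          columns=list(conditions))
    mult = pd.DataFrame(0, index=status.index, columns=status.columns, dtype=int)
    for r in records:
        symbol = registry.resolve(r.component)  # KeyError on unknown component
        if r.condition_id not in status.columns:
            continue
        mult.loc[symbol, r.condition_id] += 1
        if _PRECEDENCE[r.status] < _PRECEDENCE[status.loc[symbol, r.condition_id]]:
            status.loc[symbol, r.condition_id] = r.status
    return status, mult


def read_de_table(
    path: str | Path,
    gene_map: Mapping[str, str],
    taxon_id: str,
    condition_id: str,
    alpha: float = DEFAULT_ALPHA,
) -> list[ExpressionRecord]:
    """Read a DE results TSV (gene_id, log2fc, padj) and classify each row.

    ``gene_map`` maps gene ids to component symbols; unmapped genes are
    ignored (they are not pathway members).
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    records = []
    for row in df.itertuples(index=False):
        comp = gene_map.get(str(row.gene_id))
        if comp is None:
            continue
        padj = None if pd.isna(row.padj) else float(row.padj)
        lfc = float(row.log2fc) if not pd.isna(row.log2fc) else 0.0
        records.append(
            ExpressionRecord(taxon_id=taxon_id, gene_id=str(row.gene_id),
                             component=comp, condition_id=condition_id,
                             log2fc=lfc, padj=padj,
                             status=classify_de(lfc, padj, alpha))
        )
    return records


def write_profile_tsv(status: pd.DataFrame, path: str | Path) -> None:
    status.replace(STATUS_CODES).to_csv(path, sep="\t")
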