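"""Reading genome annotations and deriving per-genome spacing statistics.

Coordinates follow the GFF3 convention throughout the package: 1-based,
inclusive on both ends.  ``gene distance`` always means the intergenic gap,
i.e. the number of bases strictly between two genes (overlapping genes are at
distance zero); strand is ignored in every distance computation.
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "GenomeStats",
    "parse_gff",
    "write_gff",
    "genome_stats",
    "genes_per_window",
    "read_gene_table",
    "write_gene_table",
    "write_stats_tsv",
]

_ID_RE = re.compile(r"(?:^|;)\s*ID=([^;]+)")
_NAME_RE = re.compile(r"(?:^|;)\s*Name=([^;]+)")


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene locus (1-based inclusive coordinates)."""

    gene_id: str
    taxon_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "."
    label: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end < start for gene {self.gene_id}: [{self.start}, {self.end}]"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def with_label(self, label: str | None) -> "GeneRecord":
        return replace(self, label=label)


@dataclass(frozen=True)
class GenomeStats:
    """Per-genome gene-geometry summary used by the co-localization null.

    ``mean_spacing`` is the expected centre-to-centre distance between
    consecutive genes, i.e. mean gene length plus mean intergenic gap.
    """

    taxon_id: str
    n_genes: int
    mean_gene_length: float
    mean_intergenic_gap: float
    mean_spacing: float
    contig_gene_counts: dict[str, int] = field(default_factory=dict)


def parse_gff(
    path: str | Path,
    taxon_id: str,
    feature_type: str = "gene",
    fallback_type: str | None = "mRNA",
) -> list[GeneRecord]:
    """Read gene records of ``feature_type`` from a GFF3 file.

    Coordinates are preserved as written.  Records whose end precedes their
    start are rejected with a logged warning.  When the file contains no
    features of ``feature_type`` at all, ``fallback_type`` (by default
    ``mRNA``, for annotations that lack explicit gene rows) is tried instead.
    Returns records sorted by (contig, start); an empty list when nothing
    matches.
    """
    path = Path(path)
    wanted = {feature_type}
    records = _scan_gff(path, taxon_id, wanted)
    if not records and fallback_type and fallback_type != feature_type:
        records = _scan_gff(path, taxon_id, {fallback_type})
        if records:
            logger.info(
                "no %r features in %s; fell back to %r", feature_type, path, fallback_type
            )
    records.sort(key=lambda g: (g.contig_id, g.start, g.end, g.gene_id))
    return records


def _scan_gff(path: Path, taxon_id: str, wanted: set[str]) -> list[GeneRecord]:
    records: list[GeneRecord] = []
    n_anon = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                logger.warning("%s:%d: expected 9 columns, got %d; skipped",
                               path, lineno, len(fields))
                continue
            contig, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype not in wanted:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                logger.warning("%s:%d: non-numeric coordinates; skipped", path, lineno)
                continue
            if end < start:
                logger.warning(
                    "%s:%d: malformed coordinates end < start (%d < %d); record rejected",
                    path, lineno, end, start,
                )
                continue
            m = _ID_RE.search(attrs) or _NAME_RE.search(attrs)
            if m:
                gene_id = m.group(1).strip()
            else:
                n_anon += 1
                gene_id = f"{next(iter(wanted))}_{n_anon}"
            if strand not in {"+", "-", "."}:
                strand = "."
            records.append(
                GeneRecord(gene_id=gene_id, taxon_id=taxon_id, contig_id=contig,
                           start=start, end=end, strand=strand)
            )
    return records


def write_gff(genes: Iterable[GeneRecord], path: str | Path,
              feature_type: str = "gene", source: str = "facoloc") -> None:
    """Write gene records as a minimal GFF3 file (lossless round trip)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig_id, g.start, g.end, g.gene_id)):
            fh.write(
                f"{g.contig_id}\t{source}\t{feature_type}\t{g.start}\t{g.end}"
                f"\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def genome_stats(genes: Sequence[GeneRecord]) -> GenomeStats:
    """Summarize gene geometry: gene count, mean length, mean intergenic gap.

    The intergenic gap between consecutive same-contig genes (sorted by
    start) is ``max(0, next.start - prev.end - 1)``: the bases strictly
    between the two, zero when they overlap.  Contigs holding a single gene
    contribute no gap term; if no contig holds two genes the mean gap is
    defined as 0 with a warning.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("no genes")
    taxa = {g.taxon_id for g in genes}
    taxon_id = genes[0].taxon_id if len(taxa) == 1 else "+".join(sorted(taxa))

    by_contig: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)

    total_len = sum(g.length for g in genes)
    gaps: list[int] = []
    for contig_genes in by_contig.values():
        contig_genes.sort(key=lambda g: (g.start, g.end))
        for prev, nxt in zip(contig_genes, contig_genes[1:]):
            gaps.append(max(0, nxt.start - prev.end - 1))

    mean_len = total_len / len(genes)
    if gaps:
        mean_gap = sum(gaps) / len(gaps)
    else:
        warnings.warn(
            "every contig holds a single gene; mean intergenic gap undefined, using 0",
            stacklevel=2,
        )
        mean_gap = 0.0

    return GenomeStats(
        taxon_id=taxon_id,
        n_genes=len(genes),
        mean_gene_length=mean_len,
        mean_intergenic_gap=mean_gap,
        mean_spacing=mean_len + mean_gap,
        contig_gene_counts={c: len(v) for c, v in by_contig.items()},
    )


def genes_per_window(stats: GenomeStats, window: int) -> int:
    """Expected number of gene slots on ONE side of a focal gene within ``window``.

    ``m = floor(window / mean_spacing)`` clamped to ``[0, n_genes - 1]``.
    The two-sided neighborhood used by the analytic null is ``2m``.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if stats.mean_spacing <= 0:
        raise ValueError("degenerate spacing: mean_spacing must be positive")
    m = math.floor(window / stats.mean_spacing)
    return max(0, min(m, stats.n_genes - 1))


# ---------------------------------------------------------------------------
# tabular IO

_GENE_TABLE_COLS = ["taxon_id", "gene_id", "contig_id", "start", "end", "component"]


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a labeled gene table TSV (taxon_id, gene_id, contig_id, start, end,
    component).  An empty/missing component field yields an unlabeled record."""
    df = pd.read_csv(path, sep="\t", dtype={"taxon_id": str, "gene_id": str,
                                            "contig_id": str, "component": str})
    missing = [c for c in _GENE_TABLE_COLS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        label = getattr(row, "component", None)
        if label is not None and (pd.isna(label) or label == ""):
            label = None
        records.append(
            GeneRecord(gene_id=row.gene_id, taxon_id=row.taxon_id,
                       contig_id=row.contig_id, start=int(row.start),
                       end=int(row.end), label=label)
        )
    records.sort(key=lambda g: (g.taxon_id, g.contig_id, g.start, g.gene_id))
    return records


def write_gene_table(genes: Iterable[GeneRecord], path: str | Path) -> None:
    rows = [
        {"taxon_id": g.taxon_id, "gene_id": g.gene_id, "contig_id": g.contig_id,
         "start": g.start, "end": g.end, "component": g.label or ""}
        for g in genes
    ]
    pd.DataFrame(rows, columns=_GENE_TABLE_COLS).to_csv(path, sep="\t", index=False)


def write_stats_tsv(stats: GenomeStats, path: str | Path) -> None:
    pd.DataFrame(
        [{
            "taxon_id": stats.taxon_id,
            "n_genes": stats.n_genes,
            "mean_gene_length": stats.mean_gene_length,
            "mean_intergenic_gap": stats.mean_intergenic_gap,
            "mean_spacing": stats.mean_spacing,
        }]
    ).to_csv(path, sep="\t", index=False)
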