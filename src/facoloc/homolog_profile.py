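"""Phyletic profiling of pathway components from homology-hit tables.

Workflow: filter BLAST-style hits at an e-value cutoff, assign each target
protein to the component of its best-scoring hit, optionally require the
assigned component's diagnostic Pfam domain, and tabulate per-taxon copy
numbers.  Domain-architecture helpers flag truncations (missing reference
domains) and gene fusions (diagnostic domains of two components in disjoint
regions of one protein).

The best-hit assignment deliberately replaces interactive sequence-space
clustering: it is a deterministic rule (max bitscore, then min e-value, then
lexicographic component symbol) whose non-specific hits are removed by the
domain gate rather than by manual cluster inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

__all__ = [
    "SUBCOMPLEXES",
    "FAComponent",
    "Registry",
    "load_registry",
    "HomologHit",
    "DomainAnnotation",
    "Assignment",
    "filter_hits",
    "assign_best",
    "confirm_architecture",
    "build_presence_matrix",
    "detect_fusions",
    "architecture_report",
    "read_hits",
    "read_domains",
    "FusionCall",
    "ArchitectureReport",
]

SUBCOMPLEXES = (
    "Activation",
    "Core complex",
    "Monoubiquitination",
    "ID complex",
    "Endonuclease",
    "HR and DNA repair",
    "Deubiquitination",
)

DEFAULT_EVALUE_MAX = 1e-5


@dataclass(frozen=True)
class FAComponent:
    """A pathway-registry entry: gene symbol, aliases, diagnostic domains."""

    symbol: str
    aliases: tuple[str, ...] = ()
    pfam_accessions: tuple[str, ...] = ()
    interpro_accessions: tuple[str, ...] = ()
    subcomplex: str = "Core complex"

    def __post_init__(self) -> None:
        if self.subcomplex not in SUBCOMPLEXES:
            raise ValueError(f"unknown subcomplex {self.subcomplex!r}")


class Registry:
    """Ordered collection of pathway components, addressable by symbol or alias."""

    def __init__(self, components: Iterable[FAComponent]):
        self._by_symbol: dict[str, FAComponent] = {}
        for comp in components:
            if comp.symbol in self._by_symbol:
                raise ValueError(f"duplicate component symbol {comp.symbol}")
            self._by_symbol[comp.symbol] = comp
        self._alias_map: dict[str, str] = {}
        for comp in self._by_symbol.values():
            self._alias_map[comp.symbol] = comp.symbol
            for alias in comp.aliases:
                self._alias_map.setdefault(alias, comp.symbol)

    @property
    def symbols(self) -> list[str]:
        return list(self._by_symbol)

    def __len__(self) -> int:
        return len(self._by_symbol)

    def __contains__(self, name: str) -> bool:
        return name in self._alias_map

    def __getitem__(self, name: str) -> FAComponent:
        return self._by_symbol[self.resolve(name)]

    def __iter__(self):
        return iter(self._by_symbol.values())

    def resolve(self, name: str) -> str:
        """Map a symbol or alias to the canonical component symbol."""
        try:
            return self._alias_map[name]
        except KeyError:
            raise KeyError(f"unknown component or alias {name!r}") from None

    def pfam_to_components(self) -> dict[str, set[str]]:
        """Reverse map accession -> component symbols (accessions may be shared,
        e.g. the RAD51-family domain diagnoses several paralogs)."""
        rev: dict[str, set[str]] = {}
        for comp in self:
            for acc in comp.pfam_accessions:
                rev.setdefault(acc, set()).add(comp.symbol)
        return rev


def load_registry(path: str | Path | None = None) -> Registry:
    """Load the component registry; defaults to the packaged Fanconi Anemia
    pathway table (40 components).  Any TSV with columns symbol, aliases,
    pfam, interpro, subcomplex (';'-separated lists) substitutes another
    pathway."""
    if path is None:
        source = resources.files("facoloc.data").joinpath("fa_registry.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", dtype=str).fillna("")
    else:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    comps = []
    for row in df.itertuples(index=False):
        comps.append(
            FAComponent(
                symbol=row.symbol,
                aliases=tuple(a for a in row.aliases.split(";") if a),
                pfam_accessions=tuple(a for a in row.pfam.split(";") if a),
                interpro_accessions=tuple(a for a in row.interpro.split(";") if a),
                subcomplex=row.subcomplex,
            )
        )
    return Registry(comps)


@dataclass(frozen=True)
class HomologHit:
    """One homology-search hit of a pathway reference against a target proteome."""

    component: str
    target_protein_id: str
    taxon_id: str
    evalue: float
    bitscore: float
    target_start: int = 1
    target_end: int = 1

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.target_start > self.target_end:
            raise ValueError("target_start > target_end")


@dataclass(frozen=True)
class DomainAnnotation:
    """One Pfam-style domain interval on a protein (1-based inclusive, aa)."""

    protein_id: str
    domain_accession: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("domain start > end")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class Assignment:
    protein_id: str
    taxon_id: str
    component: str
    bitscore: float
    evalue: float


def filter_hits(hits: Sequence[HomologHit],
                evalue_max: float = DEFAULT_EVALUE_MAX) -> list[HomologHit]:
    """Keep hits with e-value <= cutoff (inclusive); order preserved."""
    if evalue_max <= 0:
        raise ValueError("evalue_max must be positive")
    return [h for h in hits if h.evalue <= evalue_max]


def assign_best(hits: Sequence[HomologHit]) -> dict[str, Assignment]:
    """Assign each target protein to the component of its maximum-bitscore hit.

    Ties broken by lower e-value, then lexicographically smaller component
    symbol, so the assignment is a deterministic function of the hit set and
    invariant to input order.
    """
    best: dict[str, HomologHit] = {}
    for h in hits:
        cur = best.get(h.target_protein_id)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            best[h.target_protein_id] = h
    return {
        pid: Assignment(protein_id=pid, taxon_id=h.taxon_id, component=h.component,
                        bitscore=h.bitscore, evalue=h.evalue)
        for pid, h in best.items()
    }


def _hit_rank(h: HomologHit) -> tuple:
    return (-h.bitscore, h.evalue, h.component)


class ConfirmResult(NamedTuple):
    retained: dict[str, Assignment]
    dropped: list[tuple[str, str, str]]  # (protein_id, component, reason)


def confirm_architecture(
    assignment: Mapping[str, Assignment],
    domains: Sequence[DomainAnnotation],
    registry: Registry,
    require: bool = True,
) -> ConfirmResult:
    """Gate assignments on the presence of the component's diagnostic domain.

    With ``require=True``, an assignment is dropped when its protein carries
    none of the assigned component's diagnostic Pfam accessions; components
    whose registry entry lists no Pfam accession are exempt (their presence
    can only be asserted by homology).  Dropped assignments are reported with
    a reason string.
    """
    by_protein: dict[str, set[str]] = {}
    for d in domains:
        by_protein.setdefault(d.protein_id, set()).add(d.domain_accession)

    retained: dict[str, Assignment] = {}
    dropped: list[tuple[str, str, str]] = []
    for pid, asg in assignment.items():
        if asg.component not in registry:
            raise KeyError(f"unknown component symbol {asg.component!r}")
        comp = registry[asg.component]
        if not require or not comp.pfam_accessions:
            retained[pid] = asg
            continue
        present = by_protein.get(pid, set())
        if present & set(comp.pfam_accessions):
            retained[pid] = asg
        else:
            dropped.append(
                (pid, asg.component,
                 f"no diagnostic domain of {asg.component} "
                 f"({','.join(comp.pfam_accessions)}) found")
            )
    return ConfirmResult(retained=retained, dropped=dropped)


def build_presence_matrix(
    assignments: Mapping[str, Assignment],
    taxa: Sequence[str] | None = None,
    registry: Registry | None = None,
) -> pd.DataFrame:
    """Copy-number matrix: taxa rows x component columns, counting distinct
    assigned proteins.  Requested taxa / registry components with no evidence
    appear as explicit zero rows / columns."""
    if registry is None:
        registry = load_registry()
    row_taxa = sorted(set(taxa or []) | {a.taxon_id for a in assignments.values()})
    mat = pd.DataFrame(0, index=pd.Index(row_taxa, name="taxon_id"),
                       columns=registry.symbols, dtype=int)
    for asg in assignments.values():
        symbol = registry.resolve(asg.component)
        mat.loc[asg.taxon_id, symbol] += 1
    return mat


class FusionCall(NamedTuple):
    protein_id: str
    component_n: str  # N-terminal component
    component_c: str  # C-terminal component
    n_interval: tuple[int, int]
    c_interval: tuple[int, int]


def detect_fusions(
    domains: Sequence[DomainAnnotation],
    registry: Registry,
    min_separation: int = 100,
) -> list[FusionCall]:
    """Call gene fusions: one protein carrying diagnostic domains of two
    distinct components in disjoint regions.

    For each protein, domain intervals are grouped per component (via the
    registry's Pfam reverse map); a pair of components is called when their
    interval spans do not overlap and their midpoints lie at least
    ``min_separation`` aa apart.  A domain accession shared by several
    components (identical span for each) can never separate those components
    from one another.  Components are reported in N-to-C order.
    """
    rev = registry.pfam_to_components()
    by_protein: dict[str, dict[str, list[DomainAnnotation]]] = {}
    for d in domains:
        for comp in rev.get(d.domain_accession, ()):
            by_protein.setdefault(d.protein_id, {}).setdefault(comp, []).append(d)

    calls: list[FusionCall] = []
    for pid in sorted(by_protein):
        comp_spans: dict[str, tuple[int, int]] = {}
        for comp, ds in by_protein[pid].items():
            comp_spans[comp] = (min(d.start for d in ds), max(d.end for d in ds))
        comps = sorted(comp_spans)
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                a, b = comps[i], comps[j]
                sa, sb = comp_spans[a], comp_spans[b]
                if sa[1] >= sb[0] and sb[1] >= sa[0]:
                    continue  # overlapping spans: no fusion call
                mid_a = (sa[0] + sa[1]) / 2.0
                mid_b = (sb[0] + sb[1]) / 2.0
                if abs(mid_a - mid_b) < min_separation:
                    continue
                if mid_a <= mid_b:
                    calls.append(FusionCall(pid, a, b, sa, sb))
                else:
                    calls.append(FusionCall(pid, b, a, sb, sa))
    return calls


class ArchitectureReport(NamedTuple):
    missing: tuple[str, ...]
    extra: tuple[str, ...]
    length_ratio: float | None


def architecture_report(
    protein_domains: Sequence[DomainAnnotation] | Sequence[str],
    reference_architecture: Sequence[str],
    protein_length: int | None = None,
    reference_length: int | None = None,
) -> ArchitectureReport:
    """Compare a protein's domain content against a reference architecture.

    ``missing`` lists reference accessions absent from the protein (reference
    order preserved); ``extra`` lists protein accessions outside the
    reference; ``length_ratio`` is protein/reference length when both are
    given — a ratio well below 1 together with missing domains indicates a
    truncated homolog.
    """
    if not reference_architecture:
        raise ValueError("reference architecture must be non-empty")
    accs: set[str] = set()
    for d in protein_domains:
        accs.add(d.domain_accession if isinstance(d, DomainAnnotation) else str(d))
    ref = list(reference_architecture)
    missing = tuple(a for a in ref if a not in accs)
    extra = tuple(sorted(accs - set(ref)))
    ratio = None
    if protein_length is not None and reference_length:
        ratio = protein_length / reference_length
    return ArchitectureReport(missing=missing, extra=extra, length_ratio=ratio)


# ---------------------------------------------------------------------------
# tabular IO

_OUTFMT6_COLS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                 "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def read_hits(
    path: str | Path,
    registry: Registry | None = None,
    query_map: Mapping[str, str] | None = None,
    default_taxon: str = "unknown",
) -> list[HomologHit]:
    """Read a BLAST tabular (outfmt 6 style) hit table.

    ``qseqid`` must be a component symbol or alias, or resolvable through
    ``query_map`` (reference protein id -> component).  An optional 13th
    column is taken as the target taxon id.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    if ncol < 12:
        raise ValueError(f"hit table needs >= 12 columns, got {ncol}")
    names = list(_OUTFMT6_COLS) + (["taxon_id"] if ncol >= 13 else [])
    df = df.iloc[:, : len(names)]
    df.columns = names
    hits = []
    for row in df.itertuples(index=False):
        q = str(row.qseqid)
        if query_map and q in query_map:
            q = query_map[q]
        if registry is not None:
            q = registry.resolve(q)
        taxon = str(getattr(row, "taxon_id", default_taxon))
        hits.append(
            HomologHit(component=q, target_protein_id=str(row.sseqid), taxon_id=taxon,
                       evalue=float(row.evalue), bitscore=float(row.bitscore),
                       target_start=int(row.sstart), target_end=int(row.send))
        )
    return hits


def read_domains(path: str | Path) -> list[DomainAnnotation]:
    """Read a pfam_scan-style domain table TSV: protein_id, accession, start, end."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    cols = {c.lower(): c for c in df.columns}
    needed = ["protein_id", "accession", "start", "end"]
    if not all(k in cols for k in needed):
        raise ValueError(f"domain table must have columns {needed}")
    return [
        DomainAnnotation(protein_id=str(r[cols["protein_id"]]),
                         domain_accession=str(r[cols["accession"]]),
                         start=int(r[cols["start"]]), end=int(r[cols["end"]]))
        for _, r in df.iterrows()
    ]
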