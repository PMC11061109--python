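"""Synthetic genomes, hit tables and DE tables with known planted truth.

Every pipeline stage can be exercised without downloads: the generator lays
out multi-contig gene coordinates with realistic length/spacing
distributions, plants pathway labels either uniformly (null) or as a tight
cluster (alternative), fabricates homology-hit tables whose true homologs
and decoys straddle the e-value filter, and fabricates DE result tables that
the classifier must recover exactly.

Default geometry emulates a compact fungal genome: log-normal gene lengths
with median ~1.5 kb and exponential intergenic gaps with mean ~1 kb, so a
250 kb window spans on the order of a hundred genes — the regime the
co-localization null is designed for.  All draws are governed by one integer
seed fanned out to per-generator sub-streams with fixed spawn keys, so
adding a generator never perturbs existing draws.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneRecord, write_gene_table, write_gff
from .homolog_profile import DomainAnnotation, HomologHit, Registry, load_registry

__all__ = [
    "SyntheticGenomeSpec",
    "PlantedTruth",
    "simulate_genome",
    "plant_labels",
    "simulate_hit_table",
    "simulate_domain_table",
    "make_fusion_evidence",
    "simulate_de_table",
    "write_dataset",
]

# fixed spawn keys: one sub-stream per generator
_KEY_GENOME, _KEY_LABELS, _KEY_HITS, _KEY_DE, _KEY_DOMAINS = 0, 1, 2, 3, 4


def _rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Parameters of a synthetic multi-contig genome.

    ``gene_length_median``/``gene_length_sigma`` parameterize a log-normal
    length distribution (bp); ``gap_mean`` an exponential intergenic gap
    (bp).  Constant geometries (for closed-form layouts) are selected with
    ``constant_length``/``constant_gap``.
    """

    n_contigs: int = 5
    genes_per_contig: int = 400
    gene_length_median: float = 1500.0
    gene_length_sigma: float = 0.6
    gap_mean: float = 1000.0
    constant_length: int | None = None
    constant_gap: int | None = None
    taxon_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_contigs < 1 or self.genes_per_contig < 1:
            raise ValueError("need >= 1 contig and >= 1 gene per contig")
        if self.gene_length_median <= 0 or self.gap_mean < 0:
            raise ValueError("distribution parameters must be positive")

    @property
    def mean_gene_length(self) -> float:
        if self.constant_length is not None:
            return float(self.constant_length)
        return self.gene_length_median * math.exp(self.gene_length_sigma ** 2 / 2)

    @property
    def mean_gap(self) -> float:
        if self.constant_gap is not None:
            return float(self.constant_gap)
        return self.gap_mean


@dataclass
class PlantedTruth:
    """Ground truth recorded by the generators."""

    fa_gene_ids: set[str] = field(default_factory=set)
    clusters: list[tuple[frozenset, int]] = field(default_factory=list)
    hit_truth: dict[str, str] = field(default_factory=dict)
    de_truth: dict[str, str] = field(default_factory=dict)


def simulate_genome(spec: SyntheticGenomeSpec, seed: int = 0) -> list[GeneRecord]:
    """Lay genes sequentially per contig.

    start_1 = 1 + gap_0; end_i = start_i + length_i - 1;
    start_{i+1} = end_i + 1 + gap_i.  Deterministic under (spec, seed).
    """
    rng = _rng(seed, _KEY_GENOME)
    genes: list[GeneRecord] = []
    n = spec.genes_per_contig
    for ci in range(spec.n_contigs):
        if spec.constant_length is not None:
            lengths = np.full(n, spec.constant_length, dtype=np.int64)
        else:
            lengths = np.maximum(
                1,
                np.round(rng.lognormal(math.log(spec.gene_length_median),
                                       spec.gene_length_sigma, n)).astype(np.int64),
            )
        if spec.constant_gap is not None:
            gaps = np.full(n, spec.constant_gap, dtype=np.int64)
        else:
            gaps = np.round(rng.exponential(spec.gap_mean, n)).astype(np.int64)
        contig = f"ctg{ci + 1}"
        pos = 1 + int(gaps[0])
        for gi in range(n):
            start = pos
            end = start + int(lengths[gi]) - 1
            genes.append(
                GeneRecord(gene_id=f"{contig}_g{gi + 1:05d}", taxon_id=spec.taxon_id,
                           contig_id=contig, start=start, end=end,
                           strand="+" if rng.random() < 0.5 else "-")
            )
            if gi + 1 < n:
                pos = end + 1 + int(gaps[gi + 1])
    return genes


def _default_labels(k: int) -> list[str]:
    return [f"FA{i + 1:03d}" for i in range(k)]


def plant_labels(
    genes: Sequence[GeneRecord],
    K: int,
    mode: str = "uniform",
    cluster_size: int = 5,
    max_span: int = 100_000,
    seed: int = 0,
    components: Sequence[str] | None = None,
) -> tuple[list[GeneRecord], PlantedTruth]:
    """Plant K pathway labels on a genome; returns labeled copies plus truth.

    ``uniform`` draws K loci without replacement over all genes — the null of
    the co-localization test.  ``clustered`` places ``cluster_size`` labels
    on consecutive same-contig genes whose total span of intergenic distance
    is <= ``max_span`` and spreads the remaining K - cluster_size labels
    uniformly over genes at least ``max_span`` away from the cluster, so the
    only planted signal is the cluster itself.
    """
    if K > len(genes):
        raise ValueError("K > number of genes")
    if components is not None and len(components) < K:
        raise ValueError("need >= K component labels")
    labels = list(components) if components is not None else _default_labels(K)
    rng = _rng(seed, _KEY_LABELS)
    ordered = sorted(genes, key=lambda g: (g.contig_id, g.start, g.gene_id))
    n = len(ordered)

    if mode == "uniform":
        chosen = sorted(rng.choice(n, size=K, replace=False).tolist())
        cluster_members: list[int] = []
    elif mode == "clustered":
        if cluster_size > K:
            raise ValueError("cluster_size > K")
        runs = []
        for i in range(n - cluster_size + 1):
            first, last = ordered[i], ordered[i + cluster_size - 1]
            if first.contig_id != last.contig_id:
                continue
            span = last.start - first.end - 1
            if span <= max_span:
                runs.append(i)
        if not runs:
            raise ValueError(
                f"no run of {cluster_size} same-contig genes fits max_span={max_span}"
            )
        i0 = int(runs[rng.integers(len(runs))])
        cluster_members = list(range(i0, i0 + cluster_size))
        # remainder placed away from the cluster (distance-based exclusion)
        contig = ordered[i0].contig_id
        lo = ordered[i0].start - max_span
        hi = ordered[cluster_members[-1]].end + max_span
        eligible = [
            j for j in range(n)
            if j not in cluster_members
            and not (ordered[j].contig_id == contig and lo <= ordered[j].start <= hi)
        ]
        extra = K - cluster_size
        if extra > len(eligible):
            raise ValueError("not enough eligible genes for the uniform remainder")
        picked = rng.choice(len(eligible), size=extra, replace=False) if extra else []
        chosen = sorted(cluster_members + [eligible[int(j)] for j in picked])
    else:
        raise ValueError(f"unknown mode {mode!r}")

    label_of = {idx: labels[k] for k, idx in enumerate(chosen)}
    labeled = [
        g.with_label(label_of[i]) if i in label_of else g
        for i, g in enumerate(ordered)
    ]
    truth = PlantedTruth(fa_gene_ids={ordered[i].gene_id for i in chosen})
    if cluster_members:
        truth.clusters.append(
            (frozenset(ordered[i].gene_id for i in cluster_members), max_span)
        )
    return labeled, truth


def simulate_hit_table(
    truth: Mapping[str, str],
    n_decoys: int = 0,
    seed: int = 0,
    taxon_id: str = "synthetic",
    registry: Registry | None = None,
) -> tuple[list[HomologHit], PlantedTruth]:
    """Fabricate a homology-hit table around a protein -> component truth map.

    True homologs receive e-values 10^-U(10, 100) and dominant bitscores
    (U(250, 500)) for their true component, plus one weaker cross-component
    hit (bitscore U(50, 200), e-value still below the filter) so that the
    best-hit rule is actually exercised.  Decoys receive e-values
    10^-U(0, 4.5), all above the 1e-5 cutoff, and never survive filtering.
    """
    if registry is None:
        registry = load_registry()
    rng = _rng(seed, _KEY_HITS)
    symbols = registry.symbols
    hits: list[HomologHit] = []
    for pid in sorted(truth):
        comp = truth[pid]
        hits.append(HomologHit(
            component=comp, target_protein_id=pid, taxon_id=taxon_id,
            evalue=10.0 ** -rng.uniform(10, 100), bitscore=float(rng.uniform(250, 500)),
            target_start=1, target_end=int(rng.integers(200, 800)),
        ))
        others = [s for s in symbols if s != registry.resolve(comp)]
        cross = others[int(rng.integers(len(others)))]
        hits.append(HomologHit(
            component=cross, target_protein_id=pid, taxon_id=taxon_id,
            evalue=10.0 ** -rng.uniform(6, 9), bitscore=float(rng.uniform(50, 200)),
            target_start=1, target_end=int(rng.integers(100, 400)),
        ))
    for i in range(n_decoys):
        comp = symbols[int(rng.integers(len(symbols)))]
        hits.append(HomologHit(
            component=comp, target_protein_id=f"DECOY_{i + 1:04d}", taxon_id=taxon_id,
            evalue=10.0 ** -rng.uniform(0, 4.5), bitscore=float(rng.uniform(20, 60)),
            target_start=1, target_end=int(rng.integers(50, 300)),
        ))
    out = PlantedTruth(hit_truth=dict(truth))
    return hits, out


def simulate_domain_table(
    truth: Mapping[str, str],
    registry: Registry | None = None,
    seed: int = 0,
    wrong_domain_proteins: Sequence[str] = (),
) -> list[DomainAnnotation]:
    """Domain annotations consistent with a protein -> component truth map.

    Each protein gets one diagnostic domain of its true component (when the
    registry lists one).  Proteins named in ``wrong_domain_proteins`` instead
    receive a domain diagnostic of a different component, so that the
    architecture gate must drop them.
    """
    if registry is None:
        registry = load_registry()
    rng = _rng(seed, _KEY_DOMAINS)
    wrong = set(wrong_domain_proteins)
    rows: list[DomainAnnotation] = []
    for pid in sorted(truth):
        comp = registry[truth[pid]]
        accs = comp.pfam_accessions
        if pid in wrong:
            pool = [
                a for other in registry
                for a in other.pfam_accessions
                if a not in accs
            ]
            acc = pool[int(rng.integers(len(pool)))]
        elif accs:
            acc = accs[0]
        else:
            continue  # component with no diagnostic domain: nothing to annotate
        start = int(rng.integers(5, 50))
        rows.append(DomainAnnotation(protein_id=pid, domain_accession=acc,
                                     start=start, end=start + 180))
    return rows


def make_fusion_evidence(
    protein_id: str,
    component_n: str,
    component_c: str,
    registry: Registry | None = None,
    taxon_id: str = "synthetic",
    protein_length: int = 1850,
) -> tuple[list[HomologHit], list[DomainAnnotation]]:
    """Evidence for a two-component fusion protein: strong hits to both
    components with disjoint target intervals, and both diagnostic domains at
    opposite ends of an atypically long protein."""
    if registry is None:
        registry = load_registry()
    comp_n, comp_c = registry[component_n], registry[component_c]
    if not comp_n.pfam_accessions or not comp_c.pfam_accessions:
        raise ValueError("both fusion partners need diagnostic domains")
    n_end = protein_length // 3
    c_start = protein_length - protein_length // 4
    hits = [
        HomologHit(component=comp_n.symbol, target_protein_id=protein_id,
                   taxon_id=taxon_id, evalue=1e-50, bitscore=400.0,
                   target_start=10, target_end=n_end),
        HomologHit(component=comp_c.symbol, target_protein_id=protein_id,
                   taxon_id=taxon_id, evalue=1e-40, bitscore=350.0,
                   target_start=c_start, target_end=protein_length - 20),
    ]
    domains = [
        DomainAnnotation(protein_id=protein_id,
                         domain_accession=comp_n.pfam_accessions[0],
                         start=10, end=n_end),
        DomainAnnotation(protein_id=protein_id,
                         domain_accession=comp_c.pfam_accessions[0],
                         start=c_start, end=protein_length - 20),
    ]
    return hits, domains


def simulate_de_table(
    planted: Mapping[str, str | Sequence[str]],
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Fabricate a DE results table from a component -> status plant.

    up: log2fc ~ +U(0.5, 3), padj ~ U(0, alpha); down: negated fold change;
    not_significant: padj ~ U(alpha, 1); not_detected: row absent.  A list of
    statuses plants multiple gene copies of one component.  The classifier
    recovers the plant exactly by construction.
    """
    rng = _rng(seed, _KEY_DE)
    rows = []
    truth: dict[str, str] = {}
    for comp in sorted(planted):
        statuses = planted[comp]
        if isinstance(statuses, str):
            statuses = [statuses]
        for i, status in enumerate(statuses):
            gene_id = f"{comp.lower()}_g{i + 1}"
            truth[gene_id] = status
            if status == "not_detected":
                continue
            if status == "up":
                lfc = float(rng.uniform(0.5, 3.0))
                padj = float(rng.uniform(0, alpha))
            elif status == "down":
                lfc = -float(rng.uniform(0.5, 3.0))
                padj = float(rng.uniform(0, alpha))
            elif status == "not_significant":
                lfc = float(rng.uniform(-1, 1))
                padj = float(rng.uniform(alpha, 1))
                padj = min(1.0, max(padj, np.nextafter(alpha, 1.0)))
            else:
                raise ValueError(f"unknown status {status!r}")
            rows.append({"gene_id": gene_id, "component": comp,
                         "log2fc": lfc, "padj": padj})
    df = pd.DataFrame(rows, columns=["gene_id", "component", "log2fc", "padj"])
    return df, PlantedTruth(de_truth=truth)


def write_dataset(preset: str, out_dir: str | Path, seed: int = 17) -> None:
    """Write a full synthetic dataset (GFF3, label table, hit table, DE table,
    truth JSON) for the ``null`` or ``clustered`` preset."""
    if preset not in {"null", "clustered"}:
        raise ValueError("preset must be 'null' or 'clustered'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = load_registry()

    spec = SyntheticGenomeSpec()
    genes = simulate_genome(spec, seed=seed)
    components = registry.symbols[:20]
    labeled, truth = plant_labels(
        genes, K=20, mode="uniform" if preset == "null" else "clustered",
        cluster_size=5, max_span=100_000, seed=seed, components=components,
    )
    write_gff(labeled, out / "genome.gff3")
    write_gene_table(labeled, out / "genes.tsv")

    hit_truth = {f"PROT_{s}": s for s in components}
    hits, hit_t = simulate_hit_table(hit_truth, n_decoys=30, seed=seed,
                                     taxon_id=spec.taxon_id, registry=registry)
    pd.DataFrame([
        {"qseqid": h.component, "sseqid": h.target_protein_id, "pident": 40.0,
         "length": h.target_end - h.target_start + 1, "mismatch": 0, "gapopen": 0,
         "qstart": 1, "qend": h.target_end, "sstart": h.target_start,
         "send": h.target_end, "evalue": h.evalue, "bitscore": h.bitscore,
         "taxon_id": h.taxon_id}
        for h in hits
    ]).to_csv(out / "hits.tsv", sep="\t", index=False, header=False)

    domains = simulate_domain_table(hit_truth, registry, seed=seed)
    pd.DataFrame([
        {"protein_id": d.protein_id, "accession": d.domain_accession,
         "start": d.start, "end": d.end}
        for d in domains
    ]).to_csv(out / "domains.tsv", sep="\t", index=False)

    plant = {s: ["up", "down", "not_significant", "not_detected"][i % 4]
             for i, s in enumerate(components)}
    de, de_t = simulate_de_table(plant, seed=seed)
    de.to_csv(out / "de_results.tsv", sep="\t", index=False)

    truth_blob = {
        "preset": preset,
        "seed": seed,
        "fa_gene_ids": sorted(truth.fa_gene_ids),
        "clusters": [[sorted(c), span] for c, span in truth.clusters],
        "hit_truth": hit_t.hit_truth,
        "de_truth": de_t.de_truth,
    }
    (out / "truth.json").write_text(json.dumps(truth_blob, indent=2))
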