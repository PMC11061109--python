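"""Genomic co-localization of pathway genes and its random-placement null.

Two pathway genes are *colocalized* when they sit on the same contig within a
window W (default 250 kb, the range of enhancer-promoter-scale interactions);
same-contig pairs beyond W are *long-range*.  Distances are intergenic gaps:
bases strictly between the two loci, zero on overlap.

The per-genome test asks whether the observed number of pathway genes having
at least one pathway neighbor within W (the statistic X) is larger than
expected if the K pathway labels fell uniformly on the genome's N gene loci.
Two p-values are produced:

* ``p_analytic`` — a closed form built from average gene geometry: a focal
  gene sees d = min(2m, N-1) neighboring gene slots (m = floor(W / mean
  spacing) per side); the chance that none of the other K-1 labels falls in
  those d slots is hypergeometric, and X is approximated as Binomial(K,
  p_focal).  This ignores contig ends and the pairing dependence between
  labels (if a gene has a neighbor, that neighbor has one too), so it is an
  approximation — accurate in the sparse regime (K*m << N), biased otherwise.
* ``p_perm`` — the authoritative Monte Carlo p-value: K labels are reassigned
  uniformly without replacement over the real gene coordinates, preserving
  contig structure and spacing heterogeneity exactly.

Significance decisions use ``p_perm``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome_io import GeneRecord, GenomeStats, genes_per_window, genome_stats

__all__ = [
    "DEFAULT_WINDOW",
    "ColocPair",
    "ColocTestResult",
    "gene_distance",
    "pairwise_coloc",
    "coloc_fraction",
    "pair_network",
    "write_network",
    "focal_neighbor_prob",
    "analytic_pvalue",
    "permutation_pvalue",
    "PermutationResult",
    "run_coloc_test",
    "bh_adjust",
    "write_pairs_tsv",
    "write_results_tsv",
]

DEFAULT_WINDOW = 250_000
DEFAULT_ALPHA = 0.01
DEFAULT_B = 10_000


@dataclass(frozen=True)
class ColocPair:
    taxon_id: str
    component_a: str
    component_b: str
    gene_a: str
    gene_b: str
    contig_id: str
    distance: int
    coloc_class: str  # "colocalized" | "long_range"

    def __post_init__(self) -> None:
        if self.component_a > self.component_b:
            raise ValueError("components must be ordered a <= b")
        if self.coloc_class not in {"colocalized", "long_range"}:
            raise ValueError(f"bad coloc_class {self.coloc_class!r}")


@dataclass(frozen=True)
class ColocTestResult:
    taxon_id: str
    n_genes: int
    n_fa: int
    window: int
    m: int
    x_obs: int
    p_analytic: float
    p_perm: float
    n_permutations: int
    seed: int
    alpha: float
    significant: bool
    n_pairs_colocalized: int = 0  # secondary statistic


def gene_distance(a: GeneRecord, b: GeneRecord) -> int | None:
    """Intergenic distance in bp, or None when the genes sit on different
    contigs.  Overlapping genes are at distance 0; symmetric."""
    if a.contig_id != b.contig_id:
        return None
    up, down = (a, b) if a.start <= b.start else (b, a)
    return max(0, down.start - up.end - 1)


def pairwise_coloc(
    fa_genes: Sequence[GeneRecord],
    window: int = DEFAULT_WINDOW,
    include_paralog_pairs: bool = False,
) -> list[ColocPair]:
    """All unordered same-contig pairs of labeled genes, classified by distance.

    Pairs between two copies of the same component are excluded unless
    ``include_paralog_pairs``.  The threshold is inclusive: distance == window
    classifies as colocalized.  Output order is deterministic: (taxon, contig,
    upstream start).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    labeled = [g for g in fa_genes if g.label is not None]
    labeled.sort(key=lambda g: (g.taxon_id, g.contig_id, g.start, g.gene_id))
    pairs: list[ColocPair] = []
    for i, a in enumerate(labeled):
        for b in labeled[i + 1:]:
            if b.taxon_id != a.taxon_id or b.contig_id != a.contig_id:
                break  # sorted: once contig changes, no more partners for a
            if not include_paralog_pairs and a.label == b.label:
                continue
            d = gene_distance(a, b)
            assert d is not None
            comp_a, comp_b = sorted((a.label, b.label))
            gene_a, gene_b = (a.gene_id, b.gene_id) if a.label <= b.label else (b.gene_id, a.gene_id)
            pairs.append(
                ColocPair(taxon_id=a.taxon_id, component_a=comp_a, component_b=comp_b,
                          gene_a=gene_a, gene_b=gene_b, contig_id=a.contig_id,
                          distance=d,
                          coloc_class="colocalized" if d <= window else "long_range")
            )
    return pairs


def coloc_fraction(fa_genes: Sequence[GeneRecord], pairs: Sequence[ColocPair]) -> float:
    """Fraction of pathway genes participating in >= 1 colocalized pair."""
    labeled = [g for g in fa_genes if g.label is not None]
    if not labeled:
        raise ValueError("zero pathway genes")
    involved = set()
    for p in pairs:
        if p.coloc_class == "colocalized":
            involved.add((p.taxon_id, p.gene_a))
            involved.add((p.taxon_id, p.gene_b))
    ids = {(g.taxon_id, g.gene_id) for g in labeled}
    return len(involved & ids) / len(ids)


def pair_network(
    pairs: Iterable[ColocPair],
    class_filter: str = "colocalized",
) -> pd.DataFrame:
    """Cross-taxon co-occurrence network: one edge per unordered component
    pair, weighted by the number of distinct taxa contributing >= 1 pair of
    ``class_filter``.  Returns a (component_a, component_b, n_taxa) frame."""
    taxa_per_edge: dict[tuple[str, str], set[str]] = {}
    for p in pairs:
        if p.coloc_class != class_filter:
            continue
        taxa_per_edge.setdefault((p.component_a, p.component_b), set()).add(p.taxon_id)
    rows = [
        {"component_a": a, "component_b": b, "n_taxa": len(taxa)}
        for (a, b), taxa in sorted(taxa_per_edge.items())
    ]
    return pd.DataFrame(rows, columns=["component_a", "component_b", "n_taxa"])


def write_network(edges: pd.DataFrame, tsv_path: str | Path,
                  graphml_path: str | Path | None = None) -> None:
    """Write the co-occurrence network as TSV and, optionally, GraphML for
    Cytoscape-style rendering."""
    edges.to_csv(tsv_path, sep="\t", index=False)
    if graphml_path is not None:
        import networkx as nx

        g = nx.Graph()
        for row in edges.itertuples(index=False):
            g.add_edge(row.component_a, row.component_b, n_taxa=int(row.n_taxa))
        nx.write_graphml(g, graphml_path)


# ---------------------------------------------------------------------------
# analytic null

def focal_neighbor_prob(N: int, K: int, m: int) -> float:
    """Probability that a focal pathway gene has >= 1 of the other K-1 labels
    among its d = min(2m, N-1) neighboring gene slots, under uniform label
    placement: 1 - C(N-K, d)/C(N-1, d).  Zero when K == 1 or d == 0."""
    if N < 2:
        raise ValueError("N must be >= 2")
    if not (1 <= K <= N):
        raise ValueError("K must satisfy 1 <= K <= N")
    if m < 0:
        raise ValueError("m must be >= 0")
    d = min(2 * m, N - 1)
    if K == 1 or d == 0:
        return 0.0
    # zero-class of Hypergeometric(population N-1, successes K-1, draws d),
    # evaluated in log space by scipy for numerical stability at large N
    log_p0 = sps.hypergeom.logpmf(0, N - 1, K - 1, d)
    return float(-np.expm1(log_p0))


def analytic_pvalue(N: int, K: int, m: int, x_obs: int) -> float:
    """Upper-tail P(X >= x_obs) with X ~ Binomial(K, p_focal).

    The binomial treats the K per-gene neighbor indicators as independent;
    they are not (neighbors come in pairs), so this is the closed-form
    approximation — the permutation p-value is authoritative.
    """
    if not (0 <= x_obs <= K):
        raise ValueError("x_obs must satisfy 0 <= x_obs <= K")
    if x_obs == 0:
        return 1.0
    p_focal = focal_neighbor_prob(N, K, m)
    return float(sps.binom.sf(x_obs - 1, K, p_focal))


# ---------------------------------------------------------------------------
# permutation null

class PermutationResult(NamedTuple):
    x_obs: int
    x_null: np.ndarray  # B null draws of the statistic
    p_perm: float


class _GeneArrays(NamedTuple):
    starts: np.ndarray
    ends: np.ndarray
    contigs: np.ndarray  # integer codes
    label_idx: np.ndarray  # indices of labeled genes (sorted gene order)


def _to_arrays(genes: Sequence[GeneRecord]) -> _GeneArrays:
    ordered = sorted(genes, key=lambda g: (g.contig_id, g.start, g.end, g.gene_id))
    starts = np.array([g.start for g in ordered], dtype=np.int64)
    ends = np.array([g.end for g in ordered], dtype=np.int64)
    contig_codes: dict[str, int] = {}
    contigs = np.array(
        [contig_codes.setdefault(g.contig_id, len(contig_codes)) for g in ordered],
        dtype=np.int64,
    )
    label_idx = np.array(
        [i for i, g in enumerate(ordered) if g.label is not None], dtype=np.int64
    )
    return _GeneArrays(starts, ends, contigs, label_idx)


def _neighbor_stat(arr: _GeneArrays, idx2d: np.ndarray, window: int) -> np.ndarray:
    """For each row of label indices, count labels with >= 1 same-contig
    labeled neighbor at intergenic distance <= window.  Exact O(K^2) pairwise
    evaluation, vectorized over rows."""
    S = arr.starts[idx2d]
    E = arr.ends[idx2d]
    C = arr.contigs[idx2d]
    Si, Sj = S[:, :, None], S[:, None, :]
    # upstream gene = smaller start; distance = other.start - upstream.end - 1
    Eup = np.where(Si <= Sj, E[:, :, None], E[:, None, :])
    dist = np.maximum(Si, Sj) - Eup - 1
    np.clip(dist, 0, None, out=dist)
    close = (dist <= window) & (C[:, :, None] == C[:, None, :])
    k = idx2d.shape[1]
    close &= ~np.eye(k, dtype=bool)
    return close.any(axis=2).sum(axis=1)


def permutation_pvalue(
    all_genes: Sequence[GeneRecord],
    K: int | None = None,
    window: int = DEFAULT_WINDOW,
    B: int = DEFAULT_B,
    seed: int = 0,
) -> PermutationResult:
    """Monte Carlo null for the co-localization statistic.

    The observed statistic comes from the genes currently carrying labels;
    each of the B null draws reassigns the K labels uniformly without
    replacement over all N gene positions (coordinates fixed).  The p-value
    uses the add-one estimator p = (1 + #{X_b >= x_obs}) / (B + 1), so it is
    never exactly zero, and is bit-reproducible for a given seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    arr = _to_arrays(all_genes)
    N = len(arr.starts)
    n_labeled = len(arr.label_idx)
    if K is None:
        K = n_labeled
    if K != n_labeled:
        raise ValueError(f"K={K} but {n_labeled} genes carry labels")
    if K > N:
        raise ValueError("K > N")
    if K == 0:
        return PermutationResult(0, np.zeros(B, dtype=np.int64), 1.0)

    x_obs = int(_neighbor_stat(arr, arr.label_idx[None, :], window)[0])
    rng = np.random.default_rng(seed)
    x_null = np.empty(B, dtype=np.int64)
    # batch the B draws to bound the B x N scratch memory
    batch = max(1, min(B, int(2e7 // max(N, 1))))
    done = 0
    while done < B:
        b = min(batch, B - done)
        u = rng.random((b, N))
        idx = np.argpartition(u, K - 1, axis=1)[:, :K]
        x_null[done:done + b] = _neighbor_stat(arr, idx, window)
        done += b
    p_perm = (1 + int((x_null >= x_obs).sum())) / (B + 1)
    return PermutationResult(x_obs=x_obs, x_null=x_null, p_perm=p_perm)


def run_coloc_test(
    genes: Sequence[GeneRecord],
    window: int = DEFAULT_WINDOW,
    B: int = DEFAULT_B,
    seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    include_paralog_pairs: bool = False,
) -> ColocTestResult:
    """Full per-genome co-localization test on labeled gene records.

    Assembles genome statistics -> m -> observed statistic -> analytic and
    permutation p-values; significance is decided on ``p_perm < alpha``.
    """
    stats = genome_stats(genes)
    m = genes_per_window(stats, window)
    K = sum(1 for g in genes if g.label is not None)
    perm = permutation_pvalue(genes, K=K, window=window, B=B, seed=seed)
    if K == 0:
        p_analytic = 1.0
    else:
        p_analytic = analytic_pvalue(stats.n_genes, K, m, perm.x_obs)
    labeled = [g for g in genes if g.label is not None]
    n_pairs = sum(
        1 for p in pairwise_coloc(labeled, window, include_paralog_pairs)
        if p.coloc_class == "colocalized"
    )
    return ColocTestResult(
        taxon_id=stats.taxon_id, n_genes=stats.n_genes, n_fa=K, window=window,
        m=m, x_obs=perm.x_obs, p_analytic=p_analytic, p_perm=perm.p_perm,
        n_permutations=B, seed=seed, alpha=alpha,
        significant=perm.p_perm < alpha, n_pairs_colocalized=n_pairs,
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional cross-genome correction)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# tabular IO

def write_pairs_tsv(pairs: Sequence[ColocPair], path: str | Path) -> None:
    pd.DataFrame([p.__dict__ for p in pairs]).to_csv(path, sep="\t", index=False)


def write_results_tsv(results: Sequence[ColocTestResult], path: str | Path,
                      bh: bool = False) -> None:
    df = pd.DataFrame([r.__dict__ for r in results])
    if bh and len(df):
        df["p_bh"] = bh_adjust(df["p_perm"].to_numpy())
    df.to_csv(path, sep="\t", index=False)
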