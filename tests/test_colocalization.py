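"""Distance classification, co-occurrence networks, and the analytic and
permutation nulls for pathway-gene co-localization."""

import itertools
import math

import numpy as np
import pytest

from facoloc.colocalization import (
    analytic_pvalue,
    bh_adjust,
    coloc_fraction,
    focal_neighbor_prob,
    gene_distance,
    pair_network,
    pairwise_coloc,
    permutation_pvalue,
    run_coloc_test,
)
from facoloc.genome_io import GeneRecord


def g(gene_id, start, end, contig="ctg1", taxon="T", label=None):
    return GeneRecord(gene_id=gene_id, taxon_id=taxon, contig_id=contig,
                      start=start, end=end, label=label)


def regular_contig(n, length=1000, gap=1000, taxon="T", labels=None):
    """n equally spaced genes; gene i at [i*(length+gap)+1, ...]."""
    spacing = length + gap
    genes = []
    for i in range(n):
        start = 1 + gap + i * spacing
        lab = labels.get(i) if labels else None
        genes.append(g(f"g{i}", start, start + length - 1, label=lab))
    return genes


class TestGeneDistance:
    def test_inclusive_boundary_at_window(self):
        a, b = g("a", 1, 1000), g("b", 251_001, 252_000)
        assert gene_distance(a, b) == 250_000

    def test_one_past_boundary(self):
        a, b = g("a", 1, 1000), g("b", 251_002, 252_000)
        assert gene_distance(a, b) == 250_001

    def test_overlap_is_zero(self):
        assert gene_distance(g("a", 1, 1000), g("b", 500, 2000)) == 0

    def test_cross_contig_undefined(self):
        assert gene_distance(g("a", 1, 10), g("b", 1, 10, contig="ctg2")) is None

    def test_symmetric(self):
        a, b = g("a", 1, 1000), g("b", 5000, 6000)
        assert gene_distance(a, b) == gene_distance(b, a) == 3999


class TestPairwiseColoc:
    def test_three_close_genes_form_complete_graph(self):
        genes = [g("a", 1, 1000, label="FANCM"),
                 g("b", 5000, 6000, label="SLX1"),
                 g("c", 9000, 9500, label="FANCT")]
        pairs = pairwise_coloc(genes, window=250_000)
        assert len(pairs) == 3
        assert all(p.coloc_class == "colocalized" for p in pairs)

    def test_cross_contig_pairs_never_emitted(self):
        genes = [g("a", 1, 1000, label="FANCM"),
                 g("b", 1, 1000, contig="ctg2", label="SLX1")]
        assert pairwise_coloc(genes) == []

    def test_chained_gaps_classify_per_constructed_distance(self):
        # four genes chained at gaps 200 kb / 300 kb / 200 kb
        genes = [g("a", 1, 1000, label="C1")]
        gaps = [200_000, 300_000, 200_000]
        names = ["C2", "C3", "C4"]
        for i, gap in enumerate(gaps):
            prev = genes[-1]
            start = prev.end + gap + 1
            genes.append(g(f"g{i+1}", start, start + 999, label=names[i]))
        pairs = pairwise_coloc(genes, window=250_000)
        by_pair = {(p.component_a, p.component_b): p.coloc_class for p in pairs}
        assert by_pair[("C1", "C2")] == "colocalized"      # 200 kb
        assert by_pair[("C2", "C3")] == "long_range"        # 300 kb
        assert by_pair[("C3", "C4")] == "colocalized"      # 200 kb
        assert by_pair[("C1", "C3")] == "long_range"
        assert by_pair[("C1", "C4")] == "long_range"

    def test_same_component_copies_excluded_by_default(self):
        genes = [g("a", 1, 1000, label="FANCM"), g("b", 3000, 4000, label="FANCM")]
        assert pairwise_coloc(genes) == []
        included = pairwise_coloc(genes, include_paralog_pairs=True)
        assert len(included) == 1

    def test_components_ordered_within_pair(self):
        genes = [g("a", 1, 1000, label="SLX1"), g("b", 3000, 4000, label="FANCM")]
        (p,) = pairwise_coloc(genes)
        assert p.component_a == "FANCM" and p.component_b == "SLX1"


class TestColocFraction:
    def test_two_genes_one_pair_is_one(self):
        genes = [g("a", 1, 1000, label="A"), g("b", 3000, 4000, label="B")]
        assert coloc_fraction(genes, pairwise_coloc(genes)) == 1.0

    def test_ten_genes_one_pair_is_fifth(self):
        genes = [g("a", 1, 1000, label="A"), g("b", 3000, 4000, label="B")]
        genes += [g(f"far{i}", 1, 1000, contig=f"c{i+2}", label=f"X{i}")
                  for i in range(8)]
        assert coloc_fraction(genes, pairwise_coloc(genes)) == pytest.approx(0.2)

    def test_zero_pathway_genes_errors(self):
        with pytest.raises(ValueError):
            coloc_fraction([g("a", 1, 10)], [])


class TestPairNetwork:
    def test_weight_counts_distinct_taxa(self):
        pairs = []
        for t in ("T1", "T2", "T3"):
            genes = [g("a", 1, 1000, taxon=t, label="FANCT"),
                     g("b", 3000, 4000, taxon=t, label="REV3")]
            pairs += pairwise_coloc(genes)
        edges = pair_network(pairs, "colocalized")
        assert len(edges) == 1
        assert edges.iloc[0]["n_taxa"] == 3

    def test_empty_input_empty_edges(self):
        assert len(pair_network([], "colocalized")) == 0

    def test_planted_edges_recovered_exactly(self):
        pairs = []
        plants = {("A", "B"): ["T1", "T2"], ("B", "C"): ["T1"], ("A", "C"): ["T3"]}
        for (ca, cb), taxa in plants.items():
            for t in taxa:
                genes = [g("x", 1, 1000, taxon=t, label=ca),
                         g("y", 3000, 4000, taxon=t, label=cb)]
                pairs += pairwise_coloc(genes)
        edges = pair_network(pairs, "colocalized")
        got = {(r.component_a, r.component_b): r.n_taxa
               for r in edges.itertuples(index=False)}
        assert got == {("A", "B"): 2, ("B", "C"): 1, ("A", "C"): 1}


class TestFocalNeighborProb:
    def test_single_label_has_no_neighbor(self):
        assert focal_neighbor_prob(100, 1, 10) == 0.0

    def test_neighborhood_covering_genome_is_certain(self):
        assert focal_neighbor_prob(10, 2, 100) == 1.0

    def test_matches_exhaustive_enumeration(self):
        # N=11, K=3, m=2 -> d=4: enumerate every placement of the other 2
        # labels among 10 positions against a fixed 4-slot neighborhood
        N, K, m = 11, 3, 2
        d = 2 * m
        neighborhood = set(range(d))
        total = hit = 0
        for placement in itertools.combinations(range(N - 1), K - 1):
            total += 1
            if set(placement) & neighborhood:
                hit += 1
        exact = hit / total
        assert exact == pytest.approx(1 - math.comb(8, 4) / math.comb(10, 4))
        assert focal_neighbor_prob(N, K, m) == pytest.approx(exact, abs=1e-12)

    def test_monotone_in_k_and_m(self):
        ps_k = [focal_neighbor_prob(200, k, 5) for k in range(2, 30)]
        assert all(b >= a for a, b in zip(ps_k, ps_k[1:]))
        ps_m = [focal_neighbor_prob(200, 5, m) for m in range(0, 50)]
        assert all(b >= a for a, b in zip(ps_m, ps_m[1:]))

    def test_bound_violations_rejected(self):
        with pytest.raises(ValueError):
            focal_neighbor_prob(1, 1, 1)
        with pytest.raises(ValueError):
            focal_neighbor_prob(10, 0, 1)
        with pytest.raises(ValueError):
            focal_neighbor_prob(10, 11, 1)
        with pytest.raises(ValueError):
            focal_neighbor_prob(10, 2, -1)


class TestAnalyticPvalue:
    def test_zero_observed_gives_one(self):
        assert analytic_pvalue(100, 5, 10, 0) == 1.0

    def test_two_gene_case_squares_focal_probability(self):
        # documented independence approximation: exact p is p_focal, the
        # binomial form gives p_focal^2
        p_focal = focal_neighbor_prob(50, 2, 3)
        assert analytic_pvalue(50, 2, 3, 2) == pytest.approx(p_focal ** 2)

    def test_non_increasing_in_x_obs(self):
        ps = [analytic_pvalue(500, 10, 5, x) for x in range(11)]
        assert all(b <= a + 1e-15 for a, b in zip(ps, ps[1:]))

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            analytic_pvalue(100, 5, 10, 6)


class TestPermutationPvalue:
    def test_all_genes_labeled_is_invariant(self):
        genes = regular_contig(6, labels={i: f"C{i}" for i in range(6)})
        res = permutation_pvalue(genes, window=10_000, B=200, seed=1)
        assert res.p_perm == 1.0
        assert (res.x_null == res.x_obs).all()

    def test_single_label_never_significant(self):
        genes = regular_contig(8, labels={0: "A"})
        res = permutation_pvalue(genes, window=2500, B=100, seed=1)
        assert res.x_obs == 0 and res.p_perm == 1.0

    def test_matches_exhaustive_enumeration_on_small_contig(self):
        # N=8, K=2, W=2500: only adjacent genes are within the window
        genes = regular_contig(8, labels={0: "A", 1: "B"})
        spacing_pairs = 0
        coords = [(x.start, x.end) for x in regular_contig(8)]
        for i, j in itertools.combinations(range(8), 2):
            dist = max(0, coords[j][0] - coords[i][1] - 1)
            if dist <= 2500:
                spacing_pairs += 1
        exact_p = spacing_pairs / math.comb(8, 2)
        res = permutation_pvalue(genes, window=2500, B=20_000, seed=42)
        assert res.x_obs == 2
        se = math.sqrt(exact_p * (1 - exact_p) / 20_000)
        assert abs(res.p_perm - exact_p) <= 3 * se

    def test_seed_reproducibility_bit_identical(self):
        genes = regular_contig(50, labels={3: "A", 17: "B", 40: "C"})
        r1 = permutation_pvalue(genes, window=10_000, B=500, seed=7)
        r2 = permutation_pvalue(genes, window=10_000, B=500, seed=7)
        assert r1.p_perm == r2.p_perm
        assert (r1.x_null == r2.x_null).all()

    def test_k_larger_than_n_rejected(self):
        genes = regular_contig(4, labels={i: f"C{i}" for i in range(4)})
        with pytest.raises(ValueError):
            permutation_pvalue(genes, K=10, window=1000, B=10, seed=0)

    def test_pvalue_never_below_floor(self):
        genes = regular_contig(30, labels={0: "A", 1: "B", 2: "C"})
        res = permutation_pvalue(genes, window=2500, B=50, seed=0)
        assert res.p_perm >= 1 / 51


class TestRunColocTest:
    def test_single_label_yields_unit_pvalues(self):
        genes = regular_contig(20, labels={5: "FANCM"})
        res = run_coloc_test(genes, window=2500, B=200, seed=1)
        assert res.p_analytic == 1.0 and res.p_perm == 1.0
        assert not res.significant

    def test_result_echoes_inputs(self):
        genes = regular_contig(20, labels={0: "A", 1: "B"})
        res = run_coloc_test(genes, window=2500, B=300, seed=9, alpha=0.05)
        assert (res.window, res.n_permutations, res.seed, res.alpha) == (2500, 300, 9, 0.05)
        assert res.n_genes == 20 and res.n_fa == 2
        assert 0 <= res.x_obs <= res.n_fa
        assert res.significant == (res.p_perm < 0.05)


def test_bh_adjustment_matches_definition():
    p = [0.001, 0.01, 0.02, 0.9]
    adj = bh_adjust(p)
    assert adj[0] == pytest.approx(0.004)
    assert np.all(adj >= p) and np.all(adj <= 1)
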