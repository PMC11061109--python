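# Methods

## The problem

Genes acting in one pathway are often physically clustered in fungal
genomes, and clustering is circumstantial evidence of co-regulation and of
a functionally intact pathway. Given a genome annotation with N gene loci,
K of which encode pathway components, we want (i) a classification of
pathway-gene pairs by genomic distance, (ii) a per-genome significance test
of whether the observed proximity could arise if the pathway labels fell on
gene loci at random, (iii) a phyletic presence/copy-number profile of the
pathway across taxa built from homology evidence, and (iv) a
condition-specific expression profile of the pathway genes.

## Distance convention

All coordinates are GFF3-style: 1-based, inclusive. The distance between
two genes on the same contig is the **intergenic gap** — the number of
bases strictly between them, `max(0, downstream.start − upstream.end − 1)`
— so overlapping or book-ended genes are at distance 0. Genes on different
contigs have no defined distance and never pair. Strand is ignored. The
data formats leave "gene distance" ambiguous (gap vs start-to-start); the
gap was chosen because it is well defined for genes of unequal length and
degrades gracefully on overlap, and the choice is isolated in
`gene_distance` / `genome_stats`.

Pairs at distance ≤ W classify as *colocalized*, beyond W as *long_range*;
the threshold is inclusive at exactly W. W defaults to 250 kb, the scale at
which biologically meaningful genomic contacts (enhancer–promoter range)
occur. Pairs between two copies of the same component are excluded by
default (`include_paralog_pairs` restores them): co-occurrence of distinct
components is what speaks to pathway integrity, tandem duplicates do not.

## The co-localization test

**Statistic.** X = number of pathway genes with at least one pathway
neighbor within W on the same contig. This matches the "fraction of
pathway genes colocalized" framing used when comparing taxa; the number of
colocalized pairs is computed alongside as a secondary descriptor. Note X
can never equal 1: proximity is symmetric, so neighbors come in pairs.

**Analytic approximation.** From the genome's mean gene length L̄ and mean
intergenic gap ḡ, the mean spacing is s = L̄ + ḡ and a window of W bp
holds m = ⌊W/s⌋ gene slots per side of a focal gene, d = min(2m, N−1) in
total. If the other K−1 labels fall uniformly on the other N−1 loci, the
number landing in the d neighboring slots is hypergeometric, and the
no-neighbor probability is C(N−K, d)/C(N−1, d) (evaluated in log space).
With p_focal its complement, the analytic p-value is the upper tail of
Binomial(K, p_focal) at the observed X. Two approximations are involved:
contig ends are ignored, and the K neighbor indicators are treated as
independent although they are positively dependent in pairs. In the
two-gene case the binomial form gives p_focal² where the exact answer is
p_focal. The closed form is therefore reported as a descriptive
approximation — accurate in the sparse regime (K·m ≪ N, where both
p-values are small) and anti-conservative to conservative elsewhere.

**Permutation null (authoritative).** The K labels are reassigned
uniformly without replacement over the real N gene coordinates B times
(default B = 10 000); contig structure, gene lengths and spacing
heterogeneity are preserved exactly, which also handles contig-end effects
the closed form ignores. The p-value uses the add-one estimator
p = (1 + #{X_b ≥ X_obs})/(B + 1), which is never 0, has floor 1/(B+1),
and is super-uniform under the null, so the test is valid (slightly
conservative). Significance is decided on p_perm < α with α = 0.01.
A single integer seed drives all draws; the permutation is vectorized
(batched argpartition sampling + exact O(K²) pairwise distance evaluation),
so B = 2000 on a 5000-gene genome runs in ~0.2 s. No cross-genome
multiple-testing correction is applied by default (per-genome decisions at
α = 0.01); a Benjamini–Hochberg column is available behind a flag, computed
by statsmodels.

**Validation design.** Test problem sizes were chosen so each check runs in
seconds to ~2 minutes on one CPU while retaining resolution:

* *Exact oracle*: N = 8 equally spaced genes, K = 2 — all C(8,2) = 28 label
  placements enumerated by independent brute force; the permutation
  p-value (B = 20 000) must sit within 3 Monte-Carlo SE of the exact
  p-value, and the focal-neighbor probability must match the enumerated
  pair probability up to the documented contig-end bias (≤ 0.05 here;
  exact equality in the window-covers-contig limit).
* *Type-I calibration*: 500 genomes of N = 2000 genes (default fungal-like
  geometry), K = 20 uniform labels, W = 250 kb, B = 2000; the rejection
  rate at α = 0.01 must fall in the exact binomial 99% acceptance region.
* *Power*: 200 genomes of N = 5000 genes — a typical fungal gene count —
  with all K = 5 labels planted as one cluster spanning ≤ 100 kb; detection
  (p_perm < 0.01) is required in ≥ 95% of replicates.
* *Analytic agreement*: constant-spacing genomes (so m is exact) on a
  sparse-regime grid (N, K, m) ∈ {(1000,2,2), (2000,3,3), (2000,4,2),
  (4000,3,10)}, B = 10 000; |p_analytic − p_perm| ≤ max(0.02, 3 SE) at
  X ∈ {1, 2}. Outside this regime the binomial independence approximation
  visibly fails, which is exactly why the permutation p-value is the
  decision rule.

## Phyletic profiling

Hits are filtered at e ≤ 1e-5 (inclusive). Each target protein is assigned
to the component of its maximum-bitscore hit; ties break by lower e-value,
then lexicographically smaller component symbol — determinism is required
for reproducible matrices, and the specific order is immaterial. The
interactive sequence-space clustering sometimes used to weed out
non-specific hits has no crisp decision rule to reimplement; its function
is recovered by the **domain gate**: with `require=True` (default in the
CLI), an assignment is dropped unless the protein carries one of the
assigned component's diagnostic Pfam accessions. Components whose registry
entry lists no Pfam accession (FANCB, FANCG, REV3) are exempt. Because the
gate's historical use is uncertain, it is a switch rather than a hard rule.

Copy numbers count distinct protein IDs; splice-isoform deduplication is
the caller's responsibility. The registry transcribes the 40-component FA
pathway table (symbol, aliases, Pfam/InterPro accessions, subcomplex) and
is user-replaceable, so the machinery generalizes to any pathway.

**Fusions.** A protein is called a fusion when it carries diagnostic
domains of ≥ 2 distinct components whose per-component interval spans do
not overlap and whose midpoints are ≥ 100 aa apart (`min_separation`,
chosen as roughly a domain's width; the motivating natural example — an
N-terminal FANCM domain with a C-terminal XPF endonuclease on one
1800–1900 aa protein — separates partners by >1000 aa, so the call is
insensitive to this default). An accession shared by several components
(e.g. the RAD51-family domain) produces identical spans for all of them
and can never fuse those components with each other. Calls report partners
in N→C order.

**Architecture reports** list reference accessions missing from a protein,
extra accessions, and the protein/reference length ratio — the signature
of truncated homologs (e.g. a helicase reduced to a solo DEAD/DEAH-box
domain at a third of the reference length).

## Expression classification

TPM_i = (c_i/ℓ_i) / Σ_j (c_j/ℓ_j) × 10⁶; the vector sums to 10⁶ by
construction and is invariant to scaling all counts. Classification of DE
results: missing padj (gene absent from the analysis) → `not_detected`;
padj > 0.05 → `not_significant`; otherwise the sign of log2FC decides up
vs down, with log2FC = 0 assigned `not_significant` (zero is neither up-
nor downregulation). The DE model fit itself (size factors, dispersion,
Wald tests) is upstream and out of scope; this module's contribution is
the classification rule and the profile matrix. When several copies of one
component land in one condition, the displayed cell takes the
highest-precedence status (up > down > not_significant > not_detected) —
a display convention, since a grid has one cell per component — and the
copy count is kept in a parallel multiplicity grid so the collapse is
lossless.

## Synthetic data

The generator emulates compact fungal genome geometry: log-normal gene
lengths (median 1.5 kb, σ = 0.6 → mean ≈ 1.8 kb) and exponential
intergenic gaps (mean 1 kb), giving a mean spacing of ≈ 2.8 kb so that a
250 kb window spans on the order of 100 genes — the regime the analytic
null is meant for. Genes are laid sequentially per contig; labels are
planted uniformly (null) or as a run of consecutive genes within a span
bound (alternative), with the uniform remainder kept at least the span
bound away from the cluster so the cluster is the only planted signal.
Hit tables give true homologs e-values of 10^−U(10,100) with dominant
bitscores (U(250,500)) plus a weaker cross-component hit, and decoys
e-values of 10^−U(0,4.5) — entirely above the 1e-5 cutoff, so filter
recovery is exact by construction. DE tables draw effect sizes and padj
values strictly inside their class regions, so classification recovery is
likewise exact. One global seed fans out to per-generator sub-streams via
fixed spawn keys; adding a generator never perturbs existing draws.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: transposon-rich or repeat-driven genome
reshuffling, assembly fragmentation correlated with gene density, gene
length/spacing autocorrelation, orthology ambiguity from deep paralogy
(decoys are unambiguous by construction), and DE effect-size distributions
of real transcriptomes. The statistical calibration of the permutation
test transfers to real genomes because it conditions only on the observed
coordinates; the exact-recovery results for profiling and expression are
guarantees about the code path, not about noisy biological inputs.

## Numerical and degenerate-input choices

Hypergeometric zero-class probabilities are computed via scipy's log-pmf
and `expm1`, stable for N in the 10⁴–10⁵ range. `genes_per_window` floors
and clamps to [0, N−1]. K = 1 (or d = 0) yields p_focal = 0 and p-values
of 1; X_obs = 0 yields p = 1. A genome whose contigs each hold a single
gene has an undefined mean gap, defined as 0 with a warning. Malformed
GFF3 rows (end < start) are rejected with a logged warning rather than
aborting a whole genome. Records are sorted (contig, start) everywhere, so
results are independent of input order.

## Known limitations

The analytic p-value should not be used for decisions outside the sparse
regime; it is retained because it makes the average-geometry construction
inspectable. The test statistic ignores how *many* neighbors a gene has
and the *tightness* of clusters below W; a span-based scan statistic would
have more power against very tight clusters but no longer matches the
fraction-colocalized framing. Fusion detection depends entirely on the
supplied domain annotations; split or missed domains produce missed or
spurious calls.
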