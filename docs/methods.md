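# Methods

## The measurement model

Polysome profiling separates a cytoplasmic extract on a sucrose gradient;
mRNAs sediment with the ribosomes bound to them. The pipeline's primary
statistic, the translation index (TI), is the ratio of a gene's mRNA in
the heavy fractions (tetrasome and heavier) to its mRNA in the light
fractions (40S, 60S, 80S). Di- and trisome fractions belong to neither
pool and are excluded: the heavy pool is "four or more ribosomes", the
light pool subunits plus monosome. TI is a within-gene ratio of two
sequencing libraries, so fraction samples are normalized per column only
(CPM); any between-sample normalization (TMM, quantile) would silently
rescale the ratio and is deliberately absent. Total-RNA samples are
normalized to TPM with ORF lengths (the annotation model carries no UTRs,
and all length analyses downstream are ORF-based), and define the
expressed-gene universe as mean TPM strictly greater than 1 across the
total samples of the two compared groups — symmetric between the strains
being compared, since the assay gives no reason to privilege either.

## Translation-index computation

Per replicate, TI_g = (CPM_heavy + c)/(CPM_light + c) with pseudocount
c = 0.5 CPM by default. Zero-handling is otherwise unspecified by the
assay; 0.5 CPM keeps ratios finite without materially moving genes that
pass the expression filter. Genes with zero counts in both fractions of a
replicate are flagged, never dropped. Replicates combine as the mean of
log2 TI (the symmetric choice for a ratio statistic on the log scale); a
pooled-CPM mode is available for comparison. Differential translation
between a test and a reference group thresholds Δ = log2 TI_test −
log2 TI_ref at strictly more than 0.5 in either direction. The threshold
is an effect-size cut, not a significance test — with n = 2 biological
replicates no per-gene test is attempted, and none is provided.
Inversely regulated genes are those over-translated in one comparison and
under-translated in the other, in either orientation, on a shared
universe.

## ORF-length statistics

Two-sample length comparisons use the Mann–Whitney U with midranks for
ties. While C(n+m, n) ≤ 2×10⁵ the p-value is exact: all labelings of the
pooled sample are enumerated and the two-sided p is the fraction whose U
is at least as far from nm/2 as observed (this remains exact under ties,
where the classical null distribution does not apply). Larger samples use
the tie-corrected normal approximation with continuity correction
(scipy). Top-N summaries rank called genes by |Δlog2 TI| with gene id as
a deterministic tiebreak; if a side has fewer than N calls the summary
shrinks with a warning. The ribosome-density proxy used by the TI–length
correlation is TI divided by ORF length — a per-nucleotide loading proxy
chosen because density is a loading-per-length notion; the correlation is
also available on raw TI.

## Kozak context score

Start contexts are the 6 nt upstream and 3 nt downstream of the annotated
AUG on the coding strand (positions −6..−1 and +4..+6; the A of AUG is
+1). The matrix holds raw nucleotide incidences per position — no
pseudocounts, no log-odds, no background — and a context scores the sum
of its 9 per-position frequencies. A sum is the natural additive form for
an incidence matrix: it ranges over [0, 9], and the per-position argmax is
provably the global maximum (verified against exhaustive enumeration of
all 4⁹ contexts in the tests). The invariant AUG is excluded from matrix
and score. Ties in the consensus are broken alphabetically and flagged.

## Enrichment

Over-representation is the one-sided hypergeometric tail P(X ≥ k),
delegated to scipy's stable implementation and checked exhaustively
against direct combinatorial summation on the complete lattice up to
N = 12. The universe is the expression-filtered gene set of the
comparison, not the genome — the standard guard against detection bias.
Bonferroni multiplies by the number of categories actually tested
(≥ 3 universe members by default); testing categories that cannot reach
significance would make the correction vacuous. Significance is strict
(p_adj < α, default α = 0.001). GO-graph propagation and term redundancy
reduction are out of scope; the category map is taken as given.

## qPCR and proteomics

RQ follows the comparative-Ct formula with amplification efficiency fixed
at 2, exactly as the assay defines it; technical replicates are averaged
on the Ct scale before exponentiation (standard ΔCt practice). Biological
replicates combine as the mean of RQs. The qPCR translation index is the
gene's heavy/light quantity ratio divided by the control transcript's,
i.e. RQ with the light fraction as reference. Peptide intensities
aggregate by plain summation; percent N-terminal acetylation is
100 × acetylated/(acetylated + non-acetylated) within a sample, and
paralog ratios are within-sample sums — both therefore invariant to any
global intensity scaling, so no normalization is applied. A missing
acetyl-state stratum is treated as 0 with a warning.

## Synthetic data: what it emulates and what it does not

The generator draws ORF lengths LogNormal(7.2, 0.6) in log-nt (median
≈ 1,339 nt, rounded to codon multiples, minimum 75 nt — a realistic yeast
ORF spread centred on a mid-size gene) and abundances LogNormal(4.0, 1.2)
on the log-TPM scale. The latent TI is

    log2 ti(g, s, c) = ti_base + β_length[s]·z_g + 1{treated}·δ_drug[s]·z_g
                       + N(0, σ_TI)

with z the standardized log length, defaults β = {WT: 0, ul30bb: +0.4},
δ = {WT: 0, ul30bb: +0.2}, σ_TI = 0.25 log2 units (the assay reports no
replicate noise magnitude at n = 2; 0.25 is a convention giving a
realistic few-percent null call rate). Each gene's mRNA allocates to the
heavy compartment with probability ti/(1+ti) — the minimal two-compartment
model consistent with TI's definition as a heavy/light ratio — and counts
are Negative-Binomial with shared dispersion 0.05 (Poisson at 0) at
5×10⁶ expected counts per library, two replicates per (strain, condition,
fraction). A "cell periphery" label is assigned with probability
increasing in length (expected share 15%), plus two length-independent
background categories, so a positive length effect reproduces the
periphery-enrichment pattern and the Bonferroni factor is non-trivial.

Not emulated: positional read biases, UMI structure, isoform ambiguity,
UTRs, between-replicate library-preparation batch effects, and any direct
coupling of abundance to translation. Passing recovery tests therefore
show the pipeline's statistics are faithful to this generative structure,
not that real libraries satisfy it.

### A note on null calibration

Because every sample is renormalized to a fixed library size, the log2 TI
difference between two strains carries a small offset shared by all genes
(the compositional constant Σaᵢ(1−pᵢ)/Σaᵢpᵢ fluctuates between libraries
when abundances are heavy-tailed). Under the null this offset is zero in
expectation but varies by seed with a spread larger than binomial error
at n = 2000. The calibration tests therefore check symmetry of over/under
calls per seed *after removing the shared offset* (median-centering Δ),
and that the raw over-minus-under difference is zero-mean across seeds.
The same offset exists in real fraction libraries; interpreting absolute
call counts should keep it in mind.

## Numerical and interface choices

GFF3 coordinates are treated as 1-based inclusive, internal coordinates
0-based half-open; minus-strand contexts are reverse-complemented before
validation. Gene identifiers match exactly, case-preserved. Numeric
output is written with 6 significant digits, counts as integers, so
writer → reader round-trips are exact. All randomness flows through
`numpy.random.default_rng(seed)`; the same seed reproduces every table
byte for byte. Problem sizes in the tests and the acceptance script
(2,000 genes, 6–20 seeds, 2 replicates) were chosen as the smallest sizes
at which the length effect, the null calibration, and the enrichment
pattern are statistically decisive.

## Known limitations

The expression filter, pseudocount, and replicate-combination rules are
conventions where the assay description is silent; all are configurable
in `AnalysisConfig`. The exact Mann–Whitney enumerator is O(C(n+m, n))
and intended for the small called sets where exactness matters. The
enrichment stage performs no GO-graph reasoning. Counts are consumed as
given: read alignment, counting, and MS peak integration are upstream of
this package by design.
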