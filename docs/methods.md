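# Methods

## The clonal quantification model

Bulk bisulfite sequencing reports, per CpG site, how many reads were
methylated — an average over a heterogeneous population of cells.  The
traditional summaries of a region are the **mean** level
`(1/n) Σ C_i/(C_i+T_i)` (average of per-site ratios over the region's `n`
CpGs) and the **weighted** level `Σ C_i / Σ (C_i+T_i)` (total methylated
calls over total calls).  Both treat CpGs as exchangeable across cells and
therefore cannot distinguish a region where 20% of cells are fully
methylated from one where every cell carries a single methylated CpG —
two situations with very different regulatory consequences, since one
methylated CpG suffices to recruit methyl-binding repressors.

The clonal quantification implemented here treats each sequenced fragment
as a proxy for one cell.  A read with at least `min_mcpg` methylated CpGs
(default 1) counts as a *methylated read*; the region's clonal methylation
level is

    chalm = n_m / (n_m + n_u)

the fraction of reads carrying methylation.  In the two scenarios above
this yields 0.2 and 1.0 while both traditional summaries report 0.2.
A read is "mapped to" a region iff it contributes at least one non-NA CpG
call inside it; coordinate overlap without an informative call carries no
evidence and such reads are excluded from both counts.  Undefined levels
(no qualifying reads, zero depth) are NaN, never 0, because 0 is a
meaningful methylation level.

Per-CpG outputs (the inputs to the mean/weighted formulas, and the
transformed ratios below) apply the standard coverage filter of ≥ 4 reads
per CpG; the read-level count itself is not depth-filtered, mirroring the
per-CpG phrasing of the conventional pipeline.

For *de novo* differential analysis with external segmentation tools, the
per-CpG clonal transform propagates methylation along reads: any read with
≥ 1 mCpG has all its informative calls set to M (the cell is methylated,
so each of its CpGs is methylated at the cell level), NA calls and the
coverage pattern are untouched, and the transformed pileup gives a clonal
level per CpG site in a Metilene-ready table.  Under uniform coverage
every transformed per-CpG ratio equals the region-level clonal value — a
property the tests assert by brute force.

## Input model and conventions

Coordinates are 0-based half-open throughout (BED convention); GTF records
are converted on read, with minus-strand TSS = transcript end − 1.
Promoter CpG islands are CGIs sharing ≥ 1 base with a 2-kb window centered
on any transcript TSS; window touching without overlap does not count
(standard half-open interval algebra — the boundary case is asserted in
tests).  Transcript-level TSSs are the default; every transcript
contributes a window and duplicate CGI hits are collapsed.

Reads come from SAM/BAM with Bismark-style `XM` call strings (via pysam;
G-strand calls are collapsed onto the C-strand CpG coordinate) or from a
canonical TSV dialect (`read_id chrom start end strand pos:state,...`)
that keeps every test self-contained.  Mate pairs sharing a read id are
merged into one fragment; where mates overlap and disagree the call
becomes NA rather than picking a winner.  Duplicate-read marking is the
caller's responsibility.

## Differential clonal methylation

For region *i* with methylated/unmethylated read counts `(n_mi, n_ui)`,
the methylated-read count is binomial, `n_mi ~ B(n_mi + n_ui, p_i)`, with
a Beta(α, β) prior on `p_i` shared across regions within a condition.
The prior is fitted by an empirical-Bayes method of moments: the
depth-weighted across-region variance of observed ratios is decomposed
into binomial sampling noise plus prior variance, solving for the
intraclass correlation ρ = 1/(α+β+1); if the observed variance does not
exceed the binomial floor (no detectable overdispersion) the flat
Beta(1, 1) prior is used.  Priors are fitted per condition, respecting
potentially different methylation landscapes; at least 10 regions with
nonzero counts are required, otherwise the caller must supply a prior.

The test statistic is fully Bayesian and self-contained: each condition's
posterior is the conjugate Beta(α + n_m, β + n_u); the distribution of
d = p₂ − p₁ is obtained by discretizing both posteriors on a uniform grid
(512 points; doubling the grid changes p by < 10⁻³, asserted in tests) and
convolving.  The reported p-value is the two-sided posterior tail
2·min(P(d ≤ 0), P(d ≥ 0)), with the lattice point at d = 0 split evenly so
identical posteriors give exactly p = 1, clipped below at 1/512² so
Benjamini–Hochberg adjustment stays well defined.  This is a declared
substitute for the credible-methylation-difference machinery of dedicated
beta-binomial DMR callers, not a bit-identical reimplementation; it is
validated against a 10⁶-draw Monte-Carlo posterior-sampling oracle
(agreement within ±0.01) and against a null calibration study (shared
latent ratio per region, depth 30: empirical P(p < 0.05) ≈ 0.02–0.08).
Significance requires both |Δ| ≥ 0.1 (posterior-mean difference) and
BH q < 0.05.

## Read extension by low-rank imputation

Reads (~100 bp) are short relative to promoter CGIs, so the reads × CpGs
matrix of a region is mostly missing.  Eligible regions (strictly longer
than 500 bp, strictly more than 300 mapped reads) are completed by a
rank-k SVD approximation estimated by EM: missing cells are initialized
with column means and repeatedly overwritten by the rank-k reconstruction
until the imputed cells' relative change falls below 10⁻⁴ (max 100
iterations).  Observed cells are never altered (bit-identical before and
after, asserted); all-NA columns are dropped since nothing constrains
them; the completed values are clipped to [0, 1]; the procedure is
deterministic.  The rank defaults to 4 and is configurable — clonal
two-pattern regions are rank 1, and the default leaves headroom for more
epialleles.  The EM objective (Frobenius error of the reconstruction on
observed cells) is non-increasing, which the tests verify directly.

Extension then augments each read with binarized imputed calls (≥ 0.5 →
M; the threshold is symmetric) at region CpGs within `target_length/2`
(default 300 bp total, where clonal quantification performance plateaus)
of the read midpoint — midpoint anchoring keeps extension symmetric.
Original calls are never overwritten.  All region CpGs are imputed once;
each read uses its windowed subset.

## Correlation comparison

Because most promoter CGIs are unmethylated, correlation analyses first
rebalance: regions are binned into 200 equal-width bins over [0, 1] by
traditional methylation and up to 60 are drawn per bin without
replacement (seeded).

Two Spearman correlations computed on equal-sized paired samples are
compared by permutation: the (x, y) pairs of both samples are pooled
(pairs travel together — splitting tuples would destroy the correlations
under test), the pool is split uniformly at random into two halves B =
10,000 times, and the p-value is the plain exceedance fraction
`(1/B) Σ I(r_d^(b) ≥ r_d)` with r_d = r₂ − r₁.  There is deliberately no
add-one smoothing, so p may be exactly 0; the granularity is 1/B.  The
permutation loop is vectorized (row-wise rank correlation over a B × n
index matrix) and seeded.

## Read-image encoding and the convolutional predictor

Regions with more than 50 mapped reads are encoded as 200 × 10 × 2
arrays.  Rows are pseudo-reads sorted by per-read methylation fraction
f_m = N_m/(N_m + N_u): with exactly 200 reads the reads themselves; with
fewer, a seeded bootstrap up to 200; with more, `200·F` randomly chosen
reads (F the largest integer with 200·F < N_r) sorted by f_m and averaged
in consecutive blocks of F.  Columns compress the region's CpGs to 10:
with ≥ 10 CpGs, contiguous near-equal bins are averaged (NA excluded);
with fewer, calls are replicated into pseudo-CpGs; columns left empty
inherit the nearest filled column.  Channel 0 holds methylation, channel
1 the signed read-midpoint distance to the TSS divided by 1000 bp,
replicated across the row.

The regression network mirrors the 200 × 10 × 2 geometry: three stacked
convolutions with kernels (5,1), (4,1), (3,1) and stride (1,1) — height-
only kernels that read vertical clonal structure across f_m-sorted rows —
each followed by ReLU, then dropout (p = 0.2) and a single linear output.
No pooling, since the column dimension is small.  Training minimizes MSE
with Adam (lr 10⁻³) in batches of 32 on a seeded 50/50 train/test split,
with 20% of the training half held out for early stopping (patience 5,
max 50 epochs) and targets standardized on the training half.  The
network, its backpropagation and the optimizer are implemented directly
in numpy (the architecture is small enough that no deep-learning
framework is needed), which keeps runs exactly reproducible for a fixed
seed; gradients are verified against finite differences in the tests.

The clonal-disruption control, `shuffle_mcpgs`, pools all covered
read-position slots, re-places the observed total number of mCpGs
uniformly at random (at most one per slot) and sets every other slot to
U.  The total mCpG count is conserved exactly (asserted on every call)
and per-read coverage patterns are unchanged, so region-level weighted
methylation is preserved while read-level clonal structure is destroyed.
On the 10-read, 5-CpG toy with 2 fully methylated reads, the expected
number of methylated reads after shuffling has the closed form
`10·(1 − C(45,10)/C(50,10)) ≈ 6.90` (a read escapes all 10 mCpGs iff they
all land in the other 45 slots), which the tests check against 10,000
shuffles.

## The synthetic-read generator

Clones are per-CpG Bernoulli probability vectors with mixture weights, so
both idealized scenarios (deterministic fully-methylated vs fully-
unmethylated programs; one dispersed mCpG per cell) and noisy mixtures
are expressible.  A read draws its clone by weight, its start uniformly
over the region, and each covered CpG independently by the clone's
probability.  Read counts are Poisson with mean `depth · region_length /
read_length`, making `depth` the expected per-CpG coverage.  Ground truth
(clone labels, methylated-clone fraction, per-CpG marginals) is returned
with the reads; for full-span reads the expected clonal level has the
closed form `Σ_c w_c (1 − Π_j (1 − p_cj))`, used as an exact recovery
oracle.

The *clustered-epiallele cohort* used in the expression-prediction
experiment draws, per region, a repressed-cell fraction θ ~ U(0.05, 0.5)
(a fully methylated clone) and a background clone carrying dispersed
mCpGs at a per-CpG rate set so the region's expected mean methylation
lands near 0.55 (jittered U(0.5, 0.6)).  Regions therefore look almost
identical to mean-level quantification while differing strongly in clonal
structure, and expression is `y = 1 − θ + N(0, 0.1)`.  This isolates
exactly the information the clonal methods claim to use: a predictor
restricted to aggregate methylation content (as after the mCpG shuffle)
has essentially nothing to learn from, while the read-resolved encoding
retains θ.  Defaults: 500 regions, 10 CpGs spaced 20 bp, full-span reads,
mean 80 reads per region.

What the generator does *not* emulate: bisulfite-conversion failure and
sequencing error (no flat flip-rate is applied by default), mappability
and GC biases, fragment-length distributions, correlated neighboring-CpG
states within a clone beyond the clone program itself, and strand
asymmetries.  Passing tests therefore demonstrate correctness of the
algorithms under the stated generative model, not performance on real
libraries.

## Problem sizes and numerical choices

Simulation-based tests use sizes chosen to keep the whole suite fast while
leaving clear statistical margins: 1000 regions for the differential null
calibration (depth 30) and the dominance invariant; 500 regions at depth
50 for differential power; 500 regions for the deep-learning experiment;
10,000 permutations where single p-values are asserted and 500 where 200
replicate p-values feed a uniformity test; 10,000 shuffles for the
combinatorial expectation.  Ties in sorting are broken stably; the f_m
sort of image rows uses a stable argsort so equal-fraction rows keep
their draw order.  All randomness flows through seeded
`numpy.random.Generator` instances.

## Known limitations

- The posterior-difference p-value is a Bayesian tail probability; its
  frequentist calibration is demonstrated empirically under the
  beta-binomial null, not guaranteed analytically.
- Rank selection for imputation is manual; no cross-validation is
  provided.
- The permutation p-value has granularity 1/B and can be exactly 0.
- `parse_reads_sam` requires Bismark-style `XM` tags; aligners emitting
  only MD/NM cannot be consumed without a prior call-annotation step.
- The CNN is deliberately small and CPU-bound; it is a study instrument
  for the clonal-information experiment, not a tuned production
  predictor.
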