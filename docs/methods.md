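# Methods

This note documents the models and procedures implemented in `triadscan`,
the parameter defaults and why they were chosen, the numerical edge-case
conventions, and what the synthetic generator does and does not emulate.

## Triad bias classification

Bread wheat is an allohexaploid (AABBDD); a *triad* is a 1:1:1 set of
homoeologous genes on the A, B and D subgenomes. Per condition
(genotype × stage), replicate TPM values are aggregated (arithmetic mean
by default; median available via `agg="median"`) and each homoeolog's
*relative expression* is its share of the triad total. Shares are
undefined when the triad total is zero in that condition.

Categories use fixed thresholds on the share scale:

* `X_dominant` — `rel_X > 0.60` and both other shares `<= 0.20`;
* `X_suppressed` — `rel_X < 0.20` and both other shares `< 0.80`;
* `balanced` — everything else.

Conventions worth making explicit:

* **Boundaries are literal.** `(0.20, 0.40, 0.40)` is balanced (0.20 is
  not `< 0.20`); `(0.10, 0.10, 0.80)` is `D_dominant`, and without the
  dominance rule it would be balanced, because 0.80 is not `< 0.80`.
* **Precedence.** The dominant and suppressed rule families overlap on a
  sliver of the simplex (e.g. `(0.15, 0.65, 0.20)` satisfies both
  `B_dominant` and `A_suppressed`). Dominant rules win — dominance is the
  stronger, more specific signal — and such points are flagged in the
  `ambiguous` output column. After dominant precedence at most one
  suppressed rule can fire (two suppressed shares below 0.20 force the
  third above 0.60 with the others `<= 0.20`, i.e. a dominant point).
  The whole simplex is therefore partitioned exactly once; the test suite
  verifies this by dense grid enumeration against an independently coded
  rule table.
* **Expression filters.** Genes: CPM >= 1 in at least one sample (CPM is
  computed on the loaded counts with no prior gene filter). Triads:
  A+B+D TPM sum >= 5 in at least one condition, evaluated on
  replicate-mean TPM; both boundaries are inclusive. Raising either
  threshold can only shrink the retained set.
* Triads expressed overall but with a zero sum in one condition are
  `undefined` there: they are excluded from that condition's proportion
  denominator but kept in the dynamics bookkeeping.

Ternary coordinates use the standard barycentric embedding with A at the
origin, B at (1, 0) and D at (1/2, √3/2).

## Bias dynamics

A triad is *stable* in a genotype when its category is defined and
identical at all three stages; the headline "unchanged" fraction divides
by the triads defined at every stage (a category cannot be unchanged
where it does not exist). Per-category, per-stage stability is the
fraction of triads holding category c at that stage that belong to c's
stable set; a category empty at a stage yields a missing value, not 0.
The per-category *average* stability is the unweighted mean of the three
per-stage fractions (flagged partial if any stage was empty). Both the
all-stage estimand (primary) and the stage-pair transition matrices
(8×8, including `undefined`) are reported, since per-day stability can
also be read as adjacent-pair persistence.

Genotype-unique stable-biased sets are plain set differences of stable
sets, carrying the focal-subgenome gene ids (the X of `X_suppressed` /
`X_dominant`; `balanced` has no focal subgenome). DEG overlap tests those
focal genes against the union of contrasts at |log2FC| >= 1 and adjusted
p < 0.01, tallying direction by each gene's most significant hit.

## Synthetic generator

The generator emulates the standard two-genotype androgenesis time
course: 2 genotypes × 3 stages × 3 replicates (18 samples). It is the
ground-truth source for all validation.

* **Annotation.** Triad i goes to chromosome group `(i mod 7) + 1`, its
  A/B/D members on the cognate chromosomes (1A/1B/1D … 7A/7B/7D).
  Successive gene starts are spaced Uniform(0.5, 1.5) × 2 Mbp apart with
  lengths Uniform(900, 4500) bp — a deliberately scaled-down gene density
  so that a ~100-gene hotspot block spans ~200 Mbp, the magnitude of real
  wheat DEG hotspots. Non-overlap is guaranteed (and checked) because the
  minimum gap exceeds the maximum gene length.
* **Categories.** Per genotype, each triad's category follows a sticky
  Markov chain over stages: kept with probability `stability` (default
  0.7), else redrawn from the category mixture. The default mixture —
  balanced 0.745; dominant 0.025/0.030/0.025; suppressed
  0.060/0.075/0.040 (A/B/D) — mirrors the field's typical pattern:
  balanced majority, suppression commoner than dominance, B-suppression
  most and D-suppression least frequent. The closed-form probability of a
  category being identical at all S stages is
  `Σ_c p_c (s + (1−s) p_c)^(S−1)` (0.766 at the defaults), which the
  generator's truth tables reproduce to Monte-Carlo error.
* **Shares and counts.** Subgenome shares are Dirichlet draws with
  concentration 200 around category archetypes placed strictly inside the
  classification regions — balanced (1/3, 1/3, 1/3), dominant
  (0.8, 0.1, 0.1), suppressed (0.05, 0.475, 0.475) — so planted truth is
  recoverable; the thresholds define regions, not generative centres.
  Triad totals are log-normal (meanlog 4, sdlog 1, arbitrary abundance
  units shared across conditions); filler genes get flat log-normal
  abundances. Counts are negative-binomial with common dispersion 0.05
  (typical RNA-seq overdispersion) around mean = abundance × length,
  scaled to a 1.5 M library; `nb_dispersion = 0` is implemented as the
  exact noise-free limit (counts = rounded means). TPM is recomputed from
  the counts and lengths, so TPM carries the same sampling noise a real
  quantifier would give.
* **Planted effects.** Biomarker genes (default two, |log2FC| 4, one up
  and one down) shift between genotypes at all stages; hotspot blocks
  (default: 1B:40–240 Mbp up, 6B:60–160 Mbp down, |log2FC| 3) shift
  their member genes in the first genotype; `n_deg_genes` (default 150)
  filler genes get ±2 log2FC genotype shifts. DEG tables carry each
  gene's true expected log2FC; adjusted p-values are *assigned*
  (< 0.01 iff |log2FC| >= 1) because differential-expression testing
  itself is out of scope — downstream stages consume only
  (gene, log2FC, padj).
* **Interactions are real signal.** Effects compose multiplicatively: a
  hotspot member that is also a triad gene has its subgenome share — and
  hence its realized category — shifted in that genotype. Truth tables
  therefore record both the planted chain state and the realized expected
  shares/category. Validation runs that target one channel isolate it:
  the category/stability recovery run plants no genotype effects, and the
  biomarker-recovery run plants only the two biomarkers (with all triads
  balanced), because hotspot and category effects are themselves genuine
  genotype discriminators that would otherwise compete with the planted
  biomarkers — as the full-condition demo shows.
* **Not emulated:** batch or lane effects, isoforms, gene-length biases
  between subgenomes, mapping ambiguity between homoeologs (a real
  concern in hexaploids), stage main effects outside category dynamics,
  and DESeq2-style dispersion estimation. Passing recovery tests
  demonstrates correctness of the pipeline's logic under a faithful noise
  model, not robustness to those artefacts.

One integer seed fixes every output; sub-streams are spawned in a fixed
order so stages are individually reproducible.

## Hotspot scan

Smoothing is Nadaraya–Watson local kernel regression with a Gaussian
kernel in base-pair space, evaluated at gene midpoints (midpoint ties are
broken by a deterministic sub-bp jitter hashed from the gene id). The
default bandwidth is 10 Mbp — on wheat-scale chromosomes this averages
over tens of genes while resolving the ~100 Mbp+ regions of interest —
and is exposed as a parameter. Genes absent from the scanned contrast
enter with log2FC 0, so all annotated genes form the background.

Significance has two modes:

* **Permutation (default).** log2FC values are permuted over gene
  positions genome-wide; at each position the two one-sided p-values are
  the +1-continuity ranks of the observed smoothed value in its permuted
  null. p is floored at 1/(n_perm + 1); with the default 10,000
  permutations this floor is ~1e-4, so the analytic-mode convention of
  q < 1e-5 is *unreachable* after FDR correction — permutation-mode
  region calling uses q < 0.05, an algebraic consequence of the
  permutation resolution, and the null is verified super-uniform by
  construction and by test. All-equal inputs give p = 1 everywhere.
* **Analytic t.** A kernel-weighted one-sample t statistic against zero
  with a Satterthwaite-style effective sample size
  `n_eff = (Σw)² / Σw²`; this mode supports the conventional q < 1e-5
  cutoff. Degenerate (zero-variance) neighbourhoods give p = 1.

Benjamini–Hochberg runs genome-wide per direction, which makes the scan
exactly antisymmetric: negating every log2FC swaps up- and down-regions.
Regions are maximal runs of consecutive same-direction significant genes;
bounds are the min start / max end of member genes. Single-gene
chromosomes smooth to the gene's own value.

## Nearest shrunken centroids

Counts + 1 (to avoid zeros) are normalised by DESeq median-ratio size
factors (reference = per-gene geometric mean over samples; genes with any
zero are excluded from the reference — vacuous after the +1 offset) and
transformed to `log2(normalised + 0.5)`. Voom-style precision weights (a
lowess fit of √sd against mean) are available behind a flag but off by
default: the unweighted transform is fully specified and auditable,
whereas weighted-NSC internals vary between implementations.

The classifier is canonical NSC: `m_k = sqrt(1/n_k − 1/n)`, pooled
within-class standard deviations `s_i` with fudge constant
`s0 = median(s_i)`, soft-thresholded contrasts
`d'_ik = sign(d_ik)(|d_ik| − Δ)₊`, and the prior-corrected discriminant
`Σ_i (x_i − x̄'_ik)² / (s_i + s0)² − 2 log π_k` with empirical priors.
Δ is selected from a 30-point grid spanning 0 to max|d_ik| by maximum
mean accuracy under repeated stratified 5-fold cross-validation
(folds shrink gracefully when a class is smaller than 5); accuracy ties
break toward the largest Δ, i.e. the sparsest model. At Δ = 0 the rule is
exactly pooled-standardised nearest centroid; as Δ → ∞ every gene drops
and prediction falls back to the class priors. The evaluation convention
treats the recalcitrant genotype as the reference (negative) class, so
sensitivity is the true-positive rate on the responsive genotype.

The 60/40 train/test split is stratified by class and deterministic under
its seed; with 18 samples (9+9) it yields 10 training and 8 test samples.

## Validation problem sizes and known behaviours

The test suite and `scripts/acceptance.py` use: a 0.001-step simplex grid
(501,501 points) for rule agreement; 5,000 triads at concentration 200 /
dispersion 0.05 for category recovery (≈98%) and planted-chain stability
against the closed form; 1,000 triads with 10,000 permutations for
hotspot recovery (Jaccard ≳ 0.93); 200 null genomes × 1,000 permutations
for null calibration; and a 200-triad, two-biomarker run for NSC
selection. These sizes keep full runs in the seconds-to-minutes range
while leaving Monte-Carlo error well inside the asserted tolerances.

One behaviour deserves emphasis: the unchanged-category fraction computed
from *classified* categories sits ~0.03–0.05 below the planted chain's
closed form even at ≈98% per-condition recovery, because stability
requires agreement at all three stages (attenuation ≈ recovery³) and
misclassification concentrates in low-expression balanced triads whose
noisy shares dip below the 0.20 suppression threshold. Estimating
stability from classified data therefore gives a slight but systematic
underestimate — worth remembering when interpreting stability fractions
on real data, where the same attenuation applies.

## Limitations

* TPM is taken as given for real data; the pipeline never recomputes it
  from counts (gene lengths may be unavailable), though the generator
  derives both consistently.
* The triad filter's treatment of replicates (mean before thresholding)
  and the all-stage stability estimand are stated conventions; other
  choices (any-replicate filtering, pairwise persistence) are reasonable
  and the latter is computed alongside.
* The hotspot scan reimplements positional-enrichment scanning from its
  definition; it does not reproduce any particular legacy package's
  internal kernel or null choices bit-for-bit.
* Homoeolog read-mapping ambiguity, the dominant technical artefact in
  polyploid expression data, is upstream of this toolkit's inputs.
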