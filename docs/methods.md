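# Methods

`multisurv` implements a multiomics analysis for dichotomized cancer-survival
prediction: feature extraction from five omics layers, feature selection, and
classifier evaluation under balanced nested cross-validation, plus a
synthetic-cohort generator that makes every step testable without
controlled-access patient data.  This note records the models, the parameters
that matter, the numerical choices, and what the synthetic cohorts do and do
not establish.

## Survival dichotomization

Patients are labeled at a horizon H (default 730 days): dead before H →
nonsurvivor; dead at/after H, or alive with last contact at/after H →
survivor; alive with last contact before H → excluded, because reaching the
horizon cannot be ascertained.  Deaths from causes other than the cancer can
optionally be excluded when a cause-of-death flag is available.  Death exactly
at day H counts as survivor ("died within H" read strictly); the boundary is a
flag (`death_at_horizon_survives`) because the convention is genuinely
ambiguous.  Raising H can only move patients from labeled to excluded, never
back — a monotonicity the tests assert.

## Mutation featurization

**Catalogues.**  Somatic variants are classified into the three fixed schemes
used in mutational-signature analysis:

* SBS96 — single-base substitutions in their trinucleotide context, with
  purine-reference variants reverse-complemented so the mutated base is a
  pyrimidine (`G[T>C]T` denotes T→C flanked by G and T).  6 substitution
  types × 16 contexts = 96 categories.
* DBS78 — doublet substitutions in which both bases change, collapsed onto a
  canonical strand (reference doublet among AC, AT, CC, CG, CT, GC, TA, TC,
  TG, TT; for palindromic references the lexicographically smaller alternate
  is the representative).  The enumeration yields exactly 78 categories and
  is verified against a brute-force involution check over all 144 doublets.
* ID83 — small indels stratified by length, repeat context and microhomology:
  1-bp deletions/insertions by C/T base and homopolymer length (deletions
  binned 1–6+ counting the deleted base, insertions 0–5+ counting the
  pre-existing run); ≥2-bp indels by length (2,3,4,5+) × repeat-unit count
  (deletions 1–6+ including the deleted copy, insertions 0–5+); deletions at
  non-repetitive sites with flanking microhomology by length × microhomology
  length (1; 1–2; 1–3; 1–5+).  12+12+24+24+11 = 83 categories, following the
  COSMIC v3 binning conventions.  Microhomology is the longest match between
  a proper prefix (suffix) of the deleted sequence and the reference
  immediately right (left) of it.  Indels are represented VCF-style with an
  anchor base; complex indels (both alleles longer than the anchor) and
  multi-nucleotide substitutions longer than 2 are logged and skipped.

Every variant contributes to exactly one scheme or to none, so catalogue
totals conserve classifiable variant counts; a cohort-wide test asserts this.

**Signature exposures.**  A catalogue row is attributed to reference
signatures (category × signature probability matrix, columns summing to 1) by
non-negative least squares per sample, reporting the Euclidean residual as the
reconstruction error.  NNLS is exact on any row inside the non-negative cone
of the signatures; a 60/40 mixture of two synthetic signatures is recovered
within 5% relative error from a 6,000-mutation catalogue, the size at which
multinomial sampling noise puts roughly a 3-sigma margin inside that bound
(relative standard error of the smaller weight ≈ sqrt(1.5/n)).

**Gene and gene-set level.**  The gene matrix is binary: 1 when a gene
carries at least one protein-altering mutation.  "Protein-altering" maps from
MAF Variant_Classification values {Missense, Nonsense, Frame_Shift_Del/Ins,
In_Frame_Del/Ins, Splice_Site, Nonstop, Translation_Start_Site}; a flag
restricts or widens this.  Gene annotation on the variant is trusted when
present; coordinate overlap with the gene models is the fallback.  Gene-set
aggregation sums the binary indicators (the burden = number of altered member
genes); for CNV matrices the aggregate is the mean of signed segment means.
Sum-of-binaries was chosen over raw mutation counts so that one hypermutated
gene cannot dominate a set; a raw-count mode exists.

## CNV featurization

Segment means live on the log2(CN/2) scale; 0 is the diploid state and is
treated as "no alteration" (homozygous deletions are floored at CN = 0.25 by
the generator to keep the value finite).  Multi-sample aggregation:

1. elementary intervals from the union of all samples' breakpoints per
   chromosome; each sample's segment mean painted onto the intervals it
   covers, neutral elsewhere;
2. intervals altered in fewer than 2 samples dropped (configurable
   `min_support`);
3. consecutive retained intervals merged when the fraction of samples whose
   values agree exactly between the two intervals is ≥ `frac_overlap`
   (default 0.9); the merged per-sample value is the length-weighted mean.

The merge criterion is this package's concretization of partial-overlap
region aggregation; it is specified exactly and verified against a base-pair
resolution brute-force oracle on random instances rather than claiming
bit-compatibility with any other implementation.  With `frac_overlap = 1`
merging joins only intervals identical in every sample.  Gene-level values
assign each gene the segment mean of the altered region with the largest
overlap, even when the region covers only part of the gene; genes in the same
region therefore receive identical values, which is why the correlation
filter matters downstream.

## Expression and methylation

Count matrices (mRNA, miRNA) are filtered — a feature is kept if any sample
has ≥ `min_reads` (default 10) — and normalized by median-of-ratios size
factors: factor_j = median over features with a positive geometric mean of
count_fj / geomean_f.  Factors are relative to the pseudo-reference, so
scaling one sample scales its factor relative to the others; a unit test
cross-checks the factors against the established DESeq2 port (pydeseq2) on a
small matrix.  Only the size-factor component is implemented because the
pipeline consumes nothing else (no differential-expression testing).
Methylation beta values pass through raw.  PCA feature extraction (scores of
the first k components, deterministic sign convention: largest-magnitude
loading positive) is available for any dense matrix.

## Feature selection

**Filters.**  Zero-variance columns are removed first.  The correlation
filter then greedily resolves pairs with |Pearson r| > 0.9: the pair with the
largest |r| is processed first (first such pair in column order on exact
ties) and the member with the larger mean absolute correlation against all
remaining features is removed (later column on ties), until no pair exceeds
the cutoff.  The procedure is deterministic and is checked against an
independent exhaustive implementation.

**Lasso AUC profile.**  Per omics layer, an L1-penalized logistic regression
is fit along 100 log-spaced penalties from the data-derived maximal penalty
(all coefficients zero) down to 1% of it, on standardized features.  At each
penalty the nonzero-coefficient count on the full data and the stratified
k-fold (default 10) cross-validated AUC (per-fold AUCs averaged, one shared
fold assignment along the path) are recorded, up to `max_features`.  The
profile is path-indexed, not refit-on-top-k.

**Boruta.**  Each run, every active feature gets a shadow copy (its values
permuted; shadows padded to at least 5), a random forest is fit on real +
shadow columns, and an undecided feature scores a hit when its importance
Z-score exceeds the best shadow's.  After each run a two-sided binomial test
(p = 0.5, Bonferroni-corrected over the currently undecided features at level
alpha, default 0.01) confirms features with significantly many hits and
rejects those with significantly few; rejected features leave the design.
The loop ends when all features are decided or at `max_runs` (default
10,000); leftovers are Tentative and reported as such.  Confirmed features
are ranked by mean importance over the run history.

The default importance is the Z-score of per-tree impurity importances
(mean/sd over trees) — the convention of the established Python Boruta port —
because per-tree out-of-bag permutation importance is computationally
prohibitive at the matrix widths the combined multiomics matrix reaches.  A
forest-level permutation-importance Z-score (`importance="permutation_z"`) is
implemented and tested for users who want the randomForest-style measure on
small problems.

## Nested cross-validation

The outer loop is a stratified k-fold (default 10) over the labeled samples,
repeated (default 100 times) with RNG substreams spawned from the master
seed.  Inside each outer training fold:

1. the classes are balanced by down-sampling: the minority class (here
   nonsurvivors) is kept whole (multiplier 1; other multipliers resample with
   replacement) and the majority class is subsampled without replacement to
   ⌈0.3 × its size⌉ — e.g. 178 survivors / 89 nonsurvivors become 54 + 89;
2. an inner leave-one-out loop tunes the forest's variables-per-split: for
   each candidate on a square-root-anchored grid between 2 and the feature
   count, every balanced training sample is held out once, and the pooled
   leave-one-out probabilities give one AUC per candidate (single-sample
   folds admit no per-fold ROC, so pooling is forced);
3. the best candidate (smallest on ties) is refit on the balanced training
   portion and applied to the untouched outer test fold.

Outer predictions are pooled per repeat into a ROC/AUC (rank statistic with
midranks, verified against exhaustive pair counting).  Test folds never enter
balancing, tuning or fitting; each sample is predicted exactly once per
repeat, which the tests assert.  Balancing precedes the inner split (the
alternative — balancing inside every leave-one-out fit — would make the inner
AUC incomparable across candidates).  Forests default to 500 trees; a
separate `inner_n_trees` controls the tuning fits, since tuning needs ranking
stability, not converged probabilities.

**SHAP.**  Monte-Carlo Shapley attribution by permutation sampling: per
explained sample and simulation (default nsim = 10), a random feature
permutation and a random background sample (from the balanced training set)
are drawn; walking the permutation, features switch one at a time from the
background's value to the explained sample's, and each feature is credited
with the resulting change in predicted nonsurvivor probability.  The walk
telescopes, so per-simulation attributions sum exactly to f(x) − f(background),
and positive values push toward the nonsurvivor class.  Fold-level SHAP
matrices are averaged over repeats.

## Synthetic cohorts

The generator emulates the statistical structure the analysis must detect,
with defaults mirroring the study shape: 267 labeled samples, one third
nonsurvivors (89), plus 10% extra early-censored cases that exercise the
exclusion rule.  Per layer:

* **Mutations** — background missense/silent SNVs per non-pathway gene at
  rate 0.005 per gene per sample, class-independent; a planted pathway of 30
  genes mutated mutually exclusively (at most one member per sample, chosen
  uniformly) with total probability 0.62 in nonsurvivors vs 0.28 in
  survivors; plus class-independent indels and doublets so the ID83/DBS78
  catalogues are populated.  The effect sizes come from a pre-implementation
  power analysis: the burden z-score is ~sqrt(K) times the per-gene z-score,
  and K = 30 with these probabilities keeps every member gene below
  genome-wide (Bonferroni) significance while the single pre-specified
  pathway burden is significant at 0.05 — the mutual-exclusivity rescue the
  gene-set aggregation exists for.  A per-gene scan is read at the
  Bonferroni-corrected level because that is how per-gene association scans
  are read in practice; at a raw 0.05 threshold no effect size can make all
  30 weakly-loaded genes non-significant while the burden is reliably
  significant.
* **CNV** — per sample, 6 background segments (0.5–3 kb, CN ∈ {0,1,3,4})
  plus one planted three-gene deletion carried by 50% of nonsurvivors vs 25%
  of survivors — deliberately weaker than the expression signal, mirroring
  the finding that CNV features contribute least.
* **mRNA** — negative-binomial counts (var = μ + μ²·disp, disp = 0.15,
  log-normal baseline means) with 6 planted genes at log2 fold change 1.5 in
  nonsurvivors.  miRNA counts use the same model with no planted signal.
* **Methylation** — Beta-distributed values (concentration 30) with 6
  planted probes whose nonsurvivor mean shifts by 0.2 toward the far side of
  0.5.
* **Clinical** — nonsurvivors die uniformly on [30, 729] days; survivors
  have follow-up on [730, 2500] (30% of them dead later, a minority of those
  from non-cancer causes, to exercise the optional exclusion).

All randomness flows from one seed through spawned NumPy substreams, so a
seed reproduces the bundle byte for byte.  What the synthetic cohorts do NOT
emulate: mutation hotspots and signatures coupled to outcome, inter-layer
correlation beyond the shared class labels, batch effects, platform-specific
missingness, or genome-scale feature counts.  Passing tests therefore show
the machinery is correct and calibrated, not that any particular real-data
AUC is reproducible.

## Problem sizes and numerical choices

Tests and the acceptance script run the same algorithms at desk scale, the
package's own choice of problem size: cohorts of 100 genes / 100 probes / 30
miRNAs (≈450 combined features after filtering), Boruta at 100 trees per run,
nested CV with 4–5 outer folds, a tuning grid of 2–3 candidates, 15-tree
inner forests and 5–20 repeats.  The null-calibration cohort uses n = 160,
where the across-cohort null standard deviation of CV-AUC
(≈ sqrt((n₁+n₂+1)/(12·n₁·n₂)) ≈ 0.049) puts the [0.4, 0.6] acceptance band at
±2 sigma.  Degenerate inputs are defined, not special-cased: empty segment
lists give empty partitions, samples with zero variants give all-zero
catalogue rows, an empty feature matrix gives a zero-run Boruta result, and a
Z-score with zero spread over trees is 0.

## Known limitations

* The CNV region-merge rule is a documented stand-in for partial-overlap
  aggregation; other tools' epsilon-merging may split or join differently.
* Boruta's default impurity-based Z-score can favor high-cardinality
  features more than the permutation measure would; the permutation variant
  is available but slow.
* The Lasso profile uses liblinear fits at fixed penalties rather than a
  single warm-started path, so nonzero counts can be locally non-monotone
  along the path.
* Tentative Boruta features are reported as-is; no rough-fix reclassification
  is applied.
* The pipeline evaluates features on the cohort that selected them; the
  resulting AUC is optimistic in exactly the way an external validation
  cohort would expose.
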