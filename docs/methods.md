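# Methods

`dgcproteo` re-implements, as a tested library, the analysis chain used to
characterize a paired tumor/nearby-tissue proteomic cohort of diffuse-type
gastric cancer (DGC): label-free quantification and filtering, paired
permutation differential expression, consensus subtyping, mutation-proteome
association, survival modelling, and prognosis-aware drug-target nomination.
This note records the models, the parameter choices that matter, and the
limits of what the synthetic-cohort tests demonstrate.

## Quantification and the filter cascade

Protein quantification follows the iBAQ convention: the summed peptide
intensity of a protein divided by its number of theoretically observable
fully tryptic peptides (cleavage after K/R but not before P, zero missed
cleavages, peptide length 6-30 by default; both bounds are arguments, since
the matter is convention rather than principle). Within a sample, iBAQ
values are normalized to fraction of total (FOT) and presented x 10^5, so
detected values sum to 10^5 and the quantification-reliability floor of
10^-5 FOT sits at 1.0 on the working scale.

The filter cascade narrows the protein universe in nested stages:

- **D2** — identification confidence: >= 2 unique peptides and a Mascot ion
  score strictly greater than 20 in at least one sample.
- **D3** — drops keratins (configurable symbol-prefix list, default `KRT`)
  and proteins whose maximum FOT never exceeds the floor. Equality with the
  floor does not count: below-or-at-floor values are considered
  unquantifiable.
- **D4** — proteins detected (either tissue) in at least a one-sixth
  prevalence of samples.
- **D5** — proteins quantified *above the floor* in at least that same
  prevalence of samples. Remaining sub-floor or missing values are then
  floor-imputed and per-patient log10 tumor/nearby ratios are taken, so a
  protein undetected on one side still yields a finite ratio and a
  both-undetected patient yields exactly 0.
- **D6** — proteins with a T/N fold change strictly above 3 (or below 1/3)
  in at least a one-tenth prevalence of patients; this is the clustering
  set.

Prevalence counts are computed by half-up rounding of `n x fraction` with a
minimum of 1, which reproduces the reference cut-offs of 28/168 samples and
8/84 patients. D5 is a genuine subset of D4 rather than a re-labelling:
detection (any signal) and quantifiability (signal above the floor) are
distinct properties, and the cascade tests each in turn.

## Paired SAM differential expression

For each protein the paired differences are the per-patient log10 T/N
ratios z_k. The regularized statistic is d = z_bar / (s + s0) with
s = sqrt(sum (z_k - z_bar)^2 / (n(n-1))); s0 = 0 recovers the one-sample t
statistic. s0 is chosen by the percentile procedure: over candidate
percentiles of the s distribution, pick the one minimizing the coefficient
of variation of the windowed median absolute deviation of d across
quantile windows of s. The null distribution comes from sign flips of the
paired differences — all 2^n flips when n <= 12, otherwise `n_permutations`
random flips (default 1000) drawn from the mandatory seed.

For each threshold delta, asymmetric cut-points are read off the
observed-versus-expected order-statistic plot (the smallest non-negative
observed d exceeding its expectation by delta, and symmetrically below);
the called count, the median count of null statistics beyond the cuts
across permutations, and their ratio (clipped to 1) give the estimated
FDR. A protein's q-value is the smallest FDR over thresholds at which it
is called. No pi0 correction is applied by default.

Cohort-level calls layer on top:

- **significant DEPs** — q < 0.01 *and* differentially-expressed percentage
  |N_up - N_down| / N_detected strictly above 50%, where N_up/N_down count
  patients beyond 3-fold and N_detected counts patients with the protein
  detected in either tissue;
- **strict DEPs** — detected in strictly more than 75% of patients with a
  consistent >3-fold change in strictly more than 60% of the detected
  cases (the denominator counts detection in either tissue; a flag could
  switch to both, but either-tissue is the default because detection in
  one tissue alone is itself informative for a T/N contrast);
- **overexpression fractions** — per protein, the share of all patients
  (and separately of detected patients) with T/N strictly above 3-fold.

All inequality gates in the cascade and the calls are strict; values at
a boundary never qualify.

## Consensus subtyping

Patients are clustered on their D6 log-ratio profiles by consensus
k-means: 1000 resamples (default) of 80% of patients without replacement,
Euclidean k-means with k-means++ seeding and 10 restarts per subsample
for each k in 2..6. The k-means inner loop is a vectorized Lloyd
implementation written for many small problems; it is cross-checked
against scikit-learn's KMeans in the test suite. The consensus matrix
M(i,j) is the co-clustering count over the co-sampling count. Model
selection reports, per k: the empirical CDF of M's upper triangle and its
area, the relative delta-area between successive k, the proportion of
ambiguous clustering (PAC; entries strictly inside (0.1, 0.9), bounds
configurable), and the mean silhouette width on 1 - M. The selected k
minimizes PAC with ties broken toward smaller k; the full table is
reported so a human can weigh delta-area and silhouette as well. Final
labels cut an average-linkage dendrogram of 1 - M at k.

## Mutation-proteome association

Variants are gated on allele frequency — tumor VAF strictly above 0.05 and
matched-normal VAF strictly below 0.03 — and classified by a fixed
vocabulary into nonsynonymous (everything except silent/intronic/UTR) and
truncating (nonsense, frameshift, canonical splice). Per-gene frequency
counts each patient once; the 5% recurrence summary uses an inclusive
(>=) comparison.

A gene's own-protein effect is a Wilcoxon rank-sum test of detected tumor
FOT values, mutant versus wild-type carriers, with a detection-status
classification (detected in tumors / detected only in nearby tissue /
never detected / insufficient group sizes at a 3-tumor minimum). The
gene's mutation-altered proteome scans every protein after flooring
abundances at 10^-5 FOT: up-regulated means P < 0.05 and mutant/wild
mean ratio strictly above 1.6; down-regulated means P < 0.05 and ratio
strictly below 0.33. Flooring before the means keeps undetected values
from producing unbounded ratios. Altered proteomes are compared across
genes by the Jaccard index. Pathway mutation profiles mark a patient
mutated in a pathway when any member gene carries a qualifying variant,
and subtype-mutation enrichment tests each feature one-vs-rest per
subtype with Fisher's exact test.

## Survival and target nomination

Kaplan-Meier estimation delegates to lifelines. The log-rank test is the
standard O-E chi-square on k groups; given ordinal weights it becomes the
score-trend variant on one degree of freedom. Cox proportional-hazards
regression maximizes the Efron-tied partial likelihood by Newton-Raphson
with step halving (tolerance 1e-9, 100 iterations, error with the
gradient norm on failure); complete separation is detected when a
coefficient passes |ln HR| = 15 and is capped with a warning. Wald
standard errors and 95% CIs come from the inverse information. The
implementation is validated against lifelines and against brute-force
partial-likelihood maximization in the tests; it exists in-package
because the per-protein screen runs thousands of small fits.

The cohort analysis fits each covariate block univariately (age and
ordinal stage as continuous, gender/chemotherapy/site as dummies, subtype
both as categorical with the first level as reference and as an ordinal
trend) and enters clinical blocks with univariate P < 0.05 into the
multivariate model alongside subtype.

The per-protein screen restricts to patients with the protein detected
(and proteins detected in strictly more than 5 patients), dichotomizes at
the median detected T/N ratio — ties go to "low" — and reports the
binary-covariate Cox ln(HR) plus the two-group log-rank p; a continuous
mode uses the log-ratio directly. Nomination then applies:

- **proteomic screen** — overexpressed (>3-fold) in strictly more than
  half the tumors, annotated in a druggable category (enzyme, GPCR,
  kinase, ion channel, transmembrane, extracellular), and prognosis
  unfavorable (log-rank P < 0.05 with HR > 1 on the point estimate);
- **genomic screen** — members of the fixed druggable driver list that
  were screened and overexpressed are reported with their survival
  statistics and flags for unfavorable or protective associations; no
  survival gate filters this list.

Marker-high calls (e.g. for immune mediators) use the upper quartile of
detected values with the linear-interpolation (type-7) percentile
convention; a patient at the quartile exactly is high, undetected
patients are low, and fewer than 4 detected values yields all-low.

## The synthetic cohort generator

The generator emulates the cohort structure every stage is tested on.
Defaults: 84 patients (paired tumor/nearby samples), 500 proteins,
per-protein baseline log10(FOT x 1e5) drawn from N(1.7, 1.0) with
per-sample noise sd 0.25; detection is Bernoulli with probability
logistic in log10 abundance (midpoint at the 10^-5 FOT floor, steepness
1.5), which makes detection rates rise monotonically with abundance.
Tumor samples add planted effects: 10% global DEPs at 0.6 log10 units
(70% up), the first 20 of them strengthened to 1.0 log10 to serve as
strict-DEP truth; three 50-protein subtype programs (cell cycle, EMT,
immune) at 1.0 log10 units, one per subtype. The subtype proportions are
allocated exactly (largest remainder) and the programs are disjoint by
default, keeping the three subtypes near-equidistant so that the
two-cluster solution is genuinely ambiguous under resampling while the
three-cluster solution is stable — shared programs can be configured per
block. Nine driver genes carry Bernoulli mutations (frequencies 0.10 to
0.45, skewed across subtypes by multipliers 0.7/1.0/1.3); 90% of
variants pass the VAF gate by construction, and a CDH1-style program
(20 proteins x 2.0-fold up, 10 x 0.25-fold down in carriers) provides
mutation-altered truth. The planted knockdown is 4-fold rather than
2-fold because a 2-fold knockdown (mean ratio 0.5) can never pass the
< 0.33 down-gate, so recovery of a 2-fold program would be undefined.

Survival is Weibull (shape 1.2, scale 40 months) with linear predictor
0.7 per subtype step by default, censored uniformly on 8-50 months
(~30-37% censoring). Five planted drug targets are co-overexpressed
(mean 1.2 log10, +-0.75 contrast) in an "aggressive" half of the cohort
that carries a single ln(HR) = 1.1 hazard term (centered), and two
protective proteins mirror this with negative sign in an independent
half; tying the hazard to one latent factor instead of five independent
ones avoids the non-collapsibility attenuation that would otherwise make
a marginal screen unable to see effects it is supposed to recover, and
mirrors the biology of an aggressive phenotype co-expressing its markers.
The annotation table marks ~30% of proteins druggable (always including
the planted targets), and a 40-member "genomic driver" list mixes the
protective proteins, a third of overexpressed DEPs, and null proteins.

What the generator does *not* emulate: correlated protein co-expression
beyond the planted blocks, compositional coupling from FOT normalization
(values are drawn directly on the FOT scale rather than renormalized),
peptide-level evidence, realistic VAF distributions beyond the filter
gate, and clinical covariates that actually influence hazard (age,
stage, chemotherapy are drawn independently of survival). Passing tests
therefore demonstrate the statistical machinery under a clean generative
model, not robustness to the correlation structure of real cohorts.

## Problem sizes and numerical choices

The test suite and the acceptance script run cohorts of 84-200 patients
and 500 proteins, with 1000 permutations for SAM and 1000 resamples for
consensus clustering — the sizes the methods were designed around.
Ties in ranks use mid-ranks; the Wilcoxon normal approximation is
tie-corrected with a continuity correction (a flag disables it, as the
convention is not universal); Fisher's two-sided p sums hypergeometric
masses no greater than the observed table's; chi-square is Pearson
without Yates correction and refuses tables with a zero expected cell.
Degenerate inputs (all-tied samples, zero margins) return p = 1 with an
explicit flag rather than raising. All randomness flows through
explicit integer seeds; identical seeds give byte-identical outputs.

## Known limitations

Gene symbols are the only protein identifiers; multi-gene protein groups
are kept as given. The SAM q-value is the delta-table minimum, which can
be conservative between grid points at very small protein counts. The
consensus PAC criterion cannot distinguish k = 2 from k = 3 when the
true structure is strictly nested (both PACs are 0); the selection
report includes delta-area and silhouette for exactly that situation.
The genomic-target screen intentionally applies no survival gate, so its
output is an annotated evaluation, not a nomination.
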