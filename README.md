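# dgcproteo

Paired tumor/nearby-tissue proteogenomics in Python: the analysis chain
used to subtype diffuse-type gastric cancer (DGC) cohorts from label-free
proteome profiles, re-implemented as a reusable, tested library with a
synthetic-cohort generator that plants known ground truth in every stage.

DGC is the Lauren-classification gastric cancer subtype with the worst
prognosis and few targeted options; genomically it is largely "stable", so
molecular stratification has to come from elsewhere. This package covers
the proteome-first route: quantify paired tumor (T) and nearby (N) tissue,
find what changes, cluster patients on the changes, relate driver-gene
mutations to the proteome, and nominate drug targets whose overexpression
actually predicts poor survival. It is written for computational
biologists who want each stage as a callable, testable unit rather than a
one-off script stack.

## What is implemented

- **Quantification** (`dgcproteo.quantify`) — iBAQ (summed intensity /
  theoretical tryptic peptide count), FOT normalization (presented x 10^5),
  and the nested D1-D6 filter cascade: identification confidence (>= 2
  unique peptides, ion score > 20), keratin and sub-floor exclusion
  (10^-5 FOT), detection prevalence (1/6 of samples), above-floor
  prevalence with floor imputation, and the >3-fold-in-1/10-of-patients
  differential set used for clustering.
- **Differential expression** (`dgcproteo.differential`) — two-class
  paired SAM: d = z_bar/(s + s0) on per-patient log10 T/N ratios, s0 by
  the percentile procedure, sign-flip permutation null (exhaustive for
  n <= 12), asymmetric delta cut-points, median-false-count FDR, and
  q-values; plus the differentially-expressed-percentage call
  (|N_up - N_down|/N_detected > 50% at q < 0.01), the strict
  consistency-based call, and per-protein overexpression fractions.
  `PairedSAM(ratios, ...).fit()` returns a results object with
  `summary()`, `select_delta()`, and `called_at()`.
- **Subtyping** (`dgcproteo.subtype`) — consensus k-means over patient
  resamples with CDF area, delta-area, PAC and silhouette model selection
  (`ConsensusClustering(data, ...).fit()`), final labels by
  average-linkage on 1 - M, and per-cluster SAM signatures.
- **Enrichment** (`dgcproteo.enrichment`) — Fisher over-representation of
  DE sets against the detected background, GMT input.
- **Proteogenomics** (`dgcproteo.proteogenomics`) — VAF gating
  (tumor > 0.05, normal < 0.03), per-gene mutation frequencies,
  mutation-vs-own-protein effects with detection-status classification,
  mutation-altered proteomes (P < 0.05 and mean ratio > 1.6 or < 0.33),
  Jaccard similarity, pathway mutation profiles, and one-vs-rest
  subtype-mutation enrichment.
- **Survival & targets** (`dgcproteo.survival`) — Kaplan-Meier (via
  lifelines), k-group and trend log-rank, Cox regression (Efron ties,
  Newton-Raphson; validated against lifelines and brute-force partial
  likelihood), the univariate/multivariate cohort analysis, the
  per-protein median-split survival screen, upper-quartile marker calls,
  and both target-nomination screens (druggable-driver list evaluation
  and the overexpressed + druggable + poor-prognosis intersection).
- **Synthetic cohorts** (`dgcproteo.simulate`) — paired cohorts with
  log-normal abundance, abundance-dependent missingness, three planted
  subtype programs, global DEPs, driver mutations with downstream protein
  effects, Weibull survival with subtype-ordered hazards and planted
  prognostic targets, plus `truth_scorecard` for recovery metrics.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```python
from dgcproteo import CohortConfig, generate_cohort, filter_cascade, PairedSAM
from dgcproteo.differential import compute_dep_calls, call_significant_deps
from dgcproteo.subtype import ConsensusClustering
from dgcproteo.simulate import truth_scorecard

cohort = generate_cohort(CohortConfig(seed=7, n_patients=90))
cascade = filter_cascade(cohort.abundance)
print("cascade:", cascade.cardinalities)

sam = PairedSAM(cascade.ratios, n_permutations=1000, seed=7).fit()
deps = call_significant_deps(sam, compute_dep_calls(cascade.ratios))
print(f"s0 = {sam.s0:.3f}; {len(deps)} DEPs at q<0.01 "
      f"(delta = {sam.select_delta(0.01):.2f})")

data = cascade.ratios.restrict(cascade["D6"]).log_ratios.T
res = ConsensusClustering(data, n_resamples=1000, seed=7).fit()
print(res.summary().round(3))
print("ARI vs truth:",
      truth_scorecard(cohort.truth, subtype_labels=res.labels)["ari"])
```

Output:

```
cascade: {'D2': 500, 'D3': 497, 'D4': 497, 'D5': 489, 'D6': 483}
s0 = 0.018; 51 DEPs at q<0.01 (delta = 1.80)
    area  delta_area    pac  silhouette  selected
k
2  0.463       0.463  0.598       0.723     False
3  0.674       0.455  0.000       1.000      True
4  0.711       0.055  0.153       0.787     False
5  0.741       0.041  0.293       0.576     False
6  0.769       0.038  0.323       0.485     False
ARI vs truth: 1.0
```

Reading it: of 500 simulated proteins, 483 change more than threefold in
at least a tenth of patients (D6) and feed the clustering. SAM calls 51
differential proteins at FDR < 0.01 — the cohort plants 50 globally
differential proteins plus three subtype programs, so calls beyond the
global 50 are genuinely shifted subtype proteins, not noise. The
consensus table shows why k = 3 is chosen: the 2-cluster solution is
ambiguous (PAC 0.60) because the three planted subtypes are roughly
equidistant, while the 3-cluster solution is perfectly stable (PAC 0,
silhouette 1.0), and the recovered labels match the planted subtypes
exactly (adjusted Rand index 1.0).

The same stages are exposed as a CLI (`dgcproteo simulate | filter |
diff | subtype | enrich | mutprot | survival | nominate`); each
subcommand reads and writes plain TSV/CSV/GMT.

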