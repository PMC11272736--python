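# Methods

## Classification model

Both subtype tracks are deterministic precedence cascades over per-sample
evidence; neither consumes the other's output, and both are always computed
because a tumor missed by one arm (e.g. a p53-mutant tumor whose POLE status
goes untested) would otherwise be mis-risk-stratified.

**Substitution spectrum and the POLE rule.** Somatic calls are read from a
paired tumor/normal VCF and filtered (FILTER == PASS, tumor allele fraction
≥ 0.05, normal allele fraction ≤ 0.02, tumor depth ≥ 20 — conventional
paired-somatic heuristics, all configurable; the upstream caller's exact
criteria are proprietary and not reproduced). The spectrum collapses each
SNV to its pyrimidine representation (G→T counts as C>A, etc.), giving six
class fractions that sum to 1. A tumor is spectrum-POLE iff n_SNV > 500,
C>A fraction > 0.2 and C>G fraction < 0.03, all strict, exactly as the rule
is published. Indels are retained for gene flags but never counted as SNVs.
A sample with zero SNVs has an undefined spectrum and is treated as
non-POLE on this rule.

**POLE pathogenicity.** The surrogate track's POLEmut arm needs a
pathogenic/likely-pathogenic call. This package uses a transparent,
editable whitelist instead of a proprietary curation engine: the
exonuclease-domain hotspots P286R, V411L, S297F, A456P, S459F, plus any
missense mapping to residues 268–471 (the exonuclease domain). Protein
changes are read from the `AACHANGE` INFO tag.

**MSI score.** Per microsatellite locus, instability is the total-variation
distance ½·Σₖ|f_T(k) − f_N(k)| between count-normalized tumor and normal
repeat-length distributions: 0 for identical distributions, 1 for disjoint
supports, symmetric, scale-invariant, and monotone under mixing tumor
toward normal. The sample score is the unweighted mean over usable loci
(≥ 20 reads in both samples; default 60 loci at ~100 reads), and MSI-H is
called at score ≥ 0.3 (inclusive). This is an analogue of the MANTIS
tumor/normal stepwise-difference statistic with the published 0.3 operating
threshold — deliberately not a bit-exact port, since the distance bounded
in [0, 1] with these properties is what the threshold semantics require.

**CN cluster-4 predictor.** Per sample, segments are canonicalized (sorted,
adjacent equal-copy-number runs merged, so counts are representation-
independent), and alterations are segments with copy number > 2.5 (gain) or
< 1.5 (loss); the cutoffs are configurable because no published definition
exists. Features: total gains and losses; gains/losses per chromosome
(1–22, X); alteration counts for the 25 genes altered in the most training
samples (ties broken lexicographically; the list is frozen into the model);
ploidy (length-weighted mean copy number); and total altered megabases.
"Length of CN alterations per mega base" is read as altered megabases; the
alternative reading (alterations per Mb) is computed alongside but not used
as a model feature. The classifier is Gaussian Naïve Bayes with empirical
class priors and a variance floor of 1e-9 × the largest feature variance;
cluster-4 is flagged at posterior > 0.5. Performance is estimated by
stratified 5-fold cross-validation (accuracy, precision, recall, F1,
ROC-AUC averaged unweighted over folds, cluster-4 positive). The original
model was trained on 240 externally curated cases (26% cluster 4) that are
not redistributable; the synthetic training cohort reproduces n and class
balance, so cross-validation numbers here characterize the synthetic
conditions, not the original data.

**QC plausibility flags.** Four FFPE-degradation metrics correlate with
spurious MSI calls; breaching any threshold (mapped reads < 92%, on-target
reads < 66%, short fragments > 93%, adapter contamination > 6.34%, strict)
raises a flag. Flags annotate MSI-H calls as "at risk of FFPE artifact" but
never alter the cascade output — the published finding is a correlation
with false positives, not a classification rule, so auditability is
preserved without changing calls.

**Survival.** Kaplan–Meier curves per stratum; k-group log-rank test; Cox
proportional hazards with one indicator per non-reference subtype
(references: CN low and NSMP, the strata omitted from the published hazard
tables), Efron tie handling (months-resolution times tie heavily), and Wald
95% CIs (the CI construction of the original analysis is unstated; Wald is
the lifelines/R default reporting convention). Strata with zero events are
reported as HR 0 with an infinite upper CI and excluded from the fit, since
their partial-likelihood estimate diverges. Fits use a damped Newton step
(step size 0.5): full steps can overshoot into non-convergence under strong
effects with heavy ties, and the damped fit reproduces R `survival::coxph`
estimates; a fit that still fails to converge is reported as such, never
silently. Subjects missing time or status are dropped per endpoint.

## Synthetic cohort generator

The generator is the package's study population: per-sample truths are
planted, raw data are emitted, and every truth must be recoverable by the
pipeline exactly, because all signals are placed far from the decision
boundaries by construction.

* **Spectra**: POLE-signature tumors draw 600–3000 SNVs from class
  probabilities (C>A 0.32, C>G 0.01, …), resampled until the realized
  spectrum satisfies n > 500, C>A > 0.25, C>G < 0.02 — strictly inside the
  rule region. The upper SNV bound keeps per-sample VCFs at desk scale
  while remaining inside the plant region. Other tumors draw 30–300 SNVs
  with a C>T-dominated background spectrum, outside the rule on the count
  criterion alone. Passenger indels, a silent TP53 passenger (10% of
  non-p53abn samples), and three records the read filter must reject
  (non-PASS, germline leak, shallow) exercise the filtering contract.
* **MSI**: 60 loci at depth 100. Stable tumors redraw the normal length
  distribution (realized scores ~0.06 from multinomial noise, safely below
  0.3); MSI-H tumors shift 50% of reads three repeat units down (expected
  per-locus score 0.5, aggregate ≥ 0.4).
* **Copy number**: cluster-4 genomes carve 25–40 alterations (gains of 3–5
  copies, losses of 0.5–1.2) into disjoint 10 Mb cells; quiet genomes are
  diploid with segment-level jitter (CN ~ N(2, 0.08), clipped inside the
  1.5/2.5 cutoffs) and zero threshold-crossing alterations. Quiet genomes
  carry no incidental alterations deliberately: an alteration in a
  chromosome or gene never altered among quiet training samples hits a
  zero-variance Gaussian in the Naïve Bayes model and vetoes the quiet
  class regardless of every other feature, which would break exact
  recovery. Real tumors are noisier; consequently the cross-validated
  metrics on synthetic training cohorts (≈1.0) exceed what heterogeneous
  clinical data can yield, and should be read as a correctness check of
  the estimator, not an expected clinical operating point.
* **Survival**: exponential event times with multiplicative hazards keyed
  by the planted surrogate subtype — OS baseline 0.002/month (NSMP and all
  CN-quiet strata), multipliers POLEmut 0.05, dMMR 1.44, p53abn 12.8; PFS
  baseline 0.003/month with multipliers 0.05 / 2.07 / 9.58 — the magnitudes
  of the published hazard ratios, under the simplest model satisfying
  proportional hazards so Cox recovery is well-posed. Censoring is uniform
  administrative on [0, 140] months (the study's follow-up range). With
  these rates the POLE stratum is essentially event-free (per-subject OS
  event probability ≈ 0.7%), reproducing the published zero-event POLE row.
* **QC**: degraded (pre-2011-style) samples breach all four thresholds;
  clean samples sit well inside. Degradation affects QC metrics only, not
  variant calls, since the published rules act on metrics.
* **Determinism**: each sample draws from `default_rng([seed, index])`, so
  bundles are byte-identical for a fixed spec and seed.

The packaged 108-sample fixture plants 9 POLE-signature (6 pathogenic; of
the 3 signature-only, 2 MSI-H and 1 TP53-mutant), 51 further MSI-H (8 of
them QC-degraded), 15 cluster-4, 10 further TP53-mutant and 23 unremarkable
tumors, which the cascade rules necessarily map to 9/51/33/15 and
6/53/38/11.

What the generator does **not** emulate: trinucleotide-context signatures,
germline variation, subclonal allele fractions, read-level artifacts,
intra-tumor heterogeneity, correlated QC/variant degradation, and
non-proportional hazards. Recovery tests therefore validate the decision
rules and estimators, not robustness to real-data noise.

## Numerical and design choices

* Percentages round half-up to one decimal (printed-table convention).
* The SNV-count criterion counts SNVs only; whether the original counted
  indels is unknowable from the publication — the criterion's wording says
  SNV.
* The 25-gene list is re-derived at training time and frozen in the model
  JSON; gene→interval models are pluggable (BED) with a packaged synthetic
  default.
* MSI-indeterminate samples (no usable locus) are explicitly
  "unclassifiable" rather than silently dropped; per-sample pipeline
  failures are isolated and reported.
* The null baseline for the CN classifier is a cohort whose features carry
  no planted effect while labels keep the 26/74 balance — labels
  independent of features by construction. There Naïve Bayes defaults to
  the majority class (accuracy ≈ 0.74). Shuffling the labels of the
  *planted* cohort instead does not produce majority-rate accuracy: with
  many correlated informative features, label-permuted Naïve Bayes makes
  confident, effectively random cluster-level assignments (measured
  accuracy 0.35–0.61) — the known violation of the feature-independence
  assumption that the approach's own description concedes.
* Known count inconsistencies in the source tables (cohort totals 114 /
  108 / 101; a 13/59 rate printed as 22.7%) are resolved in favor of the
  one total (108) and the marginals (20/59, 13/59) consistent with every
  printed percentage.
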