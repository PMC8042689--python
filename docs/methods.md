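# Methods

This note documents the models and procedures implemented in
`splicetransfer`, the assumptions behind them, the parameters that
matter, and what the synthetic-cohort tests do and do not establish.

## Problem setting

Basal breast cancer **cell lines** split into two literature-annotated
subtypes: basal A (epithelial-like) and basal B (mesenchymal,
stem-like, drug-resistant). Basal-like / triple-negative breast cancer
**patients** carry no such annotation. The package transfers the
cell-line subtype labels into an unlabelled patient cohort using
alternative-splicing features, distils a minimal cassette-exon
signature, and tests whether the transferred groups differ in survival.

## PSI and the differential-splicing screen

For a cassette exon with inclusion-junction reads IC and
skipping-junction reads SC in one sample,

    PSI = IC / (IC + SC),   undefined when IC + SC = 0.

This is the standard junction-ratio estimator; the event-graph model of
the original quantifier is deliberately not re-implemented.

Event-level screens applied between two sample groups:

1. **Coverage filter** — pooled IC+SC ≥ 10 within *each* group
   (replicate-pooled reading; a stricter per-sample mode is available
   via `per_sample=True`).
2. **Kruskal–Wallis** on PSI (tie-corrected H, chi-square p). The
   alpha is a *required* argument — the published screens used raw
   thresholds between 1e-3 and 1e-9 depending on sample size, so no
   silent default is defensible. No multiple-testing correction by
   default (mirroring raw-p screening practice); Benjamini–Hochberg is
   available behind `bh_correct=True`.
3. **deltaPSI reliability** — deltaPSI = mean PSI(B) − mean PSI(A)
   (pairwise-complete over samples with coverage). The sign confidence
   is a Monte-Carlo posterior probability: each sample's PSI posterior
   is Beta(IC+1, SC+1) (uniform prior), joint draws are averaged within
   groups, and the probability is max(Pr(Δ>0), Pr(Δ<0)). An event is
   reliable when |deltaPSI| > 0.1 **and** probability ≥ 0.95 (defaults,
   both configurable). Default 10 000 draws; the seed is recorded in
   the run manifest.

## Iterative semi-supervised transfer (the core algorithm)

A random forest (1000 trees by default) is trained on labelled cell
lines; class probabilities are computed for every patient; patients
with probability of class B above 0.6 (or below 0.4) are candidates; at
most `10 × r` new patients are admitted at round `r`, highest
confidence first (ties broken by stable patient-id order); admitted
patients join the training set with their predicted label and are never
relabelled; the loop stops when no candidate clears a threshold.
Patients never admitted are *unclassified*.

Choices worth knowing:

* **Probability** is the forest's mean leaf probability
  (`predict_proba`); a per-tree vote fraction is available via
  `probability="vote"`. On the synthetic worlds the two are
  near-indistinguishable.
* **Thresholds** are the symmetric pair (0.6, 0.4); for mixed
  expression+splicing features the pipeline relaxes them to
  (0.55, 0.45) — only the upper value is documented for the reference
  analysis, symmetry is assumed here.
* **Feature modes**: `splicing` uses raw PSI (bounded and comparable
  across domains); `expression` uses log2(TPM+1) standardized per
  domain; `mixed` concatenates both, each standardized per domain.
  Per-domain standardization (mean 0, population sd 1, computed
  separately in cell lines and patients) removes the systematic
  culture-vs-tumour offset.
* **Missing PSI** is imputed by the training-set median of the feature,
  recomputed each round.
* **Cap reading**: `10 × r` bounds *new* admissions in round `r`; a
  cumulative-cap mode exists behind `cap_mode="cumulative"`.
* `max_rounds` defaults to 50 as a safety valve; runs on realistic
  inputs stop on their own after ~5–12 rounds.

## Boruta consensus signature

Boruta asks whether a feature's Gini importance beats the best of the
*shadow* features (per-column permutations) over repeated forest fits;
hit counts are tested against Binomial(k, 1/2) with a Bonferroni
correction over still-undecided features (alpha 0.05), giving
confirmed / rejected / tentative statuses. Because single runs are
seed-dependent, the selector repeats the run 10 times and keeps
features **confirmed in ≥ 7 runs** (tentative counts as not confirmed;
`count_tentative=True` relaxes this). Internal forests default to the
transfer classifier's 1000 trees, `max_iter=50`, shadow-percentile 100;
all logged in the run manifest. The default training set is cell lines
plus admitted patients with their assigned labels; a cells-only mode
exists.

A practical note from the power measurements in the test suite: the
max-shadow rule needs reasonably large forests — with ~100-feature
inputs, forests below ~100 trees make the shadow maximum so noisy that
genuinely informative features stop being confirmed.

## Validation and survival

* **Embedding check**: t-SNE (perplexity 20, PCA initialisation, fixed
  seed) on the signature events of a held-out cohort, followed by
  k-means (k=2, 10 restarts) and best-permutation matching against the
  true labels; accuracy is ≥ 0.5 by construction. The quantification
  rule behind the published "93 % segregation accuracy" is not stated
  anywhere; k-means-on-embedding is this package's documented choice,
  and `segregation_accuracy` also accepts raw feature matrices
  (nearest-centroid-like alternative in feature space).
* **Naive baselines**: hierarchical clustering (one-minus-Pearson,
  average linkage; constant rows dropped with a warning) and seeded
  k-means with k=2.
* **Survival**: Kaplan–Meier product-limit curves (5-year truncation
  affects *only* the plotted table, never estimation), two-group
  log-rank chi-square, and a univariate Cox proportional-hazards fit of
  the binary group indicator (Efron tie handling) reporting HR with the
  Wald 95 % CI. Unclassified patients are excluded from the A-like vs
  B-like contrast. Groups with zero events are flagged degenerate with
  an HR sentinel (0 or ∞) instead of raising. Tercile grouping splits
  at the linear-interpolation 1/3 and 2/3 quantiles, boundary ties
  going to the lower group; survival contrasts use high vs low only.

## Synthetic cohorts: what they emulate

The generator (`synthetic.generate_cohort`) draws, from one master seed
with independent substreams for PSI / counts / expression / survival:

* **Informative events**: subtype-A samples draw latent PSI from
  Beta(mean `psi_a`, concentration `c`), subtype-B from mean `psi_b`;
  non-informative events use mean `psi_background` for everyone.
* **Counts**: coverage n ~ Poisson(`depth_mean`), IC ~ Binomial(n, PSI),
  SC = n − IC. Poisson rather than negative-binomial coverage is a
  deliberate simplification: the analysis operates on PSI, so count
  overdispersion is secondary and PSI dispersion is carried by the Beta
  concentration.
* **Patient-domain shift**: PSI_patient = purity·PSI_subtype +
  (1−purity)·`psi_background`, purity ~ U(`purity_range`).
  *Unassignable* patients use purity ~ U[0, 0.2·hi]; they carry no
  latent subtype label (a hidden coin-flip subtype drives their small
  residual mixing), and their survival is drawn at the baseline hazard.
* **Expression**: log-normal TPM with a planted ±`log2fc_effect` on the
  DE genes in subtype B, attenuated by purity in patients.
* **Survival**: exponential event times at `baseline_hazard` (subtype
  A) and `baseline_hazard × hazard_ratio_true` (subtype B), independent
  uniform censoring on [0, `censor_horizon`].

Defaults: 12+12 cell lines, 120 patients (45 % latent B among
assignables, 13 % unassignable), 200 events with 30 informative at
|ΔΨ| = 0.4 (0.8 vs 0.4, background 0.6), concentration 30, depth 100,
purity 0.6–1.0, HR 4, baseline hazard 0.04 /year, 10-year censoring
horizon. Depth and PSI dispersion are not published quantities for the
real cohorts; these values are realistic for pooled junction counts in
bulk RNA-seq and are fully config-exposed.

What a green synthetic test does **not** establish: real tumours have
per-event background variation, correlated events, library-size and
mappability artefacts, annotation error, and non-proportional hazards —
none of which are simulated. The synthetic world validates the
machinery (filters, transfer dynamics, selection consistency,
statistical calibration), not biological effect sizes.

### A known emergent behaviour of self-training on this world

With a background PSI lying between the subtype means, low-purity
(unassignable) patients sit in the classifier's probability dead zone
(0.4–0.6) for as long as the training set is dominated by cell lines
and high-purity patients. Once *every* assignable patient has been
admitted, the forest retrained on patient-domain samples places split
thresholds inside the then-empty background region, and the remaining
low-purity patients are pushed out of the dead zone and absorbed in the
following rounds instead of remaining unclassified. Consequently the
unclassified rate on the default world is far lower than the share of
planted unassignable patients. This is a property of unbounded
self-training on a cleanly separable world, not of the implementation;
the corresponding acceptance test documents it by failing.

## Numerical conventions

* Z-scores use the sample sd (ddof = 1); constant rows map to zeros.
  Per-domain feature scaling uses the population sd (StandardScaler
  semantics).
* Wilcoxon rank-sum: exact permutation enumeration when min(n) ≤ 8
  (valid under ties), tie-corrected normal approximation otherwise.
* Fisher overlap tests are two-tailed (probability method); degenerate
  margins report p = 1 with an undefined odds ratio.
* BED export converts 1-based inclusive intervals to 0-based half-open;
  score = round(1000·|ΔΨ|) clipped to [0, 1000].
* All stochastic stages derive their seeds from the single global seed
  via `numpy.random.SeedSequence` substreams; re-running a manifest's
  configuration reproduces every table byte-identically.
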