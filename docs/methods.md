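# Methods

`glycoprog` reimplements, as a tested pipeline over synthetic cohorts, the
analysis chain that links plasma IgG N-glycome composition to colorectal
cancer (CRC) survival: peak-level quality control, derived glycan traits,
per-trait Cox proportional-hazards scans with FDR control, discrimination
metrics for clinical prognostic algorithms, glycan variable selection, and
the stage-stratified "rapid progressor" classification with a paired
with/without-glycans model comparison. This note records the models, the
defaults and why, the numerical choices, and what the synthetic data do and
do not establish.

## The measurement surface and derived traits

A HILIC-UPLC IgG glycome run is summarized as 24 integrated chromatogram
peaks (GP1–GP24). Because fluorescence units are arbitrary, every
chromatogram is closed by total-area normalization (each peak divided by
the row total, scaled to 100). All traits are therefore compositional:
invariant to per-sample scaling, and normalization is idempotent.

Peak-to-structure assignment is delegated to a single packaged table,
`data/peak_annotation.tsv`, holding per-peak galactose count (0–2), sialic
acid count (0–2), core-fucose and bisecting-GlcNAc flags. The packaged
table is a *synthetic convention* (the field's published assignments vary
by laboratory): it is internally coherent — biantennary IgG glycoforms with
a realistic abundance profile — and is overridable via
`PeakAnnotation.from_tsv`. The trait catalogue (61 traits: 24 measured peak
percentages, 14 neutral-fraction percentages GPkⁿ, 23 derived ratios) is
generated programmatically from the annotation, so no peak meaning is
hard-coded anywhere else. Derived traits follow the standard nomenclature:
G0ⁿ/G1ⁿ/G2ⁿ partition the neutral fraction by galactose count (they sum to
100 by construction), Fⁿ/FBⁿ split fucosylated neutral structures by
bisecting GlcNAc, and the sialylation ratios (e.g. FGS/(FG+FGS),
FBS1/FS1) compare sialylated with neutral counterparts of the same
backbone.

## Robustness QC

Each plate carries technical-standard wells: biologically identical
aliquots whose between-well variance is purely experimental. A trait's
robustness is

    robustness = 100 × Var(standard wells) / Var(cohort samples)

with unbiased variances, standards pooled across plates, computed on
normalized values (the standards pass through the same processing as
samples). Traits with robustness **strictly below 20%** are retained; the
boundary is excluded. With the generator defaults, 38 of 61 traits pass —
the same ≈½ retention the original assay reported.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

* **Clinical marginals** (n = 1229 default): age ~ N(59, 10²) truncated to
  [30, 90]; 43% female; AJCC stage drawn with probabilities
  (249, 421, 413, 146)/1229; 41% rectal site; BMI ~ N(26.6, 4.4²) with 14%
  missing completely at random; CRP log-normal with median 2 mg/l and
  10.6% above the 10 mg/l cut; operation-to-blood-draw interval log-normal
  with median 5.4 months; operation type categorical (70/20/10%).
* **Glycan composition** is logistic-normal: per-sample log-abundances =
  log reference profile + biological noise (SD `peak_concentration` = 0.18
  per log-peak) + a latent per-patient score times a pro-inflammatory axis
  (+agalactosylated, −digalactosylated, −sialylated peaks; scale 0.08) +
  plate shifts + well noise, closed to 100. Logistic-normal (not
  Dirichlet) because plate effects and biology then act additively on
  log-ratios, exactly the multiplicative noise the robustness statistic
  assumes. Technical noise per peak scales as technical_sd × (1 +
  0.5/√abundance), emulating worse integration error on small peaks — this
  is what gives traits a *spread* of robustness values so the 20% filter
  has work to do. The reference profile doubles as the plate-standard
  composition; standards receive only technical noise.
* **Survival** is Weibull proportional hazards (shape 1.2, scale 30 y)
  with planted log-HRs: stages 2–4 vs 1 at ln 1.35 / ln 2.65 / ln 14.32,
  age ln 1.03 per year, CRP>10 ln 1.96, BMI ln 1.04 per unit, latent glycan
  score ln 1.35 per SD. Patients accrue uniformly over a 7-year window and
  are administratively censored 14 years after study start, so follow-up
  caps fall in [7, 14] years; death cause is a stage-dependent Bernoulli
  label on observed deaths (CRC fractions 0.41/0.66/0.85/0.96) — a label
  model, not competing hazards, matching how registry cause-of-death is
  used. Defaults yield ≈48% deaths and ≈8-year median follow-up.
* **Plate layout**: 96-well plates, 3 standards each. The real plate count
  and layout are unpublished; these are assumptions recorded in config.

Two trait-level designs bypass the compositional layer when the question
is statistical rather than glycomic: `simulate_trait_scan` (iid
standard-normal traits, one planted at a chosen log-HR, correctly
specified stage+trait hazard) for recovery/FDR studies, and
`simulate_progression_cohort` (stage-4-like: high event rate, 5 observed
traits loading 0.75–0.4 on a latent score that multiplies the hazard by
e¹ per SD in the signal condition) for the comparison protocol. In the
glycan-null condition the latent signature does not exist and the traits
are idiosyncratic noise — the factor structure *is* the disease-linked
signature, so a null cohort has none.

## Cox engine and association scans

The engine maximizes the Efron-tie partial likelihood by Newton–Raphson
with step halving; convergence at max|score| < 1e-9 or relative
log-likelihood change < 1e-12; a coefficient passing |β| > 20 raises a
separation error naming the covariate; constant covariates and zero-event
data are rejected up front. Efron ties are the default because registry
follow-up times are tied in practice. The baseline cumulative hazard is
Breslow's step function; 5-year risks are 1 − exp(−H₀(t)·exp(xβ)).
Wald CIs and p-values are reported (matching HR-and-CI presentation);
the engine is cross-checked in the tests against lifelines (to 1e-5) and
against brute-force likelihood maximization on tiny data (to 1e-7).

Model specifications: I = trait only; II = trait + age, sex, stage;
III = II + BMI, operation-to-sample interval, operation type, CRP>10.
Outcomes: all-cause, and CRC-specific with non-CRC deaths right-censored
at death. Strata: whole sample, excluding stage 4, or a single stage
(stage dummies are dropped within a stratum). Each fit is complete-case
with dropped-row counts logged. Traits enter rank-normalized by default
(Blom offsets, (r − 3/8)/(n + ¼), average ranks on ties), so hazard ratios
are per SD. Benjamini–Hochberg q-values are computed within one
(outcome × model × stratum) scan family — the natural family for a
per-column presentation; failed fits are excluded from the family with
their reason recorded.

Diagnostics: proportional hazards are screened by correlating scaled
Schoenfeld residuals with event-time rank (Grambsch–Therneau-style);
linearity by a likelihood-ratio test of quartile-categorical vs linear
coding. Both are calibrated in the tests (null rejection ≈ 5%, power
against a sign-flipping effect).

## Discrimination metrics

Harrell's C uses the standard usable-pair definition under right
censoring with risk ties counting ½ (so C(risk) + C(−risk) = 1). The
time-dependent cumulative/dynamic AUC at horizon t estimates
P(risk_i > risk_j | T_i ≤ t < T_j). Censoring is handled by
inverse-probability-of-censoring weights from the Kaplan–Meier estimate
of the censoring distribution — chosen over the survival-function
recursion estimator of the same functional because it reduces *exactly*
to the Mann–Whitney AUC without censoring (the property the test oracles
pin down) and agrees with scikit-survival's estimator to machine
precision in the cross-check. Discrimination slope = mean predicted
5-year risk in events minus non-events; IDI = difference of slopes, with
patients censored event-free before the horizon excluded and counted.
The 5-year horizon is a configurable default.

## Variable selection

Bootstrap importance refits a gradient-boosted Cox model of depth-1 stumps
on resamples of cohort size, normalizes per-fit relative influence to 100,
and averages. The stopping iteration is chosen once by inner-fold
validation deviance of the staged predictor (learning rate 0.05, cap 400
by default — softened from a slower 0.01/2000 schedule to keep desk-scale
studies tractable; both are exposed as arguments). Forward selection walks
the ranking once, adding a trait when twice the log-likelihood gain
clears the χ²₁ critical value at α = 0.05, stopping after one failure by
default. The L1 comparison fits Cox models penalising glycan terms only
(clinical unpenalised; lifelines vector penalizer), picks the penalty on
inner folds by validation partial-likelihood deviance, and compares outer-
fold deviances of clinical vs glyco-clinical families with a paired
t-interval. Rank-normalizing monotone-related traits produces exactly
collinear columns; duplicates (|r| > 0.999) are pruned with a log note
before the penalised fit.

## Rapid progressors and the comparison protocol

Within a stage, the cutoff is the 33.33rd percentile (linear, type-7
interpolation) of CRC-death times; rapid = died of CRC with time ≤ cutoff;
everyone else in the stage is not-rapid. Stages with fewer than 3 CRC
deaths are skipped with an explicit reason (the stage-1 situation).
Five-year CRC-death labels treat other-cause deaths as negatives and
exclude patients censored event-free before 5 years (exclusion, not
imputation — the least-assumption option, counts logged).

The classifier zoo holds one configuration per model class: L1-logistic,
k-nearest-neighbours, nearest shrunken centroids, linear SVM (polynomial
variants optional), kernel-density naive Bayes, a decision tree, and
boosted stumps — scikit-learn implementations behind a uniform
fit/decision-scores contract, except the KDE naive Bayes (per-feature
Gaussian KDEs per class), which has no installed implementation and is
native. Evaluation is repeated stratified k-fold CV (default 10×10-fold;
3×10-fold in the desk-scale studies): per run, validation predictions are
pooled and scored as one merged AUC; runs are averaged. Standardization
and any filtering are fit on training folds only; a leakage test verifies
that scoring the pooled predictions against shuffled labels collapses the
AUC to chance.

The with/without-glycans comparison pairs each configuration's merged AUC
on clinical features with the same configuration on clinical + glycans and
applies the two-sided Wilcoxon signed-rank test (exact for ≤ 25 tie-free
pairs, zeros dropped, normal approximation under ties; all-zero
differences report p = 1 with a warning). W uses all configurations; Wd
first collapses to one per model class (dropping the extra SVM kernels).
Two-sided is the default because the direction of any glycan effect is
not assumed; a flag exposes one-sided alternatives.

**Calibration of the protocol.** Paired AUC differences across
configurations are not independent — every configuration sees the same
cohort, so chance association between an uninformative glycan block and
the labels moves all models together and makes the signed-rank test
anticonservative. This dependence is intrinsic to the design (the original
analysis acknowledges it); what keeps the protocol honest is limiting each
model's ability to exploit chance structure. The default zoo is therefore
strongly regularized (L1-logistic C = 0.05, SVM C = 0.03, k = 60
neighbours, centroid shrinkage 1.8, depth-1 tree, 8 boosted stumps) —
sized for ~150-patient stage strata. Under the glycan-null condition the
protocol then rejects at ≈ 2–5% (measured 2/150 at the defaults), while
under the stage-4-like signal it rejects in ≈ 90% of replicates with a
median merged-AUC gain of ≈ 0.18. Under-regularized zoos were measured at
25–35% null rejection with cross-configuration difference correlations of
≈ 0.33; regularization drives that correlation to ≈ 0.1.

## Numerical and engineering choices

* All tables are tab-delimited UTF-8, "." decimals, empty cells for
  missing; floats print with 17 significant digits and are parsed in
  round-trip mode, so write→read is exact and pipeline reruns are
  byte-identical (verified end-to-end).
* Every stochastic stage draws from named integer seeds; nothing uses
  global random state. Identical seeds reproduce cohorts bit-for-bit.
* The pipeline manifest accounts for every row at every exclusion
  (input = analysed + excluded), so complete-case ns are auditable.
* Desk-scale study sizes: oracle studies use 100 tiny datasets / 200
  enumeration draws; recovery and FDR studies 100 replicates at n = 1229;
  comparison calibration 100 replicates of n = 150 at 3×10-fold. These are
  the package's chosen standard scales for its validation studies.

## What the synthetic results do and do not show

Passing studies establish that the *machinery* is correct and calibrated:
the engine matches brute-force likelihood maximization, planted hazard
ratios are recovered with nominal CI coverage, BH controls false
discoveries, and the comparison protocol has controlled type-I error with
good power against a strong planted signature. They do not validate the
biological claims: the generator's glycome is a single-axis caricature of
real IgG covariance, plate effects are Gaussian on log-ratios, cause of
death is a clean label, and no real chromatograms, batch drifts, or
registry artefacts are modelled. Results on real cohorts depend on those
features; the pipeline's contracts (auditable annotation, train-fold-only
preprocessing, explicit exclusion accounting) are designed so a real
re-analysis would exercise identical code paths.

## Known limitations

* The Wald-based scan can be anticonservative for very large effects with
  few events (stage-4 coverage sits near 0.92–0.95, the lower half of the
  nominal band).
* The boosted-importance bootstrap shares one stopping iteration across
  resamples; per-resample stopping would be slower and noisier.
* The exact Wilcoxon falls back to a normal approximation when tied
  |differences| make full enumeration intractable.
* PH diagnostics use the residual–time-rank correlation screen, not the
  full score-process test; it is a screen, not an estimator of
  time-varying effects.
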