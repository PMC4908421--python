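# glycoprog

Prognostic modelling of colorectal cancer (CRC) survival from the plasma
IgG N-glycome — a tested, end-to-end pipeline from raw chromatogram peak
areas to survival models, exercised on a synthetic cohort generator with
known ground truth.

Protein glycosylation shifts with inflammation: decreased IgG
galactosylation and sialylation and increased bisecting GlcNAc make IgG
more pro-inflammatory, and these shifts have been linked to worse cancer
outcomes. This package implements the full analysis chain a glycomics
survival study needs, for biostatisticians and glycomics groups who want
each step reproducible and testable:

1. **Glycomics** — total-area normalization of 24 UPLC peaks (GP1–GP24),
   61 measured + derived traits (G0ⁿ/G1ⁿ/G2ⁿ, Fⁿ, FBⁿ, FGS/(FG+FGS), …)
   from an auditable peak-annotation table, robustness QC
   (100·Var(standards)/Var(cohort), strict < 20% filter), Blom rank-normal
   transform.
2. **Survival** — a native Cox proportional-hazards engine (Efron ties,
   Newton–Raphson, Breslow baseline), per-trait association scans under
   Models I/II/III for all-cause and CRC-specific mortality, with
   Benjamini–Hochberg q-values, PH and linearity diagnostics, and 5-year
   risk prediction.
3. **Discrimination** — Harrell's C, time-dependent cumulative/dynamic
   AUC (IPCW), discrimination slopes and the IDI.
4. **Selection** — bootstrap boosted-Cox-stump importance ranking, forward
   likelihood-ratio selection, and L1-penalised Cox with cross-validated
   deviance comparison of clinical vs glyco-clinical models.
5. **Progression** — stage-stratified "rapid progressor" labels (lower
   tertile of CRC-death times per stage), a 7-class classifier zoo under
   repeated stratified CV, and the paired Wilcoxon signed-rank comparison
   of models with vs without glycans (p_W, p_Wd, median AUC gain).
6. **Synthetic cohorts** — a logistic-normal compositional glycome with
   plate structure and technical standards, realistic clinical marginals,
   and Weibull proportional-hazards outcomes with planted stage and glycan
   effects, so every downstream stage is testable without patient data.

The core survival model is Cox proportional hazards,
h(t|x) = h₀(t)·exp(xᵀβ), fit by maximizing the Efron partial likelihood;
per-trait hazard ratios are reported per rank-normal SD with Wald 95% CIs
and BH-adjusted q-values.

## Worked example

```sh
python analysis/01_simulate_cohort.py
python analysis/02_glycomics_qc.py
python analysis/03_association_scan.py
python analysis/04_discrimination.py
```

which prints (abridged):

```
cohort: 1229 patients on 14 plates (42 standard wells)
deaths: 587 all-cause, 453 CRC; median follow-up 8.0 y
38 of 61 traits below the 20% robustness threshold
derived-trait means: G0n=38.5, G1n=43.8, G2n=17.7, Fn=80.7, FBn=16.3
456 fits; 99 trait-model associations with q<0.05
top whole-sample Model II (all-cause) traits:
             trait    hr  ci_low  ci_high        p        q
FBGS/(FB+FBG+FBGS) 0.829   0.763    0.901  9.4e-06 0.000357
              GP19 0.853   0.785    0.927  0.00017  0.00227
               G2n 0.857    0.79    0.929  0.00018  0.00227
all-cause mortality, clinical Model III (n=1081, events=513):
  C=0.70, AUC(5y)=0.74, IDI vs Model II=0.015
crc-cause mortality, clinical Model III (n=1081, events=392):
  C=0.75, AUC(5y)=0.79, IDI vs Model II=0.013
```

Read: 38 of 61 glycan traits survive technical QC; the generator's planted
pro-inflammatory axis surfaces as protective hazard ratios (< 1) for
digalactosylated (G2ⁿ) and sialylated (FBGS/(FB+FBG+FBGS)) traits at
q < 0.01; and the clinical algorithm's discrimination (C ≈ 0.70–0.75,
AUC(5y) ≈ 0.74–0.79) sits in the range typical of staged CRC cohorts.
`analysis/05_selection.py` and `analysis/06_progression_comparison.py`
continue the chain (glycan panel selection; per-stage with/without-glycans
comparison, including the stage-1 skip for too few events). The same
pipeline runs from the `glycoprog` CLI (`simulate`, `qc`, `scan`, `all`, …)
on any conforming peak/clinical tables.

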