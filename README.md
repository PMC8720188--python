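# neoconn

Resting-state functional connectomics for neonatal fMRI: a tested, reusable
implementation of the analysis pipeline used to ask whether a brief auditory
experience (music listening) leaves a measurable trace in a newborn's
subsequent resting-state functional connectivity, and whether prior exposure
"dose" predicts the size of that trace.

The package is aimed at researchers analysing paired pre/post resting-state
runs in small cohorts (neonatal or otherwise) who need the full path from
regional BOLD time series to group inference — and at methodologists who want
the statistical machinery exercised against a fully synthetic cohort with
known ground truth, since infant MRI data of this kind are typically not
shareable.

## What it computes

Given two runs per subject (before/after a stimulus) in three groups — e.g.
full-term controls (FT), preterm controls (PC), and a preterm music-exposed
group (PM):

1. **Frame censoring** — volumes with framewise displacement > 0.5 mm or
   DVARS > 3% are scrubbed together with 1 preceding and 2 following volumes;
   subjects keeping < 50% of volumes are excluded.
2. **Signal cleaning** — joint nuisance regression + linear detrending,
   optional gray-matter-masked regional averaging, and a zero-phase
   Butterworth band-pass (0.01–0.1 Hz).
3. **Accordance connectomes** — for regions *i*, *j* with positive/negative
   excursion indicators `u_i(t) = 1{x_i(t) > Q_0.842}` and
   `d_i(t) = 1{x_i(t) < Q_0.158}`,

   `accordance(i,j) = (⟨u_i,u_j⟩ + ⟨d_i,d_j⟩) / (‖e_i‖‖e_j‖)`, `e_i = [u_i; d_i]`,

   a 90 × 90 symmetric coupling matrix per subject per run.
4. **Paired edge contrasts** — per group, one-sided paired t-tests (run 2 >
   run 1) over the 4005 upper-triangle edges with paired Cohen's *d*; the
   PM-vs-PC contrast fuses the per-edge z-scores as
   `z_diff = (z_PM − z_PC)/√2` (standard normal per edge under the joint
   null) and reports edges with `z_diff ≥ 2.58` (p = .005).
5. **PLSC dose–response** — per PM subject, the delta nodal strength vector
   (run-2 minus run-1 row sums of the connectome) enters a partial least
   squares correlation against the exposure dose: SVD of the z-scored
   cross-covariance `R = YᵀX/(n−1) = USVᵀ`, with permutation significance
   (5000 permutations), bootstrap salience stability (200 resamples, 5th–95th
   percentile intervals), and leave-one-out cross-validated latent scores.

A synthetic cohort generator (`neoconn.simulate`) emulates the study design —
16/15/15 subjects, 2 × 300 volumes at TR 1.6 s, 90 atlas regions, motion
spikes, planted run-2 coupling increases, and a dose covariate with a
controlled generating correlation — so every stage is testable end to end
with known ground truth.

## Worked example

```python
from neoconn import CohortSpec, PipelineConfig, run_pipeline

config = PipelineConfig(
    cohort=CohortSpec(dose_effect_nodes=((40, 44, 73, 85, 86), (17, 30, 60, 62, 76))),
    seed=3,
    out_dir="demo_out",
)
manifest = run_pipeline(config)
```

This simulates the full three-group cohort with a dose effect planted on five
positive and five negative regions, runs every stage, and writes TSV tables
plus `manifest.json` into `demo_out/`. The summary printed from the manifest:

```
subjects: 46  excluded: 0  volumes censored: 3670  edges tested: 4005
fused PM>PC edges at z>=2.58: 25
PLSC: S=2.960  p_perm=0.0266  robust regions=22  LOOCV r_brain=0.77  r_outcome=1.00
```

Reading these numbers: ~13% of volumes were scrubbed (the level the emulated
acquisition reports); the fused contrast flags 25 of 4005 edges at the 2.58
threshold (expected ≈ 20 by chance at p = .005 — the planted effects here are
dose-linked, not uniform, so the fused map is near its null); and the PLSC
component relating dose to delta nodal strength is significant by permutation
(p = .027), with 22 regions showing bootstrap-stable saliences. The LOOCV
brain-score correlation (0.77) measures salience stability; the outcome-score
correlation is ≈ 1 by construction with a single outcome (see
`docs/methods.md`). Exact numbers vary with the seed — at this sample size
(n = 15) and effect size, the permutation test detects the planted dose
effect in roughly half of the cohorts.

The same run from a shell:

```bash
neoconn all --seed 3 --out demo_out          # full pipeline
neoconn simulate --seed 3 --out sim_out      # cohort TSVs only
neoconn plsc --seed 3 --n-perm 5000 --n-boot 200 --out demo_out
```

## Acceptance script

`scripts/acceptance.py` re-runs the complete pipeline from scratch on a
seeded synthetic cohort — generation, censoring, cleaning, connectomes, edge
contrasts, fusion, and PLSC with full resampling — and writes its results
JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Stage outputs land next to the results file under `pipeline_run/`.

## Layout

- `neoconn.preprocess` — censoring, DVARS/FD, GM masking, cleaning, band-pass
- `neoconn.connectome` — accordance/discordance, nodal strength,
  `AccordanceConnectivity` (scikit-learn transformer)
- `neoconn.contrast` — paired edge tests, p→z, z-fusion, significant edges
- `neoconn.plsc` — `PLSCorrelation` estimator, LOOCV scores
- `neoconn.simulate` — synthetic cohort generator + ground-truth report
- `neoconn.pipeline` / `neoconn.cli` — orchestration, tables, CLI
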