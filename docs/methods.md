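# Methods

This note documents the models, conventions, and numerical choices behind
`neoconn`, and what the synthetic cohort does and does not establish.

## Frame censoring

A volume is censored when its framewise displacement (FD) exceeds 0.5 mm or
its DVARS exceeds 3%, together with the 1 preceding and 2 following volumes;
windows from multiple triggers union and clip at run boundaries. A subject is
excluded when fewer than 50% of a run's volumes survive. Conventions:

- **FD** follows the Power formulation: sum of absolute backward differences
  of the six rigid-body parameters, rotations converted to arc length on a
  50 mm sphere. The first volume's FD is 0.
- **DVARS** is the spatial standard deviation of each successive difference
  frame, expressed as a percent of the run-mean within-mask intensity (the
  "3%" criterion needs a baseline; run-mean intensity is ours). Element 0
  is 0.
- Censored volumes are **dropped** and the retained series concatenated — no
  interpolation. Band-pass filtering is applied to the concatenated series, a
  known simplification: concatenation joins non-adjacent time points, so
  filter output near seams mixes across gaps. With the default ~10–15% frame
  loss this has negligible effect on accordance (which thresholds amplitudes
  rather than tracking phase), but heavy censoring would make it visible.
- Censoring is idempotent: every exceedance is removed, so re-censoring the
  retained trace removes nothing.

## Signal cleaning

Nuisance regression (any per-volume regressors: CSF/WM means, motion
parameters, FD/DVARS) and linear detrending are performed **jointly** in one
least-squares design (intercept + linear trend + regressors) to avoid order
ambiguity, after censoring. When voxel-level input is supplied, voxels are
residualized first and then averaged within gray-matter-retained atlas
labels; a label with no surviving voxels becomes a missing (NaN) series with
a logged warning. GM masking keeps a voxel iff P(GM) ≥ P(WM) and
P(GM) ≥ P(CSF) — ties retain the voxel, since removal requires a strict
deficit.

The band-pass filter is a zero-phase order-4 Butterworth (applied
forward–backward), pass band 0.01–0.1 Hz. The design is not pinned by the
emulated study; Butterworth + `filtfilt` is the standard choice. Pass-band
gain is within 5% of unity and stop-band attenuation below 1% in amplitude at
0.2 Hz; a second pass only re-attenuates the soft shoulders (RMS change
< 20%), which is the precise sense in which filtering is "nearly
idempotent".

## Accordance connectome

Each regional series is reduced to positive/negative excursion indicators
against its own within-run quantiles (defaults 0.842 / 0.158, the Gaussian
±1 SD equivalents; configurable). Accordance counts same-sign co-excursions,
normalized by the product of the concatenated indicator norms, so identical
series score 1 and the diagonal is exactly 1; discordance counts
opposite-sign co-excursions. Consequences worth knowing:

- accordance is invariant under strictly increasing affine transforms of any
  single region's series (quantiles move with the data);
- `0 ≤ accordance + discordance ≤ 1` pairwise (Cauchy–Schwarz);
- quantiles are computed on the retained (censored) volumes only;
- a constant regional series has no excursions and is rejected with the
  region named.

Nodal strength is the off-diagonal row sum of the connectome; delta nodal
strength is run 2 minus run 1, positive meaning stronger coupling after the
stimulus.

## Edge-wise contrast and z-fusion

Per group, each upper-triangle edge gets a one-sided paired t-test for
run 2 > run 1 and a paired Cohen's d (mean of differences over the
ddof-1 SD of differences — the d variant is stated because reporting
conventions vary). Zero-variance edges are flagged degenerate and excluded
rather than assigned an arbitrary p, keeping the downstream fusion well
defined. No multiplicity correction is applied — a deliberate choice for
small-sample exploratory contrasts, with raw p plus effect size reported and
a p < .001 default reporting filter.

One-sided p-values map to z-scores via the normal quantile (p = .005 ↦
z ≈ 2.576, the 2.58 reporting threshold). The PM−PC fused score divides the
raw z difference by √2 because the difference of independent standard
normals has variance 2; the fused map is standard normal per edge under the
joint null, verified by KS calibration on null cohorts.

## PLSC

With X the n × 90 delta-nodal-strength matrix and Y the n × 1 dose, both
z-scored across subjects, the cross-covariance `R = YᵀX/(n−1)` is the vector
of dose–region Pearson correlations. Its SVD has exactly one component, with
closed form `V = Rᵀ/‖R‖`, `S = ‖R‖` — the correctness anchor tested to
1e-10 against per-region correlation oracles. The 1/(n−1) scaling is a
convention; any positive rescaling of R leaves saliences and p-values
unchanged (tested).

**Sign convention.** The outcome salience is fixed to U = +1, which
identifies the component exactly and makes each brain salience carry the
sign of its region's dose association (positive salience = more exposure,
larger connectivity increase). Every refit — permutation, bootstrap, LOOCV
fold — shares the convention, so refitted saliences are directly comparable
without a posteriori sign alignment. (The common alternative, flipping so
the largest-magnitude brain salience is positive, makes the global sign
data-dependent: whichever of the positive or negative sub-pattern happens to
dominate dictates the orientation, and "positive nodes get positive
saliences" can fail by construction.)

**Permutation test** (default 5000): outcome rows are permuted, the permuted
singular value forms the null, and `p = (1 + #{S_perm ≥ S_obs})/(1 + n_perm)`
— the +1 smoothing avoids p = 0 and keeps the test valid.

**Bootstrap stability** (default 200): subjects are resampled with
replacement, each resample re-standardized and refit; resamples with a
zero-variance column are redrawn (warned when redraws exceed 10%). A
salience is *robust* when its 5th–95th percentile interval excludes zero
(default), or when |bootstrap mean / bootstrap SD| > 2 with
`robust="ratio"`. Caveat: a 5th–95th interval is a 90% interval, so even at
perfect coverage ~10% of truly null regions will be flagged, and percentile
intervals undercover at n = 15 (measured null flag rate ≈ 15%). Where strict
false-positive control over regions matters, use the ratio rule with a
threshold of 2–3.

**LOOCV**: each fold learns standardization and saliences on n−1 subjects
and projects the held-out subject. With a single outcome the cross-validated
*outcome* score is essentially a re-standardized copy of the full-model
score, so its full-vs-CV correlation is ≈ 1 regardless of signal — only the
*brain*-score correlation is informative, measuring the stability of V
across folds (≈ 1 for a noiseless dose–brain relation, mean ≈ 0.35 and
highly variable under the null, not 0: fold saliences share n−2 subjects and
are mutually correlated even without signal).

## Synthetic cohort

The generator restates the emulated study design as its defaults: groups
FT/PC/PM with 16/15/15 subjects, two 300-volume runs at TR 1.6 s, 90
regions, dose drawn as round(clip(N(25, 8.92), 7, 35)) sessions.

- **Signal model**: stationary Gaussian AR(1), lag coefficient 0.3, with a
  unit-diagonal stationary covariance carrying mild contiguous block
  correlation (blocks of 15, r = 0.1) as a stand-in for network structure.
  Signals sit on a baseline of 1000 with 1% fluctuation SD — the scale is
  irrelevant to accordance (affine invariance) and only sets the baseline
  DVARS level (~1.2%).
- **Planted effects**: run 2 is sampled from the baseline covariance plus
  per-edge coupling increments; a non-positive-definite plant is rejected
  with a diagnostic. Group-level planted edges are uniform across a group's
  subjects.
- **Dose effects**: the designated positive and negative node sets each form
  a clique whose increment for subject k is `base·(1 ± slope·t_k)` (clipped
  to [0, 0.85]), where `t_k = r·z_dose + √(1−r²)·η` has generating
  correlation r (default 0.9) with the standardized dose. The true nodal
  delta is the row sum of planted increments, so corr(dose, true delta) is
  controlled by construction.
- **Motion**: baseline FD |N(0.1, 0.08)| capped below threshold; spikes
  (per-volume probability 0.03, reproducing the ~10–15% frame loss the
  emulated acquisition reports) set FD above 0.5 mm and add a spatially
  heterogeneous intensity jump at the same volume, so DVARS — computed from
  the synthetic signals with the same estimator the pipeline uses — exceeds
  3% at the spike and the following difference frame. FD and DVARS criteria
  are thereby exercised jointly and separably.

**Calibrated effect sizes.** The emulated study reports no generative effect
sizes, so detectable magnitudes were calibrated empirically once and frozen:
a coupling increment of 0.5 at n = 15 subjects puts planted edges at the top
of the |t| ranking; dose-effect defaults base = 0.4, slope = 0.8. Measured
delta nodal strength is an attenuated readout of the planted truth — summing
a 90-region connectome row accumulates accordance estimation noise from all
89 edges (null between-subject SD ≈ 1.1 strength units at 300 volumes), so a
generating dose correlation of 0.9 yields measured per-node correlations of
roughly 0.4–0.6 and ~50% permutation power at n = 15 through the full
pipeline. Recovery at r = 0.9 *measured* is therefore a design-level
statement (columns built directly at that correlation), and the full-chain
tests assert direction and ranking, not the uncollapsed effect size.

**What a green test does not establish**: the generator has no hemodynamic
forward model, physiological noise, scanner drift/artifacts, or realistic
spatial covariance; passing tests certify the statistical machinery, not
performance on real infant BOLD data.

## Determinism

A run is fully determined by its configuration plus one seed: the cohort
RNG, permutation and bootstrap streams all derive from it, and TSV outputs
are written with a fixed float format, so identical configs produce
byte-identical outputs (tested end to end).

## Known limitations

- Voxel-level support is deliberately minimal (label averaging over
  GM-masked atlas voxels); registration, realignment and slice timing are
  upstream concerns for other tools.
- Filtering concatenated censored series (see above).
- The fused contrast assumes independent groups; it is not applicable to
  within-group comparisons.
- Single-outcome PLSC only; multi-outcome designs would need Procrustes
  alignment across components and are out of scope.
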