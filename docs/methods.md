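# Methods

This note documents the models and procedures implemented in `neohrv`, the
parameter choices that matter, and what the synthetic-data experiments do
and do not establish.

## Problem and outcome

Newborns with suspected hypoxic-ischaemic encephalopathy are monitored with
single-lead ECG synchronised to EEG in the first hours of life. The EEG
background grade, dichotomised into normal-mild (0) versus moderate-severe
(1), is the prediction target. The predictors are HRV features from the
earliest 1-hour ECG epoch recorded before 12 h of age, and clinical
variables knowable within ~6 h of birth (foetal distress, gestational age,
delivery mode collapsed to emergency vs non-emergency, sex, birth weight,
Apgar scores, assisted ventilation at 10 min, optionally cord pH, lactate
and base deficit).

## Preprocessing

R-peaks are detected on the Hilbert envelope of the 5–30 Hz band-passed
ECG, with a 200 ms refractory period and an adaptive amplitude threshold
(0.4 × the 90th percentile of candidate peak heights). The envelope is used
instead of the rectified signal because a single noise sample cannot cancel
an envelope peak; spurious detections are tolerated at this stage because
the artifact rules remove the implausible intervals they create. Peaks
within 250 ms of the record edges are discarded (filter transients).

Artifact screening replaces the original study's manual beat editing with
two configurable automated rules: an absolute range gate (interval outside
200–1200 ms) and a relative gate (deviation from the centred 11-beat
running median greater than 30% of that median). Flagged beats are excluded
from analysis, not interpolated; the evenly resampled tachogram used for
spectral analysis simply interpolates across the gaps.

The epoch is tiled into 300-s segments every 150 s (50% overlap). A
segment is dropped when flagged beats cover more than 50% of its span;
artifact fraction is measured in covered *time*, not beat count, so a
missed-beat artifact (one long interval) weighs appropriately. The
`removed_fraction` of an epoch is the flagged share of its total time.
Epoch selection takes the earliest contiguous window of the requested
duration ending before the age cut-off; an optional minimum-usable-fraction
requirement shifts the start to the first admissible window.

## HRV features

Eleven features per segment, summarised across retained segments by the
median (the LF/HF ratio is the median of per-segment ratios, not a ratio of
medians):

* **Mean NN, SDNN** — mean and sample SD (ddof = 1) of the unflagged
  (normal-to-normal) intervals, ms. "NN" is the standard artifact-excluded
  meaning; no amplitude normalisation is applied.
* **TINN** — the NN histogram uses 7.8125 ms (1/128 s) bins aligned to
  multiples of the bin width; a triangle with apex pinned at the modal bin
  (modal height) is fitted by exhaustive least squares over all (left base,
  right base) bin-edge pairs; TINN is the base width, ms. Bin width and the
  exhaustive grid are configurable choices, not dictated by the study.
* **Band powers** — the NN series is cubic-spline interpolated at 4 Hz,
  mean-subtracted, and a Welch PSD is computed (Hann, 120-s windows, 50%
  overlap). Powers are trapezoidal integrals of the PSD over VLF
  0.01–0.04 Hz, LF 0.04–0.2 Hz, HF 0.2–2 Hz. These neonatal bands are the
  default because newborn respiratory rates reach ~2 Hz; the adult preset
  (LF 0.04–0.15, HF 0.15–0.4 Hz) is exposed as `SpectralBands.task_force()`.
  The HF band is allowed to extend exactly to the Nyquist frequency of the
  resampled tachogram. Welch on the resampled series is itself a design
  choice; the estimator tag is recorded in the configuration.
* **Multiscale entropy** — SampEn with m = 2, tolerance r = 0.15 × the
  sample SD of the scale-1 series, held fixed across scales (standard MSE
  convention; per-scale r is available behind a flag). Coarse-graining is a
  moving-average filter of width equal to the scale (1–20) without
  decimation; a decimating variant exists for sensitivity analysis. Matches
  use the ≤ r Chebyshev convention with self-matches excluded and N − m
  templates at both lengths; entropies are in nats. When no templates match
  (A or B = 0) the value is undefined (NaN) and any summary needing that
  scale is marked missing. Summaries: complexity index (trapezoidal area
  over scales 1–20), maximum, and least-squares slopes over scales 1–5 and
  6–20.

## Statistical pipeline

Positively skewed features (SDNN, VLF, LF, HF, LF/HF, TINN) are
log10-transformed; all HRV features are then z-scored on the analysis
cohort, and the fitted recipe (transform tag, mean, SD per feature) is a
first-class object reusable on new data. Binary covariates are coded 0/1
and never standardized; birth weight enters per 100 g and pH per 0.01 unit.

Univariable logistic regressions produce per-variable odds ratios (per 1 SD
for standardized features), Wald 95% CIs, p-values and model AUROCs.
Variables with p < 0.25 are eligible; among eligible pairs with |Pearson
r| > 0.8 only the higher-AUROC variable is kept (greedy, decreasing AUROC).
Both thresholds are configurable. Multivariable models (HRV terms only,
clinical terms only, and their union) are maximum-likelihood logistic fits
(Newton-Raphson, tolerance 1e-8, at most 100 iterations, via statsmodels)
on the complete-case subset for the union of screened terms, so the three
models are compared on identical subjects; the complete-case count is
reported. Quasi-complete separation triggers a warning and a quasi-Newton
fallback whose drifting estimates are returned as-is. If nothing survives
the screen, an intercept-only model is used.

Evaluation: AUROC is the Mann-Whitney statistic with ties counted 1/2; the
95% CI uses the DeLong placement-value variance (Hanley-McNeil available).
The operating point maximises Youden's index over observed score values
with predicted-positive defined as score ≥ cutoff; ties on the index break
toward the higher-specificity (larger) cutoff. Calibration uses the
Hosmer-Lemeshow statistic over deciles of risk with df = g − 2; a
user-requested g < 3 is a configuration error, while data-driven group
collapse (tied probabilities) merges groups with a warning and yields an
undefined p-value when fewer than three groups survive. Subgroup re-runs
(cooled infants only; no anti-seizure medication before the epoch) are
configuration flags over the same code path, and add the blood-gas
covariates to the candidate list.

Transcribed published models store the printed coefficients exactly as
printed (two decimals); every derived quantity, including their odds
ratios, inherits that rounding. Their HRV terms expect standardized inputs
— the z-scoring recipe must come from the user's cohort since the original
cohort's means and SDs are unpublished — and clinical terms take raw
encodings (gestational age in weeks, Apgar-5 as an integer, flags 0/1).
Whether gestational age entered the original equations as completed or
decimal weeks is not stated; the applicator accepts either.

## Synthetic cohort generator

Each subject's interbeat series is a direct interval model: mean NN plus an
LF sinusoid (0.1 Hz), an HF sinusoid (0.7 Hz), and AR(1) noise, clipped to
200–2000 ms; beats are generated sequentially so oscillations are evaluated
at true beat times. A direct interval model was preferred to
integral-pulse-frequency modulation as it is sufficient to realise the
band-power and entropy contrasts the analysis consumes. Artifacts replace
chosen beats with halved (ectopic) or doubled (missed) intervals and are
recorded in a ground-truth mask, enabling recall/false-positive measurement
of the artifact rules.

Group defaults encode the clinical contrasts: the severe group has longer
mean NN (590 vs 525 ms), lower LF/HF balance, narrower histogram and lower
multiscale-entropy complexity. The complexity contrast required care: the
mild profile uses a large, long-memory noise component (SD 24 ms, lag-1
autocorrelation 0.94) giving high scale-1 entropy that decays slowly under
smoothing, while the severe profile is dominated by its regular
oscillations with a small white noise term (SD 1.7 ms) that is both
predictable at the beat scale (low entropy maximum) and quickly removed by
coarse-graining (steeper short-scale slope). Varying only the noise
SD/autocorrelation cannot produce the full direction set: whiter noise
raises scale-1 entropy (wrong maximum direction) while smoother noise
flattens the short-scale slope (wrong slope direction), so the oscillation
amplitudes participate in the contrast as well.

Between-subject heterogeneity makes the cohort overlap like a clinical
population: each subject draws its own mean NN (SD 60/70 ms around the
group mean) and independent lognormal multipliers (sigma 0.35) on the LF
and HF amplitudes, with half that sigma on the noise SD because the entropy
features respond very steeply to the noise-to-tolerance ratio. Clinical
covariates are sampled independently within group — medians/IQRs and
proportions are matched to the published cohort table by moment-matched
normals, rounded-clipped normals (Apgar) and Bernoulli draws — with
missing-completely-at-random gaps at the published missingness rates.
Published medians/IQRs underdetermine the true distributions, so these are
approximations, not calibrated fits.

**What passing tests show** — that every pipeline stage is correct against
closed-form or brute-force oracles, that the estimators are calibrated
(type-I error, parameter recovery), and that the full chain recovers
injected group structure in the documented directions. **What they do not
show** — predictive performance on real neonates: the generator omits
nonstationarity within the hour, respiration-gated and state-dependent
dynamics, covariate correlations (sampled independently), informative
missingness, and any realistic ECG morphology; with the default contrast
the in-sample HRV model separates the synthetic groups essentially
perfectly, which no real cohort would.

## Numerical choices and degenerate inputs

Entropy tie-breaking uses ≤ r consistently in the fast kernel, the numpy
fallback and the test oracles, so agreement is exact in floating point. A
constant series has r = 0 and is assigned entropy 0 (every template
matches). The logistic screen saturates exp() rather than overflowing when
a separated fit produces huge coefficients. Youden and AUROC handle tied
scores via midranks/threshold scanning. Deciles-of-risk edges come from
probability quantiles; duplicate edges collapse groups as described above.
All randomness flows through `numpy.random.Generator` seeded from
user-supplied integers; cohort generation spawns independent child streams
per subject, so cohorts are bit-reproducible for a given seed.

## Problem sizes used in the checks

The direction and model-comparison checks run on 100 subjects per group
with 1-hour epochs (the generator's default study conditions); estimator
calibration uses 100–200 simulation replicates (n = 600–5000 each); the
entropy oracle comparison uses 500 random series of length ≤ 200; the
iid-Gaussian entropy limit uses 20 series of n = 5000. The null
(no-contrast) screen calibration uses 120 simulated cohorts of 20 subjects
per group with 10-minute epochs, with Bonferroni-adjusted binomial bounds
across the 11 features.

## Known limitations

* The artifact rules are a stand-in for the original manual review; their
  thresholds are exposed in configuration and validated only against the
  generator's artifact model.
* EDF ingestion is a thin optional reader (via `mne`); WFDB-style records
  are not supported — plain numeric series and two-column RR text tables
  are the primary inputs.
* Apparent (in-sample) performance only, mirroring the modelling design it
  reimplements; no cross-validation or optimism correction.
* Whether the original in-house MSE implementation decimated after the
  moving average, and whether entropies were reported in nats, are not
  documented; this package assumes no decimation and nats, with the
  decimating variant behind a flag.
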