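# Methods

This note documents the models, conventions and numerical choices of the
package. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## Study design being modelled

A paired-session design: each subject is recorded twice (T0 before, T1
after a sensory-training intervention). A session is Baseline (180 s),
Task (400 s: 10 odor stimuli of 10 s at a 30 s inter-stimulus interval,
the pause after the last stimulus counted as task time), and Recovery
(180 s). Signals are single-lead ECG at 500 Hz (mV) and skin conductance
at 51.2 Hz (µS). All analysis windows are half-open `[start, end)` seconds
from record start; baseline and recovery features are computed over the
whole phase, task features per stimulus window and then averaged over the
stimuli that yielded a value (the contribution count is retained).

## Synthetic cohort generator

The generator is first-class, tested code: it defines the conditions under
which every recovery claim is made.

**RR series.** Beat-to-beat intervals are `RR_k = m + s(t_k) + ε_k` with
`m = 60/HR`, `ε_k ~ N(0, σ²)` i.i.d. per beat, and `s(t)` the sum of two
independent band-limited Gaussian processes (FFT-masked white noise,
rescaled) confined to 0.04–0.15 Hz and 0.15–0.40 Hz with prescribed
variances (s²). This partitions RR variance exactly the way the cardiac
features do: white noise sets the RMSSD floor (population RMSSD = σ√2),
the band processes set LF and HF. Intervals are clipped to
[max(0.25, 0.3·m), 3.0] s; beat times span `[0, duration]`.

**ECG.** A stylised biphasic R-dominant template (80 ms support, 1 mV
peak, two small negative lobes) is evaluated continuously at each beat
time and summed onto the sample grid, plus white noise (default
0.05 mV). True beat times are retained in `record.meta` for detector
scoring. Realism beyond detectability (full PQRST morphology, respiration,
motion artifacts) is deliberately out of scope, so detector scores on this
synthetic ECG bound performance on clean chest-strap data, not on
ambulatory recordings.

**Skin conductance.** `g(t) = tonic(t) + Σ aᵢ·B(t−tᵢ) + noise`, where `B`
is the same unit-peak Bateman kernel the decomposition uses (so a lone
event's true phasic maximum equals its amplitude). The tonic curve is the
per-phase level with 20 s linear ramps at phase boundaries plus Gaussian
drift smoothed on a 60 s timescale and mean-centred — the ≥ 60 s time
constant keeps the tonic/phasic separation well-posed by construction.
Event amplitudes are log-normal (nonnegative by construction); stimulus-
locked events onset 1–3 s after each stimulus (electrodermal latency),
plus a sparse Poisson background (1.5/min) of spontaneous responses.

**Cohort.** Default n = 11 subjects, matching the scale of the cohort the
package emulates, so the statistical-power behaviour of the paired tests
is comparable. Per-phase T0 parameter means are the published cohort
summaries (HR 75.8/80.5/76.5 bpm; RMSSD via σ = RMSSD/√2 from
0.036/0.027/0.027 s; tonic 1.792/2.819/2.941 µS); between-subject
dispersions use the published SDs where available and conservative values
where the cohort summary does not identify the between/within split (the
published SD conflates both; this is documented, not resolved). T1
parameters are T0 plus additive effect deltas matching the published
direction and magnitude of change (HR and tonic conductance down,
successive-difference scale and HF power up, LF power slightly down),
jittered ±20 % per subject so the effect is consistent in sign but not
identical across subjects. LF/HF and CSI decreases are emergent, not
injected: raising short-term (vagal) variability relative to LF modulation
lowers both ratios. A fixed seed gives byte-identical written cohorts.

## Cardiac chain

**QRS detection** is a Pan–Tompkins-style chain: 2nd-order Butterworth
5–15 Hz band-pass (zero-phase), derivative, squaring, 150 ms
moving-window integration, candidate peaks at ≥ 200 ms spacing, adaptive
dual thresholds (signal/noise level estimates updated at 0.125 per event),
final R refinement as the raw-signal maximum within ±150 ms. Flat
(peak-to-peak < 1 µV), saturated (> 20 % of samples at a rail) or < 10 s
records raise an unusable-record error, mirroring quality-based subject
exclusion.

**RR correction** flags intervals deviating > 20 % (configurable) from
the median of the 11 surrounding intervals: near-multiples of the local
median are split into equal parts (missed beats), short intervals whose
merge with their successor fits the median are merged (spurious beats),
the rest are replaced by the local median. Beat times are rebuilt from the
corrected intervals. If more than 20 % of intervals need repair the series
is declared unreliable. Repaired intervals count toward HR but are
excluded from difference statistics (RMSSD, NN50) and the Poincaré cloud,
so interpolation cannot manufacture variability.

**Conventions.**
- NN50 uses strict inequality (> 50 ms); a 1e-12 s epsilon keeps binary
  float representations of an exact 50 ms tie from counting.
- Standard deviations in SD1/SD2 are population (divide by N).
- SD1/SD2 are the centred standard deviations of the cloud projected on
  the lines perpendicular/parallel to the identity, i.e. of
  `(RRᵢ₊₁ ∓ RRᵢ)/√2`. Under this convention SD1² + SD2² equals
  var(RR[:-1]) + var(RR[1:]) exactly (the cloud-ensemble form of
  2·var(RR)), and SD1 = RMSSD/√2 exactly whenever the successive
  differences sum to zero (equal first and last intervals); for long
  series both identities hold to O(1/n) against the naive whole-series
  variance. Dispersions below 1e-12 of the mean interval are reported as
  exactly zero, and CSI/CVI are NaN (undefined), never ±∞, when either
  dispersion vanishes.
- CVI = log₁₀(SD1·SD2) with SD1·SD2 in s² (matching negative tabulated
  values near −2.8); the classical millisecond convention (+6) is
  available via `units="ms"`.
- LF/HF is always the ratio of raw band powers (s²). Raw LF/HF powers and
  their log₁₀ are both reported because published HRV tables are often
  log-scaled without saying so (negative printed "power" values cannot be
  raw); comparison tables use raw powers.

**Spectra.** Default (windows ≥ 60 s): tachogram values stamped at each
interval's closing beat, cubic-spline resampled at 4 Hz (linear below
8 beats), linearly detrended, Welch PSD (hann, 64 s segments, 50 %
overlap), band powers by trapezoidal integration. Stimulus windows (10 s):
Lomb–Scargle periodogram on the uneven beat pairs over 0.01–0.5 Hz,
normalised so total power equals tachogram variance; a 10 s window cannot
resolve 0.04 Hz content, which is logged — the per-stimulus LF estimate is
indicative only, and a `spectral_mode="phase"` option estimates task
spectra once over the whole 400 s task instead (recommended when LF
matters).

## Electrodermal chain

First-order Butterworth low-pass at 5 Hz, applied forward–backward (zero
phase, unit DC gain). Decomposition models the filtered record as
`g = tonic + B ∗ driver` with driver ≥ 0 and
`B(t) = e^(−t/τd) − e^(−t/τr)` normalised to unit peak
(peak at `ln(τd/τr)·τrτd/(τd−τr)`); defaults τr = 0.75 s, τd = 2.0 s, the
classical continuous-decomposition defaults, both configurable.

The solve alternates (≤ 10 rounds): (1) nonnegative least squares for the
driver against the banded convolution operator on a 10 Hz grid
(deconvolution needs far less bandwidth than the 51.2 Hz record; the grid
rate is configurable), solved by accelerated projected gradient (FISTA,
sparse matvecs, Lipschitz constant by power iteration, ≤ 400 inner
iterations); (2) a cubic-spline tonic update through support points every
10 s — initialised at the local 10th percentile (phasic activity only adds
conductance, so the lower envelope tracks the tonic), refined as local
means of `g − phasic`. Convergence is declared when the reconstruction
residual RMS changes by < 2 % between rounds; un-regularized NNLS keeps
creeping at the noise floor, so a much tighter criterion would never fire
— non-convergence is flagged on the result, never raised.

The reported `phasic` is defined as `global − tonic`, making the additive
identity exact by construction; `phasic_model = B ∗ driver` and
`residual = phasic − phasic_model` report how much of the fast component
the driver model explains. Window summaries (Global/Tonic/Phasic) are time
averages; the "Phasic" table entry is a mean level, not a sum of discrete
response amplitudes — the alternative reading of tabulated phasic values
exists in the literature, and this interpretation is fixed here
deliberately. Stimulus windows for conductance are extended by 4 s
(default, configurable) to absorb the 1–3 s electrodermal latency; ECG
stimulus windows are not extended.

## Statistics

Long-form feature table (subject, session, phase, feature, value), at most
one value per cell; subjects enter a comparison only with complete pairs.
Shapiro–Wilk normality is computed and recorded but does not switch tests:
the pipeline uses the paired two-sided Wilcoxon signed-rank throughout
(small non-normal cohorts), with zero differences dropped (Wilcoxon's
original policy, logged), the exact null for n ≤ 25 (tie-corrected normal
approximation otherwise), and ≥ 5 informative pairs required. Kendall τ-b
handles ties. Means ± SD use the sample (N−1) convention. Markers:
\* p < 0.05, \*\* p < 0.01; no multiple-testing correction by default, for
fidelity to common practice in these cohorts (a Benjamini–Hochberg option
would be a one-line addition to `compare_sessions` but is deliberately
absent from the default path). Odor-identification scoring counts
position-wise case-insensitive matches against the 10 descriptors, with a
configurable synonym map; unknown descriptors are flagged and counted
incorrect.

## Problem sizes used in the automated checks

Chosen as the package's own test design:

- HR recovery: 10 seeds × 180 s ECG at 500 Hz; RMSSD: 20 seeds × 180 s RR;
  tonic: 10 seeds × 180 s conductance at 51.2 Hz with 3 sparse responses.
- Type-I calibration: 200 zero-effect cohort replicates of n = 11, feature
  extraction run on simulated RR series directly (ECG waveform synthesis
  and QRS detection add only sub-millisecond beat-time jitter, which is
  irrelevant to the size of the paired test), 24 cardiac feature × phase
  cells per replicate.
- Directional recovery: one full-raw-signal cohort (n = 11, full 760 s
  sessions, both signals, all stages) with the default effect deltas.
- Detector scoring: 5 seeds × 120 s ECG at SNR 10 dB with ~2 % of beats
  dropped or ectopically inserted in the generative sequence.

## Known limitations

- The ECG template is not a physiological PQRST complex; detector scores
  here do not transfer to arrhythmic or motion-corrupted recordings.
- The RR model is stationary within a phase with an instantaneous
  parameter switch between phases (bridged only by beat continuity).
- Between-subject dispersion of the generative parameters cannot be
  separated from within-subject variability using published summary
  tables alone; the defaults treat the published SDs as between-subject
  spread, which overstates heterogeneity and makes the power checks
  conservative.
- The tonic spline can absorb slow phasic energy when responses overlap
  densely (inter-event spacing approaching the 10 s support spacing);
  the two-event resolution test bounds this at 5 s spacing but denser
  trains are untested.
- Kendall correlation is exposed and tested against pair enumeration but
  no cohort-level correlation analysis is wired into the comparison
  tables, since the emulated analysis reports none numerically.
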