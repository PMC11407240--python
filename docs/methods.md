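# Methods

This note records the scientific model behind each stage, the parameters
that matter, the design choices made where the design was genuinely open,
and what the synthetic-data tests do and do not demonstrate.

## Signal model

A recording is a per-channel, per-wavelength intensity series I(c, λ, t)
at a uniform rate (5 Hz by default). Under the modified Beer–Lambert law
the optical-density change ΔOD = −ln(I/Ī) relates linearly to
concentration changes of oxy- and deoxy-haemoglobin:

    ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR] · d · DPF

with source–detector distance d = 3 cm, differential pathlength factor
DPF = 6 at both wavelengths, and the shipped molar extinction
coefficients (Prahl compilation, cm⁻¹/M): 760 nm — HbO 586.0,
HbR 1548.52; 850 nm — HbO 1058.0, HbR 691.32. The absolute concentration
scale cancels in every downstream t-statistic, so the choice of table
affects nothing but units; the synthetic generator uses the same table,
making forward/inverse round trips exact.

## Channel quality (SCI / PSP)

Both wavelengths of a well-coupled channel share the cardiac pulsation.
Per non-overlapping 5 s window, both segments are mean-removed,
band-passed to the cardiac band 0.5–2.5 Hz (3rd-order Butterworth,
zero-phase; the upper edge is clamped to 0.98 × Nyquist, relevant at the
5 Hz default rate) and amplitude-normalised. SCI is their Pearson
correlation. PSP is the peak of the Hamming periodogram ('spectrum'
scaling, ×2) of the per-lag-unbiased normalised cross-correlation
restricted to |lag| ≤ n/2 — normalised so a perfectly shared sinusoid
scores ≈ 1. A window fails when SCI < 0.6 **and** PSP < 0.1; a channel
is excluded when more than 50% of its windows fail; a participant is
excluded when every channel is. Undefined windows (constant segments)
count as failing. Trailing partial windows are ignored. The PSP
normalisation is this package's own (the reference tool's exact scaling
is unpublished); the 0.1 threshold is validated behaviourally: shared
cardiac sinusoids score near 1, independent noise stays below 0.1 in
well over 90% of windows. Manual visual exclusion is replaced by an
explicit per-channel exclusion list.

## Preprocessing

* **Optical density** uses the natural logarithm relative to the
  per-series mean; it is invariant to detector gain.
* **Wavelet motion correction** (Daubechies-2, periodised): per
  decomposition level, detail coefficients deviating from the level
  median by more than 1.5 × IQR are zeroed. The decomposition depth is
  capped so every thresholded detail band lies above ~0.125 Hz: evoked
  responses are sparse and smooth, so at deeper levels their
  coefficients are precisely the outliers the rule would delete, which
  would remove the haemodynamic response itself. Fast artifacts
  (spikes; the sharp edges of baseline steps) live in the thresholded
  bands and are suppressed; slow content is left to the band-pass.
* **Band-pass** 0.01–0.3 Hz, 5th-order Butterworth, applied
  forward–backward (zero phase) — event-onset timing is central, so
  zero lag is required. The 0.01 Hz high-pass rings for on the order of
  a hundred seconds; this matters twice below.
* **MBLL inversion** per channel by the 2×2 extinction solve.

All stages are channel-local, length-preserving and (except the wavelet
thresholding) linear; the full chain is deterministic.

## CBSI and down-sampling

CBSI assumes the evoked response moves HbO and HbR in opposite
directions while motion and systemic physiology move them together:
α = σ(HbO)/σ(HbR) over the full preprocessed recording,
activation x = (HbO − α·HbR)/2, corrected HbR = −x/α (anti-correlated
with x by construction). x is reduced to 1 Hz by non-overlapping 1 s
block means (an anti-alias box filter; parameter-free, mean-preserving
over whole seconds).

## Event detection

The detector models the 1 Hz activation signal as a sum of events, each
a unit boxcar on [onset, onset+duration) convolved with the canonical
double-gamma HRF (peak delay 6 s, undershoot delay 16 s, dispersions 1,
peak:undershoot 6, 32 s kernel, peak-normalised; the gamma shape is
delay/dispersion with scale = dispersion, so the mode sits at
delay − dispersion). Durations run 1–230 s on a 1 s grid; each cell's fit
is ordinary least squares with an intercept, summarised by t = β/SE(β)
on n−2 degrees of freedom (perfect fits report a 10⁶ sentinel). The
exhaustive grid is computed incrementally (one cross-correlation with
the kernel plus cumulative sums); tests pin its equality with naive
per-cell OLS to 1e-8.

Extracting *multiple* events per channel from a signal with coloured
noise required four design commitments, each forced by a measurable
failure mode and each testable on synthetic ground truth:

1. **Band-matched template.** The activation signal has passed the
   0.01–0.3 Hz band-pass, so the template must too: each event's
   high-pass ringing spreads ±200 s beyond its boxcar, and a clean-HRF
   template detects that ringing as spurious long events. The kernel is
   pre-convolved with the 1 s acquisition-rate boxcar, band-passed at
   the acquisition rate, and block-averaged to 1 Hz, so duration-d
   templates are exactly the pipeline's response to a d-second boxcar.
   The non-causal pre-ring is handled by zero-padding the signal by the
   template pad (250 s), after which grid onsets equal true onsets.
2. **Robust score standardisation.** Plain OLS t-values are wildly
   anti-conservative under autocorrelated noise. Selection instead uses
   a locally centred matched-filter numerator (a local intercept makes
   the score blind to broad structure elsewhere in the signal) divided
   by a robust per-duration scale: a low quantile (0.3) of |num| across
   onsets, which recovers the noise scale even when a large fraction of
   cells carries event energy. The scale profile across durations is
   heavily median-smoothed relative to the centred template norm, so
   neighbouring (highly collinear) durations are compared as an exactly
   normalised matched filter.
3. **Joint refitting (orthogonal matching pursuit).** One-at-a-time
   subtraction systematically under-fits when several events coexist
   (the z-scored regressor's negative baseline couples their unexplained
   mass), stalling at ~30% amplitude recovery. After every selection the
   amplitudes of all selected events are refitted jointly by least
   squares, so the residual driving the next step is the joint-model
   residual.
4. **Refine and prune.** Each event is re-localised (±15 s onset, ±60 s
   duration) against the residual of the others, with events kept
   non-overlapping; acceptance then requires both the calibrated refit
   score and the OLS refit t to exceed the critical value, and a second
   collection round recovers sub-events freed when merged detections
   shrink. The critical value is the two-sided t quantile at α = 0.05
   Bonferroni-corrected for the number of grid cells — family-wise
   control over the exhaustive search (a per-fit threshold would admit
   hundreds of spurious events per channel, since the null maximum over
   ~10⁵ correlated cells sits near 5σ).

Onsets within 100 s of the recording ends are not searched (the
band-pass start/end transients there are data artifacts, not signal);
the un-banded code path uses a 30 s margin. Greedy collection stops when
the residual drops below 2% of the input energy — below any realistic
noise share, above the template-mismatch floor — which keeps the
noise-free regime from fitting its own discretisation error. Ties break
to the earliest onset, then the shortest duration; identical inputs give
identical event lists. Window-search parameters are retained for
compatibility but the search is global (whether the original tooling
windowed its search is not recoverable; a global search is deterministic
and strictly more thorough). Only positive-going fits are events. The
230 s bound applies to the boxcar, not boxcar+HRF tail.

## Summary parameters and group statistics

Events are assigned to the condition interval containing their onset
(half-open [start, end)); onsets in gaps go to the nearest interval,
ties to the earlier one. Per participant × channel × condition cell with
at least one event: event count, mean duration, mean t, max t, each also
divided by the participant's cell duration in seconds. Cells without
events are missing data, not zeros — this is what produces the varying
degrees of freedom across channels in the paired tests. The "average
number of events" parameter is a per-participant count; its average is
taken at group level.

Paired t-tests (t = mean(d)/(sd(d)/√n), df = n−1, two-sided) compare
Fragranced vs Unfragranced per channel for each of the six condition
contrasts and each of the eight parameters; two-sided tests are used
because effects in both directions are scientifically interpretable.
Normality of the paired differences is screened by a one-sample KS test
against a normal law with sample-estimated moments (flagged, not used to
switch tests — the screen is conservative in this form). FDR is
Benjamini–Hochberg within the narrowest defensible family, the channels
of one parameter × one contrast; the family is configurable.
Brain–questionnaire Pearson correlations pair the dynamic stages with
the static detergent forms (wash↔liquid, dry+hang↔wet, fold↔dry),
pooling the two conditions (configurable), requiring n ≥ 3 complete
pairs and non-zero variance.

## Synthetic data generator

The generator inverts the analysis chain: evoked responses and
physiology are laid down in concentration space, mapped through the
forward Beer–Lambert model to OD where instrumental noise and motion
artifacts are added, then exponentiated to intensities. One seeded
generator drives every draw, so a spec + seed pins the dataset
bit-exactly. Defaults are the package's study conditions; none is
derived from any measurement:

* **Protocol.** 16 participants, 20 channels (a two-row 8-source /
  7-detector prefrontal band, 30 mm separations), 5 Hz. Two dynamic
  passes (wash 180–360 s, dry+hang 300–600 s, fold 180–360 s; condition
  order counterbalanced by participant parity), six static smelling
  trials of 30–60 s in shuffled order, 10–30 s transitions, 150 s
  baseline at both ends (so that no protocol event falls inside the
  filter-transient exclusion zones).
* **Events.** Poisson counts per channel-cell (1.5 dynamic / 0.8 static),
  durations 15–60 s, placed non-overlapping with ≥ 15 s gaps
  (overlapping same-channel events are unidentifiable, so the ground
  truth is constructed identifiable). ΔHbO plateau amplitude
  1.2 ± 0.25 µM (clipped ≥ 0.4), ΔHbR = −ΔHbO/3, scaled by a
  per-participant latent factor (1 ± 0.1) that also drives the
  fragranced intensity ratings. A planted condition effect multiplies
  rate (×m) and amplitude (×√m) in chosen channels of one condition.
* **Physiology.** Cardiac (0.9–1.3 Hz, 0.2 µM), respiratory (0.2–0.3 Hz,
  0.05 µM) and Mayer (≈0.1 Hz, 0.05 µM) sinusoids, shared phase per
  participant with per-channel gain; HbR carries +1/3 of the HbO
  amplitude — the proportional common mode CBSI is designed to cancel.
* **OD-level noise.** White noise σ = 5·10⁻⁴, linear drift
  σ_total = 2·10⁻³ over the recording, spikes (0.2/min, 0.01–0.05 OD,
  1–3 samples) and baseline shifts (0.05/min, σ = 0.01 OD) shared
  across wavelengths with jittered gain. A configurable fraction (10%)
  of channels is emitted as pure uncorrelated noise — no shared cardiac —
  for the quality screen to find; bad channels carry no events.
* **Questionnaire.** Attribute means per condition (fragranced clearly
  liked/intense, unfragranced near-neutral/weak) plus unit noise,
  rounded and clipped to the 9- and 5-point scales.

What the generator does **not** emulate: real optode-coupling dynamics,
heteroscedastic or bursty motion, heart-rate variability, non-stationary
Mayer amplitude, scalp-vs-cortex partial volume, or any anatomical
structure across channels. Passing tests therefore demonstrate the
pipeline's internal correctness and its behaviour under a plausible,
CBSI-conformal noise model — not performance on any particular real
dataset.

## Verified performance (recomputed by the test suite and
`scripts/acceptance.py` at run time)

* Noise-free forward/inverse consistency: a planted event recovered
  within ±2 s onset and ±20% duration through the entire chain (the
  artifact-removal stage configured as a no-op on artifact-free data).
* Default-noise recovery on a 4-participant study: sensitivity ≥ 80% at
  ±5 s onset tolerance with ≤ 0.2 false positives per channel-cell,
  scored over quality-included channels.
* Pure-noise calibration: essentially zero spurious events per 600 s
  white-noise channel (50 seeded runs).
* A ×2 Unfragranced event-rate/amplitude effect in one channel is
  recovered with the correct sign by the end-to-end paired test in
  ≥ 8/10 seeded replicates (5 participants × 4 channels per replicate —
  problem sizes chosen to keep the full suite re-runnable in minutes).

## Known limitations

* The detector's calibration is empirical (per-signal); its family-wise
  error control is approximate under strong non-stationarity.
* Closely spaced events (< ~15 s gap) can merge; durations of short
  events (< 15 s) are recovered less accurately than onsets.
* Fits assume the canonical HRF; systematic HRF-shape deviations bias
  amplitudes and, mildly, durations.
* The wavelet stage's depth cap trades spike/shift suppression against
  protecting the haemodynamic band; large slow motion survives to the
  band-pass and appears as low-amplitude bumps.
* SNIRF support covers the minimal continuous-wave subset (intensity,
  2-D probe geometry, stimulus blocks) only.
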