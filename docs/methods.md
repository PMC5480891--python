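# Methods

`geciquant` quantifies somatic calcium signals recorded by two-photon
imaging of neurons expressing a genetically encoded calcium indicator
(GECI), with parameter defaults describing a red indicator of the
R-GECO/R-CaMP family expressed transgenically in neocortical layer-2/3
pyramidal neurons.  This note documents the models, the estimator
conventions, the synthetic-data generator, and the numerical choices, in
enough detail to know what a passing test does and does not establish.

## ΔF/F convention

Raw per-ROI fluorescence is the mean over the ROI's pixels minus a
per-frame background estimate (mean of a user-supplied background ROI;
fallback: the 1st percentile of each frame).  The normalized signal is

    ΔF/F = (F − F0) / F0,   F0 = bottom 8th percentile of the trace,

with the linear-interpolation percentile definition.  Using a *low*
percentile as F0 is deliberate — it makes F0 insensitive to activity —
but it has a measurable side effect under noise: for a trace with
per-frame noise SD σ (in ΔF/F units), the 8th percentile of pure noise
sits ≈ 1.4σ below the noise mean, so the ΔF/F of the quiescent baseline
is ≈ +1.4σ rather than 0, and every amplitude measured from ΔF/F = 0
carries that offset.  This is a property of the convention, not a bug;
analyses that need offset-free amplitudes (e.g. the ground-truth
recovery checks) subtract the trace median first.  All ΔF/F values are
fractions internally and percentages in reports.

## Spontaneous-event detection

A calcium transient is a maximal run of frames exceeding

    threshold = median(ΔF/F) + 3 · SD(ΔF/F),

with the SD taken over the full trace, events included (a
median-absolute-deviation variant is available via
`AnalysisConfig(robust_sd=True)`).  Runs separated by less than one
decay-fit window (1.1 s) are merged so one transient is not counted
twice.  Event onset is the first supra-threshold frame; the peak is the
run's argmax.

False-positive floor.  On pure Gaussian noise the per-frame exceedance
probability of median + 3 SD is Φ(−3) ≈ 1.35 × 10⁻³, so the detector
*necessarily* produces ≈ 1.3 spurious events per 1000 frames (the
13-frame merge window removes only ≈ 2% of them).  Downstream logic
must not treat "has ≥ 1 event" as proof of calcium signalling on long
traces; see the puncta classifier below.  A detector with a true
1/1000-frame floor would need a 3.09-SD threshold.

## Peak amplitude and its sampling loss

Peak amplitude is the 3-point average around the maximum (truncated at
trace edges).  At the native 12-Hz frame rate this estimator reads a
single-AP transient ≈ 40% below its true peak: the kernel peaks ≈ 76 ms
after the AP, so the three averaged frames typically straddle the rise
(near zero), the peak, and one decayed sample.  The loss shrinks
quickly with frame rate (≈ 4% at 30 Hz, ≈ 2% at 60 Hz).  Tests that
check quantitative amplitude recovery therefore sample at 30–60 Hz,
where the estimator is in its validity regime; a dedicated test pins
the 12-Hz loss itself.  Reported in-vivo-style amplitudes at 12 Hz are
estimator readings, exactly as an experimenter would obtain them.

## Decay kinetics

τ comes from a least-squares fit of `A·exp(−t/τ)` over the 1.1-s window
after the peak (≥ 4 frames required; otherwise τ is NaN, never an
exception).  Initialisation is the closed-form log-linear fit, which the
iterative fit reproduces to 10⁻⁶ on noiseless data.  The default model
has no additive offset; `AnalysisConfig(decay_offset=True)` fits
`A·exp(−t/τ) + C`, which is the right choice whenever the percentile
baseline offset (≈ +1.4σ, above) is non-negligible relative to the
amplitude — the offset-free fit then biases τ upward because the tail
cannot reach zero.  Pooled τ summaries use the median and IQR over fits
with r² ≥ 0.5: when a second transient intrudes into the fit window the
fit can return arbitrarily large τ, and a mean would be dominated by
those.

## Spike-triggered (evoked) analysis

APs recorded simultaneously with imaging are grouped into bursts by a
chaining rule: consecutive APs whose interval is ≤ 300 ms belong to one
burst (a fixed-window-from-first-AP variant is selectable; the two
coincide for the short bursts that occur in practice).  For each burst,
the evoked transient's peak is the 3-point-average maximum within
(first AP, first AP + 1.1 s]; its SNR is that peak divided by the SD of
the unfiltered ΔF/F over the 1-s window before the first AP.  Bursts
without a complete pre/post window, or whose baseline would overlap the
previous burst's 1.1-s response window, are excluded with a logged
reason; analyzed + excluded bursts always account for every burst.

The saturating ceiling ΔF/F_max is probed from a driven plateau (the
in-experiment analogue is a strong current injection) as the 99th
percentile of ΔF/F over the marked drive window.  With a hyperbolic
response this probe is a lower bound on the true ceiling — the drive
never reaches full saturation — and it is documented as such.

## Detection-efficiency calibration

The null SNR distribution is built from spike-free stretches of the
ΔF/F traces, tiled into non-overlapping 1-s segments.  Each segment is
split in half: the first half supplies the SD (noise estimate), the
second half the peak (3-point average around its argmax), so numerator
and denominator are independent.  The threshold is set from a Gaussian
fit (sample mean, sample SD) to the null SNRs at the (1 − FPR) quantile,
`μ + z₀.₉₅·σ` for the default 5% target; an empirical-percentile variant
is selectable.

Calibration accuracy.  The null statistic is a max-over-frames divided
by an independent SD estimate and is therefore right-skewed; a Gaussian
fitted by moments undercovers its upper tail.  Measured at 4 × 10⁵
segments, the empirical false-positive rate of the Gaussian-fit
threshold is ≈ 5.3% against the 5% target, while the
empirical-percentile variant achieves 5.0% by construction.  The
package reports what the procedure actually delivers; nothing is
re-tuned to force 5.0%.

Detection efficiency per AP count is the fraction of evoked transients
whose SNR exceeds the threshold, reported with exact counts and
nearest-integer percentages.

## Longitudinal stability statistics

Sessions are keyed by mouse, session id and days post-induction (DPI).
Event rates (events/min) are computed over active ROIs (≥ 1 detected
transient); active fractions over all ROIs.  Drift in pooled amplitudes
or τ across sessions is tested with a two-factor fixed-effects ANOVA:
sequential (Type-I) sums of squares for mouse then session, a common
residual, and degrees of freedom (m−1), (s−1), N−1−(m−1)−(s−1) — with
2 mice and 4 sessions this yields the F(1, N−5)/F(3, N−5) pattern
familiar from such designs.  On balanced data the decomposition is
exact (SS_total = SS_mouse + SS_session + SS_residual, verified to
10⁻⁹ relative); unbalanced designs are analyzed with a warning, Type-I
SS in fixed factor order.  Matched-cell amplitude distributions across
sessions are compared with a two-sided Wilcoxon rank-sum test, exact by
enumeration for combined n ≤ 20 (midranks for ties) and via the
tie-corrected, continuity-corrected normal approximation otherwise.

## Two-channel unmixing and puncta classification

Observed red/green channels are modelled as a 2×2 nonsingular,
non-negative mixing of an indicator source and a static
(autofluorescent, lipofuscin-like) puncta source.  The matrix is
estimated from one pure-indicator and one pure-puncta reference ROI as
column-normalized mean channel intensities; reference spectra closer
than 5° are rejected as unresolvable.  Unmixing is a per-pixel solve;
negative solutions are clipped to zero and counted (with an empty
source, noise scatter alone clips ≈ half of that source's values —
the count is diagnostic, not alarming per se).

A candidate ROI is classified from its ΔF/F dynamics:

- **functional (confident)** — carries ≥ 1 *significant* event, i.e. a
  detected transient whose peak clears the trace median by 4 robust
  (MAD-based) SDs; the noise probability of that is 3 × 10⁻⁵/frame.
- **functional (low confidence)** — no significant event, but either
  more weak events than the 1.35/1000-frame false-positive floor
  explains (Poisson bound), or trace SD > 1.5 × robust SD without
  attributable events (the dim-punctum-blurred-by-cytosol case).
- **calcium-insensitive** — otherwise; confident only when literally
  zero events were detected.

The rule is invariant to affine rescaling of the trace.

## Synthetic-data generator

The generator is first-class, tested code; every analysis stage is
validated against it because the study's raw recordings are not
deposited anywhere.

Spike trains.  Burst onsets are a Poisson process whose rate is
`firing_rate / E[burst size]`, so the *overall* AP rate equals the
configured `firing_rate`; burst sizes are truncated-geometric
(parameter `burst_prob`, cap `max_burst_size`) and intra-burst
inter-spike intervals are uniform on 5–100 ms, well inside the 300-ms
window.  With `burst_prob = 0` this reduces to a plain Poisson process
(the basis of the count oracle in the tests).

Fluorescence.  Each AP contributes a difference-of-exponentials kernel
`(1 − e^(−t/τ_r))·e^(−t/τ_d)`, normalized to unit peak and scaled by the
single-AP amplitude; the linear sum L(t) passes through a hyperbolic
(Hill coefficient 1) saturation

    s(L) = ΔF/F_max · L / (L + K),

with K calibrated numerically at construction so that
s(single-AP amplitude) equals the single-AP amplitude exactly — the
single-AP response is quasi-linear, and s → identity as ΔF/F_max → ∞.
Frames sample `F(t) = F0·(1 + s(L(t)))` plus Gaussian noise of SD
`noise_sd` (ΔF/F units) per frame; a Poisson (photon-counting-like)
option exists behind a flag.  Ground truth records per-burst true peak
ΔF/F evaluated on a 1-ms grid, immune to frame-sampling loss.

Defaults as study conditions: frame rate 12 Hz; single-AP amplitude
0.087; decay τ 0.35 s; rise τ 30 ms (the kernel needs a finite rise for
realistic peak sampling; the value is a design choice, not a measured
one); ΔF/F_max 3.73; spontaneous AP rate 0.05 Hz with burst probability
0.3 (≈ 2–3 transients/min, matching spontaneous activity of these
neurons); noise SD 0.03, chosen so the single-AP SNR sits near 2.5–3 —
the regime in which roughly half to two-thirds of single APs are
detectable, which is where somatic imaging of this indicator class
operates in vivo.  No published noise magnitude exists for these
recordings, so the suite also sweeps noise rather than trusting any
single value.

Movies.  Traces are rendered into square ROIs on a grid over a flat
background, optionally with static bright puncta pixels and a 2×2
spectral mixture, plus per-pixel Gaussian noise; written as uint16
multi-page TIFF with a JSON ground-truth sidecar (run-length-encoded
pixel sets).  What the generator does *not* emulate: optics (PSF,
depth-dependent scattering), motion artifacts, neuropil contamination,
hemodynamic signals, photobleaching.  Tests passing on this generator
establish the correctness of the estimators and their calibration, not
robustness to those real-data effects.

## Numerical choices and degenerate inputs

- Percentiles: linear interpolation everywhere.
- SDs: sample SD (ddof = 1); robust SD = 1.4826 × MAD.
- Zero-variance traces: event detection returns an empty list with a
  warning; threshold calibration with zero-spread nulls returns the
  mean with a warning; flat null segments are skipped with a warning.
- Decay fits that cannot converge, or windows truncated below 4 frames,
  yield NaN τ (flagged), never exceptions.
- Non-positive F0 raises a dedicated error naming the ROI.
- Threshold calibration requires ≥ 20 null values.
- All randomness flows through explicit integer seeds; identical seeds
  give bit-identical spike trains, traces and movies.

## Problem sizes

The test suite runs in well under a minute of CPU: simulations use
30–600 s of 12–60 Hz trace, 100–500 replicates for distributional
checks, 10⁴ segments for calibration checks and 1000 replicates for the
ANOVA type-I calibration.  The acceptance script simulates 10⁴
calibration traces and 10⁴ independent evaluation segments.  These
sizes put Monte-Carlo error comfortably below the tolerances asserted.

## Known limitations

- The Gaussian-fit detection threshold undercovers the skewed null tail
  (≈ 5.3% realized FPR at a 5% target); use the percentile method when
  exact FPR control matters.
- The 3-point peak average is biased low at 12 Hz (see above); compare
  like with like when relating amplitudes across frame rates.
- The fixed-effects "nested" ANOVA treats ROIs as independent
  observations; within-cell correlation across sessions is not
  modelled (a random-effects treatment is out of scope).
- Matched-cell comparisons rely on ROI identity keys supplied in
  metadata; no image registration is performed.
- The event detector's false-positive floor (≈ 1.3/1000 frames) is
  inherent to the median + 3 SD rule.
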