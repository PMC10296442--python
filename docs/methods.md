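# Methods

This note documents the models, numerical choices, and limitations behind
`alphaloop`. The package simulates and analyzes a two-day closed-loop
individual-alpha-frequency (IAF) neurofeedback study; because no human
recordings ship with it, all validation is by recovery of programmed
ground truth on synthetic data.

## Signal model

Synthetic EEG is the sum of two components, generated per epoch at 256 Hz
on the 16-channel 10–20 montage:

**Background.** Fractional-Gaussian `1/f^β` noise synthesized in the
frequency domain: Fourier amplitudes are complex Gaussian with standard
deviation `f^(−β/2)` inside the 2–30 Hz acquisition passband and zero
outside (a brick-wall stand-in for the amplifier band-pass — the in-band
spectrum is exactly `f^−β`, which is what the slope tests check), inverse
transformed and scaled to a per-channel RMS of 10 µV. Default `β = 1`.
Channels are independent.

**Alpha oscillator.** A single stochastic-phase source shared across
channels, `s(t) = env(t) · sin φ(t)` with
`dφ/dt = 2π (f_traj(t) + δf(t))`. The frequency jitter `δf` is an
Ornstein–Uhlenbeck (OU) process (τ = 0.5 s) with SD `bandwidth/2.355`, so
the `bandwidth` parameter reads approximately as the FWHM linewidth
(default 0.5 Hz, a sharp eyes-closed peak). The envelope is log-normal OU
(σ = 0.4, τ = 2 s), producing the waxing-and-waning of real alpha. The
oscillator was chosen over filtered noise because its instantaneous peak is
controllable sample by sample, which the closed loop requires. Spatial
gains: occipitoparietal 1, central 1/3, frontotemporal 1/6 (amplitude),
making the source occipitoparietal-dominant as in eyes-closed recordings.

**SNR convention.** `alpha_snr` is the ratio of alpha-oscillation power to
background power *within 7–13 Hz* at an occipitoparietal channel; the
default is 60 (a strongly alpha-dominant eyes-closed posterior spectrum,
individual alpha ratio ≈ 0.85 at Oz). This default matters for one honest
reason: the offline IAF is the raw band center of gravity, which any
in-band background pulls toward its own centroid (≈ 9.8 Hz for `1/f`) by
`(f_bg − f0)/(1 + SNR)`. Sub-0.1 Hz recovery of peaks at the band edges is
therefore only attainable in the strong-alpha regime; at SNR 3 the pull
alone reaches ~0.45 Hz. The generator makes no attempt to emulate weak-alpha
subjects for whom the plain CoG definition would be materially biased.

## Participant model

The expressed peak is `peak_now = clip(peak_base + x, 7, 13)`:

* `x(t)` — zero-mean OU "excitability" fluctuation, σ = 0.2 Hz, τ = 5 s.
  Over a 2-minute baseline session this yields ≈ 0.05 Hz of
  session-to-session IAF fluctuation, small against the ≈ 0.2 Hz training
  effect the protocol targets.
* `peak_base` — the slow trainable component. During training it moves by
  `k · a(t) · c(t) · dt` plus a small Gaussian walk (0.002 Hz/√s); during
  rest it relaxes toward baseline at `relax_rate = 1e-3 /s` (rest breaks
  barely erode gains; overnight consolidation is not modeled). It is
  clipped to the ceiling (baseline + 1.5 Hz by default) and the band floor.

**Why contingency-gated learning.** With `contingent=True` (default),
`c(t) = x(t)/σ_x`: reinforcement accrues only when the haptic reward
coincides with the subject's own alpha excursion. Real feedback is computed
from the subject's measured IAF, so `a(t)` and `x(t)` correlate and
`peak_base` drifts upward; replayed sham feedback is independent of `x`, so
its expected drift is exactly zero. A rule depending on amplitude alone
(`c ≡ 1`, available as `contingent=False` and used for textbook forced-drift
checks) cannot produce a sham-null: sham subjects feel as much vibration as
trained ones. The contingent rule is what makes the NF-vs-Sham contrast an
emergent property of the closed loop rather than an assumption. For the
same reason the model enforces no reflecting floor at the baseline peak —
a one-sided bound would rectify sham noise into spurious positive drift.

**Responsiveness.** `k` (Hz per Hz·s of feedback per second) defaults to
0.004, calibrated once so a typical responder gains ≈ 0.2 Hz over the
30 minutes of feedback — the short-term trainability scale this protocol
is designed around. `k = 0` is an exact non-responder.

## Real-time estimator

2 s Hann window, zero-padded to 8 s (grid 1/8 = 0.125 Hz), magnitude
squared, Savitzky–Golay smoothed along frequency (11 bins ≈ 1.375 Hz span,
order 3 — wide enough to suppress single-bin noise, narrow enough to keep
0.125 Hz peak placement), then the highest *strict* local maximum in
7–13 Hz. Band-edge bins are never peaks; exact power ties resolve to the
lower frequency. Updates advance every 100 ms (95% overlap); with a
256 Hz rate the hop alternates between 25 and 26 samples so step times stay
exactly on the 0.1 s grid. Per step, per-channel peaks are averaged over
the occipitoparietal set (averaging the channel spectra first is available
by configuration); a step is valid iff at least half the channels produce a
valid peak, and invalid steps hold the last valid value (mid-band 10 Hz
before any). Spectrum smoothing is the operative definition; optional
median smoothing of the IAF time series exists but is off by default.

**Distinctiveness gate.** A peak is accepted iff its within-band prominence
is ≥ 6 × the median band power *and* the 7–13 Hz band carries ≥ 45% of
total spectral power. Both thresholds were derived from the joint
distribution of the two statistics on background-only versus
strong-alpha windows: the `1/f` slope makes low-band noise maxima look
prominent against the band median, so neither statistic alone separates
the cases; jointly, background windows pass at ≈ 0.2% and strong-alpha
windows fail at ≈ 0.1%. With six channels and the half-valid rule this
makes background-only epochs essentially never update the feedback.

The streaming implementation is vectorized (batched FFTs over all window
positions) but is sample-exact equivalent to the public per-window
operations, which the tests verify step by step. Spectra are truncated at
32 Hz (the signals are band-limited at 30 Hz); single-epoch streams run in
≈ 0.1 s, keeping 100-run closed-loop experiments tractable.

## Feedback controller

Amplitude: trailing 500 ms moving sum of positive threshold exceedance,
`Σ max(IAF − θ, 0) · 0.1 s` over valid steps — causal, real-time
computable, and instantly zero when below threshold. Output holds across
invalid steps (the no-update rule). Threshold: initialized 0.1 Hz below the
eyes-closed baseline IAF (offline CoG of the day-1 pre baseline); after
each block, with exceed ratio r, it moves by +0.1/+0.2/+0.3 Hz for
r ∈ (0.7, 0.8] / (0.8, 0.9] / (0.9, 1], mirrored downward for
r ∈ [0.6, 0.7) / [0.5, 0.6) / [0, 0.5), holding only at exactly 0.7. The
tiering makes the printed 0.1–0.3 Hz range deterministic; invalid steps are
excluded from both sides of the ratio. A [6.5, 13.5] Hz clamp guards
against runaway adaptation in degenerate simulations. The day-2 initial
threshold carries over from day 1's final value, a deterministic stand-in
for the experimenter's manual between-session assignment. Vibration
rendering (100 Hz carrier, per-subject amplitude scaling) is out of scope;
the exported amplitude is in Hz·s.

**Closed-loop integration.** Within one 60 s epoch the trainable component
moves by well under the 0.125 Hz spectral resolution, so each epoch is
simulated with `peak_base` frozen for EEG synthesis while the learning
update is integrated step-by-step from the *actual* amplitude series and
excitability path; `x(t)` is carried at full resolution throughout. Sham
runs replay a donor responder's stored amplitude trace; their EEG is
generated and analyzed only when the offline pipeline needs it.

## Offline pipeline

2 s / 50% segmentation (trailing partial dropped), time-domain
Savitzky–Golay detrending (0.5 s window, order 2 — subtracting the smooth
trend approximates a high-pass consistent with the 2 Hz acquisition
high-pass), Hann taper, zero-padding to 100 s (0.01 Hz grid),
segment-averaged periodograms. Per-channel CoG IAFs are averaged across an
epoch's segments and a session's epochs; the alpha ratio is computed per
channel at that channel's IAF then averaged (computing it on a mean
spectrum is the undocumented alternative; per-channel was chosen as the
default). Topographic maps use separable Mitchell–Netravali kernels
(B = C = 1/3, the filter's canonical recommendation; scale 0.75 head
radii) with weights normalized to sum to one, so constant inputs reproduce
a constant field; the map is masked beyond the outer electrode ring, where
normalized scattered-data weights extrapolate badly. Electrode coordinates
are the standard azimuthal-equidistant projection of the idealized 10–20
sphere, shipped with the package.

**Trajectory statistics.** Mixed ANOVA (between: group; within: 14
sessions = 4 baselines + 10 training blocks) via pingouin, with a
Shapiro–Wilk normality report on cell-demeaned residuals and
Greenhouse–Geisser correction applied when Mauchly's test rejects
sphericity (df scaled by the session-effect ε). Holm–Bonferroni pairwise
session contrasts run per group on request. Under the null generator
(iid cells) the interaction p-value is uniform — verified at 500
replicates — and compound symmetry holds, so GG rarely triggers.

## Behavioral tasks and statistics

Mental rotation: 15-trial blocks, exactly 8 matched of 15 (probabilities
are enforced as exact per-block counts, rounding half-up, not per-trial
coin flips), 8 s stimulus window doubling as the response deadline.
N-back: 8 slots; 28-trial 1-back, 30-trial 3-back blocks, exact
`round(⅓ · (trials − n))` targets placed at lags > n, with non-target
trials explicitly avoiding accidental lag-n matches. Metrics: accuracy
(3-back: hits + correct rejections over total; 1-back accuracy is not a
reported metric), mean RT, and reaction control (sample SD of single-trial
RT, ddof = 1, undefined below two responses). The behavioral score counts
strict improvements over the full 8-metric inventory (accuracy up, RT and
reaction control down; ties never count). Friedman on two conditions uses
the tie-corrected reduction `Q = (b − c)²/(b + c)` with a χ²(1) p-value —
anticonservative at very small n, as the exhaustive-permutation test
documents, but the standard large-sample form at cohort sizes.

**Cohort generator.** Each metric improves iff
`coupling · Δ_IAF + N(0, noise) > 0` (probit link; defaults coupling = 5
/Hz, noise = 1), with change magnitudes drawn independently — the IAF
coupling lives in improvement *probability*, not size. `coupling = 0`
makes the score an independent fair-coin count, giving exact type-I
calibration for the Spearman stage (measured ≈ 5% at α = 0.05).

## Validation experiment sizes

The shipped validation suite uses: 4 programmed peaks × 120 s (offline) /
60 s (real-time) for estimator recovery; 50 paired two-day closed-loop
runs for the NF-vs-Sham contrast; 500 replicate cohorts (n = 16) for each
of the correlation power/type-I checks; 500 null + 100 powered replicates
for the ANOVA calibration. These sizes put Monte-Carlo error comfortably
below the tolerances being checked while keeping the whole suite around
six minutes on one CPU.

## What passing tests do and do not show

The generator emulates band-limited `1/f` background, a single shared
narrowband posterior source, stationary excitability, and
contingency-driven learning. It does not model eye blinks or EMG
artifacts, multiple or split alpha generators, asymmetric/skewed peak
shapes, volume-conduction correlations in the background, nonstationary
fatigue or drowsiness drifts, or overnight consolidation. Recovery results
therefore demonstrate correctness of the *pipeline* under its stated
assumptions, not robustness to real-world artifacts; the distinctiveness
gate is the only artifact defense implemented, and it is validated only
against the generator's own background. The cohort statistics inherit the
usual caveats of their tests (χ² approximations at small n, rank tests
under heavy ties).
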