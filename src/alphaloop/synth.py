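"""Synthetic EEG and simulated participants with known ground truth.

Every downstream stage of the pipeline (real-time estimator, feedback
controller, offline spectral analysis, behavioral statistics) is validated
against data produced here, where the alpha peak frequency, its response to
feedback, and the behavioral coupling are all known exactly.

The signal model is additive:

* a 1/f^beta fractional-Gaussian background, band-limited to the
  acquisition passband (2-30 Hz), synthesized in the frequency domain;
* a narrowband alpha oscillator whose instantaneous frequency follows a
  prescribed trajectory, with Ornstein-Uhlenbeck (OU) frequency jitter
  setting the linewidth and a slow log-normal envelope producing the
  waxing-and-waning typical of eyes-closed alpha;
* a fixed spatial gain profile making the oscillation
  occipitoparietal-dominant.

The simulated participant carries a slow "trainable" peak component and a
fast zero-mean excitability fluctuation; reinforcement of the peak requires
that the haptic reward coincide with the participant's own alpha excursions,
which is what distinguishes contingent neurofeedback from sham replay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .montage import CENTRAL, FRONTOTEMPORAL, MONTAGE_16, OCCIPITOPARIETAL
from .recording import EEGRecording

ALPHA_BAND = (7.0, 13.0)


# ---------------------------------------------------------------------------
# background + alpha signal generation
# ---------------------------------------------------------------------------

def _ou_path(n: int, dt: float, tau: float, sd: float,
             rng: np.random.Generator, x0: float | None = None) -> np.ndarray:
    """Stationary OU path via its exact AR(1) discretization."""
    a = math.exp(-dt / tau)
    innov_sd = sd * math.sqrt(1.0 - a * a)
    e = rng.standard_normal(n) * innov_sd
    if x0 is None:
        x0 = rng.standard_normal() * sd
    # x[k] = a*x[k-1] + e[k], x[-1] = x0
    x = lfilter([1.0], [1.0, -a], e, zi=[a * x0])[0]
    return x


def generate_background(duration_s: float, fs: float = 256.0,
                        channel_names: tuple[str, ...] = MONTAGE_16,
                        noise_exponent: float = 1.0,
                        seed: int | np.random.Generator | None = None,
                        rms_uv: float = 10.0,
                        band: tuple[float, float] = (2.0, 30.0)) -> EEGRecording:
    """Band-limited 1/f^beta background noise, independent per channel.

    Synthesized in the frequency domain: Fourier amplitudes are complex
    Gaussian with standard deviation proportional to ``f**(-beta/2)`` inside
    the passband and zero outside (a brick-wall stand-in for the amplifier's
    band-pass), then inverse transformed and scaled to ``rms_uv`` per
    channel. Deterministic for a fixed seed.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if len(channel_names) == 0:
        raise ValueError("empty montage")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration_s * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    amp[in_band] = freqs[in_band] ** (-noise_exponent / 2.0)
    n_ch = len(channel_names)
    z = rng.standard_normal((n_ch, freqs.size)) + 1j * rng.standard_normal((n_ch, freqs.size))
    x = np.fft.irfft(z * amp, n=n, axis=-1)
    rms = np.sqrt(np.mean(x ** 2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    x *= rms_uv / rms
    return EEGRecording(tuple(channel_names), fs, x, band)


def alpha_gain_profile(channel_names: tuple[str, ...] = MONTAGE_16,
                       central_ratio: float = 3.0,
                       frontal_ratio: float = 6.0) -> np.ndarray:
    """Occipitoparietal-dominant spatial gains (occipitoparietal = 1).

    Central channels are attenuated by ``central_ratio`` and
    frontotemporal channels by ``frontal_ratio`` relative to the
    occipitoparietal set.
    """
    gains = []
    for ch in channel_names:
        if ch in OCCIPITOPARIETAL:
            gains.append(1.0)
        elif ch in CENTRAL:
            gains.append(1.0 / central_ratio)
        elif ch in FRONTOTEMPORAL:
            gains.append(1.0 / frontal_ratio)
        else:  # pragma: no cover - montage is closed
            raise ValueError(f"unknown channel {ch}")
    return np.array(gains)


def background_alpha_fraction(noise_exponent: float,
                              band: tuple[float, float] = (2.0, 30.0),
                              alpha_band: tuple[float, float] = ALPHA_BAND) -> float:
    """Fraction of 1/f^beta background power falling inside the alpha band."""
    lo, hi = band
    a, b = alpha_band
    if abs(noise_exponent - 1.0) < 1e-12:
        return math.log(b / a) / math.log(hi / lo)
    e = 1.0 - noise_exponent
    return (b ** e - a ** e) / (hi ** e - lo ** e)


def alpha_rms_for_snr(snr: float, bg_rms_uv: float = 10.0,
                      noise_exponent: float = 1.0,
                      band: tuple[float, float] = (2.0, 30.0)) -> float:
    """Occipitoparietal alpha RMS (microvolts) achieving a given band SNR.

    SNR is defined as the ratio of alpha-oscillation power to background
    power *within the 7-13 Hz band* at an occipitoparietal channel.
    """
    frac = background_alpha_fraction(noise_exponent, band)
    return math.sqrt(snr * frac) * bg_rms_uv


def add_alpha(rec: EEGRecording, peak_trajectory: np.ndarray,
              alpha_amp: np.ndarray | None = None,
              bandwidth_hz: float = 0.5,
              seed: int | np.random.Generator | None = None,
              env_sd: float = 0.4, env_tau_s: float = 2.0,
              freq_tau_s: float = 0.5) -> EEGRecording:
    """Add a narrowband alpha oscillation following `peak_trajectory`.

    The oscillator is a stochastic-phase sinusoid: its instantaneous
    frequency is the trajectory value plus OU jitter whose standard
    deviation is ``bandwidth_hz / 2.355`` (so the parameter reads
    approximately as a FWHM linewidth), and its envelope is a slow
    log-normal OU process normalized to unit RMS. A single oscillation
    source is shared across channels and scaled by ``alpha_amp`` (microvolt
    RMS per channel), emulating one dominant posterior generator.

    `peak_trajectory` may be sampled at any rate of at least 10 Hz; it is
    linearly interpolated onto the sample grid. All values must lie within
    the 7-13 Hz alpha band.
    """
    traj = np.atleast_1d(np.asarray(peak_trajectory, dtype=float))
    if traj.size == 0:
        raise ValueError("empty peak trajectory")
    if np.any(traj < ALPHA_BAND[0]) or np.any(traj > ALPHA_BAND[1]):
        raise ValueError("peak trajectory values must lie within [7, 13] Hz")
    if traj.size > 1 and traj.size / rec.duration_s < 10.0 - 1e-9:
        raise ValueError("trajectory must be sampled at >= 10 Hz")
    if alpha_amp is None:
        alpha_amp = alpha_gain_profile(rec.channel_names)
    alpha_amp = np.asarray(alpha_amp, dtype=float)
    if alpha_amp.shape != (rec.n_channels,):
        raise ValueError("alpha_amp must have one gain per channel")

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = rec.n_samples
    dt = 1.0 / rec.fs
    if traj.size == 1:
        f_inst = np.full(n, traj[0])
    else:
        t_traj = np.linspace(0.0, rec.duration_s, traj.size)
        f_inst = np.interp(np.arange(n) * dt, t_traj, traj)

    f_jit = _ou_path(n, dt, freq_tau_s, bandwidth_hz / 2.355, rng)
    phase = 2.0 * np.pi * np.cumsum(f_inst + f_jit) * dt
    phase += rng.uniform(0.0, 2.0 * np.pi)
    env = np.exp(_ou_path(n, dt, env_tau_s, env_sd, rng))
    s = env * np.sin(phase)
    s_rms = math.sqrt(np.mean(s ** 2))
    if s_rms > 0:
        s /= s_rms
    out = rec.copy()
    out.data += alpha_amp[:, None] * s[None, :]
    return out


# ---------------------------------------------------------------------------
# participant model
# ---------------------------------------------------------------------------

@dataclass
class ParticipantModel:
    """Ground-truth alpha-peak dynamics of one simulated subject.

    The expressed (instantaneous) peak is ``peak_base + x`` where
    ``peak_base`` is a slow trainable component and ``x`` a zero-mean OU
    excitability fluctuation with standard deviation ``excitability_sd``
    and correlation time ``excitability_tau_s``.

    During training the trainable component moves by

    ``d peak_base = k * a(t) * c(t) * dt + jitter``

    where ``a(t)`` is the felt feedback amplitude and, when ``contingent``
    is true, ``c(t) = x(t)/excitability_sd`` is the standardized own alpha
    excursion. Learning therefore requires reward-excursion coincidence:
    replayed (sham) feedback, being uncorrelated with ``x``, produces zero
    expected drift. With ``contingent=False`` the classical forced-drift
    rule ``d peak_base = k * a * dt`` is used instead.

    During rest the trainable component relaxes toward ``baseline_peak``
    at rate ``relax_rate`` (1/s).
    """

    baseline_peak: float = 10.0
    responsiveness: float = 0.0          # Hz per (Hz*s of feedback) per s
    ceiling: float = 11.5
    relax_rate: float = 1e-3             # 1/s
    excitability_sd: float = 0.2         # Hz
    excitability_tau_s: float = 5.0
    drift_jitter: float = 0.002          # Hz per sqrt(s)
    contingent: bool = True
    alpha_snr: float = 60.0
    noise_exponent: float = 1.0
    rng_seed: int | None = None
    # state
    peak_base: float = field(default=None)  # type: ignore[assignment]
    x: float = 0.0
    rng: np.random.Generator = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (ALPHA_BAND[0] <= self.baseline_peak <= ALPHA_BAND[1]):
            raise ValueError("baseline_peak must lie in [7, 13] Hz")
        if self.responsiveness < 0:
            raise ValueError("responsiveness must be >= 0")
        if self.peak_base is None:
            self.peak_base = self.baseline_peak
        if self.rng is None:
            self.rng = np.random.default_rng(self.rng_seed)

    @property
    def peak_now(self) -> float:
        """Instantaneous expressed peak frequency in Hz."""
        return float(np.clip(self.peak_base + self.x, *ALPHA_BAND))

    def _advance_x(self, dt_s: float) -> None:
        a = math.exp(-dt_s / self.excitability_tau_s)
        self.x = a * self.x + self.excitability_sd * math.sqrt(1 - a * a) * \
            self.rng.standard_normal()

    def _learn(self, feedback_amplitude: float, dt_s: float) -> None:
        c = self.x / self.excitability_sd if self.contingent else 1.0
        step = self.responsiveness * feedback_amplitude * c * dt_s
        if self.drift_jitter > 0:
            step += self.drift_jitter * math.sqrt(dt_s) * self.rng.standard_normal()
        self.peak_base = float(np.clip(self.peak_base + step,
                                       ALPHA_BAND[0], self.ceiling))

    def _relax(self, dt_s: float) -> None:
        decay = math.exp(-self.relax_rate * dt_s)
        self.peak_base = self.baseline_peak + (self.peak_base - self.baseline_peak) * decay


def step_participant(model: ParticipantModel, feedback_amplitude: float,
                     dt_s: float, phase: str = "training") -> ParticipantModel:
    """Advance the participant state by one step of ``dt_s`` seconds.

    ``phase`` is ``"training"`` (feedback drives learning) or ``"rest"``
    (relaxation toward baseline). Returns the same (mutated) model for
    chaining. Saturation at the ceiling is handled by clipping.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if feedback_amplitude < 0:
        raise ValueError("feedback_amplitude must be >= 0")
    if phase not in ("training", "rest"):
        raise ValueError(f"unknown phase {phase!r}")
    model._advance_x(dt_s)
    if phase == "training":
        model._learn(feedback_amplitude, dt_s)
    else:
        model._relax(dt_s)
    return model


def make_cohort(n: int, seed: int | None = None,
                baseline_mean: float = 10.0, baseline_sd: float = 0.8,
                responsiveness: float = 0.0, ceiling_offset: float = 1.5,
                **kwargs) -> list[ParticipantModel]:
    """Draw ``n`` participants with baseline peaks ~ N(mean, sd), clipped
    to [8, 12] so the ceiling stays inside the alpha band."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)
    out = []
    for child in children:
        rng = np.random.default_rng(child)
        base = float(np.clip(rng.normal(baseline_mean, baseline_sd), 8.0, 12.0))
        out.append(ParticipantModel(
            baseline_peak=base, responsiveness=responsiveness,
            ceiling=min(base + ceiling_offset, ALPHA_BAND[1]), rng=rng, **kwargs))
    return out


# ---------------------------------------------------------------------------
# behavioral cohort generator
# ---------------------------------------------------------------------------

#: (task, metric, beneficial direction): +1 = larger is better
BEHAVIORAL_METRICS: tuple[tuple[str, str, int], ...] = (
    ("mr", "accuracy", +1),
    ("mr", "rt_mean", -1),
    ("mr", "reaction_control", -1),
    ("1back", "rt_mean", -1),
    ("1back", "reaction_control", -1),
    ("3back", "accuracy", +1),
    ("3back", "rt_mean", -1),
    ("3back", "reaction_control", -1),
)

#: plausible pre-training metric distributions: (mean, sd, change sd)
_METRIC_PRIORS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("mr", "accuracy"): (0.75, 0.08, 0.05),
    ("mr", "rt_mean"): (3.0, 0.5, 0.3),
    ("mr", "reaction_control"): (0.8, 0.2, 0.12),
    ("1back", "rt_mean"): (0.50, 0.08, 0.05),
    ("1back", "reaction_control"): (0.15, 0.04, 0.03),
    ("3back", "accuracy"): (0.80, 0.07, 0.05),
    ("3back", "rt_mean"): (0.70, 0.10, 0.06),
    ("3back", "reaction_control"): (0.25, 0.06, 0.04),
}


@dataclass
class BehavioralCohortSpec:
    """Generator settings for a synthetic pre/post behavioral cohort.

    ``coupling`` (per Hz) is the probit slope linking a subject's
    cumulative IAF change to the probability that each metric improves:
    P(improve) = Phi(coupling * delta / metric_noise). ``coupling = 0``
    makes improvement a fair coin independent of the IAF change.
    """

    n_subjects: int = 16
    coupling: float = 5.0
    metric_noise: float = 1.0
    rng_seed: int | None = None


def generate_behavioral_cohort(spec: BehavioralCohortSpec,
                               iaf_deltas: np.ndarray) -> pd.DataFrame:
    """Per-subject pre/post values for the 8 behavioral metrics.

    Each metric improves iff the latent variable
    ``coupling * delta + metric_noise * N(0,1)`` is positive; the magnitude
    of the change is drawn independently, so improvement probability (not
    size) carries the IAF coupling.

    Returns a tidy frame with columns
    ``subject, task, metric, direction, pre, post, improved``.
    """
    deltas = np.asarray(iaf_deltas, dtype=float)
    if spec.n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if deltas.shape != (spec.n_subjects,):
        raise ValueError("need exactly one cumulative IAF delta per subject")
    rng = np.random.default_rng(spec.rng_seed)
    rows = []
    for subj in range(spec.n_subjects):
        for task, metric, direction in BEHAVIORAL_METRICS:
            mean, sd, change_sd = _METRIC_PRIORS[(task, metric)]
            pre = rng.normal(mean, sd)
            if metric == "accuracy":
                pre = float(np.clip(pre, 0.05, 0.98))
            latent = spec.coupling * deltas[subj] + spec.metric_noise * rng.standard_normal()
            improved = latent > 0
            magnitude = abs(rng.normal(0.0, change_sd)) + 1e-9
            post = pre + direction * magnitude if improved else pre - direction * magnitude
            if metric == "accuracy":
                post = float(np.clip(post, 0.0, 1.0))
            rows.append((subj, task, metric, direction, pre, post, improved))
    return pd.DataFrame(rows, columns=[
        "subject", "task", "metric", "direction", "pre", "post", "improved"])


# ---------------------------------------------------------------------------
# session-trajectory table generator (for the mixed-ANOVA stage)
# ---------------------------------------------------------------------------

def generate_iaf_trajectory_table(n_per_arm: int, n_sessions: int = 14,
                                  baseline_mean: float = 10.0,
                                  baseline_sd: float = 0.8,
                                  drift_nf: float = 0.0,
                                  noise_sd: float = 0.05,
                                  shape: str = "ramp",
                                  seed: int | None = None) -> pd.DataFrame:
    """Per-subject per-session IAF table with a programmed NF-arm drift.

    ``shape`` is the drift profile across sessions: ``"ramp"`` (linear from
    0 to ``drift_nf``), ``"step"`` (0 for the first half, ``drift_nf``
    after), or ``"flat"`` (no session dependence; ``drift_nf`` ignored).
    The Sham arm never drifts. Cell noise is iid Gaussian ``noise_sd``.
    """
    if n_per_arm < 2:
        raise ValueError("need at least 2 subjects per arm")
    if n_sessions < 2:
        raise ValueError("need at least 2 sessions")
    rng = np.random.default_rng(seed)
    s = np.arange(n_sessions)
    if shape == "ramp":
        profile = drift_nf * s / (n_sessions - 1)
    elif shape == "step":
        profile = np.where(s >= n_sessions // 2, drift_nf, 0.0)
    elif shape == "flat":
        profile = np.zeros(n_sessions)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    rows = []
    for arm, drift in (("NF", profile), ("Sham", np.zeros(n_sessions))):
        for i in range(n_per_arm):
            base = rng.normal(baseline_mean, baseline_sd)
            vals = base + drift + rng.normal(0.0, noise_sd, n_sessions)
            for j in range(n_sessions):
                rows.append((f"{arm}{i:02d}", arm, j, vals[j]))
    return pd.DataFrame(rows, columns=["subject", "group", "session", "iaf"])
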