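"""Haptic feedback amplitude, threshold adaptation, and session orchestration.

The self-regulated signal is the occipitoparietal mean IAF. The vibration
amplitude accumulates the net increase of real-time IAF above a threshold
frequency over a trailing 500 ms window. The threshold starts 0.1 Hz below
the eyes-closed baseline IAF and adapts after every training block from the
block's exceed ratio (fraction of valid steps above threshold): above 70%
it increases by 0.1-0.3 Hz, below (i.e. under threshold more than 30% of
the time) it decreases by 0.1-0.3 Hz, with the magnitude tiered on how far
past the trigger the ratio fell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .montage import OCCIPITOPARIETAL
from .realtime import GateParams, IAFTimeSeries, realtime_stream
from .recording import EEGRecording
from .synth import (ALPHA_BAND, ParticipantModel, _ou_path, add_alpha,
                    alpha_gain_profile, alpha_rms_for_snr, generate_background)

THRESHOLD_CLAMP = (6.5, 13.5)  # safety clamp against runaway adaptation
ADAPT_TRIGGER = 0.7
ADAPT_STEPS = (0.1, 0.2, 0.3)  # Hz, tiered on 0.1-wide excess bands


@dataclass
class ThresholdState:
    """Current feedback threshold plus its adaptation history.

    ``history`` holds ``(block_index, exceed_ratio, adjustment_hz)``
    triplets; every nonzero adjustment magnitude lies in [0.1, 0.3] Hz and
    the threshold is clamped to [6.5, 13.5] Hz.
    """

    threshold: float
    history: list[tuple[int, float, float]] = field(default_factory=list)


def init_threshold(baseline_iaf: float) -> ThresholdState:
    """Initial threshold: 0.1 Hz below the eyes-closed baseline IAF."""
    if not (ALPHA_BAND[0] <= baseline_iaf <= ALPHA_BAND[1]):
        raise ValueError("baseline IAF must lie in [7, 13] Hz")
    return ThresholdState(threshold=baseline_iaf - 0.1)


def _tier(excess: float) -> float:
    """Adjustment magnitude for a ratio `excess` past the 70% trigger."""
    if excess <= 0:
        return 0.0
    for i, step in enumerate(ADAPT_STEPS):
        if excess <= 0.1 * (i + 1) + 1e-12:
            return step
    return ADAPT_STEPS[-1]


def adapt_threshold(state: ThresholdState, ratio: float,
                    block_index: int | None = None) -> ThresholdState:
    """Block-wise threshold update from the exceed ratio.

    ``ratio > 0.7`` raises the threshold, ``ratio < 0.7`` lowers it
    (equivalently: below threshold more than 30% of the time); exactly 0.7
    holds. The magnitude is 0.1 Hz per 0.1 of ratio beyond the trigger,
    capped at 0.3 Hz, and the result is clamped to [6.5, 13.5] Hz.
    """
    if not (0.0 <= ratio <= 1.0):
        raise ValueError("ratio must lie in [0, 1]")
    if ratio > ADAPT_TRIGGER:
        delta = _tier(ratio - ADAPT_TRIGGER)
    elif ratio < ADAPT_TRIGGER:
        delta = -_tier(ADAPT_TRIGGER - ratio)
    else:
        delta = 0.0
    new = float(np.clip(state.threshold + delta, *THRESHOLD_CLAMP))
    applied = new - state.threshold
    if block_index is None:
        block_index = len(state.history)
    return ThresholdState(new, state.history + [(block_index, ratio, applied)])


def feedback_amplitude(iaf_series: IAFTimeSeries, state: ThresholdState,
                       accum_window_s: float = 0.5) -> np.ndarray:
    """Vibration amplitude per step, in Hz*s.

    ``amplitude[i]`` is the sum over the valid steps in the trailing
    ``accum_window_s`` window (current step inclusive) of
    ``max(iaf - threshold, 0) * step_s``. On invalid steps the output does
    not update and holds its previous value.
    """
    k = int(round(accum_window_s / iaf_series.step_s))
    exc = np.where(iaf_series.valid,
                   np.maximum(iaf_series.iaf - state.threshold, 0.0), 0.0)
    exc = exc * iaf_series.step_s
    csum = np.concatenate(([0.0], np.cumsum(exc)))
    lo = np.maximum(np.arange(iaf_series.n_steps) - k + 1, 0)
    windowed = csum[1 + np.arange(iaf_series.n_steps)] - csum[lo]
    amp = np.empty_like(windowed)
    last = 0.0
    for i in range(windowed.size):
        if iaf_series.valid[i]:
            last = windowed[i]
        amp[i] = last
    return amp


def block_exceed_ratio(iaf_series: IAFTimeSeries, state: ThresholdState) -> float:
    """Fraction of valid steps whose IAF exceeds the current threshold.

    Invalid (no-update) steps are excluded from numerator and denominator.
    """
    valid = iaf_series.valid
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("undefined exceed ratio: no valid steps in block")
    return float(np.sum(iaf_series.iaf[valid] > state.threshold) / n_valid)


# ---------------------------------------------------------------------------
# session protocol + orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SessionProtocol:
    """Two-day schedule: per day, a pre baseline (4 x 30 s epochs with 10 s
    rests), 5 training blocks of 3 x 1-min epochs with 10 s rests, and a
    post baseline. Feedback time is 15 min per day, 30 min total."""

    days: int = 2
    baseline_epochs: int = 4
    baseline_epoch_s: float = 30.0
    baseline_rest_s: float = 10.0
    blocks_per_day: int = 5
    epochs_per_block: int = 3
    epoch_s: float = 60.0
    epoch_rest_s: float = 10.0

    @property
    def feedback_s_per_day(self) -> float:
        return self.blocks_per_day * self.epochs_per_block * self.epoch_s

    @property
    def total_feedback_s(self) -> float:
        return self.days * self.feedback_s_per_day

    def session_labels(self) -> list[str]:
        """Baseline and training-block session labels, in schedule order."""
        labels = []
        for d in range(1, self.days + 1):
            labels.append(f"day{d}-pre")
            for b in range(1, self.blocks_per_day + 1):
                labels.append(f"day{d}-block{b}")
            labels.append(f"day{d}-post")
        return labels

    @property
    def n_sessions(self) -> int:
        return self.days * (self.blocks_per_day + 2)


@dataclass
class SessionRecord:
    """One baseline session or training block of a simulated run."""

    label: str
    kind: str                      # "baseline" | "block"
    gt_peak_mean: float            # ground-truth expressed peak, session mean
    iaf_estimate: float | None = None   # offline/estimated occipitoparietal IAF
    threshold: float | None = None      # threshold active during the block
    exceed_ratio: float | None = None
    amplitudes: list[np.ndarray] | None = None  # per epoch, feedback steps
    valid_fraction: float | None = None


@dataclass
class SessionLog:
    """Full log of one participant's simulated two-day run."""

    arm: str
    sessions: list[SessionRecord] = field(default_factory=list)
    threshold_history: list[tuple[int, float, float]] = field(default_factory=list)
    recordings: list[tuple[str, EEGRecording]] = field(default_factory=list)

    def session(self, label: str) -> SessionRecord:
        for s in self.sessions:
            if s.label == label:
                return s
        raise KeyError(label)

    def gt_gain(self) -> float:
        """Ground-truth IAF gain: last post baseline minus first pre baseline."""
        base = [s for s in self.sessions if s.kind == "baseline"]
        return base[-1].gt_peak_mean - base[0].gt_peak_mean

    def amplitude_traces(self) -> list[np.ndarray]:
        """Per-epoch feedback amplitude traces, in schedule order (the
        stored trace a sham run replays)."""
        out = []
        for s in self.sessions:
            if s.kind == "block" and s.amplitudes is not None:
                out.extend(s.amplitudes)
        return out


def _session_gt_mean(participant: ParticipantModel, x_path: np.ndarray) -> float:
    peaks = np.clip(participant.peak_base + x_path, *ALPHA_BAND)
    return float(np.mean(peaks))


def run_protocol(participant: ParticipantModel,
                 protocol: SessionProtocol = SessionProtocol(),
                 arm: str = "NF",
                 sham_trace: list[np.ndarray] | None = None,
                 seed: int | None = None,
                 fs: float = 256.0,
                 channel_set: tuple[str, ...] = OCCIPITOPARIETAL,
                 eeg_channels: tuple[str, ...] | None = None,
                 gate: GateParams = GateParams(),
                 step_s: float = 0.1,
                 accum_window_s: float = 0.5,
                 bg_rms_uv: float = 10.0,
                 sham_eeg: bool = False,
                 baseline_analysis: str = "all",
                 session_callback=None) -> SessionLog:
    """Simulate one participant through the full two-day protocol.

    The NF arm closes the loop: per training epoch, EEG is generated from
    the participant's instantaneous peak, streamed through the real-time
    estimator, converted to feedback amplitude, and fed back into the
    participant's learning rule; thresholds adapt after each block. The
    Sham arm replays a stored amplitude trace (``sham_trace``, one array
    per training epoch from a responder's run) to the vibration channel
    while the participant's own EEG is, optionally (``sham_eeg``),
    still generated and analyzed.

    The participant's slow trainable component moves negligibly within one
    epoch (well under the 0.125 Hz spectral resolution), so each epoch is
    simulated with the trainable component frozen for EEG synthesis while
    the learning update is integrated step-by-step from the actual
    amplitude series; the excitability fluctuation is carried at full
    resolution throughout.

    ``session_callback(label, recording)`` is invoked for every generated
    EEG session epoch, letting callers run offline analysis without
    retaining the raw EEG in memory.
    """
    if arm not in ("NF", "Sham"):
        raise ValueError("arm must be 'NF' or 'Sham'")
    if arm == "Sham" and sham_trace is None:
        raise ValueError("Sham arm requires a stored sham_trace")
    if eeg_channels is None:
        eeg_channels = tuple(channel_set)
    seed_seq = np.random.SeedSequence(seed if seed is not None else participant.rng_seed)
    eeg_rng = np.random.default_rng(seed_seq)

    log = SessionLog(arm=arm)
    state: ThresholdState | None = None
    dt = step_s
    sig = participant.excitability_sd
    tau = participant.excitability_tau_s
    trace_iter = iter(sham_trace) if sham_trace is not None else None
    amp_profile = alpha_gain_profile(eeg_channels)
    alpha_rms = alpha_rms_for_snr(participant.alpha_snr, bg_rms_uv,
                                  participant.noise_exponent)

    def x_path_steps(duration_s: float) -> np.ndarray:
        """Advance the excitability OU on the feedback-step grid."""
        n = int(round(duration_s / dt))
        path = _ou_path(n, dt, tau, sig, participant.rng, x0=participant.x)
        participant.x = float(path[-1])
        return path

    def make_recording(x_steps: np.ndarray, duration_s: float) -> EEGRecording:
        traj_steps = np.clip(participant.peak_base + x_steps, *ALPHA_BAND)
        bg = generate_background(duration_s, fs, eeg_channels,
                                 participant.noise_exponent, eeg_rng, bg_rms_uv)
        return add_alpha(bg, traj_steps, alpha_rms * amp_profile, seed=eeg_rng)

    def rest(duration_s: float) -> None:
        decay = math.exp(-participant.relax_rate * duration_s)
        participant.peak_base = participant.baseline_peak + \
            (participant.peak_base - participant.baseline_peak) * decay
        a = math.exp(-duration_s / tau)
        participant.x = a * participant.x + \
            sig * math.sqrt(1 - a * a) * participant.rng.standard_normal()

    def run_baseline(label: str, analyze: bool) -> None:
        gt_means, iafs = [], []
        for ep in range(protocol.baseline_epochs):
            x_steps = x_path_steps(protocol.baseline_epoch_s)
            gt_means.append(_session_gt_mean(participant, x_steps))
            if analyze or session_callback is not None:
                rec = make_recording(x_steps, protocol.baseline_epoch_s)
                if session_callback is not None:
                    session_callback(label, rec)
                if analyze:
                    from .offline import cog_iaf, offline_spectrum, segment_epoch
                    sub = rec.pick(channel_set)
                    spec = offline_spectrum(segment_epoch(sub), fs)
                    iafs.append(np.mean([cog_iaf(spec, channel=c)
                                         for c in range(len(channel_set))]))
            rest(protocol.baseline_rest_s)
        log.sessions.append(SessionRecord(
            label, "baseline", float(np.mean(gt_means)),
            iaf_estimate=float(np.mean(iafs)) if iafs else None))

    def run_training_epoch(label: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
        """One 1-min feedback epoch; returns (iaf, valid, amplitude, gt mean)."""
        n_samp_steps = int(round(protocol.epoch_s / dt))
        x_steps = x_path_steps(protocol.epoch_s)
        if arm == "NF" or sham_eeg:
            rec = make_recording(x_steps, protocol.epoch_s)
            if session_callback is not None:
                session_callback(label, rec)
            series = realtime_stream(rec, channel_set, step_s=step_s, gate=gate)
        else:
            series = None
        if arm == "NF":
            amp = feedback_amplitude(series, state, accum_window_s)
            # amplitude steps start at t = window length; pad the lead-in
            lead = n_samp_steps - amp.size
            amp_full = np.concatenate([np.zeros(lead), amp])
        else:
            amp_full = next(trace_iter)
            if amp_full.size < n_samp_steps:
                amp_full = np.pad(amp_full, (0, n_samp_steps - amp_full.size))
            amp_full = amp_full[:n_samp_steps]
        # step-wise learning from the realized amplitude series
        k = participant.responsiveness
        jit = participant.drift_jitter
        if k > 0 or jit > 0:
            jitter = participant.rng.standard_normal(n_samp_steps) * jit * math.sqrt(dt) \
                if jit > 0 else np.zeros(n_samp_steps)
            c = x_steps / sig if participant.contingent else np.ones(n_samp_steps)
            pb = participant.peak_base
            lo, hi = ALPHA_BAND[0], participant.ceiling
            for i in range(n_samp_steps):
                pb += k * amp_full[i] * c[i] * dt + jitter[i]
                if pb > hi:
                    pb = hi
                elif pb < lo:
                    pb = lo
            participant.peak_base = pb
        gt = _session_gt_mean(participant, x_steps)
        if series is None:
            return None, None, amp_full, gt
        return series.iaf, series.valid, amp_full, gt

    if baseline_analysis not in ("all", "init", "none"):
        raise ValueError("baseline_analysis must be 'all', 'init' or 'none'")
    if arm == "NF" and baseline_analysis == "none":
        raise ValueError("NF arm needs baseline analysis to initialize the threshold")

    def want_analysis(label: str) -> bool:
        if arm != "NF" or baseline_analysis == "none":
            return False
        return baseline_analysis == "all" or label == "day1-pre"

    block_counter = 0
    for day in range(1, protocol.days + 1):
        run_baseline(f"day{day}-pre", analyze=want_analysis(f"day{day}-pre"))
        if arm == "NF" and day == 1:
            base_iaf = log.sessions[-1].iaf_estimate
            state = init_threshold(float(np.clip(base_iaf, *ALPHA_BAND)))
        # day-2 initial threshold carries over from day 1 (automated stand-in
        # for the experimenter's manual between-session assignment)
        for block in range(1, protocol.blocks_per_day + 1):
            label = f"day{day}-block{block}"
            ep_iaf, ep_valid, amps, gts = [], [], [], []
            for ep in range(protocol.epochs_per_block):
                iaf, valid, amp_full, gt = run_training_epoch(label)
                if iaf is not None:
                    ep_iaf.append(iaf)
                    ep_valid.append(valid)
                amps.append(amp_full)
                gts.append(gt)
                rest(protocol.epoch_rest_s)
            ratio = None
            if ep_iaf:
                block_series = IAFTimeSeries(
                    np.arange(sum(len(v) for v in ep_iaf)) * dt,
                    np.concatenate(ep_iaf), np.concatenate(ep_valid),
                    tuple(channel_set), dt)
                if arm == "NF":
                    ratio = block_exceed_ratio(block_series, state)
            log.sessions.append(SessionRecord(
                label, "block", float(np.mean(gts)),
                threshold=state.threshold if state is not None else None,
                exceed_ratio=ratio, amplitudes=amps,
                valid_fraction=float(np.mean(np.concatenate(ep_valid)))
                if ep_valid else None))
            if arm == "NF" and ratio is not None:
                state = adapt_threshold(state, ratio, block_counter)
            block_counter += 1
        run_baseline(f"day{day}-post", analyze=want_analysis(f"day{day}-post"))
    if state is not None:
        log.threshold_history = state.history
    return log
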