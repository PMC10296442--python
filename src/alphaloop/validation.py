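"""Parameter-recovery and calibration experiments on synthetic cohorts.

These are the package's headline validations: because no human data ship
with it, every claim is checked by recovery of known ground truth —
estimator accuracy for programmed alpha peaks, the closed-loop NF-vs-Sham
contrast for responsive participants, power/type-I calibration of the
behavioral-score correlation and the trajectory mixed ANOVA.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .behavior import correlate_score_iaf, metric_table_scores
from .feedback import SessionProtocol, run_protocol
from .offline import cog_iaf, offline_spectrum, segment_epoch, trajectory_stats
from .realtime import realtime_stream
from .synth import (BehavioralCohortSpec, add_alpha, alpha_gain_profile,
                    alpha_rms_for_snr, generate_background,
                    generate_behavioral_cohort,
                    generate_iaf_trajectory_table, make_cohort)
from .montage import OCCIPITOPARIETAL


def estimator_recovery(peaks: tuple[float, ...] = (8.0, 9.5, 10.4, 11.8),
                       snr: float = 60.0, seed: int = 0,
                       offline_duration_s: float = 120.0,
                       realtime_duration_s: float = 60.0) -> dict:
    """Recover programmed constant alpha peaks with both estimators.

    For each peak frequency a recording with that constant ground-truth
    peak is generated; the offline estimate is the occipitoparietal mean
    center-of-gravity IAF over ``offline_duration_s`` of data, the
    real-time estimate is the mean of the valid stream updates over
    ``realtime_duration_s``. Returns per-peak absolute errors in Hz.
    """
    root = np.random.SeedSequence(seed)
    out = {"peaks": list(peaks), "offline": [], "realtime": [],
           "offline_err": [], "realtime_err": [], "snr": snr}
    chans = OCCIPITOPARIETAL
    for f0, child in zip(peaks, root.spawn(len(peaks))):
        rng = np.random.default_rng(child)
        amp = alpha_rms_for_snr(snr) * alpha_gain_profile(chans)
        rec_off = generate_background(offline_duration_s, channel_names=chans,
                                      seed=rng)
        rec_off = add_alpha(rec_off, np.array([f0]), amp, seed=rng)
        spec = offline_spectrum(segment_epoch(rec_off), rec_off.fs)
        off = float(np.mean([cog_iaf(spec, channel=c) for c in range(len(chans))]))
        rec_rt = generate_background(realtime_duration_s, channel_names=chans,
                                     seed=rng)
        rec_rt = add_alpha(rec_rt, np.array([f0]), amp, seed=rng)
        series = realtime_stream(rec_rt)
        rt = float(np.mean(series.iaf[series.valid]))
        out["offline"].append(off)
        out["realtime"].append(rt)
        out["offline_err"].append(abs(off - f0))
        out["realtime_err"].append(abs(rt - f0))
    return out


def closed_loop_contrast(n_pairs: int = 50, responsiveness: float = 0.004,
                         seed: int = 0,
                         protocol: SessionProtocol = SessionProtocol()) -> dict:
    """NF vs Sham ground-truth IAF gain over paired closed-loop runs.

    Each pair shares a seed stream: one responsive participant runs the
    full two-day protocol with real (contingent) feedback, a second,
    equally responsive participant receives the replayed amplitude trace
    of a donor responder. The contrast is the one-sided rank-sum test on
    the post-minus-pre ground-truth baseline gains.
    """
    root = np.random.SeedSequence(seed)
    donor_seed, nf_seed, sham_seed = root.spawn(3)
    donor = make_cohort(1, seed=int(donor_seed.generate_state(1)[0] % 2**31),
                        responsiveness=responsiveness)[0]
    trace = run_protocol(donor, protocol, arm="NF",
                         seed=int(donor_seed.generate_state(1)[0] % 2**31),
                         baseline_analysis="init").amplitude_traces()
    nf_states = nf_seed.generate_state(2 * n_pairs) % 2**31
    sham_states = sham_seed.generate_state(2 * n_pairs) % 2**31
    nf_gains, sham_gains = [], []
    for i in range(n_pairs):
        p_nf = make_cohort(1, seed=int(nf_states[2 * i]),
                           responsiveness=responsiveness)[0]
        nf_gains.append(run_protocol(
            p_nf, protocol, arm="NF", seed=int(nf_states[2 * i + 1]),
            baseline_analysis="init").gt_gain())
        p_sh = make_cohort(1, seed=int(sham_states[2 * i]),
                           responsiveness=responsiveness)[0]
        sham_gains.append(run_protocol(
            p_sh, protocol, arm="Sham", sham_trace=trace,
            seed=int(sham_states[2 * i + 1]),
            baseline_analysis="none").gt_gain())
    u, p = stats.mannwhitneyu(nf_gains, sham_gains, alternative="greater")
    return {"nf_gains": np.array(nf_gains), "sham_gains": np.array(sham_gains),
            "nf_mean": float(np.mean(nf_gains)),
            "sham_mean": float(np.mean(sham_gains)),
            "ranksum_p": float(p), "n_pairs": n_pairs}


def correlation_recovery(n_cohorts: int = 500, n_subjects: int = 16,
                         coupling: float = 5.0, delta_mean: float = 0.2,
                         delta_sd: float = 0.1, alpha: float = 0.05,
                         seed: int = 0) -> dict:
    """Score-vs-IAF-change Spearman correlation across replicate cohorts.

    Per cohort, cumulative IAF deltas are drawn N(delta_mean, delta_sd),
    the behavioral table is generated with the given coupling, and the
    Spearman correlation between behavioral scores and deltas is computed.
    Reports the fraction of cohorts with ``rho > 0`` and the fraction with
    two-sided ``p < alpha`` (the type-I rate when ``coupling = 0``).
    """
    root = np.random.SeedSequence(seed)
    states = root.generate_state(2 * n_cohorts) % 2**31
    pos = 0
    rejections = 0
    used = 0
    for i in range(n_cohorts):
        rng = np.random.default_rng(int(states[2 * i]))
        deltas = rng.normal(delta_mean, delta_sd, n_subjects)
        spec = BehavioralCohortSpec(n_subjects=n_subjects, coupling=coupling,
                                    rng_seed=int(states[2 * i + 1]))
        table = generate_behavioral_cohort(spec, deltas)
        scores = metric_table_scores(table)["score"].to_numpy()
        if np.ptp(scores) == 0:
            continue  # degenerate cohort: correlation undefined
        rho, p = correlate_score_iaf(scores, deltas)
        used += 1
        pos += rho > 0
        rejections += p < alpha
    return {"n_cohorts": used, "frac_rho_positive": pos / used,
            "frac_significant": rejections / used, "coupling": coupling}


def anova_calibration(n_reps: int = 500, n_per_arm: int = 16,
                      drift_nf: float = 0.0, noise_sd: float = 0.05,
                      n_sessions: int = 14, alpha: float = 0.05,
                      seed: int = 0) -> dict:
    """Mixed-ANOVA interaction rejection rate on generated trajectories.

    With ``drift_nf = 0`` both arms are exchangeable and the rejection rate
    estimates the type-I error (should sit at ``alpha``); with a positive
    programmed NF drift it estimates power.
    """
    states = np.random.SeedSequence(seed).generate_state(n_reps) % 2**31
    rejections = 0
    pvals = np.empty(n_reps)
    for i in range(n_reps):
        table = generate_iaf_trajectory_table(
            n_per_arm, n_sessions=n_sessions, drift_nf=drift_nf,
            noise_sd=noise_sd, seed=int(states[i]))
        res = trajectory_stats(table, pairwise=False)
        pvals[i] = res["interaction_p"]
        rejections += pvals[i] < alpha
    return {"n_reps": n_reps, "rejection_rate": rejections / n_reps,
            "pvals": pvals, "drift_nf": drift_nf}
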