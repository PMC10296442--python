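"""Cognitive task generation, scoring, and the behavioral group statistics.

Tasks: a mental-rotation (MR) test (15-trial blocks, 50% matched pairs,
8 s response window) and visuospatial n-back tests (eight stimulus slots;
one 28-trial 1-back block, two 30-trial 3-back blocks, 33% targets).
Metrics per task: accuracy, mean reaction time, and reaction control (the
standard deviation of single-trial reaction times). The behavioral score
counts strictly improved metrics from pre to post; it is correlated with
the cumulative baseline-IAF change by Spearman rank correlation. Group
contrasts use the Mann-Whitney U test (baseline) and the Friedman test
(pre/post change).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import BEHAVIORAL_METRICS

MR_RESPONSE_WINDOW_S = 8.0  # stimulus presentation doubles as the deadline
N_SLOTS = 8


@dataclass
class TrialRecord:
    """One task trial: stimulus, ground truth, and (optional) response."""

    task: str                      # "mr" | "1back" | "3back"
    stimulus: int                  # MR: 1 matched / 0 mismatched; n-back: slot 0-7
    is_target: bool                # MR: pair matched; n-back: lag-n match
    response: str | None = None    # MR: "match"/"mismatch"; n-back: "press"/None
    rt_s: float | None = None

    def __post_init__(self) -> None:
        if (self.rt_s is None) != (self.response is None):
            raise ValueError("rt_s must be present iff a response was made")


@dataclass
class MetricSet:
    """Task metrics: accuracy, mean RT, and reaction control (RT SD).

    Fields are ``None`` when undefined for the task (1-back accuracy) or
    degenerate (fewer than one/two responded trials for RT statistics).
    """

    accuracy: float | None
    rt_mean: float | None
    reaction_control: float | None
    n_trials: int = 0
    n_responded: int = 0


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def gen_mr_block(trials: int = 15, match_prob: float = 0.5,
                 seed: int | np.random.Generator | None = None) -> list[TrialRecord]:
    """Mental-rotation trial stubs with an exact matched-pair count.

    The matched count is ``round(match_prob * trials)`` (half-up; 8 of 15
    at 50%) rather than per-trial coin flips, so the printed probability
    holds exactly in every block; the order is shuffled by the seed.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_match = _round_half_up(match_prob * trials)
    flags = np.zeros(trials, dtype=bool)
    flags[:n_match] = True
    rng.shuffle(flags)
    return [TrialRecord("mr", int(f), bool(f)) for f in flags]


def gen_nback_block(n: int, trials: int, target_prob: float = 1 / 3,
                    seed: int | np.random.Generator | None = None,
                    n_slots: int = N_SLOTS) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-random n-back slot sequence with an exact target count.

    Targets (lag-``n`` repeats) number ``round(target_prob * (trials - n))``
    and occupy positions ``>= n``; non-target trials explicitly avoid
    accidental lag-``n`` matches. Returns ``(slots, is_target)``.
    """
    if trials <= n:
        raise ValueError("trials must exceed n")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eligible = trials - n
    n_targets = _round_half_up(target_prob * eligible)
    target_pos = rng.choice(np.arange(n, trials), size=n_targets, replace=False)
    is_target = np.zeros(trials, dtype=bool)
    is_target[target_pos] = True
    slots = np.empty(trials, dtype=int)
    for i in range(trials):
        if i < n:
            slots[i] = rng.integers(n_slots)
        elif is_target[i]:
            slots[i] = slots[i - n]
        else:
            choices = np.delete(np.arange(n_slots), slots[i - n])
            slots[i] = rng.choice(choices)
    return slots, is_target


def nback_records(slots: np.ndarray, is_target: np.ndarray,
                  task: str) -> list[TrialRecord]:
    """Wrap a generated n-back sequence into trial records."""
    return [TrialRecord(task, int(s), bool(t)) for s, t in zip(slots, is_target)]


def simulate_responses(records: list[TrialRecord], accuracy: float = 0.8,
                       rt_median_s: float = 0.7, rt_sigma: float = 0.3,
                       seed: int | np.random.Generator | None = None,
                       ) -> list[TrialRecord]:
    """Attach simulated human responses to trial stubs.

    Per trial the intended response is correct with probability
    ``accuracy`` (Bernoulli); reaction times are log-normal with median
    ``rt_median_s`` and log-scale ``rt_sigma``. MR trials always receive a
    forced choice (match/mismatch); n-back trials receive a press for an
    intended "target" judgement and no response otherwise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for r in records:
        correct = rng.random() < accuracy
        rt = float(rng.lognormal(math.log(rt_median_s), rt_sigma))
        if r.task == "mr":
            truth = "match" if r.is_target else "mismatch"
            wrong = "mismatch" if r.is_target else "match"
            resp = truth if correct else wrong
            if rt > MR_RESPONSE_WINDOW_S:
                resp, rt = None, None
            out.append(TrialRecord(r.task, r.stimulus, r.is_target, resp, rt))
        else:
            press = r.is_target if correct else not r.is_target
            out.append(TrialRecord(r.task, r.stimulus, r.is_target,
                                   "press" if press else None,
                                   rt if press else None))
    return out


def _rt_stats(rts: list[float]) -> tuple[float | None, float | None]:
    if len(rts) == 0:
        return None, None
    mean = float(np.mean(rts))
    if len(rts) < 2:
        return mean, None  # reaction control undefined for a single response
    return mean, float(np.std(rts, ddof=1))


def score_mr(records: list[TrialRecord]) -> MetricSet:
    """MR metrics: accuracy = correct/total (no response counts as an
    error); RT statistics over responded trials within the 8 s window."""
    if not records:
        raise ValueError("empty trial list")
    correct = 0
    rts = []
    for r in records:
        truth = "match" if r.is_target else "mismatch"
        responded = r.response is not None and r.rt_s is not None \
            and r.rt_s <= MR_RESPONSE_WINDOW_S
        if responded:
            rts.append(r.rt_s)
            if r.response == truth:
                correct += 1
    rt_mean, rc = _rt_stats(rts)
    return MetricSet(correct / len(records), rt_mean, rc, len(records), len(rts))


def score_1back(records: list[TrialRecord]) -> MetricSet:
    """1-back metrics: reaction time and reaction control only (accuracy is
    not a reported 1-back metric)."""
    if not records:
        raise ValueError("empty trial list")
    rts = [r.rt_s for r in records if r.response is not None]
    rt_mean, rc = _rt_stats(rts)
    return MetricSet(None, rt_mean, rc, len(records), len(rts))


def score_3back(records: list[TrialRecord]) -> MetricSet:
    """3-back metrics with the hits + correct-rejections accuracy.

    accuracy = ((targets - misses) + (distractors - false alarms)) / total;
    RT statistics cover responded trials.
    """
    if not records:
        raise ValueError("empty trial list")
    n = len(records)
    targets = sum(r.is_target for r in records)
    distractors = n - targets
    misses = sum(r.is_target and r.response is None for r in records)
    false_alarms = sum((not r.is_target) and r.response is not None for r in records)
    accuracy = ((targets - misses) + (distractors - false_alarms)) / n
    rts = [r.rt_s for r in records if r.response is not None]
    rt_mean, rc = _rt_stats(rts)
    return MetricSet(accuracy, rt_mean, rc, n, len(rts))


# ---------------------------------------------------------------------------
# behavioral score and correlations
# ---------------------------------------------------------------------------

def behavioral_score(pre: dict[tuple[str, str], float | None],
                     post: dict[tuple[str, str], float | None]) -> int:
    """Count of the 8 task metrics strictly improved from pre to post.

    Keys are ``(task, metric)`` pairs covering the full inventory: MR
    accuracy/RT/reaction-control, 1-back RT/reaction-control, 3-back
    accuracy/RT/reaction-control. Improvement is strict in the beneficial
    direction (accuracy up; RT and reaction control down); ties do not
    count. Metric sets must match exactly.
    """
    expected = {(t, m) for t, m, _ in BEHAVIORAL_METRICS}
    if set(pre) != expected or set(post) != expected:
        raise ValueError("pre/post must each provide exactly the 8 task metrics")
    score = 0
    for task, metric, direction in BEHAVIORAL_METRICS:
        a, b = pre[(task, metric)], post[(task, metric)]
        if (a is None) != (b is None):
            raise ValueError(f"metric {(task, metric)} defined on one side only")
        if a is None:
            continue
        if direction * (b - a) > 0:
            score += 1
    return score


def metric_table_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Behavioral scores from a tidy cohort table (one row per subject x
    metric with ``pre``/``post`` columns, as produced by the cohort
    generator)."""
    rows = []
    for subj, sub in table.groupby("subject"):
        pre = {(r.task, r.metric): r.pre for r in sub.itertuples()}
        post = {(r.task, r.metric): r.post for r in sub.itertuples()}
        rows.append((subj, behavioral_score(pre, post)))
    return pd.DataFrame(rows, columns=["subject", "score"])


def correlate_score_iaf(scores: np.ndarray, iaf_deltas: np.ndarray,
                        ) -> tuple[float, float]:
    """Spearman rank correlation (tie-corrected midranks, two-sided p)
    between behavioral scores and cumulative baseline-IAF changes."""
    s = np.asarray(scores, dtype=float)
    d = np.asarray(iaf_deltas, dtype=float)
    if s.shape != d.shape or s.ndim != 1:
        raise ValueError("scores and deltas must be equal-length vectors")
    if s.size < 4:
        raise ValueError("need >= 4 paired observations")
    if np.ptp(s) == 0 or np.ptp(d) == 0:
        raise ValueError("undefined correlation: constant input vector")
    rho, p = stats.spearmanr(s, d)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

def friedman_prepost(pre: np.ndarray, post: np.ndarray) -> tuple[float, float]:
    """Friedman test for two repeated conditions (tie-corrected).

    With two conditions the tie-corrected Friedman statistic reduces to
    ``Q = (b - c)^2 / (b + c)`` where ``b``/``c`` count subjects whose value
    rose/fell (ties drop out), referred to chi-square with 1 df. Returns
    ``(Q, p)``; with no untied pairs ``Q = 0`` and ``p = 1``.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or pre.size < 2:
        raise ValueError("pre and post must be equal-length vectors, n >= 2")
    b = int(np.sum(post > pre))
    c = int(np.sum(post < pre))
    if b + c == 0:
        return 0.0, 1.0
    q = (b - c) ** 2 / (b + c)
    return float(q), float(stats.chi2.sf(q, df=1))


def group_tests(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Between-arm baseline and within-arm pre/post tests per metric.

    ``tables`` maps arm label -> tidy cohort table (columns ``subject,
    task, metric, pre, post``). Per metric: a two-sided Mann-Whitney U test
    (midranks) compares the arms' pre-training values, and a pre/post
    Friedman test is run within each arm. Requires >= 2 subjects per arm.
    """
    if len(tables) != 2:
        raise ValueError("need exactly two arms")
    arms = list(tables)
    for arm, tab in tables.items():
        if tab["subject"].nunique() < 2:
            raise ValueError(f"arm {arm!r} needs >= 2 subjects")
    rows = []
    for task, metric, _ in BEHAVIORAL_METRICS:
        vals = {}
        for arm in arms:
            sub = tables[arm]
            sel = sub[(sub["task"] == task) & (sub["metric"] == metric)]
            sel = sel.sort_values("subject")
            vals[arm] = (sel["pre"].to_numpy(), sel["post"].to_numpy())
        u, u_p = stats.mannwhitneyu(vals[arms[0]][0], vals[arms[1]][0],
                                    alternative="two-sided")
        row = {"task": task, "metric": metric,
               "mannwhitney_U": float(u), "mannwhitney_p": float(u_p)}
        for arm in arms:
            q, p = friedman_prepost(*vals[arm])
            row[f"friedman_Q_{arm}"] = q
            row[f"friedman_p_{arm}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
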