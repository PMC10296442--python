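"""Offline spectral pipeline and IAF-trajectory group statistics.

Epoch recordings are segmented by a 2-s, 50%-overlapping sliding window,
detrended with a time-domain Savitzky-Golay filter, zero-padded to a
0.01 Hz frequency resolution, and averaged into a high-resolution power
spectrum. The offline IAF is the center-of-gravity frequency of the 7-13 Hz
band; alpha amplitude is summarized by the power ratio between the
individual alpha band (IAF +/- 1 Hz) and the 3-30 Hz spectrum. Topographic
maps resample channel values onto a head grid with Mitchell-Netravali
cubic kernels; session trajectories are compared between arms with a mixed
ANOVA (group x time) plus Holm-Bonferroni pairwise contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.fft
from scipy import stats
from scipy.signal import get_window, savgol_filter

from .montage import CENTRAL, ELECTRODE_XY, OCCIPITOPARIETAL
from .recording import EEGRecording

ALPHA_BAND = (7.0, 13.0)
BROAD_BAND = (3.0, 30.0)


@dataclass
class OfflineSpectrum:
    """Segment-averaged power spectrum on a 0.01 Hz grid."""

    freqs: np.ndarray
    power: np.ndarray          # (n_channels, n_freqs)
    n_segments: int
    resolution: float = 0.01

    def __post_init__(self) -> None:
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")


def segment_epoch(rec: EEGRecording | np.ndarray, win_s: float = 2.0,
                  overlap: float = 0.5, fs: float | None = None) -> np.ndarray:
    """Split an epoch into 2-s, 50%-overlapping segments.

    Returns ``(n_segments, n_channels, n_win)``; a trailing partial window
    is dropped.
    """
    if isinstance(rec, EEGRecording):
        data, fs = rec.data, rec.fs
    else:
        data = np.atleast_2d(np.asarray(rec, dtype=float))
        if fs is None:
            raise ValueError("fs required for array input")
    n_win = int(round(win_s * fs))
    hop = int(round(win_s * (1.0 - overlap) * fs))
    if data.shape[-1] < n_win:
        raise ValueError("insufficient data: epoch shorter than one window")
    n_seg = (data.shape[-1] - n_win) // hop + 1
    starts = np.arange(n_seg) * hop
    segs = data[:, starts[:, None] + np.arange(n_win)]
    return np.swapaxes(segs, 0, 1)


def offline_spectrum(segments: np.ndarray, fs: float = 256.0,
                     sg_window_s: float = 0.5, sg_order: int = 2,
                     target_res: float = 0.01) -> OfflineSpectrum:
    """Detrended, zero-padded, segment-averaged power spectrum.

    Each segment's smooth Savitzky-Golay trend (time-domain window
    ``sg_window_s``, order ``sg_order``) is subtracted — a gentle high-pass
    consistent with the 2 Hz acquisition high-pass — then the segment is
    Hann-tapered, zero-padded to ``1/target_res`` seconds (100 s, giving a
    0.01 Hz grid), and the magnitude-squared spectra are averaged.
    """
    segs = np.asarray(segments, dtype=float)
    if segs.ndim == 2:
        segs = segs[:, None, :]
    if segs.ndim != 3 or segs.shape[0] < 1:
        raise ValueError("need >= 1 segment of shape (n_channels, n_win)")
    n_seg, n_ch, n_win = segs.shape
    sg_bins = int(round(sg_window_s * fs))
    if sg_bins % 2 == 0:
        sg_bins += 1
    trend = savgol_filter(segs, sg_bins, sg_order, axis=-1)
    detrended = segs - trend
    w = get_window("hann", n_win, fftbins=True)
    n_pad = int(round(fs / target_res))
    buf = np.zeros((n_seg * n_ch, n_pad))
    buf[:, :n_win] = (detrended * w).reshape(-1, n_win)
    X = scipy.fft.rfft(buf, axis=-1)
    power = (X.real ** 2 + X.imag ** 2) * (2.0 / (fs * np.sum(w ** 2)))
    power = power.reshape(n_seg, n_ch, -1).mean(axis=0)
    freqs = np.arange(power.shape[-1]) * target_res
    return OfflineSpectrum(freqs, power, n_seg, target_res)


def _band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    eps = 1e-9
    return (freqs >= band[0] - eps) & (freqs <= band[1] + eps)


def cog_iaf(spec: OfflineSpectrum, band: tuple[float, float] = ALPHA_BAND,
            channel: int = 0) -> float:
    """Center-of-gravity IAF: sum(f * P(f)) / sum(P(f)) over the band."""
    m = _band_mask(spec.freqs, band)
    p = spec.power[channel][m]
    total = p.sum()
    if total <= 0:
        raise ValueError("undefined IAF: zero band power")
    return float(np.sum(spec.freqs[m] * p) / total)


def alpha_ratio(spec: OfflineSpectrum, iaf: float, channel: int = 0,
                half_width: float = 1.0,
                broad_band: tuple[float, float] = BROAD_BAND) -> float:
    """Individual alpha power ratio: power in IAF +/- 1 Hz over 3-30 Hz."""
    if not (ALPHA_BAND[0] <= iaf <= ALPHA_BAND[1]):
        raise ValueError("iaf must lie in [7, 13] Hz")
    p = spec.power[channel]
    num = p[_band_mask(spec.freqs, (iaf - half_width, iaf + half_width))].sum()
    den = p[_band_mask(spec.freqs, broad_band)].sum()
    if den <= 0:
        raise ValueError("undefined ratio: zero 3-30 Hz power")
    return float(num / den)


@dataclass
class SessionSummary:
    """Per-channel and channel-group IAF/alpha-ratio summary of one session."""

    label: str
    iaf_cog: dict[str, float]
    alpha_ratio: dict[str, float]
    occipitoparietal_iaf: float
    central_iaf: float
    occipitoparietal_ratio: float
    central_ratio: float
    n_epochs: int


def session_summary(recordings: list[EEGRecording], label: str = "",
                    win_s: float = 2.0, overlap: float = 0.5) -> SessionSummary:
    """Average the offline per-channel IAF and alpha ratio across the
    session's recording epochs, with occipitoparietal and central group
    means computed from the per-channel averages."""
    if len(recordings) == 0:
        raise ValueError("need >= 1 epoch per session")
    names = recordings[0].channel_names
    iafs = np.zeros((len(recordings), len(names)))
    ratios = np.zeros_like(iafs)
    for e, rec in enumerate(recordings):
        spec = offline_spectrum(segment_epoch(rec, win_s, overlap), rec.fs)
        for c in range(len(names)):
            iafs[e, c] = cog_iaf(spec, channel=c)
            ratios[e, c] = alpha_ratio(spec, iafs[e, c], channel=c)
    iaf_mean = iafs.mean(axis=0)
    ratio_mean = ratios.mean(axis=0)
    by_ch_iaf = dict(zip(names, iaf_mean))
    by_ch_ratio = dict(zip(names, ratio_mean))

    def group_mean(vals: dict[str, float], group: tuple[str, ...]) -> float:
        present = [vals[c] for c in group if c in vals]
        return float(np.mean(present)) if present else float("nan")

    return SessionSummary(
        label, by_ch_iaf, by_ch_ratio,
        group_mean(by_ch_iaf, OCCIPITOPARIETAL), group_mean(by_ch_iaf, CENTRAL),
        group_mean(by_ch_ratio, OCCIPITOPARIETAL), group_mean(by_ch_ratio, CENTRAL),
        len(recordings))


# ---------------------------------------------------------------------------
# topographic interpolation
# ---------------------------------------------------------------------------

def mitchell_netravali_kernel(x: np.ndarray, b: float = 1 / 3,
                              c: float = 1 / 3) -> np.ndarray:
    """The Mitchell-Netravali piecewise-cubic kernel (support |x| < 2)."""
    ax = np.abs(np.asarray(x, dtype=float))
    out = np.zeros_like(ax)
    inner = ax < 1
    outer = (ax >= 1) & (ax < 2)
    a1 = ax[inner]
    out[inner] = ((12 - 9 * b - 6 * c) * a1 ** 3 +
                  (-18 + 12 * b + 6 * c) * a1 ** 2 + (6 - 2 * b)) / 6.0
    a2 = ax[outer]
    out[outer] = ((-b - 6 * c) * a2 ** 3 + (6 * b + 30 * c) * a2 ** 2 +
                  (-12 * b - 48 * c) * a2 + (8 * b + 24 * c)) / 6.0
    return out


def topographic_map(channel_values: dict[str, float],
                    coords: dict[str, tuple[float, float]] | None = None,
                    b: float = 1 / 3, c: float = 1 / 3,
                    grid_n: int = 64, kernel_scale: float = 0.75,
                    mask_radius: float | None = None,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample scattered electrode values onto a regular head grid.

    Weights are separable Mitchell-Netravali kernels of scale
    ``kernel_scale`` (head radii), normalized to sum to one at every grid
    point so constant inputs reproduce a constant field. The map is masked
    (NaN) outside ``mask_radius`` (default: just beyond the outermost
    electrode ring — normalized kernel weights extrapolate badly past the
    electrodes), outside the unit head circle, and wherever the weight sum
    degenerates. Returns ``(grid_x, grid_y, field)`` with ``field[i, j]``
    at ``(grid_y[i], grid_x[j])``.
    """
    if len(channel_values) < 3:
        raise ValueError("need >= 3 electrodes with values")
    if coords is None:
        coords = ELECTRODE_XY
    missing = [ch for ch in channel_values if ch not in coords]
    if missing:
        raise KeyError(f"no coordinates for channels: {missing}")
    chans = list(channel_values)
    vals = np.array([channel_values[ch] for ch in chans])
    ex = np.array([coords[ch][0] for ch in chans])
    ey = np.array([coords[ch][1] for ch in chans])
    gx = np.linspace(-1.0, 1.0, grid_n)
    gy = np.linspace(-1.0, 1.0, grid_n)
    wx = mitchell_netravali_kernel((gx[:, None] - ex[None, :]) / kernel_scale, b, c)
    wy = mitchell_netravali_kernel((gy[:, None] - ey[None, :]) / kernel_scale, b, c)
    w = wy[:, None, :] * wx[None, :, :]          # (ny, nx, n_el)
    wsum = w.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        field = (w @ vals) / wsum
    if mask_radius is None:
        mask_radius = float(np.max(np.hypot(ex, ey)))
    yy, xx = np.meshgrid(gy, gx, indexing="ij")
    field[xx ** 2 + yy ** 2 > mask_radius ** 2] = np.nan
    peak_w = mitchell_netravali_kernel(np.zeros(1), b, c)[0] ** 2
    field[wsum < 0.05 * peak_w] = np.nan
    return gx, gy, field


# ---------------------------------------------------------------------------
# trajectory statistics
# ---------------------------------------------------------------------------

def trajectory_stats(table: pd.DataFrame, pairwise: bool = True,
                     sphericity_alpha: float = 0.05,
                     correction: str | bool = "auto") -> dict:
    """Mixed ANOVA of the per-session IAF trajectories.

    ``table`` is long-form with columns ``subject, group, session, iaf``
    and must be balanced (every subject measured in every session, at least
    two subjects per arm). Reports the group and time main effects and the
    time x group interaction; the interaction p-value is
    Greenhouse-Geisser-corrected when Mauchly's test rejects sphericity
    (``correction="auto"``). A Shapiro-Wilk normality gate on the
    cell-demeaned residuals and, optionally, Holm-Bonferroni-corrected
    pairwise session contrasts per group are included.
    """
    import pingouin as pg

    required = {"subject", "group", "session", "iaf"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    counts = table.groupby(["subject", "session"], observed=True).size()
    if (counts != 1).any():
        raise ValueError("unbalanced table: need exactly one value per cell")
    n_sessions = table["session"].nunique()
    per_subj = table.groupby("subject", observed=True)["session"].nunique()
    if (per_subj != n_sessions).any():
        raise ValueError("unbalanced table: missing sessions for some subjects")
    groups = table["group"].unique()
    if len(groups) != 2:
        raise ValueError("need exactly two arms")
    if table.groupby("group", observed=True)["subject"].nunique().min() < 2:
        raise ValueError("need >= 2 subjects per arm")

    resid = table["iaf"] - table.groupby(["group", "session"], observed=True)[
        "iaf"].transform("mean")
    sw_stat, sw_p = stats.shapiro(resid.to_numpy())

    use_corr = correction if isinstance(correction, bool) else True
    aov = pg.mixed_anova(data=table, dv="iaf", within="session",
                         subject="subject", between="group",
                         correction=use_corr)
    aov = aov.set_index("Source")
    inter = aov.loc["Interaction"]
    time_row = aov.loc["session"]
    sphericity_ok = True
    eps = float("nan")
    if use_corr and "sphericity" in aov.columns:
        val = time_row.get("sphericity")
        sphericity_ok = bool(val) if val == val else True
        eps = float(time_row.get("eps", float("nan")))
    apply_gg = (not sphericity_ok) if correction == "auto" else bool(correction)

    def pick_p(row) -> float:
        # Greenhouse-Geisser: rescale both df by the session-effect epsilon
        if apply_gg and eps == eps:
            return float(stats.f.sf(row["F"], row["DF1"] * eps, row["DF2"] * eps))
        return float(row["p_unc"])

    out = {
        "anova": aov.reset_index(),
        "shapiro": {"stat": float(sw_stat), "p": float(sw_p)},
        "sphericity_ok": sphericity_ok,
        "gg_epsilon": eps,
        "gg_applied": apply_gg,
        "group_F": float(aov.loc["group", "F"]),
        "group_p": float(aov.loc["group", "p_unc"]),
        "time_F": float(time_row["F"]),
        "time_p": pick_p(time_row),
        "interaction_F": float(inter["F"]),
        "interaction_p": pick_p(inter),
    }
    if pairwise:
        pw = {}
        for g in groups:
            sub = table[table["group"] == g]
            pw[str(g)] = pg.pairwise_tests(
                data=sub, dv="iaf", within="session", subject="subject",
                padjust="holm")
        out["pairwise"] = pw
    return out
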