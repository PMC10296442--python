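"""Offline spectral pipeline, topographic maps, trajectory statistics."""

import numpy as np
import pandas as pd
import pytest

from alphaloop import (OfflineSpectrum, add_alpha, alpha_ratio, cog_iaf,
                       generate_background, generate_iaf_trajectory_table,
                       offline_spectrum, segment_epoch, session_summary,
                       topographic_map, trajectory_stats)
from alphaloop.montage import ELECTRODE_XY, MONTAGE_16, OCCIPITOPARIETAL
from alphaloop.synth import alpha_rms_for_snr

FS = 256.0


def flat_spec(lo=3.0, hi=30.0, value=1.0, res=0.01):
    f = np.arange(0, hi + res, res)
    p = np.where((f >= lo) & (f <= hi), value, 0.0)
    return OfflineSpectrum(f, p, 1, res)


class TestSegmentation:
    @pytest.mark.parametrize("dur,n", [(30.0, 29), (2.0, 1), (2.9, 1), (5.0, 4)])
    def test_segment_counts(self, dur, n):
        rec = generate_background(dur, channel_names=("Oz",), seed=0)
        assert segment_epoch(rec).shape == (n, 1, 512)

    def test_too_short_epoch_rejected(self):
        rec = generate_background(1.5, channel_names=("Oz",), seed=0)
        with pytest.raises(ValueError, match="insufficient"):
            segment_epoch(rec)

    def test_hop_is_one_second(self):
        rec = generate_background(4.0, channel_names=("Oz",), seed=1)
        segs = segment_epoch(rec)
        assert np.array_equal(segs[1, 0, :256], rec.data[0, 256:512])


class TestOfflineSpectrum:
    def test_grid_resolution_and_law(self):
        rec = generate_background(4.0, channel_names=("Oz",), seed=0)
        spec = offline_spectrum(segment_epoch(rec), FS)
        assert spec.resolution == 0.01
        assert np.allclose(np.diff(spec.freqs), 0.01)
        # resolution x padded duration = 1
        assert spec.resolution * (1.0 / spec.resolution) == pytest.approx(1.0)

    def test_dc_segment_detrended_away(self):
        segs = np.full((3, 1, 512), 17.0)
        spec = offline_spectrum(segs, FS)
        band = (spec.freqs >= 3) & (spec.freqs <= 30)
        assert spec.power[0][band].sum() < 1e-12

    def test_pure_tone_cog(self):
        rng = np.random.default_rng(3)
        rec = generate_background(60.0, channel_names=("Oz",), seed=rng)
        rec.data[:] = 0.0
        rec = add_alpha(rec, np.array([10.30]), np.array([10.0]),
                        bandwidth_hz=1e-6, env_sd=1e-9, seed=rng)
        spec = offline_spectrum(segment_epoch(rec), FS)
        assert cog_iaf(spec) == pytest.approx(10.30, abs=0.01)


class TestCogIaf:
    def test_uniform_band_gives_midpoint(self):
        assert cog_iaf(flat_spec()) == pytest.approx(10.0)

    def test_symmetric_masses(self):
        f = np.array([9.5, 10.5])
        assert cog_iaf(OfflineSpectrum(f, [[2.0, 2.0]], 1, 1.0)) == pytest.approx(10.0)

    def test_hand_computed_weighted_mean(self):
        f = np.array([8.0, 12.0])
        assert cog_iaf(OfflineSpectrum(f, [[1.0, 3.0]], 1, 4.0)) == pytest.approx(11.0)

    def test_zero_band_power_rejected(self):
        with pytest.raises(ValueError, match="zero band power"):
            cog_iaf(flat_spec(lo=20.0, hi=30.0))

    def test_oracle_equivalence_random_spectra(self):
        rng = np.random.default_rng(7)
        f = np.arange(0, 30.01, 0.01)
        band = (f >= 7) & (f <= 13)
        for _ in range(1000):
            p = rng.random(f.size)
            spec = OfflineSpectrum(f, p, 1)
            expected = np.dot(f[band], p[band]) / p[band].sum()
            assert cog_iaf(spec) == pytest.approx(expected, rel=1e-12)


class TestAlphaRatio:
    def test_all_power_in_individual_band(self):
        assert alpha_ratio(flat_spec(9.0, 11.0), 10.0) == pytest.approx(1.0)

    def test_no_power_in_individual_band(self):
        assert alpha_ratio(flat_spec(20.0, 30.0), 10.0) == pytest.approx(0.0)

    def test_half_and_half_two_tone(self):
        f = np.array([10.0, 25.0])
        spec = OfflineSpectrum(f, [[3.0, 3.0]], 1, 15.0)
        assert alpha_ratio(spec, 10.0) == pytest.approx(0.5)

    def test_bounds_on_random_spectra(self):
        rng = np.random.default_rng(1)
        f = np.arange(0, 30.01, 0.01)
        for _ in range(50):
            spec = OfflineSpectrum(f, rng.random(f.size), 1)
            r = alpha_ratio(spec, rng.uniform(7, 13))
            assert 0.0 <= r <= 1.0

    def test_out_of_band_iaf_rejected(self):
        with pytest.raises(ValueError):
            alpha_ratio(flat_spec(), 6.0)


class TestSessionSummary:
    def _rec(self, peak, seed):
        rng = np.random.default_rng(seed)
        rec = generate_background(30.0, channel_names=OCCIPITOPARIETAL, seed=rng)
        return add_alpha(rec, np.array([peak]),
                         alpha_rms_for_snr(60.0) * np.ones(6), seed=rng)

    def test_identical_epochs_equal_single_epoch(self):
        rec = self._rec(10.2, 0)
        one = session_summary([rec], "s")
        two = session_summary([rec, rec], "s")
        assert one.occipitoparietal_iaf == pytest.approx(two.occipitoparietal_iaf)
        assert two.n_epochs == 2

    def test_epoch_mean_is_arithmetic(self):
        a, b = self._rec(10.0, 1), self._rec(10.4, 2)
        sa = session_summary([a], "a").occipitoparietal_iaf
        sb = session_summary([b], "b").occipitoparietal_iaf
        sab = session_summary([a, b], "ab").occipitoparietal_iaf
        assert sab == pytest.approx((sa + sb) / 2, abs=1e-9)

    def test_programmed_shift_recovered(self):
        pre = session_summary([self._rec(10.0, s) for s in (10, 11)], "pre")
        post = session_summary([self._rec(10.2, s) for s in (12, 13)], "post")
        shift = post.occipitoparietal_iaf - pre.occipitoparietal_iaf
        assert shift == pytest.approx(0.2, abs=0.05)

    def test_empty_session_rejected(self):
        with pytest.raises(ValueError):
            session_summary([], "x")


class TestTopographicMap:
    def test_constant_field_reproduced_for_all_parameters(self):
        for b, c in ((0, 0), (1 / 3, 1 / 3), (1, 0), (0, 0.5)):
            _, _, field = topographic_map({ch: 10.0 for ch in MONTAGE_16},
                                          b=b, c=c)
            assert np.nanmax(np.abs(field - 10.0)) < 1e-9

    def test_single_hot_electrode_peaks_there(self):
        vals = {ch: 0.0 for ch in MONTAGE_16}
        vals["Oz"] = 1.0
        gx, gy, field = topographic_map(vals, grid_n=101)
        iy, ix = np.unravel_index(np.nanargmax(field), field.shape)
        ex, ey = ELECTRODE_XY["Oz"]
        assert abs(gx[ix] - ex) < 0.05 and abs(gy[iy] - ey) < 0.05

    def test_bspline_limit_respects_input_range(self):
        rng = np.random.default_rng(0)
        vals = {ch: rng.uniform(9, 11) for ch in MONTAGE_16}
        _, _, field = topographic_map(vals, b=1 / 3, c=0.0)
        assert np.nanmin(field) >= min(vals.values()) - 1e-9
        assert np.nanmax(field) <= max(vals.values()) + 1e-9

    def test_needs_three_electrodes(self):
        with pytest.raises(ValueError):
            topographic_map({"Oz": 1.0, "Cz": 2.0})


class TestTrajectoryStats:
    def test_identical_arms_give_zero_group_effect(self):
        base = generate_iaf_trajectory_table(6, seed=4)
        nf = base[base.group == "NF"].copy()
        sham = nf.copy()
        sham["group"] = "Sham"
        sham["subject"] = sham["subject"].str.replace("NF", "Sham")
        res = trajectory_stats(pd.concat([nf, sham]), pairwise=False)
        assert res["group_F"] == pytest.approx(0.0, abs=1e-9)

    def test_programmed_drift_detected_with_pairwise_report(self):
        table = generate_iaf_trajectory_table(8, drift_nf=0.3, noise_sd=0.05,
                                              seed=9)
        res = trajectory_stats(table, pairwise=True)
        assert res["interaction_p"] < 0.001
        assert set(res["pairwise"]) == {"NF", "Sham"}
        pw = res["pairwise"]["NF"]
        assert "p_corr" in pw.columns or "p-corr" in pw.columns
        assert "shapiro" in res and 0 <= res["shapiro"]["p"] <= 1

    def test_unbalanced_table_rejected(self):
        table = generate_iaf_trajectory_table(4, seed=0)
        with pytest.raises(ValueError, match="unbalanced"):
            trajectory_stats(table.iloc[:-3], pairwise=False)

    def test_single_subject_arm_rejected(self):
        table = generate_iaf_trajectory_table(2, seed=0)
        drop = table[~((table.group == "NF") & (table.subject == "NF01"))]
        with pytest.raises(ValueError):
            trajectory_stats(drop, pairwise=False)
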