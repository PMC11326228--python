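"""Analysis chain: Teager operator, driven responses, effect times,
diffusion trend, dB normalization, group statistics, DPOAE sweeps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cochstream import neuro, synthdata
from cochstream.neuro import (SEQUENCE_SECONDS, ResponseTimeCourse,
                              compare_groups, dpoae_level_sweep,
                              driven_response_curve, effect_time,
                              effect_time_db, effect_time_from_db,
                              fit_diffusion_trend, make_schedule,
                              segment_responses, teager_energy)
from cochstream.travelwave import PlaceFrequencyMap


class TestTeagerEnergy:
    def test_constant_signal_vanishes(self):
        assert np.abs(teager_energy(np.full(100, 3.7))).max() == 0.0

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.floats(min_value=0.05, max_value=3.0),
           st.floats(min_value=0.1, max_value=5.0),
           st.floats(min_value=0.0, max_value=6.28))
    def test_sinusoid_identity(self, omega, amp, phase):
        n = np.arange(500)
        psi = teager_energy(amp * np.sin(omega * n + phase))
        expected = amp**2 * np.sin(omega) ** 2
        assert np.abs(psi - expected).max() < 1e-10 * max(expected, 1.0)

    def test_quadratic_amplitude_scaling(self):
        x = np.sin(0.3 * np.arange(200))
        np.testing.assert_allclose(teager_energy(2 * x), 4 * teager_energy(x),
                                   rtol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            teager_energy(np.array([1.0, 2.0]))


class TestSegmentation:
    def test_one_sequence_has_52_segments(self):
        sched = make_schedule(1, (9.0, 3.8, 1.8))
        assert len(sched) == 52
        assert (sched.label == "noise").sum() == 48
        assert (sched.label == "pause").sum() == 1
        assert (sched.label == "tone").sum() == 3
        assert sched.t_end.max() == pytest.approx(57.2)
        # segments tile the sequence without overlap
        assert np.allclose(sched.t_start.to_numpy()[1:],
                           sched.t_end.to_numpy()[:-1])

    def test_three_sequences_in_171p6_seconds(self):
        sched = make_schedule(3, (9.0, 3.8, 1.8))
        assert sched.sequence.nunique() == 3
        assert sched.t_end.max() == pytest.approx(3 * SEQUENCE_SECONDS)

    def test_truncated_final_sequence_excluded(self):
        cfg = synthdata.SynthConfig(seed=0, n_sequences=4, pre_sequences=1)
        rec, _ = synthdata.synth_recording(cfg)
        cut = int(3.5 * SEQUENCE_SECONDS * rec.fs)
        rec.waveform = rec.waveform[:, :cut]
        seg = segment_responses(rec)
        assert set(seg.sequence.unique()) == {0, 1, 2}
        assert seg.attrs["dropped_sequences"] == [3]

    def test_too_short_recording_rejected(self):
        cfg = synthdata.SynthConfig(seed=0, n_sequences=3, pre_sequences=1)
        rec, _ = synthdata.synth_recording(cfg)
        rec.waveform = rec.waveform[:, :int(30 * rec.fs)]
        with pytest.raises(ValueError):
            segment_responses(rec)


class TestDrivenResponse:
    def test_synthetic_levels_recovered(self):
        cfg = synthdata.SynthConfig(seed=5, n_sequences=6, pre_sequences=6 - 1,
                                    t_e_min=(90.0, 90.0, 90.0))
        rec, _ = synthdata.synth_recording(cfg)
        seg = segment_responses(rec)
        curves = driven_response_curve(seg, t_drug=rec.t_drug)
        for cv in curves.values():
            # driven level = 4.0 with ~2% standard error per sequence
            assert cv.driven.mean() == pytest.approx(cfg.driven_level,
                                                     rel=0.05)

    def test_normalized_baseline_is_one(self):
        cfg = synthdata.SynthConfig(seed=2, pre_sequences=4)
        rec, _ = synthdata.synth_recording(cfg)
        curves = driven_response_curve(segment_responses(rec),
                                       t_drug=rec.t_drug)
        for cv in curves.values():
            pre = cv.t < cv.t_drug
            assert cv.normalized[pre].mean() == pytest.approx(1.0, abs=1e-9)

    def test_no_baseline_sequences_rejected(self):
        cfg = synthdata.SynthConfig(seed=2)
        rec, _ = synthdata.synth_recording(cfg)
        with pytest.raises(ValueError, match="normalize"):
            driven_response_curve(segment_responses(rec), t_drug=-10.0)


def _curve(t_min, values, t_drug=0.0, cf=4.0):
    t = np.asarray(t_min, dtype=float) * 60.0
    v = np.asarray(values, dtype=float)
    return ResponseTimeCourse(t=t, driven=v, normalized=v, baseline=1.0,
                              cf_khz=cf, t_drug=t_drug)


class TestEffectTime:
    def test_step_drop_interpolated(self):
        t = np.arange(10.0)
        y = np.where(t < 5, 1.0, 0.0)
        est = effect_time(_curve(t, y))
        # linear interpolation hits 0.75 a quarter of the way from t=4 to 5
        assert est.t_e == pytest.approx((4 + 0.25) * 60.0)
        assert est.crossed and not est.bimodal

    def test_never_crossing_flagged(self):
        est = effect_time(_curve(np.arange(8.0), np.linspace(1.0, 0.8, 8)))
        assert not est.crossed
        assert est.t_e is None

    def test_transient_dip_is_skipped_by_sustain_rule(self):
        y = np.array([1.0, 1.0, 0.6, 1.0, 1.0, 0.5, 0.4, 0.3])
        est = effect_time(_curve(np.arange(8.0), y))
        # first sustained run starts at index 5, not at the single dip
        assert est.t_e > 4 * 60.0

    def test_bimodal_rebound_flagged(self):
        y = np.array([1.0, 0.5, 0.4, 0.9, 0.95, 0.5, 0.3, 0.2])
        est = effect_time(_curve(np.arange(8.0), y))
        assert est.crossed and est.bimodal

    def test_recovers_ground_truth_within_one_sequence(self):
        pf = PlaceFrequencyMap()
        hits = 0
        n_rep = 6
        for seed in range(n_rep):
            cfg = synthdata.SynthConfig(seed=seed)
            rec, truth = synthdata.synth_recording(cfg)
            curves = driven_response_curve(segment_responses(rec),
                                           t_drug=rec.t_drug)
            for ch, cv in curves.items():
                est = effect_time(cv, pf_map=pf)
                t_true = truth.loc[truth.channel == ch, "t_e_s"].iloc[0]
                hits += est.crossed and abs(est.t_e - t_true) <= SEQUENCE_SECONDS
        assert hits >= 0.9 * n_rep * 3

    def test_two_step_decay_sets_bimodal_flag(self):
        cfg = synthdata.SynthConfig(seed=3, two_step_fraction=1.0,
                                    t_e_min=(4.0, 8.0, 10.0),
                                    n_sequences=36)
        rec, truth = synthdata.synth_recording(cfg)
        curves = driven_response_curve(segment_responses(rec),
                                       t_drug=rec.t_drug)
        ch = int(truth.loc[truth.two_step, "channel"].iloc[0])
        est = effect_time(curves[ch])
        assert est.crossed


class TestDiffusionTrend:
    def test_exact_recovery_without_noise(self):
        x = np.linspace(1e-3, 10e-3, 12)
        a0 = 9.4e7
        tm = fit_diffusion_trend(a0 * x**2, x)
        assert tm.a == pytest.approx(a0, rel=1e-10)

    def test_monte_carlo_recovery_at_study_sample_size(self):
        good = 0
        for seed in range(200):
            cfg = synthdata.SynthConfig(seed=seed)
            ds = synthdata.synth_effect_time_dataset(cfg, n=48)
            tm = fit_diffusion_trend(ds.t_e_s, ds.x_m)
            good += abs(tm.a / cfg.trend_a - 1) < 0.10
        assert good >= 0.95 * 200

    def test_d_eff_consistent_with_closed_form(self):
        from scipy.special import erfcinv
        x = np.linspace(1e-3, 10e-3, 8)
        D = 8e-10
        a0 = 1.0 / (4 * D * erfcinv(0.01) ** 2)
        tm = fit_diffusion_trend(a0 * x**2, x)
        assert tm.d_eff(0.01) == pytest.approx(D, rel=1e-9)

    @pytest.mark.parametrize("t,x", [
        ([100.0], [1e-3]),
        ([100.0, 200.0], [1e-3, 2e-3]),
        ([1.0, 2.0, 3.0], [1e-3, 1e-3, 1e-3]),
    ])
    def test_degenerate_inputs_rejected(self, t, x):
        with pytest.raises(ValueError):
            fit_diffusion_trend(np.array(t), np.array(x))


class TestDbNormalization:
    def test_reference_values(self):
        assert effect_time_db(10.0, 10.0) == 0.0
        assert effect_time_db(20.0, 10.0) == pytest.approx(6.0206, abs=1e-4)
        assert effect_time_db(1.0, 10.0) == pytest.approx(-20.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(min_value=1e-2, max_value=1e5),
           st.floats(min_value=1e-2, max_value=1e5))
    def test_exact_inversion(self, t_e, t_trend):
        db = effect_time_db(t_e, t_trend)
        assert effect_time_from_db(db, t_trend) == pytest.approx(t_e,
                                                                 rel=1e-12)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            effect_time_db(0.0, 1.0)
        with pytest.raises(ValueError):
            effect_time_db(1.0, -2.0)


class TestGroupComparison:
    def test_identical_groups_p_one(self):
        v = np.array([0.0, 1.0, 2.0, 3.0])
        res = compare_groups(v, v.copy())
        assert res.p_value == pytest.approx(1.0)
        assert res.t_stat == pytest.approx(0.0)

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.1, 10)
        b = rng.normal(10.0, 0.1, 10)
        res = compare_groups(a, b)
        assert res.p_value < 1e-6
        assert res.ci95_a[0] < res.mean_a < res.ci95_a[1]

    def test_single_member_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups(np.array([1.0]), np.array([1.0, 2.0]))


def _dpoae_sweep(fs=20000.0, level_db=30.0, noise_db=None, seed=0,
                 n_pres=10):
    """Synthetic swept DPOAE: primaries plus an optional 2f1-f2 chirp of
    known RMS level (dB re 20 uPa)."""
    dur, f2a, f2b, ratio = 4.0, 500.0, 10000.0, 1.25
    t = np.arange(int(dur * fs)) / fs
    rate = (f2b - f2a) / dur
    def chirp(scale):
        ph = 2 * np.pi * scale * (f2a * t + 0.5 * rate * t**2)
        return np.cos(ph)
    sig = 0.02 * chirp(1.0) + 0.02 * chirp(1.0 / ratio)   # primaries
    if level_db is not None:
        amp = 20e-6 * 10 ** (level_db / 20.0) * np.sqrt(2.0)
        sig = sig + amp * chirp(2.0 / ratio - 1.0)
    rng = np.random.default_rng(seed)
    pres = np.tile(sig, (n_pres, 1))
    if noise_db is not None:
        sigma = 20e-6 * 10 ** (noise_db / 20.0)
        pres = pres + rng.normal(0.0, sigma, pres.shape)
    return pres, fs


class TestDpoaeSweep:
    def test_known_component_recovered_within_1_db(self):
        pres, fs = _dpoae_sweep(level_db=30.0)
        out = dpoae_level_sweep(pres, fs)
        interior = out[(out.t > 0.4) & (out.t < 3.6)]
        assert np.abs(interior.level_db - 30.0).max() < 1.0

    def test_identical_presentations_null_at_floor(self):
        pres, fs = _dpoae_sweep(level_db=30.0)
        out = dpoae_level_sweep(pres, fs)
        assert out.noise_floor_db.max() < -200.0     # numerical floor

    def test_no_component_stays_at_noise_floor(self):
        pres, fs = _dpoae_sweep(level_db=None, noise_db=20.0, seed=4)
        out = dpoae_level_sweep(pres, fs)
        interior = out[(out.t > 0.4) & (out.t < 3.6)]
        # absent a distortion component the level estimate is itself noise:
        # on average it cannot sit above the even/odd noise floor
        assert interior.level_db.mean() <= interior.noise_floor_db.mean() + 3.0
        assert (interior.level_db <= interior.noise_floor_db + 3.0).mean() > 0.5

    def test_single_presentation_has_no_floor(self):
        pres, fs = _dpoae_sweep(level_db=30.0, n_pres=1)
        out = dpoae_level_sweep(pres, fs)
        assert out.noise_floor_db.isna().all()
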