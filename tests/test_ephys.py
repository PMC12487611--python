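"""Patch-clamp analysis procedures on constructed and generated sweeps."""

import numpy as np
import pytest

from kcmodel.ephys import (AnalysisError, SweepSet, detect_spikes,
                           fast_inward_events, nachbac_current,
                           nachbac_decay_tau, nachbac_potential_metrics,
                           passive_from_sweep, spike_features,
                           steady_state_decomposition)
from kcmodel.synth import FastCellConfig, gen_cc_recording, gen_vc_recording

RATE = 50.0  # kHz


def _sweepset(v, steps, mode="current", onset=100.0, offset=1100.0):
    v = np.atleast_2d(v)
    t = np.arange(v.shape[1]) / RATE
    return SweepSet(t=t, data=v, step_values=np.asarray(steps, float),
                    onset=onset, offset=offset, mode=mode, sample_rate_khz=RATE)


class TestSweepSet:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(AnalysisError):
            SweepSet(t=np.arange(10.0), data=np.zeros((2, 9)),
                     step_values=np.array([1.0, 2.0]), onset=1, offset=5,
                     mode="current", sample_rate_khz=1.0)

    def test_save_load_roundtrip(self, tmp_path):
        ss, _ = gen_cc_recording(FastCellConfig(), steps_pa=(-20, 20),
                                 duration_ms=300, onset_ms=50, offset_ms=250,
                                 seed=0)
        p = tmp_path / "sweeps.tsv"
        ss.save(p)
        back = SweepSet.load(p)
        assert np.allclose(back.data, ss.data)
        assert back.mode == ss.mode
        assert back.onset == ss.onset


class TestPassiveFromSweep:
    def test_capacitance_is_tau_over_r(self):
        # exact RC sweep: R = 1 GOhm, tau = 20 ms -> C = 20 pF
        t = np.arange(0, 1200, 1 / RATE)
        I = -20.0
        v = np.full_like(t, -60.0)
        m = (t >= 100) & (t < 1100)
        v[m] += I * 1.0 * (1 - np.exp(-(t[m] - 100) / 20.0))
        ss = _sweepset(v, [I])
        p = passive_from_sweep(ss)
        assert p.input_resistance_gohm == pytest.approx(1.0, rel=1e-3)
        assert p.tau_ms == pytest.approx(20.0, rel=1e-3)
        assert p.capacitance_pf == pytest.approx(20.0, rel=1e-2)
        assert not p.qc_excluded

    def test_generator_roundtrip_within_1pct(self):
        cfg = FastCellConfig(R_gohm=1.5, C_pf=25.0, spike_amp_mV=0.0)
        ss, _ = gen_cc_recording(cfg, steps_pa=(-40, -20), seed=1)
        p = passive_from_sweep(ss)
        assert p.input_resistance_gohm == pytest.approx(1.5, rel=0.01)
        assert p.capacitance_pf == pytest.approx(25.0, rel=0.01)

    def test_low_input_resistance_flagged(self):
        cfg = FastCellConfig(R_gohm=0.5, C_pf=25.0, spike_amp_mV=0.0)
        ss, _ = gen_cc_recording(cfg, steps_pa=(-40,), seed=1)
        assert passive_from_sweep(ss).qc_excluded

    def test_no_negative_step_rejected(self):
        ss, _ = gen_cc_recording(FastCellConfig(), steps_pa=(20, 40), seed=1)
        with pytest.raises(AnalysisError):
            passive_from_sweep(ss)


def _piecewise_spike(t, t_on, t_peak, v_base=-55.0, amp=20.0):
    """Piecewise-exponential spike: flat baseline, then a saturating
    (concave) upstroke from t_on, then an exponential decay.  The first
    derivative jumps at t_on, so the second derivative peaks exactly at
    the onset kink."""
    v = np.full_like(t, v_base)
    tau_r = (t_peak - t_on) / 2.0
    rise = (t >= t_on) & (t <= t_peak)
    norm = 1 - np.exp(-(t_peak - t_on) / tau_r)
    v[rise] += amp * (1 - np.exp(-(t[rise] - t_on) / tau_r)) / norm
    after = t > t_peak
    v[after] += amp * np.exp(-(t[after] - t_peak) / 2.0)
    return v


class TestSpikeFeatures:
    def test_onset_recovered_on_constructed_waveform(self):
        t = np.arange(0, 1200, 1 / RATE)
        t_on, t_peak = 500.0, 503.0
        v = _piecewise_spike(t, t_on, t_peak)
        ss = _sweepset(v, [30.0])
        sf = spike_features(ss)
        assert len(sf.table) == 1
        assert sf.table.t_onset_ms.iloc[0] == pytest.approx(t_on, abs=0.2)
        assert sf.min_voltage_to_spike_mv == pytest.approx(
            sf.table.v_onset_mv.iloc[0])

    def test_height_scales_linearly(self):
        t = np.arange(0, 1200, 1 / RATE)
        h1 = spike_features(_sweepset(
            _piecewise_spike(t, 500, 503, amp=10.0), [30.0])).table.height_mv[0]
        h2 = spike_features(_sweepset(
            _piecewise_spike(t, 500, 503, amp=20.0), [30.0])).table.height_mv[0]
        assert h2 == pytest.approx(2 * h1, rel=0.02)

    def test_pure_ramp_yields_no_onset(self):
        t = np.arange(0, 1200, 1 / RATE)
        v = -60 + 0.02 * t  # no inflection, one "peak" at the end
        ss = _sweepset(v, [30.0])
        sf = spike_features(ss, spike_times={30.0: [600.0]})
        assert len(sf.table) == 0

    def test_edge_spike_skipped_with_warning(self):
        t = np.arange(0, 1200, 1 / RATE)
        v = _piecewise_spike(t, 5.0, 8.0)
        ss = _sweepset(v, [30.0])
        with pytest.warns(UserWarning, match="edge"):
            sf = spike_features(ss, spike_times={30.0: [8.0]})
        assert sf.n_skipped_edge == 1


class TestNachbacCurrent:
    def test_median_filter_rejects_fast_transients(self):
        # slow inward current with a flat -100 pA top + 5 pA fast blips
        t = np.arange(0, 1200, 1 / RATE)
        i = np.zeros_like(t)
        m = (t >= 100) & (t < 1100)
        top = (t >= 120) & (t < 280)
        decay = (t >= 280) & (t < 1100)
        i[(t >= 100) & (t < 120)] = -100.0 * (t[(t >= 100) & (t < 120)] - 100) / 20
        i[top] = -100.0
        i[decay] = -100.0 * np.exp(-(t[decay] - 280) / 150.0)
        rng = np.random.default_rng(0)
        for t0 in np.arange(150, 1050, 97):
            sel = (t >= t0) & (t < t0 + 1.0)
            i[sel] += 5.0 * np.sin(np.pi * (t[sel] - t0))
        ss = _sweepset(i, [-40.0], mode="voltage")
        cur = nachbac_current(ss, capacitance_pf=20.0)
        assert cur.peak_pa.iloc[0] == pytest.approx(-100.0, abs=2.0)

    def test_flat_trace_zero(self):
        t = np.arange(0, 1200, 1 / RATE)
        ss = _sweepset(np.full_like(t, 3.0), [-40.0], mode="voltage")
        cur = nachbac_current(ss, 20.0)
        assert cur.peak_pa.iloc[0] == 0.0

    def test_density_is_peak_over_capacitance(self):
        t = np.arange(0, 1200, 1 / RATE)
        i = np.zeros_like(t)
        m = (t >= 150) & (t < 400)
        i[m] = -200.0
        ss = _sweepset(i, [-40.0], mode="voltage")
        cur = nachbac_current(ss, capacitance_pf=20.0)
        assert cur.density_pa_pf.iloc[0] == pytest.approx(-10.0, rel=0.02)

    def test_short_step_rejected(self):
        t = np.arange(0, 300, 1 / RATE)
        ss = SweepSet(t=t, data=np.zeros((1, len(t))),
                      step_values=np.array([-40.0]), onset=50, offset=150,
                      mode="voltage", sample_rate_khz=RATE)
        with pytest.raises(AnalysisError):
            nachbac_current(ss, 20.0)


class TestNachbacPotential:
    def test_square_plateau_hand_computed(self):
        # 20 mV plateau over the first 500 ms of a 1 s step -> mean 10 mV
        t = np.arange(0, 1200, 1 / RATE)
        v = np.full_like(t, -60.0)
        v[(t >= 100) & (t < 600)] += 20.0
        ss = _sweepset(v, [40.0])
        m = nachbac_potential_metrics(ss)
        assert m.crossed
        assert m.avg_depolarization_mv == pytest.approx(10.0, abs=0.1)

    def test_flat_trace_zero_with_flag(self):
        t = np.arange(0, 1200, 1 / RATE)
        ss = _sweepset(np.full_like(t, -60.0), [40.0])
        m = nachbac_potential_metrics(ss)
        assert m.avg_depolarization_mv == 0.0
        assert not m.crossed

    def test_invariant_to_constant_offset(self):
        t = np.arange(0, 1200, 1 / RATE)
        v = np.full_like(t, -60.0)
        v[(t >= 100) & (t < 600)] += 20.0
        m1 = nachbac_potential_metrics(_sweepset(v, [40.0]))
        m2 = nachbac_potential_metrics(_sweepset(v + 13.0, [40.0]))
        assert m1.avg_depolarization_mv == pytest.approx(
            m2.avg_depolarization_mv)


class TestDecayTau:
    def test_pure_exponential_recovered(self):
        t = np.arange(0, 1200, 1 / RATE)
        i = np.zeros_like(t)
        m = (t >= 100) & (t < 1100)
        i[m] = -100.0 * np.exp(-(t[m] - 100) / 50.0)
        ss = _sweepset(i, [-40.0], mode="voltage")
        fit = nachbac_decay_tau(ss, capacitance_pf=20.0)
        assert fit.fit_ok and not fit.excluded
        assert fit.tau_ms == pytest.approx(50.0, rel=0.01)

    def test_generator_roundtrip_180ms(self):
        ss, _ = gen_vc_recording(
            FastCellConfig(nachbac_peak_pa=-120, nachbac_tau_ms=180), seed=3)
        fit = nachbac_decay_tau(ss, capacitance_pf=25.0)
        assert fit.tau_ms == pytest.approx(180.0, abs=9.0)

    def test_noisy_roundtrip_within_5pct(self):
        ss, _ = gen_vc_recording(
            FastCellConfig(nachbac_peak_pa=-120, nachbac_tau_ms=180,
                           noise_sd=2.4), seed=3)
        fit = nachbac_decay_tau(ss, capacitance_pf=25.0)
        assert fit.tau_ms == pytest.approx(180.0, rel=0.05)

    def test_low_density_cell_excluded(self):
        # peak density ~1 pA/pF is below the 2 pA/pF inclusion threshold
        ss, _ = gen_vc_recording(
            FastCellConfig(nachbac_peak_pa=-40, C_pf=25.0), seed=3)
        fit = nachbac_decay_tau(ss, capacitance_pf=25.0)
        assert fit.excluded


class TestFastEvents:
    def test_three_embedded_events_detected(self):
        cfg = FastCellConfig(n_events_per_step=3, event_amp_pa=-10,
                             nachbac_peak_pa=0.0)
        ss, truth = gen_vc_recording(cfg, steps_mv=(-20.0,), seed=4)
        ev = fast_inward_events(ss, smooth_ms=0.8)
        assert len(ev.table) == 3
        got = np.sort(ev.table.t_trough_ms.to_numpy())
        want = np.sort(truth.params["event_times"]["-20.0"])
        assert np.allclose(got, want, atol=2.0)

    def test_noise_alone_produces_no_events(self):
        cfg = FastCellConfig(n_events_per_step=0, nachbac_peak_pa=0.0,
                             noise_sd=0.2)
        ss, _ = gen_vc_recording(cfg, steps_mv=(-20.0, 0.0), seed=5)
        assert len(fast_inward_events(ss).table) == 0

    def test_small_trough_fails_prominence_rule(self):
        cfg = FastCellConfig(n_events_per_step=2, event_amp_pa=-1.0,
                             nachbac_peak_pa=0.0)
        ss, _ = gen_vc_recording(cfg, steps_mv=(-20.0,), seed=6)
        assert len(fast_inward_events(ss, smooth_ms=0.8).table) == 0

    @pytest.mark.parametrize("param", ["deriv_threshold_pa_ms",
                                       "deriv_prominence_pa_ms",
                                       "trough_prominence_pa"])
    def test_count_monotone_in_thresholds(self, param):
        cfg = FastCellConfig(n_events_per_step=3, event_amp_pa=-10,
                             nachbac_peak_pa=0.0, noise_sd=0.3)
        ss, _ = gen_vc_recording(cfg, steps_mv=(-20.0, 0.0), seed=7)
        base = {"deriv_threshold_pa_ms": 2.5, "deriv_prominence_pa_ms": 5.0,
                "trough_prominence_pa": 2.0}
        counts = []
        for scale in (0.5, 1.0, 2.0, 4.0):
            kw = dict(base)
            kw[param] = base[param] * scale
            counts.append(len(fast_inward_events(ss, smooth_ms=0.8, **kw).table))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestDecomposition:
    def test_ratio_rule_direct_substitution(self):
        # ratio 0.2 at the -50 mV reference scales I_Np,obs(-30) = -50 pA
        # to a residual of -10 pA
        t = np.arange(0, 1300, 1 / RATE)
        steps = np.arange(-100.0, 31.0, 10.0)
        data = np.zeros((len(steps), len(t)))
        g = 0.5  # nS leak
        in_step = (t >= 100) & (t < 1100)
        for k, V in enumerate(steps):
            data[k, in_step] = g * (V + 60.0)
            if V in (-50.0, -30.0):
                peak = -40.0 if V == -50.0 else -50.0
                td = t[in_step] - 100.0
                shape = np.clip(td / 20.0, 0, 1) * np.exp(
                    -np.maximum(td - 20.0, 0.0) / 2000.0)
                data[k, in_step] += peak * shape
        ss = SweepSet(t=t, data=data, step_values=steps, onset=100,
                      offset=1100, mode="voltage", sample_rate_khz=RATE)
        dec = steady_state_decomposition(ss)
        row50 = dec.table[dec.table.step_mv == -50.0].iloc[0]
        row30 = dec.table[dec.table.step_mv == -30.0].iloc[0]
        ratio = dec.ratio_nr_np
        assert dec.reference_step_mv == -50.0
        assert row30.i_nr_pa == pytest.approx(ratio * row30.i_np_obs_pa)
        assert row30.i_nr_pa / row30.i_np_obs_pa == pytest.approx(ratio)

    def test_ohmic_cell_has_no_voltage_gated_current(self):
        ss, _ = gen_vc_recording(FastCellConfig(nachbac_peak_pa=0.0), seed=7)
        dec = steady_state_decomposition(ss)
        assert dec.no_nachbac
        assert np.max(np.abs(dec.table.i_k_pa)) < 0.5

    def test_known_outward_conductance_recovered(self):
        cfg = FastCellConfig(nachbac_peak_pa=-120, nachbac_tau_ms=200,
                             shab_gmax_ns=0.8)
        ss, truth = gen_vc_recording(cfg, seed=9)
        dec = steady_state_decomposition(ss)
        for _, row in dec.table.iterrows():
            true_ik = truth.params["i_k_pa"].get(str(row.step_mv), 0.0)
            if true_ik > 10.0:
                assert row.i_k_pa == pytest.approx(true_ik, rel=0.10)

    def test_identity_holds_exactly(self):
        ss, _ = gen_vc_recording(
            FastCellConfig(nachbac_peak_pa=-120, shab_gmax_ns=0.5), seed=10)
        dec = steady_state_decomposition(ss)
        resid = dec.table.i_obs_pa - (dec.table.i_leak_pa + dec.table.i_nr_pa
                                      + dec.table.i_k_pa)
        assert np.max(np.abs(resid)) < 1e-9

    def test_baseline_drift_flags_cell(self):
        ss, _ = gen_vc_recording(FastCellConfig(nachbac_peak_pa=0.0), seed=11)
        post = ss.t >= ss.offset + 5.0
        ss.data[3, post] += 40.0  # post-step baseline jumps by 40 pA
        dec = steady_state_decomposition(ss)
        assert dec.cell_excluded

    def test_time_shift_invariance(self):
        # shifting the whole protocol in time leaves per-step metrics alone
        cfg = FastCellConfig(nachbac_peak_pa=-120)
        ss, _ = gen_vc_recording(cfg, onset_ms=100.0, offset_ms=1100.0,
                                 duration_ms=1300.0, seed=12)
        ss2, _ = gen_vc_recording(cfg, onset_ms=150.0, offset_ms=1150.0,
                                  duration_ms=1350.0, seed=12)
        c1 = nachbac_current(ss, 20.0)
        c2 = nachbac_current(ss2, 20.0)
        assert np.allclose(c1.peak_pa, c2.peak_pa, atol=1e-6)
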