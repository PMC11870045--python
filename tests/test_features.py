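import dataclasses
import math

import numpy as np
import pytest

from conftest import (
    DT_MS,
    RATE,
    oracle_spike_count,
    paste_spikes,
    stepset_from_counts,
)
from patchkit import synth
from patchkit.features import (
    SpikeEvent,
    ThresholdError,
    analyze_sweep,
    assemble_features,
    detect_spikes,
    excitability_scalars,
    passive_properties,
    spike_shape,
    spike_threshold,
)
from patchkit.io import SweepSet
from patchkit.pipeline import extract_cell
from patchkit.synth import NeuronSpec, Protocol, simulate_sweeps


def triangle_spike(baseline=-40.0, peak=20.0, slope_per_sample=1.0,
                   decay_floor=-50.0, pad=200):
    """A triangular AP with exact closed-form shape values."""
    up = np.arange(baseline, peak + 1e-9, slope_per_sample)
    down = np.arange(peak - slope_per_sample, decay_floor - 1e-9,
                     -slope_per_sample)
    v = np.concatenate([
        np.full(pad, baseline), up, down, np.full(pad, decay_floor)
    ])
    peak_idx = pad + len(up) - 1
    return v, peak_idx


class TestDetectSpikes:
    def test_flat_trace_has_no_events(self):
        assert detect_spikes(np.full(4000, -70.0), DT_MS) == []

    def test_subthreshold_hump_excluded_by_definition(self):
        t = np.arange(4000)
        v = -70.0 + 60.0 * np.exp(-((t - 2000) / 300.0) ** 2)  # peaks -10
        assert v.max() < 0
        assert detect_spikes(v, DT_MS) == []

    def test_pasted_waveforms_found_within_one_sample(self):
        idx = [1000, 3000, 5200, 9000, 12000]
        v = paste_spikes(-70.0, 15000, idx)
        shape = synth.ApShape()
        n_rise = int(round(shape.rise_ms / DT_MS))
        events = detect_spikes(v, DT_MS)
        assert len(events) == len(idx)
        for ev, i0 in zip(events, idx):
            assert abs(ev.peak_index - (i0 + n_rise)) <= 1

    def test_count_equals_bruteforce_scan_on_random_sweeps(self):
        """Spike counts agree with an independent 0 mV-crossing scan."""
        rng = np.random.default_rng(2024)
        wf_len = len(synth.ap_waveform(synth.ApShape(), -41.0, -52.0, DT_MS))
        for _ in range(200):
            n = 10000
            k = int(rng.integers(0, 6))
            starts = np.sort(rng.choice(
                np.arange(100, n - wf_len - 100, wf_len + 20), size=k,
                replace=False,
            )) if k else []
            v = paste_spikes(-70.0, n, starts)
            v += rng.normal(0.0, 2.0, n) * (v < -60)  # noise off-spike only
            got = len(detect_spikes(v, DT_MS))
            assert got == oracle_spike_count(v) == k


class TestSpikeThreshold:
    def test_quadratic_ramp_closed_form(self):
        """V = -60 + 2.5 t^2 has dV/dt = 5t: criterion met at t = 1 ms,
        V = -57.5 mV."""
        t = np.arange(0.0, 8.0, DT_MS)
        v = -60.0 + 2.5 * t ** 2
        ev = SpikeEvent(peak_index=len(v) - 1,
                        peak_time_ms=(len(v) - 1) * DT_MS,
                        peak_V_mV=v[-1])
        thr = spike_threshold(v, ev, DT_MS)
        assert ev.threshold_time_ms == pytest.approx(1.0, abs=DT_MS / 2)
        assert thr == pytest.approx(-57.5, abs=0.01)

    def test_instantaneous_step_thresholds_at_onset(self):
        v = np.concatenate([np.full(400, -60.0), np.full(200, 20.0)])
        ev = SpikeEvent(peak_index=400, peak_time_ms=400 * DT_MS,
                        peak_V_mV=20.0)
        thr = spike_threshold(v, ev, DT_MS)
        assert thr == -60.0
        assert ev.threshold_time_ms == pytest.approx(399 * DT_MS)

    def test_criterion_never_met_raises(self):
        v = np.linspace(-70.0, -69.0, 2000)  # 0.01 mV/ms ramp
        ev = SpikeEvent(peak_index=1999, peak_time_ms=1999 * DT_MS,
                        peak_V_mV=v[-1])
        with pytest.raises(ThresholdError):
            spike_threshold(v, ev, DT_MS)

    def test_simulated_onset_recovered_within_one_sample(self, presets):
        """Pasted-waveform onset (the generator's V_cut) is recovered."""
        spec = presets["type1"]
        proto = Protocol(kind="step_family", step_max_pA=100.0)
        ss = simulate_sweeps(spec, proto, "control", seed=4)
        true_ms = ss.true_spike_times_ms(ss.n_sweeps - 1)
        events = analyze_sweep(ss.sweeps[-1], DT_MS)
        assert len(events) == len(true_ms)
        for ev, t0 in zip(events, true_ms):
            assert abs(ev.threshold_time_ms - t0) <= DT_MS
            assert ev.threshold_V_mV == pytest.approx(spec.V_cut, abs=1e-9)


class TestSpikeShape:
    def test_triangle_closed_form(self):
        v, peak_idx = triangle_spike()
        ev = SpikeEvent(peak_index=peak_idx,
                        peak_time_ms=peak_idx * DT_MS, peak_V_mV=20.0)
        ev.threshold_V_mV = -40.0
        amp, hw, fahp, mahp = spike_shape(v, ev, DT_MS)
        assert amp == pytest.approx(60.0)
        # symmetric 1 mV/sample slopes: half-max span = amplitude samples
        assert hw == pytest.approx(60.0 * DT_MS, abs=1e-9)

    def test_monotone_decay_gives_unclamped_negative_mahp(self):
        v, peak_idx = triangle_spike(decay_floor=-35.0)
        ev = SpikeEvent(peak_index=peak_idx,
                        peak_time_ms=peak_idx * DT_MS, peak_V_mV=20.0)
        ev.threshold_V_mV = -40.0
        _, _, fahp, mahp = spike_shape(v, ev, DT_MS)
        assert mahp == pytest.approx(-5.0)  # reported as computed
        assert fahp <= 0

    def test_truncated_window_warns_and_reports_missing(self):
        v, peak_idx = triangle_spike(pad=10)
        v = v[:peak_idx + 30]  # cut off decay
        ev = SpikeEvent(peak_index=peak_idx,
                        peak_time_ms=peak_idx * DT_MS, peak_V_mV=20.0)
        ev.threshold_V_mV = -40.0
        with pytest.warns(UserWarning):
            _, hw, fahp, _ = spike_shape(v, ev, DT_MS)
        assert math.isnan(fahp)

    def test_simulated_shape_matches_waveform_ground_truth(self, presets):
        spec = presets["type1"]
        proto = Protocol(kind="step_family", step_max_pA=100.0)
        ss = simulate_sweeps(spec, proto, "control", seed=4)
        events = analyze_sweep(ss.sweeps[-1], DT_MS)
        for k, ev in enumerate(events[:-1]):  # last AHP window may clip
            truth = synth.ap_ground_truth(spec.ap_shape, spec.V_cut, k)
            assert ev.amplitude_mV == pytest.approx(
                truth["amplitude_mV"], abs=1e-6
            )
            assert ev.half_width_ms == pytest.approx(
                truth["half_width_ms"], abs=DT_MS
            )
            assert ev.fAHP_mV == pytest.approx(truth["fAHP_mV"], abs=0.5)

    def test_translation_invariance_of_differences(self):
        """Amplitude, half-width and AHPs are unchanged by a DC offset."""
        v, peak_idx = triangle_spike()
        results = []
        for offset in (0.0, 7.3):
            ev = SpikeEvent(peak_index=peak_idx,
                            peak_time_ms=peak_idx * DT_MS,
                            peak_V_mV=20.0 + offset)
            ev.threshold_V_mV = -40.0 + offset
            results.append(spike_shape(v + offset, ev, DT_MS))
        assert results[0] == pytest.approx(results[1])


class TestExcitability:
    def test_counts_arithmetic(self):
        stepset = stepset_from_counts([0, 0, 1, 4, 12],
                                      [10, 20, 30, 40, 50])
        exc = excitability_scalars(stepset)
        assert list(exc.counts) == [0, 0, 1, 4, 12]
        assert exc.rheobase_pA == 30.0
        assert exc.max_freq_Hz == 24.0
        assert exc.mean_freq_Hz == pytest.approx((0 + 0 + 2 + 8 + 24) / 5)

    def test_amplitude_change_from_first_two_spikes(self):
        """A1 = 60, A2 = 54 -> (A2-A1)/A1 = -0.1 at the half-max step."""
        proto = Protocol(kind="step_family", step_min_pA=10,
                         step_max_pA=30, step_increment_pA=10)
        i0, i1 = proto.pulse_window()
        n = proto.sweep_samples()
        shape = synth.ApShape(peak_mV=20.0)
        sweeps = [
            np.full(n, -70.0),
            paste_spikes(-70.0, n, [i0 + 500, i0 + 3000], shape=shape,
                         v_onset=-40.0, amp_scales=[1.0, 0.9]),
            paste_spikes(-70.0, n, list(i0 + 500 + 2000 * np.arange(4)),
                         shape=shape, v_onset=-40.0),
        ]
        stepset = SweepSet(
            sample_rate=RATE, channel_kind="voltage_mV",
            sweeps=np.array(sweeps), step_amplitudes=[10.0, 20.0, 30.0],
            protocol=proto,
        )
        exc = excitability_scalars(stepset)
        assert exc.shape_step_index == 1  # count 2 of max 4
        assert exc.amplitude_change == pytest.approx(-0.1, abs=1e-9)

    def test_no_spikes_leaves_rheobase_missing(self):
        stepset = stepset_from_counts([0, 0, 0, 0], [10, 20, 30, 40])
        exc = excitability_scalars(stepset)
        assert math.isnan(exc.rheobase_pA)
        assert math.isnan(exc.max_freq_Hz)

    def test_rheobase_within_one_step_of_fine_grid_oracle(self, presets):
        spec = presets["type1"]
        coarse = excitability_scalars(simulate_sweeps(
            spec, Protocol(kind="step_family", step_max_pA=150.0),
            "control", seed=5,
        ))
        r10 = coarse.rheobase_pA
        # brute-force 1 pA search just below the coarse estimate
        r1 = r10
        for amp in np.arange(r10 - 10.0, r10 + 0.5, 1.0):
            proto = Protocol(kind="step_family", step_min_pA=amp,
                             step_max_pA=amp + 10.0, step_increment_pA=10.0)
            ss = simulate_sweeps(spec, proto, "control", seed=5)
            if len(detect_spikes(ss.sweeps[0], DT_MS)) > 0:
                r1 = amp
                break
        assert 0.0 <= r10 - r1 <= 10.0

    def test_added_leak_never_lowers_rheobase(self, presets):
        rheos = []
        for extra in (0.0, 0.5, 1.0):
            spec = dataclasses.replace(
                presets["type1"],
                g_L=presets["type1"].g_L + extra,
            )
            exc = excitability_scalars(simulate_sweeps(
                spec, Protocol(kind="step_family", step_max_pA=200.0),
                "control", seed=5,
            ))
            rheos.append(exc.rheobase_pA)
        assert rheos == sorted(rheos)


class TestPassiveProperties:
    def test_rc_closed_forms(self, rc_spec):
        """R = 400 MOhm, C = 100 pF cell: R_in, tau = RC, Cp recovered."""
        test = simulate_sweeps(rc_spec, Protocol(kind="test_pulse"),
                               "control", seed=0)
        p = passive_properties(test)
        assert p.R_in_MOhm == pytest.approx(400.0, rel=0.02)
        assert p.tau_ms == pytest.approx(40.0, rel=0.05)
        assert p.capacitance_pF == pytest.approx(100.0, rel=0.07)
        assert p.V_m_mV == pytest.approx(-70.0, abs=0.5)

    def test_pure_rc_has_no_sag(self):
        spec = NeuronSpec(
            C_m=100.0, g_L=4.0, E_L=-70.0, a_w=0.0, b_w=0.0, g_h=0.0,
            g_BK=0.0, g_tonic_inh=0.0, sigma_noise=0.0,
            V_T=-40.0, V_cut=-35.0,
        )
        test = simulate_sweeps(spec, Protocol(kind="test_pulse"),
                               "control", seed=0)
        sag = simulate_sweeps(spec, Protocol(kind="sag_pulse"),
                              "control", seed=0)
        p = passive_properties(test, sag)
        assert p.sag_amplitude_mV < 0.5
        assert not p.rebound

    def test_sag_amplitude_definition(self, rc_spec):
        """V_min -85 vs late steady -80 during the pulse gives sag 5 mV."""
        proto = Protocol(kind="sag_pulse")
        i0, i1 = proto.pulse_window()
        n = proto.sweep_samples()
        v = np.full(n, -70.0)
        t = np.arange(i1 - i0) * (DT_MS / 1000.0)
        v[i0:i1] = -80.0 - 5.0 * np.exp(-t / 0.05)  # dips to -85, relaxes
        sag_set = SweepSet(
            sample_rate=RATE, channel_kind="voltage_mV", sweeps=v[None, :],
            step_amplitudes=[-200.0], protocol=proto,
        )
        test = simulate_sweeps(rc_spec, Protocol(kind="test_pulse"),
                               "control", seed=0)
        p = passive_properties(test, sag_set)
        assert p.sag_amplitude_mV == pytest.approx(5.0, abs=0.05)


class TestAssembleFeatures:
    def test_complete_cell_has_all_18_features(self, preset_features):
        vec = preset_features["type1"]
        assert vec.n_missing() == 0
        assert not vec.excluded

    def test_non_spiking_cell_is_excluded(self):
        spec = NeuronSpec(
            C_m=100.0, g_L=4.0, E_L=-70.0, a_w=0.0, b_w=0.0, g_h=0.0,
            g_BK=0.0, g_tonic_inh=0.0, sigma_noise=0.0,
            V_T=-10.0, V_cut=-5.0,  # unreachably high threshold
        )
        vec, _ = extract_cell(spec, "control", seed=1,
                              step_max_pA=50.0)
        assert math.isnan(vec.rheobase_pA)
        assert vec.excluded

    def test_type2_flagged_as_burst(self, preset_features):
        assert preset_features["type2"].burst_or_adaptive == "burst"
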