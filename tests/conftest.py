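import numpy as np
import pytest

from patchkit import synth
from patchkit.io import SweepSet
from patchkit.pipeline import extract_cell

DT_MS = 0.05
RATE = 20000.0


@pytest.fixture(scope="session")
def presets():
    return synth.make_presets()


@pytest.fixture(scope="session")
def preset_features(presets):
    """Extracted feature vectors for the three reference phenotypes."""
    out = {}
    for name, spec in presets.items():
        vec, hill = extract_cell(spec, "control", seed=3, cell_id=name)
        out[name] = vec
    return out


@pytest.fixture(scope="session")
def rc_spec():
    """A purely passive RC cell: R = 400 MOhm, C = 100 pF, tau = 40 ms."""
    return synth.NeuronSpec(
        C_m=100.0, g_L=2.5, E_L=-70.0, a_w=0.0, b_w=0.0,
        g_h=0.0, g_BK=0.0, g_tonic_inh=0.0, g_GIRK=0.0,
        sigma_noise=0.0, V_T=-40.0, V_cut=-35.0,
    )


def paste_spikes(baseline_mV, n_samples, spike_idx, shape=None,
                 v_onset=-41.0, v_reset=-52.0, amp_scales=None):
    """Build a voltage trace with stereotyped APs pasted at given indices.

    A slow (< 5 mV/ms) depolarizing ramp precedes each waveform so the
    pasted onset is a genuine dV/dt threshold, as in a real approach to
    spiking.
    """
    if shape is None:
        shape = synth.ApShape()
    v = np.full(n_samples, baseline_mV, dtype=float)
    ramp_n = int(np.ceil((v_onset - baseline_mV) / (4.5 * DT_MS)))
    for k, idx in enumerate(spike_idx):
        r0 = max(0, idx - ramp_n)
        v[r0:idx] = np.linspace(baseline_mV, v_onset, idx - r0,
                                endpoint=False)
        if amp_scales is None:
            wf = synth.ap_waveform(shape, v_onset, v_reset, DT_MS)
        else:
            import dataclasses
            peak = v_onset + (shape.peak_mV - v_onset) * amp_scales[k]
            wf = synth.ap_waveform(
                dataclasses.replace(shape, peak_mV=peak),
                v_onset, v_reset, DT_MS,
            )
        stop = min(idx + len(wf), n_samples)
        v[idx:stop] = wf[: stop - idx]
    return v


def stepset_from_counts(counts, currents, shape=None):
    """A synthetic step family whose sweeps contain the given spike counts."""
    proto = synth.Protocol(
        kind="step_family",
        step_min_pA=float(currents[0]),
        step_max_pA=float(currents[-1]),
        step_increment_pA=float(currents[1] - currents[0]),
    )
    i0, i1 = proto.pulse_window()
    n = proto.sweep_samples()
    sweeps = []
    for count in counts:
        if count == 0:
            sweeps.append(np.full(n, -70.0))
            continue
        idx = np.linspace(i0 + 200, i1 - 400, count).astype(int)
        sweeps.append(paste_spikes(-70.0, n, idx, shape=shape))
    return SweepSet(
        sample_rate=RATE, channel_kind="voltage_mV",
        sweeps=np.array(sweeps), step_amplitudes=np.asarray(currents,
                                                           dtype=float),
        protocol=proto,
    )


def oracle_spike_count(v, dt_ms=DT_MS, refractory_ms=1.0):
    """Brute-force 0 mV upward-crossing scan (independent of the package)."""
    count = 0
    last_peak = -1e9
    i = 1
    n = len(v)
    while i < n:
        if v[i - 1] < 0.0 <= v[i]:
            j = i
            while j + 1 < n and v[j + 1] >= 0.0:
                j += 1
            peak = i + int(np.argmax(v[i:j + 1]))
            if (peak - last_peak) * dt_ms >= refractory_ms:
                count += 1
                last_peak = peak
            i = j + 1
        else:
            i += 1
    return count
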