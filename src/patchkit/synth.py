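"""Synthetic current-clamp neurons with known ground truth.

The generator produces voltage sweeps for the standard square-pulse
stimulation protocols used to characterize cortical interneurons (500 ms
depolarizing step families in +10 pA increments, a -200 pA sag/rebound
pulse, a -10 pA test pulse, and gap-free records), plus noisy synaptic
current traces with known event times.

The neuron model is a hybrid: adaptive-exponential integrate-and-fire
subthreshold dynamics (leak, spike-initiation exponential, subthreshold
and spike-triggered adaptation, an HCN-like sag conductance, a BK-like
Ca-dependent K conductance, tonic Cl and GIRK K leaks, optional
Ornstein-Uhlenbeck current noise), with each threshold crossing replaced
in the output by a stereotyped action-potential waveform.  The pasted
waveform makes spike peak, amplitude, half-width and AHP depth exact
ground truth for testing feature extraction, which a bare
integrate-and-fire model cannot provide.

Pharmacology is expressed as :class:`DrugCondition` transformations of a
:class:`NeuronSpec`: the GABAbR agonist baclofen adds a GIRK K leak and
suppresses the BK conductance (the indirect pathway), the BK blocker
paxilline zeroes it, picrotoxin removes the tonic Cl conductance, and
glutamate-receptor blockers silence the background synaptic drive.  The
BK conductance has a tonic fraction (active between spikes, scaled by the
extracellular-Ca factor ``ca_scale``) and a spike-triggered increment
that decays with ``tau_BK``; the tonic part is what lets BK blockade move
rheobase, while the triggered part shapes firing-rate adaptation.

Integration is fixed-step exponential Euler at dt = 0.05 ms (one sample
at 20 kHz); identical (spec, protocol, condition, seed) inputs give
bit-identical sweeps.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .io import SweepSet

__all__ = [
    "ApShape",
    "NeuronSpec",
    "Protocol",
    "DrugCondition",
    "PSCTraceSpec",
    "CONDITIONS",
    "IntegrationError",
    "simulate_sweeps",
    "simulate_psc_trace",
    "make_presets",
    "make_cohort",
    "resting_potential",
    "ap_waveform",
    "ap_ground_truth",
    "ou_noise",
    "psc_kernel",
    "save_scenario",
    "load_scenario",
]

#: Numerical-divergence guard on the membrane potential (mV), applied away
#: from the pasted spike waveform.
V_GUARD = (-150.0, 80.0)


class IntegrationError(RuntimeError):
    """Membrane potential left the physical range during integration."""


@dataclass(frozen=True)
class ApShape:
    """Stereotyped action-potential waveform parameters.

    The waveform rises linearly from the onset voltage to ``peak_mV`` over
    ``rise_ms``, falls linearly to ``onset - ahp_depth_mV`` over
    ``fall_ms``, and relaxes exponentially toward the reset potential with
    time constant ``ahp_tau_ms``.
    """

    peak_mV: float = 25.0
    rise_ms: float = 0.6
    fall_ms: float = 1.2
    ahp_depth_mV: float = 14.0
    ahp_tau_ms: float = 1.5
    #: Fractional amplitude decline from the first to the second spike
    #: (accommodation), so the amplitude-change feature (A2-A1)/A1 equals
    #: -droop exactly.  The decline saturates geometrically at
    #: ``droop_floor`` of the first amplitude so late spikes still
    #: overshoot 0 mV; requires droop_per_spike < 1 - droop_floor.
    droop_per_spike: float = 0.0
    droop_floor: float = 0.75


@dataclass(frozen=True)
class NeuronSpec:
    """Generative model parameters for one synthetic neuron.

    Conductances in nS, capacitance in pF, voltages in mV, times in ms,
    currents in pA.  ``ca_scale`` in [0, 1] mimics the extracellular Ca2+
    level and multiplies the BK conductance (1 ~ 2.5 mM recording ACSF,
    0 ~ BK functionally silent at 1 mM).
    """

    C_m: float = 80.0
    g_L: float = 2.5
    E_L: float = -70.0
    Delta_T: float = 2.0
    V_T: float = -45.0
    V_reset: float = -52.0
    V_cut: float = -41.0
    a_w: float = 0.5
    b_w: float = 20.0
    tau_w: float = 120.0
    g_h: float = 1.5
    E_h: float = -30.0
    V_half_h: float = -85.0
    k_h: float = 8.0
    tau_h: float = 60.0
    g_BK: float = 2.0
    bk_tonic_frac: float = 0.3
    tau_BK: float = 60.0
    E_K: float = -90.0
    ca_scale: float = 1.0
    g_tonic_inh: float = 0.3
    E_Cl: float = -72.0
    g_GIRK: float = 0.0
    sigma_noise: float = 0.0
    tau_noise: float = 3.0
    ap_shape: ApShape = field(default_factory=ApShape)

    def __post_init__(self) -> None:
        for name in ("g_L", "a_w", "g_h", "g_BK", "g_tonic_inh", "g_GIRK"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.Delta_T <= 0:
            raise ValueError("Delta_T must be > 0")
        if not 0.0 <= self.ca_scale <= 1.0:
            raise ValueError("ca_scale must lie in [0, 1]")
        if self.V_reset >= self.V_cut:
            raise ValueError("V_reset must be below V_cut")
        for name in ("tau_w", "tau_h", "tau_BK", "tau_noise", "C_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class Protocol:
    """Stimulation protocol metadata.

    ``step_family`` delivers 500 ms square pulses in +10 pA increments;
    ``sag_pulse`` a single -200 pA / 500 ms hyperpolarizing pulse;
    ``test_pulse`` a -10 pA / 100 ms pulse for passive properties;
    ``gap_free`` a continuous record with no injected current.
    """

    kind: str = "step_family"
    step_start_s: float = 0.1
    step_dur_s: float = 0.5
    step_increment_pA: float = 10.0
    step_min_pA: float = 10.0
    step_max_pA: float = 200.0
    sag_amp_pA: float = -200.0
    test_amp_pA: float = -10.0
    test_dur_s: float = 0.1
    tail_s: float = 0.15
    duration_s: float = 30.0
    sample_rate_hz: float = 20000.0
    #: Sweep repeats for the single-pulse protocols (test/sag); repeats
    #: are averaged when estimating passive properties on noisy cells.
    repeats: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("step_family", "sag_pulse", "test_pulse", "gap_free"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.step_dur_s <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("durations and sample rate must be positive")
        if self.kind == "step_family":
            span = self.step_max_pA - self.step_min_pA
            n = span / self.step_increment_pA
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    "step_increment_pA must divide step_max_pA - step_min_pA"
                )

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate_hz

    def step_amplitudes(self) -> np.ndarray:
        if self.kind == "step_family":
            n = int(round(
                (self.step_max_pA - self.step_min_pA) / self.step_increment_pA
            )) + 1
            return self.step_min_pA + self.step_increment_pA * np.arange(n)
        if self.kind == "sag_pulse":
            return np.full(self.repeats, self.sag_amp_pA)
        if self.kind == "test_pulse":
            return np.full(self.repeats, self.test_amp_pA)
        return np.array([0.0])

    def sweep_samples(self) -> int:
        rate = self.sample_rate_hz
        if self.kind == "gap_free":
            return int(round(self.duration_s * rate))
        dur = self.test_dur_s if self.kind == "test_pulse" else self.step_dur_s
        total = self.step_start_s + dur + self.tail_s
        return int(round(total * rate))

    def pulse_window(self) -> tuple[int, int]:
        """(start, stop) sample indices of the injected pulse."""
        rate = self.sample_rate_hz
        dur = self.test_dur_s if self.kind == "test_pulse" else self.step_dur_s
        i0 = int(round(self.step_start_s * rate))
        return i0, i0 + int(round(dur * rate))

    @classmethod
    def from_strings(cls, mapping) -> "Protocol":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in mapping:
                raw = mapping[f.name]
                if f.name == "kind":
                    kwargs[f.name] = raw
                elif f.name == "repeats":
                    kwargs[f.name] = int(float(raw))
                else:
                    kwargs[f.name] = float(raw)
        return cls(**kwargs)


@dataclass(frozen=True)
class DrugCondition:
    """A bath-applied drug state expressed as NeuronSpec deltas.

    ``apply`` is pure: it returns a new spec and never mutates its input,
    so reverting a condition is simply keeping the original spec.
    """

    name: str
    girk_add_nS: float = 0.0
    bk_scale: float = 1.0
    tonic_inh_scale: float = 1.0
    drive_scale: float = 1.0

    def apply(self, spec: NeuronSpec) -> NeuronSpec:
        return replace(
            spec,
            g_GIRK=spec.g_GIRK + self.girk_add_nS,
            g_BK=spec.g_BK * self.bk_scale,
            g_tonic_inh=spec.g_tonic_inh * self.tonic_inh_scale,
            sigma_noise=spec.sigma_noise * self.drive_scale,
        )


#: Default suppression of the BK conductance by GABAbR activation.  The
#: magnitude is a calibration knob of the generator, not a measured value.
BACLOFEN_BK_SUPPRESSION = 0.2
#: GIRK conductance added by baclofen, sized to reproduce the modest
#: (~6%) input-resistance drop seen with GABAbR activation.
BACLOFEN_GIRK_NS = 0.15

CONDITIONS: dict[str, DrugCondition] = {
    "control": DrugCondition("control"),
    "baclofen": DrugCondition(
        "baclofen",
        girk_add_nS=BACLOFEN_GIRK_NS,
        bk_scale=BACLOFEN_BK_SUPPRESSION,
    ),
    "paxilline": DrugCondition("paxilline", bk_scale=0.0),
    "picrotoxin": DrugCondition("picrotoxin", tonic_inh_scale=0.0),
    "apv_dnqx": DrugCondition("apv_dnqx", drive_scale=0.0),
    "pax_bac": DrugCondition(
        "pax_bac", girk_add_nS=BACLOFEN_GIRK_NS, bk_scale=0.0
    ),
    "ptx_pax": DrugCondition("ptx_pax", bk_scale=0.0, tonic_inh_scale=0.0),
    "ptx_pax_bac": DrugCondition(
        "ptx_pax_bac",
        girk_add_nS=BACLOFEN_GIRK_NS,
        bk_scale=0.0,
        tonic_inh_scale=0.0,
    ),
}


# ---------------------------------------------------------------------------
# Stereotyped AP waveform


def ap_waveform(shape: ApShape, v_onset: float, v_reset: float,
                dt_ms: float, spike_index: int = 0) -> np.ndarray:
    """Sampled AP waveform starting at the onset (threshold) voltage.

    Tail length is fixed at 6.5 ms after the trough so the fast (4 ms) and
    medium (6 ms) AHP windows lie entirely inside the paste.  For
    ``spike_index`` k > 0 the amplitude is reduced by the droop factor.
    """
    n_rise = max(1, int(round(shape.rise_ms / dt_ms)))
    n_fall = max(1, int(round(shape.fall_ms / dt_ms)))
    n_tail = int(round(6.5 / dt_ms))
    amp = (shape.peak_mV - v_onset) * _droop_factor(shape, spike_index)
    peak = v_onset + amp
    v_min = v_onset - shape.ahp_depth_mV
    rise = np.linspace(v_onset, peak, n_rise + 1)
    fall = np.linspace(peak, v_min, n_fall + 1)[1:]
    t_tail = dt_ms * np.arange(1, n_tail + 1)
    tail = v_reset + (v_min - v_reset) * np.exp(-t_tail / shape.ahp_tau_ms)
    return np.concatenate([rise, fall, tail])


def _droop_factor(shape: ApShape, spike_index: int) -> float:
    """Saturating accommodation: floor + (1-floor) * r^k with the ratio r
    chosen so the first-to-second decline equals droop_per_spike."""
    d, fl = shape.droop_per_spike, shape.droop_floor
    if d == 0.0:
        return 1.0
    if d >= 1.0 - fl:
        raise ValueError("droop_per_spike must be < 1 - droop_floor")
    r = 1.0 - d / (1.0 - fl)
    return fl + (1.0 - fl) * r ** spike_index


def ap_ground_truth(shape: ApShape, v_onset: float,
                    spike_index: int = 0) -> dict:
    """Closed-form spike-shape values implied by the pasted waveform."""
    amp = (shape.peak_mV - v_onset) * _droop_factor(shape, spike_index)
    half_width = shape.rise_ms / 2.0 + (
        shape.fall_ms * amp / (2.0 * (amp + shape.ahp_depth_mV))
    )
    return {
        "threshold_mV": v_onset,
        "peak_mV": v_onset + amp,
        "amplitude_mV": amp,
        "half_width_ms": half_width,
        "fAHP_mV": shape.ahp_depth_mV,
        "mAHP_mV": shape.ahp_depth_mV,
        "amplitude_change": -shape.droop_per_spike,
    }


# ---------------------------------------------------------------------------
# Core integrator


@njit(cache=True)
def _integrate(i_inj, noise, dt, C, gL, EL, dT, vT, v_reset, v_cut,
               a_w, b_w, tau_w, g_h, E_h, v_half_h, k_h, tau_h,
               g_bk_trig, g_bk_tonic, tau_bk, E_K, g_tonic, E_Cl,
               g_girk, n_ref, v0, w0, h0):
    n = i_inj.shape[0]
    V = np.empty(n)
    V[0] = v0
    spikes = np.empty(n, np.int64)
    ns = 0
    v = v0
    w = w0
    h = h0
    gbk = 0.0
    ref = 0
    diverged = -1
    for i in range(1, n):
        if ref > 0:
            ref -= 1
            v = v_reset
        else:
            g_tot = gL + g_h * h + g_bk_tonic + gbk + g_tonic + g_girk
            drive = (gL * EL + g_h * h * E_h + (g_bk_tonic + gbk) * E_K
                     + g_tonic * E_Cl + g_girk * E_K)
            ex = (v - vT) / dT
            if ex > 20.0:
                ex = 20.0
            i_exp = gL * dT * math.exp(ex)
            v_inf = (drive + i_exp - w + i_inj[i] + noise[i]) / g_tot
            v = v_inf + (v - v_inf) * math.exp(-dt * g_tot / C)
        w += dt * (a_w * (v - EL) - w) / tau_w
        hinf = 1.0 / (1.0 + math.exp((v - v_half_h) / k_h))
        h += dt * (hinf - h) / tau_h
        gbk -= dt * gbk / tau_bk
        if ref == 0 and v >= v_cut:
            spikes[ns] = i
            ns += 1
            v = v_reset
            w += b_w
            gbk += g_bk_trig
            ref = n_ref
        V[i] = v
        if ref == 0 and (v < V_GUARD[0] or v > V_GUARD[1]):
            diverged = i
            break
    return V, spikes[:ns], diverged


def resting_potential(spec: NeuronSpec) -> float:
    """Closed-form resting potential: root of the steady-state current.

    Solves the subthreshold fixed point including the sag conductance at
    its steady activation and the subthreshold adaptation coupling.
    """
    s = spec
    g_bk_tonic = s.g_BK * s.ca_scale * s.bk_tonic_frac

    def f(v):
        h = 1.0 / (1.0 + math.exp((v - s.V_half_h) / s.k_h))
        ex = min((v - s.V_T) / s.Delta_T, 20.0)
        return (
            s.g_L * (s.E_L - v)
            + s.g_L * s.Delta_T * math.exp(ex)
            + s.g_h * h * (s.E_h - v)
            + g_bk_tonic * (s.E_K - v)
            + s.g_tonic_inh * (s.E_Cl - v)
            + s.g_GIRK * (s.E_K - v)
            - s.a_w * (v - s.E_L)
        )

    return brentq(f, -120.0, s.V_cut - 0.5, xtol=1e-10)


def ou_noise(n: int, dt_ms: float, sigma: float, tau_ms: float,
             rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck current noise (pA)."""
    if sigma == 0.0:
        return np.zeros(n)
    from scipy.signal import lfilter

    rho = math.exp(-dt_ms / tau_ms)
    eps = rng.standard_normal(n)
    drive = sigma * math.sqrt(1.0 - rho * rho) * eps
    drive[0] = sigma * eps[0]  # start from the stationary distribution
    return lfilter([1.0], [1.0, -rho], drive)


def _sweep_seed(seed: int, sweep_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(sweep_index,))
    )


def simulate_sweeps(spec: NeuronSpec, protocol: Protocol,
                    condition: DrugCondition | str = "control",
                    seed: int = 0) -> SweepSet:
    """Simulate one protocol run and return voltage sweeps in mV.

    Each model spike is replaced by the stereotyped ``ap_shape`` waveform
    (onset pinned at ``V_cut``), so spike peak, amplitude, half-width and
    AHP depth have exact ground truth, recorded in the annotations along
    with the true spike times.

    Raises
    ------
    IntegrationError
        If the membrane potential leaves [-150, +80] mV away from the
        pasted waveform, reporting the sweep index.
    """
    if isinstance(condition, str):
        condition = CONDITIONS[condition]
    eff = condition.apply(spec)
    dt = protocol.dt_ms
    if dt > 0.05 + 1e-12:
        raise ValueError("integration requires dt <= 0.05 ms (>= 20 kHz)")
    n_samples = protocol.sweep_samples()
    amps = protocol.step_amplitudes()
    wf = ap_waveform(eff.ap_shape, eff.V_cut, eff.V_reset, dt)
    n_ref = len(wf) - 1
    v0 = resting_potential(eff)
    w0 = eff.a_w * (v0 - eff.E_L)
    h0 = 1.0 / (1.0 + math.exp((v0 - eff.V_half_h) / eff.k_h))
    g_bk_tonic = eff.g_BK * eff.ca_scale * eff.bk_tonic_frac
    g_bk_trig = eff.g_BK * eff.ca_scale * (1.0 - eff.bk_tonic_frac)

    i0, i1 = (0, 0)
    if protocol.kind != "gap_free":
        i0, i1 = protocol.pulse_window()

    sweeps = np.empty((len(amps), n_samples))
    spike_times_ms: list[list[float]] = []
    for k, amp in enumerate(amps):
        i_inj = np.zeros(n_samples)
        if protocol.kind != "gap_free":
            i_inj[i0:i1] = amp
        rng = _sweep_seed(seed, k)
        noise = ou_noise(n_samples, dt, eff.sigma_noise, eff.tau_noise, rng)
        V, spike_idx, diverged = _integrate(
            i_inj, noise, dt, eff.C_m, eff.g_L, eff.E_L, eff.Delta_T,
            eff.V_T, eff.V_reset, eff.V_cut, eff.a_w, eff.b_w, eff.tau_w,
            eff.g_h, eff.E_h, eff.V_half_h, eff.k_h, eff.tau_h,
            g_bk_trig, g_bk_tonic, eff.tau_BK, eff.E_K,
            eff.g_tonic_inh, eff.E_Cl, eff.g_GIRK, n_ref, v0, w0, h0,
        )
        if diverged >= 0:
            raise IntegrationError(
                f"sweep {k}: V diverged at sample {diverged} "
                f"({V[diverged]:.1f} mV)"
            )
        for ksp, idx in enumerate(spike_idx):
            wfk = wf if ksp == 0 else ap_waveform(
                eff.ap_shape, eff.V_cut, eff.V_reset, dt, spike_index=ksp
            )
            stop = min(idx + len(wfk), n_samples)
            V[idx:stop] = wfk[: stop - idx]
        sweeps[k] = V
        spike_times_ms.append([float(idx * dt) for idx in spike_idx])

    truth = ap_ground_truth(eff.ap_shape, eff.V_cut)
    annotations = {
        "condition": condition.name,
        "true_spike_times_ms": json.dumps(spike_times_ms),
        "ap_ground_truth": json.dumps(truth),
        "seed": str(seed),
    }
    return SweepSet(
        sample_rate=protocol.sample_rate_hz,
        channel_kind="voltage_mV",
        sweeps=sweeps,
        step_amplitudes=amps,
        protocol=protocol,
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# Synaptic-current traces


@dataclass(frozen=True)
class PSCTraceSpec:
    """Synthetic spontaneous-PSC current trace parameters.

    Events are inward (negative) biexponential deflections at Poisson
    times with log-normal amplitudes, on correlated Gaussian baseline
    noise.  Ground truth records every onset time and peak magnitude.
    """

    rate_hz: float = 2.0
    amp_median_pA: float = 15.0
    amp_sigma: float = 0.35
    #: Truncation floor of the log-normal amplitude distribution (pA);
    #: draws below it are rejected and redrawn.
    amp_min_pA: float = 0.0
    tau_rise_ms: float = 0.5
    tau_decay_ms: float = 5.0
    noise_sd_pA: float = 1.5
    #: Baseline-noise correlation time; 0.3 ms emulates white recording
    #: noise low-pass filtered at ~3 kHz before 20 kHz digitization.
    noise_tau_ms: float = 0.3
    duration_s: float = 60.0
    sample_rate_hz: float = 20000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_hz < 0:
            raise ValueError("rate_hz must be >= 0")
        if self.tau_rise_ms >= self.tau_decay_ms:
            raise ValueError("tau_rise must be shorter than tau_decay")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")


def psc_kernel(tau_rise_ms: float, tau_decay_ms: float, dt_ms: float,
               length_ms: float = 30.0) -> np.ndarray:
    """Biexponential PSC kernel normalized to unit peak."""
    t = dt_ms * np.arange(int(round(length_ms / dt_ms)))
    k = np.exp(-t / tau_decay_ms) - np.exp(-t / tau_rise_ms)
    return k / k.max()


def simulate_psc_trace(spec: PSCTraceSpec):
    """Synthesize a PSC current trace and its ground-truth event list.

    Returns ``(trace_pA, events)`` where ``events`` is a list of
    ``(onset_time_s, amplitude_pA)`` with positive magnitudes; the trace
    itself carries inward (negative) deflections.
    """
    rng = np.random.default_rng(spec.seed)
    dt = 1000.0 / spec.sample_rate_hz
    n = int(round(spec.duration_s * spec.sample_rate_hz))
    trace = ou_noise(n, dt, spec.noise_sd_pA, spec.noise_tau_ms, rng)
    kernel = psc_kernel(spec.tau_rise_ms, spec.tau_decay_ms, dt)
    n_events = rng.poisson(spec.rate_hz * spec.duration_s)
    onsets = np.sort(rng.uniform(0.0, spec.duration_s, size=n_events))
    amps = spec.amp_median_pA * np.exp(
        spec.amp_sigma * rng.standard_normal(n_events)
    )
    while np.any(amps < spec.amp_min_pA):
        redo = amps < spec.amp_min_pA
        amps[redo] = spec.amp_median_pA * np.exp(
            spec.amp_sigma * rng.standard_normal(int(redo.sum()))
        )
    events = []
    for t0, amp in zip(onsets, amps):
        idx = int(round(t0 * spec.sample_rate_hz))
        if idx >= n:
            continue
        stop = min(idx + len(kernel), n)
        trace[idx:stop] -= amp * kernel[: stop - idx]
        events.append((idx / spec.sample_rate_hz, float(amp)))
    return trace, events


# ---------------------------------------------------------------------------
# Presets and cohorts


def make_presets() -> dict[str, NeuronSpec]:
    """Reference neuron specs for the three firing phenotypes.

    ``type1`` fires continuously with spike-frequency adaptation;
    ``type2`` is a bursting cell with low rheobase, high input resistance
    and the slowest membrane time constant, with a prominent sag and
    rebound spike; ``type3`` fires irregularly (driven by OU current
    noise) with high rheobase, low input resistance and the fastest
    membrane time constant.
    """
    type1 = NeuronSpec(
        C_m=80.0, g_L=1.1, E_L=-70.0, V_T=-45.0, V_cut=-41.0,
        V_reset=-52.0, a_w=0.25, b_w=12.0, tau_w=120.0,
        g_h=1.0, tau_h=60.0,
        g_BK=1.2, bk_tonic_frac=0.35, tau_BK=50.0,
        g_tonic_inh=0.25, sigma_noise=0.0,
        ap_shape=ApShape(peak_mV=25.0, rise_ms=0.6, fall_ms=1.2,
                         ahp_depth_mV=14.0, ahp_tau_ms=1.5,
                         droop_per_spike=0.06),
    )
    type2 = NeuronSpec(
        C_m=90.0, g_L=0.55, E_L=-70.0, V_T=-50.0, V_cut=-46.0,
        V_reset=-47.2, a_w=0.1, b_w=35.0, tau_w=250.0,
        g_h=5.0, E_h=-20.0, V_half_h=-85.0, k_h=6.0, tau_h=120.0,
        g_BK=1.2, bk_tonic_frac=0.35, tau_BK=50.0,
        g_tonic_inh=0.2, sigma_noise=0.0,
        ap_shape=ApShape(peak_mV=20.0, rise_ms=0.7, fall_ms=1.4,
                         ahp_depth_mV=10.0, ahp_tau_ms=1.8,
                         droop_per_spike=0.12),
    )
    type3 = NeuronSpec(
        C_m=55.0, g_L=1.7, E_L=-70.0, V_T=-42.0, V_cut=-38.0,
        V_reset=-54.0, a_w=0.8, b_w=5.0, tau_w=80.0,
        g_h=0.4, tau_h=60.0,
        g_BK=1.2, bk_tonic_frac=0.35, tau_BK=50.0,
        g_tonic_inh=0.3, sigma_noise=8.0, tau_noise=4.0,
        ap_shape=ApShape(peak_mV=28.0, rise_ms=0.5, fall_ms=1.0,
                         ahp_depth_mV=16.0, ahp_tau_ms=1.2,
                         droop_per_spike=0.03),
    )
    return {"type1": type1, "type2": type2, "type3": type3}


#: Parameters jittered when building a cohort, with multiplicative noise.
_JITTER_FIELDS = ("C_m", "g_L", "b_w", "g_h", "g_BK", "g_tonic_inh",
                  "sigma_noise", "a_w")


def make_cohort(n_per_type=(17, 3, 5), seed: int = 0, jitter: float = 0.05):
    """Draw a cohort of synthetic cells around the three presets.

    Returns a list of ``(cell_id, type_name, NeuronSpec)``.  Each cell is
    the preset with log-normal jitter (geometric SD ``jitter``) on its
    conductances/capacitance and a small additive shift of the spike
    threshold, emulating biological cell-to-cell variability.
    """
    presets = make_presets()
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=int(seed), spawn_key=(9001,)
    ))
    cohort = []
    for tname, n_cells in zip(("type1", "type2", "type3"), n_per_type):
        base = presets[tname]
        for j in range(n_cells):
            changes = {
                name: getattr(base, name)
                * math.exp(jitter * rng.standard_normal())
                for name in _JITTER_FIELDS
            }
            dv = 1.0 * rng.standard_normal()
            changes["V_T"] = base.V_T + dv
            changes["V_cut"] = base.V_cut + dv
            changes["V_reset"] = base.V_reset + dv
            spec = replace(base, **changes)
            cohort.append((f"{tname}_c{j:02d}", tname, spec))
    return cohort


# ---------------------------------------------------------------------------
# Scenario files (flat key=value)


def save_scenario(path, spec: NeuronSpec, protocol: Protocol,
                  condition: DrugCondition | str = "control") -> None:
    """Write (neuron spec, protocol, condition) as flat key=value text."""
    cond = condition if isinstance(condition, str) else condition.name
    lines = [f"condition = {cond}"]
    for key, val in dataclasses.asdict(spec).items():
        if key == "ap_shape":
            for k2, v2 in val.items():
                lines.append(f"neuron.ap_shape.{k2} = {v2}")
        else:
            lines.append(f"neuron.{key} = {val}")
    for key, val in dataclasses.asdict(protocol).items():
        lines.append(f"protocol.{key} = {val}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_scenario(path):
    """Read a scenario file; returns (NeuronSpec, Protocol, DrugCondition)."""
    neuron: dict = {}
    shape: dict = {}
    proto: dict = {}
    cond_name = "control"
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            val = val.strip()
            if key == "condition":
                cond_name = val
            elif key.startswith("neuron.ap_shape."):
                shape[key.rsplit(".", 1)[1]] = float(val)
            elif key.startswith("neuron."):
                neuron[key.split(".", 1)[1]] = float(val)
            elif key.startswith("protocol."):
                proto[key.split(".", 1)[1]] = val
    spec = NeuronSpec(**neuron, ap_shape=ApShape(**shape)) if shape else \
        NeuronSpec(**neuron)
    protocol = Protocol.from_strings(proto)
    return spec, protocol, CONDITIONS[cond_name]
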