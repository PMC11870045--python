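"""Per-cell electrophysiological feature extraction from current-clamp sweeps.

Operational definitions follow standard practice for characterizing
cortical interneurons from square-pulse protocols:

* spikes are voltage deflections overshooting 0 mV (upward crossing
  followed by a local maximum, 1 ms refractory);
* spike threshold is the voltage where the rising phase first accelerates
  to 5 mV/ms (two-point forward difference at the native sampling);
* half-width is the time between the half-amplitude crossings of the
  rising and decay phases (linear interpolation);
* fast and medium AHP are the depth below threshold of the voltage
  minimum within 4 and 6 ms after the spike peak;
* rheobase is the smallest current step evoking at least one spike, with
  spikes of amplitude < 5 mV (spikelets during depolarization block)
  excluded from all counts;
* AP-shape features are measured at the step evoking ~50% of the maximum
  firing (count nearest to half the maximum, ties toward lower current);
* passive properties come from the -10 pA test pulse (input resistance,
  membrane time constant from a single-exponential fit cross-checked
  against the 63% criterion, capacitance as tau/R) and the -200 pA pulse
  (sag amplitude, rebound spike).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .io import FEATURE_COLUMNS, SweepSet

__all__ = [
    "SpikeEvent",
    "FeatureVector",
    "Excitability",
    "PassiveProperties",
    "ThresholdError",
    "detect_spikes",
    "spike_threshold",
    "spike_shape",
    "analyze_sweep",
    "excitability_scalars",
    "passive_properties",
    "capacitance_from_vc",
    "assemble_features",
]

logger = logging.getLogger("patchkit")

SPIKE_DETECT_THRESHOLD_MV = 0.0
REFRACTORY_MS = 1.0
DVDT_CRITERION = 5.0  # mV/ms
AMPLITUDE_CUTOFF_MV = 5.0
FAHP_WINDOW_MS = 4.0
MAHP_WINDOW_MS = 6.0


class ThresholdError(ValueError):
    """The dV/dt criterion was never met in the backward search window."""


@dataclass
class SpikeEvent:
    """One action potential and its shape measurements."""

    peak_index: int
    peak_time_ms: float
    peak_V_mV: float
    threshold_V_mV: float = math.nan
    threshold_time_ms: float = math.nan
    amplitude_mV: float = math.nan
    half_width_ms: float = math.nan
    fAHP_mV: float = math.nan
    mAHP_mV: float = math.nan


@dataclass
class FeatureVector:
    """The 18 per-cell properties used for electrophysiological typing."""

    cell_id: str = "cell"
    rheobase_pA: float = math.nan
    capacitance_pF: float = math.nan
    resting_potential_mV: float = math.nan
    input_resistance_MOhm: float = math.nan
    max_freq_Hz: float = math.nan
    sag_amplitude_mV: float = math.nan
    rebound: bool | float = math.nan
    burst_or_adaptive: str = "neither"
    mean_freq_Hz: float = math.nan
    mAHP_mV: float = math.nan
    fAHP_mV: float = math.nan
    midpoint_pA: float = math.nan
    steepness_Hz_per_pA: float = math.nan
    tau_ms: float = math.nan
    threshold_mV: float = math.nan
    amplitude_change: float = math.nan
    half_width_ms: float = math.nan
    mean_isi_ms: float = math.nan
    excluded: bool = False

    def as_dict(self) -> dict:
        d = {col: getattr(self, col) for col in FEATURE_COLUMNS}
        d["cell_id"] = self.cell_id
        return d

    def n_missing(self) -> int:
        n = 0
        for col in FEATURE_COLUMNS:
            val = getattr(self, col)
            if isinstance(val, float) and math.isnan(val):
                n += 1
        return n


def detect_spikes(v: np.ndarray, dt_ms: float,
                  window: tuple[int, int] | None = None,
                  detect_mV: float = SPIKE_DETECT_THRESHOLD_MV,
                  refractory_ms: float = REFRACTORY_MS) -> list[SpikeEvent]:
    """Detect spikes as upward crossings of 0 mV followed by a local max.

    Returns one event per accepted crossing, ordered in time, with a
    ``refractory_ms`` dead time between accepted peaks.  Subthreshold
    humps that never overshoot ``detect_mV`` are excluded by definition.
    """
    v = np.asarray(v, dtype=float)
    lo, hi = (0, len(v)) if window is None else window
    seg = v[lo:hi]
    above = seg >= detect_mV
    if not above.any():
        return []
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above[0]:
        crossings = np.concatenate([[0], crossings])
    refr = int(round(refractory_ms / dt_ms))
    events: list[SpikeEvent] = []
    last_peak = -10 ** 9
    for c in crossings:
        # local maximum before the trace falls back below the criterion
        j = c
        while j + 1 < len(seg) and above[j + 1]:
            j += 1
        peak_rel = c + int(np.argmax(seg[c:j + 1]))
        peak = lo + peak_rel
        if peak - last_peak < refr:
            continue
        last_peak = peak
        events.append(SpikeEvent(
            peak_index=peak,
            peak_time_ms=peak * dt_ms,
            peak_V_mV=float(v[peak]),
        ))
    return events


def _dvdt(v: np.ndarray, dt_ms: float,
          savgol_window: int | None = None) -> np.ndarray:
    if savgol_window is not None:
        from scipy.signal import savgol_filter

        v = savgol_filter(v, savgol_window, polyorder=3)
    return np.diff(v) / dt_ms


def spike_threshold(v: np.ndarray, event: SpikeEvent, dt_ms: float,
                    dvdt_crit: float = DVDT_CRITERION,
                    max_back_ms: float = 10.0,
                    savgol_window: int | None = None) -> float:
    """Voltage where the rising phase accelerates to ``dvdt_crit`` mV/ms.

    Walks backward from the peak through the contiguous run of samples
    whose two-point forward dV/dt meets the criterion; the threshold is
    the earliest sample of that run, searched no more than
    ``max_back_ms`` before the peak.
    """
    v = np.asarray(v, dtype=float)
    peak = event.peak_index
    dvdt = _dvdt(v, dt_ms, savgol_window)
    stop = max(0, peak - int(round(max_back_ms / dt_ms)))
    j = peak - 1
    while j >= stop and dvdt[j] < dvdt_crit:
        j -= 1
    if j < stop:
        raise ThresholdError(
            f"dV/dt never reached {dvdt_crit} mV/ms within "
            f"{max_back_ms} ms before the peak at {event.peak_time_ms} ms"
        )
    while j - 1 >= stop and dvdt[j - 1] >= dvdt_crit:
        j -= 1
    event.threshold_V_mV = float(v[j])
    event.threshold_time_ms = j * dt_ms
    return float(v[j])


def spike_shape(v: np.ndarray, event: SpikeEvent, dt_ms: float):
    """Amplitude, half-width and AHP depths for one spike.

    Amplitude is peak minus threshold; the half-width interpolates the
    two half-amplitude crossings linearly; fast/medium AHP are the depth
    of the voltage minimum in (peak, peak + 4 ms] and (peak, peak + 6 ms]
    below threshold, reported as positive depths (no clamping: a decay
    that never dips below threshold gives a negative value).  Windows
    truncated by the sweep end yield NaN with a warning.
    """
    v = np.asarray(v, dtype=float)
    peak = event.peak_index
    thr = event.threshold_V_mV
    if math.isnan(thr):
        raise ValueError("spike_shape requires the threshold to be set")
    amp = float(v[peak]) - thr
    half = thr + amp / 2.0

    def _interp_crossing(i_out, i_in):
        # linear interpolation between a sample below and above half-level
        v0, v1 = v[i_out], v[i_in]
        if v1 == v0:
            return float(i_in)
        return i_out + (half - v0) / (v1 - v0) * (i_in - i_out)

    half_width = math.nan
    j = peak
    while j > 0 and v[j] > half:
        j -= 1
    k = peak
    while k + 1 < len(v) and v[k] > half:
        k += 1
    if v[j] <= half and v[k] <= half:
        t_rise = _interp_crossing(j, j + 1)
        t_fall = _interp_crossing(k, k - 1)
        half_width = (t_fall - t_rise) * dt_ms
    else:
        warnings.warn("half-amplitude crossing truncated by sweep end")

    def _ahp(window_ms):
        n = int(round(window_ms / dt_ms))
        if peak + n >= len(v):
            warnings.warn(
                f"{window_ms:g} ms AHP window truncated by sweep end"
            )
            return math.nan
        return thr - float(np.min(v[peak + 1: peak + n + 1]))

    fahp = _ahp(FAHP_WINDOW_MS)
    mahp = _ahp(MAHP_WINDOW_MS)
    event.amplitude_mV = amp
    event.half_width_ms = half_width
    event.fAHP_mV = fahp
    event.mAHP_mV = mahp
    return amp, half_width, fahp, mahp


def analyze_sweep(v: np.ndarray, dt_ms: float,
                  window: tuple[int, int] | None = None) -> list[SpikeEvent]:
    """Detect spikes and fill threshold and shape for each event."""
    events = detect_spikes(v, dt_ms, window=window)
    for ev in events:
        try:
            spike_threshold(v, ev, dt_ms)
        except ThresholdError:
            continue
        spike_shape(v, ev, dt_ms)
    return events


def _accepted(events: list[SpikeEvent]) -> list[SpikeEvent]:
    """Apply the 5 mV amplitude cutoff (unmeasurable amplitudes kept)."""
    return [
        ev for ev in events
        if math.isnan(ev.amplitude_mV)
        or ev.amplitude_mV >= AMPLITUDE_CUTOFF_MV
    ]


@dataclass
class Excitability:
    """Spike-train scalars over a depolarizing step family."""

    currents_pA: np.ndarray
    counts: np.ndarray
    freqs_Hz: np.ndarray
    rheobase_pA: float
    max_freq_Hz: float
    mean_freq_Hz: float
    mean_isi_ms: float
    amplitude_change: float
    burst_or_adaptive: str
    shape_step_index: int
    threshold_mV: float
    half_width_ms: float
    fAHP_mV: float
    mAHP_mV: float
    events_per_step: list = field(default_factory=list, repr=False)


def _half_max_step(counts: np.ndarray) -> int:
    """Index of the step whose count is nearest 50% of the maximum count,
    ties broken toward the lower current."""
    target = counts.max() / 2.0
    dist = np.abs(counts - target)
    return int(np.argmin(dist))  # argmin takes the first (lowest current)


def _burst_or_adaptive(isis: np.ndarray) -> str:
    if len(isis) >= 2:
        if isis[0] < 0.5 * float(np.median(isis[1:])):
            return "burst"
        if isis[-1] / isis[0] > 1.3:
            return "adaptive"
    return "neither"


def excitability_scalars(stepset: SweepSet) -> Excitability:
    """Rheobase, firing frequencies and AP-shape scalars from a step family.

    Frequencies are spike count / step duration.  A cell with no spikes
    at any step has undefined (NaN) rheobase and is flagged by the caller.
    """
    proto = stepset.protocol
    dt = stepset.dt_ms
    step_dur_s = proto.step_dur_s if proto is not None else 0.5
    if proto is not None:
        i0, i1 = proto.pulse_window()
        window = (i0, min(i1 + int(round(2.0 / dt)), stepset.n_samples))
    else:
        window = None
    depol = np.flatnonzero(stepset.step_amplitudes > 0)
    if len(depol) < 2:
        raise ValueError("need at least 2 depolarizing steps")
    currents = stepset.step_amplitudes[depol]
    events_per_step = []
    counts = np.zeros(len(depol), dtype=int)
    for m, k in enumerate(depol):
        events = _accepted(analyze_sweep(stepset.sweeps[k], dt, window))
        events_per_step.append(events)
        counts[m] = len(events)
    freqs = counts / step_dur_s
    spiking = np.flatnonzero(counts > 0)
    if len(spiking) == 0:
        return Excitability(
            currents_pA=currents, counts=counts, freqs_Hz=freqs,
            rheobase_pA=math.nan, max_freq_Hz=math.nan,
            mean_freq_Hz=float(freqs.mean()), mean_isi_ms=math.nan,
            amplitude_change=math.nan, burst_or_adaptive="neither",
            shape_step_index=-1, threshold_mV=math.nan,
            half_width_ms=math.nan, fAHP_mV=math.nan, mAHP_mV=math.nan,
            events_per_step=events_per_step,
        )
    rheobase = float(currents[spiking[0]])
    max_freq = float(freqs.max())
    mean_freq = float(freqs.mean())

    sel = _half_max_step(counts)
    sel_events = events_per_step[sel]
    peaks_ms = np.array([ev.peak_time_ms for ev in sel_events])
    isis = np.diff(peaks_ms)
    mean_isi = float(isis.mean()) if len(isis) >= 1 else math.nan
    amps = [ev.amplitude_mV for ev in sel_events
            if not math.isnan(ev.amplitude_mV)]
    amp_change = (
        (amps[1] - amps[0]) / amps[0] if len(amps) >= 2 else math.nan
    )
    pattern = _burst_or_adaptive(isis) if len(sel_events) >= 3 else "neither"

    def _mean_of(attr):
        vals = [getattr(ev, attr) for ev in sel_events]
        vals = [x for x in vals if not math.isnan(x)]
        return float(np.mean(vals)) if vals else math.nan

    return Excitability(
        currents_pA=currents, counts=counts, freqs_Hz=freqs,
        rheobase_pA=rheobase, max_freq_Hz=max_freq, mean_freq_Hz=mean_freq,
        mean_isi_ms=mean_isi, amplitude_change=amp_change,
        burst_or_adaptive=pattern, shape_step_index=sel,
        threshold_mV=_mean_of("threshold_V_mV"),
        half_width_ms=_mean_of("half_width_ms"),
        fAHP_mV=_mean_of("fAHP_mV"), mAHP_mV=_mean_of("mAHP_mV"),
        events_per_step=events_per_step,
    )


@dataclass
class PassiveProperties:
    R_in_MOhm: float
    tau_ms: float
    capacitance_pF: float
    V_m_mV: float
    sag_amplitude_mV: float
    rebound: bool


def _exp_decay(t, v_ss, dv, tau):
    return v_ss + dv * np.exp(-t / tau)


def passive_properties(test_set: SweepSet,
                       sag_set: SweepSet | None = None) -> PassiveProperties:
    """Passive membrane properties from the test and sag pulses.

    ``R_in`` is the steady-state voltage deflection over the -10 pA test
    current; ``tau`` comes from a single-exponential fit to the pulse
    onset transient, cross-checked against the 63% rise-time criterion;
    ``Cp = tau / R_in``.  Sag amplitude is the depth of the early minimum
    below the late steady state of the -200 pA pulse; rebound is any
    spike within 100 ms of that pulse's offset.
    """
    proto = test_set.protocol
    dt = test_set.dt_ms
    # repeats of the same pulse are averaged to suppress background noise
    v = test_set.sweeps.mean(axis=0)
    i0, i1 = proto.pulse_window()
    if i0 * dt < 50.0:
        warnings.warn("baseline shorter than 50 ms before the test pulse")
    baseline = float(np.mean(v[:i0]))
    amp_pA = test_set.step_amplitudes[0]
    n20 = int(round(20.0 / dt))
    steady = float(np.mean(v[i1 - n20:i1]))
    dv_ss = steady - baseline

    # single-exponential fit to the onset transient; when it is good its
    # extrapolated plateau replaces the windowed mean (a 100 ms pulse is
    # only ~2.5 tau for a slow cell, so the raw mean undershoots)
    seg = v[i0:i1]
    t = dt * np.arange(len(seg))
    tau = math.nan
    try:
        # 63% criterion as the initial guess for the fitted tau
        target = baseline + 0.63 * dv_ss
        reached = (
            np.flatnonzero(seg <= target) if dv_ss < 0
            else np.flatnonzero(seg >= target)
        )
        tau0 = t[reached[0]] if len(reached) else 10.0
        popt, _ = curve_fit(
            _exp_decay, t, seg,
            p0=[steady, baseline - steady, max(tau0, dt)],
            maxfev=10000,
        )
        rmse = float(np.sqrt(np.mean((seg - _exp_decay(t, *popt)) ** 2)))
        if rmse > 0.2 * abs(dv_ss):
            warnings.warn("noisy/non-exponential transient; tau undefined")
        else:
            tau = float(abs(popt[2]))
            steady = float(popt[0])
            dv_ss = steady - baseline
    except (RuntimeError, IndexError):
        warnings.warn("transient fit failed; tau undefined")
    r_in = abs(dv_ss) / (abs(amp_pA) / 1000.0)  # mV/nA = MOhm
    cp = tau / r_in * 1000.0 if not math.isnan(tau) else math.nan  # pF

    sag_amp = math.nan
    rebound = False
    if sag_set is not None:
        sproto = sag_set.protocol
        s0, s1 = sproto.pulse_window()
        sv = sag_set.sweeps.mean(axis=0)
        sdt = sag_set.dt_ms
        n50 = int(round(50.0 / sdt))
        v_steady = float(np.mean(sv[s1 - n50:s1]))
        v_min = float(np.min(sv[s0:s1]))
        sag_amp = v_steady - v_min
        n100 = int(round(100.0 / sdt))
        rebound = any(
            len(detect_spikes(
                sw, sdt, window=(s1, min(s1 + n100, len(sw)))
            )) > 0
            for sw in sag_set.sweeps
        )

    return PassiveProperties(
        R_in_MOhm=r_in, tau_ms=tau, capacitance_pF=cp, V_m_mV=baseline,
        sag_amplitude_mV=sag_amp, rebound=rebound,
    )


def capacitance_from_vc(current_pA: np.ndarray, dt_ms: float,
                        delta_V_mV: float, baseline_samples: int) -> float:
    """Capacitance from a voltage-clamp charging transient.

    Integrates the capacitive charge of the transient (baseline-corrected
    current) over the step and divides by the voltage step: C = Q / dV.
    Returns pF given pA, ms and mV.
    """
    i = np.asarray(current_pA, dtype=float)
    steady = i[-baseline_samples:].mean()
    q = np.sum(i - steady) * dt_ms  # pA*ms = fC
    return abs(q / delta_V_mV)  # fC/mV = pF


MAX_MISSING_FEATURES = 4


def assemble_features(step_set: SweepSet, test_set: SweepSet,
                      sag_set: SweepSet, hill_fit=None,
                      cell_id: str = "cell") -> FeatureVector:
    """Build the 18-feature vector for one cell.

    ``hill_fit`` is a fitted F-I curve result (midpoint and steepness);
    if omitted it is fitted here from the step family.  A vector with
    more than 4 missing features is flagged ``excluded`` and logged.
    """
    exc = excitability_scalars(step_set)
    passive = passive_properties(test_set, sag_set)
    if hill_fit is None and not math.isnan(exc.rheobase_pA):
        from .fihill import FitError, HillModel, build_fi

        try:
            curve = build_fi(step_set, exc.counts)
            hill_fit = HillModel(curve).fit()
        except (FitError, ValueError):
            hill_fit = None
    midpoint = hill_fit.midpoint_pA if hill_fit is not None else math.nan
    steepness = (
        hill_fit.steepness_Hz_per_pA if hill_fit is not None else math.nan
    )
    vec = FeatureVector(
        cell_id=cell_id,
        rheobase_pA=exc.rheobase_pA,
        capacitance_pF=passive.capacitance_pF,
        resting_potential_mV=passive.V_m_mV,
        input_resistance_MOhm=passive.R_in_MOhm,
        max_freq_Hz=exc.max_freq_Hz,
        sag_amplitude_mV=passive.sag_amplitude_mV,
        rebound=passive.rebound,
        burst_or_adaptive=exc.burst_or_adaptive,
        mean_freq_Hz=exc.mean_freq_Hz,
        mAHP_mV=exc.mAHP_mV,
        fAHP_mV=exc.fAHP_mV,
        midpoint_pA=midpoint,
        steepness_Hz_per_pA=steepness,
        tau_ms=passive.tau_ms,
        threshold_mV=exc.threshold_mV,
        amplitude_change=exc.amplitude_change,
        half_width_ms=exc.half_width_ms,
        mean_isi_ms=exc.mean_isi_ms,
    )
    if vec.n_missing() > MAX_MISSING_FEATURES:
        vec.excluded = True
        logger.warning(
            "cell %s excluded: %d of 18 features missing",
            cell_id, vec.n_missing(),
        )
    return vec
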