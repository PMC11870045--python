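"""Spontaneous event detection: action potentials and postsynaptic currents.

Spontaneous APs in gap-free voltage records use the same 0 mV-overshoot
criterion as evoked spikes; event frequency is events per second (Hz).

Spontaneous PSCs in gap-free current records are found with the
optimally-scaled sliding-template method (Clements & Bekkers): at every
offset the template is fitted to the data with a free scale and baseline
offset, and the detection score is scale / sqrt(SSE/(N-2)).  Events are
accepted where the score exceeds the detection criterion (default 3.5,
the standard value for this statistic) AND the fitted amplitude exceeds
the amplitude cutoff (default 5 pA).  Because the template is unit-peak,
the fitted scale is directly the event's peak amplitude.  The free
offset makes detection exactly invariant to DC shifts of the trace.

Inward events (EPSCs at -70 mV holding) are negative deflections; the
detector operates on the negated trace so amplitudes are reported as
positive magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, find_peaks

from .features import detect_spikes

__all__ = [
    "Template",
    "PSCEvent",
    "detect_saps",
    "detect_pscs",
    "event_stats",
    "cb_score",
]

DEFAULT_CRITERION = 3.5
DEFAULT_AMP_CUTOFF_PA = 5.0


@dataclass
class Template:
    """A unit-peak biexponential PSC template.

    Default kinetics (0.5 ms rise, 5 ms decay, 20 ms length) describe a
    typical cortical EPSC; adjust to the recorded events when known.
    """

    tau_rise_ms: float = 0.5
    tau_decay_ms: float = 5.0
    length_ms: float = 20.0
    sample_rate_hz: float = 20000.0
    samples: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.tau_rise_ms >= self.tau_decay_ms:
            raise ValueError("tau_rise must be shorter than tau_decay")
        if self.samples is None:
            dt = 1000.0 / self.sample_rate_hz
            t = dt * np.arange(int(round(self.length_ms / dt)))
            k = np.exp(-t / self.tau_decay_ms) - np.exp(-t / self.tau_rise_ms)
            self.samples = k / k.max()
        else:
            self.samples = np.asarray(self.samples, dtype=float)
            peak = self.samples.max()
            if not math.isclose(peak, 1.0, rel_tol=1e-9):
                self.samples = self.samples / peak

    @property
    def time_to_peak_ms(self) -> float:
        """Analytic rise time (onset to peak) of the biexponential."""
        tr, td = self.tau_rise_ms, self.tau_decay_ms
        return tr * td / (td - tr) * math.log(td / tr)


@dataclass
class PSCEvent:
    onset_time_s: float
    peak_amplitude_pA: float
    detection_score: float


def detect_saps(trace_mV: np.ndarray, sample_rate_hz: float):
    """Spontaneous APs in a gap-free voltage trace.

    Returns ``(times_s, frequency_Hz)`` with frequency = events / duration.
    """
    dt_ms = 1000.0 / sample_rate_hz
    events = detect_spikes(np.asarray(trace_mV, dtype=float), dt_ms)
    times = np.array([ev.peak_time_ms / 1000.0 for ev in events])
    duration_s = len(trace_mV) / sample_rate_hz
    return times, len(times) / duration_s


def cb_score(trace: np.ndarray, template: np.ndarray):
    """Sliding optimally-scaled-template statistic.

    For every window the template is fitted as ``scale*T + offset`` by
    least squares; returns ``(score, scale)`` arrays of length
    ``len(trace) - len(template) + 1`` where
    ``score = scale / sqrt(SSE/(N-2))``.
    """
    d = np.asarray(trace, dtype=float)
    T = np.asarray(template, dtype=float)
    N = len(T)
    if N > len(d):
        raise ValueError("template longer than trace")
    sum_T = T.sum()
    sum_TT = float(T @ T)
    c = np.cumsum(np.concatenate([[0.0], d]))
    c2 = np.cumsum(np.concatenate([[0.0], d * d]))
    n_win = len(d) - N + 1
    sum_d = c[N:] - c[:-N]
    sum_dd = c2[N:] - c2[:-N]
    sum_Td = fftconvolve(d, T[::-1], mode="valid")
    denom = sum_TT - sum_T * sum_T / N
    scale = (sum_Td - sum_T * sum_d / N) / denom
    offset = (sum_d - scale * sum_T) / N
    sse = (
        sum_dd + scale ** 2 * sum_TT + N * offset ** 2
        - 2.0 * scale * sum_Td - 2.0 * offset * sum_d
        + 2.0 * scale * offset * sum_T
    )
    sse = np.maximum(sse, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = scale / np.sqrt(sse / (N - 2))
    score[~np.isfinite(score)] = 0.0
    assert len(score) == n_win
    return score, scale


def detect_pscs(trace_pA: np.ndarray, template: Template | None = None,
                criterion: float = DEFAULT_CRITERION,
                amp_cutoff_pA: float = DEFAULT_AMP_CUTOFF_PA,
                sample_rate_hz: float = 20000.0,
                polarity: str = "inward") -> list[PSCEvent]:
    """Detect PSCs by sliding optimally-scaled-template matching.

    Events are local maxima of the detection score at least the
    template's rise time apart, accepted when score >= ``criterion`` and
    fitted amplitude >= ``amp_cutoff_pA``.  ``polarity="inward"`` negates
    the trace so inward (negative) events give positive amplitudes.
    """
    if template is None:
        template = Template(sample_rate_hz=sample_rate_hz)
    d = np.asarray(trace_pA, dtype=float)
    if polarity == "inward":
        d = -d
    elif polarity != "outward":
        raise ValueError("polarity must be 'inward' or 'outward'")
    score, scale = cb_score(d, template.samples)
    dt_ms = 1000.0 / sample_rate_hz
    min_sep = max(1, int(round(template.time_to_peak_ms / dt_ms)))
    peaks, _ = find_peaks(score, height=criterion, distance=min_sep)
    # one strong event produces a plateau of suprathreshold score around
    # its onset; greedy non-maximum suppression keeps the best-scoring
    # candidate within half the template length
    suppress = int(round(len(template.samples) / 2))
    order = peaks[np.argsort(-score[peaks], kind="stable")]
    accepted: list[int] = []
    for i in order:
        if all(abs(i - j) > suppress for j in accepted):
            accepted.append(int(i))
    events = []
    for i in sorted(accepted):
        if scale[i] >= amp_cutoff_pA:
            events.append(PSCEvent(
                onset_time_s=i / sample_rate_hz,
                peak_amplitude_pA=float(scale[i]),
                detection_score=float(score[i]),
            ))
    return events


def event_stats(events, duration_s: float):
    """(frequency Hz, mean amplitude pA) for a list of accepted events.

    With zero events the frequency is 0 and the amplitude is NaN.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = len(events)
    freq = n / duration_s
    if n == 0:
        return freq, math.nan
    amps = [
        ev.peak_amplitude_pA if hasattr(ev, "peak_amplitude_pA") else ev
        for ev in events
    ]
    return freq, float(np.mean(amps))
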