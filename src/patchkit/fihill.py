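"""Hill-sigmoid characterization of firing-frequency vs current (F-I) curves.

The F-I curve of a neuron (spike count per 500 ms step, in Hz, against
injected current in pA) is fitted with the sigmoidal Hill function

    f(x) = a * x**b / (c**b + x**b)

whose three parameters describe the dynamics of intrinsic excitability:
``a`` is the curve maximum (maximum frequency, Hz), ``b`` the
dimensionless Hill exponent, and ``c`` the midpoint (the current at
which firing reaches half of the maximum, pA; f(c) = a/2 identically).
The neuronal gain ("steepness") is reported as the slope of the fitted
curve at its midpoint, f'(c) = a*b/(4c) in Hz/pA, which carries the
units gain is conventionally quoted in; the raw exponent ``b`` is kept
alongside.

The fit is nonlinear least squares with bounds chosen for stability on
sparse 10 pA grids: a in (0, 3*max F], b in (0, 100], c in
(0, 3*max current]; start values a0 = max observed F, c0 = the current
of the first point at or above a0/2, b0 = 2; tolerances 1e-10, at most
1e4 function evaluations.  Zero-frequency points are kept (they
constrain the midpoint).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .io import SweepSet

__all__ = [
    "FICurve",
    "HillModel",
    "HillFitResults",
    "FitError",
    "build_fi",
    "fit_hill",
    "hill",
]


class FitError(ValueError):
    """The F-I data cannot support a Hill fit."""


def hill(x, a, b, c):
    """The Hill sigmoid a*x^b / (c^b + x^b), defined as 0 at x = 0."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(x > 0, (c / np.maximum(x, 1e-300)) ** b, np.inf)
    return a / (1.0 + ratio)


@dataclass
class FICurve:
    """An observed F-I relation: ascending currents (pA) and rates (Hz)."""

    currents_pA: np.ndarray
    freqs_Hz: np.ndarray

    def __post_init__(self) -> None:
        self.currents_pA = np.asarray(self.currents_pA, dtype=float)
        self.freqs_Hz = np.asarray(self.freqs_Hz, dtype=float)
        if len(self.currents_pA) != len(self.freqs_Hz):
            raise ValueError("currents and frequencies differ in length")
        if np.any(np.diff(self.currents_pA) <= 0):
            raise ValueError("currents must be strictly increasing")


def build_fi(stepset: SweepSet, counts: np.ndarray,
             step_dur_s: float | None = None) -> FICurve:
    """F-I curve from per-step spike counts (amplitude filter applied
    upstream): one (I, F) point per depolarizing step, F = count/duration."""
    proto = stepset.protocol
    if step_dur_s is None:
        step_dur_s = proto.step_dur_s if proto is not None else 0.5
    depol = stepset.step_amplitudes > 0
    currents = stepset.step_amplitudes[depol]
    counts = np.asarray(counts, dtype=float)
    if len(counts) == len(stepset.step_amplitudes):
        counts = counts[depol]
    if len(counts) != len(currents):
        raise ValueError("counts do not match the depolarizing steps")
    return FICurve(currents, counts / step_dur_s)


class HillModel:
    """Hill-sigmoid model of an F-I curve.

    Examples
    --------
    >>> curve = FICurve([20, 40, 60, 80], [0, 4, 10, 18])
    >>> res = HillModel(curve).fit()
    >>> round(res.midpoint_pA)  # doctest: +SKIP
    """

    def __init__(self, curve: FICurve | None = None, currents=None,
                 freqs=None):
        if curve is None:
            curve = FICurve(currents, freqs)
        self.curve = curve
        x, y = curve.currents_pA, curve.freqs_Hz
        if len(x) < 4:
            raise FitError("fit refused: need at least 4 F-I points")
        if not np.any(y > 0):
            raise FitError("fit refused: flat (all-zero) F-I curve")
        if len(np.unique(y[y > 0])) <= 1 and np.count_nonzero(y) <= 1:
            raise FitError("degenerate data: one distinct nonzero frequency")

    @classmethod
    def from_sweepset(cls, stepset: SweepSet, counts) -> "HillModel":
        return cls(build_fi(stepset, counts))

    def fit(self, tol: float = 1e-10, max_nfev: int = 10000
            ) -> "HillFitResults":
        x, y = self.curve.currents_pA, self.curve.freqs_Hz
        a0 = float(y.max())
        above = np.flatnonzero(y >= a0 / 2.0)
        c0 = float(x[above[0]]) if len(above) else float(np.median(x))
        b0 = 2.0
        lo = np.array([1e-9, 1e-9, 1e-9])
        hi = np.array([3.0 * a0, 100.0, 3.0 * float(x.max())])
        p0 = np.clip([a0, b0, c0], lo, hi)

        def resid(p):
            return hill(x, *p) - y

        sol = least_squares(
            resid, p0, bounds=(lo, hi), xtol=tol, ftol=tol, gtol=tol,
            max_nfev=max_nfev,
        )
        a, b, c = sol.x
        at_bound = bool(np.any(np.isclose(sol.x, hi, rtol=1e-6)))
        converged = bool(sol.status > 0) and not at_bound \
            and sol.nfev < max_nfev
        rmse = float(np.sqrt(np.mean(sol.fun ** 2)))
        return HillFitResults(
            model=self, a_Hz=float(a), b=float(b), c_pA=float(c),
            rmse_Hz=rmse, converged=converged, n_points=len(x),
            extrapolated_maximum=bool(a >= y.max() * (1.0 + 1e-9)),
        )


@dataclass
class HillFitResults:
    """Fitted F-I parameters and diagnostics.

    ``steepness_Hz_per_pA`` is the midpoint slope a*b/(4c) — the
    neuronal gain in Hz/pA; ``b`` is the dimensionless exponent.
    ``extrapolated_maximum`` notes fits where the estimated plateau
    exceeds the largest observed rate (curve not yet saturated).
    """

    model: HillModel
    a_Hz: float
    b: float
    c_pA: float
    rmse_Hz: float
    converged: bool
    n_points: int
    extrapolated_maximum: bool = False

    @property
    def max_freq_Hz(self) -> float:
        return self.a_Hz

    @property
    def midpoint_pA(self) -> float:
        return self.c_pA

    @property
    def steepness_Hz_per_pA(self) -> float:
        return self.a_Hz * self.b / (4.0 * self.c_pA)

    def predict(self, currents) -> np.ndarray:
        return hill(currents, self.a_Hz, self.b, self.c_pA)

    def params_dict(self) -> dict:
        return {
            "a_Hz": self.a_Hz,
            "b": self.b,
            "c_pA": self.c_pA,
            "steepness_Hz_per_pA": self.steepness_Hz_per_pA,
            "rmse_Hz": self.rmse_Hz,
            "converged": self.converged,
            "n_points": self.n_points,
            "extrapolated_maximum": self.extrapolated_maximum,
        }

    def summary(self) -> str:
        lines = [
            "Hill F-I fit: f(x) = a x^b / (c^b + x^b)",
            f"  n points            {self.n_points:>10d}",
            f"  a (max freq, Hz)    {self.a_Hz:>10.3f}",
            f"  b (exponent)        {self.b:>10.3f}",
            f"  c (midpoint, pA)    {self.c_pA:>10.3f}",
            f"  gain a*b/4c (Hz/pA) {self.steepness_Hz_per_pA:>10.4f}",
            f"  RMSE (Hz)           {self.rmse_Hz:>10.3f}",
            f"  converged           {str(self.converged):>10s}",
        ]
        if self.extrapolated_maximum:
            lines.append("  note: plateau extrapolated beyond observed rates")
        return "\n".join(lines)


def fit_hill(curve: FICurve, **kwargs) -> HillFitResults:
    """Functional wrapper: fit the Hill sigmoid to an F-I curve."""
    return HillModel(curve).fit(**kwargs)


def midpoint_identity_gap(result: HillFitResults) -> float:
    """|f(c) - a/2| for a fitted curve; zero under the model."""
    return float(abs(result.predict(result.c_pA) - result.a_Hz / 2.0))
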