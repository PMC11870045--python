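"""Reading and writing sweep data and result tables.

The on-disk sweep format is a diff-able TSV dialect: ``#``-prefixed
``key=value`` header lines, then a column-header row
(``time_s  sweep_000  sweep_001 ...``), then one row per sample.  Voltages
and currents are written as decimal text with 6 significant digits and are
parsed back with ``float``, so a write -> read -> write cycle is stable
byte-for-byte.

Internal unit conventions (fixed across the package): mV, pA, ms for
reported quantities, seconds on the file time axis, MOhm, pF, Hz.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SweepSet",
    "FormatError",
    "read_sweeps",
    "write_sweeps",
    "export_feature_matrix",
    "result_table",
    "read_abf",
    "read_nwb",
    "FEATURE_COLUMNS",
]

CHANNEL_KINDS = ("voltage_mV", "current_pA")

#: Fixed column order of the 18-feature matrix used for clustering.
FEATURE_COLUMNS = [
    "rheobase_pA",
    "capacitance_pF",
    "resting_potential_mV",
    "input_resistance_MOhm",
    "max_freq_Hz",
    "sag_amplitude_mV",
    "rebound",
    "burst_or_adaptive",
    "mean_freq_Hz",
    "mAHP_mV",
    "fAHP_mV",
    "midpoint_pA",
    "steepness_Hz_per_pA",
    "tau_ms",
    "threshold_mV",
    "amplitude_change",
    "half_width_ms",
    "mean_isi_ms",
]


class FormatError(ValueError):
    """Raised when a sweep file does not conform to the TSV dialect."""


@dataclass
class SweepSet:
    """A family of time-aligned sweeps from one cell and one protocol.

    Parameters
    ----------
    sample_rate : float
        Sampling rate in Hz.
    channel_kind : str
        ``"voltage_mV"`` or ``"current_pA"``.
    sweeps : ndarray, shape (n_sweeps, n_samples)
        Sample matrix; all sweeps have equal length.
    step_amplitudes : ndarray, shape (n_sweeps,)
        Injected step amplitude per sweep in pA (0 for gap-free records).
    protocol : object, optional
        The stimulation protocol that produced the sweeps.
    annotations : dict
        Free-form string metadata (cell id, condition, ground truth for
        synthetic data, ...).
    """

    sample_rate: float
    channel_kind: str
    sweeps: np.ndarray
    step_amplitudes: np.ndarray
    protocol: object | None = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sweeps = np.asarray(self.sweeps, dtype=float)
        if self.sweeps.ndim == 1:
            self.sweeps = self.sweeps[None, :]
        self.step_amplitudes = np.asarray(self.step_amplitudes, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.channel_kind not in CHANNEL_KINDS:
            raise ValueError(f"channel_kind must be one of {CHANNEL_KINDS}")
        if len(self.step_amplitudes) != self.n_sweeps:
            raise ValueError(
                "step_amplitudes length does not match number of sweeps"
            )

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def n_samples(self) -> int:
        return self.sweeps.shape[1]

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate

    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def true_spike_times_ms(self, sweep: int) -> np.ndarray | None:
        """Ground-truth spike times for synthetic sweeps, if recorded."""
        raw = self.annotations.get("true_spike_times_ms")
        if raw is None:
            return None
        times = json.loads(raw) if isinstance(raw, str) else raw
        return np.asarray(times[sweep], dtype=float)


def write_sweeps(sweepset: SweepSet, path) -> None:
    """Write a :class:`SweepSet` in the TSV sweep dialect."""
    ss = sweepset
    lines = ["# patchkit-sweeps v1"]
    lines.append(f"# sample_rate_hz={ss.sample_rate:.6g}")
    lines.append(f"# channel_kind={ss.channel_kind}")
    amps = ",".join(f"{a:.6g}" for a in ss.step_amplitudes)
    lines.append(f"# step_amplitudes_pA={amps}")
    if ss.protocol is not None:
        for key, val in dataclasses.asdict(ss.protocol).items():
            if isinstance(val, bool) or not isinstance(val, (int, float)):
                text = str(val)
            elif key == "repeats":
                text = str(int(val))
            else:
                text = repr(float(val))  # normalized: idempotent round trip
            lines.append(f"# protocol:{key}={text}")
    for key, val in sorted(ss.annotations.items()):
        if "\n" in str(val):
            raise ValueError(f"annotation {key!r} contains a newline")
        lines.append(f"# annotation:{key}={val}")
    header = "time_s\t" + "\t".join(
        f"sweep_{i:03d}" for i in range(ss.n_sweeps)
    )
    lines.append(header)
    time = ss.time_s()
    for j in range(ss.n_samples):
        row = [f"{time[j]:.6g}"]
        row.extend(f"{ss.sweeps[i, j]:.6g}" for i in range(ss.n_sweeps))
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_sweeps(path) -> SweepSet:
    """Read a sweep file in the TSV dialect; errors are total.

    Raises
    ------
    FormatError
        On missing header keys, ragged rows, non-numeric samples or an
        unknown channel kind, naming the offending line.
    """
    meta: dict[str, str] = {}
    protocol_meta: dict[str, str] = {}
    annotations: dict[str, str] = {}
    rows: list[list[str]] = []
    n_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    continue  # banner line
                key, _, val = body.partition("=")
                key = key.strip()
                if key.startswith("protocol:"):
                    protocol_meta[key[len("protocol:"):]] = val
                elif key.startswith("annotation:"):
                    annotations[key[len("annotation:"):]] = val
                else:
                    meta[key] = val
                continue
            cells = line.split("\t")
            if n_cols is None:
                if cells[0] != "time_s":
                    raise FormatError(
                        f"{path}:{lineno}: expected 'time_s' column header"
                    )
                n_cols = len(cells)
                continue
            if len(cells) != n_cols:
                raise FormatError(
                    f"{path}:{lineno}: ragged row "
                    f"({len(cells)} columns, expected {n_cols})"
                )
            rows.append(cells)
    if n_cols is None:
        raise FormatError(f"{path}: no column header row found")
    for required in ("sample_rate_hz", "channel_kind"):
        if required not in meta:
            raise FormatError(f"{path}: missing header key {required}")
    try:
        sample_rate = float(meta["sample_rate_hz"])
    except ValueError as exc:
        raise FormatError(f"{path}: bad sample_rate_hz") from exc
    channel_kind = meta["channel_kind"]
    if channel_kind not in CHANNEL_KINDS:
        raise FormatError(
            f"{path}: unknown channel_kind {channel_kind!r} "
            f"(unit mismatch?)"
        )
    n_sweeps = n_cols - 1
    try:
        data = np.array(
            [[float(c) for c in row[1:]] for row in rows], dtype=float
        ).T
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric sample value") from exc
    if data.size == 0:
        data = np.empty((n_sweeps, 0))
    amps_raw = meta.get("step_amplitudes_pA", "")
    if amps_raw.strip():
        amps = np.array([float(a) for a in amps_raw.split(",")])
        if len(amps) != n_sweeps:
            raise FormatError(
                f"{path}: step_amplitudes_pA lists {len(amps)} values "
                f"for {n_sweeps} sweeps"
            )
    else:
        amps = np.zeros(n_sweeps)
    protocol = None
    if protocol_meta:
        from .synth import Protocol  # local import to avoid a cycle

        protocol = Protocol.from_strings(protocol_meta)
    return SweepSet(
        sample_rate=sample_rate,
        channel_kind=channel_kind,
        sweeps=data,
        step_amplitudes=amps,
        protocol=protocol,
        annotations=annotations,
    )


def export_feature_matrix(vectors: Sequence, path=None) -> pd.DataFrame:
    """Assemble per-cell feature vectors into a cells x 18 table.

    Column order is fixed (:data:`FEATURE_COLUMNS`).  Missing values are
    written as ``NA``.  Returns the DataFrame; writes CSV when ``path``
    is given.
    """
    records = []
    index = []
    for vec in vectors:
        d = vec.as_dict() if hasattr(vec, "as_dict") else dict(vec)
        index.append(d.pop("cell_id", f"cell_{len(index):03d}"))
        records.append({col: d.get(col, np.nan) for col in FEATURE_COLUMNS})
    frame = pd.DataFrame(records, columns=FEATURE_COLUMNS)
    frame.insert(0, "cell_id", index)
    if path is not None:
        frame.to_csv(path, index=False, na_rep="NA", float_format="%.6g")
    return frame


def result_table(rows: Sequence[tuple]) -> pd.DataFrame:
    """Long-format results: one row per (cell, condition, feature).

    Each input row is ``(cell_id, condition, feature, value, unit)``; a
    unit is attached to every value.
    """
    frame = pd.DataFrame(
        rows, columns=["cell_id", "condition", "feature", "value", "unit"]
    )
    if frame["unit"].isna().any():
        raise ValueError("every value must carry a unit")
    dupes = frame.duplicated(["cell_id", "condition", "feature"])
    if dupes.any():
        raise ValueError("duplicate (cell, condition, feature) rows")
    return frame


def read_abf(path) -> SweepSet:
    """Adapter for Axon Binary Format files (requires ``pyabf``)."""
    try:
        import pyabf  # type: ignore
    except ImportError as exc:  # pragma: no cover - backend optional
        raise ImportError(
            "reading ABF files requires the optional 'pyabf' package"
        ) from exc
    abf = pyabf.ABF(str(path))  # pragma: no cover
    sweeps = []
    for i in range(abf.sweepCount):
        abf.setSweep(i)
        sweeps.append(np.asarray(abf.sweepY, dtype=float))
    kind = "voltage_mV" if "mV" in (abf.sweepUnitsY or "mV") else "current_pA"
    return SweepSet(
        sample_rate=float(abf.dataRate),
        channel_kind=kind,
        sweeps=np.vstack(sweeps),
        step_amplitudes=np.zeros(len(sweeps)),
        annotations={"source": str(path)},
    )


def read_nwb(path) -> SweepSet:
    """Adapter for NWB intracellular files (requires ``pynwb``)."""
    try:
        import pynwb  # type: ignore # noqa: F401
    except ImportError as exc:  # pragma: no cover - backend optional
        raise ImportError(
            "reading NWB files requires the optional 'pynwb' package"
        ) from exc
    raise NotImplementedError(  # pragma: no cover
        "NWB adapter: map your acquisition series onto SweepSet explicitly"
    )
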