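"""Severity quantization of raw vital-sign series (personalization stage).

Raw sensor values are discretized into an ordered alphabet of severity
symbols centred on the clinically normal level ``A``: above-normal values
map to ``A+``, ``A++``, ... and sub-normal values to ``A-``, ``A--``, ...
The number of levels, the normal band, and the interval breadth are all
per-sensor, per-patient configuration — that is where personalization
lives.  Quantized series from several sensors are then aligned into a
patient-specific matrix (PSM) of N sensor rows by W time-window columns,
the unit on which motif extraction operates.

Boundary convention: a value sitting exactly on an interval boundary takes
the *less severe* of the two adjacent symbols.  In particular, for a MAP
sensor with normal band starting at 60 mmHg, a reading of exactly 60 is
normal (``A``), consistent with hypotensive events being defined by values
strictly below 60.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "MISSING",
    "SeveritySymbol",
    "SensorSpec",
    "SeverityScheme",
    "QuantizedSeries",
    "PSM",
    "build_uniform_scheme",
    "quantize_series",
    "build_psm",
    "resample_hold",
]

#: Marker used in symbol sequences for samples that were never observed.
MISSING = None


@dataclass(frozen=True, order=True)
class SeveritySymbol:
    """One severity level.

    ``ordinal`` 0 is the normal level ``A``; positive ordinals carry that
    many ``+`` marks, negative ordinals that many ``-`` marks.  Ordering of
    symbols follows the ordinal, so sorting runs from the most sub-normal
    to the most supra-normal level.
    """

    ordinal: int

    @property
    def label(self) -> str:
        if self.ordinal >= 0:
            return "A" + "+" * self.ordinal
        return "A" + "-" * (-self.ordinal)

    @classmethod
    def from_label(cls, label: str) -> "SeveritySymbol":
        if not label.startswith("A"):
            raise InvalidParameterError(f"malformed severity label: {label!r}")
        marks = label[1:]
        if marks == "" :
            return cls(0)
        if set(marks) == {"+"}:
            return cls(len(marks))
        if set(marks) == {"-"}:
            return cls(-len(marks))
        raise InvalidParameterError(f"malformed severity label: {label!r}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label

    def __repr__(self) -> str:
        return f"SeveritySymbol({self.label!r})"


@dataclass(frozen=True)
class SensorSpec:
    """Static description of one body sensor and its severity grading.

    Parameters
    ----------
    sensor_id
        Short identifier used in PSM rows, files and motif codecs.
    name, units
        Human-readable descriptors (e.g. "Mean arterial pressure", "mmHg").
    sampling_freq
        Nominal sampling rate in samples per minute.
    n_sub_levels, n_supra_levels
        How many severity levels extend below and above the normal band.
        Together with the normal level they give the sensor's level count.
    near_normal_threshold
        Hamming distance from ``A`` below which a symbol still counts as
        near-normal for consensus purposes.
    intervention_times
        Map from severity label to the medically accepted intervention time
        in minutes.  A missing entry means the level carries no urgency.
    """

    sensor_id: str
    name: str = ""
    units: str = ""
    sampling_freq: float = 1.0
    n_sub_levels: int = 2
    n_supra_levels: int = 2
    near_normal_threshold: int = 1
    intervention_times: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_sub_levels < 0 or self.n_supra_levels < 0:
            raise InvalidParameterError("level counts must be non-negative")
        if self.sampling_freq <= 0:
            raise InvalidParameterError("sampling_freq must be positive")
        if self.near_normal_threshold < 0:
            raise InvalidParameterError("near_normal_threshold must be >= 0")
        if self.near_normal_threshold > max(self.n_sub_levels, self.n_supra_levels, 0):
            raise InvalidParameterError(
                "near_normal_threshold exceeds the sensor's level range"
            )
        for label, delta in self.intervention_times.items():
            SeveritySymbol.from_label(label)  # validates the label
            if delta <= 0:
                raise InvalidParameterError(
                    f"intervention time for {label} must be positive"
                )

    @property
    def n_levels(self) -> int:
        return self.n_sub_levels + self.n_supra_levels + 1

    def symbols(self) -> list[SeveritySymbol]:
        """All levels of this sensor, most sub-normal first."""
        return [
            SeveritySymbol(k)
            for k in range(-self.n_sub_levels, self.n_supra_levels + 1)
        ]


@dataclass(frozen=True)
class SeverityScheme:
    """The quantizer for one sensor: raw-value intervals -> severity symbols.

    ``breakpoints`` are the strictly increasing interval boundaries and
    ``symbols`` the per-interval severity levels (one more than there are
    breakpoints).  The outermost intervals are unbounded, so every finite
    raw value maps to exactly one symbol; values beyond the configured range
    clip to the extreme symbol on that side.
    """

    sensor_id: str
    breakpoints: tuple[float, ...]
    symbols: tuple[SeveritySymbol, ...]

    def __post_init__(self) -> None:
        if len(self.symbols) != len(self.breakpoints) + 1:
            raise InvalidParameterError(
                "scheme needs exactly one symbol per interval"
            )
        if len(self.symbols) == 0:
            raise InvalidParameterError("scheme must define at least one symbol")
        if any(b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])):
            raise InvalidParameterError("breakpoints must be strictly increasing")
        ords = [s.ordinal for s in self.symbols]
        # severity must be monotone on each side of the normal level
        try:
            i0 = ords.index(min(ords, key=abs))
        except ValueError:  # pragma: no cover - len>=1 guaranteed above
            raise
        below, above = ords[: i0 + 1], ords[i0:]
        if any(b2 < b1 for b1, b2 in zip(below, below[1:])) or any(
            b2 < b1 for b1, b2 in zip(above, above[1:])
        ):
            raise InvalidParameterError("symbol ordinals must increase with raw value")

    def quantize_value(self, value: float) -> Optional[SeveritySymbol]:
        """Map one raw value to its severity symbol (``MISSING`` for NaN)."""
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return MISSING
        j = bisect_left(self.breakpoints, value)
        if j < len(self.breakpoints) and self.breakpoints[j] == value:
            # boundary: take the less severe neighbour
            left, right = self.symbols[j], self.symbols[j + 1]
            return left if abs(left.ordinal) < abs(right.ordinal) else right
        return self.symbols[j]


@dataclass(frozen=True)
class QuantizedSeries:
    """A severity-symbol series on a regular time grid.

    ``start_time`` and ``step`` are in minutes; ``symbols`` may contain the
    ``MISSING`` marker where no sample was observed.
    """

    sensor_id: str
    start_time: float
    step: float
    symbols: tuple[Optional[SeveritySymbol], ...]

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise InvalidParameterError("step must be positive")

    def __len__(self) -> int:
        return len(self.symbols)

    def ordinals(self, missing: float = math.nan) -> np.ndarray:
        """Symbols as signed ordinals (float array; missing -> ``missing``)."""
        return np.array(
            [missing if s is MISSING else float(s.ordinal) for s in self.symbols]
        )


@dataclass(frozen=True)
class PSM:
    """Patient Specific Matrix: N sensor rows by W time-window columns.

    Each cell holds one severity symbol (or the missing marker).  Row order
    is the declared sensor order and is what motif entries follow.
    """

    patient_id: str
    sensor_ids: tuple[str, ...]
    cells: tuple[tuple[Optional[SeveritySymbol], ...], ...]

    def __post_init__(self) -> None:
        if len(self.cells) != len(self.sensor_ids):
            raise InvalidParameterError("one cell row per sensor required")
        widths = {len(row) for row in self.cells}
        if len(widths) > 1:
            raise InvalidParameterError("all PSM rows must have equal width")

    @property
    def n_sensors(self) -> int:
        return len(self.sensor_ids)

    @property
    def window_len(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    def row(self, sensor_id: str) -> tuple[Optional[SeveritySymbol], ...]:
        try:
            return self.cells[self.sensor_ids.index(sensor_id)]
        except ValueError:
            raise InvalidParameterError(f"unknown sensor {sensor_id!r}") from None


def build_uniform_scheme(
    sensor: SensorSpec,
    normal_band: tuple[float, float],
    breadth: float,
) -> SeverityScheme:
    """Build a quantizer with equal-width severity intervals.

    Intervals of width ``breadth`` (raw units, e.g. mmHg) are stacked
    outward from the normal band ``[low, high]``: ``n_sub_levels`` below
    and ``n_supra_levels`` above.  The outermost intervals are unbounded so
    out-of-range values clip to the extreme symbol.  ``high`` may be
    ``inf`` for sensors graded only downward (e.g. MAP for hypotension).

    Example: MAP with normal band starting at 60 mmHg and breadth 10 puts
    ``A-`` on [50, 60) and ``A--`` on values below 50.
    """
    low, high = normal_band
    if breadth <= 0:
        raise InvalidParameterError("quantization breadth must be positive")
    if low > high:
        raise InvalidParameterError("inverted normal band")
    if sensor.n_sub_levels > 0 and not math.isfinite(low):
        raise InvalidParameterError("sub-normal levels need a finite band low edge")
    if sensor.n_supra_levels > 0 and not math.isfinite(high):
        raise InvalidParameterError("supra-normal levels need a finite band high edge")
    breakpoints: list[float] = []
    for k in range(sensor.n_sub_levels, 0, -1):
        breakpoints.append(low - (k - 1) * breadth)
    for k in range(1, sensor.n_supra_levels + 1):
        breakpoints.append(high + (k - 1) * breadth)
    symbols = sensor.symbols()
    return SeverityScheme(
        sensor_id=sensor.sensor_id,
        breakpoints=tuple(breakpoints),
        symbols=tuple(symbols),
    )


def quantize_series(
    values: Sequence[float] | np.ndarray,
    scheme: SeverityScheme,
    start_time: float = 0.0,
    step: float = 1.0,
) -> QuantizedSeries:
    """Quantize a regularly sampled raw series into severity symbols.

    NaN samples become the missing marker; everything else maps through
    ``scheme``, clipping out-of-range values to the extreme symbol.
    """
    arr = np.asarray(values, dtype=float)
    symbols = tuple(scheme.quantize_value(v) for v in arr)
    return QuantizedSeries(
        sensor_id=scheme.sensor_id, start_time=start_time, step=step, symbols=symbols
    )


def build_psm(
    series: Mapping[str, QuantizedSeries],
    window_start: float,
    window_len: int,
    patient_id: str = "",
    sensor_order: Sequence[str] | None = None,
) -> PSM:
    """Assemble a PSM from aligned quantized series.

    All series must share a common step (resample first if sensors run at
    different rates).  ``window_start`` is in minutes; samples outside a
    series are padded with the missing marker so a short series still
    yields a full-width row.
    """
    if window_len <= 0:
        raise InvalidParameterError("window length W must be positive")
    if not series:
        raise InvalidParameterError("at least one sensor series required")
    order = tuple(sensor_order) if sensor_order is not None else tuple(series)
    for sid in order:
        if sid not in series:
            raise InvalidParameterError(f"unknown sensor {sid!r}")
    steps = {series[sid].step for sid in order}
    if len(steps) != 1:
        raise InvalidParameterError("series must share a common step; resample first")
    step = steps.pop()
    rows = []
    for sid in order:
        qs = series[sid]
        offset = (window_start - qs.start_time) / step
        i0 = round(offset)
        if abs(offset - i0) > 1e-9:
            raise InvalidParameterError(
                f"window start is not aligned to the grid of sensor {sid!r}"
            )
        row = [
            qs.symbols[i] if 0 <= i < len(qs.symbols) else MISSING
            for i in range(i0, i0 + window_len)
        ]
        rows.append(tuple(row))
    return PSM(patient_id=patient_id, sensor_ids=order, cells=tuple(rows))


def resample_hold(
    times: Sequence[float] | np.ndarray,
    values: Sequence[float] | np.ndarray,
    step: float = 1.0,
    start: float | None = None,
    end: float | None = None,
    max_hold: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Previous-value-hold resampling onto a regular grid.

    Multi-rate sensors are aligned to a common step (default one minute)
    before PSM assembly.  Each grid point takes the most recent sample at
    or before it; if ``max_hold`` minutes (default: one native inter-sample
    gap, estimated as the median spacing) have passed since that sample,
    the grid point is left as NaN — gaps stay gaps instead of being imputed.

    Returns ``(grid_times, grid_values)``.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size == 0:
        return np.array([]), np.array([])
    if step <= 0:
        raise InvalidParameterError("step must be positive")
    order = np.argsort(t, kind="stable")
    t, v = t[order], v[order]
    if max_hold is None:
        max_hold = float(np.median(np.diff(t))) if t.size > 1 else step
    lo = t[0] if start is None else start
    hi = t[-1] if end is None else end
    n = int(math.floor((hi - lo) / step)) + 1
    grid = lo + step * np.arange(max(n, 0))
    idx = np.searchsorted(t, grid, side="right") - 1
    out = np.full(grid.shape, np.nan)
    ok = idx >= 0
    age = np.where(ok, grid - t[np.clip(idx, 0, None)], np.inf)
    ok &= age <= max_hold + 1e-9
    out[ok] = v[idx[ok]]
    return grid, out
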