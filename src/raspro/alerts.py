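"""Interventional-time alert scoring and patient prioritization (prevention stage).

Every (sensor, severity level) pair may carry a medically accepted
intervention time ``delta`` in minutes — how long a physician has to act
once that level is observed.  Dividing a physician-set patient constant
``K_P`` (minutes) by ``delta`` turns urgency into a weight::

    theta[sensor][level] = K_P / delta[sensor][level]

The Alert Measure Index (AMI) of a patient window is the weighted severity
of their consensus abnormality motif::

    AMI = sum_n theta[S_n][CAM_n] * num(CAM_n)

where ``num`` counts the +/- marks of a level (``A`` -> 0, ``A+``/``A-``
-> 1, ``A++``/``A--`` -> 2, ...).  Levels without a configured delta have
weight zero: no intervention time means no urgency.  Sorting patients by
descending AMI yields the prioritization table physicians triage from.

The weight rule is pluggable (``weight_fn`` of ``weight_matrix``) so more
elaborate urgency models can replace the reciprocal without touching the
scoring; the reciprocal is the default and only built-in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

from .errors import ConfigurationError, InvalidParameterError
from .motifs import ConsensusMotif
from .quantize import SensorSpec, SeveritySymbol

__all__ = [
    "WeightMatrix",
    "AlertRecord",
    "weight_matrix",
    "num_severity",
    "compute_ami",
    "prioritize",
]


@dataclass(frozen=True)
class WeightMatrix:
    """Weights theta indexed by (sensor_id, severity label), plus K_P."""

    k_p: float
    weights: Mapping[str, Mapping[str, float]]

    def theta(self, sensor_id: str, symbol: SeveritySymbol) -> float:
        if sensor_id not in self.weights:
            raise ConfigurationError(f"sensor {sensor_id!r} not in weight matrix")
        return self.weights[sensor_id].get(symbol.label, 0.0)


@dataclass(frozen=True)
class AlertRecord:
    """One scored patient window: who, when, how urgent, and the motif."""

    patient_id: str
    window_end: float
    ami: float
    cam: Optional[ConsensusMotif] = None

    def __post_init__(self) -> None:
        if self.ami < 0:
            raise InvalidParameterError("AMI must be non-negative")


def weight_matrix(
    specs: Mapping[str, SensorSpec],
    k_p: float,
    weight_fn: Callable[[float, float], float] | None = None,
) -> WeightMatrix:
    """Derive the severity weight matrix from intervention-time tables.

    ``weight_fn(k_p, delta)`` defaults to the reciprocal rule
    ``k_p / delta``.  Levels absent from a sensor's intervention-time table
    get weight zero.
    """
    if k_p <= 0:
        raise InvalidParameterError("K_P must be positive")
    fn = weight_fn if weight_fn is not None else (lambda kp, delta: kp / delta)
    table: dict[str, dict[str, float]] = {}
    for sid, spec in specs.items():
        row: dict[str, float] = {}
        for label, delta in spec.intervention_times.items():
            if delta <= 0:
                raise InvalidParameterError(
                    f"intervention time for ({sid}, {label}) must be positive"
                )
            row[label] = fn(k_p, delta)
        table[sid] = row
    return WeightMatrix(k_p=k_p, weights=table)


def num_severity(symbol: SeveritySymbol) -> int:
    """Count of +/- marks: ``A`` -> 0, ``A+``/``A-`` -> 1, ``A--`` -> 2, ..."""
    return abs(symbol.ordinal)


def compute_ami(cam: ConsensusMotif, weights: WeightMatrix) -> float:
    """Alert Measure Index of one consensus abnormality motif.

    Sum over sensors of ``theta * num``; none-markers and normal entries
    contribute zero.  Raises :class:`ConfigurationError` when the motif
    references a sensor the weight matrix does not know.
    """
    total = 0.0
    for sid, sym in zip(cam.sensor_ids, cam.entries):
        if sym is None:
            continue
        total += weights.theta(sid, sym) * num_severity(sym)
    return total


def prioritize(records: Sequence[AlertRecord]) -> list[AlertRecord]:
    """Priority table: descending AMI; ties go to the earlier window, then
    lexicographic patient id (stable and documented, so repeated runs agree)."""
    return sorted(records, key=lambda r: (-r.ami, r.window_end, r.patient_id))
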