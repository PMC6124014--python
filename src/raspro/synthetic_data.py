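"""Seeded synthetic MAP cohorts with the structure the evaluation assumes.

The generator emulates an ICU-style monitoring cohort: 35 event patients
(group H) whose mean arterial pressure sustains a dip below 60 mmHg for
more than 30 minutes, marked by a time ``t0`` up to one hour before onset,
and 35 controls (group G) who never do.  Each series is one sample per
minute.

The signal model is an AR(1) Gaussian baseline — the simplest process with
the short-range autocorrelation of slowly varying vitals — plus, for H
patients, two deterministic structures:

* a terminal hypotensive episode: a linear ramp down to a plateau below
  60 mmHg held for ``dip_duration`` minutes;
* a borderline phase: for up to half an hour before onset (but never
  before t0) the pressure hovers just under the 60 mmHg threshold without
  yet sustaining — sustained episodes rarely begin from a healthy baseline
  in one step, and this phase is what makes the post-marker hour
  recognisably abnormal from its first minutes;
* a hypotensive *prodrome*: a few short (sub-threshold-duration) dips
  below 60 mmHg in the window before t0, plus a lower running baseline.
  Patients heading into hypotension do not look like healthy controls
  right up to the event; transient pressure drops in the preceding hours
  are what give pre-onset windows any predictive signal at all.

Labels are guaranteed, not merely likely: every generated series is
checked with the episode detector and resampled (fresh substream) if noise
accidentally created — or destroyed — an event.  Each patient draws from
an independent substream of the master seed, so cohorts are reproducible
and insensitive to generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .errors import InvalidParameterError
from .evaluate import (
    AHE_THRESHOLD_MMHG,
    LabeledEpisode,
    detect_ahe,
)
from .quantize import MISSING, SeverityScheme, SeveritySymbol

__all__ = [
    "CohortConfig",
    "generate_map_series",
    "generate_cohort",
    "generate_multisensor_patient",
]


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation parameters (all times in minutes, MAP in mmHg).

    Defaults mirror the evaluation cohort: 35 event patients and 35
    controls, series long enough to hold a 180-minute pre-marker window,
    the marker itself, and a sustained dip.
    """

    n_h: int = 35
    n_g: int = 35
    duration: int = 300
    baseline_mean: float = 85.0
    h_baseline_mean: float = 75.0
    baseline_sd: float = 4.0
    ar1_rho: float = 0.9
    dip_depth: float = 8.0
    dip_duration: int = 45
    onset_ramp: int = 10
    prodrome_dips: int = 3
    prodrome_depth: float = 5.0
    prodrome_duration: int = 10
    borderline_duration: int = 30
    borderline_offset: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_h < 1 or self.n_g < 1:
            raise InvalidParameterError("both groups need at least one patient")
        if self.duration < 180:
            raise InvalidParameterError("series must span at least 180 minutes")
        if self.dip_duration <= 30:
            raise InvalidParameterError(
                "dip_duration must exceed 30 minutes to qualify as an episode"
            )
        if self.dip_depth <= 0 or self.prodrome_depth <= 0:
            raise InvalidParameterError("dip depths must be positive")
        if not (0.0 <= self.ar1_rho < 1.0):
            raise InvalidParameterError("ar1_rho must be in [0, 1)")
        if self.baseline_sd < 0:
            raise InvalidParameterError("baseline_sd must be non-negative")
        if not (0 < self.prodrome_duration <= 30):
            raise InvalidParameterError(
                "prodrome dips must be at most 30 minutes (never an episode)"
            )
        if self.onset_ramp < 1:
            raise InvalidParameterError("onset_ramp must be at least 1 minute")
        if self.borderline_duration < 0 or self.borderline_offset < 0:
            raise InvalidParameterError(
                "borderline phase parameters must be non-negative"
            )


def _ar1(
    n: int, mean: float, sd: float, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) path: marginal N(mean, sd^2), lag-1 correlation rho."""
    innov_sd = sd * math.sqrt(1.0 - rho * rho)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i]
    return mean + x


def _overlay_dip(
    series: np.ndarray,
    start: int,
    length: int,
    floor: float,
    ramp: int,
    rng: np.random.Generator,
) -> None:
    """In-place dip: ramp down over ``ramp`` minutes, plateau, ramp back.

    The plateau keeps a quarter of the ambient noise but is clipped one
    mmHg under the episode threshold so its sub-60 run is never broken.
    """
    n = len(series)
    lo = max(start - ramp, 0)
    hi = min(start + length, n)
    for i in range(lo, start):  # descent
        frac = (i - lo + 1) / (start - lo + 1)
        series[i] = series[i] * (1 - frac) + floor * frac
    plateau = floor + 0.25 * rng.normal(0.0, 1.0, size=max(hi - start, 0)) * max(
        floor * 0.02, 0.5
    )
    series[start:hi] = np.minimum(plateau, AHE_THRESHOLD_MMHG - 1.0)
    for j, i in enumerate(range(hi, min(hi + ramp, n))):  # recovery
        frac = (j + 1) / (ramp + 1)
        series[i] = floor * (1 - frac) + series[i] * frac


def _valid_h(series: np.ndarray, t0: int) -> bool:
    events = detect_ahe(series)
    if not events:
        return False
    first_onset = events[0][0]
    return t0 <= first_onset <= t0 + 60


def generate_map_series(
    config: CohortConfig,
    group: Literal["H", "G"],
    rng_stream: Sequence[int],
    patient_id: str,
    max_tries: int = 50,
) -> LabeledEpisode:
    """One labelled MAP episode, fully determined by ``rng_stream``.

    ``rng_stream`` is the substream key (e.g. ``(seed, patient_index)``).
    Generated H series are validated with the episode detector — exactly
    the first detected event must begin in ``[t0, t0 + 60]`` — and G series
    must contain no event at all; offending draws are rejected and redrawn
    from a derived substream.
    """
    if group not in ("H", "G"):
        raise InvalidParameterError("group must be 'H' or 'G'")
    d = config.duration
    for attempt in range(max_tries):
        rng = np.random.default_rng([*rng_stream, attempt])
        if group == "G":
            series = _ar1(d, config.baseline_mean, config.baseline_sd, config.ar1_rho, rng)
            if not detect_ahe(series):
                return LabeledEpisode(patient_id, series, "G", None)
            continue
        series = _ar1(d, config.h_baseline_mean, config.baseline_sd, config.ar1_rho, rng)
        # place the marker, then the onset at most one hour after it
        gap = float(rng.uniform(config.onset_ramp, 60.0))
        # the post-marker hour and the dip must both fit inside the series
        t0_max = min(d - config.dip_duration - int(math.ceil(gap)), d - 60)
        t0_min = min(180, t0_max)
        if t0_max < t0_min:
            raise InvalidParameterError(
                "duration too short for the dip and marker placement"
            )
        t0 = int(rng.integers(t0_min, t0_max + 1))
        onset = t0 + int(math.ceil(gap))
        # prodrome: short sub-60 dips strictly before t0, one guaranteed
        # inside the last half hour so even the shortest pre-marker window
        # carries signal
        prodrome_floor = AHE_THRESHOLD_MMHG - config.prodrome_depth
        placed: list[tuple[int, int]] = []
        if config.prodrome_dips >= 1:
            s = int(rng.integers(t0 - 25, t0 - config.prodrome_duration - 2))
            placed.append((s, config.prodrome_duration))
        hi_free = t0 - config.prodrome_duration - 35
        for _ in range(max(config.prodrome_dips - 1, 0)):
            if hi_free <= 30:
                break
            for _try in range(20):
                s = int(rng.integers(30, hi_free))
                if all(
                    s + config.prodrome_duration + 20 < e or e + el + 20 < s
                    for e, el in placed
                ):
                    placed.append((s, config.prodrome_duration))
                    break
        for s, length in placed:
            _overlay_dip(series, s, length, prodrome_floor, max(config.onset_ramp // 2, 2), rng)
        # borderline phase: in the run-up to onset (never before t0) the
        # pressure hovers just under the episode threshold without yet
        # sustaining, so the post-marker hour is abnormal from its start
        if config.borderline_duration > 0:
            b_lo = max(t0, onset - config.borderline_duration)
            b_mean = AHE_THRESHOLD_MMHG - config.borderline_offset
            n_b = onset - b_lo
            if n_b > 0:
                series[b_lo:onset] = b_mean + 0.6 * config.baseline_sd * rng.normal(
                    0.0, 1.0, size=n_b
                )
        # terminal episode
        _overlay_dip(
            series,
            onset,
            config.dip_duration,
            AHE_THRESHOLD_MMHG - config.dip_depth,
            config.onset_ramp,
            rng,
        )
        if _valid_h(series, t0):
            return LabeledEpisode(patient_id, series, "H", float(t0))
    raise InvalidParameterError(
        f"could not generate a valid {group} series in {max_tries} attempts"
    )


def generate_cohort(config: CohortConfig) -> list[LabeledEpisode]:
    """The full labelled cohort: ``n_h`` event patients then ``n_g`` controls.

    Each patient uses an independent substream of ``config.seed``, so the
    cohort is reproducible and any one patient can be regenerated alone.
    """
    episodes: list[LabeledEpisode] = []
    for i in range(config.n_h):
        episodes.append(
            generate_map_series(config, "H", (config.seed, 0, i), f"H{i + 1:03d}")
        )
    for i in range(config.n_g):
        episodes.append(
            generate_map_series(config, "G", (config.seed, 1, i), f"G{i + 1:03d}")
        )
    return episodes


def generate_multisensor_patient(
    severity_script: Mapping[str, Sequence[SeveritySymbol | None]],
    schemes: Mapping[str, SeverityScheme],
    seed: int = 0,
    margin: float = 0.05,
) -> dict[str, np.ndarray]:
    """Raw multi-sensor series that quantize back to a prescribed script.

    ``severity_script`` gives, per sensor, the wanted symbol at each sample
    (``None`` for a missing sample -> NaN).  Values are drawn uniformly
    from the *interior* of each symbol's interval (keeping ``margin`` of
    the width away from the boundaries), so re-quantizing under the same
    schemes recovers the script exactly.  Used to build fixtures for the
    matrix/motif/alert layers.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for sid, script in severity_script.items():
        if sid not in schemes:
            raise InvalidParameterError(f"no scheme for sensor {sid!r}")
        scheme = schemes[sid]
        allowed = {s.ordinal for s in scheme.symbols}
        widths = [
            b2 - b1 for b1, b2 in zip(scheme.breakpoints, scheme.breakpoints[1:])
        ]
        typical = widths[0] if widths else 10.0
        values = np.empty(len(script))
        for i, sym in enumerate(script):
            if sym is MISSING:
                values[i] = np.nan
                continue
            if sym.ordinal not in allowed:
                raise InvalidParameterError(
                    f"symbol {sym.label} outside the levels of sensor {sid!r}"
                )
            j = [s.ordinal for s in scheme.symbols].index(sym.ordinal)
            lo = scheme.breakpoints[j - 1] if j > 0 else None
            hi = scheme.breakpoints[j] if j < len(scheme.breakpoints) else None
            if lo is None and hi is None:
                values[i] = rng.uniform(-typical, typical)
            elif lo is None:
                values[i] = hi - typical * (margin + (1 - 2 * margin) * rng.random())
            elif hi is None:
                values[i] = lo + typical * (margin + (1 - 2 * margin) * rng.random())
            else:
                width = hi - lo
                values[i] = lo + width * (margin + (1 - 2 * margin) * rng.random())
        out[sid] = values
    return out
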