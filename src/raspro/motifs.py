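"""Consensus-motif extraction (precision stage).

A W-sample window of severity symbols from one sensor is summarized by the
candidate that minimizes the sum of hamming distances to all candidates in
the window (sigma).  Splitting candidates by their distance to the normal
level ``A`` yields two summaries per sensor row:

* the consensus *normal* symbol — minimal-sigma candidate among those with
  ``D(alpha, A) < S_THRESH`` (near-normal),
* the consensus *abnormality* symbol — minimal-sigma candidate among those
  with ``D(alpha, A) >= S_THRESH``.

Stacked over the N rows of a patient-specific matrix these give the
consensus normal motif (CNM) and consensus abnormality motif (CAM).  A
frequency map (per-row symbol counts) is the next, more detailed tier; the
motif time series (MTS) applies the unconstrained consensus blockwise to a
whole quantized series and is the compact representation fed to
classifiers.

Tie-breaking: when several qualifying candidates share the minimal sigma,
the most severe (largest ``|ordinal|``) wins, then the earliest occurrence
in the window.  Alerts should err toward severity, never under-report.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .errors import InvalidParameterError, NoConsensusError
from .quantize import MISSING, PSM, QuantizedSeries, SensorSpec, SeveritySymbol

__all__ = [
    "NORMAL",
    "ConsensusMotif",
    "hamming_distance",
    "sigma_profile",
    "consensus_normal_symbol",
    "consensus_abnormality_symbol",
    "consensus_symbol",
    "extract_motifs",
    "motif_time_series",
    "frequency_map",
]

#: The normal level shared by every sensor.
NORMAL = SeveritySymbol(0)


def hamming_distance(a: SeveritySymbol, b: SeveritySymbol) -> int:
    """Distance between two severity levels of one sensor.

    Neighbouring levels (``A`` and ``A+``) are at distance 1, so the
    distance is simply the absolute ordinal difference.
    """
    return abs(a.ordinal - b.ordinal)


def _clean(window: Iterable[Optional[SeveritySymbol]]) -> list[SeveritySymbol]:
    return [s for s in window if s is not MISSING]


def sigma_profile(window: Sequence[Optional[SeveritySymbol]]) -> list[int]:
    """Sum of hamming distances from each candidate to all candidates.

    Missing markers are dropped before the computation.  The self-term
    contributes zero, matching the plain sum over the whole window.
    """
    cand = _clean(window)
    if not cand:
        raise NoConsensusError("empty observation window")
    return [sum(hamming_distance(a, b) for b in cand) for a in cand]


def _argmin_consensus(
    cand: Sequence[SeveritySymbol], sigmas: Sequence[int], mask: Sequence[bool]
) -> Optional[SeveritySymbol]:
    best: Optional[SeveritySymbol] = None
    best_key: tuple[int, int] | None = None
    for a, s, ok in zip(cand, sigmas, mask):
        if not ok:
            continue
        key = (s, -abs(a.ordinal))  # min sigma, then most severe; first wins ties
        if best_key is None or key < best_key:
            best, best_key = a, key
    return best


def consensus_normal_symbol(
    window: Sequence[Optional[SeveritySymbol]], s_thresh: int
) -> Optional[SeveritySymbol]:
    """Minimal-sigma candidate whose distance to ``A`` is below ``s_thresh``.

    Returns ``None`` when no candidate is near-normal; raises
    :class:`NoConsensusError` on an empty window.
    """
    if s_thresh < 0:
        raise InvalidParameterError("s_thresh must be non-negative")
    cand = _clean(window)
    if not cand:
        raise NoConsensusError("empty observation window")
    sigmas = sigma_profile(cand)
    mask = [hamming_distance(a, NORMAL) < s_thresh for a in cand]
    return _argmin_consensus(cand, sigmas, mask)


def consensus_abnormality_symbol(
    window: Sequence[Optional[SeveritySymbol]], s_thresh: int
) -> Optional[SeveritySymbol]:
    """Minimal-sigma candidate whose distance to ``A`` is >= ``s_thresh``."""
    if s_thresh < 0:
        raise InvalidParameterError("s_thresh must be non-negative")
    cand = _clean(window)
    if not cand:
        raise NoConsensusError("empty observation window")
    sigmas = sigma_profile(cand)
    mask = [hamming_distance(a, NORMAL) >= s_thresh for a in cand]
    return _argmin_consensus(cand, sigmas, mask)


def consensus_symbol(
    window: Sequence[Optional[SeveritySymbol]],
) -> SeveritySymbol:
    """Unconstrained consensus: minimal sigma over *all* candidates.

    Used for the motif time series, where every window must yield a symbol
    regardless of the near-normal threshold.
    """
    cand = _clean(window)
    if not cand:
        raise NoConsensusError("empty observation window")
    sigmas = sigma_profile(cand)
    out = _argmin_consensus(cand, sigmas, [True] * len(cand))
    assert out is not None
    return out


@dataclass(frozen=True)
class ConsensusMotif:
    """Per-sensor consensus symbols for one patient window.

    ``kind`` is ``"CNM"`` (consensus normal motif) or ``"CAM"`` (consensus
    abnormality motif); ``entries`` follow PSM row order and may hold the
    none-marker where a row had no qualifying candidate (or no data).
    """

    patient_id: str
    kind: str
    sensor_ids: tuple[str, ...]
    entries: tuple[Optional[SeveritySymbol], ...]

    def __post_init__(self) -> None:
        if self.kind not in ("CNM", "CAM"):
            raise InvalidParameterError("motif kind must be 'CNM' or 'CAM'")
        if len(self.sensor_ids) != len(self.entries):
            raise InvalidParameterError("one entry per sensor required")

    def entry(self, sensor_id: str) -> Optional[SeveritySymbol]:
        try:
            return self.entries[self.sensor_ids.index(sensor_id)]
        except ValueError:
            raise InvalidParameterError(f"unknown sensor {sensor_id!r}") from None


def extract_motifs(
    psm: PSM,
    specs: Mapping[str, SensorSpec],
    max_missing_frac: float = 0.5,
) -> tuple[ConsensusMotif, ConsensusMotif]:
    """Row-wise CNM and CAM of a patient-specific matrix.

    Each row is treated as an observation window; the per-sensor near-normal
    threshold comes from ``specs``.  Rows that are empty or more than
    ``max_missing_frac`` missing yield none-markers.  When a row has no
    abnormal candidate at all, the CAM entry falls back to the row's
    consensus normal symbol — the abnormality motif then simply reports a
    normal level, which contributes nothing to downstream alert scores.
    """
    cnm_entries: list[Optional[SeveritySymbol]] = []
    cam_entries: list[Optional[SeveritySymbol]] = []
    for sid, row in zip(psm.sensor_ids, psm.cells):
        try:
            thresh = specs[sid].near_normal_threshold
        except KeyError:
            raise InvalidParameterError(f"no spec for sensor {sid!r}") from None
        present = _clean(row)
        if not present or (row and len(present) / len(row) < 1 - max_missing_frac):
            cnm_entries.append(None)
            cam_entries.append(None)
            continue
        cns = consensus_normal_symbol(present, thresh)
        cas = consensus_abnormality_symbol(present, thresh)
        cnm_entries.append(cns)
        cam_entries.append(cas if cas is not None else cns)
    return (
        ConsensusMotif(psm.patient_id, "CNM", psm.sensor_ids, tuple(cnm_entries)),
        ConsensusMotif(psm.patient_id, "CAM", psm.sensor_ids, tuple(cam_entries)),
    )


def motif_time_series(
    qts: QuantizedSeries,
    window: int,
) -> QuantizedSeries:
    """Summarize a quantized series into one consensus symbol per W-block.

    Consecutive non-overlapping blocks of ``window`` samples are each
    replaced by their unconstrained consensus symbol; a trailing partial
    block is summarized as-is.  Blocks that are entirely missing yield the
    missing marker.
    """
    if window <= 0:
        raise InvalidParameterError("summarization window W must be positive")
    out: list[Optional[SeveritySymbol]] = []
    for i in range(0, len(qts.symbols), window):
        block = qts.symbols[i : i + window]
        if not _clean(block):
            out.append(MISSING)
        else:
            out.append(consensus_symbol(block))
    return QuantizedSeries(
        sensor_id=qts.sensor_id,
        start_time=qts.start_time,
        step=qts.step * window,
        symbols=tuple(out),
    )


def frequency_map(psm: PSM) -> dict[str, dict[str, int]]:
    """Severity frequency map: per-sensor counts of each symbol in the window.

    Missing cells are excluded, so each row's counts sum to the number of
    observed samples.  Keys are severity labels for easy serialization.
    """
    out: dict[str, dict[str, int]] = {}
    for sid, row in zip(psm.sensor_ids, psm.cells):
        counts = Counter(s.label for s in row if s is not MISSING)
        out[sid] = dict(sorted(counts.items(), key=lambda kv: SeveritySymbol.from_label(kv[0]).ordinal))
    return out
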