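"""AHE classification / prediction protocol over severity representations.

An acute hypotensive episode (AHE) is a run of mean arterial pressure (MAP)
samples strictly below 60 mmHg lasting more than 30 minutes.  Patients who
experienced one (group H) carry a marker ``t0`` after which the episode
began within one hour; controls (group G) never dip that long.

Three feature representations of a MAP window are compared:

* OTS — the original time series (raw mmHg values),
* QTS — the quantized time series (signed severity ordinals, breadth B),
* MTS — the motif time series (one consensus ordinal per W-sample block).

Three experiment modes mirror the clinical questions:

* ``precision``  — classify the 60 minutes *after* t0 as AHE or not
  (can symbols replace raw data for diagnosis?),
* ``expanding``  — predict the upcoming AHE from the T minutes *before*
  t0, T in {30..180} (can symbols predict?),
* ``moving``     — same, from an isolated 30-minute slice ending T
  minutes back from t0.

Each grid cell trains a support-vector classifier (RBF kernel, small
regularization grid chosen by stratified 5-fold cross-validation on a 70%
split) and reports the F1 score on the held-out 30%.  Controls have no t0,
so each G patient gets one anchor drawn from the seeded stream and reused
across the whole grid.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import InvalidInputError, InvalidParameterError
from .motifs import motif_time_series
from .quantize import SensorSpec, SeverityScheme, build_uniform_scheme, quantize_series

__all__ = [
    "AHE_THRESHOLD_MMHG",
    "AHE_MIN_DURATION_MIN",
    "LabeledEpisode",
    "ExperimentConfig",
    "detect_ahe",
    "map_scheme",
    "make_feature_vector",
    "f1_score",
    "rmse",
    "run_experiment",
    "best_per_representation",
]

#: MAP threshold (mmHg) and minimum sustained duration (min) defining an AHE.
AHE_THRESHOLD_MMHG = 60.0
AHE_MIN_DURATION_MIN = 30.0


@dataclass(frozen=True)
class LabeledEpisode:
    """One patient's MAP record: values at 1/min, group label, t0 marker.

    ``t0`` is required for group H (the episode starts within 60 minutes
    after it) and absent for controls.
    """

    patient_id: str
    map_series: np.ndarray
    group: Literal["H", "G"]
    t0: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "map_series", np.asarray(self.map_series, dtype=float)
        )
        if self.group not in ("H", "G"):
            raise InvalidParameterError("group must be 'H' or 'G'")
        if self.group == "H" and self.t0 is None:
            raise InvalidParameterError("group H episodes need a t0 marker")

    @property
    def duration(self) -> int:
        return len(self.map_series)


@dataclass(frozen=True)
class ExperimentConfig:
    """Grid and protocol settings for one evaluation run.

    Defaults reproduce the published protocol: quantization breadths
    B in {5,10,15,20} mmHg, summarization windows W in {5,10,15} samples,
    backward offsets T in {30..180} minutes, a stratified 70/30 split and
    5-fold cross-validated model selection.
    """

    mode: Literal["precision", "expanding", "moving"]
    b_grid: tuple[int, ...] = (5, 10, 15, 20)
    w_grid: tuple[int, ...] = (5, 10, 15)
    t_grid: tuple[int, ...] = (30, 60, 90, 120, 150, 180)
    train_frac: float = 0.70
    cv_folds: int = 5
    seed: int = 0
    svm_c_grid: tuple[float, ...] = (0.1, 1.0, 10.0)
    svm_gamma_grid: tuple[float | str, ...] = ("scale",)

    def __post_init__(self) -> None:
        if self.mode not in ("precision", "expanding", "moving"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        if not (0.0 < self.train_frac < 1.0):
            raise InvalidParameterError("train fraction must be in (0, 1)")
        if not (self.b_grid and self.w_grid and self.t_grid):
            raise InvalidParameterError("grids must be non-empty")
        if self.cv_folds < 2:
            raise InvalidParameterError("cv_folds must be at least 2")


def detect_ahe(
    map_series: Sequence[float] | np.ndarray,
    threshold: float = AHE_THRESHOLD_MMHG,
    min_duration: float = AHE_MIN_DURATION_MIN,
    step: float = 1.0,
) -> list[tuple[int, int]]:
    """Find acute hypotensive episodes in a regularly sampled MAP series.

    Returns ``(onset, end)`` index pairs (half-open, in samples) of maximal
    runs strictly below ``threshold`` whose duration strictly exceeds
    ``min_duration`` minutes.  A run of exactly 30 one-minute samples is
    *not* an event: the definition is "more than 30 min".
    """
    arr = np.asarray(map_series, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("empty MAP series")
    below = arr < threshold
    # maximal runs via edge detection
    padded = np.diff(np.concatenate(([0], below.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return [
        (int(s), int(e))
        for s, e in zip(starts, ends)
        if (e - s) * step > min_duration
    ]


def map_scheme(breadth: float, normal_low: float = AHE_THRESHOLD_MMHG) -> SeverityScheme:
    """Severity scheme for a MAP sensor graded downward from 60 mmHg.

    Sub-normal levels of width ``breadth`` cover the full clinical range
    down to 0 mmHg (so ceil(60/B) levels); there are no supra-normal
    levels, since the event of interest is defined only by low MAP.
    """
    n_sub = int(math.ceil(normal_low / breadth))
    spec = SensorSpec(
        sensor_id="MAP",
        name="Mean arterial pressure",
        units="mmHg",
        sampling_freq=1.0,
        n_sub_levels=n_sub,
        n_supra_levels=0,
        near_normal_threshold=min(1, n_sub),
    )
    return build_uniform_scheme(spec, (normal_low, math.inf), breadth)


def _window_bounds(
    episode: LabeledEpisode,
    mode: str,
    t_offset: int,
    anchor: Optional[float],
) -> tuple[int, int]:
    """Start/end sample indices of the requested window.

    Prevention windows end at or before t0 — they never see post-marker
    samples (that would leak the event into the predictor).
    """
    ref = episode.t0 if episode.t0 is not None else anchor
    if ref is None:
        raise InvalidInputError(
            f"episode {episode.patient_id}: control needs an anchor"
        )
    ref = int(round(ref))
    if mode == "precision":
        lo, hi = ref, ref + 60
    elif mode == "expanding":
        lo, hi = ref - t_offset, ref
    elif mode == "moving":
        lo, hi = ref - t_offset, ref - t_offset + 30
    else:  # pragma: no cover
        raise InvalidParameterError(f"unknown mode {mode!r}")
    if lo < 0 or hi > episode.duration:
        raise InvalidInputError(
            f"episode {episode.patient_id}: window [{lo}, {hi}) outside series "
            f"of length {episode.duration}"
        )
    return lo, hi


def make_feature_vector(
    episode: LabeledEpisode,
    representation: Literal["OTS", "QTS", "MTS"],
    mode: Literal["precision", "expanding", "moving"] = "precision",
    t_offset: int = 60,
    breadth: float = 10.0,
    window: int = 5,
    anchor: Optional[float] = None,
) -> np.ndarray:
    """Numeric feature vector for one episode and one grid cell.

    OTS returns the raw mmHg values of the window; QTS their signed
    severity ordinals under a breadth-``breadth`` scheme; MTS the ordinals
    of the blockwise consensus symbols (one per ``window`` samples).
    ``anchor`` substitutes for t0 on control episodes.
    """
    lo, hi = _window_bounds(episode, mode, t_offset, anchor)
    raw = episode.map_series[lo:hi]
    if representation == "OTS":
        return raw.astype(float)
    scheme = map_scheme(breadth)
    qts = quantize_series(raw, scheme, start_time=float(lo))
    if representation == "QTS":
        return qts.ordinals()
    if representation == "MTS":
        return motif_time_series(qts, window).ordinals()
    raise InvalidParameterError(f"unknown representation {representation!r}")


def f1_score(tp: int, fp: int, fn: int) -> float:
    """F1 = harmonic mean of precision and recall, from confusion counts.

    Returns 0 when there are no true positives (the precision/recall
    harmonic mean is taken as zero in the degenerate case).
    """
    if min(tp, fp, fn) < 0:
        raise InvalidParameterError("confusion counts must be non-negative")
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2.0 * precision * recall / (precision + recall)


def rmse(series_a: Sequence[float], series_b: Sequence[float]) -> float:
    """Root mean square error between two equal-length sequences."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise InvalidInputError("series must have equal, non-zero length")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _fit_and_score(
    x: np.ndarray, y: np.ndarray, config: ExperimentConfig
) -> float:
    """70/30 split, CV-selected RBF SVM, F1 on the held-out test set."""
    x_tr, x_te, y_tr, y_te = train_test_split(
        x,
        y,
        train_size=config.train_frac,
        stratify=y,
        random_state=config.seed,
    )
    cv = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=config.seed
    )
    model = GridSearchCV(
        Pipeline(
            [("scale", StandardScaler()), ("svc", SVC(kernel="rbf"))]
        ),
        param_grid={
            "svc__C": list(config.svm_c_grid),
            "svc__gamma": list(config.svm_gamma_grid),
        },
        scoring="f1",
        cv=cv,
    )
    model.fit(x_tr, y_tr)
    pred = model.predict(x_te)
    tp = int(np.sum((pred == 1) & (y_te == 1)))
    fp = int(np.sum((pred == 1) & (y_te == 0)))
    fn = int(np.sum((pred == 0) & (y_te == 1)))
    return f1_score(tp, fp, fn)


def _draw_anchors(
    cohort: Sequence[LabeledEpisode], config: ExperimentConfig
) -> dict[str, int]:
    """One seeded anchor per control, reused across the whole grid.

    Precision mode needs 60 minutes after the anchor; prevention modes need
    max(T) minutes before it.  Anchors are drawn uniformly from the feasible
    range of each series.
    """
    rng = np.random.default_rng(config.seed)
    anchors: dict[str, int] = {}
    if config.mode == "precision":
        lo_need, hi_need = 60, 60  # symmetric slack keeps anchors interior
    else:
        lo_need, hi_need = max(config.t_grid), 0
    for ep in cohort:
        if ep.group != "G":
            continue
        low = lo_need if config.mode != "precision" else 60
        high = ep.duration - (60 if config.mode == "precision" else hi_need)
        if high < low:
            raise InvalidInputError(
                f"episode {ep.patient_id}: too short for the requested windows"
            )
        anchors[ep.patient_id] = int(rng.integers(low, high + 1))
    return anchors


def run_experiment(
    cohort: Sequence[LabeledEpisode], config: ExperimentConfig
) -> pd.DataFrame:
    """Run the full representation-by-grid comparison on one cohort.

    Returns a tidy table with columns ``mode, representation, B, W, T, f1``
    (unused grid axes are NaN).  Precision mode produces 1 OTS row, one QTS
    row per breadth and one MTS row per (B, W); prevention modes repeat
    that for every backward offset T.  The run is fully determined by
    ``config.seed``.
    """
    groups = {ep.group for ep in cohort}
    if groups != {"H", "G"}:
        raise InvalidInputError("cohort must contain both H and G episodes")
    anchors = _draw_anchors(cohort, config)
    t_values: Sequence[Optional[int]]
    if config.mode == "precision":
        t_values = [None]
    else:
        t_values = list(config.t_grid)

    def matrix(representation: str, b: float, w: int, t: Optional[int]):
        xs, ys = [], []
        for ep in cohort:
            vec = make_feature_vector(
                ep,
                representation,  # type: ignore[arg-type]
                mode=config.mode,
                t_offset=t if t is not None else 60,
                breadth=b,
                window=w,
                anchor=anchors.get(ep.patient_id),
            )
            xs.append(vec)
            ys.append(1 if ep.group == "H" else 0)
        return np.vstack(xs), np.asarray(ys)

    rows = []
    for t in t_values:
        cells: list[tuple[str, float, float]] = [("OTS", math.nan, math.nan)]
        cells += [("QTS", float(b), math.nan) for b in config.b_grid]
        cells += [
            ("MTS", float(b), float(w))
            for b, w in itertools.product(config.b_grid, config.w_grid)
        ]
        for rep, b, w in cells:
            x, y = matrix(
                rep,
                b if not math.isnan(b) else 10.0,
                int(w) if not math.isnan(w) else 5,
                t,
            )
            score = _fit_and_score(x, y, config)
            rows.append(
                {
                    "mode": config.mode,
                    "representation": rep,
                    "B": b,
                    "W": w,
                    "T": float(t) if t is not None else math.nan,
                    "f1": score,
                }
            )
    return pd.DataFrame(rows, columns=["mode", "representation", "B", "W", "T", "f1"])


def best_per_representation(table: pd.DataFrame) -> pd.DataFrame:
    """Best-scoring (B, W) per representation — per T in prevention modes.

    The analogue of the published QTSmax/MTSmax curves: for each backward
    offset, keep the grid cell with the highest F1 for each representation.
    """
    keys = ["representation"] + (["T"] if table["T"].notna().any() else [])
    idx = table.groupby(keys, dropna=False)["f1"].idxmax()
    return table.loc[idx].sort_values(keys).reset_index(drop=True)
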