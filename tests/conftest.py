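"""Shared fixtures and independent reference implementations.

The oracles here are deliberately naive (exhaustive filters, run-length
scans, hand arithmetic) and independent of the library code paths they
check.
"""

from __future__ import annotations

import numpy as np
import pytest

from raspro import CohortConfig, SensorSpec, SeveritySymbol, generate_cohort


def sym(label: str) -> SeveritySymbol:
    return SeveritySymbol.from_label(label)


def syms(*labels: str) -> list[SeveritySymbol]:
    return [sym(l) for l in labels]


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_sigma(window: list[SeveritySymbol]) -> list[int]:
    return [
        sum(abs(a.ordinal - b.ordinal) for b in window) for a in window
    ]


def oracle_consensus(
    window: list[SeveritySymbol], s_thresh: int, kind: str
) -> SeveritySymbol | None:
    """Exhaustive filter-then-argmin with the documented tie-break.

    ``kind`` is 'normal' (distance to A below threshold), 'abnormal'
    (at or above threshold) or 'any' (no filter).
    """
    sigmas = oracle_sigma(window)
    qualifiers = []
    for i, (a, s) in enumerate(zip(window, sigmas)):
        d = abs(a.ordinal)
        if kind == "normal" and not d < s_thresh:
            continue
        if kind == "abnormal" and not d >= s_thresh:
            continue
        qualifiers.append((s, -abs(a.ordinal), i, a))
    if not qualifiers:
        return None
    return min(qualifiers)[3]


def oracle_runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Brute-force scan for maximal true-runs strictly longer than min_len."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i > min_len:
                out.append((i, j))
            i = j
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_cohort():
    """The full evaluation cohort (35 event patients + 35 controls)."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for protocol tests that do not need power."""
    return generate_cohort(CohortConfig(n_h=8, n_g=8, seed=3))


@pytest.fixture()
def bp_hr_specs():
    """Two-sensor configuration used throughout the motif/alert tests."""
    return {
        "BP": SensorSpec(
            sensor_id="BP",
            name="Blood pressure",
            units="mmHg",
            n_sub_levels=2,
            n_supra_levels=2,
            near_normal_threshold=1,
            intervention_times={"A--": 30.0, "A-": 60.0, "A+": 60.0, "A++": 30.0},
        ),
        "HR": SensorSpec(
            sensor_id="HR",
            name="Heart rate",
            units="bpm",
            n_sub_levels=2,
            n_supra_levels=2,
            near_normal_threshold=1,
            intervention_times={"A++": 20.0, "A--": 20.0},
        ),
    }
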