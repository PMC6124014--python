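"""Consensus symbols, motifs, frequency maps, and the sigma machinery."""

import numpy as np
import pytest

from raspro import (
    MISSING,
    ConsensusMotif,
    InvalidParameterError,
    NoConsensusError,
    PSM,
    SeveritySymbol,
    consensus_abnormality_symbol,
    consensus_normal_symbol,
    consensus_symbol,
    extract_motifs,
    frequency_map,
    hamming_distance,
    motif_time_series,
    quantize_series,
    sigma_profile,
)
from raspro.evaluate import map_scheme

from conftest import oracle_consensus, oracle_sigma, sym, syms


def random_window(rng, max_w=15, lo=-3, hi=3):
    w = int(rng.integers(1, max_w + 1))
    return [SeveritySymbol(int(o)) for o in rng.integers(lo, hi + 1, size=w)]


class TestHammingDistance:
    @pytest.mark.parametrize(
        "a,b,d",
        [("A", "A+", 1), ("A", "A", 0), ("A--", "A+", 3), ("A-", "A--", 1)],
    )
    def test_is_ordinal_difference(self, a, b, d):
        assert hamming_distance(sym(a), sym(b)) == d
        assert hamming_distance(sym(b), sym(a)) == d


class TestSigmaProfile:
    def test_pairwise_sums(self):
        assert sigma_profile(syms("A", "A", "A+")) == [1, 1, 2]
        assert sigma_profile(syms("A")) == [0]
        assert sigma_profile(syms("A+", "A+", "A+")) == [0, 0, 0]

    def test_empty_window_rejected(self):
        with pytest.raises(NoConsensusError):
            sigma_profile([])
        with pytest.raises(NoConsensusError):
            sigma_profile([MISSING, MISSING])

    def test_sigma_conservation(self):
        """Sum of all sigmas equals twice the sum over distinct pairs."""
        rng = np.random.default_rng(7)
        for _ in range(200):
            window = random_window(rng)
            sigmas = sigma_profile(window)
            pair_sum = sum(
                abs(a.ordinal - b.ordinal)
                for i, a in enumerate(window)
                for b in window[i + 1:]
            )
            assert sum(sigmas) == 2 * pair_sum


class TestConsensusSymbols:
    def test_normal_consensus_worked_examples(self):
        assert consensus_normal_symbol(syms("A", "A", "A+"), 2) == sym("A")
        # all at exactly the threshold distance: none is near-normal
        assert consensus_normal_symbol(syms("A++", "A++", "A++"), 2) is None
        assert consensus_normal_symbol(syms("A"), 1) == sym("A")

    def test_abnormality_consensus_worked_examples(self):
        assert consensus_abnormality_symbol(syms("A++", "A+", "A++"), 2) == sym("A++")
        assert consensus_abnormality_symbol(syms("A", "A", "A"), 1) is None
        assert consensus_abnormality_symbol(syms("A--", "A-", "A--"), 2) == sym("A--")

    def test_empty_window_raises(self):
        for fn in (consensus_normal_symbol, consensus_abnormality_symbol):
            with pytest.raises(NoConsensusError):
                fn([], 1)

    def test_missing_markers_are_ignored(self):
        window = [MISSING, sym("A"), MISSING, sym("A"), sym("A+")]
        assert consensus_normal_symbol(window, 2) == sym("A")

    def test_consensus_is_an_element_of_the_window(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            window = random_window(rng)
            thresh = int(rng.integers(0, 4))
            for fn in (consensus_normal_symbol, consensus_abnormality_symbol):
                out = fn(window, thresh)
                assert out is None or out in window
            assert consensus_symbol(window) in window

    def test_matches_exhaustive_oracle(self):
        """Filter-then-argmin brute force agrees on randomized windows."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            window = random_window(rng)
            thresh = int(rng.integers(0, 4))
            assert consensus_normal_symbol(window, thresh) == oracle_consensus(
                window, thresh, "normal"
            )
            assert consensus_abnormality_symbol(window, thresh) == oracle_consensus(
                window, thresh, "abnormal"
            )
            assert consensus_symbol(window) == oracle_consensus(window, 0, "any")
            assert sigma_profile(window) == oracle_sigma(window)

    def test_determinism_under_tie_break(self):
        window = syms("A-", "A+", "A-", "A+")  # symmetric sigmas
        results = {consensus_symbol(list(window)).label for _ in range(10)}
        assert len(results) == 1


class TestExtractMotifs:
    def make_psm(self, rows):
        cells = tuple(tuple(syms(*labels)) for labels in rows)
        return PSM("P1", ("BP", "HR"), cells)

    def test_two_sensor_abnormality_motif(self, bp_hr_specs):
        """A sustained BP drop with steady HR yields CAM <A--, A>."""
        psm = self.make_psm(
            [["A--"] * 4, ["A"] * 4]
        )
        cnm, cam = extract_motifs(psm, bp_hr_specs)
        assert cam.kind == "CAM"
        assert [e.label for e in cam.entries] == ["A--", "A"]
        assert cnm.entries[0] is None  # no near-normal BP candidate
        assert cnm.entries[1] == sym("A")

    def test_all_normal_psm(self, bp_hr_specs):
        psm = self.make_psm([["A"] * 4, ["A"] * 4])
        cnm, cam = extract_motifs(psm, bp_hr_specs)
        assert [e.label for e in cnm.entries] == ["A", "A"]
        # abnormality motif falls back to the normal consensus
        assert [e.label for e in cam.entries] == ["A", "A"]

    def test_mixed_rows_follow_filter_then_argmin(self, bp_hr_specs):
        psm = self.make_psm([["A", "A+", "A", "A"], ["A-", "A-", "A", "A-"]])
        _, cam = extract_motifs(psm, bp_hr_specs)
        assert [e.label for e in cam.entries] == ["A+", "A-"]

    def test_mostly_missing_row_yields_none(self, bp_hr_specs):
        cells = (
            (sym("A"), MISSING, MISSING, MISSING),
            tuple(syms("A", "A", "A", "A")),
        )
        psm = PSM("P1", ("BP", "HR"), cells)
        cnm, cam = extract_motifs(psm, bp_hr_specs)
        assert cnm.entries[0] is None and cam.entries[0] is None
        assert cnm.entries[1] == sym("A")

    def test_unknown_sensor_spec_rejected(self, bp_hr_specs):
        psm = PSM("P1", ("XX",), ((sym("A"),),))
        with pytest.raises(InvalidParameterError):
            extract_motifs(psm, bp_hr_specs)


class TestMotifTimeSeries:
    def test_block_counts(self):
        scheme = map_scheme(10)
        qts = quantize_series(np.full(60, 70.0), scheme)
        assert len(motif_time_series(qts, 5)) == 12
        assert len(motif_time_series(qts, 15)) == 4

    def test_trailing_partial_block_is_summarized(self):
        scheme = map_scheme(10)
        qts = quantize_series(np.full(17, 55.0), scheme)
        mts = motif_time_series(qts, 5)
        assert len(mts) == 4
        assert all(s.label == "A-" for s in mts.symbols)

    def test_constant_series_maps_to_constant_motifs(self):
        scheme = map_scheme(10)
        qts = quantize_series(np.full(30, 45.0), scheme)
        mts = motif_time_series(qts, 10)
        assert [s.label for s in mts.symbols] == ["A--"] * 3

    def test_step_scales_with_window(self):
        scheme = map_scheme(10)
        qts = quantize_series(np.full(30, 70.0), scheme, step=1.0)
        assert motif_time_series(qts, 10).step == 10.0

    def test_invalid_window_rejected(self):
        scheme = map_scheme(10)
        qts = quantize_series([70.0], scheme)
        with pytest.raises(InvalidParameterError):
            motif_time_series(qts, 0)


class TestFrequencyMap:
    def test_counts_per_row(self):
        cells = (
            tuple(syms("A", "A", "A+")),
            tuple(syms("A-", "A-", "A--")),
        )
        psm = PSM("P", ("S1", "S2"), cells)
        fmap = frequency_map(psm)
        assert fmap["S1"] == {"A": 2, "A+": 1}
        assert fmap["S2"] == {"A--": 1, "A-": 2}

    def test_missing_cells_excluded(self):
        cells = ((MISSING, MISSING),)
        assert frequency_map(PSM("P", ("S1",), cells))["S1"] == {}

    def test_counts_sum_to_observed_samples(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            row = [
                MISSING if rng.random() < 0.3 else SeveritySymbol(int(rng.integers(-2, 3)))
                for _ in range(12)
            ]
            psm = PSM("P", ("S1",), (tuple(row),))
            counts = frequency_map(psm)["S1"]
            assert sum(counts.values()) == sum(s is not MISSING for s in row)
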