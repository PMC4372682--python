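"""Scoring of repeat traces: indices, filtering, mode metrics, invariants."""

from __future__ import annotations

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cagscore import (
    RepeatTrace,
    call_main_allele,
    distance_between_modes,
    distance_to_longest,
    filter_peaks,
    instability_index,
)

from conftest import traces


def brute_force_index(peaks, rel_threshold=0.20):
    """Independent recomputation: explicit loop, no shared code path."""
    main, main_h = None, -1.0
    for c in sorted(peaks):
        if peaks[c] > main_h:
            main, main_h = c, peaks[c]
    kept = [(c, h) for c, h in peaks.items() if h >= rel_threshold * main_h or c == main]
    total = sum(h for _, h in kept)
    return sum(h / total * (c - main) for c, h in kept)


class TestMainAllele:
    @pytest.mark.parametrize(
        "peaks,expected",
        [
            ({139: 1000.0, 141: 400.0}, 139),
            ({139: 500.0, 141: 500.0}, 139),  # tie breaks to the smaller CAG
            ({150: 10.0}, 150),
        ],
    )
    def test_highest_peak_called(self, peaks, expected):
        assert call_main_allele(RepeatTrace(peaks=peaks)) == expected

    def test_all_zero_heights_rejected(self):
        with pytest.raises(ValueError):
            RepeatTrace(peaks={139: 0.0, 141: 0.0})


class TestFilterPeaks:
    def test_peaks_below_threshold_dropped(self):
        t = RepeatTrace(peaks={139: 1000.0, 141: 250.0, 145: 100.0})
        assert set(filter_peaks(t, 0.20).peaks) == {139, 141}

    def test_boundary_peak_retained(self):
        # "less than" the threshold is excluded, so an exactly-20% peak stays
        t = RepeatTrace(peaks={139: 1000.0, 141: 200.0})
        assert set(filter_peaks(t, 0.20).peaks) == {139, 141}

    def test_single_peak_unchanged(self):
        t = RepeatTrace(peaks={139: 10.0})
        assert filter_peaks(t).peaks == t.peaks

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2])
    def test_threshold_domain(self, bad):
        with pytest.raises(ValueError):
            filter_peaks(RepeatTrace(peaks={139: 1.0}), bad)


class TestInstabilityIndex:
    def test_single_peak_scores_zero(self):
        r = instability_index(RepeatTrace(peaks={139: 500.0}))
        assert r.instability_index == r.expansion_index == r.contraction_index == 0

    def test_expansion_ladder(self):
        trace = RepeatTrace(peaks={139: 600.0, 141: 300.0, 143: 100.0})
        # threshold retaining all peaks: weights 0.6/0.3/0.1,
        # index = 0.3*2 + 0.1*4 = 1.0
        r = instability_index(trace, rel_threshold=0.15)
        assert r.main_allele_cag == 139
        assert r.instability_index == pytest.approx(1.0, abs=1e-12)
        assert r.expansion_index == pytest.approx(1.0, abs=1e-12)
        assert r.contraction_index == 0
        # at the default 20% cutoff the 143-repeat peak (100 < 120) drops
        # and the remaining heights renormalise: (300/900)*2 = 2/3
        r20 = instability_index(trace, rel_threshold=0.20)
        assert r20.instability_index == pytest.approx(2 / 3, abs=1e-12)

    def test_contraction_side(self):
        r = instability_index(RepeatTrace(peaks={137: 200.0, 139: 800.0}))
        assert r.instability_index == pytest.approx(-0.4, abs=1e-12)
        assert r.contraction_index == pytest.approx(-0.4, abs=1e-12)
        assert r.expansion_index == 0

    @given(traces())
    def test_matches_brute_force_oracle(self, trace):
        r = instability_index(trace)
        assert r.instability_index == pytest.approx(
            brute_force_index(trace.peaks), abs=1e-12
        )

    @given(traces())
    def test_additivity_and_weight_normalisation(self, trace):
        r = instability_index(trace)
        assert r.instability_index == pytest.approx(
            r.expansion_index + r.contraction_index, abs=1e-9
        )
        assert sum(r.retained_peaks.values()) == pytest.approx(1.0, abs=1e-9)
        assert r.expansion_index >= 0 >= r.contraction_index

    @given(traces(), st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, trace, c):
        scaled = RepeatTrace(peaks={k: v * c for k, v in trace.peaks.items()})
        r0, r1 = instability_index(trace), instability_index(scaled)
        assert r1.instability_index == pytest.approx(
            r0.instability_index, rel=1e-9, abs=1e-9
        )
        assert r1.main_allele_cag == r0.main_allele_cag

    @given(traces(), st.integers(min_value=-40, max_value=40))
    def test_translation_equivariance(self, trace, k):
        shifted = RepeatTrace(peaks={c + k: v for c, v in trace.peaks.items()})
        r0, r1 = instability_index(trace), instability_index(shifted)
        assert r1.main_allele_cag == r0.main_allele_cag + k
        assert r1.instability_index == pytest.approx(
            r0.instability_index, abs=1e-9
        )

    @given(
        traces(),
        st.floats(min_value=0.05, max_value=0.95),
        st.floats(min_value=0.05, max_value=0.95),
    )
    def test_threshold_monotonicity(self, trace, t1, t2):
        lo, hi = sorted((t1, t2))
        kept_strict = set(filter_peaks(trace, hi).peaks)
        kept_loose = set(filter_peaks(trace, lo).peaks)
        assert kept_strict <= kept_loose


class TestPatternMetrics:
    def test_distance_to_longest_after_threshold(self):
        t = RepeatTrace(peaks={139: 1000.0, 141: 300.0, 147: 210.0})
        assert distance_to_longest(t, 0.20, constitutive=139) == 8

    def test_single_peak_at_constitutive(self):
        t = RepeatTrace(peaks={139: 100.0})
        assert distance_to_longest(t, 0.20, constitutive=139) == 0

    def test_floored_when_max_below_constitutive(self):
        t = RepeatTrace(peaks={135: 100.0, 136: 90.0})
        assert distance_to_longest(t, 0.20, constitutive=139) == 0

    def test_bimodal_trace_yields_mode_distance(self, liver_like_trace):
        m = distance_between_modes(liver_like_trace, 0.20)
        assert m.modes == (139, 152)
        assert m.distance_between_modes == 13

    def test_monotone_decay_is_unimodal(self):
        t = RepeatTrace(
            peaks={139 + i: 1000.0 * 0.8**i for i in range(9)},
            constitutive_cag=139,
        )
        m = distance_between_modes(t, 0.20)
        assert m.distance_between_modes is None
        assert m.modes == (139,)

    def test_close_maxima_merge_into_one_mode(self):
        t = RepeatTrace(peaks={139: 1000.0, 142: 800.0}, constitutive_cag=139)
        m = distance_between_modes(t, 0.20, min_separation=5)
        assert m.distance_between_modes is None
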