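"""Synthetic generators: determinism, parameter recovery, cohort structure."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from cagscore import (
    CohortSpec,
    TissueProfile,
    default_profile,
    distance_between_modes,
    expansion_bias,
    instability_index,
    simulate_cohort,
    simulate_trace,
    simulate_transmissions,
    true_index,
)
from cagscore.phenotypes import mouse_darpp32, trait_table, weight_traits


class TestTraceGenerator:
    def test_same_seed_reproduces_trace(self):
        p = default_profile("striatum")
        assert simulate_trace(p, 42).peaks == simulate_trace(p, 42).peaks

    def test_distinct_seeds_differ(self):
        p = default_profile("striatum")
        assert simulate_trace(p, 1).peaks != simulate_trace(p, 2).peaks

    def test_tail_trace_scores_zero_after_filtering(self):
        p = replace(default_profile("tail"), noise_cv=0.0)
        r = instability_index(simulate_trace(p, 0))
        assert r.instability_index == 0.0  # stutter sits below the 20% cutoff
        assert r.main_allele_cag == 139

    def test_liver_mode_offset_recovered(self):
        p = replace(default_profile("liver"), noise_cv=0.0)
        m = distance_between_modes(simulate_trace(p, 0))
        assert m.distance_between_modes == p.expanded_mode_offset

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            TissueProfile(kind="tail", expansion_mean=2.0)
        with pytest.raises(ValueError):
            TissueProfile(kind="liver")  # missing expanded_mode_offset
        with pytest.raises(ValueError):
            TissueProfile(kind="spleen")


class TestTrueIndex:
    def test_tail_expectation_is_zero(self):
        assert true_index(default_profile("tail")) == 0.0

    def test_two_point_mixture_hand_expectation(self):
        # all stutter suppressed, no spread: masses 0.6 / 0.4 at delta 0 / 13
        p = TissueProfile(
            kind="liver",
            expanded_mode_offset=13,
            expansion_sd=1e-6,
            expanded_fraction=0.4,
            stutter_decay=1e-9,
            noise_cv=0.0,
        )
        assert true_index(p) == pytest.approx(0.4 * 13, abs=1e-6)

    def test_subthreshold_expansion_scores_zero(self):
        # expanded mass far below 20% of the main peak is filtered out
        p = TissueProfile(
            kind="liver",
            expanded_mode_offset=13,
            expansion_sd=1e-6,
            expanded_fraction=0.05,
            stutter_decay=1e-9,
            noise_cv=0.0,
        )
        assert true_index(p) == 0.0

    def test_noiseless_simulation_matches_expectation_exactly(self):
        for kind in ("tail", "striatum", "liver"):
            p = replace(default_profile(kind), noise_cv=0.0)
            scored = [
                instability_index(simulate_trace(p, s)).instability_index
                for s in range(200)
            ]
            assert np.mean(scored) == pytest.approx(true_index(p), abs=1e-6)


class TestCohortGenerator:
    def test_full_design_grid(self):
        recs = simulate_cohort(CohortSpec(n_per_cell=2, seed=3))
        assert len(recs) == 2 * 2 * 2 * 2
        cells = {(r.htt_genotype, r.chr10_background, r.sex) for r in recs}
        assert len(cells) == 8
        assert all(len(set(r.id for r in recs)) == len(recs) for _ in [0])

    def test_deterministic_under_seed(self):
        a = simulate_cohort(CohortSpec(n_per_cell=2, seed=9))
        b = simulate_cohort(CohortSpec(n_per_cell=2, seed=9))
        assert [r.weights for r in a] == [r.weights for r in b]

    def test_mutants_get_constitutive_cag_in_transmitted_range(self):
        recs = simulate_cohort(CohortSpec(n_per_cell=4, seed=0))
        for r in recs:
            if r.htt_genotype == "Q111/+":
                assert 133 <= r.constitutive_cag <= 149
                assert r.inclusion_counts
            else:
                assert r.constitutive_cag is None
                assert not r.inclusion_counts

    def test_group_parameters_recovered_at_scale(self):
        recs = simulate_cohort(CohortSpec(n_per_cell=150, seed=11))
        wt = [
            mouse_darpp32(r)
            for r in recs
            if r.htt_genotype == "+/+" and r.chr10_background == "B6J/B6J"
        ]
        mut = [
            mouse_darpp32(r)
            for r in recs
            if r.htt_genotype == "Q111/+" and r.chr10_background == "B6J/B6J"
        ]
        reduction = 100 * (np.mean(wt) - np.mean(mut)) / np.mean(wt)
        assert reduction == pytest.approx(14.0, abs=1.5)
        wg = [
            weight_traits(r).WG
            for r in recs
            if r.chr10_background == "B6J/B6J" and r.sex == "male"
        ]
        assert np.mean(wg) == pytest.approx(0.133, abs=0.005)

    def test_trait_table_runs_on_simulated_cohort(self):
        recs = simulate_cohort(CohortSpec(n_per_cell=1, seed=0))
        df = trait_table(recs)
        assert {"IW", "WG", "inclusion_pct", "darpp32"} <= set(df.columns)
        assert len(df) == 8


class TestTransmissionGenerator:
    def test_certain_expansion(self):
        ev = simulate_transmissions(20, p_expand=1.0, seed=0)
        assert expansion_bias(ev) == 100.0

    def test_empty(self):
        assert simulate_transmissions(0, seed=0) == []

    def test_bias_recovered_at_scale(self):
        ev = simulate_transmissions(10_000, p_expand=0.74, seed=5)
        assert expansion_bias(ev) == pytest.approx(74.0, abs=2.0)

    def test_minimum_change_is_one_repeat(self):
        ev = simulate_transmissions(500, p_expand=0.5, magnitude_sd=0.1, seed=2)
        assert all(abs(e.delta) >= 1 for e in ev)
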