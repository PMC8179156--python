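"""Isotopologue-pair screen: criteria, boundaries, oracle equivalence."""

import numpy as np
import pytest

from tracerscreen.feature_table import group_means
from tracerscreen.pair_screen import (
    PairCandidate,
    ScreenConfig,
    criterion_coelution,
    criterion_intensity,
    criterion_mass_shift,
    criterion_treatment_max,
    screen_pairs,
)
from tracerscreen.preprocess import floor_noise

from conftest import make_table, small_config
from oracles import brute_force_pairs
from tracerscreen.simulate import generate

CFG = ScreenConfig()


class TestCriterionIntensity:
    @pytest.mark.parametrize("values,expected", [
        ([500] * 9, False),          # everything at floor
        ([500] * 8 + [1001], True),  # one group mean just above 2x floor
        ([500] * 8 + [1000], False),  # exactly 2x floor: "more than" is strict
    ])
    def test_threshold_strictness(self, values, expected):
        t = floor_noise(make_table([values]))
        assert criterion_intensity("F0", t, CFG) is expected


class TestCriterionMassShift:
    def test_reported_pair_matches_five_deuteriums(self):
        ok, n = criterion_mass_shift(485.1184, 490.1494, CFG)
        assert ok and n == 5

    def test_far_off_gap_rejected(self):
        ok, n = criterion_mass_shift(485.1184, 485.1184 + 4.90, CFG)
        assert not ok and n is None

    def test_tolerance_scales_with_query_mz(self):
        # 20 ppm of 100 is 0.002 Da
        assert criterion_mass_shift(100.0, 100.0 + 2.0126 + 0.0019, CFG)[0]
        assert not criterion_mass_shift(100.0, 100.0 + 2.0126 + 0.0021, CFG)[0]

    def test_brute_force_verdicts(self):
        """Random gaps judged identically by a direct loop over all
        (count, tolerance) combinations."""
        rng = np.random.default_rng(5)
        deltas = CFG.shift_spec.deltas()
        for _ in range(300):
            mz_a = rng.uniform(100, 900)
            gap = rng.choice([
                rng.uniform(1.9, 10.2),
                float(rng.choice(list(deltas.values()))) + rng.normal(0, 2e-3),
            ])
            expected_n = None
            for n in sorted(deltas):
                if abs(gap - deltas[n]) <= 20e-6 * mz_a:
                    expected_n = n
                    break
            ok, n = criterion_mass_shift(mz_a, mz_a + gap, CFG)
            assert (ok, n) == (expected_n is not None, expected_n)


class TestCriterionCoelution:
    @pytest.mark.parametrize("rt_a,rt_b,expected", [
        (2.741, 2.741, True),
        (2.741, 2.791, True),   # |drt| = 0.05 inclusive
        (2.741, 2.7921, False),  # just outside
    ])
    def test_boundaries(self, rt_a, rt_b, expected):
        assert criterion_coelution(rt_a, rt_b, CFG) is expected


class TestCriterionTreatmentMax:
    def _pair_table(self, unlabeled_row, labeled_row):
        return floor_noise(make_table(
            [unlabeled_row, labeled_row], mz=[200.0, 205.0314]))

    def test_correct_pattern_passes(self):
        t = self._pair_table(
            [500, 500, 500, 500, 9000, 500, 500, 500, 500],
            [500, 500, 500, 500, 500, 500, 500, 8000, 500])
        assert criterion_treatment_max("F0", "F1", t)

    def test_labeled_peaking_in_control_fails(self):
        t = self._pair_table(
            [500, 500, 500, 500, 9000, 500, 500, 500, 500],
            [8000, 500, 500, 500, 500, 500, 500, 500, 500])
        assert not criterion_treatment_max("F0", "F1", t)

    def test_tied_argmax_disqualifies(self):
        # unlabeled's max tied between a tracer group and control
        t = self._pair_table(
            [9000, 500, 500, 9000, 500, 500, 500, 500, 500],
            [500, 500, 500, 500, 500, 500, 500, 8000, 500])
        assert not criterion_treatment_max("F0", "F1", t)


class TestScreenPairs:
    def test_empty_table_empty_result(self, small_sim):
        table, _ = small_sim
        empty = table.copy()
        empty.features = empty.features.iloc[:0]
        empty.intensities = empty.intensities.iloc[:0]
        assert screen_pairs(floor_noise(empty)) == []

    def test_requires_floored(self, small_sim):
        table, _ = small_sim
        with pytest.raises(ValueError, match="floored"):
            screen_pairs(table)

    def test_recovers_planted_pairs_and_no_decoys(self, small_sim):
        table, truth = small_sim
        pairs = screen_pairs(floor_noise(table))
        got = {(p.unlabeled_id, p.labeled_id) for p in pairs}
        assert got == truth.pair_set()
        assert not {p.unlabeled_id for p in pairs} & truth.decoy_feature_ids()
        by_id = {(p.unlabeled_id, p.labeled_id): p.n_label for p in pairs}
        for planted in truth.pairs:
            assert by_id[(planted.unlabeled_id, planted.labeled_id)] == planted.n_label

    def test_matches_brute_force_oracle(self, small_sim):
        table, _ = small_sim
        floored = floor_noise(table)
        got = {(p.unlabeled_id, p.labeled_id, p.n_label)
               for p in screen_pairs(floored)}
        assert got == brute_force_pairs(floored, ScreenConfig())

    def test_reported_pairs_satisfy_all_criteria_individually(self, small_sim):
        table, _ = small_sim
        floored = floor_noise(table)
        means = group_means(floored)
        feats = floored.features.set_index(floored.features["id"].astype(str))
        for p in screen_pairs(floored):
            assert criterion_intensity(p.unlabeled_id, floored, CFG, means)
            assert criterion_intensity(p.labeled_id, floored, CFG, means)
            ok, n = criterion_mass_shift(
                feats.loc[p.unlabeled_id, "mz"], feats.loc[p.labeled_id, "mz"], CFG)
            assert ok and n == p.n_label
            assert criterion_coelution(
                feats.loc[p.unlabeled_id, "rt"], feats.loc[p.labeled_id, "rt"], CFG)
            assert criterion_treatment_max(p.unlabeled_id, p.labeled_id, floored, CFG, means)
            assert p.delta_ppm_error <= CFG.delta_ppm_tol
            assert abs(p.rt_diff) <= CFG.rt_tol_min

    def test_row_permutation_invariance(self, small_sim):
        table, _ = small_sim
        floored = floor_noise(table)
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(floored.features))
        shuffled = floored.copy()
        shuffled.features = shuffled.features.iloc[perm].reset_index(drop=True)
        shuffled.intensities = shuffled.intensities.iloc[perm]
        assert screen_pairs(floored) == screen_pairs(shuffled)

    def test_monotone_under_tolerance_relaxation(self, small_sim):
        table, _ = small_sim
        floored = floor_noise(table)
        base = {(p.unlabeled_id, p.labeled_id) for p in screen_pairs(floored)}
        relaxed_cfg = ScreenConfig(delta_ppm_tol=60.0, rt_tol_min=0.2)
        relaxed = {(p.unlabeled_id, p.labeled_id)
                   for p in screen_pairs(floored, relaxed_cfg)}
        assert base <= relaxed

    def test_zero_planted_zero_found(self):
        table, truth = generate(small_config(
            seed=4, n_planted_pairs_pos=0, n_planted_pairs_neg=0,
            n_cobehave_up=0, n_cobehave_down=0, n_adduct_triplets=0))
        assert truth.pair_set() == set()
        assert screen_pairs(floor_noise(table)) == []
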