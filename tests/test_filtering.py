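"""The three-rule replicate filter: examples, oracle equivalence, monotonicity."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proxiscreen import (ConfigurationError, FilterCriteria, ValidationError,
                         apply_replicate_filter, fold_enrichment, passing_set)

from conftest import brute_force_filter, single_condition_matrix

count_rows = st.lists(st.lists(st.integers(0, 30), min_size=6, max_size=6),
                      min_size=1, max_size=20)


class TestFoldEnrichment:
    @pytest.mark.parametrize("bait, control, pc, expected", [
        ((8, 8, 8), (3, 4, 5), 0.0, 2.0),        # 8 / 4
        ((5, 6, 7), (0, 0, 0), 0.0, math.inf),   # zero background
        ((4, 4, 4), (4, 4, 4), 0.0, 1.0),        # identical means
        ((0, 0, 0), (0, 0, 0), 0.0, 0.0),        # nothing detected anywhere
        ((6, 6, 6), (2, 2, 2), 1.0, 2.0),        # 6 / (2 + 1)
    ])
    def test_examples(self, bait, control, pc, expected):
        assert fold_enrichment(bait, control, pseudocount=pc) == expected

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            fold_enrichment([], [1, 2])
        with pytest.raises(ValidationError):
            fold_enrichment([1], [])

    def test_control_aggregate_max(self):
        # mean-based passes (8 vs mean 4), max-based reference is stricter
        assert fold_enrichment((8, 8, 8), (3, 4, 5),
                               control_aggregate="max") == pytest.approx(8 / 5)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            fold_enrichment([1, -1], [0, 0])


class TestApplyReplicateFilter:
    def run_one(self, bait, control, **crit):
        m = single_condition_matrix([bait], [control])
        criteria = FilterCriteria(**crit) if crit else None
        return apply_replicate_filter(m, "3D", criteria)[0]

    def test_single_replicate_detection_fails(self):
        h = self.run_one((3, 0, 0), (0, 0, 0))
        assert not h.pass_detection and not h.pass_all
        assert h.pass_fold  # infinite enrichment still satisfies rule 2

    def test_control_cap_is_strict(self):
        h = self.run_one((20, 20, 20), (9, 9, 11))
        assert not h.pass_control_cap and not h.pass_all
        assert h.pass_detection
        h2 = self.run_one((20, 20, 20), (9, 9, 9))
        assert h2.pass_control_cap

    def test_all_rules_pass(self):
        h = self.run_one((8, 8, 8), (3, 4, 5))
        assert h.pass_detection and h.pass_fold and h.pass_control_cap
        assert h.pass_all
        assert h.fold_enrichment == 2.0

    def test_twofold_is_inclusive(self):
        # mean bait exactly twice mean control passes ("at least twice")
        assert self.run_one((8, 8, 8), (4, 4, 4)).pass_fold
        assert not self.run_one((7, 8, 8), (4, 4, 4)).pass_fold

    def test_zero_control_full_detection_passes(self):
        h = self.run_one((1, 1, 1), (0, 0, 0))
        assert h.pass_all and h.fold_enrichment == math.inf

    def test_missing_control_runs_is_config_error(self):
        m = single_condition_matrix([[1, 2, 3]], [[0, 0, 0]])
        with pytest.raises(ConfigurationError):
            apply_replicate_filter(m, "2D")

    def test_output_order_matches_matrix(self, default_screen):
        matrix, _, _ = default_screen
        hits = apply_replicate_filter(matrix, "3D")
        assert [h.protein_id for h in hits] == matrix.protein_ids

    @settings(max_examples=200, deadline=None)
    @given(rows=count_rows)
    def test_oracle_equivalence(self, rows):
        """Filter flags match an exact-arithmetic rule evaluator per protein."""
        arr = np.asarray(rows)
        m = single_condition_matrix(arr[:, :3], arr[:, 3:])
        hits = apply_replicate_filter(m, "3D")
        for h, row in zip(hits, arr):
            det, fold, cap = brute_force_filter(row[:3], row[3:])
            assert (h.pass_detection, h.pass_fold, h.pass_control_cap) == \
                   (det, fold, cap), f"counts {row}"

    @settings(max_examples=100, deadline=None)
    @given(rows=count_rows, data=st.data())
    def test_monotone_in_bait_and_control(self, rows, data):
        """Raising a bait count never loses a hit; raising a control count
        never creates one."""
        arr = np.asarray(rows)
        i = data.draw(st.integers(0, arr.shape[0] - 1))
        j = data.draw(st.integers(0, 5))
        bump = data.draw(st.integers(1, 10))
        m = single_condition_matrix(arr[:, :3], arr[:, 3:])
        before = apply_replicate_filter(m, "3D")[i].pass_all
        arr2 = arr.copy()
        arr2[i, j] += bump
        m2 = single_condition_matrix(arr2[:, :3], arr2[:, 3:])
        after = apply_replicate_filter(m2, "3D")[i].pass_all
        if j < 3:  # bait bumped
            assert not (before and not after)
        else:      # control bumped
            assert not (after and not before)

    @settings(max_examples=50, deadline=None)
    @given(rows=count_rows, data=st.data())
    def test_row_order_invariance(self, rows, data):
        arr = np.asarray(rows)
        perm = data.draw(st.permutations(range(arr.shape[0])))
        m1 = single_condition_matrix(arr[:, :3], arr[:, 3:])
        m2 = single_condition_matrix(arr[list(perm), :3],
                                     arr[list(perm), 3:],
                                     protein_ids=[f"P{p + 1}" for p in perm])
        by_id1 = {h.protein_id: h for h in apply_replicate_filter(m1, "3D")}
        by_id2 = {h.protein_id: h for h in apply_replicate_filter(m2, "3D")}
        assert by_id1 == by_id2


class TestPassingSet:
    def test_all_fail_empty(self):
        m = single_condition_matrix([[1, 0, 0], [0, 0, 0]],
                                    [[0, 0, 0], [0, 0, 0]])
        assert passing_set(apply_replicate_filter(m, "3D")) == set()

    def test_mixed_list_hand_counted(self):
        m = single_condition_matrix(
            [[8, 8, 8], [3, 0, 0], [20, 20, 20], [2, 2, 2]],
            [[3, 4, 5], [0, 0, 0], [9, 9, 11], [1, 1, 1]])
        hits = apply_replicate_filter(m, "3D")
        # P1 passes all; P2 fails detection; P3 fails the control cap;
        # P4: mean 2 vs 1, twofold inclusive -> passes
        assert passing_set(hits) == {"P1", "P4"}
        assert passing_set(hits) == passing_set(hits)  # idempotent


class TestCriteriaValidation:
    @pytest.mark.parametrize("kwargs", [
        {"min_detected_replicates": 0},
        {"min_detected_replicates": 4, "total_bait_replicates": 3},
        {"min_fold_over_control": 0.0},
        {"max_control_count": 0},
        {"pseudocount": -0.5},
        {"control_aggregate": "median"},
    ])
    def test_invalid_criteria_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            FilterCriteria(**kwargs)
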