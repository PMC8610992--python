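"""Synthetic-screen generator: determinism, distribution, recovery metrics."""

from __future__ import annotations

import numpy as np
import pytest

from proxiscreen import (GroundTruth, SyntheticScreenConfig, ValidationError,
                         evaluate_recovery, simulate_screen,
                         synthetic_annotations)


class TestSimulateScreen:
    def test_dimensions_and_metadata(self, default_screen):
        matrix, truth, config = default_screen
        n = config.n_background + config.n_true + config.n_contaminant
        assert matrix.n_proteins == n
        assert matrix.n_runs == 2 * config.replicates * len(config.conditions)
        for cond in config.conditions:
            for role in ("bait", "control"):
                cols = matrix.column_indices(role=role, condition=cond)
                assert len(cols) == config.replicates
        assert len(truth.true_interactors) == config.n_true
        assert len(truth.contaminants) == config.n_contaminant
        assert not truth.true_interactors & truth.contaminants

    def test_fixed_seed_bit_identical(self):
        cfg = SyntheticScreenConfig(seed=11)
        m1, t1 = simulate_screen(cfg)
        m2, t2 = simulate_screen(cfg)
        assert np.array_equal(m1.counts, m2.counts)
        assert m1.protein_ids == m2.protein_ids and m1.runs == m2.runs
        assert t1 == t2

    def test_different_seeds_differ(self):
        m1, _ = simulate_screen(SyntheticScreenConfig(seed=1))
        m2, _ = simulate_screen(SyntheticScreenConfig(seed=2))
        assert not np.array_equal(m1.counts, m2.counts)

    def test_no_signal_config_gives_empty_truth(self):
        cfg = SyntheticScreenConfig(n_true=0, n_contaminant=0,
                                    n_background=50,
                                    n_condition_enriched=0, seed=3)
        matrix, truth = simulate_screen(cfg)
        assert truth.true_interactors == frozenset()
        assert truth.contaminants == frozenset()
        assert truth.condition_enriched == {}
        # bait and control cells are exchangeable: compare group means
        bait = matrix.group_counts("bait", "3D")
        ctrl = matrix.group_counts("control", "3D")
        se = np.sqrt(2 * cfg.bg_rate / bait.size)
        assert abs(bait.mean() - ctrl.mean()) < 4 * se

    def test_background_mean_near_rate(self):
        """Mean of background cells within 3 SE of the Poisson rate."""
        cfg = SyntheticScreenConfig(n_true=0, n_contaminant=0,
                                    n_background=2000,
                                    n_condition_enriched=0, seed=5)
        matrix, _ = simulate_screen(cfg)
        cells = matrix.counts.astype(float)
        se = np.sqrt(cfg.bg_rate / cells.size)
        assert abs(cells.mean() - cfg.bg_rate) <= 3 * se

    def test_contaminants_high_in_bait_and_control(self, default_screen):
        matrix, truth, config = default_screen
        idx = [matrix.protein_ids.index(p) for p in sorted(truth.contaminants)]
        for role in ("bait", "control"):
            grp = matrix.group_counts(role, "3D")[idx]
            se = np.sqrt(config.contaminant_mean / grp.size)
            assert abs(grp.mean() - config.contaminant_mean) <= 4 * se

    def test_condition_multiplier_raises_bait_counts(self, default_screen):
        matrix, truth, config = default_screen
        enriched = sorted(truth.condition_enriched)
        assert truth.condition_enriched == {p: "3D" for p in enriched}
        idx = [matrix.protein_ids.index(p) for p in enriched]
        m3 = matrix.group_counts("bait", "3D")[idx].mean()
        m2 = matrix.group_counts("bait", "2D")[idx].mean()
        assert m3 > 5 * m2  # multiplier 25 with noise clears 5x easily

    def test_explicit_condition_effect_map(self):
        cfg = SyntheticScreenConfig(
            n_background=10, n_true=3, n_contaminant=0,
            n_condition_enriched=0, seed=9,
            condition_effect={"INT002": {"2D": 10.0}})
        _, truth = simulate_screen(cfg)
        assert truth.condition_enriched == {"INT002": "2D"}

    @pytest.mark.parametrize("kwargs", [
        {"replicates": 0}, {"bg_rate": 0.0}, {"dropout": 1.5},
        {"n_condition_enriched": 99}, {"conditions": ("2D", "2D")},
        {"enriched_condition": "organoid"},
        {"condition_effect": {"NOPE": {"3D": 5.0}}},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            cfg = SyntheticScreenConfig(**kwargs)
            simulate_screen(cfg)


class TestEvaluateRecovery:
    TRUTH = GroundTruth(frozenset({"a", "b", "c"}), frozenset({"x"}))

    def test_perfect_prediction(self):
        m = evaluate_recovery({"a", "b", "c"}, self.TRUTH)
        assert m.sensitivity == 1.0 and m.fdr == 0.0

    def test_empty_prediction(self):
        m = evaluate_recovery(set(), self.TRUTH)
        assert m.sensitivity == 0.0 and m.fdr == 0.0

    def test_hand_made_confusion(self):
        m = evaluate_recovery({"a", "b", "x"}, self.TRUTH)
        assert m.sensitivity == pytest.approx(2 / 3)
        assert m.fdr == pytest.approx(1 / 3)

    def test_unknown_id_rejected_against_universe(self):
        with pytest.raises(ValidationError, match="ghost"):
            evaluate_recovery({"ghost"}, self.TRUTH,
                              universe={"a", "b", "c", "x"})

    def test_ranked_auc_perfect_vs_inverted(self):
        perfect = {"a": 3.0, "b": 2.5, "c": 2.0, "x": 0.1}
        inverted = {"a": 0.1, "b": 0.2, "c": 0.3, "x": 3.0}
        auc_good = evaluate_recovery(perfect, self.TRUTH).auc_sens_fdr
        auc_bad = evaluate_recovery(inverted, self.TRUTH).auc_sens_fdr
        assert auc_good > auc_bad
        # perfect ranking: sensitivity hits 1 before any false positive,
        # then FDR sweeps out to 1/4 -> area = 1 * 1/4
        assert auc_good == pytest.approx(0.25)

    def test_set_input_has_no_auc(self):
        assert evaluate_recovery({"a"}, self.TRUTH).auc_sens_fdr is None


class TestSyntheticAnnotations:
    def test_terms_deterministic_and_disjoint_classes(self, default_screen):
        matrix, truth, _ = default_screen
        t1 = synthetic_annotations(truth, matrix.protein_ids, seed=4)
        t2 = synthetic_annotations(truth, matrix.protein_ids, seed=4)
        assert [(a.term_id, a.members) for a in t1] == \
               [(a.term_id, a.members) for a in t2]
        by_id = {a.term_id: a for a in t1}
        assert by_id["SYN:TRUE"].members == truth.true_interactors
        assert by_id["SYN:CONT"].members == truth.contaminants
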