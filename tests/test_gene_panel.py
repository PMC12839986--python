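"""Differential expression, fidelity filtering and GA subset search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hrdfuse import gene_panel, synthdata
from hrdfuse.gene_panel import (
    EmptySurvivorSet,
    GAConfig,
    differential_expression,
    fidelity_filter,
    ga_select,
    select_panel,
)
from hrdfuse.io_core import SplitManifest, StateError

from conftest import labels01


def bh_stepup_oracle(pvals, alpha):
    """Brute-force Benjamini-Hochberg step-up: reject p_(i) iff some
    j >= i has p_(j) <= alpha*j/m."""
    m = len(pvals)
    order = np.argsort(pvals)
    rejected = np.zeros(m, bool)
    max_j = 0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= alpha * rank / m:
            max_j = rank
    rejected[order[:max_j]] = True
    return rejected


class TestDifferentialExpression:
    def test_planted_shift_is_detected_and_null_genes_are_not(self):
        rng = np.random.default_rng(0)
        n_hi, n_lo = 60, 140
        y = np.r_[np.ones(n_hi, bool), np.zeros(n_lo, bool)]
        X = rng.standard_normal((200, 50))
        X[y, 0] += 2.0  # planted d = 2
        ids = [f"G{i}" for i in range(50)]
        results, retained = differential_expression(X, y, ids, alpha_fdr=0.05)
        assert "G0" in retained
        assert results[0].direction == 1
        assert len(retained) <= 5  # overwhelmingly just the planted gene

    def test_constant_gene_gets_p_one_and_never_retained(self):
        rng = np.random.default_rng(1)
        y = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        X = rng.standard_normal((20, 3))
        X[:, 1] = 7.0
        results, retained = differential_expression(X, y, ["A", "B", "C"], 0.9)
        assert results[1].p_value == 1.0
        assert "B" not in retained

    def test_bh_adjustment_matches_stepup_oracle(self):
        """Retention = the brute-force BH step-up rule on the raw p-values."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            m = rng.integers(5, 50)
            pvals = rng.random(m) ** rng.uniform(0.5, 3)
            from statsmodels.stats.multitest import multipletests

            reject, q, _, _ = multipletests(pvals, alpha=0.1, method="fdr_bh")
            np.testing.assert_array_equal(reject, bh_stepup_oracle(pvals, 0.1))
            assert (q >= pvals - 1e-12).all()

    def test_fdr_controlled_under_null(self):
        """Average retained fraction at FDR 0.05 stays below 0.05 when no
        gene differs between classes (reduced-size replicate check)."""
        rng = np.random.default_rng(3)
        fracs = []
        for _ in range(40):
            y = np.r_[np.ones(30, bool), np.zeros(70, bool)]
            X = rng.standard_normal((100, 200))
            _, retained = differential_expression(X, y, list(map(str, range(200))), 0.05)
            fracs.append(len(retained) / 200)
        assert np.mean(fracs) <= 0.05

    def test_too_few_samples_per_class_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            differential_expression(np.zeros((3, 2)), [1, 0, 0], ["a", "b"])


class TestFidelityFilter:
    def test_identical_matrices_retain_everything(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 8))
        results, retained = fidelity_filter(X, X, list("abcdefgh"), min_pcc=1.0)
        assert retained == list("abcdefgh")
        assert all(abs(r.pcc - 1.0) < 1e-12 for r in results)

    def test_anticorrelated_genes_are_dropped(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 4))
        _, retained = fidelity_filter(-X, X, list("abcd"), min_pcc=0.3)
        assert retained == []

    def test_zero_variance_column_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 3))
        P = X.copy()
        P[:, 1] = 4.2
        with pytest.warns(RuntimeWarning, match="zero variance"):
            results, _ = fidelity_filter(P, X, list("abc"), 0.0)
        assert [r.gene_id for r in results] == ["a", "c"]

    def test_retained_fraction_matches_fisher_z_prediction(self):
        """Sampling distribution check: at true rho and n samples, the
        probability that the sample r clears the threshold follows the
        Fisher z-transform normal approximation."""
        rho, n, thr = 0.6061, 200, 0.4
        z = lambda r: np.arctanh(r)
        p_retain = 1 - stats.norm.cdf((z(thr) - z(rho)) * np.sqrt(n - 3))
        rng = np.random.default_rng(4)
        X = rng.standard_normal((n, 3000))
        P = synthdata.emulate_predictor(X, rho, seed=9)
        _, retained = fidelity_filter(P, X, list(map(str, range(3000))), thr)
        assert abs(len(retained) / 3000 - p_retain) < 0.03

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            fidelity_filter(np.zeros((3, 2)), np.zeros((3, 3)), ["a", "b"])


def synergy_pool(seed, n=160, n_noise=18, amp=1.5):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.4).astype(int)
    X = rng.standard_normal((n, n_noise))
    s1 = rng.choice([-1.0, 1.0], size=n)
    s2 = np.where(y == 1, s1, -s1)
    X = np.column_stack(
        [X, s1 * amp + 0.5 * rng.standard_normal(n), s2 * amp + 0.5 * rng.standard_normal(n)]
    )
    ids = [f"G{i:03d}" for i in range(n_noise + 2)]
    return X, y, ids, {ids[-2], ids[-1]}


class TestGeneticAlgorithm:
    def test_pool_equal_to_panel_returns_pool_immediately(self):
        X, y, ids, _ = synergy_pool(0)
        cfg = GAConfig(panel_size=len(ids), generations=10, seed=0)
        panel = ga_select(X, y, ids, cfg)
        assert sorted(panel.gene_ids) == sorted(ids)
        assert len(panel.ga_history) == 1

    def test_best_fitness_history_is_non_decreasing(self):
        X, y, ids, _ = synergy_pool(1)
        cfg = GAConfig(population_size=12, generations=8, panel_size=4, seed=1)
        panel = ga_select(X, y, ids, cfg)
        assert all(b >= a for a, b in zip(panel.ga_history, panel.ga_history[1:]))
        assert len(panel.ga_history) == 9

    def test_degenerate_ga_reduces_to_initial_population(self):
        """With no crossover, no mutation, no immigrants and full elitism the
        GA just evaluates generation 0 repeatedly."""
        X, y, ids, _ = synergy_pool(2)
        cfg = GAConfig(
            population_size=8, generations=5, panel_size=4, crossover_rate=0.0,
            mutation_rate=0.0, n_immigrants=0, elitism=7, seed=3,
        )
        panel = ga_select(X, y, ids, cfg)
        assert len(set(panel.ga_history)) == 1  # never improves past gen 0

    def test_ga_finds_synergy_pair_more_often_than_marginal_ranking(self):
        """Reduced-replicate version of the synergy-recovery comparison."""
        ga_hits, marginal_hits, runs = 0, 0, 6
        for seed in range(runs):
            X, y, ids, pair = synergy_pool(seed)
            cfg = GAConfig(population_size=30, generations=15, panel_size=5, seed=seed)
            panel = ga_select(X, y, ids, cfg)
            ga_hits += pair <= set(panel.gene_ids)
            d = np.abs(X[y == 1].mean(0) - X[y == 0].mean(0))
            marginal_hits += pair <= {ids[i] for i in np.argsort(-d)[:5]}
        assert ga_hits > marginal_hits
        assert ga_hits >= runs - 1

    def test_infeasible_cardinality_rejected(self):
        X, y, ids, _ = synergy_pool(0)
        with pytest.raises(ValueError, match="panel_size"):
            ga_select(X, y, ids, GAConfig(panel_size=len(ids) + 1))

    @given(seed=st.integers(0, 50))
    @settings(max_examples=8, deadline=None, derandomize=True)
    def test_panel_members_always_come_from_pool_without_duplicates(self, seed):
        X, y, ids, _ = synergy_pool(seed, n=80, n_noise=8)
        cfg = GAConfig(population_size=8, generations=3, panel_size=4, seed=seed)
        panel = ga_select(X, y, ids, cfg)
        assert len(panel.gene_ids) == 4
        assert len(set(panel.gene_ids)) == 4
        assert set(panel.gene_ids) <= set(ids)


class TestSelectPanel:
    def make_cohort(self, seed=11):
        spec = synthdata.CohortSpec(
            n_patients=150, n_genes=60, n_de_genes=20, de_effect=1.5,
            n_synergy_pairs=0, predictor_fidelity=0.9, seed=seed,
        )
        pats, truth = synthdata.generate_cohort(spec)
        ids = [p.patient_id for p in pats]
        manifest = SplitManifest({p: "train" for p in ids}, "hrd_label", 0)
        true_e = np.vstack([p.true_expression for p in pats])
        pred_e = np.vstack([p.inferred_expression for p in pats])
        return true_e, pred_e, labels01(pats), synthdata.gene_names(60), ids, manifest

    def test_panel_is_subset_of_stage_survivors_with_requested_size(self):
        true_e, pred_e, y, genes, ids, manifest = self.make_cohort()
        ga = GAConfig(population_size=12, generations=4, panel_size=8, seed=0)
        panel = select_panel(true_e, pred_e, y, genes, ids, manifest, ga_config=ga)
        assert len(panel.gene_ids) == 8
        _, de_kept = differential_expression(pred_e, y, genes, 0.05)
        assert set(panel.gene_ids) <= set(de_kept)

    def test_same_inputs_and_seed_give_identical_panel(self):
        true_e, pred_e, y, genes, ids, manifest = self.make_cohort()
        ga = GAConfig(population_size=10, generations=3, panel_size=6, seed=4)
        p1 = select_panel(true_e, pred_e, y, genes, ids, manifest, ga_config=ga)
        p2 = select_panel(true_e, pred_e, y, genes, ids, manifest, ga_config=ga)
        assert p1.gene_ids == p2.gene_ids

    def test_non_training_sample_raises(self):
        true_e, pred_e, y, genes, ids, manifest = self.make_cohort()
        manifest.assignments[ids[0]] = "test"
        with pytest.raises(StateError, match=ids[0]):
            select_panel(true_e, pred_e, y, genes, ids, manifest)

    def test_thresholds_excluding_everything_raise_not_silent_empty(self):
        true_e, pred_e, y, genes, ids, manifest = self.make_cohort()
        with pytest.raises(EmptySurvivorSet, match="relaxing"):
            select_panel(true_e, pred_e, y, genes, ids, manifest, min_pcc=1.1)
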