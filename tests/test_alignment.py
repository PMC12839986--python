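"""InfoNCE correctness, contrastive training behaviour, fusion algebra."""

import inspect

import numpy as np
import pytest

from hrdfuse import alignment
from hrdfuse.alignment import (
    AlignmentConfig,
    EncoderBundle,
    EncoderSpec,
    embed_cohort,
    fuse,
    info_nce_pair,
    multimodal_loss,
    retrieval_top1_accuracy,
    train_alignment,
)

from conftest import cohort_views


def naive_info_nce(Za, Zb, tau):
    """Independent double-loop reference implementation."""
    An = Za / np.linalg.norm(Za, axis=1, keepdims=True)
    Bn = Zb / np.linalg.norm(Zb, axis=1, keepdims=True)
    N = len(An)
    total = 0.0
    for i in range(N):
        num = np.exp(An[i] @ Bn[i] / tau)
        den_ab = sum(np.exp(An[i] @ Bn[j] / tau) for j in range(N))
        den_ba = sum(np.exp(An[j] @ Bn[i] / tau) for j in range(N))
        total += -0.5 * (np.log(num / den_ab) + np.log(num / den_ba))
    return total / N


class TestInfoNCE:
    def test_single_pair_has_zero_loss(self):
        assert info_nce_pair(np.array([[1.0, 2.0]]), np.array([[3.0, 1.0]])) == 0.0

    @pytest.mark.parametrize("n", [2, 5, 9])
    def test_identical_rows_give_log_n(self, n):
        rng = np.random.default_rng(n)
        Z = np.tile(rng.standard_normal(6), (n, 1))
        assert abs(info_nce_pair(Z, Z, 0.07) - np.log(n)) < 1e-9

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        N, d = rng.integers(2, 16), rng.integers(2, 32)
        Za, Zb = rng.standard_normal((N, d)), rng.standard_normal((N, d))
        tau = rng.uniform(0.05, 1.0)
        assert abs(info_nce_pair(Za, Zb, tau) - naive_info_nce(Za, Zb, tau)) < 1e-6

    def test_invariant_under_joint_row_permutation(self):
        rng = np.random.default_rng(0)
        Za, Zb = rng.standard_normal((7, 5)), rng.standard_normal((7, 5))
        perm = rng.permutation(7)
        assert abs(
            info_nce_pair(Za, Zb, 0.2) - info_nce_pair(Za[perm], Zb[perm], 0.2)
        ) < 1e-12

    def test_mismatched_single_view_permutation_changes_loss(self):
        rng = np.random.default_rng(1)
        Za, Zb = rng.standard_normal((6, 4)), rng.standard_normal((6, 4))
        shifted = np.roll(np.arange(6), 1)
        assert abs(info_nce_pair(Za, Zb, 0.2) - info_nce_pair(Za, Zb[shifted], 0.2)) > 1e-6

    def test_loss_vanishes_for_separated_pairs_at_low_temperature(self):
        Z = np.eye(5)  # each patient on its own axis: positives dominate
        assert info_nce_pair(Z, Z, 0.01) < 1e-6

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            info_nce_pair(np.ones((2, 3)), np.ones((3, 3)))
        with pytest.raises(ValueError):
            info_nce_pair(np.array([[np.nan, 1.0]]), np.ones((1, 2)))
        with pytest.raises(ValueError):
            info_nce_pair(np.ones((2, 2)), np.ones((2, 2)), temperature=0.0)

    def test_analytic_gradients_match_finite_differences(self):
        from hrdfuse.alignment import _info_nce_pair_grad

        rng = np.random.default_rng(3)
        Za, Zb = rng.standard_normal((4, 6)), rng.standard_normal((4, 6))
        tau, eps = 0.3, 1e-6
        _, dZa, _, dtau = _info_nce_pair_grad(Za, Zb, tau)
        for i, j in [(0, 0), (1, 3), (3, 5)]:
            Zp, Zm = Za.copy(), Za.copy()
            Zp[i, j] += eps
            Zm[i, j] -= eps
            num = (info_nce_pair(Zp, Zb, tau) - info_nce_pair(Zm, Zb, tau)) / (2 * eps)
            assert abs(num - dZa[i, j]) < 1e-7
        num_tau = (
            info_nce_pair(Za, Zb, tau + eps) - info_nce_pair(Za, Zb, tau - eps)
        ) / (2 * eps)
        assert abs(num_tau - dtau) < 1e-7


class TestMultimodalLoss:
    def test_single_pair_weight_reduces_to_pair_loss(self):
        rng = np.random.default_rng(0)
        Zm, Zc, Zt = (rng.standard_normal((5, 4)) for _ in range(3))
        cfg = AlignmentConfig(pair_weights=(1.0, 0.0, 0.0), temperature=0.1)
        assert abs(multimodal_loss(Zm, Zc, Zt, cfg) - info_nce_pair(Zm, Zc, 0.1)) < 1e-12

    def test_equals_sum_of_three_pair_losses(self):
        rng = np.random.default_rng(1)
        Zm, Zc, Zt = (rng.standard_normal((6, 4)) for _ in range(3))
        cfg = AlignmentConfig(temperature=0.2)
        expected = (
            info_nce_pair(Zm, Zc, 0.2)
            + info_nce_pair(Zm, Zt, 0.2)
            + info_nce_pair(Zc, Zt, 0.2)
        )
        assert abs(multimodal_loss(Zm, Zc, Zt, cfg) - expected) < 1e-12

    def test_indistinguishable_patients_give_three_log_n(self):
        # every patient identical in every view -> uniform softmax per pair
        rng = np.random.default_rng(2)
        Z = np.tile(rng.standard_normal(5), (8, 1))
        cfg = AlignmentConfig(temperature=0.07)
        assert abs(multimodal_loss(Z, Z, Z, cfg) - 3 * np.log(8)) < 1e-9

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="pair_weights"):
            AlignmentConfig(pair_weights=(0.0, 0.0, 0.0)).validate()


def small_training_config(**kw):
    defaults = dict(epochs=25, batch_size=128, seed=1)
    defaults.update(kw)
    return AlignmentConfig(**defaults)


def small_specs(views, embed_dim=16):
    return {
        m: EncoderSpec(m, X.shape[1], embed_dim=embed_dim) for m, X in views.items()
    }


class TestTraining:
    def test_loss_decreases_and_training_is_deterministic(self, shared_factor_cohort):
        patients, _ = shared_factor_cohort
        views = {m: X[:100] for m, X in cohort_views(patients).items()}
        cfg = small_training_config(epochs=10)
        b1 = train_alignment(views, small_specs(views), cfg)
        b2 = train_alignment(views, small_specs(views), cfg)
        assert b1.loss_curve[-1] <= b1.loss_curve[0]
        assert b1.loss_curve == b2.loss_curve
        np.testing.assert_array_equal(
            b1.encoders["morphology"].W[0], b2.encoders["morphology"].W[0]
        )

    def test_api_accepts_no_labels(self):
        params = inspect.signature(train_alignment).parameters
        assert "labels" not in params
        assert "y" not in params

    def test_batch_size_below_two_rejected(self):
        with pytest.raises(ValueError, match="batch_size"):
            AlignmentConfig(batch_size=1).validate()

    def test_held_out_retrieval_beats_chance_on_shared_factor(self, shared_factor_cohort):
        patients, _ = shared_factor_cohort
        views = cohort_views(patients)
        tr = {m: X[:160] for m, X in views.items()}
        cfg = small_training_config(epochs=60)
        bundle = train_alignment(tr, small_specs(views, 32), cfg)
        acc = retrieval_top1_accuracy(
            bundle.project("morphology", views["morphology"][160:]),
            bundle.project("transcriptomic", views["transcriptomic"][160:]),
        )
        assert acc >= 5 * (1 / 40)

    def test_bundle_save_load_roundtrip(self, tmp_path, shared_factor_cohort):
        patients, _ = shared_factor_cohort
        views = {m: X[:60] for m, X in cohort_views(patients).items()}
        bundle = train_alignment(views, small_specs(views), small_training_config(epochs=3))
        bundle.save(tmp_path / "bundle.npz")
        back = EncoderBundle.load(tmp_path / "bundle.npz")
        for m in views:
            np.testing.assert_array_equal(
                bundle.project(m, views[m]), back.project(m, views[m])
            )
        assert back.temperature == bundle.temperature


class TestFusion:
    def test_single_modality_is_normalised_projection(self):
        v = np.array([3.0, 4.0])
        emb = fuse({"morphology": v}, "P1")
        np.testing.assert_allclose(emb.vector, [0.6, 0.8])
        assert emb.modalities_used == ("morphology",)

    def test_identical_unit_vectors_are_fixed_point(self):
        v = np.array([1.0, 0.0, 0.0])
        emb = fuse({"a": v, "b": v})
        np.testing.assert_allclose(emb.vector, v)

    def test_three_orthogonal_units_average_to_diagonal(self):
        emb = fuse({"a": np.eye(3)[0], "b": np.eye(3)[1], "c": np.eye(3)[2]})
        np.testing.assert_allclose(emb.vector, np.ones(3) / np.sqrt(3))

    def test_antipodal_inputs_cannot_be_fused(self):
        v = np.array([1.0, 0.0])
        with pytest.raises(ValueError, match="cancel"):
            fuse({"a": v, "b": -v})

    def test_fused_vectors_are_unit_norm(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            proj = {m: rng.standard_normal(8) for m in ("a", "b", "c")}
            assert abs(np.linalg.norm(fuse(proj).vector) - 1.0) < 1e-12


class TestEmbedCohort:
    @pytest.fixture(scope="class")
    def trained(self, shared_factor_cohort):
        patients, _ = shared_factor_cohort
        views = {m: X[:80] for m, X in cohort_views(patients).items()}
        bundle = train_alignment(views, small_specs(views), small_training_config(epochs=5))
        return bundle, views, [p.patient_id for p in patients[:80]]

    def test_full_modality_patient_uses_all_three(self, trained):
        bundle, views, ids = trained
        embs = embed_cohort(bundle, views, ids)
        assert embs[0].modalities_used == ("morphology", "molecular", "transcriptomic")
        assert all(abs(np.linalg.norm(e.vector) - 1) < 1e-9 for e in embs)

    def test_image_only_inference_drops_molecular(self, trained):
        bundle, views, ids = trained
        partial = {k: v for k, v in views.items() if k != "molecular"}
        embs = embed_cohort(bundle, partial, ids)
        assert embs[0].modalities_used == ("morphology", "transcriptomic")

    def test_missing_mandatory_modality_is_named(self, trained):
        bundle, views, ids = trained
        with pytest.raises(ValueError, match="morphology"):
            embed_cohort(bundle, {"molecular": views["molecular"]}, ids)

    def test_default_configuration_yields_512_dimensions(self, shared_factor_cohort):
        patients, _ = shared_factor_cohort
        views = {m: X[:40] for m, X in cohort_views(patients).items()}
        bundle = train_alignment(views, config=small_training_config(epochs=2))
        embs = embed_cohort(bundle, views, [p.patient_id for p in patients[:40]])
        assert embs[0].vector.shape == (512,)
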