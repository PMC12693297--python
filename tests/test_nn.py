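"""Network forward/backward correctness, distances, and the triplet loss."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemsiam.nn.losses import (
    inverse_distance,
    inverse_distance_matrix,
    pairwise_distance,
    triplet_loss,
    triplet_loss_batch,
)
from chemsiam.nn.network import ModelConfig, SiameseNet

TINY = ModelConfig(
    embedding_dim=6,
    conv_channels=(4, 8),
    mlp_hidden=(8, 4),
    proj_hidden=(8,),
    input_size=8,
    seed=3,
)


def tiny_inputs(rng, n=2):
    mep = rng.random((n, 3, 8, 8))
    glcm = rng.random((n, 64))
    glcm /= glcm.sum(axis=1, keepdims=True)
    return mep, glcm


class TestGradients:
    """Analytic backprop vs central finite differences."""

    def test_parameter_gradients_match_numeric(self, rng):
        net = SiameseNet(TINY)
        mep, glcm = tiny_inputs(rng)
        R = rng.standard_normal((2, TINY.embedding_dim))

        def loss():
            return float(np.sum(net.forward(mep, glcm) * R))

        loss()
        net.backward(R)
        analytic = [g.copy() for g in net.grads]
        eps = 1e-6
        for p, g in zip(net.params, analytic):
            flat = p.reshape(-1)
            idx = rng.choice(flat.size, size=min(8, flat.size), replace=False)
            for i in idx:
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss()
                flat[i] = orig - eps
                lm = loss()
                flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                assert g.reshape(-1)[i] == pytest.approx(numeric, rel=1e-4, abs=1e-7)

    def test_glcm_input_gradient_matches_numeric(self, rng):
        net = SiameseNet(TINY)
        mep, glcm = tiny_inputs(rng, n=1)
        R = rng.standard_normal((1, TINY.embedding_dim))
        net.forward(mep, glcm)
        d_glcm = net.backward(R)
        eps = 1e-6
        for i in rng.choice(64, size=6, replace=False):
            gp, gm = glcm.copy(), glcm.copy()
            gp[0, i] += eps
            gm[0, i] -= eps
            numeric = (
                float(np.sum(net.forward(mep, gp) * R))
                - float(np.sum(net.forward(mep, gm) * R))
            ) / (2 * eps)
            assert d_glcm[0, i] == pytest.approx(numeric, rel=1e-4, abs=1e-7)


class TestBranches:
    def test_forward_deterministic_for_fixed_weights(self, rng):
        net = SiameseNet(TINY)
        mep, glcm = tiny_inputs(rng)
        assert np.array_equal(net.forward(mep, glcm), net.forward(mep, glcm))

    def test_cnn_branch_batch_shape(self, rng):
        net = SiameseNet(TINY)
        mep, _ = tiny_inputs(rng, n=5)
        assert net.cnn_branch(mep).shape == (5, TINY.conv_channels[-1])

    def test_cnn_branch_zero_image_finite(self):
        net = SiameseNet(TINY)
        out = net.cnn_branch(np.zeros((1, 3, 8, 8)))
        assert np.all(np.isfinite(out))

    def test_cnn_branch_wrong_shape_rejected(self, rng):
        net = SiameseNet(TINY)
        with pytest.raises(ValueError):
            net.cnn_branch(rng.random((1, 3, 7, 8)))

    def test_mlp_branch_shape_and_length_check(self, rng):
        net = SiameseNet(TINY)
        out = net.mlp_branch(rng.random((3, 64)))
        assert out.shape == (3, TINY.mlp_hidden[-1])
        with pytest.raises(ValueError):
            net.mlp_branch(rng.random((3, 63)))

    def test_fused_embedding_dimension(self, rng):
        net = SiameseNet(TINY)
        mep, glcm = tiny_inputs(rng, n=4)
        assert net.forward(mep, glcm).shape == (4, TINY.embedding_dim)

    def test_normalized_embeddings_unit_norm(self, rng):
        cfg = ModelConfig(
            embedding_dim=6,
            conv_channels=(4, 8),
            mlp_hidden=(8, 4),
            proj_hidden=(8,),
            input_size=8,
            normalize_embeddings=True,
            seed=3,
        )
        net = SiameseNet(cfg)
        emb = net.forward(*tiny_inputs(rng, n=3))
        assert np.allclose(np.linalg.norm(emb, axis=1), 1.0, atol=1e-6)

    def test_texture_modality_influences_embedding(self, rng):
        net = SiameseNet(TINY)
        mep, glcm = tiny_inputs(rng, n=1)
        e1 = net.forward(mep, glcm)
        e2 = net.forward(mep, np.zeros_like(glcm))
        assert not np.allclose(e1, e2)

    def test_checkpoint_round_trip(self, rng, tmp_path):
        net = SiameseNet(TINY)
        mep, glcm = tiny_inputs(rng)
        before = net.forward(mep, glcm)
        path = tmp_path / "ckpt.npz"
        net.save(str(path))
        loaded = SiameseNet.load(str(path))
        assert loaded.config == TINY
        assert np.array_equal(loaded.forward(mep, glcm), before)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(margin=0.0)
        with pytest.raises(ValueError):
            ModelConfig(embedding_dim=-1)
        with pytest.raises(ValueError):
            ModelConfig(input_size=30)  # not divisible by 2^3


class TestDistances:
    def test_zero_and_pythagoras_and_symmetry(self):
        assert pairwise_distance([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert pairwise_distance([0.0, 0.0], [3.0, 4.0]) == pytest.approx(5.0)
        a, b = [1.0, -2.0, 0.5], [0.0, 1.0, 2.0]
        assert pairwise_distance(a, b) == pairwise_distance(b, a)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distance([1.0], [1.0, 2.0])

    @pytest.mark.parametrize("d,expected", [(0.0, 1.0), (1.0, 0.5), (3.0, 0.25)])
    def test_inverse_distance_closed_form(self, d, expected):
        assert inverse_distance(d) == pytest.approx(expected)

    def test_inverse_distance_negative_rejected(self):
        with pytest.raises(ValueError):
            inverse_distance(-0.1)

    @given(
        d1=st.floats(0, 1e6, allow_nan=False),
        d2=st.floats(0, 1e6, allow_nan=False),
    )
    @settings(deadline=None, derandomize=True)
    def test_inverse_distance_strictly_decreasing_into_unit_interval(self, d1, d2):
        s1, s2 = inverse_distance(d1), inverse_distance(d2)
        assert 0.0 < s1 <= 1.0
        if d1 < d2:
            assert s1 > s2


class TestTripletLoss:
    def test_margin_satisfied_is_zero(self):
        # 1-D embeddings with d(a,p)=0.2, d(a,n)=1.0
        assert triplet_loss([0.0], [0.2], [1.0], margin=0.5) == 0.0

    def test_margin_violated_arithmetic(self):
        # d(a,p)=1.0, d(a,n)=0.2 -> 1.0 - 0.2 + 0.5
        assert triplet_loss([0.0], [1.0], [0.2], margin=0.5) == pytest.approx(1.3)

    def test_anchor_equals_positive(self):
        # loss = max(0, margin - d(a,n))
        assert triplet_loss([0.0], [0.0], [0.3], margin=0.5) == pytest.approx(0.2)
        assert triplet_loss([0.0], [0.0], [2.0], margin=0.5) == 0.0

    def test_nonpositive_margin_rejected(self):
        with pytest.raises(ValueError):
            triplet_loss([0.0], [1.0], [2.0], margin=0.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            triplet_loss([0.0, 1.0], [1.0], [2.0], margin=0.5)

    def test_nonnegative_and_zero_iff_margin_met(self, rng):
        for _ in range(50):
            ea, ep, en = rng.standard_normal((3, 4))
            loss = triplet_loss(ea, ep, en, margin=0.7)
            gap = pairwise_distance(ea, en) - pairwise_distance(ea, ep)
            assert loss >= 0
            assert (loss == 0) == (gap >= 0.7)

    def test_batch_gradient_matches_numeric(self, rng):
        emb = rng.standard_normal((5, 3))
        ia, ip, ineg = np.array([0, 1]), np.array([2, 3]), np.array([4, 0])
        loss, grad = triplet_loss_batch(emb, ia, ip, ineg, margin=1.0, with_grad=True)
        eps = 1e-6
        for i in range(emb.shape[0]):
            for j in range(emb.shape[1]):
                ep_, em_ = emb.copy(), emb.copy()
                ep_[i, j] += eps
                em_[i, j] -= eps
                lp = triplet_loss_batch(ep_, ia, ip, ineg, margin=1.0)
                lm = triplet_loss_batch(em_, ia, ip, ineg, margin=1.0)
                assert grad[i, j] == pytest.approx((lp - lm) / (2 * eps), abs=1e-5)


class TestInverseDistanceMatrix:
    def test_identical_embeddings_all_ones(self):
        e = {k: np.array([1.0, 2.0]) for k in "abc"}
        m = inverse_distance_matrix(e)
        assert np.allclose(m.values, 1.0)

    def test_matches_entrywise_recomputation(self, rng):
        emb = {f"c{i}": rng.standard_normal(4) for i in range(5)}
        m = inverse_distance_matrix(emb)
        for i in m.index:
            for j in m.columns:
                if i == j:
                    assert m.loc[i, j] == 1.0
                else:
                    expected = inverse_distance(pairwise_distance(emb[i], emb[j]))
                    assert m.loc[i, j] == pytest.approx(expected)

    def test_symmetry_unit_diagonal_range(self, rng):
        emb = {f"c{i}": rng.standard_normal(6) * 10 for i in range(6)}
        m = inverse_distance_matrix(emb)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 1.0)
        assert np.all(m.values > 0) and np.all(m.values <= 1)
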