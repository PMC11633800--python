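"""Ranking-attention pooling: scores, selection, aggregation, gradients."""

import numpy as np
import pytest

from ramil.encoders import IdentityEncoder
from ramil.pooling import (
    AttentionParams,
    MILModel,
    aggregate,
    attention_scores,
    classify,
    forward,
    gated_attention_scores,
    pool_max,
    pool_mean,
    rank_select,
)
from ramil.training import LossSpec


def brute_force_select(a, C):
    """Oracle: full sort by (-score, index)."""
    order = sorted(range(len(a)), key=lambda i: (-a[i], i))
    return order[: min(C, len(a))]


class TestAttentionScores:
    def test_singleton_bag(self, rng):
        p = AttentionParams(V=rng.normal(size=(4, 3)), w=rng.normal(size=4))
        assert np.allclose(attention_scores(rng.normal(size=(1, 3)), p), [1.0])

    def test_identical_rows_symmetric(self, rng):
        p = AttentionParams(V=rng.normal(size=(4, 3)), w=rng.normal(size=4))
        h = rng.normal(size=3)
        assert np.allclose(attention_scores(np.stack([h, h]), p), [0.5, 0.5])

    def test_scalar_softmax_example(self):
        # logits (tanh(10), 0): softmax = (e^t/(e^t+1), 1/(e^t+1)) with t = tanh(10)
        p = AttentionParams(V=[[1.0, 0.0]], w=[1.0])
        a = attention_scores(np.array([[10.0, 0.0], [0.0, 0.0]]), p)
        t = np.tanh(10.0)
        expected = np.array([np.exp(t), 1.0]) / (np.exp(t) + 1.0)
        assert np.allclose(a, expected, atol=1e-10)
        assert a == pytest.approx([0.7311, 0.2689], abs=1e-4)

    def test_normalization_over_random_bags(self, rng):
        for _ in range(50):
            K, L, D = rng.integers(1, 30), rng.integers(1, 10), rng.integers(1, 8)
            p = AttentionParams(V=rng.normal(size=(D, L)), w=rng.normal(size=D))
            a = attention_scores(rng.normal(scale=5, size=(K, L)), p)
            assert a.sum() == pytest.approx(1.0, abs=1e-6)
            assert (a >= 0).all() and (a <= 1).all()

    def test_dimension_mismatch(self, rng):
        p = AttentionParams(V=rng.normal(size=(4, 3)), w=rng.normal(size=4))
        with pytest.raises(ValueError, match="does not match"):
            attention_scores(rng.normal(size=(2, 5)), p)


class TestRankSelect:
    def test_descending_selection(self):
        sel = rank_select(np.array([0.1, 0.5, 0.4]), np.eye(3), C=2)
        assert sel.indices.tolist() == [1, 2]
        assert sel.slice_numbers.tolist() == [2, 3]
        assert np.allclose(sel.scores, [0.5, 0.4])

    def test_tie_breaks_to_lower_index(self):
        sel = rank_select(np.array([0.4, 0.4, 0.2]), np.eye(3), C=1)
        assert sel.indices.tolist() == [0]

    def test_c_clamped_to_bag_size(self):
        sel = rank_select(np.array([0.2, 0.5, 0.3]), np.eye(3), C=10)
        assert sel.indices.tolist() == [1, 2, 0]
        assert sel.scores.sum() == pytest.approx(1.0)

    def test_invalid_c(self):
        with pytest.raises(ValueError):
            rank_select(np.array([1.0]), np.ones((1, 2)), C=0)

    def test_scores_are_pure_gather(self, rng):
        a = rng.dirichlet(np.ones(8))
        H = rng.normal(size=(8, 3))
        sel = rank_select(a, H, C=4)
        assert np.array_equal(sel.scores, a[sel.indices])
        assert np.array_equal(sel.features, H[sel.indices])

    def test_matches_brute_force_oracle_with_ties(self, rng):
        for _ in range(300):
            K = int(rng.integers(1, 31))
            a = rng.choice([0.0, 0.1, 0.25, 0.5], size=K)  # heavy ties
            a = a / max(a.sum(), 1e-12)
            C = int(rng.integers(1, 12))
            sel = rank_select(a, rng.normal(size=(K, 2)), C)
            assert sel.indices.tolist() == brute_force_select(a, C)

    def test_sum_selected_increases_with_c(self, rng):
        a = rng.dirichlet(np.ones(10))  # distinct almost surely
        H = rng.normal(size=(10, 2))
        sums = [rank_select(a, H, C).scores.sum() for C in range(1, 11)]
        assert all(s2 > s1 for s1, s2 in zip(sums, sums[1:]))
        assert sums[-1] == pytest.approx(1.0, abs=1e-9)


class TestAggregateClassify:
    def test_single_instance_weight_one(self, rng):
        H = rng.normal(size=(1, 5))
        sel = rank_select(np.array([1.0]), H, C=1)
        assert np.allclose(aggregate(sel), H[0])

    def test_unit_basis_arithmetic(self):
        sel = rank_select(np.array([0.5, 0.4, 0.1]), np.eye(3), C=2)
        assert np.allclose(aggregate(sel), [0.5, 0.4, 0.0])

    def test_zero_features(self):
        sel = rank_select(np.array([0.6, 0.4]), np.zeros((2, 4)), C=2)
        assert np.array_equal(aggregate(sel), np.zeros(4))

    def test_classify_neutral_and_monotone(self):
        z = np.array([1.0, -2.0])
        assert classify(z, np.zeros(2), 0.0) == pytest.approx(0.5)
        probs = [classify(z, np.zeros(2), b) for b in (-5, 0, 5, 50)]
        assert all(p1 < p2 for p1, p2 in zip(probs, probs[1:]))
        assert probs[-1] == pytest.approx(1.0, abs=1e-6)


class TestPoolingBaselines:
    def test_mean_max_single_row(self, rng):
        H = rng.normal(size=(1, 4))
        assert np.allclose(pool_mean(H), H[0])
        assert np.allclose(pool_max(H), H[0])

    def test_unit_basis(self):
        H = np.eye(2, 5)
        assert np.allclose(pool_mean(H), [0.5, 0.5, 0, 0, 0])
        assert np.allclose(pool_max(H), [1, 1, 0, 0, 0])

    def test_mean_le_max(self, rng):
        H = rng.normal(size=(6, 8))
        assert (pool_mean(H) <= pool_max(H) + 1e-12).all()

    def test_gated_zero_gate_matches_half_scale_attention(self, rng):
        # U = 0 => gate = 0.5 everywhere => logits are w·(tanh(Vh)·0.5),
        # identical to plain attention with w/2
        D, L = 4, 6
        V, w = rng.normal(size=(D, L)), rng.normal(size=D)
        H = rng.normal(size=(5, L))
        gated = gated_attention_scores(H, AttentionParams(V=V, w=w), U=np.zeros((D, L)))
        plain = attention_scores(H, AttentionParams(V=V, w=w / 2))
        assert np.allclose(gated, plain, atol=1e-12)

    def test_gated_singleton_and_symmetry(self, rng):
        D, L = 3, 4
        params = AttentionParams(V=rng.normal(size=(D, L)), w=rng.normal(size=D))
        U = rng.normal(size=(D, L))
        assert np.allclose(gated_attention_scores(rng.normal(size=(1, L)), params, U), [1.0])
        h = rng.normal(size=L)
        assert np.allclose(
            gated_attention_scores(np.stack([h, h]), params, U), [0.5, 0.5]
        )


class TestForward:
    def test_functional_composition_matches_model(self, rng):
        enc = IdentityEncoder(6)
        model = MILModel(enc, variant="ramil", C=3, D=4, seed=5)
        X = rng.normal(size=(7, 6))
        res = model.forward(X, precomputed_H=True)
        prob, a, sel = forward(
            X,
            enc,
            model.attention_params,
            model.params["head_w"],
            model.params["head_b"][0],
            C=3,
        )
        assert prob == pytest.approx(res.probability, abs=1e-12)
        assert np.allclose(a, res.attention)
        assert sel.indices.tolist() == res.selection.indices.tolist()

    def test_c_geq_k_identical_to_attention_mil(self, rng):
        enc = IdentityEncoder(5)
        ramil = MILModel(enc, variant="ramil", C=12, D=4, seed=2)
        attn = MILModel(enc, variant="attention", D=4, seed=99)
        attn.load_state_dict(ramil.state_dict())
        for _ in range(20):
            X = rng.normal(size=(int(rng.integers(1, 12)), 5))
            r1 = ramil.forward(X, precomputed_H=True)
            r2 = attn.forward(X, precomputed_H=True)
            assert r1.probability == r2.probability  # bit-identical
            assert np.max(np.abs(r1.z - r2.z)) == 0.0

    def test_permutation_equivariance(self, rng):
        model = MILModel(IdentityEncoder(4), variant="ramil", C=3, D=4, seed=0)
        for _ in range(20):
            X = rng.normal(size=(8, 4))
            perm = rng.permutation(8)
            r = model.forward(X, precomputed_H=True)
            rp = model.forward(X[perm], precomputed_H=True)
            if len(np.unique(np.round(r.attention, 12))) < 8:
                continue  # ties would legitimately change the gather
            assert np.allclose(rp.attention, r.attention[perm])
            assert rp.probability == pytest.approx(r.probability, abs=1e-12)


class TestGradients:
    @pytest.mark.parametrize("variant", ["ramil", "attention", "gated", "mean", "max"])
    def test_analytic_matches_finite_difference(self, variant, rng):
        """Loss gradients w.r.t. V, w, U, head match central differences
        within 1e-4 relative error on a 3-instance bag (scores well separated
        so the top-C selection is fixed between perturbed evaluations)."""
        spec = LossSpec(1, 1)
        model = MILModel(IdentityEncoder(5), variant=variant, C=2, D=4, seed=1)
        X = rng.normal(size=(3, 5)) * 2  # separated scores
        y = 1

        def loss():
            res = model.forward(X, precomputed_H=True)
            q = np.clip(res.probability, 1e-12, 1 - 1e-12)
            return -spec.beta_P * np.log(q), res

        base, res = loss()
        grads = model.backward(res, spec.beta_P * (res.probability - y))
        for name, p in model.params.items():
            num = np.zeros_like(p)
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = p[i]
                p[i] = orig + 1e-6
                up, _ = loss()
                p[i] = orig - 1e-6
                down, _ = loss()
                p[i] = orig
                num[i] = (up - down) / 2e-6
            denom = max(np.abs(num).max(), 1e-8)
            assert np.abs(grads.get(name, np.zeros_like(p)) - num).max() / denom < 1e-4, name
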