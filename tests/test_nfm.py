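import numpy as np
import pytest

from kgenfm.errors import DimensionError, TrainingSetupError
from kgenfm.nfm import (
    FieldSpec,
    NFMParams,
    NFMTrainConfig,
    bi_interaction,
    embed_features,
    init_nfm,
    load_nfm,
    nfm_forward,
    nfm_loss_and_grads,
    predict_proba,
    save_nfm,
    train_nfm,
)


def bi_interaction_oracle(V_x):
    """O(n^2) double sum of pairwise elementwise products."""
    n, k = V_x.shape
    out = np.zeros(k)
    for i in range(n):
        for j in range(i + 1, n):
            out += V_x[i] * V_x[j]
    return out


class TestEmbedFeatures:
    def test_zero_instance_annihilates(self):
        V = np.random.default_rng(0).normal(size=(4, 3))
        assert np.all(embed_features(np.zeros(4), V) == 0.0)

    def test_hand_scaling(self):
        out = embed_features(np.array([2.0]), np.array([[1.0, 1.0]]))
        np.testing.assert_array_equal(out, [[2.0, 2.0]])

    def test_cardinality(self):
        V = np.zeros((7, 2))
        assert embed_features(np.ones(7), V).shape == (7, 2)

    def test_size_mismatch(self):
        with pytest.raises(DimensionError):
            embed_features(np.ones(3), np.zeros((4, 2)))


class TestBiInteraction:
    def test_single_feature_no_pairs(self):
        assert np.all(bi_interaction(np.array([[1.0, 2.0]])) == 0.0)

    def test_hand_example(self):
        V_x = np.array([[1.0, 2.0], [3.0, 4.0]])  # x = (1,1)
        np.testing.assert_allclose(bi_interaction(V_x), [3.0, 8.0])

    def test_fast_identity_matches_double_sum(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n, k = int(rng.integers(1, 21)), int(rng.integers(1, 8))
            V_x = rng.normal(size=(n, k))
            np.testing.assert_allclose(
                bi_interaction(V_x), bi_interaction_oracle(V_x), atol=1e-6
            )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bi_interaction(np.empty((0, 3)))


def zero_params(n=3, k=2, h=2):
    return NFMParams(
        w0=0.0, w=np.zeros(n), V=np.zeros((n, k)),
        layers=[(np.zeros((h, k)), np.zeros(h), "relu")], p=np.zeros(h),
    )


class TestForward:
    def test_zero_network_gives_half(self):
        score, prob = nfm_forward(np.array([1.0, -2.0, 3.0]), zero_params())
        assert score == 0.0 and prob == 0.5

    def test_pure_linear_when_hidden_zero(self):
        params = zero_params()
        params.w0 = 0.5
        params.w = np.array([1.0, 2.0, -1.0])
        x = np.array([1.0, 0.5, 2.0])
        score, _ = nfm_forward(x, params)
        assert score == pytest.approx(0.5 + 1.0 + 1.0 - 2.0)

    def test_hand_forward_pass(self):
        # n=2 features, k=2, one identity hidden layer with hand-set 2x2 weights
        x = np.array([1.0, 2.0])
        V = np.array([[1.0, 0.0], [0.0, 1.0]])
        # bi-interaction: (1*v1) (*) (2*v2) = (1,0)*(0,2) = (0,0)... pick denser V
        V = np.array([[1.0, 2.0], [3.0, 1.0]])
        u1, u2 = x[0] * V[0], x[1] * V[1]
        z0 = u1 * u2  # = (6, 4)
        W = np.array([[1.0, -1.0], [0.5, 0.5]])
        b = np.array([0.1, -0.1])
        p = np.array([2.0, 1.0])
        z1 = W @ z0 + b
        expected = 0.25 + np.array([0.5, -0.5]) @ x + p @ z1
        params = NFMParams(w0=0.25, w=np.array([0.5, -0.5]), V=V,
                           layers=[(W, b, "identity")], p=p)
        score, prob = nfm_forward(x, params)
        assert score == pytest.approx(float(expected))
        assert 0.0 < prob < 1.0

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        n, k = 6, 4
        params = init_nfm(n, k, hidden=(5,), seed=0)
        params.w = rng.normal(size=n)
        x = rng.normal(size=n)
        perm = rng.permutation(n)
        permuted = NFMParams(w0=params.w0, w=params.w[perm], V=params.V[perm],
                             layers=params.layers, p=params.p)
        s1, _ = nfm_forward(x, params)
        s2, _ = nfm_forward(x[perm], permuted)
        assert s1 == pytest.approx(s2)


class TestGradients:
    def test_finite_difference_check(self):
        rng = np.random.default_rng(3)
        n, k = 5, 3
        params = init_nfm(n, k, hidden=(4,), activation="tanh", seed=1)
        params.w = rng.normal(size=n) * 0.1
        params.w0 = 0.2
        X = rng.normal(size=(7, n))
        y = rng.integers(0, 2, size=7).astype(float)
        loss, grads = nfm_loss_and_grads(params, X, y, l2=1e-3)
        flat = params.flat()
        eps = 1e-6
        for arr, g in zip(flat, grads):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                ix = it.multi_index
                orig = arr[ix]
                arr[ix] = orig + eps
                params.w0 = float(flat[0][0])
                lp, _ = nfm_loss_and_grads(params, X, y, l2=1e-3)
                arr[ix] = orig - eps
                params.w0 = float(flat[0][0])
                lm, _ = nfm_loss_and_grads(params, X, y, l2=1e-3)
                arr[ix] = orig
                params.w0 = float(flat[0][0])
                fd = (lp - lm) / (2 * eps)
                denom = max(abs(fd), abs(g[ix]), 1e-8)
                assert abs(fd - g[ix]) / denom < 1e-4


def separable_data(n=200, seed=0):
    """Linearly separable with a margin, so a perfect ranking is reachable."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n, 2))
    keep = np.abs(X[:, 0] + X[:, 1]) > 0.3
    X = X[keep][:n]
    y = (X[:, 0] + X[:, 1] > 0).astype(float)
    return X, y


class TestTraining:
    def test_zero_epochs_returns_init(self):
        X, y = separable_data()
        cfg = NFMTrainConfig(k=4, hidden=(4,), epochs=0, seed=5)
        params = train_nfm(X, y, cfg)
        ref = init_nfm(2, 4, (4,), "relu", 5)
        np.testing.assert_array_equal(params.V, ref.V)
        np.testing.assert_array_equal(params.p, ref.p)

    def test_seed_determinism(self):
        X, y = separable_data()
        cfg = NFMTrainConfig(k=4, hidden=(4,), epochs=3, seed=5)
        a, b = train_nfm(X, y, cfg), train_nfm(X, y, cfg)
        np.testing.assert_array_equal(a.V, b.V)
        assert a.w0 == b.w0

    def test_separable_reaches_perfect_training_auroc(self):
        from sklearn.metrics import roc_auc_score

        X, y = separable_data()
        cfg = NFMTrainConfig(k=8, hidden=(8,), epochs=60, learning_rate=0.02,
                             dropout=0.0, seed=2)
        params = train_nfm(X, y, cfg)
        assert roc_auc_score(y, predict_proba(params, X)) == pytest.approx(1.0)

    def test_loss_monotone_first_epochs(self):
        X, y = separable_data()
        history: list[float] = []
        cfg = NFMTrainConfig(k=4, hidden=(4,), epochs=5, learning_rate=0.003,
                             dropout=0.0, seed=1)
        train_nfm(X, y, cfg, loss_history=history)
        assert all(b <= a + 1e-9 for a, b in zip(history, history[1:]))

    def test_single_class_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(TrainingSetupError):
            train_nfm(X, np.ones(4), NFMTrainConfig(epochs=1))


class TestSerialization:
    def test_round_trip_and_byte_determinism(self, tmp_path):
        X, y = separable_data()
        cfg = NFMTrainConfig(k=4, hidden=(4,), epochs=2, seed=3)
        params = train_nfm(X, y, cfg, field_spec=FieldSpec([("a", 1), ("b", 1)]))
        p1, p2 = tmp_path / "m1.zip", tmp_path / "m2.zip"
        save_nfm(params, p1, seed=3)
        save_nfm(params, p2, seed=3)
        assert p1.read_bytes() == p2.read_bytes()
        back = load_nfm(p1)
        np.testing.assert_array_equal(back.V, params.V)
        assert back.field_spec.blocks == [("a", 1), ("b", 1)]
        x = np.array([0.3, -0.7])
        assert nfm_forward(x, back) == nfm_forward(x, params)
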