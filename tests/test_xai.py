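"""Attribution methods: Shapley axioms, oracle equivalences, LIME recovery
and the correctly-classified-ictal filter."""

import numpy as np
import pytest

from eegxai.containers import WindowSet
from eegxai.correlation import spearman
from eegxai.synth import make_linear_oracle
from eegxai.xai import (AttributionQuery, CoalitionTree, LimeConfig,
                        MaskingPolicy, exact_shapley, explain_correct_ictal,
                        lime_channels, partition_shapley,
                        permutation_shapley)


def as_batch(x):
    x = np.asarray(x, float)
    return x[None] if x.ndim == 2 else x


class ConstantModel:
    def predict_proba(self, x):
        return np.full(len(as_batch(x)), 0.5)


class AdditiveModel:
    """f(x) = sum_c g_c(mean power of channel c), g_c = w_c * tanh."""

    def __init__(self, weights):
        self.w = np.asarray(weights, float)

    def per_channel(self, x):
        mp = np.mean(as_batch(x) ** 2, axis=2)
        return self.w * np.tanh(mp)

    def predict_proba(self, x):
        return self.per_channel(x).sum(axis=1)


def random_window(rng, m, L=64):
    return rng.standard_normal((m, L))


class TestExactShapley:
    def test_constant_model_all_zero(self, rng):
        q = AttributionQuery(model=ConstantModel(), x=random_window(rng, 5))
        phi, base = exact_shapley(q)
        assert np.allclose(phi, 0.0, atol=1e-12)
        assert base == 0.5

    def test_additive_model_closed_form(self, rng):
        # with zeros masking, additivity forces phi_c = g_c(x_c) - g_c(0)
        model = AdditiveModel([0.5, -0.3, 0.8, 0.1])
        x = random_window(rng, 4)
        q = AttributionQuery(model=model, x=x)
        phi, base = exact_shapley(q)
        expected = model.per_channel(x)[0] - model.per_channel(np.zeros_like(x))[0]
        assert np.allclose(phi, expected, atol=1e-10)
        assert phi.sum() + base == pytest.approx(model.predict_proba(x[None])[0])

    @pytest.mark.parametrize("m", [4, 6])
    def test_equals_permutation_oracle(self, rng, m):
        model = make_linear_oracle(rng.normal(size=m), threshold=1.0, gain=1.5)
        q = AttributionQuery(model=model, x=random_window(rng, m))
        phi, _ = exact_shapley(q)
        phi_perm = permutation_shapley(q)
        assert np.allclose(phi, phi_perm, atol=1e-10)

    def test_large_m_refused(self, rng):
        q = AttributionQuery(model=ConstantModel(), x=random_window(rng, 17))
        with pytest.raises(ValueError, match="partition_shapley"):
            exact_shapley(q)


class TestAxioms:
    def test_efficiency_dummy_symmetry(self, rng):
        for _ in range(10):
            m = int(rng.integers(3, 8))
            w = rng.normal(size=m)
            w[1] = 0.0          # dummy channel
            w[2] = w[0]         # candidate symmetric pair
            model = make_linear_oracle(w, threshold=float(rng.normal()), gain=1.0)
            x = random_window(rng, m)
            x[2] = x[0]         # identical content -> symmetric channels
            q = AttributionQuery(model=model, x=x)
            phi, base = exact_shapley(q)
            fx = float(model.predict_proba(x))
            assert abs(phi.sum() + base - fx) <= 1e-8
            assert abs(phi[1]) <= 1e-10
            assert abs(phi[0] - phi[2]) <= 1e-8


class TestPartitionShapley:
    def test_tree_structure(self):
        tree = CoalitionTree.build(5)  # padded to 8 slots
        assert sorted(tree.channels) == [0, 1, 2, 3, 4]
        tree.validate(5)
        assert (0, 1) in tree.deepest_pairs()

    def test_additive_equals_exact(self, rng):
        model = AdditiveModel(rng.normal(size=8))
        q = AttributionQuery(model=model, x=random_window(rng, 8))
        phi_exact, _ = exact_shapley(q)
        phi_owen, _ = partition_shapley(q)
        assert np.allclose(phi_owen, phi_exact, atol=1e-8)

    def test_constant_model_zero(self, rng):
        q = AttributionQuery(model=ConstantModel(), x=random_window(rng, 6))
        phi, _ = partition_shapley(q)
        assert np.allclose(phi, 0.0, atol=1e-12)

    def test_efficiency_on_random_windows(self, rng):
        model = make_linear_oracle(rng.normal(size=10), threshold=2.0, gain=0.8)
        for _ in range(20):
            x = random_window(rng, 10)
            q = AttributionQuery(model=model, x=x)
            phi, base = partition_shapley(q)
            assert abs(phi.sum() + base - float(model.predict_proba(x))) <= 1e-8

    def test_close_to_exact_for_nonadditive(self, rng):
        # sigmoid-of-additive is not additive; the Owen values still track
        # the exact Shapley values closely on the balanced default tree
        model = make_linear_oracle(rng.normal(size=8) ** 2, threshold=4.0, gain=1.0)
        x = random_window(rng, 8)
        q = AttributionQuery(model=model, x=x)
        phi_exact, _ = exact_shapley(q)
        phi_owen, _ = partition_shapley(q)
        assert np.max(np.abs(phi_exact - phi_owen)) < 0.1

    def test_pair_mean_averages_and_preserves_sum(self, rng):
        model = AdditiveModel(rng.normal(size=6))
        x = random_window(rng, 6)
        q = AttributionQuery(model=model, x=x)
        phi, base = partition_shapley(q, pair_mean=False)
        phim, basem = partition_shapley(q, pair_mean=True)
        assert phim.sum() == pytest.approx(phi.sum(), abs=1e-12)
        assert phim[0] == pytest.approx(phim[1])
        assert phim[0] == pytest.approx(0.5 * (phi[0] + phi[1]))


class TestMaskingPolicy:
    def test_zeros_and_channel_mean(self, rng):
        x = rng.standard_normal((3, 16)) + 5.0
        masks = np.array([[1.0, 0.0, 1.0]])
        z = MaskingPolicy("zeros").apply(x, masks)[0]
        assert np.allclose(z[1], 0.0)
        assert np.allclose(z[0], x[0])
        cm = MaskingPolicy("channel_mean").apply(x, masks)[0]
        assert np.allclose(cm[1], x[1].mean())

    def test_reference_requires_window(self, rng):
        with pytest.raises(ValueError):
            MaskingPolicy("reference")
        ref = rng.standard_normal((3, 16))
        pol = MaskingPolicy("reference", reference=ref)
        out = pol.apply(rng.standard_normal((3, 16)), np.array([[0.0, 1.0, 0.0]]))[0]
        assert np.allclose(out[0], ref[0])


class TestLime:
    def test_constant_model_zero_coefficients(self, rng):
        q = AttributionQuery(model=ConstantModel(), x=random_window(rng, 6))
        coef = lime_channels(q, LimeConfig(n_samples=200, seed=0))
        assert np.allclose(coef, 0.0, atol=1e-8)

    def test_recovers_oracle_ranking_and_tracks_shapley(self, rng):
        w = np.array([0.5, 1.5, 1.0, 0.1, 2.0, 0.0, 0.8, 0.3])
        model = make_linear_oracle(w, threshold=np.sum(w) / 2, gain=0.5)
        x = random_window(rng, 8, L=128)
        q = AttributionQuery(model=model, x=x)
        coef = lime_channels(q, LimeConfig(n_samples=2000, ridge_alpha=1e-3,
                                           seed=11))
        phi, _ = exact_shapley(q)
        rho = spearman(coef, phi).rho
        assert rho >= 0.99

    def test_converges_to_weighted_least_squares_closed_form(self, rng):
        # brute-force WLS on the full 2^M mask set is the target of the
        # sampling estimator
        m = 6
        model = make_linear_oracle(rng.uniform(0.2, 2.0, m), threshold=2.0,
                                   gain=0.8)
        x = random_window(rng, m, L=128)
        q = AttributionQuery(model=model, x=x)
        masks = ((np.arange(2 ** m)[:, None] >> np.arange(m)) & 1).astype(float)
        preds = np.concatenate([
            np.atleast_1d(model.predict_proba(q.masking.apply(x, masks[i:i + 1])))
            for i in range(2 ** m)])
        width = 0.75 * np.sqrt(m)
        wts = np.exp(-np.sum((masks - 1) ** 2, axis=1) / width ** 2)
        X = np.hstack([masks, np.ones((2 ** m, 1))])
        A = X.T @ (wts[:, None] * X)
        alpha = 1e-3
        A[:m, :m] += alpha * np.eye(m)
        beta = np.linalg.solve(A, X.T @ (wts * preds))
        coef = lime_channels(q, LimeConfig(n_samples=6000, ridge_alpha=alpha,
                                           seed=5))
        assert np.allclose(coef, beta[:m], atol=0.02)

    def test_single_informative_channel_dominates(self, rng):
        w = np.zeros(6); w[3] = 2.0
        model = make_linear_oracle(w, threshold=1.0, gain=1.0)
        x = random_window(rng, 6, L=128)
        q = AttributionQuery(model=model, x=x)
        for seed in range(20):
            coef = lime_channels(q, LimeConfig(n_samples=500, seed=seed))
            assert np.argmax(np.abs(coef)) == 3

    def test_undersampling_warns(self, rng):
        q = AttributionQuery(model=ConstantModel(), x=random_window(rng, 12))
        with pytest.warns(UserWarning, match="10"):
            lime_channels(q, LimeConfig(n_samples=50, seed=0))


class TestExplainCorrectIctal:
    def make_test_set(self, rng, probs_model, n=8, m=4):
        data = rng.standard_normal((n, m, 64))
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        return WindowSet(data=data, labels=labels,
                         provenance=[("r", i) for i in range(n)], fs=64.0)

    def test_no_true_positive_empty_with_warning(self, rng):
        class AlwaysNeg:
            def predict_proba(self, x):
                return np.zeros(len(np.atleast_3d(x)))

        ws = self.make_test_set(rng, None)
        with pytest.warns(UserWarning, match="no correctly classified"):
            out = explain_correct_ictal(AlwaysNeg(), ws)
        assert out.empty

    def test_row_count_matches_tp_oracle(self, rng):
        model = make_linear_oracle(np.ones(4), threshold=4.0, gain=2.0)
        ws = self.make_test_set(rng, model)
        probs = model.predict_proba(ws.data)
        tp = int(np.sum((ws.labels == 1) & (probs >= 0.5)))
        out = explain_correct_ictal(model, ws, lime_config=LimeConfig(
            n_samples=100, seed=0))
        assert set(out["method"]) <= {"shap", "lime"}
        assert len(out) == tp * 4 * 2  # windows x channels x methods
        assert set(out.loc[out["method"] == "shap", "window"]) == \
            set(np.flatnonzero((ws.labels == 1) & (probs >= 0.5)))
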