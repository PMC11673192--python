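import numpy as np
import pytest

from metasurv.model import (
    HighwayEncoderConfig,
    ModelConfig,
    MultiOmicsSurvivalModel,
    cosine_similarity,
    cox_partial_likelihood_loss,
    fuse,
    highway_layer,
    risk_score,
    similarity_loss,
)

from _oracles import cox_loss_bruteforce, random_survival_instance
from conftest import make_dataset, tiny_model


class TestHighwayLayer:
    def _params(self, d, t_bias):
        # H = tanh(x), T gate forced via large bias, G = identity
        return {
            "H": (np.eye(d), np.zeros(d)),
            "T": (np.zeros((d, d)), np.full(d, t_bias)),
            "G": (np.eye(d), np.zeros(d)),
        }

    def test_closed_gate_is_carry_path(self):
        x = np.array([0.3, -1.2])
        out = highway_layer(x, self._params(2, -50.0))
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_open_gate_is_transform_path(self):
        x = np.array([0.3, -1.2])
        out = highway_layer(x, self._params(2, 50.0))
        np.testing.assert_allclose(out, np.tanh(x), atol=1e-12)

    def test_hand_computed_gate_mixture(self):
        # 2-dim, T bias 0 with zero weights -> gate exactly 0.5 everywhere
        x = np.array([1.0, -2.0])
        out = highway_layer(x, self._params(2, 0.0))
        np.testing.assert_allclose(out, 0.5 * np.tanh(x) + 0.5 * x, atol=1e-12)


class TestEncode:
    def test_identical_rows_identical_embeddings(self, rng):
        m = tiny_model()
        theta = m.init_parameters(rng)
        X = np.tile(rng.normal(size=(1, 10)), (4, 1))
        Z = np.asarray(m.encode(theta, X, 0))
        assert np.ptp(Z, axis=0).max() == 0

    def test_permutation_equivariance(self, rng):
        m = tiny_model()
        theta = m.init_parameters(rng)
        X = rng.normal(size=(6, 10))
        perm = rng.permutation(6)
        np.testing.assert_array_equal(
            np.asarray(m.encode(theta, X, 0))[perm], np.asarray(m.encode(theta, X[perm], 0)))

    def test_no_batch_coupling(self, rng):
        m = tiny_model()
        theta = m.init_parameters(rng)
        X = rng.normal(size=(5, 10))
        single = np.asarray(m.encode(theta, X[2:3], 0))
        # tolerance instead of bitwise: BLAS may sum a 1-row and a 5-row
        # matmul in different orders, shifting the last ulp
        np.testing.assert_allclose(
            np.asarray(m.encode(theta, X, 0))[2], single[0], rtol=0, atol=1e-12)

    def test_input_dim_mismatch_rejected(self, rng):
        m = tiny_model()
        theta = m.init_parameters(rng)
        with pytest.raises(ValueError, match="features"):
            m.encode(theta, np.zeros((3, 7)), 0)


class TestCosine:
    def test_identical_vectors(self):
        assert cosine_similarity([1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert cosine_similarity([1.0, 0.0], [0.0, 3.0]) == pytest.approx(0.0)

    def test_hand_value(self):
        assert cosine_similarity([1.0, 0.0], [1.0, 1.0]) == pytest.approx(1 / np.sqrt(2), abs=1e-4)

    def test_scale_invariance(self, rng):
        a, b = rng.normal(size=4), rng.normal(size=4)
        assert cosine_similarity(3.7 * a, b) == pytest.approx(cosine_similarity(a, b))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cosine_similarity([0.0, 0.0], [1.0, 0.0])


class TestSimilarityLoss:
    def test_zero_when_margin_satisfied(self):
        Z = np.eye(4)  # own-view pairs aligned, cross pairs orthogonal
        assert similarity_loss(Z, Z, margin=0.2, negative_rule="all_pairs") == pytest.approx(0.0)

    def test_equal_similarities_give_margin(self):
        Z1 = np.tile([1.0, 0.0], (3, 1))  # every similarity identical
        Z2 = np.tile([1.0, 0.0], (3, 1))
        val = similarity_loss(Z1, Z2, margin=0.3, negative_rule="all_pairs")
        assert val == pytest.approx(0.3)

    def test_two_sample_all_pairs_hand_value(self):
        Z1 = np.array([[1.0, 0.0], [0.0, 1.0]])
        Z2 = np.array([[1.0, 1.0], [1.0, 0.0]])
        # S = [[1/sqrt2, 1], [1/sqrt2, 0]] ; anchors: max(0, M - (S00-S01)), max(0, M-(S11-S10))
        M = 0.2
        s = 1 / np.sqrt(2)
        expected = (max(0, M - (s - 1)) + max(0, M - (0 - s))) / 2
        val = similarity_loss(Z1, Z2, margin=M, negative_rule="all_pairs")
        assert val == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("rule", ["one_random", "all_pairs", "hardest"])
    def test_bounded_by_margin_plus_two(self, rng, rule):
        M = 0.2
        for _ in range(20):
            n = rng.integers(2, 8)
            Z1, Z2 = rng.normal(size=(n, 5)), rng.normal(size=(n, 5))
            val = similarity_loss(Z1, Z2, margin=M, negative_rule=rule, rng=rng)
            assert 0.0 <= val <= M + 2.0

    def test_single_sample_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            similarity_loss(np.ones((1, 3)), np.ones((1, 3)), 0.2, "all_pairs")


class TestFuseAndHead:
    def test_fuse_cases(self):
        np.testing.assert_array_equal(fuse(np.array([1.0, 3.0]), np.array([3.0, 1.0])), [2, 2])
        z = np.array([0.5, -2.0])
        np.testing.assert_array_equal(fuse(z, z), z)
        np.testing.assert_array_equal(fuse(z, -z), [0, 0])

    def test_linear_head_hand_values(self):
        assert risk_score([2.0, 0.5], [0.0, 0.0]) == 0.0
        assert risk_score([2.0, 0.5], [1.0, -1.0]) == pytest.approx(1.5)
        assert risk_score([2.0, 0.5], [1.0, -1.0], bias=0.25) == pytest.approx(1.75)


class TestCoxLoss:
    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(7)
        for trial in range(200):
            n = int(rng.integers(2, 21))
            tie = trial % 3 == 0
            h, times, events = random_survival_instance(rng, n, tie_times=tie)
            for rule in ("geq", "gt"):
                try:
                    expected = cox_loss_bruteforce(h, times, events, rule)
                except ValueError:
                    with pytest.raises(ValueError):
                        cox_partial_likelihood_loss(h, times, events, rule)
                    continue
                got = cox_partial_likelihood_loss(h, times, events, rule)
                assert got == pytest.approx(expected, abs=1e-10)

    def test_shift_invariance(self, rng):
        h, times, events = random_survival_instance(rng, 15)
        base = cox_partial_likelihood_loss(h, times, events)
        shifted = cox_partial_likelihood_loss(h + 123.456, times, events)
        assert abs(base - shifted) <= 1e-10

    def test_all_censored_returns_zero_with_warning(self, rng):
        with pytest.warns(UserWarning, match="censored"):
            val = cox_partial_likelihood_loss(rng.normal(size=5), np.ones(5) + 1, np.zeros(5))
        assert val == 0.0

    def test_single_event_self_risk_set_is_zero(self):
        assert cox_partial_likelihood_loss([0.7], [3.0], [1]) == pytest.approx(0.0)

    def test_hand_case_three_samples(self):
        h, times, events = [0.5, -0.2, 0.1], [1.0, 2.0, 3.0], [1, 0, 1]
        expected = cox_loss_bruteforce(h, times, events, "geq")
        assert cox_partial_likelihood_loss(h, times, events) == pytest.approx(expected, abs=1e-12)

    def test_tied_event_times_use_full_batch_risk_set(self):
        # Breslow convention: with all times equal and all events, every term
        # shares the full batch as its risk set.
        h = np.array([0.3, -0.1, 0.8])
        loss = cox_partial_likelihood_loss(h, [5.0, 5.0, 5.0], [1, 1, 1], "geq")
        lse = np.log(np.exp(h).sum())
        expected = -np.mean(h - lse)
        assert loss == pytest.approx(expected, abs=1e-12)

    def test_strict_rule_empty_risk_set_errors(self):
        with pytest.raises(ValueError, match="empty risk set"):
            cox_partial_likelihood_loss([0.1, 0.2], [1.0, 2.0], [1, 1], "gt")

    def test_strict_rule_matches_printed_formula_when_defined(self):
        h, times, events = [0.5, -0.2, 0.1], [1.0, 2.0, 3.0], [1, 1, 0]
        expected = cox_loss_bruteforce(h, times, events, "gt")
        assert cox_partial_likelihood_loss(h, times, events, "gt") == pytest.approx(expected)


class TestTotalLoss:
    def test_breakdown_invariant_and_simweight_zero(self, rng):
        ds = make_dataset(rng)
        m = tiny_model()
        theta = m.init_parameters(rng)
        neg = m.sample_negatives(ds.n_samples, rng)
        lb = m.loss(theta, ds.view_values(), ds.times, ds.events, neg_idx=neg)
        assert lb.total == pytest.approx(lb.cox + lb.sim_weight * lb.sim)
        m0 = tiny_model(sim_weight=0.0)
        lb0 = m0.loss(theta, ds.view_values(), ds.times, ds.events, neg_idx=neg)
        assert lb0.total == pytest.approx(lb0.cox)
        assert lb0.sim == 0.0

    def test_hand_built_batch_is_sum_of_component_oracles(self, rng):
        ds = make_dataset(rng, n=3)
        m = tiny_model(negative_rule="all_pairs")
        theta = m.init_parameters(rng)
        Z1 = np.asarray(m.encode(theta, ds.views[0].values, 0))
        Z2 = np.asarray(m.encode(theta, ds.views[1].values, 1))
        h = m.risk_scores(theta, ds.view_values())
        cox = cox_loss_bruteforce(h, ds.times, ds.events, "geq")
        sim = similarity_loss(Z1, Z2, m.config.margin, "all_pairs")
        lb = m.loss(theta, ds.view_values(), ds.times, ds.events)
        assert lb.total == pytest.approx(cox + sim, abs=1e-8)

    @pytest.mark.parametrize("rule", ["all_pairs", "hardest", "one_random"])
    def test_backprop_matches_finite_differences(self, rule):
        rng = np.random.default_rng(21)
        for trial in range(5):
            ds = make_dataset(rng, n=8)
            m = tiny_model(negative_rule=rule)
            theta = m.init_parameters(rng)
            neg = m.sample_negatives(8, rng)
            val, grad = m.loss_value_and_grad(theta, ds.view_values(), ds.times,
                                              ds.events, neg_idx=neg)
            idx = rng.choice(len(theta), 25, replace=False)
            eps = 1e-6
            for i in idx:
                tp, tm = theta.copy(), theta.copy()
                tp[i] += eps
                tm[i] -= eps
                fp = m.loss(tp, ds.view_values(), ds.times, ds.events, neg_idx=neg).total
                fm = m.loss(tm, ds.view_values(), ds.times, ds.events, neg_idx=neg).total
                fd = (fp - fm) / (2 * eps)
                assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-7)


def test_parameters_flatten_and_restore_losslessly(rng):
    m = tiny_model()
    theta = m.init_parameters(rng)
    blocks = {name: np.asarray(m.spec.get(theta, name)) for name, _ in m.spec.entries}
    np.testing.assert_array_equal(m.spec.pack(blocks), theta)


def test_hidden_head_and_wider_highway_variants_run(rng):
    cfg = ModelConfig(
        encoders=[HighwayEncoderConfig(10, n_layers=2, embed_dim=6, hidden_dim=12),
                  HighwayEncoderConfig(6, n_layers=2, embed_dim=6, hidden_dim=12)],
        head_hidden_dim=4,
    )
    m = MultiOmicsSurvivalModel(cfg)
    theta = m.init_parameters(rng)
    ds = make_dataset(rng, n=6)
    val, grad = m.loss_value_and_grad(theta, ds.view_values(), ds.times, ds.events, rng=rng)
    assert np.isfinite(val) and np.all(np.isfinite(grad))
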