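import numpy as np
import pytest

from survfuse import (
    SimConfig,
    breslow_baseline,
    concordance_index,
    cox_neg_log_partial_likelihood,
    risk_score,
    simulate_cohort,
)
from survfuse.graph import fuse_graphs, knn_affinity, normalize_adjacency
from survfuse.network import (
    Network,
    TrainConfig,
    cox_loss_and_risk_gradient,
    get_variant,
    train_network,
)

from conftest import random_censored_outcome


def cox_loss_oracle(risk, time, event):
    """Direct summation of the negative partial log-likelihood, term by term."""
    total = 0.0
    n = len(risk)
    for i in range(n):
        if event[i]:
            denom = sum(np.exp(risk[j]) for j in range(n) if time[j] >= time[i])
            total += np.log(denom) - risk[i]
    return total


def breslow_oracle(risk, time, event):
    """Term-by-term Breslow cumulative hazard at each distinct event time."""
    times = sorted(set(t for t, e in zip(time, event) if e))
    cum, out = 0.0, []
    for tk in times:
        d_k = sum(1 for t, e in zip(time, event) if e and t == tk)
        denom = sum(np.exp(r) for r, t in zip(risk, time) if t >= tk)
        cum += d_k / denom
        out.append(cum)
    return np.array(times), np.array(out)


class TestCoxLoss:
    def test_single_event_is_zero(self):
        assert cox_neg_log_partial_likelihood(np.array([3.7]), np.array([2.0]), np.array([1])) == pytest.approx(0.0)

    def test_two_events_zero_risk(self):
        loss = cox_neg_log_partial_likelihood(
            np.zeros(2), np.array([1.0, 2.0]), np.array([1, 1])
        )
        assert loss == pytest.approx(np.log(2.0))

    def test_matches_term_by_term_oracle(self):
        risk = np.array([0.5, -0.2, 0.1])
        time = np.array([1.0, 2.0, 3.0])
        event = np.array([1, 0, 1])
        assert cox_neg_log_partial_likelihood(risk, time, event) == pytest.approx(
            cox_loss_oracle(risk, time, event)
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_random_instances_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 25))
        time, event = random_censored_outcome(rng, n)
        risk = rng.normal(size=n)
        assert cox_neg_log_partial_likelihood(risk, time, event) == pytest.approx(
            cox_loss_oracle(risk, time, event), rel=1e-10
        )

    def test_shift_invariance(self, rng):
        time, event = random_censored_outcome(rng, 30)
        risk = rng.normal(size=30)
        base = cox_neg_log_partial_likelihood(risk, time, event)
        shifted = cox_neg_log_partial_likelihood(risk + 123.456, time, event)
        assert shifted == pytest.approx(base, abs=1e-8)

    def test_analytic_gradient_vs_finite_differences(self, rng):
        n = 20
        time, event = random_censored_outcome(rng, n)
        risk = rng.normal(size=n)
        _, grad = cox_loss_and_risk_gradient(risk, time, event)
        eps = 1e-5
        for i in range(n):
            e_i = np.zeros(n)
            e_i[i] = eps
            fd = (
                cox_neg_log_partial_likelihood(risk + e_i, time, event)
                - cox_neg_log_partial_likelihood(risk - e_i, time, event)
            ) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_requires_an_event(self):
        with pytest.raises(ValueError):
            cox_neg_log_partial_likelihood(np.zeros(3), np.arange(3.0), np.zeros(3, int))

    def test_rejects_nonfinite_risk(self):
        with pytest.raises(ValueError):
            cox_neg_log_partial_likelihood(
                np.array([np.inf, 0.0]), np.array([1.0, 2.0]), np.array([1, 1])
            )


class TestRiskScore:
    def test_zero_beta(self, rng):
        np.testing.assert_allclose(risk_score(rng.normal(size=(5, 3)), np.zeros(3)), 0.0)

    def test_scalar_head(self):
        z = np.array([[1.0], [2.0]])
        np.testing.assert_allclose(risk_score(z, np.array([2.0])), [2.0, 4.0])

    def test_matches_dot_loop(self, rng):
        z = rng.normal(size=(6, 4))
        beta = rng.normal(size=4)
        scores = risk_score(z, beta)
        for i in range(6):
            assert scores[i] == pytest.approx(sum(z[i, j] * beta[j] for j in range(4)))

    def test_width_mismatch(self, rng):
        with pytest.raises(ValueError):
            risk_score(rng.normal(size=(3, 4)), np.zeros(5))


class TestBreslow:
    def test_zero_risk_reduces_to_nelson_aalen(self):
        n = 6
        time = np.arange(1.0, n + 1)
        event = np.ones(n, dtype=int)
        bh = breslow_baseline(np.zeros(n), time, event)
        expected = np.cumsum([1.0 / (n - k) for k in range(n)])
        np.testing.assert_allclose(bh.cumulative_hazard, expected)

    def test_single_event_first_jump(self):
        n = 5
        time = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 0, 0, 0, 0])
        bh = breslow_baseline(np.zeros(n), time, event)
        assert bh.cumulative_hazard[0] == pytest.approx(1.0 / n)

    def test_matches_term_by_term_oracle(self, rng):
        time, event = random_censored_outcome(rng, 6)
        risk = rng.normal(size=6)
        bh = breslow_baseline(risk, time, event)
        times, cum = breslow_oracle(risk, time, event)
        np.testing.assert_allclose(bh.event_times, times)
        np.testing.assert_allclose(bh.cumulative_hazard, cum, rtol=1e-10)

    def test_nondecreasing_and_zero_before_first_event(self, rng):
        time, event = random_censored_outcome(rng, 40)
        risk = rng.normal(size=40)
        bh = breslow_baseline(risk, time, event)
        assert np.all(np.diff(bh.cumulative_hazard) >= 0)
        assert bh.cumulative_at(bh.event_times[0] - 1e-9)[0] == 0.0


class TestNetworkWiring:
    def _toy(self, rng, n=20, p1=8, p2=6):
        X1 = rng.normal(size=(n, p1))
        X2 = rng.normal(size=(n, p2))
        a = normalize_adjacency(
            fuse_graphs([knn_affinity(X1, 4, 0.3), knn_affinity(X2, 4, 0.2)])
        ).a_hat
        return X1, X2, a

    def test_identity_graph_equals_no_graph_forward(self, rng):
        X1, X2, _ = self._toy(rng)
        net = Network("FULL", 8, 6, l=5, d=2, m=3, h1=4, h2=3, seed=0)
        r_eye, _ = net.forward(X1, X2, np.eye(20))
        r_none, _ = net.forward(X1, X2, None)
        np.testing.assert_allclose(r_eye, r_none, atol=1e-12)

    def test_fused_widths(self):
        full = Network("FULL", 8, 6, l=50, d=4, m=10, h1=4, h2=3, seed=0)
        no_fbm = Network("NO_FBM", 8, 6, l=50, d=4, m=10, h1=4, h2=3, seed=0)
        assert full.feature_width == 60
        assert no_fbm.feature_width == 50

    def test_high_ff_identical_to_no_graph(self, rng):
        X1, X2, _ = self._toy(rng)
        a = Network("HIGH_FF", 8, 6, l=5, d=2, m=3, h1=4, h2=3, seed=3)
        b = Network("NO_GRAPH", 8, 6, l=5, d=2, m=3, h1=4, h2=3, seed=3)
        ra, _ = a.forward(X1, X2, None)
        rb, _ = b.forward(X1, X2, None)
        np.testing.assert_allclose(ra, rb)

    def test_unknown_variant(self):
        with pytest.raises(ValueError, match="unknown variant"):
            get_variant("BOGUS")

    def test_head_matches_loop_oracle(self, rng):
        """sigmoid(tanh(A Z W1) W2) beta against an explicit index-loop."""
        X1, X2, a = self._toy(rng, n=7)
        net = Network("FULL", 8, 6, l=4, d=2, m=2, h1=3, h2=2, seed=1)
        risk, cache = net.forward(X1, X2, a)
        Z = cache["Z"]
        n, w = Z.shape
        W1, W2, beta = net.params["W1"], net.params["W2"], net.params["beta"]
        for i in range(n):
            s1 = [sum(a[i, q] * Z[q, c] for q in range(n)) for c in range(w)]
            h1 = [np.tanh(sum(s1[c] * W1[c, u] for c in range(w))) for u in range(W1.shape[1])]
            zh = [
                1.0 / (1.0 + np.exp(-sum(h1[u] * W2[u, v] for u in range(W1.shape[1]))))
                for v in range(W2.shape[1])
            ]
            assert risk[i] == pytest.approx(sum(zh[v] * beta[v] for v in range(len(beta))), abs=1e-6)

    def test_zero_w1_gives_half_activations(self, rng):
        X1, X2, a = self._toy(rng)
        net = Network("FULL", 8, 6, l=4, d=2, m=2, h1=3, h2=2, seed=1)
        net.params["W1"][:] = 0.0
        net.params["W2"][:] = 0.0
        _, cache = net.forward(X1, X2, a)
        np.testing.assert_allclose(cache["Zh"], 0.5)

    def test_full_gradient_against_finite_differences(self, rng):
        X1, X2, a = self._toy(rng)
        time, event = random_censored_outcome(rng, 20)
        net = Network("FULL", 8, 6, l=4, d=2, m=3, h1=3, h2=2, seed=5)
        risk, cache = net.forward(X1, X2, a)
        _, g_risk = cox_loss_and_risk_gradient(risk, time, event)
        grads = net.backward(g_risk, cache)
        eps = 1e-6
        for name, P in net.params.items():
            idx = tuple(rng.integers(s) for s in P.shape)
            old = P[idx]
            P[idx] = old + eps
            up = cox_neg_log_partial_likelihood(net.forward(X1, X2, a)[0], time, event)
            P[idx] = old - eps
            dn = cox_neg_log_partial_likelihood(net.forward(X1, X2, a)[0], time, event)
            P[idx] = old
            fd = (up - dn) / (2 * eps)
            assert grads[name][idx] == pytest.approx(fd, rel=1e-3, abs=1e-7), name


class TestTraining:
    def _setup(self, rng, n=30):
        X1 = rng.normal(size=(n, 10))
        X2 = rng.normal(size=(n, 6))
        a = normalize_adjacency(
            fuse_graphs([knn_affinity(X1, 4, 0.3), knn_affinity(X2, 4, 0.2)])
        ).a_hat
        time, event = random_censored_outcome(rng, n)
        return X1, X2, a, time, event

    def test_zero_learning_rate_freezes_parameters(self, rng):
        X1, X2, a, time, event = self._setup(rng)
        net = Network("FULL", 10, 6, l=4, d=2, m=2, h1=3, h2=2, seed=0)
        before = {k: v.copy() for k, v in net.params.items()}
        _, losses = train_network(
            net, X1, X2, a, time, event, np.arange(30),
            TrainConfig(learning_rate=0.0, max_epochs=30, patience=5),
        )
        for k in before:
            np.testing.assert_array_equal(net.params[k], before[k])
        assert np.allclose(losses, losses[0])

    def test_same_seed_is_bitwise_deterministic(self, rng):
        X1, X2, a, time, event = self._setup(rng)
        results = []
        for _ in range(2):
            net = Network("FULL", 10, 6, l=4, d=2, m=2, h1=3, h2=2, seed=9)
            risk, losses = train_network(
                net, X1, X2, a, time, event, np.arange(30),
                TrainConfig(learning_rate=1e-3, max_epochs=40),
            )
            results.append((risk, losses[-1]))
        np.testing.assert_array_equal(results[0][0], results[1][0])
        assert results[0][1] == results[1][1]

    def test_loss_nonincreasing_for_small_learning_rate(self, rng):
        X1, X2, a, time, event = self._setup(rng)
        net = Network("FULL", 10, 6, l=4, d=2, m=2, h1=3, h2=2, seed=2)
        _, losses = train_network(
            net, X1, X2, a, time, event, np.arange(30),
            TrainConfig(learning_rate=1e-4, max_epochs=200),
        )
        increases = sum(b > a + 1e-9 for a, b in zip(losses, losses[1:]))
        assert increases <= max(1, int(0.01 * len(losses)))

    def test_requires_training_event(self, rng):
        X1, X2, a, time, event = self._setup(rng)
        event[:] = 0
        net = Network("FULL", 10, 6, l=4, d=2, m=2, h1=3, h2=2, seed=0)
        with pytest.raises(ValueError):
            train_network(net, X1, X2, a, time, event, np.arange(30), TrainConfig())

    def test_strong_signal_training_fit(self):
        """On a strong additive-signal cohort the model should nearly sort
        the training samples by hazard (C-index > 0.9 at convergence)."""
        ds, _ = simulate_cohort(
            SimConfig(n_samples=300, beta_additive=2.0, beta_cross=1.0,
                      target_censoring=0.4, seed=11)
        )
        from survfuse import GraphFusionSurvival

        model = GraphFusionSurvival(variant="FULL", random_state=0, max_epochs=900)
        model.fit(ds, ds.outcome)
        assert concordance_index(model.risk_scores_, ds.outcome) > 0.9
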