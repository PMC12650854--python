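import itertools

import numpy as np
import pytest

from lpbn import core, estimators
from lpbn.core import OperatorSet, SelectorPolicy, StructureSample
from lpbn.estimators import (
    BaselineState,
    EntropySchedule,
    anneal,
    clip_grad_norm,
    clip_values,
    ema_update,
    entropy,
    entropy_grad,
    gumbel_softmax_sample,
    optimal_constant_baseline,
    rao_blackwell_grad,
    score_function_grad,
    straight_through_grad,
)


def _enumerate_structures(pol):
    """All (structure, probability) pairs of a small policy."""
    pa = core.selector_probs(pol.a_logits)
    pb = core.selector_probs(pol.b_logits)
    po = core.selector_probs(pol.o_logits)
    per_unit = list(
        itertools.product(range(pol.m), range(pol.m), range(pol.n_ops))
    )
    for combo in itertools.product(per_unit, repeat=pol.N):
        s = StructureSample(
            np.array([c[0] for c in combo]),
            np.array([c[1] for c in combo]),
            np.array([c[2] for c in combo]),
        )
        prob = 1.0
        for n, (a, b, o) in enumerate(combo):
            prob *= pa[n, a] * pb[n, b] * po[n, o]
        yield s, prob


def _exact_grad(pol, F_of, baseline=0.0):
    """Exact ascent gradient of E[F] by full enumeration."""
    total = None
    for s, prob in _enumerate_structures(pol):
        g = score_function_grad(pol, s, F_of(s), baseline)
        total = g.scaled(prob) if total is None else total + g.scaled(prob)
    return total


class TestScoreFunctionGrad:
    def test_expected_gradient_on_operator_indicator(self):
        """F = 1{O = XOR} on a uniform 4-way operator selector: the exact
        expected gradient of the XOR logit is 0.25*0.75 and of the AND
        logit is -0.0625 (enumeration over the 4 outcomes)."""
        pol = SelectorPolicy.uniform(1, 1)  # A and B slots are degenerate
        g = _exact_grad(pol, lambda s: float(s.O[0] == 2))
        assert g.o[0, 2] == pytest.approx(0.25 * 0.75)
        assert g.o[0, 0] == pytest.approx(-0.0625)

    def test_constant_feedback_has_zero_mean_gradient(self):
        pol = SelectorPolicy(
            np.array([[0.4, -0.1, 0.2]]),
            np.array([[0.0, 0.7, -0.5]]),
            np.array([[0.1, 0.0, -0.2, 0.3]]),
        )
        for b in (0.0, 1.7):
            g = _exact_grad(pol, lambda s: 3.0, baseline=b)
            assert np.allclose(g.a, 0, atol=1e-12)
            assert np.allclose(g.b, 0, atol=1e-12)
            assert np.allclose(g.o, 0, atol=1e-12)

    def test_non_finite_feedback_rejected(self):
        pol = SelectorPolicy.uniform(1, 2)
        s = StructureSample(np.array([0]), np.array([0]), np.array([0]))
        with pytest.raises(ValueError):
            score_function_grad(pol, s, np.nan)

    def test_monte_carlo_unbiased_for_any_baseline(self, rng):
        """MC mean over 1e5 samples matches the enumerated exact gradient of
        E[F] within 3 standard errors, for b = 0 and b = an EMA-like value."""
        pol = SelectorPolicy(
            rng.standard_normal((2, 3)) * 0.5,
            rng.standard_normal((2, 3)) * 0.5,
            rng.standard_normal((2, 4)) * 0.5,
        )

        def F_of(s):
            # an arbitrary structure-dependent feedback
            return float(s.A[0] + 2.0 * (s.O[1] == 3) - 0.5 * s.B[1])

        exact = _exact_grad(pol, F_of)
        n = 100_000
        for b in (0.0, 0.8):
            samples = core.sample_structures_batch(pol, n, rng)
            F = (
                samples.A[:, 0]
                + 2.0 * (samples.O[:, 1] == 3)
                - 0.5 * samples.B[:, 1]
            ).astype(float)
            mc = estimators.batch_score_function_grad(pol, samples, F, b)
            # per-entry standard error from a single-sample pilot variance
            pilot = np.stack(
                [
                    score_function_grad(
                        pol,
                        StructureSample(
                            samples.A[i], samples.B[i], samples.O[i]
                        ),
                        F[i],
                        b,
                    ).flat()
                    for i in range(2000)
                ]
            )
            se = pilot.std(axis=0) / np.sqrt(n)
            assert np.all(np.abs(mc.flat() - exact.flat()) <= 3 * se + 1e-4)

    def test_baseline_invariance_of_exact_gradient(self, rng):
        pol = SelectorPolicy(
            rng.standard_normal((1, 3)),
            rng.standard_normal((1, 3)),
            rng.standard_normal((1, 4)),
        )
        F_of = lambda s: float(s.A[0] * 2 - s.O[0])
        g0 = _exact_grad(pol, F_of, baseline=0.0)
        g1 = _exact_grad(pol, F_of, baseline=1.234)
        assert np.allclose(g0.flat(), g1.flat(), atol=1e-10)


class TestBaselines:
    def test_ema_arithmetic(self):
        state = BaselineState(0.0, 0.95, initialized=True)
        assert ema_update(state, 1.0).b == pytest.approx(0.05)

    def test_ema_fixed_point(self):
        state = BaselineState(2.5, 0.95, initialized=True)
        assert ema_update(state, 2.5).b == pytest.approx(2.5)

    def test_ema_initializes_to_first_feedback(self):
        state = BaselineState(ema_decay=0.9)
        assert ema_update(state, 7.0).b == pytest.approx(7.0)

    def test_ema_converges_geometrically(self):
        state = BaselineState(ema_decay=0.9)
        for _ in range(200):
            state = ema_update(state, 3.0)
        assert state.b == pytest.approx(3.0)

    def test_decay_range_enforced(self):
        with pytest.raises(ValueError):
            BaselineState(ema_decay=0.5)

    def test_constant_feedback_optimal_baseline(self):
        assert optimal_constant_baseline([2.0] * 5, [1.0, 2, 3, 4, 5]) == 2.0

    def test_independent_feedback_gives_mean(self, rng):
        F = rng.standard_normal(200_000) + 1.5
        s = rng.uniform(0.5, 2.0, size=200_000)  # independent of F
        assert optimal_constant_baseline(F, s) == pytest.approx(1.5, abs=0.02)

    def test_all_zero_norms_rejected(self):
        with pytest.raises(ValueError):
            optimal_constant_baseline([1.0, 2.0], [0.0, 0.0])

    def test_optimal_baseline_minimizes_second_moment(self, rng):
        """Grid oracle: on a tiny enumerable policy, b* from the closed form
        minimizes E[(F-b)^2 ||score||^2] over a fine grid of b values."""
        pol = SelectorPolicy(
            rng.standard_normal((1, 2)),
            rng.standard_normal((1, 2)),
            rng.standard_normal((1, 4)),
        )
        F_of = lambda s: float(3 * s.A[0] + s.O[0] ** 2)
        probs, Fs, norms = [], [], []
        for s, prob in _enumerate_structures(pol):
            g = score_function_grad(pol, s, 1.0, 0.0)  # score vector itself
            probs.append(prob)
            Fs.append(F_of(s))
            norms.append(float((g.flat() ** 2).sum()))
        probs, Fs, norms = map(np.asarray, (probs, Fs, norms))
        b_star = (Fs * norms * probs).sum() / (norms * probs).sum()
        grid = np.linspace(Fs.min() - 1, Fs.max() + 1, 401)
        second_moment = [
            ((Fs - b) ** 2 * norms * probs).sum() for b in grid
        ]
        b_grid = grid[int(np.argmin(second_moment))]
        assert b_star == pytest.approx(b_grid, abs=grid[1] - grid[0])
        # and the closed-form helper agrees when fed enumeration as samples
        reps = (probs * 1e6).astype(int)
        helper = optimal_constant_baseline(
            np.repeat(Fs, reps), np.repeat(norms, reps)
        )
        assert helper == pytest.approx(b_star, abs=1e-3)


class TestEntropy:
    def test_uniform_entropy(self):
        assert entropy(np.full(4, 0.25)) == pytest.approx(np.log(4))

    def test_one_hot_entropy_zero(self):
        assert entropy(np.array([0.0, 1.0, 0.0])) == 0.0

    def test_uniform_maximizes(self, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(5))
            assert entropy(p) <= np.log(5) + 1e-12

    def test_gradient_zero_at_uniform(self):
        assert np.allclose(entropy_grad(np.zeros(6)), 0.0, atol=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        logits = rng.standard_normal(5)
        g = entropy_grad(logits)
        eps = 1e-6
        for i in range(5):
            up, dn = logits.copy(), logits.copy()
            up[i] += eps
            dn[i] -= eps
            fd = (
                entropy(core.selector_probs(up))
                - entropy(core.selector_probs(dn))
            ) / (2 * eps)
            assert g[i] == pytest.approx(fd, abs=1e-6)

    def test_gradient_pushes_concentrated_logits_toward_uniform(self):
        logits = np.array([4.0, 0.0, 0.0])
        g = entropy_grad(logits)
        assert g[0] < 0 and g[1] > 0 and g[2] > 0

    def test_entropy_regularized_flow_reaches_uniform(self):
        """With F = 0 and lambda > 0, gradient flow on the entropy bonus
        alone drives concentrated logits back to the uniform simplex."""
        logits = np.array([3.0, -1.0, 0.5, 0.0])
        for _ in range(3000):
            logits = logits + 0.05 * entropy_grad(logits)
        assert np.allclose(core.selector_probs(logits), 0.25, atol=1e-4)


class TestAnneal:
    def test_profile(self):
        sched = EntropySchedule(1e-3, 100)
        assert anneal(sched, 0) == pytest.approx(1e-3)
        assert anneal(sched, 50) == 0.0
        assert anneal(sched, 100) == 0.0
        assert anneal(sched, 25) == pytest.approx(5e-4)


class TestGumbelSoftmax:
    def test_zero_temperature_limit_is_argmax(self, rng):
        logits = rng.standard_normal(5)
        noise = rng.gumbel(size=5)
        relaxed = gumbel_softmax_sample(logits, 1e-8, noise)
        assert np.argmax(relaxed) == np.argmax(logits + noise)
        assert relaxed.max() == pytest.approx(1.0)

    def test_uniform_logits_zero_noise_uniform_output(self):
        for tau in (0.1, 1.0, 10.0):
            out = gumbel_softmax_sample(np.zeros(4), tau, np.zeros(4))
            assert np.allclose(out, 0.25)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            gumbel_softmax_sample(np.zeros(3), 0.0, np.zeros(3))

    def test_gumbel_max_recovers_categorical(self, rng):
        logits = np.array([0.2, -0.4, 1.0])
        p = core.selector_probs(logits)
        n = 100_000
        noise = rng.gumbel(size=(n, 3))
        hard = np.argmax(logits + noise, axis=1)
        for k in range(3):
            se = np.sqrt(p[k] * (1 - p[k]) / n)
            assert abs((hard == k).mean() - p[k]) < 3 * se + 1e-12


class TestRaoBlackwell:
    def _toy_policy(self, rng):
        return SelectorPolicy(
            rng.standard_normal((2, 2)) * 0.3,
            rng.standard_normal((2, 2)) * 0.3,
            rng.standard_normal((2, 4)) * 0.3,
        )

    @staticmethod
    def _F(s):
        return float(s.A[0] + s.B[1] + (s.O[0] == 1) * 2.0 - (s.O[1] == 3))

    def _conditional_tables(self, pol, unit, fixed):
        """E[F | one slot of `unit`], holding other units at `fixed` and
        marginalizing the unit's remaining slots exactly."""
        pa = core.selector_probs(pol.a_logits)
        pb = core.selector_probs(pol.b_logits)
        po = core.selector_probs(pol.o_logits)

        def cond_exact(slot, value):
            total = 0.0
            slots = {"a": range(pol.m), "b": range(pol.m), "o": range(pol.n_ops)}
            others = [k for k in ("a", "b", "o") if k != slot]
            for v1 in slots[others[0]]:
                for v2 in slots[others[1]]:
                    choice = {slot: value, others[0]: v1, others[1]: v2}
                    prob = 1.0
                    marg = {"a": pa, "b": pb, "o": po}
                    for k in others:
                        prob *= marg[k][unit, choice[k]]
                    s = StructureSample(
                        fixed.A.copy(), fixed.B.copy(), fixed.O.copy()
                    )
                    s.A[unit] = choice["a"]
                    s.B[unit] = choice["b"]
                    s.O[unit] = choice["o"]
                    total += prob * self._F(s)
            return total

        return {
            "a": np.array([cond_exact("a", i) for i in range(pol.m)]),
            "b": np.array([cond_exact("b", i) for i in range(pol.m)]),
            "o": np.array([cond_exact("o", i) for i in range(pol.n_ops)]),
        }

    def test_constant_table_gives_zero_gradient(self, rng):
        pol = self._toy_policy(rng)
        tables = {"a": np.full(2, 1.3), "b": np.full(2, 1.3), "o": np.full(4, 1.3)}
        g = rao_blackwell_grad(pol, 0, tables, baseline=0.0)
        assert np.allclose(g.flat(), 0.0, atol=1e-12)

    def test_table_size_mismatch_rejected(self, rng):
        pol = self._toy_policy(rng)
        with pytest.raises(ValueError):
            rao_blackwell_grad(
                pol, 0, {"a": np.zeros(3), "b": np.zeros(2), "o": np.zeros(4)}
            )

    def test_rb_matches_exact_gradient_and_lowers_variance(self, rng):
        """On an enumerable 2-unit toy: the RB estimate for unit 0 averaged
        over draws of the other unit equals the enumerated exact gradient,
        and its empirical variance is no larger than raw REINFORCE's (law
        of total variance)."""
        pol = self._toy_policy(rng)
        exact = _exact_grad(pol, self._F)
        unit = 0
        n = 10_000
        rb_draws = np.empty((n, pol.m * 2 + pol.n_ops))
        raw_draws = np.empty_like(rb_draws)
        for i in range(n):
            s = core.sample_structure(pol, rng)
            tables = self._conditional_tables(pol, unit, s)
            g_rb = rao_blackwell_grad(pol, unit, tables, baseline=0.0)
            rb_draws[i] = np.concatenate(
                [g_rb.a[unit], g_rb.b[unit], g_rb.o[unit]]
            )
            g_raw = score_function_grad(pol, s, self._F(s), 0.0)
            raw_draws[i] = np.concatenate(
                [g_raw.a[unit], g_raw.b[unit], g_raw.o[unit]]
            )
        exact_unit = np.concatenate(
            [exact.a[unit], exact.b[unit], exact.o[unit]]
        )
        se_rb = rb_draws.std(axis=0) / np.sqrt(n)
        se_raw = raw_draws.std(axis=0) / np.sqrt(n)
        assert np.all(np.abs(rb_draws.mean(0) - exact_unit) <= 3 * se_rb + 1e-4)
        assert np.all(np.abs(raw_draws.mean(0) - exact_unit) <= 3 * se_raw + 1e-4)
        assert rb_draws.var(axis=0).sum() <= raw_draws.var(axis=0).sum() + 1e-9


class TestStraightThroughAndClipping:
    def test_zero_upstream_gives_zero(self):
        assert straight_through_grad(1, 0.7, 0.0) == 0.0

    def test_identity_within_clip_range(self):
        assert straight_through_grad(0, 0.4, 0.35) == pytest.approx(0.35)

    def test_saturated_upstream_clipped_to_unit_magnitude(self):
        assert straight_through_grad(1, 0.99, 4.2) == 1.0
        assert straight_through_grad(0, 0.01, -4.2) == -1.0

    def test_surrogate_outside_open_interval_rejected(self):
        with pytest.raises(ValueError):
            straight_through_grad(1, 1.0, 0.5)

    def test_advantage_clipping(self):
        assert clip_values(np.array([7.0]))[0] == 5.0
        assert clip_values(np.array([-9.0]))[0] == -5.0
        assert clip_values(np.array([3.0]))[0] == 3.0

    def test_gradient_norm_rescaling(self):
        v = np.zeros(9)
        v[0] = 3.0
        assert np.array_equal(clip_grad_norm(v, 5.0), v)
        v[0] = 10.0
        assert np.linalg.norm(clip_grad_norm(v, 5.0)) == pytest.approx(5.0)
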