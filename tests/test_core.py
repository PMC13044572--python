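"""Arm-level probability model and marginalized likelihood.

The independent oracle used throughout is brute-force enumeration of all
five-part multinomial outcomes, mapped to the aggregate triple
(y, z, m) = (w1+w2+w3, w1+w3+w5, w1).
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from aemeta.core import (
    ArmAggregate,
    ArmRates,
    CategoryProbabilities,
    InconsistentDataError,
    arm_log_likelihood,
    category_probabilities,
    feasible_w3_range,
    latent_counts,
)


def brute_force_log_likelihood(n, y, z, m, p):
    """Enumerate all w-compositions of n consistent with (y, z, m)."""
    p = np.asarray(p, dtype=float)
    total = 0.0
    for w in itertools.product(range(n + 1), repeat=4):
        w1, w2, w3, w5 = w
        w4 = n - w1 - w2 - w3 - w5
        if w4 < 0:
            continue
        if (w1 + w2 + w3, w1 + w3 + w5, w1) != (y, z, m):
            continue
        logc = gammaln(n + 1) - sum(gammaln(k + 1) for k in (w1, w2, w3, w4, w5))
        logp = sum(k * math.log(pk) if k else 0.0
                   for k, pk in zip((w1, w2, w3, w4, w5), p) if pk > 0 or k == 0)
        if any(k > 0 and pk == 0 for k, pk in zip((w1, w2, w3, w4, w5), p)):
            continue
        total += math.exp(logc + logp)
    return math.log(total) if total > 0 else -math.inf


def mk_arm(n, y, z, m, tau=1.0, trial="t", arm=0):
    return ArmAggregate(trial, arm, n, y, z, m, tau)


class TestCategoryProbabilities:
    def test_no_events_limit(self):
        # lam -> 0: only administrative censoring or drop-out remain
        p = category_probabilities(ArmRates(1e-12, 0.5, 0.3, 2.0))
        expected = np.array([0.0, 0.0, 0.0, math.exp(-1.0), 1 - math.exp(-1.0)])
        np.testing.assert_allclose(p.as_array(), expected, atol=1e-10)

    def test_no_dropout_no_fatality_limit(self):
        p = category_probabilities(ArmRates(0.5, 1e-12, 0.0, 2.0))
        expected = np.array([0.0, 1 - math.exp(-1.0), 0.0, math.exp(-1.0), 0.0])
        np.testing.assert_allclose(p.as_array(), expected, atol=1e-10)

    def test_monte_carlo_oracle(self, rng):
        # simulate patient timelines directly from the generative story
        lam, mu, q, tau = 0.5, 0.5, 0.35, 1.0
        n = 10**6
        x = rng.exponential(1 / lam, n)
        c = rng.exponential(1 / mu, n)
        fatal = rng.random(n) < q
        event = (x <= tau) & (x <= c)
        cats = np.select(
            [event & fatal, event & ~fatal & (c > tau), event & ~fatal & (c <= tau),
             (~event) & (c <= tau) & (c < x)],
            [1, 2, 3, 5], default=4)
        freq = np.bincount(cats, minlength=6)[1:] / n
        p = category_probabilities(ArmRates(lam, mu, q, tau)).as_array()
        se = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(freq - p) < 4 * se + 1e-12)

    @pytest.mark.parametrize("lam,mu,q,tau", [
        (0.5, 0.5, 0.35, 1.0),
        (0.01, 2.0, 0.9, 10.0),
        (3.0, 0.02, 0.0, 0.3),
        (1e-7, 1e-7, 0.5, 1.0),
        (50.0, 50.0, 1.0, 5.0),
    ])
    def test_normalization(self, lam, mu, q, tau):
        p = category_probabilities(ArmRates(lam, mu, q, tau)).as_array()
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p >= 0)

    def test_long_followup_limits(self):
        # tau -> inf: no administrative censoring; the event races drop-out
        p = category_probabilities(ArmRates(1.0, 1.0, 0.3, 1e4))
        assert p.p4 < 1e-8
        assert abs((p.p1 + p.p3) - 0.5) < 1e-8
        assert abs(p.p5 - 0.5) < 1e-8

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            ArmRates(0.0, 0.5, 0.1, 1.0)
        with pytest.raises(ValueError):
            ArmRates(0.5, -1.0, 0.1, 1.0)
        with pytest.raises(ValueError):
            ArmRates(0.5, 0.5, 1.5, 1.0)
        with pytest.raises(ValueError):
            ArmRates(0.5, 0.5, 0.1, 0.0)


class TestFeasibleRange:
    def test_published_example_row(self):
        # treatment arm of the first packaged oncology trial
        assert feasible_w3_range(mk_arm(400, 5, 65, 0, tau=30.0)) == (0, 5)

    def test_all_events_fatal_forces_zero(self):
        assert feasible_w3_range(mk_arm(10, 2, 2, 2)) == (0, 0)

    def test_tight_lower_bound(self):
        # brute-force enumeration over all w-vectors with n=4 gives w3 in {2, 3}
        arm = mk_arm(4, 3, 3, 0)
        assert feasible_w3_range(arm) == (2, 3)
        feasible = set()
        for w in itertools.product(range(5), repeat=4):
            w1, w2, w3, w5 = w
            w4 = 4 - sum(w)
            if w4 >= 0 and (w1 + w2 + w3, w1 + w3 + w5, w1) == (3, 3, 0):
                feasible.add(w3)
        assert feasible == {2, 3}

    def test_inconsistent_row_rejected_with_row_identity(self):
        with pytest.raises(InconsistentDataError, match="trial 'bad'"):
            ArmAggregate("bad", 0, n=4, y=4, z=0, m=1, tau=1.0)

    def test_fatal_exceeding_discontinuations_rejected(self):
        # fatal events count as discontinuations, so m > z is malformed
        with pytest.raises(InconsistentDataError):
            ArmAggregate("t", 0, n=10, y=5, z=1, m=2, tau=1.0)


class TestLatentCounts:
    def test_reconstruction_example(self):
        w = latent_counts(mk_arm(400, 5, 65, 0), 0)
        assert (w.w1, w.w2, w.w3, w.w4, w.w5) == (0, 5, 0, 330, 65)
        assert w.n == 400

    def test_empty_counts(self):
        w = latent_counts(mk_arm(10, 0, 0, 0), 0)
        assert (w.w1, w.w2, w.w3, w.w4, w.w5) == (0, 0, 0, 10, 0)

    def test_upper_end_of_range(self):
        w = latent_counts(mk_arm(4, 3, 3, 0), 3)
        assert (w.w1, w.w2, w.w3, w.w4, w.w5) == (0, 0, 3, 1, 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside feasible range"):
            latent_counts(mk_arm(4, 3, 3, 0), 1)

    @given(st.integers(0, 12), st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_roundtrip_over_feasible_range(self, n, data):
        y = data.draw(st.integers(0, n))
        z = data.draw(st.integers(0, n))
        m = data.draw(st.integers(0, min(y, z)))
        r1 = max(0, y + z - m - n)
        r2 = min(y - m, z - m)
        if r1 > r2:
            with pytest.raises(InconsistentDataError):
                mk_arm(n, y, z, m)
            return
        arm = mk_arm(n, y, z, m)
        for w3 in range(r1, r2 + 1):
            w = latent_counts(arm, w3)
            assert w.as_array().min() >= 0
            assert w.n == n and w.y == y and w.z == z and w.m == m


class TestArmLogLikelihood:
    P = CategoryProbabilities(0.1, 0.2, 0.1, 0.5, 0.1)

    def test_empty_arm(self):
        assert arm_log_likelihood(mk_arm(0, 0, 0, 0), self.P) == 0.0

    def test_single_term_closed_form(self):
        ll = arm_log_likelihood(mk_arm(7, 0, 0, 0), self.P)
        assert ll == pytest.approx(7 * math.log(0.5), abs=1e-12)

    def test_brute_force_oracle_example(self):
        ll = arm_log_likelihood(mk_arm(3, 1, 1, 0), self.P)
        assert ll == pytest.approx(
            brute_force_log_likelihood(3, 1, 1, 0, self.P.as_array()), abs=1e-10)

    @pytest.mark.parametrize("probs", [
        (0.1, 0.2, 0.1, 0.5, 0.1),
        (0.02, 0.5, 0.03, 0.05, 0.4),
        (0.3, 0.05, 0.25, 0.3, 0.1),
    ])
    def test_brute_force_oracle_all_small_arms(self, probs):
        p = CategoryProbabilities(*probs)
        for n in range(1, 9):
            for y in range(n + 1):
                for z in range(n + 1):
                    for m in range(min(y, z) + 1):
                        if max(0, y + z - m - n) > min(y - m, z - m):
                            continue
                        arm = mk_arm(n, y, z, m)
                        expect = brute_force_log_likelihood(n, y, z, m, p.as_array())
                        got = arm_log_likelihood(arm, p)
                        assert got == pytest.approx(expect, abs=1e-10)

    @pytest.mark.parametrize("probs", [
        (0.1, 0.2, 0.1, 0.5, 0.1),
        (0.02, 0.5, 0.03, 0.05, 0.4),
    ])
    def test_total_probability_one(self, probs):
        # every multinomial outcome maps to exactly one aggregate triple
        p = CategoryProbabilities(*probs)
        for n in range(0, 7):
            total = 0.0
            for y in range(n + 1):
                for z in range(n + 1):
                    for m in range(min(y, z) + 1):
                        if max(0, y + z - m - n) > min(y - m, z - m):
                            continue
                        total += math.exp(arm_log_likelihood(mk_arm(n, y, z, m), p))
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_impossible_data_gives_neg_inf_not_exception(self):
        # fatal events observed but the fatal category has zero probability
        p = CategoryProbabilities(0.0, 0.3, 0.1, 0.5, 0.1)
        assert arm_log_likelihood(mk_arm(5, 2, 2, 1), p) == -math.inf

    def test_value_is_log_probability(self):
        assert arm_log_likelihood(mk_arm(50, 10, 20, 2), self.P) <= 0.0
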