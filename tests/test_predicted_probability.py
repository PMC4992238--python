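"""Closed-form joint probabilities, observed probabilities and scans."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from activitycanyon import (
    ModelConstants,
    RangeQuery,
    observed_prob,
    predicted_prob_cd,
    predicted_prob_cs,
    rmse,
    scale_predictions,
    scan_thresholds,
)
from activitycanyon import EnsembleSpec, sample_pair_weights
from activitycanyon.errors import OutOfSupportError


def quadrature_joint(k: ModelConstants, q: RangeQuery) -> float:
    """Independent oracle: numerically integrate the marginal densities."""
    pc = quad(k.pdf_c, q.c1, q.c2, epsabs=1e-13, epsrel=1e-13)[0]
    if q.measure == "s":
        pm = quad(k.pdf_s, q.lo, q.hi, epsabs=1e-13, epsrel=1e-13)[0]
    else:
        pm = quad(k.pdf_d, q.lo, q.hi, epsabs=1e-13, epsrel=1e-13)[0]
    return pc * pm


def random_query(rng, k: ModelConstants, measure: str) -> RangeQuery:
    c1 = k.c_min * math.exp(rng.uniform(0, 5))
    c2 = c1 * math.exp(rng.uniform(0.1, 3))
    if measure == "s":
        lo = k.s_min * math.exp(rng.uniform(0, 3))
        hi = lo * math.exp(rng.uniform(0.1, 2))
    else:
        lo = k.d_min + rng.uniform(0, 25)
        hi = lo + rng.uniform(0.5, 40)
    return RangeQuery(c1, c2, lo, hi, measure)


class TestClosedForms:
    @pytest.mark.parametrize("mode", ["normalized", "paper_constants"])
    def test_agreement_with_quadrature_oracle(self, mode, rng):
        k = ModelConstants(mode=mode)
        for _ in range(60):
            for measure, fn in (("s", predicted_prob_cs), ("d", predicted_prob_cd)):
                q = random_query(rng, k, measure)
                assert fn(k, q) == pytest.approx(quadrature_joint(k, q), abs=1e-8)

    def test_zero_width_band_gives_zero(self):
        k = ModelConstants()
        q = RangeQuery(0.3, 0.6, 2.0, 2.0, "s")
        assert predicted_prob_cs(k, q) == pytest.approx(0.0, abs=1e-15)

    def test_normalized_full_range_is_one(self):
        k = ModelConstants(mode="normalized")
        qs = RangeQuery(k.c_min, math.inf, k.s_min, math.inf, "s")
        qd = RangeQuery(k.c_min, math.inf, k.d_min, math.inf, "d")
        assert predicted_prob_cs(k, qs) == pytest.approx(1.0)
        assert predicted_prob_cd(k, qd) == pytest.approx(1.0)

    def test_historical_prefactor_full_range_d(self):
        # literal evaluation with lambda = 0.17 gives 0.042 / 0.17
        k = ModelConstants(mode="paper_constants")
        q = RangeQuery(k.c_min, math.inf, 0.0, math.inf, "d")
        assert predicted_prob_cd(k, q) == pytest.approx(0.042 / 0.17, rel=1e-12)

    def test_strictly_decreasing_in_lower_d_bound(self):
        k = ModelConstants()
        vals = [
            predicted_prob_cd(k, RangeQuery(0.3, 0.8, d1, math.inf, "d"))
            for d1 in (0.0, 2.0, 5.0, 11.0)
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_independence_factorization_in_normalized_mode(self, rng):
        k = ModelConstants(mode="normalized")
        for _ in range(20):
            q = random_query(rng, k, "d")
            joint = predicted_prob_cd(k, q)
            c_only = predicted_prob_cd(k, RangeQuery(q.c1, q.c2, k.d_min, math.inf, "d"))
            m_only = predicted_prob_cd(k, RangeQuery(k.c_min, math.inf, q.lo, q.hi, "d"))
            assert joint == pytest.approx(c_only * m_only, rel=1e-10)

    def test_axis_additivity(self, rng):
        k = ModelConstants()
        for _ in range(20):
            a = k.c_min * math.exp(rng.uniform(0, 2))
            b = a * math.exp(rng.uniform(0.1, 1))
            c = b * math.exp(rng.uniform(0.1, 1))
            left = predicted_prob_cs(k, RangeQuery(a, b, 1.0, 5.0, "s"))
            right = predicted_prob_cs(k, RangeQuery(b, c, 1.0, 5.0, "s"))
            whole = predicted_prob_cs(k, RangeQuery(a, c, 1.0, 5.0, "s"))
            assert left + right == pytest.approx(whole, rel=1e-10)

    def test_below_support_rejected(self):
        k = ModelConstants()
        with pytest.raises(OutOfSupportError):
            predicted_prob_cs(k, RangeQuery(0.001, 0.5, 1.0, 2.0, "s"))
        with pytest.raises(OutOfSupportError):
            predicted_prob_cs(k, RangeQuery(0.3, 0.5, 0.5, 2.0, "s"))

    def test_monte_carlo_joint_frequencies(self):
        # 1e6 independent (c, d) draws from the normalized marginals
        k = ModelConstants(mode="normalized")
        n = 1_000_000
        rng = np.random.default_rng(2024)
        u = rng.random(n)
        c = k.c_min * u ** (1.0 / (1.0 - k.gamma))  # unbounded Pareto
        d = rng.exponential(1.0 / k.lambda_, size=n) + k.d_min
        qrng = np.random.default_rng(5)
        for _ in range(12):
            q = random_query(qrng, k, "d")
            p = predicted_prob_cd(k, q)
            freq = np.mean((c >= q.c1) & (c <= q.c2) & (d >= q.lo) & (d <= q.hi))
            se = math.sqrt(p * (1 - p) / n)
            assert abs(freq - p) <= 3 * se + 1e-12


class TestObservedProb:
    def test_full_range_is_one(self, toy_pairs):
        q = RangeQuery(0.0, 1.0, 0.0, math.inf, "d")
        assert observed_prob(toy_pairs, q) == 1.0

    def test_empty_intersection_is_zero(self, toy_pairs):
        q = RangeQuery(0.9, 1.0, 100.0, math.inf, "d")
        assert observed_prob(toy_pairs, q) == 0.0

    def test_joint_count_matches_hand_scan(self, toy_pairs, toy_expected):
        # c >= 0.3 and d >= 3: hand scan of the expected table
        hand = toy_expected[(toy_expected["c"] >= 0.3) & (toy_expected["d"] >= 3)]
        q = RangeQuery(0.3, 1.0, 3.0, math.inf, "d")
        assert observed_prob(toy_pairs, q) == pytest.approx(len(hand) / 15)

    def test_conditional_denominator(self, toy_pairs, toy_expected):
        in_c = toy_expected["c"] >= 0.3
        hand = toy_expected[in_c & (toy_expected["d"] >= 3)]
        q = RangeQuery(0.3, 1.0, 3.0, math.inf, "d")
        got = observed_prob(toy_pairs, q, conditional_on_c=True)
        assert got == pytest.approx(len(hand) / int(in_c.sum()))


class TestRmseAndScaling:
    def test_identical_vectors_give_zero(self):
        assert rmse([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == 0.0

    def test_hand_value(self):
        assert rmse([0.0, 0.0], [1.0, 1.0]) == pytest.approx(math.sqrt(2.0))

    def test_permutation_invariance(self, rng):
        a, b = rng.random(10), rng.random(10)
        perm = rng.permutation(10)
        assert rmse(a, b) == pytest.approx(rmse(a[perm], b[perm]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            rmse([1.0], [1.0])

    def test_scale_factor_identity_and_half(self):
        v = np.array([0.2, 0.4, 0.1])
        _, f1 = scale_predictions(v, v)
        assert f1 == pytest.approx(1.0)
        _, f2 = scale_predictions(2 * v, v)
        assert f2 == pytest.approx(0.5)

    def test_scale_factor_closed_form(self, rng):
        a, b = rng.random(20), rng.random(20)
        _, f = scale_predictions(a, b)
        assert f == pytest.approx(np.sum(a * b) / np.sum(a * a))

    def test_all_zero_predictions_rejected(self):
        with pytest.raises(ValueError):
            scale_predictions([0.0, 0.0], [0.1, 0.2])


@pytest.fixture(scope="module")
def model_pairs():
    return sample_pair_weights(EnsembleSpec(seed=7, n_pairs=100_000))


class TestScan:
    def test_single_point_grid_reduces_to_above_average(self, toy_pairs):
        k = ModelConstants()
        scan = scan_thresholds(toy_pairs, k, region=(0.3, 1.0), n_grid=[0.0], measure="d")
        # 8 pairs with c >= 0.3; d >= mu_d = 4.625 holds for 4 of them
        assert scan.p_obs.tolist() == [0.5]

    @pytest.mark.parametrize("measure", ["s", "d"])
    def test_self_consistency_on_model_ensemble(self, model_pairs, measure):
        k = ModelConstants(mode="normalized")
        scan = scan_thresholds(model_pairs, k, region=(k.c_min, 1.0), measure=measure)
        assert scan.rmse < 0.01
        assert np.all(np.diff(scan.p_obs) <= 1e-12)
        assert np.all(np.diff(scan.p_pred) <= 1e-12)

    def test_s_thresholds_clamped_to_support(self, model_pairs):
        k = ModelConstants()
        scan = scan_thresholds(model_pairs, k, region=(k.c_min, 1.0), measure="s")
        assert (scan.thresholds >= k.s_min).all()

    def test_frame_round_trip_columns(self, toy_pairs):
        k = ModelConstants()
        scan = scan_thresholds(toy_pairs, k, region=(0.3, 1.0), n_grid=[0, 1], measure="d")
        df = scan.to_frame()
        assert list(df.columns) == ["n", "threshold", "p_obs", "p_pred_raw", "p_pred_scaled"]
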