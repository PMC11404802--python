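"""Group statistics: library agreement, hand examples, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

from cliquebars import (
    entropy_regression,
    ks_two_sample,
    lilliefors,
    pool_lengths,
    t_and_d,
)


class TestKSTwoSample:
    def test_identical_samples_give_zero(self):
        d, _ = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0

    def test_disjoint_supports_give_one(self):
        d, _ = ks_two_sample([0.0, 0.0], [1.0, 1.0])
        assert d == 1.0

    def test_shifted_triples(self):
        d, _ = ks_two_sample([1, 2, 3], [2, 3, 4])
        assert d == pytest.approx(1 / 3)

    def test_agrees_with_scipy_asymptotic(self, rng):
        for _ in range(100):
            n1, n2 = rng.integers(5, 300, size=2)
            a = rng.normal(0, 1, n1)
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), n2)
            if rng.random() < 0.3:  # exercise ties
                a, b = np.round(a, 1), np.round(b, 1)
            d, p = ks_two_sample(a, b)
            ref = sps.ks_2samp(a, b, method="asymp")
            assert d == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_symmetric_in_sample_order(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 40)
        assert ks_two_sample(a, b) == ks_two_sample(b, a)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestLilliefors:
    def test_distance_agrees_with_statsmodels(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 200))
            x = rng.normal(0, 1, n) if rng.random() < 0.5 else rng.exponential(1, n)
            d, _ = lilliefors(x)
            d_ref, _ = sm_lilliefors(x, dist="norm")
            assert d == pytest.approx(d_ref, abs=1e-9)

    def test_calibration_on_normal_samples(self, rng):
        """A normal sample should rarely be rejected."""
        hits = sum(
            lilliefors(rng.standard_normal(1000))[1] > 0.05 for _ in range(100)
        )
        assert hits >= 90

    def test_power_on_exponential_samples(self, rng):
        hits = sum(
            lilliefors(rng.exponential(1.0, 1000))[1] < 0.05
            for _ in range(100)
        )
        assert hits >= 90

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            lilliefors([1.0, 1.0, 1.0, 1.0])

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 4"):
            lilliefors([1.0, 2.0, 3.0])


class TestTTestAndCohensD:
    def test_equal_means_give_zero(self):
        r = t_and_d([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert r["t"] == 0.0 and r["cohen_d"] == 0.0

    def test_unit_separation_gives_unit_d(self, rng):
        x1 = rng.normal(0, 1, 500)
        x1 = (x1 - x1.mean()) / x1.std(ddof=1) + 1.0  # mean 1, sd 1 exactly
        x2 = rng.normal(0, 1, 500)
        x2 = (x2 - x2.mean()) / x2.std(ddof=1)
        assert t_and_d(x1, x2)["cohen_d"] == pytest.approx(1.0, abs=1e-12)

    def test_shifted_triples_d_is_one(self):
        r = t_and_d([1, 2, 3], [2, 3, 4])
        assert r["cohen_d"] == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_scipy_pooled(self, rng):
        for _ in range(100):
            n1, n2 = rng.integers(3, 60, size=2)
            a = rng.normal(0, 1, n1)
            b = rng.normal(0.3, 1.4, n2)
            r = t_and_d(a, b)
            ref = sps.ttest_ind(a, b, equal_var=True)
            assert r["t"] == pytest.approx(ref.statistic, abs=1e-9)
            assert r["p"] == pytest.approx(ref.pvalue, abs=1e-9)

    def test_group_swap_flips_t_keeps_d(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(1, 1, 25)
        r1, r2 = t_and_d(a, b), t_and_d(b, a)
        assert r1["t"] == pytest.approx(-r2["t"], abs=1e-12)
        assert r1["cohen_d"] == pytest.approx(r2["cohen_d"], abs=1e-12)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            t_and_d([1.0, 1.0], [1.0, 1.0])


class TestPoolLengths:
    def test_concatenates_by_group_and_dim(self):
        ls = {
            "a": {0: np.array([1.0, 2, 3]), 1: np.array([0.5])},
            "b": {0: np.array([4.0, 5, 6]), 1: np.array([0.7])},
        }
        pooled = pool_lengths(ls, {"a": "control", "b": "case"})
        assert pooled.get("control", 0).tolist() == [1, 2, 3]
        assert pooled.sizes() == {"control_dim0": 3, "case_dim0": 3,
                                  "control_dim1": 1, "case_dim1": 1}

    def test_order_invariance(self, rng):
        ls = {f"s{i}": {0: rng.uniform(0, 1, 5), 1: rng.uniform(0, 1, 3)}
              for i in range(6)}
        groups = {f"s{i}": ("control" if i % 2 else "case") for i in range(6)}
        p1 = pool_lengths(ls, groups)
        shuffled = dict(reversed(list(ls.items())))
        p2 = pool_lengths(shuffled, groups)
        for key in p1.pools:
            assert np.array_equal(p1.pools[key], p2.pools[key])

    def test_empty_group_rejected(self):
        ls = {"a": {0: np.array([1.0]), 1: np.array([1.0])}}
        with pytest.raises(ValueError, match="pool"):
            pool_lengths(ls, {"a": "control"})


def _cohort_frame(rng, n=43, beta3=0.0, noise=1.0):
    group = np.array(["control"] * 19 + ["case"] * (n - 19))
    sex = rng.integers(0, 2, n)
    age = rng.integers(13, 18, n)
    e = 4.3 + beta3 * (group == "case") + noise * rng.standard_normal(n)
    return pd.DataFrame({"group": group, "sex": sex, "age": age, "e0": e})


class TestEntropyRegression:
    def test_noiseless_recovery_of_diagnostic_effect(self, rng):
        df = _cohort_frame(rng, noise=0.0, beta3=-0.25)
        r = entropy_regression(df, 0)
        assert r.params["diagnostic"] == pytest.approx(-0.25, abs=1e-10)
        assert r.params["const"] == pytest.approx(4.3, abs=1e-10)
        assert r.rsquared == pytest.approx(1.0, abs=1e-10)

    def test_null_calibration_of_slope_pvalues(self, rng):
        """With no true effects, each slope rejects at ~5%."""
        hits = {"sex": 0, "age": 0, "diagnostic": 0}
        n_rep = 100
        for _ in range(n_rep):
            df = _cohort_frame(rng, n=200)
            r = entropy_regression(df, 0)
            for k in hits:
                hits[k] += r.pvalues[k] < 0.05
        for k, h in hits.items():
            assert h <= 10, f"{k} rejected {h}/{n_rep} under the null"

    def test_designed_group_gap_gives_negative_beta3(self, rng):
        df = _cohort_frame(rng, beta3=-0.3, noise=0.05)
        r = entropy_regression(df, 0)
        assert r.params["diagnostic"] < 0
        assert r.pvalues["diagnostic"] < 0.001

    def test_group_swap_flips_beta3(self, rng):
        df = _cohort_frame(rng, beta3=-0.3, noise=0.1)
        swapped = df.assign(
            group=np.where(df["group"] == "case", "control", "case")
        )
        r1, r2 = entropy_regression(df, 0), entropy_regression(swapped, 0)
        assert r1.params["diagnostic"] == pytest.approx(
            -r2.params["diagnostic"], abs=1e-9)

    def test_minmax_scaling_preserves_t_and_p(self, rng):
        df = _cohort_frame(rng, beta3=-0.2, noise=0.1)
        raw = entropy_regression(df, 0, scaling="none")
        scaled = entropy_regression(df, 0, scaling="minmax")
        for k in ("sex", "age", "diagnostic"):
            assert scaled.tvalues[k] == pytest.approx(raw.tvalues[k], abs=1e-9)
            assert scaled.pvalues[k] == pytest.approx(raw.pvalues[k], abs=1e-9)
        assert 0.0 <= scaled.params["const"] <= 1.0

    def test_rank_deficient_design_rejected(self, rng):
        df = _cohort_frame(rng)
        df["age"] = 15  # constant column -> collinear with intercept
        with pytest.raises(ValueError, match="rank"):
            entropy_regression(df, 0)

    def test_too_few_cases_rejected(self, rng):
        df = _cohort_frame(rng).head(4)
        with pytest.raises(ValueError, match="n > 4"):
            entropy_regression(df, 0)
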