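"""Mann-Whitney U, mean +/- SEM, log-normal fits, proportion tallies."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from axonstat import group_stats as gs
from axonstat.types import ValidationError, VaricosityRecord


def enumeration_p_two_tailed(x, y):
    """Exact two-tailed p by full enumeration of group assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n = len(x)
    u_obs = sum((xi > yj) for xi in x for yj in y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        us.append(sum((xi > yj) for xi in xs for yj in ys))
    us = np.asarray(us)
    p = 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return min(1.0, p)


class TestMannWhitney:
    def test_tiny_separation_example(self):
        u, p, method = gs.mann_whitney_two_tailed([1, 2], [3, 4])
        assert u == 0
        assert p == pytest.approx(2 / 6)
        assert method == "exact"

    def test_three_vs_three_example(self):
        u, p, method = gs.mann_whitney_two_tailed([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)
        assert method == "exact"

    def test_identical_samples(self):
        u, p, method = gs.mann_whitney_two_tailed([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)
        assert method == "normal_approx"  # ties force the approximate path

    def test_empty_sample_errors(self):
        with pytest.raises(ValidationError):
            gs.mann_whitney_two_tailed([], [1.0])

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=15)
    def test_exact_path_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 6, size=2)
        pooled = rng.permutation(np.arange(1.0, n + m + 1))  # tie-free
        x, y = pooled[:n], pooled[n:]
        u, p, method = gs.mann_whitney_two_tailed(x, y)
        assert method == "exact"
        assert p == pytest.approx(enumeration_p_two_tailed(x, y))

    def test_u_is_the_smaller_of_the_pair(self):
        u, _, _ = gs.mann_whitney_two_tailed([10, 11, 12], [1, 2])
        assert u == 0.0  # U_y = 0 is reported although U_x = 6


class TestMeanSem:
    def test_closed_form(self):
        mean, sem, n = gs.mean_sem([1.0, 2.0, 3.0])
        assert (mean, n) == (2.0, 3)
        assert sem == pytest.approx(1 / np.sqrt(3))

    def test_constant_sample(self):
        _, sem, _ = gs.mean_sem([5.0, 5.0, 5.0, 5.0])
        assert sem == 0.0

    def test_shift_equivariance(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=20)
        m1, s1, _ = gs.mean_sem(v)
        m2, s2, _ = gs.mean_sem(v + 7.5)
        assert m2 == pytest.approx(m1 + 7.5)
        assert s2 == pytest.approx(s1)

    def test_single_value_flags_sem_undefined(self):
        _, sem, _ = gs.mean_sem([4.2])
        assert np.isnan(sem)


class TestLogNormalFit:
    def test_constant_values(self):
        fit = gs.fit_lognormal([np.e**8] * 10)
        assert fit.mu == pytest.approx(8.0)
        assert fit.sigma == pytest.approx(0.0, abs=1e-12)

    def test_two_point_mean(self):
        a, b = 3.0, 17.0
        fit = gs.fit_lognormal([a, b])
        assert fit.mu == pytest.approx((np.log(a) + np.log(b)) / 2)

    def test_recovery_at_large_n(self):
        rng = np.random.default_rng(7)
        mu, sigma, n = 8.3, 0.8, 10_000
        fit = gs.fit_lognormal(rng.lognormal(mu, sigma, n))
        assert abs(fit.mu - mu) <= 3 * sigma / np.sqrt(n)
        assert abs(fit.sigma - sigma) <= 3 * sigma / np.sqrt(2 * n)

    def test_nonpositive_errors(self):
        with pytest.raises(ValidationError):
            gs.fit_lognormal([1.0, 0.0])


class TestProportionTable:
    def test_reference_tally(self):
        labels = ["axo_axonic"] * 49 + ["axo_dendritic"] * 10
        table = gs.proportion_table(labels)
        aa = table[table.partner_class == "axo_axonic"].iloc[0]
        assert aa["count"] == 49
        assert aa.fraction == pytest.approx(49 / 59)
        assert table.fraction.sum() == pytest.approx(1.0)

    def test_single_class(self):
        table = gs.proportion_table(["axo_axonic"] * 5)
        assert table.fraction.tolist() == [1.0, 0.0]

    def test_invariant_under_shuffling(self):
        rng = np.random.default_rng(2)
        labels = list(rng.choice(["axo_axonic", "axo_dendritic"], 40))
        t1 = gs.proportion_table(labels)
        rng.shuffle(labels)
        t2 = gs.proportion_table(labels)
        assert t1.equals(t2)


class TestMitoCooccurrence:
    def varics(self, flags, types=None):
        types = types or ["II"] * len(flags)
        return [
            VaricosityRecord("a", i, 1, vtype=t, mito_within_1um=f)
            for i, (t, f) in enumerate(zip(types, flags))
        ]

    def test_all_flagged(self):
        table = gs.mito_cooccurrence(self.varics([True] * 8))
        assert table[table.vtype == "II"].fraction_with_mito.iloc[0] == 1.0

    def test_alternating_flags(self):
        table = gs.mito_cooccurrence(self.varics([True, False] * 10))
        assert table[table.vtype == "all"].fraction_with_mito.iloc[0] == 0.5

    def test_empty_stratum_is_nan(self):
        table = gs.mito_cooccurrence(self.varics([True], types=["III"]))
        assert np.isnan(table[table.vtype == "I"].fraction_with_mito.iloc[0])

    def test_bernoulli_half_recovery(self):
        rng = np.random.default_rng(5)
        n = 4000
        types = list(rng.choice(["I", "II", "III", "IV"], n))
        flags = list(rng.random(n) < 0.5)
        table = gs.mito_cooccurrence(self.varics(flags, types))
        for _, row in table.iterrows():
            se = np.sqrt(0.25 / row.n)
            assert abs(row.fraction_with_mito - 0.5) <= 3 * se
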