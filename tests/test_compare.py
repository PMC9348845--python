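"""Between-curve hypothesis tests and multiplicity correction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import f as f_dist, t as t_dist

import betadose as bd
from betadose.compare import bh_adjust


def _relabelled(two_group_frame):
    """Identical data under two labels (exact null)."""
    df = two_group_frame[two_group_frame["group"] == "A"].copy()
    dup = df.copy()
    dup["group"] = "B"
    return pd.concat([df, dup], ignore_index=True)


class TestGlobalTests:
    def test_identical_groups_give_null_results(self, two_group_frame):
        res = bd.compare_groups(_relabelled(two_group_frame))
        assert res["model_equality"].statistic == pytest.approx(0.0, abs=1e-4)
        assert res["model_equality"].p_value > 0.99
        assert res["slope_equality"].p_value > 0.99
        assert res["potency_equality"].statistic == pytest.approx(0.0, abs=1e-4)
        assert res["pairwise_potency"].pairs[0][3] > 0.99  # raw p

    def test_degrees_of_freedom_counting(self, two_group_frame):
        res = bd.compare_groups(two_group_frame)
        assert res["model_equality"].df == 2       # 2(G-1), G=2
        assert res["slope_equality"].df == 1       # G-1
        df1, df2 = res["potency_equality"].df
        assert df1 == 1 and df2 == 42 - 6          # N - k (4 mean + 2 prec)

    def test_f_equals_squared_t_for_two_groups(self, two_group_frame):
        res = bd.compare_groups(two_group_frame)
        free = bd.fit_mle(two_group_frame)
        vals, cov = free.log_dm_vector()
        tstat = (vals[0] - vals[1]) / np.sqrt(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
        assert res["potency_equality"].statistic == pytest.approx(tstat**2, rel=1e-9)
        # and the F(1, nu) p-value equals the two-sided t p-value
        nu = res["potency_equality"].df[1]
        assert res["potency_equality"].p_value == pytest.approx(
            2 * t_dist.sf(abs(tstat), nu), rel=1e-9)

    def test_separated_groups_detected(self, seven_dose_design):
        # intercepts two logit units apart at n=21 per group: clearly distinct
        d = seven_dose_design
        mu_a = bd.inv_logit(np.log(d))
        mu_b = bd.inv_logit(np.log(d) + 2.0)
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "dose": np.concatenate([d, d]),
            "response": np.concatenate([rng.beta(mu_a * 100, (1 - mu_a) * 100),
                                        rng.beta(mu_b * 100, (1 - mu_b) * 100)]),
            "group": ["A"] * d.size + ["B"] * d.size})
        res = bd.compare_groups(df)
        assert res["model_equality"].p_value < 0.001
        assert res["potency_equality"].p_value < 0.001

    def test_single_group_not_applicable(self, two_group_frame):
        single = two_group_frame[two_group_frame["group"] == "A"]
        with pytest.raises(ValueError):
            bd.compare_groups(single)

    def test_three_groups_pairwise_count(self, two_group_frame):
        df = two_group_frame.copy()
        extra = df[df["group"] == "A"].copy()
        extra["group"] = "C"
        res = bd.compare_groups(pd.concat([df, extra], ignore_index=True))
        assert len(res["pairwise_potency"].pairs) == 3
        for *_, raw_p, adj_p in res["pairwise_potency"].pairs:
            assert adj_p >= raw_p - 1e-15
            assert adj_p <= 1.0


class TestBhAdjust:
    def _oracle(self, p):
        """Independent step-up computation: p_(i) * m / i with running min
        from the largest rank down."""
        p = np.asarray(p, dtype=float)
        m = p.size
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        return adj

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.123]), [0.123])

    @pytest.mark.parametrize("p, expected", [
        ((0.01, 0.02, 0.03), (0.03, 0.03, 0.03)),
        ((0.005, 0.04, 0.1), (0.015, 0.06, 0.1)),
    ])
    def test_hand_computed_examples(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_ties_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 12))
            np.testing.assert_allclose(bh_adjust(p), self._oracle(p), atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=8)
        perm = rng.permutation(8)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]),
                                   atol=1e-12)

    def test_monotone_nondecreasing_after_sorting(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            adj = bh_adjust(rng.uniform(size=10))
            s = np.sort(adj)
            assert np.all(np.diff(s) >= -1e-15)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
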