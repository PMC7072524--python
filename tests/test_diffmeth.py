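"""M-value transform, moderated-t engine, SAM engine, selection and overlap."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from methinv import (
    SelectionConfig,
    beta_to_m,
    fit_moderated_t,
    intersect_sites,
    sam_d_statistic,
    sam_permutation,
    select_sites,
)
from methinv.diffmeth import default_s0, percentile_s0, trigamma_inverse


class TestBetaToM:
    def test_half_maps_to_zero(self):
        assert beta_to_m(np.array([0.5])) == pytest.approx(0.0, abs=1e-9)

    def test_closed_form(self):
        assert beta_to_m(np.array([0.8]), epsilon=0.0)[0] == pytest.approx(2.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_strictly_increasing(self, seed):
        rng = np.random.default_rng(seed)
        grid = np.sort(rng.uniform(0, 1, 50))
        grid = np.unique(grid)
        m = beta_to_m(grid)
        assert (np.diff(m) > 0).all()

    def test_endpoints_finite(self):
        m = beta_to_m(np.array([0.0, 1.0]))
        assert np.isfinite(m).all()


def _toy_table(rng, n_probes=50, n1=3, n2=3, scale=1.0):
    x = rng.normal(0, scale, (n_probes, n1 + n2))
    idx = [f"p{i:03d}" for i in range(n_probes)]
    return pd.DataFrame(x, index=idx), np.array(["a"] * n1 + ["b"] * n2)


class TestModeratedT:
    def test_zero_difference_gives_null_stats(self):
        x = pd.DataFrame([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                          [0.5, 1.0, 0.2, 0.9, 0.1, 0.7]])
        groups = np.array(["a"] * 3 + ["b"] * 3)
        tab, _ = fit_moderated_t(x, groups, d0_override=0)
        assert tab.loc[0, "logFC"] == pytest.approx(0.0, abs=1e-12)
        assert tab.loc[0, "t"] == pytest.approx(0.0, abs=1e-12)
        assert tab.loc[0, "p"] == pytest.approx(1.0)

    def test_no_shrinkage_equals_pooled_t(self):
        rng = np.random.default_rng(1)
        x, groups = _toy_table(rng)
        tab, _ = fit_moderated_t(x, groups, d0_override=0)
        t_ref, p_ref = stats.ttest_ind(x.iloc[:, :3], x.iloc[:, 3:], axis=1)
        np.testing.assert_allclose(tab["t"], t_ref, atol=1e-10)
        np.testing.assert_allclose(tab["p"], p_ref, atol=1e-10)

    def test_posterior_variance_is_convex_combination(self):
        rng = np.random.default_rng(2)
        x, groups = _toy_table(rng)
        # heteroscedastic rows so the prior df estimate is finite
        x = x.mul(np.sqrt(rng.chisquare(3, len(x)) / 3), axis=0)
        tab, hyper = fit_moderated_t(x, groups, robust=False)
        assert np.isfinite(hyper.d0)
        s2 = tab["s2"].to_numpy()
        se = tab["logFC"].to_numpy() / tab["t"].replace(0, np.nan).to_numpy()
        s2_post = se**2 / (1 / 3 + 1 / 3)
        lo = np.minimum(s2, hyper.s0_sq) - 1e-12
        hi = np.maximum(s2, hyper.s0_sq) + 1e-12
        ok = np.isfinite(s2_post)
        assert ((s2_post[ok] >= lo[ok]) & (s2_post[ok] <= hi[ok])).all()

    def test_infinite_prior_df_limit(self):
        rng = np.random.default_rng(3)
        x, groups = _toy_table(rng)
        s0 = 0.7
        tab, _ = fit_moderated_t(x, groups, d0_override=np.inf, s0_override=s0)
        expected = tab["logFC"].to_numpy() / (np.sqrt(s0) * np.sqrt(1 / 3 + 1 / 3))
        np.testing.assert_allclose(tab["t"], expected, rtol=1e-10)

    def test_matches_reference_eb_implementation(self):
        """Frozen oracle: hyperparameters and moderated t computed once with
        the R reference implementation of EB variance moderation (limma
        eBayes, non-robust) on this exact fixture."""
        rng = np.random.default_rng(42)
        s = np.sqrt(rng.chisquare(4, 60) / 4)
        x = rng.normal(0, 1, (60, 8)) * s[:, None]
        x[:10, :4] += 1.0
        frame = pd.DataFrame(x, index=[f"p{i:02d}" for i in range(60)])
        groups = np.array(["g1"] * 4 + ["g2"] * 4)
        tab, hyper = fit_moderated_t(frame, groups, robust=False)
        assert hyper.d0 == pytest.approx(3.820147, abs=1e-5)
        assert hyper.s0_sq == pytest.approx(0.5383872, abs=1e-6)
        t_ref = [3.2989325768, 1.3946771243, 3.4076815196, 3.9542477076,
                 5.4196341345, 1.5873723991, 0.4805446716, 1.3903561363,
                 -0.0524504887, 0.6173174117]
        np.testing.assert_allclose(tab["t"].to_numpy()[:10], t_ref, atol=1e-8)
        p_ref = [8.2232128589e-03, 1.9385687310e-01, 6.8590790419e-03,
                 2.8091027562e-03, 3.1222638212e-04]
        np.testing.assert_allclose(tab["p"].to_numpy()[:5], p_ref, rtol=1e-6)

    def test_bh_q_values_monotone_and_bounded(self):
        rng = np.random.default_rng(4)
        x, groups = _toy_table(rng, n_probes=200)
        tab, _ = fit_moderated_t(x, groups)
        srt = tab.sort_values("p")
        assert (srt["q"].to_numpy() >= srt["p"].to_numpy() - 1e-12).all()
        assert (np.diff(srt["q"].to_numpy()) >= -1e-12).all()
        assert srt["q"].between(0, 1).all()

    def test_all_zero_variance_degenerate(self):
        x = pd.DataFrame(np.ones((5, 6)))
        groups = np.array(["a"] * 3 + ["b"] * 3)
        with pytest.raises(ValueError, match="degenerate"):
            fit_moderated_t(x, groups, robust=False)

    def test_trigamma_inverse_roundtrip(self):
        from scipy import special

        for y in [0.01, 0.1, 1.0, 5.0]:
            x = trigamma_inverse(y)
            assert special.polygamma(1, x) == pytest.approx(y, rel=1e-8)


class TestSamD:
    def test_identical_groups_zero(self):
        x = pd.DataFrame([[1.0, 2.0, 1.0, 2.0]])
        d = sam_d_statistic(x, np.array(["a", "a", "b", "b"]), s0_sam=0.1)
        assert d[0] == pytest.approx(0.0)

    def test_hand_computed_pooled_se(self):
        # group1 = 1 +/- a, group2 = 0 -/+ a with a chosen so pooled SE = 0.5
        a = 0.25 * np.sqrt(2.0)
        x = pd.DataFrame([[1 + a, 1 - a, a, -a]])
        d = sam_d_statistic(x, np.array(["a", "a", "b", "b"]), s0_sam=0.0)
        assert d[0] == pytest.approx(2.0, rel=1e-12)

    def test_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(6)
        x = pd.DataFrame(rng.normal(0, 1, (20, 8)))
        g = np.array(["a"] * 4 + ["b"] * 4)
        g_swapped = np.array(["b"] * 4 + ["a"] * 4)
        d1 = sam_d_statistic(x, g, 0.05)
        d2 = sam_d_statistic(x, g_swapped, 0.05)
        np.testing.assert_allclose(d1, -d2, atol=1e-12)


def _exhaustive_sam_oracle(x: np.ndarray, s0: float):
    """Full enumeration over the 6 balanced label assignments of 4 samples."""
    ds = []
    for combo in itertools.combinations(range(4), 2):
        mask = np.isin(np.arange(4), combo)
        m1, m2 = x[:, mask].mean(1), x[:, ~mask].mean(1)
        ss = ((x[:, mask] - m1[:, None]) ** 2).sum(1) + ((x[:, ~mask] - m2[:, None]) ** 2).sum(1)
        s = np.sqrt(ss / 2)
        ds.append((m1 - m2) / (s + s0))
    ds = np.array(ds)
    de_rank = np.sort(ds, axis=1)[:, ::-1].mean(axis=0)
    return ds, de_rank


class TestSamPermutation:
    def test_exhaustive_2v2_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        x = pd.DataFrame(rng.normal(0, 1, (15, 4)))
        groups = np.array(["a", "a", "b", "b"])
        s0 = 0.1
        res = sam_permutation(x, groups, SelectionConfig(permutations=1000, seed=0), s0_sam=s0)
        assert res.exhaustive and res.M == 6
        ds, de_rank = _exhaustive_sam_oracle(x.to_numpy(), s0)
        d = sam_d_statistic(x, groups, s0)
        order = np.argsort(-d)
        de_probe = np.empty_like(de_rank)
        de_probe[order] = de_rank
        np.testing.assert_allclose(res.table["dE"], de_probe, atol=1e-12)
        np.testing.assert_allclose(res.table["delta"], np.abs(d - de_probe), atol=1e-12)
        null = np.abs(ds).ravel()
        p_oracle = np.array([(1 + (null >= abs(di)).sum()) / (1 + null.size) for di in d])
        np.testing.assert_allclose(res.table["p"], p_oracle, atol=1e-12)

    def test_delta_zero_when_observed_equals_expected(self):
        # symmetric data make every permutation equivalent: d == dE rank-wise
        x = pd.DataFrame(np.zeros((5, 4)) + np.arange(4)[None, :] * 0.0)
        x.iloc[:, :] = 1.0
        groups = np.array(["a", "a", "b", "b"])
        res = sam_permutation(x, groups, SelectionConfig(seed=0), s0_sam=0.5)
        np.testing.assert_allclose(res.table["delta"], 0.0, atol=1e-12)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(8)
        x = pd.DataFrame(rng.normal(0, 1, (2000, 40)))
        groups = np.array(["a"] * 20 + ["b"] * 20)
        res = sam_permutation(x, groups, SelectionConfig(permutations=500, seed=8))
        frac = float((res.table["p"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_bit_reproducible_under_seed(self):
        rng = np.random.default_rng(9)
        x = pd.DataFrame(rng.normal(0, 1, (100, 12)))
        groups = np.array(["a"] * 6 + ["b"] * 6)
        cfg = SelectionConfig(permutations=50, seed=123)
        r1 = sam_permutation(x, groups, cfg)
        r2 = sam_permutation(x, groups, cfg)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_default_s0_is_median_se(self):
        rng = np.random.default_rng(10)
        x = pd.DataFrame(rng.normal(0, 1, (30, 8)))
        groups = np.array(["a"] * 4 + ["b"] * 4)
        s0 = default_s0(x, groups)
        m1 = x.iloc[:, :4].mean(1)
        m2 = x.iloc[:, 4:].mean(1)
        ss = ((x.iloc[:, :4].sub(m1, axis=0)) ** 2).sum(1) + ((x.iloc[:, 4:].sub(m2, axis=0)) ** 2).sum(1)
        se = np.sqrt(ss / 6 * (1 / 4 + 1 / 4))
        assert s0 == pytest.approx(float(np.median(se)), rel=1e-12)


class TestFudgeFactorSearch:
    def test_percentile_s0_lies_in_se_range_and_stabilizes_d(self):
        rng = np.random.default_rng(12)
        # heteroscedastic probes: small-SE probes would dominate |d| at s0=0
        x = pd.DataFrame(rng.normal(0, 1, (500, 12)) * rng.uniform(0.1, 3, 500)[:, None])
        groups = np.array(["a"] * 6 + ["b"] * 6)
        s0 = percentile_s0(x, groups)
        m1 = x.iloc[:, :6].mean(1)
        m2 = x.iloc[:, 6:].mean(1)
        ss = ((x.iloc[:, :6].sub(m1, axis=0)) ** 2).sum(1) + ((x.iloc[:, 6:].sub(m2, axis=0)) ** 2).sum(1)
        se = np.sqrt(ss / 10 * (2 / 6))
        assert se.min() - 1e-12 <= s0 <= se.max() + 1e-12
        d_raw = sam_d_statistic(x, groups, 0.0)
        d_reg = sam_d_statistic(x, groups, s0)
        assert np.abs(d_reg).max() <= np.abs(d_raw).max()


class TestSelection:
    def _table(self, logfc, p, q):
        return pd.DataFrame(
            {"logFC": logfc, "p": p, "q": q},
            index=[f"p{i}" for i in range(len(logfc))],
        )

    def test_effect_size_gate(self):
        t = self._table([1.4], [0.001], [0.001])
        assert len(select_sites(t)) == 0

    def test_p_value_gate(self):
        t = self._table([2.0], [0.02], [0.001])
        assert len(select_sites(t)) == 0

    def test_planted_pass_set_recovered(self):
        rng = np.random.default_rng(11)
        logfc = rng.uniform(-3, 3, 100)
        p = rng.uniform(0, 1, 100)
        q = np.minimum(p * 2, 1.0)
        t = self._table(logfc, p, q)
        expected = t.index[(np.abs(logfc) >= 1.5) & (p < 0.01) & (q <= 0.01)]
        assert list(select_sites(t)) == list(expected)

    def test_intersection_ordering(self):
        a = pd.Index(["x", "y", "z"])
        assert list(intersect_sites(a, ["z", "x"])) == ["x", "z"]
        assert list(intersect_sites(a, [])) == []
        assert list(intersect_sites(a, a)) == ["x", "y", "z"]
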