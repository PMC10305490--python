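import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from rdnacn.association import (
    bh_fdr,
    group_comparison,
    per_bin_regression,
    platform_correlation,
)
from rdnacn.copynumber import CnEstimate
from rdnacn.methylation import MethylBin


def cn_est(sid, cn, segment="18S"):
    return CnEstimate(sid, segment, ard=cn * 10, brd=10.0, cn=cn)


def meth_bin(start, meth, n_cpgs=5, reads=100, passes=True):
    return MethylBin(
        start=start,
        end=start + 199,
        n_cpgs_covered=n_cpgs,
        total_reads=reads,
        mean_meth=meth,
        passes_filters=passes,
    )


# ------------------------------------------------------------------ bh_fdr

def oracle_bh(pvals):
    """Literal step-up: q_(i) = min_{j>=i} p_(j)*n/j, order preserved."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    q = [None] * n
    best = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        best = min(best, pvals[i] * n / rank)
        q[i] = best
    return q


class TestBhFdr:
    def test_stepup_example(self):
        # oracle: ranked q = min over j>=i of p_j*4/j = 0.04 for all
        got = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])
        assert np.allclose(oracle_bh([0.01, 0.02, 0.03, 0.04]), got)

    def test_single_p(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_equal(self):
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_empty(self):
        assert bh_fdr([]).size == 0

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=100))
    def test_matches_oracle(self, pvals):
        assert np.allclose(bh_fdr(pvals), oracle_bh(pvals))

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=50), st.randoms())
    def test_permutation_equivariance(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        q = bh_fdr(pvals)
        q_perm = bh_fdr([pvals[i] for i in perm])
        assert np.allclose(q_perm, [q[i] for i in perm])

    def test_monotone_in_ranked_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


# ------------------------------------------------- per-bin regression

def oracle_ols(y, X):
    """Normal equations with an intercept column prepended."""
    X1 = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(X1.T @ X1, X1.T @ y)
    resid = y - X1 @ beta
    dof = len(y) - X1.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X1.T @ X1)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2 * sps.t.sf(np.abs(t), dof)
    return beta, se, p


class TestPerBinRegression:
    def _cohort(self, n, meth_fn, rng=None, covar=True):
        rng = rng or np.random.default_rng(0)
        cns = rng.uniform(100, 300, size=n)
        ages = rng.uniform(20, 80, size=n)
        sexes = rng.integers(0, 2, size=n)
        groups = rng.integers(0, 2, size=n)
        ids = [f"s{i}" for i in range(n)]
        cn = [cn_est(sid, c) for sid, c in zip(ids, cns)]
        bins = {
            sid: [meth_bin(1, meth_fn(cns[i], ages[i], sexes[i], groups[i]))]
            for i, sid in enumerate(ids)
        }
        cols = {"age": ages, "sex": sexes, "group": groups}
        covariates = pd.DataFrame(cols if covar else {}, index=ids)
        return cn, bins, covariates

    def test_exact_linear_fit(self):
        # meth = cn/10 exactly, no covariate effects -> beta = 10, p ~ 0
        cn, bins, cov = self._cohort(12, lambda c, a, s, g: c / 10)
        (res,) = per_bin_regression(cn, bins, cov)
        assert res.beta == pytest.approx(10.0, abs=1e-8)
        assert res.p_value < 1e-12

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        n = 6
        cns = rng.uniform(100, 300, size=n)
        meths = rng.uniform(20, 60, size=n)
        ages = rng.uniform(20, 80, size=n)
        sexes = np.array([0, 1, 0, 1, 0, 1])
        groups = np.array([0, 0, 1, 1, 0, 1])
        ids = [f"s{i}" for i in range(n)]
        cn = [cn_est(sid, c) for sid, c in zip(ids, cns)]
        bins = {sid: [meth_bin(1, meths[i])] for i, sid in enumerate(ids)}
        cov = pd.DataFrame({"age": ages, "sex": sexes, "group": groups}, index=ids)
        (res,) = per_bin_regression(cn, bins, cov, min_samples=6)
        X = np.column_stack([meths, ages, sexes, groups])
        beta, se, p = oracle_ols(cns, X)
        assert res.beta == pytest.approx(beta[1])
        assert res.se == pytest.approx(se[1])
        assert res.p_value == pytest.approx(p[1])

    def test_slope_invariant_to_constant_meth_shift(self):
        rng = np.random.default_rng(6)
        cn, bins, cov = self._cohort(
            15, lambda c, a, s, g: c / 10 + rng.normal(0, 2), rng=rng
        )
        shifted = {
            sid: [meth_bin(1, b[0].mean_meth + 25.0)] for sid, b in bins.items()
        }
        (r1,) = per_bin_regression(cn, bins, cov)
        (r2,) = per_bin_regression(cn, shifted, cov)
        assert r1.beta == pytest.approx(r2.beta)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_underpowered_bin_skipped_with_reason(self):
        cn, bins, cov = self._cohort(4, lambda c, a, s, g: c / 10)
        (res,) = per_bin_regression(cn, bins, cov)
        assert res.skipped_reason is not None
        assert np.isnan(res.p_value)

    def test_failing_bins_not_tested(self):
        cn, bins, cov = self._cohort(12, lambda c, a, s, g: c / 10)
        for sid in bins:
            bins[sid][0] = meth_bin(1, bins[sid][0].mean_meth, passes=False)
        (res,) = per_bin_regression(cn, bins, cov)
        assert res.skipped_reason is not None

    def test_collinear_design_skipped(self):
        # methylation constant -> collinear with intercept
        cn, bins, cov = self._cohort(12, lambda c, a, s, g: 42.0)
        (res,) = per_bin_regression(cn, bins, cov)
        assert res.skipped_reason == "collinear design"

    def test_mixed_segments_rejected(self):
        cn = [cn_est("a", 100), cn_est("b", 120, segment="28S")]
        with pytest.raises(ValueError, match="mixed segments"):
            per_bin_regression(cn, {"a": [], "b": []}, pd.DataFrame(index=["a", "b"]))

    def test_missing_covariate_raises(self):
        cn, bins, cov = self._cohort(12, lambda c, a, s, g: c / 10)
        cov.loc["s3", "age"] = np.nan
        with pytest.raises(ValueError, match="s3"):
            per_bin_regression(cn, bins, cov)

    def test_meth_as_response_direction(self):
        cn, bins, cov = self._cohort(12, lambda c, a, s, g: c / 10)
        (res,) = per_bin_regression(cn, bins, cov, meth_as_response=True)
        assert res.beta == pytest.approx(0.1, abs=1e-8)


# ------------------------------------------------------ group comparison

class TestGroupComparison:
    def _covariates(self, ids, groups, rng):
        return pd.DataFrame(
            {
                "age": rng.uniform(20, 80, size=len(ids)),
                "sex": rng.integers(0, 2, size=len(ids)),
                "group": groups,
            },
            index=ids,
        )

    def test_null_rejection_rate_close_to_alpha(self):
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 100
        for _ in range(reps):
            ids = [f"s{i}" for i in range(100)]
            groups = np.array([0] * 50 + [1] * 50)
            cns = rng.uniform(100, 300, size=100)
            cov = self._covariates(ids, groups, rng)
            res = group_comparison([cn_est(i, c) for i, c in zip(ids, cns)], cov)
            rejections += res.p_value < 0.05
        # binomial(100, .05): 3 SE band around 5
        assert rejections <= 5 + 3 * np.sqrt(100 * 0.05 * 0.95)

    def test_power_under_strong_shift(self):
        rng = np.random.default_rng(12)
        hits = 0
        reps = 40
        for _ in range(reps):
            ids = [f"s{i}" for i in range(60)]
            groups = np.array([0] * 30 + [1] * 30)
            # ~1.5 SD shift: strong effect but distributions still overlap
            cns = np.where(groups == 1, rng.normal(210, 40, 60), rng.normal(150, 40, 60))
            cov = self._covariates(ids, groups, rng)
            res = group_comparison([cn_est(i, c) for i, c in zip(ids, cns)], cov)
            hits += res.estimable and res.p_value < 0.05
        assert hits >= 0.95 * reps

    def test_constant_cn_non_estimable(self):
        rng = np.random.default_rng(13)
        ids = [f"s{i}" for i in range(20)]
        groups = np.array([0] * 10 + [1] * 10)
        cov = self._covariates(ids, groups, rng)
        res = group_comparison([cn_est(i, 200.0) for i in ids], cov)
        assert not res.estimable
        assert "constant" in res.diagnostic

    def test_too_few_samples(self):
        rng = np.random.default_rng(14)
        ids = [f"s{i}" for i in range(5)]
        cov = self._covariates(ids, np.array([0, 0, 1, 1, 1]), rng)
        with pytest.raises(ValueError, match=">= 8"):
            group_comparison([cn_est(i, 100 + k) for k, i in enumerate(ids)], cov)


# ------------------------------------------------- platform correlation

def oracle_spearman(a, b):
    """Average-rank Spearman via Pearson on ranks."""
    ra = sps.rankdata(a)
    rb = sps.rankdata(b)
    return np.corrcoef(ra, rb)[0, 1]


class TestPlatformCorrelation:
    def _pairs(self, va, vb):
        ids = [f"s{i}" for i in range(len(va))]
        return (
            [cn_est(i, v) for i, v in zip(ids, va)],
            [cn_est(i, v) for i, v in zip(ids, vb)],
        )

    def test_monotone_pairs(self):
        a, b = self._pairs([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        res = platform_correlation(a, b)
        assert res["spearman_r"] == pytest.approx(1.0)
        assert res["pearson_r2"] == pytest.approx(1.0)

    def test_reversed(self):
        a, b = self._pairs([1, 2, 3, 4], [8, 6, 4, 2])
        assert platform_correlation(a, b)["spearman_r"] == pytest.approx(-1.0)

    def test_unmatched_ids_listed(self):
        a = [cn_est("x", 1.0), cn_est("y", 2.0), cn_est("z", 3.0), cn_est("w", 4.0)]
        b = [cn_est("x", 1.0), cn_est("y", 2.0), cn_est("z", 3.0), cn_est("q", 4.0)]
        with pytest.raises(ValueError, match="q"):
            platform_correlation(a, b)

    def test_too_few_pairs(self):
        a, b = self._pairs([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match=">= 4"):
            platform_correlation(a, b)

    @settings(max_examples=50)
    @given(
        st.lists(st.integers(0, 20), min_size=4, max_size=30),
        st.randoms(use_true_random=False),
    )
    def test_matches_rank_oracle_with_ties(self, va, rnd):
        vb = [max(0, v + rnd.randint(-3, 3)) for v in va]
        if len(set(va)) < 2 or len(set(vb)) < 2:
            return  # correlation undefined for constant input
        a, b = self._pairs([float(v) for v in va], [float(v) for v in vb])
        res = platform_correlation(a, b)
        assert res["spearman_r"] == pytest.approx(oracle_spearman(va, vb))
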