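"""IVW, MR-Egger, leave-one-out, BH FDR and two-step chaining."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gutlink import (SingleInstrumentError, bh_fdr, leave_one_out, mr_egger,
                     mr_ivw, two_step_mr)

from conftest import build_harmonized


class TestIVW:
    def test_degenerate_agreement(self):
        h = build_harmonized(bx=[0.2, 0.4], by=[0.1, 0.2])
        res = mr_ivw(h)
        assert res.beta_ivw == pytest.approx(0.5)
        assert res.q_stat == pytest.approx(0.0, abs=1e-12)

    def test_single_iv_refused(self):
        h = build_harmonized(bx=[0.2], by=[0.1])
        with pytest.raises(SingleInstrumentError):
            mr_ivw(h)

    def test_zero_exposure_beta_dropped(self):
        h = build_harmonized(bx=[0.2, 0.0, 0.4], by=[0.1, 0.5, 0.2])
        assert mr_ivw(h).n_iv == 2

    @pytest.mark.parametrize("seed", range(100))
    def test_equals_weighted_regression_through_origin(self, seed):
        """Algebraic identity oracle: IVW == WLS of beta_out on beta_exp
        through the origin with weights se_out^-2."""
        rng = np.random.default_rng(seed)
        m = rng.integers(2, 12)
        bx = rng.uniform(0.05, 0.5, m) * rng.choice([-1, 1], m)
        by = rng.normal(0.3 * bx, 0.05)
        sey = rng.uniform(0.01, 0.1, m)
        h = build_harmonized(bx, by, sey=sey)
        res = mr_ivw(h, mode="fixed")
        # independent oracle: weighted least squares via lstsq
        w = np.sqrt(sey ** -2.0)
        slope = np.linalg.lstsq((w * bx)[:, None], w * by, rcond=None)[0][0]
        assert res.beta_ivw == pytest.approx(slope, rel=1e-10)

    def test_invariant_to_reordering_and_joint_sign_flip(self):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.1, 0.5, 6)
        by = rng.normal(0.2 * bx, 0.03)
        sey = rng.uniform(0.01, 0.05, 6)
        base = mr_ivw(build_harmonized(bx, by, sey=sey))
        perm = rng.permutation(6)
        res_p = mr_ivw(build_harmonized(bx[perm], by[perm], sey=sey[perm]))
        flip = np.array([1, -1, 1, -1, 1, 1])
        res_f = mr_ivw(build_harmonized(bx * flip, by * flip, sey=sey))
        for r in (res_p, res_f):
            assert r.beta_ivw == pytest.approx(base.beta_ivw)
            assert r.se_ivw == pytest.approx(base.se_ivw)
            assert r.q_stat == pytest.approx(base.q_stat)

    def test_fixed_equals_re_when_underdispersed(self):
        h = build_harmonized(bx=[0.2, 0.25, 0.3], by=[0.1, 0.125, 0.15])
        fixed = mr_ivw(h, mode="fixed")
        re = mr_ivw(h, mode="multiplicative_re")
        assert fixed.q_stat <= fixed.n_iv - 1
        assert re.se_ivw == pytest.approx(fixed.se_ivw)


class TestEgger:
    def test_two_ivs_screen_skipped(self, caplog):
        h = build_harmonized(bx=[0.2, 0.3], by=[0.1, 0.15])
        assert mr_egger(h) is None

    def test_exact_fit_recovers_intercept_and_slope(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.05 + 0.5 * bx  # exact directional pleiotropy, no noise
        res = mr_egger(build_harmonized(bx, by))
        assert res.intercept == pytest.approx(0.05, abs=1e-10)
        assert res.slope == pytest.approx(0.5, abs=1e-10)

    def test_intercept_p_uniform_without_pleiotropy(self):
        """Under InSIDE with normal errors the intercept p is exactly
        uniform; KS over 200 replicates at the 0.01 level."""
        rng = np.random.default_rng(10)
        pvals = []
        for _ in range(200):
            bx = rng.uniform(0.1, 0.5, 20)
            sey = rng.uniform(0.02, 0.05, 20)
            by = rng.normal(0.3 * bx, sey)
            pvals.append(mr_egger(build_harmonized(bx, by, sey=sey)).intercept_p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_orientation_independence(self):
        """Egger orients all exposure betas positive; flipping an IV's
        allele coding leaves the result unchanged."""
        rng = np.random.default_rng(4)
        bx = rng.uniform(0.1, 0.4, 8)
        by = rng.normal(0.02 + 0.3 * bx, 0.03)
        base = mr_egger(build_harmonized(bx, by))
        flip = np.ones(8); flip[[1, 5]] = -1
        res = mr_egger(build_harmonized(bx * flip, by * flip))
        assert res.intercept == pytest.approx(base.intercept)
        assert res.intercept_p == pytest.approx(base.intercept_p)


class TestLeaveOneOut:
    def test_cardinality(self):
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.1, 0.4, 5)
        by = rng.normal(0.3 * bx, 0.02)
        loo, flagged = leave_one_out(build_harmonized(bx, by))
        assert len(loo) == 5

    def test_identical_ratios_no_flags(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        loo, flagged = leave_one_out(build_harmonized(bx, 0.5 * bx))
        assert not flagged
        assert np.allclose(loo["beta"], 0.5)

    def test_outlier_produces_largest_delta(self):
        bx = np.full(10, 0.2)
        by = np.full(10, 0.1)
        by[7] = 1.4  # gross outlier ratio
        loo, _ = leave_one_out(build_harmonized(bx, by))
        assert loo["delta_beta"].abs().idxmax() == 7

    def test_below_three_ivs_not_applicable(self):
        loo, flagged = leave_one_out(build_harmonized([0.2, 0.3], [0.1, 0.15]))
        assert loo is None and flagged is None


def _bh_oracle(p):
    """Brute-force BH step-up."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


class TestBH:
    def test_known_vector(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_empty(self):
        assert len(bh_fdr([])) == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_stepup_oracle_and_monotone(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1, rng.integers(1, 40))
        q = bh_fdr(p)
        np.testing.assert_allclose(q, _bh_oracle(p), atol=1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_scoped_groups_are_independent(self):
        p = np.array([0.01, 0.04, 0.01, 0.04])
        labels = ["a", "a", "b", "b"]
        q = bh_fdr(p, labels)
        np.testing.assert_allclose(q[:2], _bh_oracle(p[:2]))
        np.testing.assert_allclose(q[2:], _bh_oracle(p[2:]))


class TestTwoStep:
    def _step_frames(self, p2=1e-4):
        step1 = pd.DataFrame({"gene": ["g1"], "genus": ["m1"],
                              "beta": [0.4], "se": [0.05],
                              "fdr_ok": [True], "egger_ok": [True],
                              "heidi_ok": [True]})
        step2 = pd.DataFrame({"genus": ["m1"], "trait": ["t1"],
                              "beta": [0.5], "se": [0.05], "pval": [p2]})
        return step1, step2

    def test_supported_triad_present_with_chained_effect(self):
        out = two_step_mr(*self._step_frames())
        assert len(out) == 1
        assert out["beta_chain"].iloc[0] == pytest.approx(0.2)
        se = np.sqrt(0.5 ** 2 * 0.05 ** 2 + 0.4 ** 2 * 0.05 ** 2)
        assert out["se_chain"].iloc[0] == pytest.approx(se)

    def test_nonsignificant_step2_absent(self):
        out = two_step_mr(*self._step_frames(p2=0.2))
        assert out.empty

    def test_failed_step1_qc_absent(self):
        s1, s2 = self._step_frames()
        s1["heidi_ok"] = False
        assert two_step_mr(s1, s2).empty
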