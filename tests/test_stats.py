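"""ICC(3,k), LME group inference, FDR, effect sizes and summary t-tests."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from relconn.stats import (bh_fdr, classify_icc, cohens_f2,
                           correlate_with_psychometrics, fit_lme, icc_3k,
                           lme_table, reliability_grid, screen_reliability,
                           t_from_summary)


class TestICC:
    def test_duplicated_rows_give_exactly_one(self):
        grid = np.tile([1.0, 2.0, 3.0, 7.0], (40, 1))
        assert icc_3k(grid) == 1.0

    def test_hand_anova_worked_example(self):
        # 2 raters x 3 targets, reversed second rater:
        # grand=2, BMS: col means (2,2,2) -> ss_targets=0 -> ICC undefined
        assert np.isnan(icc_3k(np.array([[1., 2., 3.], [3., 2., 1.]])))
        # grid with genuine target variance, mean squares computed by hand
        M = np.array([[1.0, 2.0, 4.0],
                      [2.0, 3.0, 6.0]])
        k, n = 2, 3
        grand = M.mean()
        bms = k * ((M.mean(axis=0) - grand) ** 2).sum() / (n - 1)
        jms = n * ((M.mean(axis=1) - grand) ** 2).sum()
        ems = (((M - grand) ** 2).sum() - bms * (n - 1) - jms) / ((n - 1) * (k - 1))
        assert icc_3k(M) == pytest.approx((bms - ems) / bms, abs=1e-10)

    def test_matches_pingouin_icc3k(self, rng):
        pingouin = pytest.importorskip("pingouin")
        M = rng.standard_normal((5, 8)) + np.linspace(0, 3, 8)
        df = pd.DataFrame([
            {"rater": i, "target": j, "score": M[i, j]}
            for i in range(5) for j in range(8)])
        out = pingouin.intraclass_corr(df, targets="target", raters="rater",
                                       ratings="score")
        # two-way mixed, consistency, average-measures ("ICC(C,k)" / ICC3k)
        mask = out["Type"].isin(["ICC3k", "ICC(C,k)"])
        ref = out.loc[mask, "ICC"].iloc[0]
        assert icc_3k(M) == pytest.approx(ref, abs=1e-10)

    def test_location_scale_invariance(self, rng):
        M = rng.standard_normal((6, 10))
        base = icc_3k(M)
        assert icc_3k(3.0 * M + 7.0) == pytest.approx(base, abs=1e-12)

    def test_null_grid_centered_near_zero(self):
        # many targets: the small-sample bias of (BMS-EMS)/BMS is ~ -2/(n-3)
        vals = [icc_3k(np.random.default_rng(s).standard_normal((10, 100)))
                for s in range(100)]
        assert abs(np.mean(vals)) < 0.05

    def test_shape_preconditions(self):
        with pytest.raises(ValueError):
            icc_3k(np.ones((1, 5)))


class TestClassify:
    @pytest.mark.parametrize("icc,label", [
        (0.39, "poor"), (0.40, "fair"), (0.59, "fair"), (0.60, "good"),
        (0.74, "good"), (0.75, "excellent"), (0.95, "excellent"),
        (-0.2, "poor"), (float("nan"), "undefined"),
    ])
    def test_bins(self, icc, label):
        assert classify_icc(icc) == label


def _lme_data(beta1=-0.01, sigma_u=0.005, sigma=0.01, n_sub=19, n_epoch=40,
              seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for gi, gname in enumerate(("Control", "Miners")):
        for s in range(n_sub):
            u = rng.normal(0, sigma_u)
            base = 0.5 + beta1 * gi + u
            for e in range(n_epoch):
                rows.append({"subject_id": f"{gname[0]}{s:02d}",
                             "group": gname, "epoch": e + 1,
                             "value": base + rng.normal(0, sigma)})
    return pd.DataFrame(rows)


class TestLME:
    def test_exchangeable_subjects_reduce_to_group_mean_difference(self):
        df = _lme_data(beta1=-0.02, sigma_u=0.0, sigma=0.01, n_sub=8,
                       n_epoch=10, seed=1)
        res = fit_lme(df)
        raw_diff = (df.query("group == 'Miners'")["value"].mean()
                    - df.query("group == 'Control'")["value"].mean())
        assert res.beta1 == pytest.approx(raw_diff, abs=1e-8)

    def test_ci_contains_point_estimate_and_brackets_truth(self):
        res = fit_lme(_lme_data(seed=2))
        assert res.ci_low <= res.beta1 <= res.ci_high
        assert res.ci_low <= -0.01 <= res.ci_high

    def test_coverage_quick_check(self):
        hits = 0
        for seed in range(60):
            res = fit_lme(_lme_data(seed=seed))
            hits += res.ci_low <= -0.01 <= res.ci_high
        assert hits >= 50        # ~95% nominal; full sweep in acceptance

    def test_variance_components_recovered(self):
        res = fit_lme(_lme_data(sigma_u=0.005, sigma=0.01, seed=3))
        assert res.sigma2 == pytest.approx(0.01**2, rel=0.2)
        assert res.sigma_u2 == pytest.approx(0.005**2, rel=0.8)

    def test_one_group_rejected(self):
        df = _lme_data().query("group == 'Miners'")
        with pytest.raises(ValueError, match="two groups"):
            fit_lme(df)


class TestCohensF2:
    def test_zero_effect_gives_zero(self):
        df = _lme_data(beta1=0.0, sigma_u=0.003, seed=4)
        res = fit_lme(df)
        assert res.f2 < 0.02

    def test_closed_form_partition(self):
        # construct an LMEResult whose fixed-effect share of variance is 13%
        from relconn.stats import LMEResult

        df = pd.DataFrame({
            "group": ["Control"] * 50 + ["Miners"] * 50,
            "subject_id": ["a"] * 50 + ["b"] * 50,
            "Value": 0.0,
        })
        beta1 = 1.0
        var_fixed = beta1**2 / 4              # balanced two-group indicator
        total_rest = var_fixed * (1 - 0.13) / 0.13
        res = LMEResult(0.0, beta1, 0, 0, 1.0, total_rest / 2, total_rest / 2,
                        float("nan"), False)
        f2 = cohens_f2(res, df)
        assert f2 == pytest.approx(0.13 / 0.87, rel=1e-10)

    def test_monotone_in_effect_size(self):
        f2s = [fit_lme(_lme_data(beta1=b, seed=5)).f2
               for b in (0.0, -0.005, -0.01, -0.02)]
        assert all(a < b for a, b in zip(f2s, f2s[1:]))


def _oracle_bh(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        val = min(prev, p[idx] * m / rank)
        adj[idx] = val
        prev = val
    return adj


class TestFDR:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.3]), [0.3])

    def test_matches_independent_step_up_oracle(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(2, 30))
            np.testing.assert_allclose(bh_fdr(p), _oracle_bh(p), atol=1e-12)

    def test_adjusted_not_below_raw_and_order_preserving(self, rng):
        p = rng.random(25)
        adj = bh_fdr(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestCorrelations:
    def test_exact_negative_relation(self):
        x = pd.DataFrame({"idx": np.arange(10.0)}, index=[f"s{i}" for i in range(10)])
        y = pd.DataFrame({"score": -np.arange(10.0)}, index=x.index)
        out = correlate_with_psychometrics(x, y)
        assert out["r"].iloc[0] == pytest.approx(-1.0)
        assert out["p_fdr"].iloc[0] < 1e-6

    def test_power_at_generator_effect_size(self):
        # |r_true| = 0.6, n = 19: recovered significant in most seeds
        hits, sign_ok = 0, 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            z = rng.standard_normal(19)
            e = rng.standard_normal(19)
            y = -0.6 * (z - z.mean()) / z.std() + np.sqrt(1 - 0.36) * e
            x = pd.DataFrame({"idx": z}, index=[f"s{i}" for i in range(19)])
            s = pd.DataFrame({"recall": y}, index=x.index)
            out = correlate_with_psychometrics(x, s)
            sign_ok += out["r"].iloc[0] < 0
            hits += bool(out["significant"].iloc[0])
        assert sign_ok >= 0.9 * n_seeds
        assert hits >= 0.7 * n_seeds

    def test_null_false_positive_rate_controlled(self):
        fp = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            x = pd.DataFrame({"idx": rng.standard_normal(19)},
                             index=[f"s{i}" for i in range(19)])
            s = pd.DataFrame({"a": rng.standard_normal(19),
                              "b": rng.standard_normal(19)}, index=x.index)
            out = correlate_with_psychometrics(x, s)
            fp += int(out["significant"].sum() > 0)
        assert fp / n_seeds <= 0.10

    def test_zero_variance_flagged(self):
        x = pd.DataFrame({"idx": np.ones(6)}, index=[f"s{i}" for i in range(6)])
        y = pd.DataFrame({"score": np.arange(6.0)}, index=x.index)
        out = correlate_with_psychometrics(x, y)
        assert np.isnan(out["r"].iloc[0])


class TestSummaryT:
    def test_education_row_equal_summaries(self):
        t, p = t_from_summary(12.63, 2.00, 19, 12.63, 2.00, 19)
        assert t == 0.0 and p == 1.0

    def test_equal_means_any_sds(self):
        t, _ = t_from_summary(5.0, 1.0, 10, 5.0, 3.0, 12)
        assert t == 0.0

    def test_hand_pooled_variance_example(self):
        t, p = t_from_summary(10, 2, 4, 8, 2, 4)
        assert t == pytest.approx(np.sqrt(2.0))
        assert p == pytest.approx(2 * scipy.stats.t.sf(np.sqrt(2.0), 6))

    def test_degenerate_zero_sd_convention(self):
        assert t_from_summary(3, 0, 5, 3, 0, 5) == (0.0, 1.0)


class TestGridsAndScreening:
    def _long_table(self, rng, icc_high=True):
        rows = []
        for g in ("Control", "Miners"):
            for s in range(5):
                subj_mean = (s if icc_high else 0.0)
                for e in range(6):
                    rows.append({
                        "group": g, "state": "EC", "cleaning": "ASR",
                        "measure": "DTF", "band": "full", "index_name": "GE",
                        "subject_id": f"{g[0]}{s}", "epoch": e + 1,
                        "value": subj_mean + rng.standard_normal() * 0.1})
        return pd.DataFrame(rows)

    def test_reliability_grid_and_screen(self, rng):
        grid = reliability_grid(self._long_table(rng, icc_high=True))
        assert set(grid["group"]) == {"Control", "Miners"}
        assert (grid["icc"] > 0.9).all()
        screened = screen_reliability(grid, 0.6)
        assert len(screened) == 1

    def test_unreliable_cells_screened_out(self, rng):
        grid = reliability_grid(self._long_table(rng, icc_high=False))
        screened = screen_reliability(grid, 0.6)
        assert len(screened) == 0

    def test_lme_table_applies_fdr_across_cells(self, rng):
        lt = pd.concat([
            self._long_table(rng).assign(band="full"),
            self._long_table(rng).assign(band="alpha")])
        out = lme_table(lt)
        assert len(out) == 2
        assert (out["p_fdr"] >= out["p"] - 1e-15).all()
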