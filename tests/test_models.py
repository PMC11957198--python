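"""Association-engine oracles: closed forms, calibration, power, symmetry."""

import numpy as np
import pandas as pd
import pytest

from sextwas import models as mo
from sextwas import simulate as sim

IDX = lambda n, p="s": pd.Index([f"{p}{i}" for i in range(n)])  # noqa: E731


def make_visits(g, seed, n_visits=8, slope_sd=0.05, noise_sd=0.25,
                intercept_sd=0.6, gene_time=0.0, sex=None, sex_gene_time=None,
                apoe=None, apoe_terms=None):
    """Simulate trajectories from the exact mixed model."""
    rng = np.random.default_rng(seed)
    rows = []
    for i, d in enumerate(g.index):
        u = rng.normal(0, intercept_sd)
        v = rng.normal(0, slope_sd)
        slope = -0.05 + v + gene_time * g[d]
        if sex is not None and sex_gene_time is not None and sex[d] == "male":
            slope += sex_gene_time * g[d]
        if apoe is not None and apoe_terms is not None:
            slope += apoe_terms.get((sex[d], int(apoe[d])), 0.0) * g[d]
        t = -np.arange(n_visits - 1, -1, -1.0)
        y = 0.2 + u + 0.1 * g[d] + slope * t + rng.normal(0, noise_sd, n_visits)
        for tt, yy in zip(t, y):
            rows.append((d, tt, yy))
    df = pd.DataFrame(rows, columns=["decedent_id", "time", "cognition"])
    df.insert(1, "visit", df.groupby("decedent_id").cumcount())
    return df


class TestCrossSectional:
    def test_toy_slope_matches_normal_equations(self):
        x = pd.Series([-2, -1, 0, 0, 1, 2.0], index=IDX(6))
        y = 2 * x + pd.Series([0.1, -0.1, 0.1, -0.1, 0.1, -0.1], index=IDX(6))
        res = mo.fit_cross_sectional(x, y)
        beta_oracle = (x * y).sum() / (x * x).sum()  # centered x: closed form
        assert res.beta == pytest.approx(beta_oracle, abs=1e-6)
        assert res.beta == pytest.approx(2.0, abs=0.05)

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(0)
        n_rep, n = 1000, 100
        # replicates vectorized through the screen: each gene its own x,
        # outcome refreshed per block of independent replicates
        rej = 0
        for block in range(10):
            expr = pd.DataFrame(rng.standard_normal((n_rep // 10, n)),
                                index=IDX(n_rep // 10, "g"), columns=IDX(n))
            y = pd.Series(rng.standard_normal(n), index=IDX(n))
            res = mo.cross_sectional_screen(expr, y)
            rej += (res.p < 0.05).sum()
        rate = rej / n_rep
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep) + 0.01

    def test_slope_invariant_to_covariate_shift(self):
        rng = np.random.default_rng(1)
        n = 60
        x = pd.Series(rng.standard_normal(n), index=IDX(n))
        cov = pd.DataFrame({"a": rng.standard_normal(n)}, index=IDX(n))
        y = pd.Series(rng.standard_normal(n), index=IDX(n))
        r1 = mo.fit_cross_sectional(x, y, cov)
        r2 = mo.fit_cross_sectional(x + 7.0, y, cov + 3.0)
        assert r2.beta == pytest.approx(r1.beta, abs=1e-10)

    def test_zero_variance_gene_flagged(self):
        x = pd.Series(1.0, index=IDX(20))
        y = pd.Series(np.random.default_rng(2).standard_normal(20), index=IDX(20))
        res = mo.fit_cross_sectional(x, y)
        assert not res.estimable

    def test_screen_matches_statsmodels_per_gene(self):
        rng = np.random.default_rng(3)
        n = 50
        expr = pd.DataFrame(rng.standard_normal((8, n)), index=IDX(8, "g"),
                            columns=IDX(n))
        y = pd.Series(rng.standard_normal(n), index=IDX(n))
        cov = pd.DataFrame({"a": rng.standard_normal(n),
                            "b": rng.choice(["x", "y"], n)}, index=IDX(n))
        scr = mo.cross_sectional_screen(expr, y, cov)
        for gi in range(8):
            ref = mo.fit_cross_sectional(expr.iloc[gi], y, cov)
            row = scr.iloc[gi]
            assert row.beta == pytest.approx(ref.beta, abs=1e-10)
            assert row.se == pytest.approx(ref.se, abs=1e-10)
            assert row.p == pytest.approx(ref.p, abs=1e-10)

    def test_p_consistent_with_statistic(self):
        from scipy import stats
        rng = np.random.default_rng(4)
        n = 40
        x = pd.Series(rng.standard_normal(n), index=IDX(n))
        y = pd.Series(0.3 * x + rng.standard_normal(n), index=IDX(n))
        res = mo.fit_cross_sectional(x, y)
        assert res.p == pytest.approx(
            2 * stats.t.sf(abs(res.statistic), res.df), abs=1e-8)


class TestLongitudinal:
    def test_parameter_recovery(self):
        """Simulating from the exact model recovers gene x time = 0.05."""
        est = []
        for s in range(30):
            rng = np.random.default_rng(100 + s)
            g = pd.Series(rng.standard_normal(150), index=IDX(150, "d"))
            visits = make_visits(g, seed=s, gene_time=0.05)
            res = mo.fit_longitudinal(g, visits)
            est.append(res.beta)
        est = np.asarray(est)
        mc_se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 0.05) < 2 * mc_se + 1e-12

    def test_single_visit_design_flagged(self):
        g = pd.Series([0.5, -0.5, 1.0], index=IDX(3, "d"))
        visits = pd.DataFrame({
            "decedent_id": [f"d{i}" for i in range(3)],
            "visit": [0, 0, 0], "time": [0.0, 0.0, 0.0],
            "cognition": [0.1, -0.2, 0.3],
        })
        res = mo.fit_longitudinal(g, visits)
        assert not res.estimable

    def test_zero_random_effects_agrees_with_ols(self):
        rng = np.random.default_rng(5)
        g = pd.Series(rng.standard_normal(120), index=IDX(120, "d"))
        visits = make_visits(g, seed=6, slope_sd=0.0, intercept_sd=0.0,
                             noise_sd=0.3, gene_time=0.04)
        res = mo.fit_longitudinal(g, visits)
        # OLS on the identical fixed-effect design
        d = visits.copy()
        d["g"] = d.decedent_id.map(g)
        X = np.column_stack([np.ones(len(d)), d.g, d.time, d.g * d.time])
        beta_ols = np.linalg.lstsq(X, d.cognition.to_numpy(), rcond=None)[0][3]
        assert res.beta == pytest.approx(beta_ols, abs=1e-4)

    def test_screen_tracks_full_mixed_model(self):
        rng = np.random.default_rng(7)
        g0 = pd.Series(rng.standard_normal(150), index=IDX(150, "d"))
        expr = pd.DataFrame(
            rng.standard_normal((4, 150)), index=IDX(4, "g"), columns=g0.index)
        expr.iloc[0] = g0
        visits = make_visits(g0, seed=8, gene_time=0.06)
        scr = mo.longitudinal_screen(expr, visits, None)
        full = mo.fit_longitudinal(expr.iloc[0], visits, None)
        row = scr.iloc[0]
        assert row.beta == pytest.approx(full.beta, rel=0.15, abs=0.01)
        assert row.p < 0.01 and full.p < 0.01


class TestInteraction:
    def _pooled(self, seed, n=150, f_eff=0.4, m_eff=0.0):
        rng = np.random.default_rng(seed)
        idx = IDX(2 * n, "d")
        sex = pd.Series(["female"] * n + ["male"] * n, index=idx)
        g = pd.Series(rng.standard_normal(2 * n), index=idx)
        eff = np.where(sex == "female", f_eff, m_eff)
        y = pd.Series(eff * g + rng.standard_normal(2 * n), index=idx)
        return g, y - y.mean(), sex

    def test_sex_label_swap_flips_beta_sign(self):
        g, y, sex = self._pooled(9)
        r1 = mo.fit_interaction(g, outcome=y, covariates=None, sex=sex)
        swapped = sex.map({"female": "male", "male": "female"})
        r2 = mo.fit_interaction(g, outcome=y, covariates=None, sex=swapped)
        assert r2.beta == pytest.approx(-r1.beta, abs=1e-10)
        assert r2.p == pytest.approx(r1.p, abs=1e-10)

    def test_power_for_female_only_effect(self):
        hits = 0
        n_rep = 200
        for s in range(n_rep):
            g, y, sex = self._pooled(1000 + s)
            res = mo.fit_interaction(g, outcome=y, covariates=None, sex=sex)
            hits += res.p < 0.05
        assert hits / n_rep >= 0.8

    def test_type_one_error_for_shared_effect(self):
        rej = 0
        n_rep = 200
        for s in range(n_rep):
            g, y, sex = self._pooled(2000 + s, f_eff=0.4, m_eff=0.4)
            res = mo.fit_interaction(g, outcome=y, covariates=None, sex=sex)
            rej += res.p < 0.05
        rate = rej / n_rep
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep) + 0.01

    def test_single_sex_rejected(self):
        g, y, sex = self._pooled(10)
        only_f = sex[sex == "female"].index
        with pytest.raises(ValueError, match="both sexes"):
            mo.fit_interaction(g.loc[only_f], outcome=y.loc[only_f],
                               covariates=None, sex=sex.loc[only_f])

    def test_screen_matches_single_fits(self):
        g, y, sex = self._pooled(11, n=60)
        expr = g.to_frame().T.set_axis(["g0"])
        scr = mo.interaction_screen(expr, y, sex)
        ref = mo.fit_interaction(g, outcome=y, covariates=None, sex=sex)
        assert scr.iloc[0].beta == pytest.approx(ref.beta, abs=1e-8)
        assert scr.iloc[0].p == pytest.approx(ref.p, abs=1e-8)


class TestThreeWay:
    def _dataset(self, seed, n_cell=150, carrier_male_eff=0.0):
        rng = np.random.default_rng(seed)
        idx = IDX(4 * n_cell, "d")
        sex = pd.Series((["female"] * (2 * n_cell)) + (["male"] * (2 * n_cell)),
                        index=idx)
        apoe = pd.Series(([0] * n_cell + [1] * n_cell) * 2, index=idx)
        g = pd.Series(rng.standard_normal(4 * n_cell), index=idx)
        visits = make_visits(
            g, seed=seed + 1, sex=sex, apoe=apoe,
            apoe_terms={("male", 1): carrier_male_eff})
        return g, visits, sex, apoe

    def test_power_for_male_carrier_effect(self):
        hits = 0
        n_rep = 25
        for s in range(n_rep):
            g, visits, sex, apoe = self._dataset(3000 + s,
                                                 carrier_male_eff=0.12)
            res = mo.fit_three_way(g, visits, None, sex=sex, apoe_positive=apoe)
            hits += res.p < 0.05
        assert hits / n_rep >= 0.8

    def test_null_rejection_near_alpha(self):
        rej = 0
        n_rep = 25
        for s in range(4000, 4000 + n_rep):
            g, visits, sex, apoe = self._dataset(s)
            res = mo.fit_three_way(g, visits, None, sex=sex, apoe_positive=apoe)
            rej += res.p < 0.05
        # binomial(25, 0.05): >= 6 rejections has probability < 1e-3
        assert rej <= 5

    def test_constant_apoe_rejected(self):
        g, visits, sex, apoe = self._dataset(5000, n_cell=10)
        with pytest.raises(ValueError, match="constant|cell"):
            mo.fit_three_way(g, visits, None, sex=sex,
                             apoe_positive=pd.Series(0, index=apoe.index))

    def test_subgroup_slopes_reflect_planted_cell(self):
        g, visits, sex, apoe = self._dataset(6000, carrier_male_eff=0.15)
        res = mo.fit_three_way(g, visits, None, sex=sex, apoe_positive=apoe)
        slopes = res.extra["subgroup_slopes"]
        assert slopes["male_apoe1"] == max(slopes.values())


class TestSensitivity:
    def _base(self, seed, n=120, confounded=False):
        rng = np.random.default_rng(seed)
        idx = IDX(n)
        c = pd.Series(rng.standard_normal(n), index=idx)
        if confounded:
            g = 0.8 * c + 0.6 * pd.Series(rng.standard_normal(n), index=idx)
            y = 0.8 * c + 0.6 * pd.Series(rng.standard_normal(n), index=idx)
        else:
            g = pd.Series(rng.standard_normal(n), index=idx)
            y = 0.4 * g + pd.Series(rng.standard_normal(n), index=idx)
        return g, y - y.mean(), pd.DataFrame({"c": c})

    def test_empty_extra_set_identical_to_base(self):
        g, y, cov = self._base(12)
        base = mo.fit_cross_sectional(g, y)
        sens = mo.sensitivity_refit("cross_sectional", g, y, None,
                                    pd.DataFrame(index=y.index))
        assert sens.beta == pytest.approx(base.beta, abs=1e-12)

    def test_orthogonal_covariate_barely_moves_beta(self):
        shifts = []
        for s in range(100):
            g, y, cov = self._base(100 + s)
            base = mo.fit_cross_sectional(g, y)
            sens = mo.sensitivity_refit("cross_sectional", g, y, None, cov)
            shifts.append(abs(sens.beta - base.beta))
        assert np.mean(shifts) < 0.02

    def test_confounder_kills_association(self):
        lost = 0
        n_rep = 100
        for s in range(n_rep):
            g, y, cov = self._base(200 + s, confounded=True)
            base = mo.fit_cross_sectional(g, y)
            sens = mo.sensitivity_refit("cross_sectional", g, y, None, cov)
            if base.p <= 0.05:
                lost += sens.p > 0.05
        assert lost / n_rep >= 0.90

    def test_outcome_as_covariate_rejected(self):
        g, y, _ = self._base(13)
        with pytest.raises(ValueError, match="identical to the outcome"):
            mo.sensitivity_refit("cross_sectional", g, y, None,
                                 pd.DataFrame({"y": y}))


class TestWilcoxon:
    def test_exact_small_sample(self):
        x = pd.Series([1, 2, 3, 4, 5, 6.0], index=IDX(6))
        sex = pd.Series(["female"] * 3 + ["male"] * 3, index=IDX(6))
        _, p = mo.wilcoxon_sex_difference(x, sex)
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_p_one(self):
        x = pd.Series([1, 2, 3, 1, 2, 3.0], index=IDX(6))
        sex = pd.Series(["female"] * 3 + ["male"] * 3, index=IDX(6))
        _, p = mo.wilcoxon_sex_difference(x, sex)
        assert p == pytest.approx(1.0)

    def test_large_sample_null_calibrated(self):
        rng = np.random.default_rng(14)
        rej = 0
        n_rep = 1000
        for _ in range(n_rep):
            x = pd.Series(rng.standard_normal(60), index=IDX(60))
            sex = pd.Series(["female"] * 30 + ["male"] * 30, index=IDX(60))
            _, p = mo.wilcoxon_sex_difference(x, sex)
            rej += p < 0.05
        assert abs(rej / n_rep - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep) + 0.005

    def test_empty_group_rejected(self):
        x = pd.Series([1.0, 2.0], index=IDX(2))
        sex = pd.Series(["female", "female"], index=IDX(2))
        with pytest.raises(ValueError, match="both sexes"):
            mo.wilcoxon_sex_difference(x, sex)


class TestStratifiedInteractionCoherence:
    def test_equal_effects_agree_between_sexes(self):
        """Shared effects: stratified betas agree and interaction covers 0."""
        rng = np.random.default_rng(15)
        gaps, covered = [], 0
        n_rep = 60
        for s in range(n_rep):
            n = 150
            idx = IDX(2 * n, "d")
            sex = pd.Series(["female"] * n + ["male"] * n, index=idx)
            g = pd.Series(rng.standard_normal(2 * n), index=idx)
            y = 0.3 * g + pd.Series(rng.standard_normal(2 * n), index=idx)
            y -= y.mean()
            rf = mo.fit_cross_sectional(g[sex == "female"], y[sex == "female"])
            rm = mo.fit_cross_sectional(g[sex == "male"], y[sex == "male"])
            ri = mo.fit_interaction(g, outcome=y, covariates=None, sex=sex)
            gaps.append(rf.beta - rm.beta)
            lo, hi = ri.beta - 1.96 * ri.se, ri.beta + 1.96 * ri.se
            covered += lo <= 0 <= hi
        assert abs(np.mean(gaps)) < 3 * np.std(gaps, ddof=1) / np.sqrt(n_rep)
        assert covered / n_rep > 0.88
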