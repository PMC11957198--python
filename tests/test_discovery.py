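"""Partitioned FDR, the sex-specificity rule, tallies, and their invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from sextwas import discovery as dc
from sextwas import models as mo


def bh_oracle(p):
    """Definition-based step-up, written independently with explicit loops."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    running_min = float("inf")
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, m * p[i] / rank)
        q[i] = min(running_min, 1.0)
    return np.array(q)


class TestBH:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.5], [0.5]),
            ([1.0, 1.0], [1.0, 1.0]),
        ],
    )
    def test_examples(self, p, expected):
        assert np.allclose(dc.bh_adjust(p), expected)

    def test_matches_definition_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            k = rng.integers(1, 9)
            p = rng.random(k) * 0.999 + 1e-6
            assert np.max(np.abs(dc.bh_adjust(p) - bh_oracle(p))) < 1e-12

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(1)
        p = rng.random(500) * 0.999 + 1e-6
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(dc.bh_adjust(p), ref, atol=1e-12)

    def test_invalid_p_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.2], [np.nan, 0.3]):
            with pytest.raises(ValueError):
                dc.bh_adjust(bad)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0,
                              exclude_min=False), min_size=1, max_size=8))
    def test_oracle_agreement_property(self, p):
        assert np.max(np.abs(dc.bh_adjust(p) - bh_oracle(p))) < 1e-12

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(2)
        p = rng.random(50) * 0.999 + 1e-6
        q = dc.bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestFamilies:
    def _frame(self, pvals, fams):
        return pd.DataFrame({
            "p": pvals,
            "region": [f[0] for f in fams],
            "outcome": "tau",
            "stratum": "female",
            "chromosome_class": [f[1] for f in fams],
        })

    def test_per_family_adjustment_values(self):
        df = self._frame([0.01, 0.04, 0.01, 0.04],
                         [("A", "autosomal")] * 2 + [("A", "X")] * 2)
        out = dc.adjust_by_family(df)
        assert np.allclose(out["p_fdr"], [0.02, 0.04, 0.02, 0.04])

    def test_partition_changes_adjustment(self):
        # a small X family is not swamped by a larger autosomal one
        df = self._frame([0.012, 0.011, 0.013, 0.04],
                         [("A", "autosomal")] * 3 + [("A", "X")])
        out = dc.adjust_by_family(df)
        pooled = dc.bh_adjust(df["p"].to_numpy())
        assert out["p_fdr"].iloc[3] == pytest.approx(0.04)
        assert pooled[3] == pytest.approx(0.04)
        assert not np.allclose(out["p_fdr"].to_numpy(), pooled)

    def test_family_of_one_is_identity(self):
        df = self._frame([0.037], [("A", "autosomal")])
        out = dc.adjust_by_family(df)
        assert out["p_fdr"].iloc[0] == pytest.approx(0.037)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        df = self._frame(
            rng.random(40) * 0.999 + 1e-6,
            [("A", "autosomal")] * 20 + [("B", "X")] * 20)
        out1 = dc.adjust_by_family(df)
        perm = rng.permutation(40)
        out2 = dc.adjust_by_family(df.iloc[perm])
        merged = out1["p_fdr"].to_numpy()[perm]
        assert np.allclose(merged, out2["p_fdr"].to_numpy())

    def test_missing_family_key_rejected(self):
        with pytest.raises(ValueError, match="family"):
            dc.adjust_by_family(pd.DataFrame({"p": [0.1]}))


def _res(gene="g", region="DLPFC", outcome="tau", **kw):
    defaults = dict(stratum="female", beta=0.1, se=0.05, statistic=2.0,
                    p=0.05, n=100, df=98, model="ols")
    defaults.update(kw)
    return mo.AssociationResult(gene=gene, outcome=outcome, region=region,
                                **defaults)


class TestClassifier:
    def test_female_specific_rule(self):
        call = dc.classify_sex_specific(
            _res(p_fdr=0.03), _res(stratum="male", p_fdr=0.40),
            _res(stratum="interaction", p=0.01))
        assert call.category == "female_specific"

    def test_both_significant_is_both_sexes(self):
        call = dc.classify_sex_specific(
            _res(p_fdr=0.03), _res(stratum="male", p_fdr=0.04),
            _res(stratum="interaction", p=0.001))
        assert call.category == "both_sexes"

    def test_failed_interaction_screen_not_called(self):
        call = dc.classify_sex_specific(
            _res(p_fdr=0.03), _res(stratum="male", p_fdr=0.40),
            _res(stratum="interaction", p=0.20))
        assert call.category == "not_significant"

    def test_stringent_tier_requires_interaction_fdr(self):
        loose = dc.classify_sex_specific(
            _res(p_fdr=0.03), _res(stratum="male", p_fdr=0.40),
            _res(stratum="interaction", p=0.01, p_fdr=0.30))
        tight = dc.classify_sex_specific(
            _res(p_fdr=0.03), _res(stratum="male", p_fdr=0.40),
            _res(stratum="interaction", p=0.01, p_fdr=0.08))
        assert not loose.stringent and tight.stringent

    def test_missing_result_not_evaluable(self):
        call = dc.classify_sex_specific(_res(p_fdr=0.03), None,
                                        _res(stratum="interaction", p=0.01))
        assert call.category == "not_evaluable"

    def test_table_classifier_agrees_with_scalar_rule(self):
        rng = np.random.default_rng(4)
        n = 200
        genes = [f"g{i}" for i in range(n)]
        def tbl(stratum, with_fdr=True):
            d = pd.DataFrame({
                "gene": genes, "region": "PCC", "outcome": "tau",
                "stratum": stratum, "beta": rng.standard_normal(n),
                "p": rng.random(n) * 0.999 + 1e-6,
            })
            d["p_fdr"] = rng.random(n) * 0.999 + 1e-6 if with_fdr else np.nan
            return d
        fem, mal, inter = tbl("female"), tbl("male"), tbl("interaction")
        calls = dc.classify_table(fem, mal, inter)
        for i in rng.integers(0, n, 30):
            g = genes[i]
            scalar = dc.classify_sex_specific(
                _res(gene=g, region="PCC",
                     p_fdr=fem.loc[fem.gene == g, "p_fdr"].iloc[0]),
                _res(gene=g, region="PCC", stratum="male",
                     p_fdr=mal.loc[mal.gene == g, "p_fdr"].iloc[0]),
                _res(gene=g, region="PCC", stratum="interaction",
                     p=inter.loc[inter.gene == g, "p"].iloc[0],
                     p_fdr=inter.loc[inter.gene == g, "p_fdr"].iloc[0]))
            assert calls.loc[calls.gene == g, "category"].iloc[0] == scalar.category

    def test_label_symmetry(self):
        """Swapping sexes swaps female_specific <-> male_specific exactly."""
        rng = np.random.default_rng(5)
        n = 300
        genes = [f"g{i}" for i in range(n)]
        fem = pd.DataFrame({"gene": genes, "region": "CN", "outcome": "amyloid",
                            "stratum": "female",
                            "beta": rng.standard_normal(n),
                            "p_fdr": rng.random(n) * 0.999 + 1e-6})
        mal = fem.copy()
        mal["stratum"] = "male"
        mal["p_fdr"] = rng.random(n) * 0.999 + 1e-6
        mal["beta"] = rng.standard_normal(n)
        inter = pd.DataFrame({"gene": genes, "region": "CN",
                              "outcome": "amyloid", "stratum": "interaction",
                              "beta": rng.standard_normal(n),
                              "p": rng.random(n) * 0.999 + 1e-6,
                              "p_fdr": rng.random(n) * 0.999 + 1e-6})
        fwd = dc.classify_table(fem, mal, inter)
        swp = dc.classify_table(
            mal.assign(stratum="female"), fem.assign(stratum="male"), inter)
        mapping = {"female_specific": "male_specific",
                   "male_specific": "female_specific"}
        expect = fwd.set_index("gene")["category"].map(
            lambda c: mapping.get(c, c))
        got = swp.set_index("gene")["category"]
        assert (expect.loc[got.index] == got).all()

    def test_null_call_rate_matches_screen_product(self):
        """With shared effects and no sex-specificity, the sex-specific rate
        is governed by the interaction screen (alpha) times the chance of a
        discordant stratified pair; the empirical calibration stays near it."""
        rng = np.random.default_rng(6)
        calls_spec = 0
        total = 0
        curve = []
        for rep in range(40):
            n_gene, n = 50, 120
            idx = pd.Index([f"d{i}" for i in range(2 * n)])
            sex = pd.Series(["female"] * n + ["male"] * n, index=idx)
            expr = pd.DataFrame(rng.standard_normal((n_gene, 2 * n)),
                                index=[f"g{i}" for i in range(n_gene)],
                                columns=idx)
            # shared effect for half the genes, in both sexes equally
            beta = np.where(np.arange(n_gene) < n_gene // 2, 0.5, 0.0)
            y = pd.Series(beta @ expr.to_numpy() * 0 +  # no cross-gene mixing
                          rng.standard_normal(2 * n), index=idx)
            y = y + (expr.iloc[0] * 0.5)  # one strong shared gene
            y -= y.mean()
            fem_scr = mo.cross_sectional_screen(
                expr.loc[:, sex == "female"], y[sex == "female"],
                stratum="female", outcome_name="tau", region="R")
            mal_scr = mo.cross_sectional_screen(
                expr.loc[:, sex == "male"], y[sex == "male"],
                stratum="male", outcome_name="tau", region="R")
            int_scr = mo.interaction_screen(expr, y, sex, outcome_name="tau",
                                            region="R")
            for scr in (fem_scr, mal_scr, int_scr):
                scr["chromosome_class"] = "autosomal"
            fem_scr = dc.adjust_by_family(fem_scr)
            mal_scr = dc.adjust_by_family(mal_scr)
            int_scr = dc.adjust_by_family(int_scr)
            calls = dc.classify_table(fem_scr, mal_scr, int_scr)
            spec = calls.category.isin(["female_specific", "male_specific"])
            calls_spec += spec.sum()
            total += len(calls)
            curve.append(spec.mean())
        rate = calls_spec / total
        # interaction screen at 0.05 dominates; discordance adds another factor
        assert rate < 0.05 + 2 * np.sqrt(0.05 * 0.95 / total)
        assert len(curve) == 40  # calibration curve available per replicate


class TestCrossRegion:
    def _calls(self, rows):
        return pd.DataFrame(rows)

    def test_two_regions_consistent_sign_highlighted(self):
        calls = self._calls([
            dict(gene="g", outcome="tau", region="DLPFC",
                 category="female_specific", female_beta=0.2, male_beta=0.0),
            dict(gene="g", outcome="tau", region="PCC",
                 category="female_specific", female_beta=0.15, male_beta=0.0),
        ])
        out = dc.cross_region_consistency(calls)
        assert (out.regions_support == 2).all() and out.highlighted.all()

    def test_sign_flip_breaks_support(self):
        calls = self._calls([
            dict(gene="g", outcome="tau", region="DLPFC",
                 category="female_specific", female_beta=0.2, male_beta=0.0),
            dict(gene="g", outcome="tau", region="PCC",
                 category="female_specific", female_beta=-0.15, male_beta=0.0),
        ])
        out = dc.cross_region_consistency(calls)
        assert (out.regions_support == 1).all() and not out.highlighted.any()

    def test_three_region_support(self):
        calls = self._calls([
            dict(gene="g", outcome="cognition", region=r,
                 category="male_specific", female_beta=0.0, male_beta=0.02)
            for r in ("DLPFC", "PCC", "CN")
        ])
        out = dc.cross_region_consistency(calls)
        assert (out.regions_support == 3).all()


class TestTally:
    def make_calls(self):
        """Calls table carrying the printed per-category/chromosome counts."""
        rows = []
        def add(n, category, chrom):
            rows.extend({"category": category, "chromosome_class": chrom,
                         "any_significant": True} for _ in range(n))
        add(1622, "female_specific", "autosomal")
        add(75, "female_specific", "X")
        add(609, "male_specific", "autosomal")
        add(14, "male_specific", "X")
        add(23118 - 2320, "both_sexes", "autosomal")
        return pd.DataFrame(rows)

    def test_printed_counts_reproduce_shares(self):
        tally = dc.tally_summary(self.make_calls())
        assert tally["n_sex_specific"] == 2320
        assert tally["n_female_specific"] == 1697
        assert tally["n_male_specific"] == 623
        assert tally["n_significant"] == 23118
        assert tally["shares"]["female_share_pct"] == 73.1
        assert tally["shares"]["x_linked_share_pct"] == 3.8
        assert tally["shares"]["sex_specific_pct_of_significant"] == 10.0

    def test_all_not_significant_zero_shares(self):
        calls = pd.DataFrame({"category": ["not_significant"] * 5,
                              "chromosome_class": ["autosomal"] * 5,
                              "any_significant": [False] * 5})
        tally = dc.tally_summary(calls)
        assert tally["n_sex_specific"] == 0
        assert tally["shares"]["female_share_pct"] == 0.0

    def test_single_call_full_share(self):
        calls = pd.DataFrame({"category": ["male_specific"],
                              "chromosome_class": ["X"],
                              "region": ["CN"], "outcome": ["tau"],
                              "any_significant": [True]})
        tally = dc.tally_summary(calls)
        assert tally["shares"]["male_share_pct"] == 100.0
        assert tally["shares"]["by_region_pct"]["CN"] == 100.0

    def test_empty_input(self):
        tally = dc.tally_summary(pd.DataFrame(columns=["category"]))
        assert tally["n_sex_specific"] == 0
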