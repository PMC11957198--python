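"""Reproducible benchmark routines for the pipeline's statistical guarantees.

Each function regenerates its inputs from a seed, runs the package's own
machinery, and returns measured quantities: tally arithmetic on the published
category counts, step-up adjustment accuracy against a definition-based
oracle, realized false-discovery proportions on null simulations, operating
characteristics of the sex-specificity classifier, mixed-model parameter
recovery, running-sum enrichment accuracy and planted-set detection,
matching balance improvement, and label-swap symmetry.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from sextwas import discovery as dc
from sextwas import enrichment as en
from sextwas import matching as mt
from sextwas import models as mo
from sextwas import simulate as sim

# Published per-category counts for the tally worked example: sex-specific
# associations by sex and chromosome class, regional and outcome marginals,
# and the total number of significant associations they sit inside.
PUBLISHED_COUNTS = {
    "female_autosomal": 1622,
    "female_x": 75,
    "male_autosomal": 609,
    "male_x": 14,
    "total_significant": 23118,
    "dlpfc": 1619,
    "tau": 908,
    "cognition": 1182,
}


def published_calls_table() -> pd.DataFrame:
    """Reconstruct a calls table carrying the published marginal counts."""
    c = PUBLISHED_COUNTS
    rows = []
    for (cat, chrom), n in (
        (("female_specific", "autosomal"), c["female_autosomal"]),
        (("female_specific", "X"), c["female_x"]),
        (("male_specific", "autosomal"), c["male_autosomal"]),
        (("male_specific", "X"), c["male_x"]),
    ):
        rows.extend({"category": cat, "chromosome_class": chrom,
                     "any_significant": True} for _ in range(n))
    n_spec = len(rows)
    amyloid = n_spec - c["tau"] - c["cognition"]
    regions = (["DLPFC"] * c["dlpfc"]
               + ["PCC/CN"] * (n_spec - c["dlpfc"]))
    outcomes = (["tau"] * c["tau"] + ["cognition"] * c["cognition"]
                + ["amyloid"] * amyloid)
    calls = pd.DataFrame(rows)
    calls["region"] = regions
    calls["outcome"] = outcomes
    rest = pd.DataFrame({
        "category": "both_sexes", "chromosome_class": "autosomal",
        "any_significant": True, "region": "DLPFC", "outcome": "tau",
    }, index=range(c["total_significant"] - n_spec))
    return pd.concat([calls, rest], ignore_index=True)


def tally_benchmark() -> dict:
    """Run tally_summary over the published counts; return the headline shares."""
    tally = dc.tally_summary(published_calls_table())
    shares = tally["shares"]
    return {
        "n_sex_specific": tally["n_sex_specific"],
        "n_female_specific": tally["n_female_specific"],
        "n_male_specific": tally["n_male_specific"],
        "sex_specific_pct_of_significant":
            shares["sex_specific_pct_of_significant"],
        "female_share_pct": shares["female_share_pct"],
        "x_linked_share_pct": shares["x_linked_share_pct"],
        "dlpfc_share_pct": shares["by_region_pct"]["DLPFC"],
        "tau_share_pct": shares["by_outcome_pct"]["tau"],
        "cognition_share_pct": shares["by_outcome_pct_1dp"]["cognition"],
    }


def _bh_definition_oracle(p) -> np.ndarray:
    """Step-up adjustment written independently with explicit loops."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [1.0] * m
    running = float("inf")
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = min(running, 1.0)
    return np.asarray(q)


def bh_benchmark(n_vectors: int = 1000, max_len: int = 8, seed: int = 0) -> dict:
    """Max |bh_adjust - definition oracle| over random short p-vectors."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        k = int(rng.integers(1, max_len + 1))
        p = rng.random(k) * 0.999 + 1e-6
        dev = np.max(np.abs(dc.bh_adjust(p) - _bh_definition_oracle(p)))
        worst = max(worst, float(dev))
    return {"max_abs_deviation": worst, "n_vectors": n_vectors}


def fdr_null_benchmark(
    n_rep: int = 200, n_genes: int = 500, n_per_sex: int = 100, seed: int = 0
) -> dict:
    """Realized FDP per chromosome-class family on all-null simulations.

    Expression and a pathology outcome are drawn with no true effects; the
    female-stratified screen plus partitioned BH at 0.05 is applied; every
    discovery is false, so the family FDP is discoveries > 0 weighted by 1.
    """
    rng = np.random.default_rng(seed)
    n_auto = int(round(n_genes * 0.92))
    chrom = np.array(["autosomal"] * n_auto + ["X"] * (n_genes - n_auto))
    fdp = {"autosomal": [], "X": []}
    samples = pd.Index([f"d{i}" for i in range(n_per_sex)])
    genes = pd.Index([f"g{i}" for i in range(n_genes)])
    for _ in range(n_rep):
        expr = pd.DataFrame(rng.standard_normal((n_genes, n_per_sex)),
                            index=genes, columns=samples)
        y = pd.Series(rng.standard_normal(n_per_sex), index=samples)
        res = mo.cross_sectional_screen(expr, y, stratum="female",
                                        outcome_name="tau", region="R")
        res["chromosome_class"] = chrom
        res = dc.adjust_by_family(res)
        for fam in ("autosomal", "X"):
            d = (res.loc[res.chromosome_class == fam, "p_fdr"] <= 0.05).sum()
            fdp[fam].append(1.0 if d > 0 else 0.0)  # all discoveries false
    out = {}
    for fam, vals in fdp.items():
        vals = np.asarray(vals)
        out[f"fdp_{fam}"] = float(vals.mean())
        out[f"fdp_{fam}_mc_se"] = float(vals.std(ddof=1) / np.sqrt(len(vals)))
    out["n_rep"] = n_rep
    return out


def classifier_benchmark(
    n_rep: int = 4, n_per_sex: int = 150, n_genes: int = 200,
    n_causal: int = 30, n_shared: int = 30, effect: float = 0.4,
    seed: int = 0,
) -> dict:
    """Operating characteristics of the sex-specificity rule.

    Each gene is an independent experiment: its own expression vector and its
    own outcome, so a causal gene's standardized effect is exactly ``effect``
    (female-only for the causal tier, equal in both sexes for the shared
    tier) rather than being diluted by other planted genes. The stratified
    and interaction fits run through the package models; BH is applied over
    the whole gene family per stratum, as in the pipeline. Returns the
    female_specific call rate among causal genes (power) and the rate of any
    sex-specific call among shared-effect genes (misclassification).
    """
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"d{i}" for i in range(2 * n_per_sex)])
    sex = pd.Series(["female"] * n_per_sex + ["male"] * n_per_sex, index=idx)
    is_f = (sex == "female").to_numpy(dtype=float)
    power_hits = shared_spec = 0
    for _ in range(n_rep):
        rows_f, rows_m, rows_i = [], [], []
        kinds = (["causal"] * n_causal + ["shared"] * n_shared
                 + ["null"] * (n_genes - n_causal - n_shared))
        for gi, kind in enumerate(kinds):
            g = pd.Series(rng.standard_normal(2 * n_per_sex), index=idx)
            y = rng.standard_normal(2 * n_per_sex)
            if kind == "causal":
                y = y + effect * g.to_numpy() * is_f
            elif kind == "shared":
                y = y + effect * g.to_numpy()
            y = pd.Series(y - y.mean(), index=idx)
            name = f"g{gi:03d}"
            rf = mo.fit_cross_sectional(g[sex == "female"], y[sex == "female"],
                                        stratum="female", gene=name,
                                        outcome_name="tau", region="R")
            rm = mo.fit_cross_sectional(g[sex == "male"], y[sex == "male"],
                                        stratum="male", gene=name,
                                        outcome_name="tau", region="R")
            ri = mo.fit_interaction(g, outcome=y, covariates=None, sex=sex,
                                    gene=name, outcome_name="tau", region="R")
            for res, rows in ((rf, rows_f), (rm, rows_m), (ri, rows_i)):
                rows.append({"gene": res.gene, "region": "R", "outcome": "tau",
                             "stratum": res.stratum, "beta": res.beta,
                             "p": res.p, "chromosome_class": "autosomal"})
        fem, mal, inter = (pd.DataFrame(r) for r in (rows_f, rows_m, rows_i))
        calls = dc.classify_table(dc.adjust_by_family(fem),
                                  dc.adjust_by_family(mal),
                                  dc.adjust_by_family(inter))
        calls = calls.set_index("gene")
        causal_names = [f"g{i:03d}" for i, k in enumerate(kinds)
                        if k == "causal"]
        shared_names = [f"g{i:03d}" for i, k in enumerate(kinds)
                        if k == "shared"]
        power_hits += (calls.loc[causal_names, "category"]
                       == "female_specific").sum()
        shared_spec += calls.loc[shared_names, "category"].isin(
            ["female_specific", "male_specific"]).sum()
    n_power = n_rep * n_causal
    n_shared_tot = n_rep * n_shared
    return {
        "female_specific_power": float(power_hits / n_power),
        "shared_misclassification_rate": float(shared_spec / n_shared_tot),
        "power_mc_se": float(np.sqrt(0.9 * 0.1 / n_power)),
        "shared_mc_se": float(np.sqrt(0.05 * 0.95 / n_shared_tot)),
        "n_rep": n_rep,
    }


def lmm_recovery_benchmark(
    n_rep: int = 100, n_decedents: int = 200, visits_mean: float = 8.0,
    effect: float = 0.05, seed: int = 0,
) -> dict:
    """Bias of the mixed-model gene x time estimate under the exact model."""
    estimates = []
    rng = np.random.default_rng(seed)
    for r in range(n_rep):
        cfg = sim.SimulationConfig(
            n_male=n_decedents // 2, n_female=n_decedents - n_decedents // 2,
            n_genes_autosomal=2, n_genes_x=1, n_genes_y=1,
            visits_mean=visits_mean, seed=int(rng.integers(2**31 - 1)),
            causal_table=[(0, "cognition", "both", effect)],
        )
        cohort = sim.generate_cohort(cfg)
        z = pd.DataFrame(rng.standard_normal((1, len(cohort))),
                         index=["g"], columns=cohort.index)
        # causal index 0 refers to the first gene of the latent matrix
        out = sim.generate_outcomes(cfg, cohort, z)
        res = mo.fit_longitudinal(z.iloc[0], out.visits, None, gene="g")
        if res.estimable:
            estimates.append(res.beta)
    est = np.asarray(estimates)
    mc_se = est.std(ddof=1) / np.sqrt(len(est))
    return {
        "mean_estimate": float(est.mean()),
        "true_effect": effect,
        "bias": float(est.mean() - effect),
        "mc_se": float(mc_se),
        "n_converged": int(len(est)),
    }


def gsea_benchmark(
    n_instances: int = 500, n_perm: int = 1000, seed: int = 0
) -> dict:
    """Running-sum accuracy vs brute force, plus planted-set detection."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(3, 51))
        betas = np.sort(rng.standard_normal(n))[::-1]
        k = int(rng.integers(1, n + 1))
        flags = np.zeros(n, bool)
        flags[rng.choice(n, k, replace=False)] = True
        es, _, _ = en.enrichment_score(betas, flags)
        ref = _brute_force_es(betas, flags)
        worst = max(worst, abs(es - ref))
    betas = np.sort(rng.standard_normal(1000))[::-1]
    ranked = pd.Series(betas, index=[f"g{i:04d}" for i in range(1000)])
    sets = {"planted": set(ranked.index[:20])}
    res = en.gsea_preranked(ranked, sets, n_perm=n_perm,
                            seed=int(rng.integers(2**31 - 1)))
    return {
        "max_abs_deviation": float(worst),
        "planted_set_p": float(res["p"].iloc[0]),
        "planted_set_nes": float(res["NES"].iloc[0]),
    }


def _brute_force_es(betas, flags, weight: float = 1.0) -> float:
    n = len(betas)
    hit_w = [abs(b) ** weight if f else 0.0 for b, f in zip(betas, flags)]
    tot = sum(hit_w)
    n_hit = int(sum(flags))
    if tot == 0:
        hit_w = [1.0 if f else 0.0 for f in flags]
        tot = float(n_hit)
    s, hi, lo = 0.0, -2.0, 2.0
    for i in range(n):
        if flags[i]:
            s += hit_w[i] / tot
        elif n > n_hit:
            s -= 1.0 / (n - n_hit)
        s = min(1.0, max(-1.0, s))  # ES is bounded by definition
        hi = max(hi, s)
        lo = min(lo, s)
    return hi if hi >= -lo - 1e-12 else lo  # ties resolve positive


def matching_benchmark(
    n_rep: int = 100, n_male: int = 100, n_female: int = 200, seed: int = 0
) -> dict:
    """Balance improvement of the matcher on sex-shifted cohorts.

    Every continuous criterion is shifted between the sexes. Matching runs
    on the QC-passed cohort (the pipeline's stage order: sample QC removes
    the planted extreme-PMI/RIN decedents before matching). Counts the
    replicates where each post-match SMD is strictly below pre-match, and
    the fraction where the post-match balance test passes outright.
    """
    from sextwas import preprocess as pp

    rng = np.random.default_rng(seed)
    improved = 0
    balance_pass = 0
    for _ in range(n_rep):
        cfg = sim.SimulationConfig(
            n_male=n_male, n_female=n_female, n_genes_autosomal=2,
            n_genes_x=1, n_genes_y=1, seed=int(rng.integers(2**31 - 1)),
            sex_shift={"age_death": 2.5, "education": -1.0, "pmi": 1.5,
                       "latency": 0.4},
        )
        cohort = sim.generate_cohort(cfg)
        kept, _ = pp.qc_samples(cohort)
        cohort = cohort.loc[kept]
        m = mt.PropensityMatcher().fit(cohort)
        all_better = all(
            mt.standardized_mean_difference(cohort, c, m.matched_ids_)
            < mt.standardized_mean_difference(cohort, c)
            for c in mt.CONTINUOUS_CRITERIA
        )
        improved += all_better
        balance_pass += bool(m.balanced_)
    return {
        "improved_fraction": improved / n_rep,
        "balance_pass_fraction": balance_pass / n_rep,
        "n_rep": n_rep,
    }


def label_symmetry_benchmark(
    n_genes: int = 150, n_per_sex: int = 120, seed: int = 0
) -> dict:
    """Fraction of calls that map exactly under a global sex-label swap."""
    rng = np.random.default_rng(seed)
    genes = pd.Index([f"g{i}" for i in range(n_genes)])
    idx = pd.Index([f"d{i}" for i in range(2 * n_per_sex)])
    sex = pd.Series(["female"] * n_per_sex + ["male"] * n_per_sex, index=idx)
    expr = pd.DataFrame(rng.standard_normal((n_genes, 2 * n_per_sex)),
                        index=genes, columns=idx)
    is_f = (sex == "female").to_numpy(dtype=float)
    y = rng.standard_normal(2 * n_per_sex)
    y += 0.5 * (expr.iloc[:20].to_numpy() * is_f).sum(axis=0)
    y += 0.5 * (expr.iloc[20:35].to_numpy() * (1 - is_f)).sum(axis=0)
    y += 0.4 * expr.iloc[35:50].to_numpy().sum(axis=0)
    y = pd.Series(y - y.mean(), index=idx)

    def calls_for(sex_labels):
        fem = mo.cross_sectional_screen(
            expr.loc[:, sex_labels == "female"], y[sex_labels == "female"],
            stratum="female", outcome_name="tau", region="R")
        mal = mo.cross_sectional_screen(
            expr.loc[:, sex_labels == "male"], y[sex_labels == "male"],
            stratum="male", outcome_name="tau", region="R")
        inter = mo.interaction_screen(expr, y, sex_labels,
                                      outcome_name="tau", region="R")
        for scr in (fem, mal, inter):
            scr["chromosome_class"] = "autosomal"
        return dc.classify_table(dc.adjust_by_family(fem),
                                 dc.adjust_by_family(mal),
                                 dc.adjust_by_family(inter)).set_index("gene")

    fwd = calls_for(sex)
    swapped = sex.map({"female": "male", "male": "female"})
    rev = calls_for(swapped)
    mapping = {"female_specific": "male_specific",
               "male_specific": "female_specific"}
    expected = fwd["category"].map(lambda c: mapping.get(c, c))
    agree = (expected.loc[rev.index] == rev["category"]).mean()
    n_spec = int(fwd["category"].isin(list(mapping)).sum())
    return {"agreement_fraction": float(agree), "n_sex_specific_calls": n_spec}
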