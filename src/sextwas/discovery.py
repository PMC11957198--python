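"""Chromosome-partitioned FDR and the sex-specificity decision framework.

Benjamini-Hochberg adjustment is applied within families defined by the full
cross-product of region, outcome, stratum (or interaction term) and
chromosome class, so that sex-chromosome genes are not swamped by the
autosome. A gene association is called sex-specific when it is FDR-significant
in exactly one sex's stratified model and shows a nominal sex x gene
interaction; the stringent tier additionally requires the interaction to
survive FDR at 0.10. Cross-region consistency and Results-style tallies
summarize the calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FAMILY_COLS = ("region", "outcome", "stratum", "chromosome_class")

ALPHA_STRATIFIED = 0.05
ALPHA_INTERACTION = 0.05
ALPHA_INTERACTION_FDR = 0.10


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sort ascending, q_(i) = min_{j>=i} m * p_(j) / j, capped at 1, mapped
    back to input order. Ties share adjusted values by construction.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def adjust_by_family(
    results: pd.DataFrame,
    p_col: str = "p",
    family_cols=FAMILY_COLS,
    out_col: str = "p_fdr",
) -> pd.DataFrame:
    """BH-adjust within each (region, outcome, stratum, chromosome class) family.

    Rows with an inestimable/missing p are left NaN and excluded from their
    family's multiplicity count. Returns a copy with ``out_col`` added.
    """
    missing = [c for c in family_cols if c not in results.columns]
    if missing:
        raise ValueError(f"results lack family key column(s): {missing}")
    out = results.copy()
    out[out_col] = np.nan
    ok = out[p_col].notna()
    for _, idx in out[ok].groupby(list(family_cols), sort=False).groups.items():
        out.loc[idx, out_col] = bh_adjust(out.loc[idx, p_col].to_numpy())
    return out


@dataclass
class SexSpecificityCall:
    """Categorical sex-specificity decision for one (gene, region, outcome)."""

    gene: str
    region: str
    outcome: str
    category: str            # female_specific | male_specific | both_sexes |
                             # not_significant | not_evaluable
    stringent: bool = False  # interaction p_fdr <= 0.10 and sex-specific
    regions_support: int = 1
    female_p_fdr: float = np.nan
    male_p_fdr: float = np.nan
    interaction_p: float = np.nan
    interaction_p_fdr: float = np.nan
    female_beta: float = np.nan
    male_beta: float = np.nan


def classify_sex_specific(
    female_result,
    male_result,
    interaction_result,
    alpha_strat: float = ALPHA_STRATIFIED,
    alpha_inter: float = ALPHA_INTERACTION,
    alpha_inter_fdr: float = ALPHA_INTERACTION_FDR,
) -> SexSpecificityCall:
    """Apply the a-priori sex-specificity rule to one gene's three results.

    female_specific: female p_fdr <= 0.05, male p_fdr > 0.05, and nominal
    interaction p < 0.05 (mirror for male_specific). Significance in both
    strata is both_sexes regardless of the interaction; significance in one
    stratum without the interaction screen is not called. The stringent flag
    marks sex-specific calls whose interaction also passes FDR at 0.10.
    """
    if female_result is None or male_result is None or interaction_result is None:
        any_res = female_result or male_result or interaction_result
        return SexSpecificityCall(
            gene=getattr(any_res, "gene", "?"),
            region=getattr(any_res, "region", ""),
            outcome=getattr(any_res, "outcome", ""),
            category="not_evaluable",
        )
    f_q, m_q = female_result.p_fdr, male_result.p_fdr
    i_p = interaction_result.p
    i_q = getattr(interaction_result, "p_fdr", None)
    if f_q is None or m_q is None or not np.isfinite(f_q) or not np.isfinite(m_q):
        category = "not_evaluable"
    else:
        f_sig, m_sig = f_q <= alpha_strat, m_q <= alpha_strat
        inter = np.isfinite(i_p) and i_p < alpha_inter
        if f_sig and m_sig:
            category = "both_sexes"
        elif f_sig and not m_sig and inter:
            category = "female_specific"
        elif m_sig and not f_sig and inter:
            category = "male_specific"
        else:
            category = "not_significant"
    stringent = (
        category in ("female_specific", "male_specific")
        and i_q is not None and np.isfinite(i_q) and i_q <= alpha_inter_fdr
    )
    return SexSpecificityCall(
        gene=female_result.gene, region=female_result.region,
        outcome=female_result.outcome, category=category, stringent=stringent,
        female_p_fdr=f_q, male_p_fdr=m_q, interaction_p=i_p,
        interaction_p_fdr=np.nan if i_q is None else i_q,
        female_beta=female_result.beta, male_beta=male_result.beta,
    )


def classify_table(
    female: pd.DataFrame,
    male: pd.DataFrame,
    interaction: pd.DataFrame,
    alpha_strat: float = ALPHA_STRATIFIED,
    alpha_inter: float = ALPHA_INTERACTION,
    alpha_inter_fdr: float = ALPHA_INTERACTION_FDR,
) -> pd.DataFrame:
    """Vectorized sex-specificity calls for whole result tables.

    Inputs are tidy per-gene tables (as produced by the screens, after
    :func:`adjust_by_family`) for the same (region, outcome). Returns one row
    per gene with the category, stringent flag, an ``any_significant``
    column (FDR-significant in at least one stratum, the denominator of the
    Results-style share), and carried-through betas.
    """
    key = ["gene", "region", "outcome"]
    f = female.set_index(key)
    m = male.set_index(key)
    i = interaction.set_index(key)
    idx = f.index.union(m.index).union(i.index)
    out = pd.DataFrame(index=idx).reset_index()
    for src, tag in ((f, "female"), (m, "male")):
        out[f"{tag}_p_fdr"] = out.set_index(key).index.map(src["p_fdr"]).to_numpy()
        out[f"{tag}_beta"] = out.set_index(key).index.map(src["beta"]).to_numpy()
    out["interaction_p"] = out.set_index(key).index.map(i["p"]).to_numpy()
    if "p_fdr" in i.columns:
        out["interaction_p_fdr"] = out.set_index(key).index.map(i["p_fdr"]).to_numpy()
    else:
        out["interaction_p_fdr"] = np.nan
    if "chromosome_class" in female.columns:
        cmap = female.set_index("gene")["chromosome_class"]
        out["chromosome_class"] = out["gene"].map(cmap)

    f_q = out["female_p_fdr"].to_numpy(dtype=float)
    m_q = out["male_p_fdr"].to_numpy(dtype=float)
    i_p = out["interaction_p"].to_numpy(dtype=float)
    i_q = out["interaction_p_fdr"].to_numpy(dtype=float)
    f_sig = np.nan_to_num(f_q, nan=1.0) <= alpha_strat
    m_sig = np.nan_to_num(m_q, nan=1.0) <= alpha_strat
    inter = np.nan_to_num(i_p, nan=1.0) < alpha_inter
    category = np.where(
        ~np.isfinite(f_q) | ~np.isfinite(m_q), "not_evaluable",
        np.where(
            f_sig & m_sig, "both_sexes",
            np.where(
                f_sig & ~m_sig & inter, "female_specific",
                np.where(m_sig & ~f_sig & inter, "male_specific", "not_significant"),
            ),
        ),
    )
    out["category"] = category
    out["any_significant"] = (f_sig | m_sig) & np.isfinite(f_q) & np.isfinite(m_q)
    out["stringent"] = (
        np.isin(category, ("female_specific", "male_specific"))
        & (np.nan_to_num(i_q, nan=1.0) <= alpha_inter_fdr)
    )
    return out


def cross_region_consistency(calls: pd.DataFrame) -> pd.DataFrame:
    """Count, per (gene, outcome), the regions sharing the call with same sign.

    ``regions_support`` for a sex-specific call is the number of regions in
    which the same category holds and the significant stratum's beta has the
    same sign; ``highlighted`` flags support in at least two regions.
    """
    out = calls.copy()
    out["regions_support"] = 1
    out["highlighted"] = False
    sexspec = out["category"].isin(["female_specific", "male_specific"])
    for (gene, outcome, cat), grp in out[sexspec].groupby(
        ["gene", "outcome", "category"], sort=False
    ):
        beta_col = "female_beta" if cat == "female_specific" else "male_beta"
        signs = np.sign(grp[beta_col].to_numpy(dtype=float))
        for idx, s in zip(grp.index, signs):
            support = int(np.sum(signs == s)) if s != 0 else 1
            out.loc[idx, "regions_support"] = support
            out.loc[idx, "highlighted"] = support >= 2
    return out


def tally_summary(calls: pd.DataFrame) -> dict:
    """Results-style counts and shares over a complete calls table.

    Returns a dict with total significant associations, sex-specific counts
    (overall, per sex, per chromosome class, per region, per outcome) and the
    corresponding percentage shares. Shares of the sex-specific total are
    reported to one decimal; region/outcome shares additionally as whole
    percents (the precision the headline figures are usually quoted at). All
    ratios are exact before rounding.
    """
    if calls.empty:
        return {"n_significant": 0, "n_sex_specific": 0, "by_category": {},
                "shares": {}}
    sexspec = calls["category"].isin(["female_specific", "male_specific"])
    n_spec = int(sexspec.sum())
    if "any_significant" in calls.columns:
        n_sig = int(calls["any_significant"].sum())
    else:
        n_sig = int((calls["category"] != "not_significant").sum())
    by_category = calls["category"].value_counts().to_dict()
    spec = calls[sexspec]
    n_female = int((spec["category"] == "female_specific").sum())
    n_male = int((spec["category"] == "male_specific").sum())

    def pct(a, b, nd=1):
        return round(100.0 * a / b, nd) if b else 0.0

    shares = {
        "sex_specific_pct_of_significant": pct(n_spec, n_sig),
        "female_share_pct": pct(n_female, n_spec),
        "male_share_pct": pct(n_male, n_spec),
    }
    summary = {
        "n_significant": n_sig,
        "n_sex_specific": n_spec,
        "n_female_specific": n_female,
        "n_male_specific": n_male,
        "by_category": by_category,
        "n_stringent": int(calls.get("stringent", pd.Series(dtype=bool)).sum()),
    }
    if "chromosome_class" in calls.columns:
        by_chrom = spec.groupby(["category", "chromosome_class"]).size()
        summary["by_category_chromosome"] = {
            f"{c}_{ch}": int(v) for (c, ch), v in by_chrom.items()
        }
        n_x = int((spec["chromosome_class"] == "X").sum())
        summary["n_x_linked_sex_specific"] = n_x
        shares["x_linked_share_pct"] = pct(n_x, n_spec)
    for col, nd in (("region", 0), ("outcome", 0)):
        if col in calls.columns:
            counts = spec.groupby(col).size().to_dict()
            summary[f"by_{col}"] = {k: int(v) for k, v in counts.items()}
            shares[f"by_{col}_pct"] = {
                k: pct(v, n_spec, nd) for k, v in counts.items()
            }
            shares[f"by_{col}_pct_1dp"] = {
                k: pct(v, n_spec, 1) for k, v in counts.items()
            }
    summary["shares"] = shares
    return summary


def chord_edges(calls: pd.DataFrame) -> pd.DataFrame:
    """Region x outcome x category counts, chord-diagram-ready."""
    spec = calls[calls["category"].isin(["female_specific", "male_specific"])]
    if spec.empty:
        return pd.DataFrame(columns=["region", "outcome", "category", "n"])
    return (
        spec.groupby(["region", "outcome", "category"]).size()
        .rename("n").reset_index()
    )
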