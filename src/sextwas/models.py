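"""Per-gene association engines.

Cross-sectional outcomes (square-root amyloid and tau) are analyzed by
ordinary least squares with gene expression as the predictor of interest;
longitudinal cognition by a linear mixed model with per-decedent random
intercept and random time slope, the reported association being the
gene x time coefficient (the effect on annual rate of decline). Interaction
variants add sex (and APOE-e4) moderation terms on the pooled sample. A
vectorized many-gene screen is provided for each model family: exact
Frisch-Waugh-Lovell OLS for the cross-sectional models, and a plug-in
generalized-least-squares screen for the longitudinal models that estimates
the variance components once from the gene-free null model and then solves
the per-gene fixed effects in closed form (the common fast approximation for
longitudinal omics screens; the full per-gene mixed model is available via
:func:`fit_longitudinal`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm


@dataclass
class AssociationResult:
    """One (gene, region, outcome, stratum) association."""

    gene: str
    outcome: str
    stratum: str
    beta: float
    se: float
    statistic: float
    p: float
    n: int
    df: float
    model: str
    region: str = ""
    term: str = "gene"
    estimable: bool = True
    p_fdr: float | None = None
    extra: dict = field(default_factory=dict)


def _design(covariates: pd.DataFrame | None, index) -> pd.DataFrame:
    """Constant + covariates, categoricals expanded to indicator contrasts."""
    if covariates is None or covariates.shape[1] == 0:
        X = pd.DataFrame(index=index)
    else:
        X = pd.get_dummies(covariates.loc[index], drop_first=True, dtype=float)
    X.insert(0, "const", 1.0)
    return X.astype(float)


def _drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    """Drop later columns that are linear combinations of earlier ones."""
    A = X.to_numpy()
    keep, rank = [], 0
    for j in range(A.shape[1]):
        if np.linalg.matrix_rank(A[:, keep + [j]]) > rank:
            keep.append(j)
            rank += 1
        else:
            warnings.warn(f"dropping collinear design column {X.columns[j]!r}")
    return X.iloc[:, keep]


def fit_cross_sectional(
    gene_expr: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    stratum: str = "pooled",
    gene: str = "gene",
    outcome_name: str = "outcome",
    region: str = "",
) -> AssociationResult:
    """OLS of a centered outcome on one gene's expression plus covariates.

    The p-value uses the t reference with residual degrees of freedom. A fit
    with n <= parameters or a zero-variance gene is returned flagged
    ``estimable=False`` rather than raising.
    """
    idx = gene_expr.index.intersection(outcome.index)
    x = gene_expr.loc[idx].astype(float)
    y = outcome.loc[idx].astype(float)
    X = _design(covariates, idx)
    X["gene"] = x
    bad = AssociationResult(
        gene=gene, outcome=outcome_name, stratum=stratum, beta=np.nan,
        se=np.nan, statistic=np.nan, p=np.nan, n=len(idx), df=np.nan,
        model="ols", region=region, estimable=False,
    )
    if len(idx) <= X.shape[1] or np.isclose(x.var(ddof=0), 0.0):
        return bad
    X = _drop_collinear(X)
    if "gene" not in X.columns:
        return bad
    res = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    j = list(X.columns).index("gene")
    return AssociationResult(
        gene=gene, outcome=outcome_name, stratum=stratum,
        beta=float(res.params[j]), se=float(res.bse[j]),
        statistic=float(res.tvalues[j]), p=float(res.pvalues[j]),
        n=int(res.nobs), df=float(res.df_resid), model="ols", region=region,
    )


def cross_sectional_screen(
    expr: pd.DataFrame,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    stratum: str = "pooled",
    outcome_name: str = "outcome",
    region: str = "",
) -> pd.DataFrame:
    """Exact OLS over all genes at once via Frisch-Waugh-Lovell projection.

    ``expr`` is genes x samples. Returns a tidy frame (one row per gene) with
    beta, se, statistic, p, n, df, identical to per-gene OLS.
    """
    samples = expr.columns.intersection(outcome.index)
    E = expr.loc[:, samples].to_numpy(dtype=float)
    y = outcome.loc[samples].to_numpy(dtype=float)
    X = _drop_collinear(_design(covariates, samples)).to_numpy()
    n, k = X.shape
    df = n - k - 1
    if df <= 0:
        raise ValueError(f"not enough samples (n={n}) for {k + 1} parameters")
    Q, _ = np.linalg.qr(X)
    My = y - Q @ (Q.T @ y)
    ME = E - (E @ Q) @ Q.T
    gg = np.einsum("ij,ij->i", ME, ME)
    ok = gg > 1e-12
    beta = np.full(len(E), np.nan)
    beta[ok] = (ME[ok] @ My) / gg[ok]
    rss = np.maximum(My @ My - beta**2 * gg, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / gg)
        tval = beta / se
    p = 2.0 * stats.t.sf(np.abs(tval), df)
    out = pd.DataFrame(
        {
            "gene": expr.index,
            "region": region,
            "outcome": outcome_name,
            "stratum": stratum,
            "beta": beta,
            "se": se,
            "statistic": tval,
            "p": p,
            "n": n,
            "df": float(df),
            "model": "ols",
            "estimable": ok,
        }
    )
    return out


def interaction_screen(
    expr: pd.DataFrame,
    outcome: pd.Series,
    sex: pd.Series,
    covariates: pd.DataFrame | None = None,
    outcome_name: str = "outcome",
    region: str = "",
) -> pd.DataFrame:
    """Sex x gene interaction OLS for every gene on the pooled sample.

    Female is the reference level: the reported beta is the male deviation of
    the gene slope. One row per gene with the interaction term's statistics.
    """
    samples = expr.columns.intersection(outcome.index)
    sx = sex.loc[samples]
    if sx.nunique() < 2:
        raise ValueError("interaction models require both sexes in the sample")
    male = (sx == "male").to_numpy(dtype=float)
    y = outcome.loc[samples].to_numpy(dtype=float)
    B = _drop_collinear(_design(covariates, samples))
    if "sex" not in B.columns:
        B["sex_male"] = male
    B = B.to_numpy(dtype=float)
    E = expr.loc[:, samples].to_numpy(dtype=float)
    n = len(samples)
    k = B.shape[1] + 2
    df = n - k
    rows = []
    for gi in range(E.shape[0]):
        g = E[gi]
        X = np.column_stack([B, g, g * male])
        if df <= 0 or np.isclose(g.var(), 0.0):
            rows.append((np.nan, np.nan, np.nan, np.nan, False))
            continue
        XtX = X.T @ X
        try:
            XtXi = np.linalg.inv(XtX)
        except np.linalg.LinAlgError:
            rows.append((np.nan, np.nan, np.nan, np.nan, False))
            continue
        b = XtXi @ (X.T @ y)
        resid = y - X @ b
        s2 = (resid @ resid) / df
        se = np.sqrt(s2 * XtXi[-1, -1])
        tval = b[-1] / se
        pval = 2.0 * stats.t.sf(abs(tval), df)
        rows.append((b[-1], se, tval, pval, True))
    out = pd.DataFrame(rows, columns=["beta", "se", "statistic", "p", "estimable"])
    out.insert(0, "gene", expr.index.to_numpy())
    out["region"] = region
    out["outcome"] = outcome_name
    out["stratum"] = "interaction"
    out["term"] = "sex:gene"
    out["n"] = n
    out["df"] = float(df)
    out["model"] = "ols"
    return out


# ---------------------------------------------------------------------------
# longitudinal models
# ---------------------------------------------------------------------------

def _merge_visits(
    gene_expr: pd.Series,
    visits: pd.DataFrame,
    covariates: pd.DataFrame | None,
) -> pd.DataFrame:
    d = visits.copy()
    d["gene"] = d["decedent_id"].map(gene_expr)
    if covariates is not None:
        X = pd.get_dummies(covariates, drop_first=True, dtype=float)
        for c in X.columns:
            d[c] = d["decedent_id"].map(X[c])
    d = d.dropna(subset=["gene", "cognition", "time"])
    return d


def _fit_mixed(md):
    """ML fit with an optimizer fallback chain; returns the best converged fit.

    The default BFGS family occasionally stalls on flat variance-component
    surfaces; conjugate-gradient or Powell then usually succeeds. Falls back
    to the highest-likelihood non-converged fit only if nothing converges.
    """
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", None, "powell"):
            kwargs = {"reml": False, "maxiter": 300}
            if method is not None:
                kwargs["method"] = method
            try:
                res = md.fit(**kwargs)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if res.converged and np.all(np.isfinite(res.bse_fe)):
                return res
            if best is None or res.llf > best.llf:
                best = res
    if best is None:
        raise np.linalg.LinAlgError("mixed-model fit failed for every optimizer")
    return best


def _wald(params, bse, names, term):
    j = names.index(term)
    beta, se = float(params[j]), float(bse[j])
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return beta, se, z, p


def fit_longitudinal(
    gene_expr: pd.Series,
    visits: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    stratum: str = "pooled",
    gene: str = "gene",
    region: str = "",
    report: str = "gene:time",
) -> AssociationResult:
    """Linear mixed model of cognition trajectories on one gene.

    cognition ~ gene + time + gene:time + covariates with a per-decedent
    random intercept and random time slope (unstructured 2x2 covariance),
    fitted by maximum likelihood. The reported coefficient is ``report``
    ("gene:time" by default, i.e. the effect on the rate of decline;
    "gene" gives the level effect instead). Inference is a Wald test with a
    normal reference. A non-converged fit is retried with a random intercept
    only (tagged "mixedlm-reduced"); if that also fails the result is flagged
    inestimable, as is a design with no within-decedent time variation.
    """
    d = _merge_visits(gene_expr, visits, covariates)
    n_dec = d["decedent_id"].nunique()
    bad = AssociationResult(
        gene=gene, outcome="cognition", stratum=stratum, beta=np.nan, se=np.nan,
        statistic=np.nan, p=np.nan, n=n_dec, df=np.inf, model="mixedlm",
        region=region, term=report, estimable=False,
    )
    if d.empty or np.isclose(d["gene"].var(), 0.0):
        return bad
    within = d.groupby("decedent_id")["time"].nunique()
    if (within <= 1).all():
        return bad  # slope terms inestimable with one visit per decedent
    fixed = ["gene", "time"]
    d["gene:time"] = d["gene"] * d["time"]
    fixed.append("gene:time")
    cov_cols = [c for c in d.columns if c not in
                ("decedent_id", "visit", "time", "cognition", "gene", "gene:time")]
    X = d[fixed + cov_cols].copy()
    X.insert(0, "const", 1.0)
    X = _drop_collinear(X)
    y = d["cognition"].to_numpy(dtype=float)
    groups = d["decedent_id"].to_numpy()

    for re_cols, tag in ((("const", "time"), "mixedlm"), (("const",), "mixedlm-reduced")):
        exog_re = d.assign(const=1.0)[list(re_cols)].to_numpy(dtype=float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = sm.MixedLM(y, X.to_numpy(dtype=float), groups=groups, exog_re=exog_re)
                res = _fit_mixed(md)
            if not res.converged:
                continue
            names = list(X.columns)
            beta, se, z, p = _wald(res.fe_params, res.bse_fe, names, report)
            if not np.isfinite(se) or se <= 0:
                continue
            return AssociationResult(
                gene=gene, outcome="cognition", stratum=stratum, beta=beta,
                se=se, statistic=z, p=p, n=n_dec, df=np.inf, model=tag,
                region=region, term=report,
            )
        except (np.linalg.LinAlgError, ValueError):
            continue
    return replace(bad, model="mixedlm-failed")


def _null_variance_components(
    d: pd.DataFrame, cov_cols: list[str]
) -> tuple[float, np.ndarray]:
    """ML variance components of the gene-free trajectory model."""
    X = d[["time"] + cov_cols].copy()
    X.insert(0, "const", 1.0)
    X = _drop_collinear(X)
    exog_re = d.assign(const=1.0)[["const", "time"]].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = sm.MixedLM(
            d["cognition"].to_numpy(dtype=float),
            X.to_numpy(dtype=float),
            groups=d["decedent_id"].to_numpy(),
            exog_re=exog_re,
        )
        res = _fit_mixed(md)
    sigma2 = float(res.scale)
    G = np.asarray(res.cov_re)  # statsmodels reports this on the outcome scale
    return sigma2, G


def longitudinal_screen(
    expr: pd.DataFrame,
    visits: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    stratum: str = "pooled",
    region: str = "",
    sex: pd.Series | None = None,
    interaction: bool = False,
) -> pd.DataFrame:
    """Fast many-gene longitudinal screen by plug-in GLS.

    Variance components (random intercept/slope covariance and residual
    variance) are estimated once by maximum likelihood on the gene-free
    model; each gene's fixed effects are then solved by generalized least
    squares with those components held fixed, which is exact conditional on
    the variance components and vectorizes over genes because expression is
    constant within a decedent. Reported term: gene x time, or
    sex x gene x time when ``interaction=True`` (female reference).
    """
    if interaction and sex is None:
        raise ValueError("interaction screen requires sex labels")
    cov = covariates
    if covariates is not None:
        cov = pd.get_dummies(covariates, drop_first=True, dtype=float)
    d = visits.dropna(subset=["cognition", "time"]).copy()
    cov_cols: list[str] = []
    if cov is not None:
        for c in cov.columns:
            d[c] = d["decedent_id"].map(cov[c])
            cov_cols.append(c)
    if interaction:
        male = (sex == "male").astype(float)
        d["sex_male"] = d["decedent_id"].map(male)
        d["sex_male:time"] = d["sex_male"] * d["time"]
        cov_cols += ["sex_male", "sex_male:time"]
    d = d.dropna(subset=cov_cols) if cov_cols else d
    sigma2, G = _null_variance_components(d, cov_cols)

    dec_ids = d["decedent_id"].unique()
    expr_d = expr.loc[:, expr.columns.intersection(dec_ids)]
    d = d[d["decedent_id"].isin(expr_d.columns)]
    dec_ids = [i for i in expr_d.columns]
    n_genes = len(expr_d.index)

    # base design per visit row: const, covars, time (gene columns added per gene)
    base_cols = ["const"] + cov_cols + ["time"]
    d = d.assign(const=1.0)
    # per-decedent sufficient statistics under V_i = Z_i G Z_i' + sigma2 I
    p = len(base_cols)
    if interaction:
        g_cols = 4  # g, g*t, g*male, g*t*male ; reported last
    else:
        g_cols = 2  # g, g*t ; reported last
    q = p + g_cols
    # accumulators: A = X'V^-1 X pieces, b = X'V^-1 y pieces
    BB = np.zeros((p, p))
    Bt_list, yB = [], np.zeros(p)
    # per-decedent cross products with the gene-multiplied columns
    # u_i = [1, t] scaled by g (and male interactions); precompute per decedent:
    # B'V^-1 U0, U0'V^-1 U0, U0'V^-1 y where U0 = [1, t] (and male-scaled copies)
    stats_per_dec = []
    grouped = d.groupby("decedent_id", sort=False)
    for did, grp in grouped:
        t = grp["time"].to_numpy(dtype=float)
        ni = len(t)
        Z = np.column_stack([np.ones(ni), t])
        V = Z @ G @ Z.T + sigma2 * np.eye(ni)
        Vi = np.linalg.inv(V)
        B = grp[base_cols].to_numpy(dtype=float)
        if interaction:
            m = float(grp["sex_male"].iloc[0])
            U0 = np.column_stack([np.ones(ni), t, m * np.ones(ni), m * t])
        else:
            U0 = Z
        y = grp["cognition"].to_numpy(dtype=float)
        BB += B.T @ Vi @ B
        yB += B.T @ Vi @ y
        stats_per_dec.append(
            (did, B.T @ Vi @ U0, U0.T @ Vi @ U0, U0.T @ Vi @ y)
        )
    dec_index = {did: i for i, (did, *_) in enumerate(stats_per_dec)}
    BU = np.stack([s[1] for s in stats_per_dec])   # n_dec x p x g_cols
    UU = np.stack([s[2] for s in stats_per_dec])   # n_dec x g_cols x g_cols
    Uy = np.stack([s[3] for s in stats_per_dec])   # n_dec x g_cols
    order = [dec_index[c] for c in expr_d.columns]
    Gmat = expr_d.to_numpy(dtype=float)[:, order]  # genes x n_dec aligned

    rows = []
    for gi in range(n_genes):
        g = Gmat[gi]
        if np.isclose(g.var(), 0.0):
            rows.append((np.nan, np.nan, np.nan, np.nan, False))
            continue
        XX = np.zeros((q, q))
        Xy = np.zeros(q)
        XX[:p, :p] = BB
        Xy[:p] = yB
        XX[:p, p:] = np.einsum("d,dpg->pg", g, BU)
        XX[p:, :p] = XX[:p, p:].T
        XX[p:, p:] = np.einsum("d,dgh->gh", g**2, UU)
        Xy[p:] = np.einsum("d,dg->g", g, Uy)
        try:
            C = np.linalg.inv(XX)
        except np.linalg.LinAlgError:
            rows.append((np.nan, np.nan, np.nan, np.nan, False))
            continue
        b = C @ Xy
        beta = b[-1]
        se = np.sqrt(C[-1, -1])
        z = beta / se
        pval = 2.0 * stats.norm.sf(abs(z))
        rows.append((beta, se, z, pval, True))
    out = pd.DataFrame(rows, columns=["beta", "se", "statistic", "p", "estimable"])
    out.insert(0, "gene", expr_d.index.to_numpy())
    out["region"] = region
    out["outcome"] = "cognition"
    out["stratum"] = "interaction" if interaction else stratum
    out["term"] = "sex:gene:time" if interaction else "gene:time"
    out["n"] = len(dec_ids)
    out["df"] = np.inf
    out["model"] = "gls-plugin"
    return out


def fit_interaction(
    gene_expr: pd.Series,
    outcome: pd.Series | None = None,
    visits: pd.DataFrame | None = None,
    covariates: pd.DataFrame | None = None,
    sex: pd.Series | None = None,
    gene: str = "gene",
    outcome_name: str = "outcome",
    region: str = "",
) -> AssociationResult:
    """Sex-moderation model on the pooled sample (female reference).

    Cross-sectional (``outcome`` given): adds sex and sex x gene; the reported
    term is sex x gene. Longitudinal (``visits`` given): adds sex, sex x gene,
    sex x time and sex x gene x time; the reported term is sex x gene x time.
    """
    if sex is None:
        raise ValueError("sex labels are required")
    if (outcome is None) == (visits is None):
        raise ValueError("provide exactly one of outcome or visits")
    if sex.nunique() < 2:
        raise ValueError("interaction models require both sexes")
    male = (sex == "male").astype(float)
    if outcome is not None:
        idx = gene_expr.index.intersection(outcome.index)
        X = _design(covariates, idx)
        X["sex_male"] = male.loc[idx]
        X["gene"] = gene_expr.loc[idx]
        X["sex:gene"] = X["sex_male"] * X["gene"]
        X = _drop_collinear(X)
        y = outcome.loc[idx].to_numpy(dtype=float)
        res = sm.OLS(y, X.to_numpy(dtype=float)).fit()
        j = list(X.columns).index("sex:gene")
        return AssociationResult(
            gene=gene, outcome=outcome_name, stratum="interaction",
            beta=float(res.params[j]), se=float(res.bse[j]),
            statistic=float(res.tvalues[j]), p=float(res.pvalues[j]),
            n=int(res.nobs), df=float(res.df_resid), model="ols",
            region=region, term="sex:gene",
        )
    d = _merge_visits(gene_expr, visits, covariates)
    d["sex_male"] = d["decedent_id"].map(male)
    d = d.dropna(subset=["sex_male"])
    for a, b, nm in (
        ("gene", "time", "gene:time"),
        ("sex_male", "gene", "sex:gene"),
        ("sex_male", "time", "sex:time"),
    ):
        d[nm] = d[a] * d[b]
    d["sex:gene:time"] = d["sex_male"] * d["gene"] * d["time"]
    fixed = ["gene", "time", "gene:time", "sex_male", "sex:gene", "sex:time",
             "sex:gene:time"]
    cov_cols = [c for c in d.columns if c not in
                ("decedent_id", "visit", "time", "cognition") and c not in fixed]
    X = d[fixed + cov_cols].copy()
    X.insert(0, "const", 1.0)
    X = _drop_collinear(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = sm.MixedLM(
            d["cognition"].to_numpy(dtype=float), X.to_numpy(dtype=float),
            groups=d["decedent_id"].to_numpy(),
            exog_re=d.assign(const=1.0)[["const", "time"]].to_numpy(dtype=float),
        )
        res = _fit_mixed(md)
    beta, se, z, p = _wald(res.fe_params, res.bse_fe, list(X.columns), "sex:gene:time")
    return AssociationResult(
        gene=gene, outcome="cognition", stratum="interaction", beta=beta, se=se,
        statistic=z, p=p, n=d["decedent_id"].nunique(), df=np.inf,
        model="mixedlm", region=region, term="sex:gene:time",
    )


def fit_three_way(
    gene_expr: pd.Series,
    visits: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    sex: pd.Series | None = None,
    apoe_positive: pd.Series | None = None,
    gene: str = "gene",
    region: str = "",
) -> AssociationResult:
    """Sex x gene x APOE-e4 moderation of cognitive decline.

    Fits the full factorial of gene, sex, APOE-e4 positivity and time (all
    nested two- and three-way products) and reports the
    sex x gene x APOE x time coefficient. Per-cell gene x time slopes for the
    four sex x APOE subgroups are returned in ``extra['subgroup_slopes']``.
    """
    if sex is None or apoe_positive is None:
        raise ValueError("sex and apoe_positive are required")
    apoe = apoe_positive.astype(float)
    if apoe.nunique() < 2:
        raise ValueError("APOE-e4 status is constant in this sample")
    male = (sex == "male").astype(float)
    cells = pd.crosstab(sex, apoe_positive)
    if (cells == 0).any().any() or cells.shape != (2, 2):
        empty = [
            f"{s} x apoe={a}" for s in ("female", "male") for a in (0, 1)
            if s not in cells.index or a not in cells.columns
            or cells.loc[s, a] == 0
        ]
        raise ValueError(f"empty sex x APOE cell(s): {', '.join(empty)}")
    d = _merge_visits(gene_expr, visits, covariates)
    d["sex_male"] = d["decedent_id"].map(male)
    d["apoe"] = d["decedent_id"].map(apoe)
    d = d.dropna(subset=["sex_male", "apoe"])
    base = {"g": d["gene"], "s": d["sex_male"], "a": d["apoe"], "t": d["time"]}
    terms = {}
    for name in ("g", "s", "a", "t", "gs", "ga", "sa", "gt", "st", "at",
                 "gsa", "gst", "gat", "sat", "gsat"):
        v = np.ones(len(d))
        for ch in name:
            v = v * base[ch].to_numpy(dtype=float)
        terms[name] = v
    cov_cols = [c for c in d.columns if c not in
                ("decedent_id", "visit", "time", "cognition", "gene",
                 "sex_male", "apoe")]
    X = pd.DataFrame(terms, index=d.index)
    for c in cov_cols:
        X[c] = d[c]
    X.insert(0, "const", 1.0)
    X = _drop_collinear(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = sm.MixedLM(
            d["cognition"].to_numpy(dtype=float), X.to_numpy(dtype=float),
            groups=d["decedent_id"].to_numpy(),
            exog_re=d.assign(const=1.0)[["const", "time"]].to_numpy(dtype=float),
        )
        res = _fit_mixed(md)
    names = list(X.columns)
    beta, se, z, p = _wald(res.fe_params, res.bse_fe, names, "gsat")
    coef = dict(zip(names, res.fe_params))
    slopes = {}
    for s_lab, s_val in (("female", 0.0), ("male", 1.0)):
        for a_val in (0.0, 1.0):
            slope = coef.get("gt", 0.0) + s_val * coef.get("gst", 0.0) \
                + a_val * coef.get("gat", 0.0) + s_val * a_val * coef.get("gsat", 0.0)
            slopes[f"{s_lab}_apoe{int(a_val)}"] = slope
    return AssociationResult(
        gene=gene, outcome="cognition", stratum="interaction", beta=beta,
        se=se, statistic=z, p=p, n=d["decedent_id"].nunique(), df=np.inf,
        model="mixedlm", region=region, term="sex:gene:apoe:time",
        extra={"subgroup_slopes": slopes},
    )


def sensitivity_refit(
    kind: str,
    gene_expr: pd.Series,
    outcome_or_visits,
    covariates: pd.DataFrame | None,
    extra_covariates: pd.DataFrame,
    **kwargs,
) -> AssociationResult:
    """Refit a base model with extra covariates (APOE status, amyloid, tau).

    ``kind`` is "cross_sectional" or "longitudinal". The result is tagged
    ``sensitivity`` in ``extra``; sensitivity p-values are reported
    uncorrected by convention (discovery FDR never applies to them).
    """
    if extra_covariates is None or extra_covariates.shape[1] == 0:
        extra = None
    else:
        extra = extra_covariates
    if kind == "cross_sectional" and extra is not None:
        y = outcome_or_visits
        for c in extra.columns:
            common = y.index.intersection(extra.index)
            if np.allclose(y.loc[common].to_numpy(dtype=float),
                           extra[c].loc[common].to_numpy(dtype=float)):
                raise ValueError(f"sensitivity covariate {c!r} is identical to the outcome")
    cov = covariates
    if extra is not None:
        cov = extra if cov is None else cov.join(extra, how="inner")
    if kind == "cross_sectional":
        res = fit_cross_sectional(gene_expr, outcome_or_visits, cov, **kwargs)
    elif kind == "longitudinal":
        res = fit_longitudinal(gene_expr, outcome_or_visits, cov, **kwargs)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    res.extra["sensitivity"] = list(extra.columns) if extra is not None else []
    return res


def compare_sensitivity(
    base: list[AssociationResult], sens: list[AssociationResult], alpha: float = 0.05
) -> pd.DataFrame:
    """Which base-significant results remain p <= alpha after adjustment."""
    rows = []
    sens_by_gene = {r.gene: r for r in sens}
    for b in base:
        if b.p_fdr is not None and b.p_fdr <= alpha:
            s = sens_by_gene.get(b.gene)
            rows.append((b.gene, b.outcome, b.stratum, b.p_fdr,
                         s.p if s else np.nan,
                         bool(s and s.p <= alpha)))
    return pd.DataFrame(
        rows, columns=["gene", "outcome", "stratum", "base_p_fdr",
                       "sensitivity_p", "retained"]
    )


def wilcoxon_sex_difference(
    gene_expr: pd.Series, sex: pd.Series
) -> tuple[float, float]:
    """Two-sided rank-sum comparison of expression between the sexes.

    Exact enumeration when both groups have n <= 10 and the data are
    tie-free; normal approximation with tie correction otherwise.
    """
    idx = gene_expr.index.intersection(sex.index)
    x = gene_expr.loc[idx]
    s = sex.loc[idx]
    f = x[s == "female"].to_numpy(dtype=float)
    m = x[s == "male"].to_numpy(dtype=float)
    if len(f) == 0 or len(m) == 0:
        raise ValueError("both sexes must be present")
    vals = np.concatenate([f, m])
    ties = len(np.unique(vals)) < len(vals)
    method = "exact" if (len(f) <= 10 and len(m) <= 10 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(f, m, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
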