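"""Propensity-score matching of females to males with balance diagnostics.

The female excess of the cohort is subsampled by 1:1 greedy nearest-neighbor
matching on the logit of a propensity score — the fitted probability of
being male from a logistic model on the six matching criteria (age at death,
PMI, education, latency to death, race, APOE-e4 allele count). Matching is
without replacement, males are processed in descending score order, ties are
broken by decedent id, and an optional caliper leaves distant males
unmatched. Post-match balance is checked criterion by criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

CRITERIA = ("age_death", "pmi", "education", "latency", "race", "apoe4")
CONTINUOUS_CRITERIA = ("age_death", "pmi", "education", "latency")
CATEGORICAL_CRITERIA = ("race", "apoe4")


@dataclass
class MatchResult:
    """Matched pairs, per-decedent scores, and the balance table."""

    pairs: list           # (male_id, female_id)
    scores: pd.Series     # propensity in (0, 1), all decedents
    unmatched_males: list = field(default_factory=list)
    balance: pd.DataFrame | None = None
    balanced: bool | None = None

    @property
    def matched_ids(self) -> list:
        return [i for pair in self.pairs for i in pair]


def _criteria_design(cohort: pd.DataFrame, criteria) -> pd.DataFrame:
    cols = {}
    for c in criteria:
        if c not in cohort.columns:
            raise ValueError(f"cohort lacks matching criterion {c!r}")
        col = cohort[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            for d in dummies.columns:
                cols[d] = dummies[d]
        else:
            cols[c] = col.astype(float)
    X = pd.DataFrame(cols, index=cohort.index)
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValueError(f"missing values in matching criteria: {bad}")
    return X


def estimate_propensity(
    cohort: pd.DataFrame, criteria=CRITERIA
) -> pd.Series:
    """Fitted probability of being male from a logistic model on the criteria.

    Uses an unpenalized maximum-likelihood logit; on perfect separation or
    non-convergence it falls back to a ridge-penalized fit with a warning.
    """
    X = _criteria_design(cohort, criteria)
    y = (cohort["sex"] == "male").astype(float)
    Xc = sm.add_constant(X.to_numpy(dtype=float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            res = sm.Logit(y.to_numpy(), Xc).fit(disp=0, maxiter=200)
        scores = res.predict(Xc)
        if not np.all(np.isfinite(scores)):
            raise ValueError("non-finite fitted probabilities")
    except Exception:
        warnings.warn("logit did not converge cleanly; using ridge-penalized fit")
        lr = LogisticRegression(C=1.0, max_iter=2000)
        lr.fit(X.to_numpy(dtype=float), y.to_numpy())
        scores = lr.predict_proba(X.to_numpy(dtype=float))[:, 1]
    eps = 1e-12
    return pd.Series(np.clip(scores, eps, 1 - eps), index=cohort.index,
                     name="propensity")


def match_pairs(
    scores: pd.Series,
    cohort: pd.DataFrame,
    caliper: float | None = None,
) -> MatchResult:
    """1:1 greedy nearest-neighbor matching on the logit of the score.

    Males are processed in descending score order (ties by id); each takes
    the closest unused female on the logit scale (ties by id). With a
    caliper (in logit units), males with no female inside it stay unmatched.
    Deterministic given the inputs; no female is reused.
    """
    sex = cohort["sex"]
    males = sorted(sex.index[sex == "male"])
    females = sorted(sex.index[sex == "female"])
    if not females:
        raise ValueError("no female decedents to match against")
    if not males:
        raise ValueError("no male decedents to match")
    logit = np.log(scores / (1 - scores))
    order = sorted(males, key=lambda i: (-logit[i], i))
    available = {f: logit[f] for f in females}
    pairs, unmatched = [], []
    for m in order:
        if not available:
            unmatched.append(m)
            continue
        best = min(available, key=lambda f: (abs(available[f] - logit[m]), f))
        dist = abs(available[best] - logit[m])
        if caliper is not None and dist > caliper:
            unmatched.append(m)
            continue
        pairs.append((m, best))
        del available[best]
    return MatchResult(pairs=pairs, scores=scores, unmatched_males=unmatched)


def standardized_mean_difference(
    cohort: pd.DataFrame, criterion: str, ids=None
) -> float:
    """Absolute SMD between sexes, pooled-SD denominator."""
    d = cohort if ids is None else cohort.loc[ids]
    f = d.loc[d["sex"] == "female", criterion].astype(float)
    m = d.loc[d["sex"] == "male", criterion].astype(float)
    pooled = np.sqrt((f.var(ddof=1) + m.var(ddof=1)) / 2.0)
    if pooled == 0 or np.isnan(pooled):
        return 0.0
    return float(abs(f.mean() - m.mean()) / pooled)


def check_balance(
    match_result: MatchResult,
    cohort: pd.DataFrame,
    criteria=CRITERIA,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, bool]:
    """Two-sample balance tests on the matched sample, pre vs post.

    Continuous criteria use the two-sample (equal-variance) t-test,
    categorical ones chi-square, or Fisher's exact test when a 2x2 table has
    an expected cell below 5. A constant criterion is reported with p = 1.
    The pass flag is True iff every post-match p > alpha.
    """
    if len(match_result.pairs) < 2:
        raise ValueError("balance check needs at least 2 matched pairs")
    matched = match_result.matched_ids
    rows = []
    for c in criteria:
        if c not in cohort.columns:
            continue
        is_cat = cohort[c].dtype == object or c in CATEGORICAL_CRITERIA
        entry = {"criterion": c}
        for scope, ids in (("pre", None), ("post", matched)):
            d = cohort if ids is None else cohort.loc[ids]
            f = d.loc[d["sex"] == "female", c]
            m = d.loc[d["sex"] == "male", c]
            if d[c].nunique() <= 1:
                p, note = 1.0, "constant"
            elif is_cat:
                tab = pd.crosstab(d["sex"], d[c])
                expected = stats.contingency.expected_freq(tab.to_numpy())
                if tab.shape == (2, 2) and (expected < 5).any():
                    _, p = stats.fisher_exact(tab.to_numpy())
                    note = "fisher"
                else:
                    if (expected < 5).any():
                        note = "chi2_small_cells"
                    else:
                        note = "chi2"
                    _, p, _, _ = stats.chi2_contingency(tab.to_numpy())
            else:
                _, p = stats.ttest_ind(f.astype(float), m.astype(float),
                                       equal_var=True)
                note = "ttest"
            entry[f"{scope}_p"] = float(p)
            entry[f"{scope}_test"] = note
            if not is_cat:
                entry[f"{scope}_smd"] = standardized_mean_difference(cohort, c, ids)
        rows.append(entry)
    balance = pd.DataFrame(rows)
    passed = bool((balance["post_p"] > alpha).all())
    return balance, passed


class PropensityMatcher(BaseEstimator):
    """Sklearn-style wrapper for the whole matching stage.

    Parameters
    ----------
    criteria : tuple of str
        Matching criteria; categoricals are expanded to indicators, APOE-e4
        enters as the 0/1/2 allele count.
    caliper : float or None
        Maximum allowed logit-score distance for a pair.
    alpha : float
        Balance-test significance level.

    After ``fit(cohort)``: ``scores_``, ``pairs_``, ``unmatched_males_``,
    ``balance_``, ``balanced_``, ``matched_ids_``.
    """

    def __init__(self, criteria=CRITERIA, caliper: float | None = None,
                 alpha: float = 0.05):
        self.criteria = criteria
        self.caliper = caliper
        self.alpha = alpha

    def fit(self, cohort: pd.DataFrame, y=None) -> "PropensityMatcher":
        scores = estimate_propensity(cohort, self.criteria)
        result = match_pairs(scores, cohort, caliper=self.caliper)
        if len(result.pairs) >= 2:
            balance, passed = check_balance(result, cohort, self.criteria,
                                            self.alpha)
        else:
            balance, passed = None, None
        self.scores_ = scores
        self.pairs_ = result.pairs
        self.unmatched_males_ = result.unmatched_males
        self.balance_ = balance
        self.balanced_ = passed
        self.matched_ids_ = result.matched_ids
        self.result_ = MatchResult(
            pairs=result.pairs, scores=scores,
            unmatched_males=result.unmatched_males, balance=balance,
            balanced=passed,
        )
        return self

    def transform(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """Return the matched subsample of the cohort."""
        return cohort.loc[self.matched_ids_]
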