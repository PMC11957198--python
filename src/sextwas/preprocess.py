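"""Counts-to-analysis-ready expression: QC, normalization, residualization.

The fixed stage order is: sample QC (RIN/PMI/missingness) -> low-expression
gene filter (CPM, per diagnosis group) -> log2-CPM normalization with
per-sample GC and log-length detrending -> 5-SD winsorization (outliers set
to 0) -> PCA-based sample QC with a sex-concordance check -> residualization
on technical covariates -> per-gene mean-centering. Chromosome classes
(autosomal, X, Y) are processed as separate matrices, the Y matrix on male
samples only. A :class:`QCReport` reconciles dropped + kept = input at every
step.

Matrix orientation: file-level matrices are genes x samples (the common
counts-file layout); the sklearn-style transformers follow the sklearn
convention of samples x features and the functional wrappers transpose as
needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

REQUIRED_COVARIATES = ("sex", "age_death", "pmi", "rin")


@dataclass
class QCStep:
    name: str
    n_in: int
    n_kept: int
    dropped: dict  # id -> reason

    def __post_init__(self) -> None:
        if self.n_kept + len(self.dropped) != self.n_in:
            raise ValueError(
                f"QC step {self.name!r} does not reconcile: "
                f"{self.n_kept} kept + {len(self.dropped)} dropped != {self.n_in} in"
            )


@dataclass
class QCReport:
    """Per-step tally of dropped samples/genes with reasons."""

    steps: list = field(default_factory=list)

    def add(self, name: str, n_in: int, kept, dropped: dict) -> None:
        self.steps.append(QCStep(name, n_in, len(kept), dict(dropped)))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            if s.dropped:
                for item, reason in s.dropped.items():
                    rows.append((s.name, s.n_in, s.n_kept, item, reason))
            else:
                rows.append((s.name, s.n_in, s.n_kept, "", ""))
        return pd.DataFrame(
            rows, columns=["step", "n_in", "n_kept", "dropped_id", "reason"]
        )

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.n_in, s.n_kept, len(s.dropped)) for s in self.steps],
            columns=["step", "n_in", "n_kept", "n_dropped"],
        )


def qc_samples(
    cohort: pd.DataFrame,
    rin_min: float = 4.0,
    pmi_max_hours: float = 24.0,
    required: tuple = REQUIRED_COVARIATES,
    report: QCReport | None = None,
) -> tuple[list, QCReport]:
    """Drop samples failing RIN/PMI thresholds or missing required covariates.

    Retained iff RIN >= rin_min, PMI <= pmi_max_hours and no required
    covariate is missing (boundary values are kept; the removal rules are the
    strict inequalities RIN < 4, PMI > 24). Missing RIN or PMI drops with
    reason "missing".
    """
    report = report or QCReport()
    if cohort.empty:
        warnings.warn("qc_samples received an empty cohort")
        report.add("sample_qc", 0, [], {})
        return [], report
    dropped: dict = {}
    kept = []
    for sid, row in cohort.iterrows():
        missing = [c for c in required if c in cohort.columns and pd.isna(row.get(c))]
        if missing:
            dropped[sid] = "missing"
        elif row["rin"] < rin_min:
            dropped[sid] = "RIN"
        elif row["pmi"] > pmi_max_hours:
            dropped[sid] = "PMI"
        else:
            kept.append(sid)
    report.add("sample_qc", len(cohort), kept, dropped)
    return kept, report


def filter_low_expression(
    counts: pd.DataFrame,
    diagnosis_labels: pd.Series,
    cpm_min: float = 1.0,
    fraction: float = 0.5,
    any_group: bool = True,
    report: QCReport | None = None,
) -> tuple[list, QCReport]:
    """Keep genes expressed at >= cpm_min CPM in >= ``fraction`` of a group.

    ``counts`` is genes x samples. With ``any_group=True`` (default) a gene
    survives if it clears the threshold in at least one diagnosis group; with
    False it must clear it in every group.
    """
    report = report or QCReport()
    libsize = counts.sum(axis=0).astype(float)
    if (libsize <= 0).any():
        zero = list(libsize.index[libsize <= 0])
        raise ValueError(f"zero library size for sample(s): {zero}")
    labels = diagnosis_labels.loc[counts.columns]
    cpm = counts / libsize * 1e6
    per_group = []
    for _, cols in labels.groupby(labels).groups.items():
        frac_ok = (cpm.loc[:, cols] >= cpm_min).mean(axis=1)
        per_group.append(frac_ok >= fraction)
    ok_mat = pd.concat(per_group, axis=1)
    ok = ok_mat.any(axis=1) if any_group else ok_mat.all(axis=1)
    kept = list(counts.index[ok])
    dropped = {g: "low_expression" for g in counts.index[~ok]}
    report.add("gene_filter", len(counts), kept, dropped)
    return kept, report


class GCLengthDetrender(BaseEstimator, TransformerMixin):
    """log2-CPM with per-sample removal of linear GC and log-length trends.

    Stateless per sample: transform computes log2(CPM + 1) and, for each
    sample, regresses expression across genes on centered GC fraction and
    centered log length, subtracting the fitted trend while preserving the
    sample mean. Input/output samples x genes.
    """

    def __init__(self, gc: pd.Series | None = None, length: pd.Series | None = None,
                 log_transform: bool = True):
        self.gc = gc
        self.length = length
        self.log_transform = log_transform

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.gc is None or self.length is None:
            raise ValueError("gc and length annotation are required")
        genes = X.columns
        gc = self.gc.loc[genes].to_numpy(dtype=float)
        ln = np.log(self.length.loc[genes].to_numpy(dtype=float))
        A = X.to_numpy(dtype=float)
        if self.log_transform:
            lib = A.sum(axis=1, keepdims=True)
            cpm = A / lib * 1e6
            A = np.log2(cpm + 1.0)
        D = np.column_stack([np.ones(len(genes)), gc - gc.mean(), ln - ln.mean()])
        # per-sample least squares across genes; shared design -> one solve
        coef, *_ = np.linalg.lstsq(D, A.T, rcond=None)
        trend = (D[:, 1:] @ coef[1:, :]).T  # slope parts only: keep sample mean
        return pd.DataFrame(A - trend, index=X.index, columns=genes)


def normalize(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    report: QCReport | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Normalize a genes x samples counts matrix to detrended log2-CPM.

    Genes missing GC or length annotation are dropped and reported. The
    output carries no linear GC trend (mean per-sample GC slope ~ 0).
    """
    report = report or QCReport()
    ann = annotation.reindex(counts.index)
    ok = ann["gc"].notna() & ann["length"].notna()
    dropped = {g: "missing_annotation" for g in counts.index[~ok]}
    kept = counts.index[ok]
    report.add("annotation_filter", len(counts), list(kept), dropped)
    sub = counts.loc[kept]
    det = GCLengthDetrender(gc=ann.loc[kept, "gc"], length=ann.loc[kept, "length"])
    expr = det.transform(sub.T).T
    return expr, report


class Winsorizer(BaseEstimator, TransformerMixin):
    """Set entries > ``sd_threshold`` SDs from their gene's mean to 0.

    Single pass: thresholds come from the pre-replacement per-gene statistics
    (population SD). Zero-variance genes are untouched. samples x genes.
    """

    def __init__(self, sd_threshold: float = 5.0):
        self.sd_threshold = sd_threshold

    def fit(self, X: pd.DataFrame, y=None):
        A = np.asarray(X, dtype=float)
        self.mean_ = A.mean(axis=0)
        self.sd_ = A.std(axis=0)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        A = np.asarray(X, dtype=float)
        with np.errstate(invalid="ignore"):
            out_mask = np.abs(A - self.mean_) > self.sd_threshold * self.sd_
        out_mask &= self.sd_ > 0
        self.n_replaced_ = int(out_mask.sum())
        A = np.where(out_mask, 0.0, A)
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(A, index=X.index, columns=X.columns)
        return A


def winsorize_outliers(
    expr: pd.DataFrame, sd_threshold: float = 5.0
) -> tuple[pd.DataFrame, int]:
    """Functional wrapper over :class:`Winsorizer` for genes x samples input."""
    w = Winsorizer(sd_threshold=sd_threshold)
    out = w.fit(expr.T).transform(expr.T).T
    return out, w.n_replaced_


def pca_sample_qc(
    expr: pd.DataFrame,
    cohort: pd.DataFrame,
    sd_threshold: float = 5.0,
    n_pcs: int = 2,
    y_expression: pd.Series | None = None,
    escape_expression: pd.Series | None = None,
    report: QCReport | None = None,
) -> tuple[list, QCReport]:
    """Drop PC outliers and samples whose expression contradicts reported sex.

    ``expr`` is genes x samples. Samples more than ``sd_threshold`` SDs from
    the mean on any of the first ``n_pcs`` principal components are dropped.
    If per-sample mean Y-linked expression (and optionally XCI-escape
    expression) is supplied, samples are 2-means-clustered on those axes; the
    cluster with higher Y expression is labelled male, and samples whose
    cluster contradicts reported sex are dropped with reason "sex_mismatch".
    """
    report = report or QCReport()
    samples = list(expr.columns)
    if len(samples) < 3:
        raise ValueError("pca_sample_qc requires at least 3 samples")
    n_pcs_eff = min(n_pcs, len(samples) - 1, expr.shape[0])
    if n_pcs_eff < n_pcs:
        warnings.warn(f"reducing PCs from {n_pcs} to {n_pcs_eff}")
    X = expr.T.to_numpy(dtype=float)
    pcs = PCA(n_components=n_pcs_eff, random_state=0).fit_transform(
        X - X.mean(axis=0)
    )
    sd = pcs.std(axis=0)
    sd[sd == 0] = 1.0
    zz = np.abs((pcs - pcs.mean(axis=0)) / sd)
    outlier = (zz > sd_threshold).any(axis=1)

    mismatch = np.zeros(len(samples), dtype=bool)
    if y_expression is not None:
        feats = [y_expression.loc[samples].to_numpy(dtype=float)]
        if escape_expression is not None:
            feats.append(escape_expression.loc[samples].to_numpy(dtype=float))
        F = np.column_stack(feats)
        Fz = (F - F.mean(axis=0)) / np.where(F.std(axis=0) == 0, 1, F.std(axis=0))
        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(Fz)
        y_means = [F[km.labels_ == k, 0].mean() for k in (0, 1)]
        male_cluster = int(np.argmax(y_means))
        inferred = np.where(km.labels_ == male_cluster, "male", "female")
        reported = cohort.loc[samples, "sex"].to_numpy()
        mismatch = inferred != reported

    dropped = {}
    kept = []
    for i, sid in enumerate(samples):
        if outlier[i]:
            dropped[sid] = "pc_outlier"
        elif mismatch[i]:
            dropped[sid] = "sex_mismatch"
        else:
            kept.append(sid)
    report.add("pca_qc", len(samples), kept, dropped)
    return kept, report


class TechnicalResidualizer(BaseEstimator, TransformerMixin):
    """Per-gene OLS residuals on technical covariates (batch as indicators).

    Collinear design columns are dropped with a warning. After transform,
    every gene is orthogonal to every retained numeric covariate. The fitted
    projection comes from the fit-time samples. samples x genes.
    """

    def __init__(self, covariates: pd.DataFrame | None = None,
                 keep_mean: bool = True):
        self.covariates = covariates
        self.keep_mean = keep_mean

    def _design(self, index) -> np.ndarray:
        C = pd.get_dummies(self.covariates.loc[index], drop_first=True, dtype=float)
        C.insert(0, "const", 1.0)
        A = C.to_numpy(dtype=float)
        keep, rank = [], 0
        for j in range(A.shape[1]):
            r = np.linalg.matrix_rank(A[:, keep + [j]])
            if r > rank:
                keep.append(j)
                rank = r
            else:
                warnings.warn(f"dropping collinear covariate {C.columns[j]!r}")
        self.design_columns_ = [C.columns[j] for j in keep]
        return A[:, keep]

    def fit(self, X: pd.DataFrame, y=None):
        if self.covariates is None:
            raise ValueError("covariates are required")
        D = self._design(X.index)
        self.q_, _ = np.linalg.qr(D)
        self.index_ = list(X.index)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if list(X.index) != self.index_:
            raise ValueError("transform must use the fit-time samples")
        A = X.to_numpy(dtype=float)
        resid = A - self.q_ @ (self.q_.T @ A)
        if self.keep_mean:
            resid = resid + A.mean(axis=0, keepdims=True)
        return pd.DataFrame(resid, index=X.index, columns=X.columns)


def residualize_technical(
    expr: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Residuals of genes x samples expression on the technical covariates."""
    tr = TechnicalResidualizer(covariates=covariates, keep_mean=False)
    return tr.fit(expr.T).transform(expr.T).T


def center_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Mean-center each gene (row) of a genes x samples matrix."""
    return expr.sub(expr.mean(axis=1), axis=0)


def transform_outcomes(pathology: pd.DataFrame | pd.Series):
    """Square-root transform raw pathology, then mean-center.

    Raw values must be non-negative. Returns the centered analysis-scale
    outcome(s).
    """
    vals = pathology.astype(float)
    if (np.asarray(vals) < 0).any():
        raise ValueError("pathology values must be non-negative")
    rooted = np.sqrt(vals)
    return rooted - rooted.mean()


def preprocess_chromosome_class(
    counts: pd.DataFrame,
    annotation: pd.DataFrame,
    cohort: pd.DataFrame,
    samples: pd.DataFrame,
    chromosome_class: str,
    rin_min: float = 4.0,
    pmi_max_hours: float = 24.0,
    cpm_min: float = 1.0,
    cpm_fraction: float = 0.5,
    sd_winsor: float = 5.0,
    technical_covariates: tuple = ("batch", "age_death", "pmi", "rin",
                                   "pct_coding", "pct_intronic", "pct_intergenic"),
    sex_check: bool = True,
) -> tuple[pd.DataFrame, QCReport]:
    """Run the full preprocessing chain for one chromosome class.

    ``counts`` is genes x samples for one brain region; ``samples`` maps
    sample id to decedent. Y-linked matrices are restricted to male samples.
    Returns the centered, residualized expression and the QC report.
    """
    report = QCReport()
    class_genes = annotation.index[annotation["chromosome_class"] == chromosome_class]
    sub = counts.loc[counts.index.intersection(class_genes)]

    per_sample = samples.join(cohort, on="decedent_id")
    if chromosome_class == "Y":
        male_ids = per_sample.index[per_sample["sex"] == "male"]
        sub = sub.loc[:, sub.columns.intersection(male_ids)]
        per_sample = per_sample.loc[sub.columns]
    kept_samples, report = qc_samples(
        per_sample, rin_min=rin_min, pmi_max_hours=pmi_max_hours, report=report
    )
    sub = sub.loc[:, kept_samples]
    kept_genes, report = filter_low_expression(
        sub, per_sample.loc[kept_samples, "diagnosis"], cpm_min=cpm_min,
        fraction=cpm_fraction, report=report,
    )
    sub = sub.loc[kept_genes]
    expr, report = normalize(sub, annotation, report=report)
    expr, _ = winsorize_outliers(expr, sd_threshold=sd_winsor)

    y_mean = esc_mean = None
    if sex_check and chromosome_class != "Y":
        y_genes = annotation.index[annotation["chromosome_class"] == "Y"]
        y_in = counts.index.intersection(y_genes)
        if len(y_in):
            lib = counts.loc[:, expr.columns].sum(axis=0).astype(float)
            y_cpm = counts.loc[y_in, expr.columns] / lib * 1e6
            y_mean = np.log2(y_cpm + 1.0).mean(axis=0)
        if "xci_escape" in annotation.columns:
            esc = annotation.index[annotation["xci_escape"].fillna(False).astype(bool)]
        else:
            esc = annotation.index[:0]
        esc_in = expr.index.intersection(esc)
        if len(esc_in):
            esc_mean = expr.loc[esc_in].mean(axis=0)
    kept_samples, report = pca_sample_qc(
        expr, per_sample, sd_threshold=sd_winsor,
        y_expression=y_mean, escape_expression=esc_mean, report=report,
    )
    expr = expr.loc[:, kept_samples]
    tech = per_sample.loc[kept_samples, [c for c in technical_covariates
                                         if c in per_sample.columns]]
    expr = residualize_technical(expr, tech)
    expr = center_genes(expr)
    return expr, report
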