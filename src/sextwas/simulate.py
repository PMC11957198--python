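"""Synthetic autopsy-cohort generator with planted sex-specific gene effects.

Emulates the structure of a two-to-one female-excess brain-donation cohort:
per-decedent covariates, three brain regions with region-specific sample
availability, negative-binomial RNA-seq counts for autosomal, X-linked and
Y-linked genes (with sex-dependent dosage and X-inactivation escape),
square-root-scale pathology outcomes, and longitudinal cognition with
per-decedent random intercepts and random slopes. Every planted effect is
recorded in a :class:`GroundTruth` so downstream stages can be tested for
recovery and calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

REGIONS = ("DLPFC", "PCC", "CN")
OUTCOMES = ("amyloid", "tau", "cognition")
DIAGNOSES = ("NC", "MCI", "AD")

# Stage offsets keep the per-operation RNG streams independent under one seed.
_STREAM_COHORT = 1
_STREAM_COUNTS = 2
_STREAM_OUTCOMES = 3
_STREAM_GENESETS = 4


@dataclass(frozen=True)
class CausalEffect:
    """A planted gene effect: which gene, which outcome, in which sex.

    ``effect`` is on the standardized analysis scale: for pathology it is the
    shift in square-root-scale outcome per SD of latent expression; for
    cognition it is the shift in annual slope per SD of latent expression.
    """

    gene: int
    outcome: str
    stratum: str  # "female" | "male" | "both"
    effect: float

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.stratum not in ("female", "male", "both"):
            raise ValueError(f"unknown stratum {self.stratum!r}")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the cohort the pipeline was designed around: 328 males and
    640 females across three brain regions, on average 7.4 annual cognitive
    visits, ~26% APOE-e4 carriers, a predominantly single-category race
    variable, and about a third of X-linked genes escaping inactivation. The
    gene panel is a desk-scale transcriptome (hundreds of genes, not tens of
    thousands); counts are negative-binomial with sample-specific library
    sizes and per-sample GC/length trends for the normalization stage.
    """

    n_male: int = 328
    n_female: int = 640
    n_regions: int = 3
    n_genes_autosomal: int = 500
    n_genes_x: int = 40
    n_genes_y: int = 10
    causal_table: Sequence[CausalEffect] = field(default_factory=tuple)
    nb_dispersion: float = 0.2
    library_size_range: tuple[float, float] = (5e5, 2e6)
    xci_escape_fraction: float = 1.0 / 3.0
    xci_escape_dosage: float = 1.4
    y_female_leakage: float = 1e-7
    visits_mean: float = 7.4
    seed: int = 0

    # covariate structure
    age_mean: float = 88.3
    age_sd: float = 6.5
    education_mean: float = 16.3
    education_sd: float = 3.5
    apoe4_allele_freq: float = 0.14
    qc_fail_fraction: float = 0.05
    sex_shift: dict = field(default_factory=lambda: {"age_death": 2.0, "education": -0.8})
    two_race_categories: bool = False
    region_missingness: float = 0.35

    # expression structure
    bio_sd_log2: float = 0.5
    gc_slope_sd: float = 0.3
    length_slope_sd: float = 0.1

    # outcome structure
    pathology_noise_sd: float = 1.0
    pathology_raw_scale: bool = False
    female_tau_shift: float = 0.2
    rand_intercept_sd: float = 0.6
    rand_slope_sd: float = 0.05
    cognition_noise_sd: float = 0.25
    mean_slope: float = -0.05

    def __post_init__(self) -> None:
        coerced = []
        for eff in self.causal_table:  # allow plain tuples/dicts (e.g. from YAML)
            if isinstance(eff, CausalEffect):
                coerced.append(eff)
            elif isinstance(eff, dict):
                coerced.append(CausalEffect(**eff))
            else:
                coerced.append(CausalEffect(*eff))
        self.causal_table = tuple(coerced)
        for name in ("n_male", "n_female", "n_regions", "n_genes_autosomal",
                     "n_genes_x", "n_genes_y"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not (0.0 <= self.xci_escape_fraction <= 1.0):
            raise ValueError("xci_escape_fraction must be in [0, 1]")
        if not (0.0 <= self.region_missingness < 1.0):
            raise ValueError("region_missingness must be in [0, 1)")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library_size_range must be positive and ordered")
        if self.visits_mean <= 0:
            raise ValueError("visits_mean must be positive")
        n_genes = self.n_genes_autosomal + self.n_genes_x + self.n_genes_y
        for eff in self.causal_table:
            if not (0 <= eff.gene < n_genes):
                raise ValueError(f"causal gene index {eff.gene} out of range")

    @property
    def n_genes(self) -> int:
        return self.n_genes_autosomal + self.n_genes_x + self.n_genes_y

    def regions(self) -> tuple[str, ...]:
        return REGIONS[: self.n_regions]


@dataclass
class GroundTruth:
    """Book-keeping of everything planted into a simulated dataset."""

    effects: pd.DataFrame          # columns: gene, outcome, sex, beta
    latent: pd.DataFrame           # genes x decedents standardized expression
    annotation: pd.DataFrame       # gene annotation incl. causal flags
    random_effects: pd.DataFrame | None = None  # decedent intercept/slope

    def true_effect(self, gene: str, outcome: str, sex: str) -> float:
        """Planted effect of ``gene`` on ``outcome`` in ``sex`` (0 if none)."""
        m = self.effects
        hit = m[(m["gene"] == gene) & (m["outcome"] == outcome) & (m["sex"] == sex)]
        return float(hit["beta"].sum())


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Draw per-decedent covariates with configurable sex shifts.

    Returns a DataFrame indexed by ``decedent_id`` with the six matching
    criteria (age at death, PMI, education, latency to death, race, APOE-e4
    allele count) plus RIN, diagnosis, batch, and alignment-metric columns. A
    ``qc_fail_fraction`` of decedents is given RIN < 4 or PMI > 24 h so the
    QC stage has work to do.
    """
    rng = _rng(config, _STREAM_COHORT)
    n = config.n_male + config.n_female
    sex = np.array(["male"] * config.n_male + ["female"] * config.n_female)
    is_f = sex == "female"

    age = rng.normal(config.age_mean, config.age_sd, n)
    edu = rng.normal(config.education_mean, config.education_sd, n)
    pmi = rng.gamma(3.0, 2.3, n)
    latency = rng.gamma(2.0, 0.55, n)
    shifts = dict(config.sex_shift)
    cols = {"age_death": age, "education": edu, "pmi": pmi, "latency": latency}
    for name, delta in shifts.items():
        if name not in cols:
            raise ValueError(f"sex_shift refers to unknown covariate {name!r}")
        cols[name] = cols[name] + delta * is_f
    cols["age_death"] = np.clip(cols["age_death"], 65.0, 110.0)
    cols["education"] = np.clip(np.round(cols["education"]), 6, 30)
    cols["pmi"] = np.clip(cols["pmi"], 0.5, None)
    cols["latency"] = np.clip(cols["latency"], 0.0, None)

    apoe4 = rng.binomial(2, config.apoe4_allele_freq, n)
    rin = np.clip(rng.normal(7.2, 1.1, n), 1.0, 10.0)

    # planted QC failures, split between the RIN and PMI rules
    fail = rng.random(n) < config.qc_fail_fraction
    fail_kind = rng.random(n) < 0.5
    rin = np.where(fail & fail_kind, rng.uniform(1.5, 3.9, n), rin)
    cols["pmi"] = np.where(fail & ~fail_kind, rng.uniform(24.5, 48.0, n), cols["pmi"])

    if config.two_race_categories:
        race = np.where(rng.random(n) < 0.98, "NHW", "other")
    else:
        race = np.repeat("NHW", n)
    diagnosis = rng.choice(DIAGNOSES, size=n, p=(0.35, 0.25, 0.40))
    batch = rng.integers(0, 3, n)

    cohort = pd.DataFrame(
        {
            "sex": sex,
            "age_death": cols["age_death"],
            "pmi": cols["pmi"],
            "education": cols["education"],
            "latency": cols["latency"],
            "race": race,
            "apoe4": apoe4,
            "rin": rin,
            "diagnosis": diagnosis,
            "batch": batch.astype(str),
            "pct_coding": np.clip(rng.normal(0.45, 0.05, n), 0.2, 0.7),
            "pct_intronic": np.clip(rng.normal(0.30, 0.04, n), 0.1, 0.5),
            "pct_intergenic": np.clip(rng.normal(0.10, 0.02, n), 0.02, 0.3),
        },
        index=pd.Index([f"D{i:04d}" for i in range(n)], name="decedent_id"),
    )
    return cohort


def _gene_annotation(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    ids = (
        [f"GA{i:04d}" for i in range(config.n_genes_autosomal)]
        + [f"GX{i:03d}" for i in range(config.n_genes_x)]
        + [f"GY{i:02d}" for i in range(config.n_genes_y)]
    )
    chrom = (
        ["autosomal"] * config.n_genes_autosomal
        + ["X"] * config.n_genes_x
        + ["Y"] * config.n_genes_y
    )
    n = len(ids)
    escape = np.zeros(n, dtype=bool)
    n_escape = int(round(config.xci_escape_fraction * config.n_genes_x))
    x_lo = config.n_genes_autosomal
    escape[x_lo : x_lo + n_escape] = True
    ann = pd.DataFrame(
        {
            "chromosome_class": chrom,
            "gc": rng.uniform(0.35, 0.65, n),
            "length": np.exp(rng.normal(7.8, 0.7, n)),
            "xci_escape": escape,
        },
        index=pd.Index(ids, name="gene_id"),
    )
    for eff in config.causal_table:
        gid = ids[eff.gene]
        ann.loc[gid, f"causal_{eff.outcome}"] = eff.stratum
    return ann


def generate_counts(
    config: SimulationConfig, cohort: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate negative-binomial counts for every (decedent, region) sample.

    Returns ``(counts, samples, annotation, truth)``: counts is genes x
    samples; ``samples`` maps sample id to decedent and region. Each decedent
    contributes a region-shared latent standardized expression deviate per
    gene (the biological signal that outcomes are planted on); counts add
    region effects, per-sample GC and log-length trends, library-size
    variation, and gamma-Poisson (negative binomial) noise with variance
    ``m + dispersion * m**2``. Y-linked genes are essentially silent in
    females; XCI-escape genes get an elevated female mean.
    """
    if cohort.empty:
        raise ValueError("cohort must be non-empty")
    if config.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    rng = _rng(config, _STREAM_COUNTS)
    ann = _gene_annotation(config, rng)
    genes = ann.index.to_numpy()
    n_genes = len(genes)
    decedents = cohort.index.to_numpy()
    n_dec = len(decedents)
    regions = config.regions()

    # per-decedent latent standardized expression, shared across regions
    z = rng.standard_normal((n_genes, n_dec))
    latent = pd.DataFrame(z, index=ann.index, columns=decedents)

    # sample availability: every decedent keeps >= 1 region
    avail = rng.random((n_dec, len(regions))) >= config.region_missingness
    none = ~avail.any(axis=1)
    if none.any():
        forced = rng.integers(0, len(regions), none.sum())
        avail[np.flatnonzero(none), forced] = True

    mu = rng.normal(5.0, 2.0, n_genes)  # baseline log2 relative abundance
    region_shift = rng.normal(0.0, 0.2, (len(regions), n_genes))
    is_f = (cohort["sex"] == "female").to_numpy()
    is_y = (ann["chromosome_class"] == "Y").to_numpy()
    escape = ann["xci_escape"].to_numpy()

    gc_c = ann["gc"].to_numpy() - ann["gc"].mean()
    loglen_c = np.log(ann["length"].to_numpy())
    loglen_c -= loglen_c.mean()

    blocks, sample_rows = [], []
    for r_i, region in enumerate(regions):
        dec_idx = np.flatnonzero(avail[:, r_i])
        n_s = len(dec_idx)
        log2rel = (
            mu[:, None]
            + config.bio_sd_log2 * z[:, dec_idx]
            + region_shift[r_i][:, None]
        )
        fem = is_f[dec_idx]
        log2rel[np.ix_(escape, fem)] += np.log2(config.xci_escape_dosage)
        gc_slope = rng.normal(0.0, config.gc_slope_sd, n_s)
        len_slope = rng.normal(0.0, config.length_slope_sd, n_s)
        log2rel += gc_c[:, None] * gc_slope[None, :]
        log2rel += loglen_c[:, None] * len_slope[None, :]
        rel = np.exp2(log2rel)
        rel[np.ix_(is_y, fem)] *= config.y_female_leakage
        rel /= rel.sum(axis=0, keepdims=True)
        lib = rng.uniform(*config.library_size_range, n_s)
        m = rel * lib[None, :]
        lam = rng.gamma(1.0 / config.nb_dispersion, config.nb_dispersion * m)
        counts = rng.poisson(lam)
        blocks.append(counts)
        for d in dec_idx:
            sample_rows.append((f"{decedents[d]}_{region}", decedents[d], region))

    sample_ids = [r[0] for r in sample_rows]
    counts_df = pd.DataFrame(
        np.concatenate(blocks, axis=1),
        index=ann.index,
        columns=pd.Index(sample_ids, name="sample_id"),
    )
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "decedent_id", "region"]
    ).set_index("sample_id")

    eff_rows = []
    for eff in config.causal_table:
        gid = genes[eff.gene]
        for sx in (("female", "male") if eff.stratum == "both" else (eff.stratum,)):
            eff_rows.append((gid, eff.outcome, sx, eff.effect))
    effects = pd.DataFrame(eff_rows, columns=["gene", "outcome", "sex", "beta"])
    truth = GroundTruth(effects=effects, latent=latent, annotation=ann)
    return counts_df, samples, ann, truth


@dataclass
class OutcomeTables:
    pathology: pd.DataFrame      # index decedent_id: amyloid, tau (analysis scale)
    visits: pd.DataFrame         # long: decedent_id, visit, time, cognition
    random_effects: pd.DataFrame  # index decedent_id: intercept, slope


def generate_outcomes(
    config: SimulationConfig,
    cohort: pd.DataFrame,
    true_expression: pd.DataFrame,
) -> OutcomeTables:
    """Generate pathology and longitudinal cognition from latent expression.

    Pathology is generated directly on the square-root (analysis) scale:
    covariate effects plus planted sex-specific gene effects plus Gaussian
    noise; set ``pathology_raw_scale`` to emit squared (raw) values instead.
    Cognition visits are annually spaced with time measured backwards from the
    final visit (time <= 0, so a positive slope-interaction means slower
    decline); each decedent gets a random intercept and a random slope, and
    planted cognition effects act on the slope.
    """
    if not set(cohort.index) <= set(true_expression.columns):
        raise ValueError("cohort decedents and expression columns do not match")
    rng = _rng(config, _STREAM_OUTCOMES)
    dec = cohort.index.to_numpy()
    n = len(dec)
    z = true_expression.loc[:, dec]
    is_f = (cohort["sex"] == "female").to_numpy()

    age_c = cohort["age_death"].to_numpy() - cohort["age_death"].mean()
    apoe = cohort["apoe4"].to_numpy()

    def planted(outcome: str) -> np.ndarray:
        total = np.zeros(n)
        for eff in config.causal_table:
            if eff.outcome != outcome:
                continue
            zg = z.iloc[eff.gene].to_numpy()
            if eff.stratum == "both":
                total += eff.effect * zg
            elif eff.stratum == "female":
                total += eff.effect * zg * is_f
            else:
                total += eff.effect * zg * (~is_f)
        return total

    sqrt_amyloid = (
        1.6 + 0.02 * age_c + 0.30 * apoe + planted("amyloid")
        + rng.normal(0.0, config.pathology_noise_sd, n)
    )
    sqrt_tau = (
        1.4 + 0.02 * age_c + 0.25 * apoe + config.female_tau_shift * is_f
        + planted("tau")
        + rng.normal(0.0, config.pathology_noise_sd, n)
    )
    pathology = pd.DataFrame(
        {"amyloid": sqrt_amyloid, "tau": sqrt_tau}, index=cohort.index
    )
    if config.pathology_raw_scale:
        pathology = pathology.clip(lower=0.0) ** 2

    u = rng.normal(0.0, config.rand_intercept_sd, n)
    v = rng.normal(0.0, config.rand_slope_sd, n)
    slope = config.mean_slope + v + planted("cognition")
    level = u - 0.03 * age_c + 0.02 * (
        cohort["education"].to_numpy() - cohort["education"].mean()
    )

    n_visits = np.maximum(1, rng.poisson(config.visits_mean, n))
    rows = []
    for i, d in enumerate(dec):
        k = n_visits[i]
        times = -np.arange(k - 1, -1, -1.0)  # annual, final visit at 0
        eps = rng.normal(0.0, config.cognition_noise_sd, k)
        cog = level[i] + slope[i] * times + eps
        for j in range(k):
            rows.append((d, j, times[j], cog[j]))
    visits = pd.DataFrame(rows, columns=["decedent_id", "visit", "time", "cognition"])
    rand = pd.DataFrame({"intercept": u, "slope": v}, index=cohort.index)
    return OutcomeTables(pathology=pathology, visits=visits, random_effects=rand)


def compose_global_cognition(test_scores: np.ndarray | Sequence[float]) -> float | np.ndarray:
    """Global cognition composite: mean of the available test z-scores.

    Accepts a vector of (up to 17) per-test z-scores for one visit, or a 2-D
    array (visits x tests); missing entries (NaN) are ignored, and a visit
    with no available score composes to NaN.
    """
    arr = np.asarray(test_scores, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        out = np.nanmean(arr, axis=-1)
    return out


def generate_gene_sets(
    annotation: pd.DataFrame,
    n_sets: int = 25,
    size_range: tuple[int, int] = (15, 60),
    seed: int = 0,
) -> dict[str, set[str]]:
    """Random autosomal gene sets (GMT-shaped) for exercising enrichment."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_GENESETS]))
    auto = annotation.index[annotation["chromosome_class"] == "autosomal"].to_numpy()
    lo, hi = size_range
    hi = min(hi, len(auto))
    sets = {}
    for i in range(n_sets):
        k = int(rng.integers(lo, hi + 1))
        sets[f"SET_{i:03d}"] = set(rng.choice(auto, size=k, replace=False))
    return sets
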