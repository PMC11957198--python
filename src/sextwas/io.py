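"""File formats, run configuration, and the end-to-end pipeline driver.

Counts round-trip as TSV or MatrixMarket (MTX plus row/col index files);
cohort, pathology, cognition-visit and ground-truth tables as CSV; results
as tidy TSV with a deterministic column order. A YAML run configuration
holds every threshold of the analysis under a named key. ``run_pipeline``
executes simulate -> preprocess -> match -> associate -> discover ->
sensitivity -> enrich -> report, writing a manifest with input hashes so a
rerun with the same config and seed reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp
import yaml

from sextwas import discovery, enrichment, matching, models, preprocess, simulate

log = logging.getLogger("sextwas")

RESULT_COLUMNS = [
    "gene", "region", "outcome", "stratum", "term", "chromosome_class",
    "beta", "se", "statistic", "p", "p_fdr", "n", "df", "model", "estimable",
]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_counts_mtx(counts: pd.DataFrame, prefix) -> None:
    """MTX plus <prefix>.rows / <prefix>.cols index files."""
    prefix = Path(prefix)
    sio.mmwrite(str(prefix.with_suffix(".mtx")), sp.csr_matrix(counts.to_numpy()))
    prefix.with_suffix(".rows").write_text("\n".join(map(str, counts.index)) + "\n")
    prefix.with_suffix(".cols").write_text("\n".join(map(str, counts.columns)) + "\n")


def read_counts_mtx(prefix) -> pd.DataFrame:
    prefix = Path(prefix)
    m = sio.mmread(str(prefix.with_suffix(".mtx")))
    rows = prefix.with_suffix(".rows").read_text().splitlines()
    cols = prefix.with_suffix(".cols").read_text().splitlines()
    dense = np.asarray(m.todense()) if sp.issparse(m) else np.asarray(m)
    return pd.DataFrame(dense, index=pd.Index(rows, name="gene_id"),
                        columns=pd.Index(cols, name="sample_id"))


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, index_col=index_col)


def write_results(results: pd.DataFrame, path) -> None:
    """Tidy results TSV with the canonical deterministic column order."""
    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    cols += [c for c in results.columns if c not in cols]
    results[cols].to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gmt(sets: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            desc = (descriptions or {}).get(name, "na")
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Every analysis threshold and path, as named keys with the printed defaults."""

    out_dir: str = "run"
    seed: int = 0
    simulate: bool = True
    counts_path: str | None = None
    annotation_path: str | None = None
    cohort_path: str | None = None
    pathology_path: str | None = None
    visits_path: str | None = None
    gene_sets_path: str | None = None

    # QC / preprocessing thresholds
    rin_min: float = 4.0
    pmi_max: float = 24.0
    cpm_min: float = 1.0
    cpm_fraction: float = 0.5
    sd_winsor: float = 5.0

    # discovery thresholds
    alpha_strat: float = 0.05
    alpha_inter: float = 0.05
    alpha_inter_fdr: float = 0.10

    # enrichment
    gsea_min_size: int = 15
    gsea_max_size: int = 500
    gsea_n_perm: int = 500

    # outcome scale: pathology tables are analysis-scale (sqrt) by default;
    # set True if they hold raw values that still need the sqrt transform
    pathology_is_raw: bool = False

    # stage toggles
    run_matching: bool = True
    run_sensitivity: bool = True
    run_enrichment: bool = True

    # simulation scale (used when simulate=True)
    sim: dict = field(default_factory=lambda: {
        "n_male": 100, "n_female": 200, "n_genes_autosomal": 420,
        "n_genes_x": 60, "n_genes_y": 20, "n_regions": 3,
    })

    def __post_init__(self) -> None:
        for a in ("alpha_strat", "alpha_inter", "alpha_inter_fdr"):
            if not (0 < getattr(self, a) < 1):
                raise ValueError(f"{a} must lie in (0, 1)")
        for a in ("rin_min", "pmi_max", "cpm_min", "sd_winsor"):
            if getattr(self, a) <= 0:
                raise ValueError(f"{a} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline halted at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline into ``config.out_dir``; returns the run dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs_hashed: dict[str, str] = {}

    stage = "simulate"
    try:
        if config.simulate:
            sim_cfg = simulate.SimulationConfig(seed=config.seed, **config.sim)
            cohort = simulate.generate_cohort(sim_cfg)
            counts, samples, ann, truth = simulate.generate_counts(sim_cfg, cohort)
            outcomes = simulate.generate_outcomes(sim_cfg, cohort, truth.latent)
            pathology, visits = outcomes.pathology, outcomes.visits
            gene_sets = simulate.generate_gene_sets(ann, seed=config.seed)
            sim_dir = out / "simulate"
            sim_dir.mkdir(exist_ok=True)
            write_counts_tsv(counts, sim_dir / "counts.tsv")
            write_counts_mtx(counts, sim_dir / "counts")
            write_table(cohort, sim_dir / "cohort.csv")
            write_table(samples, sim_dir / "samples.csv")
            write_table(ann, sim_dir / "annotation.csv")
            write_table(pathology, sim_dir / "pathology.csv")
            write_table(visits, sim_dir / "visits.csv", index=False)
            write_table(truth.effects, sim_dir / "ground_truth.csv", index=False)
            write_gmt(gene_sets, sim_dir / "gene_sets.gmt")
            log.info("simulate: %d genes x %d samples, %d decedents",
                     *counts.shape, len(cohort))
        else:
            if not config.counts_path or not Path(config.counts_path).exists():
                raise FileNotFoundError(
                    "counts file missing and simulation disabled "
                    f"(counts_path={config.counts_path!r})"
                )
            stage = "preprocess"
            counts = read_counts_tsv(config.counts_path)
            ann = read_table(config.annotation_path)
            cohort = read_table(config.cohort_path)
            pathology = read_table(config.pathology_path)
            visits = read_table(config.visits_path, index_col=None)
            samples = pd.DataFrame(
                {"decedent_id": counts.columns.str.rsplit("_", n=1).str[0],
                 "region": counts.columns.str.rsplit("_", n=1).str[1]},
                index=counts.columns,
            )
            gene_sets = enrichment.read_gmt(config.gene_sets_path).sets \
                if config.gene_sets_path else {}
            for p in (config.counts_path, config.annotation_path,
                      config.cohort_path, config.pathology_path,
                      config.visits_path):
                if p:
                    inputs_hashed[str(p)] = _sha256(Path(p))
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - report stage and cause
        raise StageError(stage, exc) from exc

    regions = sorted(samples["region"].unique())
    per_sample = samples.join(cohort, on="decedent_id")

    # preprocess + match + associate per region
    all_results = []
    try:
        stage = "preprocess"
        expr_by_region: dict[str, dict[str, pd.DataFrame]] = {}
        for region in regions:
            region_samples = samples.index[samples["region"] == region]
            rc = counts.loc[:, region_samples]
            expr_by_region[region] = {}
            pp_dir = out / "preprocess"
            pp_dir.mkdir(exist_ok=True)
            for chrom in ("autosomal", "X", "Y"):
                expr, rep = preprocess.preprocess_chromosome_class(
                    rc, ann, cohort, samples.loc[region_samples], chrom,
                    rin_min=config.rin_min, pmi_max_hours=config.pmi_max,
                    cpm_min=config.cpm_min, cpm_fraction=config.cpm_fraction,
                    sd_winsor=config.sd_winsor,
                )
                expr_by_region[region][chrom] = expr
                write_table(expr, pp_dir / f"expr_{region}_{chrom}.tsv")
                write_table(rep.to_frame(), pp_dir / f"qc_{region}_{chrom}.tsv",
                            index=False)
                log.info("preprocess %s/%s: %d genes x %d samples",
                         region, chrom, *expr.shape)

        stage = "match"
        matched_by_region: dict[str, list] = {}
        match_dir = out / "match"
        match_dir.mkdir(exist_ok=True)
        for region in regions:
            ids = per_sample.loc[samples["region"] == region, "decedent_id"]
            sub = cohort.loc[sorted(set(ids))]
            if config.run_matching:
                m = matching.PropensityMatcher().fit(sub)
                matched_by_region[region] = m.matched_ids_
                pd.DataFrame(m.pairs_, columns=["male_id", "female_id"]).to_csv(
                    match_dir / f"pairs_{region}.csv", index=False)
                if m.balance_ is not None:
                    write_table(m.balance_, match_dir / f"balance_{region}.tsv",
                                index=False)
            else:
                matched_by_region[region] = list(sub.index)

        stage = "associate"
        cs_covars = ["age_death", "pmi"]
        lg_covars = ["age_death", "pmi", "latency", "education"]
        for region in regions:
            matched = matched_by_region[region]
            sub_cohort = cohort.loc[matched]
            sex = sub_cohort["sex"]
            for chrom in ("autosomal", "X", "Y"):
                expr_s = expr_by_region[region][chrom]
                if expr_s.empty:
                    continue
                # sample-level -> decedent-level expression for this region
                cols = [c for c in expr_s.columns]
                dec = samples.loc[cols, "decedent_id"]
                expr_d = expr_s.T.groupby(dec.to_numpy()).mean().T
                keep = expr_d.columns.intersection(matched)
                expr_d = expr_d.loc[:, keep]
                strata = [("female", sex == "female"), ("male", sex == "male"),
                          ("pooled", sex.notna())]
                if chrom == "Y":
                    strata = [("male", sex == "male")]
                for outc in ("amyloid", "tau"):
                    if config.pathology_is_raw:
                        y = preprocess.transform_outcomes(pathology.loc[keep, outc])
                    else:
                        raw = pathology.loc[keep, outc]
                        y = raw - raw.mean()
                    for name, mask in strata:
                        ids = [i for i in keep if mask.get(i, False)]
                        cov = sub_cohort.loc[ids, cs_covars + (
                            ["sex"] if name == "pooled" else [])]
                        res = models.cross_sectional_screen(
                            expr_d.loc[:, ids], y.loc[ids], cov,
                            stratum=name, outcome_name=outc, region=region)
                        res["term"] = "gene"
                        res["chromosome_class"] = chrom
                        all_results.append(res)
                    if chrom != "Y":
                        cov = sub_cohort.loc[keep, cs_covars]
                        res = models.interaction_screen(
                            expr_d.loc[:, keep], y.loc[keep], sex.loc[keep],
                            cov, outcome_name=outc, region=region)
                        res["chromosome_class"] = chrom
                        all_results.append(res)
                # longitudinal cognition
                vis = visits[visits["decedent_id"].isin(keep)]
                for name, mask in strata:
                    ids = [i for i in keep if mask.get(i, False)]
                    cov = sub_cohort.loc[ids, lg_covars].apply(
                        lambda c: c - c.mean())
                    res = models.longitudinal_screen(
                        expr_d.loc[:, ids],
                        vis[vis["decedent_id"].isin(ids)], cov,
                        stratum=name, region=region)
                    res["chromosome_class"] = chrom
                    all_results.append(res)
                if chrom != "Y":
                    cov = sub_cohort.loc[keep, lg_covars].apply(
                        lambda c: c - c.mean())
                    res = models.longitudinal_screen(
                        expr_d.loc[:, keep], vis, cov, region=region,
                        sex=sex.loc[keep], interaction=True)
                    res["chromosome_class"] = chrom
                    all_results.append(res)
        results = pd.concat(all_results, ignore_index=True)
        assoc_dir = out / "associate"
        assoc_dir.mkdir(exist_ok=True)

        stage = "discover"
        results = discovery.adjust_by_family(results)
        write_results(results, assoc_dir / "associations.tsv")
        disc_dir = out / "discover"
        disc_dir.mkdir(exist_ok=True)
        calls_all = []
        for (region, outc), _ in results.groupby(["region", "outcome"]):
            sub = results[(results["region"] == region)
                          & (results["outcome"] == outc)]
            fem = sub[sub["stratum"] == "female"]
            mal = sub[sub["stratum"] == "male"]
            inter = sub[sub["stratum"] == "interaction"]
            if fem.empty or mal.empty or inter.empty:
                continue
            calls = discovery.classify_table(
                fem, mal, inter, alpha_strat=config.alpha_strat,
                alpha_inter=config.alpha_inter,
                alpha_inter_fdr=config.alpha_inter_fdr)
            calls_all.append(calls)
        calls = pd.concat(calls_all, ignore_index=True)
        calls = discovery.cross_region_consistency(calls)
        write_table(calls, disc_dir / "calls.tsv", index=False)
        tally = discovery.tally_summary(calls)
        (disc_dir / "tally.json").write_text(json.dumps(tally, indent=2,
                                                        default=str))
        write_table(discovery.chord_edges(calls), disc_dir / "chord_edges.tsv",
                    index=False)

        stage = "sensitivity"
        if config.run_sensitivity:
            sens = _sensitivity_stage(config, results, calls, expr_by_region,
                                      samples, cohort, pathology, visits,
                                      matched_by_region)
            write_results(sens, disc_dir / "sensitivity.tsv")

        stage = "enrich"
        if config.run_enrichment and gene_sets:
            enr_dir = out / "enrich"
            enr_dir.mkdir(exist_ok=True)
            enr_all = []
            for (region, outc, strat), sub in results.groupby(
                    ["region", "outcome", "stratum"]):
                if strat not in ("female", "male"):
                    continue
                auto = sub[(sub["chromosome_class"] == "autosomal")
                           & sub["beta"].notna()]
                if len(auto) < config.gsea_min_size:
                    continue
                ranked = enrichment.rank_genes(auto)
                r = enrichment.gsea_preranked(
                    ranked, gene_sets, n_perm=config.gsea_n_perm,
                    seed=config.seed, min_size=config.gsea_min_size,
                    max_size=config.gsea_max_size,
                    list_id=f"{strat}_{region}_{outc}")
                enr_all.append(r)
            if enr_all:
                enr = pd.concat(enr_all, ignore_index=True)
                write_table(enr, enr_dir / "enrichment.tsv", index=False)

        stage = "report"
        report(out)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "version": _version(),
        "input_hashes": inputs_hashed or {
            "simulated": hashlib.sha256(
                json.dumps(asdict(config), sort_keys=True, default=str).encode()
            ).hexdigest()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return out


def _version() -> str:
    from sextwas import __version__
    return __version__


def _sensitivity_stage(config, results, calls, expr_by_region, samples,
                       cohort, pathology, visits, matched_by_region
                       ) -> pd.DataFrame:
    """Refit sex-specific hits with APOE-e4 (and pathology, for cognition)."""
    hits = calls[calls["category"].isin(["female_specific", "male_specific"])]
    rows = []
    for _, h in hits.head(50).iterrows():  # cap refits at 50 hits per run
        region, outc, gene = h["region"], h["outcome"], h["gene"]
        stratum = "female" if h["category"] == "female_specific" else "male"
        chrom = h.get("chromosome_class", "autosomal")
        expr_s = expr_by_region[region].get(chrom)
        if expr_s is None or gene not in expr_s.index:
            continue
        dec = samples.loc[expr_s.columns, "decedent_id"]
        g = expr_s.loc[gene].groupby(dec.to_numpy()).mean()
        ids = [i for i in matched_by_region[region]
               if i in g.index and cohort.loc[i, "sex"] == stratum]
        extra = pd.DataFrame({"apoe4_pos": (cohort["apoe4"] > 0).astype(float)})
        if outc == "cognition":
            extra = extra.join(pathology[["amyloid", "tau"]])
            res = models.sensitivity_refit(
                "longitudinal", g.loc[ids],
                visits[visits["decedent_id"].isin(ids)],
                cohort.loc[ids, ["age_death", "pmi", "latency", "education"]],
                extra.loc[ids], stratum=stratum, gene=gene, region=region)
        else:
            if config.pathology_is_raw:
                y = preprocess.transform_outcomes(pathology.loc[ids, outc])
            else:
                raw = pathology.loc[ids, outc]
                y = raw - raw.mean()
            res = models.sensitivity_refit(
                "cross_sectional", g.loc[ids], y,
                cohort.loc[ids, ["age_death", "pmi"]], extra.loc[ids],
                stratum=stratum, gene=gene, outcome_name=outc, region=region)
        rows.append({
            "gene": gene, "region": region, "outcome": outc,
            "stratum": stratum, "beta": res.beta, "se": res.se,
            "statistic": res.statistic, "p": res.p, "n": res.n,
            "model": res.model + "+sensitivity", "estimable": res.estimable,
        })
    return pd.DataFrame(rows)


def report(run_dir) -> dict:
    """Summarize a completed run: tallies, highlighted and stringent genes."""
    run_dir = Path(run_dir)
    calls_path = run_dir / "discover" / "calls.tsv"
    if not calls_path.exists():
        raise FileNotFoundError("discover stage has not completed (no calls.tsv)")
    calls = pd.read_csv(calls_path, sep="\t")
    tally = discovery.tally_summary(calls)
    doc = {
        "tally": tally,
        "stringent_genes": calls.loc[calls.get("stringent", False) == True,  # noqa: E712
                                     ["gene", "region", "outcome", "category"]]
        .to_dict("records"),
        "highlighted_cross_region": calls.loc[
            calls.get("highlighted", False) == True,  # noqa: E712
            ["gene", "outcome", "category", "regions_support"]]
        .drop_duplicates().to_dict("records"),
    }
    enr_path = run_dir / "enrich" / "enrichment.tsv"
    if enr_path.exists():
        enr = pd.read_csv(enr_path, sep="\t")
        doc["n_enriched_sets"] = int((enr["p_fdr"] <= 0.05).sum())
    (run_dir / "report.json").write_text(json.dumps(doc, indent=2, default=str))
    lines = [
        "sextwas run summary",
        f"  significant associations: {tally.get('n_significant', 0)}",
        f"  sex-specific: {tally.get('n_sex_specific', 0)} "
        f"(female {tally.get('n_female_specific', 0)}, "
        f"male {tally.get('n_male_specific', 0)})",
        f"  stringent tier: {tally.get('n_stringent', 0)}",
        f"  cross-region highlighted: {len(doc['highlighted_cross_region'])}",
    ]
    (run_dir / "report.txt").write_text("\n".join(lines) + "\n")
    return doc
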