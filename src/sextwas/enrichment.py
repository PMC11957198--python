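"""Pre-ranked gene set enrichment from the weighted running-sum statistic.

Genes are ranked by their sex-stratified association coefficients (autosomal
genes only, one ranked list per sex, region and outcome). For each set, the
classic weighted Kolmogorov-Smirnov running sum is computed: hits increment
by |beta|^weight normalized over the set's hits, misses decrement by
1/(N - N_hits); the enrichment score (ES) is the running-sum value of
maximal absolute deviation. The null is gene-label permutation preserving
set size; p-values use the matching-sign null tail with a +1 pseudocount,
and NES divides ES by the mean |null ES| of matching sign. BH correction is
applied across sets within one ranked list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sextwas.discovery import bh_adjust


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional provenance tag."""

    sets: dict[str, set[str]]
    source: str = ""
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def size_filtered(self, universe, min_size: int = 15, max_size: int = 500
                      ) -> "GeneSetCollection":
        """Keep sets whose overlap with the ranked universe is within bounds."""
        uni = set(universe)
        kept = {}
        for name, members in self.sets.items():
            ov = members & uni
            if min_size <= len(ov) <= max_size:
                kept[name] = ov
        return GeneSetCollection(kept, source=self.source,
                                 descriptions=self.descriptions)


def read_gmt(path) -> GeneSetCollection:
    """Read a tab-separated GMT file (name, description, members...).

    Duplicate members within a set are counted once; sets that end up empty
    are dropped with a warning; a line with fewer than three fields is a
    format error reported with its line number.
    """
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line ({len(fields)} fields, need >= 3)"
                )
            name, description = fields[0], fields[1]
            members = {f for f in fields[2:] if f}
            if not members:
                warnings.warn(f"{path}:{lineno}: set {name!r} is empty, dropped")
                continue
            sets[name] = members
            desc[name] = description
    return GeneSetCollection(sets, source=str(path), descriptions=desc)


def rank_genes(association_results: pd.DataFrame) -> pd.Series:
    """Beta-descending ranked list for one (sex, region, outcome).

    Input is a tidy per-gene result table with ``gene`` and ``beta`` columns
    (already restricted to autosomal genes by the caller, if desired). Ties
    are broken by gene id for determinism. Duplicated gene ids are rejected.
    """
    df = association_results
    if df["gene"].duplicated().any():
        dups = df.loc[df["gene"].duplicated(), "gene"].unique()[:5]
        raise ValueError(f"duplicate gene ids in ranking input: {list(dups)}")
    df = df.sort_values(["beta", "gene"], ascending=[False, True], kind="mergesort")
    return pd.Series(df["beta"].to_numpy(dtype=float), index=df["gene"].to_numpy(),
                     name="beta")


def enrichment_score(
    ranked_betas: np.ndarray,
    member_flags: np.ndarray,
    weight: float = 1.0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Weighted KS running sum for one set against one ranked list.

    Returns ``(es, running_sum, leading_edge_positions)``. Leading edge:
    member positions at or before the extremum for positive ES, at or after
    it for negative ES.
    """
    beta = np.asarray(ranked_betas, dtype=float)
    hits = np.asarray(member_flags, dtype=bool)
    n = beta.size
    n_hit = int(hits.sum())
    if n_hit == 0:
        raise ValueError("set has no members in the ranked universe")
    w = np.abs(beta) ** weight
    w_hit = np.where(hits, w, 0.0)
    tot = w_hit.sum()
    if tot <= 0:
        w_hit = hits.astype(float)   # all-zero betas: unweighted hits
        tot = float(n_hit)
    inc = w_hit / tot
    if n_hit < n:
        dec = (~hits) / float(n - n_hit)
    else:
        dec = np.zeros(n)
    running = np.clip(np.cumsum(inc - dec), -1.0, 1.0)  # guard fp overshoot
    hi, lo = float(running.max()), float(running.min())
    # maximal absolute deviation; an exact positive/negative tie (possible
    # with rational increments) resolves to the positive extremum
    if hi >= -lo - 1e-12:
        es = hi
        pos = int(np.argmax(running))
    else:
        es = lo
        pos = int(np.argmin(running))
    hit_pos = np.flatnonzero(hits)
    if es >= 0:
        leading = hit_pos[hit_pos <= pos]
    else:
        leading = hit_pos[hit_pos >= pos]
    return es, running, leading


def _null_es(
    abs_w: np.ndarray, size: int, n_perm: int, rng: np.random.Generator,
    chunk: int = 250,
) -> np.ndarray:
    """Permutation null: ES for random same-size member sets, vectorized."""
    n = abs_w.size
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        # b random size-`size` subsets via partial argsort of random keys
        keys = rng.random((b, n))
        idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
        H = np.zeros((b, n), dtype=bool)
        np.put_along_axis(H, idx, True, axis=1)
        W = np.where(H, abs_w[None, :], 0.0)
        tot = W.sum(axis=1, keepdims=True)
        zero = tot[:, 0] <= 0
        if zero.any():
            W[zero] = H[zero].astype(float)
            tot = W.sum(axis=1, keepdims=True)
        inc = W / tot
        dec = (~H) / float(n - size) if size < n else np.zeros((b, n))
        run = np.cumsum(inc - dec, axis=1)
        hi = run.max(axis=1)
        lo = run.min(axis=1)
        out[done:done + b] = np.where(hi >= -lo - 1e-12, hi, lo)
        done += b
    return out


def gsea_preranked(
    ranked: pd.Series,
    sets: GeneSetCollection | dict,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 15,
    max_size: int = 500,
    list_id: str = "",
) -> pd.DataFrame:
    """Permutation GSEA over a collection of sets for one ranked list.

    ``ranked`` is a beta-descending Series indexed by gene id. Sets are
    size-filtered against the universe; zero-overlap sets are skipped with a
    warning. Deterministic for a fixed seed. Returns one row per set with
    ES, NES, p, p_fdr, leading edge and direction.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives very coarse p-values")
    if isinstance(sets, dict):
        sets = GeneSetCollection(sets)
    universe = ranked.index.to_numpy()
    beta = ranked.to_numpy(dtype=float)
    abs_w = np.abs(beta) ** weight
    rng = np.random.default_rng(seed)
    filtered = sets.size_filtered(universe, min_size, max_size)
    for name in sets.sets:
        if name not in filtered.sets and not (set(sets.sets[name]) & set(universe)):
            warnings.warn(f"set {name!r} has no overlap with the ranked universe")
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    pos_index = {g: i for i, g in enumerate(universe)}
    for name in sorted(filtered.sets):
        members = filtered.sets[name]
        flags = np.zeros(len(universe), dtype=bool)
        flags[[pos_index[g] for g in members]] = True
        es, _, leading = enrichment_score(beta, flags, weight)
        size = int(flags.sum())
        if size not in null_cache:
            null_cache[size] = _null_es(abs_w, size, n_perm, rng)
        null = null_cache[size]
        same = null[null >= 0] if es >= 0 else null[null < 0]
        p = (1.0 + np.sum(np.abs(same) >= abs(es))) / (1.0 + len(same))
        denom = np.mean(np.abs(same)) if len(same) else np.mean(np.abs(null))
        nes = es / denom if denom > 0 else 0.0
        rows.append(
            {
                "list_id": list_id,
                "set": name,
                "size": size,
                "ES": es,
                "NES": nes,
                "p": min(p, 1.0),
                "leading_edge": ";".join(universe[leading]),
                "direction": "up" if es >= 0 else "down",
            }
        )
    res = pd.DataFrame(rows)
    if not res.empty:
        res["p_fdr"] = bh_adjust(res["p"].to_numpy())
    return res


class PrerankedGSEA:
    """Estimator-style wrapper: configure once, fit per ranked list.

    Parameters mirror :func:`gsea_preranked`; after :meth:`fit` the results
    table is available as ``results_``.
    """

    def __init__(self, n_perm: int = 1000, seed: int = 0, weight: float = 1.0,
                 min_size: int = 15, max_size: int = 500):
        self.n_perm = n_perm
        self.seed = seed
        self.weight = weight
        self.min_size = min_size
        self.max_size = max_size

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("n_perm", "seed", "weight", "min_size", "max_size")}

    def set_params(self, **params) -> "PrerankedGSEA":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, ranked: pd.Series, sets, list_id: str = "") -> "PrerankedGSEA":
        self.results_ = gsea_preranked(
            ranked, sets, n_perm=self.n_perm, seed=self.seed,
            weight=self.weight, min_size=self.min_size,
            max_size=self.max_size, list_id=list_id,
        )
        return self
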