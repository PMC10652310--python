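"""Preranked gene-set enrichment (GSEA) with a permutation null.

Genes are ranked by a differential-expression score; for each gene set
the enrichment score (ES) is the signed extremum of the weighted
Kolmogorov-Smirnov running sum (hits advance by |score|^w normalized to
the in-set total, misses retreat by 1/(N - set size)).  The null is a
gene-label permutation: random same-size sets drawn from the ranked
universe.  NES normalizes ES by the mean |null ES| of matching sign
(Subramanian convention); p-values are sign-stratified permutation tails
with a +1 pseudocount (so p >= 1/(nPerm+1)) and are BH-adjusted across
sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .de import DEResult

__all__ = [
    "EnrichmentResult",
    "rank_genes",
    "enrichment_score",
    "gsea",
    "set_overlap_table",
]


@dataclass
class EnrichmentResult:
    """Per-set GSEA output table plus run parameters."""

    table: pd.DataFrame  # set, size, es, nes, p, q, direction, leading_edge
    excluded: pd.DataFrame  # set, reason
    n_perm: int
    min_size: int
    max_size: int
    weight: float
    seed: int | None = None
    ranking: pd.Series | None = field(default=None, repr=False)

    def significant(self, q_threshold: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < q_threshold]


def rank_genes(de: DEResult | pd.DataFrame, metric: str = "stat") -> pd.Series:
    """Descending ranking of tested genes by a DE score.

    ``metric`` is a column of the DE table (default the Wald statistic;
    ``log2FC`` also supported).  Ties break deterministically by gene id
    (lexicographic ascending).
    """
    table = de.table if isinstance(de, DEResult) else de
    if table.empty:
        raise ValueError("no finite scores to rank")
    if "tested" in table.columns:
        table = table[table["tested"]]
    scores = table[metric].astype(float)
    scores = scores[np.isfinite(scores)]
    if scores.empty:
        raise ValueError("no finite scores to rank")
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    return scores.loc[order]


def _walk_extrema(positions: np.ndarray, w_hit: np.ndarray, n_universe: int):
    """Vectorised ES of the weighted KS walk for rows of sorted hit positions.

    ``positions``: (m, k) sorted 0-based ranks of hits; ``w_hit``: matching
    |score|^w values.  Returns (es, arg) where ``arg`` is the hit index
    attaining the extremum (for the leading edge).
    """
    m, k = positions.shape
    totals = w_hit.sum(axis=1, keepdims=True)
    flat = totals[:, 0] <= 0
    if flat.any():  # all-zero scores in the set: fall back to equal weights
        w_hit = w_hit.copy()
        w_hit[flat] = 1.0
        totals = w_hit.sum(axis=1, keepdims=True)
    cumw = np.cumsum(w_hit, axis=1) / totals
    idx = np.arange(k)
    misses = (positions - idx) / (n_universe - k)
    up = cumw - misses                      # walk value just after each hit
    down = np.concatenate([np.zeros((m, 1)), cumw[:, :-1]], axis=1) - misses  # just before
    up_max = up.max(axis=1)
    down_min = np.minimum(down.min(axis=1), 0.0)
    es = np.where(up_max >= -down_min, up_max, down_min)
    arg = np.where(up_max >= -down_min, up.argmax(axis=1), down.argmin(axis=1))
    return es, arg


def enrichment_score(
    ranked: pd.Series, gene_set, weight: float = 1.0
) -> tuple[float, int, list[str]]:
    """ES of one gene set against a ranked scores series.

    Returns ``(es, extremum_rank, leading_edge)`` where ``extremum_rank``
    is the 0-based rank position where the running sum attains the ES and
    the leading edge lists the set members driving it.
    """
    genes = ranked.index.to_numpy()
    hit_pos = np.flatnonzero(pd.Index(genes).isin(set(gene_set)))
    if hit_pos.size == 0:
        raise ValueError("gene set has empty intersection with the ranked universe")
    if hit_pos.size >= len(genes):
        raise ValueError("gene set covers the whole universe; ES is degenerate")
    w_hit = np.abs(ranked.to_numpy()[hit_pos]) ** weight
    es, arg = _walk_extrema(hit_pos[None, :], w_hit[None, :], len(genes))
    es, arg = float(es[0]), int(arg[0])
    if es >= 0:
        leading = genes[hit_pos[: arg + 1]].tolist()
    else:
        leading = genes[hit_pos[arg:]].tolist()
    return es, int(hit_pos[arg]), leading


def _sample_positions(rng: np.random.Generator, n_perm: int, k: int, n: int) -> np.ndarray:
    """Draw ``n_perm`` sorted k-subsets of range(n) without replacement."""
    if k * (k - 1) < 0.1 * n:  # rejection sampling is cheap for small sets
        pos = rng.integers(0, n, size=(n_perm, k))
        for _ in range(64):
            pos.sort(axis=1)
            bad = (np.diff(pos, axis=1) == 0).any(axis=1)
            if not bad.any():
                break
            pos[bad] = rng.integers(0, n, size=(int(bad.sum()), k))
        return pos
    chunks = []
    chunk_rows = max(1, int(2e7 // n))
    done = 0
    while done < n_perm:
        rows = min(chunk_rows, n_perm - done)
        keys = rng.random((rows, n))
        part = np.argpartition(keys, k, axis=1)[:, :k]
        part.sort(axis=1)
        chunks.append(part)
        done += rows
    return np.vstack(chunks)


def gsea(
    de: DEResult | pd.Series,
    gene_sets: dict[str, list[str]],
    n_perm: int = 15000,
    min_size: int = 10,
    max_size: int = 600,
    weight: float = 1.0,
    metric: str = "stat",
    seed: int = 0,
) -> EnrichmentResult:
    """Preranked GSEA over a GMT-style dict of gene sets.

    The universe is the tested, ranked genes.  Sets whose intersection
    with the universe falls outside [min_size, max_size] are excluded and
    reported with a reason.  Same-size sets share one permutation null,
    which keeps the run reproducible under ``seed`` and independent of set
    iteration order.
    """
    ranked = de if isinstance(de, pd.Series) else rank_genes(de, metric=metric)
    genes = ranked.index.to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    abs_scores = np.abs(ranked.to_numpy()) ** weight

    eligible: dict[str, np.ndarray] = {}
    excluded_rows = []
    for name in sorted(gene_sets):
        pos = np.array(sorted(gene_pos[g] for g in set(gene_sets[name]) if g in gene_pos), dtype=int)
        if pos.size == 0:
            excluded_rows.append({"set": name, "reason": "empty intersection with universe"})
        elif pos.size < min_size:
            excluded_rows.append({"set": name, "reason": f"size {pos.size} < min_size {min_size}"})
        elif pos.size > max_size or pos.size >= n:
            excluded_rows.append({"set": name, "reason": f"size {pos.size} > max_size {max_size}"})
        else:
            eligible[name] = pos
    excluded = pd.DataFrame(excluded_rows, columns=["set", "reason"])
    if not eligible:
        warnings.warn("no eligible gene sets after size filtering", stacklevel=2)
        empty = pd.DataFrame(
            columns=["set", "size", "es", "nes", "p", "q", "direction", "leading_edge"]
        )
        return EnrichmentResult(empty, excluded, n_perm, min_size, max_size, weight, seed, ranked)

    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}
    for k in sorted({pos.size for pos in eligible.values()}):
        perm_pos = _sample_positions(rng, n_perm, k, n)
        null_es, _ = _walk_extrema(perm_pos, abs_scores[perm_pos], n)
        null_cache[k] = null_es

    rows = []
    for name, pos in eligible.items():
        es, arg = _walk_extrema(pos[None, :], abs_scores[pos][None, :], n)
        es, arg = float(es[0]), int(arg[0])
        null = null_cache[pos.size]
        if es >= 0:
            same = null[null >= 0]
            count = int((same >= es).sum())
            leading = genes[pos[: arg + 1]]
        else:
            same = null[null < 0]
            count = int((same <= es).sum())
            leading = genes[pos[arg:]]
        p = (1.0 + count) / (1.0 + same.size)
        denom = np.abs(same).mean() if same.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        rows.append(
            {
                "set": name,
                "size": int(pos.size),
                "es": es,
                "nes": nes,
                "p": p,
                "direction": "up" if es >= 0 else "down",
                "leading_edge": ",".join(leading),
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    table = table[["set", "size", "es", "nes", "p", "q", "direction", "leading_edge"]]
    table = table.sort_values("p", kind="mergesort").reset_index(drop=True)
    return EnrichmentResult(table, excluded, n_perm, min_size, max_size, weight, seed, ranked)


def set_overlap_table(gene_sets: dict[str, list[str]], names=None) -> pd.DataFrame:
    """Pairwise Jaccard overlap between gene sets (symmetric, diagonal 1)."""
    if names is None:
        names = sorted(gene_sets)
    names = list(names)
    members = {n: set(gene_sets[n]) for n in names}
    mat = np.zeros((len(names), len(names)))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j < i:
                mat[i, j] = mat[j, i]
                continue
            union = members[a] | members[b]
            mat[i, j] = len(members[a] & members[b]) / len(union) if union else 0.0
    return pd.DataFrame(mat, index=names, columns=names)
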