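"""Preranked gene-set enrichment and 2x2 over-representation tests.

The enrichment score (ES) is the signed maximum deviation of the weighted
Kolmogorov–Smirnov running sum over a ranking: walking the ranked list,
the sum rises by ``|score|^weight`` (normalized over the set) at set genes
and falls by ``1/(N - |S|)`` elsewhere.  Significance comes from a null of
random same-size gene sets; the normalized ES (NES) divides the observed
ES by the mean magnitude of the same-sign null ES values, and p-values use
add-one smoothing so a finite number of permutations never yields p = 0.

miRNA-target over-representation among down-regulated genes uses the
one-sided Fisher exact test, which is checked against the hypergeometric
survival function (the two are the same tail probability).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .core import GeneSetCollection, ValidationError
from .diffexpr import bh_adjust

logger = logging.getLogger("pdotme")

__all__ = ["preranked_gsea", "target_enrichment", "ContingencyResult", "running_sum"]


def running_sum(
    ranked_genes: list[str], scores: np.ndarray, gene_set: set[str], weight: float
) -> np.ndarray:
    """Explicit KS running sum over a ranking (used for plots and oracles)."""
    n = len(ranked_genes)
    hits = np.array([g in gene_set for g in ranked_genes])
    s = int(hits.sum())
    if s == 0 or s == n:
        raise ValidationError("gene set must hit a strict subset of the ranking")
    w = np.abs(scores) ** weight
    hit_inc = np.where(hits, w, 0.0)
    tot = hit_inc.sum()
    if tot == 0:
        hit_inc = hits.astype(float)
        tot = hit_inc.sum()
    steps = hit_inc / tot - (~hits) / (n - s)
    return np.cumsum(steps)


def _es_from_positions(
    positions: np.ndarray, absw: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ES for rows of hit positions (0-based, per permutation).

    Returns (es, peak_k) where peak_k is the 1-based hit index at the
    extreme (for leading-edge extraction).
    """
    pos = np.sort(positions, axis=1)
    s = pos.shape[1]
    w = absw[pos]
    tot = w.sum(axis=1, keepdims=True)
    flat = tot[:, 0] == 0
    if np.any(flat):  # all-zero scores in the set: fall back to unweighted
        w[flat] = 1.0
        tot[flat] = s
    cumw = np.cumsum(w, axis=1) / tot
    k = np.arange(1, s + 1)[None, :]
    miss = 1.0 / (n - s)
    top = cumw - (pos + 1 - k) * miss
    bot = np.concatenate([np.zeros((pos.shape[0], 1)), cumw[:, :-1]], axis=1) - (
        pos - (k - 1)
    ) * miss
    i_top = np.argmax(top, axis=1)
    i_bot = np.argmin(bot, axis=1)
    es_top = top[np.arange(len(pos)), i_top]
    es_bot = bot[np.arange(len(pos)), i_bot]
    use_top = np.abs(es_top) >= np.abs(es_bot)
    es = np.where(use_top, es_top, es_bot)
    peak = np.where(use_top, i_top + 1, i_bot + 1)
    return es, peak


def preranked_gsea(
    ranking: pd.Series | dict[str, float],
    sets: GeneSetCollection,
    nperm: int = 50_000,
    weight: float = 1.0,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Permutation GSEA on a preranked gene list.

    ``ranking`` maps gene symbol -> score; genes are ranked by decreasing
    score.  Returns a DataFrame (set, es, nes, p, p_adj, size,
    leading_edge) sorted by p.
    """
    if isinstance(ranking, dict):
        ranking = pd.Series(ranking)
    if ranking.index.duplicated().any():
        raise ValidationError("ranking contains duplicate genes")
    if not np.all(np.isfinite(ranking.to_numpy(dtype=float))):
        raise ValidationError("ranking scores must be finite")
    if nperm < 100:
        logger.warning("preranked_gsea: nperm < 100 gives unstable p-values")
    ranking = ranking.sort_values(ascending=False, kind="stable")
    genes = ranking.index.to_numpy()
    scores = ranking.to_numpy(dtype=float)
    n = genes.size
    pos_of = {g: i for i, g in enumerate(genes)}
    absw = np.abs(scores) ** weight
    rng = np.random.default_rng(seed)

    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for name, members in sets.items():
        pos = np.array(sorted(pos_of[g] for g in members if g in pos_of))
        size = pos.size
        if size == 0:
            logger.warning("preranked_gsea: set %r has no genes in the ranking", name)
            continue
        if not (min_size <= size <= max_size) or size == n:
            continue
        es_arr, peak = _es_from_positions(pos[None, :], absw, n)
        es, k_peak = float(es_arr[0]), int(peak[0])
        if es >= 0:
            leading = [genes[p] for p in pos[:k_peak]]
        else:
            leading = [genes[p] for p in pos[k_peak - 1 :]]

        if size not in null_cache:
            null_cache[size] = _null_es(rng, nperm, size, absw, n)
        null = null_cache[size]
        same = null[null > 0] if es >= 0 else null[null < 0]
        n_same = same.size
        n_extreme = int(np.sum(np.abs(same) >= abs(es)))
        p = (1 + n_extreme) / (1 + n_same) if n_same else 1.0
        nes = es / np.mean(np.abs(same)) if n_same else np.nan
        rows.append((name, es, nes, p, size, ",".join(map(str, leading))))

    out = pd.DataFrame(rows, columns=["set", "es", "nes", "p", "size", "leading_edge"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out.sort_values("p", kind="stable").reset_index(drop=True)[
        ["set", "es", "nes", "p", "p_adj", "size", "leading_edge"]
    ]


def _null_es(
    rng: np.random.Generator, nperm: int, size: int, absw: np.ndarray, n: int
) -> np.ndarray:
    """Null ES distribution from random same-size gene sets (chunked)."""
    out = np.empty(nperm)
    chunk = max(1, min(nperm, int(4e6 // max(n, 1))))
    done = 0
    while done < nperm:
        m = min(chunk, nperm - done)
        keys = rng.random((m, n))
        pos = np.argpartition(keys, size - 1, axis=1)[:, :size]
        es, _ = _es_from_positions(pos, absw, n)
        out[done : done + m] = es
        done += m
    return out


@dataclass
class ContingencyResult:
    table: np.ndarray  # 2x2 [[a, b], [c, d]]
    odds_ratio: float
    p_one_sided: float
    p_hypergeom: float
    continuity_corrected: bool = False


def target_enrichment(
    down_genes: set[str], target_genes: set[str], universe: set[str]
) -> ContingencyResult:
    """One-sided over-representation of miRNA targets among down genes.

    a = down & target, b = down only, c = target only, d = neither; the
    one-sided (greater) Fisher p and the hypergeometric survival p are
    computed independently and agree to numerical precision.  The sample
    (cross-product) odds ratio is reported, with a 0.5 continuity
    substitution (flagged) when a zero cell makes it undefined.
    """
    if not universe:
        raise ValidationError("universe must be non-empty")
    universe = set(universe)
    if not set(down_genes) <= universe:
        raise ValidationError("down_genes must be a subset of the universe")
    down = set(down_genes)
    target = set(target_genes) & universe
    a = len(down & target)
    b = len(down - target)
    c = len(target - down)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    _, p_fisher = scipy.stats.fisher_exact(table, alternative="greater")
    # hypergeometric: draws = |down|, successes in population = |target|
    p_hyper = float(scipy.stats.hypergeom.sf(a - 1, len(universe), a + c, a + b))
    if a == 0 and b == 0:  # empty down set: no evidence either way
        return ContingencyResult(table, float("nan"), 1.0, 1.0, True)
    corrected = b == 0 or c == 0  # zero denominator cell makes the OR undefined
    if corrected:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
        odds = (aa * dd) / (bb * cc)
    else:
        odds = (a * d) / (b * c)
    return ContingencyResult(table, float(odds), float(p_fisher), p_hyper, corrected)
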