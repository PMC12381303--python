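"""Per-cell signature scoring and group-level signature statistics.

Module scores follow the bin-matched control scheme common in single-cell
toolkits: genes are binned by average expression, each signature gene is
paired with randomly drawn control genes from its bin, and the score is
the mean expression of the signature genes minus the mean of the pooled
controls — cancelling cell-level technical effects such as library depth.

The composite exosome-response signature takes the top differentially
expressed genes up-regulated under T2D-exosome treatment (equivalently
down-regulated under ND-exosome treatment in the two-group contrast), for
projection onto external cohorts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats

from .core import ExpressionMatrix, ValidationError, normalize_log1p

logger = logging.getLogger("pdotme")

__all__ = [
    "module_score",
    "build_composite_signature",
    "score_group_test",
    "cross_signature_correlation",
]


def module_score(
    expr: ExpressionMatrix,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Bin-controlled per-cell score for one gene set.

    Genes are ranked by mean normalized expression across cells and split
    into ``n_bins`` equal-frequency bins; for each set gene, ``n_ctrl``
    control genes are sampled (seeded; with replacement when the bin is
    small) from its bin excluding set genes.  The score is the set mean
    minus the pooled control mean, per cell.
    """
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    if expr.normalized is None:
        normalize_log1p(expr)
    symbols = expr.gene_table["symbol"].to_numpy()
    sym_index = pd.Index(symbols)
    present = [g for g in gene_set if g in sym_index]
    if not present:
        raise ValidationError(f"no gene of the set is present; missing: {list(gene_set)[:10]}")
    missing = [g for g in gene_set if g not in sym_index]
    if missing:
        logger.warning("module_score: %d set genes absent from the matrix", len(missing))
    norm = np.asarray(expr.normalized.todense())
    avg = norm.mean(axis=1)

    # equal-frequency bins on the expression rank (ties broken by index)
    order = np.argsort(avg, kind="stable")
    bins = np.empty(len(avg), dtype=int)
    bins[order] = np.minimum((np.arange(len(avg)) * n_bins) // len(avg), n_bins - 1)

    set_idx = sym_index.get_indexer(present)
    in_set = np.zeros(len(avg), dtype=bool)
    in_set[set_idx] = True
    rng = np.random.default_rng(seed)
    ctrl_rows: list[np.ndarray] = []
    for gi in set_idx:
        pool = np.flatnonzero((bins == bins[gi]) & ~in_set)
        if pool.size == 0:
            continue  # fully self-controlled bin: set mean cancels anyway
        replace = pool.size < n_ctrl
        ctrl_rows.append(rng.choice(pool, size=n_ctrl, replace=replace))
    set_mean = norm[set_idx].mean(axis=0)
    if ctrl_rows:
        ctrl = np.concatenate(ctrl_rows)
        ctrl_mean = norm[ctrl].mean(axis=0)
    else:
        ctrl_mean = set_mean
    return set_mean - ctrl_mean


def build_composite_signature(
    de_result: pd.DataFrame, n_top: int = 100
) -> tuple[list[str], list[str]]:
    """Top up- and down-regulated gene lists from a two-group DE table.

    Returns ``(up_list, down_list)``: genes with positive log_fc (up in
    group2, i.e. the T2D-exosome arm when the contrast is ND vs T2D)
    ranked by p, and the complementary negative-log_fc list.  Fewer than
    ``n_top`` qualifying genes returns all of them with a warning.
    """
    de = de_result.sort_values("p", kind="stable")
    up = de.loc[de["log_fc"] > 0, "gene_id"].tolist()
    down = de.loc[de["log_fc"] < 0, "gene_id"].tolist()
    if len(up) < n_top:
        logger.warning("build_composite_signature: only %d up-regulated genes", len(up))
    if len(down) < n_top:
        logger.warning("build_composite_signature: only %d down-regulated genes", len(down))
    return up[:n_top], down[:n_top]


def score_group_test(
    scores: np.ndarray,
    group: np.ndarray,
    batch: np.ndarray | None = None,
) -> tuple[float, float]:
    """Group effect on per-cell scores with a batch random intercept.

    Fits score ~ group with batch as a random intercept (mixed model) when
    batch has >= 3 levels; otherwise — or when the mixed fit fails — falls
    back to an ordinary linear model with fixed-effect batch.  Returns the
    contrast estimate (second group level minus first) and its p-value.
    """
    scores = np.asarray(scores, dtype=float)
    group = np.asarray(group)
    levels = sorted(pd.unique(group).tolist())
    if len(levels) < 2:
        raise ValidationError("need >= 2 group levels")
    if np.std(scores) == 0:
        logger.warning("score_group_test: constant scores")
        return 0.0, 1.0
    g01 = (group == levels[1]).astype(float)
    df = pd.DataFrame({"score": scores, "g": g01})
    if batch is not None:
        df["batch"] = pd.factorize(np.asarray(batch))[0]
        n_levels = df["batch"].nunique()
    else:
        n_levels = 1

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if n_levels >= 3:
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = smf.mixedlm("score ~ g", df, groups=df["batch"]).fit(reml=True)
            return float(fit.params["g"]), float(fit.pvalues["g"])
        except Exception:
            logger.warning("score_group_test: mixed model failed; fixed-effect fallback")
    if n_levels >= 2:
        X = pd.get_dummies(df["batch"], prefix="b", drop_first=True).astype(float)
        X.insert(0, "g", df["g"])
        X = sm.add_constant(X)
    else:
        X = sm.add_constant(df[["g"]])
    fit = sm.OLS(df["score"], X).fit()
    return float(fit.params["g"]), float(fit.pvalues["g"])


def cross_signature_correlation(
    scores_a: np.ndarray, scores_b: np.ndarray
) -> tuple[float, float]:
    """Spearman co-enrichment of two per-cell signature scores."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size != b.size:
        raise ValidationError("score vectors must be aligned")
    if a.size < 10:
        raise ValidationError("need >= 10 cells")
    if np.std(a) == 0 or np.std(b) == 0:
        logger.warning("cross_signature_correlation: constant score vector")
        return float("nan"), 1.0
    rho, p = scipy.stats.spearmanr(a, b)
    return float(rho), float(p)
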