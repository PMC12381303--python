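"""Differential cell-type composition between conditions.

Each cluster's abundance is modelled as a binomial response — cells in the
cluster out of all cells of the analyzed compartment per (patient,
condition) sample — in a logit-link GLM with condition and patient-batch
fixed effects.  The condition contrast is reported as a log-odds ratio
from estimated marginal means (condition linear predictors averaged over
batch levels), with Wald CI and BH adjustment across clusters; the fold
change is the ratio of pooled proportions, the quantity headline
"x-fold expansion" statements refer to.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .core import ValidationError
from .diffexpr import bh_adjust

logger = logging.getLogger("pdotme")

__all__ = ["composition_test", "proportion_table"]


def proportion_table(
    cell_table: pd.DataFrame, cluster_col: str, condition_col: str
) -> pd.DataFrame:
    """Cluster x condition proportions; every column sums to 1."""
    if cell_table.empty:
        raise ValidationError("cell table is empty")
    counts = pd.crosstab(cell_table[cluster_col], cell_table[condition_col])
    return counts / counts.sum(axis=0)


def _marginal_log_odds(
    fit, cond_levels: list[str], batch_levels: list[str], contrast: tuple[str, str]
) -> tuple[float, float]:
    """Contrast of condition linear predictors averaged over batch levels."""
    names = list(fit.model.exog_names)

    def avg_row(cond: str) -> np.ndarray:
        rows = []
        for b in batch_levels:
            row = np.zeros(len(names))
            row[names.index("const")] = 1.0
            cname = f"cond[{cond}]"
            if cname in names:
                row[names.index(cname)] = 1.0
            bname = f"batch[{b}]"
            if bname in names:
                row[names.index(bname)] = 1.0
            rows.append(row)
        return np.mean(rows, axis=0)

    c = avg_row(contrast[1]) - avg_row(contrast[0])
    est = float(c @ fit.params.to_numpy())
    se = float(np.sqrt(c @ fit.cov_params().to_numpy() @ c))
    return est, se


def composition_test(
    cell_table: pd.DataFrame,
    cluster_col: str,
    condition_col: str,
    batch_col: str | None = None,
    contrast: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-cluster differential abundance between two condition levels.

    Returns a DataFrame per cluster: sample counts, pooled proportions in
    both contrast levels, marginal log-odds ratio with SE / 95% CI / Wald
    p, BH-adjusted p, and the pooled-proportion fold change
    ``prop(level2) / prop(level1)`` (0.5 added to both margins of a
    cluster's pooled 2x2 only when a zero count would otherwise make the
    fold change degenerate; flagged).
    """
    conditions = pd.unique(cell_table[condition_col])
    if contrast is None:
        if len(conditions) != 2:
            raise ValidationError("contrast must be given when >2 condition levels")
        contrast = (str(conditions[0]), str(conditions[1]))
    for level in contrast:
        if level not in set(map(str, conditions)):
            raise ValidationError(f"condition level {level!r} missing from the data")
    tbl = cell_table[cell_table[condition_col].astype(str).isin(contrast)].copy()
    tbl["cond"] = tbl[condition_col].astype(str)
    tbl["batch"] = tbl[batch_col].astype(str) if batch_col else "all"
    batch_levels = sorted(tbl["batch"].unique())

    # aggregated binomial rows: one per (batch, condition)
    totals = tbl.groupby(["batch", "cond"]).size().rename("total").reset_index()

    rows = []
    for cluster in sorted(tbl[cluster_col].astype(str).unique()):
        hit = (
            tbl.assign(hit=(tbl[cluster_col].astype(str) == cluster).astype(int))
            .groupby(["batch", "cond"])["hit"]
            .sum()
            .reset_index()
        )
        agg = totals.merge(hit, on=["batch", "cond"])
        n1 = int(agg.loc[agg["cond"] == contrast[0], "hit"].sum())
        n2 = int(agg.loc[agg["cond"] == contrast[1], "hit"].sum())
        t1 = int(agg.loc[agg["cond"] == contrast[0], "total"].sum())
        t2 = int(agg.loc[agg["cond"] == contrast[1], "total"].sum())
        if n1 + n2 == 0:
            logger.warning("composition_test: cluster %r absent in both levels", cluster)
            continue

        X = pd.DataFrame({"const": 1.0}, index=agg.index)
        for cond in sorted(set(agg["cond"]))[1:]:
            X[f"cond[{cond}]"] = (agg["cond"] == cond).astype(float)
        for b in batch_levels[1:]:
            X[f"batch[{b}]"] = (agg["batch"] == b).astype(float)
        endog = np.column_stack([agg["hit"], agg["total"] - agg["hit"]])
        import warnings

        with warnings.catch_warnings():
            # saturated aggregated fits (rows == params) are expected and fine
            warnings.simplefilter("ignore")
            fit = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        log_or, se = _marginal_log_odds(fit, sorted(set(agg["cond"])), batch_levels, contrast)
        z = log_or / se if se > 0 else 0.0
        p = 2 * float(scipy.stats.norm.sf(abs(z)))

        flagged = n1 == 0 or n2 == 0
        if flagged:
            fc = ((n2 + 0.5) / (t2 + 0.5)) / ((n1 + 0.5) / (t1 + 0.5))
        else:
            fc = (n2 / t2) / (n1 / t1)
        rows.append(
            dict(
                cluster=cluster,
                n_1=n1,
                n_2=n2,
                total_1=t1,
                total_2=t2,
                prop_1=n1 / t1,
                prop_2=n2 / t2,
                log_or=log_or,
                se=se,
                ci_low=log_or - 1.959963984540054 * se,
                ci_high=log_or + 1.959963984540054 * se,
                p=p,
                fold_change=fc,
                zero_corrected=flagged,
            )
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out.attrs["contrast"] = contrast
    return out
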