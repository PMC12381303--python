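"""Signature projection onto bulk cohorts and survival modelling.

A gene signature derived from the organoid experiment is projected onto a
bulk expression cohort as the per-sample mean of per-dataset z-scaled
signature-gene expression.  The score's association with overall survival
is estimated by a Cox proportional-hazards model adjusted for clinical
covariates (age, intrinsic subtype, proliferation and inflammation
scores, or any subset), and visualized by stratifying patients into score
tertiles with Kaplan–Meier curves and a log-rank test.

Partial-likelihood estimation (Efron ties), Kaplan–Meier and log-rank are
delegated to lifelines; the scoring and stratification logic is local.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .core import ValidationError

logger = logging.getLogger("pdotme")

__all__ = ["cohort_signature_score", "cox_signature", "tertile_stratify"]


def cohort_signature_score(
    bulk_expr: pd.DataFrame, signature: list[str]
) -> tuple[pd.Series, int]:
    """Per-sample signature score on a genes x samples expression table.

    Each gene is z-scaled across the samples of the dataset (zero-variance
    genes contribute 0, flagged), then the score is the per-sample mean
    over the signature genes present.  Returns (scores, n_missing_genes).
    """
    present = [g for g in signature if g in bulk_expr.index]
    n_missing = len(signature) - len(present)
    if not present:
        raise ValidationError("no signature gene present in the cohort expression")
    if n_missing:
        logger.warning("cohort_signature_score: %d signature genes missing", n_missing)
    sub = bulk_expr.loc[present].astype(float)
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.warning("cohort_signature_score: %d constant genes contribute 0", int(flat.sum()))
    z = sub.sub(mean, axis=0).div(sd.replace(0, np.inf), axis=0)
    return z.mean(axis=0), n_missing


def cox_signature(
    cohort: pd.DataFrame,
    covariate_cols: list[str] | None = None,
    score_col: str = "score",
) -> tuple[float, tuple[float, float], float]:
    """Adjusted Cox PH fit; returns (HR, 95% CI, p) for the signature score.

    Categorical covariates are one-hot encoded with the most frequent
    level as reference.  Requires >= 10 events and no constant covariate.
    """
    covariate_cols = covariate_cols or []
    if cohort["event"].sum() < 10:
        raise ValidationError("need >= 10 events")
    cols = {"time": cohort["time"].to_numpy(dtype=float),
            "event": cohort["event"].to_numpy(dtype=int),
            score_col: cohort[score_col].to_numpy(dtype=float)}
    df = pd.DataFrame(cols)
    for c in covariate_cols:
        v = cohort[c]
        if pd.api.types.is_numeric_dtype(v):
            if v.nunique() < 2:
                raise ValidationError(f"constant covariate {c!r}")
            df[c] = v.to_numpy(dtype=float)
        else:
            ref = v.value_counts().idxmax()
            for level in sorted(v.unique()):
                if level == ref:
                    continue
                df[f"{c}__{level}"] = (v == level).astype(float).to_numpy()
    fitter = CoxPHFitter()
    fitter.fit(df, duration_col="time", event_col="event")
    coef = float(fitter.params_[score_col])
    se = float(fitter.standard_errors_[score_col])
    lo, hi = coef - 1.959963984540054 * se, coef + 1.959963984540054 * se
    p = float(fitter.summary.loc[score_col, "p"])
    return float(np.exp(coef)), (float(np.exp(lo)), float(np.exp(hi))), p


def tertile_stratify(
    cohort: pd.DataFrame, score_col: str = "score"
) -> tuple[pd.Series, dict[str, pd.DataFrame], float]:
    """Stratify by signature tertiles; KM curves and three-way log-rank p.

    Cutpoints are the 33.3%/66.7% score quantiles; boundary ties go to the
    lower stratum.  Returns (labels, {stratum: KM table}, log-rank p).
    """
    scores = cohort[score_col].to_numpy(dtype=float)
    if len(scores) < 9:
        raise ValidationError("need >= 9 subjects")
    if len(np.unique(scores)) < 3:
        raise ValidationError("need >= 3 distinct score values")
    q1, q2 = np.quantile(scores, [1 / 3, 2 / 3])
    labels = pd.Series(
        np.where(scores <= q1, "low", np.where(scores <= q2, "mid", "high")),
        index=cohort.index,
        name="tertile",
    )
    curves: dict[str, pd.DataFrame] = {}
    for stratum in ("low", "mid", "high"):
        sel = labels == stratum
        if not sel.any():  # heavy ties can empty the middle stratum
            logger.warning("tertile_stratify: stratum %r is empty", stratum)
            curves[stratum] = pd.DataFrame(columns=["time", "survival"])
            continue
        km = KaplanMeierFitter()
        km.fit(cohort.loc[sel, "time"], cohort.loc[sel, "event"], label=stratum)
        curves[stratum] = km.survival_function_.reset_index().rename(
            columns={"timeline": "time", stratum: "survival"}
        )
    lr = multivariate_logrank_test(cohort["time"], labels, cohort["event"])
    return labels, curves, float(lr.p_value)
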