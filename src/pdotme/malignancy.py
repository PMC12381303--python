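"""Neoplastic-cell calling from expression-inferred copy number.

The chain is: (1) smooth each cell's normalized expression relative to a
reference population along the genome (:func:`infer_cnv`); (2) summarize
each cell's departure from diploidy as a genomic instability score — the
mean of squared per-locus-scaled smoothed values (:func:`genomic_instability`);
(3) correlate every cell with the average CNV profile of each patient's
most unstable cells to obtain a malignancy score (:func:`malignancy_score`);
(4) threshold both scores jointly, choosing mean + m*SD cutoffs by a grid
search over SD multipliers that maximizes the average silhouette width of
the resulting tumor/normal partition (:func:`call_tumor`).

This is a deliberately simplified copy-number smoother — reference
subtraction, centered moving average within chromosomes, per-cell median
re-centering and clipping — without any HMM state segmentation: only the
smoothed signal feeds the downstream scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, ValidationError, genomic_gene_order, normalize_log1p

logger = logging.getLogger("pdotme")

__all__ = [
    "CNVMatrix",
    "MalignancyCall",
    "infer_cnv",
    "genomic_instability",
    "malignancy_score",
    "call_tumor",
    "pam_silhouette_k",
]


@dataclass
class CNVMatrix:
    """Cells x loci smoothed relative expression (log2-like units)."""

    values: np.ndarray  # cells x loci
    locus_table: pd.DataFrame  # chromosome, position, gene_id per locus
    cell_ids: np.ndarray
    reference_cell_ids: list[str] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]


@dataclass
class MalignancyCall:
    gis: np.ndarray
    mal: np.ndarray
    sd_multipliers: tuple[float, float]
    cutoffs: tuple[float, float]
    label: np.ndarray  # "tumor" / "normal" per cell
    silhouette: float
    grid_silhouettes: pd.DataFrame | None = None


def _moving_average_shrinking(block: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1 with edge-shrinking window."""
    n = block.shape[1]
    half = window // 2
    csum = np.cumsum(block, axis=1)
    csum = np.concatenate([np.zeros((block.shape[0], 1)), csum], axis=1)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    width = (hi - lo + 1).astype(float)
    return (csum[:, hi + 1] - csum[:, lo]) / width[None, :]


def infer_cnv(
    expr: ExpressionMatrix,
    reference_cells: list[str] | np.ndarray,
    window: int = 101,
    clip: float = 3.0,
) -> CNVMatrix:
    """Smoothed relative-expression CNV signal per cell.

    Per gene the relative value is normalized expression minus its mean
    over the reference cells; per cell the relative values are smoothed by
    a centered moving average of ``window`` genes within each chromosome
    (the window shrinks at chromosome edges), re-centered by the cell's
    median and clipped to +/- ``clip``.
    """
    if window < 3 or window % 2 == 0:
        raise ValidationError("window must be odd and >= 3")
    reference_cells = list(reference_cells)
    if not reference_cells:
        raise ValidationError("reference cell set is empty")
    cell_index = pd.Index(expr.cell_ids)
    ref_pos = cell_index.get_indexer(reference_cells)
    if np.any(ref_pos < 0):
        missing = [c for c, p in zip(reference_cells, ref_pos) if p < 0]
        raise ValidationError(f"reference cells not found: {missing[:5]}")

    if expr.normalized is None:
        normalize_log1p(expr)
    order = genomic_gene_order(expr.gene_table)
    if order.size == 0:
        raise ValidationError("no genes carry usable chromosome/start annotation")
    chroms = expr.gene_table["chromosome"].to_numpy()[order]
    if max(pd.Series(chroms).value_counts()) < window and len(set(chroms)) > 0:
        if all(np.sum(chroms == c) < window for c in set(chroms)):
            raise ValidationError(
                f"every chromosome has fewer usable genes than the {window}-gene window"
            )

    norm = np.asarray(expr.normalized.todense())[order, :]  # genes x cells
    rel = (norm - norm[:, ref_pos].mean(axis=1, keepdims=True)) / np.log(2)  # log2 units
    rel = rel.T  # cells x loci

    smoothed = np.empty_like(rel)
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero(chroms == chrom)
        block = rel[:, sel]
        smoothed[:, sel] = _moving_average_shrinking(block, window)
    smoothed -= np.median(smoothed, axis=1, keepdims=True)
    np.clip(smoothed, -clip, clip, out=smoothed)

    locus_table = pd.DataFrame(
        {
            "gene_id": expr.gene_table["gene_id"].to_numpy()[order],
            "chromosome": chroms,
            "position": pd.to_numeric(expr.gene_table["start_bp"], errors="coerce")
            .to_numpy()[order],
        }
    )
    return CNVMatrix(
        values=smoothed,
        locus_table=locus_table,
        cell_ids=np.asarray(expr.cell_ids),
        reference_cell_ids=[str(c) for c in reference_cells],
    )


def genomic_instability(cnv: CNVMatrix) -> np.ndarray:
    """Per-cell mean of squared per-locus z-scaled CNV values.

    Each locus is scaled across cells to zero mean and unit variance
    (sample SD, ddof=1); loci with zero variance contribute 0.  The score
    is the mean of the squared scaled values over loci — large when a
    cell's smoothed profile departs from the cohort at many loci.
    """
    if cnv.n_cells < 2 or cnv.n_loci < 2:
        raise ValidationError("need >= 2 cells and >= 2 loci to scale")
    v = cnv.values
    mean = v.mean(axis=0, keepdims=True)
    sd = v.std(axis=0, ddof=1, keepdims=True)
    z = np.zeros_like(v)
    nz = sd[0] > 0
    z[:, nz] = (v[:, nz] - mean[:, nz]) / sd[:, nz]
    return np.mean(z**2, axis=1)


def malignancy_score(
    cnv: CNVMatrix,
    gis: np.ndarray,
    top_fraction: float = 0.05,
    patient: np.ndarray | None = None,
) -> np.ndarray:
    """Correlation of each cell's CNV row with its patient's tumor profile.

    Per patient the profile is the locus-wise mean over the ``top_fraction``
    of cells with the highest instability scores (at least 2 cells; ties
    broken by cell order).  Cells with a zero-variance CNV row score 0.
    Patients with fewer than 2 cells are skipped (scores NaN) with a
    warning.
    """
    if not (0 < top_fraction <= 1):
        raise ValidationError("top_fraction must lie in (0, 1]")
    gis = np.asarray(gis, dtype=float)
    if patient is None:
        patient = np.repeat("all", cnv.n_cells)
    patient = np.asarray(patient)
    scores = np.full(cnv.n_cells, np.nan)
    for pat in pd.unique(patient):
        idx = np.flatnonzero(patient == pat)
        if idx.size < 2:
            logger.warning("malignancy_score: patient %r has < 2 cells; skipped", pat)
            continue
        n_top = max(2, int(np.ceil(top_fraction * idx.size)))
        # stable sort on -gis keeps cell order among ties
        top = idx[np.argsort(-gis[idx], kind="stable")[:n_top]]
        profile = cnv.values[top].mean(axis=0)
        pv = profile - profile.mean()
        pnorm = np.sqrt(np.sum(pv**2))
        rows = cnv.values[idx] - cnv.values[idx].mean(axis=1, keepdims=True)
        rnorm = np.sqrt(np.sum(rows**2, axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = rows @ pv / (rnorm * pnorm)
        r[(rnorm == 0) | (pnorm == 0)] = 0.0
        scores[idx] = r
    return scores


def _binary_silhouette(dist: np.ndarray, labels: np.ndarray) -> float:
    """Average silhouette width for a two-class labeling (precomputed dists)."""
    n = dist.shape[0]
    onehot = np.stack([labels == 0, labels == 1], axis=1).astype(float)
    counts = onehot.sum(axis=0)
    sums = dist @ onehot  # n x 2: total distance to each cluster
    own = labels.astype(int)
    a = sums[np.arange(n), own] / np.maximum(counts[own] - 1, 1)
    b = sums[np.arange(n), 1 - own] / counts[1 - own]
    s = (b - a) / np.maximum(a, b)
    s[counts[own] == 1] = 0.0  # singleton convention
    return float(np.mean(s))


def call_tumor(
    gis: np.ndarray,
    mal: np.ndarray,
    grid: np.ndarray | None = None,
    min_class_frac: float = 0.10,
    keep_grid: bool = False,
) -> MalignancyCall:
    """Silhouette-optimized joint thresholding of the two scores.

    For every pair of SD multipliers (m1, m2) on the grid, the cutoffs are
    ``mean + m*SD`` of each score and a cell is called tumor when BOTH
    scores exceed their cutoffs.  The pair maximizing the average
    silhouette width — computed on the per-score standardized 2-D space
    with Euclidean distance — wins; ties go to the lexicographically
    smaller pair.

    Both classes must contain at least ``min_class_frac`` of the cells
    (default 10%): instability scores are heavy-tailed (sequencing depth
    inflates the CNV noise of shallow cells), and an unconstrained average
    silhouette width is maximized by splitting off a small knot of extreme
    outlier cells — a degenerate partition that threshold inspection would
    reject, and far below the tumor or normal fractions seen in resected
    carcinoma samples.  Set ``min_class_frac=0`` to only require non-empty
    classes.
    """
    gis = np.asarray(gis, dtype=float)
    mal = np.asarray(mal, dtype=float)
    if gis.size < 10:
        raise ValidationError("need >= 10 cells to threshold")
    if not (np.all(np.isfinite(gis)) and np.all(np.isfinite(mal))):
        raise ValidationError("scores must be finite")
    if grid is None:
        grid = np.round(np.arange(-1.0, 3.0 + 1e-9, 0.1), 10)
    sd_g, sd_m = gis.std(ddof=1), mal.std(ddof=1)
    if sd_g == 0 or sd_m == 0:
        raise ValidationError("a score is constant; no valid tumor/normal partition")
    zg = (gis - gis.mean()) / sd_g
    zm = (mal - mal.mean()) / sd_m
    pts = np.stack([zg, zm], axis=1)
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=2))

    min_size = max(1, int(np.ceil(min_class_frac * gis.size)))
    best = None
    records = []
    for m1 in grid:
        lab_g = zg > m1
        for m2 in grid:
            labels = (lab_g & (zm > m2)).astype(int)
            k = labels.sum()
            if k < min_size or labels.size - k < min_size:
                continue
            s = _binary_silhouette(dist, labels)
            if keep_grid:
                records.append((m1, m2, s))
            if best is None or s > best[0] + 1e-15:
                best = (s, float(m1), float(m2), labels)
    if best is None:
        raise ValidationError(
            "no grid point produced two non-empty classes; widen the grid"
        )
    s, m1, m2, labels = best
    return MalignancyCall(
        gis=gis,
        mal=mal,
        sd_multipliers=(m1, m2),
        cutoffs=(gis.mean() + m1 * sd_g, mal.mean() + m2 * sd_m),
        label=np.where(labels == 1, "tumor", "normal"),
        silhouette=s,
        grid_silhouettes=pd.DataFrame(records, columns=["m_gis", "m_mal", "silhouette"])
        if keep_grid
        else None,
    )


# --------------------------------------------------------------------------
# PAM (k-medoids) with silhouette-based k selection


def _pam(dist: np.ndarray, k: int) -> np.ndarray:
    """Classic PAM: greedy BUILD then SWAP until no improvement."""
    n = dist.shape[0]
    medoids = [int(np.argmin(dist.sum(axis=0)))]
    while len(medoids) < k:
        cur = dist[:, medoids].min(axis=1)
        gains = np.maximum(cur[:, None] - dist, 0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)

    def cost(meds: list[int]) -> float:
        return float(dist[:, meds].min(axis=1).sum())

    best_cost = cost(medoids)
    improved = True
    while improved:
        improved = False
        for mi, m in enumerate(list(medoids)):
            for h in range(n):
                if h in medoids:
                    continue
                trial = sorted(medoids[:mi] + [h] + medoids[mi + 1 :])
                c = cost(trial)
                if c < best_cost - 1e-12:
                    best_cost, medoids, improved = c, trial, True
        # loop until a full pass makes no swap
    return np.argmin(dist[:, medoids], axis=1)


def pam_silhouette_k(
    points: np.ndarray, k_range: list[int] | range
) -> tuple[int, np.ndarray]:
    """PAM clustering for each k; return the k with maximal silhouette."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = points.shape[0]
    if n < 3:
        raise ValidationError("need >= 3 points")
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2 or ks[-1] > n - 1:
        raise ValidationError("k_range must lie within [2, n-1]")
    diff = points[:, None, :] - points[None, :, :]
    dist = np.sqrt(np.sum(diff**2, axis=2))
    from sklearn.metrics import silhouette_score

    best_k, best_s, best_labels = None, -np.inf, None
    for k in ks:
        labels = _pam(dist, k)
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(dist, labels, metric="precomputed")
        if s > best_s + 1e-15:
            best_k, best_s, best_labels = k, s, labels
    if best_k is None:
        raise ValidationError("no k produced a valid partition")
    return best_k, best_labels
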