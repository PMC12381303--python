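"""Organoid image segmentation and shape statistics.

Organoids are segmented by global Otsu thresholding (bright objects on a
dark background) followed by a 3x3 binary closing, hole filling and
8-connected labeling.  Per-object statistics use physical units: area in
um^2, perimeter in um via the 4-direction Crofton estimator (a raw
pixel-boundary perimeter systematically overestimates and would break the
circularity-of-a-disk sanity property), and circularity
``4*pi*area / perimeter^2`` clipped at 1.  Objects at or below the
single-cell size cutoff (300 um^2 by default) are excluded before group
comparisons, which use pairwise two-sided Wilcoxon rank-sum tests with
Bonferroni correction.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.stats
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import perimeter_crofton, regionprops
from skimage.morphology import closing, footprint_rectangle

from .core import ValidationError

logger = logging.getLogger("pdotme")

__all__ = ["segment", "shape_stats", "mask_circularity", "compare_circularity"]


def segment(image: np.ndarray, method: str = "otsu", invert: bool = False) -> np.ndarray:
    """Label mask of bright objects from a single-channel image."""
    image = np.asarray(image)
    if image.ndim != 2 or min(image.shape) < 32:
        raise ValidationError("image must be single-channel and >= 32x32 px")
    if method != "otsu":
        raise ValidationError(f"unknown thresholding method {method!r}")
    if invert:
        image = image.max() - image
    if np.all(image == image.flat[0]):
        logger.warning("segment: blank image, no objects")
        return np.zeros(image.shape, dtype=int)
    thresh = threshold_otsu(image)
    binary = image > thresh
    binary = closing(binary, footprint_rectangle((3, 3)))
    binary = scipy.ndimage.binary_fill_holes(binary)
    return sk_label(binary, connectivity=2)


def mask_circularity(mask: np.ndarray) -> float:
    """Circularity of a single binary mask via the Crofton perimeter."""
    area = float(mask.sum())
    perim = float(perimeter_crofton(mask, directions=4))
    if perim == 0:
        return 1.0
    return min(1.0, 4.0 * np.pi * area / perim**2)


def shape_stats(
    mask: np.ndarray,
    pixel_size_um: float = 1.0,
    image_id: str = "",
    group: str = "",
) -> pd.DataFrame:
    """Per-object area (um^2), perimeter (um), circularity and centroid."""
    if pixel_size_um <= 0:
        raise ValidationError("pixel_size_um must be positive")
    rows = []
    for prop in regionprops(mask):
        single = mask == prop.label
        area = prop.area * pixel_size_um**2
        perim = perimeter_crofton(single, directions=4) * pixel_size_um
        circ = 1.0 if perim == 0 else min(1.0, 4.0 * np.pi * area / perim**2)
        cy, cx = prop.centroid
        rows.append(
            dict(
                label=prop.label,
                area=area,
                perimeter=perim,
                circularity=circ,
                centroid_x=cx,
                centroid_y=cy,
                image_id=image_id,
                group=group,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label", "area", "perimeter", "circularity",
            "centroid_x", "centroid_y", "image_id", "group",
        ],
    )


def compare_circularity(
    stats: pd.DataFrame,
    group_col: str = "group",
    min_area_um2: float = 300.0,
) -> pd.DataFrame:
    """Pairwise Wilcoxon rank-sum tests of circularity between groups.

    Objects with area <= ``min_area_um2`` (single cells) are dropped
    first; the Bonferroni multiplier is the number of group pairs.
    """
    kept = stats[stats["area"] > min_area_um2]
    groups = sorted(kept[group_col].unique())
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups after the area filter")
    pairs = list(itertools.combinations(groups, 2))
    rows = []
    for g1, g2 in pairs:
        x = kept.loc[kept[group_col] == g1, "circularity"].to_numpy()
        y = kept.loc[kept[group_col] == g2, "circularity"].to_numpy()
        if len(x) < 3 or len(y) < 3:
            logger.warning("compare_circularity: pair (%s, %s) skipped (too few objects)", g1, g2)
            continue
        stat, p = scipy.stats.ranksums(x, y)
        rows.append(
            dict(
                group_1=g1,
                group_2=g2,
                n_1=len(x),
                n_2=len(y),
                median_1=float(np.median(x)),
                median_2=float(np.median(y)),
                statistic=float(stat),
                p=float(p),
                p_adj=min(1.0, float(p) * len(pairs)),
            )
        )
    return pd.DataFrame(rows)
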