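"""Background-referenced threshold statistic: the hyperintense SNpc area.

For each subject, the two consecutive axial slices with the most midbrain are
selected; the background is the midbrain minus the SNpc, whose mean signal
intensity (MSI) and standard deviation define a per-subject threshold
``MSI + k * SD``.  The hyperintense area is the number of SNpc pixels with
signal strictly above that threshold, multiplied by the in-plane pixel area
(mm^2).  Candidate multipliers k of 1, 1.5 and 2 are swept on a labelled
cohort and the k with the highest ROC AUC is frozen for external use; 1.5 is
the multiplier the original study selected.

Because the threshold is an affine function of the background statistics, the
suprathreshold pixel set is invariant under any positive affine intensity
rescaling of the image (x -> a*x + b, a > 0), which makes the statistic robust
to global scanner gain/offset differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .imageio import ImageStack, Label, LabelMask

__all__ = [
    "BackgroundStats",
    "HyperintenseResult",
    "select_slices",
    "background_stats",
    "hyperintense_area",
    "threshold_sweep",
    "relative_variation",
    "quantify_cohort",
    "DEFAULT_K_VALUES",
]

DEFAULT_K_VALUES: tuple[float, ...] = (1.0, 1.5, 2.0)


@dataclass
class BackgroundStats:
    """Mean (MSI) and sample SD of the midbrain-minus-SNpc region."""

    msi: float
    sd: float
    n_pixels: int
    slice_indices: tuple[int, int]


@dataclass
class HyperintenseResult:
    """Suprathreshold SNpc pixel count and area for one subject and one k."""

    k: float
    threshold: float
    n_suprathreshold: int
    area_mm2: float
    per_slice: dict[int, int]
    background: BackgroundStats


def select_slices(mask: LabelMask) -> tuple[int, int]:
    """The consecutive slice pair maximizing total midbrain pixel count.

    Ties break to the smaller index.  Raises if no consecutive pair contains
    midbrain.
    """
    mb_counts = (mask.data != Label.OUTSIDE).sum(axis=(1, 2))
    if mask.data.shape[0] < 2:
        raise ValueError("mask has fewer than 2 slices")
    pair_sums = mb_counts[:-1] + mb_counts[1:]
    if pair_sums.max() == 0:
        raise ValueError("no consecutive slice pair contains midbrain")
    i = int(np.argmax(pair_sums))  # argmax returns the first maximum
    return (i, i + 1)


def background_stats(
    image: ImageStack, mask: LabelMask, slice_pair: tuple[int, int] | None = None, ddof: int = 1
) -> BackgroundStats:
    """MSI and SD pooled over BACKGROUND pixels of both selected slices.

    One statistic per subject: values from the two slices are pooled before
    the mean/SD.  Sample SD (ddof=1) by default.
    """
    mask.check_alignment(image)
    if slice_pair is None:
        slice_pair = select_slices(mask)
    i, j = slice_pair
    sel = mask.data[[i, j]] == Label.BACKGROUND
    vals = image.data[[i, j]][sel]
    if vals.size < 2:
        raise ValueError(f"need >= 2 background pixels on slices {slice_pair}, got {vals.size}")
    return BackgroundStats(
        msi=float(vals.mean()),
        sd=float(vals.std(ddof=ddof)),
        n_pixels=int(vals.size),
        slice_indices=(int(i), int(j)),
    )


def hyperintense_area(
    image: ImageStack,
    mask: LabelMask,
    k: float,
    slice_pair: tuple[int, int] | None = None,
    stats: BackgroundStats | None = None,
) -> HyperintenseResult:
    """Count SNpc pixels strictly above ``MSI + k * SD`` on the slice pair.

    The area is the count times the image's in-plane pixel area, so
    ``area / pixel_area`` is always the integer count.
    """
    mask.check_alignment(image)
    if stats is None:
        stats = background_stats(image, mask, slice_pair)
    threshold = stats.msi + k * stats.sd
    per_slice: dict[int, int] = {}
    total = 0
    for i in stats.slice_indices:
        sel = mask.data[i] == Label.SNPC
        n = int((image.data[i][sel] > threshold).sum())  # strict inequality
        per_slice[int(i)] = n
        total += n
    return HyperintenseResult(
        k=float(k),
        threshold=float(threshold),
        n_suprathreshold=total,
        area_mm2=total * image.pixel_area_mm2,
        per_slice=per_slice,
        background=stats,
    )


def relative_variation(stats: BackgroundStats) -> float:
    """Background image-quality index: MSI divided by SD."""
    if stats.sd == 0:
        raise ZeroDivisionError("relative variation undefined for sd = 0")
    return stats.msi / stats.sd


def quantify_cohort(
    subjects: Sequence[tuple[str, str, ImageStack, LabelMask]],
    k_values: Sequence[float] = DEFAULT_K_VALUES,
) -> pd.DataFrame:
    """Per-subject hyperintense areas for every k.

    ``subjects`` yields (subject_id, group, image, mask) tuples; the result has
    one row per subject and k with columns subject_id, group, k, msi, sd,
    threshold, count, area_mm2, slice_lo, slice_hi.
    """
    rows = []
    for sid, group, image, mask in subjects:
        stats = background_stats(image, mask)
        for k in k_values:
            res = hyperintense_area(image, mask, k, stats=stats)
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "k": float(k),
                    "msi": stats.msi,
                    "sd": stats.sd,
                    "threshold": res.threshold,
                    "count": res.n_suprathreshold,
                    "area_mm2": res.area_mm2,
                    "slice_lo": stats.slice_indices[0],
                    "slice_hi": stats.slice_indices[1],
                }
            )
    return pd.DataFrame(rows)


def threshold_sweep(results: pd.DataFrame) -> tuple[float, dict[float, float]]:
    """Pick the k with the highest diagnostic AUC (low area indicates PD).

    ``results`` is the table from :func:`quantify_cohort` with both groups
    present.  Returns (optimal k, {k: auc}); AUC ties break to the smallest k.
    """
    from .evalstats import roc_auc

    aucs: dict[float, float] = {}
    for k, sub in results.groupby("k"):
        labels = sub["group"].to_numpy()
        if len(set(labels)) < 2:
            raise ValueError("threshold sweep needs both HC and PD subjects")
        report = roc_auc(sub["area_mm2"].to_numpy(), labels, orientation="low_is_positive")
        aucs[float(k)] = report.auc
    best = min(sorted(aucs), key=lambda k: (-aucs[k], k))
    return best, aucs
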