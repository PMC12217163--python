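"""Foci detection, per-cell counting and object-based colocalization.

Covers the cell-population readouts: counting damage-marker (galectin) foci
per cell over long time-lapse acquisitions, total LNP uptake intensity per
cell, normalization of responses to a control condition, and two
object-based colocalization rules — resizing foci to 5-px discs and testing
pixel overlap, or requiring >25% area overlap between segmented objects.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import FOCI_COLUMNS

logger = logging.getLogger("lnptrace")

#: 8-connectivity structuring element for 2-D labeling.
STRUCTURE_8 = np.ones((3, 3), dtype=bool)


def enhance_foci(image: np.ndarray, median_kernel_px: int = 9) -> np.ndarray:
    """Enhance small bright foci: raw minus median-filtered, clamped at 0.

    The median filter tracks the smooth background (including gradients wider
    than the kernel), so the difference isolates structures smaller than the
    kernel.
    """
    if median_kernel_px < 3 or median_kernel_px % 2 == 0:
        raise ValueError("median kernel must be odd and >= 3")
    image = np.asarray(image, dtype=float)
    background = ndimage.median_filter(image, size=median_kernel_px)
    return np.clip(image - background, 0.0, None)


def detect_foci(enhanced: np.ndarray, intensity_threshold: float,
                size_range: tuple[int, int] = (1, 10_000), *,
                frame: int = 0, channel: str | int = 0,
                cell_labels: np.ndarray | None = None,
                raw: np.ndarray | None = None) -> pd.DataFrame:
    """Detect foci as 8-connected components above an intensity threshold.

    Components with pixel area outside ``size_range`` (inclusive) are
    discarded.  ``total_intensity`` is summed over *raw* if given, else over
    the enhanced image.  Each focus is assigned the cell label under its
    centroid (0 if outside every cell).

    Returns rows of the foci table (see :data:`lnptrace.io.FOCI_COLUMNS`).
    """
    enhanced = np.asarray(enhanced, dtype=float)
    mask = enhanced > intensity_threshold
    labels, n = ndimage.label(mask, structure=STRUCTURE_8)
    measure_on = np.asarray(raw, dtype=float) if raw is not None else enhanced
    rows = []
    if n:
        idx = np.arange(1, n + 1)
        areas = ndimage.sum_labels(np.ones_like(labels), labels, idx)
        sums = ndimage.sum_labels(measure_on, labels, idx)
        centroids = ndimage.center_of_mass(enhanced, labels, idx)
        fid = 0
        for i, (area, total, (cy, cx)) in enumerate(zip(areas, sums, centroids)):
            if not size_range[0] <= area <= size_range[1]:
                continue
            cell = 0
            if cell_labels is not None:
                cell = int(cell_labels[int(round(cy)), int(round(cx))])
            rows.append({
                "frame": frame, "channel": channel, "focus_id": fid,
                "x_px": float(cx), "y_px": float(cy),
                "area_px": int(area), "total_intensity": float(total),
                "cell_id": cell,
            })
            fid += 1
    return pd.DataFrame(rows, columns=FOCI_COLUMNS)


def foci_per_cell(foci: pd.DataFrame, n_cells_first_frame: int,
                  baseline_frames: int = 1) -> pd.DataFrame:
    """Baseline-subtracted foci count per cell over time.

    The count in each frame is divided by the number of cells identified in
    the first frame; the mean per-cell count over the first
    ``baseline_frames`` frames is then subtracted.  Values are reported as
    computed (slightly negative values are possible and not clamped).
    """
    if n_cells_first_frame <= 0:
        raise ValueError("first-frame cell count must be positive")
    frames = np.arange(int(foci["frame"].max()) + 1) if len(foci) else np.array([0])
    counts = foci.groupby("frame").size().reindex(frames, fill_value=0)
    per_cell = counts / n_cells_first_frame
    baseline = per_cell.iloc[:baseline_frames].mean()
    return pd.DataFrame({
        "frame": frames,
        "foci_per_cell": per_cell.to_numpy(),
        "foci_per_cell_baseline_subtracted": per_cell.to_numpy() - baseline,
    })


def uptake_intensity(foci: pd.DataFrame, n_cells_first_frame: int
                     ) -> pd.DataFrame:
    """Total focus intensity (sum) per frame divided by the first-frame cell
    count; the uptake readout for LNP channels."""
    if n_cells_first_frame <= 0:
        raise ValueError("first-frame cell count must be positive")
    frames = np.arange(int(foci["frame"].max()) + 1) if len(foci) else np.array([0])
    totals = (foci.groupby("frame")["total_intensity"].sum()
              .reindex(frames, fill_value=0.0))
    return pd.DataFrame({
        "frame": frames,
        "intensity_per_cell": totals.to_numpy() / n_cells_first_frame,
    })


def normalize_response(series: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Divide a condition's response series by the maximum of the negative
    control series (so the control peaks at exactly 1)."""
    control = np.asarray(control, dtype=float)
    peak = control.max()
    if not peak > 0:
        raise ValueError("control maximum must be positive")
    return np.asarray(series, dtype=float) / peak


def segment_objects(image: np.ndarray,
                    threshold: float | str = "otsu") -> np.ndarray:
    """Segment diffuse structures into a label image by global thresholding.

    *threshold* is either an absolute intensity or ``"otsu"`` (default).
    A configurable stand-in for pipeline-specific automatic thresholding of
    e.g. lipid-dye structures; the choice is recorded by the caller's config.
    """
    from skimage.filters import threshold_otsu

    image = np.asarray(image, dtype=float)
    t = threshold_otsu(image) if threshold == "otsu" else float(threshold)
    labels, _ = ndimage.label(image > t, structure=STRUCTURE_8)
    return labels


def _disc_mask(shape: tuple[int, int], centers: np.ndarray,
               diameter_px: float) -> np.ndarray:
    """Boolean image with a disc of the given diameter at each (y, x) center."""
    out = np.zeros(shape, dtype=bool)
    r = diameter_px / 2.0
    n = int(np.ceil(r))
    h, w = shape
    for cy, cx in centers:
        iy, ix = int(round(cy)), int(round(cx))
        y0, y1 = max(0, iy - n), min(h, iy + n + 1)
        x0, x1 = max(0, ix - n), min(w, ix + n + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        out[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
    return out


def colocalize_resized(foci_a: pd.DataFrame, foci_b: pd.DataFrame,
                       shape: tuple[int, int], disc_diameter_px: float = 5.0
                       ) -> tuple[np.ndarray, float]:
    """Resized-disc colocalization of foci centroids.

    Every focus is replaced by a disc of ``disc_diameter_px`` at its centroid;
    a focus of A colocalizes if its disc shares at least one pixel with any
    B disc.  Returns per-A flags and the colocalized fraction.
    """
    if len(foci_a) == 0:
        return np.zeros(0, dtype=bool), np.nan
    b_mask = _disc_mask(shape, foci_b[["y_px", "x_px"]].to_numpy(float),
                        disc_diameter_px) if len(foci_b) else \
        np.zeros(shape, dtype=bool)
    flags = np.zeros(len(foci_a), dtype=bool)
    for i, (cy, cx) in enumerate(foci_a[["y_px", "x_px"]].to_numpy(float)):
        a_mask = _disc_mask(shape, np.array([[cy, cx]]), disc_diameter_px)
        flags[i] = bool((a_mask & b_mask).any())
    return flags, float(flags.mean())


def colocalize_overlap(labels_a: np.ndarray, labels_b: np.ndarray,
                       min_fraction: float = 0.25
                       ) -> tuple[dict[int, bool], float]:
    """Area-overlap colocalization between two label images.

    An A object colocalizes iff the pixels it shares with some *single* B
    object exceed ``min_fraction`` of the A object's area (strict inequality).
    The relation is asymmetric: swap the arguments for the B-side fractions.

    Returns ``({a_label: flag}, fraction of A objects colocalized)``.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label images must share geometry")
    ids_a = np.unique(labels_a)
    ids_a = ids_a[ids_a > 0]
    flags: dict[int, bool] = {}
    for a in ids_a:
        sel = labels_a == a
        area = int(sel.sum())
        overlap_b = labels_b[sel]
        overlap_b = overlap_b[overlap_b > 0]
        best = 0
        if overlap_b.size:
            best = int(np.bincount(overlap_b).max())
        flags[int(a)] = best / area > min_fraction
    frac = float(np.mean(list(flags.values()))) if flags else np.nan
    return flags, frac
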