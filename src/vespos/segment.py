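"""Puncta segmentation: thresholding, labeling, watershed splitting, cell QC.

Thresholding follows the study protocol of a single fixed threshold per
channel per experiment batch; an Otsu auto mode is available for synthetic
runs.  Structures are 8-connected components above a minimum size (default
4 px, suppressing single-pixel noise).  Touching structures can be split by
marker-based watershed on the Euclidean distance transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .ioutil import CellROI, TissueScene

log = logging.getLogger("vespos")

DEFAULT_MIN_SIZE_PX = 4


@dataclass
class StructureSet:
    """Labeled above-threshold structures within one cell.

    ``label_map`` is a full-frame integer array (0 = background); ``table``
    has one row per structure with columns ``label``, ``area_px``,
    ``area_um2``, ``centroid_row``, ``centroid_col``, ``mean_intensity``,
    ``bbox_*``.
    """

    cell_id: int
    channel: str
    label_map: np.ndarray
    table: pd.DataFrame
    pixel_size: float = 1.0

    @property
    def count(self) -> int:
        return len(self.table)

    def foreground(self) -> np.ndarray:
        return self.label_map > 0


def threshold_channel(scene: TissueScene, role: str, roi: CellROI,
                      threshold=None, exclude_nucleus: bool = True,
                      ) -> np.ndarray:
    """Binary signal mask: channel intensity > threshold, within the cell.

    ``threshold`` is a fixed value, or ``None``/``"otsu"`` for Otsu's method
    computed over the in-cell pixels.  Nucleus pixels are excluded by default
    so that downstream scoring sees cytoplasmic signal only.
    """
    img = scene.channel(role)
    region = roi.cytoplasm_mask if exclude_nucleus else roi.cell_mask
    if not region.any():
        raise ValueError(f"cell {roi.cell_id}: empty ROI for thresholding")
    if threshold is None or threshold == "otsu":
        threshold = threshold_otsu(img[region])
    elif isinstance(threshold, str):
        raise ValueError(f"unknown auto-threshold method {threshold!r}")
    elif threshold < 0:
        raise ValueError("threshold must be >= 0")
    return (img > threshold) & region


def label_structures(mask: np.ndarray, min_size_px: int = DEFAULT_MIN_SIZE_PX,
                     cell_id: int = 0, channel: str = "",
                     pixel_size: float = 1.0, intensity_image=None,
                     split: bool = False) -> StructureSet:
    """Label 8-connected components of ``mask`` and tabulate their stats.

    Components smaller than ``min_size_px`` are discarded.  With
    ``split=True`` touching structures are first separated by
    :func:`split_touching` (post-watershed labels are then measured, matching
    the endosome-sizing path; raw components otherwise).
    """
    mask = np.asarray(mask, bool)
    if split:
        lab = split_touching(mask)
    else:
        lab = cc_label(mask, connectivity=2)
    rows = []
    keep = np.zeros_like(lab)
    next_id = 0
    for prop in regionprops(lab, intensity_image=intensity_image):
        if prop.area < min_size_px:
            continue
        next_id += 1
        keep[lab == prop.label] = next_id
        r, c = prop.centroid
        rows.append({
            "label": next_id,
            "area_px": int(prop.area),
            "area_um2": float(prop.area) * pixel_size ** 2,
            "centroid_row": r,
            "centroid_col": c,
            "mean_intensity": (float(prop.mean_intensity)
                               if intensity_image is not None else np.nan),
            "bbox_min_row": prop.bbox[0], "bbox_min_col": prop.bbox[1],
            "bbox_max_row": prop.bbox[2], "bbox_max_col": prop.bbox[3],
        })
    cols = ["label", "area_px", "area_um2", "centroid_row", "centroid_col",
            "mean_intensity", "bbox_min_row", "bbox_min_col",
            "bbox_max_row", "bbox_max_col"]
    table = pd.DataFrame(rows, columns=cols)
    return StructureSet(cell_id=cell_id, channel=channel, label_map=keep,
                        table=table, pixel_size=pixel_size)


def split_touching(mask: np.ndarray, smoothing_sigma: float = 1.0,
                   min_marker_distance: int = 2) -> np.ndarray:
    """Separate touching objects by watershed on the distance transform.

    Markers are regional maxima of the Gaussian-smoothed (σ = 1 px) Euclidean
    distance transform, merged when closer than 2 px.  Watershed lines
    (single-pixel separations) are removed from the foreground, so the union
    of output labels is a subset of the input mask.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        return np.zeros(mask.shape, np.int32)
    dist = ndimage.distance_transform_edt(mask)
    smooth = gaussian(dist, sigma=smoothing_sigma, preserve_range=True)
    peaks = peak_local_max(smooth, min_distance=min_marker_distance,
                           labels=mask, exclude_border=False)
    markers = np.zeros(mask.shape, np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:  # flat tiny object: keep as one label
        return cc_label(mask, connectivity=2).astype(np.int32)
    return watershed(-smooth, markers, mask=mask, watershed_line=True)


def qc_cells(rois) -> list[CellROI]:
    """Keep cells whose nucleus is present and lies in the focal plane."""
    kept = []
    for roi in rois:
        if roi.nucleus_in_plane and roi.nucleus_mask.any():
            kept.append(roi)
        else:
            log.info("QC: excluding cell %d (nucleus_in_plane=%s, nucleus_px=%d)",
                     roi.cell_id, roi.nucleus_in_plane, int(roi.nucleus_mask.sum()))
    return kept
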