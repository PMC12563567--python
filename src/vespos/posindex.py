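"""Perinuclear/peripheral equal-area partition and the distribution index.

The distribution index D summarizes where thresholded signal sits inside a
cell.  Each cell's cytoplasm is split into two domains of equal pixel area by
Euclidean distance to the nucleus: the half closest to the nucleus is the
perinuclear domain, its complement the peripheral domain.  With signal areas
A_peri, A_periph and A_total = A_peri + A_periph,

    D = (A_peri - A_periph) / A_total

so D = +1 for perfectly perinuclear signal, 0 for evenly dispersed signal and
-1 for perfectly peripheral signal.

"Equal" is enforced per cell as equal pixel area (within one pixel for odd
cytoplasm areas).  Pixels tied exactly at the split distance are assigned in
deterministic raster (row-major) order, which makes the partition — and hence
D — exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .ioutil import CellROI, TissueScene


@dataclass
class DomainPartition:
    """Equal-area perinuclear/peripheral split of one cell's cytoplasm."""

    cell_id: int
    perinuclear_mask: np.ndarray
    peripheral_mask: np.ndarray
    split_distance: float  # d*, px from nucleus mask
    area_difference: int   # |area(peri) - area(periph)|, px


@dataclass
class DistributionResult:
    """Signed distribution index for one cell and channel."""

    cell_id: int
    channel: str
    area_perinuclear: int
    area_peripheral: int
    area_total: int
    index: float
    defined: bool = True


@dataclass
class LocalizationCall:
    """Phenotype category assigned to one cell."""

    cell_id: int
    category: str  # perinuclear | dispersed | peripheral | ectopic_focus
    index: float
    cluster_fraction: float
    cluster_distance_um: float


def nucleus_distance_map(roi: CellROI) -> np.ndarray:
    """Euclidean distance of every pixel to the nucleus mask (0 inside it)."""
    if not roi.nucleus_mask.any():
        raise ValueError(
            f"cell {roi.cell_id}: empty nucleus mask — partition undefined "
            "without a nucleus reference"
        )
    return ndimage.distance_transform_edt(~roi.nucleus_mask)


def equal_area_partition(roi: CellROI) -> DomainPartition:
    """Split the cytoplasm into equal-area perinuclear/peripheral domains.

    Cytoplasmic pixels are ranked by Euclidean distance to the nucleus mask;
    the split distance d* is the distance at the half-area rank.  Pixels
    strictly below d* are perinuclear, strictly above are peripheral, and
    ties at d* are assigned in raster order to the perinuclear domain until
    it holds ``ceil(cytoplasm_area / 2)`` pixels.
    """
    dist = nucleus_distance_map(roi)
    cyto = roi.cytoplasm_mask
    rr, cc = np.nonzero(cyto)  # row-major order by construction
    d = dist[rr, cc]
    n = d.size
    half = (n + 1) // 2
    d_star = float(np.partition(d, half - 1)[half - 1])

    peri = np.zeros_like(cyto)
    below = d < d_star
    peri[rr[below], cc[below]] = True
    deficit = half - int(below.sum())
    if deficit > 0:
        tie_idx = np.nonzero(d == d_star)[0][:deficit]  # raster order
        peri[rr[tie_idx], cc[tie_idx]] = True
    periph = cyto & ~peri
    return DomainPartition(
        cell_id=roi.cell_id,
        perinuclear_mask=peri,
        peripheral_mask=periph,
        split_distance=d_star,
        area_difference=abs(int(peri.sum()) - int(periph.sum())),
    )


def distribution_index(partition: DomainPartition, signal_mask: np.ndarray,
                       channel: str = "") -> DistributionResult:
    """Compute D from a partition and a thresholded signal mask.

    Signal is clipped to the cytoplasm (the union of the two domains) before
    counting, so nucleus-overlapping or extracellular pixels never contribute.
    When no signal remains, the result is flagged undefined rather than
    raising.
    """
    signal = np.asarray(signal_mask, bool)
    a_peri = int((signal & partition.perinuclear_mask).sum())
    a_periph = int((signal & partition.peripheral_mask).sum())
    a_total = a_peri + a_periph
    if a_total == 0:
        return DistributionResult(partition.cell_id, channel, 0, 0, 0,
                                  index=float("nan"), defined=False)
    return DistributionResult(
        cell_id=partition.cell_id,
        channel=channel,
        area_perinuclear=a_peri,
        area_peripheral=a_periph,
        area_total=a_total,
        index=(a_peri - a_periph) / a_total,
    )


@dataclass
class ClassifierThresholds:
    """Decision thresholds for :func:`classify_localization`.

    ``d_hi``/``d_lo`` bound the perinuclear/peripheral calls on the index;
    a cell is called ``ectopic_focus`` when the largest single-linkage cluster
    of structure centroids (linked within ``link_radius_um``) carries at least
    ``cluster_fraction`` of total structure area and its centroid lies more
    than ``offset_um`` from the nucleus boundary.
    """

    d_hi: float = 0.5
    d_lo: float = -0.5
    cluster_fraction: float = 0.5
    offset_um: float = 10.0
    link_radius_um: float = 3.0


def classify_localization(result: DistributionResult, structures, roi: CellROI,
                          pixel_size: float,
                          thresholds: ClassifierThresholds | None = None,
                          ) -> LocalizationCall:
    """Assign one of perinuclear/dispersed/peripheral/ectopic_focus.

    ``structures`` is a :class:`~vespos.segment.StructureSet`; its centroid
    table drives the ectopic-focus test, which takes precedence over the
    index-based calls.
    """
    th = thresholds or ClassifierThresholds()
    frac, dist_um = _dominant_cluster(structures, roi, pixel_size,
                                      th.link_radius_um)
    if frac >= th.cluster_fraction and dist_um > th.offset_um:
        cat = "ectopic_focus"
    elif result.defined and result.index >= th.d_hi:
        cat = "perinuclear"
    elif result.defined and result.index <= th.d_lo:
        cat = "peripheral"
    else:
        cat = "dispersed"
    return LocalizationCall(roi.cell_id, cat, result.index, frac, dist_um)


def _dominant_cluster(structures, roi, pixel_size, link_radius_um):
    """Area fraction and nucleus-boundary distance of the largest centroid
    cluster (single linkage)."""
    tab = structures.table
    if len(tab) == 0:
        return 0.0, 0.0
    pts = tab[["centroid_row", "centroid_col"]].to_numpy(float)
    areas = tab["area_px"].to_numpy(float)
    if len(tab) == 1:
        labels = np.array([1])
    else:
        z = linkage(pdist(pts) * pixel_size, method="single")
        labels = fcluster(z, t=link_radius_um, criterion="distance")
    best_frac, best_sel = 0.0, None
    for lab in np.unique(labels):
        sel = labels == lab
        frac = areas[sel].sum() / areas.sum()
        if frac > best_frac:
            best_frac, best_sel = frac, sel
    centroid = np.average(pts[best_sel], axis=0, weights=areas[best_sel])
    dist = nucleus_distance_map(roi)
    r = int(round(np.clip(centroid[0], 0, dist.shape[0] - 1)))
    c = int(round(np.clip(centroid[1], 0, dist.shape[1] - 1)))
    return best_frac, float(dist[r, c]) * pixel_size


def cohort_index_table(scene: TissueScene, rois, channel: str,
                       threshold=None, exclude_nucleus: bool = True,
                       clone_only: bool = True) -> pd.DataFrame:
    """Per-cell distribution-index table over a cohort.

    Runs QC (nucleus-in-plane), thresholds the named channel inside each
    eligible cell, partitions it, and returns one row per cell with a defined
    index.  Cells with no above-threshold signal are excluded (they carry no
    distribution information) and counted in the log.
    """
    from .segment import qc_cells, threshold_channel

    eligible = [r for r in qc_cells(rois) if r.clone or not clone_only]
    if not eligible:
        raise ValueError("no eligible cells (clone + QC pass) in cohort")
    rows = []
    for roi in eligible:
        mask = threshold_channel(scene, channel, roi, threshold=threshold,
                                 exclude_nucleus=exclude_nucleus)
        res = distribution_index(equal_area_partition(roi), mask, channel)
        if res.defined:
            rows.append({
                "cell_id": res.cell_id,
                "A_peri": res.area_perinuclear,
                "A_periph": res.area_peripheral,
                "A_total": res.area_total,
                "D": res.index,
            })
    return pd.DataFrame(rows)
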