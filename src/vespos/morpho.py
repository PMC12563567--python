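"""Structure size statistics and neighbor-cell intensity comparison."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ioutil import CellROI, TissueScene
from .segment import StructureSet


@dataclass
class SizeStats:
    """Per-cell structure-size summary and signal area fraction."""

    cell_id: int
    channel: str
    areas_um2: np.ndarray
    mean_um2: float
    median_um2: float
    count: int
    area_fraction: float  # signal px / cell px, in [0, 1]


@dataclass
class IntensityComparison:
    """Mean gray values of a clone cell and its neighboring control."""

    clone_id: int
    control_id: int
    channel: str
    clone_mean: float
    control_mean: float
    ratio: float  # clone / control


def size_stats(structures: StructureSet, roi: CellROI,
               pixel_size: float | None = None) -> SizeStats:
    """Summarize per-structure areas (µm²) and the cell's area fraction.

    When watershed splitting is wanted (endosome sizing), build the
    StructureSet with ``split=True``; raw connected components otherwise.
    """
    px = structures.pixel_size if pixel_size is None else pixel_size
    areas = structures.table["area_px"].to_numpy(float) * px ** 2
    signal_px = int(structures.foreground().sum())
    cell_px = int(roi.cell_mask.sum())
    return SizeStats(
        cell_id=structures.cell_id,
        channel=structures.channel,
        areas_um2=areas,
        mean_um2=float(areas.mean()) if areas.size else 0.0,
        median_um2=float(np.median(areas)) if areas.size else 0.0,
        count=int(areas.size),
        area_fraction=signal_px / cell_px,
    )


def neighbor_intensity_ratio(scene: TissueScene, clone_roi: CellROI,
                             control_roi: CellROI, channel: str,
                             background: float = 0.0) -> IntensityComparison:
    """Mean gray value of a clone cell vs a neighboring control cell.

    Means are taken over each full cell mask on the same channel; an optional
    constant ``background`` is subtracted from both before the ratio.
    """
    img = np.asarray(scene.channel(channel), float)
    for roi in (clone_roi, control_roi):
        if not roi.cell_mask.any():
            raise ValueError(f"cell {roi.cell_id}: empty mask")
    clone_mean = float(img[clone_roi.cell_mask].mean()) - background
    control_mean = float(img[control_roi.cell_mask].mean()) - background
    ratio = clone_mean / control_mean if control_mean != 0 else float("nan")
    return IntensityComparison(
        clone_id=clone_roi.cell_id,
        control_id=control_roi.cell_id,
        channel=channel,
        clone_mean=clone_mean,
        control_mean=control_mean,
        ratio=ratio,
    )


def size_table(stats_list) -> pd.DataFrame:
    """Long-form per-structure table from a list of SizeStats."""
    rows = []
    for s in stats_list:
        for a in s.areas_um2:
            rows.append({"cell_id": s.cell_id, "channel": s.channel,
                         "area_um2": a})
    return pd.DataFrame(rows, columns=["cell_id", "channel", "area_um2"])
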