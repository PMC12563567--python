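"""Colocalization: structure overlap, overlap removal, pixel Pearson.

Structure-level colocalization calls a structure in channel A double-positive
when it shares at least ``min_shared_px`` pixels (default 1) with any
structure in channel B; the table is computed symmetrically in both
directions.  Pixel-level colocalization is the product-moment (Pearson)
correlation of raw intensities over cytoplasmic pixels, with the per-pixel
intensity pairs exported for scatter plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ioutil import CellROI, TissueScene
from .segment import StructureSet


@dataclass
class ColocResult:
    cell_id: int
    channel_pair: tuple[str, str]
    overlap_table: pd.DataFrame | None = None
    double_positive_a: int = 0
    double_positive_b: int = 0
    single_positive_a: int = 0
    single_positive_b: int = 0
    overlap_fraction: float = float("nan")  # double-positive / total in A
    pearson_r: float = float("nan")
    pearson_defined: bool = False
    scatter: np.ndarray | None = None  # (n_px, 2) intensities A, B


def _overlap_pairs(a: StructureSet, b: StructureSet) -> pd.DataFrame:
    """Shared-pixel counts for every touching (label_a, label_b) pair."""
    both = (a.label_map > 0) & (b.label_map > 0)
    la, lb = a.label_map[both], b.label_map[both]
    if la.size == 0:
        return pd.DataFrame(columns=["label_a", "label_b", "shared_px"])
    pairs, counts = np.unique(np.column_stack([la, lb]), axis=0,
                              return_counts=True)
    return pd.DataFrame({"label_a": pairs[:, 0], "label_b": pairs[:, 1],
                         "shared_px": counts})


def structure_overlap(a: StructureSet, b: StructureSet,
                      min_shared_px: int = 1) -> ColocResult:
    """Count double- and single-positive structures between two channels."""
    if a.label_map.shape != b.label_map.shape:
        raise ValueError("structure sets must share one frame shape")
    pairs = _overlap_pairs(a, b)
    strong = pairs[pairs["shared_px"] >= min_shared_px]
    dp_a = strong["label_a"].nunique()
    dp_b = strong["label_b"].nunique()
    total_a, total_b = a.count, b.count
    return ColocResult(
        cell_id=a.cell_id,
        channel_pair=(a.channel, b.channel),
        overlap_table=strong.reset_index(drop=True),
        double_positive_a=int(dp_a),
        double_positive_b=int(dp_b),
        single_positive_a=int(total_a - dp_a),
        single_positive_b=int(total_b - dp_b),
        overlap_fraction=dp_a / total_a if total_a else float("nan"),
    )


def remove_overlapping(a: StructureSet, b: StructureSet,
                       min_shared_px: int = 1,
                       ) -> tuple[StructureSet, StructureSet]:
    """Delete double-positive structures from both sets.

    The surviving sets hold only non-colocalizing structures and are disjoint
    at the ``min_shared_px`` criterion; they are the intended input for
    distribution-index scoring of non-colocalizing structures.
    """
    res = structure_overlap(a, b, min_shared_px)
    drop_a = set(res.overlap_table["label_a"])
    drop_b = set(res.overlap_table["label_b"])
    return _drop_labels(a, drop_a), _drop_labels(b, drop_b)


def _drop_labels(s: StructureSet, labels: set) -> StructureSet:
    keep_map = s.label_map.copy()
    keep_map[np.isin(keep_map, list(labels))] = 0
    table = s.table[~s.table["label"].isin(labels)].reset_index(drop=True)
    return StructureSet(cell_id=s.cell_id, channel=s.channel,
                        label_map=keep_map, table=table,
                        pixel_size=s.pixel_size)


def pixel_pearson(scene: TissueScene, roi: CellROI,
                  channel_pair: tuple[str, str] = ("puncta_a", "puncta_b"),
                  subtract_background: bool = False,
                  background: float = 0.0) -> ColocResult:
    """Pearson correlation of two channels over cytoplasmic pixels.

    Zero variance in either channel yields a flagged-undefined result.  The
    per-pixel (A, B) intensity pairs are returned for scatter export.
    """
    ra, rb = channel_pair
    cyto = roi.cytoplasm_mask
    if cyto.sum() < 2:
        raise ValueError("need >= 2 cytoplasmic pixels for correlation")
    xa = np.asarray(scene.channel(ra), float)[cyto]
    xb = np.asarray(scene.channel(rb), float)[cyto]
    if subtract_background:
        xa = xa - background
        xb = xb - background
    scatter = np.column_stack([xa, xb])
    if xa.std() == 0 or xb.std() == 0:
        return ColocResult(roi.cell_id, channel_pair, pearson_r=float("nan"),
                           pearson_defined=False, scatter=scatter)
    r = float(stats.pearsonr(xa, xb).statistic)
    return ColocResult(roi.cell_id, channel_pair, pearson_r=r,
                       pearson_defined=True, scatter=scatter)


def mean_pearson(results) -> float:
    """Average R over cells, skipping undefined entries."""
    vals = [r.pearson_r for r in results if r.pearson_defined]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def export_scatter(result: ColocResult, path) -> None:
    ra, rb = result.channel_pair
    pd.DataFrame(result.scatter, columns=[ra, rb]).to_csv(path, index=False)
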