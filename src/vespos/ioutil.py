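"""Scene and ROI containers, stack projection, and TIFF/CSV I/O.

Conventions used throughout the package: images are 2D ``numpy`` arrays in
row-major order with 0-based pixel indices; a pixel belongs to a mask iff its
value is nonzero; areas are pixel counts, converted to µm² by multiplying with
``pixel_size ** 2``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

#: Channel roles understood by the pipeline.
CHANNEL_ROLES = ("clone", "nucleus", "puncta_a", "puncta_b")


@dataclass
class TissueScene:
    """A multi-channel 2D fluorescence scene.

    Parameters
    ----------
    channels
        Mapping from channel role (e.g. ``"nucleus"``, ``"puncta_a"``) to a 2D
        intensity array. All channels must share one shape.
    pixel_size
        Physical pixel size in µm/pixel.
    provenance
        Free-form origin note (source path or generator spec hash).
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("scene needs at least one channel")
        shapes = {role: ch.shape for role, ch in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise KeyError(
                f"channel role {role!r} not in scene (has {sorted(self.channels)})"
            ) from None


@dataclass
class CellROI:
    """One cell's region of interest: masks plus QC flags.

    Masks are full-frame boolean arrays. ``nucleus_mask`` must be contained in
    ``cell_mask`` and the cytoplasm (cell minus nucleus) must be non-empty.
    """

    cell_id: int
    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    clone: bool = False
    tissue_edge: bool = False
    nucleus_in_plane: bool = True

    def __post_init__(self) -> None:
        self.cell_mask = np.asarray(self.cell_mask, bool)
        self.nucleus_mask = np.asarray(self.nucleus_mask, bool)
        if self.cell_mask.shape != self.nucleus_mask.shape:
            raise ValueError("cell and nucleus masks must share one shape")
        if not self.cell_mask.any():
            raise ValueError(f"cell {self.cell_id}: empty cell mask")
        if (self.nucleus_mask & ~self.cell_mask).any():
            raise ValueError(f"cell {self.cell_id}: nucleus extends outside cell")
        if not self.cytoplasm_mask.any():
            raise ValueError(f"cell {self.cell_id}: empty cytoplasm")

    @property
    def cytoplasm_mask(self) -> np.ndarray:
        return self.cell_mask & ~self.nucleus_mask


def project_stack(planes, method: str = "max") -> np.ndarray:
    """Merge consecutive focal planes into a single image.

    Parameters
    ----------
    planes
        Sequence of equally shaped 2D arrays.
    method
        ``"max"`` for per-pixel maximum-intensity projection (default) or
        ``"mean"`` for the per-pixel arithmetic mean.
    """
    planes = [np.asarray(p) for p in planes]
    if not planes:
        raise ValueError("need at least one plane")
    ref = planes[0].shape
    for i, p in enumerate(planes):
        if p.shape != ref:
            raise ValueError(f"plane {i} has shape {p.shape}, expected {ref}")
    stack = np.stack(planes)
    if method == "max":
        return stack.max(axis=0)
    if method == "mean":
        return stack.mean(axis=0)
    raise ValueError(f"unknown projection method {method!r}")


# ---------------------------------------------------------------------------
# Scene / ROI persistence.  A scene is written as a multi-page TIFF (one page
# per channel) plus a JSON sidecar recording channel order and pixel size;
# ROIs as two 16-bit label TIFFs (cell and nucleus label maps) plus a CSV of
# per-cell flags.
# ---------------------------------------------------------------------------


def save_scene(scene: TissueScene, directory, stem: str = "scene") -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    roles = list(scene.channels)
    pages = np.stack([np.asarray(scene.channels[r]) for r in roles])
    tif = directory / f"{stem}.tif"
    tifffile.imwrite(tif, pages, photometric="minisblack")
    meta = {
        "channel_order": roles,
        "pixel_size_um": scene.pixel_size,
        "provenance": scene.provenance,
    }
    (directory / f"{stem}.json").write_text(json.dumps(meta, indent=2))
    return tif


def load_scene(path, channel_map=None, pixel_size: float | None = None) -> TissueScene:
    """Load a multi-page TIFF as a :class:`TissueScene`.

    ``channel_map`` maps page index -> role; when omitted, the JSON sidecar
    written by :func:`save_scene` supplies channel order and pixel size.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if channel_map is None:
        roles = meta.get("channel_order")
        if roles is None:
            raise ValueError("no channel_map given and no JSON sidecar found")
        channel_map = dict(enumerate(roles))
    if pixel_size is None:
        pixel_size = meta.get("pixel_size_um")
        if pixel_size is None:
            raise ValueError("pixel_size not given and not in sidecar")
    channels = {}
    for idx, role in sorted(channel_map.items()):
        if idx >= len(pages):
            raise ValueError(f"channel_map refers to page {idx}, file has {len(pages)}")
        channels[role] = pages[idx]
    return TissueScene(channels=channels, pixel_size=pixel_size,
                       provenance=str(path))


def require_roles(scene: TissueScene, roles) -> None:
    missing = [r for r in roles if r not in scene.channels]
    if missing:
        raise ValueError(f"scene is missing required channel role(s): {missing}")


def save_rois(rois, directory, stem: str = "rois") -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    shape = rois[0].cell_mask.shape
    cell_lab = np.zeros(shape, np.uint16)
    nuc_lab = np.zeros(shape, np.uint16)
    rows = []
    for roi in rois:
        cell_lab[roi.cell_mask] = roi.cell_id
        nuc_lab[roi.nucleus_mask] = roi.cell_id
        rows.append({
            "cell_id": roi.cell_id,
            "clone": roi.clone,
            "tissue_edge": roi.tissue_edge,
            "nucleus_in_plane": roi.nucleus_in_plane,
        })
    tifffile.imwrite(directory / f"{stem}_cells.tif", cell_lab)
    tifffile.imwrite(directory / f"{stem}_nuclei.tif", nuc_lab)
    pd.DataFrame(rows).to_csv(directory / f"{stem}_flags.csv", index=False)
    return directory / f"{stem}_cells.tif"


def load_rois(directory, stem: str = "rois") -> list[CellROI]:
    directory = Path(directory)
    cell_lab = tifffile.imread(directory / f"{stem}_cells.tif")
    nuc_lab = tifffile.imread(directory / f"{stem}_nuclei.tif")
    flags = pd.read_csv(directory / f"{stem}_flags.csv").set_index("cell_id")
    rois = []
    for cid in sorted(flags.index):
        row = flags.loc[cid]
        rois.append(CellROI(
            cell_id=int(cid),
            cell_mask=cell_lab == cid,
            nucleus_mask=nuc_lab == cid,
            clone=bool(row["clone"]),
            tissue_edge=bool(row["tissue_edge"]),
            nucleus_in_plane=bool(row["nucleus_in_plane"]),
        ))
    return rois


def write_results(tables: dict[str, pd.DataFrame], directory) -> list[Path]:
    """Write each named table as ``<name>.csv`` under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for name, df in tables.items():
        p = directory / f"{name}.csv"
        df.to_csv(p, index=False)
        out.append(p)
    return out
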