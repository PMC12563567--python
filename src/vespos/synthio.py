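"""Synthetic mosaic-tissue and cultured-cell scene generation.

Generates multi-channel 2D fluorescence scenes with exact ground truth,
emulating a mosaic fat-body field: space-filling polygonal cells (Voronoi
tessellation of jittered-grid seeds, eroded by one pixel to create
boundaries), one round nucleus per cell, a clone marker channel labeling a
subset of cells, and puncta channels whose diffraction-limited spots
(isotropic 2D Gaussians truncated at 3σ, σ = radius/2) are placed by a
configurable spatial law:

``perinuclear`` / ``peripheral``
    each spot center is drawn inside the cell's perinuclear equal-area
    domain with probability ``f`` (else the peripheral domain), using the
    same partition the scorer computes — generator truth and scorer
    definition coincide by construction;
``uniform``
    uniform over the cytoplasm;
``ectopic_focus``
    a Gaussian cluster around a point offset from the nucleus.

Noise (constant background, optional Poisson stage, additive Gaussian) is
applied last.  Identical spec + seed yield bit-identical scenes.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .ioutil import CellROI, TissueScene
from .posindex import equal_area_partition

MODES = ("perinuclear", "peripheral", "uniform", "ectopic_focus")

#: intensity of the rendered clone-marker / nuclear-stain fills
CLONE_LEVEL = 120.0
NUCLEUS_LEVEL = 200.0


@dataclass
class SceneSpec:
    """Geometry, labeling and noise parameters of a synthetic scene.

    Defaults emulate a 40x field of fat-body-like tissue: 512x512 px at
    0.16 µm/px (~82 µm field), 9 large polygonal cells (~27 µm across, the
    scale of fat-body cells), a third of them clone-positive, nuclei at 0.35
    of the cell radius, constant background 10 with Gaussian read noise of
    sd 2.
    """

    shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.16
    n_cells: int = 9
    clone_fraction: float = 0.3
    nucleus_ratio: float = 0.35
    seed: int = 0
    background: float = 10.0
    noise_sd: float = 2.0
    poisson_noise: bool = False
    tissue_edge: bool = False
    edge_margin_px: int = 6

    def validate(self) -> None:
        if not 0.0 <= self.clone_fraction <= 1.0:
            raise ValueError("clone_fraction must lie in [0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if not 0.0 < self.nucleus_ratio < 1.0:
            raise ValueError("nucleus_ratio must lie in (0, 1)")

    def digest(self) -> str:
        return hashlib.sha1(repr(asdict(self)).encode()).hexdigest()[:12]


@dataclass
class PunctaSpec:
    """Placement and rendering law for one puncta channel.

    ``f`` is the perinuclear-fraction: the probability that a spot center is
    drawn in the perinuclear equal-area domain (modes perinuclear /
    peripheral; ``None`` resolves to 1 or 0 by mode).  Spot radii are drawn
    from a normal distribution (µm, clipped to be positive); the default
    0.25 µm radius matches diffraction-limited puncta.  ``diffuse_level``
    adds a constant cell-filling component on top of the puncta (an
    expression-level term for mean-gray-value comparisons).  ``clone_scale``
    multiplies both peak and diffuse intensity in clone-positive cells.
    """

    role: str = "puncta_a"
    mode: str = "perinuclear"
    f: float | None = None
    n_spots: int = 50
    radius_um: float = 0.25
    radius_sd_um: float = 0.05
    peak: float = 150.0
    focus_offset_um: float = 5.0
    focus_spread_um: float = 1.0
    diffuse_level: float = 0.0
    clone_scale: float = 1.0
    edge_bias: bool = False

    def resolved_f(self) -> float:
        if self.f is not None:
            return self.f
        return {"perinuclear": 1.0, "peripheral": 0.0}.get(self.mode, 0.5)

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not 0.0 <= self.resolved_f() <= 1.0:
            raise ValueError("perinuclear-fraction f must lie in [0, 1]")
        if self.n_spots < 0:
            raise ValueError("n_spots must be >= 0")
        if self.radius_um <= 0:
            raise ValueError("spot radius must be > 0")


GROUND_TRUTH_COLUMNS = [
    "spot_id", "cell_id", "channel", "row", "col", "radius_px", "radius_um",
    "peak", "mode", "true_f", "placement_domain", "pair_id",
]


class GroundTruth:
    """Per-spot ground truth: one row per rendered spot.

    ``table`` columns: spot id, cell id, channel role, center (row, col in
    px), radius (px and µm), rendered peak, spatial mode, true perinuclear
    fraction f, the domain the center was placed in at placement time, and a
    cross-channel ``pair_id`` (non-null for co-centered spot pairs).
    """

    def __init__(self, rows=None):
        self.table = pd.DataFrame(rows or [], columns=GROUND_TRUTH_COLUMNS)

    def for_channel(self, role: str) -> pd.DataFrame:
        return self.table[self.table["channel"] == role]

    def paired_count(self, role: str = "puncta_a") -> int:
        sub = self.for_channel(role)
        return int(sub["pair_id"].notna().sum())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _cell_seeds(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Jittered-grid seed points: regular, space-filling polygonal cells."""
    h, w = spec.shape
    side = math.ceil(math.sqrt(spec.n_cells))
    ys = (np.arange(side) + 0.5) * h / side
    xs = (np.arange(side) + 0.5) * w / side
    grid = np.array([(y, x) for y in ys for x in xs])
    jitter = rng.uniform(-0.3, 0.3, grid.shape) * [h / side, w / side]
    pts = grid + jitter
    order = rng.permutation(len(pts))[:spec.n_cells]
    return pts[order]


def _tessellate(spec: SceneSpec, rng: np.random.Generator):
    """Voronoi label map (1..n) and per-cell masks eroded by 1 px."""
    h, w = spec.shape
    seeds = _cell_seeds(spec, rng)
    rr, cc = np.mgrid[0:h, 0:w]
    _, idx = cKDTree(seeds).query(np.column_stack([rr.ravel(), cc.ravel()]))
    labels = (idx + 1).reshape(h, w).astype(np.int32)
    if spec.tissue_edge and spec.edge_margin_px > 0:
        labels[:, w - spec.edge_margin_px:] = 0  # free hemolymph-facing margin
    masks = {}
    for i in range(1, len(seeds) + 1):
        m = ndimage.binary_erosion(labels == i)
        if m.sum() >= 64:  # drop slivers the margin may create
            masks[i] = m
    return labels, masks


def _nucleus_for_cell(mask: np.ndarray, ratio: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Round nucleus fully inside the cell, centered near its deepest point."""
    edt = ndimage.distance_transform_edt(mask)
    r0, c0 = np.unravel_index(np.argmax(edt), edt.shape)
    depth = edt[r0, c0]
    r_eff = math.sqrt(mask.sum() / math.pi)
    radius = min(ratio * r_eff, 0.75 * depth)
    radius = max(radius, 2.0)
    # small deterministic jitter keeps nuclei off exact cell centers
    dr, dc = rng.uniform(-0.15, 0.15, 2) * depth
    r0, c0 = r0 + dr, c0 + dc
    h, w = mask.shape
    rr, cc = np.ogrid[0:h, 0:w]
    nuc = ((rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2) & mask
    # guarantee cytoplasm remains
    if nuc.sum() >= mask.sum() - 8:
        raise ValueError("nucleus_ratio leaves no cytoplasm; reduce it")
    return nuc


# ---------------------------------------------------------------------------
# spot placement and rendering
# ---------------------------------------------------------------------------

def _render_spot(img: np.ndarray, row: float, col: float, sigma: float,
                 peak: float, clip_mask: np.ndarray | None = None) -> None:
    """Add an isotropic Gaussian spot truncated at 3σ, in place."""
    h, w = img.shape
    ext = int(math.ceil(3 * sigma))
    r0, r1 = max(0, int(row) - ext), min(h, int(row) + ext + 1)
    c0, c1 = max(0, int(col) - ext), min(w, int(col) + ext + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d2 = (rr - row) ** 2 + (cc - col) ** 2
    patch = peak * np.exp(-d2 / (2 * sigma ** 2))
    patch[d2 > (3 * sigma) ** 2] = 0.0
    if clip_mask is not None:
        patch = patch * clip_mask[r0:r1, c0:c1]
    img[r0:r1, c0:c1] += patch


def _sample_in_mask(mask: np.ndarray, n: int, rng: np.random.Generator,
                    weights: np.ndarray | None = None) -> np.ndarray:
    """Uniform (or weighted) pixel draws inside a mask, with subpixel jitter."""
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        raise ValueError("cannot place spots: empty placement domain")
    p = None
    if weights is not None:
        wv = weights[rr, cc].astype(float)
        p = wv / wv.sum() if wv.sum() > 0 else None
    idx = rng.choice(rr.size, size=n, p=p)
    pts = np.column_stack([rr[idx], cc[idx]]).astype(float)
    pts += rng.uniform(-0.5, 0.5, pts.shape)
    return pts


def _place_spots(spec: PunctaSpec, roi: CellROI, partition,
                 rng: np.random.Generator, pixel_size: float,
                 edge_weight: np.ndarray | None):
    """Draw spot centers for one cell; return (centers, placement domains)."""
    n = spec.n_spots
    cyto = roi.cytoplasm_mask
    peri, periph = partition.perinuclear_mask, partition.peripheral_mask
    if spec.mode in ("perinuclear", "peripheral"):
        f = spec.resolved_f()
        in_peri = rng.random(n) < f
        centers = np.empty((n, 2))
        w = edge_weight if (spec.edge_bias and spec.mode == "peripheral") else None
        if in_peri.any():
            centers[in_peri] = _sample_in_mask(peri, int(in_peri.sum()), rng)
        if (~in_peri).any():
            centers[~in_peri] = _sample_in_mask(periph, int((~in_peri).sum()),
                                                rng, weights=w)
    elif spec.mode == "uniform":
        centers = _sample_in_mask(cyto, n, rng)
    elif spec.mode == "ectopic_focus":
        centers = _ectopic_centers(spec, roi, rng, pixel_size, n)
    else:  # pragma: no cover - validated earlier
        raise ValueError(spec.mode)
    # record the domain each center landed in (post-jitter, nearest pixel)
    ri = np.clip(np.rint(centers[:, 0]).astype(int), 0, cyto.shape[0] - 1)
    ci = np.clip(np.rint(centers[:, 1]).astype(int), 0, cyto.shape[1] - 1)
    domains = np.where(peri[ri, ci], "perinuclear",
                       np.where(periph[ri, ci], "peripheral", "outside"))
    return centers, domains


def _ectopic_centers(spec, roi, rng, pixel_size, n):
    """Gaussian cluster around a focus offset from the nucleus boundary."""
    cyto = roi.cytoplasm_mask
    nuc_edt = ndimage.distance_transform_edt(~roi.nucleus_mask)
    # aim the focus toward the cytoplasmic point deepest from the nucleus;
    # walk the ray until the requested nucleus-boundary offset is reached
    # (or stop at the deepest reachable point inside the cell)
    far = np.array(np.unravel_index(np.argmax(np.where(cyto, nuc_edt, -1)),
                                    cyto.shape), float)
    nr, nc = ndimage.center_of_mass(roi.nucleus_mask)
    vec = far - [nr, nc]
    vec /= max(np.linalg.norm(vec), 1e-9)
    offset_px = spec.focus_offset_um / pixel_size
    focus = far
    for t in np.arange(0.0, np.linalg.norm(far - [nr, nc]) + 1.0, 1.0):
        p = np.array([nr, nc]) + vec * t
        ri, ci = int(round(p[0])), int(round(p[1]))
        if not (0 <= ri < cyto.shape[0] and 0 <= ci < cyto.shape[1]):
            break
        if cyto[ri, ci] and nuc_edt[ri, ci] >= offset_px:
            focus = p
            break
    spread_px = spec.focus_spread_um / pixel_size
    centers = np.empty((n, 2))
    placed = 0
    while placed < n:
        cand = rng.normal(focus, spread_px, size=(4 * (n - placed), 2))
        ri = np.rint(cand[:, 0]).astype(int)
        ci = np.rint(cand[:, 1]).astype(int)
        ok = ((ri >= 0) & (ri < cyto.shape[0]) & (ci >= 0) & (ci < cyto.shape[1]))
        ok[ok] &= cyto[ri[ok], ci[ok]]
        take = min(int(ok.sum()), n - placed)
        centers[placed:placed + take] = cand[ok][:take]
        placed += take
        spread_px *= 1.3  # widen if the focus hugs a boundary
    return centers


def _check_spot_fits(spec: PunctaSpec, masks, pixel_size: float) -> None:
    min_r_eff = min(math.sqrt(m.sum() / math.pi) for m in masks.values())
    if spec.radius_um / pixel_size >= min_r_eff:
        raise ValueError(
            f"spot radius {spec.radius_um} µm ({spec.radius_um / pixel_size:.1f} px) "
            f"is no smaller than the smallest cell (r_eff {min_r_eff:.1f} px); "
            "reduce radius_um or enlarge cells"
        )


def _apply_noise(img: np.ndarray, spec: SceneSpec,
                 rng: np.random.Generator) -> np.ndarray:
    out = img + spec.background
    if spec.poisson_noise:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if spec.noise_sd > 0:
        out = out + rng.normal(0.0, spec.noise_sd, out.shape)
    return np.clip(out, 0, None).astype(np.float32)


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def generate_scene(spec: SceneSpec, puncta: list[PunctaSpec],
                   ) -> tuple[TissueScene, list[CellROI], GroundTruth]:
    """Render a mosaic-tissue scene with exact per-spot ground truth.

    Returns the multi-channel scene (clone + nucleus channels plus one
    channel per :class:`PunctaSpec`), the per-cell ROIs (clone status and
    tissue-edge contact flagged), and the :class:`GroundTruth` table.
    """
    spec.validate()
    for ps in puncta:
        ps.validate()
    rng = np.random.default_rng(spec.seed)

    labels, masks = _tessellate(spec, rng)
    for ps in puncta:
        _check_spot_fits(ps, masks, spec.pixel_size)

    h, w = spec.shape
    cell_ids = sorted(masks)
    n_clone = int(round(spec.clone_fraction * len(cell_ids)))
    clone_ids = set(np.array(cell_ids)[rng.permutation(len(cell_ids))[:n_clone]])

    border = np.zeros((h, w), bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    if spec.tissue_edge and spec.edge_margin_px > 0:
        border[:, w - spec.edge_margin_px - 2:] = True

    rois, partitions = [], {}
    for cid in cell_ids:
        mask = masks[cid]
        nuc = _nucleus_for_cell(mask, spec.nucleus_ratio, rng)
        roi = CellROI(cell_id=cid, cell_mask=mask, nucleus_mask=nuc,
                      clone=cid in clone_ids,
                      tissue_edge=bool((mask & border).any()))
        rois.append(roi)
        partitions[cid] = equal_area_partition(roi)

    channels: dict[str, np.ndarray] = {
        "clone": np.zeros((h, w)),
        "nucleus": np.zeros((h, w)),
    }
    for roi in rois:
        if roi.clone:
            channels["clone"][roi.cell_mask] = CLONE_LEVEL
        channels["nucleus"][roi.nucleus_mask] = NUCLEUS_LEVEL

    # distance-to-margin weight for optional edge-biased peripheral placement
    edge_weight = None
    if any(ps.edge_bias for ps in puncta):
        margin = np.zeros((h, w), bool)
        margin[:, w - 1] = True
        dist_to_margin = ndimage.distance_transform_edt(~margin)
        edge_weight = 1.0 / (1.0 + dist_to_margin)

    gt_rows = []
    spot_id = 0
    for ps in puncta:
        img = channels.setdefault(ps.role, np.zeros((h, w)))
        for roi in rois:
            centers, domains = _place_spots(ps, roi, partitions[roi.cell_id],
                                            rng, spec.pixel_size, edge_weight)
            radii_um = np.clip(
                rng.normal(ps.radius_um, ps.radius_sd_um, len(centers)),
                0.25 * ps.radius_um, None)
            scale = ps.clone_scale if roi.clone else 1.0
            peak = ps.peak * scale
            if ps.diffuse_level:
                img[roi.cell_mask] += ps.diffuse_level * scale
            for (r, c), rad_um, dom in zip(centers, radii_um, domains):
                rad_px = rad_um / spec.pixel_size
                _render_spot(img, r, c, sigma=rad_px / 2.0, peak=peak,
                             clip_mask=roi.cell_mask)
                gt_rows.append({
                    "spot_id": spot_id, "cell_id": roi.cell_id,
                    "channel": ps.role, "row": r, "col": c,
                    "radius_px": rad_px, "radius_um": rad_um, "peak": peak,
                    "mode": ps.mode, "true_f": ps.resolved_f(),
                    "placement_domain": dom, "pair_id": None,
                })
                spot_id += 1

    noisy = {role: _apply_noise(img, spec, rng) for role, img in channels.items()}
    scene = TissueScene(channels=noisy, pixel_size=spec.pixel_size,
                        provenance=f"synthio:{spec.digest()}")
    return scene, rois, GroundTruth(gt_rows)


def generate_cultured_cell(spec: SceneSpec, coloc_fraction: float,
                           puncta: tuple[PunctaSpec, PunctaSpec],
                           min_separation_px: float | None = None,
                           ) -> tuple[TissueScene, CellROI, GroundTruth]:
    """Render a single round cultured cell with two puncta channels.

    A deterministic ``round(coloc_fraction * n_A)`` of channel-A spots are
    co-centered with a channel-B spot; the pairing is recorded via
    ``pair_id``.  All spot centers keep a minimum mutual separation (default
    6x the mean spot radius) so structures stay well separated for
    overlap-based colocalization truth.
    """
    spec.validate()
    spec_a, spec_b = puncta
    spec_a.validate()
    spec_b.validate()
    if not 0.0 <= coloc_fraction <= 1.0:
        raise ValueError("coloc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)

    h, w = spec.shape
    rr, cc = np.ogrid[0:h, 0:w]
    cell_r = 0.42 * min(h, w)
    cell = ((rr - h / 2) ** 2 + (cc - w / 2) ** 2) <= cell_r ** 2
    nuc_r = spec.nucleus_ratio * cell_r
    nuc = ((rr - h / 2) ** 2 + (cc - w / 2) ** 2) <= nuc_r ** 2
    roi = CellROI(cell_id=1, cell_mask=cell, nucleus_mask=nuc, clone=True)
    for ps in (spec_a, spec_b):
        if ps.radius_um / spec.pixel_size >= cell_r:
            raise ValueError("spot radius is no smaller than the cell")

    if min_separation_px is None:
        min_separation_px = 6.0 * max(spec_a.radius_um, spec_b.radius_um) / spec.pixel_size

    n_a, n_b = spec_a.n_spots, spec_b.n_spots
    n_paired = int(round(coloc_fraction * n_a))
    n_total = n_a + (n_b - n_paired)
    centers = _separated_centers(roi.cytoplasm_mask, n_total,
                                 min_separation_px, rng)
    a_centers = centers[:n_a]
    b_centers = np.vstack([a_centers[:n_paired], centers[n_a:]])

    part = equal_area_partition(roi)
    channels = {"nucleus": np.zeros((h, w))}
    channels["nucleus"][nuc] = NUCLEUS_LEVEL
    gt_rows = []
    spot_id = 0
    for ps, pts, pair_ids in (
        (spec_a, a_centers, [i if i < n_paired else None for i in range(n_a)]),
        (spec_b, b_centers, [i for i in range(n_paired)] + [None] * (n_b - n_paired)),
    ):
        img = channels.setdefault(ps.role, np.zeros((h, w)))
        radii_um = np.clip(rng.normal(ps.radius_um, ps.radius_sd_um, len(pts)),
                           0.25 * ps.radius_um, None)
        ri = np.clip(np.rint(pts[:, 0]).astype(int), 0, h - 1)
        ci = np.clip(np.rint(pts[:, 1]).astype(int), 0, w - 1)
        doms = np.where(part.perinuclear_mask[ri, ci], "perinuclear",
                        np.where(part.peripheral_mask[ri, ci], "peripheral",
                                 "outside"))
        for (r, c), rad_um, dom, pid in zip(pts, radii_um, doms, pair_ids):
            rad_px = rad_um / spec.pixel_size
            _render_spot(img, r, c, sigma=rad_px / 2.0, peak=ps.peak,
                         clip_mask=cell)
            gt_rows.append({
                "spot_id": spot_id, "cell_id": 1, "channel": ps.role,
                "row": r, "col": c, "radius_px": rad_px, "radius_um": rad_um,
                "peak": ps.peak, "mode": ps.mode, "true_f": ps.resolved_f(),
                "placement_domain": dom, "pair_id": pid,
            })
            spot_id += 1

    noisy = {role: _apply_noise(img, spec, rng) for role, img in channels.items()}
    scene = TissueScene(channels=noisy, pixel_size=spec.pixel_size,
                        provenance=f"synthio:cultured:{spec.digest()}")
    return scene, roi, GroundTruth(gt_rows)


def _separated_centers(mask, n, min_sep, rng, max_tries=20000):
    """Dart-throwing placement with a minimum mutual distance."""
    rr, cc = np.nonzero(mask)
    pts = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n} spots at separation {min_sep:.1f} px; "
                "reduce n_spots or the separation")
        i = rng.integers(rr.size)
        cand = np.array([rr[i], cc[i]], float) + rng.uniform(-0.5, 0.5, 2)
        if pts:
            d = np.linalg.norm(np.array(pts) - cand, axis=1)
            if (d < min_sep).any():
                continue
        pts.append(cand)
    return np.array(pts)
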