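# Methods

## The distribution index and the equal-area partition

Each cell is reduced to a binary cell mask and a binary nucleus mask; the
cytoplasm is their difference. Every cytoplasmic pixel is assigned its
Euclidean distance to the nearest nucleus pixel (distance to the nucleus
*mask*, not to its centroid: nuclei in fat-body-type cells are large, and
the perinuclear compartment of interest hugs the nuclear envelope, so a
centroid reference would distort the split for off-center or elongated
nuclei). Pixels are ranked by this distance; the split distance `d*` is the
distance at the half-area rank. Pixels strictly below `d*` form the
perinuclear domain, strictly above the peripheral domain, and pixels tied
exactly at `d*` are assigned in raster (row-major) order to the perinuclear
domain until it holds `⌈cytoplasm/2⌉` pixels. This makes the two domain
areas equal to within one pixel for any cell shape, and the whole
construction deterministic: repeated runs produce bit-identical partitions.

"Equal" is enforced as equal *pixel area* per cell (a width-equal annulus
would break the ±1 normalization for irregular cells: the index could then
not reach its extremes). Signal is measured as thresholded **area**, not
integrated intensity, and is clipped to the cytoplasm before counting, so
nucleus-overlapping signal never contributes. With areas `A_peri`,
`A_periph`, `A_total`:

```
D = (A_peri − A_periph) / A_total
```

`D` is undefined (flagged, not raised) for cells with no above-threshold
signal; cohort tables exclude and count such cells. For a disk cell of
radius `R` with a concentric nucleus of radius `r`, the continuum split
radius is `sqrt((R² + r²)/2)`, which the discrete partition reproduces
within one pixel — the standard analytic check.

## Segmentation

The study protocol this emulates sets one signal threshold per channel per
experiment batch; `threshold_channel` therefore takes a single fixed value
(an Otsu auto mode over in-cell pixels is provided for synthetic runs where
no human sets the bar). Structures are 8-connected components; components
under 4 px (default) are discarded as single-pixel noise. Touching vesicles
are split by marker-based watershed on the Euclidean distance transform:
markers are regional maxima of the σ = 1 px Gaussian-smoothed transform,
merged when closer than 2 px; watershed lines are removed from the
foreground, so labeled area never exceeds the input mask. Per-structure
sizing uses post-watershed labels when splitting is enabled (the
endosome-sizing path) and raw components otherwise. Cell-level QC keeps
only cells with a non-empty nucleus mask flagged as lying in the focal
plane, since a cell whose nucleus is out of plane has no meaningful
perinuclear reference.

## Localization phenotype classifier

The ectopic-focus call is an automated surrogate for what is normally a
manual count. Structure centroids are clustered by single linkage at a
configurable linking radius (default 3 µm); a cell is called
`ectopic_focus` when the largest cluster carries ≥ 50% of total structure
area *and* its area-weighted centroid lies farther than a configurable
offset from the nucleus boundary (distance evaluated on the
nucleus-distance transform). Otherwise the index decides: perinuclear for
`D ≥ 0.5`, peripheral for `D ≤ −0.5`, dispersed between. All four
thresholds are configurable defaults — the corresponding manual calls were
made by eye, so there is no ground value to match; tests pair the
classifier with generator settings whose geometry places the focus well
beyond the distance threshold.

## Statistical protocol

Every group is tested with the D'Agostino & Pearson omnibus normality test.
If all groups pass at α = 0.05, comparison is by unpaired two-tailed t-test
(two groups) or one-way ANOVA with Dunnett's vs-control procedure
(`scipy.stats.dunnett`). If any group fails — or is smaller than 8, the
omnibus test's minimum, in which case the group is flagged — the
nonparametric branch runs: Mann-Whitney U, or Kruskal-Wallis with Dunn's
vs-control comparisons. Dunn's test is implemented in-package (pooled-rank
z statistic with the standard tie correction `Σ(t³−t)/(12(N−1))`,
two-sided normal p multiplied by the number of vs-control comparisons,
i.e. Bonferroni) and is identified in run logs as
`dunn-z-bonferroni(vespos)`; which p-adjustment a given commercial package
applies varies, so the variant is named explicitly. P-values map to
asterisks (`<0.0001 ****`, `0.0001–0.001 ***`, `0.001–0.01 **`,
`0.01–0.05 *`, else ns); values falling exactly on a bin boundary take the
less-significant bin, the conservative reading of the interval notation.

## The synthetic-scene generator

`synthio` emulates a mosaic fat-body field. Geometry: cell seed points on a
jittered grid (±30% of the pitch), Voronoi assignment of pixels to the
nearest seed, 1 px erosion to create boundaries — polygonal, space-filling
cells like the real tissue. Defaults: 512×512 px at 0.16 µm/px (a 40×-class
field of ~82 µm), 9 cells (~27 µm across, the scale of fat-body cells),
nuclei at 0.35 of the effective cell radius placed at the cell's deepest
interior point with a small jitter, 30% clone fraction. Noise: constant
background 10, optional Poisson stage, additive Gaussian (sd 2) last.
Spots are isotropic 2D Gaussians truncated at 3σ with σ = radius/2
(diffraction-limited puncta; default radius 0.25 µm), clipped to the cell
mask. An optional per-cell diffuse component models expression-level
differences for mean-gray-value comparisons (`clone_scale` multiplies both
diffuse and peak intensity in clone cells).

Spot placement uses the *same* equal-area partition the scorer computes, so
generator truth and scorer definition coincide by construction: in
perinuclear/peripheral modes each center is drawn in the perinuclear domain
with probability `f`, making `E[D] = 2f − 1` exact at the center level.
The measured index deviates slightly because a spot centered within a
footprint-radius of the domain boundary spreads thresholded area across it;
the effect scales as (footprint radius)/(cell radius) and is ~0.02 at the
default geometry, inside the ±0.05 recovery tolerance the tests enforce.
The ectopic mode walks a ray from the nucleus toward the cell's deepest
point and centers a Gaussian cluster where the nucleus-boundary distance
reaches the requested offset — the offset is measured from the nucleus
*boundary*, so classifier distance thresholds remain meaningful for large
nuclei.

What the generator does **not** emulate: 3D structure (scenes are single
planes; stack projection is provided separately and defaults to maximum
intensity, with mean as the alternative since the acquisition description
leaves the merge operator open), optical PSF beyond the Gaussian spot,
photobleaching, spatially varying background, and real cell-size
statistics (no published geometry distribution exists for calibration, so
cell-scale defaults are stated choices, not fits). Passing tests therefore
demonstrate correctness of the *measurement* pipeline under a controlled
imaging model, not robustness to every real-microscopy artifact.

## Numerical choices and degenerate inputs

- Ties at `d*`: raster-order assignment (reproducibility; keeps the ≤1 px
  area-difference invariant).
- Distance maps: `scipy.ndimage.distance_transform_edt` throughout.
- Structure overlap: any `min_shared_px ≥ 1` shared pixels (default 1)
  makes a pair double-positive; after `remove_overlapping`, a re-run of
  `structure_overlap` reports zero double-positives by construction.
- Pearson `R` is computed on raw intensities over cytoplasmic pixels,
  without thresholding; zero variance in either channel flags the result
  undefined instead of raising.
- Empty signal, empty structure sets, and cells failing QC are flagged or
  excluded, never silently scored.
- Problem sizes in tests (cohorts of 9–10 cells, 50–200 spots/cell,
  640 px fields for 10-cell cohorts, 1000-rep null simulations) mirror the
  per-genotype sample sizes of the experimental design (typically n = 10
  cells) while keeping the full suite fast.

## Known limitations

- The classifier thresholds encode one reasonable operating point; they are
  not learned and will need adjustment for organelles with different
  clustering scales.
- Dunn p-values use the normal approximation; exact small-sample behavior
  is not implemented.
- The tissue-edge flag is reported but no special peripheral-domain
  handling is applied for cells facing the free margin; edge-biased
  placement exists in the generator (off by default) to study exactly this.
- 2D only: indices from projected stacks inherit whatever positioning
  information survives projection.
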