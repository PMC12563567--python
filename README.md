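# vespos

Quantification of organelle positioning in fluorescence micrographs of
mosaic tissue — built for the kind of experiment where a genetically marked
(clone) cell expressing an RNAi sits next to unmodified neighbors, and the
question is *where* vesicles (autophagosomes, lysosomes, endosomes) sit
inside each cell: hugging the nucleus, pushed to the cell edge, dispersed,
or clustered at an ectopic microtubule-organizing focus.

## The statistic

For each cell the cytoplasm is split into a **perinuclear** and a
**peripheral** domain of equal pixel area, by Euclidean distance to the
nucleus mask. With the thresholded signal areas `A_peri`, `A_periph` and
`A_total = A_peri + A_periph`, the distribution index is

```
D = (A_peri − A_periph) / A_total ∈ [−1, +1]
```

`D = +1` perfectly perinuclear, `D = 0` evenly dispersed, `D = −1`
perfectly peripheral. The equal-area split makes `D` comparable across
cells of different size and shape.

Around this core the package provides puncta segmentation (fixed or Otsu
threshold, 8-connected labeling, watershed splitting of touching vesicles),
structure-level and pixel-level colocalization (overlap counts, removal of
double-positive structures, Pearson `R` with scatter export), per-structure
size and area-fraction metrics, neighbor-cell mean-intensity ratios, a
localization-phenotype classifier (perinuclear / dispersed / peripheral /
ectopic focus), and a normality-gated statistical comparison protocol
(D'Agostino–Pearson gate, then t-test / ANOVA + Dunnett or Mann-Whitney /
Kruskal-Wallis + Dunn, with asterisk categories).

Because positioning papers rarely ship raw images, the `synthio` module
generates complete mosaic-tissue scenes with exact ground truth: polygonal
space-filling cells, one nucleus each, a clone-marker channel, and puncta
channels placed by a configurable spatial law whose perinuclear fraction
`f` makes the expected index `E[D] = 2f − 1` known in advance.

## Worked example

```python
import numpy as np
from vespos import (SceneSpec, PunctaSpec, generate_scene,
                    equal_area_partition, threshold_channel,
                    distribution_index)

spec = SceneSpec(seed=1, clone_fraction=1.0)
puncta = [PunctaSpec(mode="perinuclear", f=0.9, n_spots=100)]
scene, rois, truth = generate_scene(spec, puncta)

for roi in rois[:3]:
    part = equal_area_partition(roi)
    signal = threshold_channel(scene, "puncta_a", roi, threshold=40)
    res = distribution_index(part, signal)
    print(f"cell {roi.cell_id}: A_peri={res.area_perinuclear} "
          f"A_periph={res.area_peripheral} D={res.index:+.3f}")
```

prints

```
cell 1: A_peri=628 A_periph=47 D=+0.861
cell 2: A_peri=606 A_periph=58 D=+0.825
cell 3: A_peri=572 A_periph=96 D=+0.713
```

Spots were placed with perinuclear fraction `f = 0.9`, so the expected
index is `2f − 1 = 0.8`; the per-cell values scatter around it with
spot-count sampling noise, and most of each cell's signal area indeed falls
in the perinuclear half.

The same pipeline is scriptable from the shell:

```
vespos simulate scene.yaml out/ --seed 4
vespos index out/scene.tif out/ --channel puncta_a --threshold 40 --out cells.csv
vespos compare cells_grouped.csv --metric D --control luciferase
```

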