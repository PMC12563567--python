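import math

import numpy as np
import pandas as pd
import pytest

from vespos.posindex import (ClassifierThresholds, DomainPartition,
                             classify_localization, cohort_index_table,
                             distribution_index, equal_area_partition)
from vespos.segment import StructureSet, label_structures, threshold_channel
from vespos.synthio import PunctaSpec, SceneSpec, generate_scene

from conftest import make_disk_roi


class TestEqualAreaPartition:
    def test_disk_split_radius_matches_annulus_closed_form(self, disk_roi):
        """For a disk cell the equal-area split radius is sqrt((R²+r²)/2)."""
        part = equal_area_partition(disk_roi)
        split_radius = 20 + part.split_distance  # distance is to nucleus mask
        assert split_radius == pytest.approx(math.sqrt((100**2 + 20**2) / 2),
                                             abs=1.0)

    def test_domains_tile_cytoplasm(self, disk_roi):
        part = equal_area_partition(disk_roi)
        cyto = disk_roi.cytoplasm_mask
        assert np.array_equal(part.perinuclear_mask | part.peripheral_mask, cyto)
        assert not (part.perinuclear_mask & part.peripheral_mask).any()

    def test_area_difference_at_most_one_pixel(self, perinuclear_scene):
        _, rois, _ = perinuclear_scene
        for roi in rois:
            part = equal_area_partition(roi)
            assert part.area_difference <= 1

    def test_distance_ordering_up_to_ties(self, disk_roi):
        """Every perinuclear pixel is at most as far from the nucleus as
        every peripheral pixel."""
        from scipy import ndimage
        part = equal_area_partition(disk_roi)
        dist = ndimage.distance_transform_edt(~disk_roi.nucleus_mask)
        assert dist[part.perinuclear_mask].max() <= dist[part.peripheral_mask].min()

    def test_deterministic_across_repeated_runs(self, uniform_scene):
        _, rois, _ = uniform_scene
        for roi in rois[:5]:
            a = equal_area_partition(roi)
            b = equal_area_partition(roi)
            assert np.array_equal(a.perinuclear_mask, b.perinuclear_mask)
            assert a.split_distance == b.split_distance

    def test_empty_nucleus_rejected(self):
        roi_like = make_disk_roi(6, 2, pad=2)
        roi_like.nucleus_mask = np.zeros_like(roi_like.nucleus_mask)
        with pytest.raises(ValueError, match="nucleus"):
            equal_area_partition(roi_like)


class TestDistributionIndex:
    def test_extreme_values_at_domain_confined_signal(self, disk_roi):
        """Signal wholly in one domain gives exactly +1 (perinuclear) or
        -1 (peripheral); cytoplasm-filling signal gives |D| <= 1/A_total."""
        part = equal_area_partition(disk_roi)
        assert distribution_index(part, part.perinuclear_mask).index == 1.0
        assert distribution_index(part, part.peripheral_mask).index == -1.0
        full = distribution_index(part, disk_roi.cytoplasm_mask)
        assert abs(full.index) <= 1.0 / full.area_total

    def test_index_bounded(self, uniform_scene):
        scene, rois, _ = uniform_scene
        for roi in rois:
            part = equal_area_partition(roi)
            mask = threshold_channel(scene, "puncta_a", roi, threshold=40)
            res = distribution_index(part, mask)
            if res.defined:
                assert -1.0 <= res.index <= 1.0

    def test_undefined_when_no_signal(self, disk_roi):
        part = equal_area_partition(disk_roi)
        res = distribution_index(part, np.zeros_like(disk_roi.cell_mask))
        assert not res.defined and math.isnan(res.index)

    def test_signal_clipped_to_cytoplasm(self, disk_roi):
        """Nucleus-overlapping signal never contributes to the areas."""
        part = equal_area_partition(disk_roi)
        signal = disk_roi.nucleus_mask | part.perinuclear_mask
        res = distribution_index(part, signal)
        assert res.area_total == int(part.perinuclear_mask.sum())
        assert res.index == 1.0

    def test_antisymmetry_under_domain_swap(self, disk_roi):
        part = equal_area_partition(disk_roi)
        rng = np.random.default_rng(3)
        signal = disk_roi.cytoplasm_mask & (rng.random(disk_roi.cell_mask.shape) < 0.3)
        swapped = DomainPartition(part.cell_id, part.peripheral_mask,
                                  part.perinuclear_mask, part.split_distance,
                                  part.area_difference)
        d = distribution_index(part, signal).index
        d_sw = distribution_index(swapped, signal).index
        assert d_sw == pytest.approx(-d, abs=1e-15)

    def test_monotone_in_perinuclear_area(self, disk_roi):
        """Moving one unit of signal from peripheral to perinuclear raises D."""
        part = equal_area_partition(disk_roi)
        rng = np.random.default_rng(4)
        signal = disk_roi.cytoplasm_mask & (rng.random(disk_roi.cell_mask.shape) < 0.2)
        d0 = distribution_index(part, signal).index
        move_from = signal & part.peripheral_mask
        add_to = part.perinuclear_mask & ~signal
        src = tuple(np.argwhere(move_from)[0])
        dst = tuple(np.argwhere(add_to)[0])
        signal2 = signal.copy()
        signal2[src] = False
        signal2[dst] = True
        assert distribution_index(part, signal2).index > d0

    def test_oracle_equivalence_brute_force(self, uniform_scene):
        """Pipeline D equals an explicit per-pixel recount, bit-exactly."""
        scene, rois, _ = uniform_scene
        for roi in rois[:5]:
            part = equal_area_partition(roi)
            mask = threshold_channel(scene, "puncta_a", roi, threshold=40)
            res = distribution_index(part, mask)
            a_peri = a_periph = 0
            for r, c in zip(*np.nonzero(mask)):
                if part.perinuclear_mask[r, c]:
                    a_peri += 1
                elif part.peripheral_mask[r, c]:
                    a_periph += 1
            assert (a_peri, a_periph) == (res.area_perinuclear, res.area_peripheral)
            assert res.index == (a_peri - a_periph) / (a_peri + a_periph)

    def test_recovers_placement_bias(self):
        """Cohort generated at f = 0.75 scores near D = 2f - 1 = 0.5."""
        spec = SceneSpec(seed=21, clone_fraction=1.0)
        scene, rois, _ = generate_scene(
            spec, [PunctaSpec(mode="perinuclear", f=0.75, n_spots=200)])
        ds = []
        for roi in rois:
            part = equal_area_partition(roi)
            mask = threshold_channel(scene, "puncta_a", roi, threshold=40)
            ds.append(distribution_index(part, mask).index)
        assert np.mean(ds) == pytest.approx(0.5, abs=0.05)


def _structures_at(points, areas, shape=(64, 64)):
    rows = [{"label": i + 1, "area_px": a, "area_um2": float(a),
             "centroid_row": p[0], "centroid_col": p[1],
             "mean_intensity": np.nan, "bbox_min_row": 0, "bbox_min_col": 0,
             "bbox_max_row": 1, "bbox_max_col": 1}
            for i, (p, a) in enumerate(zip(points, areas))]
    return StructureSet(cell_id=1, channel="puncta_a",
                        label_map=np.zeros(shape, np.int32),
                        table=pd.DataFrame(rows))


class TestClassifyLocalization:
    def test_tight_far_cluster_is_ectopic(self, disk_roi):
        part = equal_area_partition(disk_roi)
        res = distribution_index(part, part.peripheral_mask)
        # one tight cluster ~60 px from the nucleus boundary, pixel 0.5 µm
        pts = [(30, 30), (31, 31), (30, 32)]
        ss = _structures_at(pts, [50, 40, 30], shape=disk_roi.cell_mask.shape)
        call = classify_localization(res, ss, disk_roi, pixel_size=0.5,
                                     thresholds=ClassifierThresholds(
                                         cluster_fraction=0.5, offset_um=10.0,
                                         link_radius_um=2.0))
        assert call.category == "ectopic_focus"
        assert call.cluster_fraction == 1.0

    def test_high_index_without_cluster_is_perinuclear(self, disk_roi):
        part = equal_area_partition(disk_roi)
        res = distribution_index(part, part.perinuclear_mask)  # D = 1 > 0.5
        # scattered small structures near the nucleus
        pts = [(104, 104), (104, 130), (130, 104), (90, 104)]
        ss = _structures_at(pts, [10, 10, 10, 10],
                            shape=disk_roi.cell_mask.shape)
        call = classify_localization(res, ss, disk_roi, pixel_size=0.16)
        assert call.category == "perinuclear"

    def test_low_index_is_peripheral_and_middle_dispersed(self, disk_roi):
        part = equal_area_partition(disk_roi)
        ss = _structures_at([(104, 30), (30, 104)], [10, 10],
                            shape=disk_roi.cell_mask.shape)
        th = ClassifierThresholds(offset_um=1e9)  # disable ectopic branch
        lo = distribution_index(part, part.peripheral_mask)
        assert classify_localization(lo, ss, disk_roi, 0.16, th).category == \
            "peripheral"
        even = distribution_index(part, disk_roi.cytoplasm_mask)
        assert classify_localization(even, ss, disk_roi, 0.16, th).category == \
            "dispersed"


class TestCohortTable:
    def test_row_per_eligible_clone_cell(self, perinuclear_scene):
        scene, rois, _ = perinuclear_scene
        table = cohort_index_table(scene, rois, "puncta_a", threshold=40)
        assert len(table) == sum(r.clone and r.nucleus_in_plane for r in rois)
        assert set(table.columns) == {"cell_id", "A_peri", "A_periph",
                                      "A_total", "D"}
        assert (table["A_peri"] + table["A_periph"] == table["A_total"]).all()
        # perinuclear cohort scores uniformly high
        assert (table["D"] > 0.8).all()

    def test_no_eligible_cells_errors(self, perinuclear_scene):
        scene, rois, _ = perinuclear_scene
        stripped = [type(r)(r.cell_id, r.cell_mask, r.nucleus_mask,
                            clone=False) for r in rois]
        with pytest.raises(ValueError, match="eligible"):
            cohort_index_table(scene, stripped, "puncta_a", threshold=40)
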