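"""Imaging chain: segmentation, ring regions, spot detection, aggregation."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from steatoscreen.imaging import (
    CellRecord,
    NucleusRecord,
    ValidityCriteria,
    aggregate_well,
    filter_valid_nuclei,
    find_nuclei,
    find_spots,
    label_image_from_records,
    per_cell_features,
    quantify_field,
    select_cell_region,
)
from steatoscreen.synthetic import FieldImage, FieldParams, generate_field

from conftest import disk_mask


def brute_force_rings(labels: np.ndarray, width: int) -> np.ndarray:
    """Per-pixel nearest-nucleus assignment oracle (ties to the lower label)."""
    out = np.zeros(labels.shape, dtype=int)
    ids = sorted(set(labels.ravel()) - {0})
    pix = np.argwhere(labels >= 0)
    dists = {}
    for lab in ids:
        pts = np.argwhere(labels == lab)
        dists[lab] = cdist(pix, pts).min(axis=1)
    for k, (r, c) in enumerate(pix):
        if labels[r, c] > 0:
            continue
        best_lab, best_d = 0, np.inf
        for lab in ids:  # increasing label order: ties keep the lower id
            if dists[lab][k] < best_d:
                best_d, best_lab = dists[lab][k], lab
        if 0 < best_d <= width:
            out[r, c] = best_lab
    return out


class TestFindNuclei:
    def test_blank_raster_is_empty_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            records, labels = find_nuclei(np.zeros((64, 64)))
        assert records == [] and labels.max() == 0

    def test_empty_raster_is_an_error(self):
        with pytest.raises(ValueError):
            find_nuclei(np.zeros((0, 0)))

    def test_single_disk_area_close_to_analytic(self):
        img = np.where(disk_mask((64, 64), (32, 32), 10), 500.0, 100.0)
        records, _ = find_nuclei(img)
        assert len(records) == 1
        assert records[0].area == pytest.approx(math.pi * 100, rel=0.15)
        assert records[0].roundness > 0.9

    def test_recovers_all_nuclei_at_moderate_noise(self):
        """Noise at a tenth of the background leaves detection essentially exact."""
        params = FieldParams(
            shape=(1024, 1024), n_nuclei=50, noise_sigma=(10.0, 0.0), steatosis_level=0.0
        )
        image, truth = generate_field(params, seed=4)
        records, _ = find_nuclei(image.nuclear)
        assert len(records) == 50
        centers = np.array([n.center for n in truth.nuclei])
        found = np.array([r.centroid for r in records])
        d = cdist(centers, found)
        assert np.all(d.min(axis=1) <= 2.0)


class TestFilterValidNuclei:
    def _record(self, **kw):
        base = dict(
            label=1, centroid=(10.0, 10.0), area=300.0, roundness=0.95,
            mean_intensity=500.0, integrated_intensity=150000.0,
            bbox=(5, 5, 15, 15), touches_border=False,
        )
        base.update(kw)
        return NucleusRecord(**base)

    def test_empty_input_is_empty_output(self):
        assert filter_valid_nuclei([], ValidityCriteria()) == []

    def test_fragmented_nuclei_fail_area_interval(self):
        params = FieldParams(
            shape=(320, 320), n_nuclei=5, n_invalid=3, noise_sigma=(0.0, 0.0),
            steatosis_level=0.0,
        )
        image, _ = generate_field(params, seed=6)
        records, _ = find_nuclei(image.nuclear)
        flagged = filter_valid_nuclei(records, ValidityCriteria())
        assert sum(r.valid for r in flagged) == 5
        assert sum(not r.valid for r in flagged) == 3

    def test_unbounded_criteria_accept_everything(self):
        criteria = ValidityCriteria(
            min_area=0.0, min_roundness=0.0, exclude_border=False
        )
        records = [self._record(), self._record(label=2, roundness=0.1, area=5.0)]
        assert all(r.valid for r in filter_valid_nuclei(records, criteria))

    def test_border_exclusion_toggle(self):
        rec = self._record(touches_border=True)
        assert not filter_valid_nuclei([rec], ValidityCriteria())[0].valid
        ok = filter_valid_nuclei([rec], ValidityCriteria(exclude_border=False))
        assert ok[0].valid


class TestSelectCellRegion:
    def test_zero_width_gives_empty_regions(self):
        labels = disk_mask((64, 64), (32, 32), 8).astype(int)
        assert select_cell_region(labels, 0).max() == 0

    def test_annulus_pixel_count_matches_distance_oracle(self):
        r, w = 8, 5
        labels = disk_mask((64, 64), (32, 32), r).astype(int)
        rings = select_cell_region(labels, w)
        rr, cc = np.mgrid[:64, :64]
        pts = np.argwhere(labels == 1)
        d = cdist(np.argwhere(labels >= 0), pts).min(axis=1).reshape(64, 64)
        oracle = (d > 0) & (d <= w)
        assert np.array_equal(rings > 0, oracle)

    def test_two_close_nuclei_split_the_overlap(self):
        labels = disk_mask((96, 96), (48, 38), 6).astype(int)
        labels[disk_mask((96, 96), (48, 58), 6)] = 2
        rings = select_cell_region(labels, 15)
        # disjoint by construction of a label raster; check against the
        # brute-force morphology oracle: union == dilation(union) - nuclei
        oracle = brute_force_rings(labels, 15)
        assert np.array_equal(rings, oracle)
        union = labels > 0
        from scipy import ndimage as ndi

        dil = ndi.distance_transform_edt(~union) <= 15
        assert np.array_equal((rings > 0), dil & ~union)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_fields(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.zeros((64, 64), dtype=int)
        for lab in range(1, rng.integers(2, 5)):
            center = rng.uniform(8, 56, size=2)
            labels[disk_mask((64, 64), center, rng.uniform(3, 7))] = lab
        width = int(rng.integers(3, 16))
        assert np.array_equal(
            select_cell_region(labels, width), brute_force_rings(labels, width)
        )


class TestFindSpots:
    def test_uniform_lipid_channel_yields_no_spots(self):
        cyto = disk_mask((64, 64), (32, 32), 20).astype(int)
        assert find_spots(np.full((64, 64), 50.0), cyto) == []

    def test_shape_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            find_spots(np.zeros((10, 10)), np.zeros((12, 12), dtype=int))

    def test_spots_closer_than_two_pixels_merge(self):
        cyto = np.ones((64, 64), dtype=int)
        img = np.zeros((64, 64))
        img[20, 20] = 300.0
        img[21, 21] = 200.0  # center distance sqrt(2) < 2
        spots = find_spots(img, cyto)
        assert len(spots) == 1
        assert spots[0].integrated_intensity == pytest.approx(500.0)
        assert spots[0].area == 2

    def test_spots_beyond_two_pixels_stay_separate(self):
        cyto = np.ones((64, 64), dtype=int)
        img = np.zeros((64, 64))
        img[20, 20] = 300.0
        img[20, 23] = 200.0
        spots = find_spots(img, cyto)
        assert len(spots) == 2

    def test_planted_spot_recovery_at_high_snr(self):
        params = FieldParams(shape=(320, 320), n_nuclei=6, noise_sigma=(0.0, 30.0))
        image, truth = generate_field(params, seed=8)
        records, labels = find_nuclei(image.nuclear)
        records = filter_valid_nuclei(records)
        rings = select_cell_region(label_image_from_records(labels, records), 15)
        spots = find_spots(image.lipid, rings)
        centers = np.array([d.center for d in truth.droplets])
        found = np.array([s.center for s in spots])
        recovered = (cdist(centers, found).min(axis=1) <= 2.0).sum()
        assert recovered >= 0.95 * len(truth.droplets)
        # every detected spot lies inside a cytoplasm ring by construction
        for s in spots:
            assert rings[int(round(s.center[0])), int(round(s.center[1]))] >= 0


class TestPerCellFeatures:
    def _cell(self, label):
        return NucleusRecord(
            label=label, centroid=(0, 0), area=100, roundness=1.0,
            mean_intensity=1.0, integrated_intensity=100.0,
            bbox=(0, 0, 10, 10), valid=True,
        )

    def test_cell_without_spots_has_zero_features(self):
        out = per_cell_features([self._cell(1)], [])
        assert out[0].spot_count == 0
        assert out[0].integrated_spot_signal == 0.0
        assert out[0].total_spot_area == 0

    def test_orphan_spot_is_an_error_naming_the_spot(self):
        from steatoscreen.imaging import SpotRecord

        spot = SpotRecord(center=(5.0, 5.0), area=4, integrated_intensity=10.0, owner=99)
        with pytest.raises(ValueError, match="99"):
            per_cell_features([self._cell(1)], [spot])

    def test_noiseless_field_features_equal_truth_exactly(self, small_field_params):
        image, truth = generate_field(small_field_params, seed=1)
        cells = quantify_field(image)
        det = sorted(c.integrated_spot_signal for c in cells)
        exp = sorted(truth.per_cell_signal().values())
        assert len(det) == len(exp)
        assert np.allclose(det, exp, rtol=1e-9)
        assert sorted(c.spot_count for c in cells) == sorted(
            truth.per_cell_count().values()
        )


class TestAggregateWell:
    def _cell(self, signal, count=1, area=4):
        nuc = NucleusRecord(
            label=1, centroid=(0, 0), area=100, roundness=1.0, mean_intensity=1.0,
            integrated_intensity=100.0, bbox=(0, 0, 1, 1), valid=True,
        )
        return CellRecord(
            nucleus=nuc, spot_count=count, integrated_spot_signal=signal,
            total_spot_area=area,
        )

    def test_single_cell_well_equals_that_cell(self):
        well = aggregate_well([[self._cell(7.0, count=2, area=9)]])
        assert well.valid_cell_count == 1
        assert well.iss_mean == 7.0 and well.spot_count_mean == 2.0

    def test_well_average_pools_cells_across_fields(self):
        fields = [
            [self._cell(2.0), self._cell(2.0)],
            [self._cell(4.0), self._cell(4.0), self._cell(4.0)],
        ]
        well = aggregate_well(fields)
        assert well.iss_mean == pytest.approx(3.2)
        assert well.valid_cell_count == 5

    def test_empty_fields_flagged_not_error(self):
        well = aggregate_well([[], []])
        assert well.valid_cell_count == 0
        assert well.undefined and well.low_cell_flag
        assert math.isnan(well.iss_mean)

    def test_no_fields_is_an_error(self):
        with pytest.raises(ValueError):
            aggregate_well([])


class TestPipelineProperties:
    def test_determinism_of_full_chain(self, small_field_params):
        image, _ = generate_field(small_field_params, seed=12)
        a = quantify_field(image)
        b = quantify_field(image)
        assert [c.integrated_spot_signal for c in a] == [
            c.integrated_spot_signal for c in b
        ]

    def test_lipid_scaling_scales_signals_linearly(self, small_field_params):
        image, _ = generate_field(small_field_params, seed=13)
        base = quantify_field(image)
        scaled_img = FieldImage(nuclear=image.nuclear, lipid=image.lipid * 2.5)
        scaled = quantify_field(scaled_img)
        a = np.array(sorted(c.integrated_spot_signal for c in base))
        b = np.array(sorted(c.integrated_spot_signal for c in scaled))
        assert np.allclose(b, 2.5 * a, rtol=1e-9)

    def test_conservation_of_signal(self, small_field_params):
        image, truth = generate_field(small_field_params, seed=14)
        records, labels = find_nuclei(image.nuclear)
        records = filter_valid_nuclei(records)
        rings = select_cell_region(label_image_from_records(labels, records), 15)
        spots = find_spots(image.lipid, rings)
        total_detected = sum(s.integrated_intensity for s in spots)
        bg = np.median(image.lipid[rings > 0])
        total_available = np.sum(np.clip(image.lipid[rings > 0] - bg, 0, None))
        assert total_detected <= total_available + 1e-6
        # noiseless: equality on the planted droplets
        assert total_detected == pytest.approx(truth.total_signal(), rel=1e-9)
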