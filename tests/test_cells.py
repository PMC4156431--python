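"""Connected-component cell detection and double-label counting."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from conftest import brute_force_components, random_blob_mask

from ftlquant import DetectorParams, count_double_labeled, detect_cells
from ftlquant.errors import AlignmentError


def _roi(shape):
    return np.ones(shape, dtype=bool)


class TestDetect:
    def test_empty_mask(self):
        params = DetectorParams(min_area=1, max_area=100)
        assert detect_cells(np.zeros((10, 10), bool), _roi((10, 10)), params) == []

    def test_single_square(self):
        """A 3x3 solid square: one cell, centroid at its center, area 9."""
        mask = np.zeros((10, 10), bool)
        mask[4:7, 4:7] = True
        params = DetectorParams(min_area=4, max_area=100)
        cells = detect_cells(mask, _roi((10, 10)), params)
        assert len(cells) == 1
        assert cells[0].area == 9
        assert cells[0].centroid_xy == (5.0, 5.0)

    def test_diagonal_connectivity(self):
        mask = np.zeros((5, 5), bool)
        mask[1, 1] = mask[2, 2] = True
        four = DetectorParams(min_area=1, max_area=10, connectivity=4)
        eight = DetectorParams(min_area=1, max_area=10, connectivity=8)
        assert len(detect_cells(mask, _roi((5, 5)), four)) == 2
        assert len(detect_cells(mask, _roi((5, 5)), eight)) == 1

    def test_area_band_excludes_puncta_and_clumps(self):
        mask = np.zeros((20, 20), bool)
        mask[1, 1] = True              # punctum, area 1
        mask[4:7, 4:7] = True          # cell, area 9
        mask[10:18, 10:18] = True      # clump, area 64
        params = DetectorParams(min_area=4, max_area=20)
        cells = detect_cells(mask, _roi((20, 20)), params)
        assert [c.area for c in cells] == [9]

    def test_roi_clipping_uses_in_roi_area(self):
        """A component straddling the ROI boundary is kept if its in-ROI
        part fits the band."""
        mask = np.zeros((10, 10), bool)
        mask[0:2, 0:10] = True  # area 20
        roi = np.zeros((10, 10), bool)
        roi[0:2, 0:4] = True    # clips it to area 8
        params = DetectorParams(min_area=4, max_area=10)
        cells = detect_cells(mask, roi, params)
        assert len(cells) == 1 and cells[0].area == 8

    @pytest.mark.parametrize("seed,connectivity", [
        (s, c) for s in range(8) for c in (4, 8)
    ])
    def test_matches_brute_force_components(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        mask = random_blob_mask(rng, (48, 48))
        lo, hi = 2, int(rng.integers(8, 30))
        params = DetectorParams(min_area=lo, max_area=hi,
                                connectivity=connectivity)
        cells = detect_cells(mask, _roi((48, 48)), params)
        ref = [c for c in brute_force_components(mask, connectivity)
               if lo <= c["area"] <= hi]
        assert len(cells) == len(ref)
        if ref:
            got = np.array(sorted(c.centroid_xy for c in cells))
            want = np.array(sorted(c["centroid_xy"] for c in ref))
            assert np.allclose(got, want)
            assert sorted(c.area for c in cells) == sorted(c["area"] for c in ref)

    def test_dimension_mismatch(self):
        params = DetectorParams(min_area=1, max_area=10)
        with pytest.raises(AlignmentError):
            detect_cells(np.ones((4, 4), bool), np.ones((4, 5), bool), params)


class TestDoubleLabel:
    def _mask_with_cells(self, centers, shape=(40, 40), half=1):
        mask = np.zeros(shape, bool)
        for r, c in centers:
            mask[r - half:r + half + 1, c - half:c + half + 1] = True
        return mask

    def test_identical_masks_all_double(self):
        mask = self._mask_with_cells([(5, 5), (20, 20), (30, 10)])
        params = DetectorParams(min_area=4, max_area=20)
        n, cells = count_double_labeled(None, mask, mask.copy(), params)
        assert n == 3 and all(c.is_double for c in cells)

    def test_disjoint_masks_zero(self):
        a = self._mask_with_cells([(5, 5), (20, 20)])
        b = self._mask_with_cells([(30, 30)])
        params = DetectorParams(min_area=4, max_area=20)
        n, cells = count_double_labeled(None, a, b, params)
        assert n == 0 and not any(c.is_double for c in cells)

    def test_double_count_never_exceeds_cell_count(self, rng):
        params = DetectorParams(min_area=1, max_area=50)
        for _ in range(10):
            a = random_blob_mask(rng, (32, 32))
            b = random_blob_mask(rng, (32, 32))
            n, cells = count_double_labeled(None, a, b, params)
            assert 0 <= n <= len(cells)

    def test_growing_other_mask_monotone(self, rng):
        """Adding pixels to the beta-gal mask never loses a double."""
        params = DetectorParams(min_area=1, max_area=50)
        a = random_blob_mask(rng, (32, 32))
        b = random_blob_mask(rng, (32, 32))
        n0, _ = count_double_labeled(None, a, b, params)
        grown = b | (rng.random((32, 32)) < 0.2)
        n1, _ = count_double_labeled(None, a, grown, params)
        assert n1 >= n0

    def test_annotates_detected_cells_in_order(self):
        a = self._mask_with_cells([(5, 5), (20, 20)])
        b = self._mask_with_cells([(20, 20)])
        params = DetectorParams(min_area=4, max_area=20)
        cells = detect_cells(a, _roi((40, 40)), params, channel="cfos")
        n, annotated = count_double_labeled(cells, a, b, params)
        assert n == 1
        flags = {c.centroid_xy: c.is_double for c in annotated}
        assert flags[(5.0, 5.0)] is False and flags[(20.0, 20.0)] is True


class TestPlantedRecovery:
    @pytest.mark.parametrize("fraction", [0.0, 0.5, 1.0])
    def test_double_fraction_recovered(self, fraction):
        """High-SNR scenes: counted doubles equal the planted number and
        one-sided populations (c-Fos without beta-gal and vice versa) are
        reported correctly against truth."""
        from ftlquant import SceneParams, generate_section
        from ftlquant.imgproc import aggregate_roi_pixels, binarize, estimate_threshold
        from ftlquant.pipeline import default_detectors
        from ftlquant.roi import rasterize_polygon

        params = SceneParams(
            image_height=224, image_width=224, n_cfos_cells=12,
            n_bgal_cells=12, double_label_fraction=fraction, n_puncta=8,
            seed=int(fraction * 100) + 3,
        )
        sec, truth = generate_section(params)
        rm = rasterize_polygon(truth.roi_polygon, sec.shape)
        det = default_detectors(params)
        masks = {}
        for ch in ("cfos", "bgal"):
            s = aggregate_roi_pixels([sec], [truth.roi_polygon], ch, roi_masks=[rm])
            masks[ch] = binarize(sec.channels[ch],
                                 estimate_threshold(s).cutoff).mask & rm.mask
        n_cfos_dbl, cfos_cells = count_double_labeled(
            None, masks["cfos"], masks["bgal"], det["cfos"])
        n_bgal_dbl, bgal_cells = count_double_labeled(
            None, masks["bgal"], masks["cfos"], det["bgal"])
        planted = truth.n_double()
        assert n_cfos_dbl == planted
        assert n_bgal_dbl == planted
        assert len(cfos_cells) - n_cfos_dbl == 12 - planted  # cfos-only
        assert len(bgal_cells) - n_bgal_dbl == 12 - planted  # bgal-only

    def test_centroids_match_truth(self):
        from ftlquant import SceneParams, generate_section
        from ftlquant.imgproc import aggregate_roi_pixels, binarize, estimate_threshold
        from ftlquant.pipeline import default_detectors
        from ftlquant.roi import rasterize_polygon

        params = SceneParams(seed=99)
        sec, truth = generate_section(params)
        rm = rasterize_polygon(truth.roi_polygon, sec.shape)
        det = default_detectors(params)
        for ch in ("cfos", "bgal"):
            s = aggregate_roi_pixels([sec], [truth.roi_polygon], ch, roi_masks=[rm])
            mask = binarize(sec.channels[ch], estimate_threshold(s).cutoff)
            cells = detect_cells(mask, rm, det[ch], channel=ch)
            planted = truth.cells_in(ch)
            assert len(cells) == len(planted)
            d = cdist(np.array([c.centroid_xy for c in planted]),
                      np.array([c.centroid_xy for c in cells]))
            assert d.min(axis=1).max() <= 1.0
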