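"""Segmentation, leakage score, QC filters, and detection assignment."""

import numpy as np
import pandas as pd
import pytest

from papaquant import (
    NucleusRecord,
    QCParams,
    apply_qc,
    assign_detections,
    leakage_score,
    segment_nuclei_threshold,
)
from papaquant.segmentation import LEAKAGE_UNDEFINED


def _square_image(shape, squares, value=100.0):
    img = np.zeros(shape)
    for (r0, c0, h, w) in squares:
        img[r0 : r0 + h, c0 : c0 + w] = value
    return img


class TestSegmentation:
    def test_flat_image_yields_no_nuclei(self):
        labels = segment_nuclei_threshold(np.full((64, 64), 7.0), 2.0, 10)
        assert labels.max() == 0

    def test_single_bright_square_yields_one_nucleus(self):
        img = _square_image((300, 300), [(50, 50, 100, 100)])
        labels = segment_nuclei_threshold(img, smoothing_sigma=0.0, min_area=5000)
        assert labels.max() == 1
        assert (labels == 1).sum() >= 5000

    def test_min_area_cut_is_strictly_smaller_than(self):
        """Areas 4,999 and 5,001 with min_area 5,000: exactly one survives."""
        img = np.zeros((250, 400))
        img[10:80, 10:81] = 100.0  # 70 x 71 = 4970
        img[80, 10:39] = 100.0  # + 29 -> 4999
        img[120:190, 200:271] = 100.0  # 4970
        img[190, 200:231] = 100.0  # + 31 -> 5001
        assert (img[:100] > 0).sum() == 4999
        assert (img[100:] > 0).sum() == 5001
        labels = segment_nuclei_threshold(img, smoothing_sigma=0.0, min_area=5000)
        kept = [l for l in np.unique(labels) if l > 0]
        assert len(kept) == 1
        assert (labels > 0).sum() == 5001


def _record(mask):
    return NucleusRecord(label=1, mask=mask, area=int(mask.sum()))


class TestLeakageScore:
    def test_uniform_image_scores_one(self):
        mask = np.zeros((40, 40), bool)
        mask[15:25, 15:25] = True
        assert leakage_score(np.full((40, 40), 3.0), _record(mask)) == pytest.approx(
            1.0
        )

    def test_forced_ring_and_nuclear_means(self):
        mask = np.zeros((40, 40), bool)
        mask[15:25, 15:25] = True
        img = np.full((40, 40), 2.0)
        img[mask] = 4.0
        assert leakage_score(img, _record(mask)) == pytest.approx(0.5)

    def test_matches_brute_force_pixel_enumeration(self):
        rng = np.random.default_rng(0)
        img = rng.random((40, 40)) * 50
        mask = np.zeros((40, 40), bool)
        mask[12:20, 18:27] = True
        ring_width = 4
        # brute force: a pixel is in the ring iff it is off-mask and within
        # euclidean distance <= ring_width of some mask pixel (disk footprint)
        ys, xs = np.nonzero(mask)
        ring = np.zeros_like(mask)
        for i in range(40):
            for j in range(40):
                if mask[i, j]:
                    continue
                d2 = (ys - i) ** 2 + (xs - j) ** 2
                if d2.min() <= ring_width**2:
                    ring[i, j] = True
        expected = img[ring].mean() / img[mask].mean()
        assert leakage_score(img, _record(mask), ring_width=ring_width) == (
            pytest.approx(expected)
        )

    def test_invariant_under_positive_scaling(self):
        rng = np.random.default_rng(1)
        img = rng.random((30, 30)) + 0.5
        mask = np.zeros((30, 30), bool)
        mask[10:18, 10:18] = True
        base = leakage_score(img, _record(mask))
        for factor in (0.25, 3.0, 1e4):
            assert leakage_score(img * factor, _record(mask)) == pytest.approx(base)

    def test_zero_nuclear_mean_returns_failing_sentinel(self):
        mask = np.zeros((20, 20), bool)
        mask[8:12, 8:12] = True
        img = np.ones((20, 20))
        img[mask] = 0.0
        score = leakage_score(img, _record(mask))
        assert score == LEAKAGE_UNDEFINED
        assert not score <= 0.7  # fails the QC comparison

    def test_neighboring_nucleus_pixels_excluded_from_ring(self):
        mask_a = np.zeros((30, 30), bool)
        mask_a[5:15, 5:15] = True
        labeled = np.zeros((30, 30), np.uint16)
        labeled[mask_a] = 1
        labeled[5:15, 16:26] = 2  # neighbor directly adjacent
        img = np.ones((30, 30))
        img[labeled == 2] = 100.0
        with_neighbor = leakage_score(img, _record(mask_a), all_nuclei_mask=labeled)
        assert with_neighbor == pytest.approx(1.0)


def _nuc(label, area=6000, leakage=0.0, count=500, edges=()):
    mask = np.zeros((10, 10), bool)
    mask[0, 0] = True
    rec = NucleusRecord(label=label, mask=mask, area=area)
    rec.leakage_score = leakage
    rec.detection_count = count
    rec.touches_edges = edges
    return rec


class TestQC:
    def test_leakage_exclusion_is_strictly_greater_than_070(self):
        nuclei = [
            _nuc(1, leakage=0.69),
            _nuc(2, leakage=0.70),
            _nuc(3, leakage=0.71),
        ]
        kept, report = apply_qc(
            nuclei,
            QCParams(min_area=None, max_leakage=0.7, count_bounds=None,
                     exclude_edges=None),
        )
        assert [n.label for n in kept] == [1, 2]
        assert report["nuclei"][3]["reasons"]

    def test_area_exclusion_is_strictly_smaller_than_5000(self):
        nuclei = [_nuc(1, area=4999), _nuc(2, area=5000)]
        kept, _ = apply_qc(
            nuclei,
            QCParams(min_area=5000, max_leakage=None, count_bounds=None,
                     exclude_edges=None),
        )
        assert [n.label for n in kept] == [2]

    def test_all_filters_disabled_is_identity(self):
        nuclei = [_nuc(1, area=10, leakage=9.0, count=0, edges=("top",))]
        kept, _ = apply_qc(
            nuclei,
            QCParams(min_area=None, max_leakage=None, count_bounds=None,
                     exclude_edges=None),
        )
        assert kept == nuclei

    def test_edge_and_count_filters(self):
        nuclei = [
            _nuc(1, edges=("top",)),
            _nuc(2, edges=("left",)),
            _nuc(3, count=5),
        ]
        kept, report = apply_qc(
            nuclei,
            QCParams(min_area=None, max_leakage=None, count_bounds=(100, 1000),
                     exclude_edges=("top", "bottom")),
        )
        assert [n.label for n in kept] == [2]
        assert "edge" in report["nuclei"][1]["reasons"][0]
        assert "count" in report["nuclei"][3]["reasons"][0]

    def test_relaxing_one_threshold_never_removes_a_retained_nucleus(self):
        rng = np.random.default_rng(2)
        nuclei = [
            _nuc(i, area=int(rng.integers(3000, 8000)),
                 leakage=float(rng.random() * 1.2),
                 count=int(rng.integers(0, 2000)))
            for i in range(30)
        ]
        base = QCParams(min_area=5000, max_leakage=0.7, count_bounds=(100, 1500),
                        exclude_edges=None)
        kept_base = {n.label for n in apply_qc(nuclei, base)[0]}
        relaxed = [
            QCParams(min_area=4000, max_leakage=0.7, count_bounds=(100, 1500),
                     exclude_edges=None),
            QCParams(min_area=5000, max_leakage=0.9, count_bounds=(100, 1500),
                     exclude_edges=None),
            QCParams(min_area=5000, max_leakage=0.7, count_bounds=(50, 1800),
                     exclude_edges=None),
        ]
        for params in relaxed:
            kept = {n.label for n in apply_qc(nuclei, params)[0]}
            assert kept_base <= kept


class TestAssignDetections:
    def _mask(self):
        mask = np.zeros((50, 50), np.uint16)
        mask[5:15, 5:15] = 3
        mask[30:40, 30:40] = 7
        return mask

    def test_centroid_and_background_assignment(self):
        det = pd.DataFrame(
            {
                "frame": [0, 0, 1],
                "y": [10.0, 2.0, 35.2],
                "x": [10.0, 2.0, 34.9],
                "trajectory": [0, 1, 2],
                "channel": "receiver",
            }
        )
        out, report = assign_detections(det, self._mask())
        assert list(out["nucleus"]) == [3, 0, 7]
        assert report["n_unassigned"] == 1

    def test_out_of_bounds_unassigned_and_counted(self):
        det = pd.DataFrame(
            {
                "frame": [0],
                "y": [-3.0],
                "x": [10.0],
                "trajectory": [0],
                "channel": "receiver",
            }
        )
        out, report = assign_detections(det, self._mask())
        assert list(out["nucleus"]) == [0]
        assert report["n_out_of_bounds"] == 1

    def test_matches_brute_force_lookup_and_partitions(self):
        rng = np.random.default_rng(3)
        mask = self._mask()
        n = 1000
        det = pd.DataFrame(
            {
                "frame": rng.integers(0, 10, n),
                "y": rng.random(n) * 55 - 2,
                "x": rng.random(n) * 55 - 2,
                "trajectory": rng.integers(0, 200, n),
                "channel": "receiver",
            }
        )
        out, _ = assign_detections(det, mask)
        for _, row in out.iterrows():
            iy, ix = int(np.floor(row.y)), int(np.floor(row.x))
            expected = (
                int(mask[iy, ix]) if 0 <= iy < 50 and 0 <= ix < 50 else 0
            )
            assert row.nucleus == expected
        # partition: every detection has exactly one label (possibly 0)
        assert out["nucleus"].notna().all()
        assert len(out) == n

    def test_trajectory_label_is_first_detection_label(self):
        det = pd.DataFrame(
            {
                "frame": [5, 1, 9],
                "y": [2.0, 10.0, 35.0],
                "x": [2.0, 10.0, 35.0],
                "trajectory": [0, 0, 0],
                "channel": "receiver",
            }
        )
        out, _ = assign_detections(det, self._mask())
        assert set(out["traj_nucleus"]) == {3}  # first frame (1) is in nucleus 3
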