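"""Segmentation, gating, foci detection, colocalization, micronuclei."""

import numpy as np
import pytest

from cfskit.errors import GatingError
from cfskit.imaging import (
    CellRecord,
    costes_test,
    count_foci,
    detect_foci,
    detect_micronuclei,
    gate_cell_cycle,
    object_colocalization,
    segment_nuclei,
)
from cfskit.imaging.foci import FociSet
from cfskit.imaging.records import measure_intensities

from conftest import match_truth_to_labels


def _disk_image(shape, disks, value=1.0):
    """disks: list of (row, col, radius)."""
    img = np.zeros(shape)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for r, c, rad in disks:
        img[(rr - r) ** 2 + (cc - c) ** 2 <= rad**2] = value
    return img


def _spot(img, r, c, sigma=1.5, amp=1.0):
    rr, cc = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    img += amp * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma**2))
    return img


class TestSegmentation:
    def test_single_disk(self):
        img = _disk_image((100, 100), [(50, 50, 15)])
        mask = segment_nuclei(img, min_area=50)
        assert mask.n_nuclei == 1
        assert mask.areas[1] == pytest.approx(np.pi * 15**2, rel=0.1)

    def test_two_disks(self):
        img = _disk_image((120, 120), [(30, 30, 12), (85, 85, 12)])
        mask = segment_nuclei(img, min_area=50)
        assert mask.n_nuclei == 2

    def test_blank_image_empty_mask(self):
        mask = segment_nuclei(np.zeros((50, 50)))
        assert mask.n_nuclei == 0

    def test_generator_cell_count(self, small_image_set):
        params, images, truths = small_image_set
        mask = segment_nuclei(images.dapi, min_area=120, max_area=5000)
        assert mask.n_nuclei == params.n_cells


def _record(i, dapi, edu, cyc=None):
    return CellRecord(cell_id=i, dapi_integrated=dapi, edu_mean=edu, cyclinA_mean=cyc)


class TestGating:
    def test_two_value_dapi_perfect_split(self):
        rng = np.random.default_rng(0)
        records = []
        for i in range(60):
            records.append(_record(i, 1000.0 + rng.normal(0, 1), 0.05))
        for i in range(60, 120):
            records.append(_record(i, 2000.0 + rng.normal(0, 1), 0.05))
        gate_cell_cycle(records)
        assert all(r.stage == "G1" for r in records[:60])
        assert all(r.stage == "G2" for r in records[60:])

    def test_every_cell_exactly_one_stage(self, small_image_set):
        params, images, truths = small_image_set
        mask = segment_nuclei(images.dapi, min_area=120, max_area=5000)
        records = measure_intensities(mask, images.dapi, images.edu)
        gate_cell_cycle(records)
        stages = [r.stage for r in records]
        assert all(s in ("G1", "earlyS", "midS", "lateS", "G2") for s in stages)

    def test_stage_median_dapi_ordering(self, small_image_set):
        params, images, truths = small_image_set
        mask = segment_nuclei(images.dapi, min_area=120, max_area=5000)
        records = measure_intensities(mask, images.dapi, images.edu)
        gate_cell_cycle(records)
        med = {
            s: np.median([r.dapi_integrated for r in records if r.stage == s])
            for s in ("G1", "earlyS", "midS", "lateS", "G2")
        }
        assert med["G1"] < med["earlyS"] <= med["midS"] <= med["lateS"] < med["G2"]

    def test_recall_against_reference_gate_oracle(self, small_image_set):
        """Per-stage recall close to a known-modes reference gate.

        The oracle applies the same EdU split and DAPI terciles but with
        the true generator modes; the fitted gate must come within a
        small estimation allowance of the oracle's per-stage recall.
        """
        params, images, truths = small_image_set
        mask = segment_nuclei(images.dapi, min_area=120, max_area=5000)
        records = measure_intensities(mask, images.dapi, images.edu)
        gate_cell_cycle(records)
        label_of = match_truth_to_labels(truths, mask)
        true_stage = {label_of[t.cell_id]: t.stage for t in truths}

        # oracle: gate per-cell *truth* features with the true modes
        rng = np.random.default_rng(99)
        n_mc = 20000
        stages = ("G1", "earlyS", "midS", "lateS", "G2")
        frac = {"G1": 0.0, "earlyS": 0.25, "midS": 0.5, "lateS": 0.75, "G2": 1.0}
        m2, m4 = params.dapi_2n_mean, params.dapi_4n_mean
        b1, b2 = m2 + (m4 - m2) / 3, m2 + 2 * (m4 - m2) / 3
        oracle_recall = {}
        for s in stages:
            mean = m2 + frac[s] * (m4 - m2)
            draws = mean * (1 + params.dapi_cv * rng.standard_normal(n_mc))
            if s in ("earlyS", "midS", "lateS"):
                calls = np.where(draws < b1, "earlyS",
                                 np.where(draws < b2, "midS", "lateS"))
            else:
                calls = np.where(np.abs(draws - m2) <= np.abs(draws - m4), "G1", "G2")
            oracle_recall[s] = float(np.mean(calls == s))

        for s in stages:
            cells = [r for r in records if true_stage.get(r.cell_id) == s]
            if len(cells) < 5:
                continue
            recall = np.mean([r.stage == s for r in cells])
            se = np.sqrt(oracle_recall[s] * (1 - oracle_recall[s]) / len(cells))
            assert recall >= oracle_recall[s] - 3 * se - 0.05

    def test_cyclin_a_negative_defines_g1(self):
        rng = np.random.default_rng(1)
        records = []
        for i in range(50):  # G1: 2N, EdU-, CycA-
            records.append(_record(i, 1000 + rng.normal(0, 30), 0.05, cyc=0.1))
        for i in range(50, 100):  # G2: 4N, EdU-, CycA+
            records.append(_record(i, 2000 + rng.normal(0, 30), 0.05, cyc=1.0))
        gate_cell_cycle(records, use_cyclin_a=True)
        assert all(r.stage == "G1" for r in records[:50])
        assert all(r.stage == "G2" for r in records[50:])

    def test_unimodal_dapi_raises(self):
        rng = np.random.default_rng(2)
        records = [_record(i, 1000 + rng.normal(0, 10), 0.05) for i in range(100)]
        with pytest.raises(GatingError):
            gate_cell_cycle(records)


class TestDetectFoci:
    def _nucleus(self, shape=(80, 80), radius=25):
        dapi = _disk_image(shape, [(shape[0] // 2, shape[1] // 2, radius)])
        return segment_nuclei(dapi, min_area=100)

    def test_planted_noiseless_spots_exact(self):
        mask = self._nucleus()
        img = np.zeros((80, 80))
        planted = [(30, 30), (50, 45), (40, 55)]
        for r, c in planted:
            _spot(img, r, c)
        foci = detect_foci(img, mask, spot_sigma=1.5, rel_threshold=6.0)
        assert len(foci) == 3
        det = foci.positions()
        for r, c in planted:
            assert np.min(np.abs(det - [r, c]).sum(axis=1)) <= 2

    def test_dim_spot_below_threshold_not_detected(self):
        rng = np.random.default_rng(5)
        dapi = _disk_image((80, 80), [(40, 40, 25)])
        mask = segment_nuclei(dapi, min_area=100)
        img = rng.normal(0, 0.05, (80, 80)).clip(0)
        _spot(img, 40, 40, amp=0.02)  # DoG response ~0.004 << 6*noise scale
        foci = detect_foci(img, mask, spot_sigma=1.5, rel_threshold=6.0)
        assert len(foci) == 0

    def test_intensity_rescale_invariance(self):
        rng = np.random.default_rng(6)
        dapi = _disk_image((100, 100), [(50, 50, 30)])
        mask = segment_nuclei(dapi, min_area=100)
        img = rng.normal(0, 0.02, (100, 100)).clip(0)
        for r, c in [(35, 40), (60, 55), (50, 70)]:
            _spot(img, r, c)
        f1 = detect_foci(img, mask)
        f2 = detect_foci(img * 7.3, mask)
        assert f1.data[["cell_id", "row", "col"]].equals(
            f2.data[["cell_id", "row", "col"]]
        )

    def test_foci_inside_parent_nucleus(self, small_image_set):
        params, images, truths = small_image_set
        mask = segment_nuclei(images.dapi, min_area=120, max_area=5000)
        foci = detect_foci(images.chan_a, mask)
        for row in foci.data.itertuples():
            assert mask.labels[row.row, row.col] == row.cell_id

    def test_per_stage_counts_match_planted(self, small_image_set):
        """Mean detected foci per stage within 3 s.e. of planted means."""
        params, images, truths = small_image_set
        mask = segment_nuclei(images.dapi, min_area=120, max_area=5000)
        foci = detect_foci(images.chan_a, mask)
        counts = count_foci(foci, mask)
        label_of = match_truth_to_labels(truths, mask)
        by_stage = {}
        for t in truths:
            by_stage.setdefault(t.stage, []).append(
                (counts[label_of[t.cell_id]], len(t.a_foci))
            )
        for stage, pairs in by_stage.items():
            det = np.array([d for d, _ in pairs], float)
            planted = np.array([p for _, p in pairs], float)
            se = max(planted.std(ddof=1), 1e-9) / np.sqrt(len(pairs))
            assert abs(det.mean() - planted.mean()) <= 3 * se + 0.15, stage


def _foci_set(cell_positions, channel="a"):
    import pandas as pd

    rows = [
        {"cell_id": cid, "row": r, "col": c, "peak": 1.0}
        for cid, pts in cell_positions.items()
        for r, c in pts
    ]
    return FociSet(
        channel=channel,
        data=pd.DataFrame(rows, columns=["cell_id", "row", "col", "peak"]),
    )


class TestObjectColocalization:
    def test_identical_sets_all_overlap(self):
        a = _foci_set({1: [(10, 10), (20, 20), (30, 15)]})
        res = object_colocalization(a, a, overlap_radius=2.0)
        assert res.loc[0, "overlap"] == 3 and res.loc[0, "adjacent"] == 0

    def test_adjacent_band(self):
        a = _foci_set({1: [(10.0, 10.0)]})
        b = _foci_set({1: [(10.0, 13.0)]}, "b")  # distance 3 = 1.5 * radius 2
        res = object_colocalization(a, b, overlap_radius=2.0)
        assert (res.loc[0, "overlap"], res.loc[0, "adjacent"]) == (0, 1)

    def test_beyond_double_radius_unmatched(self):
        a = _foci_set({1: [(10, 10)]})
        b = _foci_set({1: [(10, 15)]}, "b")
        res = object_colocalization(a, b, overlap_radius=2.0)
        assert (res.loc[0, "overlap"], res.loc[0, "adjacent"]) == (0, 0)

    def test_each_focus_used_once(self):
        a = _foci_set({1: [(10, 10)]})
        b = _foci_set({1: [(10, 11), (10, 9)]}, "b")
        res = object_colocalization(a, b, overlap_radius=2.0)
        assert res.loc[0, "overlap"] == 1

    def test_overlap_symmetric(self, rng):
        pa = [(float(r), float(c)) for r, c in rng.integers(0, 50, (8, 2))]
        pb = [(float(r), float(c)) for r, c in rng.integers(0, 50, (6, 2))]
        ab = object_colocalization(_foci_set({1: pa}), _foci_set({1: pb}, "b"), 3.0)
        ba = object_colocalization(_foci_set({1: pb}, "b"), _foci_set({1: pa}), 3.0)
        assert ab.loc[0, "overlap"] == ba.loc[0, "overlap"]


class TestCostes:
    def test_identity_pearson_one(self, rng):
        a = rng.random((40, 40))
        res = costes_test(a, a, n_rand=199, seed=0)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.p_value <= 0.01

    def test_planted_coloc_min_p(self, rng):
        img = np.zeros((60, 60))
        for r, c in [(15, 15), (30, 40), (45, 20), (20, 45)]:
            _spot(img, r, c)
        a = img + rng.normal(0, 0.01, (60, 60))
        b = img + rng.normal(0, 0.01, (60, 60))
        res = costes_test(a, b, n_rand=999, seed=1, block_px=5)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.fold_over_random > 10

    def test_seed_reproducibility(self, rng):
        a = rng.random((32, 32))
        b = rng.random((32, 32))
        r1 = costes_test(a, b, n_rand=99, seed=5, block_px=4)
        r2 = costes_test(a, b, n_rand=99, seed=5, block_px=4)
        assert (r1.pearson_r, r1.p_value, r1.rand_mean_r, r1.rand_sd_r) == (
            r2.pearson_r, r2.p_value, r2.rand_mean_r, r2.rand_sd_r
        )

    def test_constant_image_raises(self):
        with pytest.raises(ValueError, match="constant"):
            costes_test(np.ones((20, 20)), np.random.default_rng(0).random((20, 20)),
                        n_rand=99)

    def test_p_floor_invariant(self, rng):
        a = rng.random((32, 32))
        res = costes_test(a, a, n_rand=99, seed=2, block_px=4)
        assert res.p_value >= 1 / 100


class TestMicronuclei:
    def test_satellite_within_radius_counted(self):
        dapi = _disk_image((100, 100), [(50, 50, 15)])
        dapi = np.maximum(dapi, _disk_image((100, 100), [(50, 75, 3)]))
        mask = segment_nuclei(dapi, min_area=100)
        counts = detect_micronuclei(dapi, mask, max_mn_area=80, search_radius=20)
        assert counts == {1: 1}

    def test_satellite_beyond_radius_ignored(self):
        dapi = _disk_image((200, 200), [(50, 50, 15)])
        dapi = np.maximum(dapi, _disk_image((200, 200), [(50, 150, 3)]))
        mask = segment_nuclei(dapi, min_area=100)
        counts = detect_micronuclei(dapi, mask, max_mn_area=80, search_radius=20)
        assert counts == {1: 0}

    def test_generator_micronucleus_fraction(self, small_image_set):
        params, images, truths = small_image_set
        mask = segment_nuclei(images.dapi, min_area=120, max_area=5000)
        counts = detect_micronuclei(
            images.dapi, mask, max_mn_area=80, search_radius=20
        )
        frac = np.mean([c > 0 for c in counts.values()])
        p = params.micronucleus_prob
        se = np.sqrt(p * (1 - p) / params.n_cells)
        assert abs(frac - p) <= 3 * se + 0.02
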