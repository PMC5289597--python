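import numpy as np
import pytest

from vesel.io_formats import LabelStack
from vesel.morphometry import (
    FilterCriteria,
    MeasureConfig,
    apply_criteria,
    delete_labels,
    elongation,
    mean_and_corrected_diameter,
    measure_all,
    measure_label,
    merge_labels,
    nearest_neighbor_distances,
    parse_edit_list,
    sphericity,
)

from conftest import digitize_ball


def label_stack(mask, dz=1.0):
    return LabelStack(mask.astype(np.int32), 1.0, dz)


def ellipsoid_mask(a, b, c, pad=4):
    nx, ny, nz = int(2 * a) + 2 * pad, int(2 * b) + 2 * pad, int(2 * c) + 2 * pad
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(float)
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    return (
        ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 + ((zz - cz) / c) ** 2
    ) <= 1.0


class TestSphericityElongation:
    def test_sphere_exact(self):
        r = 7.3
        v = 4.0 / 3.0 * np.pi * r**3
        a = 4.0 * np.pi * r**2
        assert sphericity(v, a) == pytest.approx(1.0, abs=1e-12)

    def test_cube_closed_form(self):
        a = 3.7
        s = sphericity(a**3, 6 * a**2)
        assert s == pytest.approx((np.pi / 6.0) ** (1.0 / 3.0), abs=1e-12)

    def test_rod_closed_form(self):
        # cylinder h = k*r: S = 1.6477 * k^(2/3) / (k + 1)
        def cyl(k):
            r = 1.0
            v = np.pi * r**2 * (k * r)
            a = 2 * np.pi * r * (k * r) + 2 * np.pi * r**2
            return sphericity(v, a)

        k = 10.0
        expected = (
            np.pi ** (1 / 3) * (6 * np.pi * k) ** (2 / 3) / (2 * np.pi * (k + 1))
        )
        assert cyl(10.0) == pytest.approx(expected, abs=1e-12)
        # long rods eventually drop below the 0.5 exclusion threshold
        assert cyl(40.0) < 0.5

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sphericity(0.0, 1.0)
        with pytest.raises(ValueError):
            elongation(2.0, 0.0)
        with pytest.raises(ValueError):
            elongation(1.0, 2.0)

    def test_elongation_ratio(self):
        assert elongation(30.0, 10.0) == pytest.approx(3.0)
        assert elongation(5.0, 5.0) == pytest.approx(1.0)


class TestMeasureLabel:
    def test_ball_volume_and_diameters(self):
        ball = digitize_ball(10.0, shape=(25, 25, 25))
        rec = measure_label(label_stack(ball), 1)
        assert rec.volume_vx == pytest.approx(4.0 / 3.0 * np.pi * 1000, rel=0.02)
        assert rec.volume_nm3 == rec.volume_vx
        for d in rec.diam_nm:
            assert d == pytest.approx(20.0, rel=0.05)
        assert 19.0 <= rec.feret_nm <= 21.5
        assert rec.sphericity == pytest.approx(1.0, abs=0.05)
        assert rec.elongation == pytest.approx(1.0, abs=0.05)

    def test_ball_anisotropic_volume(self):
        dz = 1.6
        ball = digitize_ball(10.0, shape=(16, 25, 25), dz=dz)
        rec = measure_label(label_stack(ball, dz=dz), 1)
        assert rec.volume_nm3 == pytest.approx(rec.volume_vx * dz)
        assert rec.volume_nm3 == pytest.approx(4.0 / 3.0 * np.pi * 1000, rel=0.04)

    def test_ellipsoid_ordered_diameters(self):
        mask = ellipsoid_mask(15.0, 10.0, 5.0)
        rec = measure_label(label_stack(mask), 1)
        d1, d2, d3 = rec.diam_nm
        assert d1 >= d2 >= d3 > 0
        assert d1 == pytest.approx(30.0, rel=0.06)
        assert d2 == pytest.approx(20.0, rel=0.06)
        assert d3 == pytest.approx(10.0, rel=0.06)
        assert rec.elongation == pytest.approx(1.5, rel=0.08)

    def test_center_in_nm(self):
        mask = np.zeros((6, 10, 10), dtype=bool)
        mask[2:4, 3:5, 6:8] = True
        rec = measure_label(label_stack(mask, dz=2.0), 1)
        assert rec.center_nm[0] == pytest.approx(6.5)  # x
        assert rec.center_nm[1] == pytest.approx(3.5)  # y
        assert rec.center_nm[2] == pytest.approx(5.0)  # z = 2.5 slices * 2 nm

    def test_single_voxel_valid_record(self):
        mask = np.zeros((3, 5, 5), dtype=bool)
        mask[1, 2, 2] = True
        rec = measure_label(label_stack(mask), 1)
        d1, d2, d3 = rec.diam_nm
        assert d3 > 0
        assert rec.sphericity > 0

    def test_missing_label(self):
        mask = np.zeros((2, 4, 4), dtype=bool)
        mask[0, 0, 0] = True
        with pytest.raises(KeyError):
            measure_label(label_stack(mask), 7)

    def test_feret_at_least_09_d1(self):
        mask = ellipsoid_mask(12.0, 6.0, 4.0)
        rec = measure_label(label_stack(mask), 1)
        assert rec.feret_nm >= rec.diam_nm[0] * 0.9


class TestApplyCriteria:
    def _three_objects(self):
        arr = np.zeros((30, 90, 40), dtype=np.int32)
        ball = digitize_ball(10.0, shape=(30, 30, 40))  # ~4189 vx sphere
        arr[:, 0:30][ball] = 1
        arr[5:8, 35:55, 5:25] = 2  # flat slab: poor sphericity
        small = digitize_ball(4.0, shape=(30, 30, 40))  # ~268 vx
        arr[:, 60:90][small] = 3
        return label_stack(arr)

    def test_rules_and_compaction(self):
        labels = self._three_objects()
        records = measure_all(labels)
        criteria = FilterCriteria(min_volume_vx=3000, min_sphericity=0.5,
                                  max_elongation=2.0)
        new_labels, kept = apply_criteria(records, labels, criteria)
        assert [r.label for r in kept] == [1]
        assert set(np.unique(new_labels.labels)) == {0, 1}
        # voxel conservation against the surviving mask
        assert (new_labels.labels > 0).sum() == kept[0].volume_vx

    def test_idempotent(self):
        labels = self._three_objects()
        records = measure_all(labels)
        criteria = FilterCriteria(min_volume_vx=3000)
        l1, r1 = apply_criteria(records, labels, criteria)
        l2, r2 = apply_criteria(r1, l1, criteria)
        np.testing.assert_array_equal(l1.labels, l2.labels)
        assert len(r1) == len(r2)

    def test_kept_records_satisfy_criteria(self):
        labels = self._three_objects()
        criteria = FilterCriteria(min_volume_vx=100, min_sphericity=0.5,
                                  max_elongation=2.0)
        _, kept = apply_criteria(measure_all(labels), labels, criteria)
        for r in kept:
            assert r.volume_vx >= 100
            assert r.sphericity >= 0.5
            assert r.elongation <= 2.0

    def test_elongation_threshold_is_strict(self):
        crit = FilterCriteria(min_volume_vx=0, min_sphericity=0.0,
                              max_elongation=2.0)
        from vesel.io_formats import VesicleRecord

        def rec(e):
            return VesicleRecord(
                label=1, center_nm=(0, 0, 0), volume_nm3=1.0, volume_vx=1,
                surface_nm2=1.0, feret_nm=1.0, diam_nm=(e, 1.0, 1.0),
                sphericity=1.0, elongation=e,
            )

        assert crit.passes(rec(1.99))
        assert not crit.passes(rec(2.01))


class TestEdits:
    def _two_hemispheres(self):
        ball = digitize_ball(8.0, shape=(20, 20, 20))
        arr = np.zeros_like(ball, dtype=np.int32)
        arr[:, :, :10][ball[:, :, :10]] = 1
        arr[:, :, 10:][ball[:, :, 10:]] = 2
        extra = np.zeros_like(ball, dtype=np.int32)
        return label_stack(arr)

    def test_delete_compacts(self):
        labels = self._two_hemispheres()
        records = measure_all(labels)
        new_labels, kept = delete_labels(labels, records, [1])
        assert [r.label for r in kept] == [1]  # relabeled from 2
        assert set(np.unique(new_labels.labels)) == {0, 1}

    def test_delete_unknown_id(self):
        labels = self._two_hemispheres()
        records = measure_all(labels)
        with pytest.raises(KeyError):
            delete_labels(labels, records, [9])

    def test_merge_conserves_voxels(self):
        labels = self._two_hemispheres()
        records = measure_all(labels)
        total = sum(r.volume_vx for r in records)
        new_labels, kept = merge_labels(labels, records, 1, 2)
        assert len(kept) == 1
        assert kept[0].volume_vx == total
        assert kept[0].sphericity == pytest.approx(1.0, abs=0.06)

    def test_merge_non_adjacent_rejected(self):
        arr = np.zeros((3, 10, 10), dtype=np.int32)
        arr[1, 1, 1] = 1
        arr[1, 8, 8] = 2
        labels = label_stack(arr)
        records = measure_all(labels)
        with pytest.raises(ValueError):
            merge_labels(labels, records, 1, 2)

    def test_parse_edit_list(self):
        edits = parse_edit_list("delete 3\n# comment\nmerge 1 2\n\n")
        assert edits == [("delete", 3), ("merge", 1, 2)]
        with pytest.raises(ValueError):
            parse_edit_list("explode 1")


class TestNeighbors:
    def _records_at(self, centers):
        from vesel.io_formats import VesicleRecord

        return [
            VesicleRecord(
                label=i + 1, center_nm=tuple(c), volume_nm3=1.0, volume_vx=1,
                surface_nm2=1.0, feret_nm=1.0, diam_nm=(1.0, 1.0, 1.0),
                sphericity=1.0, elongation=1.0,
            )
            for i, c in enumerate(centers)
        ]

    def test_two_centers_symmetric(self):
        recs = self._records_at([(0, 0, 0), (50, 0, 0)])
        nearest_neighbor_distances(recs, MeasureConfig(n_neighbors=1))
        assert recs[0].nn_dists_nm == [50.0]
        assert recs[1].nn_dists_nm == [50.0]

    def test_line_example(self):
        recs = self._records_at([(0, 0, 0), (10, 0, 0), (25, 0, 0), (45, 0, 0)])
        nearest_neighbor_distances(recs, MeasureConfig(n_neighbors=2))
        assert recs[0].nn_dists_nm == [10.0, 25.0]
        assert recs[2].nn_dists_nm == [15.0, 20.0]

    def test_zero_neighbors(self):
        recs = self._records_at([(0, 0, 0), (1, 1, 1)])
        nearest_neighbor_distances(recs, MeasureConfig(n_neighbors=0))
        assert recs[0].nn_dists_nm == []

    def test_padding_when_too_few(self):
        recs = self._records_at([(0, 0, 0), (3, 0, 0)])
        nearest_neighbor_distances(recs, MeasureConfig(n_neighbors=3))
        assert recs[0].nn_dists_nm[0] == 3.0
        assert np.isnan(recs[0].nn_dists_nm[1])
        assert len(recs[0].nn_dists_nm) == 3

    def test_matches_brute_force_oracle(self, rng):
        centers = rng.uniform(0, 100, size=(12, 3))
        recs = self._records_at(centers)
        nearest_neighbor_distances(recs, MeasureConfig(n_neighbors=4))
        from scipy.spatial.distance import cdist

        dm = cdist(centers, centers)
        for i, rec in enumerate(recs):
            expected = np.sort(np.delete(dm[i], i))[:4]
            np.testing.assert_allclose(rec.nn_dists_nm, expected, atol=1e-9)

    def test_ascending(self, rng):
        centers = rng.uniform(0, 50, size=(8, 3))
        recs = self._records_at(centers)
        nearest_neighbor_distances(recs, MeasureConfig(n_neighbors=5))
        for rec in recs:
            d = rec.nn_dists_nm
            assert all(d[i] <= d[i + 1] for i in range(len(d) - 1))

    def test_symmetry_crosscheck(self, rng):
        centers = rng.uniform(0, 60, size=(6, 3))
        recs = self._records_at(centers)
        nearest_neighbor_distances(recs, MeasureConfig(n_neighbors=5))
        # if B is among A's neighbors at distance d, d appears in B's list
        from scipy.spatial.distance import cdist

        dm = cdist(centers, centers)
        for i in range(6):
            for d in recs[i].nn_dists_nm:
                j = int(np.argmin(np.abs(dm[i] - d + np.eye(6)[i] * 1e9)))
                assert any(
                    abs(dd - dm[j, i]) < 1e-9 for dd in recs[j].nn_dists_nm
                )


class TestMeanCorrected:
    def _rec(self, diam):
        from vesel.io_formats import VesicleRecord

        return VesicleRecord(
            label=1, center_nm=(0, 0, 0), volume_nm3=1.0, volume_vx=1,
            surface_nm2=1.0, feret_nm=diam[0], diam_nm=diam,
            sphericity=1.0, elongation=diam[0] / diam[1],
        )

    def test_default_membrane_offset(self):
        rec = mean_and_corrected_diameter(self._rec((40.0, 40.0, 40.0)))
        assert rec.mean_diam_nm == pytest.approx(40.0)
        assert rec.corrected_diam_nm == pytest.approx(48.9)

    def test_zero_offset(self):
        rec = mean_and_corrected_diameter(
            self._rec((40.0, 40.0, 40.0)), MeasureConfig(membrane_offset_nm=0.0)
        )
        assert rec.corrected_diam_nm == rec.mean_diam_nm

    def test_arithmetic(self):
        rec = mean_and_corrected_diameter(self._rec((48.0, 42.0, 39.0)))
        assert rec.mean_diam_nm == pytest.approx(43.0)
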