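import numpy as np
import pytest

from cephalo3d.cephalometrics import (
    MEASURE_IDS,
    DegenerateGeometryError,
    FrameError,
    fit_plane_tls,
    frankfort_frame,
    measure_all,
    plane_angle,
    schema,
    three_point_angle,
)
from cephalo3d.imaging_io import LandmarkSet


def _rotation(rng):
    # random rotation via QR of a Gaussian matrix, det forced positive
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _drop(lms: LandmarkSet, *ids):
    entries = {k: v for k, v in lms.entries.items() if k not in ids}
    return LandmarkSet(entries, lms.schema_ids)


class TestSchema:
    def test_counts_and_partition(self):
        defs = schema()
        assert len(defs) == 46
        assert sum(d.laterality == "midline" for d in defs) == 14
        pairs = {(d.id, d.mirror_id) for d in defs if d.laterality == "left"}
        assert len(pairs) == 16
        groups = {g: sum(d.group == g for d in defs) for g in
                  ("dental", "facial-surgery", "skeletal")}
        assert groups == {"dental": 12, "facial-surgery": 9, "skeletal": 25}

    def test_mirror_convention(self):
        by_id = {d.id: d for d in schema()}
        assert by_id["PoL"].mirror_id == "PoR"
        assert by_id["PoR"].mirror_id == "PoL"
        assert by_id["S"].mirror_id is None

    def test_ids_unique(self):
        ids = [d.id for d in schema()]
        assert len(set(ids)) == 46


class TestPlaneFit:
    def test_exact_plane_recovered(self):
        pts = [(0, 0, 5), (1, 0, 5), (0, 1, 5), (3, -2, 5)]
        centroid, normal = fit_plane_tls(pts)
        assert abs(normal[2]) == pytest.approx(1.0)
        assert centroid[2] == pytest.approx(5.0)

    def test_three_points_zero_residual(self):
        pts = np.array([(0, 0, 0), (1, 0, 1), (0, 1, 2)], dtype=float)
        centroid, normal = fit_plane_tls(pts)
        for p in pts:
            assert abs(np.dot(p - centroid, normal)) < 1e-12

    def test_matches_svd_oracle_on_noisy_points(self, rng):
        for _ in range(100):
            n = rng.integers(4, 12)
            base = rng.normal(size=3)
            u, v = rng.normal(size=3), rng.normal(size=3)
            t = rng.normal(size=(n, 2))
            pts = base + t[:, :1] * u + t[:, 1:] * v + 1e-3 * rng.normal(size=(n, 3))
            _, normal = fit_plane_tls(pts)
            centered = pts - pts.mean(axis=0)
            svd_normal = np.linalg.svd(centered)[2][-1]  # independent oracle
            assert min(
                np.linalg.norm(normal - svd_normal), np.linalg.norm(normal + svd_normal)
            ) < 1e-9

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateGeometryError):
            fit_plane_tls([(0, 0, 0), (1, 1, 1)])
        with pytest.raises(DegenerateGeometryError):
            fit_plane_tls([(0, 0, 0), (1, 0, 0), (2, 0, 0)])


class TestAngles:
    def test_right_angle(self):
        assert three_point_angle((0, 10, 0), (0, 0, 0), (10, 0, 0)) == pytest.approx(90.0)

    def test_collinear_is_180(self):
        assert three_point_angle((-1, 0, 0), (0, 0, 0), (5, 0, 0)) == pytest.approx(180.0)

    def test_45_degrees(self):
        assert three_point_angle((1, 0, 0), (0, 0, 0), (1, 1, 0)) == pytest.approx(45.0, abs=1e-9)

    def test_zero_length_ray(self):
        with pytest.raises(DegenerateGeometryError):
            three_point_angle((0, 0, 0), (0, 0, 0), (1, 0, 0))

    def test_plane_angle_constructed(self):
        a = np.radians(10)
        assert plane_angle((0, 0, 1), (0, np.sin(a), np.cos(a))) == pytest.approx(10.0)

    def test_plane_angle_unsigned(self):
        assert plane_angle((0, 0, 1), (0, 0, -1)) == pytest.approx(0.0)
        assert plane_angle((0, 0, 1), (0, 0, 1)) == pytest.approx(0.0)

    def test_plane_angle_rejects_non_unit(self):
        with pytest.raises(ValueError):
            plane_angle((0, 0, 2), (0, 0, 1))


def _frame_set(extra=None, dz=0.0):
    from cephalo3d.cephalometrics import schema_id_list

    coords = {
        "PoL": np.array([-40.0, -60.0, 0.0 + dz]),
        "PoR": np.array([40.0, -60.0, 0.0 + dz]),
        "OrL": np.array([-30.0, 10.0, 0.0 + dz]),
        "OrR": np.array([30.0, 10.0, 0.0 + dz]),
        "N": np.array([0.0, 20.0, 30.0 + dz]),
    }
    coords.update(extra or {})
    return LandmarkSet(coords, tuple(schema_id_list()))


class TestFrankfortFrame:
    def test_planar_configuration_axes(self):
        f = frankfort_frame(_frame_set())
        np.testing.assert_allclose(f.superior, [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(f.anterior, [0, 1, 0], atol=1e-12)

    def test_translation_invariance(self):
        f0 = frankfort_frame(_frame_set())
        f7 = frankfort_frame(_frame_set(dz=7.0))
        np.testing.assert_allclose(f7.superior, f0.superior, atol=1e-12)
        np.testing.assert_allclose(f7.anterior, f0.anterior, atol=1e-12)
        np.testing.assert_allclose(f7.fh_point - f0.fh_point, [0, 0, 7], atol=1e-12)

    def test_rotation_equivariance(self, rng):
        base = _frame_set()
        f0 = frankfort_frame(base)
        for _ in range(10):
            rot = _rotation(rng)
            rotated = base.transformed(lambda p: rot @ p)
            f = frankfort_frame(rotated)
            np.testing.assert_allclose(f.superior, rot @ f0.superior, atol=1e-9)
            np.testing.assert_allclose(f.anterior, rot @ f0.anterior, atol=1e-9)
            np.testing.assert_allclose(f.lateral, rot @ f0.lateral, atol=1e-9)

    def test_three_point_fallback_and_failure(self):
        f = frankfort_frame(_drop(_frame_set(), "PoL"))
        np.testing.assert_allclose(abs(f.superior[2]), 1.0, atol=1e-9)
        with pytest.raises(FrameError):
            frankfort_frame(_drop(_frame_set(), "PoL", "OrL"))

    def test_orthonormal_triad(self):
        f = frankfort_frame(_frame_set())
        triad = np.stack([f.anterior, f.lateral, f.superior])
        np.testing.assert_allclose(triad @ triad.T, np.eye(3), atol=1e-9)


class TestMeasures:
    def test_345_mandibular_length(self, full46_landmarks):
        entries = dict(full46_landmarks.entries)
        entries["CoL"] = entries["Gn"] + np.array([3.0, 4.0, 0.0])
        lms = LandmarkSet(entries, full46_landmarks.schema_ids)
        report = measure_all(lms)
        assert report.value("left_effective_mandibular_length") == pytest.approx(5.0)

    def test_parallel_planes_give_zero_mandibular_angle(self):
        lms = _frame_set(
            {
                "Me": np.array([0.0, -80.0, -40.0]),
                "GoL": np.array([-40.0, -50.0, -40.0]),
                "GoR": np.array([40.0, -50.0, -40.0]),
            }
        )
        report = measure_all(lms)
        assert report.value("mandibular_plane_angle") == pytest.approx(0.0, abs=1e-9)

    def test_all_16_present_exactly_once(self, full46_landmarks):
        report = measure_all(full46_landmarks)
        assert tuple(report.measures) == MEASURE_IDS
        assert all(m.available for m in report.measures.values())

    def test_vector_components_match_hand_computed_projections(self, full46_landmarks):
        report = measure_all(full46_landmarks)
        f = frankfort_frame(full46_landmarks)
        g = full46_landmarks.get
        assert report.value("nasion_perpendicular_to_A") == pytest.approx(
            float(np.dot(g("A") - g("N"), f.anterior)), abs=1e-9
        )
        assert report.value("pogonion_to_nasion_perpendicular") == pytest.approx(
            float(np.dot(g("Pog") - g("N"), f.anterior)), abs=1e-9
        )
        assert report.value("left_upper_incisor_A_vertical") == pytest.approx(
            float(np.dot(g("UIEL") - g("A"), f.anterior)), abs=1e-9
        )
        # lower incisor offset: independent formula via projection removal
        a, pog, lie = g("A"), g("Pog"), g("LIEL")
        u = (pog - a) / np.linalg.norm(pog - a)
        off = (lie - a) - np.dot(lie - a, u) * u
        expected = np.sign(np.dot(off, f.anterior)) * np.linalg.norm(off)
        assert report.value("left_lower_incisor_to_A_pog_line") == pytest.approx(
            float(expected), abs=1e-9
        )

    def test_sna_snb_difference_signed(self, full46_landmarks):
        report = measure_all(full46_landmarks)
        assert report.value("SNA_minus_SNB") == pytest.approx(
            report.value("SNA") - report.value("SNB"), abs=1e-12
        )

    def test_rigid_invariance_except_true_horizontal(self, full46_landmarks, rng):
        base = measure_all(full46_landmarks)
        for _ in range(20):
            rot = _rotation(rng)
            t = rng.uniform(-30, 30, size=3)
            moved = full46_landmarks.transformed(lambda p: rot @ p + t)
            report = measure_all(moved)
            for mid in MEASURE_IDS:
                if mid == "frankfort_horizontal_angle":
                    continue
                assert report.value(mid) == pytest.approx(base.value(mid), abs=1e-6), mid

    def test_true_horizontal_angle_tracks_rotation(self, full46_landmarks):
        a = np.radians(25.0)
        rot = np.array(
            [[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]]
        )
        moved = full46_landmarks.transformed(lambda p: rot @ p)
        base = measure_all(full46_landmarks)
        report = measure_all(moved)
        shift = report.value("frankfort_horizontal_angle") - base.value(
            "frankfort_horizontal_angle"
        )
        assert abs(shift) == pytest.approx(25.0, abs=1e-6)

    def test_mirror_swaps_left_right_measures(self, full46_landmarks):
        from cephalo3d.cephalometrics import schema as _schema

        center_x = 76.0
        mirror_of = {d.id: (d.mirror_id or d.id) for d in _schema()}
        mirrored = {
            mirror_of[lid]: np.array([2 * center_x - c[0], c[1], c[2]])
            for lid, c in full46_landmarks.entries.items()
        }
        mset = LandmarkSet(mirrored, full46_landmarks.schema_ids)
        base = measure_all(full46_landmarks)
        flip = measure_all(mset)
        swaps = {
            "left_effective_mandibular_length": "right_effective_mandibular_length",
            "left_effective_midfacial_length": "right_effective_midfacial_length",
            "left_upper_incisor_A_vertical": "right_upper_incisor_A_vertical",
            "left_lower_incisor_to_A_pog_line": "right_lower_incisor_to_A_pog_line",
        }
        for left, right in swaps.items():
            assert flip.value(left) == pytest.approx(base.value(right), abs=1e-9)
            assert flip.value(right) == pytest.approx(base.value(left), abs=1e-9)
        for mid in ("anterior_facial_height", "SNA", "SNB", "mandibular_plane_angle"):
            assert flip.value(mid) == pytest.approx(base.value(mid), abs=1e-9)

    def test_absence_propagation(self, full46_landmarks):
        # one Porion missing: frame still works
        r1 = measure_all(_drop(full46_landmarks, "PoL"))
        assert r1.measures["nasion_perpendicular_to_A"].available
        # a Porion and an Orbitale missing: frame-dependent measures out,
        # point-to-point measures survive
        r2 = measure_all(_drop(full46_landmarks, "PoL", "OrL"))
        assert not r2.measures["nasion_perpendicular_to_A"].available
        assert not r2.measures["mandibular_plane_angle"].available
        assert not r2.measures["frankfort_horizontal_angle"].available
        assert r2.measures["anterior_facial_height"].available
        assert r2.measures["SNA"].available
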