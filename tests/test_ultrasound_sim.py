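"""Scan-line layout, crossover search, grey filling, scan conversion."""

import numpy as np
import pytest
import trimesh

from fetalecho.heart_model import (HeartModel, Material, MaterialTable, Pose,
                                   Structure, apply_pose, compose)
from fetalecho.ultrasound_sim import (ProbeConfig, ScanLine, SimulationError,
                                      add_speckle, build_index,
                                      compute_scanlines, default_materials,
                                      fill_scanline, intersect, scan_convert,
                                      simulate)

from conftest import make_sphere_model, random_rigid_pose


def nested_spheres(r_in=5.0, r_out=8.0, center=(0.0, 20.0, 0.0)):
    inner = trimesh.creation.icosphere(4, r_in)
    outer = trimesh.creation.icosphere(4, r_out)
    inner.apply_translation(center)
    outer.apply_translation(center)
    return HeartModel([Structure("outer", outer, "artery", 1),
                       Structure("inner", inner, "chamber", 2)])


OFFAXIS = np.array([0.37, 0.0, 0.13])  # avoids icosphere pole degeneracy


def winding_inside(mesh, points):
    """Independent point-in-mesh oracle: generalized winding number via
    summed signed solid angles (van Oosterom-Strackee), no ray casting."""
    tris = mesh.triangles
    out = np.empty(len(points), dtype=bool)
    for i, p in enumerate(points):
        a = tris[:, 0] - p
        b = tris[:, 1] - p
        c = tris[:, 2] - p
        la = np.linalg.norm(a, axis=1)
        lb = np.linalg.norm(b, axis=1)
        lc = np.linalg.norm(c, axis=1)
        num = np.einsum("ij,ij->i", a, np.cross(b, c))
        den = (la * lb * lc + np.einsum("ij,ij->i", a, b) * lc
               + np.einsum("ij,ij->i", b, c) * la
               + np.einsum("ij,ij->i", a, c) * lb)
        w = np.sum(2.0 * np.arctan2(num, den)) / (4.0 * np.pi)
        out[i] = abs(w) > 0.5
    return out


class TestScanlines:
    def test_linear_two_lines_span_footprint(self):
        probe = ProbeConfig(kind="linear", n_scanlines=2, footprint_mm=10.0,
                            fov_deg=None, transducer_radius_mm=None)
        lines = compute_scanlines(probe)
        assert np.linalg.norm(lines[1].origin - lines[0].origin) == \
            pytest.approx(10.0)
        for l in lines:
            np.testing.assert_allclose(l.direction, [0, 1, 0])

    def test_linear_single_line_on_axis(self):
        probe = ProbeConfig(kind="linear", n_scanlines=1, footprint_mm=10.0,
                            fov_deg=None, transducer_radius_mm=None)
        (line,) = compute_scanlines(probe)
        np.testing.assert_allclose(line.origin, [0, 0, 0])

    def test_curvilinear_even_angles(self):
        probe = ProbeConfig(kind="curvilinear", n_scanlines=61, fov_deg=60.0,
                            transducer_radius_mm=30.0)
        lines = compute_scanlines(probe)
        angles = np.degrees([np.arctan2(l.direction[0], l.direction[1])
                             for l in lines])
        np.testing.assert_allclose(np.diff(angles), 1.0, atol=1e-9)
        # origins sit on the transducer arc through the contact point
        for l in lines:
            r = np.linalg.norm(l.origin - np.array([0, -30.0, 0]))
            assert r == pytest.approx(30.0, abs=1e-9)

    def test_left_to_right_ordering(self):
        probe = ProbeConfig(n_scanlines=11)
        xs = [l.origin[0] for l in compute_scanlines(probe)]
        assert xs == sorted(xs)


class TestIntersect:
    def test_sphere_analytic_distances(self):
        model = make_sphere_model(radius=5.0, center=(0, 20, 0),
                                  subdivisions=5)
        index = build_index(model)
        line = ScanLine(OFFAXIS, np.array([0.0, 1.0, 0.0]), 40.0, 0.2)
        crossings = intersect(index, line)
        assert [c.entering for c in crossings] == [True, False]
        chord = np.sqrt(5.0 ** 2 - OFFAXIS[0] ** 2 - OFFAXIS[2] ** 2)
        # icosphere at subdivision 5 approximates the sphere to ~0.2%
        assert crossings[0].distance_mm == pytest.approx(20 - chord, abs=0.02)
        assert crossings[1].distance_mm == pytest.approx(20 + chord, abs=0.02)

    def test_miss_returns_empty(self):
        model = make_sphere_model(radius=5.0, center=(0, 20, 0))
        line = ScanLine(np.array([30.0, 0.0, 0.0]),
                        np.array([0.0, 1.0, 0.0]), 40.0, 0.2)
        assert intersect(build_index(model), line) == []

    def test_nested_spheres_four_crossings(self):
        model = nested_spheres()
        line = ScanLine(OFFAXIS, np.array([0.0, 1.0, 0.0]), 40.0, 0.2)
        crossings = intersect(build_index(model), line)
        assert [c.structure for c in crossings] == \
            ["outer", "inner", "inner", "outer"]
        expected = [20 - 8, 20 - 5, 20 + 5, 20 + 8]
        got = [c.distance_mm for c in crossings]
        np.testing.assert_allclose(got, expected, atol=0.03)
        # per-structure alternation
        assert [c.entering for c in crossings] == [True, True, False, False]


class TestOracleEquivalence:
    @pytest.mark.parametrize("case", ["normal", "double_aortic_arch",
                                      "hrh_vsd_mga_pa"])
    def test_bvh_equals_brute_force(self, case_hearts, case):
        """The defining contract of the spatial index: accelerated
        crossings match all-triangle brute force to 1e-9 mm with the same
        structure tags, on hundreds of random rays per case model."""
        index = build_index(case_hearts[case])
        rng = np.random.default_rng(hash(case) % (2 ** 31))
        lo, hi = case_hearts[case].bounds()
        for _ in range(350):
            origin = rng.uniform(lo - 10, hi + 10)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            fast = index.query(origin, direction, 0.0, 120.0)
            slow = index.query_brute(origin, direction, 0.0, 120.0)
            assert len(fast) == len(slow)
            for f, s in zip(fast, slow):
                assert abs(f.distance_mm - s.distance_mm) <= 1e-9
                assert f.structure == s.structure
                assert f.entering == s.entering

    def test_parity_even_for_closed_structures(self, normal_heart):
        """Rays starting and ending outside a closed structure cross its
        surface an even number of times."""
        index = build_index(normal_heart)
        rng = np.random.default_rng(42)
        center = normal_heart.bounds().mean(axis=0)
        for _ in range(200):
            # origin on a sphere far outside the anatomy, ray through it
            u = rng.normal(size=3)
            origin = center + 70.0 * u / np.linalg.norm(u)
            target = center + rng.uniform(-12, 12, size=3)
            direction = target - origin
            direction /= np.linalg.norm(direction)
            crossings = index.query(origin, direction, 0.0, 200.0)
            per_structure: dict[str, int] = {}
            for c in crossings:
                per_structure[c.structure] = per_structure.get(c.structure, 0) + 1
            for name, count in per_structure.items():
                assert count % 2 == 0, (name, count)

    def test_crossings_consistent_with_winding_number(self):
        """Between consecutive crossings the containment state inferred
        from the crossing list matches an independent winding-number
        point-in-mesh oracle."""
        model = nested_spheres()
        index = build_index(model)
        rng = np.random.default_rng(3)
        checked = 0
        for _ in range(12):
            origin = np.array([rng.uniform(-11, 11), -5.0,
                               rng.uniform(-11, 11)])
            direction = np.array([0.02, 1.0, -0.015])
            direction /= np.linalg.norm(direction)
            crossings = index.query(origin, direction, 0.0, 60.0)
            edges = [0.0] + [c.distance_mm for c in crossings] + [60.0]
            mids = 0.5 * (np.array(edges[:-1]) + np.array(edges[1:]))
            pts = origin + np.outer(mids, direction)
            for name in ("outer", "inner"):
                mesh = model.get(name).mesh
                oracle = winding_inside(mesh, pts)
                state = False
                states = []
                k = 0
                for c in crossings:
                    states.append(state)
                    if c.structure == name:
                        state = c.entering
                states.append(state)
                np.testing.assert_array_equal(np.array(states), oracle,
                                              err_msg=name)
                checked += len(states)
        assert checked > 50


class TestFillScanline:
    def _line(self, depth=40.0, ds=0.2):
        return ScanLine(np.zeros(3), np.array([0.0, 1.0, 0.0]), depth, ds)

    def test_empty_crossings_background(self):
        model = make_sphere_model(radius=2.0, center=(30, 0, 30))
        index = build_index(model)
        mats = default_materials()
        inten, labels = fill_scanline([], self._line(), index, mats)
        assert np.all(inten == mats.background.grey_value)
        assert np.all(labels == 0)

    def test_single_structure_band(self):
        model = make_sphere_model(radius=5.0, center=(0, 20, 0),
                                  subdivisions=5, material="chamber")
        index = build_index(model)
        mats = MaterialTable({"chamber": Material("chamber", 200)},
                             background=Material("background", 0))
        line = ScanLine(OFFAXIS, np.array([0.0, 1.0, 0.0]), 40.0, 0.1)
        inten, labels = fill_scanline(intersect(index, line), line, index, mats)
        d = line.sample_distances()
        chord = np.sqrt(25 - OFFAXIS[0] ** 2 - OFFAXIS[2] ** 2)
        inside = (d > 20 - chord + 0.05) & (d < 20 + chord - 0.05)
        outside = (d < 20 - chord - 0.05) | (d > 20 + chord + 0.05)
        assert np.all(inten[inside] == 200)
        assert np.all(inten[outside] == 0)

    def test_nested_banding_matches_pointwise_oracle(self):
        """Nested spheres produce 0|outer|inner|outer|0 banding identical
        to an independent per-sample point-in-mesh classification."""
        model = nested_spheres()
        index = build_index(model)
        mats = MaterialTable(
            {"artery": Material("artery", 200),
             "chamber": Material("chamber", 30)},
            background=Material("background", 0))
        line = ScanLine(OFFAXIS, np.array([0.0, 1.0, 0.0]), 40.0, 0.25)
        inten, labels = fill_scanline(intersect(index, line), line, index, mats)
        pts = line.origin + np.outer(line.sample_distances(), line.direction)
        expected = np.zeros(len(pts))
        in_outer = winding_inside(model.get("outer").mesh, pts)
        in_inner = winding_inside(model.get("inner").mesh, pts)
        expected[in_outer] = 200
        expected[in_inner] = 30  # inner has higher priority
        np.testing.assert_array_equal(inten, expected)

    def test_origin_inside_structure(self):
        """A probe origin inside a structure is legal: parity state is
        seeded by a point-in-mesh test."""
        model = make_sphere_model(radius=6.0, center=(0, 0, 0),
                                  material="chamber")
        index = build_index(model)
        mats = default_materials()
        line = ScanLine(np.array([0.2, 0.0, 0.1]),
                        np.array([0.0, 1.0, 0.0]), 20.0, 0.2)
        inten, labels = fill_scanline(intersect(index, line), line, index, mats)
        d = line.sample_distances()
        assert np.all(labels[d < 5.8] == 1)
        assert np.all(labels[d > 6.2] == 0)

    def test_inconsistent_parity_detected(self):
        """A surface patch that cannot alternate enter/exit flags signals
        a broken (non-watertight) mesh."""
        from fetalecho.ultrasound_sim import Crossing
        model = make_sphere_model(radius=5.0, center=(0, 20, 0))
        index = build_index(model)
        bogus = [Crossing(10.0, "S", True), Crossing(12.0, "S", True),
                 Crossing(14.0, "S", False)]
        with pytest.raises(SimulationError, match="parity"):
            fill_scanline(bogus, self._line(), index, default_materials())

    def test_attenuation_monotone_decay(self):
        """Inside a homogeneous attenuating block, intensity never
        increases with depth."""
        box = trimesh.creation.box(extents=(30, 30, 30))
        box.apply_translation([0, 20, 0])
        model = HeartModel([Structure("B", box, "gel", 1)])
        index = build_index(model)
        mats = MaterialTable({"gel": Material("gel", 220, 0.05)},
                             background=Material("background", 0))
        line = ScanLine(np.array([0.3, 0.0, 0.2]),
                        np.array([0.0, 1.0, 0.0]), 38.0, 0.1)
        inten, _ = fill_scanline(intersect(index, line), line, index, mats)
        d = line.sample_distances()
        inside = (d > 5.5) & (d < 34.5)
        assert np.all(np.diff(inten[inside]) <= 1e-12)
        assert inten[inside][-1] < inten[inside][0]


class TestScanConvert:
    def test_uniform_field_uniform_image(self):
        probe = ProbeConfig(n_scanlines=60, samples_per_line=80,
                            image_width_px=100, image_height_px=100,
                            pixel_spacing_mm=0.6)
        data = np.full((60, 80), 123.0)
        img = scan_convert(data, probe)
        inside = img > 0
        assert inside.any()
        assert np.all(img[inside] == pytest.approx(123.0))

    def test_linear_identity_mapping(self):
        """With samples aligned to pixel rows and lines to pixel columns,
        nearest-neighbour scan conversion is an exact identity."""
        h = w = 64
        ps = 0.5
        probe = ProbeConfig(kind="linear", n_scanlines=w,
                            samples_per_line=h, image_width_px=w,
                            image_height_px=h, pixel_spacing_mm=ps,
                            scanline_depth_mm=h * ps,
                            footprint_mm=(w - 1) * ps,
                            fov_deg=None, transducer_radius_mm=None,
                            interpolation="nearest")
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 255, size=(w, h))
        img = scan_convert(data, probe)
        np.testing.assert_array_equal(img, data.T)

    def test_curvilinear_corners_outside_fan(self):
        probe = ProbeConfig(n_scanlines=40, samples_per_line=50,
                            image_width_px=120, image_height_px=120,
                            pixel_spacing_mm=0.5, fov_deg=45.0)
        img = scan_convert(np.full((40, 50), 200.0), probe, fill=0.0)
        assert img[0, 0] == 0.0
        assert img[0, -1] == 0.0
        assert img[-1, 0] == 0.0

    def test_mismatched_line_count_rejected(self):
        probe = ProbeConfig(n_scanlines=40, samples_per_line=50)
        with pytest.raises(ValueError, match="shape"):
            scan_convert(np.zeros((41, 50)), probe)


class TestSimulate:
    def test_sphere_area_fraction(self):
        """Foreground pixel fraction of a sphere in a linear-probe
        rectangle matches the analytic circle area within 2%."""
        probe = ProbeConfig(kind="linear", n_scanlines=200,
                            samples_per_line=200, image_width_px=200,
                            image_height_px=200, pixel_spacing_mm=0.2,
                            scanline_depth_mm=40.0, footprint_mm=40.0,
                            fov_deg=None, transducer_radius_mm=None)
        model = make_sphere_model(radius=8.0, center=(0, 20, 0),
                                  subdivisions=4)
        _, label = simulate(model, Pose.identity(), probe)
        frac = (label.pixels > 0).mean()
        assert frac == pytest.approx(np.pi * 64 / (40 * 40), rel=0.02)

    def test_resolution_consistency(self):
        """Doubling samples_per_line changes the measured area fraction by
        less than 1%."""
        base = dict(kind="linear", n_scanlines=150, image_width_px=150,
                    image_height_px=150, pixel_spacing_mm=0.25,
                    scanline_depth_mm=37.5, footprint_mm=37.5,
                    fov_deg=None, transducer_radius_mm=None)
        model = make_sphere_model(radius=8.0, center=(0, 18, 0),
                                  subdivisions=4)
        fracs = []
        for spl in (150, 300):
            probe = ProbeConfig(samples_per_line=spl, **base)
            _, label = simulate(model, Pose.identity(), probe)
            fracs.append((label.pixels > 0).mean())
        assert abs(fracs[1] - fracs[0]) / fracs[0] < 0.01

    def test_frame_invariance(self, normal_heart, fast_probe):
        """simulate(T*model, T*pose) is pixel-identical to
        simulate(model, pose) for random rigid T (nearest interpolation)."""
        import dataclasses
        probe = dataclasses.replace(fast_probe, interpolation="nearest")
        views = __import__("fetalecho.views", fromlist=["standard_views"])
        pose = views.standard_views()["four_chamber"].pose
        img0, lab0 = simulate(normal_heart, pose, probe)
        rng = np.random.default_rng(123)
        for _ in range(3):
            T = random_rigid_pose(rng)
            moved = apply_pose(normal_heart, T)
            img1, lab1 = simulate(moved, compose(T, pose), probe)
            np.testing.assert_array_equal(img0.pixels, img1.pixels)
            np.testing.assert_array_equal(lab0.pixels, lab1.pixels)

    def test_four_chamber_labels_present(self, normal_heart, fast_probe):
        from fetalecho.views import standard_views
        pose = standard_views()["four_chamber"].pose
        _, label = simulate(normal_heart, pose, fast_probe)
        names = {label.label_map[l] for l in np.unique(label.pixels) if l}
        assert {"LA", "RA", "LV", "RV"} <= names

    def test_deterministic_without_speckle(self, normal_heart, fast_probe):
        from fetalecho.views import standard_views
        pose = standard_views()["lvot"].pose
        a, _ = simulate(normal_heart, pose, fast_probe)
        b, _ = simulate(normal_heart, pose, fast_probe)
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestSpeckle:
    def _image(self):
        probe = ProbeConfig(kind="linear", n_scanlines=64, samples_per_line=64,
                            image_width_px=64, image_height_px=64,
                            pixel_spacing_mm=0.5, scanline_depth_mm=32.0,
                            footprint_mm=32.0, fov_deg=None,
                            transducer_radius_mm=None)
        from fetalecho.ultrasound_sim import BModeImage
        return BModeImage(np.full((64, 64), 128, dtype=np.uint8), 0.5,
                          Pose.identity(), probe)

    def test_sd_zero_identity(self):
        img = self._image()
        out = add_speckle(img, seed=1, sd=0.0)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_seeded_reproducible(self):
        img = self._image()
        a = add_speckle(img, seed=9, sd=0.1)
        b = add_speckle(img, seed=9, sd=0.1)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        c = add_speckle(img, seed=10, sd=0.1)
        assert not np.array_equal(a.pixels, c.pixels)

    def test_mean_preserved(self):
        img = self._image()
        out = add_speckle(img, seed=2, sd=0.1)
        drift = abs(out.pixels.mean() - 128.0) / 128.0
        assert drift < 0.02
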