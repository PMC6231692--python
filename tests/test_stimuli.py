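"""Contour synthesis, straightening, rendering and set-level invariants."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from shapersa import stimuli as st


def circle(radius=1.0):
    return st.ContourDescriptor(radius, [])


class TestIrregularContours:
    def test_zero_harmonics_gives_circle(self):
        shape = st.make_irregular_contour(circle(2.0), 256)
        r = np.linalg.norm(shape.vertices - shape.vertices.mean(axis=0), axis=1)
        assert np.allclose(r, 2.0, atol=1e-9)

    def test_single_harmonic_curvature_alternations(self):
        # one frequency-2 harmonic: curvature alternates through 2 maxima and
        # 2 minima (4 sign changes of the curvature derivative per revolution)
        d = st.ContourDescriptor(1.0, [(2, 0.2, 0.0)])
        shape = st.make_irregular_contour(d, 2048)
        ext = st.curvature_extrema(shape.vertices)
        assert len(ext) == 4

    def test_determinism(self):
        d = st.ContourDescriptor(1.0, [(3, 0.15, 0.4), (5, 0.05, 1.0)])
        a = st.make_irregular_contour(d, 512, seed=3)
        b = st.make_irregular_contour(d, 512, seed=3)
        assert np.array_equal(a.vertices, b.vertices)

    def test_negative_radius_rejected(self):
        d = st.ContourDescriptor(1.0, [(2, 1.5, 0.0)])
        with pytest.raises(ValueError):
            st.make_irregular_contour(d, 256)

    def test_descriptor_invariants(self):
        with pytest.raises(ValueError):
            st.ContourDescriptor(1.0, [(2, 0.1, 0.0), (2, 0.2, 0.0)])  # dup freq
        with pytest.raises(ValueError):
            st.ContourDescriptor(1.0, [(0, 0.1, 0.0)])  # non-positive freq
        with pytest.raises(ValueError):
            st.ContourDescriptor(1.0, [(2, -0.1, 0.0)])  # negative amp


class TestComplexify:
    BASE = st.ContourDescriptor(1.0, [(2, 0.15, 0.1), (3, 0.1, 1.2), (4, 0.06, 2.0)])

    def test_cardinality_and_frequency_contract(self):
        out = st.complexify(self.BASE, 4, 12, seed=0)
        assert len(out.harmonics) == 7
        assert self.BASE.max_frequency < out.max_frequency <= 12

    def test_zero_added_rejected(self):
        with pytest.raises(ValueError):
            st.complexify(self.BASE, 0, 12)

    def test_max_frequency_must_increase(self):
        with pytest.raises(ValueError):
            st.complexify(self.BASE, 2, 4)

    @pytest.mark.parametrize("seed", range(20))
    def test_boundary_complexity_increases(self, seed):
        # isoperimetric ratio perimeter^2 / (4 pi area) strictly increases
        out = st.complexify(self.BASE, 4, 12, seed=seed)
        def ratio(desc):
            p = Polygon(st.make_irregular_contour(desc, 1024).vertices)
            return p.length**2 / (4 * np.pi * p.area)
        assert ratio(out) > ratio(self.BASE)


class TestPerturbPair:
    BASE = st.ContourDescriptor(1.0, [(2, 0.15, 0.1), (4, 0.08, 1.2)])

    def test_zero_magnitude_rejected(self):
        with pytest.raises(ValueError):
            st.perturb_pair(self.BASE, "phase", 0.0)

    def test_amplitude_mode_isolates_field(self):
        out = st.perturb_pair(self.BASE, "amplitude", 0.3, seed=1)
        assert [h[0] for h in out.harmonics] == [h[0] for h in self.BASE.harmonics]
        assert [h[2] for h in out.harmonics] == [h[2] for h in self.BASE.harmonics]
        assert any(h[1] != g[1] for h, g in zip(out.harmonics, self.BASE.harmonics))

    def test_phase_mode_isolates_field(self):
        out = st.perturb_pair(self.BASE, "phase", 0.5, seed=1)
        assert [h[:2] for h in out.harmonics] == [h[:2] for h in self.BASE.harmonics]
        assert all(h[2] != g[2] for h, g in zip(out.harmonics, self.BASE.harmonics))

    def test_frequency_mode_keeps_count(self):
        out = st.perturb_pair(self.BASE, "frequency", 1.0, seed=1)
        assert len(out.harmonics) == len(self.BASE.harmonics)
        assert {h[0] for h in out.harmonics} != {h[0] for h in self.BASE.harmonics}

    def test_perturbed_rendering_differs(self):
        out = st.perturb_pair(self.BASE, "phase", 0.6, seed=2)
        a = st.render(st.make_irregular_contour(self.BASE, 512), 64, scale_factor=20)
        b = st.render(st.make_irregular_contour(out, 512), 64, scale_factor=20)
        assert st.pixel_distance(a, b) > 0


class TestStraighten:
    def test_circle_has_no_extrema(self):
        shape = st.make_irregular_contour(circle(), 512)
        with pytest.raises(ValueError):
            st.straighten_contour(shape)

    def test_three_lobed_contour_gives_hexagon(self):
        # frequency-3 harmonic: 3 curvature maxima + 3 minima -> hexagon
        d = st.ContourDescriptor(1.0, [(3, 0.15, 0.0)])
        shape = st.make_irregular_contour(d, 1024)
        ext = st.curvature_extrema(shape.vertices)
        out = st.straighten_contour(shape)
        assert len(out.vertices) == 6
        # retained vertices are exactly input extremum points
        assert np.allclose(out.vertices, shape.vertices[ext])

    def test_output_is_straight_between_vertices(self):
        d = st.ContourDescriptor(1.0, [(3, 0.15, 0.0), (5, 0.05, 0.7)])
        out = st.straighten_contour(st.make_irregular_contour(d, 1024))
        assert out.boundary_style == "straight"
        dense = st.ContourShape(st._densify(out.vertices, 512), "straight")
        kappa = st.discrete_curvature(dense.vertices)
        # curvature is concentrated at the retained corners; edges are flat
        assert np.median(np.abs(kappa)) < 1e-9

    def test_idempotent_on_own_output(self):
        d = st.ContourDescriptor(1.0, [(3, 0.15, 0.0), (5, 0.05, 0.7)])
        once = st.straighten_contour(st.make_irregular_contour(d, 1024))
        twice = st.straighten_contour(once)
        assert np.array_equal(once.vertices, twice.vertices)


class TestRegularShapes:
    def test_square_has_zero_edge_curvature(self):
        sq = st.make_regular_shape("straight_contour", dict(n_sides=4, size=1.0))
        kappa = st.discrete_curvature(sq.vertices)
        assert np.median(np.abs(kappa)) < 1e-9

    def test_parallelism_contrast(self):
        # oracle: detect the 4 corners from curvature spikes, then compare
        # the directions of opposite edges
        a, b = st.regular_pair(1, magnitude=1.0)

        def min_opposite_edge_cross(shape):
            v = shape.vertices
            kappa = np.abs(st.discrete_curvature(v))
            spike = np.where(kappa > 0.5 * kappa.max())[0]
            # cluster consecutive spike indices into corner representatives
            corners = []
            for i in spike:
                if corners and i - corners[-1][-1] <= 2:
                    corners[-1].append(i)
                else:
                    corners.append([i])
            pts = np.array([v[c].mean(axis=0) for c in corners])
            assert len(pts) == 4
            edges = np.roll(pts, -1, axis=0) - pts
            edges = edges / np.linalg.norm(edges, axis=1, keepdims=True)
            crosses = [abs(edges[i, 0] * edges[i + 2, 1] - edges[i, 1] * edges[i + 2, 0])
                       for i in range(2)]
            return max(crosses)

        assert min_opposite_edge_cross(a) < 1e-6   # rectangle: both pairs parallel
        assert min_opposite_edge_cross(b) > 0.05   # trapezoid: one pair not

    def test_vertical_symmetry(self):
        for j in range(1, 9):
            a, b = st.regular_pair(j, magnitude=1.0)
            assert st.symmetry_axis_error(a) < 0.02, j
            assert st.symmetry_axis_error(b) < 0.02, j

    def test_unsupported_kind(self):
        with pytest.raises(ValueError):
            st.make_regular_shape("spiral", {})


class TestRender:
    SHAPE = st.make_irregular_contour(st.ContourDescriptor(1.0, [(3, 0.1, 0.0)]), 512)

    def test_binary_two_levels(self):
        img = st.render(self.SHAPE, 64, fill_level=255, background_level=128,
                        scale_factor=20)
        assert set(np.unique(img.pixels)) == {128, 255}

    def test_area_scales_quadratically(self):
        img1 = st.render(self.SHAPE, 128, scale_factor=40)
        img2 = st.render(self.SHAPE, 128, scale_factor=20)
        a1 = (img1.pixels == 255).sum()
        a2 = (img2.pixels == 255).sum()
        assert abs(a2 / a1 - 0.25) < 0.05 * 0.25 + 0.01

    def test_determinism_and_fit_errors(self):
        i1 = st.render(self.SHAPE, 64, scale_factor=20)
        i2 = st.render(self.SHAPE, 64, scale_factor=20)
        assert np.array_equal(i1.pixels, i2.pixels)
        with pytest.raises(ValueError):
            st.render(self.SHAPE, 64, scale_factor=100)
        with pytest.raises(ValueError):
            st.render(self.SHAPE, 64, fill_level=128, background_level=128)

    def test_foreground_connected(self):
        from scipy.ndimage import label
        img = st.render(self.SHAPE, 96, scale_factor=30)
        _, n = label(img.pixels == 255)
        assert n == 1


class TestShapeSet:
    def test_structure_and_metadata(self, shape_set):
        assert len(shape_set.stimuli) == 64
        labels = {(s.group, s.pair_index, s.member) for s in shape_set.stimuli}
        assert len(labels) == 64
        for s in shape_set.stimuli:
            assert s.stimulus_id == f"{s.group}{s.pair_index:02d}{s.member}"

    def test_iss_members_are_straightened_isc_contours(self, shape_set):
        for j in range(1, 9):
            for m in "ab":
                s = shape_set.get("ISS", j, m)
                assert s.shape.boundary_style == "straight"
                assert s.descriptor is not None  # ISC-family source descriptor

    def test_all_contours_simple_with_positive_area(self, shape_set):
        for s in shape_set.stimuli:
            assert s.shape.is_simple()
            assert s.shape.area > 0

    def test_column_matching(self, shape_set):
        tol = shape_set.config.matching_tolerance
        for j, target in shape_set.column_matching.items():
            for g in st.GROUPS:
                for m in "ab":
                    sh = shape_set.get(g, j, m).shape
                    assert abs(sh.area - target["area"]) / target["area"] < tol
                    ar = st.contour_aspect(sh.vertices)
                    assert abs(ar - target["aspect"]) / target["aspect"] < tol

    def test_seed_determinism(self):
        a = st.build_shape_set(seed=3)
        b = st.build_shape_set(seed=3)
        for sa, sb in zip(a.stimuli, b.stimuli):
            assert np.array_equal(sa.image.pixels, sb.image.pixels)

    def test_save_roundtrip(self, shape_set, tmp_path):
        import json
        manifest_path = st.save_shape_set(shape_set, tmp_path)
        manifest = json.loads(manifest_path.read_text())
        assert len(manifest["stimuli"]) == 64
        from PIL import Image
        im = np.asarray(Image.open(tmp_path / "R01a.png"))
        assert np.array_equal(im, shape_set.get("R", 1, "a").image.pixels)


class TestBalancing:
    def test_balanced_set_is_fixed_point(self, shape_set):
        report = st.group_pixel_imbalance(shape_set)
        balanced = st.balance_pixel_differences(
            shape_set, tolerance=report["max_abs_relative_deviation"] + 0.01)
        assert balanced.balance_report["iterations"] == 0

    def test_balancing_reaches_tolerance(self):
        ss = st.build_shape_set(seed=21)
        out = st.balance_pixel_differences(ss, tolerance=0.1, max_iter=15)
        rep = st.group_pixel_imbalance(out)
        assert rep["max_abs_relative_deviation"] <= 0.1

    def test_max_iter_zero_on_unbalanced_errors(self):
        cfg = st.StimulusConfig(group_magnitudes={"R": 3.0, "IC": 0.2, "ISC": 0.2, "ISS": 0.2})
        ss = st.build_shape_set(cfg, seed=5)
        with pytest.raises(st.BalanceError) as exc:
            st.balance_pixel_differences(ss, tolerance=0.02, max_iter=0)
        assert exc.value.report["max_abs_relative_deviation"] > 0.02
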