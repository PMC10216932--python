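"""Geometric FAZ parameters against analytic shapes and brute-force oracles."""

import math

import numpy as np
import pytest
from scipy.ndimage import rotate as ndrotate

from conftest import rasterize_disk, rasterize_ellipse, rasterize_square
from oracles import (feret_extents_fine_sweep, inscribed_radius_bruteforce,
                     minimal_enclosing_circle_bruteforce)
from octafaz.shape import (circularity_index, circumcircle_radius,
                           compute_shape_params, ellipse_moments,
                           equivalent_diameter, feret_extents,
                           inscribed_circle_radius, perimeter_length,
                           region_area, _hull_points)


class TestArea:
    def test_pixel_count_times_scale_sq(self):
        m = np.zeros((20, 20), dtype=bool)
        m[5:15, 5:15] = True
        assert region_area(m, 0.1) == pytest.approx(1.0)

    @pytest.mark.parametrize("r", [20, 50, 100])
    def test_disk_area_within_two_percent(self, r):
        m = rasterize_disk(r)
        assert region_area(m, 6 / 420) == pytest.approx(
            math.pi * (r * 6 / 420) ** 2, rel=0.02)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            region_area(np.zeros((5, 5), dtype=bool), 1.0)


class TestEquivalentDiameter:
    @pytest.mark.parametrize("area,expected", [
        (math.pi, 2.0), (0.25 * math.pi, 1.0)])
    def test_analytic(self, area, expected):
        assert equivalent_diameter(area) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            equivalent_diameter(0.0)

    @pytest.mark.parametrize("r", [20, 50])
    def test_disk_recovers_diameter(self, r):
        d = equivalent_diameter(region_area(rasterize_disk(r), 1.0))
        assert d == pytest.approx(2 * r, rel=0.02)


class TestEllipseMoments:
    def test_disk_eccentricity_near_zero(self):
        _, _, _, ecc = ellipse_moments(rasterize_disk(50))
        assert ecc < 0.05

    def test_axis_aligned_ellipse(self):
        major, minor, orient, ecc = ellipse_moments(
            rasterize_ellipse(60, 30))
        assert ecc == pytest.approx(math.sqrt(1 - 0.25), abs=0.01)
        assert major == pytest.approx(120, rel=0.01)
        assert minor == pytest.approx(60, rel=0.01)
        assert abs(orient) < 1.0

    def test_rotation_moves_orientation_not_eccentricity(self):
        m = rasterize_ellipse(60, 30)
        mr = ndrotate(m.astype(float), 45, reshape=True, order=0) > 0.5
        major, minor, orient, ecc = ellipse_moments(mr)
        _, _, _, ecc0 = ellipse_moments(m)
        assert orient == pytest.approx(45.0, abs=2.0)
        assert ecc == pytest.approx(ecc0, rel=0.02)

    def test_single_pixel_degenerate(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        with pytest.warns(UserWarning, match="degenerate"):
            major, minor, orient, ecc = ellipse_moments(m)
        assert major == 0.0 and minor == 0.0


class TestPerimeter:
    def test_square_traced_convention(self):
        # hand-traced 10x10 square boundary: 4*(10-1) unit steps
        assert perimeter_length(rasterize_square(10)) == pytest.approx(36.0)

    def test_disk_within_five_percent_of_circumference(self):
        p = perimeter_length(rasterize_disk(50))
        assert p == pytest.approx(2 * math.pi * 50, rel=0.055)

    def test_double_resolution_doubles_traced_length(self):
        # rasterising the same shape at twice the resolution doubles the
        # traced perimeter (nearest-neighbour pixel doubling would not:
        # it genuinely roughens the contour)
        assert perimeter_length(rasterize_disk(40)) == pytest.approx(
            2 * perimeter_length(rasterize_disk(20)), rel=0.03)


class TestFeret:
    def test_square_calipers(self):
        fmin, fmax = feret_extents(rasterize_square(50))
        assert fmin == pytest.approx(50.0, rel=0.01)
        assert fmax == pytest.approx(50 * math.sqrt(2), rel=0.01)

    def test_disk_calipers(self):
        fmin, fmax = feret_extents(rasterize_disk(40))
        assert fmin == pytest.approx(80, abs=1.5)
        assert fmax == pytest.approx(80, abs=1.5)

    def test_matches_fine_sweep_oracle(self, rng):
        from oracles import random_blob
        for _ in range(20):
            m = random_blob(rng, 30, sigma=2.5)
            pts = _hull_points(m)
            fmin, fmax = feret_extents(m)
            omin, omax = feret_extents_fine_sweep(pts)
            assert fmin == pytest.approx(omin, rel=0.01)
            assert fmax == pytest.approx(omax, rel=0.01)

    def test_single_pixel(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        fmin, fmax = feret_extents(m)
        assert fmin == pytest.approx(1.0, abs=0.05)


class TestInscribedCircle:
    def test_square_half_side(self):
        assert inscribed_circle_radius(rasterize_square(50)) == pytest.approx(
            25.0, abs=1.0)

    def test_disk_radius(self):
        assert inscribed_circle_radius(rasterize_disk(40)) == pytest.approx(
            40.0, abs=1.0)

    def test_crescent_matches_exhaustive_search(self):
        m = rasterize_disk(30, pad=10)
        shifted = np.roll(m, (0, 18), axis=(0, 1))
        crescent = m & ~shifted
        assert inscribed_circle_radius(crescent) == pytest.approx(
            inscribed_radius_bruteforce(crescent), abs=1.0)


class TestCircumcircle:
    def test_square(self):
        assert circumcircle_radius(rasterize_square(50)) == pytest.approx(
            50 * math.sqrt(2) / 2, rel=0.02)

    def test_disk(self):
        assert circumcircle_radius(rasterize_disk(40)) == pytest.approx(
            40.0, abs=1.0)

    def test_matches_exact_oracle_on_blobs(self, rng):
        from oracles import random_blob
        for _ in range(15):
            m = random_blob(rng, 24, sigma=2.0)
            pts = _hull_points(m)
            assert circumcircle_radius(m) == pytest.approx(
                minimal_enclosing_circle_bruteforce(pts), rel=1e-6)


class TestCircularity:
    def test_circle_is_one(self):
        r = 3.0
        assert circularity_index(math.pi * r * r,
                                 2 * math.pi * r) == pytest.approx(1.0)

    def test_square_is_pi_over_four(self):
        s = 7.0
        assert circularity_index(s * s, 4 * s) == pytest.approx(math.pi / 4)

    def test_zero_perimeter_rejected(self):
        with pytest.raises(ValueError):
            circularity_index(1.0, 0.0)

    def test_decreases_with_boundary_perturbation(self):
        from octafaz.synthetic import PhantomSpec, _rasterize_faz
        values = []
        for amp in (0.0, 0.08, 0.16, 0.24, 0.32):
            spec = PhantomSpec(faz_shape="blob", radius_mm=0.5,
                               acircularity=amp, seed=42)
            mask, _ = _rasterize_faz(spec)
            values.append(compute_shape_params(mask).circularity)
        assert all(a > b for a, b in zip(values, values[1:]))


class TestInvariants:
    def test_linear_scaling(self):
        m = rasterize_disk(30)
        p1 = compute_shape_params(m, 1.0)
        p2 = compute_shape_params(m, 2.0)
        assert p2.area == pytest.approx(4 * p1.area)
        for f in ("equiv_diameter", "major_axis", "perimeter", "fmin",
                  "fmax", "inner_circle_radius", "circumcircle_radius"):
            assert getattr(p2, f) == pytest.approx(2 * getattr(p1, f))
        assert p2.eccentricity == pytest.approx(p1.eccentricity)
        assert p2.circularity == pytest.approx(p1.circularity)

    @staticmethod
    def _rotated_ellipse(a, b, deg, n=160):
        # analytic rotation then rasterisation (nearest-neighbour rotation
        # of a mask roughens its boundary and is not a pure rotation)
        c = (n - 1) / 2.0
        t = math.radians(deg)
        rr, cc = np.mgrid[0:n, 0:n]
        x, y = cc - c, rr - c
        u = x * math.cos(t) + y * math.sin(t)
        v = -x * math.sin(t) + y * math.cos(t)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def test_rotation_invariance_within_digitization(self):
        p0 = compute_shape_params(self._rotated_ellipse(50, 28, 0))
        p1 = compute_shape_params(self._rotated_ellipse(50, 28, 30))
        for f in ("area", "perimeter", "eccentricity", "fmin", "fmax",
                  "inner_circle_radius", "circumcircle_radius",
                  "circularity"):
            assert getattr(p1, f) == pytest.approx(getattr(p0, f),
                                                   rel=0.025), f

    def test_ordering_invariants_on_random_phantoms(self, rng):
        from octafaz.synthetic import PhantomSpec, _rasterize_faz
        for seed in range(8):
            spec = PhantomSpec(faz_shape="blob", radius_mm=0.4,
                               acircularity=float(rng.uniform(0, 0.3)),
                               seed=seed)
            mask, _ = _rasterize_faz(spec)
            p = compute_shape_params(mask, spec.scale)
            assert p.minor_axis <= p.major_axis
            assert p.fmin <= p.fmax + 1e-9
            assert p.inner_circle_radius <= p.circumcircle_radius
            assert 0.0 <= p.eccentricity < 1.0
            assert 0.0 < p.circularity <= 1.1
            assert -90.0 < p.orientation <= 90.0
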