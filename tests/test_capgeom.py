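import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from capcolony import (
    PackingModel,
    SphericalCap,
    cap_base_from_sphere,
    cap_sphere_radius,
    cap_volume,
    colony_volume,
    contact_angle,
    interior_cap,
    layer_radius,
    midsection_profile,
    shape_parameter,
    solve_cap_height,
    upper_cap,
)
from capcolony.fixtures import disc_integral_volume

# positive floats spanning flat pancakes to near-closed spheres
pos_scale = st.floats(1e-3, 1e3)
ratio = st.floats(1e-2, 1e2)


class TestPackingModel:
    def test_f3d_derived_as_three_halves_power(self):
        p = PackingModel(r_c=1.0, f_2d=1.2)
        assert p.f_3d == pytest.approx(1.2 ** 1.5, rel=1e-12)

    def test_f3d_override(self):
        p = PackingModel(r_c=1.0, f_2d=1.2, f_3d=1.32)
        assert p.f_3d == 1.32

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(ValueError, match="r_c"):
            PackingModel(r_c=0.0)


@pytest.mark.parametrize(
    "n_l1, f_2d, expected",
    [(1, 1.2, math.sqrt(1.2)), (100, 1.2, math.sqrt(120)), (1, 1.0, 1.0)],
)
def test_layer_radius(n_l1, f_2d, expected):
    p = PackingModel(r_c=1.0, f_2d=f_2d)
    assert layer_radius(n_l1, p) == pytest.approx(expected, rel=1e-12)
    # the stated area relation holds by construction
    area = math.pi * layer_radius(n_l1, p) ** 2
    assert area == pytest.approx(n_l1 * f_2d * math.pi, rel=1e-12)


@pytest.mark.parametrize(
    "n_tot, f_3d, expected",
    [
        (1, 1.0, 4.0 * math.pi / 3.0),
        (1, 1.2 ** 1.5, 1.2 ** 1.5 * 4.0 * math.pi / 3.0),  # 5.5063077
        (1000, 1.0, 4000.0 * math.pi / 3.0),
    ],
)
def test_colony_volume(n_tot, f_3d, expected):
    p = PackingModel(r_c=1.0, f_2d=1.2, f_3d=f_3d)
    assert colony_volume(n_tot, p) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("bad_count", [0.0, -3.0])
def test_count_validation(bad_count):
    p = PackingModel()
    with pytest.raises(ValueError):
        layer_radius(bad_count, p)
    with pytest.raises(ValueError):
        colony_volume(bad_count, p)


@pytest.mark.parametrize(
    "h, r, expected",
    [
        (1.0, 1.0, 2.0 * math.pi / 3.0),           # hemisphere
        (0.5, 1.0, (math.pi / 6.0) * 1.625),       # 0.850848, minor cap
        (1.5, 1.0, (math.pi / 6.0) * 7.875),       # 4.12334, major cap
    ],
)
def test_cap_volume_known_values(h, r, expected):
    assert cap_volume(h, r) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "h, r, expected",
    [(1.0, 1.0, 1.0), (0.5, 1.0, 1.25), (1.5, 1.0, 13.0 / 12.0)],
)
def test_cap_sphere_radius_known_values(h, r, expected):
    assert cap_sphere_radius(h, r) == pytest.approx(expected, rel=1e-12)


@given(h=pos_scale, q=ratio)
def test_chord_relation(h, q):
    """r_base² = h(2R − h) for every cap, minor or major."""
    r = h * q
    R = cap_sphere_radius(h, r)
    assert r * r == pytest.approx(h * (2.0 * R - h), rel=1e-9)


@given(r=pos_scale, q=st.floats(1.0 + 1e-6, 50.0))
def test_major_cap_equals_sphere_minus_complement(r, q):
    """Unified formula reproduces the subtraction form for bulging caps."""
    h = r * q  # h > r: major cap
    R = cap_sphere_radius(h, r)
    complement = cap_volume(2.0 * R - h, r)
    assert cap_volume(h, r) == pytest.approx(
        (4.0 / 3.0) * math.pi * R ** 3 - complement, rel=1e-9
    )


def test_cap_volume_limits():
    R = 2.7
    assert cap_volume(R, R) == pytest.approx((2.0 / 3.0) * math.pi * R ** 3, rel=1e-12)
    # full-sphere limit: base radius shrinks to zero at h = 2R
    assert cap_volume(2.0 * R, 1e-9) == pytest.approx(
        (4.0 / 3.0) * math.pi * R ** 3, rel=1e-6
    )


@given(h=pos_scale, q=ratio)
def test_cap_volume_matches_disc_integration(h, q):
    r = h * q
    assert cap_volume(h, r) == pytest.approx(disc_integral_volume(h, r), rel=1e-6)


@pytest.mark.parametrize(
    "V, r, expected",
    [
        (2.0 * math.pi / 3.0, 1.0, 1.0),
        ((math.pi / 6.0) * 1.625, 1.0, 0.5),
        ((math.pi / 6.0) * 7.875, 1.0, 1.5),
    ],
)
def test_solve_cap_height_known_roots(V, r, expected):
    assert solve_cap_height(V, r) == pytest.approx(expected, rel=1e-12)


def test_solve_cap_height_round_trip_across_scales():
    """Inversion is exact to 1e-10 relative over six decades of aspect ratio."""
    for r in np.logspace(-2, 2, 9):
        for q in np.logspace(-3, 3, 25):
            h = r * q
            got = solve_cap_height(cap_volume(h, r), r)
            assert got == pytest.approx(h, rel=1e-10), (h, r)


@pytest.mark.parametrize(
    "R, h, expected",
    [(1.0, 1.0, 1.0), (1.25, 0.5, 1.0), (1.0, 2.0, 0.0)],
)
def test_cap_base_from_sphere(R, h, expected):
    assert cap_base_from_sphere(R, h) == pytest.approx(expected, abs=1e-12)


def test_cap_base_from_sphere_rejects_out_of_range_height():
    with pytest.raises(ValueError):
        cap_base_from_sphere(1.0, 2.5)


class TestSubCaps:
    """Worked colony: r_L1 = 10, h = 4, r_C = 1, F_2D = 1.2 (R = 14.5).

    Reference volumes were cross-checked against brute-force disc
    integration of the greater sphere.
    """

    colony = SphericalCap(r_base=10.0, h=4.0)
    p = PackingModel(r_c=1.0, f_2d=1.2)

    def test_upper_cap_reduced_dimensions(self):
        uc = upper_cap(self.colony, self.p)
        assert uc.h == pytest.approx(4.0 - 2.0 * math.sqrt(1.2), rel=1e-12)
        assert uc.r_base == pytest.approx(7.013651343598859, rel=1e-9)
        assert uc.V == pytest.approx(142.88927239404558, rel=1e-9)
        assert uc.V == pytest.approx(disc_integral_volume(uc.h, uc.r_base), rel=1e-9)
        # reduced cap shares the colony's greater sphere
        assert uc.R == pytest.approx(self.colony.R, rel=1e-9)

    def test_interior_cap_reduced_dimensions(self):
        inner = interior_cap(self.colony, self.p)
        assert inner.h == pytest.approx(4.0 - 2.0 * math.sqrt(1.2) - 1.0, rel=1e-12)
        assert inner.r_base == pytest.approx(4.603401478207835, rel=1e-9)
        assert inner.V == pytest.approx(27.21036380737551, rel=1e-9)

    def test_monolayer_colony_has_no_upper_cap(self):
        thin = SphericalCap(r_base=10.0, h=1.0)  # below one layer thickness
        assert upper_cap(thin, self.p) is None
        assert interior_cap(thin, self.p) is None

    def test_interior_nested_within_upper(self):
        uc = upper_cap(self.colony, self.p)
        inner = interior_cap(self.colony, self.p)
        assert inner.V < uc.V


@pytest.mark.parametrize(
    "h, r, expected",
    [(1.0, 1.0, 1.0), (0.5, 1.0, 0.4), (1.5, 1.0, 18.0 / 13.0)],
)
def test_shape_parameter(h, r, expected):
    assert shape_parameter(SphericalCap(r_base=r, h=h)) == pytest.approx(expected, rel=1e-12)


def test_shape_parameter_sphere_limit():
    cap = SphericalCap(r_base=1e-7, h=2.0)
    assert shape_parameter(cap) == pytest.approx(2.0, rel=1e-6)


@pytest.mark.parametrize(
    "h, r, expected",
    [
        (1.0, 1.0, 90.0),                                          # hemisphere
        (0.5, 1.0, 90.0 - math.degrees(math.asin(0.6))),           # 53.1301
        (1.5, 1.0, 90.0 + math.degrees(math.acos(12.0 / 13.0))),   # 112.620
    ],
)
def test_contact_angle_known_values(h, r, expected):
    assert contact_angle(SphericalCap(r_base=r, h=h)) == pytest.approx(expected, abs=1e-9)


def test_contact_angle_continuous_and_increasing_in_height():
    r = 1.0
    heights = np.linspace(0.05, 5.0, 400)
    thetas = [contact_angle(SphericalCap(r_base=r, h=h)) for h in heights]
    assert all(b > a for a, b in zip(thetas, thetas[1:]))
    # continuity across the hemisphere branch point h = r
    below = contact_angle(SphericalCap(r_base=r, h=r * (1 - 1e-9)))
    above = contact_angle(SphericalCap(r_base=r, h=r * (1 + 1e-9)))
    assert abs(below - 90.0) < 1e-3 and abs(above - 90.0) < 1e-3


class TestMidsectionProfile:
    def test_hemisphere_three_points(self):
        cap = SphericalCap(r_base=1.0, h=1.0)
        pts = midsection_profile(cap, 3)
        np.testing.assert_allclose(pts, [(-1, 0), (0, 1), (1, 0)], atol=1e-12)

    @pytest.mark.parametrize("h, r", [(0.5, 1.0), (1.0, 1.0), (3.0, 1.0), (2.0, 7.0)])
    def test_points_lie_on_greater_circle(self, h, r):
        cap = SphericalCap(r_base=r, h=h)
        pts = midsection_profile(cap, 101)
        resid = pts[:, 0] ** 2 + (pts[:, 1] - (cap.h - cap.R)) ** 2 - cap.R ** 2
        assert np.abs(resid).max() < 1e-9 * cap.R ** 2
        assert (pts[:, 1] >= 0).all()
        assert pts[0, 1] == 0.0 and pts[-1, 1] == 0.0
        assert pts[:, 1].max() == pytest.approx(h, rel=1e-9)
        assert pts[0, 0] == pytest.approx(-r, rel=1e-9)
        assert pts[-1, 0] == pytest.approx(r, rel=1e-9)

    def test_rejects_too_few_points(self):
        with pytest.raises(ValueError):
            midsection_profile(SphericalCap(r_base=1.0, h=1.0), 2)
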