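"""Lens profile construction, thickness calibration, layering and fibre
placement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zonula import geometry as geo
from zonula.geometry import (
    GeometryError,
    LensGeometrySpec,
    ZonularSpec,
    build_profile,
    calibrate_thickness,
    generate_fibres,
    layer_contours,
    locate_insertions,
)
from zonula.optics import central_optical_power


def spherical_cap_spec(R=4.6):
    # both surfaces degenerate to hemispheres of radius R: a full sphere
    return LensGeometrySpec(
        name="sphere", r_anterior=R, r_posterior=R, thickness=2 * R, equatorial_diameter=2 * R
    )


class TestBuildProfile:
    def test_paraxial_radii_match_spec(self, asymmetric_profile):
        prof = asymmetric_profile
        # analytic curvature at the pole: d2h/dr2|0 = 1/R by construction
        r = np.array([1e-4, 2e-4])
        sag_a = prof.anterior.sag(r)
        assert np.allclose(2 * sag_a / r**2, 1 / 10.96, rtol=1e-4)
        sag_p = prof.posterior.sag(r)
        assert np.allclose(2 * sag_p / r**2, 1 / 6.94, rtol=1e-4)

    def test_axial_extent_and_equator(self, asymmetric_profile):
        prof = asymmetric_profile
        spec = prof.spec
        z_eq, r_eq = prof.equator_point
        assert z_eq == spec.equatorial_offset
        assert r_eq == spec.equatorial_diameter / 2
        # surfaces meet the equator plane at the full semi-diameter
        assert prof.anterior.sag(r_eq) == pytest.approx(prof.anterior.s_max, abs=1e-12)
        assert prof.posterior.z_of_r(0.0) - prof.anterior.z_of_r(0.0) == pytest.approx(
            spec.thickness
        )

    def test_mirror_symmetric_spec(self):
        spec = LensGeometrySpec(
            name="sym", r_anterior=6.0, r_posterior=6.0, thickness=4.4, equatorial_diameter=9.2
        )
        prof = build_profile(spec)
        r = np.linspace(0, 4.59, 50)
        assert np.allclose(prof.anterior.z_of_r(r), -prof.posterior.z_of_r(r), atol=1e-12)

    def test_spherical_cap_is_exact_circle(self):
        prof = build_profile(spherical_cap_spec())
        R = 4.6
        r = np.linspace(0, R * (1 - 1e-6), 200)
        z = prof.anterior.z_of_r(r)
        # anterior sphere centred at z = -t/2 + R = 0
        dist = np.hypot(r, z)
        assert np.max(np.abs(dist - R)) < 1e-9

    def test_tangent_vertical_at_equator(self, symmetric_profile):
        d = symmetric_profile.anterior.dsag_dr(4.6 * (1 - 1e-10))
        assert d > 1e3  # dz/dr blows up: 0-degree tangent slope to the axis

    def test_infeasible_geometry_raises(self):
        # radius far too small to reach the equator smoothly
        with pytest.raises(GeometryError):
            build_profile(
                LensGeometrySpec(
                    name="bad",
                    r_anterior=1.2,
                    r_posterior=5.0,
                    thickness=4.4,
                    equatorial_diameter=9.2,
                )
            )

    def test_determinism(self):
        a = build_profile(geo.asymmetric_lens_spec())
        b = build_profile(geo.asymmetric_lens_spec())
        r = np.linspace(0, 4.6, 1000)
        assert np.array_equal(a.anterior.sag(r), b.anterior.sag(r))
        assert np.array_equal(a.posterior.sag(r), b.posterior.sag(r))


class TestCalibrateThickness:
    @pytest.mark.parametrize(
        "r_a,r_p,cop",
        [(10.96, 6.94, 19.48), (5.33, 5.00, 31.75)],
    )
    def test_roundtrip_exact(self, r_a, r_p, cop):
        t = calibrate_thickness(r_a, r_p, cop)
        assert t > 0
        assert central_optical_power(r_a, r_p, t) == pytest.approx(cop, abs=1e-9)

    def test_reference_values(self):
        # inversion of the thick-lens formula for the two printed powers
        assert calibrate_thickness(10.96, 6.94, 19.48) == pytest.approx(4.4082, abs=2e-4)
        assert calibrate_thickness(5.33, 5.00, 31.75) == pytest.approx(4.3434, abs=2e-4)

    def test_zero_thickness_limit(self):
        dn = 1.42 - 1.336
        p_thin = dn / 0.01 + dn / 0.008
        assert calibrate_thickness(10.0, 8.0, p_thin) == pytest.approx(0.0, abs=1e-12)

    def test_unreachable_power_raises(self):
        with pytest.raises(GeometryError):
            calibrate_thickness(10.0, 8.0, 50.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        r_a=st.floats(5.0, 15.0),
        r_p=st.floats(5.0, 15.0),
        t=st.floats(0.5, 6.0),
    )
    def test_inversion_property(self, r_a, r_p, t):
        cop = central_optical_power(r_a, r_p, t)
        assert calibrate_thickness(r_a, r_p, cop) == pytest.approx(t, rel=1e-9)


class TestLayerContours:
    def test_scale_ladder(self, asymmetric_profile):
        contours = layer_contours(asymmetric_profile)
        expected = np.linspace(0.5, 1.0, 13)
        assert np.allclose(contours.scales, expected)

    def test_nesting(self, asymmetric_profile):
        contours = layer_contours(asymmetric_profile)
        polys = [contours.contour_points(k, n=100) for k in range(13)]
        # successive contours strictly nested: radial coordinate grows with k
        # along every ray from the centre (affine scaling about one point)
        for inner, outer in zip(polys, polys[1:]):
            d_in = np.hypot(inner[:, 1], inner[:, 0] - contours.z_centre)
            d_out = np.hypot(outer[:, 1], outer[:, 0] - contours.z_centre)
            assert np.all(d_out >= d_in - 1e-12)
            assert d_out.max() > d_in.max()

    def test_layer_of_point_binning(self, asymmetric_profile):
        contours = layer_contours(asymmetric_profile)
        spec = asymmetric_profile.spec
        # half-open ladder 0.5, 0.5+1/24, ..., 1: scale 0.95 falls between the
        # 0.9167 and 0.9583 boundaries (layer 12); 0.97 is outermost (13)
        z = contours.z_centre + 0.95 * (spec.z_posterior_pole - contours.z_centre)
        assert contours.layer_of_point(z, 0.0) == 12
        z = contours.z_centre + 0.97 * (spec.z_posterior_pole - contours.z_centre)
        assert contours.layer_of_point(z, 0.0) == 13
        # centre point -> nucleus
        assert contours.layer_of_point(contours.z_centre, 0.0) == 1
        # half-open binning at a boundary: scale 0.5 starts the first cortical layer
        z = contours.z_centre + 0.5 * (spec.z_posterior_pole - contours.z_centre)
        assert contours.layer_of_point(z + 1e-9, 0.0) == 2

    def test_bad_nucleus_fraction(self):
        with pytest.raises(GeometryError):
            LensGeometrySpec(
                name="x",
                r_anterior=10.96,
                r_posterior=6.94,
                thickness=4.4,
                equatorial_diameter=9.2,
                nucleus_fraction=1.5,
            )


class TestInsertions:
    def test_equatorial_at_maximum_radius(self, asymmetric_profile):
        ins = locate_insertions(asymmetric_profile, ZonularSpec.from_combination("A"))
        assert ins["equatorial"] == asymmetric_profile.equator_point

    def test_sphere_closed_form(self):
        # anterior hemisphere of radius R: insertion at axial distance d from
        # the equator lies at radial coordinate sqrt(R^2 - d^2)
        prof = build_profile(spherical_cap_spec(R=4.6))
        z = ZonularSpec(anterior_insertion_distance=1.0, posterior_insertion_distance=1.5)
        ins = locate_insertions(prof, z)
        assert ins["anterior"][1] == pytest.approx(np.sqrt(4.6**2 - 1.0**2), abs=1e-9)
        assert ins["posterior"][1] == pytest.approx(np.sqrt(4.6**2 - 1.5**2), abs=1e-9)

    def test_zero_distance_degenerates_to_equator(self, asymmetric_profile):
        z = ZonularSpec(anterior_insertion_distance=0.0, posterior_insertion_distance=0.0)
        ins = locate_insertions(asymmetric_profile, z)
        for key in ("anterior", "equatorial", "posterior"):
            assert ins[key] == pytest.approx(asymmetric_profile.equator_point)

    def test_beyond_pole_raises(self, asymmetric_profile):
        z = ZonularSpec(anterior_insertion_distance=3.0, posterior_insertion_distance=1.0)
        with pytest.raises(GeometryError):
            locate_insertions(asymmetric_profile, z)

    def test_mirror_symmetry_of_insertions(self):
        spec = LensGeometrySpec(
            name="sym", r_anterior=6.0, r_posterior=6.0, thickness=4.4, equatorial_diameter=9.2
        )
        prof = build_profile(spec)
        z = ZonularSpec(anterior_insertion_distance=1.1, posterior_insertion_distance=1.1)
        ins = locate_insertions(prof, z)
        assert ins["anterior"][0] == pytest.approx(-ins["posterior"][0])
        assert ins["anterior"][1] == pytest.approx(ins["posterior"][1], abs=1e-9)


class TestFibres:
    def test_counts_and_spacing(self, asymmetric_profile):
        zspec = ZonularSpec.from_combination("A")
        fibres = generate_fibres(locate_insertions(asymmetric_profile, zspec), zspec)
        assert len(fibres) == 51
        az = sorted(f.azimuth_deg for f in fibres if f.section == "equatorial")
        assert np.allclose(np.diff(az), 90 / 16)
        assert az[0] == 0.0 and az[-1] == 90.0

    def test_lengths_and_angles(self, asymmetric_profile):
        zspec = ZonularSpec.from_combination("B")
        fibres = generate_fibres(locate_insertions(asymmetric_profile, zspec), zspec)
        for f in fibres:
            assert f.length == pytest.approx(1.5, abs=1e-12)
            dz = f.free_end[2] - f.lens_end[2]
            if f.section == "equatorial":
                assert dz == pytest.approx(0.0, abs=1e-12)
            else:
                # 15-degree section angle: |axial run| = L sin(15 deg)
                assert abs(dz) == pytest.approx(1.5 * np.sin(np.deg2rad(15)), abs=1e-12)
                assert dz < 0 if f.section == "anterior" else dz > 0

    def test_equatorial_fibre_is_radial(self, asymmetric_profile):
        zspec = ZonularSpec.from_combination("A")
        fibres = generate_fibres(locate_insertions(asymmetric_profile, zspec), zspec)
        f = [x for x in fibres if x.section == "equatorial" and x.azimuth_deg == 0.0][0]
        r_eq = asymmetric_profile.equator_point[1]
        assert f.free_end[0] == pytest.approx(r_eq + 1.5)
        assert f.free_end[1] == pytest.approx(0.0, abs=1e-12)

    def test_named_combinations(self):
        assert geo.ZONULAR_COMBINATIONS == {
            "A": (1.0, 1.2),
            "B": (1.0, 1.6),
            "C": (1.0, 1.0),
            "D": (1.0, 1.4),
        }
        with pytest.raises(GeometryError):
            ZonularSpec.from_combination("Z")
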