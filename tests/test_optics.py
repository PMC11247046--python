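"""Circle fitting, the thick-lens power formula and kinematic measures."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zonula import geometry as geo
from zonula.fem import assemble, build_constraints, solve_static
from zonula.mesh import Resolution, attach_zonules, mesh_quarter_lens, skin_capsule
from zonula.optics import (
    OpticalConstants,
    OpticsError,
    axial_thickness,
    central_optical_power,
    extract_surface_points,
    fit_paraxial_radius,
    measure_shifts,
)


def ray_transfer_power(r_a, r_p, t, n1=1.42, na=1.336):
    """Independent paraxial oracle: system matrix of refraction-translation-
    refraction for a thick lens immersed in aqueous, radii in mm."""
    P1 = (n1 - na) / (r_a * 1e-3)
    P2 = (n1 - na) / (r_p * 1e-3)
    R1 = np.array([[1.0, -P1], [0.0, 1.0]])
    T = np.array([[1.0, 0.0], [t * 1e-3 / n1, 1.0]])
    R2 = np.array([[1.0, -P2], [0.0, 1.0]])
    M = R2 @ T @ R1
    return -M[0, 1]


class TestCentralOpticalPower:
    def test_matches_ray_transfer_matrix_grid(self):
        """Thick-lens formula agrees with the ray-matrix oracle to 1e-9 D
        over a 1000-point parameter grid."""
        rng = np.random.default_rng(7)
        r_a = rng.uniform(4.0, 15.0, 1000)
        r_p = rng.uniform(4.0, 15.0, 1000)
        t = rng.uniform(0.5, 6.0, 1000)
        for ra, rp, tt in zip(r_a, r_p, t):
            assert central_optical_power(ra, rp, tt) == pytest.approx(
                ray_transfer_power(ra, rp, tt), abs=1e-9
            )

    def test_flat_surfaces_zero_power(self):
        assert central_optical_power(1e12, 1e12, 4.0) == pytest.approx(0.0, abs=1e-9)

    def test_single_surface_closed_form(self):
        # t = 0, r_a = 84 mm, flat posterior: exactly dn / r = 1.0 D
        assert central_optical_power(84.0, 1e15, 0.0) == pytest.approx(1.0, abs=1e-9)

    def test_reference_lens_power(self):
        t = geo.calibrate_thickness(10.96, 6.94, 19.48)
        assert central_optical_power(10.96, 6.94, t) == pytest.approx(19.48, abs=1e-9)

    def test_monotone_in_radii_and_thickness(self):
        """Power decreases as either radius magnitude or thickness grows."""
        grid = np.linspace(5.0, 14.0, 12)
        for rp in (5.0, 8.0):
            p = [central_optical_power(ra, rp, 4.0) for ra in grid]
            assert np.all(np.diff(p) < 0)
            p = [central_optical_power(rp, ra, 4.0) for ra in grid]
            assert np.all(np.diff(p) < 0)
        ts = np.linspace(0.0, 6.0, 13)
        p = [central_optical_power(8.0, 6.0, t) for t in ts]
        assert np.all(np.diff(p) < 0)

    def test_invalid_radius(self):
        with pytest.raises(OpticsError):
            central_optical_power(0.0, 5.0, 4.0)


class TestCircleFit:
    def test_exact_circle_recovered(self):
        theta = np.linspace(-0.3, 0.3, 40)
        pts = np.column_stack([5.0 * np.sin(theta), 7.0 - 5.0 * np.cos(theta)])
        assert fit_paraxial_radius(pts, halfwidth=5.0) == pytest.approx(5.0, abs=1e-9)

    def test_three_point_circumcircle(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.2], [-0.8, 0.15]])
        # closed-form circumcircle radius
        a = np.linalg.norm(pts[0] - pts[1])
        b = np.linalg.norm(pts[1] - pts[2])
        c = np.linalg.norm(pts[2] - pts[0])
        s = (a + b + c) / 2
        area = np.sqrt(s * (s - a) * (s - b) * (s - c))
        R = a * b * c / (4 * area)
        assert fit_paraxial_radius(pts, halfwidth=2.0, mirror=False) == pytest.approx(
            R, rel=1e-9
        )

    def test_noisy_circle_matches_bruteforce_geometric_fit(self):
        rng = np.random.default_rng(11)
        theta = np.linspace(-0.15, 0.15, 120)
        R0 = 10.0
        pts = np.column_stack(
            [R0 * np.sin(theta), R0 - R0 * np.cos(theta)]
        ) + rng.normal(0, 1e-3, (120, 2))
        fitted = fit_paraxial_radius(pts, halfwidth=1.5)
        # brute force: direct minimisation of geometric distance on a grid +
        # Nelder-Mead polish, independent of the implementation path
        from scipy.optimize import minimize

        mirrored = np.vstack([pts, pts * [-1, 1]])

        def cost(p):
            return np.sum((np.hypot(mirrored[:, 0] - p[0], mirrored[:, 1] - p[1]) - p[2]) ** 2)

        best = min(
            (
                minimize(cost, [0.0, z0, R], method="Nelder-Mead").x
                for z0 in (9.0, 10.0, 11.0)
                for R in (9.0, 10.0, 11.0)
            ),
            key=cost,
        )
        assert fitted == pytest.approx(abs(best[2]), rel=1e-3)

    def test_too_few_points(self):
        with pytest.raises(OpticsError):
            fit_paraxial_radius(np.array([[0.0, 0.0], [1.0, 0.1]]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(R=st.floats(3.0, 30.0), z0=st.floats(-5.0, 5.0))
    def test_exact_arc_property(self, R, z0):
        theta = np.linspace(-0.2, 0.2, 25)
        pts = np.column_stack([R * np.sin(theta), z0 + R - R * np.cos(theta)])
        assert fit_paraxial_radius(pts, halfwidth=R) == pytest.approx(R, rel=1e-7)


@pytest.fixture(scope="module")
def solved_coarse_run():
    spec = geo.asymmetric_lens_spec()
    prof = geo.build_profile(spec)
    cont = geo.layer_contours(prof)
    zspec = geo.ZonularSpec.from_combination("A")
    ins = geo.locate_insertions(prof, zspec)
    m = mesh_quarter_lens(prof, cont, Resolution(16, 8, 8), [ins["anterior"], ins["posterior"]])
    skin_capsule(m, 0.006)
    attach_zonules(m, geo.generate_fibres(ins, zspec))
    from zonula.materials import MaterialTable

    mat = MaterialTable()
    K = assemble(m, mat)
    sol = solve_static(K, build_constraints(m, 0.5), m, mat)
    return spec, m, sol


class TestSurfaceExtraction:
    def test_undeformed_points_on_profile(self, solved_coarse_run):
        spec, m, _ = solved_coarse_run
        prof = geo.build_profile(spec)
        pts = extract_surface_points(m, None, "anterior", 6.0)
        for r, z in pts:
            if r > 1e-9:
                # node coordinates come from an arc-length interpolation
                # table, accurate to ~1e-6 mm in z
                assert z == pytest.approx(float(prof.anterior.z_of_r(r)), abs=5e-6)

    def test_saturating_zone_returns_all(self, solved_coarse_run):
        _, m, sol = solved_coarse_run
        pts = extract_surface_points(m, sol, "anterior", 1e6)
        assert len(pts) == len(m.node_sets["anterior_surface"])

    def test_selection_matches_bruteforce(self, solved_coarse_run):
        _, m, sol = solved_coarse_run
        zone = 6.0
        pts = extract_surface_points(m, sol, "posterior", zone)
        nids = m.node_sets["posterior_surface"]
        xyz = m.nodes[nids] + sol.u[nids]
        r = np.hypot(xyz[:, 0], xyz[:, 1])
        assert len(pts) == int(np.sum(r <= zone / 2))

    def test_paraxial_recovery_within_half_percent(self, solved_coarse_run):
        """Even at coarse resolution the undeformed surface fit recovers the
        prescribed paraxial radii within 0.5%."""
        spec, m, _ = solved_coarse_run
        ra = fit_paraxial_radius(extract_surface_points(m, None, "anterior", 6.0))
        rp = fit_paraxial_radius(extract_surface_points(m, None, "posterior", 6.0))
        assert ra == pytest.approx(spec.r_anterior, rel=0.005)
        assert rp == pytest.approx(spec.r_posterior, rel=0.005)


class TestShiftsAndThickness:
    def test_zero_solution_measures(self, solved_coarse_run):
        spec, m, sol = solved_coarse_run
        null = type(sol)(
            u=np.zeros_like(sol.u),
            reactions=np.zeros_like(sol.reactions),
            hex_stress=sol.hex_stress * 0,
            hex_von_mises=sol.hex_von_mises * 0,
            capsule_von_mises=None,
            bar_axial_force=None,
            strain_energy=0.0,
            external_work=0.0,
            residual=0.0,
        )
        assert measure_shifts(m, null) == (0.0, 0.0, 0.0)
        assert axial_thickness(m, null) == pytest.approx(spec.thickness, abs=1e-9)

    def test_rigid_axial_translation(self, solved_coarse_run):
        _, m, sol = solved_coarse_run
        rigid = type(sol)(
            u=np.tile([0.0, 0.0, 0.2], (m.n_nodes, 1)),
            reactions=np.zeros_like(sol.reactions),
            hex_stress=sol.hex_stress * 0,
            hex_von_mises=sol.hex_von_mises * 0,
            capsule_von_mises=None,
            bar_axial_force=None,
            strain_energy=0.0,
            external_work=0.0,
            residual=0.0,
        )
        ant, post, eq = measure_shifts(m, rigid)
        assert ant == pytest.approx(0.2) and post == pytest.approx(0.2)
        assert eq == pytest.approx(0.0, abs=1e-12)

    def test_thickness_consistent_with_pole_shifts(self, solved_coarse_run):
        """Under stretch the lens thins axially by the sum of the two inward
        pole shifts."""
        spec, m, sol = solved_coarse_run
        ant, post, eq = measure_shifts(m, sol)
        t1 = axial_thickness(m, sol)
        assert t1 == pytest.approx(spec.thickness - ant - post, abs=1e-9)
        assert t1 < spec.thickness
        assert eq > 0


def test_optical_constants_validation():
    with pytest.raises(OpticsError):
        OpticalConstants(n_lens=1.3, n_aqueous=1.336)


def test_central_sag_polynomial_on_exact_parabola():
    from zonula.optics import fit_central_sag_polynomial

    r = np.linspace(-3, 3, 50)
    z = 1.0 + 0.05 * r**2 - 2e-4 * r**4
    c = fit_central_sag_polynomial(np.column_stack([r, z]))
    assert c == pytest.approx([1.0, 0.05, -2e-4], abs=1e-12)
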