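"""Parametric lens geometry: meridional surface profiles, layer contours and
zonular anchor points.

The crystalline lens is modelled in cylindrical coordinates ``(z, r)`` with the
optic axis along ``z``.  The anterior pole sits at ``z = -t/2`` and the
posterior pole at ``z = +t/2`` (``t`` = sagittal thickness); the equatorial
plane — the plane of maximum radial extent — sits at ``z = equatorial_offset``
(negative values shift it towards the anterior pole).

Each surface is described by its sag ``h(r)`` measured axially from the pole
towards the equator,

    h(r) = s_max * [1 - sqrt(1 - u^2) * (1 + psi2*u^2 + psi4*u^4)],  u = r/a,

where ``a`` is the equatorial radius and ``s_max`` the pole-to-equator axial
distance of that side.  ``psi2`` and ``psi4`` are fixed in closed form so that
the Taylor series of ``h`` matches a sphere of the prescribed paraxial radius
through fourth order, while the ``sqrt(1-u^2)`` factor closes the contour with
a vertical tangent (tangent slope 0 degrees to the optic axis) at the equator.
When the prescribed radius, semi-diameter and sag are those of a spherical cap
the profile degenerates to that exact sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GeometryError",
    "LensGeometrySpec",
    "SurfaceProfile",
    "LayerContours",
    "ZonularSpec",
    "FibreSegment",
    "ZONULAR_COMBINATIONS",
    "build_profile",
    "calibrate_thickness",
    "layer_contours",
    "locate_insertions",
    "generate_fibres",
    "asymmetric_lens_spec",
    "symmetric_lens_spec",
]


class GeometryError(ValueError):
    """A lens geometry request is infeasible; the message names the violated
    constraint."""


# Named posterior-insertion combinations: (anterior, posterior) axial distance
# from the equatorial plane, mm.  A/B belong to the asymmetric lens, C/D to the
# symmetric lens.
ZONULAR_COMBINATIONS: dict[str, tuple[float, float]] = {
    "A": (1.0, 1.2),
    "B": (1.0, 1.6),
    "C": (1.0, 1.0),
    "D": (1.0, 1.4),
}


@dataclass(frozen=True)
class LensGeometrySpec:
    """Prescription for one lens shape.

    Parameters
    ----------
    name : str
        Label, e.g. ``"asymmetric"`` or ``"symmetric"``.
    r_anterior, r_posterior : float
        Paraxial (osculating) radii of curvature of the two surfaces, mm,
        entered as positive magnitudes.
    thickness : float
        Pole-to-pole sagittal thickness, mm.
    equatorial_diameter : float
        Maximum lens diameter, mm.
    equatorial_offset : float
        Signed axial position of the equatorial plane relative to
        mid-thickness, mm (negative = shifted anteriorly).
    n_cortex_layers : int
        Number of cortical shells surrounding the nucleus.
    nucleus_fraction : float
        Scale of the nucleus contour relative to the outer contour, in (0, 1).
    """

    name: str
    r_anterior: float
    r_posterior: float
    thickness: float
    equatorial_diameter: float
    equatorial_offset: float = 0.0
    n_cortex_layers: int = 12
    nucleus_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.r_anterior <= 0 or self.r_posterior <= 0:
            raise GeometryError("paraxial radii must be positive")
        if self.thickness <= 0:
            raise GeometryError("thickness must be positive")
        if self.equatorial_diameter <= 0:
            raise GeometryError("equatorial_diameter must be positive")
        if abs(self.equatorial_offset) >= self.thickness / 2:
            raise GeometryError(
                "equatorial_offset must place the equator strictly between the poles"
            )
        if self.n_cortex_layers < 1:
            raise GeometryError("n_cortex_layers must be >= 1")
        if not 0.0 < self.nucleus_fraction < 1.0:
            raise GeometryError("nucleus_fraction must lie in (0, 1)")

    @property
    def z_anterior_pole(self) -> float:
        return -self.thickness / 2

    @property
    def z_posterior_pole(self) -> float:
        return self.thickness / 2

    @property
    def z_equator(self) -> float:
        return self.equatorial_offset

    @property
    def equatorial_radius(self) -> float:
        return self.equatorial_diameter / 2


@dataclass(frozen=True)
class _Side:
    """One surface of the lens as an axial sag function from its pole."""

    z_pole: float
    direction: float  # +1: sag increases z (anterior side); -1: decreases z
    s_max: float
    a: float
    R: float
    psi2: float
    psi4: float

    def sag(self, r):
        """Axial sag from the pole, valid for 0 <= r <= a."""
        r = np.asarray(r, dtype=float)
        u = r / self.a
        u = np.clip(u, 0.0, 1.0)
        psi = 1.0 + self.psi2 * u**2 + self.psi4 * u**4
        return self.s_max * (1.0 - np.sqrt(np.maximum(1.0 - u**2, 0.0)) * psi)

    def dsag_dr(self, r):
        r = np.asarray(r, dtype=float)
        u = np.clip(r / self.a, 0.0, 1.0 - 1e-12)
        w = np.sqrt(1.0 - u**2)
        psi = 1.0 + self.psi2 * u**2 + self.psi4 * u**4
        dpsi = 2.0 * self.psi2 * u + 4.0 * self.psi4 * u**3
        return self.s_max / self.a * (u / w * psi - w * dpsi)

    def z_of_r(self, r):
        return self.z_pole + self.direction * self.sag(r)

    def r_of_axial_distance_from_equator(self, d: float) -> float:
        """Radial coordinate where the surface crosses the plane at axial
        distance ``d`` from the equatorial plane (towards the pole)."""
        if d < 0:
            raise GeometryError("axial distance must be non-negative")
        if d > self.s_max:
            raise GeometryError(
                f"axial distance {d} mm lies beyond the pole (side extent "
                f"{self.s_max:.4f} mm)"
            )
        target = self.s_max - d  # sag value at the requested plane
        if target <= 0.0:
            return 0.0
        if d == 0.0:
            return self.a
        return brentq(lambda r: self.sag(r) - target, 0.0, self.a, xtol=1e-12)


def _make_side(z_pole: float, direction: float, s_max: float, a: float, R: float) -> _Side:
    if s_max <= 0:
        raise GeometryError("pole-to-equator axial extent must be positive")
    beta = a * a / (R * s_max)
    psi2 = 0.5 * (1.0 - beta)
    psi4 = 0.5 * psi2 + 0.125 - a**4 / (8.0 * R**3 * s_max)
    side = _Side(z_pole, direction, s_max, a, R, psi2, psi4)
    psi1 = 1.0 + psi2 + psi4
    if psi1 <= 0.0:
        raise GeometryError(
            "infeasible surface: paraxial radius too small to reach the "
            f"equator smoothly (psi(1) = {psi1:.4f} <= 0)"
        )
    # single-valued r(z) requires monotone sag
    rs = np.linspace(1e-6, a * (1 - 1e-9), 512)
    if np.any(side.dsag_dr(rs) <= 0.0):
        raise GeometryError(
            "infeasible surface: sag is not monotone (contour would fold back)"
        )
    return side


@dataclass(frozen=True)
class SurfaceProfile:
    """Meridional outline of one lens: two sag curves meeting at the equator
    with matching value and a vertical (0 degree) tangent."""

    spec: LensGeometrySpec
    anterior: _Side = field(repr=False)
    posterior: _Side = field(repr=False)

    @property
    def equator_point(self) -> tuple[float, float]:
        """(axial, radial) coordinate of the maximum radial extent."""
        return (self.spec.z_equator, self.spec.equatorial_radius)

    def side(self, which: str) -> _Side:
        if which == "anterior":
            return self.anterior
        if which == "posterior":
            return self.posterior
        raise ValueError(f"unknown side {which!r}")

    def radial_at_z(self, z):
        """Radial coordinate of the outer contour at axial position(s) ``z``."""
        z = np.asarray(z, dtype=float)
        out = np.empty_like(z)
        flat = z.ravel()
        res = out.ravel()
        for i, zi in enumerate(flat):
            if zi <= self.spec.z_anterior_pole or zi >= self.spec.z_posterior_pole:
                res[i] = 0.0
                continue
            if zi <= self.spec.z_equator:
                side = self.anterior
                sag = zi - side.z_pole
            else:
                side = self.posterior
                sag = side.z_pole - zi
            res[i] = brentq(lambda r: side.sag(r) - sag, 0.0, side.a, xtol=1e-12)
        return out if out.shape else float(out)

    def contour_polyline(self, n_per_side: int = 400) -> np.ndarray:
        """Dense (z, r) polyline from posterior pole to anterior pole."""
        r = self.spec.equatorial_radius * np.sin(
            np.linspace(0.0, np.pi / 2, n_per_side)
        )
        post = np.column_stack([self.posterior.z_of_r(r), r])
        ant = np.column_stack([self.anterior.z_of_r(r), r])[::-1]
        return np.vstack([post, ant[1:]])


def build_profile(spec: LensGeometrySpec) -> SurfaceProfile:
    """Construct the meridional surface profile for a lens prescription.

    Raises :class:`GeometryError` naming the violated constraint when the
    combination of radii, thickness, diameter and offset cannot produce a
    single-valued contour with a smooth equator.
    """
    a = spec.equatorial_radius
    anterior = _make_side(
        spec.z_anterior_pole, +1.0, spec.z_equator - spec.z_anterior_pole, a, spec.r_anterior
    )
    posterior = _make_side(
        spec.z_posterior_pole, -1.0, spec.z_posterior_pole - spec.z_equator, a, spec.r_posterior
    )
    return SurfaceProfile(spec=spec, anterior=anterior, posterior=posterior)


# refractive indices of the thick-lens power formula
N_LENS = 1.42
N_AQUEOUS = 1.336


def calibrate_thickness(
    r_a: float,
    r_p: float,
    target_cop: float,
    n_lens: float = N_LENS,
    n_aqueous: float = N_AQUEOUS,
) -> float:
    """Back-solve the lens thickness from the thick-lens power formula.

    The central optical power of a lens of equivalent index ``n_lens`` in
    aqueous is ``COP = dn/r_a + dn/r_p - t*dn^2/(r_a*r_p*n_lens)`` with
    ``dn = n_lens - n_aqueous`` and all lengths in metres; the formula is
    linear in ``t``, so inversion is exact.

    Parameters are in mm and dioptres; the returned thickness is in mm.
    """
    if r_a <= 0 or r_p <= 0:
        raise GeometryError("radii must be positive")
    dn = n_lens - n_aqueous
    ra_m, rp_m = r_a * 1e-3, r_p * 1e-3
    p_thin = dn / ra_m + dn / rp_m
    if target_cop > p_thin:
        raise GeometryError(
            f"target power {target_cop} D exceeds the zero-thickness power "
            f"{p_thin:.4f} D; no positive thickness exists"
        )
    t_m = (p_thin - target_cop) * ra_m * rp_m * n_lens / dn**2
    return t_m * 1e3


@dataclass(frozen=True)
class LayerContours:
    """Nested meridional contours delimiting the nucleus and cortical layers.

    ``scales[0]`` is the nucleus boundary scale, ``scales[-1] == 1`` the outer
    surface; all contours are affine scalings of the outer contour about the
    centre point ``(z_centre, 0)`` on the optic axis, which preserves nesting
    by construction.  Layer ids run 1 (nucleus) .. n_cortex_layers+1
    (outermost cortex).
    """

    profile: SurfaceProfile
    scales: np.ndarray
    z_centre: float

    @property
    def n_layers(self) -> int:
        return len(self.scales)

    def scale_of_point(self, z: float, r: float) -> float:
        """Relative scale of the contour through (z, r): the factor by which
        the outer contour must be shrunk about the centre to pass through the
        point (1 = on the surface, 0 = at the centre)."""
        dz, dr = z - self.z_centre, r
        if dr == 0.0 and dz == 0.0:
            return 0.0

        def f(s: float) -> float:
            # signed distance of the point scaled outward by 1/s to the surface
            zz = self.z_centre + dz / s
            rr = dr / s
            if zz <= self.profile.spec.z_anterior_pole or zz >= self.profile.spec.z_posterior_pole:
                return rr - (-1.0)  # outside axially: treat as outside
            return rr - self.profile.radial_at_z(zz)

        lo, hi = 1e-9, 1.0
        if f(hi) > 0:  # point outside the lens
            return np.inf
        return brentq(f, lo, hi, xtol=1e-10)

    def layer_of_point(self, z: float, r: float) -> int:
        """Layer index 1..n_layers containing the point, half-open binning
        [scale_{k-1}, scale_k)."""
        s = self.scale_of_point(z, r)
        if not np.isfinite(s) or s > 1.0 + 1e-9:
            raise GeometryError("point lies outside the lens")
        idx = int(np.searchsorted(self.scales, s, side="right")) + 1
        return min(idx, self.n_layers)

    def contour_points(self, k: int, n: int = 200) -> np.ndarray:
        """Sampled (z, r) polyline of contour ``k`` (0 = nucleus boundary)."""
        outer = self.profile.contour_polyline(n_per_side=n)
        s = self.scales[k]
        z = self.z_centre + s * (outer[:, 0] - self.z_centre)
        return np.column_stack([z, s * outer[:, 1]])


def layer_contours(profile: SurfaceProfile, spec: LensGeometrySpec | None = None) -> LayerContours:
    """Nest nucleus + cortical contours inside the outer profile.

    The nucleus boundary is the outer contour scaled by ``nucleus_fraction``;
    the cortical boundaries are placed at equal scale increments up to 1.
    """
    spec = spec or profile.spec
    f = spec.nucleus_fraction
    if not 0.0 < f < 1.0:
        raise GeometryError("nucleus_fraction must lie in (0, 1)")
    scales = np.linspace(f, 1.0, spec.n_cortex_layers + 1)
    return LayerContours(profile=profile, scales=scales, z_centre=spec.z_equator)


@dataclass(frozen=True)
class ZonularSpec:
    """Zonular fibre dimensions, section angles and insertion distances.

    Three fibre sections anchor on the capsule: the equatorial section at the
    equator (0 degrees), and the anterior/posterior sections at +/-15 degrees
    to the equatorial plane, inserting at a configurable axial distance from
    it.  Distances for the named combinations: A (1.0, 1.2), B (1.0, 1.6),
    C (1.0, 1.0), D (1.0, 1.4) mm.
    """

    anterior_insertion_distance: float
    posterior_insertion_distance: float
    combination_label: str = "custom"
    fibres_per_section: int = 17
    fibre_length: float = 1.5
    fibre_radius: float = 0.025
    section_angles: tuple[float, float, float] = (15.0, 0.0, -15.0)

    def __post_init__(self) -> None:
        if self.anterior_insertion_distance < 0 or self.posterior_insertion_distance < 0:
            raise GeometryError("insertion distances must be non-negative")
        if self.fibres_per_section < 1:
            raise GeometryError("fibres_per_section must be >= 1")
        if self.fibre_length <= 0 or self.fibre_radius <= 0:
            raise GeometryError("fibre dimensions must be positive")

    @classmethod
    def from_combination(cls, label: str, **overrides) -> "ZonularSpec":
        try:
            d_ant, d_post = ZONULAR_COMBINATIONS[label]
        except KeyError:
            raise GeometryError(
                f"unknown zonular combination {label!r}; expected one of "
                f"{sorted(ZONULAR_COMBINATIONS)}"
            ) from None
        return cls(
            anterior_insertion_distance=d_ant,
            posterior_insertion_distance=d_post,
            combination_label=label,
            **overrides,
        )

    @property
    def cross_section_area(self) -> float:
        """Fibre cross-section, mm^2."""
        return float(np.pi * self.fibre_radius**2)


SECTIONS = ("anterior", "equatorial", "posterior")


def locate_insertions(
    profile: SurfaceProfile, zspec: ZonularSpec
) -> dict[str, tuple[float, float]]:
    """Meridional (axial, radial) insertion points of the three sections.

    The equatorial section inserts at the contour point with a 0 degree
    tangent slope (the equator); the anterior and posterior sections insert on
    their surfaces at the configured axial distance from the equatorial plane.
    """
    z_eq, r_eq = profile.equator_point
    r_ant = profile.anterior.r_of_axial_distance_from_equator(
        zspec.anterior_insertion_distance
    )
    r_post = profile.posterior.r_of_axial_distance_from_equator(
        zspec.posterior_insertion_distance
    )
    return {
        "anterior": (z_eq - zspec.anterior_insertion_distance, r_ant),
        "equatorial": (z_eq, r_eq),
        "posterior": (z_eq + zspec.posterior_insertion_distance, r_post),
    }


@dataclass(frozen=True)
class FibreSegment:
    """One zonular fibre: straight segment from its capsule anchor to its
    free (ciliary) end, in 3D Cartesian coordinates (x, y, z), mm."""

    section: str
    azimuth_deg: float
    lens_end: np.ndarray
    free_end: np.ndarray

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.free_end - self.lens_end))


def generate_fibres(
    insertions: dict[str, tuple[float, float]],
    zspec: ZonularSpec,
    quarter_span: float = 90.0,
) -> list[FibreSegment]:
    """Place the discrete fibres of all three sections around the quarter
    model.

    Fibres are spaced uniformly in azimuth, inclusive of both boundary
    azimuths (17 fibres over 90 degrees -> 90/16 degree spacing).  Each fibre
    points outward; the anterior and posterior fibres additionally make the
    section angle with the equatorial plane, directed away from the equator on
    their own side (anterior = towards negative z).
    """
    n = zspec.fibres_per_section
    if n == 1:
        azimuths = np.array([0.0])
    else:
        azimuths = np.linspace(0.0, quarter_span, n)
    angle_by_section = dict(zip(SECTIONS, zspec.section_angles))
    fibres: list[FibreSegment] = []
    for section in SECTIONS:
        z_ins, r_ins = insertions[section]
        ang = np.deg2rad(abs(angle_by_section[section]))
        # axial direction away from the equator on this side
        if section == "anterior":
            axial_sign = -1.0
        elif section == "posterior":
            axial_sign = 1.0
        else:
            axial_sign = 0.0
        L = zspec.fibre_length
        for phi_deg in azimuths:
            phi = np.deg2rad(phi_deg)
            e_r = np.array([np.cos(phi), np.sin(phi), 0.0])
            lens_end = r_ins * e_r + np.array([0.0, 0.0, z_ins])
            direction = np.cos(ang) * e_r + np.array([0.0, 0.0, axial_sign * np.sin(ang)])
            fibres.append(
                FibreSegment(
                    section=section,
                    azimuth_deg=float(phi_deg),
                    lens_end=lens_end,
                    free_end=lens_end + L * direction,
                )
            )
    return fibres


def asymmetric_lens_spec(**overrides) -> LensGeometrySpec:
    """Default asymmetric-lens prescription (anterior flatter than posterior);
    thickness calibrated so the undeformed thick-lens power is 19.48 D."""
    defaults = dict(
        name="asymmetric",
        r_anterior=10.96,
        r_posterior=6.94,
        equatorial_diameter=9.2,
        equatorial_offset=-0.35,
    )
    defaults.update(overrides)
    if "thickness" not in defaults:
        defaults["thickness"] = calibrate_thickness(
            defaults["r_anterior"], defaults["r_posterior"], 19.48
        )
    return LensGeometrySpec(**defaults)


def symmetric_lens_spec(**overrides) -> LensGeometrySpec:
    """Default symmetric-lens prescription; thickness calibrated so the
    undeformed thick-lens power is 31.75 D."""
    defaults = dict(
        name="symmetric",
        r_anterior=5.33,
        r_posterior=5.00,
        equatorial_diameter=9.2,
        equatorial_offset=0.0,
    )
    defaults.update(overrides)
    if "thickness" not in defaults:
        defaults["thickness"] = calibrate_thickness(
            defaults["r_anterior"], defaults["r_posterior"], 31.75
        )
    return LensGeometrySpec(**defaults)
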