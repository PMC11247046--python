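"""Optical and kinematic post-processing of a stretch solution.

Turns deformed surface nodes into the quantities tabulated for each run:
paraxial radii of curvature (least-squares circle over +/-1.5 mm of the
optic axis), axial thickness, the thick-lens central optical power

    COP = (n1-na)/r_a + (n1-na)/r_p - t (n1-na)^2 / (r_a r_p n1)

with ``n1`` = 1.42 the equivalent lens index and ``na`` = 1.336 the aqueous
index (lengths in metres, power in dioptres), and the pole/equator
displacements.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import least_squares

from .fem import ElasticitySolution
from .mesh import FEMesh

__all__ = [
    "OpticsError",
    "OpticalConstants",
    "StretchRecord",
    "extract_surface_points",
    "fit_paraxial_radius",
    "fit_central_sag_polynomial",
    "central_optical_power",
    "measure_shifts",
    "axial_thickness",
]


class OpticsError(RuntimeError):
    pass


@dataclass(frozen=True)
class OpticalConstants:
    """Refractive indices and fit-region sizes of the power calculation."""

    n_lens: float = 1.42
    n_aqueous: float = 1.336
    paraxial_halfwidth: float = 1.5  # mm, circle-fit half width
    central_zone_diameter: float = 6.0  # mm, surface-extraction zone

    def __post_init__(self) -> None:
        if not self.n_lens > self.n_aqueous > 1.0:
            raise OpticsError("require n_lens > n_aqueous > 1")


@dataclass
class StretchRecord:
    """Before/after optical and kinematic summary of one stretch run."""

    lens_label: str
    combination_label: str
    r_a_initial: float
    r_a_final: float
    r_p_initial: float
    r_p_final: float
    t_initial: float
    t_final: float
    cop_initial: float
    cop_final: float
    delta_cop: float
    anterior_shift: float
    posterior_shift: float
    equatorial_shift: float
    n_elements: int = 0
    config_hash: str = ""

    def as_dict(self) -> dict:
        return asdict(self)


def extract_surface_points(
    mesh: FEMesh,
    solution: ElasticitySolution | None,
    side: str,
    zone_diameter: float = 6.0,
) -> np.ndarray:
    """Deformed (radial, axial) coordinates of outer-surface nodes of one
    side within the central zone.

    ``solution=None`` returns the undeformed surface.  The radial cut is
    applied to the deformed radial coordinate.
    """
    key = f"{side}_surface"
    if key not in mesh.node_sets:
        raise OpticsError(f"mesh has no node set {key!r}")
    nids = mesh.node_sets[key]
    xyz = mesh.nodes[nids].copy()
    if solution is not None:
        xyz = xyz + solution.u[nids]
    r = np.hypot(xyz[:, 0], xyz[:, 1])
    z = xyz[:, 2]
    keep = r <= zone_diameter / 2
    if not np.any(keep):
        raise OpticsError(
            f"no {side} surface nodes within the {zone_diameter} mm zone; "
            "refine the mesh"
        )
    return np.column_stack([r[keep], z[keep]])


def _kasa_circle(r: np.ndarray, z: np.ndarray):
    """Algebraic (Kasa) circle fit; returns centre (r0, z0) and radius."""
    A = np.column_stack([2 * r, 2 * z, np.ones_like(r)])
    b = r**2 + z**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    r0, z0, c = sol
    rad2 = c + r0**2 + z0**2
    if rad2 <= 0:
        raise OpticsError("degenerate circle fit")
    return r0, z0, float(np.sqrt(rad2))


def fit_paraxial_radius(
    points: np.ndarray, halfwidth: float = 1.5, mirror: bool = True
) -> float:
    """Least-squares circle radius of meridional (radial, axial) points with
    radial coordinate within ``halfwidth`` of the optic axis.

    A Kasa algebraic fit seeds a geometric (orthogonal-distance) refinement.
    With ``mirror`` (the default for axisymmetric surface caps) the points
    are reflected across the axis so the fitted centre is not biased to one
    side; pass ``mirror=False`` to fit arbitrary point sets, e.g. the
    circumcircle of three points.
    """
    pts = np.asarray(points, dtype=float)
    pts = pts[np.abs(pts[:, 0]) <= halfwidth]
    if len(pts) < 3:
        raise OpticsError("need at least 3 points within the paraxial zone")
    r, z = pts[:, 0], pts[:, 1]
    if mirror:
        r = np.concatenate([r, -r])
        z = np.concatenate([z, z])
    if np.ptp(r) < 1e-12 and np.ptp(z) < 1e-12:
        raise OpticsError("points are coincident")
    try:
        r0, z0, rad = _kasa_circle(r, z)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise OpticsError("circle fit failed") from exc
    if not np.isfinite(rad):
        raise OpticsError("collinear points: circle radius is infinite")

    def resid(p):
        return np.hypot(r - p[0], z - p[1]) - p[2]

    out = least_squares(resid, x0=[r0, z0, rad], method="lm", xtol=1e-14, ftol=1e-14)
    rad = float(abs(out.x[2]))
    if not np.isfinite(rad) or rad <= 0:
        raise OpticsError("geometric circle refinement failed")
    return rad


def fit_central_sag_polynomial(points: np.ndarray, zone_radius: float = 3.0) -> np.ndarray:
    """Even-polynomial sag fit z = c0 + c2 r^2 + c4 r^4 over the central
    zone; exported for surface-shape inspection (the power calculation uses
    only the paraxial circle fit)."""
    pts = np.asarray(points, dtype=float)
    pts = pts[np.abs(pts[:, 0]) <= zone_radius]
    if len(pts) < 3:
        raise OpticsError("too few points for the sag fit")
    r, z = pts[:, 0], pts[:, 1]
    A = np.column_stack([np.ones_like(r), r**2, r**4])
    coeffs, *_ = np.linalg.lstsq(A, z, rcond=None)
    return coeffs


def central_optical_power(
    r_a: float, r_p: float, t: float, constants: OpticalConstants = OpticalConstants()
) -> float:
    """Thick-lens power in dioptres from radii and thickness in mm.

    Both radii are entered as positive magnitudes (the posterior surface's
    sign is absorbed into the additive form of the formula).
    """
    if r_a <= 0 or r_p <= 0:
        raise OpticsError("radii must be positive magnitudes")
    dn = constants.n_lens - constants.n_aqueous
    ra, rp, tm = r_a * 1e-3, r_p * 1e-3, t * 1e-3
    return dn / ra + dn / rp - tm * dn**2 / (ra * rp * constants.n_lens)


def measure_shifts(mesh: FEMesh, solution: ElasticitySolution) -> tuple[float, float, float]:
    """(anterior, posterior, equatorial) displacement magnitudes, mm.

    Pole shifts are |axial displacement| at the surface pole nodes; the
    equatorial shift is the radial displacement of the equator node on the
    y=0 symmetry plane.
    """
    for key in ("anterior_pole", "posterior_pole", "equator_node_y0"):
        if key not in mesh.node_sets:
            raise OpticsError(f"mesh has no node set {key!r}")
    na = int(mesh.node_sets["anterior_pole"][0])
    npo = int(mesh.node_sets["posterior_pole"][0])
    neq = int(mesh.node_sets["equator_node_y0"][0])
    anterior = abs(float(solution.u[na, 2]))
    posterior = abs(float(solution.u[npo, 2]))
    x, y = mesh.nodes[neq, 0], mesh.nodes[neq, 1]
    e_r = np.array([x, y]) / np.hypot(x, y)
    equatorial = float(solution.u[neq, :2] @ e_r)
    return anterior, posterior, equatorial


def axial_thickness(mesh: FEMesh, solution: ElasticitySolution | None = None) -> float:
    """Deformed pole-to-pole distance along the optic axis, mm."""
    na = int(mesh.node_sets["anterior_pole"][0])
    npo = int(mesh.node_sets["posterior_pole"][0])
    za, zp = mesh.nodes[na, 2], mesh.nodes[npo, 2]
    if solution is not None:
        za += solution.u[na, 2]
        zp += solution.u[npo, 2]
    return float(abs(zp - za))
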