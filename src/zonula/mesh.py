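"""Structured hexahedral meshing of the quarter lens.

The meridional half-section is gridded by two families of lines: scaled
copies of the outer contour (so every ring boundary coincides with a layer
contour and each element belongs to exactly one stiffness layer) and rays
from the lens centre to meridional stations distributed by arc length along
the outer contour.  Sweeping this quad grid through 90 degrees of azimuth
produces the quarter model; cells touching the optic axis or the centre are
collapsed hexahedra (wedges/tets with repeated nodes), which trilinear
elements handle with non-negative Jacobians.

The capsule is skinned onto the outer hex faces as conforming membrane
quads, and zonular fibres become 2-node bars whose lens ends are snapped to
the nearest capsule node and tied (equal translations) to the surrounding
capsule nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import FibreSegment, LayerContours, SurfaceProfile

__all__ = [
    "MeshError",
    "Resolution",
    "FEMesh",
    "mesh_quarter_lens",
    "skin_capsule",
    "attach_zonules",
    "structured_box_mesh",
    "structured_annulus_mesh",
]


class MeshError(RuntimeError):
    pass


@dataclass(frozen=True)
class Resolution:
    """Structured-grid density.

    ``n_meridional`` — stations along the outer contour (pole to pole);
    ``n_radial`` — target radial subdivisions across the lens half-width
    (the nucleus receives ``max(2, n_radial*nucleus_fraction)`` rings, each
    cortical layer at least one); ``n_azimuthal`` — intervals over the 90
    degree sweep.
    """

    n_meridional: int = 40
    n_radial: int = 16
    n_azimuthal: int = 16

    def __post_init__(self) -> None:
        if min(self.n_meridional, self.n_radial, self.n_azimuthal) < 2:
            raise MeshError("resolution counts must each be >= 2")


@dataclass
class FEMesh:
    """Finite-element discretisation of the quarter lens (or of a test body).

    Coordinates are mm.  ``hexes`` are 8-node trilinear bricks (possibly with
    repeated node ids for collapsed axis/centre cells); ``hex_layer`` gives the
    1-based stiffness layer of each.  ``capsule_quads`` and ``zonule_bars``
    are filled by :func:`skin_capsule` / :func:`attach_zonules`.
    """

    nodes: np.ndarray
    hexes: np.ndarray
    hex_layer: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    surface_faces: np.ndarray | None = None
    capsule_quads: np.ndarray | None = None
    capsule_thickness: float | None = None
    zonule_bars: np.ndarray | None = None
    zonule_area: float | None = None
    zonule_sections: list[str] = field(default_factory=list)
    ties: list[tuple[int, np.ndarray]] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_hexes(self) -> int:
        return len(self.hexes)

    def element_count(self) -> int:
        n = self.n_hexes
        if self.capsule_quads is not None:
            n += len(self.capsule_quads)
        if self.zonule_bars is not None:
            n += len(self.zonule_bars)
        return n


# ----------------------------------------------------------------------
# quarter-lens meshing

_DENSE = 2000  # samples per side for arc-length tables


def _side_arclength_table(profile: SurfaceProfile, which: str):
    """(r, z, cumulative arc length) from the pole to the equator."""
    side = profile.side(which)
    t = np.linspace(0.0, np.pi / 2, _DENSE)
    r = side.a * np.sin(t)
    z = side.z_of_r(r)
    ds = np.hypot(np.diff(r), np.diff(z))
    s = np.concatenate([[0.0], np.cumsum(ds)])
    return r, z, s


def _stations_for_side(r, z, s, n_int: int, snap_arcs: list[float]):
    """Arc-length positions of n_int+1 stations from pole (s=0) to equator,
    with interior stations snapped exactly onto ``snap_arcs``."""
    total = s[-1]
    arcs = np.linspace(0.0, total, n_int + 1)
    for sa in snap_arcs:
        if sa <= 0.0 or sa >= total:
            continue
        j = int(np.argmin(np.abs(arcs[1:-1] - sa))) + 1
        arcs[j] = sa
    arcs = np.sort(arcs)
    rj = np.interp(arcs, s, r)
    zj = np.interp(arcs, s, z)
    rj[0], zj[0] = r[0], z[0]
    rj[-1], zj[-1] = r[-1], z[-1]
    return rj, zj


def _radial_scales(contours: LayerContours, n_radial: int):
    """Ring scale values 0..1 with every layer boundary included; returns
    (scales, 1-based layer id per ring band)."""
    layer_bounds = contours.scales  # nucleus_fraction .. 1
    f = layer_bounds[0]
    n_cortex = len(layer_bounds) - 1
    n_nuc = max(2, round(n_radial * f))
    n_cor = max(1, round(n_radial * (1 - f) / max(n_cortex, 1)))
    rho = list(np.linspace(0.0, f, n_nuc + 1))
    band_layer = [1] * n_nuc
    for layer in range(n_cortex):
        lo, hi = layer_bounds[layer], layer_bounds[layer + 1]
        seg = np.linspace(lo, hi, n_cor + 1)[1:]
        rho.extend(seg)
        band_layer.extend([layer + 2] * n_cor)
    return np.asarray(rho), np.asarray(band_layer, dtype=int)


def mesh_quarter_lens(
    profile: SurfaceProfile,
    contours: LayerContours,
    resolution: Resolution = Resolution(),
    snap_meridional_points: list[tuple[float, float]] | None = None,
) -> FEMesh:
    """Sweep a layer-conforming meridional grid through 90 degrees of azimuth.

    ``snap_meridional_points`` are (axial, radial) points on the outer
    contour (e.g. zonular insertion points); the nearest meridional station
    on the matching side is moved exactly onto each, so insertion rings exist
    at every resolution.
    """
    spec = profile.spec
    z_eq = spec.z_equator
    zc = contours.z_centre

    r_post, z_post, s_post = _side_arclength_table(profile, "posterior")
    r_ant, z_ant, s_ant = _side_arclength_table(profile, "anterior")
    L_post, L_ant = s_post[-1], s_ant[-1]

    n_m = resolution.n_meridional
    n_post = int(np.clip(round(n_m * L_post / (L_post + L_ant)), 2, n_m - 2))
    n_ant = n_m - n_post

    snaps_post, snaps_ant = [], []
    for (zs, rs) in snap_meridional_points or []:
        if zs > z_eq:  # posterior side
            snaps_post.append(float(np.interp(rs, r_post, s_post)))
        elif zs < z_eq:
            snaps_ant.append(float(np.interp(rs, r_ant, s_ant)))

    rj_post, zj_post = _stations_for_side(r_post, z_post, s_post, n_post, snaps_post)
    rj_ant, zj_ant = _stations_for_side(r_ant, z_ant, s_ant, n_ant, snaps_ant)

    # full station list: posterior pole (j=0) -> equator (j=n_post) -> anterior pole
    r_st = np.concatenate([rj_post, rj_ant[::-1][1:]])
    z_st = np.concatenate([zj_post, zj_ant[::-1][1:]])
    j_eq = n_post
    n_stations = len(r_st)  # n_m + 1

    rho, band_layer = _radial_scales(contours, resolution.n_radial)
    n_rings = len(rho) - 1
    n_a = resolution.n_azimuthal
    phi = np.linspace(0.0, np.pi / 2, n_a + 1)

    # node ids: centre (0), axis columns (j=0 and j=n_m, i>=1), then regular
    ids = np.full((len(rho), n_stations, n_a + 1), -1, dtype=int)
    coords: list[tuple[float, float, float]] = [(0.0, 0.0, zc)]
    ids[0, :, :] = 0
    next_id = 1
    axis_js = (0, n_stations - 1)
    for j in axis_js:
        for i in range(1, len(rho)):
            zi = zc + rho[i] * (z_st[j] - zc)
            ids[i, j, :] = next_id
            coords.append((0.0, 0.0, zi))
            next_id += 1
    for i in range(1, len(rho)):
        for j in range(n_stations):
            if j in axis_js:
                continue
            ri = rho[i] * r_st[j]
            zi = zc + rho[i] * (z_st[j] - zc)
            for k in range(n_a + 1):
                ids[i, j, k] = next_id
                coords.append((ri * np.cos(phi[k]), ri * np.sin(phi[k]), zi))
                next_id += 1
    nodes = np.asarray(coords, dtype=float)

    hexes, hex_layer = [], []
    for i in range(n_rings):
        for j in range(n_stations - 1):
            for k in range(n_a):
                c = [
                    ids[i, j, k],
                    ids[i + 1, j, k],
                    ids[i + 1, j + 1, k],
                    ids[i, j + 1, k],
                    ids[i, j, k + 1],
                    ids[i + 1, j, k + 1],
                    ids[i + 1, j + 1, k + 1],
                    ids[i, j + 1, k + 1],
                ]
                hexes.append(c)
                hex_layer.append(band_layer[i])
    hexes = np.asarray(hexes, dtype=int)
    hex_layer = np.asarray(hex_layer, dtype=int)

    # fix global orientation if the sweep handedness came out negative
    from .fem import hex_volumes

    vols = hex_volumes(nodes, hexes)
    if vols.sum() < 0:
        hexes = hexes[:, [4, 5, 6, 7, 0, 1, 2, 3]]
        vols = -vols
    bad = np.where(vols < -1e-12)[0]
    if len(bad):
        raise MeshError(f"negative-volume cell(s) at hex indices {bad[:5].tolist()}")

    # outer surface faces (ring i = n_rings), oriented consistently with hexes
    i = n_rings
    faces = []
    face_station = []
    for j in range(n_stations - 1):
        for k in range(n_a):
            faces.append([ids[i, j, k], ids[i, j + 1, k], ids[i, j + 1, k + 1], ids[i, j, k + 1]])
            face_station.append(j)
    surface_faces = np.asarray(faces, dtype=int)

    surf_ids = ids[n_rings]
    node_sets = {
        "centre_node": np.array([0]),
        "symmetry_plane_y": np.unique(ids[:, :, 0]),
        "symmetry_plane_x": np.unique(ids[:, :, n_a]),
        "posterior_pole": np.array([ids[n_rings, 0, 0]]),
        "anterior_pole": np.array([ids[n_rings, n_stations - 1, 0]]),
        "equator_nodes": np.unique(surf_ids[j_eq]),
        "equator_node_y0": np.array([surf_ids[j_eq, 0]]),
        "anterior_surface": np.unique(surf_ids[j_eq + 1 :]),
        "posterior_surface": np.unique(surf_ids[:j_eq]),
    }

    return FEMesh(
        nodes=nodes,
        hexes=hexes,
        hex_layer=hex_layer,
        node_sets=node_sets,
        surface_faces=surface_faces,
    )


def skin_capsule(mesh: FEMesh, thickness: float = 0.006) -> FEMesh:
    """Attach one conforming membrane quad per outer hex face."""
    if thickness <= 0:
        raise MeshError("capsule thickness must be positive")
    if mesh.surface_faces is None:
        raise MeshError("mesh has no identified outer surface to skin")
    mesh.capsule_quads = mesh.surface_faces.copy()
    mesh.capsule_thickness = float(thickness)
    return mesh


def _local_spacing(mesh: FEMesh, node: int) -> float:
    """Median edge length of capsule quads incident to ``node``."""
    quads = mesh.capsule_quads
    inc = quads[np.any(quads == node, axis=1)]
    lengths = []
    for q in inc:
        for a in range(4):
            n1, n2 = q[a], q[(a + 1) % 4]
            if n1 != n2:
                lengths.append(np.linalg.norm(mesh.nodes[n1] - mesh.nodes[n2]))
    return float(np.median(lengths))


def attach_zonules(
    mesh: FEMesh,
    fibres: list[FibreSegment],
    tie_radius: float | None = 0.5,
    zonule_area: float = float(np.pi * 0.025**2),
) -> FEMesh:
    """Turn fibre segments into bar elements anchored on the capsule.

    Each fibre's lens end is snapped to the nearest capsule node (the tie
    master); capsule nodes within ``tie_radius`` of the snapped position are
    tied to it with equal translations.  The free end becomes a new node at
    the snapped position plus the fibre's own span vector, so length and
    angle are preserved exactly.

    ``tie_radius`` defaults to a fixed 0.5 mm physical patch (about the
    azimuthal spacing of adjacent fibres at the equator), which keeps the
    modelled insertion footprint independent of mesh density; pass ``None``
    to use 1.5x the local capsule nodal spacing instead.
    """
    if mesh.capsule_quads is None:
        raise MeshError("attach_zonules requires a skinned capsule")
    cap_nodes = np.unique(mesh.capsule_quads)
    cap_xyz = mesh.nodes[cap_nodes]

    new_nodes = [mesh.nodes]
    next_id = mesh.n_nodes
    bars, sections = [], []
    free_by_section: dict[str, list[int]] = {}
    lens_by_section: dict[str, list[int]] = {}

    # pass 1: snap every fibre to its master node
    masters: list[int] = []
    radii: dict[int, float] = {}
    for fibre in fibres:
        d2 = np.sum((cap_xyz - fibre.lens_end) ** 2, axis=1)
        nearest = int(np.argmin(d2))
        master = int(cap_nodes[nearest])
        radius = tie_radius if tie_radius is not None else 1.5 * _local_spacing(mesh, master)
        if np.sqrt(d2[nearest]) > radius:
            raise MeshError(
                f"no capsule node within tie radius {radius:.3f} mm of "
                f"{fibre.section} fibre at azimuth {fibre.azimuth_deg:.1f} deg"
            )
        masters.append(master)
        radii[master] = max(radius, radii.get(master, 0.0))

        free_xyz = mesh.nodes[master] + (fibre.free_end - fibre.lens_end)
        free_id = next_id
        next_id += 1
        new_nodes.append(free_xyz[None, :])
        bars.append((master, free_id))
        sections.append(fibre.section)
        free_by_section.setdefault(fibre.section, []).append(free_id)
        lens_by_section.setdefault(fibre.section, []).append(master)

    # pass 2: each capsule node joins the patch of its nearest master within
    # reach; masters never become slaves, so patches are disjoint and the tie
    # graph is flat (no chains)
    uniq_masters = sorted(set(masters))
    m_xyz = mesh.nodes[uniq_masters]
    slaves_of: dict[int, list[int]] = {m: [] for m in uniq_masters}
    master_set = set(uniq_masters)
    for n, xyz in zip(cap_nodes, cap_xyz):
        if int(n) in master_set or int(n) == 0:
            continue
        d = np.linalg.norm(m_xyz - xyz, axis=1)
        best = int(np.argmin(d))
        m = uniq_masters[best]
        if d[best] <= radii[m]:
            slaves_of[m].append(int(n))
    for m in uniq_masters:
        if slaves_of[m]:
            mesh.ties.append((m, np.asarray(slaves_of[m], dtype=int)))

    mesh.nodes = np.vstack(new_nodes)
    mesh.zonule_bars = np.asarray(bars, dtype=int)
    mesh.zonule_area = float(zonule_area)
    mesh.zonule_sections = sections
    for sec, nids in free_by_section.items():
        mesh.node_sets[f"free_ends_{sec}"] = np.asarray(nids, dtype=int)
    for sec, nids in lens_by_section.items():
        mesh.node_sets[f"lens_ends_{sec}"] = np.unique(np.asarray(nids, dtype=int))
    return mesh


# ----------------------------------------------------------------------
# small structured meshes for verification problems


def structured_box_mesh(
    nx: int, ny: int, nz: int, lx: float = 1.0, ly: float = 1.0, lz: float = 1.0
) -> FEMesh:
    """Regular box of nx*ny*nz hexes with face node sets (xmin, xmax, ...)."""
    xs, ys, zs = (np.linspace(0, l, n + 1) for l, n in ((lx, nx), (ly, ny), (lz, nz)))
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    nid = np.arange(nodes.shape[0]).reshape(nx + 1, ny + 1, nz + 1)
    hexes = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                hexes.append(
                    [
                        nid[i, j, k],
                        nid[i + 1, j, k],
                        nid[i + 1, j + 1, k],
                        nid[i, j + 1, k],
                        nid[i, j, k + 1],
                        nid[i + 1, j, k + 1],
                        nid[i + 1, j + 1, k + 1],
                        nid[i, j + 1, k + 1],
                    ]
                )
    node_sets = {
        "xmin": nid[0].ravel(),
        "xmax": nid[-1].ravel(),
        "ymin": nid[:, 0].ravel(),
        "ymax": nid[:, -1].ravel(),
        "zmin": nid[:, :, 0].ravel(),
        "zmax": nid[:, :, -1].ravel(),
    }
    return FEMesh(
        nodes=nodes,
        hexes=np.asarray(hexes, dtype=int),
        hex_layer=np.ones(len(hexes), dtype=int),
        node_sets=node_sets,
    )


def structured_annulus_mesh(
    r_inner: float, r_outer: float, n_radial: int, n_theta: int, depth: float = 0.2
) -> FEMesh:
    """Quarter annulus, one element deep in z, for plane-strain benchmarks."""
    rr = np.linspace(r_inner, r_outer, n_radial + 1)
    tt = np.linspace(0.0, np.pi / 2, n_theta + 1)
    zz = np.array([0.0, depth])
    nid = np.arange((n_radial + 1) * (n_theta + 1) * 2).reshape(n_radial + 1, n_theta + 1, 2)
    nodes = np.empty((nid.size, 3))
    for i, r in enumerate(rr):
        for j, t in enumerate(tt):
            for k, z in enumerate(zz):
                nodes[nid[i, j, k]] = (r * np.cos(t), r * np.sin(t), z)
    hexes = []
    for i in range(n_radial):
        for j in range(n_theta):
            hexes.append(
                [
                    nid[i, j, 0],
                    nid[i + 1, j, 0],
                    nid[i + 1, j + 1, 0],
                    nid[i, j + 1, 0],
                    nid[i, j, 1],
                    nid[i + 1, j, 1],
                    nid[i + 1, j + 1, 1],
                    nid[i, j + 1, 1],
                ]
            )
    node_sets = {
        "inner": nid[0].ravel(),
        "outer": nid[-1].ravel(),
        "theta0": nid[:, 0].ravel(),
        "theta90": nid[:, -1].ravel(),
        "zfaces": np.concatenate([nid[:, :, 0].ravel(), nid[:, :, 1].ravel()]),
    }
    return FEMesh(
        nodes=nodes,
        hexes=np.asarray(hexes, dtype=int),
        hex_layer=np.ones(len(hexes), dtype=int),
        node_sets=node_sets,
    )
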