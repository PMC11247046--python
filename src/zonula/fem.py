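"""Small-strain linear elasticity on hex + membrane + bar meshes.

Element technology
------------------
* Lens volume: 8-node trilinear hexahedra with 2x2x2 Gauss quadrature and
  B-bar (mean-dilatation) treatment of the volumetric strain, which relieves
  volumetric locking at the lens's Poisson ratio of 0.49.  Collapsed-node
  bricks (axis wedges) are admitted with non-negative Jacobians.
* Capsule: 4-node membrane quads contributing plane-stress stiffness times
  thickness in their local tangent planes (no bending).
* Zonular fibres: 2-node axial bars of stiffness E*A/L.

Constraints (symmetry-plane fixities, the fully fixed lens centre, the
radially driven fibre free ends, and the capsule tie patches) are eliminated
by master-slave reduction before a direct sparse factorisation.  Units are
mm / N / MPa throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

__all__ = [
    "FEMError",
    "ConstraintSet",
    "ElasticitySolution",
    "assemble",
    "build_constraints",
    "solve_static",
    "von_mises",
    "von_mises_from_voigt",
    "hex_volumes",
    "mesh_volume",
    "capsule_area",
]


class FEMError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# trilinear hex shape machinery

_XI = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)

_G = 1.0 / np.sqrt(3.0)
_GAUSS = np.array([[sx * _G, sy * _G, sz * _G] for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)])


def _dshape_hex(xi: np.ndarray) -> np.ndarray:
    """dN/dxi (8, 3) at one natural point."""
    out = np.empty((8, 3))
    for a in range(8):
        xa, ya, za = _XI[a]
        out[a, 0] = xa * (1 + ya * xi[1]) * (1 + za * xi[2]) / 8.0
        out[a, 1] = (1 + xa * xi[0]) * ya * (1 + za * xi[2]) / 8.0
        out[a, 2] = (1 + xa * xi[0]) * (1 + ya * xi[1]) * za / 8.0
    return out


_DSHAPE_GP = np.stack([_dshape_hex(xi) for xi in _GAUSS])  # (8gp, 8, 3)
_DSHAPE_C = _dshape_hex(np.zeros(3))

_M_VOIGT = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])


def _elastic_D(E: np.ndarray, nu: float) -> np.ndarray:
    """Isotropic 6x6 stiffness (engineering shear), batched over elements."""
    E = np.atleast_1d(np.asarray(E, dtype=float))
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((len(E), 6, 6))
    for i in range(3):
        for j in range(3):
            D[:, i, j] = lam
        D[:, i, i] += 2 * mu
        D[:, 3 + i, 3 + i] = mu
    return D


def _hex_geometry(coords: np.ndarray):
    """Per-Gauss-point detJ (E, 8) and dN/dx (E, 8gp, 8nodes, 3)."""
    n_e = coords.shape[0]
    detJ = np.empty((n_e, 8))
    dNdx = np.empty((n_e, 8, 8, 3))
    for g in range(8):
        dN = _DSHAPE_GP[g]  # (8, 3)
        J = np.einsum("eaj,ak->ejk", coords, dN)  # dx_j/dxi_k
        detJ[:, g] = np.linalg.det(J)
        ok = np.abs(detJ[:, g]) > 1e-300
        Jinv = np.empty_like(J)
        Jinv[ok] = np.linalg.inv(J[ok])
        Jinv[~ok] = 0.0
        dNdx[:, g] = np.einsum("ak,ekj->eaj", dN, Jinv)
    return detJ, dNdx


def hex_volumes(nodes: np.ndarray, hexes: np.ndarray) -> np.ndarray:
    """Signed trilinear volume of each hex by 2x2x2 quadrature."""
    coords = nodes[hexes]
    detJ, _ = _hex_geometry(coords)
    return detJ.sum(axis=1)


def mesh_volume(mesh) -> float:
    return float(hex_volumes(mesh.nodes, mesh.hexes).sum())


def _b_matrix(dNdx_g: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix (E, 6, 24) from dN/dx (E, 8, 3).
    Voigt order xx, yy, zz, xy, yz, zx with engineering shear."""
    n_e = dNdx_g.shape[0]
    B = np.zeros((n_e, 6, 24))
    dx, dy, dz = dNdx_g[:, :, 0], dNdx_g[:, :, 1], dNdx_g[:, :, 2]
    B[:, 0, 0::3] = dx
    B[:, 1, 1::3] = dy
    B[:, 2, 2::3] = dz
    B[:, 3, 0::3] = dy
    B[:, 3, 1::3] = dx
    B[:, 4, 1::3] = dz
    B[:, 4, 2::3] = dy
    B[:, 5, 0::3] = dz
    B[:, 5, 2::3] = dx
    return B


def _divergence_row(dNdx_g: np.ndarray) -> np.ndarray:
    """(E, 24) row mapping nodal displacements to volumetric strain."""
    n_e = dNdx_g.shape[0]
    b = np.empty((n_e, 24))
    b[:, 0::3] = dNdx_g[:, :, 0]
    b[:, 1::3] = dNdx_g[:, :, 1]
    b[:, 2::3] = dNdx_g[:, :, 2]
    return b


def _hex_stiffness_batch(
    coords: np.ndarray, E: np.ndarray, nu: float, bbar: bool = True
) -> np.ndarray:
    """Element stiffness matrices (E, 24, 24)."""
    detJ, dNdx = _hex_geometry(coords)
    vol = detJ.sum(axis=1)
    if np.any(vol <= 0):
        bad = int(np.argmin(vol))
        raise FEMError(f"non-positive element volume at hex {bad}")
    neg = detJ < -1e-12 * vol[:, None]
    if np.any(neg):
        bad = int(np.where(neg.any(axis=1))[0][0])
        raise FEMError(f"negative Jacobian at hex {bad}")

    D = _elastic_D(E, nu)
    if bbar:
        bdiv_mean = np.einsum("egd,eg->ed", _divergence_row_all(dNdx), detJ) / vol[:, None]
    K = np.zeros((coords.shape[0], 24, 24))
    for g in range(8):
        B = _b_matrix(dNdx[:, g])
        if bbar:
            corr = (bdiv_mean - _divergence_row(dNdx[:, g])) / 3.0
            B = B + _M_VOIGT[None, :, None] * corr[:, None, :]
        K += np.einsum("eip,eij,ejq,e->epq", B, D, B, detJ[:, g], optimize=True)
    return K


def _divergence_row_all(dNdx: np.ndarray) -> np.ndarray:
    """(E, 8gp, 24) divergence rows at every Gauss point."""
    n_e = dNdx.shape[0]
    b = np.empty((n_e, 8, 24))
    for g in range(8):
        b[:, g] = _divergence_row(dNdx[:, g])
    return b


# ----------------------------------------------------------------------
# membrane quads and bars

_GAUSS2 = np.array([[sx * _G, sy * _G] for sy in (-1, 1) for sx in (-1, 1)])
_XI2 = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)


def _dshape_quad(xi):
    out = np.empty((4, 2))
    for a in range(4):
        xa, ya = _XI2[a]
        out[a, 0] = xa * (1 + ya * xi[1]) / 4.0
        out[a, 1] = (1 + xa * xi[0]) * ya / 4.0
    return out


_DSHAPE_Q = np.stack([_dshape_quad(xi) for xi in _GAUSS2])


def _membrane_stiffness(coords: np.ndarray, E: float, nu: float, thickness: float) -> np.ndarray:
    """Curved 4-node membrane stiffness (12 x 12) in global dofs."""
    Dps = E / (1 - nu**2) * np.array([[1, nu, 0], [nu, 1, 0], [0, 0, (1 - nu) / 2]])
    K = np.zeros((12, 12))
    for g in range(4):
        dN = _DSHAPE_Q[g]  # (4, 2)
        a1 = coords.T @ dN[:, 0]
        a2 = coords.T @ dN[:, 1]
        n = np.cross(a1, a2)
        dA = np.linalg.norm(n)
        if dA < 1e-14:
            continue  # collapsed corner of a degenerate (triangle) quad
        e1 = a1 / np.linalg.norm(a1)
        e2 = np.cross(n / dA, e1)
        # 2x2 surface Jacobian in the local frame
        J = np.array([[a1 @ e1, a2 @ e1], [a1 @ e2, a2 @ e2]])
        dNdx = dN @ np.linalg.inv(J)  # (4, 2) in local coords
        B = np.zeros((3, 12))
        for a in range(4):
            cols = slice(3 * a, 3 * a + 3)
            B[0, cols] = dNdx[a, 0] * e1
            B[1, cols] = dNdx[a, 1] * e2
            B[2, cols] = dNdx[a, 1] * e1 + dNdx[a, 0] * e2
        K += thickness * B.T @ Dps @ B * abs(np.linalg.det(J))
    return K


def _bar_stiffness(x1: np.ndarray, x2: np.ndarray, EA: float) -> tuple[np.ndarray, np.ndarray, float]:
    d = x2 - x1
    L = np.linalg.norm(d)
    if L <= 0:
        raise FEMError("zero-length bar")
    d = d / L
    k = EA / L
    block = k * np.outer(d, d)
    K = np.block([[block, -block], [-block, block]])
    return K, d, L


# ----------------------------------------------------------------------
# assembly

def assemble(mesh, materials, bbar: bool = True) -> sp.csr_matrix:
    """Global stiffness matrix (3 dofs per node) of hexes + capsule + bars."""
    n_dof = 3 * mesh.n_nodes
    rows, cols, vals = [], [], []

    E_layer = materials.layer_E_mpa()
    E_hex = E_layer[mesh.hex_layer - 1]
    Ke = _hex_stiffness_batch(mesh.nodes[mesh.hexes], E_hex, materials.nu_lens, bbar=bbar)
    dofs = (3 * mesh.hexes[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)
    rows.append(np.repeat(dofs, 24, axis=1).ravel())
    cols.append(np.tile(dofs, (1, 24)).ravel())
    vals.append(Ke.ravel())

    if mesh.capsule_quads is not None:
        for q in mesh.capsule_quads:
            Kq = _membrane_stiffness(
                mesh.nodes[q], materials.E_capsule, materials.nu_capsule, mesh.capsule_thickness
            )
            qd = (3 * q[:, None] + np.arange(3)[None, :]).ravel()
            rows.append(np.repeat(qd, 12))
            cols.append(np.tile(qd, 12))
            vals.append(Kq.ravel())

    if mesh.zonule_bars is not None:
        EA = materials.E_zonule * mesh.zonule_area
        for n1, n2 in mesh.zonule_bars:
            Kb, _, _ = _bar_stiffness(mesh.nodes[n1], mesh.nodes[n2], EA)
            bd = np.concatenate([3 * n1 + np.arange(3), 3 * n2 + np.arange(3)])
            rows.append(np.repeat(bd, 6))
            cols.append(np.tile(bd, 6))
            vals.append(Kb.ravel())

    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_dof, n_dof),
    ).tocsr()
    return K


# ----------------------------------------------------------------------
# constraints

@dataclass
class ConstraintSet:
    """Homogeneous fixities, prescribed displacements and tie couplings."""

    fixed: list[tuple[int, int]] = field(default_factory=list)
    prescribed: list[tuple[int, int, float]] = field(default_factory=list)
    ties: list[tuple[int, np.ndarray]] = field(default_factory=list)

    def fix_node(self, node: int) -> None:
        for d in range(3):
            self.fixed.append((node, d))

    def n_constraints(self) -> int:
        return len(self.fixed) + len(self.prescribed)


def build_constraints(mesh, stretch: float = 0.5) -> ConstraintSet:
    """Boundary conditions of the stretch simulation.

    Symmetry planes lose their normal displacement, the lens centre is fully
    fixed, and every fibre free end is driven radially outward by ``stretch``
    mm with its azimuthal and axial components held at zero (all three
    components prescribed in the Cartesian frame).
    """
    cs = ConstraintSet(ties=list(mesh.ties))
    sets = mesh.node_sets
    for name, direction in (("symmetry_plane_y", 1), ("symmetry_plane_x", 0)):
        if name not in sets:
            raise FEMError(f"missing node set {name!r}")
        for n in sets[name]:
            cs.fixed.append((int(n), direction))
    if "centre_node" not in sets:
        raise FEMError("missing node set 'centre_node'")
    for n in sets["centre_node"]:
        cs.fix_node(int(n))
    for name, nodes in sets.items():
        if not name.startswith("free_ends_"):
            continue
        for n in nodes:
            x, y = mesh.nodes[n, 0], mesh.nodes[n, 1]
            r = np.hypot(x, y)
            if r <= 0:
                raise FEMError(f"fibre free end {n} lies on the optic axis")
            cs.prescribed.append((int(n), 0, stretch * x / r))
            cs.prescribed.append((int(n), 1, stretch * y / r))
            cs.prescribed.append((int(n), 2, 0.0))
    return cs


# ----------------------------------------------------------------------
# solve

@dataclass
class ElasticitySolution:
    """Nodal displacements with element stress recovery and diagnostics."""

    u: np.ndarray  # (N, 3) mm
    reactions: np.ndarray  # (N, 3) N
    hex_stress: np.ndarray  # (E, 6) MPa, Voigt xx yy zz xy yz zx at centroid
    hex_von_mises: np.ndarray  # (E,) MPa
    capsule_von_mises: np.ndarray | None  # (Q,) MPa
    bar_axial_force: np.ndarray | None  # (B,) N, tension positive
    strain_energy: float
    external_work: float
    residual: float


def _dof_representatives(n_dof: int, ties) -> np.ndarray:
    rep = np.arange(n_dof)
    for master, slaves in ties:
        for s in np.atleast_1d(slaves):
            for d in range(3):
                rep[3 * int(s) + d] = 3 * int(master) + d
    # flatten master-slave chains to their roots
    for _ in range(n_dof):
        nxt = rep[rep]
        if np.array_equal(nxt, rep):
            return rep
        rep = nxt
    raise FEMError("tie graph contains a cycle")


def solve_static(stiffness: sp.csr_matrix, constraints: ConstraintSet, mesh=None, materials=None) -> ElasticitySolution:
    """Solve K u = 0 under the constraint set; recover stresses if the mesh
    and materials are supplied.

    Raises :class:`FEMError` if the reduced system is singular (remaining
    rigid-body modes) or a dof receives two conflicting prescribed values.
    """
    n_dof = stiffness.shape[0]
    rep = _dof_representatives(n_dof, constraints.ties)

    dirichlet: dict[int, float] = {}
    for node, d in constraints.fixed:
        _add_dirichlet(dirichlet, rep[3 * node + d], 0.0)
    for node, d, val in constraints.prescribed:
        _add_dirichlet(dirichlet, rep[3 * node + d], float(val))

    is_rep = rep == np.arange(n_dof)
    free_mask = is_rep.copy()
    for dof in dirichlet:
        free_mask[dof] = False
    free = np.where(free_mask)[0]
    col_of = np.full(n_dof, -1)
    col_of[free] = np.arange(len(free))

    # expansion u = T u_f + u_p
    t_cols = col_of[rep]
    keep = t_cols >= 0
    T = sp.coo_matrix(
        (np.ones(keep.sum()), (np.where(keep)[0], t_cols[keep])), shape=(n_dof, len(free))
    ).tocsr()
    val_of = np.zeros(n_dof)
    has_val = np.zeros(n_dof, dtype=bool)
    for dof, val in dirichlet.items():
        val_of[dof] = val
        has_val[dof] = True
    u_p = np.where(has_val[rep], val_of[rep], 0.0)  # tied slaves follow masters
    Kff = (T.T @ stiffness @ T).tocsc()
    f = -T.T @ (stiffness @ u_p)

    if Kff.shape[0]:
        try:
            # near-symmetric-positive-definite system: symmetric-mode SuperLU
            # with minimum-degree ordering gives far less fill than COLAMD
            lu = splu(
                Kff,
                permc_spec="MMD_AT_PLUS_A",
                diag_pivot_thresh=0.001,
                options={"SymmetricMode": True},
            )
        except Exception as exc:
            raise FEMError(f"sparse factorisation failed: {exc}") from exc
        udiag = np.abs(lu.U.diagonal())
        if udiag.min() < 1e-10 * udiag.max():
            raise FEMError(
                "singular reduced system: rigid-body modes remain "
                f"(pivot ratio {udiag.min() / udiag.max():.2e})"
            )
        u_f = lu.solve(f)
        if not np.all(np.isfinite(u_f)):
            raise FEMError("singular reduced system: rigid-body modes remain")
        res_num = np.linalg.norm(Kff @ u_f - f)
        res_den = np.linalg.norm(f)
        residual = float(res_num / res_den) if res_den > 0 else float(res_num)
    else:
        u_f = np.zeros(0)
        residual = 0.0

    u = T @ u_f + u_p
    r = stiffness @ u
    strain_energy = 0.5 * float(u @ r)
    external_work = 0.5 * float(u_p @ r)

    u3 = u.reshape(-1, 3)
    r3 = r.reshape(-1, 3)
    if mesh is not None and materials is not None:
        hex_stress, hex_vm, cap_vm, bar_f = _recover_stresses(mesh, materials, u3)
    else:
        n_hex = 0
        hex_stress = np.zeros((n_hex, 6))
        hex_vm = np.zeros(n_hex)
        cap_vm, bar_f = None, None
    return ElasticitySolution(
        u=u3,
        reactions=r3,
        hex_stress=hex_stress,
        hex_von_mises=hex_vm,
        capsule_von_mises=cap_vm,
        bar_axial_force=bar_f,
        strain_energy=strain_energy,
        external_work=external_work,
        residual=residual,
    )


def _add_dirichlet(dirichlet: dict[int, float], dof: int, val: float) -> None:
    old = dirichlet.get(dof)
    if old is not None and abs(old - val) > 1e-10:
        raise FEMError(f"conflicting prescribed values at dof {dof}: {old} vs {val}")
    if old is None:
        dirichlet[dof] = val


def _recover_stresses(mesh, materials, u3: np.ndarray):
    """Centroid stress per hex (B-bar consistent), capsule von Mises, bar
    forces."""
    coords = mesh.nodes[mesh.hexes]
    detJ, dNdx = _hex_geometry(coords)
    vol = detJ.sum(axis=1)
    bdiv_mean = np.einsum("egd,eg->ed", _divergence_row_all(dNdx), detJ) / vol[:, None]

    # centroid geometry
    n_e = coords.shape[0]
    J = np.einsum("eaj,ak->ejk", coords, _DSHAPE_C)
    dNdx_c = np.einsum("ak,ekj->eaj", _DSHAPE_C, np.linalg.inv(J))
    B = _b_matrix(dNdx_c)
    corr = (bdiv_mean - _divergence_row(dNdx_c)) / 3.0
    B = B + _M_VOIGT[None, :, None] * corr[:, None, :]

    ue = u3[mesh.hexes].reshape(n_e, 24)
    strain = np.einsum("eip,ep->ei", B, ue)
    D = _elastic_D(materials.layer_E_mpa()[mesh.hex_layer - 1], materials.nu_lens)
    stress = np.einsum("eij,ej->ei", D, strain)
    hex_vm = von_mises_from_voigt(stress)

    cap_vm = None
    if mesh.capsule_quads is not None:
        Dps = materials.E_capsule / (1 - materials.nu_capsule**2) * np.array(
            [[1, materials.nu_capsule, 0], [materials.nu_capsule, 1, 0], [0, 0, (1 - materials.nu_capsule) / 2]]
        )
        cap_vm = np.zeros(len(mesh.capsule_quads))
        for qi, q in enumerate(mesh.capsule_quads):
            cap_vm[qi] = _membrane_centroid_vm(mesh.nodes[q], u3[q], Dps)

    bar_f = None
    if mesh.zonule_bars is not None:
        EA = materials.E_zonule * mesh.zonule_area
        bar_f = np.zeros(len(mesh.zonule_bars))
        for bi, (n1, n2) in enumerate(mesh.zonule_bars):
            _, d, L = _bar_stiffness(mesh.nodes[n1], mesh.nodes[n2], EA)
            bar_f[bi] = EA / L * d @ (u3[n2] - u3[n1])
    return stress, hex_vm, cap_vm, bar_f


def _membrane_centroid_vm(coords, ue, Dps) -> float:
    dN = _dshape_quad(np.zeros(2))
    a1 = coords.T @ dN[:, 0]
    a2 = coords.T @ dN[:, 1]
    n = np.cross(a1, a2)
    dA = np.linalg.norm(n)
    if dA < 1e-14:
        return 0.0
    e1 = a1 / np.linalg.norm(a1)
    e2 = np.cross(n / dA, e1)
    J = np.array([[a1 @ e1, a2 @ e1], [a1 @ e2, a2 @ e2]])
    dNdx = dN @ np.linalg.inv(J)
    B = np.zeros((3, 12))
    for a in range(4):
        cols = slice(3 * a, 3 * a + 3)
        B[0, cols] = dNdx[a, 0] * e1
        B[1, cols] = dNdx[a, 1] * e2
        B[2, cols] = dNdx[a, 1] * e1 + dNdx[a, 0] * e2
    s = Dps @ (B @ ue.ravel())
    return float(np.sqrt(s[0] ** 2 + s[1] ** 2 - s[0] * s[1] + 3 * s[2] ** 2))


def von_mises_from_voigt(stress: np.ndarray) -> np.ndarray:
    """sqrt(3 J2) of Voigt stress rows (xx, yy, zz, xy, yz, zx)."""
    s = np.atleast_2d(stress)
    sx, sy, sz, txy, tyz, tzx = s.T
    vm = np.sqrt(
        0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
        + 3.0 * (txy**2 + tyz**2 + tzx**2)
    )
    return vm if stress.ndim > 1 else float(vm[0])


def von_mises(solution: ElasticitySolution) -> np.ndarray:
    """Per-hex von Mises scalar of a computed solution."""
    return solution.hex_von_mises


def capsule_area(mesh) -> float:
    """Total membrane area by 2x2 quadrature (degenerate corners excluded)."""
    if mesh.capsule_quads is None:
        raise FEMError("mesh has no capsule")
    total = 0.0
    for q in mesh.capsule_quads:
        coords = mesh.nodes[q]
        for g in range(4):
            dN = _DSHAPE_Q[g]
            a1 = coords.T @ dN[:, 0]
            a2 = coords.T @ dN[:, 1]
            total += np.linalg.norm(np.cross(a1, a2))
    return float(total)
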