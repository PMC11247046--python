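"""Plain-text exports: VTK legacy ASCII unstructured grids, contour CSVs and
reaction tables.

The VTK writer emits hex (type 12), quad (type 9) and line (type 3) cells in
one unstructured grid with layer ids / von Mises as cell data and the
displacement vector as point data, readable by ParaView and meshio alike.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_vtk", "write_contours_csv", "write_reactions_csv"]

_VTK_HEX, _VTK_QUAD, _VTK_LINE = 12, 9, 3


def write_vtk(path, mesh, solution=None, title: str = "zonula quarter-lens model") -> Path:
    """Write the mesh (and optionally a solution) as a VTK legacy ASCII file."""
    path = Path(path)
    cells: list[np.ndarray] = [mesh.hexes]
    types: list[np.ndarray] = [np.full(len(mesh.hexes), _VTK_HEX)]
    layer_data: list[np.ndarray] = [mesh.hex_layer.astype(float)]
    if mesh.capsule_quads is not None:
        cells.append(mesh.capsule_quads)
        types.append(np.full(len(mesh.capsule_quads), _VTK_QUAD))
        layer_data.append(np.full(len(mesh.capsule_quads), -1.0))
    if mesh.zonule_bars is not None:
        cells.append(mesh.zonule_bars)
        types.append(np.full(len(mesh.zonule_bars), _VTK_LINE))
        layer_data.append(np.full(len(mesh.zonule_bars), -2.0))

    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        n_cells = sum(len(c) for c in cells)
        size = sum(len(c) * (c.shape[1] + 1) for c in cells)
        fh.write(f"CELLS {n_cells} {size}\n")
        for block in cells:
            for conn in block:
                fh.write(f"{len(conn)} " + " ".join(map(str, conn)) + "\n")
        fh.write(f"CELL_TYPES {n_cells}\n")
        for block in types:
            fh.write("\n".join(map(str, block)) + "\n")
        fh.write(f"CELL_DATA {n_cells}\n")
        fh.write("SCALARS layer_id double 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(f"{v:.9g}" for v in np.concatenate(layer_data)) + "\n")
        if solution is not None:
            vm = [solution.hex_von_mises]
            if mesh.capsule_quads is not None:
                vm.append(
                    solution.capsule_von_mises
                    if solution.capsule_von_mises is not None
                    else np.zeros(len(mesh.capsule_quads))
                )
            if mesh.zonule_bars is not None:
                vm.append(np.zeros(len(mesh.zonule_bars)))
            fh.write("SCALARS von_mises_mpa double 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(f"{v:.9g}" for v in np.concatenate(vm)) + "\n")
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            fh.write("VECTORS displacement_mm double\n")
            for v in solution.u:
                fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
    return path


def write_contours_csv(path, contours, n: int = 200) -> Path:
    """Meridional layer contours as (axial_mm, radial_mm, contour_id) rows."""
    path = Path(path)
    frames = []
    for k in range(len(contours.scales)):
        pts = contours.contour_points(k, n=n)
        frames.append(
            pd.DataFrame({"axial_mm": pts[:, 0], "radial_mm": pts[:, 1], "contour_id": k})
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def write_reactions_csv(path, mesh, solution) -> Path:
    """Nodal reaction forces (N) at every node, with node-set membership."""
    path = Path(path)
    member = np.full(mesh.n_nodes, "", dtype=object)
    for name, nodes in mesh.node_sets.items():
        for n in nodes:
            member[n] = (member[n] + "+" + name).lstrip("+")
    df = pd.DataFrame(
        {
            "node": np.arange(mesh.n_nodes),
            "rx_N": solution.reactions[:, 0],
            "ry_N": solution.reactions[:, 1],
            "rz_N": solution.reactions[:, 2],
            "node_sets": member,
        }
    )
    df.to_csv(path, index=False)
    return path
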