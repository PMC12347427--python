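"""Minimal legacy-VTK (ASCII) writer for triangle meshes with result fields."""

from __future__ import annotations

import numpy as np

from .meshing import Mesh

__all__ = ["write_vtk"]


def write_vtk(
    path,
    mesh: Mesh,
    cell_data: dict[str, np.ndarray] | None = None,
    point_data: dict[str, np.ndarray] | None = None,
    title: str = "femrem result",
) -> None:
    """Write an unstructured-grid legacy VTK file with scalar/vector fields."""
    lines: list[str] = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    for x, y in mesh.nodes:
        lines.append(f"{x:.9g} {y:.9g} 0")
    m = mesh.n_elements
    lines.append(f"CELLS {m} {4 * m}")
    for a, b, c in mesh.triangles:
        lines.append(f"3 {a} {b} {c}")
    lines.append(f"CELL_TYPES {m}")
    lines.extend(["5"] * m)  # VTK_TRIANGLE

    if cell_data:
        lines.append(f"CELL_DATA {m}")
        for name, values in cell_data.items():
            values = np.asarray(values)
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{float(v):.9g}" for v in values)
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, values in point_data.items():
            values = np.asarray(values)
            if values.ndim == 2:
                lines.append(f"VECTORS {name} double")
                lines.extend(f"{v[0]:.9g} {v[1]:.9g} 0" for v in values)
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{float(v):.9g}" for v in values)

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
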