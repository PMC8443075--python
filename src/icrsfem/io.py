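"""Export helpers: legacy-ASCII VTK, CSV tables, curvature plots."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .curvature import CurvatureProfile
from .mesh import Mesh
from .solver import SolutionField

__all__ = ["write_vtk", "write_displacements_csv", "write_geometry_csv",
           "write_curvature_csv", "plot_curvature_change"]

_VTK_QUADRATIC_QUAD = 23


def write_vtk(path, mesh: Mesh, solution: SolutionField | None = None,
              deformed: bool = False) -> None:
    """Write the (active) mesh, optionally with displacement/von Mises data."""
    path = Path(path)
    nodes = mesh.nodes if solution is None or not deformed else solution.deformed_nodes
    act = np.where(mesh.active)[0]
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\nicrsfem mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(nodes)} double\n")
        for x, y in nodes:
            fh.write(f"{x:.9g} {y:.9g} 0.0\n")
        fh.write(f"CELLS {len(act)} {9 * len(act)}\n")
        for e in act:
            fh.write("8 " + " ".join(str(i) for i in mesh.elements[e]) + "\n")
        fh.write(f"CELL_TYPES {len(act)}\n")
        fh.write("\n".join([str(_VTK_QUADRATIC_QUAD)] * len(act)) + "\n")
        if solution is not None:
            fh.write(f"POINT_DATA {len(nodes)}\n")
            fh.write("VECTORS displacement double\n")
            for ux, uy in solution.displacements:
                fh.write(f"{ux:.9g} {uy:.9g} 0.0\n")
            fh.write(f"CELL_DATA {len(act)}\n")
            fh.write("SCALARS von_mises double 1\nLOOKUP_TABLE default\n")
            for e in act:
                fh.write(f"{solution.von_mises[e]:.9g}\n")


def write_displacements_csv(path, solution: SolutionField) -> None:
    arr = np.column_stack([solution.mesh.nodes, solution.displacements])
    np.savetxt(path, arr, delimiter=",", header="x_mm,y_mm,ux_mm,uy_mm", comments="")


def write_geometry_csv(path, geometry, n: int = 200) -> None:
    np.savetxt(path, geometry.surface_polyline(n), delimiter=",",
               header="x_mm,y_mm", comments="")


def write_curvature_csv(path, cp: CurvatureProfile) -> None:
    arr = np.column_stack([cp.radial_position, cp.sagittal_power])
    np.savetxt(path, arr, delimiter=",",
               header="radial_position_mm,sagittal_power_D", comments="")


def plot_curvature_change(path, profiles: dict[str, CurvatureProfile]) -> None:
    """One curve per label: power change (D) vs radial position (mm)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for label, cp in profiles.items():
        ax.plot(cp.radial_position, cp.sagittal_power, label=label)
    ax.set_xlabel("radial position (mm)")
    ax.set_ylabel("change in sagittal power (D)")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
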