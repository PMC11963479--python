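"""Minimal legacy-ASCII VTK writer for structured 2D cell fields."""

from __future__ import annotations

import numpy as np


def write_vtk_structured(path, fields: dict[str, np.ndarray], dx: float, dy: float,
                         comment: str = "rockroot snapshot") -> None:
    """Write (ny, nx) cell-centered fields as VTK STRUCTURED_POINTS.

    The legacy ASCII format is universally readable (ParaView, VisIt,
    meshio); one scalar array per entry in ``fields``.
    """
    shapes = {f.shape for f in fields.values()}
    if len(shapes) != 1:
        raise ValueError("all fields must share one (ny, nx) shape")
    ny, nx = shapes.pop()
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(comment.replace("\n", " ")[:255] + "\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} 1\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {dx} {dy} 1\n")
        fh.write(f"CELL_DATA {nx * ny}\n")
        for name, arr in fields.items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, np.asarray(arr, dtype=float).ravel()[None], fmt="%.7g")
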