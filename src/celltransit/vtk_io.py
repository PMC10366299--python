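"""Legacy-ASCII VTK export of lattice fields for inspection.

Writes STRUCTURED_POINTS datasets (wall masks, indicator fields,
macroscopic velocity/density) that any VTK-based viewer can open.
Membrane meshes have their own polydata writer in ``surface_mesh``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_vtk_image"]


def write_vtk_image(path: str, fields: dict[str, np.ndarray],
                    origin=(0.0, 0.0, 0.0), spacing: float = 1.0) -> None:
    """Write scalar/vector grid fields as a legacy VTK image dataset.

    ``fields`` maps names to arrays of shape (nx, ny, nz) for scalars or
    (nx, ny, nz, 3) for vectors; all fields must share the grid shape.
    ``origin`` and ``spacing`` give the physical placement (um).
    """
    if not fields:
        raise ValueError("no fields to write")
    shapes = {np.asarray(f).shape[:3] for f in fields.values()}
    if len(shapes) != 1:
        raise ValueError("all fields must share one grid shape")
    nx, ny, nz = shapes.pop()
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncelltransit lattice fields\n"
                 "ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {origin[0]:.9g} {origin[1]:.9g} {origin[2]:.9g}\n")
        fh.write(f"SPACING {spacing:.9g} {spacing:.9g} {spacing:.9g}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in fields.items():
            a = np.asarray(arr)
            # VTK structured points run x fastest
            if a.ndim == 3:
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                flat = a.transpose(2, 1, 0).ravel()
                fh.write("\n".join(f"{v:.9g}" for v in flat))
                fh.write("\n")
            elif a.ndim == 4 and a.shape[3] == 3:
                fh.write(f"VECTORS {name} double\n")
                flat = a.transpose(2, 1, 0, 3).reshape(-1, 3)
                fh.write("\n".join(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}"
                                   for v in flat))
                fh.write("\n")
            else:
                raise ValueError(f"field {name!r} has unsupported shape "
                                 f"{a.shape}")
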