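"""Minimal legacy-ASCII VTK structured-points I/O for voxel fields.

Writes one ``DATASET STRUCTURED_POINTS`` file carrying any number of
per-voxel (cell) scalar arrays, and reads such files back.  The legacy
text format is deliberately chosen so exported phantoms and field
snapshots stay human-inspectable and diff-able while remaining loadable
by ParaView/VTK.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_structured_points", "read_structured_points"]


def write_structured_points(
    path: str | Path,
    spacing: tuple[float, float, float],
    cell_arrays: dict[str, np.ndarray],
    *,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    title: str = "photoseed field export",
) -> None:
    if not cell_arrays:
        raise ValueError("nothing to write")
    shapes = {a.shape for a in cell_arrays.values()}
    if len(shapes) != 1:
        raise ValueError("all cell arrays must share one grid shape")
    nx, ny, nz = shapes.pop()

    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"{title}\n")
        f.write("ASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
        f.write(f"ORIGIN {origin[0]:.9g} {origin[1]:.9g} {origin[2]:.9g}\n")
        f.write(f"SPACING {spacing[0]:.9g} {spacing[1]:.9g} {spacing[2]:.9g}\n")
        f.write(f"CELL_DATA {nx * ny * nz}\n")
        for name, arr in cell_arrays.items():
            kind = "int" if np.issubdtype(arr.dtype, np.integer) else "float"
            f.write(f"SCALARS {name} {kind} 1\n")
            f.write("LOOKUP_TABLE default\n")
            flat = np.asarray(arr).ravel(order="F")  # VTK: x varies fastest
            fmt = "%d" if kind == "int" else "%.9g"
            for start in range(0, flat.size, 9):
                f.write(" ".join(fmt % v for v in flat[start:start + 9]) + "\n")


def read_structured_points(
    path: str | Path,
) -> tuple[tuple[float, float, float], dict[str, np.ndarray]]:
    """Return (spacing, {name: (nx,ny,nz) array}) from a legacy VTK file."""
    with open(path) as f:
        tokens = f.read().split()
    it = iter(range(len(tokens)))

    def find(word: str, start: int = 0) -> int:
        return tokens.index(word, start)

    i = find("DIMENSIONS")
    dims = tuple(int(t) - 1 for t in tokens[i + 1:i + 4])
    i = find("SPACING")
    spacing = tuple(float(t) for t in tokens[i + 1:i + 4])
    n = dims[0] * dims[1] * dims[2]

    arrays: dict[str, np.ndarray] = {}
    pos = 0
    while True:
        try:
            pos = find("SCALARS", pos)
        except ValueError:
            break
        name, kind = tokens[pos + 1], tokens[pos + 2]
        start = find("LOOKUP_TABLE", pos) + 2
        vals = tokens[start:start + n]
        dtype = np.int64 if kind == "int" else np.float64
        arr = np.array(vals, dtype=dtype).reshape(dims, order="F")
        arrays[name] = arr
        pos = start + n
    return spacing, arrays
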