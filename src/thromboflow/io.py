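"""File I/O: delimited field tables and legacy-VTK export.

Field tables are UTF-8 delimited text (comma by default) with a header row
and one row per cell.  Required columns are ``x, y, u, v, mu``; ``mu_t`` and
``k`` are optional and default to zero.  Row order is irrelevant — the
rectangular lattice is reconstructed from the coordinates.  Values are SI
with no unit headers.
"""

from __future__ import annotations

from typing import Mapping, Tuple

import numpy as np
import pandas as pd

from .errors import StructuralError, ValidationError
from .fields import BLOOD_DENSITY, FlowField, StructuredGrid2D

__all__ = ["read_field_table", "write_field_table", "write_vtk"]

_REQUIRED_COLUMNS = ("x", "y", "u", "v", "mu")
_OPTIONAL_COLUMNS = ("mu_t", "k")


def _lattice_axis(values: np.ndarray, name: str) -> Tuple[np.ndarray, float]:
    """Unique sorted coordinates and the (uniform) spacing along one axis."""
    coords = np.unique(values)
    if coords.size < 2:
        raise StructuralError(f"need at least 2 distinct {name} coordinates, got {coords.size}")
    spacing = np.diff(coords)
    d = float(np.median(spacing))
    bad = np.nonzero(np.abs(spacing - d) > 1e-9 * max(abs(d), 1e-300))[0]
    if bad.size:
        raise StructuralError(
            f"non-uniform {name} lattice: spacing breaks at {name} = {coords[bad[0] + 1]!r}"
        )
    return coords, d


def read_field_table(path, delimiter: str = ",") -> Tuple[StructuredGrid2D, FlowField]:
    """Read a cell-centered flow field from a delimited text table.

    Returns the grid inferred from the unique sorted x/y coordinates and the
    flow field populated in flat-index order (``j*nx + i``).  A density
    column is not part of the format; the returned field carries the default
    blood density.
    """
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise StructuralError(f"field table missing required columns: {missing}")

    xs, dx = _lattice_axis(df["x"].to_numpy(), "x")
    ys, dy = _lattice_axis(df["y"].to_numpy(), "y")
    nx, ny = xs.size, ys.size
    if len(df) != nx * ny:
        raise StructuralError(
            f"table has {len(df)} rows but the coordinate lattice implies {nx}x{ny} = {nx * ny} cells"
        )

    ix = np.searchsorted(xs, df["x"].to_numpy())
    iy = np.searchsorted(ys, df["y"].to_numpy())
    flat = iy * nx + ix
    occupied = np.zeros(nx * ny, dtype=bool)
    occupied[flat] = True
    if not occupied.all():
        j, i = divmod(int(np.argmin(occupied)), nx)
        raise StructuralError(
            f"incomplete lattice: no row for cell at x={xs[i]!r}, y={ys[j]!r}"
        )

    grid = StructuredGrid2D(nx=nx, ny=ny, dx=dx, dy=dy,
                            origin=(float(xs[0] - dx / 2), float(ys[0] - dy / 2)))

    def gather(col: str) -> np.ndarray:
        out = np.zeros(nx * ny)
        if col in df.columns:
            out[flat] = df[col].to_numpy(dtype=float)
        return out.reshape(ny, nx)

    mu = gather("mu")
    if np.any(mu <= 0):
        raise ValidationError("field table contains non-positive viscosity values")
    flow = FlowField(u=gather("u"), v=gather("v"), mu=mu,
                     mu_t=gather("mu_t"), k=gather("k"), rho=BLOOD_DENSITY)
    return grid, flow.validate(grid)


def write_field_table(grid: StructuredGrid2D, flow: FlowField, path,
                      delimiter: str = ",", include_turbulence: bool = True) -> None:
    """Write a flow field as a delimited table, one row per cell.

    Values are written with 17 significant digits so that a write/read
    round trip reproduces every float bit-exactly.
    """
    flow.validate(grid)
    X, Y = grid.meshgrid()
    columns = {
        "x": X.ravel(), "y": Y.ravel(),
        "u": flow.u.ravel(), "v": flow.v.ravel(), "mu": flow.mu.ravel(),
    }
    if include_turbulence:
        columns["mu_t"] = flow.mu_t.ravel()
        columns["k"] = flow.k.ravel()
    pd.DataFrame(columns).to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def write_vtk(grid: StructuredGrid2D, named_fields: Mapping[str, np.ndarray], path) -> None:
    """Write cell-centered scalar fields as a legacy-VTK structured-points file.

    One ``CELL_DATA`` array is emitted per named field, in insertion order,
    loadable by standard visualization tools.  The 2D grid is written as a
    one-cell-thick 3D structured-points dataset.
    """
    arrays = {}
    for name, arr in named_fields.items():
        arrays[name] = grid.check_field(arr, name)

    lines = [
        "# vtk DataFile Version 3.0",
        "thromboflow cell-centered fields",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {grid.nx + 1} {grid.ny + 1} 2",
        f"ORIGIN {grid.origin[0]:.17g} {grid.origin[1]:.17g} 0",
        f"SPACING {grid.dx:.17g} {grid.dy:.17g} {min(grid.dx, grid.dy):.17g}",
        f"CELL_DATA {grid.n_cells}",
    ]
    for name, arr in arrays.items():
        safe = name.replace(" ", "_")
        lines.append(f"SCALARS {safe} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.17g}" for v in arr.ravel())
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
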