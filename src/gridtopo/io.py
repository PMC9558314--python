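"""File formats and result serialization.

Supported inputs:

* Gaussian cube files (scalar field on a uniform lattice, atomic-units
  convention; negative voxel counts signal Angstrom axes and are
  converted on read).  Values are stored z-fastest per the format.
* Delimited point tables: rows of ``x y z value [weight]`` (or fewer
  coordinate columns for 1D/2D data), units bohr / a.u., ``#`` comments.

All coordinates are bohr internally; results are written as CSV (17
significant digits, '.' decimal) plus a provenance JSON block sufficient
to re-run the analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from . import __version__
from .grids import Grid
from .transforms import ScalarField

__all__ = [
    "read_cube",
    "write_cube",
    "read_points",
    "write_points",
    "AnalysisResult",
    "provenance_block",
]

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903


class CubeFormatError(ValueError):
    pass


def read_cube(path) -> tuple[Grid, ScalarField, dict]:
    """Read a Gaussian cube file -> (Grid, ScalarField, metadata).

    The grid carries voxel-volume weights; atom records are returned in
    ``metadata["atoms"]`` as (Z, charge, x, y, z) tuples (bohr).
    """
    with open(path) as fh:
        lines = fh.readlines()
    try:
        comment = lines[0].strip(), lines[1].strip()
    except IndexError:
        raise CubeFormatError(f"{path}: truncated header (line 1-2)") from None

    def floats(line_no):
        try:
            return lines[line_no].split()
        except IndexError:
            raise CubeFormatError(f"{path}: truncated at line {line_no + 1}") from None

    try:
        head = floats(2)
        natoms_raw = int(head[0])
        origin = np.array(head[1:4], dtype=float)
    except (ValueError, IndexError):
        raise CubeFormatError(f"{path}: malformed header at line 3") from None
    has_dset = natoms_raw < 0
    natoms = abs(natoms_raw)

    shape = np.empty(3, dtype=int)
    axes = np.empty((3, 3))
    for i in range(3):
        try:
            row = floats(3 + i)
            shape[i] = int(row[0])
            axes[i] = [float(v) for v in row[1:4]]
        except (ValueError, IndexError):
            raise CubeFormatError(f"{path}: malformed axis at line {4 + i}") from None
    # negative voxel count: axis given in Angstrom
    for i in range(3):
        if shape[i] < 0:
            shape[i] = -shape[i]
            axes[i] *= BOHR_PER_ANGSTROM

    atoms = []
    for a in range(natoms):
        try:
            row = floats(6 + a)
            atoms.append((int(row[0]), float(row[1]), float(row[2]), float(row[3]), float(row[4])))
        except (ValueError, IndexError):
            raise CubeFormatError(f"{path}: malformed atom record at line {7 + a}") from None

    data_start = 6 + natoms + (1 if has_dset else 0)
    try:
        values = np.fromiter(
            (float(tok) for line in lines[data_start:] for tok in line.split()),
            dtype=float,
        )
    except ValueError:
        raise CubeFormatError(f"{path}: non-numeric voxel data after line {data_start}") from None
    n_expected = int(np.prod(shape))
    if len(values) != n_expected:
        raise CubeFormatError(
            f"{path}: expected {n_expected} voxel values, found {len(values)} "
            f"(data starting line {data_start + 1})"
        )

    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])  # z fastest
    pts = origin + idx @ axes
    vol = float(abs(np.linalg.det(axes)))
    grid = Grid(pts, np.full(len(pts), vol), provenance={"kind": "cube", "path": str(path)})
    meta = {"comment": comment, "atoms": atoms, "origin": origin, "axes": axes, "shape": shape}
    return grid, ScalarField(values, name="cube", source="input"), meta


def write_cube(path, shape, origin, axes, values, atoms=(), comment="gridtopo cube") -> None:
    """Write a Gaussian cube file (bohr units, z-fastest values)."""
    shape = np.asarray(shape, dtype=int)
    origin = np.asarray(origin, dtype=float)
    axes = np.asarray(axes, dtype=float)
    values = np.asarray(values, dtype=float).ravel()
    if len(values) != int(np.prod(shape)):
        raise ValueError("value count does not match shape")
    with open(path, "w") as fh:
        fh.write(f"{comment}\n")
        fh.write("scalar field\n")
        fh.write(f"{len(atoms):5d} {origin[0]:19.12e} {origin[1]:19.12e} {origin[2]:19.12e}\n")
        for i in range(3):
            fh.write(
                f"{shape[i]:5d} {axes[i, 0]:19.12e} {axes[i, 1]:19.12e} {axes[i, 2]:19.12e}\n"
            )
        for z, q, x, y, zz in atoms:
            fh.write(f"{int(z):5d} {q:19.12e} {x:19.12e} {y:19.12e} {zz:19.12e}\n")
        for start in range(0, len(values), 6):
            fh.write(" ".join(f"{v:19.12e}" for v in values[start : start + 6]) + "\n")


def read_points(path) -> tuple[Grid, ScalarField]:
    """Read a delimited ``x [y z] value [weight]`` table (bohr / a.u.).

    A leading ``# x y z value weight``-style header line, when present,
    fixes the column layout; without one, 4 columns are taken as 3D
    coordinates plus value (the documented full format).
    """
    with open(path) as fh:
        first = fh.readline()
    header_cols = first[1:].split() if first.startswith("#") else None
    try:
        df = pd.read_csv(path, sep=r"\s+", comment="#", header=None, dtype=float)
    except (ValueError, pd.errors.ParserError) as err:
        raise ValueError(f"{path}: could not parse point table: {err}") from None
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax()) + 1
        raise ValueError(f"{path}: non-numeric or ragged data near row {row}")
    ncol = df.shape[1]
    if ncol < 2 or ncol > 5:
        raise ValueError(f"{path}: expected 2-5 columns (x [y z] value [weight]), got {ncol}")
    if header_cols and len(header_cols) == ncol and "value" in header_cols:
        d = header_cols.index("value")
        has_w = "weight" in header_cols
    elif ncol in (2, 3):
        d, has_w = ncol - 1, False
    elif ncol == 4:
        d, has_w = 3, False
    else:
        d, has_w = 3, True
    arr = df.to_numpy()
    pts = arr[:, :d]
    vals = arr[:, d]
    w = arr[:, d + 1] if has_w else None
    grid = Grid(pts, w, provenance={"kind": "points", "path": str(path)})
    if grid.n != len(vals):
        # deduplication merged rows; re-associate values by nearest point
        idx = grid.nearest(pts)
        merged = np.empty(grid.n)
        merged[idx] = vals
        vals = merged
    return grid, ScalarField(vals, name="points", source="input")


def write_points(path, grid: Grid, field, header: bool = True) -> None:
    """Write the tabular point format; includes weights when the grid has them."""
    from .transforms import field_values

    vals = field_values(field)
    cols = [grid.points, vals[:, None]]
    names = [c for c in ("x", "y", "z")[: grid.dim]] + ["value"]
    if grid.weights is not None:
        cols.append(grid.weights[:, None])
        names.append("weight")
    arr = np.hstack(cols)
    with open(path, "w") as fh:
        if header:
            fh.write("# " + " ".join(names) + "\n")
        np.savetxt(fh, arr, fmt="%.17g")


@dataclass
class AnalysisResult:
    """Bundle of per-point labels, per-family integrals, and network data."""

    basin: np.ndarray | None = None
    family: np.ndarray | None = None
    charges: dict | None = None
    network_edges: list | None = None
    critical_points: dict | None = None
    provenance: dict = dataclass_field(default_factory=dict)

    def write(self, prefix: str) -> list[str]:
        written = []
        if self.basin is not None:
            df = pd.DataFrame(
                {"point": np.arange(len(self.basin)), "basin": self.basin, "family": self.family}
            )
            df.to_csv(f"{prefix}.basins.csv", index=False)
            written.append(f"{prefix}.basins.csv")
        if self.charges is not None:
            df = pd.DataFrame(
                {"family": list(self.charges), "charge": list(self.charges.values())}
            )
            df.to_csv(f"{prefix}.charges.csv", index=False, float_format="%.17g")
            written.append(f"{prefix}.charges.csv")
        if self.network_edges is not None:
            df = pd.DataFrame(self.network_edges, columns=["i", "j", "filled"])
            df.to_csv(f"{prefix}.network.csv", index=False)
            written.append(f"{prefix}.network.csv")
        if self.critical_points is not None:
            rows = [
                {"max_i": k[0], "max_j": k[1], "node": v[0], "value": v[1]}
                for k, v in sorted(self.critical_points.items())
            ]
            pd.DataFrame(rows).to_csv(
                f"{prefix}.cpoints.csv", index=False, float_format="%.17g"
            )
            written.append(f"{prefix}.cpoints.csv")
        with open(f"{prefix}.provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=_json_default)
        written.append(f"{prefix}.provenance.json")
        return written


def _json_default(obj):
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def provenance_block(**kwargs) -> dict:
    """Standard provenance dict: software version + caller-supplied parameters."""
    block = {"software": "gridtopo", "version": __version__}
    block.update(kwargs)
    return block
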