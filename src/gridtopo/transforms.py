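"""Scalar fields and the pointwise transforms that feed one basin engine.

The basin/critical-network machinery only ever sees "a scalar per grid
point"; all the different analyses (minima, isosurfaces, shell structure,
stagnation graphs) are obtained by transforming the input field first:

* minima of f          -> maxima of ``negate(f)``
* isosurface f = f_iso -> maxima families of ``isosurface_aux(f, f_iso)``
* shells of the density Laplacian -> maxima families of ``abs_field(lap)``
* stagnation graph of a current J -> critical network of
  ``negate(vector_magnitude(Jx, Jy, Jz))``

Transforms materialize new :class:`ScalarField` objects (with a source
tag recording the lineage) rather than wrapping lazily.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScalarField",
    "field_values",
    "negate",
    "abs_field",
    "isosurface_aux",
    "vector_magnitude",
]


@dataclass
class ScalarField:
    """One real value per grid node, in atomic units appropriate to the quantity.

    ``source`` tags how the field arose: input | negated | abs |
    isosurface_aux | magnitude.
    """

    values: np.ndarray
    name: str = "field"
    source: str = "input"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(v)):
            raise ValueError("field contains non-finite values")
        self.values = v

    def __len__(self) -> int:
        return len(self.values)


def field_values(field) -> np.ndarray:
    """Accept a ScalarField or a bare array and return the value array."""
    if isinstance(field, ScalarField):
        return field.values
    return np.asarray(field, dtype=float).ravel()


def negate(field) -> ScalarField:
    """-f: maxima of the result are minima of the input."""
    name = field.name if isinstance(field, ScalarField) else "field"
    return ScalarField(-field_values(field), name=f"-({name})", source="negated")


def abs_field(field) -> ScalarField:
    """|f|: folds sign changes into extended maxima (e.g. Laplacian shells)."""
    name = field.name if isinstance(field, ScalarField) else "field"
    return ScalarField(np.abs(field_values(field)), name=f"|{name}|", source="abs")


def isosurface_aux(field, f_iso: float) -> ScalarField:
    """Auxiliary field exp(-|f - f_iso|), maximal (= 1) exactly on the isosurface.

    Its maxima families are a discrete representation of the connected
    components of the isosurface f = f_iso.
    """
    name = field.name if isinstance(field, ScalarField) else "field"
    vals = np.exp(-np.abs(field_values(field) - float(f_iso)))
    return ScalarField(vals, name=f"iso[{name}={f_iso:g}]", source="isosurface_aux")


def vector_magnitude(fx, fy, fz) -> ScalarField:
    """Pointwise Euclidean norm of a 3-component vector field on one grid."""
    vx, vy, vz = field_values(fx), field_values(fy), field_values(fz)
    if not (len(vx) == len(vy) == len(vz)):
        raise ValueError(
            f"component grids differ: lengths {len(vx)}, {len(vy)}, {len(vz)}"
        )
    return ScalarField(np.sqrt(vx * vx + vy * vy + vz * vz), name="|J|", source="magnitude")
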