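"""Gaussian basis-set data (published cc-pVDZ parameters).

Exponents and contraction coefficients are the standard Dunning cc-pVDZ
values (segmented form) for the elements used by the built-in benchmarks
and validation tests.  Shells are stored as (angular momentum l,
exponents, contraction coefficients); coefficients refer to normalized
primitives, and final AO normalization is fixed numerically from the
overlap matrix, so no convention-dependent prefactors are stored.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CC_PVDZ", "ATOMIC_NUMBERS"]

ATOMIC_NUMBERS = {"H": 1, "He": 2, "C": 6, "N": 7, "O": 8, "Ne": 10}

CC_PVDZ: dict[str, list[tuple[int, list[float], list[float]]]] = {
    "H": [
        (0, [13.0100, 1.9620, 0.4446, 0.1220],
            [0.0196850, 0.1379770, 0.4781480, 0.5012400]),
        (0, [0.1220], [1.0]),
        (1, [0.7270], [1.0]),
    ],
    "He": [
        (0, [38.360, 5.770, 1.240],
            [0.0238090, 0.1548910, 0.4699870]),
        (0, [0.29760], [1.0]),
        (1, [1.2750], [1.0]),
    ],
    "C": [
        (0, [6665.0, 1000.0, 228.0, 64.71, 21.06, 7.495, 2.797, 0.5215, 0.1596],
            [0.000692, 0.005329, 0.027077, 0.101718, 0.274740, 0.448564,
             0.285074, 0.015204, -0.003191]),
        (0, [6665.0, 1000.0, 228.0, 64.71, 21.06, 7.495, 2.797, 0.5215, 0.1596],
            [-0.000146, -0.001154, -0.005725, -0.023312, -0.063955, -0.149981,
             -0.127262, 0.544529, 0.580496]),
        (0, [0.1596], [1.0]),
        (1, [9.439, 2.002, 0.5456, 0.1517],
            [0.038109, 0.209480, 0.508557, 0.468842]),
        (1, [0.1517], [1.0]),
        (2, [0.5500], [1.0]),
    ],
    "O": [
        (0, [11720.0, 1759.0, 400.8, 113.7, 37.03, 13.27, 5.025, 1.013, 0.3023],
            [0.000710, 0.005470, 0.027837, 0.104800, 0.283062, 0.448719,
             0.270952, 0.015458, -0.002585]),
        (0, [11720.0, 1759.0, 400.8, 113.7, 37.03, 13.27, 5.025, 1.013, 0.3023],
            [-0.000160, -0.001263, -0.006267, -0.025716, -0.070924, -0.165411,
             -0.116955, 0.557368, 0.572759]),
        (0, [0.3023], [1.0]),
        (1, [17.70, 3.854, 1.046],
            [0.043018, 0.228913, 0.508728]),
        (1, [0.2753], [1.0]),
        (2, [1.185], [1.0]),
    ],
    "Ne": [
        (0, [17880.0, 2683.0, 611.5, 173.5, 56.64, 20.42, 7.810, 1.653, 0.4869],
            [0.000738, 0.005677, 0.028883, 0.108540, 0.290907, 0.448324,
             0.258026, 0.015063, -0.002100]),
        (0, [17880.0, 2683.0, 611.5, 173.5, 56.64, 20.42, 7.810, 1.653, 0.4869],
            [-0.000172, -0.001357, -0.006737, -0.027663, -0.076288, -0.175143,
             -0.107836, 0.567124, 0.565524]),
        (0, [0.4869], [1.0]),
        (1, [28.39, 6.270, 1.695],
            [0.046087, 0.240181, 0.508744]),
        (1, [0.4317], [1.0]),
        (2, [2.202], [1.0]),
    ],
}


def primitive_norm(alpha: float, l: int) -> float:
    """Norm of a (l, 0, 0) cartesian Gaussian primitive."""
    dfact = 1.0
    for k in range(2 * l - 1, 0, -2):
        dfact *= k
    return (2 * alpha / np.pi) ** 0.75 * (4 * alpha) ** (l / 2.0) / np.sqrt(dfact)
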