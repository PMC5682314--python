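"""Wavelet packet transform (WPT) used to build the per-segment feature matrix.

A full binary analysis tree is applied to each fixed-length MMG segment:
every node is split by an orthonormal conjugate-quadrature filter pair
(scaling filter ``h``, wavelet filter ``g[n] = (-1)^n h[L-1-n]``) with
periodic boundary extension and dyadic downsampling.  At level ``J`` the
``2**J`` leaves, kept in natural (Paley) tree order with the lowpass child
first, each hold ``LN / 2**J`` coefficients; stacking them as columns gives
the ``(LN/32) x 32`` feature matrix at the default level 5.

With an orthogonal family and periodization the transform is an orthonormal
change of basis, so leaf energies sum to the segment energy and the
decomposition is exactly invertible — both properties are used as tests.

Daubechies scaling filters are embedded at full double precision (db2 in
closed form from sqrt(3)); no external wavelet library is required.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "available_wavelets",
    "wavelet_filters",
    "wpt_decompose",
    "wpt_reconstruct",
    "build_feature_matrix",
]

_SQRT2 = math.sqrt(2.0)
_SQRT3 = math.sqrt(3.0)

# Orthonormal scaling (lowpass) filters, sum(h) = sqrt(2), sum(h^2) = 1.
_SCALING_FILTERS: dict[str, np.ndarray] = {
    "haar": np.array([1.0, 1.0]) / _SQRT2,
    "db2": np.array(
        [1.0 + _SQRT3, 3.0 + _SQRT3, 3.0 - _SQRT3, 1.0 - _SQRT3]
    )
    / (4.0 * _SQRT2),
    # db3/db4 computed by spectral factorization of the Daubechies binomial
    # polynomial (min-phase root selection); orthonormal to machine precision.
    "db3": np.array(
        [
            0.3326705529500826,
            0.8068915093110924,
            0.4598775021184915,
            -0.1350110200102546,
            -0.08544127388202669,
            0.035226291885709526,
        ]
    ),
    "db4": np.array(
        [
            0.23037781330889645,
            0.7148465705529156,
            0.630880767929859,
            -0.02798376941685959,
            -0.18703481171909309,
            0.03084138183556063,
            0.03288301166688517,
            -0.010597401785069018,
        ]
    ),
}
_SCALING_FILTERS["db1"] = _SCALING_FILTERS["haar"]


def available_wavelets() -> list[str]:
    """Names of the supported orthogonal wavelet families."""
    return sorted(_SCALING_FILTERS)


def wavelet_filters(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Return the analysis pair ``(h, g)`` for a named orthogonal family."""
    try:
        h = _SCALING_FILTERS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown wavelet {name!r}; supported families: "
            f"{', '.join(available_wavelets())}"
        ) from None
    n = np.arange(h.size)
    g = ((-1.0) ** n) * h[::-1]
    return h.copy(), g


def _analysis_step(x: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """Periodized convolution-decimation: ``y[k] = sum_n f[n] x[(2k+n) % N]``."""
    n = x.size
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(filt.size)[None, :]) % n
    return x[idx] @ filt


def _synthesis_step(a: np.ndarray, d: np.ndarray, h: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_analysis_step` for an orthonormal pair."""
    n = 2 * a.size
    m = np.arange(n)[:, None]
    k = 2 * np.arange(a.size)[None, :]
    hp = np.zeros(n)
    hp[: h.size] = h
    gp = np.zeros(n)
    gp[: g.size] = g
    return hp[(m - k) % n] @ a + gp[(m - k) % n] @ d


def wpt_decompose(
    segment: np.ndarray, level: int = 5, wavelet: str = "db4"
) -> list[np.ndarray]:
    """Decompose a segment into its ``2**level`` level-``level`` packet leaves.

    Leaves are returned in natural (Paley) order: the children of node ``p``
    are ``2p-1`` (lowpass) and ``2p`` (highpass), numbered left to right.
    """
    x = np.asarray(segment, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("segment must be one-dimensional")
    h, g = wavelet_filters(wavelet)
    if level < 1:
        raise ValueError("level must be >= 1")
    if x.size % (2**level) != 0:
        raise ValueError(
            f"segment length {x.size} is not a multiple of 2**{level}"
        )
    if x.size // (2**level) < 1 or x.size // (2 ** (level - 1)) < h.size:
        raise ValueError(
            f"segment length {x.size} too short for level {level} with a "
            f"{h.size}-tap filter"
        )
    nodes = [x]
    for _ in range(level):
        nxt: list[np.ndarray] = []
        for node in nodes:
            nxt.append(_analysis_step(node, h))
            nxt.append(_analysis_step(node, g))
        nodes = nxt
    return nodes


def wpt_reconstruct(leaves: list[np.ndarray], wavelet: str = "db4") -> np.ndarray:
    """Invert :func:`wpt_decompose`; exact for orthogonal families."""
    n_leaves = len(leaves)
    if n_leaves < 2 or n_leaves & (n_leaves - 1):
        raise ValueError(f"number of leaves must be a power of two, got {n_leaves}")
    h, g = wavelet_filters(wavelet)
    nodes = [np.asarray(v, dtype=np.float64) for v in leaves]
    while len(nodes) > 1:
        nodes = [
            _synthesis_step(nodes[i], nodes[i + 1], h, g)
            for i in range(0, len(nodes), 2)
        ]
    return nodes[0]


def build_feature_matrix(leaves: list[np.ndarray]) -> np.ndarray:
    """Stack 32 level-5 leaves column-wise into the ``(LN/32) x 32`` matrix."""
    if len(leaves) != 32:
        raise ValueError(f"expected 32 leaves, got {len(leaves)}")
    lengths = {len(v) for v in leaves}
    if len(lengths) != 1:
        raise ValueError(f"ragged leaves (lengths {sorted(lengths)})")
    return np.column_stack(leaves)
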