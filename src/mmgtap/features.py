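"""SVD feature compression and F-value feature ranking.

Each detected segment and channel yields a ``(LN/32) x 32`` wavelet-packet
coefficient matrix; its 32 singular values, in descending order, are the
per-channel feature vector.  Singular values are invariant to orthogonal
transformations of either side of the matrix, which makes them a compact,
rotation-insensitive summary of how energy distributes across the packet
leaves.

Feature ranking scores each feature ``i`` by two mean absolute distances:

* ``d_ai``  — within-gesture: mean over gestures of the mean absolute
  difference between ordered sample pairs of feature ``i``;
* ``d'_ai`` — between-gesture: mean absolute difference between ordered
  pairs of the per-gesture feature means.

Two ratio conventions are provided.  ``as_printed`` scores ``d_ai / d'_ai``;
``fisher`` scores ``d'_ai / d_ai``, under which a feature with tight classes
and well-separated means scores high, and is the default used for selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "F_CAP",
    "FeatureRanking",
    "svd_compress",
    "f_value_ranking",
    "select_features",
    "segment_features",
]

logger = logging.getLogger(__name__)

#: Finite stand-in for an infinite F ratio (zero denominator, nonzero
#: numerator); keeps the ranking order total.
F_CAP = 1e12

Convention = Literal["fisher", "as_printed"]


@dataclass(frozen=True)
class FeatureRanking:
    """Per-feature distances, F-values, and the descending-F rank order."""

    d_within: np.ndarray
    d_between: np.ndarray
    f_values: np.ndarray
    order: np.ndarray
    convention: str


def svd_compress(x: np.ndarray) -> np.ndarray:
    """Singular values of the feature matrix, descending.

    Requires at least as many rows as columns so that all 32 singular values
    are defined by the column space.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if np.isnan(x).any():
        raise ValueError("feature matrix contains NaN")
    if x.shape[0] < x.shape[1]:
        raise ValueError(
            f"feature matrix needs rows >= columns, got shape {x.shape}"
        )
    return np.linalg.svd(x, compute_uv=False)


def _mean_abs_pairwise(values: np.ndarray) -> np.ndarray:
    """Mean |v_m - v_n| over ordered pairs m != n, per column.

    ``values`` has shape (n_samples, n_features); normalisation is
    ``1 / (N (N-1))`` with both (m, n) and (n, m) counted.
    """
    n = values.shape[0]
    diff = np.abs(values[:, None, :] - values[None, :, :])
    return diff.sum(axis=(0, 1)) / (n * (n - 1))


def f_value_ranking(
    x: np.ndarray,
    y: np.ndarray,
    convention: Convention = "fisher",
) -> FeatureRanking:
    """Rank features by their F-value over a labelled sample.

    Parameters
    ----------
    x
        Feature array of shape ``(n_samples, n_features)``.
    y
        Gesture label per sample (any hashable values, >= 2 distinct).
    convention
        ``fisher`` ranks by between/within; ``as_printed`` by within/between.

    Degenerate ratios: 0/0 maps to F = 0 (uninformative, ranked last among
    equals); x/0 maps to the finite cap :data:`F_CAP` with a warning.
    Ties are broken by lower feature index.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("x must be (n_samples, n_features) aligned with y")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("at least 2 gestures are required for ranking")
    n_feat = x.shape[1]

    d_ij = np.empty((classes.size, n_feat))
    means = np.empty((classes.size, n_feat))
    for j, c in enumerate(classes):
        xj = x[y == c]
        if xj.shape[0] < 2:
            raise ValueError(
                f"gesture {c!r} has {xj.shape[0]} sample(s); within-gesture "
                "distance needs at least 2"
            )
        d_ij[j] = _mean_abs_pairwise(xj)
        means[j] = xj.mean(axis=0)
    d_within = d_ij.mean(axis=0)
    d_between = _mean_abs_pairwise(means)

    if convention == "fisher":
        num, den = d_between, d_within
    elif convention == "as_printed":
        num, den = d_within, d_between
    else:
        raise ValueError(f"unknown ranking convention {convention!r}")

    f = np.zeros(n_feat)
    ok = den > 0
    f[ok] = num[ok] / den[ok]
    capped = (~ok) & (num > 0)
    if capped.any():
        logger.warning(
            "feature(s) %s have zero F denominator; capping F at %.1e",
            np.flatnonzero(capped).tolist(),
            F_CAP,
        )
        f[capped] = F_CAP
    # stable sort on -f keeps lower feature index first among ties
    order = np.argsort(-f, kind="stable")
    return FeatureRanking(
        d_within=d_within,
        d_between=d_between,
        f_values=f,
        order=order,
        convention=convention,
    )


def select_features(
    rankings: Sequence[FeatureRanking], k: int
) -> list[np.ndarray]:
    """Top-``k`` feature indices per channel, in that channel's rank order."""
    n_feat = rankings[0].f_values.size
    if not (1 <= k <= n_feat):
        raise ValueError(f"k must be in 1..{n_feat}, got {k}")
    return [r.order[:k].copy() for r in rankings]


def segment_features(
    segment: np.ndarray, level: int = 5, wavelet: str = "db4"
) -> np.ndarray:
    """Per-channel singular-value features of one extracted segment.

    ``segment`` has shape ``(n_channels, LN)``; the result has shape
    ``(n_channels, 2**level)`` with each row descending.
    """
    from .wavelet import build_feature_matrix, wpt_decompose

    segment = np.atleast_2d(np.asarray(segment, dtype=np.float64))
    rows = []
    for ch in range(segment.shape[0]):
        leaves = wpt_decompose(segment[ch], level=level, wavelet=wavelet)
        rows.append(svd_compress(build_feature_matrix(leaves)))
    return np.vstack(rows)
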