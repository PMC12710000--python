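"""Minimal distances between straight root segments.

The matcher needs, for every ground-truth segment i and traced segment j,
the minimal Euclidean distance

    D[i, j] = min_{x, y in [0, 1]} || (A0 + x (A1 - A0)) - (B0 + y (B1 - B0)) ||

between the two closed segments.  The closed-form solution is the
classic clamped-quadratic segment–segment distance; a brute-force grid
search over (x, y) is kept in the test suite as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rsa import Segment, segment_arrays

_EPS = 1e-12


class DegenerateSegmentError(ValueError):
    """Raised when a zero-length segment reaches the distance kernel."""


@dataclass
class DistanceMatrix:
    """Pairwise minimal segment distances, ground truth x traced (cm)."""

    values: np.ndarray           # (n_gt, n_traced)
    row_root_ids: list[str]      # GT root id per row segment
    col_root_ids: list[str]      # traced root id per column segment
    row_lengths: np.ndarray      # GT segment lengths, cm
    col_lengths: np.ndarray      # traced segment lengths, cm

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_csv(self, path) -> None:
        """Dense CSV dump for debugging."""
        np.savetxt(path, self.values, delimiter=",", fmt="%.6g")


def _pairwise_segment_distance(
    a0: np.ndarray, a1: np.ndarray, b0: np.ndarray, b1: np.ndarray
) -> np.ndarray:
    """Clamped closest-approach distance for broadcastable endpoint arrays.

    Inputs are (..., 3) arrays; output is (...).  Degenerate inputs are
    the caller's responsibility.
    """
    d1 = a1 - a0
    d2 = b1 - b0
    r = a0 - b0
    a = np.sum(d1 * d1, axis=-1)
    e = np.sum(d2 * d2, axis=-1)
    b = np.sum(d1 * d2, axis=-1)
    c = np.sum(d1 * r, axis=-1)
    f = np.sum(d2 * r, axis=-1)

    denom = a * e - b * b
    # s: parameter on segment a for the unclamped closest approach of the
    # infinite lines; parallel pairs (denom ~ 0) start from s = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > _EPS * a * e + _EPS, (b * f - c * e) / denom, 0.0)
    s = np.clip(s, 0.0, 1.0)
    t = (b * s + f) / e
    # clamp t, then recompute s for clamped t and clamp again
    t_clamped = np.clip(t, 0.0, 1.0)
    s = np.where(t != t_clamped, np.clip((b * t_clamped - c) / a, 0.0, 1.0), s)
    closest_a = a0 + s[..., None] * d1
    closest_b = b0 + t_clamped[..., None] * d2
    return np.linalg.norm(closest_a - closest_b, axis=-1)


def segment_distance(
    a: Segment, b: Segment, *, allow_degenerate: bool = False
) -> float:
    """Minimal Euclidean distance between two closed segments (cm).

    Symmetric, never larger than the closest endpoint pair, zero exactly
    for intersecting segments.  Zero-length segments are rejected unless
    ``allow_degenerate`` enables the point-to-segment fallback.
    """
    if (a.length <= 0 or b.length <= 0) and not allow_degenerate:
        raise DegenerateSegmentError(
            f"zero-length segment ({a.root_id}[{a.index}] or {b.root_id}[{b.index}])"
        )
    a0 = np.asarray(a.start, dtype=float)
    a1 = np.asarray(a.end, dtype=float)
    b0 = np.asarray(b.start, dtype=float)
    b1 = np.asarray(b.end, dtype=float)
    if a.length <= 0 and b.length <= 0:
        return float(np.linalg.norm(a0 - b0))
    if a.length <= 0:
        return float(_point_segment_distance(a0, b0, b1))
    if b.length <= 0:
        return float(_point_segment_distance(b0, a0, a1))
    return float(_pairwise_segment_distance(a0, a1, b0, b1))


def _point_segment_distance(p: np.ndarray, s0: np.ndarray, s1: np.ndarray) -> float:
    d = s1 - s0
    t = np.clip(np.dot(p - s0, d) / np.dot(d, d), 0.0, 1.0)
    return float(np.linalg.norm(p - (s0 + t * d)))


def distance_matrix(
    gt_segments: list[Segment], traced_segments: list[Segment]
) -> DistanceMatrix:
    """Full ground-truth x traced minimal segment distance matrix.

    ``values[i, j] == segment_distance(gt_segments[i], traced_segments[j])``,
    computed vectorised.
    """
    if not gt_segments or not traced_segments:
        raise ValueError("distance_matrix requires non-empty segment lists")
    a0, a1, alen, arids = segment_arrays(gt_segments)
    b0, b1, blen, brids = segment_arrays(traced_segments)
    if np.any(alen <= 0) or np.any(blen <= 0):
        raise DegenerateSegmentError("zero-length segment in distance_matrix input")
    values = _pairwise_segment_distance(
        a0[:, None, :], a1[:, None, :], b0[None, :, :], b1[None, :, :]
    )
    return DistanceMatrix(
        values=values,
        row_root_ids=arids,
        col_root_ids=brids,
        row_lengths=alen,
        col_lengths=blen,
    )
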