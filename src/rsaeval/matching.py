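"""Topology-aware correspondence between a traced RSA and ground truth.

Matching runs at two granularities:

* **segments** — a two-phase nearest-neighbour assignment under a
  distance threshold ``d`` (diagnostic; exposes where a tracing deviates
  locally), and
* **roots** — the level the scores are built on.  Stage 1 solves the
  globally optimal one-to-one assignment between ground-truth and traced
  roots under the cumulative root distance and keeps pairs within the
  threshold; Stage 2 attaches leftover traced roots (fragments of an
  organ traced in several pieces) to the closest Stage-1-matched
  ground-truth root, yielding 1-to-n pairs.

The cumulative distance between a ground-truth root n and a traced root
m is the length-weighted mean, over the segments of n, of each segment's
minimal distance to the segments of m — so it lives on the same scale as
segment distances and is directly comparable to the threshold.

The field convention expresses the threshold in voxel units of the
underlying MRI grid (default 15); :func:`voxel_threshold_to_cm` converts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import DistanceMatrix, distance_matrix
from .rsa import RootSystem, to_segments

#: distance-matching threshold in voxel units, the field's convention
DEFAULT_THRESHOLD_VOXELS = 15.0

CumulativeMode = Literal["length-weighted-mean", "mean", "sum"]


def voxel_threshold_to_cm(threshold_vox: float, voxel_size: float) -> float:
    """Convert a threshold in voxel units to cm."""
    if threshold_vox <= 0 or voxel_size <= 0:
        raise ValueError("threshold_vox and voxel_size must be positive")
    return threshold_vox * voxel_size


# ---------------------------------------------------------------------------
# Segment-level correspondence
# ---------------------------------------------------------------------------

@dataclass
class SegmentCorrespondence:
    """1-to-n map from ground-truth segments to traced segments.

    ``assignments[i]`` is the (possibly empty) list of traced segment
    indices matched to GT segment i; ``unmatched_traced`` are traced
    segment indices farther than the threshold from every eligible GT
    segment.  ``pair_distances[(i, j)]`` records the distance of each
    recorded pair, always <= threshold.
    """

    assignments: dict[int, list[int]]
    unmatched_traced: list[int]
    pair_distances: dict[tuple[int, int], float]
    threshold: float


def match_segments(
    D: DistanceMatrix,
    threshold: float,
    *,
    phase2_relax: float = 1.0,
) -> SegmentCorrespondence:
    """Two-phase nearest-neighbour segment assignment under a threshold.

    Phase 1: every traced segment is assigned to its nearest GT segment
    when that distance is within the threshold, producing 1-to-n sets per
    GT segment.  Phase 2: traced segments left unmatched are attached to
    the nearest GT segment *among those holding exactly one
    correspondence*, within ``phase2_relax * threshold`` (the relaxation
    defaults to 1, i.e. the same threshold).  Ties break on the lowest
    GT row index; the result is deterministic given ``D``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    values = D.values
    n_gt, n_tr = values.shape
    assignments: dict[int, list[int]] = {i: [] for i in range(n_gt)}
    pair_distances: dict[tuple[int, int], float] = {}
    unmatched: list[int] = []

    nearest = np.argmin(values, axis=0)  # lowest row index wins ties
    nearest_d = values[nearest, np.arange(n_tr)]
    for j in range(n_tr):
        if nearest_d[j] <= threshold:
            i = int(nearest[j])
            assignments[i].append(j)
            pair_distances[(i, j)] = float(nearest_d[j])
        else:
            unmatched.append(j)

    # phase 2: only GT segments holding exactly one correspondence are
    # eligible anchors for the remaining traced segments
    singles = np.array(
        [i for i in range(n_gt) if len(assignments[i]) == 1], dtype=int
    )
    if singles.size and unmatched:
        still: list[int] = []
        for j in unmatched:
            col = values[singles, j]
            k = int(np.argmin(col))
            if col[k] <= phase2_relax * threshold:
                i = int(singles[k])
                assignments[i].append(j)
                pair_distances[(i, j)] = float(col[k])
            else:
                still.append(j)
        unmatched = still

    return SegmentCorrespondence(
        assignments=assignments,
        unmatched_traced=unmatched,
        pair_distances=pair_distances,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Root-level matching
# ---------------------------------------------------------------------------

@dataclass
class RootPair:
    """One matched ground-truth root with its traced counterpart(s)."""

    gt_root_id: str
    traced_root_ids: list[str]
    distance: float                       # Stage-1 cumulative distance d(m, n)
    fragment_distances: dict[str, float] = field(default_factory=dict)


@dataclass
class RootMatch:
    """Root-level assignment between ground truth and a tracing."""

    pairs: list[RootPair]
    gt_root_ids: list[str]                # I_GT
    traced_root_ids: list[str]            # I_T
    threshold: float

    @property
    def matched_gt(self) -> list[str]:
        """I_GC — ground-truth roots with a traced counterpart."""
        return [p.gt_root_id for p in self.pairs]

    @property
    def matched_traced(self) -> list[str]:
        """I_TC — traced roots matched to some ground-truth root."""
        return [m for p in self.pairs for m in p.traced_root_ids]

    @property
    def false_negative_roots(self) -> list[str]:
        """I_GT \\ I_GC — ground-truth roots nobody traced."""
        gc = set(self.matched_gt)
        return [r for r in self.gt_root_ids if r not in gc]

    @property
    def false_positive_roots(self) -> list[str]:
        """I_T \\ I_TC — traced roots with no ground-truth counterpart."""
        tc = set(self.matched_traced)
        return [r for r in self.traced_root_ids if r not in tc]

    def to_dict(self) -> dict:
        return {
            "threshold_cm": self.threshold,
            "pairs": [
                {
                    "gt_root": p.gt_root_id,
                    "traced_roots": list(p.traced_root_ids),
                    "distance_cm": p.distance,
                    "fragment_distances_cm": dict(p.fragment_distances),
                }
                for p in self.pairs
            ],
            "false_negative_roots": self.false_negative_roots,
            "false_positive_roots": self.false_positive_roots,
        }


def _root_cost_matrix(
    D: DistanceMatrix, mode: CumulativeMode
) -> tuple[np.ndarray, list[str], list[str]]:
    """Cumulative root-to-root distances d(m, n) for all (GT, traced) pairs."""
    gt_ids = list(dict.fromkeys(D.row_root_ids))
    tr_ids = list(dict.fromkeys(D.col_root_ids))
    row_rid = np.asarray(D.row_root_ids)
    col_rid = np.asarray(D.col_root_ids)
    cost = np.empty((len(gt_ids), len(tr_ids)))
    for a, n in enumerate(gt_ids):
        rows = np.flatnonzero(row_rid == n)
        w = D.row_lengths[rows]
        for b, m in enumerate(tr_ids):
            cols = np.flatnonzero(col_rid == m)
            per_seg_min = D.values[np.ix_(rows, cols)].min(axis=1)
            if mode == "length-weighted-mean":
                cost[a, b] = float(np.average(per_seg_min, weights=w))
            elif mode == "mean":
                cost[a, b] = float(per_seg_min.mean())
            else:
                cost[a, b] = float(per_seg_min.sum())
    return cost, gt_ids, tr_ids


def cumulative_root_distance(
    D: DistanceMatrix,
    gt_root_id: str,
    traced_root_id: str,
    *,
    mode: CumulativeMode = "length-weighted-mean",
) -> float:
    """Cumulative distance d(m, n) between one GT root and one traced root.

    Length-weighted mean (default) over the GT root's segments of each
    segment's minimal distance to the traced root's segments; the
    unweighted mean and the raw sum are available as alternatives.
    """
    rows = np.flatnonzero(np.asarray(D.row_root_ids) == gt_root_id)
    cols = np.flatnonzero(np.asarray(D.col_root_ids) == traced_root_id)
    if rows.size == 0 or cols.size == 0:
        raise ValueError(
            f"root {gt_root_id!r} or {traced_root_id!r} has no segments in D"
        )
    per_seg_min = D.values[np.ix_(rows, cols)].min(axis=1)
    if mode == "length-weighted-mean":
        return float(np.average(per_seg_min, weights=D.row_lengths[rows]))
    if mode == "mean":
        return float(per_seg_min.mean())
    if mode == "sum":
        return float(per_seg_min.sum())
    raise ValueError(f"unknown cumulative mode {mode!r}")


def match_roots(
    gt: RootSystem,
    traced: RootSystem,
    threshold: float,
    *,
    mode: CumulativeMode = "length-weighted-mean",
    assignment: Literal["optimal", "greedy"] = "optimal",
) -> RootMatch:
    """Match traced roots to ground-truth roots under a threshold (cm).

    Stage 1 solves the rectangular one-to-one assignment minimising the
    total cumulative distance (``assignment="greedy"`` instead picks
    pairs in ascending distance, for comparison) and keeps pairs with
    d(m, n) <= threshold.  Stage 2 attaches each remaining traced root
    to the Stage-1-matched ground-truth root of least cumulative
    distance, when within the threshold — the fragment case where one
    organ is traced in several pieces.  Everything left over becomes a
    false-negative (GT) or false-positive (traced) root.

    An empty tracing is a legal input and yields an all-false-negative
    match, not an error.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    gt.validate()
    traced.validate()
    if not gt.roots:
        raise ValueError("ground truth must contain at least one root")
    gt_ids = gt.root_ids
    tr_ids = traced.root_ids
    if not traced.roots:
        return RootMatch(
            pairs=[], gt_root_ids=gt_ids, traced_root_ids=tr_ids,
            threshold=threshold,
        )

    D = distance_matrix(to_segments(gt), to_segments(traced))
    cost, gt_order, tr_order = _root_cost_matrix(D, mode)

    pairs: list[RootPair] = []
    if assignment == "optimal":
        rows, cols = linear_sum_assignment(cost)
    elif assignment == "greedy":
        rows, cols = _greedy_assignment(cost)
    else:
        raise ValueError(f"unknown assignment strategy {assignment!r}")
    taken_traced: set[str] = set()
    for a, b in sorted(zip(rows, cols)):
        d = float(cost[a, b])
        if d <= threshold:
            pairs.append(
                RootPair(
                    gt_root_id=gt_order[a],
                    traced_root_ids=[tr_order[b]],
                    distance=d,
                )
            )
            taken_traced.add(tr_order[b])

    if pairs:
        anchor_rows = [gt_order.index(p.gt_root_id) for p in pairs]
        for b, m in enumerate(tr_order):
            if m in taken_traced:
                continue
            col = cost[anchor_rows, b]
            k = int(np.argmin(col))
            if col[k] <= threshold:
                pairs[k].traced_root_ids.append(m)
                pairs[k].fragment_distances[m] = float(col[k])
                taken_traced.add(m)

    return RootMatch(
        pairs=pairs, gt_root_ids=gt_ids, traced_root_ids=tr_ids,
        threshold=threshold,
    )


def _greedy_assignment(cost: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-to-one assignment by ascending distance (comparison baseline)."""
    n, m = cost.shape
    order = np.argsort(cost, axis=None, kind="stable")
    rows_taken: set[int] = set()
    cols_taken: set[int] = set()
    rows: list[int] = []
    cols: list[int] = []
    for flat in order:
        a, b = divmod(int(flat), m)
        if a in rows_taken or b in cols_taken:
            continue
        rows.append(a)
        cols.append(b)
        rows_taken.add(a)
        cols_taken.add(b)
        if len(rows) == min(n, m):
            break
    return np.asarray(rows), np.asarray(cols)
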