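"""RSA trait measures: length totals, lateral counts, inter-lateral spacing.

These are the architectural descriptors commonly compared against ground
truth in phenotyping studies: total root length Σlᵢ, average root
length, the number of lateral roots above a minimum-length filter (short
stubs are usually tracing artifacts, not organs), and the mean
arc-length spacing between consecutive lateral attachment points along
the taproot.  Relative errors against ground-truth values quantify
per-trait tracing accuracy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .rsa import Root, RootSystem

#: laterals shorter than this (cm) are excluded from the count by default
DEFAULT_LATERAL_MIN_LENGTH_CM = 3.0


class UndefinedTraitError(ValueError):
    """Raised when a trait has no defined value for the given system."""


@dataclass(frozen=True)
class TraitReport:
    """Per-system trait summary (all lengths in cm)."""

    total_length: float
    average_root_length: float
    lateral_count: int
    inter_lateral_distance: float | None
    filter_min_length: float

    def to_dict(self) -> dict:
        return {
            "total_length_cm": self.total_length,
            "average_root_length_cm": self.average_root_length,
            "lateral_count": self.lateral_count,
            "inter_lateral_distance_cm": self.inter_lateral_distance,
            "filter_min_length_cm": self.filter_min_length,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def total_length(rsa: RootSystem) -> float:
    """Σlᵢ over all segments of all roots, cm."""
    rsa.validate()
    return float(sum(r.length for r in rsa.roots))


def average_root_length(rsa: RootSystem) -> float:
    """Total length divided by the number of roots."""
    if not rsa.roots:
        raise UndefinedTraitError("average root length undefined for empty system")
    return total_length(rsa) / len(rsa.roots)


def lateral_count(
    rsa: RootSystem, min_length: float = DEFAULT_LATERAL_MIN_LENGTH_CM
) -> int:
    """Number of roots of order >= 1 at least ``min_length`` cm long."""
    if min_length < 0:
        raise ValueError("min_length must be non-negative")
    rsa.validate()
    return sum(1 for r in rsa.roots if r.order >= 1 and r.length >= min_length)


def attachment_arc_position(taproot: Root, lateral: Root) -> float:
    """Arc-length position (cm) of a lateral's branching point on the taproot.

    Uses the recorded attachment when present; otherwise the lateral's
    first node is projected to the nearest point of the taproot polyline
    (tracings attach laterals visually, not topologically).
    """
    if lateral.parent_attachment is not None:
        return float(np.clip(lateral.parent_attachment, 0.0, taproot.length))
    p = np.asarray(lateral.nodes[0].position, dtype=float)
    pos = taproot.positions
    a = pos[:-1]
    b = pos[1:]
    d = b - a
    seg_len2 = np.sum(d * d, axis=1)
    t = np.clip(np.sum((p - a) * d, axis=1) / seg_len2, 0.0, 1.0)
    closest = a + t[:, None] * d
    dist = np.linalg.norm(closest - p, axis=1)
    i = int(np.argmin(dist))
    arc = taproot.arc_positions()
    return float(arc[i] + t[i] * np.sqrt(seg_len2[i]))


def inter_lateral_distance(rsa: RootSystem) -> float:
    """Mean arc-length spacing between consecutive laterals on the taproot.

    Measured along the taproot, not as straight-line distance between
    branch points.  Requires exactly one taproot carrying >= 2 laterals.
    """
    rsa.validate()
    taproots = rsa.taproots()
    if len(taproots) != 1:
        raise UndefinedTraitError(
            f"inter-lateral distance needs exactly one taproot, found {len(taproots)}"
        )
    taproot = taproots[0]
    laterals = [
        r for r in rsa.roots
        if r.order == 1 and (
            r.parent_root_id == taproot.root_id or r.parent_root_id is None
        )
    ]
    if len(laterals) < 2:
        raise UndefinedTraitError(
            f"inter-lateral distance needs >= 2 laterals, found {len(laterals)}"
        )
    arcs = np.sort([attachment_arc_position(taproot, lat) for lat in laterals])
    return float(np.mean(np.diff(arcs)))


def relative_error(traced_value: float, gt_value: float) -> float:
    """|traced − gt| / gt; the per-trait accuracy measure."""
    if gt_value <= 0:
        raise ValueError("ground-truth value must be positive")
    return abs(traced_value - gt_value) / gt_value


def trait_report(
    rsa: RootSystem, min_length: float = DEFAULT_LATERAL_MIN_LENGTH_CM
) -> TraitReport:
    """All traits for one system; inter-lateral distance is None when undefined."""
    try:
        ild = inter_lateral_distance(rsa)
    except UndefinedTraitError:
        ild = None
    return TraitReport(
        total_length=total_length(rsa),
        average_root_length=average_root_length(rsa),
        lateral_count=lateral_count(rsa, min_length),
        inter_lateral_distance=ild,
        filter_min_length=min_length,
    )
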