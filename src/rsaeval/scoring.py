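"""Matched-length precision, recall and F1 for RSA tracings.

After root-level matching, whole-root lengths are summed over the index
sets: L_GC over matched ground-truth roots (I_GC), L_TC over matched
traced roots (I_TC), L_FN over untraced ground-truth roots, L_FP over
spurious traced roots.  Note L_GC != L_TC in general, because I_GC and
I_TC index different systems.

    R  = L_GC / (L_GC + L_FN + pen_R)      pen_R = max(0, L_GC - L_TC)
    P  = L_GC / (L_GC + L_FP + pen_P)      pen_P = max(0, L_TC - L_GC)
    F1 = 2 P R / (P + R)

The penalties charge recall for under-traced matched length and
precision for over-traced matched length, keeping both in [0, 1].  A
``literal-min`` mode replaces max(0, .) with min(0, .) — the sign
convention some sources print — for forensic comparison; that form
zeroes the penalty in exactly the scenarios it is meant to punish and
can exceed 1, so it is not the default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal

from .matching import RootMatch, match_roots
from .rsa import RootSystem

PenaltyMode = Literal["max", "literal-min"]


@dataclass(frozen=True)
class LengthDecomposition:
    """Whole-root length totals (cm) over the match index sets."""

    L_GT: float
    L_GC: float
    L_TC: float
    L_FN: float
    L_FP: float

    def __post_init__(self) -> None:
        for name in ("L_GT", "L_GC", "L_TC", "L_FN", "L_FP"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class ScoreReport:
    """Recall, precision and F1 with their length decomposition."""

    recall: float
    precision: float
    f1: float
    lengths: LengthDecomposition
    penalty_mode: PenaltyMode = "max"
    threshold: float | None = None

    def to_dict(self) -> dict:
        return {
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "penalty_mode": self.penalty_mode,
            "threshold_cm": self.threshold,
            "lengths_cm": {
                "L_GT": self.lengths.L_GT,
                "L_GC": self.lengths.L_GC,
                "L_TC": self.lengths.L_TC,
                "L_FN": self.lengths.L_FN,
                "L_FP": self.lengths.L_FP,
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def length_decomposition(
    match: RootMatch, gt: RootSystem, traced: RootSystem
) -> LengthDecomposition:
    """Sum whole-root lengths over the match's index sets."""
    gt_len = {r.root_id: r.length for r in gt.roots}
    tr_len = {r.root_id: r.length for r in traced.roots}
    for rid in match.gt_root_ids:
        if rid not in gt_len:
            raise ValueError(f"match references unknown ground-truth root {rid!r}")
    for rid in match.traced_root_ids:
        if rid not in tr_len:
            raise ValueError(f"match references unknown traced root {rid!r}")
    L_GT = sum(gt_len[r] for r in match.gt_root_ids)
    L_GC = sum(gt_len[r] for r in match.matched_gt)
    L_TC = sum(tr_len[r] for r in match.matched_traced)
    L_FN = sum(gt_len[r] for r in match.false_negative_roots)
    L_FP = sum(tr_len[r] for r in match.false_positive_roots)
    return LengthDecomposition(L_GT=L_GT, L_GC=L_GC, L_TC=L_TC, L_FN=L_FN, L_FP=L_FP)


def _penalty(delta: float, mode: PenaltyMode) -> float:
    if mode == "max":
        return max(0.0, delta)
    if mode == "literal-min":
        return min(0.0, delta)
    raise ValueError(f"unknown penalty mode {mode!r}")


def recall(ld: LengthDecomposition, *, penalty_mode: PenaltyMode = "max") -> float:
    """How much of the ground truth, in length, was traced (0 on empty)."""
    denom = ld.L_GC + ld.L_FN + _penalty(ld.L_GC - ld.L_TC, penalty_mode)
    return ld.L_GC / denom if denom > 0 else 0.0


def precision(ld: LengthDecomposition, *, penalty_mode: PenaltyMode = "max") -> float:
    """Whether the tracing contains only as much length as the ground truth."""
    denom = ld.L_GC + ld.L_FP + _penalty(ld.L_TC - ld.L_GC, penalty_mode)
    return ld.L_GC / denom if denom > 0 else 0.0


def f1(P: float, R: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if not (0.0 <= P <= 1.0) or not (0.0 <= R <= 1.0):
        raise ValueError(f"P={P} and R={R} must lie in [0, 1]")
    return 2.0 * P * R / (P + R) if P + R > 0 else 0.0


def score(
    gt: RootSystem,
    traced: RootSystem,
    threshold: float,
    *,
    penalty_mode: PenaltyMode = "max",
) -> ScoreReport:
    """Match, decompose lengths, and compute R, P, F1 in one call.

    An empty tracing scores R = P = F1 = 0.
    """
    match = match_roots(gt, traced, threshold)
    ld = length_decomposition(match, gt, traced)
    R = recall(ld, penalty_mode=penalty_mode)
    P = precision(ld, penalty_mode=penalty_mode)
    # literal-min can push P or R past 1; the harmonic mean is then taken
    # as-is rather than rejected, so the forensic mode stays comparable
    F = 2.0 * P * R / (P + R) if P + R > 0 else 0.0
    return ScoreReport(
        recall=R, precision=P, f1=F, lengths=ld,
        penalty_mode=penalty_mode, threshold=threshold,
    )
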