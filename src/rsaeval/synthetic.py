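"""Parametric ground-truth RSAs and a tracing-error perturbation model.

The generator emulates the shape of a young faba-bean root system as it
appears in MRI soil columns: a single tortuous taproot growing downward
with first-order laterals attached at regular arc-length spacing along
it.  It is parameter-transparent — every trait of the output (total
length, lateral count, inter-lateral spacing) is recoverable from the
parameters, which makes it a test oracle for the trait and scoring
pipeline.  It does not model physiology (no growth dynamics, no water
uptake, no diameter tapering along an organ).

The perturbation model turns a ground truth into a plausible human
tracing by composing, in a fixed order, the artifact classes observed
when people trace root MRI data: dropped roots, node placement jitter,
over-/under-traced tips, spurious short branches from misclicks along
an organ, and free-floating false-positive roots (misclicks into the
water volume).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .rsa import Node, Root, RootSystem, copy_system


def _load_params(cls, path):
    path = Path(path)
    if path.suffix.lower() == ".toml":
        import tomllib

        data = tomllib.loads(path.read_text())
    else:
        import json

        data = json.loads(path.read_text())
    return cls(**data)


@dataclass
class GeneratorParams:
    """Faba-bean-like RSA parameters (lengths in cm, angles in degrees)."""

    taproot_length: float = 15.0
    n_laterals: int = 25
    inter_lateral_distance: float = 0.5
    first_lateral_offset: float = 1.0
    lateral_length_mean: float = 5.0
    lateral_length_sd: float = 1.0
    lateral_length_min: float = 3.0
    branching_angle_mean: float = 70.0
    branching_angle_sd: float = 10.0
    node_spacing: float = 0.25
    tortuosity: float = 0.1          # per-step direction noise, radians-scale
    gravitropism: float = 0.08       # per-step pull back toward straight down
    attachment_jitter_sd: float = 0.0
    taproot_diameter: float = 0.3
    lateral_diameter: float = 0.1
    #: per-lateral diameter overrides, e.g. {12: 0.03} for one thin root
    diameter_overrides: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "taproot_length", "inter_lateral_distance", "lateral_length_mean",
            "node_spacing", "taproot_diameter", "lateral_diameter",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_laterals < 0:
            raise ValueError("n_laterals must be non-negative")
        if self.n_laterals:
            last = (
                self.first_lateral_offset
                + (self.n_laterals - 1) * self.inter_lateral_distance
            )
            if last >= self.taproot_length:
                raise ValueError(
                    f"{self.n_laterals} laterals at spacing "
                    f"{self.inter_lateral_distance} cm do not fit on a "
                    f"{self.taproot_length} cm taproot"
                )

    @classmethod
    def from_file(cls, path) -> "GeneratorParams":
        return _load_params(cls, path)


@dataclass
class PerturbationParams:
    """Tracing-artifact magnitudes; all-zero is the identity."""

    node_jitter_sd: float = 0.0          # cm, isotropic Gaussian on every node
    drop_root_prob: float = 0.0          # per non-taproot root (with descendants)
    overtrace_fraction: float = 0.0      # signed; +extends, −truncates each tip
    spurious_branch_rate: float = 0.0    # Poisson mean per surviving root
    spurious_branch_length: float = 1.0  # cm, mean of short misclick branches
    false_positive_count: int = 0
    false_positive_length_mean: float = 2.0
    false_positive_length_sd: float = 0.5
    #: (x, y) placement of false positives, cm; None centres on the RSA
    false_positive_center: tuple[float, float] | None = None
    false_positive_spread: float = 0.75  # cm, lateral scatter of misclicks
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.drop_root_prob <= 1.0):
            raise ValueError("drop_root_prob must lie in [0, 1]")
        if self.node_jitter_sd < 0 or self.spurious_branch_rate < 0:
            raise ValueError("jitter and branch rate must be non-negative")
        if self.false_positive_count < 0:
            raise ValueError("false_positive_count must be non-negative")

    @property
    def is_identity(self) -> bool:
        return (
            self.node_jitter_sd == 0
            and self.drop_root_prob == 0
            and self.overtrace_fraction == 0
            and self.spurious_branch_rate == 0
            and self.false_positive_count == 0
        )

    @classmethod
    def from_file(cls, path) -> "PerturbationParams":
        return _load_params(cls, path)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _random_walk(
    start: np.ndarray,
    direction: np.ndarray,
    length: float,
    spacing: float,
    tortuosity: float,
    gravitropism: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Polyline of exact arc length ``length`` from a biased random walk."""
    n_full = max(1, int(math.ceil(length / spacing)))
    steps = np.full(n_full, spacing)
    steps[-1] = length - spacing * (n_full - 1)
    if steps[-1] <= 1e-9:  # exact multiple of spacing
        steps = steps[:-1]
        steps[-1] = spacing
    down = np.array([0.0, 0.0, 1.0])
    points = [start.copy()]
    d = direction / np.linalg.norm(direction)
    for s in steps:
        d = d + tortuosity * rng.standard_normal(3) + gravitropism * (down - d)
        d = d / np.linalg.norm(d)
        points.append(points[-1] + s * d)
    return np.asarray(points)


def _orthonormal_frame(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to t and to each other."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(t @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(t, helper)
    u /= np.linalg.norm(u)
    v = np.cross(t, u)
    return u, v


def _polyline_nodes(points: np.ndarray, diameter: float) -> list[Node]:
    return [Node(position=tuple(p), diameter=diameter) for p in points]


def generate_root_system(params: GeneratorParams) -> RootSystem:
    """Generate a taproot with regularly spaced first-order laterals.

    Reproducible from ``params.seed``; the output passes RSA validation
    and, at zero attachment jitter, recovers ``inter_lateral_distance``
    and the lateral count exactly through the trait pipeline.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    tap_points = _random_walk(
        start=np.zeros(3),
        direction=np.array([0.0, 0.0, 1.0]),
        length=params.taproot_length,
        spacing=params.node_spacing,
        tortuosity=params.tortuosity,
        gravitropism=params.gravitropism,
        rng=rng,
    )
    taproot = Root(
        root_id="taproot",
        nodes=_polyline_nodes(tap_points, params.taproot_diameter),
        order=0,
    )
    roots = [taproot]

    for k in range(params.n_laterals):
        s = params.first_lateral_offset + k * params.inter_lateral_distance
        if params.attachment_jitter_sd > 0:
            s += rng.normal(0.0, params.attachment_jitter_sd)
            s = float(np.clip(s, 0.0, params.taproot_length - 1e-6))
        attach = taproot.point_at(s)
        # local tangent of the taproot at the attachment point
        arc = taproot.arc_positions()
        i = min(int(np.searchsorted(arc, s, side="right")) - 1, len(arc) - 2)
        t = tap_points[i + 1] - tap_points[i]
        t = t / np.linalg.norm(t)
        u, v = _orthonormal_frame(t)
        theta = math.radians(
            rng.normal(params.branching_angle_mean, params.branching_angle_sd)
        )
        phi = rng.uniform(0.0, 2.0 * math.pi)
        direction = (
            math.cos(theta) * t
            + math.sin(theta) * (math.cos(phi) * u + math.sin(phi) * v)
        )
        length = max(
            params.lateral_length_min,
            rng.normal(params.lateral_length_mean, params.lateral_length_sd),
        )
        lat_points = _random_walk(
            start=attach,
            direction=direction,
            length=length,
            spacing=params.node_spacing,
            tortuosity=params.tortuosity,
            gravitropism=params.gravitropism * 0.5,
            rng=rng,
        )
        diameter = params.diameter_overrides.get(k, params.lateral_diameter)
        roots.append(
            Root(
                root_id=f"lateral-{k:02d}",
                nodes=_polyline_nodes(lat_points, diameter),
                order=1,
                parent_root_id="taproot",
                parent_attachment=s,
            )
        )

    rsa = RootSystem(roots=roots, label=f"synthetic-faba-{params.seed}")
    rsa.validate()
    return rsa


# ---------------------------------------------------------------------------
# Perturbation
# ---------------------------------------------------------------------------

def _truncate_root(root: Root, target_length: float) -> Root:
    """Shorten a root's polyline to ``target_length`` of arc (>= 1 segment)."""
    arc = root.arc_positions()
    target = max(target_length, float(arc[1]) * 0.5)  # keep at least half a step
    target = min(target, float(arc[-1]))
    keep = int(np.searchsorted(arc, target, side="left"))
    pts = root.positions[:keep]
    tip = root.point_at(target)
    if len(pts) == 0 or np.linalg.norm(tip - pts[-1]) < 1e-9:
        pts_out = pts
    else:
        pts_out = np.vstack([pts, tip])
    if len(pts_out) < 2:
        pts_out = np.vstack([root.positions[0], tip])
    dia = root.nodes[0].diameter
    return replace(root, nodes=_polyline_nodes(pts_out, dia))


def _extend_root(root: Root, extra_length: float) -> Root:
    """Extend the tip along the last segment direction."""
    pos = root.positions
    d = pos[-1] - pos[-2]
    d = d / np.linalg.norm(d)
    new_tip = pos[-1] + extra_length * d
    nodes = list(root.nodes) + [
        Node(position=tuple(new_tip), diameter=root.nodes[-1].diameter)
    ]
    return replace(root, nodes=nodes)


def perturb_tracing(rsa: RootSystem, params: PerturbationParams) -> RootSystem:
    """Derive a plausible human tracing from a ground-truth RSA.

    Perturbations apply in a fixed, documented order so seeds are
    reproducible: (1) root dropping (non-taproot roots, with their
    descendants), (2) node jitter, (3) tip over-/under-tracing,
    (4) spurious short branches, (5) free-floating false-positive
    roots.  All-zero parameters return an identical copy.
    """
    params.validate()
    rsa.validate()
    if params.is_identity:
        return copy_system(rsa)
    rng = np.random.default_rng(params.seed)

    # (1) drop roots; dropping a root removes its whole subtree
    # (parents are visited before children: order ascends along any chain)
    survivors: list[Root] = []
    dropped: set[str] = set()
    for root in sorted(rsa.roots, key=lambda r: r.order):
        if root.parent_root_id in dropped:
            dropped.add(root.root_id)
            continue
        if root.order >= 1 and rng.random() < params.drop_root_prob:
            dropped.add(root.root_id)
            continue
        survivors.append(replace(root, nodes=list(root.nodes)))

    # (2) node jitter
    if params.node_jitter_sd > 0:
        jittered: list[Root] = []
        for root in survivors:
            pos = root.positions + rng.normal(
                0.0, params.node_jitter_sd, size=(len(root.nodes), 3)
            )
            nodes = [
                Node(position=tuple(p), diameter=n.diameter)
                for p, n in zip(pos, root.nodes)
            ]
            # a tracing attaches laterals visually, not topologically
            jittered.append(replace(root, nodes=nodes, parent_attachment=None))
        survivors = jittered

    # (3) tip over-/under-tracing
    f = params.overtrace_fraction
    if f != 0.0:
        adjusted: list[Root] = []
        for root in survivors:
            length = root.length
            if f > 0:
                adjusted.append(_extend_root(root, f * length))
            else:
                adjusted.append(_truncate_root(root, (1.0 + f) * length))
        survivors = adjusted

    # (4) spurious short branches along surviving roots
    spurs: list[Root] = []
    if params.spurious_branch_rate > 0:
        for root in survivors:
            for j in range(rng.poisson(params.spurious_branch_rate)):
                s = rng.uniform(0.0, root.length)
                start = root.point_at(s)
                direction = rng.standard_normal(3)
                direction /= np.linalg.norm(direction)
                length = max(0.3, rng.normal(params.spurious_branch_length, 0.3))
                pts = _random_walk(
                    start, direction, length, spacing=0.25,
                    tortuosity=0.1, gravitropism=0.0, rng=rng,
                )
                spurs.append(
                    Root(
                        root_id=f"spur-{root.root_id}-{j}",
                        nodes=_polyline_nodes(pts, root.nodes[0].diameter),
                        order=root.order + 1,
                        parent_root_id=root.root_id,
                        parent_attachment=None,
                    )
                )

    # (5) free-floating false positives (misclicks into the water volume)
    fps: list[Root] = []
    if params.false_positive_count > 0:
        all_pts = np.concatenate([r.positions for r in rsa.roots])
        lo, hi = all_pts.min(axis=0), all_pts.max(axis=0)
        if params.false_positive_center is None:
            cx, cy = 0.5 * (lo[0] + hi[0]), 0.5 * (lo[1] + hi[1])
        else:
            cx, cy = params.false_positive_center
        for j in range(params.false_positive_count):
            start = np.array(
                [
                    cx + rng.normal(0.0, params.false_positive_spread),
                    cy + rng.normal(0.0, params.false_positive_spread),
                    rng.uniform(lo[2], hi[2]),
                ]
            )
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            length = max(
                0.5,
                rng.normal(
                    params.false_positive_length_mean,
                    params.false_positive_length_sd,
                ),
            )
            pts = _random_walk(
                start, direction, length, spacing=0.25,
                tortuosity=0.15, gravitropism=0.0, rng=rng,
            )
            fps.append(
                Root(
                    root_id=f"fp-{j:02d}",
                    nodes=_polyline_nodes(pts, 0.1),
                    order=1,
                    parent_root_id=None,
                )
            )

    traced = RootSystem(
        roots=survivors + spurs + fps,
        label=f"{rsa.label}-traced",
        unit=rsa.unit,
    )
    traced.validate()
    return traced
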