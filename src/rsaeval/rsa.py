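"""Root system architecture (RSA) data model and RSML interchange.

An RSA is a forest of rooted polyline organs: an order-0 taproot (primary
root) with nested lateral roots of increasing order.  Each node carries a
3D position and a diameter.  All lengths are held internally in
centimetres; RSML metadata (``unit``/``resolution``) is honoured on read
and written explicitly on write.

The polyline decomposition into straight segments produced by
:func:`to_segments` is the atomic unit of the downstream distance matrix
and of every length-based score and trait.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from lxml import etree

logger = logging.getLogger("rsaeval")

#: diameter (cm) assumed when a tracing carries no diameter information
DEFAULT_DIAMETER_CM = 0.1

#: conversion factors from RSML unit tags to centimetres
_UNIT_TO_CM = {
    "m": 100.0,
    "dm": 10.0,
    "cm": 1.0,
    "mm": 0.1,
    "um": 1e-4,
    "micron": 1e-4,
    "pixel": 1.0,  # dimensionless grids are taken at face value (cm)
    "": 1.0,
}


class RSAValidationError(ValueError):
    """Raised when a root system violates a structural invariant."""


class RSMLParseError(ValueError):
    """Raised when an RSML document cannot be parsed or understood."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Node:
    """A polyline vertex: position (cm) and local root diameter (cm)."""

    position: tuple[float, float, float]
    diameter: float = DEFAULT_DIAMETER_CM

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.position):
            raise RSAValidationError(f"non-finite node position {self.position}")
        if not (self.diameter >= 0 and math.isfinite(self.diameter)):
            raise RSAValidationError(f"invalid node diameter {self.diameter}")


@dataclass
class Root:
    """A single organ: an ordered polyline of at least two nodes.

    ``order`` follows the usual convention: 0 for the taproot, 1 for
    first-order laterals, and so on.  ``parent_attachment`` is the
    arc-length position (cm) of the branching point along the parent,
    when known; tracings typically attach laterals visually, so it is
    optional.
    """

    root_id: str
    nodes: list[Node]
    order: int = 0
    parent_root_id: str | None = None
    parent_attachment: float | None = None

    def validate(self) -> None:
        if len(self.nodes) < 2:
            raise RSAValidationError(
                f"root {self.root_id!r} has {len(self.nodes)} node(s); need >= 2"
            )
        if self.order < 0:
            raise RSAValidationError(f"root {self.root_id!r} has negative order")
        if self.order == 0 and self.parent_root_id is not None:
            raise RSAValidationError(
                f"taproot {self.root_id!r} must not have a parent"
            )
        pos = np.asarray([n.position for n in self.nodes], dtype=float)
        step = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        if np.any(step <= 0.0):
            i = int(np.argmin(step))
            raise RSAValidationError(
                f"root {self.root_id!r}: consecutive nodes {i} and {i + 1} coincide"
            )

    @property
    def positions(self) -> np.ndarray:
        """Node positions as an (n, 3) float array, cm."""
        return np.asarray([n.position for n in self.nodes], dtype=float)

    @property
    def length(self) -> float:
        """Arc length of the polyline, cm."""
        pos = self.positions
        return float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())

    def arc_positions(self) -> np.ndarray:
        """Cumulative arc length at each node (starts at 0), cm."""
        pos = self.positions
        step = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(step)])

    def point_at(self, s: float) -> np.ndarray:
        """Interpolated point at arc-length position ``s`` (clamped)."""
        arc = self.arc_positions()
        s = float(np.clip(s, 0.0, arc[-1]))
        i = int(np.searchsorted(arc, s, side="right") - 1)
        i = min(i, len(arc) - 2)
        seg = arc[i + 1] - arc[i]
        t = 0.0 if seg == 0 else (s - arc[i]) / seg
        pos = self.positions
        return pos[i] + t * (pos[i + 1] - pos[i])


@dataclass
class RootSystem:
    """A validated forest of roots; the unit of scoring and simulation."""

    roots: list[Root] = field(default_factory=list)
    label: str = ""
    unit: str = "cm"

    def validate(self) -> None:
        ids = [r.root_id for r in self.roots]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise RSAValidationError(f"duplicate root ids {dupes}")
        by_id = {r.root_id: r for r in self.roots}
        for r in self.roots:
            r.validate()
            if r.parent_root_id is not None:
                parent = by_id.get(r.parent_root_id)
                if parent is None:
                    raise RSAValidationError(
                        f"root {r.root_id!r}: parent {r.parent_root_id!r} not found"
                    )
                if r.order != parent.order + 1:
                    raise RSAValidationError(
                        f"root {r.root_id!r}: order {r.order} != parent order "
                        f"{parent.order} + 1"
                    )
        # acyclicity: walk each parent chain; orders strictly decrease so a
        # cycle can only arise through inconsistent orders, caught above,
        # but guard against pathological hand-built systems anyway
        for r in self.roots:
            seen = {r.root_id}
            cur = r
            while cur.parent_root_id is not None:
                if cur.parent_root_id in seen:
                    raise RSAValidationError(f"parent cycle through {r.root_id!r}")
                seen.add(cur.parent_root_id)
                cur = by_id[cur.parent_root_id]

    def root(self, root_id: str) -> Root:
        for r in self.roots:
            if r.root_id == root_id:
                return r
        raise KeyError(root_id)

    @property
    def root_ids(self) -> list[str]:
        return [r.root_id for r in self.roots]

    def children_of(self, root_id: str) -> list[Root]:
        return [r for r in self.roots if r.parent_root_id == root_id]

    def taproots(self) -> list[Root]:
        return [r for r in self.roots if r.order == 0]

    def validation_report(self) -> dict:
        """Machine-readable validity summary (JSON-friendly)."""
        try:
            self.validate()
            return {"valid": True, "n_roots": len(self.roots), "errors": []}
        except RSAValidationError as exc:
            return {"valid": False, "n_roots": len(self.roots), "errors": [str(exc)]}


@dataclass(frozen=True)
class Segment:
    """A straight piece of root between two consecutive nodes."""

    root_id: str
    index: int
    start: tuple[float, float, float]
    end: tuple[float, float, float]
    length: float
    radius: float  # mean of endpoint radii, cm


# ---------------------------------------------------------------------------
# Segment decomposition
# ---------------------------------------------------------------------------

def to_segments(rsa: RootSystem) -> list[Segment]:
    """Decompose every root polyline into straight segments.

    One segment per consecutive node pair, in stable (root order within
    the system, node order within the root) sequence; the sum of segment
    lengths equals the system's total length.
    """
    rsa.validate()
    segments: list[Segment] = []
    for root in rsa.roots:
        pos = root.positions
        dia = np.asarray([n.diameter for n in root.nodes], dtype=float)
        step = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        for i in range(len(root.nodes) - 1):
            segments.append(
                Segment(
                    root_id=root.root_id,
                    index=i,
                    start=tuple(pos[i]),
                    end=tuple(pos[i + 1]),
                    length=float(step[i]),
                    radius=float(0.25 * (dia[i] + dia[i + 1])),
                )
            )
    return segments


def segment_arrays(
    segments: Sequence[Segment],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Pack segments into (start, end, length) arrays plus root ids.

    Convenience for the vectorised geometry kernels.
    """
    if not segments:
        return (
            np.zeros((0, 3)),
            np.zeros((0, 3)),
            np.zeros((0,)),
            [],
        )
    p0 = np.asarray([s.start for s in segments], dtype=float)
    p1 = np.asarray([s.end for s in segments], dtype=float)
    ln = np.asarray([s.length for s in segments], dtype=float)
    ids = [s.root_id for s in segments]
    return p0, p1, ln, ids


# ---------------------------------------------------------------------------
# RSML reading
# ---------------------------------------------------------------------------

def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _parse_point(el: etree._Element) -> tuple[float, float, float]:
    try:
        return (float(el.get("x")), float(el.get("y")), float(el.get("z", 0.0)))
    except (TypeError, ValueError) as exc:
        raise RSMLParseError(
            f"bad point attributes at line {el.sourceline}: {dict(el.attrib)}"
        ) from exc


def _find_child(el: etree._Element, name: str) -> etree._Element | None:
    for child in el:
        if _local(child.tag) == name:
            return child
    return None


def _read_diameters(root_el: etree._Element, n_points: int) -> list[float] | None:
    """Per-node diameters from a 'diameter' sample function, if present."""
    functions = _find_child(root_el, "functions")
    if functions is None:
        return None
    for fn in functions:
        if _local(fn.tag) != "function":
            continue
        if (fn.get("name") or "").lower() != "diameter":
            continue
        samples = [
            float(s.get("value"))
            for s in fn
            if _local(s.tag) == "sample" and s.get("value") is not None
        ]
        if not samples:
            return None
        if len(samples) == n_points:
            return samples
        # tolerate truncated/over-long sample runs: clip or pad with last
        logger.warning(
            "diameter function has %d samples for %d points; adjusting",
            len(samples),
            n_points,
        )
        samples = samples[:n_points]
        samples += [samples[-1]] * (n_points - len(samples))
        return samples
    return None


def _read_properties(root_el: etree._Element) -> dict[str, str]:
    props: dict[str, str] = {}
    properties = _find_child(root_el, "properties")
    if properties is None:
        return props
    for p in properties:
        name = p.get("name") or _local(p.tag)
        value = p.get("value")
        if value is None:
            value = (p.text or "").strip()
        props[name.lower()] = value
    return props


def _walk_root(
    root_el: etree._Element,
    depth: int,
    parent_id: str | None,
    scale: float,
    flip_z: bool,
    default_diameter: float,
    counter: Iterator[int],
    out: list[Root],
) -> None:
    rid = root_el.get("ID") or root_el.get("id") or f"root-{next(counter)}"
    geometry = _find_child(root_el, "geometry")
    polyline = _find_child(geometry, "polyline") if geometry is not None else None
    if polyline is None:
        raise RSMLParseError(
            f"root {rid!r} (line {root_el.sourceline}) has no polyline geometry"
        )
    points = [_parse_point(p) for p in polyline if _local(p.tag) == "point"]
    if len(points) < 2:
        raise RSAValidationError(
            f"root {rid!r} has {len(points)} point(s); RSML roots need >= 2"
        )
    diameters = _read_diameters(root_el, len(points))
    props = _read_properties(root_el)
    if diameters is None:
        # fall back to a root-level diameter property/attribute
        d_attr = props.get("diameter") or root_el.get("diameter")
        d = float(d_attr) * scale if d_attr is not None else default_diameter
        diameters = [d] * len(points)
    else:
        diameters = [d * scale for d in diameters]

    order = depth
    label_order = props.get("order")
    if label_order is not None:
        try:
            explicit = int(float(label_order))
        except ValueError:
            explicit = None
        if explicit is not None and explicit != depth:
            warnings.warn(
                f"root {rid!r}: labelled order {explicit} conflicts with nesting "
                f"depth {depth}; using nesting depth",
                stacklevel=2,
            )

    attach = props.get("insertion_position")
    zsign = -1.0 if flip_z else 1.0
    nodes = [
        Node(
            position=(x * scale, y * scale, z * scale * zsign),
            diameter=d,
        )
        for (x, y, z), d in zip(points, diameters)
    ]
    out.append(
        Root(
            root_id=rid,
            nodes=nodes,
            order=order,
            parent_root_id=parent_id,
            parent_attachment=float(attach) * scale if attach is not None else None,
        )
    )
    for child in root_el:
        if _local(child.tag) == "root":
            _walk_root(
                child, depth + 1, rid, scale, flip_z, default_diameter, counter, out
            )


def read_rsml(
    path: str | Path,
    *,
    default_diameter: float = DEFAULT_DIAMETER_CM,
    flip_z: bool = False,
) -> RootSystem:
    """Read an RSML file into a validated :class:`RootSystem` (cm units).

    Root order is taken from nesting depth (a conflicting textual
    ``order`` property triggers a warning).  Coordinates are scaled to cm
    from the metadata ``unit`` and ``resolution`` fields.  ``flip_z``
    negates the z axis for data recorded with z pointing up out of the
    soil column.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise RSMLParseError(f"{path}: malformed XML: {exc}") from exc
    rsml = tree.getroot()
    if _local(rsml.tag) != "rsml":
        raise RSMLParseError(f"{path}: top-level element is <{rsml.tag}>, not <rsml>")

    unit = "cm"
    resolution = 1.0
    label = path.stem
    metadata = _find_child(rsml, "metadata")
    if metadata is not None:
        unit_el = _find_child(metadata, "unit")
        if unit_el is not None and unit_el.text:
            unit = unit_el.text.strip().lower()
        res_el = _find_child(metadata, "resolution")
        if res_el is not None and res_el.text:
            resolution = float(res_el.text.strip())
        label_el = _find_child(metadata, "label")
        if label_el is not None and label_el.text:
            label = label_el.text.strip()
    if unit not in _UNIT_TO_CM:
        raise RSMLParseError(f"{path}: unsupported unit {unit!r}")
    if resolution <= 0:
        raise RSMLParseError(f"{path}: non-positive resolution {resolution}")
    # RSML convention: coordinate / resolution = value in `unit`
    scale = _UNIT_TO_CM[unit] / resolution

    roots: list[Root] = []
    counter = iter(range(10**9))
    for scene in rsml:
        if _local(scene.tag) != "scene":
            continue
        for plant in scene:
            if _local(plant.tag) != "plant":
                continue
            for root_el in plant:
                if _local(root_el.tag) == "root":
                    _walk_root(
                        root_el, 0, None, scale, flip_z, default_diameter,
                        counter, roots,
                    )
    rsa = RootSystem(roots=roots, label=label, unit="cm")
    rsa.validate()
    return rsa


# ---------------------------------------------------------------------------
# RSML writing
# ---------------------------------------------------------------------------

def write_rsml(rsa: RootSystem, path: str | Path) -> None:
    """Write a root system as RSML (per-node diameter sample functions).

    Laterals are nested under their parents; the metadata block records
    the unit (cm) and a software tag.  The system is validated before any
    bytes are written.
    """
    rsa.validate()
    rsml = etree.Element("rsml")
    metadata = etree.SubElement(rsml, "metadata")
    etree.SubElement(metadata, "version").text = "1"
    etree.SubElement(metadata, "unit").text = "cm"
    etree.SubElement(metadata, "resolution").text = "1"
    etree.SubElement(metadata, "software").text = "rsaeval"
    if rsa.label:
        etree.SubElement(metadata, "label").text = rsa.label
    scene = etree.SubElement(rsml, "scene")
    plant = etree.SubElement(scene, "plant", id="1", label=rsa.label or "plant")

    elements: dict[str, etree._Element] = {}

    def emit(root: Root, parent_el: etree._Element) -> None:
        el = etree.SubElement(parent_el, "root", ID=root.root_id)
        elements[root.root_id] = el
        props = etree.SubElement(el, "properties")
        if root.parent_attachment is not None:
            etree.SubElement(
                props,
                "property",
                name="insertion_position",
                value=repr(float(root.parent_attachment)),
            )
        geometry = etree.SubElement(el, "geometry")
        polyline = etree.SubElement(geometry, "polyline")
        for node in root.nodes:
            x, y, z = node.position
            etree.SubElement(
                polyline, "point", x=repr(float(x)), y=repr(float(y)), z=repr(float(z))
            )
        functions = etree.SubElement(el, "functions")
        fn = etree.SubElement(
            functions, "function", name="diameter", domain="polyline"
        )
        for node in root.nodes:
            etree.SubElement(fn, "sample", value=repr(float(node.diameter)))

    # topological emission: parents before children
    remaining = list(rsa.roots)
    emitted: set[str] = set()
    while remaining:
        progressed = False
        for root in list(remaining):
            if root.parent_root_id is None:
                emit(root, plant)
            elif root.parent_root_id in emitted:
                emit(root, elements[root.parent_root_id])
            else:
                continue
            emitted.add(root.root_id)
            remaining.remove(root)
            progressed = True
        if not progressed:  # pragma: no cover - validate() rules this out
            raise RSAValidationError("unresolvable parent ordering")

    Path(path).write_bytes(
        etree.tostring(
            rsml, pretty_print=True, xml_declaration=True, encoding="UTF-8"
        )
    )


def copy_system(rsa: RootSystem) -> RootSystem:
    """Deep, independent copy of a root system."""
    return RootSystem(
        roots=[
            replace(r, nodes=list(r.nodes))
            for r in rsa.roots
        ],
        label=rsa.label,
        unit=rsa.unit,
    )
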