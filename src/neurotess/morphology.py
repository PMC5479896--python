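"""Neuron morphological tracings: SWC reading/writing, validation, synthesis.

A morphological tracing is a rooted tree of points, each carrying a 3D
position (micrometres), a radius (micrometres) and a structure type.  The
de-facto interchange format is SWC: seven whitespace-separated columns
``id type x y z radius parent`` with ``#`` comment lines.  The soma may be
encoded either as a single point (centre + mean radius) or as a ring/contour
of several type-1 points; both dialects are normalised here into a
:class:`SomaDescriptor` while the raw soma points are preserved for lossless
round-trips.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

SOMA_TYPE = 1

__all__ = [
    "TracingPoint",
    "SomaDescriptor",
    "MorphologyTracing",
    "SynthesisParams",
    "ValidationReport",
    "SWCError",
    "SWCParseError",
    "SWCStructureError",
    "SWCValidationError",
    "read_swc",
    "parse_swc_text",
    "write_swc",
    "swc_text",
    "validate",
    "generate_synthetic_morphology",
]


class SWCError(ValueError):
    """Base class for SWC reading problems."""


class SWCParseError(SWCError):
    """A line could not be parsed as an SWC record."""


class SWCStructureError(SWCError):
    """The records do not form a single rooted tree."""


class SWCValidationError(SWCError):
    """A record violates a value invariant (e.g. non-positive radius)."""


@dataclass
class TracingPoint:
    """One SWC record: a sample along the traced morphology."""

    id: int
    type_code: int
    position: np.ndarray  # (3,) float64, micrometres
    radius: float  # micrometres, > 0
    parent_id: int  # -1 for the tree root

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.radius = float(self.radius)


@dataclass
class SomaDescriptor:
    """Normalised soma: centre plus mean radius, whatever the SWC dialect.

    ``contour_points`` keeps the raw positions when the soma was encoded as a
    multi-point ring/contour; it is not used by the meshing method but is
    preserved on round-trip.
    """

    center: np.ndarray
    mean_radius: float
    contour_points: Optional[List[np.ndarray]] = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.mean_radius = float(self.mean_radius)
        if self.mean_radius <= 0:
            raise SWCValidationError("soma mean_radius must be > 0")


@dataclass
class MorphologyTracing:
    """Rooted tree of tracing points with a normalised soma descriptor.

    ``points`` maps id -> TracingPoint for the *neurite* points only; the raw
    soma points live in ``soma_points`` and are summarised by ``soma``.
    ``neurite_roots`` lists the ids of first-order neurite points (non-soma
    points whose parent is a soma point).
    """

    points: Dict[int, TracingPoint]
    soma: SomaDescriptor
    soma_points: List[TracingPoint]
    neurite_roots: List[int]
    children: Dict[int, List[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.children:
            self.children = {pid: [] for pid in self.points}
            for p in self.points.values():
                if p.parent_id in self.points:
                    self.children[p.parent_id].append(p.id)

    def n_points(self) -> int:
        return len(self.points) + len(self.soma_points)

    def n_bifurcations(self) -> int:
        return sum(1 for c in self.children.values() if len(c) >= 2)

    def subtree_ids(self, root_id: int) -> List[int]:
        """Ids in the subtree rooted at ``root_id``, depth-first, children in
        id order (deterministic)."""
        out: List[int] = []
        stack = [root_id]
        while stack:
            pid = stack.pop()
            out.append(pid)
            stack.extend(sorted(self.children.get(pid, []), reverse=True))
        return out


@dataclass
class SynthesisParams:
    """Parameters of the synthetic-morphology generator.

    Lengths and radii are micrometres.  The generator emulates the gross
    statistics of laboratory tracings: a handful of first-order neurites
    leaving a spherical soma, tortuous tapering paths, and binary branching.
    """

    n_neurites: int = 4
    mean_segment_length: float = 8.0
    branch_probability: float = 0.5
    max_depth: int = 3
    initial_radius: float = 1.2
    taper_ratio: float = 0.92
    tortuosity: float = 0.25
    seed: int = 0
    soma_radius: float = 8.0

    def validate(self) -> None:
        if self.n_neurites < 0:
            raise ValueError("n_neurites must be >= 0")
        if self.mean_segment_length <= 0:
            raise ValueError("mean_segment_length must be > 0")
        if not 0.0 <= self.branch_probability <= 1.0:
            raise ValueError("branch_probability must be in [0, 1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.initial_radius <= 0:
            raise ValueError("initial_radius must be > 0")
        if not 0.0 < self.taper_ratio <= 1.0:
            raise ValueError("taper_ratio must be in (0, 1]")
        if self.tortuosity < 0:
            raise ValueError("tortuosity must be >= 0")
        if self.soma_radius <= 0:
            raise ValueError("soma_radius must be > 0")


@dataclass
class ValidationReport:
    """Findings of :func:`validate`; empty lists mean a well-formed tracing."""

    zero_radius_ids: List[int] = field(default_factory=list)
    duplicate_position_pairs: List[tuple] = field(default_factory=list)
    out_of_tree_ids: List[int] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (
            self.zero_radius_ids
            or self.duplicate_position_pairs
            or self.out_of_tree_ids
        )


# ---------------------------------------------------------------------------
# Reading


def _parse_records(lines: Sequence[str]) -> List[TracingPoint]:
    records: List[TracingPoint] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) != 7:
            raise SWCParseError(
                f"line {lineno}: expected 7 columns, got {len(cols)}: {line!r}"
            )
        try:
            pid = int(cols[0])
            tcode = int(cols[1])
            xyz = np.array([float(cols[2]), float(cols[3]), float(cols[4])])
            radius = float(cols[5])
            parent = int(cols[6])
        except ValueError as exc:
            raise SWCParseError(f"line {lineno}: {exc}") from exc
        if pid < 1:
            raise SWCParseError(f"line {lineno}: id must be >= 1, got {pid}")
        records.append(TracingPoint(pid, tcode, xyz, radius, parent))
    return records


def _build_tracing(records: List[TracingPoint]) -> MorphologyTracing:
    if not records:
        raise SWCStructureError("no records in SWC input")
    by_id = {r.id: r for r in records}
    if len(by_id) != len(records):
        raise SWCStructureError("duplicate point ids")

    roots = [r for r in records if r.parent_id == -1]
    if len(roots) != 1:
        raise SWCStructureError(f"expected exactly one root, found {len(roots)}")
    for r in records:
        if r.parent_id != -1 and r.parent_id not in by_id:
            raise SWCStructureError(
                f"point {r.id} names missing parent {r.parent_id}"
            )
        if r.radius <= 0:
            raise SWCValidationError(f"point {r.id}: radius must be > 0")

    # cycle / connectivity check: walk up from every node
    for r in records:
        seen = set()
        cur = r
        while cur.parent_id != -1:
            if cur.id in seen:
                raise SWCStructureError(f"cycle detected at point {cur.id}")
            seen.add(cur.id)
            cur = by_id[cur.parent_id]

    soma_points = [r for r in records if r.type_code == SOMA_TYPE]
    if not soma_points:
        raise SWCStructureError("no soma (type 1) point present")
    soma = _soma_from_points(soma_points)

    soma_ids = {r.id for r in soma_points}
    neurite_points = {r.id: r for r in records if r.id not in soma_ids}
    # reparent neurite points hanging off any soma point onto the descriptor
    neurite_roots = sorted(
        r.id for r in neurite_points.values() if r.parent_id in soma_ids
    )
    for r in neurite_points.values():
        if r.parent_id not in soma_ids and r.parent_id not in neurite_points:
            raise SWCStructureError(
                f"neurite point {r.id} not reachable from a soma point"
            )

    tracing = MorphologyTracing(
        points=neurite_points,
        soma=soma,
        soma_points=soma_points,
        neurite_roots=neurite_roots,
    )
    _collapse_zero_length(tracing)
    logger.info(
        "parsed tracing: %d points, %d neurites, %d bifurcations",
        tracing.n_points(),
        len(tracing.neurite_roots),
        tracing.n_bifurcations(),
    )
    return tracing


def _soma_from_points(soma_points: List[TracingPoint]) -> SomaDescriptor:
    if len(soma_points) == 1:
        p = soma_points[0]
        logger.debug("soma dialect: single point")
        return SomaDescriptor(center=p.position, mean_radius=p.radius)
    # ring / contour dialect: centroid + mean distance from centroid
    pos = np.array([p.position for p in soma_points])
    center = pos.mean(axis=0)
    dists = np.linalg.norm(pos - center, axis=1)
    mean_r = float(dists.mean())
    if mean_r <= 0:
        # degenerate contour collapsed onto its centroid: fall back to radii
        mean_r = float(np.mean([p.radius for p in soma_points]))
    logger.debug("soma dialect: %d-point contour", len(soma_points))
    return SomaDescriptor(
        center=center,
        mean_radius=mean_r,
        contour_points=[p.position.copy() for p in soma_points],
    )


def _collapse_zero_length(tracing: MorphologyTracing) -> None:
    """Remove neurite points coincident with their parent (zero-length
    segments break orientation-vector normalisation downstream)."""
    removed = []
    changed = True
    while changed:
        changed = False
        for pid in sorted(tracing.points):
            p = tracing.points[pid]
            if p.parent_id in tracing.points:
                parent = tracing.points[p.parent_id]
                if np.array_equal(parent.position, p.position):
                    # splice p out: reattach its children to parent
                    for cid in tracing.children[pid]:
                        tracing.points[cid].parent_id = parent.id
                        tracing.children[parent.id].append(cid)
                    tracing.children[parent.id].remove(pid)
                    del tracing.points[pid]
                    del tracing.children[pid]
                    removed.append(pid)
                    changed = True
                    break
    if removed:
        warnings.warn(
            f"collapsed {len(removed)} zero-length segment(s): points {removed}",
            stacklevel=3,
        )


def parse_swc_text(text: str) -> MorphologyTracing:
    """Parse SWC records from a string."""
    return _build_tracing(_parse_records(text.splitlines()))


def read_swc(path) -> MorphologyTracing:
    """Read and validate an SWC file into a :class:`MorphologyTracing`."""
    text = Path(path).read_text()
    return parse_swc_text(text)


# ---------------------------------------------------------------------------
# Writing


def swc_text(tracing: MorphologyTracing) -> str:
    """Serialise a tracing to SWC text, renumbering ids sequentially."""
    lines = ["# generated by neurotess", "# id type x y z radius parent"]
    id_map: Dict[int, int] = {}
    next_id = 1
    rows: List[str] = []

    def fmt(pid, tcode, pos, radius, parent):
        return (
            f"{pid} {tcode} {pos[0]:.17g} {pos[1]:.17g} {pos[2]:.17g} "
            f"{radius:.17g} {parent}"
        )

    for sp in tracing.soma_points:
        id_map[sp.id] = next_id
        parent = -1 if sp.parent_id == -1 else id_map.get(sp.parent_id, -1)
        rows.append(fmt(next_id, SOMA_TYPE, sp.position, sp.radius, parent))
        next_id += 1

    for root in tracing.neurite_roots:
        for pid in tracing.subtree_ids(root):
            p = tracing.points[pid]
            id_map[pid] = next_id
            parent = id_map.get(p.parent_id, id_map[tracing.soma_points[0].id])
            rows.append(fmt(next_id, p.type_code, p.position, p.radius, parent))
            next_id += 1

    return "\n".join(lines + rows) + "\n"


def write_swc(tracing: MorphologyTracing, path) -> None:
    """Write a tracing to ``path`` in SWC format (round-trips with
    :func:`read_swc` up to id renumbering and float formatting)."""
    Path(path).write_text(swc_text(tracing))


# ---------------------------------------------------------------------------
# Validation


def validate(tracing: MorphologyTracing) -> ValidationReport:
    """Report invariant violations without raising.

    Flags non-positive radii, consecutive duplicate positions (which would
    produce zero-length direction vectors downstream) and points unreachable
    from a neurite root.
    """
    report = ValidationReport()
    for p in tracing.points.values():
        if p.radius <= 0:
            report.zero_radius_ids.append(p.id)
        if p.parent_id in tracing.points:
            parent = tracing.points[p.parent_id]
            if np.array_equal(parent.position, p.position):
                report.duplicate_position_pairs.append((parent.id, p.id))
    reachable = set()
    for root in tracing.neurite_roots:
        reachable.update(tracing.subtree_ids(root))
    for pid in tracing.points:
        if pid not in reachable:
            report.out_of_tree_ids.append(pid)
    return report


# ---------------------------------------------------------------------------
# Synthesis


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def _spiral_direction(i: int) -> np.ndarray:
    """Unit direction for neurite index ``i`` on a golden-section spiral.

    Depends only on ``i`` (not on the total neurite count), so adding a
    neurite never moves the existing ones."""
    phi = (1 + 5**0.5) / 2
    z = 1 - 2 * (((i + 0.5) / phi) % 1.0)
    theta = 2 * np.pi * i / phi
    r = np.sqrt(max(0.0, 1 - z * z))
    return np.array([r * np.cos(theta), r * np.sin(theta), z])


def _perp_pair(d: np.ndarray) -> tuple:
    axis = int(np.argmin(np.abs(d)))
    e = np.zeros(3)
    e[axis] = 1.0
    u = _unit(np.cross(d, e))
    return u, np.cross(d, u)


def generate_synthetic_morphology(params: SynthesisParams) -> MorphologyTracing:
    """Generate a seeded synthetic neuron tracing.

    Each neurite draws from its own counter-based RNG stream
    (``default_rng([seed, neurite_index])``) so adding a neurite leaves the
    existing ones unchanged.  When branching is enabled
    (``branch_probability > 0`` and ``max_depth >= 2``) at least one
    bifurcation is guaranteed: if the stochastic pass produced none, the first
    neurite is regrown with a forced branch at the end of its first section.
    """
    params.validate()
    center = np.zeros(3)
    records: List[TracingPoint] = [
        TracingPoint(1, SOMA_TYPE, center, params.soma_radius, -1)
    ]
    next_id = 2
    n_bif = 0

    def grow_neurite(idx: int, force_branch: bool) -> List[TracingPoint]:
        nonlocal next_id, n_bif
        rng = np.random.default_rng([params.seed, idx])
        d = _unit(_spiral_direction(idx) + 0.05 * rng.normal(size=3))
        tcode = 2 if idx == 0 else 3
        root_pos = center + params.soma_radius * d
        pts = [TracingPoint(next_id, tcode, root_pos, params.initial_radius, 1)]
        next_id += 1

        def section(start: TracingPoint, direction, radius, depth, forced):
            nonlocal next_id, n_bif
            prev = start
            d_cur = direction
            r = radius
            n_steps = int(rng.integers(2, 5))
            for _ in range(n_steps):
                step = params.mean_segment_length * (0.7 + 0.6 * rng.random())
                d_cur = _unit(d_cur + params.tortuosity * rng.normal(size=3))
                r = r * params.taper_ratio
                p = TracingPoint(
                    next_id, tcode, prev.position + step * d_cur, r, prev.id
                )
                next_id += 1
                pts.append(p)
                prev = p
            do_branch = depth < params.max_depth and (
                forced or rng.random() < params.branch_probability
            )
            if do_branch:
                n_bif += 1
                u, _ = _perp_pair(d_cur)
                ang = np.deg2rad(25 + 25 * rng.random())
                for sgn in (1.0, -1.0):
                    child_dir = _unit(
                        np.cos(ang) * d_cur + sgn * np.sin(ang) * u
                    )
                    section(prev, child_dir, r, depth + 1, False)

        section(pts[0], d, params.initial_radius, 1, force_branch)
        return pts

    neurite_records: List[List[TracingPoint]] = []
    for i in range(params.n_neurites):
        neurite_records.append(grow_neurite(i, False))

    need_bif = params.branch_probability > 0 and params.max_depth >= 2
    if need_bif and params.n_neurites > 0 and n_bif == 0:
        # regrow neurite 0 deterministically with a forced first branch
        first_ids = {p.id for p in neurite_records[0]}
        records_keep = [r for r in neurite_records[1:]]
        next_id = 2 + sum(len(r) for r in records_keep)
        # renumber kept neurites compactly before regrowing
        remap: Dict[int, int] = {1: 1}
        nid = 2
        renumbered: List[List[TracingPoint]] = []
        for rec in records_keep:
            out = []
            for p in rec:
                remap[p.id] = nid
                out.append(
                    TracingPoint(
                        nid, p.type_code, p.position, p.radius, remap[p.parent_id]
                    )
                )
                nid += 1
            renumbered.append(out)
        next_id = nid
        forced = grow_neurite(0, True)
        neurite_records = renumbered + [forced]
        del first_ids

    for rec in neurite_records:
        records.extend(rec)

    tracing = _build_tracing_from_records(records)
    logger.info(
        "synthesized morphology: %d points, %d neurites, %d bifurcations (seed=%d)",
        tracing.n_points(),
        len(tracing.neurite_roots),
        tracing.n_bifurcations(),
        params.seed,
    )
    return tracing


def _build_tracing_from_records(records: List[TracingPoint]) -> MorphologyTracing:
    return _build_tracing(records)
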