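"""Soma reconstruction: volumetric icosphere + static linear-elastic FEM.

The soma is reconstructed from the single (centre, mean radius) pair stored
in the tracing by deforming a sphere: a tetrahedral icosphere is built, its
surface triangles are paired into quads, the quads nearest to each neurite
insertion point are selected, and their vertices are prescribed (Dirichlet
boundary conditions) onto a square sized to the neurite's start diameter.
All remaining vertices follow from static equilibrium of linear isotropic
elasticity on linear tetrahedral elements.

Because the boundary conditions are pure displacement constraints, the
solution depends on Poisson's ratio only; Young's modulus scales the whole
stiffness matrix and cancels.  Lower Poisson's ratio lets the pulled material
swell more, which is the single shape-control knob of the method.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

__all__ = [
    "TetIcosphere",
    "ElasticParams",
    "NeuriteAnchor",
    "build_tet_icosphere",
    "pair_triangles_to_quads",
    "select_neurite_quads",
    "solve_dirichlet",
    "deform_soma",
    "poisson_sweep",
]


@dataclass
class ElasticParams:
    """Isotropic linear elasticity parameters.

    Young's modulus is nominal: under pure displacement constraints the
    equilibrium displacements are invariant to it (it scales out of the
    linear system).  Poisson's ratio controls lateral contraction and hence
    the degree of soma swelling.
    """

    poisson: float = 0.3
    young: float = 1.0

    def __post_init__(self) -> None:
        if not -1.0 < self.poisson < 0.5:
            raise ValueError("poisson must be in (-1, 0.5)")
        if self.young <= 0:
            raise ValueError("young must be > 0")


@dataclass
class NeuriteAnchor:
    """A neurite insertion site on the soma surface."""

    neurite_root_id: int
    insertion_point: np.ndarray  # first tracing point of the neurite, um
    start_radius: float  # um
    assigned_quad: Optional[int] = None

    def __post_init__(self) -> None:
        self.insertion_point = np.asarray(self.insertion_point, float).reshape(3)


@dataclass
class TetIcosphere:
    """Volumetric icosphere: surface triangulation + interior tetrahedra.

    Level 0 is the icosahedron with its 20 surface triangles coned to the
    centre vertex.  Level L >= 1 subdivides the surface L times (vertices
    projected to the sphere) and fills the interior with L concentric shells
    of the same triangulation plus the centre, connected by prisms split into
    tetrahedra with an index-based diagonal rule, so neighbouring prisms
    always agree on shared faces.
    """

    vertices: np.ndarray  # (n, 3)
    tetrahedra: np.ndarray  # (m, 4) int
    surface_triangles: np.ndarray  # (t, 3) int
    center: np.ndarray
    radius: float
    subdivision_level: int
    surface_quads: Optional[np.ndarray] = None  # (q, 4) int, after pairing
    quad_triangle_pairs: Optional[np.ndarray] = None  # (q, 2) triangle indices

    @property
    def n_surface_vertices(self) -> int:
        return int(np.unique(self.surface_triangles).size)


# ---------------------------------------------------------------------------
# Icosphere construction


def _icosahedron() -> Tuple[np.ndarray, np.ndarray]:
    phi = (1 + 5**0.5) / 2
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    v /= np.linalg.norm(v[0])
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return v, f


def _subdivide_surface(verts: np.ndarray, faces: np.ndarray):
    """One 4-to-1 midpoint subdivision with projection to the unit sphere."""
    verts = list(verts)
    cache: Dict[Tuple[int, int], int] = {}

    def midpoint(a: int, b: int) -> int:
        key = (a, b) if a < b else (b, a)
        if key not in cache:
            m = verts[a] + verts[b]
            m = m / np.linalg.norm(m)
            cache[key] = len(verts)
            verts.append(m)
        return cache[key]

    out = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        out.extend([[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]])
    return np.array(verts), np.array(out, dtype=np.int64)


def _unit_icosphere_surface(level: int):
    v, f = _icosahedron()
    for _ in range(level):
        v, f = _subdivide_surface(v, f)
    return v, f


def _prism_to_tets(bot: Sequence[int], top: Sequence[int]) -> List[List[int]]:
    """Split the triangular prism (bot0..2, top0..2, vertex i matched to
    vertex i) into 3 tetrahedra.

    Each quad side face is cut by the diagonal through its globally smallest
    vertex index, so adjacent prisms always agree on shared faces
    (index-based rule; the decomposition is normalised so the prism's global
    minimum vertex sits at a bottom corner, which makes both of its adjacent
    faces cut through it and leaves one free face decided by the same rule).
    Tetrahedron orientation is fixed afterwards by the caller.
    """
    b, t = list(bot), list(top)
    if min(t) < min(b):
        b, t = t, b  # flip prism so the global min vertex is on the bottom
    start = int(np.argmin(b))
    b = [b[(start + i) % 3] for i in range(3)]
    t = [t[(start + i) % 3] for i in range(3)]
    # faces (b0,b1,t1,t0) and (b2,b0,t0,t2) are cut through b0 (global min);
    # the far face (b1,b2,t2,t1) is cut through its own min vertex
    if min(b[1], t[2]) < min(b[2], t[1]):  # diagonal b1 - t2
        return [
            [b[0], b[1], b[2], t[2]],
            [b[0], b[1], t[2], t[1]],
            [b[0], t[1], t[2], t[0]],
        ]
    # diagonal b2 - t1
    return [
        [b[0], b[1], b[2], t[1]],
        [b[0], t[1], b[2], t[2]],
        [b[0], t[1], t[2], t[0]],
    ]


def _tet_volumes(verts: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a = verts[tets[:, 1]] - verts[tets[:, 0]]
    b = verts[tets[:, 2]] - verts[tets[:, 0]]
    c = verts[tets[:, 3]] - verts[tets[:, 0]]
    return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0


def build_tet_icosphere(
    center, radius: float, subdivision_level: int = 2
) -> TetIcosphere:
    """Build the volumetric icosphere used as the soma's FEM domain.

    Surface triangle windings are outward; every tetrahedron has positive
    signed volume.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if subdivision_level < 0:
        raise ValueError("subdivision_level must be >= 0")
    center = np.asarray(center, float).reshape(3)

    sv, sf = _unit_icosphere_surface(subdivision_level)
    n_shell = subdivision_level  # interior shells (radial layering)
    fracs = [(k + 1) / (n_shell + 1) for k in range(n_shell)]
    all_shell_fracs = [1.0] + list(reversed(fracs))  # descending radii
    verts_acc = []
    offsets = []
    for fr in all_shell_fracs:
        offsets.append(sum(len(v) for v in verts_acc))
        verts_acc.append(sv * fr)
    center_idx = sum(len(v) for v in verts_acc)
    all_verts = np.vstack(verts_acc + [np.zeros((1, 3))])

    tets: List[List[int]] = []
    for s in range(len(all_shell_fracs) - 1):
        off_out, off_in = offsets[s], offsets[s + 1]
        for tri in sf:
            bot = [off_in + int(i) for i in tri]
            top = [off_out + int(i) for i in tri]
            tets.extend(_prism_to_tets(bot, top))
    # innermost shell to centre: cone
    off_last = offsets[-1]
    for tri in sf:
        tets.append([center_idx, off_last + int(tri[0]),
                     off_last + int(tri[1]), off_last + int(tri[2])])

    tets_arr = np.array(tets, dtype=np.int64)
    vols = _tet_volumes(all_verts, tets_arr)
    flip = vols < 0
    if np.any(flip):
        tets_arr[flip, 0], tets_arr[flip, 1] = (
            tets_arr[flip, 1].copy(),
            tets_arr[flip, 0].copy(),
        )
    vols = _tet_volumes(all_verts, tets_arr)
    if np.any(vols <= 0):
        raise RuntimeError("degenerate tetrahedron in icosphere construction")

    scaled = center + radius * all_verts
    return TetIcosphere(
        vertices=scaled,
        tetrahedra=tets_arr,
        surface_triangles=sf.copy(),
        center=center.copy(),
        radius=float(radius),
        subdivision_level=subdivision_level,
    )


# ---------------------------------------------------------------------------
# Triangle -> quad pairing


def _planarity_score(verts, tri_a, tri_b) -> float:
    """Coplanarity of two adjacent triangles: dot of unit normals in [-1, 1]."""

    def n(tri):
        v = verts[tri]
        nrm = np.cross(v[1] - v[0], v[2] - v[0])
        return nrm / np.linalg.norm(nrm)

    return float(np.dot(n(tri_a), n(tri_b)))


def _merge_pair(tri_a, tri_b) -> List[int]:
    """Order the 4 distinct vertices of two edge-adjacent triangles into a
    simple quad cycle, preserving tri_a's winding.  The cycle starts on the
    shared edge so that fan-splitting the quad at its first vertex
    reproduces exactly the two source triangles (the quad is reported as
    the triangles' union)."""
    shared = [v for v in tri_a if v in tri_b]
    assert len(shared) == 2
    apex_b = [v for v in tri_b if v not in shared][0]
    a = list(tri_a)
    # rotate tri_a so the shared edge is (a[1], a[2]) — insert apex between
    for _ in range(3):
        if a[1] in shared and a[2] in shared:
            break
        a = a[1:] + a[:1]
    # cycle [a1, apex, a2, a0]: diagonal (a1, a2) = the shared edge
    return [a[1], apex_b, a[2], a[0]]


def _exhaustive_matching(adj_edges, scores, n_tris):
    """Brute-force best perfect matching (tiny inputs only)."""
    best, best_score = None, -np.inf

    def rec(remaining, chosen, total):
        nonlocal best, best_score
        if not remaining:
            if total > best_score:
                best, best_score = list(chosen), total
            return
        t = min(remaining)
        for (u, v), s in zip(adj_edges, scores):
            if t in (u, v):
                other = v if u == t else u
                if other in remaining:
                    rec(remaining - {t, other}, chosen + [(u, v)], total + s)

    rec(frozenset(range(n_tris)), [], 0.0)
    if best is None:
        raise ValueError("no perfect matching of surface triangles exists")
    return best


_PAIRING_CACHE: Dict[int, np.ndarray] = {}


def pair_triangles_to_quads(ico: TetIcosphere) -> TetIcosphere:
    """Merge adjacent surface triangles into quads via a maximum-weight
    perfect matching on the triangle dual graph, scored by coplanarity.

    For <= 24 triangles the matching is found by exhaustive search; larger
    surfaces use blossom matching.  The pairing depends only on the
    subdivision level (icosphere topology and shape are level-determined up
    to similarity), so it is cached per level.
    """
    sf = ico.surface_triangles
    n_tris = len(sf)
    if n_tris % 2 != 0:
        raise ValueError("odd number of surface triangles cannot be paired")

    if ico.subdivision_level in _PAIRING_CACHE:
        pairs = _PAIRING_CACHE[ico.subdivision_level]
    else:
        unit_v, _ = _unit_icosphere_surface(ico.subdivision_level)
        edge_to_tris: Dict[Tuple[int, int], List[int]] = {}
        for ti, tri in enumerate(sf):
            for i in range(3):
                e = tuple(sorted((int(tri[i]), int(tri[(i + 1) % 3]))))
                edge_to_tris.setdefault(e, []).append(ti)
        adj = sorted(
            tuple(sorted(ts)) for ts in edge_to_tris.values() if len(ts) == 2
        )
        scores = [
            _planarity_score(unit_v, sf[a], sf[b]) for a, b in adj
        ]
        if n_tris <= 24:
            matching = _exhaustive_matching(adj, scores, n_tris)
        else:
            g = nx.Graph()
            # weight shifted positive; deterministic tie-break by index term
            for k, ((a, b), s) in enumerate(zip(adj, scores)):
                g.add_edge(a, b, weight=2.0 + s - 1e-12 * k)
            m = nx.max_weight_matching(g, maxcardinality=True)
            matching = sorted(tuple(sorted(e)) for e in m)
            if 2 * len(matching) != n_tris:
                raise ValueError(
                    "no perfect triangle pairing found; use a different "
                    "subdivision level"
                )
        pairs = np.array(sorted(matching), dtype=np.int64)
        _PAIRING_CACHE[ico.subdivision_level] = pairs

    quads = np.array(
        [_merge_pair(list(map(int, sf[a])), list(map(int, sf[b]))) for a, b in pairs],
        dtype=np.int64,
    )
    ico.surface_quads = quads
    ico.quad_triangle_pairs = pairs.copy()
    return ico


# ---------------------------------------------------------------------------
# Anchor selection


def select_neurite_quads(
    ico: TetIcosphere, anchors: List[NeuriteAnchor]
) -> List[NeuriteAnchor]:
    """Assign each neurite a distinct surface quad by minimising the total
    angular distance between quad-centroid direction and insertion direction
    (globally optimal assignment, so near-coincident neurites never collide).
    """
    if not anchors:
        return anchors
    if ico.surface_quads is None:
        raise ValueError("call pair_triangles_to_quads first")
    quads = ico.surface_quads
    if len(anchors) > len(quads):
        raise ValueError("more neurite anchors than surface quads")

    centroids = ico.vertices[quads].mean(axis=1) - ico.center
    cdirs = centroids / np.linalg.norm(centroids, axis=1, keepdims=True)
    cost = np.empty((len(anchors), len(quads)))
    for i, anc in enumerate(anchors):
        d = anc.insertion_point - ico.center
        d = d / np.linalg.norm(d)
        cost[i] = np.arccos(np.clip(cdirs @ d, -1.0, 1.0))

    # Globally optimal assignment; re-solve with the costlier of any two
    # vertex-sharing quads forbidden, because each anchor quad's 4 vertices
    # receive Dirichlet constraints and therefore no two anchors may share a
    # corner vertex.
    quad_sets = [set(map(int, q)) for q in quads]
    work = cost.copy()
    for _ in range(8 * len(anchors) + 8):
        rows, cols = linear_sum_assignment(work)
        conflict = None
        for (i, qi), (j, qj) in itertools.combinations(zip(rows, cols), 2):
            if quad_sets[qi] & quad_sets[qj]:
                conflict = (i, qi) if work[i, qi] >= work[j, qj] else (j, qj)
                break
        if conflict is None:
            break
        work[conflict[0], conflict[1]] = 1e6
    else:
        raise ValueError("could not find vertex-disjoint anchor quads")
    for i, q in zip(rows, cols):
        anchors[i].assigned_quad = int(q)
    logger.debug(
        "anchor quads: %s", [(a.neurite_root_id, a.assigned_quad) for a in anchors]
    )
    return anchors


# ---------------------------------------------------------------------------
# FEM


def _elasticity_matrix(young: float, poisson: float) -> np.ndarray:
    e, nu = young, poisson
    lam = e * nu / ((1 + nu) * (1 - 2 * nu))
    mu = e / (2 * (1 + nu))
    d = np.zeros((6, 6))
    d[:3, :3] = lam
    d[np.diag_indices(3)] = lam + 2 * mu
    d[3:, 3:] = np.eye(3) * mu
    return d


def _assemble_stiffness(verts: np.ndarray, tets: np.ndarray, d: np.ndarray):
    """Global stiffness for linear (constant-strain) tetrahedral elements."""
    n = len(verts)
    p0, p1, p2, p3 = (verts[tets[:, i]] for i in range(4))
    # shape-function gradients: rows of the inverse Jacobian construction
    j = np.stack([p1 - p0, p2 - p0, p3 - p0], axis=2)  # (m, 3, 3) columns
    detj = np.linalg.det(j)
    vol = detj / 6.0
    jinv = np.linalg.inv(j)
    # gradients of barycentric coords 1..3 are the rows of jinv; coord 0 = -sum
    g123 = jinv  # (m, 3, 3): row k = grad of local coord k+1
    g0 = -g123.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g123], axis=1)  # (m, 4, 3)

    m = len(tets)
    b = np.zeros((m, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        b[:, 0, c] = gx
        b[:, 1, c + 1] = gy
        b[:, 2, c + 2] = gz
        b[:, 3, c] = gy
        b[:, 3, c + 1] = gx
        b[:, 4, c + 1] = gz
        b[:, 4, c + 2] = gy
        b[:, 5, c] = gz
        b[:, 5, c + 2] = gx
    ke = np.einsum("mia,ij,mjb,m->mab", b, d, b, vol)

    dof = (3 * tets[:, :, None] + np.arange(3)[None, None, :]).reshape(m, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    k = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(3 * n, 3 * n))
    return k.tocsr()


def _anchor_square(
    ico: TetIcosphere, anchor: NeuriteAnchor
) -> Tuple[np.ndarray, np.ndarray]:
    """Target positions for the 4 vertices of the anchor's assigned quad.

    The square is centred at the neurite insertion point, normal to the
    insertion direction (soma centre -> insertion point), with half-diagonal
    equal to the neurite start radius, and rotated in-plane to stay as close
    as possible to the original quad corners (minimal twist).
    """
    quad = ico.surface_quads[anchor.assigned_quad]
    d = anchor.insertion_point - ico.center
    d = d / np.linalg.norm(d)
    ex = np.zeros(3)
    ex[int(np.argmin(np.abs(d)))] = 1.0
    u = np.cross(d, ex)
    u /= np.linalg.norm(u)
    w = np.cross(d, u)
    corners = ico.vertices[quad]
    rel = corners - ico.center
    # in-plane angles of the original corners
    ang = np.arctan2(rel @ w, rel @ u)
    base = ang[0]
    # preserve the winding sense of the original quad as seen along d
    sense = 1.0 if (ang[1] - ang[0]) % (2 * np.pi) < np.pi else -1.0
    cb, sb = np.cos(base), np.sin(base)
    dir0 = cb * u + sb * w
    dir1 = sense * (-sb * u + cb * w)  # base rotated by sense * 90 degrees
    # corners built as exact antipodal pairs so the square's centroid is the
    # insertion point bit-exactly (trajectory-preservation invariant)
    dirs = np.stack([dir0, dir1, -dir0, -dir1])
    targets = anchor.insertion_point[None, :] + anchor.start_radius * dirs
    return quad, targets


def solve_dirichlet(
    ico: TetIcosphere,
    constrained_vertices: Sequence[int],
    target_positions: np.ndarray,
    elastic: ElasticParams = ElasticParams(),
) -> np.ndarray:
    """Static linear-elastic equilibrium with the given vertices prescribed
    to target positions (pure displacement boundary conditions); returns the
    deformed vertex array.  With no constraints the rest state is returned."""
    n = len(ico.vertices)
    constrained_vertices = np.asarray(constrained_vertices, dtype=np.int64)
    if constrained_vertices.size == 0:
        return ico.vertices.copy()
    target_positions = np.asarray(target_positions, float).reshape(-1, 3)

    d = _elasticity_matrix(elastic.young, elastic.poisson)
    k = _assemble_stiffness(ico.vertices, ico.tetrahedra, d)

    ndof = 3 * n
    fixed_dof = (
        3 * constrained_vertices[:, None] + np.arange(3)[None, :]
    ).reshape(-1)
    u_c = (target_positions - ico.vertices[constrained_vertices]).reshape(-1)
    free = np.setdiff1d(np.arange(ndof), fixed_dof)

    k_ff = k[free][:, free]
    k_fc = k[free][:, fixed_dof]
    u_f = spla.spsolve(k_ff.tocsc(), -(k_fc @ u_c))

    u = np.zeros(ndof)
    u[fixed_dof] = u_c
    u[free] = u_f
    return ico.vertices + u.reshape(n, 3)


def deform_soma(
    ico: TetIcosphere,
    anchors: List[NeuriteAnchor],
    elastic: ElasticParams = ElasticParams(),
):
    """Deform the icosphere by static linear FEM with the anchor quads
    prescribed onto neurite-sized squares at the insertion points.

    Returns ``(deformed_vertices, anchor_quad_map)`` where
    ``deformed_vertices`` has the same indexing as ``ico.vertices`` and
    ``anchor_quad_map`` maps neurite_root_id -> surface quad index.
    """
    if ico.surface_quads is None:
        raise ValueError("call pair_triangles_to_quads first")
    for a in anchors:
        if a.assigned_quad is None:
            raise ValueError("anchors must be assigned (select_neurite_quads)")
    assigned = [a.assigned_quad for a in anchors]
    if len(set(assigned)) != len(assigned):
        raise ValueError("anchor quads must be pairwise distinct")

    n = len(ico.vertices)
    if not anchors:
        return ico.vertices.copy(), {}

    # Dirichlet data
    fixed_idx: List[int] = []
    fixed_pos: List[np.ndarray] = []
    seen: Dict[int, np.ndarray] = {}
    for a in anchors:
        quad, targets = _anchor_square(ico, a)
        for vid, tgt in zip(quad, targets):
            vid = int(vid)
            if vid in seen:
                raise ValueError(f"vertex {vid} constrained by two anchors")
            seen[vid] = tgt
            fixed_idx.append(vid)
            fixed_pos.append(tgt)

    deformed = solve_dirichlet(ico, fixed_idx, np.array(fixed_pos), elastic)

    vols = _tet_volumes(deformed, ico.tetrahedra)
    n_inv = int(np.sum(vols <= 0))
    if n_inv:
        logger.warning("%d inverted tetrahedra after soma deformation", n_inv)

    anchor_map = {a.neurite_root_id: a.assigned_quad for a in anchors}
    return deformed, anchor_map


def poisson_sweep(
    ico: TetIcosphere,
    anchors: List[NeuriteAnchor],
    nu_values: Sequence[float],
    young: float = 1.0,
) -> List[Tuple[float, float]]:
    """Deform the soma at each Poisson's ratio and report surface volume.

    Decreasing Poisson's ratio increases soma swelling, so the reported
    volumes are expected to be non-increasing across an ascending sweep for
    a fixed nontrivial anchor set.
    """
    from .mesh_quality_io import Mesh, mesh_volume

    nus = list(nu_values)
    if nus != sorted(nus):
        raise ValueError("nu_values must be sorted ascending")
    out = []
    for nu in nus:
        deformed, _ = deform_soma(ico, anchors, ElasticParams(poisson=nu, young=young))
        mesh = Mesh(vertices=deformed, faces=[list(map(int, q)) for q in ico.surface_quads])
        out.append((float(nu), float(mesh_volume(mesh))))
    return out
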