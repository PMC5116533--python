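"""Vascular networks grown inside a fruit mesh.

The branching geometry is synthesized with a space colonization algorithm:
attractor points mark available space, nodes that sense nearby attractors
extend toward them, and attractors are consumed as the network approaches.
Vessel radii follow Murray's law r_parent^n = sum_c r_child^n with pipe
exponent n, assigned from the tips basipetally to the pedicel.  The xylem
and phloem are twin networks sharing one geometry.

Trees are stored node-wise: node 0 is the pedicel root; every other node
carries one segment to its parent with a radius.  Parents always precede
children in index order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidGeometryError, StateError
from .mesh import TetMesh


@dataclass
class SCAParams:
    """Space-colonization settings (lengths in cm)."""

    attractor_count: int = 2000
    influence_radius: float = 0.8
    kill_radius: float = 0.4
    step_length: float = 0.2
    max_iterations: int = 400
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.kill_radius < self.influence_radius:
            raise ValueError("kill_radius must be < influence_radius")
        if not self.step_length <= self.kill_radius + 1e-12:
            raise ValueError("step_length must be <= kill_radius")


@dataclass
class VascularTree:
    """Rooted, acyclic network of cylindrical vessel segments."""

    nodes: np.ndarray                      # (n, 3) positions, node 0 = root
    parents: np.ndarray                    # (n,) parent index, -1 for root
    radii: np.ndarray | None = None        # (n,) radius of segment node->parent
    kind: str = "xylem"

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.parents = np.asarray(self.parents, dtype=np.int64)
        if self.radii is not None:
            self.radii = np.asarray(self.radii, dtype=float)
        self._validate()

    def _validate(self) -> None:
        n = len(self.nodes)
        if len(self.parents) != n or self.parents[0] != -1:
            raise InvalidGeometryError("tree must have exactly one root at index 0")
        if np.any(self.parents[1:] < 0):
            raise InvalidGeometryError("forest with multiple roots not allowed")
        # acyclicity: walk each parent chain with a visited budget
        for i in range(n):
            j, steps = i, 0
            while j != -1:
                j = self.parents[j]
                steps += 1
                if steps > n:
                    raise InvalidGeometryError("cycle detected in vascular tree")

    @property
    def n_segments(self) -> int:
        return len(self.nodes) - 1

    @property
    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """(start, end) point arrays of all segments, child order 1..n-1."""
        child = np.arange(1, len(self.nodes))
        return self.nodes[self.parents[child]], self.nodes[child]

    @property
    def segment_lengths(self) -> np.ndarray:
        a, b = self.segments
        return np.linalg.norm(b - a, axis=1)

    @property
    def segment_radii(self) -> np.ndarray:
        if self.radii is None:
            raise StateError("radii not assigned; run assign_radii_murray")
        return self.radii[1:]

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(len(self.nodes))]
        for i, p in enumerate(self.parents):
            if p >= 0:
                ch[p].append(i)
        return ch

    def total_lateral_area(self) -> float:
        return float(np.sum(2.0 * np.pi * self.segment_radii * self.segment_lengths))


# ---------------------------------------------------------------------------
# Attractor sampling
# ---------------------------------------------------------------------------

def sample_attractors(
    mesh: TetMesh, tissues: set[str] | list[str], count: int, seed: int = 0
) -> np.ndarray:
    """Uniform random points inside the union of tets with the given tissue
    labels: a tet is drawn proportionally to its volume, then a point is
    placed uniformly in it via Dirichlet barycentric coordinates."""
    tissues = list(tissues)
    if not tissues:
        raise ValueError("tissue selection must be non-empty")
    if count < 1:
        raise ValueError("count must be >= 1")
    mask = mesh.tissue_mask(*tissues)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ValueError(f"no tets with tissues {tissues}")
    rng = np.random.default_rng(seed)
    p = mesh.volumes[idx] / mesh.volumes[idx].sum()
    chosen = rng.choice(idx, size=count, p=p)
    bary = rng.dirichlet(np.ones(4), size=count)
    return np.einsum("nk,nkd->nd", bary, mesh.vertices[mesh.tets[chosen]])


# ---------------------------------------------------------------------------
# Space colonization
# ---------------------------------------------------------------------------

def _resample_polyline(poly: np.ndarray, step: float) -> np.ndarray:
    """Evenly respace a polyline at roughly `step` intervals."""
    poly = np.asarray(poly, dtype=float)
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(2, int(np.ceil(total / step)) + 1)
    si = np.linspace(0.0, total, n)
    return np.column_stack([np.interp(si, s, poly[:, d]) for d in range(3)])


def grow_network(
    mesh: TetMesh,
    main_bundles: list[np.ndarray],
    attractors: np.ndarray,
    params: SCAParams,
    kind: str = "xylem",
) -> VascularTree:
    """Grow a vascular tree by space colonization, seeded by the main
    bundle polylines (the first bundle starts at the pedicel root).

    Each iteration: (1) every live attractor within ``influence_radius`` of
    the network associates with its nearest node (ties to the lower node
    index); (2) every node with associated attractors extends one segment of
    ``step_length`` along the normalized mean direction toward them;
    (3) attractors within ``kill_radius`` of any node are removed.  New
    nodes whose segment midpoint would leave the mesh are not created.
    """
    if not main_bundles:
        raise InvalidGeometryError("at least one main bundle (pedicel anchor) required")
    nodes: list[np.ndarray] = []
    parents: list[int] = []
    for b, poly in enumerate(main_bundles):
        pts = _resample_polyline(poly, params.step_length)
        mid = 0.5 * (pts[:-1] + pts[1:])
        if not mesh.contains(mid).all():
            raise InvalidGeometryError(f"main bundle {b} leaves the mesh volume")
        if b == 0:
            nodes.append(pts[0])
            parents.append(-1)
            start = 1
        else:
            # attach to the nearest existing node
            arr = np.asarray(nodes)
            parent = int(np.argmin(np.linalg.norm(arr - pts[0], axis=1)))
            nodes.append(pts[0])
            parents.append(parent)
            start = 1
        for p in pts[start:]:
            nodes.append(p)
            parents.append(len(nodes) - 2)

    live = np.ones(len(attractors), dtype=bool) if len(attractors) else np.zeros(0, bool)
    if live.any():
        d, _ = cKDTree(np.asarray(nodes)).query(attractors)
        live &= d >= params.kill_radius

    for _ in range(params.max_iterations):
        if not live.any():
            break
        arr = np.asarray(nodes)
        tree = cKDTree(arr)
        pts = attractors[live]
        dist, nearest = tree.query(pts)
        assoc = dist <= params.influence_radius
        if not assoc.any():
            break
        # mean normalized direction per node
        dirs = pts[assoc] - arr[nearest[assoc]]
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        order = np.argsort(nearest[assoc], kind="stable")
        node_ids, starts = np.unique(nearest[assoc][order], return_index=True)
        assoc_idx = np.flatnonzero(live)[assoc]  # attractor index per assoc row
        grew = False
        drop: list[np.ndarray] = []
        for ni, st, en in zip(
            node_ids, starts, np.append(starts[1:], assoc.sum())
        ):
            group = order[st:en]
            mean_dir = dirs[group].sum(axis=0)
            norm = np.linalg.norm(mean_dir)
            if norm < 1e-12:
                drop.append(assoc_idx[group])
                continue
            new = arr[ni] + params.step_length * mean_dir / norm
            # a stalled node (leaving the mesh, or stepping onto an existing
            # node) would oscillate forever: discard its attractors instead
            if not mesh.contains(0.5 * (arr[ni] + new))[0]:
                drop.append(assoc_idx[group])
                continue
            d_near, _ = tree.query(new)
            if d_near < 0.45 * params.step_length:
                drop.append(assoc_idx[group])
                continue
            nodes.append(new)
            parents.append(int(ni))
            grew = True
        for idx in drop:
            live[idx] = False
        # kill attractors close to the (extended) network
        arr = np.asarray(nodes)
        d, _ = cKDTree(arr).query(attractors[live])
        kill = d < params.kill_radius
        alive_idx = np.flatnonzero(live)
        live[alive_idx[kill]] = False
        if not grew and not kill.any():
            break

    return VascularTree(
        nodes=np.asarray(nodes), parents=np.asarray(parents, dtype=np.int64), kind=kind
    )


# ---------------------------------------------------------------------------
# Murray's law radii
# ---------------------------------------------------------------------------

def assign_radii_murray(
    tree: VascularTree,
    n: float,
    tip_radius: float = 0.01,
    pedicel_radius: float | None = None,
) -> VascularTree:
    """Assign radii by Murray's law with pipe exponent n.

    Tips get ``tip_radius``; each junction satisfies
    r_parent = (sum_children r_child^n)^(1/n); pass-through nodes copy the
    child radius.  If ``pedicel_radius`` is given, all radii are rescaled by
    one global factor so the root segment radius matches it.
    """
    if n <= 0:
        raise ValueError("pipe exponent n must be > 0")
    nnodes = len(tree.nodes)
    n_children = np.zeros(nnodes, dtype=np.int64)
    for p in tree.parents[1:]:
        n_children[p] += 1
    r = np.zeros(nnodes)
    acc = np.zeros(nnodes)  # running sum of child r^n
    # children have larger indices than parents, so one reverse sweep works
    for i in range(nnodes - 1, 0, -1):
        if n_children[i] == 0:
            r[i] = tip_radius
        elif n_children[i] == 1:
            r[i] = acc[i] ** (1.0 / n)  # pass-through: equals the child radius
        else:
            r[i] = acc[i] ** (1.0 / n)
        acc[tree.parents[i]] += r[i] ** n
    r[0] = acc[0] ** (1.0 / n) if n_children[0] > 0 else tip_radius
    if pedicel_radius is not None:
        r *= pedicel_radius / r[0]
    tree.radii = r
    return tree


# ---------------------------------------------------------------------------
# Contact areas
# ---------------------------------------------------------------------------

@dataclass
class ContactAreaMap:
    """Per-tet lateral vessel areas A_i^x, A_i^p (cm^2) and the fixed initial
    area ratios a_i^v = A_i^v(0) / A_i(0)."""

    A_x: np.ndarray
    A_p: np.ndarray
    a_x: np.ndarray = field(default=None)
    a_p: np.ndarray = field(default=None)

    @classmethod
    def from_areas(cls, A_x, A_p, total_area) -> "ContactAreaMap":
        total = np.maximum(np.asarray(total_area, dtype=float), 1e-300)
        return cls(
            A_x=np.asarray(A_x, float),
            A_p=np.asarray(A_p, float),
            a_x=np.asarray(A_x, float) / total,
            a_p=np.asarray(A_p, float) / total,
        )


def contact_areas(tree: VascularTree, mesh: TetMesh, phloem_scale: float = 1.0) -> ContactAreaMap:
    """Lateral vessel surface area per tetrahedron by exact convex clipping
    of each cylindrical segment's axis against the tet's four half-spaces:
    the contribution of a segment to a tet is 2*pi*r times the clipped
    length.  Xylem and phloem twins share the geometry (A_p = phloem_scale * A_x).
    """
    if tree.radii is None:
        raise StateError("radii not assigned; run assign_radii_murray first")
    mesh._require_geometry()
    p0, p1 = tree.segments
    radii = tree.segment_radii
    A = np.zeros(mesh.n_tets)

    verts = mesh.vertices[mesh.tets]  # (n_t, 4, 3)
    # inward-oriented face planes: face k opposite local vertex k
    opp = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
    normals = np.empty((mesh.n_tets, 4, 3))
    offsets = np.empty((mesh.n_tets, 4))
    for k, idx in enumerate(opp):
        a, b, c = verts[:, idx[0]], verts[:, idx[1]], verts[:, idx[2]]
        nrm = np.cross(b - a, c - a)
        apex = verts[:, k]
        sgn = np.sign(np.einsum("ij,ij->i", nrm, apex - a))
        nrm *= sgn[:, None]
        normals[:, k] = nrm
        offsets[:, k] = np.einsum("ij,ij->i", nrm, a)

    lo = verts.min(axis=1)
    hi = verts.max(axis=1)
    slo = np.minimum(p0, p1)
    shi = np.maximum(p0, p1)
    for s in range(len(p0)):
        cand = np.flatnonzero(
            np.all(hi >= slo[s] - 1e-12, axis=1) & np.all(lo <= shi[s] + 1e-12, axis=1)
        )
        if len(cand) == 0:
            continue
        d0 = np.einsum("tkd,d->tk", normals[cand], p0[s]) - offsets[cand]
        d1 = np.einsum("tkd,d->tk", normals[cand], p1[s]) - offsets[cand]
        dd = d1 - d0
        with np.errstate(divide="ignore", invalid="ignore"):
            t_cross = -d0 / dd
        t_lo = np.zeros(len(cand))
        t_hi = np.ones(len(cand))
        entering = dd > 0
        leaving = dd < 0
        t_lo = np.maximum(t_lo, np.where(entering, t_cross, 0.0).max(axis=1))
        t_hi = np.minimum(t_hi, np.where(leaving, t_cross, 1.0).min(axis=1))
        outside = ((dd == 0) & (d0 < 0)).any(axis=1)
        frac = np.clip(t_hi - t_lo, 0.0, None)
        frac[outside] = 0.0
        seg_len = np.linalg.norm(p1[s] - p0[s])
        np.add.at(A, cand, 2.0 * np.pi * radii[s] * frac * seg_len)

    return ContactAreaMap.from_areas(A, phloem_scale * A, mesh.total_area)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_tree(tree: VascularTree, path) -> None:
    data = {
        "kind": tree.kind,
        "nodes": tree.nodes.tolist(),
        "parents": tree.parents.tolist(),
        "radii": None if tree.radii is None else tree.radii.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(data, fh)


def read_tree(path) -> VascularTree:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise InvalidGeometryError(f"malformed tree file: {exc}") from exc
    return VascularTree(
        nodes=np.asarray(data["nodes"], dtype=float),
        parents=np.asarray(data["parents"], dtype=np.int64),
        radii=None if data.get("radii") is None else np.asarray(data["radii"], float),
        kind=data.get("kind", "xylem"),
    )
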