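"""Labeled tetrahedral fruit meshes built from 2D profile curves.

A fruit is described by an outer profile and zero or more nested inner
profiles drawn in the (radial, axial) half-plane; each profile is the
generatrix of a surface of revolution about the fruit axis (z, pedicel at
z_min).  Meshes are generated by tetrahedralizing a structured point cloud
in the unit ball and radially mapping it onto the swept outer profile,
which yields a conforming mesh without any external geometry dependency.

All lengths are centimetres, areas cm^2, volumes cm^3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import Polygon
from shapely import contains_xy

from .errors import InvalidGeometryError, StateError, UnsupportedCellError

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


# ---------------------------------------------------------------------------
# Profile specification
# ---------------------------------------------------------------------------

@dataclass
class ProfileSpec:
    """Parametric description of a fruit: outer skin plus nested tissue
    boundaries, as polylines of (radial, axial) points in cm.

    ``tissue_labels`` is ordered outermost first (skin-adjacent tissue),
    so ``len(tissue_labels) == 1 + len(inner_profiles)``.
    """

    outer_profile: np.ndarray
    inner_profiles: list[np.ndarray] = field(default_factory=list)
    tissue_labels: list[str] = field(default_factory=lambda: ["flesh"])

    def __post_init__(self) -> None:
        self.outer_profile = np.asarray(self.outer_profile, dtype=float)
        self.inner_profiles = [np.asarray(p, dtype=float) for p in self.inner_profiles]
        if len(self.tissue_labels) != 1 + len(self.inner_profiles):
            raise InvalidGeometryError(
                "need one tissue label per region: "
                f"{len(self.inner_profiles)} inner profiles require "
                f"{1 + len(self.inner_profiles)} labels"
            )
        for prof in [self.outer_profile, *self.inner_profiles]:
            if prof.ndim != 2 or prof.shape[1] != 2 or prof.shape[0] < 3:
                raise InvalidGeometryError("profiles need >= 3 (radial, axial) points")
            if np.any(prof[:, 0] < -1e-12):
                raise InvalidGeometryError("radial coordinates must be >= 0")
        polys = [_profile_polygon(p) for p in [self.outer_profile, *self.inner_profiles]]
        for prof, poly in zip([self.outer_profile, *self.inner_profiles], polys):
            if not poly.is_valid or poly.area <= 1e-12:
                raise InvalidGeometryError("profile is self-intersecting or degenerate")
        scale = max(self.outer_profile.max(), 1.0)
        for outer, inner in zip(polys[:-1], polys[1:]):
            # tolerant nesting test: profiles legitimately meet at the axis
            if not outer.buffer(1e-9 * scale).covers(inner):
                raise InvalidGeometryError("inner profiles must be strictly nested")

    @property
    def z_extent(self) -> tuple[float, float]:
        z = self.outer_profile[:, 1]
        return float(z.min()), float(z.max())

    @property
    def swept_volume(self) -> float:
        """Volume of the solid of revolution of the outer profile (Pappus)."""
        poly = _profile_polygon(self.outer_profile)
        return 2.0 * np.pi * poly.area * poly.centroid.x


def _profile_polygon(profile: np.ndarray) -> Polygon:
    """Close a (radial, axial) polyline into a polygon against the axis."""
    pts = [tuple(p) for p in profile]
    r0, z0 = profile[0]
    r1, z1 = profile[-1]
    closing = []
    if r1 > 1e-12:
        closing.append((0.0, z1))
    if r0 > 1e-12:
        closing.append((0.0, z0))
    return Polygon(pts + closing)


def _radius_function(profile: np.ndarray, n_angles: int = 1024):
    """Tabulate the swept-surface distance R(phi) from the profile's axial
    midpoint, phi being the polar angle from +z; returns (phi_grid, R)."""
    zmin, zmax = profile[:, 1].min(), profile[:, 1].max()
    zc = 0.5 * (zmin + zmax)
    phis = np.linspace(0.0, np.pi, n_angles)
    seg_a = profile[:-1]
    seg_b = profile[1:]
    radii = np.empty(n_angles)
    for k, phi in enumerate(phis):
        d = np.array([np.sin(phi), np.cos(phi)])  # (rho, z) direction
        # ray (0, zc) + t*d against each profile segment
        e = seg_b - seg_a
        w = seg_a - np.array([0.0, zc])
        denom = d[0] * e[:, 1] - d[1] * e[:, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            s = (d[1] * w[:, 0] - d[0] * w[:, 1]) / denom
            t = (w[:, 0] * e[:, 1] - w[:, 1] * e[:, 0]) / denom
        ok = np.isfinite(s) & np.isfinite(t) & (s >= -1e-9) & (s <= 1 + 1e-9) & (t > 1e-12)
        if np.any(ok):
            radii[k] = t[ok].min()
        else:  # ray along the axis grazing an endpoint
            ends = np.vstack([profile[0], profile[-1]]) - np.array([0.0, zc])
            proj = ends @ d
            radii[k] = max(proj.max(), 1e-9)
    return phis, radii, zc


# ---------------------------------------------------------------------------
# Tetrahedral mesh
# ---------------------------------------------------------------------------

@dataclass
class TetMesh:
    """Conforming labeled tetrahedral mesh with cached geometric quantities.

    Geometry caches (filled by :func:`compute_geometry`):

    - ``volumes``        per-tet volume v_i (cm^3)
    - ``face_areas``     (n_tets, 4) area of the k-th face of tet i (cm^2)
    - ``face_neighbor``  (n_tets, 4) adjacent tet across face k, -1 on the
      boundary
    - ``pairs`` / ``pair_faces``  unique adjacent pairs (i, j) with the local
      face index of the shared face in each tet
    - ``ext_area``       external (boundary) area A_i^ext per tet (cm^2)
    """

    vertices: np.ndarray
    tets: np.ndarray
    tissue: np.ndarray
    tissue_names: list[str]

    volumes: np.ndarray | None = None
    face_areas: np.ndarray | None = None
    face_neighbor: np.ndarray | None = None
    pairs: np.ndarray | None = None
    pair_faces: np.ndarray | None = None
    ext_area: np.ndarray | None = None
    _centroid_tree: cKDTree | None = None

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    @property
    def centroids(self) -> np.ndarray:
        return self.vertices[self.tets].mean(axis=1)

    @property
    def total_area(self) -> np.ndarray:
        """A_i = sum_k A_i^k, the total surface area of each tet."""
        self._require_geometry()
        return self.face_areas.sum(axis=1)

    def tissue_mask(self, *names: str) -> np.ndarray:
        idx = [self.tissue_names.index(n) for n in names]
        return np.isin(self.tissue, idx)

    def neighbors(self, i: int) -> np.ndarray:
        """N(i): indices of tets sharing a face with tet i."""
        self._require_geometry()
        nb = self.face_neighbor[i]
        return nb[nb >= 0]

    def shared_area(self, i: int, j: int) -> float:
        """A_ij, the area of the face shared by adjacent tets i and j."""
        self._require_geometry()
        for k in range(4):
            if self.face_neighbor[i, k] == j:
                return float(self.face_areas[i, k])
        return 0.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized point-in-mesh test via barycentric checks against
        nearby tets (nearest-centroid candidates)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self._centroid_tree is None:
            self._centroid_tree = cKDTree(self.centroids)
        k = min(32, self.n_tets)
        _, cand = self._centroid_tree.query(points, k=k)
        cand = np.atleast_2d(cand)
        inside = np.zeros(len(points), dtype=bool)
        verts = self.vertices
        for col in range(cand.shape[1]):
            todo = ~inside
            if not todo.any():
                break
            tet_idx = cand[todo, col]
            tet_v = verts[self.tets[tet_idx]]
            inside[todo] |= _in_tet(points[todo], tet_v)
        return inside

    def _require_geometry(self) -> None:
        if self.volumes is None:
            raise StateError("geometry caches not computed; call compute_geometry")

    def copy(self) -> "TetMesh":
        return TetMesh(
            vertices=self.vertices.copy(),
            tets=self.tets.copy(),
            tissue=self.tissue.copy(),
            tissue_names=list(self.tissue_names),
            volumes=None if self.volumes is None else self.volumes.copy(),
            face_areas=None if self.face_areas is None else self.face_areas.copy(),
            face_neighbor=None if self.face_neighbor is None else self.face_neighbor.copy(),
            pairs=None if self.pairs is None else self.pairs.copy(),
            pair_faces=None if self.pair_faces is None else self.pair_faces.copy(),
            ext_area=None if self.ext_area is None else self.ext_area.copy(),
        )


def _in_tet(points: np.ndarray, tet_verts: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """points (m,3), tet_verts (m,4,3) -> bool (m,)."""
    a = tet_verts[:, 0]
    T = np.stack([tet_verts[:, 1] - a, tet_verts[:, 2] - a, tet_verts[:, 3] - a], axis=-1)
    rhs = points - a
    det = np.linalg.det(T)
    ok = np.abs(det) > 1e-300
    bary = np.zeros((len(points), 3))
    if ok.any():
        bary[ok] = np.linalg.solve(T[ok], rhs[ok][..., None])[..., 0]
    s = bary.sum(axis=1)
    return ok & (bary >= -tol).all(axis=1) & (s <= 1 + tol)


# ---------------------------------------------------------------------------
# Mesh construction
# ---------------------------------------------------------------------------

def _ball_points(n_points: int, seed: int = 12345) -> np.ndarray:
    """Structured point cloud in the unit ball: a centre point plus
    concentric Fibonacci-sphere shells with counts scaling as r^2."""
    n_shells = max(2, int(round((n_points / 4.2) ** (1.0 / 3.0) * 1.9)))
    radii = (np.arange(1, n_shells + 1)) / n_shells
    weights = radii**2
    counts = np.maximum(4, np.round(weights / weights.sum() * (n_points - 1)).astype(int))
    rng = np.random.default_rng(seed)
    pts = [np.zeros((1, 3))]
    for s, (r, c) in enumerate(zip(radii, counts)):
        i = np.arange(c, dtype=float)
        z = 1.0 - 2.0 * (i + 0.5) / c
        rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
        theta = _GOLDEN_ANGLE * i + 2.399963 * s  # de-phase successive shells
        shell = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z]) * r
        if s >= n_shells - 2 and c >= 12:
            # pole caps subtend a small solid angle but hold the fruit's
            # extremities (pedicel scar, stylar tip): refine them so slender
            # profile features survive the radial mapping
            n_cap = max(4, c // 12)
            j = np.arange(n_cap, dtype=float)
            zc_ = 1.0 - 0.08 * (j + 0.5) / n_cap
            rho_c = np.sqrt(np.clip(1.0 - zc_**2, 0.0, None))
            th = _GOLDEN_ANGLE * j + 0.7 * s
            cap_hi = np.column_stack([rho_c * np.cos(th), rho_c * np.sin(th), zc_]) * r
            cap_lo = cap_hi * np.array([1.0, -1.0, -1.0])
            shell = np.vstack([shell, cap_hi, cap_lo])
        if s < n_shells - 1:  # jitter interior shells to avoid degeneracies
            shell = shell + rng.normal(scale=2e-3 * r, size=shell.shape)
        pts.append(shell)
    return np.vstack(pts)


def _signed_volumes(vertices: np.ndarray, tets: np.ndarray) -> np.ndarray:
    v = vertices[tets]
    return np.einsum(
        "ij,ij->i", v[:, 1] - v[:, 0], np.cross(v[:, 2] - v[:, 0], v[:, 3] - v[:, 0])
    ) / 6.0


def build_mesh(spec: ProfileSpec, resolution: int = 500) -> TetMesh:
    """Build a conforming labeled tet mesh approximating the swept profile.

    ``resolution`` is a target tetrahedron count; the generated count is
    within about +-30% of it.  Tissue labels are assigned by a centroid
    containment test against the swept inner surfaces (innermost wins).
    """
    if resolution < 50:
        raise ValueError("resolution must be >= 50")
    phis, radii, zc = _radius_function(spec.outer_profile)

    n_pts = max(30, int(resolution / 5.7))
    mesh = None
    for _ in range(4):
        mesh = _build_from_points(_ball_points(n_pts), phis, radii, zc, spec)
        if abs(mesh.n_tets - resolution) <= 0.25 * resolution:
            break
        n_pts = max(30, int(n_pts * resolution / mesh.n_tets))
    compute_geometry(mesh)
    # the faceted boundary is inscribed in the smooth swept surface, so the
    # discrete solid under-fills it; calibrate by a uniform dilation about
    # the profile centre so the mesh volume matches the Pappus volume
    gamma = (spec.swept_volume / mesh.volumes.sum()) ** (1.0 / 3.0)
    centre = np.array([0.0, 0.0, zc])
    mesh.vertices = centre + gamma * (mesh.vertices - centre)
    compute_geometry(mesh)
    return mesh


def _build_from_points(ball, phis, radii, zc, spec: ProfileSpec) -> TetMesh:
    tri = Delaunay(ball)
    tets = tri.simplices.copy()
    r = np.linalg.norm(ball, axis=1)
    with np.errstate(invalid="ignore"):
        phi = np.arccos(np.clip(np.where(r > 0, ball[:, 2] / np.maximum(r, 1e-300), 1.0), -1, 1))
    R = np.interp(phi, phis, radii)
    verts = ball * (R[:, None])
    verts[:, 2] += zc
    sv = _signed_volumes(verts, tets)
    flip = sv < 0
    tets[flip] = tets[flip][:, [0, 1, 3, 2]]
    sv = np.abs(sv)
    keep = sv > 1e-12 * np.median(sv)
    tets = tets[keep]

    # tissue labels by centroid containment, innermost containing profile wins
    cent = verts[tets].mean(axis=1)
    rho = np.hypot(cent[:, 0], cent[:, 1])
    tissue = np.zeros(len(tets), dtype=np.int32)
    for k, prof in enumerate(spec.inner_profiles):
        poly = _profile_polygon(prof)
        inside = contains_xy(poly, rho, cent[:, 2]) | contains_xy(
            poly.boundary.buffer(1e-12), rho, cent[:, 2]
        )
        tissue[inside] = k + 1
    return TetMesh(
        vertices=verts, tets=tets, tissue=tissue, tissue_names=list(spec.tissue_labels)
    )


# ---------------------------------------------------------------------------
# Geometry caches
# ---------------------------------------------------------------------------

def compute_geometry(mesh: TetMesh) -> TetMesh:
    """Fill the per-tet volume, face-area, adjacency, and boundary caches.

    Raises InvalidGeometryError on inverted or non-conforming elements.
    """
    sv = _signed_volumes(mesh.vertices, mesh.tets)
    flip = sv < 0
    if flip.any():
        mesh.tets[flip] = mesh.tets[flip][:, [0, 1, 3, 2]]
        sv = np.abs(sv)
    if np.any(sv <= 0):
        raise InvalidGeometryError(
            f"{int(np.sum(sv <= 0))} degenerate/inverted tetrahedra"
        )
    mesh.volumes = sv

    # face k of a tet is the face opposite local vertex k
    n_t = mesh.n_tets
    opp = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
    faces = np.stack([mesh.tets[:, idx] for idx in opp], axis=1)  # (n_t, 4, 3)
    v = mesh.vertices[faces]  # (n_t, 4, 3, 3)
    cross = np.cross(v[:, :, 1] - v[:, :, 0], v[:, :, 2] - v[:, :, 0])
    mesh.face_areas = 0.5 * np.linalg.norm(cross, axis=-1)

    key = np.sort(faces.reshape(-1, 3), axis=1)
    order = np.lexsort(key.T[::-1])
    sk = key[order]
    same = np.all(sk[1:] == sk[:-1], axis=1)
    # each sorted face key appears once (boundary) or twice (internal)
    runs = np.flatnonzero(same)
    if np.any(same[1:] & same[:-1]):
        raise InvalidGeometryError("non-conforming mesh: a face is shared by >2 tets")
    face_neighbor = np.full((n_t, 4), -1, dtype=np.int64)
    flat_tet = order // 4
    flat_k = order % 4
    i1, k1 = flat_tet[runs], flat_k[runs]
    i2, k2 = flat_tet[runs + 1], flat_k[runs + 1]
    face_neighbor[i1, k1] = i2
    face_neighbor[i2, k2] = i1
    mesh.face_neighbor = face_neighbor
    mesh.pairs = np.column_stack([i1, i2])
    mesh.pair_faces = np.column_stack([k1, k2])
    ext_mask = face_neighbor < 0
    mesh.ext_area = np.where(ext_mask, mesh.face_areas, 0.0).sum(axis=1)
    mesh._centroid_tree = None
    return mesh


def boundary_volume(mesh: TetMesh) -> float:
    """Volume enclosed by the boundary surface via the divergence theorem
    (independent oracle for sum(v_i))."""
    opp = [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
    total = 0.0
    for k, idx in enumerate(opp):
        b = mesh.face_neighbor[:, k] < 0
        if not b.any():
            continue
        tri = mesh.tets[b][:, idx]
        p = mesh.vertices[tri]
        total += np.einsum("ij,ij->", p[:, 0], np.cross(p[:, 1], p[:, 2])) / 6.0
    return abs(total)


# ---------------------------------------------------------------------------
# Region partitions
# ---------------------------------------------------------------------------

@dataclass
class RegionPartition:
    """Per-tet bin indices for the summary partitions of the fruit."""

    transversal_layer: np.ndarray | None = None
    angular_sector: np.ndarray | None = None
    region64: np.ndarray | None = None


def partition_regions(
    mesh: TetMesh,
    n_layers: int = 10,
    n_sectors: int = 40,
    scheme: str = "layers",
) -> RegionPartition:
    """Bin tets by centroid into axial slabs and azimuthal sectors, or into
    the 64-region scheme (4 axial quarters x 8 azimuthal eighths x
    inner/outer radial half between the innermost-tissue surface and skin).
    """
    if n_layers < 1 or n_sectors < 1:
        raise ValueError("n_layers and n_sectors must be >= 1")
    mesh._require_geometry()
    cent = mesh.centroids
    z = cent[:, 2]
    zlo, zhi = mesh.vertices[:, 2].min(), mesh.vertices[:, 2].max()
    azim = np.mod(np.arctan2(cent[:, 1], cent[:, 0]), 2 * np.pi)

    part = RegionPartition()
    if scheme == "layers":
        part.transversal_layer = _bin(z, zlo, zhi, n_layers)
        part.angular_sector = _bin(azim, 0.0, 2 * np.pi, n_sectors)
    elif scheme == "region64":
        quarter = _bin(z, zlo, zhi, 4)
        eighth = _bin(azim, 0.0, 2 * np.pi, 8)
        radial = _radial_half(mesh, cent)
        part.region64 = (quarter * 16 + eighth * 2 + radial).astype(np.int64)
    else:
        raise ValueError(f"unknown partition scheme {scheme!r}")
    return part


def _bin(x, lo, hi, n):
    f = (x - lo) / max(hi - lo, 1e-300)
    return np.clip((f * n).astype(np.int64), 0, n - 1)


def _radial_half(mesh: TetMesh, cent: np.ndarray, n_phi: int = 24) -> np.ndarray:
    """0 = inner, 1 = outer, split at the mid radial distance between the
    innermost tissue surface (e.g., the stone) and the skin, estimated
    per polar-angle bin from the mesh itself."""
    zlo, zhi = mesh.vertices[:, 2].min(), mesh.vertices[:, 2].max()
    zc = 0.5 * (zlo + zhi)
    centre = np.array([0.0, 0.0, zc])
    d = cent - centre
    dist = np.linalg.norm(d, axis=1)
    phi = np.arccos(np.clip(d[:, 2] / np.maximum(dist, 1e-300), -1, 1))
    bins = np.clip((phi / np.pi * n_phi).astype(int), 0, n_phi - 1)

    bverts = np.unique(mesh.tets[mesh.ext_area > 0])
    dv = mesh.vertices[bverts] - centre
    distv = np.linalg.norm(dv, axis=1)
    phiv = np.arccos(np.clip(dv[:, 2] / np.maximum(distv, 1e-300), -1, 1))
    binsv = np.clip((phiv / np.pi * n_phi).astype(int), 0, n_phi - 1)
    r_out = np.full(n_phi, distv.max())
    for b in range(n_phi):
        m = binsv == b
        if m.any():
            r_out[b] = distv[m].max()

    inner_idx = len(mesh.tissue_names) - 1
    r_in = np.zeros(n_phi)
    if inner_idx > 0:
        m_in = mesh.tissue == inner_idx
        if m_in.any():
            di = dist[m_in]
            bi = bins[m_in]
            for b in range(n_phi):
                m = bi == b
                if m.any():
                    r_in[b] = di[m].max()
    split = 0.5 * (r_in[bins] + r_out[bins])
    return (dist > split).astype(np.int64)


# ---------------------------------------------------------------------------
# VTK legacy unstructured-grid I/O (ASCII)
# ---------------------------------------------------------------------------

def write_mesh(mesh: TetMesh, path, fields: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh as a VTK legacy ASCII unstructured grid with an
    integer cell-data array ``tissue`` plus any extra per-tet scalars."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 4.2\n")
        fh.write("carposim tissues:" + ",".join(mesh.tissue_names) + "\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(mesh.vertices)} double\n")
        np.savetxt(fh, mesh.vertices, fmt="%.10g")
        n_t = mesh.n_tets
        fh.write(f"CELLS {n_t} {5 * n_t}\n")
        np.savetxt(
            fh,
            np.column_stack([np.full(n_t, 4, dtype=np.int64), mesh.tets]),
            fmt="%d",
        )
        fh.write(f"CELL_TYPES {n_t}\n")
        fh.write("\n".join(["10"] * n_t) + "\n")
        fh.write(f"CELL_DATA {n_t}\n")
        fh.write("SCALARS tissue int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(t)) for t in mesh.tissue) + "\n")
        for name, arr in (fields or {}).items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, np.asarray(arr, dtype=float), fmt="%.10g")


def read_mesh(path) -> TetMesh:
    """Read a VTK legacy ASCII unstructured grid of linear tetrahedra.

    A missing ``tissue`` cell-data array defaults to a single tissue with a
    warning; non-tet cell types raise UnsupportedCellError.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    tissue_names = ["flesh"]
    if len(lines) > 1 and "tissues:" in lines[1]:
        tissue_names = lines[1].split("tissues:", 1)[1].split(",")
        tissue_names = [t.strip() for t in tissue_names if t.strip()]
    tok = iter(_tokens(lines))

    def until(word):
        for t in tok:
            if t.upper() == word:
                return True
        return False

    if not until("POINTS"):
        raise InvalidGeometryError("not a VTK unstructured grid: POINTS missing")
    n_pts = int(next(tok))
    next(tok)  # dtype
    verts = np.array([float(next(tok)) for _ in range(3 * n_pts)]).reshape(n_pts, 3)
    if not until("CELLS"):
        raise InvalidGeometryError("CELLS section missing")
    n_cells = int(next(tok))
    next(tok)  # total ints
    tets = np.empty((n_cells, 4), dtype=np.int64)
    for i in range(n_cells):
        npt = int(next(tok))
        if npt != 4:
            raise UnsupportedCellError(f"cell {i} has {npt} points; only tetrahedra supported")
        tets[i] = [int(next(tok)) for _ in range(4)]
    if not until("CELL_TYPES"):
        raise InvalidGeometryError("CELL_TYPES section missing")
    next(tok)
    for i in range(n_cells):
        ct = int(next(tok))
        if ct != 10:
            raise UnsupportedCellError(f"cell {i} has VTK type {ct}; only type 10 supported")

    tissue = None
    rest = list(tok)
    for i, t in enumerate(rest):
        if t == "tissue":
            vals = rest[i + 1 :]
            # skip "int 1 LOOKUP_TABLE default"
            j = 0
            while j < len(vals) and not _is_int(vals[j]):
                j += 1
            j += 1  # the component count
            while j < len(vals) and not _is_int(vals[j]):
                j += 1
            tissue = np.array([int(v) for v in vals[j : j + n_cells]], dtype=np.int32)
            break
    if tissue is None or len(tissue) != n_cells:
        warnings.warn("no 'tissue' cell-data array; defaulting to a single tissue")
        tissue = np.zeros(n_cells, dtype=np.int32)
        tissue_names = ["flesh"]
    mesh = TetMesh(vertices=verts, tets=tets, tissue=tissue, tissue_names=tissue_names)
    compute_geometry(mesh)
    return mesh


def _tokens(lines):
    for ln in lines[2:]:
        yield from ln.split()


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False
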