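"""Geometry updates driven by computed volume changes.

Two modes:

* unconstrained — vertices never move; the four face areas of each tet are
  scaled by (v_new/v_old)^(2/3), shared contact areas are the minimum of
  the two adjacent faces, and vessel contact areas stay proportional to
  the tet's total area.
* constrained — the whole mesh is first scaled uniformly so total volume
  matches the summed targets, then interior (flesh) vertices are relaxed
  by Metropolis dynamics minimizing H = lambda_v * sum_i (v*_i - v_i)^2,
  with skin and stone vertices held fixed.  Water content is afterwards
  readjusted so each compartment's volume matches what the mesh achieved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TetMesh, compute_geometry
from .transport import CompartmentState, TransportParams


@dataclass
class GrowthParams:
    """Settings for the constrained (Metropolis) growth step."""

    mode: str = "unconstrained"
    lambda_v: float = 1.0      # resistance to compression/expansion
    G: float = 1e-5            # Boltzmann noise scale
    step_size: float = 0.01    # vertex move magnitude epsilon (cm)
    min_stall_iters: int = 10
    max_sweeps: int = 200
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_v <= 0 or self.G <= 0 or self.step_size <= 0:
            raise ValueError("lambda_v, G and step_size must be > 0")
        if self.min_stall_iters < 1:
            raise ValueError("min_stall_iters must be >= 1")


def scale_faces(face_areas: np.ndarray, v_old: np.ndarray, v_new: np.ndarray) -> np.ndarray:
    """A_i^k(t+dt) = A_i^k(t) * (v_new/v_old)^(2/3)."""
    v_old = np.asarray(v_old, dtype=float)
    v_new = np.asarray(v_new, dtype=float)
    if np.any(v_old <= 0) or np.any(v_new <= 0):
        raise ValueError("volumes must be > 0")
    ratio = (v_new / v_old) ** (2.0 / 3.0)
    return face_areas * ratio[:, None]


def contact_surface(A_ik: float, A_jl: float) -> float:
    """Shared contact area between differently grown adjacent faces."""
    if A_ik < 0 or A_jl < 0:
        raise ValueError("areas must be >= 0")
    return min(A_ik, A_jl)


def update_vessel_areas(a_v: np.ndarray, total_area: np.ndarray) -> np.ndarray:
    """A_i^v(t+dt) = a_i^v * A_i(t+dt) with the ratios fixed at t=0."""
    return np.asarray(a_v, float) * np.asarray(total_area, float)


def water_readjust(
    state: CompartmentState, v_star: np.ndarray, params: TransportParams
) -> CompartmentState:
    """Set w_i = (v*_i - s_i/D_s) * D_w so the content matches the achieved
    volume exactly; s and P are untouched."""
    v_star = np.asarray(v_star, dtype=float)
    if np.any(v_star <= 0):
        raise ValueError("achieved volumes must be > 0")
    w = (v_star - state.s / params.D_s) * params.D_w
    if np.any(w <= 0):
        bad = int(np.argmin(w))
        raise ValueError(
            f"achieved volume {v_star[bad]:.3g} cannot hold dry mass "
            f"{state.s[bad]:.3g} in compartment {bad}"
        )
    out = state.copy()
    out.w = w
    return out


# ---------------------------------------------------------------------------
# Constrained step
# ---------------------------------------------------------------------------

def _incidence(mesh: TetMesh) -> list[np.ndarray]:
    inc: list[list[int]] = [[] for _ in range(len(mesh.vertices))]
    for t, tet in enumerate(mesh.tets):
        for vv in tet:
            inc[vv].append(t)
    return [np.asarray(a, dtype=np.int64) for a in inc]


def constrained_step(
    mesh: TetMesh,
    v_target: np.ndarray,
    params: GrowthParams,
    movable: np.ndarray | None = None,
    v_min: np.ndarray | None = None,
) -> tuple[TetMesh, np.ndarray]:
    """Deform the mesh so per-tet volumes approach ``v_target``.

    Step 1 scales the whole mesh uniformly so total volume matches the
    summed targets exactly.  Step 2 runs Metropolis sweeps over the movable
    vertices (skin/boundary and stone vertices are fixed by default): a
    vertex move x' = x + eps*r with r uniform on the unit sphere is
    accepted if it lowers H = lambda_v*sum (v*_i - v_i)^2, or with
    probability exp(-dH/G) otherwise; moves inverting any tet are always
    rejected.  Sweeps stop when H has not changed (to 1e-12) for
    ``min_stall_iters`` consecutive sweeps.  Returns the deformed mesh and
    the achieved volumes.
    """
    v_target = np.asarray(v_target, dtype=float)
    if np.any(v_target <= 0):
        raise ValueError("target volumes must be > 0")
    mesh._require_geometry()
    out = mesh.copy()

    # step 1: global scale (moves every vertex, including skin and stone)
    scale = (v_target.sum() / out.volumes.sum()) ** (1.0 / 3.0)
    centre = out.vertices.mean(axis=0)
    out.vertices = centre + scale * (out.vertices - centre)
    compute_geometry(out)

    if movable is None:
        boundary_verts = np.unique(
            np.concatenate(
                [
                    out.tets[t][list(idx)]
                    for t in range(out.n_tets)
                    for k, idx in enumerate([(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)])
                    if out.face_neighbor[t, k] < 0
                ]
            )
        ) if out.n_tets else np.array([], dtype=int)
        movable = np.ones(len(out.vertices), dtype=bool)
        movable[boundary_verts] = False
        inner_idx = len(out.tissue_names) - 1
        if inner_idx > 0:
            stone_verts = np.unique(out.tets[out.tissue == inner_idx])
            movable[stone_verts] = False
    else:
        movable = np.asarray(movable, dtype=bool)

    verts = out.vertices
    tets = out.tets
    vols = out.volumes.copy()
    inc = _incidence(out)
    lam = params.lambda_v
    H = lam * float(np.sum((v_target - vols) ** 2))
    rng = np.random.default_rng(params.rng_seed)
    mov = np.flatnonzero(movable)

    def tet_vols(tids, vertices):
        v = vertices[tets[tids]]
        return (
            np.einsum(
                "ij,ij->i", v[:, 1] - v[:, 0], np.cross(v[:, 2] - v[:, 0], v[:, 3] - v[:, 0])
            )
            / 6.0
        )

    best_H = H
    best_verts = verts.copy()
    stall = 0
    for _ in range(params.max_sweeps):
        H_start = H
        order = rng.permutation(mov)
        mus = rng.uniform(-1.0, 1.0, size=len(order))
        thetas = rng.uniform(0.0, 2.0 * np.pi, size=len(order))
        accept_u = rng.uniform(size=len(order))
        rho = np.sqrt(np.clip(1.0 - mus**2, 0.0, None))
        dirs = np.column_stack([rho * np.cos(thetas), rho * np.sin(thetas), mus])
        for m, vi in enumerate(order):
            tids = inc[vi]
            old_pos = verts[vi].copy()
            old_v = vols[tids]
            verts[vi] = old_pos + params.step_size * dirs[m]
            new_v = tet_vols(tids, verts)
            # hard rejects: inverted elements, or compartments squeezed
            # below the volume their dry matter physically occupies
            if np.any(new_v <= 0) or (
                v_min is not None and np.any(new_v < v_min[tids])
            ):
                verts[vi] = old_pos
                continue
            dH = lam * float(
                np.sum((v_target[tids] - new_v) ** 2) - np.sum((v_target[tids] - old_v) ** 2)
            )
            if dH <= 0 or accept_u[m] < np.exp(-dH / params.G):
                vols[tids] = new_v
                H += dH
            else:
                verts[vi] = old_pos
        if H < best_H:
            best_H = H
            best_verts = verts.copy()
        if abs(H - H_start) <= 1e-12:
            stall += 1
            if stall >= params.min_stall_iters:
                break
        else:
            stall = 0

    # the Boltzmann acceptance keeps exploring around the optimum; return
    # the best configuration seen so H(final) <= H(after step 1)
    out.vertices = best_verts
    compute_geometry(out)
    return out, out.volumes.copy()
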