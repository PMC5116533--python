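"""Water and dry-matter transport coupled to turgor-driven expansion.

Each tetrahedral compartment i carries water mass w_i (g), dry matter
s_i (g) and turgor pressure P_i (bar).  Water moves between neighbouring
compartments, from the xylem/phloem vessels crossing a compartment, and is
lost by transpiration through the skin (optionally enhanced by cuticular
microcracks).  Sugars arrive by bulk flow, active Michaelis-Menten uptake
and passive diffusion, and are consumed by respiration.  Volume change
feeds back on turgor through a Lockhart/Ortega envelope: elastic below the
yield threshold Y, plastic above it.

Units: cm / cm^2 / cm^3, g, h, bar, K.  Conductivities act on areas in
cm^2 (see docs/methods.md for the unit audit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import coo_matrix

from .errors import IntegrationError, StateError
from .mesh import TetMesh
from .vascular import ContactAreaMap


def saturation_vapor_concentration(T: float) -> float:
    """Saturated water-vapour concentration alpha(T) in g cm^-3, from the
    Tetens saturation-pressure formula and the ideal gas law.

    At 293.15 K this is ~1.73e-5 g cm^-3.
    """
    Tc = T - 273.15
    p_sat = 610.78 * np.exp(17.27 * Tc / (Tc + 237.3))  # Pa
    M_w, R_gas = 18.0e-3, 8.314  # kg/mol, J/mol/K
    return p_sat * M_w / (R_gas * T) * 1e-3  # kg/m^3 -> g/cm^3


@dataclass
class TransportParams:
    """Physical parameters of the coupled transport/growth model.

    Defaults are the tomato values; the nectarine set is provided by
    :func:`carposim.scenarios.nectarine_config`.
    """

    R: float = 83.0              # cm^3 bar mol^-1 K^-1
    T: float = 293.15            # K
    D_w: float = 1.0             # g cm^-3
    D_s: float = 1.6             # g cm^-3
    M_w: float = 18.0            # g mol^-1
    M_s: float = 342.3           # g mol^-1
    beta: float = 0.52           # soluble fraction of the carbohydrate pool
    pi_b: float = 5.0            # bar, non-sugar osmotic pressure in flesh
    pi_b_p: float = 5.0          # bar, non-sugar osmotic pressure in phloem
    Y: float = 1.0               # bar, yield threshold
    phi_ext: float = 0.02        # bar^-1 h^-1, wall extensibility
    eps_elast: float = 100.0     # bar, elastic modulus
    H_f: float = 0.996
    H_air: float = 0.7
    rho_ext: float = 22.0        # cm h^-1, surface permeation
    rho_crk: float = 3838.0      # cm h^-1, microcrack permeation
    alpha: float | None = None   # g cm^-3; None -> Tetens at T
    q_g: float = 0.22
    q_m_ref: float = 0.00042     # h^-1 at 293.15 K
    q_10: float = 1.4
    sigma_p: float = 1.0
    nu_max: float = 9.0e-5       # g h^-1 cm^-2
    K_m: float = 0.08
    k_diff: float = 0.0          # g h^-1 cm^-2, passive diffusion
    t_star: float | None = None  # h; None disables the active-uptake decline
    tau: float = 1.0
    L_x: float = 1.0e-5          # g h^-1 cm^-2 bar^-1
    L_p: float = 5.0e-4
    L: float = 0.0               # inter-compartment conductivity

    def __post_init__(self) -> None:
        if not (0.0 <= self.sigma_p <= 1.0):
            raise ValueError("sigma_p must be in [0, 1]")
        if not (0.0 < self.beta <= 1.0):
            raise ValueError("beta must be in (0, 1]")
        for name in ("L_x", "L_p", "L", "rho_ext", "rho_crk"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.H_f <= 1.0 and 0.0 <= self.H_air <= 1.0):
            raise ValueError("humidities must be in [0, 1]")

    @property
    def alpha_T(self) -> float:
        return self.alpha if self.alpha is not None else saturation_vapor_concentration(self.T)

    def q_m(self) -> float:
        """Maintenance respiration coefficient at temperature T (Q10 law)."""
        return self.q_m_ref * self.q_10 ** ((self.T - 293.15) / 10.0)


@dataclass
class VesselBoundary:
    """Constant xylem/phloem boundary conditions, set by the pedicel."""

    psi_stem: float    # bar
    S_p: float         # g sugar / g FW in the phloem sap

    def pressures(self, params: TransportParams) -> tuple[float, float, float]:
        """(P_x, pi_p, P_p): xylem osmotic pressure is neglected, so
        P_x = psi_stem; P_p = P_x + pi_p keeps the two water potentials equal."""
        pi_p = osmotic_pressure(self.S_p, params.pi_b_p, params)
        P_x = self.psi_stem
        return P_x, pi_p, P_x + pi_p


@dataclass
class CrackModel:
    """Per-compartment microcrack fractions driven by whole-fruit mass.

    z_i is the measured (or synthetic) crack percentage per external
    compartment; the whole-fruit crack coverage C(X) follows the
    allometric threshold law with parameters a, b, lam.
    """

    z: np.ndarray            # (n_tets,) percent, zero on internal tets
    a: float = 5.396
    b: float = 0.635
    lam: float = 0.41

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if np.any(self.z < 0):
            raise ValueError("crack percentages must be >= 0")
        if self.a <= 0 or self.b <= 0 or self.lam <= 0:
            raise ValueError("crack-law parameters a, b, lam must be > 0")


@dataclass
class CompartmentState:
    """Per-compartment state (w, s, P) with derived quantities."""

    w: np.ndarray
    s: np.ndarray
    P: np.ndarray
    params: TransportParams

    @property
    def v(self) -> np.ndarray:
        return self.w / self.params.D_w + self.s / self.params.D_s

    @property
    def S(self) -> np.ndarray:
        return sugar_concentration(self.s, self.w, self.params.beta)

    @property
    def pi(self) -> np.ndarray:
        return osmotic_pressure(self.S, self.params.pi_b, self.params)

    @property
    def psi(self) -> np.ndarray:
        return self.P - self.pi

    def copy(self) -> "CompartmentState":
        return CompartmentState(self.w.copy(), self.s.copy(), self.P.copy(), self.params)


@dataclass
class FluxReport:
    """Instantaneous per-compartment fluxes (g/h)."""

    U_x: np.ndarray
    U_p: np.ndarray
    U_neigh: np.ndarray   # sum_j U_ji into each i
    T: np.ndarray
    V_m: np.ndarray
    V_a: np.ndarray
    V_d: np.ndarray
    R: np.ndarray

    @property
    def U_v(self) -> np.ndarray:
        return self.U_x + self.U_p


# ---------------------------------------------------------------------------
# Elementary relations
# ---------------------------------------------------------------------------

def sugar_concentration(s, w, beta):
    """Soluble sugar concentration S = beta*s / (beta*s + w), g/g FW."""
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("water mass must be > 0")
    s = np.asarray(s, dtype=float)
    return beta * s / (beta * s + w)


def osmotic_pressure(S, pi_base, params: TransportParams):
    """van't Hoff osmotic pressure pi = pi_base + R*T*S/M_s (bar), taking the
    solution density as 1 g cm^-3 to convert the mass fraction S to a molar
    concentration."""
    return pi_base + params.R * params.T * np.asarray(S, dtype=float) / params.M_s


def water_flux(A, L_c, P_a, P_b, pi_a, pi_b, sigma=1.0):
    """Membrane water flux U = A*L_c*(P_a - P_b - sigma*(pi_a - pi_b)), g/h,
    positive from side a to side b."""
    return A * L_c * (P_a - P_b - sigma * (pi_a - pi_b))


def crack_area_total(X, a, b, lam):
    """Whole-fruit crack coverage C (%) as a function of fresh weight X (g):
    zero below the threshold X^lam = a, then (b*(X^lam - a))^(1/lam)."""
    if a <= 0 or b <= 0 or lam <= 0:
        raise ValueError("crack-law parameters must be > 0")
    X = np.asarray(X, dtype=float)
    if np.any(X <= 0):
        raise ValueError("fresh weight must be > 0")
    xl = X**lam
    return np.where(xl >= a, (b * np.clip(xl - a, 0.0, None)) ** (1.0 / lam), 0.0)


def crack_coverage_pct(crack_area, surface_area):
    """Whole-fruit crack coverage in percent from measured areas (cm^2)."""
    if surface_area <= 0:
        raise ValueError("surface area must be > 0")
    if crack_area < 0:
        raise ValueError("crack area must be >= 0")
    return 100.0 * crack_area / surface_area


def crack_fraction(z, A_ext, C):
    """Per-compartment cracked fraction c_i of the external area.

    c_i = z_i / sum_j(z_j A_ext_j) * C * sum_j(A_ext_j) / 100, clamped to
    [0, 1]; the area-weighted mean of c_i equals C/100 before clamping.
    """
    z = np.asarray(z, dtype=float)
    A_ext = np.asarray(A_ext, dtype=float)
    if C == 0:
        return np.zeros_like(z)
    denom = float(np.sum(z * A_ext))
    if denom <= 0:
        raise ValueError("all z_i are zero while C > 0")
    return np.clip(z / denom * (C * A_ext.sum()) / 100.0, 0.0, 1.0)


def transpiration(A_ext, c, params: TransportParams):
    """Skin transpiration T_i = A_ext*(c*rho_crk + (1-c)*rho_ext)*alpha(T)*
    (H_f - H_air), g/h.  c = 0 recovers the uncracked single-coefficient form."""
    c = np.asarray(c, dtype=float)
    if np.any((c < 0) | (c > 1)):
        raise ValueError("crack fraction must be in [0, 1]")
    rho = c * params.rho_crk + (1.0 - c) * params.rho_ext
    return np.asarray(A_ext, float) * rho * params.alpha_T * (params.H_f - params.H_air)


def sugar_fluxes(S_i, A_v, U_p, boundary: VesselBoundary, params: TransportParams, t=0.0):
    """(V_m, V_a, V_d): bulk flow, active Michaelis-Menten uptake (with an
    optional logistic decline in time), and passive diffusion of sugars."""
    S_p = boundary.S_p
    U_p = np.asarray(U_p, dtype=float)
    V_m = (1.0 - params.sigma_p) * U_p * np.where(U_p >= 0, S_p, S_i)
    decline = 1.0
    if params.t_star is not None:
        decline = 1.0 / (1.0 + np.exp((t - params.t_star) / params.tau))
    V_a = np.asarray(A_v, float) * params.nu_max * S_p / (params.K_m + S_p) * decline
    V_d = np.asarray(A_v, float) * params.k_diff * (S_p - S_i)
    return V_m, V_a, V_d


# ---------------------------------------------------------------------------
# Assembled right-hand side
# ---------------------------------------------------------------------------

class TransportSystem:
    """Precomputed geometry/coupling arrays for fast RHS evaluation.

    ``active`` marks compartments that exchange water and grow (inert
    tissues, e.g. a stone, keep w, s, P frozen and exchange nothing).
    The face-area state lives here (it is updated by the growth module
    between integration windows); A_ij is min over the two adjacent faces.
    """

    def __init__(
        self,
        mesh: TetMesh,
        contact: ContactAreaMap,
        boundary: VesselBoundary,
        params: TransportParams,
        crack: CrackModel | None = None,
        active: np.ndarray | None = None,
    ):
        mesh._require_geometry()
        self.mesh = mesh
        self.contact = contact
        self.boundary = boundary
        self.params = params
        self.crack = crack
        n = mesh.n_tets
        self.active = np.ones(n, dtype=bool) if active is None else np.asarray(active, bool)

        self.face_areas = mesh.face_areas.copy()
        self.volumes0 = mesh.volumes.copy()
        self.A_x = contact.A_x.copy()
        self.A_p = contact.A_p.copy()
        pairs = mesh.pairs
        both = self.active[pairs[:, 0]] & self.active[pairs[:, 1]]
        self.pairs = pairs[both]
        self.pair_faces = mesh.pair_faces[both]
        self.ext_area = mesh.ext_area.copy()
        self.P_x, self.pi_p, self.P_p = boundary.pressures(params)
        # vessels only feed active flesh
        self.A_x = np.where(self.active, self.A_x, 0.0)
        self.A_p = np.where(self.active, self.A_p, 0.0)
        self.inert_mass = 0.0  # constant (w+s) of inert tets, for X(t)

    # -- geometry updates (called between windows by the growth module) ----
    def pair_areas(self) -> np.ndarray:
        i, j = self.pairs.T
        ki, kj = self.pair_faces.T
        return np.minimum(self.face_areas[i, ki], self.face_areas[j, kj])

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        n = self.mesh.n_tets
        w, s, P = y[:n], y[n : 2 * n], y[2 * n :]
        p = self.params
        wc = np.maximum(w, 1e-12)
        S = p.beta * s / (p.beta * s + wc)
        pi = p.pi_b + p.R * p.T * S / p.M_s
        psi = P - pi

        U_x = self.A_x * p.L_x * (self.P_x - P + pi)
        U_p = self.A_p * p.L_p * (self.P_p - P - p.sigma_p * (self.pi_p - pi))

        dw = np.where(self.active, U_x + U_p, 0.0)
        if p.L > 0 and len(self.pairs):
            i, j = self.pairs.T
            Uji = self.pair_areas() * p.L * (psi[j] - psi[i])
            np.add.at(dw, i, Uji)
            np.add.at(dw, j, -Uji)

        T_i = self._transpiration(w, s)
        dw -= T_i

        V_m = (1.0 - p.sigma_p) * U_p * np.where(U_p >= 0, self.boundary.S_p, S)
        decline = 1.0
        if p.t_star is not None:
            decline = 1.0 / (1.0 + np.exp((t - p.t_star) / p.tau))
        A_v = self.A_p
        V_a = A_v * p.nu_max * self.boundary.S_p / (p.K_m + self.boundary.S_p) * decline
        V_d = A_v * p.k_diff * (self.boundary.S_p - S)
        ds = np.where(self.active, (V_m + V_a + V_d - p.q_m() * s) / (1.0 + p.q_g), 0.0)

        dv = dw / p.D_w + ds / p.D_s
        v = wc / p.D_w + s / p.D_s
        dP = np.where(
            self.active,
            p.eps_elast * (dv / v - p.phi_ext * np.maximum(0.0, P - p.Y)),
            0.0,
        )
        return np.concatenate([dw, ds, dP])

    def _transpiration(self, w, s) -> np.ndarray:
        p = self.params
        ext = np.where(self.active, self.ext_area, 0.0)
        if self.crack is None:
            c = 0.0
            rho = p.rho_ext
            return ext * rho * p.alpha_T * (p.H_f - p.H_air)
        X = float(np.sum(w[self.active]) + np.sum(s[self.active])) + self.inert_mass
        C = float(crack_area_total(X, self.crack.a, self.crack.b, self.crack.lam))
        if C == 0:
            return ext * p.rho_ext * p.alpha_T * (p.H_f - p.H_air)
        c = crack_fraction(self.crack.z, np.maximum(ext, 1e-300), C)
        c = np.where(ext > 0, c, 0.0)
        return transpiration(ext, c, p)

    def flux_report(self, state: CompartmentState, t: float = 0.0) -> FluxReport:
        p = self.params
        S, pi, P = state.S, state.pi, state.P
        U_x = np.where(self.active, self.A_x * p.L_x * (self.P_x - P + pi), 0.0)
        U_p = np.where(self.active, self.A_p * p.L_p * (self.P_p - P - p.sigma_p * (self.pi_p - pi)), 0.0)
        U_n = np.zeros(self.mesh.n_tets)
        if p.L > 0 and len(self.pairs):
            i, j = self.pairs.T
            psi = state.psi
            Uji = self.pair_areas() * p.L * (psi[j] - psi[i])
            np.add.at(U_n, i, Uji)
            np.add.at(U_n, j, -Uji)
        T_i = self._transpiration(state.w, state.s)
        V_m, V_a, V_d = sugar_fluxes(S, self.A_p, U_p, self.boundary, p, t)
        V_m = np.where(self.active, V_m, 0.0)
        V_a = np.where(self.active, V_a, 0.0)
        V_d = np.where(self.active, V_d, 0.0)
        ds = (V_m + V_a + V_d - p.q_m() * state.s) / (1.0 + p.q_g)
        R_i = np.where(self.active, p.q_g * ds + p.q_m() * state.s, 0.0)
        return FluxReport(U_x=U_x, U_p=U_p, U_neigh=U_n, T=T_i, V_m=V_m, V_a=V_a, V_d=V_d, R=R_i)

    def jac_sparsity(self):
        n = self.mesh.n_tets
        rows, cols = [], []

        def block(ii, jj):
            for a in range(3):
                for b in range(3):
                    rows.append(ii + a * n)
                    cols.append(jj + b * n)

        idx = np.arange(n)
        for a in range(3):
            for b in range(3):
                rows.extend(idx + a * n)
                cols.extend(idx + b * n)
        for i, j in self.pairs:
            block(i, j)
            block(j, i)
        data = np.ones(len(rows), dtype=np.int8)
        return coo_matrix((data, (rows, cols)), shape=(3 * n, 3 * n)).tocsr()


def assemble_rhs(
    state: CompartmentState,
    mesh: TetMesh,
    contact: ContactAreaMap,
    boundary: VesselBoundary,
    params: TransportParams,
    crack: CrackModel | None = None,
    t: float = 0.0,
    active: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate (dw/dt, ds/dt, dP/dt) for every compartment."""
    if (
        np.any(~np.isfinite(state.w))
        or np.any(~np.isfinite(state.s))
        or np.any(state.w <= 0)
        or np.any(state.s < 0)
    ):
        raise StateError("state contains NaN or non-positive masses")
    sys = TransportSystem(mesh, contact, boundary, params, crack=crack, active=active)
    y = np.concatenate([state.w, state.s, state.P])
    dy = sys.rhs(t, y)
    n = mesh.n_tets
    return dy[:n], dy[n : 2 * n], dy[2 * n :]


def init_state(
    mesh: TetMesh, S_0: float, P_0: float, params: TransportParams
) -> CompartmentState:
    """Homogeneous initial state: per tet, (w, s) solve
    {v = w/D_w + s/D_s, S_0 = beta*s/(beta*s + w)} exactly; P = P_0."""
    if S_0 >= params.beta:
        raise ValueError(f"S_0={S_0} must be < beta={params.beta}")
    if S_0 < 0:
        raise ValueError("S_0 must be >= 0")
    mesh._require_geometry()
    v = mesh.volumes
    r = S_0 / (1.0 - S_0)  # = beta*s/w
    w = v / (1.0 / params.D_w + r / (params.beta * params.D_s))
    s = r * w / params.beta
    return CompartmentState(w=w, s=s, P=np.full(mesh.n_tets, float(P_0)), params=params)


# ---------------------------------------------------------------------------
# Time integration
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Sampled states of a simulation at the geometry-update instants."""

    times: np.ndarray
    w: np.ndarray           # (n_times, n_tets)
    s: np.ndarray
    P: np.ndarray
    params: TransportParams
    total_transpired: float = 0.0

    def state(self, k: int = -1) -> CompartmentState:
        return CompartmentState(self.w[k].copy(), self.s[k].copy(), self.P[k].copy(), self.params)

    @property
    def total_water(self) -> np.ndarray:
        return self.w.sum(axis=1)

    @property
    def fresh_weight(self) -> np.ndarray:
        return self.w.sum(axis=1) + self.s.sum(axis=1)


def integrate(
    state0: CompartmentState,
    mesh: TetMesh,
    contact: ContactAreaMap,
    boundary: VesselBoundary,
    params: TransportParams,
    t_span: tuple[float, float],
    dt_geom: float = 1.0,
    crack: CrackModel | None = None,
    active: np.ndarray | None = None,
    growth_callback=None,
    update_vessel_areas: bool = True,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> Trajectory:
    """Integrate the coupled (w, s, P) system with a stiff BDF method,
    updating the face/contact-area geometry every ``dt_geom`` hours with
    the unconstrained scaling rule (or a caller-supplied growth callback).

    ``growth_callback(system, state, t)`` runs at each geometry instant
    and may mutate the system's area caches and the state (constrained
    growth); when None the unconstrained face-scaling update is applied.
    """
    from . import growth as growth_mod

    sys_ = TransportSystem(mesh, contact, boundary, params, crack=crack, active=active)
    sparsity = sys_.jac_sparsity()
    t0, t1 = t_span
    n_windows = max(1, int(round((t1 - t0) / dt_geom)))
    edges = np.linspace(t0, t1, n_windows + 1)

    state = state0.copy()
    times = [t0]
    W, S_, P_ = [state.w.copy()], [state.s.copy()], [state.P.copy()]
    v_window = state.v.copy()

    for k in range(n_windows):
        y0 = np.concatenate([state.w, state.s, state.P])
        sol = solve_ivp(
            sys_.rhs,
            (edges[k], edges[k + 1]),
            y0,
            method="BDF",
            jac_sparsity=sparsity,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            n = mesh.n_tets
            dy = sys_.rhs(sol.t[-1], sol.y[:, -1])
            worst = int(np.argmax(np.abs(dy[:n])))
            raise IntegrationError(
                f"BDF failed at t={sol.t[-1]:.3f} h ({sol.message}); "
                f"largest |dw/dt| in compartment {worst}"
            )
        n = mesh.n_tets
        y = sol.y[:, -1]
        state.w, state.s, state.P = y[:n].copy(), y[n : 2 * n].copy(), y[2 * n :].copy()

        if growth_callback is not None:
            growth_callback(sys_, state, edges[k + 1])
            v_window = state.v.copy()
        else:
            # unconstrained growth: scale the four faces of each tet by the
            # volume change over the window; vessel areas follow A_i
            v_new = state.v
            sys_.face_areas = growth_mod.scale_faces(sys_.face_areas, v_window, v_new)
            sys_.ext_area = _ext_from_faces(sys_)
            if update_vessel_areas:
                A_tot = sys_.face_areas.sum(axis=1)
                sys_.A_x = np.where(sys_.active, sys_.contact.a_x * A_tot, 0.0)
                sys_.A_p = np.where(sys_.active, sys_.contact.a_p * A_tot, 0.0)
            v_window = v_new.copy()

        times.append(edges[k + 1])
        W.append(state.w.copy())
        S_.append(state.s.copy())
        P_.append(state.P.copy())

    return Trajectory(
        times=np.asarray(times),
        w=np.asarray(W),
        s=np.asarray(S_),
        P=np.asarray(P_),
        params=params,
    )


def _ext_from_faces(sys_: TransportSystem) -> np.ndarray:
    return np.where(sys_.mesh.face_neighbor < 0, sys_.face_areas, 0.0).sum(axis=1)
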