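"""1D pulse-wave haemodynamics of a compliant arterial bifurcation.

Solves the standard one-dimensional axisymmetric blood-flow equations for
cross-sectional area A(z,t) and volumetric flux Q(z,t),

    dU/dt + dF/dz = S,    U = (A, Q),
    F  = (Q,  Q²/A + (f/ρ)·√(A0·A)),
    S2 = −(2πνR/δb)·(Q/A) + (r0'/ρ)·[2√A(√π·f + √A0·f') − A·f'],

on a middle-cerebral-artery (MCA) trunk feeding two daughter vessels.  The
wall is elastic with stiffness f(r0) = (4/3)(k1·exp(k2·r0) + k3) and the
transmural pressure obeys the state equation p − p0 = f·(1 − √(A0/A)).
The scheme is Richtmyer's two-step Lax–Wendroff; boundaries are closed with
characteristic compatibility: a prescribed periodic flux at the inlet, a
three-element Windkessel (R1 — R2‖CT) at each daughter outlet, and an
iterative junction solve enforcing flux conservation and pressure continuity
at the bifurcation.

All quantities are CGS (cm, g, s; pressures in dyn cm⁻²).  Solver-internal
pressure is the excess over diastolic (p0 = 0 inside the solver); the
diastolic offset is added only at reporting boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RHO_BLOOD",
    "VesselSegment",
    "WindkesselParams",
    "SolverGrid",
    "HemoField",
    "NetworkResult",
    "wall_stiffness",
    "state_pressure",
    "area_from_pressure",
    "boundary_layer_thickness",
    "wave_speed",
    "lax_wendroff_step",
    "windkessel_pressure",
    "simulate_network",
    "mca_network",
]

#: Blood density, g cm⁻³.
RHO_BLOOD = 1.06

# Wall-compliance constants (CGS), standard estimates for cerebral arteries.
K1_DEFAULT = 2.0e7     # g cm⁻¹ s⁻²
K2_DEFAULT = -22.53    # cm⁻¹
K3_DEFAULT = 8.65e5    # g cm⁻¹ s⁻²
NU_BLOOD = 0.046       # kinematic viscosity of blood, cm² s⁻¹


class SolverDivergenceError(RuntimeError):
    """Raised when the scheme produces NaN/non-positive areas or violates CFL."""


def wall_stiffness(r0, k1=K1_DEFAULT, k2=K2_DEFAULT, k3=K3_DEFAULT):
    """Elastic stiffness f(r0) = 4Eh/(3 r0) = (4/3)(k1 exp(k2 r0) + k3)."""
    r0 = np.asarray(r0, dtype=float)
    if np.any(r0 <= 0):
        raise ValueError("rest radius must be positive")
    return (4.0 / 3.0) * (k1 * np.exp(k2 * r0) + k3)


def _dfdr0(r0, k1=K1_DEFAULT, k2=K2_DEFAULT, k3=K3_DEFAULT):
    return (4.0 / 3.0) * k1 * k2 * np.exp(k2 * np.asarray(r0, dtype=float))


def state_pressure(A, A0, f, p0=0.0):
    """Transmural state equation p = p0 + f·(1 − √(A0/A))."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0) or np.any(np.asarray(A0) <= 0):
        raise ValueError("areas must be positive")
    return p0 + f * (1.0 - np.sqrt(A0 / A))


def area_from_pressure(p, A0, f, p0=0.0):
    """Inverse of :func:`state_pressure`: A = A0 / (1 − (p−p0)/f)²."""
    x = 1.0 - (np.asarray(p, dtype=float) - p0) / f
    if np.any(x <= 0):
        raise ValueError("pressure exceeds the asymptote p0 + f")
    return A0 / x**2


def boundary_layer_thickness(nu, T):
    """Oscillatory (Stokes) boundary-layer thickness δb = √(νT/2π)."""
    if nu <= 0 or T <= 0:
        raise ValueError("nu and T must be positive")
    return float(np.sqrt(nu * T / (2.0 * np.pi)))


def wave_speed(A, A0, f, rho=RHO_BLOOD):
    """Local pulse-wave (Moens–Korteweg-type) speed c = √(f/2ρ)·(A0/A)^¼."""
    return np.sqrt(f / (2.0 * rho)) * (np.asarray(A0) / np.asarray(A)) ** 0.25


@dataclass
class VesselSegment:
    """Geometry and compliance of one tapered compliant segment.

    The rest radius tapers from ``R_u`` at the upstream end to ``R_d``
    downstream; exponential taper r0(z) = R_u·(R_d/R_u)^(z/L) by default,
    linear as an option.
    """

    R_u: float
    R_d: float
    L: float
    k1: float = K1_DEFAULT
    k2: float = K2_DEFAULT
    k3: float = K3_DEFAULT
    taper: str = "exponential"
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.R_u >= self.R_d > 0):
            raise ValueError("need R_u >= R_d > 0 (slight taper)")
        if self.L <= 0:
            raise ValueError("length must be positive")
        if self.taper not in ("exponential", "linear"):
            raise ValueError("taper must be 'exponential' or 'linear'")

    def r0(self, z):
        """Rest radius profile, cm; z measured from the upstream end."""
        z = np.asarray(z, dtype=float)
        if self.taper == "exponential":
            return self.R_u * (self.R_d / self.R_u) ** (z / self.L)
        return self.R_u + (self.R_d - self.R_u) * z / self.L

    def dr0dz(self, z):
        z = np.asarray(z, dtype=float)
        if self.taper == "exponential":
            return self.r0(z) * np.log(self.R_d / self.R_u) / self.L
        return np.full_like(z, (self.R_d - self.R_u) / self.L)

    def A0(self, z):
        """Rest area, cm²."""
        return np.pi * self.r0(z) ** 2

    def stiffness(self, z):
        return wall_stiffness(self.r0(z), self.k1, self.k2, self.k3)


@dataclass
class WindkesselParams:
    """Three-element Windkessel: R1 in series with (R2 parallel CT)."""

    R1: float = 14.130       # g cm⁻⁴ s⁻¹
    R2: float = 7.200        # g cm⁻⁴ s⁻¹
    CT: float = 2.4752e-3    # cm⁴ s² g⁻¹

    def __post_init__(self) -> None:
        if min(self.R1, self.R2, self.CT) <= 0:
            raise ValueError("Windkessel elements must be strictly positive")


@dataclass
class SolverGrid:
    """Space-time discretisation; vertex-centred, z_0 = 0 at the inlet."""

    dz: float = 0.1          # cm
    dt: float = 1e-5         # s
    T: float = 0.85          # cardiac period, s
    n_cycles: int = 8
    store_every: int = 100   # hemodynamic steps between stored snapshots

    def __post_init__(self) -> None:
        if self.dz <= 0 or self.dt <= 0 or self.T <= 0 or self.n_cycles < 1:
            raise ValueError("grid parameters must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.n_cycles * self.T / self.dt))

    @property
    def steps_per_cycle(self) -> int:
        return int(round(self.T / self.dt))


@dataclass
class HemoField:
    """Space-time fields of one segment (rows: stored times, cols: z nodes)."""

    z: np.ndarray
    t: np.ndarray
    A: np.ndarray
    Q: np.ndarray
    p: np.ndarray            # excess over diastolic, dyn cm⁻²
    A0: np.ndarray
    r0: np.ndarray
    name: str = ""

    def final_cycle(self, T: float) -> "HemoField":
        """View restricted to the final cardiac period (endpoint included)."""
        dt = self.t[1] - self.t[0]
        n = int(round(T / dt))
        sl = slice(len(self.t) - n - 1, len(self.t))
        return HemoField(self.z, self.t[sl], self.A[sl], self.Q[sl],
                         self.p[sl], self.A0, self.r0, self.name)

    def cycle_periodicity_defect(self, T: float) -> float:
        """Relative L∞ difference between the last two stored cycles."""
        dt = self.t[1] - self.t[0]
        n = int(round(T / dt))
        last, prev = self.A[-n:], self.A[-2 * n:-n]
        scale = np.abs(last - self.A0).max()
        return float(np.abs(last - prev).max() / max(scale, 1e-300))


@dataclass
class NetworkResult:
    """Fields for every segment plus solver diagnostics."""

    fields: dict
    grid: SolverGrid
    max_junction_residual: float = 0.0
    max_conservation_residual: float = 0.0
    max_cfl: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def parent(self) -> HemoField:
        return self.fields["mca"]


# ----------------------------------------------------------------- scheme --

def lax_wendroff_step(U, dz, dt, flux_fn, source_fn=None, x=None):
    """One Richtmyer two-step Lax–Wendroff update of the interior nodes.

    Parameters
    ----------
    U : ndarray, shape (m, N)
        Conserved state at the N vertex-centred nodes.
    flux_fn, source_fn : callables
        ``flux_fn(U, x)`` returning the flux with the same shape; evaluated
        at nodes and at cell midpoints (``x`` gives the positions so that
        z-dependent coefficients can be honoured).  ``source_fn`` may be None.
    x : ndarray, optional
        Node positions; defaults to ``arange(N)*dz``.

    Returns
    -------
    ndarray
        Updated state; boundary columns are copied unchanged (the caller
        closes them with boundary conditions).
    """
    U = np.asarray(U, dtype=float)
    if U.ndim == 1:
        out = lax_wendroff_step(U[None, :], dz, dt, flux_fn, source_fn, x)
        return out[0]
    m, N = U.shape
    if x is None:
        x = np.arange(N) * dz
    xh = 0.5 * (x[:-1] + x[1:])
    F = flux_fn(U, x)
    S = source_fn(U, x) if source_fn is not None else 0.0
    Sh_old = 0.0 if source_fn is None else 0.5 * (S[:, :-1] + S[:, 1:])
    # predictor: half-step state at cell midpoints
    Uh = (0.5 * (U[:, :-1] + U[:, 1:])
          - (dt / (2.0 * dz)) * (F[:, 1:] - F[:, :-1])
          + (dt / 2.0) * Sh_old)
    Fh = flux_fn(Uh, xh)
    Sh = source_fn(Uh, xh) if source_fn is not None else None
    Unew = U.copy()
    Unew[:, 1:-1] = U[:, 1:-1] - (dt / dz) * (Fh[:, 1:] - Fh[:, :-1])
    if Sh is not None:
        Unew[:, 1:-1] += dt * 0.5 * (Sh[:, :-1] + Sh[:, 1:])
    return Unew


class _SegmentSolver:
    """Discretised segment: precomputed coefficients + one LW update."""

    def __init__(self, seg: VesselSegment, grid: SolverGrid, nu: float,
                 rho: float):
        self.seg = seg
        n = int(round(seg.L / grid.dz)) + 1
        if n < 3:
            raise ValueError(f"segment {seg.name!r} too short for dz={grid.dz}")
        self.z = np.linspace(0.0, seg.L, n)
        self.dz = self.z[1] - self.z[0]
        self.dt = grid.dt
        self.rho = rho
        self.delta_b = boundary_layer_thickness(nu, grid.T)
        self.nu = nu
        for attr, zz in (("n", self.z), ("h", 0.5 * (self.z[:-1] + self.z[1:]))):
            r0 = seg.r0(zz)
            co = {
                "r0": r0,
                "A0": np.pi * r0**2,
                "sqrtA0": np.sqrt(np.pi) * r0,
                "f": seg.stiffness(zz),
                "dfdr0": _dfdr0(r0, seg.k1, seg.k2, seg.k3),
                "dr0dz": seg.dr0dz(zz),
            }
            setattr(self, f"co_{attr}", co)
        self.A = self.co_n["A0"].copy()
        self.Q = np.zeros(n)

    # -- physics on a coefficient set ------------------------------------
    def _flux(self, A, Q, co):
        return Q, Q * Q / A + (co["f"] / self.rho) * co["sqrtA0"] * np.sqrt(A)

    def _source2(self, A, Q, co):
        R = np.sqrt(A / np.pi)
        fric = -(2.0 * np.pi * self.nu / self.delta_b) * R * Q / A
        sqrtA = np.sqrt(A)
        taper = (co["dr0dz"] / self.rho) * (
            2.0 * sqrtA * (np.sqrt(np.pi) * co["f"] + co["sqrtA0"] * co["dfdr0"])
            - A * co["dfdr0"]
        )
        return fric + taper

    def pressure(self, A=None):
        A = self.A if A is None else A
        co = self.co_n
        return co["f"] * (1.0 - np.sqrt(co["A0"] / A))

    def speed(self, A=None):
        A = self.A if A is None else A
        co = self.co_n
        return np.sqrt(co["f"] / (2.0 * self.rho)) * (co["A0"] / A) ** 0.25

    def cfl(self):
        c = self.speed()
        return float(((np.abs(self.Q / self.A) + c) * self.dt / self.dz).max())

    def step_interior(self):
        """Advance interior nodes one Δt; returns half-step face fluxes."""
        A, Q = self.A, self.Q
        F1, F2 = self._flux(A, Q, self.co_n)
        S2 = self._source2(A, Q, self.co_n)
        lam = dt_dz = self.dt / self.dz
        Ah = 0.5 * (A[:-1] + A[1:]) - 0.5 * lam * (F1[1:] - F1[:-1])
        Qh = (0.5 * (Q[:-1] + Q[1:]) - 0.5 * lam * (F2[1:] - F2[:-1])
              + 0.25 * self.dt * (S2[:-1] + S2[1:]))
        if np.any(Ah <= 0) or not np.isfinite(Ah).all():
            raise SolverDivergenceError(
                f"non-positive/NaN half-step area in segment {self.seg.name!r}")
        Fh1, Fh2 = self._flux(Ah, Qh, self.co_h)
        Sh2 = self._source2(Ah, Qh, self.co_h)
        self.A[1:-1] -= dt_dz * (Fh1[1:] - Fh1[:-1])
        self.Q[1:-1] -= dt_dz * (Fh2[1:] - Fh2[:-1])
        self.Q[1:-1] += 0.5 * self.dt * (Sh2[:-1] + Sh2[1:])
        return Fh1, Fh2

    # -- characteristic extrapolation ------------------------------------
    def invariant_foot(self, side: str, A_old, Q_old):
        """Riemann invariant advected to the boundary from the interior.

        For this tube law c ∝ A^(−1/4) and the invariants are W± = u ∓ 4c,
        following dW±/dt = g_u − (1/ρ)·∂p/∂z|_A ∓ 4λ±·∂c/∂z|_A along
        dz/dt = λ± = u ± c, where g_u is the friction deceleration and the
        explicit-z terms stem from the tapering rest geometry (they vanish
        on a uniform vessel but are leading-order at tapered boundaries).
        ``side='end'`` returns W+ carried to the last node along the forward
        characteristic; ``side='start'`` returns W− carried to the first
        node along the backward one, both corrected for the path source.
        """
        u = Q_old / A_old
        c = self.speed(A_old)
        co = self.co_n
        j = -1 if side == "end" else 0
        Aj, uj, cj = A_old[j], u[j], c[j]
        r0, f, df, dr0 = co["r0"][j], co["f"][j], co["dfdr0"][j], co["dr0dz"][j]
        A0 = co["A0"][j]
        # friction deceleration g_u = S2_friction / A
        g_u = -(2.0 * np.pi * self.nu / self.delta_b) * np.sqrt(Aj / np.pi) \
            * uj / Aj
        # explicit axial derivative of the tube law at fixed A
        sq = np.sqrt(A0 / Aj)
        dp_exp = dr0 * (df * (1.0 - sq) - f * np.pi * r0 / np.sqrt(A0 * Aj))
        # explicit axial derivative of the wave speed at fixed A
        dc_exp = cj * dr0 * (df / (2.0 * f) + 0.5 / r0)
        if side == "end":
            lam = uj + cj
            frac = lam * self.dt / self.dz  # in [0,1) for CFL<1
            w = u - 4.0 * c
            foot = w[-1] + frac * (w[-2] - w[-1])
            return foot + self.dt * (g_u - dp_exp / self.rho
                                     - 4.0 * lam * dc_exp)
        lam = uj - cj
        frac = -lam * self.dt / self.dz
        w = u + 4.0 * c
        foot = w[0] + frac * (w[1] - w[0])
        return foot + self.dt * (g_u - dp_exp / self.rho + 4.0 * lam * dc_exp)


def windkessel_pressure(Q_new, pc_old, wk: WindkesselParams, dt: float):
    """Advance the 3WK outlet one step (backward-Euler capacitor).

    Returns (p_outlet, p_capacitor).  Steady state: p = Q·(R1+R2); a step in
    Q relaxes to it with time constant R2·CT.
    """
    pc = (pc_old + (dt / wk.CT) * Q_new) / (1.0 + dt / (wk.R2 * wk.CT))
    return wk.R1 * Q_new + pc, pc


def _newton_outlet(sol: _SegmentSolver, wplus: float, pc_old: float,
                   wk: WindkesselParams, dt: float):
    """Solve for the outlet area: state pressure == Windkessel pressure."""
    co = sol.co_n
    f, A0 = co["f"][-1], co["A0"][-1]
    cfac = np.sqrt(f / (2.0 * sol.rho)) * A0**0.25
    beta = 1.0 + dt / (wk.R2 * wk.CT)
    A = sol.A[-1]
    for _ in range(60):
        c = cfac * A**-0.25
        Q = A * (wplus + 4.0 * c)
        p_state = f * (1.0 - np.sqrt(A0 / A))
        g = p_state - wk.R1 * Q - (pc_old + (dt / wk.CT) * Q) / beta
        dQdA = wplus + 3.0 * c
        dg = (f * np.sqrt(A0) * 0.5 * A**-1.5
              - wk.R1 * dQdA - (dt / (wk.CT * beta)) * dQdA)
        step = g / dg
        A -= step
        if A <= 0:
            raise SolverDivergenceError("outlet Newton left the physical branch")
        if abs(step) < 1e-14 * max(A, 1.0):
            break
    c = cfac * A**-0.25
    Q = A * (wplus + 4.0 * c)
    return A, Q


def _newton_inlet_area(sol: _SegmentSolver, Fh1, Q_in_half):
    """Inlet compatibility closure for A via the continuity ghost flux."""
    dt_dz = sol.dt / sol.dz
    return sol.A[0] - dt_dz * 2.0 * (Fh1[0] - Q_in_half)


def _junction_newton(par: _SegmentSolver, d1: _SegmentSolver,
                     d2: _SegmentSolver, wp, wm1, wm2, tol=1e-12, maxit=50):
    """Bifurcation closure: 6 unknowns (A,Q at the three meeting nodes).

    Enforces the advected Riemann invariants, Q_p = Q_1 + Q_2, and pressure
    continuity p_p = p_1 = p_2; Newton iteration with analytic Jacobian,
    scaled residual norm below ``tol``.
    """
    segs = (par, d1, d2)
    idx = (-1, 0, 0)
    f = np.array([s.co_n["f"][i] for s, i in zip(segs, idx)])
    A0 = np.array([s.co_n["A0"][i] for s, i in zip(segs, idx)])
    cf = np.sqrt(f / (2.0 * par.rho)) * A0**0.25
    x = np.array([par.A[-1], par.Q[-1], d1.A[0], d1.Q[0], d2.A[0], d2.Q[0]])
    w = np.array([wp, wm1, wm2])
    sgn = np.array([-1.0, 1.0, 1.0])  # W+ = u−4c at parent, W− = u+4c at daughters
    c0 = cf[0] * A0[0] ** -0.25
    scale = np.array([c0, c0, c0, max(abs(x[1]), A0[0] * c0),
                      par.rho * c0**2, par.rho * c0**2])
    res = None
    for _ in range(maxit):
        A = x[0::2]
        Q = x[1::2]
        c = cf * A**-0.25
        u = Q / A
        g = np.empty(6)
        g[0:3] = u + sgn * 4.0 * c - w
        g[3] = x[1] - x[3] - x[5]
        p = f * (1.0 - np.sqrt(A0 / A))
        g[4] = p[0] - p[1]
        g[5] = p[0] - p[2]
        res = float(np.abs(g / scale).max())
        if res < tol:
            break
        J = np.zeros((6, 6))
        dcdA = -0.25 * c / A
        for k in range(3):
            J[k, 2 * k] = -u[k] / A[k] + sgn[k] * 4.0 * dcdA[k]
            J[k, 2 * k + 1] = 1.0 / A[k]
        J[3, 1], J[3, 3], J[3, 5] = 1.0, -1.0, -1.0
        dpdA = 0.5 * f * np.sqrt(A0) * A**-1.5
        J[4, 0], J[4, 2] = dpdA[0], -dpdA[1]
        J[5, 0], J[5, 4] = dpdA[0], -dpdA[2]
        x = x - np.linalg.solve(J, g)
        if np.any(x[0::2] <= 0):
            raise SolverDivergenceError("junction Newton produced A <= 0")
    else:
        raise SolverDivergenceError(
            f"junction iteration failed to converge; residual {res:.3e}")
    par.A[-1], par.Q[-1] = x[0], x[1]
    d1.A[0], d1.Q[0] = x[2], x[3]
    d2.A[0], d2.Q[0] = x[4], x[5]
    cons = abs(x[1] - x[3] - x[5])
    return res, cons


# ---------------------------------------------------------------- network --

def mca_network():
    """The MCA trunk and its first bifurcation (lengths ≈ 50·R_u; daughter
    radii scaled by 0.91, right daughter slightly shortened to de-symmetrise
    wave reflections)."""
    return {
        "mca": VesselSegment(0.14, 0.14, 7.0, name="mca"),
        "left": VesselSegment(0.13, 0.08, 6.5, name="left"),
        "right": VesselSegment(0.13, 0.08, 6.4, name="right"),
    }


def simulate_network(
    segments: dict | None = None,
    inlet=None,
    wk: WindkesselParams | None = None,
    grid: SolverGrid | None = None,
    nu: float = NU_BLOOD,
    rho: float = RHO_BLOOD,
    check_every: int = 1,
) -> NetworkResult:
    """Run the bifurcation model for ``grid.n_cycles`` cardiac cycles.

    Parameters
    ----------
    segments : dict with keys 'mca', 'left', 'right'
        Vessel geometry; defaults to :func:`mca_network`.
    inlet : InletWaveform (flux) or callable t -> Q
        Periodic inlet volumetric flux, cm³ s⁻¹.
    wk : WindkesselParams
        Outlet model, applied identically at both daughter outlets.
    """
    from .waveform import InletWaveform, default_inlet_flux

    segments = segments or mca_network()
    wk = wk or WindkesselParams()
    grid = grid or SolverGrid()
    if inlet is None:
        inlet = default_inlet_flux()
    if isinstance(inlet, InletWaveform):
        if inlet.kind != "flux":
            raise ValueError("inlet waveform must carry flux samples")
        q_in = inlet.interpolator()
    else:
        q_in = inlet

    par = _SegmentSolver(segments["mca"], grid, nu, rho)
    d1 = _SegmentSolver(segments["left"], grid, nu, rho)
    d2 = _SegmentSolver(segments["right"], grid, nu, rho)
    solvers = {"mca": par, "left": d1, "right": d2}

    n_steps = grid.n_steps
    store = grid.store_every
    n_store = n_steps // store + 1
    stored = {k: {"A": np.empty((n_store, s.z.size)),
                  "Q": np.empty((n_store, s.z.size))}
              for k, s in solvers.items()}
    t_store = np.empty(n_store)

    def snapshot(i, t):
        t_store[i] = t
        for k, s in solvers.items():
            stored[k]["A"][i] = s.A
            stored[k]["Q"][i] = s.Q

    # start from rest with the inlet flux ramped over the first cycle to
    # avoid an impulsive start
    ramp_T = grid.T
    pc1 = pc2 = 0.0
    snapshot(0, 0.0)
    max_res = max_cons = max_cfl = 0.0
    isnap = 1
    for n in range(n_steps):
        t_new = (n + 1) * grid.dt
        t_half = (n + 0.5) * grid.dt
        ramp_new = min(t_new / ramp_T, 1.0)
        ramp_half = min(t_half / ramp_T, 1.0)

        if n % check_every == 0:
            cfl = max(s.cfl() for s in solvers.values())
            max_cfl = max(max_cfl, cfl)
            if cfl > 1.0:
                raise SolverDivergenceError(
                    f"CFL violation ({cfl:.3f} > 1) at t={t_new:.5f}s")

        A_old = {k: s.A.copy() for k, s in solvers.items()}
        Q_old = {k: s.Q.copy() for k, s in solvers.items()}

        Fh1_par, _ = par.step_interior()
        d1.step_interior()
        d2.step_interior()

        # inlet: prescribed flux + continuity ghost closure for A
        par.Q[0] = ramp_new * float(q_in(t_new))
        par.A[0] = _newton_inlet_area(par, Fh1_par,
                                      ramp_half * float(q_in(t_half)))
        if par.A[0] <= 0:
            raise SolverDivergenceError("inlet area went non-positive")

        # bifurcation
        wp = par.invariant_foot("end", A_old["mca"], Q_old["mca"])
        wm1 = d1.invariant_foot("start", A_old["left"], Q_old["left"])
        wm2 = d2.invariant_foot("start", A_old["right"], Q_old["right"])
        res, cons = _junction_newton(par, d1, d2, wp, wm1, wm2)
        max_res = max(max_res, res)
        max_cons = max(max_cons, cons)

        # daughter outlets: characteristic + Windkessel
        wpl1 = d1.invariant_foot("end", A_old["left"], Q_old["left"])
        wpl2 = d2.invariant_foot("end", A_old["right"], Q_old["right"])
        d1.A[-1], d1.Q[-1] = _newton_outlet(d1, wpl1, pc1, wk, grid.dt)
        d2.A[-1], d2.Q[-1] = _newton_outlet(d2, wpl2, pc2, wk, grid.dt)
        _, pc1 = windkessel_pressure(d1.Q[-1], pc1, wk, grid.dt)
        _, pc2 = windkessel_pressure(d2.Q[-1], pc2, wk, grid.dt)

        if (n + 1) % store == 0:
            snapshot(isnap, t_new)
            isnap += 1

    fields = {}
    for k, s in solvers.items():
        A = stored[k]["A"][:isnap]
        Q = stored[k]["Q"][:isnap]
        co = s.co_n
        p = co["f"] * (1.0 - np.sqrt(co["A0"] / A))
        fields[k] = HemoField(z=s.z, t=t_store[:isnap], A=A, Q=Q, p=p,
                              A0=co["A0"], r0=co["r0"], name=k)
    return NetworkResult(
        fields=fields, grid=grid,
        max_junction_residual=max_res,
        max_conservation_residual=max_cons,
        max_cfl=max_cfl,
        meta={"nu": nu, "rho": rho, "ramp_cycles": 1},
    )
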