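"""Brute-force 2D Darcy reference solver for the annular BM strip.

The lubrication reduction in :mod:`ipadflow.drainage` rests on the scale
separation W ≪ L between the BM width and the vessel length.  This module
solves the *full* axisymmetric Darcy problem

    ∇·(K ∇p) = 0   in   R_i(z) < r < R_o(z),  0 < z < L,

in cylindrical coordinates (so the discrete operator conserves r-weighted
flux), with prescribed pressures at the two z-ends and no-flux conditions on
the inner and outer sheaths (a static geometry slice; the kinematic wall
condition reduces to zero normal flux when the walls are frozen).  It is
intentionally simple and direct — a small boundary-fitted finite-volume
discretisation solved with a sparse direct factorisation — and serves as the
independent check that the 1D model's fluxes are accurate to O((W/L)²).

The annulus is mapped onto the unit rectangle via σ = (r − R_i)/W, W = R_o −
R_i.  In (z, σ) the equation keeps the symmetric divergence form

    ∂z(a11 p_z + a12 p_σ) + ∂σ(a12 p_z + a22 p_σ) = 0,
    a11 = K r W,  a12 = K r W σ_z,  a22 = K r W (σ_z² + σ_r²),

with σ_r = 1/W and σ_z = −(R_i' + σ W')/W.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

__all__ = ["Darcy2DResult", "darcy2d_oracle", "lubrication_flux_1d"]

MAX_CELLS = 10_000  # brute-force reference: small instances only


@dataclass
class Darcy2DResult:
    """Solution fields on the (z, σ) tensor grid (shape nz × nr)."""

    z: np.ndarray
    sigma: np.ndarray
    r: np.ndarray        # physical radius r(z, sigma)
    p: np.ndarray
    q1: np.ndarray       # axial Darcy flux, cm/s
    q2: np.ndarray       # radial Darcy flux, cm/s

    def gap_mean_q1(self) -> np.ndarray:
        """Width-averaged axial flux per z station."""
        return np.trapezoid(self.q1, self.sigma, axis=1)

    def gap_flux(self) -> np.ndarray:
        """Annulus-integrated axial flux 2π∫q1 r dr per z station, cm³/s."""
        W = self.r[:, -1] - self.r[:, 0]
        return 2.0 * np.pi * W * np.trapezoid(self.q1 * self.r,
                                              self.sigma, axis=1)


def _d_central(n: int, h: float) -> sp.csr_matrix:
    """Second-order first derivative, one-sided at the ends."""
    D = sp.lil_matrix((n, n))
    for k in range(1, n - 1):
        D[k, k - 1], D[k, k + 1] = -0.5 / h, 0.5 / h
    D[0, 0], D[0, 1], D[0, 2] = -1.5 / h, 2.0 / h, -0.5 / h
    D[-1, -1], D[-1, -2], D[-1, -3] = 1.5 / h, -2.0 / h, 0.5 / h
    return D.tocsr()


def _d_face(n: int, h: float) -> sp.csr_matrix:
    """Node-to-face difference, shape (n−1, n)."""
    return (sp.diags([-1.0, 1.0], [0, 1], shape=(n - 1, n)) / h).tocsr()


def _a_face(n: int) -> sp.csr_matrix:
    """Node-to-face average, shape (n−1, n)."""
    return sp.diags([0.5, 0.5], [0, 1], shape=(n - 1, n)).tocsr()


def _div(n: int, h: float) -> sp.csr_matrix:
    """Face-to-node divergence; boundary rows use the half control volume."""
    D = sp.lil_matrix((n, n - 1))
    for k in range(1, n - 1):
        D[k, k - 1], D[k, k] = -1.0 / h, 1.0 / h
    D[0, 0] = 2.0 / h
    D[-1, -1] = -2.0 / h
    return D.tocsr()


def darcy2d_oracle(
    Ri_fn,
    Ro_fn,
    L: float,
    K,
    p_in,
    p_out,
    nz: int = 101,
    nr: int = 17,
) -> Darcy2DResult:
    """Solve the static annular Darcy problem by direct discretisation.

    Parameters
    ----------
    Ri_fn, Ro_fn : callables z → radius (cm)
        Inner/outer sheath shapes (static slice of the moving geometry).
    K : float or callable (z, r) → mobility
        Darcy mobility field, cm³ s g⁻¹.
    p_in, p_out : float or callable σ → pressure
        Dirichlet pressures at z = 0 and z = L.
    nz, nr : int
        Grid nodes; ``nz·nr`` must stay ≤ 10⁴ (brute-force oracle).
    """
    if nz * nr > MAX_CELLS:
        raise ValueError(f"oracle limited to {MAX_CELLS} cells, got {nz * nr}")
    if nz < 5 or nr < 3:
        raise ValueError("grid too coarse for the 2D stencil")
    z = np.linspace(0.0, L, nz)
    sig = np.linspace(0.0, 1.0, nr)
    dz = z[1] - z[0]
    ds = sig[1] - sig[0]
    Ri = np.asarray(Ri_fn(z), dtype=float)
    Ro = np.asarray(Ro_fn(z), dtype=float)
    W = Ro - Ri
    if np.any(W <= 0) or np.any(Ri <= 0):
        raise ValueError("need R_o > R_i > 0 everywhere")
    dRi = np.gradient(Ri, z)
    dW = np.gradient(W, z)
    R = Ri[:, None] + sig[None, :] * W[:, None]           # (nz, nr)
    sigma_z = -(dRi[:, None] + sig[None, :] * dW[:, None]) / W[:, None]
    sigma_r = 1.0 / W[:, None] * np.ones_like(sig)[None, :]
    Kfield = (np.full_like(R, float(K)) if np.isscalar(K)
              else np.asarray(K(z[:, None], R), dtype=float) * np.ones_like(R))

    a11 = Kfield * R * W[:, None]
    a12 = a11 * sigma_z
    a22 = a11 * (sigma_z**2 + sigma_r**2)

    Iz, Is = sp.identity(nz), sp.identity(nr)
    Ds_nodes = sp.kron(Iz, _d_central(nr, ds)).tocsr()
    Dz_nodes = sp.kron(_d_central(nz, dz), Is).tocsr()

    # z-faces: (nz-1) x nr values
    Fz_grad = sp.kron(_d_face(nz, dz), Is)
    Fz_avg = sp.kron(_a_face(nz), Is)
    a11_zf = 0.5 * (a11[:-1] + a11[1:])
    a12_zf = 0.5 * (a12[:-1] + a12[1:])
    Fz_op = (sp.diags(a11_zf.ravel()) @ Fz_grad
             + sp.diags(a12_zf.ravel()) @ Fz_avg @ Ds_nodes)

    # sigma-faces: nz x (nr-1) values
    Fs_grad = sp.kron(Iz, _d_face(nr, ds))
    Fs_avg = sp.kron(Iz, _a_face(nr))
    a22_sf = 0.5 * (a22[:, :-1] + a22[:, 1:])
    a12_sf = 0.5 * (a12[:, :-1] + a12[:, 1:])
    Fs_op = (sp.diags(a22_sf.ravel()) @ Fs_grad
             + sp.diags(a12_sf.ravel()) @ Fs_avg @ Dz_nodes)

    Lap = (sp.kron(_div(nz, dz), Is) @ Fz_op
           + sp.kron(Iz, _div(nr, ds)) @ Fs_op).tolil()

    rhs = np.zeros(nz * nr)
    p_in_v = (np.full(nr, float(p_in)) if np.isscalar(p_in)
              else np.asarray(p_in(sig), dtype=float))
    p_out_v = (np.full(nr, float(p_out)) if np.isscalar(p_out)
               else np.asarray(p_out(sig), dtype=float))
    for j in range(nr):
        for i, val in ((0, p_in_v[j]), (nz - 1, p_out_v[j])):
            row = i * nr + j
            Lap.rows[row] = [row]
            Lap.data[row] = [1.0]
            rhs[row] = val

    p = spsolve(Lap.tocsr(), rhs).reshape(nz, nr)

    p_sig = (Ds_nodes @ p.ravel()).reshape(nz, nr)
    p_zeta = (Dz_nodes @ p.ravel()).reshape(nz, nr)
    q1 = -Kfield * (p_zeta + sigma_z * p_sig)
    q2 = -Kfield * sigma_r * p_sig
    return Darcy2DResult(z=z, sigma=sig, r=R, p=p, q1=q1, q2=q2)


def lubrication_flux_1d(Ri, h, K, p_in, p_out, z):
    """Steady 1D lubrication counterpart of the oracle's configuration.

    For a static gap the thickness equation reduces to R·h·K·p_z = const;
    integrating between the Dirichlet ends gives the pressure profile and
    the (z-independent) annulus flux Q = −2π·const.  Returns (q1(z), Q).
    """
    Ri = np.asarray(Ri, dtype=float)
    h = np.asarray(h, dtype=float)
    g = 1.0 / (Ri * h * K)
    denom = np.trapezoid(g, z)
    const = (p_out - p_in) / denom           # = R h K p_z
    q1 = -const / (Ri * h)                   # = -K p_z
    Q = 2.0 * np.pi * Ri * h * q1            # uniform in z up to round-off
    return q1, float(Q.mean())
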