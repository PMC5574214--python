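"""Arterial-wall mechanics: from lumen fields to basement-membrane inputs.

The drainage model needs, at the radial position of the basement membrane
(BM) inside the wall, (i) the moving interface radius R_i(z,t) and (ii) the
interstitial-fluid (ISF) pressure p(z,t) and its axial gradient p_z.  Both
are obtained from the 1D haemodynamic fields through a linear-elasticity
approximation of the wall, here the classical incompressible thick-walled
cylinder (Lamé) solution:

* the radial displacement decays through the wall as u(r) ∝ 1/r, so the
  lumen displacement ξ reaches the BM attenuated by a/(a + η·h_w);
* the pulsatile radial stress (≈ pore pressure) decays with the Lamé weight
  w(η) = a²(b² − r²)/(r²(b² − a²)), r = a + η·h_w, which is 1 at the lumen
  and 0 at the stress-free outer wall.

η ∈ [0,1] places the BM within the wall (0 = adjacent to the lumen, 1 = at
the outer wall).  Both transfer functions are pluggable; the Lamé choice is
documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hemodynamics import HemoField

__all__ = [
    "WallGeometry",
    "WallKinematics",
    "lumen_displacement",
    "bm_interface_radius",
    "lame_stress_weight",
    "isf_pressure",
    "axial_pressure_gradient",
    "wall_kinematics",
]


@dataclass
class WallGeometry:
    """Wall geometry at one axial station (or arrays along z).

    a : lumen rest radius (cm); h_w : wall thickness (cm), default 0.1·a
    (physiological wall-to-radius ratio); eta : dimensionless BM position,
    r = a + eta·h_w.
    """

    a: float | np.ndarray
    h_w: float | np.ndarray | None = None
    eta: float = 0.0

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        if np.any(self.a <= 0):
            raise ValueError("lumen rest radius must be positive")
        if self.h_w is None:
            self.h_w = 0.1 * self.a
        self.h_w = np.asarray(self.h_w, dtype=float)
        if np.any(self.h_w < 0):
            raise ValueError("wall thickness must be non-negative")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")

    @property
    def b(self):
        """Outer rest radius."""
        return self.a + self.h_w

    @property
    def r_bm(self):
        """Rest radius of the BM position, a + eta*h_w."""
        return self.a + self.eta * self.h_w


@dataclass
class WallKinematics:
    """BM-level inputs to the drainage model on the (t, z) grid."""

    z: np.ndarray
    t: np.ndarray
    R_i: np.ndarray          # BM inner-interface radius, cm
    p_isf: np.ndarray        # ISF pressure (excess over diastolic), dyn/cm^2
    p_z: np.ndarray          # axial ISF pressure gradient, dyn/cm^3
    geom: WallGeometry = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if np.any(self.R_i <= 0):
            raise ValueError("R_i must be positive")


def lumen_displacement(hemo: HemoField) -> np.ndarray:
    """Radial lumen-wall displacement ξ = √(A/π) − r0 implied by the areas."""
    if np.any(hemo.A <= 0):
        raise ValueError("areas must be positive")
    return np.sqrt(hemo.A / np.pi) - hemo.r0[None, :]


def bm_interface_radius(xi: np.ndarray, geom: WallGeometry) -> np.ndarray:
    """BM inner-interface radius R_i = (a + η·h_w) + ξ·a/(a + η·h_w).

    The rest radius at the BM position plus the lumen displacement attenuated
    by the incompressible thick-cylinder kinematics u(r) ∝ 1/r.  With η = 0
    (or a membrane-thin wall) this reduces to a + ξ.
    """
    r_rest = geom.r_bm
    atten = np.where(r_rest > 0, geom.a / np.maximum(r_rest, 1e-300), 1.0)
    return r_rest + np.asarray(xi) * atten


def lame_stress_weight(geom: WallGeometry) -> np.ndarray | float:
    """Radial-stress transfer weight w(η) = a²(b²−r²)/(r²(b²−a²)).

    Monotone decreasing across the wall, w(0) = 1 (full pulse pressure at
    the lumen), w(1) = 0 (stress-free outer surface).  For a membrane-thin
    wall (h_w → 0) the weight degenerates to 1 − η.
    """
    a, b, r = geom.a, geom.b, geom.r_bm
    thin = b**2 - a**2 <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        w = a**2 * (b**2 - r**2) / (r**2 * (b**2 - a**2))
    return np.where(thin, 1.0 - geom.eta, w) if np.ndim(w) else (
        float(1.0 - geom.eta) if thin else float(w))


def isf_pressure(p_blood: np.ndarray, geom: WallGeometry,
                 p0: float = 0.0, weight=None) -> np.ndarray:
    """Pulsatile ISF pressure at the BM: p_isf = (p_blood − p0)·w(η).

    ``p_blood`` is the haemodynamic pressure field (excess over diastolic if
    p0 = 0).  A custom transfer ``weight`` (scalar or z-array) may replace
    the Lamé weight.
    """
    w = lame_stress_weight(geom) if weight is None else weight
    return (np.asarray(p_blood, dtype=float) - p0) * w


def axial_pressure_gradient(p_isf: np.ndarray, dz: float) -> np.ndarray:
    """∂p/∂z by second-order central differences (one-sided at the ends)."""
    p = np.atleast_2d(np.asarray(p_isf, dtype=float))
    if p.shape[-1] < 3:
        raise ValueError("need at least 3 axial nodes for a second-order gradient")
    pz = np.empty_like(p)
    pz[..., 1:-1] = (p[..., 2:] - p[..., :-2]) / (2.0 * dz)
    pz[..., 0] = (-3.0 * p[..., 0] + 4.0 * p[..., 1] - p[..., 2]) / (2.0 * dz)
    pz[..., -1] = (3.0 * p[..., -1] - 4.0 * p[..., -2] + p[..., -3]) / (2.0 * dz)
    return pz if np.asarray(p_isf).ndim > 1 else pz[0]


def wall_kinematics(hemo: HemoField, eta: float = 0.0,
                    h_w: float | None = None,
                    displacement_weight=None,
                    pressure_weight=None) -> WallKinematics:
    """Assemble the BM-model inputs from one segment's haemodynamic fields.

    The wall geometry follows the segment's (possibly tapered) rest radius;
    custom displacement/pressure transfer functions may be supplied in place
    of the Lamé defaults (each called with the :class:`WallGeometry`).
    """
    geom = WallGeometry(a=hemo.r0, h_w=h_w, eta=eta)
    xi = lumen_displacement(hemo)
    if displacement_weight is None:
        R_i = bm_interface_radius(xi, geom)
    else:
        R_i = geom.r_bm + xi * displacement_weight(geom)
    p_isf = isf_pressure(hemo.p, geom, weight=(
        None if pressure_weight is None else pressure_weight(geom)))
    dz = float(hemo.z[1] - hemo.z[0])
    p_z = axial_pressure_gradient(p_isf, dz)
    return WallKinematics(z=hemo.z, t=hemo.t, R_i=R_i, p_isf=p_isf,
                          p_z=p_z, geom=geom)
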