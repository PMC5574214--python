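"""Synthetic middle-cerebral-artery (MCA) inlet waveforms.

The pulse-wave solver needs a periodic volumetric-flux boundary condition at
the MCA inlet.  Clinically this comes from a transcranial Doppler velocity
recording; here a documented synthetic generator stands in for such a
recording.  The generator produces a pulsatile velocity trace — fast systolic
upstroke, sharp post-systolic deceleration into a dicrotic notch, slow
diastolic decay — with per-beat amplitude jitter and additive measurement
noise.  The trace is then smoothed exactly the way a measured one would be:
the final ``n_peaks`` beats are segmented at the waveform foot, resampled onto
a common one-period grid, and averaged coefficient-wise in Fourier space.

Units are CGS throughout: velocities in cm s⁻¹, fluxes in cm³ s⁻¹.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

__all__ = [
    "VelocityTimeSeries",
    "InletWaveform",
    "beat_template",
    "synth_doppler_series",
    "fourier_average_peaks",
    "velocity_to_flux",
]

#: Default cardiac period (s).
DEFAULT_PERIOD = 0.85

# Template parameters (cm/s unless noted).  The periodic bumps are von-Mises
# shaped, exp(kappa*(cos(2*pi*(phi-c)) - 1)), so the template closes exactly
# over one period.  Amplitudes are chosen once so that the converted flux for
# a 0.14 cm lumen sits in the literature MCA range (mean ≈ 2.4 cm³ s⁻¹,
# systolic peak ≈ 5 cm³ s⁻¹); see docs/methods.md.
_TEMPLATE = {
    "baseline": 34.0,        # end-diastolic velocity
    "sys_amp": 52.0,         # systolic bump amplitude
    "sys_center": 0.14,      # phase of systolic peak
    "sys_kappa": 40.0,       # systolic bump sharpness
    "dic_amp": 14.0,         # dicrotic bump amplitude
    "dic_center": 0.42,
    "dic_kappa": 25.0,
    "decay_amp": 6.0,        # slow diastolic relaxation component
}


def _vm_bump(phase: np.ndarray, center: float, kappa: float) -> np.ndarray:
    """Periodic unit-height bump (von Mises shape) at ``center`` in [0,1)."""
    return np.exp(kappa * (np.cos(2.0 * np.pi * (phase - center)) - 1.0))


def beat_template(phase: np.ndarray, params: dict | None = None) -> np.ndarray:
    """Evaluate the canonical single-beat velocity template at ``phase`` ∈ [0,1).

    The template is exactly periodic in the phase and mimics an MCA Doppler
    envelope: rapid systolic upstroke to a peak, steep deceleration into a
    dicrotic notch, secondary (reflected-wave) bump, and diastolic decay.
    """
    p = dict(_TEMPLATE)
    if params:
        p.update(params)
    phase = np.asarray(phase, dtype=float) % 1.0
    v = (
        p["baseline"]
        + p["sys_amp"] * _vm_bump(phase, p["sys_center"], p["sys_kappa"])
        + p["dic_amp"] * _vm_bump(phase, p["dic_center"], p["dic_kappa"])
        + p["decay_amp"] * _vm_bump(phase, p["sys_center"] + 0.12, 8.0)
    )
    return v


@dataclass
class VelocityTimeSeries:
    """Uniformly sampled velocity trace emulating a Doppler recording.

    Attributes
    ----------
    t : ndarray
        Sample times in seconds, strictly increasing, uniform spacing.
    v : ndarray
        Velocity in cm s⁻¹ (mean cross-sectional velocity under the
        mostly-flat profile assumption).
    meta : dict
        Generator parameters including the seed.
    """

    t: np.ndarray
    v: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.v.shape:
            raise ValueError("t and v must be 1-D arrays of equal length")
        dt = np.diff(self.t)
        if not (dt > 0).all():
            raise ValueError("t must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-8):
            raise ValueError("t must be uniformly spaced")
        if not np.isfinite(self.v).all():
            raise ValueError("velocity values must be finite")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass
class InletWaveform:
    """One cardiac period of an inlet signal (velocity or flux).

    ``samples`` covers exactly one period on a uniform grid ``t`` in
    ``[0, T)``; the value at ``T`` wraps to ``samples[0]``.
    """

    T: float
    t: np.ndarray
    samples: np.ndarray
    kind: str = "velocity"  # "velocity" (cm/s) or "flux" (cm^3/s)
    periodic: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.T <= 0:
            raise ValueError("period T must be positive")
        if not np.isfinite(self.samples).all():
            raise ValueError("waveform samples must be finite")

    def periodicity_defect(self) -> float:
        """|x(0) − x(T)| / max|x| using the periodic wrap of the grid."""
        spline = self.interpolator()
        closure = abs(float(spline(0.0)) - float(spline(self.T)))
        return closure / max(float(np.abs(self.samples).max()), 1e-300)

    def interpolator(self) -> CubicSpline:
        """Periodic cubic interpolant valid for any t (wraps modulo T)."""
        tt = np.append(self.t, self.T)
        xx = np.append(self.samples, self.samples[0])
        base = CubicSpline(tt, xx, bc_type="periodic")
        T = self.T

        def wrapped(t):
            return base(np.asarray(t, dtype=float) % T)

        wrapped.derivative = base.derivative  # pragma: no cover - convenience
        return wrapped

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        unit = "cm_s" if self.kind == "velocity" else "cm3_s"
        header = f"t_seconds,value_{unit}"
        np.savetxt(
            path,
            np.column_stack([self.t, self.samples]),
            delimiter=",",
            header=header,
            comments="",
        )
        sidecar = {"period_s": self.T, "kind": self.kind, "meta": self.meta}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "InletWaveform":
        path = Path(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        side = json.loads(path.with_suffix(".json").read_text())
        return cls(
            T=float(side["period_s"]),
            t=data[:, 0],
            samples=data[:, 1],
            kind=side.get("kind", "velocity"),
            meta=side.get("meta", {}),
        )


def synth_doppler_series(
    period: float = DEFAULT_PERIOD,
    n_beats: int = 12,
    amplitude_params: dict | None = None,
    jitter: float = 0.04,
    noise_sd: float = 0.5,
    fs: float = 200.0,
    seed: int | None = 0,
) -> VelocityTimeSeries:
    """Generate a synthetic Doppler-like MCA velocity time series.

    Parameters
    ----------
    period : float
        Cardiac period in seconds.
    n_beats : int
        Number of beats to generate.
    amplitude_params : dict, optional
        Overrides for the beat-template shape parameters.
    jitter : float
        Relative s.d. of the per-beat multiplicative amplitude jitter applied
        to the pulsatile (above-baseline) component.  Must be ≥ 0.
    noise_sd : float
        Additive white measurement noise s.d. in cm s⁻¹.
    fs : float
        Sampling rate in Hz.
    seed : int, optional
        Seed for the random generator; fixed seed gives a bitwise-identical
        series.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if n_beats <= 0:
        raise ValueError("n_beats must be positive")
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(n_beats * period * fs))) / fs
    phase = t / period
    beat_idx = np.floor(phase).astype(int)
    base = beat_template(phase, amplitude_params)
    baseline = (_TEMPLATE if amplitude_params is None
                else {**_TEMPLATE, **amplitude_params})["baseline"]
    gains = 1.0 + jitter * rng.standard_normal(n_beats)
    v = baseline + gains[beat_idx] * (base - baseline)
    if noise_sd > 0:
        v = v + noise_sd * rng.standard_normal(t.size)
    meta = {
        "period_s": period,
        "n_beats": n_beats,
        "jitter": jitter,
        "noise_sd_cm_s": noise_sd,
        "fs_hz": fs,
        "seed": seed,
        "template": {**_TEMPLATE, **(amplitude_params or {})},
    }
    return VelocityTimeSeries(t=t, v=v, meta=meta)


def _detect_feet(series: VelocityTimeSeries, period: float) -> np.ndarray:
    """Indices of waveform feet (minimum preceding each maximal upslope).

    The foot of each beat is located as the local minimum immediately
    preceding the steepest systolic upstroke — the standard fiducial point in
    pulse-wave analysis, robust to additive noise after mild smoothing.
    """
    dt = series.dt
    # light moving-average smoothing against additive noise
    win = max(3, int(round(0.02 / dt)) | 1)
    kernel = np.ones(win) / win
    v = np.convolve(series.v, kernel, mode="same")
    dv = np.gradient(v, dt)
    min_sep = int(round(0.6 * period / dt))
    ups, _ = find_peaks(dv, distance=min_sep, height=0.3 * dv.max())
    feet = []
    for k in ups:
        lo = max(0, k - int(round(0.3 * period / dt)))
        if lo >= k:
            continue
        feet.append(lo + int(np.argmin(v[lo:k])))
    return np.asarray(feet, dtype=int)


def fourier_average_peaks(
    series: VelocityTimeSeries,
    n_peaks: int = 10,
    period: float = DEFAULT_PERIOD,
    n_grid: int = 1024,
) -> InletWaveform:
    """Average the final ``n_peaks`` beats of a series in Fourier space.

    Beats are segmented by foot detection, each beat is resampled by cubic
    interpolation onto a common ``n_grid``-point one-period grid, the complex
    Fourier coefficients are averaged across beats, and the average is
    transformed back.  Averaging the coefficients is linear, so the result
    equals the time-domain beat average on the common grid; the gain is that
    the single smooth period is directly usable as a spectral description of
    the inlet.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    feet = _detect_feet(series, period)
    usable = [f for f in feet if series.t[f] + period <= series.t[-1] + series.dt / 2]
    if len(usable) < n_peaks:
        raise ValueError(
            f"insufficient data: {len(usable)} complete beats detected, "
            f"{n_peaks} requested"
        )
    tau = np.arange(n_grid) * (period / n_grid)
    spline = CubicSpline(series.t, series.v)
    t_end = series.t[-1]
    beats = []
    for f in usable[-n_peaks:]:
        t0 = series.t[f]
        beats.append(spline(np.minimum(t0 + tau, t_end)))
    coeffs = np.fft.rfft(np.asarray(beats), axis=1).mean(axis=0)
    avg = np.fft.irfft(coeffs, n=n_grid)
    meta = dict(series.meta)
    meta.update({"n_peaks": n_peaks, "n_grid": n_grid})
    return InletWaveform(T=period, t=tau, samples=avg, kind="velocity", meta=meta)


def velocity_to_flux(
    waveform: InletWaveform,
    lumen_radius: float = 0.14,
    profile_factor: float = 1.0,
) -> InletWaveform:
    """Convert a velocity waveform (cm s⁻¹) to volumetric flux (cm³ s⁻¹).

    Q(t) = profile_factor · v(t) · π · lumen_radius².  The default
    ``profile_factor`` of 1 corresponds to the mostly-flat velocity profile
    with a thin boundary layer assumed by the 1D haemodynamic model.
    Negative velocities are converted as-is, not clipped.
    """
    if lumen_radius <= 0:
        raise ValueError("lumen_radius must be positive")
    if not (0.0 < profile_factor <= 1.0):
        raise ValueError("profile_factor must be in (0, 1]")
    if waveform.kind != "velocity":
        raise ValueError("waveform must carry velocity samples")
    q = profile_factor * waveform.samples * np.pi * lumen_radius**2
    meta = dict(waveform.meta)
    meta.update({"lumen_radius_cm": lumen_radius, "profile_factor": profile_factor})
    return InletWaveform(
        T=waveform.T, t=waveform.t, samples=q, kind="flux",
        periodic=waveform.periodic, meta=meta,
    )


def default_inlet_flux(seed: int = 0, lumen_radius: float = 0.14) -> InletWaveform:
    """Canonical inlet: synthesise, Fourier-average the last 10 beats, convert."""
    series = synth_doppler_series(seed=seed)
    wave = fourier_average_peaks(series, n_peaks=10, period=DEFAULT_PERIOD)
    return velocity_to_flux(wave, lumen_radius=lumen_radius)
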