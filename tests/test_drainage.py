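"""BM drainage: valve, conservative evolution, metrics, threshold search."""

import numpy as np
import pytest

from ipadflow.drainage import (BMConfig, BMState, NoThresholdError, bm_evolve,
                               flux_metrics, reverse_flow_threshold,
                               valve_permeability)


class TestValve:
    def test_branches(self):
        assert valve_permeability(-10.0, 1.0, 3.0) == 1.0
        assert valve_permeability(0.0, 1.0, 3.0) == 3.0   # p_z >= 0 branch
        assert valve_permeability(5.0, 1.0, 3.0) == 3.0

    def test_degenerate_valve_constant(self):
        pz = np.linspace(-5, 5, 11)
        assert np.all(valve_permeability(pz, 2.0, 2.0) == 2.0)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            valve_permeability(0.0, 3.0, 1.0)

    def test_config_mobilities(self):
        cfg = BMConfig()
        # K1 = k/mu with k = 1e-10 cm^2, mu = 1.5e-3 Pa s = 1.5e-2 P
        assert cfg.K1 == pytest.approx(1e-10 / 1.5e-2, rel=1e-12)
        assert cfg.K0 == pytest.approx(0.01 * cfg.K1, rel=1e-12)


class TestEvolution:
    def _grid(self, nz=21, nt=51, L=2.0, T=0.1):
        return (np.linspace(0, L, nz), np.linspace(0, T, nt))

    def test_equilibrium_static(self):
        z, t = self._grid()
        R = np.full((t.size, z.size), 0.14)
        pz = np.zeros_like(R)
        cfg = BMConfig()
        st = bm_evolve(R, pz, cfg, z, t)
        assert np.allclose(st.h_bm, cfg.h_bm0, atol=0)

    def test_closed_form_breathing_radius(self):
        """With zero pressure gradient, γ·R_i·h_bm is conserved pointwise:
        h(z,t) = h0 · R(z,0)/R(z,t)."""
        z, t = self._grid()
        Rz = 0.1 + 0.02 * np.sin(2 * np.pi * z / z[-1])
        g = 1.0 + 0.05 * np.sin(2 * np.pi * t / t[-1])
        R = Rz[None, :] * g[:, None]
        cfg = BMConfig()
        st = bm_evolve(R, np.zeros_like(R), cfg, z, t)
        expected = cfg.h_bm0 * R[0][None, :] / R
        assert np.allclose(st.h_bm, expected, rtol=1e-13)

    def test_discrete_volume_conservation_machine_precision(self, rng):
        z, t = self._grid(nz=31, nt=41)
        R = 0.1 + 0.01 * rng.random((t.size, z.size))
        p = 500.0 * rng.standard_normal((t.size, z.size)).cumsum(axis=1)
        from ipadflow.wall import axial_pressure_gradient
        pz = axial_pressure_gradient(p, z[1] - z[0])
        cfg = BMConfig(ratio=0.1)
        st = bm_evolve(R, pz, cfg, z, t, p_isf=p)
        assert st.conservation_defect < 1e-12

    def test_periodic_bc_conserves_too(self, rng):
        z, t = self._grid(nz=16, nt=21)
        R = np.full((t.size, z.size), 0.1)
        pz = 300.0 * np.sin(2 * np.pi * z / (z[-1] + z[1]))[None, :] \
            * np.ones((t.size, 1))
        st = bm_evolve(R, pz, BMConfig(ratio=0.5), z, t, bc="periodic")
        sums = (st.R_i * st.h_bm).sum(axis=1)
        assert np.abs(sums - sums[0]).max() / sums[0] < 1e-12

    def test_peristaltic_rectification_second_order(self):
        """A travelling pressure wave pumps in the wave direction with mean
        flux ≈ 2π·a·h0·K²k²P²/(2γc) — classical lubrication rectification,
        derived independently at second order in the amplitude."""
        a, h0, gamma = 0.01, 2e-5, 0.5
        cfg = BMConfig(h_bm0=h0, gamma=gamma, ratio=1.0)
        K = cfg.K1
        L, c_w = 0.1, 10.0
        k = 2 * np.pi / L
        T_w = L / c_w
        nz, per = 64, 400
        z = np.arange(nz) * (L / nz)
        t = np.arange(6 * per + 1) * (T_w / per)
        fluxes = {}
        for P in (1e4, 5e3):
            theta = k * (z[None, :] - c_w * t[:, None])
            p = P * np.sin(theta)
            R = a * (1.0 + 1e-3 * np.sin(theta))
            pz = P * k * np.cos(theta)
            st = bm_evolve(R, pz, cfg, z, t, p_isf=p, bc="periodic")
            m = flux_metrics(st, T=T_w)
            fluxes[P] = m.mean_flux_um3_s / 1e12   # back to cm^3/s
        predicted = 2 * np.pi * a * h0 * K**2 * k**2 * 1e8 / (2 * gamma * c_w)
        assert fluxes[1e4] > 0                      # wave (+z) direction
        assert fluxes[1e4] == pytest.approx(predicted, rel=0.05)
        assert fluxes[1e4] / fluxes[5e3] == pytest.approx(4.0, rel=0.05)

    def test_divergence_reported(self):
        z, t = self._grid(nz=11, nt=3)
        R = np.full((t.size, z.size), 0.1)
        pz = np.full_like(R, 1e12)   # absurd gradient -> h collapses
        with pytest.raises(RuntimeError, match="diverged|reduce"):
            bm_evolve(R, pz, BMConfig(), z, t, cfl_target=50.0)


class TestMetrics:
    def _state(self, q1, h=2e-5, R=0.14, T=1.0, nt=101, nz=11):
        t = np.linspace(0, 2 * T, nt)
        z = np.linspace(0, 1, nz)
        q = np.broadcast_to(q1, (nt, nz)).copy()
        hh = np.full((nt, nz), h)
        RR = np.full((nt, nz), R)
        return BMState(z=z, t=t, h_bm=hh, q1=q,
                       Q_bm=2 * np.pi * RR * hh * q, R_i=RR)

    def test_constant_velocity_average(self):
        m = flux_metrics(self._state(0.5), T=1.0)
        assert m.mean_velocity_um_s == pytest.approx(0.5 * 1e4, rel=1e-12)

    def test_zero_mean_oscillation(self):
        st = self._state(0.0)
        st.q1 = np.sin(2 * np.pi * st.t)[:, None] * np.ones(11)[None, :]
        st.Q_bm = 2 * np.pi * st.R_i * st.h_bm * st.q1
        m = flux_metrics(st, T=1.0)
        assert abs(m.mean_velocity_um_s) < 1e-8

    def test_unit_conversion_arithmetic(self):
        m = flux_metrics(self._state(1.0), T=1.0)
        # Q = 2π · 0.14 · 2e-5 cm^3/s = 1.76e-5 cm^3/s = 1.76e7 μm^3/s
        assert m.mean_flux_um3_s == pytest.approx(
            2 * np.pi * 0.14 * 2e-5 * 1e12, rel=1e-12)
        assert m.mean_flux_um3_s == pytest.approx(1.76e7, rel=5e-3)
        assert m.direction == 1

    def test_window_shorter_than_period_rejected(self):
        with pytest.raises(ValueError):
            flux_metrics(self._state(1.0, nt=5), T=10.0)


class TestThreshold:
    def test_linear_function_root(self):
        root, (lo, hi), _ = reverse_flow_threshold(
            lambda r: r - 0.3, lo=0.01, hi=1.0, tol=1e-6)
        assert root == pytest.approx(0.3, abs=1e-5)
        assert hi - lo < 1e-6

    def test_tolerance_contract(self):
        _, b1, _ = reverse_flow_threshold(lambda r: r - 0.4, tol=1e-3)
        _, b2, _ = reverse_flow_threshold(lambda r: r - 0.4, tol=5e-4)
        assert (b2[1] - b2[0]) <= (b1[1] - b1[0]) / 2 + 1e-12

    def test_no_sign_change_reported(self):
        with pytest.raises(NoThresholdError):
            reverse_flow_threshold(lambda r: 1.0 + r, lo=0.01, hi=1.0)
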