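"""Forward-model physics: equilibrium laws, relaxation times, dynamic solver."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nlrm2.constants import CONST
from nlrm2.datatypes import DriveConditions, default_drive
from nlrm2.physics import (
    ensemble_m2,
    langevin,
    langevin_d2,
    lognormal_moment_nodes,
    neel_time,
    quasistatic_m2_fft,
    quasistatic_m2_perturbative,
    single_particle_m2,
    single_particle_m2_timestep,
)

POINT_DRIVE = DriveConditions(h=13.8, f=15.7e6, T=300.0, H_grid=np.array([0.0]))


class TestLangevin:
    def test_reference_value(self):
        # coth(1) - 1 to five digits
        assert langevin(1.0) == pytest.approx(0.31304, abs=5e-6)

    def test_zero(self):
        assert langevin(0.0) == 0.0

    @given(st.floats(min_value=1e-6, max_value=50.0))
    @settings(max_examples=50, deadline=None)
    def test_odd(self, xi):
        assert langevin(-xi) == pytest.approx(-langevin(xi), rel=1e-12)

    def test_series_matches_closed_form_at_switch(self):
        xi = 1.5e-3  # just above the switch: closed form still accurate here
        series = xi / 3.0 - xi**3 / 45.0
        assert langevin(xi) == pytest.approx(series, rel=1e-9)

    def test_saturation(self):
        assert langevin(1e3) == pytest.approx(1.0, rel=1e-2)

    def test_d2_series_matches_closed_form_at_switch(self):
        xi = 0.12  # closed form, compared against the series branch value
        series = -2.0 * xi / 15.0 + 8.0 * xi**3 / 189.0 - xi**5 / 112.5
        assert langevin_d2(xi) == pytest.approx(series, rel=1e-6)


class TestNeelTime:
    @pytest.mark.parametrize(
        "M_C, alpha, expected, rtol",
        [
            (31580.0, 0.2057, 1.020, 0.005),  # solution row, sub-percent
            (25700.0, 1.036, 0.332, 0.04),
            (26400.0, 0.287, 0.651, 0.04),
            (20600.0, 0.291, 0.502, 0.04),
        ],
    )
    def test_reference_rows(self, M_C, alpha, expected, rtol):
        assert neel_time(M_C, alpha, 300.0) == pytest.approx(expected, rel=rtol)

    def test_linear_in_moment(self):
        assert neel_time(2 * 31580, 0.2, 300) == pytest.approx(
            2 * neel_time(31580, 0.2, 300), rel=1e-12
        )

    def test_zero_damping_rejected(self):
        with pytest.raises(ValueError):
            neel_time(31580, 0.0, 300)


class TestQuasistatic:
    def test_perturbative_matches_fft(self):
        pert = quasistatic_m2_perturbative([100.0], 30000, 13.8, 300)
        fft = quasistatic_m2_fft([100.0], 30000, 13.8, 300)
        assert pert.re[0] == pytest.approx(fft.re[0], rel=0.01)
        assert fft.im[0] == pytest.approx(0.0, abs=1e-12 * abs(fft.re[0]))

    def test_zero_field_kills_even_harmonics(self):
        fft = quasistatic_m2_fft([0.0], 30000, 13.8, 300)
        assert fft.re[0] == pytest.approx(0.0, abs=1e-30)
        assert fft.im[0] == pytest.approx(0.0, abs=1e-30)

    def test_small_drive_limit_recovers_perturbative(self):
        # response/h^2 converges to the perturbative coefficient as h -> 0
        m, T, H = 30000, 300.0, 120.0
        coef = quasistatic_m2_perturbative([H], m, 1.0, T).re[0]  # -(1/4) M''
        prev = None
        for h in (4.0, 2.0, 1.0):
            val = quasistatic_m2_fft([H], m, h, T).re[0] / h**2
            err = abs(val - coef) / abs(coef)
            if prev is not None:
                assert err < 0.35 * prev  # ~O(h^2) convergence
            prev = err
        assert err < 1e-3

    def test_h_squared_scaling(self):
        # log-log slope of the 2w amplitude vs h is 2.00 +- 0.02 for small h
        m, H = 31580, 100.0
        a1 = abs(quasistatic_m2_fft([H], m, 1.0, 300).re[0])
        a2 = abs(quasistatic_m2_fft([H], m, 2.0, 300).re[0])
        slope = np.log(a2 / a1) / np.log(2.0)
        assert slope == pytest.approx(2.0, abs=0.02)

    def test_decay_at_large_field(self):
        resp = quasistatic_m2_perturbative([50.0, 5000.0], 30000, 13.8, 300)
        assert abs(resp.re[1]) < 1e-2 * abs(resp.re[0])


class TestSingleParticle:
    def test_odd_in_field(self):
        resp = single_particle_m2([-150.0, 150.0], 31580, 1.02, 8.3, POINT_DRIVE)
        assert resp.re[0] == pytest.approx(-resp.re[1], rel=1e-10)
        assert resp.im[0] == pytest.approx(-resp.im[1], rel=1e-10)

    def test_zero_field(self):
        resp = single_particle_m2([0.0], 31580, 1.02, 8.3, POINT_DRIVE)
        assert resp.re[0] == 0.0
        assert resp.im[0] == 0.0

    def test_quasistatic_limit(self):
        # with f scaled far down the dynamic solution becomes adiabatic
        H = [50.0, 150.0, 300.0]
        slow = dataclasses.replace(POINT_DRIVE, f=15.7e3)
        dyn = single_particle_m2(H, 31580, 1.02, 8.3, slow)
        eq = quasistatic_m2_fft(H, 31580, 13.8, 300, E_A=8.3)
        peak = np.abs(eq.re).max()
        assert np.abs(dyn.re - eq.re).max() < 1e-3 * peak
        assert np.abs(dyn.im).max() < 1e-2 * peak

    def test_matches_time_stepping(self):
        # quick cross-check of the two solution methods (full grid in the
        # acceptance suite)
        H = [100.0]
        hb = single_particle_m2(H, 31580, 1.02, 8.3, POINT_DRIVE)
        ts = single_particle_m2_timestep(H, 31580, 1.02, 8.3, POINT_DRIVE, l_max=24)
        rel = abs(hb.complex[0] - ts.complex[0]) / abs(ts.complex[0])
        assert rel < 1e-3

    def test_finite_frequency_produces_quadrature(self):
        resp = single_particle_m2([100.0], 31580, 1.02, 8.3, POINT_DRIVE)
        assert abs(resp.im[0]) > 0.05 * abs(resp.re[0])


class TestEnsemble:
    def test_monodisperse_identity(self, solution):
        mono = dataclasses.replace(solution, sigma=0.0)
        drive = default_drive(7)
        ens = ensemble_m2(mono, drive)
        single = single_particle_m2(
            drive.H_grid, solution.M_C, solution.tau_N, solution.E_A, drive
        )
        n_p = solution.M_tilde / (solution.M_C * CONST.mu_B)
        np.testing.assert_allclose(ens.re, n_p * single.re, rtol=1e-12)
        np.testing.assert_allclose(ens.im, n_p * single.im, rtol=1e-12)

    def test_odd_in_field(self, solution_model):
        re, im = solution_model.real, solution_model.imag
        peak = np.abs(re).max()
        np.testing.assert_allclose(re, -re[::-1], atol=1e-9 * peak)
        np.testing.assert_allclose(im, -im[::-1], atol=1e-9 * peak)

    def test_linear_in_magnetization(self, solution):
        drive = default_drive(7)
        c1 = ensemble_m2(solution, drive)
        c2 = ensemble_m2(
            dataclasses.replace(solution, M_tilde=2 * solution.M_tilde), drive
        )
        np.testing.assert_allclose(c2.re, 2 * c1.re, rtol=1e-12)
        np.testing.assert_allclose(c2.im, 2 * c1.im, rtol=1e-12)

    def test_sign_flip_switch(self, solution):
        drive = default_drive(5)
        a = ensemble_m2(solution, drive)
        b = ensemble_m2(solution, drive, sign_flip=True)
        np.testing.assert_allclose(b.re, -a.re)
        np.testing.assert_allclose(b.im, -a.im)


class TestMomentDistribution:
    def test_minimum_node_count_enforced(self):
        with pytest.raises(ValueError):
            lognormal_moment_nodes(31580, 0.7, n_nodes=11)

    def test_weights_normalized_and_mean_preserved(self):
        nodes, w = lognormal_moment_nodes(31580, 0.734, n_nodes=41)
        assert w.sum() == pytest.approx(1.0, rel=1e-12)
        # truncated lognormal mean within a percent of the nominal mean
        assert (w * nodes).sum() == pytest.approx(31580, rel=0.01)

    def test_degenerate_sigma(self):
        nodes, w = lognormal_moment_nodes(31580, 0.0)
        assert len(nodes) == 1 and nodes[0] == 31580 and w[0] == 1.0
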