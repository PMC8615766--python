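"""Preprocessing: branch averaging, odd-part extraction, hysteresis screening."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nlrm2.datatypes import DriveConditions, FieldSweepBranch
from nlrm2.signal_processing import (
    HysteresisThresholds,
    PreprocessingError,
    antisymmetrize,
    average_branches,
    hysteresis_index,
    preprocess,
    superparamagnetic_check,
)

DRIVE = DriveConditions(h=13.8, f=15.7e6, T=300.0, H_grid=np.array([0.0]))


def make_branch(H, re, im=None, direction="direct", F_sc=8.0, label="x"):
    re = np.asarray(re, dtype=float)
    im = np.zeros_like(re) if im is None else np.asarray(im, dtype=float)
    return FieldSweepBranch(
        H=np.asarray(H, dtype=float), re=re, im=im,
        direction=direction, F_sc=F_sc, drive=DRIVE, label=label,
    )


H_GRID = np.linspace(-300, 300, 61)


class TestAverageBranches:
    def test_mean_of_identical_branches(self):
        d = make_branch(H_GRID, np.sin(H_GRID / 90))
        r = dataclasses.replace(d, direction="reverse")
        avg = average_branches(d, r)
        np.testing.assert_allclose(avg.re, d.re)

    def test_opposite_branches_cancel(self):
        d = make_branch(H_GRID, np.sin(H_GRID / 90))
        r = make_branch(H_GRID, -np.sin(H_GRID / 90), direction="reverse")
        avg = average_branches(d, r)
        np.testing.assert_allclose(avg.re, 0.0, atol=1e-15)

    def test_symmetric_offsets_cancel(self):
        base = np.sin(H_GRID / 90)
        delta = 0.07
        d = make_branch(H_GRID, base + delta)
        r = make_branch(H_GRID, base - delta, direction="reverse")
        avg = average_branches(d, r)
        np.testing.assert_allclose(avg.re, base, atol=1e-14)

    def test_mismatched_scan_frequency_rejected(self):
        d = make_branch(H_GRID, H_GRID)
        r = make_branch(H_GRID, H_GRID, direction="reverse", F_sc=0.25)
        with pytest.raises(PreprocessingError):
            average_branches(d, r)

    def test_insufficient_overlap_rejected(self):
        d = make_branch(np.linspace(-300, -50, 26), np.ones(26))
        r = make_branch(np.linspace(-60, 300, 37), np.ones(37), direction="reverse")
        with pytest.raises(PreprocessingError):
            average_branches(d, r)


class TestAntisymmetrize:
    def test_even_input_vanishes(self):
        curve = antisymmetrize(make_branch(H_GRID, H_GRID**2))
        np.testing.assert_allclose(curve.re, 0.0, atol=1e-9)

    def test_odd_input_unchanged(self):
        curve = antisymmetrize(make_branch(H_GRID, H_GRID**3))
        pos = H_GRID[H_GRID >= 0]
        np.testing.assert_allclose(curve.re, pos**3, rtol=1e-12)

    def test_mixed_polynomial(self):
        # s(H) = H^2 + 3H has odd part 3H
        curve = antisymmetrize(make_branch(H_GRID, H_GRID**2 + 3 * H_GRID))
        np.testing.assert_allclose(curve.re, 3 * curve.H, rtol=1e-12)

    def test_idempotent_on_odd_part(self):
        branch = make_branch(H_GRID, H_GRID**2 + 3 * H_GRID, im=np.cos(H_GRID / 40))
        once = antisymmetrize(branch)
        # re-feed the odd curve mirrored onto the signed axis
        signed = make_branch(
            np.concatenate([-once.H[:0:-1], once.H]),
            np.concatenate([-once.re[:0:-1], once.re]),
            im=np.concatenate([-once.im[:0:-1], once.im]),
        )
        twice = antisymmetrize(signed)
        np.testing.assert_allclose(twice.re, once.re, rtol=1e-12, atol=1e-15)
        np.testing.assert_allclose(twice.im, once.im, rtol=1e-12, atol=1e-15)

    def test_single_sign_rejected(self):
        with pytest.raises(PreprocessingError):
            antisymmetrize(make_branch(np.linspace(1, 300, 30), np.ones(30)))

    def test_commutes_with_averaging(self, solution_model, drive121):
        # on noiseless model data avg->antisym equals antisym of each branch
        d = make_branch(drive121.H_grid, solution_model.real, solution_model.imag)
        r = dataclasses.replace(d, direction="reverse")
        c1 = antisymmetrize(average_branches(d, r))
        c2 = antisymmetrize(d)
        np.testing.assert_allclose(c1.re, c2.re, rtol=1e-12, atol=1e-18)


class TestHysteresisIndex:
    def test_identical_branches(self):
        d = make_branch(H_GRID, np.sin(H_GRID / 90))
        r = dataclasses.replace(d, direction="reverse")
        assert hysteresis_index(d, r) == 0.0

    def test_half_ptp_shift_gives_half(self):
        s = np.sin(H_GRID / 100)
        d = make_branch(H_GRID, s)
        r = make_branch(H_GRID, s + np.ptp(s) / 2, direction="reverse")
        assert hysteresis_index(d, r) == pytest.approx(0.5, rel=1e-12)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, kappa):
        s = np.sin(H_GRID / 100)
        d = make_branch(H_GRID, kappa * (s + 0.1))
        r = make_branch(H_GRID, kappa * (s - 0.1), direction="reverse")
        ref_d = make_branch(H_GRID, s + 0.1)
        ref_r = make_branch(H_GRID, s - 0.1, direction="reverse")
        assert hysteresis_index(d, r) == pytest.approx(
            hysteresis_index(ref_d, ref_r), rel=1e-9
        )

    def test_flat_signal_rejected(self):
        d = make_branch(H_GRID, np.full_like(H_GRID, 0.3))
        r = make_branch(H_GRID, np.full_like(H_GRID, -0.3), direction="reverse")
        with pytest.raises(PreprocessingError):
            hysteresis_index(d, r)


def offset_pair(offset, F_sc):
    """Branch pair with a branch-antisymmetric offset of the given fraction."""
    s = np.sin(H_GRID / 100)
    shift = offset * np.ptp(s) / 2
    d = make_branch(H_GRID, s + shift, F_sc=F_sc)
    r = make_branch(H_GRID, s - shift, direction="reverse", F_sc=F_sc)
    return d, r


class TestSuperparamagneticCheck:
    def test_clean_data_pass(self):
        rep = superparamagnetic_check(offset_pair(0.0, 8.0), offset_pair(0.0, 0.25))
        assert rep.flag == "PASS"

    def test_persistent_hysteresis_fails(self):
        rep = superparamagnetic_check(offset_pair(0.1, 8.0), offset_pair(0.1, 0.25))
        assert rep.flag == "FAIL"

    def test_relaxing_hysteresis_passes(self):
        rep = superparamagnetic_check(offset_pair(0.1, 8.0), offset_pair(0.0, 0.25))
        assert rep.flag == "PASS"
        assert any("decreases" in n for n in rep.notes)

    def test_ambiguous_behaviour_warns(self):
        rep = superparamagnetic_check(offset_pair(0.3, 8.0), offset_pair(0.12, 0.25))
        assert rep.flag == "WARN"

    def test_deterministic(self):
        args = (offset_pair(0.1, 8.0), offset_pair(0.02, 0.25))
        assert superparamagnetic_check(*args) == superparamagnetic_check(*args)

    def test_thresholds_configurable(self):
        strict = HysteresisThresholds(index_max=1e-6)
        rep = superparamagnetic_check(
            offset_pair(0.01, 8.0), offset_pair(0.01, 0.25), strict
        )
        assert rep.flag == "FAIL"


class TestPreprocess:
    def test_noiseless_model_roundtrip(self, noiseless_curve, solution_model, drive121):
        H = drive121.H_grid
        pos = H[H >= 0]
        model_re = np.interp(pos, H, solution_model.real)
        np.testing.assert_allclose(noiseless_curve.re, model_re, rtol=1e-9)
        assert noiseless_curve.hysteresis_index == pytest.approx(0.0, abs=1e-12)
        assert noiseless_curve.re[0] == 0.0 and noiseless_curve.im[0] == 0.0
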