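"""Sweep preprocessing: branch averaging, antisymmetrization, hysteresis checks.

Raw measurements are recorded as a direct scan (dc field swept up) and
a reverse scan (swept down) at one or two scan frequencies.  For a
superparamagnetic specimen the two branches coincide up to noise; a
persistent branch separation (field hysteresis) signals a spontaneous
ferromagnetic moment and invalidates the superparamagnetic fitting
model.  The model response is odd in H, so before fitting the branches
are averaged and the odd part is extracted on the nonnegative field
axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import FieldSweepBranch, M2Curve

__all__ = [
    "average_branches",
    "antisymmetrize",
    "hysteresis_index",
    "superparamagnetic_check",
    "preprocess",
    "ApplicabilityReport",
    "HysteresisThresholds",
    "PreprocessingError",
]


class PreprocessingError(ValueError):
    """Raised for incompatible or degenerate sweep inputs."""


@dataclass(frozen=True)
class HysteresisThresholds:
    """Decision thresholds of the superparamagnetic applicability test.

    ``index_max``: hysteresis index below which a specimen passes
    outright at the fast scan.  ``decrease_min``: fractional decrease
    of the index from the fast to the slow scan that, combined with a
    slow-scan index below ``index_max``, also passes (scan-rate
    dependent hysteresis relaxes away, as superparamagnets do).
    ``equal_tol``: fractional difference below which the two indices
    count as "practically the same", the multi-domain failure mode.
    """

    index_max: float = 0.05
    decrease_min: float = 0.30
    equal_tol: float = 0.10


@dataclass(frozen=True)
class ApplicabilityReport:
    flag: str  # PASS | WARN | FAIL
    indices: dict  # F_sc -> hysteresis index
    notes: tuple = ()


def _check_compatible(direct: FieldSweepBranch, reverse: FieldSweepBranch):
    if direct.drive.h != reverse.drive.h or direct.drive.f != reverse.drive.f \
            or direct.drive.T != reverse.drive.T:
        raise PreprocessingError("branches have mismatched drive conditions")
    if direct.F_sc != reverse.F_sc:
        raise PreprocessingError("branches have mismatched scan frequencies")


def _common_grid(direct: FieldSweepBranch, reverse: FieldSweepBranch) -> np.ndarray:
    lo = max(direct.H.min(), reverse.H.min())
    hi = min(direct.H.max(), reverse.H.max())
    union_lo = min(direct.H.min(), reverse.H.min())
    union_hi = max(direct.H.max(), reverse.H.max())
    if hi <= lo:
        raise PreprocessingError("branches do not overlap in field")
    if (hi - lo) < 0.5 * (union_hi - union_lo):
        raise PreprocessingError("branches overlap over less than half the field range")
    grid = np.union1d(direct.H, reverse.H)
    return grid[(grid >= lo) & (grid <= hi)]


def _interp_branch(branch: FieldSweepBranch, grid: np.ndarray):
    order = np.argsort(branch.H)
    H = branch.H[order]
    re = np.interp(grid, H, branch.re[order])
    im = np.interp(grid, H, branch.im[order])
    return re, im


def average_branches(direct: FieldSweepBranch, reverse: FieldSweepBranch) -> FieldSweepBranch:
    """Pointwise complex mean of the direct and reverse scans.

    Both branches are linearly interpolated onto the union of their
    sample points clipped to the overlapping field range.  Averaging
    cancels any branch-antisymmetric hysteresis component exactly.
    """
    _check_compatible(direct, reverse)
    grid = _common_grid(direct, reverse)
    d_re, d_im = _interp_branch(direct, grid)
    r_re, r_im = _interp_branch(reverse, grid)
    return FieldSweepBranch(
        H=grid,
        re=0.5 * (d_re + r_re),
        im=0.5 * (d_im + r_im),
        direction="direct",
        F_sc=direct.F_sc,
        drive=direct.drive,
        label=direct.label or reverse.label,
        specimen_mass=direct.specimen_mass,
    )


def antisymmetrize(branch: FieldSweepBranch) -> M2Curve:
    """Extract the odd part (s(H) - s(-H))/2 on the nonnegative field grid.

    The model response is strictly odd in H, so the even content of a
    measured sweep is instrumental offset/background; discarding it
    folds the two field signs into one fit-ready half-curve that passes
    through zero at H = 0 exactly.
    """
    if branch.H.min() >= 0 or branch.H.max() <= 0:
        raise PreprocessingError("antisymmetrization needs both field signs")
    order = np.argsort(branch.H)
    H = branch.H[order]
    re = branch.re[order]
    im = branch.im[order]
    pos = H[H >= 0]
    if len(pos) == 0 or pos[0] != 0.0:
        pos = np.concatenate([[0.0], pos])
    pos = pos[pos <= -H.min()]  # -H must be interpolable
    re_o = 0.5 * (np.interp(pos, H, re) - np.interp(-pos, H, re))
    im_o = 0.5 * (np.interp(pos, H, im) - np.interp(-pos, H, im))
    re_o[0] = 0.0
    im_o[0] = 0.0
    return M2Curve(
        H=pos, re=re_o, im=im_o,
        drive=branch.drive,
        provenance=(branch.label, branch.F_sc),
        label=branch.label,
    )


def hysteresis_index(direct: FieldSweepBranch, reverse: FieldSweepBranch) -> float:
    """Dimensionless branch-separation measure of one scan-frequency pair.

    Mean absolute complex difference between the branches divided by
    the peak-to-peak amplitude of their mean (combined over both
    channels in quadrature).  Zero for identical branches; invariant
    under a common rescaling of both branches.
    """
    _check_compatible(direct, reverse)
    grid = _common_grid(direct, reverse)
    d_re, d_im = _interp_branch(direct, grid)
    r_re, r_im = _interp_branch(reverse, grid)
    diff = np.abs((d_re - r_re) + 1j * (d_im - r_im)).mean()
    mean_re = 0.5 * (d_re + r_re)
    mean_im = 0.5 * (d_im + r_im)
    ptp = np.hypot(np.ptp(mean_re), np.ptp(mean_im))
    if ptp == 0.0:
        raise PreprocessingError("flat mean signal: hysteresis index undefined")
    return float(diff / ptp)


def superparamagnetic_check(
    sweeps_8Hz: tuple,
    sweeps_0p25Hz: tuple,
    thresholds: HysteresisThresholds = HysteresisThresholds(),
) -> ApplicabilityReport:
    """Decide whether the superparamagnetic fitting model applies.

    Parameters are (direct, reverse) branch pairs at the fast (8 Hz)
    and slow (0.25 Hz) scan frequencies.  PASS: negligible hysteresis
    at the fast scan, or hysteresis that relaxes away at the slow scan.
    FAIL: practically the same, above-threshold hysteresis at both scan
    rates — the signature of a multi-domain / ferromagnetic fraction.
    Anything in between is WARN.
    """
    idx_fast = hysteresis_index(*sweeps_8Hz)
    idx_slow = hysteresis_index(*sweeps_0p25Hz)
    indices = {sweeps_8Hz[0].F_sc: idx_fast, sweeps_0p25Hz[0].F_sc: idx_slow}
    notes = []

    if idx_fast < thresholds.index_max:
        flag = "PASS"
        notes.append(f"fast-scan hysteresis index {idx_fast:.3g} below threshold")
    elif (
        idx_fast > 0
        and (idx_fast - idx_slow) / idx_fast >= thresholds.decrease_min
        and idx_slow < thresholds.index_max
    ):
        flag = "PASS"
        notes.append(
            f"hysteresis decreases with scan rate ({idx_fast:.3g} -> {idx_slow:.3g})"
        )
    elif abs(idx_fast - idx_slow) <= thresholds.equal_tol * max(idx_fast, idx_slow):
        flag = "FAIL"
        notes.append(
            "practically the same above-threshold hysteresis at both scan "
            "frequencies: multi-domain / ferromagnetic fraction suspected"
        )
    else:
        flag = "WARN"
        notes.append(
            f"ambiguous hysteresis behaviour (indices {idx_fast:.3g}, {idx_slow:.3g})"
        )
    return ApplicabilityReport(flag=flag, indices=indices, notes=tuple(notes))


def preprocess(
    direct: FieldSweepBranch,
    reverse: FieldSweepBranch,
    report: ApplicabilityReport | None = None,
) -> M2Curve:
    """Average the two branches, antisymmetrize, and attach applicability.

    Convenience wrapper implementing the standard preprocessing order:
    branch average first, then odd-part extraction.
    """
    avg = average_branches(direct, reverse)
    curve = antisymmetrize(avg)
    idx = hysteresis_index(direct, reverse)
    flag = report.flag if report is not None else "PASS"
    return M2Curve(
        H=curve.H, re=curve.re, im=curve.im,
        drive=curve.drive,
        provenance=(direct.label, direct.F_sc),
        hysteresis_index=idx,
        applicability=flag,
        label=direct.label,
    )
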