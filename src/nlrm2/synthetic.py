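"""Synthetic raw field sweeps with known ground truth.

The instrument data this pipeline targets (direct/reverse dc-field
scans of the complex second harmonic, per-gram normalized, at two scan
frequencies) are not publicly released, so this module generates
realistic stand-ins from known ensemble parameters: the forward model
evaluated on the signed field grid, plus additive homoscedastic
Gaussian noise and an optional scan-frequency-dependent
branch-antisymmetric offset that emulates field hysteresis — the
controllable pathology that the applicability check must catch.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path

import numpy as np

from .biodistribution import count_centers, count_mscs
from .datatypes import (
    DriveConditions,
    EnsembleParams,
    FieldSweepBranch,
    NoiseModel,
    PhantomStudy,
    default_drive,
)
from .physics import ensemble_m2
from .reference import REFERENCE_STUDY, reference_calibration, solution_params

__all__ = [
    "simulate_sweep",
    "make_phantom_study",
    "rat1_phantom",
    "ORGAN_NAMES",
]

#: Organs sampled in the biodistribution protocol.
ORGAN_NAMES = (
    "brain", "tumor", "kidney", "pancreas", "lungs",
    "liver", "spleen", "heart", "muscle", "skin",
)


def simulate_sweep(
    params: EnsembleParams,
    drive: DriveConditions,
    F_sc: float,
    noise: NoiseModel,
    label: str = "",
    model: "np.ndarray | None" = None,
) -> tuple:
    """Generate one (direct, reverse) branch pair at scan frequency ``F_sc``.

    The underlying curve is the ensemble forward model on the signed
    ``drive.H_grid`` (independent of ``F_sc``; precompute it once and
    pass ``model`` as a complex array to amortize over scan
    frequencies).  The hysteresis offset configured for this ``F_sc``
    shifts the direct branch up and the reverse branch down by the
    given fraction of each channel's peak amplitude; Gaussian noise of
    ``noise.sigma_abs`` is then added per point and channel.
    Deterministic given ``noise.seed`` (the seed is combined with
    ``F_sc`` and the label so branches differ but reruns do not).
    """
    H = drive.H_grid
    if model is None:
        resp = ensemble_m2(params, drive)
        model = resp.complex
    off_frac = noise.hysteresis_offset.get(F_sc, 0.0)
    d_re = np.abs(model.real).max() * off_frac
    d_im = np.abs(model.imag).max() * off_frac

    key = zlib.crc32(f"{label}|{F_sc:g}".encode()) % (2**31)
    rng = np.random.default_rng([noise.seed, key])
    branches = []
    for direction, sign in (("direct", +1.0), ("reverse", -1.0)):
        re = model.real + sign * d_re + noise.sigma_abs * rng.standard_normal(len(H))
        im = model.imag + sign * d_im + noise.sigma_abs * rng.standard_normal(len(H))
        branches.append(FieldSweepBranch(
            H=H, re=re, im=im, direction=direction,
            F_sc=F_sc, drive=drive, label=label,
        ))
    return tuple(branches)


def rat1_phantom(
    drive: DriveConditions | None = None,
    noise: NoiseModel | None = None,
    organs: "tuple | None" = None,
    seed: int = 0,
) -> PhantomStudy:
    """Phantom study preset mirroring the first injected animal.

    Each organ takes its published saturation magnetization.  Organs
    with published magnetic shape parameters use them directly; for the
    rest the effective mean aggregate moment is derived from the
    published center count (``M_C = M_tilde / (N_P mu_B)``, the same
    identity the quantification relies on) while the distribution
    width, damping and anisotropy are inherited from the injection
    solution — the aggregates are unchanged after injection, so organ
    signals differ mainly in amplitude and mean moment.
    """
    from .constants import CONST
    from .physics import neel_time

    drive = drive if drive is not None else default_drive()
    sol = solution_params()
    table = REFERENCE_STUDY[REFERENCE_STUDY.subject == "rat1"]
    if organs is not None:
        table = table[table.organ.isin(organs)]
    params = {}
    for _, row in table.iterrows():
        if row.status == "fitted" and not np.isnan(row.M_C):
            params[row.organ] = EnsembleParams(
                M_tilde=float(row.M_tilde), M_C=float(row.M_C),
                sigma=float(row.sigma), alpha=float(row.alpha),
                tau_N=float(row.tau_N), E_A=float(row.E_A),
            )
        else:
            m_c = float(row.M_tilde) / (float(row.N_P) * CONST.mu_B)
            params[row.organ] = dataclasses.replace(
                sol, M_tilde=float(row.M_tilde), M_C=m_c,
                tau_N=neel_time(m_c, sol.alpha, drive.T),
            )
    if noise is None:
        noise = NoiseModel(sigma_abs=0.0, seed=seed)
    return PhantomStudy(
        subject="rat1", organs=params, drive=drive, noise=noise,
        solution=sol,
    )


def default_noise_sigma(study: PhantomStudy, fraction: float = 0.01) -> float:
    """Instrument-noise default: a fraction of the solution-row peak |Re|."""
    sol = study.solution if study.solution is not None else solution_params()
    resp = ensemble_m2(sol, study.drive)
    return float(fraction * np.abs(resp.re).max())


def make_phantom_study(study: PhantomStudy, out_dir) -> dict:
    """Write sweep files for every (specimen, F_sc) plus a truth manifest.

    One file per specimen and scan frequency, each holding both
    branches, written through :mod:`nlrm2.sweepio`.  The manifest
    (``manifest.json``) records the true ensemble parameters, the
    derived true center and cell counts per gram, the noise settings
    and the seed.  Returns the manifest as a dict.
    """
    from . import sweepio  # local import to keep module layers acyclic

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cal = reference_calibration()

    specimens = dict(study.organs)
    if study.solution is not None:
        specimens = {"solution": study.solution, **specimens}

    manifest = {
        "subject": study.subject,
        "seed": study.noise.seed,
        "noise_sigma_abs": study.noise.sigma_abs,
        "hysteresis_offset": {str(k): v for k, v in study.noise.hysteresis_offset.items()},
        "F_sc_values": list(study.F_sc_values),
        "drive": {"h_Oe": study.drive.h, "f_Hz": study.drive.f, "T_K": study.drive.T},
        "specimens": {},
        "files": [],
    }
    for name, params in specimens.items():
        model = ensemble_m2(params, study.drive).complex
        n_p = count_centers(params.M_tilde, params.M_C)
        manifest["specimens"][name] = {
            "M_tilde": params.M_tilde, "M_C": params.M_C,
            "sigma": params.sigma, "alpha": params.alpha,
            "tau_N": params.tau_N, "E_A": params.E_A,
            "N_P": n_p, "N_MSC": count_mscs(n_p, cal),
        }
        for F_sc in study.F_sc_values:
            branches = simulate_sweep(
                params, study.drive, F_sc, study.noise, label=name, model=model
            )
            fname = f"{name}_Fsc{F_sc:g}Hz.tsv"
            sweepio.write_sweep(
                branches, out / fname,
                metadata={
                    "specimen": name, "organ": name, "subject": study.subject,
                    "seed": study.noise.seed,
                },
            )
            manifest["files"].append(fname)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
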