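"""Reference parameter sets from the rat glioma biodistribution study.

These are the published per-organ fit results for two rats injected
intravenously with SPION-labeled mesenchymal stem cells (1.5e5 cells),
plus the injection solution itself, measured 24 h after administration.
They serve three purposes here: validation targets for the arithmetic
identities (center and cell counts, Neel-time consistency, organ
ranking), realistic parameter presets for the synthetic-data
generator, and the calibration reference linking aggregates to cells.

``M_tilde`` is the saturation magnetization (emu/g), ``N_P`` the
number of magnetically active centers (aggregates) per gram, ``N_MSC``
the labeled stem cells per gram, ``M_C`` the mean aggregate moment
(Bohr magnetons), ``sigma`` the lognormal log-width, ``alpha`` the
damping factor, ``tau_N`` the Neel time (ns) and ``E_A`` the
anisotropy energy (K).  Rows with status other than ``fitted`` were
not fitted magnetically: their magnetization was estimated by scaling
response amplitudes (and organ masses) against a fitted organ.
"""

from __future__ import annotations

import pandas as pd

from .datatypes import CalibrationReference, EnsembleParams

__all__ = [
    "REFERENCE_STUDY",
    "solution_params",
    "reference_params",
    "reference_calibration",
    "PUBLISHED_RANKING",
]

_COLUMNS = [
    "organ", "subject", "M_tilde", "N_P", "N_MSC",
    "M_C", "sigma", "alpha", "tau_N", "E_A", "status",
]

_ROWS = [
    ("solution", "solution", 3.633e-6, 1.24e10, 1.5e5, 31580.0, 0.734, 0.2057, 1.020, 8.3, "fitted"),
    ("tumor",    "rat1", 6.495e-6, 2.65e10,  3.2e5, 26400.0, 0.485, 0.287,  0.651, 0.0, "fitted"),
    ("brain",    "rat1", 4.303e-7, 1.18e9,   1.4e4, 39400.0, 0.241, 0.207,  1.29,  0.0, "fitted"),
    ("lungs",    "rat1", 4.26e-6,  1.74e10,  2.1e5, None, None, None, None, None, "mass-scaled"),
    ("spleen",   "rat1", 4.093e-6, 1.578e10, 1.9e5, 28000.0, 0.758, 0.2374, 0.810, 17.4, "fitted"),
    ("muscle",   "rat1", 6.77e-6,  2.85e10,  3.4e5, None, None, None, None, None, "mass-scaled"),
    ("liver",    "rat1", 6.618e-6, 3.24e10,  3.9e5, None, None, None, None, None, "mass-scaled"),
    ("skin",     "rat1", 1.52e-6,  4.17e9,   5.0e4, None, None, None, None, None, "amplitude-scaled"),
    ("pancreas", "rat1", 2.64e-7,  0.72e9,   8.7e3, None, None, None, None, None, "amplitude-scaled"),
    ("tumor",    "rat2", 3.17e-6,  1.29e10,  1.6e5, None, None, None, None, None, "mass-scaled"),
    ("brain",    "rat2", 2.17e-7,  0.59e9,   7.1e3, None, None, None, None, None, "mass-scaled"),
    ("lungs",    "rat2", 2.479e-5, 1.01e11,  1.2e6, 26700.0, 0.786, 0.2421, 0.759, 13.3, "fitted"),
    ("spleen",   "rat2", 2.61e-6,  1.01e10,  1.2e5, None, None, None, None, None, "mass-scaled"),
    ("muscle",   "rat2", 1.572e-6, 0.662e10, 8.0e4, 25700.0, 0.283, 1.036,  0.332, 8.22, "fitted"),
    ("liver",    "rat2", 6.64e-6,  3.48e10,  4.2e5, 20600.0, 0.862, 0.291,  0.502, 0.0, "fitted"),
    ("skin",     "rat2", 8.78e-6,  2.41e10,  2.9e5, None, None, None, None, None, "amplitude-scaled"),
    ("pancreas", "rat2", 5.44e-7,  1.49e9,   1.8e4, None, None, None, None, None, "amplitude-scaled"),
]

#: Published per-organ quantification table (see module docstring).
REFERENCE_STUDY = pd.DataFrame(_ROWS, columns=_COLUMNS)

#: Published ascending-N_MSC organ orderings for the two animals.
PUBLISHED_RANKING = {
    "rat1": ["pancreas", "brain", "skin", "spleen", "lungs", "tumor", "muscle", "liver"],
    "rat2": ["brain", "pancreas", "muscle", "spleen", "tumor", "skin", "liver", "lungs"],
}


def reference_params(organ: str, subject: str) -> EnsembleParams:
    """EnsembleParams of one fitted reference row."""
    row = REFERENCE_STUDY[
        (REFERENCE_STUDY.organ == organ) & (REFERENCE_STUDY.subject == subject)
    ]
    if row.empty:
        raise KeyError(f"no reference row for {organ!r}/{subject!r}")
    r = row.iloc[0]
    if r.status != "fitted" or pd.isna(r.M_C):
        raise ValueError(f"{organ}/{subject} has no fitted magnetic parameters")
    return EnsembleParams(
        M_tilde=float(r.M_tilde), M_C=float(r.M_C), sigma=float(r.sigma),
        alpha=float(r.alpha), tau_N=float(r.tau_N),
        E_A=float(r.E_A) if r.E_A else 0.0,
    )


def solution_params() -> EnsembleParams:
    """Magnetic parameters of the MSC-SPION injection solution in PBS."""
    return reference_params("solution", "solution")


def reference_calibration() -> CalibrationReference:
    """Calibration facts of the injection solution (aggregates per cell etc.)."""
    return CalibrationReference(solution_params=solution_params())
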