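"""Core containers shared by the measurement, modelling and reporting stages.

The pipeline handles three kinds of objects: raw directional field sweeps
(:class:`FieldSweepBranch`), preprocessed fit-ready response curves
(:class:`M2Curve`), and the magnetic parameter sets describing a
polydisperse superparamagnetic aggregate ensemble
(:class:`EnsembleParams`).  Downstream quantification uses
:class:`CalibrationReference` and :class:`OrganRecord`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "DriveConditions",
    "EnsembleParams",
    "ComplexResponse",
    "FieldSweepBranch",
    "M2Curve",
    "FitResult",
    "CalibrationReference",
    "OrganRecord",
    "NoiseModel",
    "PhantomStudy",
]


def _as_float_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValueError("expected a 1-D array")
    return a


@dataclass(frozen=True)
class DriveConditions:
    """Excitation conditions of a second-harmonic magnetization measurement.

    Parameters
    ----------
    h : float
        ac drive amplitude (Oe); the sample sees ``H + h sin(2 pi f t)``.
    f : float
        ac drive frequency (Hz).
    T : float
        absolute temperature (K).
    H_grid : ndarray
        ordered dc-field values (Oe) at which the response is evaluated.
    """

    h: float
    f: float
    T: float
    H_grid: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "H_grid", _as_float_array(self.H_grid))
        if not (self.h > 0 and self.f > 0 and self.T > 0):
            raise ValueError("h, f and T must be positive")
        if len(self.H_grid) > 1 and not np.all(np.diff(self.H_grid) > 0):
            raise ValueError("H_grid must be strictly increasing")

    @property
    def omega(self) -> float:
        """Angular drive frequency (rad/s)."""
        return 2.0 * np.pi * self.f

    def with_grid(self, H_grid) -> "DriveConditions":
        return replace(self, H_grid=_as_float_array(H_grid))


#: Default drive used by the study emulated here: h = 13.8 Oe at 15.7 MHz,
#: dc field scanned over +-300 Oe, room temperature.
def default_drive(n_points: int = 301) -> DriveConditions:
    return DriveConditions(
        h=13.8, f=15.7e6, T=300.0, H_grid=np.linspace(-300.0, 300.0, n_points)
    )


@dataclass(frozen=True)
class EnsembleParams:
    """Magnetic parameters of a polydisperse aggregate ensemble.

    Attributes
    ----------
    M_tilde : float
        saturation magnetization of the specimen (emu per gram of tissue).
    M_C : float
        ensemble-mean magnetic moment of one aggregate (Bohr magnetons).
    sigma : float
        dimensionless log-width of the lognormal moment distribution.
    alpha : float
        dimensionless damping factor of the magnetization dynamics.
    tau_N : float
        longitudinal free-relaxation (Neel) time (ns).  Kept consistent
        with ``alpha`` through :func:`nlrm2.physics.neel_time`.
    E_A : float
        magnetic anisotropy energy expressed in Kelvin.
    """

    M_tilde: float
    M_C: float
    sigma: float
    alpha: float
    tau_N: float
    E_A: float

    def __post_init__(self):
        if self.M_tilde < 0:
            raise ValueError("M_tilde must be nonnegative")
        if self.M_C <= 0:
            raise ValueError("M_C must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.tau_N <= 0:
            raise ValueError("tau_N must be positive")
        if self.E_A < 0:
            raise ValueError("E_A must be nonnegative")


@dataclass(frozen=True)
class ComplexResponse:
    """Second-harmonic response sampled on a dc-field grid.

    ``re`` is the cos(2wt) coefficient and ``im`` the sin(2wt)
    coefficient of the magnetization under a drive ``h sin(wt)``.
    Units are emu/g for ensemble curves and emu for single particles.
    """

    H: np.ndarray
    re: np.ndarray
    im: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "H", _as_float_array(self.H))
        object.__setattr__(self, "re", _as_float_array(self.re))
        object.__setattr__(self, "im", _as_float_array(self.im))
        if not (len(self.H) == len(self.re) == len(self.im)):
            raise ValueError("H, re, im must have equal length")
        if not (np.all(np.isfinite(self.re)) and np.all(np.isfinite(self.im))):
            raise ValueError("non-finite response values")

    @property
    def complex(self) -> np.ndarray:
        return self.re + 1j * self.im


@dataclass(frozen=True)
class FieldSweepBranch:
    """One directional dc-field scan of the second-harmonic response."""

    H: np.ndarray
    re: np.ndarray
    im: np.ndarray
    direction: str  # "direct" | "reverse"
    F_sc: float  # field scan (cycle) frequency, Hz
    drive: DriveConditions
    label: str = ""
    specimen_mass: Optional[float] = None  # grams, optional

    def __post_init__(self):
        object.__setattr__(self, "H", _as_float_array(self.H))
        object.__setattr__(self, "re", _as_float_array(self.re))
        object.__setattr__(self, "im", _as_float_array(self.im))
        if self.direction not in ("direct", "reverse"):
            raise ValueError("direction must be 'direct' or 'reverse'")
        if not (len(self.H) == len(self.re) == len(self.im)):
            raise ValueError("H, re, im must have equal length")
        if not (np.all(np.isfinite(self.re)) and np.all(np.isfinite(self.im))):
            raise ValueError("non-finite sweep values")

    @property
    def complex(self) -> np.ndarray:
        return self.re + 1j * self.im


@dataclass(frozen=True)
class M2Curve:
    """Branch-averaged, antisymmetrized response on the nonnegative field axis."""

    H: np.ndarray
    re: np.ndarray
    im: np.ndarray
    drive: DriveConditions
    provenance: tuple = ()
    hysteresis_index: Optional[float] = None
    applicability: str = "PASS"  # PASS | WARN | FAIL
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "H", _as_float_array(self.H))
        object.__setattr__(self, "re", _as_float_array(self.re))
        object.__setattr__(self, "im", _as_float_array(self.im))
        if np.any(self.H < 0):
            raise ValueError("M2Curve grid must be nonnegative")
        if len(self.H) and self.H[0] == 0.0:
            if self.re[0] != 0.0 or self.im[0] != 0.0:
                raise ValueError("odd response must vanish at H = 0")

    @property
    def complex(self) -> np.ndarray:
        return self.re + 1j * self.im


@dataclass(frozen=True)
class FitResult:
    """Outcome of inverting one M2Curve into ensemble parameters."""

    params: EnsembleParams
    uncertainties: dict
    residual_rms: float
    n_points: int
    converged: bool
    applicability: str = "PASS"
    label: str = ""
    cost: float = float("nan")


@dataclass(frozen=True)
class CalibrationReference:
    """Injection-solution facts converting aggregate counts into cell counts.

    The labeled-cell suspension used for injection carries on average
    ``aggregates_per_cell`` magnetically active centers (SPION aggregates)
    per stem cell, each aggregate containing ``nanoparticles_per_aggregate``
    nanoparticles.
    """

    aggregates_per_cell: float = 8.27e4
    nanoparticles_per_aggregate: float = 160.0
    cells_injected: float = 1.5e5
    solution_params: Optional[EnsembleParams] = None

    def __post_init__(self):
        if self.aggregates_per_cell <= 0 or self.nanoparticles_per_aggregate <= 0:
            raise ValueError("calibration counts must be positive")
        if self.cells_injected <= 0:
            raise ValueError("cells_injected must be positive")


@dataclass(frozen=True)
class OrganRecord:
    """Per-organ quantification row: magnetics and derived counts per gram."""

    organ: str
    subject: str
    M_tilde: float
    N_P: float
    N_MSC: float
    status: str = "fitted"  # fitted | mass-scaled | amplitude-scaled
    source_fit: Optional[FitResult] = None

    def __post_init__(self):
        if self.status not in ("fitted", "mass-scaled", "amplitude-scaled"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.N_P < 0 or self.N_MSC < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def approximate(self) -> bool:
        return self.status != "fitted"


@dataclass(frozen=True)
class NoiseModel:
    """Instrument-noise and hysteresis-pathology settings for simulated sweeps.

    ``sigma_abs`` is the additive Gaussian standard deviation (emu/g)
    applied independently to the real and imaginary channels of every
    sample.  ``hysteresis_offset`` maps a scan frequency (Hz) to a
    branch-antisymmetric offset expressed as a fraction of the peak
    response amplitude: the direct branch is shifted up, the reverse
    branch down, emulating scan-rate-dependent branch separation.
    """

    sigma_abs: float = 0.0
    hysteresis_offset: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.sigma_abs < 0:
            raise ValueError("sigma_abs must be nonnegative")
        if any(v < 0 for v in self.hysteresis_offset.values()):
            raise ValueError("hysteresis offsets must be nonnegative")


@dataclass(frozen=True)
class PhantomStudy:
    """Definition of a synthetic biodistribution study with known truth."""

    subject: str
    organs: dict  # organ name -> EnsembleParams
    drive: DriveConditions
    noise: NoiseModel
    F_sc_values: tuple = (8.0, 0.25)
    solution: Optional[EnsembleParams] = None
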