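"""Inversion of a preprocessed response curve into ensemble parameters.

The forward model (``nlrm2.physics.ensemble_m2``) maps
``(M_tilde, M_C, sigma, alpha, E_A)`` to a complex curve; the inverse
problem is solved by simultaneous nonlinear least squares on the
concatenated real and imaginary samples with equal weights.  The Neel
time is not an independent degree of freedom: it is derived from
``(M_C, alpha)`` through the free-diffusion relation, so fits report a
self-consistent dynamics pair (an option to free it exists for
comparison).  Uncertainties are 1-sigma values from the Jacobian-based
covariance at the optimum, scaled by the residual variance.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .constants import CONST
from .datatypes import DriveConditions, EnsembleParams, FitResult, M2Curve
from .physics import ConvergenceError, ensemble_m2, langevin_d2, neel_time

__all__ = ["initialize_params", "fit_m2", "FitOptions", "FitError", "XI_PEAK"]


class FitError(RuntimeError):
    """Raised when a curve cannot be fitted (inapplicable or degenerate)."""


def _find_xi_peak() -> float:
    """Reduced field at which |L''(xi)| is maximal (computed, not hardcoded)."""
    res = minimize_scalar(lambda x: -abs(langevin_d2(x)), bounds=(0.2, 6.0),
                          method="bounded")
    return float(res.x)


#: |L''| peaks near xi ~ 1.5; the quasi-static response extremum of a
#: monodisperse ensemble sits at H* with m mu_B H* / k_B T ~ XI_PEAK.
XI_PEAK = _find_xi_peak()

# default parameter bounds: generous envelopes around realistic aggregates
_BOUNDS_LO = np.array([0.0, 1e3, 0.0, 0.01, 0.0])
_BOUNDS_HI = np.array([np.inf, 1e6, 2.0, 5.0, 100.0])


@dataclasses.dataclass(frozen=True)
class FitOptions:
    """Tunable fitting options.

    ``multistart``: number of perturbed initial points (best-of
    selection); ``seed`` controls the perturbations.  ``n_nodes``:
    quadrature nodes of the lognormal moment average.
    ``free_tau_N``: fit the Neel time independently instead of deriving
    it from (M_C, alpha).  ``weighting``: "equal" (default) or
    "amplitude" (residuals divided by the channel peak amplitude).
    """

    multistart: int = 5
    seed: int = 0
    n_nodes: int = 25
    free_tau_N: bool = False
    weighting: str = "equal"
    sign_flip: bool = False
    perturbation: float = 0.3
    xtol: float = 1e-8
    ftol: float = 1e-10


def _params_from_vector(x, drive, free_tau_N):
    M_tilde, M_C, sigma, alpha, E_A = x[:5]
    tau = x[5] if free_tau_N else neel_time(M_C, alpha, drive.T)
    return EnsembleParams(
        M_tilde=M_tilde, M_C=M_C, sigma=sigma, alpha=alpha, tau_N=tau, E_A=E_A
    )


def initialize_params(curve: M2Curve, drive: DriveConditions) -> EnsembleParams:
    """Data-driven starting point for the inversion.

    The mean moment is guessed from the field of the |Re| extremum via
    the quasi-static relation ``m mu_B H* / k_B T ~ XI_PEAK`` (the
    reduced field where |L''| peaks); the magnetization from the peak
    amplitude against a unit-magnetization model curve.  Shape and
    dynamics parameters start at typical aggregate values.
    """
    i_pk = int(np.argmax(np.abs(curve.re)))
    H_star = curve.H[i_pk]
    amp = np.abs(curve.re[i_pk])
    if amp == 0.0:
        raise FitError("flat curve: no resolvable extremum in Re")
    interior = 0 < i_pk < len(curve.H) - 1
    if not interior and H_star == curve.H[-1]:
        raise FitError(
            "Re extremum at the field-range edge: widen the field range"
        )
    M_C = XI_PEAK * CONST.k_B * drive.T / (CONST.mu_B * H_star)
    guess = EnsembleParams(
        M_tilde=1.0, M_C=M_C, sigma=0.5, alpha=0.2,
        tau_N=neel_time(M_C, 0.2, drive.T), E_A=10.0,
    )
    # one coarse forward evaluation fixes the amplitude scale
    coarse = np.linspace(curve.H[0], curve.H[-1], 15)
    model = ensemble_m2(guess, drive.with_grid(coarse))
    model_amp = np.abs(model.re).max()
    M_tilde = amp / model_amp if model_amp > 0 else 1.0
    return dataclasses.replace(guess, M_tilde=M_tilde)


def _residuals(x, curve, drive, opts, norm=1.0):
    # `norm` (the data peak amplitude) rescales the problem to O(1) so the
    # optimizer's gradient/step tolerances behave; a uniform scale leaves
    # both the optimum and the parameter covariance unchanged.
    try:
        p = _params_from_vector(x, drive, opts.free_tau_N)
        model = ensemble_m2(p, drive.with_grid(curve.H),
                            n_nodes=opts.n_nodes, sign_flip=opts.sign_flip)
    except (ConvergenceError, ValueError):
        return np.full(2 * len(curve.H), 1e3)
    res = np.concatenate([model.re - curve.re, model.im - curve.im]) / norm
    if opts.weighting == "amplitude":
        w = np.concatenate([
            np.full(len(curve.H), np.abs(curve.re).max() + 1e-300),
            np.full(len(curve.H), np.abs(curve.im).max() + 1e-300),
        ]) / norm
        res = res / w
    return res


def fit_m2(
    curve: M2Curve,
    drive: DriveConditions,
    init: EnsembleParams | None = None,
    bounds: tuple | None = None,
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Least-squares inversion of one preprocessed curve.

    Free parameters are ``(M_tilde, M_C, sigma, alpha, E_A)`` (plus
    ``tau_N`` with ``options.free_tau_N``); the fit minimizes the joint
    sum of squared residuals over the concatenated Re and Im samples.
    Curves flagged FAIL by the applicability check are rejected: their
    hysteresis indicates a multi-domain fraction for which the
    superparamagnetic formalism does not hold.

    Returns a :class:`FitResult` with 1-sigma uncertainties (including
    the derived Neel time, by error propagation) and the residual RMS.
    """
    if curve.applicability == "FAIL":
        raise FitError(
            "multi-domain fraction suspected (applicability FAIL): "
            "superparamagnetic formalism inapplicable; "
            "refusing to fit"
        )
    if init is None:
        init = initialize_params(curve, drive)
    lo, hi = bounds if bounds is not None else (_BOUNDS_LO.copy(), _BOUNDS_HI.copy())
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    x0 = np.array([init.M_tilde, init.M_C, init.sigma, init.alpha, init.E_A])
    if options.free_tau_N:
        x0 = np.append(x0, init.tau_N)
        if len(lo) == 5:
            lo = np.append(lo, 1e-4)
            hi = np.append(hi, 1e3)
    x0 = np.clip(x0, lo, np.where(np.isfinite(hi), hi, x0))

    rng = np.random.default_rng(options.seed)
    starts = [x0]
    for _ in range(max(0, options.multistart - 1)):
        factors = np.exp(options.perturbation * rng.standard_normal(len(x0)))
        starts.append(np.clip(x0 * factors, lo, np.where(np.isfinite(hi), hi, x0 * factors)))

    scale = np.where(x0 > 0, x0, 1.0)
    norm = float(np.abs(curve.re).max()) or 1.0
    best = None
    for s in starts:
        try:
            res = least_squares(
                _residuals, s, bounds=(lo, hi), x_scale=scale,
                xtol=options.xtol, ftol=options.ftol,
                args=(curve, drive, options), kwargs={"norm": norm},
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("all fit starts failed to converge; inspect the curve")

    n = 2 * len(curve.H)
    p = len(best.x)
    ssr = 2.0 * best.cost
    dof = max(n - p, 1)
    s2 = ssr / dof
    # covariance in x_scale units: raw parameter magnitudes span ~12 decades,
    # so JtJ must be equilibrated before inversion to keep the weakly
    # constrained directions (and hence honest marginal errors)
    J_s = best.jac * scale[None, :]
    cov_s = s2 * np.linalg.pinv(J_s.T @ J_s, hermitian=True)
    cov = cov_s * scale[:, None] * scale[None, :]
    sig = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    params = _params_from_vector(best.x, drive, options.free_tau_N)
    names = ["M_tilde", "M_C", "sigma", "alpha", "E_A"]
    unc = dict(zip(names, sig[:5]))
    if options.free_tau_N:
        unc["tau_N"] = sig[5]
    else:
        # tau = k (1 + a^2) M_C / a  ->  propagate (M_C, alpha) errors
        M_C, alpha = best.x[1], best.x[3]
        tau = params.tau_N
        d_mc = tau / M_C
        d_al = tau * (2 * alpha / (1 + alpha**2) - 1 / alpha)
        i_mc, i_al = 1, 3
        var = (d_mc**2 * cov[i_mc, i_mc] + d_al**2 * cov[i_al, i_al]
               + 2 * d_mc * d_al * cov[i_mc, i_al])
        unc["tau_N"] = float(np.sqrt(max(var, 0.0)))

    return FitResult(
        params=params,
        uncertainties=unc,
        residual_rms=float(np.sqrt(ssr / n)) * norm,
        n_points=n,
        converged=bool(best.status > 0),
        applicability=curve.applicability,
        label=curve.label,
        cost=float(best.cost),
    )
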