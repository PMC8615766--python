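# Methods

## Physical model

A single-domain superparamagnetic aggregate of moment *m* (stored in Bohr
magnetons; *m*·μ_B in emu) in a dc field *H* plus collinear ac drive
*h*·sin(ωt), ω = 2πf, has orientation distribution W(x, t), x = cos θ,
governed by the axially symmetric Brown rotational Fokker–Planck equation

    2 τ ∂W/∂t = ∂/∂x [ (1 − x²) ( ∂W/∂x + W ∂(βE)/∂x ) ],

with reduced energy βE = −ξ(t)·x − σ_A·x², where

- ξ(t) = m μ_B (H + h sin ωt) / (k_B T) — reduced instantaneous field,
- σ_A = E_A / T — reduced uniaxial anisotropy, easy axis along the field,
- τ — free-diffusion relaxation time of the first moment (the Néel time).

Expanding W in Legendre polynomials, the moments a_l = ⟨P_l(x)⟩ obey, with
c_l = l(l+1)/(2l+1) and a₀ = 1,

    2 τ ȧ_l = −l(l+1) a_l + ξ(t) c_l (a_{l−1} − a_{l+1})
              + 2 σ_A c_l [ (l−1)/(2l−1) a_{l−2}
                            + ( l/(2l−1) − (l+1)/(2l+3) ) a_l
                            − (l+2)/(2l+3) a_{l+2} ].

The magnetization is M(t) = m μ_B a₁(t); the observable is the complex 2ω
Fourier amplitude M₂(H), reported as the cos(2ωt) (Re) and sin(2ωt) (Im)
coefficients under the drive convention h·sin(ωt). M₂ is odd in H and scales
as h² for small drives. A single global sign flip (instrument phase
convention) is exposed as a configuration switch; synthetic data and fits are
self-consistent under the default.

### Harmonic balance

The periodic steady state is written a_l(t) = Σ_n c_{l,n} e^{inωt},
|n| ≤ n_max, l ≤ l_max, giving a banded complex linear system over (l, n)
with bandwidth 2(2 n_max + 1). Truncation starts at (l_max, n_max) = (10, 4)
— raised proportionally to the largest reduced field on the grid — and both
orders are doubled until the 2ω amplitude changes by less than 10⁻⁴ relative,
with a hard cap of (80, 16); exceeding the cap raises a solver error naming
the offending field and moment. The orders actually used are the coarse pair
verified against the doubled solve. For speed, converged orders are memoized
on a coarsely quantized operating point, and the per-field-grid systems are
stacked block-diagonally (chunks of 16) into single banded factorizations.

### Independent oracles

Two independent routes check the solver:

- **Quasi-static limit.** For f·τ → 0 the distribution follows the
  instantaneous Boltzmann equilibrium, so M(t) = M_eq(H + h sin ωt) with
  M_eq computed by Gauss–Legendre quadrature of ⟨x⟩ under
  exp(ξx + σ_A x²) (the Langevin function when E_A = 0). Sampling one drive
  period and projecting the 2ω Fourier coefficient gives a non-perturbative
  oracle; the analytic weak-drive limit Re M₂ = −(h²/4) d²M_eq/dH², Im = 0
  checks both.
- **Time stepping.** The same moment hierarchy is integrated in the time
  domain (LSODA, rtol 10⁻¹⁰) to its periodic steady state (16 periods; the
  transient decays on the scale τ ≪ 1/f) and the 2ω coefficient is projected
  over the final period. Harmonic balance and time stepping agree to better
  than 10⁻³ relative across the fitted parameter range.

### Polydispersity

Aggregate moments follow a lognormal distribution with **mean** M_C and
log-standard-deviation σ, i.e. ln m ~ N(ln M_C − σ²/2, σ²). This choice makes
N_P = M̃/(M_C μ_B) the exact aggregate count per gram, which reproduces every
published (M̃, M_C) → N_P row to better than 1%. The ensemble average uses a
fixed log-grid Gauss–Legendre rule over ±4σ with lognormal-density weights
renormalized to unit mass (25 nodes by default, 21 minimum). Gauss–Hermite
quadrature was rejected: for σ ≈ 0.7 its extreme nodes reach reduced fields
ξ ~ 500 that no practical Legendre truncation can follow, while the log-grid
truncation discards < 10⁻³ of the distribution mean. Each node carries its
own Néel time, scaled linearly with the node moment at fixed damping α (the
free-diffusion relation τ ∝ m); the anisotropy energy is kept common across
nodes. σ = 0 bypasses quadrature exactly.

### Constants and units

CGS-Gaussian throughout: fields in Oe, moments in emu (quoted in μ_B =
9.274 × 10⁻²¹ emu), k_B = 1.3807 × 10⁻¹⁶ erg/K, γ = 1.76 × 10⁷ rad s⁻¹ Oe⁻¹.
The measurement temperature is fixed at T = 300 K; this reconstructs the
solution-row Néel time from its (M_C, α) pair to 0.2%, and all seven fully
fitted rows to within 4%.

## Preprocessing

Raw data are direct and reverse dc-field scans at scan frequencies
F_sc = 8 and 0.25 Hz. The pipeline averages the two branches (linear
interpolation onto the union of sample points clipped to the overlap, ≥ 50%
overlap required), then extracts the odd part (s(H) − s(−H))/2 on the
nonnegative field axis — the model is strictly odd, so even content is
instrumental background, and the negative half-axis is redundant for
fitting. The order (average, then antisymmetrize) matches standard practice;
the two operations commute on noiseless data.

**Hysteresis index**: mean absolute complex branch difference divided by the
peak-to-peak amplitude of the branch mean (both channels combined in
quadrature); zero for identical branches, scale-invariant, and exactly equal
to the injected offset fraction for the synthetic pathology below.
**Applicability**: PASS if the fast-scan index is below 0.05, or if the index
falls by ≥ 30% at the slow scan and ends below 0.05 (scan-rate-dependent
hysteresis relaxing away is superparamagnetic behavior); FAIL if the indices
are within 10% of each other and above threshold (persistent hysteresis — a
multi-domain/ferromagnetic fraction, for which the formalism is refused);
WARN otherwise. All thresholds are configurable; the defaults were chosen so
noiseless synthetic data pass and the constructed persistent-hysteresis
pathology fails. Note that for specimens whose signal sits close to the
absolute noise floor, noise alone produces equal branch-separation indices at
both scan rates and can trigger WARN/FAIL; inspect the indices in that case.

## Inversion

Joint nonlinear least squares on the concatenated Re and Im samples with
equal weights (amplitude-proportional weighting available). Free parameters:
(M̃, M_C, σ, α, E_A); the Néel time is derived from (M_C, α) — the published
pairs satisfy the free-diffusion relation, so fitting τ_N independently would
double-count one degree of freedom (a configuration flag enables it for
comparison). Bounds: M_C ∈ [10³, 10⁶] μ_B, σ ∈ [0, 2], α ∈ [0.01, 5],
E_A ∈ [0, 100] K. Initialization: M_C from the field H* of the |Re| extremum
via m μ_B H*/(k_B T) ≈ 1.372 (the numerically computed |L''| peak), M̃ from
the peak amplitude against a unit-magnetization curve; multistart (default 5
log-normally perturbed starts, fixed seed) with best-of selection.

Numerical details that matter: residuals are normalized by the curve peak
amplitude (raw values ~10⁻⁹ emu/g otherwise trip the optimizer's gradient
tolerance), and the covariance is computed in x_scale-equilibrated space
because raw parameter magnitudes span twelve decades and a naive
pseudo-inverse silently truncates the weakly constrained directions. 1σ
uncertainties come from the Jacobian covariance scaled by the residual
variance; the derived τ_N uncertainty follows by error propagation from the
(M_C, α) block. E_A ≲ 20 K has a sub-percent effect on the curve at
σ_A ≤ 0.06, so its interval is wide — consistent with published values
quoted as 0 with finite uncertainty. Curves flagged FAIL are rejected with
an explicit "formalism inapplicable" error.

## Counting and ranking

N_P = M̃/(M_C μ_B); N_MSC = N_P / (8.27 × 10⁴ aggregates per cell), with the
calibration anchored in the injection solution (1.5 × 10⁵ cells, ~160
nanoparticles per aggregate). Organs whose sweeps cannot be fitted are
estimated by scaling response amplitudes (peak |Re| by default, RMS
available) against a fitted reference organ assuming similar aggregate
moments; per-gram-normalized amplitudes make organ masses cancel, raw
amplitudes plus masses are also accepted. Such rows are flagged approximate
("~") and N_MSC is reported to two significant figures. Ranking is a stable
ascending sort on N_MSC, ties broken alphabetically with a warning.

## Synthetic data

The generator emulates the study's measurement design: 301-point sweeps over
±300 Oe (both scan frequencies emitted), additive homoscedastic Gaussian
noise (default 1% of the solution-row peak — an absolute instrument floor,
so weak organs are noisier in relative terms), and an optional
branch-antisymmetric offset per scan frequency that reproduces the
hysteresis phenomenology without modelling multi-domain physics (the offset
cancels exactly in branch averaging, so it perturbs only the applicability
decision, not the fitted curve). Seeds fully determine the output; per-label
and per-frequency RNG streams are derived with a stable CRC so reruns are
bitwise identical. The bundled phantom preset mirrors the first animal of
the reference study: organs with published magnetic parameters use them;
the remaining organs get an effective mean moment M_C = M̃/(N_P μ_B) derived
from their published counts with the solution-row shape parameters, so the
manifest's true N_MSC values span the published range (≈ 8.7 × 10³ to
3.9 × 10⁵ per gram).

What synthetic tests demonstrate: the inversion is unbiased and its
uncertainty intervals are honest under the generator's assumptions
(Gaussian noise, exact forward model, lognormal polydispersity). What they
do not demonstrate: robustness to correlated instrument drift, background
subtraction errors, non-lognormal aggregate populations, or genuine
multi-domain contamination beyond the offset pathology.

## Problem sizes

Defaults chosen for desk-scale reproducibility: synthetic studies on
121-point signed grids (61 fit points), 25 quadrature nodes, 10 replicates
in the recovery study with single-start fits from the data-driven
initializer. The quasi-static comparison uses 31 field points with the
drive frequency scaled down 10³×; the oracle cross-check uses three-point
grids at three (m, τ_N) combinations spanning the fitted range.

## Known limitations

- Axially symmetric solver: no transverse field components or precessional
  dynamics; α enters only through τ_N. Justified at σ_A ≤ 0.06 but untested
  against a full vector treatment.
- Powder (easy-axis orientation) averaging is omitted for the same reason.
- Single temperature; temperature sweeps are out of scope.
- Aggregate moments are assumed field-independent (rigid-moment aggregates).
- The hysteresis index conflates noise with branch separation near the
  noise floor (see Preprocessing).
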