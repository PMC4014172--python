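# Methods

## Model

The microdosimetric-kinetic (MK) model treats the cell nucleus as `N`
independent domains of radius `r_d` and density `ρ`. A dose `D` deposits
a stochastic specific energy `z` per domain with moments `⟨z⟩ = D` and
`⟨z²⟩ = z̄₁ D + D²`, where `z̄₁ = y_D K / (ρ π r_d²)` is the dose-mean
specific energy of a single event and `y_D` the dose-mean lineal energy
of the radiation quality. Potentially lethal lesions (PLLs, identified
with DNA double-strand breaks) are created at `k_d` per domain per Gy
and evolve as

    dP/dt = -(a + c) P - 2 b_d P²
    dL/dt =  a P + b_d P²

with first-order lethal conversion `a`, repair `c`, pairwise lethal
conversion `b_d`, and a deadline `t_r` at which surviving PLLs become
lethal. Linearising the PLL equation (valid while
`2 b_d P ≪ a + c`) gives `P(t) = k_d z e^{-(a+c)t}` and a per-domain
lethal yield `L = A z + B z²` with

    A = [a/(a+c)] k_d + [c/(a+c)] k_d e^{-(a+c) t_r}
    B = b_d k_d² / (2(a+c)) · (1 - e^{-2(a+c) t_r}).

`A` includes the PLLs that persist to `t_r`; the numerical oracle in
`mkmodel.kinetics` therefore compares the closed form against
`L(t_r) + P(t_r)`, the deadline-inclusive lethal total. With a
Poisson-distributed lethal count per nucleus, `S = exp(-N⟨L⟩)` expands
to the linear–quadratic law `-ln S = α D + β D²` with `α = α₀ + β z̄₁`
and `β = N B`. Because `β / k²` (with `k = N k_d` the DSB yield per
nucleus per Gy) is a cell-specific constant when `(a+c) t_r > 3`,

    k'/k = sqrt(β'/β),

which is the package's central estimator: relative DSB yields from β
ratios, absolute yields by anchoring the reference quality to a
γ-H2AX foci count `k_exp`, and `RBE₃₇ = D₃₇(ref)/D₃₇(test)` from the
positive root of `α D + β D² = 1`.

## Parameters and defaults

| parameter | unit | default | rationale |
| --- | --- | --- | --- |
| `r_d` | μm | 0.5 | standard domain radius for mammalian nuclei in photon MK analyses |
| `ρ` | g/cm³ | 1.0 | water-equivalent density |
| site diameter (lineal energy) | μm | 1.0 | conventional microdosimetric site; mean chord = 2/3 diameter |
| `K` | Gy per (keV/μm)/(g·cm⁻³·μm²) | 0.1602 | exact unit conversion: 1 keV = 1.602×10⁻¹⁶ J over 10⁻¹⁵ kg per μm³ at unit density |
| reference quality | — | 200 kVp X-rays | the standard radiation the foci anchor was measured for; configurable |
| D₃₇ convention | — | `-ln S = 1` | the standard reading of "37 % survival" (S = e⁻¹ ≈ 36.8 %); a literal level such as 0.37 can be passed — for the bundled parameters both conventions agree to 3 decimals |
| ODE tolerances | — | rtol 1e-8, atol 1e-10 | stiff-capable LSODA; rate constants span orders of magnitude in sweeps |

## Uncertainty propagation

All derived uncertainties use first-order (delta-method) propagation
with independent operands: relative errors add in quadrature through
products, quotients and powers (so the relative SE of `sqrt(β'/β)` is
half the quadrature sum of the two β relative SEs), absolute errors add
in quadrature through sums. α₀'s SE combines `alpha_se` and
`γ·beta_se` this way, ignoring the α–β fit correlation. The spread
attached to a foci-based `k_exp` is the per-nucleus SD by default (SEM
by flag): published ratio uncertainties are reproduced exactly by
SD-based quadrature and not by SEM-based, so ratios of `k_exp` describe
per-nucleus variability. A Monte-Carlo oracle in the test suite
(Gaussian draws on the β's and the anchor) confirms the quadrature SEs
of the absolute-k column to within 5 % relative. D₃₇ standard errors
use numeric partial derivatives of the quadratic root.

The pipeline's reference row is anchored directly to `k_exp` (its β
ratio is identically one), so no β uncertainty is propagated there —
propagating the same β twice as if independent would inflate the SE.

## Fitting

LQ fits minimise `Σ w_i (-ln S_i - α D_i - β D_i²)²`: linear in the
parameters, no intercept (surviving fractions are assumed normalised to
plating efficiency, so S(0) ≡ 1), unweighted by default with optional
inverse-variance weights `w = (S/se)²`. α and β are estimated as two
independent parameters under the box constraint α, β ≥ 0; when the
unconstrained optimum is negative the fit switches to non-negative
least squares and sets a `clipped` flag rather than silently truncating.
Covariances come from `s² (XᵀWX)⁻¹` with the residual variance on
`n - 2` degrees of freedom. At least three distinct positive doses are
required.

## Synthetic data

The generators emulate the statistical shape, not the biology, of the
assays:

* **Survival**: `S_ij = exp(-α D_i - β D_i²) · ε_ij` with lognormal
  `ln ε ~ N(0, σ²)`, capped at 1. Defaults: a control plus seven doses
  up to 8 Gy, three replicate platings per dose, σ = 0.1 — the
  magnitude of scatter typical of colony counts — and LQ truth
  (0.284, 0.0425), a 200 kVp-like quality.
* **Foci**: per-nucleus counts are negative binomial with mean
  `background + k_true·D`. Defaults (background 18.7, `k_true` 32.2 at
  1 Gy, 80 nuclei) reproduce a raw irradiated mean of 50.9; the
  dispersion 17.5 is moment-matched so the per-nucleus SD is ≈ 14,
  roughly twice Poisson, as observed counts are. Poisson is available
  as the dispersion → ∞ limit.

What passing recovery tests show: the fit is unbiased and its Wald
intervals are roughly calibrated *under multiplicative lognormal noise
and a correctly specified LQ mean*. Real clonogenic data add
plating-efficiency error, inter-experiment heterogeneity and counting
saturation that the generator does not model; foci data add segmentation
thresholds, focus overlap at high dose and time-dependence of the focus
count (the generators describe a fixed post-irradiation time point).

## Numerical choices

* LQ fitting is done in `-ln S` space (convex, closed-form covariance)
  rather than by nonlinear least squares on S; the two differ only in
  the implied error model, and the chosen one matches the lognormal
  noise assumption.
* Spectrum moments use trapezoidal quadrature on the tabulated grid;
  spectra are renormalised on construction (idempotent), and `y_D` may
  be supplied directly, bypassing spectra, since published values are
  routinely consumed as constants.
* The β-from-kinetics helper reports both the exact finite-deadline
  form and the `(a+c) t_r > 3` approximation; the approximate form is
  used as the operative value only when that condition holds, otherwise
  the exact form is used and a warning emitted.
* The ODE right-hand side keeps the factor 2 on `b_d P²` in the PLL
  equation and 1 in the lethal equation (two PLLs consumed, one lethal
  lesion formed per pairwise interaction).
* Degenerate two-sample foci comparisons (both samples constant) are
  reported as p = 1 (equal) or p = 0 (unequal) instead of NaN.
* Welch's t-test is used for condition comparisons; the choice is
  recorded in the result object since count data could equally justify
  a rank or GLM-based test.

## Scale of the shipped analyses

The recovery study runs 200 replicates of an 8-dose × 3-replicate
design (with a paired contrast quality), and the Monte-Carlo error
oracle uses 10⁵ draws per table row; both finish in seconds and give
Monte-Carlo error comfortably below the tolerances they are checked
against.

## Known limitations

* The kinetic rates `a, b_d, c, t_r` are never estimated from data —
  survival data identify only α and β; the kinetics module exists to
  validate the closed forms and delimit the linearised regime.
* No dose-rate, fractionation or protraction extensions; single acute
  doses only.
* Survival is strictly Poisson in the lethal-lesion count; no
  overdispersed-kill corrections.
* The bundled published table reproduces all derived columns within
  rounding except the H1299 RBE₃₇ column, which does not follow from
  its own printed α, β (recomputation gives 0.523/0.639/0.692 against
  the published 0.539/0.659/0.713, while every CHO-K1 row matches to
  ≤ 0.005). The published values were presumably computed from
  unrounded fit parameters; the package keeps the recomputed values and
  flags the difference rather than patching it.
* Error propagation assumes independent Gaussian errors; α–β fit
  correlations are available in `FitResult.covariance` but deliberately
  unused in the α₀ SE to match the SE convention of the published
  table.
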