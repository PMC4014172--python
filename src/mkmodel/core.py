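"""Closed-form relations of the microdosimetric-kinetic (MK) model.

The MK model pictures a cell nucleus as ``N`` sub-micrometre *domains*.
Radiation deposits a stochastic specific energy ``z`` [Gy] in each domain
and creates potentially lethal lesions (PLLs) — identified with DNA
double-strand breaks — in proportion to ``z``.  A PLL can then

* convert to a lethal lesion through a first-order process (rate ``a``),
* convert to a lethal lesion by pairwise interaction with another PLL
  (second-order rate ``b_d``),
* be repaired (first-order rate ``c``), or
* persist until a deadline ``t_r`` hours after irradiation, at which
  point it becomes lethal.

Linearising the PLL kinetics (valid while first-order removal dominates
the pairwise channel) gives a lethal-lesion yield per domain that is
linear–quadratic in ``z``, ``L = A z + B z**2``, and — after averaging
over the microdosimetric distribution of ``z`` — the familiar
linear–quadratic (LQ) surviving fraction

    S(D) = exp(-(alpha * D + beta * D**2)),

with ``alpha = alpha_0 + beta * y_D * K / (rho * pi * r_d**2)`` carrying
the radiation-quality dependence through the dose-mean lineal energy
``y_D``.  This module holds the domain types and the closed forms; the
nonlinear kinetics are integrated numerically in :mod:`mkmodel.kinetics`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .uncertainty import ValueWithError

__all__ = [
    "LINEAL_TO_SPECIFIC_ENERGY",
    "DomainGeometry",
    "KineticRates",
    "LQParameters",
    "MKDerived",
    "LethalCoefficients",
    "BetaFromKinetics",
    "SingularKineticsError",
    "pll_count",
    "lethal_coefficients",
    "beta_from_kinetics",
    "survival",
    "lethal_lesions",
    "alpha_decomposition",
    "single_event_dose_mean",
]

#: Gy per [keV/μm divided by g·cm⁻³·μm²]:
#: 1 keV = 1.602e-16 J and 1 (g/cm³)·μm³ = 1e-15 kg, so
#: (keV/μm) / (g·cm⁻³·μm²) = 1.602e-16 J / 1e-15 kg = 0.1602 Gy.
LINEAL_TO_SPECIFIC_ENERGY = 0.1602


class SingularKineticsError(ValueError):
    """Raised when a + c = 0 makes the closed forms singular."""


@dataclass(frozen=True)
class DomainGeometry:
    """Geometry of the sub-nuclear domains.

    Parameters
    ----------
    r_d:
        Domain radius [μm]; 0.5 μm for the photon analyses here.
    rho:
        Domain density [g/cm³]; unit density (water) by default.
    N:
        Number of domains per cell nucleus.  Optional: only needed when
        converting between per-domain and per-nucleus quantities.
    """

    r_d: float = 0.5
    rho: float = 1.0
    N: int | None = None

    def __post_init__(self) -> None:
        if not self.r_d > 0:
            raise ValueError(f"domain radius must be positive, got {self.r_d}")
        if not self.rho > 0:
            raise ValueError(f"domain density must be positive, got {self.rho}")
        if self.N is not None and self.N < 1:
            raise ValueError(f"number of domains must be >= 1, got {self.N}")

    def require_n(self) -> int:
        if self.N is None:
            raise ValueError("this quantity needs the number of domains N per nucleus")
        return self.N


@dataclass(frozen=True)
class KineticRates:
    """PLL transformation rates of the MK model.

    ``a`` [1/h] first-order lethal conversion, ``b_d`` per-domain
    second-order lethal conversion, ``c`` [1/h] first-order repair, and
    ``t_r`` [h] the deadline after which a surviving PLL turns lethal.

    Note on units: the second-order constant is conventionally quoted
    with dimensions [h⁻²] although it acts as a per-PLL-pair rate
    (effectively per PLL per hour); the numerics are unaffected because
    ``b_d`` only ever multiplies ``P**2``.
    """

    a: float
    b_d: float
    c: float
    t_r: float

    def __post_init__(self) -> None:
        for name in ("a", "b_d", "c", "t_r"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"kinetic rate {name} must be finite and >= 0, got {v}")

    @property
    def removal_rate(self) -> float:
        """Total first-order PLL removal rate a + c [1/h]."""
        return self.a + self.c

    @property
    def well_approximated(self) -> bool:
        """Whether (a + c) * t_r > 3, so exp(-2(a+c)t_r) is negligible
        and beta ≈ b k² / (2(a+c)) holds (Hawkins' condition)."""
        return self.removal_rate * self.t_r > 3.0


@dataclass(frozen=True)
class LQParameters:
    """Linear–quadratic coefficients for one cell line × radiation quality."""

    alpha: float
    beta: float
    alpha_se: float = 0.0
    beta_se: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.alpha_se < 0 or self.beta_se < 0:
            raise ValueError("standard errors must be >= 0")

    @property
    def alpha_we(self) -> ValueWithError:
        return ValueWithError(self.alpha, self.alpha_se)

    @property
    def beta_we(self) -> ValueWithError:
        return ValueWithError(self.beta, self.beta_se)


@dataclass(frozen=True)
class MKDerived:
    """Quality-dependent MK quantities derived from (alpha, beta, y_D)."""

    alpha0: ValueWithError
    k: ValueWithError
    y_d: float

    def __post_init__(self) -> None:
        if self.k.value < 0:
            raise ValueError("DSB yield k must be >= 0")


@dataclass(frozen=True)
class LethalCoefficients:
    """Per-domain lethal-lesion coefficients: L(z) = A z + B z**2."""

    A: float
    B: float

    def lesions(self, z: float | np.ndarray) -> float | np.ndarray:
        z = np.asarray(z, dtype=float)
        out = self.A * z + self.B * z**2
        return float(out) if out.ndim == 0 else out


def pll_count(rates: KineticRates, k_d: float, z: float, t: float) -> float:
    """PLLs per domain at time ``t`` after depositing specific energy ``z``.

    Uses the linearised kinetics, P(t) = k_d * z * exp(-(a+c) t), valid
    while first-order removal dominates the pairwise channel.
    """
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    if z < 0:
        raise ValueError(f"specific energy must be >= 0, got {z}")
    if k_d < 0:
        raise ValueError(f"PLL yield k_d must be >= 0, got {k_d}")
    return k_d * z * math.exp(-rates.removal_rate * t)


def lethal_coefficients(rates: KineticRates, k_d: float) -> LethalCoefficients:
    """Closed-form (A, B) of the per-domain lethal-lesion yield at ``t_r``.

    A counts PLLs that convert first-order plus those that survive to the
    deadline; B counts pairwise conversions accumulated over [0, t_r]:

        A = [a/(a+c)] k_d + [c/(a+c)] k_d exp(-(a+c) t_r)
        B = b_d k_d² / (2(a+c)) * (1 - exp(-2(a+c) t_r))
    """
    ac = rates.removal_rate
    if ac == 0:
        raise SingularKineticsError("a + c = 0: no first-order removal, closed form is singular")
    decay = math.exp(-ac * rates.t_r)
    A = (rates.a / ac) * k_d + (rates.c / ac) * k_d * decay
    B = rates.b_d * k_d**2 / (2.0 * ac) * (1.0 - decay**2)
    return LethalCoefficients(A=A, B=B)


@dataclass(frozen=True)
class BetaFromKinetics:
    """Exact and approximate beta implied by the kinetics, beta = N B."""

    exact: float
    approximate: float
    well_approximated: bool

    @property
    def relative_discrepancy(self) -> float:
        if self.exact == 0.0:
            return 0.0
        return abs(self.approximate - self.exact) / self.exact

    @property
    def value(self) -> float:
        """The operative beta: the approximate form when Hawkins'
        condition (a+c) t_r > 3 holds, the exact form otherwise."""
        return self.approximate if self.well_approximated else self.exact


def beta_from_kinetics(rates: KineticRates, k: float, geometry: DomainGeometry) -> BetaFromKinetics:
    """Quadratic LQ coefficient implied by the kinetics and the DSB yield.

    With b = b_d / N and k the PLL (DSB) count per nucleus per Gy,

        beta_exact  = b k² / (2(a+c)) * (1 - exp(-2(a+c) t_r))
        beta_approx = b k² / (2(a+c))          [(a+c) t_r > 3]

    Both are returned; beta / k² is a cell-specific constant, which is
    what lets a beta ratio stand in for a squared DSB-yield ratio.
    """
    ac = rates.removal_rate
    if ac == 0:
        raise SingularKineticsError("a + c = 0: beta from kinetics is singular")
    if k < 0:
        raise ValueError(f"DSB yield k must be >= 0, got {k}")
    b = rates.b_d / geometry.require_n()
    approx = b * k**2 / (2.0 * ac)
    exact = approx * (1.0 - math.exp(-2.0 * ac * rates.t_r))
    result = BetaFromKinetics(exact=exact, approximate=approx, well_approximated=rates.well_approximated)
    if not rates.well_approximated:
        warnings.warn(
            f"(a+c)*t_r = {ac * rates.t_r:.3g} <= 3: using the exact beta; "
            f"the quadratic approximation is off by {result.relative_discrepancy:.2%}",
            stacklevel=2,
        )
    return result


def lethal_lesions(lq: LQParameters, dose: float | np.ndarray) -> float | np.ndarray:
    """Mean lethal lesions per nucleus, -ln S = alpha D + beta D**2."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be >= 0")
    out = lq.alpha * d + lq.beta * d**2
    return float(out) if out.ndim == 0 else out


def survival(lq: LQParameters, dose: float | np.ndarray) -> float | np.ndarray:
    """LQ surviving fraction S = exp(-alpha D - beta D**2).

    The exponential form embodies a Poisson-distributed lethal-lesion
    count per nucleus; no non-Poisson correction is applied.
    """
    out = np.exp(-np.asarray(lethal_lesions(lq, dose), dtype=float))
    return float(out) if out.ndim == 0 else out


def single_event_dose_mean(y_d: float, geometry: DomainGeometry = DomainGeometry()) -> float:
    """Dose-mean specific energy per event z̄₁ [Gy] in one domain.

    z̄₁ = K * y_D / (rho * pi * r_d²) with K = 0.1602 converting
    keV/μm per (g·cm⁻³·μm²) to Gy.
    """
    if not math.isfinite(y_d) or y_d < 0:
        raise ValueError(f"y_D must be finite and >= 0, got {y_d}")
    return LINEAL_TO_SPECIFIC_ENERGY * y_d / (geometry.rho * math.pi * geometry.r_d**2)


def alpha_decomposition(
    lq: LQParameters, y_d: float, geometry: DomainGeometry = DomainGeometry()
) -> ValueWithError:
    """Intrinsic linear coefficient alpha_0 = alpha - beta * z̄₁(y_D).

    Splits alpha into a quality-independent part alpha_0 and the
    microdosimetric contribution beta * y_D * K / (rho * pi * r_d²).
    The standard error combines alpha_se and beta_se in quadrature
    (the alpha/beta fit correlation is ignored).
    """
    gamma = single_event_dose_mean(y_d, geometry)
    return lq.alpha_we - gamma * lq.beta_we
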