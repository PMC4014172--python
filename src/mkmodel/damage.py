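"""DSB-yield and RBE estimators built on fitted LQ parameters.

Because beta / k² is a cell-specific constant in the MK model, the ratio
of DSB yields between two radiation qualities follows from the beta
ratio alone,

    k_test / k_ref = sqrt(beta_test / beta_ref),

and an absolute yield follows by anchoring the reference quality to an
experimental foci count k_exp.  RBE is evaluated at the 37 % survival
level: D37 is the dose with -ln S = 1 (S = e⁻¹), the standard reading
of "37 % survival"; a literal survival level can be passed instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DomainGeometry, LQParameters, MKDerived, alpha_decomposition
from .uncertainty import ValueWithError

__all__ = [
    "DSBEstimate",
    "RBEResult",
    "k_ratio",
    "absolute_k",
    "d37",
    "d37_with_error",
    "rbe37",
    "derive_photon_table",
]


@dataclass(frozen=True)
class DSBEstimate:
    """A DSB yield per nucleus per Gy with its provenance."""

    k: ValueWithError
    basis: str  # 'ratio-scaled' or 'direct-foci'
    reference_label: str = ""

    def __post_init__(self) -> None:
        if self.k.value < 0:
            raise ValueError("DSB yield must be >= 0")
        if self.basis not in ("ratio-scaled", "direct-foci"):
            raise ValueError(f"unknown basis {self.basis!r}")


@dataclass(frozen=True)
class RBEResult:
    """RBE at the 37 % survival level: D37(reference) / D37(test)."""

    d37_test: float
    d37_reference: float
    rbe37: ValueWithError

    def __post_init__(self) -> None:
        if self.d37_test <= 0 or self.d37_reference <= 0:
            raise ValueError("D37 doses must be positive")


def _require_positive_beta(beta: ValueWithError, name: str) -> None:
    if beta.value <= 0:
        raise ValueError(f"{name} must be positive for a beta-ratio estimate, got {beta.value}")


def k_ratio(beta_test: ValueWithError, beta_ref: ValueWithError) -> ValueWithError:
    """Relative DSB yield sqrt(beta_test / beta_ref).

    The relative SE is half the quadrature sum of the two beta relative
    SEs (first-order propagation through the square root).
    """
    _require_positive_beta(beta_test, "beta_test")
    _require_positive_beta(beta_ref, "beta_ref")
    return (beta_test / beta_ref) ** 0.5


def absolute_k(
    beta_test: ValueWithError,
    beta_ref: ValueWithError,
    k_exp_ref: ValueWithError,
    reference_label: str = "",
) -> DSBEstimate:
    """Absolute DSB yield k = k_exp_ref * sqrt(beta_test / beta_ref).

    Anchors the beta-ratio estimate to the experimentally counted foci
    yield of the reference quality.
    """
    if k_exp_ref.value <= 0:
        raise ValueError(f"reference k_exp must be positive, got {k_exp_ref.value}")
    k = k_exp_ref * k_ratio(beta_test, beta_ref)
    return DSBEstimate(k=k, basis="ratio-scaled", reference_label=reference_label)


def _log_kill_target(survival_level: float | None) -> float:
    if survival_level is None:
        return 1.0  # S = e^-1, the D37 convention
    if not 0 < survival_level < 1:
        raise ValueError(f"survival level must be in (0, 1), got {survival_level}")
    return -math.log(survival_level)


def d37(lq: LQParameters, survival_level: float | None = None) -> float:
    """Dose [Gy] at which survival drops to e⁻¹ (or a given level).

    Solves alpha D + beta D² = -ln S_target; the positive quadratic root

        D = (-alpha + sqrt(alpha² + 4 beta τ)) / (2 beta),  τ = -ln S_target

    or τ/alpha for a purely exponential curve.
    """
    tau = _log_kill_target(survival_level)
    if lq.alpha == 0 and lq.beta == 0:
        raise ValueError("alpha = beta = 0: no cell kill, D37 undefined")
    if lq.beta == 0:
        return tau / lq.alpha
    return (-lq.alpha + math.sqrt(lq.alpha**2 + 4.0 * lq.beta * tau)) / (2.0 * lq.beta)


def d37_with_error(lq: LQParameters, survival_level: float | None = None) -> ValueWithError:
    """D37 with a delta-method SE from (alpha_se, beta_se), treated as
    independent (numeric partial derivatives, central differences)."""
    value = d37(lq, survival_level)
    h_a = 1e-6 * max(abs(lq.alpha), 1.0)
    var = 0.0
    if lq.alpha_se > 0:
        lo = LQParameters(lq.alpha - h_a, lq.beta)
        hi = LQParameters(lq.alpha + h_a, lq.beta)
        dda = (d37(hi, survival_level) - d37(lo, survival_level)) / (2 * h_a)
        var += (dda * lq.alpha_se) ** 2
    if lq.beta_se > 0 and lq.beta > 0:
        h_b = min(1e-6 * max(lq.beta, 1.0), 0.5 * lq.beta)
        lo = LQParameters(lq.alpha, lq.beta - h_b)
        hi = LQParameters(lq.alpha, lq.beta + h_b)
        ddb = (d37(hi, survival_level) - d37(lo, survival_level)) / (2 * h_b)
        var += (ddb * lq.beta_se) ** 2
    return ValueWithError(value, math.sqrt(var))


def rbe37(
    lq_test: LQParameters, lq_ref: LQParameters, survival_level: float | None = None
) -> RBEResult:
    """RBE at 37 % survival, D37(reference) / D37(test)."""
    dt = d37_with_error(lq_test, survival_level)
    dr = d37_with_error(lq_ref, survival_level)
    return RBEResult(d37_test=dt.value, d37_reference=dr.value, rbe37=dr / dt)


_REQUIRED_COLUMNS = ("cell_line", "quality", "alpha", "alpha_se", "beta", "beta_se", "y_d")


def derive_photon_table(
    table: pd.DataFrame,
    reference_quality: str = "200 kVp",
    k_exp_reference: dict[str, ValueWithError] | None = None,
    geometry: DomainGeometry = DomainGeometry(),
    survival_level: float | None = None,
) -> pd.DataFrame:
    """Derive (alpha0, k, RBE37) for every cell line × quality row.

    Parameters
    ----------
    table:
        Columns ``cell_line, quality, alpha, alpha_se, beta, beta_se,
        y_d`` and — unless ``k_exp_reference`` is given — ``k_exp,
        k_exp_se`` populated at least on the reference rows.
    reference_quality:
        The quality used as the standard radiation, per cell line.
    k_exp_reference:
        Optional explicit foci anchor per cell line, overriding the
        table's reference-row k_exp.

    Returns a tidy frame with columns ``cell_line, quality, alpha,
    alpha_se, alpha0, alpha0_se, beta, beta_se, y_d, k, k_se, rbe37``.
    """
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"input table is missing columns: {missing}")

    rows = []
    for cell_line, group in table.groupby("cell_line", sort=False):
        ref_rows = group[group["quality"] == reference_quality]
        if ref_rows.empty:
            raise ValueError(
                f"cell line {cell_line!r} has no reference quality {reference_quality!r}"
            )
        ref = ref_rows.iloc[0]
        lq_ref = LQParameters(
            alpha=ref["alpha"], beta=ref["beta"],
            alpha_se=ref["alpha_se"], beta_se=ref["beta_se"],
        )
        if k_exp_reference is not None and cell_line in k_exp_reference:
            k_anchor = k_exp_reference[cell_line]
        else:
            if "k_exp" not in table.columns or pd.isna(ref.get("k_exp")):
                raise ValueError(
                    f"no foci anchor (k_exp) for the reference quality of {cell_line!r}"
                )
            k_anchor = ValueWithError(
                float(ref["k_exp"]),
                0.0 if pd.isna(ref.get("k_exp_se")) else float(ref["k_exp_se"]),
            )

        for _, row in group.iterrows():
            lq = LQParameters(
                alpha=row["alpha"], beta=row["beta"],
                alpha_se=row["alpha_se"], beta_se=row["beta_se"],
                label=f"{cell_line} {row['quality']}",
            )
            alpha0 = alpha_decomposition(lq, row["y_d"], geometry)
            if row["quality"] == reference_quality:
                # the reference is anchored directly: its beta ratio is
                # identically 1, so no beta uncertainty propagates
                estimate = DSBEstimate(k=k_anchor, basis="direct-foci")
            else:
                estimate = absolute_k(
                    lq.beta_we, lq_ref.beta_we, k_anchor,
                    reference_label=f"{cell_line} {reference_quality}",
                )
            rbe = rbe37(lq, lq_ref, survival_level)
            derived = MKDerived(alpha0=alpha0, k=estimate.k, y_d=float(row["y_d"]))
            rows.append(
                {
                    "cell_line": cell_line,
                    "quality": row["quality"],
                    "alpha": lq.alpha,
                    "alpha_se": lq.alpha_se,
                    "alpha0": derived.alpha0.value,
                    "alpha0_se": derived.alpha0.se,
                    "beta": lq.beta,
                    "beta_se": lq.beta_se,
                    "y_d": derived.y_d,
                    "k": derived.k.value,
                    "k_se": derived.k.se,
                    "rbe37": rbe.rbe37.value,
                }
            )
    return pd.DataFrame(rows)
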