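"""Least-squares fitting of the LQ survival law to clonogenic data.

Because -ln S = alpha*D + beta*D² is linear in (alpha, beta), the fit is
done in log-survival space: an intercept-free linear regression of
-ln S on (D, D²).  That keeps the least-squares problem convex and makes
the covariance of (alpha, beta) available in closed form.  Surviving
fractions are assumed already normalised to the plating efficiency of
unirradiated cells, so S(0) = 1 and the model has no constant term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .core import LQParameters, survival

__all__ = ["SurvivalDataset", "FitResult", "fit_lq", "survival_curve_table"]


@dataclass(frozen=True)
class SurvivalDataset:
    """Clonogenic survival observations for one cell line × quality.

    ``se`` (optional) are standard errors of the surviving fractions,
    used only when inverse-variance weighting is requested.
    """

    dose: np.ndarray
    surviving_fraction: np.ndarray
    se: np.ndarray | None = None
    cell_line: str = ""
    quality: str = ""

    def __post_init__(self) -> None:
        d = np.atleast_1d(np.asarray(self.dose, dtype=float))
        s = np.atleast_1d(np.asarray(self.surviving_fraction, dtype=float))
        if d.shape != s.shape:
            raise ValueError("dose and surviving_fraction must have the same length")
        if np.any(d < 0):
            raise ValueError("doses must be >= 0")
        if np.any((s <= 0) | (s > 1)):
            raise ValueError("surviving fractions must lie in (0, 1]")
        object.__setattr__(self, "dose", d)
        object.__setattr__(self, "surviving_fraction", s)
        if self.se is not None:
            se = np.atleast_1d(np.asarray(self.se, dtype=float))
            if se.shape != d.shape:
                raise ValueError("se must match the number of observations")
            if np.any(se < 0):
                raise ValueError("standard errors must be >= 0")
            object.__setattr__(self, "se", se)

    @property
    def n_distinct_positive_doses(self) -> int:
        return int(np.unique(self.dose[self.dose > 0]).size)

    @property
    def label(self) -> str:
        return " ".join(p for p in (self.cell_line, self.quality) if p)


@dataclass(frozen=True)
class FitResult:
    """An LQ fit with its covariance and residual summary."""

    lq: LQParameters
    covariance: np.ndarray
    residual_ss: float
    n_points: int
    clipped: bool = False  # a coefficient hit the alpha, beta >= 0 bound

    @property
    def dof(self) -> int:
        return self.n_points - 2


def fit_lq(data: SurvivalDataset, weighting: str = "unweighted") -> FitResult:
    """Fit S = exp(-alpha D - beta D²) by least squares on -ln S.

    Parameters
    ----------
    data:
        Needs at least three distinct positive doses for the
        two-parameter fit.
    weighting:
        ``"unweighted"`` (default: every observation counts equally) or
        ``"inverse_variance"`` (weights 1/Var(ln S) ≈ (S/se)², requires
        ``data.se``).

    alpha and beta are estimated as two independent parameters subject
    to the box constraint alpha, beta >= 0; when the unconstrained
    optimum would be negative the fit falls back to non-negative least
    squares and flags ``clipped``.  Standard errors come from the
    covariance of the linear design with residual variance on n - 2
    degrees of freedom.
    """
    if data.n_distinct_positive_doses < 3:
        raise ValueError(
            f"need >= 3 distinct positive doses for a two-parameter fit, "
            f"got {data.n_distinct_positive_doses}"
        )
    d = data.dose
    y = -np.log(data.surviving_fraction)
    X = np.column_stack([d, d**2])

    if weighting == "unweighted":
        w = np.ones_like(d)
    elif weighting == "inverse_variance":
        if data.se is None:
            raise ValueError("inverse-variance weighting needs per-point standard errors")
        if np.any(data.se == 0):
            raise ValueError("zero standard errors cannot be inverse-variance weighted")
        w = (data.surviving_fraction / data.se) ** 2
    else:
        raise ValueError(f"unknown weighting scheme {weighting!r}")

    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    clipped = False
    if np.any(coef < 0):
        coef, _ = nnls(X * sw[:, None], y * sw)
        clipped = True

    resid = y - X @ coef
    n = d.size
    if n <= 2:
        raise ValueError("not enough observations to estimate residual variance")
    s2 = float(np.sum(w * resid**2) / (n - 2))
    xtwx = X.T @ (X * w[:, None])
    cov = s2 * np.linalg.inv(xtwx)
    ses = np.sqrt(np.diag(cov))

    lq = LQParameters(
        alpha=float(coef[0]),
        beta=float(coef[1]),
        alpha_se=float(ses[0]),
        beta_se=float(ses[1]),
        label=data.label,
    )
    return FitResult(
        lq=lq,
        covariance=cov,
        residual_ss=float(np.sum(w * resid**2)),
        n_points=n,
        clipped=clipped,
    )


def survival_curve_table(fit: FitResult, doses: np.ndarray) -> np.ndarray:
    """Predicted surviving fractions of a fit at the given doses."""
    return np.asarray(survival(fit.lq, np.asarray(doses, dtype=float)))
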