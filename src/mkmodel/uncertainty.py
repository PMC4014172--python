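"""First-order (delta-method) propagation of standard errors.

Products, quotients and powers combine *relative* errors in quadrature;
sums and differences combine *absolute* errors in quadrature.  Operands
are always treated as statistically independent — correlations are the
caller's responsibility to rule out or accept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class ValueWithError:
    """A scalar measurement with its standard error.

    Parameters
    ----------
    value:
        The point estimate.
    se:
        Its standard error (>= 0).  Defaults to 0 (an exact value).
    """

    value: float
    se: float = 0.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"value must be finite, got {self.value!r}")
        if not (math.isfinite(self.se) and self.se >= 0.0):
            raise ValueError(f"se must be finite and non-negative, got {self.se!r}")

    @property
    def rel_se(self) -> float:
        """Relative standard error se/|value| (inf for a noisy zero)."""
        if self.value == 0.0:
            return math.inf if self.se > 0.0 else 0.0
        return self.se / abs(self.value)

    # -- multiplicative arithmetic: relative errors in quadrature ---------
    def __mul__(self, other: "ValueWithError | float") -> "ValueWithError":
        if isinstance(other, ValueWithError):
            v = self.value * other.value
            return ValueWithError(v, abs(v) * math.hypot(self.rel_se, other.rel_se))
        return ValueWithError(self.value * other, self.se * abs(other))

    __rmul__ = __mul__

    def __truediv__(self, other: "ValueWithError | float") -> "ValueWithError":
        if isinstance(other, ValueWithError):
            v = self.value / other.value
            return ValueWithError(v, abs(v) * math.hypot(self.rel_se, other.rel_se))
        return ValueWithError(self.value / other, self.se / abs(other))

    def __pow__(self, exponent: float) -> "ValueWithError":
        v = self.value**exponent
        return ValueWithError(v, abs(v * exponent) * self.rel_se)

    # -- additive arithmetic: absolute errors in quadrature ---------------
    def __add__(self, other: "ValueWithError | float") -> "ValueWithError":
        if isinstance(other, ValueWithError):
            return ValueWithError(self.value + other.value, math.hypot(self.se, other.se))
        return ValueWithError(self.value + other, self.se)

    __radd__ = __add__

    def __sub__(self, other: "ValueWithError | float") -> "ValueWithError":
        if isinstance(other, ValueWithError):
            return ValueWithError(self.value - other.value, math.hypot(self.se, other.se))
        return ValueWithError(self.value - other, self.se)

    def __rsub__(self, other: float) -> "ValueWithError":
        return ValueWithError(other - self.value, self.se)

    def __neg__(self) -> "ValueWithError":
        return ValueWithError(-self.value, self.se)

    def __str__(self) -> str:
        return f"{self.value:.4g} ± {self.se:.3g}"
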