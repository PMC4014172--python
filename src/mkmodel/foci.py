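"""Statistics of per-nucleus γ-H2AX focus counts.

Each focus marks a phosphorylated-H2AX site at a DNA double-strand
break, so the mean focus count per nucleus per Gy is the experimental
counterpart (k_exp) of the MK model's DSB yield k.  Counts are consumed
as tabular data; image acquisition and focus segmentation happen
upstream.

The spread attached to k_exp is the per-nucleus standard deviation, not
the standard error of the mean: published ratio uncertainties are
reproduced exactly by SD-based quadrature and not by SEM-based, so SD is
the default, with SEM available by flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .uncertainty import ValueWithError

__all__ = [
    "FociDataset",
    "FociSummary",
    "ComparisonResult",
    "summarize_foci",
    "foci_ratio",
    "compare_conditions",
]


@dataclass(frozen=True)
class FociDataset:
    """Per-nucleus integer focus counts for one condition.

    ``dose`` is 0 for unirradiated (background) controls.
    """

    counts: np.ndarray
    dose: float
    condition: str = ""
    cell_line: str = ""

    def __post_init__(self) -> None:
        counts = np.atleast_1d(np.asarray(self.counts))
        if counts.size < 1:
            raise ValueError("a foci dataset needs at least one nucleus")
        if np.any(counts < 0):
            raise ValueError("focus counts must be >= 0")
        if not np.all(counts == np.floor(counts)):
            raise ValueError("focus counts must be integers")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        object.__setattr__(self, "counts", counts.astype(int))

    @property
    def n_nuclei(self) -> int:
        return int(self.counts.size)


@dataclass(frozen=True)
class FociSummary:
    """Mean ± SD of focus counts and, for irradiated conditions, k_exp."""

    mean: float
    sd: float
    n_nuclei: int
    dose: float
    k_exp: ValueWithError | None
    condition: str = ""
    cell_line: str = ""


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sample comparison of focus counts (Welch's t-test)."""

    statistic: float
    p_value: float
    significant: bool
    test_name: str = "Welch two-sample t-test"


def summarize_foci(
    data: FociDataset, spread: str = "sd", background: float = 0.0
) -> FociSummary:
    """Per-nucleus mean and SD, plus k_exp = mean/D for irradiated data.

    Parameters
    ----------
    spread:
        ``"sd"`` (default) attaches the per-nucleus standard deviation
        to k_exp; ``"sem"`` attaches SD/sqrt(n) instead.
    background:
        Mean background count subtracted from the irradiated mean before
        dividing by dose.  Off (0.0) by default: published per-Gy yields
        are raw means.

    For a background condition (dose 0) k_exp is undefined and None.
    """
    if spread not in ("sd", "sem"):
        raise ValueError(f"spread must be 'sd' or 'sem', got {spread!r}")
    counts = data.counts
    mean = float(np.mean(counts))
    sd = float(np.std(counts, ddof=1)) if counts.size > 1 else 0.0
    k_exp = None
    if data.dose > 0:
        spread_value = sd if spread == "sd" else sd / math.sqrt(counts.size)
        k_exp = ValueWithError((mean - background) / data.dose, spread_value / data.dose)
    return FociSummary(
        mean=mean,
        sd=sd,
        n_nuclei=counts.size,
        dose=data.dose,
        k_exp=k_exp,
        condition=data.condition,
        cell_line=data.cell_line,
    )


def foci_ratio(test: FociSummary, ref: FociSummary) -> ValueWithError:
    """Ratio of foci-based DSB yields k_exp(test) / k_exp(ref).

    Relative uncertainties combine in quadrature; with the default
    SD-based spreads the result describes per-nucleus variability, not
    the standard error of the mean ratio.
    """
    if test.k_exp is None or ref.k_exp is None:
        raise ValueError("both summaries need a defined k_exp (irradiated conditions)")
    if ref.k_exp.value == 0:
        raise ValueError("reference k_exp is zero; ratio undefined")
    return test.k_exp / ref.k_exp


def compare_conditions(a: FociDataset, b: FociDataset, alpha_level: float = 0.05) -> ComparisonResult:
    """Welch's two-sample t-test on per-nucleus counts.

    Flags significance at p < ``alpha_level``.  Degenerate inputs (both
    samples constant) are reported as p = 1 when the constants agree and
    p = 0 when they differ, rather than NaN.
    """
    if a.n_nuclei < 2 or b.n_nuclei < 2:
        raise ValueError("each condition needs at least two nuclei to compare")
    if np.ptp(a.counts) == 0 and np.ptp(b.counts) == 0:
        same = a.counts[0] == b.counts[0]
        return ComparisonResult(
            statistic=0.0 if same else math.inf,
            p_value=1.0 if same else 0.0,
            significant=not same,
        )
    t, p = stats.ttest_ind(a.counts, b.counts, equal_var=False)
    return ComparisonResult(statistic=float(t), p_value=float(p), significant=bool(p < alpha_level))
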