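"""Readers and writers for the package's plain-text data dialects.

All on-disk formats are delimited text: a survival CSV
(``dose_gy, surviving_fraction, se?, cell_line, quality``), a foci CSV
(``cell_line, condition, dose_gy, nucleus_id, focus_count``), a
two-column lineal-energy spectrum (``# comments``, y then f(y)), and a
YAML analysis configuration.  Malformed rows are rejected with their
1-based line numbers.
"""

from __future__ import annotations

import hashlib
import importlib.resources
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import DomainGeometry
from .fitting import SurvivalDataset
from .foci import FociDataset
from .microdosimetry import LinealEnergySpectrum
from .uncertainty import ValueWithError

__all__ = [
    "DataFormatError",
    "AnalysisConfig",
    "read_survival_csv",
    "write_survival_csv",
    "read_foci_csv",
    "write_foci_csv",
    "read_spectrum",
    "write_spectrum",
    "load_published_table",
]

#: significant digits used when writing numeric CSV/spectrum columns
_DIGITS = 12


class DataFormatError(ValueError):
    """A file violated its documented dialect; the message names the line."""


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing required column(s) {missing}")


def _numeric(df: pd.DataFrame, column: str, path: Path) -> pd.Series:
    converted = pd.to_numeric(df[column], errors="coerce")
    bad = df.index[converted.isna() & df[column].notna()]
    if len(bad):
        # +2: one for the header line, one for 0-based indexing
        raise DataFormatError(
            f"{path}: non-numeric value in column {column!r} at line {bad[0] + 2}"
        )
    return converted


def read_survival_csv(path: str | Path) -> list[SurvivalDataset]:
    """Load survival observations, one dataset per cell line × quality."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("dose_gy", "surviving_fraction"), path)
    dose = _numeric(df, "dose_gy", path)
    sf = _numeric(df, "surviving_fraction", path)
    for idx in df.index:
        if pd.isna(dose[idx]) or pd.isna(sf[idx]):
            raise DataFormatError(f"{path}: empty dose or surviving fraction at line {idx + 2}")
        if dose[idx] < 0:
            raise DataFormatError(f"{path}: negative dose at line {idx + 2}")
        if not 0 < sf[idx] <= 1:
            raise DataFormatError(f"{path}: surviving fraction outside (0, 1] at line {idx + 2}")
    df["dose_gy"] = dose
    df["surviving_fraction"] = sf
    if "cell_line" not in df.columns:
        df["cell_line"] = ""
    if "quality" not in df.columns:
        df["quality"] = ""
    datasets = []
    for (cell_line, quality), group in df.groupby(["cell_line", "quality"], sort=False):
        se = None
        if "se" in group.columns and group["se"].notna().all():
            se = _numeric(group, "se", path).to_numpy()
        datasets.append(
            SurvivalDataset(
                dose=group["dose_gy"].to_numpy(),
                surviving_fraction=group["surviving_fraction"].to_numpy(),
                se=se,
                cell_line=str(cell_line),
                quality=str(quality),
            )
        )
    return datasets


def write_survival_csv(datasets: SurvivalDataset | list[SurvivalDataset], path: str | Path) -> None:
    if isinstance(datasets, SurvivalDataset):
        datasets = [datasets]
    frames = []
    for ds in datasets:
        frame = pd.DataFrame(
            {
                "dose_gy": ds.dose,
                "surviving_fraction": ds.surviving_fraction,
                "se": ds.se if ds.se is not None else np.nan,
                "cell_line": ds.cell_line,
                "quality": ds.quality,
            }
        )
        frames.append(frame)
    pd.concat(frames).to_csv(path, index=False, float_format=f"%.{_DIGITS}g")


def read_foci_csv(path: str | Path) -> list[FociDataset]:
    """Load per-nucleus focus counts, one dataset per condition."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ("cell_line", "condition", "dose_gy", "focus_count"), path)
    dose = _numeric(df, "dose_gy", path)
    counts = _numeric(df, "focus_count", path)
    for idx in df.index:
        if dose[idx] < 0:
            raise DataFormatError(f"{path}: negative dose at line {idx + 2}")
        if counts[idx] < 0 or counts[idx] != np.floor(counts[idx]):
            raise DataFormatError(f"{path}: focus_count not a non-negative integer at line {idx + 2}")
    df["dose_gy"] = dose
    df["focus_count"] = counts
    datasets = []
    for (cell_line, condition), group in df.groupby(["cell_line", "condition"], sort=False):
        doses = group["dose_gy"].unique()
        if doses.size != 1:
            raise DataFormatError(
                f"{path}: condition {condition!r} of {cell_line!r} mixes doses {sorted(doses)}"
            )
        datasets.append(
            FociDataset(
                counts=group["focus_count"].to_numpy(dtype=int),
                dose=float(doses[0]),
                condition=str(condition),
                cell_line=str(cell_line),
            )
        )
    return datasets


def write_foci_csv(datasets: FociDataset | list[FociDataset], path: str | Path) -> None:
    if isinstance(datasets, FociDataset):
        datasets = [datasets]
    frames = []
    for ds in datasets:
        frames.append(
            pd.DataFrame(
                {
                    "cell_line": ds.cell_line,
                    "condition": ds.condition,
                    "dose_gy": ds.dose,
                    "nucleus_id": np.arange(1, ds.n_nuclei + 1),
                    "focus_count": ds.counts,
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False, float_format=f"%.{_DIGITS}g")


def read_spectrum(path: str | Path) -> LinealEnergySpectrum:
    """Load a two-column (y [keV/μm], f(y)) spectrum; '#' starts a comment."""
    path = Path(path)
    try:
        data = np.loadtxt(path, comments="#", ndmin=2)
    except ValueError as exc:
        raise DataFormatError(f"{path}: could not parse spectrum file ({exc})") from exc
    if data.shape[1] != 2:
        raise DataFormatError(f"{path}: spectrum file needs exactly two columns, got {data.shape[1]}")
    try:
        return LinealEnergySpectrum(y=data[:, 0], f=data[:, 1])
    except ValueError as exc:
        raise DataFormatError(f"{path}: invalid spectrum ({exc})") from exc


def write_spectrum(spectrum: LinealEnergySpectrum, path: str | Path) -> None:
    header = "lineal energy spectrum: y [keV/um]  f(y) [per keV/um]"
    np.savetxt(path, np.column_stack([spectrum.y, spectrum.f]), header=header,
               fmt=f"%.{_DIGITS}g")


@dataclass
class AnalysisConfig:
    """Pipeline configuration; round-trips losslessly through YAML."""

    r_d: float = 0.5
    rho: float = 1.0
    reference_quality: str = "200 kVp"
    #: per cell line: [k_exp value, k_exp spread] for the reference quality
    k_exp_reference: dict[str, list[float]] = field(default_factory=dict)
    survival_level: float | None = None  # None -> the e^-1 (D37) convention
    spread: str = "sd"  # 'sd' or 'sem' on foci-based k_exp
    seed: int = 0

    @property
    def geometry(self) -> DomainGeometry:
        return DomainGeometry(r_d=self.r_d, rho=self.rho)

    def k_exp_values(self) -> dict[str, ValueWithError]:
        return {
            cell: ValueWithError(float(v[0]), float(v[1]) if len(v) > 1 else 0.0)
            for cell, v in self.k_exp_reference.items()
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise DataFormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def load_published_table() -> pd.DataFrame:
    """The bundled published MK parameter table for CHO-K1 and H1299
    photon exposures (alpha, beta, alpha0, y_D, k and foci yields with
    standard errors) — the package's primary regression surface."""
    ref = importlib.resources.files("mkmodel").joinpath("data/published_photon_parameters.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
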