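"""Core containers for UV absorbance data.

A calibration study pairs a :class:`SpectralMatrix` (samples x wavelengths,
the ``X`` block of every model) with a :class:`ConcentrationMatrix`
(samples x components in ug/mL, the ``Y`` block).  Both are bound to sample
identifiers so alignment can be checked, and spectra are additionally bound
to a :class:`WavelengthGrid` so no module ever addresses wavelengths by
bare column index.

The CSV dialects here are the interchange format of the whole package:
spectra are stored wide (one column per sample, matching instrument
exports), concentrations long (one row per sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "SpectralMatrix",
    "ConcentrationMatrix",
    "make_grid",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_concentrations_csv",
    "write_concentrations_csv",
    "mean_center",
]

#: Processing stages a spectral block can be in.  Raw absorbance must be
#: (essentially) non-negative; derivative and SNV stages may not be.
STAGES = ("raw", "smoothed", "derivative1", "derivative2", "snv", "centered")

#: Small negative absorbances are tolerated in the raw stage: near-zero
#: signal plus instrument noise and baseline drift legitimately dip below
#: zero on real spectrometers.
RAW_NEGATIVE_TOL = 0.05


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength axis in nm."""

    start_nm: float
    end_nm: float
    step_nm: float
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=float)
        object.__setattr__(self, "labels", labels)
        if self.step_nm <= 0:
            raise ValueError(f"step_nm must be positive, got {self.step_nm}")
        if self.end_nm < self.start_nm:
            raise ValueError(
                f"end_nm ({self.end_nm}) must be >= start_nm ({self.start_nm})"
            )
        n = round((self.end_nm - self.start_nm) / self.step_nm) + 1
        if len(labels) != n:
            raise ValueError(
                f"grid advertises {n} points but carries {len(labels)} labels"
            )
        if n > 1:
            diffs = np.diff(labels)
            if np.any(diffs <= 0):
                raise ValueError("wavelength labels must be strictly increasing")
            if np.max(np.abs(diffs - self.step_nm)) > 1e-9:
                raise ValueError("wavelength labels are not uniformly spaced")

    @property
    def n_points(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return self.n_points


def make_grid(start_nm: float, end_nm: float, step_nm: float) -> WavelengthGrid:
    """Build a uniform grid from *start_nm* to *end_nm* inclusive.

    The step must divide the span to within 1e-6 nm; the default study grid
    ``make_grid(200, 260, 0.2)`` has 301 points.
    """
    if step_nm <= 0:
        raise ValueError(f"step_nm must be positive, got {step_nm}")
    if end_nm < start_nm:
        raise ValueError(f"end_nm ({end_nm}) < start_nm ({start_nm})")
    span = end_nm - start_nm
    n_steps = round(span / step_nm)
    if abs(span - n_steps * step_nm) > 1e-6:
        raise ValueError(
            f"step {step_nm} nm does not divide the span {span} nm evenly"
        )
    labels = start_nm + step_nm * np.arange(n_steps + 1)
    # pin the endpoint exactly to avoid accumulated float drift
    labels[-1] = end_nm
    return WavelengthGrid(start_nm, end_nm, step_nm, labels)


def _check_ids(ids: Sequence[str], n: int, what: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if len(ids) != n:
        raise ValueError(f"{what}: {len(ids)} ids for {n} rows")
    if len(set(ids)) != len(ids):
        raise ValueError(f"{what}: duplicate identifiers")
    return ids


@dataclass(frozen=True)
class SpectralMatrix:
    """Absorbance block: one row per sample on a shared wavelength grid."""

    grid: WavelengthGrid
    absorbance: np.ndarray
    sample_ids: tuple[str, ...]
    stage: str = "raw"

    def __post_init__(self) -> None:
        a = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        object.__setattr__(self, "absorbance", a)
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if a.shape[1] != self.grid.n_points:
            raise ValueError(
                f"absorbance has {a.shape[1]} columns but grid has "
                f"{self.grid.n_points} points"
            )
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance contains non-finite entries")
        if self.stage == "raw" and a.size and a.min() < -RAW_NEGATIVE_TOL:
            raise ValueError(
                f"raw absorbance has entries below -{RAW_NEGATIVE_TOL} AU "
                f"(min {a.min():.4g})"
            )
        object.__setattr__(
            self, "sample_ids", _check_ids(self.sample_ids, a.shape[0], "spectra")
        )

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]

    def with_values(self, values: np.ndarray, stage: str) -> "SpectralMatrix":
        return replace(self, absorbance=np.asarray(values, float), stage=stage)


@dataclass(frozen=True)
class ConcentrationMatrix:
    """Component concentrations in ug/mL, one row per sample."""

    concentrations: np.ndarray
    component_names: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.concentrations, dtype=float))
        object.__setattr__(self, "concentrations", c)
        if not np.all(np.isfinite(c)):
            raise ValueError("concentrations contain non-finite entries")
        if c.size and c.min() < 0:
            raise ValueError(f"concentrations must be >= 0 (min {c.min():.4g})")
        names = tuple(str(n) for n in self.component_names)
        if len(names) != c.shape[1]:
            raise ValueError(
                f"{len(names)} component names for {c.shape[1]} columns"
            )
        object.__setattr__(self, "component_names", names)
        object.__setattr__(
            self, "sample_ids", _check_ids(self.sample_ids, c.shape[0], "concentrations")
        )

    @property
    def n_samples(self) -> int:
        return self.concentrations.shape[0]

    @property
    def n_components(self) -> int:
        return self.concentrations.shape[1]


def check_aligned(X: SpectralMatrix, Y: ConcentrationMatrix) -> None:
    """Raise unless X and Y carry the same samples in the same order."""
    if X.sample_ids != Y.sample_ids:
        raise ValueError("spectra and concentrations are not sample-aligned")


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def write_spectra_csv(spectra: SpectralMatrix, path: str | Path) -> None:
    """Write the wide spectra dialect: wavelength_nm column + one per sample."""
    df = pd.DataFrame(
        spectra.absorbance.T,
        columns=list(spectra.sample_ids),
    )
    df.insert(0, "wavelength_nm", spectra.grid.labels)
    df.to_csv(path, index=False, float_format="%.17g")


def read_spectra_csv(path: str | Path, stage: str = "raw") -> SpectralMatrix:
    """Read the wide spectra dialect written by :func:`write_spectra_csv`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"{path}: cannot parse spectra CSV: {exc}") from exc
    if df.columns[0] != "wavelength_nm":
        raise ValueError(
            f"{path}: first column must be 'wavelength_nm', got {df.columns[0]!r}"
        )
    if df.shape[1] < 2:
        raise ValueError(f"{path}: no sample columns")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.argmax((bad | df[col].isna()).to_numpy()))
            raise ValueError(
                f"{path}: non-numeric or missing cell at row {row + 2}, "
                f"column {col!r}"
            )
    wl = df["wavelength_nm"].to_numpy(float)
    dwl = np.diff(wl)
    if np.any(dwl == 0):
        dup = wl[1:][dwl == 0][0]
        raise ValueError(f"{path}: duplicated wavelength row at {dup} nm")
    if np.any(dwl < 0):
        raise ValueError(f"{path}: wavelengths are not strictly increasing")
    step = float(np.mean(dwl)) if len(wl) > 1 else 1.0
    grid = WavelengthGrid(float(wl[0]), float(wl[-1]), step, wl)
    values = df.iloc[:, 1:].to_numpy(float).T
    return SpectralMatrix(grid, values, tuple(df.columns[1:]), stage=stage)


def write_concentrations_csv(conc: ConcentrationMatrix, path: str | Path) -> None:
    df = pd.DataFrame(conc.concentrations, columns=list(conc.component_names))
    df.insert(0, "sample_id", list(conc.sample_ids))
    df.to_csv(path, index=False, float_format="%.17g")


def read_concentrations_csv(path: str | Path) -> ConcentrationMatrix:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "sample_id":
        raise ValueError(
            f"{path}: first column must be 'sample_id', got {df.columns[0]!r}"
        )
    values = df.iloc[:, 1:].to_numpy(float)
    return ConcentrationMatrix(
        values, tuple(df.columns[1:]), tuple(df["sample_id"].astype(str))
    )


# ---------------------------------------------------------------------------
# Centering
# ---------------------------------------------------------------------------

def mean_center(block):
    """Column-center a data block.

    Accepts a plain 2-D array, a :class:`SpectralMatrix` or a
    :class:`ConcentrationMatrix`.  Returns ``(centered, column_means)`` where
    *centered* has the same type as the input (stage becomes ``centered``
    for spectra).
    """
    if isinstance(block, SpectralMatrix):
        centered, means = mean_center(block.absorbance)
        return block.with_values(centered, "centered"), means
    if isinstance(block, ConcentrationMatrix):
        values = block.concentrations
        if values.shape[0] < 1:
            raise ValueError("cannot center an empty matrix")
        means = values.mean(axis=0)
        return values - means, means
    values = np.atleast_2d(np.asarray(block, dtype=float))
    if values.shape[0] < 1 or values.size == 0:
        raise ValueError("cannot center an empty matrix")
    means = values.mean(axis=0)
    return values - means, means
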