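"""Synthetic two-component UV mixture spectra.

The study system is a binary mixture of two strongly overlapping
UV-absorbing analytes measured over 200-260 nm.  Pure-component spectra
are modelled as sums of Gaussian bands scaled to plausible bench-UV
absorbances; mixtures follow Beer-Lambert superposition
``A = C @ S.T`` with optional multiplicative scatter, linear baseline
drift and additive instrument noise.  ``make_study`` assembles the full
study bundle: the 25-mixture five-level calibration design over
5-25 ug/mL, 13-point LHS and Monte Carlo validation sets, and an
optional plasma-surrogate set carrying a broad matrix-interferent band.

The band positions are synthetic stand-ins reproducing the overlap
regime, not measurements of the real drugs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .design import DEFAULT_LEVELS, lhs_sample, mc_sample, multilevel_design
from .spectra import (
    ConcentrationMatrix,
    SpectralMatrix,
    WavelengthGrid,
    make_grid,
    write_concentrations_csv,
    write_spectra_csv,
)

__all__ = [
    "ComponentSpec",
    "NoiseSpec",
    "StudyBundle",
    "default_grid",
    "default_components",
    "pure_spectrum",
    "simulate_mixtures",
    "make_study",
    "write_bundle",
]


@dataclass(frozen=True)
class ComponentSpec:
    """Pure-component spectrum as Gaussian bands.

    bands: (center_nm, sigma_nm, height) triples; molar_scale converts the
    unit band envelope to absorbance per (ug/mL).
    """

    name: str
    bands: tuple[tuple[float, float, float], ...]
    molar_scale: float

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError(f"component {self.name!r} has no bands")
        for c, s, h in self.bands:
            if s <= 0:
                raise ValueError(f"band sigma must be > 0, got {s}")
            if h < 0:
                raise ValueError(f"band height must be >= 0, got {h}")
        if self.molar_scale < 0:
            raise ValueError("molar_scale must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Instrument-noise settings for the generator.

    additive_sd: homoscedastic detector noise (AU); scatter_sd: SD of the
    per-sample multiplicative scatter factor; baseline_slope_sd: SD of the
    per-sample linear baseline slope (AU/nm); interferent_on adds the broad
    plasma-surrogate band and raises additive noise.
    """

    additive_sd: float = 0.002
    scatter_sd: float = 0.01
    baseline_slope_sd: float = 1e-4
    interferent_on: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("additive_sd", "scatter_sd", "baseline_slope_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


NoiseSpec.NONE = NoiseSpec(0.0, 0.0, 0.0, False, 0)


def default_grid() -> WavelengthGrid:
    """The study grid: 200-260 nm at 0.2 nm (301 points)."""
    return make_grid(200.0, 260.0, 0.2)


def _band_envelope(bands, labels: np.ndarray) -> np.ndarray:
    out = np.zeros_like(labels, dtype=float)
    for center, sigma, height in bands:
        out += height * np.exp(-((labels - center) ** 2) / (2 * sigma**2))
    return out


def _scaled_component(name, bands, grid: WavelengthGrid, peak_at_15: float = 0.4):
    """Fix molar_scale so 15 ug/mL gives the stated peak absorbance.

    0.4 AU keeps the strongest 25+25 ug/mL mixture under ~1.3 AU, inside
    the Beer-Lambert linear range of a bench UV instrument.
    """
    peak = _band_envelope(bands, grid.labels).max()
    return ComponentSpec(name, bands, peak_at_15 / (15.0 * peak))


def default_components(grid: WavelengthGrid | None = None):
    """Two strongly overlapping synthetic analytes (stand-in band sets).

    Both are normalised so 15 ug/mL yields a ~0.4 AU peak; their
    normalised spectra overlap with cosine similarity > 0.7 on the study
    grid, reproducing the heavily overlapped regime that motivates
    multivariate calibration.
    """
    grid = grid or default_grid()
    a = _scaled_component(
        "analyte_a", ((210.0, 8.0, 1.0), (240.0, 12.0, 0.35)), grid
    )
    b = _scaled_component(
        "analyte_b", ((205.0, 6.0, 1.2), (225.0, 10.0, 0.5)), grid
    )
    return (a, b)


#: Broad matrix-interferent band used by the plasma surrogate (200-220 nm).
_INTERFERENT_BANDS = ((208.0, 14.0, 1.0),)


def pure_spectrum(spec: ComponentSpec, grid: WavelengthGrid) -> np.ndarray:
    """Unit-concentration spectrum s(lambda) of one component (1-D array)."""
    return spec.molar_scale * _band_envelope(spec.bands, grid.labels)


def simulate_mixtures(
    concentrations: ConcentrationMatrix,
    specs,
    noise: NoiseSpec = NoiseSpec.NONE,
    grid: WavelengthGrid | None = None,
) -> SpectralMatrix:
    """Beer-Lambert mixture spectra with optional instrument noise.

    ``A = (C @ S.T) * (1 + scatter) + baseline + additive``; with the
    all-zero NoiseSpec the map is exactly linear in the concentrations.
    """
    grid = grid or default_grid()
    specs = tuple(specs)
    C = concentrations.concentrations
    if C.shape[1] != len(specs):
        raise ValueError(
            f"{C.shape[1]} concentration columns for {len(specs)} components"
        )
    S = np.stack([pure_spectrum(s, grid) for s in specs], axis=1)  # p x k
    A = C @ S.T
    n, p = A.shape
    rng = np.random.default_rng(noise.seed)
    if noise.scatter_sd > 0:
        A = A * (1.0 + rng.normal(0.0, noise.scatter_sd, size=(n, 1)))
    if noise.baseline_slope_sd > 0:
        slopes = rng.normal(0.0, noise.baseline_slope_sd, size=(n, 1))
        A = A + slopes * (grid.labels - grid.labels[0])
    additive_sd = noise.additive_sd
    if noise.interferent_on:
        amp = np.abs(rng.normal(0.0, 0.03, size=(n, 1)))
        A = A + amp * _band_envelope(_INTERFERENT_BANDS, grid.labels)
        additive_sd = max(additive_sd, 1.5 * noise.additive_sd)
    if additive_sd > 0:
        A = A + rng.normal(0.0, additive_sd, size=(n, p))
    return SpectralMatrix(grid, A, concentrations.sample_ids, stage="raw")


@dataclass(frozen=True)
class StudyBundle:
    """Complete synthetic study: calibration + validation sets."""

    grid: WavelengthGrid
    specs: tuple[ComponentSpec, ...]
    noise: NoiseSpec
    calibration_x: SpectralMatrix
    calibration_y: ConcentrationMatrix
    validation_lhs_x: SpectralMatrix
    validation_lhs_y: ConcentrationMatrix
    validation_mc_x: SpectralMatrix
    validation_mc_y: ConcentrationMatrix
    plasma_x: SpectralMatrix | None = None
    plasma_y: ConcentrationMatrix | None = None
    seed: int = 0


def _conc_matrix(points: np.ndarray, names, prefix: str) -> ConcentrationMatrix:
    ids = tuple(f"{prefix}{i + 1:02d}" for i in range(points.shape[0]))
    return ConcentrationMatrix(points, names, ids)


def make_study(
    seed: int = 0,
    noise: NoiseSpec | None = None,
    n_validation: int = 13,
    plasma: bool = False,
    specs=None,
    grid: WavelengthGrid | None = None,
) -> StudyBundle:
    """Generate the full study bundle.

    25 calibration mixtures from the five-level design, *n_validation*
    (default 13) LHS and Monte Carlo validation points over 5-25 ug/mL,
    and optionally a plasma-surrogate set (LHS points re-simulated with
    the interferent band on).  Deterministic given *seed*.
    """
    grid = grid or default_grid()
    specs = tuple(specs) if specs is not None else default_components(grid)
    names = tuple(s.name for s in specs)
    if noise is None:
        noise = NoiseSpec(seed=seed)
    design = multilevel_design(5, 2, DEFAULT_LEVELS)
    bounds = ((DEFAULT_LEVELS[0], DEFAULT_LEVELS[-1]),) * 2
    cal_y = _conc_matrix(design.concentrations, names, "cal")
    lhs = lhs_sample(n_validation, 2, bounds, seed=seed + 1)
    mc = mc_sample(n_validation, 2, bounds, seed=seed + 2)
    lhs_y = _conc_matrix(lhs.points, names, "val_lhs")
    mc_y = _conc_matrix(mc.points, names, "val_mc")

    def sim(conc, sub_seed, interferent=False):
        ns = NoiseSpec(
            noise.additive_sd,
            noise.scatter_sd,
            noise.baseline_slope_sd,
            interferent,
            seed=sub_seed,
        )
        return simulate_mixtures(conc, specs, ns, grid)

    cal_x = sim(cal_y, seed + 10)
    lhs_x = sim(lhs_y, seed + 11)
    mc_x = sim(mc_y, seed + 12)
    plasma_x = plasma_y = None
    if plasma:
        plasma_y = _conc_matrix(lhs.points, names, "plasma")
        plasma_x = sim(plasma_y, seed + 13, interferent=True)
    return StudyBundle(
        grid, specs, noise, cal_x, cal_y, lhs_x, lhs_y, mc_x, mc_y,
        plasma_x, plasma_y, seed,
    )


def write_bundle(bundle: StudyBundle, out_dir: str | Path) -> None:
    """Write the bundle as spectra/concentration CSVs plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs = {
        "calibration": (bundle.calibration_x, bundle.calibration_y),
        "validation_lhs": (bundle.validation_lhs_x, bundle.validation_lhs_y),
        "validation_mc": (bundle.validation_mc_x, bundle.validation_mc_y),
    }
    if bundle.plasma_x is not None:
        pairs["plasma"] = (bundle.plasma_x, bundle.plasma_y)
    for name, (x, y) in pairs.items():
        write_spectra_csv(x, out / f"{name}_spectra.csv")
        write_concentrations_csv(y, out / f"{name}_concentrations.csv")
    manifest = {
        "seed": bundle.seed,
        "synthetic": True,
        "note": "band positions are synthetic stand-ins, not the real drugs",
        "components": [asdict(s) for s in bundle.specs],
        "noise": asdict(bundle.noise),
        "grid": {
            "start_nm": bundle.grid.start_nm,
            "end_nm": bundle.grid.end_nm,
            "step_nm": bundle.grid.step_nm,
        },
        "sets": {k: v[0].n_samples for k, v in pairs.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
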