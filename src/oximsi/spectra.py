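"""Chromophore extinction spectra and wavelength-grid arithmetic.

This module holds the spectral building blocks shared by the forward tissue
model (:mod:`oximsi.phantom`) and the inverse model (:mod:`oximsi.unmixing`):
the acquisition wavelength grid, oxy-/deoxy-hemoglobin extinction spectra
resampled onto that grid, and the Beer–Lambert regression design matrix whose
columns are the per-band extinction coefficients plus a constant scattering
offset (and an optional linear-in-wavelength slope).

All extinction values are in relative units: only the oxygen-saturation ratio
and relative total hemoglobin are ever reported, so an absolute molar scale is
unnecessary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "SpectraError",
    "InvalidGridError",
    "OutOfSupportError",
    "UnderdeterminedError",
    "CollinearityError",
    "WavelengthGrid",
    "ExtinctionSpectrum",
    "DesignMatrix",
    "default_grid",
    "load_extinction_table",
    "resample_extinction",
    "build_design",
]

#: Wavelength range (nm) addressable by the tuneable filter / light source.
FILTER_RANGE_NM = (400.0, 720.0)

#: Default filter passband full width at half maximum, nm.
DEFAULT_BANDWIDTH_FWHM = 15.0

_EXTINCTION_RESOURCE = "hemoglobin_extinction_synthetic.csv"


class SpectraError(ValueError):
    """Base class for spectral-model errors."""


class InvalidGridError(SpectraError):
    """Wavelength grid violates its invariants."""


class OutOfSupportError(SpectraError):
    """Requested wavelengths fall outside a spectrum's support."""


class UnderdeterminedError(SpectraError):
    """Fewer bands than regressors."""


class CollinearityError(SpectraError):
    """Design matrix is rank deficient."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band centers (nm) defining the depth of a reflectance cube.

    Parameters
    ----------
    centers
        Strictly increasing band-center wavelengths in nm, each within the
        tuneable-filter range of 400–720 nm.
    bandwidth_fwhm
        Filter passband full width at half maximum, nm.
    """

    centers: np.ndarray
    bandwidth_fwhm: float = DEFAULT_BANDWIDTH_FWHM

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        if centers.ndim != 1 or centers.size == 0:
            raise InvalidGridError("grid needs a 1-D, non-empty list of centers")
        if centers.size > 1 and not np.all(np.diff(centers) > 0):
            raise InvalidGridError("band centers must be strictly increasing")
        lo, hi = FILTER_RANGE_NM
        if centers[0] < lo or centers[-1] > hi:
            raise InvalidGridError(
                f"band centers must lie within [{lo:.0f}, {hi:.0f}] nm, "
                f"got [{centers[0]:.1f}, {centers[-1]:.1f}]"
            )
        if not self.bandwidth_fwhm > 0:
            raise InvalidGridError("bandwidth_fwhm must be positive")
        object.__setattr__(self, "centers", centers)

    def __len__(self) -> int:
        return int(self.centers.size)

    def to_dict(self) -> dict:
        """JSON-serializable description ({start, stop, step, fwhm} style)."""
        d = {"centers": self.centers.tolist(), "fwhm": float(self.bandwidth_fwhm)}
        if len(self) > 1:
            steps = np.diff(self.centers)
            if np.allclose(steps, steps[0]):
                d.update(
                    start=float(self.centers[0]),
                    stop=float(self.centers[-1]),
                    step=float(steps[0]),
                )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "WavelengthGrid":
        fwhm = float(d.get("fwhm", DEFAULT_BANDWIDTH_FWHM))
        if "centers" in d:
            return cls(np.asarray(d["centers"], dtype=float), fwhm)
        return default_grid(d["start"], d["stop"], d["step"], bandwidth_fwhm=fwhm)


def default_grid(
    start_nm: float = 500.0,
    stop_nm: float = 620.0,
    step_nm: float = 10.0,
    *,
    bandwidth_fwhm: float = DEFAULT_BANDWIDTH_FWHM,
) -> WavelengthGrid:
    """Arithmetic acquisition grid ``start, start+step, ..., stop`` (inclusive).

    The defaults give the 13-band 500–620 nm cube used throughout the package.
    """
    if step_nm <= 0:
        raise InvalidGridError("step must be positive")
    if start_nm > stop_nm:
        raise InvalidGridError("start must not exceed stop")
    n = int(round((stop_nm - start_nm) / step_nm)) + 1
    centers = start_nm + step_nm * np.arange(n)
    centers = centers[centers <= stop_nm + 1e-9]
    return WavelengthGrid(centers, bandwidth_fwhm)


@dataclass(frozen=True)
class ExtinctionSpectrum:
    """Tabulated extinction coefficient of one chromophore (relative units)."""

    name: str
    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if w.shape != v.shape or w.ndim != 1 or w.size < 2:
            raise SpectraError("spectrum needs matching 1-D wavelength/value arrays")
        if not np.all(np.diff(w) > 0):
            raise SpectraError("spectrum wavelengths must be strictly increasing")
        if np.any(v < 0):
            raise SpectraError("extinction values must be non-negative")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "values", v)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])


def load_extinction_table() -> dict[str, ExtinctionSpectrum]:
    """Load the packaged hemoglobin extinction table.

    Returns a mapping with keys ``"oxyhemoglobin"`` and ``"deoxyhemoglobin"``.
    The packaged table is a synthetic analytic compilation (see the CSV header
    for its construction) covering 450–1000 nm at 2 nm spacing, in relative
    units.
    """
    import pandas as pd

    ref = resources.files("oximsi.data").joinpath(_EXTINCTION_RESOURCE)
    with ref.open("r") as fh:
        raw = pd.read_csv(fh, comment="#")
    wl = raw["wavelength_nm"].to_numpy()
    return {
        "oxyhemoglobin": ExtinctionSpectrum("oxyhemoglobin", wl, raw["epsilon_oxy"]),
        "deoxyhemoglobin": ExtinctionSpectrum(
            "deoxyhemoglobin", wl, raw["epsilon_deoxy"]
        ),
    }


def resample_extinction(
    spectrum: ExtinctionSpectrum,
    grid: WavelengthGrid,
    *,
    simulate_bandwidth: bool = False,
    passband: str = "boxcar",
    n_quad: int = 33,
) -> np.ndarray:
    """Place a tabulated spectrum on the acquisition grid.

    With ``simulate_bandwidth=False`` the spectrum is linearly interpolated at
    each band center.  With ``simulate_bandwidth=True`` each band value is the
    passband-weighted mean of the spectrum around the center: a boxcar of width
    ``grid.bandwidth_fwhm`` by default, or a Gaussian of that FWHM
    (``passband="gaussian"``, truncated at ±2σ).
    """
    lo, hi = spectrum.support
    half = grid.bandwidth_fwhm / 2.0 if simulate_bandwidth else 0.0
    if passband == "gaussian" and simulate_bandwidth:
        half = grid.bandwidth_fwhm / 2.3548 * 2.0  # ±2 sigma
    if grid.centers[0] - half < lo - 1e-9 or grid.centers[-1] + half > hi + 1e-9:
        raise OutOfSupportError(
            f"grid (±{half:.1f} nm) exceeds spectrum support [{lo:.0f}, {hi:.0f}] nm"
        )
    if not simulate_bandwidth:
        return np.interp(grid.centers, spectrum.wavelengths, spectrum.values)
    offsets = np.linspace(-half, half, n_quad)
    samples = np.interp(
        grid.centers[:, None] + offsets[None, :],
        spectrum.wavelengths,
        spectrum.values,
    )
    if passband == "gaussian":
        sigma = grid.bandwidth_fwhm / 2.3548
        w = np.exp(-0.5 * (offsets / sigma) ** 2)
        return samples @ w / w.sum()
    if passband != "boxcar":
        raise SpectraError(f"unknown passband {passband!r}")
    return samples.mean(axis=1)


@dataclass(frozen=True)
class DesignMatrix:
    """Beer–Lambert regression design: rows = bands, columns = regressors.

    Column order is always ``[oxyhemoglobin, deoxyhemoglobin, offset]`` with an
    optional trailing normalized wavelength ``slope`` column.
    """

    grid: WavelengthGrid
    columns: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.grid), len(self.columns)):
            raise SpectraError("design shape must be (n_bands, n_regressors)")
        object.__setattr__(self, "matrix", m)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    @property
    def oxy(self) -> np.ndarray:
        return self.matrix[:, self.columns.index("oxyhemoglobin")]

    @property
    def deoxy(self) -> np.ndarray:
        return self.matrix[:, self.columns.index("deoxyhemoglobin")]


def build_design(
    grid: WavelengthGrid,
    oxy: np.ndarray | None = None,
    deoxy: np.ndarray | None = None,
    *,
    include_slope: bool = False,
    simulate_bandwidth: bool = False,
    condition_cap: float = 1e8,
) -> DesignMatrix:
    """Assemble the per-pixel regression design on ``grid``.

    ``oxy``/``deoxy`` are extinction vectors already resampled on the grid;
    when omitted they are resampled from the packaged table.  A constant
    offset column models wavelength-independent scattering attenuation; with
    ``include_slope=True`` a centered, span-normalized wavelength column
    additionally captures a linear scattering trend.
    """
    if oxy is None or deoxy is None:
        table = load_extinction_table()
        if oxy is None:
            oxy = resample_extinction(
                table["oxyhemoglobin"], grid, simulate_bandwidth=simulate_bandwidth
            )
        if deoxy is None:
            deoxy = resample_extinction(
                table["deoxyhemoglobin"], grid, simulate_bandwidth=simulate_bandwidth
            )
    oxy = np.asarray(oxy, dtype=float)
    deoxy = np.asarray(deoxy, dtype=float)
    if oxy.shape != (len(grid),) or deoxy.shape != (len(grid),):
        raise SpectraError("oxy/deoxy must be resampled on the grid")

    cols: list[np.ndarray] = [oxy, deoxy, np.ones(len(grid))]
    names = ["oxyhemoglobin", "deoxyhemoglobin", "offset"]
    if include_slope:
        span = grid.centers[-1] - grid.centers[0]
        span = span if span > 0 else 1.0
        cols.append((grid.centers - grid.centers.mean()) / span)
        names.append("slope")

    matrix = np.column_stack(cols)
    if len(grid) < matrix.shape[1]:
        raise UnderdeterminedError(
            f"{len(grid)} bands cannot identify {matrix.shape[1]} regressors"
        )
    cond = np.linalg.cond(matrix)
    if not np.isfinite(cond) or cond > condition_cap:
        raise CollinearityError(
            f"design condition number {cond:.3g} exceeds cap {condition_cap:.3g} "
            "(oxy/deoxy columns collinear?)"
        )
    return DesignMatrix(grid, tuple(names), matrix)
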