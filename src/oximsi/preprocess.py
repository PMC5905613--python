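"""Raw-stack calibration and inter-band motion correction.

Raw counts are converted to reflectance against the dark and white (spectralon)
reference frames, then the bands — each exposed at a different time during the
multi-second acquisition and therefore displaced by breathing/peristalsis — are
rigidly aligned to a reference band by normalized cross-correlation with
quadratic subpixel refinement.

Coordinate convention: arrays are (row, col) with the origin at top-left and
0-based indices; a shift is ``(dy, dx)`` in pixels, the displacement of a
band's content relative to the reference band.  Aligning applies the negated
estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .spectra import WavelengthGrid

__all__ = [
    "PreprocessError",
    "DegenerateReferenceError",
    "ReflectanceCube",
    "to_reflectance",
    "attenuation",
    "register_bands",
]

logger = logging.getLogger("oximsi")

#: Dead zone (pixels): estimated shifts smaller than this are treated as zero.
#: Set at the estimator's noise floor (subpixel estimates below a quarter
#: pixel are dominated by interpolation/noise error at realistic SNR), which
#: also makes registration idempotent: re-registering an aligned cube applies
#: no resampling at all.
SHIFT_SNAP_PX = 0.25

#: Subpixel refinement offsets smaller than this are snapped back to the
#: integer correlation peak, so exact integer displacements are recovered
#: exactly instead of picking up interpolation jitter.
REFINE_SNAP_PX = 0.05


class PreprocessError(ValueError):
    """Invalid calibration or registration input."""


class DegenerateReferenceError(PreprocessError):
    """White and dark reference frames do not separate."""


@dataclass(frozen=True)
class ReflectanceCube:
    """Calibrated reflectance stack: one 2-D image per wavelength band.

    ``valid`` marks pixels whose reference separation ``white − dark`` was
    large enough for the flat-field division to be meaningful in every band.
    ``shifts_applied`` records the per-band (dy, dx) corrections applied by
    :func:`register_bands` (None before registration).
    """

    grid: WavelengthGrid
    bands: np.ndarray                       # (n_bands, H, W)
    valid: np.ndarray                       # (H, W) bool
    registered: bool = False
    shifts_applied: np.ndarray | None = None
    clip_max: float = 1.5
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        b = np.asarray(self.bands, dtype=float)
        if b.ndim != 3 or b.shape[0] != len(self.grid):
            raise PreprocessError(
                "bands must be a (n_bands, H, W) stack matching the grid"
            )
        if self.valid.shape != b.shape[1:]:
            raise PreprocessError("valid mask must match the band shape")
        if self.clip_max < 1.0:
            raise PreprocessError("clip_max must be at least 1")
        object.__setattr__(self, "bands", b)

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[1:]


def to_reflectance(
    raw_stack: np.ndarray,
    white_frame: np.ndarray,
    dark_frame: np.ndarray,
    grid: WavelengthGrid,
    *,
    clip_max: float = 1.5,
    min_separation: float = 1e-6,
    min_valid_fraction: float = 0.01,
) -> ReflectanceCube:
    """Flat-field calibration: ``R = (raw − dark) / (white − dark)`` per band.

    Pixels where the reference separation ``white − dark`` is at most
    ``min_separation`` in any band are flagged invalid.  Reflectance may
    legitimately exceed 1 on specular pixels, so values are clipped to
    ``[0, clip_max]`` (default 1.5) rather than to 1.

    Raises
    ------
    DegenerateReferenceError
        If fewer than ``min_valid_fraction`` of pixels separate — e.g. a white
        frame equal to the dark frame.
    """
    raw = np.asarray(raw_stack, dtype=float)
    white = np.asarray(white_frame, dtype=float)
    dark = np.asarray(dark_frame, dtype=float)
    if raw.ndim != 3 or raw.shape[0] != len(grid):
        raise PreprocessError("raw stack must be (n_bands, H, W) matching the grid")
    if white.shape != raw.shape or dark.shape != raw.shape:
        raise PreprocessError("white/dark frames must match the raw stack shape")

    sep = white - dark
    valid = np.all(sep > min_separation, axis=0)
    if valid.mean() < min_valid_fraction:
        raise DegenerateReferenceError(
            "white and dark references coincide on "
            f"{100 * (1 - valid.mean()):.1f}% of pixels"
        )
    refl = np.zeros_like(raw)
    ok = sep > min_separation
    refl[ok] = (raw[ok] - dark[ok]) / sep[ok]
    refl = np.clip(refl, 0.0, clip_max)
    return ReflectanceCube(
        grid,
        refl,
        valid,
        clip_max=clip_max,
        provenance={"calibration": "flat-field (raw-dark)/(white-dark)"},
    )


def attenuation(cube: ReflectanceCube, floor: float = 1e-4) -> np.ndarray:
    """Beer–Lambert attenuation stack ``A = −log10(max(R, floor))``.

    The floor keeps dark/invalid pixels finite; validity is carried separately
    by ``cube.valid``.
    """
    if not floor > 0:
        raise PreprocessError("floor must be positive")
    return -np.log10(np.maximum(cube.bands, floor))


def _ncc_surface(ref: np.ndarray, band: np.ndarray, max_shift: int) -> np.ndarray:
    """Normalized cross-correlation over integer shifts within ±max_shift.

    Correlates the central crop of ``ref`` against equally sized crops of
    ``band`` displaced by every candidate (dy, dx), so no wrap-around or
    padding artifacts enter the comparison.
    """
    m = max_shift
    h, w = ref.shape
    t = ref[m : h - m, m : w - m]
    t = t - t.mean()
    t_norm = np.sqrt((t**2).sum())
    surface = np.full((2 * m + 1, 2 * m + 1), -np.inf)
    for iy, dy in enumerate(range(-m, m + 1)):
        for ix, dx in enumerate(range(-m, m + 1)):
            c = band[m + dy : h - m + dy, m + dx : w - m + dx]
            c = c - c.mean()
            denom = t_norm * np.sqrt((c**2).sum())
            surface[iy, ix] = (t * c).sum() / denom if denom > 0 else 0.0
    return surface


def _quadratic_peak(c_m1: float, c_0: float, c_p1: float) -> float:
    """Vertex offset of the parabola through three equally spaced samples."""
    denom = c_m1 - 2.0 * c_0 + c_p1
    if denom >= 0:  # not a maximum; keep the integer peak
        return 0.0
    offset = 0.5 * (c_m1 - c_p1) / denom
    offset = float(np.clip(offset, -0.5, 0.5))
    return 0.0 if abs(offset) < REFINE_SNAP_PX else offset


def register_bands(
    cube: ReflectanceCube,
    reference_band: int | None = None,
    max_shift: int = 5,
) -> tuple[ReflectanceCube, np.ndarray, list[dict]]:
    """Align all bands to a reference band (star topology).

    Each band's rigid translation relative to the reference is estimated by
    maximizing normalized cross-correlation over integer shifts within
    ``±max_shift`` and refining to subpixel precision by quadratic
    interpolation of the correlation peak; the band is then resampled with
    linear interpolation.  The reference defaults to the middle band (560 nm
    on the default grid), avoiding the drift a chained pairwise scheme would
    accumulate.

    Estimates with magnitude below :data:`SHIFT_SNAP_PX` are snapped to zero,
    so registering an already-registered cube leaves it untouched.

    Returns
    -------
    (aligned_cube, estimated_shifts, report)
        ``estimated_shifts[b]`` is the (dy, dx) displacement of band ``b``
        relative to the reference; ``report`` carries the correlation peak and
        a failure flag per band (a featureless, zero-variance band is passed
        through unshifted and flagged).
    """
    n_bands = cube.bands.shape[0]
    if reference_band is None:
        reference_band = n_bands // 2
    if not 0 <= reference_band < n_bands:
        raise PreprocessError(f"reference band {reference_band} out of range")
    if max_shift < 0:
        raise PreprocessError("max_shift must be non-negative")
    m = int(max_shift)
    h, w = cube.shape
    if m > 0 and (h <= 4 * m or w <= 4 * m):
        raise PreprocessError("max_shift too large for the image size")

    ref = cube.bands[reference_band]
    if ref.std() == 0:
        raise PreprocessError("reference band is featureless (zero variance)")

    aligned = np.empty_like(cube.bands)
    shifts = np.zeros((n_bands, 2))
    report: list[dict] = []
    for b in range(n_bands):
        band = cube.bands[b]
        entry = {"band": b, "shift": (0.0, 0.0), "peak_ncc": 1.0, "failed": False}
        if b == reference_band:
            aligned[b] = band
            report.append(entry)
            continue
        if band.std() == 0 or m == 0:
            aligned[b] = band
            entry["failed"] = band.std() == 0
            entry["peak_ncc"] = float("nan") if entry["failed"] else 1.0
            report.append(entry)
            continue
        surf = _ncc_surface(ref, band, m)
        iy, ix = np.unravel_index(np.argmax(surf), surf.shape)
        dy, dx = float(iy - m), float(ix - m)
        if 0 < iy < 2 * m:
            dy += _quadratic_peak(surf[iy - 1, ix], surf[iy, ix], surf[iy + 1, ix])
        if 0 < ix < 2 * m:
            dx += _quadratic_peak(surf[iy, ix - 1], surf[iy, ix], surf[iy, ix + 1])
        if abs(dy) < SHIFT_SNAP_PX:
            dy = 0.0
        if abs(dx) < SHIFT_SNAP_PX:
            dx = 0.0
        shifts[b] = (dy, dx)
        entry["shift"] = (dy, dx)
        entry["peak_ncc"] = float(surf[iy, ix])
        if dy == 0.0 and dx == 0.0:
            aligned[b] = band
        else:
            aligned[b] = ndimage.shift(band, (-dy, -dx), order=1, mode="nearest")
        report.append(entry)

    logger.info(
        "registered %d bands to band %d; max |shift| %.2f px",
        n_bands,
        reference_band,
        float(np.abs(shifts).max()),
    )
    out = replace(
        cube,
        bands=aligned,
        registered=True,
        shifts_applied=shifts,
        provenance={**cube.provenance, "registration": "ncc-star"},
    )
    return out, shifts, report
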