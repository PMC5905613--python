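"""Per-pixel spectral unmixing into oxy/deoxy-hemoglobin and scattering terms.

Each pixel's attenuation spectrum ``A(λ) = −log10 R(λ)`` is decomposed by
linear least squares onto the design built in :mod:`oximsi.spectra`:
oxy-hemoglobin extinction, deoxy-hemoglobin extinction, a constant offset
absorbing wavelength-flat scattering, and an optional linear slope.  Working
in attenuation rather than raw reflectance linearizes the Beer–Lambert model,
so the regression is exact under the forward model.  Oxygen saturation is the
oxyhemoglobin share of total hemoglobin, ``sat = c_oxy / (c_oxy + c_deoxy)``.

By default the two chromophore coefficients are constrained non-negative
(physical concentrations); the unconstrained ordinary-least-squares mode is
kept for oracle comparisons, and pixels it drives outside [0, 1] are masked
and counted rather than clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import ReflectanceCube, attenuation
from .spectra import DesignMatrix

__all__ = [
    "UnmixingError",
    "PixelFit",
    "OxygenationMap",
    "fit_pixel",
    "saturation_map",
    "roi_summary",
    "reconstruct_rgb",
    "render_sat_image",
    "default_rgb_response",
]

logger = logging.getLogger("oximsi")

#: Neutral grey used for masked pixels in saturation renders.
MASK_GREY = (0.5, 0.5, 0.5)


class UnmixingError(ValueError):
    """Invalid unmixing input."""


@dataclass(frozen=True)
class PixelFit:
    """Least-squares decomposition of one attenuation spectrum."""

    c_oxy: float
    c_deoxy: float
    offset: float
    slope: float | None
    residual_rms: float
    valid: bool


@dataclass(frozen=True)
class OxygenationMap:
    """Per-pixel O₂Sat fraction, total hemoglobin and fit diagnostics.

    ``sat`` is defined (in [0, 1]) only where ``mask`` is True; masked pixels
    hold NaN.  ``n_out_of_range`` counts unconstrained-fit pixels whose raw
    saturation fell outside [0, 1] and were therefore masked.
    """

    sat: np.ndarray
    thb: np.ndarray
    residual: np.ndarray
    mask: np.ndarray
    thb_floor: float
    n_out_of_range: int = 0

    def __post_init__(self) -> None:
        s = self.sat[self.mask]
        if s.size and (np.any(s < 0) or np.any(s > 1) or np.any(~np.isfinite(s))):
            raise UnmixingError("saturation outside [0, 1] on unmasked pixels")


def _solve_subset(a: np.ndarray, x: np.ndarray, keep: list[int]) -> np.ndarray:
    """Least squares on a column subset, zeros elsewhere. a: (N, B), x: (B, K)."""
    coef = np.zeros((a.shape[0], x.shape[1]))
    sub = np.linalg.lstsq(x[:, keep], a.T, rcond=None)[0].T
    coef[:, keep] = sub
    return coef


def _fit_many(a: np.ndarray, design: DesignMatrix, nonneg: bool) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-pixel fits.

    For the non-negative mode the two chromophore coefficients are the only
    constrained variables, so the exact NNLS solution is found by enumerating
    the four active sets (both free, oxy clamped, deoxy clamped, both clamped)
    and taking the feasible candidate with the smallest residual — the
    standard KKT enumeration for a two-bound quadratic program.

    Returns ``(coefs (N, K), residual_rms (N,))``.
    """
    x = design.matrix
    n, k = a.shape[0], x.shape[1]
    free = list(range(k))
    cand_sets = [free]
    if nonneg:
        cand_sets += [
            [i for i in free if i != 0],
            [i for i in free if i != 1],
            [i for i in free if i not in (0, 1)],
        ]
    best_coef = np.zeros((n, k))
    best_rss = np.full(n, np.inf)
    for keep in cand_sets:
        coef = _solve_subset(a, x, keep)
        rss = ((a - coef @ x.T) ** 2).sum(axis=1)
        feasible = (
            (coef[:, 0] >= -1e-12) & (coef[:, 1] >= -1e-12)
            if nonneg
            else np.ones(n, dtype=bool)
        )
        better = feasible & (rss < best_rss - 1e-15)
        best_coef[better] = coef[better]
        best_rss[better] = rss[better]
    if nonneg:
        best_coef[:, :2] = np.maximum(best_coef[:, :2], 0.0)
    return best_coef, np.sqrt(best_rss / x.shape[0])


def fit_pixel(a: np.ndarray, design: DesignMatrix, nonneg: bool = True) -> PixelFit:
    """Fit one attenuation spectrum against the design.

    Ordinary least squares when ``nonneg`` is off; otherwise the chromophore
    coefficients are constrained non-negative while offset (and slope) remain
    free.  A non-finite input vector yields an invalid fit rather than an
    exception.
    """
    a = np.asarray(a, dtype=float)
    if a.shape != (design.matrix.shape[0],):
        raise UnmixingError(
            f"spectrum length {a.shape} does not match design rows "
            f"{design.matrix.shape[0]}"
        )
    if not np.all(np.isfinite(a)):
        return PixelFit(np.nan, np.nan, np.nan, None, np.nan, valid=False)
    coefs, rms = _fit_many(a[None, :], design, nonneg)
    c = coefs[0]
    slope = float(c[design.columns.index("slope")]) if "slope" in design.columns else None
    return PixelFit(
        c_oxy=float(c[0]),
        c_deoxy=float(c[1]),
        offset=float(c[design.columns.index("offset")]),
        slope=slope,
        residual_rms=float(rms[0]),
        valid=True,
    )


def saturation_map(
    cube: ReflectanceCube,
    design: DesignMatrix,
    *,
    thb_floor: float | None = None,
    nonneg: bool = True,
    attenuation_floor: float = 1e-4,
) -> OxygenationMap:
    """Unmix a reflectance cube into O₂Sat and total-hemoglobin maps.

    ``thb_floor`` masks pixels whose fitted total hemoglobin is too small for
    the saturation ratio to be meaningful (avoids 0/0 on bloodless pixels);
    the default is 5% of the median fitted THb over valid pixels.  With the
    unconstrained fit, pixels whose saturation falls outside [0, 1] are masked
    and counted in ``n_out_of_range``.
    """
    if (
        not cube.registered
        and cube.shifts_applied is not None
        and np.any(cube.shifts_applied)
    ):
        logger.warning(
            "unmixing an unregistered cube with recorded nonzero band shifts; "
            "saturation maps will smear across the motion"
        )
    att = attenuation(cube, floor=attenuation_floor)
    n_bands, h, w = att.shape
    pixels = att.reshape(n_bands, -1).T
    finite = np.all(np.isfinite(pixels), axis=1)
    coefs = np.zeros((pixels.shape[0], design.matrix.shape[1]))
    rms = np.full(pixels.shape[0], np.nan)
    if finite.any():
        coefs[finite], rms[finite] = _fit_many(pixels[finite], design, nonneg)

    c_oxy, c_deoxy = coefs[:, 0], coefs[:, 1]
    thb = c_oxy + c_deoxy
    if thb_floor is None:
        # tissue-median THb: ignore numerically bloodless pixels so a large
        # zero-THb background cannot drag the floor to zero
        top = float(thb.max()) if thb.size else 0.0
        ref = thb[finite & (thb > 1e-9 * max(top, 1e-300))]
        thb_floor = 0.05 * float(np.median(ref)) if ref.size else 0.0
    defined = finite & (thb >= thb_floor) & (thb > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(defined, c_oxy / np.where(thb > 0, thb, 1.0), np.nan)

    out_of_range = defined & ((sat < 0) | (sat > 1))
    n_oor = int(out_of_range.sum())
    mask = defined & ~out_of_range & cube.valid.reshape(-1)
    sat = np.where(mask, sat, np.nan)

    masked_fraction = 1.0 - mask.mean()
    logger.info(
        "saturation map: %.1f%% of pixels masked (thb_floor=%.3g, "
        "%d out-of-range sat)",
        100 * masked_fraction,
        thb_floor,
        n_oor,
    )
    return OxygenationMap(
        sat=sat.reshape(h, w),
        thb=np.maximum(thb, 0.0).reshape(h, w),
        residual=rms.reshape(h, w),
        mask=mask.reshape(h, w),
        thb_floor=float(thb_floor),
        n_out_of_range=n_oor,
    )


def roi_summary(
    omap: OxygenationMap,
    rois: dict[str, np.ndarray],
    select: list[str] | None = None,
    erode_px: int = 0,
):
    """Mean saturation, mean THb and pixel count per region of interest.

    ``rois`` maps labels to boolean masks; means are taken over the
    intersection of each ROI with the validity mask.  ``erode_px`` shrinks
    each ROI by that many pixels first — the usual partial-volume exclusion
    of boundary pixels, where optical blur and residual inter-band motion mix
    neighbouring tissues.  An empty intersection yields a row with
    ``defined=False`` and NaN means rather than an error.  Unknown labels in
    ``select`` raise, listing what is available.
    """
    import pandas as pd
    from scipy import ndimage

    names = list(rois) if select is None else list(select)
    unknown = [n for n in names if n not in rois]
    if unknown:
        raise KeyError(
            f"unknown ROI label(s) {unknown}; available: {sorted(rois)}"
        )
    rows = []
    for name in names:
        roi = np.asarray(rois[name], dtype=bool)
        if roi.shape != omap.sat.shape:
            raise UnmixingError(f"ROI {name!r} shape does not match the map")
        if erode_px > 0:
            roi = ndimage.binary_erosion(roi, iterations=erode_px)
        sel = roi & omap.mask
        n = int(sel.sum())
        rows.append(
            {
                "roi": name,
                "mean_sat": float(omap.sat[sel].mean()) if n else np.nan,
                "mean_thb": float(omap.thb[sel].mean()) if n else np.nan,
                "n_pixels": n,
                "defined": n > 0,
            }
        )
    return pd.DataFrame(rows)


def default_rgb_response(grid) -> np.ndarray:
    """Stand-in RGB camera response on the grid: Gaussians at 610/540/460 nm,
    σ = 30 nm, ordered (R, G, B)."""
    centers = np.asarray([610.0, 540.0, 460.0])
    return np.exp(
        -0.5 * ((grid.centers[None, :] - centers[:, None]) / 30.0) ** 2
    )


def reconstruct_rgb(
    cube: ReflectanceCube, rgb_response: np.ndarray | None = None
) -> np.ndarray:
    """Integrate the cube under an RGB filter response into a color image.

    Each channel is the response-weighted average of the reflectance bands,
    normalized so a spectrally flat ``R = 1`` pixel maps to (1, 1, 1).
    """
    if rgb_response is None:
        rgb_response = default_rgb_response(cube.grid)
    w = np.asarray(rgb_response, dtype=float)
    if w.shape != (3, cube.bands.shape[0]):
        raise UnmixingError("rgb_response must have shape (3, n_bands)")
    sums = w.sum(axis=1)
    if np.any(sums <= 1e-12):
        raise UnmixingError("an RGB response channel is zero over the grid")
    img = np.tensordot(w / sums[:, None], cube.bands, axes=(1, 0))
    return np.clip(np.moveaxis(img, 0, -1), 0.0, 1.0)


def render_sat_image(omap: OxygenationMap) -> np.ndarray:
    """Color-map the saturation to the blue→red display scale.

    Saturation 0 maps to the dark-blue end and 1 to the bright-red end of a
    jet-style scale; masked pixels render neutral grey.  Returns an
    (H, W, 3) float image in [0, 1].
    """
    from matplotlib import colormaps

    cmap = colormaps["jet"]
    filled = np.where(omap.mask, omap.sat, 0.0)
    rgb = np.asarray(cmap(np.clip(filled, 0.0, 1.0)))[..., :3]
    rgb[~omap.mask] = MASK_GREY
    return rgb
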