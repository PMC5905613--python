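# Methods

This note documents the models implemented in `oximsi`, the parameter
choices that matter, what the synthetic phantom does and does not emulate,
and the numerical conventions.

## Spectral model

Per-pixel reflectance is modelled through the modified Beer–Lambert law: the
attenuation `A(λ) = −log₁₀ R(λ)` is linear in chromophore concentrations,

```
A(λ) = ε_HbO₂(λ)·c_HbO₂ + ε_Hb(λ)·c_Hb + s [+ m·(λ−λ̄)/span]
```

with a constant offset `s` absorbing wavelength-flat scattering attenuation
and an optional centered linear slope `m` for a wavelength-dependent
scattering trend (off by default; both forward and inverse models use the
same design, so the choice is self-consistent).  The regression is performed
in attenuation, not raw reflectance: the log transform makes the model exact
under the forward simulation and is the conventional domain for this
decomposition.

All concentrations are in relative units (unitless pathlength).  Only the
saturation ratio `c_HbO₂/(c_HbO₂+c_Hb)` and relative total hemoglobin are
reported, so an absolute molar scale would add nothing.

### Extinction table

The packaged table (`hemoglobin_extinction_synthetic.csv`) is a synthetic
analytic compilation, constructed as sums of Gaussian absorption bands,
a Soret-edge exponential and smooth near-infrared terms, sampled at 2 nm
from 450 to 1000 nm.  It reproduces the qualitative band structure of adult
hemoglobin that both analyses depend on — oxyhemoglobin α/β bands near
577/542 nm, the single broad deoxyhemoglobin band near 555 nm, four
isosbestic crossings within the 500–620 nm acquisition window, a several-fold
deoxy-over-oxy contrast at 660 nm, and an NIR crossover leaving oxyhemoglobin
dominant at 940 nm — but its magnitudes are arbitrary relative units, not
measured molar coefficients.  Every quantitative claim in the tests is made
against this table's own forward model, never against literature extinction
values.

### Wavelength grid and band integration

The default acquisition grid is 500–620 nm in 10 nm steps (13 bands) with a
15 nm FWHM passband, within the 400–720 nm tuneable range.  Resampling a
spectrum onto the grid is linear interpolation at band centers by default; a
boxcar passband mean of the FWHM width (or a Gaussian passband, truncated at
±2σ) is available behind a flag.  On a locally linear spectrum the boxcar
mean equals the center value, so band integration matters only where the
spectrum is strongly curved.

### Design matrix

Columns are `[ε_HbO₂, ε_Hb, 1, optional slope]`, resampled from the packaged
table.  The 13-band default design has condition number ≈ 68 (frozen as a
regression value); building a design with fewer bands than regressors or
with collinear chromophore columns raises immediately.

## Synthetic phantom

`make_phantom` builds a two-cornua scene: two vertical ellipses (left/right),
each split into medial/lateral halves at its own axis, on a background
standing in for connective tissue.  Layout presets encode the study's two
conditions: cornua mean saturation 0.90 pre-transplant and 0.55 immediately
post-reperfusion, on a 0.30-saturation background.  Texture is a smooth
Gaussian-filtered random field (σ = 4 px; saturation sd 0.02, hemoglobin
relative sd 0.10), recentred to zero mean within each region so region means
equal the layout targets exactly.  Total hemoglobin defaults (cornua 0.04,
background 0.01, relative units) are chosen so that peak attenuation over
the grid stays near 2.5 — reflectance well above the log floor, as in
tissue; the scattering offset default is 0.1 attenuation units.  Scattering
magnitude in tissue is not well constrained here; these are documented free
parameters, not claimed measurements.

`render_cube` applies the forward model, translates each band by an
independent random rigid shift (breathing/peristalsis over a multi-second
acquisition is approximately rigid at this field size; rotations and
deformations are out of scope), multiplies by a smooth lamp spectrum times a
photon-count scale, and adds signal-proportional Gaussian shot noise (a
Poisson flag exists; the Gaussian proxy keeps the noise model invertible in
tests) plus read noise and a dark offset.  The white frame is the dark level
plus the illumination — a spectralon-style flat reference.  True shifts are
returned as registration ground truth.  With no noise and non-negative
offsets, rendered reflectance lies in (0, 1].

The phantom does **not** simulate radiative transfer, specular highlights,
3-D geometry, chromophores beyond hemoglobin, or spatially varying
illumination.  Passing recovery tests therefore demonstrates the correctness
of the processing chain under its own forward model, not clinical accuracy
on real tissue.

## Preprocessing

Flat-field calibration is `R = (raw − dark)/(white − dark)` per band; pixels
whose reference separation is non-positive are flagged invalid, and a white
frame equal to the dark frame raises a degenerate-reference error.
Reflectance may legitimately exceed 1 on specular pixels, so values are
clipped to `[0, 1.5]` with the clip recorded, not silently forced to 1.
Attenuation uses a reflectance floor of 1e-4 (so A ≤ 4).

Registration is translation-only, band-to-reference (star topology, middle
band ≈ 560 nm by default, avoiding chained-pairwise drift): normalized
cross-correlation over integer shifts within ±max_shift (computed on central
crops so no padding enters the comparison), refined to subpixel by quadratic
interpolation of the correlation peak, then resampled with linear
interpolation.  Conventions: (row, col) arrays, 0-based, origin top-left;
a shift is the (dy, dx) displacement of a band's content relative to the
reference.  Two dead zones keep the estimator honest about its own
precision: refinement offsets below 0.05 px snap back to the integer peak
(exact integer displacements are recovered exactly), and estimates below
0.25 px — the estimator's noise floor at realistic SNR — are not applied at
all, which also makes registration idempotent.  A zero-variance band is
flagged as failed and passed through unshifted.

## Unmixing

Each pixel's attenuation spectrum is fitted by least squares.  The
non-negative mode (default: concentrations are physical) constrains only the
two chromophore coefficients, leaving offset and slope free; because only
two variables are bounded, the exact solution is found by enumerating the
four active sets and keeping the feasible candidate with minimum residual,
vectorized over all pixels (verified against SciPy's NNLS).  The
unconstrained mode exists for oracle comparisons; pixels it drives outside
[0, 1] are masked and counted, never clipped.

Saturation is undefined on bloodless pixels; the `thb_floor` mask (default
5% of the median fitted THb over pixels with non-negligible THb) removes
them before the ratio is formed.  The masked fraction is logged.

ROI summaries average saturation and THb over each labelled region
intersected with the validity mask.  `erode_px` shrinks regions before
averaging — the standard partial-volume exclusion.  Fractional inter-band
motion blurs band content by bilinear interpolation, and registration cannot
restore what interpolation discarded, so a 1–2 px boundary ring mixes
background into the cornua; eroding by 2 px removes this ring and leaves the
interior estimate unbiased.  Phantom recovery checks and the acceptance
script therefore evaluate ROI means with 2 px erosion (applied identically
to truth and recovered maps).

RGB reconstruction integrates the cube under three Gaussian response curves
(610/540/460 nm, σ = 30 nm) — a documented stand-in for an unspecified
color camera — normalized so a flat unit-reflectance pixel maps to white.
Saturation maps render on a jet-style blue (0) → red (1) scale with masked
pixels in neutral grey.

## Pulse oximetry

The PPG forward model transmits
`I(t) = I₀·10^(−[A_static + A_pulse·(1+sin 2πft)/2])` per LED wavelength
(660/940 nm defaults), where `A_static` mixes a tissue term (1.0) with
venous blood (concentration 0.5 at saturation 0.70) and
`A_pulse = pulsatile_fraction · ε(arterial_sat)`.  The default pulsatile
fraction 0.002 puts AC/DC near 0.5% — the perfusion-index magnitude the
probe reports on uterine tissue.  The waveform is sinusoidal on purpose:
AC/DC extraction is morphology-insensitive, so dicrotic-notch realism would
not change anything measured.

Analysis: DC is the trace mean; the signal is band-passed to the cardiac
band (0.5–5 Hz, zero-phase Butterworth), peaks are detected, and AC is the
mean cycle-wise peak-to-trough amplitude (robust to mild non-stationarity,
unlike a single FFT amplitude).  Fewer than three beats or grossly irregular
beat spacing raises a no-pulse error, mirroring a probe losing the signal.
PI is reported in percent, on the infrared channel by convention.

Commercial SpO₂ calibrations are proprietary and fitted on human
volunteers; none is available here.  `spo2_from_ratio` therefore ships the
stand-in line `SpO₂ = clamp(110 − 25·R, 0, 100)`, and `calibrate_spo2` fits
the two parameters against the package's own forward model by simulating two
anchor saturations (defaults 0.75 and 1.00) and passing the line through
them.  Because the true saturation→ratio map is a Möbius function, the
linear fit is approximate between anchors; across 0.80–0.97 the residual is
well under 3 SpO₂ points.  Absolute agreement with the study's printed probe
values is not claimed — only the table statistics are reproduced.

## Statistics

Site summaries use the arithmetic mean and the n−1 sample SD of non-missing
values.  Rounding follows the printed tables: half-up to integer percent for
O₂Sat means, two decimals for perfusion index; O₂Sat SDs are printed as a
fraction of 1 (e.g. "98 ± 0.02"), exposed as an explicit `sd_convention`
flag rather than a silent unit mix.  Values are snapped to nine decimals
before quantization so statistics that are exact halves in real arithmetic
round upward as intended.

The Mann–Whitney U test computes U from mid-ranks; the p-value is exact (full
enumeration of all `C(n1+n2, n1)` labelings) when the pooled sample is ≤ 12
with no ties, otherwise a normal approximation with tie and continuity
corrections.  Two-sided testing is assumed (the study does not state
sidedness), with significance at p < 0.05.  Pre/post comparisons pool all
four cornua sites per phase — the study reports one comparison per phase
pair, not per-site p-values — and drop missing values.

Two documented data quirks: the day-89 pre-embryo-transfer re-measurement of
the surviving recipient is included in the multispectral rabbit table's
post-transplant summary cells (the printed means demonstrably include it)
but excluded from hypothesis tests by default; and fourteen donor/
recipient-pre summary cells of that same table are internally inconsistent
with their own printed row values.  These are recorded in a packaged
exclusion file with both the printed and recomputed values; the reproduction
report asserts every other cell (60 cells total, all of the pulse-oximetry
and sheep tables reproduce exactly) and flags the exclusions as known
discrepancies rather than correcting them.

## Problem sizes and determinism

Every generator is a pure function of its parameters and a seed.  Recovery
checks run on 64×64 scenes in unit tests and a 128×128×13 cube in the
acceptance script; the 30 dB signal-to-noise condition is established by
setting the photon scale so the median band signal is 10³ counts (shot-noise
amplitude SNR of ~31.6), and inter-band motion uses shift sd 1.5 px within a
±6 px search window.  At these sizes the full test suite and the acceptance
script each complete in seconds.

## Known limitations

- The extinction table is synthetic; absolute spectra, and therefore any
  absolute concentration scale, are out of scope.
- Registration is rigid translation only; deformable motion (peristalsis
  proper) is not modelled or corrected.
- The SpO₂ calibration is self-referential to the forward model; no claim is
  made about agreement with a physical probe.
- Sub-0.25 px motion is deliberately left uncorrected (estimator dead zone).
- The Gaussian shot-noise proxy underestimates the skewness of true photon
  noise at very low counts.
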