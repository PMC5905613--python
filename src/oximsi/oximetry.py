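"""Two-wavelength pulse-oximetry analysis: AC/DC extraction, perfusion index,
ratio-of-ratios and SpO₂.

The transmitted-light photoplethysmogram (PPG) at each LED wavelength is split
into a non-pulsatile baseline (DC, venous/capillary blood and static tissue)
and a pulsatile component (AC, arterial inflow).  The perfusion index
PI = 100·AC/DC is a relative blood-volume indicator; the ratio-of-ratios
R = (AC/DC)_red / (AC/DC)_ir is mapped to an arterial saturation percentage
through an empirical linear calibration.  Commercial probes are calibrated on
human volunteers; that curve is unavailable, so the default line
SpO₂ = 110 − 25·R is a documented stand-in and :func:`calibrate_spo2` can fit
the two parameters against the package's own forward model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "NoPulseError",
    "PPGTrace",
    "OximetryReading",
    "extract_ac_dc",
    "perfusion_index",
    "ratio_of_ratios",
    "spo2_from_ratio",
    "calibrate_spo2",
    "analyze",
    "DEFAULT_CALIBRATION",
]

#: Default linear ratio-to-SpO₂ calibration (intercept, slope): 110 − 25·R.
DEFAULT_CALIBRATION = (110.0, 25.0)

#: Cardiac band for pulse detection, Hz.
CARDIAC_BAND_HZ = (0.5, 5.0)


class NoPulseError(RuntimeError):
    """No periodic pulsatile component detected in the trace."""


@dataclass(frozen=True)
class PPGTrace:
    """Uniformly sampled transmitted-intensity time series at one wavelength."""

    time: np.ndarray
    intensity: np.ndarray
    wavelength: float
    sample_rate: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if t.shape != y.shape or t.ndim != 1 or t.size < 4:
            raise ValueError("trace needs matching 1-D time/intensity arrays")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("trace must be uniformly sampled")
        if np.any(y <= 0):
            raise ValueError("transmitted intensity must be positive")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "intensity", y)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass(frozen=True)
class OximetryReading:
    """One probe reading: SpO₂ (%), perfusion index (%), R, pulse rate (bpm)."""

    spo2: float
    pi: float
    ratio: float
    pulse_rate: float


def _bandpass(y: np.ndarray, fs: float, band=CARDIAC_BAND_HZ) -> np.ndarray:
    nyq = fs / 2.0
    hi = min(band[1], 0.95 * nyq)
    sos = signal.butter(2, [band[0] / nyq, hi / nyq], btype="band", output="sos")
    return signal.sosfiltfilt(sos, y)


def extract_ac_dc(trace: PPGTrace) -> tuple[float, float, float]:
    """Split a PPG trace into pulsatile and baseline parts.

    Returns ``(ac, dc, pulse_rate_bpm)`` where ``dc`` is the trace mean and
    ``ac`` the mean cycle-wise peak-to-trough amplitude of the band-passed
    (0.5–5 Hz) signal.  Cycle-wise extraction is used instead of a spectral
    amplitude because it is insensitive to mild waveform non-stationarity.

    Raises
    ------
    NoPulseError
        If no stable periodic component is found (fewer than three beats, or
        grossly irregular beat spacing) — the analogue of a probe losing the
        pulsatile signal.
    """
    y = trace.intensity
    dc = float(y.mean())
    if y.std() == 0:
        raise NoPulseError("trace is constant: no pulsatile component")
    filt = _bandpass(y, trace.sample_rate)
    min_dist = max(1, int(trace.sample_rate / CARDIAC_BAND_HZ[1]))
    prom = 0.5 * filt.std()
    peaks, _ = signal.find_peaks(filt, distance=min_dist, prominence=prom)
    if len(peaks) < 3:
        raise NoPulseError("fewer than three pulse peaks detected")
    spacing = np.diff(peaks)
    if spacing.std() / spacing.mean() > 0.25:
        raise NoPulseError("pulse peak spacing too irregular to be cardiac")
    pulse_rate = 60.0 * trace.sample_rate / float(np.median(spacing))

    amps = [
        filt[a] - filt[a : b + 1].min() for a, b in zip(peaks[:-1], peaks[1:])
    ]
    ac = float(np.mean(amps))
    if ac <= 0:
        raise NoPulseError("non-positive pulsatile amplitude")
    return ac, dc, float(pulse_rate)


def perfusion_index(trace: PPGTrace) -> float:
    """Perfusion index in percent: ``100 · AC / DC``.

    Conventionally computed on the infrared channel.  Invariant to scaling the
    intensity by any positive constant.
    """
    ac, dc, _ = extract_ac_dc(trace)
    return 100.0 * ac / dc


def ratio_of_ratios(red: PPGTrace, ir: PPGTrace) -> float:
    """R = (AC/DC at the red wavelength) / (AC/DC at the infrared wavelength)."""
    if red.time.shape != ir.time.shape or not np.allclose(red.time, ir.time):
        raise ValueError("red and infrared traces must be time-aligned")
    ac_r, dc_r, _ = extract_ac_dc(red)
    ac_i, dc_i, _ = extract_ac_dc(ir)
    return (ac_r / dc_r) / (ac_i / dc_i)


def spo2_from_ratio(
    r: float, calibration: tuple[float, float] = DEFAULT_CALIBRATION
) -> float:
    """Map a ratio-of-ratios to SpO₂ percent via a linear calibration.

    ``SpO₂ = clamp(a − b·R, 0, 100)`` with ``(a, b) = calibration``; the
    default is the stand-in line (110, 25).
    """
    if not r > 0:
        raise ValueError("ratio-of-ratios must be positive")
    a, b = calibration
    return float(np.clip(a - b * r, 0.0, 100.0))


def calibrate_spo2(
    anchor_sats: tuple[float, float] = (0.75, 1.0),
    *,
    spec=None,
    table=None,
) -> tuple[float, float]:
    """Fit the linear ratio curve against the package's own PPG forward model.

    Simulates noiseless traces at two anchor arterial saturations, measures R
    for each, and solves for ``(a, b)`` such that ``a − b·R`` passes through
    both anchors (in percent).  ``spec`` is a template
    :class:`oximsi.phantom.PPGSpec` whose non-saturation parameters are kept.
    """
    from dataclasses import replace

    from .phantom import PPGSpec, render_ppg  # lazy: avoids import cycle

    if spec is None:
        spec = PPGSpec(noise_sd=0.0)
    rs = []
    for s in anchor_sats:
        red, ir = render_ppg(replace(spec, arterial_sat=s, noise_sd=0.0), table=table)
        rs.append(ratio_of_ratios(red, ir))
    (r1, r2), (s1, s2) = rs, anchor_sats
    if np.isclose(r1, r2):
        raise ValueError("anchor saturations give identical ratios")
    b = 100.0 * (s2 - s1) / (r1 - r2)
    a = 100.0 * s1 + b * r1
    return float(a), float(b)


def analyze(
    red: PPGTrace,
    ir: PPGTrace,
    calibration: tuple[float, float] = DEFAULT_CALIBRATION,
) -> OximetryReading:
    """Full probe reading from a red/infrared trace pair."""
    r = ratio_of_ratios(red, ir)
    pi = perfusion_index(ir)
    _, _, pulse_rate = extract_ac_dc(ir)
    return OximetryReading(
        spo2=spo2_from_ratio(r, calibration), pi=pi, ratio=r, pulse_rate=pulse_rate
    )
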