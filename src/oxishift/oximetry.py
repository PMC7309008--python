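"""SpO2 estimation models, PPG simulation and the linearization error.

A two-wavelength pulse oximeter measures a photoplethysmogram (PPG) at
a red and an infrared channel, forms per-cycle perfusion indices
AC/DC and takes their ratio of ratios

    R = (AC_red / DC_red) / (AC_ir / DC_ir).

Under the Beer-Lambert law (BLL) with effective extinction
coefficients eps at the two channels,

    SpO2 = 100 (eps_Hb(l1) - eps_Hb(l2) R)
           / (eps_Hb(l1) - eps_HbO2(l1) + (eps_HbO2(l2) - eps_Hb(l2)) R)

while deployed systems mostly use the linear approximation
``SpO2 = a R + b`` with the classic coefficients (a, b) = (-25, 110).
This module implements both, a forward PPG model to close the loop
(simulate -> segment -> R -> SpO2), and the relative deviation

    dSpO2 = (BLL - Approx) / BLL * 100 %

profiled over an R grid with special attention to the clinically
critical 90-100 % saturation window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .chromophores import ChannelExtinction, EffectiveCoefficients
from .errors import (
    DegenerateInputError,
    InputError,
    SingularityError,
)

__all__ = [
    "CalibrationLine",
    "DEFAULT_CALIBRATION",
    "PPGTrace",
    "ForwardModelParams",
    "ErrorProfile",
    "absorbance",
    "spo2_bll",
    "invert_spo2_bll",
    "spo2_linear",
    "fit_linear_calibration",
    "segment_cycles",
    "count_cycles",
    "ratio_of_ratios",
    "synth_ppg",
    "error_profile",
    "max_abs_error_in_window",
]

_SINGULARITY_TOL = 1e-12


@dataclass(frozen=True)
class CalibrationLine:
    """Linear SpO2 calibration ``SpO2 = a R + b`` (percent)."""

    a: float = -25.0
    b: float = 110.0


#: The classic textbook line SpO2 = 110 - 25 R.
DEFAULT_CALIBRATION = CalibrationLine(-25.0, 110.0)


@dataclass(frozen=True)
class PPGTrace:
    """A uniformly sampled photoplethysmogram.

    ``intensity`` is the detected light level in arbitrary detector
    units (non-negative); a large quasi-constant DC level with a small
    cardiac AC modulation on top.
    """

    time: np.ndarray
    intensity: np.ndarray
    sampling_rate: float
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        x = np.asarray(self.intensity, dtype=float)
        if t.shape != x.shape or t.ndim != 1 or t.size < 2:
            raise InputError("time and intensity must be equal-length 1-D "
                             "arrays with >= 2 samples")
        if np.any(x < 0):
            raise InputError("PPG intensity must be non-negative")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "intensity", x)

    def perfusion_index(self) -> float:
        """Global AC/DC (peak-to-peak over mean); 0 for a flat trace."""
        dc = float(self.intensity.mean())
        if dc <= 0:
            raise DegenerateInputError("PPG trace has non-positive mean")
        return float(np.ptp(self.intensity)) / dc


@dataclass(frozen=True)
class ForwardModelParams:
    """Parameters of the Beer-Lambert PPG forward model.

    ``sao2_true`` is the arterial saturation as a fraction;
    ``c_hb_total`` the total hemoglobin molarity (mol/L, ~2.3e-3 for
    150 g/L blood); ``d_static`` the baseline optical path in cm and
    ``delta_d_amp`` the pulsatile path amplitude in cm (the same at
    both wavelengths, the standard small-signal assumption).
    """

    sao2_true: float
    c_hb_total: float = 2.3e-3
    d_static: float = 1.0
    delta_d_amp: float = 0.01
    heart_rate_bpm: float = 60.0
    i0: float = 1.0
    waveform: str = "cosine"
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.sao2_true <= 1.0:
            raise InputError("sao2_true must lie in [0, 1]")
        if self.delta_d_amp < 0 or self.d_static <= 0:
            raise InputError("path lengths must be positive")


@dataclass(frozen=True)
class ErrorProfile:
    """BLL vs. linear SpO2 over an R grid, with the 90-100 % window."""

    r_grid: np.ndarray
    spo2_bll: np.ndarray
    spo2_linear: np.ndarray
    delta_spo2: np.ndarray
    window: np.ndarray = field(repr=False)
    window_range: tuple[float, float] = (90.0, 100.0)


# ---------------------------------------------------------------------------
# Beer-Lambert basics
# ---------------------------------------------------------------------------

def absorbance(i, i0):
    """Absorbance A = -ln(I/I0) of transmitted light."""
    i = np.asarray(i, dtype=float)
    i0 = np.asarray(i0, dtype=float)
    if np.any(i <= 0) or np.any(i0 <= 0):
        raise InputError("intensities must be strictly positive")
    out = -np.log(i / i0)
    return float(out) if out.ndim == 0 else out


def spo2_bll(eps: EffectiveCoefficients, r):
    """Beer-Lambert SpO2 (percent) from the ratio of ratios R.

    Uses the effective coefficients at the red (l1) and IR (l2)
    channels.  Raises :class:`SingularityError` when the denominator
    vanishes at a scalar R; array input returns NaN at singular points.
    """
    r = np.asarray(r, dtype=float)
    h1, o1 = eps.red.eps_hb, eps.red.eps_hbo2
    h2, o2 = eps.ir.eps_hb, eps.ir.eps_hbo2
    num = h1 - h2 * r
    den = (h1 - o1) + (o2 - h2) * r
    scale = abs(h1 - o1) + abs(o2 - h2) * np.abs(r) + _SINGULARITY_TOL
    singular = np.abs(den) <= 1e-9 * scale
    if r.ndim == 0:
        if singular:
            raise SingularityError(f"BLL saturation formula singular at "
                                   f"R = {float(r):g}")
        return float(100.0 * num / den)
    out = np.full_like(r, np.nan)
    ok = ~singular
    out[ok] = 100.0 * num[ok] / den[ok]
    return out


def invert_spo2_bll(eps: EffectiveCoefficients, spo2):
    """R value at which the BLL formula yields the given SpO2 (percent)."""
    s = np.asarray(spo2, dtype=float)
    h1, o1 = eps.red.eps_hb, eps.red.eps_hbo2
    h2, o2 = eps.ir.eps_hb, eps.ir.eps_hbo2
    num = 100.0 * h1 - s * (h1 - o1)
    den = s * (o2 - h2) + 100.0 * h2
    out = num / den
    return float(out) if out.ndim == 0 else out


def spo2_linear(line: CalibrationLine, r, clamp: bool = False):
    """Linear-approximation SpO2 = a R + b, optionally clamped to [0, 100].

    Unclamped by default: the classic line exceeds 100 % at small R,
    and that excess is part of the error being quantified.
    """
    r = np.asarray(r, dtype=float)
    out = line.a * r + line.b
    if clamp:
        out = np.clip(out, 0.0, 100.0)
    return float(out) if out.ndim == 0 else out


def fit_linear_calibration(eps: EffectiveCoefficients,
                           r_range: tuple[float, float] | None = None,
                           n_points: int = 100) -> CalibrationLine:
    """Least-squares line through the BLL curve over an R range.

    The default range maps to BLL SpO2 in [70, 100] %, the span over
    which deployed single-line calibrations are meant to hold.
    """
    if r_range is None:
        r_lo = invert_spo2_bll(eps, 100.0)
        r_hi = invert_spo2_bll(eps, 70.0)
        r_range = (min(r_lo, r_hi), max(r_lo, r_hi))
    r = np.linspace(r_range[0], r_range[1], n_points)
    s = spo2_bll(eps, r)
    if np.any(~np.isfinite(s)):
        raise SingularityError("BLL formula singular inside the fit range")
    a, b = np.polyfit(r, s, 1)
    return CalibrationLine(float(a), float(b))


# ---------------------------------------------------------------------------
# PPG simulation and the ratio of ratios
# ---------------------------------------------------------------------------

def _pulse_waveform(phase: np.ndarray, waveform: str) -> np.ndarray:
    """Periodic unimodal pulse shape in [0, 1] versus phase in cycles."""
    if waveform == "cosine":
        return 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    if waveform == "systolic":
        # sharper, slightly asymmetric upstroke reminiscent of arterial pulses
        p = np.mod(phase, 1.0)
        shape = np.sin(np.pi * p) ** 3 * (1.0 + 0.3 * np.cos(np.pi * p))
        return shape / shape.max() if shape.max() > 0 else shape
    raise InputError(f"unknown waveform {waveform!r}")


def synth_ppg(params: ForwardModelParams,
              eps_at_channel: ChannelExtinction,
              duration: float = 10.0,
              sampling_rate: float = 100.0,
              label: str = "") -> PPGTrace:
    """Synthetic PPG at one channel from the Beer-Lambert forward model.

    I(t) = I0 exp(-eps_tot c (d_static + delta_d pulse(t))) + noise,
    with eps_tot = eps_HbO2 SaO2 + eps_Hb (1 - SaO2) and the same
    pulsatile path excursion at every channel.  Noise is additive,
    Gaussian relative to the DC level, seeded and clipped so the trace
    stays non-negative.
    """
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    eps_tot = (eps_at_channel.eps_hbo2 * params.sao2_true
               + eps_at_channel.eps_hb * (1.0 - params.sao2_true))
    pulse = _pulse_waveform(t * params.heart_rate_bpm / 60.0, params.waveform)
    path = params.d_static + params.delta_d_amp * pulse
    intensity = params.i0 * np.exp(-eps_tot * params.c_hb_total * path)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        intensity = intensity + rng.normal(
            0.0, params.noise_sd * intensity.mean(), size=n)
    intensity = np.clip(intensity, 0.0, None)
    return PPGTrace(t, intensity, sampling_rate, label=label)


def _dominant_frequency(x: np.ndarray, fs: float) -> float:
    """Frequency of the largest non-DC spectral component, Hz."""
    spec = np.abs(np.fft.rfft(x - x.mean()))
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    if spec.size < 2 or spec[1:].max() == 0:
        raise DegenerateInputError("trace has no periodic component")
    return float(freqs[1 + int(np.argmax(spec[1:]))])


def segment_cycles(trace: PPGTrace) -> list[slice]:
    """Cardiac-cycle windows from minima-to-minima on the trace.

    Minima are detected with a minimum spacing derived from the
    dominant frequency, so no prior heart-rate value is needed.
    """
    x = trace.intensity
    f0 = _dominant_frequency(x, trace.sampling_rate)
    distance = max(1, int(0.6 * trace.sampling_rate / f0))
    minima, _ = find_peaks(-x, distance=distance,
                           prominence=0.25 * np.ptp(x))
    if minima.size < 2:
        raise DegenerateInputError(
            "fewer than two pulse minima found; need >= 1 full cardiac cycle")
    return [slice(minima[i], minima[i + 1] + 1)
            for i in range(minima.size - 1)]


def count_cycles(trace: PPGTrace) -> int:
    """Number of detected pulse minima (beats) in the trace."""
    x = trace.intensity
    f0 = _dominant_frequency(x, trace.sampling_rate)
    distance = max(1, int(0.6 * trace.sampling_rate / f0))
    minima, _ = find_peaks(-x, distance=distance,
                           prominence=0.25 * np.ptp(x))
    return int(minima.size)


def ratio_of_ratios(ppg_red: PPGTrace, ppg_ir: PPGTrace) -> float:
    """Ratio of perfusion indices R by the peak-and-valley method.

    Cycles are segmented minima-to-minima on the IR trace (the
    conventionally cleaner channel); per cycle AC is the peak-to-peak
    and DC the mean of each trace over that window, and the per-cycle
    R values are averaged.
    """
    if ppg_red.intensity.size != ppg_ir.intensity.size:
        raise InputError("red and IR traces must have the same length")
    cycles = segment_cycles(ppg_ir)
    r_values = []
    for window in cycles:
        red, ir = ppg_red.intensity[window], ppg_ir.intensity[window]
        ac_ir, dc_ir = float(np.ptp(ir)), float(ir.mean())
        ac_red, dc_red = float(np.ptp(red)), float(red.mean())
        if ac_ir <= 0 or dc_ir <= 0:
            raise DegenerateInputError("IR trace has zero perfusion in a "
                                       "cycle; R is undefined")
        if dc_red <= 0:
            raise DegenerateInputError("red trace has non-positive DC")
        r_values.append((ac_red / dc_red) / (ac_ir / dc_ir))
    return float(np.mean(r_values))


# ---------------------------------------------------------------------------
# error profile of the linear approximation
# ---------------------------------------------------------------------------

def default_r_grid(n: int = 400,
                   r_min: float = 0.3,
                   r_max: float = 3.0) -> np.ndarray:
    """Default R grid: covers SpO2 ~40-110 % for physiological tables."""
    return np.linspace(r_min, r_max, n)


def error_profile(eps: EffectiveCoefficients,
                  line: CalibrationLine = DEFAULT_CALIBRATION,
                  r_grid: np.ndarray | None = None,
                  window: tuple[float, float] = (90.0, 100.0)) -> ErrorProfile:
    """Relative deviation of the linear approximation from the BLL.

    dSpO2 = (BLL - Approx)/BLL * 100 % per grid point; negative values
    mean the linear line overestimates saturation.  Singular grid
    points are dropped with a warning.  ``window`` flags the entries
    whose BLL saturation falls in the critical range (90-100 % by
    default).
    """
    r = default_r_grid() if r_grid is None else np.asarray(r_grid, dtype=float)
    bll = spo2_bll(eps, r)
    keep = np.isfinite(bll) & (np.abs(bll) > _SINGULARITY_TOL)
    if not np.all(keep):
        warnings.warn(f"dropping {int((~keep).sum())} singular grid points "
                      "from the error profile", stacklevel=2)
    r, bll = r[keep], bll[keep]
    lin = spo2_linear(line, r)
    delta = (bll - lin) / bll * 100.0
    mask = (bll >= window[0]) & (bll <= window[1])
    return ErrorProfile(r_grid=r, spo2_bll=bll, spo2_linear=lin,
                        delta_spo2=delta, window=mask, window_range=window)


def max_abs_error_in_window(profile: ErrorProfile) -> float:
    """Largest |dSpO2| (percent) where BLL SpO2 lies in the window."""
    if not np.any(profile.window):
        raise DegenerateInputError(
            f"no grid points with BLL SpO2 in "
            f"[{profile.window_range[0]:g}, {profile.window_range[1]:g}] %")
    return float(np.abs(profile.delta_spo2[profile.window]).max())
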