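"""Parametric and sampled spectral models for LEDs and photodetectors.

Emission spectra of oximetry LEDs are, to first order, Gaussian bands
characterised by a peak wavelength and a full width at half maximum
(FWHM).  Real devices deviate from the symmetric bell: measured spectra
lean left or right (the dominant/centroid wavelength then differs from
the peak wavelength) and most LEDs show a small stray secondary peak.
This module provides

* :class:`GaussianBand` -- the normalized symmetric model
  ``I(lambda) = A * exp(-4 ln 2 ((lambda - center)/fwhm)^2)``,
* :class:`SkewedBand` -- a skew-normal lineshape reparameterised by
  (mode, FWHM, shape) so datasheet quantities stay meaningful,
* :class:`SampledSpectrum` -- the common sampled-curve currency for
  emission, sensitivity and extinction data,
* peak/FWHM extraction, resampling, normalization, pointwise spectral
  products and a seeded synthetic-spectrum generator that emulates a
  spectrometer export (finite resolution, skew, stray peaks, noise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Sequence, Union

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import skewnorm

from .errors import DegenerateInputError, ExtractionError, InputError

__all__ = [
    "FOUR_LN2",
    "DEFAULT_GRID_STEP_NM",
    "DEFAULT_GRID_RANGE_NM",
    "default_grid",
    "SampledSpectrum",
    "GaussianBand",
    "SkewedBand",
    "LightSource",
    "Photodetector",
    "evaluate_band",
    "evaluate_skewed_band",
    "normalize",
    "resample_to_grid",
    "spectral_product",
    "extract_peak_fwhm",
    "synth_led_spectrum",
]

FOUR_LN2 = 4.0 * np.log(2.0)

#: Default working grid: finer than the 0.6 nm instrument resolution so
#: that resampled curves are not the accuracy bottleneck.
DEFAULT_GRID_STEP_NM = 0.2
DEFAULT_GRID_RANGE_NM = (300.0, 1100.0)


def default_grid(step: float = DEFAULT_GRID_STEP_NM,
                 lo: float = DEFAULT_GRID_RANGE_NM[0],
                 hi: float = DEFAULT_GRID_RANGE_NM[1]) -> np.ndarray:
    """Uniform wavelength grid in nm, inclusive of both endpoints."""
    if step <= 0:
        raise InputError(f"grid step must be positive, got {step}")
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def _validate_grid(grid: Sequence[float]) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise InputError("wavelength grid must be a non-empty 1-D sequence")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise InputError("wavelength grid must be strictly ascending")
    return grid


@dataclass(frozen=True)
class SampledSpectrum:
    """A curve sampled on a strictly ascending wavelength grid.

    Parameters
    ----------
    wavelengths : array of float
        Wavelengths in nm, strictly increasing.
    values : array of float
        Non-negative relative values (intensity, sensitivity or
        extinction), same length as ``wavelengths``.
    kind : str
        One of ``emission``, ``sensitivity``, ``extinction`` or
        ``derived``.
    label : str
        Free-text identifier used in reports and plots.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "emission"
    label: str = ""

    def __post_init__(self) -> None:
        wl = _validate_grid(self.wavelengths)
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != wl.shape:
            raise InputError(
                f"values length {vals.size} != wavelengths length {wl.size}")
        if not np.all(np.isfinite(vals)):
            raise InputError("spectrum values must be finite")
        if np.any(vals < 0):
            raise InputError("spectrum values must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    # -- derived quantities -------------------------------------------------

    @property
    def step(self) -> float:
        """Median grid step in nm."""
        if self.wavelengths.size < 2:
            return np.nan
        return float(np.median(np.diff(self.wavelengths)))

    def centroid(self) -> float:
        """Intensity-weighted mean wavelength (trapezoidal), nm."""
        w = np.trapezoid(self.values, self.wavelengths)
        if w <= 0:
            raise DegenerateInputError("cannot take centroid of a zero spectrum")
        return float(np.trapezoid(self.wavelengths * self.values,
                                  self.wavelengths) / w)

    # -- transformations ----------------------------------------------------

    def normalize(self) -> "SampledSpectrum":
        return normalize(self)

    def resample(self, grid: Sequence[float]) -> "SampledSpectrum":
        return resample_to_grid(self, grid)


BandLike = Union["GaussianBand", "SkewedBand"]


@dataclass(frozen=True)
class GaussianBand:
    """Symmetric spectral band: peak wavelength, FWHM, relative amplitude."""

    center: float
    fwhm: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise InputError(f"fwhm must be positive, got {self.fwhm}")
        if self.center <= 0:
            raise InputError(f"center must be positive, got {self.center}")
        if self.amplitude < 0:
            raise InputError("amplitude must be non-negative")

    @property
    def sigma(self) -> float:
        """Gaussian standard deviation equivalent to the FWHM."""
        return self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    def __call__(self, wavelengths: np.ndarray) -> np.ndarray:
        lam = np.asarray(wavelengths, dtype=float)
        return self.amplitude * np.exp(
            -FOUR_LN2 * ((lam - self.center) / self.fwhm) ** 2)


@lru_cache(maxsize=256)
def _skewnorm_standard_mode_fwhm(shape: float) -> tuple[float, float]:
    """Mode and FWHM of the standardized skew-normal pdf with given shape."""
    pdf = lambda z: skewnorm.pdf(z, shape)
    res = minimize_scalar(lambda z: -pdf(z), bounds=(-3.0, 3.0),
                          method="bounded",
                          options={"xatol": 1e-10})
    mode = float(res.x)
    top = pdf(mode)
    half = lambda z: pdf(z) - 0.5 * top
    left = brentq(half, mode - 12.0, mode, xtol=1e-10)
    right = brentq(half, mode, mode + 12.0, xtol=1e-10)
    return mode, float(right - left)


@dataclass(frozen=True)
class SkewedBand:
    """Skew-normal band reparameterised by (mode, FWHM, shape).

    ``skew`` is the skew-normal shape parameter: zero gives back the
    symmetric Gaussian exactly, positive values lean the tail to longer
    wavelengths (centroid above the mode), negative to shorter ones.
    The lineshape is numerically renormalised to a unit maximum; the
    functional form is deliberately kept behind this one interface
    because no single skewed lineshape fits every measured LED.
    """

    mode: float
    fwhm: float
    skew: float = 0.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise InputError(f"fwhm must be positive, got {self.fwhm}")
        if self.mode <= 0:
            raise InputError(f"mode must be positive, got {self.mode}")

    # GaussianBand-compatible alias so bands are interchangeable
    @property
    def center(self) -> float:
        return self.mode

    def __call__(self, wavelengths: np.ndarray) -> np.ndarray:
        lam = np.asarray(wavelengths, dtype=float)
        if self.skew == 0.0:
            return GaussianBand(self.mode, self.fwhm, self.amplitude)(lam)
        m0, w0 = _skewnorm_standard_mode_fwhm(float(self.skew))
        scale = self.fwhm / w0
        loc = self.mode - m0 * scale
        vals = skewnorm.pdf(lam, self.skew, loc=loc, scale=scale)
        peak = skewnorm.pdf(loc + m0 * scale, self.skew, loc=loc, scale=scale)
        return self.amplitude * vals / peak

    def centroid(self) -> float:
        """Analytic centroid (mean) of the lineshape, nm."""
        if self.skew == 0.0:
            return self.mode
        m0, w0 = _skewnorm_standard_mode_fwhm(float(self.skew))
        scale = self.fwhm / w0
        loc = self.mode - m0 * scale
        return float(skewnorm.mean(self.skew, loc=loc, scale=scale))


@dataclass(frozen=True)
class LightSource:
    """An LED (or one band of a multi-band device) with optional stray peaks.

    ``drive_current_ma`` is metadata only; spectra are assumed to be
    acquired at the datasheet forward current (20 mA when unspecified).
    """

    name: str
    primary_band: BandLike
    stray_bands: tuple[GaussianBand, ...] = ()
    drive_current_ma: float = 20.0

    def __post_init__(self) -> None:
        strays = tuple(self.stray_bands)
        for b in strays:
            if b.amplitude > self.primary_band.amplitude:
                raise InputError(
                    f"stray band amplitude {b.amplitude} exceeds primary "
                    f"amplitude {self.primary_band.amplitude}")
        object.__setattr__(self, "stray_bands", strays)

    @property
    def nominal_center(self) -> float:
        return self.primary_band.center


@dataclass(frozen=True)
class Photodetector:
    """A photodetector identified by its relative spectral response."""

    name: str
    response: Union[GaussianBand, SampledSpectrum]

    def sampled(self, grid: np.ndarray) -> SampledSpectrum:
        """Response evaluated/resampled on ``grid`` (not renormalised)."""
        if isinstance(self.response, SampledSpectrum):
            return resample_to_grid(self.response, grid)
        return SampledSpectrum(grid, self.response(grid),
                               kind="sensitivity", label=self.name)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def evaluate_band(band: GaussianBand, grid: Sequence[float]) -> SampledSpectrum:
    """Sample a symmetric Gaussian band on an ascending wavelength grid."""
    grid = _validate_grid(grid)
    return SampledSpectrum(grid, band(grid), kind="emission",
                           label=f"gaussian({band.center:g},{band.fwhm:g})")


def evaluate_skewed_band(band: SkewedBand,
                         grid: Sequence[float]) -> SampledSpectrum:
    """Sample a skewed band on a grid, renormalised to a unit grid maximum.

    With ``skew == 0`` this reduces exactly to :func:`evaluate_band`.
    """
    grid = _validate_grid(grid)
    vals = band(grid)
    if band.skew != 0.0 and vals.max() > 0:
        vals = vals * (band.amplitude / vals.max())
    return SampledSpectrum(grid, vals, kind="emission",
                           label=f"skewed({band.mode:g},{band.fwhm:g},"
                                 f"{band.skew:g})")


def normalize(s: SampledSpectrum) -> SampledSpectrum:
    """Scale a spectrum to a unit maximum."""
    top = s.values.max() if s.values.size else 0.0
    if top <= 0:
        raise DegenerateInputError(f"cannot normalize all-zero spectrum "
                                   f"{s.label!r}")
    return replace(s, values=s.values / top)


def resample_to_grid(s: SampledSpectrum,
                     grid: Sequence[float]) -> SampledSpectrum:
    """Linearly interpolate a spectrum onto a new grid.

    Points outside the original support are set to zero: emission and
    sensitivity curves are physically negligible far from their band,
    and refusing to extrapolate keeps weighted sums artifact-free.
    """
    if s.wavelengths.size < 2:
        raise InputError("cannot resample a spectrum with fewer than 2 points")
    grid = _validate_grid(grid)
    vals = np.interp(grid, s.wavelengths, s.values, left=0.0, right=0.0)
    return replace(s, wavelengths=grid, values=vals)


def _common_grid(a: SampledSpectrum, b: SampledSpectrum) -> np.ndarray:
    step = np.nanmin([a.step, b.step])
    lo = min(a.wavelengths[0], b.wavelengths[0])
    hi = max(a.wavelengths[-1], b.wavelengths[-1])
    return default_grid(step=step, lo=lo, hi=hi)


def spectral_product(a: SampledSpectrum, b: SampledSpectrum,
                     grid: Sequence[float] | None = None) -> SampledSpectrum:
    """Pointwise product of two spectra on a common grid.

    When ``grid`` is omitted, the union of both supports at the finer of
    the two native steps is used.  Disjoint supports produce an all-zero
    result with a warning rather than an error, so batch pairing sweeps
    keep going.
    """
    grid = _common_grid(a, b) if grid is None else _validate_grid(grid)
    av = resample_to_grid(a, grid).values
    bv = resample_to_grid(b, grid).values
    vals = av * bv
    if vals.max() == 0.0:
        warnings.warn(
            f"spectral_product: supports of {a.label!r} and {b.label!r} "
            "are disjoint; result is identically zero",
            stacklevel=2)
    return SampledSpectrum(grid, vals, kind="derived",
                           label=f"({a.label})*({b.label})")


def _half_crossing(wl: np.ndarray, vals: np.ndarray, i_peak: int,
                   half: float, direction: int) -> float:
    """Wavelength of the half-maximum crossing nearest the peak.

    ``direction`` is -1 (scan to shorter wavelengths) or +1.  The
    crossing is linearly interpolated between the bracketing samples.
    """
    j = i_peak
    while 0 <= j + direction < wl.size:
        k = j + direction
        if vals[k] <= half:
            # crossing between j and k
            if vals[j] == vals[k]:
                return float(wl[k])
            frac = (vals[j] - half) / (vals[j] - vals[k])
            return float(wl[j] + frac * (wl[k] - wl[j]))
        j = k
    side = "short-wavelength" if direction < 0 else "long-wavelength"
    raise ExtractionError(
        f"no half-maximum crossing on the {side} side of the peak")


def extract_peak_fwhm(s: SampledSpectrum) -> tuple[float, float]:
    """Peak wavelength and FWHM of the main lobe of a sampled spectrum.

    The peak is the grid argmax (ties resolved to the lowest
    wavelength); the FWHM is the distance between the two half-maximum
    crossings nearest the peak, each linearly interpolated between
    samples.  Spectra whose main lobe does not cross half maximum on
    both sides (e.g. a monotonic ramp) raise :class:`ExtractionError`.
    """
    if s.values.max() <= 0:
        raise ExtractionError("cannot extract peak of an all-zero spectrum")
    i = int(np.argmax(s.values))
    half = 0.5 * s.values[i]
    left = _half_crossing(s.wavelengths, s.values, i, half, -1)
    right = _half_crossing(s.wavelengths, s.values, i, half, +1)
    return float(s.wavelengths[i]), right - left


def synth_led_spectrum(source: LightSource,
                       resolution: float = 0.6,
                       noise_sd: float = 0.0,
                       seed: int | np.random.Generator | None = None,
                       grid_range: tuple[float, float] = DEFAULT_GRID_RANGE_NM,
                       ) -> SampledSpectrum:
    """Generate a spectrometer-style emission spectrum for a light source.

    Emulates what a fibre spectrometer export of a real LED looks like:
    the primary (possibly skewed) band plus any stray secondary peaks,
    sampled at the instrument resolution (0.6 nm by default), with
    additive Gaussian noise relative to the peak, clipped at zero and
    normalized.  Reproducible for a fixed ``seed``.
    """
    if resolution <= 0:
        raise InputError(f"resolution must be positive, got {resolution}")
    grid = default_grid(step=resolution, lo=grid_range[0], hi=grid_range[1])
    band = source.primary_band
    if isinstance(band, SkewedBand):
        vals = evaluate_skewed_band(band, grid).values.copy()
    else:
        vals = band(grid)
    for stray in source.stray_bands:
        vals = vals + stray(grid)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, noise_sd * vals.max(), size=vals.size)
    vals = np.clip(vals, 0.0, None)
    spec = SampledSpectrum(grid, vals, kind="emission", label=source.name)
    return normalize(spec)
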