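"""Closed-form analysis of LED/photodetector Gaussian pairing.

When a Gaussian emission band ``(lambda_LED, dlam_LED)`` is weighted by
a Gaussian detector response ``(lambda_PD, dlam_PD)``, the product is
again a Gaussian whose parameters follow from completing the square:

    w          = dlam_LED^2 / (dlam_LED^2 + dlam_PD^2)
    lambda_eff = lambda_LED + w (lambda_PD - lambda_LED)
    dlam_eff   = dlam_LED dlam_PD / sqrt(dlam_LED^2 + dlam_PD^2)

so the effective centre is always pulled from the LED peak toward the
detector peak (delta_lambda = lambda_eff - lambda_LED carries the sign
of lambda_PD - lambda_LED) and the effective band is narrower than
either factor.  A first-order approximation in (dlam_LED/dlam_PD)^2 is
provided for the usual design regime of a narrow source on a broad
detector, where the shift reduces to
``(lambda_PD - lambda_LED) (dlam_LED/dlam_PD)^2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Union

import numpy as np

from .errors import InputError
from .spectra import (
    GaussianBand,
    LightSource,
    Photodetector,
    SampledSpectrum,
    SkewedBand,
    default_grid,
    evaluate_band,
    extract_peak_fwhm,
    spectral_product,
)

__all__ = [
    "SourceDetectorPair",
    "EffectiveBand",
    "effective_band_exact",
    "effective_band_paper_approx",
    "pair_report",
]


@dataclass(frozen=True)
class SourceDetectorPair:
    """A red source, an IR source and the shared photodetector."""

    red_source: LightSource
    ir_source: LightSource
    detector: Photodetector
    label: str = ""

    def __post_init__(self) -> None:
        if self.red_source.nominal_center >= self.ir_source.nominal_center:
            raise InputError(
                f"red source centre {self.red_source.nominal_center:g} nm "
                f"must lie below IR source centre "
                f"{self.ir_source.nominal_center:g} nm")
        if not self.label:
            object.__setattr__(
                self, "label",
                f"{self.red_source.name}+{self.ir_source.name}")


@dataclass(frozen=True)
class EffectiveBand:
    """Effective centre, width and shift of a source-detector product."""

    lambda_eff: float
    fwhm_eff: float
    delta_lambda: float


def effective_band_exact(led: GaussianBand,
                         pd: GaussianBand) -> EffectiveBand:
    """Exact Gaussian-product centre, FWHM and shift."""
    dl2, dp2 = led.fwhm ** 2, pd.fwhm ** 2
    w = dl2 / (dl2 + dp2)
    lambda_eff = led.center + w * (pd.center - led.center)
    fwhm_eff = led.fwhm * pd.fwhm / np.sqrt(dl2 + dp2)
    return EffectiveBand(lambda_eff=float(lambda_eff),
                         fwhm_eff=float(fwhm_eff),
                         delta_lambda=float(lambda_eff - led.center))


def effective_band_paper_approx(led: GaussianBand,
                                pd: GaussianBand) -> EffectiveBand:
    """First-order effective band for a narrow source on a broad detector.

    Valid for ``dlam_LED <= dlam_PD``; with r = dlam_LED/dlam_PD,

        delta_lambda ~= (lambda_PD - lambda_LED) r^2
        dlam_eff     ~= dlam_LED (1 - r^2 / 2)

    which agrees with :func:`effective_band_exact` to first order in
    r^2 and satisfies the sign rule sign(delta) = sign(lambda_PD -
    lambda_LED): the pairing pulls the centre wavelengths together.
    Outside the regime the exact form is returned with a warning.
    """
    if led.fwhm > pd.fwhm:
        warnings.warn(
            "approximation regime requires source FWHM <= detector FWHM; "
            "falling back to the exact Gaussian-product form",
            stacklevel=2)
        return effective_band_exact(led, pd)
    r2 = (led.fwhm / pd.fwhm) ** 2
    delta = (pd.center - led.center) * r2
    return EffectiveBand(lambda_eff=float(led.center + delta),
                         fwhm_eff=float(led.fwhm * (1.0 - 0.5 * r2)),
                         delta_lambda=float(delta))


def _band_of(response: Union[GaussianBand, SkewedBand, SampledSpectrum],
             grid_step: float = 0.2) -> tuple[GaussianBand, bool]:
    """Gaussian (center, FWHM) summary of a response; flags numeric fits.

    Returns ``(band, fitted)`` where ``fitted`` is True when the band
    was extracted numerically from a sampled curve rather than given
    parametrically.
    """
    if isinstance(response, GaussianBand):
        return response, False
    if isinstance(response, SkewedBand):
        grid = default_grid(step=grid_step)
        from .spectra import evaluate_skewed_band

        peak, fwhm = extract_peak_fwhm(evaluate_skewed_band(response, grid))
        return GaussianBand(peak, fwhm), True
    peak, fwhm = extract_peak_fwhm(response)
    return GaussianBand(peak, fwhm), True


def _numeric_effective_band(led_band: GaussianBand,
                            detector: Photodetector,
                            grid_step: float) -> EffectiveBand:
    """Effective band from the numerically sampled emission*response."""
    grid = default_grid(step=grid_step)
    led_spec = evaluate_band(led_band, grid)
    det_spec = detector.sampled(grid)
    product = spectral_product(led_spec, det_spec, grid=grid)
    peak, fwhm = extract_peak_fwhm(product)
    return EffectiveBand(lambda_eff=peak, fwhm_eff=fwhm,
                         delta_lambda=peak - led_band.center)


def pair_report(pair: SourceDetectorPair,
                table=None,
                grid_step: float = 0.2) -> dict:
    """Structured effective-band and effective-extinction summary.

    Per channel: the source's Gaussian summary, the effective band of
    the source-detector product and, when an extinction ``table`` is
    given, the effective coefficients and their shifts.  Detectors
    whose sampled response has no extractable peak/FWHM (e.g. a
    quasi-linear ramp) trigger a fully numeric effective band, flagged
    by ``detector_model = "numeric-fallback"``.
    """
    from .chromophores import effective_coefficients
    from .errors import ExtractionError

    report: dict = {"pair": pair.label, "detector": pair.detector.name}
    try:
        det_band, fitted = _band_of(pair.detector.response, grid_step)
        report["detector_model"] = "gaussian-fit" if fitted else "gaussian"
        report["detector_band"] = {"center_nm": det_band.center,
                                   "fwhm_nm": det_band.fwhm}
    except ExtractionError:
        det_band = None
        report["detector_model"] = "numeric-fallback"

    for channel, source in (("red", pair.red_source), ("ir", pair.ir_source)):
        led_band, _ = _band_of(source.primary_band, grid_step)
        if det_band is not None:
            eff = effective_band_exact(led_band, det_band)
        else:
            eff = _numeric_effective_band(led_band, pair.detector, grid_step)
        report[channel] = {
            "source": source.name,
            "nominal_nm": led_band.center,
            "fwhm_nm": led_band.fwhm,
            "lambda_eff_nm": eff.lambda_eff,
            "fwhm_eff_nm": eff.fwhm_eff,
            "delta_lambda_nm": eff.delta_lambda,
        }

    if table is not None:
        coeffs = effective_coefficients(table, pair,
                                        grid=default_grid(step=grid_step))
        for channel in ("red", "ir"):
            ch = getattr(coeffs, channel)
            report[channel]["eps_hbo2_eff"] = ch.eps_hbo2
            report[channel]["eps_hb_eff"] = ch.eps_hb
            report[channel]["shift_hbo2"] = coeffs.shift(channel, "hbo2")
            report[channel]["shift_hb"] = coeffs.shift(channel, "hb")
    return report
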