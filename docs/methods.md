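# Methods

This note records the models implemented in `oxishift`, the assumptions
behind them, the defaults and why they were chosen, and what the
bundled synthetic data can and cannot establish.

## Spectral models

**Symmetric bands.** LED emission and photodetector responsivity are
modelled as normalized Gaussians parameterised by peak wavelength and
full width at half maximum,
`I(λ) = exp(−4 ln 2 · ((λ − λ_peak)/Δλ)²)`, the parameterisation in
which datasheet values are quoted. The half-maximum identity
`I(λ_peak ± Δλ/2) = 1/2` holds exactly and is tested.

**Skewed bands.** Measured LED spectra lean left or right; when a
datasheet quotes both a dominant (centroid) and a peak wavelength, the
difference is a direct signature of skew. `SkewedBand` uses a
skew-normal lineshape reparameterised by (mode, FWHM, shape): the
standardized skew-normal mode and FWHM are found numerically (bounded
scalar minimisation plus bracketed root finding, both to 1e−10) and the
location/scale are solved so the requested mode and FWHM are exact.
Zero shape reduces *exactly* to the Gaussian (special-cased, not
approximated). No single skewed analytic form fits every measured LED,
so the lineshape sits behind one interface and can be replaced without
touching the rest of the pipeline.

**Sampled spectra.** `SampledSpectrum` carries any curve on a strictly
ascending wavelength grid. Resampling is linear interpolation with
out-of-support values set to zero — spectra are physically negligible
far from their band, and refusing to extrapolate keeps weighted sums
free of edge artifacts. Normalisation scales to unit maximum and is
idempotent. Peak/FWHM extraction takes the grid argmax (ties resolved
to the lowest wavelength) and linearly interpolates the two
half-maximum crossings nearest the peak; spectra without a crossing on
both sides (e.g. a monotonic ramp) raise an error rather than return a
fabricated width.

**Working grids.** The default working grid is 0.2 nm over
300–1100 nm, deliberately finer than the 0.6 nm resolution of the
fibre spectrometers whose exports the CSV reader emulates, so that
resampling is never the accuracy bottleneck. The synthetic-spectrum
generator defaults to 0.6 nm to mimic an instrument export: primary
(possibly skewed) band plus stray secondary peaks, additive seeded
Gaussian noise relative to the peak, clipped at zero, normalized.

## Hemoglobin extinction table

Effective-coefficient computations need tabulated molar extinction of
HbO2 and Hb. The bundled table (`reference_extinction_table`) is a
**synthetic compilation**: monotone piecewise-cubic (PCHIP)
interpolation, in log10 space, through anchor knots that reproduce the
canonical features of the hemoglobin spectra — Soret bands near
415/432 nm, the HbO2 α/β doublet at 542/577 nm, the steep red edge,
the Hb bump near 760 nm, the ~800 nm isosbestic crossing and the flat
NIR plateau. The oximetry-critical anchors at 660 nm
(ε_HbO2 = 319.6, ε_Hb = 3226.56 L·mol⁻¹·cm⁻¹) and 940 nm
(1214, 693.44) match the values in widespread use. Log-space
interpolation keeps the five-decade dynamic range positive and smooth.
The table is tagged `synthetic-compilation`; any measured table can be
substituted via the three-column extinction CSV loader, and
quantitative agreement with results computed from a specific published
compilation should only be expected when that compilation is supplied.

Interpolation within the table is linear and exact at nodes;
wavelengths outside 400–1000 nm are refused rather than extrapolated.

## Effective coefficients and the pairing shift

The effective extinction under a source–detector pairing is the
normalized weighted mean

```
ε_eff = Σᵢ ε(λᵢ)·I_LED(λᵢ)·H_PD(λᵢ) / Σᵢ I_LED(λᵢ)·H_PD(λᵢ)
```

The normalisation is deliberate: it makes ε_eff invariant under
rescaling of either spectrum, keeps the units L·mol⁻¹·cm⁻¹, bounds
ε_eff by the extinction extrema over the weight's support, and
reproduces the pointwise table value in the monochromatic/flat-detector
limit (verified to <0.5 % at 1 nm FWHM). Weight falling outside the
tabulated range is ignored, with a warning once it exceeds 1 % of the
total.

For Gaussian factors the product parameters have the exact closed form
given in the README; `effective_band_exact` is the reference
implementation and is validated against the argmax/FWHM of the
numerically sampled product over 10⁴ random parameter draws (within
one grid step at Δλ_eff/20 resolution). A first-order approximation for
the design regime of a narrow source on a broad detector,
`δλ ≈ (λ_PD − λ_LED)·(Δλ_LED/Δλ_PD)²`, is provided separately; it
satisfies the sign rule (the pairing pulls the centre wavelengths
together) and converges to the exact form as Δλ_LED/Δλ_PD → 0. Outside
its regime it warns and defers to the exact form.

Shift tables report ε_eff − ε(λ_nominal) per chromophore per channel,
where λ_nominal is the centre of the band actually used in modelling
(measured peak wavelength by default; datasheet values with the
dominant wavelength preferred when `prefer="datasheet"`, matching how
datasheets highlight their key optical feature).

## SpO2 models and the error profile

The Beer–Lambert saturation formula and the linear approximation are
implemented as in the README. Points worth noting:

- `spo2_linear` does **not** clamp to [0, 100] by default: the classic
  line exceeds 100 % at small R and that excess is part of the error
  being quantified. A clamp flag exists for display.
- `fit_linear_calibration` least-squares fits a line to the BLL curve;
  the default R range is obtained by inverting the BLL formula at 70 %
  and 100 % saturation, the span over which single-line calibrations
  are meant to hold.
- The error profile is `ΔSpO2 = (BLL − Approx)/BLL · 100 %` per grid
  point (negative where the linear line overestimates), on a default
  grid of 400 points over R ∈ [0.3, 3.0], which covers roughly
  40–110 % saturation for physiological coefficient sets. Grid points
  where the BLL value is singular or zero are dropped with a warning.
  The 90–100 % window mask supports the clinically critical summary
  `max_abs_error_in_window`.

An empirical observation made during validation: with the fixed
110 − 25·R line and the bundled table, widening the source FWHM does
**not** monotonically increase the window error — the effective
coefficients can move the BLL curve *toward* the classic line (7.6 %
at 1 nm FWHM down to 5.5 % at 40/100 nm, flat detector). What does
grow monotonically with FWHM is the pairing effect itself, the gap
between the BLL curve with effective and with nominal coefficients;
that is the monotonicity the test suite asserts.

## PPG forward model

`synth_ppg` generates transmitted-intensity traces
`I(t) = I0·exp(−ε_tot·c·(d + Δd·pulse(t))) + noise` with
`ε_tot = ε_HbO2·SaO2 + ε_Hb·(1 − SaO2)`. Defaults: total hemoglobin
2.3 mmol/L (≈150 g/L blood), baseline path 1 cm, pulsatile amplitude
0.01 cm (Δd/d = 10⁻², identical at both wavelengths — the standard
small-signal assumption), 60 bpm, 100 Hz sampling, a raised-cosine
pulse (a sharper asymmetric "systolic" waveform is available). Noise
is additive Gaussian relative to the DC level, seeded, clipped at
zero.

`ratio_of_ratios` segments cardiac cycles minima-to-minima on the IR
trace (the conventionally cleaner channel; the cycle definition is a
design choice since only per-cycle AC/DC is specified by the method
itself), with the minimum-spacing constraint derived from the trace's
dominant frequency so no prior heart-rate value is needed. Per cycle,
AC is the peak-to-peak and DC the mean; per-cycle R values are
averaged. The end-to-end loop — simulate at known SaO2, segment,
compute R, invert through the BLL — recovers the configured saturation
within 0.5 percentage points for SaO2 ∈ {80, 90, 97, 100} % in the
noiseless monochromatic setting, limited only by the second-order
(AC/DC vs. absorbance-difference) approximation, which is O((ε·c·Δd)²).

## Fixtures and synthetic stand-ins

- **Component registry** (`data/components.yaml`): candidate oximetry
  LEDs with datasheet parameters (dominant wavelength, peak
  wavelength, FWHM; absent where the datasheet omits them) and
  spectrometer-measured parameters (peak, FWHM). Measured values are
  preferred for modelling by default; commercial probe emitters carry
  measured values only. The registry is validated cell-for-cell in the
  test suite.
- **Detectors**: measured responsivity curves are manufacturer data
  and are not redistributed. Five synthetic stand-ins cover the
  response shapes that matter for pairing analysis: `flat` (the
  monochromatic-theory limit), `broad-si` (Gaussian, 900/470 nm, a
  generic silicon photodiode), `mid-symmetric` (800/380 nm, symmetric
  about the midpoint of the two channels), `vis-peaked` (780/250 nm, a
  narrower response weighting the visible side), and `ramp` (a
  quasi-linear rising response). Results obtained with these stand-ins
  demonstrate the mechanism and its magnitude class; device-specific
  numbers require the device's measured curve, supplied as a
  two-column CSV.

Because the extinction table and the detectors are synthetic, passing
tests establish the correctness of the computations and the realistic
magnitude of the effects (shifts of tens to ~10² L·mol⁻¹·cm⁻¹,
window errors of several percent), not the exact published values for
any specific instrument.

## Problem sizes and numerical choices

The default analyses run on a 0.2 nm grid (4001 points), 400-point R
grids, 10–20 s of simulated PPG at 100 Hz, and a 10⁴-draw randomized
validation of the Gaussian-product closed form; the full suite plus
the acceptance script completes in a few seconds on one core. Ties at
a sampled maximum resolve to the lowest wavelength; half-maximum
crossings are linearly interpolated; all stochastic operations take
explicit seeds and are bitwise reproducible for a fixed seed.

## Known limitations

- Temperature, drive-current and process dependence of spectra are out
  of scope; the registry's drive current is metadata only.
- Dyshemoglobins (COHb, MetHb) and multi-wavelength co-oximetry are
  not modelled; concentrations are never solved for absolutely.
- The skew-normal is one choice of skewed lineshape; measured spectra
  with strong secondary structure are better represented as sampled
  curves than by any three-parameter band.
- Motion artifacts, respiratory modulation and detector photo-response
  non-uniformity are not simulated.
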