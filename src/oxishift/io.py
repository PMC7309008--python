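"""File I/O, the component registry and synthetic detector stand-ins.

Spectra travel as two-column CSV files (wavelength_nm, value) with an
optional single header line -- the layout a fibre-spectrometer export
produces.  Extinction tables are three-column CSV with a mandatory
header.  The bundled component registry holds the datasheet and
measured optical parameters of candidate oximetry LEDs; photodetector
curves are not bundled (they are manufacturer data), so named synthetic
stand-ins with the qualitative shapes relevant to pairing analysis
(flat, broad Gaussian, symmetric mid-peak, quasi-linear ramp) are
provided for tests and design sweeps.
"""

from __future__ import annotations

import csv
import io as _io
import importlib.resources
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd
import yaml

from .chromophores import ChromophoreTable
from .errors import InputError
from .pairing import SourceDetectorPair
from .spectra import (
    GaussianBand,
    LightSource,
    Photodetector,
    SampledSpectrum,
    default_grid,
)

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_extinction_csv",
    "write_extinction_csv",
    "RegistryBand",
    "RegistryEntry",
    "ComponentRegistry",
    "load_registry",
    "generic_pair_sources",
    "synthetic_detector",
    "SYNTHETIC_DETECTORS",
    "standard_pairs",
]


# ---------------------------------------------------------------------------
# spectrum / extinction CSV
# ---------------------------------------------------------------------------

def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_spectrum_csv(source: Union[str, Path, _io.TextIOBase],
                      kind: str = "emission",
                      label: str = "") -> SampledSpectrum:
    """Read a two-column (wavelength_nm, value) CSV into a spectrum.

    A single non-numeric header line is tolerated; any later
    non-numeric row raises :class:`InputError` with its line number.
    Rows are sorted ascending and duplicate wavelengths are averaged
    (with a warning), matching how repeated spectrometer exports are
    merged.
    """
    if isinstance(source, (str, Path)):
        handle = open(source, "r", newline="")
        close, name = True, str(source)
    else:
        handle, close, name = source, False, getattr(source, "name", "<file>")
    wl, vals = [], []
    try:
        for lineno, row in enumerate(csv.reader(handle), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise InputError(f"{name}:{lineno}: expected two columns, "
                                 f"got {len(row)}")
            a, b = row[0].strip(), row[1].strip()
            if not (_is_number(a) and _is_number(b)):
                if lineno == 1:
                    continue  # header
                raise InputError(f"{name}:{lineno}: non-numeric row {row!r}")
            wl.append(float(a))
            vals.append(float(b))
    finally:
        if close:
            handle.close()
    if len(wl) < 2:
        raise InputError(f"{name}: need at least 2 data rows, got {len(wl)}")
    wl_arr = np.asarray(wl)
    vals_arr = np.asarray(vals)
    order = np.argsort(wl_arr, kind="stable")
    wl_arr, vals_arr = wl_arr[order], vals_arr[order]
    uniq, inverse, counts = np.unique(wl_arr, return_inverse=True,
                                      return_counts=True)
    if uniq.size != wl_arr.size:
        warnings.warn(f"{name}: duplicate wavelengths averaged", stacklevel=2)
        sums = np.zeros_like(uniq)
        np.add.at(sums, inverse, vals_arr)
        wl_arr, vals_arr = uniq, sums / counts
    if not label:
        label = Path(name).stem
    return SampledSpectrum(wl_arr, vals_arr, kind=kind, label=label)


def write_spectrum_csv(spectrum: SampledSpectrum,
                       target: Union[str, Path, _io.TextIOBase],
                       header: bool = True) -> None:
    """Write a spectrum as two-column CSV, lossless to float precision."""
    if isinstance(target, (str, Path)):
        handle, close = open(target, "w", newline=""), True
    else:
        handle, close = target, False
    try:
        writer = csv.writer(handle)
        if header:
            writer.writerow(["wavelength_nm", "value"])
        for w, v in zip(spectrum.wavelengths, spectrum.values):
            writer.writerow([repr(float(w)), repr(float(v))])
    finally:
        if close:
            handle.close()


_EXTINCTION_COLUMNS = ["wavelength_nm", "eps_hbo2", "eps_hb"]


def read_extinction_csv(source: Union[str, Path, _io.TextIOBase],
                        source_tag: str = "") -> ChromophoreTable:
    """Read a three-column extinction CSV (header required)."""
    frame = pd.read_csv(source)
    missing = [c for c in _EXTINCTION_COLUMNS if c not in frame.columns]
    if missing:
        raise InputError(f"extinction CSV missing columns {missing}; "
                         f"expected header {_EXTINCTION_COLUMNS}")
    frame = frame.sort_values("wavelength_nm")
    if not source_tag:
        source_tag = str(getattr(source, "name", source))
    return ChromophoreTable(frame["wavelength_nm"].to_numpy(),
                            frame["eps_hbo2"].to_numpy(),
                            frame["eps_hb"].to_numpy(),
                            source_tag=source_tag)


def write_extinction_csv(table: ChromophoreTable,
                         target: Union[str, Path, _io.TextIOBase]) -> None:
    pd.DataFrame({
        "wavelength_nm": table.wavelengths,
        "eps_hbo2": table.eps_hbo2,
        "eps_hb": table.eps_hb,
    }).to_csv(target, index=False)


# ---------------------------------------------------------------------------
# component registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegistryBand:
    """One emission band of a registry component."""

    channel: str
    lambda_dom: float | None = None
    lambda_dom_tol: float | None = None
    lambda_peak: float | None = None
    lambda_peak_tol: float | None = None
    fwhm: float | None = None
    measured_lambda_peak: float | None = None
    measured_fwhm: float | None = None

    def gaussian(self, prefer: str = "measured") -> GaussianBand:
        """Gaussian (center, FWHM) for modelling.

        ``prefer="measured"`` uses the spectrometer values;
        ``prefer="datasheet"`` uses the dominant wavelength when the
        datasheet reports both it and the peak (the dominant wavelength
        is the highlighted key feature), else the peak wavelength.
        Falls back to the other provenance when the preferred one is
        incomplete.
        """
        candidates = {"measured": (self.measured_lambda_peak,
                                   self.measured_fwhm),
                      "datasheet": (self.lambda_dom
                                    if self.lambda_dom is not None
                                    else self.lambda_peak,
                                    self.fwhm)}
        if prefer not in candidates:
            raise InputError(f"prefer must be 'measured' or 'datasheet', "
                             f"got {prefer!r}")
        order = [prefer] + [k for k in candidates if k != prefer]
        for key in order:
            center, fwhm = candidates[key]
            if center is not None and fwhm is not None:
                return GaussianBand(float(center), float(fwhm))
        raise InputError(f"band {self.channel!r} has no usable "
                         "(center, fwhm) in datasheet or measurement")


@dataclass(frozen=True)
class RegistryEntry:
    name: str
    manufacturer: str
    package: str
    bands: tuple[RegistryBand, ...]

    def band(self, channel: str) -> RegistryBand:
        for b in self.bands:
            if b.channel == channel:
                return b
        raise InputError(f"component {self.name!r} has no {channel!r} band")


class ComponentRegistry:
    """Named LED components with datasheet and measured optical parameters."""

    def __init__(self, entries: Iterable[RegistryEntry]):
        self._entries = {e.name: e for e in entries}

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    @property
    def names(self) -> list[str]:
        return list(self._entries)

    def get(self, name: str) -> RegistryEntry:
        try:
            return self._entries[name]
        except KeyError:
            raise InputError(
                f"unknown component {name!r}; known components: "
                f"{', '.join(self._entries)}") from None

    def light_source(self, name: str, channel: str | None = None,
                     prefer: str = "measured") -> LightSource:
        """Build a LightSource from a registry entry.

        ``channel`` selects the band of multi-band devices; single-band
        devices need no channel.
        """
        entry = self.get(name)
        if channel is None:
            if len(entry.bands) != 1:
                raise InputError(
                    f"component {name!r} has bands "
                    f"{[b.channel for b in entry.bands]}; specify one")
            band = entry.bands[0]
        else:
            band = entry.band(channel)
        label = name if channel is None else f"{name}/{channel}"
        return LightSource(name=label, primary_band=band.gaussian(prefer))


def _parse_band(raw: dict) -> RegistryBand:
    ds = raw.get("datasheet") or {}
    meas = raw.get("measured") or {}
    band = RegistryBand(
        channel=raw["channel"],
        lambda_dom=ds.get("lambda_dom"),
        lambda_dom_tol=ds.get("lambda_dom_tol"),
        lambda_peak=ds.get("lambda_peak"),
        lambda_peak_tol=ds.get("lambda_peak_tol"),
        fwhm=ds.get("fwhm"),
        measured_lambda_peak=meas.get("lambda_peak"),
        measured_fwhm=meas.get("fwhm"),
    )
    has_datasheet = ((band.lambda_dom is not None
                      or band.lambda_peak is not None)
                     and band.fwhm is not None)
    has_measured = (band.measured_lambda_peak is not None
                    and band.measured_fwhm is not None)
    if not (has_datasheet or has_measured):
        raise InputError(f"band {band.channel!r} lacks both datasheet and "
                         "measured (center, fwhm)")
    return band


def load_registry(config: Union[str, Path, dict, None] = None
                  ) -> ComponentRegistry:
    """Load a component registry from YAML (bundled fixture by default)."""
    if config is None:
        ref = importlib.resources.files("oxishift.data") / "components.yaml"
        raw = yaml.safe_load(ref.read_text())
    elif isinstance(config, dict):
        raw = config
    else:
        raw = yaml.safe_load(Path(config).read_text())
    entries = []
    for comp in raw["components"]:
        entries.append(RegistryEntry(
            name=comp["name"],
            manufacturer=str(comp.get("manufacturer", "")),
            package=str(comp.get("package", "")),
            bands=tuple(_parse_band(b) for b in comp["bands"]),
        ))
    return ComponentRegistry(entries)


# ---------------------------------------------------------------------------
# generic pair, synthetic detectors, standard pairings
# ---------------------------------------------------------------------------

def generic_pair_sources() -> tuple[LightSource, LightSource]:
    """The generic red/IR pair: 660 nm / 20 nm and 940 nm / 50 nm."""
    return (LightSource("generic-red", GaussianBand(660.0, 20.0)),
            LightSource("generic-ir", GaussianBand(940.0, 50.0)))


def _ramp_response(grid: np.ndarray) -> SampledSpectrum:
    vals = np.clip((grid - 350.0) / (1000.0 - 350.0), 0.0, None)
    vals = np.minimum(vals, 1.0)
    return SampledSpectrum(grid, vals, kind="sensitivity", label="ramp")


# Sampled stand-ins: a spectrally flat reference detector (the
# monochromatic-theory limit) and a quasi-linear rising ramp.
_SAMPLED_DETECTORS = {
    "flat": lambda grid: SampledSpectrum(
        grid, np.ones_like(grid), kind="sensitivity", label="flat"),
    "ramp": _ramp_response,
}

# Parametric stand-ins: broad NIR-peaked silicon response, a response
# symmetric about the midpoint of the two oximetry channels, and a
# narrower response peaking below the NIR channel.
_GAUSSIAN_DETECTORS = {
    "broad-si": GaussianBand(900.0, 470.0),
    "mid-symmetric": GaussianBand(800.0, 380.0),
    "vis-peaked": GaussianBand(780.0, 250.0),
}

#: Names of the bundled synthetic detector stand-ins.
SYNTHETIC_DETECTORS = ("flat", "broad-si", "mid-symmetric", "vis-peaked",
                       "ramp")


def synthetic_detector(name: str,
                       grid: np.ndarray | None = None) -> Photodetector:
    """A named synthetic photodetector stand-in.

    These are not measured device curves: they reproduce the
    qualitative response shapes that matter for pairing analysis
    (flat, broad NIR-peaked Gaussian, symmetric mid-peak, narrower
    visible-side peak, quasi-linear ramp) so sweeps and tests run
    without manufacturer data.  Supply measured curves as spectrum CSVs
    for device-specific results.
    """
    if name in _GAUSSIAN_DETECTORS:
        return Photodetector(name, _GAUSSIAN_DETECTORS[name])
    if name in _SAMPLED_DETECTORS:
        grid = default_grid(step=1.0) if grid is None else grid
        return Photodetector(name, _SAMPLED_DETECTORS[name](grid))
    raise InputError(f"unknown synthetic detector {name!r}; available: "
                     f"{', '.join(SYNTHETIC_DETECTORS)}")


def standard_pairs(registry: ComponentRegistry | None = None,
                   detector: Photodetector | None = None,
                   prefer: str = "measured") -> list[SourceDetectorPair]:
    """The study's red/IR pairings plus the generic pair.

    Pairs the typical red LED with the typical IR LED, each
    dual/triple-wavelength device with itself, and appends the generic
    660/20 + 940/50 pair.
    """
    registry = load_registry() if registry is None else registry
    detector = synthetic_detector("flat") if detector is None else detector
    ls = lambda name, ch=None: registry.light_source(name, ch, prefer=prefer)
    pairs = [
        SourceDetectorPair(ls("LHQ974"), ls("SFH4248"), detector,
                           label="typical"),
        SourceDetectorPair(ls("VSMD66694", "red"), ls("VSMD66694", "ir"),
                           detector, label="VSMD66694"),
        SourceDetectorPair(ls("SMT660/890", "red"), ls("SMT660/890", "ir"),
                           detector, label="SMT660/890"),
        SourceDetectorPair(ls("SFH7050", "red"), ls("SFH7050", "ir"),
                           detector, label="SFH7050"),
        SourceDetectorPair(ls("LED #1", "red"), ls("LED #1", "ir"),
                           detector, label="LED #1"),
        SourceDetectorPair(ls("LED #2", "red"), ls("LED #2", "ir"),
                           detector, label="LED #2"),
    ]
    red, ir = generic_pair_sources()
    pairs.append(SourceDetectorPair(red, ir, detector, label="generic"))
    return pairs
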