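"""Spectral data model and titration-series handling.

A :class:`Spectrum` is a sampled optical trace — steady-state emission,
UV–Vis absorbance, or a constant-offset synchronous scan — on a strictly
increasing wavelength grid.  A :class:`TitrationSeries` bundles one spectrum
per quencher concentration at a fixed temperature, which is the unit of data
every downstream analysis (Stern–Volmer, double-log binding, FRET) consumes.

File format: a plain CSV with a ``wavelength_nm`` column and one intensity
column per concentration, plus a JSON metadata sidecar carrying the design
(concentrations, units, temperature, excitation wavelength).  Concentrations
are always molar internally; file units must be declared in metadata.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumKind",
    "ShiftDirection",
    "ValidationError",
    "Spectrum",
    "Competitor",
    "TitrationSeries",
    "PeakShiftResult",
    "load_titration",
    "write_titration",
    "inner_filter_correct",
    "subtract_background",
    "intensity_at",
    "peak_position",
    "synchronous_shift",
]

_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9}


class ValidationError(ValueError):
    """Raised when input data violate the spectral data contract."""


class SpectrumKind(str, Enum):
    EMISSION = "emission"
    ABSORBANCE = "absorbance"
    SYNCHRONOUS = "synchronous"


class ShiftDirection(str, Enum):
    BLUESHIFT = "blueshift"
    REDSHIFT = "redshift"
    NONE = "none"


@dataclass(frozen=True)
class Spectrum:
    """A single optical trace on a wavelength grid.

    Parameters
    ----------
    kind
        Trace type: emission intensity, absorbance, or synchronous scan.
    wavelengths_nm
        Strictly increasing wavelength grid (nm), at least two points.
    values
        Intensity (arbitrary units) or absorbance (dimensionless); same
        length as the grid.  Negative absorbance values are clipped to zero
        with a warning (instrument baseline noise after subtraction).
    label
        Free-text identifier used in file headers and error messages.
    """

    kind: SpectrumKind
    wavelengths_nm: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        kind = SpectrumKind(self.kind)
        if wl.ndim != 1 or wl.size < 2:
            raise ValidationError("wavelengths_nm must be 1-D with >= 2 points")
        if vals.shape != wl.shape:
            raise ValidationError(
                f"values length {vals.size} != grid length {wl.size}"
            )
        if not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelengths_nm must be strictly increasing")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(vals))):
            raise ValidationError("wavelengths and values must be finite")
        if kind is SpectrumKind.ABSORBANCE and np.any(vals < 0):
            warnings.warn(
                f"negative absorbance clipped to 0 in spectrum {self.label!r}",
                stacklevel=2,
            )
            vals = np.clip(vals, 0.0, None)
        wl.setflags(write=False)
        vals.setflags(write=False)
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)

    def with_values(self, values: np.ndarray, **changes) -> "Spectrum":
        return replace(self, values=np.asarray(values, dtype=float), **changes)


@dataclass(frozen=True)
class Competitor:
    name: str
    conc_M: float


@dataclass(frozen=True)
class TitrationSeries:
    """Spectra indexed by quencher concentration at one temperature.

    The first concentration may be zero; that trace defines the unquenched
    reference intensity F0.  All spectra must share one wavelength grid and
    concentrations must be strictly increasing.
    """

    spectra: tuple[Spectrum, ...]
    quencher_concs_M: np.ndarray
    temperature_K: float
    excitation_nm: float
    fluorophore_conc_M: float
    competitor: Optional[Competitor] = None
    corrected: bool = False
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        spectra = tuple(self.spectra)
        concs = np.asarray(self.quencher_concs_M, dtype=float)
        if len(spectra) == 0:
            raise ValidationError("series must contain at least one spectrum")
        if concs.ndim != 1 or concs.size != len(spectra):
            raise ValidationError(
                f"{concs.size} concentrations for {len(spectra)} spectra"
            )
        if np.any(concs < 0):
            raise ValidationError("quencher concentrations must be non-negative")
        if concs.size > 1 and not np.all(np.diff(concs) > 0):
            raise ValidationError("quencher concentrations must be strictly increasing")
        if self.temperature_K <= 0:
            raise ValidationError("temperature_K must be positive")
        grid = spectra[0].wavelengths_nm
        for sp in spectra[1:]:
            if sp.wavelengths_nm.shape != grid.shape or not np.array_equal(
                sp.wavelengths_nm, grid
            ):
                raise ValidationError("all spectra must share one wavelength grid")
        concs.setflags(write=False)
        object.__setattr__(self, "spectra", spectra)
        object.__setattr__(self, "quencher_concs_M", concs)

    @property
    def wavelengths_nm(self) -> np.ndarray:
        return self.spectra[0].wavelengths_nm

    @property
    def has_reference(self) -> bool:
        """True if the series starts at zero quencher (an F0 trace)."""
        return self.quencher_concs_M[0] == 0.0

    def intensities_at(self, lambda_nm: float) -> np.ndarray:
        """Intensity at a fixed emission wavelength for every concentration."""
        return np.array([intensity_at(sp, lambda_nm) for sp in self.spectra])


@dataclass(frozen=True)
class PeakShiftResult:
    """Net emission-peak displacement over a synchronous titration.

    ``shift_nm`` is the peak wavelength at the highest quencher concentration
    minus the peak at zero quencher; negative values are blueshifts.
    """

    offset_nm: float
    peak_nm_by_conc: Mapping[float, float]
    shift_nm: float
    direction: ShiftDirection


# ---------------------------------------------------------------------------
# I/O


def _require(meta: Mapping[str, object], key: str) -> object:
    if key not in meta or meta[key] is None:
        raise ValidationError(f"metadata field {key!r} is missing")
    return meta[key]


def load_titration(
    spectra_csv_path: str | Path,
    metadata_path: str | Path,
    kind: SpectrumKind | str | None = None,
) -> TitrationSeries:
    """Read a titration series from a spectra CSV and its metadata sidecar.

    The CSV must contain a ``wavelength_nm`` column and one intensity column
    per concentration listed in the metadata (same order).  Metadata must
    declare ``units`` for the concentration fields; internal representation
    is molar.
    """
    meta = json.loads(Path(metadata_path).read_text())
    frame = pd.read_csv(spectra_csv_path, float_precision="round_trip")
    if "wavelength_nm" not in frame.columns:
        raise ValidationError("CSV is missing the 'wavelength_nm' column")
    units = str(_require(meta, "units"))
    if units not in _UNIT_TO_MOLAR:
        raise ValidationError(f"unknown concentration unit {units!r}")
    scale = _UNIT_TO_MOLAR[units]
    concs = np.asarray(_require(meta, "quencher_concs"), dtype=float) * scale
    intensity_cols = [c for c in frame.columns if c != "wavelength_nm"]
    if len(intensity_cols) != concs.size:
        raise ValidationError(
            f"CSV has {len(intensity_cols)} intensity columns but metadata "
            f"lists {concs.size} concentrations"
        )
    wl = frame["wavelength_nm"].to_numpy(dtype=float)
    if not np.all(np.diff(wl) > 0):
        raise ValidationError("wavelength_nm column must be strictly increasing")
    if kind is None:
        kind = meta.get("kind", SpectrumKind.EMISSION)
    kind = SpectrumKind(kind)
    spectra = tuple(
        Spectrum(kind, wl, frame[col].to_numpy(dtype=float), label=col)
        for col in intensity_cols
    )
    competitor = None
    if meta.get("competitor"):
        comp = meta["competitor"]
        competitor = Competitor(str(comp["name"]), float(comp["conc"]) * scale)
    return TitrationSeries(
        spectra=spectra,
        quencher_concs_M=concs,
        temperature_K=float(_require(meta, "temperature_K")),
        excitation_nm=float(_require(meta, "excitation_nm")),
        fluorophore_conc_M=float(_require(meta, "fluorophore_conc")) * scale,
        competitor=competitor,
        corrected=bool(meta.get("corrected", False)),
        meta={k: v for k, v in meta.items() if k.startswith("sim_")},
    )


def write_titration(
    series: TitrationSeries,
    spectra_csv_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write a series back to CSV + JSON, roundtrip-exact for finite inputs.

    Values are formatted with shortest-roundtrip ``repr`` so that
    ``load_titration(write_titration(s))`` reproduces the arrays bit for bit.
    Concentrations are written in molar with ``units: "M"``.
    """
    concs = series.quencher_concs_M
    header = ["wavelength_nm"] + [f"I_{float(c)!r}" for c in concs]
    lines = [",".join(header)]
    cols = [series.wavelengths_nm] + [sp.values for sp in series.spectra]
    for row in zip(*cols):
        lines.append(",".join(repr(float(v)) for v in row))
    Path(spectra_csv_path).write_text("\n".join(lines) + "\n")
    meta: dict[str, object] = {
        "temperature_K": series.temperature_K,
        "excitation_nm": series.excitation_nm,
        "fluorophore_conc": series.fluorophore_conc_M,
        "quencher_concs": [float(c) for c in concs],
        "units": "M",
        "competitor": (
            {"name": series.competitor.name, "conc": series.competitor.conc_M}
            if series.competitor
            else None
        ),
        "corrected": series.corrected,
        "kind": series.spectra[0].kind.value,
    }
    meta.update(series.meta)
    Path(metadata_path).write_text(json.dumps(meta, indent=1) + "\n")


# ---------------------------------------------------------------------------
# Corrections


def inner_filter_correct(
    series: TitrationSeries,
    absorbance_ex: Sequence[float],
    absorbance_em: Sequence[Spectrum],
) -> TitrationSeries:
    """Remove the inner-filter attenuation from a titration series.

    Each observed intensity is scaled by ``exp((A_ex + A_em(λ)) / 2)`` where
    ``A_ex`` is the sample absorbance at the excitation wavelength and
    ``A_em(λ)`` the absorbance at each emission wavelength, both per
    quencher concentration.  Since A >= 0 the factor is >= 1: correction
    never decreases an intensity.
    """
    if series.corrected:
        raise ValidationError("series is already inner-filter corrected")
    a_ex = np.asarray(absorbance_ex, dtype=float)
    if a_ex.size != len(series.spectra) or len(absorbance_em) != len(series.spectra):
        raise ValidationError("absorbance entries must align with concentrations")
    if np.any(a_ex < 0):
        raise ValidationError("negative excitation absorbance")
    corrected = []
    for sp, ax, abs_em in zip(series.spectra, a_ex, absorbance_em):
        a_em = np.interp(sp.wavelengths_nm, abs_em.wavelengths_nm, abs_em.values)
        if np.any(abs_em.values < 0):
            raise ValidationError("negative emission absorbance")
        factor = np.exp((ax + a_em) / 2.0)
        corrected.append(sp.with_values(sp.values * factor))
    return replace(series, spectra=tuple(corrected), corrected=True)


def subtract_background(sample: Spectrum, background: Spectrum) -> Spectrum:
    """Pointwise-subtract a background trace (e.g. ligand intrinsic
    absorbance) from a sample spectrum.

    The background is linearly interpolated onto the sample grid when the
    grids differ; extrapolation beyond the background's range is refused.
    """
    lo, hi = background.wavelengths_nm[0], background.wavelengths_nm[-1]
    if sample.wavelengths_nm[0] < lo or sample.wavelengths_nm[-1] > hi:
        raise ValidationError(
            "background does not cover the sample wavelength range "
            f"[{sample.wavelengths_nm[0]}, {sample.wavelengths_nm[-1]}] nm"
        )
    bg = np.interp(
        sample.wavelengths_nm, background.wavelengths_nm, background.values
    )
    return sample.with_values(sample.values - bg)


# ---------------------------------------------------------------------------
# Extraction


def intensity_at(spectrum: Spectrum, lambda_nm: float) -> float:
    """Intensity at a wavelength, linearly interpolated; exact on grid points."""
    wl = spectrum.wavelengths_nm
    if not (wl[0] <= lambda_nm <= wl[-1]):
        raise ValidationError(
            f"{lambda_nm} nm outside grid range [{wl[0]}, {wl[-1]}]"
        )
    return float(np.interp(lambda_nm, wl, spectrum.values))


def peak_position(spectrum: Spectrum, window_nm: tuple[float, float]) -> float:
    """Wavelength of the maximum within a window; ties break toward shorter λ."""
    lo, hi = window_nm
    mask = (spectrum.wavelengths_nm >= lo) & (spectrum.wavelengths_nm <= hi)
    if not np.any(mask):
        raise ValidationError(f"window [{lo}, {hi}] nm contains no grid points")
    wl = spectrum.wavelengths_nm[mask]
    vals = spectrum.values[mask]
    return float(wl[int(np.argmax(vals))])  # argmax takes the first maximum


def synchronous_shift(
    series: TitrationSeries,
    offset_nm: float,
    window_nm: Optional[tuple[float, float]] = None,
) -> PeakShiftResult:
    """Track the synchronous-scan band maximum across a titration.

    Reports the peak wavelength per concentration and the net shift between
    the highest concentration and the zero-quencher trace.  Shifts smaller
    than half a grid step are classified as ``none`` — sub-resolution
    displacements are not claims.
    """
    if len(series.spectra) < 2:
        raise ValidationError("need at least 2 concentrations to measure a shift")
    grid = series.wavelengths_nm
    if window_nm is None:
        window_nm = (float(grid[0]), float(grid[-1]))
    peaks = {
        float(c): peak_position(sp, window_nm)
        for c, sp in zip(series.quencher_concs_M, series.spectra)
    }
    concs = series.quencher_concs_M
    shift = peaks[float(concs[-1])] - peaks[float(concs[0])]
    step = float(np.median(np.diff(grid)))
    if abs(shift) < 0.5 * step:
        direction = ShiftDirection.NONE
    elif shift < 0:
        direction = ShiftDirection.BLUESHIFT
    else:
        direction = ShiftDirection.REDSHIFT
    return PeakShiftResult(
        offset_nm=float(offset_nm),
        peak_nm_by_conc=peaks,
        shift_nm=float(shift),
        direction=direction,
    )
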