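"""Data model and I/O for 2D peak lists and gridded 1H-13C HSQC spectra.

Peak lists are read from Sparky-style text ("assignment w1 w2 [value]") or
CSV; gridded spectra use a self-describing container: a one-line JSON header
(axis start/step/count, multiplicity-edited flag) followed by the intensity
matrix in whitespace-delimited text.  Axes are stored ascending in ppm
internally; reporting follows the NMR convention of decreasing ppm.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .exceptions import AxisOrderError, PeakListParseError, SpectrumFormatError

__all__ = [
    "CrossPeak",
    "PeakList",
    "GriddedSpectrum2D",
    "read_peaklist",
    "write_peaklist_csv",
    "read_gridded",
    "write_gridded",
    "estimate_noise",
    "heights_to_volumes",
]

_H1_WINDOW = (0.0, 13.0)  # plausible 1H ppm range; guards silent transposition

#: MAD -> sigma factor for samples truncated at the 90th percentile of |I|:
#: for N(0, s), the retained values are |I| < 1.645 s and their MAD is
#: Phi^-1(0.725) * s, so dividing by that quantile de-biases the estimate.
_TRUNCATED_MAD_TO_SIGMA = 1.0 / norm.ppf(0.725)


@dataclass
class CrossPeak:
    """One 2D cross-peak: position, signed volume (or height), multiplicity.

    ``sign`` is +1 (CH/CH3 in a multiplicity-edited spectrum), -1 (CH2) or 0
    when unknown; ``multiplicity_class`` mirrors it as CH-like/CH2-like.
    """

    c13: float
    h1: float
    volume: float
    sign: int = 0
    multiplicity_class: str = "unknown"  # CH-like | CH2-like | unknown
    fit_quality: float = math.nan
    assignment: str | None = None

    def __post_init__(self) -> None:
        if self.sign not in (-1, 0, 1):
            raise ValueError("sign must be -1, 0 or +1")


@dataclass
class PeakList:
    peaks: list[CrossPeak]
    provenance: str = ""
    multiplicity_edited: bool = False
    values_are: str = "volume"  # volume | height

    def __post_init__(self) -> None:
        self.sort()

    def sort(self) -> None:
        self.peaks.sort(key=lambda p: (p.c13, p.h1))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


@dataclass
class GriddedSpectrum2D:
    """Dense intensity matrix (rows = 13C, cols = 1H) with ppm axes."""

    intensity: np.ndarray
    c13_axis: np.ndarray
    h1_axis: np.ndarray
    multiplicity_edited: bool = False
    noise_sigma_estimate: float | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.c13_axis = np.asarray(self.c13_axis, dtype=float)
        self.h1_axis = np.asarray(self.h1_axis, dtype=float)
        if self.intensity.ndim != 2:
            raise SpectrumFormatError("intensity must be a 2-D matrix")
        if self.intensity.shape != (self.c13_axis.size, self.h1_axis.size):
            raise SpectrumFormatError(
                f"matrix shape {self.intensity.shape} does not match axes "
                f"({self.c13_axis.size}, {self.h1_axis.size})"
            )
        for name, ax in (("c13", self.c13_axis), ("h1", self.h1_axis)):
            if not np.all(np.isfinite(ax)):
                raise SpectrumFormatError(f"{name} axis contains non-finite ppm")
            if ax.size > 1 and not (np.all(np.diff(ax) > 0) or np.all(np.diff(ax) < 0)):
                raise SpectrumFormatError(f"{name} axis is not strictly monotone")
        # normalize to ascending internally
        if self.c13_axis.size > 1 and self.c13_axis[1] < self.c13_axis[0]:
            self.c13_axis = self.c13_axis[::-1].copy()
            self.intensity = self.intensity[::-1, :].copy()
        if self.h1_axis.size > 1 and self.h1_axis[1] < self.h1_axis[0]:
            self.h1_axis = self.h1_axis[::-1].copy()
            self.intensity = self.intensity[:, ::-1].copy()

    @property
    def c13_step(self) -> float:
        return float(self.c13_axis[1] - self.c13_axis[0]) if self.c13_axis.size > 1 else 0.0

    @property
    def h1_step(self) -> float:
        return float(self.h1_axis[1] - self.h1_axis[0]) if self.h1_axis.size > 1 else 0.0

    def nearest_index(self, c13: float, h1: float) -> tuple[int, int]:
        i = int(np.argmin(np.abs(self.c13_axis - c13)))
        j = int(np.argmin(np.abs(self.h1_axis - h1)))
        return i, j


def read_peaklist(
    path: str | Path,
    dialect: str = "sparky",
    *,
    h1_first: bool = False,
    multiplicity_edited: bool = False,
    values_are: str = "volume",
) -> PeakList:
    """Read a peak list from Sparky-style text or CSV.

    Sparky rows are ``assignment w1 w2 [height/volume]`` with w1 = 13C and
    w2 = 1H by default (heteronuclear convention); pass ``h1_first=True``
    when the axes are swapped.  Rows whose 1H value falls outside 0-13 ppm
    trigger an :class:`AxisOrderError` rather than a silent transposition.
    """
    path = Path(path)
    if dialect == "sparky":
        peaks = _read_sparky(path, h1_first=h1_first)
    elif dialect == "csv":
        peaks = _read_csv_peaks(path, h1_first=h1_first)
    else:
        raise PeakListParseError(f"unknown peak-list dialect {dialect!r}")
    for pk in peaks:
        if pk.sign and pk.multiplicity_class == "unknown":
            pk.multiplicity_class = "CH-like" if pk.sign > 0 else "CH2-like"
    return PeakList(
        peaks=peaks,
        provenance=str(path),
        multiplicity_edited=multiplicity_edited,
        values_are=values_are,
    )


def _read_sparky(path: Path, h1_first: bool) -> list[CrossPeak]:
    peaks: list[CrossPeak] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.lower().startswith("assignment"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise PeakListParseError(f"{path}:{lineno}: expected 'assignment w1 w2 [value]'")
            try:
                w1, w2 = float(fields[1]), float(fields[2])
                value = float(fields[3]) if len(fields) > 3 else 1.0
            except ValueError:
                raise PeakListParseError(f"{path}:{lineno}: non-numeric shift or value") from None
            c13, h1 = (w2, w1) if h1_first else (w1, w2)
            _check_axis_order(c13, h1, path, lineno)
            peaks.append(_make_peak(c13, h1, value, fields[0]))
    return peaks


def _read_csv_peaks(path: Path, h1_first: bool) -> list[CrossPeak]:
    import csv

    peaks: list[CrossPeak] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return peaks
        cols = [c.strip() for c in reader.fieldnames]
        if "c13_ppm" not in cols or "h1_ppm" not in cols:
            raise PeakListParseError(f"{path}: CSV header must contain c13_ppm,h1_ppm[,volume,sign]")
        for lineno, row in enumerate(reader, start=2):
            try:
                c13 = float(row["c13_ppm"])
                h1 = float(row["h1_ppm"])
                value = float(row.get("volume") or 1.0)
                sign = int(row["sign"]) if row.get("sign") not in (None, "") else 0
            except (TypeError, ValueError):
                raise PeakListParseError(f"{path}:{lineno}: malformed row") from None
            if h1_first:
                c13, h1 = h1, c13
            _check_axis_order(c13, h1, path, lineno)
            pk = _make_peak(c13, h1, value, row.get("assignment"))
            if sign:
                pk.sign = sign
            peaks.append(pk)
    return peaks


def _check_axis_order(c13: float, h1: float, path: Path, lineno: int) -> None:
    lo, hi = _H1_WINDOW
    if not lo <= h1 <= hi:
        raise AxisOrderError(
            f"{path}:{lineno}: 1H value {h1} outside the plausible {lo}-{hi} ppm "
            "window; the w1/w2 axis order is probably transposed (use h1_first)"
        )


def _make_peak(c13: float, h1: float, value: float, assignment: str | None) -> CrossPeak:
    sign = 1 if value > 0 else (-1 if value < 0 else 0)
    label = None if assignment in (None, "?", "") else assignment
    return CrossPeak(c13=c13, h1=h1, volume=value, sign=sign, assignment=label)


def write_peaklist_csv(peaklist: PeakList, path: str | Path) -> None:
    """Write a peak list as CSV (header: c13_ppm,h1_ppm,volume,sign)."""
    import csv

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["c13_ppm", "h1_ppm", "volume", "sign", "assignment"])
        for pk in peaklist:
            writer.writerow([repr(pk.c13), repr(pk.h1), repr(pk.volume), pk.sign, pk.assignment or ""])


def write_gridded(spectrum: GriddedSpectrum2D, path: str | Path) -> None:
    """Write a spectrum: JSON header line + whitespace-delimited matrix."""
    header = {
        "format": "amadori-grid-v1",
        "c13": {
            "start": float(spectrum.c13_axis[0]),
            "step": spectrum.c13_step,
            "count": int(spectrum.c13_axis.size),
        },
        "h1": {
            "start": float(spectrum.h1_axis[0]),
            "step": spectrum.h1_step,
            "count": int(spectrum.h1_axis.size),
        },
        "multiplicity_edited": spectrum.multiplicity_edited,
    }
    with Path(path).open("w") as fh:
        fh.write(json.dumps(header) + "\n")
        np.savetxt(fh, spectrum.intensity, fmt="%.17g")


def read_gridded(path: str | Path) -> GriddedSpectrum2D:
    """Read a spectrum written by :func:`write_gridded`.

    ``write_gridded`` followed by ``read_gridded`` is the identity up to
    floating-point text representation.
    """
    path = Path(path)
    with path.open() as fh:
        try:
            header = json.loads(fh.readline())
        except json.JSONDecodeError as exc:
            raise SpectrumFormatError(f"{path}: bad JSON header ({exc})") from None
        try:
            axes = {}
            for name in ("c13", "h1"):
                meta = header[name]
                start, step, count = float(meta["start"]), float(meta["step"]), int(meta["count"])
                if step == 0.0 or count < 1:
                    raise SpectrumFormatError(f"{path}: {name} axis step 0 or empty (non-monotone)")
                axes[name] = start + step * np.arange(count)
            edited = bool(header.get("multiplicity_edited", False))
        except (KeyError, TypeError, ValueError) as exc:
            if isinstance(exc, SpectrumFormatError):
                raise
            raise SpectrumFormatError(f"{path}: malformed header ({exc})") from None
        matrix = np.loadtxt(fh, ndmin=2)
    if matrix.shape != (axes["c13"].size, axes["h1"].size):
        raise SpectrumFormatError(
            f"{path}: matrix shape {matrix.shape} disagrees with header "
            f"({axes['c13'].size}, {axes['h1'].size})"
        )
    return GriddedSpectrum2D(
        intensity=matrix,
        c13_axis=axes["c13"],
        h1_axis=axes["h1"],
        multiplicity_edited=edited,
    )


def heights_to_volumes(peaklist: PeakList, sigma_c13: float, sigma_h1: float) -> PeakList:
    """Convert a height-valued peak list to volumes assuming common Gaussian
    lineshape widths (V = 2*pi*h*sigma_C*sigma_H)."""
    if peaklist.values_are != "height":
        return peaklist
    if sigma_c13 <= 0 or sigma_h1 <= 0:
        raise ValueError("lineshape widths must be positive")
    factor = 2.0 * math.pi * sigma_c13 * sigma_h1
    peaks = [replace(pk, volume=pk.volume * factor) for pk in peaklist]
    return PeakList(
        peaks=peaks,
        provenance=f"{peaklist.provenance}|heights_to_volumes",
        multiplicity_edited=peaklist.multiplicity_edited,
        values_are="volume",
    )


def estimate_noise(spectrum: GriddedSpectrum2D) -> float:
    """Robust noise sigma from signal-free regions of the matrix.

    Keeps intensities with |I| below the 90th percentile of |I| (discarding
    the strong-signal tail), then converts their median absolute deviation
    to a Gaussian sigma with the truncation-corrected factor.  Deterministic
    for fixed input; returns 0 for an all-zero matrix.
    """
    data = spectrum.intensity.ravel()
    if data.size == 0 or not np.any(data):
        return 0.0
    absi = np.abs(data)
    kept = data[absi <= np.quantile(absi, 0.90)]
    if kept.size == 0:
        return 0.0
    mad = np.median(np.abs(kept - np.median(kept)))
    return float(mad * _TRUNCATED_MAD_TO_SIGMA)


def attach_noise_estimate(spectrum: GriddedSpectrum2D) -> GriddedSpectrum2D:
    if spectrum.noise_sigma_estimate is None:
        spectrum.noise_sigma_estimate = estimate_noise(spectrum)
    return spectrum
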