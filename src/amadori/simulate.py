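"""Synthetic multiplicity-edited 1H-13C HSQC spectra with known ground truth.

Emulates the spectrum of a urea-denatured protein: every residue type
contributes random-coil cross-peaks scaled by its count in the sequence,
a Ser/Thr preceding a proline moves to its X-Pro anchor position, and a
glycated sample adds Amadori-product cross-peaks at the fingerprint
positions, split over the cyclic forms by their equilibrium populations
(0.70/0.13/0.13/0.04 by default).  Peaks are axis-aligned 2D Gaussians
(closed-form volume 2*pi*A*sigma_C*sigma_H), CH positive / CH2 negative
under multiplicity editing, on a grid covering the sugar/Ca region, plus
optional white noise.

Within one multiplicity class the per-proton volume scale is identical for
protein and Amadori peaks; between CH and CH2 it differs by a fixed
configurable factor, modelling the non-comparability of multiplicities
under a compromise INEPT delay.  A single integer seed drives the noise
stream only; positions and volumes are deterministic functions of the
configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .exceptions import SequenceError
from .library import (
    AMINO_ACIDS,
    Correlation,
    RandomCoilTable,
    ShiftLibrary,
    load_default_library,
    load_random_coil_table,
)
from .spectra import CrossPeak, GriddedSpectrum2D, PeakList

__all__ = [
    "GridSpec",
    "DecoyPeak",
    "SimulationConfig",
    "TruthPeak",
    "SyntheticGroundTruth",
    "simulate_hsqc",
    "truth_peaklist",
    "gaussian_volume",
]

#: Small demonstration sequence: contains an X-Pro anchor motif (S-P),
#: several lysines, and at least one of each preferred reference residue.
EXAMPLE_SEQUENCE = "MKSPGFRIGKTAWLKNDQEVHYCK"

DEFAULT_FORM_POPULATIONS = {
    "beta-pyranose": 0.70,
    "alpha-furanose": 0.13,
    "beta-furanose": 0.13,
    "alpha-pyranose": 0.04,
}


class GridSpec(BaseModel):
    """ppm ranges and steps of the simulated grid (ascending axes)."""

    model_config = ConfigDict(extra="forbid")

    c13_min: float = 40.0
    c13_max: float = 105.0
    c13_step: float = Field(default=0.05, gt=0)
    h1_min: float = 2.5
    h1_max: float = 5.5
    h1_step: float = Field(default=0.005, gt=0)

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        c13 = np.arange(self.c13_min, self.c13_max + 0.5 * self.c13_step, self.c13_step)
        h1 = np.arange(self.h1_min, self.h1_max + 0.5 * self.h1_step, self.h1_step)
        return c13, h1


class DecoyPeak(BaseModel):
    """An extraneous (e.g. glycan-like) peak injected for specificity tests."""

    model_config = ConfigDict(extra="forbid")

    c13: float
    h1: float
    volume: float = 1.0
    sign: int = 1


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    sequence: str
    glycations_per_molecule: float = Field(default=0.0, ge=0)
    form_populations: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_FORM_POPULATIONS)
    )
    sigma_c13: float = Field(default=0.05, gt=0)
    sigma_h1: float = Field(default=0.006, gt=0)
    noise_sigma: float = Field(default=0.0, ge=0)
    h1_exchange_attenuation: float = Field(default=0.8, ge=0, le=1)
    ch2_response_factor: float = Field(default=0.85, gt=0)
    volume_per_proton: float = Field(default=1.0, gt=0)
    multiplicity_edited: bool = True
    grid: GridSpec = Field(default_factory=GridSpec)
    decoy_peaks: list[DecoyPeak] = Field(default_factory=list)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = [i + 1 for i, aa in enumerate(self.sequence) if aa not in AMINO_ACIDS]
        if bad:
            raise SequenceError(
                f"unknown residue letter(s) at position(s) {bad} in sequence"
            )
        if any(p < 0 for p in self.form_populations.values()):
            raise ValueError("form populations must be non-negative")
        if sum(self.form_populations.values()) > 1.0 + 1e-9:
            raise ValueError("form populations must sum to at most 1")
        return self


@dataclass
class TruthPeak:
    """One generated cross-peak as the generator knows it."""

    c13: float
    h1: float
    volume: float  # unsigned
    sign: int
    multiplicity: str
    protons_in_signal: int
    owner: str  # residue type, Amadori form name, or "decoy"
    label: str
    overlapped: bool = False
    in_grid: bool = True

    @property
    def signed_volume(self) -> float:
        return self.sign * self.volume


@dataclass
class SyntheticGroundTruth:
    peaks: list[TruthPeak]
    glycations_per_molecule: float
    seed: int
    config: SimulationConfig = field(repr=False, default=None)

    def amadori_peaks(self) -> list[TruthPeak]:
        forms = set(DEFAULT_FORM_POPULATIONS) | set(self.config.form_populations if self.config else [])
        return [p for p in self.peaks if p.owner in forms]

    def protein_peaks(self) -> list[TruthPeak]:
        return [p for p in self.peaks if len(p.owner) == 1]


def gaussian_volume(amplitude: float, sigma_c13: float, sigma_h1: float) -> float:
    """Closed-form volume of an axis-aligned 2D Gaussian."""
    return 2.0 * math.pi * amplitude * sigma_c13 * sigma_h1


def _class_factor(multiplicity: str, config: SimulationConfig) -> float:
    return config.ch2_response_factor if multiplicity == "CH2" else 1.0


def _sign(multiplicity: str, edited: bool) -> int:
    if not edited:
        return 1
    return -1 if multiplicity == "CH2" else 1


def _residue_counts(sequence: str) -> tuple[dict[str, int], dict[str, int]]:
    """Counts per residue type, splitting Ser/Thr that precede a proline."""
    generic: dict[str, int] = {}
    anchored: dict[str, int] = {}
    n = len(sequence)
    for i, aa in enumerate(sequence):
        before_pro = i + 1 < n and sequence[i + 1] == "P"
        if before_pro and aa in ("S", "T"):
            anchored[aa] = anchored.get(aa, 0) + 1
        else:
            generic[aa] = generic.get(aa, 0) + 1
    return generic, anchored


def _build_truth(
    config: SimulationConfig,
    library: ShiftLibrary,
    coil_table: RandomCoilTable,
) -> list[TruthPeak]:
    scale = config.volume_per_proton
    edited = config.multiplicity_edited
    peaks: list[TruthPeak] = []

    def add(corr: Correlation, count: float, owner: str, attenuation: float = 1.0) -> None:
        if not corr.hsqc_visible or count <= 0:
            return
        vol = count * corr.protons_in_signal * scale * _class_factor(corr.multiplicity, config) * attenuation
        peaks.append(
            TruthPeak(
                c13=corr.c13_shift,
                h1=corr.h1_shift,
                volume=vol,
                sign=_sign(corr.multiplicity, edited),
                multiplicity=corr.multiplicity,
                protons_in_signal=corr.protons_in_signal,
                owner=owner,
                label=corr.label,
            )
        )

    generic, anchored = _residue_counts(config.sequence)
    totals: dict[str, int] = dict(generic)
    for aa, count in anchored.items():
        totals[aa] = totals.get(aa, 0) + count
    # side chains pool over all copies of a residue type; only the Ca-Ha of a
    # Ser/Thr preceding proline moves to the X-Pro anchor position
    for aa, total in sorted(totals.items()):
        n_anchor = anchored.get(aa, 0)
        for corr in coil_table.correlations_for(aa):
            if corr.label == "Ca-Ha":
                add(corr, total - n_anchor, owner=aa)
            else:
                add(corr, total, owner=aa)
        if n_anchor:
            anchor = coil_table.anchor(aa)
            if anchor is not None:
                add(anchor, n_anchor, owner=aa)

    G = config.glycations_per_molecule
    if G > 0:
        for form_name, population in config.form_populations.items():
            if population <= 0:
                continue
            for corr in library.hsqc_correlations(form_name):
                att = config.h1_exchange_attenuation if corr.exchange_affected else 1.0
                add(corr, G * population, owner=form_name, attenuation=att)

    for decoy in config.decoy_peaks:
        peaks.append(
            TruthPeak(
                c13=decoy.c13,
                h1=decoy.h1,
                volume=abs(decoy.volume),
                sign=decoy.sign,
                multiplicity="CH" if decoy.sign >= 0 else "CH2",
                protons_in_signal=1,
                owner="decoy",
                label="decoy",
            )
        )

    _mark_overlaps(peaks, config)
    return peaks


def _mark_overlaps(peaks: list[TruthPeak], config: SimulationConfig) -> None:
    # peaks from distinct owners closer than 0.5 sigma on both axes physically
    # superimpose on the grid; flag them so per-peak assertions can skip them
    for i, a in enumerate(peaks):
        for b in peaks[i + 1 :]:
            if a.owner == b.owner and a.label == b.label:
                continue
            if (
                abs(a.c13 - b.c13) < 0.5 * config.sigma_c13
                and abs(a.h1 - b.h1) < 0.5 * config.sigma_h1
            ):
                a.overlapped = b.overlapped = True


def simulate_hsqc(
    config: SimulationConfig,
    library: ShiftLibrary | None = None,
    coil_table: RandomCoilTable | None = None,
) -> tuple[GriddedSpectrum2D, SyntheticGroundTruth]:
    """Render the synthetic spectrum and return it with its ground truth.

    The intensity is the sum of signed 2D Gaussians (evaluated on a +/- 6
    sigma window around each apex) plus white Gaussian noise of standard
    deviation ``noise_sigma``.  Peaks whose apex falls outside the grid are
    recorded in the ground truth with ``in_grid=False`` and not rendered.
    """
    library = library or load_default_library()
    coil_table = coil_table or load_random_coil_table()
    truth = _build_truth(config, library, coil_table)

    c13_axis, h1_axis = config.grid.axes()
    intensity = np.zeros((c13_axis.size, h1_axis.size))
    sc, sh = config.sigma_c13, config.sigma_h1

    for peak in truth:
        if not (c13_axis[0] <= peak.c13 <= c13_axis[-1] and h1_axis[0] <= peak.h1 <= h1_axis[-1]):
            peak.in_grid = False
            continue
        amp = peak.signed_volume / (2.0 * math.pi * sc * sh)
        ic = np.searchsorted(c13_axis, [peak.c13 - 6 * sc, peak.c13 + 6 * sc])
        ih = np.searchsorted(h1_axis, [peak.h1 - 6 * sh, peak.h1 + 6 * sh])
        cs = c13_axis[ic[0] : ic[1] + 1]
        hs = h1_axis[ih[0] : ih[1] + 1]
        gc = np.exp(-0.5 * ((cs - peak.c13) / sc) ** 2)
        gh = np.exp(-0.5 * ((hs - peak.h1) / sh) ** 2)
        intensity[ic[0] : ic[0] + cs.size, ih[0] : ih[0] + hs.size] += amp * np.outer(gc, gh)

    if config.noise_sigma > 0:
        rng = np.random.default_rng(config.seed)
        intensity += rng.normal(0.0, config.noise_sigma, size=intensity.shape)

    spectrum = GriddedSpectrum2D(
        intensity=intensity,
        c13_axis=c13_axis,
        h1_axis=h1_axis,
        multiplicity_edited=config.multiplicity_edited,
    )
    ground_truth = SyntheticGroundTruth(
        peaks=truth,
        glycations_per_molecule=config.glycations_per_molecule,
        seed=config.seed,
        config=config,
    )
    return spectrum, ground_truth


def truth_peaklist(ground_truth: SyntheticGroundTruth) -> PeakList:
    """Noiseless peak list straight from the ground truth (all peaks,
    including any outside the grid window)."""
    config = ground_truth.config
    peaks = [
        CrossPeak(
            c13=p.c13,
            h1=p.h1,
            volume=p.signed_volume,
            sign=p.sign if config.multiplicity_edited else 0,
            multiplicity_class=(
                ("CH2-like" if p.multiplicity == "CH2" else "CH-like")
                if config.multiplicity_edited
                else "unknown"
            ),
            assignment=f"{p.owner}/{p.label}",
        )
        for p in ground_truth.peaks
    ]
    return PeakList(
        peaks=peaks,
        provenance=f"synthetic(seed={ground_truth.seed})",
        multiplicity_edited=config.multiplicity_edited,
    )
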