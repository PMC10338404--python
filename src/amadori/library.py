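"""Chemical-shift fingerprint of the Amadori product and random-coil anchors.

The Amadori product of glucose and a lysine side chain (fructoselysine)
equilibrates between cyclic forms; the dominant beta-pyranose form (~70%)
gives a characteristic set of 1H-13C HSQC cross-peaks that identifies
glucose-induced glycation in denatured proteins.  This module holds that
fingerprint, the random-coil cross-peak table of the 20 amino acids used to
predict the protein background and to pick quantification references, and
the additive conversions between chemical-shift reference standards.

All shifts are stored DSS-referenced; conversions from TMS or 1,4-dioxane
referencing are applied only at I/O boundaries.

Notes on the shipped values
---------------------------
The beta-pyranose column reproduces the glycated-BSA assignments (e.g.
C5-H5 at 71.8/4.00 ppm).  Running text elsewhere quotes C5 H5 as 4.01 and
C4 as 72.2; the tabulated BSA values (4.00, 72.1) are used and the 0.01/0.1
ppm discrepancy is absorbed by the matching tolerance.  C2 (98.2 ppm) bears
no proton and is kept with ``hsqc_visible=False``; the C1-H1 protons
exchange with solvent deuterium and C1-H1 is therefore flagged
``exchange_affected`` and excluded from quantification by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import pandas as pd

from .exceptions import ConfigurationError

__all__ = [
    "Correlation",
    "AmadoriForm",
    "ShiftLibrary",
    "RandomCoilTable",
    "load_default_library",
    "load_random_coil_table",
    "convert_reference",
    "REFERENCE_OFFSETS_TO_DSS",
    "AMINO_ACIDS",
    "DIAGNOSTIC_LABELS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: The three beta-pyranose markers that do not superimpose with protein or
#: glycan signals and therefore carry the presence call.
DIAGNOSTIC_LABELS = ("C5-H5", "C6-H6", "C6-H6'")

#: Additive 13C/1H offsets that bring a shift onto the DSS scale.
REFERENCE_OFFSETS_TO_DSS = {"DSS": 0.0, "TMS": 2.5, "dioxane": 1.8}


@dataclass(frozen=True)
class Correlation:
    """One 1H-13C cross-peak position with its bookkeeping.

    ``protons_in_signal`` counts protons contributing to this single signal:
    1 for a resolved H6 vs H6' pair, 2 for a degenerate CH2 giving one peak.
    """

    label: str
    c13_shift: float
    h1_shift: float | None
    multiplicity: str  # CH | CH2 | CH3 | Cq (no attached proton)
    protons_in_signal: int = 1
    diagnostic: bool = False
    exchange_affected: bool = False
    hsqc_visible: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.c13_shift <= 220.0:
            raise ConfigurationError(
                f"{self.label}: 13C shift {self.c13_shift} outside 0-220 ppm"
            )
        if self.hsqc_visible:
            if self.h1_shift is None:
                raise ConfigurationError(f"{self.label}: HSQC-visible but no 1H shift")
            if not 0.0 <= self.h1_shift <= 13.0:
                raise ConfigurationError(
                    f"{self.label}: 1H shift {self.h1_shift} outside 0-13 ppm"
                )
        if self.protons_in_signal not in (1, 2):
            raise ConfigurationError(
                f"{self.label}: protons_in_signal must be 1 or 2"
            )
        if self.diagnostic and self.multiplicity not in ("CH", "CH2"):
            raise ConfigurationError(
                f"{self.label}: diagnostic markers must be CH or CH2"
            )


@dataclass(frozen=True)
class AmadoriForm:
    """A named cyclic form of fructoselysine with its equilibrium population."""

    name: str
    correlations: tuple[Correlation, ...]
    population: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.population <= 1.0:
            raise ConfigurationError(f"{self.name}: population must be in [0, 1]")

    def correlation(self, label: str) -> Correlation:
        for corr in self.correlations:
            if corr.label == label:
                return corr
        raise KeyError(f"form {self.name!r} has no correlation {label!r}")


@dataclass(frozen=True)
class ShiftLibrary:
    """Fingerprint library: the Amadori forms and their cross-peaks."""

    forms: tuple[AmadoriForm, ...]
    reference_standard: str = "DSS"
    source_column: str = "BSA"

    def __post_init__(self) -> None:
        if self.reference_standard not in REFERENCE_OFFSETS_TO_DSS:
            raise ConfigurationError(
                f"unknown reference standard {self.reference_standard!r}"
            )
        total = sum(f.population for f in self.forms)
        if total > 1.0 + 1e-9:
            raise ConfigurationError(
                f"form populations sum to {total:.3f} > 1 (open forms may be "
                "omitted but populations cannot exceed unity)"
            )
        beta = self.form("beta-pyranose")
        if any(f.population > beta.population for f in self.forms):
            raise ConfigurationError("beta-pyranose must be the dominant form")

    def form(self, name: str) -> AmadoriForm:
        for f in self.forms:
            if f.name == name:
                return f
        raise KeyError(f"no Amadori form named {name!r}")

    @property
    def form_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.forms)

    def lookup(self, form: str, label: str) -> tuple[float, float | None]:
        """Return the (13C, 1H) position of one correlation."""
        corr = self.form(form).correlation(label)
        return corr.c13_shift, corr.h1_shift

    def diagnostic_correlations(self, form: str = "beta-pyranose") -> tuple[Correlation, ...]:
        return tuple(c for c in self.form(form).correlations if c.diagnostic)

    def hsqc_correlations(self, form: str) -> tuple[Correlation, ...]:
        return tuple(c for c in self.form(form).correlations if c.hsqc_visible)


@dataclass(frozen=True)
class RandomCoilTable:
    """Random-coil cross-peak positions per residue type.

    A Ser or Thr immediately preceding a proline has its Ca-Ha perturbed to a
    unique, isolated position (the "X-Pro anchor"); ``correlations_for`` with
    ``before_pro=True`` substitutes that anchor for the generic Ca-Ha.
    """

    entries: tuple[tuple[str, bool, Correlation], ...] = field(repr=False)

    def __post_init__(self) -> None:
        for aa in AMINO_ACIDS:
            if not any(
                res == aa and corr.label == "Ca-Ha" and not bp
                for res, bp, corr in self.entries
            ):
                raise ConfigurationError(f"random-coil table lacks Ca-Ha for {aa}")

    def correlations_for(self, residue: str, before_pro: bool = False) -> tuple[Correlation, ...]:
        generic = [c for res, bp, c in self.entries if res == residue and not bp]
        if before_pro:
            anchors = {
                c.label: c for res, bp, c in self.entries if res == residue and bp
            }
            if anchors:
                generic = [anchors.get(c.label, c) for c in generic]
        return tuple(generic)

    def anchor(self, residue: str) -> Correlation | None:
        """The X-Pro anchor Ca-Ha of ``residue``, if one is tabulated."""
        for res, bp, corr in self.entries:
            if res == residue and bp and corr.label == "Ca-Ha":
                return corr
        return None

    @property
    def residues(self) -> tuple[str, ...]:
        return tuple(sorted({res for res, _, _ in self.entries}))

    def all_positions(self) -> list[tuple[str, Correlation]]:
        return [(res, corr) for res, bp, corr in self.entries]


def convert_reference(shift: float, from_standard: str, to_standard: str) -> float:
    """Convert a 13C (or 1H) shift between DSS, TMS and 1,4-dioxane referencing.

    The standards differ by fixed additive offsets (TMS -> DSS: +2.5 ppm,
    dioxane -> DSS: +1.8 ppm); compositions and inverses follow.
    """
    try:
        to_dss = REFERENCE_OFFSETS_TO_DSS[from_standard]
        from_dss = REFERENCE_OFFSETS_TO_DSS[to_standard]
    except KeyError as exc:
        raise ConfigurationError(f"unknown reference standard {exc.args[0]!r}") from None
    return shift + to_dss - from_dss


def _read_data_csv(name: str) -> pd.DataFrame:
    with resources.files("amadori.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, comment="#")


def load_default_library() -> ShiftLibrary:
    """Load the DSS-referenced fructoselysine fingerprint (BSA column).

    The beta-pyranose correlations are the experimental values; the minor
    forms carry synthetic placeholder positions (see the data-file header)
    at the equilibrium populations 0.70/0.13/0.13/0.04.
    """
    df = _read_data_csv("amadori_shifts.csv")
    forms: list[AmadoriForm] = []
    for name, grp in df.groupby("form", sort=False):
        corrs = tuple(
            Correlation(
                label=row.label,
                c13_shift=float(row.c13_ppm),
                h1_shift=None if pd.isna(row.h1_ppm) else float(row.h1_ppm),
                multiplicity=row.multiplicity,
                protons_in_signal=int(row.protons_in_signal),
                diagnostic=_to_bool(row.diagnostic),
                exchange_affected=_to_bool(row.exchange_affected),
                hsqc_visible=_to_bool(row.hsqc_visible),
            )
            for row in grp.itertuples()
        )
        forms.append(AmadoriForm(name=name, correlations=corrs, population=float(grp.population.iloc[0])))
    return ShiftLibrary(forms=tuple(forms))


def load_random_coil_table() -> RandomCoilTable:
    """Load the shipped random-coil cross-peak table (DSS-referenced)."""
    df = _read_data_csv("random_coil_shifts.csv")
    entries = tuple(
        (
            row.residue,
            _to_bool(row.before_pro),
            Correlation(
                label=row.label,
                c13_shift=float(row.c13_ppm),
                h1_shift=float(row.h1_ppm),
                multiplicity=row.multiplicity,
                protons_in_signal=int(row.protons_in_signal),
            ),
        )
        for row in df.itertuples()
    )
    return RandomCoilTable(entries=entries)


def _to_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("true", "1", "yes")
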