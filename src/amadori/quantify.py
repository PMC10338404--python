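"""Stoichiometry of glycation from matched cross-peak volumes.

The procedure compares the volume of each usable Amadori marker with the
per-proton ("normalized") volume of an isolated protein reference signal of
the same multiplicity class: the reference integral is divided by the count
of that residue type in the sequence and, for a degenerate CH2 giving a
single signal, by 2.  CH markers are only ever compared with CH references
and CH2 markers with CH2 references, because HSQC response under a
compromise INEPT delay differs between multiplicities.

Because the measured beta-pyranose volume reflects only the beta-pyranose
fraction of the Amadori equilibrium (~70%), the per-marker estimate is by
default divided by the form population to express total glycations per
molecule; with the correction disabled the numbers are raw volume ratios
(the "7-9 times a normalized CH group" style of statement).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

from .detect import DEFAULT_TOL_C13, DEFAULT_TOL_H1, MatchReport
from .exceptions import QuantificationError, SequenceError
from .library import (
    AMINO_ACIDS,
    Correlation,
    RandomCoilTable,
    ShiftLibrary,
    load_default_library,
    load_random_coil_table,
)
from .spectra import PeakList

__all__ = [
    "ReferenceSignal",
    "MarkerEstimate",
    "QuantifyOptions",
    "QuantificationReport",
    "select_reference_signals",
    "measure_reference_volumes",
    "normalized_volume",
    "quantify_glycation",
    "relative_form_abundances",
]

#: Reference signals that are reliably isolated in denatured proteins and are
#: always proposed when the sequence contains them.  The two X-Pro anchors
#: are single-residue references; the others are residue-type sums.
_PREFERRED_REFERENCES = (
    # (key, residue, correlation label, before_pro)
    ("Ser-Pro Ca-Ha", "S", "Ca-Ha", True),
    ("Thr-Pro Ca-Ha", "T", "Ca-Ha", True),
    ("Gln Cg-Hg", "Q", "Cg-Hg", False),
    ("Glu Cg-Hg", "E", "Cg-Hg", False),
    ("Arg Cd-Hd", "R", "Cd-Hd", False),
    ("Phe Ca-Ha", "F", "Ca-Ha", False),
    ("Ile Cb-Hb", "I", "Cb-Hb", False),
    ("Gly Ca-Ha", "G", "Ca-Ha", False),
)


@dataclass
class ReferenceSignal:
    """An isolated protein signal used as the per-proton volume yardstick."""

    label: str
    c13: float
    h1: float
    multiplicity: str
    residue_count: int
    protons_in_signal: int
    isolation_score: float = math.inf
    volume: float | None = None  # measured, unsigned

    def normalized_volume(self) -> float:
        if self.volume is None:
            raise QuantificationError(f"reference {self.label} has no measured volume")
        return normalized_volume(self.volume, self.residue_count, self.protons_in_signal)

    @property
    def multiplicity_class(self) -> str:
        return "CH2-like" if self.multiplicity == "CH2" else "CH-like"


def normalized_volume(v_ref: float, n: int, p: int) -> float:
    """Per-proton volume: V / (n * p) with n residues and p protons per signal."""
    if v_ref <= 0:
        raise QuantificationError("reference volume must be positive")
    if n < 1:
        raise QuantificationError("residue count must be >= 1")
    if p not in (1, 2):
        raise QuantificationError("protons_in_signal must be 1 or 2")
    return v_ref / (n * p)


def _sequence_counts(sequence: str) -> tuple[dict[str, int], dict[str, int]]:
    generic: dict[str, int] = {}
    anchored: dict[str, int] = {}
    n = len(sequence)
    for i, aa in enumerate(sequence):
        if aa not in AMINO_ACIDS:
            raise SequenceError(f"unknown residue {aa!r} at position {i + 1}")
        before_pro = i + 1 < n and sequence[i + 1] == "P"
        if before_pro and aa in ("S", "T"):
            anchored[aa] = anchored.get(aa, 0) + 1
        else:
            generic[aa] = generic.get(aa, 0) + 1
    return generic, anchored


def _predicted_positions(
    sequence: str, coil_table: RandomCoilTable, library: ShiftLibrary
) -> list[tuple[float, float]]:
    generic, anchored = _sequence_counts(sequence)
    positions = []
    for aa in generic:
        for corr in coil_table.correlations_for(aa):
            positions.append((corr.c13_shift, corr.h1_shift))
    for aa in anchored:
        for corr in coil_table.correlations_for(aa, before_pro=True):
            positions.append((corr.c13_shift, corr.h1_shift))
    for fname in library.form_names:
        for corr in library.hsqc_correlations(fname):
            positions.append((corr.c13_shift, corr.h1_shift))
    return positions


def select_reference_signals(
    sequence: str,
    coil_table: RandomCoilTable | None = None,
    library: ShiftLibrary | None = None,
    tol_c13: float = DEFAULT_TOL_C13,
    tol_h1: float = DEFAULT_TOL_H1,
) -> list[ReferenceSignal]:
    """Propose reference signals for a sequence, ranked by isolation.

    The isolation score of a candidate is its distance, in tolerance-
    normalized ppm units, to the nearest other predicted protein or Amadori
    cross-peak; candidates closer than 1 normalized unit to a neighbour are
    dropped.  The preferred references (X-Pro anchors, Gln/Glu Cg, Arg Cd,
    Phe Ca, Ile Cb, Gly Ca) are always included when the sequence allows.
    """
    coil_table = coil_table or load_random_coil_table()
    library = library or load_default_library()
    generic, anchored = _sequence_counts(sequence)
    positions = _predicted_positions(sequence, coil_table, library)

    def isolation(c13: float, h1: float) -> float:
        best = math.inf
        for pc, ph in positions:
            d = math.hypot((pc - c13) / tol_c13, (ph - h1) / tol_h1)
            if 1e-9 < d < best:
                best = d
        return best

    refs: list[ReferenceSignal] = []
    seen: set[str] = set()
    for key, residue, label, before_pro in _PREFERRED_REFERENCES:
        count = anchored.get(residue, 0) if before_pro else generic.get(residue, 0)
        if count < 1:
            continue
        corrs = {
            c.label: c for c in coil_table.correlations_for(residue, before_pro=before_pro)
        }
        corr = corrs.get(label)
        if corr is None:
            continue
        refs.append(
            ReferenceSignal(
                label=key,
                c13=corr.c13_shift,
                h1=corr.h1_shift,
                multiplicity=corr.multiplicity,
                residue_count=count,
                protons_in_signal=corr.protons_in_signal,
                isolation_score=isolation(corr.c13_shift, corr.h1_shift),
            )
        )
        seen.add(f"{residue}/{label}/{before_pro}")

    # any other sufficiently isolated correlation of a present residue type
    for residue, count in generic.items():
        for corr in coil_table.correlations_for(residue):
            key = f"{residue}/{corr.label}/False"
            if key in seen:
                continue
            score = isolation(corr.c13_shift, corr.h1_shift)
            if score >= 1.0:
                refs.append(
                    ReferenceSignal(
                        label=f"{residue} {corr.label}",
                        c13=corr.c13_shift,
                        h1=corr.h1_shift,
                        multiplicity=corr.multiplicity,
                        residue_count=count,
                        protons_in_signal=corr.protons_in_signal,
                        isolation_score=score,
                    )
                )

    refs.sort(key=lambda r: (-r.isolation_score, r.label))
    for cls in ("CH-like", "CH2-like"):
        if not any(r.multiplicity_class == cls for r in refs):
            warnings.warn(
                f"sequence offers no usable {cls} reference signal; "
                f"quantification of {cls} markers is disabled",
                stacklevel=2,
            )
    return refs


def measure_reference_volumes(
    references: list[ReferenceSignal],
    peaklist: PeakList,
    tol_c13: float = DEFAULT_TOL_C13,
    tol_h1: float = DEFAULT_TOL_H1,
) -> list[ReferenceSignal]:
    """Fill reference volumes from the nearest peak inside the tolerance box."""
    measured = []
    for ref in references:
        best, best_d = None, math.inf
        for pk in peaklist:
            dc, dh = pk.c13 - ref.c13, pk.h1 - ref.h1
            if abs(dc) > tol_c13 or abs(dh) > tol_h1:
                continue
            d = math.hypot(dc / tol_c13, dh / tol_h1)
            if d < best_d:
                best, best_d = pk, d
        if best is not None and abs(best.volume) > 0:
            ref.volume = abs(best.volume)
            measured.append(ref)
    return measured


@dataclass
class MarkerEstimate:
    form: str
    label: str
    multiplicity: str
    volume: float
    reference_label: str
    reference_multiplicity: str
    glycations_per_molecule: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class QuantifyOptions:
    form_population_correction: bool = True
    include_exchange_affected: bool = False
    include_lys_epsilon: bool = False
    markers: list[str] | None = None  # restrict to these labels if given
    forms: tuple[str, ...] = ("beta-pyranose",)
    force: bool = False


@dataclass
class QuantificationReport:
    """Per-marker stoichiometry estimates and their aggregate."""

    marker_estimates: list[MarkerEstimate]
    glycations_per_molecule: float
    percent_molecules_glycated: float
    references_used: list[ReferenceSignal]
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (label, reason)
    warnings: list[str] = field(default_factory=list)

    @property
    def estimate_range(self) -> tuple[float, float]:
        values = [m.glycations_per_molecule for m in self.marker_estimates]
        return (min(values), max(values))

    def summary_phrase(self) -> str:
        g = self.glycations_per_molecule
        if g <= 1.0:
            return f"{100.0 * g:.0f}% of molecules glycated"
        return f"{g:.1f} glycations per molecule"

    def to_dict(self) -> dict:
        return {
            "glycations_per_molecule": self.glycations_per_molecule,
            "percent_molecules_glycated": self.percent_molecules_glycated,
            "marker_estimates": [m.to_dict() for m in self.marker_estimates],
            "references_used": [
                {
                    "label": r.label,
                    "multiplicity": r.multiplicity,
                    "residue_count": r.residue_count,
                    "protons_in_signal": r.protons_in_signal,
                    "volume": r.volume,
                    "normalized_volume": r.normalized_volume(),
                }
                for r in self.references_used
            ],
            "excluded_markers": [{"label": l, "reason": r} for l, r in self.excluded],
            "warnings": self.warnings,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def _pooled_reference(
    references: list[ReferenceSignal], cls: str
) -> tuple[float, str, list[ReferenceSignal]] | None:
    """Mean normalized (per-proton) volume over the measured references of a
    class.  Pooling several isolated signals reduces the noise carried by any
    single reference integral."""
    usable = [r for r in references if r.volume is not None and r.multiplicity_class == cls]
    if not usable:
        return None
    usable.sort(key=lambda r: -r.isolation_score)
    norm = sum(r.normalized_volume() for r in usable) / len(usable)
    label = usable[0].label
    if len(usable) > 1:
        label += f" (+{len(usable) - 1} pooled)"
    return norm, label, usable


def quantify_glycation(
    match_report: MatchReport,
    references: list[ReferenceSignal],
    options: QuantifyOptions | None = None,
) -> QuantificationReport:
    """Estimate glycations per molecule from matched marker volumes.

    Every matched, non-overlapping, non-exchange-affected marker i of the
    requested forms yields g_i = |V_i| / (p_i * normalized reference volume
    of the same multiplicity class [* form population if correcting]), where
    the normalized reference volume is the mean per-proton volume pooled
    over all measured references of that class; the aggregate is the
    unweighted mean of the g_i, reported both as glycations per molecule and
    as percent of molecules glycated.
    """
    options = options or QuantifyOptions()
    if not match_report.presence and not options.force:
        raise QuantificationError(
            "no glycation presence call in the match report; pass force=True "
            "to quantify anyway"
        )

    overlap_labels = {
        note.split(" also ")[0].rsplit("/", 1)[-1] for note in match_report.notes
    }
    estimates: list[MarkerEstimate] = []
    excluded: list[tuple[str, str]] = []
    warns: list[str] = []
    refs_used: dict[str, ReferenceSignal] = {}
    missing_classes: set[str] = set()

    for (form, label), m in sorted(match_report.matches.items()):
        if form not in options.forms:
            continue
        corr = m.correlation
        if not m.matched:
            excluded.append((f"{form}/{label}", "not matched"))
            continue
        if options.markers is not None and label not in options.markers:
            excluded.append((f"{form}/{label}", "not in requested marker set"))
            continue
        if corr.exchange_affected and not options.include_exchange_affected:
            excluded.append((f"{form}/{label}", "exchange-affected (solvent deuterium)"))
            continue
        if label.startswith("Lys") and not options.include_lys_epsilon:
            excluded.append((f"{form}/{label}", "congested Lys epsilon region"))
            continue
        if label in overlap_labels:
            excluded.append((f"{form}/{label}", "ambiguous overlap with another library entry"))
            continue
        cls = "CH2-like" if corr.multiplicity == "CH2" else "CH-like"
        pooled = _pooled_reference(references, cls)
        if pooled is None:
            missing_classes.add(cls)
            excluded.append((f"{form}/{label}", f"no {cls} reference available"))
            continue
        norm_ref, ref_label, pool = pooled
        pop = m.form_population if options.form_population_correction else 1.0
        if pop <= 0:
            excluded.append((f"{form}/{label}", "zero form population"))
            continue
        g = abs(m.peak.volume) / (corr.protons_in_signal * norm_ref * pop)
        estimates.append(
            MarkerEstimate(
                form=form,
                label=label,
                multiplicity=corr.multiplicity,
                volume=abs(m.peak.volume),
                reference_label=ref_label,
                reference_multiplicity="CH2" if cls == "CH2-like" else "CH",
                glycations_per_molecule=g,
            )
        )
        for r in pool:
            refs_used[r.label] = r

    if not estimates:
        detail = (
            f"missing reference class(es): {sorted(missing_classes)}"
            if missing_classes
            else "no usable markers"
        )
        raise QuantificationError(f"cannot quantify glycation: {detail}")
    if missing_classes:
        warns.append(
            f"markers of class {sorted(missing_classes)} skipped: no reference of that class"
        )

    g_mean = sum(e.glycations_per_molecule for e in estimates) / len(estimates)
    return QuantificationReport(
        marker_estimates=estimates,
        glycations_per_molecule=g_mean,
        percent_molecules_glycated=100.0 * g_mean,
        references_used=list(refs_used.values()),
        excluded=excluded,
        warnings=warns,
    )


def relative_form_abundances(
    match_report: MatchReport,
    multiplicity: str = "CH",
) -> dict[str, float]:
    """Relative equilibrium abundances of the matched Amadori forms.

    Uses the mean per-proton volume of each form's matched correlations of
    one multiplicity class (CH by default, so volumes are comparable), then
    normalizes to sum to 1 over the matched forms.  With a single matched
    form the result is {form: 1.0} and a dominance-only warning is emitted.
    """
    means: dict[str, list[float]] = {}
    for (form, _), m in match_report.matches.items():
        if not m.matched or m.correlation.multiplicity != multiplicity:
            continue
        per_proton = abs(m.peak.volume) / m.correlation.protons_in_signal
        means.setdefault(form, []).append(per_proton)
    if not means:
        raise QuantificationError(
            f"no matched {multiplicity} correlations; cannot estimate form abundances"
        )
    mean_volumes = {form: sum(v) / len(v) for form, v in means.items()}
    if len(mean_volumes) == 1:
        only = next(iter(mean_volumes))
        warnings.warn(
            f"only {only} matched; reporting dominance without relative abundances",
            stacklevel=2,
        )
        return {only: 1.0}
    total = sum(mean_volumes.values())
    return {form: v / total for form, v in mean_volumes.items()}
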