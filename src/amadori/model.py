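"""Model/Results surface tying the pipeline together.

``GlycationHSQC`` is built from a spectrum (or peak list) and the protein
sequence; ``fit()`` runs pick -> Gaussian fit -> fingerprint match ->
reference selection -> stoichiometry and returns a ``GlycationResults``
carrying the presence call, per-marker estimates, form abundances and a
``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .detect import (
    DEFAULT_TOL_C13,
    DEFAULT_TOL_H1,
    MatchReport,
    detect_glycation,
)
from .exceptions import QuantificationError
from .library import RandomCoilTable, ShiftLibrary, load_default_library, load_random_coil_table
from .quantify import (
    QuantificationReport,
    QuantifyOptions,
    measure_reference_volumes,
    quantify_glycation,
    relative_form_abundances,
    select_reference_signals,
)
from .spectra import GriddedSpectrum2D, PeakList

__all__ = ["GlycationHSQC", "GlycationResults", "read_sequence"]


def read_sequence(source: str | Path) -> str:
    """Return a one-letter sequence from a FASTA file or a literal string."""
    path = Path(source)
    if path.exists():
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"{path}: no FASTA records")
        return str(records[0].seq).upper()
    return str(source).strip().upper()


class GlycationHSQC:
    """Glycation analysis of one denatured-protein HSQC measurement.

    Parameters
    ----------
    data:
        A :class:`GriddedSpectrum2D` (pick/fit/match path) or a volume-valued
        :class:`PeakList` (direct matching path).
    sequence:
        One-letter protein sequence; drives reference-signal selection.
    library, coil_table:
        Fingerprint and random-coil tables; defaults are the shipped ones.
    """

    def __init__(
        self,
        data: GriddedSpectrum2D | PeakList,
        sequence: str,
        library: ShiftLibrary | None = None,
        coil_table: RandomCoilTable | None = None,
        tol_c13: float = DEFAULT_TOL_C13,
        tol_h1: float = DEFAULT_TOL_H1,
        threshold_multiplier: float = 5.0,
        init_sigma_c13: float = 0.05,
        init_sigma_h1: float = 0.006,
    ) -> None:
        self.data = data
        self.sequence = read_sequence(sequence)
        self.library = library or load_default_library()
        self.coil_table = coil_table or load_random_coil_table()
        self.tol_c13 = tol_c13
        self.tol_h1 = tol_h1
        self.threshold_multiplier = threshold_multiplier
        self.init_sigma_c13 = init_sigma_c13
        self.init_sigma_h1 = init_sigma_h1

    @classmethod
    def from_files(cls, spectrum_path: str | Path, sequence: str | Path, **kwargs) -> "GlycationHSQC":
        from .spectra import read_gridded

        return cls(read_gridded(spectrum_path), read_sequence(sequence), **kwargs)

    def fit(self, quantify_options: QuantifyOptions | None = None) -> "GlycationResults":
        options = quantify_options or QuantifyOptions()
        if isinstance(self.data, PeakList) and self.data.values_are == "height":
            # heights are not volumes; integrals require lineshape widths
            raise QuantificationError(
                "peak list carries heights, not volumes; convert with "
                "spectra.heights_to_volumes using known lineshape widths"
            )
        report, fitted = detect_glycation(
            self.data,
            self.library,
            tol_c13=self.tol_c13,
            tol_h1=self.tol_h1,
            threshold_multiplier=self.threshold_multiplier,
            init_sigma_c13=self.init_sigma_c13,
            init_sigma_h1=self.init_sigma_h1,
        )
        references = select_reference_signals(
            self.sequence, self.coil_table, self.library, self.tol_c13, self.tol_h1
        )
        measured = measure_reference_volumes(references, fitted, self.tol_c13, self.tol_h1)

        quantification = None
        quant_error = None
        if report.presence or options.force:
            try:
                quantification = quantify_glycation(report, measured, options)
            except QuantificationError as exc:
                quant_error = str(exc)

        abundances: dict[str, float] = {}
        if report.presence:
            import warnings as _warnings

            try:
                with _warnings.catch_warnings():
                    # a single matched form is the common case; dominance-only
                    # output is already visible in the result itself
                    _warnings.simplefilter("ignore", UserWarning)
                    abundances = relative_form_abundances(report)
            except QuantificationError:
                abundances = {}

        return GlycationResults(
            model=self,
            match_report=report,
            fitted_peaks=fitted,
            references=measured,
            quantification=quantification,
            quantification_error=quant_error,
            form_abundances=abundances,
        )


@dataclass
class GlycationResults:
    """Fitted results: presence call, stoichiometry, diagnostics."""

    model: GlycationHSQC = field(repr=False)
    match_report: MatchReport
    fitted_peaks: PeakList = field(repr=False)
    references: list = field(repr=False)
    quantification: QuantificationReport | None = None
    quantification_error: str | None = None
    form_abundances: dict[str, float] = field(default_factory=dict)

    @property
    def presence(self) -> bool:
        return self.match_report.presence

    @property
    def glycations_per_molecule(self) -> float | None:
        return None if self.quantification is None else self.quantification.glycations_per_molecule

    @property
    def percent_molecules_glycated(self) -> float | None:
        return None if self.quantification is None else self.quantification.percent_molecules_glycated

    def summary(self) -> str:
        lines = []
        lines.append("Glycation HSQC analysis")
        lines.append("=" * 64)
        lines.append(f"Sequence length:        {len(self.model.sequence)} residues")
        lines.append(f"Peaks analysed:         {len(self.fitted_peaks)}")
        lines.append(
            f"Matching tolerance:     +/-{self.match_report.tol_c13} ppm (13C), "
            f"+/-{self.match_report.tol_h1} ppm (1H)"
        )
        lines.append(f"Diagnostic markers hit: {self.match_report.diagnostic_hits}/3")
        lines.append(f"Glycation present:      {'yes' if self.presence else 'no'}")
        lines.append("")
        lines.append(f"{'correlation':<26}{'expected':>16}{'found':>18}{'volume':>12}")
        lines.append("-" * 72)
        for (form, label), m in sorted(self.match_report.matches.items()):
            if form != "beta-pyranose":
                continue
            exp = f"{m.correlation.c13_shift:.1f}/{m.correlation.h1_shift:.2f}"
            if m.matched:
                found = f"{m.peak.c13:.1f}/{m.peak.h1:.2f}"
                vol = f"{abs(m.peak.volume):.3g}"
            else:
                found, vol = "-", "-"
            tag = " *" if m.correlation.diagnostic else ""
            lines.append(f"{form + '/' + label + tag:<26}{exp:>16}{found:>18}{vol:>12}")
        lines.append("(* diagnostic marker)")
        if self.quantification is not None:
            q = self.quantification
            lines.append("")
            lines.append("Stoichiometry")
            lines.append("-" * 72)
            for est in q.marker_estimates:
                lines.append(
                    f"  {est.label:<10} ({est.multiplicity:<3} vs {est.reference_label}): "
                    f"g = {est.glycations_per_molecule:.2f}"
                )
            lo, hi = q.estimate_range
            lines.append(f"  per-marker range: {lo:.2f} - {hi:.2f}")
            lines.append(f"  aggregate: {q.summary_phrase()}")
        elif self.quantification_error:
            lines.append("")
            lines.append(f"Quantification unavailable: {self.quantification_error}")
        if self.form_abundances:
            lines.append("")
            lines.append("Relative form abundances")
            lines.append("-" * 72)
            for form, frac in sorted(self.form_abundances.items(), key=lambda kv: -kv[1]):
                lines.append(f"  {form:<16} {100 * frac:5.1f}%")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "presence": self.presence,
            "match_report": self.match_report.to_dict(),
            "quantification": None if self.quantification is None else self.quantification.to_dict(),
            "quantification_error": self.quantification_error,
            "form_abundances": self.form_abundances,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)
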