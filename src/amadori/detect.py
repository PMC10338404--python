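"""Peak picking, 2D Gaussian fitting/integration, and fingerprint matching.

The presence call for glucose-induced glycation requires all three
diagnostic beta-pyranose markers (C5-H5, C6-H6, C6-H6') to match, with
multiplicity-consistent sign where the spectrum is multiplicity-edited;
C3-H3 and C4-H4 matches corroborate but are never required, since other
signals can partially superimpose with them.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy import ndimage

from .exceptions import ConfigurationError
from .library import Correlation, ShiftLibrary, load_default_library
from .spectra import (
    CrossPeak,
    GriddedSpectrum2D,
    PeakList,
    estimate_noise,
)

__all__ = [
    "MatchedCorrelation",
    "MatchReport",
    "pick_peaks",
    "fit_and_integrate",
    "match_amadori",
    "detect_glycation",
    "DEFAULT_TOL_C13",
    "DEFAULT_TOL_H1",
]

logger = logging.getLogger(__name__)

#: Default matching tolerances, sized to span the inter-protein spread of the
#: fingerprint positions (13C values of one correlation vary by a few tenths
#: of a ppm between proteins) with margin.
DEFAULT_TOL_C13 = 0.4
DEFAULT_TOL_H1 = 0.04


def pick_peaks(
    spectrum: GriddedSpectrum2D,
    threshold_multiplier: float = 5.0,
    noise_sigma: float | None = None,
    min_sep_c13: float | None = None,
    min_sep_h1: float | None = None,
) -> PeakList:
    """Pick local extrema of |I| above ``threshold_multiplier`` x noise sigma.

    A point is picked when it is the strict maximum of |I| over its 3x3
    neighbourhood; the sign of the extremum is recorded when the spectrum is
    multiplicity-edited.  Returned values are apex heights, not volumes.
    ``min_sep_*`` (ppm) suppress the weaker of two picks closer than that in
    both axes — noise riding on a broad peak otherwise splits it into
    several picks; pass roughly the expected linewidth.  The default keeps
    everything beyond one grid step.
    """
    if noise_sigma is None:
        noise_sigma = (
            spectrum.noise_sigma_estimate
            if spectrum.noise_sigma_estimate is not None
            else estimate_noise(spectrum)
        )
    absi = np.abs(spectrum.intensity)
    if absi.size == 0 or absi.max() == 0:
        return PeakList(peaks=[], multiplicity_edited=spectrum.multiplicity_edited, values_are="height")
    # small absolute floor guards against numerically-flat regions of a
    # noiseless spectrum producing spurious extrema
    threshold = max(threshold_multiplier * noise_sigma, 1e-9 * absi.max())
    local_max = absi == ndimage.maximum_filter(absi, size=3, mode="constant")
    candidates = np.argwhere(local_max & (absi > threshold))
    # minimum separation in grid steps; at least one step either way, which
    # also removes duplicate picks when an apex falls between samples
    sep_i = max(1, int(round((min_sep_c13 or 0.0) / spectrum.c13_step)) if spectrum.c13_step else 1)
    sep_j = max(1, int(round((min_sep_h1 or 0.0) / spectrum.h1_step)) if spectrum.h1_step else 1)
    order = np.argsort(-absi[candidates[:, 0], candidates[:, 1]]) if candidates.size else []
    accepted: list[tuple[int, int]] = []
    for idx in order:
        i, j = map(int, candidates[idx])
        if any(abs(i - a) <= sep_i and abs(j - b) <= sep_j for a, b in accepted):
            continue
        accepted.append((i, j))
    peaks = []
    for i, j in accepted:
        value = float(spectrum.intensity[i, j])
        sign = (1 if value > 0 else -1) if spectrum.multiplicity_edited else 0
        peaks.append(
            CrossPeak(
                c13=float(spectrum.c13_axis[i]),
                h1=float(spectrum.h1_axis[j]),
                volume=value,
                sign=sign,
                multiplicity_class=(
                    ("CH-like" if value > 0 else "CH2-like")
                    if spectrum.multiplicity_edited
                    else "unknown"
                ),
            )
        )
    out = PeakList(peaks=peaks, multiplicity_edited=spectrum.multiplicity_edited, values_are="height")
    out.provenance = f"pick_peaks(k={threshold_multiplier})"
    return out


def _window_bounds(
    spectrum: GriddedSpectrum2D, peak: CrossPeak, half_c: float, half_h: float
) -> tuple[int, int, int, int]:
    i0 = int(np.searchsorted(spectrum.c13_axis, peak.c13 - half_c))
    i1 = int(np.searchsorted(spectrum.c13_axis, peak.c13 + half_c, side="right"))
    j0 = int(np.searchsorted(spectrum.h1_axis, peak.h1 - half_h))
    j1 = int(np.searchsorted(spectrum.h1_axis, peak.h1 + half_h, side="right"))
    return i0, max(i1, i0 + 1), j0, max(j1, j0 + 1)


def _group_windows(boxes: list[tuple[int, int, int, int]]) -> list[list[int]]:
    """Connected components of window rectangles that intersect in both axes."""
    n = len(boxes)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(n):
        for b in range(a + 1, n):
            ia0, ia1, ja0, ja1 = boxes[a]
            ib0, ib1, jb0, jb1 = boxes[b]
            if ia0 < ib1 and ib0 < ia1 and ja0 < jb1 and jb0 < ja1:
                parent[find(a)] = find(b)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def fit_and_integrate(
    spectrum: GriddedSpectrum2D,
    peaklist: PeakList,
    init_sigma_c13: float = 0.05,
    init_sigma_h1: float = 0.006,
    window_sigmas: float = 4.0,
) -> PeakList:
    """Refine picked peaks by least-squares 2D Gaussian fits; return volumes.

    Each peak is fit as an axis-aligned 2D Gaussian plus a constant local
    baseline on a window of +/- ``window_sigmas`` initial widths; peaks whose
    windows overlap are fit jointly.  Volume = 2*pi*A*sigma_C*sigma_H.  A
    non-convergent fit falls back to direct window summation and is flagged
    with infinite ``fit_quality``.
    """
    half_c = window_sigmas * init_sigma_c13
    half_h = window_sigmas * init_sigma_h1
    boxes = [_window_bounds(spectrum, p, half_c, half_h) for p in peaklist]
    refined: list[CrossPeak] = []
    for group in _group_windows(boxes):
        refined.extend(
            _fit_group(
                spectrum,
                [peaklist.peaks[i] for i in group],
                [boxes[i] for i in group],
                init_sigma_c13,
                init_sigma_h1,
            )
        )
    out = PeakList(
        peaks=refined,
        provenance=f"{peaklist.provenance}|fit",
        multiplicity_edited=peaklist.multiplicity_edited,
        values_are="volume",
    )
    return out


def _fit_group(
    spectrum: GriddedSpectrum2D,
    peaks: list[CrossPeak],
    boxes: list[tuple[int, int, int, int]],
    s_c: float,
    s_h: float,
) -> list[CrossPeak]:
    i0 = min(b[0] for b in boxes)
    i1 = max(b[1] for b in boxes)
    j0 = min(b[2] for b in boxes)
    j1 = max(b[3] for b in boxes)
    cs = spectrum.c13_axis[i0:i1]
    hs = spectrum.h1_axis[j0:j1]
    data = spectrum.intensity[i0:i1, j0:j1]
    cgrid, hgrid = np.meshgrid(cs, hs, indexing="ij")

    baseline0 = float(np.median(data))
    params = lmfit.Parameters()
    params.add("baseline", value=baseline0)
    span_c = max(cs[-1] - cs[0], s_c)
    span_h = max(hs[-1] - hs[0], s_h)
    for k, pk in enumerate(peaks):
        params.add(f"amp{k}", value=float(pk.volume) - baseline0)
        params.add(f"c{k}", value=pk.c13, min=pk.c13 - 0.5 * span_c, max=pk.c13 + 0.5 * span_c)
        params.add(f"h{k}", value=pk.h1, min=pk.h1 - 0.5 * span_h, max=pk.h1 + 0.5 * span_h)
        params.add(f"sc{k}", value=s_c, min=0.2 * s_c, max=5.0 * s_c)
        params.add(f"sh{k}", value=s_h, min=0.2 * s_h, max=5.0 * s_h)

    def model(p: lmfit.Parameters) -> np.ndarray:
        out = np.full_like(data, p["baseline"].value)
        for k in range(len(peaks)):
            out += p[f"amp{k}"].value * np.exp(
                -0.5 * ((cgrid - p[f"c{k}"].value) / p[f"sc{k}"].value) ** 2
                - 0.5 * ((hgrid - p[f"h{k}"].value) / p[f"sh{k}"].value) ** 2
            )
        return out

    scale = float(np.max(np.abs(data))) or 1.0
    try:
        result = lmfit.minimize(lambda p: (model(p) - data).ravel(), params, method="leastsq")
        ok = result.success
    except Exception:  # numerical failure inside the optimizer
        result = None
        ok = False

    refined = []
    if ok:
        p = result.params
        quality = float(np.sqrt(np.mean(result.residual**2)) / scale)
        for k, pk in enumerate(peaks):
            amp = p[f"amp{k}"].value
            vol = 2.0 * math.pi * amp * p[f"sc{k}"].value * p[f"sh{k}"].value
            refined.append(
                CrossPeak(
                    c13=float(p[f"c{k}"].value),
                    h1=float(p[f"h{k}"].value),
                    volume=float(vol),
                    sign=pk.sign,
                    multiplicity_class=pk.multiplicity_class,
                    fit_quality=quality,
                    assignment=pk.assignment,
                )
            )
    else:
        logger.warning(
            "Gaussian fit did not converge for %d peak(s); falling back to window summation",
            len(peaks),
        )
        dc = spectrum.c13_step or 1.0
        dh = spectrum.h1_step or 1.0
        for pk, (bi0, bi1, bj0, bj1) in zip(peaks, boxes):
            window = spectrum.intensity[bi0:bi1, bj0:bj1]
            vol = float((window - baseline0).sum() * dc * dh)
            refined.append(
                CrossPeak(
                    c13=pk.c13,
                    h1=pk.h1,
                    volume=vol,
                    sign=pk.sign,
                    multiplicity_class=pk.multiplicity_class,
                    fit_quality=math.inf,
                    assignment=pk.assignment,
                )
            )
    return refined


@dataclass
class MatchedCorrelation:
    """One library correlation with its matched peak (if any)."""

    form: str
    correlation: Correlation
    peak: CrossPeak | None = None
    delta_c13: float | None = None
    delta_h1: float | None = None
    normalized_distance: float | None = None
    sign_consistent: bool | None = None
    form_population: float = 0.0

    @property
    def matched(self) -> bool:
        return self.peak is not None

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "label": self.correlation.label,
            "expected_c13": self.correlation.c13_shift,
            "expected_h1": self.correlation.h1_shift,
            "multiplicity": self.correlation.multiplicity,
            "matched": self.matched,
            "peak_c13": None if self.peak is None else self.peak.c13,
            "peak_h1": None if self.peak is None else self.peak.h1,
            "peak_volume": None if self.peak is None else self.peak.volume,
            "delta_c13": self.delta_c13,
            "delta_h1": self.delta_h1,
            "normalized_distance": self.normalized_distance,
            "sign_consistent": self.sign_consistent,
        }


@dataclass
class MatchReport:
    """Result of matching a peak list against the Amadori fingerprint."""

    matches: dict[tuple[str, str], MatchedCorrelation]
    diagnostic_hits: int
    presence: bool
    tol_c13: float
    tol_h1: float
    notes: list[str] = field(default_factory=list)

    def matched_for_form(self, form: str) -> list[MatchedCorrelation]:
        return [m for (f, _), m in self.matches.items() if f == form and m.matched]

    def get(self, form: str, label: str) -> MatchedCorrelation:
        return self.matches[(form, label)]

    def to_dict(self) -> dict:
        return {
            "presence": self.presence,
            "diagnostic_hits": self.diagnostic_hits,
            "tolerances": {"c13_ppm": self.tol_c13, "h1_ppm": self.tol_h1},
            "correlations": [m.to_dict() for m in self.matches.values()],
            "notes": self.notes,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def _sign_consistent(corr: Correlation, peak: CrossPeak, edited: bool) -> bool:
    if not edited or peak.sign == 0:
        return True
    expected = -1 if corr.multiplicity == "CH2" else 1
    return peak.sign == expected


def match_amadori(
    peaklist: PeakList,
    library: ShiftLibrary | None = None,
    tol_c13: float = DEFAULT_TOL_C13,
    tol_h1: float = DEFAULT_TOL_H1,
    forms: list[str] | None = None,
) -> MatchReport:
    """Match a peak list against the fingerprint and call presence/absence.

    Every HSQC-visible library correlation (of the requested forms) competes
    for peaks inside its +/- tolerance box; assignment is greedy by ascending
    normalized Euclidean distance sqrt((dC/tolC)^2 + (dH/tolH)^2), each peak
    satisfying at most one entry, ties broken by peak order.  Candidates with
    a multiplicity-inconsistent sign are rejected up front.  Presence is true
    iff all three diagnostic markers matched.
    """
    if tol_c13 <= 0 or tol_h1 <= 0:
        raise ConfigurationError("matching tolerances must be positive")
    library = library or load_default_library()
    form_names = forms if forms is not None else list(library.form_names)

    entries: list[tuple[str, Correlation, float]] = []
    for fname in form_names:
        form = library.form(fname)
        for corr in library.hsqc_correlations(fname):
            entries.append((fname, corr, form.population))

    candidates = []  # (distance, entry_index, peak_index)
    peaks = list(peaklist.peaks)
    for ei, (fname, corr, _pop) in enumerate(entries):
        for pi, pk in enumerate(peaks):
            dc = pk.c13 - corr.c13_shift
            dh = pk.h1 - corr.h1_shift
            if abs(dc) > tol_c13 or abs(dh) > tol_h1:
                continue
            if not _sign_consistent(corr, pk, peaklist.multiplicity_edited):
                continue
            dist = math.hypot(dc / tol_c13, dh / tol_h1)
            candidates.append((dist, ei, pi))
    candidates.sort(key=lambda t: (t[0], t[2], t[1]))

    matches = {
        (fname, corr.label): MatchedCorrelation(form=fname, correlation=corr, form_population=pop)
        for fname, corr, pop in entries
    }
    used_entries: set[int] = set()
    used_peaks: set[int] = set()
    notes: list[str] = []
    for dist, ei, pi in candidates:
        if ei in used_entries or pi in used_peaks:
            continue
        used_entries.add(ei)
        used_peaks.add(pi)
        fname, corr, pop = entries[ei]
        pk = peaks[pi]
        matches[(fname, corr.label)] = MatchedCorrelation(
            form=fname,
            correlation=corr,
            peak=pk,
            delta_c13=pk.c13 - corr.c13_shift,
            delta_h1=pk.h1 - corr.h1_shift,
            normalized_distance=dist,
            sign_consistent=_sign_consistent(corr, pk, peaklist.multiplicity_edited),
            form_population=pop,
        )

    # overlap warnings: a matched peak sitting inside the tolerance box of a
    # second library entry cannot be attributed unambiguously
    for (fname, label), m in matches.items():
        if not m.matched:
            continue
        for oname, corr, _pop in entries:
            if (oname, corr.label) == (fname, label):
                continue
            if (
                abs(m.peak.c13 - corr.c13_shift) <= tol_c13
                and abs(m.peak.h1 - corr.h1_shift) <= tol_h1
            ):
                notes.append(
                    f"peak matched to {fname}/{label} also lies in the tolerance "
                    f"box of {oname}/{corr.label}"
                )

    diagnostics = [
        m
        for (fname, _), m in matches.items()
        if fname == "beta-pyranose" and m.correlation.diagnostic
    ]
    hits = sum(1 for m in diagnostics if m.matched and m.sign_consistent)
    presence = len(diagnostics) == 3 and hits == 3
    return MatchReport(
        matches=matches,
        diagnostic_hits=hits,
        presence=presence,
        tol_c13=tol_c13,
        tol_h1=tol_h1,
        notes=notes,
    )


def detect_glycation(
    data: GriddedSpectrum2D | PeakList,
    library: ShiftLibrary | None = None,
    tol_c13: float = DEFAULT_TOL_C13,
    tol_h1: float = DEFAULT_TOL_H1,
    threshold_multiplier: float = 5.0,
    init_sigma_c13: float = 0.05,
    init_sigma_h1: float = 0.006,
    forms: list[str] | None = None,
) -> tuple[MatchReport, PeakList]:
    """Pick -> fit -> match for gridded input, direct match for a peak list.

    Returns the match report together with the (fitted) peak list actually
    matched, so downstream quantification can reuse the measured volumes.
    """
    if isinstance(data, GriddedSpectrum2D):
        picked = pick_peaks(
            data,
            threshold_multiplier=threshold_multiplier,
            min_sep_c13=2.0 * init_sigma_c13,
            min_sep_h1=2.0 * init_sigma_h1,
        )
        fitted = fit_and_integrate(
            data, picked, init_sigma_c13=init_sigma_c13, init_sigma_h1=init_sigma_h1
        )
    elif isinstance(data, PeakList):
        if data.values_are != "volume":
            warnings.warn(
                "matching a height-valued peak list; volumes are required for quantification",
                stacklevel=2,
            )
        fitted = data
    else:
        raise TypeError("data must be a GriddedSpectrum2D or a PeakList")
    report = match_amadori(fitted, library, tol_c13=tol_c13, tol_h1=tol_h1, forms=forms)
    return report, fitted
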