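"""Peak picking, Gaussian fitting/integration and fingerprint matching."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amadori import (
    SimulationConfig,
    detect_glycation,
    fit_and_integrate,
    match_amadori,
    pick_peaks,
    simulate_hsqc,
)
from amadori.library import Correlation
from amadori.simulate import gaussian_volume
from amadori.spectra import CrossPeak, GriddedSpectrum2D, PeakList

EXPECTED_SINGLE_VOLUME = gaussian_volume(1.0, 0.05, 0.005)


def library_peaklist(library, volume_of=None, displace=None):
    """Peaks exactly at the HSQC-visible beta-pyranose positions."""
    displace = displace or {}
    peaks = []
    for corr in library.hsqc_correlations("beta-pyranose"):
        dc, dh = displace.get(corr.label, (0.0, 0.0))
        vol = (volume_of or {}).get(corr.label, 1.0)
        sign = -1 if corr.multiplicity == "CH2" else 1
        peaks.append(
            CrossPeak(corr.c13_shift + dc, corr.h1_shift + dh, sign * vol, sign=sign)
        )
    return PeakList(peaks, multiplicity_edited=True)


class TestPickPeaks:
    def test_single_gaussian_picked_at_apex(self):
        c = 40 + 0.05 * np.arange(61)
        h = 3 + 0.005 * np.arange(61)
        cg, hg = np.meshgrid(c, h, indexing="ij")
        intensity = 10 * np.exp(-0.5 * ((cg - 41.5) / 0.05) ** 2 - 0.5 * ((hg - 3.15) / 0.005) ** 2)
        spec = GriddedSpectrum2D(intensity, c, h)
        pl = pick_peaks(spec, 5.0, noise_sigma=1.0)
        assert len(pl) == 1
        assert (pl.peaks[0].c13, pl.peaks[0].h1) == (41.5, 3.15)

    def test_two_gaussians_4sigma_apart_give_two_picks(self):
        c = 40 + 0.0125 * np.arange(161)
        h = 3 + 0.00125 * np.arange(161)
        cg, hg = np.meshgrid(c, h, indexing="ij")
        intensity = np.exp(-0.5 * ((cg - 40.8) / 0.05) ** 2 - 0.5 * ((hg - 3.1) / 0.005) ** 2)
        intensity += np.exp(-0.5 * ((cg - 41.0) / 0.05) ** 2 - 0.5 * ((hg - 3.1) / 0.005) ** 2)
        spec = GriddedSpectrum2D(intensity, c, h)
        pl = pick_peaks(spec, 5.0, noise_sigma=0.01, min_sep_c13=0.1, min_sep_h1=0.01)
        # brute-force extrema oracle
        inner = spec.intensity[1:-1, 1:-1]
        n_oracle = int(
            np.sum(
                (inner > 0.05)
                & np.all(
                    [inner >= np.roll(np.roll(spec.intensity, di, 0), dj, 1)[1:-1, 1:-1]
                     for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)],
                    axis=0,
                )
            )
        )
        assert len(pl) == n_oracle == 2

    def test_negative_extrema_picked_with_sign(self):
        c = 40 + 0.05 * np.arange(41)
        h = 3 + 0.005 * np.arange(41)
        cg, hg = np.meshgrid(c, h, indexing="ij")
        intensity = -8 * np.exp(-0.5 * ((cg - 41) / 0.05) ** 2 - 0.5 * ((hg - 3.1) / 0.005) ** 2)
        spec = GriddedSpectrum2D(intensity, c, h, multiplicity_edited=True)
        pl = pick_peaks(spec, 5.0, noise_sigma=1.0)
        assert len(pl) == 1
        assert pl.peaks[0].sign == -1
        assert pl.peaks[0].multiplicity_class == "CH2-like"

    def test_false_positive_rate_on_pure_noise(self):
        """At k = 5 the expected false-pick count is far below 1 per 1e5 points."""
        total = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            spec = GriddedSpectrum2D(
                rng.normal(0, 1.0, (400, 250)),
                40 + 0.05 * np.arange(400),
                3 + 0.005 * np.arange(250),
            )
            total += len(pick_peaks(spec, 5.0))
        assert total <= 2  # 10 x 1e5 points


class TestFitAndIntegrate:
    def test_noiseless_volume_matches_closed_form(self, single_gaussian_spectrum):
        pl = pick_peaks(single_gaussian_spectrum, 5.0, noise_sigma=0.0)
        fitted = fit_and_integrate(single_gaussian_spectrum, pl, 0.05, 0.005)
        assert len(fitted) == 1
        assert fitted.peaks[0].volume == pytest.approx(EXPECTED_SINGLE_VOLUME, rel=0.01)
        assert fitted.peaks[0].c13 == pytest.approx(42.0, abs=1e-6)

    def test_volume_within_5pct_at_snr_20(self, single_gaussian_spectrum):
        rng = np.random.default_rng(5)
        noisy = GriddedSpectrum2D(
            single_gaussian_spectrum.intensity + rng.normal(0, 1 / 20, single_gaussian_spectrum.intensity.shape),
            single_gaussian_spectrum.c13_axis,
            single_gaussian_spectrum.h1_axis,
        )
        pl = pick_peaks(noisy, 5.0, min_sep_c13=0.1, min_sep_h1=0.01)
        fitted = fit_and_integrate(noisy, pl, 0.05, 0.005)
        main = max(fitted.peaks, key=lambda p: abs(p.volume))
        assert main.volume == pytest.approx(EXPECTED_SINGLE_VOLUME, rel=0.05)

    def test_fully_overlapping_pair_fit_jointly(self, single_gaussian_spectrum):
        doubled = GriddedSpectrum2D(
            2 * single_gaussian_spectrum.intensity,
            single_gaussian_spectrum.c13_axis,
            single_gaussian_spectrum.h1_axis,
        )
        picks = PeakList([CrossPeak(42.0, 3.2, 2.0), CrossPeak(42.0, 3.2, 2.0)])
        fitted = fit_and_integrate(doubled, picks, 0.05, 0.005)
        total = sum(p.volume for p in fitted)
        # numeric-integration oracle for the doubled spectrum
        oracle = float(doubled.intensity.sum() * doubled.c13_step * doubled.h1_step)
        assert total == pytest.approx(oracle, rel=0.02)
        assert total == pytest.approx(2 * EXPECTED_SINGLE_VOLUME, rel=0.02)


class TestMatchAmadori:
    def test_exact_placement_gives_presence(self, library):
        report = match_amadori(library_peaklist(library), library)
        assert report.presence
        assert report.diagnostic_hits == 3

    def test_empty_peaklist_gives_absence(self, library):
        report = match_amadori(PeakList([], multiplicity_edited=True), library)
        assert not report.presence
        assert report.diagnostic_hits == 0

    def test_displaced_c6_markers_break_presence(self, library):
        """C5-H5 alone is not enough: both C6 entries displaced by 2x tol."""
        displaced = library_peaklist(
            library, displace={"C6-H6": (0.8, 0.0), "C6-H6'": (0.8, 0.0)}
        )
        report = match_amadori(displaced, library, tol_c13=0.4, tol_h1=0.04)
        assert report.get("beta-pyranose", "C5-H5").matched
        assert not report.get("beta-pyranose", "C6-H6").matched
        assert not report.presence

    def test_sign_inconsistent_candidates_rejected(self, library):
        peaks = library_peaklist(library)
        for pk in peaks:  # flip every sign
            pk.sign = -pk.sign
            pk.volume = -pk.volume
        report = match_amadori(peaks, library)
        assert not report.presence
        assert report.diagnostic_hits == 0

    def test_tolerance_monotonicity(self, library):
        """Markers matched at a tight tolerance stay matched at any looser one."""
        peaks = library_peaklist(
            library,
            displace={
                "C5-H5": (0.15, 0.01),
                "C6-H6": (-0.3, -0.02),
                "C4-H4": (0.45, 0.0),
            },
        )
        previous: set = set()
        for tol_c in (0.1, 0.2, 0.4, 0.8):
            report = match_amadori(peaks, library, tol_c13=tol_c, tol_h1=0.1 * tol_c)
            matched = {key for key, m in report.matches.items() if m.matched}
            assert previous <= matched
            previous = matched

    def test_matching_invariant_under_intensity_scaling(self, library):
        peaks = library_peaklist(library)
        scaled = PeakList(
            [CrossPeak(p.c13, p.h1, 1e6 * p.volume, sign=p.sign) for p in peaks],
            multiplicity_edited=True,
        )
        r1 = match_amadori(peaks, library)
        r2 = match_amadori(scaled, library)
        assert {k for k, m in r1.matches.items() if m.matched} == {
            k for k, m in r2.matches.items() if m.matched
        }

    @settings(deadline=None, max_examples=50)
    @given(data=st.data())
    def test_greedy_matches_exhaustive_on_separated_instances(self, data):
        """On well-separated instances the greedy assignment is optimal."""
        tol_c, tol_h = 0.4, 0.04
        n_entries = data.draw(st.integers(1, 6))
        # entries separated by >= 3 tolerance units along 13C
        base_c = data.draw(st.floats(45, 60))
        entries = [
            Correlation(label=f"E{k}", c13_shift=base_c + 3 * tol_c * k, h1_shift=3.5,
                        multiplicity="CH")
            for k in range(n_entries)
        ]
        peaks = []
        for k in range(n_entries):
            if data.draw(st.booleans()):
                dc = data.draw(st.floats(-0.4, 0.4)) * tol_c
                dh = data.draw(st.floats(-0.4, 0.4)) * tol_h
                peaks.append(CrossPeak(entries[k].c13_shift + dc, entries[k].h1_shift + dh, 1.0))
        for _ in range(data.draw(st.integers(0, 2))):  # far decoys
            peaks.append(CrossPeak(90.0 + data.draw(st.floats(0, 5)), 3.5, 1.0))

        greedy = _greedy_assign(entries, peaks, tol_c, tol_h)
        optimal = _exhaustive_assign(entries, peaks, tol_c, tol_h)
        assert len(greedy) == len(optimal)
        assert greedy == optimal

    def test_round_trip_presence_on_synthetic_spectrum(self, library, example_sequence):
        config = SimulationConfig(sequence=example_sequence, glycations_per_molecule=8.0)
        spectrum, _ = simulate_hsqc(config)
        report, _ = detect_glycation(spectrum, library)
        assert report.presence

    def test_no_presence_without_glycation(self, library, example_sequence):
        config = SimulationConfig(sequence=example_sequence, glycations_per_molecule=0.0)
        spectrum, _ = simulate_hsqc(config)
        report, _ = detect_glycation(spectrum, library)
        assert not report.presence

    def test_decoy_peaks_do_not_trigger_presence(self, library, example_sequence):
        """Specificity: extraneous peaks >= 1 ppm (13C) from the diagnostics."""
        decoys = [
            {"c13": 70.3, "h1": 4.00, "volume": 5.0, "sign": 1},
            {"c13": 65.3, "h1": 3.99, "volume": 5.0, "sign": -1},
            {"c13": 68.0, "h1": 3.76, "volume": 5.0, "sign": -1},
        ]
        config = SimulationConfig(
            sequence=example_sequence, glycations_per_molecule=0.0, decoy_peaks=decoys
        )
        spectrum, _ = simulate_hsqc(config)
        report, _ = detect_glycation(spectrum, library)
        assert not report.presence

    def test_fitted_positions_reproduce_library_within_grid_step(
        self, library, example_sequence
    ):
        config = SimulationConfig(sequence=example_sequence, glycations_per_molecule=2.0)
        spectrum, _ = simulate_hsqc(config)
        report, _ = detect_glycation(spectrum, library)
        for label in ("C3-H3", "C4-H4", "C5-H5", "C6-H6", "C6-H6'"):
            m = report.get("beta-pyranose", label)
            assert m.matched
            assert abs(m.delta_c13) <= config.grid.c13_step
            assert abs(m.delta_h1) <= config.grid.h1_step


def _greedy_assign(entries, peaks, tol_c, tol_h):
    pl = PeakList(list(peaks))
    # run the production matcher through a minimal single-form library
    from amadori.library import AmadoriForm, ShiftLibrary

    lib = ShiftLibrary(
        forms=(AmadoriForm(name="beta-pyranose", correlations=tuple(entries), population=0.7),)
    )
    report = match_amadori(pl, lib, tol_c13=tol_c, tol_h1=tol_h)
    return {
        (m.correlation.label, round(m.peak.c13, 6))
        for m in report.matches.values()
        if m.matched
    }


def _exhaustive_assign(entries, peaks, tol_c, tol_h):
    """Best injective assignment: max matches, then min total distance."""
    def dist(e, p):
        dc, dh = p.c13 - e.c13_shift, p.h1 - e.h1_shift
        if abs(dc) > tol_c or abs(dh) > tol_h:
            return None
        return math.hypot(dc / tol_c, dh / tol_h)

    sorted_peaks = sorted(peaks, key=lambda p: (p.c13, p.h1))
    best, best_key = set(), (-1, math.inf)
    n = len(entries)
    for subset_size in range(min(n, len(sorted_peaks)), -1, -1):
        for entry_subset in itertools.combinations(range(n), subset_size):
            for peak_perm in itertools.permutations(range(len(sorted_peaks)), subset_size):
                total = 0.0
                ok = True
                for ei, pi in zip(entry_subset, peak_perm):
                    d = dist(entries[ei], sorted_peaks[pi])
                    if d is None:
                        ok = False
                        break
                    total += d
                if ok:
                    key = (subset_size, -total)
                    if key > (best_key[0], -best_key[1]):
                        best_key = (subset_size, total)
                        best = {
                            (entries[ei].label, round(sorted_peaks[pi].c13, 6))
                            for ei, pi in zip(entry_subset, peak_perm)
                        }
        if best_key[0] == subset_size and best_key[0] >= 0 and best:
            break
    return best
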