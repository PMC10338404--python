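# Methods

## The measurement this package models

A protein denatured in 7 M deuterated urea behaves as a random coil: its
¹H-¹³C HSQC spectrum reduces to one cross-peak per chemically distinct C-H
group of each residue *type*, with volumes proportional to (number of
residues of that type) × (protons contributing to the signal). A residue
immediately preceding a proline is perturbed away from its generic
position; for Ser and Thr this produces isolated Cα-Hα "X-Pro anchor"
peaks at 56.6/4.71 and 60.1/4.60 ppm that act as single-residue rulers.

Glycation by glucose adds the Amadori product fructoselysine, an
equilibrium of cyclic forms dominated by the β-pyranose (populations used
throughout: β-pyranose 0.70, α- and β-furanose 0.13 each, α-pyranose 0.04;
open forms < 1% and neglected). The β-pyranose ring carbons give a fixed
fingerprint of HSQC cross-peaks; C5-H5 (71.8/4.00), C6-H6 (66.7/3.99) and
C6-H6′ (66.7/3.76) fall in regions free of protein and glycan signals and
are the diagnostic markers. C3-H3/C4-H4 corroborate but can superimpose
with other signals; C1-H1 protons exchange against solvent deuterium and
the Lys Cε-Hε region is congested, so neither is used for quantification
by default. C2 bears no proton and never appears in an HSQC.

In a multiplicity-edited HSQC, CH and CH₃ peaks are positive and CH₂ peaks
negative. Because the INEPT transfer delay is a compromise across
multiplicities, integrals are comparable only *within* a multiplicity
class; the package enforces CH-with-CH and CH₂-with-CH₂ comparisons
everywhere.

All chemical shifts are stored DSS-referenced. Values referenced to TMS or
1,4-dioxane are converted by the fixed additive offsets +2.5 and +1.8 ppm
respectively; conversions happen only at I/O boundaries.

### Library values and their provenance

The β-pyranose column ships the experimental glycated-BSA assignments.
Two small inconsistencies exist between the tabulated values and running
text elsewhere (C5 H5 4.00 vs 4.01; C4 ¹³C 72.1 vs 72.2); the tabulated
values are authoritative here and the 0.01/0.1 ppm difference is far
inside the matching tolerance. Published main-text assignments exist only
for the β-pyranose form, so the minor forms carry *synthetic placeholder*
positions (flagged as such in the data file), kept ≥ 1 ppm (¹³C) from the
diagnostic markers; presence calls never rest on them. The random-coil
table beyond the two printed X-Pro anchors is compiled from standard
random-coil shift compilations and shipped as a versioned CSV.

## Synthetic spectra

`simulate_hsqc` renders every peak as an axis-aligned 2D Gaussian with
closed-form volume `V = 2π A σ_C σ_H`, evaluated on a ±6σ window, plus
optional white Gaussian noise. Defaults (and why):

| parameter | default | rationale |
|---|---|---|
| grid | ¹³C 40–105 ppm @ 0.05, ¹H 2.5–5.5 ppm @ 0.005 | covers the sugar/Cα region of interest at realistic digital resolution (~600×1300 points) |
| σ_C, σ_H | 0.05, 0.006 ppm | linewidths of a denatured mid-size protein at 600 MHz |
| form populations | 0.70/0.13/0.13/0.04 | the fructoselysine equilibrium |
| h1_exchange_attenuation | 0.8 | partial deuterium exchange of the C1-H1 protons; multiplies the C1-H1 volume |
| ch2_response_factor | 0.85 | the CH₂/CH response ratio under the compromise INEPT delay is not published; this is an explicit free parameter, not an estimate — quantification is insensitive to it by class hygiene |
| noise_sigma | 0 | noiseless by default; tests set it explicitly per scenario |

Within one multiplicity class the per-proton volume scale is identical for
protein and Amadori peaks, which is exactly the assumption the
quantification procedure relies on. The single integer seed drives only
the noise stream; positions and volumes are deterministic functions of the
configuration. Peaks from distinct owners closer than 0.5σ on both axes
physically superimpose; the ground truth flags them so per-peak assertions
can skip them. Amadori peak volumes scale as G × (form population) ×
(protons in signal), with G the expected glycations per molecule.

What the generator deliberately does **not** emulate: J-coupling multiplet
structure, t₁-noise ridges, solvent streaks, lineshape deviations from
Gaussian, chemical-shift dispersion of multiple copies of one residue
type, depletion of the unmodified Lys Cε signal by the glycation itself,
and glycan backgrounds (a decoy-peak list can be injected for specificity
tests). Passing round-trip tests therefore demonstrates the correctness of
the algorithms under the stated statistical model, not robustness to every
artefact of real spectra.

## Detection

1. **Noise estimate**: median absolute deviation of intensities below the
   90th percentile of |I|, divided by Φ⁻¹(0.725) ≈ 0.598. The divisor is
   the MAD of a standard normal truncated at its 90th |·| percentile, so
   the estimate is unbiased on pure Gaussian noise; the plain 1.4826×MAD
   factor would read ~11% low.
2. **Picking**: strict 3×3 local extrema of |I| above k×σ (default k = 5 —
   a false-pick probability per point of ~6×10⁻⁸). The weaker of two picks
   closer than ~2 linewidths on both axes is suppressed, since noise
   riding on a broad peak otherwise fragments it.
3. **Fitting**: least-squares axis-aligned 2D Gaussian plus constant local
   baseline on a ±4σ window (lmfit/Levenberg-Marquardt); peaks with
   intersecting windows are fit jointly. Volume `2πAσ_Cσ_H`; a
   non-convergent fit falls back to direct window summation and is flagged
   (infinite fit-quality metric).
4. **Matching**: each library correlation accepts peaks inside a ±0.4 ppm
   (¹³C) / ±0.04 ppm (¹H) tolerance box — sized to span the inter-protein
   spread of the fingerprint positions, and configurable since no
   canonical tolerance exists. Assignment is greedy by ascending
   normalized distance √((ΔC/tol_C)² + (ΔH/tol_H)²), one peak per entry,
   ties broken by peak order (deterministic). Sign-inconsistent candidates
   (e.g. a positive peak for a CH₂ entry in an edited spectrum) are
   rejected up front. Greedy equals the exhaustive optimum whenever
   entries are separated by more than two tolerance units, which holds for
   the fingerprint; it can differ on adversarial overlapping instances.
5. **Presence rule**: glycation is called present iff all three diagnostic
   markers match with consistent signs. C3-H3/C4-H4 and the minor forms
   are reported but never required.

## Quantification

For each usable matched marker *i*:

```
g_i = |V_i| / (p_i · V̄_ref · pop_form)
```

where `p_i` is the marker's protons-per-signal (1 for each resolved C6
proton — the /2 rule applies only when a degenerate CH₂ gives a single
signal), `V̄_ref` is the per-proton reference volume of the *same*
multiplicity class, and `pop_form` is the library population of the
marker's form (0.70 for β-pyranose). Dividing by the population converts
the measured β-pyranose-only abundance into total glycations per molecule;
with the correction disabled (`form_population_correction=False`) the
numbers are raw volume ratios of the kind "the marker is 7–9× a normalized
CH group".

`V̄_ref` is the unweighted mean of `V/(n·p)` over all measured reference
signals of the class. Pooling several isolated references instead of
trusting a single one reduces the noise any one integral carries into
every estimate; with one reference it reduces to the classical
single-reference ratio. Reference candidates are ranked by an isolation
score (tolerance-normalized distance to the nearest other predicted peak);
the X-Pro anchors, Gln/Glu Cγ-Hγ, Arg Cδ-Hδ, Phe Cα-Hα, Ile Cβ-Hβ and Gly
Cα-Hα are always proposed when the sequence contains them.

The aggregate is the unweighted mean of the per-marker estimates — the
per-marker values are always reported so a range ("7–9") stays visible;
no weighting scheme is implied by the procedure itself. The result is
expressed both as glycations per molecule and, when ≤ 1, as percent of
molecules glycated; both numbers are always present in machine-readable
output.

Relative form abundances are the per-form means of per-proton volumes of
matched CH correlations, normalized to sum to 1 over matched forms; with a
single matched form the function reports dominance only.

## Detection limit

`min_detectable_fraction = 100 · min(1, c_LOD / c_protein)` with the
empirical `c_LOD` defaulting to 55 µmol/L of modified species in a 5 mm
tube (≈ 27.5 nmol in 500 µL). Display values round half-up to integer
percent/nmol (27.5 → 28, 6.11 → 6); exact values are preserved in JSON.
`c_LOD` is configurable rather than a constant: it depends on field,
probe and measurement time, and published statements derived from it are
not all mutually consistent (a claimed 0.7% at 3.85 mmol/L corresponds to
~28 µmol/L, not 55). No first-principles sensitivity model is attempted.

## Problem sizes and determinism

Round-trip validation runs the full gridded pipeline on the default
600×1300-point grid: noiseless recovery is exercised over G ∈ {0.25, 0.5,
1, 2, 4, 8} (estimates within 10% of truth) and noisy recovery at an SNR
of 10 on the weakest quantified marker over 20 seeds (within 25%). A
single pipeline run takes well under a second on one CPU. All randomness
flows through explicit integer seeds; noiseless results are exactly
reproducible and noisy results are reproducible per seed.

## Known limitations

- Minor-form positions are placeholders; only dominance of the β-pyranose
  and the population arithmetic are meaningful for them, never absolute
  positions.
- The matcher assigns at most one peak per library entry and cannot
  deconvolve a genuine superposition of two species onto one peak (it
  flags tolerance-box overlaps instead).
- Quantification assumes equal ¹J(CH), T₁ and transfer efficiency within
  a multiplicity class; systematic deviations in real spectra propagate
  directly into the stoichiometry.
- Heights are not volumes: peak lists carrying heights are refused for
  quantification unless lineshape widths are supplied.
- The sequence-composition model treats all copies of a residue type as
  one peak; real spectra show residual dispersion that spreads reference
  volumes over clusters of peaks.
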