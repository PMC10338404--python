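# amadori

Unambiguous identification and quantification of glucose-induced glycation
(Amadori products) in proteins from 2D ¹H-¹³C HSQC spectra of denatured
samples.

Glycation is the spontaneous reaction of a reducing sugar with a protein
primary amine — most often glucose with a lysine Nε — which after Amadori
rearrangement yields fructoselysine. It is a critical quality attribute of
therapeutic monoclonal antibodies, and mass spectrometry cannot distinguish
it from an extra hexose on a glycan (both are +162 Da). In a urea-denatured
protein, however, the ¹H-¹³C HSQC collapses to the random-coil cross-peaks
of the 20 amino-acid types, and the dominant β-pyranose form of
fructoselysine (~70% of the ring/open-chain equilibrium) adds a
characteristic fingerprint. Three of its correlations — C5-H5 at 71.8/4.00
ppm, C6-H6 at 66.7/3.99 ppm and C6-H6′ at 66.7/3.76 ppm (¹³C/¹H, DSS) — do
not superimpose with protein or glycan signals and act as diagnostic
markers.

The package is aimed at NMR spectroscopists and protein-analytics groups
who want a scriptable, testable version of this workflow:

- **Fingerprint library** of the fructoselysine forms plus a random-coil
  cross-peak table with the Ser-Pro (56.6/4.71) and Thr-Pro (60.1/4.60)
  X-Pro anchor positions (`amadori.library`).
- **Spectrum model and I/O**: Sparky-style and CSV peak lists, a
  self-describing gridded-spectrum container, robust noise estimation
  (`amadori.spectra`).
- **Detection**: local-extremum peak picking, axis-aligned 2D Gaussian
  fitting/integration (volume `2πAσ_Cσ_H`), tolerance-box fingerprint
  matching with a sign-aware presence rule (`amadori.detect`).
- **Quantification**: per-proton normalized reference volumes
  (`V/(n·p)` — residue count `n`, protons per signal `p`, the `/2` rule for
  a degenerate CH₂), strict CH-with-CH / CH₂-with-CH₂ comparison, and
  glycations-per-molecule estimates per marker (`amadori.quantify`).
- **Detection-limit model**: minimal detectable modification fraction
  `100·min(1, c_LOD/c_protein)` with the empirical `c_LOD = 55 µmol/L`
  (`amadori.lod`).
- **Synthetic-data generator** producing multiplicity-edited spectra
  (CH positive, CH₂ negative) of denatured proteins with known glycation
  ground truth, for validation end to end (`amadori.simulate`).

## Worked example

```python
from amadori import GlycationHSQC, SimulationConfig, simulate_hsqc
from amadori.simulate import EXAMPLE_SEQUENCE

config = SimulationConfig(
    sequence=EXAMPLE_SEQUENCE,       # 24-residue demo with an S-P anchor motif
    glycations_per_molecule=2.0,     # ground truth
    noise_sigma=0.0,
)
spectrum, truth = simulate_hsqc(config)
results = GlycationHSQC(spectrum, EXAMPLE_SEQUENCE).fit()
print(results.summary())
```

prints

```
Glycation HSQC analysis
================================================================
Sequence length:        24 residues
Peaks analysed:         41
Matching tolerance:     +/-0.4 ppm (13C), +/-0.04 ppm (1H)
Diagnostic markers hit: 3/3
Glycation present:      yes

correlation                       expected             found      volume
------------------------------------------------------------------------
beta-pyranose/C1-H1              55.6/3.29         55.6/3.29         1.9
beta-pyranose/C3-H3              72.4/3.75         72.4/3.75         1.4
beta-pyranose/C4-H4              72.1/3.89         72.1/3.89         1.4
beta-pyranose/C5-H5 *            71.8/4.00         71.8/4.00         1.4
beta-pyranose/C6-H6 *            66.7/3.99         66.7/3.99        1.19
beta-pyranose/C6-H6' *           66.7/3.76         66.7/3.76        1.19
beta-pyranose/Lys Ce-He          50.9/3.06         50.9/3.06        2.38
(* diagnostic marker)

Stoichiometry
------------------------------------------------------------------------
  C3-H3      (CH  vs A Ca-Ha (+14 pooled)): g = 2.00
  C4-H4      (CH  vs A Ca-Ha (+14 pooled)): g = 2.00
  C5-H5      (CH  vs A Ca-Ha (+14 pooled)): g = 2.00
  C6-H6      (CH2 vs Gly Ca-Ha (+3 pooled)): g = 2.00
  C6-H6'     (CH2 vs Gly Ca-Ha (+3 pooled)): g = 2.00
  per-marker range: 2.00 - 2.00
  aggregate: 2.0 glycations per molecule

Relative form abundances
------------------------------------------------------------------------
  beta-pyranose     70.0%
  alpha-furanose    13.0%
  beta-furanose     13.0%
  alpha-pyranose     4.0%
```

All three diagnostic markers are found at their library positions
(presence call), every marker's volume ratio against the pooled per-proton
reference volume recovers the simulated stoichiometry of 2 glycations per
molecule, and the relative volumes of the four cyclic forms reproduce the
equilibrium populations the generator was given (70/13/13/4).

The same analysis is available from a shell:

```bash
amadori simulate --sequence MKSPGFRIGKTAWLKNDQEVHYCK -g 2.0 --seed 7 \
        --out-spectrum run.grid
amadori detect --input run.grid --report match.json
amadori quantify --input run.grid --sequence MKSPGFRIGKTAWLKNDQEVHYCK
amadori lod --protein-conc 220        # -> 25% minimal detectable fraction
```

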