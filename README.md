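# glycomob

Ion-mobility glycomics of mucin-type *O*-glycan alditols.

Mucins are heavily *O*-glycosylated proteins whose glycosylation profile
shifts in diseases such as cystic fibrosis. The released glycans are short,
highly isomeric oligosaccharides built on a reduced GalNAc alditol
(GalNAc-ol) with one of eight core types. Trapped ion mobility spectrometry
(TIMS) separates these isomers in minutes and characterises each one by its
collision cross section (CCS, Å²) — an instrument-independent molecular
property that can replace chromatographic retention time for
database-driven assignment.

`glycomob` is a toolkit for that workflow, aimed at glycomics MS
practitioners:

- **Mass arithmetic / composition search** (`glycomob.chem`): monoisotopic
  masses from elemental residue formulas (Hex C₆H₁₀O₅, HexNAc C₈H₁₃NO₅,
  dHex C₆H₁₀O₄, NeuAc C₁₁H₁₇NO₈, sulfate +SO₃); neutral mass
  *M* = Σ residues + H₂O + H₂ (alditol), observed as [M − zH]ᶻ⁻; exhaustive
  composition search from observed *m/z* within a ppm tolerance.
- **Structures** (`glycomob.structures`): condensed-notation trees
  (`Fuc(a1-2)Gal(b1-3)[GlcNAc(b1-6)]GalNAc-ol`), core 1–8 classification
  and motif detection (blood-group H, type I/II chains, sialylation,
  fucosylation, sulfation).
- **Negative-mode fragments** (`glycomob.fragments`): B/C/Y/Z glycosidic
  ions with exact mass conservation (B+Y = C+Z = M), alditol chain
  (cross-ring-type) cleavages, spectrum annotation and a configurable
  diagnostic rule engine for core assignment.
- **CCS calibration** (`glycomob.calibration`): TWIMS log-log calibration
  with EDC drift-time correction t_D′ = t_D − C·√(m/z)/1000 and reduced
  CCS′ = CCS·√µ/z (µ the ion–N₂ reduced mass); TIMS linear 1/K₀
  calibration; cross-instrument %STD.
- **Mobilograms** (`glycomob.mobilogram`): extracted ion mobilograms,
  Gaussian mixture deconvolution with BIC model selection, relative isomer
  areas, charge-state gating, resolving power; CSV and mzML input.
- **Profiling and libraries** (`glycomob.profiling`, `glycomob.libio`):
  per-sample core/feature area summaries, isomer-ratio comparison with
  rank-inversion flags, CCS library I/O and (m/z, CCS) matching.
- **Synthetic data** (`glycomob.fixtures`): seeded generators for frames,
  CID spectra and calibrant ladders, used throughout the test suite.

## Worked example

Four isomers share the composition dHex₁Hex₂HexNAc₂ ([M − H]⁻ at *m/z*
895). Simulate their mobilogram, deconvolve it, and match a CCS against the
packaged demonstration library:

```python
from glycomob.calibration import TIMSCalibration, tims_ccs, tims_inv_k0
from glycomob.chem import Composition, mz
from glycomob.fixtures import TruthRecord, synth_frame
from glycomob.mobilogram import detect_peaks, extract_eim, relative_areas

cal = TIMSCalibration(slope=1050.0)          # Å²·cm²/(V·s), CCS' = slope/K0
target = mz(Composition.parse("Hex2HexNAc2dHex1"), 1)   # 895.3412
truth = []
for ccs, area in zip([273.0, 275.0, 290.0, 297.0], [20, 30, 35, 15]):
    inv = tims_inv_k0(ccs, target, 1, cal)
    sigma = tims_inv_k0(ccs + 0.6, target, 1, cal) - inv
    truth.append(TruthRecord("Hex2HexNAc2dHex1", None, 1, inv, sigma, area))

frame = synth_frame(truth, noise_rel=0.01, seed=42)
peaks = relative_areas(detect_peaks(extract_eim(frame, target, 0.05)))
for p in peaks:
    print(f"CCS {tims_ccs(p.centroid, target, 1, cal):6.1f} A^2  "
          f"rel. area {p.relative_area:5.2f} %")
```

prints

```
CCS  273.0 A^2  rel. area 19.99 %
CCS  275.0 A^2  rel. area 30.02 %
CCS  290.0 A^2  rel. area 35.04 %
CCS  297.0 A^2  rel. area 14.95 %
```

i.e. the four Gaussian components are recovered with their CCS centroids
and relative areas, even for the 273/275 pair separated by only 2 Å².
The same isomers can then be told apart structurally: feeding each
candidate structure's CID fragments through
`fragments.score_core_diagnostics` ranks core 2 first for the two compact
isomers and core 1 for the two extended ones, and
`libio.match(895.3412, 297.0, 1, records)` returns the matching library
record within a 0.5 % CCS tolerance.

The same operations are available from the shell:

```
glycomob compsearch --mz 675.246 --z 1 --ppm 10
glycomob calibrate --mode tims --calibrants cal.csv
glycomob peaks --frame frame.csv --mz 895.3412
glycomob assign --spectrum spec.csv --structure-candidates "Gal(b1-3)GalNAc-ol"
glycomob match --mz 895.3412 --ccs 296.0
```

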