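# Methods

## Scope and model

`glycomob` models the negative-mode ion-mobility MS analysis of mucin-type
*O*-glycan alditols: short oligosaccharides released by reductive
β-elimination, so every structure is rooted at an open-chain GalNAc-ol and
carries +H₂O +2H relative to the sum of dehydrated residue masses. Observed
ions are deprotonated, [M − zH]ᶻ⁻, with the proton mass taken as
1.007276 Da (electron mass folded in). Singly charged ions dominate;
doubly deprotonated species are expected only above a neutral-mass
threshold of 1200 Da (configurable; the boundary itself is treated as
singly charged).

Monoisotopic residue masses are computed at import time from elemental
formulas (Hex C₆H₁₀O₅, HexNAc C₈H₁₃NO₅, dHex C₆H₁₀O₄, NeuAc C₁₁H₁₇NO₈)
via pyteomics, to ≥6 decimal places. Sulfation is a +SO₃ count on the
composition rather than a residue node, because MS-level data localise a
sulfate only rarely; this keeps "sulfated" a composition feature, which is
how profiling reports it.

## Composition search

`search_compositions` enumerates the full count lattice within per-class
bounds (defaults Hex ≤ 8, HexNAc ≤ 8, dHex ≤ 4, NeuAc ≤ 4, S ≤ 2 — wide
enough for the ≤2500 Da range typical of gastric-mucin O-glycomes) and
keeps reduced compositions within a ppm tolerance of the observed m/z,
subject to biological constraints (HexNAc ≥ 1 for mucin-type alditols,
sulfate ≤ 2, NeuAc ≤ 4). The default tolerance is 10 ppm, a typical
QTOF mass accuracy; it is an explicit parameter everywhere. Results are
sorted by absolute ppm error. The implementation is itself a brute force,
and the test suite checks it against a second, independently coded
enumeration with independently summed atomic masses.

## Structures, cores, motifs

Structures are rooted trees in a condensed IUPAC-like text form read
right-to-left with brackets for branches. Anomer (`a`/`b`/`?`) and parent
linkage position (1–8/`?`) are recorded per residue; `?` acts as a
wildcard in motif matching because CID spectra often leave these open.
Branches are canonically ordered by linkage position (unknown last), which
makes serialize∘parse the identity and tree equality well defined.

Core classification looks only at the identity/anomer of the residues
attached at C3 and C6 of GalNAc-ol (core 1 Galβ1-3; core 2 Galβ1-3 +
GlcNAcβ1-6; core 3 GlcNAcβ1-3; core 4 GlcNAcβ1-3 + GlcNAcβ1-6; core 5
GalNAcα1-3; core 6 GlcNAcβ1-6; core 7 GalNAcα1-6; core 8 Galα1-3), so
extensions beyond the core never change the label. The templates are a
module-level table and can be replaced. Motifs: blood-group H =
Fuc(α1-2)→Gal; type I / II chains = Gal(β1-3)/Gal(β1-4)→GlcNAc; LacNAc
extension = either chain type; sialylated/fucosylated/sulfated from class
counts.

## Fragmentation model

Glycosidic cleavages follow the standard B/C (non-reducing side) and Y/Z
(alditol side) nomenclature with neutral masses defined so that B + Y =
C + Z = M exactly for every single cleavage; C = B + H₂O, Y = Z + H₂O.
With two cleavages, root-retaining Y/Y and Z/Z double losses are
generated; internal (B+Y) fragments are not, as the diagnostic content
targeted here lives in root-retaining and chain-cleavage ions. The intact
precursor is included as a pseudo-fragment (kind "M"), since [M − H]⁻
survives CID and is evidence in its own right. Fragments are deduplicated
by (kind, neutral mass) with their cleavage-site metadata merged. Only 1−
fragments are modelled, matching the predominant precursor charge.

Because GalNAc-ol is open-chain, its "cross-ring" cleavages are chain
cleavages. Two defaults are tabulated, with backbone masses from
elemental formulas: splitting C2–C3 retains a C₄H₈O₄ backbone
(120.042259 Da) plus the C3-/C6-substituents; splitting C4–C5 retains
C₂H₆O₂ (62.036779 Da) plus the C6-substituent only. The latter is the
classic 6-arm indicator separating cores 2/4/6/7 from 3-substituted-only
cores. The table is keyed by (residue class, label) and is configurable,
as is appropriate for diagnostics that differ between instruments and
collision energies.

### Core-diagnostic rules

Rules test structural descriptors of matched fragments, not absolute
masses: a root-retaining ion proving a specific immediate child of the
alditol ("root_child"), a chain cleavage proving a non-empty 6-arm and the
identity of its first residue ("chain_A"), and mass-window descriptors for
hand-written rules. The default rule set is derived from the core
templates: one rule per core requiring its C3 evidence and/or 6-arm
evidence and forbidding contradicting evidence, weighted by the number of
required descriptors. Descriptor-level (rather than mass-level) rules are
what keeps the assignment invariant under chain extension — extension
changes every fragment mass but not the descriptors. Scores are summed
per core label (+weight if a rule's requirements are met, −weight if its
forbidden evidence appears); all-zero outcomes are flagged "unassigned"
and equal top scores as ties. Rules load from YAML/JSON for override.

## Calibration

TWIMS: drift times are EDC-corrected, t_D′ = t_D − C·√(m/z)/1000 with
C = 1.41 by default, and reference CCS values reduced to CCS′ = CCS·√µ/z.
The calibration is an unweighted least-squares line in
ln CCS′ vs ln t_D′ (R² and residuals stored). TIMS reports 1/K₀
directly; CCS′ is fitted as slope·(1/K₀), through the origin by default
(Mason–Schamp proportionality), with an affine option. Two conventions
are switchable and documented: the ion mass entering the reduced mass is
m = mz·z by default (the deprotonated ion; using the neutral-equivalent
m + z·1.007276 changes √µ by <0.2 % at these masses), and the N₂ mass
defaults to the average molecular mass 28.0134 Da (monoisotopic 28.00615
available). Dextran-ladder reference CCS values are not shipped as data;
the calibrant table is a user-supplied CSV, and all tests use synthetic
calibrants generated from the forward models.

Cross-instrument reproducibility is quantified per structure as the
two-value sample standard deviation |a−b|/√2 over the pair mean, ×100.

## Mobilogram deconvolution

EIMs are extracted by summing intensity within an m/z window onto the
frame's native mobility grid (fixed-width binning, default 1000 bins, when
no native grid applies). Deconvolution fits 1..k_max Gaussians by
bounded nonlinear least squares with heteroscedastic weights σᵢ ∝ the
smoothed signal level (floored at 3 % of the maximum) — ion-count noise is
multiplicative, and weighting is what makes the information criterion
behave. Model order is chosen by BIC; initial centroids come from peak
picking on a Savitzky–Golay-smoothed trace, further components are seeded
at the largest weighted residual, so the whole procedure is deterministic.
Post-fit, components closer than one width are merged and refitted
(duplicate components describing one physical peak), components narrower
than two grid steps are discarded (sub-sampling spikes), and components
below 5× the residual-MAD noise level are discarded. Relative areas
normalise A·σ·√(2π) per m/z to 100 %.

With the study-like conditions used in the tests — four components at CCS
273/275/290/297 Å², widths σ = 0.6 Å² (resolving power ≈ 200, typical for
TIMS), 1 % multiplicative noise, 5·10⁻⁴ V·s/cm² grid — the four
components are recovered with centroid errors < 0.02 Å² and relative-area
errors < 0.3 % across 50 seeds, comfortably inside the 0.5 Å² / 5 %
acceptance bands.

## Profiling

Core grouping reports percent of total mobility-peak area per core label
(cores 5–8 and unassigned fold into "other" by default) and sums to 100 %.
Feature grouping (sialylated, fucosylated, sulfated) is multi-membership:
a peak counts toward every feature it carries, so the three percentages
are individually in [0, 100] but unconstrained in sum. Summaries are
computed over assigned peaks (switchable in principle by what the caller
puts into the profile). Isomer-ratio tables compare per-m/z relative
areas between two samples, pairing isomers by mobility order, and flag
rank-order inversions. No statistical testing is performed — the intended
comparisons are n=1 vs n=1 proof-of-principle profiles.

## Synthetic data

Generators emulate: accumulated TIMS frames (Gaussian mobility profiles at
theoretical m/z, multiplicative log-normal intensity noise), CID peak
lists (fragment m/z with unit intensities, noise and seeded dropout), and
calibrant ladders (dextran-like m/z series pushed through the forward
calibration models). They do not emulate isotope envelopes, chimeric
spectra, baseline drift, detector saturation, or fucose migration; tests
passing on this data therefore validate the numerics and logic of the
pipeline, not its robustness to those real-data artefacts. Every
generator takes a mandatory seed and returns its ground truth alongside
the data.

The packaged demonstration library (`data/pgm_demo_synthetic.csv`) is
synthetic: 49 plausible mucin-type structures (~2 isomers per composition)
with computed m/z and modelled CCS values (CCS ∝ M^(2/3) with small
isomer offsets; paired TIMS/TWIMS values within 1 % by construction). It
exists so the library reader, validator and matcher can be exercised
without downloads, and is labelled as synthetic in the file itself.

## Numerical choices and limitations

- Mass comparisons in validation use 5 ppm (library m/z-vs-composition
  consistency) and 10 ppm (default search/annotation) tolerances.
- Library matching default CCS tolerance is 0.5 %, the half-width of the
  ~1 % inter-instrument spread; ranking uses the normalized Euclidean
  distance in (ppm, CCS %) space.
- Tie-breaks: equidistant spectrum annotations resolve by fragment kind
  order B < C < Y < Z < A; equal diagnostic scores are reported as ties,
  not broken.
- Charge gating requires non-overlapping bands and errors otherwise;
  points outside all bands are "unassigned".
- mzML support covers the subset needed here (m/z, intensity and
  ion-mobility arrays; 32/64-bit floats, optional zlib) via a contained
  stdlib decoder; vendor raw formats (.d/.tdf) are out of scope.
- Anomeric configuration and linkage positions are never inferred from
  data; they enter only through user-supplied candidate structures, and
  mass-identical cores (e.g. core 3 vs core 5) are separable only when
  candidates constrain identity/anomer.
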