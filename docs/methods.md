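# Methods

This note documents the models, conventions, calibrations and known
limitations behind `helixread`. Everything quantitative stated here is
computed by the test suite or the acceptance script.

## Structure model and parsing policy

Structures are read with gemmi (PDB and mmCIF) into a plain
chains → residues → atoms container. Three policies are applied at
parse time and everywhere downstream:

- **No hydrogens.** Crystallographic protein–DNA models at moderate
  resolution carry none, so all distances, contacts and surfaces are
  heavy-atom quantities and contact classification is distance-only
  (no donor–hydrogen–acceptor angles).
- **Single conformer.** For alternate locations the highest-occupancy
  altloc is kept (ties broken by altloc letter ascending); the number of
  dropped conformers is recorded on the model. This makes all geometry
  deterministic.
- **Waters and ions excluded** from contact and surface computations by
  default; hetero groups such as iron–sulfur clusters are retained and
  counted with the protein group in surface-area work (they are buried
  in the dimer core). Selection by polymer kind partitions every atom
  into protein / DNA / hetero (+ water) with no loss or duplication.

Operator numbering is never guessed from author numbering: the centring
nucleotide is part of the configuration. Strand-c indices increase
5′→3′ from the centre; strand-d nucleotides take the negated index of
their Watson–Crick partner, which makes the numbering antisymmetric
under the duplex dyad (and identical to index negation only for a
perfect palindrome). Re-centring by +k shifts strand-c indices by −k.

## Torsions and backbone substates

Backbone torsions follow the IUPAC definitions (α: O3′(i−1)–P–O5′–C5′
… ζ: C3′–O3′–P(i+1)–O5′(i+1); χ over the glycosidic bond, O4′–C1′–N9–C4
for purines and O4′–C1′–N1–C2 for pyrimidines), signed by the standard
atan2 formula and wrapped to (−180°, +180°]. A torsion whose defining
atoms are absent (chain termini, disorder) is explicitly undefined,
never zero, and undefined phosphates are excluded from state counts —
so a blunt 23-bp duplex has 44 classifiable phosphates, not 46.

The B_I/B_II substate is a pure function of ε−ζ: B_I for ε−ζ ≤ −45°,
B_II for ≥ +45°, intermediate in the symmetric dead zone between.
Canonical values sit near −90° (B_I) and +90° (B_II); the ±45° band is
a configurable design choice placed halfway, wide enough that an
intermediate class exists without starving the two canonical classes.
Classification is monotone in ε−ζ by construction.

## Base frames, pair and step parameters

Idealized heavy-atom geometry for the four bases is embedded in the
standard (Tsukuba-convention) reference frame: x toward the major
groove, y along the pseudo-dyad toward the sequence strand, z along the
helix 5′→3′, so an ideal Watson–Crick partner frame is the 180°
rotation about x. A base's frame is obtained by least-squares (SVD)
superposition of the embedded ring atoms onto the observed ones; the
fitted rotation and translation are the frame and origin, and fits are
refused below six ring atoms.

Pairs are detected geometrically: C1′–C1′ distance 10.4 ± 1.6 Å, at
least two inter-base N/O pairs within 3.5 Å, base-plane angle ≤ 65°,
greedy one-partner-per-nucleotide matching preferring more
hydrogen-bond-like contacts. Complementary bases passing these gates
are labelled Watson–Crick, everything else `other`.

Pair and step parameters use the mid-frame (CEHS-style) construction:
the rotation between two triads factorises into twist about the mean
z-axis and a roll/tilt rotation about the hinge, with translations
expressed in the mid-frame. `compose_step`/`decompose_step` are exact
inverses (round-trip error < 1e-12, property-tested). Intra-pair
parameters reuse the same algebra with the strand-d frame flipped about
its x-axis, ordered strand II → strand I, so (buckle, propeller,
opening) occupy the (tilt, roll, twist) slots; with this convention the
usual B-DNA propeller is negative. All parameters are invariant under
rigid-body motion of the whole structure (tested to 1e-6).

Regional curvature is summarised as the arithmetic mean roll over the
steps lying fully inside an operator-index interval.

## Groove profiles

Groove widths are raw cross-strand P–P distances — no phosphate-radius
subtraction — because that is the scale on which operator narrowing is
reported (values ~9.6–13.8 Å). For a strand-c phosphate at aligned
position i, the minor-groove width is the minimum distance to
strand-d phosphates at aligned offsets −5…−2 (bracketing the canonical
≈3-bp cross-groove register while letting the true minimum be found);
the major groove uses +2…+7. On strand d both windows mirror in sign,
which is forced by the duplex dyad. Positions with a truncated window
are reported but flagged as edge values and excluded from interior
means; 5′-terminal nucleotides without phosphate are recorded as
skipped. The minor-groove reference for regular B-DNA is 11.7 Å, and
deltas (ΔPP_MiG) are reported against it.

## Contacts

All inter-component heavy-atom pairs within the outer cutoff are
enumerated (grid-accelerated, proven equal to the brute-force all-pairs
scan). Classification is nested by distance: H-bond for N/O–N/O pairs
≤ 3.3 Å; salt bridge for titratable side-chain nitrogens (Arg
NH1/NH2/NE, Lys NZ, His ND1/NE2) against phosphate oxygens (or P as
proxy) ≤ 3.3 Å — histidine cases flagged "possible" because the
protonation state is unknowable without hydrogens; everything else
below 3.8 Å is van der Waals. The 3.3 Å boundary is inclusive and the
3.8 Å boundary exclusive (both configurable). DNA atoms carry a
phosphate / sugar / base moiety label; protein main-chain N/O are
flagged so helix-dipole H-bonds are distinguishable from side-chain
chemistry. Interface residues with missing (disordered) side-chain
atoms are listed rather than silently treated as absent.

## Surface areas

SASA is Shrake–Rupley with a 1.4 Å probe: each solvent-expanded sphere
is sampled with a deterministic Fibonacci lattice (default 960 points;
no RNG, bit-reproducible) and a point is accessible when outside every
neighbouring expanded sphere. Radii are Bondi-type (C 1.70, N 1.55,
O 1.52, P 1.80, S 1.80, Fe 1.40 Å); unknown elements are an error, not
a default. Buried surface area between two disjoint groups is
SASA(A) + SASA(B) − SASA(A∪B) with third-party atoms excluded from all
three terms. Verification: the closed form for an isolated atom, the
spherical-cap closed form for two overlapping spheres, additivity,
symmetry, monotone decay with separation, and ≤1% agreement with a
10,000-point evaluation (doubling the density moves totals by <0.5%).
Different radius sets shift absolute BSAs by a few percent, which is
why interface areas should be compared at the ±5% level.

## Operator threading and clash scanning

Threading is rigid by construction: at each substituted position the
standard geometry of the new base is placed in the frame fitted to the
old base; backbone and sugar atoms through C1′ are bit-identical to the
template (asserted atom-wise). Because standard frames of ideally
paired bases coincide up to the dyad, one rule covers
purine↔pyrimidine swaps: the new base lands as if forming an ideal
Watson–Crick pair with the untouched partner, which is what rigid
interactive mutation produces. Substituting position k on strand c
automatically substitutes the complement at the paired strand-d
position. No minimisation, repacking or relaxation follows.

The clash scan reports, for every base atom (optionally only modelled
ones), protein heavy atoms within 4.0 Å; a record is repulsive below
2.85 Å regardless of chemistry, with N/O–N/O pairs in 2.6–2.85 Å
additionally flagged as possible H-bonds rather than certain clashes
(close polar approaches are judged repulsive by default because rigid
threading cannot vouch for geometry that would make them favourable).
Verdicts are monotone in the cutoff, and identity threading changes no
contact classification.

## The synthetic fiber generator

`build_fiber_bdna` is first-class, tested code, not a fixture. It
places base pairs by composing per-step rigid-body parameters (exactly
the algebra the analyzer inverts, so generator/analyzer closure is
structural) and attaches to each base a single frozen sugar–phosphate
repeating unit expressed in the base-pair frame; the complementary
strand is the unit's image under the pair dyad.

The unit was derived once, by the shipped
`scripts/derive_fiber_template.py`: an exact C2′-endo deoxyribose
(pseudorotation phase 162°, amplitude 35°, standard bond lengths and
angles, substituent chirality matched to the chemical component
dictionary), then a four-parameter torsion-space fit (χ, γ, β, helix
axis offset) under 36.0° twist / 3.38 Å rise helical symmetry,
targeting B_I phosphodiester torsions, canonical O3′–P connectivity
(1.607 Å) and cross-strand minor-groove P–P of 11.75 Å at offsets
−3/−4, with penalties keeping all other cross-strand distances above
11 Å. The solved unit is canonical B-DNA: χ −111°, γ +56°, δ +143°,
α −66°, ζ −102°, ε−ζ −95°, phosphorus 9.5 Å from the axis. The axis
offset implies a constant slide of −0.864 Å in the default step, which
keeps the duplex straight around a fixed axis; the calibration is
frozen (the 11.7 Å reference is an empirical property of regular
B-DNA, not a formula, so it is built in once and never revisited).

Defaults are therefore: twist 36.0°, rise 3.38 Å, roll/tilt/shift 0,
slide −0.8642 Å, propeller 0°, C2′-endo sugars, 5′-hydroxyl termini.
The default build of any sequence is straight, entirely B_I, pairs
perfectly, and shows a flat minor-groove profile averaging 11.78 Å.

Perturbations:

- per-step roll/twist/rise overrides enter the frame chain directly and
  are recovered exactly by the analyzer (closure tested to
  0.2°/0.01 Å over random sequences of length 10–40);
- per-nucleotide ε/ζ overrides rotate the 3′-phosphate group about the
  C3′–O3′ bond (ε) and the O5′ about the O3′–P bond (ζ). This is the
  minimal local change that flips the classified state without touching
  sugars or pairing; the strain is absorbed by the neighbour's O5′–C5′
  bond, which is chemically distorted at overridden positions —
  acceptable for fixtures exercising the classifier, not a model of
  real B_II energetics;
- nonzero propeller rotates the two bases of a pair in opposite senses
  about the pair long axis (bases only; the backbone stays on the fiber
  path, so the glycosidic bond stretches slightly at large propeller);
- optional Gaussian coordinate jitter, the generator's only randomised
  feature, is controlled by an explicit seed.

Probe groups (point atom, Lys/Arg/His-like heads) are placed along the
outward ray through a groove anchor so that the closest approach equals
the requested distance within 0.05 Å. For groove targets the distance
is measured to the groove floor (base atoms) — the sugar O4′ rim may
then sit slightly closer, as it does for real edge-on minor-groove
binders; for phosphate targets it is measured to all atoms. Placements
that would overlap the duplex raise an error.

### What the generator does and does not emulate

It reproduces the geometric structure the analysis assumes — helical
symmetry, standard base pairing, B_I backbone, calibrated groove
dimensions — and gives exact ground truth for round-trip testing. It
has no sequence-dependent structure (all sequences get the same
backbone), no thermal disorder unless jitter is requested, no
sequence-dependent flexibility model, no solvent, and its bent variants
distort O3′–P connectivity slightly rather than re-relaxing the
backbone. Passing tests on synthetic duplexes therefore validate the
measurement machinery, not claims about how real sequences deform.

## Problem sizes and numerical choices

The default test suite runs entirely on synthetic duplexes (10–40 bp,
≤ ~1600 atoms) with 960-point SASA spheres except where convergence is
itself under test; dihedral and superposition oracles use 1e-6°/1e-6 Å
agreement thresholds; groove and contact oracles are exact
(brute-force equality). Comparisons against deposited crystal
structures live in a separate regression module that fetches them from
the PDB archive and skips when it is unreachable. Tie-breaks worth
noting: altloc ties go to the ascending letter; pair matching prefers
more N/O contacts, then C1′–C1′ distance closest to 10.4 Å; the twist
sign at a 180° bend is taken from the hinge construction's mid-frame.

## Known limitations

- Distance-only contact chemistry (no angular criteria, no waters):
  "H-bond" means a compatible heavy-atom pair at H-bond range.
- Pisa-style interface areas depend on the radius set; agreement with
  published BSAs is expected at the ±5% level, not exactly.
- Threading is rigid; a repulsive verdict means "not accommodated in
  this pose", not a free-energy statement, and near-cutoff polar
  contacts are genuinely ambiguous (flagged, not resolved).
- The B_I/B_II band is a convention; census counts near the band edge
  can move by one or two phosphates as the band changes, which is why
  the band is configuration, not constant.
- No groove-depth, curvilinear-axis widths, A/Z-form classification, or
  Hoogsteen/wobble typing beyond `other`.
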