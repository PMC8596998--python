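# Methods

## The structural model

The builder produces idealized cross-β steric-zipper assemblies: flat
antiparallel β-sheets of identical peptide strands, stacked so that
adjacent sheets meet through either a dry (apolar, Phe) or a wet (polar,
Tyr/Cys) interface.  For sequences that strictly alternate apolar and
polar residues — FYFCFYF is the motivating case — each strand presents all
Phe side chains on one face and all Tyr/Cys on the other, so a single
sheet geometry supports both interface types; successive interfaces must
then alternate dry/wet, and the builder rejects layouts that do not.

Coordinates live in a fixed right-handed frame: strand axis x, in-sheet
strand stacking y, sheet normal z.  Residues are numbered 1-based within
each strand.

### Strand geometry

Each strand is generated as an exact two-fold screw: residue i+1 is
residue i rotated 180° about the strand axis and translated along it.
Backbone atom positions for the repeating unit are derived once per
(φ, rise) at run time:

- bond lengths are ideal (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å) and
  the peptide bond is planar trans (ω = 180°);
- the peptide-unit angles at C and N are solved (1-D root find) so that
  the consecutive Cα–Cα distance equals the template `rise` exactly
  (default 3.45 Å).  This compresses those angles to ≈99° — a deliberate
  idealization: a textbook trans peptide unit gives a 3.8 Å virtual Cα–Cα
  bond, and the exact-rise contract is what makes the assembly's
  by-construction metrics (4.75 Å inter-strand spacing, 10.8 Å mean-plane
  separation, interface purity) sharp, machine-precision test oracles;
- the default torsions are φ = −143°, ψ = +143°.  An exactly flat
  (zero-twist) strand with equal unit angles requires ψ = −φ; (−143, 143)
  is the nearest point of the β basin on that diagonal to the classic
  antiparallel values.  The template validates φ ∈ [−180°, −90°],
  ψ ∈ [90°, 180°], rise ∈ [3.2, 3.6] Å and the ψ = −φ constraint;
- Cα atoms pleat ±0.615 Å about the screw axis (a by-product of the exact
  screw solution), so consecutive side chains point to alternating faces;
  Cβ placement is tetrahedral with L-amino-acid chirality.

Side chains are built by internal coordinates: full rings for Phe/Tyr
(χ1 trans by default, ring torsion χ2 = 95°), Sγ (+ thiol H) for Cys;
every other standard residue is reduced to Cβ (none for Gly).  χ2 = 95°
rather than the rotamer-library modal ≈80° because the packed dry
interface needs the extra clearance: the minimum non-bonded distance in a
built assembly is 1.83 Å at 95° but would dip to 1.74 Å at 80°, below the
1.8 Å floor the geometry promises.  A `chi1_rule` on the template can
alternate χ1 states (e.g. trans / gauche−) between successive strands.

The C-terminus is amide-capped by default (an `NT` nitrogen at the
position the next backbone N would occupy), matching Rink-amide synthesis
chemistry; the cap also provides the ψ dihedral of the final residue.

### Sheets and assemblies

Sheets stack strand copies along y at the inter-strand spacing; odd
strands are flipped head-to-tail about the sheet normal, which preserves
the in-register column structure (the FYFCFYF palindrome maps onto
itself) and the face identity of the side chains.  Assemblies stack
sheets along z, flipping each sheet about the strand axis as its
interface labels demand, and translate each sheet so the **mean Cα
plane** sits exactly at k × inter-sheet spacing.  Sheets are flat (no
twist, no stagger): twist in real assemblies emerges from dynamics, which
is out of scope here; the synthetic-trajectory generator imposes it
parametrically instead.

### Disulfides

`add_disulfides` pairs each unpaired Cys Sγ across a wet interface with
its geometrically nearest unpaired partner (ties broken by sheet, then
strand index — the choice is deterministic but arbitrary, as no pairing
rule is dictated by the chemistry at this resolution).  Both sulfurs move
symmetrically along the S–S axis to a 2.05 Å bond and thiol hydrogens are
removed; the Cβ–Sγ bonds inherit whatever stretch that implies.  The
operation is idempotent, records pairs on the assembly, and warns (rather
than fails) when an interface offers no facing Cys.

### File format

PDB via MDAnalysis.  Chain IDs recycle A–Z a–z 0–9, so identity beyond 62
strands is carried in the 4-character segment ID (hex sheet + 3-digit
strand), which the reader prefers; SSBOND records are standard, and a
REMARK 99 SSPAIR line per bond (keyed by segment ID) keeps the pairing
lossless under chain-ID recycling.  Coordinates round-trip to the PDB's
10⁻³ Å precision.  The scheme caps at 16 sheets × 1000 strands.

## Trajectory metrics

All metrics are plain functions of a coordinate frame plus the topology
assembly.  Gyration radius is mass-weighted (frozen atomic weights).
RMSD optionally superposes by Kabsch SVD.  Inter-sheet distance offers
the representative-pair mode (central Cα of the central strand of each
sheet, ties toward lower indices) and the mean-planes mode (distance
between least-squares Cα planes along their mean normal); both are
invariant under rigid motion of the frame.

β structure uses a dihedral+contact rule rather than a hydrogen-bond
DSSP: a residue counts as β when φ ∈ [−180°, −45°], ψ (mod 360°) ∈
[45°, 225°], and its Cα has a cross-strand Cα neighbour within 5.5 Å.
Eligible residues are those with both dihedrals defined; the fraction is
β-labelled / eligible, and a frame with no eligible residues scores 0.
The rule is frozen; it is calibrated to β-dominated zipper assemblies and
is not a general secondary-structure assignment.

χ1 = dihedral(N, Cα, Cβ, γ-heavy-atom), classified on [0°, 360°) as
gauche+ [0, 120), trans [120, 240), gauche− [240, 360) — an exhaustive,
exclusive partition.  Residues lacking the γ atom are flagged
unclassified, not guessed.

RMSIP between two windows diagonalises the per-window covariance of the
selected (typically Cα) coordinates after superposing every frame onto a
common reference — the earliest frame across both windows, with a
content-based tie-break so the measure is exactly symmetric — and sums
squared inner products of the top-k eigenvectors (k = 10 by default, the
community convention).  Windows must exceed k frames and k must not
exceed the 3n available modes.

## WAXS reduction

q is computed with the exact wide-angle relation q = (4π/λ)sin(θ/2),
θ = atan(r/D); no small-angle approximation.  Radial folding averages
pixel intensities into 0.005 Å⁻¹ bins by default (the observed peak
spacings, ≥0.21 Å⁻¹, span >40 bins); empty bins are dropped, and the
count-weighted bin sums conserve total intensity exactly.  Azimuthal
profiles use 2° bins with azimuth 0 along the detector +x axis.  Peak
detection is scipy `find_peaks` with a prominence threshold expressed as
a fraction of the profile's dynamic range, refined by three-point
parabolic interpolation.  Assignment compares d = 2π/q against the
model's inter-sheet and inter-strand spacings at 10% relative tolerance;
unmatched peaks stay "other".  Detector calibration (beam centre,
distance) is taken as known input; standard-based calibration is out of
scope.

## Assay arithmetic

Atomic weights are frozen at four decimals; reported masses round to one
decimal to match characterisation conventions.  Adduct m/z is
(M + Σ adduct)/z with the H/Na atom masses (electron mass neglected —
three orders below the printed precision).  The loss tangent is returned
in both conventions (G″/G′ and G′/G″) because hydrogel reports sometimes
print "tan δ" for the stiffness ratio G′/G″; the package labels rather
than silently corrects.

The CAC break-point fit replaces graphical extrapolation with a
continuous two-segment least-squares model y = b₀ + b₁x + b₂·max(0, x−c):
the knot c is searched exhaustively over interior grid concentrations
(≥3 points per side) and refined by 60 golden-section iterations between
the neighbouring grid points.  Concentrations and intensities are
normalised internally, which conditions the solve and makes the fit
exactly equivariant under rescaling of either axis.  A two-segment model
that does not beat a single line in an F-test (2 extra parameters,
α = 0.05) yields a signalled "no breakpoint" result.  The optional
residual bootstrap (percentile CI) is seeded and deterministic.  Fitting
is on the linear concentration scale by default, matching the visual
break-point reading; `log_x=True` fits in log-concentration for
titrations spanning decades.

## Synthetic data: what it does and does not emulate

The generators provide ground-truth-known inputs, not physics:

- **Trajectories** start from the exactly built model (frame 0 is always
  unperturbed) and apply, in order, sinusoidal breathing of the
  inter-sheet separation, a linearly ramped per-strand twist about the
  fibril axis, and i.i.d. Gaussian positional noise (σ is the RMS
  displacement per atom, σ/√3 per coordinate; 0.3 Å default keeps the β
  fraction ≈0.99).  Noise comes after the geometric transforms so the
  recorded ground truth refers to the noiseless geometry.  Real MD has
  correlated, anharmonic fluctuations, solvent, and emergent (not
  imposed) twist — passing recovery tests here validates the metrics'
  arithmetic, not any thermodynamics.
- **Patterns** are sums of radially Gaussian rings (optional azimuthal
  arcs) on a constant background with optional Poisson sampling, on a
  512×512, 100 µm, 60 mm, Cu-Kα geometry — the paper-grade pixel size
  and wavelength with a shorter camera length so the whole wide-angle
  ring set (to q ≈ 1.6 Å⁻¹) fits a modest grid.  No structure factors,
  polarisation or absorption.
- **Titrations** are piecewise-linear with multiplicative Gaussian noise
  on a 20-point geometric grid spanning 10⁻⁵–10⁻³ mol/L around the
  break; real dye titrations saturate and have heteroscedastic optics.

Every generator is a pure function of (recipe, seed): identical inputs
give bit-identical outputs.

## Problem sizes and determinism

The test suite and the acceptance script run on desk-scale inputs chosen
as the package's own study conditions: the fifty-strand two-sheet model
(7600 atoms), the four-sheet ten-strand systems (~3000 atoms), 60–200
frame synthetic trajectories, 512² detector images, 100-replicate noise
studies.  Everything completes in well under a minute on one CPU; all
randomness flows from explicit seeds.

## Known limitations

- The strand geometry is an idealization tuned for exact testable
  invariants; its compressed peptide-unit angles and stretched Cβ–Sγ
  bonds after disulfide formation are not energy-minimised chemistry.
- Only F, Y and C get full side chains; other residues reduce to Cβ, so
  interface-purity censuses on other sequences consider Cβ only.
- The β assignment is dihedral+contact, not hydrogen-bond based; it will
  overcount β in tightly packed non-sheet geometries.
- The wet-interface disulfide pairing assumes near-in-register facing
  strands; heavily twisted frames may pair non-facing Cys.
- Fiber patterns are ring models; no attempt is made to simulate
  scattering from atomic coordinates.
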