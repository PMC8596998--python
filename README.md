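# crossbeta

Computational companion to the characterisation of aromatic-peptide
hydrogels built on the cross-β motif: the heptapeptide **FYFCFYF** (and its
PEG8 conjugate), in which a central cysteine inserted into the (FY)₃
scaffold allows disulfide cross-linking of the assembled material.  The
package is aimed at structural/biophysical researchers who need to (re)build
the steric-zipper models behind such studies, compute the standard
trajectory metrics on multi-frame coordinate sets, reduce wide-angle X-ray
scattering (WAXS) fiber patterns, and carry out the solution-assay
arithmetic (CAC break points, masses, conversions, rheology ratios) that
produces a paper's printed numbers.

## What it computes

**Steric-zipper builder** (`crossbeta.builder`) — idealized cross-β
assemblies from a one-letter sequence: antiparallel β-strands generated as
an exact 2-fold screw (rise 3.45 Å per residue along the strand axis),
stacked at 4.75 Å into flat sheets, and paired at 10.8 Å so that each
sheet-sheet interface is either *dry* (interdigitated Phe faces) or *wet*
(solvent-exposed Tyr/Cys faces).  Cys pairs facing across a wet interface
can be oxidised to 2.05 Å disulfides.  Models are written/read as standard
PDB (SSBOND records, segment IDs carrying sheet/strand identity).

**Trajectory metrics** (`crossbeta.traj_analysis`) — gyration radius, RMSD
(Kabsch), inter-sheet distance traces (representative Cα pair or
least-squares mean planes), χ1 rotamer states, a dihedral+contact
β-structure fraction, minimal S–S approach across an interface, average
structures, and the RMSIP overlap of essential-dynamics subspaces

```
RMSIP = sqrt( (1/k) Σᵢⱼ (uᵢ·vⱼ)² ),  u, v: top-k covariance eigenvectors
```

used as the convergence check between trajectory halves.

**WAXS reduction** (`crossbeta.waxs`) — exact wide-angle q calibration
(q = 4π/λ · sin(θ/2), θ = atan(r/D)), azimuthal averaging into I(q), peak
detection with parabolic refinement, azimuthal profiles on a chosen ring,
and assignment of d = 2π/q spacings to the model's inter-sheet (10.8 Å) and
inter-strand (4.75 Å) periodicities.

**Assay arithmetic** (`crossbeta.assays`) — continuous two-segment
break-point fitting of dye titrations (the CAC), average masses from Hill
formulas and ESI adduct m/z, molar↔mass conversions, Beer–Lambert
quantitation, swelling ratio q = (Ws−Wd)/Wd·100, and storage/loss modulus
ratios in both conventions.

**Synthetic data** (`crossbeta.synthetic_data`) — seeded generators with
machine-readable ground truth for perturbed-assembly trajectories, ring/arc
diffraction patterns and two-regime titration curves; they power the test
suite and the analysis scripts.

## Worked example

```python
from crossbeta import builder as B, traj_analysis as T, waxs as W, assays as A

asm = B.build_assembly(B.spec_st10_sh4(disulfide=True))
print(len(asm.disulfide_pairs))                     # 10
print(T.inter_sheet_distance(asm.xyz, asm, 1, 2))   # 10.800000000000002
print(T.beta_content(asm.xyz, asm)[0])              # 1.0

print(round(W.q_to_d(0.58), 1), round(W.q_to_d(1.32), 2))   # 10.8 4.76

m = A.formula_mass("C57H62N8O9S")
print(round(m, 1), round(A.adduct_mz(m, "+Na"), 1))         # 1035.2 1058.2
print(round(A.molar_to_mass(9.09e-5, "C57H62N8O9S"), 1))    # 94.1
print(round(A.modulus_ratio(970, 71).rigidity_ratio, 1))    # 13.7
```

The ten disulfides bridge the single wet interface of the four-sheet model;
the 10.8 Å mean-plane separation and full β content are exact by
construction.  The q→d conversions map the two strong fiber reflections to
the inter-sheet and inter-strand periodicities, and the assay lines
reproduce the characterisation arithmetic of the peptides (average mass,
sodium adduct, CAC mass concentration, gel rigidity ratio).

A command-line interface mirrors the library:

```bash
crossbeta build --sequence FYFCFYF --strands 10 --sheets 4 \
    --layout dry,wet,dry --disulfide --out model.pdb
crossbeta assay mass --formula C57H62N8O9S
```

## Analysis scripts

`analysis/01_build_models.py` … `04_solution_assays.py` are thin numbered
drivers that run the package end to end (model building, trajectory
metrics, WAXS reduction, assay fits) and write their tables under
`results/`.

## Documentation

`docs/methods.md` describes the geometric model, its assumptions and
deliberate idealizations, the numerical choices, and what the synthetic
generators do and do not emulate.
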