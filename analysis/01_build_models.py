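#!/usr/bin/env python
"""Build the three steric-zipper model systems and tabulate their geometry.

Constructs the two-sheet fifty-strand zipper (ST50_SH2), the four-sheet
ten-strand system with dry/wet/dry interfaces (ST10_SH4) and its
disulfide-oxidised variant (ST10_SH4 SS).  Coordinates go to scratch/models/
(bulky); the geometric summary table goes to results/.

Findings: all three models realise the cross-beta metrics exactly by
construction -- 4.75 A nearest inter-strand C-alpha spacing, 10.8 A
separation between mean C-alpha sheet planes, chemically pure dry (Phe) and
wet (Tyr/Cys) interfaces, and, in the SS variant, ten 2.05 A disulfides
bridging the single wet interface.
"""
import os
import sys

import numpy as np

sys.path.insert(0, os.path.join(os.path.dirname(__file__), os.pardir, "src"))

from crossbeta import builder as B
from crossbeta import pdbio

HERE = os.path.dirname(os.path.abspath(__file__))
MODELS = os.path.join(HERE, os.pardir, "scratch", "models")
RESULTS = os.path.join(HERE, os.pardir, "results")


def describe(name, asm):
    row = {"system": name, "atoms": asm.n_atoms, "sheets": asm.n_sheets,
           "strands_per_sheet": asm.n_strands(0),
           "disulfides": len(asm.disulfide_pairs)}
    ca0 = asm.ca_xyz(sheet=0, strand=0)
    ca1 = asm.ca_xyz(sheet=0, strand=1)
    row["interstrand_ca_A"] = float(
        np.linalg.norm(ca0[:, None] - ca1[None, :], axis=2).min())
    if asm.n_sheets > 1:
        row["intersheet_A"] = float(asm.mean_ca_plane_z(1)
                                    - asm.mean_ca_plane_z(0))
    return row


def main():
    os.makedirs(MODELS, exist_ok=True)
    os.makedirs(RESULTS, exist_ok=True)
    systems = {
        "FYFCFYF_ST50_SH2": B.build_assembly(B.spec_st50_sh2()),
        "FYFCFYF_ST10_SH4": B.build_assembly(B.spec_st10_sh4()),
        "FYFCFYF_ST10_SH4_SS": B.build_assembly(B.spec_st10_sh4(disulfide=True)),
    }
    rows = []
    for name, asm in systems.items():
        pdbio.write_coordinates(asm, os.path.join(MODELS, f"{name}.pdb"))
        rows.append(describe(name, asm))
        print(f"{name}: {rows[-1]}")

    import pandas as pd
    pd.DataFrame(rows).to_csv(os.path.join(RESULTS, "model_geometry.csv"),
                              index=False)
    print(f"wrote {RESULTS}/model_geometry.csv and PDB models to {MODELS}/")


if __name__ == "__main__":
    main()
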