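#!/usr/bin/env python
"""Reduce a synthetic fiber-diffraction pattern and assign its peaks.

Generates a Poisson-noised 2D pattern carrying the four observed wide-angle
rings (q = 0.58, 1.05, 1.32, 1.53 1/A), the first with a mild equatorial
arc anisotropy; folds it radially, detects and assigns peaks against the
built zipper model, and extracts the azimuthal profile of the first ring.

Findings (seed 1): all four rings are recovered within one 0.005 1/A bin;
q1 maps to the 10.8 A inter-sheet separation, q3 to the 4.75 A inter-strand
repeat, while q2 and q4 stay unassigned ("other"); the azimuthal profile of
q1 shows the imposed equatorial maxima 180 degrees apart.
"""
import os
import sys

import numpy as np

sys.path.insert(0, os.path.join(os.path.dirname(__file__), os.pardir, "src"))

import pandas as pd

from crossbeta import builder as B
from crossbeta import synthetic_data as S
from crossbeta import waxs as W

HERE = os.path.dirname(os.path.abspath(__file__))
RESULTS = os.path.join(HERE, os.pardir, "results")
SEED = 1


def main():
    os.makedirs(RESULTS, exist_ok=True)
    rings = (S.RingSpec(0.58, intensity=30.0,
                        arcs=((90.0, 25.0, 1.0), (270.0, 25.0, 1.0))),
             S.RingSpec(1.05, intensity=12.0),
             S.RingSpec(1.32, intensity=20.0),
             S.RingSpec(1.53, intensity=10.0))
    pat, truth = S.make_pattern(S.PatternRecipe(rings=rings, poisson=True,
                                                seed=SEED))
    prof = W.radial_fold(pat)
    pd.DataFrame({"q_invA": prof.q, "intensity": prof.intensity,
                  "count": prof.counts}).to_csv(
        os.path.join(RESULTS, "waxs_radial_profile.csv"), index=False)

    peaks = W.detect_peaks(prof, 0.1)
    model = B.build_assembly(B.spec_st10_sh4())
    assignments = W.assign_peaks(peaks, model)
    df = pd.DataFrame([{"q_invA": a.q_peak, "d_A": a.d, "label": a.label}
                       for a in assignments])
    df.to_csv(os.path.join(RESULTS, "waxs_peak_assignments.csv"), index=False)
    print(df.to_string(index=False,
                       formatters={"q_invA": "{:.3f}".format,
                                   "d_A": "{:.2f}".format}))

    az, inten = W.azimuthal_profile(pat, 0.58, 0.02)
    pd.DataFrame({"azimuth_deg": az, "intensity": inten}).to_csv(
        os.path.join(RESULTS, "waxs_azimuthal_q1.csv"), index=False)
    top2 = np.sort(az[np.argsort(inten)[-2:]])
    print(f"azimuthal maxima of q1 ring: {top2[0]:.0f} and {top2[1]:.0f} deg")


if __name__ == "__main__":
    main()
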