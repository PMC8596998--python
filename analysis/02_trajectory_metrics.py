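#!/usr/bin/env python
"""Trajectory metrics on a synthetic perturbed-assembly trajectory.

Generates a seeded trajectory of the four-sheet system with positional
noise, a twist ramp and breathing of the inter-sheet separation, then runs
the full metric battery: gyration radius, RMSD versus the initial model,
inter-sheet distance traces for all three interfaces, beta-structure
fraction, chi1 rotamer census, minimal S-S approach across the wet
interface, and the RMSIP convergence check between the trajectory halves.

Findings (seed 1): the beta fraction stays >= 0.97 at 0.3 A noise, the
breathing of the wet interface is recovered in the mean-plane distance
trace, >99% of side chains stay in their built trans rotamer, and the
two-halves RMSIP of a pure-noise trajectory is low (~0.25) -- the expected
baseline for uncorrelated fluctuations, against which genuinely converged
dynamics (RMSIP -> 1) would stand out.
"""
import os
import sys

import numpy as np

sys.path.insert(0, os.path.join(os.path.dirname(__file__), os.pardir, "src"))

import pandas as pd

from crossbeta import builder as B
from crossbeta import synthetic_data as S
from crossbeta import traj_analysis as T

HERE = os.path.dirname(os.path.abspath(__file__))
RESULTS = os.path.join(HERE, os.pardir, "results")
SEED = 1


def main():
    os.makedirs(RESULTS, exist_ok=True)
    rec = S.TrajectoryRecipe(spec=B.spec_st10_sh4(), n_frames=100,
                             noise_sigma=0.3, twist_rate=1.0,
                             breathing_amplitude=0.4, breathing_period=25,
                             seed=SEED)
    traj, topo, truth = S.make_trajectory(rec)
    ca = topo.names == "CA"

    rows = []
    for i, (t, f) in enumerate(zip(traj.times, traj.frames)):
        row = {"time_ns": t,
               "rg_A": T.radius_of_gyration(f, topo),
               "rmsd_ca_A": T.rmsd(f, traj.frames[0], selection=ca),
               "beta_fraction": T.beta_content(f, topo)[0],
               "true_intersheet_A": truth["inter_sheet"][i]}
        for k in range(3):
            row[f"intersheet_{k}{k+1}_A"] = T.inter_sheet_distance(
                f, topo, k, k + 1, "mean_planes")
        row["ss_min_approach_A"] = T.ss_min_approach(f, topo, 1)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(os.path.join(RESULTS, "trajectory_metrics.csv"), index=False)

    refs, states = T.chi1_states(traj.frames[-1], topo)
    chi1 = pd.Series([s for s in states if s is not None]).value_counts()

    half = traj.n_frames // 2
    rep = T.rmsip(traj.window(0, half), traj.window(half, traj.n_frames),
                  k=10, selection=ca)

    summary = {
        "beta_fraction_min": df.beta_fraction.min(),
        "wet_interface_mean_A": df.intersheet_12_A.mean(),
        "wet_interface_tracking_rmse_A": float(np.sqrt(np.mean(
            (df.intersheet_12_A - df.true_intersheet_A) ** 2))),
        "chi1_trans_fraction": chi1.get("trans", 0) / chi1.sum(),
        "rmsip_halves": rep.rmsip,
    }
    pd.Series(summary).to_csv(os.path.join(RESULTS, "trajectory_summary.csv"),
                              header=False)
    for k, v in summary.items():
        print(f"{k}: {v:.4g}")


if __name__ == "__main__":
    main()
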