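#!/usr/bin/env python
"""Ablation-recoil analysis: velocities, Kelvin-Voigt fits, group comparisons.

Reads the vertex tracks written by 01_simulate_datasets.py, fits each
junction, and writes per-track results plus the two condition comparisons
(knockdown vs control, overexpression vs control) under results/recoil/.
Reports retraction-velocity percent change with a Mann-Whitney p, and the
relaxation-time summaries (mean +/- s.d. and s.e.m.).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from epimech.io import comparison_to_dict, read_vertex_tracks
from epimech.recoil import analyze_tracks, results_to_frame
from epimech.stats import GroupSample, compare_groups, summarize

DATA = Path("results/data")
OUT = Path("results/recoil")

PAIRS = [("control_kd", "knockdown"), ("control_oe", "overexpression")]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    frames = {}
    for csv in sorted(DATA.glob("tracks_*.csv")):
        cond = csv.stem.removeprefix("tracks_")
        tracks = read_vertex_tracks(csv)
        df = results_to_frame(analyze_tracks(tracks))
        df.insert(0, "condition", cond)
        frames[cond] = df
        bad = int((~df["converged"]).sum())
        print(f"{cond}: {len(df)} fits ({bad} non-converged)")
    all_df = pd.concat(frames.values(), ignore_index=True)
    all_df.to_csv(OUT / "per_track_results.csv", index=False)

    report = {}
    for ctrl, treated in PAIRS:
        vel = compare_groups(
            GroupSample(ctrl, frames[ctrl]["velocity_um_s"].to_numpy()),
            GroupSample(treated, frames[treated]["velocity_um_s"].to_numpy()),
            test="mann-whitney")
        tau_groups = {}
        for cond in (ctrl, treated):
            df = frames[cond]
            tau_groups[cond] = GroupSample(
                cond, df.loc[df["converged"], "tau_s"].to_numpy())
        tau = compare_groups(tau_groups[ctrl], tau_groups[treated],
                             test="mann-whitney")
        key = f"{treated}_vs_{ctrl}"
        report[key] = {"velocity": comparison_to_dict(vel),
                       "tau": comparison_to_dict(tau)}
        print(f"\n{treated} vs {ctrl}:")
        print(f"  velocity change {vel.percent_change:+.1f}% "
              f"(Mann-Whitney p = {vel.p_value:.2e} {vel.stars})")
        for cond in (ctrl, treated):
            s = summarize(tau_groups[cond])
            sem = s.sd / np.sqrt(s.n)
            print(f"  tau[{cond}] = {s.mean:.1f} +/- {s.sd:.1f} s (s.d.), "
                  f"+/- {sem:.1f} s (s.e.m.), n = {s.n}")
        print(f"  tau change {tau.percent_change:+.1f}% "
              f"(p = {tau.p_value:.3f} {tau.stars})")
    (OUT / "comparisons.json").write_text(json.dumps(report, indent=1))


if __name__ == "__main__":
    main()
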