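#!/usr/bin/env python
"""Generate the synthetic study datasets for the downstream analyses.

Writes, under results/data/:

* vertex-track CSVs (+ ground-truth JSON sidecars) for four ablation
  conditions mirroring the two experiments being emulated --
  knockdown (n = 12, tau 12 s) vs its control (n = 17, tau 11 s) with a
  programmed 49% velocity decrease, and overexpression (n = 12, tau 8 s)
  vs its control (n = 17, tau 10 s) with a programmed 43% increase;
* epithelium z-stacks (TIFF) for 7 uniform-junction and 9 punctate-junction
  embryos, with junction-line sidecars;
* a clone/control apical-width table for 15 follicle-like units at a
  programmed constriction factor of 0.6.

Run from the repository root:  python analysis/01_simulate_datasets.py
"""

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from epimech.io import write_clone_sets, write_stack, write_tracks
from epimech.linescan import ImageStack
from epimech.synth import (EnsembleSpec, simulate_condition_ensemble,
                           synth_clone_widths, synth_epithelium_image)

SEED = 20260929
OUT = Path("results/data")

# velocity scale: control 0.100 um/s; programmed effects set via D at each tau
ABLATION_CONDITIONS = {
    "control_kd": dict(n_replicates=17, D_mean=1.31212, tau_mean=11.0),   # 0.100
    "knockdown": dict(n_replicates=12, D_mean=0.71966, tau_mean=12.0),    # 0.051
    "control_oe": dict(n_replicates=17, D_mean=1.21328, tau_mean=10.0),   # 0.100
    "overexpression": dict(n_replicates=12, D_mean=1.45374, tau_mean=8.0),  # 0.143
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    for name, pars in ABLATION_CONDITIONS.items():
        spec = EnsembleSpec(L0_mean=4.0, L0_cv=0.15, D_cv=0.2, tau_cv=0.15,
                            noise_sd=0.05, seed=int(rng.integers(2 ** 31)),
                            label=name, **pars)
        ens = simulate_condition_ensemble(spec)
        write_tracks(ens.tracks, OUT / f"tracks_{name}.csv")
        (OUT / f"tracks_{name}.ground_truth.json").write_text(json.dumps(
            {"spec": asdict(spec), "params": [asdict(p) for p in ens.params]},
            indent=1))
        print(f"{name}: {len(ens)} junction tracks "
              f"(mean generating tau {np.mean([p.tau for p in ens.params]):.1f} s)")

    for cond, n_embryos, punct in (("uniform", 7, 0.0), ("punctate", 9, 0.5)):
        for e in range(n_embryos):
            ep = synth_epithelium_image(n_cells=30, pixel_size=0.1,
                                        punctateness=punct,
                                        background_noise_sd=2.0, n_slices=5,
                                        seed=int(rng.integers(2 ** 31)))
            stem = OUT / f"epithelium_{cond}_{e:02d}"
            write_stack(ImageStack(data=ep.image, pixel_size=ep.pixel_size,
                                   z_step=ep.z_step), f"{stem}.tif")
            p0, p1 = ep.longest_junction()
            Path(f"{stem}.ground_truth.json").write_text(json.dumps(
                {"punctateness": punct,
                 "longest_junction_um": [list(map(float, p0)),
                                         list(map(float, p1))]}, indent=1))
        print(f"epithelium/{cond}: {n_embryos} five-slice stacks")

    sets = [synth_clone_widths(n_cells=40, clone_fraction=0.5,
                               constriction_factor=0.6, width_mean=3.0,
                               width_cv=0.15, unit_id=f"unit-{i:03d}",
                               seed=int(rng.integers(2 ** 31)))
            for i in range(15)]
    write_clone_sets(sets, OUT / "clone_widths.csv")
    print(f"clones: {len(sets)} units at programmed constriction 0.6")


if __name__ == "__main__":
    main()
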