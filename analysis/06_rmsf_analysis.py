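#!/usr/bin/env python
"""Side-chain RMSF across replicate trajectories and dRMSF between states.

Generates five-replicate synthetic trajectory sets for a quiet ground-like
condition and a fluctuation-enhanced M-like condition (larger positional
noise and more frequent conformer switching), computes per-residue
side-chain RMSF with replicate means and standard deviations, and reports
dRMSF = mean(M) - mean(ground).  A Gaussian-noise control verifies the
sigma*sqrt(3) closed form for per-atom fluctuations.

Writes results/rmsf_tables.csv and results/delta_rmsf.csv.
"""

import pathlib

import numpy as np
import pandas as pd

from helioproton.synthetic import TrajectorySpec, gen_trajectory_set
from helioproton.trajectory import rmsf, rmsf_table

RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"

CONDITIONS = {
    # stay-probabilities and noise emulate quiet vs agitated H-bond networks
    "ground": dict(transition=((0.99, 0.01), (0.10, 0.90)), noise_sigma=0.10),
    "M_state": dict(transition=((0.92, 0.08), (0.04, 0.96)), noise_sigma=0.22),
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    tables = {}
    for ci, (name, kw) in enumerate(CONDITIONS.items()):
        spec = TrajectorySpec(seed=900 + ci, n_replicates=5, n_frames=1000,
                              distance_means=((3.0,), (7.5,)),
                              distance_sds=((0.15,), (0.4,)), **kw)
        trajs, _ = gen_trajectory_set(spec)
        tables[name] = rmsf_table(trajs)
        print(f"[{name}] per-residue side-chain RMSF (mean +/- SD over 5 runs):")
        for res in tables[name].mean.index:
            print(f"  {res:>6s}: {tables[name].mean[res]:.3f} +/- "
                  f"{tables[name].sd[res]:.3f} A")

    combined = pd.concat(
        {name: pd.DataFrame({"mean": t.mean, "sd": t.sd})
         for name, t in tables.items()},
        names=["condition", "residue"],
    )
    combined.to_csv(RESULTS / "rmsf_tables.csv")

    delta = tables["M_state"].delta(tables["ground"])
    delta.to_csv(RESULTS / "delta_rmsf.csv")
    print("\ndRMSF (M_state - ground), positive = enhanced fluctuation:")
    print(delta.to_string(float_format=lambda v: f"{v:+.3f}"))

    sigma = 0.2
    control = TrajectorySpec(seed=990, n_frames=1000, noise_sigma=sigma,
                             transition=((1.0, 0.0), (0.0, 1.0)), start="state:0",
                             distance_sds=((0.0,), (0.0,)))
    trajs, _ = gen_trajectory_set(control)
    r = rmsf(trajs[0], align=None)
    print(f"\nGaussian control: per-atom RMSF {r.mean():.4f} A vs "
          f"sigma*sqrt(3) = {sigma * np.sqrt(3):.4f} A "
          f"({abs(r.mean() / (sigma * np.sqrt(3)) - 1):.1%} off at 1000 frames)")


if __name__ == "__main__":
    main()
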