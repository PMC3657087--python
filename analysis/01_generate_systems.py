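#!/usr/bin/env python
"""Generate the synthetic study systems and write them to disk.

Builds two seeded replicas of the two-pose flavoenzyme-glucose-like system
(pose A = C2-oxidation mode, pose B = C3-oxidation mode, stationary pose-A
fraction 0.85) plus the Gaussian-cloud and ideal-backbone fixtures, and
stores structures (PDB), trajectories (frames text) and the analytic ground
truth (JSON) under scratch/systems/.
"""

import json
from pathlib import Path

import numpy as np

from glycotraj.model_io import write_frames, write_parameter_sidecar, \
    write_pdb
from glycotraj.synthetic import (GaussianTrajSpec, TwoPoseSpec,
                                 gen_gaussian_trajectory,
                                 gen_ideal_backbones, gen_two_pose_trajectory)

OUT = Path("scratch/systems")
OUT.mkdir(parents=True, exist_ok=True)
N_FRAMES = 2000
SEEDS = (1, 2)

for seed in SEEDS:
    spec = TwoPoseSpec(n_frames=N_FRAMES, seed=seed)
    top, stream, truth = gen_two_pose_trajectory(spec)
    prefix = OUT / f"twopose_run{seed}"
    write_pdb(f"{prefix}.pdb", top, next(iter(stream)))
    write_frames(f"{prefix}.frames", stream)
    # charges, LJ parameters and united-carbon flags have no PDB fields
    write_parameter_sidecar(f"{prefix}_params.dat", top)
    with open(f"{prefix}_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, default=float)
    print(f"run {seed}: {top.n_atoms} atoms, {N_FRAMES} frames, "
          f"pose A fraction {truth['pose_fraction_a']}, "
          f"pose RMSD {truth['pose_rmsd']:.3f} nm")

gspec = GaussianTrajSpec(n_atoms=3, masses=np.full(3, 12.011),
                         covariance=np.full(9, 0.0025), n_frames=20_000,
                         seed=42)
gtop, gstream, closed = gen_gaussian_trajectory(gspec)
write_pdb(OUT / "gaussian.pdb", gtop, next(iter(gstream)))
write_frames(OUT / "gaussian.frames", gstream)
print(f"gaussian cloud: closed-form Schlitter entropy "
      f"{closed:.2f} J/mol/K (oracle for 03)")

for kind, n in (("helix", 20), ("hairpin", 16), ("extended", 12)):
    top, frame = gen_ideal_backbones(kind, n)
    write_pdb(OUT / f"{kind}.pdb", top, frame)
print(f"wrote systems to {OUT}")
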