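# glycotraj

Trajectory-derived statistics for flavoenzyme–sugar complexes, built around
the question of how a sugar oxidoreductase such as pyranose dehydrogenase
(PDH) can oxidize d-glucose at either the C2 or the C3 position: which ring
hydrogen sits close enough to the flavin N5 for hydride transfer, which
active-site residues hydrogen-bond the sugar's hydroxyls, how much
conformational entropy the ligand loses on binding, and whether
electrostatics or shape complementarity drives binding.

The package implements, as a tested library with a thin CLI, every
statistic that kind of study derives from molecular-dynamics trajectories:

* **Superposition** — Kabsch least-squares fitting (proper rotations only),
  RMSD time series with independent fit/measure selections (e.g. fit on the
  protein backbone, measure on the ligand), per-atom RMSF about the
  trajectory mean, and the isotropic Debye–Waller conversion
  B = (8π²/3)⟨Δr²⟩ between crystallographic B-factors and RMSF.
* **Schlitter conformational entropy** —
  S = ½ k_B ln det[**1** + (k_B T e²/ħ²)**Mσ**], with **σ** the covariance
  of atom-positional fluctuations accumulated in a single streaming pass
  after a rototranslational fit (on the protein backbone, keeping the
  ligand's rigid-body freedom, or on the ligand itself).
* **Hydrogen bonds** — the strict geometric criterion
  (H···acceptor < 0.25 nm AND donor–H–acceptor angle > 135°), aggregated to
  per-partner-residue occupancy tables whose rows sum over atom pairs and
  can exceed 100%.
* **Virtual hydrogens** — united-atom CH carbons carry no explicit
  hydrogen; the hydride-transfer geometry needs one, reconstructed by
  tetrahedral completion of the three heavy-atom bonds.
* **Distance statistics** — per-frame series (including "N\_δ or N\_ε,
  whichever is closer" minimum modes), normalized histograms, and
  below-cutoff fractions with strict inequality.
* **Nonbonded energetics** — ligand–surrounding electrostatic energies with
  the Tironi reaction-field correction (ε_RF = 61, cutoff 1.4 nm) and
  C12/C6 Lennard-Jones terms, with block-averaging error estimates for
  correlated series and quadrature error propagation over replica runs.
* **Secondary structure** — Kabsch–Sander (DSSP) assignment
  (H/G/I/E/B/T/S/C) from backbone hydrogen-bond patterns, with geometric
  amide-H reconstruction.
* **Synthetic systems** — generators with analytic ground truth: Gaussian
  atom clouds (closed-form entropy oracle), a protein-like scaffold whose
  glucose-like ligand switches between a C2-oxidation and a C3-oxidation
  binding pose via a Markov chain, ideal helix/hairpin/extended backbones,
  and AR(1) series for the block-averaging oracle.

## Worked example

The `analysis/` scripts run the full study on the synthetic two-pose
system (two seeded 2000-frame replicas, pose-A fraction 0.85):

```sh
python analysis/01_generate_systems.py
python analysis/02_structure_stability.py
python analysis/03_conformational_entropy.py
python analysis/04_interactions.py
python analysis/05_energetics.py
```

which prints, among other things:

```
run 1: backbone RMSD stays at 0.005 nm; ligand RMSD bimodal, 83.5% of frames near the reference pose
run 1: S(protein fit) = 126.0, S(self fit) = 98.5 J/mol/K (rototranslational freedom accounts for the difference)
HC2-N5 below 0.3 nm in 83.9% of frames (pose-A / C2-oxidation fraction; generator truth 85%)
H-bond occupancy, averaged over runs:
  Gln-392      7.9% (O4)
  Val-511    152.1% (O1/O2)
  His-512     13.7% (O3)
  His-556     67.0% (O6)
  Total      240.8% ()
combined: V_ES = -4.81 +/- 0.26, V_vdW = -29.51 +/- 0.01 kJ/mol (vdW dominates binding)
```

Reading this like the real study: the protein scaffold is rigid while the
ligand hops between two poses (the bimodal ligand RMSD after a backbone
fit); the virtual HC2 hydrogen is within hydride-transfer range of the
flavin N5 exactly as often as the ligand occupies pose A; Val-511 is bound
through two simultaneous hydroxyl contacts, so its occupancy row exceeds
100%; the ligand entropy after a protein fit exceeds the self-fit value by
the rigid-body contribution; and binding is dominated by the van der Waals
term.  Tables land under `results/`, regenerable inputs under `scratch/`.

The same stages are available one-off from the shell, e.g.

```sh
glycotraj synth twopose --seed 3 --n-frames 500 --out-prefix scratch/demo
glycotraj hbonds --traj scratch/demo.frames --ref scratch/demo.pdb
glycotraj entropy --traj scratch/demo.frames --ref scratch/demo.pdb \
    --entropy-sel "resname GLC" --fit-mode backbone
glycotraj run --config config.yaml   # the whole bundle from a YAML config
```

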