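# Methods

This note documents the models and procedures glycotraj implements, the
defaults and why they were chosen, what the synthetic systems do and do not
emulate, and the numerical choices that matter.

## Units and data model

All internal quantities are in nm, ps, amu, kJ/mol and elementary charges;
PDB Ångström values are converted at the I/O boundary.  A `Topology` holds
atoms (name, element, mass, charge, Lennard-Jones C6/C12, united-carbon
flag), residues, and bonds; bonds come from CONECT records when present,
otherwise from a built-in amino-acid template.  Charges and LJ parameters
have no PDB fields and are supplied by a plain-text parameter sidecar
(one row per residue/atom name).  Atom indices are 0-based internally;
user-facing selections use the residue numbers as authored in the file.
Distances use the minimum-image convention whenever a frame carries a
rectangular box, plain Euclidean distances otherwise.

## Rigid-body fitting and fluctuations

Superposition uses the Kabsch SVD solution with the determinant correction
that excludes reflections; configurations with fewer than three or
(near-)collinear fit atoms raise a degenerate-fit error (detected through
the singular values of the centered, weighted coordinate cloud).  RMSD and
RMSF use uniform weights by default — the analyses are phrased in terms of
"backbone atoms", not mass-weighted coordinates — with an optional weight
vector.  RMSF is measured about each atom's trajectory-mean position after
per-frame fitting, consistent with the fluctuation definition underlying
the entropy covariance; profiles from replica runs combine by arithmetic
mean.  The B-factor conversion uses the isotropic 3D convention
B = 8π²⟨Δr²⟩/3, i.e. RMSF(nm) = √(3B/8π²)/10 for B in Å².

## Schlitter entropy

The estimator is S = ½ k_B ln det[1 + (k_B T e²/ħ²) M σ] with e Euler's
number and σ the covariance of Cartesian fluctuations about the mean,
reported as a molar quantity (× Avogadro).  Numerics:

* The covariance accumulates streaming first and second moments (single
  pass, constant memory in the number of frames); frames are equally
  weighted, with no convergence extrapolation.
* Each frame is first least-squares fitted to the reference (the first
  frame) either on a separate subset — fitting on the protein backbone
  keeps the ligand's translational/rotational freedom inside σ — or on the
  entropy atoms themselves, which isolates the conformational part.  The
  first convention always gives the larger value; both are reported.
* The log-determinant is evaluated through the eigenvalues of the
  symmetrized mass-weighted matrix M^{1/2} σ M^{1/2} (similar to M σ),
  summing log1p(c·λ) terms: for 3N in the hundreds-to-thousands the
  determinant itself would overflow, and the symmetric form keeps the
  eigenproblem well conditioned.  Eigenvalues below −10⁻¹⁰ (relative)
  raise an error; small negative round-off is clipped to zero.
* Constants in SI: k_B = 1.380649e-23 J/K, ħ = 1.0545718e-34 J·s,
  1 amu = 1.66053907e-27 kg; molar output uses R = N_A·k_B.

For Boltzmann-sampled positions of a harmonic oscillator the estimate is
an upper bound on the exact quantum entropy
S/R = ξ/(e^ξ−1) − ln(1−e^(−ξ)), ξ = ħω/k_BT, approached as ξ → 0; the test
suite checks the bound at ξ ∈ {0.1, 1, 5}.  Note the bound holds for the
true variance; at ξ = 0.1 the Schlitter excess (~0.03%) is comparable to
the sampling noise of a 10⁵-sample variance, so bound violations of a few
hundredths of a percent in any single draw are sampling effects, not
estimator defects.

## Hydrogen bonds, virtual hydrogens, distances

A hydrogen bond is present when the hydrogen–acceptor distance is strictly
below 0.25 nm and the donor–hydrogen–acceptor angle (vertex at the
hydrogen) strictly above 135°.  The built-in chemistry table takes N and O
with a bonded hydrogen as donors and N and O as acceptors; both are
overridable.  Occupancy tables count frame × atom-pair events per partner
residue, so a residue engaged through two simultaneous pairs can exceed
100% — this additive convention is what makes per-residue rows comparable
across binding modes.  Occupancies from replica runs combine by arithmetic
mean (a partner absent from a run contributes zero).

United-atom CH (methylidyne) carbons get a virtual hydrogen at a
configurable 0.1 nm (ideal sp³ C–H; the force-field literature does not
fix a value for a virtual site) along the direction opposite the
normalized sum of the three carbon→heavy-neighbor unit vectors.  This
tetrahedral completion coincides with the direction making equal angles to
the three neighbors only to first order in the distortion of the center;
for the near-ideal geometries of sugar rings the difference is well below
a degree.  A planar neighbor arrangement whose unit vectors cancel has no
defined completion and raises an error.

Distance series support one-to-one and min-over-set modes (the latter for
"N_δ or N_ε, whichever is closer" style questions); virtual hydrogens are
resolved on the fly when a site name like `HC2` has no explicit atom.
Below-cutoff fractions use strict inequality; histograms are normalized to
unit integral with bin edges on multiples of the bin width (default
0.005 nm, which resolves the 0.25 and 0.30 nm thresholds cleanly).

## Nonbonded energetics and error estimation

Per-configuration ligand–surrounding energies use a single straight cutoff
at 1.4 nm (the pair-list bookkeeping schemes of MD engines are an
integration optimization, not part of the energy definition) and sum only
cross-group pairs — intra-ligand terms are excluded.  Electrostatics adds
the Tironi reaction-field correction for a homogeneous dielectric beyond
the cutoff at zero ionic strength, C_rf = (2ε−2)/(2ε+1), with ε_RF = 61 as
appropriate for SPC water; the conversion factor is 138.9355 kJ·mol⁻¹·nm·e⁻².
Lennard-Jones cross terms use geometric-mean combination of C6 and C12, the
united-atom force-field convention.

Statistical errors of time averages use block averaging with doubling
block sizes (1, 2, 4, …, n/4); the reported error is the first plateau
value (change < 5% between consecutive doublings) or, failing a plateau,
the maximum of the curve.  For an AR(1) process this recovers the
√((1+φ)/(1−φ)) inflation of the naive standard error.  Estimates at large
block sizes rest on few blocks and are themselves noisy (χ²-distributed),
which is why the plateau rule scans from small blocks upward.  Replica
runs combine as the unweighted mean of run means with errors propagated in
quadrature, √(Σeᵢ²)/k.

## Kabsch–Sander secondary structure

Backbone hydrogen bonds are scored with the Kabsch–Sander electrostatic
model E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol (distances
in Å), bond when E < −0.5; near-fused geometries are clamped.  Amide
hydrogens are reconstructed 0.1 nm from N anti-parallel to the preceding
carbonyl unless an explicit H is bonded to the backbone N — united-atom
trajectories may carry none — and proline never donates.  n-turns
(i+n → i, n = 3, 4, 5) in back-to-back pairs produce G/H/I helices;
parallel/antiparallel bridges follow the standard pattern definitions,
with ladders of ≥ 2 consecutive bridges scored E and isolated bridges B —
so deleting one strand of a two-strand sheet demotes the partner, the
bridge-vs-strand distinction that matters for substrate-binding loops.
Hydrogen bonds may cross chains; sequence patterns (turns, the ±1 windows
of the bridge definitions) require chain continuity, with CA–CA > 0.5 nm
or non-consecutive residue numbers treated as segment boundaries.  Final
per-residue priority is H > E > B > G > I > T > S > C.  On the ideal
fixtures the assignment agrees with the reference DSSP implementation
bundled in mdtraj at ≥ 95% of residues (the residual disagreement sits at
strand termini, where implementations differ on terminal bridges).

## Synthetic systems: what they emulate, and what they do not

The generators replace unavailable production trajectories with systems
whose expected observables are known analytically from the specification —
truth values are computed from the generator parameters, never from the
generated samples.

* **Gaussian clouds** sample i.i.d. from a prescribed (diagonal or full)
  covariance; the closed-form Schlitter value of that covariance is the
  estimator oracle.
* **The two-pose system** is a ~215-atom abstract scaffold — not a
  homology model — with a flavin-like group (atom N5), the active-site
  cast of residues (Gln-392, Tyr-510, Val-511, His-512, His-556) around a
  glucose-like ring, and an alanine shell for bulk.  The ligand switches
  between pose A (virtual HC2 at 0.27 nm from N5, the C2-oxidation mode)
  and pose B (HC3 at 0.26 nm, C3-oxidation) through a two-state Markov
  chain with stationary pose-A fraction p (default 0.85) and mixing rate
  0.6 (sum of the two transition probabilities; 1 would be i.i.d. draws).
  The default mixing keeps pose dwells of ~10 frames while letting 5000
  frames estimate fractions to about ±0.01 (one standard error);
  RMSD-plateau demonstrations of long-lived poses should lower the switch
  rate explicitly.  Hydrogen-bond pairs are prescribed per pose with a
  persistence probability q; donor hydrogens point along the
  donor–acceptor line when formed (H···A = 0.2 nm, angle 180°) and
  directly away otherwise.  Acceptor atoms are placed by a deterministic
  search that keeps the exact donor geometry while clearing every other
  ligand heavy atom (no LJ clashes), keeping acceptors ≥ 0.45 nm apart,
  and rejecting any candidate whose induced hydrogen orientations could
  satisfy the criterion with an unintended acceptor; the generator then
  re-validates all margins (≥ 0.02 nm / 10°) before emitting frames and
  raises if the requested noise (default σ = 0.002 nm per atom) would
  violate them.  Expected observables follow from p and q alone:
  fraction(HC2–N5 < 0.3 nm) = p, occupancy = 100·q·P(pose).
* **Ideal backbones** are built by internal-coordinate chain extension
  with standard bond lengths/angles; the helix uses φ = −57°, ψ = −47°,
  strands φ = −139°, ψ = +135°.  The hairpin's second strand is placed by
  solving for the rigid transform that realizes the antiparallel hydrogen-
  bond register (target N/O positions from the first strand's donor and
  acceptor geometry, Kabsch fit, short deterministic polish).
* **AR(1) series** provide the block-averaging oracle with known marginal
  variance σ²/(1−φ²) and statistical inefficiency (1+φ)/(1−φ).

What passing these tests shows: the estimators, counting rules and error
formulas are implemented correctly at realistic problem sizes.  What it
does not show: anything about real flavoenzyme energetics or force-field
accuracy.  The scaffold's charge/LJ set is schematic (neutral dipolar
groups, uncharged apolar atoms) — chosen so hydrogen bonds are net
attractive and binding is van-der-Waals-dominated, mirroring the
qualitative physics, not any fitted force field — and the generated
dynamics has no solvent, no correlated backbone motion and no force-field
energy surface.  Statements about the real enzyme require real
trajectories, fed in through the same PDB/frames interfaces.

## Pipeline conventions and problem sizes

`pipeline.run_paper_suite` validates every selection before any stage runs
(fail fast), writes one TSV per table, logs each stage with seed, package
version and parameters to `log.jsonl`, and removes partial output on any
stage failure, so a bundle on disk is always complete and reproducible —
identical configurations yield byte-identical bundles.  Aggregation over
replica runs is encoded once: entropies as mean ± between-run standard
deviation, energies as mean with propagated block errors, occupancies as
arithmetic means of rows.

Default problem sizes — 2000-frame replicas in the analysis scripts,
5000 frames for two-pose recovery checks, 10⁵ samples for the entropy,
histogram and block-averaging oracles — are the sizes at which the
statistical tolerances above (2% entropy, ±0.02 fractions, ±3 occupancy
points, 10–15% error recovery) correspond to roughly two standard errors
of the respective estimators, keeping the full suite in the
tens-of-seconds range.

## Known limitations

* PDB support is deliberately narrow: one model per frame, no altlocs or
  insertion codes, no binary trajectory formats (the `FrameStream`
  contract accommodates them if added).
* The selection grammar covers conjunctions/disjunctions of residue name,
  residue number, atom name, element, index ranges and the `backbone`/
  `protein` keywords — not a full query language.
* π-helix and 3₁₀ codes follow standard precedence but are not exercised
  by dedicated fixtures; DSSP bulge linking is not implemented.
* Energetics recomputes per-configuration pair sums; it is not an MD
  engine and has no PME/Ewald, bonded terms or free-energy estimators.
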