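"""Ligand-surrounding nonbonded energies and block-averaging error estimates.

Pair energies are recomputed per configuration with a single straight cutoff:
Lennard-Jones C12/C6 terms plus Coulomb with the Tironi reaction-field
correction for a homogeneous dielectric continuum beyond the cutoff
(zero ionic strength),

    V_es(r) = f q_i q_j [ 1/r + C_rf r^2 / (2 R_c^3) - (1 + C_rf/2)/R_c ],
    C_rf    = (2 eps - 2) / (2 eps + 1),

with f = 138.9355 kJ mol^-1 nm e^-2 and the defaults the GROMOS/SPC setup
uses: R_c = 1.4 nm and eps_rf = 61.  Only cross (group-group) pairs are
summed; intra-ligand terms are excluded.

Statistical errors of time averages over correlated series use block
averaging with doubling block sizes; multi-run results combine as the mean
of run means with errors propagated in quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model_io import Frame, Selection, Topology, minimum_image

__all__ = [
    "COULOMB_CONSTANT",
    "NonbondedParams",
    "EnergyEstimate",
    "reaction_field_constant",
    "pair_energies",
    "block_average",
    "combine_runs",
]

COULOMB_CONSTANT = 138.9355  # kJ mol^-1 nm e^-2


@dataclass
class NonbondedParams:
    """Cutoff (nm), reaction-field dielectric, and optional parameter overrides.

    Per-atom charge/C6/C12 default to the topology's values (from the
    parameter sidecar); LJ cross terms use geometric-mean combination.
    """

    cutoff: float = 1.4
    eps_rf: float = 61.0

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.eps_rf < 1:
            raise ValueError("eps_rf must be >= 1")


def reaction_field_constant(eps_rf: float) -> float:
    """C_rf = (2 eps - 2)/(2 eps + 1); 0 for vacuum, -> 1 as eps -> infinity."""
    return (2.0 * eps_rf - 2.0) / (2.0 * eps_rf + 1.0)


@dataclass
class EnergyEstimate:
    mean: float                      # kJ/mol
    error: float                     # kJ/mol
    n_samples: int
    block_curve: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self):
        if self.error < 0:
            raise ValueError("error must be >= 0")


def pair_energies(frame: Frame, group_l: Selection, group_s: Selection,
                  topology: Topology, params: NonbondedParams | None = None
                  ) -> tuple[float, float]:
    """Electrostatic (reaction-field) and Lennard-Jones cross energies, kJ/mol.

    Sums over all ligand-surrounding pairs within the cutoff, minimum-image
    when the frame has a box.  Groups must be disjoint.
    """
    if params is None:
        params = NonbondedParams()
    il = np.asarray(group_l.indices, int)
    js = np.asarray(group_s.indices, int)
    if len(il) == 0 or len(js) == 0:
        raise ValueError("empty group selection")
    if np.intersect1d(il, js).size:
        raise ValueError("ligand and surrounding groups overlap")
    q = topology.charges()
    c6 = np.array([a.lj_c6 for a in topology.atoms])
    c12 = np.array([a.lj_c12 for a in topology.atoms])

    coords = frame.coordinates
    delta = coords[il][:, None, :] - coords[js][None, :, :]
    if frame.box is not None:
        delta = minimum_image(delta, frame.box)
    r2 = np.sum(delta * delta, axis=-1)
    rc = params.cutoff
    within = r2 < rc * rc
    if not within.any():
        return 0.0, 0.0
    r2 = r2[within]
    r = np.sqrt(r2)

    qq = np.outer(q[il], q[js])[within]
    crf = reaction_field_constant(params.eps_rf)
    v_es = COULOMB_CONSTANT * np.sum(
        qq * (1.0 / r + crf * r2 / (2.0 * rc ** 3) - (1.0 + crf / 2.0) / rc))

    c6_ij = np.sqrt(np.outer(c6[il], c6[js]))[within]
    c12_ij = np.sqrt(np.outer(c12[il], c12[js]))[within]
    inv_r6 = 1.0 / r2 ** 3
    v_vdw = np.sum((c12_ij * inv_r6 - c6_ij) * inv_r6)
    return float(v_es), float(v_vdw)


def block_average(series: np.ndarray) -> EnergyEstimate:
    """Mean and block-averaged standard error of a (possibly correlated) series.

    Block sizes double from 1 to n/4; at each size the estimate is the
    standard error of the block means.  The reported error is the first
    plateau value (change < 5% between consecutive doublings), else the
    maximum over the curve.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    if n < 4:
        raise ValueError(f"need >= 4 samples for block averaging, got {n}")
    mean = float(series.mean())
    curve: list[tuple[int, float]] = []
    size = 1
    while size <= n // 4:
        n_blocks = n // size
        blocks = series[:n_blocks * size].reshape(n_blocks, size).mean(axis=1)
        se = float(blocks.std(ddof=1) / math.sqrt(n_blocks))
        curve.append((size, se))
        size *= 2
    error = curve[-1][1]
    for (s0, e0), (s1, e1) in zip(curve, curve[1:]):
        denom = max(abs(e1), 1e-300)
        if abs(e1 - e0) / denom < 0.05:
            error = e1
            break
    else:
        error = max(e for _, e in curve)
    return EnergyEstimate(mean=mean, error=error, n_samples=n, block_curve=curve)


def combine_runs(estimates: list[EnergyEstimate]) -> EnergyEstimate:
    """Equal-weight average over independent runs with error propagation.

    error = sqrt(sum e_i^2) / k, the standard propagation of independent
    per-run errors through the arithmetic mean.
    """
    if not estimates:
        raise ValueError("no estimates to combine")
    k = len(estimates)
    mean = float(np.mean([e.mean for e in estimates]))
    error = float(math.sqrt(sum(e.error ** 2 for e in estimates)) / k)
    return EnergyEstimate(mean=mean, error=error,
                          n_samples=sum(e.n_samples for e in estimates))
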