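"""Schlitter quasi-harmonic conformational entropy from atom-positional fluctuations.

The Schlitter estimate is an upper bound on the conformational entropy of a
solute, computed from the mass-weighted covariance matrix of Cartesian
fluctuations:

    S = (1/2) k_B ln det[ 1 + (k_B T e^2 / hbar^2) M sigma ]

with e Euler's number, M the 3N-diagonal mass matrix and sigma the covariance
of atom positions about their means, accumulated after a rototranslational
least-squares fit of every frame (either on a separate subset such as the
protein backbone, or on the entropy atoms themselves).  Output is molar
(J mol^-1 K^-1).

The determinant is evaluated through the eigenvalues of the symmetrized
matrix M^{1/2} sigma M^{1/2} (similar to M sigma), summing log1p terms —
3N can be large and the determinant itself would overflow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model_io import Frame, FrameStream, Selection
from .superpose import kabsch_fit

__all__ = [
    "KB", "HBAR", "AMU", "AVOGADRO", "R_GAS",
    "CovarianceAccumulator",
    "EntropyResult",
    "accumulate",
    "schlitter_entropy",
    "schlitter_entropy_1d",
    "quantum_harmonic_entropy",
    "entropy_convergence",
]

KB = 1.380649e-23          # J/K
HBAR = 1.0545718e-34       # J s
AMU = 1.66053907e-27       # kg
AVOGADRO = 6.02214076e23   # 1/mol
R_GAS = KB * AVOGADRO      # J/(mol K)
_NM2 = 1e-18               # m^2 per nm^2


@dataclass
class EntropyResult:
    s: float                 # J mol^-1 K^-1
    n_atoms: int
    n_frames: int
    temperature: float       # K
    fit_mode: str = "none"


@dataclass
class CovarianceAccumulator:
    """Streaming first/second moments of fitted coordinates (single pass,
    constant memory in the number of frames).

    ``fit_mode`` is ``"none"``, ``"self"`` (fit on the entropy atoms
    themselves) or ``"subset"`` (fit on ``fit_selection``, e.g. the protein
    backbone, so the ligand's rototranslational freedom stays in sigma).
    """

    n_dof: int
    fit_mode: str = "none"
    fit_selection: Selection | None = None
    n_frames: int = 0
    sum: np.ndarray = field(default=None)  # type: ignore[assignment]
    outer_sum: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.fit_mode not in ("none", "self", "subset"):
            raise ValueError(f"unknown fit mode {self.fit_mode!r}")
        if self.fit_mode == "subset" and self.fit_selection is None:
            raise ValueError("fit_mode 'subset' requires a fit_selection")
        if self.sum is None:
            self.sum = np.zeros(self.n_dof)
        if self.outer_sum is None:
            self.outer_sum = np.zeros((self.n_dof, self.n_dof))

    def add(self, x: np.ndarray) -> None:
        x = np.asarray(x, float).ravel()
        if x.size != self.n_dof:
            raise ValueError(f"expected {self.n_dof} dof, got {x.size}")
        self.sum += x
        self.outer_sum += np.outer(x, x)
        self.n_frames += 1

    def add_batch(self, xs: np.ndarray) -> None:
        """Accumulate a (n_frames, n_dof) block in one BLAS call."""
        xs = np.asarray(xs, float).reshape(-1, self.n_dof)
        self.sum += xs.sum(axis=0)
        self.outer_sum += xs.T @ xs
        self.n_frames += xs.shape[0]

    def finalize(self) -> np.ndarray:
        """Covariance matrix sigma_ij = <x_i x_j> - <x_i><x_j>, symmetrized."""
        if self.n_frames == 0:
            raise ValueError("no frames accumulated")
        mean = self.sum / self.n_frames
        cov = self.outer_sum / self.n_frames - np.outer(mean, mean)
        return 0.5 * (cov + cov.T)


def accumulate(acc: CovarianceAccumulator, frame: Frame, sel: Selection,
               reference: Frame | None = None) -> CovarianceAccumulator:
    """Fit ``frame`` per the accumulator's fit mode, then update moments."""
    coords = frame.coordinates
    if acc.fit_mode != "none":
        if reference is None:
            raise ValueError(f"fit mode {acc.fit_mode!r} requires a reference frame")
        fit_idx = (sel.indices if acc.fit_mode == "self"
                   else acc.fit_selection.indices)
        tf = kabsch_fit(coords[fit_idx], reference.coordinates[fit_idx])
        coords = tf.apply(coords)
    acc.add(coords[sel.indices])
    return acc


def _entropy_from_eigenvalues(eigvals: np.ndarray, temperature: float) -> float:
    """Molar Schlitter entropy from eigenvalues of M^{1/2} sigma M^{1/2}
    expressed in amu nm^2."""
    c = KB * temperature * math.e ** 2 / HBAR ** 2 * AMU * _NM2
    return 0.5 * R_GAS * float(np.sum(np.log1p(c * eigvals)))


def schlitter_entropy(cov: np.ndarray, masses: Sequence[float],
                      temperature: float = 300.0, fit_mode: str = "none",
                      n_frames: int = 0) -> EntropyResult:
    """Schlitter entropy (J mol^-1 K^-1) from a finalized covariance matrix.

    ``cov`` is 3N x 3N in nm^2, ``masses`` the N atomic masses in amu.
    """
    masses = np.asarray(masses, float)
    cov = np.asarray(cov, float)
    n = masses.size
    if cov.shape != (3 * n, 3 * n):
        raise ValueError(f"covariance is {cov.shape}, expected {(3 * n, 3 * n)}")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    sqrt_m = np.sqrt(np.repeat(masses, 3))
    weighted = sqrt_m[:, None] * cov * sqrt_m[None, :]
    eigvals = np.linalg.eigvalsh(0.5 * (weighted + weighted.T))
    tol = 1e-10 * max(1.0, float(eigvals[-1]))
    if eigvals[0] < -tol:
        raise ValueError(
            f"covariance not positive semi-definite: smallest eigenvalue "
            f"{eigvals[0]:.3e} amu nm^2")
    eigvals = np.clip(eigvals, 0.0, None)
    s = _entropy_from_eigenvalues(eigvals, temperature)
    return EntropyResult(s=s, n_atoms=n, n_frames=n_frames,
                         temperature=temperature, fit_mode=fit_mode)


def schlitter_entropy_1d(variance_nm2: float, mass_amu: float,
                         temperature: float = 300.0) -> float:
    """Closed-form single-degree-of-freedom Schlitter entropy (J mol^-1 K^-1).

    Scalar oracle for the matrix path: (R/2) ln(1 + kB T e^2 m sigma^2 / hbar^2).
    """
    c = KB * temperature * math.e ** 2 / HBAR ** 2 * mass_amu * AMU * variance_nm2 * _NM2
    return 0.5 * R_GAS * math.log1p(c)


def quantum_harmonic_entropy(xi: float) -> float:
    """Exact molar entropy of a 1D quantum harmonic oscillator.

    ``xi`` = hbar omega / kB T.  S/R = xi/(e^xi - 1) - ln(1 - e^-xi).
    The Schlitter estimate is an upper bound on this for Boltzmann-sampled
    positions, approaching it as xi -> 0.
    """
    if xi <= 0:
        raise ValueError("xi must be > 0")
    return R_GAS * (xi / math.expm1(xi) - math.log(-math.expm1(-xi)))


def entropy_convergence(frames: FrameStream, sel: Selection,
                        masses: Sequence[float], temperature: float,
                        checkpoints: Sequence[int], fit_mode: str = "none",
                        fit_selection: Selection | None = None,
                        reference: Frame | None = None) -> list[EntropyResult]:
    """Schlitter entropy evaluated at increasing frame-count checkpoints.

    For stationary input the series is non-decreasing in expectation — the
    covariance fills in as phase space is sampled — which makes it the
    standard convergence diagnostic for Schlitter estimates.
    """
    checkpoints = list(checkpoints)
    if any(b <= a for a, b in zip(checkpoints, checkpoints[1:])):
        raise ValueError("checkpoints must be strictly increasing")
    masses = np.asarray(masses, float)
    if masses.size != len(sel):
        raise ValueError("one mass per selected atom required")
    acc = CovarianceAccumulator(n_dof=3 * len(sel), fit_mode=fit_mode,
                                fit_selection=fit_selection)
    results: list[EntropyResult] = []
    pending = iter(checkpoints)
    target = next(pending, None)
    n_seen = 0
    for frame in frames:
        if reference is None:
            reference = frame
        accumulate(acc, frame, sel, reference)
        n_seen += 1
        while target is not None and n_seen == target:
            if acc.n_frames < 2:
                results.append(EntropyResult(0.0, len(sel), acc.n_frames,
                                             temperature, fit_mode))
            else:
                results.append(schlitter_entropy(acc.finalize(), masses,
                                                 temperature, fit_mode,
                                                 acc.n_frames))
            target = next(pending, None)
    if target is not None:
        warnings.warn(f"trajectory ended at {n_seen} frames before checkpoint "
                      f"{target}; reporting final value", stacklevel=2)
        results.append(schlitter_entropy(acc.finalize(), masses, temperature,
                                         fit_mode, acc.n_frames))
    return results
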