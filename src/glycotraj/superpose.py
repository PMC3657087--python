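"""Rigid-body least-squares fitting and fluctuation statistics.

Implements the Kabsch superposition (proper rotations only), RMSD time
series with independent fit/calculation selections, per-atom RMSF profiles
measured about the trajectory-mean positions, and the isotropic
Debye-Waller conversion between crystallographic B-factors and RMSF,
B = (8 pi^2 / 3) <Delta r^2>.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_io import Frame, FrameStream, Selection

__all__ = [
    "RigidTransform",
    "FluctuationProfile",
    "DegenerateFitError",
    "kabsch_fit",
    "rmsd",
    "rmsd_series",
    "rmsf_profile",
    "average_profiles",
    "bfactor_to_rmsf",
    "rmsf_to_bfactor",
]


class DegenerateFitError(ValueError):
    """Raised when a superposition problem is under-determined."""


@dataclass
class RigidTransform:
    """Proper rotation + translation, applied as ``x -> x @ R.T + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class FluctuationProfile:
    """Per-atom RMSF (nm) and mean positions over a fitted trajectory."""

    atom_indices: np.ndarray
    rmsf: np.ndarray
    mean_positions: np.ndarray


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray,
               weights: np.ndarray | None = None) -> RigidTransform:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Returns the proper rigid transform minimizing the weighted sum of squared
    deviations; reflections are excluded by the determinant correction of the
    SVD solution.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference shapes differ")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateFitError(f"need >= 3 fit atoms, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("negative fit weights")
        total = w.sum()
        if total <= 0:
            raise DegenerateFitError("all fit weights are zero")
        w = w / total
    mob_c = mobile - w @ mobile
    ref_c = reference - w @ reference
    # collinearity/coincidence check via the rank of the weighted cloud
    spread = np.linalg.svd(mob_c * np.sqrt(w)[:, None], compute_uv=False)
    if spread[1] < 1e-10 * max(spread[0], 1e-30) or spread[0] < 1e-12:
        raise DegenerateFitError("fit atoms are collinear or coincident")
    h = (mob_c * w[:, None]).T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = math.copysign(1.0, np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = w @ reference - rot @ (w @ mobile)
    return RigidTransform(rotation=rot, translation=trans)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (unfitted) root-mean-square deviation between coordinate sets."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(frames: FrameStream, reference: Frame, fit_sel: Selection,
                calc_sel: Selection, weights: np.ndarray | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame RMSD of ``calc_sel`` after fitting each frame on ``fit_sel``.

    Fitting on the protein backbone while measuring on the ligand reproduces
    the standard ligand-stability analysis.  Returns (times ps, rmsd nm).
    """
    if len(calc_sel) == 0:
        raise ValueError("calc selection is empty")
    if len(fit_sel) == 0:
        raise ValueError("fit selection is empty")
    ref_fit = reference.coordinates[fit_sel.indices]
    ref_calc = reference.coordinates[calc_sel.indices]
    times, values = [], []
    for frame in frames:
        tf = kabsch_fit(frame.coordinates[fit_sel.indices], ref_fit, weights)
        moved = tf.apply(frame.coordinates[calc_sel.indices])
        times.append(frame.time)
        values.append(rmsd(moved, ref_calc))
    return np.array(times), np.array(values)


def rmsf_profile(frames: FrameStream, sel: Selection, fit_sel: Selection | None = None,
                 reference: Frame | None = None) -> FluctuationProfile:
    """Per-atom RMSF about the trajectory-mean position after per-frame fitting.

    When ``fit_sel`` is given each frame is first superposed on ``reference``
    (default: the first frame) using those atoms.  Two passes over the stream:
    one for the mean structure, one for the deviations.
    """
    first = None
    for first in frames:
        break
    if first is None:
        raise ValueError("empty trajectory")
    if reference is None:
        reference = first

    def fitted(frame: Frame) -> np.ndarray:
        if fit_sel is None:
            return frame.coordinates[sel.indices]
        tf = kabsch_fit(frame.coordinates[fit_sel.indices],
                        reference.coordinates[fit_sel.indices])
        return tf.apply(frame.coordinates)[sel.indices]

    n = 0
    mean = np.zeros((len(sel), 3))
    for frame in frames:
        mean += fitted(frame)
        n += 1
    if n < 2:
        raise ValueError("RMSF undefined for fewer than 2 frames")
    mean /= n
    sq = np.zeros(len(sel))
    for frame in frames:
        d = fitted(frame) - mean
        sq += np.sum(d * d, axis=1)
    return FluctuationProfile(atom_indices=sel.indices.copy(),
                              rmsf=np.sqrt(sq / n), mean_positions=mean)


def average_profiles(profiles: list[FluctuationProfile]) -> FluctuationProfile:
    """Arithmetic mean of RMSF profiles from independent runs."""
    if not profiles:
        raise ValueError("no profiles")
    idx = profiles[0].atom_indices
    for p in profiles[1:]:
        if not np.array_equal(p.atom_indices, idx):
            raise ValueError("profiles cover different atom sets")
    return FluctuationProfile(
        atom_indices=idx.copy(),
        rmsf=np.mean([p.rmsf for p in profiles], axis=0),
        mean_positions=np.mean([p.mean_positions for p in profiles], axis=0))


_B_TO_MSF = 3.0 / (8.0 * math.pi ** 2)  # <dr^2> in A^2 per unit B


def bfactor_to_rmsf(b) -> np.ndarray | float:
    """RMSF (nm) from an isotropic crystallographic B-factor (A^2)."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("negative B-factor")
    out = np.sqrt(_B_TO_MSF * b) / 10.0  # A -> nm
    return float(out) if out.ndim == 0 else out


def rmsf_to_bfactor(rmsf_nm) -> np.ndarray | float:
    """Inverse of :func:`bfactor_to_rmsf`: B (A^2) from RMSF in nm."""
    r = np.asarray(rmsf_nm, dtype=float)
    if np.any(r < 0):
        raise ValueError("negative RMSF")
    out = (r * 10.0) ** 2 / _B_TO_MSF
    return float(out) if out.ndim == 0 else out
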