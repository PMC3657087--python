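"""Kabsch-Sander secondary-structure assignment (DSSP codes H/G/I/E/B/T/S/C).

Backbone hydrogen bonds are scored with the Kabsch-Sander electrostatic
model,

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol,

distances in Angstrom between the carbonyl (C, O) of the acceptor and the
amide (N, H) of the donor; a bond is declared when E < -0.5 kcal/mol.
Amide hydrogens are always reconstructed from geometry (0.1 nm from N,
anti-parallel to the preceding carbonyl C=O) unless an explicit H is bonded
to the backbone N, since united-atom trajectories may carry none.  Proline
never donates.

From the bond pattern: n-turns (i+n donates to i, n = 3,4,5) give G/H/I
stretches, bridges give B, ladders of >= 2 consecutive bridges give E
(so removing one strand of a two-strand sheet demotes the partner to B/C),
turns give T, bends (CA pseudo-angle > 70 deg) give S.  Final per-residue
priority: H > E > B > G > I > T > S > C.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .model_io import AMINO_ACIDS, Frame, FrameStream, Topology

__all__ = [
    "SSAssignment",
    "HBOND_ENERGY_CUTOFF",
    "backbone_hbond_energy",
    "assign",
    "assign_trajectory",
]

HBOND_ENERGY_CUTOFF = -0.5       # kcal/mol
_KS_FACTOR = 0.084 * 332.0       # kcal A / mol, q1*q2*332
CHAIN_BREAK_CA = 0.5             # nm
_AMIDE_NH = 0.1                  # nm


@dataclass
class SSAssignment:
    """Residue x frame matrix of one-letter codes."""

    resids: np.ndarray
    resnames: list[str]
    codes: np.ndarray  # (n_residues, n_frames), dtype '<U1'


class _Backbone:
    """Backbone coordinate bundle for the protein residues of one frame."""

    def __init__(self, frame: Frame, topology: Topology):
        residues = [r for r in topology.residues if r.resname in AMINO_ACIDS]
        self.resids = np.array([r.resid for r in residues])
        self.resnames = [r.resname for r in residues]
        nres = len(residues)
        self.n = np.full((nres, 3), np.nan)
        self.ca = np.full((nres, 3), np.nan)
        self.c = np.full((nres, 3), np.nan)
        self.o = np.full((nres, 3), np.nan)
        self.h = np.full((nres, 3), np.nan)
        explicit_h = np.zeros(nres, dtype=bool)
        for k, res in enumerate(residues):
            for i in res.atom_indices:
                name = topology.atoms[i].name
                if name == "N":
                    self.n[k] = frame.coordinates[i]
                    for j in topology.bonded_neighbors(i):
                        if topology.atoms[j].element == "H":
                            self.h[k] = frame.coordinates[j]
                            explicit_h[k] = True
                elif name == "CA":
                    self.ca[k] = frame.coordinates[i]
                elif name == "C":
                    self.c[k] = frame.coordinates[i]
                elif name == "O":
                    self.o[k] = frame.coordinates[i]
        self.valid = ~np.isnan(self.n[:, 0] + self.ca[:, 0]
                               + self.c[:, 0] + self.o[:, 0])
        for k in np.flatnonzero(~self.valid):
            warnings.warn(f"residue {self.resnames[k]}-{self.resids[k]}: "
                          "missing backbone atom, skipped", stacklevel=3)
        # segment ids: break where consecutive CA-CA > 0.5 nm or either invalid
        self.segment = np.zeros(nres, dtype=int)
        seg = 0
        for k in range(1, nres):
            d = np.linalg.norm(self.ca[k] - self.ca[k - 1])
            if not (self.valid[k] and self.valid[k - 1]) or not d <= CHAIN_BREAK_CA \
                    or self.resids[k] != self.resids[k - 1] + 1:
                seg += 1
            self.segment[k] = seg
        # reconstruct amide hydrogens where absent
        for k in range(nres):
            if explicit_h[k] or not self.valid[k] or self.resnames[k] == "PRO":
                continue
            if k == 0 or self.segment[k] != self.segment[k - 1] \
                    or not self.valid[k - 1]:
                continue  # segment start: no preceding carbonyl, cannot donate
            u = self.c[k - 1] - self.o[k - 1]
            self.h[k] = self.n[k] + _AMIDE_NH * u / np.linalg.norm(u)
        self.can_donate = self.valid & ~np.isnan(self.h[:, 0]) \
            & np.array([rn != "PRO" for rn in self.resnames])

    def hbond_energy(self, donor: int, acceptor: int) -> float:
        """Kabsch-Sander energy (kcal/mol) of N-H(donor) ... O=C(acceptor)."""
        if not (self.can_donate[donor] and self.valid[acceptor]):
            return 0.0
        to_a = 10.0  # nm -> Angstrom
        r_on = np.linalg.norm(self.o[acceptor] - self.n[donor]) * to_a
        r_ch = np.linalg.norm(self.c[acceptor] - self.h[donor]) * to_a
        r_oh = np.linalg.norm(self.o[acceptor] - self.h[donor]) * to_a
        r_cn = np.linalg.norm(self.c[acceptor] - self.n[donor]) * to_a
        if min(r_on, r_ch, r_oh, r_cn) < 0.5:
            return -9.9  # atoms essentially fused; treat as bonded (clamped)
        return _KS_FACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)

    def bond_matrix(self) -> np.ndarray:
        """Boolean matrix: bonds[d, a] == True if N-H of d bonds C=O of a."""
        nres = len(self.resids)
        bonds = np.zeros((nres, nres), dtype=bool)
        for d in range(nres):
            if not self.can_donate[d]:
                continue
            for a in range(nres):
                if abs(d - a) <= 1:
                    continue
                # prune by CA distance (9 A as in the original algorithm)
                if np.linalg.norm(self.ca[d] - self.ca[a]) > 0.9:
                    continue
                if self.hbond_energy(d, a) < HBOND_ENERGY_CUTOFF:
                    bonds[d, a] = True
        return bonds


def backbone_hbond_energy(frame: Frame, topology: Topology,
                          donor: int, acceptor: int) -> float:
    """Kabsch-Sander H-bond energy between two protein residues (by position
    in the protein residue list), kcal/mol; < -0.5 declares a bond."""
    bb = _Backbone(frame, topology)
    if donor == acceptor:
        raise ValueError("self hydrogen bonds are excluded by definition")
    return bb.hbond_energy(donor, acceptor)


def _bends(bb: _Backbone) -> np.ndarray:
    nres = len(bb.resids)
    bend = np.zeros(nres, dtype=bool)
    for i in range(2, nres - 2):
        if bb.segment[i - 2] != bb.segment[i + 2] or not bb.valid[i]:
            continue
        u = bb.ca[i] - bb.ca[i - 2]
        v = bb.ca[i + 2] - bb.ca[i]
        cosang = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
        if math.degrees(math.acos(min(1.0, max(-1.0, cosang)))) > 70.0:
            bend[i] = True
    return bend


def assign(frame: Frame, topology: Topology) -> tuple[np.ndarray, np.ndarray]:
    """One-frame Kabsch-Sander assignment.

    Returns (resids, codes) over the protein residues.
    """
    bb = _Backbone(frame, topology)
    nres = len(bb.resids)
    if nres < 5:
        raise ValueError(f"need >= 5 consecutive protein residues, got {nres}")
    bonds = bb.bond_matrix()
    same_seg = bb.segment[:, None] == bb.segment[None, :]

    def hb(d: int, a: int) -> bool:
        # hydrogen bonds may cross chains; sequence patterns check contiguity
        return 0 <= d < nres and 0 <= a < nres and bonds[d, a]

    # n-turns: residue i starts an n-turn if i+n donates back to i
    # (sequence-contiguous by definition)
    turn = {n: np.array([hb(i + n, i) and same_seg[i, i + n]
                         if i + n < nres else False
                         for i in range(nres)]) for n in (3, 4, 5)}

    helix = {n: np.zeros(nres, dtype=bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(1, nres - n):
            if turn[n][i - 1] and turn[n][i]:
                helix[n][i:i + n] = True

    # bridges
    par = {}
    anti = {}
    for i in range(1, nres - 1):
        if not same_seg[i - 1, i + 1]:
            continue
        for j in range(i + 3, nres - 1):
            if not same_seg[j - 1, j + 1]:
                continue
            if np.linalg.norm(bb.ca[i] - bb.ca[j]) > 0.9:
                continue
            if (hb(i + 1, j) and hb(j, i - 1)) or (hb(j + 1, i) and hb(i, j - 1)):
                par[(i, j)] = True
            if (hb(i + 1, j - 1) and hb(j + 1, i - 1)) or (hb(j, i) and hb(i, j)):
                anti[(i, j)] = True

    bridge = np.zeros(nres, dtype=bool)
    strand = np.zeros(nres, dtype=bool)
    for table, step in ((par, +1), (anti, -1)):
        for (i, j) in table:
            bridge[i] = bridge[j] = True
            if (i + 1, j + step) in table or (i - 1, j - step) in table:
                strand[i] = strand[j] = True
                other = (i + 1, j + step) if (i + 1, j + step) in table else (i - 1, j - step)
                strand[other[0]] = strand[other[1]] = True

    in_turn = np.zeros(nres, dtype=bool)
    for n in (3, 4, 5):
        for i in np.flatnonzero(turn[n]):
            in_turn[i + 1:i + n] = True
    bend = _bends(bb)

    codes = np.full(nres, "C", dtype="<U1")
    codes[bend] = "S"
    codes[in_turn] = "T"
    codes[helix[5]] = "I"
    codes[helix[3]] = "G"
    codes[bridge] = "B"
    codes[strand] = "E"
    codes[helix[4]] = "H"
    codes[~bb.valid] = "C"
    return bb.resids.copy(), codes


def assign_trajectory(frames: FrameStream, topology: Topology) -> SSAssignment:
    """DSSP codes as a residues x frames matrix."""
    columns = []
    resids = None
    for frame in frames:
        resids, codes = assign(frame, topology)
        columns.append(codes)
    if not columns:
        raise ValueError("empty trajectory")
    resnames = [r.resname for r in topology.residues if r.resname in AMINO_ACIDS]
    return SSAssignment(resids=resids, resnames=resnames,
                        codes=np.stack(columns, axis=1))
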