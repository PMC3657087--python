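"""Geometric hydrogen bonds, virtual united-atom hydrogens, and distance analyses.

A hydrogen bond is declared when the hydrogen-acceptor distance is lower than
0.25 nm AND the donor-hydrogen-acceptor angle (vertex at the hydrogen) is
larger than 135 degrees; both inequalities are strict.  Occupancies are
reported per partner residue as 100 x events / n_frames summed over all
distinct donor/acceptor atom pairs involving that residue, so a residue
engaged through two simultaneous atom pairs can exceed 100%.

United-atom force fields carry no aliphatic hydrogens; for hydride-transfer
geometry a virtual hydrogen is reconstructed on each CH (methylidyne) carbon
along the tetrahedral completion of its three heavy-atom bonds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .model_io import Frame, FrameStream, Selection, Topology, minimum_image

__all__ = [
    "HBondSpec", "HBondRecord", "OccupancyRow", "OccupancyTable",
    "DistanceSeries", "DistanceHistogram", "Site",
    "place_virtual_hydrogen", "virtual_site", "atom_sites", "resolve_sites",
    "distance_series", "fraction_below", "histogram",
    "detect_hbonds", "occupancy_table", "average_tables", "cross_hbond_spec",
]

DEFAULT_DISTANCE_CUTOFF = 0.25   # nm, hydrogen-acceptor
DEFAULT_ANGLE_CUTOFF = 135.0     # degrees, donor-hydrogen-acceptor
DEFAULT_CH_BOND = 0.1            # nm, virtual C-H bond length
DONOR_ELEMENTS = {"N", "O"}
ACCEPTOR_ELEMENTS = {"N", "O"}


# ---------------------------------------------------------------------------
# Virtual hydrogens


def place_virtual_hydrogen(center: int, frame: Frame, topology: Topology,
                           bond_length: float = DEFAULT_CH_BOND) -> np.ndarray:
    """Position of the implicit hydrogen on a united CH carbon.

    The carbon must be flagged ``is_united_carbon`` and have exactly three
    bonded heavy neighbors; the hydrogen is placed at ``bond_length`` from the
    carbon along the direction opposite the normalized sum of the three
    carbon->neighbor unit vectors (tetrahedral completion).
    """
    atom = topology.atoms[center]
    if not atom.is_united_carbon:
        raise ValueError(f"atom {center} ({atom.name}) is not a united carbon")
    heavy = [j for j in topology.bonded_neighbors(center)
             if topology.atoms[j].element != "H"]
    if len(heavy) != 3:
        raise ValueError(
            f"united carbon {atom.name} has {len(heavy)} heavy neighbors, "
            "methylidyne geometry requires exactly 3")
    c = frame.coordinates[center]
    units = []
    for j in heavy:
        v = frame.coordinates[j] - c
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            raise ValueError(f"neighbor {j} coincides with carbon {center}")
        units.append(v / norm)
    s = -np.sum(units, axis=0)
    s_norm = np.linalg.norm(s)
    if s_norm < 1e-6:
        raise ValueError("degenerate neighbor arrangement: unit vectors sum to zero")
    return c + bond_length * s / s_norm


@dataclass(frozen=True)
class Site:
    """A distance-measurement site: a real atom or a virtual hydrogen."""

    label: str
    atom_index: int
    virtual: bool = False
    bond_length: float = DEFAULT_CH_BOND

    def position(self, frame: Frame, topology: Topology) -> np.ndarray:
        if self.virtual:
            return place_virtual_hydrogen(self.atom_index, frame, topology,
                                          self.bond_length)
        return frame.coordinates[self.atom_index]


def atom_sites(sel: Selection, topology: Topology) -> list[Site]:
    return [Site(label=topology.atoms[i].name, atom_index=int(i))
            for i in sel.indices]


def virtual_site(topology: Topology, carbon_index: int,
                 bond_length: float = DEFAULT_CH_BOND) -> Site:
    name = topology.atoms[carbon_index].name
    return Site(label=f"H{name}", atom_index=int(carbon_index), virtual=True,
                bond_length=bond_length)


def resolve_sites(names: Sequence[str], topology: Topology,
                  resname: str | None = None,
                  bond_length: float = DEFAULT_CH_BOND) -> list[Site]:
    """Map site names to atoms; ``HC2``-style names that are absent from the
    topology resolve to virtual hydrogens on the corresponding carbon."""
    atom_names = topology.names()
    in_res = (topology.atom_resname == resname) if resname else np.ones(
        topology.n_atoms, dtype=bool)
    sites = []
    for name in names:
        hits = np.flatnonzero((atom_names == name) & in_res)
        if len(hits) == 1:
            sites.append(Site(label=name, atom_index=int(hits[0])))
            continue
        if len(hits) > 1:
            raise ValueError(f"site name {name!r} is ambiguous ({len(hits)} atoms)")
        if name.startswith("H"):
            parent = np.flatnonzero((atom_names == name[1:]) & in_res)
            if len(parent) == 1 and topology.atoms[parent[0]].is_united_carbon:
                sites.append(Site(label=name, atom_index=int(parent[0]),
                                  virtual=True, bond_length=bond_length))
                continue
        raise ValueError(f"cannot resolve site {name!r}")
    return sites


# ---------------------------------------------------------------------------
# Distances


@dataclass
class DistanceSeries:
    label: str
    times: np.ndarray
    values: np.ndarray  # nm

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class DistanceHistogram:
    bin_edges: np.ndarray
    density: np.ndarray
    n_samples: int


def _as_sites(sel, topology: Topology) -> list[Site]:
    if isinstance(sel, Selection):
        return atom_sites(sel, topology)
    return list(sel)


def distance_series(frames: FrameStream, sel_a, sel_b, topology: Topology,
                    mode: str = "pairwise_single") -> DistanceSeries:
    """Per-frame distance between sites (minimum image when a box is present).

    ``pairwise_single``: one site on each side.  ``min_over_a``: the shortest
    of the distances from each site in ``sel_a`` to the single site in
    ``sel_b`` (e.g. "N-delta or N-epsilon, whichever is closer").
    """
    sites_a = _as_sites(sel_a, topology)
    sites_b = _as_sites(sel_b, topology)
    if not sites_a or not sites_b:
        raise ValueError("empty site selection")
    if len(sites_b) != 1:
        raise ValueError("sel_b must resolve to exactly one site")
    if mode == "pairwise_single" and len(sites_a) != 1:
        raise ValueError("pairwise_single requires exactly one site per side")
    if mode not in ("pairwise_single", "min_over_a"):
        raise ValueError(f"unknown mode {mode!r}")
    times, values = [], []
    b = sites_b[0]
    for frame in frames:
        pb = b.position(frame, topology)
        deltas = np.array([a.position(frame, topology) - pb for a in sites_a])
        deltas = minimum_image(deltas, frame.box)
        d = np.linalg.norm(deltas, axis=1)
        values.append(d[0] if mode == "pairwise_single" else d.min())
        times.append(frame.time)
    label_a = "/".join(s.label for s in sites_a)
    return DistanceSeries(label=f"{label_a}-{b.label}",
                          times=np.array(times), values=np.array(values))


def fraction_below(series: DistanceSeries | np.ndarray, cutoff: float) -> float:
    """Fraction of frames with distance strictly below ``cutoff`` (nm)."""
    values = series.values if isinstance(series, DistanceSeries) else np.asarray(series)
    if len(values) == 0:
        raise ValueError("empty distance series")
    return float(np.count_nonzero(values < cutoff) / len(values))


def histogram(series: DistanceSeries | np.ndarray,
              bin_width: float = 0.005) -> DistanceHistogram:
    """Normalized distance distribution with edges on multiples of ``bin_width``."""
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    values = series.values if isinstance(series, DistanceSeries) else np.asarray(series)
    if len(values) == 0:
        raise ValueError("empty distance series")
    lo = math.floor(values.min() / bin_width) * bin_width
    hi = math.ceil(values.max() / bin_width) * bin_width
    if hi <= lo + 1e-15:
        hi = lo + bin_width
    edges = lo + bin_width * np.arange(round((hi - lo) / bin_width) + 1)
    counts, edges = np.histogram(values, bins=edges)
    density = counts / (len(values) * bin_width)
    return DistanceHistogram(bin_edges=edges, density=density,
                             n_samples=len(values))


# ---------------------------------------------------------------------------
# Hydrogen bonds


@dataclass(frozen=True)
class HBondRecord:
    donor: int
    hydrogen: int
    acceptor: int


@dataclass
class HBondSpec:
    """Donor (heavy, hydrogen) pairs, acceptor atoms, and the two cutoffs."""

    donors: list[tuple[int, int]]
    acceptors: list[int]
    distance_cutoff: float = DEFAULT_DISTANCE_CUTOFF
    angle_cutoff: float = DEFAULT_ANGLE_CUTOFF

    def validate(self, topology: Topology) -> None:
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        for d, h in self.donors:
            if h not in topology.bonded_neighbors(d):
                raise ValueError(
                    f"hydrogen {topology.atoms[h].name} ({h}) is not bonded to "
                    f"stated donor {topology.atoms[d].name} ({d})")


def _donor_pairs(topology: Topology, indices: Iterable[int]) -> list[tuple[int, int]]:
    pairs = []
    for i in indices:
        if topology.atoms[i].element not in DONOR_ELEMENTS:
            continue
        for j in topology.bonded_neighbors(i):
            if topology.atoms[j].element == "H":
                pairs.append((int(i), int(j)))
    return pairs


def cross_hbond_spec(topology: Topology, group_a: Selection, group_b: Selection,
                     distance_cutoff: float = DEFAULT_DISTANCE_CUTOFF,
                     angle_cutoff: float = DEFAULT_ANGLE_CUTOFF) -> HBondSpec:
    """Spec covering all donor->acceptor pairs *between* two groups, both
    directions, using the built-in N/O chemistry table."""
    set_a, set_b = set(group_a.indices), set(group_b.indices)

    def acceptors(indices):
        return [int(i) for i in indices
                if topology.atoms[i].element in ACCEPTOR_ELEMENTS]

    donors = _donor_pairs(topology, group_a.indices) + \
        _donor_pairs(topology, group_b.indices)
    spec = HBondSpec(donors=donors,
                     acceptors=acceptors(group_a.indices) + acceptors(group_b.indices),
                     distance_cutoff=distance_cutoff, angle_cutoff=angle_cutoff)
    spec.validate(topology)
    # remember group membership for cross-pair filtering
    spec._group_a = set_a  # type: ignore[attr-defined]
    spec._group_b = set_b  # type: ignore[attr-defined]
    return spec


def _cross_ok(spec: HBondSpec, donor: int, acceptor: int) -> bool:
    ga = getattr(spec, "_group_a", None)
    if ga is None:
        return True
    gb = spec._group_b  # type: ignore[attr-defined]
    return (donor in ga and acceptor in gb) or (donor in gb and acceptor in ga)


def detect_hbonds(frame: Frame, spec: HBondSpec,
                  topology: Topology | None = None) -> set[HBondRecord]:
    """Hydrogen bonds present in one frame under the geometric criterion."""
    found: set[HBondRecord] = set()
    coords = frame.coordinates
    acceptors = np.asarray(spec.acceptors, dtype=int)
    if len(acceptors) == 0 or not spec.donors:
        return found
    cos_cut = math.cos(math.radians(spec.angle_cutoff))
    for d, h in spec.donors:
        ha = minimum_image(coords[acceptors] - coords[h], frame.box)
        dist = np.linalg.norm(ha, axis=1)
        close = dist < spec.distance_cutoff
        if not close.any():
            continue
        hd = minimum_image(coords[d] - coords[h], frame.box)
        hd_norm = np.linalg.norm(hd)
        for k in np.flatnonzero(close):
            a = int(acceptors[k])
            if a == d or a == h or not _cross_ok(spec, d, a):
                continue
            # angle donor-hydrogen-acceptor, vertex at the hydrogen
            cos_ang = float(hd @ ha[k] / (hd_norm * dist[k]))
            if cos_ang < cos_cut:  # angle > cutoff  <=>  cos < cos(cutoff)
                found.add(HBondRecord(donor=d, hydrogen=int(h), acceptor=a))
    return found


@dataclass
class OccupancyRow:
    partner: str          # e.g. "Val-511"
    resid: int
    percentage: float
    ligand_atoms: tuple[str, ...]


@dataclass
class OccupancyTable:
    rows: list[OccupancyRow]

    @property
    def total(self) -> float:
        return float(sum(r.percentage for r in self.rows))


def occupancy_table(frames: FrameStream, spec: HBondSpec, topology: Topology,
                    ligand_sel: Selection) -> OccupancyTable:
    """Per-partner-residue H-bond occupancy over a trajectory.

    Events are counted per distinct donor/acceptor atom pair and summed within
    each partner (non-ligand) residue, so a partner bound through several
    simultaneous pairs can exceed 100%.
    """
    ligand = set(int(i) for i in ligand_sel.indices)
    pair_counts: dict[tuple[int, int], int] = {}
    n_frames = 0
    for frame in frames:
        n_frames += 1
        for rec in detect_hbonds(frame, spec, topology):
            pair = (rec.donor, rec.acceptor)
            pair_counts[pair] = pair_counts.get(pair, 0) + 1
    if n_frames == 0:
        raise ValueError("empty trajectory")
    by_residue: dict[int, dict] = {}
    for (donor, acceptor), count in pair_counts.items():
        lig_atom, partner_atom = (donor, acceptor) if donor in ligand else (acceptor, donor)
        if lig_atom not in ligand:
            continue  # H-bond not involving the ligand
        res = topology.residue_of(partner_atom)
        entry = by_residue.setdefault(res.resid, {
            "resname": res.resname, "events": 0, "lig_atoms": set()})
        entry["events"] += count
        entry["lig_atoms"].add(topology.atoms[lig_atom].name)
    rows = [
        OccupancyRow(
            partner=f"{entry['resname'].capitalize()}-{resid}",
            resid=resid,
            percentage=100.0 * entry["events"] / n_frames,
            ligand_atoms=tuple(sorted(entry["lig_atoms"])))
        for resid, entry in sorted(by_residue.items())
    ]
    return OccupancyTable(rows=rows)


def average_tables(tables: Sequence[OccupancyTable]) -> OccupancyTable:
    """Arithmetic mean of occupancy tables over independent runs.

    A partner absent from a run contributes 0% to its average.
    """
    if not tables:
        raise ValueError("no tables")
    k = len(tables)
    merged: dict[int, dict] = {}
    for table in tables:
        for row in table.rows:
            entry = merged.setdefault(row.resid, {
                "partner": row.partner, "pct": 0.0, "atoms": set()})
            entry["pct"] += row.percentage
            entry["atoms"].update(row.ligand_atoms)
    rows = [OccupancyRow(partner=e["partner"], resid=resid,
                         percentage=e["pct"] / k,
                         ligand_atoms=tuple(sorted(e["atoms"])))
            for resid, e in sorted(merged.items())]
    return OccupancyTable(rows=rows)
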