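"""Per-snapshot structural metrics for kinase MD ensembles.

This module owns the coordinate-level analysis: a light trajectory container
read from multi-model PDB, the named inter-atom distances used to monitor the
ZAP-70 C-helix and substrate groove, Kabsch–Sander secondary-structure
assignment, residue contact-frequency maps over pooled ensembles, and
Shrake–Rupley solvent-accessible surface area.

All coordinates are in Angstroms, all times in picoseconds, and residue
numbers follow the PDB residue field directly (ZAP-70 numbering, e.g. K369,
D379, K476) with no re-indexing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("ubikin")

# ---------------------------------------------------------------------------
# Physical constants
# ---------------------------------------------------------------------------

#: Atomic masses (u) for center-of-mass calculations.
ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971,
}

#: Bondi van der Waals radii (Angstrom) for SASA.
VDW_RADIUS = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52,
    "S": 1.80, "P": 1.80, "SE": 1.90,
}

#: Kabsch–Sander electrostatic prefactor: q1*q2*f = 0.42*0.20*332 kcal/mol*A.
_KS_PREFACTOR = 0.084 * 332.0
#: Hydrogen bond iff E below this energy (kcal/mol).
_KS_HBOND_CUTOFF = -0.5
#: Peptide C(i)-N(i+1) distance above which the chain is considered broken.
CHAIN_BREAK_CUTOFF = 2.5

#: Named atom-pair presets (ZAP-70 numbering).
DISTANCE_PRESETS = {
    "chelix_position": ((349, "CA"), (379, "CB")),
    "groove": ((348, "CA"), (501, "CA")),
}

SS_CODES = ("H", "G", "I", "E", "B", "T", "C")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain: str = "A"


class Topology:
    """Atom table with (residue_index, atom_name) lookup."""

    def __init__(self, atoms: Sequence[Atom]):
        self.atoms = list(atoms)
        self._index: dict[tuple[int, str], int] = {}
        self._by_residue: dict[int, list[int]] = {}
        for i, a in enumerate(self.atoms):
            key = (a.residue_index, a.name)
            if key in self._index:
                raise ValueError(f"duplicate atom {a.name} in residue {a.residue_index}")
            self._index[key] = i
            self._by_residue.setdefault(a.residue_index, []).append(i)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residues(self) -> list[int]:
        return sorted(self._by_residue)

    def index_of(self, residue_index: int, atom_name: str) -> int:
        try:
            return self._index[(residue_index, atom_name)]
        except KeyError:
            raise KeyError(
                f"atom {atom_name} of residue {residue_index} not in topology"
            ) from None

    def has_atom(self, residue_index: int, atom_name: str) -> bool:
        return (residue_index, atom_name) in self._index

    def residue_atom_indices(self, residue_index: int) -> list[int]:
        try:
            return self._by_residue[residue_index]
        except KeyError:
            raise KeyError(f"residue {residue_index} not in topology") from None

    def residue_name(self, residue_index: int) -> str:
        return self.atoms[self._by_residue[residue_index][0]].residue_name


@dataclass
class Trajectory:
    """Ordered coordinate frames (n_frames, n_atoms, 3) in Angstroms."""

    topology: Topology
    xyz: np.ndarray
    timestep: float = 1.0  # ps
    sim_id: str = "sim0"

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim == 2:
            self.xyz = self.xyz[None, :, :]
        if self.xyz.shape[1:] != (self.topology.n_atoms, 3):
            raise ValueError(
                f"coordinate shape {self.xyz.shape} does not match "
                f"{self.topology.n_atoms} topology atoms"
            )
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]


@dataclass
class EnsembleSet:
    """Independent simulations of one construct sharing a topology."""

    label: str
    trajectories: list[Trajectory]

    def __post_init__(self):
        if not self.trajectories:
            raise ValueError("EnsembleSet requires at least one trajectory")
        n0 = self.trajectories[0].topology.n_atoms
        for t in self.trajectories:
            if t.topology.n_atoms != n0:
                raise ValueError("member trajectories do not share a topology")
        ids = [t.sim_id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            raise ValueError("sim_ids must be unique within an ensemble")

    @property
    def n_frames(self) -> int:
        return sum(t.n_frames for t in self.trajectories)


@dataclass
class SecondaryStructureSeries:
    """Per-snapshot, per-residue DSSP codes ('H G I E B T C')."""

    residue_ids: list[int]
    codes: np.ndarray  # (n_frames, n_residues) of single characters

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype="<U1")
        if self.codes.ndim == 1:
            self.codes = self.codes[None, :]
        if self.codes.shape[1] != len(self.residue_ids):
            raise ValueError("code matrix width does not match residue ids")
        bad = set(np.unique(self.codes)) - set(SS_CODES)
        if bad:
            raise ValueError(f"unknown secondary-structure codes {sorted(bad)}")


@dataclass
class ContactMatrix:
    row_residues: list[int]
    col_residues: list[int]
    values: np.ndarray  # fraction of evaluated snapshots in contact
    n_snapshots: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_residues), len(self.col_residues)):
            raise ValueError("contact matrix shape mismatch")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("contact fractions must lie in [0, 1]")


@dataclass
class MetricSeries:
    """One scalar per snapshot for a single independent simulation."""

    sim_id: str
    values: np.ndarray
    timestep: float = 1.0  # ps

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("MetricSeries must be non-empty")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("MetricSeries values must be finite")


# ---------------------------------------------------------------------------
# Multi-model PDB I/O
# ---------------------------------------------------------------------------

def write_multimodel_pdb(traj: Trajectory, path) -> None:
    """Write a trajectory as MODEL/ENDMDL records with standard ATOM fields."""
    top = traj.topology
    with open(path, "w") as fh:
        for m, frame in enumerate(traj.xyz, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            prev_res = None
            for i, atom in enumerate(top.atoms):
                if prev_res is not None and atom.residue_index < prev_res:
                    fh.write("TER\n")
                prev_res = atom.residue_index
                x, y, z = frame[i]
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                fh.write(
                    f"ATOM  {i + 1:5d} {name}{'':1s}{atom.residue_name:>3s} "
                    f"{atom.chain:1s}{atom.residue_index:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}\n"
                )
            fh.write("TER\nENDMDL\n")
        fh.write("END\n")


def read_multimodel_pdb(path, timestep: float = 1.0, sim_id: str = "sim0") -> Trajectory:
    """Read a (multi-)model PDB file into a Trajectory.

    The topology is taken from the first model; every later model must carry
    the same number of atoms or the file is rejected, naming the model.
    """
    models: list[list[tuple[Atom, tuple[float, float, float]]]] = []
    current: list[tuple[Atom, tuple[float, float, float]]] = []
    in_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                in_model = True
                current = []
            elif rec == "ENDMDL":
                models.append(current)
                in_model = False
                current = []
            elif rec in ("ATOM  ", "HETATM"):
                name = line[12:16].strip()
                resname = line[17:20].strip()
                chain = line[21].strip() or "A"
                resid = int(line[22:26])
                x = float(line[30:38]); y = float(line[38:46]); z = float(line[46:54])
                element = line[76:78].strip() or name[0]
                current.append((Atom(name, element.upper(), resid, resname, chain), (x, y, z)))
    if current and not in_model:
        models.append(current)  # single implicit model, no MODEL record
    elif current:
        models.append(current)  # unterminated final MODEL
    if not models or not models[0]:
        raise ValueError(f"{path}: no ATOM records found")
    n0 = len(models[0])
    for m, model in enumerate(models, start=1):
        if len(model) != n0:
            raise ValueError(
                f"{path}: model {m} has {len(model)} atoms, expected {n0}"
            )
    topology = Topology([a for a, _ in models[0]])
    xyz = np.array([[c for _, c in model] for model in models], dtype=float)
    return Trajectory(topology, xyz, timestep=timestep, sim_id=sim_id)


# ---------------------------------------------------------------------------
# Scalar and secondary-structure series readers (cpptraj-style text)
# ---------------------------------------------------------------------------

def read_scalar_series(path, timestep: float = 1.0, n_sims: int = 1) -> list[MetricSeries]:
    """Read a whitespace-delimited scalar series, split into per-simulation blocks.

    Accepts one column (values) or two (frame index, value); `#`-prefixed and
    non-numeric header lines are skipped.  The combined series is split into
    ``n_sims`` equal contiguous blocks, one per independent simulation.
    """
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                row = [float(p) for p in parts]
            except ValueError:
                continue  # tolerate textual header lines
            values.append(row[-1])
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    n = len(values)
    if n == 0:
        raise ValueError(f"{path}: no numeric data")
    if n % n_sims != 0:
        raise ValueError(
            f"{path}: {n} snapshots not divisible into {n_sims} simulations"
        )
    block = n // n_sims
    arr = np.asarray(values, dtype=float)
    return [
        MetricSeries(sim_id=f"sim{k}", values=arr[k * block:(k + 1) * block],
                     timestep=timestep)
        for k in range(n_sims)
    ]


_SS_NORMALIZE = {"S": "C", "0": "C", ".": "C", " ": "C", "-": "C"}


def read_ss_series(path, residue_ids: Sequence[int] | None = None) -> SecondaryStructureSeries:
    """Read per-snapshot secondary-structure codes, one snapshot per row.

    Codes outside {H,G,I,E,B,T,C} are normalized: bend ('S') and the
    no-assignment markers ('0', '.', '-') become coil 'C'.
    """
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            codes = line.split() if " " in line.strip() else list(line.strip())
            rows.append([_SS_NORMALIZE.get(c, c) for c in codes])
    if not rows:
        raise ValueError(f"{path}: no secondary-structure rows")
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise ValueError(f"{path}: row {i + 1} has {len(r)} codes, expected {width}")
    if residue_ids is None:
        residue_ids = list(range(1, width + 1))
    return SecondaryStructureSeries(list(residue_ids), np.array(rows, dtype="<U1"))


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def pair_distance(frame: np.ndarray, topology: Topology,
                  selA: tuple[int, str], selB: tuple[int, str]) -> float:
    """Euclidean distance (Angstrom) between two named atoms in one frame."""
    ia = topology.index_of(*selA)
    ib = topology.index_of(*selB)
    return float(np.linalg.norm(np.asarray(frame)[ia] - np.asarray(frame)[ib]))


def preset_distance_series(traj: Trajectory, preset: str) -> MetricSeries:
    """Per-snapshot series for a named distance preset over a trajectory."""
    try:
        selA, selB = DISTANCE_PRESETS[preset]
    except KeyError:
        raise ValueError(
            f"unknown preset {preset!r}; available: {sorted(DISTANCE_PRESETS)}"
        ) from None
    ia = traj.topology.index_of(*selA)
    ib = traj.topology.index_of(*selB)
    d = np.linalg.norm(traj.xyz[:, ia] - traj.xyz[:, ib], axis=1)
    return MetricSeries(sim_id=traj.sim_id, values=d, timestep=traj.timestep)


def salt_bridge_distance(frame: np.ndarray, topology: Topology,
                         lys_residue: int = 369, glu_residue: int = 386,
                         formed_cutoff: float = 4.0) -> tuple[float, bool]:
    """Minimum Lys NZ to Glu OE1/OE2 distance and a 'formed' flag.

    Defaults monitor the beta3-lysine / C-helix-glutamate ion pair (K369-E386)
    that anchors the active C-helix position.
    """
    frame = np.asarray(frame)
    nz = frame[topology.index_of(lys_residue, "NZ")]
    dists = []
    for oname in ("OE1", "OE2"):
        if topology.has_atom(glu_residue, oname):
            dists.append(float(np.linalg.norm(nz - frame[topology.index_of(glu_residue, oname)])))
    if not dists:
        raise KeyError(f"residue {glu_residue} has no OE1/OE2 atoms")
    d = min(dists)
    return d, d <= formed_cutoff


# ---------------------------------------------------------------------------
# Kabsch–Sander secondary structure
# ---------------------------------------------------------------------------

def _backbone_table(topology: Topology):
    """Per-residue backbone atom indices; residues missing backbone are flagged."""
    residues = topology.residues
    table = []
    for r in residues:
        entry = {}
        ok = True
        for name in ("N", "CA", "C", "O"):
            if topology.has_atom(r, name):
                entry[name] = topology.index_of(r, name)
            else:
                ok = False
        entry["H"] = topology.index_of(r, "H") if topology.has_atom(r, "H") else None
        entry["complete"] = ok
        entry["resname"] = topology.residue_name(r)
        table.append(entry)
    return residues, table


def _ks_hbond_matrix(frame: np.ndarray, residues, table) -> np.ndarray:
    """hb[i, j] True iff CO of residue i donates to NH of residue j (E < -0.5)."""
    n = len(residues)
    hb = np.zeros((n, n), dtype=bool)
    # amide hydrogen positions: explicit H if present, else placed 1.00 A from N
    # along the preceding C=O direction (classic DSSP convention)
    hpos = [None] * n
    for j in range(n):
        tj = table[j]
        if not tj["complete"] or tj["resname"] == "PRO":
            continue
        if tj["H"] is not None:
            hpos[j] = frame[tj["H"]]
            continue
        if j == 0:
            continue  # N-terminal residue has no amide H
        tp = table[j - 1]
        if not tp["complete"] or residues[j] != residues[j - 1] + 1:
            continue
        if np.linalg.norm(frame[tp["C"]] - frame[tj["N"]]) > CHAIN_BREAK_CUTOFF:
            continue  # chain break: no peptide bond, no placed H
        co = frame[tp["C"]] - frame[tp["O"]]
        norm = np.linalg.norm(co)
        if norm > 0:
            hpos[j] = frame[tj["N"]] + co / norm

    for i in range(n):
        ti = table[i]
        if not ti["complete"]:
            continue
        c = frame[ti["C"]]
        o = frame[ti["O"]]
        for j in range(n):
            if j == i or hpos[j] is None:
                continue
            nn = frame[table[j]["N"]]
            h = hpos[j]
            r_on = np.linalg.norm(o - nn)
            if r_on > 5.2:  # beyond plausible H-bond geometry; skip
                continue
            r_ch = np.linalg.norm(c - h)
            r_oh = np.linalg.norm(o - h)
            r_cn = np.linalg.norm(c - nn)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue  # clashing geometry, treat as no bond
            e = _KS_PREFACTOR * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            if e < _KS_HBOND_CUTOFF:
                hb[i, j] = True
    return hb


def _segments(frame: np.ndarray, residues, table) -> np.ndarray:
    """Segment label per residue; a new segment starts at each chain break."""
    n = len(residues)
    seg = np.zeros(n, dtype=int)
    s = 0
    for i in range(1, n):
        broken = True
        if (residues[i] == residues[i - 1] + 1 and table[i - 1]["complete"]
                and table[i]["complete"]):
            d = np.linalg.norm(frame[table[i - 1]["C"]] - frame[table[i]["N"]])
            broken = d > CHAIN_BREAK_CUTOFF
        if broken:
            s += 1
        seg[i] = s
    return seg


def _dssp_one_frame(frame: np.ndarray, residues, table) -> np.ndarray:
    n = len(residues)
    codes = np.full(n, "C", dtype="<U1")
    hb = _ks_hbond_matrix(frame, residues, table)
    seg = _segments(frame, residues, table)

    def turn(i: int, length: int) -> bool:
        j = i + length
        return j < n and seg[i] == seg[j] and hb[i, j]

    # assign in reverse priority so higher-priority codes overwrite:
    # T < I < G < B < E < H
    for length, helix_code in ((3, "G"), (4, "H"), (5, "I")):
        for i in range(n - length):
            if turn(i, length):
                for k in range(i + 1, i + length):
                    if codes[k] == "C":
                        codes[k] = "T"

    for length, helix_code in ((5, "I"), (3, "G")):
        for i in range(1, n - length):
            if turn(i - 1, length) and turn(i, length):
                codes[i:i + length] = helix_code

    # bridges and ladders (E/B)
    bridges: list[tuple[int, int, str]] = []
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            para = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
            anti = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            if para:
                bridges.append((i, j, "P"))
            elif anti:
                bridges.append((i, j, "A"))
    in_ladder = set()
    bridge_set = {(i, j, t) for i, j, t in bridges}
    for i, j, t in bridges:
        nxt = (i + 1, j + 1, "P") if t == "P" else (i + 1, j - 1, "A")
        prv = (i - 1, j - 1, "P") if t == "P" else (i - 1, j + 1, "A")
        if nxt in bridge_set or prv in bridge_set:
            in_ladder.add((i, j, t))
    for i, j, t in bridges:
        code = "E" if (i, j, t) in in_ladder else "B"
        for k in (i, j):
            if codes[k] not in ("E",):
                codes[k] = code

    # alpha helix has top priority
    for i in range(1, n - 4):
        if turn(i - 1, 4) and turn(i, 4):
            codes[i:i + 4] = "H"

    for i in range(n):
        if not table[i]["complete"]:
            codes[i] = "C"
    return codes


def assign_secondary_structure(traj: Trajectory) -> SecondaryStructureSeries:
    """Kabsch–Sander DSSP assignment for every frame of a trajectory.

    Hydrogen-bond energy E = 0.084*332*(1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)
    kcal/mol with a bond iff E < -0.5; helices from consecutive n-turns
    (n = 3, 4, 5 -> G, H, I), bridges/ladders -> B/E, isolated turns -> T,
    otherwise C, with priority H > E > B > G > I > T > C.  Residues missing
    backbone atoms are coded 'C' and logged; chain breaks (C-N > 2.5 A) split
    the turn bookkeeping.
    """
    residues, table = _backbone_table(traj.topology)
    incomplete = [residues[i] for i, t in enumerate(table) if not t["complete"]]
    if incomplete:
        logger.warning("residues missing backbone atoms coded 'C': %s", incomplete)
    codes = np.array([_dssp_one_frame(f, residues, table) for f in traj.xyz])
    return SecondaryStructureSeries(residues, codes)


def count_helical(codes, residue_ids: Sequence[int] | None = None,
                  residue_range: tuple[int, int] = (380, 393),
                  helix_codes: frozenset[str] | set[str] = frozenset({"H"})) -> np.ndarray:
    """Per-snapshot count of residues in ``residue_range`` with a helical code.

    The default range is the ZAP-70 C-helix (380-393 inclusive, 14 residues)
    and the default helical code is alpha ('H') only.
    """
    if isinstance(codes, SecondaryStructureSeries):
        residue_ids = codes.residue_ids
        codes = codes.codes
    codes = np.asarray(codes, dtype="<U1")
    if codes.ndim == 1:
        codes = codes[None, :]
    if residue_ids is None:
        raise ValueError("residue_ids required when codes is a bare array")
    lo, hi = residue_range
    mask = np.array([lo <= r <= hi for r in residue_ids])
    if mask.sum() != hi - lo + 1:
        raise ValueError(
            f"range {lo}-{hi} covers {mask.sum()} residues in the series, "
            f"expected {hi - lo + 1}"
        )
    helical = np.isin(codes[:, mask], sorted(helix_codes))
    return helical.sum(axis=1)


# ---------------------------------------------------------------------------
# Contact maps
# ---------------------------------------------------------------------------

def residue_center_of_mass(frame: np.ndarray, topology: Topology,
                           residue_index: int) -> np.ndarray:
    """Mass-weighted mean position of all atoms of one residue."""
    frame = np.asarray(frame)
    idx = topology.residue_atom_indices(residue_index)
    masses = []
    for i in idx:
        el = topology.atoms[i].element
        if el not in ATOMIC_MASS:
            raise ValueError(f"unknown element {el!r} for atom {topology.atoms[i].name}")
        masses.append(ATOMIC_MASS[el])
    m = np.asarray(masses)
    return (frame[idx] * m[:, None]).sum(axis=0) / m.sum()


def _com_array(traj: Trajectory, residue_list: Sequence[int]) -> np.ndarray:
    """(n_frames, n_residues, 3) center-of-mass positions."""
    out = np.empty((traj.n_frames, len(residue_list), 3))
    for j, r in enumerate(residue_list):
        idx = traj.topology.residue_atom_indices(r)
        m = np.array([ATOMIC_MASS[traj.topology.atoms[i].element] for i in idx])
        out[:, j] = (traj.xyz[:, idx] * m[None, :, None]).sum(axis=1) / m.sum()
    return out


def contact_map(ensemble: EnsembleSet, target_residues: Sequence[int],
                moiety_residues: Sequence[int], cutoff: float = 10.0,
                stride_ps: float = 100.0) -> ContactMatrix:
    """Fraction of strided snapshots with residue COM distance below cutoff.

    Snapshots are taken every ``stride_ps`` picoseconds (converted per
    trajectory through its timestep) and pooled over all member simulations.
    """
    target_residues = list(target_residues)
    moiety_residues = list(moiety_residues)
    counts = np.zeros((len(target_residues), len(moiety_residues)), dtype=int)
    total = 0
    for traj in ensemble.trajectories:
        stride = max(1, int(round(stride_ps / traj.timestep)))
        if stride > traj.n_frames:
            raise ValueError(
                f"stride {stride_ps} ps exceeds trajectory {traj.sim_id} "
                f"({traj.n_frames} frames at {traj.timestep} ps)"
            )
        sel = slice(0, traj.n_frames, stride)
        sub = Trajectory(traj.topology, traj.xyz[sel], traj.timestep, traj.sim_id)
        com_t = _com_array(sub, target_residues)
        com_m = _com_array(sub, moiety_residues)
        d = np.linalg.norm(com_t[:, :, None, :] - com_m[:, None, :, :], axis=-1)
        counts += (d < cutoff).sum(axis=0)
        total += sub.n_frames
    return ContactMatrix(target_residues, moiety_residues, counts / total, total)


# ---------------------------------------------------------------------------
# Shrake–Rupley SASA
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi * k
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa(frame: np.ndarray, topology: Topology,
         selection: Sequence[int] | None = None, probe: float = 1.4,
         n_sphere_points: int = 960,
         occluders: Sequence[int] | None = None) -> float:
    """Shrake–Rupley solvent-accessible surface area (Angstrom^2).

    ``selection`` are atom indices whose area is summed (default: all);
    ``occluders`` are atom indices that may bury surface (default: every atom
    of the frame, so a kinase selection is occluded by an attached moiety).
    """
    frame = np.asarray(frame, dtype=float)
    if selection is None:
        selection = range(topology.n_atoms)
    selection = list(selection)
    if not selection:
        raise ValueError("empty SASA selection")
    if occluders is None:
        occluders = range(topology.n_atoms)
    occluders = list(occluders)

    def radius(i: int) -> float:
        el = topology.atoms[i].element
        if el not in VDW_RADIUS:
            raise ValueError(f"no van der Waals radius for element {el!r}")
        return VDW_RADIUS[el]

    pts = _sphere_points(n_sphere_points)
    occ_centers = frame[occluders]
    occ_radii = np.array([radius(i) + probe for i in occluders])
    total = 0.0
    for i in selection:
        r = radius(i) + probe
        surface = frame[i] + r * pts
        others = [k for k, j in enumerate(occluders) if j != i]
        if others:
            c = occ_centers[others]
            rr = occ_radii[others]
            near = np.linalg.norm(c - frame[i], axis=1) < (r + rr)
            c, rr = c[near], rr[near]
            if len(c):
                d2 = ((surface[:, None, :] - c[None, :, :]) ** 2).sum(-1)
                buried = (d2 < rr[None, :] ** 2).any(axis=1)
            else:
                buried = np.zeros(len(pts), dtype=bool)
        else:
            buried = np.zeros(len(pts), dtype=bool)
        frac = 1.0 - buried.mean()
        total += frac * 4.0 * math.pi * r * r
    return float(total)
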