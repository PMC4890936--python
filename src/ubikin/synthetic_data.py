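"""Synthetic inputs with the statistical and geometric structure the
downstream analyses assume.

Every generator is a pure function of its spec plus a seed (per-simulation
random streams are derived deterministically from the master seed and the
simulation index), so outputs are bitwise reproducible.  The fixtures are
geometric/statistical stand-ins: planted category proportions for the site
tables, ideal backbone torsions for the helix, a rigid two-body tether for
the contact-map ensemble, and AR(1) noise for within-simulation correlation
of metric series.  They make no attempt to emulate force-field physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ptm_sites import SiteRecord, DomainAnnotation
from .traj_metrics import (
    Atom,
    EnsembleSet,
    MetricSeries,
    Topology,
    Trajectory,
)

# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthSiteSpec:
    """Planted composition of a synthetic ubiquitination-site table.

    Probabilities mirror the observed composition of kinase ubiquitination
    sites: the fraction on the kinase domain, on any folded domain, the
    proteasome-sensitive / insensitive split (remainder = unknown), and the
    fraction within four residues of a phosphosite.
    """

    n_kinases: int = 200
    sites_per_kinase: int = 4
    p_kinase_domain: float = 0.47
    p_folded: float = 0.72
    p_sensitive: float = 0.127
    p_insensitive: float = 0.122
    p_near_phospho: float = 0.11
    seed: int = 0

    def __post_init__(self):
        probs = {
            "p_kinase_domain": self.p_kinase_domain,
            "p_folded": self.p_folded,
            "p_sensitive": self.p_sensitive,
            "p_insensitive": self.p_insensitive,
            "p_near_phospho": self.p_near_phospho,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} is not a probability in [0, 1]")
        if self.p_sensitive + self.p_insensitive > 1.0 + 1e-12:
            raise ValueError("p_sensitive + p_insensitive must be <= 1")
        if self.p_folded < self.p_kinase_domain:
            raise ValueError("p_folded must be >= p_kinase_domain "
                             "(the kinase domain is a folded domain)")
        if self.n_kinases < 1 or self.sites_per_kinase < 1:
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class SynthTrajSpec:
    """Shape of a synthetic trajectory ensemble."""

    n_sims: int = 8
    frames_per_sim: int = 100
    timestep: float = 1.0  # ps
    geometry: str = "two_domain_tether"
    shift: float = 0.0  # Angstrom location offset for group-B series
    rho: float = 0.5  # lag-1 autocorrelation within a simulation
    seed: int = 0

    def __post_init__(self):
        if self.n_sims < 2:
            raise ValueError("n_sims must be >= 2")
        if self.frames_per_sim < 1:
            raise ValueError("frames_per_sim must be >= 1")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must satisfy 0 <= rho < 1")
        if self.geometry not in {"ideal_helix", "perturbed_helix",
                                 "two_domain_tether", "static"}:
            raise ValueError(f"unknown geometry {self.geometry!r}")


# ---------------------------------------------------------------------------
# Site tables
# ---------------------------------------------------------------------------

_SEQ_LEN = 600
_KINASE_DOMAIN = (201, 480)        # 1-based inclusive
_OTHER_FOLDED = (501, 580)
MG132_COMPARISON = "mg132_vs_ctrl"


def synth_site_table(spec: SynthSiteSpec):
    """Generate SiteRecords with planted category flags plus their annotations.

    Returns ``(sites, phospho_sites, annotations)``.  Each ubiquitination
    record carries a ``planted`` dict recording its true category so that
    downstream summaries can be checked for exact bookkeeping recovery; the
    MG-132 log2 fold-change is drawn so the classifier reproduces the planted
    sensitivity (>= 1 for sensitive, < 1 for insensitive, absent for unknown).
    """
    rng = np.random.default_rng([spec.seed, 0])
    sites: list[SiteRecord] = []
    phospho: list[SiteRecord] = []
    annotations: list[DomainAnnotation] = []
    kd_lo, kd_hi = _KINASE_DOMAIN
    of_lo, of_hi = _OTHER_FOLDED

    for k in range(spec.n_kinases):
        acc = f"SYNK{k:04d}"
        annotations.append(DomainAnnotation(acc, [
            (kd_lo, kd_hi, "kinase_domain"),
            (of_lo, of_hi, "other_folded_domain"),
        ]))
        used: set[int] = set()
        for s in range(spec.sites_per_kinase):
            u = rng.random()
            if u < spec.p_kinase_domain:
                lo, hi, region = kd_lo, kd_hi, "kinase_domain"
            elif u < spec.p_folded:
                lo, hi, region = of_lo, of_hi, "other_folded"
            else:
                lo, hi, region = 11, kd_lo - 21, "linker"
            res = int(rng.integers(lo, hi + 1))
            while res in used:
                res = int(rng.integers(lo, hi + 1))
            used.add(res)

            v = rng.random()
            if v < spec.p_sensitive:
                call = "sensitive"
                l2fc = float(rng.uniform(1.0, 3.0))
                quant = {MG132_COMPARISON: (l2fc, float(rng.uniform(0.0, 0.05)))}
            elif v < spec.p_sensitive + spec.p_insensitive:
                call = "insensitive"
                l2fc = float(rng.uniform(-1.0, 0.99))
                quant = {MG132_COMPARISON: (l2fc, float(rng.uniform(0.0, 0.05)))}
            else:
                call = "unknown"
                quant = {}

            near = bool(rng.random() < spec.p_near_phospho)
            if near:
                offset = int(rng.integers(-4, 5))
                phospho.append(SiteRecord(
                    protein_accession=acc, gene_name=acc,
                    residue_index=max(1, res + offset),
                    modification="phospho", quant={}, source=frozenset({"synthetic"}),
                ))
            sites.append(SiteRecord(
                protein_accession=acc, gene_name=acc, residue_index=res,
                modification="ubiquitin_remnant", quant=quant,
                source=frozenset({"synthetic"}),
                flags={"planted": {"sensitivity": call, "region": region,
                                   "near_phospho": near}},
            ))
    return sites, phospho, annotations


# ---------------------------------------------------------------------------
# Ideal-helix backbone builder
# ---------------------------------------------------------------------------

# standard backbone geometry (Engh–Huber-like), Angstrom / degrees
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
_OMEGA = 180.0


def _place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """Natural-extension position of atom d bonded to c (NeRF)."""
    theta = math.radians(angle_deg)
    chi = math.radians(dihedral_deg)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.cos(chi) * math.sin(theta),
        bond * math.sin(chi) * math.sin(theta),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.column_stack([bc, np.cross(n, bc), n])
    return c + m @ d_local


def build_ideal_helix(n_res: int, phi: float = -57.0, psi: float = -47.0,
                      sim_id: str = "helix") -> Trajectory:
    """Single-frame poly-alanine backbone (N, CA, C, O) with fixed torsions.

    With phi = -57, psi = -47 degrees the geometry forms the consecutive
    i -> i+4 backbone hydrogen bonds of an alpha helix.  Requires n_res >= 6
    so at least one residue can satisfy two consecutive 4-turns.
    """
    if n_res < 6:
        raise ValueError("n_res must be >= 6 (too short for a 4-turn)")
    coords: dict[tuple[int, str], np.ndarray] = {}
    # seed residue 1 in an arbitrary frame
    n0 = np.zeros(3)
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    th = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-math.cos(th), math.sin(th), 0.0])
    coords[(1, "N")], coords[(1, "CA")], coords[(1, "C")] = n0, ca0, c0

    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = (coords[(i, "N")], coords[(i, "CA")],
                                   coords[(i, "C")])
        n_new = _place_atom(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psi)
        ca_new = _place_atom(ca_prev, c_prev, n_new, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_new = _place_atom(c_prev, n_new, ca_new, _B_CA_C, _A_N_CA_C, phi)
        coords[(i + 1, "N")], coords[(i + 1, "CA")], coords[(i + 1, "C")] = (
            n_new, ca_new, c_new)
        # carbonyl O of residue i: trans to the next amide nitrogen
        coords[(i, "O")] = _place_atom(n_prev, ca_prev, c_prev, _B_C_O,
                                       _A_CA_C_O, psi + 180.0)
    coords[(n_res, "O")] = _place_atom(coords[(n_res, "N")], coords[(n_res, "CA")],
                                       coords[(n_res, "C")], _B_C_O, _A_CA_C_O,
                                       psi + 180.0)

    atoms, xyz = [], []
    for i in range(1, n_res + 1):
        for name in ("N", "CA", "C", "O"):
            atoms.append(Atom(name, name[0], i, "ALA"))
            xyz.append(coords[(i, name)])
    return Trajectory(Topology(atoms), np.array(xyz)[None, :, :], sim_id=sim_id)


def build_ideal_strand(n_res: int, sim_id: str = "strand") -> Trajectory:
    """Extended single strand (phi = -120, psi = +120): no helical H-bonds."""
    return build_ideal_helix(n_res, phi=-120.0, psi=120.0, sim_id=sim_id)


def build_antiparallel_sheet(n_res: int = 8, separation: float = 5.8,
                             register: float = 3.0,
                             sim_id: str = "sheet") -> Trajectory:
    """Two antiparallel extended strands at H-bonding distance.

    Strand one is an ideal extended chain (phi = -139, psi = +135); strand
    two is its image under the antiparallel-sheet dyad, a 180-degree rotation
    about the sheet normal, offset across the sheet by ``separation`` and
    along the strand axis by ``register`` so that backbone N-H and C=O groups
    pair into the ladder hydrogen bonds of an antiparallel beta sheet.
    Residues are numbered with a gap (chain break) between the strands.
    """
    s1 = build_ideal_helix(n_res, phi=-139.0, psi=135.0)
    xyz1 = s1.xyz[0]
    top1 = s1.topology
    ca = np.array([xyz1[top1.index_of(i, "CA")] for i in range(1, n_res + 1)])
    u = ca[-1] - ca[0]
    u /= np.linalg.norm(u)
    # mean in-plane carbonyl direction (alternating pleat sign), minus the
    # strand-axis component: points across the sheet toward the partner
    co = []
    for i in range(1, n_res + 1):
        vec = xyz1[top1.index_of(i, "O")] - xyz1[top1.index_of(i, "C")]
        co.append(vec * (-1.0) ** i)
    v = np.mean(co, axis=0)
    v -= u * (v @ u)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)  # sheet normal = dyad axis

    k = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
    rot = np.eye(3) + 2.0 * (k @ k)  # Rodrigues at 180 degrees
    center = xyz1.mean(axis=0)
    xyz2 = (xyz1 - center) @ rot.T + center + v * separation + u * register

    atoms2 = [Atom(a.name, a.element, a.residue_index + n_res + 10, a.residue_name)
              for a in top1.atoms]
    top = Topology(list(top1.atoms) + atoms2)
    return Trajectory(top, np.vstack([xyz1, xyz2])[None, :, :], sim_id=sim_id)


# ---------------------------------------------------------------------------
# Two-domain tethered ensemble
# ---------------------------------------------------------------------------

_DOMAIN_A_SIZE = 6
_DOMAIN_B_SIZE = 6
_TETHER_SIZE = 3


def _rigid_block(n: int, spacing: float = 3.8) -> np.ndarray:
    """n pseudo-residue centers on a compact 3D grid."""
    pts = []
    side = max(1, round(n ** (1 / 3)))
    i = 0
    for x in range(side + 2):
        for y in range(side + 2):
            for z in range(side + 2):
                if i >= n:
                    break
                pts.append([x * spacing, y * spacing, z * spacing])
                i += 1
    return np.array(pts[:n], dtype=float)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def synth_two_domain_ensemble(spec: SynthTrajSpec) -> EnsembleSet:
    """Two rigid pseudo-residue domains joined by a 3-residue flexible tether.

    Domain A (residues 1..6) is fixed; domain B (residues 10..15) is rigid but
    its orientation and tether extension are resampled each frame from the
    seeded distribution, standing in for a flexibly attached moiety sampling
    many relative orientations.  One carbon pseudo-atom per residue, so
    residue centers of mass equal the atom positions and true contact
    fractions are computable by exhaustive evaluation over the frames.
    """
    if spec.geometry != "two_domain_tether":
        raise ValueError("synth_two_domain_ensemble requires geometry="
                         "'two_domain_tether'")
    a_block = _rigid_block(_DOMAIN_A_SIZE)
    b_block = _rigid_block(_DOMAIN_B_SIZE)
    b_block -= b_block.mean(axis=0)
    anchor = a_block[-1]

    atoms = []
    for r in range(1, _DOMAIN_A_SIZE + 1):
        atoms.append(Atom("CA", "C", r, "GLY"))
    for t in range(1, _TETHER_SIZE + 1):
        atoms.append(Atom("CA", "C", _DOMAIN_A_SIZE + t, "GLY"))
    b_start = _DOMAIN_A_SIZE + _TETHER_SIZE + 1
    for r in range(_DOMAIN_B_SIZE):
        atoms.append(Atom("CA", "C", b_start + r, "GLY"))
    top = Topology(atoms)

    trajs = []
    for s in range(spec.n_sims):
        rng = np.random.default_rng([spec.seed, s])
        frames = np.empty((spec.frames_per_sim, top.n_atoms, 3))
        for f in range(spec.frames_per_sim):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            extension = rng.uniform(4.0, 14.0)  # tether reach, Angstrom
            tether = np.array([anchor + direction * extension * (t + 1) /
                               (_TETHER_SIZE + 1)
                               for t in range(_TETHER_SIZE)])
            center = anchor + direction * extension
            rot = _random_rotation(rng)
            b = b_block @ rot.T + center
            frames[f] = np.vstack([a_block, tether, b])
        trajs.append(Trajectory(top, frames, timestep=spec.timestep,
                                sim_id=f"sim{s}"))
    return EnsembleSet("two_domain", trajs)


# ---------------------------------------------------------------------------
# AR(1) metric series for two constructs
# ---------------------------------------------------------------------------

def synth_metric_groups(n_sims: int = 32, frames: int = 100, shift: float = 0.0,
                        rho: float = 0.5, seed: int = 0, baseline: float = 10.0,
                        sigma: float = 1.0):
    """Two groups of per-simulation metric series differing by a location shift.

    Group A fluctuates around ``baseline``; group B around ``baseline +
    shift``.  Within each simulation the series is a stationary AR(1) with
    lag-1 autocorrelation ``rho`` and marginal standard deviation ``sigma``,
    the minimal emulation of within-trajectory correlation.  Per-simulation
    streams derive deterministically from (seed, group, sim index).
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must satisfy 0 <= rho < 1")

    def make_group(group_idx: int, mu: float) -> list[MetricSeries]:
        out = []
        for s in range(n_sims):
            rng = np.random.default_rng([seed, group_idx, s])
            eps = rng.normal(size=frames)
            x = np.empty(frames)
            x[0] = mu + sigma * eps[0]
            innov = sigma * math.sqrt(1.0 - rho * rho)
            for t in range(1, frames):
                x[t] = mu + rho * (x[t - 1] - mu) + innov * eps[t]
            out.append(MetricSeries(sim_id=f"g{group_idx}_sim{s}", values=x))
        return out

    return make_group(0, baseline), make_group(1, baseline + shift)
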