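"""Coarse-grained chromatin fiber representation and energy evaluation.

The fiber is modelled at nucleosome resolution with four element types:

* nucleosome cores -- a geometric centre plus surface charge beads placed
  on a cylinder (5.5 nm radius x 5.5 nm height), standing in for the
  optimized surface-charge representation of the nucleosome;
* linker DNA -- a worm-like-chain bead model (one bead per ~9 bp, 3 nm
  equilibrium segments) with harmonic stretching, bending and twisting;
* histone tails -- flexible bead chains (five residues per bead: H3 and
  H4 five beads, H2B five, H2A N-tail three, H2A C-tail two, two copies
  each) grafted to core surface beads.  Acetylated tails adopt a compact
  folded state whose force constants are multiplied by a rigidity factor
  (100 by default) and which is excluded from all nonbonded interactions;
* linker histones -- on flagged nucleosomes, a 6-bead globular domain plus
  a 22-bead (H1e) or 21-bead (H1c) C-terminal domain chain.

Energies are expressed in units of k_B T at the configured temperature.
Nonbonded interactions use Debye-Hueckel screened electrostatics and 12-6
Lennard-Jones excluded volume within a cutoff; divalent-magnesium
conditions are modelled phenomenologically by reducing the DNA persistence
length from 50 nm to 30 nm and screening DNA--DNA electrostatics with a
larger inverse Debye length.  Charge magnitudes and LJ parameters are
plausible stand-ins (flagged in config metadata), not values re-derived
from atomistic structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .synthetic_data import NucleosomeTrack

__all__ = [
    "ForceFieldParams",
    "SimulationConditions",
    "FiberTopology",
    "FiberConfiguration",
    "Tail",
    "build_topology",
    "build_initial_fiber",
    "bonded_energy",
    "bonded_gradient",
    "nonbonded_energy",
    "total_energy",
    "FiberEnergyModel",
]

# bead classes
CORE_CENTER, CORE_CHARGE, DNA, TAIL, LH = 0, 1, 2, 3, 4

TAIL_KINDS = ("H3", "H4", "H2A-N", "H2A-C", "H2B")
TAIL_BEAD_COUNTS = {"H3": 5, "H4": 5, "H2A-N": 3, "H2A-C": 2, "H2B": 5}

def _coulomb_prefactor(temperature: float, eps_r: float) -> float:
    """e^2 / (4 pi eps0 eps_r) in units of kT(temperature) * nm."""
    e = 1.602176634e-19
    eps0 = 8.8541878128e-12
    kb = 1.380649e-23
    joule_nm = e * e / (4 * math.pi * eps0 * eps_r * 1e-9)
    return joule_nm / (kb * temperature)


@dataclass(frozen=True)
class ForceFieldParams:
    """Force-field structure and constants (energies in kT, lengths in nm).

    The functional forms are harmonic stretching/bending/twisting for the
    DNA chain, screened Coulomb electrostatics and 12-6 LJ excluded
    volume.  Charge magnitudes are stand-ins (see module docstring).
    """

    stretch_k: float = 100.0            # kT / nm^2, DNA backbone
    dna_segment_length: float = 3.0     # nm per DNA bead (~9 bp)
    bp_per_bead: int = 9
    persistence_length: float = 50.0    # nm, monovalent-salt default
    mg_persistence_length: float = 30.0  # nm, divalent mode
    torsional_persistence: float = 75.0  # nm
    eps_r: float = 80.0
    kappa: float = 1.27                 # 1/nm at 150 mM monovalent
    kappa_dd_mg: float = 2.5            # 1/nm, DNA-DNA screening in Mg mode
    cutoff: float = 7.0                 # nm, nonbonded cutoff
    lj_eps: float = 0.001               # kT, excluded-volume well depth
    rigidity_multiplier: float = 100.0  # folded (acetylated) tails
    # charges (e)
    dna_bead_charge: float = -4.0
    core_total_charge: float = -72.0
    tail_bead_charges: dict = field(
        default_factory=lambda: {
            "H3": 1.7, "H4": 2.1, "H2A-N": 1.4, "H2A-C": 1.1, "H2B": 1.3
        }
    )
    lh_globular_charge: float = 6.0     # e per globular bead (effective)
    lh_ctd_charge: float = 4.5          # e per C-terminal bead (effective)
    # LJ diameters (nm) per bead class
    sigma_core: float = 2.0
    sigma_dna: float = 2.4
    sigma_tail: float = 1.8
    sigma_lh: float = 1.8
    # geometry
    n_core_charge_beads: int = 48
    core_radius: float = 4.0            # nm, charge-bead placement radius
    core_height: float = 4.0            # nm
    tail_bond_length: float = 1.5       # nm
    tail_bend_g: float = 5.0            # kT / rad^2
    lh_bond_length: float = 1.5
    lh_attach_length: float = 5.0       # first LH bead from core centre
    lh_bend_g: float = 2.0
    folded_scale: float = 0.5           # folded-template bond compression
    charges_are_standins: bool = True   # metadata flag, see Open Questions

    def validate(self) -> None:
        if self.persistence_length not in (50.0, 30.0) and not (
            self.persistence_length > 0
        ):
            raise ValueError("persistence_length must be positive")
        for name in ("sigma_core", "sigma_dna", "sigma_tail", "sigma_lh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.rigidity_multiplier <= 0:
            raise ValueError("rigidity_multiplier must be > 0")


@dataclass(frozen=True)
class SimulationConditions:
    """Solution conditions: defaults are 293 K, 150 mM monovalent salt,
    divalent-magnesium mode on."""

    temperature: float = 293.0
    monovalent_mm: float = 150.0
    mg_mode: bool = True


@dataclass
class Tail:
    """One histone tail: bead index range, graft bead, fold state."""

    nuc: int
    kind: str
    copy: int
    start: int                 # first bead index (inclusive)
    n_beads: int
    anchor: int                # core charge bead the tail is grafted to
    acetylated: bool
    folded: bool
    bond_ids: np.ndarray = None
    angle_ids: np.ndarray = None

    @property
    def beads(self) -> np.ndarray:
        return np.arange(self.start, self.start + self.n_beads)


@dataclass
class FiberTopology:
    """Bookkeeping of the coarse-grained elements per nucleosome."""

    n_cores: int
    linker_bead_counts: np.ndarray     # (n_cores - 1,)
    acetylated: np.ndarray             # bool per core
    lh_present: np.ndarray             # bool per core
    lh_subtype: np.ndarray             # 'H1e' | 'H1c' per core
    n_core_charge_beads: int

    def __post_init__(self):
        if np.any(self.linker_bead_counts < 0):
            raise ValueError("negative linker bead count")

    @property
    def lh_density(self) -> float:
        return float(self.lh_present.mean())

    def lh_bead_count(self, core: int) -> int:
        return 6 + (22 if self.lh_subtype[core] == "H1e" else 21)


def build_topology(track: NucleosomeTrack, ff: ForceFieldParams) -> FiberTopology:
    """Map a nucleosome track to coarse-grained element counts.

    Linker bead counts are ``round(linker_bp / bp_per_bead)`` where the
    linker is the inter-dyad spacing minus the 147 bp footprint."""
    if track.n_nucleosomes < 1:
        raise ValueError("track is empty")
    linker_bp = track.linker_lengths
    if np.any(linker_bp < 0):
        raise ValueError("negative linker length after footprint accounting")
    counts = np.rint(linker_bp / ff.bp_per_bead).astype(int)
    return FiberTopology(
        n_cores=track.n_nucleosomes,
        linker_bead_counts=counts,
        acetylated=track.acetylated.copy(),
        lh_present=track.lh_bound.copy(),
        lh_subtype=np.array(["H1e"] * track.n_nucleosomes, dtype=object),
        n_core_charge_beads=ff.n_core_charge_beads,
    )


#: tail kinds whose fold state follows the nucleosome acetylation flag
ACETYLATION_FOLDS = ("H3", "H4")


def _core_charge_layout(ff: ForceFieldParams) -> np.ndarray:
    """Charge-bead offsets from the core centre: points distributed on the
    lateral surface of the core cylinder (axis along y) by golden angle."""
    n = ff.n_core_charge_beads
    k = np.arange(n)
    theta = k * (math.pi * (3 - math.sqrt(5)))
    y = (k + 0.5) / n * ff.core_height - ff.core_height / 2
    return np.column_stack(
        [ff.core_radius * np.cos(theta), y, ff.core_radius * np.sin(theta)]
    )


def _tail_anchor_beads(ff: ForceFieldParams) -> np.ndarray:
    """Ten charge-bead indices (per core) used as tail graft points."""
    n = ff.n_core_charge_beads
    return (np.arange(10) * n // 10) % n


@dataclass
class FiberConfiguration:
    """Complete bead-level state of one chromatin fiber.

    Flat arrays over all beads plus the per-tail registry, the global
    bonded-term tables (mutated in place by fold-state changes) and the
    per-segment DNA twist register.
    """

    topology: FiberTopology
    ff: ForceFieldParams
    positions: np.ndarray        # (N, 3) nm
    bead_class: np.ndarray       # int8
    group: np.ndarray            # int32 nonbonded exclusion group
    nuc_of_bead: np.ndarray      # int32; linker beads carry the left core
    charge: np.ndarray
    sigma: np.ndarray
    active: np.ndarray           # bool; folded tail beads are inactive
    core_center_idx: np.ndarray  # (n_cores,)
    backbone_idx: np.ndarray     # bead indices in chain order
    chain_pos_of_bead: np.ndarray  # backbone node position governing each bead
    dna_segment_of_bead: np.ndarray  # backbone-bond id for DNA beads, -1 else
    twist: np.ndarray            # (n_backbone_bonds,) rad
    twist_c: float               # kT nm torsional stiffness / segment length
    bonds_idx: np.ndarray        # (B, 2)
    bonds_k: np.ndarray
    bonds_l0: np.ndarray
    angles_idx: np.ndarray       # (A, 3)
    angles_g: np.ndarray
    angles_th0: np.ndarray
    tails: list
    lh_slices: dict              # core -> (start, stop) bead range
    bead_bonds: list             # per-bead bond id arrays
    bead_angles: list            # per-bead angle id arrays

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def core_positions(self) -> np.ndarray:
        return self.positions[self.core_center_idx]

    @property
    def lh_concentration(self) -> float:
        return self.topology.lh_density

    def unfolded_tails(self) -> list:
        return [t for t in self.tails if not t.folded]

    def snapshot(self) -> dict:
        return {
            "positions": self.positions.copy(),
            "twist": self.twist.copy(),
            "folded": np.array([t.folded for t in self.tails]),
        }

    def restore(self, snap: dict) -> None:
        self.positions[:] = snap["positions"]
        self.twist[:] = snap["twist"]
        for t, f in zip(self.tails, snap["folded"]):
            if t.folded != bool(f):
                apply_fold_state(self, t, bool(f))


def _local_fiber_axis(config: FiberConfiguration, nuc: int) -> np.ndarray:
    """Unit vector along the fiber axis at nucleosome ``nuc``, estimated
    from the neighbouring core centres."""
    cores = config.core_positions
    i0 = max(nuc - 1, 0)
    i1 = min(nuc + 1, len(cores) - 1)
    if i0 == i1:
        return np.array([0.0, 0.0, 1.0])
    d = cores[i1] - cores[i0]
    nrm = np.linalg.norm(d)
    return d / nrm if nrm > 1e-12 else np.array([0.0, 0.0, 1.0])


def tail_direction(config: FiberConfiguration, tail: Tail) -> np.ndarray:
    """Canonical tail graft direction: the component of the centre-to-
    anchor vector perpendicular to the local fiber axis (tails radiate
    outward from the fiber, not into neighbouring cores)."""
    anchor = config.positions[tail.anchor]
    center = config.positions[config.core_center_idx[tail.nuc]]
    d = anchor - center
    axis = _local_fiber_axis(config, tail.nuc)
    perp = d - (d @ axis) * axis
    nrm = np.linalg.norm(perp)
    if nrm < 1e-9:
        # anchor sits on the axis: fall back to any perpendicular
        perp = np.cross(axis, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(perp) < 1e-9:
            perp = np.cross(axis, np.array([0.0, 1.0, 0.0]))
        nrm = np.linalg.norm(perp)
    perp = perp / nrm
    # tilt out of the zigzag plane, alternating with nucleosome parity, so
    # the canonical tails of neighbouring cores do not run parallel
    binormal = np.cross(axis, perp)
    tilt = math.radians(35.0) * (1.0 if tail.nuc % 2 == 0 else -1.0)
    return math.cos(tilt) * perp + math.sin(tilt) * binormal


def straight_tail_template(config: FiberConfiguration, tail: Tail) -> np.ndarray:
    """Canonical unfolded tail conformation: straight chain grafted
    outward from the anchor bead, perpendicular to the local fiber axis."""
    ff = config.ff
    anchor = config.positions[tail.anchor]
    u = tail_direction(config, tail)
    steps = np.arange(1, tail.n_beads + 1)[:, None]
    return anchor + steps * ff.tail_bond_length * u


def folded_tail_template(config: FiberConfiguration, tail: Tail) -> np.ndarray:
    """Compact folded conformation: the straight template compressed
    toward the anchor by the folded bond scale."""
    ff = config.ff
    anchor = config.positions[tail.anchor]
    straight = straight_tail_template(config, tail)
    return anchor + (straight - anchor) * ff.folded_scale


def apply_fold_state(config: FiberConfiguration, tail: Tail, folded: bool) -> None:
    """Set a tail's fold state: template coordinates, equilibrium values
    and force constants, and the nonbonded-active mask."""
    ff = config.ff
    if folded:
        coords = folded_tail_template(config, tail)
        l0 = ff.tail_bond_length * ff.folded_scale
        mult = ff.rigidity_multiplier
    else:
        coords = straight_tail_template(config, tail)
        l0 = ff.tail_bond_length
        mult = 1.0
    config.positions[tail.start : tail.start + tail.n_beads] = coords
    config.bonds_l0[tail.bond_ids] = l0
    config.bonds_k[tail.bond_ids] = ff.stretch_k * mult
    config.angles_g[tail.angle_ids] = ff.tail_bend_g * mult
    # both templates are straight through the anchor: equilibrium angle pi
    config.angles_th0[tail.angle_ids] = math.pi
    config.active[tail.start : tail.start + tail.n_beads] = not folded
    tail.folded = folded


ALLOWED_B_TWIST = (-12.0, 0.0, 12.0)


def build_initial_fiber(
    track: NucleosomeTrack,
    ff: ForceFieldParams = ForceFieldParams(),
    cond: SimulationConditions = SimulationConditions(),
    b_twist: float = 0.0,
    seed: int = 0,
) -> FiberConfiguration:
    """Construct the starting configuration on an ideal two-start zigzag.

    Cores are placed on a zigzag whose inter-core separation equals the
    equilibrium linker contour length; linker DNA beads are interpolated
    between cores; tails are attached in the straight reference
    configuration, with the folded state applied to the H3/H4 tails of
    acetylation-flagged nucleosomes; LH chains are placed on flagged
    cores.  ``b_twist`` (degrees, one of -12, 0, +12) initializes the DNA
    twist register uniformly.
    """
    if b_twist not in ALLOWED_B_TWIST:
        raise ValueError(f"b_twist must be one of {ALLOWED_B_TWIST}, got {b_twist}")
    ff.validate()
    topo = build_topology(track, ff)
    n_cores = topo.n_cores
    nb = topo.linker_bead_counts
    l0 = ff.dna_segment_length

    # zigzag core centres in the xz-plane
    alpha = math.radians(50.0)
    centers = np.zeros((n_cores, 3))
    for i in range(1, n_cores):
        seg = (nb[i - 1] + 1) * l0
        sgn = 1.0 if (i - 1) % 2 == 0 else -1.0
        direction = np.array([sgn * math.sin(alpha), 0.0, math.cos(alpha)])
        centers[i] = centers[i - 1] + seg * direction

    charge_layout = _core_charge_layout(ff)
    anchor_local = _tail_anchor_beads(ff)
    q_core_bead = ff.core_total_charge / ff.n_core_charge_beads

    pos, cls, grp, nuc, q, sg = [], [], [], [], [], []
    core_center_idx = np.zeros(n_cores, dtype=np.int64)
    charge_start = np.zeros(n_cores, dtype=np.int64)
    backbone = []

    def add_bead(p, c, g, nu, qq, ss):
        pos.append(p)
        cls.append(c)
        grp.append(g)
        nuc.append(nu)
        q.append(qq)
        sg.append(ss)
        return len(pos) - 1

    # cores + linkers along the backbone
    for i in range(n_cores):
        ci = add_bead(centers[i], CORE_CENTER, i, i, 0.0, 0.0)
        core_center_idx[i] = ci
        backbone.append(ci)
        charge_start[i] = len(pos)
        for off in charge_layout:
            add_bead(centers[i] + off, CORE_CHARGE, i, i, q_core_bead,
                     ff.sigma_core)
        if i < n_cores - 1:
            for j in range(nb[i]):
                frac = (j + 1) / (nb[i] + 1)
                p = centers[i] + frac * (centers[i + 1] - centers[i])
                bi = add_bead(p, DNA, n_cores + i, i, ff.dna_bead_charge,
                              ff.sigma_dna)
                backbone.append(bi)

    # tails
    tails: list[Tail] = []
    for i in range(n_cores):
        lay = 0
        for kind in TAIL_KINDS:
            for copy in range(2):
                anchor = int(charge_start[i] + anchor_local[lay])
                lay += 1
                nb_t = TAIL_BEAD_COUNTS[kind]
                start = len(pos)
                center = centers[i]
                apos = np.asarray(pos[anchor])
                d = apos - center
                u = d / np.linalg.norm(d)
                for jb in range(nb_t):
                    p = apos + (jb + 1) * ff.tail_bond_length * u
                    add_bead(p, TAIL, i, i, ff.tail_bead_charges[kind],
                             ff.sigma_tail)
                acet = bool(topo.acetylated[i]) and kind in ACETYLATION_FOLDS
                tails.append(
                    Tail(i, kind, copy, start, nb_t, anchor, acet, False)
                )

    # linker histones
    lh_slices = {}
    for i in range(n_cores):
        if not topo.lh_present[i]:
            continue
        n_lh = topo.lh_bead_count(i)
        start = len(pos)
        u = np.array([-1.0 if i % 2 == 0 else 1.0, 0.0, 0.0])
        # compact helix around the outward direction: keeps the chain near
        # its core (instead of a 40 nm straight spike) while respecting the
        # equilibrium bond length
        origin = centers[i] + ff.lh_attach_length * u
        e1 = np.array([0.0, 1.0, 0.0])
        e2 = np.cross(u, e1)
        r_hel = 2.0
        rise = 0.5
        dtheta = math.sqrt(max(ff.lh_bond_length**2 - rise**2, 1e-6)) / r_hel
        for jb in range(n_lh):
            th = jb * dtheta
            p = (origin + jb * rise * u
                 + r_hel * (math.cos(th) * e1 + math.sin(th) * e2)
                 - r_hel * e1)
            qq = ff.lh_globular_charge if jb < 6 else ff.lh_ctd_charge
            add_bead(p, LH, i, i, qq, ff.sigma_lh)
        lh_slices[i] = (start, len(pos))

    positions = np.asarray(pos, dtype=np.float64)
    n_beads = len(positions)
    bead_class = np.asarray(cls, dtype=np.int8)
    group = np.asarray(grp, dtype=np.int32)
    nuc_of_bead = np.asarray(nuc, dtype=np.int32)
    charge = np.asarray(q, dtype=np.float64)
    sigma = np.asarray(sg, dtype=np.float64)
    active = np.ones(n_beads, dtype=bool)
    backbone_idx = np.asarray(backbone, dtype=np.int64)

    # chain position per bead: appendages share their core's node position
    chain_pos = np.zeros(n_beads, dtype=np.int64)
    node_of_core = {}
    for rank, bi in enumerate(backbone_idx):
        chain_pos[bi] = rank
        if bead_class[bi] == CORE_CENTER:
            node_of_core[int(bi)] = rank
    for b in range(n_beads):
        if bead_class[b] in (CORE_CHARGE, TAIL, LH):
            chain_pos[b] = node_of_core[int(core_center_idx[nuc_of_bead[b]])]

    # bonded tables
    lp = ff.mg_persistence_length if cond.mg_mode else ff.persistence_length
    g_dna = lp / l0  # kT per rad^2 (Lp * kT / l0 with kT = 1)
    bonds, bk, bl = [], [], []
    angles, ag, ath = [], [], []

    def add_bond(i, j, k_, l_):
        bonds.append((i, j))
        bk.append(k_)
        bl.append(l_)
        return len(bonds) - 1

    def add_angle(i, j, k, g_, th0):
        angles.append((i, j, k))
        ag.append(g_)
        ath.append(th0)
        return len(angles) - 1

    for a, b in zip(backbone_idx[:-1], backbone_idx[1:]):
        add_bond(int(a), int(b), ff.stretch_k, l0)
    for a, b, c in zip(backbone_idx[:-2], backbone_idx[1:-1], backbone_idx[2:]):
        add_angle(int(a), int(b), int(c), g_dna, math.pi)

    # DNA segment (backbone bond) owning each DNA bead: the bond ending at it
    dna_segment_of_bead = np.full(n_beads, -1, dtype=np.int64)
    for rank in range(1, len(backbone_idx)):
        bi = backbone_idx[rank]
        if bead_class[bi] == DNA:
            dna_segment_of_bead[bi] = rank - 1

    for t in tails:
        ids = []
        prev = t.anchor
        for jb in range(t.n_beads):
            ids.append(add_bond(prev, t.start + jb, ff.stretch_k,
                                ff.tail_bond_length))
            prev = t.start + jb
        aids = []
        chain = [t.anchor] + list(range(t.start, t.start + t.n_beads))
        for x, y, z in zip(chain[:-2], chain[1:-1], chain[2:]):
            aids.append(add_angle(x, y, z, ff.tail_bend_g, math.pi))
        t.bond_ids = np.asarray(ids, dtype=np.int64)
        t.angle_ids = np.asarray(aids, dtype=np.int64)

    for i, (start, stop) in lh_slices.items():
        chain = [int(core_center_idx[i])] + list(range(start, stop))
        add_bond(chain[0], chain[1], ff.stretch_k, ff.lh_attach_length)
        for a, b in zip(chain[1:-1], chain[2:]):
            add_bond(a, b, ff.stretch_k, ff.lh_bond_length)
        for x, y, z in zip(chain[:-2], chain[1:-1], chain[2:]):
            add_angle(x, y, z, ff.lh_bend_g, math.pi)

    bonds_idx = np.asarray(bonds, dtype=np.int64)
    angles_idx = (
        np.asarray(angles, dtype=np.int64)
        if angles
        else np.zeros((0, 3), dtype=np.int64)
    )
    bead_bonds = [[] for _ in range(n_beads)]
    for bid, (i, j) in enumerate(bonds):
        bead_bonds[i].append(bid)
        bead_bonds[j].append(bid)
    bead_angles = [[] for _ in range(n_beads)]
    for aid, (i, j, k) in enumerate(angles):
        for b in (i, j, k):
            bead_angles[b].append(aid)

    config = FiberConfiguration(
        topology=topo,
        ff=ff,
        positions=positions,
        bead_class=bead_class,
        group=group,
        nuc_of_bead=nuc_of_bead,
        charge=charge,
        sigma=sigma,
        active=active,
        core_center_idx=core_center_idx,
        backbone_idx=backbone_idx,
        chain_pos_of_bead=chain_pos,
        dna_segment_of_bead=dna_segment_of_bead,
        twist=np.full(len(backbone_idx) - 1, math.radians(b_twist)),
        twist_c=ff.torsional_persistence / l0,
        bonds_idx=bonds_idx,
        bonds_k=np.asarray(bk, dtype=np.float64),
        bonds_l0=np.asarray(bl, dtype=np.float64),
        angles_idx=angles_idx,
        angles_g=np.asarray(ag, dtype=np.float64),
        angles_th0=np.asarray(ath, dtype=np.float64),
        tails=tails,
        lh_slices=lh_slices,
        bead_bonds=[np.asarray(x, dtype=np.int64) for x in bead_bonds],
        bead_angles=[np.asarray(x, dtype=np.int64) for x in bead_angles],
    )
    for t in tails:
        apply_fold_state(config, t, t.acetylated)
    _relax_initial_tails(config, cond)
    return config


def _relax_initial_tails(config: FiberConfiguration,
                         cond: SimulationConditions) -> None:
    """Deterministic build-time relaxation: each unfolded tail is swept
    over a fan of straight graft directions around the local fiber axis
    (with small axial elevations) and the lowest-nonbonded-energy
    direction is kept.  Removes the steric clashes that straight radial
    grafting produces on a crowded zigzag."""
    model = FiberEnergyModel(config, config.ff, cond)
    ff = config.ff
    elevations = (0.0, math.radians(25.0), math.radians(-25.0))
    sweep = np.linspace(0.0, 2 * math.pi, 24, endpoint=False)
    for t in config.tails:
        if t.folded:
            continue
        axis = _local_fiber_axis(config, t.nuc)
        perp = tail_direction(config, t)
        binormal = np.cross(axis, perp)
        anchor = config.positions[t.anchor]
        steps = np.arange(1, t.n_beads + 1)[:, None] * ff.tail_bond_length
        best_e, best_pos = np.inf, None
        for elev in elevations:
            for a in sweep:
                u = math.cos(elev) * (math.cos(a) * perp
                                      + math.sin(a) * binormal)                     + math.sin(elev) * axis
                cand = anchor + steps * u
                e = model.interaction_with_rest(t.beads, positions=cand)
                if e < best_e:
                    best_e, best_pos = e, cand
        config.positions[t.beads] = best_pos


# ---------------------------------------------------------------------------
# bonded energy
# ---------------------------------------------------------------------------

def _bond_terms(pos, idx, k, l0):
    d = pos[idx[:, 1]] - pos[idx[:, 0]]
    r = np.linalg.norm(d, axis=1)
    return 0.5 * k * (r - l0) ** 2


def _angle_values(pos, idx):
    u = pos[idx[:, 0]] - pos[idx[:, 1]]
    v = pos[idx[:, 2]] - pos[idx[:, 1]]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    c = np.einsum("ij,ij->i", u, v) / (nu * nv)
    return np.arccos(np.clip(c, -1.0, 1.0))


def bonded_energy(config: FiberConfiguration, ff: ForceFieldParams | None = None):
    """Stretch, bend and twist components (kT).  Folded tails sit exactly
    at their rigid template so their terms vanish."""
    pos = config.positions
    if np.isnan(pos).any():
        raise ValueError("NaN coordinates in configuration")
    stretch = float(_bond_terms(pos, config.bonds_idx, config.bonds_k,
                                config.bonds_l0).sum())
    if len(config.angles_idx):
        th = _angle_values(pos, config.angles_idx)
        bend = float((0.5 * config.angles_g * (th - config.angles_th0) ** 2).sum())
    else:
        bend = 0.0
    twist = float((0.5 * config.twist_c * config.twist**2).sum())
    return {"stretch": stretch, "bend": bend, "twist": twist,
            "total": stretch + bend + twist}


def bonded_gradient(config: FiberConfiguration) -> np.ndarray:
    """Analytic gradient of the stretch + bend energy with respect to all
    bead positions (the twist register carries no positional gradient)."""
    pos = config.positions
    grad = np.zeros_like(pos)
    idx = config.bonds_idx
    d = pos[idx[:, 1]] - pos[idx[:, 0]]
    r = np.linalg.norm(d, axis=1)
    f = (config.bonds_k * (r - config.bonds_l0) / np.maximum(r, 1e-12))[:, None] * d
    np.add.at(grad, idx[:, 1], f)
    np.add.at(grad, idx[:, 0], -f)
    aidx = config.angles_idx
    if len(aidx):
        u = pos[aidx[:, 0]] - pos[aidx[:, 1]]
        v = pos[aidx[:, 2]] - pos[aidx[:, 1]]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        c = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
        th = np.arccos(c)
        s = np.sqrt(np.maximum(1.0 - c * c, 1e-14))
        pref = (config.angles_g * (th - config.angles_th0) / -s)[:, None]
        dcdu = v / (nu * nv)[:, None] - (c / nu**2)[:, None] * u
        dcdv = u / (nu * nv)[:, None] - (c / nv**2)[:, None] * v
        gi = pref * dcdu
        gk = pref * dcdv
        np.add.at(grad, aidx[:, 0], gi)
        np.add.at(grad, aidx[:, 2], gk)
        np.add.at(grad, aidx[:, 1], -(gi + gk))
    return grad


# ---------------------------------------------------------------------------
# nonbonded energy (numba kernels)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _nb_all(pos, q, sigma, group, is_dna, active, kappa, kappa_dd, pref,
            lj_eps, cutoff):
    n = pos.shape[0]
    cutoff2 = cutoff * cutoff
    e_el = 0.0
    e_lj = 0.0
    for i in range(n):
        if not active[i]:
            continue
        for j in range(i + 1, n):
            if not active[j]:
                continue
            if group[i] == group[j]:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > cutoff2:
                continue
            if r2 < 1e-18:
                return np.nan, np.nan
            r = math.sqrt(r2)
            if q[i] != 0.0 and q[j] != 0.0:
                k = kappa_dd if (is_dna[i] and is_dna[j]) else kappa
                e_el += pref * q[i] * q[j] * math.exp(-k * r) / r
            if sigma[i] > 0.0 and sigma[j] > 0.0:
                s = 0.5 * (sigma[i] + sigma[j])
                sr6 = (s * s / r2) ** 3
                e_lj += 4.0 * lj_eps * (sr6 * sr6 - sr6)
    return e_el, e_lj


@njit(cache=True, fastmath=True)
def _nb_between(posA, qA, sA, gA, dA, actA, posB, qB, sB, gB, dB, actB,
                kappa, kappa_dd, pref, lj_eps, cutoff):
    cutoff2 = cutoff * cutoff
    e = 0.0
    for a in range(posA.shape[0]):
        if not actA[a]:
            continue
        for b in range(posB.shape[0]):
            if not actB[b]:
                continue
            if gA[a] == gB[b]:
                continue
            dx = posA[a, 0] - posB[b, 0]
            dy = posA[a, 1] - posB[b, 1]
            dz = posA[a, 2] - posB[b, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > cutoff2:
                continue
            if r2 < 1e-18:
                return np.nan
            r = math.sqrt(r2)
            if qA[a] != 0.0 and qB[b] != 0.0:
                k = kappa_dd if (dA[a] and dB[b]) else kappa
                e += pref * qA[a] * qB[b] * math.exp(-k * r) / r
            if sA[a] > 0.0 and sB[b] > 0.0:
                s = 0.5 * (sA[a] + sB[b])
                sr6 = (s * s / r2) ** 3
                e += 4.0 * lj_eps * (sr6 * sr6 - sr6)
    return e


@njit(cache=True, fastmath=True)
def _nb_points(points, qa, sa, ga, da, pos, q, sigma, group, is_dna, actB,
               kappa, kappa_dd, pref, lj_eps, cutoff):
    """Nonbonded energy of each candidate point against all active beads."""
    k = points.shape[0]
    n = pos.shape[0]
    cutoff2 = cutoff * cutoff
    out = np.zeros(k)
    for b in range(n):
        if not actB[b]:
            continue
        if group[b] == ga:
            continue
        qb = q[b]
        sb = sigma[b]
        db = is_dna[b]
        for t in range(k):
            dx = points[t, 0] - pos[b, 0]
            dy = points[t, 1] - pos[b, 1]
            dz = points[t, 2] - pos[b, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > cutoff2:
                continue
            if r2 < 1e-18:
                out[t] = np.inf
                continue
            r = math.sqrt(r2)
            if qa != 0.0 and qb != 0.0:
                kap = kappa_dd if (da and db) else kappa
                out[t] += pref * qa * qb * math.exp(-kap * r) / r
            if sa > 0.0 and sb > 0.0:
                s = 0.5 * (sa + sb)
                sr6 = (s * s / r2) ** 3
                out[t] += 4.0 * lj_eps * (sr6 * sr6 - sr6)
    return out


@njit(cache=True, fastmath=True)
def _nb_delta_set(oldA, newA, qA, sA, gA, dA, actA, pos, q, sigma, group,
                  is_dna, actB, kappa, kappa_dd, pref, lj_eps, cutoff):
    """e(newA vs rest) - e(oldA vs rest) in a single pass."""
    cutoff2 = cutoff * cutoff
    de = 0.0
    for a in range(oldA.shape[0]):
        if not actA[a]:
            continue
        qa = qA[a]
        sa = sA[a]
        ga = gA[a]
        da = dA[a]
        for b in range(pos.shape[0]):
            if not actB[b]:
                continue
            if ga == group[b]:
                continue
            qb = q[b]
            sb = sigma[b]
            for which in range(2):
                if which == 0:
                    dx = oldA[a, 0] - pos[b, 0]
                    dy = oldA[a, 1] - pos[b, 1]
                    dz = oldA[a, 2] - pos[b, 2]
                    sign = -1.0
                else:
                    dx = newA[a, 0] - pos[b, 0]
                    dy = newA[a, 1] - pos[b, 1]
                    dz = newA[a, 2] - pos[b, 2]
                    sign = 1.0
                r2 = dx * dx + dy * dy + dz * dz
                if r2 > cutoff2:
                    continue
                if r2 < 1e-18:
                    return np.nan
                r = math.sqrt(r2)
                e = 0.0
                if qa != 0.0 and qb != 0.0:
                    kap = kappa_dd if (da and is_dna[b]) else kappa
                    e += pref * qa * qb * math.exp(-kap * r) / r
                if sa > 0.0 and sb > 0.0:
                    s = 0.5 * (sa + sb)
                    sr6 = (s * s / r2) ** 3
                    e += 4.0 * lj_eps * (sr6 * sr6 - sr6)
                de += sign * e
    return de


@njit(cache=True, fastmath=True)
def _bond_subset(pos, idx2, k, l0):
    e = 0.0
    for t in range(idx2.shape[0]):
        i = idx2[t, 0]
        j = idx2[t, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        e += 0.5 * k[t] * (r - l0[t]) ** 2
    return e


@njit(cache=True, fastmath=True)
def _angle_subset(pos, idx3, g, th0):
    e = 0.0
    for t in range(idx3.shape[0]):
        i = idx3[t, 0]
        j = idx3[t, 1]
        kk = idx3[t, 2]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[kk, 0] - pos[j, 0]
        vy = pos[kk, 1] - pos[j, 1]
        vz = pos[kk, 2] - pos[j, 2]
        nu = math.sqrt(ux * ux + uy * uy + uz * uz)
        nv = math.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        th = math.acos(c)
        e += 0.5 * g[t] * (th - th0[t]) ** 2
    return e


class FiberEnergyModel:
    """Evaluates total and incremental energies of one configuration.

    Holds the static nonbonded parameters; all methods act on the
    configuration's live arrays so fold-state changes are picked up
    automatically.
    """

    def __init__(self, config: FiberConfiguration,
                 ff: ForceFieldParams | None = None,
                 cond: SimulationConditions = SimulationConditions()):
        self.config = config
        self.ff = ff or config.ff
        self.cond = cond
        self.pref = _coulomb_prefactor(cond.temperature, self.ff.eps_r)
        self.kappa = self.ff.kappa
        self.kappa_dd = self.ff.kappa_dd_mg if cond.mg_mode else self.ff.kappa
        self.is_dna = (config.bead_class == DNA).astype(np.bool_)

    # -- totals ------------------------------------------------------------
    def nonbonded(self) -> dict:
        c = self.config
        e_el, e_lj = _nb_all(
            c.positions, c.charge, c.sigma, c.group, self.is_dna,
            c.active, self.kappa, self.kappa_dd, self.pref,
            self.ff.lj_eps, self.ff.cutoff,
        )
        if np.isnan(e_el):
            raise ValueError("overlapping beads at r=0 in nonbonded energy")
        return {"electrostatic": float(e_el), "excluded_volume": float(e_lj),
                "total": float(e_el + e_lj)}

    def bonded(self) -> dict:
        return bonded_energy(self.config)

    def total(self) -> float:
        return self.bonded()["total"] + self.nonbonded()["total"]

    # -- incremental pieces ------------------------------------------------
    def interaction_with_rest(self, idx: np.ndarray,
                              positions: np.ndarray | None = None,
                              self_active: np.ndarray | None = None) -> float:
        """Nonbonded energy between beads ``idx`` (at ``positions`` if
        given, else current) and all other active beads.  Pairs within
        ``idx`` are not counted.  ``self_active`` overrides the stored
        active mask for the selected beads (used by fold-state proposals
        that make inactive beads interacting)."""
        c = self.config
        idx = np.asarray(idx, dtype=np.int64)
        posA = c.positions[idx] if positions is None else positions
        actA = c.active[idx] if self_active is None else self_active
        mask = np.ones(c.n_beads, dtype=bool)
        mask[idx] = False
        actB = c.active & mask
        e = _nb_between(
            posA, c.charge[idx], c.sigma[idx], c.group[idx],
            self.is_dna[idx], actA, c.positions, c.charge, c.sigma, c.group,
            self.is_dna, actB, self.kappa, self.kappa_dd, self.pref,
            self.ff.lj_eps, self.ff.cutoff,
        )
        if np.isnan(e):
            raise ValueError("overlapping beads at r=0")
        return float(e)

    def point_energy(self, position: np.ndarray, charge: float, sigma: float,
                     group: int, is_dna: bool,
                     exclude: np.ndarray | None = None) -> float:
        """Nonbonded energy of a single candidate bead against all active
        beads (optionally excluding some indices); used by chain regrowth."""
        c = self.config
        actB = c.active.copy() if exclude is not None else c.active
        if exclude is not None:
            actB[exclude] = False
        e = _nb_between(
            position[None, :], np.array([charge]), np.array([sigma]),
            np.array([group], dtype=np.int32), np.array([is_dna]),
            np.array([True]),
            c.positions, c.charge, c.sigma, c.group, self.is_dna, actB,
            self.kappa, self.kappa_dd, self.pref, self.ff.lj_eps,
            self.ff.cutoff,
        )
        return float(e)

    def point_energies(self, points: np.ndarray, charge: float,
                       sigma: float, group: int, is_dna: bool,
                       exclude: np.ndarray | None = None) -> np.ndarray:
        """Vector of nonbonded energies for candidate positions of one
        bead (all candidates share the bead's attributes)."""
        c = self.config
        actB = c.active.copy() if exclude is not None else c.active
        if exclude is not None:
            actB[exclude] = False
        return _nb_points(
            points, charge, sigma, np.int32(group), is_dna,
            c.positions, c.charge, c.sigma, c.group, self.is_dna, actB,
            self.kappa, self.kappa_dd, self.pref, self.ff.lj_eps,
            self.ff.cutoff,
        )

    def delta_interaction(self, idx: np.ndarray,
                          new_positions: np.ndarray) -> float:
        """Change of nonbonded energy when beads ``idx`` move to
        ``new_positions`` (single pass over old and new)."""
        c = self.config
        idx = np.asarray(idx, dtype=np.int64)
        mask = np.ones(c.n_beads, dtype=bool)
        mask[idx] = False
        de = _nb_delta_set(
            c.positions[idx], new_positions, c.charge[idx], c.sigma[idx],
            c.group[idx], self.is_dna[idx], c.active[idx],
            c.positions, c.charge, c.sigma, c.group, self.is_dna,
            c.active & mask, self.kappa, self.kappa_dd, self.pref,
            self.ff.lj_eps, self.ff.cutoff,
        )
        if np.isnan(de):
            raise ValueError("overlapping beads at r=0")
        return float(de)

    def bonded_terms_for(self, bond_ids: np.ndarray, angle_ids: np.ndarray,
                         positions: np.ndarray | None = None) -> float:
        c = self.config
        pos = c.positions if positions is None else positions
        e = 0.0
        if len(bond_ids):
            e += _bond_subset(pos, c.bonds_idx[bond_ids], c.bonds_k[bond_ids],
                              c.bonds_l0[bond_ids])
        if len(angle_ids):
            e += _angle_subset(pos, c.angles_idx[angle_ids],
                               c.angles_g[angle_ids],
                               c.angles_th0[angle_ids])
        return float(e)

    def tail_bonded(self, tail: Tail) -> float:
        return self.bonded_terms_for(tail.bond_ids, tail.angle_ids)


def nonbonded_energy(config: FiberConfiguration,
                     ff: ForceFieldParams | None = None,
                     cond: SimulationConditions = SimulationConditions()) -> dict:
    """Electrostatic and excluded-volume components (kT) over all
    non-bonded pairs within the cutoff; folded tails are excluded."""
    if np.isnan(config.positions).any():
        raise ValueError("NaN coordinates in configuration")
    return FiberEnergyModel(config, ff, cond).nonbonded()


def total_energy(config: FiberConfiguration,
                 ff: ForceFieldParams | None = None,
                 cond: SimulationConditions = SimulationConditions()) -> float:
    return bonded_energy(config)["total"] + nonbonded_energy(config, ff, cond)[
        "total"
    ]
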