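"""Metropolis / configurational-bias Monte Carlo sampling of fiber states.

Five tailored moves drive the sampling:

* **pivot** -- a random backbone position is chosen and the shorter side
  of the bisected chain (tie broken toward the lower-index side) is
  rigidly rotated about a random axis through that point;
* **local translate** -- one uniformly chosen DNA or LH bead is displaced
  within the amplitude ball;
* **local rotate** -- a DNA bead's frame is rotated about the local axis
  (realized as a perturbation of its segment twist register); an LH bead
  is crank-rotated about the axis through its bonded neighbours;
* **tail regrow** -- a randomly chosen unfolded histone tail is regrown
  bead by bead from the core outward with k trial positions per bead and
  Rosenbluth acceptance min(1, W_new / W_old);
* **fold swap** -- an acetylation-flagged tail's fold state is toggled
  (template coordinates and equilibrium values exchanged) with Metropolis
  acceptance.  Folded tails are excluded from regrowth and from all
  nonbonded interactions.

Pivot, translate, rotate and fold-swap use the Metropolis criterion
min(1, exp(-dE/kT)).  One counter-based generator per trajectory, keyed
by the schedule seed, makes runs bit-reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .fiber_model import (
    DNA,
    LH,
    FiberConfiguration,
    FiberEnergyModel,
    ForceFieldParams,
    SimulationConditions,
    Tail,
    apply_fold_state,
    folded_tail_template,
    straight_tail_template,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MoveSchedule",
    "Trajectory",
    "metropolis_accept",
    "pivot_move",
    "local_translate_move",
    "local_rotate_move",
    "tail_regrow",
    "fold_swap",
    "run_trajectory",
    "convergence_report",
    "rotation_matrix",
]

MOVE_NAMES = ("pivot", "translate", "rotate", "regrow", "fold_swap")


@dataclass(frozen=True)
class MoveSchedule:
    """Move mixture, amplitudes and trajectory bookkeeping.

    The default mixture (0.2 / 0.3 / 0.2 / 0.2 / 0.1 for pivot /
    translate / rotate / regrow / fold-swap) targets conventional Monte
    Carlo efficiency; the fold-swap probability is redistributed when the
    fiber has no acetylated tails.
    """

    p_pivot: float = 0.2
    p_translate: float = 0.3
    p_rotate: float = 0.2
    p_regrow: float = 0.2
    p_fold_swap: float = 0.1
    pivot_max_deg: float = 15.0
    translate_max_nm: float = 0.35
    rotate_max_deg: float = 60.0
    regrow_trials: int = 8
    total_steps: int = 100_000
    save_interval: int = 10_000
    tail_stat_interval: int = 10_000
    seed: int = 0

    def probabilities(self, has_acetylated: bool, has_unfolded: bool) -> np.ndarray:
        p = np.array([self.p_pivot, self.p_translate, self.p_rotate,
                      self.p_regrow, self.p_fold_swap], dtype=float)
        if p.min() < 0 or not math.isclose(p.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("move probabilities must be >= 0 and sum to 1")
        if not has_acetylated:
            p[4] = 0.0
        if not has_unfolded:
            p[3] = 0.0
        if p.sum() == 0:
            raise ValueError("no applicable moves")
        return p / p.sum()

    def validate(self) -> None:
        for name in ("pivot_max_deg", "translate_max_nm", "rotate_max_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.regrow_trials < 1:
            raise ValueError("regrow_trials must be >= 1")
        if self.total_steps < 1 or self.save_interval < 1:
            raise ValueError("total_steps and save_interval must be >= 1")


def metropolis_accept(delta_energy: float, rng: np.random.Generator) -> bool:
    """min(1, exp(-dE)) acceptance; consumes one uniform draw only when
    dE > 0.  A NaN dE rejects the move (and is logged)."""
    if math.isnan(delta_energy):
        logger.warning("NaN energy change: move rejected")
        return False
    if delta_energy <= 0.0:
        return True
    return rng.random() < math.exp(-delta_energy)


def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    axis = axis / np.linalg.norm(axis)
    kx, ky, kz = axis
    k = np.array([[0.0, -kz, ky], [kz, 0.0, -kx], [-ky, kx, 0.0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


@dataclass
class Proposal:
    kind: str
    moved_idx: np.ndarray | None = None
    new_positions: np.ndarray | None = None
    twist_segment: int = -1
    new_twist: float = 0.0
    tail: Tail | None = None
    log_weight_ratio: float = 0.0     # regrow: ln(W_new / W_old)
    valid: bool = True


def _random_axis(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def pivot_move(config: FiberConfiguration, schedule: MoveSchedule,
               rng: np.random.Generator) -> Proposal:
    """Rigid rotation of the shorter side of the chain bisected at a
    random backbone node.  The unrotated side is untouched."""
    n_nodes = len(config.backbone_idx)
    t = int(rng.integers(0, n_nodes))
    left = t                      # nodes strictly before the pivot
    right = n_nodes - t - 1       # nodes strictly after
    # tie broken toward the lower-index side
    take_left = left <= right
    if take_left:
        moved = np.flatnonzero(config.chain_pos_of_bead < t)
    else:
        moved = np.flatnonzero(config.chain_pos_of_bead > t)
    if len(moved) == 0:
        return Proposal("pivot", np.empty(0, dtype=np.int64),
                        np.empty((0, 3)), valid=False)
    angle = rng.uniform(-1.0, 1.0) * math.radians(schedule.pivot_max_deg)
    axis = _random_axis(rng)
    origin = config.positions[config.backbone_idx[t]]
    R = rotation_matrix(axis, angle)
    newp = (config.positions[moved] - origin) @ R.T + origin
    return Proposal("pivot", moved, newp)


def _mobile_beads(config: FiberConfiguration) -> np.ndarray:
    return np.flatnonzero((config.bead_class == DNA) | (config.bead_class == LH))


def local_translate_move(config: FiberConfiguration, schedule: MoveSchedule,
                         rng: np.random.Generator) -> Proposal:
    """Displace one uniformly chosen DNA or LH bead within the amplitude
    ball; all other beads unchanged."""
    mobile = _mobile_beads(config)
    if len(mobile) == 0:
        return Proposal("translate", valid=False)
    b = int(mobile[rng.integers(0, len(mobile))])
    r = schedule.translate_max_nm * rng.random() ** (1.0 / 3.0)
    step = r * _random_axis(rng)
    return Proposal("translate", np.array([b]),
                    config.positions[b][None, :] + step)


def local_rotate_move(config: FiberConfiguration, schedule: MoveSchedule,
                      rng: np.random.Generator) -> Proposal:
    """Rotate one DNA or LH bead's frame within the angular amplitude.

    DNA: the segment twist register is perturbed (rotation about the
    local chain axis).  LH: the bead is crank-rotated about the axis
    through its bonded neighbours (random axis for a terminal bead).
    """
    mobile = _mobile_beads(config)
    if len(mobile) == 0:
        return Proposal("rotate", valid=False)
    b = int(mobile[rng.integers(0, len(mobile))])
    angle = rng.uniform(-1.0, 1.0) * math.radians(schedule.rotate_max_deg)
    if config.bead_class[b] == DNA:
        seg = int(config.dna_segment_of_bead[b])
        return Proposal("rotate", np.empty(0, dtype=np.int64),
                        np.empty((0, 3)), twist_segment=seg,
                        new_twist=config.twist[seg] + angle)
    # LH crankshaft: neighbours along its bonds
    nbrs = []
    for bid in config.bead_bonds[b]:
        i, j = config.bonds_idx[bid]
        nbrs.append(int(j) if int(i) == b else int(i))
    p = config.positions[b]
    if len(nbrs) >= 2:
        a0, a1 = config.positions[nbrs[0]], config.positions[nbrs[1]]
        axis = a1 - a0
        if np.linalg.norm(axis) < 1e-12:
            axis = _random_axis(rng)
        origin = a0
    else:
        axis = _random_axis(rng)
        origin = config.positions[nbrs[0]] if nbrs else p
    R = rotation_matrix(axis, angle)
    newp = (p - origin) @ R.T + origin
    return Proposal("rotate", np.array([b]), newp[None, :])


def tail_regrow(config: FiberConfiguration, model: FiberEnergyModel,
                schedule: MoveSchedule, rng: np.random.Generator) -> Proposal:
    """Configurational-bias regrowth of one unfolded tail.

    Beads are regrown from the core outward at fixed bond length with
    ``regrow_trials`` random-direction candidates per bead; candidate
    weights are exp(-u) with u the bending plus nonbonded energy of the
    candidate.  The proposal carries ln(W_new / W_old) for the Rosenbluth
    acceptance.  Folded tails are never selected.
    """
    unfolded = config.unfolded_tails()
    if not unfolded:
        return Proposal("regrow", valid=False)
    tail = unfolded[int(rng.integers(0, len(unfolded)))]
    k = schedule.regrow_trials
    ff = config.ff
    beads = tail.beads
    old_pos = config.positions[beads].copy()
    q = config.charge[beads[0]]
    sig = config.sigma[beads[0]]
    grp = int(config.group[beads[0]])
    anchor = config.positions[tail.anchor].copy()
    # live per-angle parameters of this tail (angle j-1 ends at bead j)
    gs = config.angles_g[tail.angle_ids]
    th0s = config.angles_th0[tail.angle_ids]

    def grow(first_trial_positions):
        """Returns (log_W, placed) where first_trial_positions[j] (if not
        None) is the retained old bead used as trial 0 for bead j."""
        logW = 0.0
        placed = []
        prev = anchor
        prev2 = None  # first bead has no bend term (no angle at the graft)
        for j in range(tail.n_beads):
            dirs = rng.standard_normal((k, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            trials = prev + ff.tail_bond_length * dirs
            if first_trial_positions is not None:
                trials[0] = first_trial_positions[j]
            u = model.point_energies(trials, q, sig, grp, False)
            if prev2 is not None:
                v1 = prev2 - prev
                v2 = trials - prev
                cc = (v2 @ v1) / (np.linalg.norm(v1)
                                  * np.linalg.norm(v2, axis=1))
                th = np.arccos(np.clip(cc, -1.0, 1.0))
                u = u + 0.5 * gs[j - 1] * (th - th0s[j - 1]) ** 2
            w = np.where(u < 500, np.exp(np.minimum(u, 500) * -1.0), 0.0)
            wsum = w.sum()
            if wsum <= 0.0:
                return -math.inf, placed
            logW += math.log(wsum)
            if first_trial_positions is not None:
                choice = 0
            else:
                choice = int(np.searchsorted(np.cumsum(w), rng.random() * wsum))
                choice = min(choice, k - 1)
            placed.append(trials[choice])
            prev2 = prev
            prev = trials[choice]
        return logW, placed

    logW_new, new_beads = grow(None)
    if not math.isfinite(logW_new):
        return Proposal("regrow", tail=tail, valid=False)
    logW_old, _ = grow(old_pos)
    if not math.isfinite(logW_old):
        # old state has a hard overlap; accept the regrown state
        return Proposal("regrow", beads, np.array(new_beads), tail=tail,
                        log_weight_ratio=math.inf)
    return Proposal("regrow", beads, np.array(new_beads), tail=tail,
                    log_weight_ratio=logW_new - logW_old)


def fold_swap(config: FiberConfiguration, rng: np.random.Generator) -> Proposal:
    """Toggle the fold state of one acetylation-flagged tail.

    The proposed coordinates are the canonical template of the opposite
    state (straight when unfolding, compressed when folding), so swapping
    twice restores the configuration exactly."""
    flagged = [t for t in config.tails if t.acetylated]
    if not flagged:
        return Proposal("fold_swap", valid=False)
    tail = flagged[int(rng.integers(0, len(flagged)))]
    if tail.folded:
        newp = straight_tail_template(config, tail)
    else:
        newp = folded_tail_template(config, tail)
    return Proposal("fold_swap", tail.beads, newp, tail=tail)


@dataclass
class Trajectory:
    """Saved configurations plus scalar series and acceptance counters."""

    config: FiberConfiguration          # final state (carries topology)
    snapshots: list = field(default_factory=list)   # dicts from snapshot()
    steps: list = field(default_factory=list)
    series: dict = field(default_factory=lambda: {
        "energy": [], "rg": [], "sedimentation": []})
    proposals: dict = field(default_factory=lambda: {m: 0 for m in MOVE_NAMES})
    accepts: dict = field(default_factory=lambda: {m: 0 for m in MOVE_NAMES})
    schedule: MoveSchedule | None = None

    @property
    def n_saved(self) -> int:
        return len(self.snapshots)

    def acceptance_rates(self) -> dict:
        return {
            m: (self.accepts[m] / self.proposals[m]) if self.proposals[m] else
            float("nan")
            for m in MOVE_NAMES
        }

    def analysis_snapshots(self, burn_in_fraction: float = 5 / 6) -> list:
        """Snapshots in the analysis window: by default the final sixth of
        the run (the proportional last-10M-of-60M rule)."""
        cut = burn_in_fraction * self.schedule.total_steps if self.schedule \
            else 0
        return [s for st, s in zip(self.steps, self.snapshots) if st >= cut]


def _apply(config: FiberConfiguration, prop: Proposal) -> None:
    if prop.kind == "fold_swap":
        apply_fold_state(config, prop.tail, not prop.tail.folded)
        return
    if prop.twist_segment >= 0:
        config.twist[prop.twist_segment] = prop.new_twist
    if prop.moved_idx is not None and len(prop.moved_idx):
        config.positions[prop.moved_idx] = prop.new_positions


def _delta_energy(config: FiberConfiguration, model: FiberEnergyModel,
                  prop: Proposal) -> float:
    """Energy change of a positional proposal (pivot/translate/rotate)."""
    if prop.twist_segment >= 0:
        old = config.twist[prop.twist_segment]
        return 0.5 * config.twist_c * (prop.new_twist**2 - old**2)
    idx = prop.moved_idx
    if idx is None or len(idx) == 0:
        return 0.0
    de = model.delta_interaction(idx, prop.new_positions)
    bond_ids = np.concatenate([config.bead_bonds[b] for b in idx])
    angle_ids = np.concatenate([config.bead_angles[b] for b in idx])
    eb_old = model.bonded_terms_for(bond_ids, angle_ids)
    saved = config.positions[idx].copy()
    config.positions[idx] = prop.new_positions
    try:
        eb_new = model.bonded_terms_for(bond_ids, angle_ids)
    finally:
        config.positions[idx] = saved
    return de + (eb_new - eb_old)


def _fold_swap_delta(config: FiberConfiguration, model: FiberEnergyModel,
                     prop: Proposal) -> float:
    tail = prop.tail
    beads = tail.beads
    if tail.folded:
        # folded -> unfolded: tail becomes interacting at the straight
        # template; bonded terms are zero in both template states
        return model.interaction_with_rest(
            beads, positions=prop.new_positions,
            self_active=np.ones(len(beads), dtype=bool))
    # unfolded -> folded: current nonbonded interactions vanish, and any
    # accumulated bonded strain of the unfolded tail is released
    return -model.interaction_with_rest(beads) - model.tail_bonded(tail)


def run_trajectory(initial: FiberConfiguration,
                   ff: ForceFieldParams | None = None,
                   cond: SimulationConditions = SimulationConditions(),
                   schedule: MoveSchedule = MoveSchedule()) -> Trajectory:
    """Run the move mixture for ``schedule.total_steps`` steps.

    Configurations are saved every ``save_interval`` steps (so
    ``floor(total/interval)`` snapshots), together with total energy,
    radius of gyration and sedimentation coefficient series and per-move
    acceptance counters.  Deterministic for a given schedule seed.
    """
    from .fiber_analysis import radius_of_gyration, sedimentation_coefficient

    schedule.validate()
    config = initial
    model = FiberEnergyModel(config, ff, cond)
    rng = np.random.default_rng(schedule.seed)
    traj = Trajectory(config=config, schedule=schedule)
    has_acet = any(t.acetylated for t in config.tails)

    n_unfolded = len(config.unfolded_tails())
    cum = {True: np.cumsum(schedule.probabilities(has_acet, True)),
           False: np.cumsum(schedule.probabilities(has_acet, False))
           if has_acet else None}

    for step in range(1, schedule.total_steps + 1):
        c = cum[n_unfolded > 0]
        move = MOVE_NAMES[min(int(np.searchsorted(c, rng.random())), 4)]
        traj.proposals[move] += 1
        if move == "pivot":
            prop = pivot_move(config, schedule, rng)
        elif move == "translate":
            prop = local_translate_move(config, schedule, rng)
        elif move == "rotate":
            prop = local_rotate_move(config, schedule, rng)
        elif move == "regrow":
            prop = tail_regrow(config, model, schedule, rng)
        else:
            prop = fold_swap(config, rng)

        accept = False
        if not prop.valid:
            prop = None
        elif move == "regrow":
            lw = prop.log_weight_ratio
            accept = lw >= 0 or rng.random() < math.exp(lw)
        elif move == "fold_swap":
            accept = metropolis_accept(_fold_swap_delta(config, model, prop),
                                       rng)
        else:
            try:
                de = _delta_energy(config, model, prop)
            except ValueError:
                de = float("nan")
            accept = metropolis_accept(de, rng)
        if accept and prop is not None:
            if move == "fold_swap":
                n_unfolded += 1 if prop.tail.folded else -1
            _apply(config, prop)
            traj.accepts[move] += 1

        if step % schedule.save_interval == 0:
            traj.snapshots.append(config.snapshot())
            traj.steps.append(step)
            try:
                e = model.total()
            except ValueError:
                raise RuntimeError(
                    f"energy overflow at step {step}; last valid state kept")
            traj.series["energy"].append(e)
            traj.series["rg"].append(radius_of_gyration(config))
            traj.series["sedimentation"].append(
                sedimentation_coefficient(config))
    return traj


@dataclass
class ConvergenceReport:
    status: str                     # "pass" | "fail" | "insufficient"
    window: int
    drift: dict                     # per-series relative change
    window_means: dict
    tolerance: float


def convergence_report(traj: Trajectory, window: int,
                       tolerance: float = 0.05) -> ConvergenceReport:
    """Windowed-mean drift check on the scalar series.

    Each series is split into consecutive windows of ``window`` points;
    the drift statistic is |mean(last) - mean(previous)| / |mean(previous)|
    (absolute difference when the previous mean is ~0).  All series must
    drift below ``tolerance`` to pass; fewer than two complete windows
    yields an explicit "insufficient" status.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    drift = {}
    means = {}
    status = "pass"
    for name, values in traj.series.items():
        v = np.asarray(values, dtype=float)
        n_win = len(v) // window
        if n_win < 2:
            return ConvergenceReport("insufficient", window, {}, {}, tolerance)
        wm = v[: n_win * window].reshape(n_win, window).mean(axis=1)
        means[name] = wm.tolist()
        prev, last = wm[-2], wm[-1]
        d = abs(last - prev) / abs(prev) if abs(prev) > 1e-12 else abs(last - prev)
        drift[name] = float(d)
        if d > tolerance:
            status = "fail"
    return ConvergenceReport(status, window, drift, means, tolerance)
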