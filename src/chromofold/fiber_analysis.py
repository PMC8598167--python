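"""Fiber-level compaction statistics from simulated trajectories.

All quantities are computed from nucleosome core centres and bead
coordinates of saved configurations:

* sedimentation coefficient S_w,20 (Svedbergs), a hydrodynamic compaction
  proxy built from inter-nucleosome distances:
  ``S = [S1 + (S0 - S1) * LH_conc] * (1 + (R1 / N_C) * sum_{i != j} 1/R_ij)``
  with the mononucleosome limits S0 = 12 S (LH bound) and S1 = 11.1 S
  (no LH) and the nucleosome radius R1 = 5.5 nm;
* radius of gyration of the core centres;
* fiber axis length (arc length of a smoothing spline through the core
  centres) and packing ratio (nucleosomes per 11 nm of axis);
* alpha-shape fiber volume (convex hull at alpha = infinity);
* density-based nucleosome clustering (DBSCAN, 20 nm neighbourhood,
  three neighbours);
* internucleosome contact maps (tail/charge beads within 2 nm), their
  k-neighbour intensity profile I(k), and tail--element interaction
  matrices T' and row-normalized T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError, cKDTree
from sklearn.cluster import DBSCAN as _SKDBSCAN

from .fiber_model import (
    CORE_CHARGE,
    DNA,
    TAIL,
    TAIL_KINDS,
    FiberConfiguration,
)

__all__ = [
    "SedimentationParams",
    "ClusterParams",
    "ContactDefs",
    "TailInteractionMatrix",
    "sedimentation_coefficient",
    "radius_of_gyration",
    "fiber_axis_length",
    "packing_ratio",
    "fiber_volume",
    "cluster_nucleosomes",
    "cluster_statistics",
    "internucleosome_contact_map",
    "neighbor_profile",
    "tail_interaction_matrix",
    "ELEMENT_CLASSES",
]


@dataclass(frozen=True)
class SedimentationParams:
    """Mononucleosome limits and geometry for S_w,20."""

    s0: float = 12.0      # Svedberg, mononucleosome with LH bound
    s1: float = 11.1      # Svedberg, mononucleosome without LH
    r1: float = 5.5       # nm, nucleosome spherical radius
    lh_conc: float | None = None   # None -> taken from the topology

    def __post_init__(self):
        if self.lh_conc is not None and not 0.0 <= self.lh_conc <= 1.0:
            raise ValueError("lh_conc must be in [0, 1]")


@dataclass(frozen=True)
class ClusterParams:
    """DBSCAN neighbourhood radius (nm) and minimum neighbour count
    (neighbours within the radius, excluding the point itself)."""

    neighborhood_radius: float = 20.0
    min_neighbors: int = 3


@dataclass(frozen=True)
class ContactDefs:
    contact_cutoff: float = 2.0        # nm
    record_interval: int = 10_000      # steps
    tail_stat_interval: int = 100_000  # steps

    def __post_init__(self):
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be > 0")


def _core_positions(obj, snapshot: dict | None = None) -> np.ndarray:
    if isinstance(obj, np.ndarray):
        return obj
    pos = snapshot["positions"] if snapshot is not None else obj.positions
    return pos[obj.core_center_idx]


def sedimentation_coefficient(
    config, p: SedimentationParams = SedimentationParams()
) -> float:
    """S_w,20 in Svedbergs for one configuration (or a bare (N,3) array of
    core centres, in which case ``p.lh_conc`` must be set).

    The mononucleosome limits hold exactly: a single core evaluates to
    12 S at full LH occupancy and 11.1 S at zero.  The pair sum runs over
    ordered pairs i != j.
    """
    cores = _core_positions(config)
    n = len(cores)
    if n < 1:
        raise ValueError("need at least one nucleosome")
    lh = p.lh_conc
    if lh is None:
        if isinstance(config, np.ndarray):
            raise ValueError("lh_conc required when passing bare coordinates")
        lh = config.lh_concentration
    base = p.s1 + (p.s0 - p.s1) * lh
    if n == 1:
        return float(base)
    d = np.linalg.norm(cores[:, None, :] - cores[None, :, :], axis=-1)
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0.0):
        raise ValueError("coincident nucleosome cores (R_ij = 0)")
    return float(base * (1.0 + (p.r1 / n) * (1.0 / d[off]).sum()))


def radius_of_gyration(config) -> float:
    """Root mean squared distance of core centres from their mean."""
    cores = _core_positions(config)
    return float(np.sqrt(((cores - cores.mean(axis=0)) ** 2).sum(axis=1).mean()))


def fiber_axis_length(config, smoothing: float = 0.0,
                      n_eval: int = 2000) -> float:
    """Arc length (nm) of a cubic smoothing spline through the core
    centres ordered by fiber index; ``smoothing`` is the spline residual
    budget (0 interpolates)."""
    from scipy.interpolate import splev, splprep

    cores = _core_positions(config)
    n = len(cores)
    if n < 2:
        raise ValueError("fiber axis needs at least two nucleosomes")
    if n < 4:
        # too few points for a cubic spline: polyline length
        return float(np.linalg.norm(np.diff(cores, axis=0), axis=1).sum())
    tck, _ = splprep(cores.T, s=smoothing, k=3)
    u = np.linspace(0.0, 1.0, n_eval)
    pts = np.asarray(splev(u, tck)).T
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def packing_ratio(config, smoothing: float = 0.0) -> float:
    """Nucleosomes per 11 nm of fiber axis: 11 * N_C / axis length."""
    cores = _core_positions(config)
    if len(cores) < 2:
        raise ValueError("packing ratio needs at least two nucleosomes")
    return float(11.0 * len(cores) / fiber_axis_length(config, smoothing))


def _tet_circumradius(p: np.ndarray) -> float:
    a = p[1:] - p[0]
    try:
        sq = (a**2).sum(axis=1)
        c = np.linalg.solve(2 * a, sq)
    except np.linalg.LinAlgError:
        return np.inf
    return float(np.linalg.norm(c))


def fiber_volume(config, alpha: float = np.inf) -> float:
    """Alpha-shape volume (nm^3) of the core centres.

    Delaunay tetrahedra with circumradius <= alpha are kept and their
    volumes summed; alpha = infinity reduces to the convex hull.  Volume
    is monotone non-decreasing in alpha.  Degenerate (coplanar) inputs
    raise an explicit error.
    """
    cores = _core_positions(config)
    if len(cores) < 4:
        raise ValueError("volume needs at least four nucleosomes")
    if np.isinf(alpha):
        try:
            return float(ConvexHull(cores).volume)
        except QhullError as exc:
            raise ValueError("degenerate (coplanar) point set") from exc
    try:
        tri = Delaunay(cores)
    except QhullError as exc:
        raise ValueError("degenerate (coplanar) point set") from exc
    vol = 0.0
    for simplex in tri.simplices:
        p = cores[simplex]
        if _tet_circumradius(p) <= alpha:
            vol += abs(np.linalg.det(p[1:] - p[0])) / 6.0
    return float(vol)


def cluster_nucleosomes(config, p: ClusterParams = ClusterParams()):
    """DBSCAN clustering of core centres.

    Returns (labels, n_clusters, mean_size, max_size); noise points carry
    label -1 and belong to no cluster.  ``min_neighbors`` counts
    neighbours excluding the point itself, so a core point needs
    ``min_neighbors + 1`` samples within the radius including itself.
    """
    cores = _core_positions(config)
    labels = _SKDBSCAN(
        eps=p.neighborhood_radius, min_samples=p.min_neighbors + 1
    ).fit_predict(cores)
    ids = np.unique(labels[labels >= 0])
    sizes = np.array([(labels == i).sum() for i in ids])
    n = len(ids)
    return labels, n, (float(sizes.mean()) if n else 0.0), (
        int(sizes.max()) if n else 0
    )


def cluster_statistics(trajectory, p: ClusterParams = ClusterParams(),
                       burn_in_fraction: float = 5 / 6) -> dict:
    """Cluster counts/sizes averaged over analysis-window snapshots."""
    snaps = trajectory.analysis_snapshots(burn_in_fraction)
    if not snaps:
        raise ValueError("no snapshots in analysis window")
    cfg = trajectory.config
    counts, means, maxes = [], [], []
    for s in snaps:
        cores = s["positions"][cfg.core_center_idx]
        _, n, m, mx = cluster_nucleosomes(cores, p)
        counts.append(n)
        means.append(m)
        maxes.append(mx)
    return {
        "n_clusters_mean": float(np.mean(counts)),
        "n_clusters_sd": float(np.std(counts)),
        "cluster_size_mean": float(np.mean(means)),
        "cluster_size_sd": float(np.std(means)),
        "max_cluster_size_mean": float(np.mean(maxes)),
        "max_cluster_size_sd": float(np.std(maxes)),
    }


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------

def _contact_beads(config: FiberConfiguration, snapshot: dict):
    """Tail and core-charge beads (active tails only) with their
    nucleosome labels, for the contact criterion."""
    folded = snapshot["folded"]
    active = np.ones(config.n_beads, dtype=bool)
    for t, f in zip(config.tails, folded):
        if f:
            active[t.start : t.start + t.n_beads] = False
    sel = ((config.bead_class == TAIL) | (config.bead_class == CORE_CHARGE)) \
        & active
    idx = np.flatnonzero(sel)
    return snapshot["positions"][idx], config.nuc_of_bead[idx]


def contact_matrix_single(config: FiberConfiguration, snapshot: dict,
                          cutoff: float = 2.0) -> np.ndarray:
    """Binary symmetric contact matrix for one configuration: entry
    (i, j) is 1 if any tail/charge bead of nucleosome i lies within the
    cutoff of any tail/charge bead of nucleosome j."""
    n = config.topology.n_cores
    pos, nuc = _contact_beads(config, snapshot)
    m = np.zeros((n, n))
    tree = cKDTree(pos)
    for a, b in tree.query_pairs(cutoff):
        i, j = int(nuc[a]), int(nuc[b])
        if i != j:
            m[i, j] = 1.0
            m[j, i] = 1.0
    return m


def internucleosome_contact_map(trajectories, defs: ContactDefs = ContactDefs()
                                ) -> np.ndarray:
    """Normalized internucleosome contact map.

    Per trajectory, snapshot contact matrices are accumulated over the
    full run and the resulting count matrix is normalized by its maximal
    entry (a scalar); normalized per-trajectory maps are then summed
    across trajectories.
    """
    if not isinstance(trajectories, (list, tuple)):
        trajectories = [trajectories]
    total = None
    for traj in trajectories:
        if not traj.snapshots:
            raise ValueError("empty trajectory")
        cfg = traj.config
        acc = None
        for snap in traj.snapshots:
            m = contact_matrix_single(cfg, snap, defs.contact_cutoff)
            acc = m if acc is None else acc + m
        mx = acc.max()
        if mx > 0:
            acc = acc / mx
        total = acc if total is None else total + acc
    return total


def neighbor_profile(contact_map: np.ndarray) -> np.ndarray:
    """k-neighbour intensity profile I(k), k = 1..N_C - 1.

    I(k) sums the (i, i +/- k) elements of the map and divides by the
    total of the map, so the profile of a nonzero map sums to one.
    """
    m = np.asarray(contact_map, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("contact map must be square")
    if not np.allclose(m, m.T, atol=1e-9):
        raise ValueError("contact map must be symmetric")
    total = m.sum()
    if total == 0:
        raise ValueError("all-zero contact map: I(k) undefined")
    n = m.shape[0]
    out = np.empty(n - 1)
    for k in range(1, n):
        out[k - 1] = (np.diagonal(m, k).sum() + np.diagonal(m, -k).sum()) / total
    return out


# ---------------------------------------------------------------------------
# tail interactions
# ---------------------------------------------------------------------------

ELEMENT_CLASSES = ("core", "dna", "tail")


@dataclass
class TailInteractionMatrix:
    """Raw contact-fraction matrix T' over (tail kind x element class),
    the row-normalized matrix T, and across-trajectory dispersion."""

    t_prime: np.ndarray       # (5, 3) mean over trajectories
    t_norm: np.ndarray        # row-normalized; NaN rows where T' row is 0
    t_prime_sd: np.ndarray
    tail_kinds: tuple = TAIL_KINDS
    element_classes: tuple = ELEMENT_CLASSES


def _nearest_separate_distance(pos, idx, nuc, tail, element, tp):
    """Nearest separate-nucleosome bead distance for one tail and one
    element pool (dense distance scan over the pool)."""
    owners = nuc[idx]
    if element == "dna":
        keep = ~((owners == tail.nuc) | (owners == tail.nuc - 1))
    else:
        keep = owners != tail.nuc
    if not keep.any():
        return np.inf
    sub = pos[idx[keep]]
    d = np.linalg.norm(tp[:, None, :] - sub[None, :, :], axis=-1)
    return float(d.min())


def tail_interaction_matrix(trajectories,
                            defs: ContactDefs = ContactDefs()
                            ) -> TailInteractionMatrix:
    """Tail--element interaction matrices from one or more trajectories.

    Per configuration, each unfolded tail is assigned to at most one
    element class: the class of the nearest separate-nucleosome bead,
    provided that distance is below the contact cutoff (mutual exclusion;
    nearest wins).  T'(t, e) is the fraction of sampled tail instances of
    kind t assigned to class e; T row-normalizes T' so every nonzero row
    sums to one (zero rows are reported as NaN, not 0/0).  Means and
    standard deviations are taken across trajectories.
    """
    if not isinstance(trajectories, (list, tuple)):
        trajectories = [trajectories]
    per_traj = []
    for traj in trajectories:
        if not traj.snapshots:
            raise ValueError("empty trajectory")
        cfg = traj.config
        counts = np.zeros((len(TAIL_KINDS), len(ELEMENT_CLASSES)))
        totals = np.zeros(len(TAIL_KINDS))
        stride = max(1, defs.tail_stat_interval // max(
            1, traj.schedule.save_interval if traj.schedule else 1))
        for snap in traj.snapshots[::stride]:
            c, t = _tail_counts_exact(cfg, snap, defs.contact_cutoff)
            counts += c
            totals += t
        with np.errstate(invalid="ignore", divide="ignore"):
            per_traj.append(counts / np.maximum(totals[:, None], 1))
    stack = np.stack(per_traj)
    t_prime = stack.mean(axis=0)
    t_sd = stack.std(axis=0)
    rows = t_prime.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_norm = np.where(rows > 0, t_prime / rows, np.nan)
    return TailInteractionMatrix(t_prime, t_norm, t_sd)


def _tail_counts_exact(config: FiberConfiguration, snapshot: dict,
                       cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-configuration tail assignment: per-kind counts of tail
    instances assigned to each element class, and total unfolded tail
    instances per kind."""
    pos = snapshot["positions"]
    folded = snapshot["folded"]
    cls = config.bead_class
    nuc = config.nuc_of_bead

    tail_active = np.ones(config.n_beads, dtype=bool)
    for t, f in zip(config.tails, folded):
        if f:
            tail_active[t.start : t.start + t.n_beads] = False
    pool = {
        "core": np.flatnonzero(cls == CORE_CHARGE),
        "dna": np.flatnonzero(cls == DNA),
        "tail": np.flatnonzero((cls == TAIL) & tail_active),
    }
    counts = np.zeros((len(TAIL_KINDS), len(ELEMENT_CLASSES)))
    totals = np.zeros(len(TAIL_KINDS))
    for t, f in zip(config.tails, folded):
        if f:
            continue
        ki = TAIL_KINDS.index(t.kind)
        totals[ki] += 1
        tp = pos[t.beads]
        best_e, best_d = None, np.inf
        for ei, e in enumerate(ELEMENT_CLASSES):
            d = _nearest_separate_distance(pos, pool[e], nuc, t, e, tp)
            if d < best_d:
                best_d = d
                best_e = ei
        if best_e is not None and best_d < cutoff:
            counts[ki, best_e] += 1
    return counts, totals
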