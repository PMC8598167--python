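"""Compaction statistics: sedimentation, Rg, packing, volume, clustering,
contact maps and tail-interaction matrices."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from chromofold.fiber_analysis import (
    ClusterParams,
    ContactDefs,
    SedimentationParams,
    cluster_nucleosomes,
    contact_matrix_single,
    fiber_axis_length,
    fiber_volume,
    internucleosome_contact_map,
    neighbor_profile,
    packing_ratio,
    radius_of_gyration,
    sedimentation_coefficient,
    tail_interaction_matrix,
)
from chromofold.mc_engine import MoveSchedule, run_trajectory

from conftest import make_fiber


class TestSedimentation:
    def test_mononucleosome_limits_are_exact(self):
        one = np.zeros((1, 3))
        with_lh = sedimentation_coefficient(
            one, SedimentationParams(lh_conc=1.0))
        without = sedimentation_coefficient(
            one, SedimentationParams(lh_conc=0.0))
        assert with_lh == 12.0
        assert without == 11.1

    def test_two_core_hand_evaluation(self):
        """Two cores 10 nm apart, no LH: 11.1 * (1 + (5.5/2) * (2/10))."""
        cores = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        s = sedimentation_coefficient(cores, SedimentationParams(lh_conc=0.0))
        assert s == pytest.approx(11.1 * (1 + 2.75 * 0.2))
        assert s == pytest.approx(17.205)

    def test_lh_concentration_from_topology(self):
        cfg = make_fiber(n=4, lh=1.0)
        assert cfg.lh_concentration == 1.0
        s = sedimentation_coefficient(cfg)
        s_explicit = sedimentation_coefficient(
            cfg.core_positions, SedimentationParams(lh_conc=1.0))
        assert s == pytest.approx(s_explicit)

    def test_coincident_cores_rejected(self):
        cores = np.zeros((2, 3))
        with pytest.raises(ValueError, match="R_ij"):
            sedimentation_coefficient(cores, SedimentationParams(lh_conc=0.0))


class TestRadiusOfGyration:
    def test_single_core_is_zero(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_two_cores_symmetry(self):
        cores = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        assert radius_of_gyration(cores) == pytest.approx(5.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(3)
        cores = rng.normal(0, 8, (50, 3))
        mean = cores.mean(axis=0)
        brute = np.sqrt(sum(((c - mean) ** 2).sum() for c in cores) / 50)
        assert radius_of_gyration(cores) == pytest.approx(brute, abs=1e-12)


class TestAxisAndPacking:
    def test_collinear_cores_give_straight_line_arc_length(self):
        cores = np.zeros((20, 3))
        cores[:, 2] = np.linspace(0, 110, 20)
        assert fiber_axis_length(cores) == pytest.approx(110.0, rel=1e-6)
        assert packing_ratio(cores) == pytest.approx(2.0, rel=1e-6)

    def test_scaling_property(self):
        rng = np.random.default_rng(1)
        cores = np.cumsum(rng.normal(0, 3, (15, 3)), axis=0)
        l1 = fiber_axis_length(cores)
        l2 = fiber_axis_length(2 * cores)
        assert l2 == pytest.approx(2 * l1, rel=1e-6)
        assert packing_ratio(2 * cores) == pytest.approx(
            packing_ratio(cores) / 2, rel=1e-6)

    def test_noisy_helix_matches_dense_polyline_oracle(self):
        t = np.linspace(0, 4 * np.pi, 40)
        cores = np.column_stack([10 * np.cos(t), 10 * np.sin(t), 3 * t])
        dense = np.linspace(0, 4 * np.pi, 5000)
        fine = np.column_stack(
            [10 * np.cos(dense), 10 * np.sin(dense), 3 * dense])
        oracle = np.linalg.norm(np.diff(fine, axis=0), axis=1).sum()
        assert abs(fiber_axis_length(cores) - oracle) / oracle < 0.02

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fiber_axis_length(np.zeros((1, 3)))
        with pytest.raises(ValueError):
            packing_ratio(np.zeros((1, 3)))


class TestFiberVolume:
    def test_unit_cube_convex_hull(self):
        corners = np.array(
            [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
            dtype=float)
        assert fiber_volume(corners, alpha=np.inf) == pytest.approx(1.0)

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(8)
        cores = rng.normal(0, 10, (60, 3))
        vols = [fiber_volume(cores, alpha=a) for a in (5, 10, 20, np.inf)]
        assert all(v1 <= v2 + 1e-9 for v1, v2 in zip(vols, vols[1:]))

    def test_infinite_alpha_matches_hull_oracle(self):
        rng = np.random.default_rng(9)
        cores = rng.normal(0, 10, (80, 3))
        assert fiber_volume(cores) == pytest.approx(
            ConvexHull(cores).volume, abs=1e-9)

    def test_coplanar_points_rejected(self):
        pts = np.zeros((10, 3))
        pts[:, :2] = np.random.default_rng(0).random((10, 2))
        with pytest.raises(ValueError, match="degenerate"):
            fiber_volume(pts)


def _brute_force_dbscan(points, eps, min_neighbors):
    """Independent density-based clustering: core points have more than
    ``min_neighbors`` other points within eps; clusters are connected
    components of core points (plus border points)."""
    n = len(points)
    d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
    neighbors = [np.flatnonzero((d[i] <= eps)) for i in range(n)]
    is_core = np.array([len(nb) - 1 >= min_neighbors for nb in neighbors])
    labels = np.full(n, -1)
    cur = 0
    for i in range(n):
        if labels[i] != -1 or not is_core[i]:
            continue
        stack = [i]
        labels[i] = cur
        while stack:
            p = stack.pop()
            if not is_core[p]:
                continue
            for q in neighbors[p]:
                if labels[q] == -1:
                    labels[q] = cur
                    if is_core[q]:
                        stack.append(q)
        cur += 1
    return labels


class TestClustering:
    def test_fully_dense_cloud_is_one_cluster(self):
        rng = np.random.default_rng(2)
        cores = rng.normal(0, 4, (10, 3))  # all mutually within 20 nm
        labels, n, mean, mx = cluster_nucleosomes(cores)
        assert n == 1 and mx == 10 and mean == 10.0

    def test_sparse_line_is_all_noise(self):
        cores = np.zeros((10, 3))
        cores[:, 0] = np.arange(10) * 25.0
        labels, n, mean, mx = cluster_nucleosomes(cores)
        assert n == 0 and (labels == -1).all()

    def test_labels_match_independent_implementation(self):
        rng = np.random.default_rng(17)
        cores = np.concatenate([
            rng.normal(0, 6, (80, 3)),
            rng.normal(80, 6, (60, 3)),
            rng.uniform(-200, 200, (60, 3)),
        ])
        p = ClusterParams()
        labels, *_ = cluster_nucleosomes(cores, p)
        oracle = _brute_force_dbscan(cores, p.neighborhood_radius,
                                     p.min_neighbors)
        # same partition up to label permutation; border-point ties can
        # differ between implementations, so compare core assignments
        d = np.linalg.norm(cores[:, None] - cores[None, :], axis=-1)
        n_nb = (d <= p.neighborhood_radius).sum(axis=1) - 1
        is_core = n_nb >= p.min_neighbors + 0
        mapping = {}
        for a, b in zip(labels[is_core], oracle[is_core]):
            assert a != -1 and b != -1
            mapping.setdefault(a, b)
            assert mapping[a] == b
        assert (labels[is_core] >= 0).all()


def _short_trajectory(n=4, acet=0.5, lh=0.5, steps=3000, seed=6):
    cfg = make_fiber(n=n, acet=acet, lh=lh, seed=seed)
    sched = MoveSchedule(total_steps=steps, save_interval=steps // 5,
                         seed=seed)
    return run_trajectory(cfg, schedule=sched)


class TestContactMap:
    def test_single_close_pair_gives_single_symmetric_entry(self):
        cfg = make_fiber(n=3, acet=0.0, lh=0.0)
        # separate the cores far apart, then move one tail bead of core 0
        # within the cutoff of a charge bead of core 2
        for i, ci in enumerate(cfg.core_center_idx):
            sel = cfg.nuc_of_bead == i
            cfg.positions[sel] += np.array([200.0 * i, 0.0, 0.0])
        t0 = next(t for t in cfg.tails if t.nuc == 0)
        target = np.flatnonzero((cfg.bead_class == 1)
                                & (cfg.nuc_of_bead == 2))[0]
        cfg.positions[t0.start] = cfg.positions[target] + np.array(
            [1.9, 0.0, 0.0])
        snap = cfg.snapshot()
        m = contact_matrix_single(cfg, snap, cutoff=2.0)
        expected = np.zeros((3, 3))
        expected[0, 2] = expected[2, 0] = 1.0
        np.testing.assert_array_equal(m, expected)

    def test_normalization_contract_max_entry_is_one(self):
        traj = _short_trajectory()
        m = internucleosome_contact_map(traj)
        if m.max() > 0:
            assert m.max() == pytest.approx(1.0)
        assert np.allclose(m, m.T)

    def test_matches_brute_force_distance_scan(self):
        traj = _short_trajectory(steps=2000)
        cfg = traj.config
        defs = ContactDefs()
        m = internucleosome_contact_map(traj, defs)
        # oracle: O(n^2) scan over tail/charge beads per snapshot
        n = cfg.topology.n_cores
        acc = np.zeros((n, n))
        for snap in traj.snapshots:
            pos = snap["positions"]
            active = np.ones(cfg.n_beads, dtype=bool)
            for t, f in zip(cfg.tails, snap["folded"]):
                if f:
                    active[t.start:t.start + t.n_beads] = False
            sel = ((cfg.bead_class == 1) | (cfg.bead_class == 3)) & active
            idx = np.flatnonzero(sel)
            d = np.linalg.norm(pos[idx][:, None] - pos[idx][None, :], axis=-1)
            single = np.zeros((n, n))
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    i, j = cfg.nuc_of_bead[idx[a]], cfg.nuc_of_bead[idx[b]]
                    if i != j and d[a, b] < defs.contact_cutoff:
                        single[i, j] = single[j, i] = 1.0
            acc += single
        if acc.max() > 0:
            acc /= acc.max()
        np.testing.assert_allclose(m, acc)

    def test_empty_trajectory_rejected(self):
        traj = _short_trajectory(steps=1000)
        traj.snapshots = []
        with pytest.raises(ValueError, match="empty"):
            internucleosome_contact_map(traj)


class TestNeighborProfile:
    def test_first_off_diagonal_only(self):
        m = np.zeros((5, 5))
        for i in range(4):
            m[i, i + 1] = m[i + 1, i] = 2.0
        prof = neighbor_profile(m)
        assert prof[0] == pytest.approx(1.0)
        assert np.allclose(prof[1:], 0.0)

    def test_uniform_map_proportional_to_element_counts(self):
        n = 6
        m = np.ones((n, n)) - np.eye(n)
        prof = neighbor_profile(m)
        counts = np.array([2 * (n - k) for k in range(1, n)])
        np.testing.assert_allclose(prof, counts / counts.sum())

    def test_random_map_matches_diagonal_sum_oracle(self):
        rng = np.random.default_rng(4)
        m = rng.random((8, 8))
        m = m + m.T
        np.fill_diagonal(m, 0.0)
        prof = neighbor_profile(m)
        total = m.sum()
        for k in range(1, 8):
            expected = (np.diagonal(m, k).sum()
                        + np.diagonal(m, -k).sum()) / total
            assert prof[k - 1] == pytest.approx(expected, abs=1e-12)
        assert prof.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_map_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            neighbor_profile(np.zeros((4, 4)))


class TestTailInteractions:
    def _staged_config(self):
        """Configuration with cores far apart and one engineered contact."""
        cfg = make_fiber(n=3, acet=0.0, lh=0.0)
        for i in range(3):
            sel = cfg.nuc_of_bead == i
            cfg.positions[sel] += np.array([0.0, 0.0, 300.0 * i])
        # move the linkers out of the way too
        dna = cfg.bead_class == 2
        cfg.positions[dna] += np.array([0.0, 500.0, 0.0])
        return cfg

    def test_engineered_h4_core_contact_assigned_to_core_only(self):
        cfg = self._staged_config()
        h4 = next(t for t in cfg.tails if t.kind == "H4" and t.nuc == 0)
        target = np.flatnonzero((cfg.bead_class == 1)
                                & (cfg.nuc_of_bead == 1))[0]
        cfg.positions[h4.start] = cfg.positions[target] + np.array(
            [1.5, 0.0, 0.0])
        traj = type("T", (), {})()
        traj.snapshots = [cfg.snapshot()]
        traj.config = cfg
        traj.schedule = None
        tim = tail_interaction_matrix(traj)
        ki = tim.tail_kinds.index("H4")
        assert tim.t_prime[ki, tim.element_classes.index("core")] > 0
        assert tim.t_prime[ki, tim.element_classes.index("dna")] == 0
        # only that one H4 instance contributes: fraction = 1/6
        assert tim.t_prime[ki, 0] == pytest.approx(1 / 6)

    def test_nearest_element_wins_mutual_exclusion(self):
        cfg = self._staged_config()
        h3 = next(t for t in cfg.tails if t.kind == "H3" and t.nuc == 0)
        core_bead = np.flatnonzero((cfg.bead_class == 1)
                                   & (cfg.nuc_of_bead == 1))[0]
        # a DNA bead of the far linker (the tail's own entering/exiting
        # linkers are excluded from the "separate DNA" pool)
        dna_bead = np.flatnonzero(cfg.bead_class == 2)[-1]
        # tail bead 1.2 nm from a separate DNA bead, 1.8 nm from a core
        cfg.positions[h3.start] = np.array([1000.0, 1000.0, 1000.0])
        cfg.positions[h3.start + 1:h3.start + h3.n_beads] = np.array(
            [2000.0, 2000.0, 2000.0])
        cfg.positions[dna_bead] = cfg.positions[h3.start] + np.array(
            [1.2, 0.0, 0.0])
        cfg.positions[core_bead] = cfg.positions[h3.start] + np.array(
            [0.0, 1.8, 0.0])
        traj = type("T", (), {})()
        traj.snapshots = [cfg.snapshot()]
        traj.config = cfg
        traj.schedule = None
        tim = tail_interaction_matrix(traj)
        ki = tim.tail_kinds.index("H3")
        assert tim.t_prime[ki, tim.element_classes.index("dna")] == \
            pytest.approx(1 / 6)
        assert tim.t_prime[ki, tim.element_classes.index("core")] == 0

    def test_nonzero_rows_of_t_sum_to_one_and_match_oracle(self):
        traj = _short_trajectory(n=4, steps=4000, seed=9)
        tim = tail_interaction_matrix(
            traj, ContactDefs(tail_stat_interval=traj.schedule.save_interval))
        rows = np.nansum(tim.t_norm, axis=1)
        for ki in range(len(tim.tail_kinds)):
            if np.isnan(tim.t_norm[ki]).all():
                continue
            assert rows[ki] == pytest.approx(1.0, abs=1e-9)
        # brute-force oracle over one snapshot: recompute the assignment
        cfg = traj.config
        snap = traj.snapshots[0]
        counts = np.zeros((5, 3))
        totals = np.zeros(5)
        pos = snap["positions"]
        active = np.ones(cfg.n_beads, dtype=bool)
        for t, f in zip(cfg.tails, snap["folded"]):
            if f:
                active[t.start:t.start + t.n_beads] = False
        kinds = list(tim.tail_kinds)
        for t, f in zip(cfg.tails, snap["folded"]):
            if f:
                continue
            ki = kinds.index(t.kind)
            totals[ki] += 1
            tp = pos[t.beads]
            best = (None, np.inf)
            for ei, (cls_code, name) in enumerate(
                    [(1, "core"), (2, "dna"), (3, "tail")]):
                sel = cfg.bead_class == cls_code
                if cls_code == 3:
                    sel = sel & active
                idx = np.flatnonzero(sel)
                owners = cfg.nuc_of_bead[idx]
                if name == "dna":
                    keep = ~((owners == t.nuc) | (owners == t.nuc - 1))
                else:
                    keep = owners != t.nuc
                idx = idx[keep]
                if not len(idx):
                    continue
                dmin = np.linalg.norm(
                    tp[:, None] - pos[idx][None, :], axis=-1).min()
                if dmin < best[1]:
                    best = (ei, dmin)
            if best[0] is not None and best[1] < 2.0:
                counts[ki, best[0]] += 1
        from chromofold.fiber_analysis import _tail_counts_exact
        c, tt = _tail_counts_exact(cfg, snap, 2.0)
        np.testing.assert_array_equal(c, counts)
        np.testing.assert_array_equal(tt, totals)
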