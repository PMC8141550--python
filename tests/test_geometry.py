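"""Compactness, pre/post splits, running averages, RMSD matrices."""

from __future__ import annotations

import numpy as np
import pytest

import ionbind as ib
from conftest import small_config
from ionbind.geometry import (
    CompactnessSeries,
    compactness_series,
    pairwise_rmsd,
    rmsd_matrix,
    running_average,
    split_pre_post,
)
from ionbind.synthetic import NA1_SELECTION, generate_replica_set
from ionbind.traj_core import AtomSelection, Trajectory
from oracles import apply_rigid, kabsch_svd_reference, random_rotation


def _static_traj(coords: np.ndarray, n_frames: int = 20, dt: float = 0.1) -> Trajectory:
    pos = np.tile(coords[None, :, :], (n_frames, 1, 1))
    return Trajectory(
        replica_id=0, times=np.arange(n_frames) * dt, positions=pos,
        box=np.array([10.0, 10.0, 10.0]),
    )


def _octahedron(r: float) -> np.ndarray:
    return r * np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                         [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float)


class TestCompactness:
    def test_octahedron_value_is_circumradius(self):
        traj = _static_traj(_octahedron(0.35) + 3.0)
        series = compactness_series(traj, AtomSelection("site", np.arange(6)))
        np.testing.assert_allclose(series.values, 0.35, atol=1e-12)

    def test_two_atoms_give_half_distance(self):
        coords = np.array([[0.0, 0, 0], [0.7, 0, 0]]) + 2.0
        series = compactness_series(
            _static_traj(coords), AtomSelection("pair", np.arange(2))
        )
        np.testing.assert_allclose(series.values, 0.35, atol=1e-12)

    def test_single_atom_rejected(self):
        traj = _static_traj(np.ones((1, 3)))
        with pytest.raises(ValueError):
            compactness_series(traj, AtomSelection("one", np.array([0])))

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        pos = rng.random((30, 6, 3))
        traj = Trajectory(replica_id=0, times=np.arange(30) * 0.1,
                         positions=pos + 2.0, box=np.array([10.0, 10.0, 10.0]))
        sel = AtomSelection("site", np.arange(6))
        s0 = compactness_series(traj, sel)
        R, t = random_rotation(rng), rng.standard_normal(3)
        moved = Trajectory(replica_id=0, times=traj.times,
                          positions=apply_rigid(traj.positions, R, t),
                          box=traj.box)
        s1 = compactness_series(moved, sel)
        np.testing.assert_allclose(s1.values, s0.values, atol=1e-9)

    def test_generator_apo_radius_recovered(self):
        # censored replica: time-mean compactness ~ configured apo radius
        cfg = small_config(n_replicas=1, duration=150.0, seed=40)
        cfg.site("NA1").k_on_true = 1.0  # effectively never binds
        rs, gt = generate_replica_set(cfg)
        assert gt.replicas[0].site_first_binding["NA1"] is None
        series = compactness_series(
            rs.trajectories[0], ib.select_atoms(rs.topology, NA1_SELECTION)
        )
        spec = cfg.geometry["NA1"]
        # OU noise inflates the mean radius slightly; tolerate that bias
        assert series.values.mean() == pytest.approx(spec.mean_radius_apo, abs=0.02)


class TestRunningAverage:
    def _series(self, values, dt=0.1):
        return CompactnessSeries(
            replica_id=0, site_name="NA1",
            times=np.arange(len(values)) * dt, values=np.asarray(values, float),
        )

    def test_constant_series_unchanged(self):
        s = running_average(self._series(np.full(50, 0.3)), window=1.0)
        np.testing.assert_allclose(s.values, 0.3, atol=1e-12)

    def test_impulse_spreads_to_plateau(self):
        vals = np.full(41, 1e-9)
        vals[20] = 1.0
        s = running_average(self._series(vals), window=1.0)  # 11-sample window
        np.testing.assert_allclose(s.values[15:26], 1.0 / 11, atol=1e-6)

    def test_linear_ramp_unchanged_in_interior(self):
        vals = np.linspace(0.1, 1.0, 60)
        s = running_average(self._series(vals), window=1.0)
        np.testing.assert_allclose(s.values[6:-6], vals[6:-6], atol=1e-9)

    def test_window_shorter_than_resolution_rejected(self):
        with pytest.raises(ValueError):
            running_average(self._series(np.ones(10)), window=0.01)

    def test_length_preserved(self):
        s = running_average(self._series(np.random.default_rng(0).random(37)), 1.0)
        assert len(s.values) == 37


class TestSplitPrePost:
    def _series(self, values, dt=0.1):
        return CompactnessSeries(
            replica_id=0, site_name="NA1",
            times=np.arange(len(values)) * dt, values=np.asarray(values, float),
        )

    def test_censored_keeps_everything_pre(self):
        s = self._series(np.full(30, 0.3))
        summary = split_pre_post(s, None)
        assert summary.post is None
        assert summary.value_at_binding is None
        assert summary.pre.n == 30

    def test_binding_at_zero_gives_empty_pre(self):
        s = self._series(np.full(30, 0.3))
        summary = split_pre_post(s, 0.0)
        assert summary.pre is None
        assert summary.post.n == 30

    def test_counts_partition_series(self):
        s = self._series(np.linspace(0.4, 0.2, 50))
        summary = split_pre_post(s, 2.5)
        assert summary.pre.n + summary.post.n == 50
        # pre is strictly before the binding time
        assert summary.pre.n == 25

    def test_value_at_binding_is_nearest_sample(self):
        vals = np.linspace(0.4, 0.2, 50)
        s = self._series(vals)
        summary = split_pre_post(s, 2.52)
        assert summary.value_at_binding == vals[25]

    def test_compactness_shift_recovered_from_generator(self):
        # (pre mean - post mean) ~ configured apo - bound radius gap
        shifts = []
        for seed in range(6):
            cfg = small_config(n_replicas=1, duration=150.0, seed=100 + seed)
            cfg.site("NA1").k_on_true = 4e9  # rate 0.6 /ns: binds early
            rs, gt = generate_replica_set(cfg)
            t_b = gt.replicas[0].site_first_binding["NA1"]
            if t_b is None or t_b > 30.0:
                continue
            series = compactness_series(
                rs.trajectories[0], ib.select_atoms(rs.topology, NA1_SELECTION)
            )
            # skip the relaxation transient after binding
            post_mask = series.times >= t_b + 5 * cfg.geometry["NA1"].relaxation_time
            pre_mask = series.times < t_b
            if pre_mask.sum() < 10:
                continue
            shifts.append(series.values[pre_mask].mean()
                          - series.values[post_mask].mean())
        spec = cfg.geometry["NA1"]
        delta = spec.mean_radius_apo - spec.mean_radius_bound
        assert np.mean(shifts) == pytest.approx(delta, rel=0.2)


class TestRMSDMatrix:
    def test_identical_frames_zero_matrix(self):
        traj = _static_traj(np.random.default_rng(0).random((6, 3)) + 2.0, n_frames=30)
        m = rmsd_matrix([traj], AtomSelection("s", np.arange(6)), stride=0.5)
        assert np.allclose(m.values, 0.0, atol=1e-9)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(1)
        pos = rng.random((40, 6, 3)) + 2.0
        traj = Trajectory(replica_id=0, times=np.arange(40) * 0.1,
                         positions=pos, box=np.array([10.0] * 3))
        m = rmsd_matrix([traj], AtomSelection("s", np.arange(6)), stride=0.5)
        np.testing.assert_allclose(m.values, m.values.T, atol=1e-12)
        assert np.all(np.diag(m.values) == 0.0)

    def test_agrees_with_plain_loop_reference(self):
        # batched SVD path vs an independently written per-pair Kabsch
        rng = np.random.default_rng(2)
        pos = rng.random((10, 5, 3)) + 2.0
        traj = Trajectory(replica_id=0, times=np.arange(10) * 1.0,
                         positions=pos, box=np.array([10.0] * 3))
        m = rmsd_matrix([traj], AtomSelection("s", np.arange(5)), stride=1.0)
        for i in range(10):
            for j in range(10):
                expected = kabsch_svd_reference(pos[i, :5], pos[j, :5])
                assert m.values[i, j] == pytest.approx(expected, abs=1e-9)

    def test_two_cluster_structure(self):
        # bound-like frames are mutually closer than apo-vs-bound pairs
        rng = np.random.default_rng(3)
        apo = _octahedron(0.35)
        bound = _octahedron(0.25)
        frames = []
        for k in range(10):
            base = apo if k < 5 else bound
            frames.append(base + 0.005 * rng.standard_normal((6, 3)))
        pos = np.stack(frames) + 3.0
        traj = Trajectory(replica_id=0, times=np.arange(10) * 1.0,
                         positions=pos, box=np.array([10.0] * 3))
        m = rmsd_matrix([traj], AtomSelection("s", np.arange(6)), stride=1.0)
        within_bound = m.values[5:, 5:][np.triu_indices(5, 1)]
        across = m.values[:5, 5:]
        assert within_bound.mean() < across.mean()

    def test_ordering_bound_first_by_binding_time(self):
        trajs = []
        rng = np.random.default_rng(4)
        for rid in range(4):
            pos = rng.random((6, 6, 3)) + 2.0
            trajs.append(Trajectory(replica_id=rid, times=np.arange(6) * 1.0,
                                    positions=pos, box=np.array([10.0] * 3)))
        bt = {0: None, 1: 12.0, 2: 3.0, 3: None}
        m = rmsd_matrix(trajs, AtomSelection("s", np.arange(6)),
                        binding_times=bt, stride=2.0)
        assert m.replica_order == [2, 1, 0, 3]
        assert m.block_boundaries == [0, 3, 6, 9]

    def test_variance_contraction_on_binding(self):
        # post-binding compactness fluctuates less when the generator's
        # bound-state noise is smaller
        wins = 0
        trials = 0
        for seed in range(8):
            cfg = small_config(n_replicas=1, duration=150.0, seed=200 + seed)
            cfg.site("NA1").k_on_true = 1e9  # ~6.7 ns mean binding time
            rs, gt = generate_replica_set(cfg)
            t_b = gt.replicas[0].site_first_binding["NA1"]
            if t_b is None or t_b > 50.0:
                continue
            series = compactness_series(
                rs.trajectories[0], ib.select_atoms(rs.topology, NA1_SELECTION)
            )
            pre = series.values[series.times < t_b]
            post = series.values[series.times >= t_b + 10.0]
            if len(pre) < 20 or len(post) < 20:
                continue
            trials += 1
            wins += post.var() < pre.var()
        assert trials >= 3
        assert wins / trials >= 0.8
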