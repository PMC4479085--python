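"""Stochastic simulation: exactness, reproducibility, switching statistics."""

import numpy as np
import pytest

import switchscape as sw
from switchscape.fixtures import make_fixture
from switchscape.params import STATE_CHANGES
from switchscape.ssa import PathEnsemble


class TestSimulate:
    def test_seeded_reproducibility(self, tiny):
        fx, _ = tiny
        t1 = sw.simulate(fx.params, (1, 5, 20), horizon=30.0, seed=99)
        t2 = sw.simulate(fx.params, (1, 5, 20), horizon=30.0, seed=99)
        assert np.array_equal(t1.times, t2.times)
        assert np.array_equal(t1.states, t2.states)
        t3 = sw.simulate(fx.params, (1, 5, 20), horizon=30.0, seed=100)
        assert not np.array_equal(t1.times, t3.times)

    def test_trajectory_is_single_jump_chain(self, tiny):
        fx, _ = tiny
        tr = sw.simulate(fx.params, (1, 5, 20), horizon=20.0, seed=3)
        assert np.all(np.diff(tr.times) > 0)
        steps = np.diff(tr.states, axis=0)
        legal = {tuple(c) for c in STATE_CHANGES}
        assert all(tuple(s) in legal for s in steps)

    def test_pure_death_mean_hitting_time(self):
        # mean time to extinction from n0 is the harmonic sum over 1/(d_p k)
        fx = make_fixture("pure_death")
        n0 = fx.oracle["n0"]
        times = []
        for i in range(400):
            tr = sw.simulate(fx.params, (0, 0, n0), horizon=1e3,
                             seed=sw.ssa.substream_seed(5, i))
            hit = np.flatnonzero(tr.states[:, 2] == 0)
            times.append(tr.times[hit[0]])
        mean = np.mean(times)
        se = np.std(times, ddof=1) / np.sqrt(len(times))
        assert abs(mean - fx.oracle["mfpt_to_zero"]) < 3 * se

    def test_poisson_submodel_mean_equals_variance(self):
        fx = make_fixture("poisson_mrna")
        emp = sw.empirical_distribution(fx.params, (1, 8, 0), 400_000,
                                        fx.grid.M, fx.grid.N, seed=11)
        pm = emp.sum(axis=(0, 2))
        k = np.arange(fx.grid.M)
        mean = (k * pm).sum()
        var = ((k - mean) ** 2 * pm).sum()
        lam = fx.oracle["mrna_mean"]
        assert mean == pytest.approx(lam, rel=0.05)
        assert var == pytest.approx(lam, rel=0.10)

    def test_stationary_histogram_matches_cme(self, tiny):
        fx, dist = tiny
        emp = sw.empirical_distribution(fx.params, (1, 7, 27), 1_000_000,
                                        fx.grid.M, fx.grid.N, seed=7)
        tv = 0.5 * np.abs(emp - dist.values).sum()
        assert tv < 0.02


class TestEstimateMST:
    def test_matches_first_passage_solve(self, tiny):
        fx, _ = tiny
        ns = fx.oracle["n_split"]
        t_lin = sw.basin_mfpt(fx.params, fx.grid, "off_to_on", ns, start=(0, 0, 0))
        res = sw.estimate_mst(fx.params, "off_to_on", ns, replicates=200,
                              seed=3, start=(0, 0, 0))
        assert res.censored_fraction == 0.0
        assert abs(res.mean - t_lin) < 3 * res.se

    def test_tau_leaping_consistent_with_exact(self, tiny):
        fx, _ = tiny
        ns = fx.oracle["n_split"]
        ex = sw.estimate_mst(fx.params, "on_to_off", ns, replicates=300, seed=5)
        ta = sw.estimate_mst(fx.params, "on_to_off", ns, replicates=300, seed=6,
                             method="tau")
        assert abs(ex.mean - ta.mean) < 3 * np.hypot(ex.se, ta.se)

    def test_transition_time_excludes_dwell(self, tiny):
        fx, _ = tiny
        ns = fx.oracle["n_split"]
        res = sw.estimate_mst(fx.params, "off_to_on", ns, replicates=100, seed=9,
                              start=(0, 0, 0))
        # T strips the waiting inside the source basin
        assert 0 < res.transition_mean < res.mean

    def test_replicate_validation(self, tiny):
        fx, _ = tiny
        with pytest.raises(ValueError):
            sw.estimate_mst(fx.params, "off_to_on", 8, replicates=1, seed=0)


class TestReactivePaths:
    def test_single_switch_extraction_and_density(self, tiny):
        fx, _ = tiny
        ens = sw.sample_reactive_segments(fx.params, "on_to_off", 4, seed=21,
                                          n_split=fx.oracle["n_split"])
        assert len(ens.segments) >= 3
        for seg in ens.segments:
            assert np.all(np.diff(seg[:, 0]) >= 0)
        # residence-time density integrates to the total reactive time
        total = sum(seg[-1, 0] - seg[0, 0] for seg in ens.segments)
        assert ens.total_reactive_time == pytest.approx(total, rel=0.05)

    def test_no_switch_gives_empty_ensemble(self, tiny):
        fx, _ = tiny
        tr = sw.Trajectory(
            times=np.array([0.0, 1.0, 2.0]),
            states=np.array([[1, 5, 20], [1, 6, 20], [1, 6, 21]]),
            params=fx.params, seed=0,
        )
        ens = sw.reactive_segments(tr, 8)
        assert ens.segments == []

    def test_average_path_of_identical_segments(self):
        seg = np.array([[0.0, 0, 0], [1.0, 1, 2], [2.0, 2, 4], [3.0, 4, 8]], dtype=float)
        ens = PathEnsemble(segments=[seg, seg.copy()], density={}, direction="x")
        avg = sw.average_path(ens, bins=20)
        # every averaged point lies on the common polyline
        for pt in avg:
            d = np.min(np.abs(pt[1] * 0.5 - pt[0]))  # the line n = 2 m
            assert pt[1] == pytest.approx(2 * pt[0], abs=1e-9)

    def test_average_path_mirror_symmetry(self):
        up = np.array([[0.0, 0, 0], [1.0, 1, 1], [2.0, 2, 4]], dtype=float)
        dn = up.copy()
        dn[:, 1] = -dn[:, 1]  # mirror in the first coordinate
        ens = PathEnsemble(segments=[up, dn], density={}, direction="x")
        avg = sw.average_path(ens, bins=10)
        assert np.allclose(avg[:, 0], 0.0, atol=1e-9)
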