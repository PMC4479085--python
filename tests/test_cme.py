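"""CME engine: generator structure, stationary laws, landscapes, first passage."""

import numpy as np
import pytest

import switchscape as sw
from switchscape.cme import TruncationError, TruncationGrid
from switchscape.fixtures import make_fixture


class TestGenerator:
    def test_columns_sum_to_zero(self, tiny):
        fx, _ = tiny
        Q = sw.build_generator(fx.params, fx.grid)
        assert np.abs(np.asarray(Q.sum(axis=0))).max() < 1e-9

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError):
            TruncationGrid(M=1, N=5)


class TestSteadyState:
    def test_poisson_submodel(self):
        # gene pinned open, feedback and translation off: the mRNA marginal
        # is the Poisson law of a linear birth-death process
        fx = make_fixture("poisson_mrna")
        dist = sw.steady_state(fx.params, fx.grid)
        pm = dist.mrna_marginal()
        expect = fx.oracle["pmf"](np.arange(fx.grid.M))
        assert 0.5 * np.abs(pm - expect).sum() < 1e-10

    def test_two_state_gene_balance(self):
        fx = make_fixture("two_state_gene")
        dist = sw.steady_state(fx.params, fx.grid)
        assert dist.gene_marginal()[1] == pytest.approx(fx.oracle["p_open"], rel=1e-9)

    def test_mass_normalisation_and_positivity(self, tiny):
        _, dist = tiny
        assert dist.values.sum() == pytest.approx(1.0, abs=1e-12)
        assert dist.values.min() >= 0

    def test_censoring_matches_sparse(self, tiny):
        fx, d_sparse = tiny
        d_cens = sw.steady_state(fx.params, fx.grid, method="censoring")
        assert np.abs(d_cens.values - d_sparse.values).max() < 1e-8

    def test_invariant_under_grid_enlargement(self, tiny):
        fx, d1 = tiny
        g2 = TruncationGrid(M=fx.grid.M + 8, N=fx.grid.N + 20)
        d2 = sw.steady_state(fx.params, g2, method="sparse")
        sub = d2.values[:, : fx.grid.M, : fx.grid.N]
        assert 0.5 * np.abs(sub - d1.values).sum() < 1e-7

    def test_inadequate_truncation_flagged(self, tiny):
        fx, _ = tiny
        with pytest.raises(TruncationError):
            sw.steady_state(fx.params, TruncationGrid(M=10, N=20), method="sparse")

    def test_bimodal_protein_marginal(self, slow_preset_dist):
        # two attracting basins at the reference slow parameters: a mode at
        # the origin and one at high protein counts, separated by a trough
        pn = slow_preset_dist.protein_marginal()
        assert np.argmax(pn) == 0
        high = int(np.argmax(pn[500:])) + 500
        assert high > 1500  # the second mode sits near the open-layer state
        trough = pn[50:high].min()
        assert pn[high] > 10 * trough


class TestLandscape:
    def test_uniform_distribution_flat_potential(self):
        g = TruncationGrid(M=2, N=2)
        vals = np.full((2, 2, 2), 1 / 8)
        d = sw.JointDistribution(grid=g, values=vals)
        ls = sw.landscape(d)
        assert np.allclose(ls.U, np.log(4.0))  # marginal is uniform on 4 sites

    def test_floor_applied_to_zeros(self):
        g = TruncationGrid(M=2, N=2)
        vals = np.zeros((2, 2, 2))
        vals[0, 0, 0] = 1.0
        d = sw.JointDistribution(grid=g, values=vals)
        ls = sw.landscape(d, floor=1e-16)
        assert ls.U.max() == pytest.approx(-np.log(1e-16))
        assert np.isfinite(ls.U).all()

    def test_argmin_is_argmax(self, tiny):
        _, dist = tiny
        ls = sw.landscape(dist)
        assert np.argmin(ls.U) == np.argmax(dist.marginal_mn())


class TestKL:
    def test_identical_tables_zero(self, tiny):
        _, dist = tiny
        assert sw.kl_divergence(dist.marginal_mn(), dist.marginal_mn()) == 0.0

    def test_hand_computed_value(self):
        # (1, 0) vs (1/2, 1/2) with flooring: dominated by ln 2
        kl = sw.kl_divergence(np.array([1.0, 0.0]), np.array([0.5, 0.5]))
        assert kl == pytest.approx(np.log(2.0), rel=1e-9)

    def test_nonnegative_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.random((5, 7))
            q = rng.random((5, 7))
            assert sw.kl_divergence(p, q) >= 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            sw.kl_divergence(np.ones(3), np.ones(4))


class TestMeanFirstPassage:
    def test_pure_death_harmonic_sum(self):
        fx = make_fixture("pure_death")
        Q = sw.build_generator(fx.params, fx.grid)
        g = fx.grid
        src = [int(g.state_index(0, 0, fx.oracle["n0"]))]
        tgt = [int(g.state_index(a, m, 0)) for a in (0, 1) for m in range(g.M)]
        t = sw.mean_first_passage(Q, src, tgt)
        assert t == pytest.approx(fx.oracle["mfpt_to_zero"], abs=1e-10)

    def test_source_inside_target_is_zero(self):
        fx = make_fixture("pure_death")
        Q = sw.build_generator(fx.params, fx.grid)
        g = fx.grid
        tgt = [int(g.state_index(a, m, 0)) for a in (0, 1) for m in range(g.M)]
        assert sw.mean_first_passage(Q, [tgt[0]], tgt) == 0.0

    def test_block_solver_matches_sparse(self, tiny):
        fx, _ = tiny
        g = fx.grid
        ns = fx.oracle["n_split"]
        t_block = sw.basin_mfpt(fx.params, g, "off_to_on", ns, start=(0, 0, 0))
        Q = sw.build_generator(fx.params, g)
        tgt = [
            int(g.state_index(a, m, n))
            for a in (0, 1)
            for m in range(g.M)
            for n in range(ns + 1, g.N)
        ]
        t_sparse = sw.mean_first_passage(Q, [int(g.state_index(0, 0, 0))], tgt)
        assert t_block == pytest.approx(t_sparse, rel=1e-6)
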