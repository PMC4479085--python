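"""Adiabatic reduction, Hamiltonian identities, and minimum-action paths."""

import numpy as np
import pytest

import switchscape as sw
from switchscape.fast import (
    ReducedNetwork,
    effective_synthesis,
    geometric_action,
    hamiltonian,
    reduced_network,
)
from switchscape.fixtures import make_fixture


def one_d_birth_death():
    fx = make_fixture("oneD_birth_death")
    b, d = fx.oracle["b"], fx.oracle["d"]
    net = ReducedNetwork(
        rates=lambda x: np.array([b, d * max(x[0], 0.0)]),
        rates_jac=lambda x: np.array([[0.0], [d]]),
        jumps=np.array([[1.0], [-1.0]]),
    )
    return fx, net


class TestReducedDrift:
    def test_origin_value(self, fast_preset):
        p = fast_preset
        dm, dn = sw.reduced_drift([0.0, 0.0], p)
        assert dm == pytest.approx(p.k_r0 * p.k_g0 / (p.d_g + p.k_g0), rel=1e-12)
        assert dn == 0.0

    def test_channel_decomposition_identity(self, fast_preset):
        net = reduced_network(fast_preset)
        rng = np.random.default_rng(1)
        for _ in range(100):
            x = rng.uniform(0, 200, 2)
            via_channels = net.rates(x) @ net.jumps
            assert np.allclose(via_channels, sw.reduced_drift(x, fast_preset),
                               atol=1e-12)

    def test_adiabatic_saturation(self, fast_preset):
        # with instant activation the open-gene probability tends to 1 and
        # the effective synthesis approaches the raw transcription rate
        p = fast_preset.with_(k_g=1e9, k_g0=1e6)
        n = 1000.0
        o = sw.occupancy(n, p)
        assert effective_synthesis(n, p) == pytest.approx(
            p.k_r0 + p.k_r * o, rel=1e-5
        )


class TestCriticalPoints:
    def test_bistable_structure(self, fast_preset, fast_critical):
        cp = fast_critical
        assert len(cp.points) == 3 and cp.bistable
        for x in cp.points:
            assert np.linalg.norm(sw.reduced_drift(x, fast_preset)) < 1e-10
        e_sad = cp.eigenvalues[[i for i, pt in enumerate(cp.points)
                                if np.allclose(pt, cp.saddle)][0]]
        assert e_sad.real.min() < 0 < e_sad.real.max()
        assert cp.off[1] < cp.saddle[1] < cp.on[1]

    def test_monostable_beyond_window(self, fast_preset):
        cp = sw.find_critical_points(fast_preset.with_(K=4000.0))
        assert not cp.bistable
        assert cp.off is not None and cp.on is None


class TestHamiltonian:
    def test_zero_momentum_identities(self, fast_preset):
        net = reduced_network(fast_preset)
        rng = np.random.default_rng(2)
        for _ in range(50):
            x = rng.uniform(0, 2000, 2)
            assert hamiltonian(x, np.zeros(2), net) == 0.0
            _, Hp = hamiltonian(x, np.zeros(2), net, with_grad=True)
            assert np.allclose(Hp, net.drift(x), atol=1e-12)

    def test_one_d_level_set_momentum(self):
        # for a birth-death channel pair the H = 0 momentum is ln(d n / b)
        fx, net = one_d_birth_death()
        b, d = fx.oracle["b"], fx.oracle["d"]
        n = 55.0
        path = np.array([[n], [n + 1.0]])
        _, pstars = geometric_action(net, path)
        assert pstars[0, 0] == pytest.approx(np.log(d * (n + 0.5) / b), rel=1e-9)


class TestGmam:
    def test_one_d_action_matches_closed_form(self):
        fx, net = one_d_birth_death()
        b, d = fx.oracle["b"], fx.oracle["d"]
        ap = sw.gmam(np.array([b / d]), np.array([60.0]), net, n_images=64)
        exact = fx.oracle["action"](b / d, 60.0)
        assert ap.action == pytest.approx(exact, rel=0.01)
        assert ap.action >= 0

    def test_deterministic_relaxation_costs_nothing(self, fast_preset, fast_critical):
        net = reduced_network(fast_preset)
        ap = sw.gmam(fast_critical.saddle, fast_critical.on, net, n_images=64)
        assert 0 <= ap.action < 1e-4

    def test_switching_paths_cross_at_saddle_and_differ(
        self, fast_preset, fast_critical, fast_paths
    ):
        cp = fast_critical
        up, dn = fast_paths
        net = reduced_network(fast_preset)
        # grid-cell scale of the default 40x40 landscape over the basin box
        cell = np.array([1.25 * cp.on[0] / 39, 1.25 * cp.on[1] / 39])
        for ap in (up, dn):
            assert ap.action > 0
            assert ap.constraint_residual(net) < 1e-8
            d = np.abs(ap.phi - cp.saddle) / cell
            assert np.min(np.linalg.norm(d, axis=1)) < 2.0
        # distinct curves: they separate by more than the lattice spacing
        from scipy.spatial.distance import cdist

        D = cdist(up.phi, dn.phi)
        assert max(D.min(axis=0).max(), D.min(axis=1).max()) > 1.0

    def test_needs_enough_images(self, fast_preset, fast_critical):
        with pytest.raises(ValueError):
            sw.gmam(fast_critical.off, fast_critical.on, fast_preset, n_images=8)


class TestGlobalQuasipotential:
    def test_assembled_landscape(self, fast_preset, fast_critical):
        qp = sw.global_quasipotential(fast_preset, grid_shape=(24, 24),
                                      fan_size=6, n_images=48, tol=1e-4)
        cp = fast_critical

        def value_at(x):
            i = np.argmin(np.abs(qp.m_axis - x[0]))
            j = np.argmin(np.abs(qp.n_axis - x[1]))
            return qp.S[i, j]

        # uphill actions out of both basins are positive
        assert qp.saddle_values[0] > 0 and qp.saddle_values[1] > 0
        # glued surface: non-negative, zero at the global minimum, and both
        # attractors sit far below the saddle level of their own basin
        finite = qp.S[np.isfinite(qp.S)]
        assert finite.min() == 0.0
        shift = qp.saddle_values[0] - qp.saddle_values[1]
        depth = {"off": qp.saddle_values[0], "on": qp.saddle_values[1]}
        base = max(-shift, 0.0)  # re-zeroing offset of the off surface
        assert value_at(cp.off) < base + 0.35 * depth["off"]
        assert value_at(cp.on) < (base + shift) + 0.35 * depth["on"] + 1e-9

    def test_landscape_tracks_cme_potential_along_path(
        self, fast_preset, fast_paths
    ):
        # large-deviation consistency: -ln P^ss from the CME is monotonically
        # related to the accumulated action along the uphill switching path
        from scipy.stats import spearmanr

        up, _ = fast_paths
        dist = sw.steady_state(fast_preset)
        U = sw.landscape(dist).U
        uphill = up.phi[up.cumulative < 0.98 * up.cumulative[-1]]
        s_vals = up.cumulative[: len(uphill)]
        u_vals = []
        for m, n in uphill:
            i = min(max(int(round(m)), 0), U.shape[0] - 1)
            j = min(max(int(round(n)), 0), U.shape[1] - 1)
            u_vals.append(U[i, j])
        rho = spearmanr(s_vals, u_vals).statistic
        assert rho > 0.9
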