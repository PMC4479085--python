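"""Regime experiments: bistability, reference times, sorting, classification."""

import numpy as np
import pytest

import switchscape as sw
from switchscape.experiments import (
    SortingExperimentResult,
    bistability_report,
    classify_regime,
    find_k_boundary,
    reference_time,
    sorting_experiment,
    perturbation_response,
)


class TestBistability:
    def test_report_consistency(self, tiny):
        fx, dist = tiny
        ns = fx.oracle["n_split"]
        rep = bistability_report(fx.params, n_split=ns, dist=dist)
        off, on = dist.basin_masses(ns)
        assert rep.occupancy_off == pytest.approx(off)
        assert rep.occupancy_on == pytest.approx(on)
        assert rep.occupancy_off + rep.occupancy_on == pytest.approx(1.0, abs=1e-9)
        assert rep.bistable  # both basins carry more than 1%
        strict = bistability_report(fx.params, n_split=ns, dist=dist, threshold=0.5)
        assert not strict.bistable

    def test_k_balance_point(self, tiny):
        # threshold 0.5 locates the K at which the two basins balance
        fx, _ = tiny
        ns = fx.oracle["n_split"]
        K_bal = find_k_boundary(fx.params, "lower", occupancy_threshold=0.5,
                                bracket=(10.0, 32.0), resolution=0.5, n_split=ns)
        rep = bistability_report(fx.params.with_(K=K_bal), n_split=ns)
        assert rep.occupancy_off == pytest.approx(0.5, abs=0.03)
        # stability under halving the bisection resolution
        K_bal2 = find_k_boundary(fx.params, "lower", occupancy_threshold=0.5,
                                 bracket=(10.0, 32.0), resolution=0.25, n_split=ns)
        assert abs(K_bal - K_bal2) <= 0.5

    def test_bad_bracket_rejected(self, tiny):
        fx, _ = tiny
        with pytest.raises(ValueError, match="bracket"):
            # both endpoints sit on the same side of the 50% level
            find_k_boundary(fx.params, "lower", occupancy_threshold=0.5,
                            bracket=(27.0, 31.0), n_split=fx.oracle["n_split"])


class TestReferenceTime:
    def test_exponential_decay_closed_form(self, slow_preset):
        # with near-instant mRNA turnover the relaxation is a bare protein
        # decay: T = ln(n0 / threshold) / d_p
        p = slow_preset.with_(d_r=500.0, k_r=slow_preset.k_r * 500.0 / slow_preset.d_r,
                              k_r0=slow_preset.k_r0 * 500.0 / slow_preset.d_r)
        n0 = sw.layer_fixed_point(1, p)[1]
        T = reference_time(p, "on_to_off", threshold=400.0)
        assert T == pytest.approx(np.log(n0 / 400.0) / p.d_p, rel=0.02)

    def test_threshold_at_start_is_zero(self, slow_preset):
        n0 = sw.layer_fixed_point(1, slow_preset)[1]
        assert reference_time(slow_preset, "on_to_off", threshold=n0 + 1) == 0.0

    def test_matches_ssa_relaxation_time(self, slow_preset):
        # the no-switching relaxation surrogate should match the mean
        # duration of sampled flip-to-arrival segments in the slow regime
        from switchscape.experiments import default_split

        ns = default_split(sw.kappa_family(100.0, slow_preset))
        n_on = sw.layer_fixed_point(1, slow_preset)[1]
        radius = 0.05
        ens = sw.sample_reactive_segments(slow_preset, "on_to_off", 8, seed=17,
                                          n_split=ns, arrival_radius=radius)
        durations = [seg[-1, 0] - seg[0, 0] for seg in ens.segments]
        T = reference_time(slow_preset, "on_to_off", threshold=radius * n_on)
        assert np.mean(durations) == pytest.approx(T, rel=0.3)


class TestSorting:
    def test_initial_fractions_and_martingale(self, tiny):
        fx, dist = tiny
        times = np.concatenate([[0.0], np.geomspace(0.5, 150.0, 12)])
        res = sorting_experiment(fx.params, cohort=4000, threshold=8, seed=5,
                                 dist=dist, record_times=times)
        assert res.frac_plus[0, 0] == 1.0
        assert res.frac_plus[1, 0] == 0.0
        pooled = res.pooled_fraction()
        se = np.sqrt(res.equilibrium * (1 - res.equilibrium) / 4000)
        assert np.abs(pooled - pooled[0]).max() < 4 * se

    def test_groups_converge_to_equilibrium(self, tiny):
        fx, dist = tiny
        times = np.geomspace(1.0, 400.0, 10)
        res = sorting_experiment(fx.params, cohort=4000, threshold=8, seed=8,
                                 dist=dist, record_times=times)
        assert res.frac_plus[0, -1] == pytest.approx(res.equilibrium, abs=0.04)
        assert res.frac_plus[1, -1] == pytest.approx(res.equilibrium, abs=0.04)

    def test_small_cohort_warns(self, tiny):
        fx, dist = tiny
        with pytest.warns(UserWarning, match="cohort"):
            sorting_experiment(fx.params, cohort=50, threshold=8, seed=1,
                               dist=dist, record_times=np.array([1.0]))

    def test_null_perturbation_response(self, tiny):
        fx, dist = tiny
        times = np.concatenate([[0.0], np.geomspace(0.5, 80.0, 8)])
        base = sorting_experiment(fx.params, cohort=3000, threshold=8, seed=12,
                                  dist=dist, record_times=times)
        resp = perturbation_response(fx.params, [1.0], baseline=base,
                                     cohort=3000, threshold=8, seed=13)
        assert abs(resp[1.0][1]["progress_gain"]) < 0.06


def _synthetic_result(times, frac_plus_group, equilibrium):
    frac = np.vstack([frac_plus_group, np.full_like(times, equilibrium)])
    return SortingExperimentResult(
        threshold=400, times=times, frac_plus=frac, group_sizes=(500, 500),
        equilibrium=equilibrium, params=sw.preset("slow"), seed=0, sampling="cme",
    )


class TestClassifyRule:
    """Decision logic on synthetic recovery curves (no simulation)."""

    def test_weak_memory_is_intermediate(self):
        t = np.linspace(0.0, 30.0, 16)
        base = _synthetic_result(t, 0.2 + 0.8 * np.exp(-t / 3.0), 0.2)
        call = classify_regime(base, {}, T=2.0)
        assert call.verdict == "intermediate"

    def test_strong_memory_faster_recovery_is_slow(self):
        t = np.linspace(0.0, 30.0, 16)
        base = _synthetic_result(t, 0.2 + 0.8 * np.exp(-t / 5000.0), 0.2)
        pert = _synthetic_result(t, 0.2 + 0.8 * np.exp(-t / 40.0), 0.2)
        resp = {10.0: (pert, {"progress_gain": 0.4, "half_time_change": -4000.0})}
        call = classify_regime(base, resp, T=2.0)
        assert call.verdict == "slow"

    def test_strong_memory_flat_response_is_fast(self):
        t = np.linspace(0.0, 30.0, 16)
        base = _synthetic_result(t, 0.2 + 0.8 * np.exp(-t / 5000.0), 0.2)
        pert = _synthetic_result(t, 0.2 + 0.8 * np.exp(-t / 5100.0), 0.2)
        resp = {10.0: (pert, {"progress_gain": 0.002, "half_time_change": 100.0})}
        call = classify_regime(base, resp, T=2.0)
        assert call.verdict == "fast"


class TestClassifyEndToEnd:
    @pytest.mark.parametrize("kappa, expected", [(0.001, "slow"), (0.03, "intermediate"),
                                                 (50.0, "fast")])
    def test_canonical_presets(self, slow_preset, kappa, expected):
        from switchscape.experiments import _stationary

        p = sw.kappa_family(kappa, slow_preset)
        T = reference_time(slow_preset, "on_to_off", 400)
        times = np.concatenate([[0.0], np.geomspace(0.1 * T, 30 * T, 14)])
        base = sorting_experiment(p, cohort=2000, threshold=400, seed=2,
                                  dist=_stationary(p), record_times=times)
        resp = perturbation_response(p, [10.0], baseline=base, cohort=2000,
                                     threshold=400, seed=102)
        call = classify_regime(base, resp, T)
        assert call.verdict == expected
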