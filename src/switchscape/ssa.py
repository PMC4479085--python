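"""Exact stochastic simulation of the six-reaction network.

Direct-method Gillespie kernels are JIT-compiled with numba.  A tau-leaping
variant accelerates long mean-switching-time sweeps: mRNA and protein
reaction counts are Poisson-approximated over a leap chosen by the usual
relative-change criterion, while gene-state flips are kept *exact* by capping
the leap so that at most a small expected number of switching events falls
inside it.  Leaping is disabled wherever exactness is asserted.

Switching times are measured between protein half-plane basins: a replicate
starts at the source basin's metastable point and runs until the protein
count first enters the target half-plane.  The dwell-excluded transition
time ``T`` (time since the last departure from the source basin) is recorded
alongside the full first-passage time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .params import GeneNetworkParams, STATE_CHANGES

__all__ = [
    "Trajectory",
    "MSTResult",
    "PathEnsemble",
    "simulate",
    "estimate_mst",
    "reactive_segments",
    "sample_reactive_segments",
    "average_path",
    "empirical_distribution",
    "substream_seed",
]

_EXHAUSTED = 0  # event budget hit before the horizon
_HORIZON = 1
_HIT = 2


def substream_seed(seed: int, index: int) -> int:
    """Counter-based derivation of independent per-replicate seeds.

    Replicate ``index`` always receives the same seed for a given master
    seed, so growing a replicate count never changes earlier replicates.
    """
    rng = np.random.Generator(np.random.Philox(key=seed, counter=[0, 0, 0, index]))
    return int(rng.integers(0, 2**31 - 1))


_philox = substream_seed


@njit(cache=True, inline="always")
def _occ(n, K, hill):
    if n <= 0.0:
        return 0.0
    if hill == 1.0:
        return n / (n + K)
    r = (n / K) ** hill
    return r / (1.0 + r)


@njit(cache=True, inline="always")
def _rates(alpha, m, n, p, out):
    # p = (k_g, k_g0, d_g, k_r, k_r0, k_p, d_r, d_p, K, hill)
    o = _occ(n, p[8], p[9])
    if alpha == 1:
        out[0] = p[2]
        out[1] = 0.0
        out[2] = p[3] * o + p[4]
    else:
        out[0] = 0.0
        out[1] = p[0] * o + p[1]
        out[2] = 0.0
    out[3] = p[5] * m
    out[4] = p[6] * m
    out[5] = p[7] * n


@njit(cache=True)
def _sim_record(p, alpha, m, n, t_max, max_events, seed):
    """Direct SSA recording every jump; returns filled prefix of the arrays."""
    np.random.seed(seed)
    times = np.empty(max_events)
    states = np.empty((max_events, 3), dtype=np.int64)
    rates = np.empty(6)
    t = 0.0
    k = 0
    status = _HORIZON
    while True:
        _rates(alpha, m, n, p, rates)
        tot = rates[0] + rates[1] + rates[2] + rates[3] + rates[4] + rates[5]
        if tot <= 0.0:
            break
        t += np.random.exponential(1.0 / tot)
        if t > t_max:
            break
        u = np.random.random() * tot
        acc = 0.0
        j = 0
        for jj in range(6):
            acc += rates[jj]
            if u <= acc:
                j = jj
                break
        if j == 0:
            alpha = 0
        elif j == 1:
            alpha = 1
        elif j == 2:
            m += 1
        elif j == 3:
            n += 1
        elif j == 4:
            m -= 1
        else:
            n -= 1
        times[k] = t
        states[k, 0] = alpha
        states[k, 1] = m
        states[k, 2] = n
        k += 1
        if k >= max_events:
            status = _EXHAUSTED
            break
    return times[:k], states[:k], status


@njit(cache=True)
def _run_to_basin(p, alpha, m, n, n_split, n_core, target_high, t_max, max_events, seed):
    """Exact SSA until the protein count enters the target half-plane.

    ``n_core`` marks the core of the source basin (the metastable protein
    level): the dwell-excluded transition time T is measured from the last
    visit to the core until the first entry into the target.
    Returns (first-passage time, T, status).
    """
    np.random.seed(seed)
    rates = np.empty(6)
    t = 0.0
    t_core = 0.0  # time of the most recent visit to the source core
    for _ in range(max_events):
        if target_high == 1:
            if n > n_split:
                return t, t - t_core, _HIT
            if n <= n_core:
                t_core = t
        else:
            if n <= n_split:
                return t, t - t_core, _HIT
            if n >= n_core:
                t_core = t
        _rates(alpha, m, n, p, rates)
        tot = rates[0] + rates[1] + rates[2] + rates[3] + rates[4] + rates[5]
        if tot <= 0.0:
            return t, t - t_core, _EXHAUSTED
        t += np.random.exponential(1.0 / tot)
        if t > t_max:
            return t_max, 0.0, _HORIZON
        u = np.random.random() * tot
        acc = 0.0
        j = 0
        for jj in range(6):
            acc += rates[jj]
            if u <= acc:
                j = jj
                break
        if j == 0:
            alpha = 0
        elif j == 1:
            alpha = 1
        elif j == 2:
            m += 1
        elif j == 3:
            n += 1
        elif j == 4:
            m -= 1
        else:
            n -= 1
    return t, 0.0, _EXHAUSTED


@njit(cache=True)
def _step_tau(p, alpha, m, n, t, t_end, eps, rates):
    """One hybrid step: exact when slow, Poisson leap otherwise.

    Returns (alpha, m, n, t).  Gene flips are handled exactly as long as
    they are slow on the leap timescale (the leap is capped so the flip
    probability within it stays small and a single flip time is drawn
    explicitly); when the gene flickers many times per leap, its state is
    adiabatically averaged -- transcription fires at the occupancy-weighted
    rate and the end-of-leap gene state is drawn from its equilibrium.
    """
    _rates(alpha, m, n, p, rates)
    tot = rates[0] + rates[1] + rates[2] + rates[3] + rates[4] + rates[5]
    if tot <= 0.0:
        return alpha, m, n, t_end
    # leap from relative-change control on m and n
    mu_m = rates[2] - rates[4]
    mu_n = rates[3] - rates[5]
    s2_m = rates[2] + rates[4]
    s2_n = rates[3] + rates[5]
    tau = t_end - t
    bm = max(eps * m, 1.0)
    bn = max(eps * n, 1.0)
    if mu_m != 0.0:
        tau = min(tau, bm / abs(mu_m))
    if s2_m > 0.0:
        tau = min(tau, bm * bm / s2_m)
    if mu_n != 0.0:
        tau = min(tau, bn / abs(mu_n))
    if s2_n > 0.0:
        tau = min(tau, bn * bn / s2_n)
    o = _occ(n, p[8], p[9])
    act = p[0] * o + p[1]
    flip_rate = act + p[2]
    if flip_rate * tau > 10.0:
        # adiabatic gene: many flips per leap; average the transcription
        p_open = act / flip_rate
        tr_eff = (p[3] * o + p[4]) * p_open
        s2 = tr_eff + rates[4]
        if s2 > 0.0:
            tau = min(tau, bm * bm / s2, bm / max(abs(tr_eff - rates[4]), 1e-300))
        while True:
            k_tr = np.random.poisson(tr_eff * tau)
            k_dm = np.random.poisson(rates[4] * tau)
            k_tl = np.random.poisson(rates[3] * tau)
            k_dn = np.random.poisson(rates[5] * tau)
            if m + k_tr - k_dm >= 0 and n + k_tl - k_dn >= 0:
                m = m + k_tr - k_dm
                n = n + k_tl - k_dn
                break
            tau *= 0.5
        alpha = 1 if np.random.random() < p_open else 0
        return alpha, m, n, t + tau
    if tau * tot < 10.0:
        # not worth leaping: exact step
        dt = np.random.exponential(1.0 / tot)
        if t + dt > t_end:
            return alpha, m, n, t_end
        u = np.random.random() * tot
        acc = 0.0
        j = 0
        for jj in range(6):
            acc += rates[jj]
            if u <= acc:
                j = jj
                break
        if j == 0:
            alpha = 0
        elif j == 1:
            alpha = 1
        elif j == 2:
            m += 1
        elif j == 3:
            n += 1
        elif j == 4:
            m -= 1
        else:
            n -= 1
        return alpha, m, n, t + dt
    gene_rate = rates[0] + rates[1]
    if gene_rate > 0.0:
        tau = min(tau, 0.2 / gene_rate)
    # draw the (at most one) gene flip exactly within the leap
    t_flip = tau + 1.0
    if gene_rate > 0.0:
        t_flip = np.random.exponential(1.0 / gene_rate)
        if t_flip < tau:
            tau = t_flip
    while True:
        k_tr = np.random.poisson(rates[2] * tau)
        k_tl = np.random.poisson(rates[3] * tau)
        k_dm = np.random.poisson(rates[4] * tau)
        k_dn = np.random.poisson(rates[5] * tau)
        if m + k_tr - k_dm >= 0 and n + k_tl - k_dn >= 0:
            m = m + k_tr - k_dm
            n = n + k_tl - k_dn
            break
        tau *= 0.5  # rejected leap: retry shorter
        if t_flip < tau:
            tau = t_flip
    if t_flip <= tau:
        alpha = 1 - alpha
    return alpha, m, n, t + tau


@njit(cache=True)
def _run_to_basin_tau(p, alpha, m, n, n_split, n_core, target_high, t_max, max_steps, eps, seed):
    np.random.seed(seed)
    rates = np.empty(6)
    t = 0.0
    t_core = 0.0
    for _ in range(max_steps):
        if target_high == 1:
            if n > n_split:
                return t, t - t_core, _HIT
            if n <= n_core:
                t_core = t
        else:
            if n <= n_split:
                return t, t - t_core, _HIT
            if n >= n_core:
                t_core = t
        alpha, m, n, t = _step_tau(p, alpha, m, n, t, t_max, eps, rates)
        if t >= t_max:
            return t_max, 0.0, _HORIZON
    return t, 0.0, _EXHAUSTED


@njit(cache=True)
def _evolve_to_times(p, alpha, m, n, record_times, eps, use_leap, max_steps, seed):
    """Protein (and gene/mRNA) state of one cell at each recording time."""
    np.random.seed(seed)
    rates = np.empty(6)
    R = record_times.shape[0]
    out = np.empty((R, 3), dtype=np.int64)
    t = 0.0
    for r in range(R):
        t_end = record_times[r]
        steps = 0
        while t < t_end and steps < max_steps:
            steps += 1
            if use_leap == 1:
                alpha, m, n, t = _step_tau(p, alpha, m, n, t, t_end, eps, rates)
            else:
                _rates(alpha, m, n, p, rates)
                tot = rates[0] + rates[1] + rates[2] + rates[3] + rates[4] + rates[5]
                if tot <= 0.0:
                    break
                dt = np.random.exponential(1.0 / tot)
                if t + dt > t_end:
                    t = t_end
                    break
                t += dt
                u = np.random.random() * tot
                acc = 0.0
                j = 0
                for jj in range(6):
                    acc += rates[jj]
                    if u <= acc:
                        j = jj
                        break
                if j == 0:
                    alpha = 0
                elif j == 1:
                    alpha = 1
                elif j == 2:
                    m += 1
                elif j == 3:
                    n += 1
                elif j == 4:
                    m -= 1
                else:
                    n -= 1
        out[r, 0] = alpha
        out[r, 1] = m
        out[r, 2] = n
    return out


@njit(cache=True)
def _run_until_flip(p, alpha, m, n, t_max, max_events, seed):
    """Exact SSA until the gene state changes; no event recording."""
    np.random.seed(seed)
    rates = np.empty(6)
    t = 0.0
    a0 = alpha
    for _ in range(max_events):
        _rates(alpha, m, n, p, rates)
        tot = rates[0] + rates[1] + rates[2] + rates[3] + rates[4] + rates[5]
        if tot <= 0.0:
            return t, alpha, m, n, _EXHAUSTED
        t += np.random.exponential(1.0 / tot)
        if t > t_max:
            return t_max, alpha, m, n, _HORIZON
        u = np.random.random() * tot
        acc = 0.0
        j = 0
        for jj in range(6):
            acc += rates[jj]
            if u <= acc:
                j = jj
                break
        if j == 0:
            alpha = 0
        elif j == 1:
            alpha = 1
        elif j == 2:
            m += 1
        elif j == 3:
            n += 1
        elif j == 4:
            m -= 1
        else:
            n -= 1
        if alpha != a0:
            return t, alpha, m, n, _HIT
    return t, alpha, m, n, _EXHAUSTED


@njit(cache=True)
def _occupation_histogram(p, alpha, m, n, n_events, M, N, seed):
    """Residence-time-weighted state histogram from one long exact run."""
    np.random.seed(seed)
    hist = np.zeros((2, M, N))
    rates = np.empty(6)
    for _ in range(n_events):
        _rates(alpha, m, n, p, rates)
        tot = rates[0] + rates[1] + rates[2] + rates[3] + rates[4] + rates[5]
        if tot <= 0.0:
            break
        dt = np.random.exponential(1.0 / tot)
        if m < M and n < N:
            hist[alpha, m, n] += dt
        u = np.random.random() * tot
        acc = 0.0
        j = 0
        for jj in range(6):
            acc += rates[jj]
            if u <= acc:
                j = jj
                break
        if j == 0:
            alpha = 0
        elif j == 1:
            alpha = 1
        elif j == 2:
            m += 1
        elif j == 3:
            n += 1
        elif j == 4:
            m -= 1
        else:
            n -= 1
    return hist


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Jump record of one exact simulation (the initial state is row 0)."""

    times: np.ndarray  # (k,) jump times, strictly increasing; times[0] = 0
    states: np.ndarray  # (k, 3) int: alpha, m, n after each jump
    params: GeneNetworkParams
    seed: int
    exhausted: bool = False  # event budget hit before the horizon


@dataclass
class MSTResult:
    direction: str
    mean: float
    se: float
    times: np.ndarray
    transition_times: np.ndarray  # dwell-excluded T per replicate
    censored_fraction: float
    replicates: int

    @property
    def transition_mean(self) -> float:
        return float(self.transition_times.mean()) if self.transition_times.size else np.nan


@dataclass
class PathEnsemble:
    """Reactive trajectory segments and their residence-time density."""

    segments: List[np.ndarray]  # each (k, 3): t, m, n
    density: dict  # (m, n) -> accumulated residence time
    direction: str

    @property
    def total_reactive_time(self) -> float:
        return float(sum(d for d in self.density.values()))


def simulate(
    params: GeneNetworkParams,
    initial: Tuple[int, int, int],
    horizon: float,
    seed: int,
    max_events: int = 50_000_000,
) -> Trajectory:
    """Statistically exact jump trajectory from ``initial = (alpha, m, n)``."""
    if not horizon > 0:
        raise ValueError("horizon must be positive")
    alpha, m, n = initial
    times, states, status = _sim_record(
        params.as_tuple(), alpha, m, n, float(horizon), max_events, seed
    )
    t0 = np.concatenate([[0.0], times])
    s0 = np.vstack([np.array([[alpha, m, n]], dtype=np.int64), states])
    return Trajectory(times=t0, states=s0, params=params, seed=seed,
                      exhausted=status == _EXHAUSTED)


def default_start(params: GeneNetworkParams, basin: Literal["off", "on"]) -> Tuple[int, int, int]:
    """Metastable starting point of a basin, rounded to the lattice.

    Below kappa = 1 the per-layer rate-equation fixed points are used (gene
    closed in the off basin, open in the on basin); above, the adiabatically
    reduced fixed points with the gene in its likelier state.
    """
    from .fast import find_critical_points
    from .slow import layer_fixed_point

    if params.kappa < 1.0:
        if basin == "off":
            return (0, 0, 0)
        m1, n1 = layer_fixed_point(1, params)
        return (1, int(round(m1)), int(round(n1)))
    cp = find_critical_points(params)
    if cp.off is None or cp.on is None:
        raise ValueError("parameter set is not bistable; pass an explicit start")
    m, n = cp.off if basin == "off" else cp.on
    return (1 if basin == "on" else 0, int(round(m)), int(round(n)))


def estimate_mst(
    params: GeneNetworkParams,
    direction: Literal["off_to_on", "on_to_off"],
    n_split: int,
    replicates: int,
    seed: int,
    start: Optional[Tuple[int, int, int]] = None,
    t_max: float = 1e7,
    max_events: int = 2_000_000_000,
    method: Literal["exact", "tau"] = "exact",
    eps: float = 0.03,
) -> MSTResult:
    """Mean switching time between protein half-plane basins by replicated SSA.

    Each replicate starts at the source basin's metastable point and runs
    until the protein count first enters the target half-plane (``n >
    n_split`` for off-to-on, ``n <= n_split`` for on-to-off).  Replicates
    whose event budget or horizon is exhausted are flagged censored and
    excluded from the mean.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    if start is None:
        start = default_start(params, "off" if direction == "off_to_on" else "on")
    target_high = 1 if direction == "off_to_on" else 0
    alpha0, m0, n0 = start
    n_core = n0  # source core = metastable protein level of the start
    p = params.as_tuple()
    times, tts = [], []
    censored = 0
    for i in range(replicates):
        s = _philox(seed, i)
        if method == "tau":
            t, tt, status = _run_to_basin_tau(
                p, alpha0, m0, n0, n_split, n_core, target_high, t_max, max_events, eps, s
            )
        else:
            t, tt, status = _run_to_basin(
                p, alpha0, m0, n0, n_split, n_core, target_high, t_max, max_events, s
            )
        if status == _HIT:
            times.append(t)
            tts.append(tt)
        else:
            censored += 1
    times = np.asarray(times)
    tts = np.asarray(tts)
    mean = float(times.mean()) if times.size else np.nan
    se = float(times.std(ddof=1) / np.sqrt(times.size)) if times.size > 1 else np.nan
    return MSTResult(
        direction=direction,
        mean=mean,
        se=se,
        times=times,
        transition_times=tts,
        censored_fraction=censored / replicates,
        replicates=replicates,
    )


def reactive_segments(
    traj: Trajectory,
    n_split: int,
    arrival_points: Optional[dict] = None,
    arrival_radius: float = 0.05,
) -> PathEnsemble:
    """Extract switching segments: gene-state flip -> arrival at the new state.

    A segment opens at every gene-state change that points out of the current
    basin (flip to closed while ``n > n_split``, or to open while ``n <=
    n_split``) and closes when the protein count first reaches the
    destination metastable value (within ``arrival_radius`` of the
    inter-state distance).  Segments aborted by a back-flip before arrival
    are discarded.  Residence times are accumulated on the (m, n) lattice.
    """
    if arrival_points is None:
        from .slow import layer_fixed_point

        m1, n1 = layer_fixed_point(1, traj.params)
        arrival_points = {"off": (0.0, 0.0), "on": (m1, n1)}
    t, s = traj.times, traj.states
    n_off = arrival_points["off"][1]
    n_on = arrival_points["on"][1]
    band = arrival_radius * abs(n_on - n_off)
    segments = []
    density: dict = {}
    direction = "mixed"
    i = 1
    k = len(t)
    while i < k:
        flipped = s[i, 0] != s[i - 1, 0]
        if flipped:
            to_open = s[i, 0] == 1
            dest_n = n_on if to_open else n_off
            seg = [(t[i], s[i, 1], s[i, 2])]
            j = i + 1
            ok = False
            while j < k:
                if s[j, 0] != s[j - 1, 0] and ((s[j, 0] == 1) != to_open):
                    break  # flipped back before arriving
                seg.append((t[j], s[j, 1], s[j, 2]))
                if abs(s[j, 2] - dest_n) <= band:
                    ok = True
                    break
                j += 1
            if ok:
                arr = np.asarray(seg, dtype=float)
                segments.append(arr)
                for r in range(len(arr) - 1):
                    key = (int(arr[r, 1]), int(arr[r, 2]))
                    density[key] = density.get(key, 0.0) + (arr[r + 1, 0] - arr[r, 0])
                direction = "on_to_off" if not to_open else "off_to_on"
                i = j + 1
            else:
                # aborted by a back-flip: re-examine the aborting flip
                i = j if j > i else j + 1
        else:
            i += 1
    return PathEnsemble(segments=segments, density=density, direction=direction)


def average_path(ensemble: PathEnsemble, bins: int = 50) -> np.ndarray:
    """Arc-length-binned mean switching path, shape (bins, 2) of (m, n).

    Each segment is reparameterised to [0, 1] by normalised arc length in the
    (m, n) plane; bin-wise means over the ensemble give an ordered polyline.
    This replaces a principal-curve fit; for ensembles concentrated around a
    single monotone path the two agree closely.
    """
    if not ensemble.segments:
        raise ValueError("empty ensemble")
    grid = (np.arange(bins) + 0.5) / bins
    acc = np.zeros((bins, 2))
    cnt = np.zeros(bins)
    for seg in ensemble.segments:
        xy = seg[:, 1:3]
        d = np.sqrt(((np.diff(xy, axis=0)) ** 2).sum(axis=1))
        sarc = np.concatenate([[0.0], np.cumsum(d)])
        if sarc[-1] == 0:
            continue
        sarc /= sarc[-1]
        for b, g in enumerate(grid):
            j = np.searchsorted(sarc, g)
            j = min(max(j, 1), len(sarc) - 1)
            w = (g - sarc[j - 1]) / max(sarc[j] - sarc[j - 1], 1e-300)
            acc[b] += (1 - w) * xy[j - 1] + w * xy[j]
            cnt[b] += 1
    return acc / np.maximum(cnt, 1)[:, None]


def sample_reactive_segments(
    params: GeneNetworkParams,
    direction: Literal["off_to_on", "on_to_off"],
    n_segments: int,
    seed: int,
    n_split: Optional[int] = None,
    arrival_radius: float = 0.05,
    t_max_wait: float = 1e7,
    max_events: int = 500_000_000,
    record_events: int = 2_000_000,
) -> PathEnsemble:
    """Sample reactive switching segments without storing the dwell phases.

    Each segment is obtained by running an exact trajectory from the source
    metastable point until the gene flips (discarding the dwell events),
    then recording the relaxation onto the destination layer.  By the
    strong Markov property this is equivalent to extracting the segments
    from one long trajectory; it avoids storing the ~1e6 dwell events per
    switching event of the slow regime.
    """
    from .slow import layer_fixed_point

    m1, n1 = layer_fixed_point(1, params)
    arrival = {"off": (0.0, 0.0), "on": (m1, n1)}
    src = (1, int(round(m1)), int(round(n1))) if direction == "on_to_off" else (0, 0, 0)
    p = params.as_tuple()
    ensembles = []
    horizon = 50.0 / min(params.d_r, params.d_p)  # generous relaxation window
    for i in range(n_segments):
        s = _philox(seed, i)
        t0, a, m, n, status = _run_until_flip(
            p, src[0], src[1], src[2], t_max_wait, max_events, s
        )
        if status != _HIT:
            continue
        times, states, _ = _sim_record(
            p, a, m, n, horizon, record_events, _philox(seed, 1_000_000 + i)
        )
        # stitch a two-phase mini-trajectory: one pre-flip record, the flip,
        # then the recorded relaxation, so the segment extractor sees the
        # gene-state change at its start
        t_all = np.concatenate([[0.0, 1e-12], 1e-12 + times])
        s_all = np.vstack(
            [np.array([src, (a, m, n)], dtype=np.int64), states]
        )
        traj = Trajectory(times=t_all, states=s_all, params=params, seed=s)
        ens = reactive_segments(traj, n_split if n_split is not None else 0,
                                arrival_points=arrival, arrival_radius=arrival_radius)
        ensembles.append(ens)
    segments: List[np.ndarray] = []
    density: dict = {}
    for ens in ensembles:
        if ens.segments:
            seg = ens.segments[0]  # the flip that defines this draw
            segments.append(seg)
            for r in range(len(seg) - 1):
                key = (int(seg[r, 1]), int(seg[r, 2]))
                density[key] = density.get(key, 0.0) + (seg[r + 1, 0] - seg[r, 0])
    return PathEnsemble(segments=segments, density=density, direction=direction)


def empirical_distribution(
    params: GeneNetworkParams,
    initial: Tuple[int, int, int],
    n_events: int,
    M: int,
    N: int,
    seed: int,
    burn_in: float = 0.1,
) -> np.ndarray:
    """Residence-time-normalised state histogram, shape (2, M, N).

    ``burn_in`` discards the leading fraction of events before accumulating.
    """
    p = params.as_tuple()
    alpha, m, n = initial
    nb = int(burn_in * n_events)
    if nb:
        times, states, _ = _sim_record(p, alpha, m, n, 1e300, nb, _philox(seed, 10_007))
        if len(times):
            alpha, m, n = (int(x) for x in states[-1])
    hist = _occupation_histogram(p, alpha, m, n, n_events, M, N, _philox(seed, 0))
    tot = hist.sum()
    if tot <= 0:
        raise RuntimeError("trajectory accumulated no residence time")
    return hist / tot
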