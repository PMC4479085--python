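"""Two-layer reduction for slow gene switching.

When the gene flips far more slowly than mRNA and protein turn over
(``kappa << 0.01``), the dynamics decompose into independent evolutions on a
gene-closed and a gene-open layer with rare jumps between them.  On each
layer the copy numbers follow the rate equations

    dm/dt = alpha * (k_r0 + k_r * O(n)) - d_r * m
    dn/dt = k_p * m - d_p * n

and the fluctuations around them obey the linear-noise moment equations
``sigma' = sigma J^T + J sigma + 2 D`` with drift Jacobian ``J`` and
diffusion ``D`` read off the propensities.  Concentrations are identified
with copy numbers (volume V = 1), which keeps every object in this module on
the same scale as the CME lattice.

The stationary law is then approximated by a two-component Gaussian mixture:
the *simple* mixture places one stationary Gaussian per layer with closed-
layer weight ``w = d_g / (d_g + k_g0)`` (dwell-time balance); the *modified*
mixture replaces
each component by the time-average of the relaxation Gaussians started from
the opposite layer's stationary pair, averaged over the mean residence time
of the layer (``1/d_g`` open, ``1/k_g0`` closed).  The modified mixture
keeps the probability ridge along the switching paths and reduces to the
simple one as ``kappa -> 0``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import solve_continuous_lyapunov
from scipy.optimize import brentq

from .cme import TruncationGrid, auto_grid, kl_divergence, steady_state
from .params import GeneNetworkParams, occupancy

__all__ = [
    "MomentState",
    "GaussianMixtureLandscape",
    "layer_drift",
    "layer_fixed_point",
    "moment_rhs",
    "integrate_moments",
    "stationary_moments",
    "simple_mixture",
    "modified_mixture",
    "compare_landscapes",
]


def _feedback(n, params: GeneNetworkParams):
    return occupancy(np.maximum(n, 0.0), params)


def _feedback_deriv(n, params: GeneNetworkParams):
    h, K = params.hill, params.K
    n = max(float(n), 0.0)
    if h == 1:
        return K / (n + K) ** 2
    if n == 0.0:
        return 0.0
    r = (n / K) ** h
    return h * r / (n * (1.0 + r) ** 2)


def layer_drift(alpha: int, x: np.ndarray, params: GeneNetworkParams) -> np.ndarray:
    """Rate-equation drift on layer ``alpha``; ``x = (m, n)``."""
    m, n = x
    synth = alpha * (params.k_r0 + params.k_r * _feedback(n, params))
    return np.array([synth - params.d_r * m, params.k_p * m - params.d_p * n])


def layer_fixed_point(alpha: int, params: GeneNetworkParams) -> Tuple[float, float]:
    """Unique non-negative fixed point of the layer rate equations.

    The closed layer relaxes to the origin.  On the open layer the protein
    value solves ``n = (k_p / (d_p d_r)) (k_r0 + k_r O(n))`` by bracketed
    root finding (unique for Hill exponent 1; for higher exponents the
    largest root is returned).
    """
    if alpha == 0:
        return (0.0, 0.0)
    c = params.k_p / (params.d_p * params.d_r)

    def g(n):
        return c * (params.k_r0 + params.k_r * _feedback(n, params)) - n

    hi = c * (params.k_r0 + params.k_r) + 1.0
    # scan from the top so the largest root is bracketed first
    grid = np.linspace(hi, 0.0, 400)
    vals = [g(v) for v in grid]
    for i in range(len(grid) - 1):
        if vals[i] * vals[i + 1] <= 0:
            n_star = brentq(g, min(grid[i + 1], grid[i]), max(grid[i + 1], grid[i]),
                            xtol=1e-10, rtol=1e-14)
            break
    else:
        raise RuntimeError("no fixed point found in bracket [0, hi]")
    m_star = params.d_p * n_star / params.k_p
    return (float(m_star), float(n_star))


@dataclass
class MomentState:
    """Per-layer mean vector and symmetric 2x2 covariance."""

    alpha: int
    mean: np.ndarray  # (2,)
    cov: np.ndarray  # (2, 2)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if not np.allclose(self.cov, self.cov.T, atol=1e-9):
            raise ValueError("covariance must be symmetric")


def _jacobian(alpha, x, params):
    return np.array(
        [
            [-params.d_r, alpha * params.k_r * _feedback_deriv(x[1], params)],
            [params.k_p, -params.d_p],
        ]
    )


def _diffusion(alpha, x, params):
    m, n = np.maximum(x, 0.0)
    synth = alpha * (params.k_r0 + params.k_r * _feedback(n, params))
    return 0.5 * np.array(
        [
            [params.d_r * m + synth, 0.0],
            [0.0, params.k_p * m + params.d_p * n],
        ]
    )


def moment_rhs(alpha: int, x: np.ndarray, cov: np.ndarray, params: GeneNetworkParams):
    """Right-hand side of the coupled mean/covariance equations."""
    c = layer_drift(alpha, x, params)
    J = _jacobian(alpha, x, params)
    dS = cov @ J.T + J @ cov + 2.0 * _diffusion(alpha, x, params)
    return c, dS


def integrate_moments(
    initial: MomentState,
    horizon: float,
    params: GeneNetworkParams,
    t_eval: Optional[np.ndarray] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> List[MomentState]:
    """Integrate the mean/covariance flow on the layer of ``initial``.

    The covariance is symmetrised after every evaluation, so symmetry is
    exact; positive semidefiniteness holds along the flow up to integrator
    tolerance.
    """
    alpha = initial.alpha

    def rhs(t, y):
        x = y[:2]
        cov = np.array([[y[2], y[3]], [y[3], y[4]]])
        c, dS = moment_rhs(alpha, x, cov, params)
        return [c[0], c[1], dS[0, 0], 0.5 * (dS[0, 1] + dS[1, 0]), dS[1, 1]]

    y0 = [
        initial.mean[0],
        initial.mean[1],
        initial.cov[0, 0],
        initial.cov[0, 1],
        initial.cov[1, 1],
    ]
    if t_eval is None:
        t_eval = np.linspace(0.0, horizon, 200)
    sol = solve_ivp(rhs, (0.0, horizon), y0, t_eval=t_eval, method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"moment integration failed: {sol.message}")
    out = []
    for k in range(sol.t.size):
        y = sol.y[:, k]
        out.append(
            MomentState(alpha=alpha, mean=y[:2],
                        cov=np.array([[y[2], y[3]], [y[3], y[4]]]))
        )
    return out


def stationary_moments(alpha: int, params: GeneNetworkParams) -> MomentState:
    """Layer fixed point with the stationary covariance.

    The covariance solves the Lyapunov equation ``J S + S J^T + 2 D = 0`` at
    the fixed point.  The closed layer is degenerate: its fixed point is the
    origin, where all propensities vanish, so the stationary law is a point
    mass (zero covariance).
    """
    x = np.array(layer_fixed_point(alpha, params))
    if alpha == 0:
        return MomentState(alpha=0, mean=x, cov=np.zeros((2, 2)))
    J = _jacobian(alpha, x, params)
    D = _diffusion(alpha, x, params)
    S = solve_continuous_lyapunov(J, -2.0 * D)
    return MomentState(alpha=alpha, mean=x, cov=0.5 * (S + S.T))


# ---------------------------------------------------------------------------
# Gaussian mixture landscapes
# ---------------------------------------------------------------------------

@dataclass
class GaussianMixtureLandscape:
    """Weighted Gaussian families approximating the two-layer stationary law.

    ``components[alpha]`` is a list of ``(weight, mean, cov)`` whose weights
    sum to 1 per layer; ``w`` is the closed-layer mixture weight.
    """

    w: float
    components: Tuple[list, list]
    kind: str

    def layer_lattice_density(self, alpha: int, grid: TruncationGrid) -> np.ndarray:
        """Layer density evaluated at lattice points, renormalised; (M, N)."""
        out = np.zeros((grid.M, grid.N))
        for weight, mean, cov in self.components[alpha]:
            _accumulate_gaussian(out, weight, mean, cov)
        tot = out.sum()
        if tot > 0:
            out /= tot
        return out

    def lattice_density(self, grid: TruncationGrid) -> np.ndarray:
        """Combined density w*P0 + (1-w)*P1 on the (m, n) lattice."""
        return (
            self.w * self.layer_lattice_density(0, grid)
            + (1.0 - self.w) * self.layer_lattice_density(1, grid)
        )


def _accumulate_gaussian(out: np.ndarray, weight: float, mean, cov) -> None:
    """Add a (possibly degenerate) Gaussian, evaluated at integer points."""
    M, N = out.shape
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
    if det < 1e-10 or cov[0, 0] < 1e-8 or cov[1, 1] < 1e-8:
        # point mass at the nearest lattice site
        i = min(max(int(round(mean[0])), 0), M - 1)
        j = min(max(int(round(mean[1])), 0), N - 1)
        out[i, j] += weight
        return
    sm = np.sqrt(cov[0, 0])
    sn = np.sqrt(cov[1, 1])
    i0 = max(int(np.floor(mean[0] - 8.5 * sm)), 0)
    i1 = min(int(np.ceil(mean[0] + 8.5 * sm)) + 1, M)
    j0 = max(int(np.floor(mean[1] - 8.5 * sn)), 0)
    j1 = min(int(np.ceil(mean[1] + 8.5 * sn)) + 1, N)
    if i0 >= i1 or j0 >= j1:
        return
    mi = np.arange(i0, i1)[:, None] - mean[0]
    nj = np.arange(j0, j1)[None, :] - mean[1]
    a = cov[1, 1] / det
    b = -cov[0, 1] / det
    c = cov[0, 0] / det
    q = a * mi**2 + 2.0 * b * mi * nj + c * nj**2
    out[i0:i1, j0:j1] += weight / (2.0 * np.pi * np.sqrt(det)) * np.exp(-0.5 * q)


def mixture_weight(params: GeneNetworkParams) -> float:
    """Closed-layer weight from the dwell-time balance.

    The gene leaves the open layer at rate ``d_g`` (mean dwell ``1/d_g``)
    and leaves the relaxed closed layer at rate ``k_g0`` (the occupancy is
    ~0 once the protein has decayed, mean dwell ``1/k_g0``), so the fraction
    of time spent on the closed layer is

        w = (1/k_g0) / (1/k_g0 + 1/d_g) = d_g / (d_g + k_g0),

    and the open-layer weight is ``1 - w = k_g0 / (k_g0 + d_g)``.  The
    stationary gene-state marginal of the CME confirms this balance.
    """
    return params.d_g / (params.d_g + params.k_g0)


def simple_mixture(params: GeneNetworkParams, warn_kappa: float = 0.01) -> GaussianMixtureLandscape:
    """One stationary Gaussian per layer, weighted by the dwell-time balance."""
    import warnings

    if params.kappa > warn_kappa:
        warnings.warn(
            f"kappa = {params.kappa:.3g} is outside the slow regime (<= {warn_kappa}); "
            "the two-layer mixture may be a poor approximation",
            stacklevel=2,
        )
    comps = []
    for alpha in (0, 1):
        ms = stationary_moments(alpha, params)
        comps.append([(1.0, ms.mean, ms.cov)])
    return GaussianMixtureLandscape(w=mixture_weight(params), components=(comps[0], comps[1]),
                                    kind="simple")


def _relaxation_family(alpha: int, params: GeneNetworkParams, T: float,
                       n_nodes: int) -> list:
    """Time-averaged Gaussian family along the relaxation onto layer ``alpha``.

    Integration starts from the opposite layer's stationary pair.  Beyond a
    relaxation cutoff the moments sit at the layer's own stationary pair to
    machine precision, so quadrature nodes past the cutoff reuse the final
    state; trapezoidal weights on [0, T] then give the exact long-time mass.
    """
    src = stationary_moments(1 - alpha, params)
    start = MomentState(alpha=alpha, mean=src.mean, cov=src.cov)
    slowest = min(params.d_r, params.d_p)
    t_cut = min(T, 80.0 / slowest)
    nodes = np.concatenate([[0.0], np.geomspace(max(t_cut * 1e-5, 1e-8), t_cut,
                                                n_nodes - 1)])
    states = integrate_moments(start, t_cut, params, t_eval=nodes)
    # trapezoid weights over [0, T]; the tail [t_cut, T] is stationary
    w = np.zeros(len(nodes))
    dt = np.diff(nodes)
    w[:-1] += 0.5 * dt
    w[1:] += 0.5 * dt
    w[-1] += max(T - t_cut, 0.0)
    w /= T
    return [(float(wj), st.mean, st.cov) for wj, st in zip(w, states)]


def modified_mixture(
    params: GeneNetworkParams,
    n_nodes: int = 200,
    warn_kappa: float = 0.01,
) -> GaussianMixtureLandscape:
    """Time-averaged Gaussian mixture along the switching relaxations.

    The open-layer component averages the relaxation from the closed-layer
    stationary pair over the mean open residence time ``T1 = 1/d_g``; the
    closed-layer component averages the decay from the open-layer pair over
    ``T0 = 1/k_g0``.  As ``kappa -> 0`` both averages are dominated by the
    stationary endpoint and the simple mixture is recovered.
    """
    import warnings

    if params.kappa > warn_kappa:
        warnings.warn(
            f"kappa = {params.kappa:.3g} is outside the slow regime (<= {warn_kappa})",
            stacklevel=2,
        )
    T1 = 1.0 / params.d_g
    T0 = 1.0 / params.k_g0
    comps0 = _relaxation_family(0, params, T0, n_nodes)
    comps1 = _relaxation_family(1, params, T1, n_nodes)
    return GaussianMixtureLandscape(w=mixture_weight(params), components=(comps0, comps1),
                                    kind="modified")


def compare_landscapes(
    base: GeneNetworkParams,
    kappas: Sequence[float],
    grid: Optional[TruncationGrid] = None,
    floor: float = 1e-16,
    n_nodes: int = 200,
    direction: Literal["cme_to_approx", "approx_to_cme"] = "cme_to_approx",
) -> pd.DataFrame:
    """KL divergence of both mixtures from the CME across a kappa sweep.

    For every kappa the switching rates are rescaled with locked ratios, the
    truncated CME is solved, and the two mixtures are evaluated on the same
    lattice.  Rows: (kappa, layer in {open, closed, global}, method in
    {simple, modified}, kl).  ``direction`` fixes the KL argument order;
    the default measures how much CME mass the approximation misses.
    """
    import warnings

    from .params import kappa_family

    if grid is None:
        grid = auto_grid(base)
    rows = []
    for kappa in kappas:
        params = kappa_family(kappa, base)
        dist = steady_state(params, grid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mixtures = {
                "simple": simple_mixture(params),
                "modified": modified_mixture(params, n_nodes=n_nodes),
            }
        p_layers = {
            0: dist.values[0] / dist.values[0].sum(),
            1: dist.values[1] / dist.values[1].sum(),
        }
        p_global = dist.marginal_mn()
        for method, mix in mixtures.items():
            for alpha, label in ((1, "open"), (0, "closed")):
                q = mix.layer_lattice_density(alpha, grid)
                p = p_layers[alpha]
                kl = (
                    kl_divergence(p, q, floor)
                    if direction == "cme_to_approx"
                    else kl_divergence(q, p, floor)
                )
                rows.append((kappa, label, method, kl))
            qg = mix.lattice_density(grid)
            kl = (
                kl_divergence(p_global, qg, floor)
                if direction == "cme_to_approx"
                else kl_divergence(qg, p_global, floor)
            )
            rows.append((kappa, "global", method, kl))
    return pd.DataFrame(rows, columns=["kappa", "layer", "method", "kl"])
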