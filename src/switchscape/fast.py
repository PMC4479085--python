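"""Adiabatic (fast-switching) reduction and quasi-potential landscapes.

For ``kappa >> 1`` the gene state equilibrates instantly and the network
reduces to a two-species jump process in ``(m, n)`` with four channels:

* mRNA birth at the effective rate
  ``F(n) = (k_r0 + k_r O) (k_g0 + k_g O) / (d_g + k_g0 + k_g O)``
  (transcription propensity times the equilibrium open-gene probability),
* mRNA decay ``d_r m``, protein birth ``k_p m``, protein death ``d_p n``.

Summing rate times jump over the channels reproduces the mean-field drift,
whose two stable fixed points and saddle organise the bistability.  Rare
transitions are governed by the Freidlin-Wentzell Hamiltonian

    H(x, p) = sum_j a_j(x) (exp(nu_j . p) - 1),

with ``H(x, 0) = 0`` and ``dH/dp(x, 0)`` equal to the drift.  The local
quasi-potential ``S(x; x0)`` is the minimal geometric action over curves
from the attractor ``x0`` to ``x`` subject to ``H(phi, p) = 0`` and
``H_p(phi, p) = lambda phi'``; it is computed here by a geometric
minimum-action method: an inner Newton solve recovers the momentum ``p`` on
the ``H = 0`` shell with ``H_p`` parallel to the curve tangent, and an outer
quasi-Newton relaxation moves the curve nodes, re-parameterising to uniform
arc length between rounds.  The stationary law satisfies
``P^ss(x) ~ exp(-V S(x))`` in the large-volume convention used throughout
(V = 1, copy-number coordinates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq, minimize

from .params import GeneNetworkParams, occupancy

__all__ = [
    "ReducedNetwork",
    "CriticalPoints",
    "ActionPath",
    "QuasiPotential",
    "reduced_network",
    "effective_synthesis",
    "reduced_drift",
    "find_critical_points",
    "hamiltonian",
    "geometric_action",
    "gmam",
    "global_quasipotential",
]

_EXP_CAP = 500.0  # cap on exponent arguments inside the Hamiltonian


@dataclass
class ReducedNetwork:
    """A jump network in R^d: channel rates, their gradients, and jumps."""

    rates: Callable[[np.ndarray], np.ndarray]  # x -> (k,)
    rates_jac: Callable[[np.ndarray], np.ndarray]  # x -> (k, d)
    jumps: np.ndarray  # (k, d)

    @property
    def dim(self) -> int:
        return self.jumps.shape[1]

    def drift(self, x: np.ndarray) -> np.ndarray:
        return self.rates(np.asarray(x, dtype=float)) @ self.jumps


def effective_synthesis(n, params: GeneNetworkParams):
    """Effective mRNA synthesis rate after adiabatic gene elimination."""
    o = occupancy(np.maximum(np.asarray(n, dtype=float), 0.0), params)
    act = params.k_g0 + params.k_g * o
    return (params.k_r0 + params.k_r * o) * act / (params.d_g + act)


def _effective_synthesis_deriv(n, params: GeneNetworkParams):
    n = float(max(n, 0.0))
    h, K = params.hill, params.K
    if h == 1:
        do = K / (n + K) ** 2
    elif n == 0.0:
        do = 0.0
    else:
        r = (n / K) ** h
        do = h * r / (n * (1.0 + r) ** 2)
    o = occupancy(n, params)
    act = params.k_g0 + params.k_g * o
    tr = params.k_r0 + params.k_r * o
    den = params.d_g + act
    # d/do of tr*act/den
    ddo = (params.k_r * act * den + tr * params.k_g * den - tr * act * params.k_g) / den**2
    return ddo * do


def reduced_network(params: GeneNetworkParams) -> ReducedNetwork:
    """Four-channel reduced network in (m, n) coordinates."""

    def rates(x):
        m, n = max(x[0], 0.0), max(x[1], 0.0)
        return np.array(
            [
                effective_synthesis(n, params),
                params.d_r * m,
                params.k_p * m,
                params.d_p * n,
            ]
        )

    def rates_jac(x):
        n = max(x[1], 0.0)
        return np.array(
            [
                [0.0, _effective_synthesis_deriv(n, params)],
                [params.d_r, 0.0],
                [params.k_p, 0.0],
                [0.0, params.d_p],
            ]
        )

    jumps = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
    return ReducedNetwork(rates=rates, rates_jac=rates_jac, jumps=jumps)


def reduced_drift(x, params: GeneNetworkParams) -> np.ndarray:
    """Mean-field drift of the reduced system at ``x = (m, n)``."""
    return reduced_network(params).drift(np.asarray(x, dtype=float))


@dataclass
class CriticalPoints:
    """Fixed points of the reduced drift, classified by Jacobian eigenvalues."""

    points: List[np.ndarray]  # all roots found, ascending protein value
    eigenvalues: List[np.ndarray]
    off: Optional[np.ndarray] = None
    saddle: Optional[np.ndarray] = None
    on: Optional[np.ndarray] = None

    @property
    def bistable(self) -> bool:
        return self.off is not None and self.on is not None and self.saddle is not None


def _reduced_jacobian(x, params):
    m, n = x
    return np.array(
        [
            [-params.d_r, _effective_synthesis_deriv(n, params)],
            [params.k_p, -params.d_p],
        ]
    )


def find_critical_points(
    params: GeneNetworkParams,
    n_max: Optional[float] = None,
    scan_points: int = 4000,
) -> CriticalPoints:
    """All fixed points of the reduced drift, classified as off/saddle/on.

    On the protein nullcline ``m = d_p n / k_p`` the fixed points solve
    ``(k_p / (d_p d_r)) F(n) = n``; sign changes on a dense scan are polished
    by bracketed root finding.  Stable-saddle-stable triples are labelled
    off/saddle/on by protein value; monostable parameter sets are legal
    outputs with the missing labels left unset.
    """
    c = params.k_p / (params.d_p * params.d_r)
    if n_max is None:
        n_max = 1.3 * c * (params.k_r0 + params.k_r) + 10.0

    def g(n):
        return c * effective_synthesis(n, params) - n

    ns = np.linspace(0.0, n_max, scan_points)
    vals = np.array([g(v) for v in ns])
    roots = []
    for i in range(len(ns) - 1):
        if vals[i] == 0.0:
            roots.append(ns[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(g, ns[i], ns[i + 1], xtol=1e-10, rtol=1e-14))
    pts, eigs = [], []
    for n in roots:
        x = np.array([params.d_p * n / params.k_p, n])
        pts.append(x)
        eigs.append(np.linalg.eigvals(_reduced_jacobian(x, params)))
    cp = CriticalPoints(points=pts, eigenvalues=eigs)
    stable = [i for i, e in enumerate(eigs) if np.all(e.real < 0)]
    saddles = [i for i, e in enumerate(eigs) if e.real.min() < 0 < e.real.max()]
    if len(stable) == 2 and len(saddles) == 1:
        lo, hi = sorted(stable, key=lambda i: pts[i][1])
        cp.off, cp.on, cp.saddle = pts[lo], pts[hi], pts[saddles[0]]
    elif len(stable) == 1:
        # monostable: label by protein value relative to the mid-range
        if pts[stable[0]][1] < 0.5 * n_max:
            cp.off = pts[stable[0]]
        else:
            cp.on = pts[stable[0]]
    return cp


# ---------------------------------------------------------------------------
# Hamiltonian and geometric action
# ---------------------------------------------------------------------------

def _h_terms(net: ReducedNetwork, x, p):
    a = net.rates(x)
    z = np.clip(net.jumps @ p, -_EXP_CAP, _EXP_CAP)
    e = np.exp(z)
    return a, e


def hamiltonian(x, p, params_or_net, with_grad: bool = False):
    """Freidlin-Wentzell Hamiltonian ``H(x, p)`` (optionally with ``H_p``)."""
    net = params_or_net if isinstance(params_or_net, ReducedNetwork) else reduced_network(params_or_net)
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    a, e = _h_terms(net, x, p)
    H = float(a @ (e - 1.0))
    if not with_grad:
        return H
    Hp = (a * e) @ net.jumps
    return H, Hp


def _inner_momentum_2d(net, x, v, p0=None, tol=1e-11, max_iter=60):
    """Momentum on the H = 0 shell with H_p parallel to v (forward).

    Newton on ``(H, H_p . v_perp)`` from a warm start, falling back to the
    per-coordinate detailed-balance guess ``p_i = ln(death_i / birth_i)``.
    Returns (p, mu) with ``H_p = v / mu``; the zero root (p = 0) is the
    legitimate answer when v points along the drift.
    """
    v = np.asarray(v, dtype=float)
    nv = np.linalg.norm(v)
    if nv == 0.0:
        return np.zeros(2), np.inf
    e_t = v / nv
    e_perp = np.array([-e_t[1], e_t[0]])

    a0 = net.rates(x)
    guesses = []
    if p0 is not None:
        guesses.append(np.asarray(p0, dtype=float))
    # detailed-balance-style guess from the coordinate-paired channels
    with np.errstate(divide="ignore", invalid="ignore"):
        bm, dm, bn, dn = a0
        g = np.array(
            [
                np.log(dm / bm) if bm > 0 and dm > 0 else 0.0,
                np.log(dn / bn) if bn > 0 and dn > 0 else 0.0,
            ]
        )
    guesses.append(g)
    guesses.append(np.zeros(2))

    scale = max(a0.sum(), 1e-300)
    for p in guesses:
        p = p.copy()
        ok = False
        for _ in range(max_iter):
            a = a0
            z = np.clip(net.jumps @ p, -_EXP_CAP, _EXP_CAP)
            e = np.exp(z)
            H = a @ (e - 1.0)
            Hp = (a * e) @ net.jumps
            F = np.array([H, Hp @ e_perp])
            if abs(F[0]) < tol * scale and abs(F[1]) < tol * scale:
                ok = True
                break
            Hpp = (net.jumps.T * (a * e)) @ net.jumps
            Jac = np.vstack([Hp, e_perp @ Hpp])
            det = Jac[0, 0] * Jac[1, 1] - Jac[0, 1] * Jac[1, 0]
            if not np.isfinite(det) or abs(det) < 1e-300:
                break
            step = np.linalg.solve(Jac, F)
            # damped update to stay within the exponent cap
            lim = np.max(np.abs(net.jumps @ step))
            if lim > 5.0:
                step *= 5.0 / lim
            p -= step
        if ok:
            a = a0
            e = np.exp(np.clip(net.jumps @ p, -_EXP_CAP, _EXP_CAP))
            Hp = (a * e) @ net.jumps
            fwd = Hp @ e_t
            if fwd > 0 or np.linalg.norm(p) < 1e-12:
                mu = nv / fwd if fwd > 0 else np.inf
                return p, mu
    raise RuntimeError(f"momentum solve failed at x = {x}, v = {v}")


def _inner_momentum_1d(net, x, v, p0=None, tol=1e-12):
    """Scalar analogue of the constrained momentum solve.

    ``H(x, .)`` is convex with ``H(x, 0) = 0``; the uphill momentum is the
    non-trivial root on the side of ``v``, found by removing the trivial
    root (``H(p)/p``) and bracketing.
    """
    v = float(np.asarray(v).ravel()[0])
    if v == 0.0:
        return np.zeros(1), np.inf
    sgn = 1.0 if v > 0 else -1.0
    a = net.rates(np.asarray(x, dtype=float))
    nu = net.jumps[:, 0]

    def Hp_at(p):
        e = np.exp(np.clip(nu * p, -_EXP_CAP, _EXP_CAP))
        return float((a * e) @ nu)

    b = Hp_at(0.0)
    if b * sgn >= 0.0:
        mu = abs(v) / abs(b) if b != 0.0 else np.inf
        return np.zeros(1), mu  # moving with the drift costs nothing

    def f(s):  # H(s * sgn) / s with the trivial root removed
        e = np.exp(np.clip(nu * s * sgn, -_EXP_CAP, _EXP_CAP))
        return float(a @ (e - 1.0)) / s

    s_lo, s_hi = 1e-9, 1.0
    if f(s_lo) >= 0.0:
        # degenerate double root: the drift (and hence the cost) vanishes
        mu = abs(v) / abs(b) if b != 0.0 else np.inf
        return np.zeros(1), mu
    while f(s_hi) < 0.0 and s_hi < _EXP_CAP:
        s_hi *= 2.0
    if f(s_hi) < 0.0:
        raise RuntimeError(f"no uphill momentum found at x = {x}")
    s = brentq(f, s_lo, s_hi, xtol=1e-14, rtol=1e-14)
    p = s * sgn
    fwd = Hp_at(p) * sgn
    if fwd <= 0:
        raise RuntimeError(f"momentum orientation failed at x = {x}")
    return np.array([p]), abs(v) / fwd


def _inner_momentum(net, x, v, p0=None):
    if net.dim == 1:
        return _inner_momentum_1d(net, x, v, p0)
    return _inner_momentum_2d(net, x, v, p0)


def geometric_action(
    net: ReducedNetwork,
    path: np.ndarray,
    return_grad: bool = False,
    p_warm: Optional[np.ndarray] = None,
):
    """Discrete geometric action of a polyline and (optionally) its gradient.

    The action is ``sum_seg p* . dphi`` with ``p*`` the constrained momentum
    at each segment midpoint.  The gradient with respect to the node
    positions follows from the envelope theorem:
    ``d l / d x = -mu H_x(x, p*)`` and ``d l / d v = p*``.
    """
    path = np.asarray(path, dtype=float)
    k = len(path) - 1
    S = 0.0
    pstars = np.zeros((k, net.dim))
    grad = np.zeros_like(path) if return_grad else None
    for i in range(k):
        v = path[i + 1] - path[i]
        if np.linalg.norm(v) == 0.0:
            continue
        mid = 0.5 * (path[i] + path[i + 1])
        warm = p_warm[i] if p_warm is not None else (pstars[i - 1] if i else None)
        p, mu = _inner_momentum(net, mid, v, p0=warm)
        pstars[i] = p
        S += p @ v
        if return_grad:
            a = net.rates(mid)
            e = np.exp(np.clip(net.jumps @ p, -_EXP_CAP, _EXP_CAP))
            Hx = net.rates_jac(mid).T @ (e - 1.0)
            dl_dx = -(0.0 if not np.isfinite(mu) else mu) * Hx
            grad[i] += 0.5 * dl_dx - p
            grad[i + 1] += 0.5 * dl_dx + p
    if return_grad:
        return S, pstars, grad
    return S, pstars


@dataclass
class ActionPath:
    """A converged minimum-action curve with momenta and accumulated action."""

    phi: np.ndarray  # (n_images, 2)
    p: np.ndarray  # (n_images - 1, 2) momentum per segment
    action: float
    cumulative: np.ndarray  # (n_images,) action accumulated along the curve
    converged: bool
    history: List[float]
    lam: Optional[np.ndarray] = None  # |phi'| / |H_p| per segment

    def constraint_residual(self, net: ReducedNetwork) -> float:
        """max |H| along the path (should vanish on the converged curve)."""
        r = 0.0
        for i in range(len(self.p)):
            mid = 0.5 * (self.phi[i] + self.phi[i + 1])
            a, e = _h_terms(net, mid, self.p[i])
            r = max(r, abs(float(a @ (e - 1.0))) / max(a.sum(), 1e-300))
        return r


def _reparam_arclength(path: np.ndarray) -> np.ndarray:
    d = np.sqrt(((np.diff(path, axis=0)) ** 2).sum(axis=1))
    s = np.concatenate([[0.0], np.cumsum(d)])
    if s[-1] == 0:
        return path.copy()
    s /= s[-1]
    su = np.linspace(0.0, 1.0, len(path))
    out = np.empty_like(path)
    for j in range(path.shape[1]):
        out[:, j] = np.interp(su, s, path[:, j])
    return out


def gmam(
    start: np.ndarray,
    end: np.ndarray,
    params_or_net,
    n_images: int = 100,
    tol: float = 1e-6,
    max_outer: int = 40,
    inner_maxiter: int = 120,
    init_path: Optional[np.ndarray] = None,
) -> ActionPath:
    """Minimum geometric action path from ``start`` to ``end``.

    Outer rounds alternate L-BFGS relaxation of the interior nodes of the
    discrete action with re-parameterisation to uniform arc length;
    convergence is declared when the action changes by less than ``tol``
    (relative) between rounds.  Endpoints are fixed; nodes are constrained to
    the non-negative quadrant.  A deterministic (downhill) connection
    returns an action near zero with the path tracking the flow.
    """
    net = params_or_net if isinstance(params_or_net, ReducedNetwork) else reduced_network(params_or_net)
    if n_images < 32:
        raise ValueError("need at least 32 images")
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    if init_path is None:
        path = np.linspace(0, 1, n_images)[:, None] * (end - start)[None, :] + start[None, :]
    else:
        path = _reparam_arclength(np.asarray(init_path, dtype=float))
    d = net.dim
    history: List[float] = []
    converged = False
    best_S = np.inf
    best_path = path
    stall = 0

    def objective(z):
        full = np.vstack([start, z.reshape(-1, d), end])
        S, _, g = geometric_action(net, full, return_grad=True)
        return S, g[1:-1].ravel()

    for outer in range(max_outer):
        z0 = path[1:-1].ravel()
        res = minimize(
            objective,
            z0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * z0.size,
            options={"maxiter": inner_maxiter, "ftol": 1e-14, "gtol": 1e-12},
        )
        path = np.vstack([start, res.x.reshape(-1, d), end])
        path = _reparam_arclength(path)
        S, _ = geometric_action(net, path)
        history.append(float(S))
        # progress is measured against the best action seen: once the
        # re-parameterisation-induced wobble dominates, the curve is done
        if S < best_S - tol * max(abs(best_S), 1e-12):
            best_S, best_path, stall = S, path, 0
        else:
            if S < best_S:
                best_S, best_path = S, path
            stall += 1
            if stall >= 3:
                converged = True
                break
    path = best_path
    S, pstars = geometric_action(net, path)
    incr = np.einsum("ij,ij->i", pstars, np.diff(path, axis=0))
    cumulative = np.concatenate([[0.0], np.cumsum(incr)])
    lam = np.empty(len(pstars))
    for i in range(len(pstars)):
        mid = 0.5 * (path[i] + path[i + 1])
        a, e = _h_terms(net, mid, pstars[i])
        Hp = (a * e) @ net.jumps
        nv = np.linalg.norm(path[i + 1] - path[i])
        nh = np.linalg.norm(Hp)
        lam[i] = nv / nh if nh > 0 else np.inf
    if not converged:
        warnings.warn(
            f"gMAM did not stall within {max_outer} outer rounds; "
            f"action history tail {history[-3:]}",
            stacklevel=2,
        )
    return ActionPath(
        phi=path, p=pstars, action=float(S), cumulative=cumulative,
        converged=converged, history=history, lam=lam,
    )


# ---------------------------------------------------------------------------
# global quasi-potential
# ---------------------------------------------------------------------------

@dataclass
class QuasiPotential:
    """Global quasi-potential on a rectangular grid with the optimal paths."""

    m_axis: np.ndarray
    n_axis: np.ndarray
    S: np.ndarray  # (len(m_axis), len(n_axis)); NaN where interpolation failed
    path_off_to_on: ActionPath
    path_on_to_off: ActionPath
    saddle_values: Tuple[float, float]  # local actions at the saddle (off, on)
    n_failures: int = 0


def global_quasipotential(
    params: GeneNetworkParams,
    grid_shape: Tuple[int, int] = (40, 40),
    fan_size: int = 16,
    n_images: int = 80,
    tol: float = 1e-5,
) -> QuasiPotential:
    """Assemble the global landscape from the two local quasi-potentials.

    gMAM curves fan out from each attractor towards the box boundary; the
    accumulated local action along every curve is scattered onto the grid by
    linear interpolation.  The two local surfaces are shifted to agree at
    the saddle and the pointwise minimum of the shifted surfaces is the
    glued landscape, zero at each attractor up to the local shift.
    """
    from scipy.interpolate import griddata

    net = reduced_network(params)
    cp = find_critical_points(params)
    if not cp.bistable:
        raise ValueError("global quasi-potential requires a bistable parameter set")
    m_hi = 1.25 * max(cp.on[0], cp.off[0])
    n_hi = 1.25 * max(cp.on[1], cp.off[1])
    m_axis = np.linspace(0.0, m_hi, grid_shape[0])
    n_axis = np.linspace(0.0, n_hi, grid_shape[1])

    # the two optimal switching paths (through the saddle by construction of
    # the minimisation; checked in the test-suite)
    path_up = gmam(cp.off, cp.on, net, n_images=n_images, tol=tol)
    path_dn = gmam(cp.on, cp.off, net, n_images=n_images, tol=tol)

    failures = 0
    surfaces = []
    saddle_vals = []
    for attractor, main_path in ((cp.off, path_up), (cp.on, path_dn)):
        pts = [main_path.phi]
        vals = [main_path.cumulative]
        # fan of boundary targets
        targets = []
        for f in np.linspace(0.08, 0.92, fan_size // 2):
            targets.append(np.array([m_hi, f * n_hi]))
            targets.append(np.array([f * m_hi, n_hi]))
        for tgt in targets[: fan_size]:
            try:
                ap = gmam(attractor, tgt, net, n_images=max(32, n_images // 2),
                          tol=max(tol, 1e-4), max_outer=15)
                pts.append(ap.phi)
                vals.append(ap.cumulative)
            except RuntimeError:
                failures += 1
        P = np.vstack(pts)
        V = np.concatenate(vals)
        MM, NN = np.meshgrid(m_axis, n_axis, indexing="ij")
        Sloc = griddata(P, V, (MM, NN), method="linear")
        outside = np.isnan(Sloc)
        if outside.any():
            # nodes outside the convex hull of the fan: nearest-value fill
            Sloc[outside] = griddata(P, V, (MM[outside], NN[outside]),
                                     method="nearest")
        surfaces.append(Sloc)
        # local action at the saddle from the main path
        i_sad = np.argmin(np.linalg.norm(main_path.phi - cp.saddle, axis=1))
        saddle_vals.append(float(main_path.cumulative[i_sad]))

    s_off, s_on = surfaces
    v_off, v_on = saddle_vals
    # stick: shift the on-surface so both assign the saddle the same value,
    # take the pointwise minimum, and re-zero at the global minimum (the
    # deeper attractor; the shallower one remains a local minimum at the
    # action difference of the two uphill branches)
    s_on_shifted = s_on + (v_off - v_on)
    with np.errstate(invalid="ignore"):
        S = np.where(
            np.isnan(s_off), s_on_shifted,
            np.where(np.isnan(s_on_shifted), s_off, np.minimum(s_off, s_on_shifted)),
        )
    finite = np.isfinite(S)
    if finite.any():
        S = S - S[finite].min()
    return QuasiPotential(
        m_axis=m_axis, n_axis=n_axis, S=S,
        path_off_to_on=path_up, path_on_to_off=path_dn,
        saddle_values=(v_off, v_on), n_failures=failures,
    )
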