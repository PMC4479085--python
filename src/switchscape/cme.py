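"""Truncated chemical-master-equation engine.

The CME lives on the lattice ``(alpha, m, n)`` with ``alpha`` the gene state,
``m < M`` mRNA and ``n < N`` protein copies.  Truncation is *reflecting*:
jumps that would leave the grid are suppressed, so probability is conserved
exactly and the adequacy of the grid is certified a posteriori by the mass
sitting on the outermost shells.

Two stationary solvers are provided behind :func:`steady_state`:

* a generic sparse null-space solve (replace one balance equation by the
  normalisation) for small lattices -- this is the brute-force reference;
* a level-reduction (censoring) recursion that exploits the block-tridiagonal
  structure of the generator in the protein coordinate.  Eliminating protein
  levels from the top produces the exact censored generator on the levels
  below; one backward sweep then reconstructs the full stationary law.  Cost
  is one dense ``2M x 2M`` inversion per protein level, memory one float32
  ``2M x 2M`` block per level, which keeps million-state lattices tractable.

The module also computes the potential ``U(m, n) = -ln P(m, n)``, KL
divergences between lattice distributions, and mean first-passage times
(generic linear solve on small lattices, block-tridiagonal sweep between
protein half-planes on large ones).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.linalg import inv, lu_factor, lu_solve

from .params import GeneNetworkParams, occupancy

__all__ = [
    "TruncationGrid",
    "JointDistribution",
    "Landscape",
    "auto_grid",
    "build_generator",
    "steady_state",
    "landscape",
    "kl_divergence",
    "mean_first_passage",
    "basin_mfpt",
    "TruncationError",
]


class TruncationError(RuntimeError):
    """Raised when the stationary mass on the outer shells exceeds tolerance."""


@dataclass(frozen=True)
class TruncationGrid:
    """Exclusive upper bounds of the truncated lattice: ``m < M``, ``n < N``."""

    M: int
    N: int
    mass_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.M < 2 or self.N < 2:
            raise ValueError("truncation bounds must be at least 2")

    @property
    def n_states(self) -> int:
        return 2 * self.M * self.N

    def state_index(self, alpha, m, n):
        """Flat index; protein level is the outermost (slowest) coordinate."""
        return (np.asarray(n) * self.M + np.asarray(m)) * 2 + np.asarray(alpha)


def auto_grid(
    params: GeneNetworkParams,
    mrna_factor: float = 2.5,
    protein_factor: float = 1.8,
    mass_tol: float = 1e-8,
) -> TruncationGrid:
    """Truncation bounds from the deterministic fixed points.

    The cutoffs are ``mrna_factor`` / ``protein_factor`` times the largest
    deterministic fixed-point copy numbers (the open-layer rate-equation
    fixed point, which dominates the adiabatically reduced one), with an
    additive fluctuation floor of eight standard deviations estimated from
    the linear-noise Fano factors -- the multiplicative margin alone is too
    thin when copy numbers are small.  :func:`steady_state` certifies
    adequacy a posteriori through the boundary-mass check.
    """
    from .slow import layer_fixed_point

    m1, n1 = layer_fixed_point(1, params)
    fano_n = 1.0 + params.k_p / (params.d_r + params.d_p)
    M = int(np.ceil(m1 + max((mrna_factor - 1.0) * m1, 10.0 * np.sqrt(2.0 * m1 + 4.0))))
    N = int(np.ceil(n1 + max((protein_factor - 1.0) * n1, 10.0 * np.sqrt(fano_n * n1 + 4.0))))
    return TruncationGrid(M=max(M, 4), N=max(N, 4), mass_tol=mass_tol)


@dataclass
class JointDistribution:
    """Stationary probability table ``P[alpha, m, n]`` on a truncation grid."""

    grid: TruncationGrid
    values: np.ndarray  # shape (2, M, N)
    residual: float = np.nan  # max |Q p| relative to the largest outflow rate

    def __post_init__(self) -> None:
        expect = (2, self.grid.M, self.grid.N)
        if self.values.shape != expect:
            raise ValueError(f"values must have shape {expect}")
        if np.any(self.values < 0):
            raise ValueError("probabilities must be non-negative")
        tot = self.values.sum()
        if abs(tot - 1.0) > 1e-10:
            raise ValueError(f"total mass {tot} deviates from 1")

    # -- marginals ---------------------------------------------------------
    def marginal_mn(self) -> np.ndarray:
        """P(m, n) = P0 + P1, shape (M, N)."""
        return self.values.sum(axis=0)

    def gene_marginal(self) -> np.ndarray:
        """(P(alpha=0), P(alpha=1))."""
        return self.values.sum(axis=(1, 2))

    def protein_marginal(self) -> np.ndarray:
        return self.values.sum(axis=(0, 1))

    def mrna_marginal(self) -> np.ndarray:
        return self.values.sum(axis=(0, 2))

    def boundary_mass(self) -> float:
        """Mass on the outermost mRNA and protein shells."""
        v = self.values
        return float(v[:, -1, :].sum() + v[:, :, -1].sum())

    def basin_masses(self, n_split: int) -> Tuple[float, float]:
        """(mass with n <= n_split, mass with n > n_split)."""
        pn = self.protein_marginal()
        return float(pn[: n_split + 1].sum()), float(pn[n_split + 1 :].sum())

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw joint (alpha, m, n) samples; returns an array (size, 3)."""
        p = self.values.ravel()
        idx = rng.choice(p.size, size=size, p=p / p.sum())
        a, m, n = np.unravel_index(idx, self.values.shape)
        return np.column_stack([a, m, n]).astype(np.int64)


@dataclass
class Landscape:
    """Potential U(m, n) = -ln max(P, floor) over the marginal distribution."""

    grid: TruncationGrid
    U: np.ndarray  # shape (M, N)
    floor: float


# ---------------------------------------------------------------------------
# generator construction (sparse, column convention)
# ---------------------------------------------------------------------------

def _rate_arrays(params: GeneNetworkParams, grid: TruncationGrid):
    """Vectorised propensities on the full lattice, shape (2, M, N) each."""
    M, N = grid.M, grid.N
    a = np.arange(2)[:, None, None]
    m = np.arange(M)[None, :, None].astype(float)
    n = np.arange(N)[None, None, :].astype(float)
    o = occupancy(np.arange(N).astype(float), params)[None, None, :]
    open_ = a == 1
    r = np.zeros((6, 2, M, N))
    r[0] = np.where(open_, params.d_g, 0.0)
    r[1] = np.where(~open_, params.k_g * o + params.k_g0, 0.0)
    r[2] = np.where(open_, params.k_r * o + params.k_r0, 0.0)
    r[3] = params.k_p * m * np.ones_like(r[0])
    r[4] = params.d_r * m * np.ones_like(r[0])
    r[5] = params.d_p * n * np.ones_like(r[0])
    return r


def build_generator(params: GeneNetworkParams, grid: TruncationGrid) -> sp.csc_matrix:
    """Sparse CME generator ``A`` with ``dp/dt = A p`` (columns sum to zero).

    Off-diagonal entry ``A[i, j]`` is the propensity of the jump ``j -> i``;
    jumps leaving the grid are suppressed (reflecting truncation).
    """
    M, N = grid.M, grid.N
    a = np.arange(2)[:, None, None]
    m = np.arange(M)[None, :, None]
    n = np.arange(N)[None, None, :]
    A, Mm, Nn = np.broadcast_arrays(a, m, n)
    A, Mm, Nn = A.ravel(), Mm.ravel(), Nn.ravel()
    src = grid.state_index(A, Mm, Nn)
    rates = _rate_arrays(params, grid).reshape(6, -1)

    changes = [
        # (mask of applicable states, destination index)
        (A == 1, lambda: grid.state_index(0, Mm, Nn)),
        (A == 0, lambda: grid.state_index(1, Mm, Nn)),
        ((A == 1) & (Mm < M - 1), lambda: grid.state_index(A, Mm + 1, Nn)),
        (Nn < N - 1, lambda: grid.state_index(A, Mm, Nn + 1)),
        (Mm > 0, lambda: grid.state_index(A, Mm - 1, Nn)),
        (Nn > 0, lambda: grid.state_index(A, Mm, Nn - 1)),
    ]
    rows, cols, vals = [], [], []
    for j, (mask, dst_fn) in enumerate(changes):
        mask = mask & (rates[j] > 0)
        rows.append(dst_fn()[mask])
        cols.append(src[mask])
        vals.append(rates[j][mask])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    ns = grid.n_states
    Q = sp.coo_matrix((vals, (rows, cols)), shape=(ns, ns)).tocsc()
    Q = (Q - sp.diags(np.asarray(Q.sum(axis=0)).ravel())).tocsc()
    return Q


# ---------------------------------------------------------------------------
# level blocks (row convention, used by the large-lattice solvers)
# ---------------------------------------------------------------------------

def _local_block(params: GeneNetworkParams, grid: TruncationGrid, n: int) -> np.ndarray:
    """Row-convention generator block within protein level ``n``.

    Inner index ``i = 2*m + alpha``.  The diagonal carries the full outflow,
    including the protein birth/death rates that leave the level (suppressed
    at the reflecting boundaries).
    """
    M, N = grid.M, grid.N
    W = 2 * M
    o = occupancy(float(n), params)
    L = np.zeros((W, W))
    idx = np.arange(M)
    L[2 * idx, 2 * idx + 1] = params.k_g * o + params.k_g0  # activation
    L[2 * idx + 1, 2 * idx] = params.d_g  # inactivation
    if M > 1:
        L[2 * idx[:-1] + 1, 2 * idx[:-1] + 3] = params.k_r * o + params.k_r0
        L[2 * idx[1:], 2 * idx[1:] - 2] = params.d_r * idx[1:]
        L[2 * idx[1:] + 1, 2 * idx[1:] - 1] = params.d_r * idx[1:]
    out = L.sum(axis=1)
    if n < N - 1:
        out = out + params.k_p * np.repeat(idx, 2)  # protein birth leaves level
    if n > 0:
        out = out + params.d_p * n  # protein death leaves level
    L[np.arange(W), np.arange(W)] -= out
    return L


def _up_diag(params: GeneNetworkParams, grid: TruncationGrid) -> np.ndarray:
    """Diagonal of the level-up coupling (protein birth, rate k_p * m)."""
    return params.k_p * np.repeat(np.arange(grid.M), 2).astype(float)


def _apply_generator_levels(params, grid, p):
    """Row-convention action p @ Q computed level by level; p shape (N, 2M)."""
    N = grid.N
    up = _up_diag(params, grid)
    r = np.zeros_like(p)
    for n in range(N):
        r[n] += p[n] @ _local_block(params, grid, n)
        if n < N - 1:
            r[n + 1] += p[n] * up
        if n > 0:
            r[n - 1] += p[n] * (params.d_p * n)
    return r


def _steady_state_censoring(params, grid) -> np.ndarray:
    """Stationary law by protein-level censoring; returns pi shape (N, 2M)."""
    M, N = grid.M, grid.N
    W = 2 * M
    up = _up_diag(params, grid)
    R = np.empty((N - 1, W, W), dtype=np.float32)
    S = _local_block(params, grid, N - 1)
    for n in range(N - 2, -1, -1):
        Sinv = inv(-S)
        Rn = up[:, None] * Sinv
        R[n] = Rn
        S = _local_block(params, grid, n) + params.d_p * (n + 1) * Rn
    # S is now the exact censored generator on level 0; solve pi0 S = 0
    Q0 = S.copy()
    Q0[:, 0] = 1.0
    b = np.zeros(W)
    b[0] = 1.0
    pi = np.empty((N, W))
    pi[0] = np.linalg.solve(Q0.T, b)
    for n in range(N - 1):
        pi[n + 1] = pi[n] @ R[n]
    pi = np.maximum(pi, 0.0)
    pi /= pi.sum()
    return pi


def _steady_state_sparse(params, grid, tol) -> np.ndarray:
    Q = build_generator(params, grid)
    ns = grid.n_states
    B = Q.tolil()
    B[0, :] = 1.0
    b = np.zeros(ns)
    b[0] = 1.0
    p = spla.spsolve(B.tocsc(), b)
    p = np.maximum(p, 0.0)
    p /= p.sum()
    return p.reshape(grid.N, 2 * grid.M)


def steady_state(
    params: GeneNetworkParams,
    grid: Optional[TruncationGrid] = None,
    method: Literal["auto", "sparse", "censoring"] = "auto",
    residual_tol: Optional[float] = None,
    check_boundary: bool = True,
) -> JointDistribution:
    """Stationary distribution of the truncated CME.

    Parameters
    ----------
    grid : truncation bounds; computed by :func:`auto_grid` when omitted.
    method : "sparse" replaces one balance equation with the normalisation
        and solves directly (small lattices); "censoring" runs the
        level-reduction recursion; "auto" switches on lattice size.
    residual_tol : bound on ``max |Q p|`` relative to the largest outflow
        rate times the largest probability.  Defaults to 1e-10 for the
        double-precision sparse solve and 1e-7 for the censoring recursion,
        whose back-substitution factors are stored in single precision.
    check_boundary : raise :class:`TruncationError` when the outer-shell
        mass exceeds ``grid.mass_tol``.
    """
    if grid is None:
        grid = auto_grid(params)
    if method == "auto":
        method = "sparse" if grid.n_states <= 60_000 else "censoring"
    if residual_tol is None:
        residual_tol = 1e-10 if method == "sparse" else 1e-7
    if method == "sparse":
        pi = _steady_state_sparse(params, grid, residual_tol)
    elif method == "censoring":
        pi = _steady_state_censoring(params, grid)
    else:
        raise ValueError(f"unknown method {method!r}")

    res = np.abs(_apply_generator_levels(params, grid, pi)).max()
    scale = _max_outflow(params, grid) * pi.max()
    rel = float(res / scale)
    if rel > residual_tol:
        raise RuntimeError(
            f"stationary solve residual {rel:.2e} above tolerance {residual_tol:.0e}"
        )
    values = np.moveaxis(pi.reshape(grid.N, grid.M, 2), [0, 1, 2], [2, 1, 0])
    dist = JointDistribution(grid=grid, values=values, residual=rel)
    if check_boundary and dist.boundary_mass() > grid.mass_tol:
        raise TruncationError(
            f"boundary mass {dist.boundary_mass():.2e} exceeds {grid.mass_tol:.0e}; "
            "enlarge the truncation grid"
        )
    return dist


def _max_outflow(params, grid) -> float:
    p = params
    o = occupancy(float(grid.N - 1), p)
    return max(
        p.d_g + p.k_r + p.k_r0,
        p.k_g + p.k_g0,
    ) + p.k_p * (grid.M - 1) + p.d_r * (grid.M - 1) + p.d_p * (grid.N - 1)


# ---------------------------------------------------------------------------
# landscapes and divergences
# ---------------------------------------------------------------------------

def landscape(dist: JointDistribution, floor: float = 1e-16) -> Landscape:
    """Potential U = -ln P over the gene-summed marginal, floored at ``floor``."""
    if not floor > 0:
        raise ValueError("floor must be positive")
    P = np.maximum(dist.marginal_mn(), floor)
    return Landscape(grid=dist.grid, U=-np.log(P), floor=floor)


def kl_divergence(p: np.ndarray, q: np.ndarray, floor: float = 1e-16) -> float:
    """KL(p || q) between two non-negative tables on the same grid.

    Both tables are floored at ``floor`` and renormalised first, which makes
    the divergence finite even when one table has exact zeros.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("tables must share a shape")
    p = np.maximum(p, floor)
    q = np.maximum(q, floor)
    p = p / p.sum()
    q = q / q.sum()
    return float(np.sum(p * (np.log(p) - np.log(q))))


# ---------------------------------------------------------------------------
# mean first-passage times
# ---------------------------------------------------------------------------

def mean_first_passage(
    generator: sp.spmatrix,
    source_set: Sequence[int],
    target_set: Sequence[int],
    source_dist: Optional[np.ndarray] = None,
) -> float:
    """Mean first-passage time from a source set into a target set.

    Solves the linear system ``(Q^T tau)_i = -1`` over non-target states
    (``Q`` in column convention, so ``Q^T`` acts on expectations) with
    ``tau = 0`` on the target.  Returns the expectation of ``tau`` over
    ``source_dist`` (uniform over ``source_set`` by default; a point start
    is a single-element source set).
    """
    source_set = np.asarray(list(source_set), dtype=np.int64)
    target_set = np.asarray(list(target_set), dtype=np.int64)
    if source_set.size == 0 or target_set.size == 0:
        raise ValueError("source and target sets must be non-empty")
    if np.intersect1d(source_set, target_set).size:
        # hitting time from inside the target is zero
        if np.all(np.isin(source_set, target_set)):
            return 0.0
        raise ValueError("source and target sets must be disjoint")
    ns = generator.shape[0]
    keep = np.ones(ns, dtype=bool)
    keep[target_set] = False
    idx = np.flatnonzero(keep)
    QT = generator.T.tocsr()
    A = QT[idx][:, idx]
    rhs = -np.ones(idx.size)
    tau = spla.spsolve(A.tocsc(), rhs)
    if not np.all(np.isfinite(tau)):
        raise RuntimeError("first-passage system is singular (target unreachable?)")
    full = np.zeros(ns)
    full[idx] = tau
    if source_dist is None:
        return float(full[source_set].mean())
    w = np.asarray(source_dist, dtype=float)
    w = w / w.sum()
    return float(np.dot(w, full[source_set]))


def _block_mfpt(params, grid, levels, eliminate_from_top: bool) -> np.ndarray:
    """Solve Q_rr tau = -1 on a contiguous protein-level range (row conv.).

    Returns tau with shape (len(levels), 2M).  The absorbing complement is
    whatever lies beyond the range boundary that has open coupling.
    """
    M, N = grid.M, grid.N
    W = 2 * M
    up = _up_diag(params, grid)
    nlev = len(levels)
    Gam = np.empty((nlev, W, W), dtype=np.float32)
    y = np.empty((nlev, W))
    rhs = -np.ones(W)
    if not eliminate_from_top:
        # Thomas sweep upward: levels ascending
        lu = lu_factor(_local_block(params, grid, levels[0]))
        Gam[0] = lu_solve(lu, np.diag(up))
        y[0] = lu_solve(lu, rhs)
        for i in range(1, nlev):
            n = levels[i]
            A = params.d_p * n  # coupling to the level below (scalar x I)
            Bt = _local_block(params, grid, n) - A * Gam[i - 1]
            lu = lu_factor(Bt)
            if i < nlev - 1:
                Gam[i] = lu_solve(lu, np.diag(up))
            y[i] = lu_solve(lu, rhs - A * y[i - 1])
        tau = np.empty((nlev, W))
        tau[-1] = y[-1]
        for i in range(nlev - 2, -1, -1):
            tau[i] = y[i] - Gam[i] @ tau[i + 1]
    else:
        # sweep downward from the top level
        lu = lu_factor(_local_block(params, grid, levels[-1]))
        Gam[-1] = lu_solve(lu, np.eye(W)) * (params.d_p * levels[-1])
        y[-1] = lu_solve(lu, rhs)
        for i in range(nlev - 2, -1, -1):
            n = levels[i]
            Bt = _local_block(params, grid, n) - up[:, None] * Gam[i + 1]
            lu = lu_factor(Bt)
            y[i] = lu_solve(lu, rhs - up * y[i + 1])
            if i > 0:
                Gam[i] = lu_solve(lu, np.eye(W)) * (params.d_p * n)
        tau = np.empty((nlev, W))
        tau[0] = y[0]
        for i in range(1, nlev):
            tau[i] = y[i] - Gam[i] @ tau[i - 1]
    return tau


def basin_mfpt(
    params: GeneNetworkParams,
    grid: TruncationGrid,
    direction: Literal["off_to_on", "on_to_off"],
    n_split: int,
    start: Optional[Tuple[int, int, int]] = None,
) -> float:
    """Mean first-passage time between protein half-plane basins.

    The target basin is ``n > n_split`` (off-to-on) or ``n <= n_split``
    (on-to-off).  ``start`` is ``(alpha, m, n)``; by default the relevant
    deterministic fixed point rounded to the lattice (open-layer or reduced
    system, whichever matches the regime) with the gene open in the on basin
    and closed in the off basin.
    """
    from .fast import find_critical_points
    from .slow import layer_fixed_point

    if not 0 <= n_split < grid.N - 1:
        raise ValueError("n_split must lie inside the grid")
    if start is None:
        cp = find_critical_points(params)
        if params.kappa < 1.0 and cp.on is not None:
            m1, n1 = layer_fixed_point(1, params)
            on_start = (1, int(round(m1)), int(round(n1)))
            off_start = (0, 0, 0)
        else:
            if cp.off is None or cp.on is None:
                raise ValueError("parameter set is not bistable; give start explicitly")
            off_start = (0, int(round(cp.off[0])), int(round(cp.off[1])))
            on_start = (1, int(round(cp.on[0])), int(round(cp.on[1])))
        start = off_start if direction == "off_to_on" else on_start
    alpha, m0, n0 = start
    if direction == "off_to_on":
        levels = list(range(0, n_split + 1))
        tau = _block_mfpt(params, grid, levels, eliminate_from_top=True)
        if not (0 <= n0 <= n_split):
            raise ValueError("start must lie in the source basin")
        return float(tau[n0, 2 * m0 + alpha])
    elif direction == "on_to_off":
        levels = list(range(n_split + 1, grid.N))
        tau = _block_mfpt(params, grid, levels, eliminate_from_top=False)
        if not (n_split < n0 < grid.N):
            raise ValueError("start must lie in the source basin")
        return float(tau[n0 - (n_split + 1), 2 * m0 + alpha])
    raise ValueError(f"unknown direction {direction!r}")
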