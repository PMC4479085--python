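"""Small test fixtures with closed-form or brute-force oracles.

Every fixture is a reduced parameter set small enough for exhaustive
verification, together with the analytic expectation it is checked against.
They are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Optional

import numpy as np

from .cme import TruncationGrid
from .params import GeneNetworkParams

__all__ = ["Fixture", "make_fixture", "FIXTURE_NAMES"]

_TINY = 1e-14  # numerically inert rate standing in for an absent reaction


@dataclass
class Fixture:
    name: str
    params: Optional[GeneNetworkParams]
    grid: Optional[TruncationGrid]
    oracle: Dict[str, object]
    description: str


def _poisson_mrna() -> Fixture:
    # gene effectively pinned open (instant activation, negligible
    # inactivation), feedback off, translation off: mRNA is a linear
    # birth-death process with stationary law Poisson(k_r0 / d_r)
    p = GeneNetworkParams(
        k_g=_TINY, k_g0=1e6, d_g=_TINY, k_r=_TINY, k_r0=8.0,
        k_p=_TINY, d_r=1.0, d_p=1.0, K=1e12,
    )
    lam = p.k_r0 / p.d_r
    from scipy.stats import poisson

    return Fixture(
        name="poisson_mrna",
        params=p,
        grid=TruncationGrid(M=36, N=2),
        oracle={"mrna_mean": lam, "mrna_var": lam, "pmf": lambda k: poisson.pmf(k, lam)},
        description="linear mRNA birth-death; stationary law Poisson(k_r0/d_r)",
    )


def _pure_death(n0: int = 3, d_p: float = 1.0) -> Fixture:
    p = GeneNetworkParams(
        k_g=_TINY, k_g0=_TINY, d_g=_TINY, k_r=_TINY, k_r0=_TINY,
        k_p=_TINY, d_r=1.0, d_p=d_p, K=1e12,
    )
    mfpt = sum(1.0 / (d_p * k) for k in range(1, n0 + 1))
    return Fixture(
        name="pure_death",
        params=p,
        grid=TruncationGrid(M=2, N=n0 + 2),
        oracle={"n0": n0, "mfpt_to_zero": mfpt},
        description="pure protein death from n0; MFPT to 0 is the harmonic sum",
    )


def _two_state_gene() -> Fixture:
    p = GeneNetworkParams(
        k_g=_TINY, k_g0=0.3, d_g=0.7, k_r=_TINY, k_r0=_TINY,
        k_p=_TINY, d_r=1.0, d_p=1.0, K=1e12,
    )
    return Fixture(
        name="two_state_gene",
        params=p,
        grid=TruncationGrid(M=2, N=2),
        oracle={"p_open": p.k_g0 / (p.k_g0 + p.d_g)},
        description="isolated gene flip-flop; P(open) = k_g0/(k_g0+d_g)",
    )


def _tiny_bistable() -> Fixture:
    # a scaled-down two-layer switch (on state near n ~ 26, off at the
    # origin) whose basin first-passage times are tens of time units, so
    # SSA estimates converge within ~1e6 events
    p = GeneNetworkParams(
        k_g=0.5, k_g0=0.05, d_g=0.1, k_r=10.0, k_r0=0.5,
        k_p=5.0, d_r=0.7, d_p=1.4, K=30.0,
    )
    return Fixture(
        name="tiny_bistable",
        params=p,
        grid=TruncationGrid(M=51, N=124),
        oracle={"n_split": 8,
                "check": "cross-validated: sparse null-space vs censoring vs SSA"},
        description="small bistable switch for SSA/CME cross-checks (split at n = 8)",
    )


def _oneD_birth_death(b: float = 20.0, d: float = 1.0) -> Fixture:
    # protein-only birth-death; the quasi-potential between n0 and n1 is
    # the integral of ln(d n / b)
    def action(n0: float, n1: float) -> float:
        f = lambda n: n * (np.log(d * n / b) - 1.0)
        return f(n1) - f(n0)

    return Fixture(
        name="oneD_birth_death",
        params=None,
        grid=None,
        oracle={"b": b, "d": d, "action": action},
        description="1-D birth-death; S'(n) = ln(d n / b) in closed form",
    )


_REGISTRY: Dict[str, Callable[[], Fixture]] = {
    "poisson_mrna": _poisson_mrna,
    "pure_death": _pure_death,
    "two_state_gene": _two_state_gene,
    "tiny_bistable": _tiny_bistable,
    "oneD_birth_death": _oneD_birth_death,
}

FIXTURE_NAMES = tuple(sorted(_REGISTRY))


def make_fixture(name: str) -> Fixture:
    """Build a named fixture together with its oracle expectations."""
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}") from None
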