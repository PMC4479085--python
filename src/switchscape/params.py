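"""Reaction network definition for the two-state positive-feedback circuit.

The model has four species -- the gene in a closed (``alpha = 0``) or open
(``alpha = 1``) chromatin state, mRNA (count ``m``) and protein (count ``n``)
-- coupled by six reactions:

====  =========================  ============================
 #    reaction                   propensity
====  =========================  ============================
 1    gene open -> closed        ``d_g``          (alpha = 1)
 2    gene closed -> open        ``k_g*O_p + k_g0``  (alpha = 0)
 3    transcription (open gene)  ``k_r*O_p + k_r0``  (alpha = 1)
 4    translation                ``k_p * m``
 5    mRNA decay                 ``d_r * m``
 6    protein decay              ``d_p * n``
====  =========================  ============================

``O_p = n**h / (n**h + K**h)`` is the protein occupancy of the regulatory
binding site (Hill exponent ``h``, feedback strength ``K``), which closes the
positive feedback loop: protein promotes both gene activation and
transcription.  All rates are per model time unit; no physical time unit is
assumed.

The adiabaticity parameter ``kappa = d_g / d_p`` compares the gene-state
lifetime with the protein lifetime and is the coordinate along which the
slow (``kappa << 0.01``), intermediate, and fast (``kappa >> 1``) switching
regimes are distinguished.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Dict

import numpy as np

__all__ = [
    "GeneNetworkParams",
    "MicroState",
    "ReactionChannel",
    "CHANNELS",
    "STATE_CHANGES",
    "occupancy",
    "propensities",
    "kappa_family",
    "preset",
    "PRESETS",
]

# state change of each reaction channel as (d_alpha, d_m, d_n), Table order above
STATE_CHANGES = np.array(
    [
        (-1, 0, 0),  # 1 gene inactivation
        (+1, 0, 0),  # 2 gene activation
        (0, +1, 0),  # 3 transcription
        (0, 0, +1),  # 4 translation
        (0, -1, 0),  # 5 mRNA decay
        (0, 0, -1),  # 6 protein decay
    ],
    dtype=np.int64,
)


@dataclass(frozen=True)
class GeneNetworkParams:
    """The nine kinetic constants plus the Hill exponent of the feedback.

    Rates are per model time unit; ``K`` is a copy number.
    """

    k_g: float  # activation gain
    k_g0: float  # basal activation
    d_g: float  # inactivation
    k_r: float  # transcription gain
    k_r0: float  # basal transcription
    k_p: float  # translation rate per mRNA
    d_r: float  # mRNA degradation
    d_p: float  # protein degradation
    K: float  # feedback strength (half-occupancy protein count)
    hill: int = 1  # Hill exponent of the occupancy function

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "hill":
                if int(v) != v or v < 1:
                    raise ValueError("hill must be a positive integer")
            elif not (v > 0 and np.isfinite(v)):
                raise ValueError(f"{f.name} must be strictly positive, got {v!r}")

    @property
    def kappa(self) -> float:
        """Adiabaticity ratio d_g / d_p."""
        return self.d_g / self.d_p

    def with_(self, **kw) -> "GeneNetworkParams":
        return replace(self, **kw)

    def as_dict(self) -> Dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    # tuple consumed by the numba simulation kernels
    def as_tuple(self):
        return (
            self.k_g, self.k_g0, self.d_g, self.k_r, self.k_r0,
            self.k_p, self.d_r, self.d_p, self.K, float(self.hill),
        )


@dataclass(frozen=True)
class MicroState:
    """A lattice state (gene state, mRNA count, protein count)."""

    alpha: int
    m: int
    n: int

    def __post_init__(self) -> None:
        if self.alpha not in (0, 1):
            raise ValueError("alpha must be 0 (closed) or 1 (open)")
        if self.m < 0 or self.n < 0:
            raise ValueError("copy numbers must be non-negative")


@dataclass(frozen=True)
class ReactionChannel:
    index: int  # 1-based, table order
    state_change: tuple
    name: str


CHANNELS = tuple(
    ReactionChannel(i + 1, tuple(STATE_CHANGES[i]), name)
    for i, name in enumerate(
        [
            "gene_inactivation",
            "gene_activation",
            "transcription",
            "translation",
            "mrna_decay",
            "protein_decay",
        ]
    )
)


def occupancy(n, params: GeneNetworkParams):
    """Binding-site occupancy ``O_p = n**h / (n**h + K**h)``.

    Monotone non-decreasing in ``n``; 0 at ``n = 0``; 1/2 at ``n = K``;
    tends to 1 as ``n -> inf``.  Accepts scalars or arrays.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("protein count must be non-negative")
    h = params.hill
    if h == 1:
        out = n / (n + params.K)
    else:
        # evaluate in ratio form to avoid overflow at large n
        r = (n / params.K) ** h
        out = r / (1.0 + r)
    return out if out.ndim else float(out)


def propensities(state: MicroState, params: GeneNetworkParams) -> np.ndarray:
    """Six-channel propensity vector at a micro-state (table order)."""
    o = occupancy(state.n, params)
    open_ = state.alpha == 1
    return np.array(
        [
            params.d_g if open_ else 0.0,
            0.0 if open_ else params.k_g * o + params.k_g0,
            params.k_r * o + params.k_r0 if open_ else 0.0,
            params.k_p * state.m,
            params.d_r * state.m,
            params.d_p * state.n,
        ]
    )


def kappa_family(kappa: float, base: GeneNetworkParams) -> GeneNetworkParams:
    """Rescale the gene-switching rates to a target adiabaticity ``kappa``.

    ``d_g`` is set to ``kappa * d_p`` and the activation rates are rescaled so
    the ratios ``d_g/k_g`` and ``d_g/k_g0`` keep their base values; everything
    else is untouched.  This is the one-parameter family along which the
    switching-time sweeps and the sorting experiments move.
    """
    if not kappa > 0:
        raise ValueError("kappa must be positive")
    r_g = base.d_g / base.k_g
    r_g0 = base.d_g / base.k_g0
    d_g = kappa * base.d_p
    return base.with_(d_g=d_g, k_g=d_g / r_g, k_g0=d_g / r_g0)


#: Reference parameter sets.  "slow" is the non-adiabatic corner
#: (kappa = 0.001); "fast" keeps everything but the three gene-switching
#: rates, which are scaled up 1e5-fold (kappa = 100).
PRESETS: Dict[str, GeneNetworkParams] = {
    "slow": GeneNetworkParams(
        k_g=0.028, k_g0=0.00028, d_g=0.0014,
        k_r=100.0, k_r0=0.1, k_p=51.5, d_r=0.7, d_p=1.4, K=3000.0,
    ),
}
PRESETS["fast"] = PRESETS["slow"].with_(d_g=140.0, k_g=2800.0, k_g0=28.0)


def preset(name: str) -> GeneNetworkParams:
    """Look up a named reference parameter set ("slow" or "fast")."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
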