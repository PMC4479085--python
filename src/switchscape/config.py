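"""Run configuration: YAML loading, validation, and serialisation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .cme import TruncationGrid
from .params import GeneNetworkParams, preset

__all__ = ["RunConfig", "ConfigError", "load_config"]

_PARAM_FIELDS = {"k_g", "k_g0", "d_g", "k_r", "k_r0", "k_p", "d_r", "d_p", "K", "hill"}
_TOP_KEYS = {"preset", "params", "kappa", "grid", "seed", "experiment", "out_dir"}
_GRID_KEYS = {"M", "N", "mass_tol"}
_EXP_KEYS = {"threshold", "cohort", "record_times", "replicates",
             "kappa_multipliers", "horizon"}


class ConfigError(ValueError):
    """Schema violation in a run configuration."""


@dataclass
class RunConfig:
    """Validated, fully serialisable description of a run."""

    params: GeneNetworkParams
    grid: Optional[TruncationGrid] = None
    seed: int = 0
    threshold: int = 400
    cohort: int = 50_000
    replicates: int = 10
    record_times: Optional[list] = None
    kappa_multipliers: list = field(default_factory=lambda: [10.0])
    horizon: Optional[float] = None
    out_dir: str = "."

    def to_dict(self) -> dict:
        d = {
            "params": self.params.as_dict(),
            "seed": self.seed,
            "experiment": {
                "threshold": self.threshold,
                "cohort": self.cohort,
                "replicates": self.replicates,
                "record_times": self.record_times,
                "kappa_multipliers": self.kappa_multipliers,
                "horizon": self.horizon,
            },
            "out_dir": self.out_dir,
        }
        if self.grid is not None:
            d["grid"] = {"M": self.grid.M, "N": self.grid.N,
                         "mass_tol": self.grid.mass_tol}
        return d

    def digest(self) -> str:
        """Stable hash of the resolved configuration."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _require_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    The parameter set comes either from ``preset`` (optionally rescaled by
    ``kappa``) or from an explicit ``params`` mapping containing all nine
    rates; unknown keys anywhere are rejected with field-level messages.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _require_keys(raw, _TOP_KEYS, "config")

    if ("preset" in raw) == ("params" in raw):
        raise ConfigError("give exactly one of 'preset' or 'params'")
    if "preset" in raw:
        try:
            params = preset(raw["preset"])
        except KeyError as e:
            raise ConfigError(str(e)) from None
    else:
        pd = dict(raw["params"])
        _require_keys(pd, _PARAM_FIELDS, "params")
        missing = _PARAM_FIELDS - {"hill"} - set(pd)
        if missing:
            raise ConfigError(f"missing required rate(s): {sorted(missing)}")
        try:
            params = GeneNetworkParams(**pd)
        except ValueError as e:
            raise ConfigError(str(e)) from None
    if "kappa" in raw:
        from .params import kappa_family

        params = kappa_family(float(raw["kappa"]), params)

    grid = None
    if "grid" in raw:
        gd = dict(raw["grid"])
        _require_keys(gd, _GRID_KEYS, "grid")
        if "M" not in gd or "N" not in gd:
            raise ConfigError("grid requires both M and N")
        grid = TruncationGrid(**gd)

    kw = {}
    if "experiment" in raw:
        ed = dict(raw["experiment"])
        _require_keys(ed, _EXP_KEYS, "experiment")
        kw.update(ed)
    return RunConfig(
        params=params,
        grid=grid,
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", ".")),
        **kw,
    )
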