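"""Result serialisation: delimited tables, JSON records, HDF5 grids.

Every file carries a metadata header (tool version, config digest, seed) so
results are traceable; files are bit-stable given fixed inputs and seeds.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .cme import JointDistribution, Landscape, TruncationGrid

__all__ = [
    "export_table",
    "read_table",
    "export_json",
    "export_distribution",
    "read_distribution",
    "export_landscape",
]


def _meta(seed: Optional[int], digest: Optional[str]) -> dict:
    return {
        "tool": "switchscape",
        "version": __version__,
        "seed": seed,
        "config_digest": digest,
    }


def export_table(df: pd.DataFrame, path, seed: Optional[int] = None,
                 digest: Optional[str] = None) -> Path:
    """CSV with '#'-prefixed metadata header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in _meta(seed, digest).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def export_json(record: dict, path, seed: Optional[int] = None,
                digest: Optional[str] = None) -> Path:
    path = Path(path)
    payload = {"meta": _meta(seed, digest), **record}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))
    return path


def export_distribution(dist: JointDistribution, path, seed: Optional[int] = None,
                        digest: Optional[str] = None) -> Path:
    """HDF5 grid file with per-layer tables and axis metadata."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("P0", data=dist.values[0], compression="gzip")
        f.create_dataset("P1", data=dist.values[1], compression="gzip")
        f.attrs["axis0"] = "mRNA count m"
        f.attrs["axis1"] = "protein count n"
        f.attrs["M"] = dist.grid.M
        f.attrs["N"] = dist.grid.N
        f.attrs["mass_tol"] = dist.grid.mass_tol
        f.attrs["residual"] = dist.residual
        for k, v in _meta(seed, digest).items():
            if v is not None:
                f.attrs[k] = v
    return path


def read_distribution(path) -> JointDistribution:
    with h5py.File(path, "r") as f:
        grid = TruncationGrid(M=int(f.attrs["M"]), N=int(f.attrs["N"]),
                              mass_tol=float(f.attrs["mass_tol"]))
        values = np.stack([f["P0"][...], f["P1"][...]])
        residual = float(f.attrs.get("residual", np.nan))
    return JointDistribution(grid=grid, values=values, residual=residual)


def export_landscape(ls: Landscape, path, seed: Optional[int] = None,
                     digest: Optional[str] = None) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("U", data=ls.U, compression="gzip")
        f.attrs["axis0"] = "mRNA count m"
        f.attrs["axis1"] = "protein count n"
        f.attrs["floor"] = ls.floor
        for k, v in _meta(seed, digest).items():
            if v is not None:
                f.attrs[k] = v
    return path
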