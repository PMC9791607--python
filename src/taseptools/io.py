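"""Writers and readers for profile tables and run metadata.

All outputs are plain delimited text (tab-separated, full float precision) so
results diff cleanly under version control.  Every table is paired with a
JSON metadata record (``<table>.meta.json``) holding the command, parameters,
seed, package version, timestamp and the table's SHA-256 checksum — enough to
reproduce the file exactly.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .lattice import SimResult

__all__ = ["write_profile_table", "read_profile_table", "read_metadata", "sim_result_table"]


def sim_result_table(result: SimResult) -> pd.DataFrame:
    """Tabulate a Monte Carlo result: site, rho, rho_se, J_bond, C_nn.

    Bond quantities are attached to their left site; an open chain has L-1
    bonds, so its last row carries NaNs there.
    """
    L = result.params.L
    nb = result.params.n_bonds

    def padded(arr: np.ndarray) -> np.ndarray:
        out = np.full(L, np.nan)
        out[:nb] = arr
        return out

    return pd.DataFrame(
        {
            "site": np.arange(1, L + 1),
            "rho": result.rho,
            "rho_se": result.rho_se,
            "J_bond": padded(result.J_bond),
            "J_bond_se": padded(result.J_bond_se),
            "C_nn": padded(result.C_nn),
        }
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_profile_table(
    path: str | Path,
    table: pd.DataFrame | Mapping[str, Any],
    meta: Mapping[str, Any] | None = None,
) -> Path:
    """Write a tab-separated table plus its metadata record; returns the table path."""
    path = Path(path)
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(dict(table))
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
    record = {
        "version": __version__,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "output": path.name,
        "sha256": _sha256(path),
        "rows": int(table.shape[0]),
    }
    if meta:
        record.update(meta)
    meta_path = path.with_name(path.name + ".meta.json")
    meta_path.write_text(json.dumps(record, indent=2, default=str) + "\n")
    return path


def read_profile_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_metadata(path: str | Path) -> dict[str, Any]:
    """Load the metadata record paired with a table file."""
    path = Path(path)
    return json.loads(path.with_name(path.name + ".meta.json").read_text())
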