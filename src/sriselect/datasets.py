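"""Bundled benchmark data.

``benchmark_sri.csv`` holds SRI vectors for six structurally diverse
proteins (PDB entries 1ao6, 1new, 1ro3, 2vb1, 2h8b, 1a3n): for each, the
SRI predicted from heat-denatured-aggregate micrographs, the SRI
calculated from the deposited structure, and the SRI calculated from
five homology models. It is the standing regression fixture for the
model-selection stage.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["load_benchmark_sri", "benchmark_proteins", "benchmark_vectors"]

_SRI_COLS = [f"sri_{k}" for k in range(1, 9)]


def load_benchmark_sri() -> pd.DataFrame:
    """The benchmark SRI table as a DataFrame."""
    with resources.files("sriselect.data").joinpath("benchmark_sri.csv").open() as fh:
        df = pd.read_csv(fh)
    df["model"] = df["model"].astype("Int64")
    return df


def benchmark_proteins() -> list[str]:
    return list(load_benchmark_sri()["protein"].unique())


def benchmark_vectors(protein: str) -> dict:
    """SRI vectors of one benchmark protein.

    Returns a dict with keys ``predicted`` and ``calculated`` (8-vectors)
    and ``models`` (label → 8-vector, labels "1".."5").
    """
    df = load_benchmark_sri()
    sub = df[df["protein"] == protein]
    if sub.empty:
        raise KeyError(f"unknown benchmark protein {protein!r}")

    def _vec(rows: pd.DataFrame) -> np.ndarray:
        return rows[_SRI_COLS].to_numpy(dtype=float)[0]

    return {
        "pdb_id": sub["pdb_id"].iloc[0],
        "predicted": _vec(sub[sub["role"] == "predicted"]),
        "calculated": _vec(sub[sub["role"] == "calculated_reference"]),
        "models": {
            str(int(row["model"])): row[_SRI_COLS].to_numpy(dtype=float)
            for _, row in sub[sub["role"] == "calculated_model"].iterrows()
        },
    }
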