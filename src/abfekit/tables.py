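"""Delimited-text serialisation of the package's tabular objects.

Two dialects for reduced-potential tables:

* *long*: one row per (sample, evaluation window) with columns
  ``window_id, replicate_id, sample_index, evaluated_at_window,
  reduced_potential``;
* *wide*: one row per sample with columns ``window_id, replicate_id,
  sample_index`` plus one ``u_at_<window>`` column per window.

CV sample files carry ``window_id, frame, cv1, cv2``; FES grids are
written as a flat delimited table of bin centres and free energies plus a
JSON sidecar with the exact edges, temperature and coverage.
All files are plain text (TSV) and round-trip bit-stably through pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import ReducedPotentialTable
from .fes import CVSampleSet, FESGrid

__all__ = [
    "table_to_long",
    "long_to_table",
    "table_to_wide",
    "wide_to_table",
    "write_cv_samples",
    "read_cv_samples",
    "write_fes_grid",
    "read_fes_grid",
]

SEP = "\t"


def _window_labels(table: ReducedPotentialTable) -> list[str]:
    if table.window_ids:
        return list(table.window_ids)
    return [f"w{k:03d}" for k in range(table.n_windows)]


def table_to_long(table: ReducedPotentialTable, replicate_id: int = 0) -> pd.DataFrame:
    labels = _window_labels(table)
    source = np.repeat(np.arange(table.n_windows), table.n_k)
    sample_index = np.concatenate([np.arange(n) for n in table.n_k])
    rows = {
        "window_id": np.tile([labels[s] for s in source], table.n_windows),
        "replicate_id": replicate_id,
        "sample_index": np.tile(sample_index, table.n_windows),
        "evaluated_at_window": np.repeat(labels, table.n_samples),
        "reduced_potential": table.u.ravel(),
    }
    return pd.DataFrame(rows)


def long_to_table(df: pd.DataFrame) -> ReducedPotentialTable:
    labels = list(dict.fromkeys(df["evaluated_at_window"]))
    order = {w: i for i, w in enumerate(labels)}
    df = df.copy()
    df["_src"] = df["window_id"].map(order)
    df["_eval"] = df["evaluated_at_window"].map(order)
    df = df.sort_values(["_eval", "_src", "sample_index"], kind="stable")
    n_windows = len(labels)
    n_samples = len(df) // n_windows
    u = df["reduced_potential"].to_numpy().reshape(n_windows, n_samples)
    one_eval = df[df["_eval"] == 0]
    n_k = one_eval.groupby("_src").size().reindex(range(n_windows), fill_value=0)
    return ReducedPotentialTable(u=u, n_k=n_k.to_numpy(), window_ids=tuple(labels))


def table_to_wide(table: ReducedPotentialTable, replicate_id: int = 0) -> pd.DataFrame:
    labels = _window_labels(table)
    source = np.repeat(np.arange(table.n_windows), table.n_k)
    df = pd.DataFrame(
        {
            "window_id": [labels[s] for s in source],
            "replicate_id": replicate_id,
            "sample_index": np.concatenate([np.arange(n) for n in table.n_k]),
        }
    )
    for k, lab in enumerate(labels):
        df[f"u_at_{lab}"] = table.u[k]
    return df


def wide_to_table(df: pd.DataFrame) -> ReducedPotentialTable:
    u_cols = [c for c in df.columns if c.startswith("u_at_")]
    labels = [c[len("u_at_") :] for c in u_cols]
    order = {w: i for i, w in enumerate(labels)}
    df = df.copy()
    df["_src"] = df["window_id"].map(order)
    df = df.sort_values(["_src", "sample_index"], kind="stable")
    u = df[u_cols].to_numpy().T
    n_k = df.groupby("_src").size().reindex(range(len(labels)), fill_value=0)
    return ReducedPotentialTable(u=u, n_k=n_k.to_numpy(), window_ids=tuple(labels))


def write_cv_samples(samples: CVSampleSet, path: str | Path) -> None:
    frames = []
    for w, xy in enumerate(samples.samples):
        frames.append(
            pd.DataFrame(
                {
                    "window_id": w,
                    "frame": np.arange(xy.shape[0]),
                    "cv1": xy[:, 0],
                    "cv2": xy[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep=SEP, index=False)


def read_cv_samples(
    path: str | Path,
    bias_centers: tuple[tuple[float, float], ...],
    spring_constant: float,
) -> CVSampleSet:
    df = pd.read_csv(path, sep=SEP, float_precision="round_trip")
    samples = []
    for w in range(len(bias_centers)):
        sub = df[df["window_id"] == w].sort_values("frame")
        samples.append(sub[["cv1", "cv2"]].to_numpy())
    return CVSampleSet(
        samples=tuple(samples),
        bias_centers=bias_centers,
        spring_constant=spring_constant,
    )


def write_fes_grid(grid: FESGrid, path: str | Path) -> None:
    path = Path(path)
    c1, c2 = np.meshgrid(grid.centers1, grid.centers2, indexing="ij")
    pd.DataFrame(
        {
            "cv1_center": c1.ravel(),
            "cv2_center": c2.ravel(),
            "free_energy_kcal_mol": grid.free_energy.ravel(),
            "visited": grid.visited.ravel().astype(int),
        }
    ).to_csv(path, sep=SEP, index=False)
    sidecar = {
        "edges_cv1": grid.edges1.tolist(),
        "edges_cv2": grid.edges2.tolist(),
        "temperature_K": grid.temperature,
        "coverage": grid.coverage,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_fes_grid(path: str | Path) -> FESGrid:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    df = pd.read_csv(path, sep=SEP, float_precision="round_trip")
    e1 = np.array(sidecar["edges_cv1"])
    e2 = np.array(sidecar["edges_cv2"])
    shape = (len(e1) - 1, len(e2) - 1)
    return FESGrid(
        edges1=e1,
        edges2=e2,
        free_energy=df["free_energy_kcal_mol"].to_numpy().reshape(shape),
        visited=df["visited"].to_numpy().astype(bool).reshape(shape),
        temperature=float(sidecar["temperature_K"]),
    )
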