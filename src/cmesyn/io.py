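"""Dataset, signal and configuration I/O.

Datasets travel as long-format CSV (columns ``cell, time, species,
count``) with a JSON metadata sidecar (observation times, species names,
the correlated flag, seed and — for synthetic data — the generating
parameters).  Experiment configurations are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .networks import Signal
from .ssa import SnapshotDataset

__all__ = ["write_dataset", "read_dataset", "read_signal_csv",
           "load_config", "write_manifest"]

REQUIRED_COLUMNS = ["cell", "time", "species", "count"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_dataset(data: SnapshotDataset, path) -> None:
    """Write a dataset as long CSV plus a JSON metadata sidecar."""
    path = Path(path)
    rows = []
    for c in range(data.n_cells):
        for t_i, t in enumerate(data.times):
            for s_i, s in enumerate(data.species):
                rows.append((c, t, s, int(data.counts[c, t_i, s_i])))
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS).to_csv(path, index=False)
    meta = {
        "times": list(map(float, data.times)),
        "species": list(data.species),
        "correlated": bool(data.correlated),
    }
    meta.update({k: v for k, v in data.meta.items()
                 if isinstance(v, (int, float, str, bool, dict, list))})
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_dataset(path) -> SnapshotDataset:
    """Read a long-format CSV dataset written by :func:`write_dataset`."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset CSV missing columns {missing}")
    if not np.allclose(df["count"], np.round(df["count"])):
        raise ValueError("counts must be integers")
    if (df["count"] < 0).any():
        raise ValueError("counts must be nonnegative")
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    times = np.array(meta.get("times", sorted(df["time"].unique())), float)
    species = list(meta.get("species", sorted(df["species"].unique())))
    cells = sorted(df["cell"].unique())
    counts = np.zeros((len(cells), len(times), len(species)), dtype=np.int64)
    t_idx = {t: i for i, t in enumerate(times)}
    s_idx = {s: i for i, s in enumerate(species)}
    c_idx = {c: i for i, c in enumerate(cells)}
    for row in df.itertuples(index=False):
        counts[c_idx[row.cell], t_idx[float(row.time)], s_idx[row.species]] = int(row.count)
    return SnapshotDataset(counts=counts, times=times, species=species,
                           correlated=bool(meta.get("correlated", True)),
                           meta=meta)


def read_signal_csv(path, interpolation: str = "linear",
                    upper_bound: float | None = None) -> Signal:
    """Read a two-column (time, value) CSV into a :class:`Signal`."""
    df = pd.read_csv(path)
    cols = list(df.columns[:2])
    return Signal(times=df[cols[0]].to_numpy(float),
                  values=df[cols[1]].to_numpy(float),
                  interpolation=interpolation, upper_bound=upper_bound)


def load_config(path) -> dict:
    """Load a YAML experiment configuration (must contain a ``seed``)."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a YAML mapping")
    if "seed" not in cfg:
        raise ValueError("configuration must set an explicit seed")
    return cfg


def write_manifest(path, **entries) -> None:
    """Write a JSON run manifest (seeds, methods, shapes) for reproducibility."""
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    Path(path).write_text(json.dumps(entries, indent=2, default=default))
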