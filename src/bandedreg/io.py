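"""Readers, writers and configuration parsing for the command-line layer.

Matrices travel as delimited text (CSV/TSV with a header row) or as HDF5
containers with datasets ``X``/``y``/``Y`` and a ``groups`` attribute.
Numeric CSV output uses 17 significant digits so a write-read round trip is
exact to double precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .design import GroupedDesign
from .exceptions import ConfigError
from .priors import Hyperpriors, SmoothnessSpec

FLOAT_FMT = "%.17g"


# -- matrices -------------------------------------------------------------
def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_matrix(path, dataset: str = "X") -> tuple[np.ndarray, list[str]]:
    """Read a numeric matrix; returns (array, column names).

    CSV/TSV files need a header row; ``.h5``/``.hdf5`` files are read from
    the named dataset (column names from a ``columns`` attribute when
    present).
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as fh:
            if dataset not in fh:
                raise ConfigError(f"dataset {dataset!r} not found in {path}")
            arr = np.asarray(fh[dataset], dtype=float)
            cols = fh[dataset].attrs.get("columns")
            names = (
                [c.decode() if isinstance(c, bytes) else str(c) for c in cols]
                if cols is not None
                else [f"c{i}" for i in range(arr.shape[1] if arr.ndim == 2 else 1)]
            )
        return arr, names
    df = pd.read_csv(path, sep=_sep_for(path))
    return df.to_numpy(float), [str(c) for c in df.columns]


def read_target(path, dataset: str = "y") -> np.ndarray:
    """Read target column(s); a single column is returned 1-D."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as fh:
            key = dataset if dataset in fh else ("Y" if "Y" in fh else "y")
            if key not in fh:
                raise ConfigError(f"no target dataset in {path}")
            arr = np.asarray(fh[key], dtype=float)
    else:
        arr = pd.read_csv(path, sep=_sep_for(path)).to_numpy(float)
    if arr.ndim == 2 and arr.shape[1] == 1:
        return arr[:, 0]
    return arr


def write_matrix(path, arr: np.ndarray, columns: Sequence[str] | None = None) -> None:
    path = Path(path)
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    if arr.shape[0] == 1 and arr.size > 1 and columns is None:
        arr = arr.T
    if columns is None:
        columns = [f"c{i}" for i in range(arr.shape[1])]
    pd.DataFrame(arr, columns=list(columns)).to_csv(
        path, index=False, sep=_sep_for(path), float_format=FLOAT_FMT
    )


def write_hdf5(path, X: np.ndarray, y: np.ndarray | None, groups: Mapping[str, int]) -> None:
    """Write an HDF5 container with datasets X, y and a groups attribute."""
    import h5py

    with h5py.File(path, "w") as fh:
        dx = fh.create_dataset("X", data=np.asarray(X, dtype=float))
        dx.attrs["groups"] = json.dumps({k: int(v) for k, v in groups.items()})
        if y is not None:
            y = np.asarray(y, dtype=float)
            fh.create_dataset("Y" if y.ndim == 2 else "y", data=y)


# -- configuration --------------------------------------------------------
def load_config(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() in (".yaml", ".yml"):
            cfg = yaml.safe_load(fh)
        else:
            cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def parse_group_spec(
    spec: Sequence[Mapping[str, Any]], n_columns: int
) -> tuple[list[tuple[str, int]], SmoothnessSpec]:
    """Validate a group spec: list of {name, n_columns | columns, h?}.

    ``columns`` is a half-open [start, stop) range; sizes must sum to the
    design's column count.
    """
    if not spec:
        raise ConfigError("groups: at least one group is required")
    sizes: list[tuple[str, int]] = []
    h: dict[str, float] = {}
    cursor = 0
    for i, entry in enumerate(spec):
        if "name" not in entry:
            raise ConfigError(f"groups[{i}].name is required")
        name = str(entry["name"])
        if "n_columns" in entry:
            size = int(entry["n_columns"])
        elif "columns" in entry:
            start, stop = (int(v) for v in entry["columns"])
            if start != cursor:
                raise ConfigError(
                    f"groups[{i}].columns: expected start {cursor}, got {start}"
                )
            size = stop - start
        else:
            raise ConfigError(f"groups[{i}]: need n_columns or columns")
        if size < 1:
            raise ConfigError(f"groups[{i}]: size must be >= 1")
        cursor += size
        sizes.append((name, size))
        if entry.get("h") is not None:
            h[name] = float(entry["h"])
    if cursor != n_columns:
        raise ConfigError(
            f"group sizes sum to {cursor} but the design has {n_columns} columns"
        )
    return sizes, SmoothnessSpec(h)


def hyperpriors_from_config(cfg: Mapping[str, Any]) -> Hyperpriors:
    """Build Hyperpriors from config keys gamma or (tau, eta, kappa, phi)."""
    if cfg.get("gamma") is not None:
        return Hyperpriors(gamma=float(cfg["gamma"]))
    keys = ("eta", "tau", "phi", "kappa")
    if any(k in cfg for k in keys):
        missing = [k for k in keys if k not in cfg]
        if missing:
            raise ConfigError(f"hyperpriors: missing {missing} (or give gamma)")
        return Hyperpriors(**{k: float(cfg[k]) for k in keys})
    return Hyperpriors()


def build_design(
    X: np.ndarray, sizes: Sequence[tuple[str, int]]
) -> GroupedDesign:
    return GroupedDesign.from_sizes(
        X, [s for _, s in sizes], [n for n, _ in sizes]
    )


# -- results --------------------------------------------------------------
def write_weights_csv(path, design: GroupedDesign, weights: np.ndarray) -> None:
    """Weights in long format: column index, group name, weight value(s)."""
    weights = np.asarray(weights, dtype=float)
    group_of = design.group_of_column()
    out = {
        "column": np.arange(design.n_predictors),
        "group": [design.names[g] for g in group_of],
    }
    if weights.ndim == 1:
        out["weight"] = weights
    else:
        for t in range(weights.shape[1]):
            out[f"weight_{t}"] = weights[:, t]
    pd.DataFrame(out).to_csv(path, index=False, float_format=FLOAT_FMT)


def write_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
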