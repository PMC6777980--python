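"""Reading and writing of region metadata and connectivity matrices.

All files are delimited text (comma by default, tab accepted).  Region
metadata is a table with columns ``label,x,y,z`` (coordinates in mm and
optional as a block).  Connectivity matrices are labeled square tables:
header row and first column carry region labels, rows are source regions
and columns are target (injected) regions.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import RegionSet, WeightedConnectome

__all__ = [
    "read_region_set",
    "write_region_set",
    "read_connectome",
    "write_connectome",
    "euclidean_distances",
]


def _sep(path: str | Path) -> str:
    # delimiter sniffing by hand: csv.Sniffer chokes on single-column files
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                return "\t" if "\t" in line else ","
    return ","


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep(path), comment="#", index_col=0)


def read_region_set(path: str | Path) -> RegionSet:
    """Read region labels and optional centroid coordinates.

    The file must have a header with a ``label`` column; columns
    ``x, y, z`` (mm), when all present, become centroids.  Labels keep
    file order, which defines matrix indexing downstream.
    """
    df = pd.read_csv(path, sep=_sep(path), comment="#")
    if "label" not in df.columns:
        raise ValueError(f"{path}: missing required column 'label'")
    labels = [str(l) for l in df["label"]]
    seen: set[str] = set()
    for l in labels:
        if l in seen:
            raise ValueError(f"{path}: duplicate region label: {l!r}")
        seen.add(l)
    centroids = None
    if all(c in df.columns for c in ("x", "y", "z")):
        coords = df[["x", "y", "z"]]
        for row_pos, (_, row) in enumerate(coords.iterrows()):
            vals = pd.to_numeric(row, errors="coerce")
            if vals.isna().any():
                raise ValueError(
                    f"{path}: non-numeric coordinate in row {row_pos + 1} "
                    f"(label {labels[row_pos]!r})"
                )
        centroids = coords.to_numpy(dtype=float)
    return RegionSet(labels=tuple(labels), centroids=centroids)


def write_region_set(regions: RegionSet, path: str | Path) -> None:
    data: dict = {"label": list(regions.labels)}
    if regions.centroids is not None:
        data["x"] = regions.centroids[:, 0]
        data["y"] = regions.centroids[:, 1]
        data["z"] = regions.centroids[:, 2]
    pd.DataFrame(data).to_csv(path, index=False)


def read_connectome(
    path: str | Path,
    regions: RegionSet,
    kind: str,
    directed: bool,
) -> WeightedConnectome:
    """Read a labeled square matrix and align it onto ``regions``.

    The file's labels must be a superset (or exact match) of the region
    set; rows/columns are reordered into region-set order, and subsetting
    yields the edge-complete subnetwork over the requested regions.
    A nonzero diagonal is zeroed with a warning, since self-connections
    are excluded from every normalization.
    """
    df = _read_table(path)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix is not square ({df.shape[0]}x{df.shape[1]})")
    missing = [l for l in regions.labels if l not in df.index or l not in df.columns]
    if missing:
        raise ValueError(f"{path}: region label(s) missing from file: {missing}")
    sub = df.loc[list(regions.labels), list(regions.labels)]
    W = sub.to_numpy(dtype=float)
    if np.any(W < 0):
        raise ValueError(f"{path}: negative weight encountered")
    if np.any(np.diag(W) != 0):
        warnings.warn(
            f"{path}: nonzero diagonal zeroed (self-connections excluded)",
            stacklevel=2,
        )
        np.fill_diagonal(W, 0.0)
    return WeightedConnectome(regions=regions, W=W, directed=directed, kind=kind)


def write_connectome(conn: WeightedConnectome, path: str | Path) -> None:
    """Write a labeled square matrix with a kind/orientation header comment."""
    path = Path(path)
    labels = list(conn.regions.labels)
    df = pd.DataFrame(conn.W, index=labels, columns=labels)
    with open(path, "w") as fh:
        fh.write(
            f"# kind={conn.kind} directed={conn.directed} "
            "orientation=rows:source,cols:target\n"
        )
        if "seed" in conn.meta:
            fh.write(f"# seed={conn.meta['seed']}\n")
        df.to_csv(fh)


def euclidean_distances(regions: RegionSet) -> np.ndarray:
    """Pairwise Euclidean distances (mm) between region centroids."""
    if regions.centroids is None:
        raise ValueError(
            f"no centroids available for regions {regions.labels[:3]}...; "
            "distances require centroid coordinates"
        )
    c = regions.centroids
    diff = c[:, None, :] - c[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=-1))
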