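"""Reading and writing connectomes and cohort manifests.

Connectomes are exchanged as dense delimited-text adjacency matrices or
GraphML; cohort manifests are delimited tables keyed by the sample-key
fields.  External connectome sets loaded through these functions can be
fed directly to the stability and discriminability evaluations.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import Connectome, SampleKey

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_graphml",
    "read_graphml",
    "write_manifest",
    "read_manifest",
    "key_to_filename",
]

KEY_FIELDS = ("subject", "session", "subsample", "pipeline", "mode", "sim")


def write_matrix(path: str | Path, weights: np.ndarray, delimiter: str = "\t") -> None:
    """Write a dense adjacency matrix as delimited text (full precision)."""
    np.savetxt(path, np.asarray(weights, dtype=np.float64),
               delimiter=delimiter, fmt="%.17g")


def read_matrix(path: str | Path, delimiter: str = "\t") -> np.ndarray:
    arr = np.loadtxt(path, delimiter=delimiter, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{path}: expected a square adjacency matrix")
    return arr


def write_graphml(path: str | Path, connectome: Connectome) -> None:
    g = nx.from_numpy_array(connectome.weights)
    for f, v in zip(KEY_FIELDS, connectome.key):
        g.graph[f] = v
    nx.write_graphml(g, path)


def read_graphml(path: str | Path) -> Connectome:
    g = nx.read_graphml(path)
    n = g.number_of_nodes()
    weights = np.zeros((n, n))
    index = {node: i for i, node in enumerate(g.nodes())}
    for u, v, d in g.edges(data=True):
        w = float(d.get("weight", 1.0))
        weights[index[u], index[v]] = w
        weights[index[v], index[u]] = w
    meta = g.graph
    key = SampleKey(
        subject=int(meta.get("subject", 0)),
        session=int(meta.get("session", 0)),
        subsample=int(meta.get("subsample", 0)),
        pipeline=str(meta.get("pipeline", "det-like")),
        mode=str(meta.get("mode", "dense")),
        sim=int(meta.get("sim", -1)),
    )
    return Connectome(weights, key)


def key_to_filename(key: SampleKey, ext: str = "tsv") -> str:
    sim = "ref" if key.is_reference else f"sim{key.sim:03d}"
    return (
        f"sub{key.subject:03d}_ses{key.session}_sam{key.subsample}"
        f"_{key.pipeline}_{key.mode}_{sim}.{ext}"
    )


def write_manifest(
    path: str | Path,
    connectomes: Mapping[SampleKey, Connectome] | Iterable[SampleKey],
    filenames: Mapping[SampleKey, str] | None = None,
) -> pd.DataFrame:
    """Write a cohort manifest table keyed by the sample-key fields."""
    keys = list(connectomes)
    rows = []
    for k in keys:
        row = dict(zip(KEY_FIELDS, k))
        row["filename"] = (
            filenames[k] if filenames is not None else key_to_filename(k)
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_manifest(path: str | Path) -> list[tuple[SampleKey, str]]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        key = SampleKey(
            subject=int(row["subject"]),
            session=int(row["session"]),
            subsample=int(row["subsample"]),
            pipeline=str(row["pipeline"]),
            mode=str(row["mode"]),
            sim=int(row["sim"]),
        )
        out.append((key, str(row["filename"])))
    return out
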