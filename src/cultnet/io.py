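"""Readers and writers for the pipeline's data products.

Formats are deliberately plain: traces as HDF5 (dataset ``F`` with an
``fps`` attribute) or wide CSV; rasters as sparse CSV of (roi_id, frame);
spike trains as CSV of (roi_id, time_s); culture models as JSON (nodes +
geometry) plus an edge-list TSV; effective networks as edge-list TSV or
GraphML (openable in standard graph viewers).  Every writer's output is
accepted by its paired reader.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd

from .calcium import EventRaster
from .connectivity import EffectiveNetwork
from .culture import CultureModel, SpikeTrains, TraceSet

__all__ = [
    "write_traces",
    "read_traces",
    "write_raster",
    "read_raster",
    "write_spikes",
    "read_spikes",
    "write_network",
    "read_network",
    "write_model",
    "read_model",
]


# ---------------------------------------------------------------------------
# traces


def write_traces(traces: TraceSet, path: str | Path, format: str | None = None):
    path = Path(path)
    fmt = format or ("hdf5" if path.suffix in (".h5", ".hdf5") else "csv")
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            d = f.create_dataset("F", data=traces.values)
            d.attrs["fps"] = traces.fps
            if traces.roi_meta is not None:
                f.create_dataset(
                    "roi_meta_json",
                    data=traces.roi_meta.to_json(orient="split"),
                )
    elif fmt == "csv":
        df = pd.DataFrame(traces.values)
        df.insert(0, "roi_id", np.arange(traces.n_rois))
        with open(path, "w") as f:
            f.write(f"# fps={traces.fps}\n")
            df.to_csv(f, index=False)
    else:
        raise ValueError(f"unknown traces format {fmt!r}")
    return path


def read_traces(path: str | Path, format: str | None = None) -> TraceSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("hdf5" if path.suffix in (".h5", ".hdf5") else "csv")
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            values = f["F"][...]
            if "fps" not in f["F"].attrs:
                raise ValueError(f"{path}: missing fps attribute")
            fps = float(f["F"].attrs["fps"])
            meta = None
            if "roi_meta_json" in f:
                raw = f["roi_meta_json"][()]
                meta = pd.read_json(
                    raw.decode() if isinstance(raw, bytes) else raw,
                    orient="split",
                )
        return TraceSet(values=values, fps=fps, roi_meta=meta)
    if fmt == "csv":
        with open(path) as f:
            header = f.readline().strip()
            if not header.startswith("# fps="):
                raise ValueError(f"{path}: missing '# fps=' header line")
            fps = float(header.split("=", 1)[1])
            df = pd.read_csv(f)
        values = df.drop(columns=["roi_id"]).to_numpy(dtype=float)
        return TraceSet(values=values, fps=fps)
    raise ValueError(f"unknown traces format {fmt!r}")


# ---------------------------------------------------------------------------
# rasters


def write_raster(raster: EventRaster, path: str | Path):
    """Sparse CSV of 1-entries, header carries fps/shape metadata."""
    rois, frames = np.nonzero(raster.bits)
    path = Path(path)
    with open(path, "w") as f:
        f.write(
            f"# fps={raster.fps} n_rois={raster.n_rois} "
            f"n_frames={raster.n_frames}\n"
        )
        pd.DataFrame({"roi_id": rois, "frame": frames}).to_csv(f, index=False)
    return path


def read_raster(path: str | Path) -> EventRaster:
    path = Path(path)
    with open(path) as f:
        header = f.readline().strip().lstrip("# ")
        meta = dict(kv.split("=") for kv in header.split())
        df = pd.read_csv(f)
    bits = np.zeros(
        (int(meta["n_rois"]), int(meta["n_frames"])), dtype=np.uint8
    )
    if df.duplicated().any():
        warnings.warn(f"{path}: duplicate (roi, frame) rows collapsed")
        df = df.drop_duplicates()
    bits[df["roi_id"].to_numpy(dtype=int), df["frame"].to_numpy(dtype=int)] = 1
    return EventRaster(bits=bits, fps=float(meta["fps"]))


# ---------------------------------------------------------------------------
# spike trains


def write_spikes(spikes: SpikeTrains, path: str | Path):
    path = Path(path)
    with open(path, "w") as f:
        f.write(
            f"# duration={spikes.duration} n_rois={spikes.n_rois} "
            f"seed={spikes.seed}\n"
        )
        pd.DataFrame({"roi_id": spikes.roi, "time_s": spikes.time}).to_csv(
            f, index=False
        )
    return path


def read_spikes(path: str | Path) -> SpikeTrains:
    with open(path) as f:
        header = f.readline().strip().lstrip("# ")
        meta = dict(kv.split("=") for kv in header.split())
        df = pd.read_csv(f)
    return SpikeTrains(
        roi=df["roi_id"].to_numpy(),
        time=df["time_s"].to_numpy(),
        duration=float(meta["duration"]),
        n_rois=int(meta["n_rois"]),
        seed=int(meta["seed"]),
    )


# ---------------------------------------------------------------------------
# networks


def _network_graph(network: EffectiveNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    ids = network.node_ids
    g.add_nodes_from(int(i) for i in ids)
    src, dst = np.nonzero(network.adjacency)
    for i, j in zip(src, dst):
        g.add_edge(int(ids[i]), int(ids[j]), z=float(network.z[i, j]))
    return g


def write_network(
    network: EffectiveNetwork, path: str | Path, format: str = "tsv_edgelist"
):
    path = Path(path)
    if format == "tsv_edgelist":
        src, dst = np.nonzero(network.adjacency)
        ids = network.node_ids
        df = pd.DataFrame(
            {
                "src": ids[src],
                "dst": ids[dst],
                "z": network.z[src, dst],
            }
        )
        with open(path, "w") as f:
            f.write(
                f"# n_nodes={len(ids)} z_min={network.threshold}\n"
            )
            df.to_csv(f, sep="\t", index=False)
    elif format == "graphml":
        g = _network_graph(network)
        g.graph["z_min"] = network.threshold
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")
    return path


def read_network(path: str | Path, format: str | None = None) -> EffectiveNetwork:
    path = Path(path)
    fmt = format or ("graphml" if path.suffix == ".graphml" else "tsv_edgelist")
    if fmt == "graphml":
        g = nx.read_graphml(path)
        ids = sorted(int(v) for v in g.nodes)
        pos = {v: k for k, v in enumerate(ids)}
        n = len(ids)
        adj = np.zeros((n, n), dtype=np.int8)
        z = np.zeros((n, n))
        for u, v, data in g.edges(data=True):
            adj[pos[int(u)], pos[int(v)]] = 1
            z[pos[int(u)], pos[int(v)]] = float(data.get("z", 0.0))
        return EffectiveNetwork(
            adjacency=adj,
            z=z,
            threshold=float(g.graph.get("z_min", 1.0)),
            node_ids=np.array(ids),
        )
    with open(path) as f:
        header = f.readline().strip().lstrip("# ")
        meta = dict(kv.split("=") for kv in header.split())
        df = pd.read_csv(f, sep="\t")
    n = int(meta["n_nodes"])
    adj = np.zeros((n, n), dtype=np.int8)
    z = np.zeros((n, n))
    src_i = df["src"].to_numpy(dtype=int)
    dst_i = df["dst"].to_numpy(dtype=int)
    adj[src_i, dst_i] = 1
    z[src_i, dst_i] = df["z"].to_numpy(dtype=float)
    return EffectiveNetwork(
        adjacency=adj, z=z, threshold=float(meta["z_min"])
    )


# ---------------------------------------------------------------------------
# culture models


def write_model(model: CultureModel, path_prefix: str | Path):
    """Write a model as <prefix>.json (nodes, geometry) + <prefix>_edges.tsv."""
    prefix = Path(path_prefix)
    payload = {
        "kind": model.kind,
        "geometry": model.geometry,
        "baseline_in": model.baseline_in.tolist(),
        "nodes": model.nodes.to_dict(orient="list"),
    }
    prefix.with_suffix(".json").write_text(json.dumps(payload))
    src, dst = np.nonzero(model.weights)
    pd.DataFrame(
        {"src": src, "dst": dst, "weight": model.weights[src, dst]}
    ).to_csv(prefix.parent / (prefix.stem + "_edges.tsv"), sep="\t", index=False)
    return prefix.with_suffix(".json")


def read_model(path_prefix: str | Path) -> CultureModel:
    prefix = Path(path_prefix)
    payload = json.loads(prefix.with_suffix(".json").read_text())
    nodes = pd.DataFrame(payload["nodes"])
    n = len(nodes)
    w = np.zeros((n, n))
    edges = pd.read_csv(
        prefix.parent / (prefix.stem + "_edges.tsv"), sep="\t"
    )
    w[edges["src"].to_numpy(), edges["dst"].to_numpy()] = edges[
        "weight"
    ].to_numpy()
    return CultureModel(
        nodes=nodes,
        weights=w,
        kind=payload["kind"],
        geometry=payload["geometry"],
        baseline_in=np.array(payload["baseline_in"]),
    )
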