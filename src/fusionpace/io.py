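"""Plain-text interchange: JSON run configuration and CSV exports.

Conventions: coordinates in mm (right-handed, apex toward -z), times in ms.
Graph interchange is a pair of CSVs (nodes: id,x,y,z,region,layer; edges:
u,v,time_ms); activation maps are long-format CSV with one row per node.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import CohortSpec, cohort_to_frame
from .device import DeviceConfig
from .heart import AnatomySpec, HeartGraph
from .study import ResultsTable
from .wavefront import ActivationMap

__all__ = [
    "RunConfig",
    "load_config",
    "save_cohort_csv",
    "save_graph_csv",
    "load_graph_csv",
    "activation_map_frame",
    "save_activation_map_csv",
    "save_results",
]


@dataclasses.dataclass(frozen=True)
class RunConfig:
    cohort: CohortSpec
    anatomy: AnatomySpec
    device: DeviceConfig


def _build(cls, payload: dict[str, Any], section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - valid
    if unknown:
        raise ValueError(f"unknown keys in config section {section!r}: {sorted(unknown)}")
    return cls(**payload)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Read a JSON run configuration; missing sections use defaults.

    Layout: ``{"cohort": {...}, "anatomy": {...}, "device": {...}}`` with
    keys matching the corresponding spec dataclass fields.
    """
    payload: dict[str, Any] = {}
    if path is not None:
        payload = json.loads(Path(path).read_text())
        if not isinstance(payload, dict):
            raise ValueError("config root must be a JSON object")
    cohort = _build(CohortSpec, payload.get("cohort", {}), "cohort")
    anatomy = _build(AnatomySpec, payload.get("anatomy", {}), "anatomy")
    device = _build(DeviceConfig, payload.get("device", {}), "device")
    cohort.validate()
    anatomy.validate()
    return RunConfig(cohort=cohort, anatomy=anatomy, device=device)


def save_cohort_csv(cohort, path: str | Path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def save_graph_csv(hg: HeartGraph, nodes_path: str | Path, edges_path: str | Path) -> None:
    nodes = pd.DataFrame(
        {
            "id": np.arange(hg.n_nodes),
            "x": hg.positions[:, 0],
            "y": hg.positions[:, 1],
            "z": hg.positions[:, 2],
            "region": hg.region,
            "layer": hg.layer,
        }
    )
    nodes.to_csv(nodes_path, index=False)
    edges = pd.DataFrame(
        [(u, v, t) for u, v, t in hg.graph.edges(data="time_ms")],
        columns=["u", "v", "time_ms"],
    )
    edges.to_csv(edges_path, index=False)


def load_graph_csv(nodes_path: str | Path, edges_path: str | Path) -> HeartGraph:
    nodes = pd.read_csv(nodes_path)
    edges = pd.read_csv(edges_path)
    g = nx.Graph()
    positions = nodes[["x", "y", "z"]].to_numpy(dtype=float)
    region = nodes["region"].to_numpy(dtype=object).astype(str)
    layer = nodes["layer"].to_numpy(dtype=object).astype(str)
    for i, row in nodes.iterrows():
        g.add_node(int(row["id"]), pos=positions[i], region=region[i], layer=layer[i])
    for _, row in edges.iterrows():
        g.add_edge(int(row["u"]), int(row["v"]), time_ms=float(row["time_ms"]))
    return HeartGraph(graph=g, positions=positions, region=region, layer=layer)


def activation_map_frame(amap: ActivationMap, hg: HeartGraph) -> pd.DataFrame:
    """Long-format map: node_id,x,y,z,region,layer,activation_time_ms,mode."""
    return pd.DataFrame(
        {
            "node_id": np.arange(hg.n_nodes),
            "x": hg.positions[:, 0],
            "y": hg.positions[:, 1],
            "z": hg.positions[:, 2],
            "region": hg.region,
            "layer": hg.layer,
            "activation_time_ms": amap.times,
            "mode": amap.mode,
        }
    )


def save_activation_map_csv(amap: ActivationMap, hg: HeartGraph, path: str | Path) -> None:
    activation_map_frame(amap, hg).to_csv(path, index=False)


def save_results(table: ResultsTable, out_dir: str | Path) -> dict[str, Path]:
    """Write the study outputs (VAT matrix, long metrics) as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vat": out / "vat_by_patient_mode.csv",
        "metrics": out / "metrics_long.csv",
        "cohort": out / "cohort.csv",
    }
    table.vat.to_csv(paths["vat"])
    table.metrics.to_csv(paths["metrics"], index=False)
    if table.cohort:
        save_cohort_csv(table.cohort, paths["cohort"])
    return paths
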