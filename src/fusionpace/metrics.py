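"""Activation-map measurements used by the study protocol.

Total ventricular activation time (VAT) is the span from earliest to latest
local activation over a node selection; unfiltered it spans both ventricles
jointly and serves as the QRS-duration proxy (for the native beat the two
are reported interchangeably).  Breakthrough sites are the earliest-activated
nodes within the septal region or within the endocardial/epicardial layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .heart import HeartGraph
from .wavefront import ActivationMap

__all__ = [
    "MetricsRecord",
    "total_activation_time",
    "breakthrough_site",
    "compute_metrics",
]


@dataclass(frozen=True)
class MetricsRecord:
    patient_id: str
    mode: str
    vat_total_ms: float
    vat_lv_ms: float
    vat_rv_ms: float
    vat_septum_ms: float
    earliest_septal_node: int
    earliest_septal_ms: float
    earliest_endo_node: int
    earliest_endo_ms: float
    earliest_epi_node: int
    earliest_epi_ms: float

    @property
    def qrs_proxy_ms(self) -> float:
        return self.vat_total_ms


def total_activation_time(
    amap: ActivationMap,
    graph: HeartGraph,
    region: Optional[str] = None,
    layer: Optional[str] = None,
) -> float:
    """Max minus min activation time over the selected nodes (all if None)."""
    ids = graph.select(region=region, layer=layer)
    if ids.size == 0:
        raise ValueError(f"empty node selection (region={region}, layer={layer})")
    t = amap.times[ids]
    return float(t.max() - t.min())


def breakthrough_site(
    amap: ActivationMap, graph: HeartGraph, selector: str
) -> tuple[int, float]:
    """Earliest-activated node within a selection; ties -> lowest node id.

    ``selector`` is one of ``septal`` (region), ``endo`` or ``epi`` (layer).
    """
    if selector == "septal":
        ids = graph.select(region="septum")
    elif selector in ("endo", "epi"):
        ids = graph.select(layer=selector)
    else:
        raise ValueError(f"unknown selector {selector!r} (septal|endo|epi)")
    if ids.size == 0:
        raise ValueError(f"empty selection for {selector!r}")
    t = amap.times[ids]
    order = np.lexsort((ids, t))  # time, then lowest id
    best = int(ids[order[0]])
    return best, float(amap.times[best])


def compute_metrics(amap: ActivationMap, graph: HeartGraph) -> MetricsRecord:
    """All protocol measurements for one map."""
    sep_n, sep_t = breakthrough_site(amap, graph, "septal")
    endo_n, endo_t = breakthrough_site(amap, graph, "endo")
    epi_n, epi_t = breakthrough_site(amap, graph, "epi")
    return MetricsRecord(
        patient_id=amap.patient_id,
        mode=amap.mode,
        vat_total_ms=total_activation_time(amap, graph),
        vat_lv_ms=total_activation_time(amap, graph, region="lv_free_wall"),
        vat_rv_ms=total_activation_time(amap, graph, region="rv_free_wall"),
        vat_septum_ms=total_activation_time(amap, graph, region="septum"),
        earliest_septal_node=sep_n,
        earliest_septal_ms=sep_t,
        earliest_endo_node=endo_n,
        earliest_endo_ms=endo_t,
        earliest_epi_node=epi_n,
        earliest_epi_ms=epi_t,
    )
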