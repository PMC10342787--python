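"""Biventricular conduction graph.

The anatomy is a deliberately simple surrogate for an image-derived patient
model: the left ventricle (LV) is a two-layer (endocardial/epicardial)
ellipsoidal shell open at the base; the right ventricle (RV) is a two-layer
crescent shell wrapped around the LV's septal sector and attached to it along
the anterior and posterior interventricular grooves.  Node tags partition the
myocardium into septum / lv_free_wall / rv_free_wall regions and endo / epi
layers — the topology the study metrics need (total activation time per
region, earliest septal/endocardial/epicardial breakthrough).

Conduction is encoded on edges as traversal times (edge length / velocity).
Left bundle branch block is modeled structurally: the RV endocardium carries
a fast subendocardial network (surrogate Purkinje system) while the LV
endocardium conducts at plain myocardial velocity, so intrinsic activation
enters at the RV septal margin and the LV free wall activates last by slow
transmural and circumferential spread.

Coordinates are millimeters, right-handed, apex toward -z, RV toward +x.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .cohort import PatientParams

__all__ = [
    "AnatomySpec",
    "HeartGraph",
    "build_heart_graph",
    "place_leads",
    "calibrate_conduction",
]

# Geometry constants not exposed on AnatomySpec.  Chosen once so the default
# anatomy reproduces two physiological anchors of an LBBB heart: an intrinsic
# activation span near 180 ms at unit velocity multiplier, and an intrinsic
# breakout-to-RV-apex conduction time around one fifth of that span (the
# RV-lead sensing delay scale reported for LBBB).
_LV_ELONGATION = 1.5          # LV long semi-axis / short semi-axis
_RV_ELONGATION = 1.45         # RV long semi-axis / short semi-axis
_BASE_CUT_FRAC = 0.35         # shells keep z <= frac * long semi-axis
_SEPTAL_HALF_ANGLE = math.radians(55.0)   # LV sector facing the RV
_RV_HALF_ANGLE = math.radians(80.0)       # angular extent of the RV crescent
_RV_CAVITY_WIDTH_MM = 18.0    # septal surface to RV free-wall endocardium
_RV_WALL_FRACTION = 0.45      # RV wall thickness relative to LV wall
_EDGE_RADIUS_FACTOR = 1.6     # in-shell edges connect nodes within this * spacing

_MIN_NODES = 100
_BISECT_BOUNDS = (0.1, 10.0)
_BISECT_MAX_ITER = 60


@dataclass(frozen=True)
class AnatomySpec:
    """Anatomical and conduction parameters of the surrogate heart.

    ``mesh_spacing_mm`` mirrors the 2–4 mm spatial resolution of clinical
    activation mapping; values outside that band are accepted with a warning.
    Velocities are textbook working-myocardium (0.5 mm/ms) and fast
    subendocardial network (2.0 mm/ms) values; per-patient variation is
    absorbed by conduction calibration, not by editing the spec.
    """

    mesh_spacing_mm: float = 3.0
    lv_radius_mm: float = 30.0
    rv_radius_mm: float = 42.0
    wall_thickness_mm: float = 9.0
    myocardial_velocity_mm_per_ms: float = 0.5
    fast_layer_velocity_mm_per_ms: float = 2.0
    transseptal_extra_delay_ms: float = 0.0
    n_breakout_sites: int = 3

    def validate(self) -> None:
        if not (2.0 <= self.mesh_spacing_mm <= 4.0):
            warnings.warn(
                f"mesh_spacing_mm={self.mesh_spacing_mm} outside the 2-4 mm "
                "mapping-resolution band",
                stacklevel=2,
            )
        if self.mesh_spacing_mm <= 0:
            raise ValueError("mesh_spacing_mm must be > 0")
        for name in ("lv_radius_mm", "rv_radius_mm", "wall_thickness_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("myocardial_velocity_mm_per_ms", "fast_layer_velocity_mm_per_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.transseptal_extra_delay_ms < 0:
            raise ValueError("transseptal_extra_delay_ms must be >= 0")
        if self.n_breakout_sites < 1:
            raise ValueError("n_breakout_sites must be >= 1")


@dataclass
class HeartGraph:
    """Conduction graph plus cached node arrays and lead/breakout ids.

    ``graph`` is an undirected networkx graph whose nodes are consecutive
    integers with ``pos`` / ``region`` / ``layer`` attributes and whose edges
    carry ``time_ms`` (traversal time at velocity multiplier 1).
    """

    graph: nx.Graph
    positions: np.ndarray          # (n, 3) mm
    region: np.ndarray             # (n,) str: septum | lv_free_wall | rv_free_wall
    layer: np.ndarray              # (n,) str: endo | epi
    intrinsic_breakout_nodes: list[int] = field(default_factory=list)
    rv_lead: Optional[int] = None
    lv_lead: Optional[int] = None
    spec: Optional[AnatomySpec] = None
    _csr_cache: Optional[sp.csr_matrix] = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    def select(self, region: str | None = None, layer: str | None = None) -> np.ndarray:
        """Node ids matching the given region and/or layer tags."""
        mask = np.ones(self.n_nodes, dtype=bool)
        if region is not None:
            mask &= self.region == region
        if layer is not None:
            mask &= self.layer == layer
        return np.flatnonzero(mask)

    def traversal_csr(self) -> sp.csr_matrix:
        """Symmetric sparse matrix of edge traversal times (multiplier 1)."""
        if self._csr_cache is None:
            n = self.n_nodes
            rows, cols, data = [], [], []
            for u, v, t in self.graph.edges(data="time_ms"):
                rows += [u, v]
                cols += [v, u]
                data += [t, t]
            self._csr_cache = sp.csr_matrix(
                (np.asarray(data, dtype=float), (rows, cols)), shape=(n, n)
            )
        return self._csr_cache


# ---------------------------------------------------------------------------
# construction


def _shell_nodes(
    a: float,
    c: float,
    center: np.ndarray,
    spacing: float,
    phi_center: float,
    phi_half: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample nodes on a (possibly partial) ellipsoid shell, apex included.

    Returns positions and a boolean boundary flag (crescent edges and basal
    ring) used for attaching the RV free wall to the septum.
    """
    theta_min = math.acos(_BASE_CUT_FRAC)
    # approximate meridian arc length from the basal cut to the apex pole
    thetas_fine = np.linspace(theta_min, math.pi, 200)
    dx = a * np.cos(thetas_fine)
    dz = -c * np.sin(thetas_fine)
    arc = np.trapezoid(np.hypot(dx, dz), thetas_fine)
    n_rings = max(3, int(round(arc / spacing)))

    full = phi_half >= math.pi - 1e-9
    pts, boundary = [], []
    thetas = np.linspace(theta_min, math.pi, n_rings + 1)
    for k, th in enumerate(thetas):
        z = c * math.cos(th)  # theta from the base pole (+z); apex at -z
        r = a * math.sin(th)
        if k == n_rings:  # apex pole
            pts.append(center + np.array([0.0, 0.0, -c]))
            boundary.append(False)
            continue
        sector = 2.0 * phi_half * r
        n_phi = max(3 if full else 2, int(round(sector / spacing)))
        if full:
            offs = 0.5 * (k % 2)  # stagger alternate rings
            phis = phi_center + 2.0 * math.pi * (np.arange(n_phi) + offs) / n_phi
            edge_flags = [k == 0] * n_phi
        else:
            phis = phi_center + np.linspace(-phi_half, phi_half, n_phi)
            edge_flags = [True] + [k == 0] * (n_phi - 2) + [True]
        for phi, on_edge in zip(phis, edge_flags):
            pts.append(center + np.array([r * math.cos(phi), r * math.sin(phi), z]))
            boundary.append(bool(on_edge))
    return np.asarray(pts), np.asarray(boundary)


def build_heart_graph(spec: AnatomySpec, anatomy_scale: float = 1.0) -> HeartGraph:
    """Construct the biventricular conduction graph for one patient.

    All linear dimensions are multiplied by ``anatomy_scale``.  Raises if the
    resulting graph is degenerate (< 100 nodes) or disconnected.
    """
    spec.validate()
    s = float(anatomy_scale)
    if s <= 0:
        raise ValueError("anatomy_scale must be > 0")
    spacing = spec.mesh_spacing_mm
    a_lv = spec.lv_radius_mm * s
    c_lv = a_lv * _LV_ELONGATION
    w = spec.wall_thickness_mm * s
    a_rv = spec.rv_radius_mm * s
    c_rv = a_rv * _RV_ELONGATION
    w_rv = w * _RV_WALL_FRACTION
    rv_center = np.array(
        [a_lv + w + _RV_CAVITY_WIDTH_MM * s - a_rv, 0.0, 0.0]
    )
    lv_center = np.zeros(3)

    shells = [
        # (a, c, center, phi_center, phi_half, chamber, layer)
        (a_lv, c_lv, lv_center, 0.0, math.pi, "lv", "endo"),
        (a_lv + w, c_lv + w, lv_center, 0.0, math.pi, "lv", "epi"),
        (a_rv, c_rv, rv_center, 0.0, _RV_HALF_ANGLE, "rv", "endo"),
        (a_rv + w_rv, c_rv + w_rv, rv_center, 0.0, _RV_HALF_ANGLE, "rv", "epi"),
    ]

    positions, regions, layers, boundary_flags, shell_of = [], [], [], [], []
    for si, (a, c, center, phic, phih, chamber, layer) in enumerate(shells):
        pts, bnd = _shell_nodes(a, c, center, spacing, phic, phih)
        for p, b in zip(pts, bnd):
            if chamber == "lv":
                phi = math.atan2(p[1], p[0])
                region = "septum" if abs(phi) <= _SEPTAL_HALF_ANGLE else "lv_free_wall"
            else:
                region = "rv_free_wall"
            positions.append(p)
            regions.append(region)
            layers.append(layer)
            boundary_flags.append(b and chamber == "rv")
            shell_of.append(si)

    positions = np.asarray(positions)
    region = np.asarray(regions)
    layer = np.asarray(layers)
    boundary = np.asarray(boundary_flags)
    shell_of = np.asarray(shell_of)
    n = positions.shape[0]
    if n < _MIN_NODES:
        raise ValueError(f"degenerate anatomy: only {n} nodes (< {_MIN_NODES})")

    g = nx.Graph()
    for i in range(n):
        g.add_node(i, pos=positions[i], region=region[i], layer=layer[i])

    v_myo = spec.myocardial_velocity_mm_per_ms
    v_fast = spec.fast_layer_velocity_mm_per_ms

    def add_edge(u: int, v: int, extra_ms: float = 0.0) -> None:
        if u == v or g.has_edge(u, v):
            return
        d = float(np.linalg.norm(positions[u] - positions[v]))
        fast = (
            region[u] == "rv_free_wall"
            and region[v] == "rv_free_wall"
            and layer[u] == "endo"
            and layer[v] == "endo"
        )
        vel = v_fast if fast else v_myo
        g.add_edge(u, v, time_ms=d / vel + extra_ms)

    # in-shell surface edges: local neighborhoods within each shell
    for si in range(len(shells)):
        ids = np.flatnonzero(shell_of == si)
        tree = cKDTree(positions[ids])
        for ia, ib in sorted(tree.query_pairs(r=_EDGE_RADIUS_FACTOR * spacing)):
            add_edge(int(ids[ia]), int(ids[ib]))

    # transmural edges: each endo node to its nearest epi node of the same chamber
    for endo_si, epi_si in ((0, 1), (2, 3)):
        endo_ids = np.flatnonzero(shell_of == endo_si)
        epi_ids = np.flatnonzero(shell_of == epi_si)
        tree = cKDTree(positions[epi_ids])
        _, nearest = tree.query(positions[endo_ids])
        for u, j in zip(endo_ids, nearest):
            extra = (
                spec.transseptal_extra_delay_ms
                if region[u] == "septum"
                else 0.0
            )
            add_edge(int(u), int(epi_ids[j]), extra_ms=extra)

    # interventricular grooves: RV crescent boundary attaches to the septal
    # epicardial (RV-facing) surface
    septal_epi = np.flatnonzero((region == "septum") & (layer == "epi"))
    tree = cKDTree(positions[septal_epi])
    for u in np.flatnonzero(boundary):
        _, j = tree.query(positions[u])
        add_edge(int(u), int(septal_epi[j]))

    if not nx.is_connected(g):
        raise ValueError("malformed anatomy: conduction graph is disconnected")

    hg = HeartGraph(
        graph=g, positions=positions, region=region, layer=layer, spec=spec
    )

    # intrinsic breakout: right-bundle insertion at the basal anterior RV
    # septal margin -- the n_breakout_sites RV endocardial nodes nearest it
    theta_min = math.acos(_BASE_CUT_FRAC)
    ref = rv_center + np.array(
        [
            a_rv * math.sin(theta_min) * math.cos(_RV_HALF_ANGLE),
            a_rv * math.sin(theta_min) * math.sin(_RV_HALF_ANGLE),
            c_rv * _BASE_CUT_FRAC,
        ]
    )
    rv_endo = hg.select(region="rv_free_wall", layer="endo")
    d = np.linalg.norm(positions[rv_endo] - ref, axis=1)
    order = np.lexsort((rv_endo, d))  # distance, then lowest id
    hg.intrinsic_breakout_nodes = [
        int(rv_endo[i]) for i in order[: spec.n_breakout_sites]
    ]
    return hg


def _nearest(hg: HeartGraph, candidates: np.ndarray, ref: np.ndarray) -> int:
    if candidates.size == 0:
        raise ValueError("malformed graph: empty lead candidate region")
    d = np.linalg.norm(hg.positions[candidates] - ref, axis=1)
    order = np.lexsort((candidates, d))  # ties broken by lowest node id
    return int(candidates[order[0]])


def place_leads(hg: HeartGraph) -> HeartGraph:
    """Attach the CRT leads at standard positions (in place, returned).

    RV lead: RV endocardial node nearest the RV apex pole.  LV lead: LV
    epicardial free-wall node nearest the lateral equator (the mid lateral
    wall, opposite the septum).  Nearest-node ties break to the lowest id.
    """
    rv_endo = hg.select(region="rv_free_wall", layer="endo")
    apex_ref = np.array([0.0, 0.0, hg.positions[:, 2].min() - 1.0])
    hg.rv_lead = _nearest(hg, rv_endo, apex_ref)

    lv_epi = hg.select(region="lv_free_wall", layer="epi")
    lateral_ref = np.array([-(hg.positions[:, 0].max()), 0.0, 0.0])
    hg.lv_lead = _nearest(hg, lv_epi, lateral_ref)
    return hg


def calibrate_conduction(
    hg: HeartGraph, patient: PatientParams, tol_ms: float = 1.0
) -> PatientParams:
    """Find the velocity multiplier matching intrinsic VAT to the target.

    All edge traversal times are scaled by a single multiplier m; because
    shortest-path times are homogeneous in m, intrinsic VAT is monotone
    increasing in m and bisection on [0.1, 10] is well-posed.  Returns the
    patient with ``velocity_multiplier`` set such that the intrinsic
    activation span is within ``tol_ms`` of ``target_native_vat_ms``.
    """
    from .wavefront import fastest_arrival, intrinsic_sources

    if not hg.intrinsic_breakout_nodes:
        raise ValueError("graph has no intrinsic breakout nodes")
    target = patient.target_native_vat_ms
    sources = intrinsic_sources(hg, patient)

    def vat(m: float) -> float:
        amap = fastest_arrival(hg, sources, velocity_multiplier=m)
        return float(amap.times.max() - amap.times.min())

    lo, hi = _BISECT_BOUNDS
    f_lo, f_hi = vat(lo) - target, vat(hi) - target
    if f_lo > 0 or f_hi < 0:
        raise ValueError(
            f"target VAT {target:.1f} ms unreachable with multiplier in "
            f"[{lo}, {hi}] (achievable range {f_lo + target:.1f}"
            f"..{f_hi + target:.1f} ms)"
        )
    for _ in range(_BISECT_MAX_ITER):
        mid = 0.5 * (lo + hi)
        f_mid = vat(mid) - target
        if abs(f_mid) <= tol_ms:
            return patient.calibrated(mid)
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        f"calibration did not converge within {_BISECT_MAX_ITER} iterations"
    )
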