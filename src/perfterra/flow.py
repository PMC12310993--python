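"""Steady 1D blood flow on a vascular network.

Within each segment the reduced one-dimensional momentum balance with a
parabolic velocity profile, a rigid wall, and a uniform cross-section
reduces to Poiseuille's law: dp/dz = rho * N * Q / S^2 with N = -8*pi*nu,
i.e. a linear conductance g = S^2/(8*pi*mu*L) = pi*rbar^4/(8*mu*L) between
the segment's end nodes.  Mass conservation at junctions plus pressure
continuity yields a sparse symmetric nodal system: prescribed inlet
pressures are Dirichlet pins, territory demands enter as nodal
extractions (outlet nodes and segment-midpoint sink nodes).

Interfaces use mm / mL/min / mmHg; internally everything is CGS
(cm, cm^3/s, dyn/cm^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import UnsolvableComponentError, VascularNetwork, mean_segment_radius

__all__ = [
    "FluidConstants",
    "BoundaryConditions",
    "FlowSolution",
    "FlowDistribution",
    "build_system",
    "solve_steady_flow",
    "compute_distribution",
    "inlet_contribution_map",
    "DEFAULT_INLET_PRESSURE_MMHG",
]

MMHG_TO_DYN_CM2 = 1333.22
ML_MIN_TO_CM3_S = 1.0 / 60.0
MM_TO_CM = 0.1

#: mean aortic pressure applied at the ICA and BA inlets, mmHg
DEFAULT_INLET_PRESSURE_MMHG = 93.33


@dataclass
class FluidConstants:
    """Blood rheology for the 1D momentum balance (CGS units)."""

    density: float = 1.06  # g/cm^3
    viscosity: float = 0.04  # g/cm/s (dynamic)
    delta: float = 1.0 / 3.0  # velocity-profile parameter (parabolic profile)

    def __post_init__(self):
        if not (self.density > 0 and self.viscosity > 0):
            raise ValueError("density and viscosity must be positive")

    @property
    def nu(self) -> float:
        """Kinematic viscosity, cm^2/s."""
        return self.viscosity / self.density

    @property
    def viscous_loss(self) -> float:
        """N = -8*pi*nu, the viscous loss parameter."""
        return -8.0 * np.pi * self.nu


@dataclass
class BoundaryConditions:
    inlet_pressure_mmhg: dict[int, float]  # node id -> pressure
    outlet_flow_ml_min: dict[int, float] = field(default_factory=dict)  # node id -> Q
    midpoint_sink_ml_min: dict[int, float] = field(default_factory=dict)  # segment id -> Q

    def __post_init__(self):
        bad = [k for k, q in {**self.outlet_flow_ml_min,
                              **self.midpoint_sink_ml_min}.items() if q < 0]
        if bad:
            raise ValueError(f"negative sink flows at {bad}")


@dataclass
class _Edge:
    segment_id: int
    part: str  # "whole" | "proximal" | "distal"
    u: int  # proximal node key
    v: int  # distal node key
    conductance: float  # cm^3/s per dyn/cm^2


@dataclass
class _System:
    network: VascularNetwork
    bcs: BoundaryConditions
    constants: FluidConstants
    edges: list[_Edge]
    node_keys: list  # endpoint ids and ("mid", segment_id) tuples
    extraction: dict  # node key -> cm^3/s


@dataclass
class FlowSolution:
    """Signed per-segment flows (positive proximal -> distal) and nodal pressures."""

    system: _System
    node_pressure_mmhg: dict
    edge_flow_ml_min: list[float]  # aligned with system.edges
    inlet_inflow_ml_min: dict[int, float]
    conservation_residual: float  # max nodal imbalance / total inflow

    @property
    def segment_flow_ml_min(self) -> dict[int, float]:
        """Flow entering each segment at its proximal end."""
        out: dict[int, float] = {}
        for e, q in zip(self.system.edges, self.edge_flow_ml_min):
            if e.part in ("whole", "proximal"):
                out[e.segment_id] = q
        return out

    def segment_throughflow_ml_min(self, segment_id: int) -> float:
        """Net flow carried across a segment: the mean of the proximal and
        distal sub-segment flows (they differ by the midpoint sink; for a
        communicating artery this is the collateral throughflow)."""
        qs = [q for e, q in zip(self.system.edges, self.edge_flow_ml_min)
              if e.segment_id == segment_id]
        return float(np.mean(qs))

    @property
    def total_inflow_ml_min(self) -> float:
        return float(sum(self.inlet_inflow_ml_min.values()))

    def edge_table(self):
        import pandas as pd

        p = self.node_pressure_mmhg
        return pd.DataFrame(
            {
                "segment_id": [e.segment_id for e in self.system.edges],
                "part": [e.part for e in self.system.edges],
                "label": [self.system.network.segments[e.segment_id].label
                          for e in self.system.edges],
                "Q_mL_per_min": self.edge_flow_ml_min,
                "p_proximal_mmHg": [p[e.u] for e in self.system.edges],
                "p_distal_mmHg": [p[e.v] for e in self.system.edges],
            }
        )


@dataclass
class FlowDistribution:
    """Relative flow ratios (%) of the six major cerebral arteries and the
    three inflow vessels."""

    artery_ratio_pct: dict[str, float]
    inlet_ratio_pct: dict[str, float]
    artery_flow_ml_min: dict[str, float]
    inlet_flow_ml_min: dict[str, float]
    missing_arteries: list[str] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        rows = [("artery", k, self.artery_flow_ml_min[k], v)
                for k, v in self.artery_ratio_pct.items()]
        rows += [("inlet", k, self.inlet_flow_ml_min[k], v)
                 for k, v in self.inlet_ratio_pct.items()]
        return pd.DataFrame(rows, columns=["group", "vessel", "Q_mL_per_min", "ratio_pct"])


# ----------------------------------------------------------------- assembly
def build_system(
    network: VascularNetwork,
    bcs: BoundaryConditions,
    constants: FluidConstants | None = None,
) -> _System:
    """Assemble segment conductances and nodal sinks.

    Segments carrying a midpoint sink are split at their arclength midpoint
    into two half-length sub-segments (same mean radius — the segment's
    cross-section is uniform), and the sink attaches to the new node.
    Raises :class:`UnsolvableComponentError` if some connected component
    has no pressure-pinned inlet.
    """
    import networkx as nx

    constants = constants or FluidConstants()
    edges: list[_Edge] = []
    extraction: dict = {}
    node_keys: set = set()

    for sid in sorted(network.segments):
        seg = network.segments[sid]
        u, v = seg.point_ids[0], seg.point_ids[-1]
        length_cm = network.segment_arclength(sid) * MM_TO_CM
        rbar_cm = mean_segment_radius(network, sid) * MM_TO_CM
        g = np.pi * rbar_cm**4 / (8.0 * constants.viscosity * length_cm)
        if sid in bcs.midpoint_sink_ml_min:
            mid = ("mid", sid)
            g_half = np.pi * rbar_cm**4 / (8.0 * constants.viscosity * (length_cm / 2.0))
            edges.append(_Edge(sid, "proximal", u, mid, g_half))
            edges.append(_Edge(sid, "distal", mid, v, g_half))
            extraction[mid] = bcs.midpoint_sink_ml_min[sid] * ML_MIN_TO_CM3_S
            node_keys.update((u, mid, v))
        else:
            edges.append(_Edge(sid, "whole", u, v, g))
            node_keys.update((u, v))

    for node, q in bcs.outlet_flow_ml_min.items():
        if node not in node_keys:
            raise KeyError(f"outlet flow prescribed at unknown node {node}")
        extraction[node] = extraction.get(node, 0.0) + q * ML_MIN_TO_CM3_S

    # every component must contain a pinned inlet
    g_conn = nx.Graph()
    for e in edges:
        g_conn.add_edge(e.u, e.v, segment=e.segment_id)
    pinned = set(bcs.inlet_pressure_mmhg)
    for comp in nx.connected_components(g_conn):
        if not (comp & pinned):
            labels = sorted(
                {str(network.segments[d["segment"]].label or d["segment"])
                 for _, _, d in g_conn.subgraph(comp).edges(data=True)}
            )
            raise UnsolvableComponentError(
                f"connected component without an inlet pressure: segments {labels}"
            )
    return _System(network, bcs, constants, edges, sorted(node_keys, key=str), extraction)


def solve_steady_flow(system: _System) -> FlowSolution:
    """Solve the sparse nodal pressure system and recover segment flows."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.linalg import spsolve

    keys = system.node_keys
    index = {k: i for i, k in enumerate(keys)}
    n = len(keys)

    rows, cols, vals = [], [], []
    for e in system.edges:
        i, j = index[e.u], index[e.v]
        rows += [i, j, i, j]
        cols += [i, j, j, i]
        vals += [e.conductance, e.conductance, -e.conductance, -e.conductance]
    lap = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    b = np.zeros(n)
    for k, q in system.extraction.items():
        b[index[k]] -= q  # extraction = negative injection

    # solve for the deviation from a reference inlet pressure: pressure drops
    # are tiny against the absolute head, and the shift removes the
    # catastrophic cancellation in p_u - p_v
    ref = max(system.bcs.inlet_pressure_mmhg.values()) * MMHG_TO_DYN_CM2
    fixed = {index[k]: p * MMHG_TO_DYN_CM2 - ref
             for k, p in system.bcs.inlet_pressure_mmhg.items() if k in index}
    free = np.array([i for i in range(n) if i not in fixed], dtype=np.int64)
    p = np.zeros(n)
    for i, val in fixed.items():
        p[i] = val
    if free.size:
        a_ff = lap[free][:, free]
        rhs = b[free] - lap[free][:, sorted(fixed)] @ np.array(
            [fixed[i] for i in sorted(fixed)])
        try:
            p[free] = spsolve(a_ff.tocsc(), rhs)
        except Exception as exc:  # pragma: no cover - guarded by build_system
            raise RuntimeError(f"singular flow system: {exc}") from exc
        if not np.all(np.isfinite(p)):
            raise RuntimeError("flow solve produced non-finite pressures")

    edge_q_cgs = [e.conductance * (p[index[e.u]] - p[index[e.v]]) for e in system.edges]

    # conservation check at free nodes
    imbalance = lap @ p - b
    inflow_cgs = {}
    for node in system.bcs.inlet_pressure_mmhg:
        if node in index:
            q = sum(q_e for e, q_e in zip(system.edges, edge_q_cgs) if e.u == node)
            q -= sum(q_e for e, q_e in zip(system.edges, edge_q_cgs) if e.v == node)
            inflow_cgs[node] = q
    total_in = sum(inflow_cgs.values())
    residual = float(np.max(np.abs(imbalance[free])) / abs(total_in)) if (
        free.size and total_in) else 0.0

    return FlowSolution(
        system=system,
        node_pressure_mmhg={k: (p[index[k]] + ref) / MMHG_TO_DYN_CM2 for k in keys},
        edge_flow_ml_min=[q / ML_MIN_TO_CM3_S for q in edge_q_cgs],
        inlet_inflow_ml_min={k: q / ML_MIN_TO_CM3_S for k, q in inflow_cgs.items()},
        conservation_residual=residual,
    )


# ------------------------------------------------------------- distribution
#: measurement segments: flow ratios of the major cerebral arteries are read
#: in the M1, A1 and P2 segments
DEFAULT_ARTERY_LABELS = {
    "LMCA": "LMCA-M1", "RMCA": "RMCA-M1",
    "LACA": "LACA-A1", "RACA": "RACA-A1",
    "LPCA": "LPCA-P2", "RPCA": "RPCA-P2",
}
DEFAULT_INLET_LABELS = {"LICA": "LICA", "RICA": "RICA", "BA": "BA"}


def compute_distribution(
    solution: FlowSolution,
    artery_labels: dict[str, str] | None = None,
    inlet_labels: dict[str, str] | None = None,
) -> FlowDistribution:
    """Relative flow ratios (%) at the artery measurement segments and the
    inlets.  Arteries whose labeled segment is absent (anatomical variants)
    are flagged and ratios renormalized over the present ones."""
    artery_labels = artery_labels or DEFAULT_ARTERY_LABELS
    inlet_labels = inlet_labels or DEFAULT_INLET_LABELS
    net = solution.system.network
    by_label = {seg.label: sid for sid, seg in net.segments.items() if seg.label}

    seg_flow = solution.segment_flow_ml_min
    flows, missing = {}, []
    for artery, label in artery_labels.items():
        if label in by_label and by_label[label] in seg_flow:
            flows[artery] = abs(seg_flow[by_label[label]])
        else:
            missing.append(artery)
    total = sum(flows.values())
    ratios = {a: 100.0 * q / total for a, q in flows.items()} if total else {}

    # inlet inflows, named through the label of the segment touching each inlet
    inlet_name = {}
    for name, label in inlet_labels.items():
        if label in by_label:
            seg = net.segments[by_label[label]]
            for nid in (seg.point_ids[0], seg.point_ids[-1]):
                if nid in solution.inlet_inflow_ml_min:
                    inlet_name[name] = nid
    inlet_flows = {name: solution.inlet_inflow_ml_min[nid]
                   for name, nid in inlet_name.items()}
    for nid in solution.inlet_inflow_ml_min:
        if nid not in inlet_name.values():
            inlet_flows[f"inlet_{nid}"] = solution.inlet_inflow_ml_min[nid]
    tot_in = sum(inlet_flows.values())
    inlet_ratios = {k: 100.0 * q / tot_in for k, q in inlet_flows.items()} if tot_in else {}

    return FlowDistribution(ratios, inlet_ratios, flows, inlet_flows, missing)


# ------------------------------------------------- inlet contribution mixing
def inlet_contribution_map(
    solution: FlowSolution, assignment=None, zero_flow_tol: float = 1e-12
) -> dict:
    """Fraction of each sink's supply originating from each inlet.

    At every node the outflow composition equals the flow-weighted average
    of its inflow compositions (perfect mixing); inlets are pure.  The
    steady flow field is acyclic in the direction of flow (pressure strictly
    decreases), so compositions are resolved by processing nodes in
    decreasing pressure order.  Returns ``{"nodes": {node: {inlet: f}},
    "sources": {source_id: {inlet: f}}}``; the per-source entry reads the
    composition at the node its demand is extracted from.  Nodes fed only
    through (numerically) zero-flow edges get an empty composition.
    """
    sys_ = solution.system
    inlets = [k for k in sys_.bcs.inlet_pressure_mmhg if k in sys_.node_keys]
    p = solution.node_pressure_mmhg
    qref = max(abs(solution.total_inflow_ml_min), 1.0)

    inflows: dict = {k: [] for k in sys_.node_keys}  # node -> [(q_in, from_node)]
    for e, q in zip(sys_.edges, solution.edge_flow_ml_min):
        if abs(q) <= zero_flow_tol * qref:
            continue
        if q > 0:
            inflows[e.v].append((q, e.u))
        else:
            inflows[e.u].append((-q, e.v))

    comp: dict = {}
    for node in inlets:
        comp[node] = {node: 1.0}
    for node in sorted((k for k in sys_.node_keys if k not in comp),
                       key=lambda k: -p[k]):
        feeds = inflows[node]
        total = sum(q for q, _ in feeds)
        mix: dict = {}
        if total > 0:
            for q, up in feeds:
                for inlet, f in comp.get(up, {}).items():
                    mix[inlet] = mix.get(inlet, 0.0) + f * q / total
        comp[node] = mix

    out = {"nodes": comp, "sources": {}}
    if assignment is not None:
        for s in assignment.sources:
            key = s.network_point_id if s.kind == "outlet" else ("mid", s.segment_id)
            out["sources"][s.id] = dict(comp.get(key, {}))
    return out
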