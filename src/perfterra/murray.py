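"""Murray's-law outlet boundary conditions (comparator model).

Murray's law states that flow through a vessel scales with the cube of its
radius; the total tissue demand Q_total = rho * sum_k v_k * CBF_k is split
among the network outlets in proportion to r_i^3.  Perforator perfusion is
not modelled here — no midpoint sinks are generated — so the same network
solve with these outlet flows isolates the effect of the boundary model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import VascularNetwork
from .tissue import TissueClassTable, TissueMesh, total_demand

__all__ = ["MurrayAllocation", "murray_flows", "outlet_radii", "murray_boundary"]


@dataclass
class MurrayAllocation:
    outlet_flow_ml_min: dict[int, float]  # outlet node id -> flow
    q_total_ml_min: float


def murray_flows(radii: dict[int, float], q_total: float) -> MurrayAllocation:
    """Split ``q_total`` over outlets with weights r_i^3 / sum_j r_j^3."""
    if not radii:
        raise ValueError("empty outlet set")
    if any(r <= 0 for r in radii.values()):
        raise ValueError("outlet radii must be positive")
    keys = sorted(radii)
    cubes = np.array([radii[k] ** 3 for k in keys])
    weights = cubes / cubes.sum()
    # exact normalization: all shares but one are q_total * w_i; the
    # second-largest share is computed as the residual q_total - sum(rest)
    # and summed last.  Its weight is <= 1/2, so the running sum of the
    # rest lies in [q_total/2, q_total] and the final addition restores
    # q_total bit-for-bit (Sterbenz), with the residual safely positive.
    flows: dict[int, float] = {}
    if len(keys) == 1:
        flows[keys[0]] = float(q_total)
    else:
        order = np.argsort(weights, kind="stable")
        residual_key = keys[int(order[-2])]
        for k, w in zip(keys, weights):
            if k != residual_key:
                flows[k] = q_total * w
        flows[residual_key] = q_total - sum(flows.values())
    return MurrayAllocation(flows, q_total)


def outlet_radii(
    network: VascularNetwork, window_mm: float = 1.0, terminal_point: bool = False
) -> dict[int, float]:
    """Radius of each outlet, keyed by outlet node id.

    Default: arclength-weighted mean radius over the distal-most
    ``window_mm`` of the outlet segment; ``terminal_point=True`` uses the
    terminal point's radius instead.
    """
    out: dict[int, float] = {}
    for node in network.outlet_nodes():
        seg = next(
            network.segments[sid]
            for sid in network.segments
            if node in (network.segments[sid].point_ids[0],
                        network.segments[sid].point_ids[-1])
        )
        pids = seg.point_ids if seg.point_ids[-1] == node else seg.point_ids[::-1]
        if terminal_point:
            out[node] = network.points[node].radius
            continue
        pos = network.positions(pids)
        rad = network.radii(pids)
        step = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        # walk backwards from the terminal point accumulating window_mm
        acc = 0.0
        num = 0.0
        den = 0.0
        for k in range(len(step) - 1, -1, -1):
            take = min(step[k], window_mm - acc)
            if take <= 0:
                break
            # radius varies linearly over the interval; integrate the distal part
            r1, r0 = rad[k + 1], rad[k]
            t = take / step[k] if step[k] > 0 else 0.0
            r_inner = r1 + (r0 - r1) * t  # radius at the proximal end of the slice
            num += 0.5 * (r1 + r_inner) * take
            den += take
            acc += take
        out[node] = float(num / den) if den > 0 else network.points[node].radius
    return out


def murray_boundary(
    network: VascularNetwork,
    mesh: TissueMesh,
    table: TissueClassTable,
    window_mm: float = 1.0,
    terminal_point: bool = False,
) -> MurrayAllocation:
    """Convenience: total demand of the whole mesh split by Murray's law."""
    q_total = total_demand(mesh, table)
    return murray_flows(outlet_radii(network, window_mm, terminal_point), q_total)
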