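"""Centerline-based vascular networks.

A network is a collection of :class:`CenterlinePoint` (position + lumen
radius, both in mm) organized into :class:`Segment` objects — maximal
polylines between junction points.  Segments meet only at shared endpoint
points; endpoints of graph degree 1 are terminals (inlets if flagged,
outlets otherwise) and nodes of degree >= 3 are junctions.

The module covers reading/writing (a JSON dialect and VTK XML PolyData),
resampling to uniform point spacing, arclength-weighted mean radii, and
radius-threshold truncation with protected vessels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import _vtkxml

__all__ = [
    "CenterlinePoint",
    "Segment",
    "VascularNetwork",
    "load_network",
    "save_network",
    "resample_centerline",
    "mean_segment_radius",
    "truncate_network",
]


@dataclass
class CenterlinePoint:
    """A single centerline sample: position (mm) and inscribed radius (mm)."""

    id: int
    position: np.ndarray  # shape (3,), mm
    radius: float  # mm

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"point {self.id}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"point {self.id}: non-finite coordinates")
        if not (self.radius > 0):
            raise ValueError(f"point {self.id}: radius must be > 0, got {self.radius}")


@dataclass
class Segment:
    """An ordered run of centerline points between two junction/terminal nodes."""

    id: int
    point_ids: list[int]
    label: str | None = None
    is_virtual: bool = False

    def __post_init__(self) -> None:
        if len(self.point_ids) < 2:
            raise ValueError(f"segment {self.id}: needs >= 2 points")


class NetworkValidationError(ValueError):
    pass


class UnsolvableComponentError(RuntimeError):
    """A connected component has no pressure-pinned inlet node."""


@dataclass
class VascularNetwork:
    points: dict[int, CenterlinePoint] = field(default_factory=dict)
    segments: dict[int, Segment] = field(default_factory=dict)
    inlets: set[int] = field(default_factory=set)  # point ids of inlet terminals

    # ------------------------------------------------------------------ basics
    def copy(self) -> "VascularNetwork":
        return VascularNetwork(
            points={i: replace(p, position=p.position.copy()) for i, p in self.points.items()},
            segments={i: replace(s, point_ids=list(s.point_ids)) for i, s in self.segments.items()},
            inlets=set(self.inlets),
        )

    def positions(self, point_ids) -> np.ndarray:
        return np.array([self.points[i].position for i in point_ids], dtype=float)

    def radii(self, point_ids) -> np.ndarray:
        return np.array([self.points[i].radius for i in point_ids], dtype=float)

    # ------------------------------------------------------------- node layer
    def node_degrees(self) -> dict[int, int]:
        """Degree of each segment endpoint in the segment-endpoint graph."""
        deg: dict[int, int] = {}
        for seg in self.segments.values():
            for nid in (seg.point_ids[0], seg.point_ids[-1]):
                deg[nid] = deg.get(nid, 0) + 1
        return deg

    def node_roles(self) -> dict[int, str]:
        """Map endpoint node id -> 'inlet' | 'outlet' | 'junction'."""
        roles = {}
        for nid, deg in self.node_degrees().items():
            if nid in self.inlets:
                roles[nid] = "inlet"
            elif deg == 1:
                roles[nid] = "outlet"
            else:
                roles[nid] = "junction"
        return roles

    def outlet_nodes(self) -> list[int]:
        return sorted(n for n, r in self.node_roles().items() if r == "outlet")

    def outlet_segments(self) -> list[int]:
        """Segments owning at least one outlet endpoint."""
        outs = set(self.outlet_nodes())
        return sorted(
            sid
            for sid, seg in self.segments.items()
            if seg.point_ids[0] in outs or seg.point_ids[-1] in outs
        )

    # ------------------------------------------------------------ geometry
    def segment_arclength(self, segment_id: int) -> float:
        pos = self.positions(self.segments[segment_id].point_ids)
        return float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())

    def total_arclength(self) -> float:
        return sum(self.segment_arclength(s) for s in self.segments)

    def segment_midpoint(self, segment_id: int) -> np.ndarray:
        """Position at half the segment's arclength (linear interpolation)."""
        pos = self.positions(self.segments[segment_id].point_ids)
        seglen = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seglen)])
        half = 0.5 * s[-1]
        k = int(np.searchsorted(s, half, side="right") - 1)
        k = min(k, len(seglen) - 1)
        t = (half - s[k]) / seglen[k] if seglen[k] > 0 else 0.0
        return pos[k] + t * (pos[k + 1] - pos[k])

    # ------------------------------------------------------------ validation
    def validate(self) -> None:
        bad = [i for i, p in self.points.items() if not (p.radius > 0)]
        if bad:
            raise NetworkValidationError(f"non-positive radius at points {bad}")
        for seg in self.segments.values():
            for pid in seg.point_ids:
                if pid not in self.points:
                    raise NetworkValidationError(
                        f"segment {seg.id} references missing point {pid}"
                    )
            if self.segment_arclength(seg.id) <= 0:
                raise NetworkValidationError(f"segment {seg.id} has zero arclength")
        # interior points must not be shared between segments
        interior: set[int] = set()
        for seg in self.segments.values():
            interior.update(seg.point_ids[1:-1])
        for seg in self.segments.values():
            for nid in (seg.point_ids[0], seg.point_ids[-1]):
                if nid in interior:
                    raise NetworkValidationError(
                        f"segment {seg.id} endpoint {nid} is interior to another segment"
                    )
        deg = self.node_degrees()
        for nid in self.inlets:
            if nid not in deg:
                raise NetworkValidationError(f"inlet {nid} is not a segment endpoint")

    # ------------------------------------------------- segment-level topology
    def segment_graph(self):
        """networkx MultiGraph on endpoint nodes with one edge per segment."""
        import networkx as nx

        g = nx.MultiGraph()
        for sid, seg in self.segments.items():
            g.add_edge(seg.point_ids[0], seg.point_ids[-1], key=sid, segment=sid)
        return g

    def orient_from_inlets(self) -> None:
        """Reverse segment point order so the proximal end comes first.

        Proximal = nearer an inlet by breadth-first search over the segment
        graph.  Loop segments whose two ends are reached at the same BFS
        depth keep their stored orientation (fixed and recorded).
        """
        import networkx as nx

        g = self.segment_graph()
        if not self.inlets:
            return
        dist = nx.multi_source_dijkstra_path_length(g, set(self.inlets) & set(g.nodes))
        for seg in self.segments.values():
            a, b = seg.point_ids[0], seg.point_ids[-1]
            da, db = dist.get(a, np.inf), dist.get(b, np.inf)
            if db < da:
                seg.point_ids.reverse()


# ---------------------------------------------------------------------- I/O
def load_network(path: str | Path, dialect: str | None = None,
                 radius_array: str | None = None) -> VascularNetwork:
    """Read a network from JSON or VTK XML PolyData (.vtp).

    ``dialect`` is inferred from the file suffix when omitted.  For VTP,
    polylines become segments and the per-point radius is taken from a
    point-data array named ``radius_array`` (default: first of
    "MaximumInscribedSphereRadius", "radius").
    """
    path = Path(path)
    if dialect is None:
        dialect = "vtp" if path.suffix.lower() == ".vtp" else "json"
    if dialect == "json":
        doc = json.loads(path.read_text())
        net = VascularNetwork()
        for p in doc["points"]:
            net.points[int(p["id"])] = CenterlinePoint(
                int(p["id"]), np.asarray(p["xyz"], float), float(p["radius"])
            )
        for s in doc["segments"]:
            net.segments[int(s["id"])] = Segment(
                int(s["id"]),
                [int(i) for i in s["point_ids"]],
                s.get("label"),
                bool(s.get("is_virtual", False)),
            )
        net.inlets = {int(i) for i in doc.get("inlets", [])}
    elif dialect == "vtp":
        xyz, lines, point_data, meta = _vtkxml.read_polydata(path)
        names = [radius_array] if radius_array else [
            "MaximumInscribedSphereRadius", "radius"]
        radii = None
        for name in names:
            if name in point_data:
                radii = point_data[name]
                break
        if radii is None:
            raise NetworkValidationError(
                f"no radius point-data array found (looked for {names}; "
                f"present: {sorted(point_data)})"
            )
        net = VascularNetwork()
        for i, (p, r) in enumerate(zip(xyz, radii)):
            net.points[i] = CenterlinePoint(i, p, float(r))
        for sid, conn in enumerate(lines):
            net.segments[sid] = Segment(sid, [int(i) for i in conn],
                                        meta.get("labels", {}).get(str(sid)))
        net.inlets = {int(i) for i in meta.get("inlets", [])}
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    net.validate()
    return net


def save_network(net: VascularNetwork, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    if dialect is None:
        dialect = "vtp" if path.suffix.lower() == ".vtp" else "json"
    if dialect == "json":
        doc = {
            "points": [
                {"id": i, "xyz": [float(x) for x in p.position], "radius": p.radius}
                for i, p in sorted(net.points.items())
            ],
            "segments": [
                {"id": i, "point_ids": s.point_ids, "label": s.label,
                 "is_virtual": s.is_virtual}
                for i, s in sorted(net.segments.items())
            ],
            "inlets": sorted(net.inlets),
        }
        path.write_text(json.dumps(doc, indent=1))
    elif dialect == "vtp":
        # VTP stores points 0..n-1 positionally; remap ids
        order = sorted(net.points)
        index = {pid: k for k, pid in enumerate(order)}
        xyz = np.array([net.points[i].position for i in order])
        radii = np.array([net.points[i].radius for i in order])
        lines = [[index[i] for i in net.segments[s].point_ids] for s in sorted(net.segments)]
        meta = {
            "inlets": sorted(index[i] for i in net.inlets),
            "labels": {
                str(k): net.segments[s].label
                for k, s in enumerate(sorted(net.segments))
                if net.segments[s].label
            },
        }
        _vtkxml.write_polydata(path, xyz, lines, {"radius": radii}, meta)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# --------------------------------------------------------------- operations
def resample_centerline(net: VascularNetwork, spacing: float) -> VascularNetwork:
    """Resample every segment to uniform point spacing (mm).

    Junction and terminal positions are preserved exactly; interior points
    are placed at arclengths spacing, 2*spacing, ... with the final interval
    possibly shorter.  Radii are linearly interpolated along arclength.
    """
    if not (spacing > 0):
        raise ValueError("spacing must be > 0")
    out = VascularNetwork(inlets=set(net.inlets))
    for nid in {s.point_ids[k] for s in net.segments.values() for k in (0, -1)}:
        p = net.points[nid]
        out.points[nid] = CenterlinePoint(nid, p.position.copy(), p.radius)
    next_id = max(net.points) + 1 if net.points else 0
    for sid in sorted(net.segments):
        seg = net.segments[sid]
        pos = net.positions(seg.point_ids)
        rad = net.radii(seg.point_ids)
        step = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(step)])
        total = s[-1]
        # interior sample arclengths; drop samples within 1e-9 of the far end
        n_in = int(np.floor((total - 1e-9) / spacing))
        targets = spacing * np.arange(1, n_in + 1)
        new_ids = [seg.point_ids[0]]
        for t in targets:
            p = np.array([np.interp(t, s, pos[:, k]) for k in range(3)])
            r = float(np.interp(t, s, rad))
            out.points[next_id] = CenterlinePoint(next_id, p, r)
            new_ids.append(next_id)
            next_id += 1
        new_ids.append(seg.point_ids[-1])
        out.segments[sid] = Segment(sid, new_ids, seg.label, seg.is_virtual)
    out.validate()
    return out


def mean_segment_radius(net: VascularNetwork, segment_id: int) -> float:
    """Arclength-weighted (trapezoidal) mean radius of a segment, mm."""
    seg = net.segments[segment_id]
    pos = net.positions(seg.point_ids)
    rad = net.radii(seg.point_ids)
    step = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    total = step.sum()
    if total <= 0:
        raise NetworkValidationError(f"segment {segment_id} has zero arclength")
    return float((0.5 * (rad[:-1] + rad[1:]) * step).sum() / total)


def truncate_network(
    net: VascularNetwork,
    r_t: float,
    protected: set[str] | None = None,
    excluded: set[str] | None = None,
) -> VascularNetwork:
    """Remove thin vessels and everything they alone supplied.

    Every segment with arclength-weighted mean radius < ``r_t`` whose label
    is neither protected nor excluded is removed; afterwards any segment no
    longer connected to an inlet is removed as well (this is what "removing
    a branch removes its children" means on a tree, while vessels kept alive
    through a collateral loop survive).  New degree-1 distal nodes become
    outlets.  Raises if a protected segment would lose all inlet supply.
    """
    import networkx as nx

    if r_t < 0:
        raise ValueError("truncation radius must be >= 0")
    protected = protected or set()
    excluded = excluded or set()
    keep_labels = protected | excluded

    out = net.copy()
    if r_t > 0:
        direct = {
            sid
            for sid, seg in out.segments.items()
            if (seg.label not in keep_labels)
            and mean_segment_radius(out, sid) < r_t
        }
        # never remove a segment that carries an inlet terminal
        direct = {
            sid for sid in direct
            if not ({out.segments[sid].point_ids[0], out.segments[sid].point_ids[-1]}
                    & out.inlets)
        }
        for sid in direct:
            del out.segments[sid]
        # orphan sweep: drop segments with no path to an inlet
        g = out.segment_graph()
        reachable: set[int] = set()
        for inlet in out.inlets:
            if inlet in g:
                reachable |= nx.node_connected_component(g, inlet)
        orphaned = {
            sid for sid, seg in out.segments.items()
            if seg.point_ids[0] not in reachable
        }
        for sid in orphaned:
            if out.segments[sid].label in protected:
                raise NetworkValidationError(
                    f"truncation at r_t={r_t} would disconnect protected segment "
                    f"{out.segments[sid].label!r} from all inlets"
                )
            del out.segments[sid]
    used = {pid for seg in out.segments.values() for pid in seg.point_ids}
    out.points = {i: p for i, p in out.points.items() if i in used}
    out.inlets &= used
    out.validate()
    return out
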