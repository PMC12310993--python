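"""Deterministic toy geometries: vascular-network templates (including a
circle-of-Willis-like loop) and labeled tetrahedral tissue phantoms.

Everything here is synthetic stand-in geometry for the image-derived
networks and meshes the model is designed for; it exists so that every
other module is exercisable and testable without any imaging data.  The
toy circle of Willis has three inlets (LICA, RICA, BA), the six major
cerebral arteries with labeled M1/A1/P2 measurement segments, the
communicating arteries (ACoA, L/R PCoA) as collateral loops, and small
outlet trees with branch radii spread over 0.4-0.9 mm so that the
truncation sweep prunes them gradually.  Bilateral structures are built
as exact mirror images (x -> -x is bitwise on IEEE floats), so
left/right symmetry tests can assert near-exact equality.

The tissue phantom is a structured box of tetrahedra (each grid cell
split into five, parity-alternated for conformity, mirrored across the
midplane), with an outer "gray" shell (CBF 0.8) around a "white" core
(CBF 0.2).  Convex by construction, as required for checking the
tessellation against the pure weighted-Voronoi rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import CenterlinePoint, Segment, VascularNetwork, resample_centerline
from .tissue import TissueMesh

__all__ = ["PhantomSpec", "make_phantom", "box_mesh", "perturb_radii",
           "DEFAULT_PROTECTED"]

#: segment labels never removed by the truncation sweep: the origins of the
#: MCA/ACA/PCA (measurement segments) and their parent vessels, including
#: the communicating arteries of the loop.
DEFAULT_PROTECTED = frozenset({
    "LICA", "RICA", "BA",
    "LMCA-M1", "RMCA-M1", "LACA-A1", "RACA-A1",
    "LPCA-P1", "RPCA-P1", "LPCA-P2", "RPCA-P2",
    "ACoA", "LPCoA", "RPCoA",
})


@dataclass
class PhantomSpec:
    """Parameters of a synthetic network + tissue phantom (all mm)."""

    template: str = "toy_cow"  # single_segment | y_tree | binary_tree | toy_cow
    seed: int = 0
    # tissue box: x and y centered on 0, z in [z0, z0 + extent_z]
    box_extent: tuple = (68.0, 56.0, 24.0)
    box_z0: float = 0.0
    cells: tuple = (16, 12, 8)
    gray_shell_mm: float = 4.5
    # network
    spacing: float | None = 0.5  # centerline resampling, None = keep waypoints
    tree_depth: int = 3  # binary_tree only
    acoa: bool = True
    lpcoa: bool = True
    rpcoa: bool = True
    variant: str | None = None  # None | disconnected_lmca | fetal_rpca


# =====================================================================
# tissue phantom
# =====================================================================
def box_mesh(cells=(8, 8, 8), extent=(40.0, 40.0, 40.0), z0: float = 0.0,
             gray_shell_mm: float | None = None) -> TissueMesh:
    """Structured, mirror-symmetric tetrahedral box.

    Each grid cell is split into five tetrahedra with the corner pattern
    alternating by cell parity (conforming); cells left of the midplane
    x=0 are exact mirror images of their right counterparts and the two
    are interleaved in the element list, so mirrored elements carry
    bitwise-equal volumes.  ``gray_shell_mm`` labels elements whose
    centroid lies within that distance of the box surface "gray", the
    rest "white"; ``None`` labels everything "other".
    """
    nx, ny, nz = cells
    if nx % 2:
        raise ValueError("nx must be even (midplane at x=0)")
    ex, ey, ez = extent
    dx, dy, dz = ex / nx, ey / ny, ez / nz

    def node_id(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    ii, jj, kk = np.meshgrid(np.arange(nx + 1), np.arange(ny + 1),
                             np.arange(nz + 1), indexing="ij")
    nodes = np.stack([
        (ii - nx / 2) * dx,        # exact negation under i -> nx - i
        (jj - ny / 2) * dy,
        z0 + kk * dz,
    ], axis=-1).reshape(-1, 3)

    def mirror_node(n):
        k = n % (nz + 1)
        j = (n // (nz + 1)) % (ny + 1)
        i = n // ((ny + 1) * (nz + 1))
        return node_id(nx - i, j, k)

    # five-tet corner patterns by parity (corner coords as (di, dj, dk))
    def five_tets(p):
        if p == 0:
            a, b, c, d = (0, 0, 0), (1, 1, 0), (1, 0, 1), (0, 1, 1)
            corners = [((1, 0, 0), a, b, c), ((0, 1, 0), a, b, d),
                       ((0, 0, 1), a, c, d), ((1, 1, 1), b, c, d)]
        else:
            a, b, c, d = (1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1)
            corners = [((0, 0, 0), a, b, c), ((1, 1, 0), a, b, d),
                       ((1, 0, 1), a, c, d), ((0, 1, 1), b, c, d)]
        return [(a, b, c, d)] + corners

    tets = []
    for i in range(nx // 2, nx):  # right half; mirror fills the left
        for j in range(ny):
            for k in range(nz):
                p = (i + j + k) % 2
                for corner_set in five_tets(p):
                    tet = [node_id(i + di, j + dj, k + dk)
                           for di, dj, dk in corner_set]
                    tets.append(tet)
                    tets.append([mirror_node(n) for n in tet])
    tets = np.array(tets, np.int64)

    centroids = nodes[tets].mean(axis=1)
    if gray_shell_mm is None:
        labels = ["other"] * len(tets)
    else:
        margin = np.minimum.reduce([
            ex / 2 - np.abs(centroids[:, 0]),
            ey / 2 - np.abs(centroids[:, 1]),
            centroids[:, 2] - z0,
            z0 + ez - centroids[:, 2],
        ])
        labels = np.where(margin <= gray_shell_mm, "gray", "white").tolist()
    return TissueMesh(nodes, tets, labels)


# =====================================================================
# network builder
# =====================================================================
class _Builder:
    def __init__(self):
        self.net = VascularNetwork()
        self._next_point = 0
        self._next_segment = 0

    def _point(self, xyz, r) -> int:
        pid = self._next_point
        self.net.points[pid] = CenterlinePoint(pid, np.asarray(xyz, float), float(r))
        self._next_point += 1
        return pid

    def add(self, waypoints, radii, label=None, start=None, end=None,
            inlet_start=False) -> tuple[int, int]:
        """Add one polyline segment; ``start``/``end`` reuse existing nodes."""
        waypoints = [np.asarray(w, float) for w in waypoints]
        radii = (list(radii) if np.iterable(radii)
                 else list(np.linspace(radii, radii, len(waypoints))))
        if len(radii) == 2 and len(waypoints) > 2:
            # linear in arclength between the two end radii
            steps = np.linalg.norm(np.diff(np.array(waypoints), axis=0), axis=1)
            s = np.concatenate([[0.0], np.cumsum(steps)])
            radii = list(np.interp(s, [0, s[-1]], radii))
        ids = []
        for k, (w, r) in enumerate(zip(waypoints, radii)):
            if k == 0 and start is not None:
                ids.append(start)
            elif k == len(waypoints) - 1 and end is not None:
                ids.append(end)
            else:
                ids.append(self._point(w, r))
        sid = self._next_segment
        self.net.segments[sid] = Segment(sid, ids, label)
        self._next_segment += 1
        if inlet_start:
            self.net.inlets.add(ids[0])
        return ids[0], ids[-1]

    def add_bilateral(self, waypoints_right, radii, label_right, label_left,
                      start=(None, None), end=(None, None), inlet_start=False):
        """Add a right-side polyline and its exact mirror image (x -> -x)."""
        r0, re = self.add(waypoints_right, radii, label_right,
                          start[0], end[0], inlet_start)
        left = [np.array([-w[0], w[1], w[2]]) for w in
                (np.asarray(w, float) for w in waypoints_right)]
        l0, le = self.add(left, radii, label_left, start[1], end[1], inlet_start)
        return (r0, l0), (re, le)


def _toy_cow(spec: PhantomSpec) -> VascularNetwork:
    b = _Builder()
    # inflow vessels
    _, (ica_r, ica_l) = b.add_bilateral(
        [(15, 0, -20), (14, 0, -12), (12.5, 0, -4), (12, 0, 0)],
        [2.0, 2.0], "RICA", "LICA", inlet_start=True)
    _, ba_top = b.add(
        [(0, -18, -20), (0, -16, -10), (0, -14, -2), (0, -14, 0)],
        [1.6, 1.6], "BA", inlet_start=True)

    # M1 (measurement segments of the MCA)
    _, (m1_r, m1_l) = b.add_bilateral(
        [(12, 0, 0), (15.5, 1, 1), (20, 2, 2)], [1.5, 1.4],
        "RMCA-M1", "LMCA-M1", start=(ica_r, ica_l))
    # A1 (measurement segments of the ACA)
    _, (a1_r, a1_l) = b.add_bilateral(
        [(12, 0, 0), (8, 5, 1.5), (2.5, 8, 2)], [1.2, 1.1],
        "RACA-A1", "LACA-A1", start=(ica_r, ica_l))
    # anterior communicating artery (midline, symmetric waypoints)
    if spec.acoa:
        acoa_x = np.arange(2.5, -2.51, -0.5)  # exact halves: bitwise symmetric
        b.add([(x, 8, 2) for x in acoa_x], [0.74] * len(acoa_x),
              "ACoA", start=a1_r, end=a1_l)
    # P1 from the basilar top
    _, (pj_r, pj_l) = b.add_bilateral(
        [(0, -14, 0), (4.5, -13, 0.5), (9, -11, 1)], [1.1, 1.05],
        "RPCA-P1", "LPCA-P1", start=(ba_top, ba_top))
    # posterior communicating arteries
    if spec.rpcoa:
        b.add([(12, 0, 0), (11, -4, 0.5), (9, -11, 1)], [0.71, 0.71],
              "RPCoA", start=ica_r, end=pj_r)
    if spec.lpcoa:
        b.add([(-12, 0, 0), (-11, -4, 0.5), (-9, -11, 1)], [0.71, 0.71],
              "LPCoA", start=ica_l, end=pj_l)
    # P2 (measurement segments of the PCA)
    _, (p2_r, p2_l) = b.add_bilateral(
        [(9, -11, 1), (12.5, -13, 2), (16, -15, 3)], [1.0, 0.95],
        "RPCA-P2", "LPCA-P2", start=(pj_r, pj_l))

    def tree(root_pair, branches):
        """branches: list of (waypoints_right, (r0, r1), stem) trees."""
        for waypoints, radii, stem, children in branches:
            _, ends = b.add_bilateral(waypoints, list(radii),
                                      f"R{stem}", f"L{stem}", start=root_pair)
            tree(ends, children)

    # MCA outlet trees
    tree((m1_r, m1_l), [
        ([(20, 2, 2), (23, 3, 5), (26, 4, 8)], (0.9, 0.85), "MCA-M2a", [
            ([(26, 4, 8), (28, 5, 11), (30, 6, 14)], (0.55, 0.5), "MCA-M3a", []),
            ([(26, 4, 8), (26.5, 2.5, 11.5), (27, 1, 15)], (0.5, 0.45), "MCA-M3b", []),
        ]),
        ([(20, 2, 2), (21, 0, 5.5), (22, -2, 9)], (0.85, 0.8), "MCA-M2b", [
            ([(22, -2, 9), (23.5, -4, 12), (25, -6, 15)], (0.5, 0.45), "MCA-M3c", []),
            ([(22, -2, 9), (20.5, -3, 12.5), (19, -4, 16)], (0.45, 0.4), "MCA-M3d", []),
        ]),
    ])
    # ACA outlet trees
    tree((a1_r, a1_l), [
        ([(2.5, 8, 2), (3, 10, 6), (3.5, 12, 10)], (0.9, 0.8), "ACA-A2", [
            ([(3.5, 12, 10), (3.8, 13, 14), (4, 14, 18)], (0.5, 0.45), "ACA-A3a", []),
            ([(3.5, 12, 10), (3, 10.5, 14.5), (2.5, 9, 19)], (0.45, 0.4), "ACA-A3b", []),
        ]),
    ])
    # PCA outlet trees
    tree((p2_r, p2_l), [
        ([(16, -15, 3), (18.5, -17, 6), (21, -19, 9)], (0.8, 0.7), "PCA-P3a", [
            ([(21, -19, 9), (22.5, -20, 12), (24, -21, 15)], (0.5, 0.45), "PCA-P4a", []),
            ([(21, -19, 9), (20.5, -18, 12.5), (20, -17, 16)], (0.45, 0.4), "PCA-P4b", []),
        ]),
        ([(16, -15, 3), (15, -17.5, 6.5), (14, -20, 10)], (0.75, 0.65), "PCA-P3b", [
            ([(14, -20, 10), (13, -21.5, 12.5), (12, -23, 15)], (0.5, 0.45), "PCA-P4c", []),
            ([(14, -20, 10), (12, -19, 13), (10, -18, 16)], (0.45, 0.4), "PCA-P4d", []),
        ]),
    ])

    net = b.net
    _apply_variant(net, spec.variant)
    net.validate()
    return net


def _apply_variant(net: VascularNetwork, variant: str | None) -> None:
    if variant is None:
        return
    if variant == "disconnected_lmca":
        drop = "LMCA-M1"  # the MCA tree stays, as an unsupplied component
    elif variant == "fetal_rpca":
        drop = "RPCA-P1"  # P2 then fed through the PCoA only
    else:
        raise ValueError(f"unknown variant {variant!r}")
    sid = next((s for s, seg in net.segments.items() if seg.label == drop), None)
    if sid is None:
        raise ValueError(f"variant {variant!r}: segment {drop!r} not present")
    del net.segments[sid]
    used = {pid for seg in net.segments.values() for pid in seg.point_ids}
    net.points = {i: p for i, p in net.points.items() if i in used}
    net.inlets &= used


def _single_segment(spec: PhantomSpec) -> VascularNetwork:
    b = _Builder()
    b.add([(0, 0, -10), (0, 0, 0), (0, 0, 10)], [1.0, 1.0], "trunk",
          inlet_start=True)
    return b.net


def _y_tree(spec: PhantomSpec) -> VascularNetwork:
    b = _Builder()
    _, top = b.add([(0, 0, -12), (0, 0, 0)], [1.2, 1.2], "trunk", inlet_start=True)
    b.add_bilateral([(0, 0, 0), (3, 0, 4), (6, 0, 8)], [0.9, 0.8],
                    "Rbranch", "Lbranch", start=(top, top))
    return b.net


def _binary_tree(spec: PhantomSpec) -> VascularNetwork:
    b = _Builder()
    _, root = b.add([(0, 0, -12), (0, 0, 0)], [1.4, 1.4], "root", inlet_start=True)

    def grow(node, origin, direction, length, radius, depth, name):
        if depth == 0:
            return
        for sign, tag in ((1.0, "a"), (-1.0, "b")):
            rot = np.array([direction[0] * np.cos(0.5) - sign * np.sin(0.5),
                            direction[1],
                            direction[2] * np.cos(0.5) + sign * 0.2])
            rot /= np.linalg.norm(rot)
            tip = origin + rot * length
            r_child = radius * 2.0 ** (-1.0 / 3.0)  # Murray-law taper
            _, end = b.add([origin, origin + rot * (length / 2), tip],
                           [radius, r_child], f"{name}{tag}", start=node)
            grow(end, tip, rot, length * 0.75, r_child, depth - 1, f"{name}{tag}")

    grow(root, np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0]),
         8.0, 1.4, spec.tree_depth, "b")
    return b.net


_TEMPLATES = {
    "single_segment": _single_segment,
    "y_tree": _y_tree,
    "binary_tree": _binary_tree,
    "toy_cow": _toy_cow,
}


def make_phantom(spec: PhantomSpec | None = None) -> tuple[VascularNetwork, TissueMesh]:
    """Build the (network, tissue mesh) pair described by ``spec``.

    Deterministic: the same spec always produces bit-identical geometry.
    """
    spec = spec or PhantomSpec()
    if spec.template not in _TEMPLATES:
        raise ValueError(f"unknown template {spec.template!r} "
                         f"(have {sorted(_TEMPLATES)})")
    if min(spec.cells) < 1:
        raise ValueError("tissue phantom needs at least one cell per axis")
    net = _TEMPLATES[spec.template](spec)
    if spec.spacing:
        net = resample_centerline(net, spec.spacing)
    if spec.template == "toy_cow":
        mesh = box_mesh(spec.cells, spec.box_extent, spec.box_z0,
                        spec.gray_shell_mm)
    else:
        mesh = box_mesh((max(2, spec.cells[0] // 2),) * 3, (24.0, 24.0, 24.0),
                        z0=-2.0, gray_shell_mm=spec.gray_shell_mm)
    net.validate()
    return net, mesh


def perturb_radii(
    network: VascularNetwork,
    factor: float | None = None,
    relative_sd: float | None = None,
    seed: int = 0,
    segment_ids=None,
) -> VascularNetwork:
    """Scale vessel radii, positions untouched.

    Either a fixed ``factor`` or per-segment random factors drawn from
    ``U(1 - relative_sd, 1 + relative_sd)``.  ``segment_ids`` limits the
    perturbation (e.g. to outlet segments); points shared between a
    perturbed and an unperturbed segment are scaled once.
    """
    if (factor is None) == (relative_sd is None):
        raise ValueError("give exactly one of factor or relative_sd")
    out = network.copy()
    sids = sorted(out.segments) if segment_ids is None else sorted(segment_ids)
    rng = np.random.default_rng(seed)
    touched: set[int] = set()
    for sid in sids:
        f = factor if factor is not None else float(
            rng.uniform(1.0 - relative_sd, 1.0 + relative_sd))
        if f <= 0:
            raise ValueError(f"radius factor {f} would produce nonpositive radii")
        for pid in out.segments[sid].point_ids:
            if pid not in touched:
                out.points[pid].radius *= f
                touched.add(pid)
    bad = [i for i, p in out.points.items() if not p.radius > 0]
    if bad:
        raise ValueError(f"perturbation produced nonpositive radii at {bad}")
    return out
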