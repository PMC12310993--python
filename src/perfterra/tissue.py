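"""Labeled tetrahedral tissue meshes and CBF-weighted blood-flow demand.

The tissue domain is a tetrahedral mesh whose elements carry a tissue-class
label (e.g. "gray", "white", "other").  Demand is metabolic: the flow
needed to perfuse a region is its mass times the regional cerebral blood
flow (CBF, mL/min per gram), with mass = density * volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _gmsh, _vtkxml

__all__ = ["TissueMesh", "TissueClassTable", "load_mesh", "save_mesh", "total_demand"]

MM3_PER_ML = 1000.0

#: regional CBF in mL/min/g: cerebral/cerebellar gray and white matter, and a
#: uniform value for remaining tissue; density in g/mL.
DEFAULT_CBF = {"gray": 0.8, "white": 0.2, "other": 0.5}
DEFAULT_TISSUE_DENSITY = 1.04


class MeshValidationError(ValueError):
    pass


@dataclass
class TissueClassTable:
    """Per-class CBF (mL/min/g) and the tissue mass density (g/mL)."""

    cbf: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CBF))
    density: float = DEFAULT_TISSUE_DENSITY

    def __post_init__(self) -> None:
        if not (self.density > 0):
            raise ValueError("tissue density must be > 0")
        for cls, value in self.cbf.items():
            if value < 0:
                raise ValueError(f"CBF for class {cls!r} must be >= 0")

    @classmethod
    def uniform(cls, cbf: float = 0.5, density: float = DEFAULT_TISSUE_DENSITY,
                classes=("gray", "white", "other")) -> "TissueClassTable":
        """Single CBF value for every class (the uniform-CBF comparison case)."""
        return cls({c: cbf for c in classes}, density)

    def cbf_for(self, labels) -> np.ndarray:
        try:
            return np.array([self.cbf[c] for c in labels], float)
        except KeyError as exc:
            raise KeyError(f"tissue class {exc.args[0]!r} missing from CBF table "
                           f"(known: {sorted(self.cbf)})") from None


class TissueMesh:
    """Tetrahedral mesh with per-element tissue classes.

    Element volumes are computed from node coordinates (mm) via the signed
    tetrahedron determinant; inverted elements are reoriented, degenerate
    ones rejected.  Face adjacency (two elements sharing a triangular face)
    is built lazily and used by the connectivity-constrained tessellation.
    """

    def __init__(self, nodes: np.ndarray, elements: np.ndarray, element_class):
        self.nodes = np.asarray(nodes, float)
        self.elements = np.asarray(elements, np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise MeshValidationError("nodes must be an (n, 3) array of mm coordinates")
        if self.elements.ndim != 2 or self.elements.shape[1] != 4:
            raise MeshValidationError("elements must be an (m, 4) connectivity array")
        self.element_class = np.asarray(list(element_class), dtype=object)
        if len(self.element_class) != len(self.elements):
            raise MeshValidationError("one class label per element required")

        v = self._signed_volumes()
        flipped = v < 0
        if np.any(flipped):  # fix orientation, keep geometry
            self.elements = self.elements.copy()
            self.elements[flipped, 0], self.elements[flipped, 1] = (
                self.elements[flipped, 1], self.elements[flipped, 0].copy())
            v = np.abs(v)
        degenerate = np.nonzero(v <= 0)[0]
        if degenerate.size:
            raise MeshValidationError(
                f"degenerate (zero-volume) elements: {degenerate.tolist()[:20]}")
        self.element_volume_mm3 = v
        self._adjacency = None

    def _signed_volumes(self) -> np.ndarray:
        p = self.nodes[self.elements]
        return np.linalg.det(p[:, 1:] - p[:, :1]) / 6.0

    # ------------------------------------------------------------ geometry
    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def element_volume_ml(self) -> np.ndarray:
        return self.element_volume_mm3 / MM3_PER_ML

    @property
    def total_volume_ml(self) -> float:
        return float(self.element_volume_ml.sum())

    def centroids(self) -> np.ndarray:
        """Element centroids, mm — the tissue location used in tessellation."""
        return self.nodes[self.elements].mean(axis=1)

    # ------------------------------------------------------------ topology
    def face_adjacency(self) -> np.ndarray:
        """(k, 2) array of element pairs sharing a triangular face."""
        if self._adjacency is None:
            faces: dict[tuple, int] = {}
            pairs = []
            for ei, tet in enumerate(self.elements):
                for f in ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)):
                    key = tuple(sorted(int(tet[i]) for i in f))
                    other = faces.pop(key, None)
                    if other is None:
                        faces[key] = ei
                    else:
                        pairs.append((other, ei))
            self._adjacency = (np.array(pairs, np.int64).reshape(-1, 2)
                               if pairs else np.empty((0, 2), np.int64))
        return self._adjacency

    def vertex_adjacency_graph(self):
        """Boolean CSR over elements: adjacent iff sharing >= 1 node.

        The weakest topological connectivity of the mesh; used by the
        tessellation growth constraint, where face-only adjacency would
        flag spurious single-element "pockets" that touch their region
        only through an edge or vertex.
        """
        from scipy.sparse import coo_matrix

        m = self.n_elements
        rows = np.repeat(np.arange(m), 4)
        inc = coo_matrix((np.ones(4 * m), (rows, self.elements.reshape(-1))),
                         shape=(m, len(self.nodes))).tocsr()
        adj = (inc @ inc.T).tolil()
        adj.setdiag(0)
        return adj.tocsr().astype(bool)

    def adjacency_graph(self):
        """scipy CSR graph over elements, edge weight = centroid distance (mm)."""
        from scipy.sparse import coo_matrix

        pairs = self.face_adjacency()
        cen = self.centroids()
        w = np.linalg.norm(cen[pairs[:, 0]] - cen[pairs[:, 1]], axis=1)
        i = np.concatenate([pairs[:, 0], pairs[:, 1]])
        j = np.concatenate([pairs[:, 1], pairs[:, 0]])
        return coo_matrix((np.concatenate([w, w]), (i, j)),
                          shape=(self.n_elements, self.n_elements)).tocsr()


# ---------------------------------------------------------------------- I/O
def load_mesh(path: str | Path, class_field: str = "tissue_class",
              class_names: dict[int, str] | None = None) -> TissueMesh:
    """Read a labeled tetrahedral mesh from VTU (VTK XML) or Gmsh MSH v4.1.

    For VTU the element label comes from the integer cell-data array
    ``class_field``, decoded through ``class_names`` (default mapping
    0/1/2 -> other/gray/white, matching :func:`save_mesh`).  For MSH the
    label is the physical-group name of each volume entity.
    """
    path = Path(path)
    if path.suffix.lower() == ".msh":
        points, tets, labels = _gmsh.read_msh(path)
        return TissueMesh(points, tets, labels)
    points, tets, cell_data, meta = _vtkxml.read_unstructured(path)
    if class_field not in cell_data:
        raise MeshValidationError(
            f"{path}: cell-data array {class_field!r} not found "
            f"(present: {sorted(cell_data)})")
    codes = cell_data[class_field].astype(int)
    names = class_names or {int(k): v for k, v in
                            meta.get("class_names", {0: "other", 1: "gray", 2: "white"}).items()}
    labels = [names.get(c, str(c)) for c in codes]
    return TissueMesh(points, tets, labels)


def save_mesh(mesh: TissueMesh, path: str | Path, class_field: str = "tissue_class") -> None:
    classes = sorted(set(mesh.element_class))
    default_order = {"other": 0, "gray": 1, "white": 2}
    code = {c: default_order.get(c, 3 + k) for k, c in enumerate(classes)}
    codes = np.array([code[c] for c in mesh.element_class], np.int64)
    meta = {"class_names": {str(v): k for k, v in code.items()}}
    _vtkxml.write_unstructured(Path(path), mesh.nodes, mesh.elements,
                               {class_field: codes}, meta)


# ---------------------------------------------------------------- demand
def total_demand(mesh: TissueMesh, table: TissueClassTable,
                 element_ids=None) -> float:
    """Total perfusion demand rho * sum_k v_k * CBF_k in mL/min.

    ``element_ids`` restricts the sum to a subset; summation runs in
    ascending element-id order so partition sums reproduce the total
    bit-for-bit.
    """
    if element_ids is None:
        idx = np.arange(mesh.n_elements)
    else:
        idx = np.sort(np.asarray(element_ids, np.int64))
    if idx.size == 0:
        return 0.0
    cbf = table.cbf_for(mesh.element_class[idx])
    return float(table.density * np.sum(mesh.element_volume_ml[idx] * cbf))
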