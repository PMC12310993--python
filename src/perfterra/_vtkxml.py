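"""Minimal ASCII VTK XML I/O: PolyData (.vtp) polylines and tetrahedral
UnstructuredGrid (.vtu).

Only the subset of the format this package produces and consumes is
supported: ascii-format DataArrays, polyline cells in VTP, tetra cells
(VTK type 10) in VTU.  An optional package metadata dict travels as a
FieldData Int8 array holding UTF-8 JSON, which standard VTK readers simply
ignore.
"""

from __future__ import annotations

import json
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np

META_ARRAY = "perfterra_meta"


def _data_array(name: str, values: np.ndarray, vtk_type: str, ncomp: int = 1) -> ET.Element:
    el = ET.Element(
        "DataArray",
        {"type": vtk_type, "Name": name, "NumberOfComponents": str(ncomp),
         "format": "ascii"},
    )
    flat = np.asarray(values).reshape(-1)
    if vtk_type.startswith("Float"):
        el.text = " ".join(repr(float(v)) for v in flat)
    else:
        el.text = " ".join(str(int(v)) for v in flat)
    return el


def _parse_array(el: ET.Element) -> np.ndarray:
    if el.get("format", "ascii") != "ascii":
        raise ValueError("only ascii-format VTK XML is supported")
    text = el.text or ""
    if el.get("type", "").startswith("Float"):
        return np.array(text.split(), dtype=float)
    return np.array([int(t) for t in text.split()], dtype=np.int64)


def _meta_element(meta: dict) -> ET.Element:
    payload = np.frombuffer(json.dumps(meta).encode(), dtype=np.int8)
    fd = ET.Element("FieldData")
    fd.append(_data_array(META_ARRAY, payload, "Int8"))
    return fd


def _read_meta(piece_parent: ET.Element) -> dict:
    fd = piece_parent.find("FieldData")
    if fd is None:
        return {}
    for el in fd.findall("DataArray"):
        if el.get("Name") == META_ARRAY:
            data = _parse_array(el).astype(np.int8).tobytes().decode()
            return json.loads(data)
    return {}


# ------------------------------------------------------------------ PolyData
def write_polydata(path, xyz: np.ndarray, lines, point_data: dict, meta: dict | None = None):
    xyz = np.asarray(xyz, float)
    root = ET.Element("VTKFile", {"type": "PolyData", "version": "0.1",
                                  "byte_order": "LittleEndian"})
    pd = ET.SubElement(root, "PolyData")
    piece = ET.SubElement(
        pd, "Piece",
        {"NumberOfPoints": str(len(xyz)), "NumberOfVerts": "0",
         "NumberOfLines": str(len(lines)), "NumberOfStrips": "0",
         "NumberOfPolys": "0"},
    )
    if meta:
        piece.append(_meta_element(meta))
    pts = ET.SubElement(piece, "Points")
    pts.append(_data_array("Points", xyz, "Float64", 3))
    pdata = ET.SubElement(piece, "PointData")
    for name, values in point_data.items():
        pdata.append(_data_array(name, np.asarray(values, float), "Float64"))
    cells = ET.SubElement(piece, "Lines")
    conn = np.concatenate([np.asarray(l, np.int64) for l in lines]) if lines else np.array([], np.int64)
    offsets = np.cumsum([len(l) for l in lines]).astype(np.int64)
    cells.append(_data_array("connectivity", conn, "Int64"))
    cells.append(_data_array("offsets", offsets, "Int64"))
    ET.ElementTree(root).write(Path(path), xml_declaration=True)


def read_polydata(path):
    root = ET.parse(Path(path)).getroot()
    piece = root.find("PolyData/Piece")
    if piece is None:
        raise ValueError(f"{path}: not a VTK XML PolyData file")
    xyz = _parse_array(piece.find("Points/DataArray")).reshape(-1, 3)
    point_data = {}
    pdata = piece.find("PointData")
    if pdata is not None:
        for el in pdata.findall("DataArray"):
            point_data[el.get("Name")] = _parse_array(el)
    lines = []
    cells = piece.find("Lines")
    if cells is not None:
        arrays = {el.get("Name"): _parse_array(el) for el in cells.findall("DataArray")}
        conn, offsets = arrays["connectivity"], arrays["offsets"]
        start = 0
        for off in offsets:
            lines.append(conn[start:off].tolist())
            start = int(off)
    return xyz, lines, point_data, _read_meta(piece)


# --------------------------------------------------------- UnstructuredGrid
def write_unstructured(path, points: np.ndarray, tets: np.ndarray,
                       cell_data: dict | None = None, meta: dict | None = None):
    points = np.asarray(points, float)
    tets = np.asarray(tets, np.int64)
    root = ET.Element("VTKFile", {"type": "UnstructuredGrid", "version": "0.1",
                                  "byte_order": "LittleEndian"})
    ug = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(ug, "Piece", {"NumberOfPoints": str(len(points)),
                                        "NumberOfCells": str(len(tets))})
    if meta:
        piece.append(_meta_element(meta))
    pts = ET.SubElement(piece, "Points")
    pts.append(_data_array("Points", points, "Float64", 3))
    cdata = ET.SubElement(piece, "CellData")
    for name, values in (cell_data or {}).items():
        arr = np.asarray(values)
        kind = "Float64" if arr.dtype.kind == "f" else "Int64"
        cdata.append(_data_array(name, arr, kind))
    cells = ET.SubElement(piece, "Cells")
    cells.append(_data_array("connectivity", tets.reshape(-1), "Int64"))
    cells.append(_data_array("offsets", 4 * np.arange(1, len(tets) + 1), "Int64"))
    cells.append(_data_array("types", np.full(len(tets), 10), "UInt8"))
    ET.ElementTree(root).write(Path(path), xml_declaration=True)


def read_unstructured(path):
    root = ET.parse(Path(path)).getroot()
    piece = root.find("UnstructuredGrid/Piece")
    if piece is None:
        raise ValueError(f"{path}: not a VTK XML UnstructuredGrid file")
    points = _parse_array(piece.find("Points/DataArray")).reshape(-1, 3)
    cells = piece.find("Cells")
    arrays = {el.get("Name"): _parse_array(el) for el in cells.findall("DataArray")}
    types = arrays["types"]
    if not np.all(types == 10):
        raise ValueError(f"{path}: non-tetrahedral cells present (VTK types "
                         f"{sorted(set(types.tolist()) - {10})})")
    tets = arrays["connectivity"].reshape(-1, 4)
    cell_data = {}
    cdata = piece.find("CellData")
    if cdata is not None:
        for el in cdata.findall("DataArray"):
            cell_data[el.get("Name")] = _parse_array(el)
    return points, tets, cell_data, _read_meta(piece)
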