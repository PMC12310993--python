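"""Minimal Gmsh MSH 4.1 (ASCII) tetrahedral-mesh reader.

Reads $MeshFormat, $PhysicalNames, $Entities, $Nodes and $Elements; only
element type 4 (linear tetrahedron) is accepted.  Each element's tissue
class is the physical-group name of its volume entity when one exists,
otherwise the physical tag, otherwise the entity tag, as a string.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _blocks(text: str) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    name = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("$End"):
            name = None
        elif line.startswith("$"):
            name = line[1:]
            out[name] = []
        elif name is not None:
            out[name].append(line)
    return out


def read_msh(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Return (points[n,3] mm, tets[m,4] zero-based, class label per tet)."""
    blocks = _blocks(Path(path).read_text())
    if "MeshFormat" not in blocks:
        raise ValueError(f"{path}: not a Gmsh MSH file")
    version = blocks["MeshFormat"][0].split()[0]
    if not version.startswith("4"):
        raise ValueError(f"{path}: MSH version {version} unsupported (need 4.x)")

    phys_names: dict[tuple[int, int], str] = {}
    if "PhysicalNames" in blocks:
        for line in blocks["PhysicalNames"][1:]:
            dim, tag, name = line.split(maxsplit=2)
            phys_names[(int(dim), int(tag))] = name.strip('"')

    # entity tag (dim 3) -> first physical tag
    vol_phys: dict[int, int] = {}
    if "Entities" in blocks:
        tok = " ".join(blocks["Entities"]).split()
        i = 0
        n_pts, n_crv, n_srf, n_vol = (int(tok[k]) for k in range(4))
        i = 4
        for _ in range(n_pts):
            n_phys = int(tok[i + 4])
            i += 5 + n_phys
        for count in (n_crv, n_srf):
            for _ in range(count):
                n_phys = int(tok[i + 7])
                i += 8 + n_phys
                i += 1 + int(tok[i])  # bounding entities
        for _ in range(n_vol):
            tag = int(tok[i])
            n_phys = int(tok[i + 7])
            if n_phys > 0:
                vol_phys[tag] = int(tok[i + 8])
            i += 8 + n_phys
            i += 1 + int(tok[i])

    # nodes
    lines = blocks["Nodes"]
    n_blocks = int(lines[0].split()[0])
    coords: dict[int, list[float]] = {}
    li = 1
    for _ in range(n_blocks):
        n_in_block = int(lines[li].split()[3])
        li += 1
        tags = [int(lines[li + k]) for k in range(n_in_block)]
        li += n_in_block
        for k in range(n_in_block):
            coords[tags[k]] = [float(v) for v in lines[li + k].split()[:3]]
        li += n_in_block
    order = sorted(coords)
    index = {tag: k for k, tag in enumerate(order)}
    points = np.array([coords[t] for t in order], float)

    # elements
    lines = blocks["Elements"]
    n_blocks = int(lines[0].split()[0])
    tets, labels = [], []
    li = 1
    for _ in range(n_blocks):
        dim, etag, etype, n_in_block = (int(v) for v in lines[li].split())
        li += 1
        if dim == 3:
            if etype != 4:
                raise ValueError(
                    f"{path}: non-tetrahedral 3D elements (gmsh type {etype})")
            ptag = vol_phys.get(etag)
            label = phys_names.get((3, ptag), str(ptag if ptag is not None else etag))
            for k in range(n_in_block):
                parts = lines[li + k].split()
                tets.append([index[int(t)] for t in parts[1:5]])
                labels.append(label)
        li += n_in_block
    if not tets:
        raise ValueError(f"{path}: no tetrahedral elements")
    return points, np.array(tets, np.int64), labels
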