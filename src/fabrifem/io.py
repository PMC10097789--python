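"""File formats: Abaqus .inp subset, legacy VTK, volumes, CSV exports.

The mesh format is the C3D4 subset of the Abaqus keyword format
(``*NODE``, ``*ELEMENT, TYPE=C3D4``, ``*NSET``, ``*ELSET``), with
1-based ids on disk and 0-based indices in memory.  Volumes are written
either as TIFF stacks or as raw uint8 plus a JSON sidecar (axis order
ZYX on disk).  All CSV exports carry a header with unit-annotated
column names.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .mesh import TetMesh
from .volume import BinaryVolume

log = logging.getLogger("fabrifem")

_KNOWN = ("*node", "*element", "*nset", "*elset", "*heading")


def _parse_options(header: str) -> dict:
    opts = {}
    for part in header.split(",")[1:]:
        if "=" in part:
            k, v = part.split("=", 1)
            opts[k.strip().lower()] = v.strip()
        else:
            opts[part.strip().lower()] = True
    return opts


def read_inp(path) -> TetMesh:
    """Read the supported Abaqus .inp subset; 1-based ids become 0-based."""
    path = Path(path)
    node_ids, coords = [], []
    elem_ids, conn = [], []
    nsets, elsets = {}, {}
    section = None
    target = None
    generate = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("**"):
                continue
            if line.startswith("*"):
                key = line.split(",")[0].strip().lower()
                opts = _parse_options(line)
                generate = bool(opts.get("generate", False))
                if key == "*node":
                    section = "node"
                elif key == "*element":
                    etype = opts.get("type", "").upper()
                    if etype != "C3D4":
                        raise ValueError(
                            f"{path}:{lineno}: unsupported element type '{etype}' "
                            "(only C3D4 is handled)"
                        )
                    section = "element"
                elif key == "*nset":
                    section = "nset"
                    target = opts.get("nset")
                    nsets.setdefault(target, [])
                elif key == "*elset":
                    section = "elset"
                    target = opts.get("elset")
                    elsets.setdefault(target, [])
                elif key == "*heading":
                    section = None
                else:
                    log.warning("%s:%d: skipping unknown keyword %s", path, lineno, key)
                    section = None
                continue
            vals = [v for v in (x.strip() for x in line.split(",")) if v]
            if section == "node":
                node_ids.append(int(vals[0]))
                coords.append([float(v) for v in vals[1:4]])
            elif section == "element":
                elem_ids.append(int(vals[0]))
                conn.append([int(v) for v in vals[1:5]])
            elif section in ("nset", "elset"):
                store = nsets if section == "nset" else elsets
                ids = [int(v) for v in vals]
                if generate:
                    first, last = ids[0], ids[1]
                    step = ids[2] if len(ids) > 2 else 1
                    store[target].extend(range(first, last + 1, step))
                else:
                    store[target].extend(ids)
    if not node_ids:
        raise ValueError(f"{path}: no *NODE section found")
    if not elem_ids:
        raise ValueError(f"{path}: no *ELEMENT section found")
    nmap = {nid: i for i, nid in enumerate(node_ids)}
    emap = {eid: i for i, eid in enumerate(elem_ids)}
    tets = np.array([[nmap[n] for n in row] for row in conn])
    mesh = TetMesh(np.array(coords), tets,
                   node_sets={k: np.array(sorted(nmap[i] for i in v)) for k, v in nsets.items()},
                   element_sets={k: np.array(sorted(emap[i] for i in v)) for k, v in elsets.items()})
    return mesh


def write_inp(mesh: TetMesh, path) -> None:
    """Write the mesh with 1-based ids (round-trips with :func:`read_inp`)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("*HEADING\nfabrifem tetrahedral mesh\n*NODE\n")
        for i, p in enumerate(mesh.nodes, start=1):
            fh.write(f"{i}, {p[0]:.9g}, {p[1]:.9g}, {p[2]:.9g}\n")
        fh.write("*ELEMENT, TYPE=C3D4\n")
        for e, tet in enumerate(mesh.tets, start=1):
            fh.write(f"{e}, {tet[0] + 1}, {tet[1] + 1}, {tet[2] + 1}, {tet[3] + 1}\n")
        for name, ids in mesh.node_sets.items():
            fh.write(f"*NSET, NSET={name}\n")
            _write_id_lines(fh, np.asarray(ids) + 1)
        for name, ids in mesh.element_sets.items():
            fh.write(f"*ELSET, ELSET={name}\n")
            _write_id_lines(fh, np.asarray(ids) + 1)


def _write_id_lines(fh, ids, per_line: int = 8) -> None:
    ids = list(int(i) for i in ids)
    for i in range(0, len(ids), per_line):
        fh.write(", ".join(str(x) for x in ids[i:i + per_line]) + "\n")


def write_vtk(mesh: TetMesh, path, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Legacy-ASCII VTK unstructured grid for visualization."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfabrifem result\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"CELLS {mesh.n_elements} {mesh.n_elements * 5}\n")
        for tet in mesh.tets:
            fh.write("4 " + " ".join(str(int(n)) for n in tet) + "\n")
        fh.write(f"CELL_TYPES {mesh.n_elements}\n")
        fh.write("\n".join(["10"] * mesh.n_elements) + "\n")
        for header, data in (("POINT_DATA %d" % mesh.n_nodes, point_data),
                             ("CELL_DATA %d" % mesh.n_elements, cell_data)):
            if not data:
                continue
            fh.write(header + "\n")
            for name, arr in data.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(f"{v:.9g}" for v in arr) + "\n")
                elif arr.shape[1] == 3:
                    fh.write(f"VECTORS {name} double\n")
                    for v in arr:
                        fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
                else:
                    raise ValueError(f"unsupported data shape for '{name}': {arr.shape}")


def write_volume_raw(vol: BinaryVolume, basepath) -> None:
    """Raw uint8 (ZYX on disk) with a JSON metadata sidecar."""
    basepath = Path(basepath)
    raw = np.transpose(vol.data, (2, 1, 0)).astype(np.uint8)
    raw.tofile(basepath.with_suffix(".raw"))
    meta = {
        "shape_xyz": list(vol.shape),
        "voxel_size_um": vol.voxel_size_um,
        "origin_mm": vol.origin_mm.tolist(),
        "axis_order_on_disk": "ZYX",
        "dtype": "uint8",
    }
    basepath.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_volume_raw(basepath) -> BinaryVolume:
    basepath = Path(basepath)
    meta = json.loads(basepath.with_suffix(".json").read_text())
    shape = tuple(meta["shape_xyz"])
    raw = np.fromfile(basepath.with_suffix(".raw"), dtype=np.uint8)
    data = np.transpose(raw.reshape(shape[::-1]), (2, 1, 0)) > 0
    return BinaryVolume(data, meta["voxel_size_um"], np.array(meta["origin_mm"]))


def write_volume_tiff(vol: BinaryVolume, path) -> None:
    """TIFF stack, pages are z-slices; voxel size recorded in metadata."""
    tifffile.imwrite(
        Path(path), np.transpose(vol.data, (2, 1, 0)).astype(np.uint8),
        metadata={"voxel_size_um": vol.voxel_size_um, "origin_mm": vol.origin_mm.tolist()},
    )


def read_volume_tiff(path, voxel_size_um: float | None = None,
                     origin_mm=(0.0, 0.0, 0.0)) -> BinaryVolume:
    with tifffile.TiffFile(Path(path)) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    vs = voxel_size_um or float(meta.get("voxel_size_um", 0) or 0)
    if vs <= 0:
        raise ValueError("voxel size missing from TIFF metadata; pass voxel_size_um")
    origin = np.array(meta.get("origin_mm", origin_mm), dtype=float)
    return BinaryVolume(np.transpose(data, (2, 1, 0)) > 0, vs, origin)


def structures_to_frame(structures) -> pd.DataFrame:
    """Per-element fabric table (rho, m_i, frame direction cosines)."""
    rows = []
    for s in structures:
        row = {"element_id": s.element_id, "rho_bvtv": s.rho,
               "degenerate": int(s.degenerate)}
        if s.fabric is None:
            row.update({f"m{i+1}": 1.0 for i in range(3)})
            row.update({f"frame_{i+1}{j+1}": float(i == j)
                        for i in range(3) for j in range(3)})
        else:
            for i in range(3):
                row[f"m{i+1}"] = float(s.fabric.m[i])
            for i in range(3):
                for j in range(3):
                    row[f"frame_{i+1}{j+1}"] = float(s.fabric.frame[i, j])
        rows.append(row)
    return pd.DataFrame(rows)


# our Voigt order (11,22,33,23,31,12) -> Abaqus order (11,22,33,12,13,23)
_ABAQUS_VOIGT = [0, 1, 2, 5, 4, 3]


def write_abaqus_materials(materials, path) -> None:
    """Per-element ``*ELASTIC, TYPE=ANISOTROPIC`` cards for interoperability.

    The 21 lower-triangle stiffness entries are emitted row-wise in the
    Abaqus component order (shears 12, 13, 23), eight values per line.
    """
    path = Path(path)
    with path.open("w") as fh:
        for m in materials:
            C = m.C_global[np.ix_(_ABAQUS_VOIGT, _ABAQUS_VOIGT)]
            entries = [C[i, j] for i in range(6) for j in range(i + 1)]
            fh.write(f"*MATERIAL, NAME=EL{m.element_id + 1}_{m.model_tag}\n")
            fh.write("*ELASTIC, TYPE=ANISOTROPIC\n")
            for i in range(0, 21, 8):
                fh.write(", ".join(f"{v:.6e}" for v in entries[i:i + 8]) + "\n")


def materials_to_frame(materials) -> pd.DataFrame:
    """Per-element stiffness export: 21 independent C entries (MPa)."""
    iu = np.triu_indices(6)
    rows = []
    for m in materials:
        row = {"element_id": m.element_id, "model_tag": m.model_tag,
               "rho_bvtv": m.rho}
        for i, j in zip(*iu):
            row[f"C{i+1}{j+1}_MPa"] = float(m.C_global[i, j])
        rows.append(row)
    return pd.DataFrame(rows)
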