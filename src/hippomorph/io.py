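"""File formats: surface meshes with per-vertex overlays, label volumes,
coefficient tables, transforms.

Surfaces travel as VTK legacy polydata (ASCII), PLY (ASCII) or GIFTI
(.gii, via nibabel); the spherical parameterization rides along as two
per-vertex scalar arrays named "theta" and "phi", and any number of further
overlays (jacobian, kappa, statistics) round-trip by name.  Volumes are
NIfTI-1 (nibabel), world coordinates in mm RAS+, voxel indices 0-based with
the affine mapping index to world.  SPHARM coefficient sets are plain-text
tables (l, m, cx, cy, cz) with a header recording the basis convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .align import RigidTransform
from .spharm import PdmSurface, SpharmModel

__all__ = ["write_mesh", "read_mesh", "write_memax_polyline",
           "read_label_volume", "write_label_volume", "write_vector_field_nifti",
           "save_spharm", "load_spharm", "save_transform", "load_transform"]

_FMT = "%.17g"


def _overlays_of(surface: PdmSurface, overlays: dict | None) -> dict:
    out = {"theta": surface.theta, "phi": surface.phi}
    if overlays:
        out.update({k: np.asarray(v, float) for k, v in overlays.items()})
    return out


# --------------------------------------------------------------------- VTK

def _write_vtk(path: Path, vertices, faces, overlays: dict) -> None:
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nhippomorph surface\nASCII\n"
                "DATASET POLYDATA\n")
        f.write(f"POINTS {len(vertices)} double\n")
        for p in vertices:
            f.write(" ".join(_FMT % x for x in p) + "\n")
        f.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
        for tri in faces:
            f.write("3 %d %d %d\n" % tuple(tri))
        if overlays:
            f.write(f"POINT_DATA {len(vertices)}\n")
            f.write(f"FIELD overlays {len(overlays)}\n")
            for name, vals in overlays.items():
                f.write(f"{name} 1 {len(vals)} double\n")
                f.write(" ".join(_FMT % v for v in vals) + "\n")


def _read_vtk(path: Path):
    with open(path) as f:
        lines = f.read().splitlines()
    i = 0
    vertices = faces = None
    overlays = {}
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(x) for x in lines[i].split())
                i += 1
            vertices = np.array(vals).reshape(n, 3)
            continue
        if line.startswith("POLYGONS"):
            n = int(line.split()[1])
            faces = np.empty((n, 3), dtype=np.int64)
            for k in range(n):
                i += 1
                parts = lines[i].split()
                if parts[0] != "3":
                    raise ValueError("only triangle polygons are supported")
                faces[k] = [int(x) for x in parts[1:4]]
            i += 1
            continue
        if line.startswith("FIELD"):
            n_arrays = int(line.split()[-1])
            i += 1
            for _ in range(n_arrays):
                name, _comp, count, _dtype = lines[i].split()
                vals = []
                i += 1
                while len(vals) < int(count):
                    vals.extend(float(x) for x in lines[i].split())
                    i += 1
                overlays[name] = np.array(vals)
            continue
        i += 1
    if vertices is None or faces is None:
        raise ValueError(f"{path}: not a VTK polydata surface")
    return vertices, faces, overlays


# --------------------------------------------------------------------- PLY

def _write_ply(path: Path, vertices, faces, overlays: dict) -> None:
    names = list(overlays)
    with open(path, "w") as f:
        f.write("ply\nformat ascii 1.0\ncomment hippomorph surface\n")
        f.write(f"element vertex {len(vertices)}\n")
        for p in ("x", "y", "z"):
            f.write(f"property double {p}\n")
        for name in names:
            f.write(f"property double {name}\n")
        f.write(f"element face {len(faces)}\n"
                "property list uchar int vertex_indices\nend_header\n")
        cols = np.column_stack([vertices] + [overlays[n] for n in names])
        for row in cols:
            f.write(" ".join(_FMT % x for x in row) + "\n")
        for tri in faces:
            f.write("3 %d %d %d\n" % tuple(tri))


def _read_ply(path: Path):
    with open(path) as f:
        lines = f.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ValueError(f"{path}: not a PLY file")
    i = 1
    n_vert = n_face = 0
    props = []
    element = None
    while i < len(lines):
        parts = lines[i].split()
        i += 1
        if not parts:
            continue
        if parts[0] == "format" and parts[1] != "ascii":
            raise ValueError("only ASCII PLY is supported")
        if parts[0] == "element":
            element = parts[1]
            if element == "vertex":
                n_vert = int(parts[2])
            elif element == "face":
                n_face = int(parts[2])
        elif parts[0] == "property" and element == "vertex" and parts[1] != "list":
            props.append(parts[2])
        elif parts[0] == "end_header":
            break
    data = np.array([[float(x) for x in lines[i + k].split()]
                     for k in range(n_vert)])
    i += n_vert
    faces = np.empty((n_face, 3), dtype=np.int64)
    for k in range(n_face):
        parts = lines[i + k].split()
        if parts[0] != "3":
            raise ValueError("only triangle faces are supported")
        faces[k] = [int(x) for x in parts[1:4]]
    cols = {name: data[:, j] for j, name in enumerate(props)}
    vertices = np.column_stack([cols.pop("x"), cols.pop("y"), cols.pop("z")])
    return vertices, faces, cols


# ------------------------------------------------------------------- GIFTI

def _write_gifti(path: Path, vertices, faces, overlays: dict) -> None:
    img = nib.gifti.GiftiImage()
    img.add_gifti_data_array(nib.gifti.GiftiDataArray(
        np.asarray(vertices, np.float32), intent="NIFTI_INTENT_POINTSET"))
    img.add_gifti_data_array(nib.gifti.GiftiDataArray(
        np.asarray(faces, np.int32), intent="NIFTI_INTENT_TRIANGLE"))
    for name, vals in overlays.items():
        da = nib.gifti.GiftiDataArray(np.asarray(vals, np.float32),
                                      intent="NIFTI_INTENT_SHAPE")
        da.meta = nib.gifti.GiftiMetaData(Name=name)
        img.add_gifti_data_array(da)
    nib.save(img, str(path))


def _read_gifti(path: Path):
    img = nib.load(str(path))
    vertices = faces = None
    overlays = {}
    for da in img.darrays:
        if da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
            vertices = np.asarray(da.data, float)
        elif da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
            faces = np.asarray(da.data, np.int64)
        else:
            name = dict(da.meta).get("Name", f"overlay{len(overlays)}")
            overlays[name] = np.asarray(da.data, float)
    if vertices is None or faces is None:
        raise ValueError(f"{path}: GIFTI file lacks a surface")
    return vertices, faces, overlays


# ------------------------------------------------------------------ public

_WRITERS = {".vtk": _write_vtk, ".ply": _write_ply, ".gii": _write_gifti}
_READERS = {".vtk": _read_vtk, ".ply": _read_ply, ".gii": _read_gifti}


def _dispatch(path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix not in _WRITERS:
        raise ValueError(f"unsupported mesh format '{suffix}' "
                         f"(supported: {sorted(_WRITERS)})")
    return suffix


def write_mesh(surface: PdmSurface, path, overlays: dict | None = None) -> None:
    """Write a surface with its parameterization and optional overlays."""
    suffix = _dispatch(path)
    _WRITERS[suffix](Path(path), surface.vertices, surface.faces,
                     _overlays_of(surface, overlays))


def read_mesh(path, require_params: bool = True
              ) -> tuple[PdmSurface, dict]:
    """Read a surface; returns (surface, overlays).

    With ``require_params`` the file must carry "theta" and "phi" per-vertex
    arrays (a parameterized surface); a missing array raises an error naming
    it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    suffix = _dispatch(path)
    vertices, faces, overlays = _READERS[suffix](path)
    theta = overlays.pop("theta", None)
    phi = overlays.pop("phi", None)
    if require_params:
        if theta is None:
            raise ValueError(f"{path}: missing per-vertex array 'theta'")
        if phi is None:
            raise ValueError(f"{path}: missing per-vertex array 'phi'")
    n = len(vertices)
    surface = PdmSurface(vertices, faces,
                         theta if theta is not None else np.zeros(n),
                         phi if phi is not None else np.zeros(n))
    return surface, overlays


def write_memax_polyline(points: np.ndarray, path,
                         point_data: dict | None = None) -> None:
    """MEMAX as a VTK legacy polyline with per-point arrays (kappa etc.)."""
    points = np.asarray(points, float)
    K = len(points)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nhippomorph memax\nASCII\n"
                "DATASET POLYDATA\n")
        f.write(f"POINTS {K} double\n")
        for p in points:
            f.write(" ".join(_FMT % x for x in p) + "\n")
        f.write(f"LINES 1 {K + 1}\n")
        f.write(str(K) + " " + " ".join(str(i) for i in range(K)) + "\n")
        if point_data:
            f.write(f"POINT_DATA {K}\nFIELD overlays {len(point_data)}\n")
            for name, vals in point_data.items():
                vals = np.asarray(vals, float)
                ncomp = 1 if vals.ndim == 1 else vals.shape[1]
                f.write(f"{name} {ncomp} {K} double\n")
                f.write(" ".join(_FMT % v for v in np.ravel(vals)) + "\n")


# ----------------------------------------------------------------- volumes

def read_label_volume(path, label: int = 1):
    """Binary mask of one label from an integer NIfTI-1 volume.

    Returns (mask, affine, spacing).  Non-integer data or an absent label is
    an error (the latter lists the labels present).
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"{path}: label volume has non-integer data")
        data = np.round(data).astype(np.int32)
    present = np.unique(data)
    if label not in present:
        raise ValueError(f"{path}: label {label} absent "
                         f"(available: {present.tolist()})")
    spacing = np.asarray(img.header.get_zooms()[:3], float)
    return data == label, img.affine.copy(), spacing


def write_label_volume(mask: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mask, np.int16), affine), str(path))


def write_vector_field_nifti(field, path) -> None:
    """DenseVectorField (or scalar grid + domain) as a 4D/3D NIfTI volume."""
    domain = field.domain
    affine = np.eye(4)
    affine[:3, :3] *= domain.spacing
    affine[:3, 3] = domain.origin
    data = np.nan_to_num(field.vectors, nan=0.0).astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine), str(path))


# ------------------------------------------------------------ small tables

def save_spharm(model: SpharmModel, path) -> None:
    with open(path, "w") as f:
        f.write("# hippomorph SPHARM coefficients\n"
                "# basis: real orthonormal spherical harmonics "
                "(Condon-Shortley derived; see spharm module docs)\n"
                f"# max_degree {model.max_degree}\n"
                "# l m cx cy cz\n")
        for l in range(model.max_degree + 1):
            for m in range(-l, l + 1):
                c = model.coefficients[l * l + l + m]
                f.write(f"{l} {m} " + " ".join("%.17g" % x for x in c) + "\n")


def load_spharm(path) -> SpharmModel:
    max_degree = None
    rows = {}
    with open(path) as f:
        for line in f:
            if line.startswith("#"):
                if "max_degree" in line:
                    max_degree = int(line.split()[-1])
                continue
            l, m, cx, cy, cz = line.split()
            rows[(int(l), int(m))] = [float(cx), float(cy), float(cz)]
    if max_degree is None:
        max_degree = max(l for l, _ in rows)
    coeff = np.zeros(((max_degree + 1) ** 2, 3))
    for (l, m), c in rows.items():
        coeff[l * l + l + m] = c
    return SpharmModel(max_degree, coeff)


def save_transform(transform: RigidTransform, path) -> None:
    np.savetxt(path, transform.as_matrix(), fmt="%.17g",
               header="hippomorph rigid transform (4x4 homogeneous, mm)")


def load_transform(path) -> RigidTransform:
    m = np.loadtxt(path)
    if m.shape != (4, 4):
        raise ValueError(f"{path}: expected a 4x4 matrix")
    return RigidTransform(m[:3, :3], m[:3, 3])


def save_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return str(o)
    with open(path, "w") as f:
        json.dump(obj, f, indent=1, default=default, sort_keys=True)
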