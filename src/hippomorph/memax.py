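"""Mean meridian axis (MEMAX): a correspondence-preserving skeleton.

The spherical parameterization singles out two prime meridians: the curve of
surface points at longitude 0 and its counterpart at longitude pi, each
traced over latitudes theta in (0, pi).  Averaging the two point sets
pair-wise (Euclidean midpoint per latitude) yields the mean meridian axis,
a centerline that inherits the SPHARM point correspondence and needs no
external reference to express position and bending.

Bending is quantified by a signed Gaussian curvature: an open triangulated
strip is spanned between the two meridians through the MEMAX (a 3 x K
lattice), the curvature magnitude at each interior MEMAX point comes from
the intrinsic angle-deficit (Gauss-Bonnet) estimator

    |kappa| = (2 pi - sum of incident angles) / A_mixed,

and the sign from the discrete mean curvature with respect to the strip's
consistent normal, so bending convex toward the normal is positive.  The
sign is undefined where the mean curvature vanishes (perfectly flat or
exactly balanced saddle points); there the magnitude is ~0 or the estimate
inherits the discrete sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .spharm import SpharmModel, vertex_normals_angle_weighted

__all__ = ["Meridians", "StripMesh", "Memax", "prime_meridians",
           "compute_memax", "memax_open_mesh", "strip_gaussian_curvature",
           "signed_gaussian_curvature", "position_vectors", "memax_from_model"]


@dataclass
class Meridians:
    """Prime meridian point sets at longitudes 0 (upper) and pi (lower)."""

    latitudes: np.ndarray  # (K,), strictly increasing in (0, pi)
    upper: np.ndarray  # (K, 3): s(theta_k) at phi = 0
    lower: np.ndarray  # (K, 3): s-hat(theta_k) at phi = pi


@dataclass
class StripMesh:
    """Open triangulated 3 x K lattice (rows: upper meridian, MEMAX, lower)."""

    vertices: np.ndarray  # (3K, 3); vertex (row, k) at index row*K + k
    faces: np.ndarray  # (4(K-1), 3)
    K: int

    def row(self, r: int) -> np.ndarray:
        return self.vertices[r * self.K:(r + 1) * self.K]


@dataclass
class Memax:
    """MEMAX sample points with curvature and supporting strip."""

    points: np.ndarray  # (K, 3)
    latitudes: np.ndarray  # (K,)
    curvature: np.ndarray  # (K,) signed Gaussian curvature, mm^-2
    curvature_valid: np.ndarray  # (K,) bool; False where copied/degenerate
    strip: StripMesh


def prime_meridians(model: SpharmModel, K: int = 50) -> Meridians:
    """Equiangular meridian sampling: theta_k = k pi / (K+1), k = 1..K."""
    if K < 3:
        raise ValueError("K must be >= 3")
    theta = np.arange(1, K + 1) * np.pi / (K + 1)
    upper = model.evaluate(theta, np.zeros(K))
    lower = model.evaluate(theta, np.full(K, np.pi))
    return Meridians(latitudes=theta, upper=upper, lower=lower)


def compute_memax(meridians: Meridians) -> np.ndarray:
    """Pair-wise midpoints of the two prime meridians, (K, 3)."""
    return 0.5 * (meridians.upper + meridians.lower)


def _lattice_faces(K: int) -> np.ndarray:
    faces = []
    for r in range(2):
        for k in range(K - 1):
            a = r * K + k
            b = (r + 1) * K + k
            faces.append((a, b, a + 1))
            faces.append((b, b + 1, a + 1))
    return np.array(faces, dtype=np.int64)


def _edge_triangle_hits(vertices: np.ndarray, faces: np.ndarray) -> bool:
    """Crude self-intersection check: any edge piercing a non-adjacent face."""
    edges = np.unique(np.sort(np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1), axis=0)
    tri = vertices[faces]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    for e0, e1 in edges:
        p, q = vertices[e0], vertices[e1]
        d = q - p
        denom = n @ d
        shares = (faces == e0).any(axis=1) | (faces == e1).any(axis=1)
        cand = np.abs(denom) > 1e-12
        cand &= ~shares
        if not cand.any():
            continue
        t = np.einsum("ij,ij->i", n[cand], tri[cand, 0] - p) / denom[cand]
        seg = (t > 1e-9) & (t < 1 - 1e-9)
        if not seg.any():
            continue
        pts = p + t[seg, None] * d
        tc = tri[cand][seg]
        v0 = tc[:, 1] - tc[:, 0]
        v1 = tc[:, 2] - tc[:, 0]
        v2 = pts - tc[:, 0]
        d00 = np.einsum("ij,ij->i", v0, v0)
        d01 = np.einsum("ij,ij->i", v0, v1)
        d11 = np.einsum("ij,ij->i", v1, v1)
        d20 = np.einsum("ij,ij->i", v2, v0)
        d21 = np.einsum("ij,ij->i", v2, v1)
        den = d00 * d11 - d01 * d01
        ok = den > 1e-300
        a = np.where(ok, (d11 * d20 - d01 * d21) / np.where(ok, den, 1), -1)
        b = np.where(ok, (d00 * d21 - d01 * d20) / np.where(ok, den, 1), -1)
        if np.any((a > 1e-9) & (b > 1e-9) & (a + b < 1 - 1e-9)):
            return True
    return False


def memax_open_mesh(meridians: Meridians, memax_points: np.ndarray) -> StripMesh:
    """Open strip through upper meridian, MEMAX, lower meridian."""
    K = len(meridians.latitudes)
    if K < 3:
        raise ValueError("K must be >= 3")
    vertices = np.concatenate([meridians.upper, memax_points, meridians.lower])
    faces = _lattice_faces(K)
    strip = StripMesh(vertices=vertices, faces=faces, K=K)
    if _edge_triangle_hits(vertices, faces):
        warnings.warn("MEMAX strip is self-intersecting", RuntimeWarning,
                      stacklevel=2)
    return strip


def _cot(a: np.ndarray, b: np.ndarray) -> float:
    """Cotangent of the angle between vectors a and b."""
    cross = np.linalg.norm(np.cross(a, b))
    return float(a @ b) / max(cross, 1e-300)


def strip_gaussian_curvature(strip: StripMesh) -> tuple[np.ndarray, np.ndarray]:
    """Signed Gaussian curvature along the middle lattice row.

    Returns (kappa, valid): kappa has one value per column k; the angle
    deficit is defined only at interior columns 1..K-2, the two end columns
    copy their nearest interior value and are flagged invalid.
    """
    K = strip.K
    V, F = strip.vertices, strip.faces
    mid = np.arange(K, 2 * K)  # middle-row vertex indices
    normals = vertex_normals_angle_weighted(V, F)

    # incident triangles per middle vertex
    incident: dict[int, list] = {int(i): [] for i in mid}
    for f in F:
        for v in f:
            if K <= v < 2 * K:
                incident[int(v)].append(f)

    kappa = np.zeros(K)
    valid = np.zeros(K, dtype=bool)
    for k in range(1, K - 1):
        i = K + k
        angle_sum = 0.0
        area = 0.0
        lap = np.zeros(3)
        degenerate = False
        for f in incident[i]:
            f = [int(x) for x in f]
            j = f.index(i)
            p = V[i]
            q = V[f[(j + 1) % 3]]
            r = V[f[(j + 2) % 3]]
            u, w = q - p, r - p
            nu, nw = np.linalg.norm(u), np.linalg.norm(w)
            if nu < 1e-12 or nw < 1e-12:
                degenerate = True
                break
            ang = np.arccos(np.clip((u @ w) / (nu * nw), -1.0, 1.0))
            angle_sum += ang
            # Meyer mixed area
            a_q = np.arccos(np.clip(((p - q) @ (r - q))
                                    / max(np.linalg.norm(p - q)
                                          * np.linalg.norm(r - q), 1e-300),
                                    -1, 1))
            a_r = np.pi - ang - a_q
            tri_area = 0.5 * np.linalg.norm(np.cross(u, w))
            if tri_area < 1e-300:
                degenerate = True
                break
            if max(ang, a_q, a_r) <= np.pi / 2 + 1e-12:
                area += ((nw ** 2) * _cot(p - q, r - q)
                         + (nu ** 2) * _cot(p - r, q - r)) / 8.0
            elif ang > np.pi / 2:
                area += tri_area / 2.0
            else:
                area += tri_area / 4.0
            # cotangent Laplacian contributions (for the mean-curvature sign)
            lap += _cot(p - q, r - q) * (r - p) + _cot(p - r, q - r) * (q - p)
        if degenerate or area <= 1e-300:
            kappa[k] = np.nan
            continue
        deficit = 2.0 * np.pi - angle_sum
        h_sign = -(lap @ normals[i])  # >0 where surface bends convex to normal
        s = 1.0 if h_sign >= 0 else -1.0
        kappa[k] = s * abs(deficit / area)
        valid[k] = True

    interior = np.where(valid)[0]
    if len(interior) == 0:
        raise ValueError("no valid interior curvature points (degenerate strip)")
    for k in range(K):
        if not valid[k]:
            kappa[k] = kappa[interior[np.argmin(np.abs(interior - k))]]
    return kappa, valid


def signed_gaussian_curvature(strip: StripMesh,
                              memax_points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Curvature at the MEMAX points of their open strip (see strip_gaussian_curvature)."""
    if not np.allclose(strip.row(1), memax_points):
        raise ValueError("memax points are not the middle row of the strip")
    return strip_gaussian_curvature(strip)


def position_vectors(memax_points: np.ndarray,
                     template_memax: np.ndarray) -> np.ndarray:
    """Per-point subject-minus-template 3D offsets (input to Hotelling T^2)."""
    a = np.asarray(memax_points, float)
    b = np.asarray(template_memax, float)
    if a.shape != b.shape:
        raise ValueError("MEMAX point counts differ")
    return a - b


def memax_from_model(model: SpharmModel, K: int = 50) -> Memax:
    """Full construction: meridians -> midpoints -> strip -> curvature."""
    mer = prime_meridians(model, K)
    pts = compute_memax(mer)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        strip = memax_open_mesh(mer, pts)
    kappa, valid = strip_gaussian_curvature(strip)
    return Memax(points=pts, latitudes=mer.latitudes, curvature=kappa,
                 curvature_valid=valid, strip=strip)
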