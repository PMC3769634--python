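"""Spherical-harmonic surface description with point-distribution sampling.

A closed genus-zero surface carrying a spherical parameterization
(theta, phi per vertex) is expanded coordinate-wise in a real, orthonormal
spherical-harmonic basis:

    x(theta, phi) = sum_{l=0}^{L} sum_{m=-l}^{l} c_lm Y_lm(theta, phi)

with c_lm a 3-vector per (l, m).  Sampling the model at a fixed set of
parameter locations (the subdivided-icosahedron sampling of
:mod:`hippomorph._sampling`) yields a point-distribution-model surface whose
vertex k corresponds across all subjects of a study.

Basis convention
----------------
Real harmonics built from the complex Condon-Shortley basis Y_l^m:

* m = 0:   Y_l0  (already real)
* m > 0:   sqrt(2) (-1)^m Re(Y_l^m)
* m < 0:   sqrt(2) (-1)^|m| Im(Y_l^|m|)

The basis is orthonormal on the sphere, so Y_00 = 1/sqrt(4 pi) and the
degree-0 coefficient of a coordinate function equals its spherical mean
times sqrt(4 pi) (for a surface represented exactly, the centroid offset).
Degree-1 harmonics are sqrt(3 / 4 pi) times the unit-direction components
(Y_11 ~ x, Y_1-1 ~ y, Y_10 ~ z), which is what makes the first-order
ellipsoid a plain 3x3 SVD of the degree-1 coefficient block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import sph_harm_y

from ._sampling import icosphere_sampling

__all__ = [
    "SphericalParamMesh",
    "SpharmModel",
    "PdmSurface",
    "Ellipsoid1",
    "real_sph_harm_basis",
    "fit_spharm",
    "reconstruct_pdm",
    "first_order_ellipsoid",
    "mesh_volume",
    "check_closed",
    "vertex_normals_angle_weighted",
]

Y00 = 1.0 / np.sqrt(4.0 * np.pi)  # degree-0 basis value (constant)
Y1 = np.sqrt(3.0 / (4.0 * np.pi))  # degree-1 basis amplitude


# --------------------------------------------------------------------------
# containers


@dataclass
class SphericalParamMesh:
    """Closed genus-zero triangle mesh with per-vertex (theta, phi)."""

    vertices: np.ndarray  # (N, 3) mm
    faces: np.ndarray  # (F, 3) int
    theta: np.ndarray  # (N,) polar angle in [0, pi]
    phi: np.ndarray  # (N,) azimuth in [0, 2 pi)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.theta = np.asarray(self.theta, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)

    def validate(self) -> None:
        n = len(self.vertices)
        if not (len(self.theta) == len(self.phi) == n):
            raise ValueError("theta/phi must have one entry per vertex")
        if self.theta.min() < -1e-12 or self.theta.max() > np.pi + 1e-12:
            raise ValueError("theta outside [0, pi]")
        check_closed(self.faces)
        pole = (self.theta < 1e-9) | (self.theta > np.pi - 1e-9)
        if pole.sum() != 2:
            raise ValueError("expected exactly one vertex at each pole")
        pairs = {(round(t, 10), round(p, 10)) for t, p in
                 zip(self.theta[~pole], self.phi[~pole])}
        if len(pairs) != int((~pole).sum()):
            raise ValueError("degenerate parameterization: duplicate (theta, phi)")


@dataclass
class SpharmModel:
    """Real spherical-harmonic coefficients of the three coordinate functions."""

    max_degree: int
    coefficients: np.ndarray  # ((L+1)^2, 3); row index l*l + l + m
    residuals: np.ndarray | None = None  # per-vertex fit residual (mm), if fitted

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        expected = (self.max_degree + 1) ** 2
        if self.coefficients.shape != (expected, 3):
            raise ValueError(
                f"expected {(expected, 3)} coefficients for L={self.max_degree}, "
                f"got {self.coefficients.shape}"
            )

    def evaluate(self, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        """Surface points at the given parameter locations, (N, 3) mm."""
        B = real_sph_harm_basis(self.max_degree, np.atleast_1d(theta),
                                np.atleast_1d(phi))
        return B @ self.coefficients

    @property
    def centroid(self) -> np.ndarray:
        """Spherical-mean position encoded by the degree-0 coefficients."""
        return self.coefficients[0] * Y00

    def degree_block(self, degree: int) -> np.ndarray:
        """(2l+1, 3) coefficient rows of one degree, orders -l..l."""
        lo = degree * degree
        return self.coefficients[lo: lo + 2 * degree + 1]


@dataclass
class PdmSurface:
    """Fixed-correspondence sampled surface (point distribution model)."""

    vertices: np.ndarray  # (N, 3) mm
    faces: np.ndarray  # (F, 3) int, shared across subjects
    theta: np.ndarray
    phi: np.ndarray
    subject_id: str = ""
    hemisphere: str = ""  # "left" | "right" | ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.theta = np.asarray(self.theta, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def copy_with(self, vertices: np.ndarray) -> "PdmSurface":
        return PdmSurface(np.asarray(vertices, float), self.faces, self.theta,
                          self.phi, self.subject_id, self.hemisphere,
                          dict(self.metadata))

    def same_sampling(self, other: "PdmSurface") -> bool:
        return (self.vertices.shape == other.vertices.shape
                and np.array_equal(self.faces, other.faces))

    def as_param_mesh(self) -> SphericalParamMesh:
        return SphericalParamMesh(self.vertices, self.faces, self.theta, self.phi)


@dataclass
class Ellipsoid1:
    """First-order (degree-1) ellipsoid of a SPHARM model."""

    center: np.ndarray  # (3,)
    semi_axes: np.ndarray  # (3,) descending, mm
    axis_directions: np.ndarray  # (3, 3) rows orthonormal, right-handed

    @property
    def longitudinal_axis(self) -> np.ndarray:
        return self.axis_directions[0]


# --------------------------------------------------------------------------
# basis

_BASIS_CACHE: dict[tuple, np.ndarray] = {}


def real_sph_harm_basis(max_degree: int, theta: np.ndarray,
                        phi: np.ndarray) -> np.ndarray:
    """Design matrix of real orthonormal spherical harmonics.

    Returns an (N, (L+1)^2) array; column index l*l + l + m.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    key = (max_degree, theta.tobytes(), phi.tobytes())
    cached = _BASIS_CACHE.get(key)
    if cached is not None:
        return cached
    n = len(theta)
    B = np.empty((n, (max_degree + 1) ** 2))
    for l in range(max_degree + 1):
        B[:, l * l + l] = np.real(sph_harm_y(l, 0, theta, phi))
        for m in range(1, l + 1):
            y = sph_harm_y(l, m, theta, phi)
            s = np.sqrt(2.0) * (-1.0) ** m
            B[:, l * l + l + m] = s * np.real(y)
            B[:, l * l + l - m] = s * np.imag(y)
    B.setflags(write=False)
    if len(_BASIS_CACHE) > 32:
        _BASIS_CACHE.clear()
    _BASIS_CACHE[key] = B
    return B


# --------------------------------------------------------------------------
# operations


def fit_spharm(mesh: SphericalParamMesh, max_degree: int) -> SpharmModel:
    """Least-squares SPHARM fit of the three coordinate functions.

    The system is solved per coordinate; it is overdetermined as long as the
    mesh has at least (L+1)^2 vertices in general position on the sphere.
    """
    mesh.validate()
    n_coeff = (max_degree + 1) ** 2
    if len(mesh.vertices) < n_coeff:
        raise ValueError(
            f"underdetermined fit: {len(mesh.vertices)} vertices "
            f"< {n_coeff} coefficients for L={max_degree}"
        )
    B = real_sph_harm_basis(max_degree, mesh.theta, mesh.phi)
    coeff, _, rank, _ = np.linalg.lstsq(B, mesh.vertices, rcond=None)
    if rank < n_coeff:
        raise ValueError(
            "degenerate parameterization: rank-deficient design matrix "
            f"(rank {rank} < {n_coeff})"
        )
    residuals = np.linalg.norm(B @ coeff - mesh.vertices, axis=1)
    return SpharmModel(max_degree, coeff, residuals=residuals)


def reconstruct_pdm(model: SpharmModel, sampling=None, subject_id: str = "",
                    hemisphere: str = "") -> PdmSurface:
    """Sample the model at fixed parameter locations.

    ``sampling`` is a (vertices, faces, theta, phi) tuple on the unit sphere;
    the default is the 1,002-vertex subdivided icosahedron.  Using the same
    sampling for all subjects yields vertex-wise correspondence.
    """
    if sampling is None:
        sampling = icosphere_sampling()
    _, faces, theta, phi = sampling
    if len(theta) < 4:
        raise ValueError("sampling needs at least 4 vertices")
    verts = model.evaluate(theta, phi)
    return PdmSurface(verts, np.array(faces), np.array(theta), np.array(phi),
                      subject_id=subject_id, hemisphere=hemisphere)


def _tie_break_directions(singular_values: np.ndarray, U: np.ndarray,
                          rel_tol: float = 1e-8) -> np.ndarray:
    """Deterministic axes for (near-)degenerate singular values.

    Within a group of equal singular values the axis directions are only
    defined up to rotation; pick, per group, the direction in the group's
    subspace closest to +z, then to +x (documented tie-break).
    """
    s = singular_values
    axes = U.T.copy()  # rows
    i = 0
    while i < 3:
        j = i
        while j + 1 < 3 and abs(s[j + 1] - s[i]) <= rel_tol * max(s[0], 1e-300):
            j += 1
        if j > i:
            sub = axes[i: j + 1]  # orthonormal rows spanning the tied subspace
            picked = []
            for ref in (np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]),
                        np.array([0.0, 1.0, 0.0])):
                if len(picked) == len(sub):
                    break
                v = sub.T @ (sub @ ref)
                for p in picked:
                    v = v - (v @ p) * p
                if np.linalg.norm(v) > 1e-9:
                    picked.append(v / np.linalg.norm(v))
            k = 0
            while len(picked) < len(sub):  # fall back to the SVD axes
                v = sub[k]
                for p in picked:
                    v = v - (v @ p) * p
                if np.linalg.norm(v) > 1e-9:
                    picked.append(v / np.linalg.norm(v))
                k += 1
            axes[i: j + 1] = np.array(picked)
        i = j + 1
    # deterministic signs: first nonzero-ish component of each axis positive
    for r in range(3):
        a = axes[r]
        for c in (2, 0, 1):
            if abs(a[c]) > 1e-9:
                if a[c] < 0:
                    axes[r] = -a
                break
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return axes


def first_order_ellipsoid(model: SpharmModel) -> Ellipsoid1:
    """Ellipsoid defined by the degree-0 (center) and degree-1 (axes) terms.

    The degree-1 part of the surface is a linear map of the unit direction,
    p(u) = M u with M = sqrt(3/4pi) [c_{1,1} | c_{1,-1} | c_{1,0}]; its image
    of the sphere is the ellipsoid with semi-axes the singular values of M.
    """
    if model.max_degree < 1:
        raise ValueError("model must have max_degree >= 1")
    block = model.degree_block(1)  # rows: m = -1, 0, +1 -> y, z, x directions
    M = Y1 * np.column_stack([block[2], block[0], block[1]])
    U, s, _ = np.linalg.svd(M)
    if s[0] <= 0 or s[2] < 1e-8 * s[0]:
        raise ValueError("degenerate degree-1 block (flat shape): rank < 3")
    axes = _tie_break_directions(s, U)
    return Ellipsoid1(center=model.centroid, semi_axes=s, axis_directions=axes)


def check_closed(faces: np.ndarray) -> None:
    """Raise unless every edge is shared by exactly two opposed half-edges."""
    faces = np.asarray(faces)
    half = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    fwd = {tuple(e) for e in half.tolist()}
    if len(fwd) != len(half):
        raise ValueError("mesh not consistently oriented (repeated half-edge)")
    for a, b in fwd:
        if (b, a) not in fwd:
            raise ValueError("open mesh: boundary edge present")


def mesh_volume(surface: PdmSurface | SphericalParamMesh) -> float:
    """Signed enclosed volume by the divergence theorem (mm^3).

    Positive for outward-oriented closed meshes; negative values indicate
    inverted orientation and are returned as-is so callers can flag them.
    """
    check_closed(surface.faces)
    v = surface.vertices
    t = v[surface.faces]
    return float(np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0)


def vertex_normals_angle_weighted(vertices: np.ndarray,
                                  faces: np.ndarray) -> np.ndarray:
    """Per-vertex unit normals, face normals weighted by incident corner angle."""
    v = np.asarray(vertices, float)
    f = np.asarray(faces)
    p0, p1, p2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    fn = np.cross(p1 - p0, p2 - p0)
    norm = np.linalg.norm(fn, axis=1, keepdims=True)
    fn = fn / np.where(norm > 0, norm, 1.0)

    def corner_angle(a, b, c):
        u, w = b - a, c - a
        cu = np.linalg.norm(u, axis=1)
        cw = np.linalg.norm(w, axis=1)
        cosang = np.einsum("ij,ij->i", u, w) / np.where(cu * cw > 0, cu * cw, 1.0)
        return np.arccos(np.clip(cosang, -1.0, 1.0))

    out = np.zeros_like(v)
    angles = [corner_angle(p0, p1, p2), corner_angle(p1, p2, p0),
              corner_angle(p2, p0, p1)]
    for corner in range(3):
        np.add.at(out, f[:, corner], fn * angles[corner][:, None])
    n = np.linalg.norm(out, axis=1, keepdims=True)
    return out / np.where(n > 0, n, 1.0)
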