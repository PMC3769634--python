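"""Vertex-wise volume change from template-to-subject displacement.

The displacement of each template vertex toward the corresponding subject
vertex is extended into the template interior as the steady-state solution of
the heat equation (the discrete Laplace equation, one scalar problem per
vector component, Dirichlet data on the rasterized surface).  The Jacobian
determinant of the mapping x -> x + u(x),

    J(x) = det(I + grad u(x)),

is a local volume-change factor: J - 1 > 0 growth, J - 1 < 0 shrinkage.
J is computed on the interior voxel grid by finite differences and projected
back to the surface vertices, sampled half a voxel inward along the vertex
normal because one-sided gradients at the mask edge are noisier.

The steady state is the unique bounded interpolant of the boundary data, so
the discrete solution obeys a maximum principle (interior values never exceed
the per-component boundary extrema) and reproduces constant and linear
displacement fields exactly; both properties are exercised by the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg, splu
from scipy.spatial import cKDTree

from .spharm import PdmSurface, vertex_normals_angle_weighted

__all__ = ["DisplacementField", "VoxelDomain", "DenseVectorField",
           "JacobianMap", "displacement_field", "voxelize",
           "interpolate_heat", "jacobian_determinant", "project_to_surface",
           "volume_change_map"]

_STENCIL = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class DisplacementField:
    """Per-template-vertex displacement toward the subject surface."""

    vectors: np.ndarray  # (N, 3) mm
    normal_component: np.ndarray  # (N,) mm, positive outward


@dataclass
class VoxelDomain:
    """Isotropic voxel grid over a closed surface with Dirichlet bookkeeping.

    ``interior`` marks voxels whose centers fall inside the surface (even-odd
    ray test).  Dirichlet voxels are interior voxels with at least one
    exterior 6-neighbor plus every voxel containing a surface vertex; each
    carries inverse-distance interpolation weights from its 3 nearest
    surface vertices.
    """

    origin: np.ndarray  # (3,) mm, center of voxel (0,0,0)
    spacing: float
    shape: tuple
    interior: np.ndarray  # (nx, ny, nz) bool
    dirichlet: np.ndarray  # (nx, ny, nz) bool
    dirichlet_vertex_idx: np.ndarray  # (B, 3) int, nearest surface vertices
    dirichlet_weights: np.ndarray  # (B, 3) convex weights

    @property
    def domain_mask(self) -> np.ndarray:
        return self.interior | self.dirichlet

    def voxel_centers(self, ijk: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(ijk, float) * self.spacing

    def assign_boundary(self, per_vertex_field: np.ndarray) -> np.ndarray:
        """Dirichlet values for a per-surface-vertex field (any trailing shape)."""
        f = np.asarray(per_vertex_field, float)
        vals = f[self.dirichlet_vertex_idx]  # (B, 3, ...)
        w = self.dirichlet_weights
        w = w.reshape(w.shape + (1,) * (vals.ndim - 2))
        return (vals * w).sum(axis=1)


@dataclass
class DenseVectorField:
    """Componentwise-harmonic displacement on the voxel grid."""

    domain: VoxelDomain
    vectors: np.ndarray  # (nx, ny, nz, 3), defined on domain_mask
    residual: float  # final linear-system residual (max over components)


@dataclass
class JacobianMap:
    """Per-vertex Jacobian determinant (unitless)."""

    values: np.ndarray  # (N,)
    valid: np.ndarray  # (N,) bool


def displacement_field(template: PdmSurface,
                       subject: PdmSurface) -> DisplacementField:
    """Subject-minus-template vertex displacements and their normal parts."""
    if not subject.same_sampling(template):
        raise ValueError("subject and template do not share the sampling")
    vec = subject.vertices - template.vertices
    normals = vertex_normals_angle_weighted(template.vertices, template.faces)
    return DisplacementField(vec, np.einsum("ij,ij->i", vec, normals))


def _interior_parity(vertices: np.ndarray, faces: np.ndarray,
                     origin: np.ndarray, spacing: float,
                     shape: tuple) -> np.ndarray:
    """Even-odd ray test at all voxel centers, vertical (+z) rays per column.

    Columns are offset by a tiny fixed epsilon so rays do not pass exactly
    through mesh vertices or edges of analytically placed meshes.
    """
    nx, ny, nz = shape
    eps = 1e-6 * spacing * np.array([1.0, np.sqrt(2.0)])
    cx = origin[0] + np.arange(nx) * spacing + eps[0]
    cy = origin[1] + np.arange(ny) * spacing + eps[1]
    cz = origin[2] + np.arange(nz) * spacing

    tri = vertices[faces]  # (F, 3, 3)
    inside = np.zeros(shape, dtype=bool)
    # crossings per column, accumulated triangle by triangle
    crossings: dict[tuple, list] = {}
    for t in tri:
        x0, x1 = t[:, 0].min(), t[:, 0].max()
        y0, y1 = t[:, 1].min(), t[:, 1].max()
        i0, i1 = np.searchsorted(cx, [x0, x1])
        j0, j1 = np.searchsorted(cy, [y0, y1])
        if i0 == i1 or j0 == j1:
            continue
        gx, gy = np.meshgrid(cx[i0:i1], cy[j0:j1], indexing="ij")
        px = gx.ravel() - t[0, 0]
        py = gy.ravel() - t[0, 1]
        e1 = t[1, :2] - t[0, :2]
        e2 = t[2, :2] - t[0, :2]
        det = e1[0] * e2[1] - e1[1] * e2[0]
        if abs(det) < 1e-300:
            continue
        a = (px * e2[1] - py * e2[0]) / det
        b = (-px * e1[1] + py * e1[0]) / det
        hit = (a >= 0) & (b >= 0) & (a + b <= 1)
        if not hit.any():
            continue
        # plane z at the hit points
        n = np.cross(t[1] - t[0], t[2] - t[0])
        if abs(n[2]) < 1e-300:
            continue
        z = t[0, 2] - (n[0] * px[hit] + n[1] * py[hit]) / n[2]
        ii = (i0 + np.arange(i1 - i0).repeat(j1 - j0))[hit]
        jj = (np.tile(j0 + np.arange(j1 - j0), i1 - i0))[hit]
        for i, j, zz in zip(ii, jj, z):
            crossings.setdefault((int(i), int(j)), []).append(zz)
    for (i, j), zs in crossings.items():
        zs = np.sort(np.asarray(zs))
        # voxel center is inside iff an odd number of crossings lie above it
        above = len(zs) - np.searchsorted(zs, cz, side="right")
        inside[i, j, :] = (above % 2) == 1
    return inside


def voxelize(surface: PdmSurface, spacing: float = 1.0,
             margin_voxels: int = 2) -> VoxelDomain:
    """Rasterize a closed surface into an interior mask plus Dirichlet voxels."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    v = surface.vertices
    origin = np.floor(v.min(axis=0) / spacing) * spacing - margin_voxels * spacing
    top = v.max(axis=0) + margin_voxels * spacing
    shape = tuple((np.ceil((top - origin) / spacing)).astype(int) + 1)

    interior = _interior_parity(v, surface.faces, origin, spacing, shape)
    if not interior.any():
        raise ValueError(f"spacing {spacing} too coarse: interior is empty")

    eroded = ndimage.binary_erosion(interior, structure=_STENCIL,
                                    border_value=0)
    dirichlet = interior & ~eroded
    # voxels containing surface vertices also carry Dirichlet data
    vx = np.rint((v - origin) / spacing).astype(int)
    vx = np.clip(vx, 0, np.array(shape) - 1)
    dirichlet[vx[:, 0], vx[:, 1], vx[:, 2]] = True

    bnd = np.argwhere(dirichlet)
    tree = cKDTree(v)
    d, idx = tree.query(origin + bnd * spacing, k=3)
    d = np.maximum(d, 1e-12)
    w = 1.0 / d
    exact = d <= 1e-9
    w[exact.any(axis=1)] = 0.0
    w[exact] = 1.0
    w = w / w.sum(axis=1, keepdims=True)
    return VoxelDomain(origin=np.asarray(origin, float), spacing=float(spacing),
                       shape=shape, interior=interior, dirichlet=dirichlet,
                       dirichlet_vertex_idx=idx, dirichlet_weights=w)


def interpolate_heat(domain: VoxelDomain, boundary_values: np.ndarray,
                     tolerance: float = 1e-8,
                     direct_max_unknowns: int = 200_000) -> DenseVectorField:
    """Steady-state heat (Laplace) interpolation of Dirichlet boundary data.

    ``boundary_values``: (B, C) values at ``domain.dirichlet`` voxels, in the
    order produced by ``np.argwhere(domain.dirichlet)`` (as returned by
    ``VoxelDomain.assign_boundary``).  Solved independently per component on
    the 7-point stencil; sparse direct solve up to ``direct_max_unknowns``
    unknowns, conjugate gradients beyond.
    """
    boundary_values = np.asarray(boundary_values, float)
    if boundary_values.ndim == 1:
        boundary_values = boundary_values[:, None]

    labels, n_comp = ndimage.label(domain.interior, structure=_STENCIL)
    for comp in range(1, n_comp + 1):
        if not (domain.dirichlet & (labels == comp)).any():
            raise ValueError(f"interior component {comp} has no boundary contact")

    unknown = domain.interior & ~domain.dirichlet
    n_unknown = int(unknown.sum())
    grid_index = -np.ones(domain.shape, dtype=np.int64)
    unk_ijk = np.argwhere(unknown)
    grid_index[unknown] = np.arange(n_unknown)

    dir_index = -np.ones(domain.shape, dtype=np.int64)
    dir_ijk = np.argwhere(domain.dirichlet)
    dir_index[domain.dirichlet] = np.arange(len(dir_ijk))

    n_rhs = boundary_values.shape[1]
    vectors = np.full(domain.shape + (n_rhs,), np.nan)
    vectors[domain.dirichlet] = boundary_values

    residual = 0.0
    if n_unknown:
        rows, cols, vals = [], [], []
        b = np.zeros((n_unknown, n_rhs))
        offsets = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                            [0, -1, 0], [0, 0, 1], [0, 0, -1]])
        diag = np.zeros(n_unknown)
        for off in offsets:
            nb = unk_ijk + off
            ok = np.all((nb >= 0) & (nb < np.array(domain.shape)), axis=1)
            nb_ok = nb[ok]
            u_id = np.arange(n_unknown)[ok]
            nb_unknown = grid_index[nb_ok[:, 0], nb_ok[:, 1], nb_ok[:, 2]]
            nb_dir = dir_index[nb_ok[:, 0], nb_ok[:, 1], nb_ok[:, 2]]
            in_domain = (nb_unknown >= 0) | (nb_dir >= 0)
            diag[u_id[in_domain]] += 1.0
            m = nb_unknown >= 0
            rows.append(u_id[m])
            cols.append(nb_unknown[m])
            vals.append(-np.ones(int(m.sum())))
            md = (nb_dir >= 0) & ~m
            b[u_id[md]] += boundary_values[nb_dir[md]]
        rows.append(np.arange(n_unknown))
        cols.append(np.arange(n_unknown))
        vals.append(diag)
        A = sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n_unknown, n_unknown))
        if n_unknown <= direct_max_unknowns:
            lu = splu(A.tocsc())
            x = np.column_stack([lu.solve(b[:, c]) for c in range(n_rhs)])
        else:
            x = np.empty((n_unknown, n_rhs))
            for c in range(n_rhs):
                xc, info = cg(A, b[:, c], rtol=tolerance, maxiter=20_000)
                if info != 0:
                    r = float(np.linalg.norm(A @ xc - b[:, c]))
                    raise RuntimeError(
                        f"heat interpolation did not converge (residual {r:.3e})")
                x[:, c] = xc
        residual = float(np.abs(A @ x - b).max()) / max(1.0, float(np.abs(b).max()))
        if residual > max(tolerance * 100, 1e-6):
            raise RuntimeError(
                f"heat interpolation residual {residual:.3e} above tolerance")
        vectors[unknown] = x
    return DenseVectorField(domain=domain, vectors=vectors, residual=residual)


def jacobian_determinant(field: DenseVectorField) -> tuple[np.ndarray, np.ndarray]:
    """J = det(I + grad u) per interior voxel.

    Central differences where both axis neighbors carry values, one-sided at
    mask edges; voxels lacking any valid neighbor along some axis are
    excluded (valid mask False).
    """
    dom = field.domain
    h = dom.spacing
    mask = dom.domain_mask
    u = field.vectors
    grad = np.zeros(dom.shape + (3, 3))  # [..., component, axis]
    axis_ok = np.ones(dom.shape + (3,), dtype=bool)
    for ax in range(3):
        plus = np.zeros_like(mask)
        minus = np.zeros_like(mask)
        sl_all = [slice(None)] * 3
        sp, sm = list(sl_all), list(sl_all)
        sp[ax], sm[ax] = slice(1, None), slice(None, -1)
        plus[tuple(sm)] = mask[tuple(sp)]
        minus[tuple(sp)] = mask[tuple(sm)]
        up = np.roll(u, -1, axis=ax)
        um = np.roll(u, 1, axis=ax)
        central = plus & minus
        fwd = plus & ~minus
        bwd = minus & ~plus
        g = grad[..., ax]
        g[central] = (up[central] - um[central]) / (2 * h)
        g[fwd] = (up[fwd] - u[fwd]) / h
        g[bwd] = (u[bwd] - um[bwd]) / h
        axis_ok[..., ax] = plus | minus
    valid = dom.interior & axis_ok.all(axis=-1)
    F = grad + np.eye(3)
    J = np.full(dom.shape, np.nan)
    J[valid] = np.linalg.det(F[valid])
    return J, valid


def project_to_surface(J: np.ndarray, valid: np.ndarray, domain: VoxelDomain,
                       template: PdmSurface,
                       max_fallback_voxels: float = 3.0) -> JacobianMap:
    """Sample the J grid at each vertex, half a voxel inward along the normal.

    Trilinear interpolation when all 8 cell corners are valid; otherwise the
    nearest valid interior voxel within ``max_fallback_voxels`` voxels.
    """
    normals = vertex_normals_angle_weighted(template.vertices, template.faces)
    pts = template.vertices - 0.5 * domain.spacing * normals
    rel = (pts - domain.origin) / domain.spacing
    base = np.floor(rel).astype(int)
    frac = rel - base

    values = np.full(len(pts), np.nan)
    ok = np.zeros(len(pts), dtype=bool)
    shape = np.array(domain.shape)
    in_grid = np.all((base >= 0) & (base + 1 < shape), axis=1)
    corners_valid = np.zeros(len(pts), dtype=bool)
    if in_grid.any():
        idx = np.argwhere(in_grid).ravel()
        acc = np.zeros(len(idx))
        cv = np.ones(len(idx), dtype=bool)
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    c = base[idx] + [dx, dy, dz]
                    vval = valid[c[:, 0], c[:, 1], c[:, 2]]
                    cv &= vval
                    w = (np.where(dx, frac[idx, 0], 1 - frac[idx, 0])
                         * np.where(dy, frac[idx, 1], 1 - frac[idx, 1])
                         * np.where(dz, frac[idx, 2], 1 - frac[idx, 2]))
                    jv = J[c[:, 0], c[:, 1], c[:, 2]]
                    acc += w * np.where(np.isfinite(jv), jv, 0.0)
        values[idx[cv]] = acc[cv]
        corners_valid[idx] = cv
        ok[idx[cv]] = True

    missing = ~ok
    if missing.any():
        vox = np.argwhere(valid)
        if len(vox) == 0:
            raise ValueError("no valid interior voxels to project from")
        tree = cKDTree(domain.origin + vox * domain.spacing)
        d, nn = tree.query(template.vertices[missing])
        if np.any(d > max_fallback_voxels * domain.spacing):
            raise ValueError(
                "grid too coarse: vertex farther than "
                f"{max_fallback_voxels} voxels from any valid interior voxel")
        c = vox[nn]
        values[missing] = J[c[:, 0], c[:, 1], c[:, 2]]
        ok[missing] = True
    return JacobianMap(values=values, valid=ok)


def volume_change_map(template: PdmSurface, subject: PdmSurface,
                      spacing: float = 1.0,
                      domain: VoxelDomain | None = None) -> JacobianMap:
    """Full chain: displacement -> harmonic interior field -> J -> surface.

    ``domain`` may be passed to reuse one template rasterization across the
    subjects of a study (the template, hence its grid, is shared).
    """
    disp = displacement_field(template, subject)
    if domain is None:
        domain = voxelize(template, spacing)
    bnd = domain.assign_boundary(disp.vectors)
    field = interpolate_heat(domain, bnd)
    J, valid = jacobian_determinant(field)
    return project_to_surface(J, valid, domain, template)
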