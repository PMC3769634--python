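"""Fixed spherical sampling shared by every surface in a study.

The point-distribution model needs the *same* sample locations on the unit
sphere for every subject, so that vertex k of one reconstruction corresponds
anatomically to vertex k of any other.  The default sampling is a frequency-10
geodesic subdivision of the icosahedron: V = 10 f^2 + 2 = 1,002 vertices and
F = 20 f^2 = 2,000 triangles, with one vertex exactly at each pole.

The sampling is generated deterministically (vertex order and coordinates are
bit-identical across calls and processes), which is what downstream
correspondence relies on.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["icosphere_sampling", "unit_sphere_params", "DEFAULT_FREQUENCY"]

DEFAULT_FREQUENCY = 10  # 10 f^2 + 2 = 1,002 sample points


def _base_icosahedron() -> tuple[np.ndarray, np.ndarray]:
    """Icosahedron with vertices at the two poles (z = +-1)."""
    z = 1.0 / np.sqrt(5.0)
    r = 2.0 / np.sqrt(5.0)
    upper = [
        (r * np.cos(2 * np.pi * i / 5), r * np.sin(2 * np.pi * i / 5), z)
        for i in range(5)
    ]
    lower = [
        (
            r * np.cos(2 * np.pi * i / 5 + np.pi / 5),
            r * np.sin(2 * np.pi * i / 5 + np.pi / 5),
            -z,
        )
        for i in range(5)
    ]
    verts = np.array([(0.0, 0.0, 1.0)] + upper + lower + [(0.0, 0.0, -1.0)])
    faces = []
    for i in range(5):
        j = (i + 1) % 5
        faces.append((0, 1 + i, 1 + j))            # top cap
        faces.append((1 + i, 6 + i, 1 + j))        # upper band
        faces.append((1 + j, 6 + i, 6 + j))        # upper band
        faces.append((6 + i, 11, 6 + j))           # bottom cap
    return verts, np.array(faces, dtype=np.int64)


@lru_cache(maxsize=8)
def _icosphere(frequency: int) -> tuple[np.ndarray, np.ndarray]:
    if frequency < 1:
        raise ValueError("subdivision frequency must be >= 1")
    base_v, base_f = _base_icosahedron()
    f = frequency

    # A subdivided vertex is identified by its exact barycentric weights on
    # the corner vertices of the coarse face; keying on (corner id, integer
    # weight) pairs deduplicates shared edge/corner points across faces and
    # makes the coordinates independent of which face generated them.
    key_to_index: dict[tuple, int] = {}
    vertices: list[np.ndarray] = []
    faces: list[tuple[int, int, int]] = []

    def vertex_index(corners: tuple[int, int, int], weights: tuple[int, int, int]) -> int:
        items = tuple(sorted((c, w) for c, w in zip(corners, weights) if w > 0))
        idx = key_to_index.get(items)
        if idx is None:
            p = np.zeros(3)
            for c, w in items:  # canonical (sorted) order: reproducible fp sums
                p += (w / f) * base_v[c]
            p /= np.linalg.norm(p)
            idx = len(vertices)
            key_to_index[items] = idx
            vertices.append(p)
        return idx

    for tri in base_f:
        corners = tuple(int(c) for c in tri)
        for i in range(f):
            for j in range(f - i):
                k = f - i - j
                a = vertex_index(corners, (k, i, j))
                b = vertex_index(corners, (k - 1, i + 1, j))
                c = vertex_index(corners, (k - 1, i, j + 1))
                faces.append((a, b, c))
                if i + j <= f - 2:
                    d = vertex_index(corners, (k - 2, i + 1, j + 1))
                    faces.append((b, d, c))

    V = np.array(vertices)
    F = np.array(faces, dtype=np.int64)
    # enforce outward orientation (sphere is star-shaped about the origin)
    centroids = V[F].mean(axis=1)
    normals = np.cross(V[F[:, 1]] - V[F[:, 0]], V[F[:, 2]] - V[F[:, 0]])
    flip = np.einsum("ij,ij->i", normals, centroids) < 0
    F[flip] = F[flip][:, [0, 2, 1]]
    return V, F


def unit_sphere_params(vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(theta, phi) of unit-sphere points; theta polar in [0, pi], phi in [0, 2pi)."""
    theta = np.arccos(np.clip(vertices[:, 2], -1.0, 1.0))
    phi = np.mod(np.arctan2(vertices[:, 1], vertices[:, 0]), 2.0 * np.pi)
    pole = (theta < 1e-12) | (theta > np.pi - 1e-12)
    phi[pole] = 0.0
    return theta, phi


def icosphere_sampling(frequency: int = DEFAULT_FREQUENCY):
    """Unit-sphere sampling: (vertices, faces, theta, phi), all read-only.

    frequency 10 gives the default 1,002-vertex / 2,000-face sampling.
    """
    V, F = _icosphere(frequency)
    theta, phi = unit_sphere_params(V)
    out = (V.copy(), F.copy(), theta, phi)
    for a in out:
        a.setflags(write=False)
    return out
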