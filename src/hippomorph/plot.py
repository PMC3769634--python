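"""Minimal plotting: statistic maps on surfaces and MEMAX curves."""

from __future__ import annotations

import numpy as np

from .spharm import PdmSurface


def plot_stat_map(surface: PdmSurface, values: np.ndarray, ax=None,
                  cmap: str = "coolwarm", title: str = ""):
    """Per-vertex scalar map on a 3D surface (face colors from vertex means)."""
    import matplotlib.pyplot as plt
    from mpl_toolkits.mplot3d.art3d import Poly3DCollection

    if ax is None:
        fig = plt.figure(figsize=(6, 5))
        ax = fig.add_subplot(111, projection="3d")
    v, f = surface.vertices, surface.faces
    face_vals = np.nanmean(np.asarray(values, float)[f], axis=1)
    norm = plt.Normalize(np.nanmin(face_vals), np.nanmax(face_vals))
    colors = plt.get_cmap(cmap)(norm(face_vals))
    coll = Poly3DCollection(v[f], facecolors=colors, edgecolors="none")
    ax.add_collection3d(coll)
    lo, hi = v.min(axis=0), v.max(axis=0)
    ax.set_xlim(lo[0], hi[0]); ax.set_ylim(lo[1], hi[1]); ax.set_zlim(lo[2], hi[2])
    ax.set_box_aspect(hi - lo)
    ax.set_title(title)
    return ax


def plot_memax(points: np.ndarray, curvature: np.ndarray | None = None,
               ax=None, title: str = ""):
    """MEMAX polyline in 3D, optionally colored by curvature."""
    import matplotlib.pyplot as plt

    if ax is None:
        fig = plt.figure(figsize=(6, 5))
        ax = fig.add_subplot(111, projection="3d")
    p = np.asarray(points, float)
    if curvature is None:
        ax.plot(p[:, 0], p[:, 1], p[:, 2], "-k")
    else:
        sc = ax.scatter(p[:, 0], p[:, 1], p[:, 2], c=curvature, cmap="viridis")
        ax.figure.colorbar(sc, ax=ax, label="signed Gaussian curvature (mm$^{-2}$)")
        ax.plot(p[:, 0], p[:, 1], p[:, 2], "-", color="0.6", lw=0.8)
    ax.set_title(title)
    return ax
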