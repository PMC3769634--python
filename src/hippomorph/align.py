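"""Rigid alignment, head-size scaling, and template construction.

Subjects are brought into a common space before any vertex-wise comparison:

1. each surface is inversely scaled for intracranial volume (ICV), with the
   linear factor (ICV_ref / ICV_subject)^(1/3) about the surface centroid;
2. each surface is rigidly aligned to the study template using its centroid
   and the axes of its first-order (degree-1 SPHARM) ellipsoid;
3. the template itself is the vertex-wise mean surface of all subjects,
   re-estimated after re-alignment for a configurable number of iterations.

Aligning only the longitudinal ellipsoid axis leaves a spin and a sign
ambiguity; both are resolved deterministically by also aligning the second
ellipsoid axis and choosing, among the four sign combinations that keep the
rotation proper, the one minimizing the sum of squared vertex distances.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .spharm import (Ellipsoid1, PdmSurface, first_order_ellipsoid, fit_spharm)

__all__ = ["RigidTransform", "TemplateSurface", "rigid_align", "icv_scale",
           "build_template", "surface_ellipsoid"]


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        R = np.asarray(self.rotation, float)
        if np.abs(R.T @ R - np.eye(3)).max() > 1e-9 or abs(np.linalg.det(R) - 1) > 1e-9:
            raise ValueError("rotation must be orthonormal with det +1")
        self.rotation = R
        self.translation = np.asarray(self.translation, float)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class TemplateSurface:
    """Mean surface plus provenance of its construction."""

    surface: PdmSurface
    subject_ids: list = field(default_factory=list)
    iterations: int = 0


def surface_ellipsoid(surface: PdmSurface) -> Ellipsoid1:
    """First-order ellipsoid of a sampled surface (degree-1 refit)."""
    model = fit_spharm(surface.as_param_mesh(), 1)
    return first_order_ellipsoid(model)


def rigid_align(subject: PdmSurface,
                template: PdmSurface) -> tuple[PdmSurface, RigidTransform]:
    """Align subject to template by centroid + first-order ellipsoid axes.

    Returns the aligned copy and the transform that was applied (so that
    ``transform.apply(subject.vertices)`` equals the aligned vertices).
    """
    if not subject.same_sampling(template):
        raise ValueError("subject and template do not share the sampling")
    es = surface_ellipsoid(subject)
    et = surface_ellipsoid(template)
    cs = subject.centroid
    ct = template.centroid
    Us = es.axis_directions  # rows
    Ut = et.axis_directions

    best = None
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            D = np.diag([s1, s2, s1 * s2])  # keeps det(R) = +1
            R = Ut.T @ D @ Us
            cand = (subject.vertices - cs) @ R.T + ct
            ssd = float(((cand - template.vertices) ** 2).sum())
            if best is None or ssd < best[0] - 1e-12:
                best = (ssd, R, cand)
    _, R, aligned_vertices = best
    transform = RigidTransform(R, ct - R @ cs)
    aligned = subject.copy_with(aligned_vertices)
    return aligned, transform


def icv_scale(surface: PdmSurface, subject_icv: float,
              reference_icv: float) -> PdmSurface:
    """Inverse head-size scaling about the centroid.

    Linear factor (reference_icv / subject_icv)^(1/3), so that enclosed
    volumes scale by reference_icv / subject_icv.
    """
    if subject_icv <= 0 or reference_icv <= 0:
        raise ValueError("ICV values must be positive")
    f = (reference_icv / subject_icv) ** (1.0 / 3.0)
    c = surface.centroid
    return surface.copy_with((surface.vertices - c) * f + c)


def build_template(surfaces: list[PdmSurface], iterations: int = 2) -> TemplateSurface:
    """Iterative mean-surface template.

    Start from the vertex-wise mean, then repeat (align every subject to the
    current template, re-average) ``iterations`` times.  The result is
    independent of the input order because averaging is symmetric and each
    alignment depends only on (subject, current template).
    """
    if len(surfaces) < 2:
        raise ValueError("need at least 2 surfaces to build a template")
    ref = surfaces[0]
    for s in surfaces[1:]:
        if not s.same_sampling(ref):
            raise ValueError("surfaces do not share the sampling")
    # canonical summation order makes the template bit-identical under
    # permutation of the input list
    order = sorted(range(len(surfaces)),
                   key=lambda i: hashlib.sha256(
                       surfaces[i].vertices.tobytes()).digest())
    surfaces = [surfaces[i] for i in order]
    mean = ref.copy_with(np.mean([s.vertices for s in surfaces], axis=0))
    for _ in range(iterations):
        aligned = [rigid_align(s, mean)[0].vertices for s in surfaces]
        new_mean = ref.copy_with(np.mean(aligned, axis=0))
        # anchor the new mean to the previous template's pose: without this
        # gauge fix the free spin of a near-circular cross-section lets the
        # template rotate by a constant small angle every iteration
        mean = rigid_align(new_mean, mean)[0]
    mean.subject_id = "template"
    return TemplateSurface(mean, subject_ids=[s.subject_id for s in surfaces],
                           iterations=iterations)
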