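"""Synthetic hippocampus-like shapes and cohorts with known ground truth.

No imaging data ships with the package, so every pipeline stage is exercised
on an analytically defined shape family: a curved, tapered tube whose long
axis runs along the latitude parameter theta (poles at the two ends) and
whose cross-section runs along phi.  Because the shape is written directly
in spherical parameters, its centerline, its enclosed volume and the exact
extent of any injected effect are known in closed form, which is what the
recovery tests compare against.

Injectable effects emulate the anomaly classes the pipeline is meant to
disentangle: a local radial contraction/expansion band (atrophy or
hypertrophy of a subfield strip), an out-of-plane bending ramp of the tail
(malrotation-like bending), a global positional shift, plus per-vertex noise
smoothed over one mesh ring to mimic the smoothness of segmentation error.

All randomness flows from a single integer seed through
numpy.random.SeedSequence spawning, so any one subject is reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._sampling import icosphere_sampling
from .memax import _edge_triangle_hits
from .spharm import (PdmSurface, SpharmModel, SphericalParamMesh, fit_spharm,
                     mesh_volume)
from .stats import CohortTable

import pandas as pd

__all__ = ["ShapeSpec", "BandEffect", "BendEffect", "EffectSpec",
           "SimulatedCohort", "make_shape", "apply_effects", "simulate_cohort",
           "centerline_point", "deform_vertices", "analytic_memax"]


@dataclass(frozen=True)
class ShapeSpec:
    """Analytic tapered bent tube standing in for a segmented hippocampus."""

    length: float = 40.0  # mm along the centerline
    max_radius: float = 5.0  # mm, widest cross-section
    taper: float = 0.35  # fractional radius loss from head (theta=0) to tail
    bend_deg: float = 40.0  # baseline in-plane (xz) arc angle
    icv: float = 1.5e6  # mm^3, nominal intracranial volume

    def validate(self) -> None:
        if self.length <= 0 or self.max_radius <= 0:
            raise ValueError("length and max_radius must be positive")
        if not (0 <= self.taper < 1):
            raise ValueError("taper must lie in [0, 1)")
        beta = abs(np.deg2rad(self.bend_deg))
        if beta > 0 and self.length / beta < 1.5 * self.max_radius:
            raise ValueError("bend too tight for the tube radius "
                             "(self-intersecting spec)")


@dataclass(frozen=True)
class BandEffect:
    """Radial contraction (magnitude > 0) or expansion (< 0) in a band."""

    center_lat: float = np.pi / 2  # theta of band center
    lat_extent: float = np.pi / 2  # full theta width
    center_lon: float = np.pi / 2  # phi of band center
    lon_extent: float = np.pi  # full phi width
    magnitude: float = 0.15  # fractional radial change at band center

    def validate(self) -> None:
        if not (-0.9 < self.magnitude < 0.9):
            raise ValueError("magnitude must lie in (-0.9, 0.9)")
        if not (0 < self.lat_extent <= np.pi and 0 < self.lon_extent <= 2 * np.pi):
            raise ValueError("band extents outside the parameter domain")


@dataclass(frozen=True)
class BendEffect:
    """Rotation ramp applied from start_lat to the tail pole.

    The rotation axis is tilted by ``tilt_deg`` from the in-plane normal
    toward the local centerline tangent, so the ramp both displaces the tail
    out of the baseline bend plane (medial-shift-like bending) and twists it
    about its long axis (malrotation-like torsion).  The torsion component
    is what makes the injected bend visible to the strip's Gaussian
    curvature: a pure fixed-axis bend of a ruled strip is near-developable.
    """

    start_lat: float = 2 * np.pi / 3
    angle_deg: float = 20.0
    tilt_deg: float = 45.0

    def validate(self) -> None:
        if not (0 < self.start_lat < np.pi):
            raise ValueError("start_lat outside (0, pi)")
        if not (0 <= self.tilt_deg <= 90):
            raise ValueError("tilt_deg outside [0, 90]")


@dataclass(frozen=True)
class EffectSpec:
    atrophy: BandEffect | None = None
    hypertrophy: BandEffect | None = None
    bend: BendEffect | None = None
    shift: tuple = (0.0, 0.0, 0.0)
    noise_sd: float = 0.0  # mm, per-vertex isotropic, ring-smoothed
    covariate_r: float = 0.0  # target Pearson r(duration, atrophy magnitude)

    def validate(self) -> None:
        for band in (self.atrophy, self.hypertrophy):
            if band is not None:
                band.validate()
        if self.bend is not None:
            self.bend.validate()
        if abs(self.covariate_r) > 0.99:
            raise ValueError("infeasible correlation target (|r| > 0.99)")


def _centerline_frame(spec: ShapeSpec, f: np.ndarray):
    """Centerline c(f), f in [0,1], plus in-plane/out-of-plane frame vectors."""
    f = np.asarray(f, float)
    beta = np.deg2rad(spec.bend_deg)
    # Axial position follows (1 - cos(pi f))/2 rather than f itself: with the
    # sin(theta) radius profile this gives blunt elliptical end caps (an
    # undeformed straight tube is exactly an ellipsoid, hence band-limited at
    # degree 1) instead of needle tips.  The head (theta = 0) sits at +z so
    # that, like the unit sphere, the axial coordinate decreases with
    # latitude and the sampling's outward face orientation is preserved.
    g = 0.5 * (1.0 - np.cos(np.pi * f))
    if abs(beta) < 1e-9:
        c = np.column_stack([np.zeros_like(f), np.zeros_like(f),
                             (0.5 - g) * spec.length])
        e1 = np.tile([1.0, 0.0, 0.0], (len(f), 1))
    else:
        rho = spec.length / beta
        alpha = beta * (0.5 - g)
        c = np.column_stack([rho * (np.cos(alpha) - np.cos(beta / 2)),
                             np.zeros_like(f), rho * np.sin(alpha)])
        e1 = np.column_stack([np.cos(alpha), np.zeros_like(f), -np.sin(alpha)])
    e2 = np.tile([0.0, 1.0, 0.0], (len(f), 1))
    return c, e1, e2


def centerline_point(spec: ShapeSpec, theta: np.ndarray) -> np.ndarray:
    """Analytic centerline point at latitude theta (ground-truth axis)."""
    c, _, _ = _centerline_frame(spec, np.asarray(theta, float) / np.pi)
    return c


def _radius(spec: ShapeSpec, theta: np.ndarray) -> np.ndarray:
    theta = np.asarray(theta, float)
    g = 0.5 * (1.0 - np.cos(theta))  # axial fraction, head -> tail
    return spec.max_radius * np.sin(theta) * (1.0 - spec.taper * g)


def _analytic_vertices(spec: ShapeSpec, theta: np.ndarray,
                       phi: np.ndarray) -> np.ndarray:
    f = np.asarray(theta, float) / np.pi
    c, e1, e2 = _centerline_frame(spec, f)
    r = _radius(spec, theta)[:, None]
    return c + r * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)


def make_shape(spec: ShapeSpec, sampling=None, max_degree: int = 12,
               validate: bool = True,
               subject_id: str = "", hemisphere: str = ""
               ) -> tuple[SpharmModel, PdmSurface]:
    """Analytic tube evaluated on the PDM sampling, plus its SPHARM fit.

    Deterministic: the same spec and sampling always yield bit-identical
    surfaces (no randomness enters the base shape).
    """
    spec.validate()
    if sampling is None:
        sampling = icosphere_sampling()
    _, faces, theta, phi = sampling
    verts = _analytic_vertices(spec, theta, phi)
    surface = PdmSurface(verts, np.array(faces), np.array(theta), np.array(phi),
                         subject_id=subject_id, hemisphere=hemisphere,
                         metadata={"shape_spec": spec})
    if validate:
        if _edge_triangle_hits(verts, surface.faces):
            raise ValueError("self-intersecting spec")
        surface.as_param_mesh().validate()
        if mesh_volume(surface) <= 0:
            raise ValueError("generated surface is not outward oriented")
    model = fit_spharm(surface.as_param_mesh(), max_degree)
    return model, surface


def _cos_taper(x: np.ndarray, center: float, extent: float,
               periodic: bool = False, edge_frac: float = 0.3) -> np.ndarray:
    """Plateau window: 1 on the band core, cosine rim over the outer
    ``edge_frac`` of the half-extent, 0 outside +-extent/2.

    The compact core with a narrow smooth rim mimics the sharp histological
    boundaries of a subfield band and keeps the half-maximum truth mask
    close to the detectable support.
    """
    d = np.abs(np.asarray(x, float) - center)
    if periodic:
        d = np.abs(np.mod(np.asarray(x, float) - center + np.pi, 2 * np.pi) - np.pi)
    h = extent / 2.0
    core = (1.0 - edge_frac) * h
    w = np.zeros_like(d)
    w[d <= core] = 1.0
    rim = (d > core) & (d <= h)
    w[rim] = 0.5 * (1 + np.cos(np.pi * (d[rim] - core) / (h - core)))
    return w


def _ring_smooth(values: np.ndarray, faces: np.ndarray, n: int) -> np.ndarray:
    """One averaging pass over the 1-ring neighborhood."""
    nbr_sum = np.zeros((n,) + values.shape[1:])
    deg = np.zeros(n)
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    for a, b in ((e[:, 0], e[:, 1]), (e[:, 1], e[:, 0])):
        np.add.at(nbr_sum, a, values[b])
        np.add.at(deg, a, 1.0)
    return 0.5 * values + 0.5 * nbr_sum / np.maximum(deg, 1.0)[:, None]


def _bend_axis(spec: ShapeSpec, bend: BendEffect) -> tuple[np.ndarray, np.ndarray]:
    """Hinge point and (tilted) rotation axis of a bend ramp."""
    hinge = centerline_point(spec, np.array([bend.start_lat]))[0]
    f0 = np.array([bend.start_lat / np.pi])
    _, e1, _ = _centerline_frame(spec, f0)
    eps = 1e-6
    tangent = (centerline_point(spec, np.array([bend.start_lat + eps]))[0] - hinge)
    tangent /= np.linalg.norm(tangent)
    psi = np.deg2rad(bend.tilt_deg)
    axis = np.cos(psi) * e1[0] + np.sin(psi) * tangent
    return hinge, axis / np.linalg.norm(axis)


def deform_vertices(spec: ShapeSpec, effects: EffectSpec, verts: np.ndarray,
                    theta: np.ndarray, phi: np.ndarray,
                    magnitude_scale: float = 1.0
                    ) -> tuple[np.ndarray, dict]:
    """Deterministic part of the effect model on arbitrary surface points.

    Order: radial contraction/expansion bands (toward/away from the analytic
    centerline), bend-with-torsion ramp, global shift.  Shared by
    ``apply_effects`` (which adds noise) and ``analytic_memax`` (exact
    ground truth without any spherical-harmonic fit).
    """
    effects.validate()
    verts = np.asarray(verts, float).copy()
    n = len(verts)
    truth: dict = {"atrophy_mask": np.zeros(n, dtype=bool),
                   "hypertrophy_mask": np.zeros(n, dtype=bool),
                   "bend_mask": np.zeros(n, dtype=bool),
                   "shift": np.asarray(effects.shift, float),
                   "magnitude_scale": magnitude_scale}

    for name, band in (("atrophy", effects.atrophy),
                       ("hypertrophy", effects.hypertrophy)):
        if band is None:
            continue
        w = (_cos_taper(theta, band.center_lat, band.lat_extent)
             * _cos_taper(phi, band.center_lon, band.lon_extent, periodic=True))
        mag = band.magnitude * magnitude_scale
        if abs(mag) >= 0.9:
            raise ValueError("scaled magnitude would collapse/invert the band")
        c = centerline_point(spec, theta)
        verts = c + (verts - c) * (1.0 - mag * w)[:, None]
        truth[f"{name}_mask"] = w >= 0.5
        truth[f"{name}_weight"] = w

    if effects.bend is not None:
        b = effects.bend
        ramp = np.clip((theta - b.start_lat) / (np.pi - b.start_lat), 0.0, 1.0)
        ramp = 0.5 * (1 - np.cos(np.pi * ramp))  # smoothstep
        ang = np.deg2rad(b.angle_deg) * magnitude_scale * ramp
        hinge, axis = _bend_axis(spec, b)
        rel = verts - hinge
        ca, sa = np.cos(ang)[:, None], np.sin(ang)[:, None]
        k_cross = np.cross(np.tile(axis, (n, 1)), rel)
        k_dot = (rel @ axis)[:, None]
        verts = hinge + rel * ca + k_cross * sa + axis * k_dot * (1 - ca)
        truth["bend_mask"] = ramp > 0
        truth["bend_ramp"] = ramp
        truth["bend_start_lat"] = b.start_lat

    verts = verts + np.asarray(effects.shift, float)
    return verts, truth


def apply_effects(surface: PdmSurface, effects: EffectSpec,
                  rng: np.random.Generator | int | None = None,
                  magnitude_scale: float = 1.0
                  ) -> tuple[PdmSurface, dict]:
    """Deform a generated surface and return it with ground-truth masks.

    Deterministic effects first (see ``deform_vertices``), then per-vertex
    Gaussian noise smoothed over one mesh ring.  ``magnitude_scale`` scales
    the band magnitudes and bend angle (per-subject severity variation).
    The surface must carry its ShapeSpec (as produced by make_shape),
    because the radial effects move vertices toward/away from the analytic
    centerline.
    """
    spec: ShapeSpec = surface.metadata.get("shape_spec")
    if spec is None:
        raise ValueError("surface does not carry its generating ShapeSpec")
    rng = np.random.default_rng(rng)
    verts, truth = deform_vertices(spec, effects, surface.vertices,
                                   surface.theta, surface.phi, magnitude_scale)
    if effects.noise_sd > 0:
        noise = rng.normal(0.0, effects.noise_sd, size=verts.shape)
        verts = verts + _ring_smooth(noise, surface.faces, len(verts))

    out = surface.copy_with(verts)
    out.metadata["effects"] = effects
    return out, truth


def analytic_memax(spec: ShapeSpec, effects: EffectSpec | None = None,
                   K: int = 50, magnitude_scale: float = 1.0) -> np.ndarray:
    """Exact MEMAX points of the (deformed) analytic shape, (K, 3).

    Evaluates the prime meridians analytically and midpoints them, bypassing
    any spherical-harmonic fit; this is the generator-side ground truth the
    pipeline's fitted MEMAX is compared against.
    """
    theta = np.arange(1, K + 1) * np.pi / (K + 1)
    both = np.concatenate([theta, theta])
    phis = np.concatenate([np.zeros(K), np.full(K, np.pi)])
    pts = _analytic_vertices(spec, both, phis)
    if effects is not None:
        pts, _ = deform_vertices(spec, effects, pts, both, phis, magnitude_scale)
    return 0.5 * (pts[:K] + pts[K:])


@dataclass
class SimulatedCohort:
    """Surfaces, cohort table, and generation ground truth."""

    surfaces: dict  # (subject_id, hemisphere) -> PdmSurface
    table: CohortTable
    truth: dict  # per-subject truths + shared masks + seeds


def _random_rigid_jitter(rng: np.random.Generator, max_angle_deg: float = 2.0,
                         max_shift: float = 1.0):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.deg2rad(rng.uniform(-max_angle_deg, max_angle_deg))
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
    t = rng.uniform(-max_shift, max_shift, size=3)
    return R, t


def simulate_cohort(n_controls: int, n_patients: int,
                    shape_spec: ShapeSpec | None = None,
                    effect_spec: EffectSpec | None = None,
                    seed: int = 0, hemispheres: tuple = ("left", "right"),
                    pose_jitter: bool = True,
                    focus_side: str = "alternate") -> SimulatedCohort:
    """Control and patient cohorts with ground-truth effect annotations.

    Controls are the baseline shape plus ring-smoothed vertex noise and a
    small random rigid jitter.  Patients additionally receive the effect
    spec on the hemisphere ipsilateral to their focus side (sides alternate
    deterministically), with per-subject lognormal severity variation.  The
    disease-duration covariate is drawn so that its correlation with the
    per-subject atrophy severity targets ``effect_spec.covariate_r``.
    ICVs are lognormal (median 1.5e6 mm^3, sigma_log 0.05).
    """
    if n_controls < 2 or n_patients < 2:
        raise ValueError("need at least 2 controls and 2 patients")
    shape_spec = shape_spec or ShapeSpec()
    effect_spec = effect_spec or EffectSpec()
    effect_spec.validate()
    shape_spec.validate()

    sampling = icosphere_sampling()
    _, base = make_shape(shape_spec, sampling, validate=True)

    ss = np.random.SeedSequence(seed)
    subj_seeds = ss.spawn(n_controls + n_patients + 1)
    rng_global = np.random.default_rng(subj_seeds[-1])

    surfaces: dict = {}
    rows = []
    truths: dict = {}
    severities = []

    n_total = n_controls + n_patients
    for i in range(n_total):
        is_patient = i >= n_controls
        sid = f"{'pat' if is_patient else 'ctl'}{i:03d}"
        rng = np.random.default_rng(subj_seeds[i])
        if not is_patient:
            focus = "none"
        elif focus_side == "alternate":
            focus = ("left", "right")[(i - n_controls) % 2]
        else:
            focus = focus_side
        severity = float(np.exp(rng.normal(0.0, 0.25) - 0.25 ** 2 / 2)) \
            if is_patient else 0.0
        severities.append(severity)
        icv = float(np.exp(np.log(shape_spec.icv) + rng.normal(0.0, 0.05)))
        vols = {}
        for hemi in hemispheres:
            surf = base.copy_with(base.vertices.copy())
            surf.subject_id, surf.hemisphere = sid, hemi
            surf.metadata["shape_spec"] = shape_spec
            if is_patient and hemi == focus:
                surf, truth = apply_effects(surf, effect_spec, rng,
                                            magnitude_scale=severity)
            else:
                noise_only = EffectSpec(noise_sd=effect_spec.noise_sd)
                surf, truth = apply_effects(surf, noise_only, rng)
            # head-size effect: the structure scales with ICV, which is what
            # the pipeline's inverse ICV scaling is meant to remove
            scale = (icv / shape_spec.icv) ** (1.0 / 3.0)
            c = surf.centroid
            surf = surf.copy_with((surf.vertices - c) * scale + c)
            if pose_jitter:
                R, t = _random_rigid_jitter(rng)
                c = surf.centroid
                surf = surf.copy_with((surf.vertices - c) @ R.T + c + t)
            surfaces[(sid, hemi)] = surf
            vols[hemi] = mesh_volume(surf)
            truths[(sid, hemi)] = truth
        rows.append({"id": sid,
                     "group": "patient" if is_patient else "control",
                     "focus_side": focus,
                     "vol_left_mm3": vols.get("left", np.nan),
                     "vol_right_mm3": vols.get("right", np.nan),
                     "icv_mm3": icv})

    # duration covariate: correlated with patient severity at the target r
    r = float(np.clip(effect_spec.covariate_r, -0.99, 0.99))
    sev = np.asarray(severities[n_controls:])
    z = (sev - sev.mean()) / sev.std() if sev.std() > 0 else np.zeros_like(sev)
    eps = rng_global.normal(size=n_patients)
    eps = eps - eps.mean()
    if z.std() > 0:  # orthogonalize so the sample correlation hits r exactly
        eps = eps - (eps @ z) / max(z @ z, 1e-12) * z
    eps = eps / max(eps.std(), 1e-12)
    dur_z = r * z + np.sqrt(max(0.0, 1 - r ** 2)) * eps
    durations = np.maximum(0.5, 12.0 + 6.0 * dur_z)
    for j, row in enumerate(rows):
        row["duration_years"] = float(durations[j - n_controls]) \
            if j >= n_controls else np.nan

    table = CohortTable(pd.DataFrame(rows))
    truth = {"per_subject": truths, "severities": dict(
        zip([r_["id"] for r_ in rows[n_controls:]], sev.tolist())),
        "effect_spec": effect_spec, "shape_spec": shape_spec,
        "seed": seed}
    return SimulatedCohort(surfaces=surfaces, table=table, truth=truth)
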