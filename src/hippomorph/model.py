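"""Cohort-level shape analysis as a model / results pair.

``ShapeAnalysis`` is built from a cohort of corresponding surfaces plus the
cohort table; ``fit()`` runs the full morphometric pipeline per hemisphere

    ICV scaling -> template (mean surface of controls and patients) ->
    rigid alignment -> Jacobian volume maps -> MEMAX curvature and
    position vectors -> vertex-/point-wise group statistics with BH-FDR

and returns a ``ShapeAnalysisResults`` carrying the templates, the
per-subject metric matrices, the statistic maps, the 2-SD global volumetry
labels, and a text ``summary()``.

Three metrics are compared between patients and controls: the per-vertex
Jacobian determinant (local volume change), the per-point signed Gaussian
curvature of the MEMAX strip (bending), and the per-point 3D MEMAX position
vectors (shifting; Hotelling T^2).  With ``laterality="ipsi"`` or
``"contra"`` each patient contributes the hemisphere ipsi-/contralateral to
their focus side, z-transformed against the control distribution of that
same anatomical hemisphere (no mirroring).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import build_template, icv_scale, rigid_align
from .jacobian import volume_change_map, voxelize
from .memax import memax_from_model, position_vectors
from .spharm import PdmSurface, fit_spharm
from .stats import (CohortTable, StatMap, correlate_covariate, fdr_correct,
                    global_volumetry_classify, hotelling_t2, vertex_ttest,
                    z_normalize)

__all__ = ["ShapeAnalysis", "ShapeAnalysisResults"]


@dataclass
class HemisphereMaps:
    """Per-hemisphere intermediate products of a fit."""

    template: PdmSurface
    template_memax_points: np.ndarray
    subject_ids: list
    jacobian: np.ndarray  # (n_subjects, V)
    curvature: np.ndarray  # (n_subjects, K)
    positions: np.ndarray  # (n_subjects, K, 3) deltas vs template MEMAX
    transforms: dict


class ShapeAnalysis:
    """Surface-based cohort morphometry model.

    Parameters
    ----------
    surfaces : dict
        ``(subject_id, hemisphere) -> PdmSurface`` with one shared sampling.
    cohort : CohortTable
        Subject metadata (group, focus side, volumes, ICV, covariates).
    max_degree : int
        SPHARM degree used for MEMAX construction (default 12).
    n_memax : int
        MEMAX sample count K (default 50).
    grid_spacing : float
        Voxel size of the Jacobian grid in mm (default 1.0, isotropic).
    q_fdr : float
        FDR threshold (default 0.05).
    align, icv_correct : bool
        Stage toggles; alignment and head-size correction are on by default
        and only disabled for controlled experiments (e.g. operator-recovery
        tests in generation pose).
    """

    def __init__(self, surfaces: dict, cohort: CohortTable, *,
                 max_degree: int = 12, n_memax: int = 50,
                 grid_spacing: float = 1.0, q_fdr: float = 0.05,
                 template_iterations: int = 2, align: bool = True,
                 icv_correct: bool = True):
        self.surfaces = dict(surfaces)
        self.cohort = cohort
        self.max_degree = max_degree
        self.n_memax = n_memax
        self.grid_spacing = grid_spacing
        self.q_fdr = q_fdr
        self.template_iterations = template_iterations
        self.align = align
        self.icv_correct = icv_correct
        self.hemispheres = sorted({h for _, h in self.surfaces})
        ids = set(cohort.frame["id"])
        missing = [k for k in self.surfaces if k[0] not in ids]
        if missing:
            raise ValueError(f"surfaces without cohort rows: {missing[:3]}...")

    @classmethod
    def from_simulation(cls, sim, **kwargs) -> "ShapeAnalysis":
        """Build from a ``synthetic.SimulatedCohort``."""
        return cls(sim.surfaces, sim.table, **kwargs)

    # ------------------------------------------------------------------

    def _hemisphere_ids(self, hemi: str) -> list:
        return sorted(sid for sid, h in self.surfaces if h == hemi)

    def _prepare_hemisphere(self, hemi: str,
                            metrics: tuple) -> HemisphereMaps:
        frame = self.cohort.frame.set_index("id")
        ids = self._hemisphere_ids(hemi)
        surfs = []
        ref_icv = float(frame["icv_mm3"].mean())
        for sid in ids:
            s = self.surfaces[(sid, hemi)]
            if self.icv_correct:
                s = icv_scale(s, float(frame.loc[sid, "icv_mm3"]), ref_icv)
            surfs.append(s)
        transforms = {}
        if self.align:
            template = build_template(
                surfs, iterations=self.template_iterations).surface
            aligned = []
            for sid, s in zip(ids, surfs):
                a, t = rigid_align(s, template)
                aligned.append(a)
                transforms[sid] = t
            surfs = aligned
        else:
            template = surfs[0].copy_with(
                np.mean([s.vertices for s in surfs], axis=0))
            template.subject_id = "template"

        n = len(ids)
        V = len(template.vertices)
        jac = np.full((n, V), np.nan)
        if "volume" in metrics:
            domain = voxelize(template, self.grid_spacing)
            for i, s in enumerate(surfs):
                jac[i] = volume_change_map(template, s, domain=domain).values

        tpl_model = fit_spharm(template.as_param_mesh(), self.max_degree)
        tpl_memax = memax_from_model(tpl_model, self.n_memax)
        kap = np.full((n, self.n_memax), np.nan)
        pos = np.full((n, self.n_memax, 3), np.nan)
        if "curvature" in metrics or "position" in metrics:
            for i, s in enumerate(surfs):
                model = fit_spharm(s.as_param_mesh(), self.max_degree)
                mx = memax_from_model(model, self.n_memax)
                kap[i] = mx.curvature
                pos[i] = position_vectors(mx.points, tpl_memax.points)
        return HemisphereMaps(template=template,
                              template_memax_points=tpl_memax.points,
                              subject_ids=ids, jacobian=jac, curvature=kap,
                              positions=pos, transforms=transforms)

    def _split_groups(self, hemi_maps: HemisphereMaps, values: np.ndarray,
                      hemi: str, laterality: str | None):
        """(control matrix, patient matrix) for one metric array.

        ``values`` is (n_subjects, ...) in hemi_maps.subject_ids order.
        With laterality, patients contribute only when this anatomical
        hemisphere is ipsi/contra to their focus, and both groups are
        z-transformed against the same-hemisphere control distribution.
        """
        frame = self.cohort.frame.set_index("id")
        ids = hemi_maps.subject_ids
        is_ctrl = np.array([frame.loc[s, "group"] == "control" for s in ids])
        ctrl = values[is_ctrl]
        if laterality is None:
            pat = values[~is_ctrl]
            return ctrl, pat, np.array(ids)[~is_ctrl]
        want_focus = hemi if laterality == "ipsi" else \
            ({"left": "right", "right": "left"}[hemi])
        sel = np.array([(not c) and frame.loc[s, "focus_side"] == want_focus
                        for s, c in zip(ids, is_ctrl)])
        flat = ctrl.reshape(ctrl.shape[0], -1)
        zc, _ = z_normalize(flat, flat)
        zp, _ = z_normalize(values[sel].reshape(sel.sum(), -1), flat)
        return (zc.reshape(ctrl.shape), zp.reshape((int(sel.sum()),) + values.shape[1:]),
                np.array(ids)[sel])

    def fit(self, metrics: tuple = ("volume", "curvature", "position"),
            laterality: str | None = None,
            duration_covariate: str | None = "duration_years"
            ) -> "ShapeAnalysisResults":
        """Run the pipeline and test patients against controls.

        ``laterality=None`` compares all patients to all controls within
        each anatomical hemisphere; "ipsi"/"contra" pools patients by focus
        side after per-hemisphere z-normalization.
        """
        if laterality not in (None, "ipsi", "contra"):
            raise ValueError("laterality must be None, 'ipsi' or 'contra'")
        hemi_maps = {}
        stat_maps: dict = {}
        correlations: dict = {}
        for hemi in self.hemispheres:
            hm = self._prepare_hemisphere(hemi, metrics)
            hemi_maps[hemi] = hm
            maps = {}
            if "volume" in metrics:
                ctrl, pat, pat_ids = self._split_groups(hm, hm.jacobian, hemi,
                                                        laterality)
                sm = vertex_ttest(pat, ctrl)
                maps["volume"] = fdr_correct(sm.p, self.q_fdr, sm)
                if (duration_covariate is not None
                        and duration_covariate in self.cohort.frame.columns
                        and len(pat_ids) >= 4):
                    frame = self.cohort.frame.set_index("id")
                    cov = frame.loc[list(pat_ids), duration_covariate]
                    cov = cov.to_numpy(float)
                    if np.isfinite(cov).all() and np.std(cov, ddof=1) > 0:
                        correlations[hemi] = correlate_covariate(
                            pat, cov, self.q_fdr)
            if "curvature" in metrics:
                ctrl, pat, _ = self._split_groups(hm, hm.curvature, hemi,
                                                  laterality)
                sm = vertex_ttest(pat, ctrl)
                maps["curvature"] = fdr_correct(sm.p, self.q_fdr, sm)
            if "position" in metrics:
                ctrl, pat, _ = self._split_groups(hm, hm.positions, hemi,
                                                  laterality)
                sm = hotelling_t2(pat, ctrl)
                maps["position"] = fdr_correct(sm.p, self.q_fdr, sm)
            stat_maps[hemi] = maps
        ctrl = self.cohort.controls
        if (np.isfinite(ctrl["vol_left_mm3"]).all()
                and np.isfinite(ctrl["vol_right_mm3"]).all()):
            volumetry = global_volumetry_classify(self.cohort)
        else:  # single-hemisphere cohorts: the 2-SD rule needs both sides
            volumetry = pd.DataFrame(columns=["id", "label", "z_left",
                                              "z_right", "z_asymmetry"])
        return ShapeAnalysisResults(model=self, hemi_maps=hemi_maps,
                                    stat_maps=stat_maps,
                                    duration_correlation=correlations,
                                    volumetry=volumetry,
                                    laterality=laterality)


@dataclass
class ShapeAnalysisResults:
    """Fitted cohort comparison: templates, metric maps, statistics."""

    model: ShapeAnalysis
    hemi_maps: dict  # hemisphere -> HemisphereMaps
    stat_maps: dict  # hemisphere -> {metric -> StatMap}
    duration_correlation: dict  # hemisphere -> StatMap (r)
    volumetry: pd.DataFrame
    laterality: str | None = None

    def template(self, hemisphere: str) -> PdmSurface:
        return self.hemi_maps[hemisphere].template

    def significant_fraction(self, hemisphere: str, metric: str) -> float:
        sm = self.stat_maps[hemisphere][metric]
        return float(np.mean(sm.significant))

    def summary(self) -> str:
        lines = ["Surface-based shape analysis", "=" * 60]
        lat = self.laterality or "by anatomical hemisphere"
        frame = self.model.cohort.frame
        nc = int((frame["group"] == "control").sum())
        npat = int((frame["group"] != "control").sum())
        lines.append(f"subjects: {nc} controls, {npat} patients; "
                     f"comparison: {lat}; FDR q < {self.model.q_fdr:g}")
        for hemi, maps in self.stat_maps.items():
            lines.append(f"\n[{hemi} hemisphere]")
            for metric, sm in maps.items():
                n_sig = int(np.sum(sm.significant))
                frac = 100.0 * n_sig / len(sm.p)
                pmin = np.nanmin(sm.p) if len(sm.p) else np.nan
                lines.append(f"  {metric:<10s} ({sm.stat_name:>2s}): "
                             f"{n_sig:4d}/{len(sm.p)} significant "
                             f"({frac:5.1f}%), min p = {pmin:.2e}")
            if hemi in self.duration_correlation:
                r = self.duration_correlation[hemi]
                sig = int(np.sum(r.significant))
                idx = np.nanargmax(np.abs(r.statistic))
                lines.append(f"  duration r: {sig} significant vertices, "
                             f"peak r = {r.statistic[idx]:+.2f}")
        if len(self.volumetry):
            lines.append("\nglobal volumetry (2-SD rule):")
            for label, count in self.volumetry["label"].value_counts().items():
                lines.append(f"  {label:<24s} {count}")
        return "\n".join(lines)

    def maps_frame(self, hemisphere: str) -> pd.DataFrame:
        """All per-vertex/point statistics of one hemisphere as a table."""
        frames = []
        for metric, sm in self.stat_maps[hemisphere].items():
            f = sm.to_frame()
            f.insert(0, "metric", metric)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)
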