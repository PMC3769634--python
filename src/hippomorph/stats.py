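"""Vertex- and point-wise group statistics for surface metrics.

The statistical layer compares per-vertex scalar metrics (Jacobian volume
change, signed curvature) between groups with two-sample pooled-variance
Student t-tests, and per-point 3D position vectors with two-sample Hotelling
T^2 tests.  Patient metrics can first be z-transformed against the control
distribution of the matching hemisphere, which puts left- and right-focus
patients on a common ipsi/contralateral footing without mirroring surfaces.
All maps are corrected for multiple comparisons with the Benjamini-Hochberg
false discovery rate, applied separately per metric and per hemisphere.

Global volumetry follows the classical 2-SD rule: a hemisphere is labelled
atrophic when its (head-size-corrected) volume lies more than 2 control SDs
below the control mean, or when the inter-hemispheric asymmetry index
2(L - R)/(L + R) deviates more than 2 SDs against that side; hypertrophy is
the mirror-image rule on the upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["CohortTable", "StatMap", "z_normalize", "vertex_ttest",
           "hotelling_t2", "fdr_correct", "correlate_covariate",
           "global_volumetry_classify", "asymmetry_index"]


@dataclass
class CohortTable:
    """Per-subject metadata: group, focus side, volumes, ICV, covariates.

    Thin wrapper around a pandas DataFrame with the columns
    id, group, focus_side, vol_left_mm3, vol_right_mm3, icv_mm3 and any
    number of covariate columns (e.g. duration_years).
    """

    frame: pd.DataFrame

    REQUIRED = ("id", "group", "focus_side", "vol_left_mm3", "vol_right_mm3",
                "icv_mm3")

    def __post_init__(self):
        f = self.frame
        missing = [c for c in self.REQUIRED if c not in f.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        if f["id"].duplicated().any():
            raise ValueError("subject ids must be unique")
        for c in ("vol_left_mm3", "vol_right_mm3", "icv_mm3"):
            vals = f[c].dropna()
            if (vals <= 0).any():
                raise ValueError(f"{c} must be positive")
        ctrl = f["group"] == "control"
        if ((f.loc[ctrl, "focus_side"] != "none").any()
                or (f.loc[~ctrl, "focus_side"] == "none").any()):
            raise ValueError("focus_side must be 'none' iff group is control")

    @property
    def controls(self) -> pd.DataFrame:
        return self.frame[self.frame["group"] == "control"]

    @property
    def patients(self) -> pd.DataFrame:
        return self.frame[self.frame["group"] != "control"]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path))


@dataclass
class StatMap:
    """Per-vertex/point statistics with FDR-adjusted significance."""

    statistic: np.ndarray  # t, T^2, or r per vertex
    p: np.ndarray
    q: np.ndarray | None = None  # BH-adjusted
    significant: np.ndarray | None = None  # q < threshold
    valid: np.ndarray | None = None  # False where a vertex was excluded
    stat_name: str = "t"
    threshold: float = 0.05
    extra: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        d = {"vertex_id": np.arange(len(self.p)),
             self.stat_name: self.statistic, "p": self.p}
        if self.q is not None:
            d["q"] = self.q
            d["sig"] = self.significant.astype(int)
        if self.valid is not None:
            d["valid"] = self.valid.astype(int)
        return pd.DataFrame(d)


def z_normalize(subject_values: np.ndarray, control_values: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """z-transform per vertex against the control distribution.

    ``control_values`` is (n_controls, V) from the hemisphere matching the
    subject's (callers map hemispheres to ipsi/contra via focus side before
    normalizing).  Returns (z, valid); vertices with zero control SD are
    flagged invalid and get NaN.
    """
    control_values = np.asarray(control_values, float)
    if control_values.shape[0] < 3:
        raise ValueError("need at least 3 controls for z-normalization")
    mu = control_values.mean(axis=0)
    sd = control_values.std(axis=0, ddof=1)
    valid = sd > 0
    z = np.full(np.shape(subject_values), np.nan)
    z[..., valid] = (np.asarray(subject_values, float)[..., valid] - mu[valid]) / sd[valid]
    return z, valid


def vertex_ttest(group_a: np.ndarray, group_b: np.ndarray) -> StatMap:
    """Two-sample pooled-variance t-test per vertex (two-sided).

    Vertices where the pooled variance vanishes get t = 0, p = 1 and are
    flagged invalid.
    """
    a = np.atleast_2d(np.asarray(group_a, float))
    b = np.atleast_2d(np.asarray(group_b, float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects")
    res = sps.ttest_ind(a, b, axis=0, equal_var=True)
    t = np.asarray(res.statistic, float)
    p = np.asarray(res.pvalue, float)
    bad = ~np.isfinite(t)
    t[bad] = 0.0
    p[bad] = 1.0
    return StatMap(statistic=t, p=p, valid=~bad, stat_name="t")


def hotelling_t2(group_a: np.ndarray, group_b: np.ndarray,
                 ridge: float = 1e-10) -> StatMap:
    """Two-sample Hotelling T^2 per point on d-dimensional observations.

    Inputs are (n_a, K, d) and (n_b, K, d).  The pooled covariance is
    inverted per point; p-values via the exact F transformation
    F = T^2 (n - d - 1) / (d (n - 2)), n = n_a + n_b, on (d, n - d - 1)
    degrees of freedom.  A singular pooled covariance is regularized by
    ``ridge`` times its trace and the point flagged.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.ndim == 2:
        a = a[:, None, :]
        b = b[:, None, :]
    na, K, d = a.shape
    nb = b.shape[0]
    n = na + nb
    if n - 2 < d:
        raise ValueError("too few subjects for the pooled covariance")
    t2 = np.zeros(K)
    p = np.ones(K)
    valid = np.ones(K, dtype=bool)
    dfd = n - d - 1
    for k in range(K):
        xa, xb = a[:, k, :], b[:, k, :]
        diff = xa.mean(axis=0) - xb.mean(axis=0)
        S = (np.cov(xa, rowvar=False, ddof=1) * (na - 1)
             + np.cov(xb, rowvar=False, ddof=1) * (nb - 1)) / (n - 2)
        S = np.atleast_2d(S)
        try:
            sol = np.linalg.solve(S, diff)
        except np.linalg.LinAlgError:
            S = S + ridge * max(np.trace(S), 1.0) * np.eye(d)
            sol = np.linalg.solve(S, diff)
            valid[k] = False
        t2[k] = (na * nb / n) * float(diff @ sol)
        f = t2[k] * dfd / (d * (n - 2))
        p[k] = float(sps.f.sf(f, d, dfd))
    return StatMap(statistic=t2, p=p, valid=valid, stat_name="T2")


def fdr_correct(p_values: np.ndarray, q_threshold: float = 0.05,
                stat_map: StatMap | None = None) -> StatMap:
    """Benjamini-Hochberg step-up FDR across vertices.

    NaN p-values (excluded vertices) do not participate and stay
    non-significant.  Returns a StatMap carrying q-values and the
    significance mask at ``q_threshold``; if ``stat_map`` is given its
    statistic/validity are carried over.
    """
    p = np.asarray(p_values, float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    sig = np.zeros(p.shape, dtype=bool)
    if finite.any():
        rej, qv, _, _ = multipletests(p[finite], alpha=q_threshold,
                                      method="fdr_bh")
        q[finite] = qv
        sig[finite] = rej
    base = stat_map
    return StatMap(
        statistic=base.statistic if base is not None else np.full_like(p, np.nan),
        p=p, q=q, significant=sig,
        valid=base.valid if base is not None else finite,
        stat_name=base.stat_name if base is not None else "stat",
        threshold=q_threshold)


def correlate_covariate(metric: np.ndarray, covariate: np.ndarray,
                        q_threshold: float = 0.05) -> StatMap:
    """Pearson correlation of a per-vertex metric with a subject covariate.

    ``metric`` is (n_subjects, V); returns r, two-sided p per vertex and the
    BH-FDR mask across vertices.  Constant-metric vertices are flagged and
    excluded from correction.
    """
    x = np.asarray(covariate, float)
    y = np.asarray(metric, float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if x.std(ddof=1) == 0:
        raise ValueError("covariate has zero variance")
    xc = x - x.mean()
    yc = y - y.mean(axis=0)
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum(axis=0))
    valid = denom > 0
    r = np.full(y.shape[1], np.nan)
    r[valid] = (xc @ y)[valid] / denom[valid]
    r = np.clip(r, -1.0, 1.0)
    p = np.full_like(r, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r ** 2, 1e-300))
    p[valid] = 2 * sps.t.sf(np.abs(t[valid]), n - 2)
    out = fdr_correct(p, q_threshold)
    out.statistic = r
    out.stat_name = "r"
    out.valid = valid
    return out


def asymmetry_index(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Inter-hemispheric asymmetry 2(L - R)/(L + R); positive when L > R."""
    left = np.asarray(left, float)
    right = np.asarray(right, float)
    return 2.0 * (left - right) / (left + right)


def global_volumetry_classify(cohort: CohortTable,
                              sd_threshold: float = 2.0) -> pd.DataFrame:
    """2-SD volumetry labels per patient.

    z-scores of left volume, right volume, and the asymmetry index are taken
    against the control distributions.  Per side: atrophy when the volume z
    falls below -threshold or the asymmetry z exceeds +threshold against that
    side; hypertrophy when the volume z exceeds +threshold.  Labels compose
    per side ('atrophy-L', 'atrophy-bilateral', 'hypertrophy-R',
    'atrophy-L+hypertrophy-R', 'normal').  Subjects missing a volume are
    skipped.
    """
    ctrl = cohort.controls
    if len(ctrl) < 3:
        raise ValueError("need at least 3 controls")
    cl = ctrl["vol_left_mm3"].to_numpy(float)
    cr = ctrl["vol_right_mm3"].to_numpy(float)
    cai = asymmetry_index(cl, cr)
    stats_ = {
        "L": (cl.mean(), cl.std(ddof=1)),
        "R": (cr.mean(), cr.std(ddof=1)),
        "AI": (cai.mean(), cai.std(ddof=1)),
    }
    for name, (_, sd) in stats_.items():
        if sd <= 0:
            raise ValueError(f"control {name} distribution has zero SD")

    rows = []
    for _, row in cohort.patients.iterrows():
        L, R = row["vol_left_mm3"], row["vol_right_mm3"]
        if not (np.isfinite(L) and np.isfinite(R)):
            continue
        zl = (L - stats_["L"][0]) / stats_["L"][1]
        zr = (R - stats_["R"][0]) / stats_["R"][1]
        zai = (asymmetry_index(L, R) - stats_["AI"][0]) / stats_["AI"][1]
        atrophy_L = zl < -sd_threshold or zai < -sd_threshold
        atrophy_R = zr < -sd_threshold or zai > sd_threshold
        hyper_L = zl > sd_threshold
        hyper_R = zr > sd_threshold
        parts = []
        if atrophy_L and atrophy_R:
            parts.append("atrophy-bilateral")
        elif atrophy_L:
            parts.append("atrophy-L")
        elif atrophy_R:
            parts.append("atrophy-R")
        if hyper_L and hyper_R:
            parts.append("hypertrophy-bilateral")
        elif hyper_L:
            parts.append("hypertrophy-L")
        elif hyper_R:
            parts.append("hypertrophy-R")
        label = "+".join(parts) if parts else "normal"
        rows.append({"id": row["id"], "label": label, "z_left": zl,
                     "z_right": zr, "z_asymmetry": zai})
    return pd.DataFrame(rows)
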