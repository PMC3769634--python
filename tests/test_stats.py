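"""Group statistics: z-transform, t, Hotelling T^2, FDR, correlation,
2-SD global volumetry."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hippomorph import (CohortTable, correlate_covariate, fdr_correct,
                        global_volumetry_classify, hotelling_t2, vertex_ttest,
                        z_normalize)


def brute_force_bh(p, q):
    """Step-up definition applied literally: largest i with
    p_(i) <= (i/m) q; everything up to it is significant."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i / m * q:
            k = i
    sig = np.zeros(m, dtype=bool)
    sig[order[:k]] = True
    return sig


class TestZNormalize:
    def test_control_mean_maps_to_zero(self):
        rng = np.random.default_rng(0)
        ctrl = rng.normal(size=(5, 20))
        z, valid = z_normalize(ctrl.mean(axis=0), ctrl)
        assert valid.all()
        np.testing.assert_allclose(z, 0.0, atol=1e-12)

    def test_hand_computed_example(self):
        ctrl = np.array([[8.0], [10.0], [12.0]])  # sample SD 2
        z, _ = z_normalize(np.array([14.0]), ctrl)
        np.testing.assert_allclose(z, [2.0])

    def test_hemisphere_specific_normalization(self):
        """An offset injected only into right-hemisphere controls must show
        up only when normalizing against the right distribution."""
        rng = np.random.default_rng(1)
        left = rng.normal(0.0, 1.0, size=(10, 5))
        right = left + 3.0
        subject = np.zeros(5)
        z_left, _ = z_normalize(subject, left)
        z_right, _ = z_normalize(subject, right)
        assert np.abs(z_right - z_left).min() > 1.0

    def test_zero_sd_vertex_flagged(self):
        ctrl = np.ones((4, 3))
        ctrl[:, 1] = [1, 2, 3, 4]
        z, valid = z_normalize(np.array([2.0, 2.0, 2.0]), ctrl)
        assert list(valid) == [False, True, False]
        assert np.isnan(z[0]) and np.isfinite(z[1])


class TestVertexTtest:
    def test_identical_groups(self):
        a = np.tile([1.0, 2.0, 3.0], (3, 1)).T.reshape(3, 3)
        sm = vertex_ttest(a, a)
        np.testing.assert_allclose(sm.statistic, 0.0)
        np.testing.assert_allclose(sm.p, 1.0)

    def test_worked_example(self):
        sm = vertex_ttest(np.array([[1.0], [2.0], [3.0]]),
                          np.array([[4.0], [5.0], [6.0]]))
        np.testing.assert_allclose(sm.statistic, [-3.674], atol=1e-3)
        np.testing.assert_allclose(sm.p, [0.0214], atol=1e-3)

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(4, 7)), rng.normal(size=(5, 7))
        s1, s2 = vertex_ttest(a, b), vertex_ttest(b, a)
        np.testing.assert_allclose(s1.statistic, -s2.statistic)
        np.testing.assert_allclose(s1.p, s2.p)

    def test_zero_variance_flagged(self):
        a = np.ones((3, 2))
        b = np.ones((3, 2))
        b[:, 1] = [1.0, 2.0, 3.0]
        sm = vertex_ttest(a, b)
        assert not sm.valid[0] and sm.p[0] == 1.0 and sm.statistic[0] == 0.0


class TestHotelling:
    def test_identical_means(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(6, 2, 3))
        sm = hotelling_t2(base, base)
        np.testing.assert_allclose(sm.statistic, 0.0, atol=1e-12)
        np.testing.assert_allclose(sm.p, 1.0)

    def test_one_dimensional_equals_t_squared(self):
        rng = np.random.default_rng(4)
        a1 = rng.normal(size=(7, 1))
        b1 = rng.normal(loc=0.8, size=(9, 1))
        t = vertex_ttest(a1.T.reshape(7, 1), b1.reshape(9, 1))
        t2 = hotelling_t2(a1[:, None, :], b1[:, None, :])
        np.testing.assert_allclose(t2.statistic[0], t.statistic[0] ** 2,
                                   atol=1e-9)

    def test_rotation_invariance(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(5)
        a = rng.normal(size=(8, 4, 3))
        b = rng.normal(loc=0.3, size=(10, 4, 3))
        R = Rotation.from_euler("xyz", [30, 50, -10], degrees=True).as_matrix()
        s1 = hotelling_t2(a, b)
        s2 = hotelling_t2(a @ R.T, b @ R.T)
        np.testing.assert_allclose(s1.statistic, s2.statistic, atol=1e-9)

    def test_agrees_with_independent_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        a = rng.normal(size=(12, 1, 3))
        b = rng.normal(loc=0.5, size=(15, 1, 3))
        ours = hotelling_t2(a, b)
        ref = pingouin.multivariate_ttest(a[:, 0, :], b[:, 0, :])
        np.testing.assert_allclose(ours.statistic[0], ref["T2"].iloc[0],
                                   rtol=1e-9)
        np.testing.assert_allclose(ours.p[0], ref["pval"].iloc[0], rtol=1e-9)

    def test_singular_covariance_flagged(self):
        a = np.zeros((4, 1, 3))
        b = np.zeros((4, 1, 3))
        b[:, 0, 0] = [1, 1, 1, 1.0]
        sm = hotelling_t2(a, b)
        assert not sm.valid[0]
        assert np.isfinite(sm.statistic[0])


class TestFdr:
    def test_worked_step_up_example(self):
        sm = fdr_correct(np.array([0.01, 0.02, 0.03, 0.04, 0.9]), 0.05)
        assert list(sm.significant) == [True, True, True, True, False]

    def test_all_ones_none_significant(self):
        sm = fdr_correct(np.ones(10), 0.05)
        assert not sm.significant.any()

    def test_uniform_bound_all_significant(self):
        m, q = 8, 0.05
        sm = fdr_correct(np.full(m, q / m / 2), q)
        assert sm.significant.all()

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=12),
           st.sampled_from([0.01, 0.05, 0.1, 0.25]))
    def test_matches_brute_force_step_up(self, p, q):
        sm = fdr_correct(np.array(p), q)
        assert list(sm.significant) == list(brute_force_bh(p, q))

    def test_nan_p_values_excluded(self):
        sm = fdr_correct(np.array([0.001, np.nan, 0.002]), 0.05)
        assert list(sm.significant) == [True, False, True]
        assert np.isnan(sm.q[1])


class TestCorrelation:
    def test_exact_linear_relation(self):
        cov = np.array([1.0, 2, 3, 4, 5])
        metric = (2 * cov + 1)[:, None]
        sm = correlate_covariate(metric, cov)
        np.testing.assert_allclose(sm.statistic, [1.0])

    def test_null_calibration(self):
        """Fraction of p < 0.05 under independence is ~5%."""
        rng = np.random.default_rng(7)
        n, V = 30, 1000
        sm = correlate_covariate(rng.normal(size=(n, V)), rng.normal(size=n))
        frac = np.mean(sm.p < 0.05)
        assert abs(frac - 0.05) < 0.02

    def test_negating_covariate_negates_r(self):
        rng = np.random.default_rng(8)
        m = rng.normal(size=(10, 6))
        c = rng.normal(size=10)
        s1 = correlate_covariate(m, c)
        s2 = correlate_covariate(m, -c)
        np.testing.assert_allclose(s1.statistic, -s2.statistic, atol=1e-12)

    def test_constant_metric_flagged(self):
        m = np.ones((6, 2))
        m[:, 1] = np.arange(6.0)
        sm = correlate_covariate(m, np.arange(6.0))
        assert not sm.valid[0] and sm.valid[1]


def cohort_frame(rows):
    return CohortTable(pd.DataFrame(rows))


def make_controls(n=10, L=3000.0, R=3000.0, sd=200.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        rows.append({"id": f"c{i}", "group": "control", "focus_side": "none",
                     "vol_left_mm3": L + sd * rng.standard_normal(),
                     "vol_right_mm3": R + sd * rng.standard_normal(),
                     "icv_mm3": 1.5e6})
    return rows


class TestGlobalVolumetry:
    def patient(self, L, R, pid="p0", focus="left"):
        return {"id": pid, "group": "patient", "focus_side": focus,
                "vol_left_mm3": L, "vol_right_mm3": R, "icv_mm3": 1.5e6}

    def test_mean_volumes_are_normal(self):
        rows = make_controls()
        mu_l = np.mean([r["vol_left_mm3"] for r in rows])
        mu_r = np.mean([r["vol_right_mm3"] for r in rows])
        rows.append(self.patient(mu_l, mu_r))
        out = global_volumetry_classify(cohort_frame(rows))
        assert out["label"].iloc[0] == "normal"

    def test_left_atrophy_three_sd(self):
        rows = make_controls()
        mu_l = np.mean([r["vol_left_mm3"] for r in rows])
        sd_l = np.std([r["vol_left_mm3"] for r in rows], ddof=1)
        mu_r = np.mean([r["vol_right_mm3"] for r in rows])
        rows.append(self.patient(mu_l - 3 * sd_l, mu_r))
        out = global_volumetry_classify(cohort_frame(rows))
        assert out["label"].iloc[0] == "atrophy-L"

    def test_mirrored_patient_gets_mirrored_label(self):
        rows = make_controls()
        mu_l = np.mean([r["vol_left_mm3"] for r in rows])
        sd_r = np.std([r["vol_right_mm3"] for r in rows], ddof=1)
        mu_r = np.mean([r["vol_right_mm3"] for r in rows])
        rows.append(self.patient(mu_l, mu_r - 3 * sd_r, focus="right"))
        out = global_volumetry_classify(cohort_frame(rows))
        assert out["label"].iloc[0] == "atrophy-R"

    def test_hypertrophy_and_bilateral(self):
        rows = make_controls()
        mu_l = np.mean([r["vol_left_mm3"] for r in rows])
        sd_l = np.std([r["vol_left_mm3"] for r in rows], ddof=1)
        mu_r = np.mean([r["vol_right_mm3"] for r in rows])
        sd_r = np.std([r["vol_right_mm3"] for r in rows], ddof=1)
        rows.append(self.patient(mu_l + 3 * sd_l, mu_r + 3 * sd_r, "p0"))
        rows.append(self.patient(mu_l - 3 * sd_l, mu_r - 3 * sd_r, "p1"))
        out = global_volumetry_classify(cohort_frame(rows)).set_index("id")
        assert out.loc["p0", "label"] == "hypertrophy-bilateral"
        assert out.loc["p1", "label"] == "atrophy-bilateral"

    def test_cohort_validation(self):
        rows = make_controls(3)
        rows[0]["focus_side"] = "left"  # control with a focus side
        with pytest.raises(ValueError, match="focus_side"):
            cohort_frame(rows)
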