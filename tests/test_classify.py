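import numpy as np
import pytest
from scipy import stats as sps

from relaxroi.classify import (
    METRICS,
    apply_threshold,
    build_roc,
    compute_metric,
    evaluate_masks,
    run_question,
)
from relaxroi.io import QuantitativeMapSet
from relaxroi.synthetic import CohortConfig, generate_cohort


def concordance_auc(pos, neg):
    """Oracle: tie-corrected pairwise concordance P(pos>neg) + P(pos=neg)/2."""
    pos = np.asarray(pos, float)[:, None]
    neg = np.asarray(neg, float)[None, :]
    return float(np.mean((pos > neg) + 0.5 * (pos == neg)))


def exhaustive_youden(pos, neg, thresholds):
    best_j, best_t = -np.inf, None
    for t in thresholds:
        sens = np.mean(pos > t)
        spec = np.mean(neg <= t)
        j = sens + spec - 1
        if j > best_j + 1e-15:
            best_j, best_t = j, t
    return best_t, best_j


def _mapset(t1, t2, pd_=None):
    t1 = np.asarray(t1, float).reshape(1, 1, -1)
    t2 = np.asarray(t2, float).reshape(1, 1, -1)
    pd_ = np.ones_like(t1) * 70.0 if pd_ is None else np.asarray(pd_, float).reshape(1, 1, -1)
    return QuantitativeMapSet("x", t1, t2, pd_, np.eye(4))


class TestComputeMetric:
    def test_hand_arithmetic(self):
        maps = _mapset([1000.0], [100.0])
        assert compute_metric(maps, "normT1T2")[0, 0, 0] == pytest.approx(1004.99, abs=0.01)
        assert compute_metric(maps, "normlog")[0, 0, 0] == pytest.approx(8.302, abs=0.001)
        assert compute_metric(maps, "t1")[0, 0, 0] == 1000.0

    def test_pd_variants_append_component(self):
        maps = _mapset([1000.0], [100.0], [70.0])
        expected = np.sqrt(1000.0**2 + 100.0**2 + 70.0**2)
        assert compute_metric(maps, "normT1T2PD")[0, 0, 0] == pytest.approx(expected)
        expected_log = np.sqrt(
            np.log(1000.0) ** 2 + np.log(100.0) ** 2 + np.log(70.0) ** 2
        )
        assert compute_metric(maps, "normlogT1T2PD")[0, 0, 0] == pytest.approx(expected_log)

    def test_plain_t1_ignores_zero_t2(self):
        maps = _mapset([500.0], [0.0])
        assert compute_metric(maps, "t1")[0, 0, 0] == 500.0

    def test_log_metric_masks_nonpositive(self):
        maps = _mapset([500.0, 600.0], [0.0, 50.0])
        vol = compute_metric(maps, "normlog")
        assert np.isnan(vol[0, 0, 0]) and np.isfinite(vol[0, 0, 1])

    def test_monotone_in_t1(self, rng):
        t1 = rng.uniform(2, 3000, 100)
        t2 = rng.uniform(2, 300, 100)
        for metric in ("normT1T2", "normlog"):
            lo = compute_metric(_mapset(t1, t2), metric)
            hi = compute_metric(_mapset(t1 + 10, t2), metric)
            assert np.all(hi >= lo)

    def test_unknown_metric(self):
        with pytest.raises(ValueError):
            compute_metric(_mapset([1.0], [1.0]), "nope")


class TestBuildRoc:
    def test_perfect_separation(self):
        r = build_roc([3, 4], [1, 2])
        assert r.auc == pytest.approx(1.0)
        assert r.youden_j == pytest.approx(1.0)
        assert 2 < r.youden_threshold < 3

    def test_interleaved_concordance(self):
        assert build_roc([1, 3], [2, 4]).auc == pytest.approx(0.25)

    def test_identical_classes_half(self):
        assert build_roc([1, 2, 3], [1, 2, 3]).auc == pytest.approx(0.5)

    def test_matches_concordance_oracle_random(self, rng):
        for _ in range(30):
            n_p, n_n = rng.integers(1, 200, size=2)
            # mixed continuous and tied integer values
            pos = np.round(rng.normal(1, 2, n_p), rng.integers(0, 2))
            neg = np.round(rng.normal(0, 2, n_n), rng.integers(0, 2))
            r = build_roc(pos, neg)
            assert r.auc == pytest.approx(concordance_auc(pos, neg), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        pos = rng.normal(1, 1, 150)
        neg = rng.normal(0, 1, 100)
        r = build_roc(pos, neg)
        ref = roc_auc_score(
            np.r_[np.ones(150), np.zeros(100)], np.r_[pos, neg]
        )
        assert r.auc == pytest.approx(ref, abs=1e-12)

    def test_youden_matches_exhaustive_search(self, rng):
        pos = rng.integers(0, 10, 50).astype(float)
        neg = rng.integers(-2, 8, 60).astype(float)
        r = build_roc(pos, neg)
        t, j = exhaustive_youden(pos, neg, r.thresholds)
        assert r.youden_j == pytest.approx(j, abs=1e-12)
        assert r.youden_threshold == t  # tie-break toward lower threshold
        assert r.youden_j == pytest.approx(
            r.youden_sensitivity + r.youden_specificity - 1
        )

    def test_monotone_curve(self, rng):
        r = build_roc(rng.normal(1, 1, 200), rng.normal(0, 1, 200))
        assert np.all(np.diff(r.sensitivity) <= 1e-12)
        assert np.all(np.diff(r.specificity) >= -1e-12)

    def test_gaussian_closed_form_limit(self, rng):
        # equal-variance classes 1 sigma apart: AUC -> Phi(1/sqrt(2))
        n = 10**5
        pos = rng.normal(1.0, 1.0, n)
        neg = rng.normal(0.0, 1.0, n)
        auc = build_roc(pos, neg).auc
        target = sps.norm.cdf(1 / np.sqrt(2))
        a = target
        q1, q2 = a / (2 - a), 2 * a**2 / (1 + a)
        se = np.sqrt(
            (a * (1 - a) + (n - 1) * (q1 - a**2) + (n - 1) * (q2 - a**2)) / (n * n)
        )
        assert abs(auc - target) < 3 * se

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            build_roc([], [1.0])


class TestRunQuestion:
    def test_identical_specs_exchangeable(self):
        from relaxroi.synthetic import RoiDistributionSpec, default_roi_specs

        specs = default_roi_specs()
        for m in ("t1", "t2", "pd"):
            specs[("t1e", m)] = specs[("t2h", m)]
        config = CohortConfig(
            n_enhancing=2, n_nonenhancing=0, grid_shape=(36, 36, 36),
            lesion_radius_range=(3.5, 4.5), per_roi_specs=specs, seed=5,
        )
        cohort = generate_cohort(config)
        r = run_question(cohort, "t1e_vs_t2h", "normT1T2")
        assert r.auc == pytest.approx(0.5, abs=0.05)

    def test_no_enhancement_error(self, tiny_config):
        from dataclasses import replace

        cohort = generate_cohort(replace(tiny_config, n_enhancing=0, n_nonenhancing=1))
        with pytest.raises(ValueError, match="no positive voxels"):
            run_question(cohort, "t1e_vs_t2h", "t1")

    def test_negative_set_is_configurable(self, tiny_cohort):
        default = run_question(tiny_cohort, "t1e_vs_rest", "t1")
        narrow = run_question(tiny_cohort, "t1e_vs_rest", "t1", negative_rois=("t2h", "nwm"))
        assert default.n_negative > narrow.n_negative

    def test_unknown_question(self, tiny_cohort):
        with pytest.raises(ValueError):
            run_question(tiny_cohort, "abn_vs_everything", "t1")


class TestApplyThresholdAndEvaluate:
    def test_all_below_gives_empty(self):
        vol = np.full((3, 3, 3), 1.0)
        mask = np.ones((3, 3, 3), bool)
        assert apply_threshold(vol, 2.0, mask).sum() == 0

    def test_boundary_is_strict(self):
        vol = np.array([[[8.44, 8.45]]])
        mask = np.ones_like(vol, bool)
        out = apply_threshold(vol, 8.44, mask)
        assert not out[0, 0, 0] and out[0, 0, 1]

    def test_table_level_values_bracket_reference_threshold(self):
        # normlog at normal-WM-like vs lesion-like (T1, T2) table magnitudes
        maps = _mapset([993.16, 1353.78], [92.33, 152.25])
        vol = compute_metric(maps, "normlog")
        out = apply_threshold(vol, 8.44, np.ones_like(vol, bool))
        assert not out[0, 0, 0] and out[0, 0, 1]

    def test_nan_never_positive(self):
        vol = np.array([[[np.nan, 9.0]]])
        out = apply_threshold(vol, 1.0, np.ones_like(vol, bool))
        assert not out[0, 0, 0] and out[0, 0, 1]

    def test_perfect_and_complement(self, rng):
        truth = rng.random((8, 8, 8)) > 0.7
        ev = np.ones_like(truth)
        perfect = evaluate_masks(truth, truth, ev)
        assert (perfect.sensitivity, perfect.specificity, perfect.accuracy) == (100.0, 100.0, 100.0)
        comp = evaluate_masks(~truth, truth, ev)
        assert (comp.sensitivity, comp.specificity, comp.accuracy) == (0.0, 0.0, 0.0)

    def test_confusion_matrix_arithmetic(self):
        truth = np.zeros((10, 10, 1), bool)
        truth.ravel()[:10] = True
        pred = np.zeros_like(truth)
        pred.ravel()[:7] = True  # 7 of 10 positives
        pred.ravel()[10:13] = True  # 3 of 90 negatives
        m = evaluate_masks(pred, truth, np.ones_like(truth))
        assert m.sensitivity == pytest.approx(70.0)
        assert m.specificity == pytest.approx(96.6667, abs=1e-3)
        assert m.accuracy == pytest.approx(94.0)

    def test_empty_truth_flagged(self):
        ev = np.ones((4, 4, 4), bool)
        m = evaluate_masks(np.zeros_like(ev), np.zeros_like(ev), ev)
        assert np.isnan(m.sensitivity) and m.specificity == 100.0
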