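"""Univariate marker statistics and the filtration cascade."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from metabomark import (
    CascadeConfig,
    bh_fdr,
    correlate_with_covariate,
    fit_oplsda,
    evaluate_fit,
    fold_change,
    jackknife_ci,
    qq_normality,
    roc_auc,
    select_markers,
    ttest_feature,
)
from metabomark.markers import qq_critical_r2


class TestTtest:
    def test_identical_groups(self):
        assert ttest_feature([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_hand_computed_pooled(self):
        # t = -1.2247, df = 4
        p = ttest_feature([1, 2, 3], [2, 3, 4])
        assert p == pytest.approx(2 * stats.t.sf(1.224744871, 4), abs=1e-6)
        assert p == pytest.approx(0.2879, abs=1e-3)

    def test_symmetric_in_group_order(self):
        a, b = [1.0, 2.5, 3.0, 4.1], [2.0, 3.3, 4.0]
        assert ttest_feature(a, b) == pytest.approx(ttest_feature(b, a))

    def test_degenerate_zero_variance(self):
        assert ttest_feature([2, 2], [2, 2]) == 1.0
        assert ttest_feature([2, 2], [3, 3]) == 0.0


class TestJackknife:
    def test_identical_folds_zero_width(self):
        ci = jackknife_ci([0.4], np.full((7, 1), 0.4))
        assert ci.loc[0, "ci_high"] - ci.loc[0, "ci_low"] == pytest.approx(0.0, abs=1e-10)
        assert ci.loc[0, "ci_low"] == pytest.approx(0.4)
        assert not ci.loc[0, "spans_zero"]

    def test_fold_scatter_around_zero_spans(self):
        folds = np.array([[-1.0], [1.0], [-0.5], [0.5], [0.2], [-0.2]])
        ci = jackknife_ci([0.05], folds)
        assert ci.loc[0, "spans_zero"]

    def test_hand_computed_se(self):
        folds = np.array([1.0, 1.2, 0.8, 1.1, 0.9, 1.0, 1.0])[:, None]
        se = np.sqrt(6 / 7 * ((folds - folds.mean()) ** 2).sum())
        ci = jackknife_ci([1.0], folds)
        tcrit = stats.t.ppf(0.975, 6)
        assert ci.loc[0, "ci_high"] == pytest.approx(1.0 + tcrit * se)
        assert ci.loc[0, "ci_low"] == pytest.approx(1.0 - tcrit * se)

    def test_needs_two_folds(self):
        with pytest.raises(ValueError):
            jackknife_ci([1.0], np.ones((1, 1)))


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6))
    def test_matches_brute_force_step_up(self, ps):
        """Oracle: q_(i) = min over j >= i of m * p_(j) / j, computed by
        direct enumeration over the sorted vector."""
        m = len(ps)
        order = np.argsort(ps)
        sorted_p = np.asarray(ps)[order]
        brute_sorted = [
            min(min(m * sorted_p[j] / (j + 1) for j in range(i, m)), 1.0)
            for i in range(m)
        ]
        brute = np.empty(m)
        brute[order] = brute_sorted
        assert np.allclose(bh_fdr(ps), brute)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=10))
    def test_order_preserving(self, ps):
        q = bh_fdr(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestRocAuc:
    def test_separated_groups_excellent(self):
        auc, band = roc_auc([5.0, 6.0, 7.0], [1.0, 2.0])
        assert auc == 1.0 and band == "excellent"

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 10_000))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=rng.integers(2, 8))
        b = rng.normal(size=rng.integers(2, 8)) + rng.choice([0, 1])
        auc, _ = roc_auc(a, b)
        wins = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        brute = wins / (len(a) * len(b))
        assert auc == pytest.approx(max(brute, 1 - brute))

    def test_bands(self):
        from metabomark.markers import auc_band

        assert auc_band(0.65) == "poor"
        assert auc_band(0.75) == "fair"
        assert auc_band(0.85) == "good"
        assert auc_band(0.55) == "failed"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [1.0])


class TestQqNormality:
    def test_exact_normal_quantiles_pass(self):
        v = stats.norm.ppf((np.arange(1, 21) - 0.5) / 20)
        r2, ok = qq_normality(v)
        assert r2 == pytest.approx(1.0) and ok

    def test_bimodal_sample_fails(self):
        """Two well-separated clusters give a visibly bent Q-Q plot."""
        below = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            v = np.concatenate([rng.normal(-8, 0.3, 10), rng.normal(8, 0.3, 10)])
            r2, _ = qq_normality(v)
            below += r2 < 0.95
        assert below >= 95

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            qq_normality([3.0, 3.0, 3.0])

    def test_critical_value_calibrated_to_n(self):
        """At the 5% level roughly 95% of genuinely normal samples must pass,
        even at small n where a fixed R² cutoff would reject most."""
        assert qq_critical_r2(11) < 0.95  # well below a fixed cutoff at n=11
        passes = 0
        for seed in range(400):
            rng = np.random.default_rng(seed)
            _, ok = qq_normality(rng.normal(size=11))
            passes += ok
        assert 0.90 <= passes / 400 <= 0.99


class TestFoldChange:
    def test_equal_means(self):
        assert fold_change([2.0, 4.0], [3.0, 3.0]) == (1.0, 0.0)

    def test_four_to_one(self):
        ratio, log2r = fold_change([4.0, 4.0], [1.0, 1.0])
        assert (ratio, log2r) == (4.0, 2.0)

    def test_published_marker_ratios(self):
        assert round(np.log2(0.15), 2) == -2.74
        assert round(np.log2(0.37), 2) == -1.43

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            fold_change([0.0, 0.0], [1.0, 1.0])


class TestCovariateCorrelation:
    def test_self_correlation(self):
        r, p = correlate_with_covariate([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert r == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        r, _ = correlate_with_covariate(x, y)
        direct = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(direct)

    def test_spearman_rank_based(self):
        r, _ = correlate_with_covariate([1, 2, 3, 4], [1, 10, 100, 1000], method="spearman")
        assert r == pytest.approx(1.0)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            correlate_with_covariate([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestCascade:
    @pytest.fixture(scope="class")
    def fitted_pair(self, two_group_dataset):
        from metabomark import filter_by_missingness, filter_by_rsd, log2_transform
        from metabomark.pipeline import fit_pair

        table, truth = two_group_dataset
        table, _ = filter_by_rsd(table)
        table, _ = filter_by_missingness(table)
        log2t = log2_transform(table.biological(), zeros="missing")
        model, fit, _, pair = fit_pair(log2t, "PA", "HC")
        return pair, model, fit, truth

    def test_planted_markers_dominate_selection(self, fitted_pair):
        pair, model, fit, truth = fitted_pair
        report = select_markers(pair, model, fit, group_a="PA", group_b="HC")
        selected = {r.feature_id for r in report.selected}
        planted = set(truth.feature_id)
        assert len(selected & planted) >= 6
        assert len(selected - planted) <= 2

    def test_every_record_has_stage_outcome(self, fitted_pair):
        pair, model, fit, _ = fitted_pair
        report = select_markers(pair, model, fit, group_a="PA", group_b="HC")
        assert len(report.records) == pair.n_features
        for rec in report.records:
            assert rec.selected or rec.drop_stage

    def test_stage_order_q_after_p(self, fitted_pair):
        """A feature with small p but large q must be attributed to the BH
        stage, not the t-test stage."""
        pair, model, fit, _ = fitted_pair
        cfg = CascadeConfig(alpha_t=0.5, alpha_q=1e-6)
        report = select_markers(pair, model, fit, cfg, group_a="PA", group_b="HC")
        bh_dropped = [r for r in report.records if r.drop_stage == "bh_fdr"]
        assert bh_dropped
        assert all(r.p_value <= 0.5 for r in bh_dropped)

    def test_ranked_by_vip_total(self, fitted_pair):
        pair, model, fit, _ = fitted_pair
        report = select_markers(pair, model, fit, group_a="PA", group_b="HC")
        vips = [r.vip_total for r in report.selected]
        assert vips == sorted(vips, reverse=True)

    def test_nothing_passes_under_impossible_threshold(self, fitted_pair):
        pair, model, fit, _ = fitted_pair
        cfg = CascadeConfig(alpha_t=1e-300)
        report = select_markers(pair, model, fit, cfg, group_a="PA", group_b="HC")
        assert report.selected == []
        assert all(r.drop_stage == "t_test" for r in report.records)

    @pytest.mark.parametrize(
        "field,strict,loose",
        [
            ("alpha_q", 0.01, 0.2),
            ("auc_min", 0.9, 0.5),
            ("vip_total_min", 1.5, 0.2),
            ("qq_r2_min", 0.97, 0.5),
        ],
    )
    def test_relaxing_thresholds_grows_selection(self, fitted_pair, field, strict, loose):
        pair, model, fit, _ = fitted_pair
        out = {}
        for label, value in (("strict", strict), ("loose", loose)):
            cfg = CascadeConfig(**{field: value})
            rep = select_markers(pair, model, fit, cfg, group_a="PA", group_b="HC")
            out[label] = {r.feature_id for r in rep.selected}
        assert out["strict"] <= out["loose"]

    def test_strict_vip_mode_drops_flagged(self, fitted_pair):
        pair, model, fit, _ = fitted_pair
        default = select_markers(pair, model, fit, group_a="PA", group_b="HC")
        strict = select_markers(
            pair, model, fit, CascadeConfig(require_pred_ge_ortho=True),
            group_a="PA", group_b="HC",
        )
        assert {r.feature_id for r in strict.selected} <= {
            r.feature_id for r in default.selected
        }
        for rec in strict.selected:
            assert not rec.not_biomarker_relevant

    def test_invalid_config_rejected(self, fitted_pair):
        pair, model, fit, _ = fitted_pair
        with pytest.raises(ValueError):
            select_markers(
                pair, model, fit, CascadeConfig(alpha_t=0.0), group_a="PA", group_b="HC"
            )
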