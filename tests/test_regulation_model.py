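import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicebind import regulation_model as rm
from splicebind import synthetic_data as synth
from splicebind.errors import DegenerateInputError

from _oracles import auc_by_pair_counting

NAMES = ["x1", "x2", "x3", "x4"]


def intercept_only_model(g_r=0.0, g_e=0.0):
    return rm.MultinomialLogitModel(
        feature_names=(),
        beta_repressed=np.array([g_r]),
        beta_enhanced=np.array([g_e]),
        se_repressed=np.array([np.nan]),
        se_enhanced=np.array([np.nan]),
    )


class TestClassifyFromPsi:
    def test_repressed(self):
        (res,) = rm.classify_exons_from_psi([rm.PsiMeasurement("e", 20, 60)])
        assert res == ("e", "repressed")

    def test_enhanced(self):
        (res,) = rm.classify_exons_from_psi([rm.PsiMeasurement("e", 60, 20)])
        assert res == ("e", "enhanced")

    def test_low_minor_isoform_excluded(self):
        (res,) = rm.classify_exons_from_psi([rm.PsiMeasurement("e", 2, 40)])
        assert res == ("e", "excluded")

    def test_small_delta_is_non_regulated(self):
        (res,) = rm.classify_exons_from_psi([rm.PsiMeasurement("e", 50, 53)])
        assert res == ("e", "non_regulated")

    def test_intermediate_delta_excluded(self):
        (res,) = rm.classify_exons_from_psi([rm.PsiMeasurement("e", 40, 55)])
        assert res == ("e", "excluded")

    def test_out_of_range_psi_rejected(self):
        with pytest.raises(ValueError):
            rm.PsiMeasurement("e", -1, 50)


class TestScreening:
    def test_constant_feature_dropped(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.full(60, 3.0), rng.normal(size=60)])
        labels = np.array(["repressed"] * 20 + ["enhanced"] * 20 + ["non_regulated"] * 20)
        retained = rm.screen_features_ttest(X, labels, ["flat", "noise"])
        assert "flat" not in retained

    def test_planted_two_sd_separation_retained(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(2.0, 1.0, 50), rng.normal(2.0, 1.0, 10),
                            rng.normal(0.0, 1.0, 50)])
        labels = np.array(["repressed"] * 50 + ["enhanced"] * 10 + ["non_regulated"] * 50)
        retained = rm.screen_features_ttest(x[:, None], labels, ["sep"])
        assert retained == ["sep"]

    def test_boundary_is_strict(self):
        from scipy import stats as sps

        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0.3, 1.0, 30), rng.normal(0.0, 1.0, 5),
                            rng.normal(0.0, 1.0, 30)])
        labels = np.array(["repressed"] * 30 + ["enhanced"] * 5 + ["non_regulated"] * 30)
        p_r = sps.ttest_ind(x[:30], x[35:], equal_var=False).pvalue
        p_e = sps.ttest_ind(x[30:35], x[35:], equal_var=False).pvalue
        best = min(p_r, p_e)
        # alpha exactly at the best p: strict < means the feature is dropped
        assert rm.screen_features_ttest(x[:, None], labels, ["x"], alpha=best) == []
        assert rm.screen_features_ttest(x[:, None], labels, ["x"], alpha=best + 1e-12) == ["x"]


def _simulated_table(n_total=600, seed=0, beta_r=(-0.5, 1.0, 0.8, 0.5, 0.3),
                     beta_e=(-1.0, -0.4, 0.2, 0.1, 0.6)):
    spec = synth.PlantedLogitSpec(
        beta_repressed=beta_r, beta_enhanced=beta_e,
        mode="generative", n_total=n_total, seed=seed,
    )
    return synth.gen_exon_dataset(spec)


class TestFitMultinomial:
    def test_zero_coefficients_give_uniform_probabilities(self):
        m = intercept_only_model()
        assert rm.predict_probabilities(m, []) == pytest.approx((1 / 3,) * 3)

    def test_missing_class_rejected(self):
        X = np.zeros((10, 1))
        labels = np.array(["repressed"] * 5 + ["enhanced"] * 5)
        with pytest.raises(ValueError):
            rm.fit_multinomial(X, labels, ["x1"])

    def test_separable_data_flagged_and_stabilized(self):
        x = np.concatenate([np.full(10, 5.0), np.full(10, -5.0), np.zeros(10)])
        labels = np.array(["repressed"] * 10 + ["enhanced"] * 10 + ["non_regulated"] * 10)
        m = rm.fit_multinomial(x[:, None], labels, ["x1"])
        assert m.separation
        assert np.isfinite(m.beta_repressed).all()

    def test_recovers_planted_coefficients_roughly(self):
        X, labels, truth = _simulated_table(n_total=2000, seed=5)
        m = rm.fit_multinomial(X, labels, NAMES)
        assert np.allclose(m.beta_repressed, truth["beta_repressed"], atol=0.35)
        assert np.allclose(m.beta_enhanced, truth["beta_enhanced"], atol=0.35)

    def test_coefficients_table_shape(self):
        X, labels, _ = _simulated_table(n_total=300, seed=6)
        m = rm.fit_multinomial(X, labels, NAMES)
        rows = m.coefficients_table()
        assert len(rows) == 2 * 5
        assert {r["logit"] for r in rows} == {"repressed", "enhanced"}

    def test_json_round_trip(self, tmp_path):
        X, labels, _ = _simulated_table(n_total=300, seed=7)
        m = rm.fit_multinomial(X, labels, NAMES)
        p = tmp_path / "m.json"
        m.save(p)
        back = rm.MultinomialLogitModel.load(p)
        assert np.allclose(back.beta_repressed, m.beta_repressed)
        assert back.feature_names == m.feature_names


class TestOutliers:
    def test_gross_outlier_flagged(self):
        X, labels, _ = _simulated_table(n_total=300, seed=8)
        m = rm.fit_multinomial(X, labels, NAMES)
        X2 = X.copy()
        # plant a non-regulated exon deep inside repressed territory
        j = int(np.flatnonzero(np.asarray(labels) == "non_regulated")[0])
        X2[j] = [10.0, 10.0, 10.0, 10.0]
        m2 = rm.fit_multinomial(X2, labels, NAMES)
        flags = rm.detect_outlier_exons(m2, X2, labels)
        assert flags[j]

    def test_infinite_cutoff_flags_nothing(self):
        X, labels, _ = _simulated_table(n_total=200, seed=9)
        m = rm.fit_multinomial(X, labels, NAMES)
        assert not rm.detect_outlier_exons(m, X, labels, cutoff=np.inf).any()

    def test_clean_tables_rarely_flagged(self):
        """Calibration: well-separated clean tables yield zero flags for
        nearly every seed."""
        clean = 0
        for seed in range(20):
            spec = synth.PlantedLogitSpec(
                beta_repressed=(0.0, 1.0, 1.0),
                beta_enhanced=(0.0, -1.0, -1.0),
                mode="class_conditional",
                n_per_class=(67, 67, 66),
                class_means={
                    "repressed": [3.0, 3.0],
                    "enhanced": [-3.0, -3.0],
                    "non_regulated": [0.0, 0.0],
                },
                feature_sd=0.8,
                seed=seed,
            )
            X, labels, _ = synth.gen_exon_dataset(spec)
            m = rm.fit_multinomial(X, labels, ["a", "b"])
            if not rm.detect_outlier_exons(m, X, labels).any():
                clean += 1
        assert clean >= 19


class TestStepwise:
    def test_noise_feature_eliminated(self):
        rng = np.random.default_rng(10)
        X, labels, _ = _simulated_table(
            n_total=500, seed=10,
            beta_r=(-0.5, 1.5, 0.0, 0.0, 0.0), beta_e=(-1.0, -1.2, 0.0, 0.0, 0.0),
        )
        selected, model = rm.stepwise_select(X[:, :2], labels, ["x1", "x2"], ["x1", "x2"])
        assert "x1" in selected
        assert "x2" not in selected

    def test_single_informative_feature_retained(self):
        X, labels, _ = _simulated_table(
            n_total=400, seed=11, beta_r=(-0.5, 1.5, 0, 0, 0), beta_e=(-1.0, -1.2, 0, 0, 0)
        )
        selected, _ = rm.stepwise_select(X[:, :1], labels, ["x1"], ["x1"])
        assert selected == ["x1"]

    def test_no_candidates_gives_intercept_only(self):
        X, labels, _ = _simulated_table(n_total=120, seed=12)
        selected, model = rm.stepwise_select(X, labels, [], NAMES)
        assert selected == []
        assert model.feature_names == ()


class TestPredict:
    def test_closed_form_ln2(self):
        m = intercept_only_model(g_r=np.log(2), g_e=0.0)
        assert rm.predict_probabilities(m, []) == pytest.approx((0.5, 0.25, 0.25))

    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=2))
    @settings(max_examples=50, deadline=None)
    def test_probabilities_sum_to_one(self, gs):
        m = intercept_only_model(g_r=gs[0], g_e=gs[1])
        p = rm.predict_probabilities(m, [])
        assert sum(p) == pytest.approx(1.0, abs=1e-12)

    def test_shared_shift_changes_probabilities(self):
        p0 = rm.predict_probabilities(intercept_only_model(1.0, 0.5), [])
        p1 = rm.predict_probabilities(intercept_only_model(2.0, 1.5), [])
        assert p0 != pytest.approx(p1)

    def test_feature_count_checked(self):
        m = intercept_only_model()
        with pytest.raises(ValueError):
            rm.predict_probabilities(m, [1.0])


class TestRankThreshold:
    def test_high_probability_called_repressed(self):
        (row,) = rm.rank_and_threshold(["Ptbp3_e2"], [0.89])
        assert row["call"] == "predicted_repressed"

    def test_boundaries(self):
        rows = rm.rank_and_threshold(["a", "b", "c"], [0.65, 0.20, 0.66])
        calls = {r["exon_id"]: r["call"] for r in rows}
        assert calls == {
            "a": "intermediate",  # 0.65 exactly is NOT above the threshold
            "b": "predicted_unregulated",  # 0.20 exactly is <= the low threshold
            "c": "predicted_repressed",
        }

    def test_ties_broken_by_id(self):
        rows = rm.rank_and_threshold(["b", "a"], [0.5, 0.5])
        assert [r["exon_id"] for r in rows] == ["a", "b"]


class TestRoc:
    def test_worked_four_point_example(self):
        fpr, tpr, _ = rm.roc_points([0.9, 0.2, 0.4, 0.8], [True, True, False, False])
        assert rm.auc_trapezoid(fpr, tpr) == pytest.approx(0.5)
        assert auc_by_pair_counting([0.9, 0.2, 0.4, 0.8], [True, True, False, False]) == 0.5

    def test_perfect_separation(self):
        fpr, tpr, _ = rm.roc_points([0.9, 0.8, 0.1, 0.2], [True, True, False, False])
        assert rm.auc_trapezoid(fpr, tpr) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(40)
        pos = rng.random(40) > 0.5
        if pos.all() or not pos.any():
            pos[0] = not pos[0]
        fpr, tpr, _ = rm.roc_points(scores, pos)
        assert rm.auc_trapezoid(fpr, tpr) == pytest.approx(
            auc_by_pair_counting(scores, pos), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            rm.roc_points([0.1, 0.2], [True, True])


class TestLoocv:
    def test_too_few_per_class_rejected(self):
        X = np.zeros((4, 1))
        labels = np.array(["repressed", "repressed", "enhanced", "non_regulated"])
        with pytest.raises(DegenerateInputError):
            rm.loocv_roc(X, labels, ["x1"])

    def test_separable_data_high_auc(self):
        spec = synth.PlantedLogitSpec(
            beta_repressed=(0.0, 1.0, 1.0),
            beta_enhanced=(0.0, -1.0, -1.0),
            mode="class_conditional",
            n_per_class=(12, 8, 12),
            class_means={"repressed": [2.5, 2.5], "enhanced": [-2.5, -2.5],
                         "non_regulated": [0.0, 0.0]},
            feature_sd=0.8,
            seed=3,
        )
        X, labels, _ = synth.gen_exon_dataset(spec)
        result = rm.loocv_roc(X, labels, ["a", "b"], stepwise=False)
        assert result.auc_repressed >= 0.9

    def test_sensitivity_specificity_in_range(self):
        X, labels, _ = _simulated_table(n_total=60, seed=14)
        result = rm.loocv_roc(X, labels, NAMES, stepwise=False, reselect=False)
        sens, spec = result.sensitivity_specificity(0.5)
        assert 0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0


class TestBinnedResponse:
    def test_flat_response(self):
        bins = rm.binned_response([0.1, 0.4, 0.6, 0.9], [1, 1, 1, 1], [0, 0.5, 1.0])
        assert all(b["mean"] == 1.0 for b in bins)

    def test_empty_bin_reported_and_skipped(self):
        bins = rm.binned_response([0.1, 0.15, 0.9, 0.95], [0, 0, 1, 1], [0, 0.4, 0.6, 1.0])
        assert bins[1]["n"] == 0 and bins[1]["mean"] is None
        assert bins[2]["p_vs_previous"] is not None  # tested against bin 0

    def test_no_data_rejected(self):
        with pytest.raises(DegenerateInputError):
            rm.binned_response([5.0], [1.0], [0, 1])

    def test_planted_logistic_monotone_bins(self):
        rng = np.random.default_rng(15)
        x = rng.uniform(0, 1, 2000)
        p = 1 / (1 + np.exp(-(8 * x - 4)))
        y = (rng.random(2000) < p).astype(float)
        bins = rm.binned_response(x, y, np.linspace(0, 1, 6))
        means = [b["mean"] for b in bins]
        # monotone within binomial noise: allow 3 binomial SEs of slack
        for prev, cur, b_prev, b_cur in zip(means, means[1:], bins, bins[1:]):
            se = np.sqrt(0.25 / b_prev["n"] + 0.25 / b_cur["n"])
            assert cur >= prev - 3 * se
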