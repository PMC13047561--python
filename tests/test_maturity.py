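"""Composite maturity index: PCA, coefficients, F, grading."""

import numpy as np
import pandas as pd
import pytest

import mangonir as m
from mangonir.maturity import (
    PCAResult, classify, classify_and_score, grade_label, standardize,
)
from mangonir.simulate import scale_noise


def quality_frame(firmness, ph, ssc, dmc, day=None, variety="V"):
    n = len(firmness)
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "variety": [variety] * n,
        "batch": [0] * n,
        "day": day if day is not None else [0] * n,
        "firmness": firmness, "pH": ph, "ssc": ssc, "dmc_pct": dmc,
    })


# ---------------------------------------------------------------------------
# standardisation
# ---------------------------------------------------------------------------

class TestStandardize:
    def test_fit_mode_gives_unit_columns(self, rng):
        q = quality_frame(rng.uniform(8, 13, 30), rng.uniform(2.7, 3.4, 30),
                          rng.uniform(4, 7, 30), rng.uniform(12, 19, 30))
        Z, stats = standardize(q)
        assert np.allclose(Z.mean(), 0, atol=1e-12)
        assert np.allclose(Z.std(ddof=1), 1, atol=1e-12)

    def test_simple_column(self):
        q = quality_frame([1.0, 2.0, 3.0], [3.0, 3.1, 3.2],
                          [5.0, 5.5, 6.0], [14.0, 15.0, 16.0])
        Z, _ = standardize(q)
        assert np.allclose(Z["firmness"], [-1.0, 0.0, 1.0])

    def test_apply_mode_reuses_stats(self):
        stats = pd.DataFrame([[10.0, 3.0, 5.0, 14.0], [2.0, 0.1, 0.5, 1.0]],
                             index=["mean", "sd"], columns=list(m.INDICATORS))
        q = quality_frame([14.0], [3.0], [5.0], [14.0])
        Z, _ = standardize(q, stats)
        assert Z["firmness"].iloc[0] == pytest.approx(2.0)
        assert Z["pH"].iloc[0] == pytest.approx(0.0)

    def test_constant_indicator_rejected(self):
        q = quality_frame([1.0, 1.0], [3.0, 3.1], [5.0, 6.0], [14.0, 15.0])
        with pytest.raises(ValueError, match="firmness"):
            standardize(q)


# ---------------------------------------------------------------------------
# correlation-matrix PCA
# ---------------------------------------------------------------------------

class TestPCA:
    def test_two_perfectly_correlated_variables(self, rng):
        x = rng.standard_normal(50)
        Z = pd.DataFrame({"ssc": (x - x.mean()) / x.std(ddof=1),
                          "dmc_pct": (x - x.mean()) / x.std(ddof=1)})
        p = m.pca_correlation(Z)
        assert np.allclose(p.eigenvalues, [2.0, 0.0], atol=1e-10)
        assert np.allclose(p.explained_pct, [100.0, 0.0], atol=1e-8)
        # hand eigendecomposition of [[1,1],[1,1]]: loadings [1, 1]
        assert np.allclose(p.loadings[:, 0], [1.0, 1.0], atol=1e-8)
        # score coefficients [0.5, 0.5] -> scores = z exactly
        assert np.allclose(p.score_coef[:, 0], [0.5, 0.5], atol=1e-8)
        scores = Z.to_numpy() @ p.score_coef[:, 0]
        assert np.allclose(scores, Z["ssc"], atol=1e-8)

    def test_uncorrelated_variables_have_unit_eigenvalues(self):
        rng = np.random.default_rng(0)
        Z = pd.DataFrame(rng.standard_normal((100_000, 4)),
                         columns=list(m.INDICATORS))
        p = m.pca_correlation(Z)
        assert np.allclose(p.eigenvalues, 1.0, atol=0.05)

    def test_eigenvalues_sum_to_variable_count(self, full_dataset):
        _, q = full_dataset
        Z, _ = standardize(q)
        p = m.pca_correlation(Z)
        assert p.eigenvalues.sum() == pytest.approx(4.0)
        assert p.explained_pct.sum() == pytest.approx(100.0)

    def test_scores_have_unit_variance(self, full_dataset):
        _, q = full_dataset
        Z, _ = standardize(q)
        p = m.pca_correlation(Z)
        for k in range(2):  # retained components
            s = Z.to_numpy() @ p.score_coef[:, k]
            assert s.std(ddof=1) == pytest.approx(1.0, abs=1e-8)

    def test_ssc_loading_sign_convention(self, full_dataset):
        _, q = full_dataset
        Z, _ = standardize(q)
        p = m.pca_correlation(Z)
        ssc = list(Z.columns).index("ssc")
        assert (p.loadings[ssc, :] >= -1e-12).all()

    def test_cumulative_explained_bookkeeping(self):
        p = PCAResult(("a", "b", "c", "d"),
                      np.array([1.7708, 1.1552, 0.6, 0.474]),
                      np.eye(4), np.array([44.27, 28.88, 15.0, 11.85]),
                      np.eye(4))
        assert p.cumulative_explained(2) == pytest.approx(73.15)


# ---------------------------------------------------------------------------
# composite coefficients and F
# ---------------------------------------------------------------------------

class TestComposite:
    def _pca(self, explained, score_coef):
        explained = np.asarray(explained, float)
        return PCAResult(tuple(m.INDICATORS), explained * 4 / 100,
                         np.eye(4)[:, :len(explained)], explained,
                         np.asarray(score_coef, float))

    def test_single_retained_component(self):
        sc = np.array([[-0.3], [0.2], [0.4], [0.35]])
        p = self._pca([60.0], sc)
        coeffs = m.composite_coefficients(p, retain=1)
        assert np.allclose(coeffs, sc.ravel())

    def test_equal_weights_average_rows(self):
        sc = np.array([[-0.3, 0.1], [0.2, 0.2], [0.4, 0.0], [0.35, -0.1]])
        p = self._pca([40.0, 40.0], sc)
        coeffs = m.composite_coefficients(p, retain=2)
        assert np.allclose(coeffs, sc.mean(axis=1))

    def test_sign_pattern_on_generated_orchard(self, full_dataset):
        """Single latent maturity factor: firmness loads negative on F."""
        _, q = full_dataset
        res = m.MaturityIndex(q).fit()
        a, b, c, d = res.coefficients
        assert a < 0 and b > 0 and c > 0 and d > 0

    def test_f_index_matches_dot_product_oracle(self, rng):
        Z = rng.standard_normal((20, 4))
        coeffs = rng.standard_normal(4)
        F = m.f_index(Z, coeffs)
        for i in range(20):
            assert F[i] == pytest.approx(sum(Z[i, j] * coeffs[j]
                                             for j in range(4)))
        assert np.allclose(m.f_index(np.zeros((3, 4)), coeffs), 0.0)
        assert m.f_index(np.array([[2.0, 9.9, -1, 0.5]]),
                         [1, 0, 0, 0])[0] == pytest.approx(2.0)

    def test_f_invariant_to_pca_sign_flip(self, full_dataset):
        """Flipping eigenvectors by hand must not change F after the
        SSC-positive convention is re-applied."""
        _, q = full_dataset
        Z, _ = standardize(q)
        X = Z.to_numpy()
        R = np.corrcoef(X, rowvar=False)
        eigval, eigvec = np.linalg.eigh(R)
        # poison the eigenvector signs; pca_correlation must normalise them
        p1 = m.pca_correlation(Z)
        Zf = Z.iloc[::-1].reset_index(drop=True)  # reordering samples
        p2 = m.pca_correlation(Zf)
        c1 = m.composite_coefficients(p1)
        c2 = m.composite_coefficients(p2)
        assert np.allclose(c1, c2, atol=1e-10)
        assert np.allclose(m.f_index(Z, c1), m.f_index(Z, c2), atol=1e-10)


# ---------------------------------------------------------------------------
# grade scheme
# ---------------------------------------------------------------------------

class TestGradeScheme:
    @pytest.mark.parametrize("days,grade", [
        (0, 6.5), (4, 6.5), (7, 6.5), (8, 7.0), (16, 7.5),
        (24, 8.0), (32, 8.5), (39, 8.5), (40, 9.0),
    ])
    def test_grade_mapping(self, days, grade):
        assert m.true_grade(days) == grade

    def test_grades_non_decreasing(self):
        g = m.true_grade(np.arange(0, 41))
        assert (np.diff(g) >= 0).all()

    def test_clamp_and_pre_commercial(self):
        with pytest.warns(RuntimeWarning):
            assert m.true_grade(48) == 9.0
        assert np.isnan(m.true_grade(-4))
        assert grade_label(m.true_grade(-4)) == "pre-commercial"
        assert grade_label(7.5) == "7.5"


# ---------------------------------------------------------------------------
# thresholds and classification
# ---------------------------------------------------------------------------

class TestThresholds:
    def test_two_grade_midpoint(self):
        F = np.array([-1.0, -1.0, 1.0, 1.0])
        g = np.array([6.5, 6.5, 7.0, 7.0])
        cuts, labels, means = m.calibrate_thresholds(F, g)
        assert np.allclose(cuts, [0.0])
        assert labels.tolist() == [6.5, 7.0]

    def test_equally_spaced_means_give_equally_spaced_cuts(self):
        F = np.array([0.0, 1.0, 2.0])
        g = np.array([6.5, 7.0, 7.5])
        cuts, _, _ = m.calibrate_thresholds(F, g)
        assert np.allclose(np.diff(cuts), 1.0)

    def test_generator_data_thresholds_increase(self, noiseless_profiles):
        design = m.SamplingDesign(varieties=("Tainong",),
                                  batches_per_variety=(11,), fruits_per_batch=3)
        q = m.generate_quality(design, noiseless_profiles, seed=6)
        res = m.MaturityIndex(q).fit()
        cuts, _, _ = res.thresholds["Tainong"]
        assert (np.diff(cuts) > 0).all()

    def test_non_monotone_means_isotonically_adjusted(self):
        F = np.array([0.0, 2.0, 1.0])
        g = np.array([6.5, 7.0, 7.5])
        with pytest.warns(RuntimeWarning, match="isotonic"):
            cuts, _, means = m.calibrate_thresholds(F, g)
        assert (np.diff(means) >= 0).all()
        assert (np.diff(cuts) >= 0).all()

    def test_single_grade_rejected(self):
        with pytest.raises(ValueError):
            m.calibrate_thresholds(np.array([1.0, 2.0]), np.array([6.5, 6.5]))


class TestClassification:
    def test_values_at_grade_means_classify_perfectly(self):
        labels = np.array([6.5, 7.0, 7.5])
        means = np.array([-1.0, 0.0, 1.0])
        cuts = np.array([-0.5, 0.5])
        F = np.repeat(means, 4)
        tg = np.repeat(labels, 4)
        per_grade, overall, conf = classify_and_score(F, tg, cuts, labels)
        assert overall == 100.0
        assert all(v == 100.0 for v in per_grade.values())
        assert np.trace(conf.to_numpy()) == 12

    def test_three_of_four_correct(self):
        labels = np.array([6.5, 7.0])
        cuts = np.array([0.0])
        F = np.array([-1.0, -1.0, -1.0, 1.0])   # last one crosses the cut
        tg = np.array([6.5, 6.5, 6.5, 6.5])
        per_grade, overall, _ = classify_and_score(F, tg, cuts, labels)
        assert per_grade[6.5] == pytest.approx(75.0)
        assert overall == pytest.approx(75.0)

    def test_accuracy_degrades_with_noise(self, profiles):
        """Grading accuracy is non-increasing in indicator noise."""
        design = m.SamplingDesign(varieties=("Tainong",),
                                  batches_per_variety=(11,), fruits_per_batch=6)
        acc = []
        for noise in (0.0, 0.10, 0.40):
            profs = scale_noise(profiles, fluctuation_frac=0.0,
                                noise_frac=noise)
            q = m.generate_quality(design, profs, seed=31)
            res = m.MaturityIndex(q).fit()
            acc.append(res.score(q)["Tainong"]["overall_accuracy_pct"])
        assert acc[0] == 100.0
        assert acc[0] + 5 >= acc[1] >= acc[2] - 5

    def test_empty_prediction_set_rejected(self):
        with pytest.raises(ValueError):
            classify_and_score(np.array([]), np.array([]),
                               np.array([0.0]), np.array([6.5, 7.0]))


class TestBoxplotStats:
    def test_five_numbers(self):
        F = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        g = np.full(5, 6.5)
        row = m.f_boxplot_stats(F, g).iloc[0]
        assert row["median"] == 3.0
        assert row["q1"] == 2.0 and row["q3"] == 4.0

    def test_constant_group_no_outliers(self):
        row = m.f_boxplot_stats(np.full(6, 2.5), np.full(6, 7.0)).iloc[0]
        assert row["minimum"] == row["q1"] == row["median"] == row["q3"] \
            == row["maximum"] == 2.5
        assert row["outliers"] == []

    def test_matches_sort_and_index_oracle(self, rng):
        F = rng.standard_normal(37)
        g = np.full(37, 8.0)
        row = m.f_boxplot_stats(F, g).iloc[0]
        v = np.sort(F)
        assert row["median"] == pytest.approx(np.quantile(v, 0.5))
        q1, q3 = np.quantile(v, [0.25, 0.75])
        assert row["q1"] == pytest.approx(q1)
        iqr = q3 - q1
        expected_out = v[(v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)]
        assert np.allclose(sorted(row["outliers"]), expected_out)


# ---------------------------------------------------------------------------
# model object end-to-end
# ---------------------------------------------------------------------------

class TestMaturityIndexModel:
    def test_f_tracks_maturity_time(self, full_dataset):
        _, q = full_dataset
        res = m.MaturityIndex(q).fit()
        graded = res.classify(q)
        for variety in q["variety"].unique():
            mask = (q["variety"] == variety).to_numpy()
            r = np.corrcoef(graded["F"][mask], q["day"][mask])[0, 1]
            assert r > 0.95

    def test_summary_reports_model(self, full_dataset):
        _, q = full_dataset
        res = m.MaturityIndex(q).fit()
        text = res.summary()
        assert "Z_firmness" in text and "PC1" in text and "cuts" in text
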