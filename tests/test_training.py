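import numpy as np
import pandas as pd
import pytest

from methcascade import (
    CVConfig,
    PanelClassifier,
    calibrate_cutoff,
    cv_auc,
    forward_select,
    score_samples,
    train_classifier,
)

from conftest import matrix_from_amf


def make_xy(seed=0, n=60):
    """One strong marker, one half-strength marker, two noise markers."""
    rng = np.random.default_rng(seed)
    y = np.repeat([1, 0], n // 2)
    strong = y * 2.5 + rng.normal(0, 1, n)
    weak = y * 0.8 + rng.normal(0, 1, n)
    amf = pd.DataFrame(
        {
            "strong": strong,
            "weak": weak,
            "noise1": rng.normal(0, 1, n),
            "noise2": rng.normal(0, 1, n),
        },
        index=[f"s{i}" for i in range(n)],
    )
    return amf, y


class TestCvAuc:
    def test_perfect_marker_reaches_unit_auc(self):
        y = np.repeat([1, 0], 20)
        amf = pd.DataFrame({"m": np.where(y == 1, 0.9, 0.1)},
                           index=[f"s{i}" for i in range(40)])
        res = cv_auc(["m"], amf, y, CVConfig(n_repeats=3, seed=0))
        assert res.mean_auc == 1.0

    def test_permuted_labels_stay_near_chance(self):
        """Leakage detector: with labels shuffled, repeated-CV AUC must sit
        near 0.5 — imputation/standardization fit inside folds only."""
        amf, y = make_xy(seed=1, n=80)
        rng = np.random.default_rng(2)
        aucs = []
        for _ in range(8):
            y_perm = rng.permutation(y)
            aucs.append(
                cv_auc(
                    list(amf.columns), amf, y_perm, CVConfig(n_repeats=5, seed=3)
                ).mean_auc
            )
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_reproducible_given_seed(self):
        amf, y = make_xy(seed=4)
        a = cv_auc(["strong", "weak"], amf, y, CVConfig(seed=5))
        b = cv_auc(["strong", "weak"], amf, y, CVConfig(seed=5))
        assert a.mean_auc == b.mean_auc
        assert np.array_equal(a.oof_scores, b.oof_scores)

    def test_degenerate_unstratified_fold_is_error(self):
        y = np.array([1] + [0] * 7)
        amf = pd.DataFrame({"m": np.arange(8.0)}, index=[f"s{i}" for i in range(8)])
        with pytest.raises(ValueError, match="stratified|class"):
            cv_auc(["m"], amf, y, CVConfig(n_repeats=1, stratified=False, seed=0))

    def test_missing_marker_column_is_hard_error(self):
        amf, y = make_xy()
        with pytest.raises(KeyError):
            cv_auc(["absent"], amf, y, CVConfig(seed=0))


class TestForwardSelect:
    def test_single_marker_panel_is_the_model(self):
        amf, y = make_xy(seed=6)
        model = forward_select(["weak"], amf[["weak"]], y, CVConfig(n_repeats=3, seed=0))
        assert model.markers == ["weak"]

    def test_perfect_marker_plus_noise_selects_only_it(self):
        """A perfectly separating anchor cannot be improved; the tie-break
        keeps the smallest subset."""
        rng = np.random.default_rng(7)
        y = np.repeat([1, 0], 24)
        cols = {"perfect": np.where(y == 1, 0.9, 0.1)}
        for k in range(9):
            cols[f"n{k}"] = rng.normal(0, 1, 48)
        amf = pd.DataFrame(cols, index=[f"s{i}" for i in range(48)])
        model = forward_select(list(cols), amf, y, CVConfig(n_repeats=3, seed=1))
        assert model.markers == ["perfect"]
        assert model.cv_auc_mean == 1.0

    def test_complementary_markers_both_selected(self):
        """Two half-informative markers, each separating a different half of
        the cases, must beat either alone and both enter the subset."""
        rng = np.random.default_rng(8)
        n = 120
        y = np.repeat([1, 0], n // 2)
        half = np.zeros(n, dtype=bool)
        half[: n // 4] = True  # first half of the positives
        a = np.where(y.astype(bool) & half, 3.0, 0.0) + rng.normal(0, 0.7, n)
        b = np.where(y.astype(bool) & ~half, 3.0, 0.0) + rng.normal(0, 0.7, n)
        amf = pd.DataFrame(
            {"a": a, "b": b, "noise": rng.normal(0, 1, n)},
            index=[f"s{i}" for i in range(n)],
        )
        cv = CVConfig(n_repeats=5, seed=2)
        model = forward_select(["a", "b", "noise"], amf, y, cv)
        assert {"a", "b"} <= set(model.markers)
        both = cv_auc(["a", "b"], amf, y, cv).mean_auc
        singles = max(cv_auc(["a"], amf, y, cv).mean_auc,
                      cv_auc(["b"], amf, y, cv).mean_auc)
        assert both > singles

    def test_reproducible_model(self):
        amf, y = make_xy(seed=9)
        m1 = train_classifier(list(amf.columns), amf, y, CVConfig(seed=4), mode="S")
        m2 = train_classifier(list(amf.columns), amf, y, CVConfig(seed=4), mode="S")
        assert m1.markers == m2.markers
        assert np.allclose(m1.coef, m2.coef)
        assert m1.cutoff == m2.cutoff


class TestSeededBatteries:
    @staticmethod
    def _battery_cohort(seed):
        from methcascade import SimulationConfig, simulate_cohort

        return simulate_cohort(
            SimulationConfig(
                n_cancer=40, n_benign=30, n_healthy=40,
                n_tumor_tissue=4, n_wbc=4,
                n_regions=12, n_true_dmr=4,
                tumor_fraction_range=(0.05, 0.25),
                seed=seed,
            )
        )

    def test_informative_markers_beat_noise_markers(self):
        """CV AUC of planted-DMR features strictly exceeds that of noise
        features in every seeded cohort."""
        cv = CVConfig(n_repeats=3, seed=0)
        wins = 0
        for seed in range(10):
            c = self._battery_cohort(seed)
            g = c.samples["group"]
            ids = list(g[g == "cancer"].index) + list(g[g == "healthy"].index)
            amf = c.counts.amf.loc[ids]
            y = (g.loc[ids] == "cancer").to_numpy()
            informative = list(c.truth[c.truth].index)
            noise = list(c.truth[~c.truth].index)[: len(informative)]
            if (cv_auc(informative, amf, y, cv).mean_auc
                    > cv_auc(noise, amf, y, cv).mean_auc):
                wins += 1
        assert wins == 10

    def test_screening_vs_diagnostic_asymmetry(self):
        """Across seeded cohorts, the sensitivity-tuned S model detects at
        least as many cancers as the specificity-tuned D model, and the D
        model is at least as specific against benign disease, in >= 18/20
        seeds."""
        holds = 0
        for seed in range(20):
            c = self._battery_cohort(100 + seed)
            g = c.samples["group"]
            amf = c.counts.amf
            panel = list(c.truth[c.truth].index)
            cv = CVConfig(n_repeats=3, seed=seed)

            s_ids = list(g[g.isin(["cancer", "healthy"])].index)
            s_model = train_classifier(
                panel, amf.loc[s_ids], (g.loc[s_ids] == "cancer").to_numpy(),
                cv, mode="S", target_sens=0.90,
            )
            d_ids = list(g[g.isin(["cancer", "benign"])].index)
            d_model = train_classifier(
                panel, amf.loc[d_ids], (g.loc[d_ids] == "cancer").to_numpy(),
                cv, mode="D", target_spec=0.95,
            )
            cancer = g[g == "cancer"].index
            benign = g[g == "benign"].index
            s_sens = (score_samples(s_model, amf.loc[cancer]) >= s_model.cutoff).mean()
            d_sens = (score_samples(d_model, amf.loc[cancer]) >= d_model.cutoff).mean()
            s_spec = (score_samples(s_model, amf.loc[benign]) < s_model.cutoff).mean()
            d_spec = (score_samples(d_model, amf.loc[benign]) < d_model.cutoff).mean()
            if s_sens >= d_sens and d_spec >= s_spec:
                holds += 1
        assert holds >= 18


class TestCutoffCalibration:
    def test_separated_scores_full_sensitivity(self):
        scores = np.array([0.9, 0.8, 0.85, 0.2, 0.1, 0.15])
        labels = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        c = calibrate_cutoff(scores, labels, "S", target_sens=0.90)
        assert c == 0.8  # largest cutoff keeping all positives
        assert (scores[labels] >= c).mean() == 1.0

    def test_full_sensitivity_target_forces_cutoff_below_min_positive(self):
        scores = np.array([0.7, 0.3, 0.6, 0.2])
        labels = np.array([1, 1, 0, 0], dtype=bool)
        c = calibrate_cutoff(scores, labels, "S", target_sens=1.0)
        assert c <= 0.3

    def test_mode_d_meets_specificity_target(self):
        rng = np.random.default_rng(10)
        scores = np.concatenate([rng.uniform(0.4, 1.0, 50), rng.uniform(0.0, 0.6, 50)])
        labels = np.repeat([True, False], 50)
        c = calibrate_cutoff(scores, labels, "D", target_spec=0.95)
        assert (scores[~labels] < c).mean() >= 0.95

    def test_training_sensitivity_meets_target_on_cohort(self):
        amf, y = make_xy(seed=11, n=100)
        model = train_classifier(
            list(amf.columns), amf, y, CVConfig(seed=6), mode="S", target_sens=0.90
        )
        oof = np.array([model.oof_scores[f"s{i}"] for i in range(100)])
        sens = (oof[y == 1] >= model.cutoff).mean()
        assert 0.90 <= sens <= 1.0

    def test_unattainable_specificity_returns_boundary(self):
        scores = np.array([0.5, 0.5, 0.5, 0.5])
        labels = np.array([1, 1, 0, 0], dtype=bool)
        c = calibrate_cutoff(scores, labels, "D", target_spec=0.95)
        assert c > 0.5  # above every score: nothing called positive


class TestScoring:
    def test_zero_coefficients_score_logistic_intercept(self):
        model = PanelClassifier(
            mode="S", markers=["m"], coef=[0.0], intercept=0.4,
            medians=[0.1], means=[0.1], stds=[1.0],
        )
        mat = matrix_from_amf(np.array([0.05, 0.5, 0.95]))
        mat.methylated.columns = mat.detected.columns = ["m"]
        s = score_samples(model, mat)
        assert np.allclose(s, 1 / (1 + np.exp(-0.4)))

    def test_positive_weight_monotonicity(self):
        model = PanelClassifier(
            mode="S", markers=["m"], coef=[2.0], intercept=0.0,
            medians=[0.5], means=[0.5], stds=[0.2],
        )
        mat = matrix_from_amf(np.array([0.1, 0.5, 0.9]))
        mat.methylated.columns = mat.detected.columns = ["m"]
        s = score_samples(model, mat).to_numpy()
        assert s[0] < s[1] < s[2]

    def test_missing_values_imputed_with_training_medians(self):
        model = PanelClassifier(
            mode="S", markers=["m"], coef=[2.0], intercept=0.0,
            medians=[0.5], means=[0.5], stds=[0.2],
        )
        amf = pd.DataFrame({"m": [np.nan]}, index=["s0"])
        s = score_samples(model, amf)
        assert s.iloc[0] == pytest.approx(0.5)

    def test_entirely_absent_marker_is_hard_error(self):
        model = PanelClassifier(
            mode="S", markers=["m", "gone"], coef=[1.0, 1.0], intercept=0.0,
            medians=[0.5, 0.5], means=[0.5, 0.5], stds=[0.2, 0.2],
        )
        amf = pd.DataFrame({"m": [0.1]}, index=["s0"])
        with pytest.raises(KeyError, match="gone"):
            score_samples(model, amf)

    def test_json_round_trip_preserves_scores(self, tmp_path):
        amf, y = make_xy(seed=12)
        model = train_classifier(
            list(amf.columns), amf, y, CVConfig(n_repeats=3, seed=7), mode="D"
        )
        path = tmp_path / "model.json"
        model.to_json(path)
        clone = PanelClassifier.from_json(path)
        pd.testing.assert_series_equal(
            score_samples(model, amf), score_samples(clone, amf)
        )
        assert clone.cutoff == model.cutoff
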