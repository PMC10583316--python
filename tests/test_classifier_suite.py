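import numpy as np
import pytest

from conftest import make_gaussian_table
from _oracles import auc_pairs_brute
from oscnet.classifier_suite import (
    NETWORK_COMBINATIONS,
    AlgorithmSpec,
    CvConfig,
    TrainedModel,
    cross_validate,
    fit_final,
    kernel_scale_value,
    rank_models,
    roc_auc,
)
from oscnet.exceptions import ConfigurationError, InputError
from oscnet.feature_selection import select

ALL_SPECS = [
    AlgorithmSpec(family="svm", kernel="linear"),
    AlgorithmSpec(family="svm", kernel="gaussian", kernel_scale="medium"),
    AlgorithmSpec(family="svm", kernel="gaussian", kernel_scale="fine"),
    AlgorithmSpec(family="discriminant"),
    AlgorithmSpec(family="naive_bayes"),
    AlgorithmSpec(family="knn"),
    AlgorithmSpec(family="decision_tree"),
]


class TestRocAuc:
    def test_perfect_ordering(self):
        auc, fpr, tpr = roc_auc(np.array([-2, -1, 1, 2.0]), np.array([0, 0, 1, 1]))
        assert auc == 1.0
        assert fpr[-1] == 1.0 and tpr[-1] == 1.0

    def test_all_ties_give_half(self):
        auc, _, _ = roc_auc(np.zeros(6), np.array([0, 1, 0, 1, 0, 1]))
        assert auc == pytest.approx(0.5)

    def test_six_score_fixture_matches_pair_oracle(self):
        scores = np.array([0.3, 0.3, -0.1, 0.8, -0.5, 0.3])
        labels = np.array([1, 0, 0, 1, 0, 1])
        auc, _, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(auc_pairs_brute(scores, labels))

    @pytest.mark.parametrize("n", [5, 20, 50])
    def test_random_fixtures_match_exhaustive_pairs(self, n, rng):
        for _ in range(30):
            scores = np.round(rng.standard_normal(n), 1)  # induce ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            auc, _, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(auc_pairs_brute(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))


class TestCrossValidate:
    # the 'fine' gaussian preset (scale sqrt(P)/4) is deliberately narrow and
    # does not generalise perfectly even on separated clouds, so it is not
    # part of the separable-case guarantee
    @pytest.mark.parametrize(
        "spec",
        [s for s in ALL_SPECS if s.label != "svm-gaussian-fine"],
        ids=lambda s: s.label,
    )
    def test_separable_clouds_classified_perfectly(self, spec, rng):
        table = make_gaussian_table(rng, 40, 40, 4, effect_cols=[0, 1], effect=6.0)
        report = cross_validate(table, spec, CvConfig(seed=1))
        assert report.accuracy_pct == 100.0
        assert report.auc == 1.0

    def test_deterministic_given_seed(self, rng):
        table = make_gaussian_table(rng, 15, 15, 6, effect_cols=[0], effect=1.0)
        spec = AlgorithmSpec(family="svm", kernel="gaussian", kernel_scale="medium")
        r1 = cross_validate(table, spec, CvConfig(seed=3))
        r2 = cross_validate(table, spec, CvConfig(seed=3))
        assert r1.to_dict() == r2.to_dict()

    def test_no_signal_accuracy_near_chance(self, rng):
        """Label-permuted tables score near the majority-class rate."""
        accs = []
        for _ in range(30):
            table = make_gaussian_table(rng, 12, 12, 5)
            report = cross_validate(
                table, AlgorithmSpec(family="naive_bayes"), CvConfig(seed=0)
            )
            accs.append(report.accuracy_pct)
        mean = np.mean(accs)
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(mean - 50.0) < 3 * se + 5.0

    def test_metrics_recomputable_from_confusion_counts(self, rng):
        table = make_gaussian_table(rng, 20, 20, 4, effect_cols=[0], effect=1.5)
        r = cross_validate(table, AlgorithmSpec(family="discriminant"), CvConfig(seed=0))
        assert r.accuracy_pct == pytest.approx(100.0 * (r.tp + r.tn) / r.n)
        assert r.sensitivity == pytest.approx(r.tp / (r.tp + r.fn))
        assert r.specificity == pytest.approx(r.tn / (r.tn + r.fp))
        assert r.n == 40

    def test_positive_class_is_patient_like_group(self, rng):
        """Sensitivity counts CM detections: shift CM scores up via a
        one-sided effect and check sens > spec when the classifier
        over-calls CM."""
        table = make_gaussian_table(rng, 30, 10, 3, effect_cols=[0], effect=2.0)
        r = cross_validate(table, AlgorithmSpec(family="knn", k=3), CvConfig(seed=0))
        assert r.tp + r.fn == 10  # CM group size

    def test_too_many_folds_rejected(self, rng):
        table = make_gaussian_table(rng, 3, 30, 3)
        with pytest.raises(InputError, match="n_folds"):
            cross_validate(table, AlgorithmSpec(family="naive_bayes"), CvConfig(n_folds=5))

    def test_leave_one_out_option(self, rng):
        table = make_gaussian_table(rng, 10, 10, 3, effect_cols=[0], effect=4.0)
        r = cross_validate(
            table,
            AlgorithmSpec(family="discriminant"),
            CvConfig(leave_one_out=True),
        )
        assert r.accuracy_pct > 90.0

    def test_leakage_tripwire_fold_local_label_copy_stays_at_chance(self, rng):
        """A feature equal to the labels only on one test fold's rows must
        not help: training folds see noise there, so a leakage-free CV
        stays near chance, while any implementation that fits on test rows
        would score that fold perfectly."""
        from sklearn.model_selection import StratifiedKFold

        table = make_gaussian_table(rng, 25, 25, 5)
        y = np.array([1 if g == "CM" else 0 for g in table.groups])
        cv = CvConfig(seed=2)
        splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=cv.seed)
        _, fold0_test = next(splitter.split(table.data, y))
        table.data[fold0_test, 0] = 4.0 * (2 * y[fold0_test] - 1)  # label copy
        r = cross_validate(
            table, AlgorithmSpec(family="svm", kernel="linear"), cv
        )
        assert r.accuracy_pct < 75.0  # leaky fits would clear 85%

    def test_wild_feature_scales_handled_by_per_fold_standardisation(self, rng):
        table = make_gaussian_table(rng, 25, 25, 5)
        table.data[:, 0] *= 1e6
        r = cross_validate(table, AlgorithmSpec(family="svm", kernel="linear"), CvConfig(seed=2))
        assert 20.0 < r.accuracy_pct < 80.0  # chance-level, no crash


class TestTrainedModel:
    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.label)
    def test_json_round_trip_preserves_predictions(self, spec, rng, tmp_path):
        table = make_gaussian_table(rng, 15, 15, 5, effect_cols=[0], effect=2.0)
        model = fit_final(table, spec)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = TrainedModel.from_json(path)
        probe = rng.standard_normal((20, 5))
        assert np.array_equal(
            model.decision_scores(probe), loaded.decision_scores(probe)
        )
        assert np.array_equal(model.predict(probe), loaded.predict(probe))

    def test_constant_feature_column_guarded(self, rng):
        table = make_gaussian_table(rng, 10, 10, 3, effect_cols=[1], effect=3.0)
        table.data[:, 0] = 5.0
        model = fit_final(table, AlgorithmSpec(family="svm", kernel="linear"))
        scores = model.decision_scores(table.data)
        assert np.all(np.isfinite(scores))

    def test_separable_resubstitution_perfect(self, rng):
        table = make_gaussian_table(rng, 10, 10, 3, effect_cols=[0], effect=6.0)
        for spec in (
            AlgorithmSpec(family="svm", kernel="linear"),
            AlgorithmSpec(family="knn", k=1),
        ):
            model = fit_final(table, spec)
            preds = model.predict(table.data)
            assert np.all(preds == np.array(table.groups))

    def test_single_class_rejected(self, rng):
        table = make_gaussian_table(rng, 10, 10, 3)
        single = table.with_groups(("HC",) * 20)
        with pytest.raises(InputError):
            fit_final(single, AlgorithmSpec(family="naive_bayes"))

    def test_positive_class_defaults_to_cm(self, rng):
        table = make_gaussian_table(rng, 8, 8, 3, effect_cols=[0], effect=2.0)
        model = fit_final(table, AlgorithmSpec(family="discriminant"))
        assert model.positive_class == "CM"


class TestKernelScale:
    def test_presets_follow_sqrt_p_convention(self):
        assert kernel_scale_value("medium", 16) == pytest.approx(4.0)
        assert kernel_scale_value("fine", 16) == pytest.approx(1.0)
        assert kernel_scale_value("coarse", 16) == pytest.approx(16.0)

    def test_numeric_passthrough(self):
        assert kernel_scale_value(2.5, 99) == 2.5

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            AlgorithmSpec(family="svm", kernel="gaussian", kernel_scale="huge")
        with pytest.raises(ConfigurationError):
            AlgorithmSpec(family="qda")


class TestRankModels:
    def make_network_table(self, rng, n_a=20, n_b=20):
        """Features over two networks with signal planted in PN only."""
        from oscnet.network_features import FeatureIndex, FeatureTable

        n_feat = 12
        data = rng.standard_normal((n_a + n_b, n_feat))
        data[n_a:, :3] -= 2.0  # PN signal
        triples = tuple(("PN", "alpha", f"p{k}") for k in range(6)) + tuple(
            ("VN", "alpha", f"v{k}") for k in range(6)
        )
        return FeatureTable(
            data=data,
            subject_ids=tuple(f"s{i}" for i in range(n_a + n_b)),
            groups=("HC",) * n_a + ("CM",) * n_b,
            index=FeatureIndex(triples),
        )

    def test_duplicate_combos_give_identical_metrics(self, rng):
        table = self.make_network_table(rng)
        selection = select(table, q=0.05, mode="global")
        lb, _ = rank_models(
            table,
            selection,
            combos=[("PN",), ("PN",)],
            specs=[AlgorithmSpec(family="svm", kernel="linear")],
            cv=CvConfig(seed=1),
        )
        assert len(lb) == 2
        assert lb.iloc[0]["accuracy_pct"] == lb.iloc[1]["accuracy_pct"]
        assert lb.iloc[0]["auc"] == lb.iloc[1]["auc"]

    def test_signal_network_outranks_noise_network(self, rng):
        table = self.make_network_table(rng)
        selection = select(table, q=0.4, mode="global")  # keep some VN cols too
        lb, _ = rank_models(
            table,
            selection,
            combos=[("PN",), ("VN",)],
            specs=[AlgorithmSpec(family="svm", kernel="linear")],
            cv=CvConfig(seed=1),
        )
        by_combo = lb.set_index("combo")
        if "VN" in by_combo.index:
            assert (
                by_combo.loc["PN", "accuracy_pct"]
                >= by_combo.loc["VN", "accuracy_pct"]
            )
        assert lb.iloc[0]["combo"] == "PN"

    def test_empty_selection_combo_skipped_with_warning(self, rng):
        table = self.make_network_table(rng)
        selection = select(table, q=0.05, mode="global")  # VN has no signal
        with pytest.warns(RuntimeWarning, match="no selected features"):
            lb, _ = rank_models(
                table,
                selection,
                combos=[("PN",), ("VN",)],
                specs=[AlgorithmSpec(family="naive_bayes")],
                cv=CvConfig(seed=0),
            )
        assert set(lb["combo"]) == {"PN"}

    def test_exclusion_flags_below_threshold(self, rng):
        table = self.make_network_table(rng)
        null_table = table.with_groups(
            tuple(rng.permutation(np.array(table.groups)))
        )
        selection = select(null_table, q=0.9, mode="global")
        lb, _ = rank_models(
            null_table,
            selection,
            combos=[("PN", "VN")],
            specs=[AlgorithmSpec(family="naive_bayes")],
            cv=CvConfig(seed=0),
        )
        row = lb.iloc[0]
        assert bool(row["excluded"]) == (
            row["accuracy_pct"] < 75.0 or row["auc"] < 0.75
        )

    def test_eleven_printed_combinations_constant(self):
        assert len(NETWORK_COMBINATIONS) == 11
        assert all("PN" in c for c in NETWORK_COMBINATIONS[:8])
        assert NETWORK_COMBINATIONS[7] == ("PN",)
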