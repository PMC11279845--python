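"""The six evaluation designs against geometric, null and bookkeeping
oracles on synthetic worlds."""

import numpy as np
import pandas as pd
import pytest

from elemix import (CvScheme, ModelSpec, PretreatmentSpec,
                    build_calculated_set, build_measured_set,
                    calculated_twins, default_config, expand_directed,
                    generate_pure_panel, run_approach_i, run_approach_ii,
                    run_approach_iii, run_approach_iv, run_approach_v,
                    run_baseline, sample_measured_plan)
from elemix.approaches import _twin_key
from elemix.mixtures import mixture_elements
from elemix.world import ELEMENTS

SVM_LOG = ModelSpec("svm_radial", pretreatment=PretreatmentSpec("log10"))
SVM_AUTO = ModelSpec("svm_radial", pretreatment=PretreatmentSpec("autoscale"))
SVM_RAW = ModelSpec("svm_radial")
QUICK_CV = CvScheme(folds=5, repeats=2, seed=3)


def _directed_sets(panel, world, per=2, seed=5):
    plan = sample_measured_plan(panel, per_country_per_ratio=per,
                                seed=seed)
    measured = build_measured_set(panel, plan, world, seed=seed + 1)
    twins = calculated_twins(panel, plan)
    return (expand_directed(measured), expand_directed(twins), plan)


def _focal(directed, country):
    return directed[directed["focal_country"] == country]


@pytest.fixture(scope="module")
def separated_sets(separated_panel, separated_world):
    return _directed_sets(separated_panel, separated_world)


@pytest.fixture(scope="module")
def constant_sets(constant_panel):
    world = default_config(seed=1, analytic_cv=0.0)
    plan = sample_measured_plan(constant_panel, per_country_per_ratio=2,
                                seed=2)
    measured = build_measured_set(constant_panel, plan, world)
    twins = calculated_twins(constant_panel, plan)
    calc_all = build_calculated_set(constant_panel)
    calc_all["provenance"] = "calculated"
    return {
        "measured": expand_directed(measured),
        "twins": expand_directed(twins),
        "calc_all": expand_directed(calc_all),
        "plan": plan,
    }


class TestBaseline:
    def test_separated_world_classified_perfectly(self, separated_panel):
        rep = run_baseline(separated_panel, SVM_AUTO, QUICK_CV)
        assert rep.overall_accuracy == pytest.approx(100.0)

    def test_null_world_scores_at_majority_rate(self, null_panel):
        rep = run_baseline(null_panel, SVM_RAW, QUICK_CV)
        share = null_panel["country"].value_counts(normalize=True).max()
        band = 2.576 * np.sqrt(share * (1 - share) / len(null_panel))
        assert rep.overall_accuracy / 100 < share + band

    def test_confusion_row_sums_are_test_counts(self, separated_panel):
        cv = CvScheme(folds=5, repeats=2, seed=3)
        rep = run_baseline(separated_panel, SVM_AUTO, cv)
        counts = separated_panel["country"].value_counts()
        for c in counts.index:
            assert rep.confusion.loc[c].sum() == counts[c] * cv.repeats


class TestApproachI:
    def test_high_adulteration_mixtures_all_flagged(self, separated_panel,
                                                    separated_sets):
        measured, twins, _ = separated_sets
        high = _focal(twins, "CH").query("adulteration_level >= 80")
        rep = run_approach_i(
            separated_panel, "CH", {"calculated": high},
            ModelSpec("oc_simca", {"alpha": 0.05},
                      PretreatmentSpec("log10")), seed=1)
        assert rep.extras["mixture_detection"]["calculated"] == 100.0

    def test_pure_lookalikes_flagged_at_about_alpha(self):
        # a large focal class, then fresh draws from its own distribution:
        # the false-alarm rate sits near alpha, far below mixture rates
        world = default_config(seed=41, country_separation=5.0,
                              analytic_cv=0.0,
                              samples_per_country={
                                  "DE": 10, "IT": 10, "CH": 200,
                                  "FR": 10, "CN": 10, "US": 10})
        panel = generate_pure_panel(world)
        rng = np.random.default_rng(12)
        logs = rng.multivariate_normal(
            world.log_mean.loc["CH"], world.log_cov, size=1000)
        fake = pd.DataFrame(10.0 ** logs, columns=list(ELEMENTS))
        fake[["country1", "country2", "percent_parent1"]] = ["CH", "CH", 50]
        fake[["parent1_id", "parent2_id"]] = ["x", "y"]
        fake["focal_country"] = "CH"
        rep = run_approach_i(
            panel, "CH", {"calculated": fake},
            ModelSpec("oc_simca", {"alpha": 0.10, "k": 3},
                      PretreatmentSpec("log10")), seed=1)
        rate = rep.extras["mixture_detection"]["calculated"]
        assert 1.0 < rate < 30.0

    def test_reports_both_provenances_and_acceptances(self,
                                                      separated_panel,
                                                      separated_sets):
        measured, twins, _ = separated_sets
        rep = run_approach_i(
            separated_panel, "CH",
            {"measured": _focal(measured, "CH"),
             "calculated": _focal(twins, "CH")},
            ModelSpec("oc_simca", pretreatment=PretreatmentSpec("log10")),
            seed=1)
        assert set(rep.extras["mixture_detection"]) == {"measured",
                                                        "calculated"}
        assert 0 <= rep.extras["pure_calibration_acceptance"] <= 100
        assert 0 <= rep.extras["pure_validation_acceptance"] <= 100

    def test_supervised_family_rejected(self, separated_panel,
                                        separated_sets):
        measured, _, _ = separated_sets
        with pytest.raises(ValueError, match="oc_simca or oc_svm"):
            run_approach_i(separated_panel, "CH",
                           {"measured": _focal(measured, "CH")}, SVM_LOG)


class TestApproachII:
    def test_fifty_fifty_mixtures_perfectly_separated(self,
                                                      separated_panel):
        calc = build_calculated_set(separated_panel)
        calc["provenance"] = "calculated"
        directed = expand_directed(calc)
        half = directed.query(
            "focal_country == 'CH' and adulteration_level == 50"
        ).sample(n=24, random_state=2)
        rep = run_approach_ii(separated_panel, "CH",
                              {"calculated": half}, SVM_AUTO, QUICK_CV)
        assert rep.overall_accuracy == pytest.approx(100.0)

    def test_null_world_scores_at_majority_share(self, null_panel,
                                                 null_world):
        measured, twins, _ = _directed_sets(null_panel, null_world)
        mix = _focal(measured, "CH")
        rep = run_approach_ii(null_panel, "CH", {"measured": mix},
                              SVM_RAW, QUICK_CV)
        n_pure = (null_panel["country"] == "CH").sum()
        share = max(n_pure, len(mix)) / (n_pure + len(mix))
        band = 2.576 * np.sqrt(share * (1 - share) / (n_pure + len(mix)))
        assert rep.overall_accuracy / 100 <= share + band

    def test_zero_noise_measured_matches_calculated_assignment(
            self, separated_panel, separated_sets):
        measured, twins, _ = separated_sets  # analytic_cv = 0
        sets = {"calculated": _focal(twins, "CH"),
                "measured": _focal(measured, "CH")}
        rep = run_approach_ii(separated_panel, "CH", sets, SVM_LOG,
                              QUICK_CV, variant="calc_train_measured_test")
        mirror = run_approach_ii(
            separated_panel, "CH",
            {"calculated": sets["calculated"],
             "measured": sets["calculated"]},
            SVM_LOG, QUICK_CV, variant="calc_train_measured_test")
        assert rep.extras["measured_assignment_rate"] == \
            mirror.extras["measured_assignment_rate"]

    def test_variant_needs_both_sets(self, separated_panel,
                                     separated_sets):
        measured, _, _ = separated_sets
        with pytest.raises(ValueError, match="calculated"):
            run_approach_ii(separated_panel, "CH",
                            {"measured": _focal(measured, "CH")},
                            SVM_LOG, QUICK_CV,
                            variant="calc_train_measured_test")


class TestApproachIII:
    def test_per_level_table_schema(self, separated_panel, separated_sets):
        measured, twins, _ = separated_sets
        rep = run_approach_iii(
            separated_panel, "CH",
            {"measured": _focal(measured, "CH"),
             "calculated": _focal(twins, "CH")},
            SVM_LOG, QUICK_CV, variant="per_level")
        assert rep.per_level["adulteration_level"].tolist() == list(
            range(10, 100, 10))
        assert "conformity" in rep.extras

    def test_constant_world_detects_levels_from_60(self, constant_panel,
                                                   constant_sets):
        mix = _focal(constant_sets["calc_all"], "AA")
        rep = run_approach_iii(constant_panel, "AA",
                               {"calculated": mix}, SVM_RAW,
                               CvScheme(folds=4, repeats=1, seed=2),
                               variant="per_level")
        tbl = rep.per_level.set_index("adulteration_level")
        assert (tbl.loc[60:, "accuracy_calculated"] == 100.0).all()

    def test_zero_noise_collapses_provenance_difference(
            self, separated_panel, separated_sets):
        measured, twins, _ = separated_sets  # cv = 0: same profiles
        rep = run_approach_iii(
            separated_panel, "CH",
            {"measured": _focal(measured, "CH"),
             "calculated": _focal(twins, "CH")},
            SVM_LOG, QUICK_CV, variant="per_level")
        assert (rep.per_level["difference_pct_pt"] == 0.0).all()
        assert rep.extras["conformity"] == pytest.approx(100.0)


class TestApproachIV:
    def test_training_set_disjoint_from_measured_twins(self,
                                                       constant_sets):
        calc = _focal(constant_sets["calc_all"], "AA")
        meas = _focal(constant_sets["measured"], "AA")
        rep = run_approach_iv(calc, meas,
                              ModelSpec("rf_classifier",
                                        {"n_estimators": 30}),
                              CvScheme(folds=5, repeats=1, seed=4))
        assert rep.extras["n_twins"] > 0
        assert rep.extras["n_train"] + rep.extras["n_twins"] == len(calc)
        keys_meas = set(_twin_key(meas))
        # reconstruct the training split and check disjointness
        train_keys = set(_twin_key(calc)) - keys_meas
        assert not (train_keys & keys_meas)

    def test_noiseless_twins_predicted_perfectly(self, constant_sets):
        calc = _focal(constant_sets["calc_all"], "AA")
        meas = _focal(constant_sets["measured"], "AA")
        rep = run_approach_iv(calc, meas,
                              ModelSpec("rf_classifier",
                                        {"n_estimators": 30}),
                              CvScheme(folds=5, repeats=1, seed=4))
        assert rep.extras["calculated_twin_accuracy"] == 100.0
        assert rep.extras["measured_accuracy"] == 100.0

    def test_shuffled_levels_score_at_one_in_nine(self, separated_panel):
        calc = build_calculated_set(separated_panel)
        calc["provenance"] = "calculated"
        directed = expand_directed(calc)
        mine = directed[directed["focal_country"] == "CH"].copy()
        rng = np.random.default_rng(13)
        mine["adulteration_level"] = rng.permutation(
            mine["adulteration_level"].to_numpy())
        meas = mine.sample(n=50, random_state=1)
        train = mine.drop(meas.index)
        rep = run_approach_iv(train, meas, ModelSpec("lda"),
                              CvScheme(folds=5, repeats=1, seed=6))
        p0 = 1.0 / 9.0
        band = 2.576 * np.sqrt(p0 * (1 - p0) / len(train))
        assert rep.overall_accuracy / 100 < p0 + band + 0.02


class TestApproachV:
    def test_noiseless_constant_world_rmse_below_one_point(
            self, constant_sets):
        calc = _focal(constant_sets["calc_all"], "AA")
        meas = _focal(constant_sets["measured"], "AA")
        rep = run_approach_v(calc, meas,
                             ModelSpec("plsr", {"n_components": 1}),
                             CvScheme(folds=5, repeats=1,
                                      stratified=False, seed=4))
        assert rep.regression["rmse"] < 1.0
        assert rep.extras["calculated_twins"]["rmse"] < 1.0
        assert rep.regression["r2"] > 0.99

    def test_rmse_invariant_to_row_order(self, constant_sets):
        calc = _focal(constant_sets["calc_all"], "AA")
        meas = _focal(constant_sets["measured"], "AA")
        spec = ModelSpec("plsr", {"n_components": 1})
        cv = CvScheme(folds=5, repeats=1, stratified=False, seed=4)
        a = run_approach_v(calc, meas, spec, cv)
        b = run_approach_v(calc, meas.iloc[::-1], spec, cv)
        assert a.regression["rmse"] == pytest.approx(
            b.regression["rmse"], rel=1e-9)

    def test_classifier_family_rejected(self, constant_sets):
        calc = _focal(constant_sets["calc_all"], "AA")
        meas = _focal(constant_sets["measured"], "AA")
        with pytest.raises(ValueError, match="regression family"):
            run_approach_v(calc, meas, SVM_RAW)
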