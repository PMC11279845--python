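"""The evaluation approaches for origin-mixture detection.

Six experiment designs over a pure-sample panel and its mixtures:

* ``baseline`` — six-class country classifier on pure samples (repeated
  CV), the reference point for everything else.
* ``I``   — one-class model (OC-SIMCA or OC-SVM) per country, trained on
  the country's pure samples; a mixture is detected when it is rejected
  as an outlier.
* ``II``  — two-class model, pure samples of one country vs. that
  country's mixtures; a second variant trains on calculated mixtures and
  predicts the measured ones as an independent test set.
* ``III`` — one-vs-rest model of a country's pure samples against all
  other countries' pure samples; a mixture is detected when assigned to
  the rest class.  A per-level variant scores each adulteration level
  individually.
* ``IV``  — nine-class adulteration-level classifier trained on the
  calculated mixture space (with the measured mixtures' calculated twins
  excluded from training to avoid overfitting).
* ``V``   — same design with regression on the level, scored by RMSE and
  R².

"Accuracy" for mixture test sets is the detection rate: the fraction of
mixtures given the approach's positive outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .mixtures import mixture_elements
from .models import (CvScheme, ModelRunResults, ModelSpec, build_estimator,
                     fit_predict_model, fit_simca)
from .pretreat import apply_pretreatment, fit_pretreatment
from .report import (confusion_and_accuracy, conformity, per_level_table)

__all__ = [
    "EvaluationReport",
    "run_baseline",
    "run_approach_i",
    "run_approach_ii",
    "run_approach_iii",
    "run_approach_iv",
    "run_approach_v",
]

_PURE, _MIX = "pure", "mixture"
_REST = "rest"


@dataclass
class EvaluationReport:
    """Results container shared by every approach.

    Scalar percentages are on the 0-100 scale.  ``extras`` carries the
    per-provenance breakdown; the scalar fields hold the primary view
    (measured provenance when both are supplied).
    """

    approach: str
    focal_country: str | None = None
    model_spec: dict | None = None
    cv: dict | None = None
    confusion: pd.DataFrame | None = None
    overall_accuracy: float | None = None
    sensitivity: pd.Series | None = None
    detection_rate: float | None = None
    per_level: pd.DataFrame | None = None
    regression: dict | None = None
    extras: dict = field(default_factory=dict)
    provenance_info: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"Approach {self.approach}"
                 + (f" — focal country {self.focal_country}"
                    if self.focal_country else ""),
                 "=" * 48]
        if self.model_spec:
            lines.append(f"model: {self.model_spec}")
        if self.overall_accuracy is not None:
            lines.append(f"overall accuracy: {self.overall_accuracy:.1f}%")
        if self.sensitivity is not None:
            for lab, v in self.sensitivity.items():
                lines.append(f"  sensitivity[{lab}]: {v:.1f}%")
        if self.detection_rate is not None:
            lines.append(f"mixture detection rate: "
                         f"{self.detection_rate:.1f}%")
        if self.regression:
            lines.append(
                f"RMSE: {self.regression['rmse']:.2f} %pt, "
                f"R2: {self.regression['r2']:.3f}")
        if self.per_level is not None:
            lines.append(self.per_level.to_string(index=False))
        for k, v in self.extras.items():
            if np.isscalar(v):
                lines.append(f"{k}: {v}")
        return "\n".join(lines)


def _primary(mixtures: dict[str, pd.DataFrame]) -> str:
    return "measured" if "measured" in mixtures else next(iter(mixtures))


def _check_focal(mixtures: pd.DataFrame, focal: str) -> None:
    if "focal_country" in mixtures.columns:
        if not (mixtures["focal_country"] == focal).all():
            raise ValueError(
                f"mixture set contains records whose focal country is "
                f"not {focal!r}")
    else:
        involved = ((mixtures["country1"] == focal)
                    | (mixtures["country2"] == focal))
        if not involved.all():
            raise ValueError(
                f"mixture set contains records not involving {focal!r}")


# ---------------------------------------------------------------------
# baseline and approach III share one one-vs-rest / multi-class trainer
# ---------------------------------------------------------------------

def _classify_pure(panel: pd.DataFrame, labels: pd.Series,
                   model: ModelSpec, cv: CvScheme,
                   test: pd.DataFrame | None,
                   elements: list[str]) -> ModelRunResults:
    return fit_predict_model(model, panel, labels, cv,
                             test=test, elements=elements)


def run_baseline(panel: pd.DataFrame, model: ModelSpec,
                 cv: CvScheme | None = None,
                 provenance_info: dict | None = None) -> EvaluationReport:
    """Six-class (one label per country) repeated-CV baseline."""
    cv = cv or CvScheme(folds=5, repeats=5)
    if panel["country"].nunique() < 2:
        raise ValueError("baseline needs at least two countries")
    elements = mixture_elements(panel)
    res = _classify_pure(panel, panel["country"], model, cv, None, elements)
    conf, _, sens = confusion_and_accuracy(
        res.cv_true, res.cv_pred, labels=sorted(panel["country"].unique()))
    return EvaluationReport(
        approach="baseline", model_spec=model.to_dict(), cv=cv.to_dict(),
        confusion=conf, overall_accuracy=res.cv_accuracy, sensitivity=sens,
        provenance_info=provenance_info or {},
    )


# ---------------------------------------------------------------------
# approach I — one-class models
# ---------------------------------------------------------------------

def run_approach_i(panel: pd.DataFrame, focal_country: str,
                   mixtures: dict[str, pd.DataFrame],
                   model: ModelSpec,
                   folds: int = 4, seed: int = 0,
                   provenance_info: dict | None = None) -> EvaluationReport:
    """One-class model on the focal country's pure samples.

    Reports pure-sample acceptance under calibration (resubstitution)
    and validation (k-fold CV, 4 folds by default), and the outlier
    (= detection) rate of the supplied mixtures per provenance.
    """
    if model.family not in ("oc_simca", "oc_svm"):
        raise ValueError("approach I needs an oc_simca or oc_svm model")
    pure = panel[panel["country"] == focal_country]
    if len(pure) < folds:
        raise ValueError(
            f"{focal_country} has {len(pure)} pure samples, fewer than "
            f"{folds} folds")
    elements = mixture_elements(panel)
    for prov, mx in mixtures.items():
        _check_focal(mx, focal_country)

    hp = dict(model.hyperparameters)

    def _fit(train: pd.DataFrame):
        if model.family == "oc_simca":
            m = fit_simca(train, k=hp.get("k"), alpha=hp.get("alpha", 0.05),
                          pretreatment=model.pretreatment,
                          elements=elements)
            return m, lambda df: m.predict(df)["member"].to_numpy()
        pre = fit_pretreatment(train, model.pretreatment, elements)
        est = build_estimator(model, seed=seed)
        est.fit(apply_pretreatment(pre, train).to_numpy(dtype=float))
        return (pre, est), lambda df: (
            est.predict(apply_pretreatment(pre, df)
                        .to_numpy(dtype=float)) == 1)

    full_model, accept = _fit(pure)
    calib = 100.0 * float(np.mean(accept(pure)))

    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    held = []
    for tr, te in splitter.split(pure):
        _, acc = _fit(pure.iloc[tr])
        held.append(acc(pure.iloc[te]))
    valid = 100.0 * float(np.mean(np.concatenate(held)))

    detection = {}
    for prov, mx in mixtures.items():
        detection[prov] = 100.0 * float(np.mean(~accept(mx)))

    primary = _primary(mixtures) if mixtures else None
    return EvaluationReport(
        approach="I", focal_country=focal_country,
        model_spec=model.to_dict(),
        detection_rate=detection.get(primary),
        extras={
            "pure_calibration_acceptance": calib,
            "pure_validation_acceptance": valid,
            "mixture_detection": detection,
        },
        provenance_info=provenance_info or {},
    )


# ---------------------------------------------------------------------
# approach II — pure vs. own mixtures
# ---------------------------------------------------------------------

def run_approach_ii(panel: pd.DataFrame, focal_country: str,
                    mixtures: dict[str, pd.DataFrame],
                    model: ModelSpec, cv: CvScheme | None = None,
                    variant: str = "direct",
                    provenance_info: dict | None = None) -> EvaluationReport:
    """Two-class model: pure focal-country samples vs. its mixtures."""
    if variant not in ("direct", "calc_train_measured_test"):
        raise ValueError(f"unknown approach II variant {variant!r}")
    cv = cv or CvScheme(folds=5, repeats=5)
    pure = panel[panel["country"] == focal_country]
    if len(pure) == 0:
        raise ValueError(f"no pure samples for {focal_country!r}")
    elements = mixture_elements(panel)
    for mx in mixtures.values():
        _check_focal(mx, focal_country)

    report = EvaluationReport(
        approach="II", focal_country=focal_country,
        model_spec=model.to_dict(), cv=cv.to_dict(),
        extras={"variant": variant},
        provenance_info=provenance_info or {},
    )

    if variant == "direct":
        acc, confs, senss = {}, {}, {}
        for prov, mx in mixtures.items():
            if len(mx) == 0:
                raise ValueError(f"empty {prov} mixture set")
            X = pd.concat([pure[elements], mx[elements]],
                          ignore_index=True)
            y = pd.Series([_PURE] * len(pure) + [_MIX] * len(mx))
            res = fit_predict_model(model, X, y, cv, elements=elements)
            conf, overall, sens = confusion_and_accuracy(
                res.cv_true, res.cv_pred, labels=[_PURE, _MIX])
            acc[prov] = res.cv_accuracy
            confs[prov], senss[prov] = conf, sens
        primary = _primary(mixtures)
        report.overall_accuracy = acc[primary]
        report.confusion = confs[primary]
        report.sensitivity = senss[primary]
        report.extras.update(accuracy=acc, confusion=confs,
                             sensitivity=senss)
        return report

    # calc_train_measured_test
    if "calculated" not in mixtures or "measured" not in mixtures:
        raise ValueError(
            "variant calc_train_measured_test needs both 'calculated' "
            "and 'measured' mixture sets")
    calc, meas = mixtures["calculated"], mixtures["measured"]
    X = pd.concat([pure[elements], calc[elements]], ignore_index=True)
    y = pd.Series([_PURE] * len(pure) + [_MIX] * len(calc))
    res = fit_predict_model(model, X, y, cv, test=meas, elements=elements)
    assigned = res.test_pred.to_numpy()
    rate = 100.0 * float(np.mean(assigned == _MIX))
    report.overall_accuracy = rate
    report.detection_rate = rate
    report.extras.update(
        train_cv_accuracy=res.cv_accuracy,
        measured_assignment_rate=rate,
    )
    return report


# ---------------------------------------------------------------------
# approach III — one country vs. all others
# ---------------------------------------------------------------------

def run_approach_iii(panel: pd.DataFrame, focal_country: str,
                     mixtures: dict[str, pd.DataFrame],
                     model: ModelSpec, cv: CvScheme | None = None,
                     variant: str = "all_levels",
                     provenance_info: dict | None = None
                     ) -> EvaluationReport:
    """One-vs-rest model on pure samples; mixtures scored as test sets.

    A mixture counts as detected when it is assigned to the rest class.
    ``per_level`` scores each adulteration level individually and adds
    the calculated-vs-measured %pt difference column.
    """
    if variant not in ("all_levels", "per_level"):
        raise ValueError(f"unknown approach III variant {variant!r}")
    cv = cv or CvScheme(folds=5, repeats=5)
    countries = panel["country"].unique()
    if focal_country not in countries or len(countries) < 2:
        raise ValueError(
            f"need {focal_country!r} plus at least one other country")
    elements = mixture_elements(panel)
    for mx in mixtures.values():
        _check_focal(mx, focal_country)

    y = pd.Series(np.where(panel["country"] == focal_country,
                           focal_country, _REST))
    test = (pd.concat([m[elements] for m in mixtures.values()],
                      ignore_index=True) if mixtures else None)
    res = _classify_pure(panel, y, model, cv, test, elements)
    conf, _, sens = confusion_and_accuracy(
        res.cv_true, res.cv_pred, labels=[focal_country, _REST])

    report = EvaluationReport(
        approach="III", focal_country=focal_country,
        model_spec=model.to_dict(), cv=cv.to_dict(),
        confusion=conf, overall_accuracy=res.cv_accuracy,
        sensitivity=sens,
        extras={"variant": variant},
        provenance_info=provenance_info or {},
    )
    if not mixtures:
        return report

    # slice pooled test predictions back per provenance
    offsets, detected = 0, {}
    for prov, mx in mixtures.items():
        pred = res.test_pred.to_numpy()[offsets:offsets + len(mx)]
        offsets += len(mx)
        detected[prov] = pd.Series(pred == _REST,
                                   index=mx.index)
    rates = {prov: 100.0 * float(d.mean())
             for prov, d in detected.items()}
    primary = _primary(mixtures)
    report.detection_rate = rates[primary]
    report.extras["detection"] = rates

    if variant == "per_level":
        levels = sorted(
            {int(lv) for mx in mixtures.values()
             for lv in mx["adulteration_level"].unique()})
        per_prov = {}
        for prov, mx in mixtures.items():
            g = detected[prov].groupby(
                mx["adulteration_level"].to_numpy()).mean() * 100.0
            per_prov[prov] = g
        tbl = per_level_table(levels, per_prov.get("measured"),
                              per_prov.get("calculated"))
        report.per_level = tbl
        if len(per_prov) == 2:
            report.extras["conformity"] = conformity(tbl)
    return report


# ---------------------------------------------------------------------
# approaches IV and V — models on the calculated mixture space
# ---------------------------------------------------------------------

def _twin_key(df: pd.DataFrame) -> pd.Series:
    """Canonical (unordered parent pair, oriented ratio) identity."""
    a, b = df["parent1_id"], df["parent2_id"]
    pct = df["percent_parent1"].astype(int)
    first = a.where(a < b, b)
    second = b.where(a < b, a)
    opct = pct.where(a < b, 100 - pct)
    return first + "|" + second + "|" + opct.astype(str)


def _split_training(calculated: pd.DataFrame, measured: pd.DataFrame):
    keys_meas = set(_twin_key(measured))
    is_twin = _twin_key(calculated).isin(keys_meas)
    train = calculated[~is_twin]
    twins = calculated[is_twin]
    if len(train) == 0:
        raise ValueError(
            "every calculated mixture is a twin of a measured one; "
            "nothing left to train on")
    return train, twins


def _level_accuracy(true_levels: np.ndarray,
                    pred: np.ndarray) -> pd.Series:
    ok = pd.Series(pred == true_levels)
    return ok.groupby(true_levels).mean() * 100.0


def run_approach_iv(calculated_mixtures: pd.DataFrame,
                    measured_mixtures: pd.DataFrame,
                    model: ModelSpec, cv: CvScheme | None = None,
                    provenance_info: dict | None = None
                    ) -> EvaluationReport:
    """Nine-class adulteration-level classifier on calculated mixtures.

    Calculated twins of the measured mixtures (same parent pair, same
    ratio) are excluded from training and scored as their own held-out
    test set.
    """
    cv = cv or CvScheme(folds=10, repeats=5)
    train, twins = _split_training(calculated_mixtures, measured_mixtures)
    elements = mixture_elements(calculated_mixtures)
    y = train["adulteration_level"].astype(int)
    counts = y.value_counts()
    if (counts < 1).any() or y.nunique() < 2:
        raise ValueError("a training class (adulteration level) is empty")

    test = pd.concat([measured_mixtures[elements], twins[elements]],
                     ignore_index=True)
    res = fit_predict_model(model, train, y, cv, test=test,
                            elements=elements)
    n_meas = len(measured_mixtures)
    pred_meas = res.test_pred.to_numpy()[:n_meas].astype(int)
    pred_twin = res.test_pred.to_numpy()[n_meas:].astype(int)
    lv_meas = measured_mixtures["adulteration_level"].to_numpy(int)
    lv_twin = twins["adulteration_level"].to_numpy(int)

    acc_meas = _level_accuracy(lv_meas, pred_meas)
    acc_twin = _level_accuracy(lv_twin, pred_twin)
    levels = sorted(set(lv_meas) | set(lv_twin))
    tbl = per_level_table(levels, acc_meas, acc_twin)
    return EvaluationReport(
        approach="IV",
        focal_country=(measured_mixtures["focal_country"].iloc[0]
                       if "focal_country" in measured_mixtures else None),
        model_spec=model.to_dict(), cv=cv.to_dict(),
        overall_accuracy=res.cv_accuracy, per_level=tbl,
        extras={
            "measured_accuracy": 100.0 * float(
                np.mean(pred_meas == lv_meas)),
            "calculated_twin_accuracy": (
                100.0 * float(np.mean(pred_twin == lv_twin))
                if len(lv_twin) else float("nan")),
            "n_train": len(train), "n_twins": len(twins),
        },
        provenance_info=provenance_info or {},
    )


def run_approach_v(calculated_mixtures: pd.DataFrame,
                   measured_mixtures: pd.DataFrame,
                   model: ModelSpec, cv: CvScheme | None = None,
                   provenance_info: dict | None = None) -> EvaluationReport:
    """Adulteration-level regression on calculated mixtures.

    Same exclusion design as approach IV; predictions are numeric levels
    in [10, 90], scored by RMSE (%pt) and R² on the measured set and on
    the held-out calculated twins.
    """
    if model.family not in ("svr", "plsr", "rf_regressor"):
        raise ValueError("approach V needs a regression family")
    cv = cv or CvScheme(folds=10, repeats=5, stratified=False)
    train, twins = _split_training(calculated_mixtures, measured_mixtures)
    elements = mixture_elements(calculated_mixtures)
    y = train["adulteration_level"].astype(float)

    test = pd.concat([measured_mixtures[elements], twins[elements]],
                     ignore_index=True)
    res = fit_predict_model(model, train, y, cv, test=test,
                            elements=elements)
    n_meas = len(measured_mixtures)

    def _metrics(pred, true):
        err = pred - true
        rmse = float(np.sqrt(np.mean(err ** 2)))
        ss_tot = float(np.sum((true - true.mean()) ** 2))
        r2 = (1.0 - float(np.sum(err ** 2)) / ss_tot
              if ss_tot > 0 else np.nan)
        return {"rmse": rmse, "r2": r2}

    pred = res.test_pred.to_numpy(dtype=float)
    m_meas = _metrics(pred[:n_meas],
                      measured_mixtures["adulteration_level"]
                      .to_numpy(float))
    m_twin = _metrics(pred[n_meas:],
                      twins["adulteration_level"].to_numpy(float))
    return EvaluationReport(
        approach="V",
        focal_country=(measured_mixtures["focal_country"].iloc[0]
                       if "focal_country" in measured_mixtures else None),
        model_spec=model.to_dict(), cv=cv.to_dict(),
        regression=m_meas,
        extras={
            "measured": m_meas, "calculated_twins": m_twin,
            "cv_rmse": res.cv_rmse, "cv_r2": res.cv_r2,
            "n_train": len(train), "n_twins": len(twins),
        },
        provenance_info=provenance_info or {},
    )
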