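"""Chemometric model menu: one-class SIMCA plus standard adapters.

SIMCA (soft independent modelling of class analogies) is authored here:
a per-class PCA model judging membership by two statistics — the score
distance (Mahalanobis-type, within the component subspace) and the
orthogonal distance (squared residual norm) — against chi-squared
critical limits with moment-matched degrees of freedom.

The supervised families (radial SVM, LDA, random forest, SVR, PLSR,
random-forest regression) and one-class SVM are thin adapters over
scikit-learn, run under repeated (stratified) k-fold cross-validation
with pretreatments fitted inside each training fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.base import clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import (RepeatedKFold, RepeatedStratifiedKFold)
from sklearn.svm import SVC, SVR, OneClassSVM

from .pretreat import (FittedPretreatment, PretreatmentSpec,
                       apply_pretreatment, fit_pretreatment)

__all__ = [
    "CLASSIFIER_FAMILIES",
    "REGRESSOR_FAMILIES",
    "ONE_CLASS_FAMILIES",
    "ModelSpec",
    "CvScheme",
    "SIMCA",
    "SIMCAResults",
    "fit_simca",
    "simca_classify",
    "build_estimator",
    "fit_predict_model",
    "ModelRunResults",
]

ONE_CLASS_FAMILIES = ("oc_svm", "oc_simca")
CLASSIFIER_FAMILIES = ("svm_radial", "lda", "rf_classifier")
REGRESSOR_FAMILIES = ("svr", "plsr", "rf_regressor")
_ALL_FAMILIES = ONE_CLASS_FAMILIES + CLASSIFIER_FAMILIES + REGRESSOR_FAMILIES


@dataclass(frozen=True)
class ModelSpec:
    """A model family with its hyperparameters and pretreatment."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    pretreatment: PretreatmentSpec = field(
        default_factory=lambda: PretreatmentSpec("none"))

    def __post_init__(self):
        if self.family not in _ALL_FAMILIES:
            raise ValueError(
                f"unknown model family {self.family!r}; "
                f"choose from {_ALL_FAMILIES}"
            )

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "hyperparameters": dict(self.hyperparameters),
            "pretreatment": self.pretreatment.method,
        }


@dataclass(frozen=True)
class CvScheme:
    """Repeated k-fold cross-validation settings."""

    folds: int = 5
    repeats: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    def to_dict(self) -> dict:
        return {"folds": self.folds, "repeats": self.repeats,
                "stratified": self.stratified, "seed": self.seed}


# ---------------------------------------------------------------------
# SIMCA
# ---------------------------------------------------------------------

class SIMCA:
    """One-class SIMCA model for a single class of profiles.

    Parameters
    ----------
    train
        Training profiles of the modelled class (rows = samples).
    n_components
        Number of principal components ``k``; default: smallest ``k``
        explaining at least 90% of the pretreated variance.
    alpha
        Significance level of the acceptance region: a fraction of
        roughly ``1 - alpha`` of in-class observations is accepted.
    pretreatment
        Pretreatment spec fitted on the training data.
    elements
        Feature columns; default: all columns of ``train``.
    """

    def __init__(self, train: pd.DataFrame,
                 n_components: int | None = None,
                 alpha: float = 0.05,
                 pretreatment: PretreatmentSpec | None = None,
                 elements: list[str] | None = None):
        self.train = train
        self.n_components = n_components
        self.alpha = float(alpha)
        self.pretreatment = pretreatment or PretreatmentSpec("none")
        self.elements = list(elements or train.columns)

    def fit(self) -> "SIMCAResults":
        fitted_pre = fit_pretreatment(self.train, self.pretreatment,
                                      self.elements)
        X = apply_pretreatment(fitted_pre, self.train).to_numpy(dtype=float)
        n, p = X.shape
        mean = X.mean(axis=0)
        Xc = X - mean
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        tol = s.max() * max(n, p) * np.finfo(float).eps if s.size else 0.0
        rank = int((s > tol).sum())
        var = s ** 2 / max(n - 1, 1)
        if self.n_components is None:
            frac = np.cumsum(var) / var.sum()
            k = int(np.searchsorted(frac, 0.90) + 1)
            k = min(k, max(rank - 1, 1))
        else:
            k = int(self.n_components)
        if k < 1:
            raise ValueError("n_components must be >= 1")
        if k >= n:
            raise ValueError(
                f"n_components={k} too large for {n} training rows")
        if k > rank:
            raise ValueError(
                f"n_components={k} exceeds the data rank {rank}; "
                "use a smaller k"
            )
        loadings = Vt[:k].T            # (p, k), orthonormal columns
        score_var = var[:k]            # per-component score variances
        sd, od = _distances(Xc, loadings, score_var)
        sd_crit, sd_dof = _chi2_limit(sd, self.alpha)
        od_crit, od_dof = _chi2_limit(od, self.alpha)
        return SIMCAResults(
            fitted_pretreatment=fitted_pre, mean=mean,
            loadings=loadings, score_var=score_var,
            n_components=k, alpha=self.alpha,
            sd_crit=sd_crit, od_crit=od_crit,
            sd_dof=sd_dof, od_dof=od_dof,
            train_sd=sd, train_od=od, n_train=n,
            elements=self.elements,
        )


def _distances(Xc: np.ndarray, loadings: np.ndarray,
               score_var: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    T = Xc @ loadings
    sd = np.square(T / np.sqrt(score_var)).sum(axis=1)
    resid = Xc - T @ loadings.T
    od = np.square(resid).sum(axis=1)
    return sd, od


def _chi2_limit(dist: np.ndarray, alpha: float,
                tiny: float = 1e-12) -> tuple[float, float]:
    """Chi-squared critical limit with moment-matched degrees of freedom.

    Each of the two distances gets a per-distance level of
    ``sqrt(1 - alpha)`` so that the joint acceptance (score distance and
    orthogonal distance both inside) is approximately ``1 - alpha`` —
    the two statistics are independent under the PCA model.
    """
    m = float(dist.mean())
    if m < tiny:  # degenerate direction (e.g. exact low-rank data)
        return tiny, 1.0
    v = float(dist.var(ddof=1)) if dist.size > 1 else m ** 2
    dof = max(2.0 * m ** 2 / v, 0.1) if v > 0 else 1.0
    level = np.sqrt(1.0 - alpha)
    return m / dof * chi2.ppf(level, dof), dof


@dataclass
class SIMCAResults:
    """Fitted SIMCA model: PCA geometry, distances and critical limits."""

    fitted_pretreatment: FittedPretreatment
    mean: np.ndarray
    loadings: np.ndarray
    score_var: np.ndarray
    n_components: int
    alpha: float
    sd_crit: float
    od_crit: float
    sd_dof: float
    od_dof: float
    train_sd: np.ndarray
    train_od: np.ndarray
    n_train: int
    elements: list[str] = field(default_factory=list)

    def predict(self, data: pd.DataFrame) -> pd.DataFrame:
        """Classify rows as members/outliers with both distances."""
        X = apply_pretreatment(self.fitted_pretreatment,
                               data).to_numpy(dtype=float)
        sd, od = _distances(X - self.mean, self.loadings, self.score_var)
        member = (sd <= self.sd_crit) & (od <= self.od_crit)
        return pd.DataFrame({
            "member": member,
            "score_distance": sd,
            "orthogonal_distance": od,
        }, index=data.index)

    def summary(self) -> str:
        lines = [
            "One-class SIMCA model",
            "=" * 42,
            f"training rows        : {self.n_train}",
            f"components (k)       : {self.n_components}",
            f"alpha                : {self.alpha:g}",
            f"pretreatment         : {self.fitted_pretreatment.method}",
            f"score-distance limit : {self.sd_crit:.4g} "
            f"(dof {self.sd_dof:.2f})",
            f"orth-distance limit  : {self.od_crit:.4g} "
            f"(dof {self.od_dof:.2f})",
            "explained variance   : "
            + ", ".join(f"{v:.3g}" for v in self.score_var),
        ]
        return "\n".join(lines)


def fit_simca(train: pd.DataFrame, k: int | None = None,
              alpha: float = 0.05,
              pretreatment: PretreatmentSpec | None = None,
              elements: list[str] | None = None) -> SIMCAResults:
    """Functional wrapper: fit a one-class SIMCA model."""
    return SIMCA(train, n_components=k, alpha=alpha,
                 pretreatment=pretreatment, elements=elements).fit()


def simca_classify(model: SIMCAResults, data: pd.DataFrame) -> pd.DataFrame:
    """Functional wrapper around :meth:`SIMCAResults.predict`."""
    return model.predict(data)


# ---------------------------------------------------------------------
# scikit-learn adapters
# ---------------------------------------------------------------------

def build_estimator(spec: ModelSpec, seed: int = 0):
    """Instantiate the scikit-learn estimator for a model spec."""
    hp = dict(spec.hyperparameters)
    fam = spec.family
    if fam == "oc_svm":
        return OneClassSVM(kernel=hp.pop("kernel", "rbf"),
                           nu=hp.pop("nu", 0.05),
                           gamma=hp.pop("gamma", "scale"), **hp)
    if fam == "svm_radial":
        return SVC(kernel="rbf", C=hp.pop("C", 1.0),
                   gamma=hp.pop("gamma", "scale"),
                   random_state=seed, **hp)
    if fam == "lda":
        return LinearDiscriminantAnalysis(**hp)
    if fam == "rf_classifier":
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 500),
            max_features=hp.pop("max_features", "sqrt"),
            random_state=seed, **hp)
    if fam == "svr":
        return SVR(kernel=hp.pop("kernel", "rbf"), C=hp.pop("C", 1.0),
                   **hp)
    if fam == "plsr":
        return PLSRegression(
            n_components=hp.pop("n_components", 5), **hp)
    if fam == "rf_regressor":
        return RandomForestRegressor(
            n_estimators=hp.pop("n_estimators", 500),
            max_features=hp.pop("max_features", "sqrt"),
            random_state=seed, **hp)
    raise ValueError(f"{fam!r} has no scikit-learn adapter")


@dataclass
class ModelRunResults:
    """Results of a cross-validated model run.

    ``cv_true``/``cv_pred`` pool the out-of-fold labels over all
    folds x repeats; scalar metrics average the per-fold values.
    """

    spec: ModelSpec
    cv: CvScheme
    task: str                      # "classification" | "regression"
    cv_true: np.ndarray
    cv_pred: np.ndarray
    cv_fold_scores: list[float]
    cv_accuracy: float | None = None
    cv_rmse: float | None = None
    cv_r2: float | None = None
    test_pred: pd.Series | None = None

    def summary(self) -> str:
        lines = [
            f"{self.spec.family} ({self.task}), "
            f"pretreatment={self.spec.pretreatment.method}",
            f"CV: {self.cv.folds} folds x {self.cv.repeats} repeats"
            + (" (stratified)" if self.cv.stratified else ""),
        ]
        if self.task == "classification":
            lines.append(f"CV accuracy: {self.cv_accuracy:.1f}%")
        else:
            lines.append(f"CV RMSE: {self.cv_rmse:.2f} %pt, "
                         f"R2: {self.cv_r2:.3f}")
        return "\n".join(lines)


def _is_regressor(family: str) -> bool:
    return family in REGRESSOR_FAMILIES


def fit_predict_model(spec: ModelSpec,
                      train: pd.DataFrame,
                      labels: pd.Series,
                      cv: CvScheme,
                      test: pd.DataFrame | None = None,
                      elements: list[str] | None = None) -> ModelRunResults:
    """Cross-validate a supervised model and optionally predict a test set.

    The pretreatment is fitted inside each training fold (and once on the
    full training set for the test-set prediction), so held-out rows never
    influence the fitted statistics.  Deterministic for a fixed
    ``cv.seed``.
    """
    if spec.family in ONE_CLASS_FAMILIES:
        raise ValueError(
            f"{spec.family} is a one-class family; use fit_simca / "
            "build_estimator directly"
        )
    if elements is None:
        elements = list(train.columns)
    regression = _is_regressor(spec.family)
    y = labels.to_numpy()
    if not regression and len(np.unique(y)) < 2:
        raise ValueError(
            "training labels contain a single class; a two-class "
            "classifier needs at least two"
        )
    X = train[elements]
    if cv.stratified and not regression:
        splitter = RepeatedStratifiedKFold(
            n_splits=cv.folds, n_repeats=cv.repeats, random_state=cv.seed)
    else:
        splitter = RepeatedKFold(
            n_splits=cv.folds, n_repeats=cv.repeats, random_state=cv.seed)

    fold_scores, trues, preds = [], [], []
    for i, (tr, te) in enumerate(splitter.split(X, None if regression
                                                else y)):
        pre = fit_pretreatment(X.iloc[tr], spec.pretreatment, elements)
        est = build_estimator(spec, seed=cv.seed + 1000 + i)
        Xtr = apply_pretreatment(pre, X.iloc[tr]).to_numpy(dtype=float)
        Xte = apply_pretreatment(pre, X.iloc[te]).to_numpy(dtype=float)
        est.fit(Xtr, y[tr])
        p = np.asarray(est.predict(Xte)).ravel()
        trues.append(y[te])
        preds.append(p)
        if regression:
            fold_scores.append(float(np.sqrt(np.mean((p - y[te]) ** 2))))
        else:
            fold_scores.append(float(np.mean(p == y[te])))

    cv_true = np.concatenate(trues)
    cv_pred = np.concatenate(preds)
    res = ModelRunResults(
        spec=spec, cv=cv,
        task="regression" if regression else "classification",
        cv_true=cv_true, cv_pred=cv_pred, cv_fold_scores=fold_scores,
    )
    if regression:
        res.cv_rmse = float(np.mean(fold_scores))
        ss_res = float(np.sum((cv_pred - cv_true.astype(float)) ** 2))
        ss_tot = float(np.sum((cv_true.astype(float)
                               - cv_true.astype(float).mean()) ** 2))
        res.cv_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    else:
        res.cv_accuracy = 100.0 * float(np.mean(fold_scores))

    if test is not None:
        pre = fit_pretreatment(X, spec.pretreatment, elements)
        est = build_estimator(spec, seed=cv.seed + 999)
        est.fit(apply_pretreatment(pre, X).to_numpy(dtype=float), y)
        p = np.asarray(
            est.predict(apply_pretreatment(pre, test[elements])
                        .to_numpy(dtype=float))).ravel()
        res.test_pred = pd.Series(p, index=test.index)
    return res
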