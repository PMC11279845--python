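"""Column-wise data pretreatments, fitted on training data only.

Four methods: ``none``, ``log10`` (decadic logarithm), ``autoscale``
(mean centre, sample-SD scale) and ``robust`` (median centre, IQR scale).
A fitted pretreatment freezes the training statistics, so applying it to
test data never touches the test distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "METHODS",
    "PretreatmentSpec",
    "FittedPretreatment",
    "fit_pretreatment",
    "apply_pretreatment",
    "inverse_pretreatment",
]

METHODS = ("none", "log10", "autoscale", "robust")


@dataclass(frozen=True)
class PretreatmentSpec:
    """Which transform to use; parameters are fitted later."""

    method: str = "none"

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(
                f"unknown pretreatment {self.method!r}; choose from {METHODS}"
            )


@dataclass
class FittedPretreatment:
    """A pretreatment with its training statistics frozen.

    ``center``/``scale`` are per-element Series for the scaling methods;
    ``log_floor`` is the per-element floor used by ``log10`` (half the
    smallest positive training value) so that zeros in later data do not
    produce -inf.
    """

    method: str
    elements: list[str]
    center: pd.Series | None = None
    scale: pd.Series | None = None
    log_floor: pd.Series | None = None

    def to_dict(self) -> dict:
        d: dict = {"method": self.method, "elements": list(self.elements)}
        for name in ("center", "scale", "log_floor"):
            s = getattr(self, name)
            if s is not None:
                d[name] = {k: float(v) for k, v in s.items()}
        return d


def _iqr(col: np.ndarray) -> float:
    # linear interpolation between order statistics (numpy default)
    q75, q25 = np.percentile(col, [75, 25])
    return q75 - q25


def fit_pretreatment(train: pd.DataFrame,
                     spec: PretreatmentSpec,
                     elements: list[str] | None = None) -> FittedPretreatment:
    """Fit a pretreatment on training profiles.

    autoscale: centre = column mean, scale = sample (n-1) SD.
    robust: centre = column median, scale = IQR (linear-interpolation
    quantiles).  A zero scale means a degenerate column and is an error
    naming the element.
    """
    if elements is None:
        elements = list(train.columns)
    X = train[elements]
    m = spec.method
    if m == "none":
        return FittedPretreatment(m, list(elements))
    if m == "log10":
        pos = X.where(X > 0)
        floor = pos.min() / 2.0
        floor = floor.fillna(np.finfo(float).tiny)
        return FittedPretreatment(m, list(elements), log_floor=floor)
    if len(X) < 2:
        raise ValueError(f"{m} pretreatment needs >= 2 training rows")
    if m == "autoscale":
        center = X.mean()
        scale = X.std(ddof=1)
    else:  # robust
        center = X.median()
        scale = pd.Series({e: _iqr(X[e].to_numpy(dtype=float))
                           for e in elements})
    bad = scale.index[scale <= 0].tolist()
    if bad:
        raise ValueError(
            f"degenerate (zero-spread) columns under {m!r}: {bad}"
        )
    return FittedPretreatment(m, list(elements), center=center, scale=scale)


def apply_pretreatment(fitted: FittedPretreatment,
                       data: pd.DataFrame) -> pd.DataFrame:
    """Apply a fitted pretreatment to (training or new) profiles."""
    missing = [e for e in fitted.elements if e not in data.columns]
    if missing:
        raise ValueError(f"data is missing element columns: {missing}")
    X = data[fitted.elements].astype(float)
    if fitted.method == "none":
        return X.copy()
    if fitted.method == "log10":
        return np.log10(X.clip(lower=fitted.log_floor, axis=1))
    return (X - fitted.center) / fitted.scale


def inverse_pretreatment(fitted: FittedPretreatment,
                         data: pd.DataFrame) -> pd.DataFrame:
    """Undo a pretreatment (exact away from the log floor region)."""
    X = data[fitted.elements].astype(float)
    if fitted.method == "none":
        return X.copy()
    if fitted.method == "log10":
        return pd.DataFrame(10.0 ** X, columns=fitted.elements,
                            index=data.index)
    return X * fitted.scale + fitted.center
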