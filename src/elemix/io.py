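"""File formats, configuration, seed derivation, and the
signal-to-concentration quantitation helper.

CSV dialect is fixed: comma separator, period decimal, UTF-8, header row
mandatory.  Profile units are mg/kg; mg/L appears only inside the
quantitation step (solution concentrations).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mixtures import MIX_META_COLUMNS
from .world import ELEMENTS, WorldConfig, validate_panel

__all__ = [
    "read_panel",
    "write_panel",
    "read_mixtures",
    "write_mixtures",
    "load_world_config",
    "save_world_config",
    "CalibrationCurve",
    "quantify_from_signals",
    "derive_seed",
    "config_hash",
]

_PANEL_META = ("sample_id", "country", "harvest_year")


def write_panel(panel: pd.DataFrame, path: str | Path,
                elements=ELEMENTS) -> None:
    """Write a pure-sample panel as wide CSV (schema-checked first)."""
    validate_panel(panel, elements)
    cols = list(_PANEL_META) + list(elements)
    panel[cols].to_csv(path, index=False, encoding="utf-8")


def read_panel(path: str | Path, elements=ELEMENTS) -> pd.DataFrame:
    """Read a wide-CSV panel, rejecting schema deviations loudly."""
    df = pd.read_csv(path, encoding="utf-8")
    expected = list(_PANEL_META) + list(elements)
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise ValueError(f"{path}: unknown columns {unknown}")
    if df["sample_id"].duplicated().any():
        dup = sorted(set(df.loc[df["sample_id"].duplicated(), "sample_id"]))
        raise ValueError(f"{path}: duplicate sample ids {dup}")
    for e in elements:
        col = pd.to_numeric(df[e], errors="coerce")
        if col.isna().any():
            row = int(df.index[col.isna()][0])
            raise ValueError(
                f"{path}: non-numeric value in column {e!r}, row {row}")
        df[e] = col
    validate_panel(df, elements)
    return df[expected]


def write_mixtures(records: pd.DataFrame, path: str | Path) -> None:
    """Write a mixture-record table as CSV."""
    records.to_csv(path, index=False, encoding="utf-8")


def read_mixtures(path: str | Path, elements=ELEMENTS) -> pd.DataFrame:
    """Read a mixture-record table, checking the schema."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in MIX_META_COLUMNS if c not in df.columns]
    missing += [e for e in elements if e not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def save_world_config(config: WorldConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_world_config(path: str | Path) -> WorldConfig:
    with open(path, encoding="utf-8") as fh:
        return WorldConfig.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------
# quantitation: raw signals -> mg/kg
# ---------------------------------------------------------------------

@dataclass
class CalibrationCurve:
    """External calibration for one element.

    ``points`` maps standard concentration (mg/L) to the blank-corrected,
    internal-standard-normalised signal ratio.  ``volume_ml`` and
    ``mass_g`` convert the solution concentration back to a mass
    fraction of the digested sample.
    """

    element: str
    points: list[tuple[float, float]]
    volume_ml: float
    mass_g: float

    def __post_init__(self):
        if len(self.points) < 2:
            raise ValueError("calibration needs at least two points")
        conc = [c for c, _ in self.points]
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ValueError(
                "calibration concentrations must be strictly increasing")
        if self.volume_ml <= 0 or self.mass_g <= 0:
            raise ValueError("dilution terms must be positive")


def quantify_from_signals(raw_signal: float, blank_signal: float,
                          internal_standard_signal: float,
                          curve: CalibrationCurve) -> float:
    """Convert raw instrument signals to a mass fraction in mg/kg.

    The element signal is blank-corrected and related to the internal
    standard; the solution concentration (mg/L) follows from a linear
    least-squares fit through the calibration points and is scaled by
    final volume over sample mass.
    """
    if internal_standard_signal <= 0:
        raise ValueError("internal-standard signal must be positive")
    ratio = (raw_signal - blank_signal) / internal_standard_signal
    if ratio < 0:
        warnings.warn(
            f"{curve.element}: signal below blank; clipping to 0",
            stacklevel=2)
        ratio = 0.0
    conc = np.array([c for c, _ in curve.points], dtype=float)
    sig = np.array([s for _, s in curve.points], dtype=float)
    slope, intercept = np.polyfit(sig, conc, 1)
    if not sig.min() <= ratio <= sig.max():
        warnings.warn(
            f"{curve.element}: signal ratio {ratio:.4g} outside the "
            "calibration range; extrapolating", stacklevel=2)
    solution_mg_per_l = slope * ratio + intercept
    mg_per_kg = solution_mg_per_l * curve.volume_ml / curve.mass_g
    return float(mg_per_kg)


# ---------------------------------------------------------------------
# provenance helpers
# ---------------------------------------------------------------------

def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from a global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def config_hash(obj: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
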