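"""Synthetic element-profile worlds.

Generates a panel of single-origin ("pure") samples with the statistical
structure a geographic-origin authentication study assumes: strictly
positive concentrations, country-specific level shifts, correlated
between-element biological variability, and multiplicative instrument
noise.  Concentrations live on a decadic-log scale internally and are
reported in mg/kg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ELEMENTS",
    "DEFAULT_SAMPLES_PER_COUNTRY",
    "WorldConfig",
    "ConfigError",
    "generate_pure_panel",
    "measure_profile",
    "measure_profiles",
    "validate_panel",
]

#: The 17 elements significant for geographic-origin discrimination of
#: walnuts, in fixed column order (concentrations in mg/kg).
ELEMENTS: tuple[str, ...] = (
    "Al", "B", "Ba", "Ca", "Co", "Cu", "Fe", "Ga", "Mg",
    "Mn", "Mo", "Ni", "Rb", "Sr", "Te", "Tl", "Zn",
)

#: Six-country panel layout used throughout: 206 samples in total.
DEFAULT_SAMPLES_PER_COUNTRY: dict[str, int] = {
    "DE": 49, "IT": 33, "CH": 31, "FR": 63, "CN": 15, "US": 15,
}

# Typical kernel concentrations (mg/kg) used as the world's baseline;
# order matches ELEMENTS.  Only the rough magnitude matters.
_BASE_LEVELS = (
    5.0, 10.0, 3.0, 700.0, 0.05, 12.0, 25.0, 0.01, 1500.0,
    30.0, 0.1, 1.0, 10.0, 5.0, 0.005, 0.002, 28.0,
)

#: Per-element between-country offset SD (decadic log units) at
#: country_separation = 1.
_OFFSET_SCALE = 0.10

#: Within-country biological SD on the log10 scale (~26% CV) and the
#: common between-element correlation of the default covariance.
_BIO_SIGMA = 0.10
_BIO_RHO = 0.30

_HARVEST_YEARS = (2017, 2018, 2019)


class ConfigError(ValueError):
    """A world configuration violates one of its invariants."""


@dataclass
class WorldConfig:
    """Fully specifies a synthetic sampling world.

    Parameters
    ----------
    countries
        Country codes, in panel order.
    samples_per_country
        Number of pure samples per country (each >= 2).
    elements
        Ordered element symbols (exactly 17 unique entries).
    log_mean
        (country x element) location matrix on the decadic-log scale.
    log_cov
        Shared (element x element) covariance on the log10 scale;
        symmetric positive semi-definite.
    country_separation
        Non-negative scalar that scaled the between-country offsets when
        the config was built; 0 means all countries share one mean.
    analytic_cv
        Per-element relative SD of a single instrument measurement.
    seed
        Seed that reproduces the panel draw.
    """

    countries: list[str]
    samples_per_country: dict[str, int]
    elements: list[str]
    log_mean: pd.DataFrame
    log_cov: pd.DataFrame
    country_separation: float
    analytic_cv: pd.Series
    seed: int = 0

    def validate(self) -> None:
        if len(self.elements) != len(set(self.elements)):
            raise ConfigError("element list contains duplicates")
        if len(self.elements) != 17:
            raise ConfigError(
                f"expected 17 elements, got {len(self.elements)}"
            )
        for c, n in self.samples_per_country.items():
            if n < 2:
                raise ConfigError(f"samples_per_country[{c}] = {n} < 2")
        cov = self.log_cov.to_numpy(dtype=float)
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ConfigError("log_cov is not symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() < -1e-10 * max(1.0, eigvals.max()):
            raise ConfigError(
                "log_cov is not positive semi-definite "
                f"(min eigenvalue {eigvals.min():.3g})"
            )
        if (self.analytic_cv < 0).any():
            bad = self.analytic_cv[self.analytic_cv < 0].index.tolist()
            raise ConfigError(f"negative analytic_cv for {bad}")
        if self.country_separation < 0:
            raise ConfigError("country_separation must be non-negative")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "countries": list(self.countries),
            "samples_per_country": {
                c: int(n) for c, n in self.samples_per_country.items()
            },
            "elements": list(self.elements),
            "log_mean": {
                c: [float(v) for v in self.log_mean.loc[c]]
                for c in self.countries
            },
            "log_cov": [[float(v) for v in row]
                        for row in self.log_cov.to_numpy()],
            "country_separation": float(self.country_separation),
            "analytic_cv": {
                e: float(v) for e, v in self.analytic_cv.items()
            },
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WorldConfig":
        elements = list(d["elements"])
        countries = list(d["countries"])
        log_mean = pd.DataFrame(
            [d["log_mean"][c] for c in countries],
            index=countries, columns=elements, dtype=float,
        )
        log_cov = pd.DataFrame(
            np.asarray(d["log_cov"], dtype=float),
            index=elements, columns=elements,
        )
        cfg = cls(
            countries=countries,
            samples_per_country={c: int(n) for c, n
                                 in d["samples_per_country"].items()},
            elements=elements,
            log_mean=log_mean,
            log_cov=log_cov,
            country_separation=float(d["country_separation"]),
            analytic_cv=pd.Series(d["analytic_cv"], dtype=float)
            .reindex(elements),
            seed=int(d["seed"]),
        )
        cfg.validate()
        return cfg


def default_config(
    seed: int = 0,
    country_separation: float = 1.0,
    analytic_cv: float = 0.05,
    samples_per_country: dict[str, int] | None = None,
    bio_sigma: float = _BIO_SIGMA,
    bio_rho: float = _BIO_RHO,
) -> WorldConfig:
    """Build the default six-country, 17-element world.

    Country/element offsets are drawn once from a zero-mean normal with SD
    ``country_separation * 0.1`` log10 units and frozen into the config,
    so a world is fully reproducible from its config file.  The shared
    log-scale covariance is equicorrelated with SD ``bio_sigma`` and
    correlation ``bio_rho``.
    """
    counts = dict(samples_per_country or DEFAULT_SAMPLES_PER_COUNTRY)
    countries = list(counts)
    elements = list(ELEMENTS)
    p = len(elements)

    rng = np.random.default_rng(seed)
    base = np.log10(_BASE_LEVELS)
    raw = rng.normal(0.0, _OFFSET_SCALE, size=(len(countries), p))
    log_mean = pd.DataFrame(
        base + country_separation * raw,
        index=countries, columns=elements,
    )
    cov = bio_sigma ** 2 * (
        (1.0 - bio_rho) * np.eye(p) + bio_rho * np.ones((p, p))
    )
    cfg = WorldConfig(
        countries=countries,
        samples_per_country=counts,
        elements=elements,
        log_mean=log_mean,
        log_cov=pd.DataFrame(cov, index=elements, columns=elements),
        country_separation=country_separation,
        analytic_cv=pd.Series(analytic_cv, index=elements, dtype=float),
        seed=seed,
    )
    cfg.validate()
    return cfg


def generate_pure_panel(config: WorldConfig) -> pd.DataFrame:
    """Draw the pure-sample panel defined by ``config``.

    Returns a wide table with columns ``sample_id``, ``country``,
    ``harvest_year`` and one mg/kg column per element.  Concentrations
    are log-normal around each country's location; the draw is
    deterministic for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cov = config.log_cov.to_numpy(dtype=float)
    rows = []
    for country in config.countries:
        n = config.samples_per_country[country]
        mean = config.log_mean.loc[country].to_numpy(dtype=float)
        logs = rng.multivariate_normal(mean, cov, size=n,
                                       method="svd")
        conc = 10.0 ** logs
        for i in range(n):
            row = {
                "sample_id": f"{country}{i + 1:03d}",
                "country": country,
                "harvest_year": _HARVEST_YEARS[i % len(_HARVEST_YEARS)],
            }
            row.update(dict(zip(config.elements, conc[i])))
            rows.append(row)
    panel = pd.DataFrame(rows)
    validate_panel(panel, config.elements)
    return panel


def validate_panel(panel: pd.DataFrame,
                   elements: list[str] | tuple[str, ...] = ELEMENTS) -> None:
    """Check the panel invariants: schema, unique ids, positive values."""
    missing = [e for e in elements if e not in panel.columns]
    if missing:
        raise ValueError(f"panel is missing element columns: {missing}")
    for col in ("sample_id", "country", "harvest_year"):
        if col not in panel.columns:
            raise ValueError(f"panel is missing column {col!r}")
    if panel["sample_id"].duplicated().any():
        dup = panel.loc[panel["sample_id"].duplicated(), "sample_id"]
        raise ValueError(f"duplicate sample ids: {sorted(set(dup))}")
    vals = panel[list(elements)].to_numpy(dtype=float)
    if not np.all(vals > 0):
        raise ValueError("panel contains non-positive concentrations")


def _log_sigma(cv: np.ndarray) -> np.ndarray:
    # natural-log SD giving a single draw a relative SD of exactly cv
    return np.sqrt(np.log1p(np.square(cv)))


def measure_profile(
    true_profile: pd.Series,
    config: WorldConfig,
    replicates: int = 3,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Simulate an instrument determination of one profile.

    The returned profile is the mean of ``replicates`` independent draws,
    each the true value perturbed by multiplicative log-normal noise with
    element-wise relative SD ``config.analytic_cv``.  The noise is
    unbiased on the log scale, and the SD of the mean shrinks as
    ``1/sqrt(replicates)``.
    """
    out = measure_profiles(
        true_profile.to_frame().T, config, replicates, seed=seed, rng=rng
    )
    return out.iloc[0]


def measure_profiles(
    true_profiles: pd.DataFrame,
    config: WorldConfig,
    replicates: int = 3,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Vectorised :func:`measure_profile` over the rows of a table."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    cv = config.analytic_cv.reindex(config.elements).to_numpy(dtype=float)
    if np.any(cv < 0):
        raise ValueError("analytic_cv must be non-negative")
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    true = true_profiles[config.elements].to_numpy(dtype=float)
    sigma = _log_sigma(cv)
    noise = rng.normal(
        0.0, 1.0, size=(replicates,) + true.shape
    ) * sigma  # broadcast over elements
    draws = true[None, :, :] * np.exp(noise)
    measured = draws.mean(axis=0)
    # zero-noise elements reproduce the truth bit-exactly
    measured[:, sigma == 0] = true[:, sigma == 0]
    out = true_profiles.copy()
    out[config.elements] = measured
    return out
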