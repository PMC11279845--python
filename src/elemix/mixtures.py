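"""In-silico mixtures of pure-sample element profiles.

A binary mixture of two samples has, element by element, the ratio-weighted
linear combination of its parents' concentrations:

    c_mix = x * c_parent1 + (1 - x) * c_parent2,   0 < x < 1.

This module enumerates the cross-origin mixture space of a panel, builds
the full calculated set, draws a balanced measured-mixture plan (a fixed
number of mixtures per country and mixing ratio), and simulates the
corresponding "measured" profiles by adding instrument noise to the
calculated truth.

Mixing ratios are stored as exact integer percents (10..90) to avoid
floating drift on a 0.1 grid; they are converted to fractions only at
computation time.  A mixture table is a wide DataFrame with metadata
columns ``parent1_id, parent2_id, country1, country2, percent_parent1,
provenance`` followed by one column per element.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .world import WorldConfig, measure_profiles

__all__ = [
    "RATIO_GRID",
    "MIX_META_COLUMNS",
    "calc_mixture",
    "enumerate_pairs",
    "count_pairs",
    "count_mixture_space",
    "build_calculated_set",
    "iter_calculated",
    "sample_measured_plan",
    "build_measured_set",
    "expand_directed",
    "mixture_elements",
]

#: Default mixing grid: parent-1 share in percent, 10% steps.
RATIO_GRID: tuple[int, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90)

MIX_META_COLUMNS = (
    "parent1_id", "parent2_id", "country1", "country2",
    "percent_parent1", "provenance",
)

_NON_ELEMENT = set(MIX_META_COLUMNS) | {
    "sample_id", "country", "harvest_year",
    "focal_country", "adulteration_level",
}


def mixture_elements(table: pd.DataFrame) -> list[str]:
    """Element columns of a panel or mixture table (order preserved)."""
    return [c for c in table.columns if c not in _NON_ELEMENT]


def calc_mixture(profile1: pd.Series, profile2: pd.Series,
                 x: float) -> pd.Series:
    """Element-wise convex combination of two profiles (mg/kg in, mg/kg out).

    ``x`` is the fraction of ``profile1``; the implied fraction of
    ``profile2`` is ``1 - x``.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"mixing fraction x={x} outside [0, 1]")
    e1, e2 = set(profile1.index), set(profile2.index)
    if e1 != e2:
        raise ValueError(
            "profiles cover different element sets; "
            f"symmetric difference: {sorted(e1 ^ e2)}"
        )
    p2 = profile2.reindex(profile1.index)
    return x * profile1 + (1.0 - x) * p2


def enumerate_pairs(panel: pd.DataFrame,
                    cross_origin_only: bool = True) -> list[tuple[str, str]]:
    """All unordered sample pairs, optionally without same-country pairs.

    Pairs are returned lexicographically ordered (within each pair and
    overall) so downstream construction is deterministic.
    """
    if len(panel) == 0:
        raise ValueError("panel is empty")
    ids = panel["sample_id"].tolist()
    country = dict(zip(panel["sample_id"], panel["country"]))
    out = []
    for a, b in combinations(sorted(ids), 2):
        if cross_origin_only and country[a] == country[b]:
            continue
        out.append((a, b))
    return out


def count_pairs(counts_per_country: dict[str, int],
                cross_origin_only: bool = True) -> int:
    """Closed-form pair count: C(N,2), minus within-country pairs if asked."""
    n_total = sum(counts_per_country.values())
    total = comb(n_total, 2)
    if cross_origin_only:
        total -= sum(comb(n, 2) for n in counts_per_country.values())
    return total


def count_mixture_space(panel: pd.DataFrame,
                        ratio_grid: tuple[int, ...] = RATIO_GRID) -> int:
    """Size of the cross-origin mixture space without materialising it."""
    if len(ratio_grid) == 0:
        raise ValueError("ratio grid is empty")
    counts = panel["country"].value_counts().to_dict()
    return count_pairs(counts, cross_origin_only=True) * len(ratio_grid)


def _profiles_by_id(panel: pd.DataFrame, elements: list[str]):
    mat = panel.set_index("sample_id")
    return mat[elements], dict(zip(panel["sample_id"], panel["country"]))


def iter_calculated(panel: pd.DataFrame,
                    ratio_grid: tuple[int, ...] = RATIO_GRID,
                    chunk_size: int = 50_000):
    """Stream the calculated cross-origin set as DataFrame chunks.

    Chunks follow the canonical order: parent pairs lexicographic, ratio
    ascending within a pair.
    """
    elements = mixture_elements(panel)
    profs, country = _profiles_by_id(panel, elements)
    pairs = enumerate_pairs(panel, cross_origin_only=True)
    grid = sorted(ratio_grid)
    rows_meta: list[tuple] = []
    for a, b in pairs:
        for pct in grid:
            rows_meta.append((a, b, pct))
            if len(rows_meta) >= chunk_size:
                yield _materialise(rows_meta, profs, country, elements)
                rows_meta = []
    if rows_meta:
        yield _materialise(rows_meta, profs, country, elements)


def _materialise(rows_meta, profs, country, elements) -> pd.DataFrame:
    a_ids = [r[0] for r in rows_meta]
    b_ids = [r[1] for r in rows_meta]
    x = np.array([r[2] for r in rows_meta], dtype=float)[:, None] / 100.0
    p1 = profs.loc[a_ids].to_numpy(dtype=float)
    p2 = profs.loc[b_ids].to_numpy(dtype=float)
    mix = x * p1 + (1.0 - x) * p2
    meta = pd.DataFrame({
        "parent1_id": a_ids,
        "parent2_id": b_ids,
        "country1": [country[i] for i in a_ids],
        "country2": [country[i] for i in b_ids],
        "percent_parent1": [r[2] for r in rows_meta],
        "provenance": "calculated",
    })
    return pd.concat(
        [meta, pd.DataFrame(mix, columns=elements)], axis=1
    )


def build_calculated_set(panel: pd.DataFrame,
                         ratio_grid: tuple[int, ...] = RATIO_GRID,
                         max_records: int = 500_000) -> pd.DataFrame:
    """Materialise every cross-origin mixture at every grid ratio.

    Refuses above ``max_records`` records; use :func:`iter_calculated`
    to stream larger spaces.
    """
    n = count_mixture_space(panel, tuple(ratio_grid))
    if n > max_records:
        raise ValueError(
            f"mixture space has {n} records, above the cap of "
            f"{max_records}; raise max_records or use iter_calculated()"
        )
    chunks = list(iter_calculated(panel, tuple(ratio_grid)))
    return pd.concat(chunks, ignore_index=True)


# ---------------------------------------------------------------------
# measured-mixture plan
# ---------------------------------------------------------------------

def _round_robin_matchings(n: int) -> list[list[tuple[int, int]]]:
    """Perfect matchings of K_n (circle method), n even: n-1 rounds."""
    others = list(range(1, n))
    rounds = []
    for r in range(n - 1):
        rotated = others[-r:] + others[:-r] if r else list(others)
        lineup = [0] + rotated
        rounds.append([(lineup[i], lineup[n - 1 - i])
                       for i in range(n // 2)])
    return rounds


def _ratio_pairs(grid: tuple[int, ...]) -> list[tuple[int, int]]:
    grid = tuple(sorted(grid))
    for pct in grid:
        if not 0 < pct < 100:
            raise ValueError(f"ratio percent {pct} outside (0, 100)")
        if (100 - pct) not in grid:
            raise ValueError(
                f"ratio grid must be symmetric: {pct} present but "
                f"{100 - pct} missing"
            )
    return [(pct, 100 - pct) for pct in grid if pct < 50] + (
        [(50, 50)] if 50 in grid else []
    )


def sample_measured_plan(panel: pd.DataFrame,
                         per_country_per_ratio: int = 10,
                         ratio_grid: tuple[int, ...] = RATIO_GRID,
                         seed: int = 0) -> pd.DataFrame:
    """Draw the undirected plan of physical mixtures to "measure".

    Guarantees that, in the directed view, every (country, mixing-ratio)
    cell holds exactly ``per_country_per_ratio`` distinct mixtures with
    that country as a parent.  A physical mixture serves both parents'
    quotas, so the undirected plan is half the directed count.  Country
    pairs are balanced by a circulant design; parent samples are drawn
    at random within each slot.
    """
    p = per_country_per_ratio
    if p < 1:
        raise ValueError("per_country_per_ratio must be >= 1")
    countries = list(dict.fromkeys(panel["country"]))
    n = len(countries)
    if n < 2:
        raise ValueError("need at least two countries for cross-origin mixtures")
    ids_by_country = {
        c: sorted(panel.loc[panel["country"] == c, "sample_id"])
        for c in countries
    }
    # feasibility: each ordered country pair receives at most
    # ceil(p / (n-1)) slots per ratio cell and needs that many distinct
    # sample pairs
    limiting = min(countries, key=lambda c: len(ids_by_country[c]))
    max_slots = -(-p // (n - 1)) + 1
    for c1 in countries:
        for c2 in countries:
            if c1 != c2 and (len(ids_by_country[c1])
                             * len(ids_by_country[c2])) < max_slots:
                raise ValueError(
                    f"not enough samples to fill the quota; limiting "
                    f"country: {limiting}"
                )

    rng = np.random.default_rng(seed)
    slots: list[tuple[str, str, int]] = []  # (country1, country2, pct1)
    for lo, hi in _ratio_pairs(tuple(ratio_grid)):
        if lo != hi:
            # directed design: p fixed-point-free permutation rounds
            for k in range(p):
                shift = 1 + (k % (n - 1))
                for i in range(n):
                    slots.append((countries[i],
                                  countries[(i + shift) % n], lo))
        else:
            if n % 2 == 0:
                rounds = _round_robin_matchings(n)
                for k in range(p):
                    for i, j in rounds[k % (n - 1)]:
                        slots.append((countries[i], countries[j], 50))
            else:
                if p % 2:
                    raise ValueError(
                        "50/50 quota infeasible: odd country count needs "
                        "an even per_country_per_ratio; limiting country: "
                        f"{limiting}"
                    )
                for k in range(p // 2):
                    shift = 1 + (k % (n - 1))
                    for i in range(n):
                        slots.append((countries[i],
                                      countries[(i + shift) % n], 50))

    used: set[tuple[str, str, int]] = set()
    rows = []
    for c1, c2, pct in slots:
        for _ in range(1000):
            a = ids_by_country[c1][rng.integers(len(ids_by_country[c1]))]
            b = ids_by_country[c2][rng.integers(len(ids_by_country[c2]))]
            key = (a, b, pct) if a < b else (b, a, 100 - pct)
            if key not in used:
                used.add(key)
                rows.append((a, b, c1, c2, pct))
                break
        else:
            raise ValueError(
                f"could not draw a distinct mixture for ({c1}, {c2}, "
                f"{pct}%); limiting country: {limiting}"
            )
    plan = pd.DataFrame(
        rows,
        columns=["parent1_id", "parent2_id", "country1", "country2",
                 "percent_parent1"],
    )
    return plan


def build_measured_set(panel: pd.DataFrame,
                       plan: pd.DataFrame,
                       world: WorldConfig,
                       replicates: int = 3,
                       seed: int | None = None) -> pd.DataFrame:
    """Simulate measuring the planned mixtures.

    Each profile is the triplicate-averaged (by default) noisy
    determination of the calculated truth; with ``analytic_cv`` all zero
    the measured set equals the calculated set exactly.
    """
    elements = mixture_elements(panel)
    profs, _ = _profiles_by_id(panel, elements)
    x = plan["percent_parent1"].to_numpy(dtype=float)[:, None] / 100.0
    p1 = profs.loc[plan["parent1_id"]].to_numpy(dtype=float)
    p2 = profs.loc[plan["parent2_id"]].to_numpy(dtype=float)
    true = pd.DataFrame(x * p1 + (1.0 - x) * p2, columns=elements)
    measured = measure_profiles(true, world, replicates=replicates,
                                seed=world.seed + 1 if seed is None else seed)
    out = plan.reset_index(drop=True).copy()
    out["provenance"] = "measured"
    out = pd.concat([out, measured], axis=1)
    return out[list(MIX_META_COLUMNS) + elements]


def calculated_twins(panel: pd.DataFrame, plan: pd.DataFrame) -> pd.DataFrame:
    """Calculated profiles for exactly the planned (pair, ratio) slots."""
    elements = mixture_elements(panel)
    profs, _ = _profiles_by_id(panel, elements)
    x = plan["percent_parent1"].to_numpy(dtype=float)[:, None] / 100.0
    p1 = profs.loc[plan["parent1_id"]].to_numpy(dtype=float)
    p2 = profs.loc[plan["parent2_id"]].to_numpy(dtype=float)
    out = plan.reset_index(drop=True).copy()
    out["provenance"] = "calculated"
    out = pd.concat(
        [out, pd.DataFrame(x * p1 + (1.0 - x) * p2, columns=elements)],
        axis=1,
    )
    return out[list(MIX_META_COLUMNS) + elements]


def expand_directed(records: pd.DataFrame) -> pd.DataFrame:
    """Read every mixture from both parents' perspectives.

    Each undirected record (A, B, x) yields two directed rows: one with
    focal country A at adulteration level ``100 - x`` (the share of the
    foreign parent B) and one with focal country B at level ``x``.
    Profiles are untouched, so a direction flip is an involution.
    """
    fwd = records.copy()
    fwd["focal_country"] = records["country1"]
    fwd["adulteration_level"] = 100 - records["percent_parent1"]
    rev = records.copy()
    rev["focal_country"] = records["country2"]
    rev["adulteration_level"] = records["percent_parent1"]
    out = pd.concat([fwd, rev], ignore_index=True)
    return out
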