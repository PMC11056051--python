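"""Population-weighted Theil index and its exact group decomposition.

The index used here is the population-share-weighted mean log deviation,

    TI = sum_i p_i * ln(p_i / y_i),

where ``p_i`` is county i's share of the total population and ``y_i`` its
share of the total stock of a resource (beds, doctors or nurses). TI is
zero exactly when every county holds resources in proportion to its
population, and grows as per-capita allocation becomes more uneven.

For a partition of counties into categories the index splits additively,

    TI = TI_intra + TI_inter,
    TI_intra = sum_j p_j * TI_j        (within-category inequality),
    TI_inter = sum_j p_j * ln(p_j/y_j) (between-category inequality),

where ``p_j``/``y_j`` are category shares and ``TI_j`` is the same index
computed within category j from within-category shares. The split is exact,
not approximate, which is what makes the intra/inter contribution shares
meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, TheilDivergenceError
from .panel_io import CATEGORIES, Panel


@dataclass(frozen=True)
class CategoryComponent:
    """One category's shares and within-category inequality."""

    population_share: float  # p_j
    resource_share: float  # y_j
    ti_within: float  # TI_j


@dataclass(frozen=True)
class TheilDecomposition:
    """Overall index with its exact intra/inter split.

    ``intra_share`` and ``inter_share`` are the two components as fractions
    of TI; they are ``None`` when TI is zero (0/0 is left undefined rather
    than reported as a number).
    """

    ti: float
    ti_intra: float
    ti_inter: float
    per_category: Mapping[str, CategoryComponent]

    @property
    def intra_share(self) -> float | None:
        return self.ti_intra / self.ti if self.ti > 0 else None

    @property
    def inter_share(self) -> float | None:
        return self.ti_inter / self.ti if self.ti > 0 else None


def _shares(values: np.ndarray, what: str) -> np.ndarray:
    total = values.sum()
    if total <= 0:
        raise DomainError(f"total {what} must be > 0, got {total}")
    return values / total


def _validate(populations, resources, labels):
    pop = np.asarray(populations, dtype=float)
    res = np.asarray(resources, dtype=float)
    if pop.shape != res.shape or pop.ndim != 1:
        raise DomainError(
            f"populations and resources must be 1-d and equal length, got {pop.shape} vs {res.shape}"
        )
    if not (np.isfinite(pop).all() and np.isfinite(res).all()):
        raise DomainError("populations and resources must be finite")
    if (pop <= 0).any():
        raise DomainError("all populations must be > 0")
    if (res < 0).any():
        raise DomainError("resources must be >= 0")
    if labels is None:
        labels = np.arange(pop.size)
    return pop, res, np.asarray(labels)


def theil(
    populations: Sequence[float],
    resources: Sequence[float],
    labels: Sequence | None = None,
    epsilon: float | None = None,
    _context: str = "",
) -> float:
    """Population-weighted mean-log-deviation Theil index over counties.

    Parameters
    ----------
    populations, resources:
        Per-county population and resource counts (same order).
    labels:
        Optional county identifiers used in divergence diagnostics.
    epsilon:
        Off by default. When set, zero resource shares are replaced by
        ``max(y_i, epsilon)`` instead of aborting — an exploratory escape
        hatch only, since it silently understates inequality.

    Raises
    ------
    TheilDivergenceError
        If any county has positive population but zero resources (the
        log term diverges); the error names the counties.
    """
    pop, res, labels = _validate(populations, resources, labels)
    p = _shares(pop, "population")
    y = _shares(res, "resources")
    zero = y == 0
    if zero.any():
        if epsilon is None:
            raise TheilDivergenceError(labels[zero].tolist(), _context)
        y = np.maximum(y, epsilon)
    return float(np.sum(p * np.log(p / y)))


def theil_decompose(
    populations: Sequence[float],
    resources: Sequence[float],
    categories: Sequence,
    labels: Sequence | None = None,
    epsilon: float | None = None,
    _context: str = "",
) -> TheilDecomposition:
    """Decompose the Theil index over a county partition.

    Returns the overall index together with its exact within-category
    (``ti_intra``) and between-category (``ti_inter``) components and each
    category's shares. ``ti`` is reported as ``ti_intra + ti_inter``, which
    equals the direct county-level index to machine precision.
    """
    pop, res, labels = _validate(populations, resources, labels)
    cats = np.asarray(categories)
    if cats.shape != pop.shape:
        raise DomainError("categories must align with populations")
    p = _shares(pop, "population")
    y_total = res.sum()
    if y_total <= 0:
        raise DomainError(f"total resources must be > 0, got {y_total}")

    seen = [c for c in CATEGORIES if c in set(cats.tolist())]
    seen += [c for c in pd.unique(cats) if c not in seen]

    per_category: dict = {}
    ti_intra = 0.0
    ti_inter = 0.0
    for cat in seen:
        mask = cats == cat
        p_j = float(p[mask].sum())
        y_j = float(res[mask].sum() / y_total)
        if y_j == 0 and epsilon is None:
            raise TheilDivergenceError(
                labels[mask].tolist(), _context or f"category {cat}"
            )
        ti_j = theil(
            pop[mask],
            res[mask],
            labels=labels[mask],
            epsilon=epsilon,
            _context=_context or f"category {cat}",
        )
        eff_y_j = max(y_j, epsilon) if epsilon is not None else y_j
        ti_intra += p_j * ti_j
        ti_inter += p_j * np.log(p_j / eff_y_j)
        per_category[cat] = CategoryComponent(p_j, y_j, ti_j)

    return TheilDecomposition(
        ti=ti_intra + ti_inter,
        ti_intra=ti_intra,
        ti_inter=ti_inter,
        per_category=per_category,
    )


#: panel count columns accepted by theil_series
RESOURCE_COLUMNS = ("beds", "doctors", "nurses", "health_practitioners")


def theil_series(
    panel: Panel, resource: str, epsilon: float | None = None
) -> dict[int, TheilDecomposition]:
    """Cross-sectional Theil decomposition for every panel year.

    Each year uses that year's populations and counts; errors are re-raised
    tagged with the offending year.
    """
    if resource not in RESOURCE_COLUMNS:
        raise ValueError(f"resource must be one of {RESOURCE_COLUMNS}, got {resource!r}")
    out: dict[int, TheilDecomposition] = {}
    for year in panel.years:
        sl = panel.year_slice(year)
        out[year] = theil_decompose(
            sl["population"].to_numpy(),
            sl[resource].to_numpy(),
            sl["category"].to_numpy(),
            labels=sl["county_id"].to_numpy(),
            epsilon=epsilon,
            _context=f"{resource}, year {year}",
        )
    return out


def theil_table(panel: Panel, resources: Sequence[str] = ("beds", "doctors", "nurses"),
                epsilon: float | None = None) -> pd.DataFrame:
    """Tidy per-year table of TI and its decomposition for several resources."""
    rows = []
    for resource in resources:
        for year, dec in theil_series(panel, resource, epsilon=epsilon).items():
            rows.append(
                {
                    "resource": resource,
                    "year": year,
                    "ti": dec.ti,
                    "ti_intra": dec.ti_intra,
                    "ti_inter": dec.ti_inter,
                    "intra_share": dec.intra_share,
                    "inter_share": dec.inter_share,
                }
            )
    return pd.DataFrame(rows)


def theil_category_table(
    panel: Panel, resources: Sequence[str] = ("beds", "doctors", "nurses"),
    epsilon: float | None = None,
) -> pd.DataFrame:
    """Per-category long table: shares and within-category TI per year."""
    rows = []
    for resource in resources:
        for year, dec in theil_series(panel, resource, epsilon=epsilon).items():
            for cat, comp in dec.per_category.items():
                rows.append(
                    {
                        "resource": resource,
                        "year": year,
                        "category": cat,
                        "population_share": comp.population_share,
                        "resource_share": comp.resource_share,
                        "ti_within": comp.ti_within,
                    }
                )
    return pd.DataFrame(rows)
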