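"""Per-1000 densities, growth rates, staffing ratios and county-share statistics.

Indicator names follow the field's convention: ``bed_p1000``, ``doc_p1000``,
``nur_p1000`` and ``hp_p1000`` are beds, doctors, nurses and all health
practitioners per 1000 residents; ``dnpb`` is (doctors + nurses) per bed and
``dn_hp`` the clinical share (doctors + nurses) of all practitioners.

Category-level values come in two flavours: ``aggregate`` divides category
totals (population-weighted, the province-average convention) while
``mean_of_counties`` averages county densities unweighted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DomainError, UndefinedGrowthError
from .panel_io import CATEGORIES, Panel

#: density indicator -> count column
DENSITY_INDICATORS: dict[str, str] = {
    "bed_p1000": "beds",
    "doc_p1000": "doctors",
    "nur_p1000": "nurses",
    "hp_p1000": "health_practitioners",
}
RATIO_INDICATORS: tuple[str, ...] = ("dnpb", "dn_hp")
PROVINCE = "province"


def density_per_1000(count: float, population: float) -> float:
    """Resources per 1000 residents: ``1000 * count / population``."""
    if population <= 0:
        raise DomainError(f"population must be > 0, got {population}")
    return 1000.0 * count / population


def growth_rate(h_start: float, h_end: float) -> float:
    """Decadal growth ``(H_end - H_start) / H_start`` of a per-1000 indicator."""
    if h_start == 0:
        raise UndefinedGrowthError("growth rate undefined: starting density is zero")
    return (h_end - h_start) / h_start


def dnpb(doc: float, nur: float, bed: float) -> float:
    """Doctors-and-nurses per bed, a staffing-intensity proxy."""
    if bed <= 0:
        raise DomainError(f"bed density must be > 0, got {bed}")
    return (doc + nur) / bed


def dn_hp(doc: float, nur: float, hp: float) -> float:
    """Clinical share of the workforce: (doctors + nurses) / all practitioners."""
    if hp <= 0:
        raise DomainError(f"practitioner density must be > 0, got {hp}")
    return (doc + nur) / hp


def ratio_to_province(category_value: float, province_value: float) -> float:
    """Category density as a percentage of the province average."""
    if province_value <= 0:
        raise DomainError(f"province value must be > 0, got {province_value}")
    return 100.0 * category_value / province_value


# ---------------------------------------------------------------------------
# panel-level tables


def county_density_table(panel: Panel) -> pd.DataFrame:
    """Per county-year densities and staffing ratios.

    Returns one row per county-year with the four densities plus ``dnpb``
    and ``dn_hp`` (NaN where the denominator is zero).
    """
    df = panel.data.copy()
    for name, col in DENSITY_INDICATORS.items():
        df[name] = 1000.0 * df[col] / df["population"]
    with np.errstate(divide="ignore", invalid="ignore"):
        df["dnpb"] = np.where(
            df["bed_p1000"] > 0, (df["doc_p1000"] + df["nur_p1000"]) / df["bed_p1000"], np.nan
        )
        df["dn_hp"] = np.where(
            df["hp_p1000"] > 0, (df["doc_p1000"] + df["nur_p1000"]) / df["hp_p1000"], np.nan
        )
    keep = ["county_id", "year", "category", "population", *DENSITY_INDICATORS, *RATIO_INDICATORS]
    keep += [c for c in ("income", "gdp_per_capita", "altitude") if c in df.columns]
    return df[keep]


def _group_density(group: pd.DataFrame, indicator: str, method: str) -> float:
    col = DENSITY_INDICATORS[indicator]
    if method == "aggregate":
        return 1000.0 * group[col].sum() / group["population"].sum()
    if method == "mean_of_counties":
        return float((1000.0 * group[col] / group["population"]).mean())
    raise ValueError(f"unknown method {method!r}")


def category_density(
    panel: Panel, indicator: str, year: int, method: str = "aggregate"
) -> dict[str, float]:
    """Category-level density for one indicator and year.

    ``aggregate`` is 1000 * (sum of counts) / (sum of populations) over the
    category's counties; ``mean_of_counties`` is the unweighted mean of
    county densities.
    """
    sl = panel.year_slice(year)
    out: dict[str, float] = {}
    for cat, grp in sl.groupby("category"):
        out[cat] = _group_density(grp, indicator, method)
    for cat in CATEGORIES:
        if cat in set(sl["category"]) and cat not in out:
            raise DomainError(f"empty category {cat} in year {year}")
    return out


def province_density(panel: Panel, indicator: str, year: int) -> float:
    """Province-wide aggregate density (all counties pooled)."""
    return _group_density(panel.year_slice(year), indicator, "aggregate")


def density_series(panel: Panel, method: str = "aggregate") -> pd.DataFrame:
    """Tidy category + province series of all six indicators.

    Columns: indicator, level (category|province), unit, year, value, method.
    Ratio indicators (dnpb, dn_hp) are formed from the level's own aggregate
    densities, so the province row is not a mean of category rows.
    """
    rows = []
    for year in panel.years:
        sl = panel.year_slice(year)
        groups = [(cat, "category", grp) for cat, grp in sl.groupby("category")]
        groups.append((PROVINCE, "province", sl))
        for unit, level, grp in groups:
            dens = {ind: _group_density(grp, ind, method) for ind in DENSITY_INDICATORS}
            vals = dict(dens)
            vals["dnpb"] = (
                (dens["doc_p1000"] + dens["nur_p1000"]) / dens["bed_p1000"]
                if dens["bed_p1000"] > 0
                else np.nan
            )
            vals["dn_hp"] = (
                (dens["doc_p1000"] + dens["nur_p1000"]) / dens["hp_p1000"]
                if dens["hp_p1000"] > 0
                else np.nan
            )
            for ind, value in vals.items():
                rows.append(
                    {
                        "indicator": ind,
                        "level": level,
                        "unit": unit,
                        "year": year,
                        "value": value,
                        "method": method,
                    }
                )
    return pd.DataFrame(rows)


def county_growth_table(panel: Panel, indicator: str) -> pd.DataFrame:
    """Per-county endpoint growth of a density indicator with flags.

    ``negative_growth`` marks counties whose density fell; ``below_province``
    marks counties growing strictly slower than the province aggregate.
    Counties with a zero starting density get NaN growth (they are excluded
    from shares, which the paper's data cannot produce: yearbook counts are
    positive).
    """
    if indicator not in DENSITY_INDICATORS:
        raise ValueError(f"growth is defined for density indicators, got {indicator!r}")
    y0, y1 = panel.years[0], panel.years[-1]
    dens = county_density_table(panel)
    start = dens[dens["year"] == y0].set_index("county_id")
    end = dens[dens["year"] == y1].set_index("county_id")
    prov_growth = growth_rate(
        province_density(panel, indicator, y0), province_density(panel, indicator, y1)
    )
    h0, h1 = start[indicator], end[indicator].reindex(start.index)
    growth = np.where(h0 > 0, (h1 - h0) / h0, np.nan)
    out = pd.DataFrame(
        {
            "county_id": start.index,
            "category": start["category"].values,
            "h_start": h0.values,
            "h_end": h1.values,
            "growth": growth,
            "negative_growth": growth < 0,
            "below_province": growth < prov_growth,
        }
    ).reset_index(drop=True)
    out.attrs["province_growth"] = prov_growth
    return out


def category_growth(panel: Panel, indicator: str, method: str = "aggregate") -> pd.Series:
    """Endpoint growth of category-level densities (plus the province).

    ``aggregate`` applies the growth formula to category aggregate
    densities; ``mean_of_counties`` averages county-level growth rates.
    """
    y0, y1 = panel.years[0], panel.years[-1]
    if method == "aggregate":
        d0 = category_density(panel, indicator, y0, "aggregate")
        d1 = category_density(panel, indicator, y1, "aggregate")
        vals = {cat: growth_rate(d0[cat], d1[cat]) for cat in d0}
        vals[PROVINCE] = growth_rate(
            province_density(panel, indicator, y0), province_density(panel, indicator, y1)
        )
    elif method == "mean_of_counties":
        tab = county_growth_table(panel, indicator)
        vals = tab.groupby("category")["growth"].mean().to_dict()
        vals[PROVINCE] = float(tab["growth"].mean())
    else:
        raise ValueError(f"unknown method {method!r}")
    order = [c for c in CATEGORIES if c in vals] + [PROVINCE]
    return pd.Series({k: vals[k] for k in order}, name=f"{indicator}_growth")


def share_of_counties(panel: Panel, indicator: str, predicate: str) -> pd.Series:
    """Fraction of each category's counties whose growth satisfies a predicate.

    ``negative_growth``: density fell over the study window.
    ``growth_below_province``: growth strictly lower than the province
    aggregate's growth (ties count as not-lower).
    """
    tab = county_growth_table(panel, indicator)
    if predicate == "negative_growth":
        flag = tab["negative_growth"]
    elif predicate == "growth_below_province":
        flag = tab["below_province"]
    else:
        raise ValueError(f"unknown predicate {predicate!r}")
    return flag.groupby(tab["category"]).mean().reindex(
        [c for c in CATEGORIES if c in set(tab["category"])]
    )


def growth_summary(panel: Panel, indicator: str) -> pd.DataFrame:
    """Category growth table combining both conventions and county shares.

    Columns: category, aggregate_growth, mean_county_growth,
    share_negative, share_below_province.
    """
    agg = category_growth(panel, indicator, "aggregate")
    mean = category_growth(panel, indicator, "mean_of_counties")
    neg = share_of_counties(panel, indicator, "negative_growth")
    below = share_of_counties(panel, indicator, "growth_below_province")
    cats = list(agg.index)
    return pd.DataFrame(
        {
            "indicator": indicator,
            "category": cats,
            "aggregate_growth": [agg[c] for c in cats],
            "mean_county_growth": [mean[c] for c in cats],
            "share_negative": [neg.get(c, np.nan) for c in cats],
            "share_below_province": [below.get(c, np.nan) for c in cats],
        }
    )


def ratio_to_province_series(panel: Panel, indicator: str) -> pd.DataFrame:
    """Category density as % of the province average, per year (aggregate)."""
    rows = []
    for year in panel.years:
        prov = province_density(panel, indicator, year)
        for cat, val in category_density(panel, indicator, year, "aggregate").items():
            rows.append(
                {
                    "indicator": indicator,
                    "category": cat,
                    "year": year,
                    "pct_of_province": ratio_to_province(val, prov),
                }
            )
    return pd.DataFrame(rows)
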