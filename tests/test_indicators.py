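import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from healthequity import (
    DomainError,
    UndefinedGrowthError,
    category_density,
    category_growth,
    county_density_table,
    density_per_1000,
    dn_hp,
    dnpb,
    growth_rate,
    province_density,
    ratio_to_province,
    share_of_counties,
)
from healthequity.indicators import county_growth_table, density_series

from conftest import make_rows, panel_from_rows


@pytest.mark.parametrize(
    "func,args,expected",
    [
        (density_per_1000, (50, 10_000), 5.0),
        (density_per_1000, (0, 10_000), 0.0),
        (density_per_1000, (4730, 1_000_000), 4.73),  # provincial benchmark density
        (growth_rate, (2.0, 4.8), 1.40),
        (growth_rate, (3.0, 3.0), 0.0),
        (growth_rate, (2.0, 1.0), -0.5),
        (dnpb, (1.0, 2.0, 4.0), 0.75),
        (dnpb, (0.0, 0.0, 5.0), 0.0),
        (dnpb, (1.3, 2.1, 4.25), 0.8),
        (dn_hp, (1.0, 2.0, 4.0), 0.75),
        (dn_hp, (2.0, 2.0, 4.0), 1.0),  # boundary: no pharmacists/technicians
        (dn_hp, (1.0, 1.4, 3.0), 0.8),
        (ratio_to_province, (2.0, 4.0), 50.0),
        (ratio_to_province, (4.0, 4.0), 100.0),
        (ratio_to_province, (1.15, 2.5), 46.0),
    ],
)
def test_scalar_indicator_examples(func, args, expected):
    assert func(*args) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "func,args,err",
    [
        (density_per_1000, (10, 0), DomainError),
        (growth_rate, (0.0, 1.0), UndefinedGrowthError),
        (dnpb, (1.0, 1.0, 0.0), DomainError),
        (dn_hp, (1.0, 1.0, 0.0), DomainError),
        (ratio_to_province, (1.0, 0.0), DomainError),
    ],
)
def test_scalar_indicator_domain_errors(func, args, err):
    with pytest.raises(err):
        func(*args)


@settings(derandomize=True, max_examples=100)
@given(
    h=st.floats(min_value=1e-6, max_value=1e6),
    g=st.floats(min_value=-0.99, max_value=10.0),
)
def test_growth_rate_inverts_exactly(h, g):
    assert growth_rate(h, h * (1 + g)) == pytest.approx(g, abs=1e-9)


def two_county_panel():
    df = make_rows(
        [("A", "Yi"), ("B", "Yi")],
        [2009],
        population={("A", 2009): 1000, ("B", 2009): 3000},
        beds={("A", 2009): 10, ("B", 2009): 10},
    )
    df["year"] = 2009
    return panel_from_rows(df)


def test_category_density_aggregate_vs_mean():
    panel = two_county_panel()
    agg = category_density(panel, "bed_p1000", 2009, "aggregate")
    mean = category_density(panel, "bed_p1000", 2009, "mean_of_counties")
    assert agg["Yi"] == pytest.approx(5.0)  # 20 beds / 4000 persons
    assert mean["Yi"] == pytest.approx((10.0 + 10 / 3) / 2)


def test_single_county_category_methods_agree(two_by_two):
    for method in ("aggregate", "mean_of_counties"):
        val = category_density(two_by_two, "doc_p1000", 2009, method)
        assert val["Yi"] == pytest.approx(1.0)


def test_province_density_is_weighted_mean_sandwich(paperlike_clean):
    panel, _ = paperlike_clean
    for ind in ("bed_p1000", "doc_p1000", "nur_p1000", "hp_p1000"):
        for year in (2009, 2014, 2019):
            cats = category_density(panel, ind, year, "aggregate")
            prov = province_density(panel, ind, year)
            assert min(cats.values()) <= prov <= max(cats.values())


def test_dn_hp_bounded_by_one_on_valid_panel(paperlike_noisy):
    panel, _ = paperlike_noisy
    tab = county_density_table(panel)
    assert (tab["dn_hp"] <= 1 + 1e-12).all()
    assert (tab[["bed_p1000", "doc_p1000", "nur_p1000", "hp_p1000"]] >= 0).all().all()


def test_share_of_counties_negative_growth():
    # 4 counties, 2 with falling doctor counts
    counties = [(f"c{i}", "Yi") for i in range(4)]
    doctors = {("c0", 2019): 8, ("c1", 2019): 9, ("c2", 2019): 12, ("c3", 2019): 10}
    df = make_rows(counties, [2009, 2019], doctors=doctors)
    panel = panel_from_rows(df)
    share = share_of_counties(panel, "doc_p1000", "negative_growth")
    assert share["Yi"] == pytest.approx(0.5)


def test_share_below_province_is_strict():
    # both counties grow at exactly the province rate: ties are not "lower"
    df = make_rows(
        [("A", "Yi"), ("B", "NMC")],
        [2009, 2019],
        beds={("A", 2019): 60, ("B", 2019): 60},
    )
    panel = panel_from_rows(df)
    share = share_of_counties(panel, "bed_p1000", "growth_below_province")
    assert share.fillna(0).sum() == 0


def test_share_of_counties_unknown_predicate(two_by_two):
    with pytest.raises(ValueError):
        share_of_counties(two_by_two, "bed_p1000", "no_such_predicate")


def test_category_growth_methods_and_county_table(paperlike_clean):
    panel, truth = paperlike_clean
    agg = category_growth(panel, "bed_p1000", "aggregate")
    for cat in ("Yi", "Zang", "OMC", "PSC", "NMC"):
        assert agg[cat] == pytest.approx(truth.expected_growth[("beds", cat)], abs=5e-3)
    tab = county_growth_table(panel, "bed_p1000")
    assert set(tab.columns) >= {"growth", "negative_growth", "below_province"}
    assert len(tab) == 181
    # mean-of-counties growth averages county growth rates
    mean = category_growth(panel, "bed_p1000", "mean_of_counties")
    by_cat = tab.groupby("category")["growth"].mean()
    for cat in by_cat.index:
        assert mean[cat] == pytest.approx(by_cat[cat])


def test_density_series_tidy_shape(two_by_two):
    tab = density_series(two_by_two)
    # 6 indicators x (2 categories + province) x 2 years
    assert len(tab) == 6 * 3 * 2
    assert set(tab["level"]) == {"category", "province"}
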