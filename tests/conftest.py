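import numpy as np
import pandas as pd
import pytest

from healthequity import Panel, generate_panel, paperlike_config
from healthequity.synthetic_data import SyntheticConfig


def make_rows(counties, years, **overrides):
    """Rows for a hand-built panel: equal counts unless overridden.

    ``overrides`` maps column -> {(county_id, year): value}.
    """
    rows = []
    for cid, cat in counties:
        for year in years:
            row = {
                "county_id": cid,
                "year": year,
                "category": cat,
                "population": 10_000,
                "beds": 30,
                "doctors": 10,
                "nurses": 12,
                "health_practitioners": 30,
                "income": 30_000.0,
                "gdp_per_capita": 20_000.0,
                "altitude": 800.0,
            }
            for col, table in overrides.items():
                if (cid, year) in table:
                    row[col] = table[(cid, year)]
            rows.append(row)
    return pd.DataFrame(rows)


def panel_from_rows(df, validate=True):
    return Panel.from_dataframe(df, validate=validate)


@pytest.fixture
def two_by_two():
    df = make_rows([("A", "Yi"), ("B", "NMC")], [2009, 2010])
    return panel_from_rows(df)


@pytest.fixture(scope="session")
def paperlike_clean():
    """Noise-free paper-like panel (181 counties x 11 years) + ground truth."""
    return generate_panel(paperlike_config(seed=1, noise_cv=0.0))


@pytest.fixture(scope="session")
def paperlike_noisy():
    return generate_panel(paperlike_config(seed=1, noise_cv=0.05))


def small_config(**kw):
    """A fast 5-county configuration for pipeline/CLI tests."""
    base = dict(
        seed=7,
        n_counties={c: 1 for c in ("Yi", "Zang", "OMC", "PSC", "NMC")},
        baseline_density={
            "beds": {c: 2.0 for c in ("Yi", "Zang", "OMC", "PSC", "NMC")},
            "doctors": {c: 1.0 for c in ("Yi", "Zang", "OMC", "PSC", "NMC")},
            "nurses": {c: 0.8 for c in ("Yi", "Zang", "OMC", "PSC", "NMC")},
        },
        growth={
            "beds": {c: 1.0 for c in ("Yi", "Zang", "OMC", "PSC", "NMC")},
            "doctors": {c: 0.5 for c in ("Yi", "Zang", "OMC", "PSC", "NMC")},
            "nurses": {c: 2.0 for c in ("Yi", "Zang", "OMC", "PSC", "NMC")},
        },
        noise_cv=0.0,
    )
    base.update(kw)
    return SyntheticConfig(**base)


def mld_bruteforce(populations, resources):
    """Independent mean-log-deviation evaluation (pure-Python loop)."""
    import math

    P = float(sum(populations))
    Y = float(sum(resources))
    total = 0.0
    for pop, res in zip(populations, resources):
        p = pop / P
        y = res / Y
        total += p * math.log(p / y)
    return total


def random_instance(rng, n_max=8, k_max=3):
    n = int(rng.integers(2, n_max + 1))
    k = int(rng.integers(1, k_max + 1))
    pops = rng.integers(1, 200, size=n).astype(float)
    res = rng.integers(1, 100, size=n).astype(float)
    cats = np.array([f"g{int(g)}" for g in rng.integers(0, k, size=n)])
    return pops, res, cats
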