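import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from healthequity import (
    DomainError,
    TheilDivergenceError,
    theil,
    theil_decompose,
    theil_series,
)
from healthequity.inequality import theil_category_table, theil_table
from healthequity.synthetic_data import SyntheticConfig, generate_panel

from conftest import mld_bruteforce, random_instance, small_config


def test_perfect_equality_is_zero():
    assert theil([100, 100], [20, 20]) == pytest.approx(0.0, abs=1e-15)


def test_worked_two_county_value():
    # 0.5*ln2 + 0.5*ln(2/3), evaluated independently by hand
    expected = 0.5 * math.log(2) + 0.5 * math.log(2 / 3)
    assert expected == pytest.approx(0.143841, abs=5e-7)
    assert theil([100, 100], [10, 30]) == pytest.approx(expected, rel=1e-12)


def test_permutation_symmetry():
    rng = np.random.default_rng(3)
    pops = rng.integers(1, 100, size=6).astype(float)
    res = rng.integers(1, 50, size=6).astype(float)
    perm = rng.permutation(6)
    assert theil(pops, res) == pytest.approx(theil(pops[perm], res[perm]), rel=1e-12)


def test_divergence_names_the_county():
    with pytest.raises(TheilDivergenceError) as exc:
        theil([100, 100], [0, 30], labels=["empty-county", "other"])
    assert "empty-county" in str(exc.value)
    assert exc.value.counties == ["empty-county"]


def test_epsilon_substitution_is_opt_in():
    value = theil([100, 100], [0, 30], epsilon=1e-6)
    assert np.isfinite(value) and value > 0


def test_length_mismatch_rejected():
    with pytest.raises(DomainError):
        theil([1, 2, 3], [1, 2])


def test_worked_decomposition():
    # categories A=(10,30), B=(20,20), equal populations: category shares
    # p_j = y_j = 1/2 force the between term to zero
    pops = [100, 100, 100, 100]
    res = [10, 30, 20, 20]
    cats = ["A", "A", "B", "B"]
    dec = theil_decompose(pops, res, cats)
    assert dec.ti_inter == pytest.approx(0.0, abs=1e-15)
    assert dec.ti_intra == pytest.approx(0.071920, abs=1e-6)
    assert dec.ti == pytest.approx(0.071920, abs=1e-6)
    assert dec.per_category["A"].population_share == pytest.approx(0.5)
    assert dec.per_category["A"].ti_within == pytest.approx(theil([100, 100], [10, 30]), rel=1e-12)
    assert dec.intra_share == pytest.approx(1.0)


def test_degenerate_partitions():
    rng = np.random.default_rng(11)
    pops = rng.integers(1, 100, size=5).astype(float)
    res = rng.integers(1, 50, size=5).astype(float)
    ti = theil(pops, res)
    one_group = theil_decompose(pops, res, ["all"] * 5)
    assert one_group.ti_inter == pytest.approx(0.0, abs=1e-15)
    assert one_group.ti_intra == pytest.approx(ti, rel=1e-12)
    singletons = theil_decompose(pops, res, [f"g{i}" for i in range(5)])
    assert singletons.ti_intra == pytest.approx(0.0, abs=1e-15)
    assert singletons.ti_inter == pytest.approx(ti, rel=1e-12)


def test_oracle_equivalence_and_additivity():
    rng = np.random.default_rng(42)
    for _ in range(200):
        pops, res, cats = random_instance(rng)
        dec = theil_decompose(pops, res, cats)
        brute = mld_bruteforce(pops, res)
        assert dec.ti == pytest.approx(brute, rel=1e-12, abs=1e-12)
        assert dec.ti_intra + dec.ti_inter == pytest.approx(brute, rel=1e-12, abs=1e-12)
        assert dec.ti >= -1e-15 and dec.ti_intra >= -1e-15 and dec.ti_inter >= -1e-15


def test_replication_invariance():
    pops = np.array([50.0, 120.0, 80.0])
    res = np.array([10.0, 40.0, 15.0])
    base = theil(pops, res)
    doubled = theil(np.tile(pops, 2), np.tile(res, 2))
    assert doubled == pytest.approx(base, rel=1e-12)


@settings(derandomize=True, max_examples=50)
@given(scale=st.floats(min_value=1e-3, max_value=1e3))
def test_scale_invariance(scale):
    pops = np.array([50.0, 120.0, 80.0])
    res = np.array([10.0, 40.0, 15.0])
    assert theil(pops, res * scale) == pytest.approx(theil(pops, res), rel=1e-9, abs=1e-12)


def test_progressive_transfer_never_increases_ti():
    rng = np.random.default_rng(7)
    for _ in range(50):
        pops, res, _ = random_instance(rng, n_max=8)
        pc = res / pops
        donor, recip = int(np.argmax(pc)), int(np.argmin(pc))
        if donor == recip:
            continue
        # half the transfer that would equalize the pair's per-capita levels
        delta = 0.5 * (pc[donor] - pc[recip]) / (1 / pops[donor] + 1 / pops[recip])
        moved = res.copy()
        moved[donor] -= delta
        moved[recip] += delta
        assert theil(pops, moved) <= theil(pops, res) + 1e-12


def test_share_vectors_sum_to_one(paperlike_noisy):
    panel, _ = paperlike_noisy
    for year, dec in theil_series(panel, "doctors").items():
        p_sum = sum(c.population_share for c in dec.per_category.values())
        y_sum = sum(c.resource_share for c in dec.per_category.values())
        assert p_sum == pytest.approx(1.0, abs=1e-12)
        assert y_sum == pytest.approx(1.0, abs=1e-12)
        assert dec.intra_share + dec.inter_share == pytest.approx(1.0, abs=1e-12)


def test_proportional_panel_gives_zero_series():
    # one county per category, counts exactly proportional to population
    cfg = small_config(frailty_sigma=0.0, population_sigma=0.0, integer_counts=True)
    panel, _ = generate_panel(cfg)
    tab = theil_table(panel)
    assert (tab["ti"].abs() < 1e-6).all()
    assert tab["intra_share"].isna().all()  # contributions undefined at TI = 0


def test_widening_gaps_raise_inter_and_converging_lower_ti():
    sizes = {c: 6 for c in ("Yi", "Zang", "OMC", "PSC", "NMC")}
    flat = {c: 0.0 for c in sizes}
    base = {c: 2.0 for c in sizes}
    widening = SyntheticConfig(
        seed=5,
        n_counties=sizes,
        baseline_density={
            "beds": base,
            "doctors": base,
            "nurses": base,
        },
        growth={
            "beds": flat,
            "doctors": {"Yi": -0.5, "Zang": -0.4, "OMC": 0.0, "PSC": 0.5, "NMC": 1.5},
            "nurses": flat,
        },
        noise_cv=0.0,
        frailty_sigma=0.0,
        population_sigma=0.2,
    )
    panel, _ = generate_panel(widening)
    inter = [dec.ti_inter for _, dec in sorted(theil_series(panel, "doctors").items())]
    assert all(b >= a - 1e-12 for a, b in zip(inter, inter[1:]))
    assert inter[-1] > inter[0]

    converging = widening.model_copy(
        update={
            "baseline_density": {
                "beds": base,
                "doctors": {"Yi": 1.0, "Zang": 1.4, "OMC": 2.0, "PSC": 2.8, "NMC": 4.0},
                "nurses": base,
            },
            "growth": {
                "beds": flat,
                # low-density categories catch up to a common endpoint
                "doctors": {"Yi": 3.0, "Zang": 1.857, "OMC": 1.0, "PSC": 0.429, "NMC": 0.0},
                "nurses": flat,
            },
        }
    )
    panel2, _ = generate_panel(converging)
    ti = [dec.ti for _, dec in sorted(theil_series(panel2, "doctors").items())]
    assert ti[-1] < ti[0]


def test_theil_category_table_shape(paperlike_clean):
    panel, _ = paperlike_clean
    tab = theil_category_table(panel)
    assert len(tab) == 3 * 11 * 5  # resources x years x categories
    assert (tab["ti_within"] >= -1e-15).all()
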