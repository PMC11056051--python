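import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from healthequity import (
    TheilDivergenceError,
    generate_panel,
    paperlike_config,
    theil,
    validate_panel,
)
from healthequity.panel_io import write_panel
from healthequity.synthetic_data import SyntheticConfig

from conftest import small_config


def test_generator_output_always_validates(paperlike_noisy):
    panel, _ = paperlike_noisy
    assert validate_panel(panel).ok


def test_fixed_seed_is_byte_identical(tmp_path):
    cfg = small_config(noise_cv=0.05)
    a, b = tmp_path / "a.csv", tmp_path / "b.csv"
    write_panel(generate_panel(cfg)[0], a)
    write_panel(generate_panel(cfg)[0], b)
    assert a.read_bytes() == b.read_bytes()


def test_different_seeds_differ():
    cfg = small_config(noise_cv=0.05)
    p1, _ = generate_panel(cfg)
    p2, _ = generate_panel(cfg.model_copy(update={"seed": 8}))
    assert not p1.data.equals(p2.data)


def test_noise_free_densities_match_ground_truth_trajectories():
    # one county per category, no noise: panel densities equal the expected
    # trajectories up to count rounding (at most one count per county-year)
    cfg = small_config()
    panel, truth = generate_panel(cfg)
    merged = panel.data.merge(
        truth.expected_density.pivot_table(
            index=["category", "year"], columns="resource", values="value"
        ).reset_index(),
        on=["category", "year"],
        suffixes=("", "_expected"),
    )
    for res in ("beds", "doctors", "nurses"):
        expected_counts = merged[f"{res}_expected"] * merged["population"] / 1000.0
        assert (np.abs(merged[res] - expected_counts) <= 1.0 + 1e-9).all()


def test_expected_growth_matches_noise_free_panel(paperlike_clean):
    panel, truth = paperlike_clean
    dens = truth.expected_density
    for (res, cat), g in truth.expected_growth.items():
        d = dens[(dens.resource == res) & (dens.category == cat)].sort_values("year")
        assert d.value.iloc[-1] / d.value.iloc[0] - 1 == pytest.approx(g, abs=1e-12)


def test_negative_growth_flag_bookkeeping(paperlike_clean):
    panel, truth = paperlike_clean
    assert truth.expected_negative_share[("doctors", "Yi")] == pytest.approx(1 / 3, abs=1e-12)
    assert truth.expected_negative_share[("doctors", "Zang")] == pytest.approx(0.5, abs=1e-12)
    assert len(truth.flagged_counties[("doctors", "Yi")]) == 4
    assert len(truth.flagged_counties[("doctors", "Zang")]) == 16
    # flagged counties really do lose doctor density in the noise-free panel
    from healthequity.indicators import county_growth_table

    tab = county_growth_table(panel, "doc_p1000").set_index("county_id")
    for cid in truth.flagged_counties[("doctors", "Yi")] + truth.flagged_counties[("doctors", "Zang")]:
        assert tab.loc[cid, "growth"] < 0
    unflagged = set(tab.index) - {
        c for v in truth.flagged_counties.values() for c in v
    }
    assert (tab.loc[sorted(unflagged), "growth"] > 0).all()


def test_adding_a_county_does_not_perturb_others():
    cfg = small_config()
    bigger = small_config(
        n_counties={"Yi": 2, "Zang": 1, "OMC": 1, "PSC": 1, "NMC": 1}
    )
    p_small, _ = generate_panel(cfg)
    p_big, _ = generate_panel(bigger)
    shared = p_small.counties
    a = p_small.data.set_index(["county_id", "year"])
    b = p_big.data.loc[p_big.data.county_id.isin(shared)].set_index(["county_id", "year"])
    # Zang/OMC/PSC/NMC county draws are untouched by the extra Yi county;
    # only compensated growth within Yi may shift
    cols = ["population", "altitude", "income", "gdp_per_capita"]
    pd.testing.assert_frame_equal(a[cols], b.loc[a.index, cols])
    non_yi = a[~a.index.get_level_values(0).str.startswith("Yi")]
    pd.testing.assert_frame_equal(non_yi, b.loc[non_yi.index])


def test_config_invariants_rejected_before_sampling():
    with pytest.raises(ValidationError):
        small_config(noise_cv=-0.1)
    with pytest.raises(ValidationError):
        small_config(n_counties={"Yi": 0, "Zang": 1, "OMC": 1, "PSC": 1, "NMC": 1})
    with pytest.raises(ValidationError):
        cfg = small_config()
        SyntheticConfig(**{**cfg.model_dump(), "growth": {
            "beds": {c: -1.5 for c in cfg.n_counties},
            "doctors": cfg.growth["doctors"],
            "nurses": cfg.growth["nurses"],
        }})
    with pytest.raises(ValidationError):
        small_config(baseline_density={
            "beds": {"Yi": 2.0},  # missing categories
            "doctors": {},
            "nurses": {},
        })


def test_zero_resource_switch_exercises_divergence():
    cfg = small_config(count_floor=0)
    doctors = {c: 1.0 for c in cfg.n_counties}
    doctors["Yi"] = 0.001  # rounds to zero doctors in the Yi county
    cfg = cfg.model_copy(
        update={
            "baseline_density": {**cfg.baseline_density, "doctors": doctors},
        }
    )
    panel, _ = generate_panel(cfg)
    sl = panel.year_slice(2009)
    assert (sl["doctors"] == 0).any()  # zero-resource counties now possible
    with pytest.raises(TheilDivergenceError):
        theil(sl["population"].to_numpy(), sl["doctors"].to_numpy(),
              labels=sl["county_id"].to_numpy())


def test_paperlike_config_shape():
    cfg = paperlike_config()
    assert sum(cfg.n_counties.values()) == 181
    assert cfg.years == (2009, 2019)
    assert cfg.growth["beds"]["Yi"] == pytest.approx(1.40)
    assert cfg.growth["nurses"]["OMC"] == pytest.approx(3.16)
    assert cfg.negative_growth_share["doctors"]["Zang"] == pytest.approx(0.5)


def test_pharmacist_share_bounds(paperlike_noisy):
    panel, _ = paperlike_noisy
    df = panel.data
    share = 1 - (df.doctors + df.nurses) / df.health_practitioners
    # rounding of counts can nudge the realized share slightly past the bounds
    assert share.between(0.15, 0.32).all()
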