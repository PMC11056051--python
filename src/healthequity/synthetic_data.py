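"""Synthetic county x year panels with known ground truth.

The generator emulates the structure of a provincial health-yearbook
extract: 181 counties in five fixed categories observed annually over
2009-2019, with category-specific baseline densities (per 1000 residents)
for beds, doctors and nurses, category-specific decadal growth,
multiplicative county heterogeneity ("frailty") and year-level noise, and
integer resource counts. All health practitioners are derived from doctors
plus nurses by inflating with a per-county pharmacist/lab-technician share
in the 16-31% range, so the clinical-share invariant holds by construction.

A county's noise-free density trajectory is geometric between its start
and end values:

    d(year) = baseline * frailty * (1 + g)^((year - y0) / (y1 - y0))

Counties flagged for negative growth get ``g = negative_growth_rate``; the
remaining counties' growth is solved so that the category's
population-weighted aggregate growth equals the configured target exactly
(before count rounding and noise). Optional linear altitude and income
effects can be injected into densities for regression-recovery tests.

Randomness contract: every county draws from its own substream keyed by
(root seed, county id), so adding or removing a county never perturbs the
draws of the others.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .panel_io import CATEGORIES, Panel

RESOURCES: tuple[str, ...] = ("beds", "doctors", "nurses")

#: category sizes of the Sichuan county classification
DEFAULT_SIZES: dict[str, int] = {"Yi": 12, "Zang": 32, "OMC": 23, "PSC": 32, "NMC": 82}

#: mean county altitudes (m a.s.l.); Yi/Zang/OMC as reported for Sichuan,
#: PSC/NMC calibration choices (non-minority counties sit in the basin)
DEFAULT_ALTITUDE: dict[str, float] = {
    "Yi": 2139.0,
    "Zang": 3656.0,
    "OMC": 1592.0,
    "PSC": 1100.0,
    "NMC": 550.0,
}


class SyntheticConfig(BaseModel):
    """Full parameterisation of the synthetic panel generator."""

    model_config = {"frozen": True}

    seed: int = 0
    n_counties: dict[str, int] = Field(default_factory=lambda: dict(DEFAULT_SIZES))
    years: tuple[int, int] = (2009, 2019)

    # per-resource, per-category noise-free start densities (per 1000)
    baseline_density: dict[str, dict[str, float]]
    # per-resource, per-category decadal aggregate growth (fraction)
    growth: dict[str, dict[str, float]]
    # fraction of a category's counties forced to negative growth
    negative_growth_share: dict[str, dict[str, float]] = Field(default_factory=dict)
    negative_growth_rate: float = -0.05

    # scalar, or per-category medians (minority counties are far smaller)
    population_median: float | dict[str, float] = 300_000.0
    population_sigma: float = 0.35  # log-scale SD of county population
    population_annual_growth: float = 0.005
    frailty_sigma: float = 0.35  # log-scale SD of county density heterogeneity
    noise_cv: float = 0.05  # coefficient of variation of year-level noise
    pharmacist_share: tuple[float, float] = (0.16, 0.31)

    income_level: dict[str, float] = Field(
        default_factory=lambda: {"Yi": 28e3, "Zang": 32e3, "OMC": 30e3, "PSC": 30e3, "NMC": 38e3}
    )
    income_annual_growth: float = 0.09
    income_sigma: float = 0.10
    gdp_level: dict[str, float] = Field(
        default_factory=lambda: {"Yi": 9e3, "Zang": 11e3, "OMC": 12e3, "PSC": 13e3, "NMC": 25e3}
    )
    gdp_annual_growth: float = 0.10
    gdp_sigma: float = 0.15
    altitude_mean: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_ALTITUDE))
    altitude_sigma: float = 300.0
    altitude_min: float = 200.0

    # optional injected linear effects on density (per metre / per currency unit)
    altitude_effect: dict[str, float] = Field(default_factory=dict)
    income_effect: dict[str, float] = Field(default_factory=dict)

    # counts are rounded to integers with this floor; set 0 to allow
    # zero-resource counties (exercises the Theil divergence path)
    count_floor: int = 1
    integer_counts: bool = True

    @field_validator("n_counties")
    @classmethod
    def _sizes_positive(cls, v):
        for cat, n in v.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")
            if n < 1:
                raise ValueError(f"category {cat} needs >= 1 county, got {n}")
        return v

    @field_validator("baseline_density")
    @classmethod
    def _baselines_positive(cls, v):
        for res, per_cat in v.items():
            if res not in RESOURCES:
                raise ValueError(f"unknown resource {res!r}")
            for cat, b in per_cat.items():
                if b <= 0:
                    raise ValueError(f"baseline for {res}/{cat} must be > 0, got {b}")
        return v

    @field_validator("growth")
    @classmethod
    def _growth_bounded(cls, v):
        for res, per_cat in v.items():
            for cat, g in per_cat.items():
                if g <= -1:
                    raise ValueError(f"growth for {res}/{cat} must be > -1, got {g}")
        return v

    @model_validator(mode="after")
    def _consistent(self):
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.negative_growth_rate <= -1:
            raise ValueError("negative_growth_rate must be > -1")
        if not (0 <= self.pharmacist_share[0] <= self.pharmacist_share[1] < 1):
            raise ValueError("pharmacist_share bounds must satisfy 0 <= lo <= hi < 1")
        if self.years[1] < self.years[0]:
            raise ValueError("years must be (first, last) with first <= last")
        for table, name in ((self.baseline_density, "baseline_density"), (self.growth, "growth")):
            for res in RESOURCES:
                per_cat = table.get(res, {})
                missing = [c for c in self.n_counties if c not in per_cat]
                if missing:
                    raise ValueError(f"{name}[{res}] missing categories {missing}")
        return self

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator intended, for recovery checks.

    ``expected_density`` holds noise-free category aggregate densities per
    (resource, category, year) computed from the realized county
    populations and frailties; ``expected_growth`` echoes the configured
    targets; ``expected_negative_share`` and ``flagged_counties`` record
    exactly which counties were forced to negative growth.
    """

    expected_density: pd.DataFrame
    expected_growth: dict[tuple[str, str], float]
    expected_province_growth: dict[str, float]
    expected_negative_share: dict[tuple[str, str], float]
    flagged_counties: dict[tuple[str, str], tuple[str, ...]]
    expected_slopes: dict[tuple[str, str], float] = dc_field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "expected_density": self.expected_density.to_dict(orient="records"),
                "expected_growth": {f"{r}/{c}": g for (r, c), g in self.expected_growth.items()},
                "expected_province_growth": self.expected_province_growth,
                "expected_negative_share": {
                    f"{r}/{c}": s for (r, c), s in self.expected_negative_share.items()
                },
                "flagged_counties": {
                    f"{r}/{c}": list(v) for (r, c), v in self.flagged_counties.items()
                },
                "expected_slopes": {f"{p}/{r}": s for (p, r), s in self.expected_slopes.items()},
            },
            indent=2,
        )


def _county_rng(seed: int, key: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, zlib.crc32(key.encode()))))


def _lognormal_unit_mean(z: np.ndarray, sigma: float) -> np.ndarray:
    """exp(sigma*z - sigma^2/2): multiplicative noise with expectation 1."""
    return np.exp(sigma * z - 0.5 * sigma**2)


def generate_panel(config: SyntheticConfig) -> tuple[Panel, GroundTruth]:
    """Draw one panel and its ground truth; deterministic for a fixed seed."""
    years = np.array(config.year_list)
    n_years = years.size
    horizon = max(config.years[1] - config.years[0], 1)
    t_frac = (years - config.years[0]) / horizon
    sigma_noise = float(np.sqrt(np.log1p(config.noise_cv**2)))

    counties: list[str] = []
    cat_of: dict[str, str] = {}
    for cat in CATEGORIES:
        for i in range(config.n_counties.get(cat, 0)):
            cid = f"{cat}-{i + 1:03d}"
            counties.append(cid)
            cat_of[cid] = cat

    # per-county draws, each from its own substream (fixed draw order)
    pop_base: dict[str, float] = {}
    frailty: dict[str, dict[str, float]] = {res: {} for res in RESOURCES}
    pharm_share: dict[str, float] = {}
    altitude: dict[str, float] = {}
    income_mult: dict[str, float] = {}
    gdp_mult: dict[str, float] = {}
    year_noise: dict[str, np.ndarray] = {}
    for cid in counties:
        rng = _county_rng(config.seed, cid)
        cat = cat_of[cid]
        med = (
            config.population_median[cat]
            if isinstance(config.population_median, dict)
            else config.population_median
        )
        pop_base[cid] = med * float(np.exp(config.population_sigma * rng.standard_normal()))
        for res in RESOURCES:
            frailty[res][cid] = float(
                _lognormal_unit_mean(rng.standard_normal(), config.frailty_sigma)
            )
        pharm_share[cid] = float(rng.uniform(*config.pharmacist_share))
        altitude[cid] = float(
            max(config.altitude_min, rng.normal(config.altitude_mean[cat], config.altitude_sigma))
        )
        income_mult[cid] = float(_lognormal_unit_mean(rng.standard_normal(), config.income_sigma))
        gdp_mult[cid] = float(_lognormal_unit_mean(rng.standard_normal(), config.gdp_sigma))
        year_noise[cid] = _lognormal_unit_mean(
            rng.standard_normal((n_years, len(RESOURCES))), sigma_noise
        )

    # negative-growth flags and compensated per-county growth
    growth_of: dict[str, dict[str, float]] = {res: {} for res in RESOURCES}
    flagged: dict[tuple[str, str], tuple[str, ...]] = {}
    neg_share: dict[tuple[str, str], float] = {}
    for res in RESOURCES:
        for cat in config.n_counties:
            members = [c for c in counties if cat_of[c] == cat]
            share = config.negative_growth_share.get(res, {}).get(cat, 0.0)
            n_flag = int(round(share * len(members)))
            if n_flag:
                rng_flag = _county_rng(config.seed, f"flags:{res}:{cat}")
                chosen = tuple(sorted(rng_flag.choice(members, size=n_flag, replace=False)))
            else:
                chosen = ()
            flagged[(res, cat)] = chosen
            neg_share[(res, cat)] = n_flag / len(members)
            g_target = config.growth[res][cat]
            w = np.array([pop_base[c] * frailty[res][c] for c in members])
            is_neg = np.array([c in chosen for c in members])
            if is_neg.all():
                g_pos = config.negative_growth_rate
            else:
                # solve unflagged growth so the population-weighted aggregate
                # growth hits the configured target exactly (noise-free)
                g_pos = (
                    g_target * w.sum() - config.negative_growth_rate * w[is_neg].sum()
                ) / w[~is_neg].sum()
            for c, neg in zip(members, is_neg):
                growth_of[res][c] = config.negative_growth_rate if neg else float(g_pos)

    # reference levels for injected linear effects (config-level constants)
    n_total = sum(config.n_counties.values())
    alt_ref = sum(config.n_counties[c] * config.altitude_mean[c] for c in config.n_counties)
    alt_ref /= n_total
    inc_ref0 = sum(config.n_counties[c] * config.income_level[c] for c in config.n_counties)
    inc_ref0 /= n_total

    t_idx = np.arange(n_years)
    pops_of: dict[str, np.ndarray] = {}
    income_of: dict[str, np.ndarray] = {}
    gdp_of: dict[str, np.ndarray] = {}
    raw_counts: dict[str, dict[str, np.ndarray]] = {res: {} for res in RESOURCES}
    for cid in counties:
        cat = cat_of[cid]
        pops = np.maximum(
            np.rint(pop_base[cid] * (1 + config.population_annual_growth) ** t_idx), 1
        )
        pops_of[cid] = pops
        income = (
            config.income_level[cat]
            * (1 + config.income_annual_growth) ** t_idx
            * income_mult[cid]
        )
        income_of[cid] = income
        gdp_of[cid] = (
            config.gdp_level[cat] * (1 + config.gdp_annual_growth) ** t_idx * gdp_mult[cid]
        )
        inc_ref = inc_ref0 * (1 + config.income_annual_growth) ** t_idx
        for r_i, res in enumerate(RESOURCES):
            dens = (
                config.baseline_density[res][cat]
                * frailty[res][cid]
                * (1 + growth_of[res][cid]) ** t_frac
                * year_noise[cid][:, r_i]
            )
            dens = dens + config.altitude_effect.get(res, 0.0) * (altitude[cid] - alt_ref)
            dens = dens + config.income_effect.get(res, 0.0) * (income - inc_ref)
            raw_counts[res][cid] = np.maximum(dens, 0.0) * pops / 1000.0

    # integer counts via largest-remainder rounding within each
    # (resource, category, year): every county moves by < 1 count while the
    # category total stays within half a count of the unrounded total, so
    # aggregate densities and growth are preserved to rounding precision
    counts: dict[str, dict[str, np.ndarray]] = {res: {} for res in RESOURCES}
    for res in RESOURCES:
        if not config.integer_counts:
            for cid in counties:
                counts[res][cid] = np.maximum(raw_counts[res][cid], config.count_floor)
            continue
        for cat in config.n_counties:
            members = [c for c in counties if cat_of[c] == cat]
            raw = np.stack([raw_counts[res][c] for c in members])  # (n_members, n_years)
            rounded = np.floor(raw)
            frac = raw - rounded
            for k in range(n_years):
                short = int(np.rint(raw[:, k].sum()) - rounded[:, k].sum())
                if short > 0:
                    # ties broken by county order (deterministic)
                    top = np.argsort(-frac[:, k], kind="stable")[:short]
                    rounded[top, k] += 1
            rounded = np.maximum(rounded, config.count_floor)
            for idx, cid in enumerate(members):
                counts[res][cid] = rounded[idx]

    rows = []
    for cid in counties:
        cat = cat_of[cid]
        dn = counts["doctors"][cid] + counts["nurses"][cid]
        hp = dn / (1 - pharm_share[cid])
        if config.integer_counts:
            hp = np.rint(hp)
        hp = np.maximum(hp, dn)
        for k, year in enumerate(config.year_list):
            rows.append(
                {
                    "county_id": cid,
                    "year": year,
                    "category": cat,
                    "population": pops_of[cid][k],
                    "beds": counts["beds"][cid][k],
                    "doctors": counts["doctors"][cid][k],
                    "nurses": counts["nurses"][cid][k],
                    "health_practitioners": hp[k],
                    "income": round(income_of[cid][k], 2),
                    "gdp_per_capita": round(gdp_of[cid][k], 2),
                    "altitude": round(altitude[cid], 1),
                }
            )
    panel = Panel.from_dataframe(pd.DataFrame(rows))

    # noise-free expected aggregates from realized populations/frailties
    exp_rows = []
    prov_growth: dict[str, float] = {}
    for res in RESOURCES:
        prov_traj = np.zeros(n_years)
        prov_pop = 0.0
        for cat in config.n_counties:
            members = [c for c in counties if cat_of[c] == cat]
            w = np.array([pop_base[c] * frailty[res][c] for c in members])
            g = np.array([growth_of[res][c] for c in members])
            b = config.baseline_density[res][cat]
            traj = b * (w[:, None] * (1 + g[:, None]) ** t_frac[None, :]).sum(axis=0)
            cat_pop = sum(pop_base[c] for c in members)
            for k, year in enumerate(config.year_list):
                exp_rows.append(
                    {
                        "resource": res,
                        "category": cat,
                        "year": year,
                        "value": traj[k] / cat_pop,
                    }
                )
            prov_traj += traj
            prov_pop += cat_pop
        prov = prov_traj / prov_pop
        prov_growth[res] = float(prov[-1] / prov[0] - 1) if prov[0] > 0 else np.nan

    slopes = {("altitude", res): e for res, e in config.altitude_effect.items()}
    slopes.update({("income", res): e for res, e in config.income_effect.items()})
    truth = GroundTruth(
        expected_density=pd.DataFrame(exp_rows),
        expected_growth={
            (res, cat): config.growth[res][cat] for res in RESOURCES for cat in config.n_counties
        },
        expected_province_growth=prov_growth,
        expected_negative_share=neg_share,
        flagged_counties=flagged,
        expected_slopes=slopes,
    )
    return panel, truth


def paperlike_config(seed: int = 0, noise_cv: float = 0.05) -> SyntheticConfig:
    """The packaged Sichuan-shaped configuration.

    Noise-free category aggregate growths equal the study's headline
    percentages (beds: Yi 140%, OMC 127%, NMC 121%; doctors: Yi 20%,
    Zang 11%, NMC 61%; nurses: Yi 240%, OMC 316%, NMC 198%) and the
    negative-doctor-growth shares are one third of Yi and half of Zang
    counties. Values the study does not print (Zang/PSC bed growth,
    OMC/PSC doctor growth, Zang/PSC nurse growth, baselines, covariate
    levels) are calibration choices consistent with its ordinal findings:
    Zang grows slowest everywhere, OMC/PSC sit above the province mean,
    minority counties start lower, poorer and higher.
    """
    return SyntheticConfig(
        seed=seed,
        noise_cv=noise_cv,
        baseline_density={
            "beds": {"Yi": 1.70, "Zang": 2.00, "OMC": 2.20, "PSC": 2.40, "NMC": 2.90},
            "doctors": {"Yi": 0.95, "Zang": 1.00, "OMC": 1.20, "PSC": 1.30, "NMC": 1.70},
            "nurses": {"Yi": 0.55, "Zang": 0.65, "OMC": 0.75, "PSC": 0.85, "NMC": 1.25},
        },
        growth={
            "beds": {"Yi": 1.40, "Zang": 0.85, "OMC": 1.27, "PSC": 1.30, "NMC": 1.21},
            "doctors": {"Yi": 0.20, "Zang": 0.11, "OMC": 0.70, "PSC": 0.75, "NMC": 0.61},
            "nurses": {"Yi": 2.40, "Zang": 1.20, "OMC": 3.16, "PSC": 2.60, "NMC": 1.98},
        },
        negative_growth_share={"doctors": {"Yi": 1 / 3, "Zang": 0.5}},
        population_median={
            "Yi": 180e3,
            "Zang": 60e3,
            "OMC": 150e3,
            "PSC": 300e3,
            "NMC": 550e3,
        },
    )


def write_outputs(panel: Panel, truth: GroundTruth, panel_path, truth_path=None) -> None:
    """Write the panel CSV and, optionally, the ground-truth JSON beside it."""
    from .panel_io import write_panel

    write_panel(panel, panel_path)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write(truth.to_json())
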