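"""Config-driven end-to-end runs producing the result tables.

A run takes either a panel CSV (plus optional category scheme and column
mapping) or a synthetic configuration, executes every analysis stage —
density/growth tables, staffing-ratio series, Theil decomposition series,
regression table — and writes the bundle as CSVs with a deterministic JSON
manifest. ``compare_to_reference`` checks a bundle against a table of
printed headline values under explicit rounding rules.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .association import cross_section_fit, pooled_panel_fit, regression_table
from .errors import HealthEquityError, SchemaError
from .indicators import (
    DENSITY_INDICATORS,
    density_series,
    growth_summary,
    ratio_to_province_series,
)
from .inequality import theil_category_table, theil_table
from .panel_io import Panel, read_category_scheme, read_panel
from .synthetic_data import SyntheticConfig, generate_panel, paperlike_config

logger = logging.getLogger("healthequity")

_RESOURCE_TO_INDICATOR = {
    "beds": "bed_p1000",
    "doctors": "doc_p1000",
    "nurses": "nur_p1000",
    "health_practitioners": "hp_p1000",
}


class SyntheticSpec(BaseModel):
    """Synthetic input for a run: packaged paper-like config or a full one."""

    paperlike: bool = True
    seed: int = 0
    noise_cv: float = 0.05
    config: Optional[dict] = None  # full SyntheticConfig fields; overrides paperlike

    def build(self) -> SyntheticConfig:
        if self.config is not None:
            return SyntheticConfig(**self.config)
        return paperlike_config(seed=self.seed, noise_cv=self.noise_cv)


class RunConfig(BaseModel):
    """One report run: exactly one of a panel path or a synthetic spec."""

    panel: Optional[str] = None
    scheme: Optional[str] = None
    schema_map: Optional[dict[str, str]] = None
    synthetic: Optional[SyntheticSpec] = None
    out_dir: str = "report"
    density_method: str = "aggregate"
    epsilon: Optional[float] = None

    @model_validator(mode="after")
    def _one_input(self):
        if (self.panel is None) == (self.synthetic is None):
            raise ValueError("exactly one of panel / synthetic must be set")
        if self.density_method not in ("aggregate", "mean_of_counties"):
            raise ValueError(f"unknown density_method {self.density_method!r}")
        return self


@dataclass
class ReportBundle:
    """In-memory result tables of a pipeline run, plus output paths."""

    panel: Panel
    densities: pd.DataFrame
    growth: pd.DataFrame
    ratios_to_province: pd.DataFrame
    theil: pd.DataFrame
    theil_categories: pd.DataFrame
    regressions: pd.DataFrame
    manifest: dict
    out_dir: Path | None = None


def _analysis_config(config: RunConfig) -> dict:
    # out_dir identifies where results land, not what they are
    dump = config.model_dump()
    dump.pop("out_dir", None)
    return dump


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(_analysis_config(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_panel(config: RunConfig) -> Panel:
    if config.synthetic is not None:
        panel, _ = generate_panel(config.synthetic.build())
        return panel
    panel = read_panel(config.panel, schema=config.schema_map)
    if config.scheme:
        scheme = read_category_scheme(config.scheme)
        return Panel.from_dataframe(panel.data, scheme=scheme)
    return panel


def run_pipeline(config: RunConfig, write: bool = True) -> ReportBundle:
    """Execute every stage and (optionally) write the report bundle.

    Tables are computed fully in memory before anything touches disk, so a
    failing stage leaves no partial outputs; a failure during the write
    phase removes what was already written.
    """
    stages: list[tuple[str, float]] = []

    def timed(stage, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except HealthEquityError as exc:
            raise HealthEquityError(f"stage {stage!r} failed: {exc}") from exc
        stages.append((stage, time.perf_counter() - t0))
        logger.info("stage %s done in %.2fs", stage, stages[-1][1])
        return out

    panel = timed("load", lambda: _load_panel(config))
    logger.info(
        "panel: %d counties x %d years = %d rows",
        len(panel.counties),
        len(panel.years),
        panel.n_records,
    )
    densities = timed(
        "densities",
        lambda: pd.concat(
            [density_series(panel, "aggregate"), density_series(panel, "mean_of_counties")],
            ignore_index=True,
        ),
    )
    growth = timed(
        "growth",
        lambda: pd.concat(
            [growth_summary(panel, ind) for ind in ("bed_p1000", "doc_p1000", "nur_p1000")],
            ignore_index=True,
        ),
    )
    ratios = timed(
        "ratios",
        lambda: pd.concat(
            [ratio_to_province_series(panel, ind) for ind in DENSITY_INDICATORS],
            ignore_index=True,
        ),
    )
    theil = timed("theil", lambda: theil_table(panel, epsilon=config.epsilon))
    theil_cat = timed("theil", lambda: theil_category_table(panel, epsilon=config.epsilon))

    def fit_all():
        y0, y1 = panel.years[0], panel.years[-1]
        fits = [
            pooled_panel_fit(panel, "income", "doc_p1000"),
            pooled_panel_fit(panel, "income", "nur_p1000"),
            pooled_panel_fit(panel, "gdp_per_capita", "doc_p1000"),
            pooled_panel_fit(panel, "gdp_per_capita", "nur_p1000"),
            pooled_panel_fit(panel, "gdp_per_capita", "bed_p1000"),
            cross_section_fit(panel, y1, "altitude", "doc_p1000"),
            cross_section_fit(panel, y0, "altitude", "doc_p1000"),
            cross_section_fit(panel, y1, "altitude", "nur_p1000"),
            cross_section_fit(panel, y0, "altitude", "nur_p1000"),
        ]
        for f in fits:
            if f.n_excluded:
                logger.info(
                    "%s ~ %s (%s): excluded %d rows with null values",
                    f.response,
                    f.predictor,
                    f.scope,
                    f.n_excluded,
                )
            if f.diagnostics and f.diagnostics.applicable:
                if f.diagnostics.normality_flag or f.diagnostics.homoscedasticity_flag:
                    logger.warning(
                        "%s ~ %s (%s): residual diagnostics flagged "
                        "(normality p=%.3g, homoscedasticity p=%.3g)",
                        f.response,
                        f.predictor,
                        f.scope,
                        f.diagnostics.normality_p,
                        f.diagnostics.homoscedasticity_p,
                    )
        return regression_table(fits)

    regressions = timed("regressions", fit_all)

    manifest = {
        "package_version": __version__,
        "config": _analysis_config(config),
        "config_hash": _config_hash(config),
        "seed": None if config.synthetic is None else config.synthetic.seed,
        "n_counties": len(panel.counties),
        "years": [panel.years[0], panel.years[-1]],
        "n_rows": panel.n_records,
        "category_sizes": panel.scheme.sizes,
        "notes": [
            "pooled regressions treat county-years as independent observations",
            "currency values are nominal (no deflation)",
        ],
    }
    bundle = ReportBundle(
        panel=panel,
        densities=densities,
        growth=growth,
        ratios_to_province=ratios,
        theil=theil,
        theil_categories=theil_cat,
        regressions=regressions,
        manifest=manifest,
    )
    if write:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        try:
            for name, table in [
                ("densities.csv", densities),
                ("growth.csv", growth),
                ("ratios_to_province.csv", ratios),
                ("theil.csv", theil),
                ("theil_categories.csv", theil_cat),
                ("regressions.csv", regressions),
            ]:
                path = out_dir / name
                table.to_csv(path, index=False)
                written.append(path)
            path = out_dir / "manifest.json"
            path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
            written.append(path)
        except Exception:
            for p in written:
                p.unlink(missing_ok=True)
            raise
        bundle.out_dir = out_dir
        logger.info("report written to %s (stage timings: %s)", out_dir,
                     ", ".join(f"{s}={t:.2f}s" for s, t in stages))
    return bundle


# ---------------------------------------------------------------------------
# comparison against printed reference values

_ROUNDERS = {
    "percent_int": lambda x: float(np.round(100.0 * x)),
    "int": lambda x: float(np.round(x)),
    "1dp": lambda x: float(np.round(x, 1)),
    "2dp": lambda x: float(np.round(x, 2)),
    "3dp": lambda x: float(np.round(x, 3)),
    "exact": float,
}


def _lookup(bundle: ReportBundle, quantity: str, resource: str, category, year) -> float:
    indicator = _RESOURCE_TO_INDICATOR.get(resource, resource)
    if quantity == "growth":
        tab = bundle.growth
        row = tab[(tab["indicator"] == indicator) & (tab["category"] == category)]
        if row.empty:
            raise SchemaError(f"no growth row for {resource}/{category}")
        return float(row["aggregate_growth"].iloc[0])
    if quantity == "negative_share":
        tab = bundle.growth
        row = tab[(tab["indicator"] == indicator) & (tab["category"] == category)]
        if row.empty:
            raise SchemaError(f"no growth row for {resource}/{category}")
        return float(row["share_negative"].iloc[0])
    if quantity == "density":
        tab = bundle.densities
        row = tab[
            (tab["indicator"] == indicator)
            & (tab["unit"] == category)
            & (tab["year"] == int(year))
            & (tab["method"] == "aggregate")
        ]
        if row.empty:
            raise SchemaError(f"no density row for {resource}/{category}/{year}")
        return float(row["value"].iloc[0])
    if quantity == "ratio_to_province":
        tab = bundle.ratios_to_province
        row = tab[
            (tab["indicator"] == indicator)
            & (tab["category"] == category)
            & (tab["year"] == int(year))
        ]
        if row.empty:
            raise SchemaError(f"no province-ratio row for {resource}/{category}/{year}")
        # stored as percent already; reference rounding applies to a fraction
        return float(row["pct_of_province"].iloc[0]) / 100.0
    if quantity in ("theil", "ti_intra", "ti_inter", "intra_share", "inter_share"):
        tab = bundle.theil
        row = tab[(tab["resource"] == resource) & (tab["year"] == int(year))]
        if row.empty:
            raise SchemaError(f"no Theil row for {resource}/{year}")
        col = {"theil": "ti"}.get(quantity, quantity)
        return float(row[col].iloc[0])
    raise SchemaError(f"unknown reference quantity {quantity!r}")


def compare_to_reference(bundle: ReportBundle, reference: pd.DataFrame) -> pd.DataFrame:
    """Check a report bundle against printed values under rounding rules.

    ``reference`` needs columns quantity, resource, category, year, value,
    rounding. The computed quantity is rounded per the stated rule
    (``percent_int`` prints a fraction as an integer percentage, ``kdp``
    rounds to k decimals) and compared exactly to the printed value.
    Returns one row per reference row with the raw and rounded computed
    values, the delta, and a match flag.
    """
    required = {"quantity", "resource", "category", "year", "value", "rounding"}
    missing = required - set(reference.columns)
    if missing:
        raise SchemaError(f"reference table missing columns {sorted(missing)}")
    rows = []
    for ref in reference.itertuples(index=False):
        rule = str(ref.rounding)
        if rule not in _ROUNDERS:
            raise SchemaError(f"unknown rounding rule {rule!r}")
        raw = _lookup(bundle, str(ref.quantity), str(ref.resource), ref.category, ref.year)
        rounded = _ROUNDERS[rule](raw)
        printed = float(ref.value)
        rows.append(
            {
                "quantity": ref.quantity,
                "resource": ref.resource,
                "category": ref.category,
                "year": ref.year,
                "printed": printed,
                "computed_raw": raw,
                "computed_rounded": rounded,
                "delta": rounded - printed,
                "match": bool(np.isclose(rounded, printed, rtol=0, atol=1e-9)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "quantity", "resource", "category", "year",
            "printed", "computed_raw", "computed_rounded", "delta", "match",
        ],
    )


def load_reference(path) -> pd.DataFrame:
    return pd.read_csv(path)
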