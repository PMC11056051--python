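"""Reading, validating and writing the county x year panel.

The panel is a long-format table with one row per county and calendar year,
carrying resource counts (beds, doctors, nurses, all health practitioners),
population, and three covariates (average practitioner income, GDP per
capita, mean altitude). Counties belong to exactly one of five fixed
categories: Yi, Zang and other ethnic minority counties (OMC), plus
poverty-stricken (PSC) and non-minority (NMC) counties. The covariates may
be null; counts and population may not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import PanelValidationError, SchemaError

#: The five county categories, in the order used throughout the package.
CATEGORIES: tuple[str, ...] = ("Yi", "Zang", "OMC", "PSC", "NMC")

#: Canonical column names of the long-format panel CSV.
COUNT_COLUMNS: tuple[str, ...] = ("beds", "doctors", "nurses", "health_practitioners")
COVARIATE_COLUMNS: tuple[str, ...] = ("income", "gdp_per_capita", "altitude")
PANEL_COLUMNS: tuple[str, ...] = (
    "county_id",
    "year",
    "category",
    "population",
    *COUNT_COLUMNS,
    *COVARIATE_COLUMNS,
)


@dataclass(frozen=True)
class CountyYearRecord:
    """One county's resources, population and covariates in one year."""

    county_id: str
    year: int
    category: str
    population: float
    beds: float
    doctors: float
    nurses: float
    health_practitioners: float
    income: float | None = None
    gdp_per_capita: float | None = None
    altitude: float | None = None


@dataclass(frozen=True)
class CategoryScheme:
    """Mutually exclusive, exhaustive county -> category mapping."""

    mapping: Mapping[str, str]

    def __post_init__(self):
        bad = sorted({c for c in self.mapping.values() if c not in CATEGORIES})
        if bad:
            raise SchemaError(f"unknown category labels {bad}; expected one of {CATEGORIES}")

    @property
    def sizes(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for cat in self.mapping.values():
            counts[cat] += 1
        return counts

    def category_of(self, county_id: str) -> str:
        return self.mapping[county_id]

    def counties_in(self, category: str) -> list[str]:
        return sorted(c for c, cat in self.mapping.items() if cat == category)

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass(frozen=True)
class Finding:
    """One invariant violation, with coordinates."""

    check: str
    message: str
    county_id: str | None = None
    year: int | None = None

    def __str__(self) -> str:
        where = "/".join(str(x) for x in (self.county_id, self.year) if x is not None)
        return f"[{self.check}] {where}: {self.message}" if where else f"[{self.check}] {self.message}"


@dataclass
class ValidationReport:
    """Report-only collection of invariant violations."""

    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def add(self, check: str, message: str, county_id=None, year=None) -> None:
        self.findings.append(Finding(check, message, county_id, year))

    def to_jsonl(self) -> str:
        return "\n".join(
            json.dumps(
                {"check": f.check, "county_id": f.county_id, "year": f.year, "message": f.message}
            )
            for f in self.findings
        )

    def __str__(self) -> str:
        return "valid panel" if self.ok else "\n".join(str(f) for f in self.findings)


@dataclass(frozen=True)
class Panel:
    """Balanced county x year panel with its category scheme.

    ``data`` holds the canonical long-format table, sorted by
    (county_id, year); ``scheme`` the fixed county classification.
    """

    data: pd.DataFrame
    scheme: CategoryScheme

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, scheme: CategoryScheme | None = None, validate: bool = True
    ) -> "Panel":
        df = _canonicalize(df)
        if scheme is None:
            pairs = df.drop_duplicates("county_id")[["county_id", "category"]]
            scheme = CategoryScheme(dict(zip(pairs["county_id"], pairs["category"])))
        panel = cls(data=df, scheme=scheme)
        if validate:
            report = validate_panel(panel)
            if not report.ok:
                raise PanelValidationError(report.findings)
        return panel

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique().tolist())

    @property
    def counties(self) -> list[str]:
        return sorted(self.data["county_id"].unique().tolist())

    @property
    def n_records(self) -> int:
        return len(self.data)

    def year_slice(self, year: int) -> pd.DataFrame:
        if year not in set(self.years):
            raise KeyError(f"year {year} not in panel range {self.years[0]}-{self.years[-1]}")
        return self.data[self.data["year"] == year].reset_index(drop=True)

    def to_records(self) -> Iterator[CountyYearRecord]:
        for row in self.data.itertuples(index=False):
            yield CountyYearRecord(
                county_id=row.county_id,
                year=int(row.year),
                category=row.category,
                population=float(row.population),
                beds=float(row.beds),
                doctors=float(row.doctors),
                nurses=float(row.nurses),
                health_practitioners=float(row.health_practitioners),
                income=None if pd.isna(row.income) else float(row.income),
                gdp_per_capita=None if pd.isna(row.gdp_per_capita) else float(row.gdp_per_capita),
                altitude=None if pd.isna(row.altitude) else float(row.altitude),
            )


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"panel is missing required columns: {missing}")
    df = df[list(PANEL_COLUMNS)].copy()
    df["county_id"] = df["county_id"].astype(str)
    df["category"] = df["category"].astype(str)
    df["year"] = pd.to_numeric(df["year"], errors="raise").astype(int)
    for col in ("population", *COUNT_COLUMNS):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in COVARIATE_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df.sort_values(["county_id", "year"], kind="mergesort").reset_index(drop=True)


def read_panel(
    path: str | Path, schema: Mapping[str, str] | None = None, validate: bool = True
) -> Panel:
    """Read a long-format panel CSV into a validated :class:`Panel`.

    Parameters
    ----------
    path:
        UTF-8 CSV with a header row, one row per county-year.
    schema:
        Optional mapping from canonical column names (see ``PANEL_COLUMNS``)
        to the names actually used in the file.
    validate:
        When true (default), structural violations raise
        :class:`PanelValidationError` listing every offending coordinate.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if schema:
        unknown = [c for c in schema if c not in PANEL_COLUMNS]
        if unknown:
            raise SchemaError(f"schema maps unknown canonical columns: {unknown}")
        absent = [src for src in schema.values() if src not in df.columns]
        if absent:
            raise SchemaError(f"schema names columns absent from {path.name}: {absent}")
        df = df.rename(columns={src: canon for canon, src in schema.items()})
    return Panel.from_dataframe(df, validate=validate)


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write the canonical long-format panel CSV (round-trips read_panel)."""
    panel.data.to_csv(path, index=False)


def read_category_scheme(path: str | Path) -> CategoryScheme:
    """Read a two-column ``county_id,category`` CSV.

    Duplicate county ids and labels outside the five-way enum are rejected.
    """
    df = pd.read_csv(path)
    required = {"county_id", "category"}
    if not required.issubset(df.columns):
        raise SchemaError(f"category scheme needs columns {sorted(required)}, got {list(df.columns)}")
    df["county_id"] = df["county_id"].astype(str)
    dupes = df.loc[df["county_id"].duplicated(), "county_id"].unique().tolist()
    if dupes:
        raise SchemaError(f"duplicate county ids in scheme: {dupes}")
    return CategoryScheme(dict(zip(df["county_id"], df["category"].astype(str))))


def write_category_scheme(scheme: CategoryScheme, path: str | Path) -> None:
    pd.DataFrame(
        {"county_id": list(scheme.mapping), "category": list(scheme.mapping.values())}
    ).sort_values("county_id").to_csv(path, index=False)


def validate_panel(panel: Panel | pd.DataFrame) -> ValidationReport:
    """Check every panel invariant; returns a report, never raises.

    Checks: recognised categories, one constant category per county,
    scheme/panel agreement, balance (every county observed exactly once in
    every year of the span), positive population, non-negative finite
    counts, and the practitioner-consistency bound
    ``health_practitioners >= doctors + nurses`` (all practitioners include
    pharmacists and lab technicians on top of doctors and nurses).
    """
    report = ValidationReport()
    if isinstance(panel, Panel):
        df, scheme = panel.data, panel.scheme
    else:
        df, scheme = _canonicalize(panel), None

    bad_cat = df.loc[~df["category"].isin(CATEGORIES)]
    for row in bad_cat.itertuples(index=False):
        report.add("category", f"unknown category {row.category!r}", row.county_id, int(row.year))

    # category constant per county, consistent with the scheme
    cats_per_county = df.groupby("county_id")["category"].agg(lambda s: sorted(set(s)))
    for county, cats in cats_per_county.items():
        if len(cats) > 1:
            report.add("category", f"county assigned to several categories {cats}", county)
        elif scheme is not None and county in scheme.mapping and scheme.mapping[county] != cats[0]:
            report.add(
                "category",
                f"panel says {cats[0]!r} but scheme says {scheme.mapping[county]!r}",
                county,
            )
    if scheme is not None:
        panel_counties = set(df["county_id"])
        for county in sorted(panel_counties - set(scheme.mapping)):
            report.add("scheme", "county absent from category scheme", county)
        for county in sorted(set(scheme.mapping) - panel_counties):
            report.add("scheme", "scheme county absent from panel", county)

    # balance: every county exactly once in every observed year
    years = sorted(int(y) for y in df["year"].unique())
    if years:
        span = years
        counts = df.groupby(["county_id", "year"]).size()
        for county in sorted(df["county_id"].unique()):
            seen = counts.loc[county] if county in counts.index.get_level_values(0) else pd.Series()
            for year in span:
                n = int(seen.get(year, 0))
                if n == 0:
                    report.add("balance", "county missing in year", county, year)
                elif n > 1:
                    report.add("balance", f"county appears {n} times in year", county, year)

    for row in df.itertuples(index=False):
        cid, year = row.county_id, int(row.year)
        if not np.isfinite(row.population) or row.population <= 0:
            report.add("positivity", f"population must be > 0, got {row.population}", cid, year)
        for col in COUNT_COLUMNS:
            v = getattr(row, col)
            if not np.isfinite(v) or v < 0:
                report.add("counts", f"{col} must be finite and >= 0, got {v}", cid, year)
        hp, doc, nur = row.health_practitioners, row.doctors, row.nurses
        if np.isfinite(hp) and np.isfinite(doc) and np.isfinite(nur) and hp < doc + nur:
            report.add(
                "hp_consistency",
                f"health_practitioners ({hp:g}) < doctors+nurses ({doc + nur:g})",
                cid,
                year,
            )
    return report
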