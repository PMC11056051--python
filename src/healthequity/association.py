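"""Bivariate OLS associations between densities and covariates.

Fits are simple ordinary least squares of a per-1000 density on one
covariate (practitioner income, GDP per capita, or county mean altitude).
Slope significance is the regression F-test of zero slope — for simple OLS
the same object as a one-way ANOVA on the slope — at alpha = 0.05.
Residual diagnostics (normality, homoscedasticity, independence) are
advisory and never block a fit. Pooled fits treat county-years as
independent observations; no panel correction is applied, which is recorded
in the fit's notes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.stattools import durbin_watson

from .errors import (
    DegeneratePredictorError,
    DegenerateResponseError,
    InsufficientDataError,
)
from .indicators import DENSITY_INDICATORS, county_density_table
from .panel_io import Panel

ALPHA = 0.05


@dataclass(frozen=True)
class ResidualDiagnostics:
    """Advisory checks of the OLS assumptions.

    ``normality`` is Shapiro-Wilk for n <= 5000, D'Agostino K^2 above;
    ``homoscedasticity`` is Breusch-Pagan; ``independence`` is the
    Durbin-Watson statistic (no p-value; values near 2 indicate
    uncorrelated residuals). ``applicable`` is False for degenerate
    (all-zero) residuals.
    """

    applicable: bool
    normality_test: str | None = None
    normality_stat: float | None = None
    normality_p: float | None = None
    homoscedasticity_stat: float | None = None
    homoscedasticity_p: float | None = None
    durbin_watson: float | None = None

    @property
    def normality_flag(self) -> bool | None:
        return None if self.normality_p is None else self.normality_p < ALPHA

    @property
    def homoscedasticity_flag(self) -> bool | None:
        return None if self.homoscedasticity_p is None else self.homoscedasticity_p < ALPHA


@dataclass(frozen=True)
class RegressionFit:
    """Result of a bivariate OLS fit."""

    predictor: str
    response: str
    scope: str
    n: int
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    slope_se: float
    n_excluded: int = 0
    diagnostics: ResidualDiagnostics | None = None
    notes: tuple[str, ...] = field(default=())

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def residual_diagnostics(residuals: np.ndarray, exog: np.ndarray) -> ResidualDiagnostics:
    """Run the three assumption checks on a fitted model's residuals."""
    residuals = np.asarray(residuals, dtype=float)
    if np.allclose(residuals, 0):
        return ResidualDiagnostics(applicable=False)
    n = residuals.size
    if n <= 5000:
        name = "shapiro-wilk"
        stat, p = stats.shapiro(residuals)
    else:
        name = "dagostino-k2"
        stat, p = stats.normaltest(residuals)
    bp_stat, bp_p, _, _ = het_breuschpagan(residuals, exog)
    return ResidualDiagnostics(
        applicable=True,
        normality_test=name,
        normality_stat=float(stat),
        normality_p=float(p),
        homoscedasticity_stat=float(bp_stat),
        homoscedasticity_p=float(bp_p),
        durbin_watson=float(durbin_watson(residuals)),
    )


def ols_fit(
    x,
    y,
    predictor: str = "x",
    response: str = "y",
    scope: str = "",
    diagnostics: bool = True,
    n_excluded: int = 0,
    notes: tuple[str, ...] = (),
) -> RegressionFit:
    """Simple OLS of ``y`` on ``x`` with the zero-slope F-test.

    Requires at least three observations and a non-constant predictor; a
    constant response (zero total sum of squares) makes R^2 undefined and
    is rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InsufficientDataError(f"x and y lengths differ: {x.size} vs {y.size}")
    if x.size < 3:
        raise InsufficientDataError(f"need n >= 3 observations, got {x.size}")
    if np.ptp(x) == 0:
        raise DegeneratePredictorError(f"predictor {predictor!r} is constant")
    if np.ptp(y) == 0:
        raise DegenerateResponseError(
            f"response {response!r} is constant; R^2 undefined (SST = 0)"
        )
    exog = sm.add_constant(x)
    res = sm.OLS(y, exog).fit()
    diag = residual_diagnostics(res.resid, exog) if diagnostics else None
    # perfect fits have fvalue = inf / p 0 in statsmodels; keep as-is
    return RegressionFit(
        predictor=predictor,
        response=response,
        scope=scope,
        n=int(res.nobs),
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        f_statistic=float(res.fvalue),
        p_value=float(res.f_pvalue),
        slope_se=float(res.bse[1]),
        n_excluded=n_excluded,
        diagnostics=diag,
        notes=notes,
    )


def _require_density(response: str) -> None:
    if response not in DENSITY_INDICATORS:
        raise ValueError(
            f"response must be a density indicator {tuple(DENSITY_INDICATORS)}, got {response!r}"
        )


def pooled_panel_fit(panel: Panel, predictor: str, response: str) -> RegressionFit:
    """OLS over all county-year rows pooled across the study window.

    ``predictor`` is ``income`` or ``gdp_per_capita``; rows with a null
    predictor are excluded and counted in ``n_excluded``. County-years are
    treated as independent and incomes are nominal (no deflation), as noted
    on the fit.
    """
    if predictor not in ("income", "gdp_per_capita"):
        raise ValueError(f"pooled predictor must be income or gdp_per_capita, got {predictor!r}")
    _require_density(response)
    tab = county_density_table(panel)
    ok = tab[predictor].notna() & tab[response].notna()
    excluded = int((~ok).sum())
    sub = tab[ok]
    y0, y1 = panel.years[0], panel.years[-1]
    return ols_fit(
        sub[predictor],
        sub[response],
        predictor=predictor,
        response=response,
        scope=f"pooled {y0}-{y1}",
        n_excluded=excluded,
        notes=(
            "county-years pooled as independent observations (no panel correction)",
            "nominal currency values (no deflation)",
        ),
    )


def cross_section_fit(panel: Panel, year: int, predictor: str, response: str) -> RegressionFit:
    """Single-year OLS across counties (one row per county)."""
    _require_density(response)
    sl = county_density_table(panel)
    sl = sl[sl["year"] == year]
    if sl.empty:
        raise InsufficientDataError(f"year {year} not in panel")
    ok = sl[predictor].notna() & sl[response].notna()
    excluded = int((~ok).sum())
    sub = sl[ok]
    return ols_fit(
        sub[predictor],
        sub[response],
        predictor=predictor,
        response=response,
        scope=f"cross-section {year}",
        n_excluded=excluded,
    )


def regression_table(fits) -> pd.DataFrame:
    """One row per fit: coefficients, tests and diagnostic flags."""
    rows = []
    for f in fits:
        d = f.diagnostics
        rows.append(
            {
                "predictor": f.predictor,
                "response": f.response,
                "scope": f.scope,
                "n": f.n,
                "n_excluded": f.n_excluded,
                "slope": f.slope,
                "intercept": f.intercept,
                "r_squared": f.r_squared,
                "f_statistic": f.f_statistic,
                "p_value": f.p_value,
                "significant": f.significant,
                "normality_p": None if d is None else d.normality_p,
                "homoscedasticity_p": None if d is None else d.homoscedasticity_p,
                "durbin_watson": None if d is None else d.durbin_watson,
            }
        )
    return pd.DataFrame(rows)
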