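# Methods

## Problem and data model

The package analyses the allocation of three county-level health resources
— hospital beds, doctors (licensed physicians and physician assistants,
excluding village doctors), and registered nurses — across a province's
counties over an eleven-year window (2009–2019 by default). The unit of
analysis is the county-year. Counties carry a fixed five-way classification:
Yi, Zang (Tibetan) and other ethnic minority counties (OMC), plus
poverty-stricken (PSC) and non-minority (NMC) counties; for the Sichuan
classification the sizes are 12/32/23/32/82 (181 counties, 1991
county-years). Counties flagged both minority and poverty-stricken belong to
the minority category, so the scheme is mutually exclusive and exhaustive,
and membership is constant over time.

A panel is *balanced*: every county appears exactly once in every observed
year. Counts and population must be finite and non-negative (population
strictly positive), and all health practitioners (HP) must be at least
doctors + nurses, since HP additionally includes pharmacists and clinical
lab technicians. The three covariates — average practitioner income, GDP per
capita, county mean altitude — may be null; null rows are excluded from
regression fits only, never from densities or the Theil series.

## Indicators

Densities are per-1000 residents: `1000 * count / population`. Two staffing
ratios complement them: DNpB = (Doc_p1000 + Nur_p1000) / Bed_p1000
(staffing intensity per bed) and DN/HP = (Doc_p1000 + Nur_p1000) / HP_p1000
(clinical share of the workforce, ≤ 1 whenever the HP bound holds). Decadal
growth of an indicator H is the endpoint ratio (H_last − H_first)/H_first; a
zero starting density is an error, never a silent infinity.

Category-level values exist in two conventions, both exposed and labelled:

- `aggregate` (default): 1000 × (Σ counts)/(Σ population) over the
  category's counties — the population-weighted convention that also defines
  the province average;
- `mean_of_counties`: the unweighted mean of county-level values, which is
  what distributional growth summaries (mean growth per category) use.

County-share statistics (fraction of a category's counties with negative
growth, or growth strictly below the province aggregate's growth) use
county-level growth; ties with the province rate count as *not* below.

## Theil index and decomposition

Inequality is measured by the population-share-weighted mean log deviation

    TI = Σ_i p_i ln(p_i / y_i),

with p_i the county's population share and y_i its resource share. TI ≥ 0,
equals zero exactly under per-capita proportionality, and is invariant to
permutation, replication, and scaling of resources. For the five-way county
partition the index splits exactly:

    TI = TI_intra + TI_inter,
    TI_intra = Σ_j p_j TI_j,      TI_inter = Σ_j p_j ln(p_j / y_j),

where TI_j is the same index within category j computed from within-category
shares. The between-group term has the standard mean-log-deviation form;
only with that form is the additivity identity exact, which the test suite
enforces to 1e-12 against a brute-force evaluation of the county-level sum.
Contribution shares are TI_intra/TI and TI_inter/TI; at TI = 0 they are
reported as null (0/0 is undefined, not zero).

A county with positive population and zero resources makes the index
diverge. The default behaviour is to abort with a diagnostic naming the
counties; an optional `epsilon` parameter substitutes y_i ← max(y_i, ε) for
exploratory use only, because silent regularisation understates measured
inequality. Natural logarithms throughout.

## Regression analysis

Associations between densities and covariates are bivariate OLS fits
(statsmodels): pooled county-year fits for income and GDP per capita
(county-years treated as independent, incomes nominal — both recorded in the
fit's notes and the run manifest) and single-year cross-sectional fits for
altitude at the window's endpoints. Slope significance is the regression
F-test of zero slope at α = 0.05, which for simple OLS is identical to a
one-way ANOVA on the slope and to the two-sided slope t-test; the identities
F = (n−2)R²/(1−R²) and R² = r² are verified in tests at 1e-10. Residual
diagnostics are advisory and never block a fit: Shapiro–Wilk normality for
n ≤ 5000 (D'Agostino K² above, where Shapiro–Wilk loses calibration),
Breusch–Pagan homoscedasticity, and the Durbin–Watson statistic. The test
choices are this package's; degenerate all-zero residuals are reported as
not-applicable. No multiple-testing correction is applied across the nine
fitted models.

## Synthetic panel generator

The generator produces yearbook-shaped panels with known ground truth so
every stage is testable without the source data. Per county,

    density(year) = baseline_jr × frailty_c × (1 + g_c)^((year−y0)/span) × noise_cy,

with category baselines and growth targets per resource, log-normal county
frailty (mean 1), and i.i.d. log-normal year noise of configurable CV.
Counties flagged for negative growth receive a fixed negative rate (default
−5%); the unflagged counties' growth is solved so the category's
population-weighted aggregate growth equals the configured target exactly
before rounding. Optional linear altitude and income effects are added to
densities (centred on config-level reference values) for effect-recovery
tests.

Counts are integers, as in a yearbook. Plain per-county rounding biases
small-category aggregates by up to a count or two, which is enough to move a
rounded growth percentage by one point; counts are therefore rounded by the
largest-remainder method within each (category, resource, year), which keeps
every county within one count of its unrounded value while preserving the
category total to within half a count. Doctors/nurses/beds have a floor of
one count so the Theil series is finite by default; setting the floor to
zero deliberately exercises the divergence path. HP is derived from
doctors + nurses with a per-county pharmacist/technician share drawn
uniformly in [0.16, 0.31], so the HP-consistency invariant holds by
construction.

Randomness: one root seed; each county draws from a substream keyed by
(seed, CRC32(county id)), so adding a county never perturbs the others'
draws. Negative-growth flags are drawn from per-(resource, category)
substreams.

### Paper-like configuration

`paperlike_config()` packages the study conditions: 181 counties in the
five categories over 2009–2019, noise CV 0.05, and noise-free aggregate
growths equal to the headline percentages (beds: Yi 140 %, OMC 127 %,
NMC 121 %; doctors: Yi 20 %, Zang 11 %, NMC 61 %; nurses: Yi 240 %,
OMC 316 %, NMC 198 %), with negative doctor growth injected into one third
of Yi and half of Zang counties. Quantities the study reports only ordinally
are fixed calibration choices, set once: Zang grows slowest on every
indicator (beds 85 %, doctors 11 %, nurses 120 %), OMC and PSC sit above the
province mean (doctors 70 %/75 %, beds 127 %/130 %, nurses 316 %/260 %);
baseline densities put Yi lowest (about 60 % of the province average for
doctors in 2009) and NMC highest; mean altitudes are Yi 2139 m, Zang 3656 m,
OMC 1592 m, with PSC 1100 m and NMC 550 m as basin-county choices; county
populations are log-normal (σ = 0.35) with per-category medians (Yi 180 k,
Zang 60 k, OMC 150 k, PSC 300 k, NMC 550 k) reflecting that minority
counties hold a small fraction of provincial population; county frailty
σ = 0.35 reproduces a within-category inequality contribution above 70 % of
TI. Income and GDP levels grow at 9 %/10 % a year from category-specific
2009 levels. With these conditions the generated decade reproduces the
qualitative equity findings: the doctor Theil index rises (driven by its
between-category term) while the bed and nurse indices do not.

### What the generator does not emulate

Real yearbook panels have serially correlated shocks, policy jumps,
boundary revisions, within-category spatial structure, and reporting
artefacts; the generator's year noise is i.i.d. and county heterogeneity is
a single constant frailty per resource. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated statistical
conditions, not robustness to real-data pathologies. Real within-category
dispersion is unknown; the frailty SD is a documented calibration choice.

## Numerical choices and problem sizes

- Theil additivity and oracle equivalence are asserted at 1e-12; share-sum
  identities at 1e-12.
- The worked 4-county decomposition value 0.071920 is checked at the
  printed precision (1e-6); its full value is 0.0719205181….
- Growth recovery under noise CV 0.05 compares the across-20-seed mean of
  each category's recovered aggregate growth to the configured value within
  ±0.03 absolute; a single seed's estimate has sampling SD up to ~0.07 for
  the smallest category at the largest growth, so the across-seed mean is
  the quantity with a meaningful 0.03 band.
- Regression size/power simulations use a flat single-year configuration
  (equal baselines and a common altitude distribution across categories) so
  that the null really is a null — with category-specific baselines and
  altitudes, the category structure itself induces a true altitude–density
  association. Size uses 500 replicates (binomial 3σ band around 5 %), power
  100 replicates at a slope of 2 residual SDs per altitude range.
- Report bundles are written only after all stages succeed; manifests
  contain no timestamps so identical configs give byte-identical outputs.
  Reference comparison rounds the computed value per the stated rule
  (integer percent, fixed decimals) and requires exact agreement after
  rounding.

## Known limitations

- Pooled regressions ignore within-county correlation across years; slopes
  are unbiased under the generator's model but their nominal standard errors
  would be optimistic on strongly autocorrelated real data.
- The growth formula uses window endpoints only, as defined; it is
  sensitive to endpoint shocks (no trend smoothing is offered by design).
- The Theil variant is the population-share-weighted mean log deviation,
  implemented exactly as specified for this analysis; it is not the
  resource-weighted Theil-T, and no Gini/Atkinson alternatives are provided.
- Figures are not produced; CSV tables are the contract of the report
  pipeline.
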