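"""Exception hierarchy shared across the package."""

from __future__ import annotations


class HealthEquityError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(HealthEquityError):
    """An input file does not expose the required columns or labels."""


class PanelValidationError(HealthEquityError):
    """A panel violates structural invariants.

    Carries the full list of findings so callers can report every offending
    county/year coordinate, not just the first.
    """

    def __init__(self, findings):
        self.findings = list(findings)
        lines = "; ".join(str(f) for f in self.findings[:10])
        more = "" if len(self.findings) <= 10 else f" (+{len(self.findings) - 10} more)"
        super().__init__(f"panel validation failed: {lines}{more}")


class DomainError(HealthEquityError, ValueError):
    """An operation was called outside its mathematical domain."""


class UndefinedGrowthError(DomainError):
    """Growth rate requested with a zero baseline density."""


class TheilDivergenceError(DomainError):
    """Theil index diverges: a county has population but zero resources."""

    def __init__(self, counties, context: str = ""):
        self.counties = list(counties)
        where = f" in {context}" if context else ""
        super().__init__(
            f"Theil index diverges{where}: zero resources with positive "
            f"population in counties {self.counties}"
        )


class DegeneratePredictorError(DomainError):
    """OLS requested with a constant predictor."""


class DegenerateResponseError(DomainError):
    """OLS response is constant: total sum of squares is zero."""


class InsufficientDataError(DomainError):
    """Too few observations for the requested fit."""
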