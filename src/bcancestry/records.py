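"""Shared result containers used across the regression battery."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import math


@dataclass
class RegressionRecord:
    """One fitted term from any model in the battery.

    ``estimate`` is on the natural reporting scale of the model:
    years difference for linear models, an odds ratio for logistic
    models and a multiplicative rate ratio for the negative-binomial
    TMB model.  ``ci_low``/``ci_high`` bound the 95% Wald interval on
    the same scale.
    """

    outcome: str
    term: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    model_kind: str  # "linear" | "logistic" | "negbin"
    n_used: int
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged and not (
            math.isnan(self.estimate)
            or (self.ci_low <= self.estimate <= self.ci_high)
        ):
            raise ValueError(
                f"confidence interval [{self.ci_low}, {self.ci_high}] does not "
                f"bracket estimate {self.estimate} for term {self.term!r}"
            )
        if self.converged and not math.isnan(self.p) and not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside [0, 1]")

    def covers(self, value: float) -> bool:
        """True if ``value`` lies inside the confidence interval."""
        return self.ci_low <= value <= self.ci_high

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScreeningWindow:
    """An ancestry-specific [lower, upper] age interval with coverage."""

    ancestry: str
    lower: int
    upper: int
    covered: int
    total: int

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"window lower bound {self.lower} must be < upper {self.upper}")
        if not 0 <= self.covered <= self.total:
            raise ValueError("covered count outside [0, total]")

    @property
    def coverage(self) -> float:
        """Fraction of ages falling inside the window (inclusive ends)."""
        return self.covered / self.total

    @property
    def percentage(self) -> float:
        """Coverage as a percentage rounded to one decimal place."""
        return round(100.0 * self.covered / self.total, 1)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coverage"] = self.coverage
        d["percentage"] = self.percentage
        return d


@dataclass
class LRTResult:
    """Nested likelihood-ratio test outcome."""

    outcome: str
    statistic: Optional[float]
    df: int
    p: Optional[float]
    n_used: int
    tested: bool = True
    note: str = ""

    def to_dict(self) -> dict:
        return asdict(self)
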