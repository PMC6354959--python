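"""Shared result containers and small numerical helpers.

Every estimator in the package returns a :class:`CausalEstimate`: a point
estimate on its estimation scale (log-odds of outcome per exposure unit for
the forward direction, exposure units per log-odds for the reverse), its
standard error, a 95% Wald confidence interval and a two-sided normal
p-value.  Confidence intervals use the fixed multiplier 1.96 throughout;
rounding happens only at the reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy import stats

#: fixed 95% CI multiplier used package-wide
Z95 = 1.96


def two_sided_p(beta: float, se: float) -> float:
    """Two-sided normal p-value for beta/se; p=1 when beta is 0."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return min(max(p, 5e-324), 1.0)


@dataclass(frozen=True)
class CausalEstimate:
    """A method-labelled causal (or observational) effect estimate."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    method: str
    unit: str
    n_variants: int | None = None
    n_individuals: int | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be positive")
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")

    @classmethod
    def from_beta_se(
        cls,
        beta: float,
        se: float,
        method: str,
        unit: str,
        n_variants: int | None = None,
        n_individuals: int | None = None,
    ) -> "CausalEstimate":
        return cls(
            beta=float(beta),
            se=float(se),
            ci_low=float(beta - Z95 * se),
            ci_high=float(beta + Z95 * se),
            p=two_sided_p(beta, se),
            method=method,
            unit=unit,
            n_variants=n_variants,
            n_individuals=n_individuals,
        )

    def scaled(self, factor: float, unit: str | None = None) -> "CausalEstimate":
        """Rescale beta, se and CI by a positive factor (unit conversion)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return replace(
            self,
            beta=self.beta * factor,
            se=self.se * factor,
            ci_low=self.ci_low * factor,
            ci_high=self.ci_high * factor,
            unit=unit if unit is not None else self.unit,
        )

    @property
    def odds_ratio(self) -> float:
        """exp(beta); meaningful only on a log-odds scale."""
        return math.exp(self.beta)

    def or_ci(self) -> tuple[float, float, float]:
        return (math.exp(self.beta), math.exp(self.ci_low), math.exp(self.ci_high))

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "method": self.method,
            "unit": self.unit,
            "n_variants": self.n_variants,
            "n_individuals": self.n_individuals,
        }


def format_or(beta: float, digits: int = 2) -> str:
    """Report-layer odds-ratio formatting: beta 0.08255 -> '1.09'."""
    return f"{math.exp(beta):.{digits}f}"
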