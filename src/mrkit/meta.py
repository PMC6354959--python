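"""Meta-analytic pooling and scale conversions.

Fixed-effect and DerSimonian–Laird random-effects inverse-variance pooling
with Cochran's Q, I² and τ²; the classical Egger small-study (publication
bias) regression; and the scale conversions used throughout the analysis:

* SMD → OR via the logistic scaling factor 1.81 (≈ π/√3),
* per-log-odds effects × ln 2 ≈ 0.693 to "per doubling of odds",
* SE recovery from a printed OR and log-symmetric 95% CI.

All pooling operates on (beta, se) pairs in full precision; odds-ratio
rounding is a reporting concern.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .core import Z95, CausalEstimate, two_sided_p


@dataclass(frozen=True)
class ScaleConstants:
    """Fixed conversion constants, exposed read-only.

    logistic_factor converts standardized mean differences to log odds
    ratios; doubling_factor (= ln 2) converts per-log-odds effects to
    per-doubling-of-odds; ci_width_z is the width of a 95% normal CI in SE
    units; default_exposure_sd is the median BMI SD (kg/m²) used to rescale
    per-SD estimates from inverse-normal-transformed GWAS scales.
    """

    logistic_factor: float = 1.81
    doubling_factor: float = 0.693
    ci_width_z: float = 3.92
    default_exposure_sd: float = 4.6


SCALE = ScaleConstants()


@dataclass(frozen=True)
class MetaInput:
    """One component estimate to be pooled."""

    label: str
    beta: float
    se: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.label}: se must be positive")


@dataclass(frozen=True)
class MetaResult:
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    q: float
    df: int
    i_squared: float  # percent
    tau_squared: float
    model: str  # "fixed" | "random"

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "q": self.q,
            "df": self.df,
            "i_squared": self.i_squared,
            "tau_squared": self.tau_squared,
            "model": self.model,
        }


def se_from_or_ci(label: str, or_point: float, ci_low: float, ci_high: float) -> MetaInput:
    """Recover (log-OR, SE) from a printed OR and log-symmetric 95% CI.

    se = (ln U − ln L) / 3.92.  A degenerate CI (U == L) yields se=0, which
    MetaInput rejects — such records cannot be pooled.
    """
    if not (0 < ci_low <= or_point <= ci_high):
        raise ValueError(
            f"{label}: require 0 < ci_low <= OR <= ci_high, got "
            f"({ci_low}, {or_point}, {ci_high})"
        )
    beta = math.log(or_point)
    se = (math.log(ci_high) - math.log(ci_low)) / SCALE.ci_width_z
    return MetaInput(label=label, beta=beta, se=se)


def _pool(betas: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    wsum = weights.sum()
    beta = float((weights * betas).sum() / wsum)
    se = float(wsum ** -0.5)
    return beta, se


def _heterogeneity(betas: np.ndarray, ses: np.ndarray) -> tuple[float, int, float]:
    """Cochran's Q against the fixed-effect pooled mean, df, and I² (%)."""
    w = ses ** -2.0
    beta_fe = (w * betas).sum() / w.sum()
    q = float((w * (betas - beta_fe) ** 2).sum())
    df = len(betas) - 1
    i2 = 0.0 if q <= 0 else max(0.0, (q - df) / q) * 100.0
    return q, df, i2


def fixed_effect_meta(inputs: list[MetaInput]) -> MetaResult:
    """Inverse-variance fixed-effect pooling with Q and I²."""
    if len(inputs) < 2:
        raise ValueError("fixed_effect_meta needs at least 2 inputs")
    betas = np.array([x.beta for x in inputs], dtype=float)
    ses = np.array([x.se for x in inputs], dtype=float)
    w = ses ** -2.0
    beta, se = _pool(betas, w)
    q, df, i2 = _heterogeneity(betas, ses)
    return MetaResult(
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        p=two_sided_p(beta, se),
        q=q,
        df=df,
        i_squared=i2,
        tau_squared=0.0,
        model="fixed",
    )


def _tau2_dl(betas: np.ndarray, ses: np.ndarray) -> float:
    """DerSimonian–Laird moment estimator, truncated at zero."""
    w = ses ** -2.0
    q, df, _ = _heterogeneity(betas, ses)
    denom = w.sum() - (w ** 2).sum() / w.sum()
    if denom <= 0:
        return 0.0
    return max(0.0, (q - df) / denom)


def _tau2_reml(betas: np.ndarray, ses: np.ndarray) -> float:
    """REML τ² by direct restricted-likelihood maximization."""
    v = ses ** 2.0

    def neg_restricted_ll(tau2: float) -> float:
        wi = 1.0 / (v + tau2)
        mu = (wi * betas).sum() / wi.sum()
        return 0.5 * (
            np.log(v + tau2).sum()
            + math.log(wi.sum())
            + float((wi * (betas - mu) ** 2).sum())
        )

    upper = max(_tau2_dl(betas, ses) * 10.0, betas.var() * 10.0, 1e-6)
    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(0.0, upper), method="bounded",
        options={"xatol": 1e-12},
    )
    return max(0.0, float(res.x))


def random_effects_meta(inputs: list[MetaInput], method: str = "dl") -> MetaResult:
    """Random-effects pooling; τ² by DerSimonian–Laird (default) or REML."""
    if len(inputs) < 2:
        raise ValueError("random_effects_meta needs at least 2 inputs")
    if method not in ("dl", "reml"):
        raise ValueError("method must be 'dl' or 'reml'")
    betas = np.array([x.beta for x in inputs], dtype=float)
    ses = np.array([x.se for x in inputs], dtype=float)
    tau2 = _tau2_dl(betas, ses) if method == "dl" else _tau2_reml(betas, ses)
    w = 1.0 / (ses ** 2 + tau2)
    beta, se = _pool(betas, w)
    q, df, i2 = _heterogeneity(betas, ses)
    return MetaResult(
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        p=two_sided_p(beta, se),
        q=q,
        df=df,
        i_squared=i2,
        tau_squared=float(tau2),
        model="random",
    )


@dataclass(frozen=True)
class EggerBiasTest:
    """Small-study (publication bias) Egger regression result."""

    intercept: float
    se: float
    p: float


def small_study_egger_test(inputs: list[MetaInput]) -> EggerBiasTest:
    """Classical Egger test: OLS of β_i/se_i on 1/se_i; intercept ≠ 0
    indicates small-study (funnel) asymmetry.  p is two-sided on the t
    distribution with n−2 df."""
    if len(inputs) < 3:
        raise ValueError("small_study_egger_test needs at least 3 inputs")
    betas = np.array([x.beta for x in inputs], dtype=float)
    ses = np.array([x.se for x in inputs], dtype=float)
    z = betas / ses
    precision = 1.0 / ses
    if np.ptp(precision) < 1e-12 * np.abs(precision).max():
        warnings.warn(
            "all standard errors equal: precision is collinear with the "
            "intercept; Egger intercept is weakly identified",
            stacklevel=2,
        )
    design = sm.add_constant(precision)
    fit = sm.OLS(z, design).fit()
    return EggerBiasTest(
        intercept=float(fit.params[0]),
        se=float(fit.bse[0]),
        p=float(fit.pvalues[0]),
    )


def smd_to_or(smd: float, sd_scale: float) -> float:
    """OR = exp(1.81 × sd_scale × SMD)."""
    if sd_scale <= 0:
        raise ValueError("sd_scale must be positive")
    return math.exp(SCALE.logistic_factor * sd_scale * smd)


def or_to_smd(odds_ratio: float, sd_scale: float) -> float:
    """Inverse of :func:`smd_to_or`."""
    if sd_scale <= 0:
        raise ValueError("sd_scale must be positive")
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    return math.log(odds_ratio) / (SCALE.logistic_factor * sd_scale)


def doubling_odds_scale(estimate: CausalEstimate) -> CausalEstimate:
    """Convert an effect per unit log-odds to per doubling of odds (×0.693)."""
    if "log-odds" not in estimate.unit:
        raise ValueError(
            f"doubling_odds_scale expects an estimate per unit log-odds, "
            f"got unit '{estimate.unit}'"
        )
    out = estimate.scaled(
        SCALE.doubling_factor,
        unit=estimate.unit.replace("log-odds", "doubling of odds"),
    )
    # scaling is linear so the p-value is unchanged
    return replace(out, p=estimate.p)


# ---------------------------------------------------------------------------
# I/O and reporting helpers

META_CSV_COLUMNS = ["label", "beta", "se"]
OR_CI_CSV_COLUMNS = ["label", "or", "ci_low", "ci_high"]


def read_meta_inputs(path) -> list[MetaInput]:
    """Read a (label, beta, se) CSV."""
    df = pd.read_csv(path)
    missing = [c for c in META_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"meta-input CSV missing columns: {missing}")
    return [MetaInput(str(r.label), float(r.beta), float(r.se)) for r in df.itertuples()]


def read_or_ci_inputs(path) -> list[MetaInput]:
    """Read a (label, or, ci_low, ci_high) CSV and convert to (beta, se)."""
    df = pd.read_csv(path)
    missing = [c for c in OR_CI_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"OR-CI CSV missing columns: {missing}")
    return [
        se_from_or_ci(str(row["label"]), float(row["or"]), float(row["ci_low"]), float(row["ci_high"]))
        for _, row in df.iterrows()
    ]


def forest_table(inputs: list[MetaInput], result: MetaResult, or_scale: bool = True) -> str:
    """Fixed-width text forest table of the components and the pooled row."""
    lines = [f"{'label':<24}{'estimate':>10}{'ci_low':>10}{'ci_high':>10}"]

    def fmt(b: float, lo: float, hi: float) -> tuple[str, str, str]:
        if or_scale:
            return f"{math.exp(b):.2f}", f"{math.exp(lo):.2f}", f"{math.exp(hi):.2f}"
        return f"{b:.3f}", f"{lo:.3f}", f"{hi:.3f}"

    for x in inputs:
        e, lo, hi = fmt(x.beta, x.beta - Z95 * x.se, x.beta + Z95 * x.se)
        lines.append(f"{x.label:<24}{e:>10}{lo:>10}{hi:>10}")
    e, lo, hi = fmt(result.beta, result.ci_low, result.ci_high)
    lines.append(
        f"{'pooled (' + result.model + ')':<24}{e:>10}{lo:>10}{hi:>10}"
        f"   p={result.p:.2e}  I2={result.i_squared:.1f}%"
    )
    return "\n".join(lines)
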