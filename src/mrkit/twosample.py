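"""Summary-statistic (two-sample) causal estimators.

Given harmonized per-variant exposure associations γ_j (SE σ_γj) and
outcome associations Γ_j (SE σ_Γj), the per-variant Wald ratio is
r_j = Γ_j/γ_j with first-order SE σ_Γj/|γ_j|.  Estimators:

* IVW — inverse-variance-weighted mean of the ratios, equivalently the
  weighted regression of Γ on γ through the origin; fixed-effect SE by
  default, multiplicative random-effects inflation behind a flag.
* MR-Egger — weighted regression of Γ on γ with an intercept (average
  directional pleiotropy); slope is causal under the InSIDE assumption.
* Weighted median — consistent when ≥50% of the weight is from valid
  instruments; SE by parametric bootstrap.
* Weighted mode (MBE) — argmax of a weighted normal-kernel density over
  the ratios; consistent when the largest weight class is valid.

Stochastic estimators require an explicit seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import CausalEstimate, two_sided_p
from .instruments import InstrumentRecord, InstrumentSet

#: default number of parametric-bootstrap replicates for SEs
BOOTSTRAP_REPS = 1000
#: grid sizes for the kernel-density argmax (point estimate / bootstrap)
MBE_GRID = 32768
MBE_BOOTSTRAP_GRID = 2048


@dataclass(frozen=True)
class RatioEstimate:
    """Per-variant Wald ratio with inverse-variance weight."""

    variant_id: str
    ratio: float
    se: float

    @property
    def weight(self) -> float:
        return self.se ** -2


def _ratio_se(record: InstrumentRecord, second_order: bool = False) -> float:
    se2 = record.Gamma_se ** 2 / record.gamma ** 2
    if second_order:
        se2 += record.Gamma ** 2 * record.gamma_se ** 2 / record.gamma ** 4
    return math.sqrt(se2)


def ratio_estimates(iset: InstrumentSet, second_order: bool = False) -> list[RatioEstimate]:
    out = []
    for rec in iset.records:
        if rec.gamma == 0:
            raise ZeroDivisionError(f"{rec.variant_id}: gamma is 0")
        out.append(
            RatioEstimate(rec.variant_id, rec.Gamma / rec.gamma,
                          _ratio_se(rec, second_order))
        )
    return out


def _unit(iset: InstrumentSet) -> str:
    per = "SD" if iset.exposure_scale == "sd-unit" else "unit"
    return f"log-odds of {iset.outcome} per exposure {per}"


def wald_ratio(record: InstrumentRecord, second_order: bool = False) -> CausalEstimate:
    """Single-variant causal estimate Γ/γ with first-order SE σ_Γ/|γ|."""
    if record.gamma == 0:
        raise ZeroDivisionError(f"{record.variant_id}: gamma is 0")
    return CausalEstimate.from_beta_se(
        record.Gamma / record.gamma, _ratio_se(record, second_order),
        method="Wald ratio", unit="log-odds of outcome per exposure unit",
        n_variants=1,
    )


def ivw(
    iset: InstrumentSet,
    random_effects: bool = False,
    second_order: bool = False,
) -> CausalEstimate:
    """Inverse-variance-weighted estimate over ≥2 instruments.

    beta = Σ w_j r_j / Σ w_j with w_j = (γ_j/σ_Γj)²; the fixed-effect SE is
    (Σ w_j)^(−1/2); with ``random_effects`` the SE is inflated by
    max(1, √(Q/df)) (multiplicative random-effects model).
    """
    if len(iset) < 2:
        raise ValueError("IVW needs >= 2 instruments; use wald_ratio for one")
    ratios = ratio_estimates(iset, second_order)
    r = np.array([x.ratio for x in ratios])
    w = np.array([x.weight for x in ratios])
    beta = float((w * r).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    if random_effects:
        q = float((w * (r - beta) ** 2).sum())
        df = len(r) - 1
        se *= max(1.0, math.sqrt(q / df))
    return CausalEstimate.from_beta_se(
        beta, se, method="IVW" + (" (mult. RE)" if random_effects else ""),
        unit=_unit(iset), n_variants=len(iset),
    )


@dataclass(frozen=True)
class EggerResult:
    slope: CausalEstimate
    intercept: CausalEstimate


def egger(iset: InstrumentSet) -> EggerResult:
    """MR-Egger: weighted regression of Γ on γ with intercept.

    Instruments are oriented so every γ_j ≥ 0 (flipping (γ_j, Γ_j) jointly,
    which leaves the model invariant).  Weights are σ_Γj⁻²; SEs use the
    conventional multiplicative random-effects scale floored at 1.
    """
    if len(iset) < 3:
        raise ValueError("MR-Egger needs >= 3 instruments")
    g = iset.gamma.copy()
    G = iset.Gamma.copy()
    flip = g < 0
    g[flip] *= -1
    G[flip] *= -1
    w = iset.Gamma_se ** -2.0

    x = np.column_stack([np.ones_like(g), g])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * G)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = G - x @ coef
    dof = len(g) - 2
    scale = max(1.0, float((w * resid ** 2).sum() / dof)) if dof > 0 else 1.0
    cov = np.linalg.inv(xtwx) * scale
    se = np.sqrt(np.diag(cov))

    slope = CausalEstimate.from_beta_se(
        coef[1], se[1], method="MR-Egger slope", unit=_unit(iset),
        n_variants=len(iset),
    )
    intercept = CausalEstimate.from_beta_se(
        coef[0], se[0], method="MR-Egger intercept",
        unit="average directional pleiotropy (log-odds per allele)",
        n_variants=len(iset),
    )
    return EggerResult(slope=slope, intercept=intercept)


def _weighted_median(r: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median with cumulative weights standardized as
    s_j = (Σ_{i≤j} w_i − w_j/2) / Σ w_i."""
    order = np.argsort(r)
    r = r[order]
    w = w[order]
    s = (np.cumsum(w) - 0.5 * w) / w.sum()
    return float(np.interp(0.5, s, r))


def weighted_median(
    iset: InstrumentSet,
    bootstrap_reps: int = BOOTSTRAP_REPS,
    seed: int | None = None,
    second_order: bool = False,
) -> CausalEstimate:
    """Weighted-median estimator with parametric-bootstrap SE."""
    if len(iset) < 3:
        raise ValueError("weighted median needs >= 3 instruments")
    ratios = ratio_estimates(iset, second_order)
    r = np.array([x.ratio for x in ratios])
    w = np.array([x.weight for x in ratios])
    beta = _weighted_median(r, w)
    se = _bootstrap_se(iset, bootstrap_reps, seed, second_order,
                       lambda rr, ww: _weighted_median(rr, ww))
    return CausalEstimate.from_beta_se(
        beta, se, method="weighted median", unit=_unit(iset),
        n_variants=len(iset),
    )


def weighted_median_point(iset: InstrumentSet, second_order: bool = False) -> float:
    """Weighted-median point estimate only (no bootstrap), for simulation
    studies where the SE is not needed."""
    ratios = ratio_estimates(iset, second_order)
    return _weighted_median(np.array([x.ratio for x in ratios]),
                            np.array([x.weight for x in ratios]))


def _silverman_bandwidth(r: np.ndarray) -> float:
    """Modified Silverman rule: 0.9·min(SD, normalized MAD)·n^(−1/5)."""
    sd = r.std(ddof=1)
    mad = stats.median_abs_deviation(r, scale="normal")
    s = min(sd, mad) if mad > 0 else sd
    if s <= 0:
        return 0.0
    return 0.9 * s * len(r) ** -0.2


def _mode_argmax(r: np.ndarray, w: np.ndarray, bandwidth_factor: float,
                 n_grid: int) -> float:
    h = _silverman_bandwidth(r) * bandwidth_factor
    if h <= 0:  # all ratios identical (or degenerate spread)
        return float(np.average(r, weights=w))
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, n_grid)
    dens = (w[:, None] * np.exp(-0.5 * ((grid[None, :] - r[:, None]) / h) ** 2)).sum(axis=0)
    return float(grid[np.argmax(dens)])


def mode_based_point(
    iset: InstrumentSet,
    bandwidth_factor: float = 1.0,
    second_order: bool = False,
    n_grid: int = MBE_GRID,
) -> float:
    """Mode-based point estimate only (no bootstrap)."""
    ratios = ratio_estimates(iset, second_order)
    return _mode_argmax(np.array([x.ratio for x in ratios]),
                        np.array([x.weight for x in ratios]),
                        bandwidth_factor, n_grid)


def mode_based_estimate(
    iset: InstrumentSet,
    bandwidth_factor: float = 1.0,
    bootstrap_reps: int = BOOTSTRAP_REPS,
    seed: int | None = None,
    second_order: bool = False,
) -> CausalEstimate:
    """Weighted mode-based estimate: argmax of the σ⁻²-weighted normal-kernel
    density over the per-variant ratios, bandwidth by the modified Silverman
    rule × ``bandwidth_factor``; SE by parametric bootstrap."""
    if len(iset) < 3:
        raise ValueError("mode-based estimate needs >= 3 instruments")
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be positive")
    ratios = ratio_estimates(iset, second_order)
    r = np.array([x.ratio for x in ratios])
    w = np.array([x.weight for x in ratios])
    beta = _mode_argmax(r, w, bandwidth_factor, MBE_GRID)
    se = _bootstrap_se(iset, bootstrap_reps, seed, second_order,
                       lambda rr, ww: _mode_argmax(rr, ww, bandwidth_factor,
                                                   MBE_BOOTSTRAP_GRID))
    return CausalEstimate.from_beta_se(
        beta, se, method="weighted MBE", unit=_unit(iset),
        n_variants=len(iset),
    )


def _bootstrap_se(iset, reps, seed, second_order, point_fn) -> float:
    """Parametric bootstrap: resample (γ_j, Γ_j) from their SEs, recompute
    the point estimate, take the SD."""
    if reps <= 0:
        raise ValueError("bootstrap_reps must be positive; use the *_point "
                         "functions when no SE is needed")
    if seed is None:
        raise ValueError("a seed is required for bootstrap SEs")
    rng = np.random.default_rng(seed)
    g0, gse = iset.gamma, iset.gamma_se
    G0, Gse = iset.Gamma, iset.Gamma_se
    est = np.empty(reps)
    for b in range(reps):
        g = g0 + gse * rng.standard_normal(len(g0))
        G = G0 + Gse * rng.standard_normal(len(G0))
        g = np.where(g == 0, 1e-300, g)
        r = G / g
        se_r = np.abs(Gse / g)
        if second_order:
            se_r = np.sqrt(se_r ** 2 + G ** 2 * gse ** 2 / g ** 4)
        est[b] = point_fn(r, se_r ** -2.0)
    return float(est.std(ddof=1))


def convert_per_sd_to_per_unit(estimate: CausalEstimate, sd: float) -> CausalEstimate:
    """Rescale an effect per exposure SD to per raw exposure unit
    (beta and SE divided by ``sd``; CI recomputed by scaling)."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    out = estimate.scaled(1.0 / sd, unit=estimate.unit.replace("SD", "unit"))
    return out


def all_estimates(
    iset: InstrumentSet,
    seed: int,
    bootstrap_reps: int = BOOTSTRAP_REPS,
    bandwidth_factor: float = 1.0,
) -> dict[str, CausalEstimate]:
    """Run every two-sample estimator applicable to the set size."""
    out: dict[str, CausalEstimate] = {}
    if len(iset) == 1:
        out["wald_ratio"] = wald_ratio(iset.records[0])
        return out
    out["ivw"] = ivw(iset)
    if len(iset) >= 3:
        eg = egger(iset)
        out["egger_slope"] = eg.slope
        out["egger_intercept"] = eg.intercept
        out["weighted_median"] = weighted_median(
            iset, bootstrap_reps=bootstrap_reps, seed=seed)
        out["mode_based"] = mode_based_estimate(
            iset, bandwidth_factor=bandwidth_factor,
            bootstrap_reps=bootstrap_reps, seed=seed + 1)
    return out
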