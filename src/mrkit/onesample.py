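"""Individual-level causal estimation.

Forward direction (continuous exposure → binary disease): two-stage
predictor substitution (TSPS).  Stage 1 regresses the exposure on the
instrument among controls only (restricting the first stage to controls
avoids contamination of the instrument–exposure association by any effect
of the disease on the exposure); fitted values are predicted for everyone
and the disease is regressed on them by logistic regression.  The reported
SE is the stage-2 SE of the substituted regressor, which equals the first
term of the delta-method expansion for the variance of the ratio Γ̂/γ̂; a
second-order correction adding β̂²·Var(γ̂)/γ̂² is available behind a flag.

Reverse direction (binary disease → continuous outcome): two-stage least
squares using all individuals, with the genetically predicted disease
either on the log-odds scale (logistic first stage; combine with the
×0.693 doubling-of-odds conversion for interpretation) or as a linear 0–1
variable (linear-probability first stage; the estimate is then the
case-versus-control difference in the outcome attributable to genetic
liability).

Also here: the plain observational logistic regression, the
confounder-vs-score scan, and the variance-heterogeneity check across
genetic-score levels.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import CausalEstimate
from .meta import MetaInput, random_effects_meta
from .simulate import Cohort

logger = logging.getLogger(__name__)

#: |t| threshold below which a first-stage slope is declared too weak
WEAK_T = 2.0


class WeakInstrumentError(RuntimeError):
    pass


def _covariate_matrix(cohort: Cohort, covariates: tuple[str, ...]) -> pd.DataFrame:
    """Covariate design columns; categorical columns expand to indicators."""
    if not covariates:
        return pd.DataFrame(index=range(cohort.n))
    missing = [c for c in covariates if c not in cohort.covariates.columns]
    if missing:
        raise ValueError(f"unknown covariate column(s): {missing}")
    sub = cohort.covariates[list(covariates)]
    return pd.get_dummies(sub, drop_first=True, dtype=float).reset_index(drop=True)


def _resolve_instrument(cohort: Cohort, instrument) -> np.ndarray:
    """Accept a score vector or a variant id referring to a dosage column."""
    if isinstance(instrument, str):
        if instrument not in cohort.dosages.columns:
            raise ValueError(f"variant {instrument!r} not in dosage matrix")
        return cohort.dosages[instrument].to_numpy(dtype=float)
    z = np.asarray(instrument, dtype=float)
    if z.shape != (cohort.n,):
        raise ValueError("instrument vector length must equal cohort size")
    return z


def tsps_forward(
    cohort: Cohort,
    instrument,
    covariates: tuple[str, ...] = (),
    second_order: bool = False,
) -> CausalEstimate:
    """Two-stage predictor substitution for a binary outcome.

    ``instrument`` is a per-individual score (array) or a single variant id.
    Returns the log-odds of the outcome per exposure unit.
    """
    y = cohort.outcome
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    z = _resolve_instrument(cohort, instrument)
    cov = _covariate_matrix(cohort, covariates)

    controls = y == 0
    if not controls.any():
        raise ValueError("no controls available for the first stage")
    if z[controls].std() == 0:
        raise ValueError("instrument is constant among controls")

    design = sm.add_constant(
        pd.concat([pd.Series(z, name="instrument"), cov], axis=1), has_constant="add"
    ).astype(float)
    stage1 = sm.OLS(cohort.exposure[controls], design.loc[controls]).fit()
    gamma_hat = stage1.params["instrument"]
    gamma_se = stage1.bse["instrument"]
    if abs(gamma_hat / gamma_se) < WEAK_T:
        raise WeakInstrumentError(
            f"first-stage slope indistinguishable from 0 "
            f"(|t|={abs(gamma_hat / gamma_se):.2f} < {WEAK_T})")

    fitted = design.to_numpy() @ stage1.params.to_numpy()
    design2 = sm.add_constant(
        pd.concat([pd.Series(fitted, name="fitted_exposure"), cov], axis=1),
        has_constant="add",
    ).astype(float)
    stage2 = sm.Logit(y, design2).fit(disp=0, method="newton", tol=1e-10, maxiter=200)
    beta = stage2.params["fitted_exposure"]
    se = stage2.bse["fitted_exposure"]
    if second_order:
        se = math.sqrt(se ** 2 + beta ** 2 * (gamma_se / gamma_hat) ** 2)

    return CausalEstimate.from_beta_se(
        beta, se, method="TSPS",
        unit="log-odds of outcome per exposure unit",
        n_variants=1 if isinstance(instrument, str) else None,
        n_individuals=cohort.n,
    )


def per_variant_onesample(
    cohort: Cohort,
    variant_ids: list[str] | None = None,
    covariates: tuple[str, ...] = (),
    second_order: bool = False,
) -> CausalEstimate:
    """TSPS per instrument variant, pooled by random-effects meta-analysis.

    Variants whose first stage is too weak are skipped (logged); at least
    two estimable variants are required.
    """
    ids = variant_ids if variant_ids is not None else cohort.variant_ids
    if len(ids) < 2:
        raise ValueError("need at least 2 variants")
    inputs = []
    for vid in ids:
        try:
            est = tsps_forward(cohort, vid, covariates, second_order)
        except (WeakInstrumentError, ValueError) as exc:
            logger.info("per-variant TSPS: skipping %s (%s)", vid, exc)
            continue
        inputs.append(MetaInput(vid, est.beta, est.se))
    if len(inputs) < 2:
        raise ValueError("fewer than 2 estimable variants")
    pooled = random_effects_meta(inputs)
    return CausalEstimate.from_beta_se(
        pooled.beta, pooled.se, method="per-variant TSPS + RE pooling",
        unit="log-odds of outcome per exposure unit",
        n_variants=len(inputs), n_individuals=cohort.n,
    )


def tsls_reverse(
    cohort: Cohort,
    instrument,
    covariates: tuple[str, ...] = (),
    exposure_coding: str = "log-odds",
) -> CausalEstimate:
    """Two-stage least squares with the binary disease as the exposure.

    ``exposure_coding='log-odds'`` uses a logistic first stage and returns
    the change in the continuous outcome per unit log-odds of disease;
    ``'linear01'`` uses a linear-probability first stage and returns the
    case-versus-control outcome difference attributable to genetic
    liability.
    """
    if exposure_coding not in ("log-odds", "linear01"):
        raise ValueError("exposure_coding must be 'log-odds' or 'linear01'")
    d = cohort.outcome  # binary disease plays the exposure role
    if d.min() == d.max():
        raise ValueError("disease status must contain both classes")
    z = _resolve_instrument(cohort, instrument)
    cov = _covariate_matrix(cohort, covariates)
    design1 = sm.add_constant(
        pd.concat([pd.Series(z, name="instrument"), cov], axis=1), has_constant="add"
    ).astype(float)

    if exposure_coding == "log-odds":
        stage1 = sm.Logit(d, design1).fit(disp=0, method="newton", tol=1e-10, maxiter=200)
        fitted = design1.to_numpy() @ stage1.params.to_numpy()  # linear predictor
        unit = "outcome units per unit log-odds of disease"
    else:
        stage1 = sm.OLS(d.astype(float), design1).fit()
        fitted = stage1.fittedvalues.to_numpy()
        unit = "outcome difference, cases vs controls (genetic liability)"
    g1 = stage1.params["instrument"]
    g1_se = stage1.bse["instrument"]
    if abs(g1 / g1_se) < WEAK_T:
        raise WeakInstrumentError(
            f"first-stage slope indistinguishable from 0 (|t|={abs(g1 / g1_se):.2f})")

    design2 = sm.add_constant(
        pd.concat([pd.Series(fitted, name="fitted_liability"), cov], axis=1),
        has_constant="add",
    ).astype(float)
    stage2 = sm.OLS(cohort.exposure, design2).fit()
    return CausalEstimate.from_beta_se(
        stage2.params["fitted_liability"], stage2.bse["fitted_liability"],
        method=f"TSLS ({exposure_coding})", unit=unit,
        n_individuals=cohort.n,
    )


def observational_assoc(
    cohort: Cohort, covariates: tuple[str, ...] = ()
) -> CausalEstimate:
    """Covariate-adjusted logistic regression of the outcome on the measured
    exposure (the confounded, non-genetic association)."""
    y = cohort.outcome
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    cov = _covariate_matrix(cohort, covariates)
    df = pd.concat([pd.Series(cohort.exposure, name="exposure"), cov], axis=1)
    complete = df.notna().all(axis=1).to_numpy()
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("observational_assoc: dropped %d incomplete rows", n_dropped)
    design = sm.add_constant(df.loc[complete], has_constant="add").astype(float)
    try:
        fit = sm.Logit(y[complete], design).fit(disp=0, method="newton", tol=1e-10, maxiter=200)
    except Exception as exc:  # statsmodels raises on perfect separation
        raise ValueError(f"logistic fit failed (possible separation): {exc}") from exc
    if not np.isfinite(fit.bse["exposure"]):
        raise ValueError("logistic fit degenerate (separation suspected)")
    return CausalEstimate.from_beta_se(
        fit.params["exposure"], fit.bse["exposure"],
        method="observational logistic",
        unit="log-odds of outcome per exposure unit",
        n_individuals=int(complete.sum()),
    )


def confounder_scan(score: np.ndarray, confounders: pd.DataFrame) -> pd.DataFrame:
    """Univariable regression of each putative confounder on the genetic
    score (an instrument-validity diagnostic: under valid instruments the
    score should be unrelated to confounders).

    Categorical columns expand to indicator contrasts; degenerate columns
    are reported and skipped.  ``score`` is expected standardized.
    """
    score = np.asarray(score, dtype=float)
    if abs(score.mean()) > 1e-6 or abs(score.std() - 1.0) > 1e-6:
        raise ValueError("score must be standardized (mean 0, SD 1)")
    rows = []
    design = sm.add_constant(pd.Series(score, name="score"))
    for col in confounders.columns:
        series = confounders[col]
        if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            expanded = pd.get_dummies(series, prefix=col, drop_first=True, dtype=float)
        else:
            expanded = series.to_frame()
        for name in expanded.columns:
            yv = expanded[name].to_numpy(dtype=float)
            if np.nanstd(yv) == 0:
                rows.append({"confounder": name, "beta": np.nan, "se": np.nan,
                             "p": np.nan, "note": "constant; skipped"})
                continue
            fit = sm.OLS(yv, design, missing="drop").fit()
            rows.append({"confounder": name, "beta": fit.params["score"],
                         "se": fit.bse["score"], "p": fit.pvalues["score"],
                         "note": ""})
    return pd.DataFrame(rows)


def variance_heterogeneity_check(
    values: np.ndarray, score: np.ndarray, n_bins: int = 5
) -> tuple[pd.DataFrame, float, float]:
    """Variance of a continuous trait across genetic-score levels.

    Splits the score into ``n_bins`` quantile bins, tabulates the per-bin
    trait variance, and tests homogeneity of variances with the
    Brown–Forsythe statistic (Levene's test centred at the median).
    Returns (table, statistic, p).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = np.asarray(values, dtype=float)
    score = np.asarray(score, dtype=float)
    bins = pd.qcut(score, n_bins, labels=False, duplicates="drop")
    groups = [values[bins == b] for b in np.unique(bins[~pd.isna(bins)])]
    if len(groups) < 2 or min(len(gr) for gr in groups) < 2:
        raise ValueError("a score bin has <2 observations; use fewer bins")
    stat, p = stats.levene(*groups, center="median")
    table = pd.DataFrame(
        {
            "bin": range(len(groups)),
            "n": [len(gr) for gr in groups],
            "variance": [gr.var(ddof=1) for gr in groups],
        }
    )
    return table, float(stat), float(p)
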