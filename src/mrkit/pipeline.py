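"""Pipeline orchestration: run the full forward and/or reverse analysis
from a single structured config, with deterministic, machine-readable
outputs.

Stage order (each toggleable): cohort summary → observational regression →
GRS build + strength diagnostics + confounder scan → one-sample estimation
(score TSPS and optional per-variant + RE pooling) → two-sample estimation
(all enabled estimators) → unit conversions → fixed-effect pooling of the
one- and two-sample estimates; the reverse direction runs analogously with
the doubling-of-odds conversion and the variance-heterogeneity check.

The report bundle (results.json, tables/*.tsv, manifest.json) is a pure
function of (inputs, config, seed): rerunning an identical config
byte-reproduces it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import CausalEstimate, format_or
from .instruments import (
    compute_grs,
    harmonize,
    instrument_strength,
    read_proxy_table,
    read_summary_stats,
)
from .meta import SCALE, MetaInput, doubling_odds_scale, fixed_effect_meta
from .onesample import (
    confounder_scan,
    observational_assoc,
    per_variant_onesample,
    tsls_reverse,
    tsps_forward,
    variance_heterogeneity_check,
)
from .simulate import Cohort, cohort_to_summary, read_cohort
from .twosample import all_estimates, convert_per_sd_to_per_unit

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated run configuration (mirrors the YAML schema)."""

    direction: str = "forward"  # forward | reverse | both
    dosages: str | None = None
    phenotypes: str | None = None
    exposure_stats: str | None = None       # published exposure-GWAS TSV
    outcome_stats: str | None = None        # published outcome-GWAS TSV
    disease_stats: str | None = None        # published disease-GWAS TSV (reverse)
    reverse_outcome_stats: str | None = None
    proxies: str | None = None
    covariates: list[str] = field(default_factory=list)
    estimators: dict = field(default_factory=lambda: {
        "observational": True, "tsps": True, "per_variant": False,
        "ivw": True, "egger": True, "weighted_median": True, "mbe": True,
    })
    split: float = 1.0
    bootstrap_reps: int = 1000
    bandwidth_factor: float = 1.0
    seed: int | None = None
    exposure_sd: float = SCALE.default_exposure_sd
    doubling_odds: bool = True
    meta_model: str = "fixed"
    outdir: str = "mrkit_run"

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "reverse", "both"):
            raise ValueError("direction must be forward, reverse or both")
        stochastic = self.estimators.get("weighted_median") or self.estimators.get("mbe")
        if stochastic and self.seed is None:
            raise ValueError("a seed is mandatory when stochastic estimators "
                             "(weighted median / MBE) are enabled")
        for attr in ("dosages", "phenotypes", "exposure_stats", "outcome_stats",
                     "disease_stats", "reverse_outcome_stats", "proxies"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{attr}: no such file {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass(frozen=True)
class CohortSummary:
    """Table-1-style description of a cohort."""

    n: int
    n_cases: int
    n_controls: int
    pct_cases: float  # percent, 1 dp
    covariate_summary: dict

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    """Counts, case percentage (of total n, 1 dp) and covariate summaries."""
    y = cohort.outcome
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("outcome must be binary")
    n = len(y)
    n_cases = int(y.sum())
    cov_summary: dict = {}
    full = pd.concat(
        [pd.Series(cohort.exposure, name="exposure"),
         cohort.covariates.reset_index(drop=True)], axis=1)
    for col in full.columns:
        series = full[col]
        if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            cov_summary[col] = {str(k): int(v) for k, v in series.value_counts().items()}
        else:
            cov_summary[col] = {"mean": float(series.mean()),
                                "sd": float(series.std(ddof=1))}
    return CohortSummary(
        n=n, n_cases=n_cases, n_controls=n - n_cases,
        pct_cases=round(100.0 * n_cases / n, 1),
        covariate_summary=cov_summary,
    )


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


def _est_dict(est: CausalEstimate) -> dict:
    d = est.to_dict()
    d["or"] = est.odds_ratio
    return d


def run_pipeline(config: RunConfig, cohort: Cohort | None = None) -> dict:
    """Execute the configured analysis and return the results bundle dict.

    ``cohort`` may be passed directly (e.g., a freshly simulated one);
    otherwise it is read from the configured dosage/phenotype paths.
    """
    results: dict = {"config": {k: v for k, v in asdict(config).items()},
                     "stages": {}}
    est = config.estimators
    covariates = tuple(config.covariates)

    exposure_weights = None
    if config.exposure_stats:
        exposure_weights = read_summary_stats(
            config.exposure_stats, trait="exposure", scale="raw-unit")

    if cohort is None and config.dosages and config.phenotypes:
        cohort = read_cohort(config.dosages, config.phenotypes,
                             variants=exposure_weights)
    if cohort is not None and exposure_weights is None:
        exposure_weights = cohort.variants or None

    proxies = read_proxy_table(config.proxies) if config.proxies else None
    forward = config.direction in ("forward", "both")
    reverse = config.direction in ("reverse", "both")

    if cohort is not None:
        results["stages"]["cohort_summary"] = _stage("cohort_summary")(
            lambda: summarize_cohort(cohort).to_dict())()

    # ------------------------------------------------------------------ forward
    if forward:
        fwd: dict = {}
        components: list[MetaInput] = []

        if cohort is not None:
            if est.get("observational", True):
                obs = _stage("observational")(observational_assoc)(cohort, covariates)
                fwd["observational"] = _est_dict(obs)

            if exposure_weights:
                score = _stage("grs")(compute_grs)(cohort.dosages, exposure_weights)
                strength = _stage("instrument_strength")(instrument_strength)(
                    score, cohort.exposure)
                fwd["instrument_strength"] = asdict(strength)
                scan = _stage("confounder_scan")(confounder_scan)(
                    score, cohort.covariates)
                fwd["confounder_scan"] = scan.to_dict(orient="records")

                if est.get("tsps", True):
                    tsps = _stage("tsps")(tsps_forward)(cohort, score, covariates)
                    fwd["tsps"] = _est_dict(tsps)
                    components.append(MetaInput("one-sample TSPS", tsps.beta, tsps.se))
                if est.get("per_variant", False):
                    pv = _stage("per_variant")(per_variant_onesample)(
                        cohort, covariates=covariates)
                    fwd["per_variant"] = _est_dict(pv)

        # two-sample stage: published stats if provided, else derived from
        # the cohort (sample overlap with the one-sample stage; documented)
        exp_stats = out_stats = None
        if config.exposure_stats and config.outcome_stats:
            exp_stats = exposure_weights
            out_stats = read_summary_stats(
                config.outcome_stats, trait="outcome", scale="log-odds")
        elif cohort is not None and exposure_weights:
            exp_stats = exposure_weights
            _, out_stats = _stage("cohort_to_summary")(cohort_to_summary)(
                cohort, split=config.split)
        if exp_stats and out_stats and est.get("ivw", True):
            iset = _stage("harmonize")(harmonize)(exp_stats, out_stats, proxies)
            fwd["n_instruments"] = len(iset)
            fwd["harmonization_drops"] = list(map(list, iset.drop_log))
            ts = _stage("two_sample")(all_estimates)(
                iset, seed=(config.seed or 0),
                bootstrap_reps=config.bootstrap_reps,
                bandwidth_factor=config.bandwidth_factor)
            two = {k: _est_dict(v) for k, v in ts.items()}
            key = "ivw" if "ivw" in ts else "wald_ratio"
            main = ts[key]
            if iset.exposure_scale == "sd-unit":
                main = convert_per_sd_to_per_unit(main, config.exposure_sd)
                two[key + "_per_unit"] = _est_dict(main)
            fwd["two_sample"] = two
            components.append(MetaInput("two-sample " + key.upper(), main.beta, main.se))

        if len(components) >= 2:
            pooled = _stage("pooling")(fixed_effect_meta)(components)
            fwd["pooled"] = pooled.to_dict()
            fwd["pooled"]["or"] = float(np.exp(pooled.beta))
            fwd["pooled"]["or_2dp"] = format_or(pooled.beta)
            # internal consistency: pooling must equal effect_meta on the parts
            check = fixed_effect_meta(components)
            assert abs(check.beta - pooled.beta) < 1e-12
        results["stages"]["forward"] = fwd

    # ------------------------------------------------------------------ reverse
    if reverse:
        rev: dict = {}
        disease_weights = None
        if config.disease_stats:
            disease_weights = read_summary_stats(
                config.disease_stats, trait="disease", scale="log-odds")
        if cohort is not None and disease_weights:
            dscore = _stage("reverse_grs")(compute_grs)(
                cohort.dosages, disease_weights)
            tsls = _stage("tsls_reverse")(tsls_reverse)(
                cohort, dscore, covariates, exposure_coding="log-odds")
            rev["tsls_log_odds"] = _est_dict(tsls)
            if config.doubling_odds:
                rev["tsls_per_doubling"] = _est_dict(doubling_odds_scale(tsls))
            tsls01 = _stage("tsls_linear01")(tsls_reverse)(
                cohort, dscore, covariates, exposure_coding="linear01")
            rev["tsls_linear01"] = _est_dict(tsls01)
            table, stat, p = _stage("variance_heterogeneity")(
                variance_heterogeneity_check)(cohort.exposure, dscore)
            rev["variance_heterogeneity"] = {
                "bins": table.to_dict(orient="records"),
                "statistic": stat, "p": p,
            }
        if config.disease_stats and config.reverse_outcome_stats:
            dstats = disease_weights
            rstats = read_summary_stats(
                config.reverse_outcome_stats, trait="exposure", scale="raw-unit")
            iset = _stage("reverse_harmonize")(harmonize)(dstats, rstats, proxies)
            ts = _stage("reverse_two_sample")(all_estimates)(
                iset, seed=(config.seed or 0) + 7,
                bootstrap_reps=config.bootstrap_reps,
                bandwidth_factor=config.bandwidth_factor)
            rev["two_sample"] = {k: _est_dict(v) for k, v in ts.items()}
        results["stages"]["reverse"] = rev

    return results


# ---------------------------------------------------------------------------
# reporting


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_report(results: dict, outdir) -> dict:
    """Write results.json (full precision), per-stage TSV tables, and
    manifest.json (versions, seed, input hashes).  Returns the file map."""
    outdir = Path(outdir)
    tables = outdir / "tables"
    tables.mkdir(parents=True, exist_ok=True)

    files = {}
    results_path = outdir / "results.json"
    with open(results_path, "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    files["results"] = str(results_path)

    # human-readable estimate tables per direction
    for direction in ("forward", "reverse"):
        stage = results.get("stages", {}).get(direction)
        if not stage:
            continue
        rows = []

        def collect(prefix: str, node: dict) -> None:
            if {"beta", "se"} <= set(node):
                rows.append({
                    "analysis": prefix,
                    "estimate_or": format_or(node["beta"]),
                    "ci_low": format_or(node["ci_low"]),
                    "ci_high": format_or(node["ci_high"]),
                    "beta": node["beta"], "se": node["se"],
                    "p": f"{node['p']:.2e}",
                })
            else:
                for k, v in node.items():
                    if isinstance(v, dict):
                        collect(f"{prefix}.{k}" if prefix else k, v)

        collect("", stage)
        if rows:
            path = tables / f"{direction}_estimates.tsv"
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
            files[f"{direction}_table"] = str(path)

    import scipy
    import statsmodels

    cfg = results.get("config", {})
    manifest = {
        "mrkit_version": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
        "seed": cfg.get("seed"),
        "inputs": {
            k: _hash_file(cfg[k])
            for k in ("dosages", "phenotypes", "exposure_stats", "outcome_stats",
                      "disease_stats", "reverse_outcome_stats", "proxies")
            if cfg.get(k)
        },
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files["manifest"] = str(manifest_path)
    return files
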