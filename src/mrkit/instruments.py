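"""Genetic-instrument handling: summary-statistic I/O, harmonization of
exposure/outcome association pairs, weighted standardized genetic risk
scores, and instrument-strength diagnostics.

The exposure instrument emulated throughout is a set of ~97 independent
biallelic SNPs jointly explaining ~2.7% of the variance of the exposure;
each variant carries a per-allele association with the exposure (γ̂_j) and,
after harmonization against an outcome GWAS, with the outcome (Γ̂_j).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}

#: bit-exact required header of the summary-statistic TSV schema
SUMMARY_COLUMNS = [
    "variant_id", "chr", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

PROXY_COLUMNS = ["variant_id", "proxy_id", "r2"]

#: default LD threshold for accepting a proxy variant
PROXY_R2_THRESHOLD = 0.8

#: allele-frequency window in which a palindromic variant cannot be oriented
PALINDROMIC_WINDOW = (0.42, 0.58)


@dataclass(frozen=True)
class VariantAssoc:
    """One variant's association with one trait."""

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    p: float
    n: int
    trait: str = ""
    scale: str = "raw-unit"  # raw-unit | sd-unit | log-odds
    chrom: str = "0"
    pos: int = 0
    valid: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if self.valid:
            if self.se <= 0:
                raise ValueError(f"{self.variant_id}: se must be positive")
            if self.effect_allele == self.other_allele:
                raise ValueError(f"{self.variant_id}: alleles must differ")
            if not (0 < self.eaf < 1):
                raise ValueError(f"{self.variant_id}: eaf must be in (0,1)")

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.effect_allele, self.other_allele))

    @property
    def is_palindromic(self) -> bool:
        return self.alleles in _PALINDROMIC


@dataclass(frozen=True)
class InstrumentRecord:
    """Harmonized (γ, Γ) pair for one instrument variant."""

    variant_id: str
    gamma: float
    gamma_se: float
    Gamma: float
    Gamma_se: float
    proxy_used: bool = False

    def __post_init__(self) -> None:
        if self.gamma_se <= 0 or self.Gamma_se <= 0:
            raise ValueError(f"{self.variant_id}: SEs must be positive")


@dataclass
class InstrumentSet:
    """Harmonized exposure/outcome association pairs ready for estimation."""

    records: list[InstrumentRecord]
    exposure: str = "exposure"
    exposure_scale: str = "raw-unit"
    outcome: str = "outcome"
    outcome_scale: str = "log-odds"
    drop_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.variant_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("variant ids must be unique in an InstrumentSet")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def gamma(self) -> np.ndarray:
        return np.array([r.gamma for r in self.records])

    @property
    def gamma_se(self) -> np.ndarray:
        return np.array([r.gamma_se for r in self.records])

    @property
    def Gamma(self) -> np.ndarray:
        return np.array([r.Gamma for r in self.records])

    @property
    def Gamma_se(self) -> np.ndarray:
        return np.array([r.Gamma_se for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": [r.variant_id for r in self.records],
                "gamma": self.gamma,
                "gamma_se": self.gamma_se,
                "Gamma": self.Gamma,
                "Gamma_se": self.Gamma_se,
                "proxy_used": [r.proxy_used for r in self.records],
            }
        )


def write_instrument_set(iset: InstrumentSet, path) -> None:
    iset.to_frame().to_csv(path, sep="\t", index=False)


def read_instrument_set(path, **labels) -> InstrumentSet:
    df = pd.read_csv(path, sep="\t")
    records = [
        InstrumentRecord(
            variant_id=str(r.variant_id),
            gamma=float(r.gamma),
            gamma_se=float(r.gamma_se),
            Gamma=float(r.Gamma),
            Gamma_se=float(r.Gamma_se),
            proxy_used=bool(r.proxy_used),
        )
        for r in df.itertuples()
    ]
    return InstrumentSet(records=records, **labels)


# ---------------------------------------------------------------------------
# summary-statistic I/O


def read_summary_stats(path, trait: str, scale: str) -> list[VariantAssoc]:
    """Read a summary-statistic TSV (schema: SUMMARY_COLUMNS).

    Malformed rows are collected and reported with their line numbers in a
    single error; duplicated variant ids are rejected; unexpected extra
    columns are ignored with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s): {missing}")
    extra = [c for c in df.columns if c not in SUMMARY_COLUMNS]
    if extra:
        warnings.warn(f"{path}: ignoring unexpected column(s): {extra}", stacklevel=2)

    records: list[VariantAssoc] = []
    problems: list[str] = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            rec = VariantAssoc(
                variant_id=str(row["variant_id"]),
                effect_allele=str(row["effect_allele"]),
                other_allele=str(row["other_allele"]),
                eaf=float(row["eaf"]),
                beta=float(row["beta"]),
                se=float(row["se"]),
                p=float(row["pval"]),
                n=int(float(row["n"])),
                trait=trait,
                scale=scale,
                chrom=str(row["chr"]),
                pos=int(float(row["pos"])),
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"line {line_no}: {exc}")
            continue
        records.append(rec)
    if problems:
        raise ValueError(f"{path}: malformed rows:\n" + "\n".join(problems))

    ids = pd.Series([r.variant_id for r in records])
    dups = sorted(ids[ids.duplicated()].unique())
    if dups:
        raise ValueError(f"{path}: duplicated variant id(s): {dups}")
    return records


def write_summary_stats(records: list[VariantAssoc], path) -> None:
    """Write records in the summary-statistic TSV schema (round-trips with
    :func:`read_summary_stats`)."""
    df = pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in records],
            "chr": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "effect_allele": [r.effect_allele for r in records],
            "other_allele": [r.other_allele for r in records],
            "eaf": [r.eaf for r in records],
            "beta": [r.beta for r in records],
            "se": [r.se for r in records],
            "pval": [r.p for r in records],
            "n": [r.n for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_proxy_table(path) -> pd.DataFrame:
    """Read an LD-proxy TSV (variant_id, proxy_id, r2)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PROXY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: proxy table missing column(s): {missing}")
    return df


# ---------------------------------------------------------------------------
# harmonization


def _orient_outcome(exp: VariantAssoc, out: VariantAssoc) -> VariantAssoc | None:
    """Orient an outcome record onto the exposure record's effect allele.

    Returns None when the allele pairs are irreconcilable.  Handles direct
    matches, effect/other swaps (flip beta sign, complement eaf), and strand
    flips for non-palindromic variants.
    """
    ea, oa = exp.effect_allele, exp.other_allele
    cea, coa = _COMPLEMENT.get(ea), _COMPLEMENT.get(oa)

    if (out.effect_allele, out.other_allele) == (ea, oa):
        return out
    if (out.effect_allele, out.other_allele) == (oa, ea):
        return replace(out, effect_allele=ea, other_allele=oa,
                       beta=-out.beta, eaf=1.0 - out.eaf)
    if not exp.is_palindromic and cea is not None:
        # strand-flipped representations
        if (out.effect_allele, out.other_allele) == (cea, coa):
            return replace(out, effect_allele=ea, other_allele=oa)
        if (out.effect_allele, out.other_allele) == (coa, cea):
            return replace(out, effect_allele=ea, other_allele=oa,
                           beta=-out.beta, eaf=1.0 - out.eaf)
    return None


def harmonize(
    exposure: list[VariantAssoc],
    outcome: list[VariantAssoc],
    proxies: pd.DataFrame | None = None,
    palindromic_window: tuple[float, float] = PALINDROMIC_WINDOW,
    proxy_r2: float = PROXY_R2_THRESHOLD,
) -> InstrumentSet:
    """Match exposure and outcome associations into an InstrumentSet.

    Rules, applied per exposure variant:

    * outcome records with swapped (or strand-flipped) alleles are
      re-oriented onto the exposure effect allele (beta sign flipped, eaf
      complemented);
    * palindromic (A/T, C/G) variants are dropped when the exposure eaf lies
      inside ``palindromic_window`` (frequency cannot resolve the strand),
      otherwise oriented by allele frequency;
    * a variant absent from the outcome set is substituted by a proxy with
      r² ≥ ``proxy_r2`` from the proxy table when available, else dropped.

    Invalid (flagged) records on either side are excluded up front.
    """
    if not exposure or not outcome:
        raise ValueError("exposure and outcome lists must be non-empty")
    exposure = [r for r in exposure if r.valid]
    outcome_by_id = {r.variant_id: r for r in outcome if r.valid}

    records: list[InstrumentRecord] = []
    drop_log: list[tuple[str, str]] = []
    lo, hi = palindromic_window

    for exp in exposure:
        out = outcome_by_id.get(exp.variant_id)
        proxy_used = False
        if out is None and proxies is not None:
            cand = proxies[
                (proxies["variant_id"] == exp.variant_id)
                & (proxies["r2"] >= proxy_r2)
            ]
            for proxy_id in cand.sort_values("r2", ascending=False)["proxy_id"]:
                if proxy_id in outcome_by_id:
                    # proxy association taken as published on the proxy's own
                    # effect allele, assumed positively phased with the index
                    # variant (documented convention)
                    out = outcome_by_id[proxy_id]
                    proxy_used = True
                    break
        if out is None:
            drop_log.append((exp.variant_id, "absent from outcome, no proxy"))
            continue

        if exp.is_palindromic:
            if lo <= exp.eaf <= hi:
                drop_log.append((exp.variant_id, "palindromic-ambiguous"))
                continue
            # orient by frequency: minor/major alleles must agree
            if not proxy_used and (exp.eaf < 0.5) != (out.eaf < 0.5):
                out = replace(out, effect_allele=exp.effect_allele,
                              other_allele=exp.other_allele,
                              beta=-out.beta, eaf=1.0 - out.eaf)
        elif not proxy_used:
            oriented = _orient_outcome(exp, out)
            if oriented is None:
                drop_log.append((exp.variant_id, "allele mismatch"))
                continue
            out = oriented

        records.append(
            InstrumentRecord(
                variant_id=exp.variant_id,
                gamma=exp.beta,
                gamma_se=exp.se,
                Gamma=out.beta,
                Gamma_se=out.se,
                proxy_used=proxy_used,
            )
        )

    if not records:
        raise ValueError("no variants remain after harmonization "
                         f"(dropped: {drop_log})")
    first = exposure[0]
    return InstrumentSet(
        records=records,
        exposure=first.trait,
        exposure_scale=first.scale,
        outcome=next(iter(outcome_by_id.values())).trait if outcome_by_id else "outcome",
        outcome_scale=next(iter(outcome_by_id.values())).scale if outcome_by_id else "log-odds",
        drop_log=drop_log,
    )


# ---------------------------------------------------------------------------
# genetic risk score


def compute_grs(
    dosages: pd.DataFrame,
    weights: list[VariantAssoc],
    standardized: bool = True,
) -> np.ndarray:
    """Weighted allele score: score_i = Σ_j w_j g_ij / m.

    ``dosages`` has one column per variant id; weights come from the
    exposure-GWAS betas on their published scale.  Missing dosages are
    mean-imputed as 2·eaf.  With ``standardized`` (default) the returned
    scores have sample mean 0 and SD 1; otherwise the raw divided-by-m scale
    is returned.
    """
    weights = [w for w in weights if w.valid]
    if not weights:
        raise ValueError("need at least one weight variant")
    missing_cols = [w.variant_id for w in weights if w.variant_id not in dosages.columns]
    if missing_cols:
        raise ValueError(f"weight variants absent from dosage matrix: {missing_cols}")

    g = dosages[[w.variant_id for w in weights]].to_numpy(dtype=float, copy=True)
    for j, w in enumerate(weights):
        col = g[:, j]
        col[np.isnan(col)] = 2.0 * w.eaf
    betas = np.array([w.beta for w in weights])
    raw = g @ betas / len(weights)
    if not standardized:
        return raw
    sd = raw.std(ddof=0)
    if sd <= 1e-12 * max(1.0, float(np.abs(raw).max())):
        raise ValueError("raw score has zero variance; cannot standardize")
    return (raw - raw.mean()) / sd


@dataclass(frozen=True)
class StrengthStats:
    """First-stage instrument-strength diagnostics."""

    r_squared: float
    f_statistic: float
    first_stage_beta: float
    first_stage_se: float
    n: int
    k: int


def f_from_r2(r_squared: float, n: int, k: int) -> float:
    """F = (R²/(1−R²))·((n−k−1)/k)."""
    if not (0 <= r_squared < 1):
        raise ValueError("R² must be in [0,1)")
    return (r_squared / (1.0 - r_squared)) * ((n - k - 1) / k)


def instrument_strength(instrument: np.ndarray, exposure: np.ndarray) -> StrengthStats:
    """R² and F from regressing the exposure on a score (1-D, k=1) or on all
    instrument dosages jointly (2-D, k = number of columns)."""
    y = np.asarray(exposure, dtype=float)
    x = np.asarray(instrument, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, k = x.shape
    if n <= k + 1:
        raise ValueError("need n > k+1 observations")
    if y.std() == 0:
        raise ValueError("exposure is constant")
    design = np.column_stack([np.ones(n), x])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    f = f_from_r2(max(r2, 0.0), n, k)

    # slope diagnostics: the score slope itself when k=1, otherwise the slope
    # of the exposure on the fitted allele-score combination
    sigma2 = ss_res / (n - k - 1)
    if k == 1:
        vx = x[:, 0].var(ddof=0)
        slope = float(coef[1])
        slope_se = math.sqrt(sigma2 / (n * vx))
    else:
        fitted = x @ coef[1:]
        vx = fitted.var(ddof=0)
        if vx <= 0:
            raise ValueError("instrument combination has zero variance")
        slope = float(np.cov(fitted, y, ddof=0)[0, 1] / vx)
        slope_se = math.sqrt(sigma2 / (n * vx))
    return StrengthStats(
        r_squared=float(r2),
        f_statistic=float(f),
        first_stage_beta=slope,
        first_stage_se=slope_se,
        n=n,
        k=k,
    )
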