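"""TSPS / TSLS estimation, observational regression, confounder scan and
the variance-heterogeneity check."""

import copy
import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import mrkit
from mrkit import (
    SimConfig,
    WeakInstrumentError,
    confounder_scan,
    observational_assoc,
    per_variant_onesample,
    simulate_cohort,
    tsls_reverse,
    tsps_forward,
    variance_heterogeneity_check,
)
from mrkit.meta import doubling_odds_scale


def _with(cohort, **arrays):
    c = copy.copy(cohort)
    for k, v in arrays.items():
        setattr(c, k, v)
    return c


class TestTSPSForward:
    def test_noise_free_algebraic_identity(self, cohort20):
        # exposure an exact linear function of the score: TSPS equals the
        # logistic coefficient of the score divided by the stage-1 slope
        score = mrkit.compute_grs(cohort20.dosages, cohort20.variants)
        c = _with(cohort20, exposure=3.0 + 2.5 * score)
        est = tsps_forward(c, score)
        logit = sm.Logit(c.outcome, sm.add_constant(score)).fit(disp=0, tol=1e-12)
        assert est.beta == pytest.approx(logit.params[1] / 2.5, abs=1e-8)

    def test_single_variant_equals_wald_ratio(self, cohort20):
        vid = cohort20.variant_ids[2]
        est = tsps_forward(cohort20, vid)
        g = cohort20.dosages[vid].to_numpy()
        controls = cohort20.outcome == 0
        slope = stats.linregress(g[controls], cohort20.exposure[controls]).slope
        reduced = sm.Logit(cohort20.outcome, sm.add_constant(g)).fit(
            disp=0, method="newton", tol=1e-12)
        assert est.beta == pytest.approx(reduced.params[1] / slope, abs=1e-8)

    def test_null_simulation(self, cohort_null):
        score = mrkit.compute_grs(cohort_null.dosages, cohort_null.variants)
        est = tsps_forward(cohort_null, score)
        assert abs(est.beta / est.se) < 3

    def test_recovery_with_confounding(self):
        c = simulate_cohort(SimConfig(n_individuals=20_000, seed=0))
        score = mrkit.compute_grs(c.dosages, c.variants)
        est = tsps_forward(c, score)
        assert est.ci_low <= math.log(1.09) <= est.ci_high

    def test_confounding_biases_observational_but_not_tsps(self):
        # no causal effect but strong confounding: the observational OR moves
        # away from 1 while the genetic estimate stays compatible with 0
        c = simulate_cohort(SimConfig(
            n_individuals=30_000, causal_beta=0.0,
            confounder_effect_exposure=2.0, confounder_effect_outcome=0.6,
            seed=8))
        obs = observational_assoc(c)
        assert abs(obs.beta / obs.se) > 3
        score = mrkit.compute_grs(c.dosages, c.variants)
        est = tsps_forward(c, score)
        assert est.ci_low <= 0 <= est.ci_high

    def test_orthogonalised_covariate_leaves_estimate_unchanged(self, cohort20):
        score = mrkit.compute_grs(cohort20.dosages, cohort20.variants)
        base = tsps_forward(cohort20, score)

        # construct a covariate exactly orthogonal to both stages' designs
        # and residuals, so its ML coefficient is zero in each stage
        controls = cohort20.outcome == 0
        d1 = np.column_stack([np.ones(cohort20.n), score])
        s1 = sm.OLS(cohort20.exposure[controls], d1[controls]).fit()
        fitted = d1 @ s1.params
        s2 = sm.Logit(cohort20.outcome, np.column_stack(
            [np.ones(cohort20.n), fitted])).fit(disp=0, tol=1e-12)
        resid2 = cohort20.outcome - s2.predict()
        ind = controls.astype(float)
        basis = np.column_stack([
            ind, ind * score, ind * cohort20.exposure,
            np.ones(cohort20.n), fitted, resid2,
        ])
        rng = np.random.default_rng(0)
        noise = rng.standard_normal(cohort20.n)
        cov = noise - basis @ np.linalg.lstsq(basis, noise, rcond=None)[0]

        c = _with(cohort20, covariates=cohort20.covariates.assign(orth=cov))
        est = tsps_forward(c, score, covariates=("orth",))
        assert est.beta == pytest.approx(base.beta, abs=1e-6)

    def test_second_order_se_not_smaller(self, cohort20):
        score = mrkit.compute_grs(cohort20.dosages, cohort20.variants)
        first = tsps_forward(cohort20, score)
        second = tsps_forward(cohort20, score, second_order=True)
        assert second.se >= first.se
        assert second.beta == first.beta

    def test_weak_instrument_raises(self, cohort_null, rng):
        # orthogonalize noise against the exposure among controls so the
        # first-stage slope is exactly zero
        noise = rng.standard_normal(cohort_null.n)
        controls = cohort_null.outcome == 0
        x = np.column_stack([np.ones(controls.sum()),
                             cohort_null.exposure[controls]])
        coef = np.linalg.lstsq(x, noise[controls], rcond=None)[0]
        noise[controls] -= x @ coef
        with pytest.raises(WeakInstrumentError):
            tsps_forward(cohort_null, noise)

    def test_degenerate_outcomes_raise(self, cohort20, rng):
        score = mrkit.compute_grs(cohort20.dosages, cohort20.variants)
        all_ones = _with(cohort20, outcome=np.ones(cohort20.n, dtype=int))
        with pytest.raises(ValueError):
            tsps_forward(all_ones, score)
        all_zero = _with(cohort20, outcome=np.zeros(cohort20.n, dtype=int))
        with pytest.raises(ValueError):
            tsps_forward(all_zero, score)


class TestPerVariant:
    def test_pooled_equals_dl_oracle(self):
        c = simulate_cohort(SimConfig(n_individuals=4000, n_variants=8, seed=14))
        pooled = per_variant_onesample(c)
        betas, ses = [], []
        for vid in c.variant_ids:
            try:  # same weak-instrument skip rule the pooled route applies
                est = tsps_forward(c, vid)
            except (WeakInstrumentError, ValueError):
                continue
            betas.append(est.beta)
            ses.append(est.se)
        b, v = np.array(betas), np.array(ses) ** 2
        w = 1 / v
        mu = (w * b).sum() / w.sum()
        q = (w * (b - mu) ** 2).sum()
        tau2 = max(0.0, (q - (len(b) - 1)) / (w.sum() - (w ** 2).sum() / w.sum()))
        w2 = 1 / (v + tau2)
        assert pooled.beta == pytest.approx((w2 * b).sum() / w2.sum(), abs=1e-10)
        assert pooled.se == pytest.approx(w2.sum() ** -0.5, abs=1e-10)
        assert pooled.n_variants == len(betas)

    def test_balanced_pleiotropy_inflates_tau2(self):
        from mrkit.meta import MetaInput, random_effects_meta

        hits = 0
        for seed in range(40):
            c = simulate_cohort(SimConfig(
                n_individuals=5000, n_variants=20, pleiotropy_sd=0.15,
                seed=300 + seed))
            inputs = []
            for vid in c.variant_ids:
                try:
                    est = tsps_forward(c, vid)
                except (WeakInstrumentError, ValueError):
                    continue
                inputs.append(MetaInput(vid, est.beta, est.se))
            hits += random_effects_meta(inputs).tau_squared > 0
        assert hits >= 32  # >=80% of replicates

    def test_too_few_variants_raise(self, cohort20):
        with pytest.raises(ValueError):
            per_variant_onesample(cohort20, variant_ids=[cohort20.variant_ids[0]])


@pytest.fixture(scope="module")
def disease_cohort():
    # variants act on the disease directly (no exposure pathway);
    # the continuous trait is independent of disease -> null reverse MR
    return simulate_cohort(SimConfig(
        n_individuals=20_000, n_variants=30, h2_instrument=0.0,
        pleiotropy_sd=0.12, causal_beta=0.0,
        confounder_effect_exposure=0.0, confounder_effect_outcome=0.0,
        seed=12))


@pytest.fixture(scope="module")
def disease_score(disease_cohort):
    _, dstats = mrkit.cohort_to_summary(disease_cohort)
    return mrkit.compute_grs(disease_cohort.dosages,
                             [r for r in dstats if r.valid])


class TestTSLSReverse:
    def test_null_reverse_effect_covered(self, disease_cohort, disease_score):
        est = tsls_reverse(disease_cohort, disease_score)
        assert est.ci_low <= 0 <= est.ci_high

    def test_linear01_recovers_constructed_difference(self, disease_cohort,
                                                      disease_score, rng):
        outcome_trait = 2.0 * disease_cohort.outcome + rng.standard_normal(
            disease_cohort.n)
        c = _with(disease_cohort, exposure=outcome_trait)
        est = tsls_reverse(c, disease_score, exposure_coding="linear01")
        assert est.ci_low <= 2.0 <= est.ci_high
        assert est.beta == pytest.approx(2.0, abs=3 * est.se)

    def test_doubling_odds_scaling_is_exact(self, disease_cohort, disease_score):
        est = tsls_reverse(disease_cohort, disease_score, exposure_coding="log-odds")
        scaled = doubling_odds_scale(est)
        assert scaled.beta == pytest.approx(0.693 * est.beta, abs=1e-15)
        assert scaled.se == pytest.approx(0.693 * est.se, abs=1e-15)

    def test_invalid_coding_rejected(self, disease_cohort, disease_score):
        with pytest.raises(ValueError):
            tsls_reverse(disease_cohort, disease_score, exposure_coding="probit")


class TestObservational:
    def test_matches_handrolled_irls_oracle(self, cohort20):
        est = observational_assoc(cohort20)
        # independent Newton-IRLS logistic implementation
        x = np.column_stack([np.ones(cohort20.n), cohort20.exposure])
        y = cohort20.outcome.astype(float)
        beta = np.zeros(2)
        for _ in range(50):
            eta = x @ beta
            mu = 1 / (1 + np.exp(-eta))
            w = mu * (1 - mu)
            step = np.linalg.solve(x.T @ (w[:, None] * x), x.T @ (y - mu))
            beta += step
            if np.abs(step).max() < 1e-12:
                break
        cov = np.linalg.inv(x.T @ (w[:, None] * x))
        assert est.beta == pytest.approx(beta[1], abs=1e-6)
        assert est.se == pytest.approx(math.sqrt(cov[1, 1]), rel=1e-5)

    def test_independent_exposure_gives_or_near_one(self, cohort_null, rng):
        c = _with(cohort_null, exposure=rng.standard_normal(cohort_null.n))
        est = observational_assoc(c)
        assert est.ci_low <= 0 <= est.ci_high

    def test_covariate_adjustment_runs_with_categoricals(self, cohort20):
        est = observational_assoc(cohort20, covariates=("age", "sex", "platform"))
        assert est.n_individuals == cohort20.n


class TestConfounderScan:
    def test_positive_control_detected(self, rng):
        score = rng.standard_normal(2000)
        score = (score - score.mean()) / score.std()
        conf = pd.DataFrame({"lifestyle": score + 0.5 * rng.standard_normal(2000)})
        table = confounder_scan(score, conf)
        assert table.loc[0, "p"] < 1e-10

    def test_constant_column_skipped(self, rng):
        score = rng.standard_normal(500)
        score = (score - score.mean()) / score.std()
        table = confounder_scan(score, pd.DataFrame({"flat": np.ones(500)}))
        assert table.loc[0, "note"] == "constant; skipped"
        assert math.isnan(table.loc[0, "beta"])

    def test_categorical_expansion(self, rng):
        score = rng.standard_normal(600)
        score = (score - score.mean()) / score.std()
        conf = pd.DataFrame({"smoking": rng.choice(["never", "former", "current"], 600)})
        table = confounder_scan(score, conf)
        assert len(table) == 2  # k-1 indicator contrasts
        assert all(table["confounder"].str.startswith("smoking_"))

    def test_unstandardized_score_rejected(self, rng):
        with pytest.raises(ValueError, match="standardized"):
            confounder_scan(rng.standard_normal(100) + 5, pd.DataFrame({"x": np.ones(100)}))

    def test_null_pvalues_uniform(self):
        # independence of genotype and confounder => uniform p over replicates
        rng = np.random.default_rng(77)
        ps = []
        for _ in range(200):
            score = rng.standard_normal(400)
            score = (score - score.mean()) / score.std()
            conf = pd.DataFrame({"c": rng.standard_normal(400)})
            ps.append(confounder_scan(score, conf).loc[0, "p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestVarianceHeterogeneity:
    def test_requires_at_least_two_bins(self, rng):
        with pytest.raises(ValueError):
            variance_heterogeneity_check(rng.standard_normal(100),
                                         rng.standard_normal(100), n_bins=1)

    def test_sparse_bins_raise(self, rng):
        score = np.array([0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="fewer bins"):
            variance_heterogeneity_check(rng.standard_normal(3), score, n_bins=2)

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(5)
        rej = 0
        reps = 300
        for _ in range(reps):
            vals = rng.standard_normal(2000)
            score = rng.standard_normal(2000)
            _, _, p = variance_heterogeneity_check(vals, score, n_bins=5)
            rej += p < 0.05
        assert 0.02 <= rej / reps <= 0.09

    def test_detects_variance_doubling_in_top_bin(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(20):
            score = rng.standard_normal(20_000)
            vals = rng.standard_normal(20_000)
            top = score >= np.quantile(score, 0.8)
            vals[top] *= math.sqrt(2)
            table, _, p = variance_heterogeneity_check(vals, score, n_bins=5)
            hits += p < 0.05
            assert table["variance"].iloc[-1] > table["variance"].iloc[0]
        assert hits >= 16  # >80% power
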