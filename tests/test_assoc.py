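"""IRLS logistic core, per-SNP association scan, and covariate model."""

from __future__ import annotations

import numpy as np
import pytest
import statsmodels.api as sm

from macrisk.assoc import irls_logistic, multivariate_fit, per_snp_assoc
from macrisk.cohort import GenotypeCohort, SnpRecord
from macrisk.mac import compute_mac, define_minor_alleles
from macrisk.simulate import CovariateSpec, SimConfig, simulate_cohort


class TestIrlsCore:
    def test_intercept_only_mle_is_log_odds_of_proportion(self):
        y = np.array([1.0] * 30 + [0.0] * 70)
        fit = irls_logistic(np.ones((100, 1)), y)
        assert fit.converged
        assert fit.params[0] == pytest.approx(np.log(30 / 70), abs=1e-8)

    def test_single_binary_predictor_equals_2x2_log_odds_ratio(self, rng):
        checked = 0
        while checked < 500:
            a, b, c, d = rng.integers(3, 60, 4)  # exposed-case, exposed-ctrl, ...
            x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
            y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
            fit = irls_logistic(np.column_stack([np.ones_like(x), x]), y)
            log_or = np.log(a * d / (b * c))
            se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            assert fit.params[1] == pytest.approx(log_or, abs=1e-6)
            assert fit.se[1] == pytest.approx(se, abs=1e-6)
            checked += 1

    def test_loglik_non_decreasing_across_iterations(self, rng):
        x = rng.standard_normal((300, 3))
        y = (rng.random(300) < 0.4).astype(float)
        fit = irls_logistic(np.column_stack([np.ones(300), x]), y)
        diffs = np.diff(fit.loglik_path)
        assert (diffs >= -1e-9).all()

    def test_matches_statsmodels(self, rng):
        x = rng.standard_normal((400, 2))
        eta = -0.5 + x @ np.array([0.8, -0.3])
        y = (rng.random(400) < 1 / (1 + np.exp(-eta))).astype(float)
        X = np.column_stack([np.ones(400), x])
        ours = irls_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(ours.params, ref.params, atol=1e-6)
        assert np.allclose(ours.se, ref.bse, atol=1e-6)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_wald_calibration_under_the_null(self, rng):
        # independent predictor: |beta| < 3 se in >= 99/100 replicates
        hits = 0
        for _ in range(100):
            x = rng.standard_normal(1000)
            y = (rng.random(1000) < 0.3).astype(float)
            fit = irls_logistic(np.column_stack([np.ones(1000), x]), y)
            if abs(fit.params[1]) < 3 * fit.se[1]:
                hits += 1
        assert hits >= 99

    def test_rank_deficient_design_raises(self, rng):
        x = rng.standard_normal(50)
        X = np.column_stack([np.ones(50), x, x])  # duplicated column
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(ValueError, match="rank-deficient"):
            irls_logistic(X, y)

    def test_separation_flagged_not_crashed(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = x.copy()
        fit = irls_logistic(np.column_stack([np.ones(40), x]), y)
        assert not fit.converged


def _assoc_tables(cohort):
    ma_comb = define_minor_alleles(cohort, "combined")
    return per_snp_assoc(cohort, ma_comb), ma_comb


class TestPerSnpAssoc:
    def test_requires_combined_reference(self, rng):
        cfg = SimConfig(n_cases=50, n_controls=50, n_snps=10, seed=2)
        cohort, _ = simulate_cohort(cfg)
        with pytest.raises(ValueError, match="combined"):
            per_snp_assoc(cohort, define_minor_alleles(cohort, "controls"))

    def test_matches_statsmodels_per_snp(self):
        cfg = SimConfig(n_cases=120, n_controls=150, n_snps=25, n_causal=5,
                        causal_beta_law=("constant", 0.5), missing_rate=0.05, seed=6)
        cohort, _ = simulate_cohort(cfg)
        result, ma_comb = _assoc_tables(cohort)
        d = cohort.dosage_float()
        y = cohort.is_case.astype(float)
        for sid, row in result.table.iterrows():
            if not row["converged"]:
                continue
            j = cohort.snp_index()[sid]
            x = d[:, j]
            if not ma_comb.table.loc[sid, "minor_is_b"]:
                x = 2.0 - x
            ok = ~np.isnan(x)
            ref = sm.Logit(y[ok], np.column_stack([np.ones(ok.sum()), x[ok]])).fit(disp=0)
            assert row["beta"] == pytest.approx(ref.params[1], abs=1e-5)
            assert row["se"] == pytest.approx(ref.bse[1], abs=1e-5)

    def test_flipping_coded_allele_negates_beta(self):
        cfg = SimConfig(n_cases=200, n_controls=200, n_snps=10, n_causal=3,
                        causal_beta_law=("constant", 0.4), seed=9)
        cohort, _ = simulate_cohort(cfg)
        result, ma_comb = _assoc_tables(cohort)
        flipped = ma_comb
        flipped.table = flipped.table.copy()
        flipped.table["minor_is_b"] = ~flipped.table["minor_is_b"]
        result_flipped = per_snp_assoc(cohort, flipped)
        ok = result.table["converged"] & result_flipped.table["converged"]
        assert np.allclose(
            result.table.loc[ok, "beta"], -result_flipped.table.loc[ok, "beta"], atol=1e-6
        )

    def test_permutation_equivariant_in_sample_order(self, rng):
        cfg = SimConfig(n_cases=80, n_controls=90, n_snps=15, missing_rate=0.05, seed=4)
        cohort, _ = simulate_cohort(cfg)
        perm = rng.permutation(cohort.n_samples)
        shuffled = cohort.take_samples(perm)
        r1, _ = _assoc_tables(cohort)
        r2, _ = _assoc_tables(shuffled)
        assert np.allclose(r1.table["beta"], r2.table["beta"], atol=1e-8, equal_nan=True)

    def test_monomorphic_snp_skipped(self):
        snps = [SnpRecord("mono", "1", 100, "A", "G"), SnpRecord("ok", "1", 5000, "A", "G")]
        dosage = np.column_stack([np.zeros(40), np.tile([0, 1, 2, 1], 10)]).astype(np.int8)
        cohort = GenotypeCohort(
            [f"i{k}" for k in range(40)], snps, dosage, np.array([1, 0] * 20)
        )
        result, _ = _assoc_tables(cohort)
        assert not result.table.loc["mono", "converged"]
        assert result.table.loc["ok", "converged"]


class TestMultivariateFit:
    def test_recovers_covariate_coefficient(self):
        cov = (CovariateSpec("bmi", ("normal", 27.0, 4.0), 0.16),)
        cfg = SimConfig(n_cases=500, n_controls=700, n_snps=50, covariates=cov,
                        intercept=-5.5, seed=12)
        cohort, _ = simulate_cohort(cfg)
        mac = compute_mac(cohort, define_minor_alleles(cohort, "controls"))
        model = multivariate_fit(cohort, mac)
        est = model.table.loc["bmi", "estimate"]
        se = model.table.loc["bmi", "se"]
        assert est - 2.5 * se < 0.16 < est + 2.5 * se
        assert set(model.table.index) == {"intercept", "MAC", "bmi"}

    def test_duplicate_covariate_rejected(self):
        cfg = SimConfig(n_cases=40, n_controls=40, n_snps=10, seed=2,
                        covariates=(CovariateSpec("age", ("normal", 50, 5), 0.0),))
        cohort, _ = simulate_cohort(cfg)
        mac = compute_mac(cohort, define_minor_alleles(cohort, "controls"))
        with pytest.raises(ValueError, match="duplicate"):
            multivariate_fit(cohort, mac, ["age", "age"])

    def test_listwise_deletion_counts_missing_covariates(self):
        cfg = SimConfig(n_cases=60, n_controls=60, n_snps=10, seed=2,
                        covariates=(CovariateSpec("age", ("normal", 50, 5), 0.0),))
        cohort, _ = simulate_cohort(cfg)
        cohort.covariates.loc[3, "age"] = np.nan
        cohort.covariates.loc[7, "age"] = np.nan
        mac = compute_mac(cohort, define_minor_alleles(cohort, "controls"))
        model = multivariate_fit(cohort, mac)
        assert model.n_dropped == 2
        assert model.n_used == cohort.n_samples - 2
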