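"""Risk-model building, flip detection, and Eq-style GRS scoring."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from macrisk.assoc import per_snp_assoc
from macrisk.cohort import MISSING, GenotypeCohort, SnpRecord
from macrisk.ld import prune
from macrisk.mac import define_minor_alleles
from macrisk.risk import RiskModel, build_model, score
from macrisk.simulate import SimConfig, simulate_cohort

from conftest import brute_grs, random_cohort


def _model(rows) -> RiskModel:
    snps = pd.DataFrame(rows, columns=["snp_id", "allele", "beta"]).set_index("snp_id")
    return RiskModel(snps=snps, p_threshold=1.0, ld_r2=None, flip_snp_ids=[])


class TestScore:
    def test_hand_worked_example(self):
        # hom-minor at beta 0.2 contributes 0.2; het at beta 0.3 contributes 0.15
        snps = [SnpRecord("s1", "1", 100, "A", "G"), SnpRecord("s2", "1", 90_000_000, "A", "G")]
        dosage = np.array([[2, 1], [0, 0]], dtype=np.int8)
        cohort = GenotypeCohort(["carrier", "ref"], snps, dosage, np.array([1, 0]))
        model = _model([("s1", "G", 0.2), ("s2", "G", 0.3)])
        result = score(cohort, model)
        assert result.grs[0] == pytest.approx(0.2 + 0.5 * 0.3, abs=1e-12)
        assert result.grs[1] == 0.0  # all-major homozygote

    def test_matches_brute_force_on_random_cohorts(self, rng):
        for _ in range(50):
            cohort = random_cohort(
                rng, n_samples=int(rng.integers(8, 30)), n_snps=int(rng.integers(5, 25)),
                missing_rate=0.15,
            )
            rows = []
            for snp in cohort.snps:
                if rng.random() < 0.7:
                    allele = snp.allele_b if rng.random() < 0.5 else snp.allele_a
                    rows.append((snp.snp_id, allele, float(rng.normal(0, 0.4))))
            if not rows:
                continue
            result = score(cohort, _model(rows))
            oracle = brute_grs(cohort, rows)
            assert np.allclose(result.grs, oracle, atol=1e-12)

    def test_additive_over_disjoint_snp_subsets(self, rng):
        cohort = random_cohort(rng, n_samples=25, n_snps=20, missing_rate=0.1)
        rows = [(s.snp_id, s.allele_b, float(rng.normal(0, 0.3))) for s in cohort.snps]
        whole = score(cohort, _model(rows)).grs
        part1 = score(cohort, _model(rows[:9])).grs
        part2 = score(cohort, _model(rows[9:])).grs
        assert np.allclose(whole, part1 + part2, atol=1e-12)

    def test_negating_betas_negates_scores(self, rng):
        cohort = random_cohort(rng, n_samples=20, n_snps=10, missing_rate=0.05)
        rows = [(s.snp_id, s.allele_b, float(rng.normal(0, 0.3))) for s in cohort.snps]
        neg = [(sid, al, -b) for sid, al, b in rows]
        assert np.allclose(score(cohort, _model(rows)).grs,
                           -score(cohort, _model(neg)).grs, atol=1e-12)

    def test_partial_overlap_reports_transfer_coverage(self, rng):
        cohort = random_cohort(rng, n_samples=15, n_snps=10, missing_rate=0.0)
        rows = [(s.snp_id, s.allele_b, 0.1) for s in cohort.snps[:4]]
        rows += [(f"absent{k}", "A", 0.5) for k in range(6)]
        result = score(cohort, _model(rows))
        assert result.model_n_snps == 10
        assert result.n_overlap == 4
        assert (result.n_snps_scored <= 4).all()

    def test_missing_genotype_contributes_nothing(self):
        snps = [SnpRecord("s1", "1", 100, "A", "G")]
        dosage = np.array([[MISSING], [2]], dtype=np.int8)
        cohort = GenotypeCohort(["m", "h"], snps, dosage, np.array([1, 0]))
        result = score(cohort, _model([("s1", "G", 0.4)]))
        assert result.grs[0] == 0.0
        assert result.n_snps_scored[0] == 0
        assert result.grs[1] == pytest.approx(0.4)


@pytest.fixture(scope="module")
def trained():
    cfg = SimConfig(n_cases=300, n_controls=300, n_snps=200, n_causal=40,
                    causal_beta_law=("constant", 0.4), ld_rho=0.0, seed=10)
    cohort, _ = simulate_cohort(cfg)
    ma_ctrl = define_minor_alleles(cohort, "controls")
    ma_comb = define_minor_alleles(cohort, "combined")
    assoc = per_snp_assoc(cohort, ma_comb)
    return cohort, assoc, ma_ctrl, ma_comb


class TestBuildModel:
    def test_vacuous_threshold_keeps_every_converged_snp(self, trained):
        _, assoc, ma_ctrl, ma_comb = trained
        model = build_model(assoc, 1.1, None, ma_ctrl, ma_comb)
        assert model.n_snps == int(assoc.table["converged"].sum())

    def test_threshold_and_prune_filter_compose(self, trained):
        cohort, assoc, ma_ctrl, ma_comb = trained
        kept = prune(cohort, 0.9, seed=0)
        model = build_model(assoc, 0.05, kept, ma_ctrl, ma_comb)
        assert set(model.snps.index) <= set(kept.kept_snp_ids)
        assert (assoc.table.loc[model.snps.index, "p"] < 0.05).all()
        assert model.ld_r2 == 0.9

    def test_empty_model_raises_with_advice(self, trained):
        _, assoc, ma_ctrl, ma_comb = trained
        with pytest.raises(ValueError, match="loosen"):
            build_model(assoc, 1e-300, None, ma_ctrl, ma_comb)

    def test_null_model_size_near_binomial_expectation(self):
        cfg = SimConfig(n_cases=400, n_controls=400, n_snps=2000, n_causal=0,
                        ld_rho=0.0, intercept=0.0, seed=18)
        cohort, _ = simulate_cohort(cfg)
        ma_ctrl = define_minor_alleles(cohort, "controls")
        ma_comb = define_minor_alleles(cohort, "combined")
        assoc = per_snp_assoc(cohort, ma_comb)
        model = build_model(assoc, 1e-2, None, ma_ctrl, ma_comb)
        m = int(assoc.table["converged"].sum())
        expect = m * 1e-2
        sd = np.sqrt(expect * (1 - 1e-2))
        assert abs(model.n_snps - expect) <= 3 * sd


class TestFlipDetection:
    def _flip_fixture(self):
        # one SNP constructed so control minor != combined minor, one clean
        flip_col = [2] * 10 + ([0] * 6 + [1] * 2)  # cases hom-b, controls mostly a
        clean_col = [1, 0] * 9
        dosage = np.column_stack([flip_col, clean_col]).astype(np.int8)
        snps = [SnpRecord("flipper", "1", 100, "A", "G"),
                SnpRecord("clean", "1", 90_000_000, "A", "G")]
        status = np.array([1] * 10 + [0] * 8)
        cohort = GenotypeCohort([f"i{k}" for k in range(18)], snps, dosage, status)
        ma_ctrl = define_minor_alleles(cohort, "controls")
        ma_comb = define_minor_alleles(cohort, "combined")
        assoc = per_snp_assoc(cohort, ma_comb)
        # make both SNPs eligible regardless of convergence at this tiny n
        assoc.table["converged"] = True
        assoc.table["p"] = 0.01
        assoc.table["beta"] = assoc.table["beta"].fillna(1.0)
        return assoc, ma_ctrl, ma_comb

    def test_flip_recorded_and_optionally_dropped(self):
        assoc, ma_ctrl, ma_comb = self._flip_fixture()
        kept_model = build_model(assoc, 0.05, None, ma_ctrl, ma_comb, drop_flips=False)
        assert kept_model.flip_snp_ids == ["flipper"]
        assert kept_model.n_snps == 2
        dropped_model = build_model(assoc, 0.05, None, ma_ctrl, ma_comb, drop_flips=True)
        assert dropped_model.n_snps == 1
        assert "flipper" not in dropped_model.snps.index
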