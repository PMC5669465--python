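"""Minor-allele tables and the MAC burden statistic."""

from __future__ import annotations

import numpy as np
import pytest

from macrisk.cohort import MISSING, GenotypeCohort, SnpRecord
from macrisk.mac import (
    compare_mac,
    compute_mac,
    define_minor_alleles,
    mac_case_control,
)
from macrisk.simulate import SimConfig, simulate_cohort

from conftest import brute_mac, random_cohort


def _cohort_from_columns(cols, status, snps=None):
    dosage = np.array(cols, dtype=np.int8).T
    n, m = dosage.shape
    if snps is None:
        snps = [SnpRecord(f"s{j}", "1", (j + 1) * 10, "A", "G") for j in range(m)]
    return GenotypeCohort([f"i{k}" for k in range(n)], snps, dosage, np.array(status))


class TestDefineMinorAlleles:
    def test_control_frequency_counting(self):
        # controls have allele_b dosages (0, 0, 1): freq_b = 1/6
        cohort = _cohort_from_columns([[2, 0, 0, 1]], status=[1, 0, 0, 0])
        table = define_minor_alleles(cohort, "controls")
        row = table.table.loc["s0"]
        assert row["minor_is_b"]
        assert row["minor_allele"] == "G"
        assert row["maf"] == pytest.approx(1 / 6)

    @pytest.mark.parametrize("maf_col, included", [([0, 1] * 10, False), ([0, 0, 1, 0] * 5, True)])
    def test_mac_eligibility_rule(self, maf_col, included):
        # freq 0.25 -> included; freq 0.45 band [0.4, 0.5] -> excluded
        col = [1] * 9 + [0] * 11  # freq_b = 9/40 = 0.225
        if not included:
            col = [1] * 18 + [0] * 2  # freq_b = 18/40 = 0.45
        cohort = _cohort_from_columns([col], status=[1, 0] * 10)
        table = define_minor_alleles(cohort, "controls")
        assert bool(table.table.loc["s0", "included_in_mac"]) is included

    def test_tie_at_half_broken_alphabetically_and_flagged(self):
        cohort = _cohort_from_columns([[0, 2, 1, 1]], status=[0, 0, 0, 0])
        table = define_minor_alleles(cohort, "controls")
        row = table.table.loc["s0"]
        assert row["tie"]
        assert row["minor_allele"] == "A"  # A < G
        assert row["maf"] == 0.5

    def test_control_vs_combined_flip(self):
        # allele_b rare in controls but common in cases: the two reference
        # groups disagree on the minor allele
        control_col = [0] * 6 + [1] * 2  # freq_b in controls = 2/16 < 0.5
        case_col = [2] * 10  # cases all hom-b
        col = case_col + control_col
        cohort = _cohort_from_columns([col], status=[1] * 10 + [0] * 8)
        t_ctrl = define_minor_alleles(cohort, "controls")
        t_comb = define_minor_alleles(cohort, "combined")
        assert t_ctrl.table.loc["s0", "minor_allele"] == "G"
        assert t_comb.table.loc["s0", "minor_allele"] == "A"

    def test_agreement_when_frequencies_same_side(self, rng):
        # property: tables agree whenever case and control freq_b sit on the
        # same side of 0.5
        for _ in range(20):
            cohort = random_cohort(rng, n_samples=60, n_snps=20, missing_rate=0.05)
            t_ctrl = define_minor_alleles(cohort, "controls")
            t_comb = define_minor_alleles(cohort, "combined")
            d = cohort.dosage_float()
            for j, snp in enumerate(cohort.snps):
                fc = np.nanmean(d[~cohort.is_case, j]) / 2
                fa = np.nanmean(d[:, j]) / 2
                if (fc - 0.5) * (fa - 0.5) > 0:
                    assert (
                        t_ctrl.table.loc[snp.snp_id, "minor_allele"]
                        == t_comb.table.loc[snp.snp_id, "minor_allele"]
                    )


class TestComputeMac:
    def test_definition_arithmetic(self):
        # sample i0 carries minor-allele copies (0, 1, 2, MISSING) over the
        # 4 eligible SNPs -> MAC = (0 + 1 + 2) / 3 = 1.0
        cols = [
            [0, 0, 0, 0],
            [1, 0, 0, 0],
            [2, 0, 0, 0],
            [MISSING, 0, 0, 1],
        ]
        cohort = _cohort_from_columns(cols, status=[1, 0, 0, 0])
        table = define_minor_alleles(cohort, "combined")
        assert table.table["included_in_mac"].all()
        result = compute_mac(cohort, table)
        i = result.sample_ids.index("i0")
        assert result.n_snps_used[i] == 3
        assert result.mac[i] == pytest.approx(1.0, abs=1e-12)
        expected = brute_mac(
            cohort,
            dict(table.table["minor_is_b"]),
            dict(table.table["included_in_mac"]),
        )["i0"]
        assert result.mac[i] == pytest.approx(expected, abs=1e-12)

    def test_all_major_homozygote_scores_zero(self):
        cols = [[0, 0, 0, 1], [0, 0, 1, 0]]
        cohort = _cohort_from_columns(cols, status=[1, 0, 0, 0])
        table = define_minor_alleles(cohort, "controls")
        result = compute_mac(cohort, table)
        assert result.mac[result.sample_ids.index("i0")] == 0.0

    def test_matches_brute_force_on_random_cohorts(self, rng):
        for _ in range(50):
            cohort = random_cohort(
                rng,
                n_samples=int(rng.integers(10, 40)),
                n_snps=int(rng.integers(5, 30)),
                missing_rate=0.15,
            )
            table = define_minor_alleles(cohort, "controls")
            result = compute_mac(cohort, table)
            oracle = brute_mac(
                cohort, dict(table.table["minor_is_b"]), dict(table.table["included_in_mac"])
            )
            assert set(result.sample_ids) == set(oracle)
            for sid, mac in zip(result.sample_ids, result.mac):
                assert mac == pytest.approx(oracle[sid], abs=1e-12)
                assert 0.0 <= mac <= 2.0

    def test_excluded_band_snps_never_affect_mac(self, rng):
        # removing the [0.4, 0.5]-MAF SNPs from the table changes nothing:
        # they are already excluded from the score
        cohort = random_cohort(rng, n_samples=80, n_snps=40, missing_rate=0.05)
        table = define_minor_alleles(cohort, "controls")
        full = compute_mac(cohort, table)
        trimmed = table.table[table.table["included_in_mac"]]
        table.table = trimmed
        again = compute_mac(cohort, table)
        assert np.allclose(full.mac, again.mac, atol=1e-15)


class TestCompareMac:
    def test_identical_groups_give_null_result(self):
        cols = [[1, 1, 1, 1], [0, 1, 0, 1]]
        cohort = _cohort_from_columns(cols, status=[1, 1, 0, 0])
        result = compute_mac(cohort, define_minor_alleles(cohort, "controls"))
        comp = compare_mac(result)
        assert comp.t == 0.0
        assert comp.p == 1.0

    def test_enriched_cohort_detected(self):
        cfg = SimConfig(n_cases=250, n_controls=250, n_snps=500, n_causal=250,
                        causal_beta_law=("constant", 0.35), p_minor_risk=1.0,
                        ld_rho=0.0, seed=33)
        cohort, _ = simulate_cohort(cfg)
        _, comp = mac_case_control(cohort)
        assert comp.case_mean > comp.control_mean
        assert comp.p < 0.001

    def test_calibrated_under_null_with_noise_free_tables(self):
        # with minor-allele identity and MAC eligibility taken from the
        # generative MAF (no in-sample estimation), the Welch t-test is
        # unbiased under the null: the case/control machinery itself adds
        # no spurious signal
        import pandas as pd

        from macrisk.mac import MinorAlleleTable

        ts = []
        rejections = 0
        for rep in range(30):
            cfg = SimConfig(n_cases=300, n_controls=300, n_snps=1000, n_causal=0,
                            intercept=0.0, seed=60_000 + rep)
            cohort, truth = simulate_cohort(cfg)
            tab = pd.DataFrame(
                {
                    "minor_is_b": True,
                    "minor_allele": "B",
                    "maf": truth.maf,
                    "included_in_mac": truth.maf < 0.4,
                    "tie": False,
                },
                index=pd.Index(truth.snp_ids, name="snp_id"),
            )
            result = compute_mac(cohort, MinorAlleleTable(tab, "controls"))
            comp = compare_mac(result)
            ts.append(comp.t)
            rejections += comp.p < 0.05
        assert abs(np.mean(ts)) < 0.6  # se of the mean ~ 0.18 under the null
        assert rejections <= 6

    def test_single_sample_group_rejected(self):
        cols = [[1, 0, 0, 1]]
        cohort = _cohort_from_columns(cols, status=[1, 0, 0, 0])
        result = compute_mac(cohort, define_minor_alleles(cohort, "controls"))
        with pytest.raises(ValueError):
            compare_mac(result)
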