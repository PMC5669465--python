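"""SNP and sample quality control, and PCA outlier removal.

Filters mirror standard array-QC practice for case-control panels: SNPs
failing Hardy-Weinberg equilibrium in cases or in controls (asymptotic
1-df chi-squared, p < 1e-4), SNPs with > 5% missing genotypes or MAF < 1%,
non-autosomal SNPs, and samples with > 10% missing genotypes.  Population
outliers are removed by rectangular bounds on top principal components of
the standardized genotype matrix.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .cohort import MISSING, GenotypeCohort

__all__ = [
    "QcReport",
    "hwe_chisq",
    "apply_snp_filters",
    "apply_sample_filters",
    "apply_qc",
    "pca_outliers",
]


@dataclasses.dataclass
class QcReport:
    """Accounting of one QC pass.

    Every removed SNP/sample carries exactly one reason (the first failing
    filter in the documented order), so counts satisfy
    ``n_in == n_out + len(removed)``.
    """

    n_snps_in: int = 0
    n_snps_out: int = 0
    n_samples_in: int = 0
    n_samples_out: int = 0
    removed_snps: dict[str, str] = dataclasses.field(default_factory=dict)
    removed_samples: dict[str, str] = dataclasses.field(default_factory=dict)
    thresholds: dict[str, float] = dataclasses.field(default_factory=dict)

    def check_accounting(self) -> None:
        assert self.n_snps_out + len(self.removed_snps) == self.n_snps_in
        assert self.n_samples_out + len(self.removed_samples) == self.n_samples_in

    def to_frame(self) -> pd.DataFrame:
        rows = [("snp", k, v) for k, v in self.removed_snps.items()]
        rows += [("sample", k, v) for k, v in self.removed_samples.items()]
        return pd.DataFrame(rows, columns=["kind", "id", "reason"])


def hwe_chisq(genotype_counts: Sequence[int]) -> tuple[float, float]:
    """Hardy-Weinberg 1-df chi-squared test from (n_AA, n_Aa, n_aa) counts.

    Expected counts come from the estimated allele frequency
    ``p = (2 n_AA + n_Aa) / 2n``.  A monomorphic SNP (p in {0, 1}) returns
    ``(0.0, 1.0)`` by convention: no test is possible.
    """
    n_aa_, n_ab, n_bb = (int(c) for c in genotype_counts)
    n = n_aa_ + n_ab + n_bb
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * n_aa_ + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 0.0, 1.0
    q = 1.0 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_aa_, n_ab, n_bb], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(chi2_dist.sf(chi2, df=1))


def _hwe_pvalues(dosage: np.ndarray) -> np.ndarray:
    """Vectorized per-SNP HWE p-values over the rows of ``dosage``."""
    n0 = (dosage == 0).sum(axis=0).astype(float)
    n1 = (dosage == 1).sum(axis=0).astype(float)
    n2 = (dosage == 2).sum(axis=0).astype(float)
    n = n0 + n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * n0 + n1) / (2 * n)
        q = 1.0 - p
        e0, e1, e2 = n * p * p, 2 * n * p * q, n * q * q
        chi2 = (n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2
    pvals = chi2_dist.sf(chi2, df=1)
    degenerate = (n == 0) | (p <= 0.0) | (p >= 1.0)
    pvals[degenerate] = 1.0
    return pvals


def _snp_stats(cohort: GenotypeCohort) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP missing fraction and cohort MAF over non-missing genotypes."""
    missing = cohort.dosage == MISSING
    miss_frac = missing.mean(axis=0)
    nonmiss = (~missing).sum(axis=0)
    alt = np.where(missing, 0, cohort.dosage).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_b = alt / (2.0 * nonmiss)
    freq_b = np.where(nonmiss > 0, freq_b, np.nan)
    maf = np.fmin(freq_b, 1.0 - freq_b)
    return miss_frac, maf


def apply_snp_filters(
    cohort: GenotypeCohort,
    hwe_p_max: float = 1e-4,
    snp_missing_max: float = 0.05,
    maf_min: float = 0.01,
) -> tuple[GenotypeCohort, QcReport]:
    """Drop SNPs failing the standard array-QC filters.

    Reasons are attributed in the order: non-autosomal, missingness
    (> ``snp_missing_max``), MAF (< ``maf_min``), HWE (p < ``hwe_p_max`` in
    cases or in controls).  A SNP entirely missing also falls under
    missingness/MAF as appropriate.
    """
    cohort.require_case_control()
    report = QcReport(
        n_snps_in=cohort.n_snps,
        n_samples_in=cohort.n_samples,
        n_samples_out=cohort.n_samples,
        thresholds={
            "hwe_p_max": hwe_p_max,
            "snp_missing_max": snp_missing_max,
            "maf_min": maf_min,
        },
    )
    miss_frac, maf = _snp_stats(cohort)
    hwe_case = _hwe_pvalues(cohort.dosage[cohort.is_case, :])
    hwe_control = _hwe_pvalues(cohort.dosage[~cohort.is_case, :])

    keep = np.ones(cohort.n_snps, dtype=bool)
    for snp_j, snp in enumerate(cohort.snps):
        if not snp.is_autosomal:
            reason = "non_autosomal"
        elif miss_frac[snp_j] > snp_missing_max:
            reason = "missingness"
        elif np.isnan(maf[snp_j]) or maf[snp_j] < maf_min:
            reason = "maf"
        elif hwe_case[snp_j] < hwe_p_max:
            reason = "hwe_case"
        elif hwe_control[snp_j] < hwe_p_max:
            reason = "hwe_control"
        else:
            continue
        keep[snp_j] = False
        report.removed_snps[snp.snp_id] = reason

    if not keep.any():
        raise ValueError("no SNP survives the SNP filters")
    filtered = cohort.take_snps(np.flatnonzero(keep))
    report.n_snps_out = filtered.n_snps
    report.check_accounting()
    return filtered, report


def apply_sample_filters(
    cohort: GenotypeCohort, sample_missing_max: float = 0.10
) -> tuple[GenotypeCohort, QcReport]:
    """Drop samples whose missing-genotype fraction exceeds the threshold."""
    report = QcReport(
        n_snps_in=cohort.n_snps,
        n_snps_out=cohort.n_snps,
        n_samples_in=cohort.n_samples,
        thresholds={"sample_missing_max": sample_missing_max},
    )
    miss_frac = (cohort.dosage == MISSING).mean(axis=1)
    keep = miss_frac <= sample_missing_max
    for i in np.flatnonzero(~keep):
        report.removed_samples[cohort.samples[i]] = "missingness"
    if not keep.any():
        raise ValueError("no sample survives the sample filters")
    filtered = cohort.take_samples(np.flatnonzero(keep))
    report.n_samples_out = filtered.n_samples
    report.check_accounting()
    return filtered, report


def apply_qc(
    cohort: GenotypeCohort,
    hwe_p_max: float = 1e-4,
    snp_missing_max: float = 0.05,
    maf_min: float = 0.01,
    sample_missing_max: float = 0.10,
    pc_bounds: Mapping[int, tuple[float, float]] | None = None,
    n_components: int = 3,
    pca_ld_r2: float | None = None,
    seed: int = 0,
) -> tuple[GenotypeCohort, QcReport]:
    """SNP filters, then sample filters, then optional PCA outlier removal.

    ``pca_ld_r2``, if given, LD-prunes the SNPs at that r^2 before the PCA
    so the components are not dominated by a few long-range LD blocks; the
    pruning affects only the PCA, not the returned cohort.
    """
    cohort, snp_report = apply_snp_filters(cohort, hwe_p_max, snp_missing_max, maf_min)
    cohort, sample_report = apply_sample_filters(cohort, sample_missing_max)
    report = QcReport(
        n_snps_in=snp_report.n_snps_in,
        n_snps_out=snp_report.n_snps_out,
        n_samples_in=sample_report.n_samples_in,
        removed_snps=snp_report.removed_snps,
        removed_samples=dict(sample_report.removed_samples),
        thresholds={**snp_report.thresholds, **sample_report.thresholds},
    )
    if pc_bounds:
        pca_cohort = cohort
        if pca_ld_r2 is not None:
            from .ld import prune

            kept_snps = prune(cohort, pca_ld_r2, seed=seed)
            pca_cohort = cohort.subset_snp_ids(kept_snps.kept_snp_ids)
        kept_ids, _coords = pca_outliers(pca_cohort, n_components=n_components, bounds=pc_bounds)
        kept_set = set(kept_ids)
        for sid in cohort.samples:
            if sid not in kept_set:
                report.removed_samples[sid] = "pca_outlier"
        cohort = cohort.take_samples(
            [i for i, s in enumerate(cohort.samples) if s in kept_set]
        )
    report.n_samples_out = cohort.n_samples
    report.check_accounting()
    return cohort, report


def pca_outliers(
    cohort: GenotypeCohort,
    n_components: int = 3,
    bounds: Mapping[int, tuple[float, float]] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Principal components of the genotype matrix and rectangular outlier bounds.

    Each SNP column is mean-imputed at missing genotypes, centered, and
    scaled to unit variance; sample coordinates are the unit-norm left
    singular vectors of the standardized matrix (EIGENSTRAT/GCTA-style
    scaling, so entries are O(1/sqrt(n))).  ``bounds`` maps a 1-based PC
    number to a (low, high) interval; samples falling outside any interval
    are reported as outliers.  Bounds are dataset-specific and supplied by
    the user, as is conventional for visual PCA-based outlier trimming.
    """
    if cohort.n_samples < 2 or cohort.n_snps < 2:
        raise ValueError("PCA needs at least 2 samples and 2 SNPs")
    from sklearn.utils.extmath import randomized_svd

    x = cohort.dosage_float()
    col_mean = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_mean, inds[1])
    x -= col_mean
    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("genotype matrix has zero variance everywhere")
    x = x[:, keep] / sd[keep]

    n_components = min(n_components, cohort.n_samples - 1, int(keep.sum()))
    u, s, _vt = randomized_svd(x, n_components=n_components, random_state=0)
    # deterministic sign: largest-magnitude entry of each PC is positive
    for k in range(u.shape[1]):
        j = np.argmax(np.abs(u[:, k]))
        if u[j, k] < 0:
            u[:, k] = -u[:, k]
    coords = pd.DataFrame(
        u,
        index=pd.Index(cohort.samples, name="sample_id"),
        columns=[f"PC{k + 1}" for k in range(u.shape[1])],
    )

    kept = np.ones(cohort.n_samples, dtype=bool)
    if bounds:
        for pc, (lo, hi) in bounds.items():
            col = f"PC{pc}"
            if col not in coords.columns:
                raise ValueError(f"bounds given for {col} but only {u.shape[1]} PCs computed")
            v = coords[col].to_numpy()
            kept &= (v >= lo) & (v <= hi)
    kept_ids = [s for s, k in zip(cohort.samples, kept) if k]
    return kept_ids, coords
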