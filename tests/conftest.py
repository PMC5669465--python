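"""Shared fixtures and brute-force oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from macrisk.cohort import MISSING, GenotypeCohort, SnpRecord


def random_cohort(
    rng: np.random.Generator,
    n_samples: int = 40,
    n_snps: int = 25,
    missing_rate: float = 0.05,
    n_chroms: int = 3,
) -> GenotypeCohort:
    """A small random cohort with no particular structure."""
    maf = rng.uniform(0.05, 0.5, n_snps)
    dosage = rng.binomial(2, maf, size=(n_samples, n_snps)).astype(np.int8)
    if missing_rate > 0:
        dosage[rng.random(dosage.shape) < missing_rate] = MISSING
    status = np.zeros(n_samples, dtype=np.int8)
    status[: n_samples // 2] = 1
    rng.shuffle(status)
    # ensure both classes
    status[0], status[1] = 1, 0
    alleles = ["A", "C", "G", "T"]
    snps = []
    pos = {}
    for j in range(n_snps):
        chrom = str(rng.integers(1, n_chroms + 1))
        pos[chrom] = pos.get(chrom, 0) + int(rng.integers(1_000, 50_000))
        a, b = rng.choice(alleles, size=2, replace=False)
        snps.append(
            SnpRecord(snp_id=f"rs{j:04d}", chrom=chrom, pos_bp=pos[chrom], allele_a=a, allele_b=b)
        )
    samples = [f"I{i:04d}" for i in range(n_samples)]
    return GenotypeCohort(samples=samples, snps=snps, dosage=dosage, status=status)


# ----------------------------------------------------------------------
# independent brute-force oracles (naive loops, no shared code paths)


def brute_mac(cohort: GenotypeCohort, minor_is_b: dict[str, bool], included: dict[str, bool]):
    """Naive per-sample MAC loop: returns (sample_id -> mac) skipping unusable."""
    out = {}
    for i, sid in enumerate(cohort.samples):
        num = 0.0
        den = 0
        for j, snp in enumerate(cohort.snps):
            if snp.snp_id not in minor_is_b or not included[snp.snp_id]:
                continue
            g = int(cohort.dosage[i, j])
            if g == MISSING:
                continue
            copies = g if minor_is_b[snp.snp_id] else 2 - g
            num += copies
            den += 1
        if den > 0:
            out[sid] = num / den
    return out


def brute_grs(cohort: GenotypeCohort, model_rows: list[tuple[str, str, float]]):
    """Naive per-sample GRS loop over (snp_id, allele, beta) rows."""
    idx = {s.snp_id: j for j, s in enumerate(cohort.snps)}
    out = np.zeros(cohort.n_samples)
    for i in range(cohort.n_samples):
        total = 0.0
        for sid, allele, beta in model_rows:
            j = idx.get(sid)
            if j is None:
                continue
            g = int(cohort.dosage[i, j])
            if g == MISSING:
                continue
            snp = cohort.snps[j]
            copies = g if allele == snp.allele_b else 2 - g
            if copies == 2:
                total += beta
            elif copies == 1:
                total += 0.5 * beta
        out[i] = total
    return out


def brute_auc(scores: np.ndarray, status: np.ndarray) -> float:
    """All-pairs concordance count."""
    cases = scores[status == 1]
    controls = scores[status == 0]
    wins = ties = 0
    for c in cases:
        for k in controls:
            if c > k:
                wins += 1
            elif c == k:
                ties += 1
    return (wins + 0.5 * ties) / (len(cases) * len(controls))


def brute_tpr_full_spec(scores: np.ndarray, status: np.ndarray) -> float:
    cases = scores[status == 1]
    top = max(scores[status == 0])
    return sum(1 for c in cases if c > top) / len(cases)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
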