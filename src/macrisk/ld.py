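"""Windowed LD pruning on genotype-dosage r^2.

r^2 is the squared Pearson correlation of dosage vectors over pairwise
complete observations (composite LD; no phasing).  Pruning scans SNPs in
position order and, for every still-kept pair on the same chromosome within
the base-pair window whose r^2 exceeds the threshold, removes one member by
a seeded fair coin, until no violating kept pair remains.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .cohort import GenotypeCohort

__all__ = ["PruneResult", "genotype_r2", "prune", "verify_pruned"]


def _chrom_key(chrom: object) -> tuple:
    """Sort key placing numeric chromosomes in natural order."""
    s = str(chrom).lower().removeprefix("chr")
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


@dataclasses.dataclass
class PruneResult:
    kept_snp_ids: list[str]
    removed_snp_ids: list[str]
    r2_threshold: float
    window_bp: int
    seed: int

    @property
    def n_removed(self) -> int:
        return len(self.removed_snp_ids)


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing genotypes (NaN or the int8 sentinel -1) are removed pairwise.
    Zero variance in either vector over the overlap returns 0.0 (flagged
    monomorphic-in-overlap via a warning).  Fewer than two complete pairs
    is a precondition breach.
    """
    x = np.asarray(x, dtype=float).copy()
    y = np.asarray(y, dtype=float).copy()
    x[x == -1] = np.nan
    y[y == -1] = np.nan
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        raise ValueError("need at least 2 complete pairs to compute r^2")
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        warnings.warn("monomorphic in overlap; r^2 set to 0", stacklevel=2)
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def _window_r2(
    X0: np.ndarray,
    X0sq: np.ndarray,
    M: np.ndarray,
    order: np.ndarray,
    pos: np.ndarray,
    chroms: np.ndarray,
    window_bp: int,
    chunk: int = 512,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Pairwise-deletion r^2 for every same-chromosome pair within the window.

    X0 is the dosage matrix with missing set to 0, X0sq its square, M the
    0/1 non-missing indicator; under pairwise deletion every pair's
    sufficient statistics reduce to gram-matrix entries, computed here in
    chunked BLAS matmuls.  Returns, per sorted position a, the sorted
    positions ahead of it within the window and their r^2 values.
    """
    n_sorted = len(order)
    pos_s = pos[order]
    chrom_s = chroms[order]
    # window end (exclusive) for each sorted index
    ends = np.empty(n_sorted, dtype=np.intp)
    e = 0
    for a in range(n_sorted):
        e = max(e, a + 1)
        while e < n_sorted and chrom_s[e] == chrom_s[a] and pos_s[e] - pos_s[a] <= window_bp:
            e += 1
        ends[a] = e

    out: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    a0 = 0
    while a0 < n_sorted:
        a1 = min(a0 + chunk, n_sorted)
        e_max = int(ends[a0:a1].max())
        rows = order[a0:a1]
        cols = order[a0:e_max]
        Xr, Xr2, Mr = X0[:, rows], X0sq[:, rows], M[:, rows]
        Xc, Xc2, Mc = X0[:, cols], X0sq[:, cols], M[:, cols]
        N = Mr.T @ Mc
        SX = Xr.T @ Mc  # sum of x_i over pairwise-complete, per (i, j)
        SY = Mr.T @ Xc
        SXX = Xr2.T @ Mc
        SYY = Mr.T @ Xc2
        SXY = Xr.T @ Xc
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = SXY - SX * SY / N
            vx = SXX - SX * SX / N
            vy = SYY - SY * SY / N
            r2 = cov * cov / (vx * vy)
        r2 = np.where((N >= 2) & (vx > 1e-12) & (vy > 1e-12), r2, 0.0)
        for a in range(a0, a1):
            if ends[a] > a + 1:
                ahead = np.arange(a + 1, ends[a])
                out[a] = (ahead, r2[a - a0, ahead - a0])
        a0 = a1
    return out


def prune(
    cohort: GenotypeCohort,
    r2_threshold: float,
    window_bp: int = 200_000,
    seed: int = 0,
) -> PruneResult:
    """Randomly prune one SNP of each high-LD pair within a physical window.

    Deterministic for a given seed: pairs are enumerated in position order
    and each violating pair consumes one fair-coin flip deciding which
    member is removed.  Input SNPs not sorted by (chromosome, position) are
    sorted internally with a notice; kept ids are returned in cohort order.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must lie in (0, 1]")
    chroms = cohort.chroms
    pos = cohort.positions
    order = np.array(
        sorted(range(cohort.n_snps), key=lambda j: (_chrom_key(chroms[j]), pos[j])),
        dtype=np.intp,
    )
    if not np.array_equal(order, np.arange(cohort.n_snps)):
        warnings.warn("SNPs not sorted by (chrom, pos); sorting internally", stacklevel=2)

    X = cohort.dosage_float()
    M = (~np.isnan(X)).astype(np.float64)
    X0 = np.where(np.isnan(X), 0.0, X)
    X0sq = X0 * X0
    window = _window_r2(X0, X0sq, M, order, pos, chroms, window_bp)

    rng = np.random.default_rng(seed)
    kept = np.ones(cohort.n_snps, dtype=bool)
    for a in range(len(order)):
        i = order[a]
        if not kept[i] or a not in window:
            continue
        ahead, r2 = window[a]
        removed_i = False
        for b, r2_ij in zip(ahead, r2):
            j = order[b]
            if kept[j] and r2_ij > r2_threshold:
                if rng.random() < 0.5:
                    kept[i] = False
                    removed_i = True
                else:
                    kept[j] = False
            if removed_i:
                break

    kept_ids = [s.snp_id for s, k in zip(cohort.snps, kept) if k]
    removed_ids = [s.snp_id for s, k in zip(cohort.snps, kept) if not k]
    return PruneResult(
        kept_snp_ids=kept_ids,
        removed_snp_ids=removed_ids,
        r2_threshold=r2_threshold,
        window_bp=window_bp,
        seed=seed,
    )


def verify_pruned(cohort: GenotypeCohort, result: PruneResult) -> bool:
    """Brute-force post-hoc check of the pruning invariant.

    True iff no kept same-chromosome pair within the window has
    r^2 > threshold.
    """
    sub = cohort.subset_snp_ids(result.kept_snp_ids)
    pos = sub.positions
    chroms = sub.chroms
    d = sub.dosage_float()
    order = sorted(range(sub.n_snps), key=lambda j: (_chrom_key(chroms[j]), pos[j]))
    for a in range(len(order)):
        for b in range(a + 1, len(order)):
            i, j = order[a], order[b]
            if chroms[j] != chroms[i] or pos[j] - pos[i] > result.window_bp:
                break
            if genotype_r2(d[:, i], d[:, j]) > result.r2_threshold:
                return False
    return True
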