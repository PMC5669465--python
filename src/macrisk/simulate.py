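"""Synthetic case-control genotype cohorts.

The generator emulates the statistical structure the downstream analysis
assumes: biallelic autosomal SNPs with a mostly-common MAF spectrum, block
LD, binary disease status from a logistic model over many small-effect
risk alleles preferentially aligned with minor alleles (so cases carry an
elevated minor-allele burden), optional covariates, missing genotypes, and
an optional two-subpopulation structure for PCA-outlier testing.

Genotypes come from a Gaussian-copula haplotype model: per individual
haplotype, a latent standard-normal vector with exchangeable correlation
``ld_rho`` inside each block is thresholded at the MAF quantile; the two
haplotypes are summed into a 0/1/2 dosage.  This gives direct, tunable
control over the two quantities the pipeline's statistics actually touch
(per-SNP MAF and within-block genotype r^2) without simulating demographic
history.

Case/control status is ascertained by rejection sampling: individuals are
drawn from the population model until the requested numbers of cases and
controls are reached, mirroring an ascertained case-control panel rather
than a population sample.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .cohort import MISSING, GenotypeCohort, SnpRecord

__all__ = [
    "CovariateSpec",
    "SimConfig",
    "SimTruth",
    "SimulationError",
    "simulate_cohort",
    "simulate_split",
    "split_cohort",
]

_MAX_DRAWS = 1_000_000


class SimulationError(RuntimeError):
    """Raised when the configured disease model cannot yield the requested cohort."""


def _draw(law: tuple, rng: np.random.Generator, size: int) -> np.ndarray:
    """Draw from a small tuple-coded distribution spec.

    Supported: ``("uniform", lo, hi)``, ``("normal", mu, sd)``,
    ``("bernoulli", p)``, ``("constant", value)``, and the two-component
    scale mixture ``("mixnormal", p_large, sd_small, sd_large)`` — a
    point-normal-style effect-size law mixing a polygenic background of
    small effects with a minority of large ones.
    """
    kind = law[0]
    if kind == "uniform":
        return rng.uniform(law[1], law[2], size)
    if kind == "normal":
        return rng.normal(law[1], law[2], size)
    if kind == "mixnormal":
        p_large, sd_small, sd_large = law[1], law[2], law[3]
        large = rng.random(size) < p_large
        return np.where(large, rng.normal(0.0, sd_large, size), rng.normal(0.0, sd_small, size))
    if kind == "bernoulli":
        return (rng.random(size) < law[1]).astype(float)
    if kind == "constant":
        return np.full(size, float(law[1]))
    raise ValueError(f"unknown distribution spec {law!r}")


@dataclasses.dataclass(frozen=True)
class CovariateSpec:
    """One simulated covariate: name, distribution spec, logistic coefficient."""

    name: str
    dist: tuple
    coef: float


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic cohort.

    Identical configs (including ``seed``) produce bit-identical cohorts.
    ``intercept`` is the logistic intercept on the *centered* genetic score,
    so ``expit(intercept)`` is approximately the population prevalence for a
    covariate-free model.  ``p_minor_risk`` is the probability that a causal
    effect's risk allele is the minor allele; values above 0.5 induce the
    minor-allele enrichment in cases that the burden analysis targets.
    """

    n_cases: int = 800
    n_controls: int = 1300
    n_snps: int = 5000
    maf_law: tuple = ("uniform", 0.01, 0.5)
    ld_block_size: int = 20
    ld_rho: float = 0.9
    n_causal: int = 0
    causal_beta_law: tuple = ("normal", 0.05, 0.02)
    p_minor_risk: float = 0.8
    intercept: float = -2.2
    missing_rate: float = 0.0
    covariates: tuple[CovariateSpec, ...] = ()
    substructure: tuple[float, float] | None = None  # (fraction_outliers, fst)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be positive")
        if not 0 <= self.n_causal <= self.n_snps:
            raise ValueError("need 0 <= n_causal <= n_snps")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.maf_law[0] == "uniform" and not (
            0.0 < self.maf_law[1] and self.maf_law[2] <= 0.5
        ):
            raise ValueError("maf_law support must lie in (0, 0.5]")
        if not 0.0 <= self.p_minor_risk <= 1.0:
            raise ValueError("p_minor_risk must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if self.substructure is not None:
            frac, fst = self.substructure
            if not (0.0 < frac < 1.0 and 0.0 < fst < 1.0):
                raise ValueError("substructure must be (fraction in (0,1), fst in (0,1))")


@dataclasses.dataclass
class SimTruth:
    """Generative ground truth carried alongside a simulated cohort."""

    snp_ids: list[str]
    maf: np.ndarray  # generative allele_b (minor-allele) frequency per SNP
    block: np.ndarray  # LD block index per SNP
    causal_ids: list[str]
    beta: np.ndarray  # per-SNP log-odds effect on allele_b dosage (0 if non-causal)
    covariate_coefs: dict[str, float]
    outlier_samples: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "maf": self.maf,
                "block": self.block,
                "beta": self.beta,
                "causal": np.isin(self.snp_ids, self.causal_ids),
            }
        )


# ----------------------------------------------------------------------


def _snp_layout(config: SimConfig) -> tuple[list[SnpRecord], np.ndarray]:
    """Spread LD blocks over chromosomes 1..22, in (chrom, pos) order.

    SNPs within a block are 5 kb apart (block span well inside the 200 kb
    pruning window); successive blocks on one chromosome are 1 Mb apart, so
    cross-block pairs never share a window.
    """
    block = np.arange(config.n_snps) // config.ld_block_size
    n_blocks = int(block[-1]) + 1
    blocks_per_chrom = -(-n_blocks // 22)  # ceil
    snps = []
    width = len(str(config.n_snps))
    for j in range(config.n_snps):
        b = int(block[j])
        chrom = str(b // blocks_per_chrom + 1)
        pos = (b % blocks_per_chrom) * 1_000_000 + (j % config.ld_block_size) * 5_000 + 1
        snps.append(
            SnpRecord(
                snp_id=f"snp{j:0{width}d}",
                chrom=chrom,
                pos_bp=pos,
                allele_a="A",
                allele_b="B",
            )
        )
    return snps, block


def _haplotypes(
    rng: np.random.Generator,
    n: int,
    thresh: np.ndarray,
    thresh_out: np.ndarray | None,
    outlier: np.ndarray,
    block: np.ndarray,
    rho: float,
) -> np.ndarray:
    """Draw an n x m dosage batch from the copula haplotype model."""
    n_blocks = int(block[-1]) + 1
    m = thresh.shape[0]
    t = np.broadcast_to(thresh, (n, m))
    if thresh_out is not None:
        t = np.where(outlier[:, None], thresh_out, thresh)
    dosage = np.zeros((n, m), dtype=np.int8)
    sr, se = math.sqrt(rho), math.sqrt(1.0 - rho)
    for _hap in range(2):
        u = rng.standard_normal((n, n_blocks))
        z = sr * u[:, block] + se * rng.standard_normal((n, m))
        dosage += (z < t).astype(np.int8)
    return dosage


def simulate_cohort(config: SimConfig) -> tuple[GenotypeCohort, SimTruth]:
    """Simulate one ascertained case-control cohort plus its ground truth.

    Raises
    ------
    SimulationError
        If a case (or control) cannot be found within 10^6 draws, which
        indicates an intercept/effect combination making one class
        unattainably rare.
    """
    struct_rng = np.random.default_rng([config.seed, 0])
    geno_rng = np.random.default_rng([config.seed, 1])
    miss_rng = np.random.default_rng([config.seed, 2])

    snps, block = _snp_layout(config)
    maf = np.clip(_draw(config.maf_law, struct_rng, config.n_snps), 1e-6, 0.5)
    thresh = norm.ppf(maf)

    thresh_out = None
    frac_out = 0.0
    if config.substructure is not None:
        frac_out, fst = config.substructure
        # Balding-Nichols: outlier-population frequency per SNP
        a = maf * (1.0 - fst) / fst
        b = (1.0 - maf) * (1.0 - fst) / fst
        maf_out = np.clip(struct_rng.beta(a, b), 1e-6, 1.0 - 1e-6)
        thresh_out = norm.ppf(maf_out)

    beta = np.zeros(config.n_snps)
    causal_idx = np.array([], dtype=int)
    if config.n_causal > 0:
        causal_idx = np.sort(
            struct_rng.choice(config.n_snps, config.n_causal, replace=False)
        )
        magnitude = np.abs(_draw(config.causal_beta_law, struct_rng, config.n_causal))
        minor_is_risk = struct_rng.random(config.n_causal) < config.p_minor_risk
        # allele_b is the generative minor allele (freq = maf < 0.5), so a
        # positive beta on allele_b dosage makes the minor allele the risk allele
        beta[causal_idx] = np.where(minor_is_risk, magnitude, -magnitude)

    gamma = np.array([c.coef for c in config.covariates])

    need_case, need_control = config.n_cases, config.n_controls
    rows: list[np.ndarray] = []
    statuses: list[np.ndarray] = []
    cov_rows: list[np.ndarray] = []
    outlier_rows: list[np.ndarray] = []
    drawn = 0
    while need_case > 0 or need_control > 0:
        if drawn >= _MAX_DRAWS:
            missing_class = "case" if need_case > 0 else "control"
            raise SimulationError(
                f"no {missing_class} found in {_MAX_DRAWS} draws; "
                "adjust the intercept (or effect sizes) to make the class attainable"
            )
        batch = min(4096, _MAX_DRAWS - drawn)
        drawn += batch
        outlier = (
            geno_rng.random(batch) < frac_out
            if config.substructure is not None
            else np.zeros(batch, dtype=bool)
        )
        dosage = _haplotypes(
            geno_rng, batch, thresh, thresh_out, outlier, block, config.ld_rho
        )
        lin = config.intercept + (dosage - 2.0 * maf) @ beta
        if config.covariates:
            covs = np.column_stack(
                [_draw(c.dist, geno_rng, batch) for c in config.covariates]
            )
            lin = lin + covs @ gamma
        else:
            covs = np.empty((batch, 0))
        case = geno_rng.random(batch) < expit(lin)

        take = np.zeros(batch, dtype=bool)
        case_pos = np.flatnonzero(case)[:need_case]
        ctrl_pos = np.flatnonzero(~case)[:need_control]
        take[case_pos] = True
        take[ctrl_pos] = True
        need_case -= len(case_pos)
        need_control -= len(ctrl_pos)
        if take.any():
            rows.append(dosage[take])
            statuses.append(case[take].astype(np.int8))
            cov_rows.append(covs[take])
            outlier_rows.append(outlier[take])

    dosage = np.vstack(rows)
    status = np.concatenate(statuses)
    outliers = np.concatenate(outlier_rows)
    if config.missing_rate > 0:
        mask = miss_rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = MISSING

    n = dosage.shape[0]
    samples = [f"S{i:06d}" for i in range(n)]
    covariates = None
    if config.covariates:
        covariates = pd.DataFrame(
            np.vstack(cov_rows), columns=[c.name for c in config.covariates]
        )

    cohort = GenotypeCohort(
        samples=samples, snps=snps, dosage=dosage, status=status, covariates=covariates
    )
    truth = SimTruth(
        snp_ids=[s.snp_id for s in snps],
        maf=maf,
        block=block,
        causal_ids=[snps[j].snp_id for j in causal_idx],
        beta=beta,
        covariate_coefs={c.name: c.coef for c in config.covariates},
        outlier_samples=[samples[i] for i in np.flatnonzero(outliers)],
    )
    return cohort, truth


# ----------------------------------------------------------------------


def split_cohort(
    cohort: GenotypeCohort, train_fraction: float = 0.5, seed: int = 0
) -> tuple[GenotypeCohort, GenotypeCohort]:
    """Split a cohort into disjoint training/validation halves.

    The split is a seeded shuffle stratified by case/control status, so the
    two halves keep the cohort's case:control ratio (within one sample).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng([seed, 3])
    train_idx: list[np.ndarray] = []
    valid_idx: list[np.ndarray] = []
    for is_case in (True, False):
        group = np.flatnonzero(cohort.is_case == is_case)
        rng.shuffle(group)
        k = int(round(train_fraction * len(group)))
        train_idx.append(group[:k])
        valid_idx.append(group[k:])
    train = cohort.take_samples(np.sort(np.concatenate(train_idx)))
    valid = cohort.take_samples(np.sort(np.concatenate(valid_idx)))
    for half, name in ((train, "training"), (valid, "validation")):
        if not (half.is_case.any() and (~half.is_case).any()):
            raise ValueError(f"{name} half would lack a case or a control")
    return train, valid


def simulate_split(
    config: SimConfig, train_fraction: float = 0.5
) -> tuple[GenotypeCohort, GenotypeCohort, SimTruth]:
    """Simulate a cohort and split it into training/validation halves."""
    cohort, truth = simulate_cohort(config)
    train, valid = split_cohort(cohort, train_fraction, seed=config.seed)
    return train, valid, truth
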