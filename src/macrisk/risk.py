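"""Weighted genetic risk score (GRS) models.

A risk model is a set of SNPs with per-SNP log-odds weights (betas) from
the training association scan, each coded to the combined-cohort minor
allele.  The score of an individual is

    GRS = sum(beta over model SNPs homozygous for the coded allele)
        + 0.5 * sum(beta over model SNPs heterozygous),

i.e. half the beta-weighted minor-allele dosage.  Betas keep their sign
(protective minor alleles subtract), and missing genotypes contribute
nothing — a deliberate literal reading of the score rather than the
mean-dosage imputation common in PRS tooling.

Model building also detects "flip" SNPs: model SNPs whose minor allele
defined in the controls differs from the minor allele defined in the
combined cohort.  These are near-0.5-MAF SNPs whose minor-allele status is
ambiguous; dropping them typically improves the model slightly.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .assoc import AssocResult
from .cohort import GenotypeCohort
from .ld import PruneResult
from .mac import MinorAlleleTable

__all__ = ["RiskModel", "ScoreSet", "build_model", "score"]


@dataclasses.dataclass
class RiskModel:
    """A selected SNP set with coded minor alleles and beta weights."""

    snps: pd.DataFrame  # index snp_id: allele, beta
    p_threshold: float
    ld_r2: float | None
    flip_snp_ids: list[str]
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.snps) == 0:
            raise ValueError("risk model must contain at least one SNP")
        if not np.isfinite(self.snps["beta"].to_numpy()).all():
            raise ValueError("risk model betas must be finite")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def to_tsv(self, path: str | Path) -> None:
        self.snps.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, p_threshold=float("nan"), ld_r2=None) -> "RiskModel":
        snps = pd.read_csv(path, sep="\t", index_col="snp_id")
        return cls(snps=snps, p_threshold=p_threshold, ld_r2=ld_r2, flip_snp_ids=[])


@dataclasses.dataclass
class ScoreSet:
    """Per-sample GRS values for one scored cohort."""

    sample_ids: list[str]
    grs: np.ndarray
    n_snps_scored: np.ndarray  # model SNPs present and non-missing, per sample
    n_overlap: int  # model SNPs present in the scored cohort at all
    model_n_snps: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "grs": self.grs,
                "n_snps_scored": self.n_snps_scored,
            }
        )


def build_model(
    assoc: AssocResult,
    p_threshold: float,
    kept_snps: PruneResult | None,
    ma_control: MinorAlleleTable,
    ma_combined: MinorAlleleTable,
    drop_flips: bool = False,
    ld_r2: float | None = None,
) -> RiskModel:
    """Select model SNPs by P-value threshold within the pruned SNP set.

    Model SNPs are the converged association SNPs that survived LD pruning
    (``kept_snps``; ``None`` means no pruning) with p < ``p_threshold``.
    Flip SNPs — control-defined minor allele != combined-defined minor
    allele — are recorded, and removed when ``drop_flips`` is set.
    """
    t = assoc.table
    # a threshold of 1 is vacuous: include every converged SNP, even the
    # handful whose two-sided p rounds to exactly 1.0
    p_mask = (t["p"] < p_threshold) if p_threshold < 1.0 else t["p"].notna()
    mask = t["converged"] & p_mask
    if kept_snps is not None:
        mask &= t.index.isin(kept_snps.kept_snp_ids)
        if ld_r2 is None:
            ld_r2 = kept_snps.r2_threshold
    selected = t.index[mask]
    if len(selected) == 0:
        raise ValueError(
            f"no SNP passes p < {p_threshold}; loosen the threshold"
        )

    flips = []
    for sid in selected:
        if sid in ma_control.table.index and sid in ma_combined.table.index:
            if ma_control.minor_allele(sid) != ma_combined.minor_allele(sid):
                flips.append(sid)
    if drop_flips and flips:
        selected = selected[~selected.isin(flips)]
        if len(selected) == 0:
            raise ValueError("all model SNPs were control/combined flips")

    snps = pd.DataFrame(
        {
            "allele": t.loc[selected, "coded_allele"],
            "beta": t.loc[selected, "beta"],
        },
        index=pd.Index(selected, name="snp_id"),
    )
    return RiskModel(
        snps=snps,
        p_threshold=p_threshold,
        ld_r2=ld_r2,
        flip_snp_ids=flips,
        provenance={"drop_flips": drop_flips},
    )


def score(cohort: GenotypeCohort, model: RiskModel) -> ScoreSet:
    """Score every sample of a cohort with a risk model.

    Model SNPs absent from the cohort contribute nothing (the overlap is
    reported, supporting cross-cohort transfer where only part of the
    model is typed).  For each present SNP, the coded allele is matched to
    the cohort's allele pair to orient the dosage.
    """
    index = cohort.snp_index()
    cols, betas = [], []
    for sid, row in model.snps.iterrows():
        j = index.get(sid)
        if j is None:
            continue
        snp = cohort.snps[j]
        if row["allele"] == snp.allele_b:
            orient = +1
        elif row["allele"] == snp.allele_a:
            orient = -1
        else:
            warnings.warn(
                f"model allele {row['allele']!r} not found at {sid}; SNP skipped",
                stacklevel=2,
            )
            continue
        cols.append((j, orient))
        betas.append(float(row["beta"]))

    n = cohort.n_samples
    if not cols:
        warnings.warn("no model SNP present in cohort; all scores are 0", stacklevel=2)
        return ScoreSet(
            sample_ids=list(cohort.samples),
            grs=np.zeros(n),
            n_snps_scored=np.zeros(n, dtype=int),
            n_overlap=0,
            model_n_snps=model.n_snps,
        )

    js = np.array([j for j, _ in cols])
    orients = np.array([o for _, o in cols])
    beta_vec = np.array(betas)
    d = cohort.dosage[:, js].astype(np.float64)
    miss = d == -1
    ma_dosage = np.where(orients[None, :] == 1, d, 2.0 - d)
    ma_dosage[miss] = 0.0  # missing genotype contributes nothing
    grs = 0.5 * ma_dosage @ beta_vec  # hom = beta, het = beta/2
    n_scored = (~miss).sum(axis=1)
    return ScoreSet(
        sample_ids=list(cohort.samples),
        grs=grs,
        n_snps_scored=n_scored,
        n_overlap=len(cols),
        model_n_snps=model.n_snps,
    )
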