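"""Minor-allele definition and the per-individual minor-allele content (MAC).

The minor allele (MA) of a SNP is the allele with frequency below 0.5 in a
designated reference group — either the controls (for the case/control
burden comparison) or the combined cohort (for risk-score weights).  The
MAC of an individual is the average number of minor-allele copies per
examined SNP: the sum of MA copies over eligible SNPs divided by the number
of those SNPs with a non-missing genotype, so MAC lies in [0, 2].  SNPs
with reference-group MAF in [0.4, 0.5] are excluded from MAC because their
minor-allele status is too uncertain.

Case and control mean MAC are compared with Welch's two-sample t-test.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MISSING, GenotypeCohort

__all__ = [
    "MinorAlleleTable",
    "MacResult",
    "MacComparison",
    "define_minor_alleles",
    "minor_allele_dosage",
    "compute_mac",
    "compare_mac",
    "mac_case_control",
]


@dataclasses.dataclass
class MinorAlleleTable:
    """Per-SNP minor-allele identity and frequency in a reference group.

    ``table`` is indexed by snp_id with columns:

    - ``minor_is_b``: whether the minor allele is the cohort's ``allele_b``
    - ``minor_allele``: the minor allele character
    - ``maf``: the minor allele's frequency in the reference group (<= 0.5)
    - ``included_in_mac``: ``maf < mac_maf_max`` (default 0.4)
    - ``tie``: frequency exactly 0.5, broken toward the alphabetically
      first allele
    """

    table: pd.DataFrame
    reference_group: str  # "controls" or "combined"
    mac_maf_max: float = 0.4

    def __post_init__(self) -> None:
        if self.reference_group not in ("controls", "combined"):
            raise ValueError("reference_group must be 'controls' or 'combined'")
        if (self.table["maf"] > 0.5 + 1e-12).any():
            raise ValueError("maf must not exceed 0.5")

    @property
    def snp_ids(self) -> pd.Index:
        return self.table.index

    def minor_allele(self, snp_id: str) -> str:
        return self.table.at[snp_id, "minor_allele"]


def define_minor_alleles(
    cohort: GenotypeCohort,
    reference_group: str = "controls",
    mac_maf_max: float = 0.4,
) -> MinorAlleleTable:
    """Identify each SNP's minor allele from a reference group.

    Allele frequencies are computed over non-missing genotypes of the
    reference samples only (all controls, or everyone for ``combined``).
    A frequency tie at exactly 0.5 is broken toward the alphabetically
    first allele and flagged.  SNPs entirely missing in the reference group
    are excluded from the table with a warning.
    """
    if reference_group == "controls":
        idx = np.flatnonzero(~cohort.is_case)
    elif reference_group == "combined":
        idx = np.arange(cohort.n_samples)
    else:
        raise ValueError("reference_group must be 'controls' or 'combined'")
    if len(idx) == 0:
        raise ValueError("reference group is empty")

    d = cohort.dosage[idx, :]
    missing = d == MISSING
    nonmiss = (~missing).sum(axis=0)
    alt = np.where(missing, 0, d).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_b = alt / (2.0 * nonmiss)

    all_missing = nonmiss == 0
    if all_missing.any():
        names = [cohort.snps[j].snp_id for j in np.flatnonzero(all_missing)]
        warnings.warn(
            f"{len(names)} SNP(s) entirely missing in reference group, excluded: "
            + ", ".join(names[:5])
            + ("..." if len(names) > 5 else ""),
            stacklevel=2,
        )

    rows = []
    for j, snp in enumerate(cohort.snps):
        if all_missing[j]:
            continue
        fb = freq_b[j]
        tie = fb == 0.5
        if tie:
            minor_is_b = snp.allele_b < snp.allele_a
        else:
            minor_is_b = fb < 0.5
        maf = fb if minor_is_b else 1.0 - fb
        if tie:
            maf = 0.5
        rows.append(
            (
                snp.snp_id,
                bool(minor_is_b),
                snp.allele_b if minor_is_b else snp.allele_a,
                float(maf),
                bool(maf < mac_maf_max),
                bool(tie),
            )
        )
    table = pd.DataFrame(
        rows,
        columns=["snp_id", "minor_is_b", "minor_allele", "maf", "included_in_mac", "tie"],
    ).set_index("snp_id")
    return MinorAlleleTable(table=table, reference_group=reference_group, mac_maf_max=mac_maf_max)


def minor_allele_dosage(
    cohort: GenotypeCohort, ma_table: MinorAlleleTable, snp_ids=None
) -> tuple[np.ndarray, list[str]]:
    """Dosage matrix re-oriented to count minor-allele copies.

    Returns a float matrix (NaN at missing) restricted to the requested
    SNPs (default: every table SNP present in the cohort), plus the SNP
    ids of its columns in cohort order.
    """
    index = cohort.snp_index()
    if snp_ids is None:
        snp_ids = [s for s in ma_table.snp_ids if s in index]
    cols = [index[s] for s in snp_ids]
    d = cohort.dosage[:, cols].astype(np.float64)
    d[d == MISSING] = np.nan
    minor_is_b = ma_table.table.loc[snp_ids, "minor_is_b"].to_numpy()
    d = np.where(minor_is_b[None, :], d, 2.0 - d)
    return d, list(snp_ids)


@dataclasses.dataclass
class MacResult:
    """Per-sample MAC scores (samples with zero usable SNPs are dropped)."""

    sample_ids: list[str]
    mac: np.ndarray
    n_snps_used: np.ndarray
    status: np.ndarray  # case/control of the retained samples

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "status": np.where(self.status == 1, "case", "control"),
                "mac": self.mac,
                "n_snps_used": self.n_snps_used,
            }
        )


@dataclasses.dataclass
class MacComparison:
    case_mean: float
    control_mean: float
    case_sd: float
    control_sd: float
    n_cases: int
    n_controls: int
    t: float
    p: float


def compute_mac(cohort: GenotypeCohort, ma_table: MinorAlleleTable) -> MacResult:
    """Per-sample MAC over the table's MAC-eligible SNPs.

    Missing genotypes are excluded from both numerator and denominator, so
    the score is the mean minor-allele dosage over the SNPs actually
    observed in that sample.  Samples with zero usable SNPs are dropped
    with a warning.
    """
    eligible = ma_table.table.index[ma_table.table["included_in_mac"]]
    present = set(cohort.snp_ids)
    snp_ids = [s for s in eligible if s in present]
    if not snp_ids:
        raise ValueError("no MAC-eligible SNP of the table is present in the cohort")
    d, _ = minor_allele_dosage(cohort, ma_table, snp_ids)
    used = (~np.isnan(d)).sum(axis=1)
    total = np.nansum(d, axis=1)
    ok = used > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} sample(s) with zero usable SNPs dropped from MAC",
            stacklevel=2,
        )
    mac = total[ok] / used[ok]
    return MacResult(
        sample_ids=[s for s, k in zip(cohort.samples, ok) if k],
        mac=mac,
        n_snps_used=used[ok],
        status=cohort.status[ok],
    )


def compare_mac(mac_result: MacResult, status: np.ndarray | None = None) -> MacComparison:
    """Welch two-sample t-test of mean MAC, cases vs controls (two-tailed)."""
    status = mac_result.status if status is None else np.asarray(status)
    case = mac_result.mac[status == 1]
    control = mac_result.mac[status == 0]
    if len(case) < 2 or len(control) < 2:
        raise ValueError("need at least two samples per group for the t-test")
    if np.allclose(case.var(), 0) and np.allclose(control.var(), 0) and np.isclose(
        case.mean(), control.mean()
    ):
        t, p = 0.0, 1.0  # identical degenerate groups: no evidence either way
    else:
        t, p = stats.ttest_ind(case, control, equal_var=False)
    return MacComparison(
        case_mean=float(case.mean()),
        control_mean=float(control.mean()),
        case_sd=float(case.std(ddof=1)),
        control_sd=float(control.std(ddof=1)),
        n_cases=len(case),
        n_controls=len(control),
        t=float(t),
        p=float(p),
    )


def mac_case_control(
    cohort: GenotypeCohort,
    reference_group: str = "controls",
    mac_maf_max: float = 0.4,
) -> tuple[MacResult, MacComparison]:
    """Convenience: define MAs, compute MAC, compare case/control means."""
    table = define_minor_alleles(cohort, reference_group, mac_maf_max)
    result = compute_mac(cohort, table)
    return result, compare_mac(result)
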