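"""Genotype cohort container and PLINK-text / VCF input.

The shared in-memory model for the whole pipeline is :class:`GenotypeCohort`:
a samples x SNPs dosage matrix counting copies of ``allele_b``, binary
case/control status, and optional per-sample numeric covariates.

The dosage coding is deliberately orientation-free: ``allele_b`` is just
"the second allele" of the stored :class:`SnpRecord`, with no minor/major
or risk/protective meaning.  Minor-allele orientation is resolved per
analysis by a :class:`~macrisk.mac.MinorAlleleTable`, because the minor
allele can legitimately be defined against different reference groups
(controls only for the burden statistic, the combined cohort for risk-score
weights) and the two definitions can disagree for near-0.5 frequencies.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "SnpRecord",
    "GenotypeCohort",
    "GenotypeFormatError",
    "read_ped_map",
    "write_ped_map",
    "read_vcf",
]

#: Sentinel for a missing genotype in the int8 dosage matrix.
MISSING: int = -1

_AUTOSOMES = {str(i) for i in range(1, 23)}

_CASE, _CONTROL = 1, 0


class GenotypeFormatError(ValueError):
    """Raised when an input genotype file violates its format contract."""


@dataclasses.dataclass(frozen=True)
class SnpRecord:
    """Metadata for one biallelic SNP.

    ``pos_bp`` is a 1-based physical position in base pairs (VCF / .map
    convention); all window arithmetic downstream is inclusive on base
    pairs.
    """

    snp_id: str
    chrom: str
    pos_bp: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"{self.snp_id}: pos_bp must be >= 1, got {self.pos_bp}")
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.snp_id}: allele_a == allele_b ({self.allele_a!r})")

    @property
    def is_autosomal(self) -> bool:
        """True for chromosomes 1-22 (with or without a ``chr`` prefix)."""
        return self.chrom.lower().removeprefix("chr") in _AUTOSOMES


@dataclasses.dataclass
class GenotypeCohort:
    """A case-control genotype cohort.

    Attributes
    ----------
    samples
        Sample identifiers, one per dosage row; unique.
    snps
        One :class:`SnpRecord` per dosage column; SNP ids unique.
    dosage
        int8 matrix of shape ``(len(samples), len(snps))`` with entries in
        ``{0, 1, 2, MISSING}`` counting copies of each SNP's ``allele_b``.
    status
        int8 vector, 1 = case, 0 = control.
    covariates
        Optional numeric per-sample columns (BMI, age, ...), indexed like
        ``samples``.
    """

    samples: list[str]
    snps: list[SnpRecord]
    dosage: np.ndarray
    status: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.status = np.asarray(self.status, dtype=np.int8)
        self.validate()

    # ------------------------------------------------------------------
    # invariants
    def validate(self) -> None:
        n, m = self.dosage.shape
        if n != len(self.samples):
            raise ValueError(f"dosage has {n} rows for {len(self.samples)} samples")
        if m != len(self.snps):
            raise ValueError(f"dosage has {m} columns for {len(self.snps)} SNPs")
        if self.status.shape != (n,):
            raise ValueError("status length does not match samples")
        if not np.isin(self.status, (_CASE, _CONTROL)).all():
            raise ValueError("status entries must be 0 (control) or 1 (case)")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage entries must be in {0, 1, 2, MISSING}")
        if len(set(self.samples)) != n:
            raise ValueError("duplicate sample ids")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != m:
            raise ValueError("duplicate SNP ids")
        if self.covariates is not None:
            if len(self.covariates) != n:
                raise ValueError("covariates length does not match samples")

    # ------------------------------------------------------------------
    # basic accessors
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos_bp for s in self.snps], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([s.chrom for s in self.snps], dtype=object)

    @property
    def is_case(self) -> np.ndarray:
        return self.status == _CASE

    @property
    def autosomal_mask(self) -> np.ndarray:
        return np.array([s.is_autosomal for s in self.snps], dtype=bool)

    def snp_index(self) -> dict[str, int]:
        return {s.snp_id: j for j, s in enumerate(self.snps)}

    def dosage_float(self) -> np.ndarray:
        """Dosage as float64 with ``NaN`` at missing genotypes."""
        d = self.dosage.astype(np.float64)
        d[self.dosage == MISSING] = np.nan
        return d

    def require_case_control(self) -> None:
        """Raise unless at least one case and one control are present."""
        if not (self.is_case.any() and (~self.is_case).any()):
            raise ValueError("cohort must contain at least one case and one control")

    # ------------------------------------------------------------------
    # subsetting
    def take_samples(self, indices: Sequence[int] | np.ndarray) -> "GenotypeCohort":
        indices = np.asarray(indices, dtype=np.intp)
        cov = None
        if self.covariates is not None:
            cov = self.covariates.iloc[indices].reset_index(drop=True)
        return GenotypeCohort(
            samples=[self.samples[i] for i in indices],
            snps=list(self.snps),
            dosage=self.dosage[indices, :],
            status=self.status[indices],
            covariates=cov,
        )

    def take_snps(self, indices: Sequence[int] | np.ndarray) -> "GenotypeCohort":
        indices = np.asarray(indices, dtype=np.intp)
        return GenotypeCohort(
            samples=list(self.samples),
            snps=[self.snps[j] for j in indices],
            dosage=self.dosage[:, indices],
            status=self.status.copy(),
            covariates=None if self.covariates is None else self.covariates.copy(),
        )

    def subset_snp_ids(self, snp_ids: Iterable[str]) -> "GenotypeCohort":
        idx = self.snp_index()
        return self.take_snps([idx[s] for s in snp_ids])


# ----------------------------------------------------------------------
# PLINK text format


def _parse_status(code: str, row: int) -> int:
    if code == "2":
        return _CASE
    if code == "1":
        return _CONTROL
    raise GenotypeFormatError(
        f".ped row {row}: phenotype must be 1 (control) or 2 (case), got {code!r}"
    )


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeCohort:
    """Read a PLINK text fileset (.ped / .map).

    ``allele_b`` for each SNP is the second distinct allele observed while
    scanning the .ped file top to bottom; dosage counts its copies.  The
    missing allele code is ``"0"``; a half-missing genotype (e.g. ``A 0``)
    is treated as fully missing.  Phenotype 2 maps to case, 1 to control.
    """
    map_rows: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise GenotypeFormatError(f".map line {ln}: expected 4 fields")
            chrom, snp_id, _cm, pos = parts
            map_rows.append((chrom, snp_id, int(pos)))
    m = len(map_rows)

    samples: list[str] = []
    status: list[int] = []
    geno_rows: list[list[tuple[str, str]]] = []
    with open(ped_path) as fh:
        for rn, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * m:
                raise GenotypeFormatError(
                    f".ped row {rn}: expected {6 + 2 * m} fields for {m} SNPs, "
                    f"got {len(parts)}"
                )
            samples.append(parts[1])
            status.append(_parse_status(parts[5], rn))
            alleles = parts[6:]
            geno_rows.append(
                [(alleles[2 * j], alleles[2 * j + 1]) for j in range(m)]
            )

    # first/second observed allele per SNP, scanning rows in file order
    observed: list[list[str]] = [[] for _ in range(m)]
    for row in geno_rows:
        for j, (a1, a2) in enumerate(row):
            for a in (a1, a2):
                if a != "0" and a not in observed[j]:
                    observed[j].append(a)
                    if len(observed[j]) > 2:
                        raise GenotypeFormatError(
                            f"SNP {map_rows[j][1]}: more than two alleles observed"
                        )

    snps = []
    for (chrom, snp_id, pos), obs in zip(map_rows, observed):
        a = obs[0] if len(obs) >= 1 else "N"
        b = obs[1] if len(obs) >= 2 else ("N" if a != "N" else "M")
        snps.append(SnpRecord(snp_id=snp_id, chrom=chrom, pos_bp=pos, allele_a=a, allele_b=b))

    dosage = np.full((len(samples), m), MISSING, dtype=np.int8)
    for i, row in enumerate(geno_rows):
        for j, (a1, a2) in enumerate(row):
            if a1 == "0" or a2 == "0":
                continue
            dosage[i, j] = (a1 == snps[j].allele_b) + (a2 == snps[j].allele_b)

    return GenotypeCohort(samples=samples, snps=snps, dosage=dosage, status=np.array(status))


def write_ped_map(cohort: GenotypeCohort, prefix: str | Path) -> tuple[Path, Path]:
    """Write a cohort as a PLINK text fileset ``<prefix>.ped`` / ``<prefix>.map``.

    Heterozygotes are written ``allele_a allele_b``; missing genotypes as
    ``0 0``.  Covariates are not representable in this format and are not
    written.
    """
    prefix = Path(prefix)
    ped_path = prefix.parent / (prefix.name + ".ped")
    map_path = prefix.parent / (prefix.name + ".map")
    with open(map_path, "w") as fh:
        for s in cohort.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos_bp}\n")
    geno_strings = {
        0: lambda s: f"{s.allele_a} {s.allele_a}",
        1: lambda s: f"{s.allele_a} {s.allele_b}",
        2: lambda s: f"{s.allele_b} {s.allele_b}",
        MISSING: lambda s: "0 0",
    }
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(cohort.samples):
            pheno = "2" if cohort.status[i] == _CASE else "1"
            fields = [sid, sid, "0", "0", "0", pheno]
            for j, snp in enumerate(cohort.snps):
                fields.append(geno_strings[int(cohort.dosage[i, j])](snp))
            fh.write(" ".join(fields) + "\n")
    return ped_path, map_path


# ----------------------------------------------------------------------
# VCF


def _normalize_status(value: object, sample: str) -> int:
    if value in ("case", 1, 2, _CASE, "2"):
        return _CASE
    if value in ("control", 0, _CONTROL, "1"):
        return _CONTROL
    raise GenotypeFormatError(f"sample {sample}: unrecognized status {value!r}")


def read_vcf(vcf_path: str | Path, status_map: Mapping[str, object]) -> GenotypeCohort:
    """Read a biallelic VCF (v4.2, GT field) into a cohort.

    ``allele_b`` is the ALT allele, so dosage is the ALT-allele count:
    ``0/0 -> 0``, ``0/1 -> 1``, ``1/1 -> 2``, ``./. -> MISSING``.
    ``status_map`` assigns every VCF sample a case/control label.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    missing_status = [s for s in samples if s not in status_map]
    if missing_status:
        raise GenotypeFormatError(
            "samples absent from status_map: " + ", ".join(missing_status)
        )
    status = np.array([_normalize_status(status_map[s], s) for s in samples])

    snps: list[SnpRecord] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise GenotypeFormatError(
                f"multiallelic record at {var.CHROM}:{var.POS}; biallelic VCF required"
            )
        # with gts012=True: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        columns.append(gt)
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        snps.append(
            SnpRecord(
                snp_id=snp_id,
                chrom=str(var.CHROM),
                pos_bp=int(var.POS),
                allele_a=var.REF,
                allele_b=var.ALT[0],
            )
        )
    dosage = (
        np.stack(columns, axis=1) if columns else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeCohort(samples=samples, snps=snps, dosage=dosage, status=status)
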