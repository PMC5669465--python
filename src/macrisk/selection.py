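"""Model selection over the P-threshold x LD-level grid.

For each LD level (five r^2 pruning thresholds plus "no pruning") and each
of 35 association P-value thresholds, a risk model is built on the
training cohort and evaluated two ways: externally, by scoring a disjoint
validation cohort, and internally, by stratified 5-fold cross-validation
inside the training cohort with everything — minor-allele tables,
association betas, pruning, SNP selection — refit per fold so no held-out
information leaks into the model.  The best cell is the one with the
smallest sum of its external-AUC rank and internal-mean-AUC rank; ties go
to fewer SNPs, then to the larger threshold.  The selected model is
rebuilt with flip SNPs dropped.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .assoc import AssocResult, per_snp_assoc
from .cohort import GenotypeCohort
from .ld import prune
from .mac import MinorAlleleTable, define_minor_alleles
from .risk import RiskModel, build_model, score
from .evaluate import auc as auc_ci, evaluate_scores, tpr_full_specificity

__all__ = [
    "DEFAULT_P_THRESHOLDS",
    "DEFAULT_LD_LEVELS",
    "GridSpec",
    "GridResult",
    "external_validation",
    "internal_cv",
    "run_grid",
    "rank_cells",
    "select_best",
]

#: The 35 association P-value cutoffs of the default model grid.
DEFAULT_P_THRESHOLDS: tuple[float, ...] = (
    1e-33, 1e-29, 1e-27, 1e-25, 1e-24, 1e-22, 1e-21, 1e-20, 1e-19, 1e-18,
    1e-17, 1e-16, 1e-15, 1e-14, 1e-13, 1e-12, 1e-11, 1e-10, 1e-9, 1e-8,
    1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 0.01, 0.03, 0.05, 0.07, 0.09,
    0.1, 0.3, 0.5, 0.7, 1.0,
)

#: Five pruning thresholds plus no pruning: 6 LD levels, 210 grid cells.
DEFAULT_LD_LEVELS: tuple[float | None, ...] = (0.05, 0.2, 0.4, 0.6, 0.8, None)


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """The model grid: P thresholds x LD levels (None = no pruning)."""

    p_thresholds: tuple[float, ...] = DEFAULT_P_THRESHOLDS
    ld_levels: tuple[float | None, ...] = DEFAULT_LD_LEVELS
    seed: int = 0
    drop_flips: bool = True
    window_bp: int = 200_000

    def __post_init__(self) -> None:
        if not self.p_thresholds:
            raise ValueError("p_thresholds must be non-empty")
        if not self.ld_levels:
            raise ValueError("ld_levels must be non-empty")

    @property
    def n_cells(self) -> int:
        return len(self.p_thresholds) * len(self.ld_levels)


@dataclasses.dataclass
class GridResult:
    """Grid-cell metrics plus the training-side context needed to rebuild models."""

    spec: GridSpec
    cells: pd.DataFrame
    assoc: AssocResult | None = None
    ma_control: MinorAlleleTable | None = None
    ma_combined: MinorAlleleTable | None = None
    prunes: dict = dataclasses.field(default_factory=dict)
    selection: dict | None = None
    best_model: RiskModel | None = None

    def cell(self, p_threshold: float, ld_level: float | None) -> pd.Series:
        key = _ld_key(ld_level)
        m = (self.cells["p_threshold"] == p_threshold) & (self.cells["ld_level"] == key)
        return self.cells[m].iloc[0]


def _ld_key(ld_level: float | None) -> str:
    return "none" if ld_level is None else f"{ld_level:g}"


def _ld_seed(spec: GridSpec, ld_level: float | None, salt: int = 0) -> int:
    # fixed per-level offsets keep prune RNG streams independent yet reproducible
    base = (spec.seed * 1000 + salt * 100) % (2**31)
    return base + (0 if ld_level is None else int(round(ld_level * 100)))


def _training_context(
    training: GenotypeCohort, spec: GridSpec, salt: int = 0
) -> tuple[AssocResult, MinorAlleleTable, MinorAlleleTable, dict]:
    """MA tables, association scan, and per-level pruning for one training set."""
    ma_control = define_minor_alleles(training, "controls")
    ma_combined = define_minor_alleles(training, "combined")
    assoc = per_snp_assoc(training, ma_combined)
    prunes: dict = {}
    for ld in spec.ld_levels:
        if ld is None:
            prunes[_ld_key(ld)] = None
        else:
            prunes[_ld_key(ld)] = prune(
                training, ld, window_bp=spec.window_bp, seed=_ld_seed(spec, ld, salt)
            )
    return assoc, ma_control, ma_combined, prunes


def external_validation(
    training: GenotypeCohort, validation: GenotypeCohort, spec: GridSpec
) -> GridResult:
    """Build every grid model on the training cohort; evaluate on validation.

    The two cohorts must be sample-disjoint.  Minor-allele tables, the
    association scan, and pruning are computed once per training cohort
    and reused across cells; the validation cohort is only ever scored.
    Cells whose model is empty are marked failed and the grid continues.
    """
    overlap = set(training.samples) & set(validation.samples)
    if overlap:
        raise ValueError(f"training/validation share {len(overlap)} sample(s)")
    assoc, ma_control, ma_combined, prunes = _training_context(training, spec)

    rows = []
    for ld in spec.ld_levels:
        kept = prunes[_ld_key(ld)]
        for p_thr in spec.p_thresholds:
            row = {
                "p_threshold": p_thr,
                "ld_level": _ld_key(ld),
                "n_snps": 0,
                "failed": False,
                "reason": "",
            }
            try:
                model = build_model(
                    assoc, p_thr, kept, ma_control, ma_combined,
                    drop_flips=False, ld_r2=ld,
                )
                scored = score(validation, model)
                ev = evaluate_scores(scored.grs, validation.status)
            except ValueError as exc:
                row["failed"] = True
                row["reason"] = str(exc)
                rows.append(row)
                continue
            row.update(
                n_snps=model.n_snps,
                n_flips=len(model.flip_snp_ids),
                ext_auc=ev.auc,
                ext_auc_lo=ev.auc_ci[0],
                ext_auc_hi=ev.auc_ci[1],
                ext_tpr=ev.tpr_full_spec,
                ext_tpr_lo=ev.tpr_ci[0],
                ext_tpr_hi=ev.tpr_ci[1],
                ext_r2=ev.nagelkerke_r2,
            )
            rows.append(row)
    cells = pd.DataFrame(rows)
    return GridResult(
        spec=spec,
        cells=cells,
        assoc=assoc,
        ma_control=ma_control,
        ma_combined=ma_combined,
        prunes=prunes,
    )


def _stratified_folds(
    status: np.ndarray, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold partition; re-seeds if a fold is single-class."""
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=(seed + attempt) % 2**31)
        folds = list(skf.split(np.zeros(len(status)), status))
        if all(len(np.unique(status[te])) == 2 for _tr, te in folds):
            return folds
    raise ValueError("could not build stratified folds with both classes present")


def internal_cv(training: GenotypeCohort, spec: GridSpec, k: int = 5) -> GridResult:
    """Stratified k-fold cross-validation inside the training cohort.

    Each fold refits minor-allele tables, betas, and pruning on its 4/5
    held-in samples, then scores and evaluates the held-out 1/5; per-cell
    internal metrics are fold means.  This is the leak-free reading of
    internal CV: no held-out sample influences SNP selection or weights.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    training.require_case_control()
    folds = _stratified_folds(training.status, k, spec.seed)

    sums: dict[tuple[float, str], list] = {
        (p, _ld_key(ld)): [] for ld in spec.ld_levels for p in spec.p_thresholds
    }
    for fold_i, (held_in_idx, held_out_idx) in enumerate(folds):
        held_in = training.take_samples(held_in_idx)
        held_out = training.take_samples(held_out_idx)
        assoc, ma_control, ma_combined, prunes = _training_context(
            held_in, spec, salt=fold_i + 1
        )
        for ld in spec.ld_levels:
            kept = prunes[_ld_key(ld)]
            for p_thr in spec.p_thresholds:
                try:
                    model = build_model(
                        assoc, p_thr, kept, ma_control, ma_combined,
                        drop_flips=False, ld_r2=ld,
                    )
                    scored = score(held_out, model)
                    a, _ = auc_ci(scored.grs, held_out.status)
                    t, _ = tpr_full_specificity(scored.grs, held_out.status)
                except ValueError:
                    continue
                sums[(p_thr, _ld_key(ld))].append((a, t))

    rows = []
    for ld in spec.ld_levels:
        for p_thr in spec.p_thresholds:
            vals = sums[(p_thr, _ld_key(ld))]
            rows.append(
                {
                    "p_threshold": p_thr,
                    "ld_level": _ld_key(ld),
                    "int_auc": float(np.mean([v[0] for v in vals])) if vals else np.nan,
                    "int_tpr": float(np.mean([v[1] for v in vals])) if vals else np.nan,
                    "int_n_folds": len(vals),
                }
            )
    return GridResult(spec=spec, cells=pd.DataFrame(rows))


def run_grid(
    training: GenotypeCohort,
    validation: GenotypeCohort,
    spec: GridSpec,
    k: int = 5,
) -> GridResult:
    """External validation plus internal k-fold CV, merged into one grid."""
    ext = external_validation(training, validation, spec)
    internal = internal_cv(training, spec, k=k)
    ext.cells = ext.cells.merge(internal.cells, on=["p_threshold", "ld_level"], how="left")
    return ext


def rank_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """Order non-failed grid cells by external+internal AUC rank sum.

    Rank 1 is the best AUC in each column; ties on the rank sum are broken
    toward fewer SNPs, then toward the larger P threshold.
    """
    ok = (~cells["failed"]) & cells["ext_auc"].notna() & cells["int_auc"].notna()
    if not ok.any():
        raise ValueError("every grid cell failed; nothing to select")
    sub = cells[ok].copy()
    sub["rank_ext"] = rankdata(-sub["ext_auc"].to_numpy(), method="min")
    sub["rank_int"] = rankdata(-sub["int_auc"].to_numpy(), method="min")
    sub["rank_sum"] = sub["rank_ext"] + sub["rank_int"]
    return sub.sort_values(
        ["rank_sum", "n_snps", "p_threshold"], ascending=[True, True, False]
    )


def select_best(grid: GridResult) -> RiskModel:
    """Pick the grid cell best in both external and internal validation.

    Cells are ranked by external AUC and by internal mean AUC (rank 1 =
    best); the winner minimizes the rank sum, with ties broken toward
    fewer SNPs and then toward the larger P threshold.  The winning cell's
    model is rebuilt on the training context with flip SNPs dropped (per
    the grid spec) and returned; the selection record lands on
    ``grid.selection`` and ``grid.best_model``.
    """
    if grid.assoc is None:
        raise ValueError("grid carries no training context; run external_validation first")
    cells = grid.cells
    if "int_auc" not in cells.columns:
        raise ValueError("grid has no internal-CV columns; run run_grid or internal_cv")
    best = rank_cells(cells).iloc[0]

    ld_key = best["ld_level"]
    ld = None if ld_key == "none" else float(ld_key)
    model = build_model(
        grid.assoc,
        float(best["p_threshold"]),
        grid.prunes.get(ld_key),
        grid.ma_control,
        grid.ma_combined,
        drop_flips=grid.spec.drop_flips,
        ld_r2=ld,
    )
    model.provenance.update(
        seed=grid.spec.seed,
        rank_ext=int(best["rank_ext"]),
        rank_int=int(best["rank_int"]),
        ext_auc=float(best["ext_auc"]),
        int_auc=float(best["int_auc"]),
    )
    grid.selection = {
        "p_threshold": float(best["p_threshold"]),
        "ld_level": ld,
        "rank_sum": int(best["rank_sum"]),
        "n_snps_pre_flip_drop": int(best["n_snps"]),
        "n_flips_dropped": len(model.flip_snp_ids) if grid.spec.drop_flips else 0,
    }
    grid.best_model = model
    return model
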