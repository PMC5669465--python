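"""End-to-end pipeline: simulate/load -> QC -> split -> MAC comparison ->
model grid -> best-model selection -> final evaluation.

Every stage writes its tables into the run directory, together with the
fully serialized run configuration and a structured log, so any run can be
re-created from its own artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import GenotypeCohort, read_ped_map
from .simulate import SimConfig, SimTruth, simulate_cohort, split_cohort
from .qc import apply_qc
from .mac import compare_mac, compute_mac, define_minor_alleles
from .ld import prune
from .risk import score
from .evaluate import evaluate_scores, roc_points
from .selection import GridSpec, GridResult, run_grid, select_best

__all__ = ["RunConfig", "RunResult", "run_all", "demo_config"]


def demo_config(seed: int = 1) -> SimConfig:
    """The packaged planted-signal demonstration cohort.

    4,000 cases / 4,000 controls over 5,000 common SNPs (MAF 0.05-0.5) in
    20-SNP blocks of mild LD; 300 causal SNPs whose log-odds effects follow
    a point-normal mixture — a polygenic background (sd 0.05) plus ~12%
    strong loci (sd 1.0) — with the risk allele on the minor allele 80% of
    the time, 2% missing genotypes, and ~10% baseline prevalence.  These
    are the conditions under which the pipeline's risk model is expected
    to approach the true-beta oracle.
    """
    return SimConfig(
        n_cases=4000,
        n_controls=4000,
        n_snps=5000,
        n_causal=300,
        maf_law=("uniform", 0.05, 0.5),
        ld_block_size=20,
        ld_rho=0.3,
        causal_beta_law=("mixnormal", 0.12, 0.05, 1.0),
        p_minor_risk=0.8,
        intercept=-2.2,
        missing_rate=0.02,
        seed=seed,
    )


@dataclasses.dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    sim: SimConfig | None = None  # either simulate ...
    ped_prefix: str | None = None  # ... or load a PLINK text fileset
    hwe_p_max: float = 1e-4
    snp_missing_max: float = 0.05
    maf_min: float = 0.01
    sample_missing_max: float = 0.10
    pc_bounds: dict | None = None
    mac_maf_max: float = 0.4
    mac_ld_levels: tuple[float | None, ...] = (None, 0.05, 0.2, 0.4, 0.6, 0.8)
    grid: GridSpec = dataclasses.field(default_factory=GridSpec)
    kfold: int = 5
    train_fraction: float = 0.5
    seed: int = 0
    transfer_sim: SimConfig | None = None  # optional second cohort (transfer test)

    def validate(self) -> None:
        if (self.sim is None) == (self.ped_prefix is None):
            raise ValueError("exactly one of sim / ped_prefix must be given")
        if not self.grid.p_thresholds:
            raise ValueError("empty P-threshold list")

    def to_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return str(o)

        return json.dumps(dataclasses.asdict(self), indent=2, default=default)


@dataclasses.dataclass
class RunResult:
    outdir: Path
    cohort: GenotypeCohort
    truth: SimTruth | None
    train: GenotypeCohort
    valid: GenotypeCohort
    mac_comparison: pd.DataFrame
    grid: GridResult
    final_eval: pd.DataFrame
    transfer_eval: pd.DataFrame | None = None


def _log(fh, msg: str) -> None:
    fh.write(f"[{time.strftime('%H:%M:%S')}] {msg}\n")
    fh.flush()


def run_all(config: RunConfig, outdir: str | Path) -> RunResult:
    """Run the full analysis and persist every stage's artifacts.

    Stage order: load/simulate, QC, train/validation split, MAC
    case-control comparison at every configured LD level (including no
    pruning), the P-threshold x LD grid with external and internal CV,
    best-model selection with flip-SNP removal, final external evaluation,
    and an optional transfer evaluation on a second, independently
    simulated cohort (reporting the SNP overlap).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "run_config.json").write_text(config.to_json())

    with open(outdir / "log.txt", "w") as log:
        _log(log, f"macrisk {__version__}")

        # --- input
        truth = None
        if config.sim is not None:
            cohort, truth = simulate_cohort(config.sim)
            truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
            _log(log, f"simulated cohort: {cohort.n_samples} samples x {cohort.n_snps} SNPs")
        else:
            cohort = read_ped_map(config.ped_prefix + ".ped", config.ped_prefix + ".map")
            _log(log, f"loaded cohort: {cohort.n_samples} samples x {cohort.n_snps} SNPs")

        # --- QC
        cohort, qc_report = apply_qc(
            cohort,
            hwe_p_max=config.hwe_p_max,
            snp_missing_max=config.snp_missing_max,
            maf_min=config.maf_min,
            sample_missing_max=config.sample_missing_max,
            pc_bounds=config.pc_bounds,
        )
        qc_report.to_frame().to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        _log(
            log,
            f"QC: {qc_report.n_snps_out}/{qc_report.n_snps_in} SNPs, "
            f"{qc_report.n_samples_out}/{qc_report.n_samples_in} samples kept",
        )

        # --- split
        train, valid = split_cohort(cohort, config.train_fraction, seed=config.seed)
        _log(
            log,
            f"split: train {int(train.is_case.sum())}/{int((~train.is_case).sum())} "
            f"case/control, valid {int(valid.is_case.sum())}/{int((~valid.is_case).sum())}",
        )

        # --- MAC comparison on the full QC'd cohort, at each LD level
        mac_rows = []
        for ld in config.mac_ld_levels:
            if ld is None:
                sub = cohort
            else:
                kept = prune(cohort, ld, seed=config.seed)
                sub = cohort.subset_snp_ids(kept.kept_snp_ids)
            table = define_minor_alleles(sub, "controls", config.mac_maf_max)
            result = compute_mac(sub, table)
            comp = compare_mac(result)
            mac_rows.append(
                {
                    "ld_level": "none" if ld is None else f"{ld:g}",
                    "n_snps": sub.n_snps,
                    "n_snps_mac": int(table.table["included_in_mac"].sum()),
                    "case_mean": comp.case_mean,
                    "control_mean": comp.control_mean,
                    "case_sd": comp.case_sd,
                    "control_sd": comp.control_sd,
                    "t": comp.t,
                    "p": comp.p,
                }
            )
            if ld is None:
                result.to_frame().to_csv(outdir / "mac_per_sample.tsv", sep="\t", index=False)
        mac_comparison = pd.DataFrame(mac_rows)
        mac_comparison.to_csv(outdir / "mac_comparison.tsv", sep="\t", index=False)
        _log(log, "MAC comparison done: " + ", ".join(
            f"{r['ld_level']}: p={r['p']:.3g}" for r in mac_rows
        ))

        # --- model grid + selection
        grid = run_grid(train, valid, config.grid, k=config.kfold)
        grid.cells.to_csv(outdir / "grid.tsv", sep="\t", index=False)
        best = select_best(grid)
        best.to_tsv(outdir / "best_model.tsv")
        (outdir / "best_model_meta.json").write_text(
            json.dumps(
                {
                    "p_threshold": best.p_threshold,
                    "ld_r2": best.ld_r2,
                    "n_snps": best.n_snps,
                    "flip_snp_ids": best.flip_snp_ids,
                    "provenance": best.provenance,
                },
                indent=2,
            )
        )
        _log(
            log,
            f"best model: p<{best.p_threshold:g}, r2="
            f"{'none' if best.ld_r2 is None else best.ld_r2}, {best.n_snps} SNPs "
            f"({len(best.flip_snp_ids)} flip SNPs detected)",
        )

        # --- final external evaluation of the flip-dropped model
        scored = score(valid, best)
        scored.to_frame().to_csv(outdir / "valid_scores.tsv", sep="\t", index=False)
        ev = evaluate_scores(scored.grs, valid.status)
        final_eval = ev.to_frame()
        final_eval.to_csv(outdir / "final_eval.tsv", sep="\t", index=False)
        roc_points(scored.grs, valid.status).to_csv(
            outdir / "final_roc.tsv", sep="\t", index=False
        )
        _log(
            log,
            f"final external eval: AUC={ev.auc:.4f} "
            f"({ev.auc_ci[0]:.4f}-{ev.auc_ci[1]:.4f}), "
            f"TPR@100%spec={ev.tpr_full_spec:.4f}, NagelkerkeR2={ev.nagelkerke_r2:.4f}",
        )

        # --- optional transfer cohort
        transfer_eval = None
        if config.transfer_sim is not None:
            tcohort, _ = simulate_cohort(config.transfer_sim)
            tscored = score(tcohort, best)
            tev = evaluate_scores(tscored.grs, tcohort.status)
            transfer_eval = tev.to_frame()
            transfer_eval["snp_overlap"] = tscored.n_overlap
            transfer_eval.to_csv(outdir / "transfer_eval.tsv", sep="\t", index=False)
            _log(
                log,
                f"transfer eval: AUC={tev.auc:.4f}, overlap "
                f"{tscored.n_overlap}/{best.n_snps} SNPs",
            )

    return RunResult(
        outdir=outdir,
        cohort=cohort,
        truth=truth,
        train=train,
        valid=valid,
        mac_comparison=mac_comparison,
        grid=grid,
        final_eval=final_eval,
        transfer_eval=transfer_eval,
    )
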