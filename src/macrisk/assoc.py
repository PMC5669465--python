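"""Logistic-regression association: shared IRLS core, per-SNP scan,
and the multivariate covariate model.

The per-SNP model is the additive one used throughout case-control GWAS:
status ~ intercept + minor-allele dosage, with minor alleles taken from
the combined-cohort table so that each reported beta is the log-odds per
copy of the coded (minor) allele.  P-values are asymptotic Wald tests.
Quasi-separated fits (|coefficient| > 15) are flagged rather than
penalized and are excluded from risk models downstream.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .cohort import GenotypeCohort
from .mac import MacResult, MinorAlleleTable, minor_allele_dosage

__all__ = [
    "FitResult",
    "AssocResult",
    "CovariateModel",
    "irls_logistic",
    "per_snp_assoc",
    "multivariate_fit",
]

_SEPARATION_BOUND = 15.0


@dataclasses.dataclass
class FitResult:
    """One maximum-likelihood logistic fit."""

    params: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    cov: np.ndarray
    n_obs: int
    loglik_path: list[float]

    @property
    def zvalues(self) -> np.ndarray:
        return self.params / self.se

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.zvalues))


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # sum(y*eta - log(1+exp(eta))), stable for large |eta|
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def irls_logistic(
    design: np.ndarray,
    outcome: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 25,
) -> FitResult:
    """Newton-Raphson / IRLS maximum-likelihood logistic regression.

    The design must be full rank after dropping constant columns (a
    rank-deficient design raises, naming the dependent columns).  Step
    halving guarantees a non-decreasing log-likelihood across iterations.
    Hitting ``max_iter`` or the separation bound (|coefficient| > 15)
    returns the best iterate with ``converged=False``.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("outcome length does not match design rows")

    _q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    scale = max(diag.max(), 1.0)
    dependent = np.flatnonzero(diag < 1e-10 * scale)
    if len(dependent):
        raise ValueError(
            f"rank-deficient design: column(s) {dependent.tolist()} are "
            "linearly dependent on earlier columns"
        )

    beta = np.zeros(p)
    eta = X @ beta
    ll = _loglik(eta, y)
    path = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        xtwx = X.T @ (X * w[:, None])
        grad = X.T @ (y - mu)
        step = np.linalg.solve(xtwx, grad)
        # step-halve until the log-likelihood does not decrease
        alpha = 1.0
        for _ in range(30):
            cand = beta + alpha * step
            cand_ll = _loglik(X @ cand, y)
            if cand_ll >= ll - 1e-12:
                break
            alpha *= 0.5
        beta = beta + alpha * step
        eta = X @ beta
        new_ll = _loglik(eta, y)
        path.append(new_ll)
        delta = np.max(np.abs(alpha * step))
        ll = new_ll
        if delta < tol:
            converged = True
            break

    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = np.sqrt(np.diag(cov))
    if np.max(np.abs(beta)) > _SEPARATION_BOUND:
        converged = False
    return FitResult(
        params=beta,
        se=se,
        loglik=ll,
        converged=converged,
        n_iter=it,
        cov=cov,
        n_obs=n,
        loglik_path=path,
    )


# ----------------------------------------------------------------------
# vectorized per-SNP scan


def _logistic_scan(
    G: np.ndarray,
    y: np.ndarray,
    max_iter: int = 25,
    tol: float = 1e-8,
    chunk: int = 1024,
) -> tuple[np.ndarray, ...]:
    """Fit status ~ intercept + dosage for every column of G at once.

    G is float with NaN at missing; each SNP's fit drops only that SNP's
    missing samples.  Returns (beta, se, converged, n_used) arrays.  The
    per-SNP 2x2 Newton systems are solved in closed form, chunked over
    SNPs to bound memory.
    """
    n, m = G.shape
    beta_out = np.full(m, np.nan)
    se_out = np.full(m, np.nan)
    conv_out = np.zeros(m, dtype=bool)
    n_out = np.zeros(m, dtype=int)

    for start in range(0, m, chunk):
        cols = slice(start, min(start + chunk, m))
        X = G[:, cols]
        Mk = ~np.isnan(X)
        Xf = np.where(Mk, X, 0.0)
        Mk = Mk.astype(float)
        nn = Mk.sum(axis=0)
        n_out[cols] = nn.astype(int)

        with np.errstate(invalid="ignore", divide="ignore"):
            xbar = (Xf * Mk).sum(axis=0) / nn
            xvar = ((Xf - xbar) ** 2 * Mk).sum(axis=0) / nn
            ybar = (y[:, None] * Mk).sum(axis=0) / nn
        usable = (nn >= 2) & (xvar > 1e-12) & (ybar > 0) & (ybar < 1)

        b0 = np.where(usable, np.log(np.clip(ybar, 1e-12, 1 - 1e-12) / np.clip(1 - ybar, 1e-12, 1)), 0.0)
        b1 = np.zeros_like(b0)
        active = usable.copy()
        det = np.ones_like(b0)
        s00 = np.ones_like(b0)
        for _ in range(max_iter):
            if not active.any():
                break
            eta = b0[None, :] + b1[None, :] * Xf
            mu = expit(eta)
            w = mu * (1.0 - mu) * Mk
            resid = (y[:, None] - mu) * Mk
            g0 = resid.sum(axis=0)
            g1 = (Xf * resid).sum(axis=0)
            s00 = w.sum(axis=0)
            s01 = (w * Xf).sum(axis=0)
            s11 = (w * Xf * Xf).sum(axis=0)
            det = s00 * s11 - s01 * s01
            bad = det <= 1e-12
            safe_det = np.where(bad, 1.0, det)
            d0 = np.where(active & ~bad, (s11 * g0 - s01 * g1) / safe_det, 0.0)
            d1 = np.where(active & ~bad, (-s01 * g0 + s00 * g1) / safe_det, 0.0)
            b0 += d0
            b1 += d1
            active &= np.maximum(np.abs(d0), np.abs(d1)) >= tol
            active &= ~bad
            # runaway fits: stop updating, will be flagged unconverged
            active &= np.abs(b1) <= 2 * _SEPARATION_BOUND

        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(np.where(det > 1e-12, s00 / det, np.nan))
        conv = (
            usable
            & ~active
            & (np.abs(b1) <= _SEPARATION_BOUND)
            & (np.abs(b0) <= _SEPARATION_BOUND)
            & np.isfinite(se)
        )
        beta_out[cols] = np.where(usable, b1, np.nan)
        se_out[cols] = se
        conv_out[cols] = conv
    return beta_out, se_out, conv_out, n_out


@dataclasses.dataclass
class AssocResult:
    """Per-SNP additive association results, oriented to the coded allele."""

    table: pd.DataFrame  # index snp_id: coded_allele, beta, se, z, p, converged, n
    reference_group: str

    def converged_ids(self) -> list[str]:
        return list(self.table.index[self.table["converged"]])


def per_snp_assoc(cohort: GenotypeCohort, ma_table: MinorAlleleTable) -> AssocResult:
    """Additive logistic association for every SNP in the table.

    The coded allele is the combined-cohort minor allele, matching how
    risk-score weights are defined; samples missing a SNP's genotype are
    dropped for that SNP only.  Monomorphic or separated SNPs are reported
    with ``converged=False`` and are skipped by model building.
    """
    if ma_table.reference_group != "combined":
        raise ValueError("per-SNP association requires a combined-cohort minor-allele table")
    cohort.require_case_control()
    G, snp_ids = minor_allele_dosage(cohort, ma_table)
    y = cohort.is_case.astype(float)
    beta, se, conv, n_used = _logistic_scan(G, y)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    p = 2.0 * norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "coded_allele": ma_table.table.loc[snp_ids, "minor_allele"].to_numpy(),
            "beta": beta,
            "se": se,
            "z": z,
            "p": p,
            "converged": conv,
            "n": n_used,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return AssocResult(table=table, reference_group=ma_table.reference_group)


# ----------------------------------------------------------------------


@dataclasses.dataclass
class CovariateModel:
    """Joint logistic fit of status on MAC plus covariates."""

    table: pd.DataFrame  # index predictor: estimate, se, z, p
    n_used: int
    n_dropped: int
    converged: bool
    loglik: float


def multivariate_fit(
    cohort: GenotypeCohort,
    mac_result: MacResult,
    covariate_names: list[str] | None = None,
) -> CovariateModel:
    """One joint IRLS fit: status ~ intercept + MAC + covariates.

    Covariates come from the cohort's covariate frame; rows with any
    missing covariate (or without a MAC score) are removed listwise and
    counted.  Binary covariates are expected coded 0/1.
    """
    if covariate_names is None:
        covariate_names = (
            list(cohort.covariates.columns) if cohort.covariates is not None else []
        )
    if covariate_names and cohort.covariates is None:
        raise ValueError("cohort has no covariates")
    names = list(dict.fromkeys(covariate_names))
    if len(names) != len(covariate_names):
        raise ValueError("duplicate covariate names")

    mac_by_sample = dict(zip(mac_result.sample_ids, mac_result.mac))
    rows, y_rows = [], []
    n_dropped = 0
    for i, sid in enumerate(cohort.samples):
        if sid not in mac_by_sample:
            n_dropped += 1
            continue
        cov_vals = (
            [float(cohort.covariates.iloc[i][c]) for c in names] if names else []
        )
        if any(np.isnan(v) for v in cov_vals):
            n_dropped += 1
            continue
        rows.append([1.0, mac_by_sample[sid]] + cov_vals)
        y_rows.append(float(cohort.status[i]))

    X = np.asarray(rows)
    y = np.asarray(y_rows)
    fit = irls_logistic(X, y)
    predictors = ["intercept", "MAC"] + names
    table = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.se,
            "z": fit.zvalues,
            "p": fit.pvalues,
        },
        index=pd.Index(predictors, name="predictor"),
    )
    return CovariateModel(
        table=table,
        n_used=fit.n_obs,
        n_dropped=n_dropped,
        converged=fit.converged,
        loglik=fit.loglik,
    )
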