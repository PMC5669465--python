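"""Performance measures for a scored case-control cohort.

Three measures: ROC AUC with a DeLong 95% CI, the true-positive rate at
100% specificity (fraction of cases scoring strictly above every control,
Wilson 95% CI), and Nagelkerke's pseudo-R^2 from a logistic fit of status
on the score.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.proportion import proportion_confint

from .assoc import irls_logistic

__all__ = [
    "EvalResult",
    "auc",
    "tpr_full_specificity",
    "nagelkerke_r2",
    "evaluate_scores",
    "roc_points",
]


@dataclasses.dataclass
class EvalResult:
    auc: float
    auc_ci: tuple[float, float]
    tpr_full_spec: float
    tpr_ci: tuple[float, float]
    nagelkerke_r2: float
    n_cases: int
    n_controls: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "auc": self.auc,
                    "auc_ci_low": self.auc_ci[0],
                    "auc_ci_high": self.auc_ci[1],
                    "tpr_full_spec": self.tpr_full_spec,
                    "tpr_ci_low": self.tpr_ci[0],
                    "tpr_ci_high": self.tpr_ci[1],
                    "nagelkerke_r2": self.nagelkerke_r2,
                    "n_cases": self.n_cases,
                    "n_controls": self.n_controls,
                }
            ]
        )


def _check_classes(status: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    status = np.asarray(status)
    case = status == 1
    if not case.any() or case.all():
        raise ValueError("both cases and controls are required")
    return case, ~case


def auc(scores: np.ndarray, status: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Mann-Whitney AUC with a DeLong 95% confidence interval.

    AUC = P(case score > control score) + 0.5 P(tie) over all
    case-control pairs; the CI uses the DeLong structural-component
    variance estimator and is clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    case, control = _check_classes(status)
    x, y = scores[case], scores[control]
    m, n = len(x), len(y)

    all_ranks = rankdata(np.concatenate([x, y]))
    rx, ry = all_ranks[:m], all_ranks[m:]
    auc_hat = (rx.sum() - m * (m + 1) / 2) / (m * n)

    # DeLong structural components via midranks
    v10 = (rx - rankdata(x)) / n  # per-case placement values
    v01 = 1.0 - (ry - rankdata(y)) / m  # per-control placement values
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    half = norm.ppf(0.975) * math.sqrt(max(var, 0.0))
    lo, hi = max(0.0, auc_hat - half), min(1.0, auc_hat + half)
    return float(auc_hat), (float(lo), float(hi))


def tpr_full_specificity(
    scores: np.ndarray, status: np.ndarray
) -> tuple[float, tuple[float, float]]:
    """Fraction of cases scoring strictly above the highest control.

    Strict inequality: a case tied with the maximum control is not
    counted.  The 95% CI is the Wilson interval for the binomial
    proportion.
    """
    scores = np.asarray(scores, dtype=float)
    case, control = _check_classes(status)
    top_control = scores[control].max()
    k = int((scores[case] > top_control).sum())
    n_cases = int(case.sum())
    lo, hi = proportion_confint(k, n_cases, alpha=0.05, method="wilson")
    return k / n_cases, (float(lo), float(hi))


def nagelkerke_r2(scores: np.ndarray, status: np.ndarray) -> tuple[float, bool]:
    """Nagelkerke pseudo-R^2 of a logistic fit of status on the score.

    With L0 the intercept-only likelihood and L1 the fitted likelihood over
    n samples: R^2 = [1 - (L0/L1)^(2/n)] / [1 - L0^(2/n)].  Returns the
    value plus a convergence flag (separation caps the fitted likelihood).
    """
    scores = np.asarray(scores, dtype=float)
    case, _ = _check_classes(status)
    y = case.astype(float)
    n = len(y)
    p1 = y.mean()
    ll0 = n * (p1 * math.log(p1) + (1 - p1) * math.log(1 - p1))
    if np.ptp(scores) == 0:
        return 0.0, True  # constant score: L1 == L0
    fit = irls_logistic(np.column_stack([np.ones(n), scores]), y)
    ll1 = fit.loglik
    r2_cs = 1.0 - math.exp(2.0 * (ll0 - ll1) / n)
    denom = 1.0 - math.exp(2.0 * ll0 / n)
    return r2_cs / denom, fit.converged


def evaluate_scores(scores: np.ndarray, status: np.ndarray) -> EvalResult:
    """All three measures for one scored cohort."""
    a, a_ci = auc(scores, status)
    t, t_ci = tpr_full_specificity(scores, status)
    r2, _ = nagelkerke_r2(scores, status)
    status = np.asarray(status)
    return EvalResult(
        auc=a,
        auc_ci=a_ci,
        tpr_full_spec=t,
        tpr_ci=t_ci,
        nagelkerke_r2=r2,
        n_cases=int((status == 1).sum()),
        n_controls=int((status == 0).sum()),
    )


def roc_points(scores: np.ndarray, status: np.ndarray) -> pd.DataFrame:
    """Full-threshold-sweep ROC curve points (for external plotting)."""
    scores = np.asarray(scores, dtype=float)
    case, control = _check_classes(status)
    thresholds = np.unique(scores)[::-1]
    rows = [(0.0, 0.0)]
    for t in thresholds:
        tpr = (scores[case] >= t).mean()
        fpr = (scores[control] >= t).mean()
        rows.append((float(fpr), float(tpr)))
    rows.append((1.0, 1.0))
    return pd.DataFrame(rows, columns=["fpr", "tpr"]).drop_duplicates()
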