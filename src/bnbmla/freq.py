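"""Frequentist comparison track: contingency ORs, adjusted logistic
regression, Benjamini-Hochberg FDR, Kaplan-Meier and log-rank.

These are the standard single-SNP analyses run alongside the Bayesian
network track, and double as internal oracles for the recovery tests.
Kaplan-Meier and the log-rank statistic go through lifelines; the logistic
IRLS and the BH step-up procedure are implemented here so their stopping
rules and reported thresholds are exactly as documented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE does not exist."""


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class AssociationResult:
    """One SNP-by-outcome association estimate."""

    rs_id: str
    model: str  # allelic / genotypic / additive / dominant / recessive
    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float
    adjusted_for: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.ci95[0] <= self.odds_ratio <= self.ci95[1]):
            raise ValueError("odds ratio outside its own confidence interval")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def contingency_or(a: float, b: float, c: float, d: float) -> tuple[float, tuple[float, float], float]:
    """Odds ratio with Woolf 95% CI and 1-df chi-square p from a 2x2 table.

    Table layout: ``a``/``b`` exposed/unexposed cases, ``c``/``d``
    exposed/unexposed controls.  The Haldane-Anscombe 0.5 correction is
    applied to the OR and its CI when any cell is zero; the chi-square uses
    the uncorrected counts.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("negative cell count")
    if (cells[[0, 2]] == 0).all() or (cells[[1, 3]] == 0).all() or \
       (cells[[0, 1]] == 0).all() or (cells[[2, 3]] == 0).all():
        raise ValueError("two zero cells in the same margin: OR undefined")
    aa, bb, cc, dd = cells + 0.5 if (cells == 0).any() else cells
    or_ = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    z = stats.norm.ppf(0.975)
    ci = (float(or_ * np.exp(-z * se)), float(or_ * np.exp(z * se)))
    table = cells.reshape(2, 2)
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    chi2 = float(((table - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return float(or_), ci, p


@dataclass
class LogisticFit:
    coefficients: np.ndarray
    standard_errors: np.ndarray
    odds_ratios: np.ndarray
    ci95: np.ndarray  # (k, 2)
    p_values: np.ndarray
    n_iter: int
    log_likelihood: float
    names: list[str] = field(default_factory=list)


def logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
    names: list[str] | None = None,
    add_intercept: bool = True,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    Convergence requires the score (gradient) max-norm below ``tol``.
    Rank-deficient designs and separated data raise instead of returning
    divergent estimates (separation is flagged when fitted probabilities
    pin to 0/1 while coefficients grow without bound).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        names = ["intercept"] + list(names or [f"x{i}" for i in range(X.shape[1] - 1)])
    else:
        names = list(names or [f"x{i}" for i in range(X.shape[1])])
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise np.linalg.LinAlgError("design matrix is rank deficient")

    beta = np.zeros(k)
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < tol:
            break
        w = mu * (1.0 - mu)
        if np.max(np.abs(beta)) > 30 or w.max() < 1e-10:
            raise SeparationError("complete separation detected (diverging coefficients)")
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
        beta = beta + step
    else:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")

    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    w = mu * (1.0 - mu)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    se = np.sqrt(np.diag(cov))
    z = stats.norm.ppf(0.975)
    ci = np.column_stack([np.exp(beta - z * se), np.exp(beta + z * se)])
    wald = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(wald))
    ll = float(np.sum(y * np.log(mu + 1e-300) + (1 - y) * np.log(1 - mu + 1e-300)))
    return LogisticFit(
        coefficients=beta,
        standard_errors=se,
        odds_ratios=np.exp(beta),
        ci95=ci,
        p_values=pvals,
        n_iter=it,
        log_likelihood=ll,
        names=names,
    )


def bh_fdr(p_values: np.ndarray, alpha: float = 0.01) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up procedure.

    Returns a boolean significance mask (aligned with the input order) and
    the rejection threshold ``p_(k)`` — the largest ordered p-value with
    ``p_(k) <= (k/m) * alpha`` — or 0.0 when nothing is rejected.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    crit = (np.arange(1, m + 1) / m) * alpha
    passing = np.nonzero(sorted_p <= crit)[0]
    if passing.size == 0:
        return np.zeros(m, dtype=bool), 0.0
    threshold = float(sorted_p[passing[-1]])
    return p <= threshold, threshold


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(self.survival > 1.0) or np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival must be non-increasing and <= 1")

    def at(self, t: float) -> float:
        """S(t): survival just after time t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(times: np.ndarray, events: np.ndarray) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator (events precede censorings at ties)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValueError("negative times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    event_times = event_rows.index.to_numpy(dtype=float)
    survival = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    at_risk = event_rows["at_risk"].to_numpy(dtype=int)
    return SurvivalCurve(event_times=event_times, survival=survival, at_risk=at_risk)


def logrank_test(times: np.ndarray, events: np.ndarray, groups: np.ndarray) -> tuple[float, int, float]:
    """Log-rank test across >= 2 groups; returns (chi2, df, p)."""
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("log-rank requires at least two groups")
    res = multivariate_logrank_test(np.asarray(times, float), groups, np.asarray(events, int))
    df = len(labels) - 1
    return float(res.test_statistic), df, float(res.p_value)


def cohort_summary(dataset) -> pd.DataFrame:
    """Counts and percentages per category per arm, percentages to 1 decimal.

    Mirrors the usual "characteristics of cases and controls" table: one row
    per (variable, category), with ``n (pct)`` per outcome arm.
    """
    target = dataset.target_name
    t_labels = dataset.category_labels.get(target, [str(i) for i in range(dataset.arities[target])])
    rows = []
    for var in dataset.variable_names:
        if var == target or dataset.variable_roles.get(var) == "snp":
            continue
        labels = dataset.category_labels.get(var, [str(i) for i in range(dataset.arities[var])])
        for code, label in enumerate(labels):
            row: dict[str, object] = {"variable": var, "category": label}
            for t_code, t_label in enumerate(t_labels):
                arm = dataset.data[dataset.data[target] == t_code]
                denom = int((arm[var] != labels.index("na")).sum()) if "na" in labels else len(arm)
                count = int((arm[var] == code).sum())
                pct = percentage(count, denom)
                row[f"{t_label}_n"] = count
                row[f"{t_label}_pct"] = pct
            rows.append(row)
    return pd.DataFrame(rows)


def percentage(count: int, denom: int, decimals: int = 1) -> float:
    """Percentage rounded to the reporting precision; 0.0 on an empty denominator."""
    if denom == 0:
        return 0.0
    return round(100.0 * count / denom, decimals)
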