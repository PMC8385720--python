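"""Survival arm: univariate Cox, repeated LASSO-Cox stability selection,
risk scoring and evaluation (Kaplan-Meier, log-rank, time-dependent ROC).

Cox models use the Breslow tie convention throughout.  The unpenalized
fitter maximises the partial likelihood by Newton iteration (tolerance
1e-8, at most 50 steps) and flags monotone-likelihood / non-convergent
fits instead of failing silently.  Penalized path fits go through the
coordinate-descent elastic-net solver of scikit-survival with pure L1
penalty; the cross-validation criterion is the Verweij–Van Houwelingen
partial-likelihood deviance -2*[pl_full(beta_k) - pl_train(beta_k)],
which stays defined even when a held-out fold carries few events.

Stability selection repeats the 10-fold cross-validated LASSO, re-randomising
only the fold assignment each repetition, records the nonzero-coefficient
gene set chosen at the deviance-minimising lambda, and reports combination
and per-gene selection frequencies normalised per 100 repetitions.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from .io import ClinicalTable

logger = logging.getLogger(__name__)

__all__ = [
    "split_cohort",
    "cox_partial_loglik",
    "cox_univariate",
    "cox_multivariate",
    "CoxRow",
    "lasso_stability",
    "StabilityTable",
    "RiskModel",
    "fit_risk_model",
    "risk_score",
    "dichotomize",
    "km_curve",
    "logrank",
    "td_roc_auc",
]


def split_cohort(samples: Sequence[str], seed: int = 0) -> tuple[list[str], list[str]]:
    """Seeded random split into disjoint, exhaustive near-halves.

    The training half gets ``n // 2`` samples and the validation half the
    remainder; both preserve the input ordering.
    """
    samples = list(samples)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(samples))
    train_idx = set(perm[: len(samples) // 2].tolist())
    train = [s for i, s in enumerate(samples) if i in train_idx]
    val = [s for i, s in enumerate(samples) if i not in train_idx]
    return train, val


# ---------------------------------------------------------------------------
# Breslow partial likelihood
# ---------------------------------------------------------------------------


def _risk_prefix_index(time_sorted: np.ndarray) -> np.ndarray:
    """For each position i (times sorted decreasing), the last index of its tie block."""
    n = len(time_sorted)
    idx = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and time_sorted[j + 1] == time_sorted[i]:
            j += 1
        idx[i : j + 1] = j
        i = j + 1
    return idx


def cox_partial_loglik(
    beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray, gradient: bool = False
):
    """Breslow log partial likelihood (and optionally its gradient).

    ``X`` is n x p; returns ``ll`` or ``(ll, grad)``.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    eta = X @ beta
    c = eta.max() if len(eta) else 0.0
    order = np.argsort(-np.asarray(time), kind="stable")
    t_o, e_o, eta_o, X_o = np.asarray(time)[order], np.asarray(event)[order], eta[order], X[order]
    w = np.exp(eta_o - c)
    s0 = np.cumsum(w)
    tie_end = _risk_prefix_index(t_o)
    ev = e_o.astype(bool)
    denom0 = s0[tie_end]
    ll = float(np.sum(eta_o[ev] - (np.log(denom0[ev]) + c)))
    if not gradient:
        return ll
    s1 = np.cumsum(w[:, None] * X_o, axis=0)
    grad = np.sum(X_o[ev] - s1[tie_end[ev]] / denom0[ev, None], axis=0)
    return ll, grad


def _cox_hessian(beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Negative Hessian (observed information) of the Breslow partial likelihood."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    eta = X @ beta
    c = eta.max()
    order = np.argsort(-np.asarray(time), kind="stable")
    t_o, e_o, X_o = np.asarray(time)[order], np.asarray(event)[order], X[order]
    w = np.exp(eta[order] - c)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w[:, None] * X_o, axis=0)
    s2 = np.cumsum(w[:, None, None] * X_o[:, :, None] * X_o[:, None, :], axis=0)
    tie_end = _risk_prefix_index(t_o)
    ev = e_o.astype(bool)
    info = np.zeros((X.shape[1], X.shape[1]))
    for j in tie_end[ev]:
        mu = s1[j] / s0[j]
        info += s2[j] / s0[j] - np.outer(mu, mu)
    return info


@dataclass
class CoxRow:
    """One gene's univariate Cox fit: coefficient, HR with Wald 95% CI, p, flag."""

    gene: str
    coef: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    flag: str | None = None


def _newton_cox(
    X: np.ndarray, time: np.ndarray, event: np.ndarray, tol: float = 1e-8, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray, str | None]:
    """Newton maximisation of the Breslow partial likelihood with step halving.

    Returns (beta, covariance, flag); flag marks monotone likelihood
    (diverging coefficients) or non-convergence.
    """
    p = X.shape[1]
    beta = np.zeros(p)
    scale = X.std(axis=0, ddof=1)
    scale[scale == 0] = 1.0
    flag = None
    ll, grad = cox_partial_loglik(beta, X, time, event, gradient=True)
    for _ in range(max_iter):
        info = _cox_hessian(beta, X, time, event)
        try:
            step = np.linalg.solve(info + 1e-12 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            flag = "singular_information"
            break
        # step halving to guarantee ascent
        factor = 1.0
        for _ in range(30):
            new_beta = beta + factor * step
            new_ll, new_grad = cox_partial_loglik(new_beta, X, time, event, gradient=True)
            if new_ll >= ll - 1e-12:
                break
            factor /= 2.0
        beta, ll, grad = new_beta, new_ll, new_grad
        if np.max(np.abs(beta * scale)) > 20.0:
            flag = "monotone_likelihood"
            break
        if np.max(np.abs(factor * step)) < tol:
            break
    else:
        flag = flag or "non_convergence"
    info = _cox_hessian(beta, X, time, event)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        flag = flag or "singular_information"
    return beta, cov, flag


def _align(gene_expr: pd.Series | pd.DataFrame, clinical: ClinicalTable):
    common = [s for s in clinical.samples if s in gene_expr.index] if isinstance(
        gene_expr, pd.DataFrame
    ) else [s for s in clinical.samples if s in gene_expr.index]
    if not common:
        raise ValueError("no overlap between expression samples and clinical table")
    clin = clinical.data.loc[common]
    x = gene_expr.loc[common]
    return x, clin["time"].to_numpy(float), clin["event"].to_numpy(int)


def cox_univariate(gene_expr: pd.Series, clinical: ClinicalTable, gene: str | None = None) -> CoxRow:
    """Univariate Cox PH fit of survival on one gene's expression (Breslow ties)."""
    x, time, event = _align(gene_expr, clinical)
    if event.sum() < 2:
        raise ValueError("need at least two observed events")
    X = x.to_numpy(float)[:, None]
    beta, cov, flag = _newton_cox(X, time, event)
    coef = float(beta[0])
    se = float(np.sqrt(cov[0, 0])) if np.isfinite(cov[0, 0]) else float("nan")
    z = coef / se if se and np.isfinite(se) and se > 0 else float("nan")
    from scipy import stats as _stats

    pval = float(2.0 * _stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan")
    return CoxRow(
        gene=gene or (gene_expr.name or "x"),
        coef=coef,
        se=se,
        hr=math.exp(coef),
        ci_low=math.exp(coef - 1.96 * se) if np.isfinite(se) else float("nan"),
        ci_high=math.exp(coef + 1.96 * se) if np.isfinite(se) else float("nan"),
        p=pval,
        flag=flag,
    )


def cox_multivariate(expr: pd.DataFrame, clinical: ClinicalTable) -> pd.DataFrame:
    """Joint unpenalized Cox fit on a sample x gene matrix; one row per gene."""
    x, time, event = _align(expr, clinical)
    beta, cov, flag = _newton_cox(x.to_numpy(float), time, event)
    se = np.sqrt(np.diag(cov))
    from scipy import stats as _stats

    rows = pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "hr": np.exp(beta),
            "ci_low": np.exp(beta - 1.96 * se),
            "ci_high": np.exp(beta + 1.96 * se),
            "p": 2.0 * _stats.norm.sf(np.abs(beta / se)),
        },
        index=x.columns,
    )
    rows.attrs["flag"] = flag
    return rows


# ---------------------------------------------------------------------------
# penalized path + stability selection
# ---------------------------------------------------------------------------


def _coxnet_path(
    X: np.ndarray, time: np.ndarray, event: np.ndarray, alphas: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """L1 Cox path on standardized features; coefficients on the original scale.

    Returns (alphas, coefs) with coefs of shape (p, n_alphas).
    """
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    y = Surv.from_arrays(event.astype(bool), time)
    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0,
        alphas=None if alphas is None else list(alphas),
        n_alphas=50,
        alpha_min_ratio=0.01,
        fit_baseline_model=False,
        tol=1e-7,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xs, y)
    fitted_alphas = np.asarray(model.alphas_)
    coefs = model.coef_ / sd[:, None]
    if alphas is not None and len(fitted_alphas) < len(alphas):
        # solver stopped early; pad with the last solution
        pad = np.repeat(coefs[:, -1:], len(alphas) - len(fitted_alphas), axis=1)
        coefs = np.hstack([coefs, pad])
        fitted_alphas = np.asarray(alphas)
    return fitted_alphas, coefs


def _cv_deviance(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    alphas: np.ndarray,
    k_folds: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-fold Verweij–Van Houwelingen cross-validated deviance.

    Returns a (k_folds, n_alphas) matrix of fold contributions
    -2 * [pl_full(beta_k) - pl_train(beta_k)].
    """
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=int(rng.integers(2**31)))
    dev = np.zeros((k_folds, len(alphas)))
    for f, (train_idx, _) in enumerate(kf.split(X)):
        _, coefs = _coxnet_path(X[train_idx], time[train_idx], event[train_idx], alphas)
        for a in range(len(alphas)):
            beta = coefs[:, a]
            pl_full = cox_partial_loglik(beta, X, time, event)
            pl_train = cox_partial_loglik(beta, X[train_idx], time[train_idx], event[train_idx])
            dev[f, a] = -2.0 * (pl_full - pl_train)
    return dev


def _choose_alpha_index(dev: np.ndarray, lambda_rule: str) -> int:
    """Index of the chosen alpha on the (decreasing) path.

    ``min``: minimise the mean deviance.  ``1se``: the largest alpha
    (sparsest model) whose mean deviance is within one standard error
    (over folds) of the minimum.
    """
    mean = dev.mean(axis=0)
    best = int(np.argmin(mean))
    if lambda_rule == "min":
        return best
    se = dev[:, best].std(ddof=1) / math.sqrt(dev.shape[0])
    within = np.nonzero(mean <= mean[best] + se)[0]
    return int(within[0])  # alphas decrease along the path -> first is sparsest


@dataclass
class StabilityTable:
    """Selection frequencies over repeated cross-validated LASSO fits.

    ``combinations`` maps each distinct selected gene combination to its
    count and frequency per 100 repetitions (frequencies sum to 100);
    ``marginal`` gives per-gene frequencies per 100.
    """

    combinations: pd.DataFrame  # index: '+'-joined sorted genes; columns: count, freq_per_100
    marginal: pd.Series  # gene -> freq per 100
    n_reps: int
    alphas: np.ndarray = field(repr=False, default=None)

    @property
    def top_combination(self) -> tuple[str, ...]:
        best = self.combinations["count"].idxmax()
        return tuple(best.split("+")) if best else ()


def lasso_stability(
    expr: pd.DataFrame,
    clinical: ClinicalTable,
    n_reps: int = 1000,
    k_folds: int = 10,
    seed: int = 0,
    lambda_rule: str = "1se",
) -> StabilityTable:
    """Repeated 10-fold cross-validated LASSO-Cox with combination counting.

    ``expr`` is gene x sample.  The data (and hence the regularisation path
    fitted on the full sample) are fixed; each repetition re-randomises only
    the fold assignment, picks the deviance-minimising lambda
    (``lambda_rule="1se"`` picks the sparsest lambda within one standard
    error), and records the nonzero-coefficient gene set of the full-sample
    path at that lambda.
    """
    if lambda_rule not in ("min", "1se"):
        raise ValueError("lambda_rule must be 'min' or '1se'")
    x, time, event = _align(expr.T, clinical)
    if event.sum() < k_folds:
        raise ValueError("need at least k_folds observed events")
    X = x.to_numpy(float)
    genes = list(x.columns)
    rng = np.random.default_rng(seed)

    alphas, full_coefs = _coxnet_path(X, time, event)
    nonzero_per_alpha = [tuple(g for g, c in zip(genes, full_coefs[:, a]) if c != 0.0) for a in range(len(alphas))]

    counts: dict[tuple[str, ...], int] = {}
    chosen_alphas: list[float] = []
    for _ in range(n_reps):
        dev = _cv_deviance(X, time, event, alphas, k_folds, rng)
        best = _choose_alpha_index(dev, lambda_rule)
        combo = nonzero_per_alpha[best]
        counts[combo] = counts.get(combo, 0) + 1
        chosen_alphas.append(float(alphas[best]))

    if set(counts) == {()}:
        raise ValueError("every repetition selected zero genes; review the lambda grid")

    comb = pd.DataFrame(
        {
            "count": pd.Series({"+".join(k): v for k, v in counts.items()}),
        }
    ).sort_values("count", ascending=False)
    comb["freq_per_100"] = 100.0 * comb["count"] / n_reps
    marginal = pd.Series(0.0, index=genes)
    for combo, cnt in counts.items():
        for g in combo:
            marginal[g] += cnt
    marginal = 100.0 * marginal / n_reps
    return StabilityTable(comb, marginal, n_reps, alphas=alphas)


# ---------------------------------------------------------------------------
# risk model
# ---------------------------------------------------------------------------


@dataclass
class RiskModel:
    """Linear risk score over expression: sum of coef_g * expr_g.

    ``train_stats`` summarises the training-set score distribution
    (mean, sd, median) so z-score dichotomisation is reproducible.
    """

    genes: tuple[str, ...]
    coefficients: tuple[float, ...]
    train_stats: dict[str, float] = field(default_factory=dict)
    mode: str = "penalized"
    chosen_alpha: float | None = None

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.coefficients):
            raise ValueError("genes and coefficients must align")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": list(self.genes),
            "coefficients": list(self.coefficients),
            "train_stats": self.train_stats,
            "mode": self.mode,
            "chosen_alpha": self.chosen_alpha,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModel":
        d = json.loads(Path(path).read_text())
        return cls(
            tuple(d["genes"]),
            tuple(d["coefficients"]),
            d.get("train_stats", {}),
            d.get("mode", "penalized"),
            d.get("chosen_alpha"),
        )


def fit_risk_model(
    selected_genes: Sequence[str],
    expr: pd.DataFrame,
    clinical: ClinicalTable,
    mode: str = "penalized",
    k_folds: int = 10,
    seed: int = 0,
    alpha: float | None = None,
    lambda_rule: str = "1se",
) -> RiskModel:
    """Fit the linear risk model on the selected genes.

    ``mode="penalized"`` (default) takes the L1 coefficients at the
    cross-validation-chosen lambda refitted on the full training set
    restricted to the selected genes (``alpha`` overrides the CV choice);
    ``mode="refit"`` uses the unpenalized multivariable Newton fit.
    """
    genes = list(selected_genes)
    x, time, event = _align(expr.loc[genes].T, clinical)
    X = x.to_numpy(float)
    chosen = alpha
    if mode == "penalized":
        alphas, coefs = _coxnet_path(X, time, event)
        if alpha is None:
            rng = np.random.default_rng(seed)
            dev = _cv_deviance(X, time, event, alphas, min(k_folds, max(2, int(event.sum()))), rng)
            best = _choose_alpha_index(dev, lambda_rule)
            chosen = float(alphas[best])
        else:
            # a direct single-alpha fit avoids path early-termination effects
            alphas, coefs = _coxnet_path(X, time, event, np.array([alpha]))
            best = len(alphas) - 1
        beta = coefs[:, best]
    elif mode == "refit":
        beta, _, flag = _newton_cox(X, time, event)
        if flag:
            logger.warning("unpenalized refit flagged: %s", flag)
    else:
        raise ValueError("mode must be 'penalized' or 'refit'")
    scores = X @ beta
    stats_ = {"mean": float(scores.mean()), "sd": float(scores.std(ddof=1)), "median": float(np.median(scores))}
    return RiskModel(tuple(genes), tuple(float(b) for b in beta), stats_, mode, chosen)


def risk_score(model: RiskModel, expr: pd.Series | pd.DataFrame) -> float | pd.Series:
    """Evaluate the linear risk score on one sample (Series gene -> value)
    or on a gene x sample DataFrame (returns a per-sample Series)."""
    if isinstance(expr, pd.DataFrame):
        missing = [g for g in model.genes if g not in expr.index]
        if missing:
            raise KeyError(f"model gene(s) missing from expression: {missing}")
        coefs = np.array(model.coefficients)
        return pd.Series(coefs @ expr.loc[list(model.genes)].to_numpy(float), index=expr.columns)
    missing = [g for g in model.genes if g not in expr.index]
    if missing:
        raise KeyError(f"model gene(s) missing from expression: {missing}")
    return float(np.dot(model.coefficients, expr[list(model.genes)].to_numpy(float)))


def dichotomize(scores: pd.Series, method: str = "median") -> pd.Series:
    """Split scores into 'high'/'low' groups.

    ``median``: score >= median -> high (ties to high).  ``zscore``:
    z > 0 (i.e. score above the mean) -> high.  All-equal scores give a
    single group and a logged warning.
    """
    s = scores.astype(float)
    if method == "median":
        high = s >= s.median()
    elif method == "zscore":
        sd = s.std(ddof=1)
        if sd == 0:
            high = pd.Series(True, index=s.index)
        else:
            high = (s - s.mean()) / sd > 0
    else:
        raise ValueError("method must be 'median' or 'zscore'")
    if high.all() or (~high).all():
        logger.warning("dichotomize produced a single group (degenerate scores)")
    return pd.Series(np.where(high, "high", "low"), index=s.index)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def km_curve(times: Sequence[float], events: Sequence[int]) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate; columns time, survival (S(0) = 1)."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, float), np.asarray(events, int))
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)})


def logrank(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> tuple[float, float]:
    """Two-group log-rank test (hypergeometric variance): (chi-square, p)."""
    from lifelines.statistics import logrank_test

    res = logrank_test(
        np.asarray(times_a, float),
        np.asarray(times_b, float),
        event_observed_A=np.asarray(events_a, int),
        event_observed_B=np.asarray(events_b, int),
    )
    return float(res.test_statistic), float(res.p_value)


def td_roc_auc(
    scores: pd.Series,
    clinical: ClinicalTable,
    horizon: float,
    train_clinical: ClinicalTable | None = None,
) -> float:
    """Cumulative/dynamic time-dependent AUC at ``horizon`` with IPCW weights.

    Censoring weights come from the Kaplan-Meier estimate of the censoring
    distribution on ``train_clinical`` (defaults to the evaluation data).
    """
    clin = clinical.data.loc[[s for s in clinical.samples if s in scores.index]]
    s = scores.loc[clin.index].to_numpy(float)
    time = clin["time"].to_numpy(float)
    event = clin["event"].to_numpy(int)
    if not ((event == 1) & (time <= horizon)).any():
        raise ValueError(f"no observed events at or before horizon {horizon}")
    if horizon >= time.max():
        raise ValueError("horizon must be inside the observed follow-up range")
    ref = train_clinical.data if train_clinical is not None else clin
    y_train = Surv.from_arrays(ref["event"].astype(bool), ref["time"].astype(float))
    y_test = Surv.from_arrays(event.astype(bool), time)
    auc, _ = cumulative_dynamic_auc(y_train, y_test, s, np.array([horizon]))
    return float(auc[0])
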