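"""Differential expression and region-wise differential methylation.

The workhorse is an empirical-Bayes moderated two-sample t-test: per-feature
sample variances are shrunk toward a prior (d0, s0^2) estimated from the
ensemble of variances by the method of moments on log variances, and the
moderated statistic is referred to a t distribution with d0 + d degrees of
freedom.  Benjamini–Hochberg FDR adjustment and threshold-based calling
produce the DEG (|log2FC| > 1, FDR < 0.01) and DMG (|delta beta| > 0.3,
FDR < 0.05) tables.  Methylation is aggregated to gene x sample mean beta
matrices per region before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import NORMAL, TUMOR, ExpressionMatrix, MethylationDataset, REGION_TAGS

logger = logging.getLogger(__name__)

__all__ = [
    "log2_transform",
    "moderated_t",
    "bh_fdr",
    "call_degs",
    "aggregate_region_beta",
    "call_dmgs",
    "dmg_union",
]


def log2_transform(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount) on a linear-scale matrix; flips the scale flag."""
    if expr.log_scale:
        raise ValueError("matrix is already on the log scale")
    values = np.log2(expr.values + pseudocount)
    return ExpressionMatrix(values, log_scale=True, group_labels=expr.group_labels)


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Matches the first two moments of log sample variances (Fisher's log-F
    representation): returns (d0, s0^2).  d0 = inf means complete shrinkage
    to s0^2.
    """
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[s2 > 0])) if (s2 > 0).any() else 0.0
    z = np.log(s2[ok])
    d = df[ok]
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    ebar = e.mean()
    n = len(e)
    resid_var = np.sum((e - ebar) ** 2) / (n - 1) - np.mean(special.polygamma(1, d / 2.0))
    if resid_var <= 0:
        return np.inf, float(np.exp(ebar))
    d0 = 2.0 * _trigamma_inverse(resid_var)
    s0_sq = np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def moderated_t(
    matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    moderate: bool = True,
    max_missing_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-feature moderated two-sample t-test between sample groups.

    Effect is ``mean(group_b) - mean(group_a)``.  With a single feature (no
    variance ensemble) or ``moderate=False`` the ordinary pooled-variance t
    is used.  Features missing in more than ``max_missing_fraction`` of
    either group, or with fewer than two observed values per group, are
    dropped (count logged).  Returns a DataFrame with columns
    ``effect, t, p, df``.
    """
    a = matrix[list(group_a)].to_numpy(dtype=float)
    b = matrix[list(group_b)].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need at least two samples per group")

    na = np.sum(~np.isnan(a), axis=1)
    nb = np.sum(~np.isnan(b), axis=1)
    keep = (
        (na >= 2)
        & (nb >= 2)
        & (1 - na / a.shape[1] <= max_missing_fraction)
        & (1 - nb / b.shape[1] <= max_missing_fraction)
    )
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d feature(s) with insufficient observed values", dropped)
    if not keep.any():
        raise ValueError("no feature has enough observed values in both groups")

    idx = matrix.index[keep]
    a, b, na, nb = a[keep], b[keep], na[keep], nb[keep]
    mean_a = np.nanmean(a, axis=1)
    mean_b = np.nanmean(b, axis=1)
    var_a = np.nanvar(a, axis=1, ddof=1)
    var_b = np.nanvar(b, axis=1, ddof=1)
    df_res = na + nb - 2.0
    pooled = ((na - 1) * var_a + (nb - 1) * var_b) / df_res
    if np.all(pooled == 0):
        raise ValueError("zero variance in every feature; test undefined")

    effect = mean_b - mean_a
    if moderate and len(idx) > 1:
        d0, s0_sq = _fit_variance_prior(pooled, df_res)
        if np.isinf(d0):
            s2_post = np.full_like(pooled, s0_sq)
            df_total = np.full_like(df_res, np.inf)
        else:
            s2_post = (d0 * s0_sq + df_res * pooled) / (d0 + df_res)
            df_total = d0 + df_res
    else:
        s2_post = pooled
        df_total = df_res

    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
        t = effect / se
    p = np.where(
        np.isinf(df_total),
        2.0 * stats.norm.sf(np.abs(t)),
        2.0 * stats.t.sf(np.abs(t), np.where(np.isinf(df_total), 1.0, df_total)),
    )
    p = np.where(se == 0, np.where(effect == 0, 1.0, 0.0), p)
    return pd.DataFrame({"effect": effect, "t": t, "p": p, "df": df_total}, index=idx)


def bh_fdr(pvals: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------


@dataclass
class DifferentialTable:
    """Per-feature effect, raw p, BH-FDR q and call.

    Calls are ``up``/``down``/``none`` for expression and
    ``hyper``/``hypo``/``none`` for methylation (with a ``region`` column).
    """

    table: pd.DataFrame

    def called(self, *calls: str) -> list[str]:
        """Features whose call is in ``calls`` (default: any non-'none' call)."""
        t = self.table
        if calls:
            mask = t["call"].isin(calls)
        else:
            mask = t["call"] != "none"
        return list(t.index[mask])


def call_degs(
    stats_table: pd.DataFrame, fdr_max: float = 0.01, lfc_min: float = 1.0
) -> DifferentialTable:
    """Call up/down-regulated genes: FDR < fdr_max and |log2FC| > lfc_min."""
    t = stats_table.copy()
    t["fdr"] = bh_fdr(t["p"].to_numpy())
    sig = t["fdr"] < fdr_max
    call = np.where(
        sig & (t["effect"] > lfc_min), "up", np.where(sig & (t["effect"] < -lfc_min), "down", "none")
    )
    t["call"] = call
    return DifferentialTable(t[["effect", "p", "fdr", "call"]])


def aggregate_region_beta(meth: MethylationDataset, region: str) -> pd.DataFrame:
    """Gene x sample mean beta over probes annotated to ``region``.

    Genes without a probe in the region are absent from the output.
    Aggregation ignores missing probe values pairwise.
    """
    if region not in REGION_TAGS:
        raise ValueError(f"unknown region tag {region!r}; expected one of {REGION_TAGS}")
    man = meth.manifest.loc[meth.beta.index]
    mask = man["region"] == region
    if not mask.any():
        return pd.DataFrame(columns=meth.beta.columns)
    sub = meth.beta.loc[mask]
    return sub.groupby(man.loc[mask, "gene"], sort=True).mean()


def call_dmgs(
    region_beta: pd.DataFrame,
    labels: pd.Series,
    region: str,
    fdr_max: float = 0.05,
    delta_min: float = 0.3,
    moderate: bool = True,
) -> DifferentialTable:
    """Call hyper/hypomethylated genes on one region's mean-beta matrix.

    Delta beta = mean(tumor) - mean(normal); p from the moderated t on beta
    values.  hyper: FDR < fdr_max and delta > delta_min; hypo: FDR < fdr_max
    and delta < -delta_min.
    """
    lab = labels.reindex(region_beta.columns)
    normals = list(region_beta.columns[lab == NORMAL])
    tumors = list(region_beta.columns[lab == TUMOR])
    if not normals or not tumors:
        raise ValueError("both normal and tumor groups are required")
    res = moderated_t(region_beta, normals, tumors, moderate=moderate)
    res["fdr"] = bh_fdr(res["p"].to_numpy())
    sig = res["fdr"] < fdr_max
    res["call"] = np.where(
        sig & (res["effect"] > delta_min),
        "hyper",
        np.where(sig & (res["effect"] < -delta_min), "hypo", "none"),
    )
    res["region"] = region
    return DifferentialTable(res[["effect", "p", "fdr", "call", "region"]])


def dmg_union(dmg_tables: dict[str, DifferentialTable]) -> list[str]:
    """Genes called in at least one region, deduplicated (sorted)."""
    genes: set[str] = set()
    for table in dmg_tables.values():
        genes.update(table.called())
    return sorted(genes)
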