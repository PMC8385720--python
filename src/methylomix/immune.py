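"""Checkpoint-negative stratification and stromal/immune (ESTIMATE-style) scoring.

Tumor samples are called checkpoint-negative when their checkpoint-gene
expression falls strictly below the arithmetic mean of the normal samples.
Microenvironment infiltration is summarised by single-sample gene-set
enrichment (ssGSEA) scores for a stromal and an immune signature; their sum
is the ESTIMATE score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io import NORMAL, TUMOR, ExpressionMatrix, GeneSet

__all__ = [
    "pd1_negative_samples",
    "ssgsea_score",
    "estimate_scores",
    "compare_score_groups",
]


def pd1_negative_samples(expr: ExpressionMatrix, checkpoint_gene: str) -> list[str]:
    """Tumor samples with checkpoint expression strictly below the normal-sample mean.

    Order follows the sample order of ``expr``.  Ties with the mean are
    excluded (strict inequality).
    """
    if checkpoint_gene not in expr.values.index:
        raise KeyError(f"checkpoint gene {checkpoint_gene!r} not in expression matrix")
    normals = expr.samples_in_group(NORMAL)
    if not normals:
        raise ValueError("no normal samples to define the checkpoint baseline")
    row = expr.values.loc[checkpoint_gene]
    threshold = float(row[normals].mean())
    tumors = expr.samples_in_group(TUMOR)
    return [s for s in tumors if row[s] < threshold]


def ssgsea_score(sample_values: pd.Series, gene_set: Iterable[str], exponent: float = 0.25) -> float:
    """Single-sample enrichment score of ``gene_set`` in one expression profile.

    Genes are ranked by expression (average rank on ties); walking the list in
    decreasing order, the score is the sum over positions of the difference
    between the weighted in-set ECDF (weights ``rank**exponent``) and the
    unweighted out-of-set ECDF.  Depends on the values only through their
    ranks, hence invariant to strictly monotone transforms.
    """
    members = set(gene_set) if not isinstance(gene_set, GeneSet) else gene_set.members
    x = sample_values.dropna()
    in_set = x.index.isin(members).astype(bool)
    n_in = int(in_set.sum())
    n_out = len(x) - n_in
    if n_in == 0:
        raise ValueError("gene set has no member in the expression profile")
    if n_out == 0:
        raise ValueError("gene set covers every gene; out-of-set ECDF undefined")
    ranks = stats.rankdata(x.to_numpy(), method="average")  # 1 = lowest expression
    order = np.lexsort((np.arange(len(x)), -ranks))  # decreasing expression, stable
    in_sorted = in_set[order]
    w = np.abs(ranks[order]) ** exponent
    w_in = np.where(in_sorted, w, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    p_out = np.cumsum(~in_sorted) / n_out
    return float(np.sum(p_in - p_out))


@dataclass
class ImmuneScores:
    """Per-sample stromal, immune and ESTIMATE (= stromal + immune) scores."""

    scores: pd.DataFrame  # index: sample; columns: stromal, immune, estimate

    def __post_init__(self) -> None:
        resid = self.scores["estimate"] - (self.scores["stromal"] + self.scores["immune"])
        if not np.allclose(resid, 0.0, atol=1e-9):
            raise ValueError("estimate score must equal stromal + immune")


def estimate_scores(
    expr: ExpressionMatrix,
    stromal_set: Iterable[str],
    immune_set: Iterable[str],
    exponent: float = 0.25,
) -> ImmuneScores:
    """ssGSEA stromal and immune scores per sample; estimate = stromal + immune."""
    rows = {}
    for sample in expr.samples:
        col = expr.values[sample]
        s = ssgsea_score(col, stromal_set, exponent)
        i = ssgsea_score(col, immune_set, exponent)
        rows[sample] = (s, i, s + i)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["stromal", "immune", "estimate"])
    return ImmuneScores(df.loc[expr.samples])


def compare_score_groups(
    scores: ImmuneScores, labels: pd.Series, test: str = "ranksum"
) -> pd.DataFrame:
    """Two-sided two-group comparison of each score type.

    ``test`` is ``"ranksum"`` (Wilcoxon rank-sum / Mann-Whitney, default) or
    ``"ttest"`` (Welch).  Returns a DataFrame indexed by score type with
    columns ``statistic`` and ``p``.
    """
    lab = labels.reindex(scores.scores.index)
    groups = [g for g in (NORMAL, TUMOR) if (lab == g).any()]
    if len(groups) < 2:
        raise ValueError("both groups must be non-empty")
    out = {}
    for col in scores.scores.columns:
        a = scores.scores.loc[lab == NORMAL, col].to_numpy()
        b = scores.scores.loc[lab == TUMOR, col].to_numpy()
        if test == "ranksum":
            pooled = np.concatenate([a, b])
            tie_free = len(np.unique(pooled)) == len(pooled)
            method = "exact" if tie_free and max(len(a), len(b)) <= 30 else "auto"
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        elif test == "ttest":
            res = stats.ttest_ind(a, b, equal_var=False)
        else:
            raise ValueError(f"unknown test {test!r}")
        out[col] = (float(res.statistic), float(res.pvalue))
    return pd.DataFrame.from_dict(out, orient="index", columns=["statistic", "p"])
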