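"""DMEG integration: DEG x DMG intersection, four-mode classification,
chromosome summaries, and separability checks (PCA, LDA with leave-one-out ROC).

A differentially methylated and expressed gene (DMEG) is a gene called in
both the expression table and a region's methylation table.  Each (gene,
region) pair is classified by the signs of its delta beta and log2 fold
change: HypoUp (delta < -0.3, lfc > 1), HypoDown, HyperUp, HyperDown; pairs
inside the dead zone are 'unclassified'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_curve

from .differential import DifferentialTable

logger = logging.getLogger(__name__)

__all__ = [
    "classify_mode",
    "intersect_dmegs",
    "dmeg_gene_set",
    "chromosome_distribution",
    "pca_embed",
    "lda_loocv",
    "roc_auc",
    "ClassifierReport",
]

MODES = ("HypoUp", "HypoDown", "HyperUp", "HyperDown")

_CHROM_ORDER = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY", "unplaced"]


def classify_mode(
    delta_beta: float, log2fc: float, delta_min: float = 0.3, lfc_min: float = 1.0
) -> str:
    """Four-quadrant regulation mode from (delta beta, log2FC) signs.

    Inputs inside the dead zone (|delta| <= delta_min or |lfc| <= lfc_min)
    return ``"unclassified"``.
    """
    hypo, hyper = delta_beta < -delta_min, delta_beta > delta_min
    up, down = log2fc > lfc_min, log2fc < -lfc_min
    if hypo and up:
        return "HypoUp"
    if hypo and down:
        return "HypoDown"
    if hyper and up:
        return "HyperUp"
    if hyper and down:
        return "HyperDown"
    return "unclassified"


def intersect_dmegs(
    deg_table: DifferentialTable,
    dmg_tables_by_region: dict[str, DifferentialTable],
    delta_min: float = 0.3,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """One record per (gene, region) called in both the DEG and DMG tables.

    Columns: gene, region, delta_beta, log2fc, mode.  An empty intersection
    yields an empty frame.
    """
    deg_called = set(deg_table.called())
    records = []
    for region, dmg in dmg_tables_by_region.items():
        for gene in dmg.called():
            if gene not in deg_called:
                continue
            db = float(dmg.table.loc[gene, "effect"])
            lfc = float(deg_table.table.loc[gene, "effect"])
            records.append(
                {
                    "gene": gene,
                    "region": region,
                    "delta_beta": db,
                    "log2fc": lfc,
                    "mode": classify_mode(db, lfc, delta_min, lfc_min),
                }
            )
    return pd.DataFrame(records, columns=["gene", "region", "delta_beta", "log2fc", "mode"])


def dmeg_gene_set(records: pd.DataFrame) -> list[str]:
    """Gene-level DMEG set: union over regions, deduplicated (sorted)."""
    if records.empty:
        return []
    return sorted(records["gene"].unique())


def chromosome_distribution(records: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome counts of DMEG genes by mode.

    ``manifest`` maps probes to (gene, region, chromosome); a gene without a
    chromosome annotation is counted under ``unplaced`` (logged).  Rows are
    ordered chr1..chr22, chrX, chrY, unplaced; genes counted once per mode.
    """
    gene_chrom = manifest.drop_duplicates("gene").set_index("gene")["chromosome"]
    counts: dict[tuple[str, str], set[str]] = {}
    unplaced = 0
    for _, row in records.iterrows():
        chrom = gene_chrom.get(row["gene"])
        if chrom is None or (isinstance(chrom, float) and np.isnan(chrom)):
            chrom = "unplaced"
            unplaced += 1
        counts.setdefault((chrom, row["mode"]), set()).add(row["gene"])
    if unplaced:
        logger.info("%d DMEG record(s) without chromosome annotation -> 'unplaced'", unplaced)
    modes = list(MODES) + ["unclassified"]
    out = pd.DataFrame(0, index=_CHROM_ORDER, columns=modes, dtype=int)
    for (chrom, mode), genes in counts.items():
        if chrom not in out.index:
            out.loc["unplaced", mode] += len(genes)
        else:
            out.loc[chrom, mode] += len(genes)
    return out


# ---------------------------------------------------------------------------
# separability
# ---------------------------------------------------------------------------


def pca_embed(feature_matrix: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of a sample x feature matrix.

    Component signs are fixed by the largest-absolute-loading-positive
    convention so embeddings are deterministic.  Returns (coordinates,
    explained variance ratio).
    """
    X = feature_matrix.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds data rank {rank}")
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(X)
    for k in range(n_components):
        j = np.argmax(np.abs(pca.components_[k]))
        if pca.components_[k, j] < 0:
            coords[:, k] *= -1.0
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return pd.DataFrame(coords, index=feature_matrix.index, columns=cols), pca.explained_variance_ratio_


@dataclass
class ClassifierReport:
    """Held-out scores, ROC staircase and rank AUC for a two-class problem."""

    scores: pd.Series  # per-sample decision score (higher = positive class)
    labels: pd.Series  # 0/1 per sample
    roc_points: pd.DataFrame  # columns fpr, tpr
    auc: float


def roc_auc(scores: pd.Series | np.ndarray, labels: pd.Series | np.ndarray) -> ClassifierReport:
    """ROC/AUC by the rank (Mann–Whitney) formulation; ties contribute 1/2."""
    s = pd.Series(np.asarray(scores, dtype=float))
    y = pd.Series(np.asarray(labels, dtype=int))
    if s.index.equals(y.index) is False:
        y.index = s.index
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = stats.rankdata(s.to_numpy(), method="average")
    auc = (ranks[y.to_numpy() == 1].sum() - len(pos) * (len(pos) + 1) / 2.0) / (len(pos) * len(neg))
    fpr, tpr, _ = roc_curve(y.to_numpy(), s.to_numpy())
    return ClassifierReport(
        scores=s, labels=y, roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr}), auc=float(auc)
    )


def lda_loocv(
    feature_matrix: pd.DataFrame, labels: pd.Series, shrinkage: float = 0.1
) -> ClassifierReport:
    """Two-class LDA with leave-one-out cross-validated decision scores.

    For each sample, an LDA with shrinkage-regularised pooled covariance
    (``lsqr`` solver, shrinkage toward the diagonal) is fitted on the
    remaining samples; the held-out decision score feeds a ROC/AUC.  p close
    to n makes the raw pooled covariance singular, hence the regularisation.
    """
    y = labels.reindex(feature_matrix.index)
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValueError("lda_loocv requires exactly two classes")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("each class needs at least two samples")
    X = feature_matrix.to_numpy(dtype=float)
    y01 = (y == classes[1]).astype(int).to_numpy()
    scores = np.empty(len(y01))
    for i in range(len(y01)):
        mask = np.ones(len(y01), dtype=bool)
        mask[i] = False
        if len(np.unique(y01[mask])) < 2:
            raise ValueError("leave-one-out fold lost a class")
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
        lda.fit(X[mask], y01[mask])
        scores[i] = float(lda.decision_function(X[i : i + 1])[0])
    report = roc_auc(pd.Series(scores, index=feature_matrix.index), pd.Series(y01, index=feature_matrix.index))
    return report
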