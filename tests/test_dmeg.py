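import numpy as np
import pandas as pd
import pytest

from methylomix.differential import DifferentialTable
from methylomix.dmeg import (
    chromosome_distribution,
    classify_mode,
    dmeg_gene_set,
    intersect_dmegs,
    lda_loocv,
    pca_embed,
    roc_auc,
)


class TestClassifyMode:
    def test_quadrant_grid_matches_enumeration(self):
        grid = [-0.5, -0.31, -0.3, -0.1, 0.0, 0.1, 0.3, 0.31, 0.5]
        lfcs = [-2.0, -1.01, -1.0, -0.5, 0.0, 0.5, 1.0, 1.01, 2.0]
        for db in grid:
            for lfc in lfcs:
                expected = "unclassified"
                if db < -0.3 and lfc > 1:
                    expected = "HypoUp"
                elif db < -0.3 and lfc < -1:
                    expected = "HypoDown"
                elif db > 0.3 and lfc > 1:
                    expected = "HyperUp"
                elif db > 0.3 and lfc < -1:
                    expected = "HyperDown"
                assert classify_mode(db, lfc) == expected, (db, lfc)

    def test_examples(self):
        assert classify_mode(-0.4, 2.0) == "HypoUp"
        assert classify_mode(0.4, -2.0) == "HyperDown"
        assert classify_mode(-0.2, 2.0) == "unclassified"


def _table(calls, effects, region=None):
    df = pd.DataFrame(
        {"effect": effects, "p": 1e-5, "fdr": 1e-4, "call": calls},
        index=list(calls.keys()),
    )
    df["call"] = list(calls.values())
    if region:
        df["region"] = region
    return DifferentialTable(df)


class TestIntersection:
    def test_intersection_keeps_shared_genes_only(self):
        deg = _table({"A": "up", "B": "up"}, {"A": 2.0, "B": 2.0})
        dmg = _table({"B": "hypo", "C": "hypo"}, {"B": -0.4, "C": -0.4}, "TSS200")
        rec = intersect_dmegs(deg, {"TSS200": dmg})
        assert list(rec["gene"]) == ["B"]
        assert rec["mode"].iloc[0] == "HypoUp"

    def test_multi_region_gene_counted_once_in_dedup(self):
        deg = _table({"A": "up"}, {"A": 2.0})
        dmg1 = _table({"A": "hypo"}, {"A": -0.4}, "TSS200")
        dmg2 = _table({"A": "hypo"}, {"A": -0.5}, "Body")
        rec = intersect_dmegs(deg, {"TSS200": dmg1, "Body": dmg2})
        assert len(rec) == 2
        assert dmeg_gene_set(rec) == ["A"]

    def test_empty_intersection_is_empty_frame(self):
        deg = _table({"A": "up"}, {"A": 2.0})
        dmg = _table({"B": "hypo"}, {"B": -0.4}, "TSS200")
        rec = intersect_dmegs(deg, {"TSS200": dmg})
        assert rec.empty and dmeg_gene_set(rec) == []


class TestChromosomeDistribution:
    manifest = pd.DataFrame(
        {
            "gene": ["A", "B", "C"],
            "region": ["TSS200"] * 3,
            "chromosome": ["chr7", "chr7", "chrX"],
        },
        index=pd.Index(["p1", "p2", "p3"], name="probe"),
    )

    def _records(self, genes):
        return pd.DataFrame(
            {
                "gene": genes,
                "region": "TSS200",
                "delta_beta": -0.4,
                "log2fc": 2.0,
                "mode": "HypoUp",
            }
        )

    def test_counts_by_chromosome(self):
        out = chromosome_distribution(self._records(["A", "B", "C"]), self.manifest)
        assert out.loc["chr7", "HypoUp"] == 2
        assert out.loc["chrX", "HypoUp"] == 1

    def test_empty_input_all_zero(self):
        out = chromosome_distribution(self._records([]).iloc[:0], self.manifest)
        assert (out.to_numpy() == 0).all()

    def test_missing_chromosome_goes_unplaced(self):
        out = chromosome_distribution(self._records(["ZZ"]), self.manifest)
        assert out.loc["unplaced", "HypoUp"] == 1


class TestPca:
    def test_separated_blobs_align_with_pc1(self, rng):
        a = rng.normal(0, 0.05, (20, 5))
        b = rng.normal(0, 0.05, (20, 5)) + np.array([10, 0, 0, 0, 0])
        X = pd.DataFrame(np.vstack([a, b]))
        coords, evr = pca_embed(X, 2)
        gap = coords.iloc[:20, 0].mean() - coords.iloc[20:, 0].mean()
        assert abs(gap) > 5
        assert evr[0] > 0.95

    def test_duplicate_samples_identical_coordinates(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 4)))
        X.iloc[1] = X.iloc[0]
        coords, _ = pca_embed(X, 2)
        assert np.allclose(coords.iloc[0], coords.iloc[1])

    def test_deterministic_sign_convention(self, rng):
        X = pd.DataFrame(rng.normal(size=(15, 6)))
        c1, _ = pca_embed(X, 3)
        c2, _ = pca_embed(X, 3)
        pd.testing.assert_frame_equal(c1, c2)

    def test_components_beyond_rank_rejected(self):
        X = pd.DataFrame([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        with pytest.raises(ValueError, match="rank"):
            pca_embed(X, 2)


class TestRocAuc:
    def test_perfect_and_inverted_ranking(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == 1.0
        assert roc_auc([1, 2, 3, 4], [1, 1, 0, 0]).auc == 0.0

    def test_all_ties_give_half(self):
        assert roc_auc([5, 5, 5, 5], [0, 1, 0, 1]).auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_matches_pairwise_estimator(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 40))
            scores = rng.choice(np.arange(10.0), size=n)  # ties likely
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            pos, neg = scores[labels == 1], scores[labels == 0]
            pairs = (
                (pos[:, None] > neg[None, :]).sum()
                + 0.5 * (pos[:, None] == neg[None, :]).sum()
            ) / (len(pos) * len(neg))
            assert roc_auc(scores, labels).auc == pytest.approx(pairs)

    def test_roc_is_monotone_staircase(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        rep = roc_auc(scores, labels)
        pts = rep.roc_points
        assert (pts.diff().dropna() >= -1e-12).all().all()
        assert pts.iloc[-1].tolist() == [1.0, 1.0]


class TestLdaLoocv:
    def test_separated_blobs_reach_auc_one(self, rng):
        a = rng.normal(0, 0.2, (10, 4))
        b = rng.normal(5, 0.2, (10, 4))
        X = pd.DataFrame(np.vstack([a, b]), index=[f"s{i}" for i in range(20)])
        y = pd.Series([0] * 10 + [1] * 10, index=X.index)
        assert lda_loocv(X, y).auc == 1.0

    def test_loocv_produces_one_score_per_sample(self, rng):
        X = pd.DataFrame(rng.normal(size=(4, 3)), index=list("abcd"))
        y = pd.Series([0, 0, 1, 1], index=X.index)
        rep = lda_loocv(X, y)
        assert len(rep.scores) == 4

    def test_two_class_requirement(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 2)))
        with pytest.raises(ValueError):
            lda_loocv(X, pd.Series([0] * 6, index=X.index))

    def test_planted_dmegs_separate_cohort(self, planted_cohort):
        # expression of the planted DMEG genes separates tumor from normal
        c = planted_cohort
        genes = list(c.truth.dmeg)
        X = c.expression.values.loc[genes].T
        y = (c.expression.group_labels == "tumor").astype(int)
        assert lda_loocv(X, y).auc >= 0.99
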