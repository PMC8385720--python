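import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methylomix.differential import (
    aggregate_region_beta,
    bh_fdr,
    call_degs,
    call_dmgs,
    dmg_union,
    log2_transform,
    moderated_t,
)
from methylomix.io import ExpressionMatrix, MethylationDataset


class TestLog2Transform:
    def test_values_and_scale_flag(self):
        em = ExpressionMatrix(
            pd.DataFrame({"s1": [0.0, 3.0, 1023.0]}, index=list("ABC")), log_scale=False
        )
        out = log2_transform(em, pseudocount=1.0)
        assert out.log_scale
        assert list(out.values["s1"]) == [0.0, 2.0, 10.0]

    def test_double_transform_rejected(self):
        em = ExpressionMatrix(pd.DataFrame({"s1": [1.0]}, index=["A"]), log_scale=True)
        with pytest.raises(ValueError, match="already"):
            log2_transform(em)


class TestModeratedT:
    cols = [f"s{i}" for i in range(6)]
    ga, gb = cols[:3], cols[3:]

    def test_single_feature_matches_hand_pooled_t(self):
        df = pd.DataFrame([[1, 2, 3, 4, 5, 6]], columns=self.cols, index=["f"], dtype=float)
        res = moderated_t(df, self.ga, self.gb)
        # effect = mean(B) - mean(A) = 3; pooled two-sample t = 3.674
        assert res.loc["f", "effect"] == pytest.approx(3.0)
        assert res.loc["f", "t"] == pytest.approx(3.674, abs=1e-3)

    def test_identical_group_means_give_null_result(self, rng):
        base = rng.normal(size=(30, 3))
        df = pd.DataFrame(np.hstack([base, base]), columns=self.cols)
        res = moderated_t(df, self.ga, self.gb)
        assert np.allclose(res["effect"], 0.0)
        assert (res["p"] > 0.99).all()

    def test_shrinkage_tames_outlying_small_variance(self, rng):
        M = rng.normal(0, 1, (60, 6))
        M[0] = np.repeat([0.0, 1.0], 3) + rng.normal(0, 0.001, 6)
        df = pd.DataFrame(M, columns=self.cols)
        t_mod = moderated_t(df, self.ga, self.gb).loc[0, "t"]
        t_plain = moderated_t(df, self.ga, self.gb, moderate=False).loc[0, "t"]
        # posterior variance is pulled up toward the ensemble prior
        assert abs(t_mod) < abs(t_plain)

    def test_all_zero_variance_rejected(self):
        df = pd.DataFrame([[1.0] * 6, [2.0] * 6], columns=self.cols)
        with pytest.raises(ValueError, match="variance"):
            moderated_t(df, self.ga, self.gb)

    def test_high_missingness_features_dropped(self):
        df = pd.DataFrame(
            [[np.nan, np.nan, 1, 2, 3, 4], [1, 2, 3, 4, 5, 6]],
            columns=self.cols,
            index=["gap", "full"],
            dtype=float,
        )
        res = moderated_t(df, self.ga, self.gb)
        assert list(res.index) == ["full"]


def _brute_force_bh(p):
    """Independent step-up implementation: q(i) = min_{j>=i} p(j)*n/j."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        q[i] = min(running, 1.0)
    return q


class TestBhFdr:
    def test_hand_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_degenerate_inputs(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_fdr([0.3, 0.3, 0.3]), [0.3] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=20))
    def test_matches_brute_force_step_up(self, pvals):
        p = np.asarray(pvals)
        assert np.allclose(bh_fdr(p), _brute_force_bh(p), atol=1e-12)


class TestCalling:
    def _stats(self, rows):
        return pd.DataFrame(rows, columns=["effect", "p"]).assign(
            t=0.0, df=10.0
        )

    def test_deg_threshold_quadrants(self):
        # rows engineered so BH-FDR equals raw p ranking clearly
        stats = pd.DataFrame(
            {"effect": [1.5, -1.5, 3.0, 0.5], "p": [1e-6, 1e-6, 0.9, 1e-6]},
            index=["up", "down", "big_lfc_weak_p", "small_lfc"],
        )
        table = call_degs(stats, fdr_max=0.01, lfc_min=1.0)
        assert table.table.loc["up", "call"] == "up"
        assert table.table.loc["down", "call"] == "down"
        assert table.table.loc["big_lfc_weak_p", "call"] == "none"
        assert table.table.loc["small_lfc", "call"] == "none"

    def test_dmg_threshold_boundaries(self):
        cols = [f"n{i}" for i in range(4)] + [f"t{i}" for i in range(4)]
        labels = pd.Series(["normal"] * 4 + ["tumor"] * 4, index=cols)
        jitter = np.array([0, 1e-4, -1e-4, 5e-5])
        rows = {}
        for name, delta in (("hypo_strong", -0.35), ("boundary", 0.29), ("hyper_strong", 0.4)):
            rows[name] = np.concatenate([0.5 + jitter, 0.5 + delta + jitter])
        rb = pd.DataFrame(rows, index=cols).T
        table = call_dmgs(rb, labels, "TSS200", fdr_max=0.05, delta_min=0.3)
        assert table.table.loc["hypo_strong", "call"] == "hypo"
        assert table.table.loc["boundary", "call"] == "none"
        assert table.table.loc["hyper_strong", "call"] == "hyper"
        assert dmg_union({"TSS200": table}) == ["hyper_strong", "hypo_strong"]


class TestRegionAggregation:
    def _dataset(self):
        beta = pd.DataFrame(
            {"s1": [0.2, 0.4, 0.7], "s2": [0.1, 0.3, 0.9]}, index=["p1", "p2", "p3"]
        )
        manifest = pd.DataFrame(
            {
                "gene": ["G", "G", "H"],
                "region": ["TSS200", "TSS200", "Body"],
                "chromosome": ["chr1", "chr1", "chr2"],
            },
            index=pd.Index(["p1", "p2", "p3"], name="probe"),
        )
        return MethylationDataset(beta, manifest)

    def test_mean_over_probes(self):
        rb = aggregate_region_beta(self._dataset(), "TSS200")
        assert rb.loc["G", "s1"] == pytest.approx(0.3)
        assert "H" not in rb.index

    def test_single_probe_identity(self):
        rb = aggregate_region_beta(self._dataset(), "Body")
        assert rb.loc["H", "s2"] == pytest.approx(0.9)

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError, match="unknown region"):
            aggregate_region_beta(self._dataset(), "TSS9000")

    def test_commutes_with_sample_subsetting(self, planted_cohort):
        meth = planted_cohort.methylation
        subset = meth.samples[::3]
        full = aggregate_region_beta(meth, "TSS200")[subset]
        sub = aggregate_region_beta(
            MethylationDataset(meth.beta[subset], meth.manifest), "TSS200"
        )
        pd.testing.assert_frame_equal(full, sub)
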