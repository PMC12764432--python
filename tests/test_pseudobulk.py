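"""Pseudobulk aggregation, filters, scaling, RLE, RUV-III and PRPS."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest

import trmex
from trmex.pseudobulk import _tier_sizes


def _tiny_cells(counts, donor, subset):
    n, g = np.asarray(counts).shape
    obs = pd.DataFrame(
        {"donor": donor, "tissue": "T1", "subset": subset},
        index=[f"c{i}" for i in range(n)],
    )
    return ad.AnnData(
        X=np.asarray(counts, dtype=np.int32), obs=obs,
        var=pd.DataFrame(index=[f"g{j}" for j in range(g)]),
    )


class TestAggregate:
    def test_counts_are_exact_sums(self):
        cells = _tiny_cells([[2], [3], [5]], "D1", "TRM")
        pb = trmex.aggregate_pseudobulk(cells, group_by=("donor", "subset"),
                                        min_cells=1)
        assert pb.counts.iloc[0, 0] == 10

    def test_min_cell_boundary(self):
        counts = np.ones((39, 2), dtype=int)
        donor = ["D1"] * 19 + ["D2"] * 20
        cells = _tiny_cells(counts, "D1", "TRM")
        cells.obs["donor"] = donor
        pb = trmex.aggregate_pseudobulk(cells, group_by=("donor", "subset"))
        # 19-cell sample removed ("fewer than 20"), 20-cell sample retained
        assert list(pb.sample_meta["donor"]) == ["D2"]
        assert pb.sample_meta["n_cells"].iloc[0] == 20

    def test_empty_result_is_an_error(self):
        cells = _tiny_cells(np.ones((5, 2), dtype=int), "D1", "TRM")
        with pytest.raises(ValueError, match="minimum-cell"):
            trmex.aggregate_pseudobulk(cells, group_by=("donor", "subset"))

    def test_count_conservation(self, cells_and_truth):
        cells, _ = cells_and_truth
        pb = trmex.aggregate_pseudobulk(
            cells, group_by=("donor", "tissue", "subset"), min_cells=1
        )
        assert pb.counts.to_numpy().sum() == np.asarray(cells.X).sum()


class TestFilterGenes:
    def _pb(self, counts, genes, groups):
        df = pd.DataFrame(counts, columns=genes,
                          index=[f"s{i}" for i in range(len(counts))])
        meta = pd.DataFrame({"group": groups}, index=df.index)
        return trmex.PseudobulkSet(df, meta)

    def test_receptor_prefix_removed(self):
        pb = self._pb([[10, 10], [10, 10]], ["TRBV20-1", "CXCR6"], ["a", "a"])
        out = trmex.filter_genes(pb, min_count=5, min_samples=2)
        assert list(out.counts.columns) == ["CXCR6"]

    def test_kept_if_rule_met_in_one_group(self):
        pb = self._pb([[6], [6], [0], [0]], ["CXCR6"], ["A", "A", "B", "B"])
        out = trmex.filter_genes(pb, min_count=5, min_samples=2)
        assert "CXCR6" in out.counts.columns

    def test_count_rule_is_strictly_above(self):
        pb = self._pb([[5, 6], [5, 6]], ["ITGAE", "CXCR6"], ["A", "A"])
        out = trmex.filter_genes(pb, min_count=5, min_samples=2)
        assert list(out.counts.columns) == ["CXCR6"]

    def test_all_filtered_is_error(self):
        pb = self._pb([[1], [1]], ["TRAV1"], ["A", "A"])
        with pytest.raises(ValueError):
            trmex.filter_genes(pb)


class TestLogTransform:
    def test_zero_count_half_prior(self):
        m = pd.DataFrame([[0]], columns=["g"], index=["s"])
        assert trmex.log_transform(m, prior_count=0.5).iloc[0, 0] == -1.0

    def test_count_one_prior_one(self):
        m = pd.DataFrame([[1]], columns=["g"], index=["s"])
        assert trmex.log_transform(m, prior_count=1.0).iloc[0, 0] == 1.0

    def test_cpm_path(self):
        # one gene at count 10 in a library of 1e6 -> CPM 10, log2(10+1)
        m = pd.DataFrame([[10, 10**6 - 10]], columns=["g1", "g2"], index=["s"])
        out = trmex.log_transform(m, prior_count=1.0, as_cpm=True)
        assert out.iloc[0, 0] == pytest.approx(np.log2(11))

    def test_bad_prior_rejected(self):
        m = pd.DataFrame([[1]], columns=["g"], index=["s"])
        with pytest.raises(ValueError):
            trmex.log_transform(m, prior_count=0.0)


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        m = pd.DataFrame([[10, 20, 30]] * 3, index=list("abc"))
        assert np.allclose(trmex.tmm_factors(m), 1.0)

    def test_pure_depth_difference_gives_unit_factors(self):
        # doubling every count doubles the library; composition is unchanged,
        # so the trimmed mean of library-normalized M values is 0
        rng = np.random.default_rng(0)
        base = rng.integers(1, 200, 100)
        m = pd.DataFrame([base, 2 * base], index=["a", "b"])
        assert np.allclose(trmex.tmm_factors(m), 1.0)

    def test_single_sample(self):
        m = pd.DataFrame([[5, 5]], index=["a"])
        assert trmex.tmm_factors(m).iloc[0] == 1.0

    def test_geometric_mean_is_one(self, pseudobulk_set):
        f = trmex.tmm_factors(pseudobulk_set)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)
        assert (f > 0).all()

    def test_all_zero_sample_is_error(self):
        m = pd.DataFrame([[1, 2], [0, 0]], index=["a", "zero"])
        with pytest.raises(ValueError, match="zero"):
            trmex.tmm_factors(m)

    def test_composition_bias_detected(self):
        # sample b doubles one highly expressed gene only: factor > 1 for b
        rng = np.random.default_rng(1)
        base = rng.integers(50, 200, 200).astype(float)
        other = base.copy()
        other[0] = base[0] * 50
        m = pd.DataFrame([base, other], index=["a", "b"])
        f = trmex.tmm_factors(m)
        assert f["b"] < f["a"]  # b's library is inflated by the one gene


class TestRLE:
    def test_median_profile_sample_is_zero(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(5, 1, (5, 40)))
        med_profile = m.median(axis=0)
        m.loc[5] = med_profile
        rle, _ = trmex.compute_rle(m)
        assert np.allclose(rle.loc[5], 0.0)

    def test_global_shift_moves_sample_median(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(5, 1, (6, 60)))
        # keep sample 0 clear of the gene-wise medians so they are unchanged
        m.iloc[0] += 5.0
        _, med0 = trmex.compute_rle(m)
        m2 = m.copy()
        m2.iloc[0] += 1.0
        _, med1 = trmex.compute_rle(m2)
        assert med1.iloc[0] - med0.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_constant_matrix_is_all_zero(self):
        m = pd.DataFrame(np.full((4, 8), 3.0))
        rle, med = trmex.compute_rle(m)
        assert np.allclose(rle, 0.0) and np.allclose(med, 0.0)


class TestRUV3:
    @staticmethod
    def _within_group_var(df, groups):
        return float(np.mean([
            df.loc[idx].var(axis=0).mean()
            for _, idx in groups.groupby(groups, observed=True).groups.items()
        ]))

    def test_k_zero_is_identity(self):
        expr, meta, truth = trmex.simulate_bulk_batches(n_samples=12, seed=0)
        design = trmex.ReplicateDesign.from_groups(
            meta["subtype"], truth.control_genes, k=0
        )
        out = trmex.ruv3_correct(expr, design)
        pd.testing.assert_frame_equal(out, expr)

    def test_cross_batch_replicates_remove_planted_shift(self):
        expr, meta, truth = trmex.simulate_bulk_batches(
            n_samples=60, batch_shift=2.0, seed=3
        )
        design = trmex.ReplicateDesign.from_groups(
            meta["subtype"], truth.control_genes, k=1
        )
        corr, W = trmex.ruv3_correct(expr, design, return_w=True)
        v0 = self._within_group_var(expr, meta["subtype"])
        v1 = self._within_group_var(corr, meta["subtype"])
        assert 1 - v1 / v0 >= 0.9
        assert W.shape == (60, 1)

    def test_biology_preserved_after_correction(self):
        expr, meta, truth = trmex.simulate_bulk_batches(
            n_samples=60, batch_shift=2.0, seed=3, subtype_effect=1.0
        )
        design = trmex.ReplicateDesign.from_groups(
            meta["subtype"], truth.control_genes, k=1
        )
        corr = trmex.ruv3_correct(expr, design)
        diffs = []
        for st, genes in truth.planted_up_genes.items():
            g = sorted(genes)
            in_st = meta["subtype"] == st
            diffs.append(
                (corr.loc[in_st, g].mean() - corr.loc[~in_st, g].mean()).mean()
            )
        assert np.mean(diffs) == pytest.approx(1.0, abs=0.1)

    def test_confounded_replicates_cannot_remove_shift(self):
        # replicate groups nested inside batches: the shift is biology-like
        expr, meta, truth = trmex.simulate_bulk_batches(
            n_samples=30, n_batches=3, batch_shift=2.0, seed=4
        )
        groups = meta["batch"]  # each group confined to one batch
        design = trmex.ReplicateDesign.from_groups(
            groups, truth.control_genes, k=1
        )
        corr = trmex.ruv3_correct(expr, design)
        gap0 = expr[meta["batch"] == "B3"].mean().mean() - \
            expr[meta["batch"] == "B1"].mean().mean()
        gap1 = corr[meta["batch"] == "B3"].mean().mean() - \
            corr[meta["batch"] == "B1"].mean().mean()
        assert gap1 > 0.5 * gap0  # shift survives

    def test_k_too_large_is_estimability_error(self):
        expr, meta, truth = trmex.simulate_bulk_batches(n_samples=9, seed=0)
        design = trmex.ReplicateDesign.from_groups(
            meta["subtype"], truth.control_genes, k=8
        )
        with pytest.raises(ValueError, match="estimable"):
            trmex.ruv3_correct(expr, design)

    def test_one_group_per_sample_enforced(self):
        m = pd.DataFrame([[1, 1], [1, 0]], columns=["a", "b"])
        with pytest.raises(ValueError):
            trmex.ReplicateDesign(membership=m, control_genes={"g"}, k=1)


class TestPRPS:
    def test_tier_sizes_remainder_at_bottom(self):
        assert _tier_sizes(9) == (3, 3, 3)
        assert _tier_sizes(10) == (4, 3, 3)
        assert _tier_sizes(11) == (4, 4, 3)

    @staticmethod
    def _cohort(n, subtype_counts, seed=0):
        rng = np.random.default_rng(seed)
        expr = pd.DataFrame(
            rng.normal(5, 1, (n, 50)), index=[f"s{i}" for i in range(n)]
        )
        subtypes = [st for st, k in subtype_counts.items() for _ in range(k)]
        meta = pd.DataFrame({"batch": "B1", "subtype": subtypes}, index=expr.index)
        return expr, meta

    def test_mid_size_subtype_gives_one_pseudo_sample_of_five(self):
        expr, meta = self._cohort(21, {"LumA": 21})
        # within one tier a subtype has 7 samples -> one pseudo-sample
        prps = trmex.build_prps(expr, meta, seed=1)
        assert len(prps.pseudo_samples) == 3  # one per tier
        for pid, members in prps.members.items():
            assert len(members) == 5
            np.testing.assert_allclose(
                prps.pseudo_samples.loc[pid], expr.loc[members].mean(axis=0)
            )

    def test_large_subtype_gives_two_rank_extreme_pseudo_samples(self):
        expr, meta = self._cohort(36, {"LumA": 36})
        prps = trmex.build_prps(expr, meta, seed=1)
        # 12 per tier -> bottom-5 and top-5 pseudo-samples per tier
        assert len(prps.pseudo_samples) == 6
        tags = {pid.rsplit("|", 1)[1] for pid in prps.pseudo_samples.index}
        assert tags == {"lo", "hi"}

    def test_small_subtype_contributes_nothing(self):
        expr, meta = self._cohort(12, {"LumA": 12})
        prps = trmex.build_prps(expr, meta, seed=1)  # 4 per tier < 5
        assert len(prps.pseudo_samples) == 0

    def test_missing_subtype_label_is_error(self):
        expr, meta = self._cohort(6, {"LumA": 6})
        meta.loc[meta.index[0], "subtype"] = np.nan
        with pytest.raises(ValueError, match="s0"):
            trmex.build_prps(expr, meta, seed=0)

    def test_prps_design_feeds_ruv3(self):
        expr, meta, truth = trmex.simulate_bulk_batches(
            n_samples=90, n_batches=1, batch_shift=0.0, seed=6
        )
        prps = trmex.build_prps(expr, meta, seed=0)
        stacked, design = trmex.prps_replicate_design(expr, prps, k=1)
        corr = trmex.ruv3_correct(stacked, design)
        assert corr.shape == stacked.shape
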