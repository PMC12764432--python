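"""Clonotype construction, overlap statistics and viral annotation."""

import numpy as np
import pandas as pd
import pytest

import trmex


def _contig(cell, chain, nt, umis, aa="CASS"):
    return {"cell_id": cell, "chain": chain, "cdr3_nt": nt, "cdr3_aa": aa,
            "umis": umis}


def _meta(cells, subset="TRM", donor="D1"):
    return pd.DataFrame(
        {"subset": subset, "tissue": "tumor", "donor": donor}, index=cells
    )


class TestBuildClonotypes:
    def test_highest_umi_contig_retained(self):
        contigs = pd.DataFrame([
            _contig("c1", "TRA", "AAATTT", 5), _contig("c1", "TRA", "GGGCCC", 3),
            _contig("c1", "TRB", "CCCGGG", 4),
        ])
        ct = trmex.build_clonotypes(contigs, _meta(["c1"]))
        assert ct.cells.loc[0, "cdr3a_nt"] == "AAATTT"
        assert ct.cells.loc[0, "clonotype_key"] == "AAATTT_CCCGGG"

    def test_two_distinct_beta_chains_is_doublet(self):
        contigs = pd.DataFrame([
            _contig("c1", "TRA", "AAATTT", 5),
            _contig("c1", "TRB", "CCCGGG", 9), _contig("c1", "TRB", "TTTAAA", 1),
        ])
        ct = trmex.build_clonotypes(contigs, _meta(["c1"]))
        assert len(ct) == 0  # excluded even though UMI retention could pick one

    def test_duplicate_identical_beta_not_a_doublet(self):
        contigs = pd.DataFrame([
            _contig("c1", "TRA", "AAATTT", 5),
            _contig("c1", "TRB", "CCCGGG", 9), _contig("c1", "TRB", "CCCGGG", 2),
        ])
        assert len(trmex.build_clonotypes(contigs, _meta(["c1"]))) == 1

    def test_identical_chains_share_key(self):
        contigs = pd.DataFrame([
            _contig("c1", "TRA", "AAATTT", 5), _contig("c1", "TRB", "CCCGGG", 4),
            _contig("c2", "TRA", "AAATTT", 2), _contig("c2", "TRB", "CCCGGG", 7),
        ])
        ct = trmex.build_clonotypes(contigs, _meta(["c1", "c2"]))
        assert ct.cells["clonotype_key"].nunique() == 1

    def test_unknown_chain_rejected(self):
        contigs = pd.DataFrame([_contig("c1", "TRG", "AAATTT", 5)])
        with pytest.raises(ValueError, match="chain"):
            trmex.build_clonotypes(contigs, _meta(["c1"]))

    def test_roundtrip_from_simulated_repertoire(self, repertoire):
        rep, _, _ = repertoire
        contigs = rep.to_contigs(seed=0)
        meta = rep.cells.set_index("cell_id")[["subset", "tissue", "donor"]]
        rebuilt = trmex.build_clonotypes(contigs, meta)
        assert len(rebuilt) == len(rep)
        orig = rep.cells.sort_values("cell_id")["clonotype_key"].to_numpy()
        new = rebuilt.cells.sort_values("cell_id")["clonotype_key"].to_numpy()
        assert np.array_equal(orig, new)


class TestExpandedClones:
    def test_size_boundary(self, repertoire):
        rep, _, _ = repertoire
        sizes = rep.clone_sizes()
        exp = trmex.expanded_clones(rep, min_cells=2)
        assert exp == set(sizes.index[sizes >= 2])
        assert all(sizes[k] >= 2 for k in exp)

    def test_empty_table(self):
        ct = trmex.ClonotypeTable(pd.DataFrame(columns=[
            "cell_id", "clonotype_key", "cdr3a_nt", "cdr3b_nt", "cdr3a_aa",
            "cdr3b_aa", "subset", "tissue", "donor"]))
        assert trmex.expanded_clones(ct) == set()


class TestJaccard:
    def test_worked_example(self):
        assert trmex.jaccard_dissimilarity({"x", "y", "z"}, {"y", "z", "w"}) == 0.5

    def test_identical_and_disjoint(self):
        assert trmex.jaccard_dissimilarity({"a"}, {"a"}) == 0.0
        assert trmex.jaccard_dissimilarity({"a"}, {"b"}) == 1.0

    def test_empty_sets_error(self):
        with pytest.raises(ValueError):
            trmex.jaccard_dissimilarity(set(), set())

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = {f"k{i}" for i in rng.integers(0, 40, rng.integers(1, 30))}
            b = {f"k{i}" for i in rng.integers(0, 40, rng.integers(1, 30))}
            inter = sum(1 for k in a if k in b)
            expected = 1 - inter / len(a | b)
            assert trmex.jaccard_dissimilarity(a, b) == pytest.approx(expected)
            assert trmex.jaccard_dissimilarity(a, b) == \
                trmex.jaccard_dissimilarity(b, a)


class TestSharedCounts:
    @staticmethod
    def _table(spec):
        # spec: list of (key, subset, n_cells)
        rows = []
        i = 0
        for key, subset, n in spec:
            for _ in range(n):
                rows.append({"cell_id": f"c{i}", "clonotype_key": key,
                             "cdr3a_nt": key.split("_")[0],
                             "cdr3b_nt": key.split("_")[1],
                             "cdr3a_aa": "A", "cdr3b_aa": "B",
                             "subset": subset, "tissue": "t", "donor": "D1"})
                i += 1
        return trmex.ClonotypeTable(pd.DataFrame(rows))

    def test_cutoff_behavior(self):
        ct = self._table([("AAA_TTT", "TRM", 1), ("AAA_TTT", "TEX", 3)])
        at1 = trmex.shared_clonotype_counts(ct, ["TRM", "TEX"], 1)
        at2 = trmex.shared_clonotype_counts(ct, ["TRM", "TEX"], 2)
        assert at1 == {("TRM", "TEX"): 1}
        assert at2 == {("TEX",): 1}  # only TEX reaches 2 cells

    def test_singleton_combination(self):
        ct = self._table([("AAA_TTT", "TRM", 2)])
        assert trmex.shared_clonotype_counts(ct, ["TRM", "TEX"], 1) == \
            {("TRM",): 1}

    def test_triple_combination_at_cutoff_three(self):
        ct = self._table([("AAA_TTT", "TRM", 3), ("AAA_TTT", "TEX", 3),
                          ("AAA_TTT", "TEM", 3)])
        out = trmex.shared_clonotype_counts(ct, ["TRM", "TEX", "TEM"], 3)
        assert out == {("TRM", "TEX", "TEM"): 1}

    def test_unknown_subset_rejected(self):
        ct = self._table([("AAA_TTT", "TRM", 2)])
        with pytest.raises(ValueError):
            trmex.shared_clonotype_counts(ct, ["TEX"], 1)

    def test_monotone_in_cutoff(self, repertoire):
        rep, _, _ = repertoire
        subsets = ["TRM", "TEX", "TEM"]
        prev = trmex.shared_clonotype_counts(rep, subsets, 1)
        for cut in (2, 3):
            cur = trmex.shared_clonotype_counts(rep, subsets, cut)
            # a clone qualifying for a combination at cutoff n+1 qualifies
            # for a (super)combination at cutoff n: total counts shrink
            assert sum(cur.values()) <= sum(prev.values())
            prev = cur


class TestAnnotateViral:
    @staticmethod
    def _single_clone(aa_a, aa_b, donor="D1"):
        return trmex.ClonotypeTable(pd.DataFrame([{
            "cell_id": "c0", "clonotype_key": "AAA_TTT", "cdr3a_nt": "AAA",
            "cdr3b_nt": "TTT", "cdr3a_aa": aa_a, "cdr3b_aa": aa_b,
            "subset": "TRM", "tissue": "t", "donor": donor}]))

    _refs = pd.DataFrame([
        {"cdr3a_aa": "CAVRDNYQLIW", "cdr3b_aa": "CASSLGQAYEQYF",
         "hla": "A*02:01", "species": "CMV"},
    ])

    def test_exact_match_with_matching_hla_flagged(self):
        ct = self._single_clone("CAVRDNYQLIW", "CASSLGQAYEQYF")
        ann = trmex.annotate_viral(ct, self._refs, {"D1": ["A*02:01"]})
        assert ann.loc[0, "viral"] and ann.loc[0, "min_distance"] == 0
        assert ann.loc[0, "species"] == "CMV"

    def test_hla_restriction_blocks_match(self):
        ct = self._single_clone("CAVRDNYQLIW", "CASSLGQAYEQYF")
        ann = trmex.annotate_viral(ct, self._refs, {"D1": ["B*07:02"]})
        assert not ann.loc[0, "viral"]

    def test_distance_one_threshold_boundary(self):
        ct = self._single_clone("CAVRDNYQLIW", "CASSLGQAYEQYX")  # one sub
        strict = trmex.annotate_viral(ct, self._refs, {"D1": ["A*02:01"]})
        assert strict.loc[0, "min_distance"] == 1 and not strict.loc[0, "viral"]
        loose = trmex.annotate_viral(ct, self._refs, {"D1": ["A*02:01"]},
                                     inclusive=True)
        assert loose.loc[0, "viral"]

    def test_missing_hla_record_skips_clone(self):
        ct = self._single_clone("CAVRDNYQLIW", "CASSLGQAYEQYF", donor="D9")
        with pytest.warns(UserWarning, match="D9"):
            ann = trmex.annotate_viral(ct, self._refs, {"D1": ["A*02:01"]})
        assert len(ann) == 0

    def test_matches_brute_force_oracle(self, repertoire, levenshtein_oracle):
        rep, refs, truth = repertoire
        ann = trmex.annotate_viral(rep, refs, truth.donor_hla)
        clones = rep.cells.drop_duplicates(["donor", "clonotype_key"])
        assert len(ann) == len(clones)
        lookup = ann.set_index(["donor", "clonotype_key"])
        for r in clones.itertuples():
            best = np.inf
            for ref in refs.itertuples():
                if ref.hla not in truth.donor_hla[r.donor]:
                    continue
                d = max(levenshtein_oracle(r.cdr3a_aa, ref.cdr3a_aa),
                        levenshtein_oracle(r.cdr3b_aa, ref.cdr3b_aa))
                best = min(best, d)
            row = lookup.loc[(r.donor, r.clonotype_key)]
            assert row["min_distance"] == best
            assert bool(row["viral"]) == (best < 1)

    def test_planted_clone_recovery_is_exact(self, repertoire):
        rep, refs, truth = repertoire
        ann = trmex.annotate_viral(rep, refs, truth.donor_hla)
        called = {(r.donor, r.clonotype_key) for r in ann.itertuples() if r.viral}
        assert called == truth.viral_clonotypes  # precision = recall = 1
        # distance-1 mutants sit exactly at the excluded boundary
        near = ann.set_index(["donor", "clonotype_key"]).loc[
            sorted(truth.near_viral_clonotypes), "min_distance"
        ]
        assert (near == 1).all()


class TestCloneComposition:
    def test_row_scaling_and_values(self):
        ct = TestSharedCounts._table(
            [("AAA_TTT", "TRM", 7), ("AAA_TTT", "TEX", 3)]
        )
        comp = trmex.clone_composition(ct, top_n=5)
        row = comp.iloc[0]
        assert row["TRM"] == pytest.approx(70.0)
        assert row["TEX"] == pytest.approx(30.0)
        assert comp.sum(axis=1).iloc[0] == pytest.approx(100.0, abs=1e-9)

    def test_tie_break_is_lexicographic(self):
        ct = TestSharedCounts._table(
            [("BBB_TTT", "TRM", 3), ("AAA_TTT", "TRM", 3), ("CCC_TTT", "TEX", 5)]
        )
        comp = trmex.clone_composition(ct, top_n=2)
        keys = [k[1] for k in comp.index]
        assert keys == ["CCC_TTT", "AAA_TTT"]

    def test_row_sums_on_simulated_data(self, repertoire):
        rep, _, _ = repertoire
        comp = trmex.clone_composition(rep, top_n=100)
        assert np.allclose(comp.sum(axis=1), 100.0, atol=1e-9)
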