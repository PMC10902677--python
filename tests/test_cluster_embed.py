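"""Levenshtein clustering, SGT embedding, projection, binding integration."""

import math
from functools import lru_cache

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from repseq import (BindingTable, RepertoireError, dendrogram, ld_graph,
                    ld_matrix, levenshtein, nearest_labeled_neighbors,
                    overlay_binding, reduce_to_2d, sgt_embed, to_newick)
from repseq.cluster_embed import select_top_sequences


@lru_cache(maxsize=None)
def lev_recursive(a: str, b: str) -> int:
    """Textbook recursive definition; the independent oracle."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return min(lev_recursive(a[:-1], b) + 1,
               lev_recursive(a, b[:-1]) + 1,
               lev_recursive(a[:-1], b[:-1]) + (a[-1] != b[-1]))


aa_strings = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", max_size=12)


class TestLevenshtein:
    @pytest.mark.parametrize("a,b,expected", [
        ("CAT", "BAD", 2),
        ("CAT", "CATS", 1),
        ("kitten", "sitting", 3),
        ("CAT", "CAT", 0),
        ("CAT", "", 3),
        ("", "", 0),
    ])
    def test_worked_examples(self, a, b, expected):
        assert levenshtein(a, b) == expected

    @given(aa_strings, aa_strings)
    def test_agrees_with_recursive_oracle(self, a, b):
        assert levenshtein(a, b) == lev_recursive(a, b)

    @given(aa_strings, aa_strings, aa_strings)
    def test_metric_axioms(self, a, b, c):
        assert levenshtein(a, b) == levenshtein(b, a)
        assert (levenshtein(a, b) == 0) == (a == b)
        assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)


class TestLDMatrix:
    def test_worked_entries(self):
        mat = ld_matrix(["CAT", "BAD", "CATS"])
        f = mat.to_frame()
        assert f.loc["CAT", "BAD"] == 2
        assert f.loc["CAT", "CATS"] == 1
        assert f.loc["BAD", "CATS"] == 3

    def test_duplicates_are_pooled(self):
        mat = ld_matrix(["CAT", "CAT", "DOG"])
        assert mat.sequences == ["CAT", "DOG"]

    def test_single_sequence_errors(self):
        with pytest.raises(RepertoireError):
            ld_matrix(["CAT"])

    def test_cap_selects_top_by_count_ties_lexicographic(self):
        seqs = [f"PEPTIDE{i:03d}" for i in range(500)]
        counts = [5] * 250 + [1] * 250
        top = select_top_sequences(seqs, counts, 200)
        assert len(top) == 200
        assert top == sorted(seqs[:250])[:200]
        mat = ld_matrix(seqs, counts=counts, top_n=200)
        assert mat.values.shape == (200, 200)

    def test_symmetric_zero_diagonal(self):
        mat = ld_matrix(["CARDY", "CARGY", "WWWWW"])
        assert (mat.values == mat.values.T).all()
        assert (np.diag(mat.values) == 0).all()


class TestDendrogram:
    def test_two_sequences_merge_at_their_distance(self):
        link = dendrogram(ld_matrix(["CAT", "BAD"]))
        assert link.shape == (1, 4)
        assert link[0, 2] == 2.0

    def test_collinear_average_linkage_heights(self):
        # LD(a,b)=1, LD(b,c)=1, LD(a,c)=2: merge (a,b) at 1, then c at 1.5
        mat = ld_matrix(["CAT", "CATS", "CATSS"])
        link = dendrogram(mat, method="average")
        assert link[0, 2] == pytest.approx(1.0)
        assert link[1, 2] == pytest.approx(1.5)

    def test_identical_sequences_merge_at_zero(self):
        # ld_matrix pools duplicates, so craft an explicit zero-distance pair
        from repseq.cluster_embed import DistanceMatrix
        dm = DistanceMatrix(["A1", "A2", "B"],
                            np.array([[0, 0, 3], [0, 0, 3], [3, 3, 0]]))
        link = dendrogram(dm)
        assert link[0, 2] == 0.0

    def test_newick_round_trips_leaf_names(self):
        mat = ld_matrix(["CAT", "CATS", "DOG", "DOGGY"])
        newick = to_newick(dendrogram(mat), mat.sequences)
        assert newick.endswith(";")
        for leaf in mat.sequences:
            assert leaf in newick


class TestLDGraph:
    def test_cutoff_one_components(self):
        g = ld_graph(["CAT", "CATS", "DOG"], cutoff=1)
        assert set(g.edges) == {("CAT", "CATS")}
        comps = {g.nodes[s]["component"] for s in g}
        assert len(comps) == 2

    def test_large_cutoff_single_component(self):
        g = ld_graph(["CAT", "CATS", "DOG"], cutoff=10)
        assert g.number_of_edges() == 3
        assert len({g.nodes[s]["component"] for s in g}) == 1

    def test_distant_set_edgeless(self):
        seqs = ["AAAAAAA", "WWWWWWW", "CCCCCCC"]
        g = ld_graph(seqs, cutoff=1)
        assert g.number_of_edges() == 0
        assert len({g.nodes[s]["component"] for s in g}) == 3

    def test_cutoff_below_one_rejected(self):
        with pytest.raises(RepertoireError):
            ld_graph(["CAT", "CATS"], cutoff=0)

    @given(st.lists(st.text(alphabet="ACD", min_size=1, max_size=5),
                    min_size=2, max_size=12, unique=True),
           st.integers(1, 4))
    def test_components_nest_as_cutoff_grows(self, seqs, cutoff):
        g1 = ld_graph(seqs, cutoff=cutoff)
        g2 = ld_graph(seqs, cutoff=cutoff + 1)
        for s in seqs:
            for t in seqs:
                if g1.nodes[s]["component"] == g1.nodes[t]["component"]:
                    assert g2.nodes[s]["component"] == g2.nodes[t]["component"]

    def test_node_attributes_carry_metadata(self):
        g = ld_graph(["CAT", "CATS"], cutoff=1, samples=["r0", "r1"],
                     counts=[5, 3], binding={"CAT": 0.9})
        assert g.nodes["CAT"] == {"sample": "r0", "count": 5, "binding": 0.9,
                                  "component": 0}


class TestSGT:
    def test_ab_hand_example(self):
        v = sgt_embed(["AB"], kappa=1.0, alphabet=("A", "B"))
        expected = np.zeros(4)
        expected[1] = math.exp(-1)  # feature (A, B)
        np.testing.assert_allclose(v[0], expected, atol=1e-12)

    def test_identical_sequences_identical_vectors(self):
        v = sgt_embed(["CARDY", "CARDY"])
        np.testing.assert_array_equal(v[0], v[1])

    def test_single_symbol_sequence_only_self_pair(self):
        v = sgt_embed(["AAAA"], alphabet=("A", "B"))
        assert v[0][0] > 0          # (A, A)
        assert (v[0][1:] == 0).all()

    def test_feature_zero_iff_pair_never_in_order(self):
        v = sgt_embed(["BA"], alphabet=("A", "B"))
        # A never precedes B in "BA": (A,B)=0 but (B,A)>0
        assert v[0][1] == 0.0
        assert v[0][2] > 0.0

    def test_doubling_kappa_never_raises_single_adjacent_pair_feature(self):
        for kappa in (0.5, 1.0, 2.0):
            a = sgt_embed(["AB"], kappa=kappa, alphabet=("A", "B"))[0][1]
            b = sgt_embed(["AB"], kappa=2 * kappa, alphabet=("A", "B"))[0][1]
            assert b <= a + 1e-12

    def test_dimension_is_alphabet_squared(self):
        v = sgt_embed(["CARDY", "W"])
        assert v.shape == (2, 400)

    def test_symbols_outside_alphabet_dropped(self):
        clean = sgt_embed(["CA*RDY"])
        ref = sgt_embed(["CARDY"])
        np.testing.assert_array_equal(clean, ref)

    def test_nonpositive_kappa_rejected(self):
        with pytest.raises(RepertoireError):
            sgt_embed(["AB"], kappa=0.0)


class TestReduceTo2D:
    def vectors(self, n, dim=20, seed=0):
        return np.random.default_rng(seed).normal(size=(n, dim))

    def test_fewer_than_four_points_errors(self):
        with pytest.raises(RepertoireError):
            reduce_to_2d(self.vectors(3))

    def test_fixed_seed_deterministic(self):
        v = self.vectors(30)
        a = reduce_to_2d(v, perplexity=5, seed=42)
        b = reduce_to_2d(v, perplexity=5, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_duplicate_vectors_land_near_coincident(self):
        v = self.vectors(40)
        v[7] = v[3]
        coords = reduce_to_2d(v, perplexity=5, seed=1)
        d_dup = np.linalg.norm(coords[7] - coords[3])
        dists = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        threshold = np.percentile(dists[np.triu_indices(40, 1)], 1)
        assert d_dup <= threshold

    def test_oversized_perplexity_is_lowered(self):
        coords = reduce_to_2d(self.vectors(10), perplexity=30, seed=0)
        assert coords.shape == (10, 2)


class TestBindingIntegration:
    def binding(self, rows):
        return BindingTable(pd.DataFrame(rows).set_index("aa_seq"))

    def test_overlay_marks_missing(self):
        points = pd.DataFrame({"aa_seq": [f"PEP{i}" for i in range(10)],
                               "x": 0.0, "y": 0.0})
        table = self.binding([{"aa_seq": f"PEP{i}", "tnf": 0.5} for i in range(3)])
        annotated, unmatched = overlay_binding(points, table, "tnf")
        assert annotated["binding"].notna().sum() == 3
        assert annotated["binding"].isna().sum() == 7
        assert unmatched == []

    def test_overlay_reports_unmatched_not_error(self):
        points = pd.DataFrame({"aa_seq": ["PEP0"], "x": 0.0, "y": 0.0})
        table = self.binding([{"aa_seq": "PEP0", "tnf": 1.0},
                              {"aa_seq": "GONE", "tnf": 2.0}])
        _, unmatched = overlay_binding(points, table, "tnf")
        assert unmatched == ["GONE"]

    def test_unknown_antigen_errors(self):
        table = self.binding([{"aa_seq": "PEP0", "tnf": 1.0}])
        with pytest.raises(KeyError):
            overlay_binding(pd.DataFrame({"aa_seq": ["PEP0"]}), table, "il6")

    def test_cats_candidate_from_labeled_cat(self):
        table = self.binding([{"aa_seq": "CAT", "tnf": 0.9}])
        out = nearest_labeled_neighbors(["CAT", "CATS"], table, "tnf",
                                        ld_cutoff=1, min_binding=0.5)
        assert out.to_dict("records") == [
            {"aa_seq": "CATS", "neighbor": "CAT", "ld": 1,
             "neighbor_binding": 0.9}]

    def test_cutoff_zero_only_exact_duplicates(self):
        table = self.binding([{"aa_seq": "CAT", "tnf": 0.9}])
        out = nearest_labeled_neighbors(["CATS", "DOG"], table, "tnf",
                                        ld_cutoff=0, min_binding=0.0)
        assert out.empty

    def test_all_sequences_labeled_gives_empty_list(self):
        table = self.binding([{"aa_seq": "CAT", "tnf": 0.9},
                              {"aa_seq": "CATS", "tnf": 0.2}])
        out = nearest_labeled_neighbors(["CAT", "CATS"], table, "tnf",
                                        ld_cutoff=2, min_binding=0.1)
        assert out.empty

    def test_no_qualifying_binder_errors(self):
        table = self.binding([{"aa_seq": "CAT", "tnf": 0.1}])
        with pytest.raises(RepertoireError):
            nearest_labeled_neighbors(["CATS"], table, "tnf", min_binding=0.5)

    def test_sorted_by_ld_then_binding(self):
        table = self.binding([{"aa_seq": "AAAA", "tnf": 0.6},
                              {"aa_seq": "CCCC", "tnf": 0.9}])
        out = nearest_labeled_neighbors(["AAAT", "CCCG", "AATT"], table, "tnf",
                                        ld_cutoff=2, min_binding=0.5)
        assert out["ld"].is_monotonic_increasing
        first_lds = out[out["ld"] == 1]
        assert first_lds["neighbor_binding"].is_monotonic_decreasing
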