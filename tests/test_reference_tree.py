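"""Alignment, conservation filter, JC distances, NJ and query insertion."""

import numpy as np
import pandas as pd
import pytest

from metataxa import _seq
from metataxa.reads_to_otus import _ALIGNER
from metataxa.reference_tree import (
    AlignedMatrix,
    SaturationError,
    _merge_profiles,
    align_profiles,
    conservation_mask,
    distance_matrix,
    jc_distance,
    nj_tree,
    parsimony_insert,
    place_queries,
    remove_query,
)

from oracles import additive_distances, random_additive_tree


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _substituted(rng, s, k):
    pos = rng.choice(len(s), size=k, replace=False)
    out = list(s)
    for p in pos:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


class TestAlignProfiles:
    def test_identical_references_have_no_gap_columns(self):
        aln = align_profiles({"a": "ACGTACGT", "b": "ACGTACGT"},
                             assume_collinear=False)
        assert not (aln.data == ord("-")).any()

    def test_query_equal_to_reference_reproduces_its_row(self, rng):
        refs = {"a": _random_seq(rng, 60)}
        refs["b"] = _substituted(rng, refs["a"], 6)
        aln = align_profiles(refs, {"q": refs["a"]}, assume_collinear=False)
        assert np.array_equal(aln.row("q"), aln.row("a"))

    def test_pairwise_merge_is_score_optimal(self, rng):
        # a progressive alignment of two sequences is the pairwise optimum;
        # its score must match the affine aligner's
        for _ in range(15):
            a = _random_seq(rng, int(rng.integers(20, 61)))
            b = _random_seq(rng, int(rng.integers(20, 61)))
            mA, mB = _merge_profiles(
                _seq.encode(a).reshape(1, -1), _seq.encode(b).reshape(1, -1)
            )
            score = 0.0
            open_run = None
            for ca, cb in zip(mA[0], mB[0]):
                if ca == ord("-") or cb == ord("-"):
                    side = 0 if ca == ord("-") else 1
                    score += -1.0 if open_run == side else -2.0
                    open_run = side
                else:
                    score += 1.0 if ca == cb else -1.0
                    open_run = None
            assert score == pytest.approx(_ALIGNER.score(a, b), abs=1e-6)

    def test_collinear_fast_path_matches_dp(self, rng):
        base = _random_seq(rng, 80)
        refs = {f"r{i}": _substituted(rng, base, 6) for i in range(4)}
        a1 = align_profiles(refs, assume_collinear=True)
        a2 = align_profiles(refs, assume_collinear=False)
        assert np.array_equal(a1.data, a2.data)

    def test_rejects_ambiguous_bases(self):
        with pytest.raises(ValueError):
            align_profiles({"a": "ACGN", "b": "ACGT"})


class TestConservationMask:
    def _aln(self, rows):
        data = np.array([[ord(c) for c in row] for row in rows], dtype=np.uint8)
        ids = [f"s{i}" for i in range(data.shape[0])]
        return AlignedMatrix(ids, data, np.ones(data.shape[1], bool), data.shape[0])

    def test_fully_conserved_column_kept(self):
        aln = self._aln(["AAAA", "AAAA"])
        out = conservation_mask(aln)
        assert out.mask.all()

    def test_maximally_diverse_column_dropped(self):
        aln = self._aln(["AA", "CA", "GA", "TA"])  # col0 = A/C/G/T, col1 = AAAA
        out = conservation_mask(aln, 0.30)
        assert out.mask.tolist() == [False, True]

    def test_zero_threshold_keeps_non_gappy_columns(self):
        aln = self._aln(["AA", "CA", "GA", "TA"])
        out = conservation_mask(aln, 0.0)
        assert out.mask.all()

    def test_gappy_column_dropped(self):
        aln = self._aln(["A-", "A-", "A-", "AA"])
        out = conservation_mask(aln, 0.30)
        assert out.mask.tolist() == [True, False]

    def test_all_masked_is_an_error(self):
        aln = self._aln(["A", "C", "G", "T"])
        with pytest.raises(ValueError):
            conservation_mask(aln, 0.9)


class TestJukesCantor:
    def test_closed_forms(self):
        assert jc_distance(0.0) == 0.0
        assert jc_distance(0.1) == pytest.approx(0.107326, abs=1e-6)
        assert jc_distance(0.3) == pytest.approx(0.383120, abs=1e-6)

    def test_saturation_rejected(self):
        with pytest.raises(SaturationError):
            jc_distance(0.75)

    def test_distance_matrix_uses_masked_columns_only(self):
        data = np.array(
            [[ord(c) for c in "AAAAT"], [ord(c) for c in "AAAAA"]], dtype=np.uint8
        )
        aln = AlignedMatrix(["a", "b"], data, np.array([1, 1, 1, 1, 0], bool), 2)
        D = distance_matrix(aln)
        assert D.loc["a", "b"] == 0.0  # mismatch sits in the masked column


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_exact(self):
        # tree: ((A:2,B:3):1,(C:4,D:5)) with internal edge 1
        ids = list("ABCD")
        D = pd.DataFrame(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]],
            index=ids, columns=ids, dtype=float,
        )
        tree = nj_tree(D, outgroup_id="A")
        tips = {t.name: t for t in tree.tips()}
        # path lengths reproduce the additive input
        for i in ids:
            for j in ids:
                if i != j:
                    d = tips[i].distance(tips[j])
                    assert d == pytest.approx(D.loc[i, j], abs=1e-9)
        # topology: (A,B) vs (C,D) bipartition present
        for node in tree.non_tips():
            names = frozenset(l for l in node.subset())
            assert names not in ({"A", "C"}, {"A", "D"})

    def test_three_taxa_closed_form(self):
        ids = list("ABC")
        D = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], index=ids, columns=ids, dtype=float
        )
        tree = nj_tree(D, outgroup_id="C")
        tips = {t.name: t for t in tree.tips()}
        assert tips["A"].distance(tips["B"]) == pytest.approx(3.0, abs=1e-9)
        assert tips["A"].distance(tips["C"]) == pytest.approx(4.0, abs=1e-9)
        assert tips["B"].distance(tips["C"]) == pytest.approx(5.0, abs=1e-9)

    def test_random_additive_matrices_reconstructed(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            tree, names = random_additive_tree(rng, n)
            D = pd.DataFrame(additive_distances(tree, names), index=names, columns=names)
            out = nj_tree(D, outgroup_id=names[0])
            tips = {t.name: t for t in out.tips()}
            for i in names:
                for j in names:
                    if i != j:
                        assert tips[i].distance(tips[j]) == pytest.approx(
                            D.loc[i, j], abs=1e-9
                        )

    def test_agrees_with_skbio_nj_on_additive_input(self, rng):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        tree, names = random_additive_tree(rng, 7)
        D = additive_distances(tree, names)
        ours = nj_tree(pd.DataFrame(D, index=names, columns=names), outgroup_id=names[0])
        ref = skbio_nj(DistanceMatrix(D, ids=names))
        t1 = {t.name: t for t in ours.tips()}
        t2 = {t.name: t for t in ref.tips()}
        for i in names:
            for j in names:
                if i != j:
                    assert t1[i].distance(t1[j]) == pytest.approx(
                        t2[i].distance(t2[j]), abs=1e-8
                    )

    def test_invalid_matrices_rejected(self):
        ids = list("ABC")
        bad = pd.DataFrame(np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float),
                           index=ids, columns=ids)
        with pytest.raises(ValueError):
            nj_tree(bad, outgroup_id="A")
        nan = pd.DataFrame(np.full((3, 3), np.nan), index=ids, columns=ids)
        with pytest.raises(ValueError):
            nj_tree(nan, outgroup_id="A")


class TestInsertion:
    def _tree_and_dists(self, rng, n):
        tree, names = random_additive_tree(rng, n)
        D = pd.DataFrame(additive_distances(tree, names), index=names, columns=names)
        return nj_tree(D, outgroup_id=names[0]), D, names

    def test_query_identical_to_leaf_attaches_at_zero_length(self, rng):
        tree, D, names = self._tree_and_dists(rng, 6)
        target = names[2]
        dq = {l: D.loc[target, l] for l in names}
        parsimony_insert(tree, "QUERY", dq)
        q = tree.find("QUERY")
        assert q.length == pytest.approx(0.0, abs=1e-9)
        sibs = {t.name for t in q.parent.tips()} - {"QUERY"}
        assert target in sibs

    def test_equidistant_query_lands_in_the_cherry(self):
        ids = list("ABCD")
        D = pd.DataFrame(
            [[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 2], [8, 8, 2, 0]],
            index=ids, columns=ids, dtype=float,
        )
        tree = nj_tree(D, outgroup_id="D")
        dq = {"A": 1.5, "B": 1.5, "C": 8.5, "D": 8.5}
        parsimony_insert(tree, "Q", dq)
        q = tree.find("Q")
        anc = {t.name for t in q.parent.parent.tips()}
        assert {"A", "B", "Q"} <= anc and "C" not in anc or \
               {t.name for t in q.parent.tips()} <= {"A", "B", "Q"}

    def test_insertion_matches_full_nj_on_additive_data(self, rng):
        agree = 0
        trials = 50
        for _ in range(trials):
            n = int(rng.integers(6, 11))
            tree, names = random_additive_tree(rng, n)
            D = pd.DataFrame(additive_distances(tree, names), index=names, columns=names)
            query = names[-1]
            rest = names[:-1]
            base = nj_tree(D.loc[rest, rest], outgroup_id=rest[0])
            parsimony_insert(base, query, D.loc[query].to_dict())
            full = nj_tree(D, outgroup_id=rest[0])
            s1 = frozenset(
                t.name for t in base.find(query).parent.tips()) - {query}
            s2 = frozenset(
                t.name for t in full.find(query).parent.tips()) - {query}
            others = frozenset(rest)
            norm = lambda s: min(s, others - s, key=lambda x: (len(x), sorted(x)))
            agree += norm(s1) == norm(s2)
        assert agree / trials >= 0.9

    def test_insert_then_delete_restores_newick(self, rng):
        tree, D, names = self._tree_and_dists(rng, 7)
        before = str(tree)
        dq = {l: D.loc[names[3], l] + 0.123 for l in names}
        parsimony_insert(tree, "Q", dq)
        assert "Q" in {t.name for t in tree.tips()}
        remove_query(tree, "Q")
        assert str(tree) == before

    def test_place_queries_inserts_in_order(self, rng):
        tree, D, names = self._tree_and_dists(rng, 6)
        Dq = D.copy()
        for q in ("Q1", "Q2"):
            Dq.loc[q] = 0.0
            Dq[q] = 0.0
            for l in names:
                Dq.loc[q, l] = Dq.loc[l, q] = D.loc[names[1], l] + 0.2
        Dq.loc["Q1", "Q2"] = Dq.loc["Q2", "Q1"] = 0.05
        place_queries(tree, Dq, ["Q1", "Q2"])
        assert {"Q1", "Q2"} <= {t.name for t in tree.tips()}
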