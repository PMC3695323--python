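"""Alignment statistics, 80-80-80 clustering, K2P and Neighbor-Joining."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stowaway_kit.families import (ClusterParams, DistanceMatrix,
                                   SaturationError, TreeNode, build_consensus,
                                   cluster_families, global_align,
                                   k2p_distance, k2p_matrix,
                                   mean_pairwise_identity, msa_column_identity,
                                   neighbor_joining, parse_newick,
                                   tir_consensus)
from stowaway_kit.synthetic import FamilySpec, generate_family

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = global_align("ACGTACGT", "ACGTACGT")
        assert aln.identity == 1.0 and aln.P == 0.0 and aln.Q == 0.0
        assert aln.coverage == 1.0

    def test_single_transversion(self):
        aln = global_align("ACGT", "ACGA")  # T<->A at the last column
        assert aln.identity == 0.75
        assert aln.Q == 0.25 and aln.P == 0.0

    def test_single_transition(self):
        aln = global_align("ACGT", "ACAT")  # G<->A transition
        assert aln.P == 0.25 and aln.Q == 0.0

    def test_score_matches_independent_dp_oracle(self, rng):
        # plain (non-affine-decomposed) quadratic-space DP with the same
        # gap convention: open -4 for the first gap base, -1 afterwards
        from Bio import Align
        oracle = Align.PairwiseAligner(mode="global", match_score=1,
                                       mismatch_score=-1, open_gap_score=-4,
                                       extend_gap_score=-1)
        for _ in range(50):
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(5, 200)))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(5, 200)))
            assert global_align(a, b).score == pytest.approx(oracle.score(a, b))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    @given(a=dna, b=dna)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_proportions_are_probabilities(self, a, b):
        aln = global_align(a, b)
        assert 0 <= aln.identity <= 1
        assert 0 <= aln.coverage <= 1
        assert 0 <= aln.P + aln.Q <= 1
        assert aln.identity + aln.P + aln.Q == pytest.approx(1.0) \
            or aln.coverage == 0


class TestK2P:
    def test_zero_distance(self):
        assert k2p_distance((0.0, 0.0)) == 0.0

    def test_closed_form_value(self):
        # independent arithmetic: -0.5*ln((1-0.2-0.05)*sqrt(1-0.1))
        expected = -0.5 * math.log(0.75 * math.sqrt(0.9))
        assert k2p_distance((0.1, 0.05)) == pytest.approx(expected, abs=1e-12)
        assert k2p_distance((0.1, 0.05)) == pytest.approx(0.17018, abs=1e-5)

    @pytest.mark.parametrize("P,Q", [(0.5, 0.0), (0.48, 0.05), (0.0, 0.5)])
    def test_saturation_raises_not_nan(self, P, Q):
        with pytest.raises(SaturationError):
            k2p_distance((P, Q))

    def test_symmetric_in_sequences(self):
        a, b = "ACGTTGCAACGT", "ACATTGCGACGA"
        assert k2p_distance(global_align(a, b)) == pytest.approx(
            k2p_distance(global_align(b, a)))

    def test_monotone_in_P_and_Q(self):
        base = k2p_distance((0.1, 0.1))
        assert k2p_distance((0.15, 0.1)) > base
        assert k2p_distance((0.1, 0.15)) > base


class TestClustering:
    def test_singleton(self):
        fams = cluster_families([("only", "ACGT" * 30)])
        assert len(fams) == 1 and fams[0].member_ids == ["only"]

    def test_triplet_matches_bruteforce_components(self):
        a = ("A", "ACGTTTGCAACGGT" * 8)
        b = ("B", a[1][:40] + "TTTT" + a[1][44:])  # ~96 % identical to A
        c = ("C", "TTGACACAGTCGCA" * 8)
        elements = [a, b, c]
        fams = cluster_families(elements)
        # brute force: compute relation over all pairs, take components
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(["A", "B", "C"])
        from stowaway_kit.families import related_8080
        for (i1, s1), (i2, s2) in itertools.combinations(elements, 2):
            if related_8080(s1, s2)[0]:
                g.add_edge(i1, i2)
        oracle = {frozenset(comp) for comp in nx.connected_components(g)}
        mine = {frozenset(f.member_ids) for f in fams}
        assert mine == oracle == {frozenset("AB"), frozenset("C")}

    def test_synthetic_panel_exact_family_recovery(self):
        elements, truth = [], {}
        for f in range(3):
            spec = FamilySpec(f"fam{f}", divergence=0.05, indel_rate=0.002,
                              at_fraction=0.65)
            _, copies = generate_family(spec, 5, seed=200 + f)
            for c in copies:
                elements.append((c.copy_id, c.seq))
                truth[c.copy_id] = c.family_id
        fams = cluster_families(elements)
        assert len(fams) == 3
        for fam in fams:
            assert len({truth[m] for m in fam.member_ids}) == 1

    def test_partition_and_permutation_invariance(self, rng):
        elements = []
        for f in range(3):
            spec = FamilySpec(f"fam{f}", divergence=0.05, at_fraction=0.65)
            _, copies = generate_family(spec, 4, seed=210 + f)
            elements.extend((c.copy_id, c.seq) for c in copies)
        ref = cluster_families(elements)
        all_members = sorted(m for f in ref for m in f.member_ids)
        assert all_members == sorted(e[0] for e in elements)  # exhaustive
        assert len(set(all_members)) == len(all_members)      # disjoint
        perm = [elements[i] for i in rng.permutation(len(elements))]
        shuffled = cluster_families(perm)
        assert [set(f.member_ids) for f in ref] == \
               [set(f.member_ids) for f in shuffled]

    def test_short_elements_dropped(self):
        fams = cluster_families([("long", "ACGT" * 30), ("short", "ACGTACG")])
        assert [f.member_ids for f in fams] == [["long"]]

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            cluster_families([])


class TestConsensus:
    def test_single_member_verbatim(self):
        assert build_consensus(["ACGTACGT"]) == "ACGTACGT"

    def test_tie_becomes_iupac(self):
        # column with T:3 / C:3 -> Y
        members = ["ACT", "ACT", "ACT", "ACC", "ACC", "ACC"]
        assert build_consensus(members) == "ACY"

    def test_recovers_known_consensus(self):
        spec = FamilySpec("f", divergence=0.05, indel_rate=0.002,
                          at_fraction=0.65)
        consensus, copies = generate_family(spec, 10, seed=220)
        rebuilt = build_consensus([c.seq for c in copies])
        assert global_align(consensus, rebuilt).identity >= 0.99

    def test_both_similarity_statistics_defined(self):
        spec = FamilySpec("f", divergence=0.07, at_fraction=0.65)
        _, copies = generate_family(spec, 6, seed=221)
        seqs = [c.seq for c in copies]
        assert 0.7 < mean_pairwise_identity(seqs) < 1.0
        assert 0.7 < msa_column_identity(seqs) <= 1.0


def _random_additive_tree(n_leaves, rng):
    nodes = [TreeNode(name=f"L{i}", length=float(rng.uniform(0.05, 1.0)))
             for i in range(n_leaves)]
    while len(nodes) > 2:
        j = int(rng.integers(1, len(nodes)))
        i = int(rng.integers(0, j))
        b, a = nodes.pop(j), nodes.pop(i)
        nodes.append(TreeNode(length=float(rng.uniform(0.05, 1.0)),
                              children=[a, b]))
    return TreeNode(children=nodes)


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        t = neighbor_joining(DistanceMatrix(["A", "B"],
                                            np.array([[0, 0.3], [0.3, 0]])))
        assert t.leaf_distances()[frozenset(("A", "B"))] == pytest.approx(0.3)

    def test_three_taxa_closed_form(self):
        m = np.array([[0, 0.3, 0.5], [0.3, 0, 0.4], [0.5, 0.4, 0]])
        t = neighbor_joining(DistanceMatrix(["A", "B", "C"], m))
        d = t.leaf_distances()
        # branch to A = (d_AB + d_AC - d_BC)/2 = 0.2; to B = 0.1; to C = 0.3
        assert d[frozenset(("A", "B"))] == pytest.approx(0.3)
        assert d[frozenset(("A", "C"))] == pytest.approx(0.5)
        assert d[frozenset(("B", "C"))] == pytest.approx(0.4)

    @pytest.mark.parametrize("n_leaves", [5, 6, 8, 10])
    def test_additive_matrix_recovered_exactly(self, n_leaves, rng):
        tree = _random_additive_tree(n_leaves, rng)
        truth = tree.leaf_distances()
        labels = sorted(l.name for l in tree.leaves())
        m = np.zeros((n_leaves, n_leaves))
        for i, j in itertools.combinations(range(n_leaves), 2):
            m[i, j] = m[j, i] = truth[frozenset((labels[i], labels[j]))]
        rebuilt = neighbor_joining(DistanceMatrix(labels, m))
        recovered = rebuilt.leaf_distances()
        for key, value in truth.items():
            assert recovered[key] == pytest.approx(value, abs=1e-9)

    def test_branch_lengths_nonnegative(self, rng):
        # noisy (non-additive) matrices must still produce valid trees
        for trial in range(5):
            n = 6
            base = rng.uniform(0.1, 1.0, size=(n, n))
            m = (base + base.T) / 2
            np.fill_diagonal(m, 0.0)
            t = neighbor_joining(DistanceMatrix([f"T{i}" for i in range(n)], m))

            def lengths(node):
                yield node.length
                for c in node.children:
                    yield from lengths(c)

            assert all(l >= 0 for l in lengths(t))

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], m)

    def test_newick_serialize_parse_idempotent(self, rng):
        tree = _random_additive_tree(7, rng)
        labels = sorted(l.name for l in tree.leaves())
        truth = tree.leaf_distances()
        m = np.zeros((7, 7))
        for i, j in itertools.combinations(range(7), 2):
            m[i, j] = m[j, i] = truth[frozenset((labels[i], labels[j]))]
        nj = neighbor_joining(DistanceMatrix(labels, m))
        s1 = nj.to_newick()
        s2 = parse_newick(s1).to_newick()
        assert s1 == s2

    def test_k2p_nj_end_to_end_on_family_consensi(self):
        consensi = []
        for f in range(4):
            spec = FamilySpec(f"f{f}", divergence=0.0, at_fraction=0.65)
            consensi.append((f"f{f}", generate_family(spec, 1, 230 + f)[0]))
        dm = k2p_matrix(consensi)
        assert (dm.matrix >= 0).all()
        tree = neighbor_joining(dm)
        assert sorted(l.name for l in tree.leaves()) == [c[0] for c in consensi]


class TestTIRConsensus:
    def test_identical_tirs(self):
        tc = tir_consensus([("F1", "CTCCCTAGGA"), ("F2", "CTCCCTAGGA")])
        assert tc.consensus == "CTCCCTAGGA"
        assert tc.conserved_terminal_run == 10

    def test_degenerate_columns(self):
        tc = tir_consensus([("F1", "CTCCCTA"), ("F2", "CTCCCTG")])
        assert tc.consensus == "CTCCCTR"  # {A,G} -> R
        assert tc.conserved_terminal_run == 6

    def test_planted_motif_gives_conserved_run(self):
        entries = []
        for f in range(4):
            spec = FamilySpec(f"f{f}", at_fraction=0.65)
            cons, _ = generate_family(spec, 1, seed=240 + f)
            entries.append((f"f{f}", cons[:16]))
        tc = tir_consensus(entries)
        assert tc.conserved_terminal_run >= 6

    def test_missing_tir_rejected(self):
        with pytest.raises(ValueError):
            tir_consensus([("F1", "")])
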