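"""Alignment handling, distances, neighbor joining, bootstrap, rooting."""

import math

import numpy as np
import pandas as pd
import pytest

import dendropy

from conftest import path_length_matrix, random_binary_tree, split_set
from ganokit.phylo import (
    Alignment,
    SaturationError,
    SupportTree,
    UndefinedDistanceError,
    bootstrap_support,
    concatenate,
    congruence_report,
    distance_matrix,
    nj_tree,
    pairwise_distance,
    read_alignment,
    root_with_outgroup,
    write_alignment,
)
from ganokit.synthetic import SimulationConfig, evolve_alignment, simulate_alignments, simulate_species_tree


# ---------------------------------------------------------------------- I/O

def test_read_alignment_accepts_equal_length_records(tmp_path):
    path = tmp_path / "a.fasta"
    path.write_text(">t1\nACGT\n>t2\nAC-T\n>t3\nACNT\n")
    aln = read_alignment(path, "toy")
    assert aln.n_columns == 4 and aln.tip_labels == ["t1", "t2", "t3"]


def test_read_alignment_rejects_ragged_duplicate_empty(tmp_path):
    ragged = tmp_path / "r.fasta"
    ragged.write_text(">t1\nACGT\n>t2\nAC\n")
    with pytest.raises(ValueError, match="ragged"):
        read_alignment(ragged, "r")
    dup = tmp_path / "d.fasta"
    dup.write_text(">t1\nAC\n>t1\nGT\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_alignment(dup, "d")
    empty = tmp_path / "e.fasta"
    empty.write_text("")
    with pytest.raises(ValueError, match="no FASTA"):
        read_alignment(empty, "e")


def test_fasta_roundtrip_byte_identical(tmp_path):
    truth = simulate_species_tree(SimulationConfig(seed=9, n_species=5, tips_per_species=(1, 3)))
    aln = evolve_alignment(truth.tree, 200, seed=9, locus_name="ITS")
    p1, p2 = tmp_path / "one.fasta", tmp_path / "two.fasta"
    write_alignment(aln, p1)
    write_alignment(read_alignment(p1, "ITS"), p2)
    assert p1.read_bytes() == p2.read_bytes()


# -------------------------------------------------------------- supermatrix

def test_concatenate_four_loci_gives_2470_columns():
    seqs = lambda L: {"t1": "A" * L, "t2": "C" * L}
    sm = concatenate([
        Alignment("ITS", seqs(521)), Alignment("tef1a", seqs(764)),
        Alignment("rpb1", seqs(615)), Alignment("rpb2", seqs(570)),
    ])
    assert sm.alignment.n_columns == 2470
    assert sm.partitions == [("ITS", 1, 521), ("tef1a", 522, 1285),
                             ("rpb1", 1286, 1900), ("rpb2", 1901, 2470)]
    assert "DNA, ITS = 1-521" in sm.partition_table()


def test_concatenate_single_alignment_is_identity():
    aln = Alignment("ITS", {"t1": "ACGT", "t2": "AGGT"})
    sm = concatenate([aln])
    assert sm.alignment.sequences == aln.sequences
    assert sm.partitions == [("ITS", 1, 4)]
    with pytest.raises(ValueError):
        concatenate([])


def test_missing_taxon_padded_with_question_marks():
    sm = concatenate([
        Alignment("L1", {"t1": "ACGT", "t2": "AGGT"}),
        Alignment("L2", {"t1": "CC"}),
    ])
    assert sm.alignment.sequences["t2"] == "AGGT" + "??"


def test_supermatrix_slices_back_to_inputs():
    truth = simulate_species_tree(SimulationConfig(seed=4, n_species=5, tips_per_species=(1, 2)))
    alignments = simulate_alignments(truth)
    sm = concatenate(list(alignments.values()))
    for name, aln in alignments.items():
        extracted = sm.extract(name)
        for taxon in aln.sequences:
            assert extracted.sequences[taxon] == aln.sequences[taxon]


# ---------------------------------------------------------------- distances

def test_identical_sequences_have_zero_distance():
    for model in ("p", "jc69", "k2p"):
        assert pairwise_distance("ACGTACGT", "ACGTACGT", model) == 0.0


def test_jc69_closed_form_at_p_03():
    # 30 mismatches in 100 comparable columns
    a = "A" * 100
    b = "A" * 70 + "G" * 30
    assert pairwise_distance(a, b, "p") == pytest.approx(0.3)
    assert pairwise_distance(a, b, "jc69") == pytest.approx(-0.75 * math.log(0.6), abs=5e-5)
    assert round(pairwise_distance(a, b, "jc69"), 4) == 0.3831


def test_k2p_closed_form():
    # 100 columns: 10 transitions (A<->G), 5 transversions (A<->C)
    a = "A" * 100
    b = "G" * 10 + "C" * 5 + "A" * 85
    P, Q = 0.10, 0.05
    expected = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
    assert pairwise_distance(a, b, "k2p") == pytest.approx(expected)


def test_pairwise_deletion_ignores_gaps_and_ambiguity():
    assert pairwise_distance("ACGT-N?A", "ACGATNTA", "p") == pytest.approx(1 / 5)


def test_no_comparable_columns_and_saturation_errors():
    with pytest.raises(UndefinedDistanceError):
        pairwise_distance("----", "ACGT", "p")
    a, b = "A" * 100, "G" * 80 + "A" * 20  # p = 0.8 >= 3/4
    with pytest.raises(SaturationError):
        pairwise_distance(a, b, "jc69")


def test_jc69_monotone_in_p_and_linear_near_zero():
    ps = np.linspace(0.0, 0.74, 30)
    d = -0.75 * np.log1p(-4 * ps / 3)
    assert np.all(np.diff(d) > 0)
    p = 1e-4
    assert -0.75 * math.log1p(-4 * p / 3) == pytest.approx(p, rel=1e-3)


# --------------------------------------------------------- neighbor joining

def test_three_taxon_tree_uses_three_point_formulas():
    D = pd.DataFrame(
        [[0, 3, 4], [3, 0, 5], [4, 5, 0]], index=list("ABC"), columns=list("ABC"), dtype=float)
    tree = nj_tree(D)
    lengths = {leaf.taxon.label: leaf.edge.length for leaf in tree.tree.leaf_node_iter()}
    assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}


def test_nj_input_validation():
    bad = pd.DataFrame([[0, 1], [1, 0]], index=list("AB"), columns=list("AB"), dtype=float)
    with pytest.raises(ValueError, match="at least 3"):
        nj_tree(bad)
    asym = pd.DataFrame(
        [[0, 1, 2], [9, 0, 1], [2, 1, 0]], index=list("ABC"), columns=list("ABC"), dtype=float)
    with pytest.raises(ValueError, match="symmetric"):
        nj_tree(asym)


def test_nj_recovers_five_taxon_additive_tree_exactly():
    rng = np.random.default_rng(17)
    true = random_binary_tree(5, rng)
    inferred = nj_tree(path_length_matrix(true))
    assert split_set(inferred.tree) == split_set(true)
    # branch lengths are recovered too: patristic distances match
    assert np.allclose(path_length_matrix(inferred.tree).values,
                       path_length_matrix(true).values)


def test_nj_ties_broken_by_lexicographic_label_pair():
    # perfectly symmetric 4-taxon matrix: every Q is tied
    D = pd.DataFrame(np.ones((4, 4)) - np.eye(4), index=list("dcba"), columns=list("dcba"))
    tree = nj_tree(D)
    assert split_set(tree.tree) == {frozenset({"c", "d"})}  # {a,b}|{c,d}, joined via (a,b)


def test_nj_agrees_with_dendropy_reference_on_additive_matrices():
    # independent implementation as oracle on clean (additive) inputs
    rng = np.random.default_rng(5)
    for _ in range(10):
        n = int(rng.integers(4, 11))
        true = random_binary_tree(n, rng)
        D = path_length_matrix(true)
        ours = nj_tree(D)
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_as_csv(D), delimiter=",")
        ref = pdm.nj_tree()
        assert split_set(ours.tree) == split_set(ref)


def _as_csv(D: pd.DataFrame):
    import io
    buf = io.StringIO()
    D.to_csv(buf)
    buf.seek(0)
    return buf


# ----------------------------------------------------------------- bootstrap

@pytest.fixture(scope="module")
def small_truth_and_alignment():
    config = SimulationConfig(seed=11, n_species=6, tips_per_species=(2, 3))
    truth = simulate_species_tree(config)
    aln = evolve_alignment(truth.tree, 1000, seed=12, locus_name="sim")
    return truth, aln


def test_bootstrap_single_rep_gives_0_or_100(small_truth_and_alignment):
    _, aln = small_truth_and_alignment
    tree = bootstrap_support(aln, n_reps=1, model="jc69", seed=3)
    supports = [v for v in tree.bipartitions().values() if v is not None]
    assert supports and all(v in (0.0, 100.0) for v in supports)


def test_bootstrap_reproducible_and_order_invariant(small_truth_and_alignment):
    _, aln = small_truth_and_alignment
    t1 = bootstrap_support(aln, n_reps=20, model="jc69", seed=7)
    t2 = bootstrap_support(aln, n_reps=20, model="jc69", seed=7)
    assert t1.bipartitions() == t2.bipartitions()
    shuffled = Alignment(aln.locus_name,
                         {k: aln.sequences[k] for k in sorted(aln.sequences, reverse=True)})
    t3 = bootstrap_support(shuffled, n_reps=20, model="jc69", seed=7)
    assert t3.bipartitions() == t1.bipartitions()


def test_deeply_separated_clades_get_high_support(small_truth_and_alignment):
    truth, aln = small_truth_and_alignment
    tree = bootstrap_support(aln, n_reps=100, model="jc69", seed=5)
    for species in truth.taxon_map.species:
        tips = truth.taxon_map.tips_of(species)
        if len(tips) < 2:
            continue
        assert tree.has_clade(tips)
        assert tree.clade_support(tips) >= 95


def test_bootstrap_requires_seed_and_columns(small_truth_and_alignment):
    _, aln = small_truth_and_alignment
    with pytest.raises(ValueError):
        bootstrap_support(aln, n_reps=0, seed=1)
    with pytest.raises(ValueError):
        bootstrap_support(aln, n_reps=5, seed=None)


# ------------------------------------------------------------------- rooting

def test_rooting_on_single_tip_outgroup():
    tree = SupportTree.from_newick("((A:1,B:1)90:1,(C:1,D:1)80:1);")
    rooted = root_with_outgroup(tree, {"A"})
    assert rooted.is_rooted
    root_children = rooted.tree.seed_node.child_nodes()
    sides = [frozenset(l.taxon.label for l in c.leaf_iter()) for c in root_children]
    assert frozenset({"A"}) in sides


def test_rooting_preserves_supports_and_ingroup():
    config = SimulationConfig(seed=21, n_species=5, tips_per_species=(2, 2))
    truth = simulate_species_tree(config)
    aln = evolve_alignment(truth.tree, 800, seed=22)
    tree = bootstrap_support(aln, n_reps=20, model="jc69", seed=2)
    before = tree.bipartitions()
    rooted = root_with_outgroup(tree, truth.outgroup_tips)
    assert rooted.is_rooted
    after = rooted.bipartitions()
    for split, support in before.items():
        assert after.get(split) == support
    ingroup = set(tree.tip_labels) - truth.outgroup_tips
    assert rooted.has_clade(ingroup)


def test_rooting_errors():
    tree = SupportTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
    with pytest.raises(ValueError, match="not in tree"):
        root_with_outgroup(tree, {"Z"})
    with pytest.raises(ValueError, match="monophyletic"):
        root_with_outgroup(tree, {"A", "C"})


# ---------------------------------------------------------------- congruence

def test_identical_trees_are_congruent():
    t = SupportTree.from_newick("((A,B)100,(C,D)100,E);")
    assert congruence_report([t, t], support_floor=75) == []


def test_textbook_incompatible_splits_conflict():
    t1 = SupportTree.from_newick("((A,B)100,(C,D)100);")
    t2 = SupportTree.from_newick("((A,C)100,(B,D)100);")
    conflicts = congruence_report([t1, t2], support_floor=75)
    assert len(conflicts) >= 1
    i, j, sa, sb = conflicts[0]
    assert (i, j) == (0, 1)


def test_low_support_conflicts_filtered_by_floor():
    t1 = SupportTree.from_newick("((A,B)40,(C,D)40);")
    t2 = SupportTree.from_newick("((A,C)100,(B,D)100);")
    assert congruence_report([t1, t2], support_floor=75) == []


def test_congruence_requires_shared_taxa():
    t1 = SupportTree.from_newick("((A,B),(C,D));")
    t2 = SupportTree.from_newick("((E,F),(G,H));")
    with pytest.raises(ValueError, match="fewer than 2"):
        congruence_report([t1, t2])


# ---------------------------------------------------------- newick dialects

def test_newick_support_roundtrip_label_and_comment_dialects():
    newick = "((A:1,B:1)97:0.5,(C:1,D:1)64:0.5,E:1);"
    tree = SupportTree.from_newick(newick)
    assert set(tree.bipartitions().values()) == {97.0, 64.0}
    out = tree.to_newick(dialect="comment")
    back = SupportTree.from_newick(out, dialect="comment")
    assert back.bipartitions() == tree.bipartitions()


def test_unlabeled_internal_nodes_have_absent_support():
    tree = SupportTree.from_newick("((A,B),(C,D));")
    assert all(v is None for v in tree.bipartitions().values())
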