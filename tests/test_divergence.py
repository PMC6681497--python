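"""Alignment identity, Poisson distances, neighbor joining, redundancy."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdrscan.divergence import (
    DistanceMatrix,
    PairwiseAlignment,
    SpeciesSeq,
    dedupe_by_identity,
    distance_matrix,
    global_align,
    mean_pairwise_identity,
    nj_tree,
    p_distance,
    pairwise_identity,
    poisson_distance,
    redundancy_filter,
)

DNA = st.text(alphabet="ACGT", min_size=1, max_size=40)


# ---------------------------------------------------------------------------
# global alignment


def test_identical_sequences_align_gapless():
    aln = global_align("ACGTACGT", "ACGTACGT")
    assert aln.a == aln.b == "ACGTACGT"


def test_single_gap_alignment():
    aln = global_align("ACGT", "ACT")
    assert sum(c == "-" for c in aln.a + aln.b) == 1


def test_alphabet_mismatch_rejected():
    with pytest.raises(ValueError):
        global_align("ACGT", "MKVLW")


def _enumerate_global(a, b, match, mismatch, gap_open, gap_extend):
    memo = {}

    def rec(i, j, state):
        if (i, j, state) in memo:
            return memo[i, j, state]
        if i == len(a) and j == len(b):
            return 0.0
        cands = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            cands.append(s + rec(i + 1, j + 1, 0))
        if i < len(a):
            cost = gap_extend if state == 1 else gap_open + gap_extend
            cands.append(-cost + rec(i + 1, j, 1))
        if j < len(b):
            cost = gap_extend if state == 2 else gap_open + gap_extend
            cands.append(-cost + rec(i, j + 1, 2))
        memo[i, j, state] = max(cands)
        return memo[i, j, state]

    return rec(0, 0, 0)


def test_global_align_score_matches_exhaustive_enumeration():
    from Bio.Align import PairwiseAligner

    aligner = PairwiseAligner(
        mode="global", match_score=2, mismatch_score=-3,
        open_gap_score=-7, extend_gap_score=-2,
    )
    rng = np.random.default_rng(3)
    for _ in range(25):
        a = "".join(rng.choice(list("ACGT"), size=rng.integers(2, 9)))
        b = "".join(rng.choice(list("ACGT"), size=rng.integers(2, 9)))
        expected = _enumerate_global(a, b, 2, -3, 5, 2)
        assert aligner.score(a, b) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# identity


def test_identity_of_identical_hundred_mers():
    seq = "ACGT" * 25
    assert pairwise_identity(global_align(seq, seq)) == (100.0, 100)


def test_identity_single_substitution_no_masking():
    aln = PairwiseAlignment("A" * 20, "A" * 10 + "C" + "A" * 9)
    assert pairwise_identity(aln, window=1, gap_frac=1.0) == (95.0, 20)


def test_gap_dense_windows_are_masked():
    aln = PairwiseAlignment("AAAAA-----AAAAA", "AAAAACCCCCAAAAA")
    pct, cols = pairwise_identity(aln)
    assert cols < 15 and pct == 100.0


def test_all_masked_is_undefined():
    aln = PairwiseAlignment("-----", "AAAAA")
    assert pairwise_identity(aln) is None


@settings(max_examples=40, deadline=None)
@given(DNA, DNA)
def test_identity_is_symmetric(a, b):
    ra = pairwise_identity(global_align(a, b))
    rb = pairwise_identity(global_align(b, a))
    if ra is None or rb is None:
        assert ra == rb
    else:
        assert ra[0] == pytest.approx(rb[0]) and ra[1] == rb[1]


def test_mean_identity_of_identical_triplet():
    res = mean_pairwise_identity(["ACGTACGTAC" * 5] * 3)
    assert res == (100.0, 3, 50)


def test_mean_identity_tracks_planted_divergence(rng):
    base = "".join(rng.choice(list("ACGT"), size=2000))
    copies = []
    for _ in range(5):
        arr = np.array(list(base))
        hits = rng.random(2000) < 0.025
        for p in np.nonzero(hits)[0]:
            arr[p] = rng.choice([b for b in "ACGT" if b != arr[p]])
        copies.append("".join(arr))
    mean, n, _ = mean_pairwise_identity(copies, "nucleotide")
    assert n == 5
    assert mean == pytest.approx(95.1, abs=1.0)


# ---------------------------------------------------------------------------
# Poisson correction


def test_poisson_closed_form():
    assert poisson_distance(0.0) == 0.0
    assert poisson_distance(0.5) == pytest.approx(math.log(2.0), abs=1e-12)
    with pytest.raises(ValueError):
        poisson_distance(1.0)


@settings(max_examples=60, deadline=None)
@given(st.floats(min_value=0.0, max_value=0.999))
def test_poisson_dominates_p_and_is_increasing(p):
    d = poisson_distance(p)
    assert d >= p
    if p > 1e-9:
        assert poisson_distance(p * 0.999) < d


# ---------------------------------------------------------------------------
# neighbor joining


def test_two_taxa_edge_split_at_midpoint():
    dm = DistanceMatrix(["a", "b"], np.array([[0.0, 0.4], [0.4, 0.0]]))
    tree = nj_tree(dm)
    lengths = [bl for _, bl in tree.root.children]
    assert lengths == [0.2, 0.2]


def _random_binary_tree_distances(n, rng):
    """Random topology + branch lengths; returns (matrix, true splits)."""
    nodes = [frozenset([i]) for i in range(n)]
    children: dict[frozenset, list] = {}
    dist = np.zeros((n, n))
    depth = {nd: 0.0 for nd in nodes}
    # random agglomeration builds a random topology
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        la, lb = rng.uniform(0.05, 1.0, size=2)
        merged = a | b
        children[merged] = [(a, la), (b, lb)]
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [merged]
    # leaf-to-leaf path lengths
    def paths(node, acc):
        if len(node) == 1:
            return {next(iter(node)): acc}
        out = {}
        for child, bl in children[node]:
            out.update(paths(child, acc + bl))
        return out

    root = nodes[0]
    for child, bl in children[root]:
        pass
    leaf_depth = {}
    def collect(node, d0):
        if len(node) == 1:
            leaf_depth[next(iter(node))] = d0
            return
        for child, bl in children[node]:
            collect(child, d0 + bl)
    collect(root, 0.0)
    def mrca_depth(x, y):
        node = root
        d0 = 0.0
        while len(node) > 1:
            nxt = None
            for child, bl in children[node]:
                if x in child and y in child:
                    nxt = (child, bl)
            if nxt is None:
                return d0
            node = nxt[0]
            d0 += nxt[1]
        return d0
    for x in range(n):
        for y in range(x + 1, n):
            d = leaf_depth[x] + leaf_depth[y] - 2 * mrca_depth(x, y)
            dist[x, y] = dist[y, x] = d
    splits = set()
    labels = [f"t{i}" for i in range(n)]
    alln = frozenset(labels)
    for node in children:
        side = frozenset(f"t{i}" for i in node)
        if 1 < len(side) < n - 1:
            splits.add(min(side, alln - side, key=sorted))
    return DistanceMatrix(labels, dist), splits


@pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
def test_nj_recovers_topology_from_additive_matrices(n):
    rng = np.random.default_rng(100 + n)
    for _ in range(20):
        dm, true_splits = _random_binary_tree_distances(n, rng)
        assert nj_tree(dm).splits() == true_splits


def test_nj_agrees_with_scikit_bio():
    import skbio

    rng = np.random.default_rng(77)
    for _ in range(5):
        dm, _ = _random_binary_tree_distances(6, rng)
        mine = nj_tree(dm).splits()
        sk = skbio.tree.nj(skbio.DistanceMatrix(dm.matrix, dm.labels))
        alln = frozenset(dm.labels)
        theirs = set()
        for node in sk.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(dm.labels) - 1:
                theirs.add(min(side, alln - side, key=sorted))
        assert mine == theirs


def test_nj_invariant_to_label_permutation():
    rng = np.random.default_rng(55)
    dm, _ = _random_binary_tree_distances(6, rng)
    perm = list(rng.permutation(6))
    dm2 = DistanceMatrix(
        [dm.labels[p] for p in perm], dm.matrix[np.ix_(perm, perm)]
    )
    assert nj_tree(dm).splits() == nj_tree(dm2).splits()


def test_nj_rejects_asymmetric_matrix():
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


# ---------------------------------------------------------------------------
# redundancy filtering


def _filter_setup(dists, species, seqs=None):
    labels = sorted(dists)
    # dists: dict label -> dict label -> d  (symmetric completion)
    n = len(labels)
    m = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                m[i, j] = dists[a].get(b) or dists[b][a]
    dm = DistanceMatrix(labels, m)
    tree = nj_tree(dm)
    seqs = seqs or {}
    records = [
        SpeciesSeq(l, species[l], seqs.get(l, "A" * (10 + k)))
        for k, l in enumerate(labels)
    ]
    return records, tree, dm


def test_same_species_triplet_collapses_to_longest():
    dists = {
        "x1": {"x2": 0.1, "x3": 0.15, "y": 0.9},
        "x2": {"x3": 0.12, "y": 0.92},
        "x3": {"y": 0.91},
        "y": {},
    }
    records, tree, dm = _filter_setup(dists, {"x1": "X", "x2": "X", "x3": "X", "y": "Y"})
    kept = redundancy_filter(records, tree, dm, 0.35)
    kept_x = [r.label for r in kept if r.species == "X"]
    assert len(kept_x) == 1
    longest = max((r for r in records if r.species == "X"), key=lambda r: len(r.seq))
    assert kept_x == [longest.label]


def test_threshold_boundary_keeps_both():
    dists = {"x1": {"x2": 0.40, "y": 0.9}, "x2": {"y": 0.9}, "y": {}}
    records, tree, dm = _filter_setup(dists, {"x1": "X", "x2": "X", "y": "Y"})
    assert len(redundancy_filter(records, tree, dm, 0.35)) == 3
    # exactly at the threshold: strict "< threshold" keeps both
    dists = {"x1": {"x2": 0.35, "y": 0.9}, "x2": {"y": 0.9}, "y": {}}
    records, tree, dm = _filter_setup(dists, {"x1": "X", "x2": "X", "y": "Y"})
    assert len(redundancy_filter(records, tree, dm, 0.35)) == 3


def test_mixed_species_clades_untouched():
    dists = {"x1": {"y1": 0.1, "z": 0.9}, "y1": {"z": 0.9}, "z": {}}
    records, tree, dm = _filter_setup(dists, {"x1": "X", "y1": "Y", "z": "Z"})
    assert len(redundancy_filter(records, tree, dm, 0.35)) == 3


def test_redundancy_filter_is_idempotent():
    rng = np.random.default_rng(31)
    labels = [f"s{i}" for i in range(8)]
    species = {l: ("A" if i < 5 else "B") for i, l in enumerate(labels)}
    m = np.zeros((8, 8))
    for i, j in combinations(range(8), 2):
        m[i, j] = m[j, i] = rng.uniform(0.05, 0.8)
    dm = DistanceMatrix(labels, m)
    tree = nj_tree(dm)
    records = [SpeciesSeq(l, species[l], "A" * (10 + i)) for i, l in enumerate(labels)]
    once = redundancy_filter(records, tree, dm, 0.35)
    sub_labels = [r.label for r in once]
    idx = [labels.index(l) for l in sub_labels]
    dm2 = DistanceMatrix(sub_labels, m[np.ix_(idx, idx)])
    twice = redundancy_filter(once, nj_tree(dm2), dm2, 0.35)
    assert [r.label for r in twice] == sub_labels


def test_dedupe_by_identity_drops_exact_duplicates():
    records = [
        SpeciesSeq("a", "X", "ACGTACGTACGT"),
        SpeciesSeq("b", "X", "ACGTACGTACGT"),
        SpeciesSeq("c", "X", "TTTTGGGGCCCC"),
    ]
    kept = dedupe_by_identity(records, threshold=0.99)
    assert [r.label for r in kept] == ["a", "c"]


def test_p_distance_matches_identity():
    a, b = "A" * 50, "A" * 45 + "C" * 5
    assert p_distance(a, b) == pytest.approx(0.1)
    dm = distance_matrix({"a": a, "b": b}, corrected=True)
    assert dm.get("a", "b") == pytest.approx(-math.log(0.9))
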