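"""Pairwise divergence, Poisson-corrected distances, neighbor joining, and
the same-species redundancy filter.

Identity summaries follow the convention of the copy tables: identity is
computed only over confidently aligned regions, operationalized here by
masking alignment columns that sit in gap-dense windows.  Distances are
either observed difference proportions (p-distance) or the Poisson
multiple-hit correction d = -ln(1 - p).  Trees are built with the
Saitou-Nei neighbor-joining agglomeration and exported as newick; the
redundancy filter collapses maximal same-species monophyletic clades
whose maximum pairwise distance falls below a threshold (default 0.35).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from Bio.Align import PairwiseAligner


# ---------------------------------------------------------------------------
# pairwise alignment


@dataclass
class PairwiseAlignment:
    a: str  # gapped
    b: str  # gapped

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("gapped rows differ in length")


_NT = set("ACGTN-")


def _make_aligner(level: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    if level == "nucleotide":
        aligner.match_score = 2
        aligner.mismatch_score = -3
        aligner.open_gap_score = -7
        aligner.extend_gap_score = -2
    elif level == "amino_acid":
        from Bio.Align import substitution_matrices

        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -12
        aligner.extend_gap_score = -1
    else:
        raise ValueError(f"unknown level {level!r}")
    return aligner


def global_align(a: str, b: str, level: str | None = None) -> PairwiseAlignment:
    """Optimal global alignment under affine gaps.

    ``level`` selects nucleotide or amino-acid scoring; by default it is
    inferred from the alphabet.  Ties between co-optimal alignments are
    resolved by the aligner's deterministic enumeration order.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = a.upper(), b.upper()
    if level is None:
        level = (
            "nucleotide"
            if set(a) <= _NT and set(b) <= _NT
            else "amino_acid"
        )
    nt_a, nt_b = set(a) <= _NT, set(b) <= _NT
    if nt_a != nt_b:
        raise ValueError("cannot align nucleotide against amino-acid sequence")
    aligner = _make_aligner(level)
    aln = aligner.align(a, b)[0]
    return PairwiseAlignment(str(aln[0]), str(aln[1]))


def mask_columns(aln: PairwiseAlignment, window: int = 5, gap_frac: float = 0.5) -> list[bool]:
    """Column keep-mask: drop columns inside any ``window``-column window
    whose fraction of gap-containing columns exceeds ``gap_frac``."""
    ncol = len(aln.a)
    gap = [aln.a[k] == "-" or aln.b[k] == "-" for k in range(ncol)]
    keep = [True] * ncol
    if ncol < window:
        windows = [(0, ncol)] if ncol else []
    else:
        windows = [(s, s + window) for s in range(ncol - window + 1)]
    for s, e in windows:
        if e == s:
            continue
        if sum(gap[s:e]) / (e - s) > gap_frac:
            for k in range(s, e):
                keep[k] = False
    return keep


def pairwise_identity(
    aln: PairwiseAlignment, window: int = 5, gap_frac: float = 0.5
) -> tuple[float, int] | None:
    """Percent identity over confidently aligned columns.

    Identity = matches / columns kept after gap-window masking; the kept
    column count is returned alongside.  Returns None when no columns
    survive masking (identity undefined).
    """
    keep = mask_columns(aln, window, gap_frac)
    cols = sum(keep)
    if cols == 0:
        return None
    matches = sum(
        1
        for k, kept in enumerate(keep)
        if kept and aln.a[k] == aln.b[k] and aln.a[k] != "-"
    )
    return 100.0 * matches / cols, cols


def mean_pairwise_identity(
    seqs: list[str],
    level: str | None = None,
    window: int = 5,
    gap_frac: float = 0.5,
) -> tuple[float, int, int] | None:
    """Mean all-pairs identity: (mean %, n sequences, mean aligned length).

    Pairs with undefined identity (nothing confidently aligned) are
    skipped; returns None if fewer than two sequences or no pair has a
    defined identity.
    """
    if len(seqs) < 2:
        return None
    idents, lengths = [], []
    for a, b in combinations(seqs, 2):
        res = pairwise_identity(global_align(a, b, level), window, gap_frac)
        if res is None:
            continue
        idents.append(res[0])
        lengths.append(res[1])
    if not idents:
        return None
    return (
        float(np.mean(idents)),
        len(seqs),
        int(round(float(np.mean(lengths)))),
    )


def p_distance(a: str, b: str, level: str | None = None) -> float:
    """Observed difference proportion over unmasked aligned columns."""
    res = pairwise_identity(global_align(a, b, level))
    if res is None:
        raise ValueError("p-distance undefined: no confidently aligned columns")
    return 1.0 - res[0] / 100.0


def poisson_distance(p: float) -> float:
    """Poisson multiple-hit correction d = -ln(1 - p), for 0 <= p < 1."""
    if not (0.0 <= p < 1.0):
        raise ValueError(f"difference proportion must lie in [0, 1), got {p}")
    return -math.log1p(-p)


# ---------------------------------------------------------------------------
# distance matrices


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")
        self.matrix = m

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.matrix):
                fh.write(lab + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


def distance_matrix(
    seqs: dict[str, str], level: str | None = None, corrected: bool = False
) -> DistanceMatrix:
    """All-pairs p-distances (optionally Poisson-corrected)."""
    labels = list(seqs)
    n = len(labels)
    m = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        p = p_distance(seqs[labels[i]], seqs[labels[j]], level)
        d = poisson_distance(p) if corrected else p
        m[i, j] = m[j, i] = d
    return DistanceMatrix(labels, m)


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class TreeNode:
    label: str | None = None  # leaves only
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(l.label for l in self.leaves())

    def newick(self, length: float | None = None) -> str:
        if self.is_leaf:
            core = self.label
        else:
            core = "(" + ",".join(c.newick(bl) for c, bl in self.children) + ")"
        return core if length is None else f"{core}:{length:.6f}"


@dataclass
class NjTree:
    root: TreeNode
    labels: list[str]
    negative_branches_clamped: int = 0

    def newick(self) -> str:
        return self.root.newick() + ";"

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartition halves (as leaf-label sets), for
        topology comparison of unrooted trees."""
        all_labels = frozenset(self.labels)
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> None:
            for child, _ in node.children:
                side = child.leaf_labels()
                if 1 < len(side) < len(all_labels) - 1:
                    out.add(min(side, frozenset(all_labels - side), key=sorted))
                walk(child)

        walk(self.root)
        return out

    def clades(self) -> list[TreeNode]:
        """All internal nodes (rooted reading), preorder."""
        out = []

        def walk(node: TreeNode) -> None:
            out.append(node)
            for child, _ in node.children:
                if not child.is_leaf:
                    walk(child)

        walk(self.root)
        return out


def nj_tree(dm: DistanceMatrix) -> NjTree:
    """Saitou-Nei neighbor joining with the standard Q-criterion.

    Ties in Q are broken by input label order (first minimal (i, j) pair).
    Negative branch-length estimates are clamped to zero and counted.
    When two clusters remain, the final edge is split at its midpoint,
    yielding a conventional rooted representation of the unrooted tree.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(label=l) for l in dm.labels]
    D = dm.matrix.astype(float).copy()
    active = list(range(n))
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    grown: dict[int, TreeNode] = {i: nodes[i] for i in active}
    while len(active) > 2:
        r = len(active)
        sums = {i: sum(D[i][k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (r - 2) * D[i][j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        dij = D[i][j]
        li = 0.5 * dij + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = dij - li
        li, lj = clamp(li), clamp(lj)
        new = TreeNode(children=[(grown[i], li), (grown[j], lj)])
        # distances of the new node to the others
        newD = {}
        for k in active:
            if k in (i, j):
                continue
            newD[k] = 0.5 * (D[i][k] + D[j][k] - dij)
        idx = i  # reuse slot i for the merged cluster
        for k, v in newD.items():
            D[idx][k] = D[k][idx] = max(v, 0.0)
        grown[idx] = new
        active.remove(j)
    i, j = active
    d = D[i][j]
    half = clamp(d / 2)
    root = TreeNode(children=[(grown[i], half), (grown[j], d - half)])
    return NjTree(root, list(dm.labels), clamped)


# ---------------------------------------------------------------------------
# redundancy filtering


@dataclass
class SpeciesSeq:
    label: str
    species: str
    seq: str


def dedupe_by_identity(records: list[SpeciesSeq], threshold: float = 0.95) -> list[SpeciesSeq]:
    """Greedy length-ranked pre-deduplication (CD-HIT-style).

    Records are scanned longest-first; a record is dropped when its
    unmasked global identity to an already-kept record reaches the
    threshold (a proportion).  Input order is preserved in the output.
    """
    order = sorted(records, key=lambda rec: (-len(rec.seq), rec.label))
    kept: list[SpeciesSeq] = []
    for rec in order:
        redundant = False
        for other in kept:
            res = pairwise_identity(
                global_align(rec.seq, other.seq), window=1, gap_frac=1.0
            )
            if res is not None and res[0] / 100.0 >= threshold:
                redundant = True
                break
        if not redundant:
            kept.append(rec)
    keep_labels = {rec.label for rec in kept}
    return [rec for rec in records if rec.label in keep_labels]


def redundancy_filter(
    records: list[SpeciesSeq],
    tree: NjTree,
    dm: DistanceMatrix,
    threshold: float = 0.35,
) -> list[SpeciesSeq]:
    """Collapse same-species monophyletic clades below a divergence threshold.

    Every maximal clade whose leaves all carry one species label and whose
    maximum pairwise distance is strictly below ``threshold`` keeps a
    single representative (the longest sequence; ties by label order).
    Clades containing two or more species are left untouched.  Because
    removing taxa can regroup the survivors, the collapse is iterated —
    rebuilding the tree on the retained subset — until stable, which
    makes the operation idempotent.
    """
    kept = records
    tree_cur, dm_cur = tree, dm
    while True:
        survivors = _filter_once(kept, tree_cur, dm_cur, threshold)
        if len(survivors) == len(kept):
            return survivors
        kept = survivors
        labels = [rec.label for rec in kept]
        idx = [dm.labels.index(l) for l in labels]
        dm_cur = DistanceMatrix(labels, dm.matrix[np.ix_(idx, idx)])
        tree_cur = nj_tree(dm_cur) if len(labels) >= 2 else None
        if tree_cur is None:
            return kept


def _filter_once(
    records: list[SpeciesSeq],
    tree: NjTree,
    dm: DistanceMatrix,
    threshold: float,
) -> list[SpeciesSeq]:
    by_label = {rec.label: rec for rec in records}
    missing = [l for l in tree.labels if l not in by_label]
    if missing:
        raise ValueError(f"tree leaves without sequence records: {missing}")
    for rec in records:
        if not rec.species:
            raise ValueError(f"record {rec.label!r} lacks a species label")

    drop: set[str] = set()

    def max_dist(labels: list[str]) -> float:
        return max(
            (dm.get(a, b) for a, b in combinations(labels, 2)), default=0.0
        )

    def qualifies(node: TreeNode) -> bool:
        labels = [l.label for l in node.leaves()]
        species = {by_label[l].species for l in labels}
        return len(species) == 1 and max_dist(labels) < threshold

    def walk(node: TreeNode) -> None:
        if node.is_leaf:
            return
        if qualifies(node):
            labels = [l.label for l in node.leaves()]
            rep = min(labels, key=lambda l: (-len(by_label[l].seq), l))
            drop.update(l for l in labels if l != rep)
            return  # maximal qualifying clade: do not descend
        for child, _ in node.children:
            walk(child)

    walk(tree.root)
    return [rec for rec in records if rec.label not in drop]
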