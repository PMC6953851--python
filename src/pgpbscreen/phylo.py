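"""Kimura 2-parameter distances, neighbor-joining and bootstrap support.

Distances between aligned 16S sequences use the K2P model, which separates
transitions (A<->G, C<->T) from transversions: with transition fraction P
and transversion fraction Q over usable sites,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Sites with a gap or N in either sequence are excluded pairwise.  Trees are
built by Saitou-Nei neighbor joining; nodal robustness is assessed by
resampling alignment columns with replacement and counting how often each
original bipartition reappears.
"""

from __future__ import annotations

import logging
import math
from typing import Optional

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .model import Alignment

logger = logging.getLogger(__name__)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_USABLE = frozenset("ACGT")


class SaturationError(ValueError):
    """K2P distance undefined: too many substitutions (log argument <= 0)."""


def k2p_distance(a: str, b: str) -> float:
    """K2P distance between two equal-length aligned sequences.

    Pairwise deletion: sites where either sequence has a gap or ambiguous
    base are ignored.  Raises :class:`SaturationError` when the distance is
    undefined and ``ValueError`` when no usable sites remain.
    """
    if len(a) != len(b):
        raise ValueError("sequences must have equal aligned length")
    a, b = a.upper(), b.upper()
    usable = transitions = transversions = 0
    for x, y in zip(a, b):
        if x not in _USABLE or y not in _USABLE:
            continue
        usable += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if usable == 0:
        raise ValueError("no usable (ungapped, unambiguous) sites in common")
    p = transitions / usable
    q = transversions / usable
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"substitution saturation: P={p:.4f}, Q={q:.4f}")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_matrix(alignment: Alignment) -> DistanceMatrix:
    """Pairwise K2P distance matrix over all sequences of an alignment."""
    ids = alignment.ids
    n = len(ids)
    d = np.zeros((n, n))
    seqs = [seq for _, seq in alignment.sequences]
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = k2p_distance(seqs[i], seqs[j])
    return DistanceMatrix(d, ids)


def nj_tree(dm: DistanceMatrix, clamp_negative: bool = True) -> TreeNode:
    """Neighbor-joining tree (Saitou-Nei agglomeration) from a distance matrix.

    Returns an unrooted tree represented as a :class:`skbio.TreeNode` whose
    root is the final internal node (trifurcating).  Negative branch
    lengths are clamped to 0; the raw value is kept on the node as
    ``raw_length`` and the total clamped deficit is logged.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = {(i, j): float(dm[i, j]) for i in range(n) for j in range(i + 1, n)}

    def get(i: int, j: int) -> float:
        return 0.0 if i == j else d[(min(i, j), max(i, j))]

    nodes: dict[int, TreeNode] = {i: TreeNode(name=ids[i]) for i in range(n)}
    active = list(range(n))
    next_label = n
    deficit = 0.0

    def attach(parent: TreeNode, child: TreeNode, length: float) -> None:
        nonlocal deficit
        child.raw_length = length
        if length < 0 and clamp_negative:
            deficit += -length
            length = 0.0
        child.length = length
        parent.append(child)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = get(i, j)
        vi = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = dij - vi
        parent = TreeNode()
        attach(parent, nodes[i], vi)
        attach(parent, nodes[j], vj)
        for k in active:
            if k in (i, j):
                continue
            d[(min(next_label, k), max(next_label, k))] = 0.5 * (
                get(i, k) + get(j, k) - dij
            )
        nodes[next_label] = parent
        active = [k for k in active if k not in (i, j)] + [next_label]
        next_label += 1

    i, j, k = active
    root = TreeNode()
    attach(root, nodes[i], 0.5 * (get(i, j) + get(i, k) - get(j, k)))
    attach(root, nodes[j], 0.5 * (get(i, j) + get(j, k) - get(i, k)))
    attach(root, nodes[k], 0.5 * (get(i, k) + get(j, k) - get(i, j)))
    if deficit > 0:
        logger.info("clamped negative NJ branch lengths; total deficit %.6g", deficit)
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial unrooted splits of a tree, in leaf-label canonical form.

    Each internal edge induces a bipartition of the leaf set; the side not
    containing the reference taxon (first tip in postorder of the full
    tree) represents the split.  Trivial splits (single leaves) excluded.
    """
    tips = sorted(t.name for t in tree.tips())
    all_tips = frozenset(tips)
    ref = tips[0]
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_tips - side
        if 2 <= len(side) <= len(all_tips) - 2:
            splits.add(side)
    return splits


def bootstrap_support(alignment: Alignment, n_reps: int = 1000,
                      seed: Optional[int] = None,
                      max_skip_fraction: float = 0.10) -> TreeNode:
    """NJ tree with bootstrap support on internal nodes.

    Columns are resampled with replacement ``n_reps`` times; support for
    each original bipartition is the fraction of replicate trees that
    contain it, stored as ``node.support`` in [0, 1].  Replicates raising
    a saturation error are skipped and counted; more than
    ``max_skip_fraction`` skipped replicates is an error.
    """
    if len(alignment) < 3:
        raise ValueError("bootstrap requires an alignment with >= 3 taxa")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    tree = nj_tree(k2p_matrix(alignment))

    ids = alignment.ids
    seqs = [seq for _, seq in alignment.sequences]
    ncol = alignment.length
    counts: dict[frozenset[str], int] = {s: 0 for s in bipartitions(tree)}

    skipped = 0
    used = 0
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        resampled = Alignment(tuple(
            (sid, "".join(seq[c] for c in cols)) for sid, seq in zip(ids, seqs)
        ))
        try:
            rep_tree = nj_tree(k2p_matrix(resampled))
        except SaturationError:
            skipped += 1
            continue
        used += 1
        rep_splits = bipartitions(rep_tree)
        for s in counts:
            if s in rep_splits:
                counts[s] += 1
    if skipped > max_skip_fraction * n_reps:
        raise RuntimeError(
            f"{skipped}/{n_reps} bootstrap replicates hit saturation (> {max_skip_fraction:.0%})"
        )
    if used == 0:
        raise RuntimeError("no usable bootstrap replicates")

    all_tips = frozenset(t.name for t in tree.tips())
    ref = sorted(all_tips)[0]
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = all_tips - side
        if side in counts:
            node.support = counts[side] / used
    return tree


def write_newick(tree: TreeNode, path, support_as_labels: bool = True) -> None:
    """Write a tree in Newick format, supports as internal node labels."""
    out = tree.copy()
    if support_as_labels:
        for node in out.non_tips(include_self=False):
            sup = getattr(node, "support", None)
            if sup is not None:
                node.name = f"{sup:.3g}"
    out.write(str(path))


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path))


# ---------------------------------------------------------------------------
# Fixture generation for tree-stage testing (star/additive trees and
# alignments with planted clade signal).

def random_additive_tree(n_taxa: int, seed: Optional[int] = None) -> tuple[TreeNode, DistanceMatrix]:
    """Random binary tree with positive branch lengths and its path-distance matrix.

    The matrix is exactly additive, so NJ must recover topology and branch
    lengths up to floating-point error.
    """
    if n_taxa < 3:
        raise ValueError("need >= 3 taxa")
    rng = np.random.default_rng(seed)
    names = [f"t{i}" for i in range(n_taxa)]
    subtrees = [TreeNode(name=nm) for nm in names]
    while len(subtrees) > 3:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        parent = TreeNode()
        a.length = float(rng.uniform(0.05, 1.0))
        b.length = float(rng.uniform(0.05, 1.0))
        parent.append(a)
        parent.append(b)
        subtrees.append(parent)
    root = TreeNode()
    for st in subtrees:
        st.length = float(rng.uniform(0.05, 1.0))
        root.append(st)
    dm = root.tip_tip_distances()
    order = [nm for nm in names]
    return root, DistanceMatrix(np.array([[dm[a, b] for b in order] for a in order]), order)


def two_clade_alignment(n_per_clade: int = 4, length: int = 600,
                        n_fixed_diff: int = 40, n_private: int = 2,
                        seed: Optional[int] = None) -> Alignment:
    """Alignment with two clades separated by many fixed differences.

    Useful for bootstrap tests: the clade split carries unambiguous signal
    and should receive support near 1.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    anc = rng.integers(0, 4, size=length)
    clade_b = anc.copy()
    diff_sites = rng.choice(length, size=n_fixed_diff, replace=False)
    clade_b[diff_sites] = (clade_b[diff_sites] + rng.integers(1, 4, size=n_fixed_diff)) % 4
    seqs = []
    for c, base_seq in (("A", anc), ("B", clade_b)):
        for i in range(n_per_clade):
            s = base_seq.copy()
            priv = rng.choice(length, size=n_private, replace=False)
            s[priv] = (s[priv] + rng.integers(1, 4, size=n_private)) % 4
            seqs.append((f"{c}{i}", "".join(bases[s])))
    return Alignment(tuple(seqs))
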