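"""Band-profile similarity, UPGMA dendrograms and similarity-cutoff groups.

rep-PCR (BOX-PCR) fingerprints are compared band-by-band: two fragments
match when their sizes differ by at most a proportional tolerance (default
2%, taken relative to the mean of the two sizes).  Profile similarity is
the Jaccard coefficient on matched bands; profiles are clustered by UPGMA
on distance ``1 - s`` and groups are called by cutting the dendrogram at a
similarity cutoff (70% for diversity groups, 95% for near-clonal profile
counting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import BandProfile


def match_bands(a: BandProfile, b: BandProfile, tol: float = 0.02,
                exact: bool = False) -> int:
    """Number of one-to-one matched band pairs between two profiles.

    Bands ``x`` and ``y`` are matchable iff ``|x - y| <= tol * (x + y)/2``.
    The default pairing is a greedy pass over matchable pairs ordered by
    size difference ascending (deterministic, and identical to the optimal
    assignment on well-separated gels); ``exact=True`` switches to a
    maximum-cardinality assignment for ambiguous profiles.
    """
    if tol < 0:
        raise ValueError("tolerance must be non-negative")
    pairs = [
        (abs(x - y), i, j)
        for i, x in enumerate(a.bands)
        for j, y in enumerate(b.bands)
        if abs(x - y) <= tol * (x + y) / 2.0
    ]
    if not pairs:
        return 0
    if exact:
        # maximize matched pairs; among maximum matchings this minimizes
        # total size difference
        big = 1.0 + sum(p[0] for p in pairs)
        cost = np.full((len(a.bands), len(b.bands)), big * len(pairs))
        for d, i, j in pairs:
            cost[i, j] = d
        ri, cj = linear_sum_assignment(cost)
        return int(sum(cost[i, j] < big * len(pairs) for i, j in zip(ri, cj)))
    used_a: set[int] = set()
    used_b: set[int] = set()
    m = 0
    for _, i, j in sorted(pairs):
        if i not in used_a and j not in used_b:
            used_a.add(i)
            used_b.add(j)
            m += 1
    return m


def jaccard_similarity(a: BandProfile, b: BandProfile, tol: float = 0.02,
                       exact: bool = False) -> float:
    """Jaccard coefficient ``m / (|a| + |b| - m)``; two empty profiles -> 1."""
    if not a.bands and not b.bands:
        return 1.0
    m = match_bands(a, b, tol, exact=exact)
    return m / (len(a.bands) + len(b.bands) - m)


def similarity_matrix(profiles: list[BandProfile], tol: float = 0.02,
                      exact: bool = False) -> tuple[list[str], np.ndarray]:
    """Symmetric unit-diagonal Jaccard similarity matrix over profiles."""
    n = len(profiles)
    s = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s[i, j] = s[j, i] = jaccard_similarity(profiles[i], profiles[j], tol, exact=exact)
    return [p.strain_id for p in profiles], s


@dataclass
class DendroNode:
    """Node of a UPGMA dendrogram.

    Leaves carry ``strain_id``; internal nodes carry the merge similarity
    (``1 - merge distance``) and two children.  Merge similarities are
    non-increasing from leaves to root.
    """

    similarity: Optional[float] = None
    strain_id: Optional[str] = None
    children: tuple["DendroNode", ...] = ()
    leaves: tuple[str, ...] = field(default_factory=tuple)

    @property
    def is_leaf(self) -> bool:
        return self.strain_id is not None

    @property
    def height(self) -> float:
        """Ultrametric height (half the merge distance)."""
        return 0.0 if self.is_leaf else (1.0 - self.similarity) / 2.0

    def to_newick(self) -> str:
        def render(node: DendroNode, parent_height: float) -> str:
            length = parent_height - node.height
            if node.is_leaf:
                return f"{node.strain_id}:{length:.6g}"
            inner = ",".join(render(c, node.height) for c in node.children)
            return f"({inner}):{length:.6g}"

        if self.is_leaf:
            return f"{self.strain_id}:0;"
        inner = ",".join(render(c, self.height) for c in self.children)
        return f"({inner});"


def upgma(ids: list[str], sim: np.ndarray) -> DendroNode:
    """Average-linkage agglomeration on distance ``d = 1 - s``.

    Cluster-pair distance is the size-weighted arithmetic mean over all
    cross pairs.  Ties on the minimal distance are broken by the
    lexicographically earliest pair of cluster labels, a cluster's label
    being the input position of its first member (reproducibility).
    """
    n = len(ids)
    if n == 0:
        raise ValueError("need at least one profile")
    sim = np.asarray(sim, dtype=float)
    if sim.shape != (n, n):
        raise ValueError("similarity matrix shape does not match id list")
    if not np.allclose(sim, sim.T) or not np.allclose(np.diag(sim), 1.0):
        raise ValueError("similarity matrix must be symmetric with unit diagonal")
    if sim.min() < -1e-12 or sim.max() > 1 + 1e-12:
        raise ValueError("similarities must lie in [0, 1]")

    nodes: dict[int, DendroNode] = {
        i: DendroNode(strain_id=ids[i], leaves=(ids[i],)) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    dist = {(i, j): 1.0 - sim[i, j] for i in range(n) for j in range(i + 1, n)}
    active = sorted(nodes)

    while len(active) > 1:
        best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        (i, j), dmin = best
        merged = DendroNode(
            similarity=1.0 - dmin,
            children=(nodes[i], nodes[j]),
            leaves=nodes[i].leaves + nodes[j].leaves,
        )
        si, sj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            a, b = (min(i, k), max(i, k)), (min(j, k), max(j, k))
            dik, djk = dist.pop(a), dist.pop(b)
            dist[(min(i, k), max(i, k))] = (si * dik + sj * djk) / (si + sj)
        del dist[(i, j)]
        nodes[i] = merged  # merged cluster keeps the smaller label
        sizes[i] = si + sj
        del nodes[j], sizes[j]
        active = sorted(nodes)
    return nodes[active[0]]


def cut_clusters(dend: DendroNode, cutoff: float = 0.70) -> list[list[str]]:
    """Partition leaves into maximal subtrees whose merges are all >= cutoff.

    Groups are numbered (ordered) by the input position of their first
    strain, i.e. by leaf order of the dendrogram.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    groups: list[list[str]] = []

    def walk(node: DendroNode) -> None:
        if node.is_leaf or node.similarity >= cutoff:
            groups.append(list(node.leaves))
        else:
            for c in node.children:
                walk(c)

    walk(dend)
    return groups


def count_profiles(ids: list[str], sim: np.ndarray,
                   threshold: float = 0.95) -> tuple[int, list[list[str]]]:
    """Distinct fingerprint profiles at a similarity threshold.

    Cuts the UPGMA dendrogram at ``threshold``; returns the group count and
    the near-clonal sets (groups of size >= 2).
    """
    dend = upgma(ids, sim)
    groups = cut_clusters(dend, threshold)
    clonal = [g for g in groups if len(g) >= 2]
    return len(groups), clonal
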