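"""Mutational-step distances, barcode-gap assessment, neighbor-joining
trees with bootstrap support, and monophyly checks.

Distances are raw nucleotide differences ("mutational steps") over
columns where both sequences carry a real base (gaps and N excluded).
The proportional distance divides steps by the alignment length, so that
printed step counts and percentages stay mutually consistent; per-pair
percentages over compared sites are also available from the matrix.

Tree inference is classic neighbor joining with deterministic
tie-breaking, plus nonparametric bootstrap over alignment columns; this
is a desk-scale stand-in for likelihood/Bayesian inference when the
question is topological (clade recovery, monophyly, support).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import dendropy
import numpy as np

from .seqio import MultipleAlignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    steps: np.ndarray           # integer mutational steps
    compared_sites: np.ndarray  # sites with real bases in both rows
    p_dist: np.ndarray          # steps / alignment length

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def steps_between(self, a: str, b: str) -> int:
        return int(self.steps[self.index(a), self.index(b)])


def pairwise_steps(aln: MultipleAlignment) -> DistanceMatrix:
    """All-pairs mutational steps. Errors if any pair shares no comparable
    site."""
    arr = np.array([list(r.residues.encode()) for r in aln.records],
                   dtype=np.uint8)
    valid = (arr != ord("-")) & (arr != ord("N"))
    n = len(aln.records)
    steps = np.zeros((n, n), dtype=int)
    comp = np.zeros((n, n), dtype=int)
    np.fill_diagonal(comp, valid.sum(axis=1))
    for i, j in itertools.combinations(range(n), 2):
        both = valid[i] & valid[j]
        c = int(both.sum())
        if c == 0:
            raise ValueError(
                f"no comparable sites between {aln.records[i].id!r} "
                f"and {aln.records[j].id!r}")
        d = int((both & (arr[i] != arr[j])).sum())
        steps[i, j] = steps[j, i] = d
        comp[i, j] = comp[j, i] = c
    return DistanceMatrix(
        labels=tuple(r.id for r in aln.records),
        steps=steps, compared_sites=comp,
        p_dist=steps / aln.length)


@dataclass(frozen=True)
class DivergenceSummary:
    """Intra- vs inter-group divergence in mutational steps, and a
    barcode-gap verdict per group: the gap holds when the group's nearest
    inter-group distance exceeds the intra-group spread of both groups
    involved in that nearest comparison."""

    max_intra: dict[str, int]
    min_inter: dict[tuple[str, str], int]
    barcode_gap: dict[str, bool]
    overlap_witnesses: list[tuple[tuple[str, str], int, int]]


def divergence_summary(dm: DistanceMatrix,
                       labels: Mapping[str, str] | Callable[[str], str]
                       ) -> DivergenceSummary:
    get = labels.__getitem__ if isinstance(labels, Mapping) else labels
    groups: dict[str, list[int]] = {}
    for idx, lab in enumerate(dm.labels):
        groups.setdefault(get(lab), []).append(idx)
    if len(groups) < 2:
        raise ValueError("divergence summary needs >= 2 groups")

    max_intra = {}
    for g, idxs in groups.items():
        max_intra[g] = (0 if len(idxs) == 1 else
                        int(dm.steps[np.ix_(idxs, idxs)].max()))
    min_inter = {}
    for g, h in itertools.combinations(sorted(groups), 2):
        min_inter[(g, h)] = int(
            dm.steps[np.ix_(groups[g], groups[h])].min())

    def inter(g: str, h: str) -> int:
        return min_inter[(g, h) if (g, h) in min_inter else (h, g)]

    barcode_gap = {}
    witnesses = []
    for g in groups:
        others = [h for h in groups if h != g]
        nearest = min(others, key=lambda h: inter(g, h))
        m = inter(g, nearest)
        intra = max(max_intra[g], max_intra[nearest])
        barcode_gap[g] = m > intra
        if not barcode_gap[g]:
            witnesses.append((tuple(sorted((g, nearest))), m, intra))
    return DivergenceSummary(max_intra=max_intra, min_inter=min_inter,
                             barcode_gap=barcode_gap,
                             overlap_witnesses=sorted(set(witnesses)))


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining on the proportional distances.

    Deterministic: ties in the Q criterion are broken by the smallest
    (lexicographic) pair of cluster representative labels. Negative branch
    estimates are clamped to zero with a logged note. The result is
    unrooted (trifurcating root node).
    """
    if len(dm.labels) < 3:
        raise ValueError("nj_tree needs >= 3 labels")
    if not np.allclose(dm.p_dist, dm.p_dist.T) or np.any(np.diag(dm.p_dist) != 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    taxa = dendropy.TaxonNamespace(list(dm.labels))
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: dict[str, dendropy.Node] = {}
    for label in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes[label] = node

    # active clusters keyed by representative label (smallest member label)
    d: dict[frozenset, float] = {}
    active = list(dm.labels)
    for a, b in itertools.combinations(active, 2):
        d[frozenset((a, b))] = float(dm.p_dist[dm.index(a), dm.index(b)])

    def dist(a: str, b: str) -> float:
        return d[frozenset((a, b))]

    def clamp(x: float, where: str) -> float:
        if x < 0:
            logger.info("negative NJ branch estimate %.4g at %s clamped to 0",
                        x, where)
            return 0.0
        return x

    while len(active) > 3:
        n = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(sorted(active), 2):
            q = (n - 2) * dist(a, b) - r[a] - r[b]
            key = (q, a, b)
            if best is None or key < best:
                best = key
        _, a, b = best
        la = clamp(dist(a, b) / 2 + (r[a] - r[b]) / (2 * (n - 2)), f"({a},{b})")
        lb = clamp(dist(a, b) - la, f"({a},{b})")
        new = dendropy.Node()
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        new.add_child(nodes[a])
        new.add_child(nodes[b])
        rep = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            d[frozenset((rep, c))] = (dist(a, c) + dist(b, c) - dist(a, b)) / 2
        active = [c for c in active if c not in (a, b)] + [rep]
        active.sort()
        nodes[rep] = new

    a, b, c = sorted(active)
    la = clamp((dist(a, b) + dist(a, c) - dist(b, c)) / 2, "final")
    lb = clamp((dist(a, b) + dist(b, c) - dist(a, c)) / 2, "final")
    lc = clamp((dist(a, c) + dist(b, c) - dist(a, b)) / 2, "final")
    for label, ln in ((a, la), (b, lb), (c, lc)):
        nodes[label].edge.length = ln
        tree.seed_node.add_child(nodes[label])
    tree.is_rooted = False
    return tree


def leaf_bipartitions(tree: dendropy.Tree,
                      include_trivial: bool = False) -> set[frozenset]:
    """Canonical leaf-set bipartitions of an unrooted tree: for each edge,
    the side not containing the alphabetically first leaf. Trivial
    (single-leaf) splits are excluded unless requested."""
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(all_leaves)
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_leaves - side
        if not include_trivial and not 2 <= len(side) <= len(all_leaves) - 2:
            continue
        out.add(side)
    return out


def bootstrap_support(aln: MultipleAlignment, n_reps: int,
                      seed: int) -> dendropy.Tree:
    """NJ tree on the full alignment with internal-edge bootstrap support
    (percentage of column-resampled replicates containing the same leaf
    bipartition). Reproducible for a given seed; supports are stored as
    internal node labels."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    full = nj_tree(pairwise_steps(aln))
    counts: dict[frozenset, int] = {bp: 0 for bp in leaf_bipartitions(full)}

    arr = np.array([list(r.residues) for r in aln.records])
    for _ in range(n_reps):
        cols = rng.integers(0, aln.length, size=aln.length)
        rep_records = tuple(
            r.with_residues("".join(arr[i, cols]))
            for i, r in enumerate(aln.records))
        rep_tree = nj_tree(pairwise_steps(MultipleAlignment(rep_records)))
        rep_bps = leaf_bipartitions(rep_tree)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1

    all_leaves = frozenset(lf.taxon.label for lf in full.leaf_node_iter())
    ref = min(all_leaves)
    for node in full.preorder_node_iter():
        if node is tree_seed(full) or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_leaves - side
        if side in counts:
            node.label = f"{100.0 * counts[side] / n_reps:g}"
    return full


def tree_seed(tree: dendropy.Tree) -> dendropy.Node:
    return tree.seed_node


def monophyly(tree: dendropy.Tree,
              labels: Mapping[str, str] | Callable[[str], str]
              ) -> dict[str, tuple[bool, int]]:
    """Per-group monophyly on the unrooted tree: a group is monophyletic
    iff some edge bipartition separates exactly its leaves. Also reports
    the size of the smallest clade (bipartition side) covering the group.
    Single-member groups are trivially monophyletic."""
    get = labels.__getitem__ if isinstance(labels, Mapping) else labels
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    groups: dict[str, set[str]] = {}
    for leaf in all_leaves:
        try:
            groups.setdefault(get(leaf), set()).add(leaf)
        except KeyError:
            raise ValueError(f"unlabeled leaf {leaf!r}") from None

    sides: set[frozenset] = {all_leaves}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        sides.add(side)
        sides.add(all_leaves - side)

    out = {}
    for g, members in groups.items():
        mem = frozenset(members)
        mono = mem in sides
        covering = min(len(s) for s in sides if s >= mem)
        out[g] = (mono, covering)
    return out
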