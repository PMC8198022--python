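"""Rank candidate marker genes for a target genus.

A marker is a good discrimination substrate when the target genus sits
*below* the marker's overall similarity baseline (positive margin
= total average - target-vs-others average) or when the genus forms its own
clade on that marker's tree.  Eligibility is the OR of the two criteria:
a marker whose tree isolates the genus can be selected even at a slightly
negative margin.  When trees are available, monophyly dominates the
ranking; margins break ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import dendropy

from .core_io import SimilarityMatrix, round1
from .similarity import matrix_total_average, taxon_vs_others_average

__all__ = ["MarkerScore", "rank_markers", "is_monophyletic", "nj_tree"]


@dataclass(frozen=True)
class MarkerScore:
    marker: str
    target_mean: float
    total_mean: float
    margin: float
    monophyletic: Optional[bool]
    selected: bool


def rank_markers(
    matrices: Mapping[str, SimilarityMatrix],
    target_genus: str,
    trees: Optional[Mapping[str, dendropy.Tree]] = None,
) -> list[MarkerScore]:
    """Score and order markers for discriminating ``target_genus``.

    Means are taken at one-decimal reporting precision so margins match the
    printed-table arithmetic exactly.  Markers failing both criteria are
    appended unselected (diagnostics, never an exception).
    """
    trees = trees or {}
    scores: list[MarkerScore] = []
    for marker in matrices:
        m = matrices[marker]
        total = round1(matrix_total_average(m).mean)
        target = round1(taxon_vs_others_average(m, target_genus).mean)
        margin = round(total - target, 1)
        mono: Optional[bool] = None
        if marker in trees:
            tree = trees[marker]
            labels = {
                leaf.taxon.label: leaf.taxon.label.split()[0]
                for leaf in tree.leaf_node_iter()
            }
            mono = is_monophyletic(tree, target_genus, labels)
        selected = margin > 0 or mono is True
        scores.append(
            MarkerScore(
                marker=marker,
                target_mean=target,
                total_mean=total,
                margin=margin,
                monophyletic=mono,
                selected=selected,
            )
        )

    def key(s: MarkerScore):
        return (not s.selected, s.monophyletic is not True, -s.margin, s.marker)

    return sorted(scores, key=key)


def _as_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=str(tree), schema="newick")


def is_monophyletic(tree, genus: str, labels: Optional[Mapping[str, str]] = None) -> bool:
    """Unrooted bipartition test: does some edge separate exactly the
    genus's tips from everything else?

    ``labels`` maps tip label -> genus; by default the genus is the tip
    label's leading alphabetic run (so A1, A2 belong to genus A).  A genus
    with a single tip is trivially monophyletic.
    """
    tree = _as_tree(tree)
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if labels is None:
        import re

        def tip_genus(t: str) -> str:
            m = re.match(r"[A-Za-z_.-]+", t)
            return m.group(0) if m else t

        labels = {t: tip_genus(t) for t in tips}
    else:
        missing = [t for t, g in labels.items() if g == genus and t not in set(tips)]
        if missing:
            raise ValueError(f"genus {genus!r} members missing from tree: {missing}")

    genus_tips = {t for t in tips if labels.get(t) == genus}
    if not genus_tips:
        raise ValueError(f"genus {genus!r} has no tips in tree")
    all_tips = set(tips)
    if len(genus_tips) in (1, len(all_tips)):
        return True

    # every edge (incl. leaf edges) induces a bipartition below|rest
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        if below == genus_tips or below == all_tips - genus_tips:
            return True
    return False


def nj_tree(distances, taxa=None) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix.

    Accepts a :class:`SimilarityMatrix` (converted as d = (100 - S)/100) or
    an (n, n) array with a parallel list of taxon labels.  Negative branch
    lengths are clamped to zero with the deficit shifted onto the sibling
    edge, so path lengths through each join are preserved.
    """
    if isinstance(distances, SimilarityMatrix):
        labels = distances.labels()
        D = (100.0 - distances.values) / 100.0
    else:
        D = np.asarray(distances, dtype=float).copy()
        if taxa is None:
            raise ValueError("taxon labels required with a raw distance matrix")
        labels = list(taxa)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = D.astype(float).copy()
    np.fill_diagonal(D, 0.0)

    nodes = [f"'{lab}'" if any(c in lab for c in " ()," ) else lab for lab in labels]
    active = list(range(n))
    dist = {(i, j): D[i, j] for i in range(n) for j in range(n)}
    newick = {i: nodes[i] for i in range(n)}
    next_id = n

    def d(i, j):
        return dist[(i, j)] if i <= j else dist[(j, i)]

    while len(active) > 2:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d(i, j) - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
            dist[(min(u, k), max(u, k))] = max(duk, 0.0)
        newick[u] = f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g})"
        active = [k for k in active if k not in (i, j)] + [u]

    i, j = active
    L = max(d(i, j), 0.0)
    text = f"({newick[i]}:{L / 2:.10g},{newick[j]}:{L / 2:.10g});"
    return dendropy.Tree.get(data=text, schema="newick")
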