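"""Neighbor-joining tree construction over a distance matrix.

Plumbing for grouping checks on similarity-derived distances (the
published comparative tree was built by Bayesian inference, which is out
of scope here). The implementation is the classical Saitou–Nei algorithm
with a deterministic tie-break: among pairs minimising the Q criterion,
the lexicographically smallest (sorted) taxon-name pair is joined. Trees
are returned as Bio.Phylo objects, so they serialise to Newick directly.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
from Bio.Phylo.BaseTree import Clade, Tree

from .core import ValidationError


def nj_tree(
    ids: Sequence[str],
    dmat: np.ndarray,
    outgroup_id: Optional[str] = None,
) -> Tree:
    """Build a neighbor-joining tree from a symmetric distance matrix.

    With an ``outgroup_id`` the tree is rooted on that taxon; otherwise it
    is left unrooted (trifurcating root).
    """
    ids = list(ids)
    d = np.asarray(dmat, dtype=float)
    n = len(ids)
    if d.shape != (n, n):
        raise ValidationError(f"distance matrix shape {d.shape} does not match {n} ids")
    if not np.allclose(d, d.T):
        raise ValidationError("distance matrix is not symmetric")
    if outgroup_id is not None and outgroup_id not in ids:
        raise ValidationError(f"outgroup {outgroup_id!r} not among the taxa")
    if n < 2:
        raise ValidationError("need at least two taxa")

    nodes: List[Clade] = [Clade(name=i) for i in ids]
    labels = list(ids)  # lexicographic tie-break keys, one per active node
    d = d.copy()

    while len(nodes) > 2:
        m = len(nodes)
        total = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - total[i] - total[j]
                key = (q, tuple(sorted((labels[i], labels[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = d[i, j]
        if m > 2:
            li = 0.5 * dij + (total[i] - total[j]) / (2 * (m - 2))
        else:
            li = 0.5 * dij
        lj = dij - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.branch_length = li
        child_j.branch_length = lj
        new = Clade(clades=[child_i, child_j])
        new_label = min(labels[i], labels[j])

        rest = [k for k in range(m) if k not in (i, j)]
        new_d = np.zeros((len(rest) + 1, len(rest) + 1))
        for a, ka in enumerate(rest):
            for b, kb in enumerate(rest):
                new_d[a, b] = d[ka, kb]
            new_d[a, -1] = new_d[-1, a] = 0.5 * (d[ka, i] + d[ka, j] - dij)
        nodes = [nodes[k] for k in rest] + [new]
        labels = [labels[k] for k in rest] + [new_label]
        d = new_d

    # connect the last two nodes
    a, b = nodes
    if a.is_terminal() and b.is_terminal():
        a.branch_length = b.branch_length = d[0, 1] / 2
        root = Clade(clades=[a, b])
    elif not b.is_terminal():
        a.branch_length = d[0, 1]
        b.clades.append(a)
        root = b
    else:
        b.branch_length = d[0, 1]
        a.clades.append(b)
        root = a

    tree = Tree(root=root, rooted=False)
    if outgroup_id is not None:
        tree.root_with_outgroup(outgroup_id)
        tree.rooted = True
    return tree


def leaf_sets(tree: Tree) -> set:
    """Frozensets of leaf names under each internal node (topology signature)."""
    out = set()
    for cl in tree.get_nonterminals():
        names = frozenset(t.name for t in cl.get_terminals())
        out.add(names)
    return out
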