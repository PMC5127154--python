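"""Saitou-Nei neighbor joining.

Used to build the starting tree for the ML search.  Input taxa are
canonicalized to sorted order before the algorithm runs, so the result is
exactly invariant to input permutation; remaining ties in the Q criterion
are broken lexicographically.  Negative branch-length estimates are clamped
to zero with the deficit moved to the sibling edge, preserving the joined
pair's path length.
"""

from __future__ import annotations

import numpy as np

from ..trees import Node, PhyloTree


def neighbor_joining(names: list[str], dist: np.ndarray) -> PhyloTree:
    """NJ on a symmetric distance matrix; returns an unrooted tree
    (trifurcating root).  Exact on additive distances."""
    dist = np.asarray(dist, dtype=float)
    n = len(names)
    if len(set(names)) != n:
        raise ValueError("duplicate taxon names")
    if dist.shape != (n, n):
        raise ValueError(f"distance matrix shape {dist.shape} != ({n},{n})")
    if not np.allclose(dist, dist.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal is not zero")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    order = np.argsort(np.array(names, dtype=object))
    labels = [names[i] for i in order]
    D = dist[np.ix_(order, order)].copy()
    nodes: list[Node] = [Node(name) for name in labels]
    # sort key per active node: smallest leaf label underneath
    keys: list[str] = list(labels)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q <= qmin + 1e-12)
        pick = min(
            (tuple(sorted((keys[i], keys[j]))), (i, j))
            for i, j in ties if i < j
        )[1]
        i, j = pick
        dij = D[i, j]
        vi = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = dij - vi
        # clamp negatives, moving the deficit to the sibling edge
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        parent = Node()
        a, b = nodes[i], nodes[j]
        a.length, b.length = float(vi), float(vj)
        parent.add_child(a)
        parent.add_child(b)
        newD = 0.5 * (D[i] + D[j] - dij)
        keep = [x for x in range(m) if x not in (i, j)]
        D = np.vstack([D[keep][:, keep],
                       newD[keep][None, :]])
        last_col = np.append(newD[keep], 0.0)
        D = np.hstack([D, last_col[:, None]])
        nodes = [nodes[x] for x in keep] + [parent]
        keys = [keys[x] for x in keep] + [min(keys[i], keys[j])]

    # final three-point join
    root = Node()
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lens = [0.5 * (d01 + d02 - d12),
            0.5 * (d01 + d12 - d02),
            0.5 * (d02 + d12 - d01)]
    for idx in range(3):
        extra = 0.0
        if lens[idx] < 0:
            extra = lens[idx] / 2.0  # spread deficit over the other two
            lens[idx] = 0.0
            for other in range(3):
                if other != idx:
                    lens[other] += extra
    for node, length in zip(nodes, lens):
        node.length = float(max(length, 0.0))
        root.add_child(node)
    return PhyloTree(root, rooted=False)
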