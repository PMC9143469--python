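"""Distance-based phylogeny of P450 proteins.

Distances are 1 - identity/100 from all-pairs global alignment, and trees
are built by neighbor joining (NJ). NJ is exact on additive distance
matrices -- it recovers both the topology and the branch lengths of the tree
the distances came from -- which is the property the tests lean on; on real
alignment-identity distances it is a heuristic, as for any distance method.

Ties in the NJ minimum-Q selection are broken toward the smallest index
pair, so the output is deterministic for a given input order. Negative
branch lengths (possible on non-additive input) are clamped to zero and
counted on the returned tree (``clamped_negative_branches``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .nomenclature import AlignmentParams, FamilyAssignment, pairwise_identity
from .sequence_io import ProteinRecord


def build_distance_matrix(
    sequences: list[ProteinRecord], params: AlignmentParams | None = None
) -> DistanceMatrix:
    """All-pairs identity distances d = 1 - identity_pct/100."""
    if len(sequences) < 3:
        raise ValueError("need at least 3 sequences for a distance matrix")
    params = params or AlignmentParams()
    n = len(sequences)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pct, _ = pairwise_identity(sequences[i].sequence, sequences[j].sequence, params)
            d[i, j] = d[j, i] = 1.0 - pct / 100.0
    return DistanceMatrix(d, ids=[s.id for s in sequences])


def nj_tree(dist: DistanceMatrix) -> TreeNode:
    """Neighbor joining on a distance matrix, returning an unrooted tree
    (trifurcating root) as an skbio ``TreeNode``.

    Standard Saitou-Nei agglomeration with the usual Q criterion; exact on
    additive matrices. Raises on non-symmetric input.
    """
    d = np.asarray(dist.data, dtype=float)
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")
    labels = list(dist.ids)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    D = d.copy()
    active = list(range(n))
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sums = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = clamp(0.5 * D[i, j] + (sums[i] - sums[j]) / (2 * (m - 2)))
        lj = clamp(D[i, j] - (0.5 * D[i, j] + (sums[i] - sums[j]) / (2 * (m - 2))))
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])
        # new node reuses slot i; distances to remaining nodes
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes[i] = parent
        active.remove(j)

    # join the last three nodes at the unrooted trifurcation; the three
    # pendant lengths solve the three-point equations
    i, j, k = active
    root = TreeNode()
    nodes[i].length = clamp(0.5 * (D[i, j] + D[i, k] - D[j, k]))
    nodes[j].length = clamp(0.5 * (D[i, j] + D[j, k] - D[i, k]))
    nodes[k].length = clamp(0.5 * (D[i, k] + D[j, k] - D[i, j]))
    root.extend([nodes[i], nodes[j], nodes[k]])
    root.clamped_negative_branches = clamped
    return root


def family_coloring(
    tree: TreeNode, assignments: list[FamilyAssignment], k: int = 8
) -> pd.DataFrame:
    """Leaf annotation table assigning a color index to the ``k`` most
    abundant families (by leaf count, ties by name); other families are left
    uncolored (index -1). Raises if a leaf lacks an assignment.
    """
    fam_by_id = {a.query_id: a.family for a in assignments}
    leaves = [t.name for t in tree.tips()]
    missing = [leaf for leaf in leaves if leaf not in fam_by_id]
    if missing:
        raise KeyError(f"no family assignment for leaf {missing[0]!r}")
    counts: dict[str, int] = {}
    for leaf in leaves:
        counts[fam_by_id[leaf]] = counts.get(fam_by_id[leaf], 0) + 1
    top = sorted(counts, key=lambda f: (-counts[f], f))[:k]
    color = {fam: idx for idx, fam in enumerate(top)}
    return pd.DataFrame(
        {
            "leaf_id": leaves,
            "family": [fam_by_id[leaf] for leaf in leaves],
            "color_index": [color.get(fam_by_id[leaf], -1) for leaf in leaves],
        }
    )
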