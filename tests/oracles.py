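"""Independent oracles used by unit and acceptance tests.

These deliberately avoid the implementation's code paths: the Dollo
oracle is a dynamic program over explicit presence states, the triplet
oracle is a per-species truth table, and the tree enumerator builds
every labelled rooted binary topology recursively.
"""

from __future__ import annotations

from itertools import combinations

from cooccur3 import SpeciesTree

INF = float("inf")


def enumerate_rooted_binary_trees(leaves: tuple[str, ...]):
    """Yield every labelled rooted binary topology as a Newick string."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    # split: choose the part of 'rest' that joins 'first' on the left
    for k in range(len(rest)):
        for extra in combinations(rest, k):
            left = (first,) + extra
            right = tuple(x for x in rest if x not in extra)
            if not right:
                continue
            for lt in enumerate_rooted_binary_trees(left):
                for rt in enumerate_rooted_binary_trees(right):
                    yield f"({lt},{rt})"


def all_trees(n: int) -> list[SpeciesTree]:
    leaves = tuple(f"s{i}" for i in range(1, n + 1))
    trees = []
    for nwk in enumerate_rooted_binary_trees(leaves):
        tree = SpeciesTree.from_newick(nwk + ";")
        tree.set_leaf_order(leaves)
        trees.append(tree)
    return trees


def min_dollo_losses(tree: SpeciesTree, presence) -> int:
    """Minimum loss count over all single-gain placements (DP oracle).

    cost(v, 1) assumes the gene is present on the branch above v; a
    child may stay present or be lost (one loss event, after which the
    whole child subtree must be absent).  The gain may sit above any
    node whose subtree contains every present leaf.
    """
    masks = tree.subtree_leaf_masks()
    presence = list(presence)
    n_present = sum(presence)
    assert n_present > 0

    cost: dict[tuple[int, int], float] = {}
    for v in tree.postorder():
        if tree.is_leaf(v):
            col = tree.leaves.index(tree.leaf_name[v])
            cost[(v, 1)] = 0 if presence[col] else INF
            cost[(v, 0)] = INF if presence[col] else 0
        else:
            c1 = 0.0
            c0 = 0.0
            for ch in tree.children[v]:
                c1 += min(cost[(ch, 1)], 1 + cost[(ch, 0)])
                c0 += cost[(ch, 0)]
            cost[(v, 1)] = c1
            cost[(v, 0)] = c0

    best = INF
    for g in range(tree.n_nodes):
        inside = int(sum(1 for i in range(len(presence))
                         if presence[i] and masks[g][i]))
        if inside != n_present:
            continue  # a present leaf would fall outside the gain subtree
        best = min(best, cost[(g, 1)])
    return int(best)


def truth_table_score(a, b, c) -> tuple[int, int, int, int]:
    """Per-species truth-table scoring of a profile triplet."""
    good_b = good_c = bad = 0
    for ai, bi, ci in zip(a, b, c):
        if ai and bi and not ci:
            good_b += 1
        elif ai and not bi and ci:
            good_c += 1
        elif ai and not bi and not ci:
            bad += 1
        elif not ai and (bi or ci):
            bad += 1
    return good_b, good_c, bad, min(good_b, good_c) - bad
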