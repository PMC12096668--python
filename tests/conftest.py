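"""Shared fixtures and independent brute-force oracles."""

from itertools import combinations

import pytest

from gcpsr.phylo_io import Bipartition


# ---------------------------------------------------------------------------
# brute-force tree enumeration (oracle for split compatibility)

def _insert_leaf_everywhere(tree, leaf):
    """All rooted binary trees obtained by attaching ``leaf`` on any edge of
    ``tree`` (tuple representation: a leaf is a string, an internal node a
    pair)."""
    results = [(tree, leaf)]  # attach above the root
    if isinstance(tree, tuple):
        left, right = tree
        results += [(l, right) for l in _insert_leaf_everywhere(left, leaf)]
        results += [(left, r) for r in _insert_leaf_everywhere(right, leaf)]
    return results


def all_rooted_binary_trees(taxa):
    """Every rooted binary topology on the given taxa ((2n-3)!! trees);
    their unrooted split sets cover every unrooted topology."""
    taxa = list(taxa)
    trees = [taxa[0]]
    for leaf in taxa[1:]:
        trees = [t2 for t in trees for t2 in _insert_leaf_everywhere(t, leaf)]
    return trees


def _subtree_leafsets(tree, acc):
    if isinstance(tree, str):
        acc.append(frozenset([tree]))
        return frozenset([tree])
    left = _subtree_leafsets(tree[0], acc)
    right = _subtree_leafsets(tree[1], acc)
    ls = left | right
    acc.append(ls)
    return ls


def splits_of_tree(tree, universe):
    """Non-trivial unrooted splits displayed by a tuple-tree."""
    acc = []
    _subtree_leafsets(tree, acc)
    out = set()
    for ls in acc:
        if 2 <= len(ls) <= len(universe) - 2:
            out.add(frozenset((ls, universe - ls)))
    return out


def conflicts_oracle(universe):
    """Map every unordered pair of non-trivial bipartitions of ``universe``
    to True (conflicting: displayed together by no tree) or False."""
    universe = frozenset(universe)
    trees = all_rooted_binary_trees(sorted(universe))
    split_sets = [splits_of_tree(t, universe) for t in trees]
    bips = []
    seen = set()
    for k in range(2, len(universe) - 1):
        for side in combinations(sorted(universe), k):
            b = Bipartition(frozenset(side), universe)
            if b.key() not in seen:
                seen.add(b.key())
                bips.append(b)
    verdicts = {}
    for i, a in enumerate(bips):
        for b in bips[i:]:
            coexist = any(a.key() in s and b.key() in s for s in split_sets)
            verdicts[(a, b)] = not coexist
    return bips, verdicts


@pytest.fixture(scope="session")
def quartet_conflicts():
    return conflicts_oracle("ABCD")
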