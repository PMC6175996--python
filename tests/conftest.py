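"""Shared fixtures and independent oracles for the test suite.

Oracles here deliberately avoid the code paths they check: patristic
distances are recomputed by brute-force path enumeration on an undirected
adjacency map, MRCAs by ancestor-list intersection, and rank-test p-values
by direct pairwise-count enumeration.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest

from phyloconstraint.treeio import Node, PhyloTree


# -- random tree factory -----------------------------------------------------------


def random_tree(rng: np.random.Generator, n_tips: int, ultrametric: bool = False) -> PhyloTree:
    """Random rooted binary tree, built by successive random joins.

    Branch lengths are iid uniform(0.05, 1.0) unless ultrametric.  Built
    here, independently of the package's Yule generator.
    """
    nodes: dict[int, Node] = {}
    nid = 0
    subtrees = []
    for k in range(n_tips):
        nodes[nid] = Node(nid, None, [], None, f"t{k + 1}")
        subtrees.append(nid)
        nid += 1
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        for child in (a, b):
            nodes[child].parent = nid
            nodes[child].length = float(rng.uniform(0.05, 1.0))
        nodes[nid] = Node(nid, None, [a, b], None, None)
        subtrees.append(nid)
        nid += 1
    root = subtrees[0]
    tree = PhyloTree(nodes, root, rooted=True)
    if ultrametric:
        # stretch terminal branches so all tips reach the maximum depth
        depths = tree.depths()
        h = max(depths[tree.tip_id(t)] for t in tree.tip_labels())
        for t in tree.tip_labels():
            node = tree.nodes[tree.tip_id(t)]
            node.length += h - depths[node.id]
        tree = PhyloTree(tree.nodes, tree.root_id, rooted=True)
    return tree


# -- oracles -----------------------------------------------------------------------


def adjacency(tree: PhyloTree) -> dict[int, list[tuple[int, float]]]:
    adj: dict[int, list[tuple[int, float]]] = {nid: [] for nid in tree.nodes}
    for nid, node in tree.nodes.items():
        if node.parent is not None:
            adj[nid].append((node.parent, node.length or 0.0))
            adj[node.parent].append((nid, node.length or 0.0))
    return adj


def path_sum_oracle(tree: PhyloTree, a_label: str, b_label: str) -> float:
    """Patristic distance by exhaustive DFS path enumeration."""
    adj = adjacency(tree)
    start, goal = tree.tip_id(a_label), tree.tip_id(b_label)
    stack = [(start, {start}, 0.0)]
    while stack:
        cur, seen, total = stack.pop()
        if cur == goal:
            return total  # paths in a tree are unique
        for nxt, w in adj[cur]:
            if nxt not in seen:
                stack.append((nxt, seen | {nxt}, total + w))
    raise AssertionError("no path found; tree is disconnected")


def mrca_oracle(tree: PhyloTree, labels: set[str]) -> int:
    """Deepest shared node of all root-to-tip ancestor paths."""
    paths = []
    for lab in labels:
        path = []
        cur = tree.tip_id(lab)
        while cur is not None:
            path.append(cur)
            cur = tree.nodes[cur].parent
        paths.append(list(reversed(path)))  # root first
    k = 0
    while all(len(p) > k and p[k] == paths[0][k] for p in paths):
        k += 1
    return paths[0][k - 1]


def exact_wmw_oracle(x: list[float], y: list[float], alternative: str = "two-sided") -> float:
    """Exact rank-sum p by enumeration, with U computed by direct pairwise
    counting (greater + half ties) rather than ranks."""

    def u_stat(xs, ys):
        u = 0.0
        for xv in xs:
            for yv in ys:
                if xv > yv:
                    u += 1.0
                elif xv == yv:
                    u += 0.5
        return u

    pooled = list(x) + list(y)
    n = len(x)
    u_obs = u_stat(x, y)
    n_le = n_ge = total = 0
    for idx in combinations(range(len(pooled)), n):
        chosen = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        u = u_stat(chosen, rest)
        total += 1
        if u <= u_obs + 1e-9:
            n_le += 1
        if u >= u_obs - 1e-9:
            n_ge += 1
    p_le, p_ge = n_le / total, n_ge / total
    if alternative == "less":
        return p_le
    if alternative == "greater":
        return p_ge
    return min(1.0, 2.0 * min(p_le, p_ge))


def percentile_oracle(values: list[float], q: float) -> float:
    """Type-7 (linear interpolation) percentile, written out by hand."""
    s = sorted(values)
    if len(s) == 1:
        return s[0]
    h = (len(s) - 1) * q / 100.0
    lo = math.floor(h)
    hi = min(lo + 1, len(s) - 1)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


# -- fixtures ----------------------------------------------------------------------


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def three_tip_tree():
    from phyloconstraint.treeio import parse_newick

    return parse_newick("((A:1,B:1):2,C:3);")
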