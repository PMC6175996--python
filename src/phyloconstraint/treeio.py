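"""Phylogenetic tree parsing, writing, rooting and distance measures.

Trees are stored as an explicit parent/child node table (:class:`PhyloTree`)
so that every downstream statistic — patristic distances, MRCA lookups,
distances from an internal reference node — is a plain path sum over the
table.  Newick parsing is delegated to dendropy; writing is done here so the
round trip preserves branch lengths to 10 significant digits and quotes
labels containing Newick metacharacters.

Branch lengths are substitutions per site.  Zero-length branches are legal
(they occur in real ML trees) but are logged when they touch a node used as
a reference or MRCA.  Polytomies are permitted everywhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import dendropy

from .errors import (
    DuplicateTipLabelError,
    NewickParseError,
    NonMonophyleticOutgroupError,
    UnknownLabelError,
    UnrootedTreeError,
    ValidationError,
)

logger = logging.getLogger(__name__)

_NEWICK_META = set("()[]{}:;,'\" \t\n")


@dataclass
class Node:
    id: int
    parent: int | None
    children: list[int] = field(default_factory=list)
    length: float | None = None   # branch above this node; None only for root
    label: str | None = None
    rate: float = 1.0             # per-branch rate multiplier (simulation annotation)

    @property
    def is_tip(self) -> bool:
        return not self.children


@dataclass
class NodeRef:
    """Handle to a node inside a specific tree."""

    tree: "PhyloTree"
    node_id: int

    def __post_init__(self) -> None:
        if self.node_id not in self.tree.nodes:
            raise UnknownLabelError(f"node id {self.node_id} not in tree")


class PhyloTree:
    """Rooted or unrooted tree with non-negative branch lengths.

    The storage is always a rooted data structure; ``rooted`` records
    whether the root placement is meaningful (bifurcating root) or merely
    an arbitrary anchoring of an unrooted tree (basal polytomy).
    """

    def __init__(self, nodes: dict[int, Node], root_id: int, rooted: bool | None = None):
        self.nodes = nodes
        self.root_id = root_id
        if rooted is None:
            rooted = len(nodes[root_id].children) == 2
        self.rooted = rooted
        self._tip_index: dict[str, int] = {}
        self._validate()

    # -- construction / validation ------------------------------------------------

    def _validate(self) -> None:
        seen_tips: dict[str, int] = {}
        n_root = 0
        for node in self.nodes.values():
            if node.parent is None:
                n_root += 1
                if node.id != self.root_id:
                    raise ValidationError("parentless node is not the designated root")
            else:
                if node.parent not in self.nodes:
                    raise ValidationError(f"node {node.id} has unknown parent {node.parent}")
                if node.length is None:
                    node.length = 0.0
                if not (node.length >= 0.0) or node.length != node.length:
                    raise ValidationError(
                        f"branch length above node {node.id!r} is {node.length}; must be finite and >= 0"
                    )
            if node.is_tip:
                if not node.label:
                    raise ValidationError(f"tip node {node.id} has no label")
                if node.label in seen_tips:
                    raise DuplicateTipLabelError(f"duplicate tip label {node.label!r}")
                seen_tips[node.label] = node.id
        if n_root != 1:
            raise ValidationError(f"tree must have exactly one root, found {n_root}")
        # connectivity: every node must reach the root
        for node in self.nodes.values():
            cur, steps = node, 0
            while cur.parent is not None:
                cur = self.nodes[cur.parent]
                steps += 1
                if steps > len(self.nodes):
                    raise ValidationError("cycle detected in parent links")
            if cur.id != self.root_id:
                raise ValidationError("tree is not connected")
        self._tip_index = seen_tips
        self._depths: dict[int, float] | None = None

    # -- basic accessors ------------------------------------------------------------

    @property
    def root(self) -> Node:
        return self.nodes[self.root_id]

    def tip_labels(self) -> list[str]:
        return [self.nodes[i].label for i in self.preorder() if self.nodes[i].is_tip]

    def tip_id(self, label: str) -> int:
        try:
            return self._tip_index[label]
        except KeyError:
            raise UnknownLabelError(f"unknown tip label {label!r}") from None

    def preorder(self) -> Iterator[int]:
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            yield nid
            stack.extend(reversed(self.nodes[nid].children))

    def postorder(self) -> Iterator[int]:
        out: list[int] = list(self.preorder())
        return iter(reversed(out))

    def copy(self) -> "PhyloTree":
        nodes = {
            nid: Node(n.id, n.parent, list(n.children), n.length, n.label, n.rate)
            for nid, n in self.nodes.items()
        }
        return PhyloTree(nodes, self.root_id, self.rooted)

    def n_tips(self) -> int:
        return len(self._tip_index)

    # -- path machinery --------------------------------------------------------------

    def ancestor_path(self, node_id: int) -> list[int]:
        """Node ids from ``node_id`` up to and including the root."""
        path = [node_id]
        while self.nodes[path[-1]].parent is not None:
            path.append(self.nodes[path[-1]].parent)
        return path

    def depths(self) -> dict[int, float]:
        """Path length from the root to every node (cached)."""
        if self._depths is None:
            d: dict[int, float] = {self.root_id: 0.0}
            for nid in self.preorder():
                if nid == self.root_id:
                    continue
                node = self.nodes[nid]
                d[nid] = d[node.parent] + (node.length or 0.0)
            self._depths = d
        return self._depths

    def _mrca_ids(self, node_ids: Iterable[int]) -> int:
        paths = [set(self.ancestor_path(nid)) for nid in node_ids]
        common = set.intersection(*paths)
        # deepest common ancestor = the one whose ancestor path is longest
        return max(common, key=lambda nid: len(self.ancestor_path(nid)))

    def mrca(self, tip_labels: Iterable[str]) -> NodeRef:
        """Deepest node ancestral to all named tips (rooted trees only)."""
        labels = list(tip_labels)
        if not labels:
            raise ValidationError("mrca requires a non-empty tip set")
        if not self.rooted:
            raise UnrootedTreeError(
                "mrca is undefined on an unrooted tree; call root_by_outgroup first"
            )
        ids = [self.tip_id(lab) for lab in labels]
        mid = self._mrca_ids(ids)
        if self.nodes[mid].length == 0.0 and mid != self.root_id:
            logger.warning("MRCA node %s sits below a zero-length branch", mid)
        return NodeRef(self, mid)

    def node_distance(self, a_id: int, b_id: int) -> float:
        """Path length between two nodes, summed branch by branch."""
        m = self._mrca_ids([a_id, b_id])
        total = 0.0
        for start in (a_id, b_id):
            cur = start
            while cur != m:
                node = self.nodes[cur]
                total += node.length or 0.0
                cur = node.parent
        return total

    def patristic(self, a: str, b: str) -> float:
        """Sum of branch lengths along the unique tip-to-tip path."""
        return self.node_distance(self.tip_id(a), self.tip_id(b))

    def distances_from(self, node: NodeRef | int) -> dict[str, float]:
        """Path length from a node to every tip."""
        nid = node.node_id if isinstance(node, NodeRef) else node
        if nid not in self.nodes:
            raise UnknownLabelError(f"node id {nid} not in tree")
        return {lab: self.node_distance(nid, tid) for lab, tid in sorted(self._tip_index.items())}

    def distance_matrix(self) -> tuple[list[str], list[list[float]]]:
        labels = sorted(self._tip_index)
        mat = [[0.0] * len(labels) for _ in labels]
        for i, a in enumerate(labels):
            for j in range(i + 1, len(labels)):
                d = self.patristic(a, labels[j])
                mat[i][j] = mat[j][i] = d
        return labels, mat

    def tipset(self, node_id: int) -> frozenset[str]:
        """Labels of all tips at or below a node."""
        out = []
        stack = [node_id]
        while stack:
            nid = stack.pop()
            node = self.nodes[nid]
            if node.is_tip:
                out.append(node.label)
            stack.extend(node.children)
        return frozenset(out)

    def bipartitions(self) -> set[frozenset[str]]:
        """Unrooted bipartitions, each as the smaller-side normalized tip set."""
        all_tips = frozenset(self._tip_index)
        splits: set[frozenset[str]] = set()
        for nid in self.preorder():
            if nid == self.root_id:
                continue
            below = self.tipset(nid)
            if 1 < len(below) < len(all_tips) - 1:
                other = all_tips - below
                splits.add(min(below, other, key=lambda s: (len(s), tuple(sorted(s)))))
        return splits

    # -- rooting ---------------------------------------------------------------------

    def root_by_outgroup(self, outgroup_tips: Iterable[str]) -> "PhyloTree":
        """Re-root on the branch separating the outgroup from the ingroup.

        The root bisects that stem branch 50/50, so all tip-to-tip patristic
        distances are preserved.
        """
        og = frozenset(outgroup_tips)
        if not og:
            raise ValidationError("outgroup set is empty")
        for lab in og:
            self.tip_id(lab)
        all_tips = frozenset(self._tip_index)
        if og == all_tips:
            raise ValidationError("outgroup cannot contain every tip")
        target = None
        for nid in self.preorder():
            if nid == self.root_id:
                continue
            below = self.tipset(nid)
            if below == og or all_tips - below == og:
                target = nid
                break
        if target is None:
            raise NonMonophyleticOutgroupError(
                f"outgroup {sorted(og)} is not a clade in the unrooted tree; "
                f"no edge separates it from the ingroup"
            )
        root = self.nodes[self.root_id]
        if self.nodes[target].parent == self.root_id and len(root.children) == 2:
            # the stored root is a degree-2 node on the stem itself: in the
            # unrooted tree the separating branch is the two root edges
            # merged, so bisect their combined length
            tree = self.copy()
            a, b = tree.root.children
            sibling = b if target == a else a
            total = (tree.nodes[a].length or 0.0) + (tree.nodes[b].length or 0.0)
            tree.nodes[target].length = total
            tree.nodes[sibling].length = 0.0
            return tree._reroot_on_edge(target)
        return self._reroot_on_edge(target)

    def _reroot_on_edge(self, child_id: int) -> "PhyloTree":
        """New tree rooted at the midpoint of the edge above ``child_id``."""
        tree = self.copy()
        child = tree.nodes[child_id]
        half = (child.length or 0.0) / 2.0
        child_rate = child.rate
        new_root_id = max(tree.nodes) + 1
        # path from the edge's upper node to the old root, with old edge data
        path = [child.parent]
        while tree.nodes[path[-1]].parent is not None:
            path.append(tree.nodes[path[-1]].parent)
        old_lengths = [tree.nodes[nid].length for nid in path]
        old_rates = [tree.nodes[nid].rate for nid in path]
        # detach the split edge and hang the child side off the new root
        tree.nodes[path[0]].children.remove(child_id)
        child.parent = new_root_id
        child.length = half
        # flip parent links along the path; each flipped edge keeps its length/rate
        for k, nid in enumerate(path):
            node = tree.nodes[nid]
            if k == 0:
                node.parent = new_root_id
                node.length = half
                node.rate = child_rate
            else:
                prev = path[k - 1]
                node.children.remove(prev)
                tree.nodes[prev].children.append(nid)
                node.parent = prev
                node.length = old_lengths[k - 1]
                node.rate = old_rates[k - 1]
        root = Node(new_root_id, None, [child_id, path[0]], None, None)
        tree.nodes[new_root_id] = root
        tree.root_id = new_root_id
        # suppress a unifurcation left at the old root
        old_root = tree.nodes[path[-1]]
        if len(old_root.children) == 1 and not old_root.is_tip:
            only = tree.nodes[old_root.children[0]]
            only.length = (only.length or 0.0) + (old_root.length or 0.0)
            only.parent = old_root.parent
            siblings = tree.nodes[old_root.parent].children
            siblings[siblings.index(old_root.id)] = only.id
            del tree.nodes[old_root.id]
        return PhyloTree(tree.nodes, new_root_id, rooted=True)

    # -- reporting --------------------------------------------------------------------

    def validation_report(self) -> str:
        """Tab-separated summary: node counts, zero-length branches, tips."""
        n_zero = sum(
            1 for n in self.nodes.values() if n.parent is not None and (n.length or 0.0) == 0.0
        )
        tips = ",".join(sorted(self._tip_index))
        lines = [
            "field\tvalue",
            f"n_nodes\t{len(self.nodes)}",
            f"n_tips\t{self.n_tips()}",
            f"rooted\t{self.rooted}",
            f"zero_length_branches\t{n_zero}",
            f"tips\t{tips}",
        ]
        return "\n".join(lines) + "\n"


# -- Newick I/O ----------------------------------------------------------------------


def parse_newick(text: str) -> PhyloTree:
    """Parse a single Newick statement into a :class:`PhyloTree`.

    Internal values after ')' are treated as labels; single-quoted labels and
    bracketed comments are supported; missing branch lengths default to 0
    with a warning (distance statistics are meaningless without lengths).
    """
    text = text.strip()
    if not text.endswith(";"):
        raise NewickParseError(
            f"Newick statement must end with ';' (offset {len(text)}): {text[-20:]!r}"
        )
    if text.count("(") != text.count(")"):
        off = len(text)
        raise NewickParseError(f"unbalanced parentheses in Newick (length {off})")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises a zoo of error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    nodes: dict[int, Node] = {}
    ids: dict[object, int] = {}
    missing_lengths = 0
    for i, dnode in enumerate(dtree.preorder_node_iter()):
        ids[dnode] = i
        parent = ids[dnode.parent_node] if dnode.parent_node is not None else None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        length = dnode.edge.length
        if parent is not None and length is None:
            missing_lengths += 1
            length = 0.0
        nodes[i] = Node(i, parent, [], length, label)
    for dnode, i in ids.items():
        if dnode.parent_node is not None:
            nodes[ids[dnode.parent_node]].children.append(i)
    if missing_lengths:
        warnings.warn(
            f"{missing_lengths} branch(es) without length set to 0; "
            "distance statistics on this tree are unreliable",
            stacklevel=2,
        )
    return PhyloTree(nodes, 0)


def _format_label(label: str) -> str:
    if any(c in _NEWICK_META for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_length(x: float | None) -> str:
    if x is None:
        return ""
    return ":" + format(float(x), ".10g")


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree; re-parsing yields identical topology/lengths/labels."""

    def render(nid: int) -> str:
        node = tree.nodes[nid]
        if node.is_tip:
            core = _format_label(node.label)
        else:
            core = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.label:
                core += _format_label(node.label)
        if node.parent is not None:
            core += _format_length(node.length)
        return core

    return render(tree.root_id) + ";"


def read_newick_file(path) -> PhyloTree:
    with open(path, encoding="utf-8") as fh:
        return parse_newick(fh.read())


def write_newick_file(tree: PhyloTree, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_newick(tree) + "\n")
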