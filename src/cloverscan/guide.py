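"""Guide-tree construction for profile-SCFG models.

A balanced, nested consensus structure is turned into a deterministic tree
of typed nodes: left-emitting singles (MATL), right-emitting singles
(MATR), base-pair nodes (PAIR), bifurcations (BIF) where a loop encloses
two or more helices, one ROOT, and END leaves.  The in-order traversal of
the emitting nodes recovers the consensus structure exactly; a multiloop
holding *n* helices yields *n* - 1 bifurcations, so a canonical cloverleaf
produces two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .formats import parse_pairs

ROOT, MATL, MATR, PAIR, BIF, END = range(6)
KIND_NAMES = ["ROOT", "MATL", "MATR", "PAIR", "BIF", "END"]


@dataclass
class GuideNode:
    kind: int
    colL: int = -1           # consensus column emitted on the left edge
    colR: int = -1           # consensus column emitted on the right edge
    children: list = field(default_factory=list)
    index: int = -1          # position in the pre-order flattening
    parent: int = -1


@dataclass
class GuideTree:
    nodes: list               # pre-order: parents before children
    ncols: int
    pairs: dict               # consensus column -> partner column

    @property
    def root(self) -> GuideNode:
        return self.nodes[0]

    def count(self, kind: int) -> int:
        return sum(1 for n in self.nodes if n.kind == kind)

    def columns_inorder(self) -> list:
        """Emitting-order column indices; recovers the consensus structure."""
        out = []

        def visit(node: GuideNode) -> None:
            if node.kind in (MATL, PAIR):
                out.append(node.colL)
            for ch in node.children:
                visit(ch)
            if node.kind in (MATR, PAIR):
                out.append(node.colR)

        visit(self.root)
        return out

    def column_owner(self) -> dict:
        """Map consensus column -> (node, side) with side 'L' or 'R'."""
        owner = {}
        for n in self.nodes:
            if n.colL >= 0:
                owner[n.colL] = (n, "L")
            if n.colR >= 0:
                owner[n.colR] = (n, "R")
        return owner


def build_guide_tree(ss_cons: str) -> GuideTree:
    """Build the deterministic guide tree for a consensus structure string.

    Raises :class:`StructureError` on unbalanced or crossing brackets.
    """
    pairs = parse_pairs(ss_cons)
    ncols = len(ss_cons)

    def build(lo: int, hi: int) -> GuideNode:
        if lo > hi:
            return GuideNode(END)
        if lo not in pairs:
            return GuideNode(MATL, colL=lo, children=[build(lo + 1, hi)])
        if hi not in pairs:
            return GuideNode(MATR, colR=hi, children=[build(lo, hi - 1)])
        k = pairs[lo]
        if k == hi:
            return GuideNode(PAIR, colL=lo, colR=hi,
                             children=[build(lo + 1, hi - 1)])
        # lo's helix closes before hi: split the level here.
        return GuideNode(BIF, children=[build(lo, k), build(k + 1, hi)])

    root = GuideNode(ROOT, children=[build(0, ncols - 1)])

    flat: list = []

    def flatten(node: GuideNode, parent: int) -> None:
        node.index = len(flat)
        node.parent = parent
        flat.append(node)
        for ch in node.children:
            flatten(ch, node.index)

    flatten(root, -1)
    return GuideTree(nodes=flat, ncols=ncols, pairs=pairs)


def region_owners(tree: GuideTree) -> dict:
    """Assign every between-column region to its unique insert slot.

    Region ``c`` holds residues inserted between consensus column ``c`` and
    ``c + 1`` (region ``-1`` precedes the first column).  Slots are
    ``(node_index, 'L'|'R')``: the run after a left emission belongs to that
    node's left slot; the run just before a right emission to that node's
    right slot; the gap between two helices of a multiloop to the enclosing
    BIF's slot; sequence ends fall to ROOT's left/right slots.
    """
    owner = tree.column_owner()
    nodes = tree.nodes
    result = {}

    def lca(a: GuideNode, b: GuideNode) -> GuideNode:
        seen = set()
        while a.index != -1:
            seen.add(a.index)
            if a.parent == -1:
                break
            a = nodes[a.parent]
        while b.index not in seen:
            b = nodes[b.parent]
        return b

    result[-1] = (0, "L")  # ROOT left slot
    for c in range(tree.ncols):
        if c == tree.ncols - 1:
            na, sa = owner[c]
            result[c] = (na.index, "L") if sa == "L" else (0, "R")
            continue
        na, sa = owner[c]
        nb, sb = owner[c + 1]
        if sa == "L":
            result[c] = (na.index, "L")
        elif sb == "R":
            result[c] = (nb.index, "R")
        else:
            anc = lca(na, nb)
            if anc.kind != BIF:
                raise AssertionError("region between helices not under a BIF")
            result[c] = (anc.index, "L")
    return result
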