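"""Rooted-tree model of linear and branched gluco-oligosaccharides.

A glycan is a rooted tree of glucose residues joined by β1→3 or β1→6
glycosidic bonds.  The root carries the reducing end (free anomeric C1);
a borohydride-reduced root is a glucitol (alditol) and the molecule has
no reducing-sugar character.  Every bond runs from the child's C1 to the
parent's O3 or O6, so each residue holds at most one substituent per
acceptor position.  Anomeric configuration is uniformly β and is recorded
only as the constant ``b`` in the string dialect.

String dialect (condensed-IUPAC style)
--------------------------------------
Residues are written left to right from the non-reducing end toward the
root: ``Glc(b1-3)Glc`` is laminaribiose.  A branch is enclosed in square
brackets immediately before its parent residue, with its linkage inside
the bracket: ``Glc(b1-3)[Glc(b1-6)]Glc`` is a trimer whose root bears
both an O3 and an O6 substituent.  An ``-ol`` suffix on the whole string
marks a reduced (glucitol) root.  Registered shorthand aliases: ``Glc``,
``LAM2`` … ``LAM20``, ``LAM2ol`` … ``LAM20ol`` (linear all-1,3 chains,
optionally reduced) and ``H8``/``H11``/``H14`` (default hybrid
oligomers; pentamer backbone with 1,6-linked trimer branches).

Canonical form: at each residue the O3 subtree is written inline and the
O6 subtree in brackets, so equal trees serialize identically regardless
of construction order; equality and hashing use the canonical string.
"""

from __future__ import annotations

import re
from typing import Iterable, Iterator, Optional, Sequence

GLUCOSYL = "glucosyl"
GLUCITOL = "glucitol"

#: Acceptor positions of a glycosidic bond (child C1 -> parent O3 / O6).
O3 = 3
O6 = 6

# Mass constants (average g/mol, monoisotopic Da).  Only [M+Na]+ centroids
# of neutral hexose oligomers are modelled; no isotope envelopes.
AVERAGE_ANHYDROHEXOSE = 162.141
MONOISOTOPIC_ANHYDROHEXOSE = 162.0528
AVERAGE_WATER = 18.015
MONOISOTOPIC_WATER = 18.0106
MONOISOTOPIC_SODIUM = 22.9898
#: Mass increment of an alditol (reduced C1) over the parent aldose, +H2.
AVERAGE_REDUCTION = 2.016
MONOISOTOPIC_REDUCTION = 2.0157

#: Monoisotopic spacing of a +DP3 product series (three anhydrohexoses).
DP3_MASS_SPACING = 3 * MONOISOTOPIC_ANHYDROHEXOSE

#: Branch attachment restricted to the three backbone O6 positions nearest
#: the non-reducing end (the three-isomer model of the hybrid octamer).
ATTACH_NEAR_TERMINAL = "near_terminal"
#: Branch attachment allowed at every backbone O6.
ATTACH_ALL_O6 = "all_o6"

_ATTACHMENT_MODELS = (ATTACH_NEAR_TERMINAL, ATTACH_ALL_O6)


class GlycanError(ValueError):
    """Invalid glycan structure or operation."""


class GlycanParseError(GlycanError):
    """Malformed glycan string."""


class _Node:
    __slots__ = ("kind", "o3", "o6")

    def __init__(self, kind: str = GLUCOSYL,
                 o3: Optional["_Node"] = None,
                 o6: Optional["_Node"] = None) -> None:
        self.kind = kind
        self.o3 = o3
        self.o6 = o6

    def child(self, position: int) -> Optional["_Node"]:
        if position == O3:
            return self.o3
        if position == O6:
            return self.o6
        raise GlycanError(f"invalid acceptor position {position!r}")

    def set_child(self, position: int, node: "_Node") -> None:
        if self.child(position) is not None:
            raise GlycanError(f"two substituents at O{position}")
        if position == O3:
            self.o3 = node
        else:
            self.o6 = node

    def copy(self) -> "_Node":
        return _Node(self.kind,
                     self.o3.copy() if self.o3 else None,
                     self.o6.copy() if self.o6 else None)


class Glycan:
    """Immutable rooted tree of glucosyl/glucitol residues."""

    __slots__ = ("_root", "_canon", "_dp")

    def __init__(self, root: _Node, _copy: bool = True) -> None:
        self._root = root.copy() if _copy else root
        self._canon: Optional[str] = None
        self._dp = self._validate()

    # -- construction ---------------------------------------------------

    @classmethod
    def from_bonds(cls, kinds: Sequence[str],
                   bonds: Iterable[tuple[int, int, int]]) -> "Glycan":
        """Build a glycan from residue kinds and (child, parent, position)
        bonds; residues are indexed 0..n-1 and exactly one must be root."""
        nodes = []
        for k in kinds:
            if k not in (GLUCOSYL, GLUCITOL):
                raise GlycanError(f"unknown residue kind {k!r}")
            nodes.append(_Node(k))
        has_parent = set()
        for child, parent, pos in bonds:
            if child in has_parent:
                raise GlycanError(f"residue {child} has two parents")
            nodes[parent].set_child(pos, nodes[child])
            has_parent.add(child)
        roots = [i for i in range(len(nodes)) if i not in has_parent]
        if len(roots) != 1:
            raise GlycanError(f"expected exactly one root, found {len(roots)}")
        return cls(nodes[roots[0]], _copy=False)

    # -- validation -----------------------------------------------------

    def _validate(self) -> int:
        seen: set[int] = set()

        def visit(node: _Node, is_root: bool) -> int:
            if id(node) in seen:
                raise GlycanError("residue graph is not a tree")
            seen.add(id(node))
            if node.kind == GLUCITOL and not is_root:
                raise GlycanError("glucitol allowed only at the root")
            n = 1
            for c in (node.o3, node.o6):
                if c is not None:
                    n += visit(c, False)
            return n

        return visit(self._root, True)

    # -- basic properties -----------------------------------------------

    @property
    def dp(self) -> int:
        """Degree of polymerization (residue count)."""
        return self._dp

    @property
    def reduced(self) -> bool:
        """True when the root is a glucitol (borohydride-reduced end)."""
        return self._root.kind == GLUCITOL

    @property
    def is_linear_13(self) -> bool:
        """True for an unbranched, all-β1→3 chain."""
        node = self._root
        while node is not None:
            if node.o6 is not None:
                return False
            node = node.o3
        return True

    @property
    def has_o6_bond(self) -> bool:
        return any(pos == O6 for _, _, pos in self.bonds())

    @property
    def is_branched(self) -> bool:
        """True when some residue bears substituents at both O3 and O6."""
        return any(n.o3 is not None and n.o6 is not None
                   for _, n, _ in self.walk())

    # -- traversal ------------------------------------------------------

    def walk(self) -> Iterator[tuple[tuple[int, ...], _Node, list[_Node]]]:
        """Preorder traversal yielding (path, node, ancestors).

        ``path`` is the tuple of acceptor positions from the root;
        ``ancestors`` runs root-first and excludes the node itself.
        """
        stack: list[tuple[tuple[int, ...], _Node, list[_Node]]] = [((), self._root, [])]
        while stack:
            path, node, anc = stack.pop()
            yield path, node, anc
            for pos in (O6, O3):
                c = node.child(pos)
                if c is not None:
                    stack.append((path + (pos,), c, anc + [node]))

    def residues(self) -> list[tuple[int, str]]:
        """(ordinal, kind) pairs in canonical preorder; the root is 0."""
        order = sorted(self.walk(), key=lambda t: t[0])
        return [(i, node.kind) for i, (_, node, _) in enumerate(order)]

    def bonds(self) -> list[tuple[int, int, int]]:
        """(child ordinal, parent ordinal, acceptor position) triples."""
        order = sorted(self.walk(), key=lambda t: t[0])
        index = {path: i for i, (path, _, _) in enumerate(order)}
        out = []
        for path, _, _ in order:
            if path:
                out.append((index[path], index[path[:-1]], path[-1]))
        return out

    def node_at(self, path: tuple[int, ...]) -> _Node:
        node = self._root
        for pos in path:
            node = node.child(pos)
            if node is None:
                raise GlycanError(f"no residue at path {path}")
        return node

    def leaves(self) -> list[tuple[tuple[int, ...], _Node, list[_Node]]]:
        return [(p, n, a) for p, n, a in self.walk()
                if n.o3 is None and n.o6 is None]

    def backbone(self) -> list[_Node]:
        """Main chain: residues reached from the root through O3 bonds,
        index 0 = reducing end, last = non-reducing end of the backbone."""
        out = []
        node: Optional[_Node] = self._root
        while node is not None:
            out.append(node)
            node = node.o3
        return out

    # -- derived structures ---------------------------------------------

    def without_leaf(self, path: tuple[int, ...]) -> "Glycan":
        """Copy of this glycan with the leaf residue at ``path`` removed."""
        if not path:
            raise GlycanError("cannot remove the root residue")
        target = self.node_at(path)
        if target.o3 is not None or target.o6 is not None:
            raise GlycanError("can only remove a terminal residue")
        root = self._root.copy()
        parent = root
        for pos in path[:-1]:
            parent = parent.child(pos)  # type: ignore[assignment]
        if path[-1] == O3:
            parent.o3 = None
        else:
            parent.o6 = None
        return Glycan(root, _copy=False)

    def with_o6_branch(self, backbone_position: int, branch: "Glycan") -> "Glycan":
        """Copy with ``branch`` attached through a β1→6 bond at the given
        backbone residue (1-indexed from the reducing end)."""
        if branch.reduced:
            raise GlycanError("a reduced chain cannot act as a branch")
        root = self._root.copy()
        chain = []
        node: Optional[_Node] = root
        while node is not None:
            chain.append(node)
            node = node.o3
        if not 1 <= backbone_position <= len(chain):
            raise GlycanError(
                f"backbone position {backbone_position} outside 1..{len(chain)}")
        chain[backbone_position - 1].set_child(O6, branch._root.copy())
        return Glycan(root, _copy=False)

    def free_o6_backbone_positions(self) -> list[int]:
        return [i + 1 for i, n in enumerate(self.backbone()) if n.o6 is None]

    # -- serialization / identity ---------------------------------------

    @property
    def canonical(self) -> str:
        if self._canon is None:
            self._canon = _serialize(self._root) + ("-ol" if self.reduced else "")
        return self._canon

    def __str__(self) -> str:
        return self.canonical

    def __repr__(self) -> str:
        return f"Glycan({self.canonical!r})"

    def __eq__(self, other: object):
        if not isinstance(other, Glycan):
            return NotImplemented
        return self.canonical == other.canonical

    def __hash__(self) -> int:
        return hash(self.canonical)


# -- serialization ------------------------------------------------------

def _serialize(node: _Node) -> str:
    if node.o3 is not None and node.o6 is not None:
        return (_serialize(node.o3) + "(b1-3)"
                + "[" + _serialize(node.o6) + "(b1-6)]" + "Glc")
    if node.o3 is not None:
        return _serialize(node.o3) + "(b1-3)Glc"
    if node.o6 is not None:
        return _serialize(node.o6) + "(b1-6)Glc"
    return "Glc"


def serialize_glycan(g: Glycan) -> str:
    """Canonical string for ``g``; equal glycans serialize identically."""
    return g.canonical


# -- parsing ------------------------------------------------------------

_RES_RE = re.compile(r"Glc(?:\(b1-([36])\))?")


def _parse_chain(s: str, offset: int = 0) -> _Node:
    # Tokenize one chain level: bracketed branches and Glc residues with
    # optional linkage; the final (linkage-free) residue is the local root.
    elements: list[tuple] = []
    i = 0
    while i < len(s):
        if s[i] == "[":
            depth, j = 1, i + 1
            while j < len(s) and depth:
                if s[j] == "[":
                    depth += 1
                elif s[j] == "]":
                    depth -= 1
                j += 1
            if depth:
                raise GlycanParseError(
                    f"unbalanced '[' at position {offset + i}")
            inner = s[i + 1:j - 1]
            m = re.search(r"\(b1-([36])\)$", inner)
            if m is None:
                raise GlycanParseError(
                    f"branch {inner!r} lacks a trailing linkage")
            sub = _parse_chain(inner[:m.start()], offset + i + 1)
            elements.append(("branch", sub, int(m.group(1))))
            i = j
        else:
            m = _RES_RE.match(s, i)
            if m is None or m.start() != i:
                raise GlycanParseError(
                    f"unexpected token {s[i:i + 12]!r} at position {offset + i}")
            pos = int(m.group(1)) if m.group(1) else None
            elements.append(("res", pos))
            i = m.end()

    pending_child: Optional[tuple[_Node, int]] = None
    pending_branches: list[tuple[_Node, int]] = []
    root: Optional[_Node] = None
    for k, el in enumerate(elements):
        if el[0] == "branch":
            pending_branches.append((el[1], el[2]))
            continue
        node = _Node(GLUCOSYL)
        if pending_child is not None:
            node.set_child(pending_child[1], pending_child[0])
            pending_child = None
        for b, pos in pending_branches:
            node.set_child(pos, b)
        pending_branches = []
        if el[1] is None:
            if k != len(elements) - 1:
                raise GlycanParseError(
                    "residue without linkage before the end of a chain")
            root = node
        else:
            pending_child = (node, el[1])
    if root is None or pending_child is not None or pending_branches:
        raise GlycanParseError(f"chain {s!r} lacks a terminal root residue")
    return root


def _expand_alias(text: str) -> Optional[Glycan]:
    if re.fullmatch(r"(?i)glc", text):
        return make_linear(1)
    if re.fullmatch(r"(?i)glc-?ol", text):
        return make_linear(1, reduced=True)
    m = re.fullmatch(r"(?i)lam(\d+)(ol)?", text)
    if m:
        n = int(m.group(1))
        if not 2 <= n <= 20:
            raise GlycanParseError(f"alias {text!r}: DP must be in 2..20")
        return make_linear(n, reduced=bool(m.group(2)))
    m = re.fullmatch(r"(?i)h(\d+)", text)
    if m:
        n = int(m.group(1))
        # Default hybrid series: shortest donor-derived backbone (DP 5-7)
        # plus trimer branches filled innermost-first over the three
        # near-terminal O6 positions: H8/H11/H14 are 5+3k, H9/H12 are
        # 6+3k, H10/H13 are 7+3k.
        backbone = 5 + (n - 5) % 3
        k = (n - backbone) // 3
        if n < 8 or k < 1 or k > 3:
            raise GlycanParseError(
                f"alias {text!r}: hybrid DP must be in 8..16")
        positions = (backbone - 2, backbone - 1, backbone)
        return make_hybrid(backbone, {p: 3 for p in positions[:k]})
    return None


def parse_glycan(text: str) -> Glycan:
    """Parse a glycan string (dialect above) or a registered alias."""
    t = text.strip()
    if not t:
        raise GlycanParseError("empty glycan string")
    alias = _expand_alias(t)
    if alias is not None:
        return alias
    reduced = t.endswith("-ol")
    body = t[:-3] if reduced else t
    root = _parse_chain(body)
    if reduced:
        root.kind = GLUCITOL
    return Glycan(root, _copy=False)


# -- constructors -------------------------------------------------------

def make_linear(n: int, reduced: bool = False) -> Glycan:
    """Linear all-β1→3 chain of DP ``n``; glucitol root iff ``reduced``."""
    if n < 1:
        raise GlycanError(f"DP must be >= 1, got {n}")
    node = _Node(GLUCOSYL)
    for _ in range(n - 1):
        node = _Node(GLUCOSYL, o3=node)
    # Chain was built leaf-first; the last node created is the root.
    root = node
    if reduced:
        root.kind = GLUCITOL
    return Glycan(root, _copy=False)


def make_hybrid(backbone_dp: int, branches: dict[int, int],
                reduced: bool = False) -> Glycan:
    """Linear 1,3 backbone with linear 1,3 branches attached via β1→6.

    ``branches`` maps 1-indexed backbone positions (1 = reducing end) to
    branch DP.
    """
    g = make_linear(backbone_dp, reduced=reduced)
    for position in sorted(branches):
        g = g.with_o6_branch(position, make_linear(branches[position]))
    return g


def enumerate_hybrid_isomers(backbone_dp: int, branch_dp: int,
                             model: str = ATTACH_NEAR_TERMINAL) -> list[Glycan]:
    """Distinct hybrids from one β1→6 attachment of a linear 1,3 branch.

    ``near_terminal`` restricts attachment to the three backbone positions
    nearest the non-reducing end (three isomers for a 5+3 hybrid);
    ``all_o6`` allows every backbone O6.
    """
    if model not in _ATTACHMENT_MODELS:
        raise GlycanError(f"unknown attachment model {model!r}")
    if backbone_dp < 1 or branch_dp < 0:
        raise GlycanError("backbone_dp must be >= 1 and branch_dp >= 0")
    if branch_dp > backbone_dp:
        raise GlycanError(
            f"branch DP {branch_dp} exceeds backbone DP {backbone_dp}")
    if branch_dp == 0:
        return [make_linear(backbone_dp)]
    positions = (range(max(1, backbone_dp - 2), backbone_dp + 1)
                 if model == ATTACH_NEAR_TERMINAL
                 else range(1, backbone_dp + 1))
    seen: dict[str, Glycan] = {}
    for p in positions:
        g = make_hybrid(backbone_dp, {p: branch_dp})
        seen.setdefault(g.canonical, g)
    return sorted(seen.values(), key=lambda g: g.canonical)


# -- mass arithmetic ----------------------------------------------------

def molar_mass(g: Glycan, flavor: str = "average") -> float:
    """Molar mass of ``g``.

    ``average``: sum of average anhydrohexose masses plus one water (plus
    the alditol increment for a reduced root).  ``monoisotopic``: same with
    monoisotopic constants.  ``integer``: average rounded to the nearest
    integer g/mol — the convention used for tabulated µg→nmol conversion
    (180, 342, 504, 1315 for DP 1, 2, 3, 8).
    """
    if flavor in ("average", "integer"):
        m = g.dp * AVERAGE_ANHYDROHEXOSE + AVERAGE_WATER
        if g.reduced:
            m += AVERAGE_REDUCTION
        return float(round(m)) if flavor == "integer" else m
    if flavor == "monoisotopic":
        m = g.dp * MONOISOTOPIC_ANHYDROHEXOSE + MONOISOTOPIC_WATER
        if g.reduced:
            m += MONOISOTOPIC_REDUCTION
        return m
    raise GlycanError(f"unknown mass flavor {flavor!r}")


def mz_sodiated(g: Glycan) -> float:
    """Monoisotopic m/z of the singly sodiated molecular ion [M+Na]+."""
    return molar_mass(g, "monoisotopic") + MONOISOTOPIC_SODIUM


# -- naming -------------------------------------------------------------

def species_label(g: Glycan) -> str:
    """Field-style shorthand: Glc, LAMn(/ol), Hn for hybrids, X for the
    uncleavable 1,6-containing trimer by-product."""
    if g.is_linear_13:
        if g.dp == 1:
            return "Glc-ol" if g.reduced else "Glc"
        return f"LAM{g.dp}" + ("ol" if g.reduced else "")
    if g.dp == 3:
        return "X"
    return f"H{g.dp}" + ("ol" if g.reduced else "")
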