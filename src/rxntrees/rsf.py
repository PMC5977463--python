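"""Tree structures and the reaction string format (RSF).

A reaction's decomposition is a binary tree: internal nodes record which
rule split the remaining sub-reaction (``balance`` or ``count``), tips
are either a compound pair (one substrate paired with one product) or a
loner compound left unpaired on one side.

RSF is the parenthesised text encoding of such a tree::

    >(!(C00631_)(C00631_C00074))      ids mode (illustrative)
    >(!(C)(C_C))                      pattern mode

Grammar: root ``>`` then a node; an internal node is ``(`` marker child
child ``)`` where the marker is ``!`` (balance) or ``!!`` (count); a pair
tip is ``(Ca_Cb)`` with the substrate first; a loner tip is ``(Ca_)``
(substrate side) or ``(_Ca)`` (product side).  Pattern mode replaces
every compound id with ``C`` and drops the loner side marker, so equal
patterns mean identical topology plus rule markers.  The verbose form
``root(balance(...)(...))`` is accepted on input; the compact ``>`` form
is canonical on output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Union

__all__ = [
    "Internal",
    "PairTip",
    "LonerTip",
    "TreeNode",
    "TreeStructure",
    "RsfError",
    "to_rsf",
    "parse_rsf",
    "topology_pattern",
    "tree_to_json",
    "tree_from_json",
    "write_trees_tsv",
    "read_trees_tsv",
]

BALANCE = "balance"
COUNT = "count"


class RsfError(ValueError):
    """Malformed RSF text."""


@dataclass(frozen=True)
class PairTip:
    """A substrate paired with a product."""

    substrate_id: str
    product_id: str

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.substrate_id, self.product_id))


@dataclass(frozen=True)
class LonerTip:
    """A compound left unpaired; ``side`` is substrate/product (or None
    for tips parsed from pattern-mode text, which does not record it)."""

    compound_id: str
    side: str | None

    def __post_init__(self) -> None:
        if self.side not in ("substrate", "product", None):
            raise ValueError(f"bad loner side {self.side!r}")


@dataclass(frozen=True)
class Internal:
    """A split: the remainder subtree on the left, the selected element
    of the Cartesian product on the right."""

    rule: str
    left: "TreeNode"
    right: "TreeNode"

    def __post_init__(self) -> None:
        if self.rule not in (BALANCE, COUNT):
            raise ValueError(f"bad rule {self.rule!r}")


TreeNode = Union[Internal, PairTip, LonerTip]


@dataclass(frozen=True)
class TreeStructure:
    reaction_id: str
    root: TreeNode
    rules_used: frozenset[str] = field(default_factory=frozenset)

    @staticmethod
    def from_root(reaction_id: str, root: TreeNode) -> "TreeStructure":
        return TreeStructure(reaction_id, root,
                             frozenset(_collect_rules(root)))

    def iter_tips(self) -> Iterator[TreeNode]:
        yield from iter_tips(self.root)

    def pair_tips(self) -> list[PairTip]:
        return [t for t in self.iter_tips() if isinstance(t, PairTip)]

    def loner_tips(self) -> list[LonerTip]:
        return [t for t in self.iter_tips() if isinstance(t, LonerTip)]


def iter_tips(node: TreeNode) -> Iterator[TreeNode]:
    if isinstance(node, Internal):
        yield from iter_tips(node.left)
        yield from iter_tips(node.right)
    else:
        yield node


def _collect_rules(node: TreeNode) -> Iterator[str]:
    if isinstance(node, Internal):
        yield node.rule
        yield from _collect_rules(node.left)
        yield from _collect_rules(node.right)


# ---------------------------------------------------------------------------
# Serialization

def _node_to_rsf(node: TreeNode, mode: str) -> str:
    if isinstance(node, Internal):
        marker = "!" if node.rule == BALANCE else "!!"
        return (f"({marker}{_node_to_rsf(node.left, mode)}"
                f"{_node_to_rsf(node.right, mode)})")
    if isinstance(node, PairTip):
        if mode == "pattern":
            return "(C_C)"
        return f"({node.substrate_id}_{node.product_id})"
    if isinstance(node, LonerTip):
        if mode == "pattern":
            return "(C)"
        if node.side is None:
            raise RsfError(
                f"loner {node.compound_id}: side unknown, cannot emit ids mode"
            )
        if node.side == "substrate":
            return f"({node.compound_id}_)"
        return f"(_{node.compound_id})"
    raise TypeError(f"not a tree node: {node!r}")


def to_rsf(tree: TreeStructure | TreeNode, mode: str = "ids") -> str:
    """Serialize a tree (or bare root node) to RSF text."""
    if mode not in ("ids", "pattern"):
        raise ValueError(f"unknown mode {mode!r}")
    node = tree.root if isinstance(tree, TreeStructure) else tree
    return ">" + _node_to_rsf(node, mode)


def topology_pattern(tree: TreeStructure | TreeNode) -> str:
    """The compound-agnostic topology pattern, e.g. ``>(!(C)(C_C))``."""
    return to_rsf(tree, mode="pattern")


class _Parser:
    def __init__(self, text: str, mode: str):
        self.text = text
        self.pos = 0
        self.mode = mode

    def error(self, message: str) -> RsfError:
        return RsfError(f"position {self.pos}: {message} in {self.text!r}")

    def expect(self, token: str) -> None:
        if not self.text.startswith(token, self.pos):
            raise self.error(f"expected {token!r}")
        self.pos += len(token)

    def parse(self) -> TreeNode:
        if self.text.startswith(">", self.pos):
            self.pos += 1
        elif self.text.startswith("root", self.pos):
            self.pos += 4
        else:
            raise self.error("expected '>' or 'root'")
        node = self.parse_node()
        if self.pos != len(self.text):
            raise self.error("trailing text after tree")
        return node

    def parse_node(self) -> TreeNode:
        self.expect("(")
        marker = self._marker()
        if marker is not None:
            left = self.parse_node()
            right = self.parse_node()
            self.expect(")")
            return Internal(marker, left, right)
        node = self._tip()
        self.expect(")")
        return node

    def _marker(self) -> str | None:
        if self.text.startswith("!!", self.pos):
            self.pos += 2
            return COUNT
        if self.text.startswith("!", self.pos):
            self.pos += 1
            return BALANCE
        if self.text.startswith("count(", self.pos):
            self.pos += 5
            return COUNT
        if self.text.startswith("balance(", self.pos):
            self.pos += 7
            return BALANCE
        return None

    def _tip(self) -> TreeNode:
        end = self.text.find(")", self.pos)
        if end < 0:
            raise self.error("unbalanced parentheses")
        content = self.text[self.pos:end]
        if "(" in content or not content:
            raise self.error("expected marker or tip content")
        self.pos = end
        if "_" not in content:
            if self.mode == "pattern":
                return LonerTip(content, None)
            raise self.error(f"tip {content!r} has no '_'")
        a, _, b = content.partition("_")
        if a and b:
            return PairTip(a, b)
        if a:
            return LonerTip(a, "substrate")
        if b:
            return LonerTip(b, "product")
        raise self.error("empty tip")


def parse_rsf(text: str, mode: str = "ids") -> TreeNode:
    """Parse RSF text back into a tree root node.

    ``parse_rsf(to_rsf(t))`` reproduces ``t`` in ids mode and its
    topology in pattern mode.  Raises :class:`RsfError` with the failing
    position on malformed input.
    """
    if mode not in ("ids", "pattern"):
        raise ValueError(f"unknown mode {mode!r}")
    return _Parser(text.strip(), mode).parse()


# ---------------------------------------------------------------------------
# JSON and tabular forms

def _node_to_dict(node: TreeNode) -> dict:
    if isinstance(node, Internal):
        return {"kind": "internal", "rule": node.rule,
                "left": _node_to_dict(node.left),
                "right": _node_to_dict(node.right)}
    if isinstance(node, PairTip):
        return {"kind": "pair", "substrate_id": node.substrate_id,
                "product_id": node.product_id}
    return {"kind": "loner", "compound_id": node.compound_id,
            "side": node.side}


def _node_from_dict(data: dict) -> TreeNode:
    kind = data["kind"]
    if kind == "internal":
        return Internal(data["rule"], _node_from_dict(data["left"]),
                        _node_from_dict(data["right"]))
    if kind == "pair":
        return PairTip(data["substrate_id"], data["product_id"])
    if kind == "loner":
        return LonerTip(data["compound_id"], data["side"])
    raise ValueError(f"unknown node kind {kind!r}")


def tree_to_json(tree: TreeStructure) -> str:
    return json.dumps({
        "reaction_id": tree.reaction_id,
        "root": _node_to_dict(tree.root),
        "rules_used": sorted(tree.rules_used),
        "tips": [
            {"pair": [t.substrate_id, t.product_id]}
            if isinstance(t, PairTip)
            else {"loner": t.compound_id, "side": t.side}
            for t in tree.iter_tips()
        ],
    }, sort_keys=True)


def tree_from_json(text: str) -> TreeStructure:
    data = json.loads(text)
    return TreeStructure.from_root(data["reaction_id"],
                                   _node_from_dict(data["root"]))


def write_trees_tsv(trees, handle) -> None:
    """One tree per line: reaction_id, ids-mode RSF, pattern."""
    handle.write("reaction_id\trsf_ids\trsf_pattern\n")
    for tree in trees:
        handle.write(
            f"{tree.reaction_id}\t{to_rsf(tree)}\t{topology_pattern(tree)}\n"
        )


def read_trees_tsv(handle) -> list[TreeStructure]:
    trees = []
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("reaction_id\t"):
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise RsfError(f"line {lineno}: expected id\\trsf columns")
        trees.append(
            TreeStructure.from_root(cols[0], parse_rsf(cols[1], mode="ids"))
        )
    return trees
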