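"""Rooted phylogenies: Newick parsing and writing, pruning, patristic distances.

The Newick dialect accepted here is deliberately narrow so that parse errors
are informative: branch lengths are required on every non-root edge (decimal
or scientific notation), labels may be bare or single-quoted, internal node
labels are allowed (and ignored for distance purposes), and bracketed
comments — including NHX annotations — are rejected outright.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "NewickError",
    "TreeError",
    "TreeNode",
    "Phylogeny",
    "DistanceMatrix",
    "parse_newick",
    "write_newick",
    "read_newick_file",
    "write_newick_file",
    "prune",
    "cophenetic",
]


class NewickError(ValueError):
    """Malformed Newick input; the message names the offending token."""


class TreeError(ValueError):
    """Structural violation of a phylogeny invariant."""


@dataclass
class TreeNode:
    """A node in a rooted tree; ``length`` is the edge to the parent."""

    label: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = field(default=None, repr=False, compare=False)

    @property
    def is_tip(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["TreeNode"]:
        # iterative to stay safe on caterpillar trees
        out: list[TreeNode] = []
        stack = [self]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))


class Phylogeny:
    """A rooted phylogeny with branch lengths and uniquely labeled tips."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._link_parents()
        self._validate()

    def _link_parents(self) -> None:
        self.root.parent = None
        for node in self.root.preorder():
            for child in node.children:
                child.parent = node

    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.root.preorder():
            if node is not self.root:
                if node.length is None:
                    raise TreeError(
                        f"node {node.label!r} has no branch length"
                    )
                if not math.isfinite(node.length) or node.length < 0:
                    raise TreeError(
                        f"node {node.label!r} has invalid branch length "
                        f"{node.length!r} (must be finite and >= 0)"
                    )
            if node.is_tip:
                if not node.label:
                    raise TreeError("tip with empty label")
                if node.label in seen:
                    raise TreeError(f"duplicate tip label {node.label!r}")
                seen.add(node.label)

    # -- interrogation -------------------------------------------------

    def tips(self) -> list[TreeNode]:
        """Tips in traversal (Newick appearance) order."""
        return [n for n in self.root.preorder() if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]  # type: ignore[misc]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def total_branch_length(self) -> float:
        """Sum of all branch lengths, including a root edge if present."""
        total = self.root.length or 0.0
        for node in self.root.preorder():
            if node is not self.root and node.length is not None:
                total += node.length
        return total

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length for every tip (root edge excluded)."""
        depth: dict[int, float] = {id(self.root): 0.0}
        out: dict[str, float] = {}
        for node in self.root.preorder():
            if node is not self.root:
                depth[id(node)] = depth[id(node.parent)] + float(node.length)
            if node.is_tip:
                out[node.label] = depth[id(node)]  # type: ignore[index]
        return out

    def is_ultrametric(self, rel_tol: float = 1e-8) -> bool:
        d = list(self.depths().values())
        span = max(d) - min(d)
        scale = max(abs(max(d)), 1.0)
        return span <= rel_tol * scale

    def copy(self) -> "Phylogeny":
        return parse_newick(write_newick(self))

    def __repr__(self) -> str:
        return f"<Phylogeny with {self.n_tips} tips>"


@dataclass(frozen=True)
class DistanceMatrix:
    """Square patristic distance matrix with an ordered label list."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix size")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)
        object.__setattr__(
            self, "_index", {lab: i for i, lab in enumerate(self.labels)}
        )

    def index_of(self, labels: Sequence[str]) -> np.ndarray:
        idx = self.__dict__["_index"]
        missing = [lab for lab in labels if lab not in idx]
        if missing:
            raise KeyError(f"labels not in distance matrix: {missing}")
        return np.array([idx[lab] for lab in labels], dtype=np.intp)

    def get(self, a: str, b: str) -> float:
        i = self.index_of([a, b])
        return float(self.values[i[0], i[1]])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        i = self.index_of(labels)
        return DistanceMatrix(tuple(labels), self.values[np.ix_(i, i)])


# -- Newick parsing ----------------------------------------------------

_SPECIALS = set("()[]{}:;,'\t\n\r ")


class _Cursor:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def next(self) -> str:
        ch = self.peek()
        self.pos += 1
        return ch

    def skip_ws(self) -> None:
        while self.peek() in " \t\n\r" and self.peek():
            self.pos += 1

    def error(self, msg: str) -> NewickError:
        ctx = self.text[max(0, self.pos - 15): self.pos + 15]
        return NewickError(f"{msg} at position {self.pos} (near {ctx!r})")


def _read_label(cur: _Cursor) -> str | None:
    cur.skip_ws()
    ch = cur.peek()
    if ch == "[":
        raise cur.error("bracketed comments/NHX annotations are not supported")
    if ch == "'":
        cur.next()
        out = []
        while True:
            ch = cur.next()
            if not ch:
                raise cur.error("unterminated quoted label")
            if ch == "'":
                if cur.peek() == "'":  # doubled quote escapes a quote
                    out.append("'")
                    cur.next()
                else:
                    break
            else:
                out.append(ch)
        return "".join(out)
    out = []
    while cur.peek() and cur.peek() not in _SPECIALS:
        out.append(cur.next())
    return "".join(out) or None


def _read_length(cur: _Cursor) -> float | None:
    cur.skip_ws()
    if cur.peek() != ":":
        return None
    cur.next()
    cur.skip_ws()
    start = cur.pos
    while cur.peek() and cur.peek() in "+-0123456789.eE":
        cur.next()
    token = cur.text[start:cur.pos]
    try:
        value = float(token)
    except ValueError:
        raise cur.error(f"invalid branch length token {token!r}") from None
    if not math.isfinite(value):
        raise cur.error(f"non-finite branch length {token!r}")
    if value < 0:
        raise cur.error(f"negative branch length {token!r}")
    return value


def _read_clade(cur: _Cursor, *, is_root: bool) -> TreeNode:
    cur.skip_ws()
    node = TreeNode()
    if cur.peek() == "(":
        cur.next()
        while True:
            node.children.append(_read_clade(cur, is_root=False))
            cur.skip_ws()
            ch = cur.peek()
            if ch == ",":
                cur.next()
                continue
            if ch == ")":
                cur.next()
                break
            if ch == "[":
                raise cur.error(
                    "bracketed comments/NHX annotations are not supported"
                )
            raise cur.error(f"expected ',' or ')' but found {ch!r}")
    node.label = _read_label(cur)
    node.length = _read_length(cur)
    if node.is_tip and node.label is None:
        raise cur.error("tip with missing label")
    if not is_root and node.length is None:
        raise cur.error(
            f"missing branch length for node {node.label or '(internal)'}"
        )
    return node


def parse_newick(text: str) -> Phylogeny:
    """Parse a single Newick tree string into a :class:`Phylogeny`.

    Raises :class:`NewickError` on malformed structure and
    :class:`TreeError` on invariant violations (e.g. duplicate tips).
    """
    cur = _Cursor(text)
    cur.skip_ws()
    if not cur.peek():
        raise cur.error("empty Newick input")
    root = _read_clade(cur, is_root=True)
    cur.skip_ws()
    if cur.peek() == "[":
        raise cur.error("bracketed comments/NHX annotations are not supported")
    if cur.peek() != ";":
        raise cur.error("expected trailing ';'")
    cur.next()
    cur.skip_ws()
    if cur.peek():
        raise cur.error("trailing content after ';' (one tree per input)")
    return Phylogeny(root)


def _quote_if_needed(label: str) -> str:
    if any(ch in _SPECIALS for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_node(node: TreeNode) -> str:
    if node.is_tip:
        s = _quote_if_needed(node.label or "")
    else:
        s = "(" + ",".join(_format_node(c) for c in node.children) + ")"
        if node.label:
            s += _quote_if_needed(node.label)
    if node.length is not None:
        s += f":{node.length!r}"
    return s


def write_newick(tree: Phylogeny) -> str:
    """Serialize to Newick; branch lengths use shortest round-trip repr."""
    return _format_node(tree.root) + ";"


def read_newick_file(path: str | Path) -> Phylogeny:
    return parse_newick(Path(path).read_text(encoding="utf-8"))


def write_newick_file(tree: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(write_newick(tree) + "\n", encoding="utf-8")


# -- operations --------------------------------------------------------

def cophenetic(tree: Phylogeny) -> DistanceMatrix:
    """Tip-to-tip patristic distances (sums of branch lengths on paths).

    Runs a single post-order combine, O(n_tips^2) overall.
    """
    tips = tree.tips()
    if len(tips) < 2:
        raise TreeError("cophenetic requires a tree with at least 2 tips")
    labels = tuple(t.label for t in tips)
    index = {id(t): i for i, t in enumerate(tips)}
    n = len(tips)
    dist = np.zeros((n, n), dtype=float)
    # carry[node] = list of (tip_index, distance from node to that tip)
    carry: dict[int, list[tuple[int, float]]] = {}
    for node in tree.root.postorder():
        if node.is_tip:
            carry[id(node)] = [(index[id(node)], 0.0)]
            continue
        merged: list[tuple[int, float]] = []
        for child in node.children:
            below = [
                (i, d + float(child.length)) for i, d in carry.pop(id(child))
            ]
            for i, di in below:
                for j, dj in merged:
                    dist[i, j] = dist[j, i] = di + dj
            merged.extend(below)
        carry[id(node)] = merged
    return DistanceMatrix(labels, dist)


def prune(tree: Phylogeny, keep: set[str] | Sequence[str]) -> Phylogeny:
    """Restrict a tree to ``keep`` tips, collapsing unbranched internals.

    Branch lengths of collapsed chains are summed, so patristic distances
    among the kept tips are unchanged.
    """
    keep_set = set(keep)
    if not keep_set:
        raise TreeError("prune requires at least one tip to keep")
    missing = sorted(keep_set - set(tree.tip_labels))
    if missing:
        raise TreeError(f"tips not present in tree: {missing}")

    def rec(node: TreeNode) -> TreeNode | None:
        if node.is_tip:
            if node.label in keep_set:
                return TreeNode(label=node.label, length=node.length)
            return None
        kept = [c for c in (rec(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            if node.length is not None:
                child.length = (child.length or 0.0) + node.length
            return child
        return TreeNode(label=node.label, length=node.length, children=kept)

    new_root = rec(tree.root)
    assert new_root is not None
    return Phylogeny(new_root)
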