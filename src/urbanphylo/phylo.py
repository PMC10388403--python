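"""Rooted phylogenies and the phylogenetic variance-covariance matrix.

A phylogeny enters the analysis as a rooted newick tree with branch
lengths (typically a maximum-likelihood tree, so *not* ultrametric).  Under
Brownian-motion trait evolution the tip values are multivariate normal with
covariance proportional to V, where ``V[i, j]`` is the shared branch length
from the root down to the most recent common ancestor of tips i and j, and
``V[i, i]`` is the root-to-tip path length of tip i.  That matrix drives
every downstream statistic (Blomberg's K, PGLS), so this module owns its
construction, plus the parsing, validation, sanitation and pruning needed
to keep it positive definite.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "NewickParseError",
    "TreeValidationError",
    "normalize_taxon_label",
    "parse_newick",
    "prune_to_taxa",
    "compute_vcv",
]

#: relative scale for clamping zero-length terminal branches (times tree depth)
ZERO_BRANCH_CLAMP = 1e-8


class NewickParseError(ValueError):
    """Malformed newick input (position reported where known)."""


class TreeValidationError(ValueError):
    """Structurally invalid phylogeny (duplicate tips, bad branch lengths...)."""


def normalize_taxon_label(label: str) -> str:
    """Normalize a taxon label: trim surrounding whitespace, internal spaces
    become underscores (the usual newick dialect convention).  Matching between
    tree tips and table rows is exact and case-sensitive after this."""
    return label.strip().replace(" ", "_")


class _Node:
    """Internal tree node; ``length`` is the branch above it (0 at the root)."""

    __slots__ = ("children", "length", "label")

    def __init__(self, length: float = 0.0, label: str | None = None):
        self.children: list[_Node] = []
        self.length = length
        self.label = label

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "_Node":
        n = _Node(self.length, self.label)
        n.children = [c.copy() for c in self.children]
        return n


class Phylogeny:
    """A rooted tree with branch lengths and uniquely labelled tips.

    Tip order is the left-to-right order of first encounter, which is also
    the row/column order of the covariance matrix built from the tree.
    Polytomies are allowed; trees from the simulator are strictly binary.
    """

    def __init__(self, root: _Node):
        self._root = root
        self._validate()

    # -- structure ---------------------------------------------------------

    @property
    def root(self) -> _Node:
        return self._root

    @property
    def tip_names(self) -> list[str]:
        return [n.label for n in self._iter_nodes() if n.is_leaf]

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self._iter_nodes() if n.is_leaf)

    @property
    def n_edges(self) -> int:
        # every node except the root sits below one edge
        return sum(1 for _ in self._iter_nodes()) - 1

    def _iter_nodes(self):
        """Preorder traversal (root first, children left to right)."""
        stack = [self._root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def _validate(self) -> None:
        names = self.tip_names
        if len(names) != len(set(names)):
            seen, dups = set(), set()
            for nm in names:
                (dups if nm in seen else seen).add(nm)
            raise TreeValidationError(f"duplicate tip labels: {sorted(dups)}")
        if any(nm is None or nm == "" for nm in names):
            raise TreeValidationError("unlabelled tip encountered")
        for node in self._iter_nodes():
            if node is not self._root and node.length < 0:
                raise TreeValidationError(
                    f"negative branch length {node.length!r} "
                    f"above {'tip ' + node.label if node.is_leaf else 'an internal node'}"
                )

    # -- measures ----------------------------------------------------------

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip (tree not assumed ultrametric)."""
        depths: dict[str, float] = {}

        def rec(node: _Node, d: float) -> None:
            d += node.length if node is not self._root else 0.0
            if node.is_leaf:
                depths[node.label] = d
            for c in node.children:
                rec(c, d)

        rec(self._root, 0.0)
        return depths

    def max_depth(self) -> float:
        d = self.tip_depths()
        return max(d.values()) if d else 0.0

    # -- sanitation --------------------------------------------------------

    def sanitize(self) -> "Phylogeny":
        """Return a copy with zero-length terminal branches clamped.

        V must be invertible for Blomberg's K and PGLS; a zero terminal
        branch shared between sister tips makes two V rows identical.  Zero
        terminal branches are clamped to ``ZERO_BRANCH_CLAMP`` times the tree
        depth with a warning.  Internal zero branches (soft polytomies) are
        left alone: they do not by themselves make V singular.
        """
        root = self._root.copy()
        depth = self.max_depth()
        if depth <= 0:
            raise TreeValidationError("tree has zero depth; nothing to analyse")
        eps = ZERO_BRANCH_CLAMP * depth
        clamped = []

        def rec(node: _Node) -> None:
            if node.is_leaf and node.length == 0.0:
                node.length = eps
                clamped.append(node.label)
            for c in node.children:
                rec(c)

        rec(root)
        if clamped:
            warnings.warn(
                f"clamped {len(clamped)} zero-length terminal branch(es) to "
                f"{eps:g} ({sorted(clamped)})",
                stacklevel=2,
            )
        return Phylogeny(root)

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        """Single-statement newick with branch lengths, ';'-terminated."""

        def fmt(node: _Node) -> str:
            if node.is_leaf:
                core = node.label
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node is self._root:
                return core
            return f"{core}:{node.length:.12g}"

        return fmt(self._root) + ";"

    def copy(self) -> "Phylogeny":
        return Phylogeny(self._root.copy())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Phylogeny with {self.n_tips} tips>"


@dataclass(frozen=True)
class PhyloCovariance:
    """Tip-by-tip Brownian covariance structure of a phylogeny.

    ``matrix[i, j]`` is the root-to-MRCA path length of ``taxa[i]`` and
    ``taxa[j]`` (shared evolutionary history in branch-length units);
    diagonal entries are root-to-tip depths.
    """

    taxa: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self):
        V = np.asarray(self.matrix, dtype=float)
        if V.ndim != 2 or V.shape[0] != V.shape[1] or V.shape[0] != len(self.taxa):
            raise ValueError("covariance matrix shape does not match taxa")
        object.__setattr__(self, "matrix", V)

    @property
    def n(self) -> int:
        return len(self.taxa)

    def submatrix(self, taxa: list[str]) -> "PhyloCovariance":
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in index]
        if missing:
            raise KeyError(f"taxa not in covariance: {missing}")
        idx = [index[t] for t in taxa]
        return PhyloCovariance(tuple(taxa), self.matrix[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# parsing


def _check_newick_syntax(text: str) -> str:
    stripped = text.strip()
    if not stripped:
        raise NewickParseError("empty newick input")
    if ";" not in stripped:
        raise NewickParseError(
            f"newick statement not terminated by ';' (input ends at position {len(text)})"
        )
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(f"unbalanced ')' at position {pos}")
        elif ch == ";":
            if depth != 0:
                raise NewickParseError(
                    f"';' at position {pos} inside {depth} unclosed parenthesis(es)"
                )
            break
    return stripped


def parse_newick(
    text: str,
    *,
    substitute_missing: float | None = None,
    sanitize: bool = True,
) -> Phylogeny:
    """Parse a single rooted newick statement into a :class:`Phylogeny`.

    Parameters
    ----------
    text:
        One ';'-terminated newick statement.  Internal node labels /
        support values are ignored; tip labels are normalized with
        :func:`normalize_taxon_label`.
    substitute_missing:
        Branch lengths are required by default (an ML tree always has
        them); a missing length raises unless this substitute value is
        given (a common convention is ``1.0``).
    sanitize:
        Clamp zero-length terminal branches (see :meth:`Phylogeny.sanitize`).
    """
    _check_newick_syntax(text)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        if "Duplicate taxon" in str(exc):
            raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
        raise NewickParseError(f"newick parse failed: {exc}") from exc

    def convert(dnode, is_root: bool) -> _Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else None
            if label is None:
                raise NewickParseError("tip without a label")
            node = _Node(label=normalize_taxon_label(label))
        else:
            node = _Node()
        if not is_root:
            if dnode.edge.length is None:
                if substitute_missing is None:
                    raise NewickParseError(
                        "branch length missing (pass substitute_missing=1.0 "
                        "to substitute a unit length)"
                    )
                node.length = float(substitute_missing)
            else:
                node.length = float(dnode.edge.length)
        for child in dnode.child_nodes():
            node.children.append(convert(child, False))
        return node

    root = convert(dtree.seed_node, True)
    if not root.children and root.label is None:
        raise NewickParseError("newick statement contains no tips")
    tree = Phylogeny(root)
    if tree.n_tips < 1:
        raise NewickParseError("newick statement contains no tips")
    return tree.sanitize() if sanitize and tree.n_tips >= 2 else tree


# ---------------------------------------------------------------------------
# pruning


def prune_to_taxa(tree: Phylogeny, keep: set[str] | list[str]) -> Phylogeny:
    """Restrict a tree to a subset of tips.

    Path lengths between kept tips — and their root-to-MRCA depths, hence
    the corresponding covariance entries — are preserved exactly: internal
    nodes left with a single child are collapsed with branch lengths summed,
    but the root itself is retained even if it ends up with out-degree one,
    so tip depths (V diagonals) do not shrink.
    """
    keep_set = set(keep)
    tips = set(tree.tip_names)
    unknown = keep_set - tips
    if unknown:
        raise KeyError(f"taxa not in tree: {sorted(unknown)}")
    if len(keep_set) < 2:
        raise ValueError("need at least 2 taxa to keep")

    def rec(node: _Node) -> _Node | None:
        if node.is_leaf:
            if node.label in keep_set:
                return _Node(node.length, node.label)
            return None
        kept = [c for c in (rec(ch) for ch in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            child.length += node.length
            return child
        new = _Node(node.length)
        new.children = kept
        return new

    new_root = rec(tree.root)
    assert new_root is not None
    if new_root.is_leaf or new_root.length != tree.root.length:
        # rec() merged the old root into its single surviving child; re-root
        # above it with a zero-length stem so depth bookkeeping stays exact.
        stem = _Node(0.0)
        new_root.length -= tree.root.length  # undo the root's (zero) length
        stem.children = [new_root]
        new_root = stem
    return Phylogeny(new_root)


# ---------------------------------------------------------------------------
# covariance


def compute_vcv(tree: Phylogeny) -> PhyloCovariance:
    """Build the Brownian variance-covariance matrix of a tree.

    Entry (i, j) is the depth of the MRCA of tips i and j; computed in a
    single post-order pass by filling, at each internal node, the blocks
    between tips of distinct child subtrees.  Works for polytomies and
    non-ultrametric trees alike.
    """
    names = tree.tip_names
    n = len(names)
    if n < 2:
        raise TreeValidationError("covariance needs a tree with at least 2 tips")
    index = {nm: i for i, nm in enumerate(names)}
    V = np.zeros((n, n))

    def rec(node: _Node, depth: float) -> list[int]:
        here = depth + (node.length if node is not tree.root else 0.0)
        if node.is_leaf:
            i = index[node.label]
            V[i, i] = here
            return [i]
        blocks = [rec(c, here) for c in node.children]
        for a in range(len(blocks)):
            for b in range(a + 1, len(blocks)):
                ia, ib = blocks[a], blocks[b]
                V[np.ix_(ia, ib)] = here
                V[np.ix_(ib, ia)] = here
        return [i for blk in blocks for i in blk]

    rec(tree.root, 0.0)
    return PhyloCovariance(tuple(names), V)
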