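"""Rooted phylogeny container, Newick I/O and patristic distances.

The :class:`Phylogeny` wraps a :class:`dendropy.Tree` and adds the guarantees
the rest of the package relies on: unique non-empty tip names, an explicit
"absent" state for missing branch lengths (never silently zero), optional node
ages set by dating, and a canonical deterministic Newick serialization.
"""

from __future__ import annotations

import re
from pathlib import Path

import dendropy
import numpy as np
from skbio import DistanceMatrix

from .errors import MissingBranchLengthError, NewickParseError

__all__ = [
    "Phylogeny",
    "parse_newick",
    "write_newick",
    "patristic_distances",
    "normalize_name",
]

_NEEDS_QUOTE = re.compile(r"[\s()\[\]{}:;,']")


def normalize_name(name: str) -> str:
    """Canonical form used for name matching: case-insensitive, '_' == ' '."""
    return name.strip().replace(" ", "_").lower()


def _node_name(node) -> str | None:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label


def _check_balanced(text: str) -> None:
    depth = 0
    in_quote = False
    for pos, ch in enumerate(text):
        if ch == "'":
            in_quote = not in_quote
        elif not in_quote:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise NewickParseError(
                        f"unbalanced parentheses: unmatched ')' at position {pos}"
                    )
    if depth != 0:
        raise NewickParseError(
            f"unbalanced parentheses: {depth} '(' left open at end of input"
        )
    if in_quote:
        raise NewickParseError("unterminated quoted label")


class Phylogeny:
    """A rooted phylogenetic tree with optional node ages.

    Parameters
    ----------
    tree : dendropy.Tree
        The underlying tree. Tips must carry unique, non-empty names.
        Branch lengths may be absent (``None``); they are only filled by
        explicit dating, never defaulted to zero.
    """

    def __init__(self, tree: dendropy.Tree, validate: bool = True):
        self._tree = tree
        if validate:
            self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return parse_newick(text)

    @classmethod
    def read(cls, path) -> "Phylogeny":
        """Read a tree from a Newick file, or a NEXUS file (TREES block)."""
        text = Path(path).read_text()
        if text.lstrip().upper().startswith("#NEXUS"):
            try:
                tree = dendropy.Tree.get(
                    data=text,
                    schema="nexus",
                    preserve_underscores=True,
                    suppress_internal_node_taxa=True,
                )
            except Exception as exc:  # dendropy raises many error types
                raise NewickParseError(f"could not parse NEXUS file {path}: {exc}")
            return cls(tree)
        return parse_newick(text)

    def copy(self) -> "Phylogeny":
        clone = self._tree.clone(depth=1)
        # clone(depth=1) keeps taxa shared, copies nodes/edges; carry ages over
        for src, dst in zip(
            self._tree.preorder_node_iter(), clone.preorder_node_iter()
        ):
            if hasattr(src, "age"):
                dst.age = src.age
        return Phylogeny(clone, validate=False)

    def _validate(self) -> None:
        seen = set()
        for leaf in self._tree.leaf_node_iter():
            name = _node_name(leaf)
            if not name:
                raise NewickParseError("tip with empty name")
            key = normalize_name(name)
            if key in seen:
                raise NewickParseError(f"duplicate tip name: {name!r}")
            seen.add(key)
        for node in self._tree.preorder_node_iter():
            if node.edge.length is not None and node.edge.length < 0:
                raise ValueError(
                    f"negative branch length on node {_node_name(node)!r}"
                )

    # -- basic accessors ---------------------------------------------------

    @property
    def root(self):
        return self._tree.seed_node

    @property
    def tips(self):
        return list(self._tree.leaf_node_iter())

    @property
    def tip_names(self) -> list[str]:
        return [_node_name(leaf) for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    def node_by_name(self, name: str):
        """Find a node (tip or internal) by name, underscore/case tolerant."""
        key = normalize_name(name)
        for node in self._tree.preorder_node_iter():
            label = _node_name(node)
            if label is not None and normalize_name(label) == key:
                return node
        return None

    def has_branch_lengths(self) -> bool:
        return all(
            node.edge.length is not None
            for node in self._tree.preorder_node_iter()
            if node.parent_node is not None
        )

    def total_branch_length(self) -> float:
        """Sum of all branch lengths, excluding any root stem length."""
        total = 0.0
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.edge.length is None:
                raise MissingBranchLengthError(
                    f"branch length absent above node {_node_name(node)!r}; "
                    "run bladj to date the tree first"
                )
            total += node.edge.length
        return total

    # -- depths / ultrametricity ------------------------------------------

    def _depths(self) -> dict:
        """Root-to-node path lengths for every node; errors on absent lengths."""
        depths = {self.root: 0.0}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.edge.length is None:
                raise MissingBranchLengthError(
                    f"branch length absent above node {_node_name(node)!r}; "
                    "run bladj to date the tree first"
                )
            depths[node] = depths[node.parent_node] + node.edge.length
        return depths

    def root_age(self) -> float:
        """Root age of an ultrametric tree (max root-to-tip path length)."""
        depths = self._depths()
        return max(depths[leaf] for leaf in self._tree.leaf_node_iter())

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = self._depths()
        tip_depths = [depths[leaf] for leaf in self._tree.leaf_node_iter()]
        span = max(tip_depths) - min(tip_depths)
        return span <= tol * max(1.0, max(tip_depths))

    # -- distances ---------------------------------------------------------

    def patristic_distances(self, taxa=None) -> DistanceMatrix:
        return patristic_distances(self, taxa)

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        return write_newick(self)

    def write(self, path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    def __repr__(self) -> str:
        return f"<Phylogeny: {self.n_tips} tips>"


def parse_newick(text: str) -> Phylogeny:
    """Parse a single rooted Newick description.

    Missing branch lengths are kept as absent (``None``) so that a later
    dating step can fill them; they are never interpreted as zero.
    """
    if not text or not text.strip():
        raise NewickParseError("empty input")
    _check_balanced(text)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickParseError(f"could not parse Newick: {exc}")
    return Phylogeny(tree)


def _format_length(value: float) -> str:
    return format(float(value), ".6g")


def _format_label(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Phylogeny) -> str:
    """Serialize to canonical Newick.

    Children are ordered by their smallest descendant tip name and branch
    lengths rendered with 6 significant digits, so equal trees serialize to
    equal strings. Unnamed internal nodes stay unnamed.
    """
    min_tip: dict = {}
    for node in tree._tree.postorder_node_iter():
        if node.is_leaf():
            min_tip[node] = _node_name(node) or ""
        else:
            min_tip[node] = min(min_tip[c] for c in node.child_nodes())

    def render(node) -> str:
        if node.is_leaf():
            out = _format_label(_node_name(node))
        else:
            kids = sorted(node.child_nodes(), key=lambda c: min_tip[c])
            out = "(" + ",".join(render(c) for c in kids) + ")"
            label = _node_name(node)
            if label:
                out += _format_label(label)
        if node.edge.length is not None:
            out += ":" + _format_length(node.edge.length)
        return out

    return render(tree.root) + ";"


def patristic_distances(tree: Phylogeny, taxa=None) -> DistanceMatrix:
    """Pairwise path-length (patristic) distances between tips.

    d(i, j) is the sum of branch lengths along the path i -> MRCA(i, j) -> j.
    Requires every branch length to be present.
    """
    all_tips = {normalize_name(_node_name(l)): _node_name(l) for l in tree.tips}
    if taxa is None:
        labels = sorted(all_tips.values())
    else:
        labels = sorted(set(taxa))
        missing = [t for t in labels if normalize_name(t) not in all_tips]
        if missing:
            raise ValueError(
                "taxa not found among tree tips: " + ", ".join(missing)
            )
    wanted = {normalize_name(t): i for i, t in enumerate(labels)}
    depths = tree._depths()

    n = len(labels)
    mat = np.zeros((n, n))
    # Postorder sweep: tips in different child subtrees meet at this node.
    below: dict = {}
    for node in tree._tree.postorder_node_iter():
        if node.is_leaf():
            key = normalize_name(_node_name(node))
            below[node] = [(wanted[key], depths[node])] if key in wanted else []
            continue
        groups = [below.pop(c) for c in node.child_nodes()]
        d_node = depths[node]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i, di in groups[a]:
                    for j, dj in groups[b]:
                        d = di + dj - 2.0 * d_node
                        mat[i, j] = d
                        mat[j, i] = d
        merged = []
        for g in groups:
            merged.extend(g)
        below[node] = merged
    return DistanceMatrix(mat, ids=labels)
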