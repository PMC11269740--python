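"""Newick tree I/O and tree utilities.

Trees are ``dendropy.Tree`` objects throughout. Species names are matched
between the tree and tabular inputs by exact string after normalization
(strip whitespace, spaces -> underscores); mismatches are reported and the
analysis proceeds on the intersection.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

from .errors import NewickParseError, ValidationError

logger = logging.getLogger(__name__)


def normalize_species_name(name: str) -> str:
    """Canonical species identifier: trimmed, internal spaces as underscores."""
    return name.strip().replace(" ", "_")


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Leaf labels in tree (preorder leaf) order."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _validate(tree: dendropy.Tree, source: str) -> dendropy.Tree:
    if any(leaf.taxon is None or not str(leaf.taxon.label).strip()
           for leaf in tree.leaf_node_iter()):
        raise NewickParseError(f"{source}: malformed Newick (unlabeled tip)")
    labels = [normalize_species_name(t) for t in tip_labels(tree)]
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValidationError(f"{source}: duplicate tip labels {dupes}")
    # normalize in place so downstream joins are exact-string
    for leaf in tree.leaf_node_iter():
        leaf.taxon.label = normalize_species_name(leaf.taxon.label)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            raise ValidationError(
                f"{source}: node {node.taxon.label if node.taxon else '<internal>'} "
                "has no branch length; Brownian-motion PGLS requires branch lengths "
                "on every non-root edge"
            )
        if node.edge.length < 0:
            raise ValidationError(
                f"{source}: negative branch length {node.edge.length}"
            )
    return tree


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single rooted Newick tree with branch lengths.

    Raises
    ------
    NewickParseError
        If the file is not valid single-tree Newick (the message carries the
        parser's position information).
    ValidationError
        On duplicate tip labels or missing/negative branch lengths.
    """
    path = Path(path)
    text = path.read_text()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        if "Duplicate taxon labels" in str(exc):
            raise ValidationError(f"{path}: duplicate tip labels ({exc})") from exc
        raise NewickParseError(f"{path}: malformed Newick ({exc})") from exc
    return _validate(tree, str(path))


def parse_newick(text: str, source: str = "<string>") -> dendropy.Tree:
    """Parse a Newick string (same validation as :func:`read_newick`)."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        if "Duplicate taxon labels" in str(exc):
            raise ValidationError(f"{source}: duplicate tip labels ({exc})") from exc
        raise NewickParseError(f"{source}: malformed Newick ({exc})") from exc
    return _validate(tree, source)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write one tree as Newick with full-precision branch lengths."""
    Path(path).write_text(to_newick_string(tree))


def to_newick_string(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".17g",
    ).strip() + "\n"


def prune_to_species(tree: dendropy.Tree, species: Iterable[str]) -> dendropy.Tree:
    """Return a copy of ``tree`` pruned to the given tip set.

    Raises
    ------
    ValidationError
        If any requested species is not a tip of the tree.
    """
    wanted = [normalize_species_name(s) for s in species]
    present = set(tip_labels(tree))
    missing = sorted(set(wanted) - present)
    if missing:
        raise ValidationError(f"species not in tree: {missing}")
    pruned = tree.clone(depth=1)
    if set(wanted) != present:
        pruned.retain_taxa_with_labels(wanted)
    return pruned


def intersect_species(tree_species: Sequence[str], table_species: Sequence[str]) -> list[str]:
    """Intersection of normalized species sets, logged; order follows the table."""
    tset = {normalize_species_name(s) for s in tree_species}
    out, dropped = [], []
    for s in table_species:
        ns = normalize_species_name(s)
        (out if ns in tset else dropped).append(ns)
    if dropped:
        logger.warning(
            "%d species in table absent from tree (dropped): %s%s",
            len(dropped), dropped[:10], "..." if len(dropped) > 10 else "",
        )
    tree_only = sorted(tset - {normalize_species_name(s) for s in table_species})
    if tree_only:
        logger.warning("%d tree tips absent from table (ignored)", len(tree_only))
    return out
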