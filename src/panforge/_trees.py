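"""Small tree helpers: newick parsing and PAML-style ``#1`` foreground tags."""

from __future__ import annotations

import dendropy

_FG_MARK = "@@FG"


def parse_newick(newick: str, rooted: bool = True) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        rooting="force-rooted" if rooted else "force-unrooted",
        preserve_underscores=True,
    )
    return tree


def edge_key(node: dendropy.Node):
    """Stable identifier for the edge above ``node``.

    Leaf edges are keyed by the taxon label; internal edges by the frozenset
    of descendant leaf labels.
    """
    if node.is_leaf():
        return node.taxon.label
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def lookup_branch_value(key, mapping, default=None):
    """Resolve a per-branch value from a mapping keyed by edge_key or label."""
    if not isinstance(mapping, dict):
        return mapping
    if key in mapping:
        return mapping[key]
    if isinstance(key, frozenset) and len(key) == 1:
        (label,) = key
        if label in mapping:
            return mapping[label]
    if "default" in mapping:
        return mapping["default"]
    return default


def parse_foreground_tree(newick: str, rooted: bool = True):
    """Parse a newick string with ``#1`` marks on foreground branches.

    Returns ``(tree, foreground)`` where ``foreground`` is the set of
    edge keys (see :func:`edge_key`) of marked branches. A mark after a
    closing parenthesis tags the branch above that clade, as in the PAML
    tree-file convention.
    """
    marked = newick.replace(" #1", _FG_MARK).replace("#1", _FG_MARK)
    tree = parse_newick(marked, rooted=rooted)
    foreground = set()
    for node in tree.preorder_node_iter():
        label = node.taxon.label if node.taxon is not None else node.label
        if label is not None and label.endswith(_FG_MARK):
            clean = label[: -len(_FG_MARK)]
            if node.taxon is not None:
                node.taxon.label = clean
            else:
                node.label = clean or None
            foreground.add(edge_key(node))
    return tree, foreground
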