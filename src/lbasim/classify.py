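"""Scoring of inferred trees against the generating topology.

Wrong trees are assigned to one of three long-branch artefact classes:

* class I  — the two short terminals flanking the short central branch of
  topology B are grouped together (attraction by shared ancestral states,
  symplesiomorphy);
* class II — exactly one long element (a long-terminal leaf in topology A,
  a long-branch clade in topology B) is misplaced: removing it makes the
  rest of the tree identical to the truth (signal erosion / taxon
  slippage);
* class III — the two long terminal leaves of topology A are grouped
  together (mutual attraction by convergent chance similarity, the
  Felsenstein case).

"Grouped together" is operationalized as unrooted adjacency: the two
focal leaves share an internal node.  Classes are assigned with the fixed
precedence correct > III > I > II > other, so every resolved tree receives
exactly one label.
"""

from __future__ import annotations

from enum import Enum

from .topologies import TopologySpec
from .trees import Tree, prune_taxa, rf_distance

__all__ = ["ErrorClass", "classify"]


class ErrorClass(str, Enum):
    correct = "correct"
    class_I = "class_I"
    class_II = "class_II"
    class_III = "class_III"
    other = "other"


def _leaves_adjacent(tree: Tree, a: str, b: str) -> bool:
    ids = tree.leaf_ids()
    na = next(iter(tree.neighbors(ids[a])))
    nb = next(iter(tree.neighbors(ids[b])))
    return na == nb


def _restriction_matches(true_tree: Tree, inferred: Tree, keep) -> bool:
    return rf_distance(prune_taxa(true_tree, keep), prune_taxa(inferred, keep)) == 0


def _clade_intact(tree: Tree, clade: frozenset, true_tree: Tree) -> bool:
    """The clade's leaves form a split of ``tree`` and their induced
    subtree matches the true one (checked only for clades of >= 2)."""
    all_leaves = tree.leaf_labels()
    found = any(
        tree.side_leaves(u, v) in (clade, all_leaves - clade)
        for u, v in tree.internal_edges()
    )
    if not found:
        return False
    if len(clade) >= 4:  # smaller restrictions have a single topology
        return _restriction_matches(true_tree, tree, clade)
    return True


def classify(spec: TopologySpec, true_tree: Tree, inferred: Tree) -> ErrorClass:
    """Assign one error class to ``inferred`` relative to ``true_tree``."""
    if true_tree.leaf_labels() != inferred.leaf_labels():
        raise ValueError(
            "leaf sets differ between true and inferred trees: "
            f"{sorted(true_tree.leaf_labels() ^ inferred.leaf_labels())}"
        )
    if rf_distance(true_tree, inferred) == 0:
        return ErrorClass.correct

    if spec.kind == "A":
        a, b = spec.focal_long
        if _leaves_adjacent(inferred, a, b):
            return ErrorClass.class_III
    else:
        a, b = spec.focal_short_pair
        if _leaves_adjacent(inferred, a, b):
            return ErrorClass.class_I

    all_leaves = true_tree.leaf_labels()
    restored = 0
    for element in spec.focal_long:
        if isinstance(element, str):
            keep = all_leaves - {element}
        else:
            if not _clade_intact(inferred, element, true_tree):
                continue
            keep = all_leaves - element
        if _restriction_matches(true_tree, inferred, keep):
            restored += 1
    if restored == 1:
        return ErrorClass.class_II
    return ErrorClass.other
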