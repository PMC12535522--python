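"""Decision-tree CAT (DTCAT): a classification tree administered as an adaptive test.

A single CART-style tree is grown on the calibration sample with item
scores as ordinal predictors and status (complete sum >= cutoff) as the
outcome, using Gini impurity and cost-complexity pruning.  In the
administration phase each respondent is routed from the root to a leaf
using their true scores; the items encountered on the path are the
administered items (an item split twice on one path is asked once), and
the leaf label is the predicted status.  Unlike LSCAT, only the paths
pre-specified by the tree exist, so the method is adaptive only within
that fixed menu of patterns.

The tree itself is grown and pruned by scikit-learn's CART
implementation; this module extracts it into an explicit node structure
so administration, path accounting and the flowchart printer are
independent of the fitting library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Union

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .engine import AdministrationRecord, EfficiencySummary
from .io import ResponseMatrix

__all__ = ["TreeNode", "TreeLeaf", "DecisionTree", "fit_tree", "administer_dtcat",
           "administer_dtcat_all", "dtcat_item_counts"]


@dataclass(frozen=True)
class TreeLeaf:
    predicted_status: bool
    eligible_proportion: float  # calibration proportion of eligibles at the leaf
    n_calibration: int


@dataclass(frozen=True)
class TreeNode:
    """Ordinal split: go left when score(item) <= threshold."""

    item: int
    threshold: float
    left: Union["TreeNode", TreeLeaf]
    right: Union["TreeNode", TreeLeaf]


@dataclass(frozen=True)
class DecisionTree:
    root: Union[TreeNode, TreeLeaf]
    cutoff: int
    complexity: float

    @property
    def is_degenerate(self) -> bool:
        return isinstance(self.root, TreeLeaf)

    @property
    def n_leaves(self) -> int:
        def count(node):
            if isinstance(node, TreeLeaf):
                return 1
            return count(node.left) + count(node.right)

        return count(self.root)

    def max_depth_items(self) -> int:
        """Largest number of distinct items on any root-to-leaf path."""
        def walk(node, seen: frozenset) -> int:
            if isinstance(node, TreeLeaf):
                return len(seen)
            s = seen | {node.item}
            return max(walk(node.left, s), walk(node.right, s))

        return walk(self.root, frozenset())

    def render(self) -> str:
        """Human-readable administration flowchart."""
        lines: list[str] = []

        def walk(node, prefix: str) -> None:
            if isinstance(node, TreeLeaf):
                lab = "eligible" if node.predicted_status else "not eligible"
                lines.append(
                    f"{prefix}-> {lab} "
                    f"(P(eligible)={node.eligible_proportion:.3f}, n={node.n_calibration})"
                )
                return
            lines.append(f"{prefix}item {node.item + 1} <= {node.threshold:g}?")
            walk(node.left, prefix + "  yes: ")
            walk(node.right, prefix + "  no:  ")

        walk(self.root, "")
        return "\n".join(lines)


def _extract(sk_tree, node_id: int) -> Union[TreeNode, TreeLeaf]:
    t = sk_tree.tree_
    if t.children_left[node_id] == -1:
        # sklearn >= 1.3 stores class fractions in value; recover counts robustly
        raw = t.value[node_id][0]
        if raw.sum() <= 1.0 + 1e-9:
            counts = raw * t.weighted_n_node_samples[node_id]
        else:
            counts = raw
        n = int(round(counts.sum()))
        classes = list(sk_tree.classes_)
        p_elig = float(counts[classes.index(1)] / counts.sum()) if 1 in classes else 0.0
        return TreeLeaf(p_elig >= 0.5 if 1 in classes and 0 in classes else bool(classes[0]),
                        p_elig, n)
    return TreeNode(
        int(t.feature[node_id]),
        float(t.threshold[node_id]),
        _extract(sk_tree, int(t.children_left[node_id])),
        _extract(sk_tree, int(t.children_right[node_id])),
    )


def fit_tree(
    calibration: ResponseMatrix,
    cutoff: int,
    complexity: float = 0.0,
    min_leaf: int = 50,
) -> DecisionTree:
    """Grow and cost-complexity-prune a status classification tree.

    ``complexity`` is the cost-complexity pruning parameter alpha: larger
    values give smaller trees and shorter administration paths (the
    handle used for efficiency matching).  ``min_leaf`` stabilizes leaf
    labels on survey-scale calibration samples.  A calibration sample
    with a single status yields a degenerate single-leaf tree (warned):
    such a tree asks no items and is flagged at administration.
    """
    if complexity < 0:
        raise ValueError("complexity must be >= 0")
    y = calibration.status(int(cutoff)).astype(int)
    if y.min() == y.max():
        warnings.warn("calibration sample has a single status; degenerate tree",
                      stacklevel=2)
        p = float(y.mean())
        return DecisionTree(TreeLeaf(bool(y[0]), p, y.size), int(cutoff), complexity)
    clf = DecisionTreeClassifier(
        criterion="gini",
        ccp_alpha=float(complexity),
        min_samples_leaf=int(min_leaf),
        random_state=0,
    )
    clf.fit(calibration.scores, y)
    root = _extract(clf, 0)
    return DecisionTree(root, int(cutoff), float(complexity))


def administer_dtcat(
    tree: DecisionTree, respondent_row: np.ndarray, respondent: int = 0
) -> AdministrationRecord:
    """Route a respondent down the tree using their observed scores.

    ``n_items`` counts distinct items queried on the path.  A degenerate
    single-leaf tree asks nothing: it is flagged with n_items = 0 and
    stopped_early = True.  ``final_probability`` is the leaf's calibration
    proportion of eligibles (DTCAT produces no model probability).
    """
    row = np.asarray(respondent_row, dtype=np.int64).ravel()
    node = tree.root
    items: list[int] = []
    scores: list[int] = []
    asked: set[int] = set()
    while isinstance(node, TreeNode):
        if node.item not in asked:
            asked.add(node.item)
            items.append(node.item)
            scores.append(int(row[node.item]))
        node = node.left if row[node.item] <= node.threshold else node.right
    return AdministrationRecord(
        respondent,
        tuple(items),
        tuple(scores),
        node.eligible_proportion,
        node.predicted_status,
        True,
    )


def dtcat_item_counts(tree: DecisionTree, data: ResponseMatrix) -> np.ndarray:
    """Administered-item counts per respondent, routing unique patterns once."""
    patterns, inverse = np.unique(data.scores, axis=0, return_inverse=True)
    per_pattern = np.array(
        [administer_dtcat(tree, row).n_items for row in patterns]
    )
    return per_pattern[inverse]


def administer_dtcat_all(
    tree: DecisionTree, data: ResponseMatrix
) -> tuple[list[AdministrationRecord], EfficiencySummary]:
    records = [administer_dtcat(tree, row, i) for i, row in enumerate(data.scores)]
    return records, EfficiencySummary.from_records(records)
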