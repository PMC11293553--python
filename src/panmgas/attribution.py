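"""Additive per-sample feature attributions for tree ensembles.

For every sample, each decision tree's predicted probability is
decomposed along the sample's root-to-leaf path: at each internal node
the change in node value between parent and child is credited to the
feature the node splits on. Averaging over the forest gives one
attribution per (sample, feature) plus a shared base value, satisfying
local accuracy exactly:

    base + sum_f attribution(sample, f) == predict_proba(sample)

The decomposition is computed node-by-node with boolean sample masks,
so it is vectorized over samples and linear in the number of tree nodes.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestClassifier

__all__ = ["forest_attributions"]


def _tree_attributions(tree, X: np.ndarray, class_idx: int) -> tuple[np.ndarray, float]:
    t = tree.tree_
    raw = t.value[:, 0, :]
    totals = raw.sum(axis=1)
    probs = raw[:, class_idx] / np.where(totals == 0, 1.0, totals)
    left, right, feature, threshold = (
        t.children_left, t.children_right, t.feature, t.threshold,
    )
    n, d = X.shape
    contrib = np.zeros((n, d))
    stack = [(0, np.ones(n, dtype=bool))]
    while stack:
        node, mask = stack.pop()
        if left[node] == -1:  # leaf
            continue
        f = feature[node]
        goes_left = X[:, f] <= threshold[node]
        lmask = mask & goes_left
        rmask = mask & ~goes_left
        if lmask.any():
            contrib[lmask, f] += probs[left[node]] - probs[node]
            stack.append((left[node], lmask))
        if rmask.any():
            contrib[rmask, f] += probs[right[node]] - probs[node]
            stack.append((right[node], rmask))
    return contrib, float(probs[0])


def forest_attributions(
    model: RandomForestClassifier, X, positive_class=1
) -> tuple[np.ndarray, float]:
    """(attributions, base_value) for the positive-class probability.

    attributions has shape (n_samples, n_features); base_value is the
    forest-average root value. Their sum reproduces
    ``model.predict_proba(X)[:, positive_class]`` to float precision.
    """
    X = np.asarray(X, dtype=np.float32)
    class_idx = int(np.flatnonzero(model.classes_ == positive_class)[0])
    total = np.zeros(X.shape, dtype=float)
    base = 0.0
    for est in model.estimators_:
        c, b = _tree_attributions(est, X, class_idx)
        total += c
        base += b
    k = len(model.estimators_)
    return total / k, base / k
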