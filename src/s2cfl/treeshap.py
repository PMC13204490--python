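"""Path-dependent TreeSHAP for scikit-learn decision-tree ensembles.

Computes exact Shapley feature attributions of a tree's output under the
path-dependent conditional expectation (absent features are marginalized by
training-cover fractions at each split).  Satisfies local accuracy exactly:
sum(phi) + base_value == model output.

This is the polynomial-time algorithm for tree ensembles (the EXTEND/UNWIND
path-weight recursion); correctness is checked in the test suite against a
brute-force subset-enumeration Shapley oracle on small trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UnsupportedModelError


@dataclass
class _PathEntry:
    d: int  # feature index (-1 for the root placeholder)
    z: float  # fraction of "zero" (cold) paths flowing through
    o: float  # fraction of "one" (hot) paths (0 or 1 here)
    w: float  # permutation weight


def _extend(path: list[_PathEntry], pz: float, po: float, pi: int) -> list[_PathEntry]:
    path = [ _PathEntry(e.d, e.z, e.o, e.w) for e in path ]
    l = len(path)
    path.append(_PathEntry(pi, pz, po, 1.0 if l == 0 else 0.0))
    for i in range(l - 1, -1, -1):
        path[i + 1].w += po * path[i].w * (i + 1) / (l + 1)
        path[i].w = pz * path[i].w * (l - i) / (l + 1)
    return path


def _unwind_weights(path: list[_PathEntry], i: int) -> tuple[list[_PathEntry], float]:
    """Remove entry i from the path; also return the summed weights of the
    unwound path (used for leaf contributions)."""
    l = len(path) - 1
    one = path[i].o
    zero = path[i].z
    out = [_PathEntry(e.d, e.z, e.o, e.w) for e in path]
    n = out[l].w
    for j in range(l - 1, -1, -1):
        if one != 0:
            t = out[j].w
            out[j].w = n * (l + 1) / ((j + 1) * one)
            n = t - out[j].w * zero * (l - j) / (l + 1)
        else:
            out[j].w = out[j].w * (l + 1) / (zero * (l - j))
    for j in range(i, l):
        out[j].d, out[j].z, out[j].o = out[j + 1].d, out[j + 1].z, out[j + 1].o
    return out[:-1], float(sum(e.w for e in out[:-1]))


def _leaf_values(tree, class_index: int | None) -> np.ndarray:
    v = tree.value  # (n_nodes, n_outputs, n_classes_or_1)
    if class_index is None:
        return v[:, 0, 0].astype(float)
    row = v[:, 0, :].astype(float)
    totals = row.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return (row / totals)[:, class_index]


def tree_shap_single(tree, x: np.ndarray, class_index: int | None = None) -> tuple[np.ndarray, float]:
    """SHAP values and base value of one fitted sklearn tree at sample ``x``.

    ``class_index`` selects a class-probability output for classifiers; None
    means the regression output.
    """
    left, right = tree.children_left, tree.children_right
    feature, threshold = tree.feature, tree.threshold
    cover = tree.weighted_n_node_samples.astype(float)
    values = _leaf_values(tree, class_index)
    phi = np.zeros(x.shape[0])

    def recurse(j: int, path: list[_PathEntry], pz: float, po: float, pi: int) -> None:
        path = _extend(path, pz, po, pi)
        if left[j] < 0:  # leaf
            for i in range(1, len(path)):
                _, w = _unwind_weights(path, i)
                phi[path[i].d] += w * (path[i].o - path[i].z) * values[j]
            return
        hot, cold = (left[j], right[j]) if x[feature[j]] <= threshold[j] else (right[j], left[j])
        iz, io = 1.0, 1.0
        k = next((idx for idx in range(len(path)) if path[idx].d == feature[j]), None)
        if k is not None:
            iz, io = path[k].z, path[k].o
            path, _ = _unwind_weights(path, k)
        recurse(hot, path, iz * cover[hot] / cover[j], io, feature[j])
        recurse(cold, path, iz * cover[cold] / cover[j], 0.0, feature[j])

    recurse(0, [], 1.0, 1.0, -1)
    # base value: cover-weighted expectation of the tree output
    base = path_expectation(tree, class_index)
    return phi, base


def path_expectation(tree, class_index: int | None = None) -> float:
    """Cover-weighted expected output (the attribution base value)."""
    values = _leaf_values(tree, class_index)
    cover = tree.weighted_n_node_samples.astype(float)
    left = tree.children_left
    is_leaf = left < 0
    return float(np.sum(values[is_leaf] * cover[is_leaf]) / cover[0])


def forest_shap(model, X: np.ndarray, class_indices: np.ndarray | None = None):
    """SHAP values for a RandomForest (mean over trees of per-tree values).

    ``class_indices``: per-row class selection (defaults to the predicted
    class).  Returns (phi (n, m), base (n,)) in probability space; local
    accuracy: phi.sum(1) + base == predict_proba[row, class].
    """
    from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

    if not isinstance(model, (RandomForestClassifier, RandomForestRegressor)):
        raise UnsupportedModelError(f"forest_shap does not support {type(model).__name__}")
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    is_clf = isinstance(model, RandomForestClassifier)
    if is_clf and class_indices is None:
        class_indices = np.argmax(model.predict_proba(X), axis=1)
    phi = np.zeros((n, m))
    base = np.zeros(n)
    trees = [est.tree_ for est in model.estimators_]
    for r in range(n):
        ci = int(class_indices[r]) if is_clf else None
        for t in trees:
            p, b = tree_shap_single(t, X[r], ci)
            phi[r] += p
            base[r] += b
    phi /= len(trees)
    base /= len(trees)
    return phi, base
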