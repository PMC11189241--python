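"""Path-dependent TreeSHAP for scikit-learn tree ensembles.

Exact per-record Shapley attributions for tree models, where the
conditional expectation of a feature coalition is evaluated by following
decision paths and weighting the unconditioned branch by its training cover
(the path-dependent feature perturbation).  The polynomial-time algorithm
maintains, along each root-to-leaf path, the set of unique split features
with their "zero" (cover) and "one" (decision) fractions and the
permutation-weight accumulator; attributions are accumulated at the leaves.

Attributions are computed in probability space (the ensemble-averaged leaf
class-1 fraction), so for every record ``base_value + sum(values) equals
predict_proba(x)[1]`` up to floating-point tolerance (local accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._compat import njit


@njit(cache=False)
def _unwound_sum(pz, po, pw, off, ud, i):
    one = po[off + i]
    zero = pz[off + i]
    nxt = pw[off + ud]
    total = 0.0
    if one != 0.0:
        for j in range(ud - 1, -1, -1):
            tmp = nxt * (ud + 1) / ((j + 1) * one)
            total += tmp
            nxt = pw[off + j] - tmp * zero * (ud - j) / (ud + 1)
    else:
        for j in range(ud - 1, -1, -1):
            total += pw[off + j] / (zero * (ud - j) / (ud + 1))
    return total


@njit(cache=False)
def _unwind(pd_, pz, po, pw, off, ud, i):
    one = po[off + i]
    zero = pz[off + i]
    nxt = pw[off + ud]
    for j in range(ud - 1, -1, -1):
        if one != 0.0:
            tmp = pw[off + j]
            pw[off + j] = nxt * (ud + 1) / ((j + 1) * one)
            nxt = tmp - pw[off + j] * zero * (ud - j) / (ud + 1)
        else:
            pw[off + j] = pw[off + j] * (ud + 1) / (zero * (ud - j))
    for j in range(i, ud):
        pd_[off + j] = pd_[off + j + 1]
        pz[off + j] = pz[off + j + 1]
        po[off + j] = po[off + j + 1]


@njit(cache=False)
def _extend(pd_, pz, po, pw, off, ud, pzf, pof, pif):
    pd_[off + ud] = pif
    pz[off + ud] = pzf
    po[off + ud] = pof
    pw[off + ud] = 1.0 if ud == 0 else 0.0
    for i in range(ud - 1, -1, -1):
        pw[off + i + 1] += pof * pw[off + i] * (i + 1) / (ud + 1)
        pw[off + i] = pzf * pw[off + i] * (ud - i) / (ud + 1)


@njit(cache=False)
def _recurse(cl, cr, ft, th, cover, leaf_val, x, phi,
             node, ud, off, pd_, pz, po, pw, pzf, pof, pif):
    # copy the parent's unique path, then extend with the incoming fractions
    noff = off + ud
    for i in range(ud):
        pd_[noff + i] = pd_[off + i]
        pz[noff + i] = pz[off + i]
        po[noff + i] = po[off + i]
        pw[noff + i] = pw[off + i]
    _extend(pd_, pz, po, pw, noff, ud, pzf, pof, pif)

    if cl[node] < 0:  # leaf
        for i in range(1, ud + 1):
            w = _unwound_sum(pz, po, pw, noff, ud, i)
            phi[pd_[noff + i]] += w * (po[noff + i] - pz[noff + i]) * leaf_val[node]
        return

    f = ft[node]
    if x[f] <= th[node]:
        hot, cold = cl[node], cr[node]
    else:
        hot, cold = cr[node], cl[node]
    hot_frac = cover[hot] / cover[node]
    cold_frac = cover[cold] / cover[node]
    iz = 1.0
    io = 1.0
    d = ud
    for i in range(ud + 1):
        if pd_[noff + i] == f:
            iz = pz[noff + i]
            io = po[noff + i]
            _unwind(pd_, pz, po, pw, noff, ud, i)
            d = ud - 1
            break
    _recurse(cl, cr, ft, th, cover, leaf_val, x, phi,
             hot, d + 1, noff, pd_, pz, po, pw, hot_frac * iz, io, f)
    _recurse(cl, cr, ft, th, cover, leaf_val, x, phi,
             cold, d + 1, noff, pd_, pz, po, pw, cold_frac * iz, 0.0, f)


@njit(cache=False)
def _shap_one_tree(cl, cr, ft, th, cover, leaf_val, X, phi, maxdepth):
    size = (maxdepth + 2) * (maxdepth + 3) // 2 + maxdepth + 3
    pd_ = np.empty(size, dtype=np.int64)
    pz = np.empty(size)
    po = np.empty(size)
    pw = np.empty(size)
    for r in range(X.shape[0]):
        _recurse(cl, cr, ft, th, cover, leaf_val, X[r], phi[r],
                 0, 0, 0, pd_, pz, po, pw, 1.0, 1.0, -1)


@dataclass
class ShapMatrix:
    """Per-record attributions plus the shared base value.

    ``values[r, j]`` is the contribution of feature ``j`` to record ``r``'s
    predicted lonely-class probability relative to ``base_value``; positive
    values push toward the lonely class.
    """

    values: np.ndarray
    base_value: float
    feature_names: list[str]

    def mean_abs(self) -> np.ndarray:
        return np.abs(self.values).mean(axis=0)


def _tree_arrays(tree):
    t = tree.tree_
    v = t.value[:, 0, :].astype(float)
    tot = v.sum(axis=1)
    p1 = np.where(tot > 0, v[:, -1] / np.maximum(tot, 1e-300), 0.0)
    if v.shape[1] == 1:  # degenerate single-class tree
        p1 = v[:, 0] / np.maximum(tot, 1e-300)
    return (t.children_left.astype(np.int64), t.children_right.astype(np.int64),
            t.feature.astype(np.int64), t.threshold.astype(float),
            t.weighted_n_node_samples.astype(float), p1, int(t.max_depth))


def tree_shap(model, X, feature_names=None, check_additivity: bool = True) -> ShapMatrix:
    """Path-dependent SHAP values for a fitted RandomForestClassifier.

    ``X`` may be a DataFrame or array with the model's feature count; the
    returned attributions are in probability units of the positive (lonely)
    class, averaged over the ensemble's trees.
    """
    if hasattr(X, "columns"):
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy(float)
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    p_model = getattr(model, "n_features_in_", X.shape[1])
    if X.shape[1] != p_model:
        raise ValueError(f"feature mismatch: model expects {p_model} features, "
                         f"got {X.shape[1]}")
    feature_names = feature_names or [f"x{j}" for j in range(X.shape[1])]

    trees = getattr(model, "estimators_", [model])
    phi = np.zeros_like(X)
    base = 0.0
    for est in trees:
        cl, cr, ft, th, cover, p1, maxdepth = _tree_arrays(est)
        tphi = np.zeros_like(X)
        _shap_one_tree(cl, cr, ft, th, cover, p1, X, tphi, maxdepth)
        phi += tphi
        base += p1[0]
    phi /= len(trees)
    base /= len(trees)

    if check_additivity and hasattr(model, "predict_proba"):
        pos = list(model.classes_).index(model.classes_[-1])
        pred = model.predict_proba(X)[:, pos]
        err = np.max(np.abs(base + phi.sum(axis=1) - pred)) if len(X) else 0.0
        if err > 1e-6:
            raise AssertionError(f"local accuracy violated: max error {err:.2e}")
    return ShapMatrix(phi, float(base), feature_names)
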