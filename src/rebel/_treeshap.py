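"""Exact TreeSHAP in double precision for gradient-boosted tree ensembles.

Implements the polynomial-time path algorithm for Shapley values of tree
ensembles (conditional expectations weighted by training-data cover),
operating on trees parsed out of an xgboost booster.  All arithmetic is
float64, so the local-accuracy identity — attributions plus the expected
value equal the model margin — holds to near machine precision, which the
float32 output of the booster's own contribution predictor cannot guarantee
for deep trees.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import xgboost as xgb
from numba import njit

_PATH_CAP = 64    # longest supported decision path (depth + 2)
_STACK_CAP = 256


@dataclass(frozen=True)
class ParsedTrees:
    """Flat arrays describing every tree of a booster."""

    # per node, concatenated over trees
    child_left: np.ndarray   # -1 for leaves
    child_right: np.ndarray
    feature: np.ndarray      # -1 for leaves
    threshold: np.ndarray
    value: np.ndarray        # leaf margin contribution (0 for internal)
    cover: np.ndarray
    tree_offset: np.ndarray  # start index of each tree's nodes
    base_offset: float       # margin-space intercept of the booster

    @property
    def n_trees(self) -> int:
        return len(self.tree_offset)

    @property
    def expected_value(self) -> float:
        """Cover-weighted mean margin of the ensemble (the SHAP base value)."""
        total = self.base_offset
        for t in range(self.n_trees):
            start = self.tree_offset[t]
            end = (self.tree_offset[t + 1] if t + 1 < self.n_trees
                   else len(self.value))
            total += _tree_expectation(
                self.child_left, self.child_right, self.value, self.cover,
                start,
            )
        return total


def _margin_intercept(booster: xgb.Booster) -> float:
    config = json.loads(booster.save_config())
    learner = config["learner"]
    base_score = float(learner["learner_model_param"]["base_score"])
    objective = learner["objective"]["name"]
    if objective.startswith(("binary:logistic", "reg:logistic")):
        base_score = min(max(base_score, 1e-15), 1 - 1e-15)
        return math.log(base_score / (1.0 - base_score))
    return base_score


def parse_booster(booster: xgb.Booster) -> ParsedTrees:
    df = booster.trees_to_dataframe()
    id_to_idx = {i: k for k, i in enumerate(df["ID"])}
    n = len(df)
    child_left = np.full(n, -1, dtype=np.int64)
    child_right = np.full(n, -1, dtype=np.int64)
    feature = np.full(n, -1, dtype=np.int64)
    threshold = np.zeros(n)
    value = np.zeros(n)
    cover = df["Cover"].to_numpy(dtype=float)
    tree_ids = df["Tree"].to_numpy()
    tree_offset = np.flatnonzero(np.diff(tree_ids, prepend=-1) != 0)
    leaf = df["Feature"].to_numpy() == "Leaf"
    value[leaf] = df.loc[leaf, "Gain"].to_numpy(dtype=float)
    feat_names = booster.feature_names or []
    name_to_idx = {f: i for i, f in enumerate(feat_names)}
    for k, row in enumerate(df.itertuples()):
        if leaf[k]:
            continue
        child_left[k] = id_to_idx[row.Yes]
        child_right[k] = id_to_idx[row.No]
        f = row.Feature
        feature[k] = name_to_idx.get(f, -1)
        if feature[k] < 0:  # default "f<i>" naming
            feature[k] = int(str(f).lstrip("f"))
        # thresholds arrive as shortest-decimal reprs of the model's float32
        # values; round-trip through float32 so comparisons against
        # float32-quantized inputs reproduce the booster's routing exactly
        threshold[k] = float(np.float32(row.Split))
    return ParsedTrees(
        child_left=child_left, child_right=child_right, feature=feature,
        threshold=threshold, value=value, cover=cover,
        tree_offset=tree_offset.astype(np.int64),
        base_offset=_margin_intercept(booster),
    )


@njit(cache=False)
def _tree_expectation(child_left, child_right, value, cover, root):
    """Cover-weighted mean leaf value of one tree (iterative DFS)."""
    total = 0.0
    stack = np.empty(_STACK_CAP, np.int64)
    stack[0] = root
    top = 1
    while top > 0:
        top -= 1
        node = stack[top]
        if child_left[node] < 0:
            total += value[node] * cover[node]
        else:
            stack[top] = child_left[node]
            stack[top + 1] = child_right[node]
            top += 2
    return total / cover[root]


@njit(cache=False)
def _tree_margin(child_left, child_right, feature, threshold, value, root, x):
    node = root
    while child_left[node] >= 0:
        if x[feature[node]] < threshold[node]:
            node = child_left[node]
        else:
            node = child_right[node]
    return value[node]


@njit(cache=False)
def _shap_one_tree(child_left, child_right, feature, threshold, value, cover,
                   root, x, phi):
    """Add one tree's exact Shapley contributions for sample x into phi.

    Iterative depth-first traversal; each stack frame owns a copy of the
    decision path (feature index, zero/one fractions, permutation weights)
    so no unwinding is needed on return.
    """
    D = _PATH_CAP
    st_node = np.empty(_STACK_CAP, np.int64)
    st_len = np.empty(_STACK_CAP, np.int64)
    st_pz = np.empty(_STACK_CAP, np.float64)
    st_po = np.empty(_STACK_CAP, np.float64)
    st_pi = np.empty(_STACK_CAP, np.int64)
    st_d = np.empty((_STACK_CAP, D), np.int64)
    st_z = np.empty((_STACK_CAP, D), np.float64)
    st_o = np.empty((_STACK_CAP, D), np.float64)
    st_w = np.empty((_STACK_CAP, D), np.float64)

    st_node[0] = root
    st_len[0] = 0
    st_pz[0] = 1.0
    st_po[0] = 1.0
    st_pi[0] = -1
    top = 1

    m_d = np.empty(D, np.int64)
    m_z = np.empty(D, np.float64)
    m_o = np.empty(D, np.float64)
    m_w = np.empty(D, np.float64)

    while top > 0:
        top -= 1
        node = st_node[top]
        l = st_len[top]
        pz = st_pz[top]
        po = st_po[top]
        pi = st_pi[top]
        for i in range(l):
            m_d[i] = st_d[top, i]
            m_z[i] = st_z[top, i]
            m_o[i] = st_o[top, i]
            m_w[i] = st_w[top, i]
        # EXTEND path with (pz, po, pi)
        m_d[l] = pi
        m_z[l] = pz
        m_o[l] = po
        m_w[l] = 1.0 if l == 0 else 0.0
        for i in range(l - 1, -1, -1):
            m_w[i + 1] += po * m_w[i] * (i + 1.0) / (l + 1.0)
            m_w[i] = pz * m_w[i] * (l - i) / (l + 1.0)
        depth = l  # unique_depth after extension (index of last element)

        if child_left[node] < 0:
            v = value[node]
            for i in range(1, depth + 1):
                # unwound path sum for element i
                one = m_o[i]
                zero = m_z[i]
                total = 0.0
                if one != 0.0:
                    next_one = m_w[depth]
                    for j in range(depth - 1, -1, -1):
                        tmp = next_one * (depth + 1.0) / ((j + 1.0) * one)
                        total += tmp
                        next_one = m_w[j] - tmp * zero * (depth - j) / (
                            depth + 1.0
                        )
                else:
                    for j in range(depth - 1, -1, -1):
                        total += m_w[j] * (depth + 1.0) / (
                            zero * (depth - j)
                        )
                phi[m_d[i]] += total * (m_o[i] - m_z[i]) * v
            continue

        f = feature[node]
        if x[f] < threshold[node]:
            hot, cold = child_left[node], child_right[node]
        else:
            hot, cold = child_right[node], child_left[node]
        iz = 1.0
        io = 1.0
        k = -1
        for i in range(1, depth + 1):
            if m_d[i] == f:
                k = i
                break
        plen = depth + 1  # number of path elements
        if k >= 0:
            # UNWIND element k
            iz = m_z[k]
            io = m_o[k]
            n_ = depth
            if io != 0.0:
                next_one = m_w[n_]
                for j in range(n_ - 1, -1, -1):
                    tmp = m_w[j]
                    m_w[j] = next_one * (n_ + 1.0) / ((j + 1.0) * io)
                    next_one = tmp - m_w[j] * iz * (n_ - j) / (n_ + 1.0)
            else:
                for j in range(n_ - 1, -1, -1):
                    m_w[j] = m_w[j] * (n_ + 1.0) / (iz * (n_ - j))
            for j in range(k, n_):
                m_d[j] = m_d[j + 1]
                m_z[j] = m_z[j + 1]
                m_o[j] = m_o[j + 1]
            plen = depth

        # push cold then hot (each frame copies the current path)
        for child, cz, co in (
            (cold, iz * cover[cold] / cover[node], 0.0),
            (hot, iz * cover[hot] / cover[node], io),
        ):
            st_node[top] = child
            st_len[top] = plen
            st_pz[top] = cz
            st_po[top] = co
            st_pi[top] = f
            for i in range(plen):
                st_d[top, i] = m_d[i]
                st_z[top, i] = m_z[i]
                st_o[top, i] = m_o[i]
                st_w[top, i] = m_w[i]
            top += 1


def _routing_view(X: np.ndarray) -> np.ndarray:
    """Quantize features through float32 so threshold comparisons match the
    booster's own single-precision routing, then widen back to float64."""
    return np.ascontiguousarray(
        np.asarray(X, dtype=np.float32), dtype=np.float64
    )


def shap_values(trees: ParsedTrees, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact float64 Shapley values and the shared base (expected) value.

    Returns ``(phi, base)`` where ``phi`` has shape (n, M) and
    ``phi.sum(1) + base`` equals :func:`margins` exactly (float64).
    """
    X = _routing_view(X)
    n, M = X.shape
    phi = np.zeros((n, M))
    n_nodes = len(trees.value)
    for t in range(trees.n_trees):
        root = int(trees.tree_offset[t])
        for s in range(n):
            _shap_one_tree(
                trees.child_left, trees.child_right, trees.feature,
                trees.threshold, trees.value, trees.cover, root, X[s],
                phi[s],
            )
    return phi, trees.expected_value


def margins(trees: ParsedTrees, X: np.ndarray) -> np.ndarray:
    """Float64 margin (log-odds) output of the parsed ensemble."""
    X = _routing_view(X)
    out = np.full(X.shape[0], trees.base_offset)
    for t in range(trees.n_trees):
        root = int(trees.tree_offset[t])
        for s in range(X.shape[0]):
            out[s] += _tree_margin(
                trees.child_left, trees.child_right, trees.feature,
                trees.threshold, trees.value, root, X[s],
            )
    return out
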