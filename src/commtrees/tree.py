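"""Sum-of-squares multivariate regression tree (MRT).

An MRT recursively splits a set of quadrats into two groups so as to
minimise the within-group sum of squared Euclidean distances of the
multi-column community response to the group centroid — CART with a
multivariate response and squared-Euclidean impurity.  Each split is a rule
on one explanatory variable: a threshold for numeric and ordered-categorical
variables ("value <= t" goes left; ordered variables admit only contiguous
splits in their declared level order) or a level-set for unordered
categoricals ("value in S" goes left; all 2^(L-1) - 1 binary partitions of
the observed levels are searched).

Model quality is summarised by the relative error RE = (sum of leaf
within-node SS) / (root SS) = 1 - R^2; an unsplit tree has RE = 1.  Trees
are pruned by CART weakest-link cost-complexity pruning, yielding the nested
sequence of subtrees used for cross-validated size selection.

Missing predictor values are allowed: candidate splits are scored on the
rows where the split variable is observed, and rows missing it are then sent
to the child with more training observations (majority rule, recorded on the
rule).  Surrogate splits are not implemented.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .community import CommunityMatrix, PredictorTable

__all__ = [
    "SplitRule",
    "GrowControl",
    "MultivariateTree",
    "MultivariateRegressionTree",
    "node_ss",
    "best_split",
    "grow_tree",
    "relative_error",
    "enumerate_level_sets",
]


# ---------------------------------------------------------------------------
# Predictor preparation
# ---------------------------------------------------------------------------

@dataclass
class _Column:
    name: str
    kind: str                  # numeric | ordered | unordered
    codes: np.ndarray          # float64; NaN marks missing; categoricals hold level codes
    levels: tuple | None       # level labels for categoricals


def _prepare_columns(X, variable_kinds=None) -> list[_Column]:
    """Turn a PredictorTable / DataFrame / array into typed columns."""
    if isinstance(X, PredictorTable):
        df = X.data
        kinds = {n: s.kind for n, s in X.variables.items()}
    elif isinstance(X, pd.DataFrame):
        df = X
        kinds = dict(variable_kinds or {})
    else:
        arr = np.asarray(X, dtype=float)
        df = pd.DataFrame(arr, columns=[f"x{j}" for j in range(arr.shape[1])])
        kinds = {}

    cols: list[_Column] = []
    for name in df.columns:
        col = df[name]
        kind = kinds.get(name)
        if kind is None:
            if isinstance(col.dtype, pd.CategoricalDtype):
                kind = "ordered" if col.cat.ordered else "unordered"
            elif pd.api.types.is_numeric_dtype(col):
                kind = "numeric"
            else:
                kind = "unordered"
        if kind == "numeric":
            codes = pd.to_numeric(col, errors="raise").to_numpy(dtype=float)
            levels = None
        else:
            if isinstance(col.dtype, pd.CategoricalDtype):
                cat = col
            else:
                cat = col.astype("category")
            codes = cat.cat.codes.to_numpy(dtype=float)
            codes[codes < 0] = np.nan
            levels = tuple(cat.cat.categories)
        cols.append(_Column(name, kind, codes, levels))
    return cols


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitRule:
    """One binary split: threshold (numeric/ordered) or level-set (unordered).

    For threshold form, rows with value <= threshold go left; for level-set
    form, rows with value in left_levels go left.  ``improvement`` is the
    decrease in within-node SS achieved by the split; ``missing_side`` is
    where rows missing the variable are routed.
    """

    variable: str
    kind: str
    threshold: float | None = None
    left_levels: frozenset | None = None
    improvement: float = 0.0
    missing_side: str = "left"
    levels: tuple | None = None  # declared level order, for description

    def __post_init__(self):
        if self.improvement < 0:
            raise ValueError("split improvement must be >= 0")
        if self.left_levels is not None:
            if not self.left_levels or (self.levels and
                                        set(self.left_levels) >= set(self.levels)):
                raise ValueError("level-set must be a nonempty proper subset")

    def describe(self, side: str) -> str:
        """Human-readable breakpoint description of one side."""
        if self.kind == "numeric":
            op = "<" if side == "left" else ">="
            return f"{self.variable} {op} {self.threshold:g}"
        if self.kind == "ordered":
            # threshold lies between level codes; list the levels on each side
            lo = [l for i, l in enumerate(self.levels) if i <= self.threshold]
            hi = [l for i, l in enumerate(self.levels) if i > self.threshold]
            chosen = lo if side == "left" else hi
            return f"{self.variable} = {','.join(map(str, chosen))}"
        members = sorted(self.left_levels) if side == "left" else \
            sorted(set(self.levels or ()) - set(self.left_levels))
        return f"{self.variable} = {','.join(map(str, members))}"

    def go_left(self, value) -> bool | None:
        """Route one value; None means missing -> use missing_side."""
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return None
        if self.kind in ("numeric", "ordered"):
            return bool(value <= self.threshold)
        return value in self.left_levels


@dataclass
class GrowControl:
    """Growth controls for tree construction.

    min_improvement is relative: a split must reduce SS by at least this
    fraction of the root SS.  predictor order (the column order of X)
    breaks ties between equally good splits.
    """

    min_node_size: int = 5
    min_split_size: int = 10
    min_improvement: float = 0.001
    max_depth: int | None = None

    def __post_init__(self):
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be >= 1")
        if self.min_split_size < 2 * self.min_node_size:
            raise ValueError("min_split_size must be >= 2 * min_node_size")


class _Node:
    __slots__ = ("id", "idx", "n", "centroid", "ss", "depth", "rule",
                 "left", "right", "leaf_id")

    def __init__(self, id, idx, centroid, ss, depth):
        self.id = id
        self.idx = idx
        self.n = len(idx)
        self.centroid = centroid
        self.ss = ss
        self.depth = depth
        self.rule = None
        self.left = None
        self.right = None
        self.leaf_id = None

    @property
    def is_leaf(self) -> bool:
        return self.rule is None


@dataclass
class _PruneStep:
    alpha: float
    n_leaves: int
    collapsed: frozenset       # ids of internal nodes acting as leaves
    leaf_ss: float             # sum of effective-leaf SS

    def relative_error(self, root_ss: float) -> float:
        return self.leaf_ss / root_ss if root_ss > 0 else 0.0


# ---------------------------------------------------------------------------
# Core numerics
# ---------------------------------------------------------------------------

def node_ss(rows: np.ndarray) -> float:
    """Within-node sum of squares: total squared Euclidean distance of each
    row to the columnwise mean."""
    rows = np.asarray(rows, dtype=float)
    if rows.ndim == 1:
        rows = rows[:, None]
    if rows.shape[0] == 0:
        raise ValueError("node_ss of an empty set is undefined")
    centered = rows - rows.mean(axis=0)
    return float(np.einsum("ij,ij->", centered, centered))


def enumerate_level_sets(levels: Sequence) -> list[frozenset]:
    """All binary partitions of a level set, as the left-hand subsets.

    Each partition is represented once, by the side containing the first
    level; for L levels there are exactly 2^(L-1) - 1 of them.
    """
    levels = list(levels)
    if len(levels) < 2:
        return []
    first, rest = levels[0], levels[1:]
    out = []
    for r in range(len(rest) + 1):
        for combo in combinations(rest, r):
            s = frozenset((first, *combo))
            if len(s) < len(levels):
                out.append(s)
    return out


def _split_candidates_numeric(v, Y, min_node):
    """Vectorised threshold search.  Returns (improvement, threshold) of the
    best admissible cut or None; ties resolved toward the smaller threshold.

    Between-group identity: for a cut after sorted position k, the SS
    decrease equals |S_k|^2/k + |T-S_k|^2/(m-k) - |T|^2/m with S_k the
    cumulative response sum and T the total.
    """
    m = len(v)
    order = np.argsort(v)        # ties cannot host a cut, so order within ties is inert
    vs = v[order]
    C = np.cumsum(Y[order], axis=0)
    T = C[-1]
    k = np.arange(1, m)
    ok = (vs[:-1] < vs[1:]) & (k >= min_node) & (m - k >= min_node)
    if not ok.any():
        return None
    Ck = C[:-1]
    left = np.einsum("ij,ij->i", Ck, Ck) / k
    rk = T - Ck
    right = np.einsum("ij,ij->i", rk, rk) / (m - k)
    imp = left + right - (T @ T) / m
    imp[~ok] = -np.inf
    best = int(np.argmax(imp))           # first max -> smallest threshold
    thr = 0.5 * (vs[best] + vs[best + 1])
    return float(imp[best]), thr


def _split_candidates_levels(v, Y, levels, min_node):
    """Exhaustive level-set search for an unordered categorical."""
    m = len(v)
    codes = v.astype(int)
    L = len(levels)
    counts = np.bincount(codes, minlength=L)
    q = Y.shape[1]
    sums = np.zeros((L, q))
    np.add.at(sums, codes, Y)
    present = [i for i in range(L) if counts[i] > 0]
    if len(present) < 2:
        return None
    T = sums.sum(axis=0)
    total = (T @ T) / m
    best = None
    for subset in enumerate_level_sets(present):
        nl = int(sum(counts[i] for i in subset))
        if nl < min_node or m - nl < min_node:
            continue
        Sl = sums[list(subset)].sum(axis=0)
        Sr = T - Sl
        imp = (Sl @ Sl) / nl + (Sr @ Sr) / (m - nl) - total
        key = tuple(sorted(str(levels[i]) for i in subset))
        if best is None or imp > best[0] + 1e-12 or (
                abs(imp - best[0]) <= 1e-12 and key < best[2]):
            left_levels = frozenset(levels[i] for i in subset)
            best = (float(imp), left_levels, key)
    if best is None:
        return None
    return best[0], best[1]


def best_split(Y, X, control: GrowControl | None = None, *,
               root_ss: float | None = None, variable_kinds=None):
    """Best single split of all rows of Y.

    Searches every variable and every admissible cutpoint / level-set,
    maximising the SS decrease; ties go to the earlier variable in column
    order, then the smaller threshold / lexicographically smallest
    level-set.  Returns a :class:`SplitRule` or None.
    """
    control = control or GrowControl()
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    cols = _prepare_columns(X, variable_kinds)
    idx = np.arange(Y.shape[0])
    if root_ss is None:
        root_ss = node_ss(Y)
    return _best_split_impl(Y, cols, idx, control, root_ss)[0]


def _batch_numeric_scan(V, Y, min_node):
    """Threshold search for several complete numeric/ordered variables at
    once (columns of V).  Returns per-variable (improvement, threshold) with
    improvement = -inf where no admissible cut exists."""
    m, p = V.shape
    order = np.argsort(V, axis=0)
    vs = np.take_along_axis(V, order, axis=0)
    C = np.cumsum(Y[order], axis=0)              # (m, p, q)
    T = C[-1]
    k = np.arange(1, m)[:, None]
    ok = (vs[:-1] < vs[1:]) & (k >= min_node) & (m - k >= min_node)
    Ck = C[:-1]
    left = np.einsum("kpq,kpq->kp", Ck, Ck) / k
    rk = T[None] - Ck
    right = np.einsum("kpq,kpq->kp", rk, rk) / (m - k)
    imp = left + right - (np.einsum("pq,pq->p", T, T) / m)[None]
    imp[~ok] = -np.inf
    best_k = np.argmax(imp, axis=0)              # first max -> smallest threshold
    cols = np.arange(p)
    thr = 0.5 * (vs[best_k, cols] + vs[np.minimum(best_k + 1, m - 1), cols])
    return imp[best_k, cols], thr


def _best_split_impl(Y, cols, idx, control, root_ss, parent_ss=None):
    """Returns (rule, left_idx, right_idx) or (None, None, None)."""
    Ynode = Y[idx]
    if parent_ss is None:
        parent_ss = node_ss(Ynode)
    # a split cannot help a (numerically) pure node
    if parent_ss <= 1e-12 * max(root_ss, 1.0):
        return None, None, None
    floor = max(control.min_improvement * root_ss, 1e-10 * max(root_ss, parent_ss))
    m_all = len(idx)

    # complete numeric/ordered columns are scanned in one batched pass
    values = [col.codes[idx] for col in cols]
    batch_pos = [j for j, col in enumerate(cols)
                 if col.kind in ("numeric", "ordered")
                 and not np.isnan(values[j]).any()]
    batch: dict[int, tuple[float, float]] = {}
    if batch_pos and m_all >= 2 * control.min_node_size:
        V = np.column_stack([values[j] for j in batch_pos])
        imps, thrs = _batch_numeric_scan(V, Ynode, control.min_node_size)
        batch = {j: (float(imps[i]), float(thrs[i]))
                 for i, j in enumerate(batch_pos)}

    best_rule = None
    best_imp = -np.inf
    for j, col in enumerate(cols):
        if j in batch:
            imp, thr = batch[j]
            if np.isfinite(imp) and imp > best_imp + 1e-12:
                best_imp = imp
                best_rule = SplitRule(col.name, col.kind, threshold=thr,
                                      improvement=max(imp, 0.0), levels=col.levels)
            continue
        v = values[j]
        nan = np.isnan(v)
        if nan.any():
            obs = ~nan
            m = int(obs.sum())
            vv = v[obs]
            Ysub = Ynode[obs]
        else:
            m = len(v)
            vv = v
            Ysub = Ynode
        if m < 2 * control.min_node_size:
            continue
        if col.kind in ("numeric", "ordered"):
            cand = _split_candidates_numeric(vv, Ysub, control.min_node_size)
            if cand is None:
                continue
            imp, thr = cand
            if imp > best_imp + 1e-12:
                best_imp = imp
                best_rule = SplitRule(col.name, col.kind, threshold=thr,
                                      improvement=max(imp, 0.0), levels=col.levels)
        else:
            cand = _split_candidates_levels(vv, Ysub, col.levels, control.min_node_size)
            if cand is None:
                continue
            imp, left_levels = cand
            if imp > best_imp + 1e-12:
                best_imp = imp
                best_rule = SplitRule(col.name, col.kind, left_levels=left_levels,
                                      improvement=max(imp, 0.0), levels=col.levels)
    if best_rule is None or best_imp < floor:
        return None, None, None

    # partition, sending missing rows to the larger child (majority rule)
    col = next(c for c in cols if c.name == best_rule.variable)
    v = col.codes[idx]
    obs = ~np.isnan(v)
    if best_rule.kind in ("numeric", "ordered"):
        go_left = v <= best_rule.threshold
    else:
        left_codes = {i for i, l in enumerate(col.levels) if l in best_rule.left_levels}
        go_left = np.isin(v, list(left_codes))
    go_left &= obs
    n_left = int(go_left.sum())
    n_right = int((obs & ~go_left).sum())
    missing_side = "left" if n_left >= n_right else "right"
    rule = SplitRule(best_rule.variable, best_rule.kind, threshold=best_rule.threshold,
                     left_levels=best_rule.left_levels, improvement=best_rule.improvement,
                     missing_side=missing_side, levels=best_rule.levels)
    take_left = go_left | (~obs if missing_side == "left" else np.zeros_like(obs))
    return rule, idx[take_left], idx[~take_left]


# ---------------------------------------------------------------------------
# The fitted tree
# ---------------------------------------------------------------------------

class MultivariateTree:
    """A fitted multivariate regression tree with its pruning sequence."""

    def __init__(self, root: _Node, nodes: list[_Node], columns: list[_Column],
                 response_labels: Sequence[str], root_ss: float):
        self.root = root
        self.nodes = nodes
        self.columns = columns
        self.response_labels = list(response_labels)
        self.root_ss = root_ss
        self.prune_steps: list[_PruneStep] = _weakest_link_sequence(self)
        leaf_id = 0
        for node in self.nodes:
            if node.is_leaf:
                node.leaf_id = leaf_id
                leaf_id += 1

    # -- structure -------------------------------------------------------
    def leaves(self, collapsed: frozenset = frozenset()) -> list[_Node]:
        out = []

        def walk(node):
            if node.is_leaf or node.id in collapsed:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def internal_nodes(self) -> list[_Node]:
        return [n for n in self.nodes if not n.is_leaf]

    # -- error -----------------------------------------------------------
    def relative_error(self, collapsed: frozenset = frozenset()) -> float:
        if self.root_ss <= 0:
            warnings.warn("root SS is zero (constant responses); RE defined as 0")
            return 0.0
        return sum(l.ss for l in self.leaves(collapsed)) / self.root_ss

    @property
    def sizes(self) -> list[int]:
        """Leaf counts along the pruning sequence, largest first."""
        return [s.n_leaves for s in self.prune_steps]

    def collapsed_for_size(self, size: int) -> frozenset:
        """Collapsed-node set of the largest subtree with <= size leaves."""
        for step in self.prune_steps:
            if step.n_leaves <= size:
                return step.collapsed
        return self.prune_steps[-1].collapsed

    def collapsed_for_alpha(self, alpha: float) -> frozenset:
        """Cost-complexity-optimal subtree for penalty alpha."""
        chosen = self.prune_steps[0].collapsed
        for step in self.prune_steps:
            if step.alpha <= alpha + 1e-12:
                chosen = step.collapsed
        return chosen

    # -- prediction ------------------------------------------------------
    def _route(self, cols: list[_Column], collapsed: frozenset) -> np.ndarray:
        n = len(cols[0].codes) if cols else 0
        out = np.empty(n, dtype=int)
        colmap = {c.name: c for c in cols}
        stack = [(self.root, np.arange(n))]
        while stack:
            node, rows = stack.pop()
            if node.is_leaf or node.id in collapsed:
                out[rows] = node.id
                continue
            c = colmap[node.rule.variable]
            v = c.codes[rows]
            nan = np.isnan(v)
            if node.rule.kind in ("numeric", "ordered"):
                left = v <= node.rule.threshold
            else:
                left_codes = [i for i, l in enumerate(c.levels)
                              if l in node.rule.left_levels]
                left = np.isin(v, left_codes)
            left = np.where(nan, node.rule.missing_side == "left", left)
            stack.append((node.left, rows[left]))
            stack.append((node.right, rows[~left]))
        return out

    def predict(self, X, collapsed: frozenset = frozenset(),
                variable_kinds=None) -> np.ndarray:
        cols = self._align_columns(X, variable_kinds)
        node_ids = self._route(cols, collapsed)
        byid = {n.id: n for n in self.nodes}
        return np.vstack([byid[i].centroid for i in node_ids])

    def apply(self, X, collapsed: frozenset = frozenset(),
              variable_kinds=None) -> np.ndarray:
        """Terminal node id for every row of X."""
        cols = self._align_columns(X, variable_kinds)
        return self._route(cols, collapsed)

    def _align_columns(self, X, variable_kinds=None) -> list[_Column]:
        if isinstance(X, list):  # already-prepared columns (internal fast path)
            return X
        new = _prepare_columns(X, variable_kinds)
        bymeta = {c.name: c for c in self.columns}
        out = []
        for c in new:
            meta = bymeta.get(c.name)
            if meta is None or meta.kind == "numeric":
                out.append(c)
                continue
            # recode categorical levels against the training categories
            codes = np.full(len(c.codes), np.nan)
            if c.levels:
                lut = {l: i for i, l in enumerate(meta.levels)}
                for j, lvl in enumerate(c.levels):
                    codes[c.codes == j] = lut.get(lvl, np.nan)
            out.append(_Column(c.name, meta.kind, codes, meta.levels))
        return out

    # -- export ----------------------------------------------------------
    def to_text(self, collapsed: frozenset = frozenset()) -> str:
        lines = []

        def walk(node, indent, label):
            leaf = node.is_leaf or node.id in collapsed
            mark = "*" if leaf else ""
            re_part = node.ss / self.root_ss if self.root_ss > 0 else 0.0
            lines.append(f"{'  ' * indent}{label} n={node.n} ss={node.ss:.4f} "
                         f"re_contrib={re_part:.4f}{mark}")
            if not leaf:
                walk(node.left, indent + 1, node.rule.describe("left"))
                walk(node.right, indent + 1, node.rule.describe("right"))

        walk(self.root, 0, "root")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def encode(node):
            d = {"id": node.id, "n": node.n, "ss": node.ss,
                 "centroid": [float(x) for x in node.centroid]}
            if not node.is_leaf:
                r = node.rule
                d["rule"] = {
                    "variable": r.variable, "kind": r.kind,
                    "threshold": r.threshold,
                    "left_levels": sorted(map(str, r.left_levels)) if r.left_levels else None,
                    "improvement": r.improvement, "missing_side": r.missing_side,
                }
                d["left"] = encode(node.left)
                d["right"] = encode(node.right)
            return d

        return {
            "root_ss": self.root_ss,
            "relative_error": self.relative_error(),
            "response_labels": list(self.response_labels),
            "pruning_sequence": [
                {"alpha": s.alpha, "n_leaves": s.n_leaves,
                 "relative_error": s.relative_error(self.root_ss)}
                for s in self.prune_steps
            ],
            "tree": encode(self.root),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _weakest_link_sequence(tree: MultivariateTree) -> list[_PruneStep]:
    """CART cost-complexity pruning: repeatedly collapse the internal node
    with the smallest per-leaf SS gain until only the root remains."""
    root = tree.root
    collapsed: set[int] = set()

    def branch_stats(node):
        """(leaf SS sum, leaf count) of node's branch in the current subtree."""
        if node.is_leaf or node.id in collapsed:
            return node.ss, 1
        ls, lc = branch_stats(node.left)
        rs, rc = branch_stats(node.right)
        return ls + rs, lc + rc

    full_ss, full_leaves = branch_stats(root)
    steps = [_PruneStep(0.0, full_leaves, frozenset(), full_ss)]
    prev_alpha = 0.0
    while True:
        live = []

        def collect(node):
            if node.is_leaf or node.id in collapsed:
                return
            live.append(node)
            collect(node.left)
            collect(node.right)

        collect(root)
        if not live:
            break
        gs = []
        for node in live:
            bss, bleaves = branch_stats(node)
            gs.append((node.ss - bss) / (bleaves - 1))
        g_min = min(gs)
        tol = 1e-9 * max(tree.root_ss, 1.0)
        achievers = [n for n, g in zip(live, gs) if g <= g_min + tol]
        # collapse only outermost achievers; ancestors subsume descendants
        ach_ids = {n.id for n in achievers}

        def has_achiever_ancestor(node):
            for a in achievers:
                if a.id != node.id and _is_descendant(a, node):
                    return True
            return False

        before = len(collapsed)
        for n in achievers:
            if not has_achiever_ancestor(n):
                collapsed.add(n.id)
        if len(collapsed) == before:  # no progress: collapse everything left
            collapsed.update(n.id for n in live
                             if not has_achiever_ancestor(n))
        alpha = max(g_min, prev_alpha)
        prev_alpha = alpha
        lss, lcount = branch_stats(root)
        steps.append(_PruneStep(alpha, lcount, frozenset(collapsed), lss))
    return steps


def _is_descendant(ancestor: _Node, node: _Node) -> bool:
    if ancestor.is_leaf:
        return False
    stack = [ancestor.left, ancestor.right]
    while stack:
        cur = stack.pop()
        if cur.id == node.id:
            return True
        if not cur.is_leaf:
            stack.extend((cur.left, cur.right))
    return False


# ---------------------------------------------------------------------------
# Growing
# ---------------------------------------------------------------------------

def grow_tree(Y, X, control: GrowControl | None = None, *,
              variable_kinds=None, response_labels=None) -> MultivariateTree:
    """Grow a multivariate regression tree by recursive binary partitioning.

    Deterministic given inputs and control; returns a root-only tree when no
    admissible split exists.
    """
    control = control or GrowControl()
    if isinstance(Y, CommunityMatrix):
        response_labels = list(Y.taxon_labels)
        Y = Y.values.to_numpy()
    elif isinstance(Y, pd.DataFrame):
        response_labels = list(Y.columns)
        Y = Y.to_numpy(dtype=float)
    else:
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if response_labels is None:
            response_labels = [f"y{j}" for j in range(Y.shape[1])]
    cols = _prepare_columns(X, variable_kinds)
    return _grow_from_columns(Y, cols, control, response_labels)


def _grow_from_columns(Y: np.ndarray, cols: list[_Column],
                       control: GrowControl,
                       response_labels=None) -> MultivariateTree:
    """Core growth loop on pre-prepared predictor columns (fast path used
    by cross-validation and the best-subsets search)."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if response_labels is None:
        response_labels = [f"y{j}" for j in range(Y.shape[1])]
    n = Y.shape[0]
    if cols and len(cols[0].codes) != n:
        raise ValueError("responses and predictors have different numbers of rows")
    if np.isnan(Y).any():
        raise ValueError("responses contain missing values; only predictors may")

    root_ss = node_ss(Y) if n else 0.0
    nodes: list[_Node] = []
    counter = [0]

    def make_node(idx, depth):
        rows = Y[idx]
        mean = rows.mean(axis=0)
        centered = rows - mean
        ss = float(np.einsum("ij,ij->", centered, centered))
        node = _Node(counter[0], idx, mean, ss, depth)
        counter[0] += 1
        nodes.append(node)
        return node

    def split_recursive(node):
        if node.n < control.min_split_size:
            return
        if control.max_depth is not None and node.depth >= control.max_depth:
            return
        rule, li, ri = _best_split_impl(Y, cols, node.idx, control, root_ss,
                                        parent_ss=node.ss)
        if rule is None:
            return
        node.rule = rule
        node.left = make_node(li, node.depth + 1)
        node.right = make_node(ri, node.depth + 1)
        split_recursive(node.left)
        split_recursive(node.right)

    if n == 0:
        raise ValueError("cannot grow a tree on zero rows")
    root = make_node(np.arange(n), 0)
    split_recursive(root)
    return MultivariateTree(root, nodes, cols, response_labels, root_ss)


def relative_error(tree: MultivariateTree) -> float:
    """RE = sum of leaf SS / root SS; 1 for an unsplit tree, 1 - R^2."""
    return tree.relative_error()


# ---------------------------------------------------------------------------
# scikit-learn estimator facade
# ---------------------------------------------------------------------------

class MultivariateRegressionTree(BaseEstimator, RegressorMixin):
    """Sum-of-squares multivariate regression tree, scikit-learn style.

    Parameters
    ----------
    min_node_size : int, default 5
        Smallest admissible child node.
    min_split_size : int, default 10
        Smallest node that may be split (>= 2 * min_node_size).
    min_improvement : float, default 0.001
        Minimum SS decrease for a split, as a fraction of the root SS.
    max_depth : int or None
        Depth cap; None means unlimited.
    size : int or None
        If set, predictions use the pruned subtree with at most this many
        leaves (from the weakest-link sequence); None uses the full tree.
    variable_kinds : mapping or None
        Optional name -> {"numeric","ordered","unordered"} overrides when X
        is a plain DataFrame; PredictorTable inputs carry their own kinds.

    Attributes
    ----------
    tree_ : MultivariateTree
    relative_error_ : float
        RE of the (possibly size-pruned) tree.
    r_squared_ : float
    root_ss_ : float
    n_leaves_ : int
    """

    def __init__(self, min_node_size=5, min_split_size=10, min_improvement=0.001,
                 max_depth=None, size=None, variable_kinds=None):
        self.min_node_size = min_node_size
        self.min_split_size = min_split_size
        self.min_improvement = min_improvement
        self.max_depth = max_depth
        self.size = size
        self.variable_kinds = variable_kinds

    def _control(self) -> GrowControl:
        return GrowControl(self.min_node_size, self.min_split_size,
                           self.min_improvement, self.max_depth)

    def fit(self, X, y):
        self.tree_ = grow_tree(y, X, self._control(),
                               variable_kinds=self.variable_kinds)
        self.collapsed_ = (self.tree_.collapsed_for_size(self.size)
                           if self.size is not None else frozenset())
        self.root_ss_ = self.tree_.root_ss
        self.relative_error_ = self.tree_.relative_error(self.collapsed_)
        self.r_squared_ = 1.0 - self.relative_error_
        self.n_leaves_ = len(self.tree_.leaves(self.collapsed_))
        self.pruning_sequence_ = self.tree_.prune_steps
        return self

    def predict(self, X):
        return self.tree_.predict(X, self.collapsed_,
                                  variable_kinds=self.variable_kinds)

    def apply(self, X):
        return self.tree_.apply(X, self.collapsed_,
                                variable_kinds=self.variable_kinds)
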