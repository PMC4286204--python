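"""Site-blocked cross-validation and best-subsets predictor selection.

Quadrats are nested within sites (remnant patches), so plain k-fold CV would
leak information between quadrats of the same site.  Folds here partition
*sites*; every quadrat inherits its site's fold, and no site ever spans the
train/test boundary.

The cross-validated relative error (CVRE) of a tree of a given size is the
summed squared Euclidean prediction error over held-out quadrats (each
predicted as the centroid of the leaf it lands in, from a tree grown on the
training sites and pruned to that size) divided by the total SS of the full
data about its grand mean.  CVRE = 0 is perfect prediction; CVRE >= 1 means
no predictive power; values below 0.60 are labelled strong in this package's
vocabulary.

Greedy tree growing can be "locked" by a rich candidate set into a split
sequence with poor out-of-sample performance.  Best-subsets selection
addresses this by enumerating every nonempty predictor subset, fitting and
cross-validating each on the *same* fold assignments (a paired comparison),
and selecting the subset with minimum CVRE.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .community import CommunityMatrix, PredictorTable
from .tree import (GrowControl, MultivariateTree, _Column, _grow_from_columns,
                   _prepare_columns, node_ss)

__all__ = [
    "FoldAssignment",
    "CVConfig",
    "CVResult",
    "BestSubsetsResult",
    "make_site_folds",
    "cross_validate",
    "cvre",
    "select_tree_size",
    "classify_predictive_power",
    "best_subsets_search",
    "BestSubsetsMRT",
]

SUBSET_GUARD = 15  # full enumeration refused above this without p_max


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of sites into k folds; quadrats inherit their site's fold."""

    k: int
    site_to_fold: dict
    seed: int

    def quadrat_folds(self, site_ids: Sequence) -> np.ndarray:
        return np.array([self.site_to_fold[s] for s in site_ids], dtype=int)


def make_site_folds(site_ids: Sequence, k: int, seed: int) -> FoldAssignment:
    """Shuffle sites by seed and deal them into k folds of near-equal size
    (site counts differ by at most 1)."""
    sites = list(dict.fromkeys(site_ids))  # unique, order of appearance
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(sites):
        raise ValueError(
            f"k={k} exceeds the {len(sites)} sites; use k={len(sites)} "
            "(leave-one-site-out) instead"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sites))
    mapping = {sites[j]: int(i % k) for i, j in enumerate(order)}
    return FoldAssignment(k=k, site_to_fold=mapping, seed=seed)


@dataclass
class CVConfig:
    """Cross-validation settings.

    k defaults to 10, or to the number of sites when there are fewer than 10
    (leave-one-site-out).  ``reps`` fold assignments are drawn with distinct
    seeds derived from ``seed`` and the mean CVRE over repetitions is
    reported.  ``folds`` may carry precomputed assignments to share across
    models (paired comparisons); it overrides k/reps/seed.
    """

    k: int | None = None
    reps: int = 50
    seed: int = 0
    selection_rule: str = "min_cvre"  # or "one_se"
    folds: list[FoldAssignment] | None = None

    def assignments(self, site_ids: Sequence) -> list[FoldAssignment]:
        if self.folds is not None:
            return self.folds
        n_sites = len(set(site_ids))
        k = self.k if self.k is not None else min(10, n_sites)
        return [make_site_folds(site_ids, k, self.seed + 1000 * r)
                for r in range(self.reps)]


@dataclass
class CVResult:
    """CVRE curve over tree sizes with repetition means and standard errors."""

    sizes: list[int]
    cvre_mean: dict[int, float]
    cvre_se: dict[int, float]
    chosen_size: int
    selection_rule: str
    fold_seeds: list[int]

    def curve(self) -> pd.DataFrame:
        return pd.DataFrame({
            "size": self.sizes,
            "cvre": [self.cvre_mean[s] for s in self.sizes],
            "se": [self.cvre_se[s] for s in self.sizes],
        })


def _check_fold_integrity(site_ids, folds: FoldAssignment) -> None:
    """No site may appear on both sides of a train/test division."""
    qf = folds.quadrat_folds(site_ids)
    for f in range(folds.k):
        test_sites = {s for s, x in zip(site_ids, qf) if x == f}
        train_sites = {s for s, x in zip(site_ids, qf) if x != f}
        if test_sites & train_sites:
            raise AssertionError(f"site spans train/test in fold {f}: "
                                 f"{sorted(test_sites & train_sites)}")


def _cv_errors(Y, cols, site_ids, control, assignment, sizes):
    """Per-quadrat squared prediction errors for each tree size, one fold
    assignment.  Returns dict size -> (n,) error vector."""
    n = Y.shape[0]
    _check_fold_integrity(site_ids, assignment)
    qf = assignment.quadrat_folds(site_ids)
    errors = {m: np.full(n, np.nan) for m in sizes}
    for f in range(assignment.k):
        test = qf == f
        train = ~test
        if not test.any():
            continue
        if int(train.sum()) < control.min_split_size:
            raise RuntimeError(
                f"training fold {f} has {int(train.sum())} rows, fewer than "
                f"min_split_size={control.min_split_size}")
        sub_cols = [_Column(c.name, c.kind, c.codes[train], c.levels) for c in cols]
        fold_tree = _grow_from_columns(Y[train], sub_cols, control)
        test_cols = [_Column(c.name, c.kind, c.codes[test], c.levels) for c in cols]
        for m in sizes:
            collapsed = fold_tree.collapsed_for_size(m)
            pred = fold_tree.predict(test_cols, collapsed)
            diff = Y[test] - pred
            errors[m][test] = np.einsum("ij,ij->i", diff, diff)
    return errors


def _as_response(Y):
    if isinstance(Y, CommunityMatrix):
        return Y.values.to_numpy(dtype=float), list(Y.site_ids)
    if isinstance(Y, pd.DataFrame):
        return Y.to_numpy(dtype=float), None
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    return Y, None


def cross_validate(responses, predictors, control=None, cv=None,
                   site_ids=None, full_tree=None) -> CVResult:
    """Site-blocked CV of the pruning sequence of the full-data tree."""
    control = control or GrowControl()
    cv = cv or CVConfig()
    if isinstance(predictors, PredictorTable) and isinstance(responses, CommunityMatrix):
        predictors = predictors.loc(responses.quadrat_ids)
    Y, inferred_sites = _as_response(responses)
    site_ids = list(site_ids) if site_ids is not None else inferred_sites
    if site_ids is None:
        raise ValueError("site_ids are required when responses carry none")
    cols = (predictors if isinstance(predictors, list)
            else _prepare_columns(predictors))
    if full_tree is None:
        full_tree = _grow_from_columns(Y, cols, control)
    sizes = sorted(set(full_tree.sizes))
    assignments = cv.assignments(site_ids)
    denom = node_ss(Y)
    rep_curves = []
    per_obs = None
    for a in assignments:
        errs = _cv_errors(Y, cols, site_ids, control, a, sizes)
        rep_curves.append({m: float(np.nansum(errs[m])) / denom for m in sizes})
        per_obs = errs
    mean = {m: float(np.mean([c[m] for c in rep_curves])) for m in sizes}
    if len(rep_curves) > 1:
        se = {m: float(np.std([c[m] for c in rep_curves], ddof=1)
                       / np.sqrt(len(rep_curves))) for m in sizes}
    else:
        n = Y.shape[0]
        se = {m: float(np.sqrt(n * np.var(per_obs[m])) / denom) for m in sizes}
    chosen = _select(sizes, mean, se, cv.selection_rule)
    return CVResult(sizes=sizes, cvre_mean=mean, cvre_se=se, chosen_size=chosen,
                    selection_rule=cv.selection_rule,
                    fold_seeds=[a.seed for a in assignments])


def cvre(responses, predictors, control=None, folds=None, size=None,
         site_ids=None) -> float:
    """Mean CVRE of the tree pruned to ``size`` leaves (full tree if None)."""
    cv = CVConfig(folds=[folds] if isinstance(folds, FoldAssignment) else folds)
    res = cross_validate(responses, predictors, control, cv, site_ids=site_ids)
    if size is None:
        size = max(res.sizes)
    if size not in res.cvre_mean:
        size = max(s for s in res.sizes if s <= size)
    return res.cvre_mean[size]


def _select(sizes, mean, se, rule):
    if rule == "min_cvre":
        best = min(mean.values())
        return min(s for s in sizes if mean[s] == best)
    if rule == "one_se":
        best_size = min(sizes, key=lambda s: (mean[s], s))
        limit = mean[best_size] + se[best_size]
        return min(s for s in sizes if mean[s] <= limit)
    raise ValueError(f"unknown selection rule {rule!r}")


def select_tree_size(cv_result: CVResult, rule: str = "min_cvre") -> int:
    """Pick a tree size from the CVRE curve (min_cvre or one_se)."""
    return _select(cv_result.sizes, cv_result.cvre_mean, cv_result.cvre_se, rule)


def classify_predictive_power(cvre_value: float) -> str:
    """Label predictive power: strong (< 0.60), weak (< 1), none (>= 1)."""
    if cvre_value < 0:
        raise ValueError("CVRE cannot be negative")
    if cvre_value < 0.60:
        return "strong"
    if cvre_value < 1.0:
        return "weak"
    return "none"


# ---------------------------------------------------------------------------
# Best subsets
# ---------------------------------------------------------------------------

@dataclass
class BestSubsetsResult:
    """Leaderboard of predictor subsets, each fitted and cross-validated on
    shared fold assignments; the best entry minimises CVRE (ties: smaller
    subset, then lexicographic order)."""

    leaderboard: pd.DataFrame
    best_subset: tuple[str, ...]
    best_size: int
    best_re: float
    best_cvre: float
    best_tree: MultivariateTree
    folds: list[FoldAssignment]

    @property
    def best_label(self) -> str:
        return classify_predictive_power(self.best_cvre)


def _enumerate_subsets(names: Sequence[str], p_max: int | None):
    p = len(names)
    if p_max is None and p > SUBSET_GUARD:
        raise ValueError(
            f"{p} predictors would enumerate 2^{p}-1 subsets; pass p_max to "
            "bound subset size")
    top = min(p, p_max) if p_max else p
    for r in range(1, top + 1):
        yield from itertools.combinations(range(p), r)


def best_subsets_search(responses, predictors, control=None, cv=None,
                        site_ids=None, p_max=None) -> BestSubsetsResult:
    """Enumerate predictor subsets, cross-validate each on shared folds, and
    return the leaderboard with the minimum-CVRE model."""
    control = control or GrowControl()
    cv = cv or CVConfig()
    if isinstance(predictors, PredictorTable) and isinstance(responses, CommunityMatrix):
        predictors = predictors.loc(responses.quadrat_ids)
    Y, inferred_sites = _as_response(responses)
    site_ids = list(site_ids) if site_ids is not None else inferred_sites
    if site_ids is None:
        raise ValueError("site_ids are required when responses carry none")
    cols = _prepare_columns(predictors) if not isinstance(predictors, list) else predictors
    names = [c.name for c in cols]
    assignments = cv.assignments(site_ids)
    shared_cv = CVConfig(folds=assignments, selection_rule=cv.selection_rule)

    rows = []
    trees = {}
    for subset_idx in _enumerate_subsets(names, p_max):
        subset = tuple(names[i] for i in subset_idx)
        sub_cols = [cols[i] for i in subset_idx]
        full_tree = _grow_from_columns(Y, sub_cols, control)
        res = cross_validate(Y, sub_cols, control, shared_cv,
                             site_ids=site_ids, full_tree=full_tree)
        size = res.chosen_size
        collapsed = full_tree.collapsed_for_size(size)
        re = full_tree.relative_error(collapsed)
        rows.append({
            "subset": subset, "n_predictors": len(subset), "size": size,
            "re": re, "cvre": res.cvre_mean[size],
            "label": classify_predictive_power(res.cvre_mean[size]),
        })
        trees[subset] = (full_tree, size)

    board = pd.DataFrame(rows)
    board = board.sort_values(
        by=["cvre", "n_predictors", "subset"], kind="stable"
    ).reset_index(drop=True)
    best = board.iloc[0]
    tree, size = trees[best["subset"]]
    return BestSubsetsResult(
        leaderboard=board,
        best_subset=best["subset"],
        best_size=int(best["size"]),
        best_re=float(best["re"]),
        best_cvre=float(best["cvre"]),
        best_tree=tree,
        folds=assignments,
    )


class BestSubsetsMRT(BaseEstimator):
    """Best-subsets multivariate regression tree, scikit-learn style.

    fit(X, y, groups=sites) enumerates predictor subsets of X, grows and
    prunes a tree for each, scores each by site-blocked CVRE on shared
    folds, and keeps the minimum-CVRE model.

    Attributes
    ----------
    result_ : BestSubsetsResult
    best_subset_, best_size_, best_cvre_, best_re_ : selected model summary
    leaderboard_ : DataFrame over all enumerated subsets
    """

    def __init__(self, min_node_size=5, min_split_size=10, min_improvement=0.001,
                 max_depth=None, k=None, reps=50, seed=0,
                 selection_rule="min_cvre", p_max=None):
        self.min_node_size = min_node_size
        self.min_split_size = min_split_size
        self.min_improvement = min_improvement
        self.max_depth = max_depth
        self.k = k
        self.reps = reps
        self.seed = seed
        self.selection_rule = selection_rule
        self.p_max = p_max

    def fit(self, X, y, groups=None):
        control = GrowControl(self.min_node_size, self.min_split_size,
                              self.min_improvement, self.max_depth)
        cv = CVConfig(k=self.k, reps=self.reps, seed=self.seed,
                      selection_rule=self.selection_rule)
        self.result_ = best_subsets_search(y, X, control, cv,
                                           site_ids=groups, p_max=self.p_max)
        self.best_subset_ = self.result_.best_subset
        self.best_size_ = self.result_.best_size
        self.best_cvre_ = self.result_.best_cvre
        self.best_re_ = self.result_.best_re
        self.leaderboard_ = self.result_.leaderboard
        self.tree_ = self.result_.best_tree
        self.collapsed_ = self.tree_.collapsed_for_size(self.best_size_)
        return self

    def predict(self, X):
        return self.tree_.predict(X, self.collapsed_)

    def apply(self, X):
        return self.tree_.apply(X, self.collapsed_)
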