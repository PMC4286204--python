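"""Dufrêne–Legendre indicator value (IndVal) analysis on tree groupings.

For taxon i and group j the indicator value is the product of two
components: fidelity A_ij = (mean abundance of i in j) / (sum over groups of
mean abundances of i), and frequency B_ij = proportion of quadrats in j
where i is present.  IndVal_ij = A_ij * B_ij lies in [0, 1], reaching 1 only
when the taxon occurs in every quadrat of group j and nowhere else.

Significance of each taxon's maximum IndVal is assessed by permuting quadrat
group labels; the reported probability uses the add-one estimator
(r + 1) / (n_perm + 1), so it can never be zero.

:func:`tree_group_indicators` evaluates indicators both for the leaves of a
fitted multivariate regression tree and for the two breakpoint-defined sides
of each split, mirroring how indicator tables are reported against tree
structure (e.g. "grazing = high" vs "grazing = low,medium").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .community import CommunityMatrix
from .tree import MultivariateTree, _Column

__all__ = [
    "IndicatorRecord",
    "indval",
    "indval_permutation_test",
    "tree_group_indicators",
]


@dataclass(frozen=True)
class IndicatorRecord:
    """One significant indicator: a taxon tied to a breakpoint-defined group."""

    grouping: str          # "leaves" or the split variable's description
    group: str             # e.g. "grazing = high" or "leaf 2"
    taxon: str
    indicator_value: float
    probability: float


def _as_groups(group_assignment, index) -> np.ndarray:
    g = pd.Series(group_assignment, index=index) if not isinstance(
        group_assignment, pd.Series) else group_assignment
    return g.to_numpy()


def _indval_core(X: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """IndVal matrix (taxon x group) from abundance array and group codes."""
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    sums = np.zeros((n_groups, X.shape[1]))
    np.add.at(sums, codes, X)
    pres = np.zeros((n_groups, X.shape[1]))
    np.add.at(pres, codes, (X > 0).astype(float))
    means = sums / counts[:, None]
    freqs = pres / counts[:, None]
    totals = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(totals > 0, means / totals, 0.0)
    return (A * freqs).T


def indval(cm: CommunityMatrix, group_assignment) -> pd.DataFrame:
    """Indicator value of every taxon in every group (taxon x group).

    A_ij is the taxon's mean abundance in group j relative to the sum of its
    group means (fidelity); B_ij is its occurrence frequency within group j.
    Taxa absent everywhere get an all-zero row (documented convention).
    """
    groups = _as_groups(group_assignment, cm.quadrat_ids)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("indicator analysis needs at least 2 groups")
    lut = {g: i for i, g in enumerate(labels)}
    codes = np.array([lut[g] for g in groups])
    out = _indval_core(cm.values.to_numpy(dtype=float), codes, len(labels))
    return pd.DataFrame(out, index=cm.taxon_labels, columns=labels)


def indval_permutation_test(cm: CommunityMatrix, group_assignment,
                            n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """Permutation probabilities for each taxon's maximum IndVal.

    Returns a frame indexed by taxon with columns ``group`` (argmax group),
    ``indval`` (observed maximum) and ``probability`` =
    (#permutations with max IndVal >= observed + 1) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    groups = _as_groups(group_assignment, cm.quadrat_ids)
    if len(pd.unique(groups)) < 2:
        raise ValueError("permutation test needs at least 2 groups")
    obs = indval(cm, groups)
    obs_max = obs.max(axis=1)
    obs_arg = obs.idxmax(axis=1)
    labels = list(obs.columns)
    lut = {g: i for i, g in enumerate(labels)}
    codes = np.array([lut[g] for g in groups])
    X = cm.values.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    count = np.zeros(cm.n_taxa)
    obs_vec = obs_max.to_numpy()
    for _ in range(n_perm):
        pm = _indval_core(X, rng.permutation(codes), len(labels)).max(axis=1)
        count += (pm >= obs_vec - 1e-12)
    prob = (count + 1) / (n_perm + 1)
    return pd.DataFrame({
        "group": obs_arg, "indval": obs_max, "probability": prob,
    }, index=cm.taxon_labels)


def tree_group_indicators(tree: MultivariateTree, cm: CommunityMatrix,
                          predictors, alpha: float = 0.05,
                          n_perm: int = 999, seed: int = 0,
                          collapsed: frozenset = frozenset()) -> list[IndicatorRecord]:
    """Indicator records for a fitted tree's leaves and each split's sides.

    For every internal split, the quadrats reaching that node are divided
    into its two breakpoint-labelled sides; for the whole tree, quadrats are
    grouped by leaf.  Records with probability <= alpha are returned, sorted
    by descending IndVal within each group.
    """
    records: list[IndicatorRecord] = []
    cols = tree._align_columns(predictors)

    def add_records(sub_cm, labels, grouping):
        if len(pd.unique(np.asarray(labels))) < 2:
            return
        res = indval_permutation_test(sub_cm, pd.Series(labels, index=sub_cm.quadrat_ids),
                                      n_perm=n_perm, seed=seed)
        sig = res[res["probability"] <= alpha].sort_values(
            ["group", "indval"], ascending=[True, False], kind="stable")
        for taxon, row in sig.iterrows():
            records.append(IndicatorRecord(
                grouping=grouping, group=str(row["group"]), taxon=str(taxon),
                indicator_value=float(row["indval"]),
                probability=float(row["probability"]),
            ))

    internal = [n for n in tree.nodes if not n.is_leaf and n.id not in collapsed
                and not _under_collapsed(tree, n, collapsed)]
    for node in internal:
        rule = node.rule
        idx = node.idx
        sub_vals = cm.values.iloc[idx]
        sub_cm = cm.with_values(sub_vals)
        left_ids = set(node.left.idx)
        labels = [rule.describe("left") if i in left_ids else rule.describe("right")
                  for i in idx]
        add_records(sub_cm, labels, grouping=rule.variable)

    if internal:
        node_ids = tree._route(cols, collapsed)
        leaf_names = {}
        for n in tree.leaves(collapsed):
            leaf_names[n.id] = f"leaf {n.leaf_id if n.leaf_id is not None else n.id}"
        labels = [leaf_names[i] for i in node_ids]
        add_records(cm, labels, grouping="leaves")
    return records


def _under_collapsed(tree: MultivariateTree, node, collapsed: frozenset) -> bool:
    if not collapsed:
        return False
    from .tree import _is_descendant
    byid = {n.id: n for n in tree.nodes}
    return any(_is_descendant(byid[c], node) for c in collapsed)


def records_to_frame(records: Sequence[IndicatorRecord]) -> pd.DataFrame:
    """Tabulate indicator records (breakpoint, group, IndVal, probability)."""
    return pd.DataFrame([{
        "breakpoint": r.grouping, "indicator_group": r.group, "taxon": r.taxon,
        "indicator_value": r.indicator_value, "probability": r.probability,
    } for r in records])
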