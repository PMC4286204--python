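"""Synthetic dryland survey data with known ground truth.

The generator emulates the statistical structure the tree analysis assumes:
quadrats nested in sites (remnant patches), patch-scale predictors constant
within a site, piecewise-constant community responses to threshold rules on
a few predictors, species nested within morphogroups with tunable
within-group response coherence, zero-inflated right-skewed (lognormal)
cover noise, and a tail of rare species.

Coherence c in [0, 1] blends each species' regional mean between its
morphogroup's regional profile (c = 1: member species share the group
response exactly, up to a per-species abundance share) and an independent
species-specific regional profile (c = 0: species responses carry no group
signal).  The morphogroup-vs-species comparison and the null models hinge on
this dial.

Two presets mirror the shapes of semi-arid woodland grazing/fragmentation
surveys: "fencing-like" (21 sites x 3 quadrats, 54 species in 10
morphogroups, predictors such as grazing intensity and time since livestock
exclusion) and "fragmentation-like" (25 sites, 71 quadrats, 60 species in 6
morphogroups, predictors such as remnant patch size and location in
remnant).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .community import (CommunityMatrix, MorphogroupMap, PredictorTable,
                        VariableSpec)

__all__ = [
    "PredictorDef",
    "LandscapeConfig",
    "TruthRule",
    "SyntheticTruth",
    "generate_landscape",
    "assign_regions",
    "generate_community",
    "truth_report",
    "fencing_like",
    "fragmentation_like",
    "simulate_dataset",
]


@dataclass(frozen=True)
class PredictorDef:
    """One synthetic explanatory variable: kind, survey scale and range."""

    name: str
    kind: str                       # numeric | ordered | unordered
    scale: str = "quadrat"          # patch (constant within site) | quadrat
    low: float | None = None
    high: float | None = None
    levels: tuple[str, ...] | None = None
    degradation: bool = False

    def spec(self) -> VariableSpec:
        return VariableSpec(self.name, self.kind, self.levels, self.degradation)


@dataclass
class LandscapeConfig:
    """Sampling design: sites, quadrats per site, predictor definitions."""

    predictors: list[PredictorDef]
    n_sites: int = 21
    quadrats_per_site: int | Sequence[int] = 3

    def site_sizes(self) -> list[int]:
        if isinstance(self.quadrats_per_site, int):
            return [self.quadrats_per_site] * self.n_sites
        sizes = list(self.quadrats_per_site)
        if len(sizes) != self.n_sites:
            raise ValueError("quadrats_per_site list must match n_sites")
        return sizes


@dataclass(frozen=True)
class TruthRule:
    """A generating split: left side is value <= threshold (numeric), level
    index <= that of ``threshold`` (ordered, given as a level name), or
    value in left_levels (unordered)."""

    variable: str
    threshold: float | str | None = None
    left_levels: frozenset | None = None


@dataclass
class SyntheticTruth:
    """Ground truth for a generated community."""

    rules: list[TruthRule]
    species_per_group: list[int]
    group_names: list[str] | None = None
    coherence: float = 0.9
    overdispersion: float = 0.6    # lognormal sigma of cover noise
    zero_inflation: float = 0.3    # P(observed cover forced to 0)
    rare_species: int = 0
    base_cover: float = 0.1        # mean cover of one morphogroup in a region
    profile_shape: float = 0.8     # gamma shape of regional profiles

    def __post_init__(self):
        if not 0 <= self.coherence <= 1:
            raise ValueError("coherence must lie in [0, 1]")
        if self.group_names is None:
            self.group_names = [f"group_{i + 1:02d}"
                                for i in range(len(self.species_per_group))]


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

def generate_landscape(config: LandscapeConfig, seed: int = 0) -> PredictorTable:
    """Draw a predictor table: one draw per site for patch-scale variables
    (broadcast to its quadrats), one per quadrat otherwise; numeric values
    uniform within [low, high], categorical uniform over levels."""
    rng = np.random.default_rng(seed)
    sizes = config.site_sizes()
    site_ids = np.repeat([f"site_{i + 1:02d}" for i in range(config.n_sites)], sizes)
    n = len(site_ids)
    quadrat_ids = [f"q{i + 1:03d}" for i in range(n)]

    def draw(p: PredictorDef, count: int):
        if p.kind == "numeric":
            return rng.uniform(p.low, p.high, size=count)
        return rng.choice(list(p.levels), size=count)

    data = {}
    for p in config.predictors:
        if p.scale == "patch":
            per_site = draw(p, config.n_sites)
            data[p.name] = np.repeat(per_site, sizes)
        else:
            data[p.name] = draw(p, n)
    df = pd.DataFrame(data, index=pd.Index(quadrat_ids, name="quadrat_id"))
    table = PredictorTable(df, {p.name: p.spec() for p in config.predictors})
    table.data.attrs["site_ids"] = list(site_ids)
    return table


def _rule_left(rule: TruthRule, table: PredictorTable) -> np.ndarray:
    col = table.data[rule.variable]
    spec = table.variables[rule.variable]
    if spec.kind == "numeric":
        return col.to_numpy(dtype=float) <= rule.threshold
    if spec.kind == "ordered":
        cut = spec.levels.index(rule.threshold)
        return col.cat.codes.to_numpy() <= cut
    return col.astype(object).isin(set(rule.left_levels)).to_numpy()


def assign_regions(table: PredictorTable, rules: Sequence[TruthRule]) -> np.ndarray:
    """Region id per quadrat: the crossed outcome of all rules (each rule
    contributes one bit), so the rules partition predictor space."""
    for r in rules:
        if r.variable not in table.variables:
            raise ValueError(f"truth rule references unknown predictor {r.variable!r}")
    region = np.zeros(len(table.data), dtype=int)
    for b, rule in enumerate(rules):
        region |= _rule_left(rule, table).astype(int) << b
    return region


# ---------------------------------------------------------------------------
# Community
# ---------------------------------------------------------------------------

def generate_community(predictors: PredictorTable, truth: SyntheticTruth,
                       seed: int = 0, site_ids: Sequence | None = None
                       ) -> tuple[CommunityMatrix, MorphogroupMap, np.ndarray]:
    """Generate a species x quadrat cover matrix from the truth.

    Returns the species matrix, the true morphogroup map and the region
    label of each quadrat.
    """
    rng = np.random.default_rng(seed)
    region = assign_regions(predictors, truth.rules)
    region_ids = np.unique(region)
    r_index = {r: i for i, r in enumerate(region_ids)}
    R = len(region_ids)
    G = len(truth.species_per_group)
    shape = truth.profile_shape

    # regional profile of each morphogroup: expected aggregate cover
    mu = truth.base_cover * rng.gamma(shape, 1.0 / shape, size=(R, G))
    # independent species-specific regional profiles (the incoherent part)
    S = sum(truth.species_per_group)
    nu = truth.base_cover * rng.gamma(shape, 1.0 / shape, size=(R, S))

    names, group_of, shares = [], [], []
    for g, (count, gname) in enumerate(zip(truth.species_per_group,
                                           truth.group_names)):
        w = rng.dirichlet(np.full(count, 2.0))
        for j in range(count):
            names.append(f"{gname}_sp{j + 1}")
            group_of.append(g)
            shares.append(w[j])
    shares = np.asarray(shares)
    group_of = np.asarray(group_of)

    n = len(predictors.data)
    rq = np.array([r_index[r] for r in region])
    mean = shares[None, :] * (
        truth.coherence * mu[rq][:, group_of]
        + (1.0 - truth.coherence) * nu[rq]
    )

    sigma = truth.overdispersion
    if sigma > 0:
        cover = rng.lognormal(np.log(np.maximum(mean, 1e-12)) - sigma ** 2 / 2.0,
                              sigma)
    else:
        cover = mean.copy()
    if truth.zero_inflation > 0:
        cover *= rng.random(cover.shape) >= truth.zero_inflation

    assignments = {name: truth.group_names[g] for name, g in zip(names, group_of)}
    # rare species: present in at most a few quadrats at trace cover
    for j in range(truth.rare_species):
        name = f"rare_sp{j + 1}"
        occ = int(rng.integers(1, 4))
        rows = rng.choice(n, size=occ, replace=False)
        col = np.zeros(n)
        col[rows] = 0.01 * rng.lognormal(0.0, 0.5, size=occ)
        cover = np.column_stack([cover, col])
        names.append(name)
        assignments[name] = truth.group_names[int(rng.integers(0, G))]

    if site_ids is None:
        site_ids = predictors.data.attrs.get("site_ids")
    if site_ids is None:
        raise ValueError("site_ids are required (generate_landscape stores them)")
    values = pd.DataFrame(cover, index=predictors.data.index, columns=names)
    cm = CommunityMatrix(values, pd.Series(list(site_ids),
                                           index=predictors.data.index))
    return cm, MorphogroupMap(assignments), region


# ---------------------------------------------------------------------------
# Recovery report
# ---------------------------------------------------------------------------

def truth_report(truth: SyntheticTruth, tree, predictors: PredictorTable,
                 region_labels: np.ndarray,
                 collapsed: frozenset = frozenset()) -> dict:
    """Compare a fitted tree against the generating truth.

    Reports which true split variables appear in the fitted tree, the
    threshold error for recovered numeric rules, spurious variables, and the
    Adjusted Rand Index between true regions and fitted leaves.
    """
    from .selection import BestSubsetsResult
    if isinstance(tree, BestSubsetsResult):
        collapsed = tree.best_tree.collapsed_for_size(tree.best_size)
        tree = tree.best_tree

    fitted_rules = [n.rule for n in tree.nodes
                    if not n.is_leaf and n.id not in collapsed
                    and not _under(tree, n, collapsed)]
    fitted_vars = {r.variable for r in fitted_rules}
    true_vars = [r.variable for r in truth.rules]

    threshold_errors = {}
    for tr in truth.rules:
        if tr.variable in fitted_vars and isinstance(tr.threshold, (int, float)):
            cands = [r.threshold for r in fitted_rules
                     if r.variable == tr.variable and r.threshold is not None]
            threshold_errors[tr.variable] = float(
                min(abs(c - tr.threshold) for c in cands))

    leaf_ids = tree.apply(predictors, collapsed)
    ari = float(adjusted_rand_score(np.asarray(region_labels), leaf_ids))
    return {
        "true_variables": true_vars,
        "found": {v: v in fitted_vars for v in true_vars},
        "all_found": all(v in fitted_vars for v in true_vars),
        "spurious_variables": sorted(fitted_vars - set(true_vars)),
        "threshold_errors": threshold_errors,
        "ari": ari,
        "n_leaves": len(tree.leaves(collapsed)),
    }


def _under(tree, node, collapsed):
    if not collapsed:
        return False
    from .tree import _is_descendant
    byid = {n.id: n for n in tree.nodes}
    return any(_is_descendant(byid[c], node) for c in collapsed)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

_FENCING_PREDICTORS = [
    PredictorDef("grazing", "ordered", "quadrat",
                 levels=("low", "medium", "high"), degradation=True),
    PredictorDef("time_since_fencing", "numeric", "patch", 1.0, 50.0,
                 degradation=True),
    PredictorDef("organic_c", "numeric", "quadrat", 1.3, 3.4),
    PredictorDef("ph", "numeric", "quadrat", 6.1, 8.5),
    PredictorDef("total_n", "numeric", "quadrat", 0.11, 0.30),
    PredictorDef("available_p", "numeric", "quadrat", 5.0, 43.0),
    PredictorDef("exotic_annual", "numeric", "quadrat", 0.0, 1.0,
                 degradation=True),
    PredictorDef("vegetation_community", "unordered", "patch",
                 levels=("blackbox", "buloke", "mallee")),
    PredictorDef("thk_ratio", "numeric", "patch", 3.8, 5.0),
    PredictorDef("native_grass", "numeric", "quadrat", 0.0, 0.35),
]

_FENCING_GROUPS = ["tall_moss", "short_moss", "foliose_lichen",
                   "squamulose_lichen", "gelatinous_lichen", "crustose_lichen",
                   "fruticose_lichen", "thallose_liverwort", "leafy_liverwort",
                   "black_crust"]

_FRAGMENTATION_PREDICTORS = [
    PredictorDef("patch_size", "ordered", "patch",
                 levels=("small", "medium", "large"), degradation=True),
    PredictorDef("location", "unordered", "quadrat",
                 levels=("wind", "centre", "lee"), degradation=True),
    PredictorDef("bioregion", "unordered", "patch",
                 levels=("calcareous_dunes", "alluvial_plains")),
    PredictorDef("grazing", "ordered", "quadrat",
                 levels=("low", "medium", "high"), degradation=True),
    PredictorDef("organic_c", "numeric", "quadrat", 0.48, 5.0),
    PredictorDef("ph", "numeric", "quadrat", 6.2, 8.9),
    PredictorDef("total_n", "numeric", "quadrat", 0.02, 0.30),
    PredictorDef("available_p", "numeric", "quadrat", 4.0, 98.0),
    PredictorDef("tree_cover", "numeric", "quadrat", 0.0, 0.85),
    PredictorDef("exotic_annual", "numeric", "quadrat", 0.0, 0.87,
                 degradation=True),
    PredictorDef("thk_ratio", "numeric", "patch", 3.6, 5.4),
    PredictorDef("native_grass_shrub", "numeric", "quadrat", 0.0, 0.39),
]

_FRAGMENTATION_GROUPS = ["moss", "foliose_lichen", "squamulose_lichen",
                         "crustose_lichen", "gelatinous_lichen", "liverwort"]


def fencing_like(coherence: float = 0.9, overdispersion: float = 0.6,
                 zero_inflation: float = 0.3,
                 predictor_names: Sequence[str] | None = None
                 ) -> tuple[LandscapeConfig, SyntheticTruth]:
    """Grazing-recovery survey shape: 21 sites x 3 quadrats (63 quadrats),
    54 species (44 structured + 10 rare) in 10 morphogroups; the community
    responds to grazing level and time since livestock exclusion."""
    preds = _FENCING_PREDICTORS
    if predictor_names is not None:
        preds = [p for p in preds if p.name in set(predictor_names)]
    config = LandscapeConfig(predictors=preds, n_sites=21, quadrats_per_site=3)
    truth = SyntheticTruth(
        rules=[TruthRule("grazing", threshold="medium"),
               TruthRule("time_since_fencing", threshold=29.0)],
        species_per_group=[6, 6, 5, 5, 5, 4, 4, 3, 3, 3],
        group_names=list(_FENCING_GROUPS),
        coherence=coherence, overdispersion=overdispersion,
        zero_inflation=zero_inflation, rare_species=10,
    )
    return config, truth


def fragmentation_like(coherence: float = 0.9, overdispersion: float = 0.6,
                       zero_inflation: float = 0.3,
                       predictor_names: Sequence[str] | None = None
                       ) -> tuple[LandscapeConfig, SyntheticTruth]:
    """Fragmented-landscape survey shape: 25 sites, 71 quadrats (22 sites of
    3, 2 of 2, 1 of 1), 60 species (48 structured + 12 rare) in 6
    morphogroups; the community responds to remnant patch size and location
    in remnant."""
    preds = _FRAGMENTATION_PREDICTORS
    if predictor_names is not None:
        preds = [p for p in preds if p.name in set(predictor_names)]
    config = LandscapeConfig(predictors=preds, n_sites=25,
                             quadrats_per_site=[3] * 22 + [2] * 2 + [1])
    truth = SyntheticTruth(
        rules=[TruthRule("patch_size", threshold="small"),
               TruthRule("location", left_levels=frozenset({"wind"}))],
        species_per_group=[10, 9, 9, 8, 6, 6],
        group_names=list(_FRAGMENTATION_GROUPS),
        coherence=coherence, overdispersion=overdispersion,
        zero_inflation=zero_inflation, rare_species=12,
    )
    return config, truth


def simulate_dataset(preset: str = "fencing-like", seed: int = 0, **kwargs):
    """Generate a full dataset bundle for a preset.

    Returns dict with predictors, community, morphogroup map, region labels,
    config and truth.
    """
    maker = {"fencing-like": fencing_like,
             "fragmentation-like": fragmentation_like}.get(preset)
    if maker is None:
        raise ValueError(f"unknown preset {preset!r}")
    config, truth = maker(**kwargs)
    table = generate_landscape(config, seed)
    cm, mg_map, region = generate_community(table, truth, seed + 1)
    return {"predictors": table, "community": cm, "map": mg_map,
            "regions": region, "config": config, "truth": truth}
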