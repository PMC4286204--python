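"""Data model and I/O for community survey data.

A community matrix is a quadrat x taxon table of proportion cover (or 0/1
occurrence) in which each quadrat belongs to exactly one site — the remnant
vegetation patch that is the independent sampling unit for cross-validation.
Predictor tables carry quadrat-level explanatory variables with declared
measurement kinds (numeric, ordered-categorical, unordered-categorical), and
a morphogroup map assigns every species to one morphological group (e.g.
short moss, foliose lichen) so that species covers can be summed to
morphogroup covers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CommunityMatrix",
    "VariableSpec",
    "PredictorTable",
    "MorphogroupMap",
    "read_community_matrix",
    "write_community_matrix",
    "read_predictor_table",
    "read_morphogroup_map",
    "aggregate_to_morphogroups",
    "to_occurrence",
]

VALID_KINDS = ("numeric", "ordered", "unordered")


@dataclass
class CommunityMatrix:
    """Quadrat x taxon abundance or occurrence table with site membership.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by quadrat id, one column per taxon; non-negative.
    site_ids : pandas.Series
        Site (remnant patch) label for each quadrat, aligned with ``values``.
    mode : {"abundance", "occurrence"}
    resolution : {"species", "morphogroup"}
    """

    values: pd.DataFrame
    site_ids: pd.Series
    mode: str = "abundance"
    resolution: str = "species"

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.site_ids = pd.Series(self.site_ids, index=self.values.index)
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def quadrat_ids(self) -> pd.Index:
        return self.values.index

    @property
    def taxon_labels(self) -> pd.Index:
        return self.values.columns

    @property
    def n_quadrats(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        if self.mode not in ("abundance", "occurrence"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.resolution not in ("species", "morphogroup"):
            raise ValueError(f"unknown resolution {self.resolution!r}")
        idx = self.values.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate quadrat ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon labels: {dups}")
        arr = self.values.to_numpy()
        if np.isnan(arr).any():
            raise ValueError("community matrix contains missing values")
        if (arr < 0).any():
            bad = self.values.index[(arr < 0).any(axis=1)][0]
            raise ValueError(f"negative cover value in quadrat {bad!r}")
        if self.mode == "occurrence" and not np.isin(arr, (0.0, 1.0)).all():
            raise ValueError("occurrence matrix must contain only 0/1 values")
        if self.site_ids.isna().any():
            bad = self.site_ids.index[self.site_ids.isna()][0]
            raise ValueError(f"quadrat {bad!r} has no site id")

    def copy(self) -> "CommunityMatrix":
        return CommunityMatrix(
            self.values.copy(), self.site_ids.copy(), self.mode, self.resolution
        )

    def with_values(self, values: pd.DataFrame) -> "CommunityMatrix":
        """Return a new matrix with ``values`` and site ids realigned."""
        return CommunityMatrix(
            values, self.site_ids.loc[values.index], self.mode, self.resolution
        )


@dataclass(frozen=True)
class VariableSpec:
    """Declared measurement kind of one explanatory variable."""

    name: str
    kind: str  # numeric | ordered | unordered
    levels: tuple[str, ...] | None = None  # total order for `ordered`
    degradation: bool = False

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(
                f"variable {self.name!r}: kind must be one of {VALID_KINDS}, got {self.kind!r}"
            )
        if self.kind == "ordered" and not self.levels:
            raise ValueError(f"ordered variable {self.name!r} needs an explicit level order")


@dataclass
class PredictorTable:
    """Quadrat-level explanatory variables with declared kinds.

    ``data`` is indexed by quadrat id; ordered variables are stored as pandas
    ordered categoricals, unordered as plain categoricals.  Missing values are
    allowed (trees route them by a per-split majority rule).
    """

    data: pd.DataFrame
    variables: dict[str, VariableSpec]

    def __post_init__(self) -> None:
        missing = [v for v in self.variables if v not in self.data.columns]
        if missing:
            raise ValueError(f"declared variables absent from table: {missing}")
        undeclared = [c for c in self.data.columns if c not in self.variables]
        if undeclared:
            raise ValueError(f"undeclared variables in table: {undeclared}")
        self.data = _coerce_kinds(self.data, self.variables)

    @property
    def quadrat_ids(self) -> pd.Index:
        return self.data.index

    @property
    def degradation_variables(self) -> list[str]:
        return [n for n, v in self.variables.items() if v.degradation]

    def subset(self, names: Sequence[str]) -> "PredictorTable":
        return PredictorTable(
            self.data[list(names)], {n: self.variables[n] for n in names}
        )

    def loc(self, quadrats: Iterable) -> "PredictorTable":
        out = PredictorTable.__new__(PredictorTable)
        out.data = self.data.loc[list(quadrats)]
        out.variables = self.variables
        return out


def _coerce_kinds(df: pd.DataFrame, variables: Mapping[str, VariableSpec]) -> pd.DataFrame:
    out = {}
    for name, spec in variables.items():
        col = df[name]
        if spec.kind == "numeric":
            out[name] = pd.to_numeric(col, errors="raise").astype(float)
        elif spec.kind == "ordered":
            vals = col.astype(object).where(col.notna(), None)
            bad = sorted(set(v for v in vals if v is not None) - set(spec.levels))
            if bad:
                raise ValueError(
                    f"variable {name!r}: value(s) {bad} outside declared levels {list(spec.levels)}"
                )
            out[name] = pd.Categorical(vals, categories=list(spec.levels), ordered=True)
        else:
            levels = list(spec.levels) if spec.levels else sorted(col.dropna().unique())
            bad = sorted(set(col.dropna().unique()) - set(levels))
            if bad:
                raise ValueError(
                    f"variable {name!r}: value(s) {bad} outside declared levels {levels}"
                )
            out[name] = pd.Categorical(col, categories=levels, ordered=False)
    return pd.DataFrame(out, index=df.index)


@dataclass(frozen=True)
class MorphogroupMap:
    """Taxon -> morphogroup assignment (every taxon maps to exactly one group)."""

    assignments: Mapping[str, str]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.assignments.values():
            seen.setdefault(g, None)
        return list(seen)

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for g in self.assignments.values():
            sizes[g] = sizes.get(g, 0) + 1
        return sizes

    def members(self, group: str) -> list[str]:
        return [t for t, g in self.assignments.items() if g == group]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_community_matrix(
    path: str | Path,
    *,
    quadrat_col: str = "quadrat_id",
    site_col: str = "site_id",
    mode: str | None = None,
    resolution: str = "species",
) -> CommunityMatrix:
    """Read a community matrix from CSV.

    The file must have a quadrat id column, a site id column, and one column
    per taxon.  The mode is inferred as "occurrence" iff every value is 0 or
    1, unless ``mode`` overrides the inference.
    """
    df = pd.read_csv(path)
    for col in (quadrat_col, site_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    dup = df[quadrat_col][df[quadrat_col].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate quadrat id {dup.iloc[0]!r}")
    df = df.set_index(quadrat_col)
    sites = df.pop(site_col)
    values = df.astype(float)
    if mode is None:
        mode = "occurrence" if np.isin(values.to_numpy(), (0.0, 1.0)).all() else "abundance"
    return CommunityMatrix(values, sites, mode=mode, resolution=resolution)


def write_community_matrix(cm: CommunityMatrix, path: str | Path) -> None:
    out = cm.values.copy()
    out.insert(0, "site_id", cm.site_ids)
    out.to_csv(path, index_label="quadrat_id")


def read_predictor_table(
    path: str | Path,
    variable_spec: str | Path | Mapping,
    *,
    quadrat_col: str = "quadrat_id",
) -> PredictorTable:
    """Read a predictor table from CSV with kinds declared in YAML/JSON/dict.

    The spec maps variable name -> {kind, levels, degradation}; see
    :class:`VariableSpec`.
    """
    if isinstance(variable_spec, (str, Path)):
        with open(variable_spec) as fh:
            variable_spec = yaml.safe_load(fh)
    variables = {
        name: VariableSpec(
            name=name,
            kind=entry.get("kind", "numeric"),
            levels=tuple(entry["levels"]) if entry.get("levels") else None,
            degradation=bool(entry.get("degradation", False)),
        )
        for name, entry in variable_spec.items()
    }
    df = pd.read_csv(path).set_index(quadrat_col)
    return PredictorTable(df[list(variables)], variables)


def read_morphogroup_map(path: str | Path) -> MorphogroupMap:
    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["taxon", "morphogroup"]:
        df.columns = ["taxon", "morphogroup"] + list(df.columns[2:])
    if df["taxon"].duplicated().any():
        dup = df["taxon"][df["taxon"].duplicated()].iloc[0]
        raise ValueError(f"{path}: taxon {dup!r} mapped more than once")
    return MorphogroupMap(dict(zip(df["taxon"], df["morphogroup"])))


def write_morphogroup_map(mg_map: MorphogroupMap, path: str | Path) -> None:
    pd.DataFrame(
        {"taxon": list(mg_map.assignments), "morphogroup": list(mg_map.assignments.values())}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Resolution changes
# ---------------------------------------------------------------------------

def aggregate_to_morphogroups(cm: CommunityMatrix, mg_map: MorphogroupMap) -> CommunityMatrix:
    """Sum cover of all member species within each morphogroup.

    Operates on raw (untransformed) abundance; transforms belong downstream.
    Group column order follows first appearance in the map.
    """
    if cm.mode != "abundance":
        raise ValueError("morphogroup aggregation requires abundance data")
    unmapped = [t for t in cm.taxon_labels if t not in mg_map.assignments]
    if unmapped:
        raise ValueError(f"taxa missing from morphogroup map: {unmapped}")
    groups = [g for g in mg_map.groups if any(
        mg_map.assignments[t] == g for t in cm.taxon_labels)]
    cols = {g: cm.values[[t for t in cm.taxon_labels if mg_map.assignments[t] == g]].sum(axis=1)
            for g in groups}
    values = pd.DataFrame(cols, index=cm.quadrat_ids)
    return CommunityMatrix(values, cm.site_ids, mode="abundance", resolution="morphogroup")


def to_occurrence(cm: CommunityMatrix) -> CommunityMatrix:
    """Convert abundance to presence/absence (value > 0 -> 1)."""
    values = (cm.values > 0).astype(float)
    return CommunityMatrix(values, cm.site_ids, mode="occurrence", resolution=cm.resolution)
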