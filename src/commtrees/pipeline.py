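"""End-to-end orchestration: preprocess -> resolution variants ->
best-subsets trees -> indicators -> null models, with deterministic seeding
and JSON/CSV/markdown reports.

A run analyses one survey dataset at up to three response resolutions —
morphogroup abundance, species abundance and species occurrence — with the
same candidate predictor set and the same site-blocked fold assignments
across resolutions, so the cross-resolution CVRE comparison is paired.
Occurrence responses skip the log transform and total-cover standardization
(those are cover-specific); only empty-quadrat and rare-taxon removal apply
before the 0/1 conversion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess
from .community import (CommunityMatrix, MorphogroupMap, PredictorTable,
                        aggregate_to_morphogroups, to_occurrence,
                        write_community_matrix)
from .indicators import records_to_frame, tree_group_indicators
from .null_models import null_distribution
from .selection import (CVConfig, best_subsets_search,
                        classify_predictive_power)
from .tree import GrowControl

__all__ = ["RunConfig", "run_pipeline", "RESOLUTIONS"]

RESOLUTIONS = ("morphogroup-abundance", "species-abundance", "species-occurrence")


@dataclass
class RunConfig:
    """Settings for one end-to-end run."""

    resolutions: tuple[str, ...] = RESOLUTIONS
    preprocess: preprocess.PreprocessConfig = field(
        default_factory=preprocess.PreprocessConfig)
    control: GrowControl = field(default_factory=GrowControl)
    k: int | None = None
    cv_reps: int = 1
    p_max: int | None = None
    indicator_alpha: float = 0.05
    indicator_permutations: int = 999
    null_reps: int = 0          # 0 disables the null-model stage
    seed: int = 0
    out_dir: str | Path | None = None

    def __post_init__(self):
        if not self.resolutions:
            raise ValueError("resolution set must be non-empty")
        bad = set(self.resolutions) - set(RESOLUTIONS)
        if bad:
            raise ValueError(f"unknown resolutions: {sorted(bad)}")


def _prepare_resolution(resolution: str, species_cm: CommunityMatrix,
                        mg_map: MorphogroupMap | None,
                        config: RunConfig) -> CommunityMatrix:
    if resolution == "morphogroup-abundance":
        if mg_map is None:
            raise ValueError("morphogroup resolution needs a morphogroup map")
        cm = aggregate_to_morphogroups(species_cm, mg_map)
        prepared, _ = preprocess.run(cm, config.preprocess)
        return prepared
    if resolution == "species-abundance":
        prepared, _ = preprocess.run(species_cm, config.preprocess)
        return prepared
    # species-occurrence: remove empty quadrats and rare taxa, then 0/1
    cm = preprocess.drop_empty_quadrats(species_cm)
    cm = preprocess.drop_rare_taxa(cm, config.preprocess.rarity_threshold)
    return to_occurrence(cm)


def run_pipeline(species_cm: CommunityMatrix, predictors: PredictorTable,
                 mg_map: MorphogroupMap | None = None,
                 config: RunConfig | None = None) -> dict:
    """Run every requested resolution and build the comparison report.

    Returns a dict with one model block per resolution (leaderboard, chosen
    tree, RE/CVRE and predictive-power label, indicator table) plus a
    cross-resolution comparison ranked by CVRE.  A failing resolution is
    recorded and the others continue; if all fail, raises RuntimeError.
    """
    config = config or RunConfig()
    cv = CVConfig(k=config.k, reps=config.cv_reps, seed=config.seed)
    blocks: dict[str, dict] = {}
    trees = {}
    shared_folds = None

    for resolution in config.resolutions:
        try:
            prepared = _prepare_resolution(resolution, species_cm, mg_map, config)
            if shared_folds is None:
                res_cv = cv
            else:
                res_cv = CVConfig(folds=shared_folds)
            result = best_subsets_search(prepared, predictors, config.control,
                                         res_cv, p_max=config.p_max)
            if shared_folds is None:
                shared_folds = result.folds
            collapsed = result.best_tree.collapsed_for_size(result.best_size)
            recs = tree_group_indicators(
                result.best_tree, prepared, predictors.loc(prepared.quadrat_ids),
                alpha=config.indicator_alpha,
                n_perm=config.indicator_permutations,
                seed=config.seed, collapsed=collapsed)
            blocks[resolution] = {
                "n_quadrats": prepared.n_quadrats,
                "n_taxa": prepared.n_taxa,
                "best_subset": list(result.best_subset),
                "size": result.best_size,
                "re": result.best_re,
                "cvre": result.best_cvre,
                "label": classify_predictive_power(result.best_cvre),
                "leaderboard": result.leaderboard,
                "tree_text": result.best_tree.to_text(collapsed),
                "tree_json": result.best_tree.to_dict(),
                "indicators": records_to_frame(recs),
            }
            trees[resolution] = result
        except Exception as exc:  # keep other resolutions alive
            blocks[resolution] = {"error": f"{type(exc).__name__}: {exc}"}

    ok = {r: b for r, b in blocks.items() if "error" not in b}
    if not ok:
        raise RuntimeError(f"all resolutions failed: {blocks}")

    ranking = sorted(ok, key=lambda r: ok[r]["cvre"])
    report = {
        "seed": config.seed,
        "resolutions": blocks,
        "comparison": {
            "ranking_by_cvre": ranking,
            "best_resolution": ranking[0],
            "cvre": {r: ok[r]["cvre"] for r in ranking},
        },
    }

    if config.null_reps and mg_map is not None:
        null = null_distribution(
            preprocess.drop_empty_quadrats(species_cm), mg_map, predictors,
            reps=config.null_reps, seed=config.seed, control=config.control,
            cv=CVConfig(folds=shared_folds) if shared_folds else cv,
            pre_config=config.preprocess, p_max=config.p_max)
        report["null_model"] = {
            "observed_cvre": null.observed_cvre,
            "observed_re": null.observed_re,
            "quantile": null.quantile,
            "replicates": null.replicates,
            "failures": null.failures,
            "null_cvre_p05": null.percentile_of(5),
            "null_cvre_median": null.percentile_of(50),
        }

    if config.out_dir is not None:
        _write_artifacts(report, config)
    return report


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return obj.astype(object).where(obj.notna(), None).to_dict("records")
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_artifacts(report: dict, config: RunConfig) -> None:
    out = Path(config.out_dir)
    (out / "models").mkdir(parents=True, exist_ok=True)
    (out / "indicators").mkdir(exist_ok=True)
    for resolution, block in report["resolutions"].items():
        if "error" in block:
            continue
        stem = resolution.replace("-", "_")
        lb = block["leaderboard"].copy()
        lb["subset"] = lb["subset"].map(lambda s: "+".join(s))
        lb.to_csv(out / "models" / f"{stem}_leaderboard.csv", index=False)
        (out / "models" / f"{stem}_tree.txt").write_text(block["tree_text"])
        (out / "models" / f"{stem}_tree.json").write_text(
            json.dumps(_jsonable(block["tree_json"]), indent=2))
        block["indicators"].to_csv(out / "indicators" / f"{stem}.csv", index=False)
    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2))
    lines = ["# Run report", ""]
    for resolution in report["comparison"]["ranking_by_cvre"]:
        b = report["resolutions"][resolution]
        lines.append(f"- **{resolution}**: subset={'+'.join(b['best_subset'])}, "
                     f"size={b['size']}, RE={b['re']:.3f}, CVRE={b['cvre']:.3f} "
                     f"({b['label']})")
    lines.append("")
    lines.append(f"Best resolution by CVRE: {report['comparison']['best_resolution']}")
    (out / "report.md").write_text("\n".join(lines) + "\n")
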