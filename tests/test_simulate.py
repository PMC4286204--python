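"""Synthetic landscape and community generator with known ground truth."""

import numpy as np
import pandas as pd
import pytest

from commtrees.community import aggregate_to_morphogroups
from commtrees.simulate import (LandscapeConfig, PredictorDef, SyntheticTruth,
                                TruthRule, assign_regions, fencing_like,
                                fragmentation_like, generate_community,
                                generate_landscape, simulate_dataset,
                                truth_report)
from commtrees.tree import GrowControl, grow_tree
from oracles import contingency_ari


SIMPLE_PREDS = [
    PredictorDef("ph", "numeric", "quadrat", 6.2, 8.9),
    PredictorDef("patch_size", "ordered", "patch",
                 levels=("small", "medium", "large")),
]


class TestGenerateLandscape:
    def test_dimensions_and_patch_broadcast(self):
        config = LandscapeConfig(SIMPLE_PREDS, n_sites=20, quadrats_per_site=3)
        table = generate_landscape(config, seed=1)
        assert len(table.data) == 60
        sites = table.data.attrs["site_ids"]
        per_site = pd.Series(list(table.data["patch_size"]),
                             index=sites).groupby(level=0).nunique()
        assert (per_site == 1).all()

    def test_numeric_values_within_declared_range(self):
        config = LandscapeConfig(SIMPLE_PREDS, n_sites=30, quadrats_per_site=2)
        table = generate_landscape(config, seed=2)
        ph = table.data["ph"]
        assert ph.between(6.2, 8.9).all()

    def test_same_seed_same_table(self):
        config = LandscapeConfig(SIMPLE_PREDS, n_sites=10, quadrats_per_site=3)
        a = generate_landscape(config, seed=3)
        b = generate_landscape(config, seed=3)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestGenerateCommunity:
    def coherent_truth(self, **kw):
        defaults = dict(rules=[TruthRule("ph", threshold=7.5)],
                        species_per_group=[3, 3], coherence=1.0,
                        overdispersion=0.0, zero_inflation=0.0, rare_species=0)
        defaults.update(kw)
        return SyntheticTruth(**defaults)

    def test_coherent_noiseless_is_piecewise_constant(self):
        config = LandscapeConfig(SIMPLE_PREDS, n_sites=8, quadrats_per_site=3)
        table = generate_landscape(config, seed=4)
        truth = self.coherent_truth()
        cm, mg_map, region = generate_community(table, truth, seed=5)
        agg = aggregate_to_morphogroups(cm, mg_map)
        for r in np.unique(region):
            block = agg.values.to_numpy()[region == r]
            assert np.allclose(block, block[0])
            sp_block = cm.values.to_numpy()[region == r]
            assert np.allclose(sp_block, sp_block[0])

    def test_unknown_rule_variable_rejected(self):
        config = LandscapeConfig(SIMPLE_PREDS, n_sites=4, quadrats_per_site=2)
        table = generate_landscape(config, seed=0)
        truth = self.coherent_truth(rules=[TruthRule("mystery", threshold=1.0)])
        with pytest.raises(ValueError, match="mystery"):
            generate_community(table, truth, seed=0)

    def test_zero_coherence_decouples_species_from_group(self):
        # correlation between species regional response and its group's
        # regional mean should vanish at coherence 0
        config = LandscapeConfig(SIMPLE_PREDS, n_sites=30, quadrats_per_site=2)
        rs = []
        for seed in range(100):
            table = generate_landscape(config, seed=seed)
            truth = self.coherent_truth(coherence=0.0,
                                        species_per_group=[4, 4])
            cm, mg_map, region = generate_community(table, truth, seed=seed + 1)
            agg = aggregate_to_morphogroups(cm, mg_map)
            for taxon in list(cm.taxon_labels)[:4]:
                g = mg_map.assignments[taxon]
                sp = np.array([cm.values[taxon][region == r].mean()
                               for r in np.unique(region)])
                others = np.array([
                    (agg.values[g][region == r].mean()
                     - cm.values[taxon][region == r].mean())
                    for r in np.unique(region)])
                if sp.std() > 0 and others.std() > 0:
                    rs.append(np.corrcoef(sp, others)[0, 1])
        assert abs(np.mean(rs)) < 0.1

    def test_fencing_preset_shape(self):
        bundle = simulate_dataset("fencing-like", seed=0)
        assert bundle["community"].values.shape == (63, 54)
        assert len(bundle["map"].groups) == 10
        assert bundle["community"].site_ids.nunique() == 21

    def test_fragmentation_preset_shape(self):
        bundle = simulate_dataset("fragmentation-like", seed=0)
        assert bundle["community"].values.shape == (71, 60)
        assert len(bundle["map"].groups) == 6
        assert bundle["community"].site_ids.nunique() == 25

    def test_rare_species_are_rare(self):
        bundle = simulate_dataset("fencing-like", seed=1)
        cm = bundle["community"]
        for taxon in cm.taxon_labels:
            if taxon.startswith("rare_"):
                assert (cm.values[taxon] > 0).sum() <= 3


class TestTruthReport:
    def test_exact_recovery_scores_ari_one(self):
        config = LandscapeConfig(SIMPLE_PREDS, n_sites=12, quadrats_per_site=5)
        table = generate_landscape(config, seed=6)
        truth = SyntheticTruth(rules=[TruthRule("ph", threshold=7.5)],
                               species_per_group=[3, 3], coherence=1.0,
                               overdispersion=0.0, zero_inflation=0.0)
        cm, mg_map, region = generate_community(table, truth, seed=7)
        tree = grow_tree(cm.values, table, GrowControl())
        report = truth_report(truth, tree, table, region)
        assert report["all_found"]
        assert report["ari"] == pytest.approx(1.0)
        assert report["threshold_errors"]["ph"] < 1.0

    def test_root_only_tree_misses_everything(self):
        config = LandscapeConfig(SIMPLE_PREDS, n_sites=12, quadrats_per_site=5)
        table = generate_landscape(config, seed=8)
        truth = SyntheticTruth(rules=[TruthRule("ph", threshold=7.5)],
                               species_per_group=[3, 3], coherence=1.0,
                               overdispersion=0.0, zero_inflation=0.0)
        cm, mg_map, region = generate_community(table, truth, seed=9)
        stump = grow_tree(cm.values, table,
                          GrowControl(min_node_size=40, min_split_size=80))
        report = truth_report(truth, stump, table, region)
        assert not report["all_found"]
        assert abs(report["ari"]) < 1e-9

    def test_ari_matches_contingency_oracle(self, rng):
        from sklearn.metrics import adjusted_rand_score
        for _ in range(20):
            a = rng.integers(0, 4, 30)
            b = rng.integers(0, 3, 30)
            assert adjusted_rand_score(a, b) == pytest.approx(
                contingency_ari(a, b), abs=1e-12)


class TestDifficultyMonotonicity:
    def test_recovery_degrades_with_noise_improves_with_coherence(self):
        # 2x2 corner check of the difficulty grid, 12 seeds per cell
        config, _ = fencing_like(predictor_names=["grazing",
                                                  "time_since_fencing", "ph"])

        def recovery_rate(coherence, noise):
            hits = 0
            for seed in range(12):
                _, truth = fencing_like(coherence=coherence,
                                        overdispersion=noise,
                                        predictor_names=["grazing",
                                                         "time_since_fencing",
                                                         "ph"])
                table = generate_landscape(config, seed=seed)
                cm, mg_map, region = generate_community(table, truth, seed + 1)
                agg = aggregate_to_morphogroups(cm, mg_map)
                tree = grow_tree(agg.values, table, GrowControl())
                rep = truth_report(truth, tree, table, region)
                hits += rep["all_found"]
            return hits / 12

        easy = recovery_rate(coherence=1.0, noise=0.2)
        hard = recovery_rate(coherence=0.2, noise=1.5)
        assert easy >= hard
        assert easy >= 0.8
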