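import random

import numpy as np
import pytest

from nicheshift.niche import build_catalog, build_step_matrix, records_from_table, tip_state_sets
from nicheshift.pairs import classify_pairs
from nicheshift.parsimony import sankoff_min_cost
from nicheshift.simulate import (
    SimulationConfig,
    attach_outgroups,
    generate_dataset,
    nni_perturb,
    simulate_niche_evolution,
    simulate_tree,
)
from nicheshift.stats import fit_logistic
from nicheshift.treeio import extract_sister_pairs, read_tree, read_trees, read_tree


def ingroup_dataset(cfg):
    rng = random.Random(cfg.seed)
    tree = simulate_tree(cfg, rng=rng)
    table = simulate_niche_evolution(tree, cfg, rng=rng)
    return tree, table


class TestSimulateTree:
    def test_two_tips_is_unit_cherry(self):
        tree = simulate_tree(SimulationConfig(n_tips=2, seed=1))
        leaves = list(tree.leaf_node_iter())
        assert len(leaves) == 2
        assert all(l.distance_from_root() == pytest.approx(1.0) for l in leaves)

    def test_deterministic_newick_from_seed(self):
        cfg = SimulationConfig(n_tips=40, seed=99)
        a = simulate_tree(cfg).as_string(schema="newick")
        b = simulate_tree(cfg).as_string(schema="newick")
        assert a == b

    def test_pure_birth_tip_count_and_ultrametricity(self):
        tree = simulate_tree(SimulationConfig(n_tips=100, seed=5))
        depths = [l.distance_from_root() for l in tree.leaf_node_iter()]
        assert len(depths) == 100
        assert max(depths) - min(depths) < 1e-9
        assert max(depths) == pytest.approx(1.0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_tips=1)
        with pytest.raises(ValueError):
            SimulationConfig(p_eco=1.5)


class TestNicheEvolution:
    def test_no_change_limit(self):
        """p_eco=0, ana_rate=0: one niche everywhere, zero steps, no
        niche-different pair."""
        cfg = SimulationConfig(n_tips=30, p_eco=0.0, ana_rate=0.0, seed=2)
        tree, table = ingroup_dataset(cfg)
        ingroup = table[table.outgroup == 0]
        assert ingroup.apply(lambda r: (r.feeding_habit, r.hosts), axis=1).nunique() == 1
        coding = build_catalog(records_from_table(table))
        tips = tip_state_sets(coding, {l.taxon.label for l in tree.leaf_node_iter()})
        costs = build_step_matrix(coding, rule="all_one")
        assert sankoff_min_cost(tree, tips, costs) == 0.0
        ds = classify_pairs(extract_sister_pairs(tree), coding)
        assert ds.niche_different.sum() == 0

    def test_all_ecological_specialist_limit(self):
        """p_eco=1, no generalists, no anagenetic change: every cherry is
        niche-different and the uniform-cost step count is n - 1."""
        # a wide host pool so no two cladogenetic draws collide; with p_eco=1
        # each niche is carried by exactly one lineage, so tip niches are
        # pairwise distinct and every split contributes exactly one change
        hosts = tuple(f"Genus{i}" for i in range(200))
        cfg = SimulationConfig(
            n_tips=12, p_eco=1.0, ana_rate=0.0, p_generalist=0.0, seed=3,
            host_pool=hosts,
        )
        tree, table = ingroup_dataset(cfg)
        coding = build_catalog(records_from_table(table))
        assert coding.n_states == cfg.n_tips  # no-collision precondition
        ds = classify_pairs(extract_sister_pairs(tree), coding)
        assert ds.niche_different.all()
        tips = tip_state_sets(coding, {l.taxon.label for l in tree.leaf_node_iter()})
        costs = build_step_matrix(coding, rule="all_one")
        assert sankoff_min_cost(tree, tips, costs) == pytest.approx(cfg.n_tips - 1)

    def test_anagenetic_change_raises_difference_with_age(self):
        """With post-speciational shifts, the fitted age slope is positive
        in the clear majority of replicates."""
        positives = 0
        n_rep = 10
        for rep in range(n_rep):
            cfg = SimulationConfig(n_tips=150, p_eco=0.2, ana_rate=1.5,
                                   n_outgroups=0, seed=500 + rep)
            tree, table = ingroup_dataset(cfg)
            coding = build_catalog(records_from_table(table))
            ds = classify_pairs(extract_sister_pairs(tree), coding)
            try:
                fit = fit_logistic(ds)
            except ValueError:
                continue
            if fit.converged and fit.beta1 > 0:
                positives += 1
        assert positives >= 0.7 * n_rep

    def test_pool_too_small_is_error(self):
        cfg = SimulationConfig(
            n_tips=5, p_eco=1.0, host_pool=("Salix",), habit_pool=("galling",),
            p_generalist=0.0, seed=4,
        )
        rng = random.Random(cfg.seed)
        tree = simulate_tree(cfg, rng=rng)
        with pytest.raises(ValueError, match="too small"):
            simulate_niche_evolution(tree, cfg, rng=rng)


class TestOutgroupsAndPerturbation:
    def test_attach_outgroups_keeps_ultrametric_unit_height(self):
        tree = simulate_tree(SimulationConfig(n_tips=20, seed=6))
        attach_outgroups(tree, 3)
        depths = [l.distance_from_root() for l in tree.leaf_node_iter()]
        assert len(depths) == 23
        assert max(depths) - min(depths) < 1e-9
        labels = {l.taxon.label for l in tree.leaf_node_iter()}
        assert {"OUT1", "OUT2", "OUT3"} <= labels

    def test_nni_preserves_tips_changes_topology(self):
        rng = random.Random(8)
        tree = simulate_tree(SimulationConfig(n_tips=25, seed=8))
        pert = nni_perturb(tree, 3, rng)
        from dendropy.calculate import treecompare
        assert {l.taxon.label for l in pert.leaf_node_iter()} == {
            l.taxon.label for l in tree.leaf_node_iter()
        }
        assert treecompare.symmetric_difference(tree, pert) > 0

    def test_perturbation_does_not_reduce_homoplasy_on_average(self):
        """NNI moves away from the generating topology cannot systematically
        lower the parsimony step count."""
        at_least_as_many = 0
        total = 0
        for seed in range(5):
            cfg = SimulationConfig(n_tips=40, p_eco=0.3, ana_rate=1.0,
                                   n_outgroups=0, seed=700 + seed)
            rng = random.Random(cfg.seed)
            tree = simulate_tree(cfg, rng=rng)
            table = simulate_niche_evolution(tree, cfg, rng=rng)
            coding = build_catalog(records_from_table(table))
            tips = tip_state_sets(coding, {l.taxon.label for l in tree.leaf_node_iter()})
            costs = build_step_matrix(coding, rule="all_one")
            base = sankoff_min_cost(tree, tips, costs)
            for _ in range(10):
                pert = nni_perturb(tree, 2, rng)
                total += 1
                if sankoff_min_cost(pert, tips, costs) >= base:
                    at_least_as_many += 1
        assert at_least_as_many >= total / 2


class TestGenerateDataset:
    def test_files_roundtrip_through_readers(self, tmp_path):
        cfg = SimulationConfig(n_tips=30, seed=9)
        result = generate_dataset(cfg, n_posterior_trees=4, out_dir=tmp_path)
        tree = read_tree(result["mcc_path"])
        sample = read_trees(result["posterior_path"])
        assert len(sample) == 4
        mcc_labels = {l.taxon.label for l in tree.leaf_node_iter()}
        assert len(mcc_labels) == 30 + cfg.n_outgroups
        for t in sample:
            assert {l.taxon.label for l in t.leaf_node_iter()} == mcc_labels
        from nicheshift.niche import read_niche_table
        table = read_niche_table(result["niche_path"])
        assert set(table.species) == mcc_labels

    def test_zero_posterior_trees(self, tmp_path):
        cfg = SimulationConfig(n_tips=10, seed=10)
        result = generate_dataset(cfg, n_posterior_trees=0, out_dir=tmp_path)
        assert "posterior_path" not in result
        assert len(result["posterior"]) == 0
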