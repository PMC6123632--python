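"""Generator contracts: Yule heights against the analytic expectation,
coalescent grafting, Jukes-Cantor evolution against its closed form, and the
survey's detection model."""

import numpy as np
import pytest

from metabias import (
    DetectionModel,
    RegionSpec,
    SyntheticTruth,
    assign_phyla,
    default_regions,
    evolve_sequences,
    graft_coalescent_tips,
    simulate_survey,
    simulate_yule_tree,
)
from metabias.synthetic_data import species_of_tip


class TestYule:
    def test_single_species(self):
        t = simulate_yule_tree(1, 1.0, 0)
        assert t.tip_labels() == ["sp1"]
        assert t.height == 0.0

    def test_two_species_one_split(self):
        t = simulate_yule_tree(2, 1.0, 0)
        assert len(t.tip_labels()) == 2
        assert t.is_ultrametric

    def test_internal_node_count(self):
        t = simulate_yule_tree(12, 1.0, 3)
        n_internal = sum(1 for n in t.tree.preorder_node_iter() if not n.is_leaf())
        assert n_internal == 11

    def test_deterministic_given_seed(self):
        assert simulate_yule_tree(8, 2.0, 5).to_newick() == \
            simulate_yule_tree(8, 2.0, 5).to_newick()

    def test_invalid_birth_rate(self):
        with pytest.raises(ValueError):
            simulate_yule_tree(5, 0.0, 0)

    def test_mean_root_height_matches_analytic_expectation(self):
        # E[height] = sum_{k=2..n} 1/(lambda k) for an n-tip pure-birth tree
        lam, n, reps = 1.0, 10, 500
        heights = [simulate_yule_tree(n, lam, 10_000 + i).height for i in range(reps)]
        expected = sum(1.0 / (lam * k) for k in range(2, n + 1))
        assert np.mean(heights) == pytest.approx(expected, rel=0.10)


class TestGraft:
    def test_single_tip_per_species_keeps_topology(self):
        sp = simulate_yule_tree(5, 1.0, 1)
        g = graft_coalescent_tips(sp, 1, 0.01 * sp.height, 2)
        assert sorted(g.tip_labels()) == sorted(f"sp{i}_t1" for i in range(1, 6))
        assert g.height == pytest.approx(sp.height, rel=1e-9)

    def test_tip_count_and_ultrametricity(self):
        sp = simulate_yule_tree(6, 1.0, 4)
        g = graft_coalescent_tips(sp, 3, 0.01 * sp.height, 5)
        assert len(g.tip_labels()) == 18
        assert g.is_ultrametric

    def test_within_mrcas_younger_than_species_nodes(self):
        sp = simulate_yule_tree(5, 1.0, 0)
        g = graft_coalescent_tips(sp, 4, 0.01 * sp.height, 1000)
        within, between = [], []
        for node, age in g.node_ages().items():
            if node.is_leaf():
                continue
            species = {species_of_tip(l.taxon.label) for l in node.leaf_iter()}
            (within if len(species) == 1 else between).append(age)
        assert max(within) < min(between)

    def test_invalid_theta(self):
        sp = simulate_yule_tree(3, 1.0, 0)
        with pytest.raises(ValueError):
            graft_coalescent_tips(sp, 2, 0.0, 0)


class TestEvolve:
    def test_zero_rate_gives_identical_tips(self):
        t = graft_coalescent_tips(simulate_yule_tree(4, 1.0, 0), 2, 0.01, 1)
        regions = [RegionSpec("R", length=50, rate=0.0,
                              fwd_primer="ACGT", rev_primer="TTAA")]
        seqs = evolve_sequences(t, regions, 2)
        assert len({r.seq for r in seqs}) == 1

    def test_primers_conserved_across_tips(self):
        t = simulate_yule_tree(5, 1.0, 3)
        regions = default_regions()
        seqs = evolve_sequences(t, regions, 4)
        v12 = regions[0]
        for rec in seqs:
            assert rec.seq.startswith(v12.fwd_primer)

    def test_jukes_cantor_identity_matches_closed_form(self):
        # two tips at patristic distance d: P(same base) = 1/4 + 3/4 exp(-4rd/3)
        from metabias import UltrametricTree

        d, rate, length = 1.2, 0.3, 600
        tree = UltrametricTree.from_newick(f"(A:{d / 2},B:{d / 2});")
        regions = [RegionSpec("R", length=length, rate=rate,
                              fwd_primer="AC", rev_primer="GT")]
        seqs = evolve_sequences(tree, regions, 11)
        a, b = (r.seq[2:-2] for r in seqs)
        observed = np.mean([x == y for x, y in zip(a, b)])
        expected = 0.25 + 0.75 * np.exp(-4.0 * rate * d / 3.0)
        se = np.sqrt(expected * (1 - expected) / length)
        assert abs(observed - expected) < 3 * se

    def test_deterministic_given_seed(self):
        t = simulate_yule_tree(4, 1.0, 9)
        s1 = evolve_sequences(t, default_regions(), 7)
        s2 = evolve_sequences(t, default_regions(), 7)
        assert s1 == s2


def _small_community(seed=0, n_species=7, n_phyla=7, within=1):
    sp = simulate_yule_tree(n_species, 1.0, seed)
    tree = graft_coalescent_tips(sp, within, 0.01 * sp.height, seed + 1)
    seqs = evolve_sequences(tree, default_regions(), seed + 2)
    phyla = assign_phyla(sorted({r.species for r in seqs}),
                         [f"P{i + 1}" for i in range(n_phyla)])
    return tree, seqs, phyla


class TestSurvey:
    def test_perfect_detection_recovers_truth(self):
        tree, seqs, phyla = _small_community()
        det = DetectionModel(methods=("specimen", "metabarcoding"),
                             read_depth_mean=2.0, error_rate=0.0)
        inc, observed, truth = simulate_survey(tree, seqs, 4, 0.6, det, 3,
                                               phylum_of=phyla)
        for method in det.methods:
            seen = {}
            for rec in observed[method]:
                info = truth.read_truth[rec.id]
                seen.setdefault(info["site"], set()).add(info["species"])
            for site in inc.sites:
                expected = {sp for sp in inc.units if inc.data.loc[sp, site] == 1}
                assert seen.get(site, set()) == expected

    def test_zero_detection_silences_phylum(self):
        tree, seqs, phyla = _small_community()
        target = "P3"
        det = DetectionModel(
            methods=("specimen", "metabarcoding"),
            detection={(target, "metabarcoding"): 0.0},
            read_depth_mean=2.0,
        )
        _, observed, truth = simulate_survey(tree, seqs, 4, 0.6, det, 3,
                                             phylum_of=phyla)
        assert not any(
            truth.phylum_of[truth.read_truth[r.id]["species"]] == target
            for r in observed["metabarcoding"]
        )
        assert any(
            truth.phylum_of[truth.read_truth[r.id]["species"]] == target
            for r in observed["specimen"]
        )

    def test_detection_deficit_depresses_observed_richness(self):
        # a phylum sampled at p=0.3 by one method and 0.95 elsewhere shows
        # lower observed richness under that method in nearly every survey
        tree, seqs, phyla = _small_community(n_species=14, n_phyla=7)
        target = "P2"
        det = DetectionModel(
            methods=("specimen", "metabarcoding"),
            detection={(p, m): 0.3 if (p == target and m == "metabarcoding") else 0.95
                       for p in set(phyla.values())
                       for m in ("specimen", "metabarcoding")},
            read_depth_mean=2.0,
        )
        wins = 0
        for seed in range(50):
            _, observed, truth = simulate_survey(tree, seqs, 8, 0.6, det, seed,
                                                 phylum_of=phyla)
            richness = {}
            for method in det.methods:
                per_site = {
                    (truth.read_truth[r.id]["site"], truth.read_truth[r.id]["species"])
                    for r in observed[method]
                    if truth.phylum_of[truth.read_truth[r.id]["species"]] == target
                }
                richness[method] = len(per_site)  # summed per-site richness
            wins += richness["metabarcoding"] < richness["specimen"]
        assert wins >= 45  # >= 90% of 50 seeds

    def test_truth_round_trips_and_explains_every_read(self, tmp_path):
        tree, seqs, phyla = _small_community()
        det = DetectionModel(methods=("m1",), read_depth_mean=3.0, error_rate=0.01)
        _, observed, truth = simulate_survey(tree, seqs, 3, 0.7, det, 5,
                                             phylum_of=phyla)
        assert {r.id for r in observed["m1"]} == set(truth.read_truth)
        p = tmp_path / "truth.json"
        truth.to_json(p)
        loaded = SyntheticTruth.from_json(p)
        assert loaded.read_truth == truth.read_truth
        assert loaded.incidence_true == truth.incidence_true
        assert loaded.phylum_of == truth.phylum_of

    def test_bit_reproducible(self):
        tree, seqs, phyla = _small_community()
        det = DetectionModel(methods=("m1",), read_depth_mean=3.0, error_rate=0.01)
        a = simulate_survey(tree, seqs, 3, 0.7, det, 5, phylum_of=phyla)
        b = simulate_survey(tree, seqs, 3, 0.7, det, 5, phylum_of=phyla)
        assert a[1] == b[1]
        assert a[0] == b[0]


def test_assign_phyla_partitions_deterministically():
    species = [f"sp{i}" for i in range(10)]
    mapping = assign_phyla(species, ["A", "B", "C"])
    assert set(mapping) == set(species)
    assert set(mapping.values()) == {"A", "B", "C"}
    assert mapping == assign_phyla(species, ["A", "B", "C"])
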