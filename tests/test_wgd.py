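"""WGD labeling, permutation/attribution simulations and contingency tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wgdnet.network_build import compute_degrees
from wgdnet.reaction_io import EnzymeGeneMap
from wgdnet.synthetic_data import SyntheticConfig, generate_network, plant_labels
from wgdnet.wgd import (
    WGDLabelSet,
    build_enzyme_ortholog_map,
    compare_centralities,
    contingency_test,
    cross_species_conservation,
    edge_sampling_attribution,
    expected_induced_edges,
    ibwe_count,
    ibwe_edges,
    label_from_pairs,
    label_permutation_test,
    mann_whitney_exact,
    permutation_zscore,
)
from conftest import make_network


def labelset(*enzymes):
    return WGDLabelSet(frozenset(enzymes))


class TestLabeling:
    def test_pair_within_one_enzyme_labels_it(self):
        emap = {"EC_X": EnzymeGeneMap("EC_X", {"g1", "g2"}, set())}
        labels = label_from_pairs([("g1", "g2")], emap)
        assert labels.labeled_enzymes == {"EC_X"}

    def test_pair_split_across_enzymes_labels_neither(self):
        emap = {
            "E1": EnzymeGeneMap("E1", {"g1"}, set()),
            "E2": EnzymeGeneMap("E2", {"g2"}, set()),
        }
        assert label_from_pairs([("g1", "g2")], emap).labeled_enzymes == frozenset()

    def test_empty_pairs_empty_labels(self):
        emap = {"E1": EnzymeGeneMap("E1", {"g1"}, set())}
        assert label_from_pairs([], emap).labeled_enzymes == frozenset()


class TestMannWhitney:
    def test_identical_groups_give_p_one(self):
        _, p = mann_whitney_exact([5, 5, 5], [5, 5, 5])
        assert p == 1.0

    def test_fully_separated_groups(self):
        # all 20 label splits; only U=0 and U=9 deviate as much as observed
        u, p = mann_whitney_exact([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])

    def test_exact_path_matches_scipy_exact_on_tiefree_data(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pooled = rng.permutation(np.arange(1.0, 9.0))
            n1 = int(rng.integers(1, 8))
            x, y = pooled[:n1], pooled[n1:]
            _, p_ours = mann_whitney_exact(x, y)
            p_scipy = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="exact"
            ).pvalue
            assert p_ours == pytest.approx(p_scipy, abs=1e-12)

    def test_compare_centralities_uses_exact_for_small_groups(self):
        df = pd.DataFrame(
            {"in_degree": [1, 2, 3, 10, 11, 12]},
            index=["a", "b", "c", "d", "e", "f"],
        )
        report = compare_centralities(df, labelset("d", "e", "f"))
        assert report.loc["in_degree", "method"] == "exact"
        assert report.loc["in_degree", "p_value"] == pytest.approx(0.1)

    def test_compare_centralities_requires_both_groups(self):
        df = pd.DataFrame({"x": [1, 2]}, index=["a", "b"])
        with pytest.raises(ValueError):
            compare_centralities(df, labelset("a", "b"))

    def test_planted_hub_labels_detected(self):
        hits = 0
        for seed in range(20):
            cfg = SyntheticConfig(seed=500 + seed, n_enzymes=200, target_edges=520)
            net, _, _ = generate_network(cfg)
            labels, _ = plant_labels(net, cfg)
            recs = compute_degrees(net)
            df = pd.DataFrame(
                {
                    "in_degree": {e: r.in_degree for e, r in recs.items()},
                    "out_degree": {e: r.out_degree for e, r in recs.items()},
                }
            )
            report = compare_centralities(df, labels)
            hits += (report["p_value"] < 0.05).all()
        assert hits >= 18


class TestIBWE:
    def test_all_labeled_counts_every_edge(self, worked_example):
        labels = labelset(*worked_example.enzymes)
        assert ibwe_count(worked_example, labels) == worked_example.n_edges

    def test_no_labels_counts_zero(self, worked_example):
        assert ibwe_count(worked_example, labelset()) == 0

    def test_one_labeled_edge_in_a_path(self):
        net = make_network(directional=[("A", "B"), ("B", "C")])
        assert ibwe_count(net, labelset("A", "B")) == 1

    def test_monotone_under_label_growth(self, small_bundle):
        net = small_bundle.network
        nodes = sorted(net.enzymes)
        counts = [
            ibwe_count(net, labelset(*nodes[:k])) for k in range(0, len(nodes), 20)
        ]
        assert counts == sorted(counts)


class TestExpectedInducedEdges:
    def test_no_labels(self):
        assert expected_induced_edges(10, 0, 30) == 0.0

    def test_all_labeled_recovers_edge_count(self):
        assert expected_induced_edges(10, 10, 30) == 30.0

    def test_hand_arithmetic_at_analysis_scale(self):
        assert expected_induced_edges(478, 173, 1394) == pytest.approx(
            181.92, abs=0.01
        )

    def test_tiny_n_rejected(self):
        with pytest.raises(ValueError):
            expected_induced_edges(1, 0, 0)


class TestPermutationTest:
    def test_printed_zscore_arithmetic(self):
        assert permutation_zscore(255, 183, 22) == pytest.approx(3.27, abs=0.005)

    def test_zero_sd_rejected_in_zscore(self):
        with pytest.raises(ValueError):
            permutation_zscore(10, 10, 0)

    def test_all_nodes_labeled_is_degenerate(self, worked_example):
        null = label_permutation_test(
            worked_example, labelset(*worked_example.enzymes), n_reps=50, seed=0
        )
        assert null.degenerate
        assert null.null_sd == 0.0
        assert (null.samples == worked_example.n_edges).all()

    def test_empirical_mean_matches_closed_form_across_seeds(self):
        for seed in range(5):
            cfg = SyntheticConfig(seed=700 + seed, n_enzymes=80, target_edges=200)
            net, _, _ = generate_network(cfg)
            null = label_permutation_test(net, 25, n_reps=2000, seed=seed)
            expected = expected_induced_edges(80, 25, 200)
            tol = 3 * null.null_sd / np.sqrt(null.n_reps)
            assert abs(null.null_mean - expected) <= tol

    def test_more_labels_than_nodes_rejected(self, worked_example):
        with pytest.raises(ValueError):
            label_permutation_test(worked_example, 99, n_reps=10, seed=0)

    def test_observed_and_pvalues_reported(self, small_bundle):
        null = label_permutation_test(
            small_bundle.network, small_bundle.labels, n_reps=999, seed=1
        )
        assert null.observed == ibwe_count(small_bundle.network, small_bundle.labels)
        assert 0 < null.p_empirical <= 1
        assert null.z_score == pytest.approx(
            (null.observed - null.null_mean) / null.null_sd
        )

    def test_same_seed_reproducible(self, small_bundle):
        a = label_permutation_test(small_bundle.network, 30, n_reps=500, seed=9)
        b = label_permutation_test(small_bundle.network, 30, n_reps=500, seed=9)
        assert (a.samples == b.samples).all()


class TestAttribution:
    def test_star_with_fixed_m_gives_f_m_plus_one(self):
        net = make_network(directional=[("HUB", f"L{i}") for i in range(6)])
        res = edge_sampling_attribution(net, 3, 0, n_reps=200, seed=0)
        assert res.f_mean == 4.0 and res.f_sd == 0.0

    def test_perfect_matching_gives_f_two_m(self):
        net = make_network(directional=[(f"A{i}", f"B{i}") for i in range(5)])
        res = edge_sampling_attribution(net, 3, 0, n_reps=200, seed=0)
        assert res.f_mean == 6.0 and res.f_sd == 0.0

    def test_f_bounded_by_two_m(self, small_bundle):
        res = edge_sampling_attribution(small_bundle.network, 40, 10, n_reps=500, seed=2)
        assert (res.f_samples <= 2 * res.m_samples).all()
        assert (res.f_samples >= 0).all()

    def test_mean_matches_exhaustive_enumeration_on_small_graph(self):
        edges = [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("A", "E")]
        net = make_network(directional=edges)
        m = 2
        exact = np.mean(
            [
                len({u for e in combo for u in e})
                for combo in itertools.combinations(edges, m)
            ]
        )
        res = edge_sampling_attribution(net, m, 0, n_reps=4000, seed=3)
        se = res.f_sd / np.sqrt(res.n_reps)
        assert abs(res.f_mean - exact) <= 3 * max(se, 1e-9)

    def test_nonpositive_excess_rejected(self, worked_example):
        with pytest.raises(ValueError):
            edge_sampling_attribution(worked_example, 0, 1)


class TestContingency:
    def test_age_table_nonsignificant_under_all_variants(self):
        for variant in ("pearson", "yates", "fisher"):
            res = contingency_test([[162, 11], [281, 24]], variant)
            assert res.p_value > 0.05

    def test_cross_species_table_significant(self):
        res = contingency_test([[32, 223], [36, 1103]])
        assert res.p_value < 0.01

    def test_symmetric_table(self):
        res = contingency_test([[5, 5], [5, 5]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            contingency_test([[0, 0], [3, 4]])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            contingency_test([[1, -1], [2, 3]])


class TestCrossSpecies:
    def test_identity_orthologs_with_identical_labels(self, worked_example):
        labels = labelset("ALPHA", "BETA", "S1")
        ortho = {e: {e} for e in worked_example.enzymes}
        result, edge_sets = cross_species_conservation(
            worked_example, ibwe_edges(worked_example, labels), ortho, labels
        )
        assert len(edge_sets["ibwe_and_foreign"]) == ibwe_count(worked_example, labels)
        assert result.table[0][1] == 0

    def test_empty_foreign_labels_degenerate(self, worked_example):
        labels = labelset("ALPHA", "BETA")
        ortho = {e: {e} for e in worked_example.enzymes}
        with pytest.raises(ValueError, match="degenerate"):
            cross_species_conservation(
                worked_example, ibwe_edges(worked_example, labels), ortho, labelset()
            )

    def test_enzyme_ortholog_map_from_gene_groups(self):
        table = pd.DataFrame(
            {
                "group_id": ["OG1", "OG1"],
                "species": ["arabidopsis", "populus"],
                "gene": ["g1", "p1"],
            }
        )
        native = {"E1": EnzymeGeneMap("E1", {"g1"}, set())}
        foreign = {"PE1": EnzymeGeneMap("PE1", {"p1"}, set())}
        assert build_enzyme_ortholog_map(table, native, foreign) == {"E1": {"PE1"}}

    def test_planted_conserved_networks_detected(self, small_bundle):
        from wgdnet.synthetic_data import generate_orthologs

        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SyntheticConfig(seed=900 + seed, n_enzymes=200, target_edges=520)
            net, _, emap = generate_network(cfg)
            labels, _ = plant_labels(net, cfg)
            orth = generate_orthologs(net, emap, labels, cfg)
            result, _ = cross_species_conservation(
                net,
                ibwe_edges(net, labels),
                orth.enzyme_ortholog_map,
                orth.foreign_labels,
            )
            hits += result.p_value < 0.05
        assert hits >= int(0.9 * n_seeds)
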