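"""Properties of the synthetic input generator."""

import json

import numpy as np
import pandas as pd
import pytest

from wgdnet.expression import aggregate_to_enzyme, spearman_with_fdr, summarize_genes
from wgdnet.network_build import build_enzyme_network, compute_degrees
from wgdnet.reaction_io import (
    CurrencyFilter,
    apply_currency_filter,
    format_reaction_line,
    parse_reaction_mapformula,
)
from wgdnet.synthetic_data import (
    SyntheticConfig,
    worked_example_network,
    generate_bundle,
    generate_expression,
    generate_network,
    generate_orthologs,
    generate_rates,
    generate_wgd_pairs,
    plant_labels,
    write_bundle,
)
from wgdnet.topology import degree_distribution, fit_power_law
from wgdnet.wgd import (
    cross_species_conservation,
    ibwe_edges,
    label_from_pairs,
    label_permutation_test,
)


class TestWorkedExampleNetwork:
    def test_structure(self, worked_example):
        assert worked_example.n_enzymes == 10
        recs = compute_degrees(worked_example)
        assert recs["ALPHA"].in_degree == 5
        assert recs["BETA"].out_degree == 3
        assert worked_example.bidirectional_count == 0


class TestNetworkGeneration:
    def test_exact_edge_and_bidirectional_counts(self, small_bundle):
        net = small_bundle.network
        cfg = small_bundle.config
        assert net.n_edges == cfg.target_edges
        assert net.bidirectional_count == round(
            cfg.bidirectional_fraction * cfg.target_edges
        )
        assert len(net.largest_component_nodes()) == cfg.n_enzymes

    def test_bit_reproducible_given_seed(self):
        cfg = SyntheticConfig(seed=21, n_enzymes=50, target_edges=120)
        a = generate_bundle(cfg)
        b = generate_bundle(cfg)
        assert {(e.source, e.target, e.kind) for e in a.network.edges} == {
            (e.source, e.target, e.kind) for e in b.network.edges
        }
        assert a.labels.labeled_enzymes == b.labels.labeled_enzymes
        assert (a.expression.values == b.expression.values).all()
        assert a.rates == b.rates

    @pytest.mark.parametrize("seed", range(20))
    def test_roundtrip_through_text_pipeline(self, seed):
        """Serialized reactions re-parsed, filtered and rebuilt give the
        exact same network."""
        cfg = SyntheticConfig(seed=seed, n_enzymes=60, target_edges=150)
        net, reactions, emap = generate_network(cfg)
        text = "\n".join(format_reaction_line(r) for r in reactions)
        rebuilt = build_enzyme_network(
            apply_currency_filter(
                parse_reaction_mapformula(text), CurrencyFilter.default()
            ),
            emap,
        )
        assert rebuilt.enzymes == net.enzymes
        assert {(e.source, e.target, e.kind) for e in rebuilt.edges} == {
            (e.source, e.target, e.kind) for e in net.edges
        }

    def test_no_bidirectional_when_fraction_zero(self):
        cfg = SyntheticConfig(
            seed=4, n_enzymes=50, target_edges=120, bidirectional_fraction=0.0
        )
        net, _, _ = generate_network(cfg)
        assert net.bidirectional_count == 0

    def test_out_degree_tail_exponent_recovered(self):
        cfg = SyntheticConfig(
            seed=7, n_enzymes=2000, target_edges=5800, bidirectional_fraction=0.0
        )
        net, _, _ = generate_network(cfg)
        fit = fit_power_law(degree_distribution(net, "out"))
        assert fit.exponent_t == pytest.approx(cfg.degree_exponent, abs=0.4)

    def test_infeasible_edge_target_rejected(self):
        with pytest.raises(ValueError):
            generate_network(SyntheticConfig(seed=0, n_enzymes=5, target_edges=100))


class TestLabelPlanting:
    def test_null_config_gives_null_zscores(self):
        zs = []
        for seed in range(10):
            cfg = SyntheticConfig(
                seed=1500 + seed, n_enzymes=150, target_edges=400,
                hub_bias=0.0, pair_bias=0.0,
            )
            net, _, _ = generate_network(cfg)
            labels, truth = plant_labels(net, cfg)
            assert len(labels.labeled_enzymes) == truth["budget"]
            zs.append(label_permutation_test(net, labels, n_reps=499, seed=seed).z_score)
        assert abs(np.mean(zs)) < 1.5  # centered null across seeds

    def test_strong_pair_bias_gives_large_z(self):
        hits = 0
        for seed in range(10):
            cfg = SyntheticConfig(seed=1600 + seed, pair_bias=0.8)
            net, _, _ = generate_network(cfg)
            labels, _ = plant_labels(net, cfg)
            z = label_permutation_test(net, labels, n_reps=999, seed=seed).z_score
            hits += z > 3
        assert hits >= 9

    def test_label_fraction_one_labels_every_eligible_enzyme(self):
        cfg = SyntheticConfig(
            seed=5, n_enzymes=40, target_edges=90, label_fraction=1.0, min_genes=2
        )
        net, _, _ = generate_network(cfg)
        labels, _ = plant_labels(net, cfg)
        assert labels.labeled_enzymes == frozenset(net.enzymes)

    def test_infeasible_budget_rejected(self):
        cfg = SyntheticConfig(
            seed=5, n_enzymes=40, target_edges=90, label_fraction=1.0,
            min_genes=1, max_genes=1,
        )
        net, _, _ = generate_network(cfg)
        with pytest.raises(ValueError, match="infeasible"):
            plant_labels(net, cfg)

    def test_pairs_recover_labels_through_the_pipeline(self, small_bundle):
        relabeled = label_from_pairs(small_bundle.wgd_pairs, small_bundle.enzyme_map)
        assert relabeled.labeled_enzymes == small_bundle.labels.labeled_enzymes


class TestExpressionAndRates:
    def test_positive_intensity_slope_recovered(self):
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            cfg = SyntheticConfig(seed=2000 + seed, n_enzymes=500, target_edges=1450)
            net, _, emap = generate_network(cfg)
            expr = generate_expression(net, emap, cfg)
            enz = aggregate_to_enzyme(summarize_genes(expr), emap)
            recs = compute_degrees(net)
            deg = pd.Series({e: r.in_degree + r.out_degree for e, r in recs.items()})
            (res,) = spearman_with_fdr(
                [(deg.loc[enz.index].values, enz["mean_max_intensity"].values, "d")]
            )
            hits += res.rho > 0 and res.q_value < 0.05
        assert hits >= int(0.95 * n_seeds)

    def test_zero_slope_gives_null_correlation(self):
        rhos = []
        for seed in range(10):
            from wgdnet.synthetic_data import ExpressionConfig

            cfg = SyntheticConfig(
                seed=2100 + seed, n_enzymes=300, target_edges=800,
                expression=ExpressionConfig(hub_intensity_slope=0.0),
            )
            net, _, emap = generate_network(cfg)
            expr = generate_expression(net, emap, cfg)
            enz = aggregate_to_enzyme(summarize_genes(expr), emap)
            recs = compute_degrees(net)
            deg = pd.Series({e: r.in_degree + r.out_degree for e, r in recs.items()})
            (res,) = spearman_with_fdr(
                [(deg.loc[enz.index].values, enz["mean_max_intensity"].values, "d")]
            )
            rhos.append(res.rho)
        assert abs(np.mean(rhos)) < 0.05

    def test_rates_decrease_with_degree(self, small_bundle):
        recs = compute_degrees(small_bundle.network)
        deg_by_gene = {}
        for enz, rec in small_bundle.enzyme_map.items():
            d = recs[enz].in_degree + recs[enz].out_degree
            for g in rec.gene_ids:
                deg_by_gene[g] = d
        genes = [r.gene for r in small_bundle.rates]
        ka = np.array([r.ka for r in small_bundle.rates])
        deg = np.array([deg_by_gene[g] for g in genes])
        from scipy import stats

        assert stats.spearmanr(deg, ka).statistic < 0

    def test_intensities_positive_and_shaped(self, small_bundle):
        expr = small_bundle.expression
        assert (expr.values > 0).all()
        assert expr.shape[1] == small_bundle.config.expression.n_conditions


class TestOrthologs:
    def test_full_conservation_makes_every_ibwe_conserved(self):
        cfg = SyntheticConfig(
            seed=31, n_enzymes=100, target_edges=260,
            foreign_conservation=1.0, foreign_background=0.0,
        )
        net, _, emap = generate_network(cfg)
        labels, _ = plant_labels(net, cfg)
        orth = generate_orthologs(net, emap, labels, cfg)
        ibwe = ibwe_edges(net, labels)
        _, edge_sets = cross_species_conservation(
            net, ibwe, orth.enzyme_ortholog_map, orth.foreign_labels
        )
        assert len(edge_sets["ibwe_and_foreign"]) == len(ibwe)

    def test_table_spans_both_species(self, small_bundle):
        table = small_bundle.orthologs.table
        assert set(table["species"]) == {"arabidopsis", "populus"}
        assert table.groupby("group_id")["species"].nunique().min() == 2


def test_write_bundle_emits_text_inputs(tmp_path):
    cfg = SyntheticConfig(seed=13, n_enzymes=40, target_edges=90)
    bundle = write_bundle(cfg, tmp_path)
    for name in (
        "reactions.lst",
        "enzyme_genes.tsv",
        "expression.tsv",
        "wgd_pairs.tsv",
        "rates.tsv",
        "orthologs.tsv",
        "ground_truth.json",
    ):
        assert (tmp_path / name).exists()
    truth = json.loads((tmp_path / "ground_truth.json").read_text())
    assert truth["n_edges"] == 90
    assert sorted(truth["labeled_enzymes"]) == sorted(bundle.labels.labeled_enzymes)
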