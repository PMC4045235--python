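import networkx as nx
import pandas as pd
import pytest

from interomix import (SimConfig, analyze, filter_min_peptides, simulate_all,
                       write_inputs)
from interomix.errors import ConfigError
from interomix.simulate import (simulate_expression, simulate_genesets,
                                simulate_ipms, simulate_ppi_db)

FAST = dict(n_genes=200, module_size=20, contaminant_pool=30, noise_preys_per_bait=20,
            n_distractor_de=10, n_gene_sets=15, set_size_range=(5, 12))


class TestConfig:
    def test_module_cannot_exceed_universe(self):
        with pytest.raises(ConfigError):
            SimConfig(n_genes=10, module_size=20, contaminant_pool=0)

    def test_pool_and_module_must_fit(self):
        with pytest.raises(ConfigError):
            SimConfig(n_genes=100, module_size=60, contaminant_pool=60)


class TestPpiDb:
    def test_single_gene_graph_has_no_edges(self):
        db, truth = simulate_ppi_db(SimConfig(n_genes=1, module_size=1,
                                              contaminant_pool=0))
        assert db.n_edges() == 0 and len(truth.genes) == 1

    def test_determinism(self):
        config = SimConfig(**FAST, rng_seed=11)
        a, _ = simulate_ppi_db(config)
        b, _ = simulate_ppi_db(config)
        assert sorted(a.graph.edges(data="kind")) == sorted(b.graph.edges(data="kind"))

    def test_planted_module_connected_and_contained(self):
        db, truth = simulate_ppi_db(SimConfig(**FAST, rng_seed=3))
        assert truth.module_genes <= db.nodes
        assert nx.is_connected(db.graph.subgraph(truth.module_genes))


class TestIpms:
    def test_noise_free_limit_recovers_module_exactly(self):
        config = SimConfig(n_genes=200, module_size=20, contaminant_pool=0,
                           bait_contaminant_rate=0.0, noise_preys_per_bait=0,
                           rng_seed=5)
        _, truth = simulate_ppi_db(config)
        bait_hits, _ = simulate_ipms(truth, config)
        for table in bait_hits.values():
            assert table.preys == truth.module_genes

    def test_single_peptide_noise_removed_by_filter(self):
        config = SimConfig(**FAST, noise_single_peptide_frac=1.0, rng_seed=5)
        _, truth = simulate_ppi_db(config)
        bait_hits, _ = simulate_ipms(truth, config)
        for bait, table in bait_hits.items():
            kept = filter_min_peptides(table, 2)
            assert not (kept & truth.bait_noise[bait])

    def test_contaminants_drawn_from_shared_pool(self):
        config = SimConfig(**FAST, rng_seed=9)
        _, truth = simulate_ppi_db(config)
        _, controls = simulate_ipms(truth, config)
        for table in controls:
            assert table.preys <= truth.contaminant_pool


class TestExpression:
    def test_noise_free_folds_are_exact(self):
        config = SimConfig(**FAST, noise_sd=0.0, n_unannotated_probes=0, rng_seed=2)
        _, truth = simulate_ppi_db(config)
        expr = simulate_expression(truth, config)
        from interomix import fold_change
        table = fold_change(expr)
        for probe, gene in expr.annotation.items():
            expected = truth.de_genes.get(gene, 1.0)
            assert table.loc[probe, "fold_change"] == pytest.approx(expected, rel=1e-9)

    def test_determinism(self):
        config = SimConfig(**FAST, rng_seed=13)
        _, truth1 = simulate_ppi_db(config)
        _, truth2 = simulate_ppi_db(config)
        a = simulate_expression(truth1, config)
        b = simulate_expression(truth2, config)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestGeneSets:
    def test_no_empty_sets_and_planted_recorded(self):
        config = SimConfig(**FAST, rng_seed=4)
        _, truth = simulate_ppi_db(config)
        coll = simulate_genesets(truth, config)
        assert all(gs.members for gs in coll)
        assert truth.planted_set_id in {gs.set_id for gs in coll}

    def test_determinism(self):
        config = SimConfig(**FAST, rng_seed=8)
        _, t1 = simulate_ppi_db(config)
        _, t2 = simulate_ppi_db(config)
        a = simulate_genesets(t1, config)
        b = simulate_genesets(t2, config)
        assert [(g.set_id, sorted(g.members)) for g in a] == \
               [(g.set_id, sorted(g.members)) for g in b]


def test_noise_free_end_to_end_is_exact():
    """With no contaminants and no noise every stage recovers the truth exactly."""
    config = SimConfig(n_genes=200, module_size=20, contaminant_pool=0,
                       bait_contaminant_rate=0.0, noise_preys_per_bait=0,
                       noise_sd=0.0, n_distractor_de=0, n_gene_sets=10,
                       set_size_range=(5, 12), rng_seed=6)
    d = simulate_all(config)
    r = analyze(d.bait_hits, d.control_hits, d.expression, d.db, d.collection)
    assert r.cleaned.common == d.truth.module_genes
    assert r.de_genes == set(d.truth.de_genes) == d.truth.module_genes
    module_edges = {frozenset(e) for e in
                    d.db.graph.subgraph(d.truth.module_genes).edges()}
    assert r.final_network.edge_set() == module_edges


def test_written_inputs_are_byte_identical_across_runs(tmp_path):
    config = SimConfig(**FAST, rng_seed=21)
    for sub in ("one", "two"):
        write_inputs(simulate_all(config), tmp_path / sub)
    for name in ["hits_BAIT1.tsv", "hits_CTRL1.tsv", "expression.tsv",
                 "annotation.tsv", "interactions.tsv", "genesets.gmt", "truth.json"]:
        assert (tmp_path / "one" / name).read_bytes() == \
               (tmp_path / "two" / name).read_bytes()
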