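"""Generators: determinism, planted structure, and the reference affinities."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from sgltnet import SyntheticConfig, gliflozin_affinity_table
from sgltnet import synthetic as syn
from sgltnet.ligands import read_binding_table


class TestConfig:
    def test_first_level_must_fit_in_gene_universe(self):
        with pytest.raises(ValueError, match="n_first_level"):
            SyntheticConfig(n_genes=10, n_first_level=10)

    def test_mediators_must_fit_in_first_level(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_first_level=1, planted_mediators=("A", "B"))


class TestInteractome:
    def test_target_degree_is_n_first_level(self, default_cfg, default_net):
        assert default_net.graph.degree(default_cfg.target_gene) == default_cfg.n_first_level

    def test_mediators_adjacent_to_target(self, default_cfg, default_net):
        for med in default_cfg.planted_mediators:
            assert default_net.graph.has_edge(med, default_cfg.target_gene)

    def test_connected_and_confidences_in_range(self, default_net):
        assert nx.is_connected(default_net.graph)
        confs = [c for _, _, c in default_net.edge_list()]
        assert all(0.15 <= c <= 0.999 for c in confs)

    def test_same_seed_same_edge_list(self, default_cfg):
        a = syn.generate_interactome(default_cfg).edge_list()
        b = syn.generate_interactome(default_cfg).edge_list()
        assert a == b

    def test_different_seed_different_graph(self, default_cfg, default_net):
        other = syn.generate_interactome(SyntheticConfig(seed=default_cfg.seed + 1))
        assert other.edge_list() != default_net.edge_list()


class TestKeyTermSets:
    def test_seven_sets_by_default(self, default_terms):
        assert len(default_terms) == 7
        assert set(default_terms) == set(syn.DEFAULT_KEY_TERMS)

    def test_members_in_network_and_target_excluded(self, default_cfg, default_net, default_terms):
        for genes in default_terms.values():
            assert genes <= default_net.nodes
            assert default_cfg.target_gene not in genes

    def test_mediator_adjacent_to_80pct_of_every_set(self, default_cfg, default_net, default_terms):
        g = default_net.graph
        for med in default_cfg.planted_mediators:
            for term, genes in default_terms.items():
                adj = sum(g.has_edge(med, x) for x in genes)
                assert adj >= 0.8 * len(genes) - 1, term  # mediator itself not self-adjacent

    def test_mediator_on_a_shortest_path_from_every_set(self, default_cfg, default_net, default_terms):
        """Planted-signal guarantee, checked by brute-force distances."""
        g = default_net.graph
        target = default_cfg.target_gene
        d_t = nx.single_source_shortest_path_length(g, target)
        for med in default_cfg.planted_mediators:
            d_m = nx.single_source_shortest_path_length(g, med)
            for term, genes in default_terms.items():
                best = min(d_t[x] for x in genes)
                on_shortest = any(
                    d_m.get(x, 99) + d_t[med] == d_t[x] == best for x in genes
                )
                assert on_shortest, term

    def test_empty_sets_when_genes_per_term_zero(self, default_net, caplog):
        cfg = SyntheticConfig(seed=1, genes_per_term=0)
        with caplog.at_level("WARNING"):
            sets = syn.generate_key_term_sets(cfg, default_net)
        assert all(len(g) == 0 for g in sets.values())
        assert "genes_per_term=0" in caplog.text


class TestBindingTable:
    def test_specific_ligand_hits_only_target(self, default_cfg, default_net):
        table = syn.generate_binding_table(default_cfg, default_net)
        spec = table[table["ligand_name"] == "speciflozin"]
        assert set(spec["gene_symbol"]) == {default_cfg.target_gene}

    def test_valueless_and_duplicate_rows_exist(self, default_cfg, default_net):
        table = syn.generate_binding_table(default_cfg, default_net)
        neither = table["ki_nm"].isna() & table["ic50_nm"].isna()
        assert neither.sum() >= 3
        assert table.duplicated(["ligand_id", "gene_symbol"]).any()

    def test_deterministic(self, default_cfg, default_net):
        a = syn.generate_binding_table(default_cfg, default_net)
        b = syn.generate_binding_table(default_cfg, default_net)
        pd.testing.assert_frame_equal(a, b)


class TestReferenceAffinities:
    """The printed gliflozin IC50 values toward the SGLT family."""

    @pytest.mark.parametrize(
        "ligand,gene,ic50",
        [
            ("dapagliflozin", "SGLT2", 0.49),
            ("dapagliflozin", "SGLT1", 3.2),
            ("dapagliflozin", "SGLT3", 1.35),
            ("dapagliflozin", "SGLT6", 380.0),
            ("empagliflozin", "SGLT2", 3.1),
            ("empagliflozin", "SGLT1", 3235.0),
        ],
    )
    def test_printed_ic50(self, ligand, gene, ic50):
        tbl = gliflozin_affinity_table()
        row = tbl[(tbl["ligand_id"] == ligand) & (tbl["gene_symbol"] == gene)]
        assert len(row) == 1
        assert row["ic50_nm"].iloc[0] == ic50

    def test_valueless_ligands_list_three_transporters(self):
        tbl = gliflozin_affinity_table()
        for lig in ("ertugliflozin", "sergliflozin-etabonate"):
            sub = tbl[tbl["ligand_id"] == lig]
            assert set(sub["gene_symbol"]) == {"SGLT1", "SGLT2", "SGLT3"}
            assert sub["ki_nm"].isna().all() and sub["ic50_nm"].isna().all()

    def test_roundtrip_through_binding_tsv(self, tmp_path):
        tbl = gliflozin_affinity_table()
        path = tmp_path / "affinities.tsv"
        syn.write_binding_tsv(tbl, path)
        back = read_binding_table(path)
        back["ki_nm"] = pd.to_numeric(back["ki_nm"].mask(back["ki_nm"] == "", np.nan))
        back["ic50_nm"] = pd.to_numeric(back["ic50_nm"].mask(back["ic50_nm"] == "", np.nan))
        pd.testing.assert_frame_equal(back, tbl)


class TestTissueMatrix:
    def test_values_on_confidence_scale(self, default_cfg, default_net):
        mat = syn.generate_tissue_matrix(default_cfg, default_net)
        assert float(mat.min().min()) >= 0.0
        assert float(mat.max().max()) <= 5.0

    def test_planted_high_and_low_tissues(self, default_cfg, default_net):
        mat = syn.generate_tissue_matrix(default_cfg, default_net)
        first = sorted(default_net.graph.neighbors(default_cfg.target_gene))
        high, low = mat.columns[0], mat.columns[1]
        assert mat.loc[default_cfg.target_gene, high] >= 4
        n_high = sum(mat.loc[g, high] >= 4 for g in first)
        assert n_high >= 0.9 * len(first)
        assert mat.loc[default_cfg.target_gene, low] < 1

    def test_deterministic(self, default_cfg, default_net):
        a = syn.generate_tissue_matrix(default_cfg, default_net)
        b = syn.generate_tissue_matrix(default_cfg, default_net)
        pd.testing.assert_frame_equal(a, b)


class TestAnnotationLibrary:
    def test_size_and_planted_set(self, default_cfg, default_net):
        lib = syn.generate_annotation_library(default_cfg, default_net)
        assert len(lib) >= 20
        first = set(default_net.graph.neighbors(default_cfg.target_gene))
        planted = lib["planted_first_level_disease"]
        assert len(planted & first) >= 0.5 * len(first)
        assert all(genes <= default_net.nodes for genes in lib.values())

    def test_deterministic(self, default_cfg, default_net):
        a = syn.generate_annotation_library(default_cfg, default_net)
        b = syn.generate_annotation_library(default_cfg, default_net)
        assert a == b


def test_write_inputs_emits_all_files(default_cfg, tmp_path):
    paths = syn.write_inputs(default_cfg, tmp_path)
    assert set(paths) == {
        "interactome", "key_terms", "binding", "tissue",
        "annotations", "alias_map", "reference_affinities",
    }
    for p in paths.values():
        assert p.is_file() and p.stat().st_size > 0
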