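"""Binding-table filtering, affinity aggregation and ligand rankings."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sgltnet import (
    build_profiles,
    dual_target_report,
    extract_neighborhood,
    gliflozin_affinity_table,
    load_and_filter,
    nontarget_drug_scan,
)
from sgltnet.ligands import profiles_table
from sgltnet.synthetic import generate_binding_table, write_binding_tsv

from conftest import make_network

HEADER = "ligand_id\tligand_name\tgene_symbol\tki_nm\tic50_nm\n"


def write_binding(path, rows):
    path.write_text(HEADER + "".join("\t".join(map(str, r)) + "\n" for r in rows))
    return path


@pytest.fixture(scope="module")
def sglt_nb():
    """Tiny transporter neighborhood: SGLT2 target, SGLT1 second level."""
    net = make_network(
        [("SGLT2", "M"), ("M", "SGLT1"), ("M", "SGLT3"), ("SGLT2", "X"), ("X", "SGLT6")]
    )
    return extract_neighborhood(net, "SGLT2")


@pytest.fixture(scope="module")
def fixture_profiles(sglt_nb, tmp_path_factory):
    path = tmp_path_factory.mktemp("fixture") / "affinities.tsv"
    write_binding_tsv(gliflozin_affinity_table(), path)
    return build_profiles(load_and_filter(path), sglt_nb)


class TestLoadAndFilter:
    def test_keeps_single_measure_drops_valueless_and_censored(self, tmp_path, caplog):
        p = write_binding(
            tmp_path / "b.tsv",
            [
                ("L1", "one", "A", 5.0, ""),
                ("L2", "two", "B", "", ""),
                ("L3", "three", "C", ">10000", ""),
                ("L4", "four", "D", "<1", 2.0),
            ],
        )
        with caplog.at_level("INFO"):
            out = load_and_filter(p)
        assert list(out["ligand_id"]) == ["L1", "L4"]
        assert np.isnan(out.loc[out["ligand_id"] == "L4", "ki_nm"]).all()
        assert "2 censored" in caplog.text

    def test_unrecognized_affinity_names_line(self, tmp_path):
        p = write_binding(tmp_path / "b.tsv", [("L1", "one", "A", "strong", "")])
        with pytest.raises(ValueError, match="line 2"):
            load_and_filter(p)

    def test_alias_map_applied(self, tmp_path):
        p = write_binding(tmp_path / "b.tsv", [("L1", "one", "SGLT2", 5.0, "")])
        out = load_and_filter(p, alias_map={"SGLT2": "SLC5A2"})
        assert list(out["gene_symbol"]) == ["SLC5A2"]


class TestBuildProfiles:
    def test_median_of_duplicates(self, sglt_nb, tmp_path):
        p = write_binding(
            tmp_path / "b.tsv",
            [("L1", "one", "SGLT2", 10.0, ""), ("L1", "one", "SGLT2", 30.0, "")],
        )
        prof = build_profiles(load_and_filter(p), sglt_nb)["L1"]
        assert prof.ki("SGLT2") == 20.0

    def test_aggregation_is_permutation_invariant(self, sglt_nb, tmp_path):
        rows = [("L1", "one", "SGLT2", v, "") for v in (3.0, 9.0, 27.0)]
        a = write_binding(tmp_path / "a.tsv", rows)
        b = write_binding(tmp_path / "b.tsv", rows[::-1])
        pa = build_profiles(load_and_filter(a), sglt_nb)["L1"]
        pb = build_profiles(load_and_filter(b), sglt_nb)["L1"]
        assert pa.affinities == pb.affinities

    def test_measures_ranked_independently(self, sglt_nb, tmp_path):
        p = write_binding(
            tmp_path / "b.tsv",
            [
                ("L1", "alpha", "SGLT2", 1.0, 50.0),
                ("L2", "beta", "SGLT2", 2.0, ""),
                ("L3", "gamma", "SGLT2", "", 5.0),
            ],
        )
        profs = build_profiles(load_and_filter(p), sglt_nb)
        assert (profs["L1"].specificity_rank_ki, profs["L2"].specificity_rank_ki) == (1, 2)
        assert profs["L3"].specificity_rank_ki is None
        assert (profs["L3"].specificity_rank_ic50, profs["L1"].specificity_rank_ic50) == (1, 2)

    def test_rank_invariant_under_monotone_transform(self, sglt_nb, default_cfg, default_net, tmp_path):
        nb = extract_neighborhood(default_net, default_cfg.target_gene)
        table = generate_binding_table(default_cfg, default_net)
        base = build_profiles(table.dropna(subset=["ki_nm", "ic50_nm"], how="all"), nb)
        warped = table.copy()
        warped["ki_nm"] = warped["ki_nm"] ** 1.7 * 3
        warped["ic50_nm"] = np.exp(np.log(warped["ic50_nm"]) * 2 + 1)
        after = build_profiles(warped.dropna(subset=["ki_nm", "ic50_nm"], how="all"), nb)
        for lig, prof in base.items():
            assert after[lig].specificity_rank_ki == prof.specificity_rank_ki
            assert after[lig].specificity_rank_ic50 == prof.specificity_rank_ic50


class TestReferenceFixture:
    def test_dapagliflozin_is_most_potent_target_inhibitor(self, fixture_profiles):
        dapa = fixture_profiles["dapagliflozin"]
        assert dapa.specificity_rank_ic50 == 1
        assert dapa.ic50("SGLT2") == 0.49

    def test_valueless_ligands_filtered_out(self, fixture_profiles):
        assert set(fixture_profiles) == {"dapagliflozin", "empagliflozin"}

    def test_dual_target_ordering_and_values(self, fixture_profiles):
        report = dual_target_report(fixture_profiles, "SGLT2", "SGLT1")
        assert list(report["ligand"]) == ["dapagliflozin", "empagliflozin"]
        assert list(report["ic50_SGLT1"]) == [3.2, 3235.0]
        assert report["ratio_b_over_a"].iloc[0] == pytest.approx(3.2 / 0.49)

    def test_network_target_counts(self, fixture_profiles, sglt_nb):
        # SGLT2 (target), SGLT1/SGLT3/SGLT6 (second level) are all in-network
        assert fixture_profiles["dapagliflozin"].n_network_targets == 4
        assert fixture_profiles["empagliflozin"].n_network_targets == 2


class TestDualTargetReport:
    def test_no_dual_binders_empty(self, sglt_nb, tmp_path):
        p = write_binding(tmp_path / "b.tsv", [("L1", "one", "SGLT2", "", 1.0)])
        profs = build_profiles(load_and_filter(p), sglt_nb)
        assert dual_target_report(profs, "SGLT2", "SGLT1").empty

    def test_equal_potency_breaks_alphabetically(self, sglt_nb, tmp_path):
        rows = [
            ("L1", "zeta", "SGLT2", "", 1.0), ("L1", "zeta", "SGLT1", "", 5.0),
            ("L2", "alpha", "SGLT2", "", 1.0), ("L2", "alpha", "SGLT1", "", 5.0),
        ]
        profs = build_profiles(load_and_filter(write_binding(tmp_path / "b.tsv", rows)), sglt_nb)
        assert list(dual_target_report(profs, "SGLT2", "SGLT1")["ligand"]) == ["alpha", "zeta"]


class TestNontargetDrugScan:
    def test_network_membership_and_level_flags(self, sglt_nb, tmp_path):
        rows = [
            ("L1", "one", "M", 1.0, ""),       # first level
            ("L1", "one", "OUTSIDE", 1.0, ""),  # not in network
        ]
        profs = build_profiles(load_and_filter(write_binding(tmp_path / "b.tsv", rows)), sglt_nb)
        scan = nontarget_drug_scan(profs, sglt_nb)
        assert len(scan) == 1
        row = scan.iloc[0]
        assert row["n_network_genes"] == 1
        assert row["first_level_genes"] == "M"
        assert not row["hits_target"]

    def test_planted_promiscuous_ligand_hits_four_network_genes(
        self, default_cfg, default_net
    ):
        nb = extract_neighborhood(default_net, default_cfg.target_gene)
        table = generate_binding_table(default_cfg, default_net)
        profs = build_profiles(table.dropna(subset=["ki_nm", "ic50_nm"], how="all"), nb)
        promi = profs["LIG0002"]
        # oracle: direct set intersection
        assert promi.genes & nb.members == promi.genes
        scan = nontarget_drug_scan(profs, nb)
        assert int(scan.set_index("ligand_id").loc["LIG0002", "n_network_genes"]) == 4

    def test_planted_specific_ligand_counts_one_network_target(
        self, default_cfg, default_net
    ):
        nb = extract_neighborhood(default_net, default_cfg.target_gene)
        table = generate_binding_table(default_cfg, default_net)
        profs = build_profiles(table.dropna(subset=["ki_nm", "ic50_nm"], how="all"), nb)
        assert profs["LIG0001"].n_network_targets == 1


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(min_value=0.01, max_value=1e6), min_size=1, max_size=8, unique=True))
def test_profiles_table_lists_every_gene_once(values):
    """Long-form output has one row per ligand-gene pair, whatever the values."""
    nb = extract_neighborhood(make_network([("T", "A")]), "T")
    records = pd.DataFrame(
        {
            "ligand_id": ["L1"] * len(values),
            "ligand_name": ["one"] * len(values),
            "gene_symbol": [f"G{i}" for i in range(len(values))],
            "ki_nm": values,
            "ic50_nm": [np.nan] * len(values),
        }
    )
    profs = build_profiles(records, nb)
    out = profiles_table(profs, nb)
    assert len(out) == len(values)
    assert out["gene"].is_unique
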