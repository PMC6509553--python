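"""Grafting onto a backbone and BLADJ dating."""

import numpy as np
import pandas as pd
import pytest

import phylostruct as ps
from phylostruct.errors import AgeConflictError, UngraftableSpeciesError
from phylostruct.tree import _node_name

from conftest import random_undated_tree

BACKBONE = "((Potentilla,Fragaria)Rosaceae,(Carex)Cyperaceae);"


@pytest.fixture
def taxonomy():
    return ps.TaxonomyTable(
        pd.DataFrame(
            {
                "species": [
                    "Potentilla_anserina",
                    "Potentilla_bifurca",
                    "Potentilla_fruticosa",
                    "Fragaria_vesca",
                    "Rosa_rugosa",
                    "Carex_parva",
                    "Stipa_capillata",
                ],
                "genus": [
                    "Potentilla",
                    "Potentilla",
                    "Potentilla",
                    "Fragaria",
                    "Rosa",
                    "Carex",
                    "Stipa",
                ],
                "family": [
                    "Rosaceae",
                    "Rosaceae",
                    "Rosaceae",
                    "Rosaceae",
                    "Rosaceae",
                    "Cyperaceae",
                    "Poaceae",
                ],
            }
        )
    )


class TestGraft:
    def test_congeners_form_polytomy_at_genus_node(self, taxonomy):
        tree = ps.graft_supertree(
            ps.parse_newick(BACKBONE),
            taxonomy,
            ["Potentilla_anserina", "Potentilla_bifurca", "Potentilla_fruticosa"],
        )
        genus = tree.node_by_name("Potentilla")
        kids = {_node_name(c) for c in genus.child_nodes()}
        assert kids == {
            "Potentilla_anserina",
            "Potentilla_bifurca",
            "Potentilla_fruticosa",
        }

    def test_missing_genus_created_under_family(self, taxonomy):
        tree = ps.graft_supertree(
            ps.parse_newick(BACKBONE), taxonomy, ["Rosa_rugosa", "Fragaria_vesca"]
        )
        rosa = tree.node_by_name("Rosa")
        assert rosa is not None
        assert _node_name(rosa.parent_node) == "Rosaceae"
        assert {_node_name(c) for c in rosa.child_nodes()} == {"Rosa_rugosa"}

    def test_missing_family_reported(self, taxonomy):
        with pytest.raises(UngraftableSpeciesError, match="Stipa_capillata"):
            ps.graft_supertree(
                ps.parse_newick(BACKBONE),
                taxonomy,
                ["Carex_parva", "Stipa_capillata"],
            )

    def test_drop_flag_warns_and_prunes(self, taxonomy):
        with pytest.warns(UserWarning, match="Stipa_capillata"):
            tree = ps.graft_supertree(
                ps.parse_newick(BACKBONE),
                taxonomy,
                ["Carex_parva", "Stipa_capillata", "Fragaria_vesca"],
                drop_ungraftable=True,
            )
        assert sorted(tree.tip_names) == ["Carex_parva", "Fragaria_vesca"]

    def test_order_independent(self, taxonomy):
        species = [
            "Potentilla_anserina",
            "Fragaria_vesca",
            "Carex_parva",
            "Rosa_rugosa",
        ]
        a = ps.graft_supertree(ps.parse_newick(BACKBONE), taxonomy, species)
        b = ps.graft_supertree(
            ps.parse_newick(BACKBONE), taxonomy, species[::-1]
        )
        assert a.to_newick() == b.to_newick()

    def test_result_pruned_to_requested_species(self, taxonomy):
        tree = ps.graft_supertree(
            ps.parse_newick(BACKBONE), taxonomy, ["Carex_parva"]
        )
        assert tree.tip_names == ["Carex_parva"]

    def test_name_matching_tolerates_case_and_spaces(self, taxonomy):
        tree = ps.graft_supertree(
            ps.parse_newick(BACKBONE), taxonomy, ["potentilla anserina"]
        )
        assert tree.n_tips == 1


class TestBladj:
    def test_single_undated_node_midpoint(self):
        dated = ps.bladj(ps.parse_newick("((T)x)root;"), {"root": 10})
        assert dated.to_newick() == "((T:5)x:5)root;"

    def test_two_undated_nodes_even_spacing(self):
        dated = ps.bladj(ps.parse_newick("(((T)y)x)root;"), {"root": 10})
        x = dated.node_by_name("x")
        y = dated.node_by_name("y")
        assert x.age == pytest.approx(10 * 2 / 3, abs=1e-6)
        assert y.age == pytest.approx(10 / 3, abs=1e-6)
        assert dated.total_branch_length() == pytest.approx(10.0)

    def test_fully_dated_tree_idempotent(self):
        ages = {"root": 10, "n": 4}
        tree = ps.parse_newick("((A,B)n,C)root;")
        once = ps.bladj(tree, ages)
        twice = ps.bladj(once, ages)
        assert once.to_newick() == twice.to_newick()
        assert once.node_by_name("n").age == 4

    def test_fixed_ages_never_changed(self):
        dated = ps.bladj(
            ps.parse_newick("(((A,B)g1,C)f1,(D,E)f2)root;"),
            {"root": 100, "f1": 60, "g1": 20, "f2": 45},
        )
        assert dated.node_by_name("g1").age == 20
        assert dated.node_by_name("f1").age == 60
        assert dated.is_ultrametric(1e-9)

    def test_root_missing_from_table_errors(self):
        with pytest.raises(ValueError, match="root"):
            ps.bladj(ps.parse_newick("((A,B)n,C)top;"), {"n": 4})

    def test_conflicting_table_names_the_pair(self):
        with pytest.raises(AgeConflictError, match="n.*root|root.*n"):
            ps.bladj(ps.parse_newick("((A,B)n,C)root;"), {"root": 10, "n": 50})

    def test_random_trees_become_ultrametric(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            tree, ages, root_label = random_undated_tree(
                rng, int(rng.integers(3, 12))
            )
            names = [n for n in ages if n != root_label]
            keep = {root_label: ages[root_label]}
            for name in names:
                if rng.random() < 0.4:
                    keep[name] = ages[name]
            dated = ps.bladj(tree, keep)
            assert dated.is_ultrametric(1e-9)
            assert dated.root_age() == pytest.approx(ages[root_label])


class TestTaxonomyIO:
    def test_tab_and_slash_formats(self, tmp_path):
        tab = tmp_path / "tax.tsv"
        tab.write_text(
            "species\tgenus\tfamily\nPoa_annua\tPoa\tPoaceae\n"
        )
        slash = tmp_path / "tax.txt"
        slash.write_text("poaceae/poa/poa_annua\n")
        a = ps.TaxonomyTable.from_file(tab)
        b = ps.TaxonomyTable.from_file(slash)
        assert a.lookup("Poa_annua") == ("Poa", "Poaceae")
        assert b.lookup("Poa annua") == ("poa", "poaceae")

    def test_duplicate_species_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ps.TaxonomyTable(
                pd.DataFrame(
                    {
                        "species": ["A_b", "A b"],
                        "genus": ["A", "A"],
                        "family": ["F", "F"],
                    }
                )
            )

    def test_ages_file_roundtrip(self, tmp_path):
        path = tmp_path / "ages.tsv"
        ps.AgeTable({"root": 100, "Rosaceae": 60}).write(path)
        again = ps.AgeTable.from_file(path)
        assert again["root"] == 100
        assert again["rosaceae"] == 60


def test_total_branch_length_matches_toy_and_reordering(toy_tree):
    assert ps.total_branch_length(toy_tree) == pytest.approx(5.0)
    reordered = ps.parse_newick("(C:2,(B:1,A:1):1);")
    assert ps.total_branch_length(reordered) == pytest.approx(5.0)
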