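"""Germplasm typing, pedigree integrity, samples, collections, passports."""

import random

import pytest

from chadolite.errors import ConflictError, TermLookupError, ValidationError
from chadolite.germplasm import (
    GermplasmInput,
    PassportRecord,
    add_accession,
    add_germplasm,
    add_pedigree_edge,
    derive_clone,
    derive_sample,
    record_passport,
    register_collection,
)
from chadolite.query import pedigree_tree

ORG = "Prunus persica"


def _add(store, name, gtype="cultivar"):
    return add_germplasm(store, GermplasmInput(name, ORG, type=gtype))


class TestGermplasm:
    def test_types_from_allowed_set(self, bare_store):
        _add(bare_store, "Elberta")
        _add(bare_store, "TxE_F2", "population")
        types = {
            r[0]
            for r in bare_store.execute(
                "SELECT t.name FROM stock JOIN cvterm t ON t.cvterm_id=stock.type_id"
            )
        }
        assert types == {"cultivar", "population"}

    def test_disallowed_type_rejected(self, bare_store):
        with pytest.raises(TermLookupError):
            _add(bare_store, "X", "landrace")

    def test_duplicate_conflicts(self, bare_store):
        _add(bare_store, "Elberta")
        with pytest.raises(ConflictError):
            _add(bare_store, "Elberta")


class TestPedigree:
    def test_two_parents_become_ancestors(self, bare_store):
        for n in ("M", "F", "C"):
            _add(bare_store, n)
        add_pedigree_edge(bare_store, "C", "M", "maternal")
        add_pedigree_edge(bare_store, "C", "F", "paternal")
        ancestors = {n["stock"] for n in pedigree_tree(bare_store, "C")}
        assert ancestors == {"M", "F"}

    def test_edge_direction_parent_subject(self, bare_store):
        _add(bare_store, "Elberta")
        _add(bare_store, "Red Elberta")
        add_pedigree_edge(bare_store, "Red Elberta", "Elberta", "mutational")
        row = bare_store.row(
            "SELECT su.uniquename AS parent, po.uniquename AS child, "
            "t.name AS term FROM stock_relationship sr "
            "JOIN stock su ON su.stock_id = sr.subject_id "
            "JOIN stock po ON po.stock_id = sr.object_id "
            "JOIN cvterm t ON t.cvterm_id = sr.type_id"
        )
        assert (row["parent"], row["child"], row["term"]) == (
            "Elberta",
            "Red Elberta",
            "mutational_parent_of",
        )

    def test_cycle_rejected_with_path(self, bare_store):
        for n in ("A", "B", "C"):
            _add(bare_store, n)
        add_pedigree_edge(bare_store, "B", "A", "maternal")  # A -> B
        add_pedigree_edge(bare_store, "C", "B", "maternal")  # B -> C
        with pytest.raises(ValidationError, match="cycle"):
            add_pedigree_edge(bare_store, "A", "C", "maternal")

    def test_second_mother_conflicts(self, bare_store):
        for n in ("M1", "M2", "C"):
            _add(bare_store, n)
        add_pedigree_edge(bare_store, "C", "M1", "maternal")
        with pytest.raises(ConflictError):
            add_pedigree_edge(bare_store, "C", "M2", "maternal")

    def test_random_dag_stays_acyclic(self, bare_store):
        """Parents drawn only from earlier stocks can always be added."""
        rng = random.Random(7)
        names = [f"S{i}" for i in range(60)]
        for n in names:
            _add(bare_store, n)
        for i in range(2, 60):
            mother, father = rng.sample(names[:i], 2) if i > 1 else (names[0], None)
            add_pedigree_edge(bare_store, names[i], mother, "maternal")
            if father:
                add_pedigree_edge(bare_store, names[i], father, "paternal")
        assert bare_store.check_integrity().by_kind("pedigree_cycle") == []


class TestSamplesClones:
    def test_sample_of_edge(self, bare_store):
        _add(bare_store, "Elberta")
        derive_sample(bare_store, "Elberta", "Elberta_T3_H2")
        row = bare_store.row(
            "SELECT su.uniquename AS s, t.name AS term, st.name AS stype "
            "FROM stock_relationship sr "
            "JOIN stock su ON su.stock_id=sr.subject_id "
            "JOIN cvterm t ON t.cvterm_id=sr.type_id "
            "JOIN cvterm st ON st.cvterm_id=su.type_id"
        )
        assert (row["s"], row["term"], row["stype"]) == (
            "Elberta_T3_H2",
            "sample_of",
            "sample",
        )

    def test_clone_and_unknown_germplasm(self, bare_store):
        _add(bare_store, "Elberta")
        derive_clone(bare_store, "Elberta", "Elberta_c1")
        assert bare_store.stock_id("Elberta_c1", "clone")
        with pytest.raises(ValidationError):
            derive_sample(bare_store, "Ghost", "G_S1")
        with pytest.raises(ConflictError):
            derive_clone(bare_store, "Elberta", "Elberta_c1")


class TestCollections:
    def test_accession_names_stock(self, bare_store):
        _add(bare_store, "W1", "wild/unimproved")
        register_collection(
            bare_store, "USDA-COT", "USDA Cotton Collection",
            url="https://example.org", description="stock center",
        )
        add_accession(bare_store, "USDA-COT", "W1", "PI 528201")
        assert bare_store.scalar(
            "SELECT name FROM stock WHERE uniquename='W1'"
        ) == "PI 528201"
        assert bare_store.scalar(
            "SELECT accession FROM dbxref JOIN db USING (db_id) "
            "WHERE db.name='USDA-COT'"
        ) == "PI 528201"
        assert bare_store.scalar(
            "SELECT url FROM db WHERE name='USDA-COT'"
        ) == "https://example.org"

    def test_duplicate_code_and_accession_conflict(self, bare_store):
        _add(bare_store, "W1", "wild/unimproved")
        register_collection(bare_store, "C1", "c")
        with pytest.raises(ConflictError):
            register_collection(bare_store, "C1", "c again")
        add_accession(bare_store, "C1", "W1", "ACC1")
        with pytest.raises(ConflictError):
            add_accession(bare_store, "C1", "W1", "ACC1")


class TestPassport:
    def test_geolocation_and_props(self, bare_store):
        _add(bare_store, "W1", "wild/unimproved")
        record_passport(
            bare_store,
            PassportRecord(
                stock="W1",
                location="Oaxaca, MX",
                props={"sample_size": "12"},
                collector="Collector One",
            ),
        )
        assert bare_store.count("nd_experiment") == 1
        assert bare_store.count("nd_geolocation") == 1
        assert bare_store.count("nd_experimentprop") == 1
        assert bare_store.count("nd_experiment_contact") == 1

    def test_multiple_passports_allowed_no_collector_no_contact(self, bare_store):
        _add(bare_store, "W1", "wild/unimproved")
        record_passport(bare_store, PassportRecord(stock="W1", location="site A"))
        record_passport(bare_store, PassportRecord(stock="W1", location="site B"))
        assert bare_store.count("nd_experiment") == 2
        assert bare_store.count("nd_experiment_contact") == 0

    def test_unknown_stock_rejected(self, bare_store):
        with pytest.raises(ValidationError):
            record_passport(bare_store, PassportRecord(stock="Ghost"))
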