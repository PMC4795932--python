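"""Canonical genotype strings, ND-pattern measurements, dual coding,
haplotype blocks and genotype->phenotype statements."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from chadolite.errors import ConflictError, ValidationError
from chadolite.genetic import MarkerInput, add_marker
from chadolite.germplasm import GermplasmInput, add_germplasm, derive_sample
from chadolite.phenogeno import (
    GenotypeCall,
    PhenotypeMeasurement,
    canonical_description,
    define_descriptor,
    define_haplotype_block,
    record_dual_coded,
    record_genotype,
    record_haplotype_effect,
    record_haplotype_genotype,
    record_phenotype,
)

ORG = "Prunus persica"


class TestCanonicalDescription:
    @pytest.mark.parametrize(
        "alleles,expected",
        [
            (["T", "A"], "A|T"),
            (["A", "A"], "A|A"),  # copy number preserved
            (["102", "98", "98"], "102|98|98"),  # byte order: '1' < '9'
        ],
    )
    def test_frozen_examples(self, alleles, expected):
        assert canonical_description(alleles) == expected

    def test_all_permutations_agree(self):
        results = {
            canonical_description(list(p))
            for p in itertools.permutations(["102", "98", "98"])
        }
        assert results == {"102|98|98"}

    @given(
        st.lists(
            st.text(
                alphabet=st.characters(
                    min_codepoint=33, max_codepoint=126, exclude_characters="|"
                ),
                min_size=1,
                max_size=4,
            ),
            min_size=1,
            max_size=6,
        )
    )
    @settings(max_examples=300, deadline=None)
    def test_idempotent_and_permutation_invariant(self, alleles):
        canonical = canonical_description(alleles)
        assert canonical_description(canonical.split("|")) == canonical
        assert canonical_description(list(reversed(alleles))) == canonical

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            canonical_description([])


@pytest.fixture()
def nd_store(bare_store):
    bare_store.ensure_project("EVAL")
    add_germplasm(bare_store, GermplasmInput("Elberta", ORG))
    derive_sample(bare_store, "Elberta", "S1")
    derive_sample(bare_store, "Elberta", "S2")
    define_descriptor(
        bare_store,
        "EVAL",
        "fruit_color",
        codes={str(c): f"level {c}" for c in range(1, 6)},
    )
    define_descriptor(bare_store, "EVAL", "fruit_weight")
    return bare_store


class TestPhenotyping:
    def test_uniquename_is_descriptor_underscore_value(self, nd_store):
        record_phenotype(
            nd_store, PhenotypeMeasurement("EVAL", "S1", "fruit_color", "4")
        )
        assert nd_store.scalar("SELECT uniquename FROM phenotype") == "fruit_color_4"

    def test_shared_value_upserts_one_phenotype_two_experiments(self, nd_store):
        for stock in ("S1", "S2"):
            record_phenotype(
                nd_store, PhenotypeMeasurement("EVAL", stock, "fruit_color", "4")
            )
        assert nd_store.count("phenotype") == 1
        assert nd_store.count("nd_experiment") == 2

    def test_out_of_range_code_lists_allowed(self, nd_store):
        with pytest.raises(ValidationError, match=r"\['1', '2', '3', '4', '5'\]"):
            record_phenotype(
                nd_store, PhenotypeMeasurement("EVAL", "S1", "fruit_color", "7")
            )

    def test_quantitative_value_free(self, nd_store):
        record_phenotype(
            nd_store,
            PhenotypeMeasurement(
                "EVAL", "S1", "fruit_weight", "132.5",
                stats={"standard_deviation": "4.1"},
            ),
        )
        assert nd_store.count("nd_experimentprop") == 1


class TestDualCoding:
    @pytest.fixture()
    def dual_store(self, nd_store):
        define_descriptor(
            nd_store,
            "EVAL",
            "fruit_color_std",
            codes={str(c): f"std {c}" for c in range(1, 11)},
        )
        return nd_store

    def test_two_phenotypes_two_experiments_same_stock(self, dual_store):
        record_dual_coded(
            dual_store,
            PhenotypeMeasurement("EVAL", "S1", "fruit_color", "3"),
            standard="fruit_color_std",
            code_map={str(c): str(2 * c) for c in range(1, 6)},
        )
        names = sorted(
            r[0] for r in dual_store.execute("SELECT uniquename FROM phenotype")
        )
        assert names == ["fruit_color_3", "fruit_color_std_6"]
        assert dual_store.count("nd_experiment") == 2
        stocks = {
            r[0]
            for r in dual_store.execute(
                "SELECT s.uniquename FROM nd_experiment_stock "
                "JOIN stock s USING (stock_id)"
            )
        }
        assert stocks == {"S1"}

    def test_identity_map_gives_equal_values(self, dual_store):
        record_dual_coded(
            dual_store,
            PhenotypeMeasurement("EVAL", "S1", "fruit_color", "2"),
            standard="fruit_color",
            code_map={str(c): str(c) for c in range(1, 6)},
        )
        assert dual_store.count("phenotype") == 1  # same uniquename upserted
        assert dual_store.count("nd_experiment") == 2

    def test_missing_code_mapping_rejected(self, dual_store):
        with pytest.raises(ValidationError, match="'5'"):
            record_dual_coded(
                dual_store,
                PhenotypeMeasurement("EVAL", "S1", "fruit_color", "5"),
                standard="fruit_color_std",
                code_map={"1": "2"},
            )


@pytest.fixture()
def geno_store(nd_store):
    for name in ("SSR_Ga01", "M2", "M3"):
        add_marker(
            nd_store,
            MarkerInput(name=name, organism=ORG, marker_type="SNP",
                        alleles=["A", "T"]),
        )
    return nd_store


class TestGenotyping:
    def test_uniquename_marker_underscore_description(self, geno_store):
        record_genotype(
            geno_store, GenotypeCall("EVAL", "Elberta", "SSR_Ga01", ["T", "A"])
        )
        assert (
            geno_store.scalar("SELECT uniquename FROM genotype")
            == "SSR_Ga01_A|T"
        )

    def test_shared_call_upserts(self, geno_store):
        for stock in ("S1", "S2", "Elberta"):
            record_genotype(
                geno_store, GenotypeCall("EVAL", stock, "SSR_Ga01", ["A", "T"])
            )
        assert geno_store.count("genotype") == 1
        assert geno_store.count("nd_experiment") == 3

    def test_empty_alleles_rejected(self, geno_store):
        with pytest.raises(ValidationError):
            record_genotype(geno_store, GenotypeCall("EVAL", "S1", "SSR_Ga01", []))

    def test_unknown_marker_rejected(self, geno_store):
        with pytest.raises(ValidationError):
            record_genotype(geno_store, GenotypeCall("EVAL", "S1", "nope", ["A"]))


class TestHaplotypes:
    def test_block_contains_ranked_members(self, geno_store):
        block = define_haplotype_block(
            geno_store, "Hap-G1", ["SSR_Ga01", "M2", "M3"]
        )
        edges = geno_store.execute(
            "SELECT o.uniquename AS marker, fr.rank AS rank "
            "FROM feature_relationship fr "
            "JOIN cvterm t ON t.cvterm_id=fr.type_id AND t.name='contains' "
            "JOIN feature o ON o.feature_id=fr.object_id "
            "WHERE fr.subject_id=? ORDER BY fr.rank",
            (block,),
        ).fetchall()
        assert [(e["marker"], e["rank"]) for e in edges] == [
            ("SSR_Ga01", 0), ("M2", 1), ("M3", 2),
        ]

    def test_single_marker_block_rejected(self, geno_store):
        with pytest.raises(ValidationError):
            define_haplotype_block(geno_store, "Hap-X", ["M2"])

    def test_haplotype_genotype_verbatim(self, geno_store):
        define_haplotype_block(geno_store, "Hap-G1", ["SSR_Ga01", "M2", "M3"])
        record_haplotype_genotype(geno_store, "EVAL", "Elberta", "Hap-G1", "A-C-T")
        assert geno_store.scalar(
            "SELECT uniquename FROM genotype"
        ) == "Hap-G1_A-C-T"
        assert geno_store.check_integrity().ok

    def test_effect_statement_and_duplicate(self, geno_store):
        define_haplotype_block(geno_store, "Hap-G1", ["SSR_Ga01", "M2"])
        record_haplotype_genotype(geno_store, "EVAL", "Elberta", "Hap-G1", "A-C")
        record_haplotype_effect(
            geno_store, "Hap-G1_A-C", "fruit_weight", "+12.5", project="EVAL"
        )
        assert geno_store.count("phenstatement") == 1
        assert geno_store.scalar(
            "SELECT uniquename FROM phenotype"
        ) == "fruit_weight_+12.5"
        with pytest.raises(ConflictError):
            record_haplotype_effect(
                geno_store, "Hap-G1_A-C", "fruit_weight", "+12.5", project="EVAL"
            )

    def test_unknown_genotype_or_descriptor_rejected(self, geno_store):
        with pytest.raises(ValidationError):
            record_haplotype_effect(
                geno_store, "ghost", "fruit_weight", "1", project="EVAL"
            )
        define_haplotype_block(geno_store, "H", ["M2", "M3"])
        record_haplotype_genotype(geno_store, "EVAL", "Elberta", "H", "A-A")
        with pytest.raises(ValidationError):
            record_haplotype_effect(
                geno_store, "H_A-A", "no_such_descriptor", "1", project="EVAL"
            )


class TestStoreWideConventions:
    def test_uniquename_audits_hold_on_fixture(self, session_store):
        store, _ = session_store
        for row in store.execute(
            "SELECT p.uniquename AS un, t.name AS attr, p.value AS value "
            "FROM phenotype p JOIN cvterm t ON t.cvterm_id=p.attr_id"
        ):
            assert row["un"] == f"{row['attr']}_{row['value']}"
        for row in store.execute(
            "SELECT g.uniquename AS gun, g.description AS des, "
            "f.uniquename AS fun FROM genotype g "
            "JOIN feature_genotype USING (genotype_id) "
            "JOIN feature f USING (feature_id)"
        ):
            assert row["gun"] == f"{row['fun']}_{row['des']}"

    def test_measurement_conservation(self, session_store, fixture_tree):
        """One 'phenotyping' experiment per input measurement row."""
        store, _ = session_store
        d, _ = fixture_tree
        n_rows = len((d / "phenotypes.tsv").read_text().splitlines()) - 1
        n_exp = store.scalar(
            "SELECT COUNT(*) FROM nd_experiment e JOIN cvterm t "
            "ON t.cvterm_id=e.type_id WHERE t.name='phenotyping'"
        )
        assert n_exp == n_rows
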