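"""Marker/map/QTL/MTL storage conventions and the SNP residue encoder."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from chadolite.errors import (
    ConflictError,
    NotEncodableError,
    TermLookupError,
    ValidationError,
)
from chadolite.genetic import (
    MapInput,
    MarkerInput,
    MtlInput,
    PlacementInput,
    QtlInput,
    add_map,
    add_marker,
    add_mtl,
    add_qtl,
    place_on_map,
    synthesize_snp_residues,
)
from chadolite.germplasm import GermplasmInput, add_germplasm

ORG = "Prunus persica"

# independent statement of the published ambiguity-code table
IUPAC_TABLE = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "AG": "R", "CT": "Y", "CG": "S", "AT": "W", "GT": "K", "AC": "M",
    "CGT": "B", "AGT": "D", "ACT": "H", "ACG": "V", "ACGT": "N",
}


class TestSnpResidues:
    @pytest.mark.parametrize(
        "alleles,f5,f3,expected",
        [
            (["A", "T"], "ACGT", "GGCC", "ACGTWGGCC"),
            (["C"], "", "", "C"),
            (["A", "C", "G", "T"], "AA", "TT", "AANTT"),
        ],
    )
    def test_flank_concatenation(self, alleles, f5, f3, expected):
        assert synthesize_snp_residues(alleles, f5, f3) == expected

    def test_full_iupac_table(self):
        for bases, code in IUPAC_TABLE.items():
            assert synthesize_snp_residues(list(bases)) == code

    @given(
        subset=st.sets(st.sampled_from("ACGT"), min_size=1, max_size=4),
        dup=st.integers(min_value=1, max_value=3),
        seed=st.randoms(use_true_random=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_order_and_duplication_invariant(self, subset, dup, seed):
        alleles = sorted(subset) * dup
        seed.shuffle(alleles)
        assert synthesize_snp_residues(alleles) == IUPAC_TABLE[
            "".join(sorted(subset))
        ]

    @pytest.mark.parametrize("alleles", [["A", "X"], ["AT"], [], ["a "]])
    def test_non_single_base_rejected(self, alleles):
        if alleles == ["a "]:  # whitespace-trimmed, case-folded: encodable
            assert synthesize_snp_residues(alleles) == "A"
            return
        with pytest.raises(NotEncodableError):
            synthesize_snp_residues(alleles)


class TestMarkers:
    def test_primers_named_and_adjacent(self, bare_store):
        add_marker(
            bare_store,
            MarkerInput(
                name="BPPCT001",
                organism=ORG,
                marker_type="SSR",
                primers=[
                    {"label": "F", "sequence": "ACGTACGT"},
                    {"label": "R", "sequence": "TTTTCCCC"},
                ],
                props={"screening_method": "2% agarose"},
            ),
        )
        primers = sorted(
            r[0]
            for r in bare_store.execute(
                "SELECT f.uniquename FROM feature f "
                "JOIN cvterm t ON t.cvterm_id=f.type_id WHERE t.name='primer'"
            )
        )
        assert primers == ["BPPCT001.F", "BPPCT001.R"]
        n_adj = bare_store.scalar(
            "SELECT COUNT(*) FROM feature_relationship fr "
            "JOIN cvterm t ON t.cvterm_id=fr.type_id WHERE t.name='adjacent_to'"
        )
        assert n_adj == 2
        props = {
            r["tname"]: r["value"]
            for r in bare_store.execute(
                "SELECT t.name AS tname, p.value AS value FROM featureprop p "
                "JOIN cvterm t ON t.cvterm_id = p.type_id"
            )
        }
        assert props["marker_type"] == "SSR"
        assert props["screening_method"] == "2% agarose"

    def test_snp_residues_and_allele_prop(self, bare_store):
        mid = add_marker(
            bare_store,
            MarkerInput(
                name="snp1",
                organism=ORG,
                marker_type="SNP",
                alleles=["A", "T"],
                five_prime_flank="AC",
                three_prime_flank="GT",
            ),
        )
        row = bare_store.row(
            "SELECT residues, seqlen FROM feature WHERE feature_id=?", (mid,)
        )
        assert row["residues"] == "ACWGT" and row["seqlen"] == 5
        allele = bare_store.scalar(
            "SELECT value FROM featureprop p JOIN cvterm t "
            "ON t.cvterm_id=p.type_id WHERE t.name='allele' AND p.feature_id=?",
            (mid,),
        )
        assert allele == "A/T"

    def test_duplicate_marker_conflicts(self, bare_store):
        m = MarkerInput(name="m", organism=ORG, marker_type="SNP")
        add_marker(bare_store, m)
        with pytest.raises(ConflictError):
            add_marker(bare_store, m)


class TestMapsAndPlacements:
    @pytest.fixture()
    def mapped_store(self, bare_store):
        add_germplasm(
            bare_store, GermplasmInput("TxE_F2", ORG, type="population")
        )
        add_marker(
            bare_store, MarkerInput(name="CHILLH", organism=ORG, marker_type="SSR")
        )
        add_map(
            bare_store,
            MapInput(
                name="TxE_SSR",
                unit="cM",
                props={"map_type": "genetic linkage map"},
                population_stock="TxE_F2",
                organisms=[ORG],
            ),
        )
        return bare_store

    def test_map_row_props_and_population_link(self, mapped_store):
        assert mapped_store.count("featuremap") == 1
        assert mapped_store.count("featuremapprop") == 1
        linked_type = mapped_store.scalar(
            "SELECT t.name FROM featuremap_stock fs "
            "JOIN stock USING (stock_id) "
            "JOIN cvterm t ON t.cvterm_id = stock.type_id"
        )
        assert linked_type == "population"

    def test_unknown_unit_rejected(self, bare_store):
        with pytest.raises(TermLookupError):
            add_map(bare_store, MapInput(name="bad", unit="furlong"))

    def test_repeat_placement_gets_loc_suffix(self, mapped_store):
        first = PlacementInput("TxE_SSR", "LG1", "marker", "CHILLH", "10.0")
        place_on_map(mapped_store, first)
        place_on_map(
            mapped_store, PlacementInput("TxE_SSR", "LG2", "marker", "CHILLH", "3.5")
        )
        loci = sorted(
            r[0]
            for r in mapped_store.execute(
                "SELECT f.uniquename FROM feature f JOIN cvterm t "
                "ON t.cvterm_id=f.type_id WHERE t.name='marker_locus'"
            )
        )
        assert loci == ["CHILLH", "CHILLH_loc2"]
        # each locus is an instance_of exactly one marker
        for (locus_id,) in mapped_store.execute(
            "SELECT f.feature_id FROM feature f JOIN cvterm t "
            "ON t.cvterm_id=f.type_id WHERE t.name='marker_locus'"
        ):
            n = mapped_store.scalar(
                "SELECT COUNT(*) FROM feature_relationship fr "
                "JOIN cvterm t ON t.cvterm_id=fr.type_id "
                "WHERE t.name='instance_of' AND fr.subject_id=?",
                (locus_id,),
            )
            assert n == 1

    def test_stop_before_start_rejected(self, mapped_store):
        with pytest.raises(ValidationError):
            place_on_map(
                mapped_store,
                PlacementInput(
                    "TxE_SSR", "LG1", "marker", "CHILLH", "10.0", stop="4.0"
                ),
            )

    def test_linkage_groups_scoped_per_map(self, mapped_store):
        place_on_map(
            mapped_store, PlacementInput("TxE_SSR", "G1", "marker", "CHILLH", "0")
        )
        assert mapped_store.feature_id("TxE_SSR.G1", "linkage_group")


class TestTraitLoci:
    @pytest.fixture()
    def qtl_store(self, bare_store):
        for name in ("SSR12", "SSR13"):
            add_marker(
                bare_store, MarkerInput(name=name, organism=ORG, marker_type="SSR")
            )
        return bare_store

    def test_qtl_props_and_marker_edges(self, qtl_store):
        qid = add_qtl(
            qtl_store,
            QtlInput(
                label="qFC.1-2010",
                organism=ORG,
                trait="fruit color",
                props={"R_square": "23.4", "LOD": "5.6"},
                colocalized_markers=["SSR12"],
                neighboring_markers=["SSR13"],
            ),
        )
        props = {
            r["tname"]
            for r in qtl_store.execute(
                "SELECT t.name AS tname FROM featureprop p JOIN cvterm t "
                "ON t.cvterm_id=p.type_id WHERE p.feature_id=?",
                (qid,),
            )
        }
        assert props == {"R_square", "LOD"}
        # colocalized marker is the subject of located_in, QTL the object
        row = qtl_store.row(
            "SELECT s.uniquename AS sun FROM feature_relationship fr "
            "JOIN cvterm t ON t.cvterm_id=fr.type_id AND t.name='located_in' "
            "JOIN feature s ON s.feature_id = fr.subject_id "
            "WHERE fr.object_id=?",
            (qid,),
        )
        assert row["sun"] == "SSR12"

    def test_unknown_marker_named_in_error(self, qtl_store):
        with pytest.raises(ValidationError, match="NOPE"):
            add_qtl(
                qtl_store,
                QtlInput(
                    label="qX",
                    organism=ORG,
                    trait="fruit color",
                    colocalized_markers=["NOPE"],
                ),
            )

    def test_mtl_typed_and_linked_to_gene(self, qtl_store):
        gene_id = qtl_store.insert(
            "feature",
            organism_id=qtl_store.ensure_organism(ORG),
            uniquename="PG1",
            type_id=qtl_store.cvterm("sequence", "gene"),
        )
        mid = add_mtl(
            qtl_store,
            MtlInput(
                label="Freestone",
                organism=ORG,
                trait="fruit firmness",
                underlying_gene="PG1",
            ),
        )
        mtype = qtl_store.scalar(
            "SELECT t.name FROM feature f JOIN cvterm t ON t.cvterm_id=f.type_id "
            "WHERE f.feature_id=?",
            (mid,),
        )
        assert mtype == "heritable_phenotypic_marker"
        assert qtl_store.scalar(
            "SELECT 1 FROM feature_relationship fr JOIN cvterm t "
            "ON t.cvterm_id=fr.type_id WHERE t.name='associated_with' "
            "AND fr.subject_id=? AND fr.object_id=?",
            (gene_id, mid),
        )

    def test_qtl_start_stop_peak_props(self, qtl_store, bare_store):
        add_map(qtl_store, MapInput(name="M", unit="cM", organisms=[ORG]))
        add_qtl(
            qtl_store, QtlInput(label="qW.1", organism=ORG, trait="fruit weight")
        )
        pos = place_on_map(
            qtl_store,
            PlacementInput(
                "M", "LG1", "QTL", "qW.1", "12.3", stop="18.9", qtl_peak="15.0"
            ),
        )
        terms = sorted(
            r[0]
            for r in qtl_store.execute(
                "SELECT t.name FROM featureposprop p JOIN cvterm t "
                "ON t.cvterm_id=p.type_id WHERE p.featurepos_id=?",
                (pos,),
            )
        )
        assert terms == ["qtl_peak", "start", "stop"]


def test_fixture_qtl_intervals_are_ordered(session_store):
    """For each placed QTL, numeric(stop) >= numeric(start)."""
    store, _ = session_store
    by_pos = {}
    for r in store.execute(
        "SELECT p.featurepos_id AS pid, t.name AS term, p.value AS value "
        "FROM featureposprop p JOIN cvterm t ON t.cvterm_id=p.type_id "
        "WHERE t.name IN ('start', 'stop')"
    ):
        by_pos.setdefault(r["pid"], {})[r["term"]] = float(r["value"])
    checked = 0
    for vals in by_pos.values():
        if "stop" in vals:
            assert vals["stop"] >= vals["start"]
            checked += 1
    assert checked > 0
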