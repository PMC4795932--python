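"""FASTA/GFF3/NCBI-gene loading semantics."""

import pytest

from chadolite.errors import ConflictError, ValidationError
from chadolite.genomic import load_fasta, load_gff3, load_ncbi_genes

ORG = "Prunus persica"

FASTA = ">chrA test sequence\nACGTACGTAC\n>chrB\nGGGCCC\n"

TOY_GFF = """##gff-version 3
chrA\tx\tgene\t101\t200\t.\t+\t.\tID=g1
chrA\tx\tmRNA\t101\t200\t.\t+\t.\tID=g1.t1;Parent=g1
chrA\tx\texon\t101\t140\t.\t+\t.\tID=g1.e1;Parent=g1.t1
chrA\tx\texon\t161\t200\t.\t+\t.\tID=g1.e2;Parent=g1.t1
chrA\tx\tCDS\t121\t140\t.\t+\t0\tID=g1.c1;Parent=g1.t1
"""


@pytest.fixture()
def genome_store(bare_store, tmp_path):
    fasta = tmp_path / "g.fasta"
    fasta.write_text(FASTA)
    load_fasta(bare_store, fasta, ORG)
    return bare_store


class TestFasta:
    def test_records_become_typed_features(self, genome_store):
        row = genome_store.row(
            "SELECT residues, seqlen FROM feature WHERE uniquename='chrA'"
        )
        assert row["residues"] == "ACGTACGTAC" and row["seqlen"] == 10

    def test_reload_conflicts(self, genome_store, tmp_path):
        fasta = tmp_path / "g2.fasta"
        fasta.write_text(FASTA)
        with pytest.raises(ConflictError):
            load_fasta(genome_store, fasta, ORG)

    def test_empty_file_warns(self, bare_store, tmp_path):
        empty = tmp_path / "empty.fasta"
        empty.write_text("")
        with pytest.warns(UserWarning):
            assert load_fasta(bare_store, empty, ORG) == 0


class TestGff3:
    def test_toy_gene_model_counts(self, genome_store, tmp_path):
        gff = tmp_path / "toy.gff3"
        gff.write_text(TOY_GFF)
        summary = load_gff3(genome_store, gff, ORG)
        # gene + mRNA + 2 exons + CDS + synthesised polypeptide
        assert (summary.features, summary.relationships, summary.locations) == (
            6,
            5,
            6,
        )

    def test_interbase_conversion(self, genome_store, tmp_path):
        gff = tmp_path / "toy.gff3"
        gff.write_text(TOY_GFF)
        load_gff3(genome_store, gff, ORG)
        loc = genome_store.row(
            "SELECT fmin, fmax, strand FROM featureloc "
            "JOIN feature USING (feature_id) WHERE uniquename='g1'"
        )
        assert (loc["fmin"], loc["fmax"], loc["strand"]) == (100, 200, 1)

    def test_children_contained_in_parents(self, genome_store, tmp_path):
        gff = tmp_path / "toy.gff3"
        gff.write_text(TOY_GFF)
        load_gff3(genome_store, gff, ORG)
        rows = genome_store.execute(
            "SELECT cl.fmin AS cmin, cl.fmax AS cmax, pl.fmin AS pmin, "
            "pl.fmax AS pmax FROM feature_relationship fr "
            "JOIN cvterm t ON t.cvterm_id = fr.type_id AND t.name='part_of' "
            "JOIN featureloc cl ON cl.feature_id = fr.subject_id "
            "JOIN featureloc pl ON pl.feature_id = fr.object_id"
        ).fetchall()
        assert rows
        for r in rows:
            assert r["pmin"] <= r["cmin"] and r["cmax"] <= r["pmax"]

    def test_unknown_parent_is_named(self, genome_store, tmp_path):
        gff = tmp_path / "bad.gff3"
        gff.write_text(
            "##gff-version 3\nchrA\tx\tCDS\t10\t20\t.\t+\t0\tID=c;Parent=ghost\n"
        )
        with pytest.raises(ValidationError, match="ghost"):
            load_gff3(genome_store, gff, ORG)

    def test_unknown_srcfeature_rejected(self, genome_store, tmp_path):
        gff = tmp_path / "bad2.gff3"
        gff.write_text("##gff-version 3\nchrZ\tx\tgene\t1\t10\t.\t+\t.\tID=g\n")
        with pytest.raises(ValidationError, match="chrZ"):
            load_gff3(genome_store, gff, ORG)


class TestNcbiGenes:
    def test_reference_gene_convention(self, bare_store):
        records = [
            {
                "symbol": "NIP6.1",
                "instances": [
                    {"accession": "XM_1", "residues": "ATGAAA"},
                    {"accession": "XM_2", "residues": "ATGCCC"},
                ],
            }
        ]
        summary = load_ncbi_genes(bare_store, records, ORG)
        assert summary.features == 3 and summary.relationships == 2
        ref = bare_store.row(
            "SELECT residues, seqlen FROM feature WHERE uniquename='NIP6.1'"
        )
        assert ref["residues"] == "" and ref["seqlen"] is None
        n_assoc = bare_store.scalar(
            "SELECT COUNT(*) FROM feature_relationship fr "
            "JOIN cvterm t ON t.cvterm_id=fr.type_id "
            "WHERE t.name='associated_with'"
        )
        assert n_assoc == 2

    def test_duplicate_symbol_merges_and_bare_instance(self, bare_store):
        records = [
            {"symbol": "ABC", "instances": [{"accession": "A1"}]},
            {"symbol": "ABC", "instances": [{"accession": "A2"}]},
        ]
        load_ncbi_genes(bare_store, records, ORG)
        assert (
            bare_store.scalar(
                "SELECT COUNT(*) FROM feature WHERE uniquename='ABC'"
            )
            == 1
        )
        # instances without subfeatures get no part_of edges
        assert (
            bare_store.scalar(
                "SELECT COUNT(*) FROM feature_relationship fr "
                "JOIN cvterm t ON t.cvterm_id=fr.type_id WHERE t.name='part_of'"
            )
            == 0
        )
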