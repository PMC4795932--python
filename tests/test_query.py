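"""Query operations against independent oracles; export/import round trip."""

import random

import pytest

from chadolite import memory_store
from chadolite.errors import ImportError_, ValidationError
from chadolite.germplasm import GermplasmInput, add_germplasm, add_pedigree_edge
from chadolite.query import (
    export_all,
    import_all,
    map_view,
    marker_report,
    pedigree_tree,
    trait_dossier,
)
from helpers_oracles import (
    oracle_map_view,
    oracle_pedigree,
    oracle_trait_dossier,
)

ORG = "Prunus persica"


class TestTraitDossier:
    def test_equals_naive_enumeration(self, session_store):
        store, _ = session_store
        for trait in ("fruit_color", "fruit_weight", "flowering_time",
                      "chilling_requirement"):
            got = trait_dossier(store, trait)
            expected = oracle_trait_dossier(store, trait)
            for key in ("qtls", "mtls", "phenotype_measurements", "germplasm"):
                assert got[key] == expected[key], (trait, key)

    def test_unknown_term_warns_with_empty_dossier(self, session_store):
        store, _ = session_store
        with pytest.warns(UserWarning):
            dossier = trait_dossier(store, "no_such_trait")
        assert dossier["qtls"] == [] and dossier["germplasm"] == []

    def test_germplasm_subset_of_all_stocks(self, session_store):
        store, _ = session_store
        all_stocks = {
            r[0] for r in store.execute("SELECT uniquename FROM stock")
        }
        dossier = trait_dossier(store, "fruit_color")
        assert set(dossier["germplasm"]) <= all_stocks


class TestMapView:
    def test_matches_oracle_order_and_is_total(self, session_store):
        store, manifest = session_store
        view = map_view(store, manifest["map"])
        oracle = oracle_map_view(store, manifest["map"])
        assert {
            lg: [e["locus"] for e in entries] for lg, entries in view.items()
        } == oracle
        assert sum(len(v) for v in view.values()) == store.count("featurepos")

    def test_qtl_rows_carry_peak(self, session_store):
        store, _ = session_store
        view = map_view(store, "PP_MAIN")
        qtl_entries = [
            e for entries in view.values() for e in entries if e["type"] == "QTL"
        ]
        assert qtl_entries and all(e["peak"] is not None for e in qtl_entries)

    def test_unknown_map_rejected(self, session_store):
        store, _ = session_store
        with pytest.raises(ValidationError):
            map_view(store, "NO_MAP")

    def test_empty_map_gives_empty_view(self, bare_store):
        from chadolite.genetic import MapInput, add_map

        add_map(bare_store, MapInput(name="EMPTY", unit="cM"))
        assert map_view(bare_store, "EMPTY") == {}


class TestPedigree:
    def test_chain_depths_and_depth_cap(self, bare_store):
        for n in ("A", "B", "C"):
            add_germplasm(bare_store, GermplasmInput(n, ORG))
        add_pedigree_edge(bare_store, "B", "A", "maternal")
        add_pedigree_edge(bare_store, "C", "B", "maternal")
        nodes = pedigree_tree(bare_store, "C", "ancestors")
        assert [(n["stock"], n["depth"]) for n in nodes] == [("B", 1), ("A", 2)]
        capped = pedigree_tree(bare_store, "C", "ancestors", max_depth=1)
        assert [n["stock"] for n in capped] == ["B"]

    def test_random_dag_matches_closure_oracle(self, bare_store):
        rng = random.Random(11)
        names = [f"P{i:03d}" for i in range(200)]
        for n in names:
            add_germplasm(bare_store, GermplasmInput(n, ORG))
        for i in range(1, 200):
            pool = names[:i]
            if rng.random() < 0.8:
                mother = rng.choice(pool)
                add_pedigree_edge(bare_store, names[i], mother, "maternal")
                rest = [p for p in pool if p != mother]
                if rest and rng.random() < 0.6:
                    add_pedigree_edge(
                        bare_store, names[i], rng.choice(rest), "paternal"
                    )
        for probe in rng.sample(names, 12):
            for direction in ("ancestors", "descendants"):
                got = {n["stock"] for n in pedigree_tree(bare_store, probe, direction)}
                assert got == oracle_pedigree(bare_store, probe, direction)
            got2 = {
                n["stock"]
                for n in pedigree_tree(bare_store, probe, "ancestors", max_depth=2)
            }
            assert got2 == oracle_pedigree(bare_store, probe, "ancestors", 2)

    def test_unknown_stock_rejected(self, bare_store):
        with pytest.raises(ValidationError):
            pedigree_tree(bare_store, "Ghost")


class TestMarkerReport:
    def test_fixture_snp_report(self, session_store):
        store, manifest = session_store
        snp = sorted(manifest["snp_truth"])[0]
        report = marker_report(store, snp)
        assert report["residues"] == manifest["snp_truth"][snp]
        assert report["props"]["allele"]
        assert len(report["loci"]) >= 1
        assert report["genotypes"]

    def test_marker_on_two_maps_or_positions(self, session_store):
        store, _ = session_store
        report = marker_report(store, "M001")  # placed twice by the fixture
        assert len(report["loci"]) == 2

    def test_dbsnp_id_listed(self, session_store):
        store, _ = session_store
        report = marker_report(store, "M001")
        assert "dbSNP:rs9000001" in report["dbxrefs"]


class TestRoundTrip:
    def test_fixture_roundtrip_byte_identical(self, session_store, tmp_path):
        store, _ = session_store
        first, second = tmp_path / "e1", tmp_path / "e2"
        export_all(store, first)
        export_all(import_all(first), second)
        for f in sorted(first.iterdir()):
            assert f.read_bytes() == (second / f.name).read_bytes(), f.name

    def test_empty_store_exports_header_only(self, tmp_path):
        export_all(memory_store(), tmp_path)
        content = (tmp_path / "feature.tsv").read_text().splitlines()
        assert len(content) == 1 and "uniquename" in content[0]

    def test_unknown_column_named_on_import(self, tmp_path):
        export_all(memory_store(), tmp_path)
        cv = tmp_path / "cv.tsv"
        cv.write_text("name\tdefinition\tbogus_col\n")
        with pytest.raises(ImportError_, match="bogus_col"):
            import_all(tmp_path)

    def test_schema_version_mismatch_rejected(self, tmp_path):
        export_all(memory_store(), tmp_path)
        manifest = tmp_path / "manifest.json"
        manifest.write_text(
            manifest.read_text().replace('"schema_version": "', '"schema_version": "99.')
        )
        with pytest.raises(ImportError_, match="version"):
            import_all(tmp_path)
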