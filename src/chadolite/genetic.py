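"""Genetic markers, maps, loci, bins, QTL and MTL.

Markers are ``genetic_marker`` features whose details (marker type, repeat
motif, PCR condition, ...) live in featureprop rows typed by in-house
terms. SNP alleles are collapsed to one IUPAC ambiguity base and embedded
between the flanking sequences to give searchable residues. A map
placement creates a ``marker_locus`` feature per position (locus names
repeat the marker name; extra placements on the same map get a ``_loc<n>``
suffix) and stores start/stop/peak as featureposprop rows — never in
featurepos.mappos, because QTL carry up to three positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd

from .errors import (
    ConflictError,
    NotEncodableError,
    ValidationError,
)
from .store import Store
from .vocab import ensure_trait_term, rel_term

# IUPAC ambiguity code for every non-empty subset of {A, C, G, T}
IUPAC = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

#: featureprop terms for marker details, all in the in-house vocabulary
MARKER_PROP_TERMS = (
    "repeat_motif",
    "restriction_enzyme",
    "product_length",
    "max_length",
    "min_length",
    "is_codominant",
    "PCR_condition",
    "screening_method",
    "comments",
    "source",
)

MAP_PROP_TERMS = (
    "map_type",
    "analysis_method",
    "software",
    "comments",
    "genome_group",
    "population_type",
)

QTL_PROP_TERMS = (
    "published_symbol",
    "bayes_factor",
    "P_value",
    "R_square",
    "LOD",
    "additive_effect",
    "dominance_effect",
    "direction",
    "screening_method",
    "comments",
)

MTL_PROP_TERMS = (
    "published_symbol",
    "screening_method",
    "description",
    "comments",
)


def synthesize_snp_residues(
    alleles: list[str], five_prime: str = "", three_prime: str = ""
) -> str:
    """flank5 + IUPAC(allele set) + flank3.

    Duplicate alleles and their order are irrelevant: only the set of
    bases determines the ambiguity code.
    """
    bases = frozenset(a.strip().upper() for a in alleles)
    if not bases or not bases <= frozenset("ACGT") or any(
        len(a.strip()) != 1 for a in alleles
    ):
        raise NotEncodableError(
            f"alleles {alleles!r} are not single A/C/G/T bases"
        )
    return five_prime + IUPAC[bases] + three_prime


@dataclass
class MarkerInput:
    name: str
    organism: str
    marker_type: str
    aliases: list[str] = field(default_factory=list)
    props: dict[str, str] = field(default_factory=dict)
    alleles: list[str] = field(default_factory=list)
    five_prime_flank: str = ""
    three_prime_flank: str = ""
    primers: list[dict[str, str]] = field(default_factory=list)
    probe: Optional[dict[str, str]] = None
    source_sequence: Optional[dict[str, str]] = None
    source_germplasm: str = ""
    contact: str = ""
    pub: str = ""
    genbank_id: str = ""
    dbsnp_id: str = ""


@dataclass
class MapInput:
    name: str
    unit: str = "cM"
    props: dict[str, str] = field(default_factory=dict)
    population_stock: str = ""
    parents: list[str] = field(default_factory=list)
    organisms: list[str] = field(default_factory=list)
    contact: str = ""
    pub: str = ""


@dataclass
class PlacementInput:
    map_name: str
    linkage_group: str
    locus_kind: str  # marker | QTL | MTL | bin
    target: str
    start: str
    stop: str = ""
    qtl_peak: str = ""
    probability: str = ""
    comments: str = ""


@dataclass
class QtlInput:
    label: str
    organism: str
    trait: str
    aliases: list[str] = field(default_factory=list)
    props: dict[str, str] = field(default_factory=dict)
    colocalized_markers: list[str] = field(default_factory=list)
    neighboring_markers: list[str] = field(default_factory=list)
    source_germplasm: str = ""
    dataset: str = ""
    contact: str = ""
    pub: str = ""
    anchor: Optional[dict[str, Any]] = None  # {srcfeature, fmin, fmax, strand}


@dataclass
class MtlInput(QtlInput):
    underlying_gene: str = ""


def _numeric(text: str, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ValidationError(f"{what} must be numeric, got {text!r}") from None


def add_marker(store: Store, m: MarkerInput) -> int:
    """Store one genetic marker with all its typed detail records."""
    if not m.name.strip() or not m.marker_type.strip():
        raise ValidationError("marker name and marker_type are required")
    name = m.name.strip()
    org_id = store.ensure_organism(m.organism)
    marker_type_id = store.cvterm("sequence", "genetic_marker")
    if store.feature_id(name, "genetic_marker", org_id) is not None:
        raise ConflictError(f"marker {name!r} already exists for {m.organism!r}")

    residues = ""
    if m.marker_type == "SNP" and m.alleles:
        try:
            residues = synthesize_snp_residues(
                m.alleles, m.five_prime_flank, m.three_prime_flank
            )
        except NotEncodableError:
            residues = ""
    marker_id = store.insert(
        "feature",
        organism_id=org_id,
        uniquename=name,
        name=name,
        residues=residues,
        seqlen=len(residues) if residues else None,
        type_id=marker_type_id,
    )
    store.add_prop("featureprop", marker_id, "local", "marker_type", m.marker_type)
    for alias in m.aliases:
        if alias:
            store.add_prop("featureprop", marker_id, "local", "alias", alias)
    for term in MARKER_PROP_TERMS:
        value = m.props.get(term, "")
        if value:
            store.add_prop("featureprop", marker_id, "local", term, value)
    if m.alleles:
        store.add_prop(
            "featureprop", marker_id, "sequence", "allele", "/".join(m.alleles)
        )
    if m.five_prime_flank:
        store.add_prop(
            "featureprop",
            marker_id,
            "sequence",
            "five_prime_flanking_region",
            m.five_prime_flank,
        )
    if m.three_prime_flank:
        store.add_prop(
            "featureprop",
            marker_id,
            "sequence",
            "three_prime_flanking_region",
            m.three_prime_flank,
        )
    adjacent_to = rel_term(store, "adjacent_to")
    primer_type = store.cvterm("sequence", "primer")
    for primer in m.primers:
        seq = primer.get("sequence", "")
        primer_id = store.insert(
            "feature",
            organism_id=org_id,
            uniquename=f"{name}.{primer['label']}",
            name=f"{name}.{primer['label']}",
            residues=seq,
            seqlen=len(seq) if seq else None,
            type_id=primer_type,
        )
        store.insert(
            "feature_relationship",
            subject_id=primer_id,
            object_id=marker_id,
            type_id=adjacent_to,
        )
    if m.probe:
        seq = m.probe.get("sequence", "")
        probe_id = store.insert(
            "feature",
            organism_id=org_id,
            uniquename=m.probe.get("name") or f"{name}.probe",
            residues=seq,
            seqlen=len(seq) if seq else None,
            type_id=store.cvterm("sequence", "probe"),
        )
        store.insert(
            "feature_relationship",
            subject_id=probe_id,
            object_id=marker_id,
            type_id=rel_term(store, "associated_with"),
        )
    if m.source_sequence:
        seq = m.source_sequence.get("residues", "")
        src_id = store.feature_id(
            m.source_sequence["uniquename"], "sequence_feature", org_id
        )
        if src_id is None:
            src_id = store.insert(
                "feature",
                organism_id=org_id,
                uniquename=m.source_sequence["uniquename"],
                residues=seq,
                seqlen=len(seq) if seq else None,
                type_id=store.cvterm("sequence", "sequence_feature"),
            )
        store.insert(
            "feature_relationship",
            subject_id=marker_id,
            object_id=src_id,
            type_id=rel_term(store, "derived_from"),
        )
    if m.source_germplasm:
        stock_id = store.stock_id(m.source_germplasm)
        if stock_id is None:
            raise ValidationError(
                f"source germplasm {m.source_germplasm!r} not in stock table"
            )
        store.link(
            "feature_stock",
            feature_id=marker_id,
            stock_id=stock_id,
            type_id=store.cvterm("local", "source"),
        )
    if m.contact:
        store.link(
            "feature_contact",
            feature_id=marker_id,
            contact_id=store.ensure_contact(m.contact),
        )
    if m.pub:
        store.link(
            "feature_pub", feature_id=marker_id, pub_id=store.ensure_pub(m.pub)
        )
    for db_name, accession in (("GenBank", m.genbank_id), ("dbSNP", m.dbsnp_id)):
        if accession:
            db_id = store._ensure_db(db_name)
            dbxref_id = store.link("dbxref", db_id=db_id, accession=accession)
            store.link(
                "feature_dbxref", feature_id=marker_id, dbxref_id=dbxref_id
            )
    store.commit()
    return marker_id


def add_map(store: Store, m: MapInput) -> int:
    if store.scalar("SELECT 1 FROM featuremap WHERE name=?", (m.name,)):
        raise ConflictError(f"map {m.name!r} already exists")
    unit_id = store.cvterm("local", m.unit)  # raises for unknown units
    map_id = store.insert("featuremap", name=m.name, unittype_id=unit_id)
    for term in MAP_PROP_TERMS:
        value = m.props.get(term, "")
        if value:
            store.add_prop("featuremapprop", map_id, "local", term, value)
    for stock_name in [m.population_stock, *m.parents]:
        if stock_name:
            stock_id = store.stock_id(stock_name)
            if stock_id is None:
                raise ValidationError(f"stock {stock_name!r} not found")
            store.link("featuremap_stock", featuremap_id=map_id, stock_id=stock_id)
    for organism in m.organisms:
        store.link(
            "featuremap_organism",
            featuremap_id=map_id,
            organism_id=store.ensure_organism(organism),
        )
    if m.contact:
        store.link(
            "featuremap_contact",
            featuremap_id=map_id,
            contact_id=store.ensure_contact(m.contact),
        )
    if m.pub:
        store.link(
            "featuremap_pub", featuremap_id=map_id, pub_id=store.ensure_pub(m.pub)
        )
    store.commit()
    return map_id


def _map_organism(store: Store, map_id: int) -> Optional[int]:
    return store.scalar(
        "SELECT organism_id FROM featuremap_organism WHERE featuremap_id=? "
        "ORDER BY organism_id LIMIT 1",
        (map_id,),
    )


def _upsert_lg(store: Store, map_id: int, map_name: str, lg: str, org_id: int) -> int:
    """Linkage groups are scoped per map: uniquename '<map>.<lg>'."""
    uniquename = f"{map_name}.{lg}"
    lg_id = store.feature_id(uniquename, "linkage_group")
    if lg_id is None:
        lg_id = store.insert(
            "feature",
            organism_id=org_id,
            uniquename=uniquename,
            name=lg,
            type_id=store.cvterm("sequence", "linkage_group"),
        )
    return lg_id


def place_on_map(store: Store, p: PlacementInput) -> int:
    """Place a marker locus, QTL, MTL or bin on a linkage group of a map."""
    row = store.row(
        "SELECT featuremap_id, name FROM featuremap WHERE name=?", (p.map_name,)
    )
    if row is None:
        raise ValidationError(f"unknown map {p.map_name!r}")
    map_id = row["featuremap_id"]
    start = _numeric(p.start, "start")
    stop = _numeric(p.stop, "stop") if p.stop else None
    if stop is not None and stop < start:
        raise ValidationError(f"stop {stop} < start {start}")

    located_in = rel_term(store, "located_in")
    if p.locus_kind == "marker":
        marker_id = store.feature_id(p.target, "genetic_marker")
        if marker_id is None:
            raise ValidationError(f"unknown marker {p.target!r}")
        org_id = store.scalar(
            "SELECT organism_id FROM feature WHERE feature_id=?", (marker_id,)
        )
        # count existing placements of this marker on this map
        n_prev = store.scalar(
            "SELECT COUNT(*) FROM featurepos fp "
            "JOIN feature_relationship fr ON fr.subject_id = fp.feature_id "
            "JOIN cvterm rt ON rt.cvterm_id = fr.type_id "
            "WHERE fp.featuremap_id = ? AND fr.object_id = ? "
            "AND rt.name = 'instance_of'",
            (map_id, marker_id),
        )
        locus_un = p.target if n_prev == 0 else f"{p.target}_loc{n_prev + 1}"
        locus_id = store.insert(
            "feature",
            organism_id=org_id,
            uniquename=locus_un,
            name=locus_un,
            type_id=store.cvterm("sequence", "marker_locus"),
        )
        store.insert(
            "feature_relationship",
            subject_id=locus_id,
            object_id=marker_id,
            type_id=rel_term(store, "instance_of"),
        )
    elif p.locus_kind == "QTL":
        locus_id = store.feature_id(p.target, "QTL")
        if locus_id is None:
            raise ValidationError(f"unknown QTL {p.target!r}")
        org_id = store.scalar(
            "SELECT organism_id FROM feature WHERE feature_id=?", (locus_id,)
        )
    elif p.locus_kind == "MTL":
        locus_id = store.feature_id(p.target, "heritable_phenotypic_marker")
        if locus_id is None:
            raise ValidationError(f"unknown MTL {p.target!r}")
        org_id = store.scalar(
            "SELECT organism_id FROM feature WHERE feature_id=?", (locus_id,)
        )
    elif p.locus_kind == "bin":
        org_id = _map_organism(store, map_id) or store.ensure_organism(
            "Unknown sp."
        )
        bin_un = f"{p.map_name}.{p.target}"
        locus_id = store.feature_id(bin_un, "bin")
        if locus_id is None:
            locus_id = store.insert(
                "feature",
                organism_id=org_id,
                uniquename=bin_un,
                name=p.target,
                type_id=store.cvterm("sequence", "bin"),
            )
    else:
        raise ValidationError(f"unknown locus kind {p.locus_kind!r}")

    lg_id = _upsert_lg(store, map_id, p.map_name, p.linkage_group, org_id)
    pos_id = store.insert(
        "featurepos",
        featuremap_id=map_id,
        feature_id=locus_id,
        map_feature_id=lg_id,
    )
    store.add_prop("featureposprop", pos_id, "local", "start", p.start)
    if p.stop:
        store.add_prop("featureposprop", pos_id, "local", "stop", p.stop)
    if p.qtl_peak:
        store.add_prop("featureposprop", pos_id, "local", "qtl_peak", p.qtl_peak)
    if p.probability:
        store.add_prop(
            "featureposprop", pos_id, "local", "probability", p.probability
        )
    if p.comments:
        store.add_prop("featureposprop", pos_id, "local", "comments", p.comments)

    # bin membership: a locus whose start lies inside a bin's [start, stop]
    # on the same linkage group is located_in that bin
    if p.locus_kind == "bin" and stop is not None:
        for row in _positions_on_lg(store, map_id, lg_id):
            if row["feature_id"] == locus_id:
                continue
            if row["type"] == "bin":
                continue
            if row["start"] is not None and start <= row["start"] <= stop:
                store.insert(
                    "feature_relationship",
                    subject_id=row["feature_id"],
                    object_id=locus_id,
                    type_id=located_in,
                )
    elif p.locus_kind != "bin":
        for row in _positions_on_lg(store, map_id, lg_id):
            if row["type"] != "bin":
                continue
            if (
                row["start"] is not None
                and row["stop"] is not None
                and row["start"] <= start <= row["stop"]
            ):
                store.insert(
                    "feature_relationship",
                    subject_id=locus_id,
                    object_id=row["feature_id"],
                    type_id=located_in,
                )
    store.commit()
    return pos_id


def _positions_on_lg(store: Store, map_id: int, lg_id: int):
    """Placements on one linkage group with numeric start/stop and type."""
    out = []
    for row in store.execute(
        "SELECT fp.featurepos_id AS pid, fp.feature_id AS feature_id, "
        "t.name AS type "
        "FROM featurepos fp JOIN feature f USING (feature_id) "
        "JOIN cvterm t ON t.cvterm_id = f.type_id "
        "WHERE fp.featuremap_id = ? AND fp.map_feature_id = ?",
        (map_id, lg_id),
    ):
        vals = {"feature_id": row["feature_id"], "type": row["type"],
                "start": None, "stop": None}
        for prop in store.execute(
            "SELECT t.name AS term, p.value AS value FROM featureposprop p "
            "JOIN cvterm t ON t.cvterm_id = p.type_id "
            "WHERE p.featurepos_id = ? AND t.name IN ('start', 'stop')",
            (row["pid"],),
        ):
            try:
                vals[prop["term"]] = float(prop["value"])
            except ValueError:
                pass
        out.append(vals)
    return out


def _add_trait_locus(
    store: Store, q: QtlInput, so_type: str, prop_terms: tuple[str, ...]
) -> int:
    label = q.label.strip()
    if not label:
        raise ValidationError("label is required")
    org_id = store.ensure_organism(q.organism)
    if store.feature_id(label, so_type, org_id) is not None:
        raise ConflictError(f"{so_type} {label!r} already exists")
    feature_id = store.insert(
        "feature",
        organism_id=org_id,
        uniquename=label,
        name=label,
        type_id=store.cvterm("sequence", so_type),
    )
    trait_id = ensure_trait_term(store, q.trait)
    store.link("feature_cvterm", feature_id=feature_id, cvterm_id=trait_id)
    for alias in q.aliases:
        if not alias:
            continue
        syn_id = store.scalar("SELECT synonym_id FROM synonym WHERE name=?", (alias,))
        if syn_id is None:
            syn_id = store.insert("synonym", name=alias)
        store.link("feature_synonym", synonym_id=syn_id, feature_id=feature_id)
    for term in prop_terms:
        value = q.props.get(term, "")
        if value:
            store.add_prop("featureprop", feature_id, "local", term, value)
    located_in = rel_term(store, "located_in")
    adjacent_to = rel_term(store, "adjacent_to")
    for rank, marker in enumerate(q.colocalized_markers):
        marker_id = store.feature_id(marker, "genetic_marker")
        if marker_id is None:
            raise ValidationError(f"unknown colocalized marker {marker!r}")
        store.insert(
            "feature_relationship",
            subject_id=marker_id,
            object_id=feature_id,
            type_id=located_in,
            rank=rank,
        )
    for rank, marker in enumerate(q.neighboring_markers):
        marker_id = store.feature_id(marker, "genetic_marker")
        if marker_id is None:
            raise ValidationError(f"unknown neighboring marker {marker!r}")
        store.insert(
            "feature_relationship",
            subject_id=marker_id,
            object_id=feature_id,
            type_id=adjacent_to,
            rank=rank,
        )
    if q.source_germplasm:
        stock_id = store.stock_id(q.source_germplasm)
        if stock_id is None:
            raise ValidationError(f"unknown germplasm {q.source_germplasm!r}")
        store.link(
            "feature_stock",
            feature_id=feature_id,
            stock_id=stock_id,
            type_id=store.cvterm("local", "source"),
        )
    if q.dataset:
        store.link(
            "feature_project",
            feature_id=feature_id,
            project_id=store.ensure_project(q.dataset),
        )
    if q.contact:
        store.link(
            "feature_contact",
            feature_id=feature_id,
            contact_id=store.ensure_contact(q.contact),
        )
    if q.pub:
        store.link(
            "feature_pub", feature_id=feature_id, pub_id=store.ensure_pub(q.pub)
        )
    if q.anchor:
        src_id = store.feature_id(q.anchor["srcfeature"])
        if src_id is None:
            raise ValidationError(
                f"unknown anchor srcfeature {q.anchor['srcfeature']!r}"
            )
        store.insert(
            "featureloc",
            feature_id=feature_id,
            srcfeature_id=src_id,
            fmin=int(q.anchor["fmin"]),
            fmax=int(q.anchor["fmax"]),
            strand=int(q.anchor.get("strand", 0)),
        )
    store.commit()
    return feature_id


def add_qtl(store: Store, q: QtlInput) -> int:
    """Store one QTL with trait link, statistics props and marker context."""
    return _add_trait_locus(store, q, "QTL", QTL_PROP_TERMS)


def add_mtl(store: Store, m: MtlInput) -> int:
    """Store one Mendelian trait locus (SO heritable_phenotypic_marker)."""
    feature_id = _add_trait_locus(
        store, m, "heritable_phenotypic_marker", MTL_PROP_TERMS
    )
    if m.underlying_gene:
        gene_id = store.feature_id(m.underlying_gene, "gene")
        if gene_id is None:
            raise ValidationError(f"unknown gene {m.underlying_gene!r}")
        store.insert(
            "feature_relationship",
            subject_id=gene_id,
            object_id=feature_id,
            type_id=rel_term(store, "associated_with"),
        )
        store.commit()
    return feature_id


# ---------------------------------------------------------------------------
# tab-delimited loader templates


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _split(cell: str, sep: str = ";") -> list[str]:
    return [x for x in (s.strip() for s in cell.split(sep)) if x] if cell else []


def load_markers_tsv(store: Store, path: str | Path) -> int:
    df = _read_tsv(path)
    for _, row in df.iterrows():
        primers = []
        for label in ("F", "R"):
            seq = row.get(f"primer_{label}", "")
            if seq:
                primers.append({"label": label, "sequence": seq})
        probe = None
        if row.get("probe", ""):
            pname, _, pseq = row["probe"].partition(":")
            probe = {"name": pname, "sequence": pseq}
        source_sequence = None
        if row.get("source_sequence", ""):
            sname, _, sseq = row["source_sequence"].partition(":")
            source_sequence = {"uniquename": sname, "residues": sseq}
        add_marker(
            store,
            MarkerInput(
                name=row["name"],
                organism=row["organism"],
                marker_type=row["marker_type"],
                aliases=_split(row.get("aliases", "")),
                props={
                    t: row.get(t, "") for t in MARKER_PROP_TERMS if row.get(t, "")
                },
                alleles=_split(row.get("alleles", ""), "/"),
                five_prime_flank=row.get("five_prime_flank", ""),
                three_prime_flank=row.get("three_prime_flank", ""),
                primers=primers,
                probe=probe,
                source_sequence=source_sequence,
                source_germplasm=row.get("source_germplasm", ""),
                contact=row.get("contact", ""),
                pub=row.get("pub", ""),
                genbank_id=row.get("genbank_id", ""),
                dbsnp_id=row.get("dbsnp_id", ""),
            ),
        )
    return len(df)


def load_maps_tsv(store: Store, path: str | Path) -> int:
    df = _read_tsv(path)
    for _, row in df.iterrows():
        add_map(
            store,
            MapInput(
                name=row["name"],
                unit=row.get("unit", "cM") or "cM",
                props={t: row.get(t, "") for t in MAP_PROP_TERMS if row.get(t, "")},
                population_stock=row.get("population", ""),
                parents=_split(row.get("parents", "")),
                organisms=_split(row.get("organisms", "")),
                contact=row.get("contact", ""),
                pub=row.get("pub", ""),
            ),
        )
    return len(df)


def load_positions_tsv(store: Store, path: str | Path) -> int:
    df = _read_tsv(path)
    for _, row in df.iterrows():
        place_on_map(
            store,
            PlacementInput(
                map_name=row["map"],
                linkage_group=row["linkage_group"],
                locus_kind=row["locus_type"],
                target=row["target"],
                start=row["start"],
                stop=row.get("stop", ""),
                qtl_peak=row.get("peak", ""),
                probability=row.get("probability", ""),
                comments=row.get("comments", ""),
            ),
        )
    return len(df)


def _trait_locus_input(row: pd.Series, cls, prop_terms) -> QtlInput:
    kwargs = dict(
        label=row["label"],
        organism=row["organism"],
        trait=row["trait"],
        aliases=_split(row.get("aliases", "")),
        props={t: row.get(t, "") for t in prop_terms if row.get(t, "")},
        colocalized_markers=_split(row.get("colocalized_markers", "")),
        neighboring_markers=_split(row.get("neighboring_markers", "")),
        source_germplasm=row.get("source_germplasm", ""),
        dataset=row.get("dataset", ""),
        contact=row.get("contact", ""),
        pub=row.get("pub", ""),
    )
    if cls is MtlInput:
        kwargs["underlying_gene"] = row.get("underlying_gene", "")
    return cls(**kwargs)


def load_qtl_tsv(store: Store, path: str | Path) -> int:
    df = _read_tsv(path)
    for _, row in df.iterrows():
        add_qtl(store, _trait_locus_input(row, QtlInput, QTL_PROP_TERMS))
    return len(df)


def load_mtl_tsv(store: Store, path: str | Path) -> int:
    df = _read_tsv(path)
    for _, row in df.iterrows():
        add_mtl(store, _trait_locus_input(row, MtlInput, MTL_PROP_TERMS))
    return len(df)
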