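"""Controlled vocabularies: OBO ingestion and the in-house term inventory.

Every record in the store is typed by a cvterm, so the vocabularies must be
in place before any loader runs. Three kinds are distinguished:

* ontology vocabularies read from OBO files ("sequence", "relationship",
  "trait_ontology"), never extended silently;
* the in-house vocabulary "local" holding property/type terms the
  ontologies do not provide (marker_type, start, phenotyping, ...);
* "local_trait", where trait descriptors missing from the trait ontology
  are parked as provisional terms pending ontology review.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import obonet

from .errors import OboParseError, TermLookupError, ValidationError
from .store import Store

#: SO feature-type terms the storage conventions rely on
SEQUENCE_TERMS = (
    "genetic_marker",
    "QTL",
    "marker_locus",
    "linkage_group",
    "primer",
    "probe",
    "haplotype_block",
    "heritable_phenotypic_marker",
    "sequence_feature",
    "gene",
    "mRNA",
    "CDS",
    "polypeptide",
    "exon",
    "chromosome",
    "contig",
    "allele",
    "five_prime_UTR",
    "three_prime_UTR",
    "five_prime_flanking_region",
    "three_prime_flanking_region",
    "bin",
)

#: relationship terms allowed in feature_relationship.type_id
RELATIONSHIP_TERMS = (
    "part_of",
    "derives_from",
    "associated_with",
    "adjacent_to",
    "located_in",
    "instance_of",
    "contains",
    "derived_from",
)

#: in-house terms: marker/map/QTL props, stock types, pedigree edges,
#: experiment types, map units and position props
LOCAL_TERMS = (
    "marker_type",
    "alias",
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
    "map_type",
    "analysis_method",
    "software",
    "genome_group",
    "population_type",
    "cM",
    "bin_unit",
    "bin",
    "start",
    "stop",
    "qtl_peak",
    "probability",
    "published_symbol",
    "bayes_factor",
    "P_value",
    "R_square",
    "LOD",
    "additive_effect",
    "dominance_effect",
    "direction",
    "description",
    "cultivar",
    "breeding/research material",
    "wild/unimproved",
    "population",
    "sample",
    "clone",
    "paternal_parent_of",
    "maternal_parent_of",
    "mutational_parent_of",
    "sample_of",
    "clone_of",
    "member_of",
    "phenotyping",
    "genotyping",
    "passport",
    "cross",
    "title",
    "population_size",
    "sample_size",
    "standard_deviation",
    "coefficient_of_variation",
    "skewness",
    "standard_of",
    "code",
    "haplotype_effect",
    "is_provisional",
)

#: stock types allowed for germplasm records
GERMPLASM_TYPES = (
    "cultivar",
    "breeding/research material",
    "wild/unimproved",
    "population",
)


@dataclass
class TermInventory:
    sequence_terms: tuple[str, ...] = SEQUENCE_TERMS
    relationship_terms: tuple[str, ...] = RELATIONSHIP_TERMS
    local_terms: tuple[str, ...] = LOCAL_TERMS
    provisional: list[str] = field(default_factory=list)


_QUOTED = re.compile(r'"([^"]*)"')


def _prescan_obo(path: Path) -> None:
    """Reject [Term] stanzas without a name, naming the offending line."""
    stanza_line: Optional[int] = None
    in_term = False
    has_name = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("["):
                if in_term and not has_name:
                    raise OboParseError(
                        f"{path}: [Term] stanza at line {stanza_line} has no name"
                    )
                in_term = line == "[Term]"
                stanza_line = lineno
                has_name = False
            elif in_term and line.startswith("name:"):
                has_name = True
            elif line and not line.startswith("!") and ":" not in line:
                raise OboParseError(
                    f"{path}: malformed line {lineno}: {line!r}"
                )
    if in_term and not has_name:
        raise OboParseError(
            f"{path}: [Term] stanza at line {stanza_line} has no name"
        )


def load_obo(store: Store, path: str | Path, cv_name: str) -> int:
    """Load one OBO file into *cv_name*; returns the number of new terms.

    One cvterm per non-obsolete [Term] stanza (name as the term, id as the
    accession); synonyms become alternative lookup keys in cvtermsynonym.
    Re-loading the same file is a no-op (upsert by (cv, name)).
    """
    path = Path(path)
    _prescan_obo(path)
    try:
        graph = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # obonet raises assorted ValueError subtypes
        raise OboParseError(f"{path}: {exc}") from exc
    store.ensure_cv(cv_name)
    added = 0
    for term_id, data in sorted(graph.nodes(data=True)):
        name = data.get("name")
        if not name:
            raise OboParseError(f"{path}: term {term_id} has no name")
        existing = store.get_cvterm_id(cv_name, name)
        definition = data.get("def", "")
        if definition:
            m = _QUOTED.search(definition)
            definition = m.group(1) if m else definition
        if existing is None:
            cvterm_id = store.create_cvterm(
                cv_name, name, definition=definition, accession=term_id
            )
            added += 1
        else:
            cvterm_id = existing
        for syn in data.get("synonym", []):
            m = _QUOTED.search(syn)
            if m:
                store.link(
                    "cvtermsynonym", cvterm_id=cvterm_id, synonym=m.group(1)
                )
    store.commit()
    return added


def mark_provisional(store: Store, cvterm_id: int) -> None:
    store.add_prop("cvtermprop", cvterm_id, "local", "is_provisional", "true")


def is_provisional(store: Store, cvterm_id: int) -> bool:
    return bool(
        store.scalar(
            "SELECT 1 FROM cvtermprop JOIN cvterm t ON t.cvterm_id = "
            "cvtermprop.type_id WHERE cvtermprop.cvterm_id = ? "
            "AND t.name = 'is_provisional'",
            (cvterm_id,),
        )
    )


def bootstrap_inventory(store: Store) -> TermInventory:
    """Pre-register every term the storage conventions require.

    Idempotent. SO/relationship terms an OBO load has not supplied are
    created with an empty accession and flagged provisional so that no
    loader ever mints a structural term on the fly.
    """
    inv = TermInventory()
    store.ensure_cv("sequence", "Sequence Ontology feature types")
    store.ensure_cv("relationship", "relationship types between records")
    store.ensure_cv("local", "in-house vocabulary")
    store.ensure_cv("local_trait", "provisional trait descriptors")
    store.ensure_cv("trait_ontology", "trait ontology")
    # 'is_provisional' itself must exist before anything can be flagged
    store.create_cvterm("local", "is_provisional")
    for name in SEQUENCE_TERMS:
        if store.get_cvterm_id("sequence", name) is None:
            term_id = store.create_cvterm("sequence", name)
            mark_provisional(store, term_id)
            inv.provisional.append(name)
    for name in RELATIONSHIP_TERMS:
        if store.get_cvterm_id("relationship", name) is None:
            term_id = store.create_cvterm(
                "relationship", name, is_relationshiptype=True
            )
            mark_provisional(store, term_id)
            inv.provisional.append(name)
    for name in LOCAL_TERMS:
        store.create_cvterm("local", name)
    # the alternative spelling used in some curation tables resolves to
    # the canonical SO term via a synonym
    hpm = store.cvterm("sequence", "heritable_phenotypic_marker")
    store.link(
        "cvtermsynonym", cvterm_id=hpm, synonym="heritable_morphological_marker"
    )
    store.commit()
    return inv


def resolve(store: Store, cv_name: str, term: str) -> int:
    """(cv, name) -> cvterm_id, falling back to synonym lookup keys."""
    term_id = store.get_cvterm_id(cv_name, term)
    if term_id is not None:
        return term_id
    term_id = store.scalar(
        "SELECT s.cvterm_id FROM cvtermsynonym s "
        "JOIN cvterm c ON c.cvterm_id = s.cvterm_id "
        "JOIN cv ON cv.cv_id = c.cv_id "
        "WHERE cv.name = ? AND s.synonym = ?",
        (cv_name, term),
    )
    if term_id is None:
        raise TermLookupError(f"no term {term!r} in vocabulary {cv_name!r}")
    return term_id


def rel_term(store: Store, name: str) -> int:
    """Resolve a relationship-type term ('relationship' cv, SO fallback)."""
    for cv_name in ("relationship", "sequence"):
        term_id = store.get_cvterm_id(cv_name, name)
        if term_id is not None:
            return term_id
    raise TermLookupError(f"no relationship term {name!r}")


def ensure_trait_term(store: Store, name: str, cv: str = "trait_ontology") -> int:
    """Exact-match a trait term in the trait ontology, else park it in
    'local_trait' as provisional; never silently extends the ontology."""
    name = name.strip()
    if not name:
        raise ValidationError("trait term name must be non-empty")
    if cv not in ("trait_ontology", "local_trait"):
        raise ValidationError(f"trait terms live in trait_ontology/local_trait, not {cv!r}")
    for cv_name in ("trait_ontology", "local_trait"):
        term_id = store.get_cvterm_id(cv_name, name)
        if term_id is not None:
            return term_id
    term_id = store.create_cvterm("local_trait", name)
    mark_provisional(store, term_id)
    return term_id
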