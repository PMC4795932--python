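"""Embedded relational store using the Chado table vocabulary.

The schema is the subset of Chado 1.2 used for integrated genomic, genetic
and breeding data, plus the custom linker/property tables the breeding
use case requires (featuremapprop, featureposprop, feature_stock, ...).
Every record carries a surrogate integer key; natural keys (uniquenames,
cv/term name pairs) are what loaders and exports speak.

Records are typed by controlled-vocabulary terms (cvterm rows) rather than
by dedicated tables: a genetic marker, a QTL and a linkage group are all
rows of ``feature`` distinguished only by ``type_id``.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Optional

import networkx as nx

from .errors import (
    ConflictError,
    DanglingOwnerError,
    StoreExistsError,
    TermLookupError,
)

SCHEMA_VERSION = "1.0"

STORE_FILENAME = "chado.sqlite"

#: relationship terms permitted in feature_relationship.type_id
ALLOWED_FEATURE_REL_TERMS = frozenset(
    {
        "part_of",
        "derives_from",
        "associated_with",
        "adjacent_to",
        "located_in",
        "instance_of",
        "contains",
        "derived_from",
    }
)

#: relationship terms permitted in stock_relationship.type_id
ALLOWED_STOCK_REL_TERMS = frozenset(
    {
        "paternal_parent_of",
        "maternal_parent_of",
        "mutational_parent_of",
        "sample_of",
        "clone_of",
        "member_of",
    }
)

PARENT_EDGE_TERMS = frozenset(
    {"paternal_parent_of", "maternal_parent_of", "mutational_parent_of"}
)

#: feature types placeable on a genetic map (featurepos.feature_id)
PLACEABLE_TYPES = frozenset(
    {"marker_locus", "QTL", "heritable_phenotypic_marker", "bin"}
)

# table -> (cv restriction for its type_id column); None = no restriction
TYPE_VOCAB_RULES = {
    "feature": "sequence",
    "stock": "local",
    "nd_experiment": "local",
}

# prop table -> (owner table, owner fk column)
PROP_TABLES = {
    "featureprop": ("feature", "feature_id"),
    "featuremapprop": ("featuremap", "featuremap_id"),
    "featureposprop": ("featurepos", "featurepos_id"),
    "stockprop": ("stock", "stock_id"),
    "cvtermprop": ("cvterm", "cvterm_id"),
    "nd_experimentprop": ("nd_experiment", "nd_experiment_id"),
    "eimageprop": ("eimage", "eimage_id"),
    "contactprop": ("contact", "contact_id"),
    "organismprop": ("organism", "organism_id"),
}


def _prop_ddl(table: str, owner_table: str, owner_col: str) -> str:
    return f"""
    CREATE TABLE {table} (
        {table}_id INTEGER PRIMARY KEY,
        {owner_col} INTEGER NOT NULL REFERENCES {owner_table}({owner_col}),
        type_id INTEGER NOT NULL REFERENCES cvterm(cvterm_id),
        value TEXT NOT NULL DEFAULT '',
        rank INTEGER NOT NULL DEFAULT 0,
        UNIQUE ({owner_col}, type_id, rank)
    )"""


def _linker_ddl(table: str, a: tuple[str, str], b: tuple[str, str]) -> str:
    (a_col, a_tab), (b_col, b_tab) = a, b
    return f"""
    CREATE TABLE {table} (
        {table}_id INTEGER PRIMARY KEY,
        {a_col} INTEGER NOT NULL REFERENCES {a_tab}({a_col}),
        {b_col} INTEGER NOT NULL REFERENCES {b_tab}({b_col}),
        UNIQUE ({a_col}, {b_col})
    )"""


_DDL: dict[str, str] = {}

_DDL["cv"] = """
    CREATE TABLE cv (
        cv_id INTEGER PRIMARY KEY,
        name TEXT NOT NULL UNIQUE,
        definition TEXT NOT NULL DEFAULT ''
    )"""

_DDL["db"] = """
    CREATE TABLE db (
        db_id INTEGER PRIMARY KEY,
        name TEXT NOT NULL UNIQUE,
        description TEXT NOT NULL DEFAULT '',
        urlprefix TEXT NOT NULL DEFAULT '',
        url TEXT NOT NULL DEFAULT ''
    )"""

_DDL["dbxref"] = """
    CREATE TABLE dbxref (
        dbxref_id INTEGER PRIMARY KEY,
        db_id INTEGER NOT NULL REFERENCES db(db_id),
        accession TEXT NOT NULL,
        version TEXT NOT NULL DEFAULT '',
        UNIQUE (db_id, accession, version)
    )"""

_DDL["cvterm"] = """
    CREATE TABLE cvterm (
        cvterm_id INTEGER PRIMARY KEY,
        cv_id INTEGER NOT NULL REFERENCES cv(cv_id),
        name TEXT NOT NULL,
        definition TEXT NOT NULL DEFAULT '',
        dbxref_id INTEGER REFERENCES dbxref(dbxref_id),
        is_obsolete INTEGER NOT NULL DEFAULT 0,
        is_relationshiptype INTEGER NOT NULL DEFAULT 0,
        UNIQUE (cv_id, name)
    )"""

_DDL["cvtermsynonym"] = """
    CREATE TABLE cvtermsynonym (
        cvtermsynonym_id INTEGER PRIMARY KEY,
        cvterm_id INTEGER NOT NULL REFERENCES cvterm(cvterm_id),
        synonym TEXT NOT NULL,
        UNIQUE (cvterm_id, synonym)
    )"""

_DDL["organism"] = """
    CREATE TABLE organism (
        organism_id INTEGER PRIMARY KEY,
        abbreviation TEXT NOT NULL DEFAULT '',
        genus TEXT NOT NULL,
        species TEXT NOT NULL,
        common_name TEXT NOT NULL DEFAULT '',
        UNIQUE (genus, species)
    )"""

_DDL["feature"] = """
    CREATE TABLE feature (
        feature_id INTEGER PRIMARY KEY,
        organism_id INTEGER NOT NULL REFERENCES organism(organism_id),
        name TEXT NOT NULL DEFAULT '',
        uniquename TEXT NOT NULL,
        residues TEXT NOT NULL DEFAULT '',
        seqlen INTEGER,
        type_id INTEGER NOT NULL REFERENCES cvterm(cvterm_id),
        is_analysis INTEGER NOT NULL DEFAULT 0,
        is_obsolete INTEGER NOT NULL DEFAULT 0,
        UNIQUE (organism_id, uniquename, type_id)
    )"""

_DDL["feature_relationship"] = """
    CREATE TABLE feature_relationship (
        feature_relationship_id INTEGER PRIMARY KEY,
        subject_id INTEGER NOT NULL REFERENCES feature(feature_id),
        object_id INTEGER NOT NULL REFERENCES feature(feature_id),
        type_id INTEGER NOT NULL REFERENCES cvterm(cvterm_id),
        rank INTEGER NOT NULL DEFAULT 0,
        UNIQUE (subject_id, object_id, type_id, rank)
    )"""

_DDL["featureloc"] = """
    CREATE TABLE featureloc (
        featureloc_id INTEGER PRIMARY KEY,
        feature_id INTEGER NOT NULL REFERENCES feature(feature_id),
        srcfeature_id INTEGER REFERENCES feature(feature_id),
        fmin INTEGER,
        fmax INTEGER,
        strand INTEGER NOT NULL DEFAULT 0,
        locgroup INTEGER NOT NULL DEFAULT 0,
        rank INTEGER NOT NULL DEFAULT 0,
        UNIQUE (feature_id, locgroup, rank)
    )"""

_DDL["feature_cvterm"] = """
    CREATE TABLE feature_cvterm (
        feature_cvterm_id INTEGER PRIMARY KEY,
        feature_id INTEGER NOT NULL REFERENCES feature(feature_id),
        cvterm_id INTEGER NOT NULL REFERENCES cvterm(cvterm_id),
        pub_id INTEGER REFERENCES pub(pub_id),
        rank INTEGER NOT NULL DEFAULT 0,
        UNIQUE (feature_id, cvterm_id, rank)
    )"""

_DDL["synonym"] = """
    CREATE TABLE synonym (
        synonym_id INTEGER PRIMARY KEY,
        name TEXT NOT NULL,
        type_id INTEGER REFERENCES cvterm(cvterm_id),
        synonym_sgml TEXT NOT NULL DEFAULT '',
        UNIQUE (name)
    )"""

_DDL["feature_synonym"] = """
    CREATE TABLE feature_synonym (
        feature_synonym_id INTEGER PRIMARY KEY,
        synonym_id INTEGER NOT NULL REFERENCES synonym(synonym_id),
        feature_id INTEGER NOT NULL REFERENCES feature(feature_id),
        pub_id INTEGER REFERENCES pub(pub_id),
        UNIQUE (synonym_id, feature_id)
    )"""

_DDL["pub"] = """
    CREATE TABLE pub (
        pub_id INTEGER PRIMARY KEY,
        uniquename TEXT NOT NULL UNIQUE,
        title TEXT NOT NULL DEFAULT '',
        type_id INTEGER REFERENCES cvterm(cvterm_id)
    )"""

_DDL["pubauthor"] = """
    CREATE TABLE pubauthor (
        pubauthor_id INTEGER PRIMARY KEY,
        pub_id INTEGER NOT NULL REFERENCES pub(pub_id),
        rank INTEGER NOT NULL DEFAULT 0,
        surname TEXT NOT NULL,
        givennames TEXT NOT NULL DEFAULT '',
        UNIQUE (pub_id, rank)
    )"""

_DDL["contact"] = """
    CREATE TABLE contact (
        contact_id INTEGER PRIMARY KEY,
        name TEXT NOT NULL UNIQUE,
        description TEXT NOT NULL DEFAULT '',
        type_id INTEGER REFERENCES cvterm(cvterm_id)
    )"""

_DDL["eimage"] = """
    CREATE TABLE eimage (
        eimage_id INTEGER PRIMARY KEY,
        eimage_data TEXT NOT NULL DEFAULT '',
        eimage_type TEXT NOT NULL DEFAULT '',
        image_uri TEXT NOT NULL UNIQUE
    )"""

_DDL["analysis"] = """
    CREATE TABLE analysis (
        analysis_id INTEGER PRIMARY KEY,
        name TEXT NOT NULL UNIQUE,
        description TEXT NOT NULL DEFAULT '',
        program TEXT NOT NULL DEFAULT 'unknown',
        programversion TEXT NOT NULL DEFAULT 'unknown',
        sourcename TEXT NOT NULL DEFAULT ''
    )"""

_DDL["analysisfeature"] = """
    CREATE TABLE analysisfeature (
        analysisfeature_id INTEGER PRIMARY KEY,
        feature_id INTEGER NOT NULL REFERENCES feature(feature_id),
        analysis_id INTEGER NOT NULL REFERENCES analysis(analysis_id),
        UNIQUE (feature_id, analysis_id)
    )"""

_DDL["featuremap"] = """
    CREATE TABLE featuremap (
        featuremap_id INTEGER PRIMARY KEY,
        name TEXT NOT NULL UNIQUE,
        description TEXT NOT NULL DEFAULT '',
        unittype_id INTEGER REFERENCES cvterm(cvterm_id)
    )"""

_DDL["featurepos"] = """
    CREATE TABLE featurepos (
        featurepos_id INTEGER PRIMARY KEY,
        featuremap_id INTEGER NOT NULL REFERENCES featuremap(featuremap_id),
        feature_id INTEGER NOT NULL REFERENCES feature(feature_id),
        map_feature_id INTEGER NOT NULL REFERENCES feature(feature_id),
        mappos REAL
    )"""

_DDL["stock"] = """
    CREATE TABLE stock (
        stock_id INTEGER PRIMARY KEY,
        organism_id INTEGER NOT NULL REFERENCES organism(organism_id),
        name TEXT NOT NULL DEFAULT '',
        uniquename TEXT NOT NULL,
        description TEXT NOT NULL DEFAULT '',
        type_id INTEGER NOT NULL REFERENCES cvterm(cvterm_id),
        UNIQUE (organism_id, uniquename, type_id)
    )"""

_DDL["stock_relationship"] = """
    CREATE TABLE stock_relationship (
        stock_relationship_id INTEGER PRIMARY KEY,
        subject_id INTEGER NOT NULL REFERENCES stock(stock_id),
        object_id INTEGER NOT NULL REFERENCES stock(stock_id),
        type_id INTEGER NOT NULL REFERENCES cvterm(cvterm_id),
        value TEXT NOT NULL DEFAULT '',
        rank INTEGER NOT NULL DEFAULT 0,
        UNIQUE (subject_id, object_id, type_id, rank)
    )"""

_DDL["stock_dbxref"] = """
    CREATE TABLE stock_dbxref (
        stock_dbxref_id INTEGER PRIMARY KEY,
        stock_id INTEGER NOT NULL REFERENCES stock(stock_id),
        dbxref_id INTEGER NOT NULL REFERENCES dbxref(dbxref_id),
        UNIQUE (stock_id, dbxref_id)
    )"""

_DDL["stockcollection"] = """
    CREATE TABLE stockcollection (
        stockcollection_id INTEGER PRIMARY KEY,
        type_id INTEGER REFERENCES cvterm(cvterm_id),
        contact_id INTEGER REFERENCES contact(contact_id),
        name TEXT NOT NULL DEFAULT '',
        uniquename TEXT NOT NULL UNIQUE
    )"""

_DDL["nd_geolocation"] = """
    CREATE TABLE nd_geolocation (
        nd_geolocation_id INTEGER PRIMARY KEY,
        description TEXT NOT NULL DEFAULT '',
        latitude REAL,
        longitude REAL,
        altitude REAL,
        geodetic_datum TEXT NOT NULL DEFAULT '',
        UNIQUE (description, latitude, longitude, altitude)
    )"""

_DDL["nd_experiment"] = """
    CREATE TABLE nd_experiment (
        nd_experiment_id INTEGER PRIMARY KEY,
        nd_geolocation_id INTEGER NOT NULL
            REFERENCES nd_geolocation(nd_geolocation_id),
        type_id INTEGER NOT NULL REFERENCES cvterm(cvterm_id)
    )"""

_DDL["nd_experiment_stock"] = """
    CREATE TABLE nd_experiment_stock (
        nd_experiment_stock_id INTEGER PRIMARY KEY,
        nd_experiment_id INTEGER NOT NULL
            REFERENCES nd_experiment(nd_experiment_id),
        stock_id INTEGER NOT NULL REFERENCES stock(stock_id),
        type_id INTEGER REFERENCES cvterm(cvterm_id),
        UNIQUE (nd_experiment_id, stock_id)
    )"""

_DDL["phenotype"] = """
    CREATE TABLE phenotype (
        phenotype_id INTEGER PRIMARY KEY,
        uniquename TEXT NOT NULL UNIQUE,
        name TEXT NOT NULL DEFAULT '',
        attr_id INTEGER REFERENCES cvterm(cvterm_id),
        value TEXT NOT NULL DEFAULT '',
        observable_id INTEGER REFERENCES cvterm(cvterm_id)
    )"""

_DDL["nd_experiment_phenotype"] = """
    CREATE TABLE nd_experiment_phenotype (
        nd_experiment_phenotype_id INTEGER PRIMARY KEY,
        nd_experiment_id INTEGER NOT NULL
            REFERENCES nd_experiment(nd_experiment_id),
        phenotype_id INTEGER NOT NULL REFERENCES phenotype(phenotype_id),
        UNIQUE (nd_experiment_id, phenotype_id)
    )"""

_DDL["genotype"] = """
    CREATE TABLE genotype (
        genotype_id INTEGER PRIMARY KEY,
        name TEXT NOT NULL DEFAULT '',
        uniquename TEXT NOT NULL UNIQUE,
        description TEXT NOT NULL DEFAULT '',
        type_id INTEGER REFERENCES cvterm(cvterm_id)
    )"""

_DDL["nd_experiment_genotype"] = """
    CREATE TABLE nd_experiment_genotype (
        nd_experiment_genotype_id INTEGER PRIMARY KEY,
        nd_experiment_id INTEGER NOT NULL
            REFERENCES nd_experiment(nd_experiment_id),
        genotype_id INTEGER NOT NULL REFERENCES genotype(genotype_id),
        UNIQUE (nd_experiment_id, genotype_id)
    )"""

_DDL["feature_genotype"] = """
    CREATE TABLE feature_genotype (
        feature_genotype_id INTEGER PRIMARY KEY,
        feature_id INTEGER NOT NULL REFERENCES feature(feature_id),
        genotype_id INTEGER NOT NULL REFERENCES genotype(genotype_id),
        rank INTEGER NOT NULL DEFAULT 0,
        UNIQUE (feature_id, genotype_id, rank)
    )"""

_DDL["phenstatement"] = """
    CREATE TABLE phenstatement (
        phenstatement_id INTEGER PRIMARY KEY,
        genotype_id INTEGER NOT NULL REFERENCES genotype(genotype_id),
        environment_id INTEGER NOT NULL
            REFERENCES nd_geolocation(nd_geolocation_id),
        phenotype_id INTEGER NOT NULL REFERENCES phenotype(phenotype_id),
        type_id INTEGER REFERENCES cvterm(cvterm_id),
        pub_id INTEGER REFERENCES pub(pub_id),
        UNIQUE (genotype_id, environment_id, phenotype_id, type_id)
    )"""

_DDL["project"] = """
    CREATE TABLE project (
        project_id INTEGER PRIMARY KEY,
        name TEXT NOT NULL UNIQUE,
        description TEXT NOT NULL DEFAULT ''
    )"""

_DDL["project_relationship"] = """
    CREATE TABLE project_relationship (
        project_relationship_id INTEGER PRIMARY KEY,
        subject_project_id INTEGER NOT NULL REFERENCES project(project_id),
        object_project_id INTEGER NOT NULL REFERENCES project(project_id),
        type_id INTEGER REFERENCES cvterm(cvterm_id),
        UNIQUE (subject_project_id, object_project_id)
    )"""

_DDL["library"] = """
    CREATE TABLE library (
        library_id INTEGER PRIMARY KEY,
        organism_id INTEGER NOT NULL REFERENCES organism(organism_id),
        name TEXT NOT NULL DEFAULT '',
        uniquename TEXT NOT NULL UNIQUE,
        type_id INTEGER REFERENCES cvterm(cvterm_id)
    )"""

# property tables (shared record/type/value/rank pattern)
for _t, (_ot, _oc) in PROP_TABLES.items():
    if _t != "cvtermprop":
        _DDL[_t] = _prop_ddl(_t, _ot, _oc)
# cvtermprop owner column collides with its own type_id fk naming; spell out
_DDL["cvtermprop"] = """
    CREATE TABLE cvtermprop (
        cvtermprop_id INTEGER PRIMARY KEY,
        cvterm_id INTEGER NOT NULL REFERENCES cvterm(cvterm_id),
        type_id INTEGER NOT NULL REFERENCES cvterm(cvterm_id),
        value TEXT NOT NULL DEFAULT '',
        rank INTEGER NOT NULL DEFAULT 0,
        UNIQUE (cvterm_id, type_id, rank)
    )"""

# plain two-way linker tables, standard and custom alike
_LINKERS = {
    "feature_pub": (("feature_id", "feature"), ("pub_id", "pub")),
    "feature_dbxref": (("feature_id", "feature"), ("dbxref_id", "dbxref")),
    "feature_project": (("feature_id", "feature"), ("project_id", "project")),
    "feature_contact": (("feature_id", "feature"), ("contact_id", "contact")),
    "feature_image": (("feature_id", "feature"), ("eimage_id", "eimage")),
    "stock_image": (("stock_id", "stock"), ("eimage_id", "eimage")),
    "organism_image": (("organism_id", "organism"), ("eimage_id", "eimage")),
    "eimage_contact": (("eimage_id", "eimage"), ("contact_id", "contact")),
    "featuremap_stock": (
        ("featuremap_id", "featuremap"),
        ("stock_id", "stock"),
    ),
    "featuremap_organism": (
        ("featuremap_id", "featuremap"),
        ("organism_id", "organism"),
    ),
    "featuremap_contact": (
        ("featuremap_id", "featuremap"),
        ("contact_id", "contact"),
    ),
    "featuremap_dbxref": (
        ("featuremap_id", "featuremap"),
        ("dbxref_id", "dbxref"),
    ),
    "featuremap_pub": (("featuremap_id", "featuremap"), ("pub_id", "pub")),
    "stockcollection_db": (
        ("stockcollection_id", "stockcollection"),
        ("db_id", "db"),
    ),
    "stockcollection_stock": (
        ("stockcollection_id", "stockcollection"),
        ("stock_id", "stock"),
    ),
    "library_stock": (("library_id", "library"), ("stock_id", "stock")),
    "library_contact": (("library_id", "library"), ("contact_id", "contact")),
    "analysis_organism": (
        ("analysis_id", "analysis"),
        ("organism_id", "organism"),
    ),
    "pubauthor_contact": (
        ("pubauthor_id", "pubauthor"),
        ("contact_id", "contact"),
    ),
    "nd_experiment_project": (
        ("nd_experiment_id", "nd_experiment"),
        ("project_id", "project"),
    ),
    "nd_experiment_contact": (
        ("nd_experiment_id", "nd_experiment"),
        ("contact_id", "contact"),
    ),
}
for _t, (_a, _b) in _LINKERS.items():
    _DDL[_t] = _linker_ddl(_t, _a, _b)

_DDL["organism_relationship"] = """
    CREATE TABLE organism_relationship (
        organism_relationship_id INTEGER PRIMARY KEY,
        subject_id INTEGER NOT NULL REFERENCES organism(organism_id),
        object_id INTEGER NOT NULL REFERENCES organism(organism_id),
        type_id INTEGER NOT NULL REFERENCES cvterm(cvterm_id),
        rank INTEGER NOT NULL DEFAULT 0,
        UNIQUE (subject_id, object_id, type_id, rank)
    )"""

_DDL["feature_stock"] = """
    CREATE TABLE feature_stock (
        feature_stock_id INTEGER PRIMARY KEY,
        feature_id INTEGER NOT NULL REFERENCES feature(feature_id),
        stock_id INTEGER NOT NULL REFERENCES stock(stock_id),
        type_id INTEGER REFERENCES cvterm(cvterm_id),
        UNIQUE (feature_id, stock_id, type_id)
    )"""

ALL_TABLES = tuple(_DDL)

#: the 22 custom linker/property/relationship tables beyond stock Chado 1.2
CUSTOM_TABLES = (
    "eimageprop",
    "eimage_contact",
    "feature_image",
    "stock_image",
    "organism_image",
    "featuremapprop",
    "featuremap_stock",
    "featuremap_organism",
    "feature_project",
    "organism_relationship",
    "stockcollection_db",
    "feature_stock",
    "feature_contact",
    "library_stock",
    "library_contact",
    "contactprop",
    "featuremap_contact",
    "featuremap_dbxref",
    "featureposprop",
    "organismprop",
    "analysis_organism",
    "pubauthor_contact",
)


@dataclass(frozen=True)
class Violation:
    """One conformance breach found by :meth:`Store.check_integrity`."""

    kind: str
    table: str
    record_id: int
    detail: str = ""


@dataclass
class ViolationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def by_kind(self, kind: str) -> list[Violation]:
        return [v for v in self.violations if v.kind == kind]

    def __len__(self) -> int:
        return len(self.violations)

    def __iter__(self):
        return iter(self.violations)


def _resolve_path(path: str | Path) -> Path:
    p = Path(path)
    if p.is_dir():
        return p / STORE_FILENAME
    return p


class Store:
    """Handle on one on-disk (or in-memory) store.

    Thin convenience layer over ``sqlite3``: surrogate-key inserts,
    natural-key lookups, the generic prop/rank machinery and the
    conformance validator. Domain logic lives in the loader modules.
    """

    def __init__(self, conn: sqlite3.Connection, path: Optional[Path] = None):
        self.conn = conn
        self.path = path
        self.conn.row_factory = sqlite3.Row
        self.conn.execute("PRAGMA foreign_keys = ON")

    # -- plumbing ---------------------------------------------------------

    def execute(self, sql: str, params: Iterable[Any] = ()) -> sqlite3.Cursor:
        return self.conn.execute(sql, tuple(params))

    def insert(self, table: str, **cols: Any) -> int:
        names = ", ".join(cols)
        marks = ", ".join("?" for _ in cols)
        try:
            cur = self.conn.execute(
                f"INSERT INTO {table} ({names}) VALUES ({marks})",
                tuple(cols.values()),
            )
        except sqlite3.IntegrityError as exc:
            raise ConflictError(f"{table}: {exc}") from exc
        return cur.lastrowid

    def row(self, sql: str, params: Iterable[Any] = ()) -> Optional[sqlite3.Row]:
        return self.execute(sql, params).fetchone()

    def scalar(self, sql: str, params: Iterable[Any] = ()) -> Any:
        r = self.execute(sql, params).fetchone()
        return None if r is None else r[0]

    def count(self, table: str) -> int:
        return self.scalar(f"SELECT COUNT(*) FROM {table}")

    def commit(self) -> None:
        self.conn.commit()

    def close(self) -> None:
        self.conn.commit()
        self.conn.close()

    def table_names(self) -> list[str]:
        return [
            r[0]
            for r in self.execute(
                "SELECT name FROM sqlite_master WHERE type='table' "
                "AND name NOT LIKE 'sqlite_%' ORDER BY name"
            )
        ]

    def ddl_sql(self) -> str:
        """The schema as plain CREATE TABLE text, one statement per table."""
        stmts = [_DDL[t].strip() + ";" for t in ALL_TABLES]
        return "\n\n".join(stmts) + "\n"

    # -- vocabulary primitives -------------------------------------------

    def ensure_cv(self, name: str, definition: str = "") -> int:
        cv_id = self.scalar("SELECT cv_id FROM cv WHERE name = ?", (name,))
        if cv_id is None:
            cv_id = self.insert("cv", name=name, definition=definition)
        return cv_id

    def get_cvterm_id(self, cv_name: str, term: str) -> Optional[int]:
        return self.scalar(
            "SELECT cvterm_id FROM cvterm JOIN cv USING (cv_id) "
            "WHERE cv.name = ? AND cvterm.name = ?",
            (cv_name, term),
        )

    def cvterm(self, cv_name: str, term: str) -> int:
        """Resolve (cv, name) to a cvterm_id; raise if absent."""
        term_id = self.get_cvterm_id(cv_name, term)
        if term_id is None:
            raise TermLookupError(f"no term {term!r} in vocabulary {cv_name!r}")
        return term_id

    def create_cvterm(
        self,
        cv_name: str,
        term: str,
        definition: str = "",
        accession: str = "",
        db_name: Optional[str] = None,
        is_relationshiptype: bool = False,
    ) -> int:
        cv_id = self.ensure_cv(cv_name)
        existing = self.get_cvterm_id(cv_name, term)
        if existing is not None:
            return existing
        dbxref_id = None
        if accession:
            db_id = self._ensure_db(db_name or cv_name)
            dbxref_id = self.scalar(
                "SELECT dbxref_id FROM dbxref WHERE db_id=? AND accession=?",
                (db_id, accession),
            )
            if dbxref_id is None:
                dbxref_id = self.insert(
                    "dbxref", db_id=db_id, accession=accession
                )
        return self.insert(
            "cvterm",
            cv_id=cv_id,
            name=term,
            definition=definition,
            dbxref_id=dbxref_id,
            is_relationshiptype=int(is_relationshiptype),
        )

    def _ensure_db(self, name: str, description: str = "", url: str = "") -> int:
        db_id = self.scalar("SELECT db_id FROM db WHERE name = ?", (name,))
        if db_id is None:
            db_id = self.insert(
                "db", name=name, description=description, url=url
            )
        return db_id

    def term_name(self, cvterm_id: int) -> str:
        return self.scalar(
            "SELECT name FROM cvterm WHERE cvterm_id = ?", (cvterm_id,)
        )

    # -- organisms --------------------------------------------------------

    def ensure_organism(self, name: str) -> int:
        """Resolve 'Genus species' (or a bare label) to an organism_id."""
        parts = name.strip().split(None, 1)
        genus = parts[0]
        species = parts[1] if len(parts) > 1 else "sp."
        org_id = self.scalar(
            "SELECT organism_id FROM organism WHERE genus=? AND species=?",
            (genus, species),
        )
        if org_id is None:
            org_id = self.insert("organism", genus=genus, species=species)
        return org_id

    # -- generic prop machinery ------------------------------------------

    def add_prop(
        self,
        prop_table: str,
        owner_id: int,
        vocabulary: str,
        term: str,
        value: str,
    ) -> int:
        """Attach a typed property; rank continues the per-(owner, term) run."""
        if prop_table not in PROP_TABLES:
            raise ValueError(f"unknown prop table {prop_table!r}")
        owner_table, owner_col = PROP_TABLES[prop_table]
        exists = self.scalar(
            f"SELECT 1 FROM {owner_table} WHERE {owner_col} = ?", (owner_id,)
        )
        if not exists:
            raise DanglingOwnerError(
                f"{prop_table}: no {owner_table} record with id {owner_id}"
            )
        term_id = self.get_cvterm_id(vocabulary, term)
        if term_id is None:
            if vocabulary != "local":
                raise TermLookupError(
                    f"no term {term!r} in vocabulary {vocabulary!r}"
                )
            term_id = self.create_cvterm("local", term)
        rank = self.scalar(
            f"SELECT COALESCE(MAX(rank), -1) + 1 FROM {prop_table} "
            f"WHERE {owner_col} = ? AND type_id = ?",
            (owner_id, term_id),
        )
        return self.insert(
            prop_table,
            **{owner_col: owner_id},
            type_id=term_id,
            value=value,
            rank=rank,
        )

    # -- feature / stock lookups -----------------------------------------

    def feature_id(
        self,
        uniquename: str,
        type_name: Optional[str] = None,
        organism_id: Optional[int] = None,
    ) -> Optional[int]:
        sql = (
            "SELECT feature_id FROM feature "
            "JOIN cvterm t ON t.cvterm_id = feature.type_id "
            "WHERE feature.uniquename = ?"
        )
        params: list[Any] = [uniquename.strip()]
        if type_name is not None:
            sql += " AND t.name = ?"
            params.append(type_name)
        if organism_id is not None:
            sql += " AND feature.organism_id = ?"
            params.append(organism_id)
        return self.scalar(sql, params)

    def stock_id(
        self, uniquename: str, type_name: Optional[str] = None
    ) -> Optional[int]:
        sql = (
            "SELECT stock_id FROM stock "
            "JOIN cvterm t ON t.cvterm_id = stock.type_id "
            "WHERE stock.uniquename = ?"
        )
        params: list[Any] = [uniquename.strip()]
        if type_name is not None:
            sql += " AND t.name = ?"
            params.append(type_name)
        return self.scalar(sql, params)

    def ensure_geolocation(
        self,
        description: str = "unspecified",
        latitude: Optional[float] = None,
        longitude: Optional[float] = None,
        altitude: Optional[float] = None,
    ) -> int:
        """Deduplicated lookup-or-create by (description, lat, lon, alt)."""
        row = self.row(
            "SELECT nd_geolocation_id FROM nd_geolocation WHERE description=? "
            "AND latitude IS ? AND longitude IS ? AND altitude IS ?",
            (description, latitude, longitude, altitude),
        )
        if row:
            return row[0]
        return self.insert(
            "nd_geolocation",
            description=description,
            latitude=latitude,
            longitude=longitude,
            altitude=altitude,
        )

    def ensure_contact(self, name: str) -> int:
        cid = self.scalar("SELECT contact_id FROM contact WHERE name=?", (name,))
        return cid if cid is not None else self.insert("contact", name=name)

    def ensure_pub(self, uniquename: str, title: str = "") -> int:
        pid = self.scalar(
            "SELECT pub_id FROM pub WHERE uniquename=?", (uniquename,)
        )
        if pid is None:
            pid = self.insert("pub", uniquename=uniquename, title=title)
        return pid

    def ensure_project(self, name: str, description: str = "") -> int:
        pid = self.scalar(
            "SELECT project_id FROM project WHERE name=?", (name,)
        )
        if pid is None:
            pid = self.insert("project", name=name, description=description)
        return pid

    def link(self, table: str, **cols: Any) -> int:
        """Insert into a linker table, ignoring an exact duplicate."""
        names = ", ".join(cols)
        marks = ", ".join("?" for _ in cols)
        cur = self.conn.execute(
            f"INSERT OR IGNORE INTO {table} ({names}) VALUES ({marks})",
            tuple(cols.values()),
        )
        if cur.lastrowid:
            return cur.lastrowid
        where = " AND ".join(f"{c} IS ?" for c in cols)
        return self.scalar(
            f"SELECT {table}_id FROM {table} WHERE {where}",
            tuple(cols.values()),
        )

    # -- conformance validation ------------------------------------------

    def check_integrity(self) -> ViolationReport:
        """Audit the whole store against the storage conventions.

        An empty report means the store is conformant; each violation
        carries a stable ``kind`` and the surrogate id of the offending
        record so corrupted rows can be pinpointed.
        """
        report = ViolationReport()
        add = report.violations.append

        # dangling foreign keys (corruption can only arise with pragmas off)
        for row in self.execute("PRAGMA foreign_key_check"):
            table, rowid, parent, _fkid = row
            add(
                Violation(
                    "dangling_fk",
                    table,
                    rowid if rowid is not None else -1,
                    f"references missing {parent} row",
                )
            )

        # type terms must come from the vocabulary assigned to their table
        for table, cv_name in TYPE_VOCAB_RULES.items():
            pk = f"{table}_id"
            for row in self.execute(
                f"SELECT {table}.{pk} AS rid, cvterm.name AS tname, cv.name AS cvname "
                f"FROM {table} JOIN cvterm ON cvterm.cvterm_id = {table}.type_id "
                "JOIN cv USING (cv_id)"
            ):
                if row["cvname"] != cv_name:
                    add(
                        Violation(
                            "bad_type_vocabulary",
                            table,
                            row["rid"],
                            f"type {row['tname']!r} is in cv {row['cvname']!r}, "
                            f"expected {cv_name!r}",
                        )
                    )

        # relationship types restricted to the registered closed sets
        for table, allowed in (
            ("feature_relationship", ALLOWED_FEATURE_REL_TERMS),
            ("stock_relationship", ALLOWED_STOCK_REL_TERMS),
        ):
            pk = f"{table}_id"
            for row in self.execute(
                f"SELECT {table}.{pk} AS rid, cvterm.name AS tname "
                f"FROM {table} JOIN cvterm ON cvterm.cvterm_id = {table}.type_id"
            ):
                if row["tname"] not in allowed:
                    add(
                        Violation(
                            "disallowed_relationship_type",
                            table,
                            row["rid"],
                            f"type {row['tname']!r} not an allowed relationship term",
                        )
                    )

        # phenotype uniquename convention: <descriptor>_<value>
        for row in self.execute(
            "SELECT phenotype_id, uniquename, value, cvterm.name AS attr "
            "FROM phenotype LEFT JOIN cvterm ON cvterm.cvterm_id = phenotype.attr_id"
        ):
            expected = f"{row['attr']}_{row['value']}" if row["attr"] else None
            if expected is None or row["uniquename"] != expected:
                add(
                    Violation(
                        "bad_phenotype_uniquename",
                        "phenotype",
                        row["phenotype_id"],
                        f"uniquename {row['uniquename']!r} != {expected!r}",
                    )
                )

        # genotype conventions: canonical description, uniquename rule
        from .phenogeno import canonical_description

        for row in self.execute(
            "SELECT genotype_id, uniquename, description FROM genotype"
        ):
            desc = row["description"]
            alleles = desc.split("|") if desc else []
            canonical = canonical_description(alleles) if alleles else ""
            if desc != canonical:
                add(
                    Violation(
                        "non_canonical_genotype",
                        "genotype",
                        row["genotype_id"],
                        f"description {desc!r}, canonical {canonical!r}",
                    )
                )
        for row in self.execute(
            "SELECT g.genotype_id AS gid, g.uniquename AS gun, "
            "g.description AS des, f.uniquename AS fun "
            "FROM genotype g JOIN feature_genotype fg USING (genotype_id) "
            "JOIN feature f USING (feature_id)"
        ):
            expected = f"{row['fun']}_{row['des']}"
            if row["gun"] != expected:
                add(
                    Violation(
                        "bad_genotype_uniquename",
                        "genotype",
                        row["gid"],
                        f"uniquename {row['gun']!r} != {expected!r}",
                    )
                )

        # primer uniquename convention: <marker uniquename>.<label>
        for row in self.execute(
            "SELECT p.feature_id AS pid, p.uniquename AS pun, "
            "m.uniquename AS mun "
            "FROM feature p "
            "JOIN cvterm pt ON pt.cvterm_id = p.type_id AND pt.name = 'primer' "
            "JOIN feature_relationship fr ON fr.subject_id = p.feature_id "
            "JOIN cvterm rt ON rt.cvterm_id = fr.type_id "
            "AND rt.name = 'adjacent_to' "
            "JOIN feature m ON m.feature_id = fr.object_id "
            "JOIN cvterm mt ON mt.cvterm_id = m.type_id "
            "AND mt.name = 'genetic_marker'"
        ):
            if not row["pun"].startswith(row["mun"] + "."):
                add(
                    Violation(
                        "bad_primer_uniquename",
                        "feature",
                        row["pid"],
                        f"primer {row['pun']!r} not '<marker>.<label>' for "
                        f"marker {row['mun']!r}",
                    )
                )

        # pedigree must be acyclic over *_parent_of edges
        graph = nx.DiGraph()
        edge_ids: dict[tuple[int, int], list[int]] = {}
        for row in self.execute(
            "SELECT sr.stock_relationship_id AS rid, sr.subject_id AS s, "
            "sr.object_id AS o, cvterm.name AS tname "
            "FROM stock_relationship sr "
            "JOIN cvterm ON cvterm.cvterm_id = sr.type_id"
        ):
            if row["tname"] in PARENT_EDGE_TERMS:
                graph.add_edge(row["s"], row["o"])
                edge_ids.setdefault((row["s"], row["o"]), []).append(row["rid"])
        for scc in nx.strongly_connected_components(graph):
            if len(scc) < 2 and not any(
                graph.has_edge(n, n) for n in scc
            ):
                continue
            for (s, o), rids in edge_ids.items():
                if s in scc and o in scc:
                    for rid in rids:
                        add(
                            Violation(
                                "pedigree_cycle",
                                "stock_relationship",
                                rid,
                                f"edge {s}->{o} lies on a pedigree cycle",
                            )
                        )

        # every map placement needs a numeric start property
        start_ids = [
            r[0]
            for r in self.execute(
                "SELECT cvterm_id FROM cvterm JOIN cv USING (cv_id) "
                "WHERE cv.name='local' AND cvterm.name='start'"
            )
        ]
        for row in self.execute("SELECT featurepos_id FROM featurepos"):
            fp = row[0]
            has_start = start_ids and self.scalar(
                "SELECT 1 FROM featureposprop WHERE featurepos_id=? "
                f"AND type_id IN ({','.join('?' * len(start_ids))})",
                [fp, *start_ids],
            )
            if not has_start:
                add(
                    Violation(
                        "missing_start_prop",
                        "featurepos",
                        fp,
                        "placement has no 'start' position property",
                    )
                )

        # featurepos feature types restricted to placeable kinds
        for row in self.execute(
            "SELECT fp.featurepos_id AS rid, t.name AS tname "
            "FROM featurepos fp JOIN feature f USING (feature_id) "
            "JOIN cvterm t ON t.cvterm_id = f.type_id"
        ):
            if row["tname"] not in PLACEABLE_TYPES:
                add(
                    Violation(
                        "bad_type_vocabulary",
                        "featurepos",
                        row["rid"],
                        f"placed feature type {row['tname']!r} not placeable",
                    )
                )

        # interbase coordinates: 0 <= fmin <= fmax
        for row in self.execute(
            "SELECT featureloc_id, fmin, fmax FROM featureloc "
            "WHERE fmin IS NOT NULL AND fmax IS NOT NULL "
            "AND (fmin > fmax OR fmin < 0)"
        ):
            add(
                Violation(
                    "bad_featureloc_range",
                    "featureloc",
                    row["featureloc_id"],
                    f"fmin={row['fmin']}, fmax={row['fmax']}",
                )
            )

        # residues/seqlen agreement
        for row in self.execute(
            "SELECT feature_id, uniquename, LENGTH(residues) AS n, seqlen "
            "FROM feature WHERE residues != '' AND seqlen IS NOT LENGTH(residues)"
        ):
            add(
                Violation(
                    "bad_seqlen",
                    "feature",
                    row["feature_id"],
                    f"{row['uniquename']}: seqlen {row['seqlen']} != "
                    f"len(residues) {row['n']}",
                )
            )

        return report


def init_store(path: str | Path) -> Store:
    """Create the full schema at *path* (a file, or a directory to hold one).

    Refuses to touch a file that already contains tables.
    """
    db_path = _resolve_path(path)
    if db_path.exists() and db_path.stat().st_size > 0:
        probe = sqlite3.connect(db_path)
        try:
            n = probe.execute(
                "SELECT COUNT(*) FROM sqlite_master WHERE type='table'"
            ).fetchone()[0]
        finally:
            probe.close()
        if n:
            raise StoreExistsError(f"store at {db_path} is already populated")
    db_path.parent.mkdir(parents=True, exist_ok=True)
    conn = sqlite3.connect(db_path)
    store = Store(conn, db_path)
    _create_schema(store)
    return store


def open_store(path: str | Path) -> Store:
    db_path = _resolve_path(path)
    if not db_path.exists():
        raise FileNotFoundError(f"no store at {db_path}")
    return Store(sqlite3.connect(db_path), db_path)


def memory_store() -> Store:
    """A fresh in-memory store (tests, import staging)."""
    store = Store(sqlite3.connect(":memory:"))
    _create_schema(store)
    return store


def _create_schema(store: Store) -> None:
    for table in ALL_TABLES:
        store.conn.execute(_DDL[table])
    store.conn.execute(
        "CREATE TABLE chadolite_meta (key TEXT PRIMARY KEY, value TEXT)"
    )
    store.conn.execute(
        "INSERT INTO chadolite_meta VALUES ('schema_version', ?)",
        (SCHEMA_VERSION,),
    )
    store.commit()
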