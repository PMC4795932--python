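"""Germplasm, pedigrees, samples/clones, stock collections and passports.

Every germplasm entity — population, cultivar, breeding line, wild
accession, clone, experimental sample — is a stock row typed by an
in-house term. Pedigree edges read "<parent> ..._parent_of <child>"
(subject = parent, object = child) and must stay acyclic; a child gets at
most one maternal and one paternal parent. Samples and clones hang off
their germplasm via sample_of / clone_of edges. Stock-center collections
pair a stockcollection row with a db row (same code), accessions being
dbxrefs whose accession string doubles as the stock display name.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import ConflictError, TermLookupError, ValidationError
from .store import PARENT_EDGE_TERMS, Store
from .vocab import GERMPLASM_TYPES

ROLE_TERMS = {
    "maternal": "maternal_parent_of",
    "paternal": "paternal_parent_of",
    "mutational": "mutational_parent_of",
}


@dataclass
class GermplasmInput:
    name: str
    organism: str
    type: str = "cultivar"
    aliases: list[str] = field(default_factory=list)
    description: str = ""
    images: list[dict[str, str]] = field(default_factory=list)


@dataclass
class PassportRecord:
    stock: str
    location: str = "unspecified"
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    altitude: Optional[float] = None
    props: dict[str, str] = field(default_factory=dict)
    collector: str = ""


def add_germplasm(store: Store, g: GermplasmInput) -> int:
    if g.type not in GERMPLASM_TYPES:
        raise TermLookupError(
            f"germplasm type {g.type!r} not one of {sorted(GERMPLASM_TYPES)}"
        )
    org_id = store.ensure_organism(g.organism)
    type_id = store.cvterm("local", g.type)
    name = g.name.strip()
    if store.scalar(
        "SELECT 1 FROM stock WHERE organism_id=? AND uniquename=? AND type_id=?",
        (org_id, name, type_id),
    ):
        raise ConflictError(f"stock {name!r} ({g.type}) already exists")
    stock_id = store.insert(
        "stock",
        organism_id=org_id,
        uniquename=name,
        name=name,
        type_id=type_id,
    )
    for alias in g.aliases:
        if alias:
            store.add_prop("stockprop", stock_id, "local", "alias", alias)
    if g.description:
        store.add_prop(
            "stockprop", stock_id, "local", "description", g.description
        )
    for image in g.images:
        eimage_id = store.link("eimage", image_uri=image["uri"])
        store.link("stock_image", stock_id=stock_id, eimage_id=eimage_id)
        if image.get("title"):
            store.add_prop("eimageprop", eimage_id, "local", "title", image["title"])
        if image.get("description"):
            store.add_prop(
                "eimageprop", eimage_id, "local", "description",
                image["description"],
            )
        if image.get("provider"):
            store.link(
                "eimage_contact",
                eimage_id=eimage_id,
                contact_id=store.ensure_contact(image["provider"]),
            )
    store.commit()
    return stock_id


def _parents_of(store: Store, stock_id: int) -> list[int]:
    """Immediate parents over *_parent_of edges (subject = parent)."""
    marks = ",".join("?" * len(PARENT_EDGE_TERMS))
    return [
        r[0]
        for r in store.execute(
            "SELECT sr.subject_id FROM stock_relationship sr "
            "JOIN cvterm t ON t.cvterm_id = sr.type_id "
            f"WHERE sr.object_id = ? AND t.name IN ({marks})",
            [stock_id, *sorted(PARENT_EDGE_TERMS)],
        )
    ]


def _ancestor_path(store: Store, start: int, goal: int) -> Optional[list[int]]:
    """BFS path start -> ... -> goal climbing parent edges, or None."""
    queue = deque([[start]])
    seen = {start}
    while queue:
        path = queue.popleft()
        if path[-1] == goal:
            return path
        for parent in _parents_of(store, path[-1]):
            if parent not in seen:
                seen.add(parent)
                queue.append(path + [parent])
    return None


def add_pedigree_edge(store: Store, child: str, parent: str, role: str) -> int:
    """Add one pedigree edge; rejects cycles and duplicate mother/father."""
    if role not in ROLE_TERMS:
        raise ValidationError(f"role must be one of {sorted(ROLE_TERMS)}")
    child_id = store.stock_id(child)
    parent_id = store.stock_id(parent)
    if child_id is None or parent_id is None:
        missing = child if child_id is None else parent
        raise ValidationError(f"stock {missing!r} not found")
    if child_id == parent_id:
        raise ValidationError(f"{child!r} cannot be its own parent")
    term = ROLE_TERMS[role]
    if role in ("maternal", "paternal"):
        existing = store.scalar(
            "SELECT 1 FROM stock_relationship sr "
            "JOIN cvterm t ON t.cvterm_id = sr.type_id "
            "WHERE sr.object_id = ? AND t.name = ?",
            (child_id, term),
        )
        if existing:
            raise ConflictError(f"{child!r} already has a {role} parent")
    # a cycle would form iff the child is already an ancestor of the parent
    path = _ancestor_path(store, parent_id, child_id)
    if path is not None:
        names = [
            store.scalar("SELECT uniquename FROM stock WHERE stock_id=?", (s,))
            for s in path
        ]
        raise ValidationError(
            f"edge {parent!r} -> {child!r} would close a pedigree cycle "
            f"via {' -> '.join(names)}"
        )
    rel_id = store.insert(
        "stock_relationship",
        subject_id=parent_id,
        object_id=child_id,
        type_id=store.cvterm("local", term),
    )
    store.commit()
    return rel_id


def _derive(store: Store, germplasm: str, new_id: str, kind: str) -> int:
    germ_id = store.stock_id(germplasm)
    if germ_id is None:
        raise ValidationError(f"germplasm {germplasm!r} not found")
    org_id = store.scalar(
        "SELECT organism_id FROM stock WHERE stock_id=?", (germ_id,)
    )
    type_id = store.cvterm("local", kind)
    if store.scalar(
        "SELECT 1 FROM stock WHERE organism_id=? AND uniquename=? AND type_id=?",
        (org_id, new_id.strip(), type_id),
    ):
        raise ConflictError(f"{kind} {new_id!r} already exists")
    stock_id = store.insert(
        "stock",
        organism_id=org_id,
        uniquename=new_id.strip(),
        name=new_id.strip(),
        type_id=type_id,
    )
    store.insert(
        "stock_relationship",
        subject_id=stock_id,
        object_id=germ_id,
        type_id=store.cvterm("local", f"{kind}_of"),
    )
    store.commit()
    return stock_id


def derive_sample(store: Store, germplasm: str, sample_id: str) -> int:
    """New 'sample' stock, sample_of its germplasm."""
    return _derive(store, germplasm, sample_id, "sample")


def derive_clone(store: Store, germplasm: str, clone_id: str) -> int:
    """New 'clone' stock, clone_of its germplasm."""
    return _derive(store, germplasm, clone_id, "clone")


def register_collection(
    store: Store, code: str, name: str, url: str = "", description: str = ""
) -> int:
    """A stock-center collection: stockcollection + db rows sharing *code*."""
    if store.scalar(
        "SELECT 1 FROM stockcollection WHERE uniquename=?", (code,)
    ) or store.scalar("SELECT 1 FROM db WHERE name=?", (code,)):
        raise ConflictError(f"collection code {code!r} already registered")
    coll_id = store.insert("stockcollection", uniquename=code, name=name)
    db_id = store.insert("db", name=code, description=description, url=url)
    store.insert("stockcollection_db", stockcollection_id=coll_id, db_id=db_id)
    store.commit()
    return coll_id


def add_accession(
    store: Store, collection_code: str, stock: str, accession_id: str
) -> int:
    """File a stock in a collection under its accession identifier.

    The accession string becomes both dbxref.accession and the stock's
    display name.
    """
    coll_id = store.scalar(
        "SELECT stockcollection_id FROM stockcollection WHERE uniquename=?",
        (collection_code,),
    )
    if coll_id is None:
        raise ValidationError(f"unknown collection {collection_code!r}")
    stock_id = store.stock_id(stock)
    if stock_id is None:
        raise ValidationError(f"unknown stock {stock!r}")
    db_id = store.scalar("SELECT db_id FROM db WHERE name=?", (collection_code,))
    dbxref_id = store.insert("dbxref", db_id=db_id, accession=accession_id)
    store.execute(
        "UPDATE stock SET name=? WHERE stock_id=?", (accession_id, stock_id)
    )
    store.link("stock_dbxref", stock_id=stock_id, dbxref_id=dbxref_id)
    store.link(
        "stockcollection_stock", stockcollection_id=coll_id, stock_id=stock_id
    )
    store.commit()
    return dbxref_id


def record_passport(store: Store, p: PassportRecord) -> int:
    """One 'passport' assay event tying a stock to its collection site."""
    stock_id = store.stock_id(p.stock)
    if stock_id is None:
        raise ValidationError(f"unknown stock {p.stock!r}")
    if not p.location and p.latitude is None and p.longitude is None:
        raise ValidationError("passport needs a location description or coordinates")
    geo_id = store.ensure_geolocation(
        p.location or "unspecified", p.latitude, p.longitude, p.altitude
    )
    exp_id = store.insert(
        "nd_experiment",
        nd_geolocation_id=geo_id,
        type_id=store.cvterm("local", "passport"),
    )
    store.insert(
        "nd_experiment_stock", nd_experiment_id=exp_id, stock_id=stock_id
    )
    for term in ("population_size", "sample_size", "comments"):
        value = p.props.get(term, "")
        if value:
            store.add_prop("nd_experimentprop", exp_id, "local", term, value)
    if p.collector:
        store.link(
            "nd_experiment_contact",
            nd_experiment_id=exp_id,
            contact_id=store.ensure_contact(p.collector),
        )
    store.commit()
    return exp_id


# ---------------------------------------------------------------------------
# tab-delimited loader templates


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def load_germplasm_tsv(store: Store, path: str | Path) -> int:
    df = _read_tsv(path)
    for _, row in df.iterrows():
        aliases = [a for a in row.get("aliases", "").split(";") if a]
        add_germplasm(
            store,
            GermplasmInput(
                name=row["name"],
                organism=row["organism"],
                type=row.get("type", "cultivar") or "cultivar",
                aliases=aliases,
                description=row.get("description", ""),
            ),
        )
    return len(df)


def load_pedigree_tsv(store: Store, path: str | Path) -> int:
    """pedigree.tsv: child, maternal_parent, paternal_parent, mutational_parent."""
    df = _read_tsv(path)
    edges = 0
    for _, row in df.iterrows():
        for role in ("maternal", "paternal", "mutational"):
            parent = row.get(f"{role}_parent", "")
            if parent:
                add_pedigree_edge(store, row["child"], parent, role)
                edges += 1
    return edges


def load_samples_tsv(store: Store, path: str | Path) -> int:
    """samples.tsv: germplasm, sample (one derived sample stock per row)."""
    df = _read_tsv(path)
    for _, row in df.iterrows():
        derive_sample(store, row["germplasm"], row["sample"])
    return len(df)


def load_collections_tsv(store: Store, path: str | Path) -> int:
    df = _read_tsv(path)
    for _, row in df.iterrows():
        register_collection(
            store,
            code=row["code"],
            name=row["name"],
            url=row.get("url", ""),
            description=row.get("description", ""),
        )
    return len(df)


def load_accessions_tsv(store: Store, path: str | Path) -> int:
    df = _read_tsv(path)
    for _, row in df.iterrows():
        add_accession(store, row["collection"], row["stock"], row["accession"])
    return len(df)


def load_passport_tsv(store: Store, path: str | Path) -> int:
    df = _read_tsv(path)
    for _, row in df.iterrows():
        record_passport(
            store,
            PassportRecord(
                stock=row["stock"],
                location=row.get("location", "unspecified") or "unspecified",
                latitude=float(row["latitude"]) if row.get("latitude") else None,
                longitude=float(row["longitude"]) if row.get("longitude") else None,
                altitude=float(row["altitude"]) if row.get("altitude") else None,
                props={
                    t: row.get(t, "")
                    for t in ("population_size", "sample_size", "comments")
                    if row.get(t, "")
                },
                collector=row.get("collector", ""),
            ),
        )
    return len(df)
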