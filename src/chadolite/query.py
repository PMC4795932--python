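"""Trait/map/pedigree/marker queries and the flat-file round trip.

Exports are one TSV per table, speaking natural keys only (uniquenames,
cv:term pairs), never surrogate ids, so a diff between two exports is
human-readable and an export can be re-imported into a fresh store.
Composite natural keys join their components with '::'. nd_experiment
rows have no natural key of their own; they are keyed by their position
in a canonical sort of their full linked content, which is stable across
export -> import -> export.
"""

from __future__ import annotations

import json
import warnings
from collections import deque
from pathlib import Path
from typing import Any, Optional

from .errors import ImportError_, ValidationError
from .store import (
    PARENT_EDGE_TERMS,
    SCHEMA_VERSION,
    Store,
    memory_store,
)

SEP = "::"

#: dependency-ordered table list driving both export and import
EXPORT_ORDER = (
    "cv",
    "db",
    "dbxref",
    "organism",
    "cvterm",
    "cvtermsynonym",
    "cvtermprop",
    "contact",
    "contactprop",
    "pub",
    "pubauthor",
    "pubauthor_contact",
    "analysis",
    "project",
    "project_relationship",
    "eimage",
    "eimageprop",
    "eimage_contact",
    "organismprop",
    "organism_relationship",
    "organism_image",
    "feature",
    "featureprop",
    "featureloc",
    "feature_relationship",
    "synonym",
    "feature_synonym",
    "feature_cvterm",
    "feature_pub",
    "feature_dbxref",
    "feature_project",
    "feature_contact",
    "feature_image",
    "analysisfeature",
    "analysis_organism",
    "stock",
    "stockprop",
    "stock_relationship",
    "stock_dbxref",
    "stock_image",
    "feature_stock",
    "featuremap",
    "featuremapprop",
    "featuremap_stock",
    "featuremap_organism",
    "featuremap_contact",
    "featuremap_dbxref",
    "featuremap_pub",
    "featurepos",
    "featureposprop",
    "stockcollection",
    "stockcollection_db",
    "stockcollection_stock",
    "library",
    "library_stock",
    "library_contact",
    "genotype",
    "feature_genotype",
    "phenotype",
    "nd_geolocation",
    "nd_experiment",
    "nd_experimentprop",
    "nd_experiment_stock",
    "nd_experiment_project",
    "nd_experiment_contact",
    "nd_experiment_phenotype",
    "nd_experiment_genotype",
    "phenstatement",
)

#: exported columns whose joined values form the table's natural key
NK_COLS: dict[str, tuple[str, ...]] = {
    "cv": ("name",),
    "db": ("name",),
    "dbxref": ("db_id", "accession", "version"),
    "organism": ("genus", "species"),
    "cvterm": ("cv_id", "name"),
    "contact": ("name",),
    "pub": ("uniquename",),
    "pubauthor": ("pub_id", "rank"),
    "analysis": ("name",),
    "project": ("name",),
    "eimage": ("image_uri",),
    "feature": ("organism_id", "uniquename", "type_id"),
    "synonym": ("name",),
    "stock": ("organism_id", "uniquename", "type_id"),
    "featuremap": ("name",),
    "featurepos": ("featuremap_id", "feature_id", "map_feature_id"),
    "stockcollection": ("uniquename",),
    "library": ("uniquename",),
    "genotype": ("uniquename",),
    "phenotype": ("uniquename",),
    "nd_geolocation": ("description", "latitude", "longitude", "altitude"),
    "nd_experiment": ("key",),
}


def _fmt(value: Any) -> str:
    if value is None:
        return ""
    text = repr(value) if isinstance(value, float) else str(value)
    if "\t" in text or "\n" in text:
        raise ValidationError(f"value not exportable to TSV: {text!r}")
    return text


def _table_columns(store: Store, table: str) -> list[tuple[str, str]]:
    """(name, declared type) for every column except the surrogate key."""
    pk = f"{table}_id"
    return [
        (r["name"], r["type"])
        for r in store.execute(f"PRAGMA table_info({table})")
        if r["name"] != pk
    ]


def _fk_targets(store: Store, table: str) -> dict[str, str]:
    """column name -> referenced table."""
    return {
        r["from"]: r["table"]
        for r in store.execute(f"PRAGMA foreign_key_list({table})")
    }


def _experiment_signature(store: Store, exp_id: int, nk: dict) -> tuple:
    """Canonical content tuple of one nd_experiment (order-free links)."""
    row = store.row(
        "SELECT nd_geolocation_id, type_id FROM nd_experiment "
        "WHERE nd_experiment_id=?",
        (exp_id,),
    )
    parts: list[Any] = [
        nk["cvterm"][row["type_id"]],
        nk["nd_geolocation"][row["nd_geolocation_id"]],
    ]
    for table, col, target in (
        ("nd_experiment_stock", "stock_id", "stock"),
        ("nd_experiment_project", "project_id", "project"),
        ("nd_experiment_contact", "contact_id", "contact"),
        ("nd_experiment_phenotype", "phenotype_id", "phenotype"),
        ("nd_experiment_genotype", "genotype_id", "genotype"),
    ):
        linked = sorted(
            nk[target][r[0]]
            for r in store.execute(
                f"SELECT {col} FROM {table} WHERE nd_experiment_id=?", (exp_id,)
            )
        )
        parts.append(tuple(linked))
    props = sorted(
        (nk["cvterm"][r["type_id"]], r["value"], r["rank"])
        for r in store.execute(
            "SELECT type_id, value, rank FROM nd_experimentprop "
            "WHERE nd_experiment_id=?",
            (exp_id,),
        )
    )
    parts.append(tuple(props))
    return tuple(parts)


def export_all(store: Store, outdir: str | Path) -> list[Path]:
    """Write one sorted TSV per table plus a manifest; returns file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nk: dict[str, dict[int, str]] = {}
    written = []
    counts = {}
    for table in EXPORT_ORDER:
        pk = f"{table}_id"
        cols = _table_columns(store, table)
        fk = _fk_targets(store, table)
        out_rows: list[tuple[int, dict[str, str]]] = []
        for row in store.execute(f"SELECT * FROM {table}"):
            out: dict[str, str] = {}
            for name, _type in cols:
                value = row[name]
                if name in fk and value is not None:
                    out[name] = nk[fk[name]][value]
                else:
                    out[name] = _fmt(value)
            out_rows.append((row[pk], out))
        header = [c for c, _ in cols]
        if table == "nd_experiment":
            signatures = sorted(
                (_experiment_signature(store, rid, nk), rid)
                for rid, _ in out_rows
            )
            keys = {rid: f"E{i:06d}" for i, (_, rid) in enumerate(signatures)}
            for rid, out in out_rows:
                out["key"] = keys[rid]
            header = ["key"] + header
        if table in NK_COLS:
            nk[table] = {
                rid: SEP.join(out[c] for c in NK_COLS[table])
                for rid, out in out_rows
            }
        lines = sorted(
            "\t".join(out[c] for c in header) for _, out in out_rows
        )
        path = outdir / f"{table}.tsv"
        path.write_text("\t".join(header) + "\n" + "".join(l + "\n" for l in lines))
        written.append(path)
        counts[table] = len(out_rows)
    manifest = {"schema_version": SCHEMA_VERSION, "row_counts": counts}
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(mpath)
    return written


def _parse(value: str, declared: str) -> Any:
    if value == "":
        return None if declared.upper() in ("INTEGER", "REAL") else ""
    if declared.upper() == "INTEGER":
        return int(value)
    if declared.upper() == "REAL":
        return float(value)
    return value


def import_all(indir: str | Path, target: Optional[Store] = None) -> Store:
    """Rebuild a store from an export directory (fresh in-memory by default)."""
    indir = Path(indir)
    manifest_path = indir / "manifest.json"
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        version = manifest.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ImportError_(
                f"schema version mismatch: export {version!r}, "
                f"store {SCHEMA_VERSION!r}"
            )
    store = target if target is not None else memory_store()
    nk: dict[str, dict[str, int]] = {}
    for table in EXPORT_ORDER:
        path = indir / f"{table}.tsv"
        if not path.exists():
            continue
        cols = dict(_table_columns(store, table))
        fk = _fk_targets(store, table)
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for col in header:
                if col not in cols and not (
                    table == "nd_experiment" and col == "key"
                ):
                    raise ImportError_(
                        f"{path.name}: unknown column {col!r}"
                    )
            for line in fh:
                values = line.rstrip("\n").split("\t")
                record: dict[str, Any] = {}
                raw = dict(zip(header, values))
                for col, text in raw.items():
                    if col == "key":
                        continue
                    if col in fk:
                        if text == "":
                            record[col] = None
                        else:
                            try:
                                record[col] = nk[fk[col]][text]
                            except KeyError:
                                raise ImportError_(
                                    f"{path.name}: unresolved reference "
                                    f"{text!r} in column {col!r}"
                                ) from None
                    else:
                        record[col] = _parse(text, cols[col])
                rid = store.insert(table, **record)
                if table in NK_COLS:
                    key = SEP.join(raw[c] for c in NK_COLS[table])
                    nk.setdefault(table, {})[key] = rid
    store.commit()
    return store


# ---------------------------------------------------------------------------
# queries


def _trait_term_ids(store: Store, trait: str) -> list[int]:
    ids = []
    for cv in ("trait_ontology", "local_trait"):
        tid = store.get_cvterm_id(cv, trait)
        if tid is not None:
            ids.append(tid)
    return ids


def _descriptor_term_ids(store: Store, trait: str) -> list[int]:
    """Descriptor terms named after the trait, plus descriptors whose
    'standard_of' target is such a descriptor."""
    direct = [
        r[0]
        for r in store.execute(
            "SELECT cvterm_id FROM cvterm JOIN cv USING (cv_id) "
            "WHERE cv.name LIKE '%_descriptors' AND cvterm.name = ?",
            (trait,),
        )
    ]
    mapped = []
    std_type = store.get_cvterm_id("local", "standard_of")
    if std_type is not None:
        for row in store.execute(
            "SELECT cvterm_id, value FROM cvtermprop WHERE type_id=?",
            (std_type,),
        ):
            try:
                target = json.loads(row["value"]).get("target")
            except (ValueError, AttributeError):
                continue
            if target == trait:
                mapped.append(row["cvterm_id"])
    return sorted(set(direct + mapped))


def trait_dossier(store: Store, trait: str) -> dict[str, Any]:
    """Everything linked to one trait term: QTL, MTL, descriptors,
    measurements and the germplasm they touch."""
    term_ids = _trait_term_ids(store, trait)
    if not term_ids:
        warnings.warn(f"trait term {trait!r} not found", stacklevel=2)
        return {
            "trait": trait,
            "qtls": [],
            "mtls": [],
            "descriptors": [],
            "phenotype_measurements": [],
            "germplasm": [],
        }
    loci: dict[str, list[str]] = {"QTL": [], "heritable_phenotypic_marker": []}
    marks = ",".join("?" * len(term_ids))
    for row in store.execute(
        "SELECT f.uniquename AS un, t.name AS tname FROM feature_cvterm fc "
        "JOIN feature f USING (feature_id) "
        "JOIN cvterm t ON t.cvterm_id = f.type_id "
        f"WHERE fc.cvterm_id IN ({marks})",
        term_ids,
    ):
        if row["tname"] in loci:
            loci[row["tname"]].append(row["un"])
    descriptor_ids = _descriptor_term_ids(store, trait)
    attr_ids = sorted(set(descriptor_ids + term_ids))
    measurements = []
    stocks: set[str] = set()
    marks = ",".join("?" * len(attr_ids))
    for row in store.execute(
        "SELECT s.uniquename AS stock, a.name AS descriptor, "
        "p.value AS value, e.nd_experiment_id AS eid "
        "FROM phenotype p "
        "JOIN cvterm a ON a.cvterm_id = p.attr_id "
        "JOIN nd_experiment_phenotype nep USING (phenotype_id) "
        "JOIN nd_experiment e USING (nd_experiment_id) "
        "JOIN nd_experiment_stock nes USING (nd_experiment_id) "
        "JOIN stock s USING (stock_id) "
        f"WHERE p.attr_id IN ({marks})",
        attr_ids,
    ):
        measurements.append(
            {
                "stock": row["stock"],
                "descriptor": row["descriptor"],
                "value": row["value"],
            }
        )
        stocks.add(row["stock"])
    # climb sample_of / clone_of edges to the germplasm the samples derive from
    frontier = set(stocks)
    while frontier:
        marks = ",".join("?" * len(frontier))
        parents = {
            r[0]
            for r in store.execute(
                "SELECT po.uniquename FROM stock_relationship sr "
                "JOIN cvterm t ON t.cvterm_id = sr.type_id "
                "JOIN stock su ON su.stock_id = sr.subject_id "
                "JOIN stock po ON po.stock_id = sr.object_id "
                f"WHERE su.uniquename IN ({marks}) "
                "AND t.name IN ('sample_of', 'clone_of')",
                sorted(frontier),
            )
        }
        frontier = parents - stocks
        stocks |= parents
    descriptors = sorted(
        store.term_name(d) + "@" + store.scalar(
            "SELECT cv.name FROM cvterm JOIN cv USING (cv_id) WHERE cvterm_id=?",
            (d,),
        )
        for d in descriptor_ids
    )
    return {
        "trait": trait,
        "qtls": sorted(loci["QTL"]),
        "mtls": sorted(loci["heritable_phenotypic_marker"]),
        "descriptors": descriptors,
        "phenotype_measurements": sorted(
            measurements, key=lambda m: (m["stock"], m["descriptor"], m["value"])
        ),
        "germplasm": sorted(stocks),
    }


def map_view(store: Store, map_name: str) -> dict[str, list[dict[str, Any]]]:
    """Per-linkage-group placements ordered by start position then name."""
    map_id = store.scalar(
        "SELECT featuremap_id FROM featuremap WHERE name=?", (map_name,)
    )
    if map_id is None:
        raise ValidationError(f"unknown map {map_name!r}")
    view: dict[str, list[dict[str, Any]]] = {}
    for row in store.execute(
        "SELECT fp.featurepos_id AS pid, f.uniquename AS locus, "
        "t.name AS type, lg.name AS lg "
        "FROM featurepos fp "
        "JOIN feature f ON f.feature_id = fp.feature_id "
        "JOIN cvterm t ON t.cvterm_id = f.type_id "
        "JOIN feature lg ON lg.feature_id = fp.map_feature_id "
        "WHERE fp.featuremap_id = ?",
        (map_id,),
    ):
        entry: dict[str, Any] = {
            "locus": row["locus"],
            "type": row["type"],
            "start": None,
            "stop": None,
            "peak": None,
        }
        for prop in store.execute(
            "SELECT t.name AS term, p.value AS value FROM featureposprop p "
            "JOIN cvterm t ON t.cvterm_id = p.type_id WHERE p.featurepos_id=?",
            (row["pid"],),
        ):
            key = {"start": "start", "stop": "stop", "qtl_peak": "peak"}.get(
                prop["term"]
            )
            if key:
                try:
                    entry[key] = float(prop["value"])
                except ValueError:
                    entry[key] = prop["value"]
        view.setdefault(row["lg"], []).append(entry)
    for entries in view.values():
        entries.sort(
            key=lambda e: (
                e["start"] if isinstance(e["start"], float) else float("inf"),
                e["locus"],
            )
        )
    return dict(sorted(view.items()))


def pedigree_tree(
    store: Store,
    stock: str,
    direction: str = "ancestors",
    max_depth: Optional[int] = None,
) -> list[dict[str, Any]]:
    """Breadth-first walk over *_parent_of edges from one stock.

    Returns {stock, role, depth} nodes, each stock once at its minimum
    depth. Ancestors climb child -> parent; descendants walk parent ->
    child.
    """
    if direction not in ("ancestors", "descendants"):
        raise ValidationError("direction must be 'ancestors' or 'descendants'")
    start_id = store.stock_id(stock)
    if start_id is None:
        raise ValidationError(f"unknown stock {stock!r}")
    marks = ",".join("?" * len(PARENT_EDGE_TERMS))
    if direction == "ancestors":
        sql = (
            "SELECT sr.subject_id AS nxt, t.name AS role "
            "FROM stock_relationship sr "
            "JOIN cvterm t ON t.cvterm_id = sr.type_id "
            f"WHERE sr.object_id = ? AND t.name IN ({marks})"
        )
    else:
        sql = (
            "SELECT sr.object_id AS nxt, t.name AS role "
            "FROM stock_relationship sr "
            "JOIN cvterm t ON t.cvterm_id = sr.type_id "
            f"WHERE sr.subject_id = ? AND t.name IN ({marks})"
        )
    params = sorted(PARENT_EDGE_TERMS)
    seen = {start_id}
    nodes = []
    queue = deque([(start_id, 0)])
    while queue:
        current, depth = queue.popleft()
        if max_depth is not None and depth >= max_depth:
            continue
        for row in store.execute(sql, [current, *params]):
            if row["nxt"] in seen:
                continue
            seen.add(row["nxt"])
            nodes.append(
                {
                    "stock": store.scalar(
                        "SELECT uniquename FROM stock WHERE stock_id=?",
                        (row["nxt"],),
                    ),
                    "role": row["role"],
                    "depth": depth + 1,
                }
            )
            queue.append((row["nxt"], depth + 1))
    nodes.sort(key=lambda n: (n["depth"], n["stock"]))
    return nodes


def marker_report(store: Store, marker: str) -> dict[str, Any]:
    """Everything linked to one genetic marker."""
    marker_id = store.feature_id(marker, "genetic_marker")
    if marker_id is None:
        raise ValidationError(f"unknown marker {marker!r}")
    feature = store.row(
        "SELECT uniquename, name, residues, seqlen FROM feature "
        "WHERE feature_id=?",
        (marker_id,),
    )
    props: dict[str, list[str]] = {}
    for row in store.execute(
        "SELECT t.name AS term, p.value AS value FROM featureprop p "
        "JOIN cvterm t ON t.cvterm_id = p.type_id "
        "WHERE p.feature_id=? ORDER BY t.name, p.rank",
        (marker_id,),
    ):
        props.setdefault(row["term"], []).append(row["value"])
    primers, probe, source_sequence = [], None, None
    for row in store.execute(
        "SELECT f.uniquename AS un, f.residues AS seq, t.name AS ftype, "
        "rt.name AS rel, fr.subject_id AS sid "
        "FROM feature_relationship fr "
        "JOIN cvterm rt ON rt.cvterm_id = fr.type_id "
        "JOIN feature f ON f.feature_id = "
        "  CASE WHEN fr.subject_id = ? THEN fr.object_id ELSE fr.subject_id END "
        "JOIN cvterm t ON t.cvterm_id = f.type_id "
        "WHERE fr.subject_id = ? OR fr.object_id = ?",
        (marker_id, marker_id, marker_id),
    ):
        if row["ftype"] == "primer" and row["rel"] == "adjacent_to":
            primers.append({"uniquename": row["un"], "sequence": row["seq"]})
        elif row["ftype"] == "probe" and row["rel"] == "associated_with":
            probe = {"uniquename": row["un"], "sequence": row["seq"]}
        elif row["ftype"] == "sequence_feature" and row["rel"] == "derived_from":
            source_sequence = {"uniquename": row["un"], "residues": row["seq"]}
    loci = []
    for row in store.execute(
        "SELECT locus.uniquename AS locus, fm.name AS map, lg.name AS lg, "
        "fp.featurepos_id AS pid "
        "FROM feature_relationship fr "
        "JOIN cvterm rt ON rt.cvterm_id = fr.type_id AND rt.name='instance_of' "
        "JOIN feature locus ON locus.feature_id = fr.subject_id "
        "JOIN featurepos fp ON fp.feature_id = locus.feature_id "
        "JOIN featuremap fm ON fm.featuremap_id = fp.featuremap_id "
        "JOIN feature lg ON lg.feature_id = fp.map_feature_id "
        "WHERE fr.object_id = ?",
        (marker_id,),
    ):
        positions = {
            r["term"]: r["value"]
            for r in store.execute(
                "SELECT t.name AS term, p.value AS value FROM featureposprop p "
                "JOIN cvterm t ON t.cvterm_id = p.type_id "
                "WHERE p.featurepos_id=?",
                (row["pid"],),
            )
        }
        loci.append(
            {
                "locus": row["locus"],
                "map": row["map"],
                "linkage_group": row["lg"],
                "positions": positions,
            }
        )
    genotypes = sorted(
        r[0]
        for r in store.execute(
            "SELECT g.description FROM feature_genotype fg "
            "JOIN genotype g USING (genotype_id) WHERE fg.feature_id=?",
            (marker_id,),
        )
    )
    dbxrefs = sorted(
        f"{r['db']}:{r['accession']}"
        for r in store.execute(
            "SELECT db.name AS db, dx.accession AS accession "
            "FROM feature_dbxref fd JOIN dbxref dx USING (dbxref_id) "
            "JOIN db USING (db_id) WHERE fd.feature_id=?",
            (marker_id,),
        )
    )
    pubs = sorted(
        r[0]
        for r in store.execute(
            "SELECT p.uniquename FROM feature_pub fp JOIN pub p USING (pub_id) "
            "WHERE fp.feature_id=?",
            (marker_id,),
        )
    )
    return {
        "marker": feature["uniquename"],
        "residues": feature["residues"],
        "seqlen": feature["seqlen"],
        "props": props,
        "primers": sorted(primers, key=lambda p: p["uniquename"]),
        "probe": probe,
        "source_sequence": source_sequence,
        "loci": sorted(loci, key=lambda l: (l["map"], l["locus"])),
        "genotypes": genotypes,
        "dbxrefs": dbxrefs,
        "pubs": pubs,
    }
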