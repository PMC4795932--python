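"""Independent naive-enumeration oracles for the query operations.

These deliberately share no code with chadolite.query: tables are pulled
into plain Python structures with bare SELECTs and the answers computed
by loops (or networkx closure, for pedigrees).
"""

from __future__ import annotations

import json
from typing import Any, Optional

import networkx as nx

from chadolite.store import Store

PARENT_TERMS = {"maternal_parent_of", "paternal_parent_of", "mutational_parent_of"}


def _term_names(store: Store) -> dict[int, tuple[str, str]]:
    return {
        r["cvterm_id"]: (r["cv"], r["name"])
        for r in store.execute(
            "SELECT cvterm_id, cv.name AS cv, cvterm.name AS name "
            "FROM cvterm JOIN cv USING (cv_id)"
        )
    }


def oracle_trait_dossier(store: Store, trait: str) -> dict[str, Any]:
    terms = _term_names(store)
    trait_ids = {
        tid
        for tid, (cv, name) in terms.items()
        if name == trait and cv in ("trait_ontology", "local_trait")
    }
    features = {
        r["feature_id"]: (r["uniquename"], terms[r["type_id"]][1])
        for r in store.execute("SELECT feature_id, uniquename, type_id FROM feature")
    }
    qtls, mtls = set(), set()
    for r in store.execute("SELECT feature_id, cvterm_id FROM feature_cvterm"):
        if r["cvterm_id"] in trait_ids:
            un, ftype = features[r["feature_id"]]
            if ftype == "QTL":
                qtls.add(un)
            elif ftype == "heritable_phenotypic_marker":
                mtls.add(un)
    descriptor_ids = {
        tid
        for tid, (cv, name) in terms.items()
        if name == trait and cv.endswith("_descriptors")
    }
    for r in store.execute(
        "SELECT p.cvterm_id AS tid, p.value AS value FROM cvtermprop p "
        "JOIN cvterm t ON t.cvterm_id = p.type_id WHERE t.name='standard_of'"
    ):
        if json.loads(r["value"]).get("target") == trait:
            descriptor_ids.add(r["tid"])
    attr_ids = descriptor_ids | trait_ids
    phenotypes = {
        r["phenotype_id"]: (r["attr_id"], r["value"])
        for r in store.execute("SELECT phenotype_id, attr_id, value FROM phenotype")
    }
    exp_phen = {}
    for r in store.execute(
        "SELECT nd_experiment_id, phenotype_id FROM nd_experiment_phenotype"
    ):
        exp_phen.setdefault(r["nd_experiment_id"], []).append(r["phenotype_id"])
    stocks_by_id = {
        r["stock_id"]: r["uniquename"]
        for r in store.execute("SELECT stock_id, uniquename FROM stock")
    }
    exp_stock = {}
    for r in store.execute(
        "SELECT nd_experiment_id, stock_id FROM nd_experiment_stock"
    ):
        exp_stock.setdefault(r["nd_experiment_id"], []).append(r["stock_id"])
    measurements = []
    germ: set[str] = set()
    for eid, pids in exp_phen.items():
        for pid in pids:
            attr, value = phenotypes[pid]
            if attr not in attr_ids:
                continue
            for sid in exp_stock.get(eid, []):
                measurements.append(
                    {
                        "stock": stocks_by_id[sid],
                        "descriptor": terms[attr][1],
                        "value": value,
                    }
                )
                germ.add(stocks_by_id[sid])
    up_edges = {}
    for r in store.execute(
        "SELECT sr.subject_id AS s, sr.object_id AS o, t.name AS tname "
        "FROM stock_relationship sr JOIN cvterm t ON t.cvterm_id = sr.type_id"
    ):
        if r["tname"] in ("sample_of", "clone_of"):
            up_edges.setdefault(stocks_by_id[r["s"]], []).append(
                stocks_by_id[r["o"]]
            )
    changed = True
    while changed:
        changed = False
        for s in list(germ):
            for parent in up_edges.get(s, []):
                if parent not in germ:
                    germ.add(parent)
                    changed = True
    return {
        "qtls": sorted(qtls),
        "mtls": sorted(mtls),
        "phenotype_measurements": sorted(
            measurements, key=lambda m: (m["stock"], m["descriptor"], m["value"])
        ),
        "germplasm": sorted(germ),
    }


def oracle_map_view(store: Store, map_name: str) -> dict[str, list[str]]:
    """Per-LG locus order only (the sort contract), computed naively."""
    map_id = store.scalar(
        "SELECT featuremap_id FROM featuremap WHERE name=?", (map_name,)
    )
    terms = _term_names(store)
    props: dict[int, dict[str, str]] = {}
    for r in store.execute(
        "SELECT featurepos_id, type_id, value FROM featureposprop"
    ):
        props.setdefault(r["featurepos_id"], {})[terms[r["type_id"]][1]] = r[
            "value"
        ]
    rows = []
    for r in store.execute(
        "SELECT featurepos_id, feature_id, map_feature_id FROM featurepos "
        "WHERE featuremap_id=?",
        (map_id,),
    ):
        locus = store.scalar(
            "SELECT uniquename FROM feature WHERE feature_id=?", (r["feature_id"],)
        )
        lg = store.scalar(
            "SELECT name FROM feature WHERE feature_id=?", (r["map_feature_id"],)
        )
        start = props.get(r["featurepos_id"], {}).get("start")
        rows.append((lg, float(start) if start else float("inf"), locus))
    view: dict[str, list[str]] = {}
    for lg, start, locus in sorted(rows, key=lambda t: (t[0], t[1], t[2])):
        view.setdefault(lg, []).append(locus)
    return view


def pedigree_graph(store: Store) -> tuple[nx.DiGraph, dict[str, int]]:
    names = {
        r["uniquename"]: r["stock_id"]
        for r in store.execute("SELECT stock_id, uniquename FROM stock")
    }
    graph = nx.DiGraph()
    graph.add_nodes_from(names.values())
    for r in store.execute(
        "SELECT sr.subject_id AS s, sr.object_id AS o, t.name AS tname "
        "FROM stock_relationship sr JOIN cvterm t ON t.cvterm_id = sr.type_id"
    ):
        if r["tname"] in PARENT_TERMS:
            graph.add_edge(r["s"], r["o"])  # parent -> child
    return graph, names


def oracle_pedigree(
    store: Store,
    stock: str,
    direction: str,
    max_depth: Optional[int] = None,
) -> set[str]:
    graph, names = pedigree_graph(store)
    node = names[stock]
    walk = graph.reverse(copy=False) if direction == "ancestors" else graph
    lengths = nx.single_source_shortest_path_length(walk, node, cutoff=max_depth)
    by_id = {v: k for k, v in names.items()}
    return {by_id[n] for n, d in lengths.items() if d > 0}
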