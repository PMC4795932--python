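"""Genome assemblies and structural annotation.

Chromosomes come in from FASTA, gene models from GFF3. Each GFF3 row
becomes one feature typed by its column-3 Sequence Ontology term; Parent
attributes become part_of relationships; 1-based inclusive GFF3 spans are
converted to 0-based interbase [fmin, fmax). A polypeptide is synthesised
for every coding transcript unless the file ships its own polypeptide
rows. Gene sets parsed from NCBI follow the reference-gene convention:
one residue-less feature per gene symbol, associated_with each sequenced
instance of the gene.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Optional

import gffutils
from Bio import SeqIO

from .errors import ConflictError, ValidationError
from .store import Store
from .vocab import mark_provisional, rel_term


@dataclass
class LoadSummary:
    features: int = 0
    relationships: int = 0
    locations: int = 0


def _seq_type(store: Store, name: str) -> int:
    term_id = store.get_cvterm_id("sequence", name)
    if term_id is None:
        term_id = store.create_cvterm("sequence", name)
        mark_provisional(store, term_id)
    return term_id


def _ensure_analysis(store: Store, name: str) -> int:
    aid = store.scalar("SELECT analysis_id FROM analysis WHERE name=?", (name,))
    if aid is None:
        aid = store.insert("analysis", name=name)
    return aid


def load_fasta(
    store: Store,
    path: str | Path,
    organism: str,
    type_term: str = "chromosome",
) -> int:
    """Load sequences as features of *type_term*; returns records loaded.

    The uniquename is the first whitespace token of the header; residues
    and seqlen are stored verbatim.
    """
    org_id = store.ensure_organism(organism)
    type_id = _seq_type(store, type_term)
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        uniquename = rec.id
        if store.feature_id(uniquename, type_term, org_id) is not None:
            raise ConflictError(
                f"{type_term} {uniquename!r} already loaded for {organism!r}"
            )
        seq = str(rec.seq)
        store.insert(
            "feature",
            organism_id=org_id,
            uniquename=uniquename,
            name=uniquename,
            residues=seq,
            seqlen=len(seq),
            type_id=type_id,
        )
        n += 1
    if n == 0:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    store.commit()
    return n


def load_gff3(
    store: Store,
    path: str | Path,
    organism: str,
    analysis_name: str = "genome annotation",
) -> LoadSummary:
    """Load a GFF3 annotation; srcfeatures (seqids) must already exist."""
    org_id = store.ensure_organism(organism)
    analysis_id = _ensure_analysis(store, analysis_name)
    part_of = rel_term(store, "part_of")
    derives_from = rel_term(store, "derives_from")

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    rows = list(db.all_features())
    known_ids = {f.id for f in rows}
    file_has_polypeptides = any(f.featuretype == "polypeptide" for f in rows)

    summary = LoadSummary()
    by_gff_id: dict[str, int] = {}
    anon = 0
    # feature rows first, in file order, so Parent targets resolve after
    for f in rows:
        src_id = store.feature_id(f.seqid, organism_id=org_id)
        if src_id is None:
            raise ValidationError(
                f"unknown srcfeature {f.seqid!r}; load the genome FASTA first"
            )
        fmin, fmax = f.start - 1, f.end
        uniquename = f.attributes.get("ID", [None])[0]
        if uniquename is None:
            anon += 1
            uniquename = f"{f.featuretype}-{f.seqid}-{fmin}-{fmax}-{anon}"
        feature_id = store.insert(
            "feature",
            organism_id=org_id,
            uniquename=uniquename,
            name=f.attributes.get("Name", [uniquename])[0],
            type_id=_seq_type(store, f.featuretype),
            is_analysis=1,
        )
        by_gff_id[f.id] = feature_id
        summary.features += 1
        strand = {"+": 1, "-": -1}.get(f.strand, 0)
        store.insert(
            "featureloc",
            feature_id=feature_id,
            srcfeature_id=src_id,
            fmin=fmin,
            fmax=fmax,
            strand=strand,
        )
        summary.locations += 1
        store.link(
            "analysisfeature", feature_id=feature_id, analysis_id=analysis_id
        )
    for f in rows:
        for parent in f.attributes.get("Parent", []):
            if parent not in known_ids:
                raise ValidationError(f"unknown Parent {parent!r} in {path}")
            store.insert(
                "feature_relationship",
                subject_id=by_gff_id[f.id],
                object_id=by_gff_id[parent],
                type_id=part_of,
            )
            summary.relationships += 1
    # one polypeptide per coding transcript, spanning its CDS rows
    if not file_has_polypeptides:
        poly_type = _seq_type(store, "polypeptide")
        for f in rows:
            if f.featuretype != "mRNA":
                continue
            cds = [c for c in db.children(f.id, featuretype="CDS")]
            if not cds:
                continue
            fmin = min(c.start - 1 for c in cds)
            fmax = max(c.end for c in cds)
            src_id = store.feature_id(f.seqid, organism_id=org_id)
            mrna_un = f.attributes.get("ID", [f.id])[0]
            poly_id = store.insert(
                "feature",
                organism_id=org_id,
                uniquename=f"{mrna_un}-polypeptide",
                name=f"{mrna_un}-polypeptide",
                type_id=poly_type,
                is_analysis=1,
            )
            summary.features += 1
            store.insert(
                "feature_relationship",
                subject_id=poly_id,
                object_id=by_gff_id[f.id],
                type_id=derives_from,
            )
            summary.relationships += 1
            strand = {"+": 1, "-": -1}.get(f.strand, 0)
            store.insert(
                "featureloc",
                feature_id=poly_id,
                srcfeature_id=src_id,
                fmin=fmin,
                fmax=fmax,
                strand=strand,
            )
            summary.locations += 1
            store.link(
                "analysisfeature", feature_id=poly_id, analysis_id=analysis_id
            )
    store.commit()
    return summary


def load_ncbi_genes(
    store: Store,
    records: Iterable[dict[str, Any]] | str | Path,
    organism: str,
    analysis_name: str = "NCBI gene import",
) -> LoadSummary:
    """Load pre-parsed NCBI gene entries with the reference-gene convention.

    *records* is an iterable of dicts (or a path to a JSON-lines file), one
    per gene symbol::

        {"symbol": "NIP6.1",
         "instances": [{"accession": "XM_1", "residues": "ATG...",
                        "subfeatures": [{"type": "mRNA", "residues": ""}]}]}

    The symbol becomes a residue-less reference gene; every instance is a
    residue-bearing gene feature related ``associated_with`` (instance
    subject, reference object). Subfeatures hang off the instance gene —
    or off the most recent mRNA subfeature for CDS/exon/UTR rows.
    """
    if isinstance(records, (str, Path)):
        with open(records) as fh:
            records = [json.loads(line) for line in fh if line.strip()]
    org_id = store.ensure_organism(organism)
    analysis_id = _ensure_analysis(store, analysis_name)
    gene_type = _seq_type(store, "gene")
    associated_with = rel_term(store, "associated_with")
    part_of = rel_term(store, "part_of")

    summary = LoadSummary()
    ref_ids: dict[str, int] = {}
    for rec in records:
        symbol = rec["symbol"]
        ref_id = ref_ids.get(symbol)
        if ref_id is None:
            ref_id = store.feature_id(symbol, "gene", org_id)
        if ref_id is None:
            ref_id = store.insert(
                "feature",
                organism_id=org_id,
                uniquename=symbol,
                name=symbol,
                type_id=gene_type,
            )
            summary.features += 1
            store.link(
                "analysisfeature", feature_id=ref_id, analysis_id=analysis_id
            )
        ref_ids[symbol] = ref_id
        for inst in rec.get("instances", []):
            residues = inst.get("residues", "")
            inst_id = store.insert(
                "feature",
                organism_id=org_id,
                uniquename=inst["accession"],
                name=inst.get("name", inst["accession"]),
                residues=residues,
                seqlen=len(residues) if residues else None,
                type_id=gene_type,
            )
            summary.features += 1
            store.insert(
                "feature_relationship",
                subject_id=inst_id,
                object_id=ref_id,
                type_id=associated_with,
            )
            summary.relationships += 1
            current_mrna: Optional[int] = None
            for k, sub in enumerate(inst.get("subfeatures", [])):
                sub_type = sub["type"]
                residues = sub.get("residues", "")
                sub_un = sub.get(
                    "uniquename", f"{inst['accession']}.{sub_type}.{k}"
                )
                sub_id = store.insert(
                    "feature",
                    organism_id=org_id,
                    uniquename=sub_un,
                    name=sub_un,
                    residues=residues,
                    seqlen=len(residues) if residues else None,
                    type_id=_seq_type(store, sub_type),
                )
                summary.features += 1
                parent = inst_id
                if sub_type == "mRNA":
                    current_mrna = sub_id
                elif current_mrna is not None:
                    parent = current_mrna
                store.insert(
                    "feature_relationship",
                    subject_id=sub_id,
                    object_id=parent,
                    type_id=part_of,
                )
                summary.relationships += 1
    store.commit()
    return summary
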