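"""Large-scale phenotyping and genotyping via the natural-diversity pattern.

Each measurement is one nd_experiment (type 'phenotyping' or 'genotyping')
linking a stock, a project, a geolocation and the observed phenotype or
genotype. Phenotype rows deduplicate on "<descriptor>_<value>"; genotype
rows deduplicate on "<marker>_<canonical allele string>", where the
canonical string is the alleles byte-wise sorted and joined with '|' so
copy number is preserved ("A|A" is a homozygote). Coded trait descriptors
keep their code table in cvtermprop (rank = numeric code, value = the
code's meaning); a measurement can be dual-coded under a second, standard
descriptor through an explicit code map. Haplotype blocks are
haplotype_block features that 'contain' their member markers; a
haplotype's phenotypic effect is a phenstatement tying its genotype row to
a phenotype row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .errors import ConflictError, ValidationError
from .store import Store
from .vocab import rel_term

HAPLOTYPE_SEPARATOR = "-"


def canonical_description(alleles: list[str]) -> str:
    """Alleles trimmed, byte-wise sorted, joined with '|'.

    Duplicates are retained (copy number matters); sorting is plain
    lexicographic on the strings — no numeric-aware collation, so
    ["102", "98"] canonicalises to "102|98".
    """
    if not alleles:
        raise ValidationError("allele list must be non-empty")
    cleaned = [a.strip() for a in alleles]
    if any(not a for a in cleaned):
        raise ValidationError(f"empty allele in {alleles!r}")
    return "|".join(sorted(cleaned))


@dataclass
class PhenotypeMeasurement:
    project: str
    stock: str
    descriptor: str
    value: str
    descriptor_cv: str = ""  # default: "<project>_descriptors"
    location: str = ""
    stats: dict[str, str] = field(default_factory=dict)
    contact: str = ""


@dataclass
class GenotypeCall:
    project: str
    stock: str
    marker: str
    alleles: list[str]
    location: str = ""


def define_descriptor(
    store: Store,
    project: str,
    name: str,
    codes: Optional[dict[str, str]] = None,
    standard_of: Optional[dict] = None,
) -> int:
    """Register a trait descriptor in the project's descriptor vocabulary.

    *codes* maps numeric code -> meaning for qualitative descriptors;
    empty/None means quantitative. *standard_of* records that this
    descriptor has a community standard: ``{"target": <descriptor name>,
    "map": {source code: standard code}}``, kept as a cvtermprop.
    """
    cv_name = f"{project}_descriptors"
    term_id = store.create_cvterm(cv_name, name)
    if codes:
        existing = descriptor_codes(store, term_id)
        for code, meaning in sorted(codes.items(), key=lambda kv: int(kv[0])):
            if code in existing:
                continue
            store.insert(
                "cvtermprop",
                cvterm_id=term_id,
                type_id=store.cvterm("local", "code"),
                value=meaning,
                rank=int(code),
            )
    if standard_of:
        if not store.scalar(
            "SELECT 1 FROM cvtermprop WHERE cvterm_id=? AND type_id=?",
            (term_id, store.cvterm("local", "standard_of")),
        ):
            store.insert(
                "cvtermprop",
                cvterm_id=term_id,
                type_id=store.cvterm("local", "standard_of"),
                value=json.dumps(standard_of, sort_keys=True),
            )
    store.commit()
    return term_id


def descriptor_codes(store: Store, term_id: int) -> dict[str, str]:
    """code (as string) -> meaning, empty for quantitative descriptors."""
    code_type = store.get_cvterm_id("local", "code")
    if code_type is None:
        return {}
    return {
        str(r["rank"]): r["value"]
        for r in store.execute(
            "SELECT rank, value FROM cvtermprop WHERE cvterm_id=? AND type_id=?",
            (term_id, code_type),
        )
    }


def resolve_descriptor(
    store: Store, project: str, name: str, cv_name: str = ""
) -> int:
    """Find a descriptor term: explicit cv, the project's set, then the
    trait ontologies."""
    candidates = (
        [cv_name]
        if cv_name
        else [f"{project}_descriptors", "trait_ontology", "local_trait"]
    )
    for cv in candidates:
        term_id = store.get_cvterm_id(cv, name)
        if term_id is not None:
            return term_id
    raise ValidationError(f"unknown trait descriptor {name!r}")


def _upsert_phenotype(store: Store, attr_id: int, value: str) -> int:
    attr_name = store.term_name(attr_id)
    uniquename = f"{attr_name}_{value}"
    pid = store.scalar(
        "SELECT phenotype_id FROM phenotype WHERE uniquename=?", (uniquename,)
    )
    if pid is None:
        pid = store.insert(
            "phenotype", uniquename=uniquename, attr_id=attr_id, value=value
        )
    return pid


def record_phenotype(store: Store, m: PhenotypeMeasurement) -> int:
    """Store one phenotypic measurement as its own 'phenotyping' event."""
    if not m.value:
        raise ValidationError("measurement value must be non-empty")
    project_id = store.scalar(
        "SELECT project_id FROM project WHERE name=?", (m.project,)
    )
    if project_id is None:
        raise ValidationError(f"unknown project {m.project!r}")
    stock_id = store.stock_id(m.stock)
    if stock_id is None:
        raise ValidationError(f"unknown stock {m.stock!r}")
    attr_id = resolve_descriptor(store, m.project, m.descriptor, m.descriptor_cv)
    codes = descriptor_codes(store, attr_id)
    if codes and m.value not in codes:
        raise ValidationError(
            f"value {m.value!r} not a code of {m.descriptor!r}; "
            f"allowed: {sorted(codes, key=int)}"
        )
    phenotype_id = _upsert_phenotype(store, attr_id, m.value)
    geo_id = store.ensure_geolocation(m.location or "unspecified")
    exp_id = store.insert(
        "nd_experiment",
        nd_geolocation_id=geo_id,
        type_id=store.cvterm("local", "phenotyping"),
    )
    store.insert(
        "nd_experiment_stock", nd_experiment_id=exp_id, stock_id=stock_id
    )
    store.insert(
        "nd_experiment_project", nd_experiment_id=exp_id, project_id=project_id
    )
    store.insert(
        "nd_experiment_phenotype",
        nd_experiment_id=exp_id,
        phenotype_id=phenotype_id,
    )
    for term in ("standard_deviation", "coefficient_of_variation", "skewness"):
        value = m.stats.get(term, "")
        if value:
            store.add_prop("nd_experimentprop", exp_id, "local", term, value)
    if m.contact:
        store.link(
            "nd_experiment_contact",
            nd_experiment_id=exp_id,
            contact_id=store.ensure_contact(m.contact),
        )
    store.commit()
    return exp_id


def record_dual_coded(
    store: Store,
    m: PhenotypeMeasurement,
    standard: str,
    code_map: dict[str, str],
    standard_cv: str = "",
) -> tuple[int, int]:
    """Record a coded measurement under its own and a standard descriptor.

    The same observation yields two phenotype rows and two phenotyping
    events on the same stock and project, making data comparable across
    projects that code the trait differently.
    """
    attr_id = resolve_descriptor(store, m.project, m.descriptor, m.descriptor_cv)
    codes = descriptor_codes(store, attr_id)
    if not codes:
        raise ValidationError(f"descriptor {m.descriptor!r} is not coded")
    if m.value not in code_map:
        raise ValidationError(
            f"code map has no entry for observed code {m.value!r}"
        )
    original = record_phenotype(store, m)
    std = PhenotypeMeasurement(
        project=m.project,
        stock=m.stock,
        descriptor=standard,
        value=str(code_map[m.value]),
        descriptor_cv=standard_cv or m.descriptor_cv,
        location=m.location,
        stats=dict(m.stats),
        contact=m.contact,
    )
    return original, record_phenotype(store, std)


def _genotyped_feature(store: Store, name: str) -> Optional[int]:
    for type_name in ("genetic_marker", "haplotype_block"):
        fid = store.feature_id(name, type_name)
        if fid is not None:
            return fid
    return None


def _upsert_genotype(store: Store, feature_id: int, description: str) -> int:
    feature_un = store.scalar(
        "SELECT uniquename FROM feature WHERE feature_id=?", (feature_id,)
    )
    uniquename = f"{feature_un}_{description}"
    gid = store.scalar(
        "SELECT genotype_id FROM genotype WHERE uniquename=?", (uniquename,)
    )
    if gid is None:
        gid = store.insert(
            "genotype",
            uniquename=uniquename,
            name=uniquename,
            description=description,
        )
        store.insert("feature_genotype", feature_id=feature_id, genotype_id=gid)
    return gid


def _genotyping_experiment(
    store: Store, project: str, stock: str, genotype_id: int, location: str = ""
) -> int:
    project_id = store.scalar(
        "SELECT project_id FROM project WHERE name=?", (project,)
    )
    if project_id is None:
        raise ValidationError(f"unknown project {project!r}")
    stock_id = store.stock_id(stock)
    if stock_id is None:
        raise ValidationError(f"unknown stock {stock!r}")
    geo_id = store.ensure_geolocation(location or "unspecified")
    exp_id = store.insert(
        "nd_experiment",
        nd_geolocation_id=geo_id,
        type_id=store.cvterm("local", "genotyping"),
    )
    store.insert(
        "nd_experiment_stock", nd_experiment_id=exp_id, stock_id=stock_id
    )
    store.insert(
        "nd_experiment_project", nd_experiment_id=exp_id, project_id=project_id
    )
    store.insert(
        "nd_experiment_genotype", nd_experiment_id=exp_id, genotype_id=genotype_id
    )
    store.commit()
    return exp_id


def record_genotype(store: Store, g: GenotypeCall) -> int:
    """Store one genotyping measurement; genotype rows are shared."""
    marker_id = _genotyped_feature(store, g.marker)
    if marker_id is None:
        raise ValidationError(f"unknown marker {g.marker!r}")
    description = canonical_description(g.alleles)
    genotype_id = _upsert_genotype(store, marker_id, description)
    return _genotyping_experiment(
        store, g.project, g.stock, genotype_id, g.location
    )


def define_haplotype_block(
    store: Store, name: str, member_markers: list[str], organism: str = ""
) -> int:
    """A haplotype_block feature 'contains' its markers, ranked in genomic
    order when the markers are localised, else in input order."""
    if len(member_markers) < 2:
        raise ValidationError("a haplotype block needs at least two markers")
    marker_ids = []
    for marker in member_markers:
        mid = store.feature_id(marker, "genetic_marker")
        if mid is None:
            raise ValidationError(f"unknown marker {marker!r}")
        marker_ids.append(mid)
    # genomic order when located: all on one srcfeature, sorted by fmin
    locs = {}
    for mid in marker_ids:
        row = store.row(
            "SELECT srcfeature_id, fmin FROM featureloc WHERE feature_id=?",
            (mid,),
        )
        if row is not None:
            locs[mid] = (row["srcfeature_id"], row["fmin"])
    if locs and len(locs) == len(marker_ids):
        srcs = {s for s, _ in locs.values()}
        if len(srcs) > 1:
            raise ValidationError(
                "haplotype block members lie on different srcfeatures"
            )
        marker_ids.sort(key=lambda m: locs[m][1])
    org_id = (
        store.ensure_organism(organism)
        if organism
        else store.scalar(
            "SELECT organism_id FROM feature WHERE feature_id=?",
            (marker_ids[0],),
        )
    )
    block_id = store.feature_id(name, "haplotype_block", org_id)
    if block_id is None:
        block_id = store.insert(
            "feature",
            organism_id=org_id,
            uniquename=name,
            name=name,
            type_id=store.cvterm("sequence", "haplotype_block"),
        )
        contains = rel_term(store, "contains")
        for rank, mid in enumerate(marker_ids):
            store.insert(
                "feature_relationship",
                subject_id=block_id,
                object_id=mid,
                type_id=contains,
                rank=rank,
            )
    store.commit()
    return block_id


def record_haplotype_genotype(
    store: Store, project: str, stock: str, block: str, haplotype: str,
    location: str = "",
) -> int:
    """A haplotype call, stored exactly like a marker genotype with the
    block as the linked feature; the allele separator inside *haplotype*
    is caller-defined ('-' by convention, to keep '|' for copy number)."""
    block_id = store.feature_id(block, "haplotype_block")
    if block_id is None:
        raise ValidationError(f"unknown haplotype block {block!r}")
    if not haplotype.strip():
        raise ValidationError("haplotype string must be non-empty")
    genotype_id = _upsert_genotype(store, block_id, haplotype.strip())
    return _genotyping_experiment(store, project, stock, genotype_id, location)


def record_haplotype_effect(
    store: Store,
    haplotype_genotype: str,
    trait_descriptor: str,
    effect_value: str,
    environment: str = "",
    pub: str = "",
    project: str = "",
    descriptor_cv: str = "",
) -> int:
    """phenstatement: this haplotype shifts this trait by this value."""
    genotype_id = store.scalar(
        "SELECT genotype_id FROM genotype WHERE uniquename=?",
        (haplotype_genotype,),
    )
    if genotype_id is None:
        raise ValidationError(f"unknown genotype {haplotype_genotype!r}")
    attr_id = resolve_descriptor(store, project, trait_descriptor, descriptor_cv)
    phenotype_id = _upsert_phenotype(store, attr_id, effect_value)
    geo_id = store.ensure_geolocation(environment or "unspecified")
    type_id = store.cvterm("local", "haplotype_effect")
    if store.scalar(
        "SELECT 1 FROM phenstatement WHERE genotype_id=? AND environment_id=? "
        "AND phenotype_id=? AND type_id=?",
        (genotype_id, geo_id, phenotype_id, type_id),
    ):
        raise ConflictError(
            f"effect of {haplotype_genotype!r} on {trait_descriptor!r} "
            "already recorded for this environment"
        )
    ps_id = store.insert(
        "phenstatement",
        genotype_id=genotype_id,
        environment_id=geo_id,
        phenotype_id=phenotype_id,
        type_id=type_id,
        pub_id=store.ensure_pub(pub) if pub else None,
    )
    store.commit()
    return ps_id


# ---------------------------------------------------------------------------
# tab-delimited loader templates (long format, one measurement per row)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def load_descriptors_tsv(store: Store, path: str | Path) -> int:
    """descriptors.tsv: project, name, codes ('1=light;5=dark'),
    standard_of, code_map ('1=2;2=4')."""
    df = _read_tsv(path)
    for _, row in df.iterrows():
        codes = None
        if row.get("codes", ""):
            codes = dict(
                pair.split("=", 1) for pair in row["codes"].split(";") if pair
            )
        standard_of = None
        if row.get("standard_of", ""):
            code_map = dict(
                pair.split("=", 1) for pair in row.get("code_map", "").split(";")
                if pair
            )
            standard_of = {"target": row["standard_of"], "map": code_map}
        define_descriptor(
            store, row["project"], row["name"], codes=codes,
            standard_of=standard_of,
        )
    return len(df)


def load_phenotypes_tsv(store: Store, path: str | Path) -> int:
    df = _read_tsv(path)
    for _, row in df.iterrows():
        record_phenotype(
            store,
            PhenotypeMeasurement(
                project=row["project"],
                stock=row["stock"],
                descriptor=row["descriptor"],
                value=row["value"],
                descriptor_cv=row.get("descriptor_cv", ""),
                location=row.get("location", ""),
                stats={
                    t: row.get(k, "")
                    for t, k in (
                        ("standard_deviation", "sd"),
                        ("coefficient_of_variation", "cv"),
                        ("skewness", "skewness"),
                    )
                    if row.get(k, "")
                },
            ),
        )
    return len(df)


def load_genotypes_tsv(store: Store, path: str | Path) -> int:
    df = _read_tsv(path)
    for _, row in df.iterrows():
        record_genotype(
            store,
            GenotypeCall(
                project=row["project"],
                stock=row["stock"],
                marker=row["marker"],
                alleles=[a for a in row["alleles"].split("/") if a],
                location=row.get("location", ""),
            ),
        )
    return len(df)


def load_haplotypes_tsv(store: Store, path: str | Path) -> int:
    """haplotypes.tsv: project, stock, block, members (';'), haplotype.

    The block is defined on first sight from its member list.
    """
    df = _read_tsv(path)
    for _, row in df.iterrows():
        members = [m for m in row.get("members", "").split(";") if m]
        if store.feature_id(row["block"], "haplotype_block") is None:
            define_haplotype_block(store, row["block"], members)
        record_haplotype_genotype(
            store, row["project"], row["stock"], row["block"], row["haplotype"]
        )
    return len(df)


def load_haplotype_effects_tsv(store: Store, path: str | Path) -> int:
    """haplotype_effects.tsv: genotype, project, descriptor, value, environment."""
    df = _read_tsv(path)
    for _, row in df.iterrows():
        record_haplotype_effect(
            store,
            haplotype_genotype=row["genotype"],
            trait_descriptor=row["descriptor"],
            effect_value=row["value"],
            environment=row.get("environment", ""),
            project=row.get("project", ""),
        )
    return len(df)
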