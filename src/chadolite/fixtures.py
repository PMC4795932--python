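"""Synthetic, convention-conformant breeding dataset generator.

Emits every loader format the store understands — mini ontologies (OBO),
a toy genome (FASTA + GFF3) and the tab-delimited templates for
germplasm, pedigree, markers, maps, positions, QTL, MTL, collections,
passports, descriptors, phenotypes, genotypes and haplotypes — from a
single RNG seed, so the whole stack is testable without any download.
All ontology files and sequences are synthetic stand-ins, not excerpts
of the real SO/TO.

The generator mirrors the loaders' construction rules as it writes, so
the manifest it returns carries the exact per-table record counts an
end-to-end load must produce. Genotype calls follow Hardy-Weinberg draws
with one allele frequency per marker; quantitative trait values get a
per-germplasm shift so trait-centric queries return structure, not
noise.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

from .store import Store
from .vocab import RELATIONSHIP_TERMS, SEQUENCE_TERMS

ORGANISM = "Prunus persica"

TRAITS = (
    "fruit_color",
    "fruit_weight",
    "flowering_time",
    "fruit_firmness",
    "disease_resistance",
)

#: deliberately absent from the trait OBO: exercises the provisional
#: local_trait path
EXTRA_TRAIT = "chilling_requirement"


@dataclass
class FixtureSpec:
    seed: int = 1
    n_germplasm: int = 16  # cultivars + 2 wild accessions + 1 population
    pedigree_depth: int = 3
    n_markers: int = 24
    snp_fraction: float = 0.5
    n_linkage_groups: int = 3
    map_length_cM: float = 100.0
    n_qtl: int = 4
    n_mtl: int = 2
    n_samples_per_germplasm: int = 1
    n_descriptors: int = 4
    coded_fraction: float = 0.5
    code_range: int = 5
    missing_rate: float = 0.1

    def __post_init__(self) -> None:
        counts = (
            self.n_germplasm,
            self.n_markers,
            self.n_linkage_groups,
            self.n_qtl,
            self.n_mtl,
            self.n_samples_per_germplasm,
            self.n_descriptors,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")


def _write_tsv(path: Path, header: list[str], rows: list[list[str]]) -> None:
    lines = ["\t".join(header)] + ["\t".join(r) for r in rows]
    path.write_text("".join(l + "\n" for l in lines))


def _write_obo(path: Path, prefix: str, terms: list[str]) -> None:
    chunks = ["format-version: 1.2", f"ontology: {path.stem}", ""]
    for i, name in enumerate(terms, start=1):
        chunks += [
            "[Term]",
            f"id: {prefix}:{9000000 + i:07d}",
            f"name: {name}",
            f'def: "synthetic stand-in term for {name}" []',
            "",
        ]
    path.write_text("\n".join(chunks))


def generate(spec: FixtureSpec, outdir: str | Path) -> dict[str, Any]:
    """Write the full fixture tree; returns (and writes) the manifest."""
    rng = random.Random(spec.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    n_feature = 0

    # --- ontologies ------------------------------------------------------
    _write_obo(outdir / "sequence.obo", "SO", list(SEQUENCE_TERMS))
    _write_obo(outdir / "relationship.obo", "RO", list(RELATIONSHIP_TERMS))
    _write_obo(outdir / "traits.obo", "TO", list(TRAITS))

    # --- genome + annotation --------------------------------------------
    chroms = ["chr1", "chr2"]
    with open(outdir / "genome.fasta", "w") as fh:
        for chrom in chroms:
            seq = "".join(rng.choice("ACGT") for _ in range(2000))
            fh.write(f">{chrom} synthetic\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    n_feature += len(chroms)

    gff_rows = ["##gff-version 3"]
    gene_names = []
    for g in range(3):
        chrom = chroms[g % len(chroms)]
        start = 100 + g * 500
        gene = f"gene{g + 1}"
        mrna = f"{gene}.t1"
        gene_names.append(gene)
        gff_rows += [
            f"{chrom}\tsynth\tgene\t{start}\t{start + 299}\t.\t+\t.\tID={gene}",
            f"{chrom}\tsynth\tmRNA\t{start}\t{start + 299}\t.\t+\t.\t"
            f"ID={mrna};Parent={gene}",
            f"{chrom}\tsynth\texon\t{start}\t{start + 99}\t.\t+\t.\t"
            f"ID={mrna}.e1;Parent={mrna}",
            f"{chrom}\tsynth\texon\t{start + 200}\t{start + 299}\t.\t+\t.\t"
            f"ID={mrna}.e2;Parent={mrna}",
            f"{chrom}\tsynth\tCDS\t{start + 30}\t{start + 99}\t.\t+\t0\t"
            f"ID={mrna}.cds;Parent={mrna}",
        ]
        n_feature += 6  # 5 rows + 1 synthesised polypeptide
    (outdir / "annotation.gff3").write_text("\n".join(gff_rows) + "\n")

    # --- germplasm, pedigree, samples -----------------------------------
    n_wild = min(2, max(0, spec.n_germplasm - 1))
    n_pop = 1 if spec.n_germplasm >= 1 else 0
    n_cultivar = max(0, spec.n_germplasm - n_wild - n_pop)
    cultivars = [f"G{i + 1:02d}" for i in range(n_cultivar)]
    wilds = [f"W{i + 1:02d}" for i in range(n_wild)]
    germ_rows = [
        [c, ORGANISM, "cultivar", f"alias_{c}", ""] for c in cultivars
    ]
    germ_rows += [[w, ORGANISM, "wild/unimproved", "", ""] for w in wilds]
    if n_pop:
        germ_rows.append(["POP_F2", ORGANISM, "population", "", "F2 mapping population"])
    _write_tsv(
        outdir / "germplasm.tsv",
        ["name", "organism", "type", "aliases", "description"],
        germ_rows,
    )

    ped_rows = []
    n_edges = 0
    for i, child in enumerate(cultivars):
        if i < 2:
            continue
        maternal = paternal = mutational = ""
        if i == len(cultivars) - 1 and len(cultivars) >= 2:
            mutational = cultivars[0]  # a bud sport
            n_edges += 1
        else:
            pool = cultivars[:i]
            if rng.random() < 0.85:
                maternal = rng.choice(pool)
                n_edges += 1
            rest = [p for p in pool if p != maternal]
            if rest and rng.random() < 0.7:
                paternal = rng.choice(rest)
                n_edges += 1
        ped_rows.append([child, maternal, paternal, mutational])
    _write_tsv(
        outdir / "pedigree.tsv",
        ["child", "maternal_parent", "paternal_parent", "mutational_parent"],
        ped_rows,
    )

    samples = []
    for c in cultivars:
        for s in range(spec.n_samples_per_germplasm):
            samples.append((c, f"{c}_S{s + 1}"))
    _write_tsv(
        outdir / "samples.tsv",
        ["germplasm", "sample"],
        [[g, s] for g, s in samples],
    )
    counts["stock"] = len(germ_rows) + len(samples)
    counts["stock_relationship"] = n_edges + len(samples)

    # --- stock center + passports ---------------------------------------
    _write_tsv(
        outdir / "collections.tsv",
        ["code", "name", "url", "description"],
        [
            [
                "NPGS-PRU",
                "National Prunus Collection",
                "https://example.org/npgs",
                "synthetic stock center",
            ]
        ]
        if wilds
        else [],
    )
    _write_tsv(
        outdir / "accessions.tsv",
        ["collection", "stock", "accession"],
        [["NPGS-PRU", w, f"PI 5282{i + 1:02d}"] for i, w in enumerate(wilds)],
    )
    passport_rows = [
        [
            w,
            f"Collection site {i + 1}",
            f"{17.0 + i:.1f}",
            f"{-96.5 - i:.1f}",
            "1500.0",
            "40",
            "12",
            "synthetic passport",
            "Collector One",
        ]
        for i, w in enumerate(wilds)
    ]
    _write_tsv(
        outdir / "passport.tsv",
        [
            "stock",
            "location",
            "latitude",
            "longitude",
            "altitude",
            "population_size",
            "sample_size",
            "comments",
            "collector",
        ],
        passport_rows,
    )

    # --- markers ---------------------------------------------------------
    n_snp = int(round(spec.n_markers * spec.snp_fraction))
    markers, snp_markers, ssr_markers = [], [], []
    marker_rows = []
    snp_truth: dict[str, str] = {}
    snp_alleles: dict[str, tuple[str, str]] = {}
    from .genetic import IUPAC

    for i in range(spec.n_markers):
        name = f"M{i + 1:03d}"
        markers.append(name)
        row = {
            "name": name,
            "organism": ORGANISM,
            "marker_type": "",
            "aliases": "",
            "alleles": "",
            "five_prime_flank": "",
            "three_prime_flank": "",
            "primer_F": "",
            "primer_R": "",
            "probe": "",
            "source_sequence": "",
            "source_germplasm": "",
            "genbank_id": "",
            "dbsnp_id": "",
            "repeat_motif": "",
            "product_length": "",
            "screening_method": "",
            "pub": "",
        }
        if i < n_snp:
            snp_markers.append(name)
            row["marker_type"] = "SNP"
            a1, a2 = rng.sample("ACGT", 2)
            snp_alleles[name] = (a1, a2)
            row["alleles"] = f"{a1}/{a2}"
            f5 = "".join(rng.choice("ACGT") for _ in range(20))
            f3 = "".join(rng.choice("ACGT") for _ in range(20))
            row["five_prime_flank"], row["three_prime_flank"] = f5, f3
            snp_truth[name] = f5 + IUPAC[frozenset((a1, a2))] + f3
            if i == 0:
                row["dbsnp_id"] = "rs9000001"
        else:
            ssr_markers.append(name)
            row["marker_type"] = "SSR"
            row["primer_F"] = "".join(rng.choice("ACGT") for _ in range(20))
            row["primer_R"] = "".join(rng.choice("ACGT") for _ in range(20))
            row["repeat_motif"] = rng.choice(["(AG)n", "(CT)n", "(AT)n"])
            row["product_length"] = str(rng.randint(90, 260))
            row["screening_method"] = "2% agarose"
            if len(ssr_markers) == 1:
                seq = "".join(rng.choice("ACGT") for _ in range(60))
                row["probe"] = f"{name}.probe:" + "".join(
                    rng.choice("ACGT") for _ in range(30)
                )
                row["source_sequence"] = f"{name}.src:{seq}"
                row["genbank_id"] = "AF900001"
            if cultivars:
                row["source_germplasm"] = cultivars[0] if i % 5 == 0 else ""
        marker_rows.append([row[c] for c in MARKER_COLUMNS])
    _write_tsv(outdir / "markers.tsv", list(MARKER_COLUMNS), marker_rows)

    # --- maps + positions -------------------------------------------------
    map_name = "PP_MAIN"
    _write_tsv(
        outdir / "maps.tsv",
        [
            "name",
            "unit",
            "map_type",
            "software",
            "population_type",
            "population",
            "organisms",
        ],
        [
            [
                map_name,
                "cM",
                "genetic linkage map",
                "MapMaker",
                "F2",
                "POP_F2" if n_pop else "",
                ORGANISM,
            ]
        ],
    )
    counts["featuremap"] = 1
    counts["featuremapprop"] = 3

    lgs = [f"LG{i + 1}" for i in range(spec.n_linkage_groups)]
    pos_rows = []
    n_posprop = 0
    if lgs:
        for lg in lgs:  # bins first so loci can land inside them
            pos_rows.append(
                [map_name, lg, "bin", f"BIN_{lg}", "0.0",
                 f"{spec.map_length_cM / 2:.1f}", "", "", ""]
            )
            n_posprop += 2
        lg_pos = {lg: 0.0 for lg in lgs}
        for i, marker in enumerate(markers):
            lg = lgs[i % len(lgs)]
            lg_pos[lg] += rng.uniform(2.0, spec.map_length_cM / 8)
            pos_rows.append(
                [map_name, lg, "marker", marker, f"{lg_pos[lg]:.1f}",
                 "", "", "", ""]
            )
            n_posprop += 1
        if markers:  # one marker mapped twice -> distinct locus name
            lg = lgs[-1]
            lg_pos[lg] += 1.7
            pos_rows.append(
                [map_name, lg, "marker", markers[0], f"{lg_pos[lg]:.1f}",
                 "", "", "", ""]
            )
            n_posprop += 1

    # --- QTL / MTL --------------------------------------------------------
    qtl_traits = [EXTRA_TRAIT] + [TRAITS[i % len(TRAITS)] for i in range(1, spec.n_qtl)]
    qtl_rows = []
    for i in range(spec.n_qtl):
        label = f"q{qtl_traits[i]}.{i + 1}"
        qtl_rows.append(
            [
                label,
                ORGANISM,
                qtl_traits[i],
                f"Q{i + 1}",
                f"{rng.uniform(5, 40):.1f}",
                f"{rng.uniform(2.5, 9.0):.1f}",
                markers[i % len(markers)] if markers else "",
                markers[(i + 1) % len(markers)] if len(markers) > 1 else "",
                cultivars[0] if cultivars else "",
                "QTL_STUDY_1",
                "pub:qtl_study_1",
            ]
        )
    _write_tsv(
        outdir / "qtl.tsv",
        [
            "label", "organism", "trait", "aliases", "R_square", "LOD",
            "colocalized_markers", "neighboring_markers", "source_germplasm",
            "dataset", "pub",
        ],
        qtl_rows,
    )
    mtl_rows = []
    for i in range(spec.n_mtl):
        mtl_rows.append(
            [
                f"MTL_{TRAITS[(i + 2) % len(TRAITS)]}",
                ORGANISM,
                TRAITS[(i + 2) % len(TRAITS)],
                "",
                f"mtl{i + 1}",
                gene_names[i % len(gene_names)] if i == 0 else "",
            ]
        )
    _write_tsv(
        outdir / "mtl.tsv",
        ["label", "organism", "trait", "aliases", "published_symbol",
         "underlying_gene"],
        mtl_rows,
    )
    if lgs:
        for i, row in enumerate(qtl_rows):
            lg = lgs[i % len(lgs)]
            start = rng.uniform(5, spec.map_length_cM * 0.6)
            stop = start + rng.uniform(4, 18)
            peak = (start + stop) / 2
            pos_rows.append(
                [map_name, lg, "QTL", row[0], f"{start:.1f}", f"{stop:.1f}",
                 f"{peak:.1f}", "", ""]
            )
            n_posprop += 3
        for i, row in enumerate(mtl_rows):
            lg = lgs[(i + 1) % len(lgs)]
            pos_rows.append(
                [map_name, lg, "MTL", row[0],
                 f"{rng.uniform(5, spec.map_length_cM):.1f}", "", "", "", ""]
            )
            n_posprop += 1
    _write_tsv(
        outdir / "positions.tsv",
        ["map", "linkage_group", "locus_type", "target", "start", "stop",
         "peak", "probability", "comments"],
        pos_rows,
    )
    counts["featurepos"] = len(pos_rows)
    counts["featureposprop"] = n_posprop

    # --- projects, descriptors, phenotypes -------------------------------
    pheno_project = "BREED_EVAL_2014"
    geno_project = "GENO_SCAN_1"
    _write_tsv(
        outdir / "projects.tsv",
        ["name", "description"],
        [
            [pheno_project, "synthetic cultivar evaluation"],
            [geno_project, "synthetic genotyping scan"],
        ],
    )

    n_coded = int(round(spec.coded_fraction * spec.n_descriptors))
    coded_pool = ["fruit_color", "flowering_time", "disease_resistance"]
    quant_pool = ["fruit_weight", "fruit_firmness"]
    descriptor_plan = [  # (name, coded?)
        (name, True) for name in coded_pool[:n_coded]
    ] + [(name, False) for name in quant_pool[: spec.n_descriptors - n_coded]]
    desc_rows = []
    for name, coded in descriptor_plan:
        codes = (
            ";".join(f"{c}=level {c}" for c in range(1, spec.code_range + 1))
            if coded
            else ""
        )
        standard_of = ""
        code_map = ""
        if coded and name == "fruit_color":
            standard_of = "fruit_color_std"
            code_map = ";".join(
                f"{c}={2 * c}" for c in range(1, spec.code_range + 1)
            )
        desc_rows.append([pheno_project, name, codes, standard_of, code_map])
    if any(n == "fruit_color" and c for n, c in descriptor_plan):
        desc_rows.append(
            [
                pheno_project,
                "fruit_color_std",
                ";".join(f"{c}=std level {c}" for c in range(1, 11)),
                "",
                "",
            ]
        )
    _write_tsv(
        outdir / "descriptors.tsv",
        ["project", "name", "codes", "standard_of", "code_map"],
        desc_rows,
    )

    pheno_rows = []
    pheno_pairs = set()
    for gi, (germ, sample) in enumerate(samples):
        for name, coded in descriptor_plan:
            if coded:
                value = str(rng.randint(1, spec.code_range))
            else:
                value = f"{rng.gauss(10.0 + 0.5 * (gi % 7), 1.0):.1f}"
            pheno_rows.append([pheno_project, sample, name, value, "", ""])
            pheno_pairs.add((name, value))
    _write_tsv(
        outdir / "phenotypes.tsv",
        ["project", "stock", "descriptor", "value", "sd", "location"],
        pheno_rows,
    )

    # --- genotypes, haplotypes, effects -----------------------------------
    geno_rows = []
    geno_pairs = set()
    genotyped = cultivars + wilds
    for marker in snp_markers:
        a1, a2 = snp_alleles[marker]
        p = rng.uniform(0.2, 0.8)
        for stock in genotyped:
            if rng.random() < spec.missing_rate:
                continue
            call = sorted(
                (a1 if rng.random() < p else a2) for _ in range(2)
            )
            geno_rows.append([geno_project, stock, marker, "/".join(call)])
            geno_pairs.add((marker, "|".join(call)))
    _write_tsv(
        outdir / "genotypes.tsv",
        ["project", "stock", "marker", "alleles"],
        geno_rows,
    )

    hap_rows = []
    hap_calls = set()
    block = "HAP1"
    if len(snp_markers) >= 3:
        members = snp_markers[:3]
        for stock in cultivars[:4]:
            hap = "-".join(
                rng.choice(snp_alleles[m]) for m in members
            )
            hap_rows.append(
                [geno_project, stock, block, ";".join(members), hap]
            )
            hap_calls.add(hap)
    _write_tsv(
        outdir / "haplotypes.tsv",
        ["project", "stock", "block", "members", "haplotype"],
        hap_rows,
    )

    effect_rows = []
    effect_pairs = set()
    for i, hap in enumerate(sorted(hap_calls)):
        value = f"+{0.5 * (i + 1):.1f}"
        effect_rows.append(
            [f"{block}_{hap}", pheno_project, "fruit_weight", value, "unspecified"]
        )
        effect_pairs.add(("fruit_weight", value))
    _write_tsv(
        outdir / "haplotype_effects.tsv",
        ["genotype", "project", "descriptor", "value", "environment"],
        effect_rows,
    )

    # --- derived expected counts ------------------------------------------
    n_feature += spec.n_markers
    n_feature += 2 * len(ssr_markers)  # F/R primers
    n_feature += 1 if ssr_markers else 0  # probe
    n_feature += 1 if ssr_markers else 0  # source sequence
    n_loci = (len(markers) + (1 if markers and lgs else 0)) if lgs else 0
    n_feature += n_loci
    n_feature += len(lgs) if lgs else 0  # linkage groups
    n_feature += len(lgs) if lgs else 0  # bins
    n_feature += spec.n_qtl + spec.n_mtl
    n_feature += 1 if hap_rows else 0  # haplotype block
    counts["feature"] = n_feature
    counts["phenotype"] = len(pheno_pairs | effect_pairs)
    counts["genotype"] = len(geno_pairs) + len(hap_calls)
    counts["nd_experiment"] = (
        len(pheno_rows) + len(geno_rows) + len(hap_rows) + len(passport_rows)
    )
    counts["phenstatement"] = len(effect_rows)
    counts["nd_geolocation"] = len(passport_rows) + (
        1 if (pheno_rows or geno_rows or hap_rows or effect_rows) else 0
    )
    counts["project"] = 2 + (1 if qtl_rows else 0)

    manifest = {
        "spec": asdict(spec),
        "organism": ORGANISM,
        "map": map_name,
        "projects": {"phenotyping": pheno_project, "genotyping": geno_project},
        "snp_truth": snp_truth,
        "expected_counts": counts,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


MARKER_COLUMNS = (
    "name",
    "organism",
    "marker_type",
    "aliases",
    "alleles",
    "five_prime_flank",
    "three_prime_flank",
    "primer_F",
    "primer_R",
    "probe",
    "source_sequence",
    "source_germplasm",
    "genbank_id",
    "dbsnp_id",
    "repeat_motif",
    "product_length",
    "screening_method",
    "pub",
)


def load_fixture(store: Store, fixture_dir: str | Path) -> dict[str, int]:
    """Run every loader over a generated fixture tree, in dependency order."""
    from . import genetic, genomic, germplasm, phenogeno, vocab

    d = Path(fixture_dir)
    loaded: dict[str, int] = {}
    loaded["sequence_terms"] = vocab.load_obo(store, d / "sequence.obo", "sequence")
    loaded["relationship_terms"] = vocab.load_obo(
        store, d / "relationship.obo", "relationship"
    )
    loaded["trait_terms"] = vocab.load_obo(store, d / "traits.obo", "trait_ontology")
    vocab.bootstrap_inventory(store)
    loaded["chromosomes"] = genomic.load_fasta(
        store, d / "genome.fasta", ORGANISM, "chromosome"
    )
    summary = genomic.load_gff3(store, d / "annotation.gff3", ORGANISM)
    loaded["annotation_features"] = summary.features
    loaded["germplasm"] = germplasm.load_germplasm_tsv(store, d / "germplasm.tsv")
    loaded["samples"] = germplasm.load_samples_tsv(store, d / "samples.tsv")
    loaded["pedigree_edges"] = germplasm.load_pedigree_tsv(store, d / "pedigree.tsv")
    loaded["collections"] = germplasm.load_collections_tsv(
        store, d / "collections.tsv"
    )
    loaded["accessions"] = germplasm.load_accessions_tsv(store, d / "accessions.tsv")
    loaded["passports"] = germplasm.load_passport_tsv(store, d / "passport.tsv")
    loaded["markers"] = genetic.load_markers_tsv(store, d / "markers.tsv")
    loaded["maps"] = genetic.load_maps_tsv(store, d / "maps.tsv")
    loaded["qtl"] = genetic.load_qtl_tsv(store, d / "qtl.tsv")
    loaded["mtl"] = genetic.load_mtl_tsv(store, d / "mtl.tsv")
    loaded["positions"] = genetic.load_positions_tsv(store, d / "positions.tsv")
    import pandas as pd

    projects = pd.read_csv(
        d / "projects.tsv", sep="\t", dtype=str, keep_default_na=False
    )
    for _, row in projects.iterrows():
        store.ensure_project(row["name"], row.get("description", ""))
    loaded["projects"] = len(projects)
    loaded["descriptors"] = phenogeno.load_descriptors_tsv(
        store, d / "descriptors.tsv"
    )
    loaded["phenotypes"] = phenogeno.load_phenotypes_tsv(store, d / "phenotypes.tsv")
    loaded["genotypes"] = phenogeno.load_genotypes_tsv(store, d / "genotypes.tsv")
    loaded["haplotypes"] = phenogeno.load_haplotypes_tsv(store, d / "haplotypes.tsv")
    loaded["haplotype_effects"] = phenogeno.load_haplotype_effects_tsv(
        store, d / "haplotype_effects.tsv"
    )
    store.commit()
    return loaded
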