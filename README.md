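# chadolite

An embedded, ontology-driven relational store for integrated genomic,
genetic and breeding data — the kind of data a crop database curates:
whole-genome annotation, molecular markers (SSR/SNP/RFLP/...), genetic
maps with marker loci and bins, QTL and Mendelian trait loci (MTL),
germplasm with pedigrees, samples and clones, stock-center collections,
passport records, and large-scale phenotyping/genotyping experiments.

It is aimed at breeding-informatics developers and curators who want the
Chado storage conventions for these data in a zero-setup, single-file
(SQLite) form: the table and column names follow Chado, every record is
typed by a controlled-vocabulary term (`cvterm`) rather than by a
dedicated table, and all of the community's custom linker/property
tables for breeding data (`featuremapprop`, `featureposprop`,
`feature_stock`, `stockcollection_db`, ...) are present.

## The storage model

The core discipline is *typing by ontology*:

- every sequence entity — gene, mRNA, genetic_marker, marker_locus, QTL,
  linkage_group, haplotype_block, bin — is a `feature` row whose
  `type_id` is a Sequence Ontology term; relationships (`part_of`,
  `derives_from`, `instance_of`, `located_in`, `contains`, ...) live in
  `feature_relationship`;
- genome locations use 0-based interbase `[fmin, fmax)` in `featureloc`;
  genetic-map positions live in `featureposprop` (`start`, `stop`,
  `qtl_peak`) because a QTL carries up to three positions per placement;
- SNP alleles are collapsed to one IUPAC ambiguity base and embedded
  between their flanking sequences to give searchable residues
  (alleles A/T with flanks `ACGT`/`GGCC` store residues `ACGTWGGCC`);
- germplasm at every level (population, cultivar, clone, sample) is a
  `stock`; pedigrees are `stock_relationship` edges read as
  "*parent* `maternal_parent_of` *child*", kept acyclic;
- each phenotypic or genotypic measurement is one `nd_experiment`
  linking a stock, a project, a geolocation and a deduplicated
  `phenotype` (`<descriptor>_<value>`) or `genotype`
  (`<marker>_<alleles sorted and joined with '|'>`) record;
- genotype→phenotype statements (e.g. a haplotype's effect on fruit
  weight) are `phenstatement` rows.

A conformance validator audits a whole store against these conventions
(dangling terms, uniquename rules, pedigree cycles, missing map
positions, non-canonical genotype strings, coordinate sanity) and
pinpoints every offending record.

## Worked example

Everything is runnable without any download: the fixture generator
emits a complete synthetic dataset (ontologies, genome, markers, maps,
germplasm, trials) from one seed.

```sh
chadolite make-fixture fix --seed 7
chadolite init --store breeding.sqlite
chadolite load-fixture --store breeding.sqlite fix
chadolite validate --store breeding.sqlite
chadolite query --store breeding.sqlite marker M001
```

The load reports per-loader row counts:

```json
{"command": "load-fixture", "loaded": {"accessions": 2,
 "annotation_features": 18, "chromosomes": 2, "collections": 1,
 "descriptors": 5, "genotypes": 164, "germplasm": 16,
 "haplotype_effects": 4, "haplotypes": 4, "maps": 1, "markers": 24,
 "mtl": 2, "passports": 2, "pedigree_edges": 18, "phenotypes": 52,
 "positions": 34, "projects": 2, "qtl": 4, "samples": 13, ...},
 "status": "ok"}
{"command": "validate", "status": "ok", "violations": 0}
```

`validate` returning `"violations": 0` means the loaded store satisfies
every storage convention. The marker report aggregates everything
linked to one marker — note the two loci: the fixture maps `M001` to two
positions on the same map, so the second locus gets a distinct name:

```json
{"marker": "M001",
 "props": {"allele": ["A/G"], "marker_type": ["SNP"], ...},
 "loci": [
   {"locus": "M001",      "map": "PP_MAIN", "linkage_group": "LG1",
    "positions": {"start": "7.8"}},
   {"locus": "M001_loc2", "map": "PP_MAIN", "linkage_group": "LG3",
    "positions": {"start": "56.9"}}],
 "genotypes": ["A|A", "A|G", "G|G"],
 "dbxrefs": ["dbSNP:rs9000001"]}
```

The three genotype strings are the canonical allele concatenations
observed across the genotyped germplasm (`A|G` is the heterozygote; copy
number is preserved, so a homozygote is `A|A`, never `A`).

`chadolite export DIR` writes one sorted, natural-key TSV per table plus
a manifest; `chadolite import DIR` rebuilds an equivalent store, and a
re-export is byte-identical to the original.

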