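# Methods

## Scope and model

chadolite implements the subset of the Chado relational schema needed to
integrate genomic, genetic and breeding data, plus the community's
custom breeding tables (22 linker/property/relationship tables such as
`featuremapprop`, `featureposprop`, `feature_stock`,
`stockcollection_db`, `organism_relationship`). The backend is a single
SQLite file: table and column names match Chado so the store doubles as
documentation, surrogate integer keys are auto-assigned, and natural
keys (uniquenames, cv/term pairs) are the only identifiers loaders and
exports speak — loads are therefore order-independent up to the stated
dependency order.

Typing is ontological throughout. Feature types must resolve in the
"sequence" vocabulary; stock and experiment types in the in-house
"local" vocabulary; relationship types in a closed registered set.
Trait names resolve against a trait ontology loaded from OBO; a name
with no exact match is created in `local_trait` and flagged provisional
(a `cvtermprop`), never silently added to the ontology itself. Term
matching is exact and case-sensitive; OBO synonyms are loaded as
alternative lookup keys only. One deliberate spelling bridge exists:
`heritable_morphological_marker`, used by some curation templates for
Mendelian trait loci, resolves via synonym to the SO term
`heritable_phenotypic_marker`, which is what MTL features are typed
with. Likewise the marker→source-sequence relationship is stored as
`derived_from` with the marker as subject (the direction some
free-text descriptions give as `sequence_of` from the other side).

## Conventions enforced

- Coordinates: `featureloc` is 0-based interbase half-open, strand in
  {−1, 0, +1}; GFF3's 1-based inclusive spans convert as
  `fmin = start − 1`, `fmax = end`.
- Map positions: never in `featurepos.mappos`; always `featureposprop`
  rows (`start`, optional `stop`/`qtl_peak`/`probability`/`comments`),
  because QTL carry an interval plus a peak. Every placement must have
  a `start`; `stop ≥ start` is validated numerically at load time
  (props themselves are stored as text, as Chado prop values are).
- Locus naming: the first placement of a marker on a map reuses the
  marker name; further placements on the same map get `_loc2`,
  `_loc3`, ... (the convention requires distinct names but no scheme;
  the suffix is this package's choice). Linkage groups are scoped per
  map as `<map>.<lg>` since the same LG label recurs across maps.
  Bins are features typed `bin` in the "sequence" cv (schema-wide
  feature typing is kept uniform), scoped per map the same way; a locus
  whose start lies inside a bin's interval on the same linkage group
  gets a `located_in` edge to the bin.
- SNP residues: the unique allele set maps to its IUPAC ambiguity code
  ({A,T}→W, ..., {A,C,G,T}→N) between the 5′ and 3′ flanks; non-ACGT
  or multi-base alleles are not encodable, in which case only the
  `allele` property is stored and residues stay empty.
- Genotypes: alleles are trimmed, byte-wise lexicographically sorted
  (no numeric collation — `["102","98"]` → `102|98` — chosen for
  locale-independent determinism), joined with `|`, duplicates kept so
  copy number survives. `genotype.uniquename` is
  `<marker>_<description>`; `phenotype.uniquename` is
  `<descriptor>_<value>`. Haplotype calls reuse the machinery with the
  haplotype_block feature as the linked marker; the separator inside a
  haplotype string is caller-defined (`-` by convention, keeping `|`
  for copy number).
- Coded trait descriptors: one cv per project (`<project>_descriptors`);
  each code is a `cvtermprop` with rank = numeric code and value = the
  code's meaning (which field holds which is unspecified upstream; this
  assignment is documented here). A descriptor's community standard and
  code map are kept as a JSON-valued `standard_of` prop; dual coding is
  an explicit operation that records the observation under both
  descriptors (two phenotypes, two experiments, same stock/project).
  The bulk phenotype loader never dual-codes implicitly, preserving the
  invariant that phenotyping experiments equal input measurement rows.
- Pedigrees: edges are subject = parent, object = child, so rows read
  "<parent> maternal_parent_of <child>" (the terms are fixed upstream,
  the direction is this package's choice). At most one maternal and one
  paternal edge per child (unknown parents simply omit the edge), and
  an edge that would close a cycle is rejected with the offending path.
- `nd_experiment` always has a geolocation; a singleton "unspecified"
  geolocation stands in when none is given. Geolocations deduplicate on
  (description, lat, lon, alt).

## Validator

`check_integrity` re-derives every convention store-wide: dangling
foreign keys (via `PRAGMA foreign_key_check`, reachable only by
out-of-API corruption), type terms outside their table's vocabulary,
disallowed relationship types, phenotype/genotype/primer uniquename
breaches, non-canonical genotype descriptions, pedigree cycles (SCCs of
the parent-edge graph; every edge inside a cycle is reported), map
placements lacking `start`, `fmin > fmax`, and residues/seqlen
disagreement. Each violation carries a stable kind and the surrogate id
of the offending record, so seeded-corruption tests can verify the
validator pinpoints every mutated row.

## Export / import round trip

Exports are one TSV per table, columns in schema order with every
foreign key replaced by the target's natural key (composite keys join
components with `::`), rows sorted lexicographically; a manifest records
the schema version and row counts. `nd_experiment` has no natural key,
so experiments are keyed `E000000...` by their position in a canonical
sort of their full linked content (type, geolocation, linked stocks,
projects, phenotypes, genotypes, contacts, props); identical content is
interchangeable, which keeps export → import → export byte-stable. One
known limitation: two placements of the same feature on the same map
and linkage group share a featurepos natural key and would merge on
import; the locus-naming convention makes this unreachable for marker
loci, and the fixture never produces it for QTL/bins.

## Synthetic data generator

`fixtures.generate` emulates a small breeding programme for a stone
fruit (Prunus): a 2-chromosome, 2 kb-each genome with three toy gene
models; 24 markers (half SNPs with 20-base flanks and two alleles, half
SSRs with primer pairs); one cM linkage map with 3 linkage groups, one
bin per group, every marker placed once (one marker twice), 4 QTL with
start/stop/peak and 2 MTL; 16 germplasm entries (cultivars with a
3-generation pedigree including one bud sport, two wild accessions with
collection/passport records, one F2 population); one sample per
cultivar; 4 trait descriptors (half coded 1–5 with a 1–10 standard and
code map, half quantitative); phenotypes for every sample × descriptor;
genotype calls for every SNP × germplasm under Hardy–Weinberg with one
uniform allele frequency per marker (the simplest defensible population
model) and 10% missingness; one 3-marker haplotype block with calls and
per-haplotype effect statements. Defaults keep an end-to-end load
around 1 700 rows — structure-complete rather than scale-realistic —
and all sizes are dials on `FixtureSpec`. Ontology files are synthetic
mini-OBOs (a few dozen terms with placeholder accessions), not excerpts
of the real SO/RO/TO; one trait is deliberately absent from the trait
OBO to exercise the provisional-term path.

What the generator does not emulate: genetic linkage/recombination
(marker positions are independent draws, not a linkage simulation),
genotyping error, shared environments across trials, or realistic trait
architectures. Passing tests therefore demonstrate that the storage
conventions, validator, queries and round trip are correct — not that
any biological inference would hold on real data.

As it writes, the generator counts the records each loader must create
(features including synthesized polypeptides, loci and linkage groups;
deduplicated phenotype/genotype rows; one nd_experiment per measurement
row plus passports) and stores them in its manifest; the end-to-end
test and the acceptance script assert exact equality per table.

## Numerical and design choices

- Ranks for properties are contiguous per (owner, type), in insertion
  order, starting at 0.
- Uniquenames compare case-sensitively after whitespace trimming.
- Stock uniqueness mirrors feature uniqueness: (organism, uniquename,
  type).
- Colocalized/neighboring markers of a QTL get ranks 0..k in input
  order.
- Polypeptides are synthesised per coding transcript (spanning its CDS
  rows, `derives_from` the mRNA) unless the GFF3 ships its own
  polypeptide rows; choosing the mRNA (not the CDS) as the
  `derives_from` target is deliberate.
- Query-layer sorting is total and deterministic: map views order by
  numeric start then locus name; exports sort rows lexicographically.
- Population membership of individuals has no fixed upstream term; a
  provisional `member_of` local term is registered but no loader emits
  it.

## Limitations

Single-writer embedded store; no server or concurrency guarantees. Only
the breeding-relevant subset of Chado is present (`library_stock` /
`library_contact` exist for completeness but have no loader). EST
assembly, functional annotation, map construction and any statistical
genetics (QTL detection, BLUPs, imputation) are out of scope — the
store records the results of such analyses, it does not perform them.
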