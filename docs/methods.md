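# Methods

## Taxonomy standardization

The taxonomy store loads a local tree in the NCBI taxdump dialect (nodes
and names tables, fields separated by `\t|\t`, records terminated by
`\t|`). Only names of class `scientific name` are indexed; synonyms and
common names are out of scope. Loading validates the tree completely:
exactly one root (the node that is its own parent), no orphan parents, no
cycles, no unnamed nodes — a malformed line reports file and line number,
an integrity violation lists the offending txids. Updating the store is an
explicit rebuild (`extaxsi build-store`); there are no background
downloads.

`resolve_lineage` standardizes any txid to the six main ranks (phylum,
class, order, family, genus, species). For each rank it takes the
scientific name of the nearest ancestor-or-self whose rank label matches
(case-insensitively). Ranks with no labelled ancestor are fallback-filled
with the scientific name of the nearest *named* ancestor-or-self; since
every valid taxdump node carries a scientific name, this is the queried
node's own name. Consequences worth knowing:

- the root resolves to its own name at all six ranks;
- a genus-level query fills the species slot with the genus name;
- a species hanging under unranked (`no rank`) ancestors gets its own
  name at the missing upper ranks, and any labelled ancestor (say a
  family) still lands in its proper slot.

This guarantees serialized paths (`;`-joined, six fields) never contain
blanks, which downstream taxonomy-mapping consumers require. The
alternative — filling each missing rank with the immediate parent's name —
differs only when the parent is itself unnamed, a state the loader
rejects; the behaviours coincide on valid input.

Name→txid lookup is case-insensitive exact matching. Homonyms return
every candidate txid in ascending order, and batch conversion flags such
rows `ambiguous` with one row per candidate; failing loudly was preferred
to picking silently. Unresolvable batch rows are flagged `unresolved`
rather than aborting the batch.

## Retrieval protocol

Queries are rendered in the Entrez term dialect: a numeric organism term
`N` becomes `txidN[ORGN]`, a name `name[ORGN]`, each gene term
`g[gene]`, all joined with ` AND `, raw extra terms appended verbatim.

Retrieval is windowed by `retstart` offset: requests below the batch size
(default 2,500 records) use a single window, larger result sets are split
into contiguous windows. Each window's raw text goes to a numbered
temporary file; on success temporaries are concatenated in window order
into `records.gb` and deleted. Record order is the id order returned by
search, so merged output is byte-identical for any batch size. Duplicate
ids are fetched once (first occurrence wins). On persistent window
failure (3 attempts, exponential backoff) the run aborts naming the
window and retains completed temporaries; a rerun skips them (resume).

The `Transport` contract (`search(query, offset, limit)`,
`fetch(ids)`) decouples all of this from the network. The fixture
transport replays a canned accession→record mapping deterministically and
can inject failures at chosen offsets. The live transport is a stdlib
urllib client with a token-bucket rate limiter — 3 requests/s without an
API key, 10 with, per the endpoint's etiquette; the limiter's clock is
injectable so the ceiling is testable with fake time.

## Record parsing and geography

Flat-file parsing is delegated to Biopython; the package extracts the
versioned accession, organism, txid (`db_xref="taxon:N"` on the source
feature, with the source-feature `organism` qualifier as fallback when
the annotation header is absent), sequence, definition, and the `gene`
qualifier of *every* feature type (gene, CDS, rRNA, ...), deduplicated in
first-appearance order. A truncated corpus (missing `//`) is a parse
error reporting the last complete accession.

Geography is split the way the world map needs it: a parseable `lat_lon`
(`<deg> N|S <deg> E|W`, optional decimals; N/E positive, S/W negative)
yields coordinates; otherwise a `country` qualifier yields the text
before the first `:` (region detail stripped, no gazetteer lookup);
otherwise the record is unlocated. `extract_geo` never raises:
unparseable `lat_lon` strings log a warning and fall through to the
country branch. Coordinate aggregation keys round to 4 decimal places
(≈11 m) to merge trivially different encodings of one site.

## Database outputs

FASTA headers are `>accession definition` with sequences wrapped at 70
columns; duplicate accessions are written once. The taxonomy TSV writes
`accession<TAB>path`; records whose txid is missing or unknown fall back
to an unambiguous organism-name lookup before being flagged `unresolved`
(the writer returns resolved and unresolved counts, which always sum to
the input size).

The gene survey counts *records per gene*: a record tagged with the same
gene twice counts once, since the quantity of interest is accessions
carrying a marker. Spellings differing only in case merge
(case-insensitively) under the first-seen spelling; case-sensitive
counting is the documented alternative. Ranking is count-descending with
case-insensitive lexicographic tie-break — a total order, so tables,
plots and the top-10 PNG cutoff are reproducible byte for byte.

## Visualization

The frequency filter applies at the terminal (species) level: species
with fewer records than the threshold are removed, their paths dropped,
which propagates the removal to every rank above. Discarded units go to
`filtered_out_min{threshold}.tsv` (threshold embedded in the name);
threshold 0 is the identity and writes nothing. Applying the filter per
displayed rank instead is a one-line change documented here as the
alternative.

Scatter data is a per-rank series of (taxon, count, parent-taxon) with
same-named taxa under different parents kept separate, so every rank's
counts sum to the corpus size. Sunburst nodes are keyed by the full path
prefix, disambiguating homonyms, and every internal node's count equals
the sum of its children. World-map points carry a legend concatenating
the distinct record labels at that site plus the record count; when
labels collide the concatenation is the documented choice. Marker style
(green cross for coordinates, red circle for countries) travels as
metadata in the plot data; rendering is an implementation detail.

HTML export embeds the complete dataset as a JSON `<script>` block inside
a self-contained page rendered by inline vanilla JavaScript/SVG (rank
selector for the scatter, collapsible hierarchy for the sunburst, an
equirectangular point map). No network resources are referenced, and
`extract_embedded_data` recovers the exact payload, which is how export
round-trips are tested.

## Synthetic fixtures

The fixture generators make every operation testable offline and define
the conditions the tests run under:

- **Taxonomies** are built as species-terminated chains branching off
  existing taxa, after a guaranteed complete phylum→species chain, so
  with `rank_missing_prob = 0` every leaf has a full six-rank ancestry.
  Each additional node's rank is dropped to `no rank` with probability
  `rank_missing_prob`, exercising the fallback; the generator records
  which nodes were eligible for the drop so the realized fraction can be
  checked against binomial bounds.
- **Record corpora** assign each gene in the pool to an exact-size random
  record subset (per-gene record counts are exact by construction),
  split geography by exact fractions (coordinates / country / none), and
  occasionally duplicate a gene feature within a record to exercise
  per-record dedup. Coordinates are drawn uniformly per hemisphere at 4
  decimal places. Sequences are random nucleotides of 200–1,500 bp:
  content is irrelevant to every tested operation, only identity and
  length round-trips are checked.
- The **curated demo fixture** encodes public placements of the Atlantic
  cod lineage (txid 8049 under Gadus, Gadidae, Gadiformes,
  Actinopterygii, Chordata), the Vertebrata clade (7742), sister
  Gadiformes families with their published record abundances (Gadidae
  381,460; Merlucciidae 3,252; Macrouridae 1,673), a sparsely ranked
  virus branch ending in SARS-CoV-2 (2697049), and a cod corpus whose
  marker counts match the published survey (CYTB 985, COI 455, ND2 311
  records). txids not fixed by those facts are synthetic (≥ 900000).

What the fixtures do *not* emulate: real sequence content and alignment
structure, accession semantics beyond uniqueness, the live database's
scale and snapshot drift, NCBI's full rank vocabulary, or messy real-world
`country` strings beyond the `Country: region` pattern. Passing tests
therefore demonstrate the correctness of the retrieval protocol, lineage
logic, counting and aggregation — not robustness to every dialect
irregularity in historical GenBank submissions.

## Problem sizes and numerical choices

The test suite and the acceptance script use: 100 random trees of ≤200
nodes for the lineage oracle (every node checked), a 37-record corpus for
batch invariance (batch sizes 1/3/2,500), the 2,000-record cod demo
corpus for the gene survey, 1,000 random paths for filter/scatter/
sunburst conservation, and 1,000 formatted coordinates across all four
hemisphere sign combinations for the geographic round-trip (tolerance
1e-9°, though the round-trip is exact in practice). These sizes fully
exercise every code path while keeping the whole suite in seconds.

Degenerate inputs are defined, not errors: empty search results produce
an empty merged file plus a warning; empty record lists produce empty
FASTA/TSV outputs; an empty gene table produces no PNG; empty plot data
still exports valid HTML. The only hard failures are malformed inputs
(taxdump syntax, >6-field taxonomy rows, truncated records) and
exhausted download retries.

## Limitations

Only the nucleotide database is targeted; history-server (WebEnv)
optimization and parallel window fetching are not implemented. Name
resolution covers scientific names only — no fuzzy matching or synonyms.
Country normalization does no gazetteer lookup, so spelling variants of
one country remain separate map points. The live transport is exercised
in tests only through its rate limiter and retry logic, not against the
real endpoint.
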