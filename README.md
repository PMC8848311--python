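# extaxsi

Exploration of taxonomic and molecular information from NCBI-style
nucleotide databases, for researchers designing DNA metabarcoding and
metagenomics experiments.

Building a metabarcoding study starts with two questions: *what reference
sequences exist for my taxa and markers?* and *where do they come from?*
This package answers both. It retrieves nucleotide records for an organism
(name or txid) and optional gene terms, standardizes every record's
taxonomy to the six main ranks —

```
phylum; class; order; family; genus; species
```

— against a local taxdump-dialect taxonomy store, and emits:

- **molecular databases**: a multi-FASTA of sequences, a two-column
  `accession<TAB>taxonomy-path` TSV (directly usable as a reference
  taxonomy mapping by assignment tools), and a gene-frequency table with a
  top-10 bar-plot PNG;
- **interactive exploration plots** as self-contained HTML files: a
  per-rank scatter of taxon abundances, a sunburst of the taxonomy
  hierarchy, and a world map of georeferenced records (sampling
  coordinates as green crosses, bare country names as red circles).

Taxa that lack one of the six ranks are fallback-filled with the nearest
named ancestor's scientific name (the parent-txid substitution), so
emitted paths never contain blanks. Retrieval is windowed in batches of
2,500 records with per-window temporary files merged at the end; all
network interaction sits behind a transport contract, so the entire tool
runs offline against fixture corpora — which is also how it is tested.

## Worked example (offline, built-in demo fixture)

```sh
extaxsi fixtures demo --out demo            # demo taxonomy store + corpus
extaxsi database --txid 8049 --fixture demo --store demo/store --out db
```

prints

```
db: 2000 sequences, 2000 taxonomy rows (0 unresolved), 3 distinct genes (1329/2000 records tagged)
```

meaning: 2,000 Atlantic cod (*Gadus morhua*, txid 8049) records were
retrieved from the canned corpus, all 2,000 resolved to a full six-rank
lineage, and 1,329 of them carry a `gene` qualifier covering 3 distinct
genes. `db/gene_frequencies.tsv` holds the survey — CYTB 985, COI 455,
ND2 311 records, the classic mitochondrial-marker skew for this species —
and `db/top_genes.png` the bar plot. Each row of `db/taxonomy.tsv` looks
like:

```
FX000001.1	Chordata;Actinopterygii;Gadiformes;Gadidae;Gadus;Gadus morhua
```

Convert identifiers directly:

```sh
$ extaxsi convert --txid 8049 --store demo/store
input_value	txid	rank	lineage	status
8049	8049	species	Chordata;Actinopterygii;Gadiformes;Gadidae;Gadus;Gadus morhua	ok
```

And plot, with a frequency filter that moves species seen fewer than 3
times into `filtered_out_min3.tsv`:

```sh
extaxsi viz scatter --input db/taxonomy.tsv --filter 3 --out db/scatter.html
extaxsi viz worldmap --input db/records.gb --out db/map.html
```

The HTML files open offline; the full plot dataset is embedded as JSON
inside each file (`extaxsi.extract_embedded_data` reads it back).

For live NCBI retrieval, drop `--fixture` and pass `--email` (and
optionally `--api-key`); requests are rate-limited to the endpoint's
published etiquette and retried with bounded backoff.

The same operations are available as a library
(`extaxsi.run_download`, `resolve_lineage`, `gene_frequency`,
`build_sunburst`, ...); every CLI command is a thin shell over them and
produces byte-identical files.

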