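"""Synthetic taxonomies and record corpora with ground-truth manifests.

Everything the tool consumes from the network or from NCBI dumps can be
generated here offline: random taxdump-dialect trees (with controllable
rank incompleteness, to exercise the lineage fallback), GenBank-dialect
record corpora with controllable gene qualifiers and geography, and a
curated demo fixture encoding well-known placements from the public NCBI
taxonomy (Atlantic cod and relatives, plus SARS-CoV-2) together with a
gene-survey profile matching published record counts for *Gadus morhua*
markers.  Each generator returns a manifest of ground truth whose marginals
are recomputable from the emitted files by brute force.

Sequences are random nucleotides of 200-1,500 bp: sequence content is
irrelevant to every operation the tool performs, only identity and length
round-trips are ever checked.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .taxonomy import MAIN_RANKS, TaxonNode, TaxonomyTable, resolve_lineage

NODES_FILENAME = "nodes.dmp"
NAMES_FILENAME = "names.dmp"
RECORDS_FILENAME = "records.gb"


def write_taxdump(nodes: dict[int, TaxonNode], out_dir: str | Path) -> tuple[Path, Path]:
    """Write nodes/names tables in the taxdump dialect; returns both paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nodes_file = out_dir / NODES_FILENAME
    names_file = out_dir / NAMES_FILENAME
    ordered = sorted(nodes.values(), key=lambda n: n.txid)
    with open(nodes_file, "w", encoding="utf-8") as fh:
        for n in ordered:
            fh.write(f"{n.txid}\t|\t{n.parent_txid}\t|\t{n.rank}\t|\n")
    with open(names_file, "w", encoding="utf-8") as fh:
        for n in ordered:
            fh.write(f"{n.txid}\t|\t{n.scientific_name}\t|\t\t|\tscientific name\t|\n")
    return nodes_file, names_file


@dataclass
class TaxonomyFixture:
    """A generated taxonomy tree plus its generation bookkeeping."""

    seed: int
    nodes: dict[int, TaxonNode]
    #: txids eligible for the rank-dropping coin flip (everything outside
    #: root and the guaranteed complete chain)
    flippable: list[int] = field(default_factory=list)

    @property
    def n_norank_flippable(self) -> int:
        return sum(1 for t in self.flippable if self.nodes[t].rank == "no rank")

    def table(self) -> TaxonomyTable:
        return TaxonomyTable(dict(self.nodes))

    def write(self, out_dir: str | Path) -> tuple[Path, Path]:
        return write_taxdump(self.nodes, out_dir)


def make_taxonomy(seed: int, n_nodes: int = 50,
                  rank_missing_prob: float = 0.0,
                  out_dir: str | Path | None = None) -> TaxonomyFixture:
    """Generate a random taxonomy tree in taxdump dialect.

    The tree always contains root plus one guaranteed complete six-rank
    chain (phylum..species).  Remaining nodes are added as chains branching
    off existing taxa and always terminating at species depth, so with
    ``rank_missing_prob == 0`` every leaf has a complete six-rank ancestor
    chain.  With probability ``rank_missing_prob`` each added node's rank is
    replaced by ``"no rank"``, exercising the lineage fallback.

    Requires ``n_nodes >= 7`` (root plus one full chain).
    """
    if n_nodes < 7:
        raise ValueError(f"n_nodes must be >= 7, got {n_nodes}")
    rng = random.Random(seed)
    nodes: dict[int, TaxonNode] = {1: TaxonNode(1, 1, "no rank", "root")}
    depth_idx: dict[int, int] = {1: -1}  # structural main-rank index, root = -1
    next_txid = 2
    parent = 1
    for idx, rank in enumerate(MAIN_RANKS):
        nodes[next_txid] = TaxonNode(next_txid, parent, rank,
                                     f"Taxon{next_txid:05d}")
        depth_idx[next_txid] = idx
        parent = next_txid
        next_txid += 1

    fixture = TaxonomyFixture(seed=seed, nodes=nodes)
    budget = n_nodes - len(nodes)
    while budget > 0:
        candidates = [t for t, d in depth_idx.items()
                      if d < 5 and (5 - d) <= budget]
        if not candidates:
            break
        branch = rng.choice(sorted(candidates))
        parent = branch
        for idx in range(depth_idx[branch] + 1, 6):
            rank = MAIN_RANKS[idx]
            if rng.random() < rank_missing_prob:
                rank = "no rank"
            nodes[next_txid] = TaxonNode(next_txid, parent, rank,
                                         f"Taxon{next_txid:05d}")
            depth_idx[next_txid] = idx
            fixture.flippable.append(next_txid)
            parent = next_txid
            next_txid += 1
            budget -= 1
    if out_dir is not None:
        fixture.write(out_dir)
    return fixture


@dataclass(frozen=True)
class RecordSpec:
    """Ground truth for one generated record."""

    accession: str
    txid: int
    organism: str
    gene_names: tuple[str, ...]
    country_raw: str | None
    lat_lon_raw: str | None
    lat: float | None
    lon: float | None
    sequence: str


@dataclass
class RecordsManifest:
    """Ground truth for a generated corpus, with precomputed marginals."""

    seed: int
    records: list[RecordSpec]
    gene_counts: dict[str, int]
    geo_totals: dict[str, int]
    family_counts: dict[str, int]

    def to_json(self, out: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "gene_counts": self.gene_counts,
            "geo_totals": self.geo_totals,
            "family_counts": self.family_counts,
            "records": [
                {"accession": r.accession, "txid": r.txid,
                 "genes": list(r.gene_names), "country": r.country_raw,
                 "lat_lon": r.lat_lon_raw, "length": len(r.sequence)}
                for r in self.records
            ],
        }
        Path(out).write_text(json.dumps(payload, indent=1), encoding="utf-8")


_COUNTRY_POOL = (
    "Norway: Skagerrak", "Norway", "Iceland", "Canada: Nova Scotia",
    "Japan: Hokkaido", "Italy", "Brazil", "South Africa",
)


def _format_lat_lon(lat: float, lon: float) -> str:
    ns = "N" if lat >= 0 else "S"
    ew = "E" if lon >= 0 else "W"
    return f"{abs(lat):.4f} {ns} {abs(lon):.4f} {ew}"


def _random_geo(rng: random.Random) -> tuple[float, float]:
    lat = round(rng.uniform(0, 90), 4) * rng.choice((1, -1))
    lon = round(rng.uniform(0, 180), 4) * rng.choice((1, -1))
    return lat, lon


def make_records(seed: int, table: TaxonomyTable, n_records: int,
                 gene_pool: list[tuple[str, int]] | None = None,
                 geo_profile: tuple[float, float, float] = (0.3, 0.3, 0.4),
                 out: str | Path | None = None,
                 txids: list[int] | None = None,
                 duplicate_gene_prob: float = 0.15) -> RecordsManifest:
    """Generate a GenBank-dialect corpus referencing ``table`` txids.

    ``gene_pool`` lists (gene name, exact number of records tagged with it);
    each gene is assigned to a random subset of that size, so corpus-level
    per-gene record counts are exact by construction.  ``geo_profile`` gives
    the (coordinates, country, none) fractions of records carrying each kind
    of geography.  ``duplicate_gene_prob`` injects a second feature carrying
    an already-present gene qualifier, to exercise per-record dedup.
    """
    if abs(sum(geo_profile) - 1.0) > 1e-9:
        raise ValueError("geo_profile fractions must sum to 1")
    rng = random.Random(seed)
    gene_pool = list(gene_pool or ())
    for gene, count in gene_pool:
        if count > n_records:
            raise ValueError(f"gene {gene}: count {count} exceeds n_records")
    if txids is None:
        txids = sorted(table.nodes)
    record_txids = [rng.choice(txids) for _ in range(n_records)]

    genes_per_record: list[list[str]] = [[] for _ in range(n_records)]
    for gene, count in gene_pool:
        for i in sorted(rng.sample(range(n_records), count)):
            genes_per_record[i].append(gene)

    n_coord = round(geo_profile[0] * n_records)
    n_country = min(round(geo_profile[1] * n_records), n_records - n_coord)
    geo_kinds = (["coord"] * n_coord + ["country"] * n_country
                 + ["none"] * (n_records - n_coord - n_country))
    rng.shuffle(geo_kinds)

    specs: list[RecordSpec] = []
    seqrecords: list[SeqRecord] = []
    for i in range(n_records):
        txid = record_txids[i]
        organism = table.get(txid).scientific_name
        accession = f"FX{i + 1:06d}.1"
        seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(200, 1500)))
        country = lat_lon = None
        lat = lon = None
        if geo_kinds[i] == "coord":
            lat, lon = _random_geo(rng)
            lat_lon = _format_lat_lon(lat, lon)
        elif geo_kinds[i] == "country":
            country = rng.choice(_COUNTRY_POOL)
        genes = genes_per_record[i]
        specs.append(RecordSpec(accession, txid, organism, tuple(genes),
                                country, lat_lon, lat, lon, seq))

        source_quals: dict[str, list[str]] = {
            "organism": [organism],
            "db_xref": [f"taxon:{txid}"],
        }
        if country:
            source_quals["country"] = [country]
        if lat_lon:
            source_quals["lat_lon"] = [lat_lon]
        features = [SeqFeature(FeatureLocation(0, len(seq)), type="source",
                               qualifiers=source_quals)]
        gene_feats = list(genes)
        if genes and rng.random() < duplicate_gene_prob:
            gene_feats.append(genes[0])  # duplicate tag, must dedup on parse
        for j, gene in enumerate(gene_feats):
            start = min(j * 10, max(len(seq) - 20, 0))
            features.append(SeqFeature(FeatureLocation(start, min(start + 20, len(seq))),
                                       type="gene", qualifiers={"gene": [gene]}))
        rec = SeqRecord(
            Seq(seq),
            id=accession,
            name=accession.split(".")[0],
            description=f"{organism} synthetic fixture sequence",
            annotations={"molecule_type": "DNA", "organism": organism,
                         "source": organism, "date": "01-JAN-2021"},
            features=features,
        )
        seqrecords.append(rec)

    gene_counts: dict[str, int] = {}
    for spec in specs:
        for g in {g.lower() for g in spec.gene_names}:
            gene_counts[g] = gene_counts.get(g, 0) + 1
    display = {g.lower(): g for g, _ in reversed(gene_pool)}
    gene_counts = {display.get(k, k): v for k, v in gene_counts.items()}

    family_counts: dict[str, int] = {}
    for spec in specs:
        family = resolve_lineage(table, spec.txid).family
        family_counts[family] = family_counts.get(family, 0) + 1

    manifest = RecordsManifest(
        seed=seed,
        records=specs,
        gene_counts=gene_counts,
        geo_totals={"coordinates": n_coord, "country": n_country,
                    "none": n_records - n_coord - n_country},
        family_counts=family_counts,
    )
    if out is not None:
        out = Path(out)
        out.parent.mkdir(parents=True, exist_ok=True)
        with open(out, "w", encoding="utf-8") as fh:
            SeqIO.write(seqrecords, fh, "genbank")
    return manifest


# --- curated demo fixture -------------------------------------------------
#
# Encodes public-knowledge NCBI placements: the Atlantic cod lineage
# (txid 8049, Gadus morhua: phylum Chordata; class Actinopterygii; order
# Gadiformes; family Gadidae), the Vertebrata clade txid 7742, and the
# SARS-CoV-2 species txid 2697049 under a sparsely ranked virus branch
# (which exercises the lineage fallback).  All other txids are synthetic.

#: Published per-marker record counts for the Gadus morhua gene survey.
COD_GENE_SURVEY = (("CYTB", 985), ("COI", 455), ("ND2", 311))

#: Published family-level record counts across the order Gadiformes.
GADIFORMES_FAMILY_COUNTS = (
    ("Gadidae", 381460), ("Merlucciidae", 3252), ("Macrouridae", 1673),
)


def demo_taxonomy() -> dict[int, TaxonNode]:
    """Node set of the curated demo tree (synthetic txids are >= 900000)."""
    nodes = [
        TaxonNode(1, 1, "no rank", "root"),
        TaxonNode(2759, 1, "superkingdom", "Eukaryota"),
        TaxonNode(7711, 2759, "phylum", "Chordata"),
        TaxonNode(7742, 7711, "clade", "Vertebrata"),
        TaxonNode(7898, 7742, "class", "Actinopterygii"),
        TaxonNode(8043, 7898, "order", "Gadiformes"),
        TaxonNode(8045, 8043, "family", "Gadidae"),
        TaxonNode(8048, 8045, "genus", "Gadus"),
        TaxonNode(8049, 8048, "species", "Gadus morhua"),
        # sister families within Gadiformes (synthetic txids)
        TaxonNode(900001, 8043, "family", "Merlucciidae"),
        TaxonNode(900002, 900001, "genus", "Merluccius"),
        TaxonNode(900003, 900002, "species", "Merluccius merluccius"),
        TaxonNode(900004, 8043, "family", "Macrouridae"),
        TaxonNode(900005, 900004, "genus", "Coryphaenoides"),
        TaxonNode(900006, 900005, "species", "Coryphaenoides rupestris"),
        # sparsely ranked virus branch; species under "no rank" ancestors
        TaxonNode(10239, 1, "superkingdom", "Viruses"),
        TaxonNode(900100, 10239, "no rank", "Riboviria"),
        TaxonNode(900101, 900100, "family", "Coronaviridae"),
        TaxonNode(900102, 900101, "no rank", "Betacoronavirus"),
        TaxonNode(2697049, 900102, "species",
                  "Severe acute respiratory syndrome coronavirus 2"),
    ]
    return {n.txid: n for n in nodes}


def demo_table() -> TaxonomyTable:
    return TaxonomyTable(demo_taxonomy())


def cod_survey_corpus(seed: int = 0, n_records: int = 2000,
                      out: str | Path | None = None) -> RecordsManifest:
    """Gene-survey demo corpus: Gadus morhua records whose per-marker tag
    counts equal the published survey (CYTB 985, COI 455, ND2 311)."""
    return make_records(
        seed=seed,
        table=demo_table(),
        n_records=n_records,
        gene_pool=list(COD_GENE_SURVEY),
        geo_profile=(0.3, 0.3, 0.4),
        txids=[8049],
        out=out,
    )


def gadiformes_scatter_paths() -> list[tuple[str, ...]]:
    """Six-rank paths reproducing the published family-level counts across
    Gadiformes (one path per record)."""
    table = demo_table()
    species_for_family = {"Gadidae": 8049, "Merlucciidae": 900003,
                          "Macrouridae": 900006}
    paths: list[tuple[str, ...]] = []
    for family, count in GADIFORMES_FAMILY_COUNTS:
        ranks = resolve_lineage(table, species_for_family[family]).ranks()
        paths.extend([ranks] * count)
    return paths
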