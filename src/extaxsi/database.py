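"""Database deliverables: multi-FASTA, taxonomy TSV, and gene-frequency tables.

The taxonomy TSV is the two-column accession -> six-rank-path mapping that
downstream taxonomy-assignment platforms (QIIME2-style) accept as a
reference-taxonomy file.  The gene survey counts, for every gene tag, the
number of records carrying it: a record tagged with the same gene twice
still counts once (the survey reports accessions per gene), and spellings
differing only in case are merged with the first-seen spelling reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .records import SeqRecordMeta  # noqa: E402
from .taxonomy import TaxonomyTable, name_to_txids, resolve_lineage  # noqa: E402

logger = logging.getLogger(__name__)

FASTA_WRAP = 70


def write_fasta(records: Sequence[SeqRecordMeta], out: str | Path) -> int:
    """Write records as multi-FASTA (">accession definition", 70-col wrap).

    Duplicate accessions are written once (first occurrence wins).  Returns
    the number of records written; empty input yields an empty file.
    """
    out = Path(out)
    seen: set[str] = set()
    count = 0
    with open(out, "w", encoding="utf-8") as fh:
        for rec in records:
            if rec.accession in seen:
                continue
            seen.add(rec.accession)
            header = f">{rec.accession} {rec.definition}".rstrip()
            fh.write(header + "\n")
            seq = rec.sequence
            for i in range(0, len(seq), FASTA_WRAP):
                fh.write(seq[i:i + FASTA_WRAP] + "\n")
            count += 1
    return count


@dataclass(frozen=True)
class TaxonomyWriteResult:
    """Outcome of a taxonomy-TSV write: resolved rows vs unresolved rows."""

    rows_written: int
    unresolved: int


UNRESOLVED_FLAG = "unresolved"


def write_taxonomy_tsv(records: Sequence[SeqRecordMeta], table: TaxonomyTable,
                       out: str | Path) -> TaxonomyWriteResult:
    """Write "accession<TAB>phylum;class;order;family;genus;species" rows.

    A record's lineage comes from its txid; records with a missing or
    unknown txid fall back to an organism-name lookup, and only if that is
    absent or ambiguous is the row flagged ``unresolved`` (the run never
    aborts).  ``rows_written + unresolved`` equals the input record count.
    """
    out = Path(out)
    resolved = 0
    unresolved = 0
    with open(out, "w", encoding="utf-8") as fh:
        for rec in records:
            txid = rec.txid if (rec.txid is not None and rec.txid in table) else None
            if txid is None and rec.organism:
                candidates = name_to_txids(table, rec.organism)
                if len(candidates) == 1:
                    txid = candidates[0]
            if txid is None:
                fh.write(f"{rec.accession}\t{UNRESOLVED_FLAG}\n")
                unresolved += 1
                continue
            path = resolve_lineage(table, txid)
            fh.write(f"{rec.accession}\t{path.serialize()}\n")
            resolved += 1
    if unresolved:
        logger.warning("%d of %d records had unresolvable taxonomy",
                       unresolved, len(records))
    return TaxonomyWriteResult(resolved, unresolved)


@dataclass(frozen=True)
class FrequencyTable:
    """Gene -> record-count survey, sorted by count desc then term asc."""

    entries: tuple[tuple[str, int], ...]
    total_records: int
    tagged_records: int

    def top(self, n: int) -> tuple[tuple[str, int], ...]:
        return self.entries[:n]


def gene_frequency(records: Iterable[SeqRecordMeta]) -> FrequencyTable:
    """Survey gene tags across records.

    Counting is per record and case-insensitive: each record contributes at
    most one count per distinct gene, and ``COI``/``coi`` merge into one
    entry reported under the first-seen spelling.  Ties in the ranking are
    broken lexicographically, giving a total, reproducible order.
    """
    counts: dict[str, int] = {}
    spelling: dict[str, str] = {}
    total = 0
    tagged = 0
    for rec in records:
        total += 1
        distinct = {g.lower(): g for g in reversed(rec.gene_names)}
        if distinct:
            tagged += 1
        for key, first_spelling in distinct.items():
            spelling.setdefault(key, first_spelling)
            counts[key] = counts.get(key, 0) + 1
    entries = sorted(
        ((spelling[k], c) for k, c in counts.items()),
        key=lambda e: (-e[1], e[0].lower(), e[0]),
    )
    return FrequencyTable(tuple(entries), total, tagged)


def write_gene_table(table: FrequencyTable, out: str | Path) -> int:
    """Write the survey as a two-column TSV (gene, frequency)."""
    out = Path(out)
    with open(out, "w", encoding="utf-8") as fh:
        fh.write("gene\tfrequency\n")
        for term, count in table.entries:
            fh.write(f"{term}\t{count}\n")
    return len(table.entries)


def export_top_genes(table: FrequencyTable, out: str | Path,
                     n: int = 10) -> list[tuple[str, int]] | None:
    """Render a bar plot of the top-``n`` genes to a PNG file.

    Bar order equals table order (count desc, ties lexicographic), so the
    rank-10/11 cutoff is deterministic.  An empty table writes no file and
    returns None with a warning.  Returns the (gene, count) pairs plotted.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not table.entries:
        logger.warning("gene table is empty; no plot written")
        return None
    top = list(table.top(n))
    labels = [t for t, _ in top]
    values = [c for _, c in top]
    fig, ax = plt.subplots(figsize=(max(6, 0.7 * len(top)), 4))
    ax.bar(range(len(top)), values, color="#2a6f97")
    ax.set_xticks(range(len(top)))
    ax.set_xticklabels(labels, rotation=45, ha="right")
    ax.set_ylabel("records")
    ax.set_title(f"Top {len(top)} genes by record count")
    fig.tight_layout()
    fig.savefig(out, format="png", dpi=100)
    plt.close(fig)
    return top
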