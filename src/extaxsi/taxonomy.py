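"""Local taxonomy store: taxdump loading and six-rank lineage standardization.

The store mirrors the NCBI taxonomy distribution dialect (``nodes.dmp`` /
``names.dmp``: fields separated by ``"\\t|\\t"``, records terminated by
``"\\t|"``).  Every txid or scientific name can be resolved to a standardized
six-rank lineage — phylum, class, order, family, genus, species — the depth
used by downstream metabarcoding reference databases.  Taxa that lack one of
the six ranks in their ancestor chain are fallback-filled with the scientific
name of the nearest named ancestor-or-self, so serialized paths never contain
empty fields (QIIME2-style taxonomy mappings reject blanks).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import TaxdumpParseError, TaxonomyIntegrityError, UnknownTxidError

logger = logging.getLogger(__name__)

#: The six main ranks, shallow to deep.  Matching against taxdump rank labels
#: is case-insensitive.
MAIN_RANKS = ("phylum", "class", "order", "family", "genus", "species")

_FIELD_SEP = "\t|\t"
_RECORD_TERM = "\t|"


@dataclass(frozen=True)
class TaxonNode:
    """One node of the taxonomy tree.

    The root is the unique node whose ``parent_txid`` equals its own txid.
    """

    txid: int
    parent_txid: int
    rank: str
    scientific_name: str


@dataclass(frozen=True)
class LineagePath:
    """Standardized six-rank lineage for one taxon.

    ``source_rank`` is the rank label of the queried node itself; the six
    rank fields are never empty (fallback-filled, see module docstring).
    """

    txid: int
    phylum: str
    class_: str
    order: str
    family: str
    genus: str
    species: str
    source_rank: str

    def ranks(self) -> tuple[str, ...]:
        return (self.phylum, self.class_, self.order, self.family,
                self.genus, self.species)

    def serialize(self) -> str:
        """Semicolon-joined six-field path, no surrounding whitespace."""
        return ";".join(self.ranks())


class TaxonomyTable:
    """In-memory taxonomy tree with a case-insensitive name index."""

    def __init__(self, nodes: dict[int, TaxonNode]):
        self.nodes = nodes
        self.name_index: dict[str, set[int]] = {}
        for node in nodes.values():
            self.name_index.setdefault(node.scientific_name.lower(), set()).add(node.txid)
        roots = [n.txid for n in nodes.values() if n.parent_txid == n.txid]
        if len(roots) != 1:
            raise TaxonomyIntegrityError(
                f"expected exactly one root node, found {len(roots)}", roots)
        self.root_txid: int = roots[0]
        orphans = [n.txid for n in nodes.values() if n.parent_txid not in nodes]
        if orphans:
            raise TaxonomyIntegrityError("parent txid missing from table", orphans)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        seen_ok: set[int] = {self.root_txid}
        for txid in self.nodes:
            trail = []
            cur = txid
            while cur not in seen_ok:
                trail.append(cur)
                cur = self.nodes[cur].parent_txid
                if cur in trail:
                    raise TaxonomyIntegrityError("cycle in parent links", trail)
            seen_ok.update(trail)

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, txid: int) -> bool:
        return txid in self.nodes

    def get(self, txid: int) -> TaxonNode:
        try:
            return self.nodes[txid]
        except KeyError:
            raise UnknownTxidError(txid) from None

    def ancestors(self, txid: int) -> Iterable[TaxonNode]:
        """Yield the node itself, then each ancestor up to and incl. the root."""
        node = self.get(txid)
        while True:
            yield node
            if node.parent_txid == node.txid:
                return
            node = self.nodes[node.parent_txid]


def _parse_taxdump_lines(path: Path, min_fields: int):
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.endswith(_RECORD_TERM):
                line = line[: -len(_RECORD_TERM)]
            fields = line.split(_FIELD_SEP)
            if len(fields) < min_fields:
                raise TaxdumpParseError(
                    path, lineno,
                    f"expected at least {min_fields} fields, got {len(fields)}")
            yield lineno, fields


def load_taxdump(nodes_file: str | Path, names_file: str | Path) -> TaxonomyTable:
    """Load a taxonomy table from taxdump-dialect nodes and names files.

    Only names of class ``"scientific name"`` populate ``scientific_name``
    and the name index; synonyms and common names are ignored.

    Raises
    ------
    TaxdumpParseError
        On a malformed line (file and line number reported).
    TaxonomyIntegrityError
        On orphan parent txids, missing root, cycles, or a node without a
        scientific name.
    """
    nodes_file, names_file = Path(nodes_file), Path(names_file)
    raw: dict[int, tuple[int, str]] = {}
    for lineno, fields in _parse_taxdump_lines(nodes_file, 3):
        try:
            txid = int(fields[0])
            parent = int(fields[1])
        except ValueError:
            raise TaxdumpParseError(nodes_file, lineno,
                                    "txid and parent txid must be integers") from None
        rank = fields[2].strip()
        if not rank:
            raise TaxdumpParseError(nodes_file, lineno, "empty rank field")
        raw[txid] = (parent, rank)

    names: dict[int, str] = {}
    for lineno, fields in _parse_taxdump_lines(names_file, 4):
        try:
            txid = int(fields[0])
        except ValueError:
            raise TaxdumpParseError(names_file, lineno, "txid must be an integer") from None
        if fields[3].strip().lower() == "scientific name":
            names[txid] = fields[1].strip()

    unnamed = [t for t in raw if t not in names or not names[t]]
    if unnamed:
        raise TaxonomyIntegrityError("nodes without a scientific name", unnamed)
    nodes = {
        txid: TaxonNode(txid, parent, rank, names[txid])
        for txid, (parent, rank) in raw.items()
    }
    return TaxonomyTable(nodes)


def resolve_lineage(table: TaxonomyTable, txid: int) -> LineagePath:
    """Resolve ``txid`` to its standardized six-rank lineage.

    For each main rank the value is the scientific name of the nearest
    ancestor-or-self carrying that rank label (case-insensitive match);
    ranks with no labelled ancestor are filled with the queried node's own
    scientific name — the nearest named ancestor-or-self — so no field is
    ever empty.

    Raises
    ------
    UnknownTxidError
        If ``txid`` is absent from the table.
    """
    node = table.get(txid)
    found: dict[str, str] = {}
    for anc in table.ancestors(txid):
        rank = anc.rank.lower()
        if rank in MAIN_RANKS and rank not in found:
            found[rank] = anc.scientific_name
    fallback = node.scientific_name
    values = [found.get(rank, fallback) for rank in MAIN_RANKS]
    return LineagePath(txid, *values, source_rank=node.rank)


def name_to_txids(table: TaxonomyTable, name: str) -> list[int]:
    """All txids whose scientific name matches ``name`` (case-insensitive).

    Returns an ascending list; empty when unmatched (never an error).
    Homonyms yield every candidate rather than a silent pick.
    """
    return sorted(table.name_index.get(name.strip().lower(), ()))


class ConvertDirection(str, Enum):
    TXID_TO_RANKS = "txid_to_ranks"
    NAME_TO_TXID = "name_to_txid"


#: Column layout of conversion output (also the TSV header).
CONVERT_COLUMNS = ("input_value", "txid", "rank", "lineage", "status")


def _convert_one(table: TaxonomyTable, value: str,
                 direction: ConvertDirection) -> list[dict]:
    value = value.strip()
    if direction is ConvertDirection.TXID_TO_RANKS:
        try:
            txid = int(value)
        except ValueError:
            return [dict(input_value=value, txid="", rank="", lineage="",
                         status="unresolved")]
        if txid not in table:
            return [dict(input_value=value, txid="", rank="", lineage="",
                         status="unresolved")]
        path = resolve_lineage(table, txid)
        return [dict(input_value=value, txid=txid, rank=path.source_rank,
                     lineage=path.serialize(), status="ok")]
    txids = name_to_txids(table, value)
    if not txids:
        return [dict(input_value=value, txid="", rank="", lineage="",
                     status="unresolved")]
    status = "ok" if len(txids) == 1 else "ambiguous"
    rows = []
    for txid in txids:
        path = resolve_lineage(table, txid)
        rows.append(dict(input_value=value, txid=txid, rank=path.source_rank,
                         lineage=path.serialize(), status=status))
    return rows


def convert_values(table: TaxonomyTable, values: Iterable[str],
                   direction: ConvertDirection | str) -> pd.DataFrame:
    """Convert an in-memory sequence of identifiers; one or more rows each.

    Unresolvable inputs produce a row with ``status == "unresolved"`` instead
    of aborting; ambiguous names (homonyms) produce one row per candidate
    txid flagged ``"ambiguous"``.
    """
    direction = ConvertDirection(direction)
    rows: list[dict] = []
    for value in values:
        rows.extend(_convert_one(table, str(value), direction))
    return pd.DataFrame(rows, columns=CONVERT_COLUMNS)


def convert_batch(table: TaxonomyTable, input_file: str | Path,
                  direction: ConvertDirection | str) -> pd.DataFrame:
    """Convert the first column of a TSV/CSV file, preserving input order.

    The delimiter is sniffed from the extension (``.csv`` comma, anything
    else tab).  An empty file yields an empty frame with a warning log.
    """
    input_file = Path(input_file)
    delim = "," if input_file.suffix.lower() == ".csv" else "\t"
    values: list[str] = []
    with open(input_file, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter=delim):
            if row and row[0].strip():
                values.append(row[0])
    if not values:
        logger.warning("conversion input %s is empty", input_file)
    return convert_values(table, values, direction)


def write_conversion(frame: pd.DataFrame, out: str | Path) -> None:
    """Write conversion rows as TSV with the standard column header."""
    frame.to_csv(out, sep="\t", index=False)
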