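"""Parse GenBank-dialect nucleotide records into structured metadata.

Parsing proper is delegated to Biopython's flat-file reader; this module
extracts the fields the rest of the tool consumes: versioned accession,
organism and txid (from the source feature's ``db_xref="taxon:N"``), the
sequence, ``gene`` qualifiers from every feature, and the raw geographic
qualifiers (``country``, ``lat_lon``).  Geographic references are split the
way the world-map plot needs them: records carrying parseable coordinates
go to a coordinate array, records with only a country string to a country
array, everything else to neither.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO

from .errors import RecordParseError

logger = logging.getLogger(__name__)


@dataclass
class SeqRecordMeta:
    """One parsed nucleotide record (sequence + the metadata we survey)."""

    accession: str
    organism: str
    txid: int | None
    sequence: str
    definition: str
    gene_names: list[str] = field(default_factory=list)
    country_raw: str | None = None
    lat_lon_raw: str | None = None


class GeoKind(str, Enum):
    COORDINATES = "coordinates"
    COUNTRY = "country"
    NONE = "none"


@dataclass(frozen=True)
class GeoRef:
    """A record's geographic reference: coordinates, bare country, or none."""

    kind: GeoKind
    lat: float | None = None
    lon: float | None = None
    country_name: str | None = None


_TAXON_XREF = re.compile(r"^taxon:(\d+)$")

#: INSDC lat_lon dialect: "<deg> N|S <deg> E|W", optional decimals.
_LAT_LON = re.compile(
    r"^\s*(\d+(?:\.\d+)?)\s*([NS])[,\s]+(\d+(?:\.\d+)?)\s*([EW])\s*$",
    re.IGNORECASE,
)


def _dedup_keep_order(items: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for item in items:
        if item not in seen:
            seen.add(item)
            out.append(item)
    return out


def _meta_from_seqrecord(rec) -> SeqRecordMeta:
    txid: int | None = None
    country = None
    lat_lon = None
    organism = rec.annotations.get("organism", "")
    genes: list[str] = []
    for feat in rec.features:
        genes.extend(feat.qualifiers.get("gene", ()))
        if feat.type == "source":
            for xref in feat.qualifiers.get("db_xref", ()):
                m = _TAXON_XREF.match(xref)
                if m:
                    txid = int(m.group(1))
            if not organism:
                org_vals = feat.qualifiers.get("organism")
                if org_vals:
                    organism = org_vals[0]
            vals = feat.qualifiers.get("country") or feat.qualifiers.get("geo_loc_name")
            if vals:
                country = vals[0]
            vals = feat.qualifiers.get("lat_lon")
            if vals:
                lat_lon = vals[0]
    return SeqRecordMeta(
        accession=rec.id,
        organism=organism,
        txid=txid,
        sequence=str(rec.seq),
        definition=rec.description,
        gene_names=_dedup_keep_order(genes),
        country_raw=country,
        lat_lon_raw=lat_lon,
    )


def parse_records(source: str | Path | TextIO) -> list[SeqRecordMeta]:
    """Parse zero or more GenBank-dialect records from a path, text or handle.

    Gene names are collected from the ``gene`` qualifier of *every* feature
    (gene, CDS, rRNA, ...), deduplicated in order of first appearance.
    Records lacking source qualifiers leave the optional fields unset.

    Raises
    ------
    RecordParseError
        On a truncated record (missing ``//`` terminator); the last
        completely parsed accession is reported for context.
    """
    if isinstance(source, Path) or (isinstance(source, str) and source
                                    and "\n" not in source):
        handle: TextIO = open(source, encoding="utf-8")
        close = True
    elif isinstance(source, str):
        handle = io.StringIO(source)
        close = False
    else:
        handle = source
        close = False

    metas: list[SeqRecordMeta] = []
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()
    stripped = text.strip()
    if not stripped:
        return metas
    if not stripped.endswith("//"):
        last = metas[-1].accession if metas else None
        raise RecordParseError("truncated record: missing '//' terminator",
                               accession=_last_complete_accession(text))
    try:
        for rec in SeqIO.parse(io.StringIO(text), "genbank"):
            metas.append(_meta_from_seqrecord(rec))
    except ValueError as err:
        last = metas[-1].accession if metas else None
        raise RecordParseError(str(err), accession=last) from err

    dupes = len(metas) - len({m.accession for m in metas})
    if dupes:
        logger.warning("%d duplicate accessions in parsed corpus", dupes)
    return metas


def _last_complete_accession(text: str) -> str | None:
    acc = None
    for chunk in text.split("//\n")[:-1]:
        for line in chunk.splitlines():
            if line.startswith("VERSION"):
                parts = line.split()
                if len(parts) > 1:
                    acc = parts[1]
    return acc


def parse_lat_lon(raw: str) -> tuple[float, float] | None:
    """Parse an INSDC lat_lon string into signed decimal degrees.

    N/E are positive, S/W negative.  Returns None (with a warning) for
    anything outside the accepted dialect or outside valid ranges.
    """
    m = _LAT_LON.match(raw)
    if not m:
        logger.warning("unparseable lat_lon string: %r", raw)
        return None
    lat = float(m.group(1)) * (1 if m.group(2).upper() == "N" else -1)
    lon = float(m.group(3)) * (1 if m.group(4).upper() == "E" else -1)
    if not (-90 <= lat <= 90 and -180 <= lon <= 180):
        logger.warning("lat_lon out of range: %r", raw)
        return None
    return lat, lon


def extract_geo(record: SeqRecordMeta) -> GeoRef:
    """Classify a record's geography; never raises.

    A parseable ``lat_lon`` wins; otherwise the country string (text before
    the first ``:``, region detail stripped); otherwise kind ``none``.
    """
    if record.lat_lon_raw:
        parsed = parse_lat_lon(record.lat_lon_raw)
        if parsed:
            return GeoRef(GeoKind.COORDINATES, lat=parsed[0], lon=parsed[1])
    if record.country_raw:
        name = record.country_raw.split(":", 1)[0].strip()
        if name:
            return GeoRef(GeoKind.COUNTRY, country_name=name)
    return GeoRef(GeoKind.NONE)
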