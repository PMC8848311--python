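"""Batched search/fetch against an e-utilities-style nucleotide endpoint.

Query strings follow the Entrez term dialect (``txid8049[ORGN]``,
``COI[gene]``).  Retrieval is windowed: requests below the batch size
(default 2,500 records) are served by a single query, larger ones are split
into contiguous windows whose per-window temporary files are merged — in
window order — into one output file at the end of the run.  All network
interaction goes through the :class:`Transport` contract so a fixture
transport makes every operation testable offline; the live transport is a
thin urllib client with a token-bucket rate limiter and bounded-backoff
retries.
"""

from __future__ import annotations

import logging
import time
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol, Sequence

from .errors import DownloadError, QueryValidationError

logger = logging.getLogger(__name__)

DEFAULT_BATCH_SIZE = 2500

MERGED_FILENAME = "records.gb"
_TMP_PATTERN = "window_{index:05d}.tmp"


@dataclass(frozen=True)
class QuerySpec:
    """What to search for: an organism (name or txid), genes, raw extras."""

    organism_term: str | None = None
    gene_terms: tuple[str, ...] = ()
    extra_terms: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "gene_terms", tuple(self.gene_terms))
        if not (self.organism_term or self.gene_terms or self.extra_terms):
            raise QueryValidationError(
                "query needs at least an organism, a gene term, or extra terms")


def build_query(spec: QuerySpec) -> str:
    """Render a QuerySpec as an Entrez-dialect term string.

    A numeric organism term N renders as ``txidN[ORGN]``, a name as
    ``name[ORGN]``; each gene as ``gene[gene]``; all joined by ``" AND "``
    with any extra terms appended verbatim.
    """
    parts: list[str] = []
    if spec.organism_term:
        org = spec.organism_term.strip()
        if org.isdigit():
            parts.append(f"txid{org}[ORGN]")
        else:
            parts.append(f"{org}[ORGN]")
    parts.extend(f"{gene.strip()}[gene]" for gene in spec.gene_terms)
    if spec.extra_terms:
        parts.append(spec.extra_terms.strip())
    return " AND ".join(parts)


@dataclass(frozen=True)
class BatchPlan:
    """Contiguous retrieval windows covering ``[0, total_count)``."""

    total_count: int
    batch_size: int
    windows: tuple[tuple[int, int], ...]


def plan_batches(total_count: int, batch_size: int = DEFAULT_BATCH_SIZE) -> BatchPlan:
    """Split ``total_count`` records into contiguous (offset, size) windows.

    A count below ``batch_size`` yields a single window; zero yields none.
    """
    if total_count < 0:
        raise QueryValidationError(f"total_count must be >= 0, got {total_count}")
    if batch_size < 1:
        raise QueryValidationError(f"batch_size must be >= 1, got {batch_size}")
    windows = []
    offset = 0
    while offset < total_count:
        size = min(batch_size, total_count - offset)
        windows.append((offset, size))
        offset += size
    return BatchPlan(total_count, batch_size, tuple(windows))


class Transport(Protocol):
    """Contract every record source implements (live endpoint or fixture)."""

    def search(self, query: str, offset: int, limit: int) -> tuple[int, list[str]]:
        """Return (total hit count, page of record ids at offset)."""
        ...

    def fetch(self, ids: Sequence[str]) -> str:
        """Return raw flat-file text for the given ids, in the given order."""
        ...


class FixtureTransport:
    """Replays a canned corpus deterministically; no network.

    ``corpus`` maps record id (accession) -> raw flat-file record text.
    ``query_index`` optionally maps a query string to the matching id list;
    unmapped queries match the whole corpus in insertion order.
    ``fail_windows`` makes fetches whose offset falls in the set raise, to
    exercise the failure/resume contract.
    """

    def __init__(self, corpus: dict[str, str],
                 query_index: dict[str, list[str]] | None = None,
                 fail_offsets: frozenset[int] | set[int] = frozenset()):
        self.corpus = dict(corpus)
        self.query_index = dict(query_index or {})
        self.fail_offsets = set(fail_offsets)
        self.search_calls = 0
        self.fetch_calls = 0

    def _ids_for(self, query: str) -> list[str]:
        return self.query_index.get(query, list(self.corpus))

    def search(self, query: str, offset: int, limit: int) -> tuple[int, list[str]]:
        self.search_calls += 1
        if limit > 0 and offset in self.fail_offsets:
            raise ConnectionError(f"injected failure at offset {offset}")
        ids = self._ids_for(query)
        return len(ids), ids[offset:offset + limit]

    def fetch(self, ids: Sequence[str]) -> str:
        self.fetch_calls += 1
        return "".join(self.corpus[i] for i in ids)


class RateLimiter:
    """Enforces a requests/second ceiling; clock injectable for testing."""

    def __init__(self, rate_per_sec: float,
                 now: Callable[[], float] = time.monotonic,
                 sleep: Callable[[float], None] = time.sleep):
        if rate_per_sec <= 0:
            raise ValueError("rate must be positive")
        self.min_interval = 1.0 / rate_per_sec
        self._now = now
        self._sleep = sleep
        self._last: float | None = None

    def wait(self) -> None:
        if self._last is not None:
            elapsed = self._now() - self._last
            if elapsed < self.min_interval:
                self._sleep(self.min_interval - elapsed)
        self._last = self._now()


@dataclass
class LiveTransport:
    """urllib-based e-utilities client with rate limiting and retries.

    NCBI etiquette: 3 requests/s without an API key, 10 with one.  Transient
    failures are retried up to ``max_attempts`` times with exponential
    backoff starting at ``backoff_base`` seconds.
    """

    email: str
    api_key: str | None = None
    endpoint_url: str = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"
    rate_limit: float | None = None
    max_attempts: int = 3
    backoff_base: float = 1.0
    _limiter: RateLimiter = field(init=False, repr=False)

    def __post_init__(self):
        rate = self.rate_limit or (10.0 if self.api_key else 3.0)
        self._limiter = RateLimiter(rate)

    def _request(self, path: str, params: dict) -> str:
        params = dict(params, email=self.email, db="nucleotide")
        if self.api_key:
            params["api_key"] = self.api_key
        url = f"{self.endpoint_url}/{path}?{urllib.parse.urlencode(params)}"
        last_err: Exception | None = None
        for attempt in range(self.max_attempts):
            self._limiter.wait()
            try:
                with urllib.request.urlopen(url, timeout=60) as resp:
                    return resp.read().decode("utf-8")
            except Exception as err:  # noqa: BLE001 - any transient failure retried
                last_err = err
                delay = self.backoff_base * 2 ** attempt
                logger.warning("request failed (attempt %d/%d): %s; retrying in %.1fs",
                               attempt + 1, self.max_attempts, err, delay)
                time.sleep(delay)
        raise ConnectionError(f"request failed after {self.max_attempts} attempts: {last_err}")

    def search(self, query: str, offset: int, limit: int) -> tuple[int, list[str]]:
        import xml.etree.ElementTree as ET
        text = self._request("esearch.fcgi",
                             {"term": query, "retstart": offset, "retmax": limit})
        root = ET.fromstring(text)
        total = int(root.findtext("Count", default="0"))
        ids = [el.text for el in root.iter("Id") if el.text]
        return total, ids

    def fetch(self, ids: Sequence[str]) -> str:
        return self._request("efetch.fcgi",
                             {"id": ",".join(ids), "rettype": "gb", "retmode": "text"})


def _window_ids(transport: Transport, query: str, offset: int, size: int,
                max_attempts: int, backoff_base: float) -> list[str]:
    last_err: Exception | None = None
    for attempt in range(max_attempts):
        try:
            _, ids = transport.search(query, offset, size)
            return ids
        except Exception as err:  # noqa: BLE001
            last_err = err
            logger.warning("window at offset %d failed (attempt %d/%d): %s",
                           offset, attempt + 1, max_attempts, err)
            if attempt + 1 < max_attempts and backoff_base > 0:
                time.sleep(backoff_base * 2 ** attempt)
    raise last_err  # type: ignore[misc]


def run_download(transport: Transport, spec: QuerySpec, workdir: str | Path,
                 batch_size: int = DEFAULT_BATCH_SIZE,
                 max_attempts: int = 3, backoff_base: float = 0.5) -> Path:
    """Search, fetch window by window, and merge into one raw-record file.

    One temporary file per window is written under ``workdir`` and merged in
    window order into ``records.gb``; temporaries are removed on success and
    retained on failure so a rerun skips completed windows (resume).  The
    merged content is independent of ``batch_size``.  Duplicate accessions
    within the id stream are kept once (first occurrence wins).

    Returns the merged file path.  Zero hits yield an empty merged file and
    a warning log.  A window that keeps failing raises :class:`DownloadError`
    naming the window.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    query = build_query(spec)
    total, _ = transport.search(query, 0, 0)
    plan = plan_batches(total, batch_size)
    merged_path = workdir / MERGED_FILENAME
    if not plan.windows:
        logger.warning("query %r matched zero records", query)
        merged_path.write_text("")
        return merged_path

    tmp_paths: list[Path] = []
    seen_ids: set[str] = set()
    for index, (offset, size) in enumerate(plan.windows):
        tmp = workdir / _TMP_PATTERN.format(index=index)
        tmp_paths.append(tmp)
        if tmp.exists():
            logger.info("window %d already downloaded, resuming past it", index)
            # ids in a completed temp still count as seen for dedup
            seen_ids.update(_accessions_in(tmp.read_text()))
            continue
        try:
            ids = _window_ids(transport, query, offset, size,
                              max_attempts, backoff_base)
            fresh = [i for i in ids if i not in seen_ids]
            seen_ids.update(fresh)
            text = transport.fetch(fresh) if fresh else ""
        except Exception as err:  # noqa: BLE001
            raise DownloadError(index, offset, size, err) from err
        tmp.write_text(text)

    with open(merged_path, "w", encoding="utf-8") as out:
        for tmp in tmp_paths:
            out.write(tmp.read_text())
    for tmp in tmp_paths:
        tmp.unlink()
    return merged_path


def _accessions_in(raw: str) -> list[str]:
    accs = []
    for line in raw.splitlines():
        if line.startswith("VERSION"):
            parts = line.split()
            if len(parts) > 1:
                accs.append(parts[1])
    return accs
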