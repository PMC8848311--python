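"""Exception hierarchy shared across the package."""


class ExTaxsiError(Exception):
    """Base class for all package-specific errors."""


class TaxdumpParseError(ExTaxsiError):
    """A taxdump-dialect file could not be parsed.

    Carries the offending file and 1-based line number.
    """

    def __init__(self, path, lineno, message):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{self.path}:{lineno}: {message}")


class TaxonomyIntegrityError(ExTaxsiError):
    """The loaded taxonomy violates tree invariants (orphans, missing root...)."""

    def __init__(self, message, txids=()):
        self.txids = sorted(txids)
        if self.txids:
            message = f"{message}: {self.txids}"
        super().__init__(message)


class UnknownTxidError(ExTaxsiError):
    """A txid was looked up that is not present in the taxonomy table."""

    def __init__(self, txid):
        self.txid = txid
        super().__init__(f"txid {txid} not present in the taxonomy table")


class QueryValidationError(ExTaxsiError):
    """A query specification is empty or otherwise unusable."""


class DownloadError(ExTaxsiError):
    """A batched download failed after retries.

    ``window_index`` identifies the failed retrieval window so a rerun can
    resume from retained temporaries.
    """

    def __init__(self, window_index, offset, size, cause):
        self.window_index = window_index
        self.offset = offset
        self.size = size
        super().__init__(
            f"download failed on window {window_index} "
            f"(offset={offset}, size={size}): {cause}"
        )


class RecordParseError(ExTaxsiError):
    """A flat-file nucleotide record could not be parsed (e.g. truncated)."""

    def __init__(self, message, accession=None):
        self.accession = accession
        if accession:
            message = f"{message} (last complete accession: {accession})"
        super().__init__(message)


class TaxonomyFileError(ExTaxsiError):
    """A taxonomy list file (TSV/CSV of lineage paths) is malformed."""

    def __init__(self, path, lineno, message):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{self.path}:{lineno}: {message}")
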