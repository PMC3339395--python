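"""Exception hierarchy for the boss package."""


class BossError(Exception):
    """Base class for all package errors."""


class InputError(BossError):
    """A required input file is missing or unreadable."""


class FormatError(BossError):
    """An input file exists but violates the expected record format."""


class EmptyQueryError(BossError):
    """The query contains no searchable terms after normalization."""


class ObjectNotFoundError(BossError):
    """The requested object id is not present in the index."""


class IndexVersionError(BossError):
    """A persisted index was written by an incompatible format version."""


class IndexCorruptionError(BossError):
    """A persisted index file is truncated or otherwise unparseable."""
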