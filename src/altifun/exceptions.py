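"""Exception hierarchy shared across the package.

All errors derive from :class:`AltifunError` so callers can catch the
package's failures with one clause; the subclasses distinguish malformed
files, inconsistent metadata, misuse of an API, and inputs that are
syntactically fine but mathematically degenerate (e.g. an all-zero sample).
"""


class AltifunError(Exception):
    """Base class for all altifun errors."""


class FormatError(AltifunError, ValueError):
    """A file violates its format contract (duplicate ids, bad values, parse failure)."""


class MetadataError(AltifunError, ValueError):
    """Sample/plot metadata is missing or inconsistent with the data tables."""


class UsageError(AltifunError, ValueError):
    """An operation was called with arguments outside its contract."""


class DegenerateInputError(AltifunError, ValueError):
    """Input is well-formed but the requested statistic is undefined on it."""
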