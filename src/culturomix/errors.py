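"""Exception hierarchy shared across the package.

Three error families map onto the three failure modes a pipeline user
meets: malformed input files, out-of-range values, and API misuse.
"""


class CulturomixError(Exception):
    """Base class for all package-specific errors."""


class TableFormatError(CulturomixError, ValueError):
    """A file could not be parsed into the expected structure
    (ragged rows, duplicate identifiers, unbalanced Newick, ...)."""


class DataValueError(CulturomixError, ValueError):
    """Parsed fine, but a value violates an invariant (negative
    abundance, non-integer counts, all-zero vector where forbidden)."""


class UsageError(CulturomixError, ValueError):
    """The caller asked for something the API cannot do with the given
    inputs (unknown rank, counts table where fractions are required,
    empty candidate pool, ...)."""
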