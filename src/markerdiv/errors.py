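"""Exception hierarchy for markerdiv.

``FormatError`` signals malformed input files (structural problems a user
must fix in the file); ``ValidationError`` signals well-formed data that
violates a domain invariant (e.g. an all-absent locus).  Both derive from
``MarkerdivError`` so callers can catch everything the package raises.
"""


class MarkerdivError(ValueError):
    """Base class for all markerdiv errors."""


class FormatError(MarkerdivError):
    """A file or record does not conform to the expected format."""


class ValidationError(MarkerdivError):
    """Data is structurally valid but violates a domain invariant."""


class LookupKeyError(MarkerdivError, KeyError):
    """A requested primer, system, genotype or trait is not present."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it plain
        return ValueError.__str__(self)
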