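"""Exception hierarchy shared across the package.

All errors derive from :class:`PathoraError` so callers (notably the CLI)
can catch one base class and exit nonzero with the message.
"""


class PathoraError(Exception):
    """Base class for all package errors."""


class ParseError(PathoraError):
    """Input bytes could not be parsed (malformed XML/RDF); names the line
    when the underlying parser reports one."""


class FormatError(PathoraError):
    """Input parsed but does not conform to the expected format
    (missing root element, no pathways, bad GMT line, schema mismatch)."""


class DomainError(PathoraError):
    """A numeric argument violates its mathematical precondition."""


class EmptyQueryError(PathoraError):
    """A query list is empty after filtering, or disjoint from the universe."""


class EmptyComparisonError(PathoraError):
    """A set-similarity index was requested on empty operand(s) (0/0)."""


class SpecError(PathoraError):
    """A synthetic-data specification is infeasible or inconsistent."""
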