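"""Exception hierarchy shared across the package.

All user-facing failures derive from :class:`NetVennError` so the CLI can
catch one type and print a single-line diagnostic.
"""


class NetVennError(Exception):
    """Base class for all netvenn errors."""


class GeneListParseError(NetVennError):
    """Malformed line in a two-column gene-list file."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class DirectionConflictError(NetVennError):
    """Same gene listed with both direction codes inside one file."""


class EmptyInputError(NetVennError):
    """A gene-list file yielded no records."""


class CollectionSizeError(NetVennError):
    """Fewer than 2 or more than 8 input lists."""


class NameCollisionError(NetVennError):
    """Two experiment lists share the same name."""


class AnnotationFormatError(NetVennError):
    """Malformed annotation file (bad category token, conflicting names)."""


class TermNotFoundError(NetVennError):
    """Requested term_id absent from the annotation table."""


class EnrichmentInputError(NetVennError):
    """Invalid selection/background for the over-representation test."""


class EmptySubsetError(NetVennError):
    """Gene subset does not intersect the graph."""


class LayoutError(NetVennError):
    """Invalid layout request or layout/model mismatch."""


class FixtureSpecError(NetVennError):
    """Infeasible synthetic-fixture specification."""
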