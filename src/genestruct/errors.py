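"""Exception hierarchy shared across the package."""


class GenestructError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(GenestructError):
    """A file does not conform to its declared format."""


class ModelError(GenestructError):
    """A gene model violates a structural invariant."""


class CoordinateRangeError(GenestructError, ValueError):
    """A queried coordinate is outside its valid range."""


class ResourceLookupError(GenestructError, KeyError):
    """A named resource (transcript, accession, contig) is unknown."""


class ParameterError(GenestructError, ValueError):
    """An invalid parameter was supplied to a generator or operation."""
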