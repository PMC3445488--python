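"""Exception hierarchy shared across the package."""


class CleaveSiteError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CleaveSiteError, ValueError):
    """Input violates a documented precondition or invariant."""


class AnnotationReferenceError(CleaveSiteError, KeyError):
    """An annotation row references an accession absent from the sequences."""


class FormatError(CleaveSiteError, ValueError):
    """A file does not conform to its declared dialect."""


class SchemaMismatchError(CleaveSiteError, ValueError):
    """Feature columns do not match the schema a model was trained on."""


class LeakageError(CleaveSiteError, ValueError):
    """Train and test sets share proteins."""


class GenerationError(CleaveSiteError, ValueError):
    """Synthetic-data parameters are infeasible."""
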