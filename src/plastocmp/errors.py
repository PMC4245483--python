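"""Exception hierarchy.

Every user-facing failure raises a subclass of :class:`PlastocmpError` so
pipeline callers can catch one type at the stage boundary.
"""


class PlastocmpError(Exception):
    """Base class for all plastocmp errors."""


class EmptySourceError(PlastocmpError):
    """A FASTA/GFF source contained no records."""


class DuplicateIdError(PlastocmpError):
    """Two records in one dataset share an id."""


class IllegalCharacterError(PlastocmpError):
    """A sequence contains symbols outside {A,C,G,T,N}."""


class StructureNotFoundError(PlastocmpError):
    """No inverted-repeat pair of the required length exists."""


class AmbiguousStructureError(PlastocmpError):
    """Two maximal repeat-pair candidates overlap; the quadripartite layout
    cannot be assigned uniquely."""


class AnnotationConflictError(PlastocmpError):
    """Overlapping features assign conflicting region types to a base."""


class AlignmentError(PlastocmpError):
    """Pairwise alignment or reference projection failed."""


class VariantError(PlastocmpError):
    """Variant calling / classification contract violation."""


class TreeError(PlastocmpError):
    """Phylogenetic operation received an invalid tree or matrix."""


class SimulationError(PlastocmpError):
    """Simulation parameters are infeasible."""


class ConfigError(PlastocmpError):
    """Pipeline configuration is invalid."""
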