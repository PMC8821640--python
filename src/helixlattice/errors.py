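"""Exception hierarchy for helixlattice.

All package-specific failures derive from :class:`HelixLatticeError` so callers
can catch one base class; argument-validation failures additionally derive from
:class:`ValueError` to behave like ordinary Python misuse errors.
"""


class HelixLatticeError(Exception):
    """Base class for all helixlattice errors."""


class InvalidArgumentError(HelixLatticeError, ValueError):
    """An argument violates a documented precondition."""


class NoPeriodError(HelixLatticeError):
    """No label period was found within the requested bound."""


class AmbiguousRegisterError(HelixLatticeError):
    """No strict majority offset exists, so 'out of register' is undefined."""


class InconsistentLabelingError(HelixLatticeError):
    """An observed label sequence is not generated by any register pattern.

    Carries the first index at which the reconstruction fails.
    """

    def __init__(self, message: str, index: int):
        super().__init__(message)
        self.index = index


class ConfigurationError(HelixLatticeError):
    """A model-building configuration is incomplete (e.g. missing monomer)."""


class ChainIdExhaustionError(HelixLatticeError):
    """More subunits than the output format has chain identifiers for."""


class StructureParseError(HelixLatticeError):
    """A structure file could not be parsed."""


class AnnotationError(HelixLatticeError):
    """A required atom/domain annotation is missing."""


class BoundaryError(HelixLatticeError):
    """A reference subunit is too close to a filament end for the request."""


class SelfIntersectionError(HelixLatticeError):
    """A bend specification would fold the filament through itself."""


class TopologyMismatchError(HelixLatticeError):
    """Two conformations do not share subunit/atom topology."""
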