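"""Exception hierarchy for the recruitment-quantification pipeline.

Every error raised on a per-cell basis during cohort processing
(:class:`NoCellError`, :class:`NoClusterError`, :class:`UndefinedRatioError`)
is caught by the cohort driver and turned into a logged exclusion; everything
else propagates.
"""


class OpticError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(OpticError, ValueError):
    """A parameter violates its domain (e.g. negative enrichment factor)."""


class InvalidGeometryError(OpticError, ValueError):
    """Simulated cluster and cell footprints are geometrically inconsistent."""


class NoCellError(OpticError):
    """No cell could be segmented from the protein-of-interest channel."""


class NoClusterError(OpticError):
    """No receptor cluster attached to the cell could be segmented.

    Cells without a detectable attachment site are excluded from analysis,
    mirroring scoring restricted to cells with receptor-bound particles.
    """


class UndefinedRatioError(OpticError):
    """The recruitment ratio is undefined (zero mean cell intensity)."""


class InsufficientDataError(OpticError, ValueError):
    """Too few observations for the requested summary or test."""


class SequenceParseError(OpticError, ValueError):
    """An amino-acid sequence contains characters outside the 20-letter code."""


class MutationMismatchError(OpticError, ValueError):
    """The reference residue of a point-mutation spec does not match the
    sequence at the stated position (guards against numbering-offset bugs)."""


class ConfigError(OpticError, ValueError):
    """A run configuration violates the schema; the message names the key."""
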