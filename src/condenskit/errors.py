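"""Exception hierarchy shared across the package.

Input/schema problems raise :class:`InputError` subclasses; failures of an
analysis step on valid input raise :class:`AnalysisError` subclasses.  The CLI
maps the two branches onto exit codes 1 and 2.
"""


class CondenskitError(Exception):
    """Base class for all package errors."""


class InputError(CondenskitError):
    """Invalid user input (parameters, files, schemas)."""


class ParameterError(InputError):
    """A simulation or analysis parameter is out of range or non-finite."""


class SchemaError(InputError):
    """A table or file violates its documented schema."""


class AnalysisError(CondenskitError):
    """An analysis step failed on structurally valid input."""


class NormalizationError(AnalysisError):
    """FRAP normalization impossible (e.g. non-positive corrected reference)."""


class FitError(AnalysisError):
    """A model fit did not converge from any start."""


class SegmentationError(AnalysisError):
    """Segmentation produced an empty or unusable mask."""


class GeometryError(AnalysisError):
    """Masks or geometry are mutually inconsistent (e.g. nucleus outside cell)."""
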