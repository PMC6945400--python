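"""Exception hierarchy for the dosage-DE pipeline.

Every error raised on purpose by the package derives from
:class:`DosageDEError`, so callers (and the CLI) can distinguish
pipeline-domain failures from programming errors.
"""


class DosageDEError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(DosageDEError, ValueError):
    """A user-supplied parameter is outside its legal range."""


class DesignError(DosageDEError, ValueError):
    """The experimental design does not satisfy a structural requirement
    (e.g. a pairwise comparison that is not 3-vs-3, overlapping groups)."""


class ValidationError(DosageDEError, ValueError):
    """Input data violate a stated invariant (negative counts, p outside
    [0, 1], study genes missing from the background, ...)."""


class InsufficientDataError(DosageDEError):
    """Too few usable observations for the requested fit."""


class DegenerateFitError(DosageDEError):
    """A regression cannot be fit because the predictor (or response)
    carries no variance."""


class OntologyError(DosageDEError):
    """The ontology graph is malformed (cycles, missing terms)."""


class PipelineError(DosageDEError):
    """A pipeline stage failed; the message names the stage."""
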