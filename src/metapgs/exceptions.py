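"""Exception hierarchy for metapgs."""


class MetaPGSError(Exception):
    """Base class for all package errors."""


class GRRParseError(MetaPGSError):
    """A gene-reaction-rule string could not be parsed."""


class ModelValidationError(MetaPGSError):
    """A metabolic network violates a structural invariant."""


class ModelFormatError(MetaPGSError):
    """A model file could not be read in the declared dialect."""


class ConfigError(MetaPGSError):
    """Invalid configuration parameters."""


class GeneLookupError(MetaPGSError, KeyError):
    """A rule references a gene missing from a dosage vector."""


class AlignmentError(MetaPGSError):
    """Gene sets of two objects cannot be aligned by id."""


class DegenerateFitError(MetaPGSError):
    """Regression target carries no variance."""


class FixtureIntegrityError(MetaPGSError):
    """Analytic and LP phenotypes of a toy scenario disagree."""


class EnsembleError(MetaPGSError):
    """Reference-bound ensemble produced no feasible solutions."""


class MediaGenerationError(MetaPGSError):
    """Random-media rejection sampling failed to reach the target acceptance."""
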