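"""Exception hierarchy shared across the pipeline stages."""


class ChimeraKitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ChimeraKitError, ValueError):
    """A file does not conform to its declared format (FASTA/GTF/TSV)."""


class ConfigError(ChimeraKitError, ValueError):
    """A simulation or pipeline configuration is invalid or infeasible."""


class PlantingError(ChimeraKitError, RuntimeError):
    """No eligible partner pair exists for a requested chimera class."""


class ClassificationError(ChimeraKitError, ValueError):
    """A candidate cannot be classified (e.g. breakpoint outside gene span)."""


class PatternError(ChimeraKitError, ValueError):
    """A junction search pattern cannot be built or is unusable."""


class ReferenceLookupError(ChimeraKitError, KeyError):
    """A gene or contig referenced by the data is absent from the reference."""


class AnalysisError(ChimeraKitError, RuntimeError):
    """A statistical analysis cannot proceed (e.g. no complete pairs)."""
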