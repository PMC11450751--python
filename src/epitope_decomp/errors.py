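"""Exception hierarchy shared across the pipeline stages."""


class EpitopeDecompError(Exception):
    """Base class for all package errors."""


class PDBParseError(EpitopeDecompError):
    """A coordinate file could not be parsed; the message names the offending line."""


class EmptyStructureError(EpitopeDecompError):
    """A structure or selection unexpectedly contains no atoms."""


class EmptySelectionError(EpitopeDecompError):
    """A residue selection matched nothing."""


class ResidueLookupError(EpitopeDecompError, KeyError):
    """A residue reference is absent from the structure."""


class ConfigError(EpitopeDecompError):
    """Invalid configuration (overlapping groups/regions, bad thresholds, ...)."""


class ModeError(EpitopeDecompError):
    """An operation mode is incompatible with the input (e.g. H-bond detection
    with hydrogens requested on a hydrogen-free structure)."""


class MissingEnergyError(EpitopeDecompError, KeyError):
    """A table backend has no entry for a requested subsystem."""


class SequenceError(EpitopeDecompError):
    """A peptide sequence contains a non-standard letter or violates a contract."""


class MissingResidueError(EpitopeDecompError):
    """A region to extract has a gap in the parent chain."""


class GenerationError(EpitopeDecompError):
    """A synthetic-data spec is infeasible."""


class FeatureError(EpitopeDecompError):
    """Featurization failed (missing backbone atom); message names the residue."""
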