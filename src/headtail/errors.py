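"""Exception types shared across the pipeline."""


class HeadTailError(Exception):
    """Base class for all package-specific errors."""


class SmilesParseError(HeadTailError, ValueError):
    """A SMILES or reaction-SMILES string could not be parsed."""


class ConfigurationError(HeadTailError, ValueError):
    """A configuration file or CSV header did not match expectations."""


class UnsupportedSpeciesError(HeadTailError):
    """Species outside the closed-shell neutral domain of the RHF backend."""


class EmbeddingError(HeadTailError):
    """3D conformer embedding failed after retries."""


class SCFConvergenceError(HeadTailError):
    """The self-consistent field did not converge."""
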