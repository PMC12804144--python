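"""Exception hierarchy for epidyn."""


class EpidynError(Exception):
    """Base class for all epidyn errors."""


class PDBParseError(EpidynError):
    """Raised when PDB-format text cannot be parsed."""


class CongruenceError(EpidynError):
    """Raised when trajectory models disagree in atom count or order."""


class SelectionError(EpidynError):
    """Raised when an atom selection is empty or matches nothing."""


class LookupAtomError(EpidynError):
    """Raised when a referenced atom or residue does not exist."""


class ParameterError(EpidynError):
    """Raised for invalid numeric parameters."""


class InputError(EpidynError):
    """Raised for invalid input data (non-finite coords, bad grids, ...)."""


class FitError(EpidynError):
    """Raised when a fit is refused or degenerate."""


class GenerationError(EpidynError):
    """Raised when the synthetic generator cannot satisfy its target."""


class ConfigError(EpidynError):
    """Raised for invalid pipeline configurations."""
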