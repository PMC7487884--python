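"""Exception hierarchy shared across the package."""


class LineDtiError(Exception):
    """Base class for all package-specific errors."""


class ParseError(LineDtiError):
    """A text input (edge table, FASTA, fingerprint file) is malformed."""


class ConfigError(LineDtiError):
    """A configuration value violates its documented constraints."""


class TypeConflictError(LineDtiError):
    """A node name was assigned two different molecule types."""


class DegenerateNodeError(LineDtiError):
    """An operation needs a node with positive degree but got an isolated one."""


class DimensionError(LineDtiError):
    """Vector lengths do not match the operation's contract."""


class ModeError(LineDtiError):
    """A model state does not support the requested proximity order."""


class DegenerateSequenceError(LineDtiError):
    """A protein sequence has fewer than three usable residues."""


class StructureError(LineDtiError):
    """A drug structure (SMILES) could not be parsed."""


class AssemblyError(LineDtiError):
    """Feature vectors could not be joined (length or owner mismatch)."""


class CapacityError(LineDtiError):
    """Not enough non-interacting pairs to sample the requested negatives."""


class StratificationError(LineDtiError):
    """A class has too few members for the requested number of folds."""
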