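"""Exception hierarchy for molfuse.

Every error raised by the package derives from :class:`MolfuseError` so callers
can catch package failures with a single except clause.
"""


class MolfuseError(Exception):
    """Base class for all molfuse errors."""


class ParseError(MolfuseError):
    """SMILES string is syntactically malformed or chemically invalid."""


class EmptyMoleculeError(MolfuseError):
    """Molecule has zero heavy atoms after hydrogen removal."""


class SchemaError(MolfuseError):
    """Atom or bond category falls outside the feature schema's vocabulary."""


class TokenizeError(MolfuseError):
    """A span of the SMILES matched no token and no unknown token is configured."""


class LengthError(MolfuseError):
    """Token count exceeds the tokenizer's maximum context length."""


class AlignmentError(MolfuseError):
    """Token-derived heavy-atom count disagrees with the molecular graph."""


class ShapeError(MolfuseError):
    """Matrix dimensions incompatible with the requested layer computation."""


class ModeError(MolfuseError):
    """Batch preparation or ablation request inconsistent with the model mode."""


class FormatError(MolfuseError):
    """Input table is missing required columns or holds out-of-domain labels."""


class EmptyDatasetError(MolfuseError):
    """No usable records remain after dropping invalid rows."""


class SplitError(MolfuseError):
    """Dataset split produced an empty partition or infeasible fold count."""


class DomainError(MolfuseError):
    """Numeric argument outside its mathematical domain."""


class GenerationError(MolfuseError):
    """Synthetic generator exhausted its retry budget."""


class NonFiniteLossError(MolfuseError):
    """Training loss became NaN or infinite."""
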