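"""Vocabulary-driven SMILES tokenization and token classification.

Tokens follow the convention of chemical language models: a bracket atom such
as ``[C@@H]`` is a single token, two-letter halogens (``Cl``, ``Br``) are
single tokens, ring-closure indices (including ``%nn``) and structural symbols
are their own tokens. Segmentation is greedy longest-match against the
tokenizer vocabulary with a SMILES-aware regex fallback; unknown spans map to
the unknown token. Each token is classified by atomic content: HEAVY_ATOM
(contains ≥1 non-hydrogen element), HYDROGEN_ONLY, STRUCTURAL, or SPECIAL.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .exceptions import LengthError, TokenizeError

__all__ = ["TokenClass", "TokenizerSpec", "TokenSequence", "tokenize",
           "classify_token", "token_elements", "default_tokenizer_spec",
           "load_vocabulary"]


class TokenClass(str, Enum):
    HEAVY_ATOM = "HEAVY_ATOM"
    HYDROGEN_ONLY = "HYDROGEN_ONLY"
    STRUCTURAL = "STRUCTURAL"
    SPECIAL = "SPECIAL"


# SMILES-aware fallback segmentation: bracket atoms first, then two-letter
# organic-subset halogens, single atoms (aromatic lowercase included),
# %nn ring closures, digits, and structural symbols.
_SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|b|c|n|o|s|p|B|C|N|O|S|P|F|I"
    r"|%\d{2}|\d|\(|\)|\.|=|#|\$|:|/|\\|-|\+|@|~|\*)"
)

# Two-letter element symbols recognized inside bracket atoms (maximal munch).
_TWO_LETTER_ELEMENTS = {
    "He", "Li", "Be", "Ne", "Na", "Mg", "Al", "Si", "Cl", "Ar", "Ca", "Sc",
    "Ti", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "Ga", "Ge", "As", "Se",
    "Br", "Kr", "Rb", "Sr", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag",
    "Cd", "In", "Sn", "Sb", "Te", "Xe", "Cs", "Ba", "Pt", "Au", "Hg", "Tl",
    "Pb", "Bi", "se", "as", "te",
}
_ONE_LETTER_ELEMENTS = set("HBCNOSPFIK") | set("bcnosp")

_ELEMENT_RE = re.compile(
    "(" + "|".join(sorted(_TWO_LETTER_ELEMENTS, key=len, reverse=True))
    + "|[A-Z]|[a-z])")


@dataclass(frozen=True)
class TokenizerSpec:
    """Vocabulary and special-token configuration for the tokenizer."""

    vocabulary: tuple[str, ...]
    max_length: int = 512
    bos_token: str = "[CLS]"
    eos_token: str = "[SEP]"
    pad_token: str = "[PAD]"
    unk_token: str = "[UNK]"

    def __post_init__(self):
        if self.max_length < 2:
            raise ValueError("max_length must leave room for begin/end tokens")
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ValueError("vocabulary contains duplicate tokens")

    @property
    def token_to_id(self) -> dict[str, int]:
        return {tok: i for i, tok in enumerate(self.vocabulary)}

    @property
    def special_tokens(self) -> tuple[str, ...]:
        return (self.bos_token, self.eos_token, self.pad_token, self.unk_token)

    @property
    def pad_id(self) -> int:
        return self.token_to_id[self.pad_token]


@dataclass(frozen=True)
class TokenSequence:
    """Tokenized SMILES with per-token class labels.

    ``heavy_atom_multiplicity[i]`` counts the non-hydrogen element symbols in
    token i; it is ≥1 exactly when ``classes[i]`` is HEAVY_ATOM.
    """

    tokens: tuple[str, ...]
    ids: tuple[int, ...]
    classes: tuple[TokenClass, ...]
    heavy_atom_multiplicity: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def heavy_atom_count(self) -> int:
        return sum(self.heavy_atom_multiplicity)


def token_elements(token: str) -> list[tuple[str, bool]]:
    """Element symbols contained in a token, as (symbol, is_aromatic) pairs.

    Inside bracket atoms, chirality markers (@), charges, isotope digits and
    trailing H-counts are skipped; a lone H (as in ``[H]`` or ``[2H]``) is
    reported so callers can distinguish hydrogen-only tokens. Maximal munch:
    two-letter symbols are matched before one-letter ones.
    """
    body = token[1:-1] if token.startswith("[") and token.endswith("]") else token
    found: list[tuple[str, bool]] = []
    i = 0
    while i < len(body):
        ch = body[i]
        if not ch.isalpha():
            i += 1
            continue
        two = body[i:i + 2]
        if two in _TWO_LETTER_ELEMENTS:
            found.append((two[0].upper() + two[1:].lower() if two[0].islower()
                          else two, two[0].islower()))
            i += 2
            continue
        if ch in _ONE_LETTER_ELEMENTS:
            # inside a bracket, H following another element is a hydrogen count
            if ch == "H" and any(sym != "H" for sym, _ in found):
                i += 1
                continue
            found.append((ch.upper(), ch.islower()))
            i += 1
            continue
        i += 1
    return found


def classify_token(token: str,
                   spec: TokenizerSpec | None = None
                   ) -> tuple[TokenClass, int]:
    """Classify a token and count its heavy atoms.

    Returns (class, heavy-atom multiplicity). SPECIAL for begin/end/pad/unknown
    tokens of ``spec``; HEAVY_ATOM with multiplicity m when m ≥ 1 non-hydrogen
    element symbols occur in the token; HYDROGEN_ONLY when the only element is
    H; STRUCTURAL for bonds, ring indices, branches, dots and stereo markers.
    """
    if not token:
        raise TokenizeError("cannot classify an empty token")
    if spec is not None and token in spec.special_tokens:
        return TokenClass.SPECIAL, 0
    if token.startswith("[") and token.endswith("]") and len(token) <= 2:
        raise TokenizeError(f"malformed bracket token {token!r}")
    elements = token_elements(token)
    heavy = [sym for sym, _ in elements if sym != "H"]
    if heavy:
        return TokenClass.HEAVY_ATOM, len(heavy)
    if elements:
        return TokenClass.HYDROGEN_ONLY, 0
    if _SMILES_TOKEN_RE.fullmatch(token) or token in {"(", ")"}:
        return TokenClass.STRUCTURAL, 0
    raise TokenizeError(f"unrecognized token {token!r}")


def _segment(smiles: str, spec: TokenizerSpec) -> list[str]:
    """Greedy longest-match against the vocabulary with regex fallback."""
    vocab = set(spec.vocabulary) - set(spec.special_tokens)
    max_len = max((len(t) for t in vocab), default=1)
    out = []
    i = 0
    n = len(smiles)
    while i < n:
        match = None
        for length in range(min(max_len, n - i), 0, -1):
            cand = smiles[i:i + length]
            if cand in vocab:
                # never split a bracket atom: a vocabulary hit starting with
                # "[" must extend to the closing bracket
                if cand.startswith("[") and not cand.endswith("]"):
                    continue
                match = cand
                break
        if match is None:
            m = _SMILES_TOKEN_RE.match(smiles, i)
            if m:
                match = m.group(0)
            elif spec.unk_token:
                out.append(spec.unk_token)
                i += 1
                continue
            else:
                raise TokenizeError(
                    f"unmatchable span at position {i} of {smiles!r}")
        out.append(match)
        i += len(match)
    return out


def tokenize(smiles: str, spec: TokenizerSpec) -> TokenSequence:
    """Tokenize a SMILES string under ``spec``.

    The begin/end special tokens are appended; unknown spans map to the
    unknown token. Raises :class:`LengthError` when the result exceeds
    ``spec.max_length``.
    """
    if not smiles:
        raise TokenizeError("empty SMILES string")
    body = _segment(smiles, spec)
    tokens = [spec.bos_token] + body + [spec.eos_token]
    if len(tokens) > spec.max_length:
        raise LengthError(f"{len(tokens)} tokens exceed max_length "
                          f"{spec.max_length}")
    t2i = spec.token_to_id
    unk_id = t2i[spec.unk_token]
    ids, classes, mult = [], [], []
    for tok in tokens:
        # out-of-vocabulary tokens keep their literal string and true class
        # (so alignment still works) but carry the unknown id for the encoder
        ids.append(t2i.get(tok, unk_id))
        tok_cls, m = classify_token(tok, spec)
        classes.append(tok_cls)
        mult.append(m)
    return TokenSequence(tokens=tuple(tokens), ids=tuple(ids),
                         classes=tuple(classes),
                         heavy_atom_multiplicity=tuple(mult))


def _default_vocabulary() -> tuple[str, ...]:
    """Regex-derived default vocabulary covering common SMILES tokens."""
    atoms = ["B", "C", "N", "O", "S", "P", "F", "I", "Cl", "Br",
             "b", "c", "n", "o", "s", "p"]
    brackets = ["[C@H]", "[C@@H]", "[C@]", "[C@@]", "[CH]", "[CH2]",
                "[NH]", "[NH2]", "[NH+]", "[NH2+]", "[NH3+]", "[N+]", "[N-]",
                "[nH]", "[n+]", "[O-]", "[OH]", "[O+]", "[S-]", "[S+]",
                "[s+]", "[P+]", "[H]", "[2H]", "[3H]", "[Se]", "[Si]",
                "[B-]", "[C-]", "[CH-]", "[O]", "[N]"]
    structural = ["(", ")", ".", "=", "#", "$", ":", "/", "\\", "-", "+",
                  "@", "~", "*"] + [str(d) for d in range(10)] \
        + [f"%{d:02d}" for d in range(10, 30)]
    return tuple(["[PAD]", "[CLS]", "[SEP]", "[UNK]"] + atoms + brackets
                 + structural)


def default_tokenizer_spec(max_length: int = 512) -> TokenizerSpec:
    """The shipped regex-derived tokenizer specification."""
    return TokenizerSpec(vocabulary=_default_vocabulary(),
                         max_length=max_length)


def load_vocabulary(path: str | Path, max_length: int = 512) -> TokenizerSpec:
    """Load a user vocabulary file: one token per line, id = line number.

    The file must include the four special tokens [PAD], [CLS], [SEP], [UNK].
    """
    tokens = [line.rstrip("\n") for line in Path(path).read_text().splitlines()
              if line.strip()]
    spec = TokenizerSpec(vocabulary=tuple(tokens), max_length=max_length)
    for special in spec.special_tokens:
        if special not in tokens:
            raise TokenizeError(f"vocabulary file missing special token "
                                f"{special!r}")
    return spec
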