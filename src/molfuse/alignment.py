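"""Token-to-node alignment and the fine-tuning attention mask.

Heavy atoms appear in a SMILES string in the same order the parser discovers
them, so alignment is a single left-to-right walk: each heavy-atom token of
multiplicity m consumes the next m unassigned graph node indices. Tokens that
carry no heavy atom (bonds, ring indices, branches, hydrogens, specials)
receive no node and attention 0. The element symbol of every token is checked
(case-insensitively, so aromatic lowercase matches) against the element of the
node it maps to; any disagreement signals that tokenizer and parser drifted
apart and raises :class:`AlignmentError`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import AlignmentError
from .molgraph import Molecule
from .tokenization import TokenClass, TokenSequence, token_elements

__all__ = ["AlignmentMap", "align_tokens_to_nodes", "build_attention_mask"]


@dataclass(frozen=True)
class AlignmentMap:
    """Order-preserving map from token positions to graph node indices.

    ``pairs`` lists (token position, node index) with node indices exactly
    0..num_nodes-1 in increasing order; ``attention_mask[i]`` is 1 iff token
    position i appears in ``pairs``.
    """

    pairs: tuple[tuple[int, int], ...]
    attention_mask: tuple[int, ...]

    @property
    def num_nodes(self) -> int:
        return len(self.pairs)

    def token_for_node(self) -> dict[int, int]:
        """node index → token position."""
        return {node: tok for tok, node in self.pairs}


def align_tokens_to_nodes(seq: TokenSequence,
                          molecule: Molecule) -> AlignmentMap:
    """Assign heavy-atom tokens to heavy-atom graph nodes in order.

    ``seq`` and ``molecule`` must derive from the same SMILES text. A token of
    multiplicity m > 1 broadcasts to m consecutive nodes.
    """
    num_nodes = molecule.num_atoms
    token_heavy = seq.heavy_atom_count
    if token_heavy != num_nodes:
        raise AlignmentError(
            f"token-derived heavy-atom count {token_heavy} != graph node "
            f"count {num_nodes} for {molecule.smiles!r}")
    pairs: list[tuple[int, int]] = []
    next_node = 0
    for pos, (tok, cls, mult) in enumerate(
            zip(seq.tokens, seq.classes, seq.heavy_atom_multiplicity)):
        if cls is not TokenClass.HEAVY_ATOM:
            continue
        heavy_syms = [sym for sym, _ in token_elements(tok) if sym != "H"]
        for sym in heavy_syms[:mult]:
            node_sym = molecule.atoms[next_node].symbol
            if sym.upper() != node_sym.upper():
                raise AlignmentError(
                    f"element mismatch at token {pos} ({tok!r}): token says "
                    f"{sym}, node {next_node} is {node_sym} "
                    f"({molecule.smiles!r})")
            pairs.append((pos, next_node))
            next_node += 1
    if next_node != num_nodes:
        raise AlignmentError(
            f"consumed {next_node} of {num_nodes} nodes for "
            f"{molecule.smiles!r}")
    mask = [0] * len(seq)
    for pos, _ in pairs:
        mask[pos] = 1
    return AlignmentMap(pairs=tuple(pairs), attention_mask=tuple(mask))


def build_attention_mask(seq: TokenSequence, amap: AlignmentMap,
                         include_special: bool = False) -> tuple[int, ...]:
    """0/1 mask over the token sequence: 1 exactly on mapped heavy-atom tokens.

    With ``include_special`` the begin/end tokens also receive attention;
    padding always stays 0.
    """
    if len(amap.attention_mask) != len(seq):
        raise AlignmentError("alignment map does not match token sequence")
    mask = list(amap.attention_mask)
    if include_special:
        for pos, cls in enumerate(seq.classes):
            if cls is TokenClass.SPECIAL:
                mask[pos] = 1
    return tuple(mask)
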