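"""Heavy-atom molecular graphs from SMILES.

A molecule is parsed with RDKit into a :class:`Molecule` whose atom order is
the order of first appearance of each heavy atom in the SMILES text (RDKit
preserves input order; no canonicalization is applied — downstream token/node
alignment depends on this). Hydrogens, including explicit and isotopic ones,
are removed. :func:`featurize_graph` turns a :class:`Molecule` into a
:class:`MolGraph` with node features (atomic element, formal charge,
hybridization, chirality) and edge features (bond type, bond direction), each
undirected bond stored as two directed pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .exceptions import EmptyMoleculeError, ParseError, SchemaError

RDLogger.DisableLog("rdApp.*")  # RDKit parse warnings handled via exceptions

__all__ = ["AtomRecord", "BondRecord", "Molecule", "FeatureSchema", "MolGraph",
           "parse_smiles", "featurize_graph", "DEFAULT_SCHEMA"]


@dataclass(frozen=True)
class AtomRecord:
    symbol: str
    formal_charge: int
    hybridization: str
    chirality: str
    aromatic: bool


@dataclass(frozen=True)
class BondRecord:
    i: int
    j: int
    bond_type: str
    bond_dir: str


@dataclass(frozen=True)
class Molecule:
    """Heavy-atom view of a parsed SMILES, atom order = appearance order."""

    smiles: str
    atoms: tuple[AtomRecord, ...]
    bonds: tuple[BondRecord, ...]

    @property
    def num_atoms(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class FeatureSchema:
    """Category vocabularies for one-hot encodings.

    The elements list carries an implicit trailing "other" slot; hybridization,
    chirality, bond type and bond direction are strict (an unlisted category
    raises :class:`SchemaError`).
    """

    elements: tuple[str, ...] = ("C", "N", "O", "S", "F", "Cl", "Br", "I",
                                 "P", "B")
    hybridizations: tuple[str, ...] = ("S", "SP", "SP2", "SP3", "SP3D",
                                       "SP3D2", "UNSPECIFIED")
    chirality_tags: tuple[str, ...] = ("CHI_UNSPECIFIED", "CHI_TETRAHEDRAL_CW",
                                       "CHI_TETRAHEDRAL_CCW", "CHI_OTHER")
    bond_types: tuple[str, ...] = ("SINGLE", "DOUBLE", "TRIPLE", "AROMATIC")
    bond_dirs: tuple[str, ...] = ("NONE", "ENDUPRIGHT", "ENDDOWNRIGHT")

    @property
    def d_node(self) -> int:
        # elements one-hot (+other) + charge slot + hybridization + chirality
        return (len(self.elements) + 1) + 1 + len(self.hybridizations) \
            + len(self.chirality_tags)

    @property
    def d_edge(self) -> int:
        return len(self.bond_types) + len(self.bond_dirs)

    def to_dict(self) -> dict:
        return {k: list(v) for k, v in self.__dict__.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        return cls(**{k: tuple(v) for k, v in d.items()})


DEFAULT_SCHEMA = FeatureSchema()


@dataclass(frozen=True)
class MolGraph:
    """Featurized heavy-atom graph.

    ``edge_index`` has shape (2, E) with E = 2 × number of undirected bonds;
    directed pair (i→j) and its reverse carry identical ``edge_features`` rows.
    """

    node_features: np.ndarray
    edge_index: np.ndarray
    edge_features: np.ndarray

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def num_edges(self) -> int:
        return self.edge_index.shape[1]


def parse_smiles(smiles: str) -> Molecule:
    """Parse a SMILES string into a heavy-atom :class:`Molecule`.

    Atom order equals the order of first appearance in the SMILES text;
    explicit and isotopic hydrogens are stripped after sanitization and
    aromaticity perception.

    Raises
    ------
    ParseError
        For malformed or chemically invalid SMILES.
    EmptyMoleculeError
        If no heavy atom remains (e.g. ``"[H][H]"``).
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise ParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"invalid SMILES: {smiles!r}")
    mol = Chem.RemoveAllHs(mol, sanitize=False)
    if mol.GetNumAtoms() == 0:
        raise EmptyMoleculeError(f"no heavy atoms in {smiles!r}")
    atoms = tuple(
        AtomRecord(symbol=a.GetSymbol(),
                   formal_charge=a.GetFormalCharge(),
                   hybridization=str(a.GetHybridization()),
                   chirality=str(a.GetChiralTag()),
                   aromatic=a.GetIsAromatic())
        for a in mol.GetAtoms())
    bonds = tuple(
        BondRecord(i=b.GetBeginAtomIdx(), j=b.GetEndAtomIdx(),
                   bond_type=str(b.GetBondType()),
                   bond_dir=str(b.GetBondDir()))
        for b in mol.GetBonds())
    return Molecule(smiles=smiles, atoms=atoms, bonds=bonds)


def _one_hot(value: str, categories: tuple[str, ...], other_slot: bool,
             what: str) -> list[float]:
    vec = [0.0] * (len(categories) + (1 if other_slot else 0))
    if value in categories:
        vec[categories.index(value)] = 1.0
    elif other_slot:
        vec[-1] = 1.0
    else:
        raise SchemaError(f"{what} category {value!r} not in schema "
                          f"{categories}")
    return vec


def featurize_graph(molecule: Molecule,
                    schema: FeatureSchema = DEFAULT_SCHEMA,
                    dtype=np.float32) -> MolGraph:
    """Encode a :class:`Molecule` as a :class:`MolGraph` under ``schema``.

    Node feature rows concatenate element one-hot (with "other" slot), signed
    formal charge, hybridization one-hot and chirality one-hot. Edge feature
    rows concatenate bond-type and bond-direction one-hots; every undirected
    bond contributes the directed pairs (i→j) and (j→i).
    """
    if molecule.num_atoms < 1:
        raise EmptyMoleculeError("cannot featurize an empty molecule")
    rows = []
    for atom in molecule.atoms:
        row = _one_hot(atom.symbol, schema.elements, True, "element")
        row.append(float(atom.formal_charge))
        row += _one_hot(atom.hybridization, schema.hybridizations, False,
                        "hybridization")
        row += _one_hot(atom.chirality, schema.chirality_tags, False,
                        "chirality")
        rows.append(row)
    node_features = np.asarray(rows, dtype=dtype)

    src, dst, efeat = [], [], []
    for bond in molecule.bonds:
        feat = _one_hot(bond.bond_type, schema.bond_types, False, "bond type")
        feat += _one_hot(bond.bond_dir, schema.bond_dirs, False,
                         "bond direction")
        for a, b in ((bond.i, bond.j), (bond.j, bond.i)):
            src.append(a)
            dst.append(b)
            efeat.append(feat)
    edge_index = np.asarray([src, dst], dtype=np.int64).reshape(2, -1)
    edge_features = (np.asarray(efeat, dtype=dtype)
                     if efeat else np.zeros((0, schema.d_edge), dtype=dtype))
    return MolGraph(node_features=node_features, edge_index=edge_index,
                    edge_features=edge_features)
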