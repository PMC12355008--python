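"""SMILES featurization and pair-table I/O.

A molecule is represented as a heavy-atom topological graph: hydrogens are
implicit and surface only through the bonded-H atom feature.  The feature
layout is fixed and documented below so that feature vectors are reproducible
across runs and machines.

Atom features (22 columns)
    0-9    atomic species one-hot over ``C N O F P S Cl Br I other``
    10     number of bonds to heavy atoms (degree)
    11     number of bonded hydrogen atoms
    12     ring membership flag
    13     total valence
    14     aromaticity flag
    15-18  hybridization one-hot over ``SP SP2 SP3 other``
    19     hydrogen-bond donor flag (N/O bearing at least one H)
    20     hydrogen-bond acceptor flag (N/O/F)
    21     Gasteiger partial charge (dimensionless; non-finite values -> 0)

Bond features (16 columns)
    0-3    bond type one-hot over ``single double triple aromatic``
    4      conjugation flag
    5-11   smallest-ring-size one-hot over ``none 3 4 5 6 7 8+``
    12-15  stereochemistry one-hot over ``none E Z other``

Global features (3 columns): total atom count, total bond count and the
molecular weight in g/mol.  Atom indices are 0-based everywhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.AllChem import ComputeGasteigerCharges

from .autodiff import Tensor, constant
from .errors import ConfigError, FormatError, InputError
from .nn import Linear

log = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

SPECIES = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I")
HYBRIDIZATIONS = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
)
BOND_TYPES = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)
RING_SIZES = (3, 4, 5, 6, 7)  # 8-membered and larger share the last slot

ATOM_FEATURE_DIM = len(SPECIES) + 1 + 1 + 1 + 1 + 1 + 1 + (len(HYBRIDIZATIONS) + 1) + 1 + 1 + 1
BOND_FEATURE_DIM = len(BOND_TYPES) + 1 + (len(RING_SIZES) + 2) + 4
GLOBAL_FEATURE_DIM = 3

# fixed scale applied to raw global features before the learned projection,
# keeping counts and molecular weight at O(1)
GLOBAL_FEATURE_SCALE = np.array([0.1, 0.1, 0.01])


@dataclass(frozen=True)
class MolecularGraph:
    """Featurized heavy-atom graph of one molecule."""

    smiles: str
    atom_features: np.ndarray  # (n_atoms, ATOM_FEATURE_DIM)
    bond_features: np.ndarray  # (n_bonds, BOND_FEATURE_DIM)
    bond_index: np.ndarray     # (n_bonds, 2); each undirected bond stored once
    global_features: np.ndarray  # (GLOBAL_FEATURE_DIM,)
    elements: tuple[str, ...]
    bond_orders: tuple[str, ...]  # aligned with bond_index; vocabulary labels

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.bond_index.shape[0]

    @property
    def bond_list(self) -> list[tuple[np.ndarray, int, int]]:
        """Bonds as (feature_vector, atom_p, atom_q) triplets."""
        return [
            (self.bond_features[k], int(p), int(q))
            for k, (p, q) in enumerate(self.bond_index)
        ]

    def neighbors(self, i: int) -> list[int]:
        out = []
        for p, q in self.bond_index:
            if p == i:
                out.append(int(q))
            elif q == i:
                out.append(int(p))
        return sorted(out)


@dataclass(frozen=True)
class PairExample:
    """One solute-solvent pair; the label is the solvation free energy in kcal/mol."""

    solute: MolecularGraph
    solvent: MolecularGraph
    label: float | None = None

    def __post_init__(self):
        if self.label is not None and not np.isfinite(self.label):
            raise InputError(f"non-finite label for pair "
                             f"({self.solute.smiles}, {self.solvent.smiles})")


def _one_hot(value, choices: Sequence) -> list[float]:
    """One-hot with a trailing 'other' slot; always sums to 1."""
    v = [0.0] * (len(choices) + 1)
    try:
        v[list(choices).index(value)] = 1.0
    except ValueError:
        v[-1] = 1.0
    return v


def featurize_molecule(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Raises :class:`~hypersolv.errors.InputError` for unparsable SMILES or
    molecules without heavy atoms.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"unparsable SMILES: {smiles!r}")
    if mol.GetNumAtoms() == 0:
        raise InputError(f"molecule has no heavy atoms: {smiles!r}")
    ComputeGasteigerCharges(mol)

    ring_info = mol.GetRingInfo()
    atom_rows = []
    elements = []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        elements.append(sym)
        n_h = atom.GetTotalNumHs()
        charge = atom.GetDoubleProp("_GasteigerCharge")
        if not np.isfinite(charge):
            charge = 0.0
        donor = float(sym in ("N", "O") and n_h > 0)
        acceptor = float(sym in ("N", "O", "F"))
        row = (
            _one_hot(sym, SPECIES)
            + [float(atom.GetDegree()), float(n_h), float(atom.IsInRing()),
               float(atom.GetTotalValence()), float(atom.GetIsAromatic())]
            + _one_hot(atom.GetHybridization(), HYBRIDIZATIONS)
            + [donor, acceptor, charge]
        )
        atom_rows.append(row)

    bond_rows, bond_idx, bond_orders = [], [], []
    for bond in mol.GetBonds():
        ring_size = 0
        if bond.IsInRing():
            sizes = [s for s in range(3, 9)
                     if ring_info.IsBondInRingOfSize(bond.GetIdx(), s)]
            ring_size = min(sizes) if sizes else 8
        stereo = bond.GetStereo()
        if stereo in (Chem.BondStereo.STEREOE, Chem.BondStereo.STEREOTRANS):
            stereo_vec = [0.0, 1.0, 0.0, 0.0]
        elif stereo in (Chem.BondStereo.STEREOZ, Chem.BondStereo.STEREOCIS):
            stereo_vec = [0.0, 0.0, 1.0, 0.0]
        elif stereo == Chem.BondStereo.STEREONONE:
            stereo_vec = [1.0, 0.0, 0.0, 0.0]
        else:
            stereo_vec = [0.0, 0.0, 0.0, 1.0]
        ring_vec = [0.0] * (len(RING_SIZES) + 2)
        if ring_size == 0:
            ring_vec[0] = 1.0
        elif ring_size >= 8:
            ring_vec[-1] = 1.0
        else:
            ring_vec[ring_size - 2] = 1.0  # sizes 3..7 -> slots 1..5
        type_vec = _one_hot(bond.GetBondType(), BOND_TYPES)[:-1]
        if sum(type_vec) == 0.0:  # exotic bond types fold into 'single'
            type_vec[0] = 1.0
        row = (
            type_vec
            + [float(bond.GetIsConjugated())]
            + ring_vec
            + stereo_vec
        )
        bond_rows.append(row)
        bond_idx.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
        bond_orders.append(str(bond.GetBondType()))

    n_atoms = len(atom_rows)
    n_bonds = len(bond_rows)
    return MolecularGraph(
        smiles=smiles,
        atom_features=np.asarray(atom_rows, dtype=np.float64),
        bond_features=(np.asarray(bond_rows, dtype=np.float64)
                       if bond_rows else np.zeros((0, BOND_FEATURE_DIM))),
        bond_index=(np.asarray(bond_idx, dtype=np.intp)
                    if bond_idx else np.zeros((0, 2), dtype=np.intp)),
        global_features=np.array([n_atoms, n_bonds, Descriptors.MolWt(mol)]),
        elements=tuple(elements),
        bond_orders=tuple(bond_orders),
    )


REQUIRED_COLUMNS = ("solute_smiles", "solvent_smiles")
LABEL_COLUMN = "dg_solv"


def read_pair_table(path: str | Path, strict: bool = False) -> list[PairExample]:
    """Read a delimited pair table (CSV, or TSV if the extension is .tsv).

    Expected columns: ``solute_smiles``, ``solvent_smiles`` and optionally
    ``dg_solv`` (kcal/mol).  Rows with unparsable SMILES are skipped with a
    logged row number (default) or raise in strict mode.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required columns {missing}; found {list(df.columns)}"
        )
    has_label = LABEL_COLUMN in df.columns
    out: list[PairExample] = []
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        try:
            solute = featurize_molecule(getattr(row, "solute_smiles"))
            solvent = featurize_molecule(getattr(row, "solvent_smiles"))
            label = float(getattr(row, LABEL_COLUMN)) if has_label else None
            out.append(PairExample(solute, solvent, label))
        except (InputError, ValueError) as exc:
            if strict:
                raise InputError(f"{path} line {row_number}: {exc}") from exc
            log.warning("%s line %d skipped: %s", path, row_number, exc)
    if not out:
        warnings.warn(f"{path}: no usable pairs found", stacklevel=2)
    return out


def write_pair_table(pairs: Sequence[PairExample], path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.DataFrame(
        {
            "solute_smiles": [p.solute.smiles for p in pairs],
            "solvent_smiles": [p.solvent.smiles for p in pairs],
            LABEL_COLUMN: [p.label for p in pairs],
        }
    )
    df.to_csv(path, sep=sep, index=False)


class FeatureProjector:
    """Learned linear maps standardizing atom/bond/global widths to ``d``.

    Applied once, before the first round of message passing.
    """

    def __init__(self, target_dim: int, rng: np.random.Generator,
                 identity: bool = False):
        self.target_dim = target_dim
        if identity:
            if target_dim != ATOM_FEATURE_DIM:
                raise ConfigError("identity projector requires target_dim == raw width")
            self.atom = Linear(ATOM_FEATURE_DIM, target_dim, rng)
            self.atom.W.data = np.eye(ATOM_FEATURE_DIM)
            self.bond = Linear(BOND_FEATURE_DIM, target_dim, rng, zero_init=True)
            self.glob = Linear(GLOBAL_FEATURE_DIM, target_dim, rng, zero_init=True)
        else:
            self.atom = Linear(ATOM_FEATURE_DIM, target_dim, rng)
            self.bond = Linear(BOND_FEATURE_DIM, target_dim, rng)
            self.glob = Linear(GLOBAL_FEATURE_DIM, target_dim, rng)

    def project_arrays(self, atom_raw: np.ndarray, bond_raw: np.ndarray,
                       glob_raw: np.ndarray) -> tuple[Tensor, Tensor, Tensor]:
        """Project stacked raw feature arrays (batched path)."""
        atoms = self.atom(constant(atom_raw))
        if bond_raw.shape[0]:
            bonds = self.bond(constant(bond_raw))
        else:
            bonds = constant(np.zeros((0, self.target_dim)))
        glob = self.glob(constant(np.atleast_2d(glob_raw) * GLOBAL_FEATURE_SCALE))
        return atoms, bonds, glob

    def project(self, graph: MolecularGraph) -> tuple[Tensor, Tensor, Tensor]:
        """Project one molecule's raw features to width ``target_dim``."""
        atoms = self.atom(constant(graph.atom_features))
        if graph.n_bonds:
            bonds = self.bond(constant(graph.bond_features))
        else:
            bonds = constant(np.zeros((0, self.target_dim)))
        glob = self.glob(constant((graph.global_features
                                   * GLOBAL_FEATURE_SCALE)[None, :]))
        return atoms, bonds, glob

    def parameters(self):
        return self.atom.parameters() + self.bond.parameters() + self.glob.parameters()


def standardize_feature_lengths(graph: MolecularGraph,
                                projector: FeatureProjector):
    """Spec-level convenience: returns (atom, bond, global) tensors of equal width."""
    if graph.atom_features.shape[1] != projector.atom.n_in:
        raise ConfigError(
            f"atom feature width {graph.atom_features.shape[1]} does not match "
            f"projector input width {projector.atom.n_in}"
        )
    return projector.project(graph)
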