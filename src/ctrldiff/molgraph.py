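"""Molecule data model, SDF/XYZ I/O, preprocessing and dataset splitting.

A molecule is a fully labelled 3D graph: per-atom element types and formal
charges, a symmetric bond-order matrix, and Cartesian coordinates in
ångström.  The object is what the diffusion process noises and what the
sampler generates, so no implicit hydrogens and no perception steps: the
graph *is* the molecule.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Geometry import Point3D

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Vocabulary",
    "DEFAULT_VOCAB",
    "Molecule3DGraph",
    "DatasetSplit",
    "PreprocessReport",
    "ParseError",
    "parse_xyz",
    "write_xyz",
    "read_sdf",
    "write_sdf",
    "to_rdkit",
    "from_rdkit",
    "canonical_key",
    "center_com",
    "preprocess_dataset",
    "split_dataset",
]

INVALID_KEY = "INVALID"


class ParseError(ValueError):
    """Raised on malformed molecular file content."""


@dataclasses.dataclass(frozen=True)
class Vocabulary:
    """Category vocabularies for atoms, formal charges and bond orders.

    Bond index 0 is always "none" (no bond); aromatic is a first-class
    bond category rather than a perception outcome.
    """

    atoms: tuple[str, ...] = ("H", "C", "N", "O", "F")
    charges: tuple[int, ...] = (-1, 0, 1)
    bonds: tuple[str, ...] = ("none", "single", "double", "triple", "aromatic")

    @property
    def n_atom_types(self) -> int:
        return len(self.atoms)

    @property
    def n_charges(self) -> int:
        return len(self.charges)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def atom_index(self, symbol: str) -> int:
        try:
            return self.atoms.index(symbol)
        except ValueError:
            raise ParseError(f"unknown element symbol {symbol!r}") from None

    def charge_index(self, charge: int) -> int:
        try:
            return self.charges.index(charge)
        except ValueError:
            raise ParseError(f"formal charge {charge} outside vocabulary {self.charges}") from None


DEFAULT_VOCAB = Vocabulary()

_RD_BOND = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
    4: Chem.BondType.AROMATIC,
}
_BOND_ORDER = {  # numeric order used for valency sums
    0: 0.0,
    1: 1.0,
    2: 2.0,
    3: 3.0,
    4: 1.5,
}


@dataclasses.dataclass
class Molecule3DGraph:
    """A 3D molecular graph: coordinates, atom types, charges and bonds.

    coords      (n, 3) float64, Å
    atom_types  (n,)   int indices into vocab.atoms
    charges     (n,)   int indices into vocab.charges
    bonds       (n, n) int indices into vocab.bonds, symmetric, 0 diagonal
    """

    coords: np.ndarray
    atom_types: np.ndarray
    charges: np.ndarray
    bonds: np.ndarray
    id: str = ""
    vocab: Vocabulary = DEFAULT_VOCAB

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.atom_types = np.asarray(self.atom_types, dtype=np.int64)
        self.charges = np.asarray(self.charges, dtype=np.int64)
        self.bonds = np.asarray(self.bonds, dtype=np.int64)
        n = self.n_atoms
        if n < 1:
            raise ValueError("molecule must have at least one atom")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if self.charges.shape != (n,) or self.bonds.shape != (n, n):
            raise ValueError("charges/bonds shape inconsistent with atom count")
        if not np.array_equal(self.bonds, self.bonds.T):
            raise ValueError("bond matrix must be symmetric")
        if np.any(np.diag(self.bonds) != 0):
            raise ValueError("bond matrix diagonal must be 'none'")
        for arr, size, name in (
            (self.atom_types, self.vocab.n_atom_types, "atom_types"),
            (self.charges, self.vocab.n_charges, "charges"),
            (self.bonds, self.vocab.n_bonds, "bonds"),
        ):
            if arr.min() < 0 or arr.max() >= size:
                raise ValueError(f"{name} index outside vocabulary")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_types)

    @property
    def symbols(self) -> list[str]:
        return [self.vocab.atoms[i] for i in self.atom_types]

    def formal_charges(self) -> np.ndarray:
        return np.array([self.vocab.charges[i] for i in self.charges])

    def valencies(self) -> np.ndarray:
        """Per-atom sum of bond orders (aromatic counts 1.5)."""
        order = np.array([_BOND_ORDER[b] for b in range(self.vocab.n_bonds)])
        return order[self.bonds].sum(axis=1)

    def copy(self) -> "Molecule3DGraph":
        return Molecule3DGraph(
            self.coords.copy(),
            self.atom_types.copy(),
            self.charges.copy(),
            self.bonds.copy(),
            id=self.id,
            vocab=self.vocab,
        )

    def permuted(self, perm: np.ndarray) -> "Molecule3DGraph":
        """Return a copy with atoms reordered by `perm`."""
        perm = np.asarray(perm)
        return Molecule3DGraph(
            self.coords[perm],
            self.atom_types[perm],
            self.charges[perm],
            self.bonds[np.ix_(perm, perm)],
            id=self.id,
            vocab=self.vocab,
        )


@dataclasses.dataclass(frozen=True)
class DatasetSplit:
    train: np.ndarray
    valid: np.ndarray
    test: np.ndarray
    seed: int
    ratios: tuple[float, float, float]


@dataclasses.dataclass(frozen=True)
class PreprocessReport:
    n_input: int
    n_removed_consistency: int
    n_removed_unparseable: int
    n_kept: int

    def __post_init__(self):
        expected = self.n_input - self.n_removed_consistency - self.n_removed_unparseable
        if self.n_kept != expected:
            raise ValueError("preprocess report counts do not reconcile")


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def parse_xyz(text: str, vocab: Vocabulary = DEFAULT_VOCAB) -> Molecule3DGraph:
    """Parse an (extended) XYZ block into a molecule with no bonds.

    Line 1 is the atom count, line 2 a free comment; each following line is
    ``symbol x y z``.  Coordinates are taken as Å.
    """
    lines = text.strip("\n").split("\n")
    if not lines or not lines[0].strip():
        raise ParseError("line 1: missing atom-count header")
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise ParseError(f"line 1: malformed atom-count header {lines[0]!r}") from None
    if n < 1:
        raise ParseError("line 1: atom count must be >= 1")
    atom_lines = [ln for ln in lines[2:] if ln.strip()]
    if len(atom_lines) != n:
        raise ParseError(
            f"header declares {n} atoms but {len(atom_lines)} atom lines found"
        )
    coords = np.zeros((n, 3))
    types = np.zeros(n, dtype=np.int64)
    for i, ln in enumerate(atom_lines):
        parts = ln.split()
        if len(parts) < 4:
            raise ParseError(f"line {i + 3}: expected 'symbol x y z', got {ln!r}")
        try:
            types[i] = vocab.atom_index(parts[0])
        except ParseError as exc:
            raise ParseError(f"line {i + 3}: {exc}") from None
        try:
            coords[i] = [float(v) for v in parts[1:4]]
        except ValueError:
            raise ParseError(f"line {i + 3}: non-numeric coordinate in {ln!r}") from None
    neutral = vocab.charge_index(0)
    return Molecule3DGraph(
        coords,
        types,
        np.full(n, neutral, dtype=np.int64),
        np.zeros((n, n), dtype=np.int64),
        vocab=vocab,
    )


def write_xyz(mol: Molecule3DGraph, comment: str = "") -> str:
    lines = [str(mol.n_atoms), comment.replace("\n", " ")]
    for sym, (x, y, z) in zip(mol.symbols, mol.coords):
        lines.append(f"{sym} {x:.8f} {y:.8f} {z:.8f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# rdkit bridge and SDF
# ---------------------------------------------------------------------------

def to_rdkit(mol: Molecule3DGraph, sanitize: bool = False) -> Chem.Mol:
    """Build an rdkit Mol with explicit atoms/bonds and a 3D conformer.

    No implicit hydrogens are added (``SetNoImplicit``): valence is exactly
    the sum of the stated bond orders, so sanitization judges the generated
    graph as-is.
    """
    rw = Chem.RWMol()
    for sym, q in zip(mol.symbols, mol.formal_charges()):
        atom = Chem.Atom(sym)
        atom.SetFormalCharge(int(q))
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    n = mol.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            b = int(mol.bonds[i, j])
            if b != 0:
                rw.AddBond(i, j, _RD_BOND[b])
    conf = Chem.Conformer(n)
    for i, (x, y, z) in enumerate(mol.coords):
        conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
    out = rw.GetMol()
    out.AddConformer(conf)
    if mol.id:
        out.SetProp("_Name", mol.id)
    if sanitize:
        Chem.SanitizeMol(out)
    return out


def from_rdkit(rd: Chem.Mol, mol_id: str = "", vocab: Vocabulary = DEFAULT_VOCAB) -> Molecule3DGraph:
    """Convert an rdkit Mol (with conformer) into a Molecule3DGraph."""
    n = rd.GetNumAtoms()
    if n == 0:
        raise ParseError(f"molecule {mol_id!r}: no atoms")
    types = np.zeros(n, dtype=np.int64)
    charges = np.zeros(n, dtype=np.int64)
    for i, atom in enumerate(rd.GetAtoms()):
        try:
            types[i] = vocab.atom_index(atom.GetSymbol())
            charges[i] = vocab.charge_index(atom.GetFormalCharge())
        except ParseError as exc:
            raise ParseError(f"molecule {mol_id!r}: {exc}") from None
    bonds = np.zeros((n, n), dtype=np.int64)
    inv_bond = {v: k for k, v in _RD_BOND.items()}
    for bond in rd.GetBonds():
        bt = bond.GetBondType()
        if bt not in inv_bond:
            raise ParseError(f"molecule {mol_id!r}: unmappable bond type {bt}")
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bonds[i, j] = bonds[j, i] = inv_bond[bt]
    if rd.GetNumConformers() == 0:
        coords = np.zeros((n, 3))
    else:
        coords = np.asarray(rd.GetConformer().GetPositions(), dtype=np.float64)
    name = rd.GetProp("_Name") if rd.HasProp("_Name") else mol_id
    return Molecule3DGraph(coords, types, charges, bonds, id=name or mol_id, vocab=vocab)


def read_sdf(path, vocab: Vocabulary = DEFAULT_VOCAB) -> list[Molecule3DGraph]:
    """Read a V2000 SDF file; bond orders and charges must be in-vocabulary."""
    import os

    if os.path.getsize(str(path)) == 0:
        return []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    out = []
    for k, rd in enumerate(supplier):
        if rd is None:
            raise ParseError(f"record {k}: unparseable SDF record")
        out.append(from_rdkit(rd, mol_id=f"record{k}", vocab=vocab))
    return out


def write_sdf(mols: Iterable[Molecule3DGraph], path, properties: dict | None = None) -> None:
    """Write molecules as V2000 SDF; optional shared property block entries."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for k, mol in enumerate(mols):
            rd = to_rdkit(mol)
            if not mol.id:
                rd.SetProp("_Name", f"mol{k}")
            for key, value in (properties or {}).items():
                rd.SetProp(str(key), str(value))
            writer.write(rd)
    finally:
        writer.close()


def read_sdf_properties(path) -> list[dict]:
    """Property blocks of each SDF record (for metadata round-trips)."""
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    out = []
    for rd in supplier:
        props = {} if rd is None else {k: rd.GetProp(k) for k in rd.GetPropNames()}
        out.append(props)
    return out


# ---------------------------------------------------------------------------
# canonical key, centring, preprocessing, splitting
# ---------------------------------------------------------------------------

def canonical_key(mol: Molecule3DGraph) -> str:
    """Canonical string for the labelled graph, ignoring atom order and pose.

    Canonical SMILES of the sanitized graph; molecules that fail
    sanitization get the sentinel key ``"INVALID"`` (they are not eligible
    for uniqueness/novelty bookkeeping).
    """
    try:
        rd = to_rdkit(mol, sanitize=True)
        return Chem.MolToSmiles(rd)
    except Exception:
        return INVALID_KEY


def center_com(coords: np.ndarray) -> np.ndarray:
    """Shift coordinates so the (unweighted) centre of mass is the origin."""
    coords = np.asarray(coords, dtype=np.float64)
    return coords - coords.mean(axis=0, keepdims=True)


def _consistency_ok(mol: Molecule3DGraph) -> bool:
    """Encode → decode → re-encode identity on the canonical string.

    Generic stand-in for an InChI-style round-trip check: the canonical
    SMILES must survive a parse/re-encode cycle unchanged.
    """
    smi = canonical_key(mol)
    if smi == INVALID_KEY:
        return False
    parser = Chem.SmilesParserParams()
    parser.removeHs = False  # hydrogens are explicit throughout
    reparsed = Chem.MolFromSmiles(smi, parser)
    if reparsed is None:
        return False
    return Chem.MolToSmiles(reparsed) == smi


def _parseable(mol: Molecule3DGraph) -> bool:
    try:
        to_rdkit(mol, sanitize=True)
        return True
    except Exception:
        return False


def preprocess_dataset(
    mols: Sequence[Molecule3DGraph], checks: Iterable[str] = ("consistency", "parse")
) -> tuple[list[Molecule3DGraph], PreprocessReport]:
    """Filter molecules by the enabled checks, preserving order.

    checks ⊆ {"consistency", "parse"}: an encode/decode round-trip identity
    and plain sanitizer parseability.  A molecule failing the parse check is
    counted as unparseable; one that parses but fails the round-trip is
    counted as a consistency removal.
    """
    checks = set(checks)
    unknown = checks - {"consistency", "parse"}
    if unknown:
        raise ValueError(f"unknown preprocessing checks: {sorted(unknown)}")
    kept = []
    n_cons = n_parse = 0
    for mol in mols:
        if checks and not _parseable(mol):
            # failing the sanitizer also fails consistency; attribute the
            # removal to parseability when that check is enabled
            if "parse" in checks:
                n_parse += 1
            else:
                n_cons += 1
            continue
        if "consistency" in checks and not _consistency_ok(mol):
            n_cons += 1
            continue
        kept.append(mol)
    report = PreprocessReport(
        n_input=len(mols),
        n_removed_consistency=n_cons,
        n_removed_unparseable=n_parse,
        n_kept=len(kept),
    )
    return kept, report


def split_dataset(
    n: int, ratios: tuple[float, float, float] = (0.7, 0.2, 0.1), seed: int = 0
) -> DatasetSplit:
    """Shuffle indices with a seeded PRNG and partition train/valid/test.

    Validation and test sizes are floored; the remainder goes to train, so
    (0.7, 0.2, 0.1) on 1000 records gives exactly 700/200/100.
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r < 0 for r in ratios):
        raise ValueError("ratios must be three non-negative fractions")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    if n < 3:
        raise ValueError("need at least 3 records to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_valid = math.floor(ratios[1] * n)
    n_test = math.floor(ratios[2] * n)
    n_train = n - n_valid - n_test
    return DatasetSplit(
        train=perm[:n_train],
        valid=perm[n_train : n_train + n_valid],
        test=perm[n_train + n_valid :],
        seed=seed,
        ratios=ratios,
    )
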