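"""Chemical data model, descriptors, and structure file I/O.

The universal object is :class:`Molecule3D`: an ordered list of atoms with
3D coordinates (Å), a bond list with integer orders, a name and a free-form
property map.  Open valences (points where a new bond may be formed) are
encoded as monovalent placeholder "dummy" atoms (element ``"*"``) bonded to
a single heavy anchor atom; placeholders are excluded from heavy-atom
counts, molecular weights and geometric centers.

RDKit does the heavy lifting behind this surface: SDF/MOL/SMILES parsing
and writing, 3D embedding of SMILES inputs (seeded, so reproducible),
molecular weight, Lipinski descriptors, Wildman–Crippen logP, canonical
SMILES and valence checking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Crippen, Descriptors, Lipinski

__all__ = [
    "Atom",
    "Molecule3D",
    "PLACEHOLDER",
    "heavy_atom_count",
    "molecular_weight",
    "geometric_center",
    "count_hbond_donors",
    "count_hbond_acceptors",
    "estimate_logp",
    "read_structures",
    "write_structures",
    "from_smiles",
    "to_rdkit",
    "from_rdkit",
    "canonical_smiles",
]

PLACEHOLDER = "*"

_BOND_TYPES = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}
_BOND_ORDERS = {v: k for k, v in _BOND_TYPES.items()}

_PT = Chem.GetPeriodicTable()


def _atomic_number(symbol: str) -> int:
    """Atomic number for an element symbol; placeholders map to 0."""
    if symbol == PLACEHOLDER:
        return 0
    try:
        z = _PT.GetAtomicNumber(symbol)
    except Exception:
        raise ValueError(f"unknown element symbol: {symbol!r}") from None
    if z <= 0:
        raise ValueError(f"unknown element symbol: {symbol!r}")
    return z


@dataclass
class Atom:
    """A single atom: element symbol, position in Å, placeholder flag."""

    element: str
    position: np.ndarray
    is_attachment_placeholder: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom {self.element!r}")
        if self.element == PLACEHOLDER:
            self.is_attachment_placeholder = True
        else:
            _atomic_number(self.element)  # validates the symbol

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    @property
    def is_heavy(self) -> bool:
        return not self.is_hydrogen and not self.is_attachment_placeholder

    def copy(self) -> "Atom":
        return Atom(self.element, self.position.copy(), self.is_attachment_placeholder)


@dataclass
class Molecule3D:
    """A 3D molecule: atoms, bonds ``(i, j, order)``, name and properties."""

    atoms: list[Atom]
    bonds: list[tuple[int, int, int]] = field(default_factory=list)
    name: str = ""
    properties: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        norm: list[tuple[int, int, int]] = []
        seen: set[tuple[int, int]] = set()
        for bond in self.bonds:
            if len(bond) == 2:
                i, j = bond
                order = 1
            else:
                i, j, order = bond
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i}, {j}) out of range for {n} atoms")
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
            norm.append((key[0], key[1], int(order)))
        self.bonds = norm

    # -- basic accessors ---------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms])

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.is_heavy]

    def placeholder_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.is_attachment_placeholder]

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    # -- geometry ----------------------------------------------------------

    def copy(self) -> "Molecule3D":
        return Molecule3D(
            [a.copy() for a in self.atoms],
            list(self.bonds),
            self.name,
            dict(self.properties),
        )

    def translated(self, t: np.ndarray) -> "Molecule3D":
        out = self.copy()
        t = np.asarray(t, dtype=float)
        for a in out.atoms:
            a.position = a.position + t
        return out

    def transformed(self, rotation: np.ndarray, center: np.ndarray) -> "Molecule3D":
        """Rotate about ``center`` by the 3x3 matrix ``rotation``."""
        out = self.copy()
        center = np.asarray(center, dtype=float)
        for a in out.atoms:
            a.position = rotation @ (a.position - center) + center
        return out

    def connected_components(self) -> list[list[int]]:
        adj: dict[int, list[int]] = {i: [] for i in range(self.n_atoms)}
        for i, j, _ in self.bonds:
            adj[i].append(j)
            adj[j].append(i)
        seen: set[int] = set()
        comps: list[list[int]] = []
        for start in range(self.n_atoms):
            if start in seen:
                continue
            stack, comp = [start], []
            seen.add(start)
            while stack:
                v = stack.pop()
                comp.append(v)
                for w in adj[v]:
                    if w not in seen:
                        seen.add(w)
                        stack.append(w)
            comps.append(sorted(comp))
        return comps


# ---------------------------------------------------------------------------
# RDKit interconversion
# ---------------------------------------------------------------------------


def to_rdkit(mol: Molecule3D, sanitize: bool = True) -> Chem.Mol:
    """Convert to an RDKit molecule (placeholders become dummy atoms)."""
    rw = Chem.RWMol()
    for atom in mol.atoms:
        if atom.is_attachment_placeholder:
            a = Chem.Atom(0)
        else:
            a = Chem.Atom(atom.element)
        rw.AddAtom(a)
    for i, j, order in mol.bonds:
        rw.AddBond(i, j, _BOND_TYPES.get(order, Chem.BondType.SINGLE))
    m = rw.GetMol()
    if mol.atoms:
        conf = Chem.Conformer(mol.n_atoms)
        for i, atom in enumerate(mol.atoms):
            conf.SetAtomPosition(i, [float(x) for x in atom.position])
        m.AddConformer(conf)
    if sanitize:
        Chem.SanitizeMol(m)
    m.SetProp("_Name", mol.name)
    for k, v in mol.properties.items():
        m.SetProp(str(k), str(v))
    return m


def from_rdkit(m: Chem.Mol, name: str | None = None) -> Molecule3D:
    """Convert an RDKit molecule (kekulized internally) to :class:`Molecule3D`."""
    mk = Chem.Mol(m)
    Chem.Kekulize(mk, clearAromaticFlags=True)
    if mk.GetNumConformers():
        coords = mk.GetConformer().GetPositions()
    else:
        coords = np.zeros((mk.GetNumAtoms(), 3))
    atoms = []
    for i, a in enumerate(mk.GetAtoms()):
        if a.GetAtomicNum() == 0:
            atoms.append(Atom(PLACEHOLDER, coords[i]))
        else:
            atoms.append(Atom(a.GetSymbol(), coords[i]))
    bonds = []
    for b in mk.GetBonds():
        order = _BOND_ORDERS.get(b.GetBondType(), 1)
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    if name is None:
        name = m.GetProp("_Name") if m.HasProp("_Name") else ""
    props = {k: v for k, v in m.GetPropsAsDict().items() if not k.startswith("_")}
    return Molecule3D(atoms, bonds, name=name, properties=props)


def canonical_smiles(mol: Molecule3D) -> str:
    """Canonical SMILES (placeholders as ``*``); the deduplication key."""
    return Chem.MolToSmiles(Chem.RemoveHs(to_rdkit(mol)))


# ---------------------------------------------------------------------------
# Descriptors
# ---------------------------------------------------------------------------


def heavy_atom_count(mol: Molecule3D) -> int:
    """Number of non-hydrogen, non-placeholder atoms (the GE denominator)."""
    return sum(1 for a in mol.atoms if a.is_heavy)


def molecular_weight(mol: Molecule3D) -> float:
    """Molecular weight in g/mol, implicit hydrogens included, placeholders excluded."""
    if not mol.atoms:
        return 0.0
    return float(Descriptors.MolWt(to_rdkit(mol)))


def geometric_center(mol: Molecule3D) -> np.ndarray:
    """Unweighted mean position of the heavy atoms, Å."""
    idx = mol.heavy_indices()
    if not idx:
        raise ValueError("molecule has no heavy atoms; geometric center undefined")
    return mol.positions[idx].mean(axis=0)


def count_hbond_donors(mol: Molecule3D) -> int:
    """N/O atoms bearing at least one hydrogen (explicit or implicit)."""
    return int(Lipinski.NumHDonors(to_rdkit(mol)))


def count_hbond_acceptors(mol: Molecule3D) -> int:
    """Count of N and O atoms (the classic Rule-of-Five acceptor definition)."""
    return int(Lipinski.NOCount(to_rdkit(mol)))


def estimate_logp(mol: Molecule3D) -> float:
    """Wildman–Crippen atom-contribution logP."""
    return float(Crippen.MolLogP(to_rdkit(mol)))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_FORMAT_SUFFIXES = {
    ".sdf": "sdf",
    ".mol": "mol",
    ".smi": "smiles",
    ".smiles": "smiles",
}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.lower()
        if f not in {"sdf", "mol", "smiles"}:
            raise ValueError(f"unreadable format: {fmt!r}")
        return f
    suffix = path.suffix.lower()
    if suffix not in _FORMAT_SUFFIXES:
        raise ValueError(f"cannot infer structure format from suffix {suffix!r}")
    return _FORMAT_SUFFIXES[suffix]


def from_smiles(
    smiles: str,
    name: str = "",
    seed: int = 2013,
    embed: bool = True,
    add_hs: bool = True,
) -> Molecule3D:
    """Build a :class:`Molecule3D` from SMILES with deterministic 3D embedding."""
    m = Chem.MolFromSmiles(smiles)
    if m is None:
        raise ValueError(f"could not parse SMILES: {smiles!r}")
    if add_hs:
        m = Chem.AddHs(m)
    if embed:
        # distance-bounds embedding cannot handle dummy atoms; embed them as
        # carbons (a realistic partner-atom bond length) and restore afterwards
        dummies = [a.GetIdx() for a in m.GetAtoms() if a.GetAtomicNum() == 0]
        for i in dummies:
            m.GetAtomWithIdx(i).SetAtomicNum(6)
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed) % (2**31 - 1)
        try:
            code = AllChem.EmbedMolecule(m, params)
        except RuntimeError:
            code = -1
        if code != 0:
            params.useRandomCoords = True
            try:
                code = AllChem.EmbedMolecule(m, params)
            except RuntimeError:
                code = -1
            if code != 0:
                raise ValueError(f"3D embedding failed for SMILES: {smiles!r}")
        for i in dummies:
            m.GetAtomWithIdx(i).SetAtomicNum(0)
    out = from_rdkit(m, name=name)
    out.name = name
    return out


def read_structures(
    path: str | Path,
    fmt: str | None = None,
    seed: int = 2013,
) -> list[Molecule3D]:
    """Read SDF / MOL / SMILES files into :class:`Molecule3D` records.

    SMILES inputs (one per line, optional whitespace-separated name) get
    deterministic 3D coordinates via seeded ETKDG embedding.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    f = _infer_format(path, fmt)
    RDLogger.DisableLog("rdApp.warning")
    mols: list[Molecule3D] = []
    if f in ("sdf", "mol"):
        if path.stat().st_size == 0:
            return []
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for i, m in enumerate(supplier):
            if m is None:
                raise ValueError(f"malformed structure record {i} in {path}")
            mols.append(from_rdkit(m))
    else:
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else f"smiles_{i}"
            try:
                mols.append(from_smiles(smiles, name=name, seed=seed + i))
            except ValueError as exc:
                raise ValueError(f"malformed SMILES record {i} in {path}: {exc}") from exc
    return mols


def write_structures(
    mols: Iterable[Molecule3D],
    path: str | Path,
    fmt: str | None = None,
) -> None:
    """Write molecules as a V2000 SDF (properties become SDF data fields)."""
    path = Path(path)
    f = _infer_format(path, fmt or "sdf")
    if f == "smiles":
        lines = [f"{canonical_smiles(m)} {m.name}".rstrip() for m in mols]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        return
    writer = Chem.SDWriter(str(path))
    try:
        for m in mols:
            writer.write(to_rdkit(m))
    finally:
        writer.close()
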