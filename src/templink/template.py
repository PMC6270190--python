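"""Template dissection and search-region definition (Step 1).

A two-pocket template inhibitor (e.g. a type II kinase inhibitor spanning
the ATP site and the DFG-out allosteric pocket) is cut at two user-chosen
acyclic single bonds into three connected pieces: *fragment 1* (pocket 1,
the ATP site by convention), the *linker*, and *fragment 2* (pocket 2, the
allosteric site).  Each piece receives a placeholder atom at the former
partner atom's coordinates marking the open valence.  The two docking
search regions are axis-aligned cubes (default edge 10 Å) centered on the
geometric centers of the two pocket fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .chem import Atom, Molecule3D, PLACEHOLDER, geometric_center, heavy_atom_count

__all__ = [
    "REGIONS",
    "POCKETS",
    "CutSpec",
    "FragmentSpec",
    "TemplateDecomposition",
    "GridBox",
    "decompose_template",
    "region_box",
]

REGIONS = ("pocket1", "linker", "pocket2")
POCKETS = ("pocket1", "pocket2")


@dataclass(frozen=True)
class CutSpec:
    """Which template bonds to cut, and which piece is which region.

    ``region_labels`` maps a region name to any (0-based) template atom
    index contained in that piece.  If omitted, the linker is identified as
    the piece touching both cuts and the pockets are ordered by their
    smallest template atom index.
    """

    bonds_to_cut: tuple[tuple[int, int], ...]
    region_labels: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "bonds_to_cut",
            tuple((min(i, j), max(i, j)) for i, j in self.bonds_to_cut),
        )
        if self.region_labels is not None:
            labels = set(self.region_labels)
            if labels != set(REGIONS):
                raise ValueError(f"region_labels must label exactly {REGIONS}, got {sorted(labels)}")


@dataclass
class FragmentSpec:
    """A template piece (or library fragment) with attachment annotations."""

    mol: Molecule3D
    attachment_atoms: tuple[int, ...]
    region: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")


@dataclass
class TemplateDecomposition:
    """The three labeled pieces of a template plus the intact template."""

    fragment1: FragmentSpec
    linker_piece: FragmentSpec
    fragment2: FragmentSpec
    template: Molecule3D

    @property
    def fragments(self) -> dict[str, FragmentSpec]:
        return {
            "pocket1": self.fragment1,
            "linker": self.linker_piece,
            "pocket2": self.fragment2,
        }


@dataclass(frozen=True)
class GridBox:
    """Axis-aligned cubic search region: center (Å) and edge length (Å)."""

    center: tuple[float, float, float]
    edge: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(x) for x in self.center))
        if not self.edge > 0:
            raise ValueError(f"box edge must be positive, got {self.edge}")

    @property
    def center_array(self) -> np.ndarray:
        return np.asarray(self.center)

    def contains(self, point: np.ndarray, tolerance: float = 0.0) -> bool:
        half = self.edge / 2.0 + tolerance
        return bool(np.all(np.abs(np.asarray(point) - self.center_array) <= half))


def _bond_in_ring(mol: Molecule3D, i: int, j: int) -> bool:
    """A bond is in a ring iff its endpoints stay connected without it."""
    adj: dict[int, set[int]] = {k: set() for k in range(mol.n_atoms)}
    for a, b, _ in mol.bonds:
        if {a, b} == {i, j}:
            continue
        adj[a].add(b)
        adj[b].add(a)
    stack, seen = [i], {i}
    while stack:
        v = stack.pop()
        if v == j:
            return True
        for w in adj[v]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return False


def _extract_piece(
    template: Molecule3D,
    comp: list[int],
    cut_bonds: Sequence[tuple[int, int]],
) -> tuple[Molecule3D, tuple[int, ...]]:
    """Build a piece molecule with placeholders at former partner positions."""
    local = {t: k for k, t in enumerate(comp)}
    atoms = [template.atoms[t].copy() for t in comp]
    bonds = [
        (local[a], local[b], o)
        for a, b, o in template.bonds
        if a in local and b in local and (min(a, b), max(a, b)) not in cut_bonds
    ]
    anchors: list[int] = []
    for i, j in cut_bonds:
        inside, outside = (i, j) if i in local else (j, i) if j in local else (None, None)
        if inside is None:
            continue
        ph = len(atoms)
        atoms.append(Atom(PLACEHOLDER, template.atoms[outside].position.copy()))
        bonds.append((local[inside], ph, 1))
        anchors.append(local[inside])
    piece = Molecule3D(atoms, bonds, name=template.name)
    return piece, tuple(anchors)


def decompose_template(template: Molecule3D, cuts: CutSpec) -> TemplateDecomposition:
    """Cut the template at the specified bonds into the three labeled pieces.

    Raises ``ValueError`` when a cut bond is missing, non-single, in a
    ring, or when cutting does not yield exactly three connected pieces.
    """
    bond_orders = {(min(a, b), max(a, b)): o for a, b, o in template.bonds}
    for i, j in cuts.bonds_to_cut:
        if (i, j) not in bond_orders:
            raise ValueError(f"cut bond ({i}, {j}) does not exist in the template")
        if bond_orders[(i, j)] != 1:
            raise ValueError(f"cut bond ({i}, {j}) is not a single bond")
        if _bond_in_ring(template, i, j):
            raise ValueError(f"cut bond ({i}, {j}) is in a ring")

    stripped = Molecule3D(
        [a.copy() for a in template.atoms],
        [b for b in template.bonds if (b[0], b[1]) not in set(cuts.bonds_to_cut)],
        name=template.name,
    )
    comps = stripped.connected_components()
    if len(comps) != 3:
        raise ValueError(
            f"cutting {len(cuts.bonds_to_cut)} bond(s) produced {len(comps)} pieces; exactly 3 required"
        )

    pieces = []
    for comp in comps:
        comp_set = set(comp)
        touching = tuple(
            (i, j) for i, j in cuts.bonds_to_cut if i in comp_set or j in comp_set
        )
        mol, anchors = _extract_piece(template, comp, touching)
        pieces.append({"atoms": comp_set, "mol": mol, "anchors": anchors, "n_cuts": len(touching)})

    if cuts.region_labels is not None:
        by_region = {}
        for region, atom_idx in cuts.region_labels.items():
            matches = [p for p in pieces if atom_idx in p["atoms"]]
            if not matches:
                raise ValueError(f"region label atom {atom_idx} not found in any piece")
            by_region[region] = matches[0]
        if len({id(p) for p in by_region.values()}) != 3:
            raise ValueError("region_labels must point at three distinct pieces")
    else:
        linkers = [p for p in pieces if p["n_cuts"] == len(cuts.bonds_to_cut)]
        if len(linkers) != 1:
            raise ValueError("cannot auto-label pieces: no unique piece touches every cut")
        rest = sorted((p for p in pieces if p is not linkers[0]), key=lambda p: min(p["atoms"]))
        by_region = {"linker": linkers[0], "pocket1": rest[0], "pocket2": rest[1]}

    decomp = TemplateDecomposition(
        fragment1=FragmentSpec(by_region["pocket1"]["mol"], by_region["pocket1"]["anchors"], "pocket1"),
        linker_piece=FragmentSpec(by_region["linker"]["mol"], by_region["linker"]["anchors"], "linker"),
        fragment2=FragmentSpec(by_region["pocket2"]["mol"], by_region["pocket2"]["anchors"], "pocket2"),
        template=template,
    )
    total = sum(heavy_atom_count(f.mol) for f in decomp.fragments.values())
    if total != heavy_atom_count(template):
        raise AssertionError(
            f"heavy atoms not conserved by decomposition: {total} vs {heavy_atom_count(template)}"
        )
    return decomp


def region_box(frag: FragmentSpec, edge: float = 10.0) -> GridBox:
    """Cubic search region centered on the fragment's geometric center."""
    return GridBox(tuple(geometric_center(frag.mol)), edge)
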