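"""Geometric linker splicing (Step 3).

A linker carries at least two attachment points (monovalent placeholder
atoms, each bonded to one heavy anchor).  For every ordered pair of points
(*linkingpoint1*, *linkingpoint2*) and every pair of selected pocket poses,
the linker is (i) rigidly translated so linkingpoint1 coincides with
fragment 1's attachment site a1, (ii) rotated about a1 so that the
direction linkingpoint1→linkingpoint2 (*vector2*) maps onto a1→a2
(*vector1*, a2 being fragment 2's attachment site) via the Rodrigues
formula, and (iii) accepted when the residual gap between the rotated
linkingpoint2 and a2 is below the threshold (default 0.1 Å, strict "<").
Because the rotation aligns the directions exactly, the residual gap is
the closed form ||v1| − |v2||.

Accepted placements are fused into candidate compounds: placeholders are
deleted and single bonds formed anchor–anchor; candidates failing a
valence check are discarded; duplicates (same canonical SMILES) are merged
keeping the maximum GE-sum.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .chem import (
    Atom,
    Molecule3D,
    canonical_smiles,
    geometric_center,
    heavy_atom_count,
    to_rdkit,
)
from .ge import group_efficiency
from .poses import DockedPose, PoseSet

__all__ = [
    "AttachmentPoint",
    "Linker",
    "PlacementResult",
    "Provenance",
    "CandidateCompound",
    "AssemblyResult",
    "enumerate_attachment_pairs",
    "place_linker",
    "form_bonds",
    "assemble_all",
    "rotation_aligning",
    "DEFAULT_GAP_THRESHOLD",
]

DEFAULT_GAP_THRESHOLD = 0.1
_EPS = 1e-9


# ---------------------------------------------------------------------------
# Rotation geometry
# ---------------------------------------------------------------------------


def rotation_aligning(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Proper rotation matrix mapping the direction of ``v_from`` onto ``v_to``.

    Rodrigues' formula with axis v_from × v_to.  The antiparallel
    degenerate case (undefined axis) rotates 180° about a deterministic
    perpendicular axis: the smallest-index coordinate axis not parallel to
    ``v_to``, orthogonalized against it.
    """
    a = np.asarray(v_from, dtype=float)
    b = np.asarray(v_to, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < _EPS or nb < _EPS:
        raise ValueError("cannot align zero-length vectors")
    a, b = a / na, b / nb
    cross = np.cross(a, b)
    s = np.linalg.norm(cross)
    c = float(np.dot(a, b))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: 180 deg about a perpendicular axis, chosen deterministically
        for k in range(3):
            e = np.zeros(3)
            e[k] = 1.0
            perp = e - np.dot(e, b) * b
            if np.linalg.norm(perp) > 1e-6:
                axis = perp / np.linalg.norm(perp)
                return 2.0 * np.outer(axis, axis) - np.eye(3)
        raise AssertionError("unreachable: no perpendicular axis found")
    axis = cross / s
    k_mat = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * k_mat + (1.0 - c) * (k_mat @ k_mat)


# ---------------------------------------------------------------------------
# Linker model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AttachmentPoint:
    """A placeholder atom index and its single heavy anchor atom index."""

    placeholder: int
    anchor: int


@dataclass
class Linker:
    """A connector fragment with ≥2 attachment points."""

    mol: Molecule3D
    linker_id: str = ""
    attachment_points: tuple[AttachmentPoint, ...] = ()

    def __post_init__(self) -> None:
        if not self.linker_id:
            self.linker_id = self.mol.name or "linker"
        if not self.attachment_points:
            points = []
            for ph in self.mol.placeholder_indices():
                nbrs = self.mol.neighbors(ph)
                if len(nbrs) != 1:
                    raise ValueError(
                        f"linker {self.linker_id!r}: placeholder atom {ph} must be monovalent"
                    )
                points.append(AttachmentPoint(ph, nbrs[0]))
            self.attachment_points = tuple(points)
        if len(self.attachment_points) < 2:
            raise ValueError(
                f"linker {self.linker_id!r} needs >=2 attachment points, "
                f"found {len(self.attachment_points)}"
            )


def enumerate_attachment_pairs(linker: Linker) -> list[tuple[AttachmentPoint, AttachmentPoint]]:
    """All ordered pairs of distinct attachment points (point1 faces pocket 1)."""
    return list(itertools.permutations(linker.attachment_points, 2))


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------


@dataclass
class PlacementResult:
    """Outcome of one linker placement attempt."""

    transformed_linker: Molecule3D | None
    pair: tuple[AttachmentPoint, AttachmentPoint]
    gap: float
    accepted: bool
    frag1_anchor: int = -1
    frag2_anchor: int = -1
    frag1_placeholder: int | None = None
    frag2_placeholder: int | None = None
    reason: str | None = None


def _attachment_site(mol: Molecule3D, toward: np.ndarray) -> tuple[int, int | None]:
    """Attachment site of a posed fragment: (anchor index, placeholder index).

    Annotated fragments (carrying placeholder atoms) bond at a placeholder's
    anchor — the one nearest ``toward`` when several exist.  Unannotated
    blocks bond at the heavy atom nearest ``toward`` (ties: lowest index).
    """
    placeholders = mol.placeholder_indices()
    if placeholders:
        best = min(
            placeholders,
            key=lambda ph: (float(np.linalg.norm(mol.atoms[ph].position - toward)), ph),
        )
        nbrs = mol.neighbors(best)
        if len(nbrs) != 1:
            raise ValueError(f"fragment placeholder atom {best} must be monovalent")
        return nbrs[0], best
    heavy = mol.heavy_indices()
    if not heavy:
        raise ValueError("fragment has no heavy atoms")
    anchor = min(
        heavy, key=lambda i: (float(np.linalg.norm(mol.atoms[i].position - toward)), i)
    )
    return anchor, None


def place_linker(
    linker: Linker,
    pair: tuple[AttachmentPoint, AttachmentPoint],
    frag1_pose: DockedPose,
    frag2_pose: DockedPose,
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
) -> PlacementResult:
    """Translate + rotate the linker between two pocket poses; test the gap."""
    p1, p2 = pair
    f1, f2 = frag1_pose.mol, frag2_pose.mol

    c1, c2 = geometric_center(f1), geometric_center(f2)
    # centroid pre-alignment reference for resolving unannotated attachment sites
    a1_idx, ph1 = _attachment_site(f1, toward=c2)
    a1 = f1.atoms[a1_idx].position
    a2_idx, ph2 = _attachment_site(f2, toward=a1)
    a2 = f2.atoms[a2_idx].position

    lp1 = linker.mol.atoms[p1.placeholder].position
    lp2 = linker.mol.atoms[p2.placeholder].position
    v1 = a2 - a1
    v2 = lp2 - lp1
    if np.linalg.norm(v1) < _EPS or np.linalg.norm(v2) < _EPS:
        return PlacementResult(None, pair, float("inf"), False,
                               a1_idx, a2_idx, ph1, ph2, reason="zero-length vector")

    moved = linker.mol.translated(a1 - lp1)
    rot = rotation_aligning(v2, v1)
    moved = moved.transformed(rot, a1)
    gap = float(np.linalg.norm(moved.atoms[p2.placeholder].position - a2))
    return PlacementResult(
        moved, pair, gap, gap < gap_threshold, a1_idx, a2_idx, ph1, ph2,
        reason=None if gap < gap_threshold else "gap above threshold",
    )


# ---------------------------------------------------------------------------
# Bond formation and candidate assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Provenance:
    frag1_block: str
    frag1_pose: int
    frag2_block: str
    frag2_pose: int
    linker_id: str
    point1: int
    point2: int


@dataclass
class CandidateCompound:
    """An assembled molecule with provenance, GE-sum, filter flags and rank."""

    mol: Molecule3D
    smiles: str
    ge_sum: float
    provenance: list[Provenance] = field(default_factory=list)
    filter_flags: dict = field(default_factory=dict)
    rank: int | None = None


def _drop_directed_hydrogen(mol: Molecule3D, anchor: int, toward: np.ndarray) -> int | None:
    """Index of the anchor's explicit H best aligned with the new bond, if any."""
    direction = np.asarray(toward, dtype=float) - mol.atoms[anchor].position
    n = np.linalg.norm(direction)
    hs = [i for i in mol.neighbors(anchor) if mol.atoms[i].is_hydrogen]
    if not hs:
        return None
    if n < _EPS:
        return hs[0]
    direction = direction / n
    def score(i: int) -> tuple[float, int]:
        v = mol.atoms[i].position - mol.atoms[anchor].position
        nv = np.linalg.norm(v)
        return (-(float(np.dot(v, direction) / nv) if nv > _EPS else -2.0), i)
    return min(hs, key=score)


def form_bonds(
    frag1_pose: DockedPose,
    frag2_pose: DockedPose,
    linker: Linker,
    placement: PlacementResult,
    ge_sum: float = 0.0,
) -> tuple[CandidateCompound | None, str | None]:
    """Fuse the two poses and the placed linker into one candidate.

    Used placeholders are deleted and replaced by anchor–anchor single
    bonds; the linker's unused attachment placeholders become hydrogens at
    the placeholder positions.  Annotated fragments lose their placeholder;
    unannotated fragments lose one explicit hydrogen on the bonding atom
    (the one best aligned with the new bond) when present.  A candidate
    failing RDKit's valence check is discarded with the reason returned.
    """
    if not placement.accepted:
        raise ValueError("form_bonds requires an accepted placement")
    p1, p2 = placement.pair
    lmol = placement.transformed_linker
    used_ph = {p1.placeholder, p2.placeholder}

    atoms: list[Atom] = []
    bonds: list[tuple[int, int, int]] = []
    maps: list[dict[int, int]] = []

    parts = []
    la1 = lmol.atoms[p1.anchor].position
    la2 = lmol.atoms[p2.anchor].position
    for mol, drop_ph, anchor, toward in (
        (frag1_pose.mol, placement.frag1_placeholder, placement.frag1_anchor, la1),
        (lmol, None, None, None),
        (frag2_pose.mol, placement.frag2_placeholder, placement.frag2_anchor, la2),
    ):
        drop = set()
        if mol is lmol:
            drop = set(used_ph)
        elif drop_ph is not None:
            drop = {drop_ph}
        else:
            h = _drop_directed_hydrogen(mol, anchor, toward)
            if h is not None:
                drop = {h}
        parts.append((mol, drop))

    for mol, drop in parts:
        amap: dict[int, int] = {}
        for i, atom in enumerate(mol.atoms):
            if i in drop:
                continue
            if atom.is_attachment_placeholder:
                # unused attachment point -> hydrogen cap
                amap[i] = len(atoms)
                atoms.append(Atom("H", atom.position.copy()))
                continue
            amap[i] = len(atoms)
            atoms.append(atom.copy())
        for a, b, o in mol.bonds:
            if a in amap and b in amap:
                bonds.append((amap[a], amap[b], o))
        maps.append(amap)

    m1, ml, m2 = maps
    bonds.append((m1[placement.frag1_anchor], ml[p1.anchor], 1))
    bonds.append((ml[p2.anchor], m2[placement.frag2_anchor], 1))

    name = (
        f"{frag1_pose.block_id}.p{frag1_pose.pose_index}"
        f"--{linker.linker_id}--{frag2_pose.block_id}.p{frag2_pose.pose_index}"
    )
    merged = Molecule3D(atoms, bonds, name=name)
    try:
        to_rdkit(merged)  # sanitization = valence check
        smiles = canonical_smiles(merged)
    except Exception as exc:
        return None, f"valence violation: {exc}"
    if len(merged.connected_components()) != 1:
        return None, "merged molecule not connected"
    merged.properties["ge_sum"] = ge_sum
    prov = Provenance(
        frag1_pose.block_id, frag1_pose.pose_index,
        frag2_pose.block_id, frag2_pose.pose_index,
        linker.linker_id, p1.placeholder, p2.placeholder,
    )
    return CandidateCompound(merged, smiles, ge_sum, [prov]), None


@dataclass
class AssemblyResult:
    candidates: list[CandidateCompound]
    attempts: int
    accepted: int
    rejections: list[dict]


def assemble_all(
    selected: PoseSet,
    linkers: Sequence[Linker],
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
) -> AssemblyResult:
    """Cartesian sweep: pocket-1 poses × pocket-2 poses × linkers × ordered pairs.

    Accepted placements are fused into candidates; the GE-sum of a candidate
    is the sum of its two fragment GE scores.  Duplicate structures (same
    canonical SMILES) are merged, keeping the maximum GE-sum and all
    provenances.
    """
    pocket1 = selected.poses("pocket1")
    pocket2 = selected.poses("pocket2")
    by_smiles: dict[str, CandidateCompound] = {}
    rejections: list[dict] = []
    attempts = accepted = 0
    for f1 in pocket1:
        ge1 = group_efficiency(f1.energy, heavy_atom_count(f1.mol))
        for f2 in pocket2:
            ge2 = group_efficiency(f2.energy, heavy_atom_count(f2.mol))
            for linker in linkers:
                for pair in enumerate_attachment_pairs(linker):
                    attempts += 1
                    placement = place_linker(linker, pair, f1, f2, gap_threshold)
                    if not placement.accepted:
                        rejections.append(_rejection(f1, f2, linker, pair, placement.gap, placement.reason))
                        continue
                    candidate, reason = form_bonds(f1, f2, linker, placement, ge_sum=ge1 + ge2)
                    if candidate is None:
                        rejections.append(_rejection(f1, f2, linker, pair, placement.gap, reason))
                        continue
                    accepted += 1
                    prior = by_smiles.get(candidate.smiles)
                    if prior is None:
                        by_smiles[candidate.smiles] = candidate
                    else:
                        prior.provenance.extend(candidate.provenance)
                        if candidate.ge_sum > prior.ge_sum:
                            prior.ge_sum = candidate.ge_sum
                            prior.mol.properties["ge_sum"] = candidate.ge_sum
    return AssemblyResult(list(by_smiles.values()), attempts, accepted, rejections)


def _rejection(f1, f2, linker, pair, gap, reason) -> dict:
    return {
        "frag1_block": f1.block_id, "frag1_pose": f1.pose_index,
        "frag2_block": f2.block_id, "frag2_pose": f2.pose_index,
        "linker_id": linker.linker_id,
        "point1": pair[0].placeholder, "point2": pair[1].placeholder,
        "gap": gap, "reason": reason,
    }
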