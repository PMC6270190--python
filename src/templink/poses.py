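"""Docked-pose ingestion, the pluggable docking-backend contract, and a
deterministic mock docker for fixtures (Step 2, input side).

Poses arrive either from files written by a docking program (SDF with an
energy data field, or multi-model PDBQT with Vina-style ``REMARK VINA
RESULT`` lines) or from :func:`mock_dock`, a seeded stand-in that produces
reproducible rigid-body placements with a documented toy energy.  Within a
building block, poses are ordered by ascending energy and truncated to
``max_poses`` (default 8 per block per region).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .chem import (
    Atom,
    Molecule3D,
    canonical_smiles,
    geometric_center,
    heavy_atom_count,
    read_structures,
)
from .template import GridBox, POCKETS

__all__ = [
    "DockedPose",
    "PoseSet",
    "load_poses",
    "mock_dock",
    "register_backend",
    "dock_with_backend",
    "possible_pose_count",
    "DEFAULT_MAX_POSES",
    "DEFAULT_ENERGY_TAG",
]

DEFAULT_MAX_POSES = 8
DEFAULT_ENERGY_TAG = "docking_energy"


@dataclass
class DockedPose:
    """One placed conformation of a building block with its docking energy."""

    block_id: str
    region: str
    pose_index: int
    mol: Molecule3D
    energy: float  # kcal/mol; <= 0 for binders

    def __post_init__(self) -> None:
        if self.region not in POCKETS:
            raise ValueError(f"pose region must be one of {POCKETS}, got {self.region!r}")
        if not math.isfinite(self.energy):
            raise ValueError(f"non-finite energy for block {self.block_id!r}")

    @property
    def is_binding(self) -> bool:
        return self.energy <= 0


@dataclass
class PoseSet:
    """Docked poses grouped by (region, block)."""

    max_poses: int = DEFAULT_MAX_POSES
    _groups: dict[tuple[str, str], list[DockedPose]] = field(default_factory=dict)

    def add(self, pose: DockedPose) -> None:
        group = self._groups.setdefault((pose.region, pose.block_id), [])
        if len(group) >= self.max_poses:
            raise ValueError(
                f"block {pose.block_id!r} already has {self.max_poses} poses in {pose.region}"
            )
        group.append(pose)

    def extend(self, poses: Iterable[DockedPose]) -> None:
        for p in poses:
            self.add(p)

    def poses(self, region: str | None = None) -> list[DockedPose]:
        keys = sorted(k for k in self._groups if region is None or k[0] == region)
        return [p for k in keys for p in self._groups[k]]

    def blocks(self, region: str) -> list[str]:
        return sorted(b for r, b in self._groups if r == region)

    def __len__(self) -> int:
        return sum(len(v) for v in self._groups.values())

    def __iter__(self):
        return iter(self.poses())


def possible_pose_count(n_blocks: int, max_poses: int = DEFAULT_MAX_POSES) -> int:
    """Upper bound on the pose count: every block yields ``max_poses`` poses."""
    return int(n_blocks) * int(max_poses)


# ---------------------------------------------------------------------------
# File import
# ---------------------------------------------------------------------------


def _finalize_groups(
    raw: dict[str, list[tuple[Molecule3D, float]]],
    region: str,
    max_poses: int,
    box: GridBox | None,
    box_tolerance: float,
    energy_window: float | None,
    library: Mapping[str, Molecule3D] | None,
) -> PoseSet:
    ps = PoseSet(max_poses=max_poses)
    for block_id in sorted(raw):
        entries = sorted(raw[block_id], key=lambda e: e[1])
        if library is not None:
            if block_id not in library:
                raise ValueError(f"pose block {block_id!r} not present in the library")
            ref = canonical_smiles(library[block_id])
            for mol, _ in entries:
                if canonical_smiles(mol) != ref:
                    raise ValueError(
                        f"pose graph mismatch for block {block_id!r} vs library structure"
                    )
        if box is not None:
            entries = [
                e for e in entries if box.contains(geometric_center(e[0]), box_tolerance)
            ]
        if energy_window is not None and entries:
            best = entries[0][1]
            entries = [e for e in entries if e[1] <= best + energy_window]
        for k, (mol, energy) in enumerate(entries[:max_poses], start=1):
            ps.add(DockedPose(block_id, region, k, mol, energy))
    return ps


def load_poses(
    path: str | Path,
    region: str,
    fmt: str | None = None,
    energy_tag: str = DEFAULT_ENERGY_TAG,
    max_poses: int = DEFAULT_MAX_POSES,
    box: GridBox | None = None,
    box_tolerance: float = 2.0,
    energy_window: float | None = None,
    library: Mapping[str, Molecule3D] | None = None,
) -> PoseSet:
    """Import docked poses for one region from an SDF or multi-model PDBQT.

    SDF records are grouped into blocks by molecule name and must carry the
    energy data field ``energy_tag``.  PDBQT files carry no bond graph, so
    ``library`` (block id → structure) is required for that format; model
    coordinates are applied to the library block's heavy atoms in file
    order.  Poses are sorted by ascending energy within a block, optionally
    restricted to ``box`` (with an overhang tolerance) and to an energy
    window above the best mode, then truncated to ``max_poses``.
    """
    path = Path(path)
    f = fmt.lower() if fmt else ("pdbqt" if path.suffix.lower() == ".pdbqt" else "sdf")
    raw: dict[str, list[tuple[Molecule3D, float]]] = {}
    if f == "sdf":
        for i, mol in enumerate(read_structures(path, fmt="sdf")):
            if energy_tag not in mol.properties:
                raise ValueError(
                    f"record {i} ({mol.name!r}) in {path} is missing energy tag {energy_tag!r}"
                )
            energy = float(mol.properties[energy_tag])
            block_id = mol.name or f"block{i}"
            raw.setdefault(block_id, []).append((mol, energy))
    elif f == "pdbqt":
        if library is None:
            raise ValueError("PDBQT pose import requires a reference library (no bond graph in PDBQT)")
        block_id = path.stem
        for i, (elements, coords, energy) in enumerate(_read_pdbqt_models(path)):
            if energy is None:
                raise ValueError(f"model {i + 1} in {path} has no VINA RESULT energy line")
            if block_id not in library:
                raise ValueError(f"pose block {block_id!r} not present in the library")
            mol = _apply_pdbqt_coords(library[block_id], elements, coords, block_id, i)
            raw.setdefault(block_id, []).append((mol, energy))
    else:
        raise ValueError(f"unsupported pose format: {fmt!r}")
    return _finalize_groups(
        raw, region, max_poses, box, box_tolerance, energy_window,
        library if f == "sdf" else None,
    )


# AutoDock atom types → element symbols (only types seen in small organics).
_AD_TYPE_MAP = {
    "A": "C", "C": "C", "N": "N", "NA": "N", "NS": "N", "OA": "O", "OS": "O",
    "S": "S", "SA": "S", "H": "H", "HD": "H", "HS": "H", "F": "F", "CL": "Cl",
    "BR": "Br", "I": "I", "P": "P",
}


def _read_pdbqt_models(path: Path) -> list[tuple[list[str], list[np.ndarray], float | None]]:
    models: list[tuple[list[str], list[np.ndarray], float | None]] = []
    elements: list[str] = []
    coords: list[np.ndarray] = []
    energy: float | None = None
    in_model = False
    for line in path.read_text().splitlines():
        tag = line[:6].strip()
        if tag == "MODEL":
            in_model = True
            elements, coords, energy = [], [], None
        elif tag == "ENDMDL":
            models.append((elements, coords, energy))
            in_model = False
        elif line.startswith("REMARK VINA RESULT"):
            energy = float(line.split(":", 1)[-1].split()[0])
        elif tag in ("ATOM", "HETATM"):
            x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
            ad_type = line[77:79].strip().upper() or line[12:16].strip()[:1]
            elements.append(_AD_TYPE_MAP.get(ad_type, ad_type.capitalize()))
            coords.append(np.array([x, y, z]))
    if in_model:
        models.append((elements, coords, energy))
    elif not models and elements:  # single model without MODEL/ENDMDL wrapper
        models.append((elements, coords, energy))
    return models


def _apply_pdbqt_coords(
    ref: Molecule3D,
    elements: list[str],
    coords: list[np.ndarray],
    block_id: str,
    model_index: int,
) -> Molecule3D:
    heavy = [(e, c) for e, c in zip(elements, coords) if e != "H"]
    ref_heavy = ref.heavy_indices()
    if [e for e, _ in heavy] != [ref.atoms[i].element for i in ref_heavy]:
        raise ValueError(
            f"pose graph mismatch for block {block_id!r} model {model_index + 1}: "
            "heavy-atom element sequence differs from the library structure"
        )
    mol = ref.copy()
    for (e, c), i in zip(heavy, ref_heavy):
        mol.atoms[i].position = c
    return mol


# ---------------------------------------------------------------------------
# Mock docking (deterministic fixture generator)
# ---------------------------------------------------------------------------


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def mock_energy(block: Molecule3D, box: GridBox, center: np.ndarray) -> float:
    """Toy docking energy: −0.5 × heavy atoms × (1 − |center − box center| / edge).

    More negative for larger blocks placed nearer the box center; always
    negative for placements inside the box (max offset = √3/2 · edge).
    """
    d = float(np.linalg.norm(np.asarray(center) - box.center_array))
    return -0.5 * heavy_atom_count(block) * (1.0 - d / box.edge)


def mock_dock(
    block: Molecule3D,
    box: GridBox,
    n_poses: int = DEFAULT_MAX_POSES,
    seed: int = 0,
    region: str = "pocket1",
    block_id: str | None = None,
) -> list[DockedPose]:
    """Deterministic rigid-body placements of ``block`` inside ``box``.

    For a fixed seed the placements and energies are exactly reproducible.
    Poses are returned sorted by ascending energy with 1-based indices.
    """
    if n_poses < 1:
        raise ValueError("n_poses must be >= 1")
    rng = np.random.default_rng(int(seed) % (2**31))
    block_id = block_id if block_id is not None else (block.name or "block")
    origin = geometric_center(block)
    placements = []
    for _ in range(n_poses):
        rot = _random_rotation(rng)
        center = box.center_array + rng.uniform(-box.edge / 2, box.edge / 2, size=3)
        mol = block.transformed(rot, origin).translated(center - origin)
        placements.append((mock_energy(block, box, center), mol))
    placements.sort(key=lambda e: e[0])
    return [
        DockedPose(block_id, region, k, mol, energy)
        for k, (energy, mol) in enumerate(placements, start=1)
    ]


# ---------------------------------------------------------------------------
# External docking-backend contract
# ---------------------------------------------------------------------------

_BACKENDS: dict[str, Callable] = {}


def register_backend(name: str, fn: Callable) -> None:
    """Register a docking callable ``fn(block, box, settings) -> iterable``.

    Each yielded item is either a :class:`DockedPose` or a
    ``(Molecule3D, energy)`` pair.
    """
    _BACKENDS[name] = fn


def dock_with_backend(
    name: str,
    block: Molecule3D,
    box: GridBox,
    settings: Mapping | None = None,
    region: str = "pocket1",
    block_id: str | None = None,
    max_poses: int = DEFAULT_MAX_POSES,
) -> list[DockedPose]:
    """Run a registered backend and normalize its output into poses."""
    if name not in _BACKENDS:
        raise KeyError(f"no docking backend registered under {name!r}")
    block_id = block_id if block_id is not None else (block.name or "block")
    try:
        results = list(_BACKENDS[name](block, box, settings or {}))
    except Exception as exc:
        raise RuntimeError(f"docking backend {name!r} failed for block {block_id!r}: {exc}") from exc
    entries = []
    for item in results:
        if isinstance(item, DockedPose):
            entries.append((item.energy, item.mol))
        else:
            mol, energy = item
            entries.append((float(energy), mol))
    entries.sort(key=lambda e: e[0])
    return [
        DockedPose(block_id, region, k, mol, energy)
        for k, (energy, mol) in enumerate(entries[:max_poses], start=1)
    ]
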