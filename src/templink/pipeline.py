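"""End-to-end orchestration of the five-step design protocol, plus a
seeded synthetic building-block / linker library generator for fixtures
and demonstration runs.

The pipeline: decompose the template → acquire docked poses per region
(imported files, the deterministic mock docker, or a registered external
backend) → score poses by group efficiency and select template-relative
survivors → splice every surviving pocket-1/pocket-2 pose pair with every
linker attachment-point pair → drug-likeness and stability filters → rank
by GE-sum.  A fixed seed makes the whole run reproducible.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import chem
from .assemble import AssemblyResult, Linker, assemble_all, DEFAULT_GAP_THRESHOLD
from .chem import Molecule3D, from_smiles, write_structures
from .filters import FilterConfig, apply_filters, rank_candidates, ranked_table
from .ge import ge_table, select_poses, template_criteria
from .poses import (
    DEFAULT_MAX_POSES,
    DockedPose,
    PoseSet,
    dock_with_backend,
    load_poses,
    mock_dock,
    possible_pose_count,
)
from .template import CutSpec, GridBox, TemplateDecomposition, decompose_template, region_box

__all__ = [
    "RunConfig",
    "RunReport",
    "run_design",
    "generate_synthetic_library",
    "write_synthetic_library",
]


# ---------------------------------------------------------------------------
# Synthetic library generation
# ---------------------------------------------------------------------------

# Common medicinal-chemistry ring fragments and small polar building blocks.
BLOCK_SMILES_POOL: tuple[str, ...] = (
    "c1ccccc1", "Cc1ccccc1", "c1ccncc1", "c1cncnc1", "Nc1ccccc1",
    "Oc1ccccc1", "c1c[nH]cn1", "Cn1ccnc1", "c1ccoc1", "c1ccsc1",
    "c1ccc2[nH]ccc2c1", "c1ccc2ccccc2c1", "c1ccc2ncccc2c1", "C1COCCN1",
    "C1CCNCC1", "C1CNCCN1", "C1CCCCC1", "c1cc[nH]n1", "c1ocnc1",
    "NC(=O)c1ccccc1", "CC(=O)c1ccccc1", "OC(=O)c1ccccc1", "COc1ccccc1",
    "Fc1ccccc1", "Clc1ccccc1", "N#Cc1ccccc1", "c1cc[nH]c1", "C1CCOC1",
    "CNC(=O)c1ccccn1", "Nc1ncccn1", "CC(C)c1ccccc1", "OCc1ccccc1",
)

# Linker SMILES grouped by attachment-point count (dummy atoms = points).
LINKER_SMILES_POOL: Mapping[int, tuple[str, ...]] = {
    2: ("*CC*", "*C=C*", "*C(=O)N*", "*c1ccc(*)cc1", "*CN*", "*CCC*", "*COC*"),
    3: ("*c1ccc(*)c(*)c1", "*c1cc(*)cc(*)c1", "*C(*)C*", "*N(*)C(=O)*", "*C(*)CC*"),
    4: ("*C(*)C(*)*", "*C(*)(*)C*", "*c1cc(*)c(*)cc1*"),
}
# Attachment-count mix averaging three bonding locations per linker.
LINKER_POINT_WEIGHTS: Mapping[int, float] = {2: 0.2, 3: 0.6, 4: 0.2}


def generate_synthetic_library(
    n_blocks: int,
    n_linkers: int,
    seed: int,
    decomp: TemplateDecomposition | None = None,
) -> tuple[list[Molecule3D], list[Linker]]:
    """Seeded library of small 3D building blocks and multi-point linkers.

    When a template decomposition is supplied, its own pocket fragments are
    appended to the blocks and its linker piece to the linkers, so the
    template is always reconstructible from the library.
    """
    if n_blocks < 1 or n_linkers < 1:
        raise ValueError("n_blocks and n_linkers must be >= 1")
    rng = np.random.default_rng(int(seed) % (2**31))
    blocks: list[Molecule3D] = []
    for i in range(n_blocks):
        smiles = BLOCK_SMILES_POOL[int(rng.integers(len(BLOCK_SMILES_POOL)))]
        embed_seed = int(rng.integers(1, 2**31 - 1))
        blocks.append(from_smiles(smiles, name=f"block_{i:04d}", seed=embed_seed))
    counts = sorted(LINKER_POINT_WEIGHTS)
    weights = np.array([LINKER_POINT_WEIGHTS[c] for c in counts], dtype=float)
    weights /= weights.sum()
    linkers: list[Linker] = []
    for i in range(n_linkers):
        n_points = int(rng.choice(counts, p=weights))
        pool = LINKER_SMILES_POOL[n_points]
        smiles = pool[int(rng.integers(len(pool)))]
        embed_seed = int(rng.integers(1, 2**31 - 1))
        mol = from_smiles(smiles, name=f"linker_{i:02d}", seed=embed_seed)
        linkers.append(Linker(mol, linker_id=mol.name))
    if decomp is not None:
        tname = decomp.template.name or "template"
        for region, suffix in (("pocket1", "fragment1"), ("pocket2", "fragment2")):
            frag = decomp.fragments[region].mol.copy()
            frag.name = f"{tname}_{suffix}"
            blocks.append(frag)
        lmol = decomp.linker_piece.mol.copy()
        lmol.name = f"{tname}_linker"
        linkers.append(Linker(lmol, linker_id=lmol.name))
    return blocks, linkers


def write_synthetic_library(
    blocks: Sequence[Molecule3D],
    linkers: Sequence[Linker],
    out_dir: str | Path,
) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blocks_path = out_dir / "blocks.sdf"
    linkers_path = out_dir / "linkers.sdf"
    write_structures(blocks, blocks_path)
    write_structures([lk.mol for lk in linkers], linkers_path)
    return blocks_path, linkers_path


# ---------------------------------------------------------------------------
# Run configuration and report
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything a full design run needs.

    ``cut_bonds`` and ``region_labels`` use 0-based atom indices at the API
    level; the YAML loader accepts the 1-based indices as written in an SDF
    and converts.  Exactly one pose source applies: ``files`` (per-region
    pose paths), ``mock`` (the seeded fixture docker), or the name of a
    registered external backend.
    """

    template_path: str
    cut_bonds: tuple[tuple[int, int], ...]
    template_energies: Mapping[str, float]
    region_labels: Mapping[str, int] | None = None
    pose_source: str = "mock"
    pose_paths: Mapping[str, str] | None = None
    blocks_path: str | None = None
    linkers_path: str | None = None
    n_blocks: int = 25
    n_linkers: int = 6
    seed: int = 0
    max_poses: int = DEFAULT_MAX_POSES
    box_edge: float = 10.0
    gap_threshold: float = DEFAULT_GAP_THRESHOLD
    energy_tag: str = "docking_energy"
    energy_window: float | None = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cuts = tuple((int(i) - 1, int(j) - 1) for i, j in raw.pop("cut_bonds"))
        labels = raw.pop("region_labels", None)
        if labels is not None:
            labels = {k: int(v) - 1 for k, v in labels.items()}
        fc_raw = raw.pop("filters", {})
        fc = FilterConfig(**fc_raw) if fc_raw else FilterConfig()
        return cls(cut_bonds=cuts, region_labels=labels, filter_config=fc, **raw)


@dataclass
class RunReport:
    """Per-stage counts and output locations for one design run."""

    seed: int
    n_blocks: int
    n_linkers: int
    possible_poses: int
    poses: dict[str, int]
    selected: dict[str, int]
    placements_attempted: int
    placements_accepted: int
    candidates_unique: int
    after_filters: int
    criteria: dict
    template_rank: int | None = None
    elapsed_s: float = 0.0
    outputs: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


# ---------------------------------------------------------------------------
# The five-step run
# ---------------------------------------------------------------------------


def _acquire_poses(
    cfg: RunConfig,
    blocks: Sequence[Molecule3D],
    decomp: TemplateDecomposition,
    boxes: Mapping[str, GridBox],
) -> PoseSet:
    pose_set = PoseSet(max_poses=cfg.max_poses)
    library = {b.name: b for b in blocks}
    template_blocks = {
        "pocket1": f"{decomp.template.name or 'template'}_fragment1",
        "pocket2": f"{decomp.template.name or 'template'}_fragment2",
    }
    if cfg.pose_source == "files":
        if not cfg.pose_paths:
            raise ValueError("pose_source 'files' requires pose_paths for both pockets")
        for region in ("pocket1", "pocket2"):
            loaded = load_poses(
                cfg.pose_paths[region],
                region,
                energy_tag=cfg.energy_tag,
                max_poses=cfg.max_poses,
                energy_window=cfg.energy_window,
            )
            pose_set.extend(loaded)
    elif cfg.pose_source == "mock":
        for region in ("pocket1", "pocket2"):
            box = boxes[region]
            for idx, block in enumerate(blocks):
                block_seed = (cfg.seed * 1_000_003 + idx * 97 + (0 if region == "pocket1" else 1)) % (2**31)
                n_mock = cfg.max_poses
                injected: list[DockedPose] = []
                if block.name == template_blocks[region]:
                    # the template's own fragment keeps its template pose
                    injected = [
                        DockedPose(block.name, region, 1, decomp.fragments[region].mol.copy(),
                                   float(cfg.template_energies[region]))
                    ]
                    n_mock -= 1
                mock = mock_dock(block, box, n_poses=n_mock, seed=block_seed,
                                 region=region, block_id=block.name)
                ordered = sorted(injected + mock, key=lambda p: p.energy)
                for k, p in enumerate(ordered, start=1):
                    pose_set.add(DockedPose(p.block_id, region, k, p.mol, p.energy))
    else:  # registered external backend
        for region in ("pocket1", "pocket2"):
            for block in blocks:
                pose_set.extend(
                    dock_with_backend(
                        cfg.pose_source, block, boxes[region],
                        region=region, block_id=block.name, max_poses=cfg.max_poses,
                    )
                )
    return pose_set


def run_design(cfg: RunConfig) -> RunReport:
    """Execute decompose → poses → GE selection → assembly → filters → ranking."""
    t0 = time.perf_counter()

    # Step 1: template dissection and search regions
    template = chem.read_structures(cfg.template_path)[0]
    decomp = decompose_template(template, CutSpec(cfg.cut_bonds, cfg.region_labels))
    boxes = {
        "pocket1": region_box(decomp.fragment1, cfg.box_edge),
        "pocket2": region_box(decomp.fragment2, cfg.box_edge),
    }

    # library
    if cfg.blocks_path:
        blocks = chem.read_structures(cfg.blocks_path, seed=cfg.seed)
        linkers = [Linker(m) for m in chem.read_structures(cfg.linkers_path, seed=cfg.seed)]
    else:
        blocks, linkers = generate_synthetic_library(cfg.n_blocks, cfg.n_linkers, cfg.seed, decomp)

    # Step 2: poses + GE selection
    pose_set = _acquire_poses(cfg, blocks, decomp, boxes)
    criteria = template_criteria(decomp, cfg.template_energies)
    selected = select_poses(pose_set, criteria)

    # Step 3: assembly
    assembly: AssemblyResult = assemble_all(selected, linkers, cfg.gap_threshold)

    # Steps 4-5: filters and ranking
    survivors, _removed = apply_filters(assembly.candidates, cfg.filter_config)
    ranked = rank_candidates(survivors)

    template_smiles = chem.canonical_smiles(template)
    template_rank = next((c.rank for c in ranked if c.smiles == template_smiles), None)

    outputs: dict[str, str] = {}
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ge_table(pose_set, criteria, out / "ge_scores.tsv")
        if ranked:
            write_structures([c.mol for c in ranked], out / "candidates.sdf")
        ranked_table(ranked, out / "ranked.tsv")
        import pandas as pd

        pd.DataFrame(assembly.rejections).to_csv(out / "rejections.tsv", sep="\t", index=False)
        outputs = {
            "ge_scores": str(out / "ge_scores.tsv"),
            "candidates": str(out / "candidates.sdf"),
            "ranked": str(out / "ranked.tsv"),
            "rejections": str(out / "rejections.tsv"),
        }

    report = RunReport(
        seed=cfg.seed,
        n_blocks=len(blocks),
        n_linkers=len(linkers),
        possible_poses=possible_pose_count(len(blocks), cfg.max_poses),
        poses={r: len(pose_set.poses(r)) for r in ("pocket1", "pocket2")},
        selected={r: len(selected.poses(r)) for r in ("pocket1", "pocket2")},
        placements_attempted=assembly.attempts,
        placements_accepted=assembly.accepted,
        candidates_unique=len(assembly.candidates),
        after_filters=len(ranked),
        criteria={
            "ge_min": dict(criteria.ge_min),
            "energy_max": dict(criteria.energy_max),
        },
        template_rank=template_rank,
        elapsed_s=time.perf_counter() - t0,
        outputs=outputs,
    )
    if cfg.out_dir:
        report.save(Path(cfg.out_dir) / "report.json")
    return report
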