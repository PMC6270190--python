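"""Group-efficiency scoring and the dual template-relative selection rule.

Group efficiency (GE) is the binding-energy contribution of a fragment per
non-hydrogen (heavy) atom.  With docking energies negative for binders, GE
is stored as −E/N so favorable poses score positive (a nilotinib ATP-site
fragment at −7.8 kcal/mol over 13 heavy atoms scores 0.60).  Printed GE
values are display-rounded to two decimals, half away from zero; all
comparisons use the unrounded value.

Selection is template-relative and dual: a docked fragment pose survives
only if its GE is at least the template fragment's GE for that region AND
its docking energy is at least as negative — both comparisons inclusive,
so the template's own fragments always survive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .chem import heavy_atom_count
from .poses import DockedPose, PoseSet
from .template import POCKETS, TemplateDecomposition

__all__ = [
    "GERecord",
    "SelectionCriteria",
    "group_efficiency",
    "display_ge",
    "score_poses",
    "template_criteria",
    "select_poses",
    "ge_table",
]


def group_efficiency(energy: float, n_heavy: int) -> float:
    """GE = −energy / n_heavy (kcal/mol per heavy atom, positive for binders)."""
    if n_heavy < 1:
        raise ValueError(f"group efficiency undefined for n_heavy={n_heavy}")
    return -float(energy) / int(n_heavy)


def display_ge(ge: float, ndigits: int = 2) -> float:
    """Round half away from zero for display (e.g. −6.6/17 = 0.388 → 0.39)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(ge))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GERecord:
    """GE score of one docked pose."""

    block_id: str
    region: str
    pose_index: int
    energy: float
    n_heavy: int
    ge: float
    selected: bool | None = None


def score_poses(pose_set: PoseSet | Iterable[DockedPose]) -> list[GERecord]:
    """GE records for every pose (heavy atoms counted on the posed structure)."""
    out = []
    for p in pose_set:
        n = heavy_atom_count(p.mol)
        out.append(GERecord(p.block_id, p.region, p.pose_index, p.energy, n, group_efficiency(p.energy, n)))
    return out


@dataclass(frozen=True)
class SelectionCriteria:
    """Per-region GE and energy thresholds taken from the template fragments."""

    ge_min: Mapping[str, float]
    energy_max: Mapping[str, float]

    def __post_init__(self) -> None:
        for region in self.ge_min:
            if region not in POCKETS:
                raise ValueError(f"unknown region {region!r}")


def template_criteria(
    decomp: TemplateDecomposition,
    template_energies: Mapping[str, float],
) -> SelectionCriteria:
    """Thresholds from the template fragments' docking energies.

    ``template_energies`` maps ``pocket1``/``pocket2`` to the docking
    energy (kcal/mol) of the corresponding template fragment.
    """
    ge_min: dict[str, float] = {}
    energy_max: dict[str, float] = {}
    for region in POCKETS:
        if region not in template_energies:
            raise ValueError(f"missing template fragment energy for region {region!r}")
        energy = float(template_energies[region])
        n = heavy_atom_count(decomp.fragments[region].mol)
        ge_min[region] = group_efficiency(energy, n)
        energy_max[region] = energy
    return SelectionCriteria(ge_min=ge_min, energy_max=energy_max)


def pose_passes(pose: DockedPose, criteria: SelectionCriteria) -> bool:
    n = heavy_atom_count(pose.mol)
    ge = group_efficiency(pose.energy, n)
    return ge >= criteria.ge_min[pose.region] and pose.energy <= criteria.energy_max[pose.region]


def select_poses(pose_set: PoseSet, criteria: SelectionCriteria) -> PoseSet:
    """Keep poses meeting both thresholds (inclusive) for their region."""
    out = PoseSet(max_poses=pose_set.max_poses)
    for pose in pose_set:
        if pose_passes(pose, criteria):
            out.add(pose)
    return out


def ge_table(
    pose_set: PoseSet,
    criteria: SelectionCriteria | None = None,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Tabulate GE records (optionally with the selected flag); write TSV if asked."""
    rows = []
    for rec in score_poses(pose_set):
        row = {
            "block_id": rec.block_id,
            "region": rec.region,
            "pose_index": rec.pose_index,
            "energy": rec.energy,
            "n_heavy": rec.n_heavy,
            "ge": rec.ge,
            "ge_display": display_ge(rec.ge),
        }
        if criteria is not None:
            row["selected"] = (
                rec.ge >= criteria.ge_min[rec.region]
                and rec.energy <= criteria.energy_max[rec.region]
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
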