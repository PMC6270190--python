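"""Drug-likeness and stability filters (Step 4) and GE-sum ranking (Step 5).

The drug-likeness filter is a modified Rule-of-Five: molecular weight at
most 550 g/mol (raised from Lipinski's 500), at most 5 H-bond donors, 10
N/O acceptors and logP 5 — all bounds inclusive.  By default every rule
must pass (the filter removes violators outright); ``max_violations=1``
restores Lipinski's classic "at most one violation" reading.  A second
filter removes candidates containing unstable, synthetically improbable
substructures (peroxides, contiguous N–N–N chains, heteroatom–halogen
bonds, orthoesters, aminals, hemiacetals, acyl halides, geminal diols);
the SMARTS list is configurable.

Surviving candidates are ranked by descending GE-sum (more positive =
better predicted binding), ties broken by ascending molecular weight and
then canonical SMILES, with 1-based ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem

from .assemble import CandidateCompound
from .chem import (
    count_hbond_acceptors,
    count_hbond_donors,
    estimate_logp,
    molecular_weight,
    to_rdkit,
)

__all__ = [
    "FilterConfig",
    "FilterOutcome",
    "DEFAULT_UNSTABLE_PATTERNS",
    "drug_likeness_filter",
    "unstable_bond_filter",
    "apply_filters",
    "rank_candidates",
    "ranked_table",
]

# name -> SMARTS; chemically fragile motifs a chemist would not try to make
DEFAULT_UNSTABLE_PATTERNS: tuple[tuple[str, str], ...] = (
    ("peroxide", "[OX2][OX2]"),
    ("triazane_chain", "[#7][#7][#7]"),
    ("heteroatom_halogen", "[N,O,S]~[F,Cl,Br,I]"),
    ("orthoester", "[CX4]([OX2])([OX2])[OX2]"),
    ("aminal", "[NX3][CX4][NX3]"),
    ("hemiacetal", "[OX2H][CX4][OX2]"),
    ("acyl_halide", "[CX3](=O)[F,Cl,Br,I]"),
    ("geminal_diol", "[OX2H][CX4][OX2H]"),
)


@dataclass
class FilterConfig:
    """Thresholds for the modified Rule-of-Five plus the unstable-motif list."""

    mw_max: float = 550.0  # g/mol; the modification relative to classic Ro5
    hbd_max: int = 5
    hba_max: int = 10
    logp_max: float = 5.0
    max_violations: int = 0  # 0 = strict removal filter; 1 = classic Ro5
    unstable_patterns: Sequence[tuple[str, str]] = DEFAULT_UNSTABLE_PATTERNS
    _compiled: list[tuple[str, Chem.Mol]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        for bound in (self.mw_max, self.hbd_max, self.hba_max, self.logp_max):
            if not bound > 0:
                raise ValueError("filter thresholds must be positive")
        self._compiled = []
        for name, smarts in self.unstable_patterns:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"unparseable SMARTS for pattern {name!r}: {smarts!r}")
            self._compiled.append((name, patt))

    @property
    def compiled_patterns(self) -> list[tuple[str, Chem.Mol]]:
        return self._compiled


@dataclass
class FilterOutcome:
    passed: bool
    failed_rules: list[str]
    descriptors: dict


def drug_likeness_filter(c: CandidateCompound, cfg: FilterConfig | None = None) -> FilterOutcome:
    """Modified Rule-of-Five with all failed rules listed."""
    cfg = cfg or FilterConfig()
    try:
        desc = {
            "mw": molecular_weight(c.mol),
            "hbd": count_hbond_donors(c.mol),
            "hba": count_hbond_acceptors(c.mol),
            "logp": estimate_logp(c.mol),
        }
    except Exception as exc:  # descriptor failure: flag, never silently drop
        return FilterOutcome(False, [f"descriptor_error: {exc}"], {})
    failed = []
    if desc["mw"] > cfg.mw_max:
        failed.append("MW")
    if desc["hbd"] > cfg.hbd_max:
        failed.append("HBD")
    if desc["hba"] > cfg.hba_max:
        failed.append("HBA")
    if desc["logp"] > cfg.logp_max:
        failed.append("logP")
    return FilterOutcome(len(failed) <= cfg.max_violations, failed, desc)


def unstable_bond_filter(
    c: CandidateCompound, patterns: Sequence[tuple[str, str]] | FilterConfig | None = None
) -> FilterOutcome:
    """Fail when any unstable-substructure SMARTS matches."""
    if isinstance(patterns, FilterConfig):
        compiled = patterns.compiled_patterns
    else:
        compiled = FilterConfig(
            unstable_patterns=DEFAULT_UNSTABLE_PATTERNS if patterns is None else tuple(patterns)
        ).compiled_patterns
    mol = to_rdkit(c.mol)
    matched = [name for name, patt in compiled if mol.HasSubstructMatch(patt)]
    return FilterOutcome(not matched, matched, {})


def apply_filters(
    candidates: Iterable[CandidateCompound], cfg: FilterConfig | None = None
) -> tuple[list[CandidateCompound], list[CandidateCompound]]:
    """Annotate filter flags; return (survivors, removed).

    The two filters are independent predicates, so the surviving set does
    not depend on the order they are applied in.
    """
    cfg = cfg or FilterConfig()
    survivors, removed = [], []
    for c in candidates:
        dl = drug_likeness_filter(c, cfg)
        us = unstable_bond_filter(c, cfg)
        c.filter_flags = {
            "drug_likeness": dl.passed,
            "failed_rules": list(dl.failed_rules),
            "unstable": not us.passed,
            "unstable_matches": list(us.failed_rules),
            **dl.descriptors,
        }
        (survivors if dl.passed and us.passed else removed).append(c)
    return survivors, removed


def rank_candidates(candidates: Iterable[CandidateCompound]) -> list[CandidateCompound]:
    """Descending GE-sum; ties by ascending MW, then canonical SMILES."""
    cs = list(candidates)
    for c in cs:
        if "mw" not in c.filter_flags:
            c.filter_flags["mw"] = molecular_weight(c.mol)
    ordered = sorted(cs, key=lambda c: (-c.ge_sum, c.filter_flags["mw"], c.smiles))
    for rank, c in enumerate(ordered, start=1):
        c.rank = rank
    return ordered


def ranked_table(
    candidates: Sequence[CandidateCompound], path: str | Path | None = None
) -> pd.DataFrame:
    """Tabulate ranked candidates; write TSV when a path is given."""
    rows = []
    for c in candidates:
        rows.append(
            {
                "rank": c.rank,
                "candidate": c.mol.name,
                "smiles": c.smiles,
                "ge_sum": c.ge_sum,
                "mw": c.filter_flags.get("mw"),
                "hbd": c.filter_flags.get("hbd"),
                "hba": c.filter_flags.get("hba"),
                "logp": c.filter_flags.get("logp"),
                "n_provenances": len(c.provenance),
            }
        )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
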