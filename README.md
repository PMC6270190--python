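# templink

Template-based fragment linking for two-pocket inhibitor design.

Type II kinase inhibitors such as sorafenib and nilotinib span two adjacent
pockets of the inactive (DFG-out) kinase: the ATP site and an allosteric
site, joined by a short linker. `templink` implements a five-step protocol
that uses such a known inhibitor as a template to generate new candidates
that preserve its binding interactions:

1. **Dissect** the template at two acyclic single bonds into *fragment 1*
   (pocket 1), the *linker*, and *fragment 2* (pocket 2); each pocket
   fragment defines a cubic 10 Å search region centered on its geometric
   center.
2. **Score** docked building-block poses in each region by **group
   efficiency** — the docking energy per non-hydrogen atom,

   GE = −ΔG / N<sub>heavy</sub>  (kcal/mol per heavy atom),

   and keep only poses whose GE is at least the template fragment's GE
   *and* whose docking energy is at least as negative (both inclusive).
   Poses come from docking output files (SDF with an energy tag, or
   Vina-style multi-model PDBQT), from a deterministic seeded mock docker,
   or from a user-registered docking backend.
3. **Splice** every surviving pocket-1/pocket-2 pose pair with every linker
   attachment-point pair: translate the linker so its first attachment
   point sits on fragment 1's attachment site, rotate it (Rodrigues) so the
   inter-point direction matches the site-to-site direction, and accept the
   placement when the residual gap is below 0.1 Å.
4. **Filter** assembled candidates by a modified Rule-of-Five (MW ≤ 550
   g/mol, HBD ≤ 5, HBA ≤ 10, logP ≤ 5) and a blacklist of unstable
   substructures (peroxides, acyl halides, geminal diols, …).
5. **Rank** survivors by the sum of their two fragment GE scores,
   descending.

Because selection is inclusive, the template's own fragments always
survive, the template is always regenerated — and, having the weakest
admissible fragments, it ranks *last* among the survivors. This closure
property is the protocol's built-in sanity check and is exercised in the
test suite.

The package is aimed at computational medicinal chemists prototyping
fragment-linking workflows; it deliberately stops at the geometry/scoring
layer (no bundled docking engine, no force-field refinement).

## Worked example

```python
from templink import (CutSpec, DockedPose, Linker, decompose_template,
                      display_ge, enumerate_attachment_pairs, from_smiles,
                      group_efficiency, heavy_atom_count, place_linker,
                      form_bonds, canonical_smiles)

# group efficiency of the nilotinib ATP-site fragment: -7.8 kcal/mol, 13 atoms
frag1 = from_smiles("Nc1nccc(-c2cccnc2)n1", embed=False)
print(heavy_atom_count(frag1))                               # 13
print(display_ge(group_efficiency(-7.8, 13)))                # 0.6

# dissect sorafenib at the aryl-ether and urea-aryl bonds
sora = from_smiles("CNC(=O)c1cc(Oc2ccc(NC(=O)Nc3ccc(Cl)c(C(F)(F)F)c3)cc2)ccn1",
                   name="sorafenib", seed=42)
d = decompose_template(sora, CutSpec(((7, 8), (11, 12))))
print([heavy_atom_count(f.mol) for f in d.fragments.values()])  # [11, 6, 15]

# splice the template's own pieces back together
f1 = DockedPose("f1", "pocket1", 1, d.fragment1.mol, -5.1)
f2 = DockedPose("f2", "pocket2", 1, d.fragment2.mol, -6.1)
lk = Linker(d.linker_piece.mol, "phenylene")
pl = next(p for pair in enumerate_attachment_pairs(lk)
          if (p := place_linker(lk, pair, f1, f2)).accepted)
print(round(pl.gap, 6))                                      # 0.0
cand, _ = form_bonds(f1, f2, lk, pl, ge_sum=5.1/11 + 6.1/15)
print(cand.smiles == canonical_smiles(sora))                 # True
```

The fragment GE scores printed here (0.60 for the nilotinib ATP-site
fragment; thresholds 0.46 and 0.41 for the two sorafenib fragments at
−5.1/−6.1 kcal/mol) are the selection criteria a library pose must meet or
beat, and the zero gap shows the template linker splicing its own
fragments exactly.

A full pipeline run is one call (or `templink run --config run.yaml`):

```python
from templink import RunConfig, run_design, FilterConfig
report = run_design(RunConfig(
    template_path="template.sdf",
    cut_bonds=((7, 8), (11, 12)),
    template_energies={"pocket1": -5.1, "pocket2": -6.1},
    pose_source="mock", n_blocks=10, n_linkers=4, seed=3,
    filter_config=FilterConfig(max_violations=1),
    out_dir="out",
))
print(report.template_rank, report.after_filters)
```

The report records per-stage counts (poses, selected per region,
placements attempted/accepted, unique candidates, survivors) and the
template's rank; `out/` receives the GE table, the ranked candidate TSV,
the candidate SDF and a rejection log.

## Command-line interface

`templink` exposes `decompose`, `score`, `assemble`, `filter`, `rank`,
`synth` (seeded synthetic block/linker library) and `run` (full pipeline
from YAML). See `templink --help`.
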