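"""Shared fixtures: a 3D sorafenib template, its dissection, and a small
controlled library that can reassemble it alongside strictly better
variants (for the template-ranks-last closure checks)."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import RDLogger

from templink import (
    Atom,
    CutSpec,
    DockedPose,
    Linker,
    Molecule3D,
    decompose_template,
    from_smiles,
    write_structures,
)

RDLogger.DisableLog("rdApp.*")

SORAFENIB_SMILES = "CNC(=O)c1cc(Oc2ccc(NC(=O)Nc3ccc(Cl)c(C(F)(F)F)c3)cc2)ccn1"
# cuts at the aryl ether O-C bond and the urea N-aryl bond of the central
# phenylene (0-based indices in the SMILES atom order above)
SORAFENIB_CUTS = CutSpec(((7, 8), (11, 12)))
SORAFENIB_ENERGIES = {"pocket1": -5.1, "pocket2": -6.1}


@pytest.fixture(scope="session")
def sorafenib():
    return from_smiles(SORAFENIB_SMILES, name="sorafenib", seed=42)


@pytest.fixture(scope="session")
def sorafenib_decomp(sorafenib):
    return decompose_template(sorafenib, SORAFENIB_CUTS)


def heavy_substituted_variant(mol: Molecule3D, anchors, element="C", name="variant"):
    """Copy a fragment, mutating one H (on a non-anchor heavy atom) into a
    heavy substituent — a strictly larger fragment with identical anchor
    geometry, so it splices exactly like the original."""
    out = mol.copy()
    anchors = set(anchors)
    for i, atom in enumerate(out.atoms):
        if atom.is_hydrogen:
            (nbr,) = out.neighbors(i) or (None,)
            if nbr is not None and out.atoms[nbr].is_heavy and nbr not in anchors:
                out.atoms[i] = Atom(element, atom.position.copy())
                out.name = name
                return out
    raise AssertionError("fragment has no substitutable hydrogen")


@pytest.fixture(scope="session")
def closure_poses(sorafenib_decomp):
    """DockedPoses for the template fragments plus one better variant per
    pocket, all at template coordinates (identical anchors)."""
    d = sorafenib_decomp
    v1 = heavy_substituted_variant(d.fragment1.mol, d.fragment1.attachment_atoms, name="variant1")
    v2 = heavy_substituted_variant(d.fragment2.mol, d.fragment2.attachment_atoms, name="variant2")
    f1 = d.fragment1.mol.copy()
    f1.name = "sorafenib_fragment1"
    f2 = d.fragment2.mol.copy()
    f2.name = "sorafenib_fragment2"
    return {
        "pocket1": [
            DockedPose("sorafenib_fragment1", "pocket1", 1, f1, -5.1),
            DockedPose("variant1", "pocket1", 1, v1, -5.6),
        ],
        "pocket2": [
            DockedPose("sorafenib_fragment2", "pocket2", 1, f2, -6.1),
            DockedPose("variant2", "pocket2", 1, v2, -6.6),
        ],
    }


@pytest.fixture(scope="session")
def closure_linkers(sorafenib_decomp):
    lmol = sorafenib_decomp.linker_piece.mol.copy()
    lmol.name = "sorafenib_linker"
    ethyl = from_smiles("*CC*", name="ethyl_linker", seed=11)
    return [Linker(lmol, "sorafenib_linker"), Linker(ethyl, "ethyl_linker")]


@pytest.fixture()
def closure_files(tmp_path, sorafenib, closure_poses, closure_linkers):
    """On-disk version of the closure library (template, pose SDFs, linkers)."""
    paths = {"template": tmp_path / "template.sdf"}
    write_structures([sorafenib], paths["template"])
    for region in ("pocket1", "pocket2"):
        mols = []
        for pose in closure_poses[region]:
            m = pose.mol.copy()
            m.name = pose.block_id
            m.properties["docking_energy"] = pose.energy
            mols.append(m)
        paths[region] = tmp_path / f"poses_{region}.sdf"
        write_structures(mols, paths[region])
    paths["blocks"] = tmp_path / "blocks.sdf"
    write_structures(
        [p.mol for region in ("pocket1", "pocket2") for p in closure_poses[region]],
        paths["blocks"],
    )
    paths["linkers"] = tmp_path / "linkers.sdf"
    write_structures([lk.mol for lk in closure_linkers], paths["linkers"])
    return paths


def toy_fragment(anchor_pos, direction, name="frag", extra=0):
    """Minimal annotated fragment: anchor carbon + placeholder 1.5 Å along
    ``direction`` (+ optional padding carbons away from the anchor)."""
    anchor_pos = np.asarray(anchor_pos, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    atoms = [Atom("C", anchor_pos), Atom("*", anchor_pos + 1.5 * direction)]
    bonds = [(0, 1, 1)]
    for k in range(extra):
        atoms.append(Atom("C", anchor_pos - 1.5 * (k + 1) * direction))
        prev = 0 if k == 0 else len(atoms) - 2
        bonds.append((prev, len(atoms) - 1, 1))
    return Molecule3D(atoms, bonds, name=name)


def toy_linker(length, direction=(0.0, 1.0, 0.0), name="toylinker"):
    """Two-point linker whose attachment placeholders are ``length`` Å apart."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    atoms = [
        Atom("*", np.zeros(3)),
        Atom("C", 1.0 * d),
        Atom("C", (length - 1.0) * d),
        Atom("*", length * d),
    ]
    bonds = [(0, 1, 1), (1, 2, 1), (2, 3, 1)]
    return Linker(Molecule3D(atoms, bonds, name=name), name)
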