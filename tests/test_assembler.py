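"""Linker placement geometry, bond formation, and the assembly sweep."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from templink import (
    Atom,
    DockedPose,
    Linker,
    Molecule3D,
    PoseSet,
    assemble_all,
    enumerate_attachment_pairs,
    form_bonds,
    from_smiles,
    heavy_atom_count,
    place_linker,
    rotation_aligning,
)
from templink.chem import canonical_smiles

from conftest import toy_fragment, toy_linker

vec3 = st.lists(st.floats(-10, 10), min_size=3, max_size=3).map(np.array).filter(
    lambda v: np.linalg.norm(v) > 1e-3
)


class TestRotationAligning:
    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(v_from=vec3, v_to=vec3)
    def test_rodrigues_maps_direction_and_is_proper(self, v_from, v_to):
        rot = rotation_aligning(v_from, v_to)
        mapped = rot @ (v_from / np.linalg.norm(v_from))
        target = v_to / np.linalg.norm(v_to)
        angle = np.arccos(np.clip(np.dot(mapped, target), -1, 1))
        assert angle < 1e-6
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(rot @ rot.T, np.eye(3), atol=1e-9)

    def test_antiparallel_degenerate_case(self):
        v = np.array([0.0, 0.0, 3.0])
        rot = rotation_aligning(v, -v)
        assert np.allclose(rot @ v, -v, atol=1e-9)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError):
            rotation_aligning(np.zeros(3), np.array([1.0, 0, 0]))


class TestAttachmentPairs:
    def test_two_points_two_ordered_pairs(self):
        assert len(enumerate_attachment_pairs(toy_linker(5.0))) == 2

    def test_three_points_six_ordered_pairs(self):
        lk = Linker(from_smiles("*c1cc(*)cc(*)c1", name="tri", seed=4))
        assert len(enumerate_attachment_pairs(lk)) == 6

    def test_fewer_than_two_points_rejected(self):
        mol = from_smiles("*CC", name="mono", seed=4)
        with pytest.raises(ValueError, match="attachment points"):
            Linker(mol)


def _pocket_poses(separation):
    """Annotated one-carbon fragments facing each other ``separation`` Å apart."""
    f1 = toy_fragment([0.0, 0.0, 0.0], [1, 0, 0], name="f1")
    f2 = toy_fragment([separation, 0.0, 0.0], [-1, 0, 0], name="f2")
    return (
        DockedPose("f1", "pocket1", 1, f1, -5.0),
        DockedPose("f2", "pocket2", 1, f2, -5.0),
    )


class TestPlaceLinker:
    def test_exact_fit_gap_zero(self):
        p1, p2 = _pocket_poses(5.0)
        res = place_linker(toy_linker(5.0), enumerate_attachment_pairs(toy_linker(5.0))[0], p1, p2)
        assert res.accepted
        assert res.gap == pytest.approx(0.0, abs=1e-9)

    def test_length_mismatch_gap_is_difference(self):
        p1, p2 = _pocket_poses(5.0)
        lk = toy_linker(5.2)
        res = place_linker(lk, enumerate_attachment_pairs(lk)[0], p1, p2)
        assert not res.accepted
        assert res.gap == pytest.approx(0.2, abs=1e-9)

    @pytest.mark.parametrize("length,accepted", [(5.0999, True), (5.1001, False)])
    def test_gap_threshold_boundary(self, length, accepted):
        p1, p2 = _pocket_poses(5.0)
        lk = toy_linker(length)
        res = place_linker(lk, enumerate_attachment_pairs(lk)[0], p1, p2)
        assert res.gap == pytest.approx(abs(length - 5.0), abs=1e-9)
        assert res.accepted is accepted

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        sep=st.floats(3, 9),
        length=st.floats(2, 9),
        direction=vec3,
    )
    def test_gap_equals_vector_length_difference(self, sep, length, direction):
        p1, p2 = _pocket_poses(sep)
        lk = toy_linker(length, direction=direction)
        res = place_linker(lk, enumerate_attachment_pairs(lk)[0], p1, p2)
        assert res.gap == pytest.approx(abs(sep - length), abs=1e-6)

    def test_rigid_motion_invariance(self):
        rot = rotation_aligning(np.array([1.0, 0, 0]), np.array([0.3, -0.8, 0.5]))
        shift = np.array([4.0, -7.0, 2.0])
        p1, p2 = _pocket_poses(5.0)
        lk = toy_linker(5.05)
        base = place_linker(lk, enumerate_attachment_pairs(lk)[0], p1, p2)
        moved1 = DockedPose("f1", "pocket1", 1, p1.mol.transformed(rot, np.zeros(3)).translated(shift), -5.0)
        moved2 = DockedPose("f2", "pocket2", 1, p2.mol.transformed(rot, np.zeros(3)).translated(shift), -5.0)
        moved = place_linker(lk, enumerate_attachment_pairs(lk)[0], moved1, moved2)
        assert moved.accepted == base.accepted
        assert moved.gap == pytest.approx(base.gap, abs=1e-9)

    def test_transform_preserves_linker_lengths(self):
        p1, p2 = _pocket_poses(5.0)
        lk = toy_linker(5.0)
        res = place_linker(lk, enumerate_attachment_pairs(lk)[0], p1, p2)
        before = lk.mol.positions
        after = res.transformed_linker.positions
        for i, j in itertools.combinations(range(len(before)), 2):
            assert np.linalg.norm(before[i] - before[j]) == pytest.approx(
                np.linalg.norm(after[i] - after[j]), abs=1e-6
            )


class TestFormBonds:
    def test_template_reassembly_closure(self, sorafenib, sorafenib_decomp):
        d = sorafenib_decomp
        f1 = DockedPose("f1", "pocket1", 1, d.fragment1.mol, -5.1)
        f2 = DockedPose("f2", "pocket2", 1, d.fragment2.mol, -6.1)
        lk = Linker(d.linker_piece.mol, "tmpl")
        accepted = [
            place_linker(lk, pair, f1, f2) for pair in enumerate_attachment_pairs(lk)
        ]
        accepted = [r for r in accepted if r.accepted]
        assert accepted
        cand, reason = form_bonds(f1, f2, lk, accepted[0], ge_sum=0.87)
        assert reason is None
        assert cand.smiles == canonical_smiles(sorafenib)

    def test_candidate_heavy_count_additive(self, sorafenib_decomp):
        d = sorafenib_decomp
        f1 = DockedPose("f1", "pocket1", 1, d.fragment1.mol, -5.1)
        f2 = DockedPose("f2", "pocket2", 1, d.fragment2.mol, -6.1)
        lk = Linker(d.linker_piece.mol, "tmpl")
        res = next(
            r for p in enumerate_attachment_pairs(lk)
            if (r := place_linker(lk, p, f1, f2)).accepted
        )
        cand, _ = form_bonds(f1, f2, lk, res)
        expected = sum(
            heavy_atom_count(m) for m in (d.fragment1.mol, d.linker_piece.mol, d.fragment2.mol)
        )
        assert heavy_atom_count(cand.mol) == expected

    def test_unaccepted_placement_rejected(self):
        p1, p2 = _pocket_poses(5.0)
        lk = toy_linker(6.0)
        res = place_linker(lk, enumerate_attachment_pairs(lk)[0], p1, p2)
        with pytest.raises(ValueError):
            form_bonds(p1, p2, lk, res)


class TestAssembleAll:
    def test_placement_count_two_by_two_by_one(self):
        ps = PoseSet()
        for i, sep in enumerate([5.0, 5.5]):
            f1, f2 = _pocket_poses(sep)
            ps.add(DockedPose(f"a{i}", "pocket1", 1, f1.mol, -5.0))
            ps.add(DockedPose(f"b{i}", "pocket2", 1, f2.mol, -5.0))
        result = assemble_all(ps, [toy_linker(5.0)])
        assert result.attempts == 2 * 2 * 2  # poses x poses x ordered pairs

    def test_brute_force_oracle_equivalence(self):
        """Accept/reject decisions match an independent closed-form sweep."""
        seps = [4.0, 5.0]
        lengths = [5.0, 4.05]
        ps = PoseSet()
        for i, sep in enumerate(seps):
            f1, f2 = _pocket_poses(sep)
            ps.add(DockedPose(f"p1_{i}", "pocket1", 1, f1.mol, -5.0))
            ps.add(DockedPose(f"p2_{i}", "pocket2", 1, f2.mol, -5.0))
        linkers = [toy_linker(L, name=f"lk{L}") for L in lengths]
        result = assemble_all(ps, linkers, gap_threshold=0.1)

        # oracle: a placement is accepted iff | |a2-a1| - |lp2-lp1| | < 0.1
        oracle_accepted = 0
        for f1 in ps.poses("pocket1"):
            a1 = f1.mol.atoms[0].position
            for f2 in ps.poses("pocket2"):
                a2 = f2.mol.atoms[0].position
                v1 = np.linalg.norm(a2 - a1)
                for lk in linkers:
                    pts = lk.attachment_points
                    for p, q in itertools.permutations(pts, 2):
                        v2 = np.linalg.norm(
                            lk.mol.atoms[q.placeholder].position
                            - lk.mol.atoms[p.placeholder].position
                        )
                        if abs(v1 - v2) < 0.1:
                            oracle_accepted += 1
        assert result.accepted == oracle_accepted
        assert result.attempts == len(ps.poses("pocket1")) * len(ps.poses("pocket2")) * sum(
            len(list(itertools.permutations(lk.attachment_points, 2))) for lk in linkers
        )

    def test_duplicates_merged_with_max_ge_sum(self):
        f1a, f2 = _pocket_poses(5.0)
        f1b = DockedPose("f1", "pocket1", 2, f1a.mol.copy(), -6.0)  # better energy, same geometry
        ps = PoseSet()
        ps.add(DockedPose("f1", "pocket1", 1, f1a.mol, -5.0))
        ps.add(f1b)
        ps.add(f2)
        result = assemble_all(ps, [toy_linker(5.0)])
        assert len(result.candidates) == 1
        (cand,) = result.candidates
        assert len(cand.provenance) >= 2
        best = max(6.0 / 1 + 5.0 / 1, 5.0 / 1 + 5.0 / 1)
        assert cand.ge_sum == pytest.approx(best)

    def test_no_fitting_linker_empty(self):
        f1, f2 = _pocket_poses(5.0)
        ps = PoseSet()
        ps.add(f1)
        ps.add(f2)
        result = assemble_all(ps, [toy_linker(8.0)])
        assert result.candidates == []
        assert result.rejections
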