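"""Docked-pose import, the mock docker, and the backend contract."""

import numpy as np
import pytest

from templink import (
    DockedPose,
    GridBox,
    Molecule3D,
    PoseSet,
    dock_with_backend,
    from_smiles,
    geometric_center,
    heavy_atom_count,
    load_poses,
    mock_dock,
    possible_pose_count,
    register_backend,
    write_structures,
)
from templink.poses import mock_energy


@pytest.fixture(scope="module")
def benzene():
    return from_smiles("c1ccccc1", name="benzene", seed=1)


def _pose_sdf(tmp_path, mols_energies, name="poses.sdf", tag="docking_energy"):
    mols = []
    for mol, energy in mols_energies:
        m = mol.copy()
        if energy is not None:
            m.properties[tag] = energy
        mols.append(m)
    path = tmp_path / name
    write_structures(mols, path)
    return path


class TestLoadPosesSDF:
    def test_truncates_to_max_poses_lowest_energy_first(self, tmp_path, benzene):
        energies = [-1.0, -5.0, -3.0, -2.0, -8.0, -4.0, -6.0, -7.0, -0.5, -9.0]
        path = _pose_sdf(tmp_path, [(benzene, e) for e in energies])
        ps = load_poses(path, "pocket1", max_poses=8)
        got = [p.energy for p in ps.poses("pocket1")]
        assert got == sorted(energies)[:8]
        assert [p.pose_index for p in ps.poses("pocket1")] == list(range(1, 9))

    def test_empty_file(self, tmp_path):
        p = tmp_path / "none.sdf"
        p.write_text("")
        assert len(load_poses(p, "pocket1")) == 0

    def test_positive_energy_kept_but_flagged(self, tmp_path, benzene):
        path = _pose_sdf(tmp_path, [(benzene, 1.2)])
        (pose,) = load_poses(path, "pocket1").poses()
        assert pose.energy == pytest.approx(1.2)
        assert not pose.is_binding

    def test_missing_energy_tag_errors(self, tmp_path, benzene):
        path = _pose_sdf(tmp_path, [(benzene, None)])
        with pytest.raises(ValueError, match="energy tag"):
            load_poses(path, "pocket1")

    def test_graph_mismatch_vs_library_errors(self, tmp_path, benzene):
        path = _pose_sdf(tmp_path, [(benzene, -2.0)])
        library = {"benzene": from_smiles("c1ccncc1", name="benzene", seed=2)}
        with pytest.raises(ValueError, match="mismatch"):
            load_poses(path, "pocket1", library=library)

    def test_box_containment_filter(self, tmp_path, benzene):
        far = benzene.translated([50.0, 0.0, 0.0])
        far.name = "benzene"
        path = _pose_sdf(tmp_path, [(benzene, -3.0), (far, -4.0)])
        box = GridBox(tuple(geometric_center(benzene)), 10)
        ps = load_poses(path, "pocket1", box=box)
        assert [p.energy for p in ps.poses()] == [-3.0]

    def test_energy_window(self, tmp_path, benzene):
        path = _pose_sdf(tmp_path, [(benzene, e) for e in (-8.0, -7.5, -2.0)])
        ps = load_poses(path, "pocket1", energy_window=1.0)
        assert [p.energy for p in ps.poses()] == [-8.0, -7.5]


class TestLoadPosesPDBQT:
    def _write_pdbqt(self, path, models):
        lines = []
        for k, (energy, coords) in enumerate(models, start=1):
            lines.append(f"MODEL {k}")
            lines.append(f"REMARK VINA RESULT:    {energy:8.3f}      0.000      0.000")
            for i, (x, y, z) in enumerate(coords, start=1):
                lines.append(
                    f"ATOM  {i:5d}  C   LIG A   1    {x:8.3f}{y:8.3f}{z:8.3f}  0.00  0.00     0.000 A "
                )
            lines.append("ENDMDL")
        path.write_text("\n".join(lines) + "\n")

    def test_models_parsed_with_energies(self, tmp_path, benzene):
        path = tmp_path / "benzene.pdbqt"
        ring = benzene.positions[benzene.heavy_indices()]
        self._write_pdbqt(path, [(-5.5, ring + 1.0), (-4.0, ring)])
        ps = load_poses(path, "pocket2", library={"benzene": benzene})
        poses = ps.poses("pocket2")
        assert [p.energy for p in poses] == [-5.5, -4.0]
        assert np.allclose(
            poses[0].mol.positions[poses[0].mol.heavy_indices()], ring + 1.0, atol=1e-3
        )

    def test_requires_library(self, tmp_path):
        path = tmp_path / "x.pdbqt"
        path.write_text("MODEL 1\nENDMDL\n")
        with pytest.raises(ValueError, match="library"):
            load_poses(path, "pocket1")


class TestMockDock:
    def test_deterministic_for_fixed_seed(self, benzene):
        box = GridBox((0, 0, 0), 10)
        a = mock_dock(benzene, box, n_poses=8, seed=5)
        b = mock_dock(benzene, box, n_poses=8, seed=5)
        assert [p.energy for p in a] == [p.energy for p in b]
        assert all(np.allclose(x.mol.positions, y.mol.positions) for x, y in zip(a, b))

    def test_pose_count_and_ordering(self, benzene):
        poses = mock_dock(benzene, GridBox((0, 0, 0), 10), n_poses=8, seed=1)
        assert len(poses) == 8
        energies = [p.energy for p in poses]
        assert energies == sorted(energies)

    def test_centers_inside_box(self, benzene):
        box = GridBox((3, -2, 7), 10)
        for p in mock_dock(benzene, box, n_poses=8, seed=3):
            assert box.contains(geometric_center(p.mol), tolerance=1e-6)

    def test_energy_formula_most_negative_at_center(self, benzene):
        box = GridBox((0, 0, 0), 10)
        at_center = mock_energy(benzene, box, np.zeros(3))
        assert at_center == pytest.approx(-0.5 * heavy_atom_count(benzene))
        offset = mock_energy(benzene, box, np.array([2.0, 0, 0]))
        assert at_center < offset < 0

    def test_invalid_n_poses(self, benzene):
        with pytest.raises(ValueError):
            mock_dock(benzene, GridBox((0, 0, 0), 10), n_poses=0)


class TestPoseSetInvariants:
    def test_possible_pose_identity(self):
        assert possible_pose_count(3, 8) == 24

    def test_capacity_enforced(self, benzene):
        ps = PoseSet(max_poses=2)
        ps.add(DockedPose("b", "pocket1", 1, benzene, -1.0))
        ps.add(DockedPose("b", "pocket1", 2, benzene, -0.5))
        with pytest.raises(ValueError):
            ps.add(DockedPose("b", "pocket1", 3, benzene, -0.2))

    def test_total_bounded_by_blocks_times_max(self, tmp_path, benzene):
        blocks = []
        for i in range(3):
            m = benzene.copy()
            m.name = f"b{i}"
            blocks.append(m)
        entries = [(b, -float(k + 1)) for b in blocks for k in range(10)]
        path = _pose_sdf(tmp_path, entries)
        ps = load_poses(path, "pocket1", max_poses=8)
        assert len(ps) <= possible_pose_count(3, 8)
        assert len(ps) == 24  # every block saturates


class TestBackendContract:
    def test_registered_backend_normalized(self, benzene):
        def fake_backend(block, box, settings):
            return [(block.translated([1, 0, 0]), -4.2), (block, -6.0)]

        register_backend("fake", fake_backend)
        poses = dock_with_backend("fake", benzene, GridBox((0, 0, 0), 10), region="pocket1")
        assert [p.energy for p in poses] == [-6.0, -4.2]
        assert poses[0].pose_index == 1

    def test_backend_failure_names_block(self, benzene):
        def broken(block, box, settings):
            raise RuntimeError("boom")

        register_backend("broken", broken)
        with pytest.raises(RuntimeError, match="benzene"):
            dock_with_backend("broken", benzene, GridBox((0, 0, 0), 10))

    def test_unknown_backend(self, benzene):
        with pytest.raises(KeyError):
            dock_with_backend("nope", benzene, GridBox((0, 0, 0), 10))
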