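"""Multi-model PDB I/O and geometric primitives."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import make_ensemble, make_model
from _oracles import min_rmsd_by_optimization

from pepsurf.structure_io import (
    Ensemble,
    InsufficientAtomsError,
    PDBParseError,
    StructuralInconsistencyError,
    center_of_mass,
    element_mass,
    read_multimodel_pdb,
    rmsd_after_fit,
    superpose,
    write_multimodel_pdb,
)

PDB_3_MODELS = "".join(
    f"MODEL     {m:>4}\n"
    + "".join(
        f"ATOM  {i + 1:>5}  CA  ALA A{i + 1:>4}    {float(i):8.3f}{float(m):8.3f}{0.0:8.3f}  1.00  0.00           C  \n"
        for i in range(12)
    )
    + "ENDMDL\n"
    for m in range(1, 4)
)


class TestReading:
    def test_model_blocks_are_separate_models(self, tmp_path):
        p = tmp_path / "three.pdb"
        p.write_text(PDB_3_MODELS)
        ens = read_multimodel_pdb(p)
        assert len(ens) == 3
        assert all(len(m) == 12 for m in ens)

    def test_file_without_model_records_is_single_model(self, tmp_path):
        p = tmp_path / "single.pdb"
        p.write_text(
            "ATOM      1  CA  GLY A   5       1.000   2.000   3.000  1.00  0.00           C  \n"
        )
        ens = read_multimodel_pdb(p)
        assert len(ens) == 1
        atom = ens[0].atoms[0]
        assert atom.residue_seq == 5  # numbering preserved verbatim
        assert np.allclose(atom.coords, [1, 2, 3])

    def test_malformed_atom_record_names_line(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C  \n"
            "ATOM      2  CA  ALA A   2       x.xxx   0.000   0.000  1.00  0.00           C  \n"
        )
        with pytest.raises(PDBParseError, match="line 2"):
            read_multimodel_pdb(p)

    def test_inconsistent_models_rejected(self, tmp_path):
        text = (
            "MODEL        1\n"
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C  \n"
            "ENDMDL\nMODEL        2\n"
            "ATOM      1  CA  GLY A   2       0.000   0.000   0.000  1.00  0.00           C  \n"
            "ENDMDL\n"
        )
        p = tmp_path / "mixed.pdb"
        p.write_text(text)
        with pytest.raises((StructuralInconsistencyError, PDBParseError)):
            read_multimodel_pdb(p)

    def test_hetatm_skipped_by_default(self, tmp_path):
        p = tmp_path / "het.pdb"
        p.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C  \n"
            "HETATM    2 ZN    ZN A 300       5.000   5.000   5.000  1.00  0.00          ZN  \n"
        )
        assert len(read_multimodel_pdb(p)[0]) == 1
        assert len(read_multimodel_pdb(p, include_hetatm=True)[0]) == 2


class TestRoundTrip:
    def test_synthetic_pose_ensemble_round_trips(self, tmp_path, rng):
        from pepsurf.synthetic_data import gen_pose_ensemble, peptide_ca_template

        template = peptide_ca_template("L9M")
        poses, _ = gen_pose_ensemble(
            template, [(np.zeros(3), 1.0, 5.0)], rng, n_poses=100
        )
        p = tmp_path / "poses.pdb"
        write_multimodel_pdb(p, poses)
        back = read_multimodel_pdb(p)
        assert len(back) == 100
        assert back[0].identities() == poses[0].identities()
        # coordinates written at %8.3f: exact at that precision
        assert np.abs(back.coords - poses.coords).max() <= 5.1e-4
        # second round trip is bitwise stable
        p2 = tmp_path / "again.pdb"
        write_multimodel_pdb(p2, back)
        assert p2.read_text() == p.read_text()


class TestCenterOfMass:
    def test_uniform_two_atoms(self):
        m = make_model([[0, 0, 0], [2, 0, 0]])
        assert np.allclose(center_of_mass(m, "uniform"), [1, 0, 0])

    def test_translation_equivariance(self, random_model, rng):
        t = rng.normal(size=3)
        shifted = random_model.transformed(np.eye(3), t)
        for mode in ("uniform", "element"):
            np.testing.assert_allclose(
                center_of_mass(shifted, mode), center_of_mass(random_model, mode) + t,
                atol=1e-12,
            )

    def test_element_masses_match_direct_sum(self, rng):
        elements = list(rng.choice(["C", "N", "O", "S"], size=50))
        coords = rng.normal(scale=10, size=(50, 3))
        m = make_model(coords, elements=elements)
        masses = np.array([element_mass(e) for e in elements])
        expected = (masses[:, None] * coords).sum(axis=0) / masses.sum()
        np.testing.assert_allclose(center_of_mass(m, "element"), expected, atol=1e-9)

    def test_unknown_element_is_reported(self):
        m = make_model([[0, 0, 0]], elements=["Qq"])
        with pytest.raises(Exception, match="Qq"):
            center_of_mass(m, "element")


class TestSuperposition:
    def test_self_superposition_after_rigid_motion(self, random_model, rng):
        R = Rotation.random(rng=rng).as_matrix()
        moved = random_model.transformed(R, rng.normal(size=3))
        Rfit, t, rmsd = superpose(moved, random_model)
        assert rmsd <= 1e-6
        np.testing.assert_allclose(Rfit @ R, np.eye(3), atol=1e-6)

    def test_mirror_image_gets_proper_rotation(self, random_model):
        mirrored = random_model.with_coords(random_model.coords * [-1, 1, 1])
        R, _, rmsd = superpose(mirrored, random_model)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1

    def test_rmsd_matches_global_optimization_oracle(self, rng):
        a = rng.normal(scale=5, size=(20, 3))
        b = rng.normal(scale=5, size=(20, 3))
        kabsch = rmsd_after_fit(make_model(a), make_model(b))
        oracle = min_rmsd_by_optimization(a, b)
        assert kabsch == pytest.approx(oracle, abs=1e-3)

    def test_rmsd_symmetry_and_rigid_invariance(self, rng):
        a = make_model(rng.normal(size=(15, 3)))
        b = make_model(rng.normal(size=(15, 3)))
        r_ab = rmsd_after_fit(a, b)
        assert r_ab == pytest.approx(rmsd_after_fit(b, a), abs=1e-9)
        R = Rotation.random(rng=rng).as_matrix()
        b_moved = b.transformed(R, rng.normal(size=3))
        assert r_ab == pytest.approx(rmsd_after_fit(a, b_moved), abs=1e-9)

    def test_insufficient_atoms(self):
        a = make_model([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(InsufficientAtomsError):
            superpose(a, a)


def test_ensemble_rejects_mismatched_models():
    m1 = make_model([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
    m2 = make_model([[0, 0, 0], [1, 0, 0]])
    with pytest.raises(StructuralInconsistencyError):
        Ensemble([m1, m2])
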