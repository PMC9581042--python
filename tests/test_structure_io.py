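"""Structure reading and decoy-vs-native quality measures."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from interpeprank import (
    classify_capri,
    compute_dockq,
    compute_fnat,
    compute_irmsd,
    compute_lrmsd,
    evaluate_decoy,
    read_pdb,
    write_pdb,
)
from interpeprank.structure_io import (
    ComplexStructure,
    QualityMeasures,
    ResidueRecord,
    kabsch,
    superposed_rmsd,
)
from interpeprank.fixtures import make_decoy_set, _transform_peptide

TINY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.460   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       2.000   2.000   1.000  1.00  0.00           O
ATOM      5  CA  GLY A   2       4.000   0.000   0.000  1.00  0.00           C
ATOM      6  CA  SER A   3       8.000   0.000   0.000  1.00  0.00           C
ATOM      7  CA  XYZ A   4      12.000   0.000   0.000  1.00  0.00           C
ATOM      8  CA  LEU B   1       0.000   4.000   0.000  1.00  0.00           C
ATOM      9  CA  VAL B   2       3.800   4.000   0.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.40  0.00           C
ATOM      3  CA  GLY B   1       0.000   2.000   0.000  1.00  0.00           C
END
"""


class TestReadPdb:
    def test_reads_chains_and_residue_counts(self, tmp_path):
        p = tmp_path / "tiny.pdb"
        p.write_text(TINY_PDB)
        with pytest.warns(UserWarning):  # receptor < 50 residues
            cx = read_pdb(p, receptor_chains="A", peptide_chain="B")
        assert len(cx.receptor) == 4
        assert len(cx.peptide) == 2
        assert cx.receptor[0].aa1 == "A"
        assert cx.receptor[3].aa1 == "X"  # unknown residue name

    def test_missing_chain_is_named_in_error(self, tmp_path):
        p = tmp_path / "tiny.pdb"
        p.write_text(TINY_PDB)
        with pytest.raises(ValueError, match="'C'"):
            read_pdb(p, receptor_chains="A", peptide_chain="C")

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        with pytest.warns(UserWarning):
            cx = read_pdb(p, receptor_chains="A", peptide_chain="B")
        assert len(cx.receptor) == 1
        (name, x, y, z) = cx.receptor[0].heavy_atoms[0]
        assert x == pytest.approx(1.0)  # occupancy 0.6 conformer kept

    def test_roundtrip_through_writer(self, tmp_path, toy_native):
        p = tmp_path / "native.pdb"
        write_pdb(toy_native, p)
        back = read_pdb(p, receptor_chains="A", peptide_chain="B")
        assert len(back.receptor) == len(toy_native.receptor)
        a = np.concatenate([r.coords() for r in back.residues])
        b = np.concatenate([r.coords() for r in toy_native.residues])
        np.testing.assert_allclose(a, b, atol=1.5e-3)  # PDB prints 3 decimals


class TestSuperposition:
    def test_kabsch_matches_scipy_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(size=(12, 3))
            rot = Rotation.random(random_state=42).as_matrix()
            # add noise so the residual is well away from zero, where the
            # oracle's sqrt would amplify round-off
            b = a @ rot.T + rng.normal(size=3) + rng.normal(scale=0.5, size=a.shape)
            ours = superposed_rmsd(b, a)
            est, rssd = Rotation.align_vectors(
                a - a.mean(0), b - b.mean(0), return_sensitivity=False
            )[:2]
            oracle = rssd / np.sqrt(len(a))
            assert abs(ours - oracle) < 1e-9

    def test_exact_recovery_of_rigid_motion(self, rng):
        a = rng.normal(size=(8, 3))
        rot = Rotation.from_euler("xyz", [0.3, -1.0, 2.0]).as_matrix()
        b = a @ rot.T + np.array([1.0, -2.0, 3.0])
        assert superposed_rmsd(b, a) < 1e-12
        r, t = kabsch(b, a)
        np.testing.assert_allclose(b @ r.T + t, a, atol=1e-10)


class TestLrmsd:
    def test_identity_is_zero(self, toy_native):
        assert compute_lrmsd(toy_native, toy_native) == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_equals_distance(self, toy_native):
        decoy = _transform_peptide(toy_native, None, np.array([3.0, 0.0, 0.0]), "d")
        assert compute_lrmsd(decoy, toy_native) == pytest.approx(3.0, abs=1e-9)

    def test_rotation_matches_closed_form_displacement(self, toy_native):
        # 180 degree rotation about an axis through the peptide centroid:
        # LRMSD must equal the direct RMS displacement of the backbone atoms
        axis = np.array([0.0, 0.0, 1.0])
        rot = Rotation.from_rotvec(axis * np.pi).as_matrix()
        decoy = _transform_peptide(toy_native, rot, np.zeros(3), "d")
        bb = np.concatenate([r.coords() for r in toy_native.peptide])
        c = bb.mean(axis=0)
        moved = (bb - c) @ rot.T + c
        expected = np.sqrt(np.mean(np.sum((moved - bb) ** 2, axis=1)))
        assert compute_lrmsd(decoy, toy_native) == pytest.approx(expected, abs=1e-9)

    def test_invariant_to_global_rigid_transform(self, toy_native, rng):
        decoy, lrmsd = make_decoy_set(toy_native, [2.5], seed=5, mode="mixed")[0]
        for _ in range(5):
            rot = Rotation.random(random_state=int(rng.integers(1 << 31))).as_matrix()
            t = rng.normal(scale=20, size=3)

            def move(res):
                return ResidueRecord(
                    res.chain_id, res.res_seq, res.icode, res.aa3, res.aa1,
                    [(n, *(rot @ np.array([x, y, z]) + t)) for n, x, y, z in res.heavy_atoms],
                )

            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                moved = ComplexStructure(
                    [move(r) for r in decoy.receptor],
                    [move(r) for r in decoy.peptide],
                    "moved",
                )
            assert abs(compute_lrmsd(moved, toy_native) - lrmsd) < 1e-6

    def test_sequence_mismatch_raises(self, toy_native):
        bad_pep = [
            ResidueRecord(r.chain_id, r.res_seq, r.icode, "GLY", "G", r.heavy_atoms)
            for r in toy_native.peptide
        ]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bad = ComplexStructure(toy_native.receptor, bad_pep, "bad")
        with pytest.raises(ValueError, match="mismatch"):
            compute_lrmsd(bad, toy_native)


def _ca_residue(chain, num, xyz):
    return ResidueRecord(chain, num, "", "ALA", "A", [("CA", *map(float, xyz))])


class TestInterfaceMeasures:
    def test_identity_gives_perfect_scores(self, toy_native):
        assert compute_irmsd(toy_native, toy_native) == pytest.approx(0.0, abs=1e-9)
        assert compute_fnat(toy_native, toy_native) == 1.0

    def test_far_away_peptide_has_zero_fnat(self, toy_native):
        decoy = _transform_peptide(toy_native, None, np.array([50.0, 0, 0]), "far")
        assert compute_fnat(decoy, toy_native) == 0.0

    def test_fnat_two_of_three_contacts(self):
        # native: peptide atom within 5 A of three receptor residues
        import warnings

        rec = [
            _ca_residue("A", 1, (0, 0, 0)),
            _ca_residue("A", 2, (4, 0, 0)),
            _ca_residue("A", 3, (0, 4, 0)),
        ]
        pep_n = [_ca_residue("B", 1, (2, 2, 0))]
        # decoy peptide keeps contacts to residues 1 and 2 only
        pep_d = [_ca_residue("B", 1, (2, -2, 0))]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            native = ComplexStructure(rec, pep_n, "n")
            decoy = ComplexStructure(rec, pep_d, "d")

        # brute-force contact enumeration oracle
        def contacts(cx):
            out = set()
            for i, r in enumerate(cx.receptor):
                for j, p in enumerate(cx.peptide):
                    d = np.linalg.norm(r.coords()[0] - p.coords()[0])
                    if d <= 5.0:
                        out.add((i, j))
            return out

        expect = len(contacts(native) & contacts(decoy)) / len(contacts(native))
        assert expect == pytest.approx(2 / 3)
        assert compute_fnat(decoy, native) == pytest.approx(expect)

    def test_degenerate_native_raises(self):
        import warnings

        rec = [_ca_residue("A", 1, (0, 0, 0))]
        pep = [_ca_residue("B", 1, (100, 0, 0))]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            native = ComplexStructure(rec, pep, "n")
        with pytest.raises(ValueError, match="degenerate|interface|contact"):
            compute_fnat(native, native)


class TestCapriAndDockq:
    @pytest.mark.parametrize(
        "lrmsd,irmsd,fnat,expected",
        [
            (0.8, 0.4, 0.9, "High"),
            (1.5, 0.8, 0.6, "Medium"),
            (4.0, 1.5, 0.3, "Acceptable"),
            (10.0, 5.0, 0.0, "Incorrect"),
        ],
    )
    def test_classification(self, lrmsd, irmsd, fnat, expected):
        assert classify_capri(lrmsd, irmsd, fnat) == expected

    def test_dockq_limits(self):
        assert compute_dockq(0.0, 0.0, 1.0) == pytest.approx(1.0)
        assert compute_dockq(500.0, 500.0, 0.0) < 1e-3

    def test_dockq_monotone_on_grid(self):
        lr = np.linspace(0, 20, 9)
        ir = np.linspace(0, 10, 9)
        fn = np.linspace(0, 1, 9)
        for a, b in zip(lr[:-1], lr[1:]):
            assert compute_dockq(b, 1.0, 0.5) <= compute_dockq(a, 1.0, 0.5)
        for a, b in zip(ir[:-1], ir[1:]):
            assert compute_dockq(1.0, b, 0.5) <= compute_dockq(1.0, a, 0.5)
        for a, b in zip(fn[:-1], fn[1:]):
            assert compute_dockq(1.0, 1.0, a) <= compute_dockq(1.0, 1.0, b)

    def test_dockq_orders_quality_classes(self):
        high = compute_dockq(0.9, 0.45, 0.85)
        medium = compute_dockq(1.9, 0.9, 0.55)
        acceptable = compute_dockq(4.5, 1.9, 0.25)
        assert high > medium > acceptable

    def test_negative_inputs_raise(self):
        with pytest.raises(ValueError):
            compute_dockq(-1.0, 0.0, 0.5)

    def test_quality_measures_consistency(self, toy_native):
        decoy = _transform_peptide(toy_native, None, np.array([1.0, 0, 0]), "d")
        q = evaluate_decoy(decoy, toy_native)
        assert q.is_correct == (q.lrmsd < 4.0)
        assert 0.0 <= q.fnat <= 1.0 and 0.0 <= q.dockq <= 1.0
        assert q.capri_class == classify_capri(q.lrmsd, q.irmsd, q.fnat)

    def test_invalid_fnat_rejected(self):
        with pytest.raises(ValueError):
            QualityMeasures(lrmsd=1.0, irmsd=1.0, fnat=1.5)
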