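import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from conftest import brute_force_clash, make_model
from nucaccess.seenseq import ReadCounts, enrichment
from nucaccess.structscan import (
    AtomModel,
    ProbeModel,
    clash_scan,
    interface_area,
    overlay_profiles,
    paired_anchors,
    read_structure,
    sasa,
    superpose,
    write_pdb,
)


def horn_quaternion(P, T):
    """Independent rigid superposition oracle (Horn's quaternion method)."""
    P, T = np.asarray(P, float), np.asarray(T, float)
    pc, tc = P.mean(0), T.mean(0)
    A, B = P - pc, T - tc
    M = A.T @ B
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    N = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    vals, vecs = np.linalg.eigh(N)
    q = vecs[:, -1]
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = tc - R @ pc
    return float(np.sqrt(np.mean(np.sum((P @ R.T + t - T) ** 2, 1))))


class TestSuperpose:
    def test_identity(self):
        P = np.random.default_rng(0).normal(size=(8, 3))
        R, t, rmsd = superpose(P, P)
        assert rmsd < 1e-12
        assert np.allclose(R, np.eye(3), atol=1e-9) and np.allclose(t, 0, atol=1e-9)

    def test_recovers_90_degree_rotation(self):
        P = np.random.default_rng(1).normal(size=(10, 3))
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        T = P @ Rz.T
        R, t, rmsd = superpose(P, T)
        assert rmsd < 1e-9 and np.allclose(R, Rz, atol=1e-9)

    def test_no_reflection(self):
        P = np.random.default_rng(2).normal(size=(12, 3))
        T = P.copy()
        T[:, 2] *= -1  # mirrored target
        R, _, _ = superpose(P, T)
        assert np.linalg.det(R) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quaternion_oracle_on_noisy_anchors(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.normal(size=(15, 3))
        Rm = Rotation.random(rng=np.random.default_rng(seed + 100)).as_matrix()
        T = P @ Rm.T + rng.normal(0, 0.3, size=(15, 3)) + [1, -2, 3]
        _, _, rmsd = superpose(P, T)
        assert rmsd == pytest.approx(horn_quaternion(P, T), rel=1e-9)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.c_[np.arange(5), np.zeros(5), np.zeros(5)]
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line)


class TestClashScan:
    def test_matches_generator_truth(self, toy_structures):
        nuc, anchors, probe, truth = toy_structures
        prof = clash_scan(probe, nuc, anchors)
        assert np.array_equal(prof.counts, truth.tables["clash"]["clash_count"].to_numpy())

    @pytest.mark.parametrize("threshold", [0.5, 1.0, 2.0])
    def test_equals_brute_force_all_pairs(self, toy_structures, threshold):
        nuc, anchors, probe, _ = toy_structures
        prof = clash_scan(probe, nuc, anchors, threshold_A=threshold)
        nuc_xyz = nuc.coords()
        tf_xyz = probe.model.coords("tf-protein")
        p_anch = probe.anchors.reshape(-1, 3)
        for r, count in zip(prof.registers, prof.counts):
            t_anch = anchors[r: r + probe.n_bp].reshape(-1, 3)
            R, t, _ = superpose(p_anch, t_anch)
            assert count == brute_force_clash(tf_xyz @ R.T + t, nuc_xyz, threshold)

    def test_rigid_motion_invariance(self, toy_structures):
        nuc, anchors, probe, _ = toy_structures
        base = clash_scan(probe, nuc, anchors)
        R = Rotation.from_euler("xyz", [0.4, -1.2, 2.0]).as_matrix()
        t = np.array([10.0, -5.0, 3.0])
        moved = clash_scan(probe, nuc.transformed(R, t), anchors @ R.T + t)
        assert np.array_equal(base.counts, moved.counts)

    def test_monotone_in_threshold(self, toy_structures):
        nuc, anchors, probe, _ = toy_structures
        c1 = clash_scan(probe, nuc, anchors, threshold_A=0.5).counts
        c2 = clash_scan(probe, nuc, anchors, threshold_A=1.0).counts
        c3 = clash_scan(probe, nuc, anchors, threshold_A=2.0).counts
        assert (c1 <= c2).all() and (c2 <= c3).all()

    def test_probe_without_protein_scores_zero(self, toy_structures):
        nuc, anchors, probe, _ = toy_structures
        dna_only = ProbeModel(
            model=AtomModel(probe.model.atoms[probe.model.atoms["group"] == "probe-dna"]),
            anchors=probe.anchors,
        )
        prof = clash_scan(dna_only, nuc, anchors)
        assert (prof.counts == 0).all()

    def test_constructed_coincident_atom_clashes(self, toy_structures):
        nuc, anchors, probe, _ = toy_structures
        # place a TF atom exactly on a histone atom after superposition at r=0
        p_anch = probe.anchors.reshape(-1, 3)
        t_anch = anchors[: probe.n_bp].reshape(-1, 3)
        R, t, _ = superpose(p_anch, t_anch)
        target = nuc.select("nucleosome-histone").iloc[0][["x", "y", "z"]].to_numpy(float)
        back = (target - t) @ R  # inverse rotation
        atoms = probe.model.atoms.copy()
        atoms.loc[atoms.index[-1], ["x", "y", "z"]] = back
        probe2 = ProbeModel(model=AtomModel(atoms), anchors=probe.anchors)
        prof = clash_scan(probe2, nuc, anchors)
        assert prof.counts[0] >= 1


class TestInterfaceArea:
    def test_distant_groups_bury_nothing(self):
        m = make_model([("C", 0, 0, 0, "a"), ("C", 50, 0, 0, "b")])
        assert interface_area(m, "a", "b") == 0.0

    def test_two_spheres_match_closed_form(self):
        # carbon spheres (r=1.7) at distance 2; expanded radius R=3.1,
        # buried area per sphere = 2*pi*R*h with cap height h = R - d/2
        m = make_model([("C", 0, 0, 0, "a"), ("C", 2.0, 0, 0, "b")])
        analytic = 2 * np.pi * 3.1 * (3.1 - 1.0)
        assert interface_area(m, "a", "b", n_points=2000) == pytest.approx(analytic, rel=0.02)

    def test_symmetry(self, toy_structures):
        nuc, *_ = toy_structures
        sub = AtomModel(nuc.atoms.head(200))
        ab = interface_area(sub, "nucleosome-dna", "nucleosome-histone")
        ba = interface_area(sub, "nucleosome-histone", "nucleosome-dna")
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_converges_with_lattice_density(self):
        m = make_model([("C", 0, 0, 0, "a"), ("N", 2.2, 0.5, 0, "b"), ("O", -1.0, 2.0, 0.5, "a")])
        coarse = interface_area(m, "a", "b", n_points=480)
        fine = interface_area(m, "a", "b", n_points=4000)
        assert coarse == pytest.approx(fine, rel=0.05)

    def test_unknown_element_falls_back_with_warning(self):
        m = make_model([("XX", 0, 0, 0, "a"), ("C", 2.0, 0, 0, "b")])
        with pytest.warns(UserWarning, match="unknown element"):
            area = interface_area(m, "a", "b")
        assert area > 0

    def test_empty_group_raises(self):
        m = make_model([("C", 0, 0, 0, "a")])
        with pytest.raises(ValueError):
            interface_area(m, "a", "missing")

    def test_isolated_atom_sasa_is_sphere_area(self):
        area = sasa(np.zeros((1, 3)), np.array([1.7]), n_points=960)
        assert area == pytest.approx(4 * np.pi * 3.1**2, rel=1e-6)


class TestOverlayProfiles:
    def _profile(self, values):
        n = len(values)
        bound = ReadCounts("t", "bound", "1", dict(enumerate(np.asarray(values) * 100)))
        unbound = ReadCounts("t", "unbound", "1", dict(enumerate([100] * n)))
        return enrichment(bound, unbound)

    def test_anticorrelated_pair_negative_rho(self, toy_structures):
        from nucaccess.structscan import ClashProfile

        clash = ClashProfile(
            registers=np.arange(10), counts=np.arange(10), rmsd=np.zeros(10)
        )
        prof = self._profile(np.arange(10) + 1.0)  # enrichment rises with clash
        joined = overlay_profiles(clash, prof)
        assert joined.attrs["spearman_neg_clash_vs_enrichment"] < 0

    def test_constant_clash_flagged_undefined(self):
        from nucaccess.structscan import ClashProfile

        clash = ClashProfile(registers=np.arange(5), counts=np.ones(5, int), rmsd=np.zeros(5))
        joined = overlay_profiles(clash, self._profile([1, 2, 3, 4, 5]))
        assert np.isnan(joined.attrs["spearman_neg_clash_vs_enrichment"])

    def test_disjoint_supports_raise(self):
        from nucaccess.structscan import ClashProfile

        clash = ClashProfile(registers=np.arange(5), counts=np.ones(5, int), rmsd=np.zeros(5))
        with pytest.raises(ValueError):
            overlay_profiles(clash, self._profile([1, 2]), register_offset=1000)


class TestPdbRoundTrip:
    def test_write_read_preserves_coordinates_and_anchors(self, toy_structures, tmp_path):
        nuc, anchors, probe, _ = toy_structures
        path = tmp_path / "nuc.pdb"
        write_pdb(nuc, path)
        groups = {"I": "nucleosome-dna", "J": "nucleosome-dna", "A": "nucleosome-histone"}
        back = read_structure(path, groups)
        assert len(back.atoms) == len(nuc.atoms)
        # PDB format carries 3 decimals
        orig = nuc.atoms.sort_values(["chain", "resid", "name"])[["x", "y", "z"]].to_numpy()
        got = back.atoms.sort_values(["chain", "resid", "name"])[["x", "y", "z"]].to_numpy()
        assert np.allclose(np.sort(orig, 0), np.sort(got, 0), atol=2e-3)
        re_anchors = paired_anchors(back, "I", "J")
        assert re_anchors.shape == anchors.shape
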