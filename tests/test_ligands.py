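"""PDB ligand extraction, Kabsch superposition vs a brute-force oracle,
RMSD densities and closest-conformer reporting."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import rafttrace as rt
from rafttrace.chains import ConformerSpec
from rafttrace.ligands import (AtomRecord, LigandConformer, SuperpositionError,
                               closest_conformer, parse_ligands, rmsd_density,
                               superpose_carbons)


def hetatm(serial, name, res, chain, seq, x, y, z, altloc=" ", occ=1.00,
           element=" C"):
    return (f"HETATM{serial:>5} {name:<4}{altloc}{res:<3} {chain}{seq:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00          {element:>2}")


def chain_pdb(xyz, res="PLM", chain="A", seq=1, start_serial=1):
    lines = [hetatm(start_serial + i, f"C{i + 1}", res, chain, seq, *p)
             for i, p in enumerate(xyz)]
    return "\n".join(lines) + "\nEND\n"


def make_conformer(xyz, source_id="toy", seq=1):
    atoms = [AtomRecord(name=f"C{i + 1}", element="C", xyz=tuple(p))
             for i, p in enumerate(np.asarray(xyz, dtype=float))]
    return LigandConformer(source_id=source_id, ligand_code="PLM", chain="A",
                           res_seq=seq, atoms=atoms)


ZIGZAG16 = np.array([[1.27 * i, 0.52 * (i % 2), 0.0] for i in range(16)])


class TestParsing:
    def test_hand_built_single_residue(self):
        conformers = parse_ligands(chain_pdb(ZIGZAG16), "PLM", source="fix")
        assert len(conformers) == 1
        conf = conformers[0]
        assert conf.ligand_code == "PLM"
        assert conf.carbon_names() == [f"C{i}" for i in range(1, 17)]
        np.testing.assert_allclose(conf.coords(conf.carbon_names()), ZIGZAG16,
                                   atol=1e-3)

    def test_empty_input_gives_empty_list(self):
        assert parse_ligands("END\n", "PLM") == []
        assert parse_ligands(chain_pdb(ZIGZAG16, res="PAM"), "PLM") == []

    def test_multiple_copies_kept_separate(self):
        text = (chain_pdb(ZIGZAG16, chain="A", seq=1)[:-5] + "\n"
                + chain_pdb(ZIGZAG16 + 5.0, chain="B", seq=9,
                            start_serial=40))
        confs = parse_ligands(text, "PLM", source="two")
        assert {(c.chain, c.res_seq) for c in confs} == {("A", 1), ("B", 9)}

    def test_altloc_resolved_to_highest_occupancy(self):
        lines = [
            hetatm(1, "C1", "PLM", "A", 1, 0.0, 0.0, 0.0, altloc="A", occ=0.6),
            hetatm(2, "C1", "PLM", "A", 1, 9.0, 9.0, 9.0, altloc="B", occ=0.4),
            hetatm(3, "C2", "PLM", "A", 1, 1.5, 0.0, 0.0),
            hetatm(4, "C3", "PLM", "A", 1, 3.0, 0.5, 0.0),
        ]
        conf = parse_ligands("\n".join(lines) + "\nEND\n", "PLM")[0]
        assert len([a for a in conf.atoms if a.name == "C1"]) == 1
        np.testing.assert_allclose(conf.coords(["C1"])[0], [0.0, 0.0, 0.0],
                                   atol=1e-3)

    def test_altloc_occupancy_tie_prefers_first_altloc(self):
        lines = [
            hetatm(1, "C1", "PLM", "A", 1, 1.0, 0.0, 0.0, altloc="B", occ=0.5),
            hetatm(2, "C1", "PLM", "A", 1, 2.0, 0.0, 0.0, altloc="A", occ=0.5),
            hetatm(3, "C2", "PLM", "A", 1, 3.0, 0.0, 0.0),
            hetatm(4, "C3", "PLM", "A", 1, 4.0, 0.5, 0.0),
        ]
        conf = parse_ligands("\n".join(lines) + "\nEND\n", "PLM")[0]
        np.testing.assert_allclose(conf.coords(["C1"])[0], [2.0, 0.0, 0.0],
                                   atol=1e-3)


class TestSuperposition:
    def test_identity(self):
        conf = make_conformer(ZIGZAG16)
        assert superpose_carbons(conf, conf).rmsd <= 1e-12

    def test_rigid_motion_recovered(self):
        ref = make_conformer(ZIGZAG16)
        rot = Rotation.from_rotvec(np.deg2rad(73.0) * np.array([1, 2, 0.5])
                                   / np.linalg.norm([1, 2, 0.5]))
        moved = make_conformer(rot.apply(ZIGZAG16) + [3.0, -2.0, 7.5])
        result = superpose_carbons(moved, ref)
        assert result.rmsd <= 1e-9
        assert abs(np.linalg.det(result.rotation) - 1.0) < 1e-9

    def test_rmsd_symmetric(self):
        rng = np.random.default_rng(0)
        a = make_conformer(rng.normal(size=(8, 3)))
        b = make_conformer(rng.normal(size=(8, 3)))
        assert abs(superpose_carbons(a, b).rmsd
                   - superpose_carbons(b, a).rmsd) < 1e-9

    def test_rmsd_invariant_under_rigid_motion_of_either_side(self):
        rng = np.random.default_rng(1)
        a_xyz = rng.normal(size=(6, 3))
        b_xyz = rng.normal(size=(6, 3))
        base = superpose_carbons(make_conformer(a_xyz),
                                 make_conformer(b_xyz)).rmsd
        rot = Rotation.from_euler("zyx", [10.0, 40.0, -25.0], degrees=True)
        moved_a = make_conformer(rot.apply(a_xyz) + [1.0, 2.0, 3.0])
        moved_b = make_conformer(rot.apply(b_xyz) - [4.0, 0.5, 2.0])
        assert abs(superpose_carbons(moved_a, make_conformer(b_xyz)).rmsd
                   - base) < 1e-9
        assert abs(superpose_carbons(make_conformer(a_xyz), moved_b).rmsd
                   - base) < 1e-9

    def test_matches_brute_force_rotation_grid_on_toys(self):
        # oracle: centroid alignment + exhaustive Euler-angle search, coarse
        # pass then 0.25°-resolution local refinement
        rng = np.random.default_rng(7)
        for _ in range(3):
            a_xyz = rng.normal(scale=2.0, size=(4, 3))
            b_xyz = rng.normal(scale=2.0, size=(4, 3))
            fit = superpose_carbons(make_conformer(a_xyz),
                                    make_conformer(b_xyz))
            a_c = a_xyz - a_xyz.mean(axis=0)
            b_c = b_xyz - b_xyz.mean(axis=0)

            def grid_best(center, span, step):
                axes = [np.arange(c - span, c + span + 1e-9, step)
                        for c in center]
                mesh = np.stack(np.meshgrid(*axes, indexing="ij"),
                                axis=-1).reshape(-1, 3)
                mats = Rotation.from_euler("zyz", mesh, degrees=True
                                           ).as_matrix()
                rotated = np.einsum("rij,nj->rni", mats, a_c)
                rmsds = np.sqrt(((rotated - b_c) ** 2).sum(axis=(1, 2))
                                / len(a_c))
                k = int(np.argmin(rmsds))
                return mesh[k], float(rmsds[k])

            center, best = grid_best((0.0, 90.0, 0.0), 180.0, 6.0)
            for span, step in ((6.0, 1.0), (1.0, 0.25)):
                center, best = grid_best(center, span, step)
            r_max = np.linalg.norm(a_c, axis=1).max()
            tolerance = r_max * np.deg2rad(0.5)
            assert fit.rmsd <= best + 1e-9
            assert best - fit.rmsd <= tolerance

    def test_common_subset_when_atoms_missing(self):
        ref = make_conformer(ZIGZAG16)
        partial = make_conformer(ZIGZAG16[:10])
        result = superpose_carbons(partial, ref)
        assert result.n_matched == 10
        assert result.rmsd <= 1e-9

    def test_too_few_matched_atoms_names_the_missing(self):
        ref = make_conformer(ZIGZAG16)
        tiny = make_conformer(ZIGZAG16[:2])
        with pytest.raises(SuperpositionError, match="C3"):
            superpose_carbons(tiny, ref)

    def test_no_reflection_even_for_mirrored_input(self):
        xyz = np.array([[0, 0, 0], [1.5, 0, 0], [2.2, 1.3, 0], [2.9, 1.8, 1.4]],
                       dtype=float)
        mirrored = xyz * [1.0, 1.0, -1.0]
        result = superpose_carbons(make_conformer(mirrored),
                                   make_conformer(xyz))
        assert np.linalg.det(result.rotation) > 0.999999999
        assert result.rmsd > 0.1  # a reflection could cheat this to ~0


class TestDensity:
    def test_identical_conformers_fill_first_bin(self):
        ref = make_conformer(ZIGZAG16)
        copies = [make_conformer(ZIGZAG16, source_id=f"c{i}") for i in range(5)]
        density = rmsd_density(copies, ref)
        assert density.frequencies[0] == pytest.approx(1.0)
        assert abs(density.frequencies.sum() - 1.0) < 1e-12

    @staticmethod
    def planar_procrustes_rmsd(a_xyz, b_xyz):
        """Closed-form optimal proper-rotation RMSD for planar (z = 0) sets.

        In-plane rotation Procrustes gives cost Σ|a|² + Σ|b|² − 2√(C² + S²)
        with C = Σ a·b and S = Σ a×b over centered coordinates; a proper 3D
        rotation can also flip the plane (180° about an in-plane axis),
        which mirrors the in-plane coordinates, so the optimum is the better
        of the two orientations.
        """
        a = a_xyz[:, :2] - a_xyz[:, :2].mean(axis=0)
        b = b_xyz[:, :2] - b_xyz[:, :2].mean(axis=0)
        best = np.inf
        for mirrored in (b, b * [1.0, -1.0]):
            c = float((a * mirrored).sum())
            s = float((a[:, 0] * mirrored[:, 1] - a[:, 1] * mirrored[:, 0]).sum())
            cost = (a**2).sum() + (mirrored**2).sum() - 2.0 * np.hypot(c, s)
            best = min(best, max(cost, 0.0))
        return np.sqrt(best / len(a))

    def test_histogram_matches_closed_form_rmsds(self):
        ref = make_conformer(ZIGZAG16)
        rng = np.random.default_rng(11)
        confs, oracle = [], []
        for i in range(5):
            xyz = ZIGZAG16.copy()
            xyz[:, :2] += rng.normal(scale=0.3 + 0.6 * i, size=(16, 2))
            confs.append(make_conformer(xyz, source_id=f"c{i}"))
            oracle.append(self.planar_procrustes_rmsd(xyz, ZIGZAG16))
        for conf, want in zip(confs, oracle):
            assert abs(superpose_carbons(conf, ref).rmsd - want) < 1e-9
        density = rmsd_density(confs, ref, n_bins=4, bin_range=(0.0, 6.0))
        counts, _ = np.histogram(oracle, bins=4, range=(0.0, 6.0))
        np.testing.assert_allclose(density.frequencies, counts / 5.0,
                                   atol=1e-12)
        assert abs(density.frequencies.sum() - 1.0) < 1e-12

    def test_rotamer_ensembles_span_multiple_bins(self):
        ref = rt.generate_conformers(ConformerSpec(
            dihedral_model="all_trans", n_conformers=1))[0]
        sat = rt.generate_conformers(ConformerSpec(
            dihedral_model="rotamer_sampled", n_conformers=200, seed=1))
        kinked = rt.generate_conformers(ConformerSpec(
            dihedral_model="rotamer_sampled", cis_bond_index=9,
            n_conformers=200, seed=2))
        for ensemble in (sat, kinked):
            density = rmsd_density(ensemble, ref, n_bins=20)
            assert np.count_nonzero(density.frequencies) >= 5
            assert abs(density.frequencies.sum() - 1.0) < 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rmsd_density([], make_conformer(ZIGZAG16))


class TestClosest:
    def test_exact_copy_wins_with_zero_rmsd(self):
        ref = make_conformer(ZIGZAG16)
        rng = np.random.default_rng(3)
        others = [make_conformer(ZIGZAG16 + rng.normal(scale=0.5, size=(16, 3)),
                                 source_id=f"noisy{i}") for i in range(4)]
        copy = make_conformer(ZIGZAG16, source_id="copy")
        source, rmsd = closest_conformer(others + [copy], ref)
        assert source == "copy"
        assert rmsd <= 1e-12

    def test_tie_broken_lexicographically(self):
        ref = make_conformer(ZIGZAG16)
        shifted = ZIGZAG16.copy()
        shifted[0, 1] += 1.0
        twin_b = make_conformer(shifted, source_id="beta")
        twin_a = make_conformer(shifted, source_id="alpha")
        source, _ = closest_conformer([twin_b, twin_a], ref)
        assert source == "alpha"

    def test_matches_enumeration_of_individual_rmsds(self):
        ref = rt.generate_conformers(ConformerSpec(
            dihedral_model="all_trans", n_conformers=1))[0]
        ensemble = rt.generate_conformers(ConformerSpec(
            dihedral_model="rotamer_sampled", n_conformers=10, seed=6))
        rmsds = {c.source_id: superpose_carbons(c, ref).rmsd for c in ensemble}
        source, rmsd = closest_conformer(ensemble, ref)
        assert rmsd == pytest.approx(min(rmsds.values()))
        assert source == min(rmsds, key=lambda k: (rmsds[k], k))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            closest_conformer([], make_conformer(ZIGZAG16))
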