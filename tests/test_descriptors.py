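import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from spirospace.descriptors import (
    EA_TO_DEBYE,
    DescriptorError,
    asphericity,
    compute_descriptor_vector,
    dipole_moment,
    molecular_volume,
    plane_of_best_fit,
    strain_energy,
)
from spirospace.geometry import Conformer3D, embed_and_optimize
from spirospace.library import ScaffoldRecord

from conftest import random_rotation


def make_conf(symbols, coords, charges=None):
    coords = np.asarray(coords, float)
    charges = np.zeros(len(symbols)) if charges is None else np.asarray(charges, float)
    return Conformer3D("t", list(symbols), coords, charges, "forcefield")


class TestPlaneOfBestFit:
    def test_planar_points_give_zero(self, rng):
        pts = np.column_stack([rng.normal(size=(6, 2)), np.zeros(6)])
        assert plane_of_best_fit(pts) == 0.0

    def test_three_or_fewer_points_give_zero(self, rng):
        assert plane_of_best_fit(rng.normal(size=(2, 3))) == 0.0
        assert plane_of_best_fit(rng.normal(size=(3, 3))) == 0.0

    def test_regular_tetrahedron_closed_form(self):
        # unit-edge tetrahedron; symmetry puts all 4 vertices at sqrt(2)/4
        # from any face-parallel centroid plane
        tet = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(8)
        assert plane_of_best_fit(tet) == pytest.approx(np.sqrt(2) / 4, abs=1e-12)

    def test_matches_exhaustive_plane_search(self, rng):
        """The eigen-based plane is the least-squares optimum over a dense normal scan,
        and the reported value is the mean absolute distance at that plane."""
        pts = rng.normal(size=(7, 3))
        centered = pts - pts.mean(axis=0)
        scan_best = np.inf
        for theta in np.linspace(0, np.pi, 60):
            for phi in np.linspace(0, 2 * np.pi, 120):
                n = np.array(
                    [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
                )
                scan_best = min(scan_best, float(((centered @ n) ** 2).mean()))
        _, v = np.linalg.eigh(centered.T @ centered)
        eigen_obj = float(((centered @ v[:, 0]) ** 2).mean())
        assert eigen_obj <= scan_best + 1e-6
        assert plane_of_best_fit(pts) == pytest.approx(
            np.abs(centered @ v[:, 0]).mean(), abs=1e-12
        )


class TestAsphericity:
    def test_collinear_points_give_one(self):
        pts = np.outer(np.arange(5.0), [1.0, 2.0, -1.0])
        assert asphericity(pts) == pytest.approx(1.0, abs=1e-12)

    def test_cube_vertices_give_zero(self):
        cube = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], float)
        assert asphericity(cube) == pytest.approx(0.0, abs=1e-12)

    def test_planar_square_hand_eigenvalues(self):
        # lambda1 = lambda2, lambda3 = 0 -> A = 2*l1^2 / (2*(2*l1)^2) = 1/4
        square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        assert asphericity(square) == pytest.approx(0.25, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(DescriptorError):
            asphericity(np.empty((0, 3)))


class TestDipole:
    def test_zero_charges_give_zero(self, rng):
        conf = make_conf(["C"] * 4, rng.normal(size=(4, 3)))
        assert dipole_moment(conf) == 0.0

    def test_unit_separation_half_charges(self):
        conf = make_conf(["H", "H"], [[0, 0, 0], [1, 0, 0]], [0.5, -0.5])
        assert dipole_moment(conf) == pytest.approx(2.40160, abs=1e-9)

    def test_water_point_charges_hand_vector_sum(self):
        # TIP3P-like charges on an experimental-ish geometry; oracle is the
        # explicit component-wise sum done by hand here
        coords = np.array([[0, 0, 0], [0.9572, 0, 0], [-0.2399872, 0.9266272, 0]])
        q = np.array([-0.834, 0.417, 0.417])
        conf = make_conf(["O", "H", "H"], coords, q)
        mu_vec = (
            q[0] * coords[0] + q[1] * coords[1] + q[2] * coords[2]
        )
        assert dipole_moment(conf) == pytest.approx(
            np.sqrt((mu_vec**2).sum()) * EA_TO_DEBYE, abs=1e-12
        )

    def test_neutral_dipole_invariant_under_origin_shift(self, piperidine_conf, rng):
        d0 = dipole_moment(piperidine_conf)
        shifted = Conformer3D(
            "t",
            piperidine_conf.symbols,
            piperidine_conf.coords + rng.normal(size=3) * 10,
            piperidine_conf.charges,
            "forcefield",
        )
        assert dipole_moment(shifted) == pytest.approx(d0, abs=1e-8)

    def test_net_charged_species_warns(self):
        conf = make_conf(["N"], [[0, 0, 0]], [1.0])
        with pytest.warns(UserWarning, match="origin-dependent"):
            dipole_moment(conf)


class TestVolume:
    def test_single_carbon_matches_analytic_sphere(self):
        conf = make_conf(["C"], [[0, 0, 0]])
        analytic = 4.0 / 3.0 * np.pi * 1.70**3
        assert molecular_volume(conf, 0.1) == pytest.approx(analytic, rel=0.02)

    def test_fully_overlapping_atoms_add_nothing(self):
        from spirospace.descriptors import union_volume

        one = union_volume(["C"], [[0, 0, 0]], 0.1)
        two = union_volume(["C", "C"], [[0, 0, 0], [0, 0, 0]], 0.1)
        assert two == pytest.approx(one, abs=1e-9)

    def test_monotone_under_adding_an_atom(self):
        base = make_conf(["C", "C"], [[0, 0, 0], [1.5, 0, 0]])
        more = make_conf(["C", "C", "C"], [[0, 0, 0], [1.5, 0, 0], [3.0, 0, 0]])
        assert molecular_volume(more, 0.2) >= molecular_volume(base, 0.2)

    def test_grid_convergence_on_benzene(self):
        conf = embed_and_optimize(ScaffoldRecord("bz", "c1ccccc1"), n_starts=3, seed=1)
        v_coarse = molecular_volume(conf, 0.2)
        v_fine = molecular_volume(conf, 0.1)
        assert abs(v_fine - v_coarse) / v_fine < 0.02

    def test_bad_spacing_rejected(self):
        with pytest.raises(DescriptorError):
            molecular_volume(make_conf(["C"], [[0, 0, 0]]), 0.0)


class TestStrainEnergy:
    def test_acyclic_molecule_has_zero_proxy_strain(self):
        rec = ScaffoldRecord("prop", "CCC")
        assert strain_energy(rec, mode="ff_proxy", n_starts=2, seed=1) == 0.0

    def test_external_qc_unit_conversion(self):
        rec = ScaffoldRecord("x", "C1CC1")
        val = strain_energy(rec, mode="external_qc", qc_energies=(-100.0, -100.01))
        assert val == pytest.approx(6.275095, abs=1e-9)

    def test_external_qc_requires_energies(self):
        with pytest.raises(DescriptorError):
            strain_energy(ScaffoldRecord("x", "C1CC1"), mode="external_qc")

    def test_three_ring_more_strained_than_six_ring(self):
        small = ScaffoldRecord("c3", "C1CC1")
        large = ScaffoldRecord("c6", "C1CCCCC1")
        e3 = strain_energy(small, embed_and_optimize(small, 3, 1), n_starts=3, seed=1)
        e6 = strain_energy(large, embed_and_optimize(large, 3, 1), n_starts=3, seed=1)
        assert e3 > e6

    def test_fused_aromatic_ring_opening_succeeds(self):
        rec = ScaffoldRecord("ind", "c1ccc2[nH]ccc2c1")
        val = strain_energy(rec, n_starts=2, seed=1)
        assert np.isfinite(val)


class TestDescriptorVector:
    def test_benzene_composition_forced_values(self):
        rec = ScaffoldRecord("bz", "c1ccccc1")
        vec = compute_descriptor_vector(rec, embed_and_optimize(rec, 3, 1))
        assert vec["n_heteroatoms"] == 0
        assert vec["hbd"] == 0

    def test_piperidine_composition_forced_values(self, piperidine, piperidine_conf):
        vec = compute_descriptor_vector(piperidine, piperidine_conf)
        assert vec["n_heteroatoms"] == 1
        assert vec["fraction_sp3"] == 1.0

    def test_morpholine_tpsa_matches_increment_table(self):
        # published fragment increments: ring secondary amine N 12.03, ether O 9.23
        rec = ScaffoldRecord("mor", "C1COCCN1")
        vec = compute_descriptor_vector(rec, embed_and_optimize(rec, 3, 1))
        assert vec["tpsa"] == pytest.approx(12.03 + 9.23, abs=1e-6)
        # cross-check our oracle against the library's own TPSA
        assert vec["tpsa"] == pytest.approx(
            rdMolDescriptors.CalcTPSA(Chem.MolFromSmiles("C1COCCN1")), abs=1e-9
        )

    def test_wrong_conformer_rejected(self, piperidine):
        other = embed_and_optimize(ScaffoldRecord("bz", "c1ccccc1"), 2, 1)
        with pytest.raises(DescriptorError, match="belong"):
            compute_descriptor_vector(piperidine, other)

    def test_recomputation_reproduces_exactly(self, piperidine, piperidine_conf):
        a = compute_descriptor_vector(piperidine, piperidine_conf)
        b = compute_descriptor_vector(piperidine, piperidine_conf)
        assert a.values == b.values


class TestRigidMotionInvariance:
    @pytest.mark.parametrize("n_rotations", [10])
    def test_pbf_asphericity_dipole_volume(self, small_conformers, rng, n_rotations):
        for _, conf in small_conformers:
            heavy = conf.heavy_mask()
            ref = (
                plane_of_best_fit(conf.coords[heavy]),
                asphericity(conf.coords),
                dipole_moment(conf),
                molecular_volume(conf, 0.2),
            )
            for _ in range(n_rotations):
                q = random_rotation(rng)
                moved = Conformer3D(
                    conf.scaffold_id,
                    conf.symbols,
                    conf.coords @ q.T + rng.normal(size=3) * 5,
                    conf.charges,
                    conf.provenance,
                )
                got = (
                    plane_of_best_fit(moved.coords[moved.heavy_mask()]),
                    asphericity(moved.coords),
                    dipole_moment(moved),
                    molecular_volume(moved, 0.2),
                )
                assert np.allclose(got, ref, atol=1e-8)
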