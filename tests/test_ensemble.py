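"""Superposition, RMSF, radial profiles and water contacts."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from coldscan import ensemble_analysis as ea
from coldscan import synthetic_data as sd
from coldscan.errors import DegenerateFitError


def brute_force_rmsf(coords):
    """Literal double-loop evaluation of the fluctuation formula."""
    M, S, N, _ = coords.shape
    out = np.zeros((S, N))
    for s in range(S):
        for n in range(N):
            mean = np.zeros(3)
            for m in range(M):
                mean += coords[m, s, n]
            mean /= M
            acc = 0.0
            for m in range(M):
                d = coords[m, s, n] - mean
                acc += float(d @ d)
            out[s, n] = np.sqrt(acc / M)
    return out.mean(axis=0)


class TestSuperimpose:
    def test_identity_on_reference(self):
        ens = sd.gen_coordinate_ensemble(sd.EnsembleSimConfig(
            n_residues=5, n_snapshots=1, sigma=0.0, bulk_waters_per_residue=0))
        aligned = ea.superimpose(ens)
        np.testing.assert_allclose(aligned.coords, ens.coords, atol=1e-10)

    def test_known_rigid_transform_recovered(self, rng):
        ens = sd.gen_coordinate_ensemble(sd.EnsembleSimConfig(
            n_residues=6, n_snapshots=3, sigma=0.0, bulk_waters_per_residue=0))
        R = Rotation.random(random_state=42).as_matrix()
        t = np.array([5.0, -3.0, 11.0])
        moved = ea.CoordinateEnsemble(
            coords=np.einsum("msnj,ij->msni", ens.coords, R) + t,
            reference=ens.reference)
        aligned = ea.superimpose(moved)
        rmsd = np.sqrt(np.mean(np.sum(
            (aligned.coords - ens.reference[None]) ** 2, axis=-1)))
        assert rmsd < 1e-8

    def test_kabsch_agrees_with_scipy(self, rng):
        """Independent cross-check against scipy's align_vectors."""
        P = rng.normal(size=(12, 3))
        R_true = Rotation.random(random_state=7).as_matrix()
        Q = P @ R_true.T + np.array([1.0, 2.0, 3.0])
        R_fit, t_fit = ea.kabsch_transform(P, Q)
        rot_scipy, _ = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        np.testing.assert_allclose(R_fit, rot_scipy.as_matrix(), atol=1e-8)
        np.testing.assert_allclose(P @ R_fit.T + t_fit, Q, atol=1e-8)

    def test_mirror_image_keeps_proper_rotation(self, rng):
        P = rng.normal(size=(10, 3))
        Q = P.copy()
        Q[:, 2] *= -1  # reflection
        R_fit, _ = ea.kabsch_transform(P, Q)
        assert np.linalg.det(R_fit) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_reference_rejected(self):
        line = np.stack([np.arange(5.0), np.zeros(5), np.zeros(5)], axis=1)
        with pytest.raises(DegenerateFitError):
            ea.kabsch_transform(line + 0.1, line)


class TestRMSF:
    def test_single_snapshot_is_zero(self):
        ens = sd.gen_coordinate_ensemble(sd.EnsembleSimConfig(
            n_residues=4, n_snapshots=1, sigma=1.0, bulk_waters_per_residue=0))
        np.testing.assert_allclose(ea.rmsf(ens).rmsf, 0.0, atol=1e-12)

    def test_zero_sigma_profile_is_zero(self):
        ens = sd.gen_coordinate_ensemble(sd.EnsembleSimConfig(
            n_residues=4, n_snapshots=10, sigma=0.0, bulk_waters_per_residue=0))
        np.testing.assert_allclose(ea.rmsf(ens).rmsf, 0.0, atol=1e-12)

    def test_two_snapshot_offset_hand_value(self):
        """Two snapshots at +/-d along x for one residue give RMSF = d."""
        coords = np.zeros((2, 1, 3, 3))
        coords[0, 0, 1, 0] = +0.7
        coords[1, 0, 1, 0] = -0.7
        # spread the other residues so the cloud is not degenerate
        coords[:, 0, 0] = [10.0, 0.0, 0.0]
        coords[:, 0, 2] = [0.0, 10.0, 0.0]
        prof = ea.rmsf(ea.CoordinateEnsemble(coords=coords))
        assert prof.rmsf[1] == pytest.approx(0.7, abs=1e-12)
        assert prof.rmsf[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force(self, rng):
        coords = rng.normal(size=(7, 2, 5, 3))
        ens = ea.CoordinateEnsemble(coords=coords)
        np.testing.assert_allclose(ea.rmsf(ens).rmsf, brute_force_rmsf(coords),
                                   atol=1e-12)

    def test_isotropic_gaussian_limit(self):
        """RMSF converges to sigma*sqrt(3) for isotropic fluctuations.

        Superposition absorbs the 6 rigid-body degrees of freedom and
        shrinks RMSF by ~sqrt(1 - 2/N_atoms), so the closed-form limit
        is approached once the system is large enough for that
        finite-size bias to vanish inside the tolerance."""
        sigma = 0.8
        ens = sd.gen_coordinate_ensemble(sd.EnsembleSimConfig(
            n_residues=32, n_snapshots=10000, sigma=sigma,
            bulk_waters_per_residue=0, seed=3))
        prof = ea.rmsf(ea.superimpose(ens))
        np.testing.assert_allclose(prof.rmsf, sigma * np.sqrt(3), rtol=0.02)

    def test_subunit_permutation_invariance(self, rng):
        coords = rng.normal(size=(6, 4, 5, 3))
        base = ea.rmsf(ea.CoordinateEnsemble(coords=coords)).rmsf
        perm = ea.rmsf(ea.CoordinateEnsemble(
            coords=coords[:, [2, 0, 3, 1]])).rmsf
        np.testing.assert_allclose(base, perm, atol=1e-12)


class TestFractionalChange:
    def test_identical_profiles(self):
        p = ea.RMSFProfile(rmsf=np.array([1.0, 2.0, 3.0]))
        frac, sig = ea.fractional_rmsf_change(p, p)
        np.testing.assert_allclose(frac, 0.0)
        assert not sig.any()

    def test_warm_larger_than_cold(self):
        cold = ea.RMSFProfile(rmsf=np.array([2.0]))
        warm = ea.RMSFProfile(rmsf=np.array([3.0]))
        frac, sig = ea.fractional_rmsf_change(cold, warm)
        assert frac[0] == pytest.approx(-0.5)
        assert sig[0]

    def test_flags_match_brute_thresholding(self, rng):
        c = rng.uniform(0.5, 3.0, 30)
        w = rng.uniform(0.5, 3.0, 30)
        frac, sig = ea.fractional_rmsf_change(ea.RMSFProfile(rmsf=c),
                                              ea.RMSFProfile(rmsf=w))
        expected = np.abs((c - w) / c) > 0.20
        np.testing.assert_array_equal(sig, expected)

    def test_zero_cold_rmsf_is_undefined(self):
        cold = ea.RMSFProfile(rmsf=np.array([0.0, 1.0]))
        warm = ea.RMSFProfile(rmsf=np.array([1.0, 1.0]))
        frac, sig = ea.fractional_rmsf_change(cold, warm)
        assert np.isnan(frac[0]) and not sig[0]


class TestRadialRg:
    def test_ring_radius_recovered(self):
        ens = sd.gen_coordinate_ensemble(sd.EnsembleSimConfig(
            n_residues=3, n_snapshots=5, sigma=0.0, ring_radii=18.0,
            bulk_waters_per_residue=0))
        np.testing.assert_allclose(ea.radial_rg(ens), 18.0, atol=1e-10)

    def test_atoms_on_axis_give_zero(self):
        coords = np.zeros((2, 1, 4, 3))
        coords[:, 0, :, 2] = np.arange(4.0)[None, :]  # along z
        ens = ea.CoordinateEnsemble(coords=coords)
        np.testing.assert_allclose(ea.radial_rg(ens), 0.0, atol=1e-12)

    def test_cold_contraction_gives_negative_delta(self):
        cold = sd.gen_coordinate_ensemble(sd.EnsembleSimConfig(
            n_residues=4, n_snapshots=10, sigma=0.0, ring_radii=22.0,
            bulk_waters_per_residue=0, seed=1))
        warm = sd.gen_coordinate_ensemble(sd.EnsembleSimConfig(
            n_residues=4, n_snapshots=10, sigma=0.0, ring_radii=25.0,
            bulk_waters_per_residue=0, seed=2))
        delta = ea.delta_radial_rg(cold, warm)
        np.testing.assert_allclose(delta, -3.0, atol=1e-10)

    def test_rigid_transform_invariance_after_superposition(self, rng):
        ens = sd.gen_coordinate_ensemble(sd.EnsembleSimConfig(
            n_residues=4, n_snapshots=6, sigma=0.4,
            bulk_waters_per_residue=0, seed=9))
        base = ea.radial_rg(ea.superimpose(ens))
        R = Rotation.random(random_state=1).as_matrix()
        t = np.array([3.0, 4.0, -2.0])
        moved = ea.CoordinateEnsemble(
            coords=np.einsum("msnj,ij->msni", ens.coords, R) + t,
            reference=ens.reference)
        np.testing.assert_allclose(ea.radial_rg(ea.superimpose(moved)), base,
                                   atol=1e-8)


class TestWaterContacts:
    def test_no_waters_returns_zero_with_warning(self, caplog):
        ens = sd.gen_coordinate_ensemble(sd.EnsembleSimConfig(
            n_residues=3, n_snapshots=2, sigma=0.0, bulk_waters_per_residue=0))
        counts = ea.mean_water_contacts(ens)
        np.testing.assert_allclose(counts, 0.0)

    def test_planted_counts_recovered_exactly(self):
        plant = (0, 8, 0, 3, 0)
        ens = sd.gen_coordinate_ensemble(sd.EnsembleSimConfig(
            n_residues=5, n_snapshots=4, sigma=0.5,
            planted_water_counts=plant, seed=5))
        counts = ea.mean_water_contacts(ens)
        np.testing.assert_allclose(counts, plant, atol=1e-12)

    def test_cutoff_is_strict(self):
        coords = np.zeros((1, 1, 3, 3))
        coords[0, 0, 1] = [30.0, 0.0, 0.0]
        coords[0, 0, 2] = [0.0, 30.0, 0.0]
        waters = [np.array([[3.5, 0.0, 0.0],      # exactly at the cutoff
                            [3.4999, 0.0, 0.0]])]  # just inside
        ens = ea.CoordinateEnsemble(coords=coords, waters=waters)
        assert ea.count_water_contacts(ens, 0, 0, cutoff=3.5) == pytest.approx(1.0)

    def test_delta_contacts_planted_gain(self):
        plant_cold = (0, 8, 0)
        plant_warm = (0, 0, 0)
        cold = sd.gen_coordinate_ensemble(sd.EnsembleSimConfig(
            n_residues=3, n_snapshots=5, sigma=0.0,
            planted_water_counts=plant_cold, seed=1))
        warm = sd.gen_coordinate_ensemble(sd.EnsembleSimConfig(
            n_residues=3, n_snapshots=5, sigma=0.0,
            planted_water_counts=plant_warm, seed=2))
        delta = ea.delta_water_contacts(cold, warm)
        np.testing.assert_allclose(delta, [0.0, 8.0, 0.0], atol=1e-12)


class TestPdbIO:
    def test_round_trip_preserves_descriptors(self, tmp_path):
        ens = sd.gen_coordinate_ensemble(sd.EnsembleSimConfig(
            n_residues=4, n_snapshots=3, sigma=0.5,
            planted_water_counts=(0, 5, 0, 0), seed=21))
        path = tmp_path / "ens.pdb"
        ea.write_pdb(ens, path)
        back = ea.read_pdb(path)
        assert back.coords.shape == ens.coords.shape
        # PDB stores 3 decimals; descriptors survive at that precision
        np.testing.assert_allclose(back.coords, ens.coords, atol=5e-3)
        np.testing.assert_allclose(ea.mean_water_contacts(back),
                                   ea.mean_water_contacts(ens), atol=1e-9)
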