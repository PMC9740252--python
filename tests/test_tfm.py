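"""Traction force microscopy: registration, displacement, FTTC, energy."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from epimech import synthetic, tfm
from epimech.core import IntensityImage, InputError
from epimech.tfm import (DisplacementField, RegistrationError, TractionField,
                         displacement_field, filter_islands, fold_normalise,
                         forward_displacement, fttc, register_drift,
                         strain_energy)


def dipole_field(n=128, h=2.6, amp=400.0, sep=60.0, width=10.0,
                 E=16400.0, nu=0.5):
    gx = (np.arange(n) + 0.5) * h
    spots = synthetic.dipole_spots((gx.mean(), gx.mean()), sep, amp, width)
    T = synthetic.gaussian_traction_spots(spots, gx, gx)
    return TractionField(T, h, E, nu)


class TestFttc:
    def test_roundtrip_machine_precision_on_shared_grid(self):
        T = dipole_field()
        u = forward_displacement(T, pad_factor=1)
        rec = fttc(u, T.E, T.nu, pad_factor=1)
        rel = (np.sqrt(np.mean((rec.T - T.T) ** 2))
               / np.sqrt(np.mean(T.T ** 2)))
        assert rel < 1e-6

    def test_roundtrip_through_padded_forward(self):
        # forward on the x2 padded domain, uncropped; inverting that field
        # returns the padded traction exactly
        T = dipole_field(n=64)
        u_full = forward_displacement(T, pad_factor=2, crop=False)
        rec = fttc(u_full, T.E, T.nu, pad_factor=1)
        rel = (np.sqrt(np.mean((rec.T[:64, :64] - T.T) ** 2))
               / np.sqrt(np.mean(T.T ** 2)))
        assert rel < 1e-6

    def test_zero_displacement_zero_traction(self):
        u = DisplacementField(np.zeros((32, 32, 2)), h=2.6)
        rec = fttc(u, 16400.0, 0.5)
        np.testing.assert_allclose(rec.T, 0.0)

    def test_traction_linear_in_young_modulus(self):
        T = dipole_field(n=64)
        u = forward_displacement(T, pad_factor=1)
        t1 = fttc(u, 16400.0, 0.5, pad_factor=1)
        t2 = fttc(u, 32800.0, 0.5, pad_factor=1)
        np.testing.assert_allclose(t2.T, 2.0 * t1.T, rtol=1e-10)

    def test_balanced_traction_net_force_vanishes_with_resolution(self):
        sums = []
        for n in (32, 64, 128):
            T = dipole_field(n=n)
            u = forward_displacement(T, pad_factor=1)
            rec = fttc(u, T.E, T.nu, pad_factor=1)
            net = np.abs(rec.T.sum(axis=(0, 1)))
            sums.append(np.hypot(*net) / np.abs(rec.T).sum())
        assert sums[-1] < 1e-6

    def test_invalid_elastic_parameters(self):
        u = DisplacementField(np.zeros((8, 8, 2)))
        with pytest.raises(InputError):
            fttc(u, -1.0, 0.5)
        with pytest.raises(InputError):
            fttc(u, 100.0, 0.7)


class TestRegisterDrift:
    def test_identical_images_zero_shift(self, tfm_dipole):
        (rel, _), _ = tfm_dipole
        (dx, dy), _ = register_drift(rel, rel)
        assert abs(dx) < 1e-6 and abs(dy) < 1e-6

    def test_known_subpixel_shift_recovered(self, tfm_dipole):
        (rel, _), _ = tfm_dipole
        shifted = ndimage.shift(rel.pixels, (-1.5, 3.25), order=3,
                                mode="nearest")
        moved = IntensityImage(np.clip(shifted, 0, None), rel.pixel_size)
        (dx, dy), registered = register_drift(moved, rel)
        assert dx == pytest.approx(3.25, abs=0.1)
        assert dy == pytest.approx(-1.5, abs=0.1)
        # registered relaxed image is resampled into the stressed frame
        core_region = (slice(10, -10), slice(10, -10))
        assert np.corrcoef(registered.pixels[core_region].ravel(),
                           moved.pixels[core_region].ravel())[0, 1] > 0.99

    def test_uncorrelated_noise_raises(self, rng):
        a = IntensityImage(rng.uniform(0, 100, (128, 128)))
        b = IntensityImage(rng.uniform(0, 100, (128, 128)))
        with pytest.raises(RegistrationError):
            register_drift(a, b)


class TestDisplacementField:
    def test_identical_pair_zero_field(self, tfm_dipole):
        (rel, _), _ = tfm_dipole
        u = displacement_field(rel, rel, h=2.6)
        assert np.sqrt(np.mean(u.u ** 2)) < 1e-3

    def test_recovers_forward_model_truth(self, tfm_dipole):
        (rel, st), truth = tfm_dipole
        u = displacement_field(st, rel, h=2.6)
        rms = np.sqrt(np.mean((u.u - truth.displacement.u) ** 2))
        assert rms < 0.05

    def test_registration_removes_uniform_translation(self, tfm_dipole):
        (rel, _), _ = tfm_dipole
        shifted = ndimage.shift(rel.pixels, (2.0, -3.0), order=3,
                                mode="nearest")
        moved = IntensityImage(np.clip(shifted, 0, None), rel.pixel_size)
        _, registered = register_drift(moved, rel)
        u = displacement_field(moved, registered, h=2.6)
        assert np.sqrt(np.mean(u.u ** 2)) < 0.02


class TestStrainEnergy:
    def test_zero_traction_zero_energy(self):
        u = DisplacementField(np.ones((16, 16, 2)), h=2.6)
        T = TractionField(np.zeros((16, 16, 2)), 2.6, 16400.0, 0.5)
        e = strain_energy(u, T, np.ones((16, 16), bool))
        assert e.U == 0.0 and e.density == 0.0

    def test_quadratic_scaling(self):
        T = dipole_field(n=64)
        u = forward_displacement(T, pad_factor=1)
        mask = np.hypot(T.T[..., 0], T.T[..., 1]) > 0.01 * np.abs(T.T).max()
        e1 = strain_energy(u, T, mask)
        T2 = TractionField(2 * T.T, T.h, T.E, T.nu)
        u2 = DisplacementField(2 * u.u, u.h)
        e2 = strain_energy(u2, T2, mask)
        assert e2.U == pytest.approx(4 * e1.U, rel=1e-12)

    def test_unit_conversion_pa_um3_to_joule(self):
        # uniform T.u product: U = 0.5 * dot * n_nodes * h^2 * 1e-18 J
        u = DisplacementField(np.full((4, 4, 2), 2.0), h=1.0)
        T = TractionField(np.full((4, 4, 2), 3.0), 1.0, 1000.0, 0.5)
        e = strain_energy(u, T, np.ones((4, 4), bool))
        assert e.U == pytest.approx(0.5 * (2 * 2.0 * 3.0) * 16 * 1e-18)

    def test_empty_mask_raises(self):
        u = DisplacementField(np.zeros((8, 8, 2)))
        T = TractionField(np.zeros((8, 8, 2)), 2.6, 100.0, 0.5)
        with pytest.raises(InputError):
            strain_energy(u, T, np.zeros((8, 8), bool))

    def test_energy_invariant_under_rigid_translation_of_pair(self, tfm_dipole):
        (rel, st), truth = tfm_dipole
        u0 = displacement_field(st, rel, h=2.6)
        T0 = fttc(u0, *truth.substrate)
        e0 = strain_energy(u0, T0, truth.island_mask)
        shifted = IntensityImage(
            np.clip(ndimage.shift(rel.pixels, (1.6, -2.3), order=3,
                                  mode="nearest"), 0, None), rel.pixel_size)
        st_shifted = IntensityImage(
            np.clip(ndimage.shift(st.pixels, (1.6, -2.3), order=3,
                                  mode="nearest"), 0, None), st.pixel_size)
        u1 = displacement_field(st_shifted, shifted, h=2.6)
        T1 = fttc(u1, *truth.substrate)
        e1 = strain_energy(u1, T1, truth.island_mask)
        assert e1.U == pytest.approx(e0.U, rel=0.1)


class TestIslandFilter:
    def test_balanced_kept_unbalanced_discarded(self, tfm_dipole):
        (rel, st), truth = tfm_dipole
        u = displacement_field(st, rel, h=2.6)
        T = fttc(u, *truth.substrate)
        balanced = strain_energy(u, T, truth.island_mask, island_id=1)
        assert balanced.net_force_ratio <= 0.10

        spots = [(48.0, 48.0, 400.0, 6.0, (1.0, 0.0))]   # single spot
        (rel1, st1), truth1 = synthetic.make_tfm_pair(spots, domain_um=96.0,
                                                      seed=2)
        u1 = displacement_field(st1, rel1, h=2.6)
        T1 = fttc(u1, *truth1.substrate)
        single = strain_energy(u1, T1, truth1.island_mask, island_id=2)
        assert single.net_force_ratio > 0.5

        kept, discarded = filter_islands([balanced, single])
        assert [k.island_id for k in kept] == [1]
        assert [d.island_id for d, _ in discarded] == [2]
        assert discarded[0][1] == "out_of_equilibrium"

    def test_threshold_is_inclusive_at_ten_percent(self):
        just_ok = tfm.IslandEnergy(1e-15, 100.0, 1e-17, 0.10, island_id=1)
        just_over = tfm.IslandEnergy(1e-15, 100.0, 1e-17, 0.100001,
                                     island_id=2)
        kept, discarded = filter_islands([just_ok, just_over])
        assert [k.island_id for k in kept] == [1]
        assert [d.island_id for d, _ in discarded] == [2]

    def test_area_bounds(self):
        small = tfm.IslandEnergy(1e-15, 50.0, 2e-17, 0.01, island_id=1)
        ok = tfm.IslandEnergy(1e-15, 500.0, 2e-18, 0.01, island_id=2)
        kept, discarded = filter_islands([small, ok],
                                         area_bounds=(100.0, 1000.0))
        assert [k.island_id for k in kept] == [2]
        assert discarded[0][1] == "area_out_of_bounds"

    def test_empty_input(self):
        assert filter_islands([]) == ([], [])


class TestFoldNormalise:
    def test_control_fold_is_one(self):
        table = pd.DataFrame({
            "gel": ["g1", "g1", "g2", "g2"],
            "condition": ["ctrl", "kd", "ctrl", "kd"],
            "mean_density": [2.0, 3.0, 4.0, 2.0],
        })
        out = fold_normalise(table, "ctrl")
        ctrl = out[out.condition == "ctrl"]
        np.testing.assert_allclose(ctrl["fold"], 1.0)
        kd = out[out.condition == "kd"].sort_values("gel")
        np.testing.assert_allclose(kd["fold"], [1.5, 0.5])

    def test_missing_control_raises(self):
        table = pd.DataFrame({"gel": ["g1"], "condition": ["kd"],
                              "mean_density": [1.0]})
        with pytest.raises(InputError):
            fold_normalise(table, "ctrl")

    def test_zero_control_raises(self):
        table = pd.DataFrame({"gel": ["g1", "g1"],
                              "condition": ["ctrl", "kd"],
                              "mean_density": [0.0, 1.0]})
        with pytest.raises(InputError):
            fold_normalise(table, "ctrl")


class TestFullPipelineRecovery:
    def test_energy_density_recovered_with_noise(self):
        spots = synthetic.dipole_spots((48.0, 48.0), 24.0, 400.0, 6.0)
        (rel, st), truth = synthetic.make_tfm_pair(
            spots, domain_um=96.0, bead_density=1.0, loc_noise_px=0.05,
            seed=7)
        u = displacement_field(st, rel, h=2.6)
        T = fttc(u, *truth.substrate)
        e = strain_energy(u, T, truth.island_mask)
        truth_density = truth.U_true / (truth.island_mask.sum() * 2.6 ** 2)
        assert e.density == pytest.approx(truth_density, rel=0.15)
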