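"""Ground-truth consistency and determinism of the synthetic generators."""

import numpy as np
import pytest

from epimech import synthetic, tfm
from epimech.core import InputError


class TestMonolayer:
    def test_intensity_levels_match_truth(self, monolayer):
        channels, truth = monolayer
        px = channels["junction"].pixels
        from scipy import ndimage
        from skimage.morphology import disk
        wall = ndimage.binary_dilation(truth.junction_mask,
                                       structure=disk(truth.junction_halfwidth))
        assert px[wall].mean() == pytest.approx(200.0)
        assert px[~wall].mean() == pytest.approx(100.0)

    def test_single_cell_degenerate_mosaic(self):
        channels, truth = synthetic.make_monolayer(n_cells=1, shape=(64, 64),
                                                   seed=0)
        # skeleton reduces to the image-boundary cell outline
        interior = truth.junction_mask[1:-1, 1:-1]
        assert not interior.any()
        assert truth.junction_mask[0].all() and truth.junction_mask[-1].all()
        assert truth.per_cell_area[1] == pytest.approx(
            64 * 64 * truth.pixel_size ** 2)

    def test_label_map_partitions_image(self, monolayer):
        _, truth = monolayer
        assert truth.label_map.min() >= 1
        total = sum(truth.per_cell_area.values())
        h, w = truth.label_map.shape
        assert total == pytest.approx(h * w * truth.pixel_size ** 2)

    def test_determinism(self):
        a, ta = synthetic.make_monolayer(n_cells=9, shape=(128, 128), seed=7)
        b, tb = synthetic.make_monolayer(n_cells=9, shape=(128, 128), seed=7)
        np.testing.assert_array_equal(a["junction"].pixels,
                                      b["junction"].pixels)
        np.testing.assert_array_equal(ta.label_map, tb.label_map)

    def test_invalid_parameters_raise(self):
        with pytest.raises(InputError):
            synthetic.make_monolayer(n_cells=0)
        with pytest.raises(InputError):
            synthetic.make_monolayer(J=100, C=100, B=0)


class TestTfmPair:
    def test_zero_traction_identical_images(self):
        spots = [(32.0, 32.0, 0.0, 5.0, (1.0, 0.0))]
        (rel, st), truth = synthetic.make_tfm_pair(spots, domain_um=48,
                                                   seed=4)
        np.testing.assert_allclose(rel.pixels, st.pixels)
        assert truth.U_true == 0.0

    def test_forward_model_linearity_in_amplitude(self):
        spots1 = synthetic.dipole_spots((24.0, 24.0), 12.0, 200.0, 4.0)
        spots2 = synthetic.dipole_spots((24.0, 24.0), 12.0, 400.0, 4.0)
        _, t1 = synthetic.make_tfm_pair(spots1, domain_um=48, seed=0)
        _, t2 = synthetic.make_tfm_pair(spots2, domain_um=48, seed=0)
        np.testing.assert_allclose(t2.displacement.u, 2 * t1.displacement.u,
                                   atol=1e-12)

    def test_displacement_inverse_in_young_modulus(self):
        spots = synthetic.dipole_spots((24.0, 24.0), 12.0, 200.0, 4.0)
        _, t1 = synthetic.make_tfm_pair(spots, E=16400.0, domain_um=48, seed=0)
        _, t2 = synthetic.make_tfm_pair(spots, E=32800.0, domain_um=48, seed=0)
        np.testing.assert_allclose(t2.displacement.u, 0.5 * t1.displacement.u,
                                   atol=1e-12)

    def test_forward_matches_point_load_far_field_decay(self):
        # a single compact spot approximates a tangential point load; at
        # nu = 0.5 the half-space surface solution along the force axis is
        # u_x(r) = 3 F / (2 pi E r).  The forward model pins the zero mode
        # (zero-mean field), which adds a constant offset, so the oracle is
        # compared on displacement *differences* between radii.
        E = 16400.0
        gx = (np.arange(256) + 0.5) * 2.6
        spots = [(gx.mean(), gx.mean(), 500.0, 2.0, (1.0, 0.0))]
        T = synthetic.gaussian_traction_spots(spots, gx, gx)
        field = tfm.TractionField(T, 2.6, E, 0.5)
        u = tfm.forward_displacement(field, pad_factor=2)
        F = T[..., 0].sum() * 2.6 ** 2      # total force, Pa µm²
        centre = len(gx) // 2

        def u_meas(r_nodes):
            return u.u[centre, centre + r_nodes, 0]

        def u_closed(r_nodes):
            return 3 * F / (2 * np.pi * E * (r_nodes * 2.6))

        for r1, r2 in ((10, 20), (10, 40), (20, 40)):
            meas = u_meas(r1) - u_meas(r2)
            expected = u_closed(r1) - u_closed(r2)
            assert meas == pytest.approx(expected, rel=0.1)

    def test_energy_truth_is_nonnegative_and_recorded(self, tfm_dipole):
        _, truth = tfm_dipole
        assert truth.U_true > 0
        assert truth.island_mask.any()

    def test_nu_out_of_range_raises(self):
        with pytest.raises(InputError):
            synthetic.make_tfm_pair([(10, 10, 1, 1, (1, 0))], nu=0.6)

    def test_determinism(self):
        spots = synthetic.dipole_spots((24.0, 24.0), 12.0, 200.0, 4.0)
        (r1, s1), _ = synthetic.make_tfm_pair(spots, domain_um=48, seed=5)
        (r2, s2), _ = synthetic.make_tfm_pair(spots, domain_um=48, seed=5)
        np.testing.assert_array_equal(r1.pixels, r2.pixels)
        np.testing.assert_array_equal(s1.pixels, s2.pixels)


class TestFretTriplet:
    def test_no_fret_no_crossover_gives_zero_da(self):
        (dd, da, aa), _ = synthetic.make_fret_triplet(0.0, beta=0.0, gamma=0.0)
        np.testing.assert_allclose(da.pixels, 0.0)

    def test_generator_algebra_inverts(self):
        (dd, da, aa), truth = synthetic.make_fret_triplet(0.25, beta=0.6,
                                                          gamma=0.1)
        fc = da.pixels - truth.beta * dd.pixels - truth.gamma * aa.pixels
        np.testing.assert_allclose(fc / (fc + dd.pixels), 0.25, atol=1e-12)

    def test_determinism_with_noise(self):
        a, _ = synthetic.make_fret_triplet(0.3, 0.5, 0.2, noise_sigma=2.0,
                                           seed=9)
        b, _ = synthetic.make_fret_triplet(0.3, 0.5, 0.2, noise_sigma=2.0,
                                           seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.pixels, y.pixels)

    def test_efficiency_out_of_range_raises(self):
        with pytest.raises(InputError):
            synthetic.make_fret_triplet(1.2, 0.5, 0.1)


class TestStrandNetwork:
    def test_single_strand_has_zero_depth(self):
        net, truth = synthetic.make_strand_network(n_strands=1, depth_nm=300,
                                                   seed=0)
        assert truth.depth_nm == 0.0
        assert len(net.strands) == 1

    def test_truth_reads_back_generated_geometry(self):
        net, truth = synthetic.make_strand_network(n_strands=4, depth_nm=300,
                                                   breaks=(), seed=1)
        assert truth.n_strands == 4
        assert truth.depth_nm == 300.0
        assert truth.breaks == []
        ys = [s.full_path()[:, 1].mean() for s in net.strands]
        assert max(ys) - min(ys) == pytest.approx(300.0, abs=1e-9)

    def test_breaks_have_exact_gap_length(self):
        net, truth = synthetic.make_strand_network(
            n_strands=3, depth_nm=200, breaks=[(1, 30.0)], jitter_nm=10,
            seed=2)
        assert truth.breaks == [(1, 30.0)]
        strand = net.strands[1]
        assert len(strand.segments) == 2
        gap = np.hypot(*(strand.segments[1][0] - strand.segments[0][-1]))
        assert gap == pytest.approx(30.0, abs=1e-9)

    def test_determinism(self):
        n1, _ = synthetic.make_strand_network(4, 300, breaks=[(2, 25)], seed=3)
        n2, _ = synthetic.make_strand_network(4, 300, breaks=[(2, 25)], seed=3)
        for a, b in zip(n1.strands, n2.strands):
            for sa, sb in zip(a.segments, b.segments):
                np.testing.assert_array_equal(sa, sb)


class TestAdhesionImage:
    def test_closed_form_truth(self):
        img, truth = synthetic.make_adhesion_image(
            [(10.0, 10.0, 1.0, 1.0, 0.0), (20.0, 10.0, 2.0, 0.5, 0.3)],
            shape=(256, 256), pixel_size=0.1)
        assert truth.loc[0, "area_um2"] == pytest.approx(np.pi)
        assert truth.loc[0, "max_feret_um"] == pytest.approx(2.0)
        assert truth.loc[1, "area_um2"] == pytest.approx(np.pi)
        assert truth.loc[1, "max_feret_um"] == pytest.approx(4.0)
        assert not truth["overlaps"].any()

    def test_overlap_flagged_not_error(self):
        _, truth = synthetic.make_adhesion_image(
            [(10.0, 10.0, 2.0, 2.0, 0.0), (12.0, 10.0, 2.0, 2.0, 0.0)],
            shape=(256, 256), pixel_size=0.1)
        assert truth["overlaps"].all()

    def test_empty_list_blank_image(self):
        img, truth = synthetic.make_adhesion_image([], background=5.0)
        assert len(truth) == 0
        np.testing.assert_allclose(img.pixels, 5.0)


class TestIslandField:
    def test_coverage_and_count(self):
        img, truth = synthetic.make_island_field(5, 0.30, seed=4)
        assert truth["n_islands"] == 5
        assert truth["coverage"] == pytest.approx(0.30, abs=0.01)

    def test_determinism(self):
        a, _ = synthetic.make_island_field(3, 0.2, seed=8)
        b, _ = synthetic.make_island_field(3, 0.2, seed=8)
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestNucleiImage:
    def test_requested_count_and_truth(self):
        img, centers = synthetic.make_nuclei_image(n=12, seed=5)
        assert len(centers) == 12
        assert img.pixels.max() > 0

    def test_explicit_centres_honoured(self):
        img, centers = synthetic.make_nuclei_image(
            centers_um=[(10.0, 10.0), (14.0, 10.0)])
        assert len(centers) == 2
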