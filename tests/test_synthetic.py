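"""Ground-truth scene generator contracts."""

import numpy as np
import pytest

from monomech.fields import SubstrateSpec
from monomech.synthetic import (NoiseModel, make_contractile_strip_scene,
                                make_expanding_mask_sequence,
                                render_bead_images)


class TestStripScene:
    def test_force_balance_by_antisymmetry(self, gel):
        scene = make_contractile_strip_scene(
            strip_width=200, peak_traction=80, profile="uniform-inward",
            substrate=gel, seed=0, shape=(64, 128), pixel_size=2.0,
            render_beads=False)
        assert abs(scene.traction_truth.u.sum()) < 1e-9
        assert abs(scene.traction_truth.v.sum()) < 1e-9

    def test_peak_traction_attained(self, gel):
        scene = make_contractile_strip_scene(
            strip_width=200, peak_traction=100.0, substrate=gel, seed=0,
            shape=(64, 128), pixel_size=2.0, render_beads=False)
        np.testing.assert_allclose(
            scene.traction_truth.magnitude().max(), 100.0, rtol=5e-3)

    def test_tractions_point_inward_and_vanish_outside(self, gel):
        scene = make_contractile_strip_scene(
            strip_width=200, peak_traction=100.0, substrate=gel, seed=0,
            shape=(64, 128), pixel_size=2.0, render_beads=False)
        nx = 128
        xmid = (nx - 1) / 2.0
        x = np.arange(nx)
        Tx = scene.traction_truth.u[32]
        assert (Tx[x < xmid] >= 0).all()          # pull toward midline
        assert (Tx[x > xmid] <= 0).all()
        outside = ~scene.masks.masks[0]
        assert np.abs(scene.traction_truth.u[outside]).max() == 0.0

    def test_same_seed_bit_identical(self, gel):
        kw = dict(strip_width=150, peak_traction=60.0, substrate=gel,
                  seed=11, shape=(96, 96), pixel_size=2.0, n_frames=1)
        a = make_contractile_strip_scene(**kw)
        b = make_contractile_strip_scene(**kw)
        np.testing.assert_array_equal(a.bead_reference, b.bead_reference)
        np.testing.assert_array_equal(a.bead_frames, b.bead_frames)
        np.testing.assert_array_equal(a.displacement_truth.u,
                                      b.displacement_truth.u)

    def test_strip_wider_than_domain_rejected(self, gel):
        with pytest.raises(ValueError, match="wider"):
            make_contractile_strip_scene(strip_width=400, substrate=gel,
                                         shape=(64, 128), pixel_size=2.0)

    def test_displacement_is_forward_solution(self, gel):
        from monomech.elastic import forward_displacement
        scene = make_contractile_strip_scene(
            strip_width=150, peak_traction=60.0, substrate=gel, seed=3,
            shape=(96, 96), pixel_size=2.0, render_beads=False)
        u = forward_displacement(scene.traction_truth, gel, pad=2)
        np.testing.assert_allclose(u.u, scene.displacement_truth.u)


class TestBeadRendering:
    def test_zero_displacement_reproduces_reference(self, gel):
        scene = make_contractile_strip_scene(
            strip_width=150, peak_traction=1e-9, substrate=gel, seed=5,
            shape=(96, 96), pixel_size=2.0, render_beads=False)
        scene.displacement_truth.u[:] = 0.0
        scene.displacement_truth.v[:] = 0.0
        noise = NoiseModel(photon_noise_sd=0.0)
        ref, frames = render_bead_images(scene, noise, n_frames=1)
        np.testing.assert_allclose(frames[0], ref, atol=1e-12)

    def test_rigid_shift_moves_spot_mass(self, gel):
        """A +1 px rigid displacement shifts the image centroid by +1 px."""
        scene = make_contractile_strip_scene(
            strip_width=150, peak_traction=1e-9, substrate=gel, seed=5,
            shape=(96, 96), pixel_size=2.0, render_beads=False)
        scene.displacement_truth.u[:] = 2.0     # µm = 1 px at 2 µm/px
        scene.displacement_truth.v[:] = 0.0
        ref, frames = render_bead_images(scene, NoiseModel(photon_noise_sd=0),
                                         n_frames=1)
        np.testing.assert_allclose(frames[0][4:-4, 4:-4],
                                   ref[4:-4, 3:-5], atol=0.02)

    def test_doubling_density_doubles_spot_mass(self, gel):
        scene = make_contractile_strip_scene(
            strip_width=150, peak_traction=60.0, substrate=gel, seed=5,
            shape=(96, 96), pixel_size=2.0, render_beads=False)
        lo, _ = render_bead_images(scene, NoiseModel(bead_density=0.05,
                                                     photon_noise_sd=0))
        scene.rng_seed = 5
        hi, _ = render_bead_images(scene, NoiseModel(bead_density=0.10,
                                                     photon_noise_sd=0))
        assert hi.sum() / lo.sum() == pytest.approx(2.0, rel=0.15)

    def test_low_density_warns(self, gel):
        scene = make_contractile_strip_scene(
            strip_width=150, peak_traction=60.0, substrate=gel, seed=5,
            shape=(96, 96), pixel_size=2.0, render_beads=False)
        with pytest.warns(UserWarning, match="beads per"):
            render_bead_images(scene, NoiseModel(bead_density=0.0005))


class TestExpandingMasks:
    def test_growth_one_constant(self):
        seq = make_expanding_mask_sequence(initial_width=100, n_frames=5,
                                           growth=1.0, shape=(32, 256))
        assert (seq.masks == seq.masks[0]).all()

    def test_target_area_fold(self):
        seq = make_expanding_mask_sequence(initial_width=150, n_frames=91,
                                           growth=2.7, shape=(64, 512),
                                           pixel_size=1.0)
        areas = seq.areas()
        assert areas[-1] / areas[0] == pytest.approx(2.7, rel=0.02)

    def test_monotone_area(self):
        seq = make_expanding_mask_sequence(initial_width=120, n_frames=30,
                                           growth=2.0, shape=(48, 384),
                                           roughness=1.5, seed=2)
        assert (np.diff(seq.areas()) >= 0).all()

    def test_zero_roughness_straight_edges(self):
        seq = make_expanding_mask_sequence(initial_width=100, n_frames=3,
                                           growth=1.5, shape=(32, 256))
        for m in seq.masks:
            col = m.any(axis=0)
            assert (m[:, col].all(axis=0)).all()   # each on-column fully on

    def test_overflow_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            make_expanding_mask_sequence(initial_width=300, n_frames=5,
                                         growth=3.0, shape=(32, 256),
                                         pixel_size=1.0)
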