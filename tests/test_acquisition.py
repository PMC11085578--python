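"""Trajectory geometry, signal model, and forward simulator oracles."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from sodiumqa import acquisition as acq
from sodiumqa.phantom import (AGAROSE_RELAXATION, SALINE_RELAXATION,
                              PhantomConfig, VialSpec, build_phantom,
                              voxel_coordinates)


def brute_force_kspace(phantom, trajectory, params, n_segments):
    """Independent double-loop DFT oracle with per-segment decay."""
    xs, ys, zs = voxel_coordinates(phantom.grid_shape, phantom.fov)
    voxel_volume = float(np.prod(np.asarray(phantom.fov) /
                                 np.asarray(phantom.grid_shape)))
    s = trajectory.samples_per_spoke
    seg_len = params.readout_duration / n_segments
    out = np.zeros((trajectory.n_spokes, s), dtype=complex)
    nz = np.argwhere(phantom.label_volume > 0)
    for m in range(trajectory.n_spokes):
        for j in range(s):
            k = trajectory.directions[m] * trajectory.k_radii[j]
            t_elapsed = j * params.readout_duration / s
            seg = min(int(t_elapsed / seg_len), n_segments - 1)
            t_mid = params.te + (seg + 0.5) * seg_len
            total = 0.0 + 0.0j
            for (i, jj, kk) in nz:
                vial = phantom.vials[phantom.label_volume[i, jj, kk] - 1]
                relax = phantom.relaxation_by_vial[vial.label]
                amp = (phantom.concentration_volume[i, jj, kk]
                       * acq.flash_steady_state(params.flip_angle, params.tr,
                                                relax.t1)
                       * acq.transverse_decay(t_mid, relax))
                x = np.array([xs[i], ys[jj], zs[kk]])
                total += amp * np.exp(-2j * np.pi * (k @ x))
            out[m, j] = total * voxel_volume
    return out


class TestGoldenAngleDirections:
    def test_first_spoke_is_north_pole(self):
        d = acq.golden_angle_directions(1)
        assert np.allclose(d, [[0.0, 0.0, 1.0]])

    def test_rejects_zero_spokes(self):
        with pytest.raises(ValueError):
            acq.golden_angle_directions(0)

    def test_unit_norm(self):
        d = acq.golden_angle_directions(5000)
        assert np.allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-9)

    def test_hemisphere_coverage_near_uniform(self):
        """Any hemisphere holds 40-60% of 1000 spokes."""
        d = acq.golden_angle_directions(1000)
        rng = np.random.default_rng(7)
        for _ in range(20):
            normal = rng.standard_normal(3)
            normal /= np.linalg.norm(normal)
            count = int((d @ normal > 0).sum())
            assert 400 <= count <= 600

    def test_full_protocol_mean_direction_vanishes(self):
        d = acq.golden_angle_directions(15460)
        assert np.linalg.norm(d.mean(axis=0)) < 0.05


class TestTrajectory:
    def test_protocol_kmax(self):
        params = acq.AcqParams()
        traj = acq.build_trajectory(params)
        assert traj.kmax == pytest.approx(268.817, abs=0.01)
        assert traj.samples_per_spoke == 208

    def test_center_out_ute_start(self):
        traj = acq.build_trajectory(acq.AcqParams(n_spokes=10))
        assert traj.k_radii[0] == 0.0
        assert traj.sample_times[0] == pytest.approx(0.0005)
        assert np.all(np.diff(traj.k_radii) > 0)

    def test_kmax_reciprocal_in_resolution(self):
        base = acq.AcqParams()
        halved = dataclasses.replace(base,
                                     nominal_resolution=base.nominal_resolution / 2)
        assert acq.build_trajectory(halved).kmax == pytest.approx(
            2 * acq.build_trajectory(base).kmax)

    def test_density_weights_follow_k_squared(self):
        traj = acq.build_trajectory(acq.AcqParams(n_spokes=4))
        w = traj.density_weights
        assert w[0] > 0
        # sample at 2k vs k: weight ratio 4
        assert w[4] / w[2] == pytest.approx(4.0, rel=1e-12)
        total = traj.n_spokes * w.sum()
        assert total == pytest.approx(4.0 / 3.0 * np.pi * traj.kmax ** 3,
                                      rel=1e-12)


class TestSignalModel:
    def test_flash_fully_relaxed_90(self):
        assert acq.flash_steady_state(90.0, 10.0, 0.060) == pytest.approx(
            1.0, abs=1e-6)

    def test_flash_zero_flip(self):
        assert acq.flash_steady_state(1e-12, 0.005, 0.060) == pytest.approx(
            0.0, abs=1e-9)

    def test_flash_argmax_matches_ernst(self):
        res = minimize_scalar(
            lambda a: -acq.flash_steady_state(a, 0.005, 0.060),
            bounds=(1.0, 89.0), method="bounded",
            options={"xatol": 1e-4})
        assert res.x == pytest.approx(23.07, abs=0.1)

    def test_decay_at_zero_is_one(self):
        assert acq.transverse_decay(0.0, AGAROSE_RELAXATION) == 1.0

    def test_mono_exponential_time_constant(self):
        relax = SALINE_RELAXATION
        assert acq.transverse_decay(relax.t2_slow, relax) == pytest.approx(
            np.exp(-1.0))

    def test_biexponential_closed_form(self):
        relax = AGAROSE_RELAXATION  # 0.6 fast at 3 ms, 0.4 slow at 25 ms
        expected = 0.6 * np.exp(-1.0) + 0.4 * np.exp(-3.0 / 25.0)
        assert acq.transverse_decay(0.003, relax) == pytest.approx(
            expected, rel=1e-12)
        assert expected == pytest.approx(0.5755, abs=1e-4)


class TestForwardSimulator:
    def test_zero_phantom_gives_zero_kspace(self, small_params):
        cfg = PhantomConfig(grid_shape=(8, 8, 8), vials=[])
        phantom = build_phantom(cfg)
        traj = acq.build_trajectory(small_params)
        s = acq.simulate_noiseless(phantom, traj, small_params)
        assert not s.any()

    def test_dc_sample_equals_weighted_content(self, small_phantom,
                                               small_trajectory, small_params):
        """k=0 sample is the voxel-volume-weighted sum of C x steady-state."""
        s = acq.simulate_noiseless(small_phantom, small_trajectory,
                                   small_params, apply_decay=False)
        voxel_volume = np.prod(small_phantom.voxel_size)
        relax = next(iter(small_phantom.relaxation_by_vial.values()))
        expected = (small_phantom.concentration_volume.sum() * voxel_volume
                    * acq.flash_steady_state(small_params.flip_angle,
                                             small_params.tr, relax.t1))
        assert np.allclose(s[:, 0], expected, rtol=1e-12)

    def test_matches_brute_force_dft_oracle(self, small_params):
        """Vectorized forward equals the double-loop DFT to 1e-10."""
        cfg = PhantomConfig(
            grid_shape=(8, 8, 8),
            vials=[VialSpec("a", "large", 77.0, (0.05, 0.0, 0.0), 0.08, 0.2),
                   VialSpec("b", "small", 154.0, (-0.06, 0.04, 0.0), 0.06,
                            0.15)],
            relaxation=AGAROSE_RELAXATION)
        phantom = build_phantom(cfg)
        params = dataclasses.replace(small_params, n_spokes=16)
        traj = acq.build_trajectory(params)
        got = acq.simulate_noiseless(phantom, traj, params, n_segments=4)
        expected = brute_force_kspace(phantom, traj, params, n_segments=4)
        scale = np.abs(expected).max()
        assert np.abs(got - expected).max() / scale < 1e-10

    def test_conjugate_symmetry_for_real_image(self, small_phantom,
                                               small_params):
        """S(-k) = conj(S(k)) when decay is frozen (real phantom)."""
        base = acq.golden_angle_directions(8)
        traj = acq.build_trajectory(
            dataclasses.replace(small_params, n_spokes=8))
        traj = acq.TrajectorySet(
            directions=np.vstack([base, -base]),
            k_radii=traj.k_radii, sample_times=traj.sample_times,
            kmax=traj.kmax, density_weights=traj.density_weights)
        s = acq.simulate_noiseless(small_phantom, traj, small_params,
                                   apply_decay=False)
        assert np.allclose(s[8:], np.conj(s[:8]), rtol=1e-10, atol=1e-12)

    def test_amplitude_scales_linearly_with_concentration(self, small_params):
        def make(scale):
            cfg = PhantomConfig(
                grid_shape=(12, 12, 12),
                vials=[VialSpec("a", "large", 40.0 * scale,
                                (0.04, 0.0, 0.0), 0.08, 0.2)])
            return build_phantom(cfg)

        traj = acq.build_trajectory(small_params)
        s1 = acq.simulate_noiseless(make(1.0), traj, small_params)
        s2 = acq.simulate_noiseless(make(2.0), traj, small_params)
        assert np.array_equal(s2, 2.0 * s1)

    def test_noise_and_seed_contract(self, small_phantom, small_trajectory,
                                     small_params):
        ds1 = acq.simulate_kspace(small_phantom, small_trajectory,
                                  small_params, seed=5, noise_sigma=0.1,
                                  n_repeats=3)
        ds2 = acq.simulate_kspace(small_phantom, small_trajectory,
                                  small_params, seed=5, noise_sigma=0.1,
                                  n_repeats=3)
        assert np.array_equal(ds1.samples, ds2.samples)
        ds3 = acq.simulate_kspace(small_phantom, small_trajectory,
                                  small_params, seed=6, noise_sigma=0.1,
                                  n_repeats=3)
        assert not np.array_equal(ds1.samples, ds3.samples)
        # repeats carry independent noise
        assert not np.array_equal(ds1.samples[0], ds1.samples[1])

    def test_noiseless_dataset_flagged(self, small_phantom, small_trajectory,
                                       small_params):
        ds = acq.simulate_kspace(small_phantom, small_trajectory,
                                 small_params, seed=0, noise_sigma=0.0,
                                 n_repeats=2)
        assert ds.noise_sigma == 0.0
        assert np.array_equal(ds.samples[0], ds.samples[1])

    def test_fov_mismatch_rejected(self, small_trajectory, small_params):
        cfg = PhantomConfig(grid_shape=(8, 8, 8), fov=(0.2, 0.2, 0.2),
                            vials=[])
        phantom = build_phantom(cfg)
        with pytest.raises(ValueError, match="FOV"):
            acq.simulate_noiseless(phantom, small_trajectory, small_params)
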