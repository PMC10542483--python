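"""Generator contracts: trajectories, spikes/calcium, rendering, determinism."""

import numpy as np
import pytest

from nervetrack.synthetic import (
    ArtifactConfig,
    ContractionConfig,
    DeformationConfig,
    KernelConfig,
    NoiseConfig,
    SyntheticConfig,
    generate_movie,
    generate_spikes_and_calcium,
    generate_trajectories,
)


def quiet_config(**kw):
    base = dict(
        n_neurons=5,
        n_nematocytes=0,
        T=20,
        H=96,
        W=96,
        seed=3,
        contraction=ContractionConfig(n_events=0),
        deformation=DeformationConfig(amplitude_px=0.0),
        artifact=ArtifactConfig(rate=0.0),
        noise=NoiseConfig(gaussian_sd=0.0, poisson_gain=0.0),
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestTrajectories:
    def test_zero_deformation_gives_constant_trajectories(self):
        traj, _ = generate_trajectories(quiet_config())
        assert np.allclose(traj, traj[:, :1, :])

    def test_uniform_drift_gives_straight_lines(self):
        cfg = quiet_config(
            deformation=DeformationConfig(
                amplitude_px=0.0, drift_px_per_frame=(1.0, 0.0)
            ),
            T=30,
        )
        traj, _ = generate_trajectories(cfg)
        steps = np.diff(traj, axis=1)
        assert np.allclose(steps[:, :, 0], 1.0)
        assert np.allclose(steps[:, :, 1], 0.0)

    def test_contraction_events_contain_fast_steps(self):
        cfg = SyntheticConfig(
            n_neurons=20,
            n_nematocytes=0,
            T=200,
            H=160,
            W=160,
            seed=7,
            contraction=ContractionConfig(
                n_events=2, duration_frames=10, max_displacement_px_per_frame=6.0
            ),
        )
        traj, windows = generate_trajectories(cfg)
        assert len(windows) == 2
        steps = np.linalg.norm(np.diff(traj, axis=1), axis=2)
        for s, e in windows:
            assert steps[:, max(s - 1, 0) : e].max() > 3.0

    def test_slow_steps_bounded_outside_contraction(self):
        cfg = SyntheticConfig(
            n_neurons=20, n_nematocytes=0, T=150, H=160, W=160, seed=1,
            contraction=ContractionConfig(n_events=0),
        )
        traj, _ = generate_trajectories(cfg)
        steps = np.linalg.norm(np.diff(traj, axis=1), axis=2)
        assert steps.max() <= cfg.deformation.max_displacement_px_per_frame * np.sqrt(2) + 1e-9

    def test_margin_violation_raises(self):
        cfg = quiet_config(H=30, W=30, psf_sigma=4.0)
        with pytest.raises(ValueError):
            generate_trajectories(cfg)


class TestSpikesAndCalcium:
    def test_zero_rate_gives_baseline_times_bleach(self):
        cfg = quiet_config(spike_rate=0.0, T=50)
        _, traces = generate_spikes_and_calcium(cfg)
        expected = cfg.baseline_glow * cfg.bleach.rate_green ** np.arange(50)
        assert np.allclose(traces, expected[None, :])

    def test_traces_obey_ar2_recursion(self):
        cfg = quiet_config(
            n_neurons=4, T=400, spike_rate=0.01, calcium_amplitude=1.0,
            baseline_glow=0.0, seed=5,
        )
        cfg.bleach.rate_green = 1.0
        spikes, traces = generate_spikes_and_calcium(cfg)
        g1, g2 = cfg.kernel.g1, cfg.kernel.g2
        for i in range(4):
            c = traces[i]
            resid = c[2:] - g1 * c[1:-1] - g2 * c[:-2]
            # residual is the spike input: zero off spike frames
            off = np.setdiff1d(np.arange(2, 400), spikes[i])
            assert np.allclose(resid[off - 2], 0.0, atol=1e-9)
            assert np.all(resid[spikes[i][spikes[i] >= 2] - 2] >= 0.999)

    def test_single_spike_is_impulse_response(self):
        cfg = quiet_config(n_neurons=1, T=100)
        h = cfg.kernel.impulse_response(60)
        # the impulse response itself satisfies the recursion from a unit spike
        assert h[0] == 1.0
        g1, g2 = cfg.kernel.g1, cfg.kernel.g2
        assert np.allclose(h[2:], g1 * h[1:-1] + g2 * h[:-2])

    def test_poisson_rate_matches_expectation(self):
        cfg = quiet_config(n_neurons=50, T=5000, spike_rate=0.01, seed=11)
        spikes, _ = generate_spikes_and_calcium(cfg)
        counts = np.array([len(s) for s in spikes])
        lam_t = 0.01 * 5000
        se = np.sqrt(lam_t / 50)
        assert abs(counts.mean() - lam_t) < 3 * se

    def test_unstable_kernel_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(kernel=KernelConfig(g1=2.0, g2=0.5))


class TestRendering:
    def test_single_neuron_spot_positions(self):
        cfg = quiet_config(n_neurons=1, T=5, baseline_glow=200.0, red_amplitude=200.0)
        movie, truth = generate_movie(cfg)
        for t in range(5):
            am_r = np.unravel_index(np.argmax(movie.red[t]), movie.red[t].shape)
            assert np.linalg.norm(am_r - truth.trajectories[0, t]) <= 0.5 + np.sqrt(0.5)
            am_g = np.unravel_index(np.argmax(movie.green[t]), movie.green[t].shape)
            target = truth.trajectories[0, t] + truth.offsets[0]
            assert np.linalg.norm(am_g - target) <= 0.5 + np.sqrt(0.5)

    def test_empty_movie_is_background_plus_noise(self):
        cfg = quiet_config(n_neurons=0, n_nematocytes=0, T=3)
        movie, _ = generate_movie(cfg)
        assert np.all(movie.red == cfg.background)
        assert np.all(movie.green == cfg.background)

    def test_artifact_halves_spot_intensity(self):
        from nervetrack.synthetic import render_movie

        cfg = quiet_config(n_neurons=1, T=20, background=0.0)
        cfg.artifact.depth_fraction = 0.5
        rng = np.random.default_rng(0)
        traj, _ = generate_trajectories(cfg, rng)
        traces = np.full((1, 20), 100.0)
        masks = np.zeros((1, 20), dtype=bool)
        masks[0, 10:16] = True
        movie, truth = render_movie(
            cfg, traj, traces, offsets=np.zeros((1, 2)),
            artifact_masks=masks, rng=rng,
        )
        on = movie.green[12].astype(float).sum()
        off = movie.green[5].astype(float).sum()
        assert on / off == pytest.approx(0.5, abs=0.02)

    def test_shape_mismatch_fails(self):
        from nervetrack.synthetic import render_movie

        cfg = quiet_config(n_neurons=2, T=10)
        with pytest.raises(ValueError):
            render_movie(cfg, np.zeros((1, 10, 2)), np.zeros((2, 10)))

    def test_determinism_bit_identical(self):
        cfg = SyntheticConfig(n_neurons=8, n_nematocytes=2, T=30, H=128, W=128, seed=9)
        m1, t1 = generate_movie(cfg)
        m2, t2 = generate_movie(cfg)
        assert np.array_equal(m1.red, m2.red)
        assert np.array_equal(m1.green, m2.green)
        assert np.array_equal(t1.trajectories, t2.trajectories)

    def test_red_intensity_independent_of_calcium(self):
        cfg = SyntheticConfig(
            n_neurons=1, n_nematocytes=0, T=300, H=96, W=96, seed=2,
            spike_rate=0.02,
            contraction=ContractionConfig(n_events=0),
            deformation=DeformationConfig(amplitude_px=0.0),
            artifact=ArtifactConfig(rate=0.0),
        )
        movie, truth = generate_movie(cfg)
        r, c = truth.trajectories[0, 0].astype(int)
        red_int = movie.red[:, r - 4 : r + 5, c - 4 : c + 5].astype(float).sum(axis=(1, 2))
        cal = truth.calcium_traces[0]
        corr = abs(np.corrcoef(red_int, cal)[0, 1])
        assert corr < 0.2
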