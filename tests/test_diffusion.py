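import numpy as np
import pytest

from scafdl.diffusion import (
    GuidanceConfig,
    TimestepTriple,
    build_schedule,
    forward_diffuse,
    ing_reconstruct,
    oracle_denoiser,
    predict_x0,
    reconstruct_batch,
    sample_timestep_triple,
)


@pytest.fixture(scope="module")
def sched():
    return build_schedule(200)


class TestSchedule:
    def test_linear_1000_step_tail(self):
        s = build_schedule(1000, beta_bounds=(1e-4, 0.02))
        assert s.alpha_bar[1000] < 1e-4

    def test_alpha_bar_monotone_and_anchored(self, sched):
        assert sched.alpha_bar[0] == 1.0
        assert np.all(np.diff(sched.alpha_bar) < 0)

    def test_toy_first_step_definition(self):
        s = build_schedule(10)
        assert s.alpha_bar[1] == pytest.approx(1 - s.beta[1])

    def test_default_segments_scale_proportionally(self, sched):
        assert sched.segments == ((0, 60), (60, 100), (100, 140))
        s1000 = build_schedule(1000)
        assert s1000.segments == ((0, 300), (300, 500), (500, 700))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_schedule(2)
        with pytest.raises(ValueError):
            build_schedule(100, beta_bounds=(0.0, 0.5))
        with pytest.raises(ValueError):
            build_schedule(100, segments=((0, 30), (40, 50), (50, 60)))


class TestForwardAndInvert:
    def test_t0_is_identity(self, sched, rng):
        x0 = rng.random((8, 8)).astype(np.float32)
        eps = rng.standard_normal((8, 8)).astype(np.float32)
        assert np.array_equal(forward_diffuse(x0, 0, eps, sched), x0)

    def test_zero_signal_pure_noise(self, sched, rng):
        eps = rng.standard_normal((8, 8)).astype(np.float32)
        x_t = forward_diffuse(np.zeros((8, 8), np.float32), 50, eps, sched)
        assert np.allclose(x_t, np.sqrt(1 - sched.alpha_bar[50]) * eps, atol=1e-6)

    def test_moments_match_closed_form(self, sched, rng):
        """Monte-Carlo mean/variance of x_t against the Gaussian forward
        process parameters."""
        x0 = rng.random((4, 4)).astype(np.float32)
        t = 80
        draws = rng.standard_normal((10_000, 4, 4)).astype(np.float32)
        x_t = np.sqrt(sched.alpha_bar[t]) * x0 + np.sqrt(1 - sched.alpha_bar[t]) * draws
        assert np.allclose(x_t.mean(axis=0), np.sqrt(sched.alpha_bar[t]) * x0, atol=0.04)
        assert np.allclose(x_t.var(axis=0), 1 - sched.alpha_bar[t], atol=0.05)

    @pytest.mark.parametrize("t", [1, 7, 100, 200])
    def test_round_trip_identity(self, sched, rng, t):
        x0 = rng.random((8, 8)).astype(np.float32)
        eps = rng.standard_normal((8, 8)).astype(np.float32)
        x_t = forward_diffuse(x0, t, eps, sched)
        back = predict_x0(x_t, t, eps, sched)
        assert np.abs(back - x0).max() <= 1e-5

    def test_predict_x0_zero_noise(self, sched, rng):
        x_t = rng.random((8, 8)).astype(np.float32)
        out = predict_x0(x_t, 30, np.zeros_like(x_t), sched)
        assert np.allclose(out, x_t / np.sqrt(sched.alpha_bar[30]), atol=1e-6)

    def test_predict_x0_matches_pixel_loop(self, sched, rng):
        x_t = rng.random((8, 8)).astype(np.float32)
        eh = rng.standard_normal((8, 8)).astype(np.float32)
        t = 42
        out = predict_x0(x_t, t, eh, sched)
        sa = np.sqrt(sched.alpha_bar[t])
        sb = np.sqrt(1 - sched.alpha_bar[t])
        for r in range(8):
            for c in range(8):
                assert abs(out[r, c] - (x_t[r, c] - sb * eh[r, c]) / sa) <= 1e-6

    def test_bounds_enforced(self, sched):
        x = np.zeros((4, 4), np.float32)
        with pytest.raises(ValueError):
            forward_diffuse(x, 201, x, sched)
        with pytest.raises(ValueError):
            predict_x0(x, 0, x, sched)


class TestTripleSampling:
    def test_fixed_mode_default_is_segment_bounds(self, sched):
        t = sample_timestep_triple(sched, GuidanceConfig(mode="fixed"))
        assert t.as_tuple() == (60, 100, 140)
        s1000 = build_schedule(1000)
        assert sample_timestep_triple(s1000, GuidanceConfig(mode="fixed")).as_tuple() == (
            300,
            500,
            700,
        )

    def test_random_mode_respects_segments(self, sched):
        cfg = GuidanceConfig(mode="random")
        for seed in range(500):
            t = sample_timestep_triple(sched, cfg, seed=seed)
            assert 0 < t.t_s <= 60 < t.t_m <= 100 < t.t_l <= 140

    def test_random_mode_deterministic(self, sched):
        cfg = GuidanceConfig(mode="random")
        assert (
            sample_timestep_triple(sched, cfg, seed=5).as_tuple()
            == sample_timestep_triple(sched, cfg, seed=5).as_tuple()
        )

    def test_invalid_triple_rejected(self):
        with pytest.raises(ValueError):
            TimestepTriple(100, 60, 140)


class TestIngReconstruction:
    """The guided reconstruction against its analytic oracle: with a
    denoiser that always points at a target x* and shared renoising noise,
    x0_guide = x* + (w1+w2)(1 - alpha_bar_ts)(x* - x_in)."""

    def test_closed_form_across_grid(self, sched, rng):
        x_star = rng.random((8, 8)).astype(np.float32)
        x_in = rng.random((8, 8)).astype(np.float32)
        den = oracle_denoiser(x_star, sched)
        for t_s in (5, 30, 60):
            for w1 in (0.0, 0.5, 1.5):
                for w2 in (0.0, 0.5, 0.9):
                    cfg = GuidanceConfig(w1=w1, w2=w2, mode="fixed", triple=(t_s, 100, 140))
                    _, inter = ing_reconstruct(x_in, den, sched, cfg=cfg, seed=3)
                    ab = sched.alpha_bar[t_s]
                    closed = x_star + (w1 + w2) * (1 - ab) * (x_star - x_in)
                    assert np.abs(inter["x0_raw"] - closed).max() <= 1e-6

    def test_zero_weights_reduce_to_unguided(self, sched, rng):
        x_in = rng.random((8, 8)).astype(np.float32)
        den = oracle_denoiser(rng.random((8, 8)).astype(np.float32), sched)
        cfg = GuidanceConfig(w1=0.0, w2=0.0, mode="fixed", triple=(60, 100, 140))
        _, inter = ing_reconstruct(x_in, den, sched, cfg=cfg, seed=1)
        plain = predict_x0(inter["x_ts"], 60, inter["eps_hat_s"], sched)
        assert np.array_equal(inter["x0_raw"], plain)

    def test_fixed_point_at_target(self, sched, rng):
        x_star = rng.random((8, 8)).astype(np.float32)
        den = oracle_denoiser(x_star, sched)
        cfg = GuidanceConfig(w1=2.0, w2=3.0, mode="fixed", triple=(60, 100, 140))
        _, inter = ing_reconstruct(x_star, den, sched, cfg=cfg, seed=2)
        assert np.abs(inter["x0_raw"] - x_star).max() <= 1e-5

    def test_continuity_in_weights(self, sched, rng):
        x_in = rng.random((8, 8)).astype(np.float32)
        den = oracle_denoiser(rng.random((8, 8)).astype(np.float32), sched)
        outs = []
        for w in (0.0, 1e-3):
            cfg = GuidanceConfig(w1=w, w2=w, mode="fixed", triple=(60, 100, 140))
            _, inter = ing_reconstruct(x_in, den, sched, cfg=cfg, seed=4)
            outs.append(inter["x0_raw"])
        assert np.abs(outs[0] - outs[1]).max() <= 1e-2


class TestReconstructBatch:
    def test_batch_of_one_matches_single_call(self, sched, rng):
        from scafdl.diffusion import _image_seed

        x = rng.random((16, 16)).astype(np.float32)
        den = oracle_denoiser(rng.random((16, 16)).astype(np.float32), sched)
        cfg = GuidanceConfig(mode="fixed")
        batch = reconstruct_batch([x], den, sched, cfg=cfg, seed=9)
        triple = sample_timestep_triple(sched, cfg, seed=9)
        single, _ = ing_reconstruct(x, den, sched, triple=triple, cfg=cfg, seed=_image_seed(9, x))
        assert np.array_equal(batch[0], single)

    def test_permutation_equivariance(self, sched, rng):
        xs = [rng.random((16, 16)).astype(np.float32) for _ in range(4)]
        den = oracle_denoiser(rng.random((16, 16)).astype(np.float32), sched)
        cfg = GuidanceConfig(mode="fixed")
        fwd = reconstruct_batch(xs, den, sched, cfg=cfg, seed=0)
        rev = reconstruct_batch(xs[::-1], den, sched, cfg=cfg, seed=0)
        assert np.array_equal(fwd[::-1], rev)

    def test_duplicated_image_identical_rows(self, sched, rng):
        x = rng.random((16, 16)).astype(np.float32)
        den = oracle_denoiser(rng.random((16, 16)).astype(np.float32), sched)
        out = reconstruct_batch([x, x], den, sched, cfg=GuidanceConfig(mode="fixed"), seed=1)
        assert np.array_equal(out[0], out[1])
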