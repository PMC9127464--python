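"""Microtubule random-walk simulator: geometry, rendering, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from upaint import (ConfigurationError, SimulationConfig, generate_dataset,
                    make_ground_truth, make_sparse, make_widefield, overlay_frames,
                    simulate_trajectories)
from upaint.simulate import RenderedImage, TrajectorySet, _boundary_point


def small_config(**kw):
    base = dict(field_width=64, tile_size=64, n_frames=50, step_length=0.5,
                wf_blur_sd=5.0, wf_small_size=8, seed=42)
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="module")
def traj():
    return simulate_trajectories(small_config(n_trajectories=20))


class TestTrajectories:
    def test_counts_match_config(self):
        cfg = small_config(n_trajectories=10, n_frames=500, field_width=512,
                           tile_size=256, wf_small_size=32)
        ts = simulate_trajectories(cfg)
        assert len(ts.trajectories) == 10
        assert all(len(t) == 500 for t in ts.trajectories)

    def test_single_frame_trajectory_is_boundary_point(self):
        ts = simulate_trajectories(small_config(n_frames=1))
        for t in ts.trajectories:
            assert len(t) == 1
            x, y = t[0, 1], t[0, 2]
            assert x in (0.0, 64.0) or y in (0.0, 64.0)

    def test_step_length_exact(self, traj):
        # brute-force pairwise distances over all consecutive points
        for t in traj.trajectories:
            d = np.hypot(np.diff(t[:, 1]), np.diff(t[:, 2]))
            assert np.all(np.abs(d - 0.5) < 1e-9)

    def test_boundary_starts(self, traj):
        for t in traj.trajectories:
            x, y = t[0, 1], t[0, 2]
            assert x in (0.0, 64.0) or y in (0.0, 64.0)

    def test_frame_indices_strictly_increasing(self, traj):
        for t in traj.trajectories:
            assert np.array_equal(t[:, 0], np.arange(len(t)))

    def test_noise_free_walk_is_straight(self):
        cfg = small_config(heading_noise_sd=0.0, n_trajectories=1, n_frames=40)
        ts = simulate_trajectories(cfg)
        pts = ts.trajectories[0][:, 1:]
        start, center = pts[0], np.array([32.0, 32.0])
        d = center - start
        d /= np.linalg.norm(d)
        rel = pts - start
        perp = np.abs(rel[:, 0] * d[1] - rel[:, 1] * d[0])
        assert perp.max() < 1e-9

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            small_config(step_length=0.0)
        with pytest.raises(ConfigurationError):
            small_config(n_frames=-5)
        with pytest.raises(ConfigurationError):
            small_config(sparse_fraction=1.5)
        with pytest.raises(ConfigurationError):
            small_config(wf_small_size=7)  # does not divide tile_size

    def test_boundary_point_on_perimeter(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            x, y = _boundary_point(64.0, rng)
            assert 0 <= x <= 64 and 0 <= y <= 64
            assert x in (0.0, 64.0) or y in (0.0, 64.0)


class TestOverlay:
    def test_count_conservation_vs_bruteforce(self, traj):
        frames = set(range(0, 50, 3))
        img = overlay_frames(traj, frames).data
        # independent point counter
        expected = 0
        for t in traj.trajectories:
            for f, x, y in t:
                if int(f) in frames and 0 <= x < 64 and 0 <= y < 64:
                    expected += 1
        assert img.sum() == expected

    def test_full_overlay_counts_all_infield_points(self):
        cfg = small_config(n_trajectories=10, n_frames=50, step_length=0.2)
        ts = simulate_trajectories(cfg)
        img = overlay_frames(ts, range(50)).data
        infield = sum(
            int(0 <= x < 64 and 0 <= y < 64)
            for t in ts.trajectories for _, x, y in t
        )
        # points on the far boundary (x or y == 64.0) fall outside the
        # half-open pixel grid, so infield may be slightly below 500
        assert img.sum() == infield
        assert 450 <= infield <= 500

    def test_empty_subset_gives_zero_image(self, traj):
        assert not overlay_frames(traj, set()).data.any()

    def test_floor_binning_single_point(self):
        ts = TrajectorySet([np.array([[0, 3.2, 7.9]])], field_width=16)
        img = overlay_frames(ts, {0}).data
        assert img[7, 3] == 1.0 and img.sum() == 1.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.sets(st.integers(0, 49)), st.sets(st.integers(0, 49)))
    def test_subset_monotonicity(self, traj, a, b):
        sub, sup = a & b, a | b
        small = overlay_frames(traj, sub).data
        big = overlay_frames(traj, sup).data
        assert np.all(small <= big)


class TestRenderingChain:
    def test_zero_overlay_gives_zero_ground_truth(self):
        cfg = small_config()
        zero = RenderedImage(np.zeros((64, 64)))
        assert not make_ground_truth(zero, cfg).data.any()

    def test_ground_truth_tile_shape_default_protocol(self):
        cfg = SimulationConfig(seed=0)
        ts = simulate_trajectories(cfg)
        gt = make_ground_truth(overlay_frames(ts, range(10)), cfg)
        assert gt.data.shape == (256, 256)

    def test_blur_preserves_mass_of_single_point(self):
        cfg = small_config()
        img = np.zeros((64, 64))
        img[30, 33] = 5.0
        gt = make_ground_truth(RenderedImage(img), cfg)
        assert gt.data.sum() == pytest.approx(5.0, rel=1e-3)
        assert np.all(gt.data >= 0)

    def test_overlay_too_small_rejected(self):
        cfg = small_config()
        with pytest.raises(ConfigurationError):
            make_ground_truth(RenderedImage(np.zeros((32, 32))), cfg)

    def test_widefield_shapes_default_protocol(self):
        cfg = SimulationConfig(seed=0)
        wf = make_widefield(RenderedImage(np.random.default_rng(0).random((256, 256))), cfg)
        assert wf.data.shape == (256, 256)
        assert cfg.tile_size // cfg.wf_small_size == 8  # via a 32 px intermediate

    def test_widefield_of_zero_is_zero(self):
        cfg = small_config()
        assert not make_widefield(RenderedImage(np.zeros((64, 64))), cfg).data.any()

    def test_widefield_preserves_constant_field(self):
        cfg = small_config()
        wf = make_widefield(RenderedImage(np.full((64, 64), 3.5)), cfg)
        assert np.allclose(wf.data, 3.5, atol=1e-9)


class TestSparse:
    def test_sparse_frame_count_default_protocol(self):
        assert SimulationConfig().n_sparse_frames == 50  # 10% of 500

    def test_full_fraction_equals_ground_truth(self):
        cfg = small_config(sparse_fraction=1.0)
        ts = simulate_trajectories(cfg)
        gt = make_ground_truth(overlay_frames(ts, range(cfg.n_frames)), cfg)
        sp = make_sparse(ts, cfg, np.random.default_rng(0))
        assert np.allclose(sp.data, gt.data)

    def test_first_mode_takes_leading_frames(self):
        cfg = small_config(n_frames=10, sparse_fraction=0.3)
        ts = simulate_trajectories(cfg)
        sp = make_sparse(ts, cfg, mode="first")
        manual = make_ground_truth(overlay_frames(ts, {0, 1, 2}), cfg)
        assert np.allclose(sp.data, manual.data)

    def test_too_small_fraction_rejected(self):
        cfg = small_config(n_frames=5, sparse_fraction=0.1)
        with pytest.raises(ConfigurationError):
            cfg.n_sparse_frames


class TestDataset:
    def test_deterministic_given_seed(self):
        cfg = small_config(seed=9)
        a = generate_dataset(cfg, 3)
        b = generate_dataset(cfg, 3)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.dense, tb.dense)
            assert np.array_equal(ta.sparse, tb.sparse)
            assert np.array_equal(ta.widefield, tb.widefield)

    def test_sparse_total_not_above_dense_total(self):
        for t in generate_dataset(small_config(seed=4), 5):
            assert t.sparse.sum() <= t.dense.sum()

    def test_intensities_normalized(self):
        for t in generate_dataset(small_config(seed=4), 3):
            for chan in (t.widefield, t.sparse, t.dense):
                assert chan.min() >= 0.0 and chan.max() <= 1.0
            assert t.dense.max() == pytest.approx(1.0)
            assert t.widefield.max() == pytest.approx(1.0)
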