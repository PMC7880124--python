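"""Box-counting, lacunarity, skeleton branches and tortuosity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retivasc.geometry import (
    BoxGrid,
    BranchSegment,
    box_counts,
    extract_branches,
    fractal_dimension,
    lacunarity,
    tortuosity_index,
)


def sierpinski_carpet(depth: int) -> np.ndarray:
    m = np.ones((3**depth, 3**depth), dtype=bool)
    for d in range(depth):
        hole = 3**d
        step = 3 ** (d + 1)
        for i in range(0, 3**depth, step):
            for j in range(0, 3**depth, step):
                m[i + hole:i + 2 * hole, j + hole:j + 2 * hole] = False
    return m


def brute_force_box_stats(mask, deltas, stride_fraction=1.0):
    """Independent double-loop recomputation of the per-box counts."""
    H, W = mask.shape
    out = []
    for delta in deltas:
        stride = max(1, int(np.floor(stride_fraction * delta)))
        counts = []
        for i in range(0, H, stride):
            for j in range(0, W, stride):
                counts.append(int(mask[i:i + delta, j:j + delta].sum()))
        counts = np.asarray(counts)
        out.append((int((counts > 0).sum()), counts.mean(), counts.std()))
    return out


class TestBoxCounts:
    def test_full_mask_occupancy(self):
        mask = np.ones((64, 48), dtype=bool)
        stats = box_counts(mask, BoxGrid((2, 4, 8, 16)))
        for delta, n in zip(stats.deltas, stats.n_boxes):
            assert n == np.ceil(64 / delta) * np.ceil(48 / delta)

    def test_single_pixel(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[10, 33] = True
        stats = box_counts(mask, BoxGrid((2, 4, 8, 16)))
        assert np.all(stats.n_boxes == 1)

    @pytest.mark.parametrize("stride_fraction", [1.0, 0.5])
    def test_matches_brute_force(self, stride_fraction):
        rng = np.random.default_rng(7)
        mask = rng.uniform(size=(32, 32)) < 0.3
        grid = BoxGrid((2, 3, 5, 8), stride_fraction=stride_fraction)
        stats = box_counts(mask, grid)
        brute = brute_force_box_stats(mask, grid.deltas, stride_fraction)
        for k, (n, mu, sd) in enumerate(brute):
            assert stats.n_boxes[k] == n
            assert stats.mean_count[k] == pytest.approx(mu, abs=1e-6)
            assert stats.sd_count[k] == pytest.approx(sd, abs=1e-6)

    def test_empty_mask_flagged(self):
        with pytest.warns(UserWarning, match="empty mask"):
            stats = box_counts(np.zeros((64, 64), dtype=bool))
        assert stats.empty_mask
        assert np.all(stats.n_boxes == 0)

    def test_n_non_increasing_in_delta(self, default_scene):
        stats = box_counts(default_scene.truth_mask)
        assert np.all(np.diff(stats.n_boxes) <= 0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_adding_pixels_never_decreases_n(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.uniform(size=(32, 32)) < 0.1
        grid = BoxGrid((2, 4, 8, 16))
        n0 = box_counts(mask | np.zeros_like(mask), grid).n_boxes
        extra = mask.copy()
        extra[rng.integers(0, 32), rng.integers(0, 32)] = True
        n1 = box_counts(extra, grid).n_boxes
        assert np.all(n1 >= n0)


class TestFractalDimension:
    def test_line(self):
        mask = np.zeros((512, 512), dtype=bool)
        mask[256, :] = True
        assert fractal_dimension(box_counts(mask)) == pytest.approx(1.0, abs=0.05)

    def test_plane(self):
        mask = np.ones((512, 512), dtype=bool)
        assert fractal_dimension(box_counts(mask)) == pytest.approx(2.0, abs=0.02)

    def test_sierpinski_carpet(self):
        # boxes aligned with the construction's scale hierarchy
        stats = box_counts(sierpinski_carpet(5), BoxGrid((3, 9, 27, 81)))
        assert fractal_dimension(stats) == pytest.approx(np.log(8) / np.log(3), abs=0.03)

    def test_translation_and_rotation_invariance(self, default_scene):
        mask = default_scene.truth_mask
        base = fractal_dimension(box_counts(mask))
        rolled = fractal_dimension(box_counts(np.roll(mask, (7, -13), axis=(0, 1))))
        rotated = fractal_dimension(box_counts(np.rot90(mask)))
        assert rolled == pytest.approx(base, abs=0.01)
        assert rotated == pytest.approx(base, abs=0.01)

    def test_degenerate_counts(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[5, 5] = True
        with pytest.warns(UserWarning, match="degenerate"):
            assert fractal_dimension(box_counts(mask, BoxGrid((2, 4, 8, 16)))) == 0.0


class TestLacunarity:
    def test_filled_mask_flagged(self):
        stats = box_counts(np.ones((64, 64), dtype=bool), BoxGrid((2, 4, 8, 16)))
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(lacunarity(stats))

    def test_slope_matches_brute_force(self):
        rng = np.random.default_rng(3)
        mask = rng.uniform(size=(48, 48)) < 0.25
        grid = BoxGrid((2, 4, 8, 12))
        stats = box_counts(mask, grid)
        brute = brute_force_box_stats(mask, grid.deltas)
        sd = np.array([b[2] for b in brute])
        slope = np.polyfit(np.log(grid.deltas), np.log(sd), 1)[0]
        assert lacunarity(stats) == pytest.approx(2.0 - slope, abs=1e-9)
        assert lacunarity(stats, definition="slope") == pytest.approx(slope, abs=1e-9)

    def test_anticorrelated_with_fractal_dimension(self):
        """Denser networks: higher fractal dimension, lower lacunarity."""
        import retivasc as rv
        from scipy.stats import spearmanr

        dfs, lacs = [], []
        for k, prob in enumerate(np.linspace(0.002, 0.02, 10)):
            tp = rv.TreeParams(seed=100 + k, image_size=512, disc_radius=30.0,
                               px_per_micron=30.0 / 900.0, branching_prob=prob,
                               sine_amplitude=5.0, sine_period=17.0)
            mask = rv.render_scene(rv.simulate_tree(tp), seed=k).truth_mask
            stats = box_counts(mask)
            dfs.append(fractal_dimension(stats))
            lacs.append(lacunarity(stats))
        rho = spearmanr(dfs, lacs).statistic
        assert rho < 0


class TestBranches:
    def test_straight_bar_single_segment(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[30:34, 5:60] = True
        segs = extract_branches(mask)
        assert len(segs) == 1
        assert segs[0].arc_length == pytest.approx(segs[0].chord_length, rel=0.02)

    def test_y_shape_three_segments(self):
        mask = np.zeros((101, 101), dtype=bool)
        mask[50, 10:51] = True          # stem
        for k in range(40):             # two diagonal arms
            mask[50 - k, 50 + k] = True
            mask[50 + k, 50 + k] = True
        segs = extract_branches(mask, min_branch_len=5, smooth_window=1)
        assert len(segs) == 3

    def test_segment_count_matches_generator(self):
        """Extracted branch count tracks the generator's bookkeeping (gentle
        curvature so vessels rarely self-intersect)."""
        import retivasc as rv
        from retivasc import segment as sg

        for seed in (1, 2, 3):
            tree = rv.simulate_tree(rv.TreeParams(seed=seed, sine_amplitude=4.0,
                                                  sine_period=150.0))
            scene = rv.render_scene(tree, seed=seed, noise_sd=0.0)
            zone = sg.zone_mask(scene.truth_mask.shape, scene.disc_center,
                                scene.disc_radius, sg.GEOMETRY_ZONE)
            extracted = len(extract_branches(scene.truth_mask & zone))
            r_in, r_out = sg.GEOMETRY_ZONE.radii(tree.params.disc_radius)
            c = np.array(tree.params.center)
            n_true = 0
            for s in tree.segments:
                d = np.linalg.norm(s.points - c, axis=1)
                inz = (d >= r_in) & (d < r_out)
                arc = np.linalg.norm(np.diff(s.points, axis=0), axis=1)
                if (arc * (inz[:-1] & inz[1:])).sum() >= 10:
                    n_true += 1
            assert abs(extracted - n_true) <= 0.2 * n_true

    def test_empty_mask(self):
        assert extract_branches(np.zeros((32, 32), dtype=bool)) == []


class TestTortuosity:
    def test_straight_segment_is_one(self):
        seg = BranchSegment(np.array([[0.0, 0.0], [5.0, 5.0], [10.0, 10.0]]))
        assert tortuosity_index([seg]) == pytest.approx(1.0)

    def test_semicircle(self):
        th = np.linspace(0.0, np.pi, 2001)
        seg = BranchSegment(100.0 * np.column_stack([np.sin(th), np.cos(th)]))
        assert tortuosity_index([seg]) == pytest.approx(2.0 / np.pi, abs=0.01)

    def test_arc_over_chord_convention(self):
        th = np.linspace(0.0, np.pi, 2001)
        seg = BranchSegment(100.0 * np.column_stack([np.sin(th), np.cos(th)]))
        assert tortuosity_index([seg], convention="arc_over_chord") == pytest.approx(
            np.pi / 2.0, abs=0.03)

    def test_arc_never_below_chord(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pts = np.cumsum(rng.normal(size=(20, 2)), axis=0)
            seg = BranchSegment(pts)
            assert seg.arc_length >= seg.chord_length - 1e-12

    def test_no_segments_raises(self):
        with pytest.raises(ValueError):
            tortuosity_index([])
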