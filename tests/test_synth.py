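"""Synthetic trees, scenes and cohort tables."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import retivasc as rv
from retivasc.synth import (
    METRICS,
    SDQ_SUBSCALES,
    CohortParams,
    TreeParams,
    default_repeat_study,
    marginal_to_structural,
    simulate_cohort,
    simulate_repeats,
    simulate_tree,
)


class TestSimulateTree:
    def test_deterministic(self):
        t1 = simulate_tree(TreeParams(seed=9))
        t2 = simulate_tree(TreeParams(seed=9))
        assert t1.n_segments == t2.n_segments
        for a, b in zip(t1.segments, t2.segments):
            assert np.array_equal(a.points, b.points)
            assert a.width_um == b.width_um

    def test_straight_when_amplitude_zero(self):
        tree = simulate_tree(TreeParams(seed=2, sine_amplitude=0.0, branching_prob=0.0))
        for seg in tree.segments:
            p = seg.points
            chord = np.linalg.norm(p[-1] - p[0])
            arc = np.linalg.norm(np.diff(p, axis=0), axis=1).sum()
            assert arc == pytest.approx(chord, rel=1e-9)

    def test_no_segment_enters_disc(self):
        tree = simulate_tree(TreeParams(seed=4))
        c = np.array(tree.params.center)
        r = tree.params.disc_radius
        for seg in tree.segments:
            assert np.linalg.norm(seg.points - c, axis=1).min() > r

    def test_children_start_at_parent_endpoint_and_taper(self):
        tree = simulate_tree(TreeParams(seed=6))
        taper = 2.0 ** (-1.0 / tree.params.taper_exponent)
        n_side = 0
        for seg in tree.segments:
            if seg.parent_id is None:
                continue
            parent = tree.by_id[seg.parent_id]
            assert np.allclose(seg.points[0], parent.points[-1])
            if seg.generation > parent.generation:  # side branch
                assert seg.width_um == pytest.approx(parent.width_um * taper)
                n_side += 1
            else:  # continuation
                assert seg.width_um == pytest.approx(
                    parent.width_um * tree.params.continuation_taper)
        assert n_side > 5

    def test_major_vessels_alternate_and_start_on_margin(self):
        tree = simulate_tree(TreeParams(seed=1))
        majors = [s for s in tree.segments if s.parent_id is None]
        assert len(majors) == 12
        labels = {s.label for s in majors}
        assert labels == {"arteriole", "venule"}
        c = np.array(tree.params.center)
        for s in majors:
            assert np.linalg.norm(s.points[0] - c) == pytest.approx(
                tree.params.disc_radius + 2.0, abs=1e-6)

    def test_image_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            TreeParams(image_size=256, disc_radius=60.0)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            TreeParams(root_width_mean_art=-1.0)
        with pytest.raises(ValueError):
            TreeParams(sine_amplitude=-0.1)


class TestRenderScene:
    def test_midpoint_threshold_recovers_vessel_interiors(self):
        tree = simulate_tree(TreeParams(seed=3, image_size=512, disc_radius=30.0,
                                        px_per_micron=30.0 / 900.0))
        scene = rv.render_scene(tree, contrast=1.0, noise_sd=0.0, disc_brightness=0.0)
        interior = scene.image < 1e-9  # full-contrast vessel cores
        # every fully covered pixel is truth; interiors recovered exactly
        assert np.all(scene.truth_mask[interior])

    def test_vessel_area_bookkeeping(self, small_scene):
        assert small_scene.vessel_area_px == int(small_scene.truth_mask.sum())

    def test_vessels_darker_than_local_background(self, small_scene):
        img, truth = small_scene.image, small_scene.truth_mask
        assert img[truth].mean() < img[~truth].mean()

    def test_render_deterministic(self, small_tree_params):
        tree = simulate_tree(small_tree_params)
        s1 = rv.render_scene(tree, seed=7)
        s2 = rv.render_scene(tree, seed=7)
        assert np.array_equal(s1.image, s2.image)


class TestSimulateCohort:
    def test_deterministic(self):
        c1 = simulate_cohort(CohortParams(seed=5))
        c2 = simulate_cohort(CohortParams(seed=5))
        pd.testing.assert_frame_equal(c1, c2)

    def test_sdq_additivity_and_bounds(self, default_cohort):
        sub = sum(default_cohort[f"sdq_{s}"] for s in SDQ_SUBSCALES)
        assert (default_cohort["sdq_total"] == sub).all()
        for s in SDQ_SUBSCALES:
            col = default_cohort[f"sdq_{s}"]
            assert col.between(0, 10).all()

    def test_latencies_positive(self, default_cohort):
        for col in ("stroop_ms", "cp_ms", "digit_symbol_s", "pattern_comparison_s"):
            assert (default_cohort[col] > 0).all()

    def test_eye_average_consistent(self, default_cohort):
        for m in METRICS:
            avg = 0.5 * (default_cohort[f"{m}_left"] + default_cohort[f"{m}_right"])
            assert np.allclose(avg, default_cohort[m])

    def test_visit_mix(self):
        counts = []
        for seed in range(20):
            coh = simulate_cohort(CohortParams(seed=seed))
            counts.append(coh.groupby("child_id")["n_exams"].first().value_counts(
                normalize=True).reindex([1, 2, 3]).to_numpy())
        mean = np.nanmean(counts, axis=0)
        assert mean == pytest.approx([25 / 221, 124 / 221, 72 / 221], abs=0.03)

    def test_probabilities_validated(self):
        with pytest.raises(ValueError):
            CohortParams(bmi_probs=(0.5, 0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            CohortParams(icc_targets=(1.2, 0.8, 0.8, 0.8, 0.8))

    def test_metric_means_reproduce_population(self):
        """Mean fractal dimension / tortuosity / CRAE over 40 cohorts sit on
        the configured population values (cheap slice of the calibration
        property; the full 200-cohort check runs in the acceptance suite)."""
        means = np.array([
            simulate_cohort(CohortParams(seed=s))[list(METRICS)].mean().to_numpy()
            for s in range(40)
        ]).mean(axis=0)
        assert means[0] == pytest.approx(1.500, abs=0.005)
        assert means[2] == pytest.approx(0.857, abs=0.003)
        assert means[3] == pytest.approx(163.8, abs=2.0)

    def test_sdq_median_in_published_range(self):
        meds = [simulate_cohort(CohortParams(seed=s))
                .groupby("child_id")["sdq_total"].first().median()
                for s in range(30)]
        assert np.mean(meds) == pytest.approx(7.0, abs=1.0)


class TestMarginalToStructural:
    def test_identity_without_correlation(self):
        cov = np.diag([1.0, 4.0, 9.0])
        m = np.array([2.0, -1.0, 0.5])
        assert np.allclose(marginal_to_structural(m, cov), m)

    def test_implied_marginals_match(self):
        p = CohortParams()
        m = np.array([28.0, -23.0, -49.5, 0.0, 0.0])
        beta = marginal_to_structural(m, p.metric_cov)
        implied = (p.metric_cov @ beta) / np.diag(p.metric_cov)
        assert np.allclose(implied, m)


class TestSimulateRepeats:
    def test_zero_within_sd_gives_icc_one(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(1.5, 0.03, 100)
        reps = simulate_repeats(vals, 0.0, np.full(100, 2), seed=1)
        assert rv.icc_oneway(reps).icc == pytest.approx(1.0, abs=1e-9)

    def test_zero_between_sd_gives_icc_near_zero(self):
        reps = simulate_repeats(np.full(150, 1.5), 0.02, np.full(150, 3), seed=2)
        assert rv.icc_oneway(reps).icc <= 0.05

    def test_default_world_icc_in_published_band(self):
        """ICC(1,1) of simulated repeated fractal-dimension measurements falls
        in the published 0.72-0.88 reliability band in >= 90% of replicates."""
        in_band = 0
        n_rep = 60
        for s in range(n_rep):
            icc = rv.icc_oneway(default_repeat_study(seed=s)).icc
            in_band += 0.72 <= icc <= 0.88
        assert in_band / n_rep >= 0.90

    def test_negative_within_sd_rejected(self):
        with pytest.raises(ValueError):
            simulate_repeats(np.ones(5), -0.1, np.full(5, 2), seed=0)
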