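"""Segmentation, axial profiling, 15-segment splicing and classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poletrack.quant import (
    N_SEGMENTS,
    AxialProfile,
    ClusterCallSet,
    ProfileError,
    SegmentProfile,
    axial_profile,
    build_histogram,
    classify_pattern,
    detect_clusters,
    estimate_background,
    resolve_cluster_threshold,
    segment_cells,
    splice_segments,
)
from poletrack.scenes import (
    FixedSchedule,
    NoiseModel,
    SceneConfig,
    generate_movie,
)

from conftest import match_truth


def _profile(values, positions=None, cell_id=0):
    values = np.asarray(values, dtype=float)
    if positions is None:
        positions = np.arange(len(values), dtype=float)
    return AxialProfile(cell_id=cell_id, frame=0, positions=positions, intensities=values)


class TestSegmentation:
    def test_blank_image_yields_nothing(self):
        assert segment_cells(np.full((64, 64), 7.0)) == []

    def test_single_cell_area_close_to_analytic_footprint(self, noiseless_snapshot):
        cfg, img, _ = noiseless_snapshot
        masks = segment_cells(img)
        assert len(masks) == 2
        w, length = cfg.cell_width_px, cfg.cell_length_px
        analytic = w * (length - w) + np.pi * (w / 2) ** 2
        for m in masks:
            assert abs(m.area - analytic) / analytic < 0.10

    def test_two_cells_centroids_match_truth(self, noiseless_snapshot):
        _, img, truths = noiseless_snapshot
        masks = segment_cells(img)
        assert len(masks) == 2
        for m in masks:
            t = match_truth(m, truths)
            err = np.hypot(
                m.centroid_xy[0] - t.centroids[0, 0],
                m.centroid_xy[1] - t.centroids[0, 1],
            )
            assert err < 1.0

    def test_axis_spans_cell_length(self, noiseless_snapshot):
        cfg, img, _ = noiseless_snapshot
        for m in segment_cells(img):
            span = np.linalg.norm(m.pole_tips[1] - m.pole_tips[0])
            assert span == pytest.approx(cfg.cell_length_px, rel=0.15)


class TestAxialProfile:
    def test_uniform_cell_gives_flat_profile(self, noiseless_snapshot):
        _, img, _ = noiseless_snapshot
        m = segment_cells(img)[0]
        p = axial_profile(img, m, background=100.0)
        lo, hi = np.quantile(p.positions, [0.1, 0.9])
        central = p.intensities[(p.positions >= lo) & (p.positions <= hi)]
        assert np.all(np.abs(central - central.mean()) / central.mean() < 0.02)

    def test_cluster_peak_sits_at_its_pole(self):
        cfg = SceneConfig(
            n_cells=1,
            n_frames=2,
            reversal_process=FixedSchedule([1]),
            polar_cluster_amplitudes=(6000.0, 0.0),
            initial_direction=1,
            noise=NoiseModel(0.0, 0.0),
            seed=8,
        )
        stack, truths = generate_movie(cfg)
        img = stack[0].astype(float)
        m = segment_cells(img)[0]
        p = axial_profile(img, m, background=estimate_background(img, [m]))
        peak_pos = p.positions[np.argmax(p.intensities)]
        # cluster at the leading (+x) pole, which is the last axis point
        dist_to_end = p.positions[-1] - peak_pos
        assert dist_to_end <= 2.0

    def test_profile_nonnegative_after_background_floor(self, mixed_population):
        _, img, _ = mixed_population
        masks = segment_cells(img)
        bg = estimate_background(img, masks)
        for m in masks[:5]:
            p = axial_profile(img, m, background=bg)
            assert np.all(p.intensities >= 0)

    def test_degenerate_axis_raises(self):
        from poletrack.quant import CellMask

        with pytest.raises(ProfileError):
            CellMask(
                cell_id=0, frame=0,
                pixels=(np.array([1]), np.array([1])),
                shape=(4, 4), centroid=(1.0, 1.0),
                axis=np.array([[1.0, 1.0], [1.0, 2.0]]),
            )


class TestSplicing:
    def test_constant_profile_maps_to_constant_segments(self):
        sp = splice_segments(_profile(np.full(30, 3.7)))
        assert np.allclose(sp.values, 3.7)

    def test_always_exactly_fifteen_segments(self):
        for n in (5, 16, 31, 97):
            sp = splice_segments(_profile(np.arange(n, dtype=float) + 1))
            assert len(sp.values) == N_SEGMENTS == 15

    def test_matches_bruteforce_integration_oracle(self):
        rng = np.random.default_rng(42)
        values = rng.uniform(0, 100, size=31)
        pos = np.cumsum(rng.uniform(0.5, 2.0, size=31))
        sp = splice_segments(_profile(values, pos))

        # oracle: dense midpoint quadrature of the piecewise-constant profile
        u = pos - pos[0]
        L = u[-1]
        mids = (u[:-1] + u[1:]) / 2
        edges = np.concatenate([[0.0], mids, [L]])
        xs = np.linspace(0, L, 3_000_001)[:-1] + L / 6_000_002
        idx = np.searchsorted(edges, xs, side="right") - 1
        fx = values[np.clip(idx, 0, 30)]
        expected = [
            fx[(xs >= k * L / 15) & (xs < (k + 1) * L / 15)].mean()
            for k in range(15)
        ]
        assert np.allclose(sp.values, expected, rtol=5e-5)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(st.floats(0, 1e4), min_size=4, max_size=60),
        st.integers(0, 2**31 - 1),
    )
    def test_splicing_conserves_integrated_intensity(self, values, seed):
        rng = np.random.default_rng(seed)
        pos = np.cumsum(rng.uniform(0.3, 2.0, size=len(values)))
        p = _profile(np.array(values), pos)
        sp = splice_segments(p)
        total = np.sum(sp.values) * sp.arc_length / 15
        assert total == pytest.approx(p.integrated(), rel=1e-6, abs=1e-6)

    def test_mirror_equivariance(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 50, size=40)
        pos = np.cumsum(rng.uniform(0.5, 1.5, size=40))
        fwd = splice_segments(_profile(values, pos))
        # reverse the axis orientation: same samples walked tip-to-tip backwards
        rev_pos = pos[-1] - pos[::-1]
        rev = splice_segments(_profile(values[::-1], rev_pos))
        assert np.allclose(fwd.values, rev.values[::-1], rtol=1e-9)


class TestClusterCalls:
    def test_all_below_threshold_is_diffuse(self):
        sp = SegmentProfile(0, 0, np.full(15, 10.0), 40.0)
        calls = detect_clusters(sp, 50.0)
        assert not calls.flags.any()
        assert classify_pattern(calls, sp).category == "diffuse"

    def test_zero_threshold_flags_everything(self):
        sp = SegmentProfile(0, 0, np.arange(15, dtype=float), 40.0)
        assert detect_clusters(sp, 0.0).flags.all()

    def test_relative_rule_requires_data(self):
        with pytest.raises(ValueError):
            resolve_cluster_threshold([], "quantile:0.9")

    def test_quantile_rule_resolves_globally(self):
        sps = [
            SegmentProfile(i, 0, np.full(15, float(i)), 40.0) for i in range(10)
        ]
        thr = resolve_cluster_threshold(sps, "quantile:0.5")
        assert thr == pytest.approx(4.5)

    def test_population_clusters_confined_to_polar_zone(self):
        """Unipolar population at SNR >> 5: cluster calls stay within the
        polar zone (outermost two segments; a diffraction-limited cluster's
        mass straddles at most two 2.9 px segments) and the terminal
        segment itself is flagged for at least 95% of cells."""
        cfg = SceneConfig(
            n_cells=40,
            n_frames=2,
            reversal_process=FixedSchedule([1]),
            polar_cluster_amplitudes=(2500.0, 0.0),
            spot_sigma_px=1.0,
            seed=13,
        )
        stack, _ = generate_movie(cfg)
        img = stack[0].astype(float)
        masks = segment_cells(img)
        bg = estimate_background(img, masks)
        segs = [splice_segments(axial_profile(img, m, background=bg)) for m in masks]
        thr = resolve_cluster_threshold(segs, "robust:5")
        confined = terminal = 0
        for s in segs:
            flagged = set(np.flatnonzero(detect_clusters(s, thr).flags).tolist())
            confined += bool(flagged) and flagged <= {0, 1, 13, 14}
            terminal += bool(flagged & {0, 14})
        assert confined >= 0.95 * len(segs)
        assert terminal >= 0.95 * len(segs)


class TestHistogram:
    def _calls(self, flag_positions, cell_id):
        flags = np.zeros(15, dtype=bool)
        flags[list(flag_positions)] = True
        return ClusterCallSet(cell_id, 0, flags, 1.0)

    def test_all_unipolar_at_first_segment(self):
        calls = [self._calls([0], i) for i in range(100)]
        hist = build_histogram(calls)
        assert hist.counts[0] == 100
        assert hist.counts[1:].sum() == 0
        assert hist.n_cells == 100

    def test_counts_bounded_by_population(self):
        rng = np.random.default_rng(0)
        calls = [
            self._calls(rng.choice(15, size=2, replace=False), i)
            for i in range(100)
        ]
        hist = build_histogram(calls)
        assert np.all(hist.counts <= 100)
        assert np.all((hist.frequencies >= 0) & (hist.frequencies <= 1))

    def test_duplicate_cell_rejected(self):
        with pytest.raises(ValueError):
            build_histogram([self._calls([0], 1), self._calls([1], 1)])

    def test_bipolar_count_recovered_exactly_noiseless(self):
        """0.6/0.4 unipolar/bipolar noiseless population: the last-bin count
        equals the generated bipolar count (unipolar clusters all sit at the
        leading pole, forced to the first bin)."""
        cfg = SceneConfig(
            n_cells=100,
            n_frames=2,
            reversal_process=FixedSchedule([1]),
            pattern_mix={"unipolar": 0.6, "bipolar_symmetric": 0.4},
            initial_direction=-1,
            noise=NoiseModel(0.0, 0.0),
            lane_pitch_px=14,
            seed=17,
        )
        stack, truths = generate_movie(cfg)
        img = stack[0].astype(float)
        masks = segment_cells(img)
        assert len(masks) == 100
        bg = estimate_background(img, masks)
        segs = [splice_segments(axial_profile(img, m, background=bg)) for m in masks]
        thr = resolve_cluster_threshold(segs, "robust:5")
        hist = build_histogram([detect_clusters(s, thr) for s in segs])
        n_bipolar = sum(t.pattern == "bipolar_symmetric" for t in truths)
        assert hist.counts[-1] == n_bipolar
        assert hist.counts[0] == 100  # every cell has a leading-pole cluster


class TestClassification:
    def _case(self, flags_pos, values):
        flags = np.zeros(15, dtype=bool)
        flags[list(flags_pos)] = True
        calls = ClusterCallSet(0, 0, flags, 1.0)
        sp = SegmentProfile(0, 0, np.asarray(values, dtype=float), 40.0)
        return calls, sp

    def test_single_terminal_flag_is_unipolar(self):
        vals = np.full(15, 1.0)
        vals[0] = 9.0
        calls, sp = self._case([0], vals)
        assert classify_pattern(calls, sp).category == "unipolar"

    def test_equal_terminal_intensities_are_symmetric(self):
        vals = np.full(15, 1.0)
        vals[0] = vals[14] = 5.0
        calls, sp = self._case([0, 14], vals)
        out = classify_pattern(calls, sp)
        assert out.category == "bipolar_symmetric"
        assert out.asymmetry_ratio == pytest.approx(1.0)

    def test_three_to_one_terminals_are_asymmetric(self):
        vals = np.full(15, 1.0)
        vals[0], vals[14] = 9.0, 3.0
        calls, sp = self._case([0, 14], vals)
        out = classify_pattern(calls, sp, sym_cutoff=1.5)
        assert out.category == "bipolar_asymmetric"
        assert out.asymmetry_ratio == pytest.approx(3.0)

    def test_midcell_flags_do_not_make_a_pole(self):
        vals = np.full(15, 1.0)
        vals[7] = 9.0
        calls, sp = self._case([7], vals)
        assert classify_pattern(calls, sp).category == "diffuse"


class TestEndToEndRecovery:
    def test_classification_accuracy_on_noisy_mix(self, mixed_population):
        _, img, truths = mixed_population
        masks = segment_cells(img)
        bg = estimate_background(img, masks)
        segs = [splice_segments(axial_profile(img, m, background=bg)) for m in masks]
        thr = resolve_cluster_threshold(segs, "robust:5")
        correct = 0
        for m, s in zip(masks, segs):
            t = match_truth(m, truths)
            got = classify_pattern(detect_clusters(s, thr), s, 1.5).category
            correct += got == t.pattern
        assert correct / len(masks) >= 0.95

    def test_terminal_bin_frequency_within_binomial_ci(self, mixed_population):
        from scipy import stats

        _, img, truths = mixed_population
        masks = segment_cells(img)
        bg = estimate_background(img, masks)
        segs = [splice_segments(axial_profile(img, m, background=bg)) for m in masks]
        thr = resolve_cluster_threshold(segs, "robust:5")
        hist = build_histogram([detect_clusters(s, thr) for s in segs])
        # generating probability that a given pole carries a cluster
        p_pole = sum(
            int(t.amp_pole_neg[0] > 0) + int(t.amp_pole_pos[0] > 0)
            for t in truths
        ) / (2 * len(truths))
        n = hist.n_cells
        lo, hi = stats.binom.interval(0.95, n, p_pole)
        for terminal in (hist.counts[0], hist.counts[-1]):
            assert lo <= terminal <= hi
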