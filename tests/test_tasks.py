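"""Stimulus generators, reward function and curricula."""

import numpy as np
import pytest
import scipy.stats

import relearnn as rl
from relearnn import tasks
from relearnn.architectures import build_contour_network, build_tracing_network
from relearnn.oracles import flood_fill, n_components


class TestContourStimulus:
    def test_length_nine_horizontal_fills_center_row(self):
        rng = np.random.default_rng(1)
        stim = tasks.generate_contour_stimulus(9, 0, 1.0, rng)
        side = stim.target_side
        assert np.all(stim.bars[side, 4, :] == 0)
        assert np.all(stim.contrast[side, 4, :] == 1.0)

    def test_vertical_and_diagonal_geometry(self):
        rng = np.random.default_rng(2)
        vert = tasks.generate_contour_stimulus(5, 2, 1.0, rng)
        cells = tasks.contour_cells(5, 2)
        assert cells == [(2, 4), (3, 4), (4, 4), (5, 4), (6, 4)]
        assert all(vert.bars[vert.target_side, r, c] == 2 for r, c in cells)
        diag = tasks.contour_cells(3, 1)
        assert diag == [(3, 3), (4, 4), (5, 5)]

    def test_length_one_is_indistinguishable_from_distractor(self):
        """A one-element "contour" has no orientation: both apertures are
        identically distributed and only the center contrast is set."""
        rng = np.random.default_rng(3)
        counts = np.zeros(4)
        for _ in range(400):
            stim = tasks.generate_contour_stimulus(1, 2, 1.0, rng)
            counts[stim.bars[stim.target_side, 4, 4]] += 1
            assert stim.contrast[stim.target_side, 4, 4] == 1.0
        assert counts.min() > 50  # center orientation is not fixed

    def test_background_contrast_applied_to_non_contour_bars(self):
        rng = np.random.default_rng(4)
        stim = tasks.generate_contour_stimulus(3, 0, 0.5, rng)
        side = stim.target_side
        mask = np.full((9, 9), False)
        for r, c in tasks.contour_cells(3, 0):
            mask[r, c] = True
        assert np.all(stim.contrast[side][~mask] == 0.5)
        assert np.all(stim.contrast[1 - side] == 0.5)
        assert np.all(stim.contrast[side][mask] == 1.0)

    def test_background_orientations_uniform(self):
        """Chi-square test over 10,000 draws on the distractor aperture."""
        rng = np.random.default_rng(5)
        counts = np.zeros(4)
        for _ in range(10_000):
            stim = tasks.generate_contour_stimulus(9, 0, 1.0, rng)
            other = 1 - stim.target_side
            counts += np.bincount(stim.bars[other].ravel(), minlength=4)
        _, pval = scipy.stats.chisquare(counts)
        assert pval > 0.01

    def test_invalid_length_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            tasks.generate_contour_stimulus(4, 0, 1.0, rng)

    def test_encoding_one_unit_per_cell(self):
        spec = build_contour_network()
        rng = np.random.default_rng(7)
        stim = tasks.generate_contour_stimulus(5, 0, 0.8, rng)
        I = tasks.encode_contour(stim, spec)
        assert I.shape == (648,)
        grid = I.reshape(2, 4, 9, 9)
        # exactly one orientation active per (pattern, location)
        assert np.all((grid > 0).sum(axis=1) == 1)
        # active unit's orientation matches the bar and carries the contrast
        for p in range(2):
            for r in range(9):
                for c in range(9):
                    o = stim.bars[p, r, c]
                    assert grid[p, o, r, c] == stim.contrast[p, r, c]


class TestCurveStimulus:
    @pytest.mark.parametrize("length", [2, 3, 4, 5])
    def test_invariants_across_lengths(self, length):
        rng = np.random.default_rng(10 + length)
        for _ in range(40):
            stim = tasks.generate_curve_stimulus(length, rng)
            assert len(stim.target_path) == length
            assert len(stim.distractor_path) == length
            lum = stim.channels[tasks.LUM] > 0
            labels = flood_fill(lum)
            assert labels.max() == 2
            assert labels[stim.cue_pixel] == labels[stim.target_marker_pixel]
            assert labels[stim.distractor_marker_pixel] != labels[stim.cue_pixel]
            # cue is an endpoint of the target curve, marker the other end
            assert stim.cue_pixel in (stim.target_path[0], stim.target_path[-1])
            assert {stim.cue_pixel, stim.target_marker_pixel} == {
                stim.target_path[0],
                stim.target_path[-1],
            }
            # red only at the cue, green at the two markers, luminance on curves
            assert stim.channels[tasks.RED].sum() == 1.0
            assert stim.channels[tasks.GREEN].sum() == 2.0
            assert lum.sum() == 2 * length

    def test_paths_are_4_connected_simple(self):
        rng = np.random.default_rng(20)
        for _ in range(50):
            stim = tasks.generate_curve_stimulus(5, rng)
            for path in (stim.target_path, stim.distractor_path):
                assert len(set(path)) == len(path)
                for (r1, c1), (r2, c2) in zip(path, path[1:]):
                    assert abs(r1 - r2) + abs(c1 - c2) == 1

    def test_diagonal_touch_counts_as_disconnected(self):
        """Curves that touch only diagonally are valid displays."""
        rng = np.random.default_rng(30)
        seen_diagonal_touch = False
        for _ in range(300):
            stim = tasks.generate_curve_stimulus(3, rng)
            t = set(stim.target_path)
            for r, c in stim.distractor_path:
                for dr, dc in ((-1, -1), (-1, 1), (1, -1), (1, 1)):
                    if (r + dr, c + dc) in t:
                        seen_diagonal_touch = True
        assert seen_diagonal_touch

    def test_determinism_per_seed(self):
        a = tasks.generate_curve_stimulus(4, np.random.default_rng(99))
        b = tasks.generate_curve_stimulus(4, np.random.default_rng(99))
        np.testing.assert_array_equal(a.channels, b.channels)
        assert a.target_path == b.target_path

    def test_unsatisfiable_geometry_fails_explicitly(self):
        rng = np.random.default_rng(40)
        with pytest.raises(tasks.StimulusError):
            tasks.generate_curve_stimulus(13, rng, max_tries=200)

    def test_marker_stimulus_is_single_green_square(self):
        stim = tasks.generate_marker_stimulus(np.random.default_rng(50))
        assert stim.channels[tasks.GREEN].sum() == 1.0
        assert stim.channels[tasks.LUM].sum() == 1.0
        assert stim.channels[tasks.RED].sum() == 0.0
        r, c = stim.target_marker_pixel
        assert stim.correct_action == r * 5 + c


class TestReward:
    def test_correct_and_incorrect(self):
        rng = np.random.default_rng(60)
        stim = tasks.generate_curve_stimulus(3, rng)
        assert tasks.reward_for(stim, stim.correct_action, 0.8) == 0.8
        wrong = (stim.correct_action + 1) % 25
        assert tasks.reward_for(stim, wrong, 0.8) == 0.0


class TestCurricula:
    def test_contour_contrast_sequence(self):
        cur = tasks.contour_curriculum()
        contrasts = [p.stimulus_params["contrast_bg"] for p in cur.phases]
        assert contrasts == [0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.0]
        counts = [p.n_trials for p in cur.phases]
        assert counts == [500, 100, 100, 100, 100, 100, None]
        assert sum(c for c in counts if c) == 500 + 5 * 100

    def test_contour_without_pretraining_starts_full(self):
        cur = tasks.contour_curriculum(pretraining=False)
        assert len(cur.phases) == 1
        assert cur.phases[0].stimulus_params["contrast_bg"] == 1.0

    def test_tracing_phase_sequence(self):
        cur = tasks.tracing_curriculum(max_length=5)
        names = [p.name for p in cur.phases]
        assert names == ["marker", "len2", "len3", "len4", "len5", "full"]
        assert cur.phases[-1].stimulus_params["lengths"] == (2, 3, 4, 5)

    def test_tracing_without_shaping_is_single_phase(self):
        cur = tasks.tracing_curriculum(max_length=5, shaping=False)
        assert len(cur.phases) == 1

    def test_drawn_stimuli_respect_phase_parameters(self):
        cur = tasks.tracing_curriculum(max_length=3)
        rng = np.random.default_rng(70)
        for phase in cur.phases:
            stim = tasks.draw_stimulus("tracing", phase.stimulus_params, rng, 5)
            if phase.stimulus_params.get("marker_only"):
                assert stim.cue_pixel is None
            else:
                assert len(stim.target_path) in phase.stimulus_params["lengths"]
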