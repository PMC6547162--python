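"""Segregation phenotype scoring: onset, distances, categories, summaries."""

import numpy as np
import pytest

from conftest import simple_trajectory

from meioquant import synth
from meioquant.classify import (
    CO_SEGREGATED,
    CO_SEGREGATING,
    FAILING,
    SEGREGATING,
    SPLIT_DISTAL,
    SPLIT_PROXIMAL,
    UNCLASSIFIABLE,
    anaphase_intensity_window,
    anaphase_onset,
    assign_poles,
    classify_heterozygous,
    classify_homozygous,
    link_foci,
    max_split_distance,
    normalize_intensity,
    population_summary,
    score_presence,
)


def het_trajectory(distance_um, onset=2, n_frames=6):
    """Single focus before onset; split pair at given distance after."""
    center = (2.0, 2.0)
    frames = []
    for f in range(n_frames):
        if f <= onset or distance_um is None:
            frames.append([center])
        else:
            frames.append(
                [(center[0], center[1] - distance_um / 2),
                 (center[0], center[1] + distance_um / 2)]
            )
    marker = [f >= onset for f in range(n_frames)]
    return simple_trajectory(frames, marker)


class TestAnaphaseOnset:
    def test_no_marker_transition_is_unclassifiable(self):
        traj = simple_trajectory([[(1, 1)]] * 4, [False] * 4)
        assert anaphase_onset(traj) is None
        assert classify_heterozygous(traj).category == UNCLASSIFIABLE

    def test_first_true_frame(self):
        traj = simple_trajectory([[(1, 1)]] * 4, [False, False, True, True])
        assert anaphase_onset(traj) == 2

    def test_onset_matches_ground_truth_on_simulated_population(self):
        params = synth.SimParams(seed=7, n_cells=30)
        _, trajectories, truth = synth.make_population(params, render_images=False)
        for traj, cell in zip(trajectories, truth.cells):
            assert anaphase_onset(traj) == cell.onset_frame


class TestMaxSplitDistance:
    def test_single_focus_gives_null(self):
        d, overrun = max_split_distance(het_trajectory(None), onset=2)
        assert d is None and not overrun

    def test_pixel_arithmetic(self):
        # foci at (0,0) and (0,3) px with 0.5 um/px -> 1.5 um
        traj = simple_trajectory(
            [[(0.0, 0.0)], [(0.0, 0.0), (0.0, 3 * 0.5)], [(0.0, 0.0), (0.0, 1.5)]],
            [True, True, True],
        )
        d, _ = max_split_distance(traj, onset=0)
        assert d == pytest.approx(1.5)

    def test_window_overrun_flagged(self):
        traj = het_trajectory(1.0, onset=2, n_frames=4)
        _, overrun = max_split_distance(traj, onset=2)
        assert overrun
        assert classify_heterozygous(traj).category == UNCLASSIFIABLE

    def test_distance_recovered_from_simulator(self):
        params = synth.SimParams(seed=3, n_cells=40, p_split=1.0)
        _, trajectories, truth = synth.make_population(params, render_images=False)
        for traj, cell in zip(trajectories, truth.cells):
            d, _ = max_split_distance(traj, cell.onset_frame)
            assert d == pytest.approx(cell.split_distance_um, abs=1e-9)


class TestClassifyHeterozygous:
    def test_p_split_zero_population_all_co_segregated(self):
        params = synth.SimParams(seed=5, n_cells=25, p_split=0.0)
        _, trajectories, _ = synth.make_population(params, render_images=False)
        calls = [classify_heterozygous(t) for t in trajectories]
        assert all(c.category == CO_SEGREGATED for c in calls)

    @pytest.mark.parametrize(
        "distance,expected",
        [
            (None, CO_SEGREGATED),
            (0.3, CO_SEGREGATED),  # below split_min: not two distinct foci
            (1.0, SPLIT_PROXIMAL),
            (1.99, SPLIT_PROXIMAL),
            (2.0, SPLIT_DISTAL),  # boundary convention: exactly 2 um is distal
            (3.5, SPLIT_DISTAL),
        ],
    )
    def test_distance_categories(self, distance, expected):
        assert classify_heterozygous(het_trajectory(distance)).category == expected

    def test_boundary_monotonicity(self):
        # raising the boundary can only move distal -> proximal
        for d in (0.8, 1.7, 2.3, 4.0):
            lo = classify_heterozygous(het_trajectory(d), boundary_um=2.0)
            hi = classify_heterozygous(het_trajectory(d), boundary_um=3.0)
            if lo.category == SPLIT_PROXIMAL:
                assert hi.category == SPLIT_PROXIMAL
            if hi.category == SPLIT_DISTAL:
                assert lo.category == SPLIT_DISTAL

    def test_deterministic_repeat_calls(self):
        traj = het_trajectory(1.2)
        calls = {classify_heterozygous(traj).category for _ in range(5)}
        assert calls == {SPLIT_PROXIMAL}

    def test_confusion_diagonal_on_planted_population(self):
        params = synth.SimParams(seed=11, n_cells=150, p_split=0.5)
        _, trajectories, truth = synth.make_population(params, render_images=False)
        correct = total = 0
        for traj, cell in zip(trajectories, truth.cells):
            call = classify_heterozygous(traj)
            total += 1
            correct += call.category == cell.category
        assert correct / total >= 0.95


class TestClassifyHomozygous:
    def _hom(self, category):
        trajs, truths = synth.make_homozygous_trajectories(
            30, probs=(1.0, 0.0, 0.0) if category == SEGREGATING
            else (0.0, 1.0, 0.0) if category == CO_SEGREGATING
            else (0.0, 0.0, 1.0),
            seed=2,
        )
        return trajs, truths

    @pytest.mark.parametrize("category", [SEGREGATING, CO_SEGREGATING, FAILING])
    def test_planted_categories_recovered(self, category):
        trajs, truths = self._hom(category)
        assert all(t == category for t in truths)
        assert all(classify_homozygous(t).category == category for t in trajs)

    def test_nearest_pole_heuristic(self):
        trajs, _ = synth.make_homozygous_trajectories(5, probs=(1.0, 0.0, 0.0), seed=4)
        traj = trajs[0]
        onset = anaphase_onset(traj)
        pole_a = np.array([traj.foci[onset + 1][0].y_um, traj.foci[onset + 1][0].x_um])
        pole_b = np.array([traj.foci[onset + 1][1].y_um, traj.foci[onset + 1][1].x_um])
        for frame in traj.foci:
            for focus in frame:
                focus.pole = None  # wipe simulator labels
            assign_poles(frame, pole_a, pole_b, capture_radius_um=0.5)
        assert classify_homozygous(traj).category == SEGREGATING


class TestScorePresence:
    def _traj(self, intensities, onset=1):
        n_frames = len(intensities)
        frames = [[(1.0, 1.0)] for _ in range(n_frames)]
        inten = [[intensities[f]] for f in range(n_frames)]
        marker = [f >= onset for f in range(n_frames)]
        return simple_trajectory(frames, marker, intensities=inten)

    def test_all_background_never_present(self):
        traj = self._traj([100.0] * 20)
        tc = score_presence(traj, onset=1, background=100.0)
        assert not any(tc.present)

    def test_window_is_four_hours(self):
        traj = self._traj([500.0] * 20)
        tc = score_presence(traj, onset=1, background=100.0)
        assert tc.frames == list(range(2, 18))  # 16 frames at 15 min = 4 h
        assert not tc.truncated

    def test_planted_disappearance_pattern_recovered(self):
        vals = [500.0] * 20
        for f in range(5, 9):
            vals[f] = 100.0  # disappears, then reappears
        traj = self._traj(vals)
        tc = score_presence(traj, onset=1, background=100.0)
        expected = [vals[f] > 200.0 for f in tc.frames]
        assert tc.present == expected

    def test_presence_factor_monotone_to_all_false(self):
        traj = self._traj([500.0] * 20)
        tc = score_presence(traj, onset=1, background=100.0, presence_factor=1e12)
        assert not any(tc.present)

    def test_truncation_flagged(self):
        traj = self._traj([500.0] * 10)
        tc = score_presence(traj, onset=1, background=100.0)
        assert tc.truncated


class TestIntensity:
    def test_background_value_normalizes_to_one(self):
        assert normalize_intensity([2.0], [2.0, 2.0])[0] == 1.0

    def test_hand_arithmetic(self):
        assert normalize_intensity([5.0], [1.0, 3.0])[0] == pytest.approx(2.5)

    def test_bad_background_rejected(self):
        with pytest.raises(ValueError):
            normalize_intensity([1.0], [])
        with pytest.raises(ValueError):
            normalize_intensity([1.0], [0.0, 0.0])

    def test_normalized_proportional_to_planted_amplitude(self):
        amps = [200.0, 400.0, 800.0]
        values = normalize_intensity(amps, [100.0] * 50)
        ratios = np.asarray(values) / np.asarray(amps)
        assert np.allclose(ratios, ratios[0], rtol=1e-12)

    def test_anaphase_window_constant_secondary_is_one(self):
        frames = [[(1.0, 1.0)]] * 6
        sec = [[100.0]] * 6
        inten = [[500.0]] * 6
        traj = simple_trajectory(frames, [f >= 1 for f in range(6)],
                                 intensities=inten, secondary=sec)
        value, flag = anaphase_intensity_window(traj, onset=1, background_cells=[100.0] * 50)
        assert value == pytest.approx(1.0) and not flag

    def test_anaphase_window_planted_threefold(self):
        params = synth.SimParams(seed=9, n_cells=10, secondary_amplitude=300.0,
                                 background_level=100.0)
        _, trajectories, truth = synth.make_population(params, render_images=False)
        backgrounds = [params.background_level] * 50
        for traj, cell in zip(trajectories, truth.cells):
            value, _ = anaphase_intensity_window(traj, cell.onset_frame, backgrounds)
            assert value == pytest.approx(3.0, rel=1e-9)

    def test_anaphase_window_no_foci_flagged(self):
        frames = [[(1.0, 1.0)], [], [], []]
        traj = simple_trajectory(frames, [True] * 4)
        value, flag = anaphase_intensity_window(traj, onset=0, background_cells=[1.0])
        assert value is None and flag


class TestPopulationSummary:
    def test_single_replicate_fraction_null_sem(self):
        df = population_summary([[CO_SEGREGATED] * 3 + [SPLIT_DISTAL]])
        row = df[df["category"] == SPLIT_DISTAL].iloc[0]
        assert row["mean"] == pytest.approx(0.25)
        assert row["sem"] is None

    def test_identical_replicates_zero_sem(self):
        rep = [CO_SEGREGATED, SPLIT_DISTAL]
        df = population_summary([rep, rep, rep])
        assert all(df["sem"] == 0.0)

    def test_hand_sem(self):
        reps = [
            [SPLIT_DISTAL] * 2 + [CO_SEGREGATED] * 8,
            [SPLIT_DISTAL] * 3 + [CO_SEGREGATED] * 7,
            [SPLIT_DISTAL] * 4 + [CO_SEGREGATED] * 6,
        ]
        df = population_summary(reps)
        row = df[df["category"] == SPLIT_DISTAL].iloc[0]
        assert row["mean"] == pytest.approx(0.3)
        assert row["sem"] == pytest.approx(0.1 / np.sqrt(3))

    def test_empty_replicate_rejected(self):
        with pytest.raises(ValueError):
            population_summary([[CO_SEGREGATED], []])


class TestLinking:
    def test_two_focus_tracks_stay_ordered(self):
        from meioquant.classify import Focus

        frames = [
            [Focus(1.0, 1.0, 10.0), Focus(1.0, 3.0, 9.0)],
            [Focus(1.0, 3.1, 9.5), Focus(1.0, 1.1, 10.5)],
        ]
        linked = link_foci(frames)
        assert linked[1][0].x_um == pytest.approx(1.1)
        assert linked[1][1].x_um == pytest.approx(3.1)
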