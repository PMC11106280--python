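"""RDM constructors, subsetting, alignment, containers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

import trajrsa as T
from trajrsa import io as tio
from trajrsa.rdm import block_pairs, vectorize_series
from trajrsa.trajectories import MeanTrajectorySet

from conftest import make_trial


def naive_movement_rdms(means):
    """Brute-force double loop used as the oracle."""
    S, Tn = means.mean_x.shape
    out = np.zeros((Tn, S, S))
    for t in range(Tn):
        for i in range(S):
            for j in range(S):
                out[t, i, j] = 0.0 if i == j else abs(
                    means.mean_x[i, t] - means.mean_x[j, t]
                )
    return out


class TestMovementRDMs:
    def test_hand_example(self):
        means = MeanTrajectorySet(
            labels=["A", "B", "C"],
            time_grid=np.array([1.0]),
            mean_x=np.array([[0.0], [3.0], [10.0]]),
            mean_y=np.zeros((3, 1)),
            n_contributing=np.ones((3, 1), dtype=int),
        )
        series = T.movement_rdm_series(means)
        np.testing.assert_array_equal(
            series.values[0], [[0, 3, 10], [3, 0, 7], [10, 7, 0]]
        )

    def test_identical_positions_give_zero_rdm(self):
        means = MeanTrajectorySet(
            labels=["A", "B", "C"],
            time_grid=np.array([1.0]),
            mean_x=np.full((3, 1), 7.0),
            mean_y=np.zeros((3, 1)),
            n_contributing=np.ones((3, 1), dtype=int),
        )
        assert np.all(T.movement_rdm_series(means).values == 0)

    def test_matches_double_loop_oracle_bitwise(self, mini_dataset):
        means = mini_dataset["means"]
        sub = MeanTrajectorySet(
            labels=means.labels,
            time_grid=means.time_grid[400:420],
            mean_x=means.mean_x[:, 400:420],
            mean_y=means.mean_y[:, 400:420],
            n_contributing=means.n_contributing[:, 400:420],
        )
        series = T.movement_rdm_series(sub)
        np.testing.assert_array_equal(series.values, naive_movement_rdms(sub))

    def test_translation_invariance(self, mini_dataset):
        means = mini_dataset["means"]
        shifted = MeanTrajectorySet(
            labels=means.labels,
            time_grid=means.time_grid,
            mean_x=means.mean_x + 123.0,
            mean_y=means.mean_y,
            n_contributing=means.n_contributing,
        )
        a = T.movement_rdm_series(means).values
        b = T.movement_rdm_series(shifted).values
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_too_few_stimuli(self):
        means = MeanTrajectorySet(
            labels=["A", "B"], time_grid=np.array([1.0]),
            mean_x=np.zeros((2, 1)), mean_y=np.zeros((2, 1)),
            n_contributing=np.ones((2, 1), dtype=int),
        )
        with pytest.raises(ValueError, match="at least 3"):
            T.movement_rdm_series(means)


class TestBinaryModels:
    @pytest.mark.parametrize(
        "cat_i,cat_j,task_val,look_val",
        [
            ("face", "lookalike", 1.0, 0.0),
            ("lookalike", "object", 0.0, 1.0),
            ("face", "object", 1.0, 1.0),
            ("face", "face", 0.0, 0.0),
            ("lookalike", "lookalike", 0.0, 0.0),
            ("object", "object", 0.0, 0.0),
        ],
    )
    def test_pair_assignments(self, mini_stimuli, cat_i, cat_j, task_val, look_val):
        task = T.binary_model_rdm(mini_stimuli, "task")
        look = T.binary_model_rdm(mini_stimuli, "lookalike")
        i = next(k for k, l in enumerate(task.labels)
                 if mini_stimuli.category_of(l) == cat_i)
        j = next(k for k, l in enumerate(task.labels)
                 if mini_stimuli.category_of(l) == cat_j and k != i)
        assert task.values[i, j] == task_val
        assert look.values[i, j] == look_val

    def test_binary_and_disagreement_structure(self, mini_stimuli):
        task = T.binary_model_rdm(mini_stimuli, "task")
        look = T.binary_model_rdm(mini_stimuli, "lookalike")
        assert set(np.unique(task.values)) <= {0.0, 1.0}
        assert set(np.unique(look.values)) <= {0.0, 1.0}
        disagree = task.values != look.values
        is_look = np.array(
            [mini_stimuli.category_of(l) == "lookalike" for l in task.labels]
        )
        involves_look = is_look[:, None] ^ is_look[None, :]
        np.testing.assert_array_equal(disagree, involves_look)

    def test_unknown_category_errors(self):
        bad = T.StimulusSet([T.Stimulus("a", "face"), T.Stimulus("b", "banana")])
        with pytest.raises(ValueError, match="unknown category"):
            T.binary_model_rdm(bad, "task")


class TestExecutionTimeRDM:
    def test_pairwise_absolute_differences(self):
        stimuli = T.StimulusSet(
            [T.Stimulus("object_000", "object"), T.Stimulus("object_001", "object"),
             T.Stimulus("object_002", "object")]
        )
        # box reached at 500 / 620 / 620 ms (t_max 800 not reached)
        trials = [
            make_trial([1, 500], [0, 1], stimulus="object_000"),
            make_trial([1, 620], [0, 1], index=1, stimulus="object_001"),
            make_trial([1, 620], [0, 1], index=2, stimulus="object_002"),
        ]
        rdm = T.execution_time_rdm(trials, stimuli)
        assert rdm.values[0, 1] == pytest.approx(120.0)
        assert rdm.values[1, 2] == pytest.approx(0.0)

    def test_deadline_trials_excluded_and_missing_image_errors(self):
        stimuli = T.StimulusSet(
            [T.Stimulus("object_000", "object"), T.Stimulus("object_001", "object"),
             T.Stimulus("object_002", "object")]
        )
        trials = [
            make_trial([1, 500], [0, 1], stimulus="object_000"),
            make_trial([1, 600], [0, 1], index=1, stimulus="object_001"),
            make_trial([1, 800], [0, 1], index=2, stimulus="object_002"),  # deadline
        ]
        with pytest.raises(ValueError, match="object_002"):
            T.execution_time_rdm(trials, stimuli)

    def test_matches_naive_oracle_on_generator(self, mini_dataset, mini_stimuli):
        trials = mini_dataset["kept"]
        rdm = T.execution_time_rdm(trials, mini_stimuli)
        # oracle: naive two-level mean then |difference| double loop
        labels = mini_stimuli.analysis_ids
        per = {}
        for tr in trials:
            if tr.stimulus_id in labels and tr.t[-1] < 800:
                per.setdefault(tr.participant_id, {}).setdefault(
                    tr.stimulus_id, []
                ).append(tr.t[-1])
        mean_t = {}
        for sid in labels:
            vals = [np.mean(v[sid]) for v in per.values() if sid in v]
            mean_t[sid] = np.mean(vals)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                assert rdm.values[i, j] == pytest.approx(
                    abs(mean_t[a] - mean_t[b]), abs=1e-12
                )


class TestPatternRDM:
    def test_identical_and_reversed_patterns(self):
        pats = np.array([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0],
                         [4.0, 3.0, 2.0, 1.0]])
        rdm = T.pattern_rdm(pats, ["a", "b", "c"])
        assert rdm.values[0, 1] == pytest.approx(0.0)
        assert rdm.values[0, 2] == pytest.approx(2.0)

    def test_against_independent_rank_correlation_oracle(self):
        rng = np.random.default_rng(42)
        pats = rng.normal(size=(6, 10))
        rdm = T.pattern_rdm(pats, [f"s{i}" for i in range(6)])
        for i in range(6):
            for j in range(i + 1, 6):
                rho = spearmanr(pats[i], pats[j]).statistic
                assert rdm.values[i, j] == pytest.approx(1 - rho, abs=1e-12)

    def test_constant_pattern_errors(self):
        pats = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="constant"):
            T.pattern_rdm(pats, ["a", "b"])


class TestSubsetting:
    def test_block_sizes(self):
        cfg = T.SimulationConfig.face_study(n_participants_traj=4)
        stim = T.make_stimuli(cfg)
        rdm = T.binary_model_rdm(stim, "task")
        assert len(T.subset_block(rdm, stim, "lookalike", "object")) == 32 * 32
        cfg9 = T.SimulationConfig.animal_study(n_participants_traj=4)
        stim9 = T.make_stimuli(cfg9)
        rdm9 = T.binary_model_rdm(stim9, "task")
        assert len(T.subset_block(rdm9, stim9, "lookalike", "animal")) == 81
        assert len(T.subset_block(rdm9, stim9, "animal", "animal")) == 36

    def test_cross_block_collects_all_cells(self, mini_stimuli):
        rdm = T.binary_model_rdm(mini_stimuli, "task")
        vec = T.subset_block(rdm, mini_stimuli, "face", "object")
        assert np.all(vec.entries == 1.0)  # all between-group under task model
        cats = [mini_stimuli.category_of(rdm.labels[i]) for i in vec.pairs[:, 0]]
        assert set(cats) == {"face"}

    def test_empty_category_errors(self, mini_stimuli):
        rdm = T.binary_model_rdm(mini_stimuli, "task")
        with pytest.raises(ValueError, match="empty"):
            block_pairs(rdm.labels, [], ["object_000"])


class TestAlignSeries:
    def _series(self, times):
        vals = np.zeros((len(times), 3, 3))
        for k in range(len(times)):
            vals[k, 0, 1] = vals[k, 1, 0] = float(k)
        return T.RDMSeries(["a", "b", "c"], np.asarray(times, float), vals)

    def test_nearest_assignment(self):
        s = self._series([0, 5, 10])
        out = T.align_series(s, np.array([7.0]))
        assert out.values[0, 0, 1] == 1.0  # t=7 -> source t=5

    def test_identity_on_same_grid(self):
        s = self._series([0, 5, 10])
        out = T.align_series(s, s.times)
        np.testing.assert_array_equal(out.values, s.values)

    def test_roundtrip_upsample_then_subsample(self):
        s = self._series(np.arange(0, 51, 5))
        fine = T.align_series(s, np.arange(0.0, 51.0))
        back = fine.subsample(s.times)
        np.testing.assert_array_equal(back.values, s.values)

    def test_outside_span_errors(self):
        with pytest.raises(ValueError, match="span"):
            T.align_series(self._series([0, 5, 10]), np.array([11.0]))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_constructed_rdms_are_symmetric_nonnegative_zero_diagonal(seed):
    rng = np.random.default_rng(seed)
    pats = rng.normal(size=(5, 8))
    rdm = T.pattern_rdm(pats, [f"s{i}" for i in range(5)])
    assert np.allclose(rdm.values, rdm.values.T)
    assert np.all(np.diag(rdm.values) == 0)
    assert np.all(rdm.values >= 0)


def test_rdm_validation_rejects_bad_matrices():
    with pytest.raises(ValueError, match="symmetric"):
        T.RDM(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError, match="diagonal"):
        T.RDM(["a", "b"], np.array([[1.0, 2.0], [2.0, 0.0]]))
    with pytest.raises(ValueError, match="non-negative"):
        T.RDM(["a", "b"], np.array([[0.0, -1.0], [-1.0, 0.0]]))


def test_h5_roundtrip(tmp_path, mini_dataset):
    mov = mini_dataset["mov"].subsample(np.arange(100.0, 201.0, 50.0))
    p = tmp_path / "mov.h5"
    tio.save_rdm_series(p, mov)
    back = tio.load_rdm_series(p)
    assert back.labels == mov.labels
    np.testing.assert_array_equal(back.times, mov.times)
    np.testing.assert_array_equal(back.values, mov.values)


def test_vectorize_series_upper_triangle(mini_dataset):
    mov = mini_dataset["mov"]
    V = vectorize_series(mov)
    n = len(mov.labels)
    assert V.shape == (len(mov), n * (n - 1) // 2)
    iu, ju = np.triu_indices(n, k=1)
    np.testing.assert_array_equal(V[500], mov.values[500][iu, ju])
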