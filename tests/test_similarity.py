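"""Rank correlations of RDMs: plain, partial, timecourses, time-time maps,
embeddings."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata, spearmanr

import trajrsa as T
from trajrsa.similarity import rank_corr_map


# ---------------------------------------------------------------------------
# Independent oracles


def oracle_partial_by_regression(a, b, covs):
    """Rank everything, residualize a and b on covariates by least squares
    (with intercept), Pearson of the residuals."""
    ra, rb = rankdata(a), rankdata(b)
    D = np.column_stack([np.ones(a.size)] + [rankdata(c) for c in covs])
    beta_a, *_ = np.linalg.lstsq(D, ra, rcond=None)
    beta_b, *_ = np.linalg.lstsq(D, rb, rcond=None)
    ea, eb = ra - D @ beta_a, rb - D @ beta_b
    return np.corrcoef(ea, eb)[0, 1]


def oracle_partial_by_matrix_inversion(a, b, covs):
    """Partial correlation from the inverse of the full rank-correlation
    matrix."""
    X = np.vstack([a, b] + list(covs))
    R = np.corrcoef(rankdata(X, axis=1))
    P = np.linalg.inv(R)
    return -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])


def random_instance(rng, n=None, k=None):
    n = n if n is not None else int(rng.integers(12, 501))
    k = k if k is not None else int(rng.integers(0, 4))
    a = rng.normal(size=n)
    covs = [rng.normal(size=n) for _ in range(k)]
    b = 0.5 * a + sum(0.3 * c for c in covs) + rng.normal(size=n)
    return a, b, covs


class TestSpearman:
    def test_self_correlation_is_one(self):
        v = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        assert T.spearman_rdm(v, v) == pytest.approx(1.0)

    def test_monotone_invariance(self):
        rng = np.random.default_rng(1)
        a = np.abs(rng.normal(size=30))
        assert T.spearman_rdm(a, a**2) == pytest.approx(1.0)

    def test_against_scipy_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b = rng.normal(size=(2, 10))
            assert T.spearman_rdm(a, b) == pytest.approx(
                spearmanr(a, b).statistic, abs=1e-12
            )

    def test_constant_input_warns_and_returns_nan(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = T.spearman_rdm(np.ones(10), np.arange(10.0))
        assert np.isnan(out)

    def test_pairwise_complete_with_nans(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(2, 40))
        a[5:8] = np.nan
        ok = np.isfinite(a)
        assert T.spearman_rdm(a, b) == pytest.approx(
            spearmanr(a[ok], b[ok]).statistic, abs=1e-12
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetry_in_arguments(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 15))
        assert T.spearman_rdm(a, b) == pytest.approx(T.spearman_rdm(b, a), abs=1e-14)


class TestPartialSpearman:
    def test_empty_covariates_reduce_to_spearman(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(2, 25))
        assert T.partial_spearman(a, b, []) == pytest.approx(
            T.spearman_rdm(a, b), abs=1e-14
        )

    def test_against_both_oracles(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, covs = random_instance(rng, n=int(rng.integers(12, 80)))
            got = T.partial_spearman(a, b, covs)
            assert got == pytest.approx(oracle_partial_by_regression(a, b, covs), abs=1e-10)
            assert got == pytest.approx(
                oracle_partial_by_matrix_inversion(a, b, covs), abs=1e-10
            )

    def test_partialling_shared_covariate_removes_induced_correlation(self):
        rng = np.random.default_rng(6)
        z = rng.normal(size=400)
        a = z + 0.3 * rng.normal(size=400)
        b = z + 0.3 * rng.normal(size=400)
        raw = T.spearman_rdm(a, b)
        part = T.partial_spearman(a, b, [z])
        assert raw > 0.8
        assert abs(part) < 0.25

    def test_degenerate_covariate_raises(self):
        a = np.arange(20.0)
        b = np.arange(20.0)[::-1]
        with pytest.raises(ValueError, match="degenerate covariate"):
            T.partial_spearman(a, b, [a.copy()])

    def test_collinear_covariates_raise(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=(2, 30))
        z = rng.normal(size=30)
        with pytest.raises(ValueError, match="collinear"):
            T.partial_spearman(a, b, [z, 2 * z + 1])

    def test_too_few_pairs_raise(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="too few"):
            T.partial_spearman(rng.normal(size=3), rng.normal(size=3),
                               [rng.normal(size=3)])

    def test_independent_covariates_converge_to_plain_spearman(self):
        rng = np.random.default_rng(8)
        devs = []
        for n in (50, 200, 800):
            d = []
            for _ in range(20):
                a, b = rng.normal(size=(2, n))
                b = 0.4 * a + b
                z = [rng.normal(size=n), rng.normal(size=n)]
                d.append(abs(T.partial_spearman(a, b, z) - T.spearman_rdm(a, b)))
            devs.append(np.mean(d))
        assert devs[2] < devs[0]
        assert devs[2] < 0.02


class TestModelTimecourse:
    def test_series_equal_to_model_gives_rho_one(self, mini_stimuli):
        model = T.binary_model_rdm(mini_stimuli, "task")
        vals = np.repeat(model.values[None], 5, axis=0)
        series = T.RDMSeries(model.labels, np.arange(5.0), vals)
        tc = T.model_timecourse(series, model)
        np.testing.assert_allclose(tc.rho, 1.0)

    def test_noise_series_fluctuates_near_zero(self, mini_stimuli):
        model = T.binary_model_rdm(mini_stimuli, "task")
        series = T.noise_rdm_series(model.labels, np.arange(200.0), sd=0.3, seed=9)
        tc = T.model_timecourse(series, model)
        n_pairs = len(model.labels) * (len(model.labels) - 1) / 2
        assert np.mean(np.abs(tc.rho)) < 3 / np.sqrt(n_pairs)

    def test_lookalike_divergence_delay_recovered(self, mini_stimuli, mini_config):
        """The lookalike-model correlation of noise-free trajectories rises
        with the planted category onset and the task-model correlation
        completes only after the planted lookalike delay."""
        cfg = mini_config.replace(
            traj_noise_px=0.0, participant_offset_sd_px=0.0, error_rate=0.0,
            image_weight_traj_px=0.0, bias_px=0.0, lookalike_pull=0.6,
            onset_jitter_ms=(5.0, 6.0), arrival_mean_ms=2000.0, arrival_sd_ms=0.0,
        )
        df, _ = T.simulate_trajectories(mini_stimuli, cfg, seed=13)
        kept, _ = T.filter_trials(T.load_trials(df))
        means = T.average_trajectories(
            T.mirror_to_canonical(kept, mini_stimuli), mini_stimuli
        )
        mov = T.movement_rdm_series(means)
        task = T.model_timecourse(mov, T.binary_model_rdm(mini_stimuli, "task"))
        look = T.model_timecourse(mov, T.binary_model_rdm(mini_stimuli, "lookalike"))
        onset = cfg.tau_category_ms
        early = slice(int(onset) + 10, int(onset + cfg.lookalike_delay_ms) - 10)
        late = slice(700, 800)
        assert np.nanmean(look.rho[early]) > np.nanmean(task.rho[early])
        assert np.nanmean(task.rho[late]) > 0.8


class TestTimeTimeMap:
    def test_self_map_diagonal_is_one(self, mini_stimuli):
        series = T.noise_rdm_series(
            mini_stimuli.analysis_ids, np.arange(10.0), sd=0.3, seed=10
        )
        tmap = T.time_time_map(series, series)
        assert tmap.values.shape == (1, 10, 10)
        np.testing.assert_allclose(np.diagonal(tmap.values[0]), 1.0, atol=1e-12)

    def test_output_dims(self, mini_dataset, mini_neural):
        mov = mini_dataset["mov"].subsample(np.arange(50.0, 801.0, 50.0))
        neural, _ = mini_neural
        tmap = T.time_time_map(mov, neural[:3])
        assert tmap.values.shape == (3, len(neural[0].times), 16)

    def test_label_permutation_invariance(self, mini_dataset, mini_neural):
        mov = mini_dataset["mov"].subsample(np.arange(100.0, 801.0, 100.0))
        neural, _ = mini_neural
        rng = np.random.default_rng(11)
        perm = list(rng.permutation(mov.labels))
        a = T.time_time_map(mov, neural[0])
        b = T.time_time_map(mov.reindex(perm), neural[0].reindex(perm))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_task_covariate_removes_pure_task_structure(self, mini_stimuli):
        """Series that are exact scalar multiples of the task model carry no
        information beyond it: partialling the model leaves degenerate
        (missing) cells rather than spurious correlations."""
        task = T.binary_model_rdm(mini_stimuli, "task")
        times = np.arange(5.0)
        vals = np.stack([(0.5 + 0.1 * k) * task.values for k in range(5)])
        mov = T.RDMSeries(task.labels, times, vals, "movement")
        neural = T.RDMSeries(task.labels, times, vals * 2.0, "neural")
        tmap = T.time_time_map(mov, neural, covariates=[task])
        assert np.all(np.isnan(tmap.values))

    def test_region_block_restriction(self, mini_dataset, mini_neural, mini_stimuli):
        mov = mini_dataset["mov"].subsample(np.arange(100.0, 801.0, 100.0))
        neural, _ = mini_neural
        tmap = T.time_time_map(
            mov, neural[0], region=("lookalike", "object"), stimuli=mini_stimuli
        )
        assert tmap.region == "lookalikexobject"
        assert tmap.values.shape[1:] == (len(neural[0].times), 8)


class TestPlantedLagRecovery:
    def test_cluster_sits_above_diagonal_at_planted_lag(self, mini_config):
        cfg = mini_config.replace(n_per_category=6, lag_ms=250.0)
        stim = T.make_stimuli(cfg)
        df, _ = T.simulate_trajectories(stim, cfg, seed=2)
        kept, _ = T.filter_trials(T.load_trials(df))
        kept, _ = T.filter_participants(kept)
        means = T.average_trajectories(T.mirror_to_canonical(kept, stim), stim)
        mov = T.movement_rdm_series(means).subsample(np.arange(10.0, 801.0, 10.0))
        neural, _ = T.simulate_neural_rdms(stim, cfg, seed=2)
        task = T.binary_model_rdm(stim, "task")
        tmap = T.time_time_map(mov, neural, covariates=[task])
        res = T.cluster_permutation_test(tmap.values, n_perm=500, seed=3)
        assert res.n_significant >= 1
        gm = tmap.group_mean()
        offsets = []
        for r in np.flatnonzero(res.sig_mask.any(axis=1)):
            row = np.where(res.sig_mask[r], gm[r], -np.inf)
            offsets.append(tmap.movement_times[int(np.argmax(row))] - tmap.neural_times[r])
        assert abs(np.median(offsets) - cfg.lag_ms) <= 20.0


class TestMDS:
    def test_two_points_embed_at_their_dissimilarity(self):
        rdm = T.RDM(["a", "b"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        coords = T.mds_embedding(rdm, dims=1)
        assert abs(coords[0, 0] - coords[1, 0]) == pytest.approx(3.0, abs=1e-8)

    def test_all_zero_rdm_gives_coincident_points(self):
        rdm = T.RDM(["a", "b", "c"], np.zeros((3, 3)))
        coords = T.mds_embedding(rdm)
        np.testing.assert_array_equal(coords, 0.0)

    def test_planar_configuration_recovered(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(8, 2))
        D = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        rdm = T.RDM([f"s{i}" for i in range(8)], D)
        coords = T.mds_embedding(rdm, dims=2, seed=0)
        D2 = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
        np.testing.assert_allclose(D2, D, atol=1e-6)

    def test_windowed_series_embedding(self, mini_dataset):
        mov = mini_dataset["mov"]
        coords = T.mds_embedding(mov, dims=2, window_ms=50.0, center_ms=600.0, seed=0)
        assert coords.shape == (len(mov.labels), 2)


def test_rank_corr_map_handles_mask_groups():
    """Rows with different missingness patterns are ranked within their own
    pairwise-complete subsets."""
    rng = np.random.default_rng(13)
    A = rng.normal(size=(3, 30))
    A[1, :10] = np.nan
    B = rng.normal(size=(2, 30))
    out = rank_corr_map(A, B, min_pairs=3)
    ok = np.isfinite(A[1])
    expected = spearmanr(A[1][ok], B[0][ok]).statistic
    assert out[1, 0] == pytest.approx(expected, abs=1e-12)
    assert out[0, 1] == pytest.approx(spearmanr(A[0], B[1]).statistic, abs=1e-12)
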