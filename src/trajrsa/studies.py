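"""Packaged study designs: planted-truth recovery and calibration runs.

Each function simulates a complete synthetic study under frozen conditions,
runs the corresponding stage of the pipeline, and reports the quantities a
recovery or calibration check needs.  The analysis drivers, the test suite
and the acceptance script all call these; nothing here reads anything from
outside the package.
"""

from __future__ import annotations

import warnings

import numpy as np

from .commonality import commonality_map
from .inference import cluster_permutation_test
from .rdm import binary_model_rdm, movement_rdm_series
from .similarity import model_timecourse, time_time_map
from .synthetic import (
    SimulationConfig,
    make_stimuli,
    noise_rdm_series,
    simulate_neural_rdms,
    simulate_roi_rdms,
    simulate_trajectories,
)
from .trajectories import (
    average_trajectories,
    filter_participants,
    filter_trials,
    load_trials,
    mirror_to_canonical,
)

__all__ = [
    "preprocess_simulated",
    "fwer_null_study",
    "lag_recovery_study",
    "model_dominance_study",
    "commonality_recovery_study",
    "covariate_removal_study",
]


def _child_seed(seed: int, k: int) -> int:
    """Deterministic child seed below 2**31."""
    return int(np.random.SeedSequence([int(seed), k]).generate_state(1)[0] % (2**31))


def preprocess_simulated(config: SimulationConfig, seed: int):
    """Simulate raw cursor logs and run the full preprocessing chain;
    returns (stimuli, group means, retained trials, ground truth)."""
    stimuli = make_stimuli(config)
    df, truth = simulate_trajectories(stimuli, config, seed)
    trials = load_trials(df)
    kept, _ = filter_trials(trials)
    kept, _ = filter_participants(kept)
    means = average_trajectories(mirror_to_canonical(kept, stimuli), stimuli)
    return stimuli, means, kept, truth


def movement_series(config: SimulationConfig, seed: int, step_ms: float = 10.0):
    stimuli, means, kept, truth = preprocess_simulated(config, seed)
    mov = movement_rdm_series(means)
    mov = mov.subsample(np.arange(step_ms, config.move_tmax_ms + 1e-9, step_ms))
    return stimuli, mov, kept, truth


# ---------------------------------------------------------------------------
# Family-wise error calibration


def fwer_null_study(
    n_datasets: int = 200,
    n_participants: int = 20,
    n_perm: int = 1000,
    n_neural_times: int = 60,
    n_movement_times: int = 80,
    n_stimuli: int = 12,
    noise_sd: float = 0.2,
    alpha_cluster: float = 0.05,
    alpha_fwe: float = 0.05,
    seed: int = 0,
) -> dict:
    """Empirical family-wise type-I error of the cluster-based sign-
    permutation test on time-time correlation maps.

    Every dataset is pure noise: the group movement RDM series and each
    participant's neural RDM series share nothing, so any significant
    cluster is a false positive.  Reports the fraction of datasets with at
    least one significant cluster at the nominal thresholds.
    """
    labels = [f"s{i:03d}" for i in range(n_stimuli)]
    t_neural = np.arange(n_neural_times, dtype=float) * 5.0
    t_move = np.arange(1, n_movement_times + 1, dtype=float) * 10.0
    hits = 0
    for d in range(n_datasets):
        ds = _child_seed(seed, d + 1)
        mov = noise_rdm_series(labels, t_move, sd=noise_sd, seed=ds, stream=1,
                               source="mov")
        neural = [
            noise_rdm_series(labels, t_neural, sd=noise_sd, seed=ds, stream=100 + p,
                             source=f"p{p}")
            for p in range(n_participants)
        ]
        tmap = time_time_map(mov, neural)
        res = cluster_permutation_test(
            tmap.values,
            alpha_cluster=alpha_cluster,
            alpha_fwe=alpha_fwe,
            n_perm=n_perm,
            tail="positive",
            seed=_child_seed(ds, 7),
        )
        hits += res.n_significant > 0
    return {
        "fwer": hits / n_datasets,
        "n_datasets": n_datasets,
        "n_hits": hits,
        "nominal_alpha": alpha_fwe,
    }


# ---------------------------------------------------------------------------
# Lag recovery


def lag_recovery_study(
    seed: int = 0,
    lag_ms: float = 250.0,
    n_perm: int = 1000,
    config: SimulationConfig | None = None,
) -> dict:
    """Recover a planted neural-to-movement lag from the time-time map.

    The movement expression of the shared image component lags its neural
    expression by ``lag_ms``; after partialling the task model, the
    significant cluster should sit above the diagonal and the per-row
    argmax offset should estimate the lag.
    """
    # drift-dominant image component: the time-varying part of the shared
    # geometry is what localizes each movement time to one neural time, so
    # the per-row peak traces the planted lag rather than a static plateau
    cfg = config or SimulationConfig.miniature(
        n_per_category=6,
        lag_ms=lag_ms,
        image_static_frac=0.2,
        neural_lookalike_weight=0.0,
    )
    stimuli, mov, kept, truth = movement_series(cfg, seed)
    neural, _ = simulate_neural_rdms(stimuli, cfg, seed)
    task = binary_model_rdm(stimuli, "task")
    tmap = time_time_map(mov, neural, covariates=[task])
    res = cluster_permutation_test(
        tmap.values, n_perm=n_perm, tail="positive", seed=_child_seed(seed, 3)
    )
    gm = tmap.group_mean()
    offsets, above = [], []
    for r in np.flatnonzero(res.sig_mask.any(axis=1)):
        row = np.where(res.sig_mask[r], gm[r], -np.inf)
        c = int(np.argmax(row))
        offsets.append(tmap.movement_times[c] - tmap.neural_times[r])
    for cl in res.clusters:
        if cl.significant:
            above.extend(
                tmap.movement_times[cl.cells[:, 1]] - tmap.neural_times[cl.cells[:, 0]]
            )
    return {
        "planted_lag_ms": truth.lag_ms,
        "estimated_lag_ms": float(np.median(offsets)) if offsets else float("nan"),
        "n_significant_clusters": res.n_significant,
        "fraction_cells_above_diagonal": float(np.mean(np.asarray(above) > 0))
        if above
        else float("nan"),
        "n_sig_rows": len(offsets),
    }


# ---------------------------------------------------------------------------
# Model dominance


def model_dominance_study(seed: int = 0) -> dict:
    """Early-window dominance of the lookalike vs. task model in movement
    RDM timecourses, under the two study presets.

    An animal-study-like configuration (strong confusable pull, long extra
    delay) should show the lookalike model leading over the window between
    the category onset and the lookalike divergence; a face-study-like
    configuration the reverse.
    """
    out = {}
    presets = {
        "face_like": SimulationConfig.miniature(
            study="face", lookalike_pull=0.12, lookalike_delay_ms=75.0
        ),
        "animal_like": SimulationConfig.miniature(
            study="animal", lookalike_pull=0.45, lookalike_delay_ms=110.0
        ),
    }
    for name, cfg in presets.items():
        stimuli, means, kept, _ = preprocess_simulated(cfg, seed)
        mov = movement_rdm_series(means)
        task_tc = model_timecourse(mov, binary_model_rdm(stimuli, "task"))
        look_tc = model_timecourse(mov, binary_model_rdm(stimuli, "lookalike"))
        lo = int(cfg.tau_category_ms) + 10
        hi = int(cfg.tau_category_ms + cfg.lookalike_delay_ms) - 10
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[name] = {
                "early_window_ms": [lo, hi],
                "rho_task_early": float(np.nanmean(task_tc.rho[lo:hi])),
                "rho_lookalike_early": float(np.nanmean(look_tc.rho[lo:hi])),
                "rho_task_late": float(np.nanmean(task_tc.rho[700:800])),
            }
    return out


# ---------------------------------------------------------------------------
# Commonality recovery


def commonality_recovery_study(
    seed: int = 0,
    n_repeats: int = 10,
    n_perm: int = 1000,
    step_ms: float = 20.0,
) -> dict:
    """Recover the planted ROI shared-weight ordering (0.8 > 0.4 > 0.1) and
    check that a weight-0 ROI yields no significant commonality cluster.

    Each repeat re-simulates a full study under
    :meth:`SimulationConfig.commonality_study` conditions; mean commonality
    is pooled over repeats in an active region where the shared image
    component is expressed in both series.
    """
    cfg = SimulationConfig.commonality_study()
    weights = cfg.roi_weights
    sig_counts = np.zeros(len(weights), dtype=int)
    active_means = []
    sig_means = [[] for _ in weights]
    for rep in range(n_repeats):
        rs = _child_seed(seed, 1000 + rep)
        stimuli, mov, kept, _ = movement_series(cfg, rs, step_ms=step_ms)
        neural, _ = simulate_neural_rdms(stimuli, cfg, rs)
        rois, truth = simulate_roi_rdms(stimuli, cfg, rs)
        task = binary_model_rdm(stimuli, "task")
        cmap = commonality_map(mov, neural, rois, extra_covariates=[task])
        active = np.ix_(
            range(cfg.n_participants_neural),
            cmap.neural_times >= 200,
            cmap.movement_times >= 450,
        )
        rep_means = []
        for r in range(len(weights)):
            res = cluster_permutation_test(
                cmap.values[r], n_perm=n_perm, tail="positive",
                seed=_child_seed(rs, 17),
            )
            sig_counts[r] += res.n_significant > 0
            if res.sig_mask.any():
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    gm = np.nanmean(cmap.values[r], axis=0)
                sig_means[r].append(float(np.nanmean(gm[res.sig_mask])))
            rep_means.append(float(np.nanmean(cmap.values[r][active])))
        active_means.append(rep_means)
    pooled = np.mean(active_means, axis=0)
    return {
        "weights": list(weights),
        "n_repeats": n_repeats,
        "sig_fraction": (sig_counts / n_repeats).tolist(),
        "pooled_mean_C": pooled.tolist(),
        "mean_C_in_sig_clusters": [
            float(np.mean(v)) if v else float("nan") for v in sig_means
        ],
        "weight0_sig_fraction": float(sig_counts[-1] / n_repeats)
        if weights[-1] == 0.0
        else None,
    }


# ---------------------------------------------------------------------------
# Covariate removal


def covariate_removal_study(seed: int = 0, n_perm: int = 1000) -> dict:
    """Partialling the task model removes time-time clusters when the task
    model is the only shared structure, but not when an image-level
    component is also planted."""
    out = {}
    shared_task_only = SimulationConfig.miniature(
        n_per_category=6,
        image_weight_traj_px=0.0,
        image_weight_neural=0.0,
        neural_lookalike_weight=0.0,
        lookalike_pull=0.0,
    )
    with_image = SimulationConfig.miniature(n_per_category=6)
    for name, cfg in (("task_only", shared_task_only), ("with_image", with_image)):
        stimuli, mov, kept, _ = movement_series(cfg, seed)
        neural, _ = simulate_neural_rdms(stimuli, cfg, seed)
        task = binary_model_rdm(stimuli, "task")
        res_raw = cluster_permutation_test(
            time_time_map(mov, neural).values,
            n_perm=n_perm, seed=_child_seed(seed, 5),
        )
        res_part = cluster_permutation_test(
            time_time_map(mov, neural, covariates=[task]).values,
            n_perm=n_perm, seed=_child_seed(seed, 6),
        )
        out[name] = {
            "n_sig_raw": res_raw.n_significant,
            "n_sig_partial_task": res_part.n_significant,
        }
    return out
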