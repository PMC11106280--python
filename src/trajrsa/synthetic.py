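"""Synthetic study generator with planted ground truth.

Every input the pipeline consumes can be generated here: raw cursor logs
(long-format trial tables), per-participant neural RDM series, and static
ROI RDMs — all with known, recoverable structure:

* cursor trajectories start at the bottom of the screen and diverge
  sigmoidally toward the correct response box from a category onset
  (~325 ms), with an early bias toward the face/animal side, a delayed and
  initially confusable course for lookalike stimuli, late movement onsets,
  early box-click terminations, and planted fractions of degenerate trials
  and low-accuracy participants;
* a per-image idiosyncratic component (a static part plus a slowly
  drifting part) is injected identically into the trajectories and into
  the neural RDM series, with the movement expression lagging the neural
  expression by a configurable lag — this is what makes image-wise
  time-time correlations non-trivially recoverable;
* neural RDM series mix binary category structure, lookalike structure and
  the image component with configurable onsets and weights, plus
  per-participant noise;
* ROI RDMs mix the static image component with independent structure at
  known weights.

All randomness flows from a single integer seed through fixed named
streams, so identical seed + config reproduce outputs bit for bit, and the
latent image component is shared across the trajectory / neural / ROI
generators called with the same seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .rdm import RDM, RDMSeries, binary_model_rdm
from .trajectories import LEFT, RIGHT, Stimulus, StimulusSet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_stimuli",
    "simulate_trajectories",
    "simulate_neural_rdms",
    "simulate_roi_rdms",
    "noise_rdm_series",
]

# named substreams of the root seed
_STREAM_LATENT = 0
_STREAM_TRAJ = 1
_STREAM_NEURAL = 2
_STREAM_ROI = 3
_STREAM_NULL = 4


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults describe a desk-scale study (a handful of stimuli per
    category, a few dozen online participants); :meth:`face_study` and
    :meth:`animal_study` return full-study-scale presets.  Times are ms,
    positions px.
    """

    study: str = "face"  # face | animal (unambiguous category label)
    n_per_category: int = 4
    n_filler: int = 2
    n_participants_traj: int = 24
    n_trials_per_image: int = 4  # one per block; 4 blocks, boxes swap after 2
    n_participants_neural: int = 20
    neural_step_ms: float = 5.0
    neural_tmax_ms: float = 500.0
    move_tmax_ms: int = 800

    # screen geometry
    screen_width_px: float = 1920.0
    start_y_px: float = 1000.0
    box_y_px: float = 100.0

    # trajectory dynamics
    divergence_px: float = 600.0
    tau_category_ms: float = 325.0
    lookalike_delay_ms: float = 75.0
    sigmoid_scale_ms: float = 35.0
    lookalike_pull: float = 0.12  # fraction of divergence toward the confusable side
    bias_px: float = 30.0
    bias_onset_ms: float = 150.0
    onset_jitter_ms: tuple = (30.0, 150.0)
    arrival_mean_ms: float = 660.0
    arrival_sd_ms: float = 70.0
    image_arrival_sd_ms: float = 15.0
    y_onset_ms: float = 350.0
    y_scale_ms: float = 60.0
    traj_noise_px: float = 25.0
    participant_offset_sd_px: float = 10.0
    error_rate: float = 0.16

    # shared image-level idiosyncratic component
    image_weight_traj_px: float = 60.0
    image_weight_neural: float = 0.3
    image_static_frac: float = 0.5
    image_drift_smooth_ms: float = 40.0
    image_onset_neural_ms: float = 80.0
    lag_ms: float = 250.0

    # neural mixture
    neural_task_weight: float = 0.35
    neural_task_onset_ms: float = 100.0
    neural_lookalike_weight: float = 0.10
    neural_lookalike_onset_ms: float = 90.0
    neural_onset_scale_ms: float = 30.0
    neural_noise_sd: float = 0.12
    neural_baseline: float = 1.0

    # static ROI RDMs
    roi_weights: tuple = (0.8, 0.4, 0.1)
    roi_labels: tuple | None = None
    roi_indep_weight: float = 1.0
    roi_noise_sd: float = 0.1

    # planted degenerates
    frac_short_trials: float = 0.0
    frac_low_movement_trials: float = 0.0
    frac_low_accuracy_participants: float = 0.0

    def __post_init__(self) -> None:
        if self.study not in ("face", "animal"):
            raise ValueError("study must be 'face' or 'animal'")
        if self.n_per_category < 3:
            raise ValueError("need at least 3 stimuli per category")
        if self.tau_category_ms + self.lookalike_delay_ms >= self.move_tmax_ms:
            raise ValueError("divergence onsets must lie within the movement window")
        for name in (
            "frac_short_trials",
            "frac_low_movement_trials",
            "frac_low_accuracy_participants",
            "error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if any(w < 0 for w in self.roi_weights):
            raise ValueError("ROI weights must be non-negative")

    @property
    def unambiguous_category(self) -> str:
        return self.study

    @property
    def midline_x(self) -> float:
        return self.screen_width_px / 2.0

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def face_study(cls, **kw) -> "SimulationConfig":
        """Full-scale Face Study: 32 faces / 32 lookalikes / 32 objects
        plus 32 filler faces; MEG grid at 5 ms; face model dominant."""
        base = dict(
            study="face",
            n_per_category=32,
            n_filler=32,
            n_participants_traj=268,
            n_participants_neural=22,
            neural_step_ms=5.0,
            lookalike_pull=0.12,
            lookalike_delay_ms=75.0,
            neural_task_weight=0.35,
            neural_lookalike_weight=0.10,
            roi_labels=("FFA", "OFA", "LO", "PPA"),
            roi_weights=(0.8, 0.6, 0.3, 0.15),
            frac_low_accuracy_participants=0.35,
        )
        base.update(kw)
        return cls(**base)

    @classmethod
    def animal_study(cls, **kw) -> "SimulationConfig":
        """Full-scale Animal Study: 9 animals / 9 lookalikes / 9 objects
        plus 9 filler animals; EEG grid at 4 ms; lookalike structure
        dominant early."""
        base = dict(
            study="animal",
            n_per_category=9,
            n_filler=9,
            n_participants_traj=253,
            n_participants_neural=30,
            neural_step_ms=4.0,
            lookalike_pull=0.45,
            lookalike_delay_ms=110.0,
            neural_task_weight=0.18,
            neural_lookalike_weight=0.35,
            roi_labels=("EVC", "postVTC", "antVTC"),
            roi_weights=(0.3, 0.5, 0.8),
            frac_low_accuracy_participants=0.27,
        )
        base.update(kw)
        return cls(**base)

    @classmethod
    def miniature(cls, **kw) -> "SimulationConfig":
        """Desk-scale default used by the test suite."""
        return cls(**kw)

    @classmethod
    def commonality_study(cls, **kw) -> "SimulationConfig":
        """Study conditions for ROI variance partitioning with planted
        shared weights.

        A face-study-sized stimulus set (96 images) keeps RDM-vector
        sampling noise well below the weakest ROI's shared-geometry
        correlation; the shared image component is almost entirely static
        (a slow measurement integrates it), single-participant neural noise
        is large relative to the common structure (as for single-subject
        M/EEG RDMs — and a requirement for the participant-level sign-flip
        null to be calibrated when the movement series and ROI RDMs are
        fixed), and ROI RDMs carry a moderate independent component.
        """
        base = dict(
            n_per_category=32,
            n_filler=2,
            n_participants_traj=12,
            n_participants_neural=20,
            neural_baseline=12.0,
            neural_noise_sd=2.6,
            neural_lookalike_weight=0.0,
            image_static_frac=0.95,
            neural_step_ms=10.0,
            image_weight_traj_px=150.0,
            image_weight_neural=0.45,
            roi_indep_weight=0.6,
            roi_weights=(0.8, 0.4, 0.1, 0.0),
        )
        base.update(kw)
        return cls(**base)


@dataclass
class GroundTruth:
    """Planted-truth sidecar; recovery tests read this, never re-derive
    truth from the generated outputs."""

    seed: int
    config: SimulationConfig
    labels: list[str] = field(default_factory=list)  # in-analysis stimuli
    latent_x: np.ndarray | None = None  # (stimulus, t) canonical noise-free x
    static_component: np.ndarray | None = None  # v_i, per analysis stimulus
    drift_component: np.ndarray | None = None  # u_i(t) on the 1 ms master grid
    image_component: np.ndarray | None = None  # c_i(t) = envelope * mix
    lag_ms: float | None = None
    image_arrival_offset_ms: np.ndarray | None = None
    short_trial_keys: list[tuple] = field(default_factory=list)
    low_movement_trial_keys: list[tuple] = field(default_factory=list)
    low_accuracy_participants: list[str] = field(default_factory=list)
    latent_neural: np.ndarray | None = None  # (t, n, n) noise-free series
    neural_times: np.ndarray | None = None
    roi_weights: tuple | None = None
    roi_labels: list[str] | None = None


# ---------------------------------------------------------------------------
# Stimuli


def make_stimuli(config: SimulationConfig) -> StimulusSet:
    """Labelled stimulus set: n face/animal + n lookalike + n object
    in-analysis images, plus filler face/animal images used only to equate
    response probabilities (``in_analysis=False``)."""
    cat = config.unambiguous_category
    stimuli: list[Stimulus] = []
    for i in range(config.n_per_category):
        stimuli.append(Stimulus(f"{cat}_{i:03d}", cat, f"pair{i:03d}", True))
    for i in range(config.n_per_category):
        stimuli.append(Stimulus(f"lookalike_{i:03d}", "lookalike", f"pair{i:03d}", True))
    for i in range(config.n_per_category):
        stimuli.append(Stimulus(f"object_{i:03d}", "object", f"pair{i:03d}", True))
    for i in range(config.n_filler):
        stimuli.append(Stimulus(f"filler_{cat}_{i:03d}", cat, None, False))
    return StimulusSet(stimuli)


# ---------------------------------------------------------------------------
# Shared latent image component


def _latent_image_process(stimuli: StimulusSet, config: SimulationConfig, seed: int):
    """Static + drifting per-image component on the 1 ms master grid,
    shared between the trajectory and neural generators (same seed =>
    identical component)."""
    rng = _rng(seed, _STREAM_LATENT)
    labels = stimuli.analysis_ids
    T = config.move_tmax_ms + 1  # master grid 0..move_tmax ms
    v = rng.standard_normal(len(labels))
    white = rng.standard_normal((len(labels), T))
    u = gaussian_filter1d(white, sigma=config.image_drift_smooth_ms, axis=1, mode="reflect")
    u /= np.maximum(u.std(axis=1, keepdims=True), 1e-12)
    s = np.arange(T, dtype=float)
    envelope = _sigmoid((s - config.image_onset_neural_ms) / 30.0)
    f = config.image_static_frac
    c = envelope[None, :] * (np.sqrt(f) * v[:, None] + np.sqrt(1.0 - f) * u)
    return labels, v, u, c


def _component_at(c: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Evaluate the master-grid component at arbitrary ms times (clipped)."""
    idx = np.clip(np.round(times).astype(int), 0, c.shape[1] - 1)
    return c[:, idx]


# ---------------------------------------------------------------------------
# Trajectories


def _trial_signal(category: str, t: np.ndarray, config: SimulationConfig, error: bool):
    """Canonical-frame horizontal signal (face/animal side positive)."""
    A = config.divergence_px
    k = config.sigmoid_scale_ms
    tau = config.tau_category_ms
    s_cat = _sigmoid((t - tau) / k)
    if category == "lookalike":
        P = config.lookalike_pull
        s_corr = _sigmoid((t - tau - config.lookalike_delay_ms) / k)
        if error:  # ends at the confusable (face/animal) box
            return A * (P * s_cat + (1.0 - P) * s_corr)
        return A * (P * s_cat - (1.0 + P) * s_corr)
    sign = 1.0 if category in ("face", "animal") else -1.0
    if error:
        sign = -sign
    return sign * A * s_cat


def simulate_trajectories(
    stimuli: StimulusSet, config: SimulationConfig, seed: int
) -> tuple[pd.DataFrame, GroundTruth]:
    """Raw cursor logs for every participant x image x block, with planted
    ground truth.

    Each trial: jittered movement onset, early face/animal-ward bias ramp,
    sigmoidal divergence toward the correct box (delayed and initially
    confusable for lookalikes), the lagged shared image component, smooth
    noise, and early termination on (jittered) box arrival.  Box sides swap
    after two of the four blocks and the initial arrangement alternates
    across participants.  Lapses send a trial to the wrong box at the
    configured error rate; planted fractions of degenerate trials and
    low-accuracy participants are recorded in the ground-truth sidecar.
    """
    rng = _rng(seed, _STREAM_TRAJ)
    labels, v, u, c = _latent_image_process(stimuli, config, seed)
    label_pos = {sid: i for i, sid in enumerate(labels)}
    all_ids = [s.stimulus_id for s in stimuli]
    tmax = config.move_tmax_ms
    mid = config.midline_x

    participants = [f"p{i:03d}" for i in range(config.n_participants_traj)]
    n_bad = int(round(config.frac_low_accuracy_participants * len(participants)))
    bad_participants = sorted(
        rng.choice(participants, size=n_bad, replace=False).tolist()
    )
    img_arrival = rng.normal(0.0, config.image_arrival_sd_ms, size=len(all_ids))

    # enumerate trials, then plant disjoint degenerate subsets
    trial_specs = [
        (pid, img_i, block)
        for pid in participants
        for block in range(4)
        for img_i in range(len(all_ids))
        if block < config.n_trials_per_image
    ]
    n_trials = len(trial_specs)
    n_short = int(round(config.frac_short_trials * n_trials))
    n_lowmove = int(round(config.frac_low_movement_trials * n_trials))
    degen = rng.choice(n_trials, size=n_short + n_lowmove, replace=False)
    short_set = set(degen[:n_short].tolist())
    lowmove_set = set(degen[n_short:].tolist())

    offsets = {
        pid: rng.normal(0.0, config.participant_offset_sd_px) for pid in participants
    }
    cols: dict[str, list] = {k: [] for k in (
        "participant_id", "trial_index", "stimulus_id", "block", "correct_side",
        "t_ms", "x_px", "y_px", "midline_x_px",
    )}
    short_keys, lowmove_keys = [], []
    y_drop = config.start_y_px - config.box_y_px

    for ti, (pid, img_i, block) in enumerate(trial_specs):
        sid = all_ids[img_i]
        category = stimuli.category_of(sid)
        p_index = int(pid[1:])
        # face/animal box on the right for even participants in blocks 0-1
        face_right = (p_index % 2 == 0) == (block < 2)
        frame = 1.0 if face_right else -1.0
        is_fa_target = category in ("face", "animal")
        correct_side = (
            (RIGHT if face_right else LEFT)
            if is_fa_target
            else (LEFT if face_right else RIGHT)
        )
        err_rate = 0.5 if pid in bad_participants else config.error_rate
        error = bool(rng.random() < err_rate)

        t_on = rng.uniform(*config.onset_jitter_ms)
        arrival = rng.normal(
            config.arrival_mean_ms + img_arrival[img_i], config.arrival_sd_ms
        )
        t_end = float(np.clip(arrival, t_on + 120.0, tmax))

        if ti in lowmove_set:
            t = np.arange(1, tmax + 1, dtype=float)
            x = np.full(t.size, mid + offsets[pid])
            y = np.full(t.size, config.start_y_px)
            lowmove_keys.append((pid, ti))
        else:
            if ti in short_set:
                t0, t1 = 360.0, 449.0
                short_keys.append((pid, ti))
            else:
                t0, t1 = t_on, t_end
            t = np.arange(np.ceil(t0), np.floor(t1) + 1, dtype=float)
            x_rel = (
                config.bias_px * _sigmoid((t - config.bias_onset_ms) / 40.0)
                + _trial_signal(category, t, config, error)
            )
            if sid in label_pos:
                x_rel = x_rel + config.image_weight_traj_px * _component_at(
                    c[[label_pos[sid]]], t - config.lag_ms
                )[0]
            noise = rng.standard_normal(t.size)
            if t.size > 3:
                noise = gaussian_filter1d(noise, sigma=15.0, mode="reflect")
                noise *= config.traj_noise_px / max(noise.std(), 1e-9)
            else:
                noise *= config.traj_noise_px
            x = mid + frame * x_rel + offsets[pid] + noise
            y = (
                config.start_y_px
                - y_drop * _sigmoid((t - config.y_onset_ms) / config.y_scale_ms)
                + rng.standard_normal(t.size) * 2.0
            )
        n = t.size
        cols["participant_id"].append(np.repeat(pid, n))
        cols["trial_index"].append(np.repeat(ti, n))
        cols["stimulus_id"].append(np.repeat(sid, n))
        cols["block"].append(np.repeat(block, n))
        cols["correct_side"].append(np.repeat(correct_side, n))
        cols["t_ms"].append(t)
        cols["x_px"].append(x)
        cols["y_px"].append(y)
        cols["midline_x_px"].append(np.repeat(mid, n))

    df = pd.DataFrame({k: np.concatenate(vs) for k, vs in cols.items()})

    grid = np.arange(1, tmax + 1, dtype=float)
    latent = np.empty((len(labels), grid.size))
    for i, sid in enumerate(labels):
        latent[i] = (
            mid
            + config.bias_px * _sigmoid((grid - config.bias_onset_ms) / 40.0)
            + _trial_signal(stimuli.category_of(sid), grid, config, error=False)
            + config.image_weight_traj_px
            * _component_at(c[[i]], grid - config.lag_ms)[0]
        )
    truth = GroundTruth(
        seed=seed,
        config=config,
        labels=labels,
        latent_x=latent,
        static_component=v,
        drift_component=u,
        image_component=c,
        lag_ms=config.lag_ms,
        image_arrival_offset_ms=img_arrival,
        short_trial_keys=short_keys,
        low_movement_trial_keys=lowmove_keys,
        low_accuracy_participants=bad_participants,
    )
    return df, truth


# ---------------------------------------------------------------------------
# Neural RDM series


def simulate_neural_rdms(
    stimuli: StimulusSet, config: SimulationConfig, seed: int
) -> tuple[list[RDMSeries], GroundTruth]:
    """Per-participant neural RDM series on the 0..500 ms grid.

    The latent series mixes the binary task model, the binary lookalike
    model and the pairwise distances of the shared image component (the
    same component the trajectory generator expresses ``lag_ms`` later),
    each with its own onset ramp; per-participant symmetric noise is added
    on top of a constant baseline and values are clipped non-negative.
    """
    rng = _rng(seed, _STREAM_NEURAL)
    labels, v, u, c = _latent_image_process(stimuli, config, seed)
    n = len(labels)
    times = np.arange(0.0, config.neural_tmax_ms + 1e-9, config.neural_step_ms)

    task = binary_model_rdm(stimuli, "task").values
    look = binary_model_rdm(stimuli, "lookalike").values
    ct = _component_at(c, times)  # (n, T)
    d_img = np.abs(ct[:, None, :] - ct[None, :, :])  # (n, n, T)
    d_img = np.moveaxis(d_img, -1, 0)

    ks = config.neural_onset_scale_ms
    g_task = _sigmoid((times - config.neural_task_onset_ms) / ks)
    g_look = _sigmoid((times - config.neural_lookalike_onset_ms) / ks)
    latent = (
        config.neural_baseline * (1.0 - np.eye(n))[None]
        + config.neural_task_weight * g_task[:, None, None] * task[None]
        + config.neural_lookalike_weight * g_look[:, None, None] * look[None]
        + config.image_weight_neural * d_img
    )
    latent[:, np.arange(n), np.arange(n)] = 0.0

    series = []
    iu, ju = np.triu_indices(n, k=1)
    for p in range(config.n_participants_neural):
        noise = np.zeros_like(latent)
        draws = rng.normal(0.0, config.neural_noise_sd, size=(len(times), iu.size))
        noise[:, iu, ju] = draws
        noise[:, ju, iu] = draws
        vals = np.clip(latent + noise, 0.0, None)
        vals[:, np.arange(n), np.arange(n)] = 0.0
        series.append(RDMSeries(labels, times, vals, source=f"neural_p{p:02d}"))
    truth = GroundTruth(
        seed=seed,
        config=config,
        labels=labels,
        static_component=v,
        drift_component=u,
        image_component=c,
        lag_ms=config.lag_ms,
        latent_neural=latent,
        neural_times=times,
    )
    return series, truth


# ---------------------------------------------------------------------------
# Static ROI RDMs


def simulate_roi_rdms(
    stimuli: StimulusSet, config: SimulationConfig, seed: int
) -> tuple[list[RDM], GroundTruth]:
    """Static ROI RDMs: each ROI mixes the time-integrated expressed image
    geometry (weight per ROI) with independent structure and noise.

    The shared component is the time-mean of the pairwise distances of the
    image component over the neural window — a static snapshot of the same
    representational geometry the time-resolved series express, the way a
    slow haemodynamic measurement integrates a fast response.
    """
    rng = _rng(seed, _STREAM_ROI)
    labels, v, u, c = _latent_image_process(stimuli, config, seed)
    n = len(labels)
    t_lo = int(config.image_onset_neural_ms)
    t_hi = int(config.neural_tmax_ms)
    d0 = np.abs(c[:, None, t_lo:t_hi] - c[None, :, t_lo:t_hi]).mean(axis=-1)
    iu, ju = np.triu_indices(n, k=1)
    d0 = (d0 - d0[iu, ju].mean() * (1.0 - np.eye(n))) / max(d0[iu, ju].std(), 1e-12)
    d0 = d0 - d0.min()  # keep the mixture non-negative before baseline
    np.fill_diagonal(d0, 0.0)

    roi_labels = list(
        config.roi_labels
        if config.roi_labels is not None
        else [f"ROI{i + 1}" for i in range(len(config.roi_weights))]
    )
    if len(roi_labels) != len(config.roi_weights):
        raise ValueError("roi_labels and roi_weights length mismatch")
    rois = []
    for name, w in zip(roi_labels, config.roi_weights):
        # independent structure: iid entry-wise, as for dissimilarities of
        # high-dimensional activation patterns (a low-dimensional distance
        # structure here would correlate spuriously with every other
        # distance RDM through shared stimulus indices)
        indep = np.zeros((n, n))
        g = np.abs(rng.standard_normal(iu.size))
        indep[iu, ju] = g
        indep[ju, iu] = g
        indep = indep / max(g.std(), 1e-12)
        noise = np.zeros((n, n))
        draws = rng.normal(0.0, config.roi_noise_sd, size=iu.size)
        noise[iu, ju] = draws
        noise[ju, iu] = draws
        vals = np.clip(
            config.neural_baseline * (1.0 - np.eye(n))
            + w * d0
            + config.roi_indep_weight * indep
            + noise,
            0.0,
            None,
        )
        np.fill_diagonal(vals, 0.0)
        rois.append(RDM(labels, vals, source=name))
    truth = GroundTruth(
        seed=seed,
        config=config,
        labels=labels,
        static_component=v,
        roi_weights=tuple(config.roi_weights),
        roi_labels=roi_labels,
    )
    return rois, truth


# ---------------------------------------------------------------------------
# Pure-noise series (null calibration)


def noise_rdm_series(
    labels: list[str],
    times: np.ndarray,
    sd: float = 0.2,
    seed: int = 0,
    baseline: float = 1.0,
    source: str = "noise",
    stream: int = _STREAM_NULL,
) -> RDMSeries:
    """An RDM series with independent symmetric noise at every timepoint —
    no structure shared with anything else."""
    rng = _rng(seed, stream)
    n = len(labels)
    times = np.asarray(times, dtype=float)
    iu, ju = np.triu_indices(n, k=1)
    vals = np.zeros((times.size, n, n))
    draws = rng.normal(0.0, sd, size=(times.size, iu.size))
    vals[:, iu, ju] = draws
    vals[:, ju, iu] = draws
    vals = np.clip(vals + baseline * (1.0 - np.eye(n))[None], 0.0, None)
    vals[:, np.arange(n), np.arange(n)] = 0.0
    return RDMSeries(list(labels), times, vals, source=source)
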