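"""Mouse-tracking trajectory ingestion and preprocessing.

Raw cursor logs are long-format tables with one row per cursor sample
(participant, trial, stimulus, time in ms since trial initiation, x/y in
pixels).  This module applies the study's exclusion rules, linearly
interpolates each trial onto a uniform 1 ms grid (1..800 ms) with
missing-coded head and tail (no extrapolation), and averages horizontal and
vertical position per image — first across trials within each participant,
then across participants — yielding the group-mean trajectories that all
downstream dissimilarity analyses consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Trial",
    "Stimulus",
    "StimulusSet",
    "TrialExclusionReport",
    "ParticipantExclusionReport",
    "MeanTrajectorySet",
    "ParticipantMeans",
    "load_trials",
    "trials_to_frame",
    "filter_trials",
    "score_trial",
    "filter_participants",
    "mirror_to_canonical",
    "interpolate_trajectory",
    "participant_mean_trajectories",
    "average_trajectories",
]

LEFT = "left"
RIGHT = "right"

#: Default movement recording window in ms: samples run from trial
#: initiation to the 800 ms response deadline (or to an earlier box click).
DEFAULT_T_MAX = 800


@dataclass
class Trial:
    """One trial's cursor samples plus the metadata needed to score it.

    ``correct_side`` is the screen side (``"left"``/``"right"``) of the
    correct response box on this trial; the boxes swap sides halfway through
    the session, so the side is stored per trial rather than per stimulus.
    """

    participant_id: str
    trial_index: int
    stimulus_id: str
    block: int
    correct_side: str
    midline_x: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.size == 0:
            raise ValueError("trial has no samples")
        if not (self.t.size == self.x.size == self.y.size):
            raise ValueError("t/x/y length mismatch")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.t[0] < 0:
            raise ValueError("sample times must be non-negative")
        if self.correct_side not in (LEFT, RIGHT):
            raise ValueError(f"invalid correct_side {self.correct_side!r}")

    @property
    def recorded_span_ms(self) -> float:
        """Time spanned by the recorded samples (last minus first)."""
        return float(self.t[-1] - self.t[0])

    @property
    def path_length_px(self) -> float:
        """Total Euclidean path length of the cursor trace."""
        if self.t.size < 2:
            return 0.0
        return float(np.hypot(np.diff(self.x), np.diff(self.y)).sum())

    @property
    def key(self) -> tuple:
        return (self.participant_id, self.trial_index)


@dataclass(frozen=True)
class Stimulus:
    stimulus_id: str
    category: str  # face | animal | lookalike | object | filler
    matched_pair_id: str | None = None
    in_analysis: bool = True


@dataclass
class StimulusSet:
    """Ordered stimulus metadata; the ordering fixes RDM label order."""

    stimuli: list[Stimulus]

    def __post_init__(self) -> None:
        ids = [s.stimulus_id for s in self.stimuli]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate stimulus ids")
        self._by_id = {s.stimulus_id: s for s in self.stimuli}

    def __len__(self) -> int:
        return len(self.stimuli)

    def __iter__(self):
        return iter(self.stimuli)

    def __getitem__(self, stimulus_id: str) -> Stimulus:
        return self._by_id[stimulus_id]

    def __contains__(self, stimulus_id: str) -> bool:
        return stimulus_id in self._by_id

    @property
    def analysis_ids(self) -> list[str]:
        return [s.stimulus_id for s in self.stimuli if s.in_analysis]

    def category_of(self, stimulus_id: str) -> str:
        return self._by_id[stimulus_id].category

    def ids_of_category(self, category: str, in_analysis_only: bool = True) -> list[str]:
        return [
            s.stimulus_id
            for s in self.stimuli
            if s.category == category and (s.in_analysis or not in_analysis_only)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stimulus_id": [s.stimulus_id for s in self.stimuli],
                "category": [s.category for s in self.stimuli],
                "matched_pair_id": [s.matched_pair_id for s in self.stimuli],
                "in_analysis": [s.in_analysis for s in self.stimuli],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StimulusSet":
        stimuli = [
            Stimulus(
                stimulus_id=str(r.stimulus_id),
                category=str(r.category),
                matched_pair_id=None
                if pd.isna(r.matched_pair_id)
                else str(r.matched_pair_id),
                in_analysis=bool(r.in_analysis),
            )
            for r in df.itertuples()
        ]
        return cls(stimuli)

    @classmethod
    def from_csv(cls, path) -> "StimulusSet":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class TrialExclusionReport:
    """Counts per exclusion reason. A trial can fail both criteria; it is
    removed once but counted under each reason it fails."""

    n_input: int
    n_short: int
    n_low_movement: int
    n_removed: int
    removed_keys: list[tuple] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_short": self.n_short,
            "n_low_movement": self.n_low_movement,
            "n_removed": self.n_removed,
            "n_retained": self.n_input - self.n_removed,
        }


@dataclass
class ParticipantExclusionReport:
    n_input: int
    n_low_accuracy: int
    n_zero_trials: int
    removed_ids: list[str] = field(default_factory=list)
    zero_trial_ids: list[str] = field(default_factory=list)
    accuracy: dict = field(default_factory=dict)

    @property
    def fraction_removed(self) -> float:
        return (self.n_low_accuracy + self.n_zero_trials) / self.n_input

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_low_accuracy": self.n_low_accuracy,
            "n_zero_trials": self.n_zero_trials,
            "fraction_removed": self.fraction_removed,
        }


@dataclass
class MeanTrajectorySet:
    """Group-mean cursor position per image on the uniform 1 ms grid.

    ``mean_x``/``mean_y`` are (stimulus, time) arrays; NaN where no
    participant contributed data.  ``n_contributing`` counts participants
    with data per (stimulus, time).
    """

    labels: list[str]
    time_grid: np.ndarray
    mean_x: np.ndarray
    mean_y: np.ndarray
    n_contributing: np.ndarray

    def __post_init__(self) -> None:
        s, t = len(self.labels), len(self.time_grid)
        for name in ("mean_x", "mean_y", "n_contributing"):
            arr = getattr(self, name)
            if arr.shape != (s, t):
                raise ValueError(f"{name} shape {arr.shape} != ({s}, {t})")
        defined = self.n_contributing > 0
        if np.any(np.isnan(self.mean_x[defined])):
            raise ValueError("mean undefined where n_contributing > 0")


@dataclass
class ParticipantMeans:
    """Per-participant, per-image mean trajectories (x only is used
    downstream); the input to participant-level bootstrap resampling."""

    participants: list[str]
    labels: list[str]
    time_grid: np.ndarray
    x: np.ndarray  # (participant, stimulus, time), NaN-coded
    y: np.ndarray


# ---------------------------------------------------------------------------
# I/O


TRIAL_COLUMNS = [
    "participant_id",
    "trial_index",
    "stimulus_id",
    "block",
    "correct_side",
    "t_ms",
    "x_px",
    "y_px",
    "midline_x_px",
]


def load_trials(source) -> list[Trial]:
    """Read long-format cursor logs (CSV path or DataFrame) into trials."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    trials = []
    for (pid, tidx), g in df.groupby(["participant_id", "trial_index"], sort=True):
        g = g.sort_values("t_ms")
        trials.append(
            Trial(
                participant_id=str(pid),
                trial_index=int(tidx),
                stimulus_id=str(g["stimulus_id"].iloc[0]),
                block=int(g["block"].iloc[0]),
                correct_side=str(g["correct_side"].iloc[0]),
                midline_x=float(g["midline_x_px"].iloc[0]),
                t=g["t_ms"].to_numpy(),
                x=g["x_px"].to_numpy(),
                y=g["y_px"].to_numpy(),
            )
        )
    return trials


def trials_to_frame(trials: list[Trial]) -> pd.DataFrame:
    parts = []
    for tr in trials:
        n = tr.t.size
        parts.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(tr.participant_id, n),
                    "trial_index": np.repeat(tr.trial_index, n),
                    "stimulus_id": np.repeat(tr.stimulus_id, n),
                    "block": np.repeat(tr.block, n),
                    "correct_side": np.repeat(tr.correct_side, n),
                    "t_ms": tr.t,
                    "x_px": tr.x,
                    "y_px": tr.y,
                    "midline_x_px": np.repeat(tr.midline_x, n),
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Exclusion rules


def filter_trials(
    trials: list[Trial],
    min_recorded_ms: float = 100.0,
    min_displacement_px: float = 50.0,
) -> tuple[list[Trial], TrialExclusionReport]:
    """Drop trials with under ``min_recorded_ms`` of recorded data or a
    cursor path shorter than ``min_displacement_px``.

    "Recorded data" is the time span between the first and last sample
    (robust to browsers dropping frames); movement is total Euclidean path
    length, which is stricter than net displacement and robust to
    back-and-forth jitter.
    """
    if not trials:
        raise ValueError("no trials")
    kept: list[Trial] = []
    n_short = n_low = 0
    removed = []
    for tr in trials:
        short = tr.recorded_span_ms < min_recorded_ms
        low = tr.path_length_px < min_displacement_px
        n_short += short
        n_low += low
        if short or low:
            removed.append(tr.key)
        else:
            kept.append(tr)
    report = TrialExclusionReport(
        n_input=len(trials),
        n_short=int(n_short),
        n_low_movement=int(n_low),
        n_removed=len(removed),
        removed_keys=removed,
    )
    return kept, report


def score_trial(trial: Trial) -> bool:
    """A trial is correct iff the final cursor position is on the same side
    of the screen midline as the correct response box.

    A final position exactly on the midline scores incorrect (conservative
    boundary convention).
    """
    final_x = trial.x[-1]
    if trial.correct_side == LEFT:
        return bool(final_x < trial.midline_x)
    return bool(final_x > trial.midline_x)


def filter_participants(
    trials: list[Trial], min_accuracy: float = 0.70
) -> tuple[list[Trial], ParticipantExclusionReport]:
    """Remove participants whose overall accuracy over their retained
    trials is strictly below ``min_accuracy``.

    Participants with zero retained trials are removed and flagged
    separately.  Returns the surviving trials and a report.
    """
    by_pid: dict[str, list[Trial]] = {}
    for tr in trials:
        by_pid.setdefault(tr.participant_id, []).append(tr)
    kept: list[Trial] = []
    removed, zero, accuracy = [], [], {}
    for pid, group in sorted(by_pid.items()):
        if not group:  # pragma: no cover - defensive
            zero.append(pid)
            continue
        acc = float(np.mean([score_trial(tr) for tr in group]))
        accuracy[pid] = acc
        if acc < min_accuracy:
            removed.append(pid)
        else:
            kept.extend(group)
    report = ParticipantExclusionReport(
        n_input=len(by_pid),
        n_low_accuracy=len(removed),
        n_zero_trials=len(zero),
        removed_ids=removed,
        zero_trial_ids=zero,
        accuracy=accuracy,
    )
    return kept, report


def mirror_to_canonical(trials: list[Trial], stimuli: StimulusSet) -> list[Trial]:
    """Reflect trials into a common decision frame before averaging.

    The response boxes swap sides halfway through the session (and the
    initial arrangement is counterbalanced across participants), so raw
    horizontal positions from the two arrangements would cancel in a group
    mean.  This mirrors every trial whose face/animal box is on the left
    about the screen midline, so that positive displacement from the
    midline always means face/animal-ward; ``correct_side`` is flipped
    accordingly, leaving trial scoring unchanged.
    """
    out = []
    for tr in trials:
        cat = stimuli.category_of(tr.stimulus_id) if tr.stimulus_id in stimuli else None
        fa_target = cat in ("face", "animal")
        fa_right = (tr.correct_side == RIGHT) == fa_target
        if fa_right:
            out.append(tr)
        else:
            out.append(
                Trial(
                    participant_id=tr.participant_id,
                    trial_index=tr.trial_index,
                    stimulus_id=tr.stimulus_id,
                    block=tr.block,
                    correct_side=RIGHT if tr.correct_side == LEFT else LEFT,
                    midline_x=tr.midline_x,
                    t=tr.t.copy(),
                    x=2.0 * tr.midline_x - tr.x,
                    y=tr.y.copy(),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Interpolation and averaging


def time_grid(t_max: int = DEFAULT_T_MAX) -> np.ndarray:
    """The uniform 1 ms analysis grid, 1..t_max inclusive."""
    return np.arange(1, t_max + 1, dtype=float)


def interpolate_trajectory(
    trial: Trial, t_max: int = DEFAULT_T_MAX
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate one trial onto the 1..t_max ms grid.

    Grid points before the first sample (late movement onset) and after the
    last sample (early box click) are NaN; there is no extrapolation.
    Sample times that fall on the grid are reproduced exactly.
    """
    if trial.t.size < 2:
        raise ValueError("cannot interpolate a trial with fewer than 2 samples")
    grid = time_grid(t_max)
    x = np.interp(grid, trial.t, trial.x, left=np.nan, right=np.nan)
    y = np.interp(grid, trial.t, trial.y, left=np.nan, right=np.nan)
    # np.interp treats the exact endpoints as inside; mask strictly-outside
    # points only (already NaN), keeping endpoint samples.
    return x, y


def participant_mean_trajectories(
    trials: list[Trial],
    stimuli: StimulusSet,
    t_max: int = DEFAULT_T_MAX,
) -> ParticipantMeans:
    """First averaging level: per participant and image, the mean of the
    interpolated trials at each timepoint over available (non-NaN) values."""
    labels = stimuli.analysis_ids
    if not labels:
        raise ValueError("stimulus set has no in-analysis stimuli")
    idx = {sid: i for i, sid in enumerate(labels)}
    grid = time_grid(t_max)
    per_pid: dict[str, tuple[list, list]] = {}
    for tr in trials:
        if tr.stimulus_id not in idx:
            continue  # fillers and unknown images are excluded from analysis
        sums_counts = per_pid.setdefault(
            tr.participant_id,
            (
                [np.zeros((len(labels), grid.size)) for _ in range(2)],
                [np.zeros((len(labels), grid.size)) for _ in range(2)],
            ),
        )
        xi, yi = interpolate_trajectory(tr, t_max)
        i = idx[tr.stimulus_id]
        for k, vals in enumerate((xi, yi)):
            ok = np.isfinite(vals)
            sums_counts[0][k][i, ok] += vals[ok]
            sums_counts[1][k][i, ok] += 1
    if not per_pid:
        raise ValueError("no trials for any in-analysis stimulus")
    missing = [
        sid
        for sid in labels
        if not any(cnts[0][idx[sid]].any() for _, cnts in per_pid.values())
    ]
    if missing:
        raise ValueError(f"stimuli with zero trials: {missing}")
    participants = sorted(per_pid)
    X = np.full((len(participants), len(labels), grid.size), np.nan)
    Y = np.full_like(X, np.nan)
    for p, pid in enumerate(participants):
        (sx, sy), (cx, cy) = per_pid[pid]
        with np.errstate(invalid="ignore"):
            X[p] = np.where(cx > 0, sx / np.maximum(cx, 1), np.nan)
            Y[p] = np.where(cy > 0, sy / np.maximum(cy, 1), np.nan)
    return ParticipantMeans(
        participants=participants, labels=labels, time_grid=grid, x=X, y=Y
    )


def average_participant_means(pm: ParticipantMeans) -> MeanTrajectorySet:
    """Second averaging level: unweighted mean over participants with data
    at each (stimulus, timepoint); available-case, no listwise deletion."""
    n_contrib = np.isfinite(pm.x).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        mean_x = np.nanmean(pm.x, axis=0)
        mean_y = np.nanmean(pm.y, axis=0)
    return MeanTrajectorySet(
        labels=list(pm.labels),
        time_grid=pm.time_grid.copy(),
        mean_x=mean_x,
        mean_y=mean_y,
        n_contributing=n_contrib,
    )


def average_trajectories(
    trials: list[Trial],
    stimuli: StimulusSet,
    t_max: int = DEFAULT_T_MAX,
) -> MeanTrajectorySet:
    """Two-level average: within participant across trials, then across
    participants, per image and timepoint.  Both correct and incorrect
    completed trials contribute; fillers are excluded."""
    pm = participant_mean_trajectories(trials, stimuli, t_max)
    return average_participant_means(pm)
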