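"""Representational dissimilarity matrices (RDMs) and RDM series.

An RDM is a square, symmetric, zero-diagonal, non-negative matrix of
pairwise dissimilarities between stimuli; units depend on the source
(pixels for movement, ms for execution time, 1 - rank-correlation for
activation patterns, {0, 1} for binary theoretical models, decoding
accuracy for EEG).  An :class:`RDMSeries` stacks RDMs over a strictly
increasing time grid with a constant label set; a static RDM is a series of
length one.

Vectorization convention: the strictly-upper triangle for full symmetric
RDMs (diagonal excluded); all cells for rectangular cross-category blocks.
Cross-source operations re-index by label, never by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .trajectories import MeanTrajectorySet, StimulusSet, Trial

__all__ = [
    "RDM",
    "RDMSeries",
    "RDMVector",
    "upper_vector",
    "vectorize_series",
    "movement_rdm_series",
    "binary_model_rdm",
    "execution_time_rdm",
    "pattern_rdm",
    "subset_block",
    "block_pairs",
    "align_series",
]

_SYM_TOL = 1e-9


def _validate_rdm_values(values: np.ndarray, where: str) -> None:
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"{where}: RDM must be square, got {values.shape}")
    finite = np.isfinite(values)
    both = finite & finite.T
    if not np.allclose(values[both], values.T[both], atol=_SYM_TOL):
        raise ValueError(f"{where}: RDM must be symmetric")
    diag = np.diagonal(values)
    if not np.allclose(diag[np.isfinite(diag)], 0.0, atol=_SYM_TOL):
        raise ValueError(f"{where}: RDM diagonal must be zero")
    if np.any(values[finite] < -_SYM_TOL):
        raise ValueError(f"{where}: RDM must be non-negative")


@dataclass
class RDM:
    labels: list[str]
    values: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("label count must match matrix size")
        _validate_rdm_values(self.values, f"RDM[{self.source}]")

    @property
    def n(self) -> int:
        return len(self.labels)

    def reindex(self, labels: list[str]) -> "RDM":
        pos = {l: i for i, l in enumerate(self.labels)}
        try:
            idx = np.array([pos[l] for l in labels])
        except KeyError as e:
            raise KeyError(f"label {e} not in RDM") from e
        return RDM(list(labels), self.values[np.ix_(idx, idx)], self.source)


@dataclass
class RDMSeries:
    labels: list[str]
    times: np.ndarray
    values: np.ndarray  # (time, n, n)
    source: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("series values must be (time, n, n)")
        if self.values.shape[0] != self.times.size:
            raise ValueError("time grid length must match value stack")
        if self.values.shape[1] != len(self.labels):
            raise ValueError("label count must match matrix size")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")
        # validate a sample of frames; full validation on every frame is
        # done by constructors that build frames individually
        for k in (0, self.values.shape[0] - 1):
            _validate_rdm_values(self.values[k], f"RDMSeries[{self.source}] t={self.times[k]}")

    def __len__(self) -> int:
        return self.times.size

    def at(self, k: int) -> RDM:
        return RDM(list(self.labels), self.values[k], self.source)

    def reindex(self, labels: list[str]) -> "RDMSeries":
        pos = {l: i for i, l in enumerate(self.labels)}
        idx = np.array([pos[l] for l in labels])
        return RDMSeries(
            list(labels), self.times, self.values[:, idx][:, :, idx], self.source
        )

    def subsample(self, times: np.ndarray) -> "RDMSeries":
        """Restrict to an exact subset of the existing grid."""
        times = np.asarray(times, dtype=float)
        pos = {t: i for i, t in enumerate(self.times)}
        try:
            idx = np.array([pos[t] for t in times])
        except KeyError as e:
            raise ValueError(f"time {e} not on the series grid") from e
        return RDMSeries(list(self.labels), times, self.values[idx], self.source)


@dataclass
class RDMVector:
    """Vectorized dissimilarities with their (i, j) index map.

    Indices refer to positions in ``labels``; for symmetric full RDMs only
    strictly-upper-triangle cells appear, for rectangular cross-category
    blocks all cells appear.
    """

    entries: np.ndarray
    pairs: np.ndarray  # (m, 2) int
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        self.pairs = np.asarray(self.pairs, dtype=int)
        if self.pairs.shape != (self.entries.size, 2):
            raise ValueError("index map must be (m, 2)")

    def __len__(self) -> int:
        return self.entries.size


def upper_vector(rdm: RDM) -> RDMVector:
    """Strictly-upper-triangle vectorization of a full symmetric RDM."""
    iu, ju = np.triu_indices(rdm.n, k=1)
    return RDMVector(rdm.values[iu, ju], np.column_stack([iu, ju]), list(rdm.labels))


def vectorize_series(series: RDMSeries, pairs: np.ndarray | None = None) -> np.ndarray:
    """(time, n_entries) matrix of vectorized RDM entries.

    ``pairs`` defaults to the strictly-upper triangle.
    """
    if pairs is None:
        iu, ju = np.triu_indices(len(series.labels), k=1)
    else:
        iu, ju = pairs[:, 0], pairs[:, 1]
    return series.values[:, iu, ju]


# ---------------------------------------------------------------------------
# Constructors


def movement_rdm_series(means: MeanTrajectorySet) -> RDMSeries:
    """Movement RDM at every ms: absolute difference in group-mean cursor
    horizontal position between each pair of stimuli.

    Cells involving a stimulus with a missing mean at a timepoint are NaN.
    """
    if len(means.labels) < 3:
        raise ValueError("need at least 3 stimuli for a movement RDM series")
    x = means.mean_x  # (S, T)
    d = np.abs(x[:, None, :] - x[None, :, :])  # (S, S, T)
    values = np.moveaxis(d, -1, 0)
    n = len(means.labels)
    values[:, np.arange(n), np.arange(n)] = 0.0
    return RDMSeries(list(means.labels), means.time_grid, values, source="movement")


def binary_model_rdm(stimuli: StimulusSet, grouping: str) -> RDM:
    """Binary theoretical model over the in-analysis stimuli.

    ``grouping="task"``: the ground-truth categorisation — face/animal vs.
    everything else (lookalikes grouped with objects).
    ``grouping="lookalike"``: perceptual similarity — lookalikes grouped
    with their confusable face/animal category, vs. objects.
    """
    if grouping not in ("task", "lookalike"):
        raise ValueError(f"unknown grouping {grouping!r}")
    labels = stimuli.analysis_ids
    fa = {"face", "animal"}
    group = []
    for sid in labels:
        cat = stimuli.category_of(sid)
        if cat in fa:
            group.append(1)
        elif cat == "lookalike":
            group.append(1 if grouping == "lookalike" else 0)
        elif cat == "object":
            group.append(0)
        else:
            raise ValueError(f"unknown category {cat!r} for stimulus {sid!r}")
    g = np.asarray(group)
    values = (g[:, None] != g[None, :]).astype(float)
    return RDM(labels, values, source=f"model:{grouping}")


def execution_time_rdm(
    trials: list[Trial],
    stimuli: StimulusSet,
    t_max: float = 800.0,
) -> RDM:
    """Control model: pairwise differences in mean movement execution time.

    Execution time is the time (ms) at which the cursor reached a response
    box; only trials where a box was reached (the trial ended before the
    ``t_max`` deadline) contribute.  Means are taken within participant,
    then across participants.
    """
    labels = stimuli.analysis_ids
    idx = {sid: i for i, sid in enumerate(labels)}
    per_pid: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for tr in trials:
        if tr.stimulus_id not in idx:
            continue
        if tr.t[-1] >= t_max:
            continue  # deadline reached without clicking a box
        sums, counts = per_pid.setdefault(
            tr.participant_id, (np.zeros(len(labels)), np.zeros(len(labels)))
        )
        sums[idx[tr.stimulus_id]] += tr.t[-1]
        counts[idx[tr.stimulus_id]] += 1
    if not per_pid:
        raise ValueError("no box-reaching trials")
    stack = []
    for pid in sorted(per_pid):
        sums, counts = per_pid[pid]
        with np.errstate(invalid="ignore"):
            stack.append(np.where(counts > 0, sums / np.maximum(counts, 1), np.nan))
    arr = np.vstack(stack)
    n_ok = np.isfinite(arr).sum(axis=0)
    missing = [labels[i] for i in np.flatnonzero(n_ok == 0)]
    if missing:
        raise ValueError(f"images with zero box-reaching trials: {missing}")
    mean_t = np.nansum(arr, axis=0) / n_ok
    values = np.abs(mean_t[:, None] - mean_t[None, :])
    np.fill_diagonal(values, 0.0)
    return RDM(labels, values, source="execution_time")


def pattern_rdm(patterns: np.ndarray, labels: list[str]) -> RDM:
    """1 - Spearman correlation between per-stimulus activation patterns.

    ``patterns`` is (stimulus, feature).  Constant patterns make the rank
    correlation undefined and raise.
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2 or patterns.shape[1] < 2:
        raise ValueError("patterns must be (stimulus, feature) with >= 2 features")
    if patterns.shape[0] != len(labels):
        raise ValueError("label count must match pattern count")
    ranks = rankdata(patterns, axis=1)
    sd = ranks.std(axis=1)
    if np.any(sd == 0):
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant pattern(s), rank correlation undefined: {bad}")
    z = ranks - ranks.mean(axis=1, keepdims=True)
    z /= np.sqrt((z**2).sum(axis=1, keepdims=True))
    values = 1.0 - z @ z.T
    np.fill_diagonal(values, 0.0)
    values = np.clip(0.5 * (values + values.T), 0.0, None)
    return RDM(list(labels), values, source="pattern")


# ---------------------------------------------------------------------------
# Subsetting and alignment


def block_pairs(
    labels: list[str],
    row_labels: list[str],
    col_labels: list[str],
) -> np.ndarray:
    """Index pairs for a category block of an RDM with the given labels.

    Distinct row/column sets give the full rectangular block; identical
    sets give the strictly-upper triangle of the within-category block.
    """
    if not row_labels or not col_labels:
        raise ValueError("empty category in block specification")
    pos = {l: i for i, l in enumerate(labels)}
    rows = [pos[l] for l in row_labels]
    cols = [pos[l] for l in col_labels]
    if set(row_labels) == set(col_labels):
        order = sorted(rows)
        iu, ju = np.triu_indices(len(order), k=1)
        order = np.asarray(order)
        return np.column_stack([order[iu], order[ju]])
    if set(row_labels) & set(col_labels):
        raise ValueError("cross-category block requires disjoint categories")
    return np.array([(i, j) for i in rows for j in cols], dtype=int)


def subset_block(
    rdm: RDM,
    stimuli: StimulusSet,
    row_category: str,
    col_category: str,
) -> RDMVector:
    """Vectorize a category block of an RDM (e.g. Lookalike x Object).

    Cross-category blocks vectorize all row x col cells; a within-category
    block vectorizes its strictly-upper triangle.
    """
    rows = [l for l in rdm.labels if l in stimuli and stimuli.category_of(l) == row_category]
    cols = [l for l in rdm.labels if l in stimuli and stimuli.category_of(l) == col_category]
    pairs = block_pairs(rdm.labels, rows, cols)
    entries = rdm.values[pairs[:, 0], pairs[:, 1]]
    return RDMVector(entries, pairs, list(rdm.labels))


def align_series(
    series: RDMSeries, target_times: np.ndarray, mode: str = "nearest"
) -> RDMSeries:
    """Re-grid a series: nearest-neighbour assignment (for plotting on a
    finer grid) or identity.  Targets outside the source span raise."""
    if mode == "none":
        return series
    if mode != "nearest":
        raise ValueError(f"unknown mode {mode!r}")
    target = np.asarray(target_times, dtype=float)
    if target.min() < series.times.min() or target.max() > series.times.max():
        raise ValueError("target grid outside the series' span")
    idx = np.abs(series.times[None, :] - target[:, None]).argmin(axis=1)
    return RDMSeries(list(series.labels), target, series.values[idx], series.source)
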