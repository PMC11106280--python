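"""Resampling and permutation inference.

Two procedures:

* :func:`resample_band` — participant bootstrap (selection with
  replacement) of group-level model-correlation timecourses, giving 5th/95th
  percentile bands, one-tailed significance against zero, and two-tailed
  significance of between-model differences.  The variance source is either
  the trajectory participants (group means are recomputed per resample) or
  the neural participants (per-participant RDM series are re-averaged).
  A leave-one-out jackknife mode is available but not the default.

* :func:`cluster_permutation_test` — cluster-based sign-permutation test of
  per-participant time-time maps against zero.  Per cell a one-sample t
  statistic; cells exceeding the cluster-forming threshold (alpha = 0.05 by
  default) join 4-connected clusters scored by their t-sum; the null is the
  maximum cluster sum over sign-flip permutations in which each
  participant's whole map is multiplied by +/-1.  Clusters are significant
  when their statistic beats the (1 - alpha_fwe) tail of that null.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from .rdm import RDM
from .similarity import rank_corr_map
from .trajectories import ParticipantMeans

__all__ = ["ResampleBand", "Cluster", "ClusterResult", "resample_band", "cluster_permutation_test"]

_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


@dataclass
class ResampleBand:
    times: np.ndarray
    model_tags: list[str]
    point: np.ndarray  # (model, time) group-level rho
    low: np.ndarray  # 5th percentile
    high: np.ndarray  # 95th percentile
    sig_vs_zero: np.ndarray  # (model, time) bool
    sig_between_models: np.ndarray | None  # (time,) bool, if 2 models
    n_resamples: int
    seed: int | None
    method: str = "bootstrap"

    def __post_init__(self) -> None:
        if np.any(self.low[np.isfinite(self.low)] > self.high[np.isfinite(self.low)] + 1e-12):
            raise ValueError("band low must not exceed high")


@dataclass
class Cluster:
    cells: np.ndarray  # (n_cells, 2) int indices into the map
    stat: float  # cluster-sum of t values
    p_value: float
    significant: bool
    sign: int = 1


@dataclass
class ClusterResult:
    t_map: np.ndarray
    sig_mask: np.ndarray
    clusters: list[Cluster]
    null_distribution: np.ndarray
    alpha_cluster: float
    alpha_fwe: float
    n_perm: int
    tail: str
    seed: int | None = None

    @property
    def n_significant(self) -> int:
        return sum(c.significant for c in self.clusters)

    def summary(self) -> dict:
        return {
            "n_clusters": len(self.clusters),
            "n_significant": self.n_significant,
            "clusters": [
                {
                    "n_cells": int(c.cells.shape[0]),
                    "stat": float(c.stat),
                    "p_value": float(c.p_value),
                    "significant": bool(c.significant),
                    "sign": int(c.sign),
                }
                for c in self.clusters
            ],
            "alpha_cluster": self.alpha_cluster,
            "alpha_fwe": self.alpha_fwe,
            "n_perm": self.n_perm,
            "tail": self.tail,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Bootstrap bands


def _movement_vectors(mean_x: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    """(time, pair) |Δ horizontal position| entries from (stimulus, time)
    group-mean positions."""
    d = np.abs(mean_x[pairs[:, 0]] - mean_x[pairs[:, 1]])  # (pair, time)
    return d.T


def _band_from_samples(
    times, tags, point, samples, alpha, n_resamples, seed, method
) -> ResampleBand:
    # samples: (resample, model, time)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        low = np.nanpercentile(samples, 5, axis=0)
        high = np.nanpercentile(samples, 95, axis=0)
        frac_nonpos = np.nanmean(samples <= 0, axis=0)
    sig_zero = frac_nonpos <= alpha
    sig_between = None
    if samples.shape[1] == 2:
        d = samples[:, 0] - samples[:, 1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lo = np.nanpercentile(d, 100 * alpha / 2, axis=0)
            hi = np.nanpercentile(d, 100 * (1 - alpha / 2), axis=0)
        sig_between = (lo > 0) | (hi < 0)
    return ResampleBand(
        times=times,
        model_tags=tags,
        point=point,
        low=low,
        high=high,
        sig_vs_zero=sig_zero,
        sig_between_models=sig_between,
        n_resamples=n_resamples,
        seed=seed,
        method=method,
    )


def resample_band(
    data,
    models,
    mode: str,
    n_resamples: int = 10_000,
    seed: int | None = None,
    method: str = "bootstrap",
    alpha: float = 0.05,
    min_pairs: int = 10,
) -> ResampleBand:
    """Participant-resampling confidence band for model-correlation
    timecourses.

    Parameters
    ----------
    data
        ``mode="trajectory_participants"``: a :class:`ParticipantMeans`
        (per-participant per-image mean trajectories); each resample
        recomputes the group means, the movement RDM series and the model
        correlations.  ``mode="neural_participants"``: a list of
        per-participant :class:`RDMSeries`; each resample re-averages the
        selected participants' RDMs.
    models
        One or two static model RDMs (two enables the between-model test).
    """
    model_list = [models] if isinstance(models, RDM) else list(models)
    if not 1 <= len(model_list) <= 2:
        raise ValueError("one or two models required")
    rng = np.random.default_rng(seed)

    if mode == "trajectory_participants":
        pm: ParticipantMeans = data
        P = len(pm.participants)
        if P < 2:
            raise ValueError("need at least 2 participants")
        labels = pm.labels
        model_vecs, tags = _reindexed_model_vectors(model_list, labels)
        pairs = _upper_pairs(len(labels))

        def group_rho(idx):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean_x = np.nanmean(pm.x[idx], axis=0)  # (S, T)
            V = _movement_vectors(mean_x, pairs)
            return rank_corr_map(V, model_vecs, min_pairs=min_pairs).T  # (model, T)

        times = pm.time_grid
    elif mode == "neural_participants":
        series_list = list(data)
        P = len(series_list)
        if P < 2:
            raise ValueError("need at least 2 participants")
        labels = list(series_list[0].labels)
        stack = np.stack([s.reindex(labels).values for s in series_list])
        model_vecs, tags = _reindexed_model_vectors(model_list, labels)
        pairs = _upper_pairs(len(labels))

        def group_rho(idx):
            mean_rdm = stack[idx].mean(axis=0)  # (T, n, n)
            V = mean_rdm[:, pairs[:, 0], pairs[:, 1]]
            return rank_corr_map(V, model_vecs, min_pairs=min_pairs).T

        times = series_list[0].times
    else:
        raise ValueError(f"unknown mode {mode!r}")

    point = group_rho(np.arange(P))
    if method == "bootstrap":
        draws = rng.integers(0, P, size=(n_resamples, P))
    elif method == "jackknife":
        draws = np.array([np.delete(np.arange(P), i) for i in range(P)])
        n_resamples = P
    else:
        raise ValueError(f"unknown method {method!r}")
    samples = np.stack([group_rho(idx) for idx in draws])  # (R, model, T)
    return _band_from_samples(
        times.copy(), tags, point, samples, alpha, n_resamples, seed, method
    )


def _upper_pairs(n: int) -> np.ndarray:
    iu, ju = np.triu_indices(n, k=1)
    return np.column_stack([iu, ju])


def _reindexed_model_vectors(model_list, labels):
    pairs = _upper_pairs(len(labels))
    vecs = np.vstack(
        [m.reindex(labels).values[pairs[:, 0], pairs[:, 1]] for m in model_list]
    )
    tags = [m.source or f"model{i}" for i, m in enumerate(model_list)]
    return vecs, tags


# ---------------------------------------------------------------------------
# Cluster-based sign-permutation test


def _t_from_mean_sumsq(mean: np.ndarray, sumsq: np.ndarray, n: int) -> np.ndarray:
    var = (sumsq / n - mean**2) * (n / (n - 1))
    var = np.maximum(var, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / np.sqrt(var / n)
    return np.where(var > 0, t, 0.0)


def _max_cluster_sum(tmap: np.ndarray, valid: np.ndarray, tcrit: float, tail: str) -> float:
    best = 0.0
    masks = [(tmap > tcrit) & valid]
    if tail == "two-sided":
        masks.append((-tmap > tcrit) & valid)
    for sgn, mask in zip((1, -1), masks):
        if not mask.any():
            continue
        labels, nlab = ndimage.label(mask, structure=_STRUCTURE_4)
        sums = np.bincount(labels.ravel(), weights=(sgn * tmap).ravel())[1:]
        if sums.size:
            best = max(best, float(sums.max()))
    return best


def cluster_permutation_test(
    maps,
    alpha_cluster: float = 0.05,
    alpha_fwe: float = 0.05,
    n_perm: int = 10_000,
    tail: str = "positive",
    seed: int | None = None,
    exact: bool = False,
) -> ClusterResult:
    """Cluster-based sign-permutation test of per-participant 2-D maps
    against zero.

    ``maps`` is (participant, a, b) (a :class:`~trajrsa.similarity.TimeTimeMap`'s
    ``values`` works directly); cells where any participant is missing are
    excluded from clustering.  ``tail="positive"`` forms clusters of
    positive t only (negative representational overlap is not meaningful
    for movement-neural correlation maps); ``tail="two-sided"`` forms
    clusters of either sign with a symmetric threshold.  ``exact=True``
    enumerates all 2**P sign patterns instead of Monte-Carlo sampling.
    """
    X = np.asarray(getattr(maps, "values", maps), dtype=float)
    if X.ndim != 3:
        raise ValueError("maps must be (participant, a, b)")
    P = X.shape[0]
    if P < 2:
        raise ValueError("need at least 2 participants")
    if tail not in ("positive", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    if n_perm < 100 and not exact:
        warnings.warn("n_perm < 100: the permutation null will be very coarse")

    valid = np.all(np.isfinite(X), axis=0)
    Xz = np.where(valid[None], X, 0.0)
    flat = Xz.reshape(P, -1)
    sumsq = np.einsum("ij,ij->j", flat, flat)
    df = P - 1
    if tail == "positive":
        tcrit = float(stats.t.ppf(1 - alpha_cluster, df))
    else:
        tcrit = float(stats.t.ppf(1 - alpha_cluster / 2, df))

    t_obs = _t_from_mean_sumsq(flat.mean(axis=0), sumsq, P).reshape(X.shape[1:])
    t_map = np.where(valid, t_obs, np.nan)

    # observed clusters
    clusters: list[tuple[np.ndarray, float, int]] = []
    masks = [(1, (t_obs > tcrit) & valid)]
    if tail == "two-sided":
        masks.append((-1, (-t_obs > tcrit) & valid))
    for sgn, mask in masks:
        lab, nlab = ndimage.label(mask, structure=_STRUCTURE_4)
        for li in range(1, nlab + 1):
            cells = np.argwhere(lab == li)
            stat = float(np.abs(t_obs[lab == li].sum()))
            clusters.append((cells, stat, sgn))

    # permutation null of the maximum cluster sum
    if exact:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=P)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.integers(0, 2, size=(n_perm, P)).astype(float) * 2 - 1
    null = np.empty(signs.shape[0])
    chunk = max(1, int(2e7 // max(flat.shape[1], 1)))
    for start in range(0, signs.shape[0], chunk):
        S = signs[start : start + chunk]
        means = S @ flat / P
        tperm = _t_from_mean_sumsq(means, sumsq[None], P)
        for r in range(S.shape[0]):
            null[start + r] = _max_cluster_sum(
                tperm[r].reshape(X.shape[1:]), valid, tcrit, tail
            )

    n_null = null.size
    out: list[Cluster] = []
    sig_mask = np.zeros(X.shape[1:], dtype=bool)
    for cells, stat, sgn in clusters:
        if exact:
            p = float(np.mean(null >= stat))
        else:
            p = float((1 + np.sum(null >= stat)) / (n_null + 1))
        sig = p <= alpha_fwe
        if sig:
            sig_mask[cells[:, 0], cells[:, 1]] = True
        out.append(Cluster(cells=cells, stat=stat, p_value=p, significant=sig, sign=sgn))
    out.sort(key=lambda c: -c.stat)
    return ClusterResult(
        t_map=t_map,
        sig_mask=sig_mask,
        clusters=out,
        null_distribution=null,
        alpha_cluster=alpha_cluster,
        alpha_fwe=alpha_fwe,
        n_perm=n_null,
        tail=tail,
        seed=seed,
    )
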