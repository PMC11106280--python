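"""Correlating RDMs and RDM series.

All comparisons between representational geometries use Spearman rank
correlation over vectorized RDM entries, with average-rank tie handling.
Partial correlation is computed on ranks: every vector is rank-transformed,
the ranks of the two vectors of interest are residualized on the covariate
ranks by least squares (with intercept), and the Pearson correlation of the
residuals is returned.  With no covariates this reduces exactly to plain
Spearman.

Missing entries (e.g. movement RDM cells before a stimulus has any recorded
cursor data) are handled pairwise-complete with a minimum-pair-count guard;
degenerate (constant) vectors yield missing output rather than zeros.

The time-time map generalizes this cell-wise over (neural time x movement
time), per neural participant; the movement series enters only at the group
level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .rdm import RDM, RDMSeries, RDMVector, block_pairs, vectorize_series
from .trajectories import StimulusSet

__all__ = [
    "TimeTimeMap",
    "ModelCorrelationTimecourse",
    "spearman_rdm",
    "partial_spearman",
    "rank_corr_map",
    "model_timecourse",
    "time_time_map",
    "mds_embedding",
]

#: Minimum pairwise-complete entries for series-level correlations.
MIN_PAIRS_SERIES = 10

_DEGEN_RTOL = 1e-12


@dataclass
class ModelCorrelationTimecourse:
    times: np.ndarray
    rho: np.ndarray
    model: str = ""
    covariates: list[str] = field(default_factory=list)


@dataclass
class TimeTimeMap:
    """(Partial) correlation between a neural RDM series and the group
    movement RDM series at every timepoint combination.

    ``values`` is (participant, neural time, movement time); group maps
    drop the participant axis via :meth:`group_mean`.
    """

    neural_times: np.ndarray
    movement_times: np.ndarray
    values: np.ndarray
    covariates: list[str] = field(default_factory=list)
    region: str = "full"
    participants: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.ndim == 2:
            self.values = self.values[None]
        if self.values.shape[1:] != (self.neural_times.size, self.movement_times.size):
            raise ValueError("value dims must match (neural, movement) grids")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and np.any(np.abs(finite) > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    def group_mean(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values, axis=0)


# ---------------------------------------------------------------------------
# Core rank-correlation engine


def _entries(v) -> np.ndarray:
    if isinstance(v, RDMVector):
        return v.entries
    return np.asarray(v, dtype=float)


def _rank_and_residualize(
    block: np.ndarray, Q: np.ndarray | None
) -> np.ndarray:
    """Rank rows, then center (or residualize on the covariate design Q)
    and scale to unit norm.  Rows without residual variance become NaN."""
    r = rankdata(block, axis=-1)
    if Q is None:
        r = r - r.mean(axis=-1, keepdims=True)
    else:
        r = r - (r @ Q) @ Q.T
    ss = np.einsum("ij,ij->i", r, r)
    # degeneracy threshold relative to the rank variance of m untied items
    m = block.shape[-1]
    tol = _DEGEN_RTOL * m * (m**2 - 1) / 12.0
    bad = ss <= tol
    with np.errstate(invalid="ignore", divide="ignore"):
        z = r / np.sqrt(ss)[:, None]
    z[bad] = np.nan
    return z


def _covariate_design(cov_block: np.ndarray) -> np.ndarray:
    """Orthonormal basis (QR) of [1, covariate ranks]; raises on collinear
    covariates."""
    m = cov_block.shape[-1]
    ranks = rankdata(cov_block, axis=-1)
    D = np.column_stack([np.ones(m), ranks.T])
    Q, R = np.linalg.qr(D)
    if np.any(np.abs(np.diagonal(R)) < 1e-9 * np.sqrt(m)):
        raise ValueError("collinear covariates")
    return Q


def rank_corr_map(
    A: np.ndarray,
    B: np.ndarray,
    covariates: np.ndarray | None = None,
    min_pairs: int = 3,
) -> np.ndarray:
    """(Partial) Spearman correlation between every row of ``A`` and every
    row of ``B`` (shape (Ta, n) x (Tb, n) -> (Ta, Tb)).

    NaN entries are handled pairwise-complete: rows are grouped by their
    missingness pattern and ranks are recomputed within each valid subset.
    Cells with too few complete pairs, or with a degenerate (constant or
    covariate-collinear) vector, are NaN.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("A and B must share the entry axis")
    k = 0
    cov_ok = np.ones(A.shape[1], dtype=bool)
    if covariates is not None and len(covariates):
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        k = covariates.shape[0]
        cov_ok = np.all(np.isfinite(covariates), axis=0)
    need = max(min_pairs, k + 3)

    out = np.full((A.shape[0], B.shape[0]), np.nan)
    a_mask = np.isfinite(A)
    b_mask = np.isfinite(B)
    ua, inv_a = np.unique(a_mask, axis=0, return_inverse=True)
    ub, inv_b = np.unique(b_mask, axis=0, return_inverse=True)
    for ia in range(ua.shape[0]):
        rows_a = np.flatnonzero(inv_a == ia)
        for ib in range(ub.shape[0]):
            rows_b = np.flatnonzero(inv_b == ib)
            valid = ua[ia] & ub[ib] & cov_ok
            if valid.sum() < need:
                continue
            Q = None
            if k:
                Q = _covariate_design(covariates[:, valid])
            Za = _rank_and_residualize(A[np.ix_(rows_a, np.flatnonzero(valid))], Q)
            Zb = _rank_and_residualize(B[np.ix_(rows_b, np.flatnonzero(valid))], Q)
            out[np.ix_(rows_a, rows_b)] = Za @ Zb.T
    return np.clip(out, -1.0, 1.0, out=out)


def spearman_rdm(a, b, min_pairs: int = 3) -> float:
    """Spearman rank correlation between two vectorized RDMs.

    Pairwise-complete over finite entries; a constant input yields NaN with
    a warning rather than an exception.
    """
    va, vb = _entries(a), _entries(b)
    if va.shape != vb.shape:
        raise ValueError("vectors must share the same index map")
    rho = rank_corr_map(va[None], vb[None], min_pairs=min_pairs)[0, 0]
    if np.isnan(rho):
        warnings.warn("spearman_rdm: degenerate or underpowered input, returning NaN")
    return float(rho)


def partial_spearman(a, b, covariates=(), min_pairs: int = 3) -> float:
    """Partial Spearman correlation of ``a`` and ``b`` given covariate RDM
    vectors (empty covariates reduce exactly to :func:`spearman_rdm`).

    Raises on collinear covariates or a covariate collinear with ``a`` or
    ``b`` (no residual rank variance).
    """
    va, vb = _entries(a), _entries(b)
    if va.shape != vb.shape:
        raise ValueError("vectors must share the same index map")
    cov = [_entries(c) for c in covariates]
    if not cov:
        return spearman_rdm(a, b, min_pairs=min_pairs)
    C = np.vstack(cov)
    valid = np.isfinite(va) & np.isfinite(vb) & np.all(np.isfinite(C), axis=0)
    if valid.sum() <= C.shape[0] + 2:
        raise ValueError("too few complete pairs for partial correlation")
    rho = rank_corr_map(va[None], vb[None], covariates=C, min_pairs=min_pairs)[0, 0]
    if np.isnan(rho):
        # distinguish degeneracy (residual variance gone) from plain NaN
        raise ValueError("degenerate covariate: no residual rank variance")
    return float(rho)


# ---------------------------------------------------------------------------
# Series-level operations


def _covariate_matrix(covariates, labels, pairs) -> tuple[np.ndarray | None, list[str]]:
    vecs, tags = [], []
    for cov in covariates:
        if isinstance(cov, RDM):
            c = cov.reindex(labels).values[pairs[:, 0], pairs[:, 1]]
            tags.append(cov.source or "covariate")
        elif isinstance(cov, RDMVector):
            c = cov.entries
            tags.append("covariate")
        else:
            c = np.asarray(cov, dtype=float)
            tags.append("covariate")
        vecs.append(c)
    if not vecs:
        return None, tags
    return np.vstack(vecs), tags


def _region_pairs(labels, region, stimuli: StimulusSet | None):
    if region in (None, "full"):
        iu, ju = np.triu_indices(len(labels), k=1)
        return np.column_stack([iu, ju]), "full"
    if stimuli is None:
        raise ValueError("a category-block region requires the stimulus set")
    row_cat, col_cat = region
    rows = [l for l in labels if l in stimuli and stimuli.category_of(l) == row_cat]
    cols = [l for l in labels if l in stimuli and stimuli.category_of(l) == col_cat]
    return block_pairs(labels, rows, cols), f"{row_cat}x{col_cat}"


def model_timecourse(
    series: RDMSeries,
    model: RDM,
    covariates=(),
    min_pairs: int = MIN_PAIRS_SERIES,
) -> ModelCorrelationTimecourse:
    """Per-timepoint (partial) Spearman correlation between an RDM series
    and a static model RDM."""
    model = model.reindex(series.labels)
    iu, ju = np.triu_indices(len(series.labels), k=1)
    pairs = np.column_stack([iu, ju])
    V = vectorize_series(series, pairs)
    mvec = model.values[iu, ju]
    C, tags = _covariate_matrix(covariates, series.labels, pairs)
    rho = rank_corr_map(V, mvec[None], covariates=C, min_pairs=min_pairs)[:, 0]
    return ModelCorrelationTimecourse(
        times=series.times.copy(), rho=rho, model=model.source, covariates=tags
    )


def time_time_map(
    mov: RDMSeries,
    neural,
    covariates=(),
    region=None,
    stimuli: StimulusSet | None = None,
    min_pairs: int = MIN_PAIRS_SERIES,
) -> TimeTimeMap:
    """Time-time (partial) Spearman correlation map between the group
    movement RDM series and one or more per-participant neural RDM series.

    Each cell (participant, t_neural, t_mov) correlates the vectorized
    neural RDM at t_neural with the movement RDM at t_mov, optionally
    restricted to a category block ``region=(row_category, col_category)``
    and partialling static covariate RDMs.
    """
    series_list = [neural] if isinstance(neural, RDMSeries) else list(neural)
    if not series_list:
        raise ValueError("no neural series")
    labels = list(mov.labels)
    pairs, region_tag = _region_pairs(labels, region, stimuli)
    Vm = vectorize_series(mov, pairs)
    C, tags = _covariate_matrix(covariates, labels, pairs)
    maps = []
    for s in series_list:
        s = s.reindex(labels)
        Vn = vectorize_series(s, pairs)
        maps.append(rank_corr_map(Vn, Vm, covariates=C, min_pairs=min_pairs))
    return TimeTimeMap(
        neural_times=series_list[0].times.copy(),
        movement_times=mov.times.copy(),
        values=np.stack(maps),
        covariates=tags,
        region=region_tag,
        participants=[s.source or f"p{i}" for i, s in enumerate(series_list)],
    )


# ---------------------------------------------------------------------------
# Embeddings


def mds_embedding(
    rdm: RDM | RDMSeries,
    dims: int = 2,
    window_ms: float | None = None,
    center_ms: float | None = None,
    seed: int | None = 0,
) -> np.ndarray:
    """Low-dimensional metric MDS configuration of the stimuli.

    Given an :class:`RDMSeries` with ``window_ms``/``center_ms``, the input
    RDM is the series averaged over a window of that width centred on
    ``center_ms`` (the display convention for time-resolved embeddings).
    SMACOF stress majorization is initialised from the classical
    (Torgerson) solution, which makes the result deterministic and exact
    for Euclidean-realizable dissimilarities; an all-zero RDM returns
    coincident points at the origin.
    """
    from sklearn.manifold import smacof

    if isinstance(rdm, RDMSeries):
        if center_ms is None:
            raise ValueError("an RDMSeries input requires center_ms")
        half = (window_ms or 0.0) / 2.0
        sel = np.abs(rdm.times - center_ms) <= half
        if not sel.any():
            raise ValueError("window contains no timepoints")
        D = np.nanmean(rdm.values[sel], axis=0)
    else:
        D = rdm.values
    if np.allclose(D, 0.0):
        return np.zeros((D.shape[0], dims))
    # classical MDS start: double-centre the squared dissimilarities
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(Bmat)
    order = np.argsort(w)[::-1][:dims]
    init = V[:, order] * np.sqrt(np.clip(w[order], 0.0, None))
    coords, _ = smacof(
        D,
        n_components=dims,
        init=init,
        n_init=1,
        max_iter=500,
        eps=1e-12,
        random_state=seed,
        normalized_stress=False,
    )
    return coords
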