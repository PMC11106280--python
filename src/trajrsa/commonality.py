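"""Variance partitioning of the movement-neural representational overlap.

Commonality analysis asks how much of the shared variance between the
movement and neural RDM series at a given time-time cell is uniquely
carried by one fMRI ROI's (static) RDM.  For ROI_i with the remaining ROIs
as background covariates (plus the task model):

    C(Mov, Neural, ROI_i) = R^2(Mov, Neural | ROIs except i)
                          - R^2(Mov, Neural | all ROIs)

where R^2 is the squared partial Spearman correlation between the movement
and neural RDM vectors given the listed covariates.  Coefficients are in
rho^2 units; negative values (suppression) are reported, not clipped.
Significance is assessed with the same participant-level sign-permutation
cluster test used for the raw correlation maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rdm import RDM, RDMSeries
from .similarity import MIN_PAIRS_SERIES, TimeTimeMap, time_time_map
from .trajectories import StimulusSet

__all__ = ["CommonalityMap", "commonality_map"]


@dataclass
class CommonalityMap:
    """Per-ROI stack of per-participant commonality maps (rho^2 units)."""

    roi_labels: list[str]
    neural_times: np.ndarray
    movement_times: np.ndarray
    values: np.ndarray  # (roi, participant, t_neural, t_mov)
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.ndim != 4 or self.values.shape[0] != len(self.roi_labels):
            raise ValueError("values must be (roi, participant, t_neural, t_mov)")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and np.any(np.abs(finite) > 1 + 1e-9):
            raise ValueError("|C| cannot exceed 1")

    def roi(self, name: str) -> np.ndarray:
        return self.values[self.roi_labels.index(name)]


def commonality_map(
    mov: RDMSeries,
    neural,
    roi_rdms: list[RDM],
    roi_labels: list[str] | None = None,
    extra_covariates=(),
    region=None,
    stimuli: StimulusSet | None = None,
    min_pairs: int = MIN_PAIRS_SERIES,
) -> CommonalityMap:
    """Unique time-time commonality of each ROI RDM, per neural participant.

    ``extra_covariates`` (typically the task model) are included in every
    partial correlation.  ROI RDMs are static and shared across all
    timepoint combinations.  Cells that are missing in any constituent
    partial map (degenerate covariates, too few pairs) propagate as NaN.
    """
    if not roi_rdms:
        raise ValueError("no ROI RDMs")
    if roi_labels is None:
        roi_labels = [r.source or f"roi{i}" for i, r in enumerate(roi_rdms)]
    if len(roi_labels) != len(roi_rdms):
        raise ValueError("roi_labels length mismatch")
    extra = list(extra_covariates)

    def dedup(covs):
        # identical ROI RDMs would make the covariate design singular; a
        # duplicate carries no extra variance, so keep the first occurrence
        out: list = []
        for c in covs:
            vals = c.values if isinstance(c, RDM) else np.asarray(c)
            if not any(
                np.array_equal(vals, (o.values if isinstance(o, RDM) else np.asarray(o)))
                for o in out
            ):
                out.append(c)
        return out

    def partial_map(covs) -> TimeTimeMap:
        covs = dedup(covs)
        return time_time_map(
            mov,
            neural,
            covariates=covs,
            region=region,
            stimuli=stimuli,
            min_pairs=min_pairs,
        )

    full = partial_map(list(roi_rdms) + extra)  # controls every ROI
    maps = []
    for i in range(len(roi_rdms)):
        others = [r for j, r in enumerate(roi_rdms) if j != i]
        wo = partial_map(others + extra)
        maps.append(wo.values**2 - full.values**2)
    return CommonalityMap(
        roi_labels=list(roi_labels),
        neural_times=full.neural_times,
        movement_times=full.movement_times,
        values=np.stack(maps),
        covariates=[*(c.source if isinstance(c, RDM) else "covariate" for c in extra)],
    )
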