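#!/usr/bin/env python
"""ROI variance partitioning of the movement-neural overlap.

For each study, computes each fMRI ROI's unique commonality map (the drop
in squared movement-neural partial correlation when that ROI joins the
covariate set, always controlling the task model and the remaining ROIs),
tests it with the participant-level sign-permutation cluster procedure,
and reports per-ROI significance and mean commonality inside significant
clusters to results/commonality.json.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import trajrsa as T
from trajrsa import io as tio

ROOT = Path(__file__).resolve().parents[1]
SEED = 7


def main() -> None:
    summary = {}
    for study in ("face", "animal"):
        sim = ROOT / "scratch" / f"sim_{study}"
        stimuli = T.StimulusSet.from_csv(sim / "stimuli.csv")
        means = tio.load_means(sim / "means.h5")
        mov = T.movement_rdm_series(means).subsample(np.arange(20.0, 801.0, 20.0))
        neural = [tio.load_rdm_series(p) for p in sorted(sim.glob("neural_p*.h5"))]
        rois = [tio.load_rdm(p) for p in sorted(sim.glob("roi_*.h5"))]
        task = T.binary_model_rdm(stimuli, "task")
        cmap = T.commonality_map(mov, neural, rois, extra_covariates=[task])
        summary[study] = {}
        for r, name in enumerate(cmap.roi_labels):
            res = T.cluster_permutation_test(
                cmap.values[r], n_perm=2000, tail="positive", seed=SEED
            )
            gm = np.nanmean(cmap.values[r], axis=0)
            mean_c = float(np.nanmean(gm[res.sig_mask])) if res.sig_mask.any() else None
            summary[study][name] = {
                "n_significant_clusters": res.n_significant,
                "mean_C_in_significant_cells": mean_c,
            }
            print(
                f"[{study}/{name}] {res.n_significant} significant cluster(s), "
                f"mean C in significant cells: {mean_c}"
            )
    tio.write_json(ROOT / "results" / "commonality.json", summary)


if __name__ == "__main__":
    main()
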