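#!/usr/bin/env python
"""Exclusions and group-mean trajectories for both simulated studies.

Applies the trial rules (at least 100 ms of recorded cursor data, at least
50 px of movement), scores trials by the final cursor side, removes
participants below 70% accuracy, mirrors every trial into the common
decision frame (face/animal-ward positive), interpolates to the 1 ms grid
and averages within then across participants.  Writes the exclusion report
to results/ and the mean-trajectory container to scratch/.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import trajrsa as T
from trajrsa import io as tio

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    for study in ("face", "animal"):
        sim = ROOT / "scratch" / f"sim_{study}"
        stimuli = T.StimulusSet.from_csv(sim / "stimuli.csv")
        trials = T.load_trials(sim / "trials.csv")
        kept, trial_report = T.filter_trials(trials)
        kept, part_report = T.filter_participants(kept)
        acc = float(np.mean([T.score_trial(t) for t in kept]))
        means = T.average_trajectories(T.mirror_to_canonical(kept, stimuli), stimuli)
        tio.save_means(sim / "means.h5", means)
        report = {
            "trials": trial_report.to_dict(),
            "participants": part_report.to_dict(),
            "group_accuracy_retained": acc,
        }
        (ROOT / "results").mkdir(exist_ok=True)
        tio.write_json(ROOT / "results" / f"exclusions_{study}.json", report)
        print(
            f"[{study}] trials {trial_report.n_input} -> "
            f"{trial_report.n_input - trial_report.n_removed} retained; "
            f"participants {part_report.n_input} -> "
            f"{part_report.n_input - part_report.n_low_accuracy - part_report.n_zero_trials}; "
            f"retained-group accuracy {acc:.3f}"
        )


if __name__ == "__main__":
    main()
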