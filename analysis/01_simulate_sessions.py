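#!/usr/bin/env python
"""Simulate one session of each paradigm and log the drawn ground truth.

Writes the three recordings (HDF5 fixture format) and per-trial truth tables
under results/sessions/. The offline session uses the full published design
(9 runs x 40 trials, 72 per class); the online sessions use the published
training design (5 x 30 + 4 rest runs) and a session-1-sized test design.
"""

import argparse
import os

import pandas as pd

from mrcpkit.io import write_recording
from mrcpkit.synth import (
    ParadigmConfig,
    generate_offline_session,
    generate_online_test_session,
    generate_online_training_session,
    online_template_params,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/sessions")
    args = ap.parse_args()
    os.makedirs(args.out, exist_ok=True)

    offline = ParadigmConfig(paradigm="offline", runs=9, trials_per_run=40,
                             seed=args.seed)
    rec, truth = generate_offline_session(offline)
    write_recording(rec, os.path.join(args.out, "offline.h5"))
    pd.DataFrame(truth.trials).to_csv(
        os.path.join(args.out, "offline_truth.csv"), index=False
    )
    labels = [t["class"] for t in truth.trials]
    print(f"offline: {len(labels)} trials, "
          f"{min(labels.count(c) for c in set(labels))} per class, "
          f"{rec.duration/60:.1f} min")

    training = ParadigmConfig(
        paradigm="online_training", runs=5, trials_per_run=30,
        classes=("hand_open", "palmar_grasp"), rest_runs=4, seed=args.seed + 1,
    )
    rec, truth = generate_online_training_session(
        training, online_template_params()
    )
    write_recording(rec, os.path.join(args.out, "online_training.h5"))
    pd.DataFrame(truth.trials).to_csv(
        os.path.join(args.out, "online_training_truth.csv"), index=False
    )
    move = [t for t in truth.trials if t["class"] != "rest"]
    print(f"online training: {len(move)} movement trials, "
          f"{len(truth.trials) - len(move)} rest runs, {rec.duration/60:.1f} min")

    test = ParadigmConfig(
        paradigm="online_test", runs=6, classes=("hand_open", "palmar_grasp"),
        movement_trials_per_run=4, rest_trials_per_run=1, seed=args.seed + 2,
    )
    rec, truth = generate_online_test_session(test, online_template_params())
    write_recording(rec, os.path.join(args.out, "online_test.h5"))
    pd.DataFrame(truth.attempts).to_csv(
        os.path.join(args.out, "online_test_attempts.csv"), index=False
    )
    print(f"online test: {len(truth.attempts)} self-paced attempts in "
          f"{len(truth.trials)} trials, {rec.duration/60:.1f} min")


if __name__ == "__main__":
    main()
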