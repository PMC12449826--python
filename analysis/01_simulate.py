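"""Simulate a demonstration cohort of synthetic walkers.

Writes per-trial measurement streams (gaze.csv, detections.csv,
truth_poses.csv, meta.yaml) for 3 participants x 16 trials (one pass
through every configuration) under results/simulated/. The full study
design (10 participants x 80 trials) is exercised by the test suite; this
script keeps the on-disk demo small.

Run from the repository root:  python analysis/01_simulate.py [seed]
"""

import sys
from pathlib import Path

import numpy as np

from gazewalk import io
from gazewalk.design import make_schedule
from gazewalk.simulate import WalkerProfile, simulate_trial

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/simulated")

N_PARTICIPANTS = 3
N_TRIALS = 16


def main() -> None:
    ss = np.random.SeedSequence(SEED)
    io.write_manifest(OUT, {"seed": SEED, "participants": N_PARTICIPANTS,
                            "trials": N_TRIALS})
    for p, child in enumerate(ss.spawn(N_PARTICIPANTS)):
        pseed = int(child.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(pseed)
        profile = WalkerProfile(eye_height=float(rng.uniform(149, 182)),
                                walking_speed=float(rng.uniform(95, 130)))
        schedule = make_schedule(seed=pseed)
        for idx, cfg in schedule.trials[:N_TRIALS]:
            tseed = int(np.random.SeedSequence([pseed, idx]).generate_state(1)[0] % (2**31))
            trial = simulate_trial(cfg, profile, seed=tseed)
            io.write_trial(trial, OUT / f"p{p:02d}" / f"t{idx:03d}")
        print(f"participant {p}: eye height {profile.eye_height:.0f} cm, "
              f"{N_TRIALS} trials written")
    print(f"simulated cohort in {OUT}")


if __name__ == "__main__":
    main()
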