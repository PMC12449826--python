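"""End-to-end orchestration: simulate participants, run the analysis
chain (plausibility filtering, localization, smoothing, gaze resampling,
classification), and aggregate occupancy curves, floor-looking fractions
and the factorial ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classification, detection, floormap, localization, stats
from .design import FACTORS, make_schedule
from .geometry import CameraModel, RoomLayout
from .simulate import (
    GazeScript,
    NoiseModel,
    SimulatedTrial,
    WalkerProfile,
    default_script,
    simulate_trial,
)

__all__ = ["TrialResult", "analyze_trial", "run_participant", "run_experiment",
           "ExperimentResult"]


@dataclass
class TrialResult:
    trial_index: int
    config: object
    detections: pd.DataFrame  # plausibility-filtered
    track: pd.DataFrame  # estimated + smoothed poses
    frame_gaze: pd.DataFrame
    classified: pd.DataFrame
    floor_fraction: float
    n_window_frames: int


def analyze_trial(trial: SimulatedTrial, eye_height: float,
                  layout: RoomLayout = RoomLayout(),
                  camera: CameraModel = CameraModel(),
                  config_known: bool = True) -> TrialResult:
    """Run the full analysis chain on one (simulated) trial.

    Symbolic detection mode: the simulator's detection stream is passed
    through the plausibility filter, then each frame's pose is estimated
    from the surviving cup rays and the known placements, the track is
    smoothed, gaze is resampled at frame times, and every frame is
    categorized.
    """
    cfg = trial.config if config_known else None
    filtered = detection.filter_trial(trial.detections, cfg)
    poses_est = localization.estimate_trial_poses(
        filtered, trial.placements, eye_height, camera, layout)
    track = localization.smooth_track(poses_est, layout=layout)
    frame_gaze = localization.resample_gaze(
        trial.gaze_measured, track.t_s.to_numpy())
    classified = classification.classify_trial(
        frame_gaze, track, filtered, trial.placements,
        gaze_raw=trial.gaze_measured, camera=camera)
    frac, n_win = stats.floor_fraction(classified, track, layout)
    return TrialResult(-1, trial.config, filtered, track, frame_gaze,
                       classified, frac, n_win)


def run_participant(participant: int, seed: int, n_trials: int | None = None,
                    profile: WalkerProfile | None = None,
                    script: GazeScript | None = None,
                    noise: NoiseModel | None = None,
                    layout: RoomLayout = RoomLayout(),
                    camera: CameraModel = CameraModel(),
                    reps: int = 5) -> list[TrialResult]:
    """Simulate and analyze one participant's randomized schedule."""
    rng = np.random.default_rng(seed)
    if profile is None:
        # per-participant walking style, eye height within the study's range
        profile = WalkerProfile(
            eye_height=float(rng.uniform(149, 182)),
            walking_speed=float(rng.uniform(95, 130)),
        )
    schedule = make_schedule(seed=seed, reps=reps)
    trials = schedule.trials if n_trials is None else schedule.trials[:n_trials]
    results = []
    for idx, config in trials:
        trial_seed = int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))
        trial = simulate_trial(config, profile, script, noise, layout, camera,
                               seed=trial_seed)
        res = analyze_trial(trial, profile.eye_height, layout, camera)
        res.trial_index = idx
        results.append(res)
    return results


@dataclass
class ExperimentResult:
    occupancy: pd.DataFrame
    floor_fractions: pd.DataFrame  # per trial
    cell_table: pd.DataFrame  # participant x configuration
    anova: stats.AnovaResult | None
    trials: list[list[TrialResult]] = field(default_factory=list)


def run_experiment(n_participants: int = 10, seed: int = 0,
                   n_trials: int | None = None,
                   script: GazeScript | None = None,
                   noise: NoiseModel | None = None,
                   layout: RoomLayout = RoomLayout(),
                   camera: CameraModel = CameraModel(),
                   keep_trials: bool = False) -> ExperimentResult:
    """Simulate and analyze a whole experiment.

    Defaults reproduce the study design: 10 participants, 80 trials each
    (16 configurations x 5 repetitions) in seeded random order.
    """
    ss = np.random.SeedSequence(seed)
    part_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_participants)]
    all_classified, pids, rows = [], [], []
    all_trials = []
    for p, pseed in enumerate(part_seeds):
        results = run_participant(p, pseed, n_trials, script=script, noise=noise,
                                  layout=layout, camera=camera)
        for r in results:
            all_classified.append(r.classified)
            pids.append(p)
            rows.append({"participant": p, "trial_index": r.trial_index,
                         **dict(zip(FACTORS, r.config.as_tuple())),
                         "fraction": r.floor_fraction, "n_frames": r.n_window_frames})
        if keep_trials:
            all_trials.append(results)

    occupancy = floormap.occupancy_by_distance(all_classified, participant_ids=pids)
    fractions = pd.DataFrame(rows)
    cell_table = stats.floor_fraction_table(fractions)
    anova = (stats.rm_anova_2x2x2x2(cell_table)
             if n_participants >= 2 and (n_trials is None or n_trials >= 16) else None)
    return ExperimentResult(occupancy, fractions, cell_table, anova, all_trials)
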