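"""Analyze the simulated cohort: plausibility-filter the detections,
localize the walker each frame, smooth the track, resample gaze at frame
times, and categorize every frame.

Reads results/simulated/ (from 01_simulate.py), writes per-trial
poses_est.csv / track.csv / categories.csv / floor_gaze.csv under
results/analyzed/, and prints a per-participant summary of localization
quality against the simulator's ground truth.

Run from the repository root:  python analysis/02_localize_and_classify.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gazewalk import classification, detection, floormap, io, localization
from gazewalk.geometry import CameraModel, RoomLayout, place_cups

IN = Path("results/simulated")
OUT = Path("results/analyzed")


def main() -> None:
    layout, camera = RoomLayout(), CameraModel()
    for pdir in sorted(IN.glob("p*")):
        errs, ok_frames, all_frames = [], 0, 0
        for tdir in sorted(pdir.glob("t*")):
            cfg, gaze, dets, meta = io.read_trial_inputs(tdir)
            placements = place_cups(cfg, layout)
            filtered = detection.filter_trial(dets, cfg)
            poses = localization.estimate_trial_poses(
                filtered, placements, meta["eye_height"], camera, layout)
            track = localization.smooth_track(poses, layout=layout)
            frame_gaze = localization.resample_gaze(gaze, track.t_s.to_numpy())
            classified = classification.classify_trial(
                frame_gaze, track, filtered, placements, gaze_raw=gaze, camera=camera)
            floor = floormap.map_floor_gaze(classified, track)

            odir = OUT / pdir.name / tdir.name
            odir.mkdir(parents=True, exist_ok=True)
            poses.to_csv(odir / "poses_est.csv", index=False)
            track.to_csv(odir / "track.csv", index=False)
            classified.to_csv(odir / "categories.csv", index=False)
            floor.to_csv(odir / "floor_gaze.csv", index=False)
            (odir / "meta.yaml").write_text((tdir / "meta.yaml").read_text())

            truth = pd.read_csv(tdir / "truth_poses.csv")
            m = (track.status == "ok").to_numpy()
            n = min(len(track), len(truth))
            err = np.hypot(track.x_cm.to_numpy()[:n][m[:n]] - truth.x_cm.to_numpy()[:n][m[:n]],
                           track.y_cm.to_numpy()[:n][m[:n]] - truth.y_cm.to_numpy()[:n][m[:n]])
            errs.append(np.median(err))
            ok_frames += int(m.sum())
            all_frames += len(track)
        print(f"{pdir.name}: median localization error "
              f"{np.median(errs):.2f} cm on {ok_frames}/{all_frames} reliable frames")
    print(f"analysis written to {OUT}")


if __name__ == "__main__":
    main()
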