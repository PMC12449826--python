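"""Reading and writing the pipeline's on-disk dialect.

A simulated experiment is a directory tree::

    out/
      manifest.yaml
      p00/
        t000/
          meta.yaml           # configuration, seeds, profile, noise
          gaze.csv            # t_s, az_deg, el_deg, valid
          detections.csv      # frame, t_s, cup_id, az_deg, el_deg
          truth_poses.csv     # t_s, x_cm, y_cm, eye_h_cm, yaw_deg, pitch_deg
          frames/*.png        # only when rendering is on

Analysis outputs (poses_est.csv, categories.csv, occupancy.csv,
floor_fractions.csv, anova.csv) use the column layouts documented on the
functions that produce them.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .design import FACTORS, Configuration
from .simulate import SimulatedTrial

__all__ = ["write_trial", "read_trial_inputs", "write_manifest"]


def write_trial(trial: SimulatedTrial, out_dir: str | Path,
                write_truth: bool = True) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trial.gaze_measured.to_csv(out / "gaze.csv", index=False)
    (trial.detections.drop(columns=["is_false_positive"], errors="ignore")
     .to_csv(out / "detections.csv", index=False))
    if write_truth:
        trial.true_poses.to_csv(out / "truth_poses.csv", index=False)
        trial.gaze_truth.to_csv(out / "gaze_truth.csv", index=False)
    meta = {"config": dict(zip(FACTORS, trial.config.as_tuple())), **trial.meta}
    (out / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    return out


def read_trial_inputs(trial_dir: str | Path):
    """Read back the measurement streams of a written trial.

    Returns ``(config, gaze, detections, meta)``.
    """
    d = Path(trial_dir)
    meta = yaml.safe_load((d / "meta.yaml").read_text())
    config = Configuration(**meta["config"])
    gaze = pd.read_csv(d / "gaze.csv")
    detections = pd.read_csv(d / "detections.csv")
    return config, gaze, detections, meta


def write_manifest(out_dir: str | Path, params: dict) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    clean = {k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
             for k, v in params.items()}
    path = out / "manifest.yaml"
    path.write_text(yaml.safe_dump(clean, sort_keys=False))
    return path
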