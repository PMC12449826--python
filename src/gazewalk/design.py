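"""Factorial trial design: the 16 item configurations and randomized
80-trial schedules.

Four two-level factors define a configuration: the side of the near floor
obstacle (turquoise cup), the far floor obstacle (yellow cup), the table
obstacle (red cup), and the destination cup (purple cup).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Configuration", "TrialSchedule", "enumerate_configurations", "make_schedule"]

SIDES = ("left", "right")
FACTORS = ("near_floor_side", "far_floor_side", "table_obstacle_side", "destination_side")


@dataclass(frozen=True, order=True)
class Configuration:
    near_floor_side: str
    far_floor_side: str
    table_obstacle_side: str
    destination_side: str

    def __post_init__(self) -> None:
        for f in FACTORS:
            if getattr(self, f) not in SIDES:
                raise ValueError(f"{f} must be 'left' or 'right'")

    def as_tuple(self) -> tuple[str, str, str, str]:
        return tuple(getattr(self, f) for f in FACTORS)  # type: ignore[return-value]

    @property
    def label(self) -> str:
        return "".join(s[0].upper() for s in self.as_tuple())


@dataclass(frozen=True)
class TrialSchedule:
    trials: tuple[tuple[int, Configuration], ...]
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"trial_index": i, **dict(zip(FACTORS, c.as_tuple())), "seed": self.seed}
            for i, c in self.trials
        ]
        return pd.DataFrame(rows)


def enumerate_configurations() -> list[Configuration]:
    """All 16 configurations in lexicographic order (left < right) over the
    four factors, near-floor varying slowest."""
    return [Configuration(*combo) for combo in itertools.product(SIDES, repeat=4)]


def make_schedule(seed: int, reps: int = 5) -> TrialSchedule:
    """Seeded uniform shuffle of ``reps`` copies of each configuration.

    A Fisher-Yates shuffle driven by ``numpy.random.default_rng(seed)``;
    the same seed always yields the same schedule.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    configs = enumerate_configurations() * reps
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(configs))
    trials = tuple((i, configs[j]) for i, j in enumerate(order))
    return TrialSchedule(trials=trials, seed=seed)
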