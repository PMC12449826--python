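"""Floor-looking-time fractions and the 2x2x2x2 repeated-measures ANOVA.

The behavioral window runs from 1 m before entering the room (smoothed
depth y = -100 cm) until the walker crosses the first floor obstacle
(smoothed y first exceeding the near-obstacle depth, 140 cm). Within that
window the fraction of frames spent looking at the floor or the floor
cups is the dependent variable; one cell per participant per
configuration (mean over that configuration's trials) enters a
within-subject factorial ANOVA over the four two-level side factors.

With two-level factors every effect is a single orthogonal contrast per
participant, so each F test has (1, n-1) degrees of freedom and equals
the square of the paired t statistic on that contrast; no sphericity
correction is needed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .design import FACTORS
from .floormap import FLOOR_GROUP
from .geometry import RoomLayout

__all__ = ["floor_fraction", "floor_fraction_table", "rm_anova_2x2x2x2",
           "AnovaResult", "EFFECTS"]

#: the 15 effects of the 2^4 within design, in main -> interaction order
EFFECTS: list[tuple[str, ...]] = [
    combo
    for k in (1, 2, 3, 4)
    for combo in itertools.combinations(FACTORS, k)
]


def floor_fraction(classified: pd.DataFrame, track: pd.DataFrame,
                   layout: RoomLayout = RoomLayout(),
                   window_y_cm: tuple[float, float] | None = None,
                   include_invalid: bool = True) -> tuple[float, int]:
    """Fraction of in-window time spent looking at the floor group.

    The window is defined on the smoothed track: from y = -100 cm until
    the first frame where y exceeds the near floor obstacle's depth.
    Numerator: frames categorized floor/turquoise/yellow. Denominator: all
    in-window frames (including blink/none by default; set
    ``include_invalid=False`` to restrict to frames with a category other
    than blink/none). Returns ``(fraction, n_frames)``; a trial without
    in-window frames yields ``(nan, 0)``.
    """
    if window_y_cm is None:
        window_y_cm = (-100.0, layout.floor_obstacle_depths[0])
    y_by_frame = track.set_index("frame")["y_s_cm"] if "frame" in track else track["y_s_cm"]
    y = classified.frame.map(y_by_frame)

    y_track = track["y_s_cm"].to_numpy(dtype=float)
    crossed = np.flatnonzero(y_track > window_y_cm[1])
    t_cross = track.t_s.iloc[crossed[0]] if crossed.size else np.inf

    in_window = (y >= window_y_cm[0]) & (classified.t_s < t_cross) & y.notna()
    sel = classified[in_window]
    if not include_invalid:
        sel = sel[~sel.category.isin(["blink", "none"])]
    if len(sel) == 0:
        return float("nan"), 0
    frac = sel.category.isin(FLOOR_GROUP).mean()
    return float(frac), int(len(sel))


def floor_fraction_table(records: pd.DataFrame) -> pd.DataFrame:
    """Participant x configuration table of floor-looking fractions.

    ``records`` holds one row per trial: columns ``participant``, the
    four factor columns, and ``fraction``. Cells are per-configuration
    means over trials; missing cells are imputed with the participant's
    overall mean (with a warning). Returns a long-format table with one
    row per participant per configuration.
    """
    cells = (records.dropna(subset=["fraction"])
             .groupby(["participant", *FACTORS], as_index=False)["fraction"].mean())
    participants = sorted(records.participant.unique())
    full = pd.MultiIndex.from_product(
        [participants, *[["left", "right"]] * 4], names=["participant", *FACTORS])
    cells = cells.set_index(["participant", *FACTORS]).reindex(full)
    if cells.fraction.isna().any():
        warnings.warn("missing cells imputed with the participant mean")
        part_means = cells.groupby(level="participant").fraction.transform("mean")
        cells["fraction"] = cells.fraction.fillna(part_means)
    return cells.reset_index()


@dataclass
class AnovaResult:
    table: pd.DataFrame  # effect, F, df1, df2, p
    contrasts: pd.DataFrame  # per-participant contrast values per effect

    def effect(self, *factors: str) -> pd.Series:
        name = ":".join(factors)
        return self.table.set_index("effect").loc[name]


def _contrast_codes() -> np.ndarray:
    """(16 cells, 15 effects) +/-1 coding; cells in lexicographic factor
    order with left = -1, right = +1."""
    cells = list(itertools.product((-1.0, 1.0), repeat=4))
    codes = np.empty((16, len(EFFECTS)))
    for j, eff in enumerate(EFFECTS):
        cols = [FACTORS.index(f) for f in eff]
        for i, cell in enumerate(cells):
            codes[i, j] = np.prod([cell[c] for c in cols])
    return codes


_CODES = _contrast_codes()


def rm_anova_2x2x2x2(table: pd.DataFrame) -> AnovaResult:
    """Repeated-measures ANOVA over the four two-level side factors.

    ``table`` is the long-format output of :func:`floor_fraction_table`.
    For each effect the per-participant contrast is the +/-1-coded mean
    over the 16 cells; then F = n * mean(contrast)^2 / var(contrast) with
    df (1, n-1) and an upper-tail p from the F distribution. An effect
    with zero contrast variance (and zero mean) is reported as F = 0 with
    a warning.
    """
    participants = sorted(table.participant.unique())
    n = len(participants)
    if n < 2:
        raise ValueError("need at least 2 participants")
    wide = (table.sort_values(["participant", *FACTORS])
            .pivot_table(index="participant", values="fraction",
                         columns=list(FACTORS), sort=True))
    # columns are now lexicographic over factors, matching _CODES row order
    data = wide.to_numpy()  # (n, 16)
    if data.shape[1] != 16 or np.isnan(data).any():
        raise ValueError("table must be complete: 16 cells per participant")
    contrasts = data @ _CODES / 16.0  # (n, 15)

    mean_c = contrasts.mean(axis=0)
    var_c = contrasts.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = n * mean_c**2 / var_c
    # contrasts that vanish to rounding error: no effect and no variance
    scale = max(np.abs(data).max(), 1.0)
    zero = var_c < (1e-12 * scale) ** 2
    if zero.any():
        warnings.warn("effect(s) with zero contrast variance reported as F = 0")
        F = np.where(zero & (np.abs(mean_c) < 1e-12 * scale), 0.0, F)
        F = np.where(zero & (np.abs(mean_c) >= 1e-12 * scale), np.inf, F)
    p = sstats.f.sf(F, 1, n - 1)

    names = [":".join(e) for e in EFFECTS]
    tab = pd.DataFrame({"effect": names, "F": F, "df1": 1, "df2": n - 1, "p": p})
    con = pd.DataFrame(contrasts, columns=names,
                       index=pd.Index(participants, name="participant"))
    return AnovaResult(tab, con)


def null_rejection_rates(n_participants: int = 10, n_reps: int = 2000,
                         alpha: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Type-I error of each effect under independent Gaussian cell noise.

    Vectorized over replicates; returns per-effect rejection rates at
    ``alpha``. Used to check the ANOVA's calibration.
    """
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_reps, n_participants, 16))
    contrasts = data @ _CODES / 16.0  # (reps, n, 15)
    mean_c = contrasts.mean(axis=1)
    var_c = contrasts.var(axis=1, ddof=1)
    F = n_participants * mean_c**2 / var_c
    crit = sstats.f.isf(alpha, 1, n_participants - 1)
    rates = (F > crit).mean(axis=0)
    return pd.DataFrame({"effect": [":".join(e) for e in EFFECTS], "rate": rates})
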