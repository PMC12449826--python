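"""Floor-looking-time fractions per configuration and the 2x2x2x2
repeated-measures ANOVA.

Reads results/analyzed/ (from 02_localize_and_classify.py), computes per
trial the fraction of time spent looking at the floor group between 1 m
before entering the room and crossing the first obstacle, builds the
participant x configuration cell table, runs the within-subject factorial
ANOVA over the four side factors, and writes floor_fractions.csv,
anova.csv and the per-configuration bar figure under results/.

Run from the repository root:  python analysis/05_floor_time_anova.py
"""

from pathlib import Path

import pandas as pd
import yaml

from gazewalk import plots, stats
from gazewalk.geometry import RoomLayout

IN = Path("results/analyzed")
OUT = Path("results")


def main() -> None:
    layout = RoomLayout()
    rows = []
    for pdir in sorted(IN.glob("p*")):
        p = int(pdir.name[1:])
        for tdir in sorted(pdir.glob("t*")):
            cats = pd.read_csv(tdir / "categories.csv")
            track = pd.read_csv(tdir / "track.csv")
            meta = yaml.safe_load((tdir / "meta.yaml").read_text())
            frac, n = stats.floor_fraction(cats, track, layout)
            rows.append({"participant": p, "trial_index": int(tdir.name[1:]),
                         **meta["config"], "fraction": frac, "n_frames": n})
    fractions = pd.DataFrame(rows)
    fractions.to_csv(OUT / "floor_fractions.csv", index=False)
    print(f"mean floor-looking fraction in the window: "
          f"{fractions.fraction.mean():.3f} over {len(fractions)} trials")

    cells = stats.floor_fraction_table(fractions)
    result = stats.rm_anova_2x2x2x2(cells)
    result.table.to_csv(OUT / "anova.csv", index=False)
    plots.plot_floor_fraction_bars(cells, str(OUT / "floor_bars.png"))
    print("\nwithin-subject ANOVA (each effect F(1, n-1)):")
    print(result.table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))


if __name__ == "__main__":
    main()
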