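#!/usr/bin/env python
"""Entropy-weight scoring of the synthetic panel.

Reads the panel written by 01_simulate.py, normalizes per year, computes
per-year entropy weights (per-system scope) and the three system scores
U_EC / U_SO / U_HE plus the eight subsystem condition values.
"""

from pathlib import Path

from regioncoord.entropy_scoring import score_panel
from regioncoord.panel_io import read_panel, read_region_groups

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main():
    regions = read_region_groups(OUT / "regions.csv")
    panel = read_panel(OUT / "panel.csv", regions=regions)
    norm, wset, scores = score_panel(panel)
    wset.table().to_csv(OUT / "weights.csv", index=False)
    scores.table().to_csv(OUT / "scores.csv", index=False)

    wtab = wset.table()
    top = (wtab.groupby("indicator")["weight"].mean()
           .sort_values(ascending=False).head(3))
    print(f"scored {panel.n_counties} counties over {panel.years}")
    print("highest mean entropy weights:")
    for ind, w in top.items():
        print(f"  {ind}: {w:.3f}")
    print(f"wrote {OUT/'weights.csv'} and {OUT/'scores.csv'}")


if __name__ == "__main__":
    main()
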