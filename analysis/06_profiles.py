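"""QoL-quantile compositional profiles per year.

Groups each wave's children into QoL quartiles and expresses every group's
compositional mean relative to the wave's overall compositional mean as
per-behaviour log-ratios (positive = the group spends relatively more time
on the behaviour than the wave overall).  Writes results/profiles.csv.
"""

from pathlib import Path

import pandas as pd

from codaqol.coda import CompositionSet
from codaqol.profiles import assign_quantiles, group_logratio_profile

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    df = pd.read_csv(RESULTS / "cleaned.csv")
    frames = []
    for year in sorted(df["year"].unique()):
        sub = df[df["year"] == year]
        grouping = assign_quantiles(sub["qol_total"].to_numpy(), k=4)
        cs = CompositionSet(sub[["pa_hours", "sb_hours", "sl_hours"]].to_numpy())
        prof = group_logratio_profile(cs, grouping)
        prof.insert(0, "year", year)
        frames.append(prof)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(RESULTS / "profiles.csv", index=False)
    top_vs_bottom = (
        out[out["quantile"] == 4].set_index(["year", "part"])["log_ratio"]
        - out[out["quantile"] == 1].set_index(["year", "part"])["log_ratio"]
    )
    print("log-ratio gap, top QoL quartile minus bottom (positive = more time):")
    print(top_vs_bottom.unstack().round(3).to_string())


if __name__ == "__main__":
    main()
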