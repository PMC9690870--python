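"""Record cleaning: behaviour aggregation, plausibility filters, imputation.

Raw survey records report time per named activity (chores, indoor play,
outdoor play, screen use, reading, naps, night sleep, ...).  These are
summed into the three 24-hour movement behaviours:

* PA - physical activity (chores, indoor play, outdoor play),
* SB - sedentary behaviour (screen and non-screen sitting activities),
* SL - sleep (naps plus night-time sleep).

Sleep acts as the anchor for plausibility filtering: records whose sleep
falls outside an age-appropriate range, or whose behaviour total exceeds a
daily budget, are dropped with a logged reason.  The exact thresholds are
configurable because published surveys vary; the defaults follow the common
guideline bands (11-14 h including naps for ages 1-2, 10-13 h for ages 3-5).

Missing demographics and QoL are singly imputed: QoL by the mean of the same
integer-age group, age by the overall mean, sex by the mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_ACTIVITY_MAP: dict[str, str] = {
    "chores_hours": "PA",
    "indoor_play_hours": "PA",
    "outdoor_play_hours": "PA",
    "screen_learning_hours": "SB",
    "screen_entertainment_hours": "SB",
    "reading_hours": "SB",
    "crafts_hours": "SB",
    "nap_hours": "SL",
    "night_sleep_hours": "SL",
}

# (age_min_inclusive, age_max_exclusive) -> (sleep_min, sleep_max) hours
DEFAULT_SLEEP_RANGES: dict[tuple[float, float], tuple[float, float]] = {
    (0.0, 3.0): (11.0, 14.0),
    (3.0, 7.0): (10.0, 13.0),
}


@dataclass
class CleaningConfig:
    activity_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVITY_MAP)
    )
    sleep_ranges: dict[tuple[float, float], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SLEEP_RANGES)
    )
    max_total_hours: float = 24.0
    epsilon_hours: float = 0.25  # zero-replacement amount, 15 min
    missing_warn_fraction: float = 0.05

    def __post_init__(self) -> None:
        for (lo, hi), (smin, smax) in self.sleep_ranges.items():
            if not (lo < hi and smin < smax):
                raise ValueError("malformed sleep range configuration")
        for target in self.activity_map.values():
            if target not in ("PA", "SB", "SL", "ignore"):
                raise ValueError(f"activity must map to PA/SB/SL/ignore, got {target}")

    def sleep_range_for_age(self, age: float) -> tuple[float, float] | None:
        for (lo, hi), rng in self.sleep_ranges.items():
            if lo <= age < hi:
                return rng
        return None


def aggregate_behaviours(
    df: pd.DataFrame, mapping: dict[str, str] | None = None
) -> pd.DataFrame:
    """Sum raw activity columns into pa_hours, sb_hours, sl_hours.

    Every column ending in ``_hours`` (other than the outputs) must be
    covered by the mapping or explicitly mapped to ``"ignore"``.
    """
    mapping = dict(DEFAULT_ACTIVITY_MAP) if mapping is None else mapping
    duration_cols = [
        c
        for c in df.columns
        if c.endswith("_hours") and c not in ("pa_hours", "sb_hours", "sl_hours")
    ]
    unmapped = [c for c in duration_cols if c not in mapping]
    if unmapped:
        raise KeyError(f"activity columns not covered by mapping: {unmapped}")
    out = df.copy()
    for behaviour, col in (("PA", "pa_hours"), ("SB", "sb_hours"), ("SL", "sl_hours")):
        sources = [c for c in duration_cols if mapping[c] == behaviour]
        out[col] = df[sources].sum(axis=1) if sources else 0.0
    return out


def filter_records(
    df: pd.DataFrame, config: CleaningConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply plausibility filters; return (retained, rejection log).

    Rules, in order of precedence per record:

    * ``sleep_range`` - sleep outside the age band's plausible range;
    * ``total_budget`` - PA+SB+SL exceeding the daily maximum;
    * ``nonpositive_total`` - no recorded time at all.

    The rejection log has columns ``id`` and ``rule``.  Retained records are
    returned unmodified.  The retention percentage is attached as
    ``retained.attrs["retention_pct"]``.
    """
    config = config or CleaningConfig()
    rules = []
    for _, row in df.iterrows():
        total = row["pa_hours"] + row["sb_hours"] + row["sl_hours"]
        rule = None
        rng = (
            config.sleep_range_for_age(float(row["age_years"]))
            if not pd.isna(row.get("age_years", np.nan))
            else None
        )
        if total <= 0:
            rule = "nonpositive_total"
        elif rng is not None and not (rng[0] <= row["sl_hours"] <= rng[1]):
            rule = "sleep_range"
        elif total > config.max_total_hours:
            rule = "total_budget"
        rules.append(rule)
    rules = pd.Series(rules, index=df.index, dtype=object)
    keep = rules.isna()
    retained = df.loc[keep].copy()
    rejected = pd.DataFrame(
        {"id": df.loc[~keep, "id"].to_numpy(), "rule": rules[~keep].to_numpy()}
    )
    retained.attrs["retention_pct"] = 100.0 * keep.sum() / len(df) if len(df) else 100.0
    return retained, rejected


def impute_missing(
    df: pd.DataFrame,
    qol_col: str = "qol_total",
    config: CleaningConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Single imputation of missing QoL, age and sex; returns (data, log).

    * QoL: mean of records sharing the same integer age (floor years);
      an age group with no observed QoL falls back to the overall mean.
    * Age: overall mean age.
    * Sex: modal category, ties broken by first occurrence in the data.

    Non-missing cells are untouched and re-running is a no-op.  A warning is
    emitted when any field is missing in more than the configured fraction
    of records (default 5%).
    """
    config = config or CleaningConfig()
    out = df.copy()
    log: dict[str, int] = {"qol": 0, "age": 0, "sex": 0, "qol_fallback": 0}

    n = len(out)
    import warnings

    for fieldname, col in (("qol", qol_col), ("age", "age_years"), ("sex", "sex")):
        if col in out.columns and n:
            frac = out[col].isna().mean()
            if frac >= config.missing_warn_fraction:
                warnings.warn(
                    f"{fieldname} missing in {100 * frac:.1f}% of records "
                    f"(expected < {100 * config.missing_warn_fraction:.0f}%)"
                )

    # age first: QoL group imputation needs an age for every record
    if "age_years" in out.columns:
        miss_age = out["age_years"].isna()
        if miss_age.any():
            out.loc[miss_age, "age_years"] = out["age_years"].mean()
            log["age"] = int(miss_age.sum())

    if "sex" in out.columns:
        miss_sex = out["sex"].isna()
        if miss_sex.any():
            observed = out.loc[~miss_sex, "sex"]
            counts = observed.value_counts()
            top = counts.max()
            # ties: first-observed category among the modal ones
            modal = next(v for v in observed if counts[v] == top)
            out.loc[miss_sex, "sex"] = modal
            log["sex"] = int(miss_sex.sum())

    if qol_col in out.columns:
        miss_q = out[qol_col].isna()
        if miss_q.any():
            age_group = np.floor(out["age_years"].to_numpy(dtype=float)).astype(int)
            overall = out.loc[~miss_q, qol_col].mean()
            group_means = (
                out.loc[~miss_q, qol_col].groupby(age_group[~miss_q.to_numpy()]).mean()
            )
            for idx in out.index[miss_q]:
                g = int(math.floor(out.at[idx, "age_years"]))
                if g in group_means.index:
                    out.at[idx, qol_col] = group_means[g]
                else:
                    out.at[idx, qol_col] = overall
                    log["qol_fallback"] += 1
            log["qol"] = int(miss_q.sum())

    return out, log
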