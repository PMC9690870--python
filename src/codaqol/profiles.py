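"""Quantile-group compositional profiles.

Children are grouped into k quantile bands of the QoL score, and each
group's compositional mean is expressed relative to the overall
compositional mean as per-part log-ratios

    ln( m_{g,p} / m_{all,p} )

so a positive value means the group spends relatively more time on that
behaviour than the sample as a whole.  The pooled sample profiles to zeros
by construction, and the values are invariant to the closure constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coda import CompositionSet, compositional_mean


@dataclass(frozen=True)
class QuantileGrouping:
    k: int
    assignment: np.ndarray  # group index in 0..k-1 per record
    cut_points: np.ndarray  # k-1 interior sample quantiles


def assign_quantiles(scores, k: int = 4) -> QuantileGrouping:
    """Assign each score to one of k quantile groups.

    Cut points are the i/k sample quantiles (linear interpolation between
    order statistics).  A score equal to a cut point goes to the lower
    group, deterministically.
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim != 1:
        raise ValueError("scores must be one-dimensional")
    if np.isnan(s).any():
        raise ValueError("scores must not contain missing values")
    if len(s) < k:
        raise ValueError(f"need at least k={k} scores, got {len(s)}")
    cuts = np.quantile(s, np.arange(1, k) / k, method="linear")
    # count of cut points strictly below the score -> ties fall to the lower group
    assignment = np.searchsorted(cuts, s, side="left")
    if len(np.unique(assignment)) == 1 and k > 1:
        warnings.warn("all records fall in one quantile group (tied scores)")
    return QuantileGrouping(k=k, assignment=assignment, cut_points=cuts)


def group_logratio_profile(
    data: CompositionSet, grouping: QuantileGrouping
) -> pd.DataFrame:
    """Per-group, per-part log-ratio of group mean to overall mean.

    Returns a frame with columns ``quantile`` (1-based), ``part``,
    ``log_ratio`` and ``n``; empty groups yield NaN rows with a warning.
    """
    if len(grouping.assignment) != len(data):
        raise ValueError("grouping does not cover the composition set")
    overall = compositional_mean(data)
    rows = []
    for g in range(grouping.k):
        mask = grouping.assignment == g
        if not mask.any():
            warnings.warn(f"quantile group {g + 1} is empty")
            for p in data.labels:
                rows.append(
                    {"quantile": g + 1, "part": p, "log_ratio": float("nan"), "n": 0}
                )
            continue
        m_g = compositional_mean(
            CompositionSet(data.values[mask], data.labels, data.kappa)
        )
        lr = np.log(m_g / overall)
        for p, v in zip(data.labels, lr):
            rows.append(
                {"quantile": g + 1, "part": p, "log_ratio": float(v),
                 "n": int(mask.sum())}
            )
    return pd.DataFrame(rows)
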