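"""Isotemporal substitution: predicted outcome change for time reallocation.

Given a fitted compositional linear model and a baseline day, move a fixed
amount of time from one behaviour (the donor) to another (the recipient),
keep the third behaviour and the 24-hour total unchanged, and predict the
resulting change in the outcome:

    delta = yhat(x') - yhat(x) = sum_p a_p * (ln x'_p - ln x_p)

where a is the clr-scale gradient of the fitted model.  Covariates cancel in
the difference.  Because the model is linear in *log-ratios*, delta is not
linear in the amount moved and A->B is generally not the mirror image of
B->A (the behaviours start from different baseline durations).

Confidence intervals follow from the linearity of delta in the fitted
coefficients: with contrast d = (0, dz1, dz2, 0, ...) the variance is
d' Cov(coef) d and the CI uses the t quantile at the residual degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .coda import Composition, ilr
from .regression import FittedModel, clr_gradient

DEFAULT_AMOUNTS_HOURS: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)


class InfeasibleReallocation(ValueError):
    """The requested amount meets or exceeds the donor's baseline time."""


@dataclass(frozen=True)
class Reallocation:
    donor: str
    recipient: str
    amount: float  # hours, > 0

    def __post_init__(self) -> None:
        if self.donor == self.recipient:
            raise ValueError("donor and recipient must differ")
        if self.amount < 0:
            raise ValueError("amount must be non-negative")


@dataclass(frozen=True)
class SubstitutionResult:
    donor: str
    recipient: str
    amount: float
    delta: float
    ci_low: float | None
    ci_high: float | None
    percent_of_baseline: float | None
    significant: bool | None

    def as_dict(self) -> dict:
        return {
            "donor": self.donor,
            "recipient": self.recipient,
            "amount_hours": self.amount,
            "delta": self.delta,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "percent_of_baseline": self.percent_of_baseline,
            "significant": self.significant,
        }


def reallocate(baseline: Composition, r: Reallocation) -> Composition:
    """Move ``r.amount`` hours from donor to recipient; total unchanged."""
    idx = {l: i for i, l in enumerate(baseline.labels)}
    x = baseline.values.copy()
    if r.amount >= x[idx[r.donor]]:
        raise InfeasibleReallocation(
            f"cannot move {r.amount} h out of {r.donor} "
            f"(baseline {x[idx[r.donor]]:.3g} h)"
        )
    x[idx[r.donor]] -= r.amount
    x[idx[r.recipient]] += r.amount
    return Composition(x, baseline.labels, baseline.kappa)


def _gradient_of(model) -> np.ndarray:
    if isinstance(model, FittedModel):
        return clr_gradient(model)
    return np.asarray(model, dtype=float)


def predict_delta(model, baseline: Composition, r: Reallocation) -> float:
    """Predicted outcome change, in outcome units (QoL points here).

    ``model`` may be a :class:`FittedModel` or a plain clr-scale gradient
    triple.  Computed as sum_p a_p * (ln x'_p - ln x_p); identical to the
    difference of full model predictions because covariates cancel.
    """
    a = _gradient_of(model)
    new = reallocate(baseline, r)
    return float(a @ (np.log(new.values) - np.log(baseline.values)))


def delta_ci(
    model: FittedModel,
    baseline: Composition,
    r: Reallocation,
    level: float = 0.95,
    quantile: str = "t",
) -> tuple[float, float]:
    """Confidence interval for the reallocation effect.

    delta is linear in the coefficient vector with contrast
    d = (0, z1' - z1, z2' - z2, 0, ...), so Var(delta) = d' Cov d.
    """
    if not isinstance(model, FittedModel):
        raise TypeError("CI requires a FittedModel carrying coefficient covariance")
    new = reallocate(baseline, r)
    dz = ilr(new.values, model.basis) - ilr(baseline.values, model.basis)
    d = np.zeros(len(model.params))
    d[1:3] = dz
    delta = float(d @ model.params)
    var = float(d @ model.cov_params @ d)
    alpha = 1 - level
    if quantile == "t":
        q = scipy.stats.t.ppf(1 - alpha / 2, model.df_resid)
    elif quantile == "normal":
        q = scipy.stats.norm.ppf(1 - alpha / 2)
    else:
        raise ValueError("quantile must be 't' or 'normal'")
    half = q * np.sqrt(max(var, 0.0))
    return delta - half, delta + half


def substitution_grid(
    model,
    baseline: Composition,
    amounts: tuple[float, ...] = DEFAULT_AMOUNTS_HOURS,
    level: float = 0.95,
    baseline_covariates: np.ndarray | None = None,
) -> list[SubstitutionResult]:
    """All ordered donor->recipient pairs at each amount (24 cells for D=3).

    With a :class:`FittedModel`, each cell carries a CI, a significance flag
    (CI excluding zero) and the change as a percent of the baseline
    prediction BS = yhat(baseline).  With a bare gradient, only point
    estimates are available.  Infeasible cells are recorded with NaN delta
    rather than aborting the grid.
    """
    has_model = isinstance(model, FittedModel)
    bs = None
    if has_model:
        cov = baseline_covariates
        bs = float(model.predict_composition(baseline.values, cov)[0])
    results: list[SubstitutionResult] = []
    for amount in amounts:
        for donor in baseline.labels:
            for recipient in baseline.labels:
                if donor == recipient:
                    continue
                r = Reallocation(donor, recipient, amount)
                try:
                    delta = predict_delta(model, baseline, r)
                except InfeasibleReallocation:
                    results.append(
                        SubstitutionResult(donor, recipient, amount,
                                           float("nan"), None, None, None, None)
                    )
                    continue
                lo = hi = pct = sig = None
                if has_model:
                    lo, hi = delta_ci(model, baseline, r, level)
                    sig = bool(lo > 0 or hi < 0)
                    if bs:
                        pct = 100.0 * delta / bs
                results.append(
                    SubstitutionResult(donor, recipient, amount, delta, lo, hi, pct, sig)
                )
    return results


def grid_frame(results: list[SubstitutionResult]) -> pd.DataFrame:
    """Long-format frame (one row per pair x amount), ready for plotting."""
    return pd.DataFrame([r.as_dict() for r in results])


def substitution_table(results: list[SubstitutionResult]) -> pd.DataFrame:
    """Wide printed-table layout: rows (amount, recipient), columns donors."""
    long = grid_frame(results)
    cells = long.assign(
        cell=[
            f"{r.delta:.2f} ({r.ci_low:.2f}, {r.ci_high:.2f})"
            if r.ci_low is not None and np.isfinite(r.delta)
            else (f"{r.delta:.2f}" if np.isfinite(r.delta) else "")
            for r in results
        ]
    )
    return cells.pivot(
        index=["amount_hours", "recipient"], columns="donor", values="cell"
    ).fillna("")
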