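"""Linear regression of an outcome on ilr coordinates plus covariates.

The model is

    y = b0 + b1*z1 + b2*z2 + c_age*age + c_sex*sex + e

where (z1, z2) are ilr coordinates of the (PA, SB, SL) composition in a
pivot basis and sex is coded girl = 0, boy = 1.  Because ilr bases of the
same composition differ only by rotation, fitted values and R^2 are
basis-invariant; what changes is the interpretation of the coefficients.

The headline quantity is the set of *first-pivot* coefficients: for each
behaviour p, the z1 coefficient of the model refit with p pivoted first,
which measures the effect of increasing p relative to the geometric mean of
the other two behaviours.  The three first-pivot coefficients of one fitted
model always sum to zero - they are three projections of one clr-scale
gradient, beta_p = sqrt(3/2) * a_p with sum(a) = 0.  A reported triple that
does not sum to (numerically) zero cannot come from a single fitted model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .coda import DEFAULT_LABELS, IlrBasis, ilr, pivot_basis

PIVOT_SCALE = np.sqrt(1.5)  # beta (first-pivot) = sqrt(3/2) * clr gradient, D = 3


@dataclass(frozen=True)
class ModelSpec:
    outcome: str = "qol_total"
    parts: tuple[str, ...] = DEFAULT_LABELS
    covariates: tuple[str, ...] = ("age_years", "sex")
    year: int | None = None


@dataclass(frozen=True)
class FittedModel:
    """OLS fit of outcome on [1, z1, z2, covariates...] for a stated basis."""

    basis: IlrBasis
    params: np.ndarray  # (p,) in column order below
    cov_params: np.ndarray  # (p, p)
    column_names: tuple[str, ...]
    resid_var: float
    r_squared: float
    f_pvalue: float
    n: int
    df_resid: int

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def ilr_coefs(self) -> np.ndarray:
        return self.params[1:3]

    def t_pvalues(self) -> np.ndarray:
        se = np.sqrt(np.diag(self.cov_params))
        t = self.params / se
        return 2 * scipy.stats.t.sf(np.abs(t), self.df_resid)

    def predict_composition(self, comp_values, covariates=None) -> np.ndarray:
        """Predicted outcome for composition rows at given covariate values.

        ``covariates`` defaults to zeros (the covariate part cancels in any
        between-composition difference anyway).
        """
        z = np.atleast_2d(ilr(np.atleast_2d(np.asarray(comp_values, float)), self.basis))
        n = z.shape[0]
        ncov = len(self.column_names) - 3
        C = np.zeros((n, ncov)) if covariates is None else np.atleast_2d(covariates)
        X = np.column_stack([np.ones(n), z, C])
        return X @ self.params


@dataclass(frozen=True)
class PivotBetaSet:
    """First-pivot coefficients for each behaviour, publication-table style."""

    parts: tuple[str, ...]
    betas: np.ndarray
    pvalues: np.ndarray
    r_squared: float
    model_pvalue: float
    n: int

    def __post_init__(self) -> None:
        s = float(np.sum(self.betas))
        if abs(s) > 1e-6:
            warnings.warn(
                f"first-pivot coefficients sum to {s:.4g}, not 0; "
                "this triple cannot come from one fitted ilr model"
            )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.parts, map(float, self.betas)))


def build_design(
    records: pd.DataFrame,
    basis: IlrBasis | None = None,
    spec: ModelSpec | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Assemble [1, z1, z2, covariates...] and the outcome vector.

    Records with a missing outcome or covariate are excluded (counted in a
    warning).  Sex is accepted as {girl, boy} strings or 0/1 numerics and
    coded girl = 0, boy = 1.
    """
    spec = spec or ModelSpec()
    basis = basis or pivot_basis(spec.parts)
    df = records
    if spec.year is not None and "year" in df.columns:
        df = df[df["year"] == spec.year]

    part_cols = [f"{p.lower()}_hours" for p in spec.parts]
    needed = part_cols + [spec.outcome, *spec.covariates]
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise KeyError(f"missing columns: {missing_cols}")

    work = df[needed].copy()
    if "sex" in work.columns and work["sex"].dtype == object:
        work["sex"] = work["sex"].map({"girl": 0.0, "boy": 1.0})
    complete = work.notna().all(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        warnings.warn(f"excluded {dropped} records with missing outcome/covariates")
    work = work[complete]

    comp = work[part_cols].to_numpy(dtype=float)
    if np.any(comp <= 0):
        raise ValueError("compositions must be strictly positive; clean records first")
    z = ilr(comp, basis)
    X = np.column_stack(
        [np.ones(len(work)), z, work[list(spec.covariates)].to_numpy(dtype=float)]
    )
    names = ("const", "z1", "z2", *spec.covariates)
    y = work[spec.outcome].to_numpy(dtype=float)
    return X, y, names


def fit_ols(
    X: np.ndarray,
    y: np.ndarray,
    basis: IlrBasis | None = None,
    column_names: tuple[str, ...] | None = None,
) -> FittedModel:
    """Ordinary least squares via statsmodels with an explicit rank check."""
    basis = basis or pivot_basis()
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than design columns")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    res = sm.OLS(y, X).fit()
    f_p = float(res.f_pvalue) if np.isfinite(res.f_pvalue) else float("nan")
    r2 = float(res.rsquared)
    if not np.isfinite(r2):
        r2 = 0.0  # constant outcome: no variance to explain
    return FittedModel(
        basis=basis,
        params=np.asarray(res.params, float),
        cov_params=np.asarray(res.cov_params(), float),
        column_names=column_names or tuple(f"x{i}" for i in range(X.shape[1])),
        resid_var=float(res.mse_resid),
        r_squared=r2,
        f_pvalue=f_p,
        n=int(res.nobs),
        df_resid=int(res.df_resid),
    )


def fit_model(records: pd.DataFrame, spec: ModelSpec | None = None,
              basis: IlrBasis | None = None) -> FittedModel:
    """Convenience: build the design from records and fit."""
    spec = spec or ModelSpec()
    basis = basis or pivot_basis(spec.parts)
    X, y, names = build_design(records, basis, spec)
    return fit_ols(X, y, basis, names)


def rotated_betas(records: pd.DataFrame, spec: ModelSpec | None = None) -> PivotBetaSet:
    """First-pivot coefficient and p-value for each behaviour.

    For each part p the model is refit in the pivot basis with p first; the
    reported coefficient is that fit's z1 coefficient.  Fit statistics (R^2,
    model p, n) are basis-invariant and taken from the first fit.
    """
    spec = spec or ModelSpec()
    betas, pvals = [], []
    ref: FittedModel | None = None
    for part in spec.parts:
        basis = pivot_basis(spec.parts, first=part)
        m = fit_model(records, spec, basis)
        if ref is None:
            ref = m
        betas.append(m.params[1])
        pvals.append(m.t_pvalues()[1])
    assert ref is not None
    return PivotBetaSet(
        parts=spec.parts,
        betas=np.asarray(betas),
        pvalues=np.asarray(pvals),
        r_squared=ref.r_squared,
        model_pvalue=ref.f_pvalue,
        n=ref.n,
    )


def betas_from_gradient(a: np.ndarray) -> np.ndarray:
    """Project a clr-scale gradient onto first-pivot coefficients."""
    return PIVOT_SCALE * np.asarray(a, float)


def clr_gradient(model) -> np.ndarray:
    """Recover the clr-scale gradient a (sum zero) of the fitted effect.

    Accepts a :class:`FittedModel` (a = V^T b for contrast matrix V) or a
    :class:`PivotBetaSet` / plain beta triple (a = beta / sqrt(3/2)).  The
    outcome difference between compositions x' and x is sum_p a_p *
    (ln x'_p - ln x_p).  A beta triple whose sum exceeds 0.05 in magnitude
    triggers a warning: it is not consistent with a single fitted model.
    """
    if isinstance(model, FittedModel):
        return model.basis.contrast.T @ model.ilr_coefs
    if isinstance(model, PivotBetaSet):
        betas = model.betas
    else:
        betas = np.asarray(model, dtype=float)
    s = float(betas.sum())
    if abs(s) > 0.05:
        warnings.warn(
            f"beta set sums to {s:.3g} (> 0.05); gradient is only approximate"
        )
    a = betas / PIVOT_SCALE
    return a - a.mean()  # project onto the sum-zero subspace


def oneway_anova(groups) -> tuple[float, float]:
    """Classical one-way ANOVA across groups (e.g. survey years)."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    F, p = scipy.stats.f_oneway(*groups)
    return float(F), float(p)


def residual_diagnostics(model: FittedModel, X: np.ndarray, y: np.ndarray) -> dict:
    """Linearity/normality diagnostics: residual moments and Q-Q data."""
    resid = y - X @ model.params
    std = resid.std(ddof=X.shape[1])
    sorted_resid = np.sort(resid) / std if std > 0 else np.sort(resid)
    n = len(resid)
    theo = scipy.stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return {
        "skewness": float(scipy.stats.skew(resid)),
        "excess_kurtosis": float(scipy.stats.kurtosis(resid)),
        "qq_theoretical": theo,
        "qq_sample": sorted_resid,
    }


def coefficient_table(beta_sets: dict[int, PivotBetaSet]) -> pd.DataFrame:
    """Arrange per-year pivot-beta sets as one row per year."""
    rows = []
    for year, bs in beta_sets.items():
        row = {"year": year, "r_squared": bs.r_squared, "model_p": bs.model_pvalue,
               "n": bs.n}
        for p, b, pv in zip(bs.parts, bs.betas, bs.pvalues):
            row[f"beta_{p}"] = float(b)
            row[f"p_{p}"] = float(pv)
        rows.append(row)
    return pd.DataFrame(rows)
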