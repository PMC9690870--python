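"""Synthetic survey generator with the statistical structure of the study.

The study's raw data are not deposited, so every pipeline stage is exercised
on simulated surveys that reproduce the *structure* the analysis assumes:

* daily (PA, SB, SL) compositions drawn from a logistic-normal distribution
  on the 24-hour simplex, calibrated so the pairwise log-ratio variation
  matrix matches the observed magnitudes (off-diagonals roughly 0.36-0.50)
  and the compositional centre matches the observed behaviour means;
* a QoL outcome linear in the log-composition plus weak age and sex effects
  with additive Gaussian noise, on the 0-100 PedsQL scale;
* raw activity columns that aggregate back to the drawn behaviours, optional
  item-level PedsQL responses, and a small (< 5%) injected missingness in
  QoL, age and sex.

All randomness flows from a single seed; identical configs give identical
tables byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .coda import (
    DEFAULT_KAPPA,
    DEFAULT_LABELS,
    CompositionSet,
    VariationMatrix,
    close,
    pivot_basis,
)

# Observed scale of the study population (2021 wave): behaviour means
# (hours/day, as reported, pre-closure), per-part coefficients of variation
# (sd/mean), and pairwise log-ratio variances.
BASELINE_HOURS_2021 = np.array([3.83, 4.59, 11.17])
RAW_CV_2021 = np.array([2.26 / 3.83, 2.60 / 4.59, 1.51 / 11.17])
VARIATION_2021 = np.array(
    [[0.00, 0.50, 0.36],
     [0.50, 0.00, 0.41],
     [0.36, 0.41, 0.00]]
)
# clr-scale outcome gradient matching the 2021 fitted betas / sqrt(3/2)
GRADIENT_2021 = np.array([2.82, -2.61, -0.21]) / np.sqrt(1.5)
GRADIENT_2021 -= GRADIENT_2021.mean()

# How aggregate behaviours split into raw activity columns (fixed shares).
ACTIVITY_SPLITS: dict[str, dict[str, float]] = {
    "PA": {"chores_hours": 0.15, "indoor_play_hours": 0.45, "outdoor_play_hours": 0.40},
    "SB": {
        "screen_learning_hours": 0.20,
        "screen_entertainment_hours": 0.40,
        "reading_hours": 0.20,
        "crafts_hours": 0.20,
    },
    "SL": {"nap_hours": 0.12, "night_sleep_hours": 0.88},
}


def varmat_to_clrcov(T: VariationMatrix | np.ndarray) -> np.ndarray:
    """clr covariance from a variation matrix: Sigma = -1/2 * G T G.

    G = I - (1/D) 11' centres onto the sum-zero subspace.  The identity
    T_ij = Sigma_ii + Sigma_jj - 2 Sigma_ij inverts the map.  Raises if the
    result is not positive semi-definite on the sum-zero subspace (i.e. the
    given T is not a valid variation matrix).
    """
    M = T.matrix if isinstance(T, VariationMatrix) else np.asarray(T, dtype=float)
    D = M.shape[0]
    G = np.eye(D) - np.ones((D, D)) / D
    Sigma = -0.5 * G @ M @ G
    eig = np.linalg.eigvalsh(Sigma)
    if np.any(eig < -1e-10):
        raise ValueError("variation matrix is not positive semi-definite on the simplex")
    return Sigma


def clrcov_to_varmat(Sigma: np.ndarray) -> np.ndarray:
    d = np.diag(Sigma)
    return d[:, None] + d[None, :] - 2 * Sigma


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-scale defaults for one simulated survey wave."""

    n: int = 1000
    seed: int = 0
    labels: tuple[str, ...] = DEFAULT_LABELS
    kappa: float = DEFAULT_KAPPA
    variation: np.ndarray = field(default_factory=lambda: VARIATION_2021.copy())
    mean_hours: np.ndarray = field(default_factory=lambda: BASELINE_HOURS_2021.copy())
    # per-part sd/mean of the *raw* reported hours; sets the total-scale
    # dispersion that closure removes (compositional structure is set by
    # ``variation`` alone)
    raw_cv: np.ndarray = field(default_factory=lambda: RAW_CV_2021.copy())
    # outcome model: y = b0 + a . ln(x) + c_age*age + c_sex*sex + N(0, sigma^2)
    gradient: np.ndarray = field(default_factory=lambda: GRADIENT_2021.copy())
    intercept: float = 77.2
    c_age: float = 0.3
    c_sex: float = -0.5
    sigma: float | None = None  # None -> calibrated to target_r2
    target_r2: float = 0.03
    age_range: tuple[float, float] = (2.0, 6.0)
    p_boy: float = 0.5
    clip_outcome: bool = False  # truncation biases OLS; off for recovery work
    missing_qol: float = 0.03
    missing_age: float = 0.02
    missing_sex: float = 0.02
    items: bool = False
    item_noise_sd: float = 0.6  # raw-scale sd controlling reliability
    year: int = 2021

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        g = np.asarray(self.gradient, dtype=float)
        if abs(g.sum()) > 1e-8:
            raise ValueError("outcome gradient must sum to zero (clr scale)")
        object.__setattr__(self, "gradient", g)
        object.__setattr__(self, "variation", np.asarray(self.variation, float))
        object.__setattr__(self, "mean_hours", np.asarray(self.mean_hours, float))
        object.__setattr__(self, "raw_cv", np.asarray(self.raw_cv, float))
        for rate in (self.missing_qol, self.missing_age, self.missing_sex):
            if not 0 <= rate < 0.5:
                raise ValueError("missing rates must be in [0, 0.5)")

    @property
    def clr_cov(self) -> np.ndarray:
        return varmat_to_clrcov(self.variation)

    @property
    def clr_mean(self) -> np.ndarray:
        logm = np.log(close(self.mean_hours, self.kappa))
        return logm - logm.mean()

    def raw_log_mean(self) -> np.ndarray:
        """Mean of ln(raw hours): makes arithmetic means equal mean_hours."""
        v = np.log1p(self.raw_cv**2)
        return np.log(self.mean_hours) - v / 2

    def raw_log_cov(self) -> np.ndarray:
        """Covariance of ln(raw hours).

        Built as Sigma_clr + (u_i + u_j)/2 with u_i = v_i - Sigma_ii, so the
        centred projection G C G equals the clr covariance exactly (closed
        compositions follow the target logistic-normal) while the log
        variances match the requested per-part dispersion v_i = ln(1+cv_i^2).
        """
        Sigma = self.clr_cov
        v = np.log1p(self.raw_cv**2)
        u = v - np.diag(Sigma)
        C = Sigma + (u[:, None] + u[None, :]) / 2
        w, Q = np.linalg.eigh(C)
        if np.any(w < -1e-8):
            raise ValueError(
                "raw_cv is incompatible with the variation matrix: the "
                "implied log covariance is indefinite; increase raw_cv"
            )
        return (Q * np.maximum(w, 0.0)) @ Q.T

    def signal_variance(self) -> float:
        """Variance of the systematic outcome part under the config."""
        a = self.gradient
        var_comp = float(a @ self.clr_cov @ a)
        var_age = self.c_age**2 * (self.age_range[1] - self.age_range[0]) ** 2 / 12
        var_sex = self.c_sex**2 * self.p_boy * (1 - self.p_boy)
        return var_comp + var_age + var_sex

    def resolved_sigma(self) -> float:
        """Noise sd: explicit, or calibrated so that R^2 == target_r2."""
        if self.sigma is not None:
            return float(self.sigma)
        s = self.signal_variance()
        return float(np.sqrt(s * (1 - self.target_r2) / self.target_r2))


def sample_compositions(config: GeneratorConfig, rng: np.random.Generator | None = None) -> CompositionSet:
    """Draw logistic-normal compositions matching the target structure.

    Sampling happens in ilr coordinates (where the covariance is full rank),
    then maps back through the inverse ilr and closes to kappa.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    V = pivot_basis(config.labels).contrast
    mean_z = V @ config.clr_mean
    cov_z = V @ config.clr_cov @ V.T
    z = rng.multivariate_normal(mean_z, cov_z, size=config.n, method="svd")
    x = close(np.exp(z @ V), config.kappa)
    return CompositionSet(x, config.labels, config.kappa)


def sample_raw_hours(config: GeneratorConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Raw (unclosed) behaviour hours as a survey respondent would report.

    Log-normal with the same centred log covariance as
    :func:`sample_compositions` — so closing the rows reproduces the target
    logistic-normal exactly — plus per-part marginal dispersion matching
    ``raw_cv``.  Row totals therefore vary around ``sum(mean_hours)`` the
    way real reported 24-h recalls do (they rarely sum to exactly 24).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    logx = rng.multivariate_normal(
        config.raw_log_mean(), config.raw_log_cov(), size=config.n, method="svd"
    )
    return np.exp(logx)


def sample_outcome(
    comps,
    ages: np.ndarray,
    sexes: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """QoL scores linear in ln(composition) plus covariates and noise.

    ``comps`` may be a CompositionSet or a raw (n, 3) hours array; because
    the gradient sums to zero the result is identical either way (the
    composition's overall scale cancels).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    values = comps.values if isinstance(comps, CompositionSet) else np.asarray(comps)
    sigma = config.resolved_sigma()
    y = (
        config.intercept
        + np.log(values) @ config.gradient
        + config.c_age * np.asarray(ages, float)
        + config.c_sex * np.asarray(sexes, float)
        + rng.normal(0.0, sigma, size=values.shape[0])
    )
    if config.clip_outcome:
        y = np.clip(y, 0.0, 100.0)
    return y


def _split_activities(values: np.ndarray, labels: tuple[str, ...]) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    for j, label in enumerate(labels):
        for col, share in ACTIVITY_SPLITS[label].items():
            cols[col] = values[:, j] * share
    return cols


def _items_for_totals(
    totals: np.ndarray, ages: np.ndarray, config: GeneratorConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Item-level responses whose mean transformed score tracks the total.

    Each item's raw response is the target raw level (100 - y)/25 plus
    independent noise, rounded to the 0-4 grid; item_noise_sd tunes the
    internal consistency downward from 1.
    """
    from .pedsql import form_for_age

    n = len(totals)
    data = np.full((n, 23), np.nan)
    for i in range(n):
        form = form_for_age(float(ages[i]))
        k = form.n_items
        target_raw = (100.0 - totals[i]) / 25.0
        raw = np.clip(
            np.rint(target_raw + rng.normal(0, config.item_noise_sd, size=k)), 0, 4
        )
        data[i, :k] = raw
    return pd.DataFrame(data, columns=[f"pedsql_q{i}" for i in range(1, 24)])


def generate_survey(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """One simulated survey wave.

    Returns (records, metadata).  Records carry raw activity columns (which
    aggregate back exactly to the drawn behaviours), pa/sb/sl_hours, age,
    sex, year, qol_total (and PedsQL items when ``config.items``).  Metadata
    records the seed and every true parameter for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    raw = sample_raw_hours(config, rng)
    ages = rng.uniform(*config.age_range, size=config.n)
    sexes = rng.binomial(1, config.p_boy, size=config.n).astype(float)
    y = sample_outcome(raw, ages, sexes, config, rng)

    df = pd.DataFrame({"id": np.arange(1, config.n + 1), "year": config.year})
    for col, vals in _split_activities(raw, config.labels).items():
        df[col] = vals
    df["pa_hours"] = raw[:, 0]
    df["sb_hours"] = raw[:, 1]
    df["sl_hours"] = raw[:, 2]
    df["age_years"] = ages
    df["sex"] = np.where(sexes == 1, "boy", "girl")
    df["qol_total"] = y
    if config.items:
        items = _items_for_totals(np.clip(y, 0, 100), ages, config, rng)
        df = pd.concat([df, items], axis=1)

    # inject missingness last so all fields are jointly complete beforehand
    for col, rate in (
        ("qol_total", config.missing_qol),
        ("age_years", config.missing_age),
        ("sex", config.missing_sex),
    ):
        if rate > 0:
            mask = rng.random(config.n) < rate
            df.loc[mask, col] = np.nan

    meta = {
        "seed": config.seed,
        "n": config.n,
        "year": config.year,
        "kappa": config.kappa,
        "labels": list(config.labels),
        "true_gradient": config.gradient.tolist(),
        "true_betas_pivot": (np.sqrt(1.5) * config.gradient).tolist(),
        "intercept": config.intercept,
        "c_age": config.c_age,
        "c_sex": config.c_sex,
        "sigma": config.resolved_sigma(),
        "target_r2": config.target_r2,
        "variation": config.variation.tolist(),
        "mean_hours": config.mean_hours.tolist(),
        "missing_rates": {
            "qol": config.missing_qol,
            "age": config.missing_age,
            "sex": config.missing_sex,
        },
    }
    return df, meta


def multiwave(configs: dict[int, GeneratorConfig]) -> tuple[pd.DataFrame, dict]:
    """Concatenate several waves (year -> config) into one survey table."""
    frames, metas = [], {}
    for year, cfg in configs.items():
        df, meta = generate_survey(replace(cfg, year=year))
        frames.append(df)
        metas[year] = meta
    return pd.concat(frames, ignore_index=True), metas
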