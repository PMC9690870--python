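"""Core compositional-geometry machinery for 24-hour time-use data.

A day is modelled as a composition: a vector of strictly positive parts
(physical activity, sedentary behaviour, sleep, in hours) that carries only
relative information and is closed to a constant total ``kappa`` (24 h).
Because the parts are constrained to a simplex, ordinary covariance-based
statistics are not directly applicable; analysis proceeds through log-ratio
transformations.  This module provides:

* closure and multiplicative zero replacement,
* the centred log-ratio (clr) and isometric log-ratio (ilr) transforms,
  with pivot (sequential-binary-partition) bases,
* the compositional (geometric-mean) centre and the variation matrix of
  pairwise log-ratio variances,
* barycentric coordinates for ternary plotting.

Everything is vectorised over numpy arrays; the light dataclasses exist to
fix label order and the closure constant across a dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_LABELS: tuple[str, ...] = ("PA", "SB", "SL")
DEFAULT_KAPPA: float = 24.0

__all__ = [
    "Composition",
    "CompositionSet",
    "IlrBasis",
    "VariationMatrix",
    "close",
    "replace_zeros",
    "clr",
    "ilr",
    "ilr_inverse",
    "pivot_basis",
    "compositional_mean",
    "variation_matrix",
    "ternary_coordinates",
    "DEFAULT_LABELS",
    "DEFAULT_KAPPA",
]


class ZeroPartError(ValueError):
    """A part is zero or negative; call :func:`replace_zeros` first."""


def close(values, kappa: float = DEFAULT_KAPPA) -> np.ndarray:
    """Rescale positive parts so they sum to ``kappa``.

    Works on a single vector or an (n, D) array row-wise.

    Raises
    ------
    ZeroPartError
        If any part is non-positive (log-ratios would be undefined).
    """
    values = np.asarray(values, dtype=float)
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if np.any(values <= 0):
        raise ZeroPartError(
            "composition parts must be strictly positive; "
            "use replace_zeros() to handle zero durations"
        )
    total = values.sum(axis=-1, keepdims=True)
    return values / total * kappa


def replace_zeros(values, epsilon: float = 0.25) -> np.ndarray:
    """Multiplicative zero replacement.

    Zeros become ``epsilon`` (hours) and the non-zero parts are shrunk by a
    common factor so the row total is preserved.  This keeps the ratios
    between non-zero parts intact, which is the standard way to make
    log-ratio analysis well defined for records with a zero duration.
    """
    arr = np.asarray(values, dtype=float)
    one_dim = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if np.any(arr < 0):
        raise ValueError("durations must be non-negative")
    totals = arr.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("all-zero record: no valid composition")
    zero = arr == 0
    n_zero = zero.sum(axis=1, keepdims=True)
    shrink = (totals - epsilon * n_zero) / totals
    if np.any(shrink <= 0):
        raise ValueError("epsilon too large for the row total")
    out = arr * shrink
    out[zero] = epsilon
    return out[0] if one_dim else out


@dataclass(frozen=True)
class Composition:
    """One closed composition: strictly positive hours summing to ``kappa``."""

    values: np.ndarray
    labels: tuple[str, ...] = DEFAULT_LABELS
    kappa: float = DEFAULT_KAPPA

    def __post_init__(self) -> None:
        v = close(np.asarray(self.values, dtype=float).ravel(), self.kappa)
        object.__setattr__(self, "values", v)
        if len(self.labels) != v.size:
            raise ValueError("labels and values length mismatch")

    @property
    def proportions(self) -> np.ndarray:
        return self.values / self.kappa

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, self.values))


@dataclass(frozen=True)
class CompositionSet:
    """n compositions sharing label order and closure constant."""

    values: np.ndarray  # (n, D), closed row-wise
    labels: tuple[str, ...] = DEFAULT_LABELS
    kappa: float = DEFAULT_KAPPA
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = close(np.atleast_2d(np.asarray(self.values, dtype=float)), self.kappa)
        object.__setattr__(self, "values", v)
        if v.shape[0] < 1:
            raise ValueError("need at least one composition")
        if v.shape[1] != len(self.labels):
            raise ValueError("labels and values width mismatch")

    def __len__(self) -> int:
        return self.values.shape[0]

    def row(self, i: int) -> Composition:
        return Composition(self.values[i], self.labels, self.kappa)


def pivot_basis(labels: tuple[str, ...] = DEFAULT_LABELS, first: str | None = None) -> "IlrBasis":
    """Pivot (sequential binary partition) ilr basis.

    The first coordinate contrasts the part ``first`` against the geometric
    mean of all remaining parts; subsequent coordinates peel off the
    remaining parts in order.  For D parts the i-th contrast row is

        sqrt((D-i)/(D-i+1)) * [0, ..., 1, -1/(D-i), ..., -1/(D-i)]

    which for D = 3 gives rows (sqrt(2/3), -1/sqrt(6), -1/sqrt(6)) and
    (0, 1/sqrt(2), -1/sqrt(2)).
    """
    labels = tuple(labels)
    if first is not None:
        if first not in labels:
            raise ValueError(f"unknown part {first!r}")
        order = (first,) + tuple(l for l in labels if l != first)
    else:
        order = labels
    D = len(order)
    contrast_ordered = np.zeros((D - 1, D))
    for i in range(D - 1):
        r = D - i - 1  # parts remaining after the pivot
        coef = np.sqrt(r / (r + 1))
        contrast_ordered[i, i] = coef
        contrast_ordered[i, i + 1:] = -coef / r
    # re-express in the caller's label order
    perm = [order.index(l) for l in labels]
    contrast = contrast_ordered[:, perm]
    return IlrBasis(labels=labels, order=order, contrast=contrast)


@dataclass(frozen=True)
class IlrBasis:
    """An orthonormal log-ratio basis: (D-1) x D contrast matrix.

    Rows are orthonormal and sum to zero, so ilr coordinates are invariant
    to the closure constant.
    """

    labels: tuple[str, ...]
    order: tuple[str, ...]
    contrast: np.ndarray

    def __post_init__(self) -> None:
        V = np.asarray(self.contrast, dtype=float)
        object.__setattr__(self, "contrast", V)
        if not np.allclose(V @ V.T, np.eye(V.shape[0]), atol=1e-10):
            raise ValueError("contrast rows are not orthonormal")
        if not np.allclose(V.sum(axis=1), 0.0, atol=1e-10):
            raise ValueError("contrast rows must sum to zero")


def _values_of(comp, labels=None) -> np.ndarray:
    if isinstance(comp, Composition):
        if labels is not None and tuple(comp.labels) != tuple(labels):
            raise ValueError("label order mismatch between composition and basis")
        return comp.values
    if isinstance(comp, CompositionSet):
        if labels is not None and tuple(comp.labels) != tuple(labels):
            raise ValueError("label order mismatch between composition and basis")
        return comp.values
    return np.asarray(comp, dtype=float)


def clr(comp) -> np.ndarray:
    """Centred log-ratio: ln(x_i / g(x)); components sum to zero."""
    x = _values_of(comp)
    logx = np.log(x)
    return logx - logx.mean(axis=-1, keepdims=True)


def ilr(comp, basis: IlrBasis | None = None) -> np.ndarray:
    """Isometric log-ratio coordinates z = V ln(x) for contrast matrix V."""
    if basis is None:
        basis = pivot_basis()
    x = _values_of(comp, basis.labels)
    return np.log(x) @ basis.contrast.T


def ilr_inverse(coords, basis: IlrBasis | None = None, kappa: float = DEFAULT_KAPPA) -> np.ndarray:
    """Map ilr coordinates back to a closed composition."""
    if basis is None:
        basis = pivot_basis()
    z = np.asarray(coords, dtype=float)
    return close(np.exp(z @ basis.contrast), kappa)


def compositional_mean(data: CompositionSet | np.ndarray, kappa: float | None = None) -> np.ndarray:
    """Compositional centre: per-part geometric means, closed to kappa."""
    if isinstance(data, CompositionSet):
        x, k = data.values, data.kappa
    else:
        x, k = np.atleast_2d(np.asarray(data, dtype=float)), DEFAULT_KAPPA
    if kappa is not None:
        k = kappa
    # column-wise sort makes the reduction independent of record order,
    # so recomputation on a permuted dataset is bit-identical
    gm = np.exp(np.sort(np.log(x), axis=0).mean(axis=0))
    return close(gm, k)


def variation_matrix(data: CompositionSet | np.ndarray) -> "VariationMatrix":
    """Pairwise log-ratio variances T_ij = var(ln(x_i / x_j)), unbiased.

    The variation matrix is the canonical dispersion summary for
    compositions: entries near zero indicate two parts moving in near-fixed
    proportion.  It is invariant to row-wise rescaling (closure).
    """
    if isinstance(data, CompositionSet):
        x, labels = data.values, data.labels
    else:
        x = np.atleast_2d(np.asarray(data, dtype=float))
        labels = tuple(f"p{i+1}" for i in range(x.shape[1]))
    n, D = x.shape
    if n < 2:
        raise ValueError("variation matrix needs at least two compositions")
    logx = np.log(x)
    # var(ln x_i - ln x_j) computed from the log covariance in one pass
    C = np.cov(logx, rowvar=False, ddof=1)
    d = np.diag(C)
    T = d[:, None] + d[None, :] - 2 * C
    T = np.maximum((T + T.T) / 2, 0.0)
    np.fill_diagonal(T, 0.0)
    return VariationMatrix(matrix=T, labels=labels)


@dataclass(frozen=True)
class VariationMatrix:
    matrix: np.ndarray
    labels: tuple[str, ...] = DEFAULT_LABELS

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", M)
        if not np.allclose(M, M.T, atol=1e-10):
            raise ValueError("variation matrix must be symmetric")
        if not np.allclose(np.diag(M), 0.0, atol=1e-12):
            raise ValueError("variation matrix diagonal must be zero")
        if np.any(M < -1e-12):
            raise ValueError("variation matrix entries must be non-negative")

    def pair(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[i, j])


def ternary_coordinates(comp) -> np.ndarray:
    """Barycentric plot coordinates in the unit triangle.

    Convention: part 1 at the origin, part 2 at (1, 0), part 3 at the apex
    (1/2, sqrt(3)/2).  Accepts a Composition, CompositionSet or raw array;
    proportions are taken relative to the row total.
    """
    vals = _values_of(comp)
    one_dim = vals.ndim == 1
    x = np.atleast_2d(vals)
    p = x / x.sum(axis=1, keepdims=True)
    if p.shape[1] != 3:
        raise ValueError("ternary coordinates are defined for 3 parts")
    xy = np.column_stack([p[:, 1] + p[:, 2] / 2, np.sqrt(3) / 2 * p[:, 2]])
    return xy[0] if one_dim else xy
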