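"""Parent-proxy PedsQL scoring and internal-consistency reliability.

The Pediatric Quality of Life Inventory asks parents to rate how much of a
problem each item has been, on a 0-4 scale (0 = never a problem). Raw
responses are reverse-mapped to a 0-100 scale (0->100, 1->75, 2->50, 3->25,
4->0), so higher scores mean better quality of life. Dimension scores are
the mean of the transformed scores over *answered* items; the total score is
the item mean over the whole form, and the psychosocial score is the item
mean over the emotional, social and school dimensions.

Two form versions exist: a 21-item toddler form (ages 2-4) and a 23-item
young-child form (age 5 and up); they differ only in the school dimension
(3 vs 5 items).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DIMENSIONS = ("physical", "emotional", "social", "school")


@dataclass(frozen=True)
class PedsQLForm:
    """Item layout of one PedsQL form version.

    ``items`` maps dimension name -> tuple of 1-based item numbers
    (columns ``pedsql_q<i>`` in tabular input).
    """

    name: str
    items: dict[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        all_items = [i for dims in self.items.values() for i in dims]
        if len(set(all_items)) != len(all_items):
            raise ValueError("items assigned to more than one dimension")

    @property
    def n_items(self) -> int:
        return sum(len(v) for v in self.items.values())

    @property
    def psychosocial_items(self) -> tuple[int, ...]:
        return tuple(
            i for d in ("emotional", "social", "school") for i in self.items[d]
        )


TODDLER_FORM = PedsQLForm(
    name="toddler",
    items={
        "physical": tuple(range(1, 9)),
        "emotional": tuple(range(9, 14)),
        "social": tuple(range(14, 19)),
        "school": tuple(range(19, 22)),
    },
)

YOUNG_CHILD_FORM = PedsQLForm(
    name="young_child",
    items={
        "physical": tuple(range(1, 9)),
        "emotional": tuple(range(9, 14)),
        "social": tuple(range(14, 19)),
        "school": tuple(range(19, 24)),
    },
)


def form_for_age(age_years: float) -> PedsQLForm:
    """Toddler form below the 5th birthday, young-child form from age 5."""
    return TODDLER_FORM if age_years < 5 else YOUNG_CHILD_FORM


def score_item(raw) -> np.ndarray | float:
    """Reverse-map a raw 0-4 response to the 0-100 scale: 100 - 25*raw.

    NaN (missing) passes through; out-of-range values raise.
    """
    arr = np.asarray(raw, dtype=float)
    valid = np.isnan(arr) | ((arr >= 0) & (arr <= 4) & (arr == np.floor(arr)))
    if not np.all(valid):
        raise ValueError("raw PedsQL responses must be integers in 0..4")
    out = 100.0 - 25.0 * arr
    return float(out) if np.isscalar(raw) or arr.ndim == 0 else out


def score_dimension(items, min_answered: float = 0.0) -> float:
    """Mean transformed score over answered items.

    NaN when no item was answered, or when the answered fraction is below
    ``min_answered`` (0 by default; set 0.5 for the common PedsQL
    at-least-half-completed convention).
    """
    scores = score_item(np.asarray(items, dtype=float))
    answered = ~np.isnan(scores)
    if not answered.any() or answered.mean() < min_answered:
        return float("nan")
    return float(scores[answered].mean())


def score_total(
    items,
    form: PedsQLForm,
    psychosocial: str = "item_mean",
    min_answered: float = 0.0,
) -> dict[str, float]:
    """Score one respondent's full form.

    Parameters
    ----------
    items
        Sequence of raw responses ordered q1..qN (NaN = missing).
    form
        Which form version the responses belong to.
    psychosocial
        ``"item_mean"`` (default): mean over all answered psychosocial
        items.  ``"dimension_mean"``: mean of the three dimension scores.
    min_answered
        Minimum answered fraction per block for a score to be valid (0 by
        default, i.e. any answered item scores; 0.5 gives the conventional
        at-least-half-completed rule).

    Returns a dict with ``physical``, ``psychosocial``, ``total`` and the
    four dimension scores; entries are NaN when no item of the relevant
    block was answered.
    """
    arr = np.asarray(items, dtype=float).ravel()
    if arr.size != form.n_items:
        raise ValueError(
            f"expected {form.n_items} items for the {form.name} form, got {arr.size}"
        )
    by_dim = {
        d: score_dimension(arr[[i - 1 for i in idx]], min_answered)
        for d, idx in form.items.items()
    }
    if psychosocial == "item_mean":
        psy = score_dimension(
            arr[[i - 1 for i in form.psychosocial_items]], min_answered
        )
    elif psychosocial == "dimension_mean":
        dims = [by_dim[d] for d in ("emotional", "social", "school")]
        dims = [v for v in dims if not np.isnan(v)]
        psy = float(np.mean(dims)) if dims else float("nan")
    else:
        raise ValueError("psychosocial must be 'item_mean' or 'dimension_mean'")
    return {
        **by_dim,
        "psychosocial": psy,
        "total": score_dimension(arr, min_answered),
    }


def score_table(df: pd.DataFrame, psychosocial: str = "item_mean") -> pd.DataFrame:
    """Score a table of respondents.

    Expects columns ``age_years`` and ``pedsql_q1`` .. ``pedsql_q23``
    (q22/q23 may be absent or blank for toddler-form respondents).  Returns
    a frame with ``qol_physical``, ``qol_psychosocial``, ``qol_total``.
    """
    out = []
    for _, row in df.iterrows():
        form = form_for_age(float(row["age_years"]))
        raw = [
            row.get(f"pedsql_q{i}", np.nan) for i in range(1, form.n_items + 1)
        ]
        s = score_total(raw, form, psychosocial=psychosocial)
        out.append(
            {
                "qol_physical": s["physical"],
                "qol_psychosocial": s["psychosocial"],
                "qol_total": s["total"],
            }
        )
    return pd.DataFrame(out, index=df.index)


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum(item variances) / var(total)).

    ``item_matrix`` is (n respondents, k items) with no missing values.
    Returns NaN (with a warning) when the total score has zero variance.
    """
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 respondents and 2 items")
    if np.isnan(X).any():
        raise ValueError("item matrix must be complete (no missing values)")
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        import warnings

        warnings.warn("total score has zero variance; alpha undefined")
        return float("nan")
    return float(k / (k - 1) * (1 - item_var.sum() / total_var))
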