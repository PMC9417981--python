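"""Krippendorff's alpha for inter-rater reliability.

alpha = 1 - D_o / D_e, where D_o is the observed disagreement within units
and D_e the disagreement expected when ratings are detached from units, both
computed from the coincidence matrix.  Supported difference functions:

* ``nominal``  — 0 for identical values, 1 otherwise (e.g. MRD status);
* ``interval`` — squared difference;
* ``ratio``    — squared relative difference ((v - w) / (v + w))^2, the
  natural choice for subpopulation percentages of CD45+ (nonnegative,
  ratio-scale data).

Missing ratings are permitted (NaN / None); units with fewer than two
ratings carry no information and are excluded.  When every pairable rating
is identical the expected disagreement is zero and alpha is defined as 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

METRICS = ("nominal", "interval", "ratio")


class InsufficientRatingsError(ValueError):
    """Fewer than two raters, or no unit with two or more ratings."""


def _coerce(ratings) -> np.ndarray:
    """units x raters float array with NaN for missing; factorizes strings."""
    arr = np.asarray(ratings, dtype=object)
    if arr.ndim != 2:
        raise ValueError("ratings must be a 2-D units x raters matrix")
    flat = pd.Series(arr.ravel())
    if flat.map(lambda v: isinstance(v, str)).any():
        codes, _ = pd.factorize(flat, use_na_sentinel=True)
        out = codes.astype(float)
        out[codes < 0] = np.nan
        return out.reshape(arr.shape)
    return np.asarray(ratings, dtype=float).reshape(arr.shape)


def _difference_matrix(values: np.ndarray, metric: str) -> np.ndarray:
    v = values[:, None]
    w = values[None, :]
    if metric == "nominal":
        return (v != w).astype(float)
    if metric == "interval":
        return (v - w) ** 2
    if metric == "ratio":
        if (values < 0).any():
            raise ValueError("ratio metric requires nonnegative values")
        denom = v + w
        with np.errstate(invalid="ignore", divide="ignore"):
            d = ((v - w) / denom) ** 2
        return np.where(denom == 0, 0.0, d)
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def krippendorff_alpha(ratings, metric: str = "nominal") -> float:
    """Krippendorff's alpha for a units x raters matrix.

    ``ratings`` may contain NaN for missing entries; string labels are
    accepted for the nominal metric.  The result is invariant to unit and
    rater order and, for nominal data, to relabeling of categories.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    matrix = _coerce(ratings)
    if matrix.shape[1] < 2:
        raise InsufficientRatingsError("need at least 2 raters")

    values = np.unique(matrix[np.isfinite(matrix)])
    if values.size == 0:
        raise InsufficientRatingsError("no ratings present")
    index = {v: i for i, v in enumerate(values)}
    k = values.size

    # coincidence matrix: each unit with m ratings contributes its ordered
    # pairs, each weighted 1/(m - 1)
    coincidences = np.zeros((k, k))
    for row in matrix:
        obs = row[np.isfinite(row)]
        m = obs.size
        if m < 2:
            continue
        counts = np.zeros(k)
        for v in obs:
            counts[index[v]] += 1
        coincidences += (np.outer(counts, counts) - np.diag(counts)) / (m - 1)

    totals = coincidences.sum(axis=1)
    n = totals.sum()
    if n == 0:
        raise InsufficientRatingsError("no unit has two or more ratings")

    delta = _difference_matrix(values, metric)
    d_observed = float((coincidences * delta).sum()) / n
    d_expected = float((np.outer(totals, totals) * delta).sum()) / (n * (n - 1))
    if d_expected == 0:
        # every pairable value identical: perfect agreement by definition
        return 1.0
    return 1.0 - d_observed / d_expected


@dataclass
class RatingsMatrix:
    """units x raters ratings with a declared metric level."""

    values: np.ndarray
    metric: str = "nominal"

    def alpha(self) -> float:
        return krippendorff_alpha(self.values, metric=self.metric)


def ratings_from_long(
    df: pd.DataFrame,
    unit_col: str = "unit",
    rater_col: str = "rater",
    value_col: str = "value",
) -> np.ndarray:
    """Pivot a long-format (unit, rater, value) table into a ratings matrix."""
    wide = df.pivot_table(
        index=unit_col, columns=rater_col, values=value_col, aggfunc="first"
    )
    return wide.to_numpy()
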