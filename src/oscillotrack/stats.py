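"""Group-level summaries for cohort entrainment tables.

The cohort table is a tidy DataFrame with one row per subject x condition
(columns ``subject_id, stimulus, rate, jitter, peak_plv, xcorr_max, ...``).
Group inference uses within-subject machinery throughout: an orthogonal
linear contrast across an ordered factor (e.g. jitter) summarised per
subject and tested against zero with a one-sample t-test, paired t-tests
for stimulus-domain contrasts at single design cells, and Pearson
correlations for brain--behavior relations.  PLV-like bounded quantities
are square-root transformed before testing.  Families of per-level
contrasts are Holm-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateInputError, InvalidParameterError

ALPHA = 0.05


@dataclass(frozen=True)
class TrendResult:
    """Within-subject linear trend across an ordered factor."""

    slope: float  # mean per-subject OLS slope (value units per factor unit)
    t: float
    df: int
    p: float
    n_subjects: int
    factor: str
    levels: tuple


@dataclass(frozen=True)
class ContrastResult:
    """Paired within-subject contrast between two levels of a factor."""

    mean_diff: float
    t: float
    df: int
    p: float
    n_pairs: int
    levels: tuple
    exact_separation: bool = False


def sqrt_transform(values) -> np.ndarray:
    """Element-wise square root (variance-stabilising for bounded PLV-like data)."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise InvalidParameterError("square-root transform requires non-negative values")
    return np.sqrt(arr)


def _pivot_balanced(
    table: pd.DataFrame, value: str, factor: str, within: str
) -> pd.DataFrame:
    counts = table.groupby([within, factor]).size().unstack(fill_value=0)
    missing = [(s, lv) for s in counts.index for lv in counts.columns if counts.loc[s, lv] == 0]
    if missing:
        raise InvalidParameterError(f"unbalanced cells; missing {missing}")
    if (counts.to_numpy() > 1).any():
        raise InvalidParameterError(
            "each subject must contribute each cell exactly once; "
            "collapse replicate rows first"
        )
    return table.pivot(index=within, columns=factor, values=value)


def linear_trend(
    table: pd.DataFrame,
    value: str = "peak_plv",
    factor: str = "jitter",
    within: str = "subject_id",
) -> TrendResult:
    """Orthogonal linear contrast across ``factor``, tested across subjects.

    Per subject, values across the ordered factor levels are projected onto
    the centered (orthogonal-polynomial degree-1) contrast; contrast scores
    are tested against zero with a two-sided one-sample t-test.  The
    reported slope is the mean per-subject least-squares slope.
    """
    wide = _pivot_balanced(table, value, factor, within)
    levels = np.asarray(sorted(wide.columns), dtype=float)
    wide = wide[sorted(wide.columns)]
    if len(levels) < 3:
        raise InvalidParameterError("need at least 3 factor levels for a trend")
    if len(wide) < 3:
        raise InvalidParameterError("need at least 3 subjects")
    c = levels - levels.mean()
    data = wide.to_numpy(dtype=float)
    slopes = data @ c / np.sum(c**2)
    scores = data @ (c / np.linalg.norm(c))
    if np.allclose(scores, 0.0):
        t_val, p_val = 0.0, 1.0
    else:
        t_val, p_val = sps.ttest_1samp(scores, 0.0)
        if not np.isfinite(t_val):  # identical nonzero scores
            t_val, p_val = np.inf * np.sign(scores.mean()), 0.0
    return TrendResult(
        slope=float(np.mean(slopes)),
        t=float(t_val),
        df=len(wide) - 1,
        p=float(p_val),
        n_subjects=len(wide),
        factor=factor,
        levels=tuple(levels),
    )


def paired_contrast(
    table: pd.DataFrame,
    between: str = "stimulus",
    at: dict | None = None,
    value: str = "peak_plv",
    within: str = "subject_id",
    order: tuple | None = None,
) -> ContrastResult:
    """Paired t-test between the two levels of ``between`` at one design cell.

    ``at`` filters the table (e.g. ``{"rate": 4.5, "jitter": 0.2}``); every
    subject must contribute both levels.  The difference is level[0] minus
    level[1] with ``order`` defaulting to sorted level order.  Degenerate
    certainty (identical nonzero difference for every subject) is flagged
    as exact separation with p = 0.
    """
    sub = table
    for col, val in (at or {}).items():
        if isinstance(val, (int, float, np.integer, np.floating)):
            sub = sub[np.isclose(sub[col].astype(float), float(val))]
        else:
            sub = sub[sub[col] == val]
    levels = order if order is not None else tuple(sorted(sub[between].unique()))
    if len(levels) != 2:
        raise InvalidParameterError(f"contrast needs exactly two levels, got {levels}")
    wide = _pivot_balanced(sub, value, between, within)
    if not all(lv in wide.columns for lv in levels):
        raise InvalidParameterError(f"missing level(s) among {levels}")
    diffs = (wide[levels[0]] - wide[levels[1]]).to_numpy(dtype=float)
    if len(diffs) < 2:
        raise InvalidParameterError("need at least 2 paired subjects")
    if np.allclose(diffs, 0.0):
        return ContrastResult(0.0, 0.0, len(diffs) - 1, 1.0, len(diffs), levels)
    if np.ptp(diffs) == 0.0:  # identical nonzero differences: exact separation
        return ContrastResult(
            float(diffs[0]), float(np.inf * np.sign(diffs[0])), len(diffs) - 1, 0.0,
            len(diffs), levels, exact_separation=True,
        )
    t_val, p_val = sps.ttest_rel(wide[levels[0]], wide[levels[1]])
    return ContrastResult(
        mean_diff=float(diffs.mean()),
        t=float(t_val),
        df=len(diffs) - 1,
        p=float(p_val),
        n_pairs=len(diffs),
        levels=levels,
    )


def correlate(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p from the t distribution."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("x and y must be equal-length 1-D arrays")
    if len(x) < 3:
        raise InvalidParameterError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidParameterError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero-variance input to correlate")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values for a family of contrasts."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method="holm")[1]
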