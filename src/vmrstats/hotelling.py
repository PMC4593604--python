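"""Two-sample Hotelling's T-squared test on activity-profile vectors.

The test compares the mean activity profiles of two groups over a fixed set
of seconds, treating the profile as one multivariate observation per
(animal, event).  With group mean vectors x̄₁, x̄₂ of dimension p and pooled
sample covariance S,

    T² = n₁n₂/(n₁+n₂) · (x̄₁ − x̄₂)' S⁻¹ (x̄₁ − x̄₂)

and  F = (n₁+n₂−p−1) / (p(n₁+n₂−2)) · T²  follows an F(p, n₁+n₂−p−1)
distribution under the null of equal means.  For p = 1 the statistic reduces
to the squared pooled-variance two-sample t.

Families of such tests (strain pairs, window tags, trial subsets) are
corrected with the Benjamini–Hochberg step-up FDR adjustment over all tests
of one battery invocation.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .activity import WindowedActivitySet
from .errors import (
    DimensionError,
    InsufficientDataError,
    SingularCovarianceError,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class HotellingResult:
    t2: float
    f_stat: float
    df1: int
    df2: int
    p_value: float
    n1: int
    n2: int
    p_dim: int
    mean_diff: np.ndarray
    pooled_cov: np.ndarray


def pooled_covariance(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Weighted pooled sample covariance S = ((n1-1)S1 + (n2-1)S2)/(n1+n2-2)."""
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    n1, n2 = X1.shape[0], X2.shape[0]
    if n1 < 2 and n2 < 2:
        raise InsufficientDataError(
            f"need at least one group with n >= 2, got n1={n1}, n2={n2}"
        )
    if n1 + n2 < 3:
        raise InsufficientDataError("n1 + n2 must be >= 3")

    def _scatter(X):  # (n-1) * sample covariance; zero matrix when n < 2
        if X.shape[0] < 2:
            return np.zeros((X.shape[1], X.shape[1]))
        Xc = X - X.mean(axis=0)
        return Xc.T @ Xc

    return (_scatter(X1) + _scatter(X2)) / (n1 + n2 - 2)


def hotelling_t2(
    X1: np.ndarray, X2: np.ndarray, ridge: float = 0.0
) -> HotellingResult:
    """Two-sample Hotelling T² with its F transform and p-value.

    Parameters
    ----------
    X1, X2
        (n1 x p) and (n2 x p) observation matrices with aligned columns.
    ridge
        Optional ridge added to the pooled covariance diagonal (S + ridge*I).
        Off by default: a singular S raises
        :class:`~vmrstats.errors.SingularCovarianceError` naming the offending
        columns, because silently pseudo-inverting changes the statistic's
        null distribution.
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValidationError("X1 and X2 must have the same number of columns")
    n1, n2 = X1.shape[0], X2.shape[0]
    p = X1.shape[1]
    df2 = n1 + n2 - p - 1
    if df2 < 1:
        raise DimensionError(
            f"dimension p={p} exceeds samples: need n1+n2-p-1 >= 1, got {df2}"
        )
    S = pooled_covariance(X1, X2)
    if ridge > 0:
        S = S + ridge * np.eye(p)
    diff = X1.mean(axis=0) - X2.mean(axis=0)
    try:
        sol = np.linalg.solve(S, diff)
        # reject solutions from numerically singular systems
        if not np.isfinite(sol).all() or np.linalg.cond(S) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        var = np.diag(S)
        bad = [int(j) for j in np.flatnonzero(var <= 1e-300)]
        raise SingularCovarianceError(
            "pooled covariance is singular "
            + (
                f"(zero-variance columns {bad})"
                if bad
                else "(collinear columns)"
            )
            + "; pass ridge > 0 to regularize",
            bad_columns=bad,
        ) from None
    t2 = float(n1 * n2 / (n1 + n2) * diff @ sol)
    t2 = max(t2, 0.0)
    f_stat = df2 / (p * (n1 + n2 - 2)) * t2
    p_value = float(stats.f.sf(f_stat, p, df2))
    return HotellingResult(
        t2=t2,
        f_stat=f_stat,
        df1=p,
        df2=df2,
        p_value=p_value,
        n1=n1,
        n2=n2,
        p_dim=p,
        mean_diff=diff,
        pooled_cov=S,
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order.

    q(i) = min_{j >= i} p(j) * m / j over the ascending order, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def _parse_window_tag(tag: str, pre_len: int, post_len: int) -> tuple[int, int]:
    """Map a window tag to an inclusive relative-second interval.

    ``pre`` -> (-pre_len+1, 0); ``post`` -> (1, post_len); ``A:B`` -> (A, B).
    """
    if tag == "pre":
        return (-pre_len + 1, 0)
    if tag == "post":
        return (1, post_len)
    try:
        lo, hi = tag.split(":")
        return (int(lo), int(hi))
    except Exception:
        raise ValidationError(
            f"window tag {tag!r} must be 'pre', 'post' or 'LO:HI'"
        ) from None


def pairwise_battery(
    windows: WindowedActivitySet,
    group_field: str,
    window_tags=("pre", "post"),
    comparisons="all",
    stimulus: str | None = None,
    filters: dict | None = None,
    ridge: float = 0.0,
) -> pd.DataFrame:
    """A family of pairwise Hotelling tests with a single FDR adjustment.

    One test per (group pair, window tag); the Benjamini–Hochberg family is
    all tests of this invocation.  ``filters`` restricts the observations
    (e.g. ``{"stage_dpf": 6}`` or ``{"trial_index": [2, 3]}``); ``stimulus``
    restricts to on/off events.  Observations are (animal, event) profile
    vectors, so pooled technical repeats are not independent animals — see
    the pseudoreplication note in the docs.
    """
    df = windows.data
    if group_field not in df.columns:
        raise ValidationError(f"group field {group_field!r} not in window metadata")
    mask = pd.Series(True, index=df.index)
    if stimulus is not None:
        mask &= df["stimulus"] == stimulus.lower()
    for col, val in (filters or {}).items():
        if col not in df.columns:
            raise ValidationError(f"filter field {col!r} not in window metadata")
        vals = val if isinstance(val, (list, tuple, set)) else [val]
        mask &= df[col].isin(list(vals))

    levels = sorted(df.loc[mask, group_field].dropna().unique().tolist())
    if comparisons == "all":
        pairs = list(itertools.combinations(levels, 2))
    else:
        pairs = [tuple(pair) for pair in comparisons]

    rows = []
    for tag in window_tags:
        lo, hi = _parse_window_tag(str(tag), windows.pre_len, windows.post_len)
        for a, b in pairs:
            mats = {}
            for label in (a, b):
                sub = mask & (df[group_field] == label)
                X, _ = windows.profile_matrix(lo, hi, mask=sub)
                if X.shape[0] < 2:
                    raise InsufficientDataError(
                        f"group {label!r} has n={X.shape[0]} (< 2) in window {tag!r}"
                    )
                mats[label] = X
            res = hotelling_t2(mats[a], mats[b], ridge=ridge)
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "window": str(tag),
                    "n1": res.n1,
                    "n2": res.n2,
                    "p_dim": res.p_dim,
                    "t2": res.t2,
                    "f_stat": res.f_stat,
                    "df1": res.df1,
                    "df2": res.df2,
                    "p_raw": res.p_value,
                }
            )
    table = pd.DataFrame(rows)
    table["p_adj"] = fdr_adjust(table["p_raw"].to_numpy())
    return table


def paired_window_test(
    windows: WindowedActivitySet,
    group_field: str,
    label,
    window_a: str = "pre",
    window_b: str = "post",
    stimulus: str | None = None,
    filters: dict | None = None,
    ridge: float = 0.0,
) -> HotellingResult:
    """Same-group comparison of two windows (e.g. before vs after light change).

    The two windows of each observation are treated as two samples, matching
    the two-sample contrast used for before/after activity comparisons.
    """
    df = windows.data
    mask = pd.Series(True, index=df.index) & (df[group_field] == label)
    if stimulus is not None:
        mask &= df["stimulus"] == stimulus.lower()
    for col, val in (filters or {}).items():
        vals = val if isinstance(val, (list, tuple, set)) else [val]
        mask &= df[col].isin(list(vals))
    lo_a, hi_a = _parse_window_tag(window_a, windows.pre_len, windows.post_len)
    lo_b, hi_b = _parse_window_tag(window_b, windows.pre_len, windows.post_len)
    Xa, _ = windows.profile_matrix(lo_a, hi_a, mask=mask)
    Xb, _ = windows.profile_matrix(lo_b, hi_b, mask=mask)
    if Xa.shape[1] != Xb.shape[1]:
        raise ValidationError(
            "windows being compared must have equal length "
            f"({Xa.shape[1]} vs {Xb.shape[1]} seconds)"
        )
    return hotelling_t2(Xa, Xb, ridge=ridge)
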