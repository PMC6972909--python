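"""Pearson, first- and second-order partial correlation with t-test significance.

The second-order partial correlation between series 1 (NDVI anomalies) and
2 (precipitation anomalies) controlling series 3 and 4 (temperature and
radiation anomalies) is computed by the classical recursion

    r_12.3  = (r_12 - r_13 r_23) / sqrt((1 - r_13^2)(1 - r_23^2))
    r_12.34 = (r_12.3 - r_14.3 r_24.3) / sqrt((1 - r_14.3^2)(1 - r_24.3^2))

Significance uses t = r sqrt(df / (1 - r^2)) with df = n - 2 - k controls,
two-sided against Student's t.  Missing data are handled listwise on the
full (x, y, z1, z2) tuple: a time step is dropped for all four series if
any one is missing, so every pairwise correlation in the recursion shares
one sample.  Degenerate inputs (constant series, |control correlation| = 1)
propagate as NaN, never as zero.

Scalar helpers return :class:`CorrelationValue`; the ``*_stack`` functions
are vectorised over trailing axes and back the gridded engines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationValue",
    "pearson",
    "partial_first",
    "partial_second",
    "significance",
    "critical_r",
    "pearson_stack",
    "partial_second_stack",
    "significance_stack",
    "DegenerateControlError",
    "UndefinedCorrelationError",
]

_EPS = 1e-12


class UndefinedCorrelationError(ValueError):
    """Correlation undefined (constant series or too few points)."""


class DegenerateControlError(ValueError):
    """A control variable is perfectly collinear with x or y."""


@dataclass(frozen=True)
class CorrelationValue:
    """A correlation with its significance test."""

    r: float
    order: int
    n: int
    t_stat: float
    p_value: float
    significant_at: float = 0.05

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.significant_at)


def _listwise(*series: np.ndarray) -> list[np.ndarray]:
    arrs = [np.asarray(s, dtype=float).ravel() for s in series]
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise ValueError("series lengths differ")
    keep = np.ones(n, dtype=bool)
    for a in arrs:
        keep &= np.isfinite(a)
    return [a[keep] for a in arrs]


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom <= _EPS * max(1.0, np.abs(xc).max(initial=0), np.abs(yc).max(initial=0)):
        raise UndefinedCorrelationError("constant series")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def significance(r: float, n: int, n_controls: int = 0,
                 alpha: float = 0.05) -> tuple[float, float, bool]:
    """Two-sided t-test of a (partial) correlation coefficient.

    Returns ``(t_stat, p_value, significant)``.  |r| = 1 maps to infinite t
    and p = 0 by convention.
    """
    df = n - 2 - n_controls
    if df < 1:
        raise ValueError(f"non-positive degrees of freedom (n={n}, controls={n_controls})")
    if abs(r) >= 1.0:
        return float(np.inf) * np.sign(r), 0.0, True
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p), bool(p < alpha)


def pearson(x, y, alpha: float = 0.05) -> CorrelationValue:
    """Product-moment correlation (order 0)."""
    x, y = _listwise(x, y)
    if x.size < 3:
        raise UndefinedCorrelationError("need at least 3 paired values")
    r = _pearson_r(x, y)
    t, p, _ = significance(r, x.size, 0, alpha)
    return CorrelationValue(r, 0, x.size, t, p, alpha)


def _partial_from_pearsons(r12: float, r13: float, r23: float) -> float:
    for rc in (r13, r23):
        if abs(rc) >= 1.0 - _EPS:
            raise DegenerateControlError("control perfectly correlated with a variable")
    num = r12 - r13 * r23
    den = np.sqrt((1.0 - r13 * r13) * (1.0 - r23 * r23))
    return float(np.clip(num / den, -1.0, 1.0))


def partial_first(x, y, z, alpha: float = 0.05) -> CorrelationValue:
    """First-order partial correlation r_xy.z."""
    x, y, z = _listwise(x, y, z)
    if x.size < 4:
        raise UndefinedCorrelationError("need at least 4 values for order 1")
    r = _partial_from_pearsons(_pearson_r(x, y), _pearson_r(x, z), _pearson_r(y, z))
    t, p, _ = significance(r, x.size, 1, alpha)
    return CorrelationValue(r, 1, x.size, t, p, alpha)


def partial_second(x, y, z1, z2, alpha: float = 0.05) -> CorrelationValue:
    """Second-order partial correlation r_xy.z1z2 via the recursion."""
    x, y, z1, z2 = _listwise(x, y, z1, z2)
    if x.size < 5:
        raise UndefinedCorrelationError("need at least 5 values for order 2")
    r12 = _pearson_r(x, y)
    r13 = _pearson_r(x, z1)
    r23 = _pearson_r(y, z1)
    r14 = _pearson_r(x, z2)
    r24 = _pearson_r(y, z2)
    r34 = _pearson_r(z1, z2)
    r12_3 = _partial_from_pearsons(r12, r13, r23)
    r14_3 = _partial_from_pearsons(r14, r13, r34)
    r24_3 = _partial_from_pearsons(r24, r23, r34)
    r = _partial_from_pearsons(r12_3, r14_3, r24_3)
    t, p, _ = significance(r, x.size, 2, alpha)
    return CorrelationValue(r, 2, x.size, t, p, alpha)


def critical_r(alpha: float, n: int, n_controls: int = 0) -> float:
    """|r| whose two-sided t statistic sits exactly at the alpha critical value."""
    df = n - 2 - n_controls
    if df < 1:
        raise ValueError("non-positive degrees of freedom")
    t = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(t / np.sqrt(df + t * t))


# ---------------------------------------------------------------------------
# Vectorised engine: series along axis 0, any trailing shape of "pixels"
# ---------------------------------------------------------------------------

def _stack_corr(ac, bc, mask):
    """Correlation of pre-centered arrays under a common mask."""
    cov = np.einsum("t...,t...->...", ac, bc)
    va = np.einsum("t...,t...->...", ac, ac)
    vb = np.einsum("t...,t...->...", bc, bc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(va * vb)
    bad = (va <= _EPS) | (vb <= _EPS)
    r = np.where(bad, np.nan, np.clip(r, -1.0, 1.0))
    return r


def _center(a, mask, n):
    a = np.where(mask, a, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = a.sum(axis=0) / n
    return np.where(mask, a - mean, 0.0)


def _stack_partial(r12, r13, r23):
    with np.errstate(invalid="ignore", divide="ignore"):
        den = np.sqrt((1.0 - r13 * r13) * (1.0 - r23 * r23))
        r = (r12 - r13 * r23) / den
    bad = (np.abs(r13) >= 1.0 - _EPS) | (np.abs(r23) >= 1.0 - _EPS)
    return np.where(bad, np.nan, np.clip(r, -1.0, 1.0))


def significance_stack(r: np.ndarray, n: np.ndarray, n_controls: int):
    """Vectorised t-test; returns (t, p). NaN r propagates, |r|=1 -> p=0."""
    df = n - 2 - n_controls
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * sps.t.sf(np.abs(t), np.maximum(df, 1))
    sat = np.isfinite(r) & (np.abs(r) >= 1.0)
    p = np.where(sat, 0.0, p)
    t = np.where(sat, np.sign(r) * np.inf, t)
    bad = df < 1
    p = np.where(bad, np.nan, p)
    return t, p


def pearson_stack(x: np.ndarray, y: np.ndarray):
    """Pairwise-complete Pearson r over axis 0; returns (r, n_eff)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    n = mask.sum(axis=0)
    xc = _center(x, mask, n)
    yc = _center(y, mask, n)
    r = _stack_corr(xc, yc, mask)
    r = np.where(n >= 3, r, np.nan)
    return r, n


def partial_second_stack(x, y, z1, z2):
    """Second-order partial correlation over axis 0, listwise-complete.

    Parameters are arrays of shape (n_time, ...); returns ``(r, p, n_eff)``
    with the trailing shape.
    """
    arrs = [np.asarray(a, dtype=float) for a in (x, y, z1, z2)]
    mask = np.ones(arrs[0].shape, dtype=bool)
    for a in arrs:
        mask &= np.isfinite(a)
    n = mask.sum(axis=0)
    cent = [_center(a, mask, n) for a in arrs]
    xc, yc, c1, c2 = cent
    r12 = _stack_corr(xc, yc, mask)
    r13 = _stack_corr(xc, c1, mask)
    r23 = _stack_corr(yc, c1, mask)
    r14 = _stack_corr(xc, c2, mask)
    r24 = _stack_corr(yc, c2, mask)
    r34 = _stack_corr(c1, c2, mask)
    r12_3 = _stack_partial(r12, r13, r23)
    r14_3 = _stack_partial(r14, r13, r34)
    r24_3 = _stack_partial(r24, r23, r34)
    r = _stack_partial(r12_3, r14_3, r24_3)
    r = np.where(n >= 5, r, np.nan)
    _, p = significance_stack(r, n, 2)
    return r, p, n
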