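"""Paired exposure-change statistics on the log scale.

Geometric means with t-based confidence intervals, paired geometric mean
ratios (GMR) with 90% CI and paired t-test on log-transformed values,
classification of the CI against the 0.80-1.25 bioequivalence bounds, and
the ratio-ratio regression used to probe whether two drugs' exposure changes
are correlated across subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateRegressionError,
    DomainError,
    PairingError,
    SampleSizeError,
)

BIOEQUIVALENCE_BOUNDS = (0.80, 1.25)


@dataclass(frozen=True)
class GeoMeanCI:
    """Geometric mean with a log-scale t-interval."""

    gm: float
    ci_low: float
    ci_high: float
    level: float
    n: int


@dataclass(frozen=True)
class GMRResult:
    """Paired geometric mean ratio: exp(mean paired log difference), CI, p."""

    gmr: float
    ci_low: float
    ci_high: float
    level: float
    p_value: float
    n_pairs: int
    degenerate: bool = False  # all paired log differences identical


def _check_positive(values: np.ndarray, what: str) -> None:
    if np.any(~np.isfinite(values)) or np.any(values <= 0):
        raise DomainError(f"{what} must be positive and finite")


def geomean_ci(values, level: float = 0.95) -> GeoMeanCI:
    """Geometric mean with a ``level`` t-interval on the log scale.

    gm = exp(mean log x); CI = exp(mean log +- t_{n-1} * se(log x)).
    """
    x = np.asarray(list(values), dtype=float)
    if len(x) < 2:
        raise SampleSizeError(f"need n >= 2 values, got {len(x)}")
    _check_positive(x, "values")
    logs = np.log(x)
    m = logs.mean()
    se = logs.std(ddof=1) / math.sqrt(len(x))
    tcrit = stats.t.ppf(0.5 + level / 2.0, len(x) - 1)
    return GeoMeanCI(
        gm=math.exp(m),
        ci_low=math.exp(m - tcrit * se),
        ci_high=math.exp(m + tcrit * se),
        level=level,
        n=len(x),
    )


def gmr_paired(baseline, treated, level: float = 0.90) -> GMRResult:
    """Paired GMR with CI and two-sided p-value.

    ``baseline`` and ``treated`` may be dicts keyed by subject (pairing is
    then by key with listwise deletion of incomplete pairs) or equal-length
    sequences in matching order.  The procedure is the paired t-test on
    d_i = log(treated_i) - log(baseline_i): gmr = exp(mean d),
    CI = exp(mean d +- t_{n-1} * se(d)).
    """
    if isinstance(baseline, dict) or isinstance(treated, dict):
        if not (isinstance(baseline, dict) and isinstance(treated, dict)):
            raise PairingError("both samples must be dicts when either is")
        common = sorted(set(baseline) & set(treated))
        if not common:
            raise PairingError("no common subjects between occasions")
        b = np.array([baseline[k] for k in common], dtype=float)
        t_arr = np.array([treated[k] for k in common], dtype=float)
    else:
        b = np.asarray(list(baseline), dtype=float)
        t_arr = np.asarray(list(treated), dtype=float)
        if len(b) != len(t_arr):
            raise PairingError(f"unmatched sample sizes {len(b)} vs {len(t_arr)}")
    n = len(b)
    if n < 2:
        raise SampleSizeError(f"need n >= 2 pairs, got {n}")
    _check_positive(b, "baseline values")
    _check_positive(t_arr, "treated values")
    d = np.log(t_arr) - np.log(b)
    m = d.mean()
    sd = d.std(ddof=1)
    degenerate = sd == 0.0
    se = sd / math.sqrt(n)
    tcrit = stats.t.ppf(0.5 + level / 2.0, n - 1)
    if degenerate:
        p = 1.0 if m == 0.0 else 0.0
        lo = hi = math.exp(m)
    else:
        tstat = m / se
        p = 2.0 * stats.t.sf(abs(tstat), n - 1)
        lo, hi = math.exp(m - tcrit * se), math.exp(m + tcrit * se)
    return GMRResult(
        gmr=math.exp(m),
        ci_low=lo,
        ci_high=hi,
        level=level,
        p_value=float(p),
        n_pairs=n,
        degenerate=bool(degenerate),
    )


def bioequivalence_flag(
    result: GMRResult, bounds: tuple[float, float] = BIOEQUIVALENCE_BOUNDS
) -> str:
    """Classify the GMR confidence interval against bioequivalence bounds.

    Returns ``'within'`` when the CI lies inside [lo, hi], ``'above'`` when
    entirely above, ``'below'`` when entirely below, else ``'straddles'``.
    """
    lo, hi = bounds
    if result.ci_low >= lo and result.ci_high <= hi:
        return "within"
    if result.ci_low > hi:
        return "above"
    if result.ci_high < lo:
        return "below"
    return "straddles"


def log_ratio_regression(
    x_ratios, y_ratios, scale: str = "log"
) -> tuple[float, float, float]:
    """OLS of one set of exposure ratios on another across subjects.

    Returns ``(r2, p, slope)`` where p is the two-sided slope p-value.
    Ratios are log-transformed by default (``scale='raw'`` skips it).
    """
    x = np.asarray(list(x_ratios), dtype=float)
    y = np.asarray(list(y_ratios), dtype=float)
    if len(x) != len(y):
        raise PairingError(f"unequal lengths {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise SampleSizeError(f"need n >= 3, got {len(x)}")
    if scale == "log":
        _check_positive(x, "x ratios")
        _check_positive(y, "y ratios")
        x, y = np.log(x), np.log(y)
    elif scale != "raw":
        raise ValueError(f"unknown scale {scale!r}")
    if np.ptp(x) == 0.0:
        raise DegenerateRegressionError("zero variance in x")
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2), float(fit.pvalue), float(fit.slope)
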