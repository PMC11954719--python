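"""Noncompartmental analysis of single-dose concentration-time profiles.

Implements the classic NCA estimators: terminal log-linear slope
(lambda_z, with adjusted-R2 point selection), half-life, linear-up/log-down
trapezoidal AUC with partial intervals, extrapolation to infinity, apparent
clearance CL/F and terminal volume Vz/F, dose normalization, and the
molar-sum total HMG-CoA reductase inhibitory activity.

Conventions (all standard Phoenix-compatible defaults, overridable):

* AUC segments use the linear trapezoid when concentration rises or is
  constant and the log trapezoid when it falls between two positive values;
  linear fallback when an endpoint is 0.
* lambda_z is fitted by log-linear least squares on the terminal subset of
  >= 3 points strictly after Tmax (Cmax excluded) maximizing adjusted R2;
  ties are broken toward more points.
* AUC_inf adds C_last_pred/lambda_z where C_last_pred is the regression
  prediction at the last quantifiable time (switchable to the observed value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataset_io import AnalyteSpec, ConcentrationProfile, MOLAR_UNIT
from .exceptions import (
    EmptyProfileError,
    ExtrapolationError,
    InsufficientDataError,
    NoTerminalPhaseError,
    UnitError,
)

LN2 = math.log(2.0)

#: slopes shallower than this (1/h) are treated as no terminal phase
_SLOPE_EPS = 1e-12


@dataclass(frozen=True)
class LambdaZFit:
    """Terminal log-linear regression result.

    ``t_half`` is ln2/lambda_z by construction.  ``intercept_log`` is the
    intercept of the log-concentration regression, so the predicted
    concentration at time t is ``exp(intercept_log - lambda_z * t)``.
    """

    lambda_z: float
    n_points: int
    adj_r2: float
    time_range: tuple[float, float]
    intercept_log: float

    @property
    def t_half(self) -> float:
        return LN2 / self.lambda_z

    def predict(self, time: float) -> float:
        return math.exp(self.intercept_log - self.lambda_z * time)


@dataclass
class NCAResult:
    """Exposure measures of a single profile.

    lambda_z-dependent fields (``auc_inf``, ``cl_f``, ``vz_f``, ...) are None
    when no terminal phase could be estimated; ``flags`` records why.
    """

    subject_id: str
    analyte: str
    occasion: str
    dose_ng: float
    cmax: float
    tmax: float
    auc_last: float
    lambda_z_fit: LambdaZFit | None = None
    auc_inf: float | None = None
    auc_extrap_pct: float | None = None
    cl_f: float | None = None  # mL/min
    vz_f: float | None = None  # L
    auc_tau: float | None = None
    partial_aucs: dict[tuple[float, float], float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def t_half(self) -> float | None:
        return self.lambda_z_fit.t_half if self.lambda_z_fit else None


def _fit_loglinear(t: np.ndarray, c: np.ndarray) -> tuple[float, float, float]:
    """OLS of log c on t; returns (slope, intercept, adjusted R2)."""
    y = np.log(c)
    n = len(t)
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res == 0.0 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return float(slope), float(intercept), adj_r2


def fit_lambda_z(
    profile: ConcentrationProfile,
    selection: str = "best_adj_r2",
    time_range: tuple[float, float] | None = None,
) -> LambdaZFit:
    """Estimate the terminal elimination rate constant lambda_z.

    ``selection='best_adj_r2'`` scans all contiguous terminal subsets of at
    least 3 positive-concentration points strictly after Tmax and returns the
    fit maximizing adjusted R2 (ties broken toward more points).
    ``selection='manual'`` uses the points inside ``time_range`` instead.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 eligible points.
    NoTerminalPhaseError
        The best (or manual) regression has a non-negative slope.
    """
    t, c = profile.observed()
    pos = c > 0
    t, c = t[pos], c[pos]
    if len(t) == 0:
        raise EmptyProfileError("no positive concentrations")
    i_max = int(np.argmax(c))  # earliest maximum by argmax convention
    after = t > t[i_max]
    t_el, c_el = t[after], c[after]

    if selection == "manual":
        if time_range is None:
            raise ValueError("manual selection requires time_range")
        lo, hi = time_range
        sel = (t_el >= lo) & (t_el <= hi)
        if sel.sum() < 3:
            raise InsufficientDataError(
                f"only {int(sel.sum())} points in manual range {time_range}"
            )
        slope, intercept, adj = _fit_loglinear(t_el[sel], c_el[sel])
        if slope >= -_SLOPE_EPS:
            raise NoTerminalPhaseError(f"non-negative terminal slope {slope:.4g}")
        return LambdaZFit(-slope, int(sel.sum()), adj,
                          (float(t_el[sel][0]), float(t_el[sel][-1])), intercept)

    if selection != "best_adj_r2":
        raise ValueError(f"unknown selection {selection!r}")
    n = len(t_el)
    if n < 3:
        raise InsufficientDataError(
            f"only {n} eligible points after Tmax (need >= 3)"
        )
    best: tuple[float, int, float, float] | None = None  # (adj, npts, slope, intercept)
    for start in range(n - 2):
        tt, cc = t_el[start:], c_el[start:]
        slope, intercept, adj = _fit_loglinear(tt, cc)
        if slope >= -_SLOPE_EPS:
            continue
        npts = len(tt)
        if best is None or adj > best[0] + 1e-12 or (abs(adj - best[0]) <= 1e-12 and npts > best[1]):
            best = (adj, npts, slope, intercept)
    if best is None:
        raise NoTerminalPhaseError("no terminal subset with negative slope")
    adj, npts, slope, intercept = best
    start = n - npts
    return LambdaZFit(-slope, npts, adj, (float(t_el[start]), float(t_el[-1])), intercept)


def _segment_auc(t1: float, c1: float, t2: float, c2: float) -> float:
    """AUC of one segment: linear up/equal, log down between positives."""
    dt = t2 - t1
    if c1 > 0 and c2 > 0 and c2 < c1:
        return (c1 - c2) * dt / math.log(c1 / c2)
    return 0.5 * (c1 + c2) * dt


def _interp_conc(t: np.ndarray, c: np.ndarray, x: float) -> float:
    """Concentration at x, log-interpolated within falling positive segments."""
    if x <= t[0]:
        return float(c[0]) if x == t[0] else 0.0
    i = int(np.searchsorted(t, x, side="right")) - 1
    if i >= len(t) - 1:
        return float(c[-1])
    t1, t2, c1, c2 = t[i], t[i + 1], c[i], c[i + 1]
    if x == t1:
        return float(c1)
    frac = (x - t1) / (t2 - t1)
    if c1 > 0 and c2 > 0 and c2 < c1:
        return float(c1 * (c2 / c1) ** frac)
    return float(c1 + frac * (c2 - c1))


def auc_linlog(
    profile: ConcentrationProfile,
    t_start: float,
    t_end: float,
    method: str = "linlog",
) -> float:
    """Partial AUC over [t_start, t_end] by the lin-up/log-down trapezoid.

    Interval ends falling between observations are handled by interpolation
    (log within falling positive segments, linear otherwise).  ``method`` may
    be ``'linear'`` for the pure linear trapezoid.
    """
    if not t_start < t_end:
        raise ValueError(f"need t_start < t_end, got {t_start}, {t_end}")
    t, c = profile.observed()
    if t_start < t[0] - 1e-12 or t_end > t[-1] + 1e-12:
        raise ExtrapolationError(
            f"[{t_start}, {t_end}] outside observed range [{t[0]}, {t[-1]}]"
        )
    seg = (
        _segment_auc
        if method == "linlog"
        else lambda t1, c1, t2, c2: 0.5 * (c1 + c2) * (t2 - t1)
    )
    # assemble node list: interval ends plus interior observations
    inner = [(float(tt), float(cc)) for tt, cc in zip(t, c) if t_start < tt < t_end]
    nodes = (
        [(t_start, _interp_conc(t, c, t_start))]
        + inner
        + [(t_end, _interp_conc(t, c, t_end))]
    )
    total = 0.0
    for (t1, c1), (t2, c2) in zip(nodes, nodes[1:]):
        total += seg(t1, c1, t2, c2)
    return total


def nca_summary(
    profile: ConcentrationProfile,
    tau: float | None = None,
    partial_intervals: tuple[tuple[float, float], ...] = (),
    lambda_z_selection: str = "best_adj_r2",
    lambda_z_range: tuple[float, float] | None = None,
    extrapolate_from: str = "predicted",
    auc_method: str = "linlog",
) -> NCAResult:
    """Full NCA of one LLOQ-processed profile.

    Cmax/Tmax ties are broken to the earliest time.  AUC_last runs to the last
    quantifiable observation; AUC_inf adds C_last/lambda_z with C_last the
    lambda_z-regression prediction (``extrapolate_from='observed'`` uses the
    observed value).  CL/F is returned in mL/min and Vz/F in L, matching the
    conventional reporting units.  lambda_z failures leave the dependent
    fields None and add a flag rather than raising.
    """
    t, c = profile.observed()
    if np.all(c == 0):
        raise EmptyProfileError("all concentrations zero")
    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])
    # last quantifiable (positive) observation
    pos_idx = np.nonzero(c > 0)[0]
    t_last, c_last_obs = float(t[pos_idx[-1]]), float(c[pos_idx[-1]])
    auc_last = auc_linlog(profile, float(t[0]), t_last, method=auc_method) if t_last > t[0] else 0.0

    result = NCAResult(
        subject_id=profile.subject_id,
        analyte=profile.analyte.name,
        occasion=profile.occasion,
        dose_ng=profile.dose_ng,
        cmax=cmax,
        tmax=tmax,
        auc_last=auc_last,
    )
    try:
        fit = fit_lambda_z(profile, selection=lambda_z_selection, time_range=lambda_z_range)
    except (InsufficientDataError, NoTerminalPhaseError, EmptyProfileError) as exc:
        result.flags.append(f"lambda_z: {exc}")
        fit = None
    if fit is not None:
        result.lambda_z_fit = fit
        c_tail = fit.predict(t_last) if extrapolate_from == "predicted" else c_last_obs
        result.auc_inf = auc_last + c_tail / fit.lambda_z
        result.auc_extrap_pct = 100.0 * (result.auc_inf - auc_last) / result.auc_inf
        # dose_ng / (h*ng/mL) = mL/h; /60 -> mL/min
        result.cl_f = profile.dose_ng / result.auc_inf / 60.0
        # CL [mL/h] / lambda_z [1/h] = mL; /1000 -> L
        result.vz_f = result.cl_f * 60.0 / fit.lambda_z / 1000.0
    if tau is not None:
        result.auc_tau = auc_linlog(profile, float(t[0]), min(tau, t_last), method=auc_method)
    for lo, hi in partial_intervals:
        result.partial_aucs[(lo, hi)] = auc_linlog(profile, lo, hi, method=auc_method)
    return result


def dose_normalized_auc(
    result: NCAResult, interval: tuple[float, float], reference_dose_ng: float
) -> float:
    """Partial AUC rescaled to a reference dose assuming linear PK."""
    if interval not in result.partial_aucs:
        raise KeyError(f"partial AUC {interval} not computed for this result")
    return result.partial_aucs[interval] * reference_dose_ng / result.dose_ng


def total_inhibitory_activity(
    results: list[tuple[AnalyteSpec, float]], unit: str = MOLAR_UNIT
) -> float:
    """Potency-weighted sum of molar AUC_inf values (h*nmol/L).

    The inputs must already be molar exposures; combining a mass-unit AUC is a
    :class:`UnitError`.  An empty list sums to 0.
    """
    if unit != MOLAR_UNIT:
        raise UnitError(f"total activity requires molar AUCs, got unit {unit!r}")
    return float(sum(spec.potency_weight * auc for spec, auc in results))
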