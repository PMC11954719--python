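"""Estimation of interaction-model parameters from trial concentration data.

The entry point is :class:`StatinDDIModel`, a model object built from a
:class:`~ritopk.dataset_io.TrialDataset` whose :meth:`~StatinDDIModel.fit`
returns a :class:`DDIFitResults` carrying estimates, standard errors, the
-2 log-likelihood, and a ``summary()`` table.

Two estimators are provided:

``pooled``
    Naive-pooled Gaussian maximum likelihood on log concentrations: all
    subjects share one parameter vector, the proportional residual becomes
    additive on the log scale and its variance is profiled out, so the
    optimizer minimizes the log-scale residual sum of squares.  Parameters
    are transformed internally (log for positive quantities, logit for
    theta_f, log(theta_d - 1) for the duration factor) to enforce their
    domains.

``two_stage``
    Per-subject fits of {F_rel, CL/F, Vc/F} with the remaining parameters
    held at their initial values; the population estimate is the geometric
    mean of the subject estimates and the between-subject log-SD is reported
    as the inter-individual variability omega.

Both are transparent, testable substitutes for full nonlinear mixed-effects
estimation; with this trial's rich sampling (17 points per occasion) the
pooled estimates of the shared modulation factors are comparable.
BLQ observations are excluded from the objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from .dataset_io import (
    OCCASION_BASELINE,
    OCCASION_RITONAVIR,
    TrialDataset,
)
from .ddi_model import (
    DDIModelParams,
    DoseEvent,
    DRUG_STATIN,
    ritonavir_bid_events,
    simulate_concentrations,
)
from .exceptions import (
    ComparabilityError,
    InsufficientDataError,
    SampleSizeError,
    ValidationError,
)

DEFAULT_FREE = ("cl_f_base", "vc_f", "q_f", "vp_f", "d0", "theta_f", "theta_d")
TWO_STAGE_SUBJECT_PARAMS = ("f_rel_base", "cl_f_base", "vc_f")

_LOG_PARAMS = {
    "cl_f_base", "vc_f", "q_f", "vp_f", "d0", "f_rel_base", "k_deg", "k_inact",
}


def _to_internal(name: str, value: float) -> float:
    if name in _LOG_PARAMS:
        return math.log(value)
    if name in ("theta_f", "theta_cl"):
        v = min(max(value, 1e-9), 1 - 1e-9)
        return math.log(v / (1.0 - v))
    if name == "theta_d":
        return math.log(max(value - 1.0, 1e-9))
    raise ValidationError(f"parameter {name!r} is not fittable")


def _to_natural(name: str, x: float) -> float:
    if name in _LOG_PARAMS:
        return math.exp(x)
    if name in ("theta_f", "theta_cl"):
        return 1.0 / (1.0 + math.exp(-x))
    if name == "theta_d":
        return 1.0 + math.exp(x)
    raise ValidationError(f"parameter {name!r} is not fittable")


def _natural_jacobian(name: str, x: float) -> float:
    """d natural / d internal, for delta-method standard errors."""
    if name in _LOG_PARAMS:
        return math.exp(x)
    if name in ("theta_f", "theta_cl"):
        s = 1.0 / (1.0 + math.exp(-x))
        return s * (1.0 - s)
    if name == "theta_d":
        return math.exp(x)
    raise ValidationError(name)


@dataclass
class _ObsBlock:
    """Observations of one occasion x dose group, pooled across subjects."""

    occasion: str
    dose_ng: float
    unique_times: np.ndarray   # sorted unique sample times (relative to statin dose)
    time_index: np.ndarray     # index of each observation into unique_times
    log_conc: np.ndarray


def _collect_blocks(dataset: TrialDataset, analyte: str) -> tuple[list[_ObsBlock], int]:
    groups: dict[tuple[str, float], list[tuple[float, float]]] = {}
    for p in dataset.select(analyte=analyte):
        if p.occasion not in (OCCASION_BASELINE, OCCASION_RITONAVIR):
            continue
        for r in p.records:
            if r.blq or r.concentration is None or r.concentration <= 0:
                continue
            groups.setdefault((p.occasion, p.dose_ng), []).append(
                (r.time, math.log(r.concentration))
            )
    blocks: list[_ObsBlock] = []
    n_obs = 0
    for (occ, dose), pairs in sorted(groups.items()):
        t = np.array([a for a, _ in pairs])
        y = np.array([b for _, b in pairs])
        ut, idx = np.unique(t, return_inverse=True)
        blocks.append(_ObsBlock(occ, dose, ut, idx, y))
        n_obs += len(y)
    if n_obs == 0:
        raise InsufficientDataError("dataset has no quantifiable observations")
    return blocks, n_obs


def _predict_block(params: DDIModelParams, block: _ObsBlock, engine: str) -> np.ndarray:
    if block.occasion == OCCASION_BASELINE:
        conc = simulate_concentrations(
            params, [DoseEvent(0.0, DRUG_STATIN, block.dose_ng)], [],
            block.unique_times, engine=engine,
        )
    else:
        conc = simulate_concentrations(
            params,
            [DoseEvent(96.0, DRUG_STATIN, block.dose_ng)],
            ritonavir_bid_events(),
            block.unique_times + 96.0,
            engine=engine,
        )
    return conc[block.time_index]


@dataclass
class DDIFitResults:
    """Estimation results: point estimates, SEs, likelihood and diagnostics.

    ``objective`` is the Gaussian -2 log-likelihood on the log-concentration
    scale with the residual variance profiled out.  ``estimates``/``bse`` are
    on the natural parameter scale (SEs by the delta method from the internal
    transform).  ``per_subject`` holds the subject-level estimates for the
    two-stage method.
    """

    method: str
    estimates: dict[str, float]
    bse: dict[str, float]
    objective: float
    n_obs: int
    converged: bool
    free: tuple[str, ...]
    params: DDIModelParams
    sigma: float | None = None
    per_subject: dict[str, dict[str, float]] | None = None
    iiv_omega: dict[str, float] | None = None
    excluded_subjects: list[str] = field(default_factory=list)
    n_iter: int = 0

    @property
    def aic(self) -> float:
        return self.objective + 2.0 * len(self.free)

    def summary(self) -> str:
        lines = [
            "Statin-ritonavir interaction model fit",
            "=" * 54,
            f"method:      {self.method}",
            f"n_obs:       {self.n_obs}",
            f"-2 log L:    {self.objective:.3f}",
            f"AIC:         {self.aic:.3f}",
            f"converged:   {self.converged}",
        ]
        if self.sigma is not None:
            lines.append(f"sigma (log): {self.sigma:.4f}")
        lines.append("-" * 54)
        lines.append(f"{'parameter':<14}{'estimate':>12}{'std err':>12}")
        for name in self.free:
            se = self.bse.get(name)
            se_str = f"{se:>12.4g}" if se is not None and np.isfinite(se) else f"{'--':>12}"
            lines.append(f"{name:<14}{self.estimates[name]:>12.4g}{se_str}")
        if self.iiv_omega:
            lines.append("-" * 54)
            for name, om in self.iiv_omega.items():
                lines.append(f"omega({name}):  {om:.4f}")
        if self.excluded_subjects:
            lines.append(f"excluded subjects: {', '.join(self.excluded_subjects)}")
        return "\n".join(lines)


class StatinDDIModel:
    """Semi-mechanistic interaction model bound to a trial dataset.

    Parameters
    ----------
    dataset : TrialDataset
        Concentration data with ``baseline`` and ``ritonavir_day5`` occasions.
    analyte : str
        Analyte to fit (default atorvastatin; the mechanistic model targets it).
    init : DDIModelParams, optional
        Starting values; defaults to the package's calibrated defaults.
    free : sequence of str, optional
        Parameter names estimated by the pooled fit.
    engine : str
        Simulation engine passed through to the forward model.
    """

    def __init__(
        self,
        dataset: TrialDataset,
        analyte: str = "atorvastatin",
        init: DDIModelParams | None = None,
        free: Sequence[str] = DEFAULT_FREE,
        engine: str = "analytic",
    ) -> None:
        self.dataset = dataset
        self.analyte = analyte
        self.init = init if init is not None else DDIModelParams()
        self.free = tuple(free)
        self.engine = engine
        self._blocks, self.n_obs = _collect_blocks(dataset, analyte)
        occasions = {b.occasion for b in self._blocks}
        if OCCASION_BASELINE not in occasions or OCCASION_RITONAVIR not in occasions:
            raise InsufficientDataError(
                f"need both occasions, found {sorted(occasions)}"
            )

    @classmethod
    def from_csv(cls, path, **kwargs) -> "StatinDDIModel":
        from .dataset_io import load_dataset

        return cls(load_dataset(path), **kwargs)

    # -- objective ---------------------------------------------------------
    def _params_from_vector(self, x: np.ndarray, free: tuple[str, ...],
                            base: DDIModelParams) -> DDIModelParams:
        updates = {name: _to_natural(name, xi) for name, xi in zip(free, x)}
        return replace(base, **updates)

    def _ssr(self, params: DDIModelParams, blocks: list[_ObsBlock]) -> float:
        total = 0.0
        for block in blocks:
            pred = _predict_block(params, block, self.engine)
            resid = block.log_conc - np.log(np.clip(pred, 1e-12, None))
            total += float(resid @ resid)
        return total

    def _neg2ll_from_ssr(self, ssr: float, n: int) -> float:
        sigma2 = max(ssr / n, 1e-300)
        return n * math.log(2.0 * math.pi * sigma2) + n

    def loglike_neg2(self, params: DDIModelParams) -> float:
        """Direct -2 log-likelihood evaluation at a parameter set."""
        ssr = self._ssr(params, self._blocks)
        return self._neg2ll_from_ssr(ssr, self.n_obs)

    # -- estimators --------------------------------------------------------
    def fit(self, method: str = "pooled", **kwargs) -> DDIFitResults:
        if method == "pooled":
            return self._fit_pooled(**kwargs)
        if method in ("two_stage", "two-stage"):
            return self._fit_two_stage(**kwargs)
        raise ValueError(f"unknown method {method!r}")

    def _fit_pooled(
        self,
        fixed: Sequence[str] = (),
        maxiter: int = 4000,
        polish: bool = True,
    ) -> DDIFitResults:
        free = tuple(name for name in self.free if name not in set(fixed))
        base = self.init
        if not free:
            obj = self.loglike_neg2(base)
            return DDIFitResults(
                method="pooled", estimates={}, bse={}, objective=obj,
                n_obs=self.n_obs, converged=True, free=(), params=base,
                sigma=math.sqrt(self._ssr(base, self._blocks) / self.n_obs),
            )
        x0 = np.array([_to_internal(name, getattr(base, name)) for name in free])

        def fun(x: np.ndarray) -> float:
            try:
                params = self._params_from_vector(x, free, base)
            except ValidationError:
                return 1e12
            return self._ssr(params, self._blocks)

        res = optimize.minimize(
            fun, x0, method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-7, "fatol": 1e-10, "adaptive": True},
        )
        x_best, converged, n_iter = res.x, bool(res.success), int(res.nit)
        if polish:
            res2 = optimize.minimize(fun, x_best, method="L-BFGS-B",
                                     options={"maxiter": 500})
            if res2.fun <= res.fun:
                x_best = res2.x
                converged = converged or bool(res2.success)
        ssr = fun(x_best)
        objective = self._neg2ll_from_ssr(ssr, self.n_obs)
        params = self._params_from_vector(x_best, free, base)
        estimates = {name: getattr(params, name) for name in free}
        bse = self._standard_errors(x_best, free, base)
        return DDIFitResults(
            method="pooled",
            estimates=estimates,
            bse=bse,
            objective=objective,
            n_obs=self.n_obs,
            converged=converged,
            free=free,
            params=params,
            sigma=math.sqrt(ssr / self.n_obs),
            n_iter=n_iter,
        )

    def _standard_errors(
        self, x: np.ndarray, free: tuple[str, ...], base: DDIModelParams
    ) -> dict[str, float]:
        """Delta-method SEs from a central-difference Hessian of -2LL."""
        n = len(x)

        def neg2ll(xv: np.ndarray) -> float:
            try:
                params = self._params_from_vector(xv, free, base)
            except ValidationError:
                return 1e12
            return self._neg2ll_from_ssr(self._ssr(params, self._blocks), self.n_obs)

        h = 1e-4 * np.maximum(np.abs(x), 1.0)
        hess = np.empty((n, n))
        f0 = neg2ll(x)
        for i in range(n):
            for j in range(i, n):
                xi, xj = h[i], h[j]
                xpp = x.copy(); xpp[i] += xi; xpp[j] += xj
                xpm = x.copy(); xpm[i] += xi; xpm[j] -= xj
                xmp = x.copy(); xmp[i] -= xi; xmp[j] += xj
                xmm = x.copy(); xmm[i] -= xi; xmm[j] -= xj
                if i == j:
                    hess[i, i] = (neg2ll(xpp) - 2.0 * f0 + neg2ll(xmm)) / (4.0 * xi * xj)
                else:
                    hess[i, j] = hess[j, i] = (
                        neg2ll(xpp) - neg2ll(xpm) - neg2ll(xmp) + neg2ll(xmm)
                    ) / (4.0 * xi * xj)
        bse: dict[str, float] = {}
        try:
            cov = 2.0 * np.linalg.inv(hess)
            for i, name in enumerate(free):
                var = cov[i, i]
                if var > 0:
                    bse[name] = _natural_jacobian(name, x[i]) * math.sqrt(var)
                else:
                    bse[name] = float("nan")
        except np.linalg.LinAlgError:
            bse = {name: float("nan") for name in free}
        return bse

    def _fit_two_stage(self, min_obs_per_subject: int = 6) -> DDIFitResults:
        subjects = sorted(
            {p.subject_id for p in self.dataset.select(analyte=self.analyte)}
        )
        if len(subjects) < 2:
            raise SampleSizeError(
                f"two-stage estimation needs >= 2 subjects, got {len(subjects)}"
            )
        per_subject: dict[str, dict[str, float]] = {}
        excluded: list[str] = []
        total_ssr, total_n = 0.0, 0
        for sid in subjects:
            sub = TrialDataset(
                profiles=[
                    p for p in self.dataset.profiles
                    if p.subject_id == sid and p.analyte.name == self.analyte
                ]
            )
            try:
                blocks, n_obs = _collect_blocks(sub, self.analyte)
            except InsufficientDataError:
                excluded.append(sid)
                continue
            if n_obs < min_obs_per_subject:
                excluded.append(sid)
                continue
            x0 = np.array(
                [_to_internal(n_, getattr(self.init, n_)) for n_ in TWO_STAGE_SUBJECT_PARAMS]
            )

            def fun(x: np.ndarray) -> float:
                updates = {
                    n_: _to_natural(n_, xi)
                    for n_, xi in zip(TWO_STAGE_SUBJECT_PARAMS, x)
                }
                try:
                    params = replace(self.init, **updates)
                except ValidationError:
                    return 1e12
                return self._ssr(params, blocks)

            res = optimize.minimize(
                fun, x0, method="Nelder-Mead",
                options={"maxiter": 2000, "xatol": 1e-7, "fatol": 1e-10, "adaptive": True},
            )
            if not res.success and res.fun >= fun(x0):
                excluded.append(sid)
                continue
            per_subject[sid] = {
                n_: _to_natural(n_, xi)
                for n_, xi in zip(TWO_STAGE_SUBJECT_PARAMS, res.x)
            }
            total_ssr += float(res.fun)
            total_n += n_obs
        if len(per_subject) < 2:
            raise SampleSizeError(
                f"only {len(per_subject)} subject(s) converged in two-stage fit"
            )
        estimates: dict[str, float] = {}
        omega: dict[str, float] = {}
        for name in TWO_STAGE_SUBJECT_PARAMS:
            logs = np.log([per_subject[s][name] for s in per_subject])
            estimates[name] = float(np.exp(logs.mean()))
            omega[name] = float(logs.std(ddof=1))
        params = replace(self.init, **estimates)
        objective = self._neg2ll_from_ssr(max(total_ssr, 1e-300), max(total_n, 1))
        return DDIFitResults(
            method="two_stage",
            estimates=estimates,
            bse={
                name: omega[name] / math.sqrt(len(per_subject)) * estimates[name]
                for name in estimates
            },
            objective=objective,
            n_obs=total_n,
            converged=True,
            free=tuple(TWO_STAGE_SUBJECT_PARAMS),
            params=params,
            per_subject=per_subject,
            iiv_omega=omega,
            excluded_subjects=excluded,
        )


def fit_pooled(
    dataset: TrialDataset,
    init: DDIModelParams | None = None,
    fixed: Sequence[str] = (),
    free: Sequence[str] = DEFAULT_FREE,
    **kwargs,
) -> DDIFitResults:
    """Pooled nonlinear least-squares / ML fit (see :class:`StatinDDIModel`)."""
    model = StatinDDIModel(dataset, init=init, free=free)
    return model.fit(method="pooled", fixed=fixed, **kwargs)


def fit_two_stage(
    dataset: TrialDataset, init: DDIModelParams | None = None, **kwargs
) -> DDIFitResults:
    """Two-stage estimation with subject-level {F_rel, CL/F, Vc/F}."""
    model = StatinDDIModel(dataset, init=init)
    return model.fit(method="two_stage", **kwargs)


def compare_models(a: DDIFitResults, b: DDIFitResults) -> dict:
    """Likelihood/AIC comparison of two fits of the same data.

    Returns a record with ``delta_objective`` and ``delta_aic`` (b minus a)
    and ``preferred`` in {'a', 'b', 'tie'} by lower AIC.
    """
    if a.n_obs != b.n_obs:
        raise ComparabilityError(
            f"fits are not comparable: n_obs {a.n_obs} vs {b.n_obs}"
        )
    d_obj = b.objective - a.objective
    d_aic = b.aic - a.aic
    if abs(d_aic) < 1e-9:
        preferred = "tie"
    else:
        preferred = "a" if d_aic > 0 else "b"
    return {
        "delta_objective": d_obj,
        "delta_aic": d_aic,
        "preferred": preferred,
        "aic_a": a.aic,
        "aic_b": b.aic,
    }
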