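"""Steady-state dosing-scheme simulation and dose-adjustment rules.

Simulates a patient on once-daily statin at steady state who starts a 5-day
ritonavir-boosted antiviral course, under six named adjustment scenarios
(plus custom schedules), and reports daily Cmax/Cmin/AUC24 relative to the
unperturbed steady-state day.

Grid conventions: the statin is dosed at hour 0 of each day and ritonavir at
hours 0 and 12 of treatment days 1-5.  The run-in (default 7 days, well over
five ~9-h half-lives) establishes steady state; the last run-in day is the
baseline reference and its day-over-day AUC24 drift must be below 1%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataset_io import NG_PER_MG
from .ddi_model import (
    DDIModelParams,
    DoseEvent,
    DRUG_RITONAVIR,
    DRUG_STATIN,
    simulate_concentrations,
)
from .exceptions import AnalyteLookupError, DomainError, SteadyStateError, ValidationError

SCENARIO_NAMES = (
    "a_no_adjustment",
    "b_interruption",
    "c_every_second_day",
    "d_half_days1_10",
    "e_quarter_days1_7",
    "f_mixed",
)

_NAMED_FRACTIONS = {0.0, 0.25, 0.5, 1.0}

#: Default horizon (days from the first ritonavir day) long enough to show
#: full enzyme recovery (~1/k_deg = 33 h time constant after day 5).
DEFAULT_N_DAYS = 16
DEFAULT_RUN_IN_DAYS = 7
RITONAVIR_DAYS = (1, 5)  # inclusive day range of the antiviral course


@dataclass(frozen=True)
class DoseScenario:
    """A named or custom multi-day statin dosing schedule.

    ``statin_doses`` holds (day, fraction-of-original-dose) for days 1..n;
    day 1 is the first ritonavir day.  Run-in days before day 1 always use
    the full original dose.
    """

    name: str
    original_dose_mg: float
    statin_doses: tuple[tuple[int, float], ...]
    ritonavir_days: tuple[int, int] = RITONAVIR_DAYS
    run_in_days: int = DEFAULT_RUN_IN_DAYS

    def __post_init__(self) -> None:
        if not self.original_dose_mg > 0:
            raise DomainError(f"dose must be > 0, got {self.original_dose_mg}")
        if self.run_in_days < 2:
            raise ValidationError("run_in_days must be >= 2")
        if self.name in SCENARIO_NAMES:
            bad = [f for _, f in self.statin_doses if f not in _NAMED_FRACTIONS]
            if bad:
                raise ValidationError(f"named scenarios use fractions {{0, 1/4, 1/2, 1}}, got {bad}")

    @property
    def n_days(self) -> int:
        return max(d for d, _ in self.statin_doses)

    def fractions(self) -> dict[int, float]:
        return dict(self.statin_doses)


def _scenario_fractions(name: str, n_days: int) -> list[tuple[int, float]]:
    out = []
    for day in range(1, n_days + 1):
        if name == "a_no_adjustment":
            f = 1.0
        elif name == "b_interruption":
            # no statin while ritonavir runs and for 2 days after (resume day 8)
            f = 0.0 if day <= 7 else 1.0
        elif name == "c_every_second_day":
            f = 1.0 if day % 2 == 1 else 0.0
        elif name == "d_half_days1_10":
            f = 0.5 if day <= 10 else 1.0
        elif name == "e_quarter_days1_7":
            f = 0.25 if day <= 7 else 1.0
        elif name == "f_mixed":
            # full day 1, half day 2, quarter days 3-6, half days 7-9, full from day 10
            if day == 1:
                f = 1.0
            elif day == 2:
                f = 0.5
            elif day <= 6:
                f = 0.25
            elif day <= 9:
                f = 0.5
            else:
                f = 1.0
        else:
            raise AnalyteLookupError(f"unknown scenario {name!r}")
        out.append((day, f))
    return out


def build_scenario(
    name: str,
    original_dose_mg: float,
    n_days: int = DEFAULT_N_DAYS,
    run_in_days: int = DEFAULT_RUN_IN_DAYS,
    custom_fractions: dict[int, float] | None = None,
) -> DoseScenario:
    """Expand a named scenario (or a custom day->fraction map) day by day."""
    if name == "custom":
        if not custom_fractions:
            raise ValidationError("custom scenario requires custom_fractions")
        doses = tuple(sorted(custom_fractions.items()))
    else:
        doses = tuple(_scenario_fractions(name, n_days))
    return DoseScenario(
        name=name,
        original_dose_mg=original_dose_mg,
        statin_doses=doses,
        run_in_days=run_in_days,
    )


@dataclass
class ExposureMetrics:
    """Per-day exposure metrics of a scenario run, relative to steady state."""

    days: list[int]
    cmax: np.ndarray        # ng/mL per day
    cmin: np.ndarray
    auc24: np.ndarray       # h*ng/mL per day
    baseline_cmax: float
    baseline_cmin: float
    baseline_auc24: float
    subtherapeutic_days: int
    subtherapeutic_fraction: float

    @property
    def cmax_ratio(self) -> np.ndarray:
        return self.cmax / self.baseline_cmax

    @property
    def auc_ratio(self) -> np.ndarray:
        return self.auc24 / self.baseline_auc24

    @property
    def peak_cmax_ratio(self) -> float:
        return float(self.cmax_ratio.max())

    @property
    def peak_auc_ratio(self) -> float:
        return float(self.auc_ratio.max())


def run_scenario(
    params: DDIModelParams,
    scenario: DoseScenario,
    subtherapeutic_fraction: float = 0.5,
    grid_dt: float = 0.05,
    engine: str = "analytic",
) -> ExposureMetrics:
    """Simulate run-in plus scenario and compute daily exposure metrics.

    A day with AUC24 below ``subtherapeutic_fraction`` of the steady-state
    AUC24 counts as subtherapeutic.  Raises :class:`SteadyStateError` when
    the run-in has not converged (day-over-day AUC24 drift >= 1%).
    """
    run_in = scenario.run_in_days
    n_days = scenario.n_days
    dose_ng = scenario.original_dose_mg * NG_PER_MG
    statin_events = [
        DoseEvent(24.0 * d, DRUG_STATIN, dose_ng) for d in range(run_in)
    ]
    for day, frac in scenario.statin_doses:
        if frac > 0:
            statin_events.append(
                DoseEvent(24.0 * (run_in + day - 1), DRUG_STATIN, dose_ng * frac)
            )
    lo, hi = scenario.ritonavir_days
    rtv_events = [
        DoseEvent(24.0 * (run_in + d - 1) + off, DRUG_RITONAVIR, 100.0 * NG_PER_MG)
        for d in range(lo, hi + 1)
        for off in (0.0, 12.0)
    ]
    t_end = 24.0 * (run_in + n_days)
    times = np.arange(0.0, t_end + grid_dt / 2, grid_dt)
    conc = simulate_concentrations(params, statin_events, rtv_events, times, engine=engine)

    def day_metrics(day_offset: int) -> tuple[float, float, float]:
        """Metrics over [24*day_offset, 24*(day_offset+1)] on the grid."""
        mask = (times >= 24.0 * day_offset - 1e-9) & (times <= 24.0 * (day_offset + 1) + 1e-9)
        c, t = conc[mask], times[mask]
        return float(c.max()), float(c.min()), float(np.trapezoid(c, t))

    # steady-state check on the last two run-in days
    *_, auc_prev = day_metrics(run_in - 2)
    base_cmax, base_cmin, base_auc = day_metrics(run_in - 1)
    drift = abs(base_auc - auc_prev) / base_auc
    if drift >= 0.01:
        raise SteadyStateError(
            f"run-in not at steady state: day-over-day AUC24 drift {drift:.2%}"
        )

    days = list(range(1, n_days + 1))
    cmax = np.empty(n_days)
    cmin = np.empty(n_days)
    auc24 = np.empty(n_days)
    for i, day in enumerate(days):
        cmax[i], cmin[i], auc24[i] = day_metrics(run_in + day - 1)
    subth = int(np.sum(auc24 < subtherapeutic_fraction * base_auc))
    return ExposureMetrics(
        days=days,
        cmax=cmax,
        cmin=cmin,
        auc24=auc24,
        baseline_cmax=base_cmax,
        baseline_cmin=base_cmin,
        baseline_auc24=base_auc,
        subtherapeutic_days=subth,
        subtherapeutic_fraction=subtherapeutic_fraction,
    )


@dataclass(frozen=True)
class DoseRecommendation:
    """Structured dose-adjustment advice for a ritonavir course."""

    maintenance_dose_mg: float
    fraction: float
    reduced_dose_mg: float
    reduced_days: tuple[int, int] | None  # inclusive day range, None = no change
    resume_day: int | None
    requires_quartering: bool
    note: str

    def describe(self) -> str:
        if self.reduced_days is None:
            return (
                f"{self.maintenance_dose_mg:g} mg: keep the original dose "
                f"throughout the antiviral course. {self.note}"
            )
        lo, hi = self.reduced_days
        text = (
            f"{self.maintenance_dose_mg:g} mg: take {self.reduced_dose_mg:g} mg "
            f"({self.fraction:g} of the original dose) on days {lo}-{hi} "
            f"(until 2 days after the last ritonavir dose), resume "
            f"{self.maintenance_dose_mg:g} mg from day {self.resume_day}. {self.note}"
        )
        if self.requires_quartering:
            text += " Note: this fraction requires dividing tablets into quarters."
        return text


def recommend_dose(
    maintenance_dose_mg: float, ritonavir_days: tuple[int, int] = RITONAVIR_DAYS
) -> DoseRecommendation:
    """Dose-adjustment rule for a daily statin during a short ritonavir course.

    10 mg: keep the original dose.  20 mg: half the dose until 2 days after
    ritonavir ends.  40 mg or more: a quarter of the dose until 2 days after
    ritonavir ends.  Arbitrary positive doses are mapped to the nearest rule
    (noted in the recommendation text).
    """
    if not maintenance_dose_mg > 0:
        raise DomainError(f"dose must be > 0, got {maintenance_dose_mg}")
    end = ritonavir_days[1] + 2  # reduced until 2 days after the course
    if maintenance_dose_mg < 15.0:
        note = "Exposure stays within the range of the maximum licensed dose."
        if maintenance_dose_mg != 10.0:
            note += " (nearest rule: 10 mg -> unchanged)"
        return DoseRecommendation(
            maintenance_dose_mg, 1.0, maintenance_dose_mg, None, None, False, note
        )
    if maintenance_dose_mg < 30.0:
        fraction = 0.5
        note = "" if maintenance_dose_mg == 20.0 else "(nearest rule: 20 mg -> half dose)"
    else:
        fraction = 0.25
        note = "" if maintenance_dose_mg >= 40.0 else "(nearest rule: >=40 mg -> quarter dose)"
    return DoseRecommendation(
        maintenance_dose_mg=maintenance_dose_mg,
        fraction=fraction,
        reduced_dose_mg=maintenance_dose_mg * fraction,
        reduced_days=(1, end),
        resume_day=end + 1,
        requires_quartering=fraction == 0.25,
        note=note,
    )
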