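"""Seeded virtual-trial generator.

Emulates the paired single-dose statin trial: 8 subjects, a 10-mg statin
dose at baseline and again on day 5 of ritonavir 100 mg BID, the 17-point
sampling schedule, log-normal inter-individual variability on relative
bioavailability / apparent clearance / central volume, proportional
(log-normal) residual error and LLOQ censoring.

Atorvastatin occasions are simulated mechanistically through the
two-compartment/CYP-turnover model.  Rosuvastatin is generated from an
empirical one-compartment first-order-absorption model in which ritonavir
accelerates absorption and shrinks the apparent central volume while leaving
F and CL untouched: AUC is preserved, Cmax rises ~1.94-fold and Tmax moves
earlier, mirroring the statistics-level behaviour of the observed data (no
mechanistic transporter model is attempted).

All randomness derives from ``numpy.random.default_rng`` streams keyed by
(seed, subject index, occasion), so identical configs produce byte-identical
datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dataset_io import (
    DEFAULT_ANALYTES,
    NG_PER_MG,
    OCCASION_BASELINE,
    OCCASION_RITONAVIR,
    ConcentrationProfile,
    ConcentrationRecord,
    TrialDataset,
)
from .ddi_model import (
    DDIModelParams,
    DoseEvent,
    DRUG_STATIN,
    TRIAL_SAMPLING_TIMES,
    ritonavir_bid_events,
    simulate_concentrations,
)
from .exceptions import AnalyteLookupError, DomainError, ValidationError

STATIN_MECHANISTIC = "atorvastatin_mechanistic"
STATIN_EMPIRICAL = "rosuvastatin_empirical"

#: Empirical rosuvastatin parameters (apparent, per bioavailability):
#: CL/F 257 L/h reproduces the baseline AUC_inf of ~38.9 h*ng/mL for 10 mg;
#: V/F and ka give the observed baseline Tmax ~4 h and half-life ~11 h.
#: Ritonavir raises ka and shrinks V/F (Cmax ratio ~1.94, earlier Tmax)
#: with F and CL unchanged so AUC is preserved.
ROSU_CL_F = 257.0      # L/h
ROSU_V_F = 4030.0      # L
ROSU_KA_BASE = 0.65    # 1/h
ROSU_KA_RTV = 6.0      # 1/h
ROSU_V_SHRINK = 1.65   # V/F divisor on the ritonavir occasion

#: IIV omega -> DDIModelParams field
_OMEGA_FIELDS = {"f_rel": "f_rel_base", "cl_f": "cl_f_base", "vc_f": "vc_f"}


@dataclass(frozen=True)
class OutlierSpec:
    """Direction-reversed interaction for one subject (exposure ratio target)."""

    subject_index: int = 0
    factor: float = 0.45


@dataclass
class TrialGeneratorConfig:
    """Virtual-trial configuration; defaults are the trial's design values."""

    n_subjects: int = 8
    sampling_times: tuple = TRIAL_SAMPLING_TIMES
    statin: str = STATIN_MECHANISTIC
    dose_mg: float = 10.0
    params: DDIModelParams = field(default_factory=DDIModelParams)
    omega: dict = field(default_factory=lambda: {"f_rel": 0.4, "cl_f": 0.4, "vc_f": 0.4})
    sigma_prop: float = 0.15
    lloq_censor: bool = True
    outlier: OutlierSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        times = tuple(self.sampling_times)
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("sampling_times must be strictly increasing")
        if self.n_subjects < 2:
            raise ValidationError(f"n_subjects must be >= 2, got {self.n_subjects}")
        if self.sigma_prop < 0:
            raise ValidationError("sigma_prop must be >= 0")
        if self.statin not in (STATIN_MECHANISTIC, STATIN_EMPIRICAL):
            raise ValidationError(f"unknown statin kind {self.statin!r}")
        for key, om in self.omega.items():
            if key not in _OMEGA_FIELDS:
                raise ValidationError(f"unknown omega key {key!r}")
            if om < 0:
                raise DomainError(f"omega[{key!r}] must be >= 0")


def sample_individual_params(
    config: TrialGeneratorConfig, subject_index: int
) -> DDIModelParams:
    """Subject-level parameters: population values times exp(omega * z).

    Deterministic given (config.seed, subject_index); the z-draws come from
    an rng keyed by both.
    """
    rng = np.random.default_rng([config.seed, subject_index])
    updates = {}
    for key in sorted(_OMEGA_FIELDS):
        om = config.omega.get(key, 0.0)
        if om < 0:
            raise DomainError(f"omega[{key!r}] must be >= 0")
        z = rng.standard_normal()
        field_name = _OMEGA_FIELDS[key]
        updates[field_name] = getattr(config.params, field_name) * math.exp(om * z)
    return replace(config.params, **updates)


def _empirical_rosuvastatin_conc(
    params: DDIModelParams, dose_ng: float, times: np.ndarray, ritonavir: bool
) -> np.ndarray:
    """One-compartment first-order absorption curve for the empirical arm.

    The subject's IIV multipliers (relative to the mechanistic defaults) are
    reused as multipliers on the empirical F, CL and V.
    """
    defaults = DDIModelParams()
    f_mult = params.f_rel_base / defaults.f_rel_base
    cl_mult = params.cl_f_base / defaults.cl_f_base
    v_mult = params.vc_f / defaults.vc_f
    cl = ROSU_CL_F * cl_mult                       # L/h
    v = ROSU_V_F * v_mult / (ROSU_V_SHRINK if ritonavir else 1.0)  # L
    ka = ROSU_KA_RTV if ritonavir else ROSU_KA_BASE
    ke = cl / v
    if abs(ka - ke) < 1e-12:
        ka *= 1.0 + 1e-9
    v_ml = v * 1000.0
    amp = f_mult * dose_ng / v_ml * ka / (ka - ke)
    t = np.clip(times, 0.0, None)
    return amp * (np.exp(-ke * t) - np.exp(-ka * t)) * (times >= 0)


def _observe(
    conc: np.ndarray,
    times: np.ndarray,
    rng: np.random.Generator,
    sigma: float,
    lloq: float,
    censor: bool,
) -> tuple[ConcentrationRecord, ...]:
    noise = np.exp(sigma * rng.standard_normal(len(conc))) if sigma > 0 else 1.0
    observed = conc * noise
    records = []
    for t, c in zip(times, observed):
        if censor and c < lloq:
            records.append(ConcentrationRecord(float(t), None, blq=True))
        else:
            records.append(ConcentrationRecord(float(t), float(c), blq=False))
    return tuple(records)


def generate_trial(config: TrialGeneratorConfig) -> TrialDataset:
    """Generate the paired two-occasion dataset for all subjects."""
    times = np.asarray(config.sampling_times, dtype=float)
    dose_ng = config.dose_mg * NG_PER_MG
    mechanistic = config.statin == STATIN_MECHANISTIC
    analyte = DEFAULT_ANALYTES["atorvastatin" if mechanistic else "rosuvastatin"]
    rtv_events = ritonavir_bid_events()

    profiles: list[ConcentrationProfile] = []
    for i in range(config.n_subjects):
        subject_id = f"S{i + 1:02d}"
        p_i = sample_individual_params(config, i)
        for occ_idx, occasion in enumerate((OCCASION_BASELINE, OCCASION_RITONAVIR)):
            if mechanistic:
                if occasion == OCCASION_BASELINE:
                    conc = simulate_concentrations(
                        p_i, [DoseEvent(0.0, DRUG_STATIN, dose_ng)], [], times
                    )
                else:
                    conc = simulate_concentrations(
                        p_i,
                        [DoseEvent(96.0, DRUG_STATIN, dose_ng)],
                        rtv_events,
                        times + 96.0,
                    )
            else:
                conc = _empirical_rosuvastatin_conc(
                    p_i, dose_ng, times, ritonavir=occasion == OCCASION_RITONAVIR
                )
            rng = np.random.default_rng([config.seed, i, occ_idx])
            records = _observe(
                conc, times, rng, config.sigma_prop, analyte.lloq, config.lloq_censor
            )
            profiles.append(
                ConcentrationProfile(
                    subject_id=subject_id,
                    analyte=analyte,
                    occasion=occasion,
                    dose_ng=dose_ng,
                    records=records,
                )
            )
    dataset = TrialDataset(
        profiles=profiles,
        metadata={
            "generator": "ritopk.synthetic_trial",
            "seed": config.seed,
            "statin": config.statin,
            "n_subjects": config.n_subjects,
            "dose_mg": config.dose_mg,
            "sigma_prop": config.sigma_prop,
            "omega": dict(config.omega),
            "lloq_censor": config.lloq_censor,
        },
    )
    if config.outlier is not None:
        dataset = inject_outlier(
            dataset,
            subject_id=f"S{config.outlier.subject_index + 1:02d}",
            factor=config.outlier.factor,
        )
    return dataset


def _profile_auc(profile: ConcentrationProfile) -> float:
    """Linear-trapezoid AUC over the quantifiable range (internal helper)."""
    t, c = profile.observed()
    return float(np.trapezoid(c, t))


def inject_outlier(
    dataset: TrialDataset, subject_id: str, factor: float = 0.45, mode: str = "ratio"
) -> TrialDataset:
    """Rescale one subject's ritonavir-occasion concentrations.

    ``mode='ratio'`` (default) rescales so the subject's exposure ratio
    (ritonavir/baseline AUC) equals ``factor``, emulating the
    direction-reversed responder whose ritonavir exposure fell to 45% of its
    own baseline.  ``mode='multiply'`` multiplies the concentrations by
    ``factor`` directly (so ``factor=1.0`` is an exact no-op).
    """
    if mode not in ("ratio", "multiply"):
        raise ValidationError(f"unknown outlier mode {mode!r}")
    found = False
    new_profiles = []
    for p in dataset.profiles:
        if p.subject_id == subject_id and p.occasion == OCCASION_RITONAVIR:
            if mode == "multiply":
                scale = factor
            else:
                base = dataset.get(subject_id, p.analyte.name, OCCASION_BASELINE)
                scale = factor * _profile_auc(base) / _profile_auc(p)
            records = tuple(
                ConcentrationRecord(
                    r.time,
                    None if r.concentration is None else r.concentration * scale,
                    r.blq,
                )
                for r in p.records
            )
            new_profiles.append(p.with_records(records))
            found = True
        else:
            new_profiles.append(p)
    if not found:
        raise AnalyteLookupError(f"no ritonavir-occasion profile for {subject_id!r}")
    meta = dict(dataset.metadata)
    meta["outlier"] = {"subject": subject_id, "factor": factor}
    return TrialDataset(profiles=new_profiles, metadata=meta)
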