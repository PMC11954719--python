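"""Trial concentration data model, CSV I/O, LLOQ censoring rules and unit conversion.

The central containers are :class:`ConcentrationProfile` (one subject x analyte x
occasion concentration-time series) and :class:`TrialDataset` (a collection of
profiles with provenance metadata).  All downstream modules (NCA, exposure
statistics, model fitting) consume these containers.

Units are fixed package-wide: time in hours, concentration in ng/mL (or nmol/L
after :func:`to_molar`), dose stored internally in ng.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AnalyteLookupError,
    ConfigurationError,
    EmptyProfileError,
    FormatError,
    UnitError,
    ValidationError,
)

OCCASION_BASELINE = "baseline"
OCCASION_RITONAVIR = "ritonavir_day5"
KNOWN_OCCASIONS = (OCCASION_BASELINE, OCCASION_RITONAVIR)

MASS_UNIT = "ng/mL"
MOLAR_UNIT = "nmol/L"

NG_PER_MG = 1e6

#: BLQ handling rules, see :func:`apply_lloq`.
LLOQ_RULES = ("zero_before_tmax_drop_after", "drop_all", "half_lloq")

CSV_COLUMNS = ["subject", "analyte", "occasion", "time_h", "conc_ng_ml", "dose_mg"]


@dataclass(frozen=True)
class AnalyteSpec:
    """Chemical/assay description of one analyte.

    Parameters
    ----------
    name : str
        Analyte identifier as used in dataset files.
    molar_mass : float
        Molar mass in g/mol; used for ng/mL <-> nmol/L conversion.
    lloq : float
        Lower limit of quantification in ng/mL.
    potency_weight : float
        Dimensionless weight in HMG-CoA reductase inhibitory-activity sums
        (equipotent parent/metabolite families use 1).
    """

    name: str
    molar_mass: float
    lloq: float
    potency_weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.molar_mass > 0:
            raise ConfigurationError(f"molar_mass must be > 0 for {self.name!r}")
        if not self.lloq > 0:
            raise ConfigurationError(f"lloq must be > 0 for {self.name!r}")
        if self.potency_weight < 0:
            raise ConfigurationError(f"potency_weight must be >= 0 for {self.name!r}")


#: Default analyte table.  Molar masses are from standard chemistry references
#: (monoisotopic-free average masses of the free acids/lactones); LLOQs are the
#: validated assay limits (0.1 ng/mL atorvastatin family, 0.05 ng/mL
#: rosuvastatin family, 1 pg/mL midazolam).  Atorvastatin and its hydroxy
#: metabolites are equipotent (weight 1); N-desmethyl rosuvastatin is 50% less
#: active; lactones are pharmacologically inactive at the reductase (weight 0).
DEFAULT_ANALYTES: dict[str, AnalyteSpec] = {
    spec.name: spec
    for spec in [
        AnalyteSpec("atorvastatin", 558.64, 0.1, 1.0),
        AnalyteSpec("atorvastatin_lactone", 540.63, 0.1, 0.0),
        AnalyteSpec("2oh_atorvastatin", 574.64, 0.1, 1.0),
        AnalyteSpec("2oh_atorvastatin_lactone", 556.63, 0.1, 0.0),
        AnalyteSpec("4oh_atorvastatin", 574.64, 0.1, 1.0),
        AnalyteSpec("4oh_atorvastatin_lactone", 556.63, 0.1, 0.0),
        AnalyteSpec("rosuvastatin", 481.54, 0.05, 1.0),
        AnalyteSpec("n_desmethyl_rosuvastatin", 467.52, 0.05, 0.5),
        AnalyteSpec("rosuvastatin_lactone", 463.53, 0.05, 0.0),
        AnalyteSpec("midazolam", 325.77, 0.001, 0.0),
    ]
}


@dataclass(frozen=True)
class ConcentrationRecord:
    """A single plasma sample: time (h), concentration (ng/mL or nmol/L), BLQ flag.

    A BLQ record carries ``concentration=None`` (or the assay reading when one
    was reported below the limit).
    """

    time: float
    concentration: float | None
    blq: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.time) or self.time < 0:
            raise ValidationError(f"time must be finite and >= 0, got {self.time}")
        if self.concentration is not None and self.concentration < 0:
            raise ValidationError(
                f"concentration must be >= 0, got {self.concentration} at t={self.time}"
            )


@dataclass(frozen=True)
class ConcentrationProfile:
    """One subject x analyte x occasion concentration-time series."""

    subject_id: str
    analyte: AnalyteSpec
    occasion: str
    dose_ng: float
    records: tuple[ConcentrationRecord, ...]
    unit: str = MASS_UNIT

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if not self.dose_ng > 0:
            raise ValidationError(f"dose_ng must be > 0, got {self.dose_ng}")
        times = [r.time for r in self.records]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError(
                f"records must be strictly increasing in time for subject "
                f"{self.subject_id!r}/{self.analyte.name}/{self.occasion}"
            )

    @property
    def n_quantifiable(self) -> int:
        return sum(1 for r in self.records if not r.blq and r.concentration is not None)

    def observed(self) -> tuple[np.ndarray, np.ndarray]:
        """Times and concentrations of the non-BLQ records as arrays."""
        pairs = [
            (r.time, r.concentration)
            for r in self.records
            if not r.blq and r.concentration is not None
        ]
        if not pairs:
            raise EmptyProfileError(
                f"profile {self.subject_id}/{self.analyte.name}/{self.occasion} "
                "has no quantifiable records"
            )
        t, c = zip(*pairs)
        return np.asarray(t, dtype=float), np.asarray(c, dtype=float)

    def with_records(self, records: Iterable[ConcentrationRecord]) -> "ConcentrationProfile":
        return replace(self, records=tuple(records))


@dataclass
class TrialDataset:
    """All profiles of one (virtual or real) trial plus free-form metadata."""

    profiles: list[ConcentrationProfile]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str]] = set()
        for p in self.profiles:
            key = (p.subject_id, p.analyte.name, p.occasion)
            if key in seen:
                raise ValidationError(f"duplicate profile {key}")
            seen.add(key)

    @property
    def subjects(self) -> list[str]:
        return sorted({p.subject_id for p in self.profiles})

    @property
    def analytes(self) -> list[str]:
        return sorted({p.analyte.name for p in self.profiles})

    def get(self, subject_id: str, analyte: str, occasion: str) -> ConcentrationProfile:
        for p in self.profiles:
            if (
                p.subject_id == subject_id
                and p.analyte.name == analyte
                and p.occasion == occasion
            ):
                return p
        raise AnalyteLookupError(f"no profile {(subject_id, analyte, occasion)}")

    def select(self, analyte: str | None = None, occasion: str | None = None) -> list[ConcentrationProfile]:
        out = []
        for p in self.profiles:
            if analyte is not None and p.analyte.name != analyte:
                continue
            if occasion is not None and p.occasion != occasion:
                continue
            out.append(p)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame in the package CSV dialect."""
        rows = []
        for p in self.profiles:
            for r in p.records:
                rows.append(
                    {
                        "subject": p.subject_id,
                        "analyte": p.analyte.name,
                        "occasion": p.occasion,
                        "time_h": r.time,
                        "conc_ng_ml": "BLQ" if r.blq else r.concentration,
                        "dose_mg": p.dose_ng / NG_PER_MG,
                    }
                )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _parse_conc(cell: object) -> tuple[float | None, bool]:
    """Parse a concentration cell: number, empty or the literal 'BLQ'."""
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None, True
    text = str(cell).strip()
    if text == "" or text.upper() == "BLQ":
        return None, True
    try:
        value = float(text)
    except ValueError as exc:
        raise ValidationError(f"unparseable concentration {cell!r}") from exc
    return value, False


def load_dataset(
    path,
    analyte_table: dict[str, AnalyteSpec] | Sequence[AnalyteSpec] | None = None,
) -> TrialDataset:
    """Read a long-format trial CSV into a :class:`TrialDataset`.

    The dialect is comma-separated with header
    ``subject,analyte,occasion,time_h,conc_ng_ml,dose_mg``; an empty
    concentration cell or the literal ``BLQ`` marks a below-quantification
    sample.  Doses are given in mg and converted to ng internally.

    Raises
    ------
    FormatError
        If a required column is missing.
    ValidationError
        Naming the offending CSV line for negative times/concentrations or
        duplicated (subject, analyte, occasion, time) rows.
    AnalyteLookupError
        For analyte names absent from the analyte table.
    """
    if analyte_table is None:
        table = dict(DEFAULT_ANALYTES)
    elif isinstance(analyte_table, dict):
        table = analyte_table
    else:
        table = {a.name: a for a in analyte_table}

    df = pd.read_csv(path, dtype={"subject": str, "analyte": str, "occasion": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    errors: list[str] = []
    groups: dict[tuple[str, str, str], dict] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        name = str(row["analyte"]).strip()
        if name not in table:
            raise AnalyteLookupError(f"{path} line {line}: unknown analyte {name!r}")
        try:
            time = float(row["time_h"])
            conc, blq = _parse_conc(row["conc_ng_ml"])
            rec = ConcentrationRecord(time, conc, blq)
        except ValidationError as exc:
            errors.append(f"line {line}: {exc}")
            continue
        dose_mg = float(row["dose_mg"])
        if dose_mg <= 0:
            errors.append(f"line {line}: non-positive dose {dose_mg}")
            continue
        key = (str(row["subject"]).strip(), name, str(row["occasion"]).strip())
        grp = groups.setdefault(key, {"dose_ng": dose_mg * NG_PER_MG, "records": {}})
        if time in grp["records"]:
            errors.append(
                f"line {line}: duplicate time {time} h for {key[0]}/{key[1]}/{key[2]}"
            )
            continue
        grp["records"][time] = rec

    if errors:
        raise ValidationError("; ".join(errors))

    profiles = [
        ConcentrationProfile(
            subject_id=key[0],
            analyte=table[key[1]],
            occasion=key[2],
            dose_ng=grp["dose_ng"],
            records=tuple(grp["records"][t] for t in sorted(grp["records"])),
        )
        for key, grp in groups.items()
    ]
    return TrialDataset(profiles=profiles, metadata={"source": str(path)})


def write_dataset(dataset: TrialDataset, path) -> None:
    """Write a :class:`TrialDataset` in the CSV dialect read by :func:`load_dataset`."""
    dataset.to_frame().to_csv(path, index=False)


def apply_lloq(
    profile: ConcentrationProfile, rule: str = "zero_before_tmax_drop_after"
) -> ConcentrationProfile:
    """Transform BLQ records according to a censoring rule.

    ``zero_before_tmax_drop_after`` (default; the common NCA convention):
    BLQ samples before the first quantifiable observation are set to 0,
    BLQ samples at/after it are excluded.  ``drop_all`` removes every BLQ
    record; ``half_lloq`` imputes LLOQ/2.
    """
    if rule not in LLOQ_RULES:
        raise ConfigurationError(f"unknown LLOQ rule {rule!r}; choose from {LLOQ_RULES}")
    if profile.n_quantifiable == 0:
        raise EmptyProfileError(
            f"profile {profile.subject_id}/{profile.analyte.name}/{profile.occasion}: "
            "all records are BLQ"
        )
    first_quant = min(r.time for r in profile.records if not r.blq)
    out: list[ConcentrationRecord] = []
    for r in profile.records:
        if not r.blq:
            out.append(r)
        elif rule == "drop_all":
            continue
        elif rule == "half_lloq":
            out.append(ConcentrationRecord(r.time, profile.analyte.lloq / 2.0, blq=False))
        else:  # zero_before_tmax_drop_after
            if r.time < first_quant:
                out.append(ConcentrationRecord(r.time, 0.0, blq=False))
    return profile.with_records(out)


def to_molar(profile: ConcentrationProfile) -> ConcentrationProfile:
    """Convert ng/mL concentrations to nmol/L via ``c * 1000 / molar_mass``."""
    if profile.unit != MASS_UNIT:
        raise UnitError(f"profile already in {profile.unit}")
    factor = 1000.0 / profile.analyte.molar_mass
    return _scale_profile(profile, factor, MOLAR_UNIT)


def to_mass(profile: ConcentrationProfile) -> ConcentrationProfile:
    """Inverse of :func:`to_molar` (nmol/L back to ng/mL)."""
    if profile.unit != MOLAR_UNIT:
        raise UnitError(f"profile is in {profile.unit}, expected {MOLAR_UNIT}")
    factor = profile.analyte.molar_mass / 1000.0
    return _scale_profile(profile, factor, MASS_UNIT)


def _scale_profile(
    profile: ConcentrationProfile, factor: float, unit: str
) -> ConcentrationProfile:
    records = tuple(
        ConcentrationRecord(
            r.time,
            None if r.concentration is None else r.concentration * factor,
            r.blq,
        )
        for r in profile.records
    )
    return replace(profile, records=records, unit=unit)
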