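"""Deterministic hazard-quotient arithmetic for drinking-water ingestion.

The core quantities are the estimated daily intake (EDI) of a contaminant
through drinking water,

    EDI = (C / 1000) * IR * EF * ED / (BW * AT)   [mg/kg-day]

with C the water concentration (µg/L, converted to mg/L exactly once,
here), IR the ingestion rate (L/d), EF the exposure frequency (d/yr),
ED the exposure duration (yr), BW body weight (kg), AT the averaging
time (d); and the non-carcinogenic hazard quotient

    HQ = EDI / RfD

against an oral reference dose RfD (mg/kg-day).  HQ < 1 means adverse
effects are not anticipated.

All arithmetic accepts either scalars or equal-length numpy arrays, so
the same functions serve the point-estimate assessment and every Monte
Carlo iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "UG_PER_MG",
    "PopulationGroup",
    "ExposureFactors",
    "ContaminantSpec",
    "ExposureScenario",
    "DeterministicResult",
    "compute_edi",
    "compute_hq",
    "deterministic_assessment",
]

#: micrograms per milligram; the single concentration unit conversion.
UG_PER_MG = 1000.0

Number = Union[float, np.ndarray]

#: canonical population groups of the packaged case study; user scenarios
#: may define any other label.
CANONICAL_GROUPS = ("children", "teens", "adults")

PopulationGroup = str


def _require_positive(name: str, value: Number) -> None:
    if not np.all(np.asarray(value) > 0):
        raise DomainError(f"{name} must be strictly positive")


def _require_nonnegative(name: str, value: Number) -> None:
    if not np.all(np.asarray(value) >= 0):
        raise DomainError(f"{name} must be non-negative")


@dataclass(frozen=True)
class ExposureFactors:
    """Exposure factors of the intake equation.

    Attributes
    ----------
    ir : float or ndarray
        Water ingestion rate, L/d.
    ef : float or ndarray
        Exposure frequency, d/yr (at most 366).
    ed : float or ndarray
        Exposure duration, yr.
    bw : float or ndarray
        Body weight, kg.
    at : float or ndarray
        Averaging time, d.
    """

    ir: Number
    ef: Number
    ed: Number
    bw: Number
    at: Number

    def __post_init__(self) -> None:
        for name in ("ir", "ef", "ed", "bw", "at"):
            _require_positive(name.upper(), getattr(self, name))
        if not np.all(np.asarray(self.ef) <= 366):
            raise DomainError("EF must not exceed 366 d/yr")


@dataclass(frozen=True)
class ContaminantSpec:
    """A contaminant's concentration summary and oral reference dose.

    Concentrations are stored in µg/L; the µg→mg conversion happens once,
    inside :func:`compute_edi`.
    """

    name: str
    concentration_mean: float  # µg/L
    concentration_sd: float  # µg/L
    reference_dose: float  # mg/kg-day

    def __post_init__(self) -> None:
        _require_nonnegative("concentration_mean", self.concentration_mean)
        _require_nonnegative("concentration_sd", self.concentration_sd)
        _require_positive("reference_dose", self.reference_dose)


@dataclass(frozen=True)
class ExposureScenario:
    """One assessable cell: a population group drinking from one source."""

    group: PopulationGroup
    source: str
    contaminant: ContaminantSpec
    factors: ExposureFactors


@dataclass(frozen=True)
class DeterministicResult:
    """Point EDI (mg/kg-day) and HQ for one (group, source) cell."""

    group: PopulationGroup
    source: str
    edi: float
    hq: float

    def __post_init__(self) -> None:
        _require_nonnegative("edi", self.edi)
        _require_nonnegative("hq", self.hq)


def compute_edi(
    c_ugL: Number,
    factors: ExposureFactors,
    bw_override: Number | None = None,
    concentration_in_mgL: bool = False,
) -> Number:
    """Estimated daily intake, mg/kg-day.

    Parameters
    ----------
    c_ugL
        Contaminant concentration in µg/L (non-negative).  If
        ``concentration_in_mgL`` is true the value is taken as already in
        mg/L and no conversion is applied.
    factors
        Exposure factors; scalar or per-iteration arrays.
    bw_override
        Optional body weight replacing ``factors.bw``.

    Returns
    -------
    float or ndarray
        ``(C/1000) * IR * EF * ED / (BW * AT)``, linear in concentration
        and ingestion rate, strictly decreasing in body weight and
        averaging time.
    """
    _require_nonnegative("concentration", c_ugL)
    bw = factors.bw if bw_override is None else bw_override
    _require_positive("BW", bw)
    c_mgL = np.asarray(c_ugL, dtype=float)
    if not concentration_in_mgL:
        c_mgL = c_mgL / UG_PER_MG
    edi = c_mgL * factors.ir * factors.ef * factors.ed / (bw * factors.at)
    return float(edi) if np.ndim(edi) == 0 else edi


def compute_hq(edi: Number, rfd: Number) -> Number:
    """Hazard quotient EDI/RfD (dimensionless).

    HQ below 1 indicates detrimental consequences of exposure are not
    anticipated; above 1, a potential concern.
    """
    _require_nonnegative("edi", edi)
    _require_positive("rfd", rfd)
    hq = np.asarray(edi, dtype=float) / rfd
    return float(hq) if np.ndim(hq) == 0 else hq


def deterministic_assessment(
    scenarios: list[ExposureScenario],
) -> dict[tuple[str, str], DeterministicResult]:
    """Point assessment over every (group, source) cell.

    Returns a mapping keyed by ``(group, source)``; duplicate keys are a
    configuration error, an empty scenario list a domain error.
    """
    if not scenarios:
        raise DomainError("scenario list must be non-empty")
    results: dict[tuple[str, str], DeterministicResult] = {}
    for sc in scenarios:
        key = (sc.group, sc.source)
        if key in results:
            raise ConfigurationError(f"duplicate scenario cell {key!r}")
        edi = compute_edi(sc.contaminant.concentration_mean, sc.factors)
        hq = compute_hq(edi, sc.contaminant.reference_dose)
        results[key] = DeterministicResult(sc.group, sc.source, edi, hq)
    return results
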