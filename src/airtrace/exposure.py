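"""Daily exposure concentrations, exposure error, bias, and risk scaling.

Both exposure measures are time-weighted means C = (1/T)∫c dt over the
24-hour person-day (T = 24 h):

* residence-based ``C_R``: the 24 hourly concentrations at the residence
  cell, each weighted 1 h — the conventional address-only estimate;
* activity-based ``C_A``: concentrations matched in space *and* time to every
  element of the person-day's space-time trace.

The exposure error 100·(C_A − C_R)/C_A is positive when the address-only
estimate understates exposure.  The attenuation bias factor is the OLS slope
of C_A on C_R across a sample: values below 1 mean health-effect estimates
that use the residence-based surrogate are biased toward the null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .concentration import ConcentrationField, cell_index, lookup
from .diary import AT_RESIDENCE, IN_TRAVEL, NONRESIDENTIAL
from .routing import SpaceTimeTrace

__all__ = [
    "KINDS",
    "ExposureRecord",
    "RiskSlope",
    "MORTALITY_SLOPE",
    "COUGH_SLOPE",
    "RESPIRATORY_HOSPITALIZATION_SLOPE",
    "residence_exposure",
    "activity_exposure",
    "exposure_error",
    "bias_factor",
    "activity_contributions",
    "nox_to_no2_ppbv",
    "excess_risk",
    "time_use_percentages",
]

KINDS = (AT_RESIDENCE, NONRESIDENTIAL, IN_TRAVEL)

MW_NO2 = 46.01          # g/mol
V_M_REF = 22.414        # L/mol at 0 °C, 1 atm


@dataclass
class ExposureRecord:
    """Per-person-day exposure summary.

    ``exposure_by_kind`` holds subperiod exposures E = Σ c·Δt in (μg/m³)·h;
    they sum to ``c_activity · 24``.  ``minutes_by_kind`` sums to 1440.
    """

    person_id: str
    c_activity: float            # C_A, μg/m³
    c_residence: float           # C_R, μg/m³
    exposure_by_kind: dict[str, float]
    minutes_by_kind: dict[str, float]
    error_pct: float             # 100·(C_A − C_R)/C_A
    travel_minutes: float


@dataclass(frozen=True)
class RiskSlope:
    """A literature concentration-response slope, taken as a given constant."""

    percent_increase: float
    unit: str                    # "ug/m3 NO2" or "ppbv NO2"
    unit_size: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.unit_size <= 0:
            raise ValueError("unit_size must be positive")
        if self.unit not in ("ug/m3 NO2", "ppbv NO2"):
            raise ValueError(f"unknown slope unit {self.unit!r}")


#: 2.9 % excess all-cause mortality per 10 μg/m³ of 24-h mean NO2
MORTALITY_SLOPE = RiskSlope(2.9, "ug/m3 NO2", 10.0, "all-cause mortality")
#: 61.3 % excess cough incidence in children per 20 ppbv of 24-h NO2
COUGH_SLOPE = RiskSlope(61.3, "ppbv NO2", 20.0, "child cough incidence")
#: 6.8 % excess respiratory hospitalizations (65+) per 20 ppbv daily NO2
RESPIRATORY_HOSPITALIZATION_SLOPE = RiskSlope(
    6.8, "ppbv NO2", 20.0, "respiratory hospitalization, 65+"
)


def residence_exposure(
    field: ConcentrationField, residence: tuple[float, float]
) -> float:
    """C_R: mean of the 24 hourly values at the residence cell (μg/m³).

    Each hourly value is weighted Δt = 1 h over T = 24 h.  The accumulation
    mirrors :func:`activity_exposure`'s hour-fragment loop operation for
    operation, so a zero-travel day gives C_A == C_R exactly.
    """
    i, j = cell_index(field.grid, residence[0], residence[1])
    total = 0.0
    for h in range(24):
        total += float(field.layers[h, j, i]) * 60.0   # (μg/m³)·min
    return total / 60.0 / 24.0


def activity_exposure(
    trace: SpaceTimeTrace, field: ConcentrationField, clamp: bool = False
) -> ExposureRecord:
    """C_A and subperiod exposures for a full-day space-time trace.

    Every trace point is split at hour boundaries so each fragment sees the
    correct hourly layer; fragment contributions c·Δt accumulate into
    per-activity-kind exposures (converted to (μg/m³)·h) and C_A = ΣcΔt / 24 h.
    Out-of-domain points raise (naming the offending point) unless ``clamp``.
    """
    if abs(trace.total_minutes - 1440.0) > 1e-6:
        raise ValueError(
            f"trace covers {trace.total_minutes} min, expected 1440"
        )
    e_kind = {k: 0.0 for k in KINDS}
    t_kind = {k: 0.0 for k in KINDS}
    for idx, p in enumerate(trace.points):
        t0, t1 = p.t_start, p.t_start + p.dt
        t_kind[p.kind] += p.dt
        cursor = t0
        while cursor < t1 - 1e-12:
            bound = min(math.floor(cursor / 60.0) * 60.0 + 60.0, t1)
            try:
                c = lookup(field, p.x, p.y, min(cursor, 1439.9999), clamp=clamp)
            except Exception as exc:
                raise type(exc)(
                    f"trace point {idx} at ({p.x}, {p.y}), minute {cursor}: {exc}"
                ) from exc
            e_kind[p.kind] += c * (bound - cursor)   # (μg/m³)·min
            cursor = bound
    e_kind = {k: v / 60.0 for k, v in e_kind.items()}   # → (μg/m³)·h
    c_a = sum(e_kind.values()) / 24.0
    c_r = residence_exposure(field, trace.residence)
    return ExposureRecord(
        person_id=trace.person_id,
        c_activity=c_a,
        c_residence=c_r,
        exposure_by_kind=e_kind,
        minutes_by_kind=t_kind,
        error_pct=exposure_error(c_a, c_r),
        travel_minutes=t_kind[IN_TRAVEL],
    )


def exposure_error(c_activity: float, c_residence: float) -> float:
    """Percent difference 100·(C_A − C_R)/C_A; positive = underestimation."""
    if c_activity <= 0:
        raise ValueError("exposure error undefined for C_A <= 0")
    return 100.0 * (c_activity - c_residence) / c_activity


def bias_factor(pairs) -> float:
    """Attenuation slope: OLS slope of C_A regressed on C_R.

    ``pairs`` is an iterable of (C_R, C_A).  A slope below 1 indicates that
    relative-risk estimates based on the residence-based surrogate are
    attenuated.  Requires at least 3 pairs with variation in C_R.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (C_R, C_A) pairs")
    c_r, c_a = arr[:, 0], arr[:, 1]
    var = np.var(c_r)
    if var == 0:
        raise ValueError("C_R has zero variance; bias factor undefined")
    return float(np.cov(c_r, c_a, bias=True)[0, 1] / var)


def activity_contributions(record: ExposureRecord) -> dict[str, float]:
    """Percent of total daily exposure contributed by each activity kind."""
    total = sum(record.exposure_by_kind.values())
    if total == 0:
        raise ValueError("zero total exposure; contributions undefined")
    return {k: 100.0 * v / total for k, v in record.exposure_by_kind.items()}


def nox_to_no2_ppbv(
    c_nox: float,
    no2_fraction: float = 0.8,
    temp_c: float = 25.0,
    pressure_atm: float = 1.0,
) -> float:
    """Convert an NOx mass concentration (μg/m³) to an NO2 mixing ratio (ppbv).

    The NO2 share of NOx mass is ``no2_fraction`` (0.8 is typical of a
    traffic-dominated airshed); ppbv = mass · V_m / MW with the ideal-gas
    molar volume V_m = 22.414·(T/273.15)/P L/mol (≈24.45 at 25 °C, 1 atm)
    and MW(NO2) = 46.01 g/mol.
    """
    if c_nox < 0:
        raise ValueError("concentration must be non-negative")
    if not 0 < no2_fraction <= 1:
        raise ValueError("no2_fraction must be in (0, 1]")
    if temp_c <= -273.15 or pressure_atm <= 0:
        raise ValueError("nonphysical temperature or pressure")
    v_m = V_M_REF * ((temp_c + 273.15) / 273.15) / pressure_atm
    return c_nox * no2_fraction * v_m / MW_NO2


def excess_risk(
    delta_c_nox: float, slope: RiskSlope, no2_fraction: float = 0.8
) -> float:
    """Linear excess risk (%) implied by an NOx exposure difference (μg/m³).

    The difference is first converted to the slope's NO2 unit — mass units
    multiply by the NO2 fraction; ppbv units additionally apply the gas
    conversion of :func:`nox_to_no2_ppbv` — then scaled linearly:
    ``percent = slope.percent_increase · converted / slope.unit_size``.
    """
    if slope.unit == "ug/m3 NO2":
        converted = delta_c_nox * no2_fraction
    else:  # ppbv NO2
        converted = nox_to_no2_ppbv(abs(delta_c_nox), no2_fraction)
        converted = math.copysign(converted, delta_c_nox)
    return slope.percent_increase * converted / slope.unit_size


def time_use_percentages(minutes_by_type: dict[str, float]) -> dict[str, float]:
    """Share (%) of total daily minutes per activity type, summing to 100."""
    total = sum(minutes_by_type.values())
    if total <= 0:
        raise ValueError("total minutes must be positive")
    return {k: 100.0 * v / total for k, v in minutes_by_type.items()}
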