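"""Scenario exposure assessment: source rates, intakes, limit comparisons.

Connects per-mg emission factors (for e-vapor products, EVP) or sidestream
emissions per cigarette to a well-mixed space, computes the transient
time-averaged concentration a non-user breathes, and converts it to an
inhaled mass (intake) under a fixed breathing model, assuming complete
absorption.  For scale, each constituent's intake is set against the intake
a person would receive breathing at its 8-h occupational exposure limit
(OSHA PEL or equivalent).

Units: volumes m³, air-change rate 1/h, durations h, concentrations µg/m³,
masses µg, e-liquid consumption mg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy.optimize import brentq

from .airmodel import SourceProfile, average_concentration, simulate_box

__all__ = [
    "ConstituentSpec",
    "Scenario",
    "UsageModel",
    "BreathingModel",
    "IntakeResult",
    "NotAvailableError",
    "source_rate",
    "intake",
    "limit_reference_intake",
    "run_scenario",
    "fold_difference",
    "fold_difference_from_rates",
    "transient_average",
    "calibrate_ach",
]

STATUS_COMPUTED = "COMPUTED"
STATUS_BELOW_MDL = "BELOW_MDL"
STATUS_NA = "NA"


class NotAvailableError(ValueError):
    """Raised when a scenario requires emission data the constituent lacks."""


@dataclass(frozen=True)
class ConstituentSpec:
    """One chemical's emission, volatility and reference-limit parameters."""

    name: str
    emission_factor: float  # µg exhaled per mg e-liquid consumed
    sidestream_emission: float | None = None  # µg per cigarette
    saturation_mass_concentration: float | None = None  # C*, µg/m³; None = fully volatile
    exposure_limit: float | None = None  # 8-h limit, µg/m³
    below_mdl: bool = False

    def __post_init__(self) -> None:
        if self.emission_factor < 0:
            raise ValueError("emission factor must be nonnegative")
        if self.sidestream_emission is not None and self.sidestream_emission < 0:
            raise ValueError("sidestream emission must be nonnegative")
        if self.below_mdl and self.emission_factor != 0:
            raise ValueError("a below-MDL constituent must have emission factor 0")


@dataclass(frozen=True)
class Scenario:
    """A bounded indoor space with a source population and exposure window."""

    name: str
    volume: float  # m³
    ach: float  # 1/h
    duration: float  # h
    n_users: int
    n_occupants: int
    source_kind: str = "evp"  # "evp" | "cigarette"

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.ach < 0:
            raise ValueError("air-change rate must be nonnegative")
        if not (0 <= self.n_users <= self.n_occupants):
            raise ValueError("need 0 <= n_users <= n_occupants")
        if self.source_kind not in ("evp", "cigarette"):
            raise ValueError(f"unknown source kind {self.source_kind!r}")


@dataclass(frozen=True)
class UsageModel:
    """Product-use intensity assumptions shared across scenarios."""

    evp_daily_consumption: float = 902.0  # mg e-liquid per day
    evp_use_hours: float = 16.0  # waking-use hours per day
    cigarettes_per_hour: float = 1.0
    cigarette_use_hours: float = 16.0

    def __post_init__(self) -> None:
        for v in (
            self.evp_daily_consumption,
            self.evp_use_hours,
            self.cigarettes_per_hour,
            self.cigarette_use_hours,
        ):
            if v <= 0:
                raise ValueError("usage-model parameters must be positive")

    @property
    def evp_hourly_consumption(self) -> float:
        """mg e-liquid consumed per user-hour."""
        return self.evp_daily_consumption / self.evp_use_hours


@dataclass(frozen=True)
class BreathingModel:
    """Non-user tidal breathing; defaults are 500 mL at 12 breaths/min."""

    tidal_volume_ml: float = 500.0
    breaths_per_min: float = 12.0

    def __post_init__(self) -> None:
        if self.tidal_volume_ml <= 0 or self.breaths_per_min <= 0:
            raise ValueError("breathing parameters must be positive")

    @property
    def minute_ventilation_m3_per_h(self) -> float:
        return self.tidal_volume_ml * self.breaths_per_min * 60.0 / 1e6


@dataclass(frozen=True)
class IntakeResult:
    constituent: str
    scenario: str
    source_kind: str
    average_concentration: float  # µg/m³
    intake: float  # µg
    limit_reference_intake: float | None  # µg, or None when no limit exists
    status: str = STATUS_COMPUTED


def source_rate(
    constituent: ConstituentSpec, scenario: Scenario, usage: UsageModel = UsageModel()
) -> float:
    """Whole-room constituent release rate in µg/h.

    EVP: n_users × hourly e-liquid consumption × emission factor (below-MDL
    constituents emit 0).  Cigarette: n_users × cigarettes/h × sidestream
    emission; raises :class:`NotAvailableError` when no sidestream value
    exists for the constituent (mirrored as an ``NA`` status upstream).
    """
    if scenario.source_kind == "evp":
        if constituent.below_mdl:
            return 0.0
        return scenario.n_users * usage.evp_hourly_consumption * constituent.emission_factor
    if constituent.sidestream_emission is None:
        raise NotAvailableError(
            f"no sidestream emission available for {constituent.name!r}"
        )
    return scenario.n_users * usage.cigarettes_per_hour * constituent.sidestream_emission


def intake(
    average_concentration: float,
    duration: float,
    breathing: BreathingModel = BreathingModel(),
) -> float:
    """Inhaled mass (µg): concentration × duration × minute ventilation.

    Assumes 100% absorption of inhaled constituent.  With the default
    breathing model the ventilation factor is 0.36 m³/h.
    """
    if average_concentration < 0:
        raise ValueError("concentration must be nonnegative")
    if duration < 0:
        raise ValueError("duration must be nonnegative")
    return average_concentration * duration * breathing.minute_ventilation_m3_per_h


def limit_reference_intake(
    exposure_limit: float | None,
    breathing: BreathingModel = BreathingModel(),
    hours: float = 8.0,
    rounded: bool = True,
) -> float | None:
    """Intake (µg) from breathing at the exposure limit for an 8-h shift.

    Defaults give limit × 2.88 m³; reported values are rounded to the
    nearest µg.  Returns ``None`` when the constituent has no limit.
    """
    if exposure_limit is None:
        return None
    if exposure_limit <= 0:
        raise ValueError("exposure limit must be positive")
    value = intake(exposure_limit, hours, breathing)
    return float(round(value)) if rounded else value


def run_scenario(
    scenario: Scenario,
    constituents: list[ConstituentSpec],
    usage: UsageModel = UsageModel(),
    breathing: BreathingModel = BreathingModel(),
    timestep: float | None = None,
) -> list[IntakeResult]:
    """Simulate every constituent through the box model and compute intakes.

    Sources are continuous at the scenario-level rate; the space starts
    clean (zero initial concentration).  ``NA`` (no emission data for this
    source kind) and ``BELOW_MDL`` statuses propagate into the results with
    zero/NaN quantities rather than raising.
    """
    results: list[IntakeResult] = []
    for spec in constituents:
        ref = limit_reference_intake(spec.exposure_limit, breathing)
        try:
            rate = source_rate(spec, scenario, usage)
        except NotAvailableError:
            results.append(
                IntakeResult(
                    spec.name, scenario.name, scenario.source_kind,
                    float("nan"), float("nan"), ref, STATUS_NA,
                )
            )
            continue
        status = (
            STATUS_BELOW_MDL
            if (scenario.source_kind == "evp" and spec.below_mdl)
            else STATUS_COMPUTED
        )
        state = simulate_box(
            scenario.volume,
            scenario.ach,
            SourceProfile.continuous(rate),
            scenario.duration,
            timestep=timestep,
            saturation_mass_concentration=spec.saturation_mass_concentration,
        )
        avg = average_concentration(state)
        results.append(
            IntakeResult(
                spec.name,
                scenario.name,
                scenario.source_kind,
                avg,
                intake(avg, scenario.duration, breathing),
                ref,
                status,
            )
        )
    return results


def fold_difference(cigarette_value: float, evp_value: float) -> float:
    """Cigarette-to-EVP ratio for the same constituent and geometry.

    Under the linear box model the intake ratio equals the per-user
    source-rate ratio and is independent of the space.  A zero EVP value
    (below-MDL constituent) gives ``inf``, reported symbolically downstream.
    """
    if cigarette_value < 0 or evp_value < 0:
        raise ValueError("values must be nonnegative")
    if evp_value == 0:
        return math.inf
    return cigarette_value / evp_value


def fold_difference_from_rates(
    constituent: ConstituentSpec, usage: UsageModel = UsageModel()
) -> float:
    """Per-user source-rate fold difference (cigarette / EVP)."""
    if constituent.sidestream_emission is None:
        raise NotAvailableError(
            f"no sidestream emission available for {constituent.name!r}"
        )
    cig = usage.cigarettes_per_hour * constituent.sidestream_emission
    evp = usage.evp_hourly_consumption * constituent.emission_factor
    return fold_difference(cig, evp)


def transient_average(
    source_rate_ug_h: float, volume: float, ach: float, duration: float
) -> float:
    """Closed-form time-averaged concentration for a constant source.

    From a clean start, C(t) = S/(λV)(1 − e^{−λt}); its mean over [0, T] is
    S/(λV)·(1 − (1 − e^{−λT})/(λT)), with limit S·T/(2V) as λ → 0.
    """
    if volume <= 0 or duration <= 0:
        raise ValueError("volume and duration must be positive")
    if ach < 0:
        raise ValueError("air-change rate must be nonnegative")
    lt = ach * duration
    if lt < 1e-8:
        return source_rate_ug_h * duration / (2.0 * volume)
    return (source_rate_ug_h / (ach * volume)) * (1.0 - (1.0 - math.exp(-lt)) / lt)


def calibrate_ach(
    volume: float,
    duration: float,
    source_rate_ug_h: float,
    target_average_concentration: float,
    rtol: float = 1e-6,
) -> float:
    """Air-change rate whose transient average matches a target concentration.

    The average is strictly decreasing in the air-change rate, from the
    no-ventilation bound S·T/(2V) down to zero, so the inversion is a
    monotone one-dimensional root find.  Raises with the achievable range
    when the target is infeasible.
    """
    if target_average_concentration <= 0:
        raise ValueError("target average concentration must be positive")
    if source_rate_ug_h <= 0:
        raise ValueError("source rate must be positive")
    upper = transient_average(source_rate_ug_h, volume, 0.0, duration)
    if target_average_concentration >= upper:
        raise ValueError(
            f"target {target_average_concentration:g} µg/m³ is not achievable; "
            f"the no-ventilation average bounds it at {upper:g} µg/m³"
        )
    f = lambda lam: transient_average(source_rate_ug_h, volume, lam, duration) - target_average_concentration
    lo, hi = 1e-9, 1.0
    while f(hi) > 0:
        hi *= 4.0
        if hi > 1e9:  # pragma: no cover - unreachable for feasible targets
            raise RuntimeError("failed to bracket the air-change rate")
    return float(brentq(f, lo, hi, rtol=rtol))
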