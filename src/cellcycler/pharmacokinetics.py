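"""Closed-form free-concentration time courses for the supported PK models.

Three model types are offered, mirroring common preclinical practice:

``kpd_decay``
    Kinetic-pharmacodynamic shortcut: each administration puts the drug at
    concentration ``dose_over_v`` instantly (as in an intravenous bolus)
    and it decays mono-exponentially at ``elimination_rate``.
``step_infusion``
    The concentration is held at fixed levels over specified intervals,
    as in an infusion; zero elsewhere.
``one_compartment``
    Bateman form with first-order absorption and elimination (unit
    bioavailability).

Concentrations are evaluated in closed form rather than integrated as ODE
states, so dose superposition is exact and the cell-population integrator
sees no added stiffness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = ["PKConfig", "DoseSchedule", "concentration", "expand_schedule"]

MODEL_TYPES = ("kpd_decay", "step_infusion", "one_compartment")


@dataclass(frozen=True)
class PKConfig:
    """One drug's pharmacokinetic configuration.

    ``dose_over_v`` is the concentration increment per administration (the
    administered amount already scaled by the distribution volume, in free
    concentration units); ``elimination_rate`` and ``absorption_rate`` are
    first-order rate constants in 1/h.  ``infusion_levels`` lists
    ``(start_h, end_h, level)`` intervals for the step model.
    """

    model_type: str = "kpd_decay"
    dose_over_v: float = 1.0
    elimination_rate: float = 0.1
    absorption_rate: float | None = None
    infusion_levels: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.model_type not in MODEL_TYPES:
            raise ValueError(f"model_type must be one of {MODEL_TYPES}, got {self.model_type!r}")
        if self.elimination_rate < 0:
            raise ValueError(f"elimination_rate must be >= 0, got {self.elimination_rate}")
        if self.dose_over_v < 0:
            raise ValueError(f"dose_over_v must be >= 0, got {self.dose_over_v}")
        if self.model_type == "one_compartment":
            if self.absorption_rate is None or self.absorption_rate <= 0:
                raise ValueError("one_compartment model requires absorption_rate > 0")
        if self.model_type == "step_infusion":
            levels = tuple(
                (float(a), float(b), float(c)) for a, b, c in self.infusion_levels
            )
            prev_end = -math.inf
            for start, end, _level in sorted(levels):
                if start >= end:
                    raise ValueError(f"infusion interval [{start}, {end}) is empty")
                if start < prev_end:
                    raise ValueError("infusion intervals must not overlap")
                prev_end = end
            object.__setattr__(self, "infusion_levels", levels)


@dataclass(frozen=True)
class DoseSchedule:
    """Explicit administration times, in hours from the simulation start."""

    dose_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.dose_times)
        if any(t < 0 for t in times):
            raise ValueError("dose times must be >= 0 h")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose times must be strictly increasing")
        object.__setattr__(self, "dose_times", times)

    @classmethod
    def from_times(cls, times: Iterable[float]) -> "DoseSchedule":
        return cls(tuple(sorted(set(float(t) for t in times))))

    def __len__(self) -> int:
        return len(self.dose_times)


def _bolus_superposition(dose: float, ke: float, dt: np.ndarray) -> np.ndarray:
    """Sum of bolus decays at elapsed times dt (dt < 0 entries contribute 0)."""
    active = dt >= 0
    out = np.zeros_like(dt, dtype=float)
    out[active] = dose * np.exp(-ke * dt[active])
    return out


def _bateman(dose: float, ka: float, ke: float, dt: np.ndarray) -> np.ndarray:
    active = dt >= 0
    out = np.zeros_like(dt, dtype=float)
    t = dt[active]
    if abs(ka - ke) < 1e-12 * max(ka, ke, 1.0):
        # analytic limit of the Bateman function as ka -> ke
        out[active] = dose * ke * t * np.exp(-ke * t)
    else:
        out[active] = dose * (ka / (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))
    return out


def concentration(pk: PKConfig, schedule: DoseSchedule, t) -> float | np.ndarray:
    """Free concentration at time(s) ``t`` (hours), by exact superposition.

    Doses at exactly time ``t`` are counted (the bolus has just been
    given), so for the decay model ``C(0) = dose_over_v`` when a dose is
    scheduled at 0.  The step model ignores the schedule and reads its
    ``infusion_levels`` directly.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if (t_arr < 0).any():
        raise ValueError("concentration requested at negative time")
    out = np.zeros_like(t_arr)

    if pk.model_type == "step_infusion":
        for start, end, level in pk.infusion_levels:
            out[(t_arr >= start) & (t_arr < end)] = level
    else:
        for ti in schedule.dose_times:
            dt = t_arr - ti
            if pk.model_type == "kpd_decay":
                out += _bolus_superposition(pk.dose_over_v, pk.elimination_rate, dt)
            else:
                out += _bateman(pk.dose_over_v, pk.absorption_rate, pk.elimination_rate, dt)

    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return float(out[0])
    return out


def expand_schedule(
    start_day: int = 1,
    n_days_on: int = 1,
    doses_per_day: int = 1,
    cycle_length_days: int = 7,
    n_cycles: int = 3,
    horizon_h: float | None = None,
) -> DoseSchedule:
    """Expand a cyclical dosing pattern into explicit dose times.

    Convention: "Day 1" is t = 0 h; day ``k`` starts at ``(k - 1) * 24`` h.
    Within a day, doses are spaced ``24 / doses_per_day`` h apart (once
    daily 24 h, twice daily 12 h).  The pattern doses on days
    ``start_day .. start_day + n_days_on - 1`` of each cycle and repeats
    every ``cycle_length_days`` for ``n_cycles`` cycles.  Times at or
    beyond ``horizon_h`` (when given) are dropped.
    """
    if n_days_on < 1 or doses_per_day < 1 or n_cycles < 1 or cycle_length_days < 1:
        raise ValueError("pattern counts must all be >= 1")
    if start_day < 1:
        raise ValueError("start_day counts from 1")
    if start_day - 1 + n_days_on > cycle_length_days:
        raise ValueError(
            f"days {start_day}..{start_day + n_days_on - 1} do not fit in a "
            f"{cycle_length_days}-day cycle (doses would overlap the next cycle)"
        )
    spacing = 24.0 / doses_per_day
    times = []
    for cycle in range(n_cycles):
        day0 = (start_day - 1) + cycle * cycle_length_days
        for day in range(day0, day0 + n_days_on):
            for k in range(doses_per_day):
                times.append(day * 24.0 + k * spacing)
    if horizon_h is not None:
        times = [t for t in times if t < horizon_h]
    if not times:
        raise ValueError("dosing pattern produced no doses within the horizon")
    return DoseSchedule(tuple(times))
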