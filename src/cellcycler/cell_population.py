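"""Cyclic N-compartment representation of a proliferating cell population.

The cell cycle is discretised into ``N`` sequential volume compartments of
equal duration.  A cohort of cells transits all ``N`` compartments in one
doubling time ``t_d``, with cyclic wrap-around at mitosis (compartment ``N``
feeds compartment ``1``).  In the absence of drug each compartment volume
``V_n`` obeys

    dV_n/dt = k1 * V_{n-1} - k2 * V_n,

with rate constants

    k1 = (N + ln 2) / t_d,    k2 = N / t_d,

so that the uniform state is the dominant eigenmode and the total volume
grows exactly as ``exp(t * ln 2 / t_d)``.

Drug effects add, per drug ``j`` acting on a set of compartments (one cell
cycle phase, or all):

* damage     -- first-order transfer ``k_d = damage_coef * C_j(t)`` from the
  proliferating compartment into an arrested damaged pool ``D_{j,n}``;
* repair     -- first-order return ``k_r * D_{j,n}`` back to compartment
  ``n`` (concentration independent);
* apoptosis  -- irreversible loss ``k_a = apoptosis_coef * C_j(t)`` from the
  proliferating compartment into a cumulative apoptotic sink ``A``.

Damaged cells are arrested: they do not transit the cycle and do not grow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PHASES",
    "ConfigurationError",
    "CellModelConfig",
    "PhaseMap",
    "PopulationState",
    "EffectCoefficients",
    "rate_constants",
    "phase_partition",
    "initial_state",
    "population_rhs",
]

#: Cell-cycle phases in transit order.
PHASES = ("G1", "S", "G2", "M")

#: Valid values for a drug's phase of action.
PHASE_CHOICES = PHASES + ("all",)


class ConfigurationError(ValueError):
    """Raised when a model configuration violates its constraints."""


@dataclass(frozen=True)
class CellModelConfig:
    """Structural parameters of the cell-cycle compartment model.

    Parameters
    ----------
    n_compartments
        Number of compartments ``N`` the cycle is divided into (>= 4, so
        that every phase can receive at least one compartment).
    doubling_time
        Population doubling time ``t_d`` in hours (> 0).
    phase_fractions
        Proportions of the cycle spent in (G1, S, G2, M).  Must be
        nonnegative and sum to 1 within 1e-9.  Use :meth:`with_g2_auto`
        to derive G2 as the remainder.
    """

    n_compartments: int = 50
    doubling_time: float = 24.0
    phase_fractions: tuple[float, float, float, float] = (0.2, 0.3, 0.4, 0.1)

    def __post_init__(self) -> None:
        n = self.n_compartments
        if not (isinstance(n, (int, np.integer)) and not isinstance(n, bool)):
            raise ConfigurationError(f"n_compartments must be an integer, got {n!r}")
        if n < 4:
            raise ConfigurationError(f"n_compartments must be >= 4, got {n}")
        if not (self.doubling_time > 0 and math.isfinite(self.doubling_time)):
            raise ConfigurationError(
                f"doubling_time must be a positive finite number of hours, "
                f"got {self.doubling_time!r}"
            )
        fr = tuple(float(f) for f in self.phase_fractions)
        if len(fr) != 4:
            raise ConfigurationError("phase_fractions must have four entries (G1, S, G2, M)")
        if any(f < 0 for f in fr):
            raise ConfigurationError(f"phase_fractions must be nonnegative, got {fr}")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"phase_fractions must sum to 1 (got {sum(fr)!r}); "
                "use CellModelConfig.with_g2_auto to derive G2 as the remainder"
            )
        object.__setattr__(self, "phase_fractions", fr)

    @classmethod
    def with_g2_auto(
        cls,
        g1: float,
        s: float,
        m: float,
        n_compartments: int = 50,
        doubling_time: float = 24.0,
    ) -> "CellModelConfig":
        """Build a config with the G2 fraction set to ``1 - g1 - s - m``."""
        g2 = 1.0 - g1 - s - m
        if g2 < -1e-12:
            raise ConfigurationError(
                f"G1 + S + M fractions exceed 1 (remainder for G2 = {g2:.3g})"
            )
        return cls(n_compartments, doubling_time, (g1, s, max(g2, 0.0), m))

    @property
    def growth_rate(self) -> float:
        """Exponential growth rate ``a = ln 2 / t_d`` in 1/h."""
        return math.log(2.0) / self.doubling_time


def rate_constants(config: CellModelConfig) -> tuple[float, float]:
    """Transit rate constants ``(k1, k2)`` of the compartment chain.

    ``k1 = (N + ln 2) / t_d`` feeds compartment ``n`` from ``n - 1`` and
    carries the growth excess; ``k2 = N / t_d`` drains compartment ``n``
    into ``n + 1``.  Their difference is exactly ``ln 2 / t_d``.
    """
    n, td = config.n_compartments, config.doubling_time
    k1 = (n + math.log(2.0)) / td
    k2 = n / td
    return k1, k2


@dataclass(frozen=True)
class PhaseMap:
    """Assignment of the N compartments to the four cell-cycle phases.

    ``counts`` holds the number of compartments per phase in cycle order
    (G1, S, G2, M); the compartment blocks are contiguous, in that order,
    and cover ``1..N`` with mitosis in the final block.
    """

    counts: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.counts) != 4 or any(c < 1 for c in self.counts):
            raise ConfigurationError(f"each phase needs >= 1 compartment, got {self.counts}")
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))

    @property
    def n_compartments(self) -> int:
        return sum(self.counts)

    @property
    def ranges(self) -> dict[str, range]:
        """Zero-based, half-open compartment index range per phase."""
        out: dict[str, range] = {}
        start = 0
        for phase, count in zip(PHASES, self.counts):
            out[phase] = range(start, start + count)
            start += count
        return out

    def mask(self, phase: str) -> np.ndarray:
        """Boolean mask over compartments for ``phase`` ('all' selects every one)."""
        if phase == "all":
            return np.ones(self.n_compartments, dtype=bool)
        if phase not in PHASES:
            raise ConfigurationError(f"unknown phase {phase!r}; choose from {PHASE_CHOICES}")
        m = np.zeros(self.n_compartments, dtype=bool)
        r = self.ranges[phase]
        m[r.start : r.stop] = True
        return m

    def phase_of(self, compartment: int) -> str:
        """Phase containing zero-based compartment index ``compartment``."""
        for phase, r in self.ranges.items():
            if compartment in r:
                return phase
        raise IndexError(compartment)


def phase_partition(config: CellModelConfig) -> PhaseMap:
    """Allocate the N compartments to phases by largest remainder.

    Raw counts are ``fraction * N``; each phase gets the floor, and the
    leftover compartments go to the phases with the largest fractional
    remainders, ties broken in cycle order G1, S, G2, M.  A phase whose
    allocation would be zero is an error: the resolution is too coarse
    for that phase and N must be increased.
    """
    n = config.n_compartments
    raw = np.asarray(config.phase_fractions, dtype=float) * n
    base = np.floor(raw).astype(int)
    remainder = raw - base
    deficit = n - int(base.sum())
    # stable argsort on -remainder keeps cycle order among ties
    order = np.argsort(-remainder, kind="stable")
    counts = base.copy()
    for i in order[:deficit]:
        counts[i] += 1
    if (counts < 1).any():
        starved = [p for p, c in zip(PHASES, counts) if c < 1]
        raise ConfigurationError(
            f"phase(s) {starved} would receive no compartment at N={n}; "
            "increase n_compartments to resolve the shortest phase"
        )
    return PhaseMap(tuple(int(c) for c in counts))


@dataclass
class PopulationState:
    """Full state of the cell population.

    Attributes
    ----------
    v
        Proliferating compartment volumes, shape ``(N,)`` (dimensionless,
        normalised so the default initial total is 1).
    d
        Damaged-compartment volumes per drug, shape ``(n_drugs, N)``.
    a
        Cumulative volume lost to apoptosis (scalar).
    """

    v: np.ndarray
    d: np.ndarray
    a: float = 0.0

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.v.ndim != 1:
            raise ValueError("v must be a 1-D volume vector")
        if self.d.ndim != 2 or self.d.shape[1] != self.v.shape[0]:
            raise ValueError("d must have shape (n_drugs, N)")

    @property
    def n_compartments(self) -> int:
        return self.v.shape[0]

    @property
    def n_drugs(self) -> int:
        return self.d.shape[0]

    @property
    def total_volume(self) -> float:
        """Total proliferating volume, sum of V_n."""
        return float(self.v.sum())

    @property
    def damaged_volume(self) -> float:
        return float(self.d.sum())

    def pack(self) -> np.ndarray:
        """Flatten to the vector layout used by the integrator."""
        return np.concatenate([self.v, self.d.ravel(), [self.a]])

    @classmethod
    def unpack(cls, y: np.ndarray, n_compartments: int, n_drugs: int) -> "PopulationState":
        y = np.asarray(y, dtype=float)
        v = y[:n_compartments]
        d = y[n_compartments : n_compartments + n_drugs * n_compartments]
        return cls(v=v.copy(), d=d.reshape(n_drugs, n_compartments).copy(), a=float(y[-1]))


def initial_state(config: CellModelConfig, n_drugs: int = 0) -> PopulationState:
    """Uniform initial condition: every compartment holds volume 1/N.

    The uniform state is the model's dominant eigenmode, consistent with
    cells growing at a constant rate, so the drug-free trajectory started
    here is exactly exponential with rate ``ln 2 / t_d``.
    """
    n = config.n_compartments
    return PopulationState(
        v=np.full(n, 1.0 / n),
        d=np.zeros((n_drugs, n)),
        a=0.0,
    )


@dataclass(frozen=True)
class EffectCoefficients:
    """One drug's cell-cycle effect parameters.

    damage_coef and apoptosis_coef scale linearly with free concentration:
    ``k_d(t) = damage_coef * C(t)`` and ``k_a(t) = apoptosis_coef * C(t)``
    inside the phase of action (zero outside).  repair_rate ``k_r`` is a
    concentration-independent first-order return from the damaged pool.
    All rates are per hour (per concentration unit where applicable).
    """

    phase_of_action: str = "all"
    damage_coef: float = 0.0
    repair_rate: float = 0.0
    apoptosis_coef: float = 0.0

    def __post_init__(self) -> None:
        if self.phase_of_action not in PHASE_CHOICES:
            raise ConfigurationError(
                f"phase_of_action must be one of {PHASE_CHOICES}, got {self.phase_of_action!r}"
            )
        for name in ("damage_coef", "repair_rate", "apoptosis_coef"):
            val = getattr(self, name)
            if not (val >= 0 and math.isfinite(val)):
                raise ConfigurationError(f"{name} must be a nonnegative finite rate, got {val!r}")


def population_rhs(
    state: PopulationState,
    concentrations: Sequence[float],
    effects: Sequence[EffectCoefficients],
    phase_map: PhaseMap,
    k1: float,
    k2: float,
) -> PopulationState:
    """Time derivative of the population state under the given drug exposure.

    Implements, with cyclic indexing (compartment 0 is compartment N):

        dV_n/dt = k1 V_{n-1} - k2 V_n - sum_j (k_d,j + k_a,j) V_n + sum_j k_r,j D_{j,n}
        dD_{j,n}/dt = k_d,j V_n - k_r,j D_{j,n}
        dA/dt = sum_j sum_n k_a,j V_n

    where ``k_d,j = damage_coef_j * C_j`` and ``k_a,j = apoptosis_coef_j * C_j``
    restricted to drug j's phase of action.  Returns the derivative packaged
    as a :class:`PopulationState`.
    """
    if len(concentrations) != len(effects) or len(effects) != state.n_drugs:
        raise ValueError("concentrations, effects and state.d must agree on the number of drugs")
    conc = np.asarray(concentrations, dtype=float)
    if (conc < 0).any():
        raise ValueError(f"negative drug concentration: {conc}")
    if not np.all(np.isfinite(state.v)) or not np.all(np.isfinite(state.d)):
        raise ValueError("non-finite value in population state")

    v = state.v
    dv = k1 * np.roll(v, 1) - k2 * v
    dd = np.zeros_like(state.d)
    da = 0.0
    for j, eff in enumerate(effects):
        mask = phase_map.mask(eff.phase_of_action)
        kd = eff.damage_coef * conc[j] * mask
        ka = eff.apoptosis_coef * conc[j] * mask
        dv -= (kd + ka) * v
        dv += eff.repair_rate * state.d[j]
        dd[j] = kd * v - eff.repair_rate * state.d[j]
        da += float((ka * v).sum())
    return PopulationState(v=dv, d=dd, a=da)
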