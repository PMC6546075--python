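"""Run-configuration serialisation (key-value CSV) and overlay reading.

A run configuration round-trips losslessly through a two-column CSV with
header ``parameter,value``.  The key vocabulary is documented in the
README; unknown keys warn, missing required keys raise, and constraint
violations surface through the underlying domain types.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cell_population import CellModelConfig, ConfigurationError, EffectCoefficients
from .engine import DrugSpec, SimulationSpec
from .pharmacokinetics import DoseSchedule, PKConfig
from .tumour import OverlayData, TumourConfig, growth_rate

__all__ = [
    "RunConfig",
    "read_config",
    "write_config",
    "read_overlay",
    "synthesize_control",
]

REQUIRED_KEYS = (
    "n_compartments",
    "doubling_time_h",
    "phase_g1",
    "phase_s",
    "phase_m",
    "initial_diameter_mm",
    "growing_layer_mm",
    "horizon_h",
)

_GLOBAL_OPTIONAL = ("phase_g2", "output_step_h", "rtol", "atol", "max_step_h")

_DRUG_KEYS = (
    "name",
    "pk_model",
    "dose_over_v",
    "elimination_rate",
    "absorption_rate",
    "infusion_levels",
    "phase",
    "damage",
    "repair",
    "apoptosis",
    "dose_times_h",
)


@dataclass(frozen=True)
class RunConfig:
    """Complete parameterisation of one simulation run."""

    cell: CellModelConfig = field(default_factory=CellModelConfig)
    tumour: TumourConfig = field(default_factory=lambda: TumourConfig.from_diameter(6.8, 0.24))
    drugs: tuple[DrugSpec, ...] = ()
    horizon: float = 504.0
    output_step: float = 0.5
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = 1.0

    def to_simulation_spec(self) -> SimulationSpec:
        return SimulationSpec(
            cell_config=self.cell,
            drugs=self.drugs,
            horizon=self.horizon,
            output_step=self.output_step,
            rtol=self.rtol,
            atol=self.atol,
            max_step=self.max_step,
        )

    def with_schedules(self, schedules: dict[str, DoseSchedule]) -> "RunConfig":
        """Return a copy with named drugs' dose schedules replaced.

        Drugs not named in ``schedules`` get an empty schedule (no doses),
        so an arm fully determines every drug's dosing.
        """
        new_drugs = tuple(
            replace(d, schedule=schedules.get(d.name, DoseSchedule()))
            for d in self.drugs
        )
        unknown = set(schedules) - {d.name for d in self.drugs}
        if unknown:
            raise KeyError(f"schedule given for unknown drug(s): {sorted(unknown)}")
        return replace(self, drugs=new_drugs)


def _fmt(value: float) -> str:
    return repr(float(value))


def write_config(config: RunConfig, path: str | Path) -> None:
    """Serialise a run configuration to a ``parameter,value`` CSV file."""
    rows: list[tuple[str, str]] = [
        ("n_compartments", str(config.cell.n_compartments)),
        ("doubling_time_h", _fmt(config.cell.doubling_time)),
        ("phase_g1", _fmt(config.cell.phase_fractions[0])),
        ("phase_s", _fmt(config.cell.phase_fractions[1])),
        ("phase_g2", _fmt(config.cell.phase_fractions[2])),
        ("phase_m", _fmt(config.cell.phase_fractions[3])),
        ("initial_diameter_mm", _fmt(config.tumour.initial_diameter)),
        ("growing_layer_mm", _fmt(config.tumour.layer_thickness)),
        ("horizon_h", _fmt(config.horizon)),
        ("output_step_h", _fmt(config.output_step)),
        ("rtol", _fmt(config.rtol)),
        ("atol", _fmt(config.atol)),
        ("max_step_h", _fmt(config.max_step)),
    ]
    for i, drug in enumerate(config.drugs, start=1):
        p = f"drug{i}_"
        rows.append((p + "name", drug.name))
        rows.append((p + "pk_model", drug.pk.model_type))
        rows.append((p + "dose_over_v", _fmt(drug.pk.dose_over_v)))
        rows.append((p + "elimination_rate", _fmt(drug.pk.elimination_rate)))
        if drug.pk.absorption_rate is not None:
            rows.append((p + "absorption_rate", _fmt(drug.pk.absorption_rate)))
        if drug.pk.infusion_levels:
            levels = "|".join(f"{a!r}:{b!r}:{c!r}" for a, b, c in drug.pk.infusion_levels)
            rows.append((p + "infusion_levels", levels))
        rows.append((p + "phase", drug.effects.phase_of_action))
        rows.append((p + "damage", _fmt(drug.effects.damage_coef)))
        rows.append((p + "repair", _fmt(drug.effects.repair_rate)))
        rows.append((p + "apoptosis", _fmt(drug.effects.apoptosis_coef)))
        if drug.schedule.dose_times:
            rows.append(
                (p + "dose_times_h", ";".join(_fmt(t) for t in drug.schedule.dose_times))
            )
    frame = pd.DataFrame(rows, columns=["parameter", "value"])
    frame.to_csv(path, index=False)


def _num(kv: dict[str, str], key: str) -> float:
    try:
        return float(kv[key])
    except ValueError as err:
        raise ConfigurationError(f"value for {key!r} is not numeric: {kv[key]!r}") from err


def read_config(path: str | Path) -> RunConfig:
    """Parse a ``parameter,value`` CSV into a validated :class:`RunConfig`."""
    frame = pd.read_csv(path, dtype=str)
    if list(frame.columns[:2]) != ["parameter", "value"]:
        raise ConfigurationError(
            f"{path}: expected header 'parameter,value', got {list(frame.columns)}"
        )
    kv = dict(zip(frame["parameter"].str.strip(), frame["value"].astype(str).str.strip()))

    missing = [k for k in REQUIRED_KEYS if k not in kv]
    if missing:
        raise ConfigurationError(f"{path}: missing required key(s): {missing}")

    drug_indices = sorted(
        {
            int(k.split("_", 1)[0][4:])
            for k in kv
            if k.startswith("drug") and "_" in k and k.split("_", 1)[0][4:].isdigit()
        }
    )
    known = set(REQUIRED_KEYS) | set(_GLOBAL_OPTIONAL)
    for i in drug_indices:
        known |= {f"drug{i}_{suffix}" for suffix in _DRUG_KEYS}
    unknown = sorted(set(kv) - known)
    if unknown:
        warnings.warn(f"{path}: ignoring unknown key(s): {unknown}", stacklevel=2)

    g1 = _num(kv, "phase_g1")
    s = _num(kv, "phase_s")
    m = _num(kv, "phase_m")
    if "phase_g2" in kv:
        fractions = (g1, s, _num(kv, "phase_g2"), m)
    else:
        fractions = (g1, s, 1.0 - g1 - s - m, m)
    cell = CellModelConfig(
        n_compartments=int(_num(kv, "n_compartments")),
        doubling_time=_num(kv, "doubling_time_h"),
        phase_fractions=fractions,
    )
    tumour = TumourConfig.from_diameter(
        _num(kv, "initial_diameter_mm"), _num(kv, "growing_layer_mm")
    )

    drugs = []
    for i in drug_indices:
        p = f"drug{i}_"
        model_type = kv.get(p + "pk_model", "kpd_decay")
        levels: tuple[tuple[float, float, float], ...] = ()
        if p + "infusion_levels" in kv and kv[p + "infusion_levels"]:
            levels = tuple(
                tuple(float(x) for x in chunk.split(":"))  # type: ignore[misc]
                for chunk in kv[p + "infusion_levels"].split("|")
            )
        pk = PKConfig(
            model_type=model_type,
            dose_over_v=_num(kv, p + "dose_over_v") if p + "dose_over_v" in kv else 1.0,
            elimination_rate=(
                _num(kv, p + "elimination_rate") if p + "elimination_rate" in kv else 0.1
            ),
            absorption_rate=(
                _num(kv, p + "absorption_rate") if p + "absorption_rate" in kv else None
            ),
            infusion_levels=levels,
        )
        effects = EffectCoefficients(
            phase_of_action=kv.get(p + "phase", "all"),
            damage_coef=_num(kv, p + "damage") if p + "damage" in kv else 0.0,
            repair_rate=_num(kv, p + "repair") if p + "repair" in kv else 0.0,
            apoptosis_coef=_num(kv, p + "apoptosis") if p + "apoptosis" in kv else 0.0,
        )
        times: tuple[float, ...] = ()
        if p + "dose_times_h" in kv and kv[p + "dose_times_h"]:
            times = tuple(float(x) for x in kv[p + "dose_times_h"].split(";"))
        drugs.append(
            DrugSpec(
                name=kv.get(p + "name", f"drug{i}"),
                pk=pk,
                schedule=DoseSchedule(times),
                effects=effects,
            )
        )

    return RunConfig(
        cell=cell,
        tumour=tumour,
        drugs=tuple(drugs),
        horizon=_num(kv, "horizon_h"),
        output_step=_num(kv, "output_step_h") if "output_step_h" in kv else 0.5,
        rtol=_num(kv, "rtol") if "rtol" in kv else 1e-8,
        atol=_num(kv, "atol") if "atol" in kv else 1e-10,
        max_step=_num(kv, "max_step_h") if "max_step_h" in kv else 1.0,
    )


def read_overlay(path: str | Path, volume_dialect: str = "sphere") -> OverlayData:
    """Read an observed growth curve for overlay / control fitting.

    The CSV header declares the units: a time column named ``time_h`` or
    ``time_day``, and a size column named ``diameter`` (mm) or ``volume``
    (mm^3).  Volumes are converted to diameters either through the
    spherical relation ``(6 V / pi)^(1/3)`` (``volume_dialect='sphere'``)
    or a bare cube root (``'cube_root'``).
    """
    frame = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in frame.columns}
    if "time_h" in cols:
        t = frame[cols["time_h"]].to_numpy(dtype=float)
    elif "time_day" in cols:
        t = frame[cols["time_day"]].to_numpy(dtype=float) * 24.0
    else:
        raise ConfigurationError(
            f"{path}: overlay needs a 'time_h' or 'time_day' column (units must be declared)"
        )
    if "diameter" in cols:
        diam = frame[cols["diameter"]].to_numpy(dtype=float)
    elif "volume" in cols:
        vol = frame[cols["volume"]].to_numpy(dtype=float)
        if volume_dialect == "sphere":
            diam = np.cbrt(6.0 * vol / math.pi)
        elif volume_dialect == "cube_root":
            diam = np.cbrt(vol)
        else:
            raise ValueError(f"volume_dialect must be 'sphere' or 'cube_root', got {volume_dialect!r}")
    else:
        raise ConfigurationError(f"{path}: overlay needs a 'diameter' or 'volume' column")
    return OverlayData(time_h=t, diameter_mm=diam)


def synthesize_control(
    r0_mm: float,
    layer_mm: float,
    t_d: float,
    noise_sd: float,
    times_h,
    seed: int | None = None,
) -> OverlayData:
    """Generate a synthetic control (untreated) diameter curve.

    Diameters follow the drug-free rim law ``2 * (R0 + a*d*t)`` with
    additive Gaussian measurement noise of standard deviation
    ``noise_sd`` mm, reproducible under ``seed``.  Stands in for an
    observed control arm when exercising the overlay / fitting path.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    t = np.asarray(times_h, dtype=float)
    a = growth_rate(t_d)
    diam = 2.0 * (r0_mm + a * layer_mm * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        diam = diam + rng.normal(0.0, noise_sd, size=t.shape)
    return OverlayData(time_h=t, diameter_mm=diam)
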