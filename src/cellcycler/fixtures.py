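"""Packaged case-study parameterisations and their dosing arms.

Three preclinical combination studies ship as key-value CSV fixtures:

``case1``  EGFR inhibitor (G1 damage) with a taxane (M-phase damage and
           apoptosis) — schedule-sequencing exploration in a hypothetical
           xenograft, default cell/tumour settings.
``case2``  CDK4/6 inhibitor (G1 damage) with gemcitabine (S-phase damage
           and apoptosis) in a Calu-6 xenograft parameterisation.
``case3``  MEK inhibitor (G1 damage) with docetaxel (M-phase damage and
           apoptosis, slow elimination) in an HCT-116 xenograft
           parameterisation.

Each fixture carries the base drug parameterisation with an empty dosing
schedule; the named arms supply the schedules (all arms run over a
three-week, 504 h horizon; "day 1" is t = 0 h).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .config import RunConfig, read_config
from .engine import SimulationSpec
from .pharmacokinetics import DoseSchedule, expand_schedule

__all__ = ["CaseStudy", "load_fixture", "fixture_names", "fixture_path"]

_FIXTURE_FILES = {
    "case1": "case1_egfri_taxol.csv",
    "case2": "case2_cdki_gemcitabine.csv",
    "case3": "case3_meki_docetaxel.csv",
}


def fixture_names() -> tuple[str, ...]:
    return tuple(_FIXTURE_FILES)


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture CSV."""
    if name not in _FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURE_FILES)}")
    return Path(resources.files("cellcycler.data") / _FIXTURE_FILES[name])


@dataclass(frozen=True)
class CaseStudy:
    """A fixture configuration plus its named dosing arms."""

    name: str
    config: RunConfig
    arms: dict[str, dict[str, DoseSchedule]]

    def arm_config(self, arm: str) -> RunConfig:
        if arm not in self.arms:
            raise KeyError(f"unknown arm {arm!r} for {self.name}; choose from {sorted(self.arms)}")
        return self.config.with_schedules(self.arms[arm])

    def arm_spec(self, arm: str) -> SimulationSpec:
        return self.arm_config(arm).to_simulation_spec()


def _case1_arms() -> dict[str, dict[str, DoseSchedule]]:
    taxol_day1 = expand_schedule(start_day=1, n_days_on=1, n_cycles=3)
    taxol_day6 = expand_schedule(start_day=6, n_days_on=1, n_cycles=3)
    egfri_days_1_5 = expand_schedule(start_day=1, n_days_on=5, n_cycles=3)
    egfri_days_2_6 = expand_schedule(start_day=2, n_days_on=5, n_cycles=3)
    return {
        "taxol": {"Taxol": taxol_day1},
        "egfri": {"EGFRi": egfri_days_1_5},
        "simultaneous": {"Taxol": taxol_day1, "EGFRi": egfri_days_1_5},
        "taxol_first": {"Taxol": taxol_day1, "EGFRi": egfri_days_2_6},
        "egfri_first": {"EGFRi": egfri_days_1_5, "Taxol": taxol_day6},
    }


def _case2_arms() -> dict[str, dict[str, DoseSchedule]]:
    # Gemcitabine doses once on day 3 of each 7-day cycle; the sequenced
    # arm doses on day 3 of each 4-day cycle after the 12-day CDK4/6
    # inhibitor course (days 15 and 19).
    ly_daily_21 = expand_schedule(n_days_on=21, cycle_length_days=21, n_cycles=1)
    ly_daily_12 = expand_schedule(n_days_on=12, cycle_length_days=12, n_cycles=1)
    gem_q7 = expand_schedule(start_day=3, n_days_on=1, cycle_length_days=7, n_cycles=3)
    gem_seq = DoseSchedule.from_times([336.0, 432.0])  # days 15 and 19
    return {
        "control": {},
        "ly": {"LY2835219": ly_daily_21},
        "gemcitabine": {"Gemcitabine": gem_q7},
        "combined": {"LY2835219": ly_daily_21, "Gemcitabine": gem_q7},
        "sequential": {"LY2835219": ly_daily_12, "Gemcitabine": gem_seq},
    }


def _case3_arms() -> dict[str, dict[str, DoseSchedule]]:
    meki_bid_7 = expand_schedule(n_days_on=7, doses_per_day=2, cycle_length_days=7, n_cycles=1)
    # docetaxel-first: single dose, then the MEKi course starts 24 h later
    meki_bid_7_shifted = DoseSchedule.from_times(
        [t + 24.0 for t in meki_bid_7.dose_times]
    )
    doc_single = DoseSchedule.from_times([0.0])
    # MEKi-first: docetaxel 24 h after the last MEKi dose (t = 156 + 24 h)
    doc_after_meki = DoseSchedule.from_times([meki_bid_7.dose_times[-1] + 24.0])
    return {
        "control": {},
        "meki": {"MEKi": meki_bid_7},
        "docetaxel": {"Docetaxel": doc_single},
        "meki_first": {"MEKi": meki_bid_7, "Docetaxel": doc_after_meki},
        "docetaxel_first": {"Docetaxel": doc_single, "MEKi": meki_bid_7_shifted},
    }


_ARM_BUILDERS = {
    "case1": _case1_arms,
    "case2": _case2_arms,
    "case3": _case3_arms,
}


def load_fixture(name: str) -> CaseStudy:
    """Load a packaged case study: base configuration plus dosing arms."""
    path = fixture_path(name)
    config = read_config(path)
    return CaseStudy(name=name, config=config, arms=_ARM_BUILDERS[name]())
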