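"""Patient-level data containers for longitudinal ANC records.

ANC (absolute neutrophil count) is recorded in units of 10^9 cells/L.
Study days are 1-based integers with Day 1 = day of chemotherapy
administration, so day arithmetic follows the convention
``time = event day - chemotherapy day + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Baseline body-weight strata used for stratified resampling, defined by the
#: cut-points <65 kg, 65-75 kg (inclusive both ends), >75 kg.
STRATA: tuple[str, str, str] = ("<65", "65-75", ">75")

DEFAULT_WEIGHT_CUTPOINTS: tuple[float, float] = (65.0, 75.0)


def weight_stratum(weight_kg: float, cutpoints: tuple[float, float] = DEFAULT_WEIGHT_CUTPOINTS) -> str:
    """Assign a baseline-weight stratum label.

    Weights strictly below the lower cut-point map to ``"<65"``, weights
    strictly above the upper cut-point to ``">75"``, and everything in the
    closed interval between them to ``"65-75"``.
    """
    if weight_kg <= 0:
        raise ValueError(f"weight must be positive, got {weight_kg}")
    lo, hi = cutpoints
    if weight_kg < lo:
        return STRATA[0]
    if weight_kg > hi:
        return STRATA[2]
    return STRATA[1]


@dataclass(frozen=True)
class AncSeries:
    """One patient-cycle's ordered ANC observations.

    Parameters
    ----------
    patient_id : str
        Patient identifier.
    cycle : int
        1-based chemotherapy cycle number.
    observations : sequence of (day, anc)
        Study day (integer >= 1) and ANC (x10^9/L, >= 0) pairs with strictly
        increasing days.
    """

    patient_id: str
    cycle: int
    observations: tuple[tuple[int, float], ...]

    def __init__(self, patient_id: str, cycle: int, observations: Iterable[tuple[int, float]]):
        obs = tuple((int(d), float(a)) for d, a in observations)
        days = [d for d, _ in obs]
        if any(d < 1 for d in days):
            raise ValueError("study days must be >= 1")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("study days must be strictly increasing")
        if any(a < 0 for _, a in obs):
            raise ValueError("ANC values must be non-negative")
        object.__setattr__(self, "patient_id", str(patient_id))
        object.__setattr__(self, "cycle", int(cycle))
        object.__setattr__(self, "observations", obs)

    @property
    def days(self) -> tuple[int, ...]:
        return tuple(d for d, _ in self.observations)

    @property
    def values(self) -> tuple[float, ...]:
        return tuple(a for _, a in self.observations)

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.observations:
            return np.empty(0, dtype=int), np.empty(0, dtype=float)
        days, values = zip(*self.observations)
        return np.asarray(days, dtype=int), np.asarray(values, dtype=float)

    def __len__(self) -> int:
        return len(self.observations)


@dataclass
class PatientRecord:
    """A patient's arm assignment, baseline weight, and per-cycle ANC series.

    ``temperature_events`` holds (cycle, study day, temperature in deg C)
    triples; they feed the febrile-neutropenia endpoint.
    """

    patient_id: str
    arm: str
    weight_kg: float
    cycles: tuple[AncSeries, ...]
    stratum: str = ""
    temperature_events: tuple[tuple[int, int, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ValueError(f"weight must be positive, got {self.weight_kg}")
        derived = weight_stratum(self.weight_kg)
        if not self.stratum:
            self.stratum = derived
        elif self.stratum != derived:
            raise ValueError(
                f"stratum {self.stratum!r} inconsistent with weight {self.weight_kg} kg "
                f"(expected {derived!r})"
            )
        cycles = tuple(self.cycles)
        if any(b.cycle <= a.cycle for a, b in zip(cycles, cycles[1:])):
            raise ValueError("cycles must be ordered by cycle number")
        self.cycles = cycles
        self.temperature_events = tuple(
            (int(c), int(d), float(t)) for c, d, t in self.temperature_events
        )

    def series_for(self, cycle: int) -> AncSeries:
        for s in self.cycles:
            if s.cycle == cycle:
                return s
        raise KeyError(f"patient {self.patient_id} has no cycle {cycle}")

    def has_cycle(self, cycle: int) -> bool:
        return any(s.cycle == cycle for s in self.cycles)

    def temps_for(self, cycle: int) -> tuple[tuple[int, float], ...]:
        return tuple((d, t) for c, d, t in self.temperature_events if c == cycle)


Cohort = Sequence[PatientRecord]


def arm_labels(cohort: Cohort) -> tuple[str, ...]:
    """Arm labels in order of first appearance."""
    seen: dict[str, None] = {}
    for p in cohort:
        seen.setdefault(p.arm, None)
    return tuple(seen)


def select_arm(cohort: Cohort, arm: str) -> list[PatientRecord]:
    out = [p for p in cohort if p.arm == arm]
    if not out:
        raise KeyError(f"unknown arm label {arm!r}")
    return out
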