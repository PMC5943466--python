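"""Neutropenia endpoint derivation from observed ANC series.

The primary endpoint is the duration of severe neutropenia (DSN): the
interval, in days, from the first observed grade-4 neutropenia
(ANC < 0.5 x10^9/L) to the first subsequent recovery to ANC >= 2.0 x10^9/L.
Secondary endpoints are the nadir (lowest observed ANC and its timing), time
to ANC recovery (>= 2.0 after the nadir, among patients who dipped below
2.0), and febrile neutropenia (temperature > 38.2 deg C within one day of a
grade-4 ANC, or a reported adverse event of febrile neutropenia).

Boundary conventions, as used throughout: grade 4 is ANC < 0.5 (strict),
recovery is ANC >= 2.0 (inclusive), and "dipped" is ANC < 2.0 (strict).
A DSN interval of onset day d and recovery day r counts r - d days, so
onset with next-day recovery is one day of severe neutropenia.
"""

from __future__ import annotations

import statistics
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

from .cohort import AncSeries

GRADE4_THRESHOLD = 0.5
RECOVERY_THRESHOLD = 2.0
FEVER_THRESHOLD_C = 38.2
FEVER_WINDOW_DAYS = 1


class DsnResult(NamedTuple):
    """DSN in days, with ``censored`` set when grade-4 neutropenia was
    observed but no in-cycle recovery to >= 2.0 was seen (the count then
    covers observed severe days only: last day - onset + 1)."""

    days: int
    censored: bool


class NadirResult(NamedTuple):
    depth: float
    nadir_day: int
    time_to_nadir: int


class RecoveryResult(NamedTuple):
    """Time to ANC recovery. ``time_to_recovery_days`` is None when the
    series never dipped below 2.0 (endpoint not applicable) or never
    recovered in-cycle (then ``censored`` is True)."""

    dipped_below_2: bool
    recovery_day: Optional[int]
    time_to_recovery_days: Optional[int]
    censored: bool


def derive_dsn(series: AncSeries) -> DsnResult:
    """Duration of severe neutropenia for one patient-cycle.

    Let d0 be the first observed day with ANC < 0.5. If there is none, DSN
    is 0. Otherwise let r be the first day >= d0 with ANC >= 2.0; DSN is
    r - d0. If recovery is never observed, DSN is the number of observed
    severe days (last day - d0 + 1) and the result is flagged censored.
    """
    if len(series) == 0:
        raise ValueError("cannot derive DSN from an empty series")
    onset = None
    for day, anc in series.observations:
        if onset is None:
            if anc < GRADE4_THRESHOLD:
                onset = day
        elif anc >= RECOVERY_THRESHOLD:
            return DsnResult(day - onset, False)
    if onset is None:
        return DsnResult(0, False)
    last_day = series.observations[-1][0]
    return DsnResult(last_day - onset + 1, True)


def derive_nadir(series: AncSeries, chemo_day: int = 1) -> NadirResult:
    """Lowest observed ANC, its (earliest) day, and time since chemotherapy.

    Time to nadir follows the 1-based convention nadir_day - chemo_day + 1.
    Ties in the minimum break to the earliest day.
    """
    if len(series) == 0:
        raise ValueError("cannot derive nadir from an empty series")
    depth = min(series.values)
    nadir_day = next(d for d, a in series.observations if a == depth)
    return NadirResult(depth, nadir_day, nadir_day - chemo_day + 1)


def derive_time_to_recovery(series: AncSeries, chemo_day: int = 1) -> RecoveryResult:
    """Time from chemotherapy to ANC recovery >= 2.0 after the nadir.

    Applicable only to series that dip below 2.0; the recovery day is the
    first day strictly after the nadir day with ANC >= 2.0, and the time is
    recovery_day - chemo_day + 1.
    """
    if len(series) == 0:
        raise ValueError("cannot derive recovery from an empty series")
    if min(series.values) >= RECOVERY_THRESHOLD:
        return RecoveryResult(False, None, None, False)
    nadir_day = derive_nadir(series, chemo_day).nadir_day
    for day, anc in series.observations:
        if day > nadir_day and anc >= RECOVERY_THRESHOLD:
            return RecoveryResult(True, day, day - chemo_day + 1, False)
    return RecoveryResult(True, None, None, True)


def flag_febrile_neutropenia(
    series: AncSeries,
    temps: Iterable[tuple[int, float]] = (),
    ae_flag: bool = False,
) -> bool:
    """Febrile neutropenia: temperature strictly > 38.2 deg C within one day
    of an observed ANC < 0.5, and/or a reported febrile-neutropenia AE."""
    if ae_flag:
        return True
    severe_days = [d for d, a in series.observations if a < GRADE4_THRESHOLD]
    if not severe_days:
        return False
    for t_day, temp in temps:
        if temp > FEVER_THRESHOLD_C and any(abs(t_day - u) <= FEVER_WINDOW_DAYS for u in severe_days):
            return True
    return False


@dataclass(frozen=True)
class EndpointResult:
    """All derived endpoints for one patient-cycle."""

    patient_id: str
    cycle: int
    dsn_days: int
    dsn_censored: bool
    nadir_depth: float
    nadir_day: int
    time_to_nadir: int
    dipped_below_2: bool
    recovery_day: Optional[int]
    time_to_recovery_days: Optional[int]
    recovery_censored: bool
    febrile_neutropenia: bool


def derive_endpoints(
    series: AncSeries,
    temps: Iterable[tuple[int, float]] = (),
    ae_flag: bool = False,
    chemo_day: int = 1,
) -> EndpointResult:
    """Derive every endpoint for one series (see the individual functions)."""
    dsn = derive_dsn(series)
    nadir = derive_nadir(series, chemo_day)
    rec = derive_time_to_recovery(series, chemo_day)
    return EndpointResult(
        patient_id=series.patient_id,
        cycle=series.cycle,
        dsn_days=dsn.days,
        dsn_censored=dsn.censored,
        nadir_depth=nadir.depth,
        nadir_day=nadir.nadir_day,
        time_to_nadir=nadir.time_to_nadir,
        dipped_below_2=rec.dipped_below_2,
        recovery_day=rec.recovery_day,
        time_to_recovery_days=rec.time_to_recovery_days,
        recovery_censored=rec.censored,
        febrile_neutropenia=flag_febrile_neutropenia(series, temps, ae_flag),
    )


@dataclass(frozen=True)
class ArmSummary:
    """Per-arm endpoint summary for one cycle.

    ``sd_dsn`` uses the n-1 denominator; for n == 1 it is reported as 0.0
    with ``sd_defined`` False. ``median_time_to_recovery`` is restricted to
    patients whose ANC dipped below 2.0 and who recovered in-cycle
    (``n_dipped`` counts the eligible patients).
    """

    arm: str
    cycle: int
    n: int
    mean_dsn: float
    sd_dsn: float
    sd_defined: bool
    median_dsn: float
    dsn_frequency: dict[int, int]
    n_dsn_censored: int
    median_time_to_recovery: Optional[float]
    n_dipped: int
    median_nadir_depth: float
    median_nadir_day: float
    fn_count: int


def summarize_arm(results: Sequence[EndpointResult], arm: str = "", cycle: int = 1) -> ArmSummary:
    """Summarize derived endpoints for one arm-cycle."""
    if not results:
        raise ValueError("cannot summarize an empty arm")
    dsn = [r.dsn_days for r in results]
    n = len(dsn)
    mean = sum(dsn) / n
    if n > 1:
        sd, sd_defined = statistics.stdev(dsn), True
    else:
        sd, sd_defined = 0.0, False
    recovery_times = [
        r.time_to_recovery_days
        for r in results
        if r.dipped_below_2 and r.time_to_recovery_days is not None
    ]
    return ArmSummary(
        arm=arm,
        cycle=cycle,
        n=n,
        mean_dsn=mean,
        sd_dsn=sd,
        sd_defined=sd_defined,
        median_dsn=float(statistics.median(dsn)),
        dsn_frequency=dict(sorted(Counter(dsn).items())),
        n_dsn_censored=sum(r.dsn_censored for r in results),
        median_time_to_recovery=float(statistics.median(recovery_times)) if recovery_times else None,
        n_dipped=sum(r.dipped_below_2 for r in results),
        median_nadir_depth=float(statistics.median(r.nadir_depth for r in results)),
        median_nadir_day=float(statistics.median(r.nadir_day for r in results)),
        fn_count=sum(r.febrile_neutropenia for r in results),
    )


def cohort_endpoints(cohort, cycle: int = 1) -> dict[str, list[EndpointResult]]:
    """Derive endpoints for every patient with the given cycle, grouped by arm.

    Patients lacking the cycle (e.g. early discontinuation) are skipped.
    """
    by_arm: dict[str, list[EndpointResult]] = {}
    for patient in cohort:
        if not patient.has_cycle(cycle):
            continue
        res = derive_endpoints(patient.series_for(cycle), patient.temps_for(cycle))
        by_arm.setdefault(patient.arm, []).append(res)
    return by_arm
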