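"""Delimited-text I/O for cohorts, endpoints, and comparison results.

Cohorts are stored as two (optionally three) comma-separated files with a
header row, preceded by ``#`` comment lines recording provenance (package
version and the simulation seed when known):

* patients:     patient_id, arm, weight_kg, stratum
* observations: patient_id, cycle, study_day, anc
* temperatures: patient_id, cycle, study_day, temp_c   (optional)

Day numbering is 1-based with Day 1 = chemotherapy administration.
Readers validate on load: negative ANC, non-positive weight, duplicate
(patient, cycle, day) rows, and unknown patient ids are rejected with
line-numbered messages; out-of-order observation days are accepted, sorted,
and warned about.
"""

from __future__ import annotations

import csv
import hashlib
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

from .cohort import AncSeries, PatientRecord
from .endpoints import ArmSummary, EndpointResult
from .inference import BootstrapResult
from .simulate import SimConfig


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _write_csv(path, header: Sequence[str], rows: Iterable[Sequence], comments: Sequence[str] = ()) -> None:
    with open(path, "w", newline="") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        w = csv.writer(fh)
        w.writerow(header)
        w.writerows(rows)


def write_cohort(
    cohort: Sequence[PatientRecord],
    patients_path,
    observations_path,
    temperatures_path=None,
    seed: Optional[int] = None,
) -> None:
    from . import __version__

    comments = [f"neutrokit {__version__} cohort"]
    if seed is not None:
        comments.append(f"seed: {seed}")
    _write_csv(
        patients_path,
        ("patient_id", "arm", "weight_kg", "stratum"),
        [(p.patient_id, p.arm, repr(p.weight_kg), p.stratum) for p in cohort],
        comments,
    )
    obs_rows = [
        (p.patient_id, s.cycle, day, repr(anc))
        for p in cohort
        for s in p.cycles
        for day, anc in s.observations
    ]
    _write_csv(observations_path, ("patient_id", "cycle", "study_day", "anc"), obs_rows, comments)
    if temperatures_path is not None:
        temp_rows = [
            (p.patient_id, c, d, repr(t)) for p in cohort for c, d, t in p.temperature_events
        ]
        _write_csv(
            temperatures_path, ("patient_id", "cycle", "study_day", "temp_c"), temp_rows, comments
        )


class CohortFormatError(ValueError):
    """Malformed or invalid cohort file; the message names file and line."""


def _read_rows(path, expected_header: Sequence[str]):
    """Yield (line_number, row-dict); line numbers count every physical line."""
    with open(path, newline="") as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            if line.lstrip().startswith("#") or not line.strip():
                continue
            fields = next(csv.reader([line]))
            if header is None:
                header = [f.strip() for f in fields]
                missing = set(expected_header) - set(header)
                if missing:
                    raise CohortFormatError(
                        f"{path} line {lineno}: missing column(s) {sorted(missing)}"
                    )
                continue
            if len(fields) != len(header):
                raise CohortFormatError(
                    f"{path} line {lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            yield lineno, dict(zip(header, fields))


def _parse_number(path, lineno, row, col, kind=float):
    try:
        return kind(row[col])
    except ValueError as exc:
        raise CohortFormatError(f"{path} line {lineno}: non-numeric {col!r}: {row[col]!r}") from exc


def read_cohort(patients_path, observations_path, temperatures_path=None) -> list[PatientRecord]:
    """Load and validate a cohort written by :func:`write_cohort` (or any
    files with the same columns)."""
    patients: dict[str, dict] = {}
    for lineno, row in _read_rows(patients_path, ("patient_id", "arm", "weight_kg", "stratum")):
        pid = row["patient_id"]
        if pid in patients:
            raise CohortFormatError(f"{patients_path} line {lineno}: duplicate patient {pid!r}")
        weight = _parse_number(patients_path, lineno, row, "weight_kg")
        if weight <= 0:
            raise CohortFormatError(f"{patients_path} line {lineno}: weight must be > 0, got {weight}")
        patients[pid] = {"arm": row["arm"], "weight": weight, "stratum": row["stratum"]}

    obs: dict[str, dict[int, list[tuple[int, float]]]] = {pid: {} for pid in patients}
    seen: dict[tuple[str, int, int], int] = {}
    unsorted_cycles: set[tuple[str, int]] = set()
    for lineno, row in _read_rows(observations_path, ("patient_id", "cycle", "study_day", "anc")):
        pid = row["patient_id"]
        if pid not in patients:
            raise CohortFormatError(
                f"{observations_path} line {lineno}: unknown patient {pid!r}"
            )
        cycle = _parse_number(observations_path, lineno, row, "cycle", int)
        day = _parse_number(observations_path, lineno, row, "study_day", int)
        anc = _parse_number(observations_path, lineno, row, "anc")
        if anc < 0:
            raise CohortFormatError(
                f"{observations_path} line {lineno}: negative ANC {anc} "
                f"for patient {pid!r}"
            )
        key = (pid, cycle, day)
        if key in seen:
            raise CohortFormatError(
                f"{observations_path} line {lineno}: duplicate observation for "
                f"patient {pid!r}, cycle {cycle}, day {day} (first at line {seen[key]})"
            )
        seen[key] = lineno
        series = obs[pid].setdefault(cycle, [])
        if series and day < series[-1][0]:
            unsorted_cycles.add((pid, cycle))
        series.append((day, anc))
    if unsorted_cycles:
        warnings.warn(
            f"{observations_path}: observations out of day order for "
            f"{sorted(unsorted_cycles)}; sorted on load",
            stacklevel=2,
        )

    temps: dict[str, list[tuple[int, int, float]]] = {pid: [] for pid in patients}
    if temperatures_path is not None:
        for lineno, row in _read_rows(
            temperatures_path, ("patient_id", "cycle", "study_day", "temp_c")
        ):
            pid = row["patient_id"]
            if pid not in patients:
                raise CohortFormatError(
                    f"{temperatures_path} line {lineno}: unknown patient {pid!r}"
                )
            temps[pid].append(
                (
                    _parse_number(temperatures_path, lineno, row, "cycle", int),
                    _parse_number(temperatures_path, lineno, row, "study_day", int),
                    _parse_number(temperatures_path, lineno, row, "temp_c"),
                )
            )

    cohort = []
    for pid, meta in patients.items():
        cycles = tuple(
            AncSeries(pid, cycle, sorted(days))
            for cycle, days in sorted(obs[pid].items())
        )
        try:
            rec = PatientRecord(
                pid, meta["arm"], meta["weight"], cycles,
                stratum=meta["stratum"], temperature_events=tuple(temps[pid]),
            )
        except ValueError as exc:
            raise CohortFormatError(f"patient {pid!r}: {exc}") from exc
        cohort.append(rec)
    return cohort


def load_sim_config(path) -> SimConfig:
    """Read a simulation configuration from a YAML file (keys mirror
    :class:`~neutrokit.simulate.SimConfig`, with ``arms`` a list of
    ``{label, dose_potency, n_patients}`` blocks)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise CohortFormatError(f"{path}: config must be a mapping")
    try:
        return SimConfig.from_dict(data)
    except (TypeError, ValueError) as exc:
        raise CohortFormatError(f"{path}: invalid config: {exc}") from exc


def save_sim_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def write_endpoints(results: Sequence[EndpointResult], path, arm_by_patient=None, seed=None) -> None:
    header = (
        "patient_id", "arm", "cycle", "dsn_days", "dsn_censored", "nadir_depth",
        "nadir_day", "time_to_nadir", "dipped_below_2", "recovery_day",
        "time_to_recovery_days", "recovery_censored", "febrile_neutropenia",
    )
    arm_by_patient = arm_by_patient or {}
    rows = [
        (
            r.patient_id, arm_by_patient.get(r.patient_id, ""), r.cycle, r.dsn_days,
            int(r.dsn_censored), repr(r.nadir_depth), r.nadir_day, r.time_to_nadir,
            int(r.dipped_below_2),
            "" if r.recovery_day is None else r.recovery_day,
            "" if r.time_to_recovery_days is None else r.time_to_recovery_days,
            int(r.recovery_censored), int(r.febrile_neutropenia),
        )
        for r in results
    ]
    comments = [] if seed is None else [f"seed: {seed}"]
    _write_csv(path, header, rows, comments)


def write_summaries(summaries: Sequence[ArmSummary], path, seed=None) -> None:
    header = (
        "arm", "cycle", "n", "mean_dsn", "sd_dsn", "sd_defined", "median_dsn",
        "dsn_frequency", "n_dsn_censored", "median_time_to_recovery", "n_dipped",
        "median_nadir_depth", "median_nadir_day", "fn_count",
    )
    rows = [
        (
            s.arm, s.cycle, s.n, repr(s.mean_dsn), repr(s.sd_dsn), int(s.sd_defined),
            repr(s.median_dsn),
            ";".join(f"{k}:{v}" for k, v in s.dsn_frequency.items()),
            s.n_dsn_censored,
            "" if s.median_time_to_recovery is None else repr(s.median_time_to_recovery),
            s.n_dipped, repr(s.median_nadir_depth), repr(s.median_nadir_day), s.fn_count,
        )
        for s in summaries
    ]
    comments = [] if seed is None else [f"seed: {seed}"]
    _write_csv(path, header, rows, comments)


def write_comparisons(results: Sequence[BootstrapResult], path) -> None:
    header = (
        "exp_label", "ctrl_label", "cycle", "n_exp", "n_ctrl", "mean_exp", "mean_ctrl",
        "point_diff", "ci_low", "ci_high", "p_noninferiority", "p_superiority",
        "noninferior", "margin_days", "n_resamples", "seed",
    )
    rows = [
        (
            r.exp_label, r.ctrl_label, r.cycle, r.n_exp, r.n_ctrl, repr(r.mean_exp),
            repr(r.mean_ctrl), repr(r.point_diff), repr(r.ci_low), repr(r.ci_high),
            repr(r.p_noninferiority), repr(r.p_superiority), int(r.noninferior),
            repr(r.margin_days), r.n_resamples, r.seed,
        )
        for r in results
    ]
    comments = [f"seed: {results[0].seed}"] if results else []
    _write_csv(path, header, rows, comments)
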