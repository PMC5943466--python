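"""Golden-value reproduction of the published Cycle-1 DSN analysis.

The reference cohort reconstructs the published per-patient Cycle-1 DSN
distribution of the four-arm trial (three weight-based doses of a
long-acting G-CSF versus pegfilgrastim). Running the endpoint and
bootstrap pipeline on it must reproduce the published frequency rows,
arm means and SDs, and differences versus control exactly at printed
precision; CI endpoints are checked under a tolerance because the trial's
bootstrap CI flavor and the true weight strata are unpublished, so the
printed intervals carry method uncertainty beyond Monte-Carlo error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from ._format import fmt, matches_printed
from .endpoints import cohort_endpoints, summarize_arm
from .inference import BootstrapSpec, compare_arms
from .simulate import CONTROL_ARM, REFERENCE_ARM_ORDER, REFERENCE_DSN_COUNTS, generate_reference_cohort

#: Published Cycle-1 summary cells (evaluable population).
REFERENCE_PRINTED = {
    "n": {
        "eflapegrastim_45": 39,
        "eflapegrastim_135": 36,
        "eflapegrastim_270": 36,
        CONTROL_ARM: 36,
    },
    "mean_dsn": {
        "eflapegrastim_45": 1.03,
        "eflapegrastim_135": 0.44,
        "eflapegrastim_270": 0.03,
        CONTROL_ARM: 0.31,
    },
    "sd_dsn": {
        "eflapegrastim_45": 1.55,
        "eflapegrastim_135": 1.28,
        "eflapegrastim_270": 0.17,
        CONTROL_ARM: 0.82,
    },
    "diff": {
        "eflapegrastim_45": 0.72,
        "eflapegrastim_135": 0.14,
        "eflapegrastim_270": -0.28,
    },
    "ci": {
        "eflapegrastim_45": (0.19, 1.27),
        "eflapegrastim_135": (-0.28, 0.64),
        "eflapegrastim_270": (-0.56, -0.06),
    },
    # Noninferiority P-values as published; "<0.001" is stored as an upper bound.
    "p_noninferiority": {
        "eflapegrastim_45": 0.296,
        "eflapegrastim_135": 0.002,
        "eflapegrastim_270": ("<", 0.001),
    },
}

#: Tolerance (days) for comparing computed bootstrap CI endpoints with the
#: published ones: covers Monte-Carlo error, the unpublished CI flavor, and
#: the synthetic weight strata.
CI_TOLERANCE_DAYS = 0.15

#: Tolerance for the resampling noninferiority P-value (stochastic,
#: stratification-sensitive).
P_TOLERANCE = 0.05


@dataclass(frozen=True)
class ReportCell:
    name: str
    arm: str
    computed: object
    printed: object
    kind: str  # "exact" | "stochastic" | "info"
    passed: Optional[bool]


@dataclass(frozen=True)
class ReferenceReport:
    cells: tuple[ReportCell, ...]
    seed: int
    n_resamples: int

    @property
    def exact_ok(self) -> bool:
        return all(c.passed for c in self.cells if c.kind == "exact")

    @property
    def stochastic_ok(self) -> bool:
        return all(c.passed for c in self.cells if c.kind == "stochastic")

    def format(self) -> str:
        lines = [
            "Reproduction of the published Cycle-1 DSN analysis "
            f"(bootstrap: {self.n_resamples} resamples, seed {self.seed})",
            f"{'cell':<28}{'arm':<20}{'computed':>16}{'printed':>16}  status",
        ]
        for c in self.cells:
            status = {True: "pass", False: "FAIL", None: "info"}[c.passed]
            if c.kind == "stochastic":
                status += " (stochastic)"
            lines.append(
                f"{c.name:<28}{c.arm:<20}{str(c.computed):>16}{str(c.printed):>16}  {status}"
            )
        lines.append(
            f"exact cells: {'all pass' if self.exact_ok else 'FAILURES'}; "
            f"tolerance cells: {'all pass' if self.stochastic_ok else 'FAILURES'}"
        )
        return "\n".join(lines)


def reproduce_reference(
    n_resamples: int = 10_000, seed: int = 0, stratified: bool = True
) -> ReferenceReport:
    """Rebuild the reference cohort, derive endpoints, and compare every
    computed summary and bootstrap cell with the published values.

    Frequency rows, n, means, SDs, and differences must match exactly at
    printed precision; CI endpoints and the noninferiority P-value are
    tolerance-checked (see ``CI_TOLERANCE_DAYS``, ``P_TOLERANCE``). With
    ``stratified=False`` the bootstrap ignores the synthetic weight strata.
    """
    cohort = generate_reference_cohort()
    by_arm = cohort_endpoints(cohort, cycle=1)
    cells: list[ReportCell] = []

    for arm in REFERENCE_ARM_ORDER:
        summ = summarize_arm(by_arm[arm], arm=arm, cycle=1)
        cells.append(
            ReportCell("n", arm, summ.n, REFERENCE_PRINTED["n"][arm], "exact",
                       summ.n == REFERENCE_PRINTED["n"][arm])
        )
        cells.append(
            ReportCell("dsn_frequency", arm, summ.dsn_frequency,
                       REFERENCE_DSN_COUNTS[arm], "exact",
                       summ.dsn_frequency == REFERENCE_DSN_COUNTS[arm])
        )
        for cell, value in (("mean_dsn", summ.mean_dsn), ("sd_dsn", summ.sd_dsn)):
            printed = REFERENCE_PRINTED[cell][arm]
            cells.append(
                ReportCell(cell, arm, fmt(value), printed, "exact",
                           matches_printed(value, printed))
            )

    spec = BootstrapSpec(n_resamples=n_resamples, seed=seed)
    for arm in REFERENCE_ARM_ORDER:
        if arm == CONTROL_ARM:
            continue
        res = compare_arms(cohort, arm, CONTROL_ARM, cycle=1, spec=spec, stratified=stratified)
        printed_diff = REFERENCE_PRINTED["diff"][arm]
        cells.append(
            ReportCell("diff_vs_control", arm, fmt(res.point_diff), printed_diff,
                       "exact", matches_printed(res.point_diff, printed_diff))
        )
        lo, hi = REFERENCE_PRINTED["ci"][arm]
        cells.append(
            ReportCell("ci_low", arm, fmt(res.ci_low), lo, "stochastic",
                       abs(res.ci_low - lo) <= CI_TOLERANCE_DAYS)
        )
        cells.append(
            ReportCell("ci_high", arm, fmt(res.ci_high), hi, "stochastic",
                       abs(res.ci_high - hi) <= CI_TOLERANCE_DAYS)
        )
        printed_p = REFERENCE_PRINTED["p_noninferiority"][arm]
        if isinstance(printed_p, tuple):
            ok = res.p_noninferiority < printed_p[1]
            shown = f"<{printed_p[1]}"
        else:
            ok = abs(res.p_noninferiority - printed_p) <= P_TOLERANCE
            shown = printed_p
        cells.append(
            ReportCell("p_noninferiority", arm, f"{res.p_noninferiority:.3f}", shown,
                       "stochastic", ok)
        )
        # The published superiority P-values are not reproducible from the
        # stated two-times-proportion-above-zero definition for arms where
        # the difference favors the control; reported uncompared.
        cells.append(
            ReportCell("p_superiority", arm, f"{res.p_superiority:.3f}", "-", "info", None)
        )
        cells.append(
            ReportCell("noninferior(ci_high<1)", arm, res.noninferior,
                       hi < 1.0, "stochastic", res.noninferior == (hi < 1.0))
        )
    return ReferenceReport(tuple(cells), seed=seed, n_resamples=n_resamples)
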