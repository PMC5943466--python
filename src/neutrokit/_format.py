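"""Rounding and publication-style table rendering.

Rounding to printed precision uses round-half-up (0.139 prints as 0.14,
-0.278 as -0.28). ``matches_printed`` additionally accepts a printed value
reached by successive half-up rounding (one decimal at a time), since
published tables are sometimes rounded from already-rounded intermediates;
minus signs are plain ASCII in all machine-readable output.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Optional, Sequence

from .endpoints import ArmSummary
from .inference import BootstrapResult


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (half away from zero) at ``ndigits`` decimals."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def successive_round_half_up(x: float, ndigits: int = 2, start: int = 6) -> float:
    """Half-up rounding applied one decimal place at a time from ``start``."""
    d = Decimal(repr(x))
    for nd in range(start, ndigits - 1, -1):
        d = d.quantize(Decimal(1).scaleb(-nd), rounding=ROUND_HALF_UP)
    return float(d)


def matches_printed(value: float, printed: float, ndigits: int = 2) -> bool:
    """Whether ``value`` reproduces a printed number at its precision, under
    either single or successive half-up rounding."""
    return printed in (
        round_half_up(value, ndigits),
        successive_round_half_up(value, ndigits),
    )


def fmt(x: Optional[float], ndigits: int = 2) -> str:
    if x is None:
        return "NA"
    return f"{round_half_up(x, ndigits):.{ndigits}f}"


def render_comparison_table(
    cycle: int,
    summaries: Mapping[str, Optional[ArmSummary]],
    results: Sequence[BootstrapResult],
    ctrl_label: str,
) -> str:
    """Text table for one cycle: per-arm n and mean +/- SD of DSN, then each
    experimental-vs-control difference with its 95% CI, both resampling
    P-values (3 dp), and the noninferiority decision."""
    lines = [f"Cycle {cycle} - duration of severe neutropenia (days)"]
    header = f"{'Arm':<22}{'n':>5}  {'Mean +/- SD':>14}"
    lines.append(header)
    for arm, summ in summaries.items():
        if summ is None:
            lines.append(f"{arm:<22}  (no patients in cycle {cycle}; omitted)")
            continue
        tag = " (control)" if arm == ctrl_label else ""
        lines.append(
            f"{arm + tag:<22}{summ.n:>5}  {fmt(summ.mean_dsn) + ' +/- ' + fmt(summ.sd_dsn):>14}"
        )
    if results:
        lines.append("")
        lines.append(
            f"{'Comparison':<22}{'Diff':>7}  {'95% CI':>16}  {'P-noninf':>9}"
            f"  {'P-sup':>7}  {'Noninferior':>11}"
        )
        for r in results:
            ci = f"({fmt(r.ci_low)}, {fmt(r.ci_high)})"
            lines.append(
                f"{r.exp_label:<22}{fmt(r.point_diff):>7}  {ci:>16}  "
                f"{r.p_noninferiority:>9.3f}  {r.p_superiority:>7.3f}  "
                f"{'yes' if r.noninferior else 'no':>11}"
            )
    return "\n".join(lines)
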