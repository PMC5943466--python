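"""Weight-stratified bootstrap noninferiority comparison of mean DSN.

Each bootstrap replicate resamples patients with replacement within each
(arm x baseline-weight-stratum) cell at its observed size and records the
difference in arm mean DSN (experimental minus control). The two-sided CI
is the percentile interval of the resampled differences (empirical
quantiles with linear interpolation between order statistics, the numpy
default). Noninferiority at margin m is declared when the upper CI limit is
below m. Two resampling P-values accompany the interval:

* noninferiority P = min(1, 2 * proportion of resampled differences > m)
* superiority    P = min(1, 2 * proportion of resampled differences > 0)

Ties with the margin count as not exceeding (strict ``>``).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cohort import Cohort, select_arm
from .endpoints import derive_dsn


@dataclass(frozen=True)
class BootstrapSpec:
    n_resamples: int = 10_000
    ci_level: float = 0.95
    margin_days: float = 1.0
    strata_cutpoints: tuple[float, float] = (65.0, 75.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        if self.margin_days <= 0:
            raise ValueError("margin_days must be > 0")


@dataclass(frozen=True)
class BootstrapResult:
    """Point estimate, percentile CI, resampling P-values, and margin decision
    for one experimental-vs-control comparison."""

    exp_label: str
    ctrl_label: str
    cycle: int
    n_exp: int
    n_ctrl: int
    mean_exp: float
    mean_ctrl: float
    sd_exp: float
    sd_ctrl: float
    point_diff: float
    ci_low: float
    ci_high: float
    p_noninferiority: float
    p_superiority: float
    noninferior: bool
    margin_days: float
    n_resamples: int
    seed: int
    resample_diffs: np.ndarray = field(repr=False, compare=False, default=None)


def _stratum_indices(strata: Sequence[str]) -> list[np.ndarray]:
    labels: dict[str, list[int]] = {}
    for i, s in enumerate(strata):
        labels.setdefault(s, []).append(i)
    return [np.asarray(ix, dtype=int) for ix in labels.values()]


def _resampled_arm_means(
    values: np.ndarray, strata: Sequence[str], n_resamples: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean of each stratified resample of one arm, shape (n_resamples,)."""
    totals = np.zeros(n_resamples)
    for ix in _stratum_indices(strata):
        draws = rng.integers(0, len(ix), size=(n_resamples, len(ix)))
        totals += values[ix[draws]].sum(axis=1)
    return totals / len(values)


def stratified_resample_diffs(
    exp: Sequence[tuple[float, str]],
    ctrl: Sequence[tuple[float, str]],
    spec: BootstrapSpec = BootstrapSpec(),
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Resampled differences in mean DSN (experimental minus control).

    ``exp`` and ``ctrl`` are sequences of (dsn, stratum-label) pairs.
    Stratum sizes are held fixed at their observed values; each replicate
    resamples every stratum of each arm with replacement at its own size.
    Reproducible from ``spec.seed`` when no generator is supplied.
    """
    if not exp or not ctrl:
        raise ValueError("both arms must be non-empty")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    exp_v = np.asarray([v for v, _ in exp], dtype=float)
    ctrl_v = np.asarray([v for v, _ in ctrl], dtype=float)
    exp_means = _resampled_arm_means(exp_v, [s for _, s in exp], spec.n_resamples, rng)
    ctrl_means = _resampled_arm_means(ctrl_v, [s for _, s in ctrl], spec.n_resamples, rng)
    return exp_means - ctrl_means


def percentile_ci(diffs: Sequence[float], level: float = 0.95) -> tuple[float, float]:
    """Two-sided percentile interval: empirical quantiles at (1-level)/2 and
    1-(1-level)/2, with linear interpolation between order statistics."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size == 0:
        raise ValueError("diffs must be non-empty")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(diffs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def noninferiority_pvalue(diffs: Sequence[float], margin: float = 1.0) -> float:
    """min(1, 2 * proportion of resampled differences strictly above the margin)."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size == 0:
        raise ValueError("diffs must be non-empty")
    return min(1.0, 2.0 * float(np.mean(diffs > margin)))


def superiority_pvalue(diffs: Sequence[float]) -> float:
    """min(1, 2 * proportion of resampled differences strictly above zero)."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size == 0:
        raise ValueError("diffs must be non-empty")
    return min(1.0, 2.0 * float(np.mean(diffs > 0.0)))


def compare_dsn_samples(
    exp: Sequence[tuple[float, str]],
    ctrl: Sequence[tuple[float, str]],
    spec: BootstrapSpec = BootstrapSpec(),
    exp_label: str = "experimental",
    ctrl_label: str = "control",
    cycle: int = 1,
) -> BootstrapResult:
    """Full comparison from per-patient (dsn, stratum) samples."""
    diffs = stratified_resample_diffs(exp, ctrl, spec)
    ci_low, ci_high = percentile_ci(diffs, spec.ci_level)
    exp_v = [v for v, _ in exp]
    ctrl_v = [v for v, _ in ctrl]
    return BootstrapResult(
        exp_label=exp_label,
        ctrl_label=ctrl_label,
        cycle=cycle,
        n_exp=len(exp_v),
        n_ctrl=len(ctrl_v),
        mean_exp=statistics.fmean(exp_v),
        mean_ctrl=statistics.fmean(ctrl_v),
        sd_exp=statistics.stdev(exp_v) if len(exp_v) > 1 else 0.0,
        sd_ctrl=statistics.stdev(ctrl_v) if len(ctrl_v) > 1 else 0.0,
        point_diff=statistics.fmean(exp_v) - statistics.fmean(ctrl_v),
        ci_low=ci_low,
        ci_high=ci_high,
        p_noninferiority=noninferiority_pvalue(diffs, spec.margin_days),
        p_superiority=superiority_pvalue(diffs),
        noninferior=ci_high < spec.margin_days,
        margin_days=spec.margin_days,
        n_resamples=spec.n_resamples,
        seed=spec.seed,
        resample_diffs=diffs,
    )


def dsn_samples(cohort: Cohort, arm: str, cycle: int = 1, stratified: bool = True) -> list[tuple[float, str]]:
    """Per-patient (DSN, stratum) pairs for one arm-cycle. With
    ``stratified=False`` all patients share a single pooled stratum."""
    out = []
    for p in select_arm(cohort, arm):
        if not p.has_cycle(cycle):
            continue
        dsn = derive_dsn(p.series_for(cycle)).days
        out.append((float(dsn), p.stratum if stratified else "all"))
    if not out:
        raise ValueError(f"arm {arm!r} has no patients with cycle {cycle}")
    return out


def compare_arms(
    cohort: Cohort,
    exp_label: str,
    ctrl_label: str,
    cycle: int = 1,
    spec: BootstrapSpec = BootstrapSpec(),
    stratified: bool = True,
) -> BootstrapResult:
    """Derive Cycle DSN per patient and run the stratified bootstrap
    comparison of the experimental arm against the control arm."""
    exp = dsn_samples(cohort, exp_label, cycle, stratified)
    ctrl = dsn_samples(cohort, ctrl_label, cycle, stratified)
    return compare_dsn_samples(exp, ctrl, spec, exp_label, ctrl_label, cycle)
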