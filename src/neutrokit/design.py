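"""Power and sample size for the noninferiority design.

The planning computation: with pooled experimental arms of size nE and a
control arm of size nC, DSN standard deviation sigma (treated as common and
known), noninferiority margin m, and true difference 0, success means the
one-sided (1 - alpha) upper confidence limit of the mean difference falls
below m. Under a normal approximation the power is

    Phi( m / (sigma * sqrt(1/nE + 1/nC)) - z_{1-alpha} ).

``power_simulated`` checks this by Monte Carlo with the estimated-SD
version of the criterion (pooled sample SD in place of sigma), which is how
an analysis would actually be run; the analytic/simulated discrepancy is
quantified by the returned Monte-Carlo standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, NamedTuple, Optional

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class DesignSpec:
    """Planning assumptions: DSN SD in days, margin in days, one-sided
    alpha, pooled-experimental and control sizes, and simulation settings."""

    sd_dsn: float = 2.1
    margin_days: float = 1.0
    one_sided_alpha: float = 0.05
    n_experimental: int = 108
    n_control: int = 36
    n_sim: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_dsn <= 0:
            raise ValueError("sd_dsn must be > 0")
        if self.margin_days <= 0:
            raise ValueError("margin_days must be > 0")
        if not 0.0 < self.one_sided_alpha < 0.5:
            raise ValueError("one_sided_alpha must be in (0, 0.5)")
        if self.n_experimental < 2 or self.n_control < 2:
            raise ValueError("arm sizes must be >= 2")


def power_analytic(spec: DesignSpec) -> float:
    """Normal-approximation (known-variance) power at true difference 0."""
    se = spec.sd_dsn * math.sqrt(1.0 / spec.n_experimental + 1.0 / spec.n_control)
    z_alpha = stats.norm.ppf(1.0 - spec.one_sided_alpha)
    return float(stats.norm.cdf(spec.margin_days / se - z_alpha))


class SimulatedPower(NamedTuple):
    power: float
    mc_se: float
    n_sim: int


def power_simulated(
    spec: DesignSpec,
    dsn_sampler: Optional[Callable[[np.random.Generator, tuple[int, int]], np.ndarray]] = None,
) -> SimulatedPower:
    """Monte-Carlo power: fraction of simulated trials whose one-sided
    (1 - alpha) upper confidence limit of the mean difference is below the
    margin, using the pooled sample SD.

    By default per-patient DSN is normal with mean 0 and SD ``sd_dsn`` (the
    planning model); pass ``dsn_sampler(rng, shape)`` — e.g.
    ``zero_inflated_dsn_sampler(...)`` — to quantify how much the planning
    normality assumption matters for an integer-valued, zero-inflated DSN.
    """
    if spec.n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(spec.seed)
    if dsn_sampler is None:
        def dsn_sampler(r, shape):  # noqa: ANN001 - planning model default
            return r.normal(0.0, spec.sd_dsn, size=shape)
    ne, nc = spec.n_experimental, spec.n_control
    exp = dsn_sampler(rng, (spec.n_sim, ne))
    ctrl = dsn_sampler(rng, (spec.n_sim, nc))
    diff = exp.mean(axis=1) - ctrl.mean(axis=1)
    pooled_var = ((ne - 1) * exp.var(axis=1, ddof=1) + (nc - 1) * ctrl.var(axis=1, ddof=1)) / (
        ne + nc - 2
    )
    se = np.sqrt(pooled_var * (1.0 / ne + 1.0 / nc))
    z_alpha = stats.norm.ppf(1.0 - spec.one_sided_alpha)
    upper = diff + z_alpha * se
    power = float(np.mean(upper < spec.margin_days))
    mc_se = math.sqrt(max(power * (1.0 - power), 1e-12) / spec.n_sim)
    return SimulatedPower(power, mc_se, spec.n_sim)


def zero_inflated_dsn_sampler(
    p_severe: float = 0.25, mean_severe_days: float = 3.0
) -> Callable[[np.random.Generator, tuple[int, int]], np.ndarray]:
    """Integer DSN generator: zero with probability 1 - p_severe, otherwise
    1 + Poisson(mean_severe_days - 1) days. Centered to mean 0 so the true
    treatment difference stays null."""
    if not 0.0 < p_severe < 1.0:
        raise ValueError("p_severe must be in (0, 1)")
    if mean_severe_days < 1.0:
        raise ValueError("mean_severe_days must be >= 1")
    mean = p_severe * mean_severe_days

    def sampler(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
        severe = rng.random(shape) < p_severe
        days = 1 + rng.poisson(mean_severe_days - 1.0, size=shape)
        return np.where(severe, days, 0).astype(float) - mean

    return sampler


class RequiredN(NamedTuple):
    n_experimental: int
    n_control: int
    power: float


def required_n(
    target_power: float = 0.80,
    allocation_ratio: float = 3.0,
    sd_dsn: float = 2.1,
    margin_days: float = 1.0,
    one_sided_alpha: float = 0.05,
    max_control: int = 1_000_000,
) -> RequiredN:
    """Smallest integer arm sizes on the allocation ray nE = ceil(ratio * nC)
    whose analytic power reaches the target.

    Raises if the target is not reachable within ``max_control`` control
    patients (it always is for a positive margin, but the guard reports
    mis-specification instead of looping).
    """
    if not 0.0 < target_power < 1.0:
        raise ValueError("target_power must be in (0, 1)")
    if allocation_ratio <= 0:
        raise ValueError("allocation_ratio must be > 0")
    for nc in range(2, max_control + 1):
        ne = max(2, math.ceil(allocation_ratio * nc))
        spec = DesignSpec(
            sd_dsn=sd_dsn,
            margin_days=margin_days,
            one_sided_alpha=one_sided_alpha,
            n_experimental=ne,
            n_control=nc,
        )
        p = power_analytic(spec)
        if p >= target_power:
            return RequiredN(ne, nc, p)
    raise ValueError(f"target power {target_power} unreachable within nC <= {max_control}")
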