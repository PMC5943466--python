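# Methods

## Endpoint definitions and conventions

All endpoints are derived from observed (study day, ANC) pairs; ANC is in
×10⁹/L and Day 1 is the chemotherapy day, so every "time to" quantity uses
the convention `event day − chemotherapy day + 1`.

* **DSN** counts `recovery day − onset day`, where onset is the first
  observed ANC < 0.5 and recovery the first subsequent observation ≥ 2.0.
  One grade-4 day followed by next-day recovery is therefore **1 day**;
  an inclusive-day count would shift every positive DSN up by one and is
  inconsistent with the frequency categories the reference table uses.
* DSN recovery is anchored at the **onset** day; time-to-ANC-recovery is
  anchored **after the nadir** day and restricted to patients whose ANC
  dipped below 2.0. The two definitions are deliberately independent —
  they answer different questions and are specified differently.
* Boundary conventions are strict/inclusive exactly as the thresholds are
  written: grade 4 is `< 0.5`, recovery `≥ 2.0`, daily-monitoring trigger
  `< 1.5`, fever `> 38.2 °C`.
* A series with grade-4 onset but no observed in-cycle recovery gets a
  conservative DSN of `last observed day − onset + 1` and a censoring flag
  that summaries surface (`n_dsn_censored`); the reference analysis has no
  censored series, so the flag never changes the golden values.
* Nadir ties break to the earliest day. Missing temperature data yields
  febrile-neutropenia "false" unless an adverse-event flag is supplied.
* With one patient in an arm the sample SD (n−1 denominator) is undefined;
  it is reported as 0.0 with `sd_defined = False` rather than NaN.

## The trajectory generator

The generator emulates the qualitative per-cycle ANC kinetics seen under
TC chemotherapy with G-CSF support — an early stimulation peak near Day 3,
a suppression nadir near Days 6–9, and a rebound peak near Days 10–13 —
as a patient baseline modulated by three unit-height Gaussian day-kernels:

    ANC(d) = B · max(0, 1 − s·(1−p)·K(d; 7, 1.8)
                        + 0.8·p·K(d; 3, 1.2) + 0.5·K(d; 11, 2.5))

with suppression depth `s = 1.75` and dose potency `p ∈ [0, 1]` linearly
trading suppression for stimulation. This is the simplest form matching
the described biphasic profile; a transit-compartment ODE of granulopoiesis
is deliberately not attempted. Because ∂ANC/∂p ≥ 0 pointwise, nadir depth
is non-decreasing and DSN non-increasing in potency by construction — the
dose-monotonicity tests verify the implementation, not the algebra.

Defaults and their reasoning:

* Baseline `B ~ lognormal(log 4.5, 0.25)`: pre-treatment ANC of a few
  ×10⁹/L, right-skewed and positive.
* Observation noise is multiplicative lognormal with CV 0.35 (mean 1):
  ANC is positive and right-skewed; additive noise would need ad-hoc
  truncation.
* Kernel centers 3/7/11 and widths 1.2/1.8/2.5 days place the nadir of the
  noise-free curve on Days 6–7 and both peaks above baseline for the
  default arm potencies (0.45/0.68/0.88 for the three doses, 0.63 for the
  control). With baseline 4.5 these give noise-free nadirs of about
  0.8/2.6/4.1/2.2 ×10⁹/L — the ordering and rough magnitudes of the arms'
  observed median nadirs. Potencies were set from this ordering once; no
  attempt is made to match incidence rates exactly.
* Body weight `~ lognormal(log 70, 0.15)` kg, giving roughly a 30/38/32%
  split across the <65 / 65–75 / >75 kg strata.
* Randomness uses one root seed with per-patient counter-keyed substreams
  (`SeedSequence(seed, spawn_key=(patient,))`), so cohort content does not
  depend on arm iteration order and cohorts serialize byte-identically.

**The monitoring schedule** observes Days 1–3 always, then a fixed
twice-weekly grid {7, 10, 14, 17, 21}; from the first observed ANC < 1.5
sampling is daily until an observed value ≥ 1.5, after which the grid
resumes. The protocol's "twice weekly" is calendar-ambiguous; a fixed grid
keeps every derived quantity deterministic. Thinning preserves DSN exactly
whenever the decline spends enough consecutive days in the trigger band
[0.5, 1.5) for a scheduled visit to catch it before the first grade-4 day
(grid gaps are ≤ 4 days, so a 4-day dwell suffices) and the recovery
crosses 1.5 and 2.0 on the same day; fast crashes between visits can push
the observed onset later than the latent one — which is a property of the
trial's design, not an artifact.

**What the generator does not emulate:** pharmacokinetics or CD34⁺
kinetics, cycle-to-cycle carry-over (each cycle redraws the same kernel
shape), per-patient chemosensitivity heterogeneity beyond the baseline
draw, missed visits, or dropout. Passing simulation tests therefore shows
the pipeline handles realistic-shaped, schedule-thinned data — not that
the generator reproduces any trial's incidence rates.

## The reference cohort

The published Cycle-1 DSN frequency rows (45 µg/kg: 25×0, 1×1, 5×2, 5×3,
1×4, 2×5; 135: 29×0, 3×1, 3×2, 1×7; 270: 35×0, 1×1; control: 31×0, 1×1,
2×2, 2×3) are realized patient-by-patient as minimal schedule-consistent
series: 5.0 on Days 1–3, 0.4 on days 7…7+k−1, recovery 2.5 on day 7+k,
then 2.5 on the remaining grid days (DSN-0 patients stay at 5.0 on the
no-trigger schedule). Any series deriving to the required DSN would do;
this one also satisfies the monitoring-schedule rules, so the cohort
round-trips through the full pipeline. Patient weights are unpublished, so
they are drawn from a fixed seed; the weight strata are synthetic by
necessity, and stratified results on this cohort differ from unstratified
ones only through those synthetic strata.

## Bootstrap inference

* Resampling unit: patient within (arm × stratum), stratum sizes fixed at
  observed values — the standard meaning of a stratified bootstrap.
* CI: percentile interval, the minimal reading of "CIs calculated from
  10,000 bootstrap samples"; quantiles use linear interpolation between
  order statistics (numpy default) so golden tests are stable. BCa or
  normal-approximation intervals would differ by a few hundredths of a day
  at these sizes; computed CI endpoints are compared with the published
  ones under a ±0.15-day tolerance covering Monte-Carlo error, the
  unstated CI flavor, and the synthetic strata.
* P-values are twice the proportion of resampled differences strictly
  above the margin (noninferiority) or above zero (superiority), capped at
  1; ties with the margin count as not exceeding. Note the superiority
  statistic as defined is directional — it is small only when the
  experimental arm's mean DSN is below the control's.
* Degenerate all-equal arms yield CI (0, 0) and both P-values 0 rather
  than erroring.

## Rounding of printed comparisons

Reported tables round half-up (0.139 → 0.14, −0.278 → −0.28). One
reference cell — the middle arm's SD, exact value 1.27490 — matches its
printed value 1.28 only under successive half-up rounding
(1.2749 → 1.275 → 1.28), a common artifact of tables rounded from
already-rounded intermediates; golden comparisons therefore accept a cell
when either single or successive half-up rounding reproduces it. Every
other cell matches under single rounding. Machine-readable output uses
ASCII minus signs and full-precision floats.

## Design power

The planning computation treats per-patient DSN as normal with a common
known SD of 2.1 days and uses a z-criterion; with pooled experimental 108
versus control 36 (3:1 allocation) the analytic power at a 1-day margin is
0.7966, i.e. the quoted "80%" after rounding. The simulated version uses
the estimated pooled SD, the form an actual analysis would use; at these
sample sizes the two agree within Monte-Carlo error (the returned MC
standard error quantifies it). An optional zero-inflated integer DSN
sampler (`zero_inflated_dsn_sampler`) lets users gauge how little the
normality assumption matters at these sizes. `required_n` searches along
the allocation ray `n_E = ⌈ratio·n_C⌉` for the smallest sizes reaching the
target power; exact 0.80 at 3:1 needs 148 patients, slightly more than the
planned 144 because the planned design's power is 0.7966. Minimality is
guaranteed along the ray only — off-ray reallocation can reach the target
with fewer experimental patients.

## Problem sizes

Defaults chosen once for all analyses and tests: 10,000 bootstrap
resamples and 10,000 simulated trials (the design's own Monte-Carlo
precision, ~0.4 points SE on a power near 80%); dose-monotonicity checks
use 200 patients per potency point, enough for stable arm means under the
default noise.

## Known limitations

* The simulator is phenomenological; its parameters are not estimable
  pharmacodynamic quantities.
* Hazard-ratio / survival-curve analysis of time-to-recovery and nadir
  ratio statistics are out of scope; medians and eligible-n are reported.
* The reference cohort's bootstrap replicates the published analysis only
  up to the unpublished weight strata and CI flavor; exact replication of
  the printed CIs is not possible from published data.
* No multiplicity adjustment is applied across the dose comparisons (none
  is described for the reference analysis).
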