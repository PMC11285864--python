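# Methods

## Circuit model

The pulser on-phase is an ideal series RLC loop: a capacitor bank charged to
U₀ discharges through the pulse coil (inductance L, equivalent series
resistance R) from the moment the switch closes. With I(0) = 0 and
I'(0) = U₀/L the closed-form solution is sampled directly; the damping
regime is selected by comparing α = R/2L with ω₀ = 1/√(LC), and a relative
gap |α − ω₀|/ω₀ below 1e−9 is treated as critical damping to avoid
catastrophic cancellation between two nearly equal exponentials. The
analytic samples agree with an independent adaptive ODE integration to
better than 1e−6 relative error in all three regimes (property-tested over
randomized circuits).

Assumptions and simplifications:

- The switch's milliohm on-resistance is folded into R (default 80 Ω, the
  coil ESR); no semiconductor-level behaviour (diode forward drop, MOSFET
  transients, snubber details) is modelled.
- Pulses start from a fully charged capacitor; the charging path through its
  1 kΩ resistor is outside the simulated window.
- The field is modelled only at the fixed bird position through a single
  current-to-field factor k (default 24 mT/A); there is no spatial B(s)
  profile. Consequently the modelled treatment peak (k·I_peak ≈ 57.6 mT for
  the first-generation circuit) sits above the bench-measured 52 mT; metrics
  carry a `provenance` tag (`modelled` vs `measured`) so the adequacy
  verifier can consume either.
- First-generation shut-off is approximated as a linear current ramp with
  configurable fall time (defaults: 0.69 ms treatment, 0.1 ms sham), since
  the chopping circuit is not characterised beyond its fall times.
  Second-generation shut-off is the flyback exponential with τ = L/R,
  truncated at 0.01% of the on-phase peak. The quoted shut-off "rate" is
  the mean descent slope for a ramp and the initial slope I_d/τ for a
  flyback tail.
- Default grid step 1 µs: ≥100 samples across even the 0.1 ms sham fall;
  `solve_discharge` refuses grids coarser than t_d/50.

The ideal model slightly overestimates the early current (e.g. ~0.26 A at
0.2 ms where 0.24 A was measured), consistent with unmodelled series losses;
no attempt is made to fit an extra ESR term.

## Sham design and switching thresholds

The sham duration for a target peak ratio ρ is the root of
I(t) = ρ·I_peak on the rising flank, bracketed in (0, t_peak] — well-defined
because the on-phase current increases strictly up to its peak. Onset-rate
comparisons fit a least-squares slope over the first 5% of the *shorter*
on-phase for both pulses; a truncated sham then has an ideal mismatch of
exactly zero and the 1% tolerance absorbs only sampling error.

The magnetite switching bracket defaults to 12 mT (no effect) / 25 mT (full
polarity switch). These derive from a single characterised candidate
receptor preparation; they are configuration, not physical constants, and
the boundary convention is inclusive on the stronger-effect side (≥ 25 mT →
`full_switch`, < 12 mT → `sub_threshold`). Whether a 10% peak ratio is
"safe" for all particle coercivity spectra is likewise treated as a
configurable criterion rather than a physical claim.

## Statistical battery

- **Trait I** (first-night departure) uses a 2×2 Pearson χ² with the
  truncated Yates correction, χ² = Σ max(|O−E|−½, 0)²/E, df = 1; a
  perfectly balanced table gives exactly 0.
- **Traits II–III** use the two-sided Wilcoxon rank-sum test with statistic
  W = (rank sum of group 1) − n₁(n₁+1)/2 on midranks. The `auto` policy is
  exact when n₁+n₂ ≤ 30 *or* ties are present, otherwise a tie-corrected
  normal approximation with 0.5 continuity correction. The exact p
  enumerates the permutation distribution of the rank sum on the observed
  pooled values by a dynamic programme over (items chosen, doubled-midrank
  sum); two-sided p is twice the smaller tail, capped at 1. This matches
  brute-force enumeration for every small input (property-tested with ties)
  and R's `wilcox.test(exact = TRUE)` on tie-free data. The ≤ 30 exactness
  cutoff is a tractability choice; the tie branch stays exact at the
  cohort sizes used here (~0.04 s per test at N = 120).
- **Traits IV–V** use the Mardia–Watson–Wheeler uniform-scores test:
  pooled circular ranks mapped to β_j = 2πj/N,
  W = 2[(C₁²+S₁²)/n₁ + (C₂²+S₂²)/n₂], referred to χ² with 2 df. Tied
  angles have no unique ranks, so tied observations are ordered uniformly
  at random (implemented as sub-granularity jitter), the test repeated
  (default 10 000×) and the median W reported; tie-free data is evaluated
  once. The χ²₂ tail is compared against the exhaustive permutation
  distribution at n₁ = n₂ = 4 (70 assignments); the measured approximation
  error at that size reaches ≈0.21 in absolute p and shrinks rapidly with
  n — the battery warns below 10 per group and refuses below 5.
- **Consistency sign convention:** deviation = wrapped(coast bearing −
  departure bearing) in (−180°, 180°], negative = anticlockwise; bearings
  are degrees clockwise from geographic north.
- Missing traits are dropped per test (pairwise deletion). Raw p-values are
  reported; no multiple-testing correction is applied, and text output
  rounds to 3 decimals while JSON keeps full precision.
- The departure window (default 10 nights) restricts timing/direction
  traits to birds that resumed migration promptly; stopover duration and
  first-night departure keep all birds with the relevant observation.

All randomness in a battery run descends from one seed via spawned
per-cell streams, so grids are exactly reproducible.

## Synthetic cohort generator

The generator's default layout is 31 birds per (year × age × group) cell —
two years, two age classes, two groups, 248 birds, ~62 per age × group
margin — matching the scale of a two-season release study. Defaults per
trait:

- first-night departure: Bernoulli, p = 0.57 (juveniles) / 0.43 (adults);
- extra stopover nights for non-first-night birds: geometric with mean 1.5
  (juveniles) / 4.0 (adults) nights — zero-median, long-tailed;
- night fraction at departure: Beta(2, 5.5) (median ≈ 0.24, early-night
  departures), rounded to 1%;
- departure bearing: von Mises(120°, κ = 1.0) (resultant length ≈ 0.45),
  rounded to 1°;
- consistency deviation: von Mises(−13°, κ = 3.5) added to the departure
  bearing to produce the coastline bearing;
- 12% of birds are never detected departing (censored stopover, all
  downstream traits missing); each observed trait is additionally missing
  with probability 5%, reproducing declining per-trait sample sizes.

Ties arise by rounding, as in real bearing/timing data, not by discrete
sampling. Traits are generated independently within a bird; real
timing–direction dependence is unknown and not modelled. Passing
calibration on these cohorts therefore shows that the tests hold their
nominal size under realistic marginals, ties and missingness — it does not
validate the battery against correlated traits, weather-driven departure
waves, or detection biases of real telemetry arrays.

## Monte-Carlo calibration and power

`rejection_rates` generates cohorts under one configuration and applies the
same five test routes the battery uses to the pooled sham-vs-treatment
comparison; `monte_carlo_power` composes a null and an effect configuration
into one table with Wilson 95% intervals. Inside the loop the circular
tests use 200 tie-breaking repetitions: the median W is stable well below
the 10 000-repetition default used for a one-off analysis, and this keeps a
2000-repetition calibration at 60 birds per group to a few minutes on one
core. Under the null defaults every trait test's empirical size at
α = 0.05 falls within [0.03, 0.07] (the χ² is mildly conservative by
construction of the continuity correction).

## Numerical conventions

- External units: seconds, amperes, millitesla, degrees; waveform CSV uses
  9 significant digits and round-trips losslessly at that precision.
- Exact rank-sum enumeration works on doubled midranks (integers), shifted
  to a zero-based score range.
- Wilson intervals pin the k = 0 and k = n endpoints exactly to 0 and 1 to
  keep the bounds bracketing under floating-point subtraction.
- Degenerate inputs: zero-margin contingency tables, empty samples, and
  groups below the circular test's minimum raise typed errors; inside the
  battery such cells are marked not-estimable instead of failing the run.

## Known limitations

- No spatial field profile, coil heating, or particle-level micromagnetics;
  remagnetization is a threshold classification only.
- The device audit treats earlier pulsers empirically (published peaks and
  rise specs); it cannot reconstruct, e.g., a double-wrapped solenoid's
  leakage mechanism.
- The generator does not model weather gating of departures, detection
  probability, or between-trait correlation; power estimates are
  correspondingly idealised.
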