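# Methods

## The succession model

The state of succession is summarised by one number, the Mean Individual
Biomass (MIB) of the carabid community, in mg per individual. MIB rises
along succession because large-bodied, poorly dispersing forest carabids
gradually dominate the catch; it is therefore a monotone index of
successional stage rather than a population size.

The model has four parameters:

| parameter | symbol | units | meaning |
|---|---|---|---|
| initial degradation level | N₀ | mg MIB | community state right after degradation; 0 < N₀ < K |
| delay | t_delay | years | period during which succession has not yet started |
| increase rate | r | 1/years | steepness of the logistic rise; ≥ 0 |
| recovery level | K | mg MIB | asymptotic state, possibly the pre-disturbance level |

For stand age t_start and shifted time t = t_start − t_delay, the state is
N = N₀ while t < 0, and for t ≥ 0 follows the analytic solution of the
logistic equation dN/dt = r N (K − N)/K with N(0) = N₀, i.e.
N = c e^{rt}/(1 + c e^{rt}/K) with c = N₀/(1 − N₀/K).

**Numerical form.** The solution is evaluated as
N = K / (1 + ((K − N₀)/N₀) e^{−rt}), which is algebraically identical but
uses a decaying exponential, so it cannot overflow for any r·t (the
equivalence is verified by a property test to 10⁻¹² relative, and against
an independent RK4 integration of the ODE to 10⁻⁶). Consequences of
double precision: for r·t beyond ≈ 37 the computed N saturates at exactly
K, so the mathematical strict bound N < K holds only up to float
resolution. At t_start = t_delay both branches equal N₀; the
implementation returns N₀ bit-exactly there. N₀ ≤ 0 and N₀ ≥ K are
rejected rather than treated as limits, keeping c well defined. The delay
is a continuous quantity (years), not an integer.

**Phases.** Ages before t_delay form the delay phase; once
N ≥ θ·K (θ = 0.95 by default, configurable) the curve is in the
stagnation phase, otherwise the increase phase. Only the delay boundary
is intrinsic to the model; the increase/stagnation boundary is a plotting
and reporting convention of this package.

**Shipped presets** (`data/presets.yaml`) give the characteristic values
for five degraded-area types in Poland — planted stands on forest soil
(40, 0, 0.18, 290), naturally regenerated (40, 0, 0.18, 250) and planted
(40, 0, 0.5, 250) stands on post-agricultural soil, ash heap
(40, 10, 0.28, 210) and brown-coal mining heap (40, 10, 0.6, 210) —
together with an `unverified` list for parameters that the underlying
chronosequences could not confirm (e.g. the forest-soil sites include no
young stands, so N₀, delay and rate there are nominal; the ash-heap sites
end at 14 years, so its rate and recovery level are nominal). Plots dash
the curve segments governed by unverified parameters.

## MIB computation and the age trend

`compute_mib` pools all records of one site and sampling year (traps are
assumed pooled within a site-year) and divides total biomass by total
individuals. An empty sample has no MIB — the index is undefined, not
zero — and is carried as a flagged missing point. Samples with fewer
than 25 individuals are kept but flagged unreliable, because a ratio
estimator over few individuals is noisy; exclusion is an option in both
the Spearman test and the fit, not the default, since such points still
carry information.

`build_series` attributes each sampling year's point to the site's base
stand age plus the year's offset from the site's first sampling year, so
three consecutive sampling years yield three points of consecutive age.
This is the simplest bookkeeping consistent with a repeated
chronosequence design.

`spearman_mib_age` ranks with average ranks under ties and computes the
two-sided p exactly — full enumeration of all n! rank permutations — for
n ≤ 8, switching to the usual t-approximation above that. The cutoff is
where enumeration (40,320 permutations) stops being instant.

## Parameter estimation

The model is non-smooth in t_delay, so the fit profiles the delay: for
each candidate on a grid (default 0–30 years, step 0.5) the remaining
free parameters are estimated by bounded nonlinear least squares
(`scipy.optimize.least_squares`), the candidate with minimal residual sum
of squares wins, and the winning delay is polished by a bounded scalar
minimisation within one grid step, so the returned delay is continuous.
K is parameterised as N₀ + ΔK with ΔK > 0, which enforces N₀ < K inside
the optimizer. Starting values: N₀ = min observed MIB, K = max observed
MIB, r = 0.2 (mid-range of the shipped presets); r is bounded to
[10⁻⁶, 5] y⁻¹ by default. The loss is unweighted squared error in mg;
optional weighting by catch size (√n, proportional precision) reflects
that MIB becomes inaccurate for small samples. Any of the four parameters
can be fixed, mirroring practice when data cannot identify them (e.g.
N₀ = 40 mg).

Identifiability flags are set, not errors: a series with no points
younger than t_delay + 2 years flags N₀ and t_delay; a series whose
fitted values never reach 0.8 K flags K. Degenerate inputs — fewer
points than free parameters + 1, or a constant MIB series — raise errors.
No confidence intervals are produced; the result is parameters, RSS and
flags.

## The community simulator

The simulator is the package's test harness and a study-design tool. It
realizes the mechanism behind MIB minimally: two guilds of species, small
early-successional (guild mean 40 mg) and large late-successional (guild
mean 450 mg, both configurable), with species masses spaced evenly within
±20% of the guild mean. At stand age t a catch draws each individual from
the large guild with probability w(t) solving
w·m_L + (1 − w)·m_S = N(t), so the expected MIB of a catch equals the
model trajectory exactly (symmetric within-guild masses make the uniform
species choice unbiased). The default guild means bracket all preset
recovery levels (210–290 mg), so w stays interior. Catch totals per
site-year are Poisson with configurable mean (default 200 individuals, a
plausible whole-season pitfall total for one site); negative-binomial
overdispersion is available because real pitfall catches are typically
clumped, but the default is 0 to keep the noise model minimal. Each
site-year has its own random stream derived from the master seed and the
site/year indices, so enlarging a design never perturbs existing draws.

Shipped design presets reproduce the five chronosequence layouts of the
original field study (14 forest-soil sites aged 21–119 y; 13 natural and
69 planted post-agricultural sites aged 0–64 and 2–119 y; 3 ash-heap
sites aged 8–14 y; 4 mining-heap sites aged 3–23 y), each sampled in
three consecutive years, with base ages spread evenly over the stated
range (the true site ages are not published).

**What the simulator does not emulate:** trap-level spatial structure and
unequal trap numbers per site, species turnover within guilds, year
effects and phenology, dispersal limitation, and the very large
between-site variability seen in real post-agricultural data. Passing the
round-trip tests therefore shows the estimator is consistent under the
model's own noise mechanism, not that field data of this size determine
the parameters equally well.

## Problem sizes and numerical checks in the test suite

- Exact recovery: noiseless series at ages 0, 2, …, 60 (31 points) must
  return all four parameters to 10⁻⁴ relative with RSS < 10⁻⁶.
- Stochastic round trip: 50 replicate mining-heap designs (4 sites × 3
  years, catch mean 200), fit with N₀ fixed at 40; median absolute error
  must stay within 2 years for the delay and 15% for the rate.
- ODE oracle: classic fixed-step RK4 (h = 0.02 y) over 100 years for all
  five presets, 10⁻⁶ relative agreement.
- Spearman: implementation's exact p is compared against a brute-force
  permutation oracle for n = 4…7.

## Known limitations

- The fit assumes homoscedastic additive error in MIB; real MIB noise is
  closer to multiplicative and age-dependent.
- With few sites and no young stands the delay and N₀ trade off; fixing
  N₀ is then advisable and the flags say so, but no formal uncertainty is
  attached.
- The delay grid upper bound (30 y) must exceed any plausible delay;
  series whose rise lies entirely beyond the grid will fit poorly rather
  than warn specifically.
- MIB is a community-level ratio; the logistic form is a phenomenological
  description of its trajectory, not a mechanistic population model.
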