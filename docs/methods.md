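# Methods

## Scope and moving parts

`farolcare` couples three models of hospital-seeking behaviour:

1. a **generalized El Farol bar game** capturing the congestion
   externality among `N` patients sharing one hospital of capacity `c`;
2. an **exponential belief update** (a one-state reinforcement-learning /
   exponentially weighted moving-average rule) tracking a representative
   patient's daily probability `p_t` that a visit would be uncongested;
3. a **composite payoff index** converting service-quality indicators into
   a gain `H` and loss `L`, and the belief into an expected payoff
   `E = H·p − L·(1 − p)`.

A seeded synthetic generator supplies the daily visit series the belief
stage consumes, since the hospital records that motivated the analysis are
not public.

## The bar game

Payoffs: action 0 always pays 0; action `j ≥ 1` pays `w_ij·H` when the sum
of all actions is **at or below** `c` and `−w_ij·L` above it. The weak
inequality is used consistently (an expected-payoff formula written with a
strict inequality would be inconsistent with the payoff table; the weak
form is adopted everywhere).

Beliefs about opponents are empirical action frequencies. In the binary
game the relevant statistic is the Poisson-binomial tail
`P(Σ X_k ≥ c)` for independent, non-identical Bernoulli attendances; it is
computed **exactly** by iterated convolution (dynamic programming), and the
test suite checks it against full `2^m` enumeration. A player attends iff
the tail is at most `u = H/(H+L)`; the tie (`tail = u`) goes to attending.
In the `k`-action game each player convolves the opponents' action pmfs
into an aggregate belief `Y_i` and plays the argmax of
`w_ij·(H+L)·(u − P(Y_i ≥ c−j+1))`, ties broken toward the lowest action
index (deterministic and documented).

Fictitious play uses **simultaneous updating**: all players best-respond to
the time-`t` frequencies and all counters advance together. Empirical
frequencies are undefined at `t = 0`, so the initial belief vector is a
supplied prior and counts accumulate from round 1. The discrete balance
equations are iterated as-is; their ODE approximations are not integrated
separately (the discrete system is the exact object). A helper flags
convergence when no belief moved more than 1e-6 over 100 steps — a
threshold suited to the desk-scale horizons (10^3–10^4) used here.

Two dynamical caveats, both verified by simulation and encoded in tests:
binary play from asymmetric starts sorts itself into a pure profile with
exactly `c` attendees, but **symmetric or random starts of the k-action
game can cycle**, with time-average frequencies that are not a pure
profile; the capacity-filling limit (`Σ j(i) = c`) is demonstrated from
differentiated priors. Pure-equilibrium structure itself does not depend
on the dynamics: exhaustive deviation scans confirm that the equilibria
are exactly the capacity-filling profiles.

## The belief update

`p_t = (1−ω)·p_{t−1} + ω·signal_t` with:

- **threshold `c`** (visits/day): a day with count ≤ `c` is favourable.
  Default 1,250 in the pipeline (the reference hospital's annual mean,
  rounded); the sweeps explore 900–1,700.
- **learning rate `ω ∈ (0, 1]`**: weight of the newest signal; default
  0.2. `ω = 1` is memoryless (`p_t` = raw signal), `ω → 0` freezes the
  prior; both limits are tested. The same parameter is sometimes called
  learning efficiency or discount rate; it is a single parameter here.
- **prior `p₀`**: default 0.5; treated as a prior and excluded from
  summaries (the first reported value is the day-1 update). Two
  trajectories fed identical signals forget a prior gap at the exact rate
  `(1−ω)^t`, which is tested in closed form.
- **observation window `d ≥ 1`**: the most recent `min(t, d)` days enter
  the signal, so early days use what is available and every day of the
  series is reported.
- **signal rule**: how a multi-day window enters the update is genuinely
  open; three rules are implemented. The default, *fraction* (share of
  window days at or below `c`), is the only one of the three under which
  setting `c` to the series median centres the long-run mean belief at 0.5
  for every window length — the knife-edge property the analysis turns on.
  *all* (1 iff every window day favourable) and *mean* (window mean ≤ `c`)
  are available alternatives; the decline of mean `p` with window length
  seen in real data is data-dependent, not an identity of the rule.

The telescoped envelope `(1−ω)^{t−1} p ≤ p_t ≤ 1 − (1−ω)^{t−1}(1−p)` is
asserted on every trajectory the tests generate (1,000 random ones in the
acceptance suite), with the index shifted by one because the package
reports the first *updated* value rather than the prior.

Summaries: "days with p > 0.5" is a strict inequality; monthly tables are
arithmetic means of the daily `p_t` within calendar months; reported means
are rounded half-up to 3 decimals at presentation (raw values kept
internally); percent rates of change round half-up to integers.

Emergency care is the special case prior = 1, one-day window, threshold =
the series' annual mean rounded to the nearest integer — full initial
trust eroded only by congested days.

## The payoff index

Indicators are standardised as `instance / national` (raw ratio kept; 2-dp
rounding is presentational). The mapping from standard values to the
published comprehensive indices (the "aggregative indicator" weighting) is
not reconstructible from the published table, so the package (a) ships the
published comprehensive indices as a reference fixture and (b) offers a
computed mode in which a user-supplied signed weight gives
`CI = weight · standard_value`. The published H-column entries sum to
1.56 while the published aggregate is 1.55; `aggregate_payoffs` returns
the honest column sum and `reference_payoff_index()` returns the published
pair (1.55, −0.72), with the discrepancy carried in report metadata.
Category sums use exactly rounded summation (`math.fsum`), making the
aggregation permutation-invariant.

`E = H·p − L·(1−p)` is applied literally to signed values: the empirical
loss category nets out negative (−0.72), so `E` is affine in `p` with
slope `H + L = 0.83 > 0`, minimum `min(H, −L) = 0.72 > 0`, and perfectly
correlated with the belief series. The resulting `E` feeds the
hospital-vs-pharmacy 2×2 matrix (0 / `e` / `E` / `E+e`); equilibrium
analysis of that game is out of scope here.

## The synthetic generator

Counts are Gamma-Poisson: `count_t ~ Poisson(Gamma(1/φ, φ·μ_t))` with mean
`μ_t = λ · month(t) · weekday(t) · holiday(t)` and variance `μ(1 + φμ)`;
`φ = 0` gives plain Poisson. The mixture was chosen because it adds
overdispersion with a single parameter; the default `φ = 0.003` gives a
daily standard deviation of roughly 75 at the outpatient scale.

The default outpatient configuration is one 2020 calendar year (366 days):
base rate 1295.468, weekday multipliers Mon→Sun
(1.14, 1.10, 1.07, 1.05, 1.03, 0.68, 0.62), month multipliers with a
February trough (0.72) and mild summer peak, and a ×0.65 dip on Feb 1–7
mimicking a holiday week. These values were calibrated once so that a
simulated year reproduces the reference series' annual mean (≈1,238.9)
and median (≈1,350) within 3% across seeds, with Monday the busiest
weekday. The weekend lows pull the mean below the weekday-dominated
median, giving the left-skewed shape the analysis assumes. The emergency
configuration uses a lower base rate (150/day), a flat weekday profile and
mild seasonality.

What the generator does **not** emulate: epidemic-wave disruptions (the
reference year was a pandemic year), capacity-driven censoring of demand,
long-memory autocorrelation beyond the calendar structure, and
patient-level heterogeneity. Tests passing on synthetic data therefore
demonstrate correctness of the mechanics and the calendar-scale
statistical properties, not fidelity to any particular hospital's record.

## Numerical and interface choices

- Poisson-binomial tails, equilibrium scans and deviation checks are exact
  (no Monte Carlo); enumeration is refused above `N = 20` rather than
  silently truncated.
- Degenerate inputs raise typed errors (`DomainError`,
  `DataValidationError`, `ResourceError`); the CLI maps them to exit codes
  2 (validation) and 3 (I/O).
- Visit CSVs must be consecutive calendar days; gaps are reported with the
  offending dates. Thousands separators in counts are stripped on load.
- Report bundles are byte-deterministic for a fixed configuration and
  seed, and the manifest echoes every parameter plus SHA-256 hashes of
  file inputs.
- Problem sizes in the test and acceptance runs (horizons of 10^3–10^4
  fictitious-play rounds, 366-day series, 1,000 random trajectories,
  10^5-point payoff grids) keep every check exact or tightly bounded while
  completing in seconds.

## Known limitations

- Fictitious-play convergence is not guaranteed in the k-action game
  (cycling from symmetric starts is real, not a bug).
- The belief model has one representative patient per day; no feedback
  from belief to attendance volume, so the game stage and the belief stage
  are coupled only through the payoff index.
- The published indicator weights being unrecoverable, computed-mode
  payoffs depend entirely on user-supplied weights.
- Queueing/waiting-time effects and within-day dynamics are out of scope.
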