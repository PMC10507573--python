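# Methods

## Model

A juvenile is tracked over `T` discrete decision steps with two integer
state variables: energy reserves `x ∈ 0..X` (with `x = 0` an absorbing
starvation state; live states are `x ≥ 1`) and ability `a ∈ 0..A`.  At
each step one of three activities is chosen — forage, play, rest — and at
the horizon the individual is paid `g(x)·ρ(a)` where `g(x) = (x/X)^q` for
`x ≥ x_crit` and 0 otherwise, and `ρ(a)` is the reproduction probability
(linearly increasing in ability in the reproductive-ability variants,
identically 1 otherwise).  With the default `q = 0` the reserve factor is
the binary payoff: reach `x_crit` by `T` or score nothing.

### One-step kernel

Within a timestep, events resolve in this order:

1. **Predation.**  The individual survives with probability `1 − m`,
   where `m` is the activity's risk (`m_f(a)` for foraging, constant
   `m_p`/`m_r` for play/rest).  Because death yields value 0 regardless of
   cause, placing predation first only affects the bookkeeping of death
   causes, not any value or policy.
2. **Energy update.**  Survivors pay the activity cost and collect the
   stochastic gains: foraging yield `y_e` with probability `y_z(a)`
   (foraging only) and the parental provision `w_e` with probability `w_z`
   (every activity, while `t < τ`; the window is half-open, `t = 0..τ−1`).
   Reserves cap at `X` with no carry-over.  If the result is `≤ 0` the
   individual starves — a provision received in the same step can
   therefore rescue it.
3. **Practice.**  Ability increments by one (capped at `A`) with the
   activity's practice probability (`s_f`, `s_p`, 0), independent of
   whether the foraging attempt succeeded: practice accrues with each
   session, not each success.

All ability-dependent rates interpolate linearly between their `a = 0`
and `a = A` endpoints, computed in the convex-combination form
`v0·(1−a/A) + vA·(a/A)` so both endpoints are attained exactly.

### Solver

Backward induction over the full `(x, a)` grid in double precision, with
no discounting beyond explicit mortality.  The per-activity expectation
is vectorised as a weighted sum over at most four energy outcomes of an
ability-mixed value slice; a full default solve (301 × 101 × 200 states,
3 activities) takes well under a second.  States whose optimal value is
exactly zero (the payoff is unreachable) are assigned the choice `none`.

### Degenerate optima

Away from the starvation floor and the energy cap, exchanging the order
of a play step and a forage step leaves the outcome distribution — and
hence the expected payoff — exactly unchanged.  In the reproductive-
ability variants, where foraging gives no (or merely redundant) practice
toward a terminal benefit, this makes play and forage *bit-exactly*
value-tied over large state regions: the optimum prescribes how many
steps of each activity to take, not when.  The solver therefore records
the full set of exactly co-optimal activities per state.  A single
deterministic tie order would make the entire cohort (which starts as a
point mass) switch activity in lockstep and would misrepresent an
indifferent population; instead the forward model splits the mass in a
tied state equally among its co-optima and the Monte-Carlo simulator
draws uniformly among them.  The expected payoff is unaffected by any of
these choices.  For the exported single-choice policy maps, ties resolve
to the lowest-mortality activity (rest, then play, then forage).  Tie
detection uses exact floating-point equality: the degeneracies at stake
are exact by construction, and near-ties below any epsilon are either
exact or genuinely ordered.

### Forward cohort model

A unit mass starts at `(x_start, a_start)`.  At each step, mass sitting
in zero-value states is absorbed into a **no-payoff** class before
acting (no behaviour is optimal there); the rest is pushed through the
kernel, with predation and starvation tracked as separate absorbing
classes.  Mass is conserved to ≤ 1e−10 at every step (machine precision
in practice), and the expected terminal payoff realised by the cohort
equals the dynamic-programming value at the start state to ≤ 1e−10 —
an internal exactness check performed in the tests.

Two normalisations are exposed deliberately: per-timestep activity
proportions are fractions of the initial cohort (the stacked-figure
convention, in which the cumulative no-payoff line completes each
timestep to 1), while the lifetime budget divides each activity's summed
mass by the total acting mass.  The 5% lifetime-play criterion of the
sensitivity analysis uses the acting-mass normalisation.

### Detection floor for onset/exclusivity statistics

The propagated mass always carries vanishing tails (1e−9..1e−4 of the
cohort) of off-activity mass from improbable reserve histories — e.g. an
unlucky run of failed provisions sends a sliver of the cohort foraging
during an otherwise all-play phase.  Statements like "play is the only
activity" or "play begins at t" are therefore statements about
population-visible proportions, not about literally zero mass.  The
summary statistics (`first_play_t`, `play_only_prefix`,
`rest_only_suffix`) use a detection floor of **1e−3 of the initial
cohort** — one individual per thousand, below what a stacked proportion
curve can resolve.  Probability-conservation checks are unaffected and
keep their 1e−10 tolerance.

### Monte-Carlo simulator

Individuals are simulated in chunks of 20,000, each chunk driven by its
own child stream of the master seed (so enlarging `n` appends chunks
without reshuffling earlier outcomes).  Agreement with the deterministic
forward model is checked at `n = 100,000`: the empirical terminal payoff
must lie within 3 binomial standard errors of `U*`, and the per-timestep
activity proportions are compared jointly — 600 simultaneous binomial
comparisons per variant imply ~0.3% chance exceedances of a 3-SE band
even for a perfect simulator, so the test allows at most 1% of cells
beyond 3 SE and requires every cell within 5 SE.

### Sensitivity sweeps

One parameter at a time is varied across a grid while all others stay at
the variant's defaults; each grid value triggers a full re-solve and
re-propagation from the sensitivity start state (`x = 50, a = 0`).
Variant couplings follow the swept value (in the antipredator variant,
`m_f(A)` tracks `m_p`; the aliases `m_f`/`y_z` move both endpoints of a
constant rate).  Default grids take 16 evenly spaced points across each
parameter's sensitivity span; the published grids behind the printed
qualifying ranges are not available, so reported ranges are
grid-resolution approximations and any grid can be supplied explicitly.
Qualifying ranges are maximal runs of consecutive grid values with play
share ≥ threshold; disjoint runs are reported as separate intervals.

## Default parameters

Defaults (shared unless a variant overrides): `X = 300`, `A = 100`,
`T = 200`, `τ = 50`, `w_e = 3`, `w_z = 0.7`, `y_e = 5`, `y_z = 0.7`,
`c_f = 2`, `c_p = 3`, `c_r = 1`, `m_f = 0.002`, `m_p = 0.0002`,
`m_r = 0.0001`, `s_f = 0.8`, `s_p = 0.5`, `x_crit = 150`, `q = 0`.
Variant overrides: `model1` sets `m_f(0) = 0.005, m_f(A) = m_p`;
`model2` sets `y_z(0) = 0.1, y_z(A) = 0.9`; `model3a/3b` add
`ω_z(0) = 0.1, ω_z(A) = 0.9`, with `s_f = 0` in 3a.  `c_r` may be
negative (rest with net energy gain).  Advisory orderings
(`c_f ≤ c_p`, `m_r ≤ m_p`) warn rather than fail, so deliberately
inverted configurations remain expressible.

Start states: the published time-course figures use `x_start = 100,
a_start = 0`; the sensitivity analysis uses `x_start = 50, a_start = 0`.
Both are honoured in the corresponding computations.

## Problem sizes

All computations run at the full published scale: value/policy grids of
301 × 101 × 201 states, forward propagation over 200 steps, Monte-Carlo
cross-checks at 100,000 individuals, and sweep grids of ~16 points (a
full solve takes ≈ 0.5 s, a sweep a few seconds per grid point).  The
miniature instance used for the exhaustive-recursion oracle is
`X = 20, A = 3, T = 10, τ = 5, x_crit = 10`, small enough for a plain
memoised scalar recursion to enumerate every state.

## Known limitations

* The within-timestep event order and the exact form of the
  reserve-exponent transformation `g(x) = (x/X)^q` are modelling choices;
  other orderings change death-cause bookkeeping and boundary states but
  not the qualitative structure.  All default analyses use `q = 0`, where
  any monotone `g` with `g ≡ 1` is equivalent.
* Late-life behaviour in the reproductive-ability variants is sensitive
  to kernel details: here play keeps rising into the final timesteps of
  variant 3a (peaking near 75% of the cohort) and small play/forage
  tails persist past `t = 150` in variant 3b, so the terminal rest-only
  phase measures ≈ 30 steps at the 1e−3 floor.
* Energy and ability are integer-valued with unit increments and no
  depreciation; there is no interpolation, no body-size state, and no
  social interaction between individuals.
* The sweeps are one-at-a-time by design; no interaction (global)
  sensitivity is computed.
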