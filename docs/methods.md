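# Methods

## The empirical pipeline

A conversation log is a flat file of messages, each optionally pointing at
the message it answers.  Parent links define a forest of reply trees;
projecting every reply onto (author, parent's author) yields a directed
network with integer weights `w_ij` = number of replies from user *i* to
user *j* over the whole observation window.  Policies:

* a reply whose parent is missing from the log becomes a root (crawled
  corpora truncate threads; a headless reply still tells us nothing about
  an edge, so dropping the link loses nothing and keeps the record);
* self-replies add no edge; users who only author roots appear as isolated
  nodes by default;
* the aggregation window is the whole log; a `--since/--until` timestamp
  filter exists as plumbing only.

The per-user statistic `omega_out = (sum_j w_ij) / k_out` is the average
number of replies per initiated relationship.  Users with `k_out = 0` have
no initiated relationships; they are excluded (with an error when queried
directly), not counted as zero.  The reciprocity count `rho` is the number
of neighbours with replies flowing both ways, bounded by
`min(k_in, k_out)`.

**Binning.**  Degrees are heavy-tailed, so curves use unit bins up to
degree 10 and geometric bins of ratio 1.25 above (linear binning is
available).  A bin's representative degree is the mean degree of its
members, its band the 25th/75th percentiles of the member values.  The
curve center is the per-bin *mean* for empirical data and the *median* for
model replicas, where heavy per-run tails would otherwise dominate.

**Peak location.**  The binned center is smoothed with a centred moving
average (odd window, default 3, shrinking at the edges); the smoothed
argmax is found; and the raw argmax within that window is returned.  The
two-stage rule matters: a plain smoothed argmax can shift the maximum of an
asymmetric curve by up to half a window, whereas for any strictly unimodal
noiseless curve the best averaging window provably contains the true peak,
so this procedure returns the exact argmax bin for every window while
still denoising real curves.  Ties resolve to the smallest degree, and a
maximum in the first or last kept bin is flagged `boundary`.

## The agent model

Agents sit on a static scale-free contact network (configuration model
over i.i.d. degrees `P(k) ∝ k^gamma`, self-loops and parallel edges
removed, every surviving undirected edge realised as two opposite directed
edges, so contact count = out-degree = in-degree).  Defaults: `gamma =
-2.4`, `k_min = 1`, `k_max = sqrt(N)` (the structural cutoff; the scaled
study below overrides it).  Queue capacities are `round(N(q_max, sigma))`
clamped at 1.

Per synchronous step each agent (i) replies to `S_t ~ U{0..q_i}` of its
queued messages, chosen without replacement with probability proportional
to the *sender's* static total degree — popularity buys attention — each
reply incrementing `w[agent][sender]` and travelling back to the sender;
and (ii) broadcasts to all contacts with probability `p`, a weightless
seeding of activity.  Everything produced in a step is delivered at its
end (nothing sent at *t* is answerable before *t+1*, removing
iteration-order artifacts); deliveries merge into the recipient's queue in
priority order with uniform random tie-breaks, and entries beyond capacity
are discarded lowest-first.

**Queue slots hold conversation partners, not raw messages.**  A queue
retains at most one pending entry per sender: further messages from
someone you already owe a reply occupy no extra slot.  This choice is
load-bearing and deliberate.  If duplicates from one sender could stack,
every reply re-enters the counterpart's queue, conversations on
low-degree edges bounce immortally, broadcast injection grows the message
population without bound, and after a transient *every* agent saturates —
the weight-per-contact curve then decreases monotonically with degree and
no interior peak exists at any capacity (we verified this at the study
scale, and also that a per-step queue-clearing variant yields only a flat
plateau).  With one slot per partner, queue occupancy is bounded by
`min(degree, capacity)`, so capacity binds exactly when the number of
active contacts reaches the number of attention slots: the
weight-per-contact curve rises gently below `q_max` (helped by the
priority advantage of popular agents), peaks near `q_max`, and decays as
`1/k` beyond it — the mechanism by which a finite priority queue fixes the
number of sustainable relationships.  Measured peaks at `q_max ∈ {20, 50,
100}` grow strictly and nearly linearly with capacity (slope close to 1,
R² > 0.9).

**Scaled study conditions.**  The capacity sweep runs at `N = 10^4`,
`gamma = -2.4`, `p = 0.02`, `T = 2000`, `sigma = 0`, 51 replicas per
capacity with counter-derived seeds, median curves per degree bin.  The
substrate uses `k_max = 1000` — near the natural cutoff
`N^{1/(|gamma|-1)} ≈ 700` — rather than the structural-cutoff default,
because the `q_max = 100` peak must sit well inside the degree range to be
measurable.  One substrate is generated per capacity configuration and
held fixed across replicas, which keeps degree bins identical so that
per-bin medians across replicas are well defined.

**Two engines, one dynamics.**  A compiled kernel (numba) runs the study
scale; an instrumented pure-Python engine retains the full message trace
(every broadcast root and reply, with parentage) and asserts the queue
invariants per step.  Both implement identical policies.  Priority-
proportional sampling without replacement is realised in the kernel as an
exponential race (`Exp(1)/priority`, take the `S_t` smallest), which is
distributionally identical to iterative renormalised sampling; equal-
priority ties everywhere are broken by a uniform key drawn at message
creation.  The one-draw selection law (4/5 for priorities {4, 1}) and the
uniformity of `S_t` are frequency-tested at the 1% level.

## The single-user reduction

One focal user with `k/2` partners; partner dynamics are ignored.  Each
partner sends one message per step with probability `min(1, beta * k)` —
inflow `<R> = (k/2) * beta * k ∝ k^2`, the popularity effect.  Partner
priorities are drawn once per run from a discrete power law on `[1, 10^4]`
with exponent −2.1; the focal user runs exactly the network model's queue
mechanics with capacity 50 (plus optional Gaussian noise, drawn once).
Defaults follow the study conditions: `q_cap = 50`, `T = 500`,
`beta = 5e-4`.

The normaliser `beta` has no canonical value — the proportionality between
send rate and degree is stated without a constant — so absolute peak
positions are not meaningful; only the regime structure is.  Below the
crossover (`k* ≈ sqrt(2 q_cap / beta) ≈ 450` at the defaults) nearly every
arrival is eventually answered and `omega ≈ beta * k * T` grows linearly;
above it the queue pins at capacity, replies per step converge to
`q_cap / 2`, and `omega ≈ q_cap * T / k` decays.  The package measures
both exponents by least squares on log-log grids: inflow slope 2.0 on
`k ∈ [2, 200]`, omega slope −1.0 on `k ∈ [500, 2000]` (observed 2.01 and
−1.00 at 200 replicas).  Capacity noise `sigma ∈ {0, 5, 10}` leaves the
peak position unchanged within one grid point.

## The synthetic-data generator

Real reply corpora of the scale that motivated this package are not
redistributable, so the generator makes the pipeline testable end to end:

* **abm mode** re-emits an instrumented run as a log — one root per
  broadcast event, one record per reply attached to the exact message
  answered — and ingesting that log must reproduce the run's weight matrix
  integer-exactly.  This is a mechanism-consistency check, not evidence
  about real data.
* **parametric mode** plants a known answer independent of the agent
  model: users get power-law contact counts (exponent −2.1 on [1, 2000]);
  a user with `m` contacts draws per-edge weights
  `1 + Poisson(intensity * min(m, c²/m) / c)`, so mean weight per edge
  rises linearly to the capacity parameter `c` and falls as `c²/m` beyond
  it, putting the omega peak at `c` by construction.  Populations are
  sized so the degree range around each planted peak stays populated
  (10k/20k/40k users for c = 50/150/300).  Emission is a flat forest: one
  root per contacted pair, replies attached directly to it.

What passing these tests shows: the ingest/metrics stack measures what it
claims on data whose ground truth is known, and the model's bookkeeping is
exactly consistent with its emitted logs.  What they do not show: that
real conversation corpora place their peak anywhere in particular — the
generator's degree structure is structural emulation, not calibration.

## Numerical choices and degenerate inputs

* All randomness flows through seeded generators; replica and component
  seeds derive from a master seed by a counter scheme and stay below 2^31.
  Fixed seeds give bit-identical runs per engine.
* Degree sequences with odd sums get one uniformly chosen below-maximum
  entry incremented; capacities below 1 clamp to 1.
* Empty networks yield empty curves with a warning; peak detection
  requires at least three bins; `beta * k > 1` clamps to 1 with a warning.
* The degree-sequence sampler is checked against the analytic truncated
  CDF (Kolmogorov distance < 0.01 at N = 5×10^4); the tail-exponent
  diagnostic is an exact discrete truncated MLE.

## Known limitations

* The reply-per-step law `S_t ~ U{0..q_i}` is one reading of "a random
  number between 0 and q_i"; alternatives (binomial, fixed-rate) would
  change curve amplitudes but not the capacity-bound mechanism.
* The configuration model discards self-loops and multi-edges, so hub
  degrees fall slightly below target; realised degrees are used
  throughout.
* No empirical-substrate mode, no degree correlations or clustering, no
  asynchronous scheduler, no message content.
* The alternative `append-until-full` queue policy is available only in
  the instrumented engine.
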