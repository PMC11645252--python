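# Methods

This note records the model behind `qmim`, the choices made where the design
was genuinely open, and what the synthetic validation does and does not show.

## Units of analysis

A **transaction** is one badge checkout: (user, shop, register, timestamp,
item set).  The day is divided into three half-open meal periods — breakfast
[06:00, 11:00), lunch [11:00, 14:30), afternoon [14:30, 20:00) — and each
period defines an **anchor**: a meal at lunch, a coffee or tea otherwise.  A
transaction containing both coffee and tea is anchored on coffee (a
deterministic tie-break; coffee dominates the beverage mix by a wide margin).
Transactions without an anchor stay in the log — they still occupy queue
positions and block adjacency — but cannot be dyad members.

A **dyad** is an ordered pair of transactions (partner first, focal second)
at the same shop and register, on the same date and in the same meal period,
with lag ≤ 300 s, distinct users, both anchored, and no transaction at that
register strictly between them.  Adjacency is evaluated per register stream:
the queue of interest is the physical checkout line.  Chains are allowed (a
transaction can be focal in one dyad and partner in the next).  Dyads are
kept only if their unordered user pair occurs at least `min_joint = 10`
times (both orderings pooled — the weaker reading of "adjacent together";
`pair_count_ordering="ordered"` switches to directed counting).  The
repeated-pair requirement is what makes the matched design possible: the
same partner must appear in both a treated and a control dyad.

## Identification and matching

The estimand is the total effect of the partner's purchase $Y_a(t)$ on the
focal purchase $Y_b(t)$.  The assumed DAG has stable eating profiles
$X_a, X_b$, a homophilous tie $S_{a,b}$ (influenced by both profiles), shared
context $P(t)$ affecting both choices, and the mimicry arrow
$Y_a(t) \to Y_b(t)$.  Under it, {partner identity, shared context} is a
sufficient adjustment set.  Matching realises it:

* **exact keys**: partner user, shop, meal period (calendar date is *not* a
  key; date-level information enters through availability and popularity);
* **availability**: the focus item must have been bought at least once in
  each dyad's (shop, date, period) stratum;
* **popularity caliper**: stratum popularity (fraction of the stratum's
  transactions containing the item) must agree within 10%, *relative* by
  default: |p_t − p_c| ≤ 0.10·max(p_t, p_c).  A relative caliper respects
  the wide popularity range across items; `caliper_mode="absolute"` is
  available.

**Leave-two-out popularity.**  The popularity and availability values used
for a given dyad exclude that dyad's own two transactions from the stratum
count.  This matters: the raw stratum fraction contains the partner's
exposure and the focal's outcome, so matching on it conditions on the very
quantities being compared.  At realistic stratum sizes for a scaled-down
simulation (tens of transactions), the raw variant visibly attenuates the
paired contrast — ground-truth audits here measured a matched RD of ≈ 0.11
against a true 0.15 — with the availability filter the largest offender (a
control dyad whose focal bought the item would always count as "available").
With the leave-two-out variant the matched estimate is unbiased in the same
audit.  `popularity_loo=False` restores the raw-count behaviour.

**Algorithm.**  One-to-one greedy matching without replacement within each
exact-key cell: treated dyads in chronological order, each taking the
admissible control with the smallest popularity gap; ties break by earliest
control timestamp, then a seeded draw.  Greedy-with-audit was preferred over
optimal bipartite matching for transparency; tests verify the greedy matched
set reaches the exhaustive Hopcroft–Karp optimum on reference fixtures and
stays within 10% of it in aggregate on random small instances.  Balance is
reported as the standardized mean difference of popularity
(|mean_t − mean_c| / pooled SD), with < 0.2 considered balanced.

## Estimation

From the paired table (n11, n10, n01, n00; n pairs):
RD = (n10 − n01)/n, RR = (n11+n10)/(n11+n01).  Confidence intervals are
percentile bootstrap with B = 1000 pair-level resamples (a multinomial
redraw of the four cells), seeded.  BCa refinements were judged unnecessary
at the n of interest.  The test of no treatment effect is McNemar's
χ² = (n10−n01)²/(n10+n01) on 1 df, uncorrected; an exact binomial variant is
exposed and the two agree to ~5% relative by n10+n01 ≈ 10⁴.  RR is reported
as an undefined sentinel when no control focal purchased.

**Subgroups** (status, gender, age terciles ≤22 / 23–32 / >32 at transaction
time) filter matched pairs by the attribute and re-estimate.  Age is
transaction year minus birth year (only birth year is observed).  Partner
attributes are constant within a pair by construction; for focal-side axes,
pairs whose two focals disagree on the attribute are dropped and counted
rather than split — within-pair comparability outranks sample size.  Users
missing from the demographics table are excluded, never imputed.  Levels
with fewer than 30 pairs carry a `low_n` flag.

## Robustness battery

* **Randomized partners**: each dyad's partner transaction is replaced by a
  uniform draw from the same (shop, date, period) stratum, excluding the
  focal's own transactions; register is deliberately not required, so the
  baseline retains contextual (non-queue) similarity.  The true partner
  remains eligible by default — excluding them (available as a switch) would
  slightly tilt the null.  Matching and estimation then run unchanged on the
  randomized dyads.
* **Dose–response**: each matched pair carries the *treated* dyad's lag (the
  dyad where exposure happened; `lag_mode="mean"` averages both).  RD and RR
  are estimated in 10-s bins over [0, 120) s and a weighted least-squares
  line (weights = bin pair counts) gives the slope and a two-sided p-value.
  Pairs beyond 120 s are excluded from the fit; fits with fewer than 3
  occupied bins are refused.
* **Rosenbaum bounds**: worst-case one-sided sign-test p-value under a
  treatment-odds bias of Γ, pbound(Γ) = P[Bin(n10+n01, Γ/(1+Γ)) ≥ n10];
  Γ* is found by bisection to 10⁻³.  One-sided in the direction of the
  observed effect, α = 0.05.  When n10 ≤ n01 or pbound(1) > α there is
  nothing to explain away and Γ* = 1.  Amplification solves
  Δ = (ΛΓ−1)/(Λ−Γ) on a Λ grid (Λ > Γ), and the round-trip
  (ΛΔ+1)/(Λ+Δ) = Γ is verified to 10⁻⁹.

## The synthetic generator

`synthgen.simulate` draws, per user, a status/gender/birth-year profile and
a latent "health" trait; per-user per-item propensity offsets on the
log-odds scale load on that trait (salad, fruit, vegetarian meals positive;
desserts, soft drinks negative), giving stable eating profiles with spread
`profile_sd`.  Disjoint co-queueing ties form with probability
∝ exp(−homophily_strength · |trait gap|), optionally status-assortative, so
tied users have correlated tastes — the confound the matching must remove.
Context enters as day×shop×item log-odds shocks of SD `context_sd`.  Each
day, tied pairs and singletons attend each period Bernoulli-wise
(breakfast 0.30, lunch 0.80, afternoon 0.25), pick a register uniformly and
a start time uniformly in the period; pair members arrive back-to-back with
an Exp(14 s) gap, matching observed inter-arrival times.  Walking each
register stream in time order, every arrival buys the period anchor (meal at
lunch with a vegetarian-vs-meat choice, else coffee/tea) plus each addition
with probability logistic(base + profile + context), **plus δ·e^(−lag/τ)**
when the immediately preceding transaction (same period, within 300 s)
contains the item.  The anchor-type choices (tea vs. coffee, vegetarian vs.
meat) receive the same additive mimicry as the additions, so the two
anchor-type analyses also have planted signal.  Probabilities are clipped to [0, 1] and clipping is
counted; shipped configurations stay below 1% of decisions.

Mimicry is additive on the probability scale so that the ground-truth target

    rd* = E[p(buy | exposed) − p(buy | unexposed) | exposed]

is directly comparable to the matched RD; `GroundTruth` records both
counterfactual probabilities, the realised lag and exposure for every focal
decision, and recovery tests always compare against rd*, never against δ
itself.

**Default calibration.**  Defaults are chosen so that the default run's
descriptives look like a real campus: mean dyad lag ≈ 14 s with ≈ 98% of
dyads under a minute; breakfast beverage anchors ≈ 87% coffee (the baseline
tea propensity is 0.085 — profile/context dispersion and mimicry lift the
realised share to ≈ 0.13); 12 shops with 3 registers; lunch the busiest
period; base addition popularities from 0.04 (breakfast dessert) to 0.25
(lunch condiment).  `context_sd` defaults to 0.1: the simulation runs at
hundreds of users rather than the tens of thousands behind real logs, so
stratum popularity is estimated from tens of transactions; a mild shock
keeps the signal-to-noise of the popularity proxy comparable to the real
setting.  The confounding stress configuration instead uses two dense shops
(600 users) with `context_sd = 1.5` and `homophily_strength = 3` —
popularity control works through the proxy, and with thin strata *any*
popularity-matched design retains a residual bias of order one over the
stratum size.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: menu economics and prices, seasonal and
weekday structure, group arrivals of three or more, users switching shops
or partners, register-specific queue-selection behaviour, coordination
before queueing, and demographic marginals beyond rough status/age mixes.
Passing recovery tests show the *pipeline* is consistent under its own
assumptions, not that those assumptions hold in any particular cafeteria.

## Problem sizes and numerical choices

Validation runs use 500 users × 120 days (≈ 80k transactions, ≈ 19k matched
pairs) for parameter recovery over 20 seeded replicates; 600 users × 40 days
across 2 shops for the confounding stress; 400 users × 60 days for the
randomized-queue null (10 replicates) and the lag dose–response (20
replicates, δ₀ = 0.2, τ = 30 s).  All randomness flows through
`numpy.random.default_rng` seeds; the pipeline derives one seed per stage by
hashing the stage name with the master seed, making full reports
byte-reproducible.

## Known limitations

* Greedy matching is not guaranteed optimal; the audit bounds the loss on
  small instances only.
* The popularity proxy controls context only up to its sampling noise; with
  very small strata, residual confounding of order 1/stratum-size survives
  even leave-two-out matching (measured ≈ 0.01 in the stress test).
* The randomized baseline retains the true partner as an eligible draw
  (matching its construction here to a uniform stratum draw); with very
  small strata this leaves a slight positive tilt of order δ/stratum-size.
* Bootstrap CIs ignore the matching step's variability (pairs are resampled,
  the matching itself is not redone), as is standard for matched designs.
* The exact-anchor robustness variant conditions on both members' anchor
  labels, which can shrink some cells to nothing at small n.
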