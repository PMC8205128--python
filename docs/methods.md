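# Methods

## The model

Two individuals meet; one (the **challenger**) can *take* the other's
(the **defender**'s) resource of value `v > 0` or *respect* it.  After a
take the defender *yields* (the resource changes hands) or *fights*, in
which case both sides bear an expected net loss `c > 0`.  Payoffs are
normalised so the challenger's status quo and the defender's yield payoff
are 0; an asymmetric-stakes variant (`GeneralPayoffs`) maps any ordinal
deterrence-type game onto this form by per-player affine shifts, under
which best responses are invariant.

In one shot, yielding strictly beats fighting after a take, so
take-and-yield is the unique subgame-perfect equilibrium: deterrence rests
on an empty threat.  The package studies when *reputation* rescues it.
Challengers may pay an information cost `a ≥ 0` to learn a binary
classification of the defender (*tough*/*weak*) before moving.  The six
challenger strategies are the non-checking `AllR`, `AllT` and the checking
`Disc` (take iff weak), `IR`, `IT` (check but act unconditionally) and
`Par` (take iff tough).  Defenders play stationary randomised strategies:
fight with probability `Q ∈ [0, 1]`.  The probability
`Q* = v/(c+v)` leaves a challenger indifferent between taking and
respecting.

Two reputation-assessment schemes are implemented:

* **last-action** — fight ⇒ tough, yield ⇒ weak, respected ⇒ unchanged;
* **fighting-frequency** — tough iff the empirical fighting frequency over
  the last `k` recorded reactions strictly exceeds a threshold `Q̄`
  (discriminators use `Q̄ = Q*` by default).

`k = 1` with any interior threshold reproduces last-action exactly; both
schemes run through one ring-buffer code path so this equivalence is
bitwise, not approximate.

Under last-action, a defender's tough-image probability follows a two-state
chain driven by the challenger mixture `x = (x_AllR, x_AllT, x_Disc)`:
weak→tough at rate `(x_AllT + x_Disc)·q`, tough→weak at rate
`x_AllT·(1−q)` (discriminators do not attack the tough, hence the
"stickiness" of a tough image).  The stationary probability
`π = (x_AllT+x_Disc)q / [(x_AllT+x_Disc)q + x_AllT(1−q)]` underlies all
analytic payoffs; when both rates vanish the chain never moves and a
supplied initial-image probability (default 1/2) is returned.

## Analytic dynamics

The analytic module works in the stationary-reputation limit (reputations
equilibrate between strategy revisions).  Because randomising is then
dominated for defenders (verified numerically by
`randomization_dominance_check` on a simplex × q grid), the defender
population reduces to a fighter share `y ∈ [0, 1]` and the state space is
the triangular prism `Δ² × [0, 1]`.  Revision follows best-response
dynamics, `ẋ = BR(x, y) − x`, `ẏ = BR_y(x) − y`, integrated by forward
Euler (default step `1e-3`, horizon 200; labels are verified by step
halving in the tests).

Numerical choices:

* **Ties.**  Payoff ties within `1e-9` put the flow target at the current
  relative weights on the optimal set (uniform if that weight is zero);
  on the defender indifference plane `g(x) = v·x_Disc − c·x_AllT = 0` the
  target keeps the current `y`.  This avoids artificial symmetry breaking
  and also suppresses step-level chattering across the plane.
* **Attractor labels.**  Within 0.05 of `(AllT, y = 0)` → the
  no-deterrence ESS.  `x_AllR ≥ 0.95` with
  `y ≥ max(Q*, 1 − a/v) − 0.05` → the deterrence component;
  `max(Q*, 1 − a/v)` is the fighter share above which every challenger
  strategy other than `AllR` is suboptimal, i.e. the edge of the
  equilibrium component where respect is sustained.  Everything else is
  `undetermined` (none occur on the tested grids).
* **Early exit.**  Integration stops before the horizon once the whole
  batch satisfies `max|BR − state| < 1e-9`; the flow converges
  exponentially, so the early labels equal horizon labels.
* **Projection.**  The prism is projected to a rectangle with horizontal
  coordinate `y` and vertical coordinate `(v − g(x))/(v + c)`, so the
  defender indifference plane is the horizontal line at height `v/(v+c)`
  and yielder-favouring states (`g < 0`) plot above it.  The orientation is
  a convention.

The ESS scan tests every monomorphic state (six challenger kinds × a
defender q-grid, default 21 levels) against all grid mutants at invasion
barrier `1e-3`, requiring the incumbent to earn strictly more than each
mutant in the perturbed population.  Equal-payoff drift (e.g. defender
reactions at `(AllR, F)`, which are never tested by play) therefore fails
the scan, and for any `a > 0` the unique survivor is `(AllT, q = 0)`.

## Agent-based model

`N` agents (default 10⁴) are matched into `N/2` uniform random pairs each
round; within a pair one agent, chosen uniformly, is the challenger.
Checking challengers pay `a` and classify the defender under the
configured scheme.  Intended actions can flip with implementation-error
probability `ε`; the defender's reaction is Bernoulli(`q`) with the same
error channel; recorded reactions flip with reputation-noise probability
`δ` *at recording time* (the stored image is set wrong, persistently — a
per-observation perception flip is available as `noise_mode="perception"`).
Wealth is a single per-agent stock `W ← d·W + payoff` (default `d = 0.9`).
After each round each agent independently revises each role's strategy
with probability `u`: among the strategies used in that role by her
`N_F` friends and herself, she adopts the one whose users have the highest
average wealth (ties uniform).  Afterwards each role's strategy is
replaced by a uniformly random one with experimentation probability `μ`.
Friend lists are directed, fixed at initialisation, and never include the
agent herself.  The within-round order is: match → interact (payoffs,
reputation updates, wealth) → imitation → experimentation.

Baseline parameters: `v=1, c=1.5, a=0.1, N=10⁴, N_F=100, d=0.9, u=10⁻²,
μ=ε=δ=10⁻³`, 10⁴ rounds, with long-run statistics averaged over rounds
8000–10000 and across five replicate seeds (runs are independently seeded
from one base seed; a single `numpy` generator drives each run, so runs
are bit-reproducible).

Design choices that were genuinely open, and why they were made:

* **Continuous defender strategies (default).**  `q` lives on `[0, 1]`;
  experimentation draws uniformly.  With a coarse q-grid (the alternative,
  kept behind `q_continuous=False`), friend-group average wealths cannot
  statistically separate adjacent q-levels at `N_F = 100` and the defender
  population freezes near its initial distribution; on the continuum the
  imitation rule reduces to copying the wealthiest friend's `q` (values
  are almost surely distinct), selection on defenders works, and all three
  qualitative regimes of the model (deterrence at baseline, breakdown at
  large `k`, anarchy at low `c`) emerge.
* **Behaviour classes.**  `AllR` and `IR` act identically (both always
  respect; `IR` merely wastes `a`), as do `AllT`/`IT`.  Their wealth gap,
  `a/2` per round ≈ 0.5 in discounted stock, is small against the
  per-agent wealth dispersion (≈ 1.5, dominated by the role lottery), so
  finite friend samples keep the dominated twin at a noise floor
  (~0.1–0.15 for `IR` at baseline).  Long-run challenger outcomes are
  therefore reported both per kind and per behaviour class
  (`respect = AllR + IR`, `take = AllT + IT`, `discriminate = Disc`,
  `paradoxical = Par`); the class frequencies are the quantities that a
  description of realised challenger behaviour pins down.  At baseline the
  respect class settles near 0.70 and discrimination near 0.17.
* **Initial reputations.**  Fair-coin images for last-action, empty
  histories (classified weak, strict threshold) for fighting-frequency;
  both overridable via `initial_reputation`.  Initial strategies are
  uniform over their spaces, wealth starts at 0.
* **Information cost timing.**  `a` is sunk at the moment of checking,
  before the action, and all four checking kinds pay it every challenger
  round.
* **Wealth is not reset on revision** (switchable); resetting was tested
  and does not change the baseline regime.

## What the simulations do and do not show

The agent-based runs relax every analytic idealisation — finite
population, noisy play, boundedly rational imitation instead of best
response, reputations that do not equilibrate between revisions — and
still reproduce the analytic predictions qualitatively: deterrence with
minimal information, collapse with rich information, anarchy when fighting
is cheap.  They do not model real social structure: matching is uniform
(no space or assortment), the friend network is static and random, wealth
is observable without error, and the resource, conflict and information
costs are homogeneous across agents.  Conclusions about real populations
inherit those simplifications.

## Problem sizes

Default problem sizes were chosen so the whole suite runs on one CPU core
in minutes: five replicate runs per condition (standard errors at this
replication are ≲ 0.01 on the long-run frequencies), basin estimation on a
15×15×15 prism grid, Monte-Carlo oracles at 2×10⁵ steps (chain occupancy
standard errors ≲ 5×10⁻³ against a 10⁻² tolerance).  Examples are scaled
down further (N = 2000, 3000 rounds) and say so; at that scale the
large-`k` defender payoff declines steeply but only turns negative at the
baseline scale.
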