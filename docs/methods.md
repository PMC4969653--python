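# Methods

## Setting and model

A single-arm two-stage trial with a binary response tests
`H0: pi <= pi_u` against `Ha: pi >= pi_a` (`0 < pi_u < pi_a < 1`).  Stage 1
enrols `n1` patients and observes `S ~ Binomial(n1, pi)` responses.  The
design then either stops for futility (accept H0), stops for efficacy
(reject H0), or enrols `n2(S)` further patients and rejects H0 iff the
cumulative response count exceeds `r(S)` — the strict-inequality convention
`x > r` is used uniformly, so "at least `r + 1` responses" rejects.  All
operating characteristics are exact binomial sums; nothing is approximated.

The conditional error function is the bridge between the two stages:

```
P(S | r(S), n2(S), pi) = 1 - B(r(S) - S; n2(S), pi),
```

with `B` the binomial CDF; it equals 1 when the boundary is already crossed
(`r(S) < S`) and 0 when it is unreachable (`r(S) - S >= n2(S)`).  Exact type
I error and power are `sum_S P(S|.) b(S; n1, pi)` at `pi_u` and `pi_a`
(stops contributing 0 or 1), the null expected sample size is
`ESS0 = sum_S (n1 + n2(S)) b(S; n1, pi_u)`, and the maximum sample size is
`MSS = n1 + max_S n2(S)`.  A schedule is *valid* when futility stops form a
prefix of `S = 0..n1` (with `S = 0` always a futility stop), efficacy stops
form a suffix, and `n2(S)` is non-increasing over the continuation region —
the monotonicity property that makes an adaptive design acceptable to
practitioners (more observed activity never demands a larger second stage).

## Parameters

| parameter | meaning | default / typical |
|---|---|---|
| `alpha` | type I error bound (one-sided) | 0.05 or 0.1 |
| `beta` | type II error bound; power target is `1 - beta` | 0.1 or 0.2 |
| `pi_u`, `pi_a` | unacceptable / acceptable response rates | effect `pi_a - pi_u` of 0.15–0.3 |
| `n_max` (Simon/EF) | cap on the total-size scan | Simon minimax MSS; `+35` margin for the optimal criterion |
| `n_upper` (optimal adaptive) | cap on the MSS | must exceed the minimax adaptive MSS |
| `FEAS_TOL = 1e-12` | conservative slack on the error-rate comparisons | fixed |
| `TIE_TOL = 1e-9` | ESS0 values closer than this are tied | fixed |
| `beam_width = 256` | size of the heuristic incumbent pass | fixed; never affects optima |

Feasibility is always judged conservatively: a design is admitted only if
its attained type I error is at most `alpha + 1e-12` and its attained type
II error at most `beta + 1e-12`, so floating-point round-off can exclude a
borderline design but never admit an invalid one.  ESS0 is carried at full
double precision and rounded (2 dp) only for display.

## Classical searches

**Simon designs.**  For each total size `n` (scanned upward from 2) and
each `n1 < n`, all `(r1, r)` pairs are evaluated with vectorised exact
binomial arithmetic; for fixed `(n1, r1)` the smallest alpha-admissible `r`
maximises power, reducing feasibility to one check per boundary pair.  The
first feasible `n` is the minimax MSS; the optimal criterion continues the
scan to `n_minimax + 35` (a margin that covers every configuration we
tabulate) and keeps the global ESS0 minimiser, ties broken by smaller `n`,
then smaller `n1`, then smaller `r1`.

**Minimax-EF designs** add a stage-1 efficacy boundary `r2` (stop and
reject iff `x1 > r2`; `r2 = n1` recovers Simon's design, which is how the
search's correctness is cross-checked).  The scan again moves upward in `n`
so the returned MSS is minimal by construction, with Simon's minimax MSS as
the default upper bound — guaranteed feasible because the EF space contains
Simon's.  ESS0 ties keep the largest `r1`, then the smallest `r2`, and all
co-optimal designs are logged.

## The adaptive engine

At fixed `(n1, n)` the engine minimises ESS0 over valid monotone schedules.
The candidate alphabet per response count `S` (the omega space) holds the
two stops plus one element per achievable conditional error, i.e. per pair
`(n2, c)` with `0 <= c < n2 <= n - n1`, where `c = r - S`; since the
conditional error depends on `S` only through `c`, one table sorted by
`(n2 ascending, conditional null error ascending)` serves every `S`.  Pairs
with conditional error exactly 0 duplicate the futility stop and are
dropped.

The search sweeps `S = 0, 1, ..., n1` level by level, carrying a set of
partial designs ("labels") holding accumulated type I mass, accumulated
rejection mass at `pi_a`, partial ESS0 cost, and the running cap on the next
`n2` (the monotonicity constraint).  Structure is enforced directly: one
all-futility label per level represents every futility prefix; an efficacy
tail can terminate any started label at any level; under the exact-MSS rule
the first continuation takes `n2 = n - n1`, guaranteeing `MSS = n` while
still letting the maximum recur at later `S`.

Four mechanisms keep the sweep exact but small:

1. **Dominance.**  Two labels at the same level with the same cap are
   comparable: if one is no worse in all three accumulated coordinates it
   can imitate any completion of the other at no extra cost, so the other
   is discarded.  Implemented as a 3-D Pareto filter per cap bucket
   (sort by type I mass, then a power/cost staircase).
2. **Fractional power bound.**  For each level, the achievable (type I
   mass, rejection mass) pairs are reduced to their upper concave hull;
   merging the hulls of all undecided levels by slope gives the concave
   curve `G_s(a)` = the most rejection mass levels `>= s` can contribute
   within type I budget `a`.  A label (or candidate extension) whose
   accumulated power plus `G` cannot reach the target is pruned; at the
   root the same curve certifies infeasibility of a whole `(n1, n)` in
   microseconds.  Because the running cap restricts future candidates, `G`
   is precomputed on a power-of-two ladder of caps and each query uses the
   smallest class covering the label's cap (a sound relaxation).
3. **Lagrangian cost bound.**  Relaxing the power constraint (multiplier
   `lam`) and the type I constraint (multiplier `mu`) makes the completion
   problem separable: any completion from level `s` costs at least
   `M[cap, s] + lam * (power gap) - mu * (remaining alpha)`, where `M` sums
   per-level minima of the reduced cost `n2 b0 - lam ce_a b1 + mu ce_0 b0`
   over candidates plus the efficacy stop (futility being unavailable once
   continuation starts).  The multipliers are fitted once per `(n1, n)` by
   maximising the concave dual on a log grid with local refinement; the
   bound is valid for any non-negative pair, so optimality of the
   multipliers affects only pruning strength.
4. **Beam-seeded incumbent.**  A first pass keeps only the 256 most
   promising labels per level (ranked by the Lagrangian completion
   estimate); it returns a feasible near-optimal schedule whose ESS0 seeds
   the exact pass's incumbent.  Cost pruning is strict (a branch that
   cannot beat the incumbent by more than `1e-9` is cut), so the beam never
   changes the returned optimum — when the exact pass finds nothing
   strictly better, the seed itself is provably optimal.

Every returned schedule is re-validated through the independent evaluator
(structure, error rates, ESS0 agreement to `1e-6`, exact MSS), and the
engine is tested against exhaustive enumeration over all monotone schedules
on a grid of small instances, both with and without the exact-MSS
constraint, including agreement on infeasibility.

A note on ties: equal-ESS0 schedules are pruned rather than enumerated
(the deterministic first optimum in sweep order is returned).  Enumerating
co-optima is exponentially expensive exactly where partial costs stall —
at large `S`, where the null density is vanishingly small.

## Outer drivers

**Minimax adaptive.**  The backward scan starts at the minimax-EF MSS
(feasibility is guaranteed there since the EF design is a monotone adaptive
design) and decreases the target MSS, at each value taking the best
exact-MSS schedule over `n1 = 2 .. MSS - 2` (the single-patient extremes
are excluded as impractical).  The best EF design at exactly that total
size — cheap to compute — seeds the incumbent and serves as the fallback
when branch-and-bound finds nothing strictly better; any `n1` at or above
the incumbent ESS0 is skipped since `ESS0 > n1` always.  The scan stops
after three consecutive infeasible MSS values; the exact-MSS constraint
breaks monotone feasibility in the MSS, which is why a single failure is
not conclusive.

**Optimal adaptive.**  The global ESS0 minimiser with `MSS <= n_upper` is
the best exact-MSS optimum over all MSS values up to the bound (a design
with maximum `m` found under a loose cap is the same object as the
exact-MSS optimum at `m`), computed with one global incumbent seeded by
Simon's optimal design when it fits under the bound.

**Admissible designs.**  Each candidate MSS `m` contributes the Bayes-risk
line `T_m(q) = (m - ESS0_m) q + ESS0_m`, whose slope is positive because
`ESS0 < MSS` always.  Candidates run from the minimax MSS `n_min` up to the
optimal MSS `n_opt`; `n_opt` is located by scanning upward from `n_min`
until the per-MSS optimum fails to improve for three consecutive values
(mirroring the backward rule).  The lower envelope over `q in [0, 1]` is
built by walking intersections from `q = 0` (owned by the optimal design)
to `q = 1` (the minimax design); intersections closer than `1e-9` in `q`
are merged by jumping to the shallowest line, and interval endpoints are
right-closed (assigned to the smaller-`n` design).  Infeasible intermediate
MSS values would simply contribute no line (logged); none occur in the
configurations we compute.

## Numerical choices and degenerate inputs

- All probability sums use scipy's binomial pmf/cdf in double precision;
  the CDF convention handles out-of-range arguments as empty/sure events,
  while the pmf treats them as domain errors.
- The relaxation bounds carry an extra `1e-9` slack before pruning so hull
  and suffix-sum round-off cannot cut a feasible completion.
- Schedules serialised to CSV print stopped rows as `n2 = 0, r = 0`;
  futility and efficacy stops are recovered from their position relative to
  the continuation region (a schedule with no continuation reads back as
  all-futility).  The JSON form embeds the spec and explicit stop kinds.
- An all-futility schedule is evaluable (type I error 0, power 0,
  `ESS0 = n1`) but is never returned by a search, which requires at least
  one continuation point.
- Infeasible `(n1, n)` configurations are results (`BBResult` with no
  design), not exceptions; infeasible *scans* (no design under the stated
  cap) raise an explicit error naming the cap.

## What the tests do and do not show

The oracles are exact rational arithmetic (`fractions`) for the elementary
quantities, unpruned exhaustive enumeration for the searches at small
sizes, published design tables at paper scale, and a seeded Monte-Carlo
simulation of one million trials checking the evaluator's type I error,
power and ESS0 within three standard errors.  Problem sizes were chosen so
the full suite runs in a few minutes on one CPU: the enumeration grid uses
`n1 <= 4, n <= 8`; the ordering/dominance property runs the complete
minimax-adaptive pipeline on eleven specifications with effects of 0.2–0.3
(maximum sample sizes 12–49); the heaviest single computation is the
admissible envelope at `(0.05, 0.1, 0.3, 0.5)`, whose candidate maximum
sizes run from 50 to 63.

These checks validate the *design arithmetic*, not clinical behaviour:
binary responses are assumed exchangeable with a common response
probability, response adjudication is instantaneous (no accrual overlap
between stages), and the trial follows the schedule exactly.  Departures
from those idealisations — response drift, evaluability losses,
over-running the first stage — are outside the model, as is any estimation
of the response rate after the trial stops.

## Known limitations

- Ties in ESS0 between schedules are resolved deterministically but not
  enumerated (see above); EF-level ties are logged in full.
- The optimal adaptive search requires an explicit MSS bound; the ESS0
  sequence over the MSS is not provably unimodal, so the three-value
  stall rule used to locate `n_opt` for the admissible scan is a
  convention (the same one the backward minimax scan uses), not a theorem.
- Runtime grows with the second-stage range (candidate count is
  `O((n - n1)^2)` per level); configurations around `n ~ 100` with 90%
  power remain minutes-scale per MSS value.
- The constrained variant in which all second stages above a clinician
  -chosen response count are equal is not implemented.
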