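# ph2adapt

Exact two-stage design search for single-arm phase II clinical trials with
binary endpoints: Simon's minimax and optimal designs, the minimax-EF design
(stage-1 stopping for futility *or* efficacy), minimax and optimal **adaptive**
designs in which the second-stage size shrinks as first-stage responses grow,
and admissible designs chosen by a Bayes-risk lower envelope.

## The problem

A single-arm phase II trial tests

```
H0: pi <= pi_u     against     Ha: pi >= pi_a
```

where `pi` is the response probability, `pi_u` the unacceptable rate (from
historical controls) and `pi_a` the targeted rate of the new treatment.  A
two-stage design enrols `n1` patients, observes `S` responses, and then stops
for futility, stops for efficacy, or enrols a second cohort, rejecting H0 iff
the total response count `x` exceeds a critical value `r` — all with *exact*
binomial error rates: no normal approximation anywhere.

In Simon's classical designs the second-stage size is one number.  An
adaptive design instead carries a whole schedule `(n2(S), r(S))` for
`S = 0..n1`, built on the conditional error function

```
P(S | r(S), n2(S), pi) = 1 - B(r(S) - S; n2(S), pi)
```

(`B` the binomial CDF), with the exact type I error and power obtained by
weighting these conditional probabilities by the stage-1 binomial density.
For practical use the schedule is constrained to be **monotone**: `n2(S)` is
non-increasing in `S` (more observed responses never demand more follow-up
patients), futility stops form a prefix and efficacy stops a suffix.

Two scalar criteria compete: the expected sample size under the null,
`ESS0 = sum_S (n1 + n2(S)) b(S; n1, pi_u)`, and the maximum sample size,
`MSS = n1 + max_S n2(S)`, which drives budgeting and ethics approval.  The
**minimax adaptive design** minimises MSS first and ESS0 second; it is found
here by a branch-and-bound search over the space of achievable conditional
errors at each `S`, embedded in a backward scan over candidate MSS values
that stops after three consecutive infeasible values.  The **admissible
designs** minimise the Bayes risk `T = q·MSS + (1 − q)·ESS0` for some weight
`q ∈ [0, 1]`; since each candidate contributes a line in `q`, the admissible
set is the lower envelope of those lines, interpolating between the optimal
design (`q → 0`) and the minimax design (`q → 1`).

## Worked example

A urothelial-cancer trial targets 80% power at one-sided alpha = 0.1 for an
improvement from `pi_u = 35%` to `pi_a = 50%`.  Simon's minimax design for
this setting is `(r1/n1, r/n) = (10/31, 21/49)`: stop for futility if 10 or
fewer of 31 first-stage patients respond, otherwise enrol 18 more and claim
activity iff at least 22 of 49 respond.  Its `ESS0` is 40.8 patients.

The minimax adaptive design keeps the same worst case (49 patients) but
spends fewer patients on average:

```
$ ph2adapt adaptive-minimax --alpha 0.1 --beta 0.2 --pi0 0.35 --pi1 0.5
    S  n2(S)  n(S)  r(S)
  <=6      0    21     0
    7     28    49    21
    8     28    49    21
    9     28    49    21
   10     28    49    21
   11     28    49    21
   12     28    49    20
   13     23    44    18
 >=14      0    21     0
type I error = 0.0999   power = 0.8001
ESS0 = 38.89   MSS = 49   PET0 = 0.360   PET(pi_a) = 0.134
```

Read the table as: with 21 first-stage patients, stop for futility at 6 or
fewer responses and for efficacy at 14 or more; in between, enrol a second
cohort whose size shrinks from 28 to 23 as responses accumulate, and reject
H0 iff the total count exceeds `r(S)`.  The design is exactly calibrated
(type I error 0.0999 ≤ 0.1, power 0.8001 ≥ 0.8) and saves about two expected
patients over Simon's minimax design at the same maximum size.  `PET0` is
the probability of stopping at stage 1 under the null.

Other entry points: `ph2adapt simon` / `ef` / `adaptive-optimal --n-upper` /
`admissible` / `evaluate --schedule my_schedule.csv`, each with `--json`,
`--out DIR` (schedule CSV/JSON + metrics) and `--plot` (design-size and
Bayes-risk figures).  The same functionality is available as a library:

```python
from ph2adapt import DesignSpec, find_minimax_adaptive
sel = find_minimax_adaptive(DesignSpec(alpha=0.1, beta=0.2, pi_u=0.35, pi_a=0.5))
sel.mss, round(sel.ess0, 1)   # (49, 38.9)
```

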