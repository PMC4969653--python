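"""Independent oracles used by the test suite.

Everything here is deliberately written without the package's own search or
evaluation code paths: exact rational binomial arithmetic via ``fractions``,
and plain exhaustive enumeration over monotone schedules / boundary tuples.
Slow but unarguable, at the tiny problem sizes the tests use.
"""

from fractions import Fraction
from math import comb

import numpy as np
from scipy.stats import binom as _binom


# ----------------------------------------------------------------------
# exact rational binomial quantities
# ----------------------------------------------------------------------

def frac_pmf(x: int, n: int, p: Fraction) -> Fraction:
    return Fraction(comb(n, x)) * p**x * (1 - p) ** (n - x)


def frac_cdf(x: int, n: int, p: Fraction) -> Fraction:
    if x < 0:
        return Fraction(0)
    if x >= n:
        return Fraction(1)
    return sum(frac_pmf(k, n, p) for k in range(0, x + 1))


def frac_conditional_error(s: int, r_s: int, n2_s: int, p: Fraction) -> Fraction:
    c = r_s - s
    if c < 0:
        return Fraction(1)
    if c >= n2_s:
        return Fraction(0)
    return 1 - frac_cdf(c, n2_s, p)


# ----------------------------------------------------------------------
# exhaustive enumeration over monotone adaptive schedules
# ----------------------------------------------------------------------

def enumerate_monotone_optimum(n1, n, spec, exact_mss, *, allow_non_monotone=False):
    """Minimum ESS0 over all valid schedules at (n1, n) by brute force.

    Returns ``(ess0, schedule)`` where ``schedule`` maps S to None (futility),
    'E' (efficacy) or ``(n2, r)``, or ``None`` when no schedule is feasible.
    ``allow_non_monotone`` widens the space to arbitrary per-S second-stage
    sizes (used to check that the monotone optimum is a constrained optimum).
    """
    n2max = n - n1
    b0 = _binom.pmf(np.arange(n1 + 1), n1, spec.pi_u)
    b1 = _binom.pmf(np.arange(n1 + 1), n1, spec.pi_a)
    sb0 = np.concatenate([np.cumsum(b0[::-1])[::-1], [0.0]])
    sb1 = np.concatenate([np.cumsum(b1[::-1])[::-1], [0.0]])
    # conditional rejection probabilities per (n2, c)
    ce = {}
    for n2 in range(1, n2max + 1):
        for c in range(0, n2):
            ce[(n2, c)] = (
                1.0 - _binom.cdf(c, n2, spec.pi_u),
                1.0 - _binom.cdf(c, n2, spec.pi_a),
            )
    alpha_cap = spec.alpha + 1e-12
    pow_req = 1.0 - spec.beta - 1e-12
    best = [None]

    def leaf(alpha, power, cost, sched, mss_hit):
        if alpha > alpha_cap or power < pow_req:
            return
        if exact_mss and not mss_hit:
            return
        ess0 = n1 + cost
        if best[0] is None or ess0 < best[0][0] - 1e-12:
            best[0] = (ess0, dict(sched))

    def rec(s, alpha, power, cost, cap, started, prefix, sched, mss_hit):
        if s == n1 + 1:
            if started:
                leaf(alpha, power, cost, sched, mss_hit)
            return
        if prefix:
            sched[s] = None
            rec(s + 1, alpha, power, cost, cap, started, True, sched, mss_hit)
        if s > 0:
            if started:
                # efficacy for all remaining S
                for t in range(s, n1 + 1):
                    sched[t] = "E"
                leaf(alpha + sb0[s], power + sb1[s], cost, sched, mss_hit)
            for n2 in range(1, n2max + 1):
                if not allow_non_monotone and n2 > cap:
                    continue
                if exact_mss and not started and n2 != n2max:
                    continue
                for c in range(0, n2):
                    e0, e1 = ce[(n2, c)]
                    sched[s] = (n2, s + c)
                    rec(
                        s + 1,
                        alpha + e0 * b0[s],
                        power + e1 * b1[s],
                        cost + n2 * b0[s],
                        n2,
                        True,
                        False,
                        sched,
                        mss_hit or n2 == n2max,
                    )
        sched.pop(s, None)

    rec(0, 0.0, 0.0, 0.0, n2max, False, True, {}, False)
    return best[0]


# ----------------------------------------------------------------------
# exhaustive Simon / EF searches (no pruning)
# ----------------------------------------------------------------------

def _two_stage_error_rates(n1, r1, r2, n, r, p):
    """P(reject) for futility bound r1, efficacy bound r2 (r2 = n1: none)."""
    n2 = n - n1
    total = 0.0
    for s in range(n1 + 1):
        if s <= r1:
            ce = 0.0
        elif s > r2:
            ce = 1.0
        else:
            c = r - s
            if c < 0:
                ce = 1.0
            elif c >= n2:
                ce = 0.0
            else:
                ce = 1.0 - float(_binom.cdf(c, n2, p))
        total += ce * float(_binom.pmf(s, n1, p))
    return total


def brute_simon(spec, n_max, criterion):
    """Exhaustive Simon search over all (n1, r1, n, r) with n <= n_max."""
    best_key = None
    best = None

    def better(key, ref):
        if ref is None:
            return True
        if key[0] < ref[0] - 1e-12:
            return True
        return abs(key[0] - ref[0]) <= 1e-12 and key[1] < ref[1] - 1e-12

    for n in range(2, n_max + 1):
        for n1 in range(1, n):
            for r1 in range(n1):
                for r in range(r1, n + 1):
                    a = _two_stage_error_rates(n1, r1, n1, n, r, spec.pi_u)
                    if a > spec.alpha + 1e-12:
                        continue
                    # the smallest alpha-admissible r maximises power
                    pw = _two_stage_error_rates(n1, r1, n1, n, r, spec.pi_a)
                    if pw >= 1.0 - spec.beta - 1e-12:
                        ess0 = n1 + (1.0 - float(_binom.cdf(r1, n1, spec.pi_u))) * (n - n1)
                        key = (n, ess0) if criterion == "minimax" else (ess0, n)
                        if better(key, best_key):
                            best_key = key
                            best = ((n1, r1, n, r), ess0)
                    break
    return best
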