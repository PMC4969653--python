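"""Branch-and-bound search for the minimum-ESS0 monotone adaptive design at fixed (n1, n).

The search alphabet for each stage-1 response count ``S`` is the omega space:
the futility stop (conditional error 0), the efficacy stop (conditional error
1), and one element per achievable conditional type I error value, i.e. per
pair ``(n2, c)`` with ``0 <= c < n2 <= n2_max`` where ``c = r - S`` is the
stage-2 critical value.  Because the conditional error ``1 - B(c; n2, pi)``
depends on ``S`` only through the cumulative critical value ``r = S + c``,
a single candidate table is shared by all ``S``.

The search proceeds level by level over ``S = 0, 1, ..., n1`` (futility
forced at ``S = 0``), expanding each partial design with candidates sorted by
``n2`` ascending and conditional null error ascending, and enforces the
design structure directly: futility stops form a prefix, efficacy stops a
suffix, and the second-stage size is non-increasing over the continuation
region (each candidate is restricted to ``n2 <= n2(S-1)``).  Partial designs
that agree on the decided prefix length and the running cap are compared by
their accumulated (type I mass, rejection mass at pi_a, partial ESS0): a
branch dominated in all three coordinates is discarded, since the dominating
branch can imitate any completion at no extra cost.  Three bounds prune the
remaining branches:

* accumulated type I error already exceeds alpha (undecided S contribute 0);
* accumulated rejection mass at pi_a plus an upper bound on what the
  undecided S can still contribute falls short of the power target;
* the partial ESS0 cannot beat the incumbent (undecided S contribute n1 only).

The power bound sharpens the naive "undecided S contribute 1" rule: for each
``S`` the achievable (type I mass, rejection mass at pi_a) pairs are reduced
to their upper concave hull, and the hulls of all undecided levels are merged
into a single concave budget curve G_S(a) = the maximum rejection mass levels
``>= S`` can contribute while spending at most ``a`` of type I error.  G is a
fractional relaxation (it ignores integrality), so it never prunes a feasible
completion, and it doubles as a fast root-level infeasibility certificate for
a whole (n1, n) configuration.  Because the monotonicity constraint caps every
undecided second-stage size at the last chosen one, G is precomputed for a
ladder of cap classes (powers of two); a node is bounded with the smallest
class that covers its current cap, so branches that committed to a small
``n2`` early are bounded by what small-``n2`` continuations (plus stops) can
actually deliver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import List, Optional

import numpy as np
from numba import njit
from scipy.stats import binom as _binom

from .core import (
    FEAS_TOL,
    TIE_TOL,
    AdaptiveDesign,
    DesignError,
    DesignMetrics,
    DesignSpec,
    StageTwoDecision,
    evaluate,
    is_feasible,
)

logger = logging.getLogger("ph2adapt")

#: Extra slack applied to the relaxed power bound before pruning, protecting
#: against round-off in the merged hull cumulative sums.
_BOUND_SLACK = 1e-9


@dataclass(frozen=True)
class OmegaElement:
    """One element of the per-S candidate space: a stop, or a (n2, r) pair."""

    s: int
    n2: int
    r: int
    ce_null: float
    ce_alt: float
    is_stop: str  # "futility" | "efficacy" | "none"


@dataclass
class BBStats:
    """Search statistics for one (n1, n) branch-and-bound run."""

    nodes: int = 0
    pruned_alpha: int = 0
    pruned_power: int = 0
    pruned_cost: int = 0
    dominated: int = 0
    root_pruned: bool = False


@dataclass
class BBResult:
    """Outcome of :func:`bb_search`: the best schedule at (n1, n), if any."""

    design: Optional[AdaptiveDesign]
    metrics: Optional[DesignMetrics]
    ess0: Optional[float]
    stats: BBStats

    @property
    def feasible(self) -> bool:
        return self.design is not None


# ----------------------------------------------------------------------
# candidate space
# ----------------------------------------------------------------------

def _raw_triangle(n2_max: int):
    """All (n2, c) with 0 <= c <= n2 <= n2_max and n2 >= 1 (pre-filter count check)."""
    pairs = [(n2, c) for n2 in range(1, n2_max + 1) for c in range(n2 + 1)]
    return pairs


@lru_cache(maxsize=32)
def _candidate_table(n2_max: int, spec: DesignSpec):
    """Shared continuation-candidate table, sorted by (n2 asc, ce_null asc).

    Returns ``(n2, c, ce0, ce1, gend)`` where ``c = r - S`` is the stage-2
    critical value, only pairs with conditional null error strictly inside
    (0, 1) are kept (``c = n2`` duplicates the futility stop), and
    ``gend[k]`` is the number of candidates with ``n2 <= k``.
    """
    n2_list: List[np.ndarray] = []
    c_list: List[np.ndarray] = []
    ce0_list: List[np.ndarray] = []
    ce1_list: List[np.ndarray] = []
    counts = np.zeros(n2_max + 1, dtype=np.int64)
    for n2 in range(1, n2_max + 1):
        c = np.arange(n2 - 1, -1, -1)  # ce_null ascending
        ce0 = 1.0 - _binom.cdf(c, n2, spec.pi_u)
        ce1 = 1.0 - _binom.cdf(c, n2, spec.pi_a)
        # drop duplicate (ce_null, ce_alt) pairs, keeping the smallest r
        if len(c) > 1:
            keep = np.ones(len(c), dtype=bool)
            same = (np.diff(ce0) == 0.0) & (np.diff(ce1) == 0.0)
            # of two adjacent duplicates keep the smaller c (later in the
            # descending-c ordering)
            keep[:-1][same] = False
            c, ce0, ce1 = c[keep], ce0[keep], ce1[keep]
        n2_list.append(np.full(len(c), n2, dtype=np.int64))
        c_list.append(c.astype(np.int64))
        ce0_list.append(ce0)
        ce1_list.append(ce1)
        counts[n2] = len(c)
    gend = np.cumsum(counts)
    return (
        np.concatenate(n2_list),
        np.concatenate(c_list),
        np.concatenate(ce0_list),
        np.concatenate(ce1_list),
        gend,
    )


def build_omega(n1: int, n2_max: int, spec: DesignSpec) -> List[List[OmegaElement]]:
    """Per-S candidate lists: futility, efficacy, then sorted (n2, r) elements.

    ``S = 0`` holds the futility element only (the trial always stops with no
    responses).  For the remaining ``S`` the continuation elements are the
    shared table re-expressed with the cumulative critical value ``r = S + c``.
    """
    if n2_max < 1:
        raise DesignError("n2_max must be >= 1")
    cn2, cc, ce0, ce1, _ = _candidate_table(n2_max, spec)
    omega: List[List[OmegaElement]] = []
    for s in range(n1 + 1):
        elems = [OmegaElement(s, 0, 0, 0.0, 0.0, "futility")]
        if s > 0:
            elems.append(OmegaElement(s, 0, 0, 1.0, 1.0, "efficacy"))
            elems.extend(
                OmegaElement(s, int(n2), s + int(c), float(a), float(b), "none")
                for n2, c, a, b in zip(cn2, cc, ce0, ce1)
            )
        omega.append(elems)
    return omega


# ----------------------------------------------------------------------
# relaxed power bound: merged upper concave hulls
# ----------------------------------------------------------------------

def _upper_hull_segments(x: np.ndarray, y: np.ndarray):
    """Segments (dx, dy) of the upper concave hull of {(0,0)} U points."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    hull_x = [0.0]
    hull_y = [0.0]
    for px, py in zip(xs, ys):
        if px <= 0.0:
            continue
        while len(hull_x) >= 2:
            cross = (hull_x[-1] - hull_x[-2]) * (py - hull_y[-2]) - (
                hull_y[-1] - hull_y[-2]
            ) * (px - hull_x[-2])
            if cross >= 0.0:
                hull_x.pop()
                hull_y.pop()
            else:
                break
        # keep only points not dominated from above by the current last edge
        if len(hull_x) >= 1 and px == hull_x[-1]:
            if py > hull_y[-1]:
                hull_x[-1], hull_y[-1] = px, py
            continue
        hull_x.append(px)
        hull_y.append(py)
    hx = np.asarray(hull_x)
    hy = np.asarray(hull_y)
    dx = np.diff(hx)
    dy = np.diff(hy)
    pos = (dx > 0) & (dy > 0)  # non-improving segments are never taken
    return dx[pos], dy[pos]


def _cap_classes(n2_max: int) -> np.ndarray:
    """Power-of-two cap ladder 1, 2, 4, ... covering n2_max."""
    caps = [1]
    while caps[-1] < n2_max:
        caps.append(min(caps[-1] * 2, n2_max))
    return np.asarray(caps, dtype=np.int64)


@lru_cache(maxsize=16)
def _bound_arrays(n1: int, n2_max: int, spec: DesignSpec):
    """Cap-classed, suffix-merged concave budget curves G_{c,s} (flattened).

    For each cap class ``c`` (a power-of-two ladder covering ``1..n2_max``)
    and each suffix start ``s``, the hull segments of levels
    ``max(s, 1)..n1`` — built from continuation candidates with ``n2 <= c``
    plus the efficacy stop — are merged by slope descending into cumulative
    spent type I mass ``gx``, cumulative rejection mass ``gy`` and
    per-segment slopes.  Level 0 contributes nothing (futility is forced
    there).  Bounding a node whose running cap is ``k`` with the smallest
    class ``>= k`` keeps the relaxation sound while staying cap-aware.

    Returns ``(capcls, goff, gx, gy, gslope)`` where ``capcls[k]`` maps a cap
    to its class row and ``goff`` has shape ``(n_classes, n1 + 3)``.
    """
    cn2, cc, ce0, ce1, gend = _candidate_table(n2_max, spec)
    caps = _cap_classes(n2_max)
    capcls = np.zeros(n2_max + 1, dtype=np.int64)
    for k in range(1, n2_max + 1):
        capcls[k] = int(np.searchsorted(caps, k))
    sgrid = np.arange(n1 + 1)
    b0 = _binom.pmf(sgrid, n1, spec.pi_u)
    b1 = _binom.pmf(sgrid, n1, spec.pi_a)
    n_cls = len(caps)
    goff = np.zeros((n_cls, n1 + 3), dtype=np.int64)
    gx_parts, gy_parts, gs_parts = [], [], []
    total = 0
    for ci, cap in enumerate(caps):
        hi = int(gend[cap])
        # dedupe (ce0, ce1) pairs within the capped candidate set
        pts = np.unique(np.column_stack([ce0[:hi], ce1[:hi]]), axis=0)
        level_dx = [np.empty(0)] * (n1 + 1)
        level_dy = [np.empty(0)] * (n1 + 1)
        for s in range(1, n1 + 1):
            x = np.append(pts[:, 0] * b0[s], b0[s])  # efficacy point appended
            y = np.append(pts[:, 1] * b1[s], b1[s])
            level_dx[s], level_dy[s] = _upper_hull_segments(x, y)
        for s in range(n1 + 2):
            lo = max(s, 1)
            if lo <= n1:
                dx = np.concatenate(level_dx[lo:])
                dy = np.concatenate(level_dy[lo:])
                slope = dy / dx
                order = np.argsort(-slope, kind="stable")
                gx_parts.append(np.cumsum(dx[order]))
                gy_parts.append(np.cumsum(dy[order]))
                gs_parts.append(slope[order])
                total += len(dx)
            goff[ci, s + 1] = total
        if ci + 1 < n_cls:
            goff[ci + 1, 0] = total
    gx = np.concatenate(gx_parts) if gx_parts else np.empty(0)
    gy = np.concatenate(gy_parts) if gy_parts else np.empty(0)
    gslope = np.concatenate(gs_parts) if gs_parts else np.empty(0)
    return capcls, goff, gx, gy, gslope


@njit(cache=True)
def _gquery(goff, gx, gy, gslope, ci, s, a):
    """G_{ci,s}(a): max rejection mass levels >= s can add with budget a at cap class ci."""
    if a <= 0.0:
        return 0.0
    lo = goff[ci, s]
    hi = goff[ci, s + 1]
    if lo == hi:
        return 0.0
    if a >= gx[hi - 1]:
        return gy[hi - 1]
    i = lo
    j = hi
    while i < j:
        m = (i + j) // 2
        if gx[m] >= a:
            j = m
        else:
            i = m + 1
    x0 = gx[i - 1] if i > lo else 0.0
    y0 = gy[i - 1] if i > lo else 0.0
    return y0 + gslope[i] * (a - x0)


# ----------------------------------------------------------------------
# Lagrangian cost bound
# ----------------------------------------------------------------------

@lru_cache(maxsize=16)
def _lagrange_arrays(n1: int, n2_max: int, spec: DesignSpec):
    """Multipliers and suffix reduced-cost sums for the completion cost bound.

    Relaxing the two coupling constraints (power >= target with multiplier
    ``lam``, type I <= alpha with multiplier ``mu``) makes the problem
    separable over levels: any completion of a partial design from level
    ``s`` onwards costs at least

        M[cls, s] + lam * (power still missing) - mu * (alpha still unspent),

    where ``M[cls, s]`` sums, over levels ``t >= s``, the smallest reduced
    cost ``n2 b0(t) - lam ce_alt b1(t) + mu ce_null b0(t)`` among the
    continuation candidates admitted by the cap class plus the efficacy stop
    (futility is unavailable once the continuation has started).  The bound
    is valid for every ``lam, mu >= 0``; the pair is chosen by maximising
    the concave root dual on a coarse grid with local refinement.
    """
    cn2, cc, ce0, ce1, gend = _candidate_table(n2_max, spec)
    caps = _cap_classes(n2_max)
    sgrid = np.arange(n1 + 1)
    b0 = _binom.pmf(sgrid, n1, spec.pi_u)
    b1 = _binom.pmf(sgrid, n1, spec.pi_a)
    alpha_max = spec.alpha + FEAS_TOL
    pow_req = spec.power_target - FEAS_TOL
    # per-level candidate triples (cost, power mass, type I mass); level 0 excluded
    W = np.outer(b0[1:], cn2.astype(np.float64))
    P = np.outer(b1[1:], ce1)
    A = np.outer(b0[1:], ce0)
    eff_p = b1[1:]
    eff_a = b0[1:]

    def dual(lam: float, mu: float) -> float:
        red = W - lam * P + mu * A
        rm = np.minimum(red.min(axis=1), mu * eff_a - lam * eff_p)
        # the root state may still stop for futility (reduced cost 0)
        return float(np.minimum(rm, 0.0).sum() + lam * pow_req - mu * alpha_max)

    grid = np.concatenate([[0.0], np.logspace(-1.0, 3.0, 17)])
    lam_best, mu_best, v_best = 0.0, 0.0, dual(0.0, 0.0)
    for lam in grid:
        for mu in grid:
            v = dual(lam, mu)
            if v > v_best:
                lam_best, mu_best, v_best = float(lam), float(mu), v
    for step in (1.6, 1.3, 1.15, 1.07, 1.03):
        improved = True
        while improved:
            improved = False
            for lam in (lam_best * step, lam_best / step, lam_best):
                for mu in (mu_best * step, mu_best / step, mu_best):
                    v = dual(lam, mu)
                    if v > v_best + 1e-12:
                        lam_best, mu_best, v_best = lam, mu, v
                        improved = True
    lam, mu = lam_best, mu_best
    red = W - lam * P + mu * A
    cmin = np.minimum.accumulate(red, axis=1)
    row_eff = mu * eff_a - lam * eff_p
    n_cls = len(caps)
    mlag = np.zeros((n_cls, n1 + 3))
    for ci, cap in enumerate(caps):
        level_min = np.minimum(cmin[:, gend[cap] - 1], row_eff)
        # mlag[ci, s] = sum over levels t = s..n1 (levels are offset by 1 in W)
        suffix = np.concatenate([np.cumsum(level_min[::-1])[::-1], [0.0, 0.0]])
        mlag[ci, 1:] = suffix
        mlag[ci, 0] = suffix[0]
    return lam, mu, mlag


# ----------------------------------------------------------------------
# the branch-and-bound kernel: level-synchronous search with dominance
# ----------------------------------------------------------------------

@njit(cache=True)
def _grow_f(a, newcap):
    b = np.empty(newcap, np.float64)
    b[: a.shape[0]] = a
    return b


@njit(cache=True)
def _grow_i(a, newcap):
    b = np.empty(newcap, np.int64)
    b[: a.shape[0]] = a
    return b


@njit(cache=True)
def _bb_kernel(
    n1,
    n2max,
    exact_mss,
    constant_n2,
    b0,
    b1,
    sb0,
    sb1,
    cn2,
    cce0,
    cce1,
    gend,
    capcls,
    goff,
    gx,
    gy,
    gslope,
    lam,
    mu,
    mlag,
    alpha_max,
    pow_req,
    incumbent_cost,
    beam,
):
    """Sweep the levels S = 1..n1 in order, carrying a set of partial-design
    labels (type I mass, rejection mass at pi_a, partial cost) per running
    second-stage cap.  A label whose three coordinates are all no better than
    another label's at the same cap cannot lead to a better schedule and is
    discarded (the dominating label can imitate any completion).  Terminal
    checks (stop for efficacy from S on; complete schedule at S = n1 + 1)
    update the incumbent before the level is expanded.  ``beam > 0`` turns
    the sweep into a heuristic that keeps only the ``beam`` most promising
    labels per level (by Lagrangian completion estimate); the result is then
    a feasible schedule used as an incumbent for the exact pass."""
    L = n1 + 1
    TIE = 1e-9
    EPS = 1e-9

    # global trace of kept labels, for schedule reconstruction
    g_capacity = 1024
    g_parent = np.empty(g_capacity, np.int64)
    g_choice = np.empty(g_capacity, np.int64)  # >= 0 candidate index, -1 futility
    g_parent[0] = -1
    g_choice[0] = -1  # forced futility at S = 0
    g_size = 1

    # labels entering the current level (continuation already started)
    m = 0
    c_al = np.empty(0, np.float64)
    c_pw = np.empty(0, np.float64)
    c_ct = np.empty(0, np.float64)
    c_cap = np.empty(0, np.int64)
    c_id = np.empty(0, np.int64)
    prefix_alive = 1
    prefix_id = 0

    best_cost = incumbent_cost
    best_id = -1
    best_eff = -1
    found = 0
    nodes = 0
    pr_a = 0
    pr_b = 0
    pr_c = 0
    pr_d = 0

    for s in range(1, L + 1):
        nodes += m + prefix_alive
        # ---- terminals ------------------------------------------------
        if s == L:
            for i in range(m):
                if c_pw[i] >= pow_req and c_ct[i] < best_cost - TIE:
                    best_cost = c_ct[i]
                    best_id = c_id[i]
                    best_eff = L
                    found = 1
            break
        for i in range(m):
            # stop for efficacy from S = s onwards
            if c_al[i] + sb0[s] <= alpha_max and c_pw[i] + sb1[s] >= pow_req:
                if c_ct[i] < best_cost - TIE:
                    best_cost = c_ct[i]
                    best_id = c_id[i]
                    best_eff = s
                    found = 1
        # ---- expansions -----------------------------------------------
        t_capacity = 4096
        t_al = np.empty(t_capacity, np.float64)
        t_pw = np.empty(t_capacity, np.float64)
        t_ct = np.empty(t_capacity, np.float64)
        t_cap = np.empty(t_capacity, np.int64)
        t_par = np.empty(t_capacity, np.int64)
        t_cho = np.empty(t_capacity, np.int64)
        t_n = 0
        for i in range(-1, m):
            if i < 0:
                # the all-futility prefix label opens the continuation here
                if prefix_alive == 0:
                    continue
                al = 0.0
                pw = 0.0
                ct = 0.0
                par = prefix_id
                if constant_n2 == 1 or exact_mss == 1:
                    lo = gend[n2max - 1]
                else:
                    lo = 0
                hi = gend[n2max]
            else:
                al = c_al[i]
                pw = c_pw[i]
                ct = c_ct[i]
                par = c_id[i]
                gb = _gquery(
                    goff, gx, gy, gslope, capcls[c_cap[i]], s, alpha_max - al
                )
                if pw + gb < pow_req - EPS:
                    pr_b += 1
                    continue
                lb = (
                    ct
                    + mlag[capcls[c_cap[i]], s]
                    + lam * (pow_req - pw)
                    - mu * (alpha_max - al)
                )
                if lb > best_cost - TIE:
                    pr_c += 1
                    continue
                if constant_n2 == 1:
                    lo = gend[n2max - 1]
                    hi = gend[n2max]
                else:
                    lo = 0
                    hi = gend[c_cap[i]]
            idx = lo
            while idx < hi:
                nn2 = cn2[idx]
                nc = ct + nn2 * b0[s]
                if nc >= best_cost - TIE:
                    # groups ascend in n2: no later candidate is cheaper
                    pr_c += 1
                    break
                na = al + cce0[idx] * b0[s]
                if na > alpha_max:
                    # within a group ce_null ascends: skip to the next group
                    pr_a += 1
                    idx = gend[nn2]
                    continue
                npw = pw + cce1[idx] * b1[s]
                gb = _gquery(goff, gx, gy, gslope, capcls[nn2], s + 1, alpha_max - na)
                if npw + gb < pow_req - EPS:
                    pr_b += 1
                    idx += 1
                    continue
                lb = (
                    nc
                    + mlag[capcls[nn2], s + 1]
                    + lam * (pow_req - npw)
                    - mu * (alpha_max - na)
                )
                if lb > best_cost - TIE:
                    pr_c += 1
                    idx += 1
                    continue
                if t_n == t_capacity:
                    t_capacity *= 2
                    t_al = _grow_f(t_al, t_capacity)
                    t_pw = _grow_f(t_pw, t_capacity)
                    t_ct = _grow_f(t_ct, t_capacity)
                    t_cap = _grow_i(t_cap, t_capacity)
                    t_par = _grow_i(t_par, t_capacity)
                    t_cho = _grow_i(t_cho, t_capacity)
                t_al[t_n] = na
                t_pw[t_n] = npw
                t_ct[t_n] = nc
                t_cap[t_n] = nn2
                t_par[t_n] = par
                t_cho[t_n] = idx
                t_n += 1
                idx += 1
        # extend the futility prefix (dies once no continuation can follow)
        if prefix_alive == 1:
            if s < n1 and _gquery(
                goff, gx, gy, gslope, capcls[n2max], s + 1, alpha_max
            ) >= pow_req - EPS:
                if g_size == g_capacity:
                    g_capacity *= 2
                    g_parent = _grow_i(g_parent, g_capacity)
                    g_choice = _grow_i(g_choice, g_capacity)
                g_parent[g_size] = prefix_id
                g_choice[g_size] = -1
                prefix_id = g_size
                g_size += 1
            else:
                prefix_alive = 0
        if t_n == 0:
            m = 0
            if prefix_alive == 0:
                break
            c_al = np.empty(0, np.float64)
            c_pw = np.empty(0, np.float64)
            c_ct = np.empty(0, np.float64)
            c_cap = np.empty(0, np.int64)
            c_id = np.empty(0, np.int64)
            continue
        # ---- dominance filter per cap bucket --------------------------
        cnt = np.zeros(n2max + 2, np.int64)
        for j in range(t_n):
            cnt[t_cap[j]] += 1
        off = np.zeros(n2max + 2, np.int64)
        for k in range(1, n2max + 2):
            off[k] = off[k - 1] + cnt[k - 1]
        order = np.empty(t_n, np.int64)
        fill = off.copy()
        for j in range(t_n):
            k = t_cap[j]
            order[fill[k]] = j
            fill[k] += 1
        keep = np.zeros(t_n, np.uint8)
        kept_total = 0
        f_pw = np.empty(t_n, np.float64)
        f_ct = np.empty(t_n, np.float64)
        for k in range(1, n2max + 1):
            blo = off[k]
            bn = cnt[k]
            if bn == 0:
                continue
            akeys = np.empty(bn, np.float64)
            for j in range(bn):
                akeys[j] = t_al[order[blo + j]]
            asort = np.argsort(akeys, kind="mergesort")
            fn = 0  # front of (power, cost), both ascending
            for jj in range(bn):
                j = order[blo + asort[jj]]
                p = t_pw[j]
                cst = t_ct[j]
                # dominated iff a front entry has power >= p and cost <= cst;
                # the cheapest such entry is the first with power >= p
                loi = 0
                hii = fn
                while loi < hii:
                    mid = (loi + hii) // 2
                    if f_pw[mid] >= p:
                        hii = mid
                    else:
                        loi = mid + 1
                if loi < fn and f_ct[loi] <= cst:
                    pr_d += 1
                    continue
                keep[j] = 1
                kept_total += 1
                # evict front entries the new label dominates (a contiguous
                # run with power <= p and cost >= cst), then insert
                rlo = 0
                rhi = loi
                while rlo < rhi:
                    mid = (rlo + rhi) // 2
                    if f_ct[mid] >= cst:
                        rhi = mid
                    else:
                        rlo = mid + 1
                shift = loi - rlo
                if shift > 0:
                    for t in range(loi, fn):
                        f_pw[t - shift] = f_pw[t]
                        f_ct[t - shift] = f_ct[t]
                    fn -= shift
                    loi = rlo
                for t in range(fn, loi, -1):
                    f_pw[t] = f_pw[t - 1]
                    f_ct[t] = f_ct[t - 1]
                f_pw[loi] = p
                f_ct[loi] = cst
                fn += 1
        # ---- beam truncation (heuristic pass only) ---------------------
        if beam > 0 and kept_total > beam:
            sc = np.empty(kept_total, np.float64)
            sidx = np.empty(kept_total, np.int64)
            w = 0
            for pos in range(t_n):
                j = order[pos]
                if keep[j] == 1:
                    sc[w] = (
                        t_ct[j]
                        + mlag[capcls[t_cap[j]], s + 1]
                        + lam * (pow_req - t_pw[j])
                        - mu * (alpha_max - t_al[j])
                    )
                    sidx[w] = j
                    w += 1
            rank = np.argsort(sc, kind="mergesort")
            for w2 in range(beam, kept_total):
                keep[sidx[rank[w2]]] = 0
            kept_total = beam
        # ---- commit survivors -----------------------------------------
        n_al = np.empty(kept_total, np.float64)
        n_pw = np.empty(kept_total, np.float64)
        n_ct = np.empty(kept_total, np.float64)
        n_cap = np.empty(kept_total, np.int64)
        n_id = np.empty(kept_total, np.int64)
        w = 0
        for pos in range(t_n):
            j = order[pos]
            if keep[j] == 1:
                if g_size == g_capacity:
                    g_capacity *= 2
                    g_parent = _grow_i(g_parent, g_capacity)
                    g_choice = _grow_i(g_choice, g_capacity)
                g_parent[g_size] = t_par[j]
                g_choice[g_size] = t_cho[j]
                n_al[w] = t_al[j]
                n_pw[w] = t_pw[j]
                n_ct[w] = t_ct[j]
                n_cap[w] = t_cap[j]
                n_id[w] = g_size
                g_size += 1
                w += 1
        c_al = n_al
        c_pw = n_pw
        c_ct = n_ct
        c_cap = n_cap
        c_id = n_id
        m = kept_total

    return (
        found,
        best_cost,
        best_id,
        best_eff,
        g_parent[:g_size].copy(),
        g_choice[:g_size].copy(),
        nodes,
        pr_a,
        pr_b,
        pr_c,
        pr_d,
    )


# ----------------------------------------------------------------------
# public entry point
# ----------------------------------------------------------------------

def bb_search(
    n1: int,
    n: int,
    spec: DesignSpec,
    *,
    exact_mss: bool = True,
    incumbent_ess0: Optional[float] = None,
    constant_n2: bool = False,
    beam_width: int = 256,
) -> BBResult:
    """Minimum-ESS0 monotone adaptive design at fixed (n1, n).

    Subject to attained type I error <= alpha, power >= 1 - beta, futility
    forced at S = 0, futility prefix / efficacy suffix structure and a
    non-increasing ``n2(S)``.  With ``exact_mss`` the first continuation
    point takes ``n2 = n - n1`` so the maximum sample size is exactly ``n``;
    otherwise ``n`` is only an upper bound.  ``incumbent_ess0`` is an
    exclusive bound: only schedules strictly better (beyond the 1e-9 tie
    tolerance) are reported, which is how outer drivers propagate their
    best-so-far without changing the optimum.  ``constant_n2`` restricts
    every continuation to ``n2 = n - n1`` (the EF-design subspace), used for
    consistency checks.  ``beam_width`` sizes the heuristic first pass that
    seeds the exact pass's incumbent (0 disables it); it never affects the
    returned optimum, only the amount of pruning.

    An infeasible (n1, n) yields ``BBResult(design=None, ...)`` rather than
    an exception.
    """
    if not 2 <= n1 <= n - 2:
        raise DesignError(f"require 2 <= n1 <= n - 2, got n1={n1}, n={n}")
    n2max = n - n1
    cn2, cc, ce0, ce1, gend = _candidate_table(n2max, spec)
    capcls, goff, gx, gy, gslope = _bound_arrays(n1, n2max, spec)
    sgrid = np.arange(n1 + 1)
    b0 = _binom.pmf(sgrid, n1, spec.pi_u)
    b1 = _binom.pmf(sgrid, n1, spec.pi_a)
    sb0 = np.zeros(n1 + 2)
    sb1 = np.zeros(n1 + 2)
    sb0[: n1 + 1] = np.cumsum(b0[::-1])[::-1]
    sb1[: n1 + 1] = np.cumsum(b1[::-1])[::-1]
    alpha_max = spec.alpha + FEAS_TOL
    pow_req = spec.power_target - FEAS_TOL

    stats = BBStats()
    # root certificate: even the fractional relaxation cannot reach the power
    root_bound = _gquery(goff, gx, gy, gslope, capcls[n2max], 1, alpha_max)
    if root_bound < pow_req - _BOUND_SLACK:
        stats.root_pruned = True
        return BBResult(None, None, None, stats)

    incumbent_cost = np.inf if incumbent_ess0 is None else incumbent_ess0 - n1
    lam, mu, mlag = _lagrange_arrays(n1, n2max, spec)
    args = (
        n1,
        n2max,
        1 if exact_mss else 0,
        1 if constant_n2 else 0,
        b0,
        b1,
        sb0,
        sb1,
        cn2,
        ce0,
        ce1,
        gend,
        capcls,
        goff,
        gx,
        gy,
        gslope,
        lam,
        mu,
        mlag,
        alpha_max,
        pow_req,
    )

    def _decode(best_id, best_eff, g_parent, g_choice):
        chain = []
        lid = int(best_id)
        while lid >= 0:
            chain.append(int(g_choice[lid]))
            lid = int(g_parent[lid])
        chain.reverse()
        schedule = []
        for s in range(n1 + 1):
            if s >= best_eff:
                schedule.append(StageTwoDecision.efficacy())
            elif chain[s] == -1:
                schedule.append(StageTwoDecision.futility())
            else:
                code = chain[s]
                schedule.append(
                    StageTwoDecision.cont(int(cn2[code]), s + int(cc[code]))
                )
        return AdaptiveDesign(n1=n1, schedule=tuple(schedule))

    # heuristic pass: a narrow beam finds a near-optimal feasible schedule
    # cheaply, and its ESS0 seeds the incumbent of the exact pass
    best_design = None
    best_cost = incumbent_cost
    if beam_width > 0:
        out = _bb_kernel(*args, incumbent_cost, beam_width)
        if out[0]:
            best_cost = float(out[1])
            best_design = _decode(out[2], out[3], out[4], out[5])
    out = _bb_kernel(*args, best_cost, 0)
    (found, cost, best_id, best_eff, g_parent, g_choice, nodes, pr_a, pr_b, pr_c, pr_d) = out
    stats.nodes = int(nodes)
    stats.pruned_alpha = int(pr_a)
    stats.pruned_power = int(pr_b)
    stats.pruned_cost = int(pr_c)
    stats.dominated = int(pr_d)
    if found:
        best_cost = float(cost)
        best_design = _decode(best_id, best_eff, g_parent, g_choice)
    if best_design is None:
        return BBResult(None, None, None, stats)

    metrics = evaluate(best_design, spec)
    if not is_feasible(metrics, spec):
        raise RuntimeError(
            f"internal error: bb_search(n1={n1}, n={n}) returned an infeasible "
            f"schedule (type1={metrics.type1}, power={metrics.power})"
        )
    if abs(metrics.ess0 - (n1 + best_cost)) > 1e-6:
        raise RuntimeError(
            "internal error: kernel ESS0 disagrees with the exact evaluator "
            f"({n1 + best_cost} vs {metrics.ess0})"
        )
    if exact_mss and metrics.mss != n:
        raise RuntimeError(
            f"internal error: exact-MSS search returned MSS {metrics.mss} != {n}"
        )
    logger.debug(
        "bb_search(n1=%d, n=%d): ESS0=%.4f nodes=%d pruned(alpha=%d, power=%d, "
        "cost=%d, dominated=%d)",
        n1, n, metrics.ess0, stats.nodes, stats.pruned_alpha, stats.pruned_power,
        stats.pruned_cost, stats.dominated,
    )
    return BBResult(best_design, metrics, metrics.ess0, stats)
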