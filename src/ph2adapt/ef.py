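"""Exact search for the minimax-EF design (stage-1 stopping for futility or efficacy).

The Mander-Thompson modification of Simon's design adds an efficacy boundary
``r2`` at stage 1: the trial stops for futility iff ``x1 <= r1``, stops and
rejects H0 iff ``x1 > r2``, and otherwise enrols ``n2 = n - n1`` further
patients, rejecting iff the total count exceeds ``r``.  Setting ``r2 = n1``
recovers futility-only stopping, so the EF design space contains Simon's and
its minimax total size never exceeds Simon's.

Exact error rates:

    alpha = P(X1 > r2 | pi_u) + sum_{s=r1+1}^{r2} b(s; n1, pi_u) [1 - B(r - s; n2, pi_u)]

with the analogous expression for power at ``pi_a``, and

    ESS0 = n1 + P(r1 < X1 <= r2 | pi_u) * n2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import binom as _binom

from .core import (
    FEAS_TOL,
    TIE_TOL,
    AdaptiveDesign,
    DesignError,
    DesignSpec,
    InfeasibleDesignError,
    StageTwoDecision,
    binom_cdf,
    evaluate,
)
from .simon import _conditional_reject_matrix, search_simon

logger = logging.getLogger("ph2adapt")


@dataclass(frozen=True)
class EFDesign:
    """Two-stage design with stage-1 futility and efficacy boundaries.

    Stop for futility iff ``x1 <= r1``; stop and reject iff ``x1 > r2``;
    otherwise continue to ``n`` total patients and reject iff ``x > r``.
    ``r2 = n1`` disables efficacy stopping (Simon's design).
    """

    n1: int
    r1: int
    r2: int
    n: int
    r: int

    def __post_init__(self) -> None:
        if not 1 <= self.n1 < self.n:
            raise DesignError(f"require 1 <= n1 < n, got n1={self.n1}, n={self.n}")
        if not 0 <= self.r1 < self.r2 <= self.n1:
            raise DesignError(
                f"require 0 <= r1 < r2 <= n1, got r1={self.r1}, r2={self.r2}, n1={self.n1}"
            )
        if self.r > self.n:
            raise DesignError(f"require r <= n, got r={self.r}")

    @property
    def n2(self) -> int:
        return self.n - self.n1

    def __str__(self) -> str:
        return f"(({self.r1},{self.r2})/{self.n1}, {self.r}/{self.n})"


def ef_to_adaptive(design: EFDesign) -> AdaptiveDesign:
    """Encode an EF design as an adaptive schedule (constant n2 in the middle)."""
    schedule = []
    for s in range(design.n1 + 1):
        if s <= design.r1:
            schedule.append(StageTwoDecision.futility())
        elif s > design.r2:
            schedule.append(StageTwoDecision.efficacy())
        else:
            schedule.append(StageTwoDecision.cont(design.n2, design.r))
    return AdaptiveDesign(n1=design.n1, schedule=tuple(schedule))


def pet_ef(design: EFDesign, p: float) -> float:
    """Probability of stopping at stage 1 (futility or efficacy) at response rate p."""
    return binom_cdf(design.r1, design.n1, p) + 1.0 - binom_cdf(design.r2, design.n1, p)


def best_ef_at(
    spec: DesignSpec, n1: int, n: int, *, futility_only: bool = False
):
    """Best feasible EF design at fixed ``(n1, n)``; ``(EFDesign, ess0)`` or None.

    All boundary triples (r1, r2, r) are evaluated exactly; for each (r1, r2)
    the smallest alpha-admissible ``r`` maximises power, so feasibility of the
    pair reduces to a single power check.  Ties in ESS0 keep the largest r1,
    then the smallest r2 (all co-optima are logged).
    """
    n2 = n - n1
    alpha_cap = spec.alpha + FEAS_TOL
    power_req = spec.power_target - FEAS_TOL
    s = np.arange(n1 + 1)
    b0 = _binom.pmf(s, n1, spec.pi_u)
    b1 = _binom.pmf(s, n1, spec.pi_a)
    B0 = _binom.cdf(s, n1, spec.pi_u)
    r_grid = np.arange(n + 1)
    ce0 = _conditional_reject_matrix(n1, n2, r_grid, spec.pi_u)
    ce1 = _conditional_reject_matrix(n1, n2, r_grid, spec.pi_a)
    # cum[k, r] = sum_{s <= k} b(s) CE[s, r]
    cum0 = np.cumsum(b0[:, None] * ce0, axis=0)
    cum1 = np.cumsum(b1[:, None] * ce1, axis=0)

    best = None
    best_ess0 = np.inf
    co_optima = []
    r2_values = [n1] if futility_only else range(1, n1 + 1)
    for r2 in r2_values:
        tail0 = 1.0 - B0[r2]  # P(X1 > r2 | pi_u)
        tail1 = 1.0 - float(_binom.cdf(r2, n1, spec.pi_a))
        r1_idx = np.arange(r2)  # r1 = 0..r2-1
        alpha = tail0 + cum0[r2, :][None, :] - cum0[r1_idx, :]
        ok = (alpha <= alpha_cap) & (r_grid[None, :] >= r1_idx[:, None])
        has = ok.any(axis=1)
        if not has.any():
            continue
        rstar = np.argmax(ok, axis=1)
        power = tail1 + cum1[r2, :][None, :] - cum1[r1_idx, :]
        pw = power[r1_idx, rstar]
        feasible = has & (pw >= power_req)
        if not feasible.any():
            continue
        ess0 = n1 + (B0[r2] - B0[r1_idx]) * n2
        for r1 in np.nonzero(feasible)[0]:
            cand_ess0 = float(ess0[r1])
            cand = EFDesign(n1=n1, r1=int(r1), r2=int(r2), n=n, r=int(r_grid[rstar[r1]]))
            if cand_ess0 < best_ess0 - TIE_TOL:
                best, best_ess0 = cand, cand_ess0
                co_optima = [cand]
            elif best is not None and abs(cand_ess0 - best_ess0) <= TIE_TOL:
                co_optima.append(cand)
                # prefer the largest r1, then the smallest r2
                if (cand.r1, -cand.r2) > (best.r1, -best.r2):
                    best = cand
    if best is None:
        return None
    if len(co_optima) > 1:
        logger.warning(
            "EF search at (n1=%d, n=%d): %d co-optimal designs with ESS0=%.6f: %s",
            n1, n, len(co_optima), best_ess0, "; ".join(map(str, co_optima)),
        )
    return best, best_ess0


def best_ef_at_n(spec: DesignSpec, n: int, *, futility_only: bool = False):
    """Best feasible EF design with total size exactly ``n`` over all n1."""
    best = None
    best_ess0 = np.inf
    for n1 in range(1, n):
        result = best_ef_at(spec, n1, n, futility_only=futility_only)
        if result is not None and result[1] < best_ess0 - TIE_TOL:
            best, best_ess0 = result
    if best is None:
        return None
    return best, best_ess0


def search_minimax_ef(
    spec: DesignSpec,
    n_max: Optional[int] = None,
    *,
    futility_only: bool = False,
) -> EFDesign:
    """Exact minimax-EF search: smallest feasible ``n``, then smallest ESS0.

    The scan moves upward in ``n`` so the returned total size is minimal by
    construction.  When ``n_max`` is not given, the MSS of Simon's minimax
    design bounds the scan (the EF space contains Simon's, so feasibility at
    that size is guaranteed).  ``futility_only=True`` pins ``r2 = n1`` and
    reproduces Simon's minimax design.
    """
    if n_max is None:
        n_max = search_simon(spec, "minimax").n
    for n in range(2, n_max + 1):
        result = best_ef_at_n(spec, n, futility_only=futility_only)
        if result is not None:
            design = result[0]
            _check(design, spec)
            return design
    raise InfeasibleDesignError(f"no feasible EF design with n <= {n_max} for {spec}")


def _check(design: EFDesign, spec: DesignSpec) -> None:
    m = evaluate(ef_to_adaptive(design), spec)
    if m.type1 > spec.alpha + FEAS_TOL or m.power < spec.power_target - FEAS_TOL:
        raise RuntimeError(
            f"internal error: returned EF design {design} fails re-validation "
            f"(type1={m.type1}, power={m.power})"
        )


def ef_metrics(design: EFDesign, spec: DesignSpec):
    """Exact operating characteristics via the adaptive-schedule evaluator."""
    return evaluate(ef_to_adaptive(design), spec)
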