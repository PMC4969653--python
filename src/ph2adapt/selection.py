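"""Outer design-selection drivers.

* :func:`find_minimax_adaptive` — backward scan over the maximum sample size,
  starting from the minimax-EF MSS (a guaranteed-feasible upper bound,
  because the EF design is a special case of the monotone adaptive design),
  running the branch-and-bound engine with the exact-MSS constraint at every
  first-stage size, and stopping after three consecutive MSS values with no
  feasible design.
* :func:`find_optimal_adaptive` — global minimum-ESS0 monotone design with
  MSS at most ``n_upper``.
* :func:`admissible_designs` — for each MSS between the minimax and optimal
  MSS, the Bayes risk ``T = q n + (1 - q) ESS0`` is a line in the weight
  ``q``; the lower envelope of those lines partitions [0, 1] into intervals,
  each owned by the design minimising the risk there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .bb import BBStats, bb_search
from .core import (
    TIE_TOL,
    AdaptiveDesign,
    DesignError,
    DesignMetrics,
    DesignSpec,
    InfeasibleDesignError,
    evaluate,
)
from .ef import best_ef_at_n, ef_to_adaptive, search_minimax_ef
from .simon import search_simon, simon_to_adaptive

logger = logging.getLogger("ph2adapt")

#: The backward MSS scan stops after this many consecutive infeasible values.
CONSECUTIVE_FAILURES = 3

#: Hard cap on the upward scan for the optimal MSS in admissible_designs.
_ADMISSIBLE_SCAN_CAP = 100


@dataclass
class SelectedDesign:
    """A design chosen by an outer driver, with its exact metrics."""

    design: AdaptiveDesign
    metrics: DesignMetrics
    stats: BBStats = field(default_factory=BBStats)

    @property
    def ess0(self) -> float:
        return self.metrics.ess0

    @property
    def mss(self) -> int:
        return self.metrics.mss


@dataclass(frozen=True)
class AdmissibleEntry:
    """One interval of the Bayes-risk lower envelope.

    The design with maximum sample size ``n`` and null expected size ``ess0``
    minimises ``T(q) = q n + (1 - q) ess0`` for all ``q`` in
    ``[q_lo, q_hi]``.
    """

    q_lo: float
    q_hi: float
    n: int
    ess0: float
    design: AdaptiveDesign


def _accumulate(total: BBStats, part: BBStats) -> None:
    total.nodes += part.nodes
    total.pruned_alpha += part.pruned_alpha
    total.pruned_power += part.pruned_power
    total.pruned_cost += part.pruned_cost


def _best_at_mss(spec: DesignSpec, m: int, stats: Optional[BBStats] = None):
    """Minimum-ESS0 monotone design with MSS exactly ``m`` (or None).

    The best EF design at total size exactly ``m`` (cheap, vectorised) seeds
    the incumbent; it is itself a member of the search space, so it doubles
    as a feasibility witness when the branch-and-bound finds nothing
    strictly better.  First-stage sizes run over ``2 .. m - 2`` ascending;
    any ``n1 >= incumbent ESS0`` cannot improve (ESS0 > n1 always) and ends
    the scan.
    """
    best_design: Optional[AdaptiveDesign] = None
    best_metrics: Optional[DesignMetrics] = None
    best_ess0 = np.inf
    ef_seed = best_ef_at_n(spec, m)
    if ef_seed is not None:
        best_design = ef_to_adaptive(ef_seed[0])
        best_metrics = evaluate(best_design, spec)
        best_ess0 = best_metrics.ess0
    for n1 in range(2, m - 1):
        if best_ess0 - n1 <= TIE_TOL:
            break
        incumbent = None if not np.isfinite(best_ess0) else best_ess0
        res = bb_search(n1, m, spec, exact_mss=True, incumbent_ess0=incumbent)
        if stats is not None:
            _accumulate(stats, res.stats)
        if res.feasible and res.ess0 < best_ess0 - TIE_TOL:
            best_design, best_metrics, best_ess0 = res.design, res.metrics, res.ess0
    if best_design is None:
        return None
    return SelectedDesign(best_design, best_metrics)


def find_minimax_adaptive(spec: DesignSpec) -> SelectedDesign:
    """The minimax adaptive design: smallest feasible MSS, then smallest ESS0.

    Starts at the minimax-EF MSS and decreases the target MSS until
    :data:`CONSECUTIVE_FAILURES` consecutive values admit no feasible
    monotone schedule; the design at the smallest feasible MSS is returned.
    """
    ef_design = search_minimax_ef(spec)
    n_t = ef_design.n
    stats = BBStats()
    per_mss: Dict[int, Optional[SelectedDesign]] = {}
    m = n_t
    failures = 0
    while failures < CONSECUTIVE_FAILURES and m >= 4:
        best = _best_at_mss(spec, m, stats)
        per_mss[m] = best
        if best is None:
            failures += 1
            logger.info("minimax-adaptive scan: MSS=%d infeasible (%d consecutive)", m, failures)
        else:
            failures = 0
            logger.info("minimax-adaptive scan: MSS=%d feasible, ESS0=%.4f (n1=%d)",
                        m, best.ess0, best.design.n1)
        m -= 1
    feasible_mss = sorted(k for k, v in per_mss.items() if v is not None)
    if not feasible_mss:
        raise InfeasibleDesignError(
            f"no feasible adaptive design found in the backward scan from MSS={n_t}"
        )
    chosen = per_mss[feasible_mss[0]]
    chosen.stats = stats
    logger.info(
        "minimax adaptive design: MSS=%d, n1=%d, ESS0=%.4f (nodes=%d)",
        chosen.mss, chosen.design.n1, chosen.ess0, stats.nodes,
    )
    # stash the per-MSS table for reuse (admissible envelope)
    chosen.per_mss = per_mss  # type: ignore[attr-defined]
    return chosen


def find_optimal_adaptive(spec: DesignSpec, n_upper: int) -> SelectedDesign:
    """Global minimum-ESS0 monotone adaptive design with MSS <= ``n_upper``.

    Decomposed as the best exact-MSS optimum over all MSS values up to the
    bound, carrying the global best-so-far as the incumbent; Simon's optimal
    design (when it fits under the bound) seeds the incumbent since it is a
    member of the monotone adaptive space.
    """
    if n_upper < 4:
        raise DesignError("n_upper must be >= 4")
    stats = BBStats()
    best_design: Optional[AdaptiveDesign] = None
    best_metrics: Optional[DesignMetrics] = None
    best_ess0 = np.inf
    try:
        simon_opt = search_simon(spec, "optimal", n_max=n_upper)
        best_design = simon_to_adaptive(simon_opt)
        best_metrics = evaluate(best_design, spec)
        best_ess0 = best_metrics.ess0
    except InfeasibleDesignError:
        pass
    for m in range(4, n_upper + 1):
        for n1 in range(2, m - 1):
            if best_ess0 - n1 <= TIE_TOL:
                break
            incumbent = None if not np.isfinite(best_ess0) else best_ess0
            res = bb_search(n1, m, spec, exact_mss=True, incumbent_ess0=incumbent)
            _accumulate(stats, res.stats)
            if res.feasible and res.ess0 < best_ess0 - TIE_TOL:
                best_design, best_metrics, best_ess0 = res.design, res.metrics, res.ess0
    if best_design is None:
        raise InfeasibleDesignError(
            f"no feasible adaptive design with MSS <= {n_upper} for {spec}"
        )
    out = SelectedDesign(best_design, best_metrics, stats)
    logger.info(
        "optimal adaptive design: MSS=%d, n1=%d, ESS0=%.4f (nodes=%d)",
        out.mss, out.design.n1, out.ess0, stats.nodes,
    )
    return out


# ----------------------------------------------------------------------
# admissible designs: lower envelope of Bayes-risk lines
# ----------------------------------------------------------------------

def lower_envelope(lines: List[Tuple[float, float, object]]) -> List[Tuple[float, float, object]]:
    """Lower envelope over q in [0, 1] of lines ``value = intercept + slope q``.

    ``lines`` holds ``(slope, intercept, payload)``; returns
    ``(q_lo, q_hi, payload)`` intervals partitioning [0, 1].  Intersections
    closer than 1e-9 in q are merged by jumping directly to the shallowest
    of the nearly-tied lines.
    """
    if not lines:
        raise DesignError("lower_envelope requires at least one line")
    # line minimal at q = 0: smallest intercept, tie-break smaller slope
    current = min(lines, key=lambda L: (L[1], L[0]))
    q = 0.0
    entries = []
    while True:
        # earliest q > current position where some shallower line takes over
        best_q = np.inf
        nxt = None
        for slope, intercept, payload in lines:
            if slope >= current[0] - 1e-15:
                continue
            qi = (intercept - current[1]) / (current[0] - slope)
            if qi <= q + 1e-12 or qi >= 1.0:
                continue
            if qi < best_q - 1e-9:
                best_q = qi
                nxt = (slope, intercept, payload)
            elif qi <= best_q + 1e-9 and slope < nxt[0]:
                # near-tied intersection: merge, keeping the shallowest line
                nxt = (slope, intercept, payload)
        if nxt is None:
            entries.append((q, 1.0, current[2]))
            return entries
        entries.append((q, best_q, current[2]))
        q = best_q
        current = nxt


def admissible_designs(
    spec: DesignSpec,
    *,
    n_upper: Optional[int] = None,
    minimax: Optional[SelectedDesign] = None,
) -> List[AdmissibleEntry]:
    """Admissible adaptive designs via the Bayes-risk lower envelope.

    The candidate MSS values run from the minimax adaptive MSS ``n_min`` to
    the optimal adaptive MSS ``n_opt``; for each the minimum-ESS0 design with
    exactly that MSS contributes the line ``T(q) = (n - ESS0) q + ESS0``.
    ``n_opt`` is located by scanning the MSS upward from ``n_min`` until the
    exact-MSS optimum fails to improve for three consecutive values (mirroring
    the backward stopping rule of the minimax scan); ``n_upper``, when given,
    caps that scan.  A precomputed minimax result can be passed to avoid
    re-running the backward scan.
    """
    mm = minimax if minimax is not None else find_minimax_adaptive(spec)
    n_min = mm.mss
    per_mss: Dict[int, SelectedDesign] = {n_min: mm}
    cap = n_upper if n_upper is not None else n_min + _ADMISSIBLE_SCAN_CAP
    best_e = mm.ess0
    stall = 0
    m = n_min + 1
    while stall < CONSECUTIVE_FAILURES and m <= cap:
        best = _best_at_mss(spec, m)
        if best is None:
            stall += 1
            logger.info("admissible scan: MSS=%d infeasible", m)
        else:
            per_mss[m] = best
            if best.ess0 < best_e - TIE_TOL:
                best_e = best.ess0
                stall = 0
            else:
                stall += 1
            logger.info("admissible scan: MSS=%d ESS0=%.4f", m, best.ess0)
        m += 1
    n_opt = min(m for m, d in per_mss.items() if abs(d.ess0 - best_e) <= TIE_TOL)
    candidates = {m: d for m, d in per_mss.items() if n_min <= m <= n_opt}
    logger.info(
        "admissible candidates: n_min=%d, n_opt=%d (%d lines)", n_min, n_opt, len(candidates)
    )
    lines = [(m - d.ess0, d.ess0, (m, d)) for m, d in sorted(candidates.items())]
    # diagnostic: pairwise intersections inside (0, 1)
    inside = 0
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            s1, e1, _ = lines[i]
            s2, e2, _ = lines[j]
            if s1 != s2:
                qi = (e2 - e1) / (s1 - s2)
                if 0.0 < qi < 1.0:
                    inside += 1
    logger.info("admissible envelope: %d of %d pairwise intersections inside (0, 1)",
                inside, len(lines) * (len(lines) - 1) // 2)
    entries = []
    for q_lo, q_hi, (m, d) in lower_envelope(lines):
        entries.append(AdmissibleEntry(q_lo=q_lo, q_hi=q_hi, n=m, ess0=d.ess0, design=d.design))
    return entries
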