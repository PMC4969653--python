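"""Exact binomial machinery for two-stage single-arm trial designs.

A two-stage design for testing ``H0: pi <= pi_u`` against ``Ha: pi >= pi_a``
enrols ``n1`` patients, observes ``S`` responses, and then either stops
(for futility or for efficacy) or enrols a second cohort of ``n2(S)``
patients, rejecting H0 at the end iff the cumulative response count exceeds
the critical value ``r(S)``.  Everything in this package is built on the
conditional error function

    P(s | r(s), n2(s), pi) = 1 - B(r(s) - s; n2(s), pi),

the probability of rejecting H0 after stage 2 given ``s`` first-stage
responses, where ``B`` is the binomial CDF.  Exact type I error, power,
expected sample size under the null (ESS0) and probabilities of early
termination (PET) are sums of these conditional quantities weighted by the
stage-1 binomial density.

This module holds the shared domain types (:class:`DesignSpec`,
:class:`AdaptiveDesign`, :class:`DesignMetrics`), the exact evaluator, and
the schedule serialisation used by every search in the package.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy.stats import binom as _binom

logger = logging.getLogger("ph2adapt")

#: Conservative slack when comparing attained error rates against nominal
#: bounds: a design is feasible only if type I <= alpha + FEAS_TOL and
#: type II <= beta + FEAS_TOL.  Tightening (never loosening) the nominal
#: constraint keeps double-precision round-off from admitting designs whose
#: exact error rate sits on the wrong side of the bound.
FEAS_TOL = 1e-12

#: ESS0 values closer than this are treated as tied by the searches.
TIE_TOL = 1e-9


class DesignError(ValueError):
    """A design or design specification violates one of its invariants."""


class InfeasibleDesignError(RuntimeError):
    """No design satisfying the error-rate constraints exists in the searched range."""


@dataclass(frozen=True)
class DesignSpec:
    """The four-parameter testing problem (alpha, beta, pi_u, pi_a).

    alpha : nominal type I error bound at the unacceptable rate ``pi_u``
    beta  : nominal type II error bound at the acceptable rate ``pi_a``
    pi_u  : unacceptable (null) response rate
    pi_a  : acceptable (target) response rate, ``pi_u < pi_a``
    """

    alpha: float
    beta: float
    pi_u: float
    pi_a: float

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise DesignError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (0.0 < self.beta < 1.0):
            raise DesignError(f"beta must be in (0, 1), got {self.beta}")
        if not (0.0 < self.pi_u < self.pi_a < 1.0):
            raise DesignError(
                f"response rates must satisfy 0 < pi_u < pi_a < 1, "
                f"got pi_u={self.pi_u}, pi_a={self.pi_a}"
            )

    @property
    def power_target(self) -> float:
        return 1.0 - self.beta

    def as_dict(self) -> dict:
        return {"alpha": self.alpha, "beta": self.beta, "pi_u": self.pi_u, "pi_a": self.pi_a}


class StopKind(Enum):
    """Stage-2 action taken after observing the stage-1 response count."""

    FUTILITY_STOP = "futility"
    EFFICACY_STOP = "efficacy"
    CONTINUE = "continue"


@dataclass(frozen=True)
class StageTwoDecision:
    """Stage-2 action for one stage-1 response count ``S``.

    For ``CONTINUE``, ``n2`` is the second-stage cohort size and ``r`` the
    critical value on the *cumulative* response count (reject iff x > r).
    Stopped entries carry ``n2 = r = 0``, matching the table convention used
    for serialised schedules.
    """

    kind: StopKind
    n2: int = 0
    r: int = 0

    def __post_init__(self) -> None:
        if self.kind is StopKind.CONTINUE:
            if self.n2 < 1:
                raise DesignError(f"CONTINUE requires n2 >= 1, got n2={self.n2}")
            if self.r < 0:
                raise DesignError(f"CONTINUE requires r >= 0, got r={self.r}")
        else:
            if self.n2 != 0 or self.r != 0:
                raise DesignError("stopped entries must have n2 = 0 and r = 0")

    @classmethod
    def futility(cls) -> "StageTwoDecision":
        return cls(StopKind.FUTILITY_STOP)

    @classmethod
    def efficacy(cls) -> "StageTwoDecision":
        return cls(StopKind.EFFICACY_STOP)

    @classmethod
    def cont(cls, n2: int, r: int) -> "StageTwoDecision":
        return cls(StopKind.CONTINUE, int(n2), int(r))


@dataclass(frozen=True)
class AdaptiveDesign:
    """A monotone adaptive two-stage design: ``n1`` plus one decision per S.

    ``schedule[S]`` is the :class:`StageTwoDecision` taken after observing
    ``S`` stage-1 responses, for ``S = 0, ..., n1``.  Validity requires a
    futility prefix, an efficacy suffix, a forced futility stop at ``S = 0``,
    and a non-increasing second-stage size over the continuation region.
    """

    n1: int
    schedule: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "schedule", tuple(self.schedule))

    # --- structure ----------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`DesignError` naming the first violated invariant."""
        if self.n1 < 1:
            raise DesignError(f"n1 must be >= 1, got {self.n1}")
        if len(self.schedule) != self.n1 + 1:
            raise DesignError(
                f"schedule must define every S in 0..n1: expected {self.n1 + 1} "
                f"entries, got {len(self.schedule)}"
            )
        kinds = [d.kind for d in self.schedule]
        if kinds[0] is not StopKind.FUTILITY_STOP:
            raise DesignError("schedule[0] must be FUTILITY_STOP (trial stops with no responses)")
        # futility indices must form a prefix
        seen_other = False
        for s, k in enumerate(kinds):
            if k is StopKind.FUTILITY_STOP:
                if seen_other:
                    raise DesignError(
                        f"FUTILITY_STOP indices must form a prefix: S={s} stops for "
                        "futility after a non-futility entry"
                    )
            else:
                seen_other = True
        # efficacy indices must form a suffix
        seen_eff = False
        for s, k in enumerate(kinds):
            if k is StopKind.EFFICACY_STOP:
                seen_eff = True
            elif seen_eff:
                raise DesignError(
                    f"EFFICACY_STOP indices must form a suffix: S={s} is "
                    f"{k.value} after an efficacy stop"
                )
        # n2 non-increasing over the continuation region
        prev = None
        for s, d in enumerate(self.schedule):
            if d.kind is StopKind.CONTINUE:
                if prev is not None and d.n2 > prev:
                    raise DesignError(
                        f"n2(S) must be non-increasing over the continuation "
                        f"region: n2({s})={d.n2} exceeds {prev}"
                    )
                prev = d.n2

    @property
    def mss(self) -> int:
        return self.n1 + max((d.n2 for d in self.schedule), default=0)

    @property
    def continue_region(self) -> list:
        return [s for s, d in enumerate(self.schedule) if d.kind is StopKind.CONTINUE]


@dataclass(frozen=True)
class DesignMetrics:
    """Exact operating characteristics of a two-stage design."""

    type1: float
    power: float
    ess0: float
    pet0: float
    pet_a: float
    mss: int

    def as_dict(self) -> dict:
        return {
            "type1": self.type1,
            "power": self.power,
            "ess0": self.ess0,
            "pet0": self.pet0,
            "pet_a": self.pet_a,
            "mss": self.mss,
        }


# ----------------------------------------------------------------------
# elementary binomial quantities
# ----------------------------------------------------------------------

def binom_pmf(x: int, n: int, p: float) -> float:
    """Binomial density C(n, x) p^x (1-p)^(n-x).

    ``x`` outside ``0..n`` is a domain error (unlike the CDF, where
    out-of-range arguments denote empty or sure events).
    """
    if not 0 <= x <= n:
        raise DesignError(f"binom_pmf: x={x} outside 0..{n}")
    if not 0.0 <= p <= 1.0:
        raise DesignError(f"binom_pmf: p={p} outside [0, 1]")
    return float(_binom.pmf(x, n, p))


def binom_cdf(x: int, n: int, p: float) -> float:
    """Binomial CDF P(X <= x); 0 for x < 0 and 1 for x >= n."""
    if n < 0:
        raise DesignError(f"binom_cdf: n={n} must be >= 0")
    if not 0.0 <= p <= 1.0:
        raise DesignError(f"binom_cdf: p={p} outside [0, 1]")
    if x < 0:
        return 0.0
    if x >= n:
        return 1.0
    return float(_binom.cdf(x, n, p))


def conditional_error(s: int, r_s: int, n2_s: int, p: float) -> float:
    """P(reject H0 at end of stage 2 | s stage-1 responses) = 1 - B(r_s - s; n2_s, p).

    Equals 1 when ``r_s - s < 0`` (the boundary is already crossed at the
    interim) and 0 when ``r_s - s >= n2_s`` (the boundary is unreachable
    with ``n2_s`` further patients).
    """
    if s < 0 or n2_s < 0:
        raise DesignError("conditional_error requires s >= 0 and n2_s >= 0")
    c = r_s - s
    if c < 0:
        return 1.0
    if c >= n2_s:
        return 0.0
    return 1.0 - binom_cdf(c, n2_s, p)


# ----------------------------------------------------------------------
# exact evaluation
# ----------------------------------------------------------------------

def _ce_vectors(design: AdaptiveDesign, p: float) -> np.ndarray:
    """Conditional rejection probability at each S (0 futility, 1 efficacy)."""
    ce = np.empty(design.n1 + 1)
    for s, d in enumerate(design.schedule):
        if d.kind is StopKind.FUTILITY_STOP:
            ce[s] = 0.0
        elif d.kind is StopKind.EFFICACY_STOP:
            ce[s] = 1.0
        else:
            ce[s] = conditional_error(s, d.r, d.n2, p)
    return ce


def evaluate(design: AdaptiveDesign, spec: DesignSpec, *, validate: bool = True) -> DesignMetrics:
    """Exact operating characteristics of an adaptive design.

    type1 = sum_s CE(s | pi_u) b(s; n1, pi_u)        (CE = 0 / 1 at stops)
    power = sum_s CE(s | pi_a) b(s; n1, pi_a)
    ess0  = sum_s (n1 + n2(s)) b(s; n1, pi_u)
    pet   = sum over stopped s of b(s; n1, pi)
    mss   = n1 + max_s n2(s)
    """
    if validate:
        design.validate()
    n1 = design.n1
    s = np.arange(n1 + 1)
    b0 = _binom.pmf(s, n1, spec.pi_u)
    b1 = _binom.pmf(s, n1, spec.pi_a)
    ce0 = _ce_vectors(design, spec.pi_u)
    ce1 = _ce_vectors(design, spec.pi_a)
    n2 = np.array([d.n2 for d in design.schedule], dtype=float)
    stopped = np.array([d.kind is not StopKind.CONTINUE for d in design.schedule])
    return DesignMetrics(
        type1=float(np.sum(ce0 * b0)),
        power=float(np.sum(ce1 * b1)),
        ess0=float(np.sum((n1 + n2) * b0)),
        pet0=float(np.sum(b0[stopped])),
        pet_a=float(np.sum(b1[stopped])),
        mss=design.mss,
    )


def is_feasible(metrics: DesignMetrics, spec: DesignSpec) -> bool:
    """Whether attained error rates respect the nominal bounds (conservatively)."""
    return (
        metrics.type1 <= spec.alpha + FEAS_TOL
        and metrics.power >= spec.power_target - FEAS_TOL
    )


# ----------------------------------------------------------------------
# schedule serialisation (columns S, n2, n_total, r)
# ----------------------------------------------------------------------

def schedule_frame(design: AdaptiveDesign) -> pd.DataFrame:
    """Tabular view of a schedule: one row per S with S, n2, n_total, r.

    Stopped rows carry ``n2 = 0``, ``n_total = n1`` and ``r = 0``,
    matching the printed-table convention.
    """
    rows = []
    for s, d in enumerate(design.schedule):
        rows.append(
            {
                "S": s,
                "n2": d.n2,
                "n_total": design.n1 + d.n2,
                "r": d.r,
            }
        )
    return pd.DataFrame(rows)


def write_schedule_csv(design: AdaptiveDesign, path: Union[str, Path]) -> None:
    schedule_frame(design).to_csv(path, index=False)


def read_schedule_csv(path: Union[str, Path]) -> AdaptiveDesign:
    """Read a schedule CSV written by :func:`write_schedule_csv`.

    Stopped rows (``n2 = 0``) are futility stops when they precede the first
    continuation row and efficacy stops when they follow the last one; a
    schedule with no continuation rows is all futility.
    """
    df = pd.read_csv(path)
    required = {"S", "n2", "n_total", "r"}
    if not required.issubset(df.columns):
        raise DesignError(f"schedule file must have columns {sorted(required)}")
    df = df.sort_values("S").reset_index(drop=True)
    cont = df.index[df["n2"] > 0]
    if len(cont):
        n1_vals = (df.loc[cont, "n_total"] - df.loc[cont, "n2"]).unique()
        if len(n1_vals) != 1:
            raise DesignError("inconsistent n_total - n2 across continuation rows")
        n1 = int(n1_vals[0])
    else:
        n1 = int(df["n_total"].iloc[0])
    if list(df["S"]) != list(range(n1 + 1)):
        raise DesignError("schedule must list every S in 0..n1 exactly once")
    first_cont = int(cont.min()) if len(cont) else n1 + 1
    last_cont = int(cont.max()) if len(cont) else -1
    schedule = []
    for s in range(n1 + 1):
        n2 = int(df.loc[s, "n2"])
        if n2 > 0:
            schedule.append(StageTwoDecision.cont(n2, int(df.loc[s, "r"])))
        elif s < first_cont:
            schedule.append(StageTwoDecision.futility())
        elif s > last_cont:
            schedule.append(StageTwoDecision.efficacy())
        else:
            raise DesignError(f"stopped row S={s} inside the continuation region")
    return AdaptiveDesign(n1=n1, schedule=tuple(schedule))


def write_schedule_json(
    design: AdaptiveDesign, spec: DesignSpec, path: Union[str, Path]
) -> None:
    """JSON schedule with the design spec embedded and explicit stop kinds."""
    payload = {
        "spec": spec.as_dict(),
        "n1": design.n1,
        "schedule": [
            {"S": s, "kind": d.kind.value, "n2": d.n2, "r": d.r}
            for s, d in enumerate(design.schedule)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_schedule_json(path: Union[str, Path]):
    """Read a JSON schedule; returns ``(AdaptiveDesign, DesignSpec)``."""
    payload = json.loads(Path(path).read_text())
    spec = DesignSpec(**payload["spec"])
    kinds = {k.value: k for k in StopKind}
    schedule = []
    for row in sorted(payload["schedule"], key=lambda r: r["S"]):
        kind = kinds[row["kind"]]
        if kind is StopKind.CONTINUE:
            schedule.append(StageTwoDecision.cont(row["n2"], row["r"]))
        elif kind is StopKind.FUTILITY_STOP:
            schedule.append(StageTwoDecision.futility())
        else:
            schedule.append(StageTwoDecision.efficacy())
    return AdaptiveDesign(n1=payload["n1"], schedule=tuple(schedule)), spec
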