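"""Exact binomial arithmetic, conditional errors, and the design evaluator."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import frac_cdf, frac_conditional_error, frac_pmf
from ph2adapt import (
    AdaptiveDesign,
    DesignError,
    DesignSpec,
    StageTwoDecision,
    binom_cdf,
    binom_pmf,
    conditional_error,
    evaluate,
    read_schedule_csv,
    read_schedule_json,
    write_schedule_csv,
    write_schedule_json,
)
from ph2adapt.ef import EFDesign, ef_to_adaptive


class TestBinomial:
    @pytest.mark.parametrize(
        "x, n, p, expected",
        [
            (0, 5, 0.0, 1.0),
            (2, 2, 0.5, 0.25),
            (4, 18, 0.2, float(frac_pmf(4, 18, Fraction(1, 5)))),
            (7, 31, 0.35, float(frac_pmf(7, 31, Fraction(35, 100)))),
        ],
    )
    def test_pmf_matches_rational_oracle(self, x, n, p, expected):
        assert binom_pmf(x, n, p) == pytest.approx(expected, abs=1e-14)

    @pytest.mark.parametrize(
        "x, n, p, expected",
        [
            (-1, 10, 0.3, 0.0),
            (10, 10, 0.3, 1.0),
            (25, 10, 0.3, 1.0),
            (4, 18, 0.2, float(frac_cdf(4, 18, Fraction(1, 5)))),
            (9, 21, 0.35, float(frac_cdf(9, 21, Fraction(35, 100)))),
        ],
    )
    def test_cdf_matches_rational_oracle(self, x, n, p, expected):
        assert binom_cdf(x, n, p) == pytest.approx(expected, abs=1e-14)

    def test_pmf_domain_errors(self):
        with pytest.raises(DesignError):
            binom_pmf(6, 5, 0.3)
        with pytest.raises(DesignError):
            binom_pmf(-1, 5, 0.3)
        with pytest.raises(DesignError):
            binom_pmf(2, 5, 1.5)


class TestConditionalError:
    def test_boundary_cases(self):
        # boundary already crossed at the interim
        assert conditional_error(22, 21, 5, 0.4) == 1.0
        # boundary unreachable with the remaining patients
        assert conditional_error(0, 10, 5, 0.4) == 0.0

    def test_interior_value_matches_rational_oracle(self):
        # the S = 12 row of the urothelial adaptive schedule: (n2, r) = (21, 21)
        want = float(frac_conditional_error(12, 21, 21, Fraction(35, 100)))
        assert conditional_error(12, 21, 21, 0.35) == pytest.approx(want, abs=1e-14)

    @given(
        s=st.integers(0, 15),
        r_s=st.integers(0, 25),
        n2=st.integers(1, 15),
        p_lo=st.floats(0.05, 0.9),
        dp=st.floats(0.01, 0.09),
    )
    def test_monotone_in_p_and_critical_value(self, s, r_s, n2, p_lo, dp):
        lo = conditional_error(s, r_s, n2, p_lo)
        hi = conditional_error(s, r_s, n2, min(p_lo + dp, 1.0))
        assert hi >= lo - 1e-12
        tighter = conditional_error(s, r_s + 1, n2, p_lo)
        assert tighter <= lo + 1e-12


class TestValidation:
    def test_spec_invariants(self):
        with pytest.raises(DesignError):
            DesignSpec(alpha=0.0, beta=0.2, pi_u=0.3, pi_a=0.5)
        with pytest.raises(DesignError):
            DesignSpec(alpha=0.1, beta=0.2, pi_u=0.5, pi_a=0.3)

    def test_stopped_decision_carries_zeros(self):
        with pytest.raises(DesignError):
            StageTwoDecision(kind=StageTwoDecision.futility().kind, n2=3)

    def _design(self, entries):
        return AdaptiveDesign(n1=len(entries) - 1, schedule=tuple(entries))

    def test_schedule_rules_named_in_errors(self):
        F, E = StageTwoDecision.futility, StageTwoDecision.efficacy
        C = StageTwoDecision.cont
        with pytest.raises(DesignError, match="schedule\\[0\\]"):
            self._design([C(3, 2), F(), F(), F()]).validate()
        with pytest.raises(DesignError, match="prefix"):
            self._design([F(), C(3, 2), F(), E()]).validate()
        with pytest.raises(DesignError, match="suffix"):
            self._design([F(), E(), C(3, 2), E()]).validate()
        with pytest.raises(DesignError, match="non-increasing"):
            self._design([F(), C(2, 2), C(3, 3), E()]).validate()
        # a valid schedule passes
        self._design([F(), C(3, 3), C(2, 3), E()]).validate()


def _ef_design_metrics_direct(d: EFDesign, spec: DesignSpec):
    """Two-boundary closed form for an EF design, independent of evaluate()."""
    from scipy.stats import binom

    out = []
    for p in (spec.pi_u, spec.pi_a):
        s = np.arange(d.r1 + 1, d.r2 + 1)
        tail = 1.0 - binom.cdf(d.r2, d.n1, p)
        mid = np.sum(
            binom.pmf(s, d.n1, p) * (1.0 - binom.cdf(np.clip(d.r - s, -1, d.n2), d.n2, p))
        )
        out.append(float(tail + mid))
    return out


class TestEvaluate:
    def test_all_futility_design(self, urothelial):
        n1 = 10
        design = AdaptiveDesign(
            n1=n1, schedule=tuple(StageTwoDecision.futility() for _ in range(n1 + 1))
        )
        m = evaluate(design, urothelial)
        assert m.type1 == 0.0 and m.power == 0.0
        assert m.ess0 == pytest.approx(n1)
        assert m.pet0 == pytest.approx(1.0) and m.pet_a == pytest.approx(1.0)
        assert m.mss == n1

    @given(
        n1=st.integers(4, 20),
        n2=st.integers(2, 20),
        data=st.data(),
    )
    def test_agrees_with_two_boundary_formula(self, urothelial, n1, n2, data):
        r1 = data.draw(st.integers(0, n1 - 2))
        r2 = data.draw(st.integers(r1 + 1, n1))
        r = data.draw(st.integers(r1, n1 + n2))
        d = EFDesign(n1=n1, r1=r1, r2=r2, n=n1 + n2, r=r)
        m = evaluate(ef_to_adaptive(d), urothelial)
        a_direct, pw_direct = _ef_design_metrics_direct(d, urothelial)
        assert m.type1 == pytest.approx(a_direct, abs=1e-12)
        assert m.power == pytest.approx(pw_direct, abs=1e-12)

    @given(n1=st.integers(3, 25), data=st.data())
    def test_stopping_probabilities_normalise(self, urothelial, n1, data):
        from scipy.stats import binom

        k_fut = data.draw(st.integers(0, n1 - 1))
        k_eff = data.draw(st.integers(k_fut + 1, n1))
        sched = []
        for s in range(n1 + 1):
            if s <= k_fut:
                sched.append(StageTwoDecision.futility())
            elif s <= k_eff:
                sched.append(StageTwoDecision.cont(5, s + 2))
            else:
                sched.append(StageTwoDecision.efficacy())
        design = AdaptiveDesign(n1=n1, schedule=tuple(sched))
        m = evaluate(design, urothelial)
        cont_mass = sum(
            float(binom.pmf(s, n1, urothelial.pi_u))
            for s in range(k_fut + 1, k_eff + 1)
        )
        assert m.pet0 + cont_mass == pytest.approx(1.0, abs=1e-12)


class TestScheduleIO:
    def _table1_design(self):
        F, E, C = (
            StageTwoDecision.futility,
            StageTwoDecision.efficacy,
            StageTwoDecision.cont,
        )
        sched = [F()] * 10 + [C(21, 21)] * 4 + [C(19, 20), C(18, 20)] + [E()] * 13
        return AdaptiveDesign(n1=28, schedule=tuple(sched))

    def test_csv_round_trip_metrics_bit_identical(self, tmp_path, urothelial):
        design = self._table1_design()
        path = tmp_path / "sched.csv"
        write_schedule_csv(design, path)
        back = read_schedule_csv(path)
        assert back == design
        m1, m2 = evaluate(design, urothelial), evaluate(back, urothelial)
        assert m1 == m2  # bit-identical, not approximately equal

    def test_json_round_trip_embeds_spec(self, tmp_path, urothelial):
        design = self._table1_design()
        path = tmp_path / "sched.json"
        write_schedule_json(design, urothelial, path)
        back, spec = read_schedule_json(path)
        assert back == design
        assert spec == urothelial

    def test_rejects_gap_in_schedule(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("S,n2,n_total,r\n0,0,4,0\n1,2,6,3\n3,0,4,0\n4,0,4,0\n")
        with pytest.raises(DesignError):
            read_schedule_csv(path)
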