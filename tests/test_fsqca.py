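"""Calibration, necessity, truth tables, minimization, and solutions."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regioncoord import fsqca
from regioncoord.errors import (CalibrationError, DomainError,
                                ValidationError)
from regioncoord.fsqca import (CalibrationAnchors, FuzzyCaseMatrix,
                               build_truth_table, calibrate, derive_solutions,
                               is_necessary, natural_break_pri, necessity_analysis,
                               necessity_metrics, negate, quartile_anchors,
                               quine_mccluskey, robustness_scan,
                               solution_statistics, sufficiency_metrics)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

class TestAnchors:
    def test_quartiles_of_one_to_five(self):
        a = quartile_anchors([1, 2, 3, 4, 5])
        assert (a.full, a.crossover, a.non) == (4.0, 3.0, 2.0)

    def test_constant_values_rejected(self):
        with pytest.raises(CalibrationError):
            quartile_anchors([7.0, 7.0, 7.0, 7.0])

    @given(st.floats(min_value=0.01, max_value=100),
           st.floats(min_value=-50, max_value=50))
    @settings(max_examples=30, deadline=None)
    def test_affine_equivariance(self, scale, shift):
        base = quartile_anchors([1, 2, 3, 4, 5])
        moved = quartile_anchors([scale * v + shift for v in (1, 2, 3, 4, 5)])
        assert moved.full == pytest.approx(scale * base.full + shift, rel=1e-9)
        assert moved.crossover == pytest.approx(
            scale * base.crossover + shift, rel=1e-9)

    def test_misordered_anchors_rejected(self):
        with pytest.raises(CalibrationError):
            CalibrationAnchors(full=1.0, crossover=2.0, non=0.0)


class TestCalibrate:
    anchors = CalibrationAnchors(full=4.0, crossover=3.0, non=2.0)

    def test_anchor_memberships(self):
        m = calibrate([4.0, 2.0], self.anchors)
        assert m[0] == pytest.approx(1 / (1 + math.exp(-3)), abs=1e-9)  # 0.953
        assert m[1] == pytest.approx(1 / (1 + math.exp(3)), abs=1e-9)   # 0.047

    def test_midway_membership(self):
        m = calibrate([3.5], self.anchors)
        assert m[0] == pytest.approx(1 / (1 + math.exp(-1.5)), abs=1e-9)  # 0.8176

    def test_log19_mode_hits_95_and_05(self):
        m = calibrate([4.0, 2.0], self.anchors, scaling="log19")
        assert m[0] == pytest.approx(0.95, abs=1e-9)
        assert m[1] == pytest.approx(0.05, abs=1e-9)

    def test_crossover_tie_adjusted_upward(self):
        with pytest.warns(UserWarning, match="crossover"):
            m = calibrate([3.0], self.anchors)
        assert m[0] == pytest.approx(0.5 + 1e-3)

    def test_strictly_monotone(self):
        xs = np.linspace(-1, 7, 301)  # keeps log-odds inside the clamp
        xs = xs[~np.isclose(xs, 3.0)]  # avoid the tie nudge
        m = calibrate(xs, self.anchors)
        assert (np.diff(m) > 0).all()

    def test_negate_is_involution(self):
        m = np.array([0.047, 0.5 + 1e-3, 0.953])
        np.testing.assert_allclose(negate(negate(m)), m)

    def test_negated_crossover_tie_lands_below_half(self):
        # a tie-adjusted case (0.5+1e-3) negates to 0.5-1e-3: still on one
        # definite side of every truth-table dichotomy
        m = negate([0.5 + 1e-3])
        assert m[0] == pytest.approx(0.5 - 1e-3)
        assert m[0] != 0.5


# ---------------------------------------------------------------------------
# necessity
# ---------------------------------------------------------------------------

class TestNecessity:
    def test_identity_gives_perfect_metrics(self):
        cons, cov = necessity_metrics([0.2, 0.7, 0.9], [0.2, 0.7, 0.9])
        assert cons == 1.0 and cov == 1.0

    def test_worked_example(self):
        cons, cov = necessity_metrics([0.2, 0.8], [0.4, 0.6])
        assert cons == pytest.approx(0.8)
        assert cov == pytest.approx(0.8)

    @pytest.mark.parametrize("cons,cov,expected", [
        (0.989, 0.910, True),    # published bolded decision
        (0.939, 0.321, False),   # coverage below 0.5
        (0.89, 0.95, False),     # consistency below 0.9
    ])
    def test_flagging_rule(self, cons, cov, expected):
        assert is_necessary(cons, cov) is expected

    def test_zero_mass_outcome_reported_undefined(self):
        cons, cov = necessity_metrics([0.5, 0.5], [0.0, 0.0])
        assert math.isnan(cons)

    def test_duality_with_sufficiency(self):
        rng = np.random.Generator(np.random.PCG64(5))
        x, y = rng.uniform(0.01, 0.99, 20), rng.uniform(0.01, 0.99, 20)
        n_cons, n_cov = necessity_metrics(x, y)
        s_cons, s_cov = sufficiency_metrics(y, x)
        assert n_cons == pytest.approx(s_cons)
        assert n_cov == pytest.approx(s_cov)

    def test_analysis_covers_conditions_and_negations(self):
        rng = np.random.Generator(np.random.PCG64(9))
        df = pd.DataFrame(rng.uniform(0.05, 0.95, (12, 3)),
                          columns=["Z6", "Z7", "Y"])
        matrix = FuzzyCaseMatrix(df, ["Z6", "Z7"], "Y")
        res = necessity_analysis(matrix)
        assert set(res["condition"]) == {"Z6", "~Z6", "Z7", "~Z7"}
        assert res["consistency"].between(0, 1).all()


# ---------------------------------------------------------------------------
# truth table
# ---------------------------------------------------------------------------

def _matrix_2cond(rows, outcome="Y"):
    df = pd.DataFrame(rows, columns=["A", "B", outcome],
                      index=[f"c{i}" for i in range(len(rows))])
    return FuzzyCaseMatrix(df, ["A", "B"], outcome)


FOUR_CASES = [(0.9, 0.8, 0.9), (0.9, 0.2, 0.8), (0.1, 0.9, 0.3),
              (0.2, 0.1, 0.1)]


class TestTruthTable:
    def test_each_corner_observed_once_in_four_case_example(self):
        table = build_truth_table(_matrix_2cond(FOUR_CASES),
                                  pri_threshold=0.5)
        by_corner = {r.corner: r for r in table.rows}
        assert all(r.n_cases == 1 for r in table.rows)
        # row A*B: memberships min(.9,.8)=.8, min(.9,.2)=.2, min(.1,.9)=.1,
        # min(.2,.1)=.1 -> sum 1.2; min with y: .8+.2+.1+.1=1.2 -> cons 1
        assert by_corner[(1, 1)].raw_consistency == pytest.approx(1.0)

    def test_case_counts_always_sum_to_n(self):
        rng = np.random.Generator(np.random.PCG64(11))
        df = pd.DataFrame(rng.uniform(0.05, 0.95, (30, 4)),
                          columns=["A", "B", "C", "Y"])
        matrix = FuzzyCaseMatrix(df, ["A", "B", "C"], "Y")
        table = build_truth_table(matrix, pri_threshold=0.6)
        assert sum(r.n_cases for r in table.rows) == 30

    def test_outcome_equal_to_row_membership_is_perfectly_consistent(self):
        # cases sit firmly in corner A*B and the outcome equals their row
        # membership: a perfect subset with consistency 1 and PRI 1
        rows = [(0.9, 0.8, 0.8), (0.8, 0.95, 0.8), (0.7, 0.9, 0.7)]
        table = build_truth_table(_matrix_2cond(rows), pri_threshold=0.5)
        row = {r.corner: r for r in table.rows}[(1, 1)]
        assert row.raw_consistency == pytest.approx(1.0)
        assert row.pri == pytest.approx(1.0)
        assert row.outcome_code == 1

    def test_frequency_threshold_turns_rows_into_remainders(self):
        table = build_truth_table(_matrix_2cond(FOUR_CASES),
                                  freq_threshold=2, pri_threshold=0.5)
        assert all(r.outcome_code == "remainder" for r in table.rows)

    def test_pri_never_exceeds_raw_consistency(self):
        rng = np.random.Generator(np.random.PCG64(23))
        for trial in range(20):
            df = pd.DataFrame(rng.uniform(0.05, 0.95, (15, 4)),
                              columns=["A", "B", "C", "Y"])
            matrix = FuzzyCaseMatrix(df, ["A", "B", "C"], "Y")
            table = build_truth_table(matrix, pri_threshold=0.6)
            for r in table.observed():
                assert r.pri <= r.raw_consistency + 1e-12

    def test_condition_guard(self):
        df = pd.DataFrame(np.full((3, 14), 0.6),
                          columns=[f"Z{i}" for i in range(13)] + ["Y"])
        matrix = FuzzyCaseMatrix(df, [f"Z{i}" for i in range(13)], "Y")
        with pytest.raises(ValidationError, match="guard"):
            build_truth_table(matrix)


class TestNaturalBreak:
    def test_largest_gap_midpoint(self):
        assert natural_break_pri([0.95, 0.92, 0.55, 0.50]) \
            == pytest.approx(0.735)

    def test_equal_values_fall_back(self):
        assert natural_break_pri([0.8, 0.8, 0.8]) == 0.70

    def test_extreme_gap_clamped_to_window(self):
        assert natural_break_pri([1.0, 0.0]) == pytest.approx(0.5)

    def test_no_values_rejected(self):
        with pytest.raises(ValidationError):
            natural_break_pri([])


# ---------------------------------------------------------------------------
# Quine-McCluskey
# ---------------------------------------------------------------------------

def _covers(cover, corner):
    return any(all(v is None or v == c for v, c in zip(imp, corner))
               for imp in cover)


class TestQuineMcCluskey:
    def test_adjacent_minterms_merge(self):
        _, cover = quine_mccluskey({(1, 1), (1, 0)})
        assert cover == [(1, None)]

    def test_three_minterm_example_equivalent_to_brute_force(self):
        onset = {(1, 1, 1), (1, 1, 0), (1, 0, 1)}
        _, cover = quine_mccluskey(onset)
        for corner in itertools.product((0, 1), repeat=3):
            assert _covers(cover, corner) == (corner in onset)

    def test_complete_onset_collapses_to_tautology(self):
        onset = set(itertools.product((0, 1), repeat=3))
        _, cover = quine_mccluskey(onset)
        assert cover == [(None, None, None)]

    def test_empty_onset_yields_empty_cover(self):
        primes, cover = quine_mccluskey(set())
        assert primes == set() and cover == []

    def test_dontcares_simplify_but_are_not_required(self):
        _, cover = quine_mccluskey({(1, 1)}, dontcare={(1, 0)})
        assert cover == [(1, None)]

    @given(st.integers(min_value=0, max_value=2 ** 8 - 1),
           st.integers(min_value=0, max_value=2 ** 8 - 1))
    @settings(max_examples=60, deadline=None)
    def test_cover_semantics_against_sympy(self, onset_bits, dc_bits):
        """The chosen cover is TRUE on the onset, FALSE on the offset, and
        logically equivalent to an independent SOP minimization."""
        sympy = pytest.importorskip("sympy")
        from sympy import symbols
        from sympy.logic import SOPform

        k = 3
        corners = list(itertools.product((0, 1), repeat=k))
        onset = {c for i, c in enumerate(corners) if onset_bits >> i & 1}
        dontcare = {c for i, c in enumerate(corners)
                    if dc_bits >> i & 1} - onset
        if not onset:
            return
        _, cover = quine_mccluskey(onset, dontcare)
        offset = set(corners) - onset - dontcare
        for c in onset:
            assert _covers(cover, c)
        for c in offset:
            assert not _covers(cover, c)
        # equivalence with sympy's minimization on the free corners
        syms = symbols(f"a:{k}")
        expr = SOPform(syms, [list(c) for c in onset],
                       [list(c) for c in dontcare])
        for c in corners:
            if c in dontcare:
                continue
            env = dict(zip(syms, [bool(v) for v in c]))
            assert bool(expr.subs(env)) == _covers(cover, c)


# ---------------------------------------------------------------------------
# solutions
# ---------------------------------------------------------------------------

def _table_from_codes(conditions, codes, cons_threshold=0.8):
    """Build a TruthTable directly from corner -> code assignments."""
    rows = []
    for corner, code in codes.items():
        n = 1 if code in (0, 1) else 0
        rows.append(fsqca.TruthTableRow(corner, n, 1.0 if code == 1 else 0.0,
                                        1.0 if code == 1 else 0.0, code))
    return fsqca.TruthTable(conditions, rows, 1, cons_threshold, 0.7)


class TestDeriveSolutions:
    def test_counterfactual_worked_example(self):
        codes = {(1, 1): 1, (1, 0): "remainder", (0, 0): 0, (0, 1): 0}
        table = _table_from_codes(["A", "B"], codes)
        sols = derive_solutions(table, {"A": "present", "B": "none"})
        assert sols["parsimonious"].recipe_labels() == ["A"]
        assert sols["intermediate"].recipe_labels() == ["A"]
        assert sols["complex"].recipe_labels() == ["A*B"]
        assert sols["intermediate"].recipes[0].core == {"A"}

    def test_no_remainders_collapses_all_solution_types(self):
        codes = {(1, 1): 1, (1, 0): 1, (0, 0): 0, (0, 1): 0}
        table = _table_from_codes(["A", "B"], codes)
        sols = derive_solutions(table, {"A": "present"})
        labels = {k: s.recipe_labels() for k, s in sols.items()}
        assert labels["complex"] == labels["parsimonious"] \
            == labels["intermediate"] == ["A"]

    def test_all_none_expectations_fall_back_to_complex(self):
        codes = {(1, 1): 1, (1, 0): "remainder", (0, 0): 0, (0, 1): 0}
        table = _table_from_codes(["A", "B"], codes)
        sols = derive_solutions(table, {"A": "none", "B": "none"})
        assert sols["intermediate"].recipe_labels() \
            == sols["complex"].recipe_labels() == ["A*B"]

    def test_disagreeing_remainder_is_a_difficult_counterfactual(self):
        codes = {(1, 1): 1, (1, 0): "remainder", (0, 0): 0, (0, 1): 0}
        table = _table_from_codes(["A", "B"], codes)
        sols = derive_solutions(table, {"A": "present", "B": "present"})
        # the remainder A*~B contradicts B:present, so it is not admitted
        assert sols["intermediate"].recipe_labels() == ["A*B"]
        assert sols["parsimonious"].recipe_labels() == ["A"]

    def test_unknown_expectation_condition_rejected(self):
        table = _table_from_codes(["A", "B"], {(1, 1): 1})
        with pytest.raises(ValidationError):
            derive_solutions(table, {"Q": "present"})

    def test_intermediate_sandwiched_between_parsimonious_and_complex(self):
        rng = np.random.Generator(np.random.PCG64(31))
        conds = ["A", "B", "C"]
        corners = list(itertools.product((0, 1), repeat=3))
        for trial in range(30):
            codes = {c: rng.choice([1, 0, "remainder"]) for c in corners}
            if not any(v == 1 for v in codes.values()):
                continue
            table = _table_from_codes(conds, codes)
            sols = derive_solutions(
                table, {"A": "present", "B": "absent", "C": "none"})
            for rec in sols["intermediate"].recipes:
                assert any(p.subsumes(rec)
                           for p in sols["parsimonious"].recipes)


class TestSolutionStatistics:
    def _matrix(self, seed=3, n=20):
        rng = np.random.Generator(np.random.PCG64(seed))
        df = pd.DataFrame(rng.uniform(0.05, 0.95, (n, 3)),
                          columns=["A", "B", "Y"])
        return FuzzyCaseMatrix(df, ["A", "B"], "Y")

    def test_single_recipe_unique_equals_raw(self):
        matrix = self._matrix()
        sol = fsqca.QCASolution("complex", [fsqca.Recipe({"A": 1})])
        solution_statistics(sol, matrix)
        assert sol.recipes[0].unique_coverage \
            == pytest.approx(sol.recipes[0].raw_coverage)

    def test_duplicate_recipes_have_zero_unique_coverage(self):
        matrix = self._matrix()
        sol = fsqca.QCASolution(
            "complex", [fsqca.Recipe({"A": 1}), fsqca.Recipe({"A": 1})])
        solution_statistics(sol, matrix)
        for rec in sol.recipes:
            assert rec.unique_coverage == pytest.approx(0.0, abs=1e-12)

    def test_two_case_worked_arithmetic(self):
        df = pd.DataFrame({"A": [0.2, 0.8], "Y": [0.4, 0.6]},
                          index=["c0", "c1"])
        matrix = FuzzyCaseMatrix(df, ["A"], "Y")
        sol = fsqca.QCASolution("complex", [fsqca.Recipe({"A": 1})])
        solution_statistics(sol, matrix)
        assert sol.recipes[0].consistency == pytest.approx(0.8)
        assert sol.recipes[0].raw_coverage == pytest.approx(0.8)

    def test_unique_coverages_sum_below_solution_coverage(self):
        matrix = self._matrix(seed=17, n=40)
        sol = fsqca.QCASolution("complex", [fsqca.Recipe({"A": 1}),
                                            fsqca.Recipe({"B": 0}),
                                            fsqca.Recipe({"A": 0, "B": 1})])
        solution_statistics(sol, matrix)
        assert sum(r.unique_coverage for r in sol.recipes) \
            <= sol.coverage + 1e-12
        for rec in sol.recipes:
            assert rec.unique_coverage <= rec.raw_coverage + 1e-12
        assert sol.coverage >= max(r.raw_coverage for r in sol.recipes) - 1e-12


class TestRobustness:
    def _planted_matrix(self, seed=2, n=40):
        from regioncoord.synthetic import QCAPlant, generate_qca_cases
        return generate_qca_cases(QCAPlant(recipes=[{"Z6": 1, "Z7": 1}],
                                           n_cases=n, noise=0.0, seed=seed))

    def test_zero_noise_plant_survives_scan_unchanged(self):
        rep = robustness_scan(self._planted_matrix(), thresholds=(0.75, 0.80,
                                                                  0.85))
        assert rep.all_same()

    def test_baseline_only_scan_is_identity(self):
        rep = robustness_scan(self._planted_matrix(), thresholds=(0.80,))
        assert set(rep.entries["threshold"]) == {0.80}
        assert rep.all_same()

    def test_threshold_one_may_empty_the_onset(self):
        rng = np.random.Generator(np.random.PCG64(8))
        df = pd.DataFrame(rng.uniform(0.05, 0.95, (25, 3)),
                          columns=["A", "B", "Y"])
        matrix = FuzzyCaseMatrix(df, ["A", "B"], "Y")
        rep = robustness_scan(matrix, thresholds=(0.80, 1.0),
                              pri_threshold=0.7)
        row = rep.entries[(rep.entries.threshold == 1.0)
                          & (rep.entries.solution_type == "parsimonious")]
        assert row["recipes"].iloc[0] == "(none)" or \
            not row["same_as_baseline"].iloc[0]

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(DomainError):
            robustness_scan(self._planted_matrix(), thresholds=(0.4,))
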