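"""Fuzzy-set Qualitative Comparative Analysis (fsQCA), from scratch.

Implements the full configurational workflow: direct calibration of raw
condition values into fuzzy memberships using quartile anchors, necessity
analysis, truth-table construction with frequency / raw-consistency / PRI
screens, Quine-McCluskey logical minimization with Petrick-style exact
covering, the three canonical solution types (complex, parsimonious,
intermediate with directional expectations), core/peripheral labeling of
literals, consistency and raw/unique coverage bookkeeping, and a
consistency-threshold robustness scan.

Set-theoretic statistics follow the standard fuzzy-inclusion formulas:
sufficiency consistency of X for Y is sum(min(x,y))/sum(x), coverage is
sum(min(x,y))/sum(y), and necessity swaps the two denominators.  PRI
(proportional reduction in inconsistency) subtracts the mass a row shares
with both the outcome and its negation from numerator and denominator.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CalibrationError, DomainError, ValidationError

#: default condition set: subsystem scores kept after dropping the three
#: lowest-weight first-order blocks (economic structure, efficiency,
#: public investment)
DEFAULT_CONDITIONS = ["Z1", "Z5", "Z6", "Z7", "Z8"]

TIE_EPS = 1e-3
MAX_CONDITIONS = 12

NECESSITY_CONSISTENCY_CUT = 0.9
NECESSITY_COVERAGE_CUT = 0.5


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationAnchors:
    """Full-membership / crossover / full-non-membership anchors."""

    full: float
    crossover: float
    non: float

    def __post_init__(self):
        if not (self.non < self.crossover < self.full):
            raise CalibrationError(
                f"anchors must satisfy non < crossover < full, got "
                f"({self.non}, {self.crossover}, {self.full})"
            )


def quartile_anchors(values, name: str = "") -> CalibrationAnchors:
    """Anchors at the 75th / 50th / 25th percentiles of the observed values.

    Percentiles use linear interpolation between order statistics (the
    p-th percentile sits at rank 1 + (n-1)p/100).
    """
    arr = np.asarray(values, dtype=float)
    if len(np.unique(arr)) < 4:
        raise CalibrationError(
            f"calibration of {name or 'values'} needs >= 4 distinct values"
        )
    q75, q50, q25 = np.percentile(arr, [75, 50, 25])
    if not (q25 < q50 < q75):
        raise CalibrationError(
            f"quartile anchors of {name or 'values'} are not strictly ordered "
            f"(heavy ties): ({q25}, {q50}, {q75})"
        )
    return CalibrationAnchors(full=float(q75), crossover=float(q50), non=float(q25))


def calibrate(values, anchors: CalibrationAnchors, scaling: str = "three",
              tie_eps: float = TIE_EPS) -> np.ndarray:
    """Direct-method calibration of raw values into fuzzy memberships.

    Log-odds are piecewise linear in the raw value: L(x) = s*(x-crossover)/
    (full-crossover) above the crossover and s*(x-crossover)/(crossover-non)
    below it, mapped through the logistic.  ``scaling="three"`` uses s = 3
    (anchor memberships ~0.953/0.047); ``scaling="log19"`` uses s = ln 19
    (anchors at exactly 0.95/0.05).  Values at exactly the crossover are
    nudged to 0.5 + ``tie_eps`` so every case falls on one side of each
    truth-table dichotomy.
    """
    if scaling == "three":
        s = 3.0
    elif scaling == "log19":
        s = float(np.log(19.0))
    else:
        raise ValueError(f"scaling must be 'three' or 'log19', got {scaling!r}")
    x = np.asarray(values, dtype=float)
    up = s * (x - anchors.crossover) / (anchors.full - anchors.crossover)
    down = s * (x - anchors.crossover) / (anchors.crossover - anchors.non)
    logodds = np.where(x >= anchors.crossover, up, down)
    m = 1.0 / (1.0 + np.exp(-logodds))
    ties = np.isclose(m, 0.5)
    if ties.any():
        warnings.warn(f"{int(ties.sum())} case(s) at the crossover adjusted to "
                      f"0.5+{tie_eps}", stacklevel=2)
        m = np.where(ties, 0.5 + tie_eps, m)
    return np.clip(m, 1e-6, 1.0 - 1e-6)


def negate(memberships):
    """Fuzzy negation 1 - m (elementwise involution)."""
    m = np.asarray(memberships, dtype=float)
    if ((m < 0) | (m > 1)).any():
        raise DomainError("memberships must lie in [0,1]")
    return 1.0 - m


def adjust_ties(memberships, tie_eps: float = TIE_EPS):
    """Nudge exact-0.5 memberships to 0.5 + tie_eps (crossover tie rule)."""
    m = np.asarray(memberships, dtype=float)
    return np.where(m == 0.5, 0.5 + tie_eps, m)


# ---------------------------------------------------------------------------
# case matrix
# ---------------------------------------------------------------------------

@dataclass
class FuzzyCaseMatrix:
    """Calibrated memberships of the conditions and the outcome.

    ``data`` is indexed by case id with one column per condition plus the
    outcome column.  No membership is exactly 0.5 (the tie rule is applied
    on construction) and all lie in [0,1].
    """

    data: pd.DataFrame
    conditions: list[str]
    outcome: str

    def __post_init__(self):
        missing = [c for c in self.conditions + [self.outcome]
                   if c not in self.data.columns]
        if missing:
            raise ValidationError(f"case matrix lacks columns: {missing}")
        vals = self.data[self.conditions + [self.outcome]]
        arr = vals.to_numpy(dtype=float)
        if ((arr < 0) | (arr > 1)).any():
            raise DomainError("memberships must lie in [0,1]")
        if (arr == 0.5).any():
            self.data = self.data.copy()
            for col in self.conditions + [self.outcome]:
                self.data[col] = adjust_ties(self.data[col].to_numpy())

    @property
    def cases(self) -> list:
        return list(self.data.index)

    def condition_matrix(self) -> np.ndarray:
        return self.data[self.conditions].to_numpy(dtype=float)

    def outcome_vector(self) -> np.ndarray:
        return self.data[self.outcome].to_numpy(dtype=float)

    def with_negated_outcome(self) -> "FuzzyCaseMatrix":
        df = self.data.copy()
        name = f"~{self.outcome}"
        df[name] = negate(df[self.outcome].to_numpy())
        return FuzzyCaseMatrix(df, list(self.conditions), name)


def calibrate_matrix(raw: pd.DataFrame, conditions: list[str], outcome: str,
                     scaling: str = "three",
                     anchors_override: dict[str, CalibrationAnchors] | None = None,
                     ) -> FuzzyCaseMatrix:
    """Quartile-calibrate every condition and the outcome of a raw case table.

    The outcome is calibrated with the same quartile rule as the conditions
    unless an explicit anchor override is supplied for it.
    """
    anchors_override = anchors_override or {}
    out = pd.DataFrame(index=raw.index)
    for col in conditions + [outcome]:
        a = anchors_override.get(col) or quartile_anchors(raw[col], name=col)
        out[col] = calibrate(raw[col].to_numpy(dtype=float), a, scaling=scaling)
    return FuzzyCaseMatrix(out, list(conditions), outcome)


# ---------------------------------------------------------------------------
# necessity
# ---------------------------------------------------------------------------

def necessity_metrics(x, y) -> tuple[float, float]:
    """(consistency, coverage) of condition X as necessary for outcome Y.

    consistency = sum(min(x,y))/sum(y); coverage = sum(min(x,y))/sum(x).
    Either is NaN when its denominator is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    overlap = np.minimum(x, y).sum()
    cons = overlap / y.sum() if y.sum() > 0 else float("nan")
    cov = overlap / x.sum() if x.sum() > 0 else float("nan")
    return float(cons), float(cov)


def sufficiency_metrics(x, y) -> tuple[float, float]:
    """(consistency, coverage) of X as sufficient for Y: the necessity
    formulas with the roles of X and Y swapped."""
    cons, cov = necessity_metrics(y, x)
    return cons, cov


def is_necessary(consistency: float, coverage: float) -> bool:
    """Decision rule: necessary iff consistency >= 0.9 and coverage >= 0.5."""
    return (not np.isnan(consistency) and not np.isnan(coverage)
            and consistency >= NECESSITY_CONSISTENCY_CUT
            and coverage >= NECESSITY_COVERAGE_CUT)


def necessity_analysis(matrix: FuzzyCaseMatrix,
                       outcome: str | None = None) -> pd.DataFrame:
    """Necessity consistency/coverage of every condition and its negation."""
    outcome = outcome or matrix.outcome
    if outcome not in matrix.data.columns:
        raise ValidationError(f"outcome {outcome!r} not in case matrix")
    y = matrix.data[outcome].to_numpy(dtype=float)
    rows = []
    for cond in matrix.conditions:
        x = matrix.data[cond].to_numpy(dtype=float)
        for label, xv in ((cond, x), (f"~{cond}", negate(x))):
            cons, cov = necessity_metrics(xv, y)
            rows.append({"condition": label, "consistency": cons,
                         "coverage": cov, "necessary": is_necessary(cons, cov)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# truth table
# ---------------------------------------------------------------------------

@dataclass
class TruthTableRow:
    corner: tuple          # 0/1 per condition
    n_cases: int           # cases with row membership > 0.5
    raw_consistency: float
    pri: float
    outcome_code: object   # 1, 0, or "remainder"


@dataclass
class TruthTable:
    conditions: list[str]
    rows: list[TruthTableRow]
    freq_threshold: int
    cons_threshold: float
    pri_threshold: float

    @property
    def onset(self) -> set:
        return {r.corner for r in self.rows if r.outcome_code == 1}

    @property
    def offset(self) -> set:
        return {r.corner for r in self.rows if r.outcome_code == 0}

    @property
    def remainders(self) -> set:
        return {r.corner for r in self.rows if r.outcome_code == "remainder"}

    def observed(self) -> list[TruthTableRow]:
        return [r for r in self.rows if r.n_cases >= self.freq_threshold]

    def frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = dict(zip(self.conditions, r.corner))
            rec.update(n_cases=r.n_cases, raw_consistency=r.raw_consistency,
                       pri=r.pri, outcome_code=r.outcome_code)
            recs.append(rec)
        return pd.DataFrame(recs)


def _row_membership(cond: np.ndarray, corner: tuple) -> np.ndarray:
    lits = np.where(np.asarray(corner, dtype=bool), cond, 1.0 - cond)
    return lits.min(axis=1)


def natural_break_pri(pri_values, cons_threshold: float = 0.80,
                      window_low: float = 0.5,
                      fallback: float = 0.70) -> float:
    """PRI cutoff at the midpoint of the largest gap among observed PRI
    values, restricted to the [window_low, cons_threshold] window.

    Gaps between consecutive sorted distinct PRI values are candidates when
    they intersect the window; the winning cutoff is the midpoint of the
    widest such gap, clamped into the window.  With no usable gap (all
    values equal, or every gap outside the window) the documented fallback
    of 0.70 is returned.
    """
    vals = sorted(set(float(v) for v in pri_values if not np.isnan(v)))
    if not vals:
        raise ValidationError("no observed PRI values")
    best = None  # (gap, cutoff)
    for a, b in zip(vals[:-1], vals[1:]):
        if b <= window_low or a >= cons_threshold:
            continue
        cutoff = min(max((a + b) / 2.0, window_low), cons_threshold)
        gap = b - a
        if best is None or gap > best[0]:
            best = (gap, cutoff)
    return best[1] if best is not None else fallback


def build_truth_table(matrix: FuzzyCaseMatrix, outcome: str | None = None,
                      freq_threshold: int = 1, cons_threshold: float = 0.80,
                      pri_threshold: float | str = "auto") -> TruthTable:
    """Assign cases to the 2^k corners and code each corner 1/0/remainder.

    Row membership of a case is the minimum over the k literal memberships;
    a case belongs to the corner where that membership exceeds 0.5 (exactly
    one corner per case, since no membership is exactly 0.5).  A corner is
    coded 1 only if it is observed (n_cases >= ``freq_threshold``), its raw
    consistency reaches ``cons_threshold`` and its PRI reaches
    ``pri_threshold`` ("auto" = natural-break cutoff over observed rows).
    """
    outcome = outcome or matrix.outcome
    k = len(matrix.conditions)
    if k > MAX_CONDITIONS:
        raise ValidationError(f"{k} conditions exceed the 2^k guard "
                              f"(max {MAX_CONDITIONS})")
    cond = matrix.condition_matrix()
    y = matrix.data[outcome].to_numpy(dtype=float)
    not_y = 1.0 - y

    stats = []
    for corner in itertools.product((0, 1), repeat=k):
        rm = _row_membership(cond, corner)
        n = int((rm > 0.5).sum())
        s_rm = rm.sum()
        s_y = np.minimum(rm, y).sum()
        s_both = np.minimum(np.minimum(rm, y), not_y).sum()
        cons = s_y / s_rm if s_rm > 0 else float("nan")
        denom = s_rm - s_both
        pri = (s_y - s_both) / denom if denom > 0 else 0.0
        stats.append((corner, n, float(cons), float(pri)))

    if pri_threshold == "auto":
        observed_pri = [p for (_, n, _, p) in stats if n >= freq_threshold]
        pri_cut = (natural_break_pri(observed_pri, cons_threshold)
                   if len(observed_pri) >= 2 else 0.70)
    else:
        pri_cut = float(pri_threshold)

    rows = []
    for corner, n, cons, pri in stats:
        if n < freq_threshold:
            code = "remainder"
        elif cons >= cons_threshold and pri >= pri_cut:
            code = 1
        else:
            code = 0
        rows.append(TruthTableRow(corner, n, cons, pri, code))
    total = sum(r.n_cases for r in rows)
    if total != len(matrix.cases):
        raise ValidationError(
            f"case-to-corner assignment lost cases: {total} != {len(matrix.cases)}"
        )
    return TruthTable(list(matrix.conditions), rows, freq_threshold,
                      cons_threshold, pri_cut)


# ---------------------------------------------------------------------------
# Quine-McCluskey minimization
# ---------------------------------------------------------------------------

def _mergeable(a: tuple, b: tuple):
    """Merge two implicants differing in exactly one specified position."""
    diff = None
    for i, (u, v) in enumerate(zip(a, b)):
        if u != v:
            if u is None or v is None or diff is not None:
                return None
            diff = i
    if diff is None:
        return None
    merged = list(a)
    merged[diff] = None
    return tuple(merged)


def _implicant_covers(imp: tuple, corner: tuple) -> bool:
    return all(v is None or v == c for v, c in zip(imp, corner))


def _implicant_corners(imp: tuple):
    free = [i for i, v in enumerate(imp) if v is None]
    for bits in itertools.product((0, 1), repeat=len(free)):
        corner = list(imp)
        for i, b in zip(free, bits):
            corner[i] = b
        yield tuple(corner)


def prime_implicants(onset: set, dontcare: set) -> set:
    """All prime implicants of onset u dontcare by iterative pairwise merging."""
    current = {tuple(m) for m in onset | dontcare}
    primes: set = set()
    while current:
        merged_into: set = set()
        used: set = set()
        for a, b in itertools.combinations(sorted(current, key=str), 2):
            m = _mergeable(a, b)
            if m is not None:
                merged_into.add(m)
                used.add(a)
                used.add(b)
        primes |= current - used
        current = merged_into
    return primes


def _literal_count(imp: tuple) -> int:
    return sum(1 for v in imp if v is not None)


def minimal_covers(primes: set, onset: set) -> list[list[tuple]]:
    """All minimum-cardinality covers of the onset (Petrick-style exhaustive
    search; the condition space here is small, so the search is exact)."""
    if not onset:
        return [[]]
    relevant = [p for p in primes if any(_implicant_covers(p, m) for m in onset)]
    relevant.sort(key=str)
    for size in range(1, len(relevant) + 1):
        covers = []
        for combo in itertools.combinations(relevant, size):
            if all(any(_implicant_covers(p, m) for p in combo) for m in onset):
                covers.append(list(combo))
        if covers:
            return covers
    return []


def quine_mccluskey(onset: set, dontcare: set = frozenset()
                    ) -> tuple[set, list[tuple]]:
    """Minimize a Boolean function given onset and don't-care corners.

    Returns (all prime implicants, chosen minimal cover).  Ties between
    equal-size covers are broken by fewer total literals, then by
    lexicographic order of the implicant tuples.  An empty onset yields an
    empty cover ("no sufficient configuration"); a complete onset collapses
    to the empty product (tautology), returned as the all-None implicant.
    """
    onset = {tuple(m) for m in onset}
    dontcare = {tuple(m) for m in dontcare} - onset
    if not onset:
        return set(), []
    primes = prime_implicants(onset, dontcare)
    covers = minimal_covers(primes, onset)
    covers.sort(key=lambda c: (sum(_literal_count(p) for p in c),
                               [str(p) for p in c]))
    return primes, covers[0]


# ---------------------------------------------------------------------------
# solutions
# ---------------------------------------------------------------------------

@dataclass
class Recipe:
    """One implicant of a solution: condition -> 1 (present) / 0 (absent),
    unmentioned conditions are don't-cares; ``core`` marks core literals."""

    literals: dict[str, int]
    core: set[str] = field(default_factory=set)
    consistency: float = float("nan")
    raw_coverage: float = float("nan")
    unique_coverage: float = float("nan")

    def membership(self, matrix: FuzzyCaseMatrix) -> np.ndarray:
        if not self.literals:  # empty product: tautology
            return np.ones(len(matrix.cases))
        cols = []
        for cond, v in self.literals.items():
            m = matrix.data[cond].to_numpy(dtype=float)
            cols.append(m if v == 1 else 1.0 - m)
        return np.minimum.reduce(cols)

    def label(self) -> str:
        parts = []
        for cond, v in self.literals.items():
            parts.append(cond if v == 1 else f"~{cond}")
        return "*".join(parts) if parts else "TRUE"

    def subsumes(self, other: "Recipe") -> bool:
        """True if this (more general) recipe's literals are a subset of
        ``other``'s with matching directions."""
        return all(other.literals.get(c) == v for c, v in self.literals.items())


def _recipe_from_implicant(imp: tuple, conditions: list[str]) -> Recipe:
    return Recipe({c: v for c, v in zip(conditions, imp) if v is not None})


@dataclass
class QCASolution:
    solution_type: str  # complex | parsimonious | intermediate
    recipes: list[Recipe]
    prime_implicants: set = field(default_factory=set)
    consistency: float = float("nan")
    coverage: float = float("nan")

    def membership(self, matrix: FuzzyCaseMatrix) -> np.ndarray:
        if not self.recipes:
            return np.zeros(len(matrix.cases))
        return np.maximum.reduce([r.membership(matrix) for r in self.recipes])

    def recipe_labels(self) -> list[str]:
        return [r.label() for r in self.recipes]

    def covers_corner(self, corner: tuple, conditions: list[str]) -> bool:
        lookup = dict(zip(conditions, corner))
        return any(all(lookup[c] == v for c, v in r.literals.items())
                   for r in self.recipes)


def _easy_counterfactuals(onset: set, remainders: set, conditions: list[str],
                          expectations: dict[str, str],
                          parsimonious_cover: list[tuple]) -> set:
    """Remainders admissible as easy counterfactuals.

    A remainder qualifies when (a) it lies inside the parsimonious solution
    and (b) it differs from some coded-1 corner only in conditions whose
    directional expectation is either unstated ("none") or matches the
    remainder's own literal there.
    """
    exp_val = {"present": 1, "absent": 0}
    easy = set()
    for r in remainders:
        if not any(_implicant_covers(p, r) for p in parsimonious_cover):
            continue
        for o in onset:
            ok = True
            for i, cond in enumerate(conditions):
                if r[i] != o[i]:
                    e = expectations.get(cond, "none")
                    if e != "none" and exp_val[e] != r[i]:
                        ok = False
                        break
            if ok:
                easy.add(r)
                break
    return easy


def derive_solutions(table: TruthTable,
                     expectations: dict[str, str] | None = None
                     ) -> dict[str, QCASolution]:
    """Complex, parsimonious and intermediate solutions of a truth table.

    Complex excludes all remainders; parsimonious admits every remainder as
    a don't-care; intermediate admits only the easy counterfactuals given
    the directional ``expectations`` (condition -> present/absent/none).
    With no stated expectations (all "none") the intermediate solution
    equals the complex one.  Core literals of an intermediate recipe are
    those shared with a parsimonious recipe that subsumes it; the rest are
    peripheral.
    """
    expectations = expectations or {}
    unknown = set(expectations) - set(table.conditions)
    if unknown:
        raise ValidationError(f"expectations reference unknown conditions: "
                              f"{sorted(unknown)}")
    for cond, e in expectations.items():
        if e not in ("present", "absent", "none"):
            raise ValidationError(f"bad expectation {e!r} for {cond}")
    onset, remainders = table.onset, table.remainders

    pr_c, cover_c = quine_mccluskey(onset, set())
    pr_p, cover_p = quine_mccluskey(onset, remainders)
    if all(expectations.get(c, "none") == "none" for c in table.conditions):
        pr_i, cover_i = pr_c, cover_c
    else:
        easy = _easy_counterfactuals(onset, remainders, table.conditions,
                                     expectations, cover_p)
        pr_i, cover_i = quine_mccluskey(onset, easy)

    conds = table.conditions
    sols = {
        "complex": QCASolution("complex",
                               [_recipe_from_implicant(p, conds) for p in cover_c],
                               pr_c),
        "parsimonious": QCASolution("parsimonious",
                                    [_recipe_from_implicant(p, conds) for p in cover_p],
                                    pr_p),
        "intermediate": QCASolution("intermediate",
                                    [_recipe_from_implicant(p, conds) for p in cover_i],
                                    pr_i),
    }
    # core/peripheral labeling on the intermediate recipes
    pars = sols["parsimonious"].recipes
    for rec in sols["intermediate"].recipes:
        for p in pars:
            if p.subsumes(rec):
                rec.core |= set(p.literals)
        rec.core &= set(rec.literals)
    for rec in sols["parsimonious"].recipes:
        rec.core = set(rec.literals)  # parsimonious literals are core by definition
    return sols


def solution_statistics(solution: QCASolution, matrix: FuzzyCaseMatrix,
                        outcome: str | None = None) -> QCASolution:
    """Fill per-recipe and solution-level consistency/coverage in place.

    Recipe membership is the min over its literals; solution membership the
    max over recipes.  Unique coverage of a recipe is the drop in solution
    coverage when that recipe is removed.
    """
    outcome = outcome or matrix.outcome
    y = matrix.data[outcome].to_numpy(dtype=float)
    s_y = y.sum()

    def _stats(member):
        s = member.sum()
        overlap = np.minimum(member, y).sum()
        cons = overlap / s if s > 0 else float("nan")
        cov = overlap / s_y if s_y > 0 else float("nan")
        return float(cons), float(cov)

    full = solution.membership(matrix)
    solution.consistency, solution.coverage = _stats(full)
    for i, rec in enumerate(solution.recipes):
        rec.consistency, rec.raw_coverage = _stats(rec.membership(matrix))
        others = [r for j, r in enumerate(solution.recipes) if j != i]
        if others:
            rest = np.maximum.reduce([r.membership(matrix) for r in others])
            _, cov_rest = _stats(rest)
            rec.unique_coverage = (solution.coverage - cov_rest
                                   if not np.isnan(cov_rest) else float("nan"))
        else:
            rec.unique_coverage = rec.raw_coverage
    return solution


def analyze(matrix: FuzzyCaseMatrix, outcome: str | None = None,
            freq_threshold: int = 1, cons_threshold: float = 0.80,
            pri_threshold: float | str = "auto",
            expectations: dict[str, str] | None = None
            ) -> tuple[TruthTable, dict[str, QCASolution]]:
    """Truth table + all three solution types with statistics filled."""
    table = build_truth_table(matrix, outcome, freq_threshold,
                              cons_threshold, pri_threshold)
    sols = derive_solutions(table, expectations)
    for s in sols.values():
        solution_statistics(s, matrix, outcome)
    return table, sols


# ---------------------------------------------------------------------------
# robustness
# ---------------------------------------------------------------------------

@dataclass
class RobustnessReport:
    baseline: float
    entries: pd.DataFrame  # threshold, solution_type, recipes, same_as_baseline

    def all_same(self) -> bool:
        return bool(self.entries["same_as_baseline"].all())


def robustness_scan(matrix: FuzzyCaseMatrix, outcome: str | None = None,
                    thresholds=(0.75, 0.80, 0.85), baseline: float = 0.80,
                    freq_threshold: int = 1,
                    pri_threshold: float | str = "auto",
                    expectations: dict[str, str] | None = None) -> RobustnessReport:
    """Re-run the sufficiency analysis across consistency thresholds and
    flag whether the solution set changes relative to the baseline."""
    thresholds = sorted(set(float(t) for t in thresholds) | {float(baseline)})
    for t in thresholds:
        if not (0.5 < t <= 1.0):
            raise DomainError(f"consistency threshold {t} outside (0.5, 1]")

    def _solution_sets(cons):
        _, sols = analyze(matrix, outcome, freq_threshold, cons,
                          pri_threshold, expectations)
        return {
            kind: frozenset(frozenset(r.literals.items()) for r in sol.recipes)
            for kind, sol in sols.items()
        }

    base = _solution_sets(baseline)
    rows = []
    for t in thresholds:
        sets_t = base if t == baseline else _solution_sets(t)
        for kind in ("parsimonious", "intermediate"):
            labels = sorted(
                "*".join(f"~{c}" if v == 0 else c for c, v in sorted(lits))
                or "TRUE" for lits in sets_t[kind]
            )
            rows.append({"threshold": t, "solution_type": kind,
                         "recipes": " + ".join(labels) if labels else "(none)",
                         "same_as_baseline": sets_t[kind] == base[kind]})
    return RobustnessReport(baseline, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def configuration_chart(solutions: dict[str, QCASolution],
                        conditions: list[str]) -> str:
    """Text chart of the intermediate solution: ● core present, • peripheral
    present, ⊗ core absent, (⊗) peripheral absent, blank don't-care."""
    inter = solutions["intermediate"]
    width = max([len(c) for c in conditions] + [12])
    header = " " * (width + 2) + "  ".join(
        f"P{i+1}" for i in range(len(inter.recipes)))
    lines = [header]
    for cond in conditions:
        marks = []
        for rec in inter.recipes:
            v = rec.literals.get(cond)
            if v is None:
                marks.append("  ")
            elif v == 1:
                marks.append("● " if cond in rec.core else "• ")
            else:
                marks.append("⊗ " if cond in rec.core else "(⊗)")
        lines.append(f"{cond:<{width}}  " + "  ".join(f"{m:<3}" for m in marks))
    lines.append(f"{'consistency':<{width}}  " + "  ".join(
        f"{r.consistency:.3f}" for r in inter.recipes))
    lines.append(f"{'raw coverage':<{width}}  " + "  ".join(
        f"{r.raw_coverage:.3f}" for r in inter.recipes))
    lines.append(f"{'unique coverage':<{width}}  " + "  ".join(
        f"{r.unique_coverage:.3f}" for r in inter.recipes))
    lines.append(f"solution consistency {inter.consistency:.3f}  "
                 f"solution coverage {inter.coverage:.3f}")
    return "\n".join(lines)
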