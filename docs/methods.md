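# Methods

This note records the models implemented by `regioncoord`, the conventions
chosen where the methodology literature leaves room, and what the synthetic
experiments do and do not demonstrate.

## Entropy-weight scoring

The raw input is a dense county × year × indicator panel. Each indicator is
min–max normalized; positive indicators map their observed minimum to 0 and
maximum to 1, negative indicators are reflected. Two pooling scopes exist:

* `per_year` (default): extrema are taken within each year, so weights and
  scores are cross-sectional — each year is scored against its own spread.
* `pooled`: extrema over all county-years, giving a common scale when the
  interest is cross-year trends in scores themselves.

Characteristic proportions, entropy `E_j = −(1/ln m) Σ p ln p` (with
`0·ln 0 = 0`), and weights `w_j ∝ 1 − E_j` follow the standard entropy-weight
method. Min–max normalization already guarantees nonnegativity, so no
positive shift is applied by default; a shift parameter is unnecessary for
dense panels and deliberately omitted rather than half-supported.

Weight scope is `per_system` by default: the weights of each system block
(economy x1–x7, society x8–x12, healthcare x13–x20) sum to 1, which keeps
each system score U in [0, 1] — a precondition for the coordination degree
and its grade scale to live on [0, 1]. A `global` scope (all 20 weights sum
to 1) is provided because the weighting formula's normalizing sum is
ambiguous between the two readings; results in that mode must be
interpreted on a compressed U scale.

Degenerate (constant) indicator columns carry no discriminating
information: they normalize to 0, receive entropy 1 and weight 0, and emit
a warning. A block whose every indicator is degenerate is an error, not a
silent zero.

Subsystem *condition values* (Z1–Z8) — the inputs to the configurational
analysis — are unweighted means of the normalized member indicators, so a
single-indicator subsystem (Z6) equals its indicator exactly.

## Coupling coordination degree

`C = 3·[(U_EC·U_SO·U_HE)/(U_EC+U_SO+U_HE)³]^(1/3)` is symmetric, lies in
[0, 1], equals 1 iff the three scores are equal and positive, and is 0 when
any score is 0 (including the all-zero case, taken as total disorder).
Computation is done in log space so near-zero scores cannot underflow the
cube. `T` is the α/β/γ-weighted mean (defaults 1/3 each; weights must sum
to 1), and `D = √(C·T)`.

The 10-level grade scale uses half-open intervals [0.0, 0.1), …, [0.9, 1.0]
with the top bin closed. Published versions of this scale typically print
closed-looking brackets on every row, which would double-assign the
boundaries; a partition is required for classification to be a function, and
the half-open convention assigns each boundary to the higher grade (0.7 is
*Intermediate coordination*).

Summary statistics: median is the mean of the two middle order statistics
for even n; the standard deviation is the sample (n−1) estimator with a
population switch (`ddof=0`); CV = std/mean; report tables round half away
from zero at 3 decimals while machine-readable outputs keep full precision.
Grade-band trend statistics count counties at or above a high cut
(default 0.7, Intermediate coordination or above) and strictly below a low
cut (default 0.4, Mild disorder or below); the fold increase
`(N_b − N_a)/N_a` is reported as undefined (None) when the base year count
is 0 rather than inventing a value.

## Fuzzy-set QCA

**Calibration.** Direct-method calibration with quartile anchors: the 75th,
50th and 25th percentiles of the observed values serve as full membership,
crossover, and full non-membership. Percentiles use linear interpolation
between order statistics (the p-th percentile at rank 1 + (n−1)p/100);
anchor values depend on this convention, so it is fixed and tested.
Log-odds are piecewise linear through the three anchors, scaled so the
anchors map to memberships ≈ 0.953/0.5/0.047 (scale factor 3); an exact
`log(19)` scaling (anchors at 0.95/0.05) is available as a flag. Values at
exactly the crossover are nudged to 0.5 + 10⁻³ (logged) so every case falls
on a definite side of each truth-table dichotomy; heavy ties that collapse
the quartiles raise a calibration error naming the variable. The outcome is
calibrated with the same rule as the conditions unless per-variable anchors
are supplied.

**Necessity.** Standard fuzzy inclusion: consistency
`Σ min(x,y)/Σ y`, coverage `Σ min(x,y)/Σ x`, evaluated for every condition
and its negation; a condition is flagged necessary iff consistency ≥ 0.9
and coverage ≥ 0.5. The thresholds are the conventional ones; the formulas
are the standard ones behind them (they are duals of the sufficiency
formulas with x and y swapped, which the tests assert numerically).

**Truth table.** Row membership of a case at a corner is the minimum over
the k literal memberships; each case sits in exactly one corner
(membership > 0.5). A corner is coded 1 when observed at the frequency
threshold (default ≥ 1), raw consistency ≥ 0.80, and PRI ≥ the PRI cutoff;
observed corners failing a screen are coded 0 (this is also how
contradictory rows — consistent with the outcome and its negation — are
resolved); unobserved corners are remainders. PRI =
`(Σ min(r,y) − Σ min(r,y,1−y)) / (Σ r − Σ min(r,y,1−y))`, defined as 0 when
the denominator vanishes; PRI ≤ raw consistency always.

**PRI natural break.** The "natural break" cutoff is operationalized as the
midpoint of the widest gap between consecutive sorted observed PRI values,
restricted to the window [0.5, consistency threshold] (midpoints clamped
into the window); with no usable gap the cutoff falls back to 0.70. The
window keeps the cutoff from drifting below indifference (0.5) or above the
raw-consistency screen it accompanies.

**Minimization.** Quine–McCluskey iterative merging to all prime
implicants, followed by exhaustive (Petrick-style) minimal covering of the
coded-1 corners — exact at the k ≤ 12 guard, trivial at the default k = 5.
Ties between minimum-cardinality covers are broken by fewer total literals,
then lexicographic implicant order, so runs are deterministic. The complex
solution excludes all remainders; the parsimonious solution admits them all
as don't-cares; the intermediate solution admits only *easy
counterfactuals*: remainders inside the parsimonious solution that differ
from some coded-1 corner only in conditions whose directional expectation
is unstated or matches the remainder's own literal. With no stated
expectations the intermediate solution equals the complex one (no theory,
no counterfactuals). Default expectations set all five conditions to
`present` for the positive outcome — each subsystem is theorized to promote
coordination — and to `none` for the negated outcome; both are overridable.

Core literals of an intermediate recipe are those shared with a
parsimonious recipe subsuming it; the rest are peripheral (rendered ● / •
for present, ⊗ / (⊗) for absent in the text chart). Solution statistics use
min-over-literals recipe membership and max-over-recipes solution
membership; unique coverage of a recipe is the drop in solution coverage
when it is removed.

**Robustness.** The scan re-runs the truth table and solutions at
consistency thresholds {0.75, 0.80, 0.85} (baseline 0.80, always included)
and flags per threshold whether the parsimonious and intermediate recipe
sets equal the baseline's.

**Default condition set.** Five of the eight subsystem blocks (Z1 economic
aggregate, Z5 social security, Z6 social assistance, Z7 healthcare
accessibility, Z8 healthcare fairness) form the default condition set, the
outcome being the coordination degree; with roughly 25 analysis cases,
dropping the three remaining first-order blocks keeps the 2^k corner space
commensurate with the case count. Multi-period designs are run as per-year
cross-sections compared descriptively.

## Synthetic data generator

The generator emulates the *structure* of the study system — 86 counties,
3 years, 20 positive indicators, a 25-county mountain/island stratum — not
any real province's magnitudes. Log-values are
`μ(group, indicator) + drift·(t−t₀) + spread·u_i + noise·ε`, with a fixed,
evenly spaced county effect `u_i` (so orderings are deterministic at
noise 0), a negative mountain/island offset on the economy and healthcare
blocks (default 1.2 log units, vs 0.3 on the society block — the stylized
fact that social-insurance coverage gaps are smaller than economic ones),
mild growth drift (0.08/year), and log-normal noise (σ = 0.15). All
randomness flows through a seeded PCG64 generator, so identical spec + seed
reproduce byte-identical panels on any platform.

Case matrices draw condition memberships uniformly on [0.05, 0.95] and set
the outcome to the max–min evaluation of planted recipes plus noise clipped
into [0.001, 0.999]. At noise 0 the planted configurations are exactly
recoverable, which the recovery harness and tests verify; recovery degrades
monotonically with noise (spot-checked at three noise levels).

What passing these tests shows: the pipeline's algebra is correct and the
planted structure is identifiable under clean conditions. What it does not
show: that real yearbook indicators satisfy the generator's independence
and log-normality, that real condition memberships are uniform, or that the
published configurational findings would replicate — the raw source
indicators are not redistributable, so the published solution tables are
not reproduction targets. The packaged coordination-degree matrix is the
one published artifact the package reproduces statistics from directly.

## Known limitations

* No treatment of missing cells (validation rejects them; imputation is out
  of scope), and no alternative weighting schemes (AHP, CRITIC).
* No spatial statistics (autocorrelation, Theil/Gini decomposition) or map
  rendering.
* The mountain/island roster is user-supplied configuration; the package
  ships no authoritative list.
* Crisp-set and multi-value QCA variants are not implemented; time enters
  only as side-by-side yearly cross-sections.
* The published grade-scale boundary convention and the necessity/PRI
  formulas are the field-standard ones; sources that used different
  conventions would differ at interval boundaries and in third-decimal
  statistics.
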